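"""Genetic distances, dyadic covariates, and neighbor-joining trees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefwatch import gendist, synthetic


def geno(pairs):
    return {f"L{i:02d}": p for i, p in enumerate(pairs)}


class TestGenotypeTable:
    TOY = (
        "id,sex,cross,mother_id,father_id,L01,L02\n"
        "m1,F,FF,,,100/102,200/200\n"
        "m2,M,GF,damX,sireX,100/104,212/.\n"
    )

    def test_toy_table_parsed(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.TOY)
        cohort = gendist.parse_genotype_table(p)
        assert len(cohort) == 2
        assert cohort["m1"].genotype["L01"] == (100, 102)
        assert cohort["m2"].cross == "GF"
        assert cohort.external_parents == {"damX", "sireX"}

    def test_partially_missing_locus_flagged(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.TOY)
        cohort = gendist.parse_genotype_table(p)
        assert cohort["m2"].genotype["L02"] is None

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(self.TOY + "m1,F,FF,,,100/100,200/200\n")
        with pytest.raises(ValueError, match="duplicate"):
            gendist.parse_genotype_table(p)

    def test_malformed_pair_names_row_and_locus(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text("id,sex,cross,mother_id,father_id,L01\nm1,F,FF,,,abc\n")
        with pytest.raises(ValueError, match="L01"):
            gendist.parse_genotype_table(p)

    def test_simulator_round_trip(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        gendist.write_genotype_table(cohort, path)
        back = gendist.parse_genotype_table(path)
        assert set(back.ids) == set(cohort.ids)
        for mid in cohort.ids:
            assert back[mid].genotype == cohort[mid].genotype
            assert back[mid].cross == cohort[mid].cross
            assert back[mid].mother_id == cohort[mid].mother_id

    def test_fasta_round_trip(self, cohort, tmp_path):
        path = tmp_path / "haps.fasta"
        gendist.write_haplotype_fasta(cohort, path)
        haps = gendist.read_haplotype_fasta(path)
        for mid, pair in haps.items():
            assert pair == cohort[mid].haplotypes


class TestMicrosatDistances:
    def test_identical_genotypes_zero(self):
        g = geno([(100, 102)] * 13)
        assert gendist.proportion_shared_alleles_distance(g, g) == 0.0
        assert gendist.cavalli_sforza_distance(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles(self):
        g1 = geno([(100, 102)] * 13)
        g2 = geno([(104, 106)] * 13)
        assert gendist.proportion_shared_alleles_distance(g1, g2) == 1.0
        # per-locus chord with cos(theta)=0 is (2/pi)*sqrt(2)
        assert gendist.cavalli_sforza_distance(g1, g2) == pytest.approx(
            (2 / np.pi) * np.sqrt(2), abs=1e-9
        )

    def test_half_shared_heterozygotes(self):
        g1 = geno([(100, 102)] * 13)
        g2 = geno([(102, 104)] * 13)
        assert gendist.proportion_shared_alleles_distance(g1, g2) == pytest.approx(13 / 26)

    def test_missing_loci_pairwise_deleted(self):
        g1 = geno([(100, 100), None, (102, 102)])
        g2 = geno([(100, 100), (104, 104), None])
        assert gendist.proportion_shared_alleles_distance(g1, g2) == 0.0

    def test_no_common_locus_undefined(self):
        assert np.isnan(
            gendist.proportion_shared_alleles_distance(geno([None, (1, 2)]), geno([(1, 2), None]))
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        g1 = geno([tuple(rng.integers(100, 110, 2)) for _ in range(5)])
        g2 = geno([tuple(rng.integers(100, 110, 2)) for _ in range(5)])
        assert gendist.cavalli_sforza_distance(g1, g2) == pytest.approx(
            gendist.cavalli_sforza_distance(g2, g1), abs=1e-12
        )
        assert gendist.proportion_shared_alleles_distance(
            g1, g2
        ) == gendist.proportion_shared_alleles_distance(g2, g1)

    def test_populations_separate_under_divergence(self, pop_model):
        """Mean chord distance between the two source populations exceeds
        the within-population mean (weak but present separation)."""
        rng_f = [synthetic._draw_founder(pop_model, "F", f"f{i}", "F", 1) for i in range(12)]
        rng_g = [synthetic._draw_founder(pop_model, "G", f"g{i}", "M", 1) for i in range(12)]
        within = [
            gendist.cavalli_sforza_distance(a.genotype, b.genotype)
            for pop in (rng_f, rng_g)
            for i, a in enumerate(pop)
            for b in pop[i + 1 :]
        ]
        between = [
            gendist.cavalli_sforza_distance(a.genotype, b.genotype)
            for a in rng_f
            for b in rng_g
        ]
        assert np.mean(between) > np.mean(within)


class TestAminoAcidDistances:
    def test_identical_translations_zero(self):
        s = "ATGGCTGCA"
        assert gendist.aa_p_distance(
            gendist.translate_haplotype(s), gendist.translate_haplotype(s)
        ) == 0.0

    def test_two_of_twenty_sites(self):
        a = "A" * 20
        b = "A" * 18 + "WW"
        assert gendist.aa_p_distance(a, b) == pytest.approx(0.1)

    def test_all_sites_differ(self):
        assert gendist.aa_p_distance("AAAA", "WWWW") == 1.0

    def test_excluded_sites_pairwise_deleted(self):
        # X and gap sites dropped; the remaining comparable sites match
        assert gendist.aa_p_distance("AXA-", "AAAA") == 0.0
        # one mismatch among the two comparable sites
        assert gendist.aa_p_distance("AXA-", "AAWA") == 0.5
        assert np.isnan(gendist.aa_p_distance("XX", "AA"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gendist.aa_p_distance("AA", "AAA")

    def test_gap_and_ambiguity_translation(self):
        assert gendist.translate_haplotype("ATG---GCANNN") == "M-AX"

    def test_individual_pdist_homozygous_cases(self):
        h1 = "ATGGCTGCAACC"
        h2 = "ATGTGGGCAACC"  # one aa difference out of 4
        assert gendist.individual_pdist((h1, h1), (h1, h1)) == 0.0
        assert gendist.individual_pdist((h1, h1), (h2, h2)) == pytest.approx(
            gendist.aa_p_distance(
                gendist.translate_haplotype(h1), gendist.translate_haplotype(h2)
            )
        )

    def test_individual_pdist_is_mean_of_four_pairings(self):
        rng = np.random.default_rng(1)
        model = synthetic.default_population_model(seed=3)
        haps = rng.choice(model.mhc_pool, size=4, replace=False)
        a, b = (haps[0], haps[1]), (haps[2], haps[3])
        t = {h: gendist.translate_haplotype(h) for h in haps}
        brute = np.mean(
            [gendist.aa_p_distance(t[x], t[y]) for x in a for y in b]
        )
        assert gendist.individual_pdist(a, b) == pytest.approx(brute, abs=1e-12)

    def test_mhc_diversity(self):
        h1 = "ATGGCTGCAACC"
        h2 = "ATGTGGGCAACC"
        assert gendist.mhc_diversity((h1, h1)) == 0.0
        assert gendist.mhc_diversity((h1, h2)) == pytest.approx(0.25)


class TestDyadicCovariates:
    @pytest.mark.parametrize(
        "focal, sat, expected",
        [
            ("GF", "GF", "exact"),
            ("FG", "GG", "paternal"),
            ("FG", "FF", "maternal"),
            ("GF", "FG", "none"),
        ],
    )
    def test_match_categories(self, focal, sat, expected):
        assert gendist.match_category(focal, sat) == expected

    def test_full_covariates_from_cohort(self, cohort):
        focals = synthetic.focal_ids(cohort)
        fid = focals[0]
        sats = [m for m in focals if cohort[m].sex != cohort[fid].sex][:4]
        covs = gendist.dyadic_covariates(cohort, fid, sats)
        assert len(covs) == 4
        for c in covs:
            assert not c.missing_parent
            for v in (c.mhc, c.mhcmat, c.mhcpat, c.cas, c.dps, c.mhc_diversity):
                assert np.isfinite(v) and v >= 0.0

    def test_missing_parent_flagged_not_zeroed(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text(
            "id,sex,cross,mother_id,father_id,L01\n"
            "f1,F,GF,damX,sireX,100/102\n"
            "s1,M,FF,,,100/104\n"
        )
        cohort = gendist.parse_genotype_table(p)
        covs = gendist.dyadic_covariates(cohort, "f1", ["s1"])
        assert covs[0].missing_parent
        assert np.isnan(covs[0].caspat) and np.isnan(covs[0].mhcpat)
        assert np.isfinite(covs[0].cas)


def additive_matrix_from_quartet(a, b, c, d, internal):
    """Pairwise path lengths on the unrooted quartet ((A,B),(C,D))."""
    m = np.zeros((4, 4))
    pend = [a, b, c, d]
    for i in range(4):
        for j in range(i + 1, 4):
            same = (i < 2) == (j < 2)
            m[i, j] = m[j, i] = pend[i] + pend[j] + (0 if same else internal)
    return pd.DataFrame(m, index=list("ABCD"), columns=list("ABCD"))


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        dm = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        res = gendist.neighbor_joining_tree(dm)
        tips = {t.name: t.length for t in res.tree.tips()}
        assert tips == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_three_taxa_closed_form(self):
        dm = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        res = gendist.neighbor_joining_tree(dm)
        tips = {t.name: t.length for t in res.tree.tips()}
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        assert tips["A"] == pytest.approx(0.1, abs=1e-12)
        assert tips["B"] == pytest.approx(0.2, abs=1e-12)
        assert tips["C"] == pytest.approx(0.4, abs=1e-12)

    def test_additive_quartet_recovered_exactly(self):
        dm = additive_matrix_from_quartet(1.0, 2.0, 3.0, 4.0, 1.0)
        res = gendist.neighbor_joining_tree(dm)
        ids = list(dm.index)
        patristic = res.tree.tip_tip_distances(ids)
        assert np.allclose(np.asarray(patristic.data), dm.to_numpy(), atol=1e-9)

    def test_non_symmetric_rejected(self):
        m = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            gendist.neighbor_joining_tree(m)

    def test_newick_serialization_parsable(self, cohort):
        ids = [m for m in cohort.ids if cohort[m].mother_id is None][:6]
        dm = gendist.pairwise_matrix(cohort, ids, metric="dps")
        res = gendist.neighbor_joining_tree(dm)
        assert res.newick.endswith(";")
        for mid in ids:
            assert mid in res.newick
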