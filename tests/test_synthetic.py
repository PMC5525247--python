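"""Cohort breeding, movement simulation, and read emission."""

import numpy as np
import pytest

from prefwatch import gendist, rfid, synthetic


class TestCohort:
    def test_default_design_breeds_48_focal_mice(self, cohort):
        focals = synthetic.focal_ids(cohort)
        assert len(focals) == 48
        by = {}
        for fid in focals:
            m = cohort[fid]
            by.setdefault((m.cross, m.sex), []).append(fid)
        assert all(len(v) == 6 for v in by.values())
        assert len(by) == 8  # 4 crosses x 2 sexes

    def test_offspring_alleles_are_mendelian(self, cohort):
        for fid in synthetic.focal_ids(cohort):
            m = cohort[fid]
            mother, father = cohort.parents_of(fid)
            for loc in cohort.loci:
                a_mat, a_pat = m.genotype[loc]
                assert a_mat in mother.genotype[loc]
                assert a_pat in father.genotype[loc]
            assert m.haplotypes[0] in mother.haplotypes
            assert m.haplotypes[1] in father.haplotypes

    def test_cross_code_orders_mother_first(self, cohort):
        for fid in synthetic.focal_ids(cohort):
            m = cohort[fid]
            mother, father = cohort.parents_of(fid)
            assert m.cross[0] == mother.cross[0]
            assert m.cross[1] == father.cross[1]

    def test_same_seed_identical_cohorts(self, pop_model):
        a = synthetic.simulate_cohort(pop_model, synthetic.PedigreeSpec(), seed=5)
        b = synthetic.simulate_cohort(pop_model, synthetic.PedigreeSpec(), seed=5)
        assert a.ids == b.ids
        for mid in a.ids:
            assert a[mid].genotype == b[mid].genotype
            assert a[mid].haplotypes == b[mid].haplotypes

    def test_monomorphic_pools_give_zero_distances(self):
        rng_model = synthetic.default_population_model(
            n_alleles=1, n_haplotypes=1, codon_substitution_rate=0.0, seed=2
        )
        cohort = synthetic.simulate_cohort(rng_model, synthetic.PedigreeSpec(), seed=3)
        ids = cohort.ids[:6]
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                assert gendist.cavalli_sforza_distance(
                    cohort[a].genotype, cohort[b].genotype
                ) == pytest.approx(0.0, abs=1e-12)
                assert gendist.individual_pdist(
                    cohort[a].haplotypes, cohort[b].haplotypes
                ) == 0.0

    def test_invalid_cross_code_rejected(self, pop_model):
        with pytest.raises(ValueError, match="cross code"):
            synthetic.simulate_cohort(
                pop_model, synthetic.PedigreeSpec(cross_codes=("FF", "XX")), seed=0
            )

    def test_empty_allele_pool_rejected(self, pop_model):
        broken = synthetic.PopulationModel(
            loci=pop_model.loci,
            allele_labels=pop_model.allele_labels[:, :0],
            pop_freqs={p: f[:, :0] for p, f in pop_model.pop_freqs.items()},
            mhc_pool=pop_model.mhc_pool,
            mhc_pool_freqs=pop_model.mhc_pool_freqs,
        )
        with pytest.raises(ValueError, match="empty allele pool"):
            synthetic.simulate_cohort(broken, synthetic.PedigreeSpec(), seed=0)

    def test_frequency_vectors_validated(self, pop_model):
        bad_freqs = {p: f.copy() for p, f in pop_model.pop_freqs.items()}
        bad_freqs["F"][0] *= 2.0
        broken = synthetic.PopulationModel(
            loci=pop_model.loci,
            allele_labels=pop_model.allele_labels,
            pop_freqs=bad_freqs,
            mhc_pool=pop_model.mhc_pool,
            mhc_pool_freqs=pop_model.mhc_pool_freqs,
        )
        with pytest.raises(ValueError, match="frequency"):
            broken.validate()

    def test_mhc_pool_in_frame_and_aligned(self, pop_model):
        lengths = {len(h) for h in pop_model.mhc_pool}
        assert lengths == {270}
        for h in pop_model.mhc_pool:
            aa = gendist.translate_haplotype(h)
            assert "*" not in aa and len(aa) == 90


class TestTrajectory:
    def test_zero_hazard_stays_central(self):
        params = synthetic.MovementParams(leave_central_hazard_per_h=0.0)
        truth = synthetic.simulate_trajectory(params, 136.0, np.random.default_rng(0))
        assert list(truth.cages) == [0]
        assert truth.dwell_totals_h[0] == 136.0

    def test_coverage_and_star_topology(self):
        params = synthetic.MovementParams()
        for seed in range(5):
            truth = synthetic.simulate_trajectory(params, 136.0, np.random.default_rng(seed))
            truth.validate()
            assert np.isclose((truth.end_h - truth.start_h).sum(), 136.0, atol=1e-12)
            a, b = truth.cages[:-1], truth.cages[1:]
            assert not np.any((a > 0) & (b > 0))

    def test_determinism_given_seed(self):
        params = synthetic.MovementParams()
        t1 = synthetic.simulate_trajectory(params, 48.0, np.random.default_rng(9))
        t2 = synthetic.simulate_trajectory(params, 48.0, np.random.default_rng(9))
        assert np.array_equal(t1.cages, t2.cages)
        assert np.array_equal(t1.start_h, t2.start_h)

    def test_equal_weights_equal_dwell_shares(self):
        """Long-run dwell shares converge to 1/4 per satellite: mean
        absolute deviation < 0.02 over 200 simulated days."""
        params = synthetic.MovementParams()
        truth = synthetic.simulate_trajectory(params, 200 * 24.0, np.random.default_rng(12))
        shares = truth.dwell_totals_h[1:] / truth.dwell_totals_h[1:].sum()
        assert np.abs(shares - 0.25).mean() < 0.02

    def test_strong_weight_wins_final_preference(self):
        """w = (10,1,1,1): the weighted satellite has the largest dwell in
        at least 95 of 100 replicate runs."""
        params = synthetic.MovementParams(preference_weights=(10.0, 1.0, 1.0, 1.0))
        wins = 0
        for seed in range(100):
            truth = synthetic.simulate_trajectory(params, 136.0, np.random.default_rng(seed))
            wins += int(np.argmax(truth.dwell_totals_h[1:]) == 0)
        assert wins >= 95

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic.MovementParams(satellite_dwell_mean_h=0.0).validate()
        with pytest.raises(ValueError):
            synthetic.MovementParams(preference_weights=(1.0, -1.0, 1.0, 1.0)).validate()
        params = synthetic.MovementParams()
        with pytest.raises(ValueError):
            synthetic.simulate_trajectory(params, 0.0, np.random.default_rng(0))

    def test_diurnal_multiplier_levels(self):
        p = synthetic.MovementParams()
        assert p.diurnal_multiplier(3.0) == p.night_mult
        assert p.diurnal_multiplier(20.0) == p.night_mult
        assert p.diurnal_multiplier(10.0) == p.day_mult
        assert p.diurnal_multiplier(13.0) == p.trough_mult


class TestEmitReads:
    def test_perfect_detection_two_reads_per_transition(self, layout):
        params = synthetic.MovementParams(detection_prob=1.0, lingering_per_min=0.0)
        truth = synthetic.simulate_trajectory(params, 24.0, np.random.default_rng(4))
        reads = synthetic.emit_reads(truth, params, layout, 0)
        assert len(reads) == 2 * (len(truth.cages) - 1)

    def test_zero_detection_empty_stream(self, layout):
        params = synthetic.MovementParams(detection_prob=0.0)
        truth = synthetic.simulate_trajectory(params, 24.0, np.random.default_rng(4))
        assert synthetic.emit_reads(truth, params, layout, 0) == []

    def test_single_interval_trajectory_emits_nothing_without_lingering(self, layout):
        params = synthetic.MovementParams(
            leave_central_hazard_per_h=0.0, lingering_per_min=0.0
        )
        truth = synthetic.simulate_trajectory(params, 24.0, np.random.default_rng(0))
        assert synthetic.emit_reads(truth, params, layout, 0) == []

    def test_reads_time_sorted_origin_before_destination(self, layout):
        params = synthetic.MovementParams(
            transit_s=0.0, detection_prob=1.0, lingering_per_min=0.0
        )
        truth = synthetic.simulate_trajectory(params, layout.span_hours, np.random.default_rng(8))
        reads = synthetic.emit_reads(truth, params, layout, 0)
        ts = [r.timestamp for r in reads]
        assert ts == sorted(ts)
        # zero transit: each transition's two reads share a timestamp, origin first
        for i in range(0, len(reads), 2):
            assert reads[i].timestamp == reads[i + 1].timestamp
        occ = rfid.reconstruct_occupancy(reads, layout)
        assert np.allclose(
            rfid.compute_durations(occ).totals_h[: len(truth.dwell_totals_h)],
            truth.dwell_totals_h,
            atol=1e-9,
        )

    def test_mouse_stream_isolation(self):
        """Per-mouse RNG streams: the same id gives the same stream, a
        different id a different one, under one master seed."""
        a = synthetic.mouse_rng(7, "GF_f1").normal(size=3)
        b = synthetic.mouse_rng(7, "GF_f1").normal(size=3)
        c = synthetic.mouse_rng(7, "GF_f2").normal(size=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
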