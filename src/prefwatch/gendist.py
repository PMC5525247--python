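"""Individual-level genetic distances and dyadic covariates.

Microsatellite side: proportion-of-shared-alleles distance (Dps) and the
Cavalli-Sforza & Edwards chord distance (CAS) between diploid individuals,
treating each individual as a two-allele frequency vector per locus.

MHC side: amino-acid p-distances between translated exon haplotypes —
individual-to-individual distance (mean over the four inter-individual
haplotype pairings), within-individual diversity, and parent-referenced
variants (distance from the focal animal's mother/father to each satellite).

Missing data are handled by pairwise deletion throughout: loci untyped in
either member of a pair, and alignment sites containing X, a stop, or a gap
in either sequence, are dropped from that comparison only. Undefined results
(no comparable sites/loci) propagate as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

CROSS_CODES = ("FF", "GG", "FG", "GF")
#: sites excluded from amino-acid comparisons (ambiguous, gap, stop)
_AA_EXCLUDE = set("X-*")


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class Mouse:
    """One individual: identity, pedigree links, and genetic data.

    ``cross`` is the two-letter population code with the maternal population
    first (e.g. ``GF`` = German mother, French father); founders drawn
    directly from a source population carry the pure code of that population.
    ``genotype`` maps locus name to an unordered allele pair (fragment
    lengths) or ``None`` when the locus is untyped. ``haplotypes`` holds the
    two phased nucleotide sequences of the MHC exon, or ``None``.
    """

    id: str
    sex: str  # "F" or "M"
    cross: str
    mother_id: str | None = None
    father_id: str | None = None
    genotype: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    haplotypes: tuple[str, str] | None = None

    @property
    def pure(self) -> bool:
        return self.cross in ("FF", "GG")

    @property
    def paternal_pop(self) -> str:
        return self.cross[1]

    @property
    def maternal_pop(self) -> str:
        return self.cross[0]


@dataclass
class Cohort:
    """A set of mice keyed by id, with a shared locus list."""

    mice: dict[str, Mouse]
    loci: list[str]
    #: parent ids referenced but not present in the table
    external_parents: set[str] = field(default_factory=set)

    def __getitem__(self, mouse_id: str) -> Mouse:
        return self.mice[mouse_id]

    def __contains__(self, mouse_id: str) -> bool:
        return mouse_id in self.mice

    def __len__(self) -> int:
        return len(self.mice)

    @property
    def ids(self) -> list[str]:
        return list(self.mice)

    def parents_of(self, mouse_id: str) -> tuple[Mouse | None, Mouse | None]:
        m = self.mice[mouse_id]
        mother = self.mice.get(m.mother_id) if m.mother_id else None
        father = self.mice.get(m.father_id) if m.father_id else None
        return mother, father


# ---------------------------------------------------------------------------
# genotype table I/O
# ---------------------------------------------------------------------------

def _parse_allele_pair(cell: str, row: str, locus: str) -> tuple[int, int] | None:
    """Parse ``"a/b"``; a ``.`` on either side marks the locus missing."""
    cell = str(cell).strip()
    parts = cell.split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed allele pair {cell!r} at row {row!r}, locus {locus!r}")
    if "." in (parts[0].strip(), parts[1].strip()) or cell in ("", "nan"):
        return None
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(
            f"malformed allele pair {cell!r} at row {row!r}, locus {locus!r}"
        ) from exc
    if a <= 0 or b <= 0:
        raise ValueError(f"non-positive allele at row {row!r}, locus {locus!r}")
    return (a, b)


def parse_genotype_table(path) -> Cohort:
    """Read a cohort genotype CSV.

    Expected columns: ``id, sex, cross, mother_id, father_id`` followed by
    one column per microsatellite locus holding ``"a/b"`` allele pairs
    (``.`` for a missing allele). Parents referenced by id but absent from
    the table are collected in ``Cohort.external_parents`` rather than
    rejected.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    fixed = ["id", "sex", "cross", "mother_id", "father_id"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table lacks columns {missing}")
    loci = [c for c in df.columns if c not in fixed]
    mice: dict[str, Mouse] = {}
    for _, row in df.iterrows():
        mid = row["id"].strip()
        if mid in mice:
            raise ValueError(f"duplicate id {mid!r} in genotype table")
        geno = {loc: _parse_allele_pair(row[loc], mid, loc) for loc in loci}
        cross = row["cross"].strip()
        if cross not in CROSS_CODES:
            raise ValueError(f"invalid cross code {cross!r} for {mid!r}")
        mice[mid] = Mouse(
            id=mid,
            sex=row["sex"].strip(),
            cross=cross,
            mother_id=row["mother_id"].strip() or None,
            father_id=row["father_id"].strip() or None,
            genotype=geno,
        )
    external = {
        pid
        for m in mice.values()
        for pid in (m.mother_id, m.father_id)
        if pid and pid not in mice
    }
    return Cohort(mice=mice, loci=loci, external_parents=external)


def write_genotype_table(cohort: Cohort, path) -> None:
    rows = []
    for m in cohort.mice.values():
        row = {
            "id": m.id,
            "sex": m.sex,
            "cross": m.cross,
            "mother_id": m.mother_id or "",
            "father_id": m.father_id or "",
        }
        for loc in cohort.loci:
            pair = m.genotype.get(loc)
            row[loc] = "./." if pair is None else f"{pair[0]}/{pair[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_haplotype_fasta(path, cohort: Cohort | None = None) -> dict[str, tuple[str, str]]:
    """Load phased haplotypes from FASTA with ``>{id}|hap{1,2}`` headers.

    If a cohort is given, haplotypes are attached to its mice in place.
    """
    by_id: dict[str, dict[int, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            mid, hap = rec.id.rsplit("|hap", 1)
            hap_no = int(hap)
        except ValueError as exc:
            raise ValueError(f"unrecognised FASTA header {rec.id!r}") from exc
        by_id.setdefault(mid, {})[hap_no] = str(rec.seq).upper()
    out: dict[str, tuple[str, str]] = {}
    for mid, haps in by_id.items():
        if set(haps) != {1, 2}:
            raise ValueError(f"{mid!r} does not have exactly haplotypes 1 and 2")
        out[mid] = (haps[1], haps[2])
    if cohort is not None:
        for mid, pair in out.items():
            if mid in cohort:
                cohort[mid].haplotypes = pair
    return out


def write_haplotype_fasta(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        for m in cohort.mice.values():
            if m.haplotypes is None:
                continue
            for i, seq in enumerate(m.haplotypes, start=1):
                fh.write(f">{m.id}|hap{i}\n{seq}\n")


# ---------------------------------------------------------------------------
# microsatellite distances
# ---------------------------------------------------------------------------

def _shared_loci(g1: dict, g2: dict) -> list[str]:
    return [loc for loc, pair in g1.items() if pair is not None and g2.get(loc) is not None]


def proportion_shared_alleles_distance(g1: dict, g2: dict) -> float:
    """Dps = 1 − (shared alleles) / (2 · loci typed in both).

    Per locus the number of shared alleles is the size of the multiset
    intersection of the two allele pairs (0, 1 or 2). NaN if no locus is
    typed in both individuals.
    """
    loci = _shared_loci(g1, g2)
    if not loci:
        return math.nan
    shared = 0
    for loc in loci:
        a = sorted(g1[loc])
        b = list(sorted(g2[loc]))
        for x in a:
            if x in b:
                b.remove(x)
                shared += 1
    return 1.0 - shared / (2.0 * len(loci))


def cavalli_sforza_distance(g1: dict, g2: dict) -> float:
    """Chord distance between two diploid individuals, averaged over loci.

    Each individual contributes an allele-frequency vector per locus
    (homozygote → 1, heterozygote → 0.5/0.5); with cos θ = Σ_a √(p_a q_a),
    the per-locus chord is (2/π)·√(2(1 − cos θ)). NaN if no shared typed
    locus.
    """
    loci = _shared_loci(g1, g2)
    if not loci:
        return math.nan
    total = 0.0
    for loc in loci:
        p = {a: 0.5 for a in g1[loc]} if g1[loc][0] != g1[loc][1] else {g1[loc][0]: 1.0}
        q = {a: 0.5 for a in g2[loc]} if g2[loc][0] != g2[loc][1] else {g2[loc][0]: 1.0}
        cos_theta = sum(math.sqrt(p[a] * q[a]) for a in p if a in q)
        cos_theta = min(cos_theta, 1.0)
        total += (2.0 / math.pi) * math.sqrt(2.0 * (1.0 - cos_theta))
    return total / len(loci)


# ---------------------------------------------------------------------------
# MHC amino-acid distances
# ---------------------------------------------------------------------------

def translate_haplotype(nt: str, frame: int = 0) -> str:
    """Translate an in-frame nucleotide sequence (standard nuclear code).

    Codons containing a gap translate to ``-``; codons with ambiguous bases
    to ``X``; internal stops are kept as ``*`` (flagged downstream by being
    excluded from comparisons). Trailing bases short of a codon are dropped.
    """
    s = nt[frame:].upper()
    s = s[: len(s) - len(s) % 3]
    if "-" not in s and "N" not in s:
        return str(Seq(s).translate())
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if "-" in codon:
            out.append("-")
        elif "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def aa_p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable aligned sites.

    Sites where either sequence has X, a gap, or a stop are excluded.
    NaN when no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in _AA_EXCLUDE or y in _AA_EXCLUDE:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        return math.nan
    return diffs / compared


def individual_pdist(pair_a: tuple[str, str], pair_b: tuple[str, str]) -> float:
    """Amino-acid p-distance between two diploid individuals.

    Mean over the four inter-individual haplotype pairings
    (a1–b1, a1–b2, a2–b1, a2–b2) of the translated sequences.
    """
    ta = [translate_haplotype(h) for h in pair_a]
    tb = [translate_haplotype(h) for h in pair_b]
    vals = [aa_p_distance(x, y) for x in ta for y in tb]
    return float(np.mean(vals))


def mhc_diversity(pair: tuple[str, str]) -> float:
    """p-distance between an individual's own two translated haplotypes."""
    return aa_p_distance(translate_haplotype(pair[0]), translate_haplotype(pair[1]))


# ---------------------------------------------------------------------------
# dyadic covariates
# ---------------------------------------------------------------------------

def match_category(focal_cross: str, satellite_cross: str) -> str:
    """Population-background match between a focal and a satellite mouse.

    ``exact`` — identical cross codes; ``paternal`` — same paternal letter
    (and not exact); ``maternal`` — same maternal letter (and not exact);
    ``none`` otherwise.
    """
    if focal_cross == satellite_cross:
        return "exact"
    if focal_cross[1] == satellite_cross[1]:
        return "paternal"
    if focal_cross[0] == satellite_cross[0]:
        return "maternal"
    return "none"


@dataclass
class DyadicCovariates:
    """Genetic covariates for one focal × satellite pair."""

    focal_id: str
    satellite_id: str
    mhc: float
    mhcmat: float
    mhcpat: float
    mhc_diversity: float
    cas: float
    casmat: float
    caspat: float
    dps: float
    match_category: str
    focal_pure: bool
    satellite_pure: bool
    missing_parent: bool = False


def dyadic_covariates(
    cohort: Cohort, focal_id: str, satellite_ids: list[str]
) -> list[DyadicCovariates]:
    """Compute the full covariate set for a focal mouse and its satellites.

    Parent-referenced distances (MHCmat/MHCpat, CASmat/CASpat) use the
    focal's mother/father records; if a parent is absent from the cohort the
    corresponding covariates are NaN and the dyad is flagged, never
    zero-filled.
    """
    focal = cohort[focal_id]
    mother, father = cohort.parents_of(focal_id)
    out = []
    for sid in satellite_ids:
        sat = cohort[sid]
        missing = mother is None or father is None
        mhc = (
            individual_pdist(focal.haplotypes, sat.haplotypes)
            if focal.haplotypes and sat.haplotypes
            else math.nan
        )
        mhcmat = (
            individual_pdist(mother.haplotypes, sat.haplotypes)
            if mother is not None and mother.haplotypes and sat.haplotypes
            else math.nan
        )
        mhcpat = (
            individual_pdist(father.haplotypes, sat.haplotypes)
            if father is not None and father.haplotypes and sat.haplotypes
            else math.nan
        )
        out.append(
            DyadicCovariates(
                focal_id=focal_id,
                satellite_id=sid,
                mhc=mhc,
                mhcmat=mhcmat,
                mhcpat=mhcpat,
                mhc_diversity=(
                    mhc_diversity(sat.haplotypes) if sat.haplotypes else math.nan
                ),
                cas=cavalli_sforza_distance(focal.genotype, sat.genotype),
                casmat=(
                    cavalli_sforza_distance(mother.genotype, sat.genotype)
                    if mother is not None
                    else math.nan
                ),
                caspat=(
                    cavalli_sforza_distance(father.genotype, sat.genotype)
                    if father is not None
                    else math.nan
                ),
                dps=proportion_shared_alleles_distance(focal.genotype, sat.genotype),
                match_category=match_category(focal.cross, sat.cross),
                focal_pure=focal.pure,
                satellite_pure=sat.pure,
                missing_parent=missing,
            )
        )
    return out


# ---------------------------------------------------------------------------
# distance matrices and neighbor-joining trees
# ---------------------------------------------------------------------------

def pairwise_matrix(cohort: Cohort, ids: list[str], metric: str = "cas") -> pd.DataFrame:
    """Square symmetric distance matrix over ``ids``.

    metric: ``cas`` (chord), ``dps`` (allele sharing) or ``mhc``
    (individual amino-acid p-distance).
    """
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cohort[ids[i]], cohort[ids[j]]
            if metric == "cas":
                d = cavalli_sforza_distance(a.genotype, b.genotype)
            elif metric == "dps":
                d = proportion_shared_alleles_distance(a.genotype, b.genotype)
            elif metric == "mhc":
                d = individual_pdist(a.haplotypes, b.haplotypes)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class NJResult:
    newick: str
    tree: object  # skbio.TreeNode
    negative_branches_clamped: int


def neighbor_joining_tree(dm: pd.DataFrame) -> NJResult:
    """Unrooted neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to 0
    and counted. Two-taxon input yields the single edge split evenly.
    """
    mat = np.asarray(dm, dtype=float)
    ids = [str(x) for x in dm.index]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix is not square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix has nonzero diagonal")
    if len(ids) == 2:
        half = mat[0, 1] / 2.0
        newick = f"({ids[0]}:{half:.10g},{ids[1]}:{half:.10g});"
        from skbio import TreeNode

        return NJResult(newick=newick, tree=TreeNode.read(StringIO(newick)), negative_branches_clamped=0)
    tree = _skbio_nj(DistanceMatrix(mat, ids), neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    buf = StringIO()
    tree.write(buf, format="newick")
    return NJResult(newick=buf.getvalue().strip(), tree=tree, negative_branches_clamped=clamped)
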