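"""Synthetic experiment generator with known ground truth.

Emulates the whole study pipeline: two weakly diverged source populations
with reciprocal F1 crosses (cross code = maternal letter first), Mendelian
microsatellite genotypes over 13 loci, a shared pool of in-frame MHC exon
haplotypes, star-topology movement of the focal mouse with diurnal
activity modulation, and double-antenna read emission with detection
misses and lingering re-reads.

Movement is a continuous-time alternating renewal process: the focal
mouse leaves the central cage with an exponential waiting time whose
hazard is modulated by a piecewise-constant diurnal multiplier (night /
day / midday trough; lights on 07:00, off 19:00), picks satellite cage k
with probability proportional to an effective weight
w̃_k = w_k·exp(β·z_k) (z = standardized dyadic covariate, e.g. MHCpat),
dwells there for an exponential time with mean scaled by w̃_k, and
returns to the central cage. Satellite→satellite moves never occur.

All event times are quantized to the logger's millisecond resolution, so
a lossless recording (detection probability 1, zero transit time) can be
reconstructed to ground truth up to floating-point round-off.

Each mouse draws from its own RNG stream derived from the master seed by
stable hashing of its id, so editing one animal never perturbs another's
trajectory.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from datetime import timedelta

import numpy as np

from .gendist import CROSS_CODES, Cohort, Mouse
from .rfid import AntennaLayout, AntennaRead

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_MS_PER_H = 3_600_000.0


def _quantize_ms(t_h: float) -> float:
    """Snap a time (hours) to the millisecond grid of the event logger."""
    return round(t_h * _MS_PER_H) / _MS_PER_H


def mouse_rng(master_seed: int, mouse_id: str) -> np.random.Generator:
    """Per-mouse RNG stream: master seed combined with a stable hash of
    the mouse id, so cohort edits don't reshuffle unrelated streams."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(mouse_id.encode())])
    )


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Allele frequencies of the two source populations plus the shared
    MHC haplotype pool.

    ``pop_freqs[pop]`` is an (n_loci, n_alleles) matrix of per-locus allele
    frequencies; ``allele_labels`` gives fragment-length-style labels per
    locus. ``mhc_pool`` holds aligned in-frame coding sequences shared by
    both populations; ``mhc_pool_freqs[pop]`` are the per-population
    frequencies over that pool (overlapping support).
    """

    loci: list[str]
    allele_labels: np.ndarray  # (n_loci, n_alleles) ints
    pop_freqs: dict[str, np.ndarray]
    mhc_pool: list[str]
    mhc_pool_freqs: dict[str, np.ndarray]

    def validate(self) -> None:
        n_loci = len(self.loci)
        if n_loci == 0 or self.allele_labels.shape[0] != n_loci:
            raise ValueError("allele labels do not match loci")
        if self.allele_labels.shape[1] == 0:
            raise ValueError("empty allele pool")
        for pop, f in self.pop_freqs.items():
            if f.shape != self.allele_labels.shape:
                raise ValueError(f"frequency shape mismatch for population {pop}")
            if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"invalid frequency vectors for population {pop}")
        if not self.mhc_pool:
            raise ValueError("empty MHC haplotype pool")
        length = len(self.mhc_pool[0])
        if length % 3 != 0 or any(len(h) != length for h in self.mhc_pool):
            raise ValueError("MHC pool sequences must share a length divisible by 3")
        for pop, f in self.mhc_pool_freqs.items():
            if len(f) != len(self.mhc_pool):
                raise ValueError(f"MHC frequency length mismatch for population {pop}")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid MHC frequencies for population {pop}")


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    bases = "ACGT"
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _mutate_codons(rng: np.random.Generator, seq: str, rate: float) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i in range(len(codons)):
        if rng.random() < rate:
            new = codons[i]
            while new == codons[i] or new in _STOP_CODONS:
                new = "".join(rng.choice(list("ACGT"), size=3))
            codons[i] = new
    return "".join(codons)


def default_population_model(
    n_loci: int = 13,
    n_alleles: int = 8,
    divergence: float = 0.35,
    n_haplotypes: int = 8,
    n_codons: int = 90,
    codon_substitution_rate: float = 0.10,
    seed: int = 0,
) -> PopulationModel:
    """Two weakly diverged populations sharing alleles at every locus.

    Per-locus frequencies are drawn by mixing a common symmetric-Dirichlet
    base with a per-population Dirichlet draw, weighted by ``divergence``:
    0 gives identical populations, 1 fully independent ones. The default
    0.35 keeps the populations separable but only weakly so (short branch
    lengths in an allele-sharing tree). The MHC pool mutates a common
    270-nt (90-codon) ancestral exon at ~10% of codons per haplotype,
    yielding pairwise amino-acid p-distances on the order of 0.15.
    """
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    labels = np.array(
        [[120 + 6 * i + 2 * a for a in range(n_alleles)] for i in range(n_loci)]
    )
    base = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    pop_freqs = {}
    for pop in ("F", "G"):
        own = rng.dirichlet(np.ones(n_alleles), size=n_loci)
        f = (1.0 - divergence) * base + divergence * own
        pop_freqs[pop] = f / f.sum(axis=1, keepdims=True)
    ancestor = _random_coding_sequence(rng, n_codons)
    pool = [_mutate_codons(rng, ancestor, codon_substitution_rate) for _ in range(n_haplotypes)]
    mhc_freqs = {
        pop: rng.dirichlet(np.ones(n_haplotypes) * 2.0) for pop in ("F", "G")
    }
    model = PopulationModel(
        loci=loci,
        allele_labels=labels,
        pop_freqs=pop_freqs,
        mhc_pool=pool,
        mhc_pool_freqs=mhc_freqs,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# pedigree and cohort
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Breeding design: pairs per reciprocal cross and offspring per sex.

    Cross codes put the mother's population first (GF = German mother,
    French father). Defaults give 4 crosses × 6 per sex = 48 focal-eligible
    mice.
    """

    cross_codes: tuple[str, ...] = CROSS_CODES
    pairs_per_cross: int = 3
    offspring_per_sex: int = 6

    def validate(self) -> None:
        bad = [c for c in self.cross_codes if c not in CROSS_CODES]
        if bad:
            raise ValueError(f"invalid cross code(s) {bad}; expected subset of {CROSS_CODES}")
        if self.pairs_per_cross < 1 or self.offspring_per_sex < 1:
            raise ValueError("pairs_per_cross and offspring_per_sex must be positive")


def _draw_founder(
    model: PopulationModel, pop: str, mouse_id: str, sex: str, seed: int
) -> Mouse:
    rng = mouse_rng(seed, mouse_id)
    geno = {}
    for i, loc in enumerate(model.loci):
        alleles = rng.choice(model.allele_labels[i], size=2, p=model.pop_freqs[pop][i])
        geno[loc] = (int(alleles[0]), int(alleles[1]))
    hap_idx = rng.choice(len(model.mhc_pool), size=2, p=model.mhc_pool_freqs[pop])
    return Mouse(
        id=mouse_id,
        sex=sex,
        cross=pop * 2,  # founders are pure members of their population
        genotype=geno,
        haplotypes=(model.mhc_pool[hap_idx[0]], model.mhc_pool[hap_idx[1]]),
    )


def _mendelian_offspring(
    mother: Mouse, father: Mouse, mouse_id: str, sex: str, cross: str, seed: int
) -> Mouse:
    rng = mouse_rng(seed, mouse_id)
    geno = {}
    for loc in mother.genotype:
        gm, gf = mother.genotype[loc], father.genotype[loc]
        geno[loc] = (gm[rng.integers(2)], gf[rng.integers(2)])
    haps = (
        mother.haplotypes[rng.integers(2)],
        father.haplotypes[rng.integers(2)],
    )
    return Mouse(
        id=mouse_id,
        sex=sex,
        cross=cross,
        mother_id=mother.id,
        father_id=father.id,
        genotype=geno,
        haplotypes=haps,
    )


def simulate_cohort(
    pop_model: PopulationModel, pedigree: PedigreeSpec, seed: int
) -> Cohort:
    """Breed a full experimental cohort with parents included.

    For every breeding pair of cross XY a founder dam from population X and
    a founder sire from population Y are drawn from the population allele
    frequencies; offspring receive one Mendelian allele per locus and one
    MHC haplotype from each parent. Deterministic given the seed.
    """
    pop_model.validate()
    pedigree.validate()
    mice: dict[str, Mouse] = {}
    for cross in pedigree.cross_codes:
        mat_pop, pat_pop = cross[0], cross[1]
        pairs = []
        for j in range(pedigree.pairs_per_cross):
            dam = _draw_founder(pop_model, mat_pop, f"dam_{cross}{j + 1}", "F", seed)
            sire = _draw_founder(pop_model, pat_pop, f"sire_{cross}{j + 1}", "M", seed)
            mice[dam.id] = dam
            mice[sire.id] = sire
            pairs.append((dam, sire))
        for sex, tag in (("F", "f"), ("M", "m")):
            for i in range(pedigree.offspring_per_sex):
                dam, sire = pairs[i % len(pairs)]
                mid = f"{cross}_{tag}{i + 1}"
                mice[mid] = _mendelian_offspring(dam, sire, mid, sex, cross, seed)
    return Cohort(mice=mice, loci=list(pop_model.loci))


def focal_ids(cohort: Cohort) -> list[str]:
    """Offspring (non-founder) ids — the focal-eligible animals."""
    return [m.id for m in cohort.mice.values() if m.mother_id is not None]


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

@dataclass
class MovementParams:
    """Generative parameters of the focal mouse's movement and detection.

    Defaults are the study conditions: a 12:12 light cycle (lights on
    07:00, off 19:00) with a midday activity trough 12:00–15:00; a
    leave-central hazard and satellite dwell mean tuned so the mouse spends
    roughly two-thirds of its time social; transit/detection/lingering
    parameters shaping the read stream.
    """

    leave_central_hazard_per_h: float = 4.0
    satellite_dwell_mean_h: float = 0.5
    preference_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    beta: float = 0.0  # effect of the standardized dyadic covariate on log-weight
    lights_on: float = 7.0
    lights_off: float = 19.0
    trough: tuple[float, float] = (12.0, 15.0)
    night_mult: float = 1.5
    day_mult: float = 0.7
    trough_mult: float = 0.3
    transit_s: float = 2.0
    detection_prob: float = 0.98
    lingering_per_min: float = 1.5

    def validate(self) -> None:
        if self.leave_central_hazard_per_h < 0:
            raise ValueError("leave-central hazard must be >= 0")
        if self.satellite_dwell_mean_h <= 0:
            raise ValueError("satellite dwell mean must be > 0")
        if len(self.preference_weights) != 4 or any(w <= 0 for w in self.preference_weights):
            raise ValueError("need 4 positive preference weights")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection probability must be in [0, 1]")
        if min(self.night_mult, self.day_mult, self.trough_mult) <= 0:
            raise ValueError("diurnal multipliers must be > 0")
        if self.lingering_per_min < 0 or self.transit_s < 0:
            raise ValueError("lingering rate and transit time must be >= 0")

    def diurnal_multiplier(self, clock_h: float) -> float:
        c = clock_h % 24.0
        if c >= self.lights_off or c < self.lights_on:
            return self.night_mult
        if self.trough[0] <= c < self.trough[1]:
            return self.trough_mult
        return self.day_mult

    def effective_weights(self, covariates: np.ndarray | None) -> np.ndarray:
        w = np.asarray(self.preference_weights, dtype=float)
        if covariates is not None:
            z = np.asarray(covariates, dtype=float)
            if z.shape != (4,):
                raise ValueError("need one covariate per satellite")
            w = w * np.exp(self.beta * z)
        return w


@dataclass
class SimulationTruth:
    """Ground-truth trajectory of one focal run.

    Intervals are contiguous, cover [0, duration] exactly, and alternate
    central ↔ satellite (star topology). ``dwell_totals_h[c]`` is the total
    time in cage code c (0 = central).
    """

    cages: np.ndarray
    start_h: np.ndarray
    end_h: np.ndarray
    duration_h: float
    start_clock_h: float
    params: MovementParams
    effective_weights: np.ndarray

    @property
    def dwell_totals_h(self) -> np.ndarray:
        return np.bincount(self.cages, weights=self.end_h - self.start_h, minlength=5)

    def validate(self) -> None:
        if self.start_h[0] != 0.0 or self.end_h[-1] != self.duration_h:
            raise ValueError("trajectory does not cover [0, duration]")
        if len(self.cages) > 1:
            if not np.array_equal(self.end_h[:-1], self.start_h[1:]):
                raise ValueError("trajectory intervals do not abut")
            a, b = self.cages[:-1], self.cages[1:]
            if np.any((a > 0) & (b > 0)) or np.any((a == 0) & (b == 0)):
                raise ValueError("trajectory must alternate central <-> satellite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "cages": self.cages.tolist(),
                "start_h": self.start_h.tolist(),
                "end_h": self.end_h.tolist(),
                "duration_h": self.duration_h,
                "start_clock_h": self.start_clock_h,
                "dwell_totals_h": self.dwell_totals_h.tolist(),
                "effective_weights": self.effective_weights.tolist(),
                "params": asdict(self.params),
            }
        )


class _HazardSchedule:
    """Integrated leave-central hazard over the run, piecewise constant."""

    def __init__(self, params: MovementParams, duration_h: float, start_clock_h: float):
        marks = sorted({params.lights_on, params.trough[0], params.trough[1], params.lights_off})
        bounds = [0.0]
        day = 0
        while True:
            base = 24.0 * day - start_clock_h
            nxt = [base + m for m in marks if 0.0 < base + m < duration_h]
            bounds.extend(nxt)
            if base > duration_h:
                break
            day += 1
        bounds = sorted(set(bounds))
        bounds.append(duration_h)
        self.t = np.array(bounds)
        mids = (self.t[:-1] + self.t[1:]) / 2.0
        self.rate = np.array(
            [
                params.leave_central_hazard_per_h * params.diurnal_multiplier(start_clock_h + m)
                for m in mids
            ]
        )
        self.H = np.concatenate(([0.0], np.cumsum(self.rate * np.diff(self.t))))

    def cumulative(self, t: float) -> float:
        return float(np.interp(t, self.t, self.H))

    def wait_from(self, t0: float, exp_draw: float) -> float:
        """Time at which the integrated hazard since t0 reaches exp_draw;
        inf if it never does within the run."""
        target = self.cumulative(t0) + exp_draw
        if target >= self.H[-1]:
            return float("inf")
        i = int(np.searchsorted(self.H, target, side="right")) - 1
        return float(self.t[i] + (target - self.H[i]) / self.rate[i])


def simulate_trajectory(
    params: MovementParams,
    duration_h: float,
    rng: np.random.Generator,
    covariates: np.ndarray | None = None,
    start_clock_h: float = 16.0,
) -> SimulationTruth:
    """Simulate the alternating central/satellite process for one run.

    ``covariates`` (optional, standardized, one per satellite) shift the
    log preference weights by ``params.beta``. Event times are quantized
    to the millisecond grid; zero-length intervals arising from
    quantization are skipped.
    """
    params.validate()
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    w = params.effective_weights(covariates)
    probs = w / w.sum()
    schedule = (
        _HazardSchedule(params, duration_h, start_clock_h)
        if params.leave_central_hazard_per_h > 0
        else None
    )
    cages, starts, ends = [], [], []
    t = 0.0
    loc = 0
    while t < duration_h:
        if loc == 0:
            if schedule is None:
                t_next = duration_h
            else:
                t_next = min(schedule.wait_from(t, rng.exponential()), duration_h)
        else:
            t_next = min(t + rng.exponential(params.satellite_dwell_mean_h * w[loc - 1]), duration_h)
        # quantize to the logger's ms grid; keep a 1 ms minimum dwell so
        # alternation survives quantization
        t_next = _quantize_ms(min(t_next, duration_h))
        t_next = min(max(t_next, _quantize_ms(t + 0.001 / 3600.0)), duration_h)
        cages.append(loc)
        starts.append(t)
        ends.append(t_next)
        if loc == 0:
            loc = int(rng.choice(4, p=probs)) + 1
        else:
            loc = 0
        t = t_next
    truth = SimulationTruth(
        cages=np.array(cages, dtype=int),
        start_h=np.array(starts),
        end_h=np.array(ends),
        duration_h=duration_h,
        start_clock_h=start_clock_h,
        params=params,
        effective_weights=w,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def emit_reads(
    truth: SimulationTruth,
    params: MovementParams,
    layout: AntennaLayout,
    seed: int | np.random.Generator,
) -> list[AntennaRead]:
    """Turn a trajectory into the antenna read stream.

    Each cage transition through tube k emits a read at the origin-side
    antenna at the transition time and one at the destination-side antenna
    ``transit_s`` later; every read is retained independently with the
    detection probability. While the mouse dwells in a cage, lingering
    re-reads at the current-cage-side antenna of the tube it last passed
    (satellite end in a satellite cage, central end in the central cage)
    arrive as a Poisson stream at ``lingering_per_min``; the initial
    central stay, before any tube passage, emits none. Output is
    time-sorted (stable in emission order on ties, so an origin read
    precedes its destination read even at zero transit).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times: list[float] = []
    antennas: list[int] = []
    order: list[int] = []
    seq = 0
    transit_h = params.transit_s / 3600.0
    for i in range(1, len(truth.cages)):
        a, b = int(truth.cages[i - 1]), int(truth.cages[i])
        tube = a if a > 0 else b
        origin_side = "satellite" if a > 0 else "central"
        dest_side = "central" if a > 0 else "satellite"
        t0 = float(truth.start_h[i])
        times.append(t0)
        antennas.append(layout.antenna_for(tube, origin_side))
        order.append(seq)
        seq += 1
        times.append(_quantize_ms(t0 + transit_h))
        antennas.append(layout.antenna_for(tube, dest_side))
        order.append(seq)
        seq += 1
    if params.lingering_per_min > 0:
        rate_h = params.lingering_per_min * 60.0
        last_tube = 0  # no tube passed yet during the initial central stay
        for i, (c, s, e) in enumerate(zip(truth.cages, truth.start_h, truth.end_h)):
            if c > 0:
                last_tube = int(c)
            if last_tube == 0:
                continue
            side = "satellite" if c > 0 else "central"
            n = rng.poisson(rate_h * (e - s))
            if n == 0:
                continue
            ts = rng.uniform(s, e, size=n)
            aid = layout.antenna_for(last_tube, side)
            # quantization must not push a re-read onto the interval's end,
            # where it would shadow the transition read
            hi = _quantize_ms(e - 0.001 / 3600.0)
            for tt in ts:
                times.append(min(_quantize_ms(float(tt)), hi))
                antennas.append(aid)
                order.append(seq)
                seq += 1
    if not times:
        return []
    times_a = np.array(times)
    order_a = np.array(order)
    antennas_a = np.array(antennas)
    keep = rng.random(len(times_a)) < params.detection_prob
    times_a, order_a, antennas_a = times_a[keep], order_a[keep], antennas_a[keep]
    idx = np.lexsort((order_a, times_a))
    return [
        AntennaRead(
            timestamp=layout.start + timedelta(hours=float(times_a[i])),
            antenna_id=int(antennas_a[i]),
        )
        for i in idx
    ]


def write_truth_json(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
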