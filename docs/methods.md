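# Methods

## Occupancy reconstruction

The arena is a star: satellite cages connect to the central cage only
through their own tube, each tube carrying one antenna at each end. The
reconstruction uses a **nearest-side rule**: the location implied by a
read is fully determined by that read — satellite end of tube *k* → cage
S*k*, central end → central — and changes at the read's timestamp. The
mouse starts in the central cage (where it is placed), and the final
interval extends to the run end.

This rule was chosen over explicit pairing of the two reads of a transit
because it needs no lookahead and degrades gracefully: a missed read
delays the location change only until the next read anywhere (in
practice the next lingering re-read, a few tens of seconds), rather than
corrupting a pairing state machine. Its one systematic consequence is
that tube transit time is attributed to the origin cage, so per-transition
attribution error is bounded by the transit time. Anomaly counters report
reads outside the run window and physically impossible
satellite→satellite jumps (possible only through missed reads).

The run window defaults to Thursday 16:00 → Wednesday 08:00 (136 h).
Timestamps are timezone-naive local clock times at millisecond
resolution. Recordings whose read span falls below 90% of the nominal
window (e.g. a power failure) are flagged, never silently dropped.

## Selectivity index

SI = SD/SD_max with the **sample** (n−1) standard deviation of the four
percentage dwell shares. The normalizer SD_max = 50 forces this choice:
the sample SD of (100, 0, 0, 0) is exactly 50, the population SD is
43.3. The temporal series uses cumulative (expanding) windows on a
10-minute grid — the first window is 10 min, the second 20 min, and so
on — not sliding windows. Before the first satellite visit SI is
undefined and propagated as NaN, never as 0: early grid points reflect
lack of exploration, not choice, and coercing them to a number would
bias group means. Group curves report the pointwise mean over defined
values with a t-based symmetric 95% confidence band (bootstrap bands
would also be defensible; t-based was chosen for determinism and is
noted as a package choice).

## Preference blocks and chance-match tests

The preferred cage at a grid point is the argmax of cumulative satellite
dwell. Exact ties keep the previous defined point's preference when it is
among the tied maxima, else take the lowest cage index — a deterministic
rule; ties have measure zero on continuous data and arise mainly in
degenerate synthetic inputs. Blocks are maximal runs of constant
preference over the defined points: *n* changes = *n*+1 blocks. The
summary reports the block count, the final block's share of defined grid
points, and the time the final block begins.

Early-vs-final match counts are tested against the chance expectation
n/4 with a 1-df chi-square goodness-of-fit on (matched, unmatched). The
Yates continuity correction (|O−E| reduced by 0.5, floored at 0) is on
by default; for 12 matched of 47 it yields χ² = 0.0000, p = 1, where the
uncorrected statistic is 0.0071. Both variants are exposed, and the
corrected statistic never exceeds the uncorrected one. A mouse with an
undefined preference at a checkpoint counts as a non-match and is
flagged separately.

## Genetic distances

**Microsatellites.** Each individual contributes a per-locus allele
frequency vector (homozygote 1; heterozygote 0.5/0.5). With
cos θ = Σ√(p·q), the per-locus chord distance is (2/π)·√(2(1−cos θ)),
averaged over loci typed in both individuals (CAS). The allele-sharing
distance Dps is 1 − shared/(2·L) with the multiset intersection of
allele pairs per locus. Exact chord normalizations differ between
programs in the field; the formula used here is pinned and unit-tested
rather than matched to any particular tool.

**MHC.** Haplotypes are in-frame nucleotide sequences translated with
the standard nuclear code (configurable frame); codons containing gaps
translate to `-`, ambiguous codons to `X`, and stop codons are kept as
`*`. The amino-acid p-distance is the fraction of differing sites among
comparable sites, with pairwise deletion of sites carrying `X`, `-` or
`*` in either sequence. The individual-to-individual distance averages
the four inter-individual haplotype pairings (a1b1, a1b2, a2b1, a2b2);
within-individual diversity is the p-distance between an individual's
own two haplotypes. Parent-referenced covariates (MHCmat/MHCpat,
CASmat/CASpat) replace the focal mouse with its mother/father; a missing
parent record makes the covariate NaN and flags the dyad — never a
zero-fill. Missing data are handled by pairwise deletion everywhere; no
imputation.

**Trees.** Neighbor-joining is delegated to scikit-bio behind the
module's interface; negative branch lengths are clamped to zero and
counted. Two- and three-taxon inputs are handled by closed form.

## Grouped correlations

One record per focal × satellite dyad: √(dwell duration) against MHCpat,
Spearman's r (mid-ranks on ties), t = r·√((n−2)/(1−r²)), df = n−2,
two-sided p from the central t distribution. The square-root transform
does not change a rank correlation; the column is kept for output
fidelity with the field's reporting convention. Groupings: all mice;
pure (FF, GG) vs mixed (FG, GF) background; sex × paternal background
(xF/xG = paternal letter). Groups with fewer than 5 usable records (the
configurable minimum) yield an undefined row rather than a fragile
estimate, and per-group exclusion counts are reported explicitly.

## Synthetic data generator

The generator's purpose is a ground-truthed replica of the experiment,
not a behavioural model of real mice.

**Genetics.** Two source populations share all allele support. Per-locus
frequencies mix a common symmetric-Dirichlet base with per-population
draws at divergence weight 0.35 — enough for pure-population individuals
to separate in an allele-sharing tree, but weakly (short branches).
Cohorts are bred from founder pairs per reciprocal cross (code = maternal
population first); offspring draw one Mendelian allele per locus and one
MHC haplotype from each parent. The MHC pool holds eight 270-nt
(90-codon), stop-free haplotypes derived from a common ancestor at ~10%
codon substitution, giving dyadic MHCpat values around 0.15–0.19 —
the order observed in the real cohort.

**Movement** is a continuous-time alternating renewal process (chosen
over a discrete-time chain because event-driven RFID data are
continuous-time and dwell shares stay analytically controllable): leave
the central cage with hazard 4/h modulated by a piecewise-constant
diurnal multiplier (night ×1.5 between lights-off 19:00 and lights-on
7:00; day ×0.7; midday trough 12:00–15:00 ×0.3 — the "siesta"); choose
satellite *k* with probability ∝ w̃_k; dwell there Exp(0.5 h · w̃_k);
return. The effective weight w̃_k = w_k·exp(β·z_k) modulates both the
choice probability and the dwell mean, with z the standardized dyadic
covariate (MHCpat in the studies here, z-scored across the experiment's
dyads). Defaults give roughly two-thirds social time; the baseline
weights are preference-neutral (β = 0, w = 1), so preference structure
is always injected explicitly. Piecewise-exponential central waits are
sampled exactly by inverting the integrated hazard.

**Read emission.** Each transition through tube *k* emits an origin-side
read at the transition time and a destination-side read one transit time
(default 2 s) later; every read survives with the detection probability
(default 0.98). While the mouse dwells, lingering re-reads at the
current-cage-side antenna of the last-used tube arrive at 1.5/min —
together with transitions this yields on the order of 90 reads/h,
matching the activity level of the real recordings. All event times are
quantized to the logger's millisecond grid (with a 1 ms minimum dwell so
quantization cannot break alternation, and lingering reads clamped
strictly inside their interval so they never shadow a transition read).
A lossless recording (detection 1, transit 0) therefore reconstructs to
ground truth up to floating-point round-off.

Each mouse uses an RNG stream derived from the master seed by a stable
hash (CRC-32) of its id, so editing one animal never perturbs another.

**What the generator does not emulate:** oestrus cycling and its
synchronisation, habituation (declining activity over days), t-haplotype
effects, satellite-mouse behaviour (satellites are static stimuli, as
behind the grid in the physical setup), position effects of cages in the
room, and any dependence of preference on time. Passing tests therefore
demonstrate that the analysis chain is correct and calibrated — not that
real mice follow this movement model.

## Problem sizes and numerical choices

The replicate studies use 12 focal mice × 4 dyads per replicate: 100
replicates through the full read-level pipeline for the power check at
β = 1.5, and 1000 replicates on ground-truth durations for the null
calibration at β = 0 (the calibrated object is the correlation test;
read-level fidelity is established separately by the oracle-equivalence
checks on 50 lossless and 50 noisy runs). The type-I-error property of
the uncorrected chance-match test is evaluated on 10,000 Binomial(47, ¼)
cohorts directly. Tolerances: occupancy "exactness" is asserted at
10⁻⁹ h (timestamp quantization and float round-off); NJ additivity at
10⁻⁹; printed-table consistency at the printed precision (3 decimals for
t, 4 for p). Undefined quantities are NaN throughout — never 0 — and
error states (invalid simplex, malformed genotype, non-symmetric
distance matrix) raise with the offending row, locus or line named.

## Known limitations

- The nearest-side rule attributes transit time to the origin cage; with
  2 s transits and ~180 transitions this is ~0.1% of the run span.
- The paper-style analysis chain stops at the tidy dyad table; the
  mixed-model fits the field would run on it (beta-error GLMMs) are out
  of scope, as is haplotype phasing — phased input is required.
- Grouped correlations treat dyads as independent records; the 4 dyads
  of one focal mouse are not independent. The replicate calibration shows
  the test is nevertheless well calibrated under this generator's null,
  but that is a property of the generator, not a general guarantee.
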