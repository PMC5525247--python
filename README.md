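# prefwatch

Analysis of RFID-monitored multi-choice partner-preference experiments in
house mice, with a fully synthetic, ground-truthed replica of the
experiment for validation.

## The problem

A focal mouse lives for 136 hours (Thursday 16:00 to the following
Wednesday 08:00) in a star-shaped arena: one central cage connected by
tubes to four satellite cages, each holding a stimulus animal of the
opposite sex behind a grid. Every tube carries two RFID ring antennae (one
at each end), and each passage of the tagged focal mouse produces
timestamped antenna reads. From that event stream the package answers:

- **Where was the mouse, and for how long?** Occupancy reconstruction with
  a nearest-side rule (a read at the satellite end of tube *k* places the
  mouse in satellite cage *k*; a read at the central end places it in the
  central cage), robust to missed reads.
- **How strong is its preference?** The selectivity index
  **SI = SD / SD<sub>max</sub>**, where SD is the sample standard deviation
  of the four percentage dwell shares across satellite cages and
  SD<sub>max</sub> = 50 (realised by 100/0/0/0). SI is 0 for even division
  of social time, 1 for exclusive preference. Evaluated on cumulative
  10-minute windows to trace the decision process.
- **How stable is it?** The preferred cage (argmax of cumulative dwell) on
  the 10-minute grid, segmented into *preference blocks*; plus chi-square
  tests of whether the early preference (10 min / 90 min / 24 h) matches
  the final choice more often than the 1-in-4 chance rate.
- **What predicts it?** Dyadic genetic covariates — Cavalli-Sforza chord
  and allele-sharing distances over 13 microsatellite loci, amino-acid
  p-distances at an MHC class II exon, including distances from the focal
  mouse's *parents* to each satellite (MHCmat/MHCpat, CASmat/CASpat) — and
  grouped Spearman correlations between √(dwell duration) and MHCpat with
  the t-approximation t = r·√((n−2)/(1−r²)), df = n−2, two-sided p.

The synthetic generator (`prefwatch.synthetic`) emulates the whole chain —
two weakly diverged populations with reciprocal F1 crosses, Mendelian
genotypes, a shared MHC haplotype pool, continuous-time star-topology
movement with diurnal modulation, and antenna-read emission with detection
misses and lingering re-reads — so every analysis stage is testable against
known ground truth.

## Worked example

The numbered scripts under `analysis/` run one complete synthetic
experiment (48 focal mice, MHCpat effect β = 1.5 on the log preference
weights) and analyse it exactly as a real one would be:

```sh
python analysis/01_simulate_experiment.py   # raw data: logs, genotypes, FASTA
python analysis/02_reconstruct_occupancy.py # occupancy, durations, activity
python analysis/03_selectivity_dynamics.py  # SI series and group means
python analysis/04_preference_stability.py  # blocks and chance-match tests
python analysis/05_genetic_distances.py     # distance matrices, NJ trees
python analysis/06_mhcpat_correlations.py   # grouped Spearman table
```

Outputs land under `results/experiment/`. A run with the default seed
prints, among other lines:

```
mean social time: 83.8% of the run
reconstruction error vs truth: mean 0.037% of span, worst 0.118%
mean preferred-cage share of social time: 71.9%
matches at 10 min: 13/48 (chance expectation 12.00)
matches at 24 h: 42/48 (chance expectation 12.00)
     group      r       t  df   p   n
  All mice 0.8989 28.2718 190 0.0 192
```

Read: the simulated mice spend most of their time social; occupancy
reconstruction from the noisy read stream recovers the true dwell times to
within ~0.1% of the run span; the 10-minute "preference" is at chance
while the 24-hour one already predicts the final choice; and the injected
MHCpat effect appears as a strongly positive Spearman correlation across
all 192 focal × satellite dyads. With β = 0 the same pipeline yields r
near 0 and calibrated p-values (see the acceptance script below).

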