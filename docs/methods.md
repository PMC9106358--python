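# Methods

## Operant session model

Lever pressing is a thinned Poisson process per lever: within any interval
where the schedule context is constant, presses arrive at a constant rate and
the simulator draws exponential waiting times, redrawing at every context
boundary (period edges, shocks, progressive-ratio requirement changes) —
exact by memorylessness. The schedule logic itself is a deterministic state
machine (`ScheduleEngine`) shared by the stochastic simulator and a pure
replay entry point (`replay_presses`), so any press sequence can be replayed
and checked against independent oracles.

Schedule contracts:

- **FR1/FR5** — one pellet + cue per 1 or 5 active responses outside
  time-out; every pellet starts a 10-s time-out during which responses are
  logged (`period=timeout`) but never advance the ratio, hence no two pellets
  can be closer than 10 s.
- **FR5 with pellet-free window** — the final 10 minutes of the session are
  signalled pellet-free; responses there are tagged and never reinforced.
  Persistence = mean pellet-free active count over the three such sessions.
- **Progressive ratio** — requirements follow the fixed 35-step ladder
  (1…5500). The session ends at ladder exhaustion, the 5-h cap, or a ≥ 1-h
  gap without a response on either lever; the breaking point is the ladder
  value of the last completed requirement (0 if none).
- **Shock test** — 50 min; the 4th active response of a cycle yields a shock
  only, the 5th a shock plus pellet (then time-out); if the 5th response does
  not follow the 4th within one minute the cycle resets and the shock taken
  stands. Shock intensity is metadata only ("0.18 mA, 2 s"); the simulator
  models no physics — each shock received multiplies the agent's active rate
  by its punishment sensitivity.
- **Probes** — the cue probe presents a non-contingent cue light at
  mid-session (appetitive reactivity = post-cue minus equal-length pre-cue
  active count); grid extinction is a non-reinforced session with the
  shock-grid context (aversive reactivity = active count); the reversal
  session swaps the lever contingency (flexibility errors = presses on the
  previously active lever). Probe durations (1200 s, 900 s, 3600 s) are fixed
  configuration.

Agent parameters: `active_rate`/`inactive_rate` (responses/min),
`persistence_bias` (multiplier on the active rate in non-reinforced periods,
including time-outs — this is what makes time-out responding an impulsivity
read-out), `motivation_cap` (largest PR requirement the agent will work
through), `punishment_sensitivity` ∈ (0, 1]. Post-cue responding is scaled by
`1 + persistence_bias` so cue-primed seeking exceeds baseline for persistent
agents; grid-extinction responding is scaled by
`persistence_bias × punishment_sensitivity` so shock-insensitive (vulnerable)
agents keep responding under the aversive cue.

## Cohort generator and calibration

Phenotype parameters are truncated normals whose means/SDs are frozen in
`defaults.py`. The vulnerable phenotype (25% of a 51-mouse cohort by
default) has elevated active rate, persistence bias and motivation cap and
reduced punishment sensitivity. The effect sizes were chosen once, by forward
simulation, so that the default cohort classifies ≈ 25% of mice as addicted;
no per-mouse raw scores exist to calibrate against, only that reported
fraction. Because positivity thresholds are cohort quantiles, the classified
fraction self-regulates: with strongly separated phenotypes it stays in a
0.15–0.35 corridor across seeds even though the latent vulnerable count is
binomial.

What the generator does **not** emulate: session-to-session learning curves,
within-session satiation, latency structure, inter-mouse social or litter
effects, or any early/middle/late training dynamics — a passing suite shows
the analysis chain is correct on schedule-faithful logs, not that real mice
behave like the agents.

## Classification

Thresholds are per-criterion 75th percentiles with linear interpolation
between order statistics (the common statistical default; only the
percentile itself is specified by the protocol), and positivity is strict
(`>`). The addiction label is the 2-of-3 rule. The severity scale — the
protocol names one but does not define it — is the mean fractional rank of
the three criterion scores, the simplest monotone composite; it is isolated
in `severity_scores` so an alternative can be swapped in. Vulnerable extremes
are the highest-severity addicted mice, resilient extremes the
lowest-severity nonaddicted mice; discovery takes the k most extreme per
side, replica the next k (one reading of an ambiguous selection protocol;
ties break by criterion scores, then id). PCA standardizes all seven
variables (criteria + traits have incommensurate units); loadings are the
unit-norm principal axes and the |loading| > 0.7 flag applies to them.
The χ² group test is Pearson's without continuity correction (Yates optional).

## Differential expression

Median-of-ratios size factors (features positive in all samples; factors
rescaled to geometric mean 1). The NB model uses a per-feature pooled
within-group method-of-moments dispersion on the normalized scale,
`alpha = (var − mean·E[1/s]) / mean²`, floored at 1e-4 — deliberately no
empirical-Bayes shrinkage, keeping the estimator transparent. The Wald
statistic is the log ratio of pseudo-counted normalized group means over its
delta-method standard error. **Reference distribution:** t with n1+n2−2
degrees of freedom rather than the normal. With six samples per group the
dispersion estimate is noisy and the normal reference is anti-conservative
(null fraction of p < 0.05 ≈ 0.078 in simulation); the t reference calibrates
it (≈ 0.049). A label-permutation mode provides a distribution-free
alternative and rank-agrees with the Wald p-values.

Power at this design is information-limited: with dispersion 0.1 and n = 6
vs 6, the expected Wald statistic for |log2FC| = 1 is ln2/√(2·0.1/6) ≈ 3.8
whatever the expression level, so after BH correction across a realistic
~400-feature panel only a fraction of such features reach q < 0.05 in any one
sample, and fewer in both discovery and replica. The replicated list at
default settings is therefore short; the per-feature power at nominal
p < 0.05 is ≈ 0.9.

## Set statistics

All overlap and enrichment tests are one-sided upper-tail hypergeometric
probabilities. The replication universe is the features tested in both
samples after the min-total filter (overlap probability must condition on
testability); replication requires direction consistency. Target enrichment
intersects each target set with the expressed universe and BH-corrects
across miRNAs; empty intersected sets are reported with overlap 0. Odds
ratios use a Haldane 0.5 correction when a 2×2 cell is zero.

## Synthetic omics

Counts are drawn directly as NB integers (no post-rounding) with lognormal
baselines, uniform library factors in [0.7, 1.3], and dispersion 0.1.
Defaults plant 9 down- and 2 up-regulated miRNAs at |log2FC| = 1 in the
vulnerable group on a 400-miRNA panel (a realistic filtered brain panel);
planted features get higher baselines (lognormal(5.5, 0.7)), as detected
signatures do. Each planted miRNA receives a 40-gene target set from a
2,000-gene mRNA pool (20 decoy miRNAs get target sets too); every target
gene's log2 fold change is shifted by −coupling × (miRNA lfc) — **a
down-regulated miRNA de-represses its targets upward** — with coupling 0.7 by
default; genes targeted by several planted miRNAs accumulate shifts.

## Human cohort and YFAS 2.0

Scoring: a symptom criterion is met when any of its items reaches that item's
frequency-code threshold; diagnosis needs ≥ 2 criteria plus impairment;
severity bands 2–3 / 4–5 / 6–11. Hallmark composites are sums of raw item
codes (not dichotomized items). The shipped item→criterion map (3 items per
criterion, 2 impairment items, threshold code 4) and the criterion→hallmark
grouping are a synthetic reconstruction, clearly labelled as such — the
published scoring key is external to this package — and every scoring path
reads the configurable `ItemMap`, never hard-coded items.

The generator assigns diagnosis group and symptom count first and then
derives item codes that reproduce them exactly under the same `ItemMap`
(met criteria get exactly one item at/above threshold; everything else stays
below), giving a round-trip guarantee. Because met criteria are sampled
uniformly among the 11, hallmark composites separate diagnosed from
undiagnosed subjects on average but any single composite can be
non-significant at n = 51 — matching the heterogeneity of real item data.
Circulating miRNA levels are built within each sex stratum as
`Σ_k r_k·z(score_k) + √(1 − Σ r²)·ε` on z-scored score columns, so sample
Pearson correlations converge to the planted values; defaults plant a
male-only negative persistence correlation, a male-only negative motivation
correlation, and a female-only positive reward-sensitivity correlation.

## Pipeline and reproducibility

Per-stage seeds derive from the global seed by SHA-256 of `"{seed}:{stage}"`
(kept below 2³¹), so adding stages never shifts earlier randomness. Every
output file is listed in `manifest.json` with its SHA-256; stage timings go
to `run.log`, which is excluded from the manifest so identical config + seed
give byte-identical manifests. Degenerate configurations (no addicted mice,
tiny human cohorts) complete with logged warnings rather than failing.

## Numerical choices and edge cases

- Quantiles: linear interpolation; positivity strictly `>`, so an all-equal
  cohort has no positive mouse.
- NB test pseudo-count 0.5 on normalized group means (sign-preserving).
- BH step-up computed exactly (monotone by construction); p-values outside
  [0, 1] are rejected, never clipped silently.
- Pearson correlations on constant columns return an explicit invalid row.
- PCA drops zero-variance features with a warning; missing criterion values
  exclude the mouse from classification with a logged reason; missing trait
  probes yield NaN, never silent zeros.

## Problem sizes used in the checks

The calibration suites use 2,000-feature null panels, 10,000-row
classification nulls, 50-seed cohort corridors, 11-seed recovery medians,
and n = 2,000 human cohorts — sizes at which the asserted quantities are
stable while the whole suite stays desk-scale.

## Known limitations

- The behavioural agent has constant rates within context; no learning.
- Dispersion is method-of-moments per feature; heavyweight DE tools with
  trended shrinkage will be better calibrated at very low counts.
- The YFAS item map is a reconstruction; absolute composite values are not
  comparable to scores from the published key.
- Network export is an edge list only; no layout or pathway annotation.
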