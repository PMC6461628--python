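# Methods

## Panel model and data handling

A mediator panel is a long table of non-negative concentrations (pg/ml;
nitrite/nitrate in µM) indexed by subject, time and mediator, with one
group label per subject.  Missing measurements are explicit `NaN` markers
and are never imputed; all downstream computations operate on
pairwise-complete observations.  Times are plain numbers with a declared
unit (day or hour); subjects are included only if they have at least
`min_times` (default 3) distinct observed time points, mirroring the
minimum-samples rule clinical serial-sampling cohorts use.  Background
correction subtracts the mean of a set of blank measurements from one
named mediator and clamps at zero — used for HMGB1 in cell-culture
supernatants, where serum-supplemented medium itself yields an ELISA
signal.  Values below assay detection limits are accepted as given; an
optional clamp exists in the generator but defaults off.

**Window rule.**  Time windows are closed on both ends, so a sample taken
on a boundary day (day 1 for windows d0–d1 and d1–2) contributes to both
adjacent windows.  With one sample per day, a two-day window otherwise
holds a single time point per subject; the closed–closed rule is what
makes windowed correlation estimable at all under daily sampling.  This is
a design decision, not a forced reading of the window labels.

## DyNA

For one group and one window, all (subject, time) samples inside the
window are pooled, and for every unordered mediator pair the Pearson r is
computed over samples where both values are present.  An edge is created
iff the pair has ≥ `min_pairs` complete observations (default 4 — r on
fewer points is noise-dominated), neither vector is constant (r undefined;
treated as no co-movement), and |r| ≥ stringency (default 0.7, "greater or
equal").  The edge records r, its sign, and the pair count.  Complexity is
the degree sum over (n − 1); negative edges count in degrees identically
to positive ones, since the statistic measures co-movement regardless of
direction.  No multiple-testing correction is applied: the procedure is a
fixed-threshold rule, not a p-value rule, and nothing in this module is
random.

Pooling across subjects *and* time points is the default correlation
population: per-subject windows of ≤ 2 samples cannot support a
correlation, so the pooled estimate (dominated by between-subject spread)
is the only usable one at daily resolution.  A per-subject first-difference
variant (`strategy="subject_delta"`) is available for densely sampled
designs.  Correlations run on raw concentrations by default; a
`log10(1+x)` transform is a config option.  Note that Pearson r on raw
right-skewed data is attenuated relative to the latent log-scale
correlation, and anti-correlations attenuate hardest — with log-scale
marginal spread σ the most negative achievable raw correlation is bounded
by −(1 − e^{−σ²})/(e^{σ²} − 1), which is why heavily dispersed panels may
under-count negative edges at a fixed threshold.

## DBN inference

The engine fixes, as package design decisions: first-order Markov lag
structure; per-mediator quantile discretization (default 3 levels,
computed from the analysed group's own pooled observations, with
fewer-bin fallback for ties and bin edges recorded); transitions only
between strictly consecutive observed time steps of the same subject —
subjects' series are never concatenated, gaps yield no transition, and a
gap-tolerant option (any consecutive observed pair = one step, used for
the unevenly spaced 1/3/6/24 h grid) defaults off; BDeu family scoring
with equivalent sample size 1 and a uniform structure prior; per-child
greedy search (add/remove one parent, accept the best strictly improving
move, stop at a local optimum) with 10 random restarts, a child's own lag
being a candidate parent like any other; and subject-level bootstrap
(default 100 resamples, the full discretize→transitions→search pipeline
re-run per resample) for per-edge confidence.  Deterministic tie-breaks
(score, then canonical parent-set order) and explicit seeds everywhere
make identical inputs give identical structures.  Central nodes are the
mediators whose self-loop is present at sufficient confidence, sorted by
confidence.  Edges carry no sign: the model scores dependence, not
activation vs. inhibition.

## Synthetic cohorts

Each subject follows a latent log-scale VAR(1), x(t) = A·x(t−1) + ε,
ε ~ N(0, σ²I), observed as `baseline · exp(x)` — positive, right-skewed,
multiplicative-noise data of the kind multiplex immunoassays produce.
The signed matrix A is the planted truth: hub mediators get a diagonal
self-weight (default 0.95, a strongly self-sustaining driver), targets get
off-diagonal couplings (default magnitude 0.9; negative couplings plant
anti-correlated pairs), and per-window overrides switch couplings on only
inside chosen windows.  Before the first sampled time the system is
burned in for 25 steps, so subjects enter observation in (approximately)
the stationary joint distribution — early windows carry the same planted
cross-correlation as late ones, as they would for patients enrolled
mid-process.

Defaults, chosen once as realistic for this data class: baseline
100 pg/ml for all mediators (assay units, not fitted cohort medians);
innovation σ = 0.1 (≈10% multiplicative CV, typical Luminex intra-assay
precision), which with the 0.95 hub self-weight gives ≈0.32 log-scale
marginal spread — a regime where planted |r| ≈ 0.9 couplings, positive
*and* negative, remain detectable above the 0.7 stringency on the raw
scale (see the attenuation bound above); missing-sample probability 0.25
for the human preset (clinical dropout/short stays) and 0 for the designed
in-vitro time course.  Missingness masks are redrawn until the
minimum-samples rule holds, so emitted cohorts always pass the inclusion
filter.

Two presets mirror the study designs.  The human preset has four groups —
APAPo+NAC (n = 13), non-APAPo+NAC (n = 8), non-APAPo non-NAC (n = 40),
non-survivor (n = 12) — on the daily d0–d7 grid, all sharing an HMGB1
self-feedback hub but coupling 12 / 12 / 6 / 14 targets respectively, with
the non-survivor group gaining 6 extra coupled targets only in the d1–2
and d2–3 windows (the post-enrollment complexity surge).  The mouse preset
has the four in-vitro conditions Control / APAP / NAC / APAP+NAC
(n = 12 / 3 / 9 / 3) on the 1, 3, 6, 24 h grid; APAP couples 12 targets
positively, APAP+NAC mixes 7 positive with 4 negative couplings (NAC
shifting pairs into anti-correlation), Control and NAC are sparse.

**What the generator does and does not emulate.**  It reproduces the
statistical structure the analyses consume — signed lag-one coupling,
persistence, multiplicative noise, missingness, group contrasts — but not
mechanistic liver-injury biology, mediator-specific baselines or
variances, assay censoring at detection limits, or measurement error
correlated across mediators.  Passing recovery tests therefore shows the
*methods* detect planted structure under realistic noise at the study's
sample sizes; it does not validate any biological conclusion about real
cohorts.  With n = 3 subjects per in-vitro condition (6 pooled
observations per window), sample correlations are noisy and an
appreciable fraction of edges in the mouse preset are chance crossings of
the threshold — a faithful property of small-n designs that the per-group
*contrasts* (APAP+NAC showing a higher negative fraction than APAP)
survive.

## Pipeline

`run_pipeline` chains load/simulate → inclusion filter → per-group DyNA
across the schedule → totals, negative fractions and focus-mediator
(default HMGB1) subnetworks → per-group DBN with bootstrap confidence →
comparison table, writing plain CSV/JSON plus a manifest echoing the full
configuration.  All randomness derives from the single run seed through
per-stage seeds, so any stage can be rerun in isolation and a rerun with
the same seed is byte-identical.  Groups emptied by filtering are skipped
with a warning; groups whose time grid yields no transitions skip the DBN
stage only.

## Problem sizes and numerical choices

The test suite and acceptance script run at the presets' own cohort sizes
(73 human subjects, 27 mediators; 27 mouse subjects, 22 mediators) and
estimate recovery rates from 20 seeds of small planted systems (2–6
mediators, 300 transitions for the DBN checks) — sizes at which every
property being tested is statistically stable.  Degenerate inputs are
handled conservatively throughout: constant vectors form no DyNA edge, a
constant mediator discretizes to a single bin, empty windows score
complexity 0, empty transition tables are a hard error for the scorer and
a skipped stage for the pipeline.  Known limitations: greedy parent-set
search finds local optima (mitigated, not eliminated, by restarts); BDeu
scores of families with many parents are data-hungry at short-series
sample sizes, so small groups (n = 8 subjects) under-recover and
occasionally misattribute self-feedback among strongly inter-correlated
mediators; and DyNA edge counts at n = 3 subjects carry substantial
sampling noise, as above.
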