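# Methods

## The analysis in one paragraph

A multichannel brain-state recording (one subject, one task condition) is a
T × V matrix: T time points, V channels (source-parcellated sensor
readings). The first `baseline_end` rows (default 30 of 91) are
pre-stimulus baseline. The Mapper construction summarizes the trajectory of
brain states as a graph: each state gets a scalar *lens* value — its
Euclidean distance to the reference state s_a, the mean of the baseline
rows — the lens range is covered with `Int` overlapping closed intervals,
the states in each interval's preimage are clustered with single linkage
(cut at the first-empty-histogram-bin height with `Bin` bins), each cluster
becomes a node, and two nodes sharing a time point are joined by an edge.
The *return point* is the first stimulus time point whose node also
contains an early (baseline or onset) time point, after the trajectory has
demonstrably left that neighborhood. The marker is swept over a grid of
(Int, Ovr, Bin) parameters, cleaned, correlated with task accuracy, and fed
into a paired condition comparison and two accuracy regressions.

## Mapper construction

**Cover.** With lens range R = max − min and overlap fraction g =
Ovr/100, intervals have equal length L = R / (Int − (Int − 1)·g); interval
i starts at min + i·L·(1 − g), so the first interval is anchored at the
minimum, the last ends at the maximum, and consecutive intervals overlap
by exactly g·L. Intervals are closed on both ends; boundary membership uses
a relative tolerance of 1e−9·R so that floating-point round-off can never
strand a time point outside every bin. A degenerate range (all lens values
equal, e.g. a constant recording) collapses to the single interval
[min, min] and hence a single bin.

**Clustering cutoff.** Within one bin, single-linkage merge heights plus
the bin's diameter are histogrammed into `Bin` equal-width bins spanning
[min height, diameter]. The cut height is the midpoint of the lowest-index
empty bin; if no bin is empty (heights fill the range densely — no
separation evidence) the bin stays one cluster, as it does when the height
range is degenerate. Merges are applied strictly below the cutoff;
equivalently clusters are connected components of the graph joining pairs
closer than the cutoff, which makes the partition independent of
tie-breaking among equal distances. Heights come from
`scipy.cluster.hierarchy.linkage`; partitions are cross-checked in the test
suite against an exhaustive hand-rolled agglomerative oracle.

**Indexing.** Time points are 1-based in every table, file and node member
list, matching the convention of reporting a return at, say, t = 63 of 91.

## Return-point rule

Let W = {1..early_window_end} with early_window_end = 32 by default: the 30
baseline samples plus 2 initial stimulus samples (the revisited region is
"the beginning of the stimulus", operationally bridged with the baseline
itself). A time point *touches* W when some node contains both it and a
member of W — co-membership in a cluster, not graph adjacency. The return
point is the smallest t > 32 that touches W **and** is preceded by some
t′ ∈ (32, t) that does not touch W. The second condition encodes "the state
must first leave": without it, cover overlap chains the first post-onset
sample to the baseline and every graph would report an immediate return.
A recording that never leaves (or leaves and never comes back) yields a
MISSING marker, which is a value, not an error. The window width is
configurable on every entry point.

## Grid sweep, cleaning, selection

The default grid G is {5,6,7} × {50,60,70} × {5,10} (18 points,
lexicographic order). Cleaning per condition: a subject missing the marker
at ≥ ⌈|G|/2⌉ = 9 grid points is excluded; remaining missing cells are
imputed with the mean of that subject's present cells, kept fractional
(imputation therefore never changes a subject's mean across present
cells). Subjects must survive cleaning in both conditions and carry
complete behavioral data. Parameters are selected where the Pearson
correlation between return points and accuracy is strongest; since the
expected direction is negative (slower return, lower accuracy), "strongest"
means most negative, with a magnitude-based variant behind a flag and ties
broken toward the earlier grid point. Pooled mode (most negative
column-wise mean across the two conditions) drives the paired comparison;
per-condition mode is available for the per-test regressions.

## Statistics

The paired 0B-vs-2B comparison uses a two-sided paired t-test on
(Mapper2B − Mapper0B) as primary, with the Wilcoxon signed-rank test
reported alongside; zero-variance differences are flagged degenerate
rather than producing an undefined statistic. The accuracy models are
ordinary least squares on the percentage scale (statsmodels): Model 1
regresses accuracy on median reaction time, Model 2 adds the return point.
Each fit reports RSE = √(RSS / residual df), R², and the overall F-test
p-value; Model 2 "wins" a comparison when it has both higher R² and lower
RSE, and a split criterion reports no winner. A constant response or a
collinear design is flagged/raised instead of fit.

## Synthetic cohort

The generator plants exactly the structure the marker is designed to
detect, so every detection claim can be checked against ground truth.

Per recording: baseline rows are a fixed random centroid μ0 plus i.i.d.
N(0, noise_sd²) noise per channel. During the stimulus the state is
displaced along a subject-specific random unit direction u (mimicking
subject-specific activation topography) by a piecewise-linear profile that
is zero again exactly at the planted return time; afterwards only a
sinusoidal wobble of amplitude `post_return_amplitude` (default =
noise_sd) remains, keeping late states near but not identical to baseline.

**Excursion shape.** The default profile is a trapezoid: a 2-sample
near-zero "toe" (evoked-response latency — the first two stimulus samples,
which fall inside the default early window, stay within the noise floor),
a 4-sample ramp to full amplitude, a flat plateau, and a 4-sample ramp
back to zero at the planted return. Two properties motivated this over a
midpoint-peak triangle (which remains available as `bump_shape=
"triangle"`): (1) a triangle's descent slope is 2A/window, so the state
drifts back into the lowest cover interval — and chains onto the baseline
cluster — roughly window/6 samples before the nominal return, making the
planted time ambiguous by 4–8 samples regardless of noise level; the steep
trapezoid ramp keeps the first return sharp to within ~2 samples. (2) The
flat plateau reproduces the sustained, highly self-similar mid-stimulus
state that shows up as one large engagement cluster in the graphs.

**Amplitude convention.** The displacement competes with noise in state
space, where the noise magnitude is noise_sd·√V (the distance noise
floor), not the per-channel sd. The default amplitude is therefore derived
as `excursion_snr · noise_sd · √n_channels` with excursion_snr = 10,
which makes the planted geometry — and hence every recovery result —
independent of the channel count. This is what licenses running tests at
V = 20 instead of 642: the Euclidean structure is identical, only cheaper.
An absolute amplitude can always be passed explicitly.

**Behavior.** Accuracy (per condition) is beta0 + beta_return·return +
beta_rt·rt + N(0, noise_sd_accuracy²), clipped to [0, 100]; reaction times
are N(rt_mean, rt_sd) truncated positive. Defaults beta0 = 140,
beta_return = −0.5 %/sample, beta_rt = −0.02 %/ms, noise 5 %, rt ~
N(900, 100²) ms put mean accuracy near 92 % with mild ceiling censoring —
and, with condition return distributions N(60, 2²) and N(68, 2²), produce
per-condition return/accuracy correlations around −0.2. A `missing_rate`
fraction of subjects receive a no-excursion (flat) recording in one random
condition to exercise the cleaning rules.

**What the generator does not emulate.** No sensor physics, source
leakage, oscillatory band structure, temporal autocorrelation of noise, or
multi-excursion dynamics; the post-return wobble is a stand-in, not a
claim about real post-stimulus activity. Passing recovery tests therefore
show that the pipeline detects the planted geometry it assumes, not that
real recordings contain that geometry.

## Experiment designs used by the tests and the acceptance script

- *Return recovery*: 50 subjects, T = 91, V = 20, baseline 30, planted
  returns uniform on {50..80}, default (snr = 10) amplitude; a subject
  counts as recovered when the detected return is within ±3 samples of
  truth at the majority of the 18 grid points.
- *Condition separation*: 70-subject cohorts with returns N(60, 2²) /
  N(68, 2²) (planted gap 8 samples), full pipeline, paired t-test at
  α = 1e−6. The test suite uses 20 cohorts and the acceptance script 10 —
  sizes chosen to keep a serial run comfortably short while leaving the
  rejection-rate estimate meaningful.
- *Model comparison*: 70-subject cohorts with planted returns uniform on
  {50..80} in both conditions. The uniform spread (sd ≈ 8.9 samples) is
  the operating point at which the return carries a clearly detectable
  share of the accuracy variance (partial F ≈ 56); under the narrow
  N(·, 2²) spread the return's partial signal (sd 1 % against 5 % noise)
  is too weak for any method to separate models reliably — a property of
  the design, not of the estimator. The null experiment (beta_return = 0)
  uses beta0 = 110 so mean accuracy stays at the same ~92 % operating
  point instead of saturating the 100 % ceiling.

## Numerical choices and degenerate inputs

- Bin-boundary tolerance 1e−9·R; full-precision (%.17g) CSV output so
  reruns are byte-identical and downstream recomputation is stable.
- Merges strictly below the cutoff; cutoff is a bin midpoint, which no
  merge height can equal, so < vs ≤ is immaterial and < is fixed for
  determinism.
- Empty bins cluster to the empty partition; singleton bins to a singleton
  cluster; a constant recording yields one interval, one node, MISSING.
- All randomness flows from numpy `SeedSequence`; per-subject streams are
  spawned from the cohort seed, so cohorts are reproducible byte-for-byte
  and subjects are independent of cohort size ordering.

## Known limitations

- On pure-noise (no-excursion) recordings the return rule occasionally
  fires spuriously (~18 % of grid cells at V = 20): a lens outlier can
  form its own sparse cluster, satisfying the "leaves first" condition.
  Such subjects still miss the marker at most grid points and are removed
  by the cleaning rule; MISSING-everywhere is only guaranteed noise-free.
- Detection carries a small systematic early bias (≈ 1–2 samples): the
  state enters the lowest lens interval, and merges into the baseline
  cluster, slightly before it reaches the centroid exactly.
- The per-condition regressions inherit ceiling censoring from accuracy
  clipping; with high beta0 and low noise the OLS assumptions degrade.
- Single linkage chains by design; covers with high overlap and few
  intervals produce wide bins in which chaining can bridge distinct
  regimes. That sensitivity is the reason the analysis sweeps a grid
  rather than trusting one parameter triple.
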