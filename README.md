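# statemapper

Topological summaries of brain-state dynamics. `statemapper` builds
Mapper graphs from multichannel neural time series (e.g. source-parcellated
MEG recordings of a working-memory n-back task), using the Euclidean
distance to the pre-stimulus baseline state as the lens, and extracts a
*return-point* marker: the first stimulus time point at which the brain
state re-visits the neighborhood of the baseline after having left it. The
marker is swept over a grid of Mapper parameters, cleaned, and related to
behavior (task accuracy, median reaction time) through a paired condition
comparison and nested regression models.

It is aimed at researchers studying dynamic whole-brain reconfiguration
who want a temporally resolved, per-subject marker without collapsing the
data spatially (sliding-window connectivity) or temporally (trial
averaging of state labels).

## The method

For one recording `X ∈ R^{T×V}` (T time points, V channels; rows
1..`baseline_end` are pre-stimulus baseline):

1. **Reference state** `s_a = mean(X[1..baseline_end])`, and lens
   `f_t = ||X_t − s_a||₂`.
2. **Cover** of `[min f, max f]` by `Int` equal closed intervals with
   `Ovr`% overlap: length `L = R / (Int − (Int−1)·g)`, `g = Ovr/100`.
3. **Clustering** of each interval's time points by single linkage, cut at
   the first empty bin of a `Bin`-bin histogram of merge heights (up to the
   set diameter); no empty bin ⇒ one cluster.
4. **Graph**: one node per cluster; an edge wherever two nodes share a
   time point.
5. **Return point**: with early window `W = {1..32}`, the smallest `t > 32`
   whose node also contains a member of `W`, provided some earlier
   `t′ ∈ (32, t)` does *not* share a node with `W` (the state must first
   leave). No such `t` ⇒ MISSING.

The sweep runs every `(Int, Ovr, Bin)` in the default grid
`{5,6,7} × {50,60,70} × {5,10}`; subjects missing the marker at ≥ half the
grid are excluded, remaining gaps are mean-imputed, and the grid point
whose return points correlate most negatively with accuracy is selected.
The statistics layer compares conditions with a paired t-test (Wilcoxon
alongside) and fits `Accuracy ~ MedianReactionTime` (Model 1) vs
`Accuracy ~ ReturnTime + MedianReactionTime` (Model 2) by OLS, reporting
RSE, R², and the overall F-test p-value.

A synthetic-cohort generator plants excursion-and-return trajectories with
known return times and behavior linearly coupled to them, so every stage
can be validated against ground truth; see `docs/methods.md`.

## Worked example

```sh
statemapper simulate --out cohort --n-subjects 70 --n-channels 20 --seed 11
statemapper run --data-dir cohort --out results_run
cat results_run/report.txt
```

which prints:

```
statemapper pipeline report
data: cohort
grid points: 18
0B: kept 70 subjects, excluded 0
2B: kept 70 subjects, excluded 0
final cohort: 70 subjects
selected parameters: 0B 7-50-10, 2B 7-50-10
paired 2B-0B: mean diff 7.914 samples, t = 24.040, p = 2.956e-35 (Wilcoxon p = 4.698e-13), n = 70
0B model 1: RSE 4.0550, R2 0.1523, p 8.384e-04
0B model 2: RSE 3.9887, R2 0.1919, p 7.949e-04
2B model 1: RSE 5.3753, R2 0.0950, p 9.453e-03
2B model 2: RSE 5.2745, R2 0.1414, p 6.056e-03
0B comparison: dR2 +0.0396, dRSE -0.0664, winner 2
2B comparison: dR2 +0.0464, dRSE -0.1008, winner 2
```

Reading it: the cohort was generated with a planted 8-sample gap between
the 0-back and 2-back return times; the pipeline's detected returns
recover a mean paired difference of 7.91 samples, overwhelmingly
significant. At the selected parameters (7-50-10: 7 intervals, 50 %
overlap, 10 histogram bins) adding the return time to the reaction-time
model raises R² and lowers the residual standard error in both
conditions — the planted accuracy coupling is picked up. Per-recording
graphs (GraphML, node-link JSON, a conventional layout and an
incidence-style plot with the return point drawn as a vertical rule) come
from `statemapper graph --data-dir cohort --subject S0000 --condition 0B
--grid-point 7-50-10 --out figs`.

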