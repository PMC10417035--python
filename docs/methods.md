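# Methods

## The assay and the damage metric

The comet assay (single-cell gel electrophoresis) embeds lysed cells in
agarose and pulls broken DNA out of each nucleoid by electrophoresis; the
resulting "comet" tail reflects the strand-break burden of that cell.  The
damage metric used throughout is the tail moment,

    TM = (% tail DNA × tail length) / 100,

which in Drosophila neuroblasts increases linearly with DNA damage.  Tail
length units are not fixed by the method and are carried through unchanged.
"Hedgehog" comets (nearly all DNA in the tail) signal cytotoxicity; they are
included in all statistics by default, their per-condition fraction is
reported, and an `exclude_hedgehogs` switch removes them.

## Two-tier statistics

Nucleoid-level TM distributions are strongly right-skewed, so within a
single experiment a treated condition is compared to its negative control
with the Mann–Whitney U-test.  The exact null distribution is used when
`n1·n2 ≤ 400` and the pooled sample is tie-free (that threshold is our
choice; only the test itself is dictated by the design); otherwise the
normal approximation with midrank tie correction and continuity correction.
Two constant identical samples yield p = 1, not an error.  All tests are
two-sided (the design does not fix sidedness; two-sided is the conservative
default).

Experiment means are approximately normal, so comparisons across
experiments use paired Student t-tests, pairing by experiment.  Degenerate
cases are guarded rather than raised: all-zero differences give p = 1;
constant non-zero differences give p = 0 with a `degenerate` flag.

The unit of replication is the independent experiment: the ≥50 nucleoids of
each of the (typically two) gels of a condition are pooled into one
experiment mean, and study-level summaries are the arithmetic mean of ≥3
experiment means with SE = sd/√n over experiments.

## Dose–response and line comparison

Spontaneous break levels differ among strains (genetic background), so only
induced damage is compared: `induced TM = treated − control` study mean,
which may legitimately be negative.  Each strain's induced TM is regressed
on dose by OLS.  The zero-dose point is excluded by default: induced damage
at dose 0 is identically 0 by construction, not a measurement, and fitting
the three non-zero doses is the convention that the bundled study table
follows; `include_zero_dose=True` adds a (0, 0) anchor.  With only three
points the slope SE from residual variance is reported as-is; when
per-experiment induced values are available they are the better input for
slope inference.

Strains are compared with a classical common-slope ANCOVA: an F-test of the
dose × strain interaction (slope homogeneity) against the common-slope
model, then pairwise elevation (intercept) contrasts under the pooled
slope, each a t-test on the contrast with the model's residual df.  The
pairwise matrix is symmetric with unit diagonal.  Strains with fewer than
three points are excluded with a warning.  Under identical true lines the
homogeneity test rejects at the nominal rate (checked by simulation).

## Interaction Factor

For wild type (wt), two single mutants and their double mutant, additivity
of the two pathways on the damage scale is tested with

    IF = (induced_wt + induced_double) − (induced_mut1 + induced_mut2),
    SE(IF) = sqrt( Σ over the 8 condition cells of SE² ),

and a normal-quantile CI, `IF ± z_{0.975}·SE` at the default 95% level.
The normal z (1.96) rather than a t quantile is used: it is the multiplier
consistent with the study's printed intervals, and with ≥3 experiments per
cell the difference is immaterial relative to the propagated SE.  The
verdict is `additive` when 0 lies in the closed CI, `synergistic` above,
`antagonistic` below.  Note the independence assumption in SE(IF) is
conservative when treated and control cells share experiment effects (their
covariance is ignored, inflating the SE), so additive coverage runs above
nominal — the calibration simulation confirms this.  A per-experiment IF
with a one-sample t-test against 0 is provided as a clearly-labelled
sensitivity extension.

## Ex vivo incision activity

Nucleoids from treated/untreated wild-type larvae are incubated with buffer
or a strain extract; extra breaks over the buffer lane measure the
extract's incision activity.  Extract lanes are first adjusted for protein
content multiplicatively, `TM × reference / conc`, normalizing to equal
protein input; the reference defaults to the mean extract concentration,
and buffer lanes (no extract) are left unadjusted.  Relative activity of a
mutant extract (MR) vs the efficient-repair extract (ER) is

    100 × (MR − baseline) / (ER − baseline)

computed separately on untreated (spontaneous) and treated (induced) cells.
Values are never clipped.  The primary estimate is the mean of
per-experiment activities with its SE over n experiments (matching the
design's replication unit); the plug-in estimate (formula applied to study
means) is also reported, and disagreement beyond 5 percentage points is
flagged as a nonlinearity diagnostic.  A vanishing ER-over-buffer increment
makes the ratio undefined: below 1e-9 of scale it is a hard error, below
half its own SE a warning of instability.

## Synthetic-data generator

The generator emulates the study design: 4 strains × doses {0, 0.1, 0.5,
1 mM} × 2 gels × 50 nucleoids × 3 experiments in vivo, and treated/untreated
wild-type nucleoids × {buffer + 4 extracts} × 2 gels × 3 experiments ex
vivo.  Nucleoid TM ~ gamma(shape, mean/shape) — the gamma family is a
pragmatic choice for the observed right skew; shape defaults to 2.  The
condition mean is baseline(strain) + induced(strain, dose) + experiment
effect + gel effect, with the experiment effect drawn per
(strain, experiment) and shared across doses, which is what makes paired
cross-experiment tests appropriate.  Defaults: baselines 6.20/4.70/3.29/
2.61 TM, slopes 3.61/4.68/6.02 TM/mM, a 12.0 TM plateau for the double
mutant (emulating its flat, toxicity-limited response), between-experiment
SD 0.78 (reproduces study-level control SEs of ≈0.45), between-gel SD 0.30.
Hedgehog probability grows linearly with dose in mutant strains only.
Ex vivo lanes add incision increments of 4.0 TM (spontaneous) or 8.0 TM
(induced) scaled by per-extract ground-truth activity fractions, and
extract-lane raw means are multiplied by conc/reference so the analysis
must undo a genuine protein imbalance.  `% tail DNA` is drawn uniform in
(5, 95) and tail length solved from TM, so the TM identity is exact and
the percentage cannot leave [0, 100].  `shape = inf` with zero random-effect
SDs gives the zero-noise limit (every TM equals its condition mean), used
to validate estimators exactly.

What the generator does not emulate: measurement error of the image scorer,
non-gamma tails, dose-dependent variance, inter-strain correlation of
experiment effects, or any positive intercept in the induced dose–response
(observed study regressions have one; the generator's induced damage is
linear through the origin).  Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed hierarchy, not robustness
to all features of real comet data.

## Calibration problem sizes

The additivity calibration runs 500 replicate studies per phase (control +
one dose, full pipeline) — additive ground truth sets the double mutant's
slope to s₁ + s₂ − s_wt; the synergy phase injects an offset of 4 × the
median propagated SE from the additive phase.  The ex vivo recovery check
compares one study against 2× the estimator's Monte-Carlo sampling SD taken
over 30 replicate studies (the run-reported SE has only 2 df and is too
unstable to normalize a single-run check).  Null calibrations use 1000
Mann–Whitney replicates and 400 ANCOVA replicates.  These sizes give
binomial/Monte-Carlo noise comfortably inside the asserted bands.

## Known limitations

- Slope SEs from a 3-point OLS on study means do not reproduce slope SEs
  computed from per-experiment replicates; when only means are available
  the residual-based SE is reported and should be read accordingly.
- The IF operates on the additive damage scale only; no multiplicative
  epistasis model is offered.
- The relative-activity ratio estimator carries small-sample ratio bias of
  order (SE of denominator / denominator)²; with three experiments this is
  a few percentage points and is visible in the plug-in vs per-experiment
  comparison.
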