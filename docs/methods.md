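# Methods

`spermflow` implements the computational side of a boar-semen storage study:
per-cell flow-cytometry statistics for a panel of chromatin and physiology
assays, CASA motility subpopulation extraction, and the multivariate layer
that relates the per-sample variables to male identity and storage time.  A
seeded synthetic-data generator emulates the study design so every stage can
be validated against a known estimand without any external data.

## Study design and data model

The emulated design is `boars x ejaculates_per_boar x days` (defaults
36 x 3 x {D0, D11}): every artificial-insemination dose is analysed fresh
(day 0) and again after 11 days of cooled storage, giving 216 samples under
the defaults.  Each sample carries one per-cell event table per assay
(at least 5000 events by default) and one per-cell CASA kinematic table.
Channel values live on a 10-bit display scale (`channel_max = 1023`);
values beyond full scale are clipped and the clipped mass is counted
(pile-up), never discarded.

## Per-cell statistics (cytometry module)

**Gating.** Debris is excluded by stain negativity: an event is kept if any
of the gate channels exceeds the nuclear-stain cut (default 100 channel
units).  For the acridine-orange assay this is the double-negative rule
(debris iff both green and red are at/below the cut); the physiology panel
without a permeant nuclear stain uses a side-scatter cut instead.  Gating
reports account for every input event; samples with fewer than 5000 gated
events are flagged, never silently dropped.

**SCSA.** Per-cell fragmentation index `DFI = 1000 * red/(red + green)`;
`%DFI` is the fraction of cells with DFI strictly greater than 250, `SD-DFI`
the (n-1) standard deviation of per-cell DFI, `%HDS` the fraction with green
fluorescence above a fixed position on the channel scale, `0.65 *
channel_max` by default.  The high-stainability rule is deliberately a fixed
channel cut, not an event percentile: an event-percentile reading would pin
%HDS near 35% by construction, while observed high-stainability fractions in
boar semen sit at a few percent.  The cut is configurable.

**mBBr.** Median fluorescence of the untreated split (optionally divided by
a daily standard-sample median), low/moderate/high fractions from fixed
bounds, and the disulfide-bridge index `(median_DTT - median_untreated)/2`
from the paired dithiothreitol-reduced split, whose reduced protamine
network exposes the full thiol complement.  A negative index is reported
with a quality flag.  Default references are 1.0 (raw channel medians);
with references set, only relative comparisons are meaningful.

**CMA3 / 8-oxo-dG.** Median fluorescence plus low/moderate/high fractions
(CMA3) or the high-FITC fraction (8-oxo-dG).  The low/high gate bounds for
mBBr and CMA3 are analysis choices frozen in config; `reference_bounds`
derives them as the 5th/95th percentile of a pooled day-0 reference signal
when no better calibration exists.  The synthetic defaults (110, 360) sit at
the generator's component boundaries, which is what that percentile rule
converges to on well-separated mixtures; truth-recovery tests require
bounds fixed a priori, so the fixed values are the default.

**Physiology.** Conditional fractions within their stated denominators:
viability (PI- or H258-), early apoptosis among viable (YO-PRO-1+ of PI-),
capacitation and acrosomal damage among non-apoptotic, mitochondrial
activity overall, mitochondrial superoxide among viable, and cytoplasmic ROS
as the probe median of viable cells.  An empty denominator yields NaN with a
flag rather than a failure.

## Motility (CASA) module

Derived ratios are `LIN = 100*VSL/VCL`, `STR = 100*VSL/VAP`,
`WOB = 100*VAP/VCL`; the dance measures are defined as `DNC = VCL * ALH`
(um^2/s) and `DNCm = DNC/VSL` (um), the definitions consistent with their
customary units; DNCm is undefined (NaN, flagged) at VSL = 0.  A cell is
progressive iff `VCL > 25 um/s and STR > 45%`; motile iff `VCL >= 10 um/s`
(the motile cut is configurable; the progressive rule is the assay's
criterion).

Subpopulations come from the common two-stage ("double clustering") scheme:
stage 1 compresses the z-scored kinematic cloud (VCL, VSL, VAP, LIN, STR,
WOB, ALH, BCF) with k-means into 40 centroids; stage 2 merges the centroids
by Ward linkage and cuts the tree at the k in 2..6 with the best cell-level
silhouette (evaluated on at most 10 000 cells).  DNC and DNCm are excluded
from the feature set by default because they are deterministic functions of
the others and would double-count.  K-means is fitted on lexicographically
sorted rows and labels predicted for the original order, so results are
invariant to row order at fixed seed.  Clustering pools motile cells across
all samples of a run; subpopulation percentages are then computed per
sample.  Cluster labels are ordered by ascending standardized VCL for
stability.

## Multivariate layer

**Mixed models.** Each per-sample variable is modelled as
`y ~ Day + Boar + Day:Boar` (sum-to-zero coding) with a random intercept for
the ejaculate nested in boar, fitted by REML.  Fixed terms are tested by
Wald F with containment denominator degrees of freedom: within-unit terms
(Day, Day:Boar) use `n - rank([X Z])`, the between-unit term (Boar) uses
`#units - #boars`.  Under a balanced design this reproduces split-plot
ANOVA exactly, so the day test is exactly calibrated there (verified by a
500-replicate null simulation at 12 x 2 x 2 in the test suite);
Satterthwaite approximations are not available in the underlying fitter,
and containment is the standard exact alternative for this layout.
Reported day means are marginal means (predictions averaged over boars),
equal to raw day means under balance.  A singular or non-convergent mixed
fit falls back to the fixed-effects model with a flag.

**Correlations.** Pearson r over all variable pairs; Benjamini-Hochberg
adjustment over the upper triangle; pairs with adjusted p > 0.05 are masked.
Correlation and variable-clustering analyses run separately per analysis
day (fresh vs stored associations differ); the PCA pools both days so the
storage contrast can express itself on the leading component.

**Hoeffding's D.** Computed from midranks R, S and bivariate ranks Q (the
point itself plus points strictly smaller on both axes, half credit for
ties) via the classical 30-times-normalised combination of the three
counting sums, giving a range of [-0.5, 1] with 1 at perfect functional
dependence of either direction.  Variable clustering uses `1 - D` as the
distance with average linkage (configurable); an undefined D (constant
variable) propagates as maximal distance with a flag.

**PCA.** Eigen-decomposition of the correlation matrix (variables
standardized), so eigenvalues sum to the number of variables, loadings are
variable-component correlations, and a variable's contribution to a
component is `100 * loading^2 / eigenvalue`.  Because eigenvector signs are
arbitrary, each component is oriented so its largest-|loading| variable
loads positively.  Observations are clustered by Ward linkage on the first
two component scores, cut at k = 2 (both configurable), which under the
default generator separates fresh from stored samples.

## Synthetic-data generator

Fluorescence is drawn from log-normal mixture components on the channel
scale — the standard working model for positively skewed cytometry signal —
with a broad low-intensity debris component (default 5% of events).  No
distributional claim is inherited from real instruments; the shapes are
modelling choices.  Key default components:

* SCSA: main population green ~ 500 / red ~ 70; fragmented tail with red
  raised so per-cell DFI reliably exceeds 250 (1.1% of sperm at day 0);
  high-stainability component green ~ 850 (4.5%); debris ~ 10 on both
  channels.
* mBBr: low/moderate/high components at 60/200/650 (x a location factor),
  sigma 0.12, so the default gate bounds (110, 360) sit in the gaps; the
  DTT split scales all sperm components so its mixture median exceeds the
  untreated one by twice the intended disulfide index (33 channel units at
  day 0).
* CMA3 mirrors mBBr without the paired split; 8-oxo-dG is a basal plus
  high-damage FITC mixture; the physiology panels draw per-cell Bernoulli
  states with the panel's conditional structure and map them to bright/dim
  log-normal marker signal.
* CASA: three swimming patterns (slow, fast, hyperactivated-like) with
  VCL log-normal and STR, WOB logit-normal, so `VSL <= VAP <= VCL` holds for
  every cell by construction and the ratio identities are exact; an
  immotile fraction (20% at day 0) sits near VCL ~ 4 um/s.

Boar and ejaculate identities act as Gaussian random intercepts on the
logit (fractions) or log (intensities) scale; storage day is a fixed shift
on the same scale.  Default effect directions and magnitudes reproduce the
storage response the assay panel is designed to detect: a large disulfide
drop with mBBr redistribution toward the low-fluorescence fraction, modest
increases in fragmentation, high-CMA3 and DNA oxidation, near-null CMA3
boar variance, declining motility with a growing slow subpopulation.
Sampling is driven by `SeedSequence(seed, spawn_key=(boar, ejaculate, day,
assay))`, so identical seeds give bit-identical studies regardless of
consumption order.

Every simulated table carries the *model-implied* value of each downstream
statistic (tail probabilities and gate fractions integrated against the
realized mixture, mixture medians solved numerically), so truth-recovery
tests compare each estimator with its actual estimand rather than a nominal
component weight.  What the generator does **not** emulate: spectral
overlap/compensation, acquisition drift, doublets, inter-instrument scale
differences, or the empirical joint distribution of any real data set —
passing tests certify the estimators and the statistical layer, not
instrument-specific behaviour.

## Validation strategy and problem sizes

The test suite checks hand-computable oracles exactly (the 10-event SCSA
worked set; Hoeffding's D on 5-point patterns and against a literal loop
evaluation of its counting definition on random tied/untied inputs), PCA
identities to 1e-8, and truth recovery at the full default study size
(36 x 3 x 2 samples, 5000 events each).  With roughly 3000 three-sigma
recovery comparisons, a handful of chance exceedances is expected
(~0.27% per comparison); the suite asserts exceedances stay at chance level
(at most 1%) and estimator families are unbiased, rather than demanding
literally zero three-sigma events, which a correct generator would fail.
The mixed-model type-I simulation uses 500 replicates at a reduced
12 x 2 x 2 design; the clustering recovery test uses three well-separated
kinematic components at n = 2000, where >95% label agreement is attainable
— the generator's default slow/fast/hyper components overlap in VCL and are
kept as realistic study conditions, not as a clustering benchmark.

## Known limitations

* CSV is the only event-table format; cytometry standard-format readers can
  be slotted in at `io.read_event_data` without touching the statistics.
* Gate bounds and positivity cuts are global per run; per-sample adaptive
  gating is out of scope.
* Complete-case handling only in the multivariate layer; no imputation.
* The containment-df F-tests are exact only under balance; heavily
  unbalanced designs would warrant a Satterthwaite/Kenward-Roger fitter.
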