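# Methods

## The evaluation model

A marker panel is judged as a diagnostic classifier. The panel's resolved
probe rows form the feature matrix (samples × features); each of four
classifiers — linear SVM (C = 1), random forest (500 trees), a one-hidden-
layer neural network (8 units), and a CART tree (Gini, minimum leaf 2) —
is evaluated by leave-one-out cross-validation (LOOCV). Features are
standardized with train-fold mean/SD for the scale-sensitive SVM and
neural network; tree methods see raw values. Each classifier emits a
continuous decision score for the held-out sample (signed margin for the
SVM, positive-class probability otherwise) and a hard label at its native
decision boundary; a user-defined cut-off plays no role in classification
(cut-offs apply only to survival dichotomization).

Because a one-sample fold has no per-fold measures, LOOCV output is
*pooled*: all held-out hard labels form one confusion table (giving AC, BA,
SN, SP, PPV, NPV, FPR, FDR, F1) and all held-out scores form one ROC
(giving AUC, computed as the tie-aware Mann–Whitney concordance). Folds
whose training part contains a single class are skipped and the count
disclosed. The consensus record is the arithmetic mean of each measure over
the classifiers that define it; undefined measures (degenerate
denominators) are NaN and simply drop out of the mean. Train/test and
stored-model schemes fit once on the training set; for cross-dataset
portability a stored model uses one feature per marker *name* (the mean of
its member probes), so the feature dimension is invariant to how many
probes a symbol hits in a given platform.

### A known artifact: pooled-LOOCV pessimism under the null

Pooling held-out scores across folds makes the null distribution of AUC
*pessimistic*: leaving a sample out nudges the fold's model away from that
sample's class, so on label-independent data the pooled AUC centers below
0.5 (≈0.42 for two features at 50 vs 50 in our simulations, and collapsing
toward 0 in the extreme one-feature case). This is a property of the
pooling design, not a bug: a null panel can look *worse* than chance but
never spuriously discriminative, and every quantity we attach inference to
is referenced to an empirical null that shares the same bias (below), which
cancels it. Raw AUC values of weak panels at small n should nevertheless be
read with this in mind.

## Size-matched empirical null and standardization

Raw measures inflate with panel size, so an observed consensus measure
t_o for an m-probe panel is compared with n random m-probe sets drawn
uniformly without replacement from all probes of the same dataset
(the observed panel is not excluded; the inclusion bias is O(m/#probes))
and evaluated by the *identical* LOOCV procedure. The standardized measure
is z = (t_o − t̄)/s with s the (n−1)-divisor SD, and the empirical p-value
counts null draws at least as good as the observation, ties counting
against the observed panel. Two counting modes are provided:
`as_printed` p = c/n, and the default `add_one` p = (1+c)/(n+1), which
keeps p strictly positive so that Fisher/Stouffer combination downstream
never sees p = 0. The default resample count is n = 1000 (configurable);
the resampling is deterministic given a seed, and null values can be cached
on disk keyed by dataset content, m, n, measure, classifier set and seed.

The influence of one marker is t(full panel) − t(panel without it), both
runs under the same scheme and seeds. The subset search evaluates every
non-empty subset of the panel (capped at 12 names, 4095 subsets), shares
one null per distinct resolved subset size — resampling replicate r draws
one random probe set per size — and adjusts the per-subset empirical
p-values by Westfall–Young free step-down minP over those shared
replicates: each replicate's measure is converted to a within-column rank
p, successive minima are taken over the subsets ordered by raw
significance, and monotonicity is enforced. This construction makes a
singleton family's adjusted p equal its raw p exactly, in both counting
modes, including ties. A label-permutation variant of the resampling unit
is available (`wy_unit="label_permutation"`); it is considerably slower
because every permutation re-evaluates each subset size.

## Combining evidence across datasets

Per-dataset p-values p_1..p_k are combined by minP (reported without Šidák
adjustment and flagged anti-conservative), Fisher (upper χ²_{2k} tail of
−2Σln p_i), Stouffer (1 − Φ(ΣZ_i/√k), Z_i = Φ⁻¹(1−p_i)), or weighted
Stouffer with w_i = 4/(1/n_i^case + 1/n_i^control) — four times the
harmonic-mean effective sample size — entering the numerator unsquared
against a √(Σw_i²) denominator. Because that convention differs from the
common √N_eff weighting, the latter is available via `sqrt_weights=True`.
p = 1 inputs are accepted; Φ⁻¹ is guarded by clamping p at 1 − 1e−12.

## Preprocessing

Datasets whose overall missing rate exceeds 5% (strictly) are excluded.
Below that, missing cells are imputed by the unweighted mean of the k = 10
nearest probes (Euclidean distance over co-observed samples, via
scikit-learn's KNNImputer); observed cells are never altered, and k is
clamped with a warning when fewer neighbor probes exist. Quantile
normalization maps every sample column onto the across-sample mean of
order statistics (computed over complete rows when data are missing);
within-column rank order is preserved and tied inputs stay tied. Sample QC
computes each sample's mean Pearson correlation to its own class and to
the other class, and flags a sample whose within-class mean falls more
than 3 SD (configurable) below its class average; constant samples have
undefined correlation and are flagged outright. Flags are advisory — they
mark samples for the user rather than removing them. Note the 3-SD rule
can only fire in groups of roughly a dozen samples or more, since the
maximum |z| within a group of size g is (g−1)/√g. RNA-seq input is
accepted as a pre-transformed log2-CPM matrix; no count model is fitted.

## Survival

A marker (multi-probe markers reduced to the mean of member probes) is
dichotomized at a user-chosen quantile, "high" meaning strictly above it.
Kaplan–Meier curves, the two-group log-rank test (standard hypergeometric
variance with ties; p from the upper χ²₁ tail) and Cox regression are
delegated to lifelines; Cox uses Breslow tie handling and reports
non-convergence or a degenerate (constant) covariate as a flagged result
rather than an exception. The continuous Cox covariate is standardized so
the hazard ratio is per SD of expression.

## Synthetic data

The generator emulates two-class microarray-style data: per-probe baselines
uniform on [6, 12] log2 units, Gaussian noise of SD 1 (configurable), and
planted markers whose case mean is shifted by a chosen multiple of the
noise SD. Missingness is uniform with the realized count exact to one
cell. Survival times are exponential with hazard 0.1·exp(β·z) in the
marker's standardized expression, with independent exponential censoring
tuned to the requested censored fraction. Two presets fix the study
designs used throughout the tests: `cldn_toy` (38 cases vs 31 controls,
200 probes, a three-claudin panel with effects 1.5/1.0/2.0 SD —
CLDN18 strongest, CLDN4 weakest) and `panel7` (46 vs 45, 300 probes, seven
named genes of which only BRIP1 at 2.0 SD and RB1 at 1.5 SD are
informative). What the generator does *not* emulate — probe-level platform
effects, batch structure, heavy-tailed or count noise, correlated gene
modules — bounds what green tests mean: they certify the machinery
(calibration, recovery, exactness of formulas) under the assumed Gaussian
model, not performance claims on any real cohort.

## Problem sizes and numerical choices

The simulation-based tests use deliberately chosen desk-scale designs:
null calibration uses ten independent 40-sample datasets, each with one
preconstructed 199-resample null shared by 20 random query panels
(mirroring the preconstructed-null design of the tool itself); recovery
uses twenty 50-sample replicates against 199-resample nulls; the subset
search demonstration runs the 127-subset family at 99 resamples. The
resampling-heavy checks use the linear SVM alone — its continuous margins
make pooled AUC effectively tie-free, so the ≥-counting rule is not
artificially conservative — while the consensus of four classifiers
remains the user-facing default. Equal scores in a measure are handled by
the tie rules stated above; identical probe sets drawn in degenerate
designs (m = #probes) give a null SD of 0, in which case z is NaN and the
empirical p remains valid.

## Known limitations

- Pooled-LOOCV raw measures are pessimistic at small n under weak signal
  (see above); use the standardized z/p, which are calibrated by
  construction, for inference.
- The minP combination is anti-conservative as a p-value; it is reported
  as a summary, flagged.
- Westfall–Young adjustment at resolution 1/n cannot distinguish adjusted
  from raw p when the observation beats every resample; increase n for
  sharper adjusted values.
- Cross-dataset merging in pairwise mode performs per-dataset quantile
  normalization but no batch correction; residual dataset effects inflate
  apparent separation between types measured on different platforms.
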