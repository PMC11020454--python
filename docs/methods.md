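# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Immunofluorescence scoring (`ifquant`)

Two scores are computed per microscope field from co-registered DAPI and
marker (β-catenin-type) channels:

- *Field intensity*: mean of foreground marker pixels divided by the
  slide-wide mean DAPI value. The slide-level DAPI standardization removes
  slide-to-slide illumination and staining differences, so fields from the
  control and treated slides of one donor are on a common scale.
- *Nuclear localization*: the mask of non-background DAPI pixels defines
  the nuclear compartment; the score is mean marker over those pixels
  divided by mean DAPI over the same pixels.

Background elimination defaults to Otsu (between-class-variance)
thresholding per channel per field; `quantile` and `fixed` rules are
available because the appropriate rule depends on the acquisition. The
slide DAPI mean is computed over foreground DAPI pixels pooled across all
fields — background pixels carry no nuclear signal, so including them would
make the standardization depend on the empty area of each field; a flag
restores all-pixel averaging. Fields whose mask leaves no foreground are
excluded and logged, never imputed, and a slide summary requires at least
five usable fields — the minimum the donor-level comparisons are defined
on. Donor pairs are compared by a paired two-sided t-test of slide means.

Both scores are ratios, so jointly rescaling every pixel of a slide leaves
them invariant, while rescaling only the marker channel scales them
linearly; both properties are tested.

## Antibody-array densitometry (`arraydens`)

A chemiluminescent membrane is imaged serially (default every 2 s) while
signal accumulates. Spot density is the mean intensity inside the spot
disc. A spot is *saturated* on a frame when ≥ 5% of its disc pixels sit at
the camera's clip level (the bit-depth maximum by default); the 5% default
is configurable — any nonzero clipped fraction already biases a mean
density, but a small tolerance keeps single hot pixels from discarding an
otherwise usable exposure. The quantification frame for an analyte is the
latest frame strictly before the first saturation of the analyte's spots
*or* of any positive-control spot, on either membrane, so both membranes
are quantified at a common, unclipped exposure.

Background is the pooled mean of NEG and BLANK spots on the same frame;
duplicate analyte spots are averaged after subtraction and floored at zero.
The treated membrane is normalized by the positive-control ratio
POS_control/POS_treated (POS spots carry equal loading on both membranes),
which cancels any global exposure difference between membranes — verified
numerically as an invariance test. Analytes with zero corrected control
density are flagged undefined rather than given an infinite fold change.
Detection ("clearly detected") defaults to corrected density above 3·SD of
the negative-control spots on every membrane considered; k is a parameter
since the underlying criterion is a judgment call.

Clustered heatmaps use agglomerative average linkage on Euclidean
distances, on both donors and analytes, with the color map centered at 0 on
the log2(FC) scale; ties resolve by input index order, so ordering is
deterministic.

## ΔΔCq panels and centroid scoring (`qpcrpanel`)

Relative expression per donor: ΔCq = Cq_gene − Cq_housekeeping within each
arm, averaging technical replicates *before* differencing (standard ΔΔCq
practice); ΔΔCq = ΔCq_wnt − ΔCq_control and FC = 2^−ΔΔCq, assuming ~100%
amplification efficiency (no Pfaffl correction). The panel matrix is
donors × genes of log2(FC) with no imputation — a donor missing any panel
gene is an error listing the gaps, because silently dropping or filling
panel entries would distort the embedding.

PCA z-scores each gene column (sample SD, ddof = 1) by default so that
genes with large fold-change variance do not dominate; a flag disables
scaling. Components are oriented so each component's largest-magnitude
loading is positive — distances to the centroid are invariant under any
rotation/reflection of the embedding (tested), so the convention only
stabilizes plots. Each donor's score is its Euclidean distance in the
(PC1, PC2) plane from the centroid (coordinate-wise mean) of the healthy
donors; healthy donors are scored against their own centroid and enter the
ANOVA as a group, with Dunnett many-to-one comparisons against healthy.

## 4PL ELISA curves (`assaycurves`)

OD = d + (a−d)/(1+(x/c)^b) with a/d the upper/lower asymptotes, c the
inflection concentration and b the slope; rising ELISA curves carry b < 0
in this parameterization and x = 0 is evaluated as the corresponding
limit. Fitting is bounded least squares (c > 0) initialized from the data
extremes, with the slope sign seeded from the observed trend; a
non-monotone fit over the standards' range logs a warning. Inversion is
the analytic x = c·((a−d)/(OD−d) − 1)^(1/b); ODs outside the open
asymptote interval raise an out-of-range error labeled below/above the
quantifiable range rather than extrapolating. Replicate ODs are inverted
individually and reported as mean ± range, which surfaces replicate
disagreement that averaging before inversion would hide. A "1:n" dilution
annotation is read as (n+1)-fold by default (one part sample in n parts
diluent) with an n-fold override; the parser logs the reading used.

## Transwell migration (`migrate`)

Duplicate wells are averaged per donor (arithmetic mean) before any
statistics. The media comparison is a paired two-sided t-test of Wnt-media
vs control-media counts per donor. The inhibitor metric is the direct
per-donor ratio count(with inhibitor)/count(without) within the Wnt-media
arm, averaged arithmetically over donors; the ratio cancels any
acquisition-time scaling common to a pair. Control-media normalization
before the ratio is available but off by default.

## Differential expression (`destage`)

Size factors are median-of-ratios: over genes with nonzero counts in every
sample, factor_j = median_g(count_gj / geometric-mean_g), computed as a
log-space median (identical for an odd number of reference genes; for even
counts the two middle ratios combine geometrically, matching the reference
tool's behavior). The NB Wald stage — per-gene NB GLM with log link and
size-factor offsets, trend-moderated dispersions and a two-sided Wald test
on the treatment coefficient — is delegated to pydeseq2 behind this
module's interface, with the design *~donor + treatment* (donor as an
additive covariate; a flag drops it). Cook's-distance refitting and
independent filtering are off, so padj ≥ p holds componentwise under BH;
all-zero genes are dropped before testing. The significance filter is
padj < 0.05 and |log2FC| > 1 (fold change > 2) on the unshrunk estimate,
with direction from the sign of log2FC.

The batch-removed PCA works on log2(normalized count + 1): per gene an
ordinary linear model with centered donor contrasts and the treatment term
is fitted and only the donor contribution subtracted (so the treatment
effect survives), then PCA runs on the 500 highest-variance genes of the
adjusted matrix.

## Statistical primitives (`statcore`)

All tests are two-sided. Paired t uses ddof = 1 and df = n−1; zero variance
of differences is a degenerate-test error, not p = NaN. BH is the step-up
procedure with values restored to input order. Dunnett's many-to-one
comparisons use pooled-variance statistics; the family-wise adjusted p is
evaluated by seeded Monte Carlo from the exact null structure
corr(T_i,T_j) = ρ_iρ_j, ρ_k = √(n_k/(n_k+n_0)) with a shared χ²(df)
denominator (default 10⁵ draws; half-width tolerance ≈ 1.96·√(0.25/n)
reported alongside). Monte Carlo was preferred over quadrature because it
extends to any number of groups and is directly checkable against an
independent full-layout simulation, which the tests do.

## Synthetic generators (`synthio`)

Every generator uses a single `numpy.random.default_rng(seed)` stream and
records all parameters plus the ground truth in a JSON-serializable
`TruthRecord`; identical seeds give bit-identical data.

- *Slides*: nuclei are Gaussian-profile discs (radius 7 px, σ = radius/1.6)
  on a constant background with Gaussian read noise; cytoplasm is a uniform
  annulus. The treated slide multiplies the nuclear marker amplitude by the
  enrichment factor. Defaults (10 fields of 160×160 px, 12 cells per field,
  background 150, noise SD 60 at 16 bits) keep nuclear signal well above
  background, as in usable confocal fields; the constant background under
  nuclei biases the recovered ratio a few percent toward 1, which is why
  recovery is asserted at ±10%, not exactly.
- *Exposure series*: spot signal grows linearly with exposure time and
  hard-clips at the saturation cap (the camera's bit-depth maximum in the
  realistic setting; an infinite cap models an ideal detector in tests).
  Duplicates share expected density; POS spots have a fixed known loading;
  NEG/BLANK carry background only. Chemiluminescence decay kinetics are not
  modeled.
- *Cq tables*: per-gene baseline Cq ~ U(22, 29) (housekeeping at 20),
  per-donor shifts N(0, 0.3), treatment effects subtract the group log2FC
  from the Wnt-arm Cq, replicate noise N(0, 0.2–0.3 cycles) — typical
  plate-level variability.
- *Count matrices*: NB counts with lognormal base means, per-(donor, gene)
  multiplicative batch effects (log2 SD 0.25 default), library factors
  U(0.7, 1.3), and a spiked DE set of alternating sign; the design mirrors
  the study's two-donor, six-per-arm layout. This is a bulk RNA-seq
  caricature, not a full simulator: no GC/length bias, outliers or
  correlated gene modules.
- *ELISA plates*: ODs on a known 4PL curve (8-point two-fold standard
  series around the inflection, duplicate wells, OD noise SD 0.02).
- *Transwell tables*: counts = round(expected · exp(N(0, σ))) with donor
  multipliers and condition/inhibitor effect multipliers, duplicate wells;
  σ = 0 gives the deterministic limit used by the closed-form tests.

Passing recovery tests on these fixtures shows the pipelines compute their
defined quantities correctly and recover known effects under the stated
noise; it does not validate the biological models against real microscopes,
membranes or sequencers.

## Problem sizes

The recovery and power checks use 20 replicate seeds (50 for the scalar
transwell/ELISA recoveries), a 5 000-gene null and a 2 000-gene spiked
matrix at six samples per arm, and 10⁵–10⁶ Monte Carlo draws for Dunnett
p-values — sizes at which every Monte Carlo margin is several times its
standard error.

## Known limitations

- The original immunofluorescence script's exact background rule is not
  public; Otsu is a defensible default and the choice is configurable.
- The array detection criterion ("clearly detected") and the spreadsheet's
  exact background arithmetic are not published; defaults are explicit
  (k = 3 SD, NEG+BLANK pooled) rather than inferred.
- ΔΔCq assumes equal amplification efficiencies; no melt-curve QC.
- The DE stage reproduces the reference tool's defaults through pydeseq2;
  exact reproduction of published gene counts depends on the original
  design formula and filtering settings, which are not stated.
- Published-number checks (DE counts 914/362/552; inhibitor fold changes
  1.01/0.76) require the deposited count matrix and raw transwell counts,
  which must be downloaded separately.
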