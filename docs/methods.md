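# Methods

## Scope and data model

`ithquant` quantifies spatial intra-tumor heterogeneity (ITH) from
already-segmented whole-slide label maps. Inputs per patient are a tissue
region map (tumor / stroma / other), classified nucleus centroids (tumor,
immune, connective, normal-epithelial), patch-level digital grade and
nuclear pleomorphism maps (levels 1–3), four binary differentiation
component maps (tubule-forming, mitosis-rich, high-cellularity,
discohesive architecture), and a DCIS mask. Upstream segmentation and
classification are out of scope; the package consumes their label-map
outputs.

All spatial processing uses one coordinate convention: row-major grids,
pixel (0, 0) at the top-left, 0-based indices. Nucleus centroids arrive in
full-resolution frame pixels and are rasterized with a floor rule at
five-times down-sampling — one pixel per nucleus, collisions resolved
last-writer-wins after sorting by (y, x, class code) so the raster is
independent of input order. Everything downstream operates on the
down-sampled analysis grid.

## Patch grid

Analysis layers are reduced to per-patch occupancy fractions on
non-overlapping square patches tiling the map from the top-left. The patch
side is 62 µm (3844 µm² area), rounded to whole pixels; incomplete edge
tiles are dropped. A patch is valid if its tissue coverage is ≥ 50 % and it
has no overlap with the DCIS mask — any overlap invalidates, erring toward
purity since no quantitative exclusion threshold is standard. DCIS
exclusion zeroes every analysis layer inside the mask and is idempotent.
Graded layer groups (grade, pleomorphism) are summarized per patch by the
member with the largest fraction, ties broken toward the lower level so the
summary is deterministic and conservative.

## Texture features

For each layer, a per-patch presence map is binarized and a co-occurrence
matrix (CM) is accumulated between valid patch pairs over the eight
unit-offset neighbour directions; the raw count is divided by two (each
unordered pair counted once per orientation) and normalized to sum to one,
giving a symmetric probability matrix p(i, j). Area layers (regions,
grade/pleomorphism levels, differentiation components) binarize at 0.1
patch fraction. Nuclei layers are rasterized points whose pixel fraction is
~10⁻² even at high cell density, so their presence criterion is "at least
one labelled pixel in the patch"; a fixed 0.1 threshold would declare them
absent everywhere.

Statistics per CM: contrast Σp(i,j)(i−j)², dissimilarity Σp(i,j)|i−j|,
homogeneity Σp(i,j)/(1+(i−j)²), heterogeneity = 1 − homogeneity,
correlation Σp(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ), uniformity Σp(i,j)², energy
√uniformity, entropy −Σ_{p>0} p log₂p (bits). Uniformity is the sum of
squared CM elements and energy its square root; the linear-off-diagonal
reading of "energy" is covered by dissimilarity, so both readings of that
ambiguous convention are available. Degenerate cases are data, not errors:
a layer with no valid neighbouring pair yields missing texture values, and
correlation on a constant presence map (σᵢσⱼ = 0) is flagged undefined and
recorded as missing rather than silently zero, because silent propagation
would corrupt the cohort normalization.

Colocalization of two layers is Σₖ min(aₖ, bₖ) / Σₖ max(aₖ, bₖ) over valid
patches: 0 exactly when supports are disjoint, 1 exactly when the fraction
profiles coincide. When neither layer is present the statistic is undefined
and recorded missing.

### The 162-feature catalogue

The default catalogue is 18 layers × 8 texture statistics = 144, plus 18
designated colocalization pairs, totalling 162. Layers: 3 region (tumor,
tumor-associated stroma, other stroma), 5 nuclei (tumor nuclei,
intratumoral immune, stromal immune, connective, normal-epithelial), 3
grade, 3 pleomorphism, 4 differentiation components. Every feature belongs
to exactly one family: grade, pleomorphism, differentiation-component and
tumor-nuclei features → **differentiation**; region, connective and
normal-epithelial features → **stroma**; immune features → **TILs**;
colocalization pairs are assigned family-by-pair in the catalogue. The
catalogue is data (YAML-serializable) and fully configurable; 162 is the
default structure, not a hard-coded constant.

## Overall ITH score

Features are min–max scaled to [0, 100] across the cohort; constant or
all-missing features cannot be scaled and are dropped with a warning.
Family heterogeneity scores are pairwise-complete means of the scaled
member features. Each scaled feature is screened by a univariate Cox
regression on the chosen endpoint (breast-cancer-specific-survival-style
primary endpoint by default; a DMFS-style endpoint is selectable), keeping
features with Wald p < α (default 0.05).

The screened features enter one multivariable Cox fit (Efron tie handling,
Wald inference, via lifelines). Exact collinearity is removed first by
pruning one of each pair with |Pearson r| > 0.95, keeping the smaller
univariate p. When the data cannot support the fit — fewer than 10 events
per remaining covariate — the maximum-partial-likelihood coefficients of
dozens of correlated features are numerically fragile (sign flips,
magnitude blow-ups), so the fit applies an L2 (ridge) penalty whose
strength is chosen by 3-fold cross-validated partial likelihood over the
grid {0.01, 0.1, 1, 10}. A fixed small penalty (0.01) remains the fallback
when a well-posed fit fails to converge. The overall score is
`a + Σ bᵢ·xᵢ` with the scaled features xᵢ; the offset a is 0 by default
because a Cox partial likelihood identifies no intercept — a is a pure
display shift.

### Cut-point selection

The score is dichotomized at the cut-point minimizing the two-group
log-rank p-value, scanning the midpoints between consecutive distinct
scores subject to a minimum group fraction (default 10 %) on both sides;
ties in the minimum go to the lower cut-off. Scores strictly above the
cut-off form the heterogeneous ("high") group. Because a minimum over many
correlated tests is optimistic, the Miller–Siegmund correction

p* = φ(z)(z − 1/z)·ln[((1−ε₁)(1−ε₂))/(ε₁ε₂)] + 4φ(z)/z,  z = Φ⁻¹(1−p/2)

is reported alongside (ε the group-fraction bounds, p* clipped to
[p, 1] and set to 1 when z ≤ 1). Selection still uses the raw minimum p,
mirroring common practice; the corrected p is for honest inference. The
correction is asymptotic: at n = 100 per cohort its null rejection rate is
at or below nominal in our simulations, while for much smaller cohorts
(n ≈ 60) it can exceed nominal by a small margin.

## Survival machinery

Kaplan–Meier estimation and Cox fitting delegate to lifelines. The
two-group log-rank test is computed directly over pooled risk sets in
numpy (hypergeometric variance with the exact tie factor), both because it
is the inner loop of the cut-point scan and because an independent
implementation can be cross-checked against lifelines — the test suite does
so. The proportional-hazards check augments the single-covariate model with
a genuine time-varying interaction covariate × log t (identity time
optional), fitted on episode-split data, reporting the interaction's Wald
p; PH is conventionally "satisfied" at p ≥ 0.05. Chi-square association
tables (no continuity correction) and one-way ANOVA use scipy.

## Synthetic cohort generator

The generator is the package's validation instrument; its defaults define
the study conditions used in the test suite.

**Spatial model.** Per patient a latent heterogeneity level θ is drawn from
Beta(2, 2), so cohorts contain both homogeneous and heterogeneous tumors.
Patch-label fields (regions with proportions 0.45/0.35/0.20, grade
0.30/0.45/0.25, pleomorphism 0.35/0.40/0.25, component presence 0.20–0.40)
follow a two-stage hierarchical process: a block-constant categorical base
field at the configured correlation length (124 µm ≈ 2 patches by default),
with every patch independently resampled from the marginal distribution
with probability θ. The limits are exact: θ = 0 degenerates to one
contiguous band per class (fully segregated), θ = 1 to i.i.d. patch labels
(maximal intermixing); the expected cross-level neighbour frequency — what
CM contrast measures — is monotone in θ. This process was chosen over a
Gibbs-sampled Markov random field because it controls patch-level mixing
directly, reproduces both limits exactly, and is bit-reproducible from
(seed, patient index) without convergence questions.

**Nuclei.** Homogeneous Poisson points within host regions (tumor nuclei
1500/mm² in tumor, connective 500/mm² in stroma, normal-epithelial 250/mm²
in "other", immune 350/mm² in tumor+stroma with a doubled extra intensity
in the one-patch boundary band of stroma around tumor, making TILs layers
spatially structured). Points are emitted in full-resolution coordinates
and pass through the same ×5 rasterization as real data. Tumor-associated
stroma is stroma within two patch widths of tumor; immune nuclei split into
intratumoral/stromal by the tumor mask.

**DCIS.** Random disk blobs covering ~5 % of tissue by default — enough to
exercise the exclusion path, with no claim to DCIS morphology.

**Survival.** Exponential proportional hazards:
hazard = h₀·exp(β·θ) with h₀ = 0.01/month, independent exponential
censoring at 0.005/month, administrative censoring at 240 months. The
default effect β = 2 per unit θ is sized so that a median-θ dichotomy
implies a hazard ratio near 2, the magnitude typical of prognostic
heterogeneity indices in luminal breast cancer; tests of estimator
recovery use β = 1 explicitly. A correlated DMFS-style endpoint (1.3×
baseline hazard, same θ effect) supports the endpoint switch.

**What the generator does not emulate.** Real H&E texture, nuclear
morphology, multi-slide patients, non-exponential hazards, covariate-
dependent censoring, or inter-feature correlation structures beyond those
induced by θ and shared geometry. Passing end-to-end tests therefore
demonstrates that the pipeline recovers a planted spatial-heterogeneity
effect under its own assumptions — not that the catalogue is prognostic in
any particular clinical cohort.

## Numerical choices and problem sizes

- Default analysis maps are 496 px at 2 µm/px (≈ 1 mm², a 16 × 16 patch
  grid) — small enough for cohort-scale simulation on a laptop while
  leaving ≥ 200 valid patches per map.
- Test-suite study sizes: monotonicity of the fitted score in θ at n = 100
  (Spearman ρ > 0.8); Cox recovery of β = 1 within ±0.15 at n = 1000,
  averaged over 5 replicates because one replicate's standard error is
  itself ≈ 0.15; end-to-end stratification at n = 300; screening type-I
  error with 200 null features at n = 500; cut-point null behaviour over
  500 simulated cohorts of n = 100; PH-check null uniformity over 60
  replicates at n = 80.
- Determinism: every stochastic step derives from
  `numpy.random.SeedSequence((seed, patient_index))` or an explicitly
  seeded generator; fixed seeds give bit-identical maps, tables and CSVs.
- Missingness flows through the pipeline as NaN and is excluded pairwise
  (screening per-feature, family scores pairwise-complete); only the
  multivariable fit, which needs complete rows, imputes residual missing
  values at the cohort feature mean.

## Known limitations

- The 162-feature catalogue is a documented reconstruction of a feature
  family structure, not a canonical standard; alternative catalogues plug
  in via YAML.
- The patch side treats "62 µm" as a square side (3844 µm²); a literal
  62 µm² patch (side ≈ 7.9 µm) could not contain multi-patch texture.
  The side is configurable.
- Cut-point selection by raw minimum p is intentionally optimistic
  (mirroring X-tile); downstream hazard ratios for the dichotomized score
  inherit that optimism. Use the corrected p for inference about the
  existence of a threshold effect.
- The synthetic generator's colocalization features involving mutually
  exclusive patch-pure layers (e.g. tumor × stromal immune) are constant
  zero by construction and are dropped at scaling; on real data with
  sub-patch mixing they are informative.
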