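# ithquant

Spatial **intra-tumor heterogeneity (ITH) quantification** from digital
pathology label maps, with survival-based scoring.

Morphological heterogeneity — how intermixed a tumor's differentiation
states, stroma and immune infiltrates are across the slide — carries
prognostic information that a single summary grade ignores. `ithquant`
works downstream of whole-slide segmentation models: it takes per-patient
spatial label maps (tissue regions, classified nucleus centroids, patch-wise
digital grade and pleomorphism, a DCIS exclusion mask) and turns them into
an interpretable heterogeneity index for survival stratification, targeted
at luminal (ER+/HER2−) breast cancer but agnostic to the upstream models.

## Method

1. **Patch grid.** After DCIS exclusion, every registered layer is reduced
   to per-patch occupancy fractions on non-overlapping square patches of
   62 µm side; patches with <50 % tissue or any DCIS overlap are dropped.
   Nucleus centroids are rasterized onto a five-times down-sampled grid
   beforehand.
2. **Texture features.** For each of 18 analysis layers, a symmetric
   co-occurrence matrix `p(i, j)` is accumulated over the 8 unit-offset
   neighbour directions of the patch grid (counts halved so each unordered
   pair is counted once per orientation, then normalized to Σp = 1).
   From it: contrast `Σ p(i,j)(i−j)²`, dissimilarity `Σ p(i,j)|i−j|`,
   homogeneity `Σ p(i,j)/(1+(i−j)²)`, heterogeneity `1 − homogeneity`,
   correlation, uniformity `Σ p(i,j)²`, energy `√uniformity`, and entropy
   `−Σ p log₂ p`. Eighteen layer-pair colocalization statistics
   `Σ min(aₖ,bₖ) / Σ max(aₖ,bₖ)` complete a default catalogue of
   **162 features**, each assigned to one family: tumor differentiation,
   stroma, or TILs.
3. **Overall ITH score.** Features are min–max scaled to 0–100 across the
   cohort, screened one-at-a-time by univariate Cox regression against
   outcome (Wald p < α), and the survivors enter a multivariable Cox fit.
   The score is the Cox-beta-weighted sum `a + Σ bᵢ·xᵢ`. It is dichotomized
   at the cut-point minimizing the two-group log-rank p-value (X-tile
   style), with a Miller–Siegmund-corrected p reported for the optimism of
   minimum-p selection. Family scores (mean of scaled member features) are
   produced alongside.
4. **Survival analysis.** Kaplan–Meier curves, log-rank tests, Cox models
   with hazard ratios, a time-dependent-covariate proportional-hazards
   check, and chi-square/ANOVA association tables.

Because public WSI cohorts with these label maps are scarce, the package
ships a **synthetic cohort generator**: per-patient label-map stacks whose
spatial intermixing is controlled by a latent heterogeneity level
θ ∈ [0, 1] (θ = 0: one contiguous block per class; θ = 1: i.i.d. patch
labels), and exponential proportional-hazards survival with
`hazard = h₀·exp(β·θ)`. It is first-class, tested code used to validate the
whole pipeline end-to-end.

## Worked example

```python
import ithquant as iq

params = iq.SyntheticParams(n_patients=100, seed=7)
stacks, cohort = iq.generate_cohort(params)

model = iq.ITHScoreModel.from_stacks(stacks, cohort)
res = model.fit()          # screening -> Cox weighting -> cut-point
print(res.summary())
```

```
Overall ITH score model
============================================================
patients: 100    events: 79    endpoint: bcss
features: 154 scaled, 71 screened (alpha=0.05), 24 in Cox fit (penalty=10)
cut-off: -0.09502   min-p: 0.000439   corrected p: 0.0127
high-ITH group: 59 patients, HR 2.36 (95% CI 1.44-3.85)
low/high log-rank: chi2=12.4, p=0.000439
```

Reading this: of the 162 catalogue features, 154 varied in this cohort and
71 were individually prognostic at α = 0.05; after collinearity pruning, 24
entered the ridge-stabilized Cox fit. The resulting score, cut at its
optimal threshold, splits the cohort into 41 low- and 59 high-heterogeneity
patients whose survival differs strongly (log-rank p ≈ 4×10⁻⁴; the
corrected p ≈ 0.013 accounts for scanning all cut-points). High-ITH
patients die at 2.4× the hazard of low-ITH patients — on synthetic data
where high θ truly increases hazard, recovering the planted effect.

`res.scores`, `res.groups`, `res.family_scores`, `res.km_curves()` and
`res.plot_km()` expose per-patient scores, low/high calls, the three family
heterogeneity scores and the group survival curves; `res.to_json(path)`
serializes the fitted model.

The same pipeline runs from the shell:

```bash
ith-quant all --config cohort.yaml --out results/run1 --seed 1
```

writing label maps, the feature matrix, scores, the model JSON, KM/log-rank
tables and a manifest. `simulate`, `features`, `score` and `survival` run
the stages individually from each other's outputs.

## Documentation

`docs/methods.md` describes the model, its assumptions, the synthetic-data
generator, numerical choices and known limitations.
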