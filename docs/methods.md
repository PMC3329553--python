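# Methods

This note records the models, estimators, conventions and deliberate
design choices behind `refstab`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model and Cq handling

Replicate-level Cq values are kept in long form with the unique key
(sample, gene, plate, biological replicate, technical replicate). A Cq the
instrument could not call ("Undetermined") is a first-class missing
marker, distinct from any number and never coerced to 0 or to the cycle
ceiling. Numeric Cq must lie in (0, 45] — 45 is the cycle count of the
typical protocol this workflow targets.

**Technical aggregation.** Technical replicates are averaged on the Cq
scale (arithmetic mean), the standard qPCR practice; averaging quantities
instead would weight replicates by exponentiated noise. The sample
standard deviation (n−1) of the numeric replicates is reported, and a
group is flagged when it exceeds a concordance threshold (default 0.5
cycles, configurable). Undetermined replicates are excluded from the mean
but counted in `n_tech`; a group that is entirely undetermined aggregates
to undetermined. A single numeric replicate reports sd = 0 and is never
flagged. Biological replicates are *not* averaged at the Cq level;
downstream analyses take a replicate selector or an explicit pooled mode,
because biological replicates are separate RNA preparations whose
disagreement is information, not noise to be hidden early.

**Inter-plate calibration.** With a calibrator sample measured on every
plate, each gene's Cq values on plate p shift by
−(Cq_cal(g, p) − mean over plates of Cq_cal(g, ·)). Centering on the
across-plate mean (rather than on any designated plate) makes the result
invariant to plate ordering; the calibrator's own records are shifted by
the same rule. The correction is per (gene, plate): if plate effects are
additive (identical for all genes on a plate), within-plate between-gene
differences are preserved exactly; if the calibrator exhibits
gene-specific plate effects, the per-gene correction removes those too,
by design, at the cost of that invariance.

## Amplification efficiency

Efficiency is carried on two scales used interchangeably in the field:
the amplification factor A ∈ (1, 2.2] (perfect doubling A = 2) and the
fractional efficiency e = A − 1. Both are stored; all arithmetic uses A.

**Standard curve.** Cq is regressed on log10 template quantity (OLS);
A = 10^(−1/slope). The regression orientation matters — this is the
convention that maps the canonical slope −3.3219 to A = 2. Slopes ≥ 0 or
with |slope| < 1 are rejected as implausible (they would imply A ≥ 10 or
a non-amplifying assay). The standard error of A follows from the slope
SE by the delta method, dA/d(slope) = A·ln10/slope².

**Raw-fluorescence (per-reaction) estimator.** In the spirit of
exponential-window methods operating on raw amplification curves:

1. subtract a baseline equal to the mean fluorescence of an early-cycle
   window (default cycles 3–8; skippable for pre-baselined data);
2. fit a four-parameter logistic
   F(c) = Fb + Fmax/(1 + exp(−(c − c½)/s)) by nonlinear least squares;
3. scan all contiguous cycle windows of length ≥ 4 strictly below c½ and
   keep the window maximizing R² of ln F vs c (ties, at 1e−12 resolution,
   broken toward the widest then earliest window);
4. A = exp(window slope), corrected as below;
   Cq = the fractional cycle of the logistic's second-derivative maximum,
   c½ − s·ln(2 + √3).

*Plateau correction.* The local log-slope of a logistic is
ln A · (1 − F/Fmax): even "exponential-phase" cycles below the midpoint
are already flattened, so an uncorrected window regression
underestimates A by several hundredths. When the logistic fit is
available, the window slope is divided by (1 − mean fitted F/Fmax over
the window). The correction is disabled when the logistic step is skipped
(no Fmax), which preserves exactness on pure exponential data: a
noiseless curve F = 0.01·2^c recovers A = 2 to 1e−9. Recovery tests:
noiseless logistic curves recover A within ±0.01; 100 curves with
Gaussian noise of 1% of Fmax at A = 1.93 recover the mean within ±0.03 —
the dispersion scale typical of per-tissue efficiency tables.

Per-gene (or per-tissue) summaries are arithmetic means of per-reaction
A with se = sd/√n (se = 0 by convention for n = 1).

## Relative quantification

For each gene, ΔCq_s = Cq_min − Cq_s ≤ 0 with the lowest-Cq sample
(highest expression) as calibrator, and RQ_s = A^ΔCq_s ∈ (0, 1]. The
Cq < 40 filter is strict (Cq = 40 is dropped). Missing values propagate
as missing and are never imputed; each downstream method declares its own
completeness policy. Per-tissue efficiencies are applied per sample when
provided, otherwise the gene's global efficiency.

**3′:5′ integrity ratio.** mRNA degradation proceeds predominantly from
the 5′ end of oligo(dT)-primed cDNA, so amplicons at the two ends of one
transcript diverge in apparent quantity as RNA degrades. The ratio is
computed as Ā^(Cq_5′ − Cq_3′) with Ā the geometric mean of the two
amplicons' amplification factors — our operationalization of the assay
(the exact published algebra varies); verdicts: intact ≤ 2 < caution ≤ 5
< degraded, thresholds configurable.

## Stability statistics

All three methods work on log2 relative quantities and are invariant to
per-gene rescaling (the calibrator choice is irrelevant) — asserted by
property tests.

**geNorm.** Pairwise variation V_jk = sd(n−1) of log2(RQ_j/RQ_k) across
samples; M_j = mean over k≠j of V_jk. Ranking by stepwise exclusion of
the argmax-M gene until two remain; those two are mutually unrankable and
tie at the top. Ties on M break lexicographically by gene id and are
logged. Samples missing any gene are dropped (complete-case); imputation
is rejected — a geNorm matrix must be real measurements.
V_{n,n+1} = sd of log2(NF_n/NF_{n+1}) where NF_n is the per-sample
geometric mean of the top-n genes; the smallest n with V ≤ 0.15 is
*suggested* alongside the full series, since the 0.15 value is a
guideline, not a hard rule. The stepwise implementation is verified
against a from-scratch brute-force recomputation of the definitions on
random matrices to 1e−12.

**NormFinder-style decomposition.** Within each group g, residuals after
removing gene and sample main effects estimate the intragroup variance;
per-sample centering with k genes biases the naive variance down by
(k−1)/k, so it is inflated by k/(k−1) (exact under homoscedasticity —
the variant implemented here; the inflation is switchable). The
intergroup deviation d̂_ig is the gene×group interaction of the group
means (doubly centered, so Σ_i d̂_ig = 0 per group by construction, an
asserted invariant). d̂ is shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g), where γ̂² is
the variance of the d̂'s in excess of their mean sampling variance,
floored at 0 (the floor is logged when it binds). Stability
ρ_i = mean_g(|d̃_ig| + √(σ̂²_ig/n_g)); with one group ρ reduces to the
residual sd. This estimator is validated by parameter recovery on
simulated data with known (σ, d) — mean Spearman ≥ 0.9 against the
designed ordering — rather than by transcription of any particular
implementation's numerics; no claim of numerical identity with the
original add-in is made. The "best pair" report prefers the
lowest-mean-ρ pair with opposite-signed deviations in every group
(their biases partially cancel in a geometric mean), falling back to the
lowest-ρ pair.

**CV method.** Normalized relative quantities
NRQ_gs = RQ_gs / geomean over the reference set at sample s, with the
reference set defaulting to the *whole* candidate panel, evaluated gene
included — the common reading of the normalized-quantity formula; a
leave-one-out mode is provided (for a gene with large noise the inclusive
CV is slightly conservative because the gene drags its own normalizer).
CV_g = sd(n−1)/mean of NRQ_g, ranked ascending. Replicate-level standard
errors of NRQ (delta method through A^ΔCq: se ≈ NRQ·lnA·se_Cq) are
reported for inspection but never used for ranking. The Hellemans-style
quality screen flags genes outside M ≤ 1 and CV ≤ 0.5 for heterogeneous
panels, or M ≤ 0.5 and CV ≤ 0.25 for homogeneous ones.

## Normalization factors, consensus, validation

NF = per-sample geometric mean of a gene set's RQs. Consensus intersects
the per-method top-n sets (default n = 2, matching the two-gene NF focus)
and reports the full Venn partition; an empty intersection is a logged
warning, not an error. Target validation divides the target's RQ by each
NF variant; the fold change is the ratio of condition means, and the
*average gene-specific variation* is defined here as the within-condition
CV of normalized expression, averaged over conditions, in percent — one
reasonable operationalization of a quantity for which no standard formula
exists; it is used only for the qualitative contrast stable ≪ unstable.
The default stable-set size is geNorm's suggested optimal n.

## Synthetic data

The generator works on the log2-quantity scale and is exactly inverted by
the ΔCq transform, which keeps every recovery test interpretable:

- true log2 quantity x_gj = b_j + d_g,group(j) + ε_gj, with sample
  loading effect b_j ~ N(0, sample_effect_sd²) and biological noise
  ε ~ N(0, σ_g²), drawn independently per biological replicate;
- Cq_gjr = base_cq_g − x_gj·(ln2/lnA_g) + τ_gjr, τ ~ N(0, tech_noise_sd²)
  on the cycle scale.

Noise is Gaussian on the log2 scale for biology (multiplicative on
quantities) and on the Cq scale for technical replication — where those
noise sources actually live. Amplification curves are four-parameter
logistics with steepness s = 1/lnA (so the early phase grows by exactly A
per cycle) plus Gaussian noise proportional to the plateau.

Preset parameters (chosen once, as a realistic rendering of a
multi-tissue survey):

- **study-like**: 10 candidates + 1 target, 6 tissue groups × 3 samples,
  2 biological × 3 technical replicates; A ∈ [1.84, 1.99]; base Cq
  15.5–30.5 (observed range then spans ≈14.5–31.5, matching a realistic
  14.8–31 span); biological σ ascending 0.12→1.10 log2 units with
  RG01/RG02 the designed stable pair; the four noisiest candidates also
  carry ±0.6–0.8 log2 tissue effects; tech noise 0.15 cycles; sample
  effect 0.25 log2. The extreme base-Cq values sit on low-noise genes so
  the observed range stays near the designed span.
- **two-season**: 2 groups × 8 samples; stable pair σ = 0.1 with no
  seasonal effect; six mid-noise fillers; an unstable, seasonally
  co-regulated pair (σ = 0.8 with same-direction 1.0 and 0.6 log2
  shifts — same-direction is essential: equal-and-opposite shifts would
  cancel in the geometric mean of NF2(U) and the design would test
  nothing); target σ = 0.2 with zero true effect.
- **NormFinder recovery**: 10 genes × 2 groups × 20 samples; σ ascending
  0.10→1.10; genes 3–10 carry paired opposite-signed group effects
  (δ = 0.2…1.1) that sum to zero per group, so the designed deviations
  survive the estimator's double centering and the designed score
  |d| + σ/√n is well-defined.

**What the simulations do not emulate:** PCR inhibition, primer-dimer
artifacts, melt-curve behaviour, heteroscedastic technical noise near the
detection limit, plate-position effects, or correlated regulation among
candidates beyond the explicit group effects. Passing recovery tests
therefore shows the estimators are correct and well-calibrated under the
stated model, not that any particular real panel will separate this
cleanly.

## Numerical choices and degenerate inputs

- Log base 2 throughout the stability statistics; all sds use ddof = 1.
- geNorm M ties: lexicographic exclusion, deterministic and logged.
- Window-scan R² ties in the curve estimator: compared at 1e−12
  resolution, widest-then-earliest preference.
- Shrinkage variance γ̂² < 0 is clamped to 0 (full shrinkage) and logged.
- A flat fluorescence curve fails the signal check (late mean < 3× early
  mean) and reports "no exponential phase"; a logistic fit that does not
  converge reports its residual norm.
- Analysis problem sizes (oracle matrices 5×8×100, recovery designs
  30–100 replicates, 100 curves) were chosen as the smallest sizes at
  which the Monte-Carlo rates are stable; everything runs in well under a
  minute on one CPU.

## Known limitations

- The NormFinder variant is homoscedastic; strongly gene-dependent
  within-group variances are handled only through the per-gene σ̂_ig, not
  by the full heteroscedastic weighting of the original formulation.
- Inter-plate calibration assumes the calibrator is measured for every
  gene on every plate; partial calibrator coverage is an error, not a
  fallback.
- The curve-efficiency estimator is not a reimplementation of any
  published tool's numerics; agreement is at the estimand level
  (per-reaction A), demonstrated by simulation.
- The 3′:5′ ratio formula and the gene-specific-variation percentage are
  documented conventions; both quantities are used qualitatively.
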