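# Methods

This note documents the models, parameter choices, numerical details, and
limitations of the `protmr` pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data model

**Genotypes.** Haplotypes are drawn from a Gaussian copula: a latent
AR(1) normal sequence per LD block, thresholded at $\Phi^{-1}(\mathrm{MAF})$
so the effect allele is the minor allele; dosages are sums of two
independent haplotypes, hence in Hardy–Weinberg proportions. Thresholding
attenuates correlation, so the latent AR(1) coefficient is calibrated per
adjacent pair (bisection on the bivariate-normal orthant probability,
evaluated by 48-node Gauss–Legendre quadrature) such that the **dosage**
correlation of adjacent variants equals the requested ρ; adjacent r²
therefore tracks ρ². Binary variables with unequal margins cannot be
arbitrarily correlated (the Fréchet bound); unreachable targets are
clipped to the attainable maximum, so blocks with wide MAF ranges realize
less LD than ρ² suggests. Blocks are mutually independent and placed with
3 Mb gaps, guaranteeing that different blocks never share a ±1 Mb cis
window. MAFs are restricted to [0.02, 0.5], matching the MAF ≥ 2% variant
filter the association stage assumes.

**Ground truth.** A `TruthManifest` assigns each protein one cis variant
(effect `b_cis`, default 0.5 on the log-abundance scale), optional trans
effects, optional pleiotropic hub variants feeding ≥ 5 proteins, the
causal effect θ of each protein on each outcome (0 when non-causal), and
optional direct variant→outcome effects that model horizontal pleiotropy
/ LD confounding. The encoding gene's TSS is placed 10 kb from the cis
variant, comfortably inside the 1 Mb cis window.

**Proteins and outcomes.** Log-scale abundance is
`Σ b·dosage + Γ·covariates + ε`, `ε ~ N(0, noise_sd²)` with `noise_sd = 1`
by default, i.e. a strong single cis instrument explaining roughly
`b² · 2·MAF(1−MAF) / (b²·2·MAF(1−MAF) + 1)` ≈ 10% of variance at
`b = 0.5`, MAF 0.3. Outcomes are quantitative:
`y = Σ θ·protein + Σ direct·dosage + ε`. Summary statistics are marginal
simple regressions per variant (t reference, n − 2 df). Binary outcomes
via a liability threshold are not generated; the quantitative case
exercises every downstream formula.

**Raw plates.** The clean log matrix is mapped to a raw
relative-fluorescence scale `10^(3 + 0.15·z)` and joined by 8 calibrator
wells (≈ N(1000, 20) per analyte) and 4 buffer wells (≈ N(100, 10)) per
plate, 3 plates by default — the minimal metadata that exercises all four
QC filters. Injected defects (sub-LOD samples, inflated calibrator CV, a
plate-level calibrator scale shift, gross outliers, whole-sample
outliers) are recorded in a ledger so QC recovery is testable. Defect
magnitudes are chosen so each defect trips exactly one filter.

## Proteomics QC

Four analyte filters on the raw scale, applied in this order (the order
fixes the primary removal reason when several would fire):

1. **LOD**: limit of detection = buffer mean + 2·SD (buffer wells pooled
   across plates); a sample below LOD is an outlier; analyte removed when
   outliers exceed 15% of samples (strict >).
2. **Scale factor**: per analyte and plate, factor = cross-plate median of
   plate calibrator medians divided by the plate's calibrator median;
   fail when max |factor − median factor| > 0.5. The source text uses the
   factor without defining its computation; this median-ratio definition
   is the package's choice and the rule removes the analyte (configurable
   reading of "failed this criterion").
3. **Calibrator CV**: SD/mean of calibrator wells, sample SD (ddof = 1)
   because calibrator counts are small; computed **per plate** with the
   analyte failing if any plate exceeds 0.15. Per-plate computation keeps
   a between-plate scale shift (filter 2) from masquerading as calibrator
   noise (filter 3).
4. **IQR**: on log10 values, outlier when outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 (linear-interpolation)
   quartiles; analyte removed when outliers exceed 15% of samples. A
   degenerate IQR of 0 collapses the bounds to the median, so any
   deviating value is an outlier — the limit of the rule.

Sample outliers: a sample outlying in > 15% of QC-passing analytes is
flagged; analytes outlying in ≥ 80% of flagged samples are removed;
outliers are re-called once, then removed. The ≥ 80% shared-analyte rule
speaks of a fraction of outlier samples, which is degenerate for a single
outlier; it therefore requires ≥ 2 flagged samples. The 15%-of-analytes
rule is only meaningful with tens of analytes or more; toy panels with a
handful of analytes will over-flag.

`run_qc` is idempotent on its own output: a cleaned log-scale matrix has
no reference wells, so only the IQR machinery re-runs, and on cleaned
data it removes nothing.

## pQTL mapping and thresholds

Associations are OLS of protein on dosage with covariates, computed by
Frisch–Waugh–Lovell residualization (QR-based), two-sided t p-values on
n − k − 2 df where k counts all covariate columns. The study-wide
threshold is 5×10⁻⁸ divided by the smallest number of principal
components explaining ≥ 95% of proteomic variance; PCA runs on
column-standardized analytes (aptamer dynamic ranges differ by orders of
magnitude). Filtering uses the unrounded quotient; one-significant-figure
rounding is applied only in reports, since rounding direction would
otherwise change inclusion near the boundary. The cis window is ±1 Mb
from the TSS, closed at the boundary, configurable.

## Meta-analysis

STDERR scheme: inverse-variance weights, Cochran's Q on effect estimates.
SAMPLESIZE scheme: z-combination with weights √n. No printed formula
exists for heterogeneity under the sample-size scheme; this package fits
the fixed-effect model z_i = d·√n_i + e_i (unit-variance errors) by
weighted least squares and takes Q = Σ(z_i − ẑ_i)², which is exactly
χ²(m−1) under homogeneity — verified by the uniformity of its p-values in
simulation. Flags follow the reference naming (`flag_heterogeneity`,
`flag_heterogeneity2`, `flag_hetero.all`), each set at HetPVal < 0.05.
Variants present in a single study pass through unflagged with
n_studies = 1.

## Instrument selection

Filters apply in the canonical order significance → pleiotropy → clump →
F ≥ 10, with per-protein provenance counts after each step (the order
matters; no order-invariance is assumed). Pleiotropic sentinels are
variants significantly associated with ≥ 5 proteins, counted within
tissue by default; their LD neighbors at r² ≥ 0.1 within ±1 Mb are
removed too (the source names no numbers for the neighbor rule; these
conservative defaults are configurable and logged in provenance). LD is
the squared Pearson correlation of dosages in the provided panel — no
external reference panel. Clumping is greedy by ascending (p, variant id)
with acceptance iff r² < 0.001 against all previously accepted variants.

## MR engine

Harmonization follows the four standard steps; the palindromic ambiguity
band is EAF ∈ [0.42, 0.58] (common practice; configurable). The Wald SE
is first-order delta, ignoring exposure uncertainty — with F ≥ 10
enforced the neglected term is second order. IVW with one instrument
equals the Wald ratio exactly, and with several equals the zero-intercept
weighted regression. FDR scope is per tissue × workflow, one BH family
per analysis table. Steiger computes r² per side as Σ t²/(t² + n − 2)
over instruments and compares Fisher-z transformed correlations;
"correct" requires strictly r²_exp > r²_out. MR-Egger and MR-PRESSO are
deliberately absent: in this design most proteins carry a single valid
instrument after clumping, where those estimators are undefined.

## Colocalization

Wakefield log-ABF = ½·log(1 − r) + r·z²/2 with r = W/(V + W); prior
effect SD 0.15 for quantitative traits, 0.2 for binary (log-odds) —
the reference implementation's defaults. Priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵. The five hypothesis masses are assembled entirely in log
space (logsumexp; the H3 term S1·S2 − S12 via log1p of a negative
exponential, returning −∞ for a single shared variant where H3 is
impossible). Windows are ±500 kb around each MR instrument; with several
instruments the final evidence is the arithmetic mean PP.H4, and the
strong-colocalization threshold PP.H4 > 0.80 is strict. Only the
single-causal-variant ABF analysis is implemented; multi-causal-variant
(credible-set) colocalization is out of scope.

## Cross-tissue comparison

Concordance is defined over (protein, phenotype) pairs significant and
colocalized in ≥ 2 tissues: concordant iff all tissue estimates share a
sign; the summary percent is rounded to integer. Proportion tests are
chi-square homogeneity tests over the full phenotype-category vector,
pooling cells with expected count < 1 into "other"; 2×2 tables use Yates
continuity correction. An exact (Fisher) p differs from any chi-square p
by far more than a cosmetic amount at small totals, so the test suite
verifies the chi-square arithmetic against a direct-formula oracle and
rank agreement with Fisher rather than absolute agreement. Storey's pi0
uses the λ-grid 0.05…0.95, with the smoother approximated by a
least-squares cubic evaluated at λ = 0.95 and clipped to [0, 1] (the
reference smoother is a df = 3 smoothing spline, which a cubic fit tracks
closely); a fixed-λ = 0.5 fallback is exposed for small m where the
smoother is unstable. pi1 = 1 − pi0.

## Annotation

Replication against a prior results table: replicated iff prior p < 0.05
with the same sign; rate = replicated/(replicated + not replicated),
undefined (NA) when the denominator is 0. Druggable-genome overlap
deduplicates proteins by encoding gene, assigns tiers 1–3 from the tier
table (else tier 4, unclassified), and reports the percent in tiers 1–3
with half-up rounding to one decimal (69/80 = 86.25 → 86.3, the reporting
convention of the field's tables). Drug calls keep phase-4, warning-free
drugs; predicted effect is inhibitor for a positive MR estimate,
activator for a negative one; a zero estimate yields no call.

## Validation studies and problem sizes

The canonical studies in `protmr.studies` fix the following designs,
chosen as the smallest sizes at which the asymptotic behavior the
pipeline relies on is visible:

- **Parameter recovery**: 200 replicates, n = 2000, b_cis = 0.5, θ = 0.3;
  mean Wald estimate and 95% CI coverage.
- **Null calibration**: 100 proteins × 5 outcomes (500 tests), θ = 0
  everywhere; fraction of FDR < 0.05 calls and KS uniformity of p-values.
- **Coloc discrimination**: 100 regions × 50 variants, n = 2000; shared-
  vs distinct-causal-variant scenarios.
- **Steiger**: 200 reverse-causal replicates (phenotype genetically
  driven, protein downstream).
- **QC recovery**: 240 samples × 20 analytes, one fixture with all four
  defect kinds and one defect-free.
- **Oracle agreement**: OLS vs normal equations, IVW vs zero-intercept
  WLS, BH vs step-up enumeration, Q vs the direct χ² formula, coloc vs a
  log-sum-exp enumeration.

## What the synthetic generator does and does not emulate

It reproduces the statistical structure the analysis assumes — blockwise
LD with controllable r², Hardy–Weinberg dosages, one strong cis effect
per protein, hub pleiotropy, protein-mediated outcome effects, and plate
structure with calibrator/buffer wells. It does **not** emulate real
haplotype reference panels, imputation uncertainty, fine-scale LD decay,
assay-specific aptamer cross-reactivity, case-control ascertainment, or
covariate-confounded population structure. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
assumed model, not robustness to violations a real cohort may present.

## Known limitations

- Single-causal-variant colocalization only; regions with allelic
  heterogeneity will under-call H4.
- Wald/IVW only; no pleiotropy-robust estimators (by design, see above).
- The Steiger r² formula is the quantitative-trait t-based form; for
  binary outcomes the same formula applied to logistic z-statistics is an
  approximation.
- LD is computed from the analysis panel itself; there is no external
  reference-panel lookup or proxy-variant substitution.
- The harmonizer matches variants by chromosome + position and assumes
  biallelic records.
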