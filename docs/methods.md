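# Methods

This package reimplements, over a synthetic cohort, a paediatric analysis of
urinary di-(2-ethylhexyl) phthalate (DEHP) metabolites in relation to
adiposity and insulin sensitivity: metabolite quantification and censoring,
oral-glucose-tolerance-test (OGTT) indices, nonparametric group statistics,
and an Auto-Contractive-Map (Auto-CM) semantic connectivity map. The original
subject-level data are not deposited, so a seeded generator
(`dehpkids.synth`) stands in for them; everything downstream is agnostic to
where the cohort table came from.

## Synthetic cohort

The generator emulates a cohort of 41 obese and 31 normal-weight children,
comparable in age and sex, roughly two thirds pubertal in each group.

**Marginals.** Urinary metabolite concentrations (MEHP, 5-OH-MEHP,
5-oxo-MEHP, 5-Cx-MEHP, 6-OH-MEHP) and fasting insulin are log-normal:
concentrations are positive and right-skewed, and the study population's
asymmetric median/IQR summaries are consistent with that shape. Group and
puberty effects enter as multiplicative shifts of the per-(group × puberty)
cell median; the default cell medians are the published μg/g medians
(e.g. MEHP 0.27 μg/g in prepubertal obese vs 0.04 μg/g in pubertal controls),
with a common log-SD of 1.0 (the reported IQR spans imply log-SDs of roughly
0.8–1.3). Ages, SDS values and fasting glucose are normal with per-group
means; where the source tables report mean ± SEM the generator's SD is
back-computed as SEM·√n, and where they report median (IQR) the SD is
IQR/1.349. Birth-weight SDS cell means (−0.3 control, +0.2 obese) are chosen
to reflect the reported ~0.36 kg birth-weight contrast; the source reports kg
only. Urinary creatinine is log-uniform over 0.5–2.0 g/L (median 1 g/L), so
raw μg/L cell medians and normalized μg/g cell medians coincide in the
median-of-ratios sense.

**Dependence.** Chosen rank correlations (default: MEHP vs age ρ_s = −0.35,
pairwise 0.40 among the five metabolites, 6-OH-MEHP vs fasting insulin
+0.365, signs following the study's correlation tables) are injected with a
Gaussian copula on the latent normal scale, using the bivariate-normal
conversion ρ_pearson = 2·sin(π·ρ_spearman/6). Monotone marginal transforms
preserve Spearman correlation, so the injected values are recovered exactly
in the large-n limit *within a (group × puberty) cell*. Pooled over cells,
the heterogeneous cell medians act as extra between-stratum variance and
attenuate the pooled rank correlation (about a factor 0.83 at the default
cell spread); the copula-fidelity test therefore uses a configuration with
homogeneous cell medians, which isolates the property the copula actually
guarantees. The target matrix is validated for symmetry, unit diagonal and
positive semi-definiteness after the rank-to-Pearson conversion, and a
violation is reported with the offending eigenvalue.

**OGTT curves.** The protocol samples glucose (mg/dl) and insulin (mIU/L) at
0, 30, 60, 90 and 120 min. Only summary AUCs are reported for the study, so
no kinetic model is fitted: post-load values are the fasting value times a
fixed per-time shape template (glucose ×1.55 peaking at 30 min and relaxing
to ×1.10; insulin ×6 at 30 min relaxing to ×3) times log-normal noise
(log-SD 0.08), clamped at a positive floor. Fasting insulin medians are
15.9 mIU/L (obese) and 8.5 (controls); fasting glucose 82.8 ± 6.4 and
80.2 ± 6.7 mg/dl.

**Censoring.** Draws below the metabolite's limit of detection (LOD) are
emitted as non-detects carrying the LOD value plus a flag; no imputation
happens at generation time. The generator reproduces the configured cell
medians and censoring tail probabilities, *not* the study's detectability
percentages: with the published medians sitting one to two orders of
magnitude above the LODs, a pure log-normal tail cannot produce 20–60%
non-detect rates, which in real assays also reflect matrix effects and assay
failures this generator does not model. Passing tests therefore validate the
pipeline mechanics and the configured population structure, not assay-level
realism.

**Determinism.** One seed drives everything through splittable
`numpy.random.SeedSequence` streams (subject attributes, copula, OGTT noise,
metabolite noise), so a fixed config yields byte-identical cohorts.

## Quantification

Calibration lines are ordinary least squares of peak area on standard
concentration over a 2.5–2500 ng/mL range; r² is the squared Pearson
correlation and curves pass QC when r² > 0.998. Back-calculation inverts the
line, flooring negative results at zero with a warning. Detection bands are
half-open — below LOD strictly; [LOD, LOQ) reported as detected but not
quantifiable; ≥ LOQ quantified — the limits themselves state no boundary
rule, so the inclusive-at-LOD convention is this package's documented choice.
The shipped LOQ table corrects an apparent decimal typo in the circulating
5-Cx-MEHP value (0.0051 → 0.051 μg/L): a quantification limit cannot lie
below its detection limit (0.019 μg/L). Creatinine normalization divides
μg/L by g/L, giving μg analyte per g creatinine. Non-detects propagate as
missing values (complete-case per statistic); LOD/√2 substitution is
available behind `impute_nondetects=True`. Detectability percentages use the
full group sizes as denominators and are reported to one decimal.

## Insulin-sensitivity indices

All formulas operate on the five-point OGTT:

* HOMA-IR = G₀(mmol/L) · I₀(mIU/L) / 22.5, glucose converted at
  18.016 mg/dl per mmol/L.
* FGIR = G₀(mg/dl) / I₀(μU/mL). Insulin units are harmonized as
  mIU/L ≡ μU/mL throughout — the only physiologically coherent reading of
  fasting values like 8.5 and 15.9.
* Insulinogenic index = ΔI(0–30)/ΔG(0–30). A zero glucose excursion yields a
  missing value with a warning rather than an error: real cohorts contain
  such subjects.
* WBISI (Matsuda composite) = 10000/√(G₀·I₀·Ḡ·Ī) with unweighted means over
  all five sampling times; a trapezoid-weighted-mean variant is exposed via
  `time_weighted=True`.
* AUCG and AUCI by trapezoidal integration, reported in raw value·min
  (mg·min/dl, mIU·min/L). The study's printed AUC medians (234.8, 225.5) are
  far below raw trapezoid magnitudes over 120 min and the scaling used there
  is unstated; this package reports the raw integral and documents the
  discrepancy rather than guessing a rescaling.

Insulin-resistance classification compares HOMA-IR with age/puberty cutoffs
supplied as configuration (`classify_ir`); no cutoff table is hard-coded
because the reference criteria are not printed in the source.
`tune_ir_thresholds` derives a single cutoff reproducing a stated prevalence,
which is how the 9-of-39 (23%) insulin-resistance worked example is realized.

## Statistics

A Kolmogorov–Smirnov gate (fitted-normal null, α = 0.05 on either sample)
routes two-group comparisons to Welch's t-test or Mann–Whitney; the source
names both tests "as appropriate" without a rule, so the gate is explicit
configuration here. The exact Mann–Whitney p-value is computed by full
enumeration of label assignments whenever n_x + n_y ≤ 12 and the pooled
sample is tie-free (forced exact mode also handles ties, since the
permutation distribution conditions on the observed values); larger samples
use the tie-corrected normal approximation without continuity correction.
Four-cell (group × puberty) contrasts use tie-corrected Kruskal–Wallis H with
pairwise Mann–Whitney post hocs multiplied by the number of pairs
(Bonferroni); the source names no post-hoc statistic, so pairwise
Mann–Whitney × Bonferroni is the documented realization. Correlation
matrices are Spearman over pairwise-complete observations (cells with < 4
complete pairs or a constant column are missing) because metabolite
non-detects create per-variable missingness; the MEHP-determinants model is
OLS with intercept and listwise deletion, rejecting rank-deficient designs
and naming the collinear columns.

## Auto-Contractive Map

Variables are min–max scaled to [0, 1] (constant columns map to 0.5 with a
warning) and complement-encoded: each variable X contributes "X high" = x and
"X low" = 1 − x, so the 11 study variables (five normalized metabolites,
FGIR, HOMA-IR, insulinogenic index, height SDS, BMI SDS, birth-weight SDS)
become 22 input nodes.

Training uses the three-layer contractive recurrences, per record:
h_i = x_i(1 − v_i/C); n_i = (1/N)ΣW_ij h_j; o_i = h_i(1 − n_i/C);
Δv_i = α(x_i − h_i)(1 − v_i/C); ΔW_ij = α(h_i − o_i)(1 − W_ij/C)h_j, with
both deltas computed from the pre-update state and applied together, and all
weights clipped to [0, C]. The 1/N normalization bounds the net input by C so
both contraction factors stay in [0, 1]. Defaults: C = N (the encoded
variable count), α = 0.1, tolerance 1e-6 on the mean absolute update, at most
5000 epochs. The published description of this architecture leaves the
update mathematics to its references, so these recurrences are this
package's definitive, testable contract; whether the original applies
updates per record or per epoch is not decidable from the available text —
the online form is the default and a batch option exists.

Initialization is a deterministic small positive constant, v = W = C·10⁻³,
with no randomness. Exactly-zero weights are a fixed point of the update
rules for *every* input (Δv carries a factor x·v/C and ΔW a factor net = 0),
so a zero start would never train; the positive constant preserves full
determinism while letting the mono-connections saturate. Training dynamics:
v grows logistically toward C, the hidden signal h decays to zero, and W
freezes having integrated the co-activation structure during the transient —
convergence is typically reached in well under 100 epochs for cohort-sized
tables.

Trained weights are symmetrized (W̄ = (W + Wᵀ)/2) and normalized to link
strengths s = W̄/C ∈ [0, 1]; distances d = 1 − s (diagonal forced to
d = 0). With C = N the realized strengths occupy a narrow band near the
bottom of the [0, 1] scale — relative ordering, not absolute magnitude,
carries the information, and the minimum spanning tree depends only on the
ordering. The MST is computed by Kruskal's algorithm with ties broken by
lexicographic node-name pair (stable across runs); rows with any missing
selected variable are dropped before training (a mean-imputation switch
exists, off by default). Group labels are not entered as map nodes by
default: the stated input list contains the 11 continuous variables. Exports:
GraphML and DOT with a `form` node attribute (high/low) and a 6-decimal
`strength` edge attribute, plus a TSV edge list.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script run the study-sized cohort
(72 subjects); parameter-recovery checks use 2000 subjects per group (copula)
and ~2100 per (group × puberty) cell (medians), with 10 000 draws for the
censoring-tail check — sizes at which the ±0.05 rank-correlation and ±10%
median tolerances have comfortable sampling margins. Degenerate inputs are
handled explicitly throughout: constant samples are rejected by the KS test,
constant columns map to 0.5 in scaling, zero glucose excursions yield missing
insulinogenic indices, identical calibration concentrations are rejected, and
empty groups are omitted from detectability with a warning.

## Limitations

* The generator matches medians, contrasts and injected rank correlations,
  not full joint distributions; detectability percentages and any statistic
  driven by assay-level artifacts are out of its reach.
* No dietary-intake covariate is simulated; the study itself lacks
  food/calorie-intake data.
* The Auto-CM recurrences are a faithful contractive-architecture
  implementation but cannot be verified against the original software;
  conclusions should rest on the documented contract, not on numerical
  identity with other Auto-CM implementations.
* Pooled-cohort maps are the default; whether the original analysis trained
  pooled or per-group maps is not stated.
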