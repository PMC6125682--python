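# Methods

This note documents the models, numerical choices and study conditions
implemented in `coreis`, and states explicitly what the synthetic-data
layer does and does not emulate.

## Insulin-sensitivity phenotype

The phenotype used throughout is `is_log = log10(S%)` with
`S% = 100 / HOMA-IR` and `HOMA-IR = (insulin/6.945) · glucose / 22.5`
(insulin in pmol/l, glucose in mmol/l, 6.945 pmol/l per µU/ml). This is
the classic closed-form homeostasis-model index; the genuine HOMA2
computer model is an iterative solver with no published closed form and
incorporates non-linearities this stand-in does not. The two agree in rank
order and approximately in scale over the normal fasting range, which is
what the downstream correlation/ANOVA machinery consumes, but the
stand-in's numeric values are *not* HOMA2 values. Pipelines with access to
true HOMA2 output can inject a precomputed S% column
(`augment_phenotypes(..., s_percent_col=...)`, `phenotype
--s-percent-column`).

Operating-range screening (defaults: insulin 20–400 pmol/l, glucose
3.0–25.0 mmol/l, mirroring the published calculator's accepted inputs)
excludes records rather than winsorizing them; exclusions are logged with
a reason. Both bounds are configurable.

## Probe filter cascade and chip definition

Three pure, order-independent filters intersect:

| filter | rule | default | notes |
| --- | --- | --- | --- |
| uniqueness | `map_count == 1` | — | 0 (unalignable) and ≥ 2 both fail |
| signal | linear mean ≥ `min_mean` and CV ≤ `max_cv` | 10 units, 25% | computed from the study's own samples |
| GC | `gc_low ≤ gc ≤ gc_high` | 0.20 / 0.80 | boundaries inclusive-retain (removal is for strictly extreme GC) |

CV is computed on the linear (un-logged) scale with the sample standard
deviation. The signal statistics are per study — the same probe can pass
in one tissue and fail in another — and the chip definition records the
defining sample set, the thresholds and the retained-probe count in its
provenance sidecar. Surviving probes are grouped by target transcript;
sets with fewer than `min_probes = 3` members are dropped. A probe
annotated to two targets is rejected at ingest rather than silently
resolved. When several probe-sets map to one gene, the set with the
highest mean expression wins; exact ties break to the lexicographically
smallest probe-set id.

## Quantification

Quantile normalization forces every array to the common reference
distribution (row-wise mean of sorted columns; ties receive the mean of
the reference values they span). Summarization fits each probe-set's
log2 probes × samples block with Tukey median polish (tolerance 1e-8 on
the change in total absolute residual, at most 20 iterations); the
probe-set expression for sample j is `overall + sample_j`. Median polish
is invariant to probe reordering and robust to minority outlier cells,
which is why background-dominated probes must be removed at the design
level — no background-correction model is applied, deliberately.

NUSE: per probe-set, the unscaled standard error for sample j is the RMS
of column-j residuals divided by √(probes); each set's SEs are scaled by
their cross-sample median and a sample's NUSE is the median ratio over
sets. The outlier cutoff of 1.05 follows common probe-level-model
practice; visual inspection is the tradition in this field, so the cutoff
is configurable rather than load-bearing.

## Association and meta-analysis

Per gene, `expression ~ IS * covariate` is assessed by sequential (Type-I)
ANOVA: terms enter in order (first main effect, second main effect,
interaction), each contributing one degree of freedom, with every term's
incremental sum of squares tested against the full-model residual mean
square. The implementation uses a thin QR of the ordered design matrix so
that thousands of genes are fit in one matrix product; it is verified in
the tests against both a normal-equations brute force (1e-10) and an
independent Type-I ANOVA implementation. Degenerate fits (zero residual
variance, zero expression variance) are flagged rather than silently
reported.

Both term orders are computed. With IS first, the IS term captures all
variance it can explain; with the covariate first, variance shared between
IS and the covariate is credited to the covariate. Because adiposity and
insulin sensitivity are genuinely coupled, the ordering changes the gene
list, and the package treats the comparison itself as an output (see the
acceptance script's order-effect quantities) rather than declaring either
model correct.

Cross-cohort combination is the unweighted Stouffer method on the IS-term
p-values (direction-blind F-test p-values; directionality is enforced
afterwards by the r-sign filter). A sample-size-weighted variant was
considered and left out of the default because no weighting scheme is
canonical here. Exact p of 0 or 1 are clamped to [1e-300, 1−1e-16].
Benjamini–Hochberg q-values are computed per covariate model with the
direct step-up formula `q_(i) = min_{j≥i} p_(j)·m/j` (implemented
in-package so the arithmetic matches the definition bit for bit; the
tests cross-check against the standard library implementation).

CORE-IS selection: q below the FDR threshold (default 10%) in the age
model **and** the BMI model (`both_models_required=True`; the
either-model reading is one flag away), plus a strictly consistent sign
of the univariate correlation across the designated consistency cohorts
(default: the four largest; a zero or undefined r is inconsistent). Genes
absent from any cohort's feature space are excluded from the meta rather
than imputed.

## Intervention layer

Per paired study: per-gene paired t-tests on per-subject log2 differences
(two-sided, df = n−1; zero-variance differences flagged, p = 1), Stouffer
+ BH meta-analysis across studies, and per-gene Spearman correlation
(average-rank ties) between per-subject log2 fold change and per-subject
ΔIS. The Delta-IS selection is sign-only: a gene is selected iff, in
every study, sign(ρ) is non-zero and concordant with the gene's baseline
IS direction. No |ρ| magnitude threshold is applied by default — the
weakest defensible reading of "consistently correlated"; a thresholded
variant can be layered on by callers.

The consistency statistic is the upper cumulative binomial tail
`P(X ≥ k)` for X ~ Binomial(n, p0) with `p0 = (1/2)^s` under the
sign-only null (each of s studies contributes an independent fair sign
for a null gene). The choice of null is documented prominently because
other nulls (e.g. requiring per-study significance before counting a
sign) give different p0 and are not comparable; the reported object
always includes k, n, s and p0 alongside the tail probability.

## Synthetic-data generator: what it emulates

The generator plants known structure so each stage's operating
characteristics are measurable:

* **Chip layer** (`ChipDesign`): 10 probes per gene; disjoint planted
  defects — 20% dead probes reporting lognormal optical background
  (mean 5 units, CV 30%), 10% multi-mapping probes (map_count ≥ 2,
  cross-hybridizing half their signal from a random off-target gene), 10%
  GC-extreme probes (GC outside [0.20, 0.80], compressed power-0.3
  response). These fractions put the filter cascade's total removal near
  40% of the chip, the scale typical of re-annotating a dense commercial
  array. Good probes respond linearly with a fixed per-probe affinity
  (lognormal, log2 sd 0.4) and multiplicative noise (log2 sd 0.10). The
  chip *layout* (classes, GC, affinities) is drawn from a separate layout
  seed so technical replicate hybridizations can share it.
* **Cohorts** (`CohortParams`): 6 cohorts of 80–190 subjects, 2000 genes.
  BMI and latent log-IS are bivariate Gaussian with correlation −0.4 (the
  realistic sign and magnitude of the IS–adiposity relationship); fasting
  glucose is drawn near 5.2 mmol/l, and insulin is *derived* by inverting
  the stand-in index so that phenotypes are internally consistent, then
  clipped to the assay range — which naturally produces a small fraction
  of out-of-operating-range records for the screening stage to exclude.
  5% of genes are planted IS genes at |r| = 0.3 (a typical strong
  single-gene effect; a (low, high) range of magnitudes is supported and
  used in the order-effect experiment, where boundary-strength genes are
  the object of study), 30% of them negative. Planted genes additionally
  load on the component of BMI orthogonal to log-IS (weight 0.2, sign
  opposite the IS direction): real IS genes covary with adiposity through
  their own paths, and without this term covariate-first ordering costs
  only the ~8% of signal shared through the IS–BMI correlation, far less
  than observed in practice. Because the extra component is orthogonal to
  log-IS, the planted expression–IS correlation remains exactly
  `effect_r`. Gene log2 sd is 0.30, chosen jointly with the probe noise
  so that well-behaved probes sit inside the 25% CV filter with honest
  margin.
* **Interventions** (`InterventionParams`): 4 studies of 40 subjects;
  ΔIS ~ N(0.10, 0.20) in log10 S% units (modest mean improvement, large
  individual spread). Half of the planted IS genes are delta genes whose
  log2 fold change tracks ΔIS at Spearman ρ = 0.5 (the planted Pearson
  correlation is 2·sin(πρ/6), the exact bivariate-Gaussian conversion);
  the uncentered ΔIS enters the fold change so a cohort that improves on
  average also shifts its delta genes on average.

**Not emulated:** batch effects, array spatial artifacts, vendor binary
formats, assay-specific insulin calibration differences (assay type is
metadata only), population stratification, and any direct genotype layer.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model — not robustness to the
systematic artifacts of real cohort data.

## Problem sizes and determinism

All randomness flows from explicit integer seeds; a pipeline run is a pure
function of (config, seed), and provenance JSON records every threshold,
seed and count. The test suite and the acceptance script use the default
study conditions above; the Monte-Carlo experiments use 10–20 replicates
(null calibration, covariate-order comparison, null delta selection),
sizes at which each experiment's standard error is small relative to the
effects being checked while a full run of suite plus script completes in
well under a minute.

## Known limitations

* The stand-in IS index is monotone-equivalent but not numerically equal
  to HOMA2 S%; absolute S% values should not be compared across the two.
* The sign-only Delta-IS null treats genes as independent; co-expressed
  genes violate this, so the binomial tail is anti-conservative for
  strongly correlated gene sets.
* Sequential ANOVA reports term-order-dependent p-values by design;
  neither ordering is "adjusted" in the causal sense, and the package
  deliberately surfaces both rather than resolving the ambiguity.
* The NUSE cutoff and the signal-filter thresholds are tissue- and
  study-dependent; the defaults are sensible for a well-behaved
  large-cohort muscle-like setting, not universal constants.
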