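# coreis

An insulin-sensitivity (IS) transcriptome pipeline for clinical
transcriptomics: tissue-adaptive probe filtering and probe-set
quantification for high-density expression arrays, multi-cohort
covariate-adjusted association with meta-analysis and directional
filtering, and intervention-response consistency analysis — exercised end
to end on synthetic data with planted truth.

## The scientific problem

Loss of peripheral insulin sensitivity is the central physiological defect
behind type 2 diabetes, and skeletal muscle is the largest insulin target
organ. Finding the genes whose muscle expression robustly tracks fasting
IS requires (i) quantification that is not polluted by dead, ambiguous or
non-linear array probes, (ii) association models that handle confounding
between IS and age/adiposity, (iii) replication across independent
cohorts, and (iv) evidence that candidate genes respond *in proportion* to
clinically induced changes in IS. `coreis` implements that entire chain as
a tested, reusable library with a deterministic synthetic-data layer, so
every stage can be validated against known planted structure before it
ever touches real cohort data.

## The model

**Phenotype.** IS is quantified as `is_log = log10(S%)`, where `S%` is the
insulin-sensitivity percentile from a homeostasis-model assessment of
fasting insulin I (pmol/l) and glucose G (mmol/l). The package uses the
closed-form stand-in

```
HOMA-IR = (I / 6.945) · G / 22.5,    S% = 100 / HOMA-IR
```

(the genuine HOMA2 solver is an unpublished iterative model; externally
computed S% columns can be injected instead). Records outside the model's
operating range (insulin 20–400 pmol/l, glucose 3–25 mmol/l by default)
are excluded.

**Quantification.** Probes are kept only if they map to a single genomic
location, show usable signal in the study at hand (linear mean ≥ 10 units,
CV ≤ 25%), and have non-extreme GC content (20–80%). Survivors are grouped
into probe-sets of ≥ 3 probes per transcript (a study-specific chip
definition), quantile-normalized, and summarized on the log2 scale by
Tukey median polish (`y_ij ≈ μ + probe_i + sample_j`); arrays are screened
with NUSE (normalized unscaled standard error, outlier cutoff 1.05).

**Association.** Per cohort and gene, sequential (Type-I) ANOVA of
`expression ~ IS * covariate` with age and BMI as covariates; the IS-term
p-values are combined across cohorts with the unweighted Stouffer method
`Z = Σ Φ⁻¹(1 − p_i) / √k`, converted to Benjamini–Hochberg q-values, and
genes under the FDR threshold must keep one strict sign of the univariate
correlation `r` across the designated (largest) cohorts. Survivors form
the CORE-IS gene set. Both term orders are computed, because with IS–BMI
coupling the ordering materially changes which genes survive.

**Intervention response.** For paired pre/post studies, per-gene paired
t-tests (with Stouffer/BH meta-analysis) and, per subject, the Spearman
correlation ρ between log2 fold change and ΔIS. Genes whose ρ keeps the
baseline-concordant sign in *every* study are the Delta-IS set; the
probability of observing ≥ k such genes from n under a sign-only null
(`p0 = (1/2)^s` for s studies) is reported as an upper cumulative binomial
tail.

## Worked example

Run the full synthetic pipeline (6 cohorts of 80–190 subjects, 2000 genes
with 5% planted IS genes at |r| = 0.3, one cohort re-quantified from raw
probe level, 4 paired intervention studies of 40 subjects):

```
$ coreis run --seed 7 --out results/demo
{
  "n_core_is": 97,
  "core_is_sensitivity": 1.0,
  "core_is_sign_accuracy": 1.0,
  "core_is_fdp": 0.010309278350515464,
  "n_delta_tested": 97,
  "n_delta_selected": 51,
  "delta_precision": 0.9607843137254902,
  "delta_recall": 1.0,
  "delta_binomial_p": 2.3923115568923777e-35,
  "n_de_meta_q05": 28
}
```

Reading the output: every planted IS gene that survives probe-level
quantification is recovered by the meta-analysis + directional filter
(`sensitivity 1.0`) with the correct association sign (`sign_accuracy
1.0`); the 97 selected genes include a single false positive (`fdp 0.01`,
under the nominal 10% FDR). In the intervention layer, 51 of the 97 tested genes
track ΔIS with a concordant sign in all four studies (49 of them truly
planted responders — `precision 0.96`), an excess whose sign-only null
probability is ~10⁻³⁵. `results/demo/` contains the CORE-IS table, the
per-study delta correlations and a provenance log with every threshold and
seed used. Individual stages are available as `coreis
simulate|build-cdf|quantify|phenotype|associate|meta|treatment`.

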