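"""Synthetic chips, cohorts and interventions with planted truth.

Every downstream stage of the pipeline is testable without external
downloads because this module generates:

* probe-level intensity matrices for a simulated high-density array whose
  design deliberately plants probes violating each probe-level filter
  (dead/background probes, multi-mapping probes, GC-extreme probes);
* multi-cohort studies with fasting insulin/glucose/age/BMI phenotypes in
  which a known fraction of genes has log2 expression correlated with
  log-IS at a stated effect size;
* paired pre/post intervention studies in which a planted gene subset's
  per-subject expression change rank-tracks the per-subject change in IS.

All randomness flows from explicit seeds (``numpy.random.default_rng``); the
same parameters and seed always reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phenotype

# --------------------------------------------------------------------------
# parameter containers


@dataclass
class ChipDesign:
    """Design of a simulated probe-level chip.

    Default bad-probe fractions (0.20 dead, 0.10 multi-mapping, 0.10
    GC-extreme) are chosen so that roughly 40% of probes fail the filter
    cascade, the removal scale typical of re-annotating a dense commercial
    array against a current genome.
    """

    n_genes: int
    probes_per_gene: int = 10
    frac_dead_probes: float = 0.20
    frac_multimap_probes: float = 0.10
    frac_gc_extreme: float = 0.10
    background_mean: float = 5.0
    background_cv: float = 0.30
    signal_gain: float = 1.0
    probe_noise_log2_sd: float = 0.10
    affinity_log2_sd: float = 0.40

    def __post_init__(self) -> None:
        for name in ("frac_dead_probes", "frac_multimap_probes", "frac_gc_extreme"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_dead_probes + self.frac_multimap_probes + self.frac_gc_extreme > 1.0:
            raise ValueError("bad-probe fractions sum to more than 1")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")


@dataclass
class CohortParams:
    """Structure of the simulated baseline (fasting) cohorts.

    ``n_subjects`` may be a single count applied to every cohort or a
    ``(low, high)`` range sampled per cohort.  ``effect_r`` is the target
    population correlation between a planted gene's log2 expression and
    log-IS — either one magnitude shared by all planted genes or a
    ``(low, high)`` range from which per-gene magnitudes are drawn
    uniformly (real IS genes span a spread of effect sizes, with the
    strongest single-gene correlations around |r| ~ 0.35); ``sign_mix`` the
    fraction of planted genes whose association is negative.  ``bmi_is_coupling`` is the latent correlation between BMI and
    log-IS (negative: heavier subjects tend to be less insulin sensitive).
    ``bmi_coexpression`` gives planted genes an additional direct
    association with the component of BMI orthogonal to log-IS, signed
    opposite to the gene's IS direction (genes higher in insulin-sensitive
    subjects tend lower in heavier subjects).  Because that component is
    orthogonal to log-IS the planted expression/IS correlation remains
    exactly ``effect_r``, but covariate-first model ordering now absorbs
    genuinely shared variance — the confounding structure of adiposity and
    insulin sensitivity in real cohorts.
    """

    n_subjects: int | tuple[int, int] = (80, 190)
    n_cohorts: int = 6
    n_genes: int = 2000
    frac_is_genes: float = 0.05
    effect_r: float | tuple[float, float] = 0.3
    sign_mix: float = 0.30
    insulin_range: tuple[float, float] = (9.0, 330.0)
    glucose_range: tuple[float, float] = (3.9, 7.5)
    age_range: tuple[float, float] = (18.0, 75.0)
    bmi_range: tuple[float, float] = (19.0, 45.0)
    bmi_is_coupling: float = -0.4
    bmi_coexpression: float = 0.2
    is_log_mean: float = 1.9
    is_log_sd: float = 0.25
    gene_log2_sd: float = 0.30
    baseline_log2_range: tuple[float, float] = (5.5, 9.5)
    seed: int = 0

    def __post_init__(self) -> None:
        rs = self.effect_r if isinstance(self.effect_r, tuple) else (self.effect_r,)
        if any(abs(r) >= 1.0 for r in rs):
            raise ValueError("|effect_r| must be < 1")
        if isinstance(self.effect_r, tuple) and not self.effect_r[0] < self.effect_r[1]:
            raise ValueError("effect_r range is degenerate")
        if not 0.0 <= self.frac_is_genes <= 1.0:
            raise ValueError("frac_is_genes must be in [0, 1]")
        if not 0.0 <= self.sign_mix <= 1.0:
            raise ValueError("sign_mix must be in [0, 1]")
        if abs(self.bmi_is_coupling) >= 1.0:
            raise ValueError("|bmi_is_coupling| must be < 1")
        for name in ("insulin_range", "glucose_range", "age_range", "bmi_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} is degenerate: ({lo}, {hi})")


@dataclass
class InterventionParams:
    """Structure of the paired pre/post intervention studies."""

    n_subjects: int = 40
    n_studies: int = 4
    frac_delta_genes: float = 0.5
    delta_rho: float = 0.5
    delta_is_mean: float = 0.10
    delta_is_sd: float = 0.20
    fc_log2_sd: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.delta_rho) >= 1.0:
            raise ValueError("|delta_rho| must be < 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not 0.0 <= self.frac_delta_genes <= 1.0:
            raise ValueError("frac_delta_genes must be in [0, 1]")
        if self.delta_is_sd <= 0:
            raise ValueError("delta_is_sd must be positive")


@dataclass
class CohortStudy:
    """One simulated cohort: expression, phenotypes and planted truth."""

    study_id: str
    expression: pd.DataFrame  # genes x samples, log2
    phenotypes: pd.DataFrame  # indexed by subject id
    truth: pd.DataFrame


@dataclass
class InterventionStudy:
    """One paired pre/post study."""

    study_id: str
    pre: pd.DataFrame  # genes x subjects, log2
    post: pd.DataFrame
    delta_is: pd.Series  # per subject change in is_log
    pairing: pd.DataFrame  # subject_id -> pre/post sample ids
    truth: pd.DataFrame = field(repr=False, default=None)


# --------------------------------------------------------------------------
# chip simulation

GC_NORMAL = (0.25, 0.75)
GC_EXTREME_MARGIN = 0.02  # planted extremes sit in [0.02, 0.18] / [0.82, 0.98]


def simulate_chip(
    design: ChipDesign,
    true_abundance: pd.DataFrame,
    seed: int,
    layout_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe-level intensities plus the probe annotation table.

    ``true_abundance`` is a genes x samples matrix of linear-scale
    abundances.  Each gene receives ``probes_per_gene`` probes.  The chip
    *layout* — probe classes, GC fractions, map counts, per-probe binding
    affinities and cross-hybridization partners — is a physical property of
    the array and is drawn from ``layout_seed`` (default: ``seed``), while
    measurement noise is drawn from ``seed``; simulating twice with the same
    layout seed but different seeds yields technical replicate hybridizations
    of the same chip design.  Planted bad probes violate exactly one
    design-level filter each:

    * *dead* probes report pure optical background (lognormal around
      ``background_mean``) regardless of abundance;
    * *multi-mapping* probes carry ``map_count >= 2`` and cross-hybridize: the
      signal is a mixture of the target gene and one random off-target gene;
    * *GC-extreme* probes carry a GC fraction outside [0.20, 0.80] and a
      compressed (non-linear) response to abundance.

    All remaining probes respond linearly: ``gain * abundance * affinity *
    noise`` with a per-probe affinity fixed across samples.
    """
    if (true_abundance.to_numpy() <= 0).any():
        raise ValueError("true abundances must be positive")
    if true_abundance.empty:
        raise ValueError("empty abundance matrix")
    if design.n_genes != true_abundance.shape[0]:
        raise ValueError("design.n_genes does not match abundance matrix")

    rng = np.random.default_rng([0, seed if layout_seed is None else layout_seed])
    noise_rng = np.random.default_rng([1, seed])
    genes = list(true_abundance.index)
    samples = list(true_abundance.columns)
    n_probes = design.n_genes * design.probes_per_gene

    probe_ids = np.array(
        [f"P{gi:05d}_{k:02d}" for gi in range(design.n_genes) for k in range(design.probes_per_gene)]
    )
    target = np.repeat(np.arange(design.n_genes), design.probes_per_gene)

    # disjoint probe classes: 0 good, 1 dead, 2 multimap, 3 gc-extreme
    klass = np.zeros(n_probes, dtype=int)
    perm = rng.permutation(n_probes)
    n_dead = int(round(design.frac_dead_probes * n_probes))
    n_multi = int(round(design.frac_multimap_probes * n_probes))
    n_gc = int(round(design.frac_gc_extreme * n_probes))
    klass[perm[:n_dead]] = 1
    klass[perm[n_dead : n_dead + n_multi]] = 2
    klass[perm[n_dead + n_multi : n_dead + n_multi + n_gc]] = 3

    gc = rng.uniform(*GC_NORMAL, size=n_probes)
    extreme = klass == 3
    n_ext = int(extreme.sum())
    if n_ext:
        low_side = rng.random(n_ext) < 0.5
        lo = rng.uniform(GC_EXTREME_MARGIN, 0.20 - GC_EXTREME_MARGIN, size=n_ext)
        hi = rng.uniform(0.80 + GC_EXTREME_MARGIN, 1.0 - GC_EXTREME_MARGIN, size=n_ext)
        gc[extreme] = np.where(low_side, lo, hi)

    map_count = np.ones(n_probes, dtype=int)
    multi = klass == 2
    map_count[multi] = rng.integers(2, 6, size=int(multi.sum()))

    affinity = 2.0 ** rng.normal(0.0, design.affinity_log2_sd, size=n_probes)
    abund = true_abundance.to_numpy()  # genes x samples
    signal = abund[target, :].copy()  # probes x samples

    # cross-hybridization for multi-mapping probes: half the signal comes
    # from a random other gene
    if multi.any():
        other = rng.integers(0, design.n_genes, size=int(multi.sum()))
        signal[multi, :] = 0.5 * signal[multi, :] + 0.5 * abund[other, :]

    # compressed response for GC-extreme probes (saturation-like behavior)
    if extreme.any():
        med = np.median(abund)
        signal[extreme, :] = med * (signal[extreme, :] / med) ** 0.3

    noise = 2.0 ** noise_rng.normal(
        0.0, design.probe_noise_log2_sd, size=(n_probes, len(samples))
    )
    intens = design.signal_gain * signal * affinity[:, None] * noise

    dead = klass == 1
    if dead.any():
        # lognormal parameterized to have the requested linear mean and cv
        cv2 = design.background_cv ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(design.background_mean) - 0.5 * sigma**2
        intens[dead, :] = noise_rng.lognormal(
            mu, sigma, size=(int(dead.sum()), len(samples))
        )

    annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "target_id": [genes[t] for t in target],
            "map_count": map_count,
            "gc_fraction": gc,
            "probe_class": np.array(["good", "dead", "multimap", "gc_extreme"])[klass],
        }
    ).set_index("probe_id")

    intensities = pd.DataFrame(intens, index=probe_ids, columns=samples)
    intensities.index.name = "probe_id"
    return intensities, annot


# --------------------------------------------------------------------------
# cohort simulation


def _gene_truth(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i:06d}" for i in range(params.n_genes)]
    n_planted = int(round(params.frac_is_genes * params.n_genes))
    planted = np.zeros(params.n_genes, dtype=bool)
    planted[rng.choice(params.n_genes, size=n_planted, replace=False)] = True
    direction = np.zeros(params.n_genes, dtype=int)
    neg = rng.random(params.n_genes) < params.sign_mix
    direction[planted] = np.where(neg[planted], -1, 1)
    effect = np.zeros(params.n_genes)
    if isinstance(params.effect_r, tuple):
        mags = rng.uniform(*params.effect_r, size=params.n_genes)
    else:
        mags = np.full(params.n_genes, params.effect_r)
    effect[planted] = direction[planted] * mags[planted]
    return pd.DataFrame(
        {"is_planted": planted, "true_direction": direction, "true_effect": effect},
        index=pd.Index(genes, name="gene_id"),
    )


def _simulate_phenotypes(
    params: CohortParams, n: int, rng: np.random.Generator, cohort: str
) -> pd.DataFrame:
    rho = params.bmi_is_coupling
    z_bmi = rng.standard_normal(n)
    z_is = rho * z_bmi + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    lo, hi = params.bmi_range
    bmi = np.clip((lo + hi) / 2 + (hi - lo) / 6 * z_bmi, lo, hi)
    is_log_target = params.is_log_mean + params.is_log_sd * z_is
    glucose = np.clip(
        rng.normal(5.2, 0.6, size=n), params.glucose_range[0], params.glucose_range[1]
    )
    insulin = phenotype.insulin_for_is(is_log_target, glucose)
    insulin = np.clip(insulin, params.insulin_range[0], params.insulin_range[1])
    age = rng.uniform(*params.age_range, size=n)
    subjects = [f"{cohort}_S{i:04d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "fasting_insulin": insulin,
            "fasting_glucose": glucose,
            "age": age,
            "bmi": bmi,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    # the authoritative is_log comes from the phenotype module (post-clip)
    return phenotype.augment_phenotypes(pheno)


def _planted_expression(
    truth: pd.DataFrame,
    is_log: np.ndarray,
    bmi: np.ndarray,
    params: CohortParams,
    rng: np.random.Generator,
    baselines: np.ndarray,
) -> np.ndarray:
    """Log2 expression with planted IS correlation at ``effect_r``.

    Planted genes additionally load on the BMI component orthogonal to
    log-IS with weight ``bmi_coexpression``, signed opposite the IS
    direction; unplanted genes are pure noise.
    """
    n_genes = len(truth)
    n = len(is_log)
    z_is = (is_log - is_log.mean()) / max(is_log.std(), 1e-12)
    z_bmi = (bmi - bmi.mean()) / max(bmi.std(), 1e-12)
    resid = z_bmi - np.dot(z_bmi, z_is) / np.dot(z_is, z_is) * z_is
    z_b = resid / max(resid.std(), 1e-12)
    eps = rng.standard_normal((n_genes, n))
    r = truth["true_effect"].to_numpy()[:, None]  # signed r, 0 for unplanted
    s = -np.sign(r) * params.bmi_coexpression
    resid_var = 1 - r**2 - s**2
    if np.any(resid_var <= 0):
        raise ValueError("effect_r and bmi_coexpression jointly infeasible (r^2 + s^2 >= 1)")
    latent = r * z_is[None, :] + s * z_b[None, :] + np.sqrt(resid_var) * eps
    return baselines[:, None] + params.gene_log2_sd * latent


def simulate_cohorts(params: CohortParams) -> tuple[list[CohortStudy], pd.DataFrame]:
    """Simulate ``n_cohorts`` baseline cohorts sharing one planted truth.

    Returns ``(cohorts, truth)``.  Within each cohort, planted genes' log2
    expression is ``baseline + sd * (r * z(is_log) + sqrt(1-r^2) * eps)`` so
    the population correlation with log-IS equals the signed ``effect_r``;
    unplanted genes are independent noise.
    """
    root = np.random.default_rng(params.seed)
    truth_rng = np.random.default_rng(root.integers(2**31))
    truth = _gene_truth(params, truth_rng)
    baselines = truth_rng.uniform(*params.baseline_log2_range, size=params.n_genes)

    cohorts: list[CohortStudy] = []
    for c in range(params.n_cohorts):
        crng = np.random.default_rng(root.integers(2**31))
        if isinstance(params.n_subjects, tuple):
            n = int(crng.integers(params.n_subjects[0], params.n_subjects[1] + 1))
        else:
            n = int(params.n_subjects)
        study_id = f"C{c + 1}"
        pheno = _simulate_phenotypes(params, n, crng, study_id)
        expr = _planted_expression(
            truth, pheno["is_log"].fillna(pheno["is_log"].mean()).to_numpy(),
            pheno["bmi"].to_numpy(), params, crng, baselines,
        )
        expression = pd.DataFrame(expr, index=truth.index, columns=pheno.index)
        cohorts.append(CohortStudy(study_id, expression, pheno, truth))
    return cohorts, truth


# --------------------------------------------------------------------------
# intervention simulation


def simulate_intervention(
    params: InterventionParams,
    baseline: list[CohortStudy],
) -> tuple[list[InterventionStudy], pd.DataFrame]:
    """Simulate paired pre/post studies on top of baseline cohorts.

    The delta-gene subset is drawn once (shared truth across studies) from
    the baseline planted IS genes; per study, each delta gene's per-subject
    log2 fold change rank-correlates with the subject's change in log-IS at
    ``delta_rho``, signed so that an *improvement* in IS moves expression in
    the gene's healthy direction (positive-IS genes rise, negative-IS genes
    fall).  Non-delta genes change independently of IS.
    """
    if not baseline:
        raise ValueError("baseline cohorts required")
    truth = baseline[0].truth
    rng = np.random.default_rng(params.seed)

    planted = truth.index[truth["is_planted"]].to_numpy()
    n_delta = int(round(params.frac_delta_genes * len(planted)))
    delta_genes = rng.choice(planted, size=n_delta, replace=False) if n_delta else np.array([], dtype=object)
    delta_truth = pd.DataFrame(
        {
            "is_delta": truth.index.isin(delta_genes),
            "true_direction": np.where(
                truth.index.isin(delta_genes), truth["true_direction"], 0
            ),
            "true_rho": np.where(
                truth.index.isin(delta_genes),
                truth["true_direction"] * params.delta_rho,
                0.0,
            ),
        },
        index=truth.index,
    )

    # target a *Spearman* rho: for a bivariate Gaussian, rho_s = (6/pi)
    # asin(r/2), so invert to get the Pearson r to plant
    r_plant = 2.0 * np.sin(np.pi * params.delta_rho / 6.0)

    gene_means = baseline[0].expression.mean(axis=1).to_numpy()
    n_genes = len(truth)
    studies: list[InterventionStudy] = []
    for s in range(params.n_studies):
        srng = np.random.default_rng(rng.integers(2**31))
        n = params.n_subjects
        study_id = f"I{s + 1}"
        subjects = [f"{study_id}_S{i:04d}" for i in range(n)]
        delta_is = srng.normal(params.delta_is_mean, params.delta_is_sd, size=n)
        # uncentered: a cohort whose IS improves on average also shifts its
        # delta genes on average, so the paired-DE layer sees a real signal
        z_d = delta_is / max(delta_is.std(), 1e-12)

        pre = gene_means[:, None] + 0.5 * srng.standard_normal((n_genes, n))
        eps = srng.standard_normal((n_genes, n))
        direction = delta_truth["true_direction"].to_numpy()[:, None]
        is_delta = delta_truth["is_delta"].to_numpy()[:, None]
        latent = np.where(
            is_delta,
            direction * (r_plant * z_d[None, :] + np.sqrt(1 - r_plant**2) * eps),
            eps,
        )
        fc = params.fc_log2_sd * latent
        post = pre + fc

        pre_ids = [f"{sid}_pre" for sid in subjects]
        post_ids = [f"{sid}_post" for sid in subjects]
        studies.append(
            InterventionStudy(
                study_id=study_id,
                pre=pd.DataFrame(pre, index=truth.index, columns=pre_ids),
                post=pd.DataFrame(post, index=truth.index, columns=post_ids),
                delta_is=pd.Series(delta_is, index=subjects, name="delta_is"),
                pairing=pd.DataFrame(
                    {"pre_sample": pre_ids, "post_sample": post_ids, "study": study_id},
                    index=pd.Index(subjects, name="subject_id"),
                ),
                truth=delta_truth,
            )
        )
    return studies, delta_truth
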