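"""Covariate-adjusted association of gene expression with insulin sensitivity.

Per cohort, each gene's log2 expression is modeled against log-IS together
with one clinical covariate (age or BMI) in a bivariate linear model with
interaction, ``expression ~ IS * covariate``, assessed with *sequential*
(Type-I) ANOVA.  Sequential decomposition makes the term order matter
whenever IS and the covariate are correlated: with IS first the IS term
captures all variance it can explain; with the covariate first the shared
variance is credited to the covariate.  Both orderings are computed because
the difference between them is itself informative about confounding between
adiposity and insulin sensitivity.

Cohort-level IS-term p-values are combined across studies with the
unweighted Stouffer method, converted to Benjamini-Hochberg q-values per
covariate model, and genes passing the FDR threshold are then filtered for a
directionally consistent univariate correlation sign across a designated set
of cohorts (the largest studies).  The survivors form the CORE-IS gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

P_EPS = 1e-300


# --------------------------------------------------------------------------
# sequential (Type-I) ANOVA


def _sequential_anova(Y: np.ndarray, x1: np.ndarray, x2: np.ndarray):
    """Sequential ANOVA of ``y ~ x1 * x2`` for many genes at once.

    ``Y`` is n x G (samples by genes).  Terms enter in the order
    x1, x2, x1:x2; each contributes one df and its incremental sum of
    squares is tested against the full-model residual mean square.

    Returns ``(p, F, rss, df_resid)`` where p and F are 3 x G arrays in term
    order.  Implemented via a thin QR of the ordered design matrix, whose
    successive columns span the nested model sequence, so the squared
    projections onto the Q columns are exactly the sequential SS.
    """
    n = Y.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples for the 4-parameter model")
    X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
    r12 = np.corrcoef(x1, x2)[0, 1]
    if abs(r12) > 0.999:
        raise ValueError(f"covariate collinear with IS (|r| = {abs(r12):.4f})")
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise ValueError("rank-deficient design matrix")
    C = Q.T @ Y  # 4 x G
    ss_terms = C[1:] ** 2  # sequential SS for x1, x2, x1:x2
    rss = np.maximum((Y**2).sum(axis=0) - (C**2).sum(axis=0), 0.0)
    df_resid = n - 4
    ms = rss / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_terms / ms
    p = stats.f.sf(F, 1, df_resid)
    # degenerate cases: zero residual variance
    perfect = ms <= 1e-12 * np.maximum((Y**2).sum(axis=0), 1.0)
    if perfect.any():
        zero_term = ss_terms[:, perfect] <= 1e-12
        p[:, perfect] = np.where(zero_term, 1.0, 0.0)
        F[:, perfect] = np.where(zero_term, 0.0, np.inf)
    return p, F, rss, df_resid


@dataclass
class BivariateFit:
    """Sequential-ANOVA p-values for one gene."""

    p_is: float
    p_covariate: float
    p_interaction: float
    degenerate: bool = False


def fit_bivariate_model(
    y: np.ndarray,
    is_log: np.ndarray,
    covariate: np.ndarray,
    order: str = "is_first",
) -> BivariateFit:
    """Fit ``y ~ IS * covariate`` with sequential ANOVA for one gene.

    ``order`` selects which main effect enters first: ``"is_first"``
    (discovery convention) or ``"cov_first"`` (covariate-adjusted reading).
    """
    y = np.asarray(y, dtype=float)
    is_log = np.asarray(is_log, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(is_log).all() and np.isfinite(covariate).all()):
        raise ValueError("non-finite inputs")
    if order not in ("is_first", "cov_first"):
        raise ValueError(f"unknown order {order!r}")
    if np.ptp(y) == 0:
        return BivariateFit(1.0, 1.0, 1.0, degenerate=True)
    x1, x2 = (is_log, covariate) if order == "is_first" else (covariate, is_log)
    p, F, rss, _ = _sequential_anova(y[:, None], x1, x2)
    pos_is = 0 if order == "is_first" else 1
    pos_cov = 1 - pos_is
    degenerate = bool(rss[0] <= 1e-12 * max(float((y**2).sum()), 1.0))
    return BivariateFit(
        float(p[pos_is, 0]), float(p[pos_cov, 0]), float(p[2, 0]), degenerate
    )


def univariate_r(y: np.ndarray, x: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return float("nan")
    return float(np.corrcoef(y, x)[0, 1])


def associate_study(
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariate: str,
    is_col: str = "is_log",
) -> pd.DataFrame:
    """Per-gene association table for one cohort and one covariate model.

    Subjects lacking a valid IS value (``NaN`` in ``is_col``) or the
    covariate are dropped.  Columns: ``r_is`` (univariate Pearson),
    ``p_is_first`` (IS enters first), ``p_is_adjusted`` (covariate enters
    first), ``p_interaction``, ``n``.
    """
    common = expression.columns.intersection(phenotypes.index)
    pheno = phenotypes.loc[common]
    ok = pheno[is_col].notna() & pheno[covariate].notna()
    pheno = pheno.loc[ok]
    if len(pheno) < 5:
        raise ValueError(f"only {len(pheno)} usable subjects; need >= 5")
    Y = expression[pheno.index].to_numpy(dtype=float).T  # n x G
    is_log = pheno[is_col].to_numpy(dtype=float)
    cov = pheno[covariate].to_numpy(dtype=float)

    p_first, _, _, _ = _sequential_anova(Y, is_log, cov)
    p_adj, _, _, _ = _sequential_anova(Y, cov, is_log)

    yc = Y - Y.mean(axis=0)
    xc = is_log - is_log.mean()
    denom = np.sqrt((yc**2).sum(axis=0) * (xc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (yc * xc[:, None]).sum(axis=0) / denom, np.nan)

    return pd.DataFrame(
        {
            "r_is": r,
            "p_is_first": p_first[0],
            "p_is_adjusted": p_adj[1],
            "p_interaction": p_first[2],
            "n": len(pheno),
        },
        index=expression.index,
    )


# --------------------------------------------------------------------------
# meta-analysis


def stouffer_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Unweighted Stouffer combination of one p-value per study.

    ``z_i = Phi^{-1}(1 - p_i)``, ``Z = sum z_i / sqrt(k)``,
    ``p = 1 - Phi(Z)``.  Exact 0/1 inputs are clamped to ``[1e-300,
    1 - 1e-16]``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, P_EPS, 1 - 1e-16)
    z = stats.norm.isf(p)
    Z = z.sum() / np.sqrt(p.size)
    return float(Z), float(stats.norm.sf(Z))


def stouffer_rows(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Stouffer combination (genes x studies -> Z, p_meta)."""
    p = np.clip(p_matrix.to_numpy(dtype=float), P_EPS, 1 - 1e-16)
    z = stats.norm.isf(p)
    Z = z.sum(axis=1) / np.sqrt(p.shape[1])
    return pd.DataFrame(
        {"z": Z, "p_meta": stats.norm.sf(Z)}, index=p_matrix.index
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` at sorted ranks, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def directional_consistency(
    r_by_study: Mapping[str, float], required_studies: Sequence[str]
) -> tuple[bool, int]:
    """Strict one-sign rule over the designated studies.

    Returns ``(consistent, direction)``; a zero or undefined r in any
    required study makes the gene inconsistent (direction 0).
    """
    missing = [s for s in required_studies if s not in r_by_study]
    if missing:
        raise KeyError(f"r value missing for required studies: {missing}")
    rs = np.array([r_by_study[s] for s in required_studies], dtype=float)
    if np.isnan(rs).any() or np.any(rs == 0):
        return False, 0
    signs = np.sign(rs)
    if np.all(signs == signs[0]):
        return True, int(signs[0])
    return False, 0


def assemble_core_is(
    age_model: Mapping[str, pd.DataFrame],
    bmi_model: Mapping[str, pd.DataFrame] | None = None,
    fdr_threshold: float = 0.10,
    required_studies: Sequence[str] | None = None,
    both_models_required: bool = True,
) -> pd.DataFrame:
    """Meta-analyze per-study associations into the CORE-IS gene table.

    ``age_model``/``bmi_model`` map study id -> :func:`associate_study`
    output.  Genes are restricted to those measured in every study (features
    absent from a platform are excluded, not imputed).  A gene is flagged
    ``core_is`` when its IS-first Stouffer q-value is below the threshold in
    the age model (and, if ``both_models_required`` and a BMI model is
    given, in the BMI model too) *and* its univariate r keeps one strict
    sign across ``required_studies`` (default: the four largest cohorts).
    """
    if not 0.0 < fdr_threshold < 1.0:
        raise ValueError("fdr_threshold must be in (0, 1)")
    if len(age_model) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    studies = list(age_model)
    genes = age_model[studies[0]].index
    for s in studies[1:]:
        genes = genes.intersection(age_model[s].index)
    if required_studies is None:
        sizes = {s: int(age_model[s]["n"].iloc[0]) for s in studies}
        required_studies = sorted(sizes, key=sizes.get, reverse=True)[:4]
    else:
        missing = [s for s in required_studies if s not in age_model]
        if missing:
            raise KeyError(f"required studies absent from inputs: {missing}")

    def model_meta(model: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        p = pd.DataFrame({s: model[s].loc[genes, "p_is_first"] for s in studies})
        meta = stouffer_rows(p)
        meta["q"] = bh_fdr(meta["p_meta"].to_numpy())
        return meta

    meta_age = model_meta(age_model)
    out = pd.DataFrame(index=genes)
    out["z_age"] = meta_age["z"]
    out["p_meta_age"] = meta_age["p_meta"]
    out["q_age"] = meta_age["q"]
    passed = out["q_age"] < fdr_threshold
    if bmi_model is not None:
        meta_bmi = model_meta(bmi_model)
        out["z_bmi"] = meta_bmi["z"]
        out["p_meta_bmi"] = meta_bmi["p_meta"]
        out["q_bmi"] = meta_bmi["q"]
        if both_models_required:
            passed &= out["q_bmi"] < fdr_threshold
        else:
            passed |= out["q_bmi"] < fdr_threshold

    r_cols = {}
    for s in studies:
        r_cols[f"r_{s}"] = age_model[s].loc[genes, "r_is"]
    out = pd.concat([out, pd.DataFrame(r_cols, index=genes)], axis=1)

    req = np.array([f"r_{s}" for s in required_studies])
    R = out[req].to_numpy(dtype=float)
    nonzero = ~np.isnan(R) & (R != 0)
    signs = np.sign(R)
    consistent = nonzero.all(axis=1) & (np.abs(signs.sum(axis=1)) == len(required_studies))
    direction = np.where(consistent, np.sign(signs.sum(axis=1)), 0).astype(int)
    out["consistent"] = consistent
    out["direction"] = direction
    out["core_is"] = passed.to_numpy() & consistent
    out.attrs["required_studies"] = list(required_studies)
    out.attrs["fdr_threshold"] = fdr_threshold
    out.index.name = "gene_id"
    return out
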