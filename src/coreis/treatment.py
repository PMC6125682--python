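"""Intervention layer: paired DE, delta-IS rank correlation, consistency.

Clinical interventions (exercise training, diet, insulin-sensitizing drugs)
change insulin sensitivity to a variable degree per subject.  Genes that
causally regulate IS should not merely change on average under treatment —
their per-subject expression change should *track* the per-subject change
in IS.  This module implements that test:

* paired t-test differential expression per study, with Stouffer + BH
  meta-analysis across studies;
* per gene and study, the Spearman correlation between per-subject log2
  fold change and per-subject change in log-IS;
* selection of genes whose correlation sign is strictly concordant with
  their baseline IS direction in *every* study (positive-IS genes must rise
  with improving IS, negative-IS genes must fall);
* an upper cumulative binomial tail probability for observing that many
  fully concordant genes under a sign-only null, where each study
  contributes an independent fair sign, giving a per-gene null probability
  ``p0 = (1/2)^s``.  The null model is a documented choice — sign-only,
  no magnitude threshold — and both it and ``p0`` are reported alongside
  the tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr, stouffer_rows


def paired_de(
    pre: pd.DataFrame, post: pd.DataFrame, pairing: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene paired t-test of post - pre log2 expression.

    ``pairing`` has one row per subject with ``pre_sample`` and
    ``post_sample`` columns.  Returns ``log2fc`` (mean difference), ``t``,
    ``p`` (two-sided, df = n-1) and a ``degenerate`` flag for genes whose
    differences have zero variance (p reported as 1).
    """
    if len(pairing) < 3:
        raise ValueError("paired DE needs at least 3 pairs")
    d = (
        post[pairing["post_sample"]].to_numpy(dtype=float)
        - pre[pairing["pre_sample"]].to_numpy(dtype=float)
    )
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"log2fc": mean, "t": t, "p": p, "degenerate": degenerate}, index=pre.index
    )


def de_meta(per_study_p: pd.DataFrame) -> pd.DataFrame:
    """Stouffer-combine per-study DE p-values and attach BH q-values."""
    meta = stouffer_rows(per_study_p)
    meta["q"] = bh_fdr(meta["p_meta"].to_numpy())
    return meta


def delta_correlation(log2fc: np.ndarray, delta_is: np.ndarray) -> float:
    """Spearman rho of one gene's per-subject fold change vs delta-IS."""
    log2fc = np.asarray(log2fc, dtype=float)
    delta_is = np.asarray(delta_is, dtype=float)
    if len(log2fc) < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(log2fc) == 0 or np.ptp(delta_is) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(log2fc, delta_is)
    return float(rho)


def delta_correlations(fc: pd.DataFrame, delta_is: pd.Series) -> pd.Series:
    """Vectorized per-gene Spearman rho (average-rank ties).

    ``fc`` is genes x subjects; columns must match ``delta_is``'s index.
    """
    d = delta_is.loc[fc.columns].to_numpy(dtype=float)
    ranks_d = stats.rankdata(d)
    ranks_g = np.apply_along_axis(stats.rankdata, 1, fc.to_numpy(dtype=float))
    rd = ranks_d - ranks_d.mean()
    rg = ranks_g - ranks_g.mean(axis=1, keepdims=True)
    denom = np.sqrt((rg**2).sum(axis=1) * (rd**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (rg * rd[None, :]).sum(axis=1) / denom, np.nan)
    return pd.Series(rho, index=fc.index, name="rho")


def study_delta_result(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    pairing: pd.DataFrame,
    delta_is: pd.Series,
) -> pd.DataFrame:
    """Per-gene rho and DE statistics for one paired study."""
    de = paired_de(pre, post, pairing)
    fc = pd.DataFrame(
        post[pairing["post_sample"]].to_numpy() - pre[pairing["pre_sample"]].to_numpy(),
        index=pre.index,
        columns=pairing.index,
    )
    de["rho"] = delta_correlations(fc, delta_is)
    return de


def select_consistent_genes(
    rho_by_study: pd.DataFrame,
    expected_direction: pd.Series,
) -> pd.Index:
    """Genes whose rho sign matches the expected direction in every study.

    ``rho_by_study`` is genes x studies.  A zero, NaN or discordant rho in
    any study rejects the gene; genes with expected direction 0 are never
    selected.  Raises if any gene lacks an expected direction.
    """
    missing = rho_by_study.index.difference(expected_direction.index)
    if len(missing):
        raise KeyError(f"expected_direction missing for genes: {list(missing[:3])}")
    R = rho_by_study.to_numpy(dtype=float)
    expect = expected_direction.loc[rho_by_study.index].to_numpy(dtype=float)
    good = ~np.isnan(R) & (np.sign(R) == expect[:, None]) & (expect[:, None] != 0)
    return rho_by_study.index[good.all(axis=1)]


@dataclass(frozen=True)
class BinomialTestResult:
    """Cumulative binomial consistency statistic."""

    k: int
    n: int
    s: int
    p0: float
    p_tail: float


def binomial_consistency_p(
    k: int, n: int, s: int, p0: float | None = None
) -> BinomialTestResult:
    """Upper-tail binomial probability of >= k fully concordant genes.

    Under the sign-only null each of ``s`` studies contributes an
    independent fair sign, so a gene is fully concordant with its expected
    direction with probability ``p0 = (1/2)^s`` (overridable).  The tail is
    ``sum_{j=k}^{n} C(n,j) p0^j (1-p0)^{n-j}``.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if s < 1:
        raise ValueError("s must be >= 1")
    if p0 is None:
        p0 = 0.5**s
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    p_tail = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, p0))
    return BinomialTestResult(k=k, n=n, s=s, p0=p0, p_tail=p_tail)
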