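"""Normalization, probe-set summarization and array quality control.

The quantification chain is the RMA convention: quantile-normalize the
linear-scale probe intensities across arrays, log2-transform, then fit each
probe-set's probes x samples block with Tukey median polish

    y_ij ~ overall + probe_i + sample_j

and report ``overall + sample_j`` as the probe-set's expression.  The
residual matrices feed the NUSE (normalized unscaled standard error) array
QC: per probe-set and sample an unscaled standard error is estimated from
the residual spread, scaled to a cross-array median of 1, and the per-array
median of these ratios flags outlier arrays (> 1.05 by default — the common
probe-level-model practice; visual inspection is the field's tradition, so
the numeric cutoff is configurable).

No background correction is applied: the probe filter cascade in
:mod:`coreis.probesets` removes background-dominated probes at the design
level instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probesets import ChipDefinition

log = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common reference distribution.

    The reference is the row-wise mean of the sorted columns.  Tied values
    within a column receive the mean of the reference values their positions
    span, so the transform is well defined and idempotent.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite intensities")
    n, m = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(n)
        col[order] = ref
        # average the reference over ties
        vals, inverse, counts = np.unique(x[:, j], return_inverse=True, return_counts=True)
        if len(vals) < n:
            sums = np.bincount(inverse, weights=col)
            col = (sums / counts)[inverse]
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class MedianPolishFit:
    """Additive decomposition of one probe-set block."""

    overall: float
    probe_effects: np.ndarray
    sample_effects: np.ndarray
    residuals: np.ndarray

    @property
    def expression(self) -> np.ndarray:
        """Per-sample summarized expression: overall + sample effect."""
        return self.overall + self.sample_effects


def median_polish(
    x: np.ndarray, tol: float = 1e-8, max_iter: int = 20
) -> MedianPolishFit:
    """Tukey median polish of a probes x samples matrix (log2 scale)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("median polish needs a non-empty 2-d matrix")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in probe block")
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    prev = np.abs(resid).sum()
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cdelta = np.median(col)
        col -= cdelta
        overall += cdelta

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rdelta = np.median(row)
        row -= rdelta
        overall += rdelta

        cur = np.abs(resid).sum()
        if abs(prev - cur) <= tol * max(cur, 1.0):
            break
        prev = cur
    return MedianPolishFit(overall, row, col, resid)


def summarize(
    log2_intensities: pd.DataFrame,
    chipdef: ChipDefinition,
    tol: float = 1e-8,
    max_iter: int = 20,
    estimator: str = "median_polish",
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Summarize every probe-set; returns (expression, residuals-by-set).

    ``estimator`` is ``"median_polish"`` (default, robust) or ``"mean"``
    (plain per-sample probe average, kept as a diagnostic fallback).
    """
    if estimator not in ("median_polish", "mean"):
        raise ValueError(f"unknown estimator {estimator!r}")
    samples = log2_intensities.columns
    rows = {}
    residuals: dict[str, np.ndarray] = {}
    probe_pos = {p: i for i, p in enumerate(log2_intensities.index)}
    x_all = log2_intensities.to_numpy(dtype=float)
    for ps_id, probes in chipdef.probe_sets.items():
        try:
            idx = [probe_pos[p] for p in probes]
        except KeyError as e:
            raise KeyError(f"probe {e} of probe-set {ps_id} missing from matrix") from e
        block = x_all[idx, :]
        if estimator == "mean":
            expr = block.mean(axis=0)
            resid = block - block.mean(axis=0)[None, :] - (
                block.mean(axis=1) - block.mean()
            )[:, None]
        else:
            fit = median_polish(block, tol=tol, max_iter=max_iter)
            expr = fit.expression
            resid = fit.residuals
        rows[ps_id] = expr
        residuals[ps_id] = resid
    expression = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    expression.index.name = "probe_set_id"
    return expression, residuals


def nuse_qc(
    residuals: dict[str, np.ndarray],
    samples: list[str],
    outlier_cutoff: float = 1.05,
) -> pd.DataFrame:
    """NUSE report: per-sample score (cross-array median 1) + outlier flag.

    Per probe-set the unscaled standard error for sample j is the root mean
    square of that column's residuals divided by sqrt(n_probes); each
    probe-set's SEs are scaled by their cross-sample median, and a sample's
    NUSE is the median of these ratios over probe-sets.
    """
    if len(samples) < 3:
        log.warning("NUSE with < 3 samples is uninformative")
    ratios = []
    for ps_id, resid in residuals.items():
        n_probes = resid.shape[0]
        se = np.sqrt((resid**2).mean(axis=0) / max(n_probes, 1))
        med = np.median(se)
        if med > 0:
            ratios.append(se / med)
        else:
            ratios.append(np.ones_like(se))  # perfect fit: uninformative set
    if not ratios:
        raise ValueError("no residuals provided")
    nuse = np.median(np.vstack(ratios), axis=0)
    report = pd.DataFrame(
        {"nuse": nuse, "outlier": nuse > outlier_cutoff},
        index=pd.Index(samples, name="sample_id"),
    )
    n_out = int(report["outlier"].sum())
    if n_out:
        log.info("NUSE flags %d outlier arrays (cutoff %g)", n_out, outlier_cutoff)
    return report


def quantify(
    intensities: pd.DataFrame,
    chipdef: ChipDefinition,
    outlier_cutoff: float = 1.05,
    estimator: str = "median_polish",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: quantile normalize (linear), log2, summarize, NUSE.

    Returns ``(probe-set expression, NUSE report)``.
    """
    norm = quantile_normalize(intensities)
    log2 = np.log2(norm.clip(lower=2.0**-10))
    expression, residuals = summarize(log2, chipdef, estimator=estimator)
    report = nuse_qc(residuals, list(intensities.columns), outlier_cutoff)
    return expression, report
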