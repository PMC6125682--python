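"""Insulin-sensitivity phenotyping from fasting insulin and glucose.

The phenotype modeled throughout the pipeline is ``is_log``, the log10 of the
insulin-sensitivity percentile S%.  S% is the reciprocal of a
homeostasis-model-assessment insulin-resistance index computed from fasting
insulin (pmol/l) and fasting glucose (mmol/l).  The genuine HOMA2 computer
model is an iterative solver with no published closed form, so this module
uses the classic closed-form HOMA1-style index as a documented stand-in::

    homa_ir = (insulin_uU_ml * glucose_mmol_l) / 22.5
    s_percent = 100 / homa_ir
    is_log = log10(s_percent)

with insulin converted from pmol/l to uU/ml via the conventional factor
6.945.  The stand-in is strictly monotone in both inputs and preserves the
rank order of subjects, which is what the downstream association layer
consumes; tables of true HOMA2 S% values can be injected instead via the
``s_percent`` override accepted by :func:`augment_phenotypes`.

Records outside the operating range of the HOMA model (defaults mirror the
published calculator's accepted input ranges) are flagged invalid and are
excluded from association analysis with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: pmol/l per uU/ml for insulin.
INSULIN_PMOL_PER_UU = 6.945

#: Default operating range for fasting insulin, pmol/l.
INSULIN_RANGE = (20.0, 400.0)

#: Default operating range for fasting glucose, mmol/l.
GLUCOSE_RANGE = (3.0, 25.0)


@dataclass(frozen=True)
class RangeCheck:
    """Outcome of the operating-range screen for one record."""

    valid: bool
    reason: str = ""


def validate_range(
    insulin_pmol_l: float,
    glucose_mmol_l: float,
    insulin_range: tuple[float, float] = INSULIN_RANGE,
    glucose_range: tuple[float, float] = GLUCOSE_RANGE,
) -> RangeCheck:
    """Screen one (insulin, glucose) pair against the model operating range.

    Non-positive values are rejected outright (they are physically
    meaningless); in-range but extreme values pass.
    """
    if not np.isfinite(insulin_pmol_l) or not np.isfinite(glucose_mmol_l):
        return RangeCheck(False, "non-finite input")
    if insulin_pmol_l <= 0 or glucose_mmol_l <= 0:
        raise ValueError(
            f"insulin/glucose must be positive, got ({insulin_pmol_l}, {glucose_mmol_l})"
        )
    lo, hi = insulin_range
    if not lo <= insulin_pmol_l <= hi:
        side = "below" if insulin_pmol_l < lo else "above"
        return RangeCheck(False, f"insulin {insulin_pmol_l:g} pmol/l {side} range [{lo}, {hi}]")
    lo, hi = glucose_range
    if not lo <= glucose_mmol_l <= hi:
        side = "below" if glucose_mmol_l < lo else "above"
        return RangeCheck(False, f"glucose {glucose_mmol_l:g} mmol/l {side} range [{lo}, {hi}]")
    return RangeCheck(True)


def compute_is(insulin_pmol_l, glucose_mmol_l):
    """Closed-form stand-in IS index.

    Returns ``(homa_ir, s_percent, is_log)``; accepts scalars or arrays.
    Inputs must be positive (callers screen with :func:`validate_range`
    first); the function itself does not range-check so that it can also be
    used to *derive* insulin values during simulation.
    """
    insulin = np.asarray(insulin_pmol_l, dtype=float)
    glucose = np.asarray(glucose_mmol_l, dtype=float)
    if np.any(insulin <= 0) or np.any(glucose <= 0):
        raise ValueError("insulin and glucose must be positive")
    homa_ir = (insulin / INSULIN_PMOL_PER_UU) * glucose / 22.5
    s_percent = 100.0 / homa_ir
    is_log = np.log10(s_percent)
    if np.isscalar(insulin_pmol_l) and np.isscalar(glucose_mmol_l):
        return float(homa_ir), float(s_percent), float(is_log)
    return homa_ir, s_percent, is_log


def insulin_for_is(is_log, glucose_mmol_l):
    """Invert the stand-in: fasting insulin (pmol/l) giving ``is_log`` at a glucose."""
    is_log = np.asarray(is_log, dtype=float)
    glucose = np.asarray(glucose_mmol_l, dtype=float)
    # is_log = log10(100 * 22.5 * 6.945 / (insulin * glucose))
    return 100.0 * 22.5 * INSULIN_PMOL_PER_UU / (10.0 ** is_log * glucose)


def augment_phenotypes(
    pheno: pd.DataFrame,
    insulin_col: str = "fasting_insulin",
    glucose_col: str = "fasting_glucose",
    s_percent_col: str | None = None,
    insulin_range: tuple[float, float] = INSULIN_RANGE,
    glucose_range: tuple[float, float] = GLUCOSE_RANGE,
) -> pd.DataFrame:
    """Add ``homa_ir``, ``s_percent``, ``is_log`` and ``valid`` columns.

    When ``s_percent_col`` names a column of externally computed S% values
    (e.g. from the true HOMA2 software) those are used verbatim and only the
    operating-range screen is applied.
    """
    for col in (insulin_col, glucose_col):
        if col not in pheno.columns:
            raise KeyError(f"phenotype table lacks required column {col!r}")
    out = pheno.copy()
    checks = [
        validate_range(i, g, insulin_range, glucose_range)
        for i, g in zip(out[insulin_col], out[glucose_col])
    ]
    out["valid"] = [c.valid for c in checks]
    n_invalid = int((~out["valid"]).sum())
    if n_invalid:
        for sid, c in zip(out.index, checks):
            if not c.valid:
                log.info("excluding subject %s: %s", sid, c.reason)
        log.info("%d/%d records outside HOMA operating range", n_invalid, len(out))

    if s_percent_col is not None:
        s = out[s_percent_col].astype(float)
        out["homa_ir"] = 100.0 / s
        out["s_percent"] = s
        out["is_log"] = np.log10(s)
    else:
        homa, s, islog = compute_is(
            out[insulin_col].to_numpy(), out[glucose_col].to_numpy()
        )
        out["homa_ir"] = homa
        out["s_percent"] = s
        out["is_log"] = islog
    # is_log is only reported for records that passed the range screen
    out.loc[~out["valid"], ["homa_ir", "s_percent", "is_log"]] = np.nan
    return out
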