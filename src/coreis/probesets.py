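"""Tissue/study-specific chip-definition construction.

A dense expression array assigns millions of short probes to transcripts via
a chip definition file (CDF).  Off-the-shelf definitions pool every probe
regardless of whether it behaves in the tissue at hand, so summarization
mixes in background noise.  This module rebuilds the probe -> probe-set map
per study from three design-level filters:

1. **uniqueness** — a probe must align to exactly one genomic location
   (``map_count == 1``);
2. **signal** — a probe must show usable signal in *this* study's samples
   (linear-scale mean >= 10 units and coefficient of variation <= 25% by
   default; the thresholds are tissue-dependent and configurable);
3. **GC content** — probes with extreme GC (< 20% or > 80%) respond
   non-linearly and are removed (boundaries inclusive-retain).

Surviving probes are grouped by target transcript into probe-sets; sets with
fewer than three probes are dropped.  The three filters are pure
intersections, so the cascade is order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ANNOT_COLUMNS = ("target_id", "map_count", "gc_fraction")


def _check_annotation(annot: pd.DataFrame) -> None:
    missing = [c for c in ANNOT_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"probe annotation lacks columns: {missing}")
    if annot.index.has_duplicates:
        dups = annot.index[annot.index.duplicated()].unique().tolist()[:5]
        raise ValueError(
            f"duplicate probe ids in annotation (multi-target assignment?): {dups}"
        )
    gc = annot["gc_fraction"].to_numpy(dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc_fraction outside [0, 1]")
    if annot["map_count"].isna().any():
        raise ValueError("map_count missing for some probes")


@dataclass
class ChipDefinition:
    """The derived probe -> probe-set map plus the thresholds that built it."""

    probe_sets: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probe_sets)

    @property
    def probes(self) -> set[str]:
        return {p for probes in self.probe_sets.values() for p in probes}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (ps, p, rank)
            for ps, probes in self.probe_sets.items()
            for rank, p in enumerate(probes)
        ]
        return pd.DataFrame(rows, columns=["probe_set_id", "probe_id", "rank"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "ChipDefinition":
        if frame["probe_id"].duplicated().any():
            raise ValueError("a probe appears in more than one probe-set")
        sets: dict[str, list[str]] = {}
        for ps, grp in frame.sort_values(["probe_set_id", "rank"]).groupby(
            "probe_set_id", sort=True
        ):
            sets[str(ps)] = [str(p) for p in grp["probe_id"]]
        return cls(sets, provenance or {})


# --------------------------------------------------------------------------
# individual filters


def filter_unique_probes(annot: pd.DataFrame) -> set[str]:
    """Probes aligning to exactly one genomic location.

    ``map_count == 0`` (unalignable against the current genome) and
    ``map_count >= 2`` (multi-mapping) are both discarded.
    """
    _check_annotation(annot)
    keep = annot.index[annot["map_count"] == 1]
    log.info("uniqueness filter: %d/%d probes retained", len(keep), len(annot))
    return set(keep)


def compute_probe_stats(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean and coefficient of variation on the linear scale.

    CV = sd/mean with the sample (ddof=1) standard deviation.  Probes with
    zero mean get ``cv_defined == False`` and NaN cv.
    """
    if intensities.shape[1] < 2:
        raise ValueError("probe statistics need at least 2 samples")
    x = intensities.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean_intensity": mean, "cv": cv, "cv_defined": mean > 0},
        index=intensities.index,
    )


def filter_signal(
    stats: pd.DataFrame, min_mean: float = 10.0, max_cv: float = 0.25
) -> set[str]:
    """Probes with usable signal: mean >= ``min_mean`` and cv <= ``max_cv``.

    Probes with undefined cv (zero mean) fail the mean criterion anyway.
    """
    if min_mean < 0 or max_cv < 0:
        raise ValueError("thresholds must be non-negative")
    ok = (
        (stats["mean_intensity"] >= min_mean)
        & stats["cv_defined"]
        & (stats["cv"] <= max_cv)
    )
    keep = stats.index[ok.fillna(False)]
    log.info("signal filter (mean>=%g, cv<=%g): %d/%d probes retained",
             min_mean, max_cv, len(keep), len(stats))
    return set(keep)


def filter_gc(
    annot: pd.DataFrame, gc_low: float = 0.20, gc_high: float = 0.80
) -> set[str]:
    """Probes with GC fraction inside ``[gc_low, gc_high]`` (inclusive)."""
    _check_annotation(annot)
    gc = annot["gc_fraction"]
    keep = annot.index[(gc >= gc_low) & (gc <= gc_high)]
    log.info("GC filter [%g, %g]: %d/%d probes retained", gc_low, gc_high,
             len(keep), len(annot))
    return set(keep)


# --------------------------------------------------------------------------
# assembly


def assemble_chipdef(
    retained: set[str],
    annot: pd.DataFrame,
    min_probes: int = 3,
    provenance: dict | None = None,
) -> ChipDefinition:
    """Group retained probes by target transcript into probe-sets.

    Probe order within a set follows the annotation order.  Targets with
    fewer than ``min_probes`` surviving probes emit no probe-set.
    """
    if not retained:
        raise ValueError("no probes retained; cannot assemble a chip definition")
    _check_annotation(annot)
    sub = annot.loc[annot.index.isin(retained)]
    sets: dict[str, list[str]] = {}
    for tid, grp in sub.groupby("target_id", sort=True):
        if len(grp) >= min_probes:
            sets[str(tid)] = [str(p) for p in grp.index]
    log.info("assembled %d probe-sets (>=%d probes) from %d retained probes",
             len(sets), min_probes, len(sub))
    prov = dict(provenance or {})
    prov.setdefault("min_probes", min_probes)
    return ChipDefinition(sets, prov)


def build_chipdef(
    annot: pd.DataFrame,
    intensities: pd.DataFrame,
    min_mean: float = 10.0,
    max_cv: float = 0.25,
    gc_low: float = 0.20,
    gc_high: float = 0.80,
    min_probes: int = 3,
) -> ChipDefinition:
    """Full filter cascade: uniqueness ∩ signal ∩ GC, then assembly.

    The signal statistics are computed from ``intensities`` — the study's own
    samples — which is what makes the definition experiment-specific.
    """
    stats = compute_probe_stats(intensities.loc[annot.index])
    retained = (
        filter_unique_probes(annot)
        & filter_signal(stats, min_mean, max_cv)
        & filter_gc(annot, gc_low, gc_high)
    )
    provenance = {
        "min_mean": min_mean,
        "max_cv": max_cv,
        "gc_low": gc_low,
        "gc_high": gc_high,
        "min_probes": min_probes,
        "n_probes_in": int(len(annot)),
        "n_probes_retained": int(len(retained)),
        "defining_samples": [str(c) for c in intensities.columns],
    }
    return assemble_chipdef(retained, annot, min_probes, provenance)


def unfiltered_chipdef(annot: pd.DataFrame, min_probes: int = 1) -> ChipDefinition:
    """Vendor-style definition using every annotated probe (for comparison)."""
    return assemble_chipdef(set(annot.index), annot, min_probes, {"filtered": False})


def collapse_by_gene(
    expression: pd.DataFrame, gene_map: pd.Series | dict
) -> pd.DataFrame:
    """Collapse probe-set level expression to one row per gene.

    When a gene is represented by several probe-sets, the probe-set with the
    highest mean expression across samples is kept; exact ties break to the
    lexicographically smallest probe-set id.  Probe-sets absent from
    ``gene_map`` are dropped with a warning.
    """
    gmap = pd.Series(gene_map)
    unmapped = expression.index.difference(gmap.index)
    if len(unmapped):
        log.warning("dropping %d probe-sets without a gene mapping (e.g. %s)",
                    len(unmapped), list(unmapped[:3]))
    mapped = expression.loc[expression.index.intersection(gmap.index)]
    means = mapped.mean(axis=1)
    chooser = pd.DataFrame(
        {"gene": gmap.loc[mapped.index], "mean": means, "probe_set": mapped.index}
    )
    # highest mean wins; ties -> smallest probe_set id
    chooser = chooser.sort_values(["gene", "mean", "probe_set"],
                                  ascending=[True, False, True])
    winners = chooser.drop_duplicates("gene", keep="first")
    out = mapped.loc[winners["probe_set"]]
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene_id")
    return out
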