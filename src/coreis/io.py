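"""Tab-delimited readers/writers and the study manifest.

One tabular dialect everywhere: TSV, UTF-8, dot decimal, header row, first
column the feature/subject identifier.  ``NA`` and empty fields are treated
as missing (counted and logged); duplicated identifiers are an input error,
never silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .probesets import ChipDefinition

log = logging.getLogger(__name__)

NA_TOKENS = ["NA", ""]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix.

    Rejects duplicate feature ids, non-numeric cells and all-missing rows;
    missing values (``NA`` or empty) are counted and logged.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate feature ids: {dup}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: non-numeric values in matrix") from e
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.info("%s: %d missing values", path, n_missing)
    all_missing = df.index[df.isna().all(axis=1)]
    if len(all_missing):
        raise ValueError(f"{path}: all-missing rows: {list(all_missing[:5])}")
    if np.isinf(df.to_numpy()).any():
        raise ValueError(f"{path}: non-finite values")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic keyed TSV table (phenotypes, pairing, truth...)."""
    df = pd.read_csv(
        Path(path), sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    write_matrix(df, path)


def write_chipdef(chipdef: ChipDefinition, path: str | Path) -> None:
    """Write a chip definition as TSV plus a YAML provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chipdef.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(chipdef.provenance, fh, sort_keys=True)


def read_chipdef(path: str | Path) -> ChipDefinition:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".provenance.yaml")
    provenance = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = yaml.safe_load(fh) or {}
    return ChipDefinition.from_frame(frame, provenance)


@dataclass
class StudyEntry:
    """One study's files and role in the analysis."""

    study_id: str
    expression: str
    phenotypes: str
    platform: str = "synthetic"
    covariates: tuple[str, ...] = ("age", "bmi")
    required_for_consistency: bool = False
    paired: bool = False


@dataclass
class StudyManifest:
    studies: list[StudyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.studies and not any(s.required_for_consistency for s in self.studies):
            raise ValueError("at least one study must be required_for_consistency")

    @property
    def required_studies(self) -> list[str]:
        return [s.study_id for s in self.studies if s.required_for_consistency]


def load_manifest(path: str | Path) -> StudyManifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "studies" not in raw:
        raise ValueError(f"{path}: manifest must contain a 'studies' mapping")
    base = Path(path).parent
    entries = []
    for sid, entry in raw["studies"].items():
        for key in ("expression", "phenotypes"):
            if key not in entry:
                raise ValueError(f"{path}: study {sid} lacks {key!r}")
            p = base / entry[key]
            if not p.exists():
                raise FileNotFoundError(f"{path}: study {sid}: missing file {p}")
        entries.append(
            StudyEntry(
                study_id=str(sid),
                expression=str(base / entry["expression"]),
                phenotypes=str(base / entry["phenotypes"]),
                platform=entry.get("platform", "synthetic"),
                covariates=tuple(entry.get("covariates", ("age", "bmi"))),
                required_for_consistency=bool(entry.get("required_for_consistency", False)),
                paired=bool(entry.get("paired", False)),
            )
        )
    return StudyManifest(entries)
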