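"""Readers and writers for the package's plain-text table formats.

All tables are TSV, UTF-8, ``.`` decimal separator, ``NA`` for missing
values — diff-friendly and re-parseable by these same functions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditions import (
    VALID_PROTOCOLS,
    VALID_TREATMENTS,
    condition_of,
)

NA_REP = "NA"
FLOAT_FMT = "%.6g"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix.

    First column: gene identifier; header row: sample identifiers.
    Rejects duplicate gene ids, negative and non-integer cells.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"count matrix {path} has no sample columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"duplicate gene ids in {path}: {dups}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise DataError(
                f"non-numeric count for sample {col!r}"
                f" (e.g. gene {bad[0]!r})" if len(bad) else f"non-numeric counts in {col!r}"
            )
        if np.any(vals < 0):
            gene = df.index[np.argmax(vals < 0)]
            raise DataError(f"negative count at gene {gene!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            gene = df.index[np.argmax(~np.isclose(vals, np.round(vals)))]
            raise DataError(f"non-integer count at gene {gene!r}, sample {col!r}")
    df.index.name = "gene_id"
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


DESIGN_COLUMNS = ["sample_id", "protocol", "treatment", "time_h", "replicate"]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a design sheet and attach the canonical ``condition`` column."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DataError(f"design sheet missing columns: {missing}")
    if len(design) == 0:
        raise DataError("design sheet is empty")
    design = design.copy()
    if design["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in design sheet")
    bad_proto = set(design["protocol"]) - VALID_PROTOCOLS
    if bad_proto:
        raise DataError(f"unknown protocol tokens: {sorted(bad_proto)}")
    bad_treat = set(design["treatment"]) - VALID_TREATMENTS
    if bad_treat:
        raise DataError(f"unknown treatment tokens: {sorted(bad_treat)}")
    try:
        design["condition"] = [
            condition_of(p, t, h)
            for p, t, h in zip(design["protocol"], design["treatment"], design["time_h"])
        ]
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    try:
        design = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"cannot parse design sheet {path}: {exc}") from exc
    return validate_design(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def check_counts_design(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = [s for s in counts.columns if s not in set(design["sample_id"])]
    if missing:
        raise DataError(f"samples present in counts but absent from design: {missing[:5]}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write an analysis table with the package-wide TSV conventions."""
    df.to_csv(path, sep="\t", index=index, na_rep=NA_REP, float_format=FLOAT_FMT)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA_REP])


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (set name, description, members)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = parts[0]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [g for g in parts[2:] if g]
            sets[name] = members
    if not sets:
        raise DataError(f"GMT file {path} contains no gene sets")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")


def write_config(config, path: str | Path) -> None:
    """Serialize a (dataclass) configuration as YAML."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_config_dict(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise DataError(f"config file {path} must contain a mapping")
    return payload
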