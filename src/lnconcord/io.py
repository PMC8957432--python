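"""Cohort CSV readers and writers.

All cohort tables are comma-separated UTF-8 with a mandatory header row;
boolean flags serialise as 0/1 and undefined statistics as the literal
token ``NA``.  Reading validates the schema and, crucially, recomputes the
suspicion flag of every CT node from the rule -- a stored flag that
contradicts the rule is a hard error, so downstream concordance statistics
can never be fed inconsistent labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .concordance import CT_COLUMNS, HISTO_COLUMNS
from .errors import ConfigError, DomainError, FormatError, VocabularyError
from .simulate import CohortTables, SimConfig, sim_config_from_mapping
from .suspicion import SuspicionCriteria, is_suspicious, validate_pattern

NA_TOKEN = "NA"

PATIENT_FILE = "patients.csv"
CT_FILE = "ct_nodes.csv"
HISTO_FILE = "histo_nodes.csv"

_FLAGS = ("roundness", "heterogeneous_density", "irregular_border")


def _read_csv(path: Path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing {what} file: {path}")
    df = pd.read_csv(path, dtype={"station_code": str, "patient_id": str,
                                  "node_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _parse_flag(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    vals = df[col]
    bad = ~vals.isin([0, 1, "0", "1", True, False])
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:20]
        raise FormatError(f"{path}: column {col!r} must be 0/1; bad rows {rows}")
    return vals.astype(int).astype(bool)


def read_ct_nodes(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a CT-node CSV; the suspicion flag is recomputed.

    The on-disk schema omits ``suspicious`` (it is derived); if present it
    must agree with the rule on every row.
    """
    path = Path(path)
    df = _read_csv(path, tuple(c for c in CT_COLUMNS if c != "suspicious"), "CT node")
    for col in _FLAGS:
        df[col] = _parse_flag(df, col, path)
    try:
        df["pattern"] = [validate_pattern(p).value for p in df["pattern"]]
        derived = [
            is_suspicious(sz, SuspicionCriteria(r, h, i))
            for sz, r, h, i in zip(df["short_axis_mm"], df["roundness"],
                                   df["heterogeneous_density"], df["irregular_border"])
        ]
    except (DomainError, VocabularyError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    if "suspicious" in df.columns:
        stored = _parse_flag(df, "suspicious", path)
        clash = stored != pd.Series(derived, index=df.index)
        if clash.any():
            rows = (df.index[clash] + 2).tolist()[:20]
            raise FormatError(
                f"{path}: stored suspicious flags contradict the suspicion "
                f"rule on rows {rows}"
            )
    df["suspicious"] = derived
    return df[list(CT_COLUMNS)]


def read_histo_nodes(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, HISTO_COLUMNS, "histology node")
    df["metastatic"] = _parse_flag(df, "metastatic", path)
    return df[list(HISTO_COLUMNS)]


def read_patients(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, ("patient_id", "sex", "age", "tumor_site"), "patients")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()[:20]
        raise FormatError(f"{path}: duplicate patient ids {dupes}")
    return df


def read_cohort(directory: Union[str, Path]) -> CohortTables:
    """Read the three cohort CSVs from a directory."""
    d = Path(directory)
    return CohortTables(
        patients=read_patients(d / PATIENT_FILE),
        ct_nodes=read_ct_nodes(d / CT_FILE),
        histo_nodes=read_histo_nodes(d / HISTO_FILE),
    )


def write_cohort(cohort: CohortTables, directory: Union[str, Path]) -> dict[str, Path]:
    """Write patients/CT/histology CSVs; returns the written paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    patients, ct, histo = cohort
    out = {}
    ct = ct.copy()
    for col in (*_FLAGS, "suspicious"):
        ct[col] = ct[col].astype(int)
    histo = histo.copy()
    histo["metastatic"] = histo["metastatic"].astype(int)
    for name, df in ((PATIENT_FILE, patients), (CT_FILE, ct), (HISTO_FILE, histo)):
        p = d / name
        df.to_csv(p, index=False, lineterminator="\n")
        out[name] = p
    return out


def load_sim_config(path: Union[str, Path]) -> SimConfig:
    """Load a simulation config from a flat YAML key-value file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"missing config file: {path}")
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from None
    if data is None:
        data = {}
    return sim_config_from_mapping(data)
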