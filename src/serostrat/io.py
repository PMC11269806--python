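"""Readers and writers for the pipeline's plain-text formats.

Matrix TSV dialect: header row ``protein_id  peptide_count  <sample>...``;
one row per protein; empty fields encode missing intensities.  Clinical
tables are CSV, repertoires AIRR rearrangement TSV, structured results
JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .repertoire import ClonotypeTable


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------------
def write_matrix_tsv(m: IntensityMatrix, path) -> None:
    df = m.values.copy()
    df.insert(0, "peptide_count", m.peptide_counts)
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_matrix_tsv(path) -> IntensityMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header[2:]:
        if col in seen:
            raise FormatError(f"duplicate sample column: {col!r}")
        seen.add(col)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if header[:2] != ["protein_id", "peptide_count"]:
        raise FormatError("expected columns protein_id, peptide_count, samples...")
    if raw["protein_id"].duplicated().any():
        dup = raw["protein_id"][raw["protein_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate protein id: {dup!r}")
    sample_cols = list(raw.columns[2:])
    numeric = {}
    for col in sample_cols:
        try:
            numeric[col] = pd.to_numeric(raw[col]).to_numpy()
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric cell in column {col!r}: {exc}") from exc
    values = pd.DataFrame(numeric, index=pd.Index(raw["protein_id"], name="protein_id"))
    try:
        peptide_counts = pd.to_numeric(raw["peptide_count"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric peptide_count: {exc}") from exc
    peptide_counts.index = raw["protein_id"]
    return IntensityMatrix(values, peptide_counts)


# ----------------------------------------------------------------------
def write_airr_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_airr_tsv(path) -> ClonotypeTable:
    df = pd.read_csv(path, sep="\t")
    return ClonotypeTable(df)


def write_clinical_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


# ----------------------------------------------------------------------
def _jsonable(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping, embedded in every artifact."""
    blob = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
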