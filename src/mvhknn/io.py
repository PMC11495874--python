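"""Feature-table and FASTA readers/writers plus flat config files.

Feature tables are delimited text with a header: one ID column, one
integer label column, and numeric feature columns (column order is
preserved). The delimiter is inferred from the extension (``.tsv`` /
``.tab`` -> tab, otherwise comma) and can be overridden.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import FeatureDataset
from .exceptions import DataError

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "load_config",
    "check_fasta_ids",
]


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_table(path, id_column: str = "id", label_column: str | None = "label",
                       sep: str | None = None) -> FeatureDataset:
    """Read a delimited feature table into a :class:`FeatureDataset`.

    ``label_column=None`` reads an unlabelled table (labels set to -1),
    as used for prediction inputs. Errors name the offending row and
    column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_infer_sep(path, sep),
                         float_precision="round_trip")
    except FileNotFoundError:
        raise DataError(f"feature table not found: {path}")
    except Exception as exc:  # malformed delimited text
        raise DataError(f"cannot parse feature table {path}: {exc}")

    if id_column not in df.columns:
        raise DataError(f"missing id column {id_column!r} in {path}")
    if label_column is not None and label_column not in df.columns:
        raise DataError(f"missing label column {label_column!r} in {path}")

    ids = df[id_column].astype(str).tolist()
    dup = df[id_column][df[id_column].duplicated()].unique()
    if dup.size:
        raise DataError(f"duplicate sample ids in {path}: {dup[:5].tolist()}")

    drop = [id_column] + ([label_column] if label_column else [])
    feat = df.drop(columns=drop)
    if feat.shape[1] == 0:
        raise DataError(f"no feature columns in {path}")
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric feature value in {path}, row id {ids[row]!r}, "
                f"column {col!r}: {feat[col].iloc[row]!r}"
            )
        feat[col] = coerced

    if label_column is not None:
        try:
            y = df[label_column].astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise DataError(f"labels in {path} are not integer-codable: {exc}")
    else:
        y = np.full(len(ids), -1, dtype=int)

    ds = FeatureDataset(ids=ids, X=feat.to_numpy(dtype=float), y=y)
    ds.metadata["feature_columns"] = list(feat.columns)
    return ds


def write_feature_table(data: FeatureDataset, path, sep: str | None = None,
                        id_column: str = "id", label_column: str = "label") -> None:
    path = Path(path)
    cols = data.metadata.get("feature_columns")
    if not cols or len(cols) != data.d:
        cols = [f"f{j}" for j in range(data.d)]
    df = pd.DataFrame(data.X, columns=cols)
    df.insert(0, id_column, data.ids)
    df.insert(1, label_column, data.y)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep=_infer_sep(path, sep), index=False, float_format="%.17g")


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as ``(id, SEQUENCE)`` pairs, order preserved.

    The ID is the first whitespace token of the header; sequences are
    uppercased; empty records are skipped with a warning; duplicate IDs
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            warnings.warn(f"skipping empty FASTA record {rec.id!r}", UserWarning)
            continue
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=str(sid), description="") for sid, seq in records]
    SeqIO.write(recs, str(Path(path)), "fasta")


def check_fasta_ids(records: list[tuple[str, str]],
                    data: FeatureDataset) -> dict[str, list[str]]:
    """Set differences between FASTA IDs and feature-table IDs."""
    fasta_ids = {r[0] for r in records}
    table_ids = set(data.ids)
    return {
        "fasta_only": sorted(fasta_ids - table_ids),
        "table_only": sorted(table_ids - fasta_ids),
    }


def load_config(path) -> dict:
    """Flat key-value config (YAML mapping of scalars)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DataError(f"cannot parse config {path}: {exc}")
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} must be a flat key-value mapping")
    for k, v in cfg.items():
        if isinstance(v, (dict, list)):
            raise DataError(f"config key {k!r} is not a scalar")
    return cfg
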