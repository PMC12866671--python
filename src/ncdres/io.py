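"""Typed data model and readers/writers for the tabular inputs.

All inputs are delimited text: ncRNA expression matrices (rows = ncRNAs,
columns = cancer cell lines), a drug SMILES table, and two-column pair lists
for the prior association / interaction relations.  Delimiters are
auto-detected between tab and comma; identifiers are opaque, case-preserved
strings matched case-sensitively.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1

VALID_ENTITY_TYPES = ("lncRNA", "miRNA")
VALID_RELATION_LABELS = ("lncRNA-drug", "miRNA-drug", "lncRNA-miRNA")


class NcdresError(ValueError):
    """Base class for hard data errors."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise NcdresError(f"{path}: empty file")
    return "\t" if first.count("\t") >= first.count(",") else ","


@dataclass
class ExpressionMatrix:
    """Expression profiles of one ncRNA type across cancer cell lines."""

    entity_ids: list[str]
    values: np.ndarray  # (n_entities, n_cell_lines)
    entity_type: str

    def __post_init__(self) -> None:
        if self.entity_type not in VALID_ENTITY_TYPES:
            raise NcdresError(f"entity_type must be one of {VALID_ENTITY_TYPES}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.entity_ids):
            raise NcdresError("values must be 2-D with one row per entity id")
        dup = _first_duplicate(self.entity_ids)
        if dup is not None:
            raise NcdresError(f"duplicate entity id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise NcdresError("expression matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SmilesTable:
    drug_ids: list[str]
    smiles: list[str]

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.drug_ids)
        if dup is not None:
            raise NcdresError(f"duplicate drug id {dup!r}")
        if len(self.drug_ids) != len(self.smiles):
            raise NcdresError("drug_ids and smiles must have equal length")
        for d, s in zip(self.drug_ids, self.smiles):
            if not s:
                raise NcdresError(f"empty SMILES string for drug {d!r}")


@dataclass
class PairList:
    pairs: list[tuple[str, str]]
    relation_label: str

    def __post_init__(self) -> None:
        if self.relation_label not in VALID_RELATION_LABELS:
            raise NcdresError(
                f"relation_label must be one of {VALID_RELATION_LABELS}"
            )
        dup = _first_duplicate(self.pairs)
        if dup is not None:
            raise NcdresError(f"duplicate pair {dup!r}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AssociationRecord:
    ncrna_id: str
    drug_id: str
    label: int
    split: str


@dataclass
class AssociationDataset:
    """Labelled (ncRNA, drug) pairs with train/val/test assignments.

    Positives are the curated resistance associations; negatives are sampled
    unknown pairs at twice the positive count.  No pair appears in more than
    one split.
    """

    records: list[AssociationRecord]
    task: str  # "LD" or "MD"

    def __post_init__(self) -> None:
        if self.task not in ("LD", "MD"):
            raise NcdresError("task must be 'LD' or 'MD'")
        seen: dict[tuple[str, str], int] = {}
        for r in self.records:
            key = (r.ncrna_id, r.drug_id)
            if key in seen and seen[key] != r.label:
                raise NcdresError(f"pair {key} appears as both positive and negative")
            if key in seen:
                raise NcdresError(f"pair {key} appears in more than one split")
            seen[key] = r.label
            if r.split not in ("train", "val", "test"):
                raise NcdresError(f"bad split tag {r.split!r}")
            if r.label not in (0, 1):
                raise NcdresError(f"bad label {r.label!r}")

    def subset(self, split: str) -> list[AssociationRecord]:
        return [r for r in self.records if r.split == split]

    def positives(self, split: str | None = None) -> list[tuple[str, str]]:
        return [
            (r.ncrna_id, r.drug_id)
            for r in self.records
            if r.label == 1 and (split is None or r.split == split)
        ]


def _first_duplicate(items: Iterable) -> object | None:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def load_expression_matrix(path: str | Path, entity_type: str) -> ExpressionMatrix:
    """Read a delimited expression table (first column = entity id).

    Rows containing missing values are dropped with a logged warning; a
    duplicated id or a non-numeric cell is a hard error naming the offender.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise NcdresError(f"{path}: no data rows/columns")
    ids = [str(i) for i in df.index]
    dup = _first_duplicate(ids)
    if dup is not None:
        raise NcdresError(f"{path}: duplicate entity id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise NcdresError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    na_rows = df.isna().any(axis=1)
    if na_rows.any():
        logger.warning(
            "%s: dropping %d row(s) with missing values", path, int(na_rows.sum())
        )
        df = df.loc[~na_rows]
        ids = [str(i) for i in df.index]
    if df.shape[0] == 0:
        raise NcdresError(f"{path}: all rows had missing values")
    return ExpressionMatrix(ids, df.to_numpy(dtype=np.float64), entity_type)


def load_smiles_table(path: str | Path) -> SmilesTable:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.lower() for c in df.columns]
    if "drug_id" in cols and "smiles" in cols:
        did = df[df.columns[cols.index("drug_id")]]
        smi = df[df.columns[cols.index("smiles")]]
    elif df.shape[1] >= 2:
        did, smi = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise NcdresError(f"{path}: expected two columns (drug_id, smiles)")
    return SmilesTable([str(d) for d in did], [str(s) for s in smi])


def load_pair_list(path: str | Path, relation_label: str) -> PairList:
    """Read a two-column pair list, deduplicating and logging the duplicates."""
    path = Path(path)
    sep = _sniff_sep(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise NcdresError(f"{path}:{lineno}: malformed row {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                raise NcdresError(f"{path}:{lineno}: self-pair ({a!r})")
            if (a, b) in seen:
                n_dup += 1
                continue
            seen.add((a, b))
            pairs.append((a, b))
    if n_dup:
        logger.info("%s: dropped %d duplicate pair(s)", path, n_dup)
    return PairList(pairs, relation_label)


def save_checkpoint(
    path: str | Path,
    encoder_arrays: dict[str, np.ndarray],
    decoder_arrays: dict[str, np.ndarray],
    config: dict,
) -> None:
    """Write model weights and config to a single binary checkpoint file."""
    arrays: dict[str, np.ndarray] = {}
    for name, arr in encoder_arrays.items():
        if not np.all(np.isfinite(arr)):
            raise NcdresError(f"non-finite values in encoder parameter {name!r}")
        arrays[f"enc/{name}"] = np.asarray(arr)
    for name, arr in decoder_arrays.items():
        if not np.all(np.isfinite(arr)):
            raise NcdresError(f"non-finite values in decoder parameter {name!r}")
        arrays[f"dec/{name}"] = np.asarray(arr)
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": config})
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict]:
    path = Path(path)
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, zipfile.BadZipFile, _stdio.UnsupportedOperation, KeyError) as e:
        raise NcdresError(f"{path}: unreadable or truncated checkpoint: {e}") from e
    if "__meta__" not in arrays:
        raise NcdresError(f"{path}: missing checkpoint metadata")
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise NcdresError(
            f"{path}: checkpoint version {meta.get('version')} != "
            f"code version {CHECKPOINT_VERSION}"
        )
    enc = {k[4:]: v for k, v in arrays.items() if k.startswith("enc/")}
    dec = {k[4:]: v for k, v in arrays.items() if k.startswith("dec/")}
    return enc, dec, meta["config"]


def save_metrics_report(path: str | Path, report: dict) -> None:
    """Metric reports are flat JSON keyed by metric name (and k where used)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
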