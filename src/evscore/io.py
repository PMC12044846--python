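"""Reading/writing the pipeline's tabular and JSON artifacts.

TSV (tab-separated) is canonical; comma-separated files are accepted on
read with a logged auto-detection.  Expression matrices are features x
samples with the feature id in the first column; copy tables are long
format (sample_id, patient_id, timepoint, label, gene, copies).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .atlas import ExpressionDataset
from .scoring import COPY_TABLE_COLUMNS, GeneWeights, validate_copy_table
from .tr_model import TRModel

logger = logging.getLogger("evscore")

__all__ = [
    "read_copy_table",
    "write_copy_table",
    "read_expression_dataset",
    "write_expression_dataset",
    "read_matrix",
    "write_json",
    "read_json",
    "weights_to_json",
    "weights_from_json",
    "model_to_json",
    "model_from_json",
    "file_checksum",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        logger.info("comma-separated input detected: %s", path)
        return ","
    return "\t"


def read_copy_table(path) -> pd.DataFrame:
    """Read and validate a long-format gene-copy table.

    Malformed rows (non-numeric or negative copies, duplicate
    (sample_id, gene) keys) are reported with 1-based file line numbers
    (header = line 1).
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    missing = [c for c in COPY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    copies = pd.to_numeric(table["copies"], errors="coerce")
    bad = table.index[copies.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(f"{path}: non-numeric copies at lines {lines}")
    neg = table.index[copies < 0]
    if len(neg):
        lines = [int(i) + 2 for i in neg[:5]]
        raise ValueError(f"{path}: negative copies at lines {lines}")
    table["copies"] = copies
    dup = table.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        lines = [int(i) + 2 for i in table.index[dup][:5]]
        raise ValueError(f"{path}: duplicate (sample_id, gene) at lines {lines}")
    return validate_copy_table(table)


def write_copy_table(table: pd.DataFrame, path) -> None:
    validate_copy_table(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.15g")


def write_expression_dataset(ds: ExpressionDataset, out_dir) -> None:
    """Matrix as <id>.tsv (first column = feature id), annotations sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds.values.rename_axis("feature_id").to_csv(
        out_dir / f"{ds.dataset_id}.tsv", sep="\t", float_format="%.15g"
    )
    ds.annotations.rename_axis("sample_id").to_csv(
        out_dir / f"{ds.dataset_id}.annotations.tsv", sep="\t"
    )
    if ds.feature_map is not None:
        ds.feature_map.to_csv(out_dir / f"{ds.dataset_id}.feature_map.tsv", sep="\t", index=False)


def read_expression_dataset(out_dir, dataset_id: str) -> ExpressionDataset:
    out_dir = Path(out_dir)
    values = pd.read_csv(out_dir / f"{dataset_id}.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(out_dir / f"{dataset_id}.annotations.tsv", sep="\t", index_col=0)
    fm_path = out_dir / f"{dataset_id}.feature_map.tsv"
    fmap = pd.read_csv(fm_path, sep="\t") if fm_path.exists() else None
    return ExpressionDataset(dataset_id, values, ann, fmap)


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path), index_col=0)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def weights_to_json(weights: GeneWeights, path) -> None:
    write_json(weights.to_dict(), path)


def weights_from_json(path) -> GeneWeights:
    return GeneWeights.from_dict(read_json(path))


def model_to_json(model: TRModel, path) -> None:
    write_json(model.to_dict(), path)


def model_from_json(path) -> TRModel:
    return TRModel.from_dict(read_json(path))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
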