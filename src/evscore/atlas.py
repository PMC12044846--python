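"""Cross-cohort harmonization of expression matrices (MCQ merge).

Independent microarray/RNA cohorts measured on different platforms carry
dataset-specific location and scale biases.  The harmonization chain is:
per-dataset quantile normalization -> collapse of redundant features to one
row per gene (highest mean wins) -> per-gene median centering -> quantile
scaling of each dataset's flattened value vector onto the pooled empirical
distribution -> join on the shared gene set.  The result is one virtual
atlas in which sample provenance is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "MergedAtlas",
    "quantile_normalize",
    "collapse_features",
    "median_center",
    "merge_mcq",
]

VALID_STATES = {"HCC", "nontumor", "cirrhosis", "control"}
VALID_ETIOLOGIES = {"HBV", "HCV", "ALD", "MASLD", "other"}


@dataclass
class ExpressionDataset:
    """One cohort: log2 feature x sample matrix with sample annotations.

    ``annotations`` is indexed by sample id with columns ``state`` and
    ``etiology``.  ``feature_map`` maps feature id -> gene id (a DataFrame
    with columns feature_id/gene_id, possibly one-to-many); ``None`` means
    features already are gene ids.
    """

    dataset_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame
    feature_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError(f"{self.dataset_id}: duplicated sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.dataset_id}: non-finite expression values")
        missing = set(self.values.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"{self.dataset_id}: samples without annotations: {sorted(missing)[:5]}")

    def filter_annotated(self) -> "ExpressionDataset":
        """Drop samples whose state or etiology annotation is unrecognized."""
        ann = self.annotations
        ok = ann["state"].isin(VALID_STATES) & ann["etiology"].isin(VALID_ETIOLOGIES)
        keep = [s for s in self.values.columns if ok.get(s, False)]
        return ExpressionDataset(
            self.dataset_id, self.values[keep], ann.loc[keep], self.feature_map
        )


@dataclass
class MergedAtlas:
    """Gene x sample matrix pooled across cohorts, with provenance."""

    values: pd.DataFrame
    provenance: pd.Series  # sample id -> source dataset id
    annotations: pd.DataFrame
    genes: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids in merged atlas")
        if not self.genes:
            self.genes = list(self.values.index)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean-order-statistic distribution.

    The reference vector is the row-wise mean of the column-sorted matrix;
    each column's values are replaced by reference values at their ranks.
    Tied values receive the mean of the reference values spanning their tied
    ranks, which preserves within-column rank order.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a features x samples matrix with >= 1 feature")
    if not np.isfinite(arr).all():
        raise ValueError("matrix must be finite")
    if arr.shape[1] < 2:
        warnings.warn("single-sample matrix: nothing to equalize, returned unchanged")
        return values.copy() if isinstance(values, pd.DataFrame) else values
    ref = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_features(values: pd.DataFrame, feature_map: pd.DataFrame | None) -> pd.DataFrame:
    """One row per gene: among a gene's features keep the highest-mean row.

    ``feature_map`` holds columns feature_id/gene_id; features absent from
    the map are dropped.  Ties on mean expression keep the lexicographically
    smaller feature id.
    """
    if feature_map is None:
        return values.copy()
    fm = feature_map[["feature_id", "gene_id"]].dropna()
    fm = fm[fm["feature_id"].isin(values.index)]
    if fm.empty:
        warnings.warn("empty feature map: collapsing to an empty matrix")
        return values.iloc[0:0]
    row_means = values.mean(axis=1)
    chosen: dict[str, str] = {}
    for gene, sub in fm.groupby("gene_id", sort=True):
        feats = sorted(sub["feature_id"])
        best = max(feats, key=lambda f: (row_means[f], ))
        # max() keeps the first maximum in sorted order => smaller id on ties
        best = sorted([f for f in feats if row_means[f] == row_means[best]])[0]
        chosen[str(gene)] = best
    out = values.loc[[chosen[g] for g in sorted(chosen)]].copy()
    out.index = pd.Index(sorted(chosen), name="gene_id")
    return out


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene row's median across samples (row medians become 0)."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("matrix must be finite")
    med = np.median(arr, axis=1, keepdims=True)
    out = arr - med
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _pooled_quantile_scale(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Map each vector onto the pooled distribution at ranks r/(n+1).

    Uses Weibull plotting positions on both sides (value rank r/(n+1);
    pooled quantile by linear interpolation between order statistics at
    positions k/(N+1)), so datasets drawn from identical distributions are
    left numerically unchanged.
    """
    pooled = np.concatenate(vectors)
    scaled = []
    for v in vectors:
        p = stats.rankdata(v, method="average") / (len(v) + 1.0)
        scaled.append(np.quantile(pooled, p, method="weibull"))
    return scaled


def merge_mcq(datasets: list[ExpressionDataset], *, log2_transform: bool = False) -> MergedAtlas:
    """Merge cohorts into a virtual atlas by median-centering + quantile scaling.

    Each dataset runs quantile_normalize -> collapse_features ->
    median_center; the matrices are then flattened, quantile-scaled onto the
    pooled value distribution, reshaped, and joined on the intersection of
    gene ids.  Sample ids are prefixed with the dataset id.

    Parameters
    ----------
    log2_transform
        Apply log2(x + 1) on ingestion for matrices still on linear scale.
    """
    if len(datasets) < 2:
        raise ValueError("merge_mcq needs >= 2 datasets")
    prepared = []
    audit: dict = {"datasets": {}}
    for ds in datasets:
        vals = ds.values
        if log2_transform:
            vals = np.log2(vals + 1.0)
        qn = quantile_normalize(vals)
        collapsed = collapse_features(qn, ds.feature_map)
        centered = median_center(collapsed)
        prepared.append((ds, centered))
        audit["datasets"][ds.dataset_id] = {
            "n_samples": int(centered.shape[1]),
            "n_genes": int(centered.shape[0]),
            "median_before_center": float(np.median(collapsed.to_numpy())),
        }

    genes = set(prepared[0][1].index)
    for _, mat in prepared[1:]:
        genes &= set(mat.index)
    if not genes:
        ids = [ds.dataset_id for ds, _ in prepared]
        raise ValueError(f"empty gene intersection across datasets {ids}")
    genes = sorted(genes)

    mats = [mat.loc[genes] for _, mat in prepared]
    vectors = [m.to_numpy(dtype=float).ravel(order="C") for m in mats]
    scaled = _pooled_quantile_scale(vectors)

    pieces, prov, anns = [], {}, []
    for (ds, _), mat, vec in zip(prepared, mats, scaled):
        arr = vec.reshape(mat.shape, order="C")
        cols = [f"{ds.dataset_id}:{c}" for c in mat.columns]
        pieces.append(pd.DataFrame(arr, index=genes, columns=cols))
        for c in cols:
            prov[c] = ds.dataset_id
        ann = ds.annotations.loc[mat.columns].copy()
        ann.index = cols
        anns.append(ann)

    merged = pd.concat(pieces, axis=1)
    audit["n_genes_merged"] = len(genes)
    audit["n_samples_merged"] = int(merged.shape[1])
    return MergedAtlas(
        values=merged,
        provenance=pd.Series(prov, name="dataset_id"),
        annotations=pd.concat(anns),
        genes=list(genes),
        audit=audit,
    )
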