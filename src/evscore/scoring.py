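"""Digital Score computation from absolute dPCR gene-copy measurements.

Each plasma sample yields absolute mRNA copy numbers for a small gene
panel.  Copies are log2(x + 1)-transformed; each gene carries a Golub
signal-to-noise weight w = (mean_HCC − mean_cirrhosis) / (sd_HCC +
sd_cirrhosis) estimated from a labeled pilot cohort; the per-sample
Digital Score is the weighted mean (1/m) Σ w_i · log2(copies_i + 1), and
the Δ Digital Score of a pre/post treatment pair is the same sum over
gene-wise post − pre differences — identically post score minus pre score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ROCSummary, roc_summary

__all__ = [
    "COPY_TABLE_COLUMNS",
    "GeneWeights",
    "validate_copy_table",
    "log_transform",
    "compute_weights",
    "sample_score",
    "delta_score",
    "score_table",
    "build_score_records",
    "pilot_evaluate",
]

COPY_TABLE_COLUMNS = ["sample_id", "patient_id", "timepoint", "label", "gene", "copies"]
VALID_TIMEPOINTS = {"pre", "post", "single"}
VALID_LABELS = {"HCC", "cirrhosis", "viable", "nonviable", "unknown"}

#: variance guard added to the pooled SD so degenerate groups stay finite
S2N_EPSILON = 1e-8


@dataclass
class GeneWeights:
    """Per-gene signal-to-noise weights with the statistics behind them.

    ``weights`` is a gene-indexed Series; ``reference_stats`` holds
    mean/sd of log2(copies + 1) per group per gene.
    """

    weights: pd.Series
    reference_stats: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValueError("weights must be finite")

    @property
    def m(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def to_dict(self) -> dict:
        return {
            "weights": {g: float(w) for g, w in self.weights.items()},
            "reference_stats": {
                f"{g}|{grp}": {"mean": float(r["mean"]), "sd": float(r["sd"])}
                for (g, grp), r in self.reference_stats.iterrows()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneWeights":
        weights = pd.Series(d["weights"], dtype=float).sort_index()
        rows = []
        for key, st in d.get("reference_stats", {}).items():
            g, grp = key.split("|", 1)
            rows.append({"gene": g, "group": grp, "mean": st["mean"], "sd": st["sd"]})
        stats_df = (
            pd.DataFrame(rows).set_index(["gene", "group"])
            if rows
            else pd.DataFrame(columns=["mean", "sd"])
        )
        return cls(weights=weights, reference_stats=stats_df)


def validate_copy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format copy table contract; returns the table."""
    missing = [c for c in COPY_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"copy table missing columns: {missing}")
    copies = pd.to_numeric(table["copies"], errors="raise")
    if (copies < 0).any():
        bad = table.index[copies < 0].tolist()[:5]
        raise ValueError(f"negative copies at rows {bad}")
    dup = table.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        bad = table.index[dup].tolist()[:5]
        raise ValueError(f"duplicate (sample_id, gene) at rows {bad}")
    return table


def log_transform(copies) -> np.ndarray | float:
    """log2(copies + 1); copies must be non-negative."""
    arr = np.asarray(copies, dtype=float)
    if (arr < 0).any():
        raise ValueError("copies must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(copies) or out.ndim == 0 else out


def _copies_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot to sample x gene copies, carrying one row per sample."""
    return table.pivot(index="sample_id", columns="gene", values="copies")


def compute_weights(table: pd.DataFrame, genes: list[str] | None = None) -> GeneWeights:
    """Golub signal-to-noise weights from a pilot cohort labeled HCC/cirrhosis.

    On log2(copies + 1) values, per gene:
    w = (mean_HCC − mean_cirrhosis) / (sd_HCC + sd_cirrhosis + ε)
    with sample SDs (n − 1 denominator).  Requires >= 2 samples per group
    per gene.
    """
    validate_copy_table(table)
    ref = table[table["label"].isin(["HCC", "cirrhosis"])]
    if ref.empty:
        raise ValueError("no samples labeled HCC or cirrhosis")
    mat = _copies_matrix(ref)
    if genes is not None:
        missing = [g for g in genes if g not in mat.columns]
        if missing:
            warnings.warn(f"panel genes absent from table, treated as 0 copies: {missing}")
            for g in missing:
                mat[g] = 0.0
        mat = mat[list(genes)]
    logged = np.log2(mat.fillna(0.0) + 1.0)
    group = ref.drop_duplicates("sample_id").set_index("sample_id")["label"]
    logged["__group"] = group.reindex(logged.index)

    rows, weights = [], {}
    for gene in [c for c in logged.columns if c != "__group"]:
        stats_g = {}
        for grp in ("HCC", "cirrhosis"):
            vals = logged.loc[logged["__group"] == grp, gene].dropna()
            if len(vals) < 2:
                raise ValueError(f"gene {gene}, group {grp}: need >= 2 samples")
            stats_g[grp] = (float(vals.mean()), float(vals.std(ddof=1)))
            rows.append({"gene": gene, "group": grp, "mean": stats_g[grp][0], "sd": stats_g[grp][1]})
        (mu1, sd1), (mu0, sd0) = stats_g["HCC"], stats_g["cirrhosis"]
        weights[gene] = (mu1 - mu0) / (sd1 + sd0 + S2N_EPSILON)

    return GeneWeights(
        weights=pd.Series(weights, dtype=float).sort_index(),
        reference_stats=pd.DataFrame(rows).set_index(["gene", "group"]),
    )


def _panel_logged(copies, weights: GeneWeights) -> np.ndarray:
    """log2(copies + 1) aligned to the weight panel; missing genes -> 0 copies."""
    if isinstance(copies, pd.Series):
        copies = copies.to_dict()
    missing = [g for g in weights.genes if g not in copies or pd.isna(copies[g])]
    if missing:
        warnings.warn(f"missing panel genes treated as 0 copies: {missing}")
    vals = np.array([float(copies.get(g, 0.0)) if not pd.isna(copies.get(g, 0.0)) else 0.0
                     for g in weights.genes])
    if (vals < 0).any():
        raise ValueError("copies must be non-negative")
    return np.log2(vals + 1.0)


def sample_score(copies, weights: GeneWeights) -> float:
    """Digital Score: (1/m) Σ w_i log2(copies_i + 1) over the weight panel."""
    g = _panel_logged(copies, weights)
    w = weights.weights.to_numpy(dtype=float)
    return float((w * g).sum() / weights.m)


def delta_score(pre, post, weights: GeneWeights) -> float:
    """Δ Digital Score: (1/m) Σ w_i (g_post − g_pre)_i on log2(copies + 1).

    Algebraically identical to sample_score(post) − sample_score(pre).
    """
    g_pre = _panel_logged(pre, weights)
    g_post = _panel_logged(post, weights)
    w = weights.weights.to_numpy(dtype=float)
    return float((w * (g_post - g_pre)).sum() / weights.m)


def score_table(table: pd.DataFrame, weights: GeneWeights) -> pd.Series:
    """Digital Score per sample_id for a long-format copy table."""
    validate_copy_table(table)
    mat = _copies_matrix(table)
    return pd.Series(
        {s: sample_score(mat.loc[s], weights) for s in mat.index}, name="score"
    ).sort_index()


def build_score_records(table: pd.DataFrame, weights: GeneWeights) -> pd.DataFrame:
    """Per-patient pre/post/Δ Digital Scores from a paired pre/post table.

    Returns a DataFrame indexed by patient_id with columns pre_score,
    post_score, delta_score, label.
    """
    validate_copy_table(table)
    scores = score_table(table, weights)
    meta = table.drop_duplicates("sample_id").set_index("sample_id")
    rows = {}
    for pid, sub in meta.groupby("patient_id", sort=True):
        rec = {"pre_score": np.nan, "post_score": np.nan, "delta_score": np.nan}
        for sid, r in sub.iterrows():
            if r["timepoint"] == "pre":
                rec["pre_score"] = scores[sid]
            elif r["timepoint"] == "post":
                rec["post_score"] = scores[sid]
        if np.isfinite(rec["pre_score"]) and np.isfinite(rec["post_score"]):
            rec["delta_score"] = rec["post_score"] - rec["pre_score"]
        rec["label"] = sub["label"].iloc[0]
        rows[pid] = rec
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id")


def pilot_evaluate(table: pd.DataFrame, weights: GeneWeights) -> ROCSummary:
    """Score a single-timepoint HCC vs cirrhosis cohort and summarize the ROC."""
    validate_copy_table(table)
    ref = table[table["label"].isin(["HCC", "cirrhosis"])]
    scores = score_table(ref, weights)
    labels = (
        ref.drop_duplicates("sample_id").set_index("sample_id")["label"].reindex(scores.index)
        == "HCC"
    )
    if labels.all() or not labels.any():
        raise ValueError("pilot evaluation needs both HCC and cirrhosis samples")
    return roc_summary(scores.to_numpy(), labels.to_numpy())
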