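"""Candidate marker funnel: differential expression, aux-dataset filters, qPCR ranking.

The funnel narrows a gene universe to a small dPCR panel: (i) genes
upregulated in HCC versus non-HCC liver in each of four etiology-based
comparisons (one-sided rank-sum with BH correction plus a median log2
fold-change floor, intersected across etiologies); (ii) keep genes highly
expressed in HCC cell lines; (iii) drop genes highly expressed in immune
cells; (iv) keep genes highly expressed in circulating EVs.  A qPCR screen
(expression proxy 40 − Ct in tumor cells vs white blood cells) ranks the
survivors, and the top-k are combined with a legacy panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import MergedAtlas

__all__ = [
    "SelectionParams",
    "etiology_upregulated",
    "intersect_comparisons",
    "expression_quantile_filter",
    "qpcr_rank",
    "assemble_panel",
    "run_funnel",
]

ETIOLOGIES = ("HBV", "HCV", "ALD", "MASLD")


@dataclass
class SelectionParams:
    """Thresholds of the funnel.  All are configurable analysis choices.

    fdr_q
        BH false-discovery cap for the differential step.
    min_log2fc
        floor on the median log2 difference (HCC − comparison).
    high_expr_quantile / immune_excl_quantile / ev_quantile
        quantiles of per-gene mean expression defining "highly expressed"
        in the cell-line, immune and EV reference matrices.
    top_k
        panel size taken from the qPCR ranking.
    """

    fdr_q: float = 0.05
    min_log2fc: float = 1.0
    high_expr_quantile: float = 0.75
    immune_excl_quantile: float = 0.75
    ev_quantile: float = 0.50
    top_k: int = 6

    def __post_init__(self) -> None:
        for name in ("fdr_q", "high_expr_quantile", "immune_excl_quantile", "ev_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def etiology_upregulated(
    atlas: MergedAtlas, etiology: str, params: SelectionParams
) -> tuple[pd.DataFrame, set[str]]:
    """Genes upregulated in HCC vs non-HCC samples of one etiology.

    Per gene: one-sided Mann–Whitney (HCC greater), BH q-value, median log2
    difference.  A gene passes iff q < fdr_q and the difference >=
    min_log2fc.  Returns (per-gene statistics, passing gene set).
    """
    ann = atlas.annotations
    in_etio = ann["etiology"] == etiology
    hcc_ids = ann.index[in_etio & (ann["state"] == "HCC")]
    ctrl_ids = ann.index[in_etio & (ann["state"] != "HCC")]
    if len(hcc_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError(
            f"etiology {etiology}: need >= 3 HCC and >= 3 comparison samples "
            f"(have {len(hcc_ids)}/{len(ctrl_ids)})"
        )
    hcc = atlas.values[hcc_ids].to_numpy(dtype=float)
    ctrl = atlas.values[ctrl_ids].to_numpy(dtype=float)
    res = stats.mannwhitneyu(hcc, ctrl, alternative="greater", method="asymptotic", axis=1)
    pvals = np.atleast_1d(res.pvalue)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    med_diff = np.median(hcc, axis=1) - np.median(ctrl, axis=1)
    table = pd.DataFrame(
        {
            "statistic": np.atleast_1d(res.statistic),
            "p_value": pvals,
            "q_value": qvals,
            "median_log2_diff": med_diff,
        },
        index=atlas.values.index,
    )
    table["passes"] = (table["q_value"] < params.fdr_q) & (
        table["median_log2_diff"] >= params.min_log2fc
    )
    return table, set(table.index[table["passes"]])


def intersect_comparisons(sets: list[set[str]]) -> set[str]:
    """Genes passing all four etiology comparisons."""
    if len(sets) != 4:
        raise ValueError("expected exactly four comparison gene sets")
    return set.intersection(*map(set, sets))


def expression_quantile_filter(
    genes, matrix: pd.DataFrame, q: float, mode: str
) -> set[str]:
    """Filter genes by mean expression against a quantile of all matrix rows.

    The threshold is the linear-interpolation (type-7) q-quantile of the
    per-row mean expression over *all* rows of ``matrix``.  ``keep_high``
    retains genes with mean >= threshold; ``drop_high`` removes them.
    Genes absent from the matrix fail keep_high and survive drop_high.
    """
    if mode not in {"keep_high", "drop_high"}:
        raise ValueError("mode must be 'keep_high' or 'drop_high'")
    genes = list(genes)
    row_means = matrix.mean(axis=1)
    threshold = float(np.quantile(row_means.to_numpy(dtype=float), q))
    missing = [g for g in genes if g not in row_means.index]
    if missing:
        warnings.warn(f"genes absent from reference matrix: {missing}")
    out = set()
    for g in genes:
        if g not in row_means.index:
            if mode == "drop_high":
                out.add(g)
            continue
        high = row_means[g] >= threshold
        if (mode == "keep_high" and high) or (mode == "drop_high" and not high):
            out.add(g)
    return out


def qpcr_rank(ct: pd.DataFrame) -> list[tuple[str, float]]:
    """Rank genes by qPCR differential between tumor cells and WBCs.

    ``ct`` is gene-indexed with columns ct_hepg2/ct_wbc; NaN means no
    amplification.  Expression proxy e = max(0, 40 − Ct) (absent => 0);
    differential d = e_hepg2 − e_wbc; sorted by d descending, ties by gene
    id ascending.
    """
    if ct.empty:
        raise ValueError("Ct table is empty")
    for col in ("ct_hepg2", "ct_wbc"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col}")
        vals = ct[col]
        if (vals.dropna() <= 0).any():
            raise ValueError(f"non-positive Ct values in {col}")
    e = ct[["ct_hepg2", "ct_wbc"]].apply(lambda c: np.maximum(0.0, 40.0 - c)).fillna(0.0)
    d = e["ct_hepg2"] - e["ct_wbc"]
    ranked = sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(str(g), float(v)) for g, v in ranked]


def assemble_panel(
    ranked: list[tuple[str, float]], params: SelectionParams, legacy: list[str]
) -> list[str]:
    """Top-k ranked genes plus the legacy panel, deduplicated, ranked-first."""
    if params.top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(ranked) < params.top_k:
        raise ValueError(f"ranked list shorter than top_k={params.top_k}")
    panel: list[str] = []
    for g, _ in ranked[: params.top_k]:
        if g not in panel:
            panel.append(g)
    for g in legacy:
        if g not in panel:
            panel.append(g)
    return panel


def run_funnel(
    atlas: MergedAtlas,
    ccle: pd.DataFrame,
    dmap: pd.DataFrame,
    exo: pd.DataFrame,
    params: SelectionParams | None = None,
    etiologies: tuple[str, ...] = ETIOLOGIES,
) -> dict:
    """Chain the four selection steps; returns a per-step audit dict.

    Steps: per-etiology upregulation -> intersection -> keep high in HCC
    cell lines (ccle) -> drop high in immune cells (dmap) -> keep high in
    EVs (exo).  The audit maps step names to the surviving gene sets.
    """
    params = params or SelectionParams()
    per_etiology = {}
    sets = []
    for et in etiologies:
        stats_t, passing = etiology_upregulated(atlas, et, params)
        per_etiology[et] = stats_t
        sets.append(passing)
    upregulated = intersect_comparisons(sets)
    cellline = expression_quantile_filter(upregulated, ccle, params.high_expr_quantile, "keep_high")
    nonimmune = expression_quantile_filter(cellline, dmap, params.immune_excl_quantile, "drop_high")
    ev_high = expression_quantile_filter(nonimmune, exo, params.ev_quantile, "keep_high")
    return {
        "per_etiology_stats": per_etiology,
        "steps": {
            "upregulated_intersection": sorted(upregulated),
            "cellline_high": sorted(cellline),
            "immune_excluded": sorted(nonimmune),
            "ev_high": sorted(ev_high),
        },
        "candidates": sorted(ev_high),
    }
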