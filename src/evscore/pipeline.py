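"""End-to-end study runners chaining the pipeline stages.

``run_pilot_study`` reproduces the pilot design: per-gene group comparison
between HCC and cirrhosis plasma, retention of genes at p < 0.05 (no
multiplicity correction, by design), signal-to-noise weighting, Digital
Scores and a ROC summary.

``run_tr_study`` reproduces the treatment-response design: a seeded
stratified split of paired pre/post patients into training and validation,
weights from the pilot cohort, a logistic TR model fitted on training (or
the frozen published model), the training-derived Youden cutoff applied
unchanged to validation, and LOOCV / k-fold / LASSO stability checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import tr_model as trm
from .evaluation import auroc, confusion_metrics, delong_ci, group_compare, roc_summary
from .scoring import (
    GeneWeights,
    build_score_records,
    compute_weights,
    score_table,
    validate_copy_table,
)

__all__ = ["run_pilot_study", "run_tr_study", "stratified_split"]


def run_pilot_study(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Pilot marker refinement + Digital Score evaluation on HCC vs cirrhosis.

    Returns a report dict with per-gene p-values, the retained gene set,
    the fitted GeneWeights, per-sample scores and the ROC summary.
    """
    validate_copy_table(table)
    ref = table[table["label"].isin(["HCC", "cirrhosis"])]
    mat = ref.pivot(index="sample_id", columns="gene", values="copies")
    labels = ref.drop_duplicates("sample_id").set_index("sample_id")["label"]
    logged = np.log2(mat.fillna(0.0) + 1.0)

    per_gene = {}
    for gene in logged.columns:
        a = logged.loc[labels.reindex(logged.index) == "HCC", gene]
        b = logged.loc[labels.reindex(logged.index) == "cirrhosis", gene]
        _, p = group_compare(a, b)
        per_gene[gene] = p
    retained = sorted(g for g, p in per_gene.items() if p < alpha)
    if len(retained) < 2:
        warnings.warn("fewer than 2 genes retained at p < alpha; proceeding with all genes")
        retained = sorted(per_gene)

    weights = compute_weights(ref, genes=retained)
    scores = score_table(ref, weights)
    y = (labels.reindex(scores.index) == "HCC").to_numpy()
    summary = roc_summary(scores.to_numpy(), y)
    return {
        "per_gene_p": per_gene,
        "retained_genes": retained,
        "weights": weights,
        "scores": scores,
        "roc": summary,
    }


def stratified_split(
    labels: pd.Series, train_frac: float, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded stratified patient split; returns (train_ids, validation_ids)."""
    rng = np.random.default_rng(seed)
    train, valid = [], []
    for cls in sorted(labels.unique()):
        ids = np.array(sorted(labels.index[labels == cls]))
        rng.shuffle(ids)
        n_train = int(round(train_frac * len(ids)))
        train.extend(ids[:n_train])
        valid.extend(ids[n_train:])
    return sorted(train), sorted(valid)


def _set_metrics(records: pd.DataFrame, model: trm.TRModel) -> dict:
    scores = np.array(
        [trm.tr_score(model, r.post_score, r.delta_score) for r in records.itertuples()]
    )
    y = (records["label"] == "viable").to_numpy()
    calls = scores >= model.cutoff
    sens, spec, acc = confusion_metrics(calls, y)
    low, high = delong_ci(scores, y) if y.sum() >= 2 and (~y).sum() >= 2 else (np.nan, np.nan)
    return {
        "auroc": auroc(scores, y),
        "ci_low": low,
        "ci_high": high,
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "n": int(len(y)),
        "n_viable": int(y.sum()),
        "n_nonviable": int((~y).sum()),
    }


def run_tr_study(
    tr_table: pd.DataFrame,
    pilot_table: pd.DataFrame | None = None,
    *,
    weights: GeneWeights | None = None,
    model: str = "fit",
    train_frac: float = 0.49,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Train/validate the TR classifier on a paired pre/post cohort.

    Weights come from ``weights`` or are computed from ``pilot_table``
    (HCC vs cirrhosis).  ``model`` is "fit" (logistic on training) or
    "published" (frozen coefficients and cutoff, no fitting).  The
    training-derived cutoff is applied unchanged to the validation set.
    """
    if weights is None:
        if pilot_table is None:
            raise ValueError("provide pilot_table or precomputed weights")
        weights = compute_weights(pilot_table)
    records = build_score_records(tr_table, weights).dropna(
        subset=["pre_score", "post_score", "delta_score"]
    )
    train_ids, valid_ids = stratified_split(records["label"], train_frac, seed)
    train, valid = records.loc[train_ids], records.loc[valid_ids]

    if model == "published":
        fitted = trm.published_model()
        cv = {}
    elif model == "fit":
        fitted = trm.fit_tr(train)
        cv = {
            "loocv_auroc": trm.loocv_auroc(train),
            "kfold_auroc": trm.kfold_auroc(train, k=k, seed=seed),
        }
        lasso_auc, lam = trm.lasso_auroc(train, seed=seed)
        cv["lasso_auroc"], cv["lasso_penalty"] = lasso_auc, lam
    else:
        raise ValueError("model must be 'fit' or 'published'")

    report = {
        "seed": seed,
        "model": fitted.to_dict(),
        "weights": weights.to_dict(),
        "train": _set_metrics(train, fitted),
        "validation": _set_metrics(valid, fitted),
        "records": records,
        "train_ids": train_ids,
        "validation_ids": valid_ids,
    }
    report.update(cv)
    return report
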