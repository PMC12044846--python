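#!/usr/bin/env python
"""Merge the simulated cohorts into a harmonized atlas and audit the merge.

Quantifies what the MCQ chain buys: the between-dataset share of variance
of null genes before vs after merging, and whether planted marker effects
keep their sign.  Writes results/atlas.tsv (+ annotations) and
results/atlas_audit.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from evscore import merge_mcq
from evscore.io import read_expression_dataset, write_json

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "sim"

truth = json.loads((SIM / "truth.json").read_text())
ids = sorted(p.stem for p in (SIM / "atlas").glob("*.tsv")
             if not p.stem.endswith((".annotations", ".feature_map")) and "." not in p.stem)
datasets = [read_expression_dataset(SIM / "atlas", i) for i in ids]


def between_share(values, prov):
    arr = values.to_numpy(dtype=float)
    groups = np.asarray(prov)
    grand = arr.mean(axis=1, keepdims=True)
    ssb = np.zeros(arr.shape[0])
    sst = ((arr - grand) ** 2).sum(axis=1)
    for g in np.unique(groups):
        sub = arr[:, groups == g]
        ssb += sub.shape[1] * (sub.mean(axis=1) - grand[:, 0]) ** 2
    return ssb / sst


raw = pd.concat(
    [ds.values.rename(columns=lambda c, d=ds.dataset_id: f"{d}:{c}") for ds in datasets], axis=1
)
raw_prov = [c.split(":")[0] for c in raw.columns]

atlas = merge_mcq(datasets)
planted = truth["planted_markers"]
null_genes = [g for g in atlas.genes if g not in planted]
before = between_share(raw.loc[null_genes], raw_prov)
after = between_share(atlas.values.loc[null_genes], atlas.provenance.reindex(atlas.values.columns))

ann = atlas.annotations
hcc = ann.index[ann["state"] == "HCC"]
ctrl = ann.index[ann["state"] != "HCC"]
diffs = (atlas.values.loc[planted, hcc].mean(axis=1)
         - atlas.values.loc[planted, ctrl].mean(axis=1))

atlas.values.rename_axis("gene_id").to_csv(ROOT / "atlas.tsv", sep="\t", float_format="%.8g")
out_ann = ann.copy()
out_ann["dataset_id"] = atlas.provenance
out_ann.rename_axis("sample_id").to_csv(ROOT / "atlas.annotations.tsv", sep="\t")
write_json(
    atlas.audit
    | {
        "null_gene_batch_share_median_before": float(np.median(before)),
        "null_gene_batch_share_median_after": float(np.median(after)),
        "fraction_null_genes_improved": float(np.mean(after < before)),
        "planted_effect_signs_preserved": bool((diffs > 0).all()),
    },
    ROOT / "atlas_audit.json",
)

print(f"merged {len(datasets)} cohorts -> {atlas.values.shape[0]} genes x "
      f"{atlas.values.shape[1]} samples")
print(f"  null-gene batch variance share: median {np.median(before):.3f} -> "
      f"{np.median(after):.3f} (improved for {100*np.mean(after<before):.1f}% of genes)")
print(f"  planted effects keep positive sign after merge: {(diffs > 0).all()} "
      f"(median shift {diffs.median():.2f} log2 units)")
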