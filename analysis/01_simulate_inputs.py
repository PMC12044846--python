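#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/sim/: three expression cohorts with planted
HCC-upregulated markers and batch bias (the atlas input), aux reference
matrices (cell-line / immune / EV stand-ins), a 35+35 pilot dPCR cohort, a
100-patient paired pre/post treatment cohort (67 viable / 33 nonviable),
and a qPCR Ct screen for the funnel survivors, plus the planted truth.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from evscore import SimConfig, gen_dpcr_cohort, gen_multi_cohort_expression, gen_tr_cohort
from evscore.io import write_copy_table, write_expression_dataset, write_json
from evscore.synthetic import gen_funnel_references

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=SEED)
write_json(
    {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()},
    OUT / "config.json",
)

# expression cohorts + aux references
datasets, truth = gen_multi_cohort_expression(cfg)
for ds in datasets:
    write_expression_dataset(ds, OUT / "atlas")
refs = gen_funnel_references(cfg, truth, seed=SEED + 5000)
for name in ("ccle", "dmap", "exo"):
    refs[name].rename_axis("gene_id").to_csv(OUT / f"{name}.tsv", sep="\t", float_format="%.8g")

# qPCR Ct screen: planted markers amplify early in tumor cells, late/never in WBCs
rng = np.random.default_rng(SEED + 6000)
ct_rows = {}
for g in cfg.gene_ids:
    tumor_high = g in refs["tumor_high_genes"]
    ct_rows[g] = {
        "ct_hepg2": rng.normal(22 if tumor_high else 33, 1.0),
        "ct_wbc": np.nan if tumor_high and rng.uniform() < 0.3 else rng.normal(35, 1.5),
    }
pd.DataFrame.from_dict(ct_rows, orient="index").rename_axis("gene_id").to_csv(
    OUT / "ct.tsv", sep="\t", float_format="%.6g"
)

# pilot cohort: the six panel genes elevated in HCC plasma
pilot_effects = {g: 1.0 for g in cfg.panel_genes}
pilot, _ = gen_dpcr_cohort(35, 35, pilot_effects, cfg, seed=SEED + 7000)
write_copy_table(pilot, OUT / "pilot.tsv")

# treatment-response cohort: 2:1 viable:nonviable, 100 patients
tr_table, labels, tr_truth = gen_tr_cohort(67, 33, cfg, seed=SEED + 8000)
write_copy_table(tr_table, OUT / "tr.tsv")

write_json(
    {
        "seed": SEED,
        "planted_markers": list(truth.planted_markers),
        "marker_effect": cfg.marker_effect,
        "pilot_effects": pilot_effects,
        "tr_labels": tr_truth.labels,
        "immune_genes": refs["immune_genes"],
    },
    OUT / "truth.json",
)

print(f"simulated inputs (seed {SEED}) -> {OUT}")
print(f"  atlas: {len(datasets)} cohorts x {cfg.n_genes} genes, "
      f"{datasets[0].values.shape[1]} samples each; planted {len(truth.planted_markers)} markers")
print(f"  pilot: 35 HCC vs 35 cirrhosis; TR cohort: {sum(l=='viable' for l in labels)} viable / "
      f"{sum(l=='nonviable' for l in labels)} nonviable")
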