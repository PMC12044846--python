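"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators emulate (i) a multi-cohort liver expression compendium with
dataset-specific location/scale bias and markers planted upregulated in
HCC, (ii) dPCR absolute gene-copy tables for case/control and paired
pre/post-treatment cohorts, and (iii) spike-in linearity series.  Copy
noise is rounded log-normal; a treated patient's copies are background plus
a residual fraction of a tumor component.  A single integer seed makes
every generator byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .atlas import ExpressionDataset
from .scoring import COPY_TABLE_COLUMNS

__all__ = [
    "DEFAULT_PANEL",
    "SimConfig",
    "SyntheticTruth",
    "gen_multi_cohort_expression",
    "gen_dpcr_cohort",
    "gen_tr_cohort",
    "gen_linearity_series",
    "gen_reference_matrix",
    "gen_funnel_references",
]

#: default dPCR panel (the six liver-lineage genes scored in plasma EVs)
DEFAULT_PANEL = ("ALB", "APOH", "FGB", "FGG", "H2AX", "TF")

_ETIOLOGY_CYCLE = ("HBV", "HCV", "ALD", "MASLD")


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Expression side: ``n_datasets`` cohorts of ``n_genes`` genes, with
    ``n_samples_per_group`` samples per (state, etiology) cell, additive
    dataset shifts ~ N(0, batch_shift_sd) (log2 units) and multiplicative
    scale exp(N(0, batch_scale_sd)); ``planted_markers`` are shifted up by
    ``marker_effect`` log2 units in HCC samples.

    Copy side: log-normal patient-level copies with natural-log location
    ``copy_mu`` and SD ``copy_sigma``; ``tumor_effect`` is the log-scale
    elevation of the tumor component; ``meas_sigma`` is replicate
    measurement noise.  After treatment the tumor component of a nonviable
    patient is multiplied by (1 − response_drop) and of a viable patient by
    ``viable_residual``.  When ``tr_coefficients`` (β0, β_post, β_delta) is
    set, gen_tr_cohort draws labels from that logistic model instead of
    fixing them, so parameter-recovery experiments are well specified.
    """

    seed: int = 0
    n_datasets: int = 3
    n_genes: int = 200
    n_samples_per_group: int = 50
    batch_shift_sd: float = 2.0
    batch_scale_sd: float = 0.15
    planted_markers: tuple[str, ...] | None = None
    marker_effect: float = 2.0
    copy_mu: float = 4.6
    copy_sigma: float = 0.8
    meas_sigma: float = 0.25
    tumor_effect: float = 1.5
    response_drop: float = 0.9
    viable_residual: float = 0.9
    panel_genes: tuple[str, ...] = DEFAULT_PANEL
    tr_coefficients: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("dimensions must be positive")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be >= 0")
        if not 0.0 <= self.response_drop <= 1.0:
            raise ValueError("response_drop must lie in [0, 1]")
        if not 0.0 <= self.viable_residual <= 1.0:
            raise ValueError("viable_residual must lie in [0, 1]")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch SDs must be >= 0")
        if self.planted_markers is None:
            n_plant = min(10, max(0, self.n_genes - 1))
            self.planted_markers = tuple(_gene_ids(self.n_genes)[:n_plant])
        if len(self.planted_markers) >= self.n_genes:
            raise ValueError("need more genes than planted markers")

    @property
    def gene_ids(self) -> list[str]:
        return _gene_ids(self.n_genes)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated artifact."""

    planted_markers: tuple[str, ...] = ()
    effects: dict = field(default_factory=dict)
    tr_coefficients: tuple[float, float, float] | None = None
    generating_weights: dict | None = None
    labels: dict | None = None


def gen_multi_cohort_expression(
    config: SimConfig, seed: int | None = None
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Multi-batch log-normal expression cohorts with planted HCC markers.

    Each dataset carries HCC and nontumor samples for every etiology in the
    {HBV, HCV, ALD, MASLD} cycle; planted markers are shifted up by
    ``marker_effect`` in HCC samples; the whole dataset then receives its
    additive shift and multiplicative scale bias.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.gene_ids
    for g in config.planted_markers:
        if g not in genes:
            raise ValueError(f"planted marker {g} not in the gene universe")
    base_mu = rng.normal(8.0, 1.5, size=config.n_genes)
    marker_mask = np.isin(genes, config.planted_markers)

    datasets = []
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1:02d}"
        shift = rng.normal(0.0, config.batch_shift_sd) if config.batch_shift_sd > 0 else 0.0
        scale = float(np.exp(rng.normal(0.0, config.batch_scale_sd))) if config.batch_scale_sd > 0 else 1.0
        cols, states, etios, blocks = [], [], [], []
        for etiology in _ETIOLOGY_CYCLE:
            for state in ("HCC", "nontumor"):
                n = config.n_samples_per_group
                block = base_mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n))
                if state == "HCC":
                    block[marker_mask, :] += config.marker_effect
                blocks.append(block)
                cols.extend(f"{ds_id}_{etiology}_{state}_{i:03d}" for i in range(n))
                states.extend([state] * n)
                etios.extend([etiology] * n)
        mat = shift + scale * np.concatenate(blocks, axis=1)
        values = pd.DataFrame(mat, index=genes, columns=cols)
        ann = pd.DataFrame({"state": states, "etiology": etios}, index=cols)
        datasets.append(ExpressionDataset(ds_id, values, ann, feature_map=None))

    truth = SyntheticTruth(
        planted_markers=tuple(config.planted_markers),
        effects={g: (config.marker_effect if m else 0.0) for g, m in zip(genes, marker_mask)},
    )
    return datasets, truth


def _draw_copies(rng, mu, sigma, size):
    return np.round(np.exp(rng.normal(mu, sigma, size=size)))


def gen_dpcr_cohort(
    n_case: int,
    n_control: int,
    effects: dict,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Single-timepoint dPCR cohort: cases (HCC) vs controls (cirrhosis).

    copies = round(exp(N(copy_mu + effect·group, copy_sigma))) per gene per
    sample, with group = 1 for cases.  ``effects`` maps gene -> log-scale
    shift (negative allowed).
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(effects)
    rows = []
    for grp, n, label in (("case", n_case, "HCC"), ("ctrl", n_control, "cirrhosis")):
        for i in range(n):
            pid = f"{grp}{i + 1:03d}"
            for g in genes:
                mu = config.copy_mu + (effects[g] if label == "HCC" else 0.0)
                copies = float(_draw_copies(rng, mu, config.copy_sigma, None))
                rows.append((pid, pid, "single", label, g, copies))
    table = pd.DataFrame(rows, columns=COPY_TABLE_COLUMNS)
    truth = SyntheticTruth(effects=dict(effects))
    return table, truth


def gen_tr_cohort(
    n_viable: int,
    n_nonviable: int,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Paired pre/post treatment cohort with viability labels.

    Pre-treatment copies are HCC-like for everyone: background plus a tumor
    component, each log-normal at patient level with measurement noise per
    draw.  Post-treatment the tumor component is multiplied by a residual
    fraction r — ``viable_residual`` for viable patients, 1 − response_drop
    for nonviable ones.

    With ``config.tr_coefficients`` set, r is instead drawn Uniform(0, 1)
    per patient and the label is Bernoulli(logistic(β0 + β_post·post +
    β_delta·Δ)) computed from the patient's Digital Scores under the
    generating weights (all ones); n_viable + n_nonviable then only sets
    the total cohort size.
    """
    if n_viable < 2 or n_nonviable < 2:
        raise ValueError("need >= 2 patients per group")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(config.panel_genes)
    n_total = n_viable + n_nonviable
    model_based = config.tr_coefficients is not None

    if model_based:
        residuals = rng.uniform(0.0, 1.0, size=n_total)
        labels_fixed = None
    else:
        labels_fixed = np.array(["viable"] * n_viable + ["nonviable"] * n_nonviable)
        residuals = np.where(
            labels_fixed == "viable", config.viable_residual, 1.0 - config.response_drop
        )

    rows, labels, post_scores, delta_scores = [], {}, [], []
    for p in range(n_total):
        pid = f"P{p + 1:04d}"
        lb = rng.normal(config.copy_mu, config.copy_sigma, size=len(genes))
        lt = rng.normal(config.copy_mu + config.tumor_effect, config.copy_sigma, size=len(genes))
        eps = rng.normal(0.0, config.meas_sigma, size=(4, len(genes)))
        pre = np.round(np.exp(lb + eps[0]) + np.exp(lt + eps[1]))
        post = np.round(np.exp(lb + eps[2]) + residuals[p] * np.exp(lt + eps[3]))
        g_pre = np.log2(pre + 1.0)
        g_post = np.log2(post + 1.0)
        post_scores.append(g_post.mean())
        delta_scores.append((g_post - g_pre).mean())
        if model_based:
            b0, bp, bd = config.tr_coefficients
            lp = b0 + bp * post_scores[-1] + bd * delta_scores[-1]
            labels[pid] = "viable" if rng.uniform() < expit(lp) else "nonviable"
        else:
            labels[pid] = labels_fixed[p]
        for j, g in enumerate(genes):
            rows.append((f"{pid}_pre", pid, "pre", labels[pid], g, float(pre[j])))
            rows.append((f"{pid}_post", pid, "post", labels[pid], g, float(post[j])))

    table = pd.DataFrame(rows, columns=COPY_TABLE_COLUMNS)
    truth = SyntheticTruth(
        effects={g: config.tumor_effect for g in genes},
        tr_coefficients=config.tr_coefficients,
        generating_weights={g: 1.0 for g in genes} if model_based else None,
        labels=dict(labels),
    )
    return table, pd.Series(labels, name="label"), truth


def gen_linearity_series(
    levels,
    copies_per_unit: dict,
    noise_cv: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Spike-in series: expected copies = copies_per_unit × level per gene.

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (mean-one, so expectations are exact); a zero level always
    yields zero copies.  Needs >= 3 distinct non-negative levels.
    """
    levels = np.asarray(list(levels), dtype=float)
    if (levels < 0).any():
        raise ValueError("levels must be non-negative")
    if len(np.unique(levels)) < 3:
        raise ValueError("need >= 3 distinct levels for a meaningful fit")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = []
    for g, cpu in copies_per_unit.items():
        for lv in levels:
            expected = cpu * lv
            if noise_cv == 0 or expected == 0:
                copies = expected
            else:
                copies = expected * np.exp(rng.normal(-sigma**2 / 2.0, sigma))
            rows.append((float(lv), g, float(copies)))
    return pd.DataFrame(rows, columns=["level", "gene", "copies"])


def gen_reference_matrix(
    genes,
    high_genes,
    seed: int = 0,
    n_samples: int = 20,
    base_mean: float = 6.0,
    high_shift: float = 4.0,
    sd: float = 1.0,
) -> pd.DataFrame:
    """Synthetic stand-in for an auxiliary reference expression matrix.

    Emulates the shape of cell-line / immune / EV compendia used by the
    quantile filters: log2 expression around ``base_mean`` with the listed
    ``high_genes`` elevated by ``high_shift``.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    mat = rng.normal(base_mean, sd, size=(len(genes), n_samples))
    mask = np.isin(genes, list(high_genes))
    mat[mask, :] += high_shift
    return pd.DataFrame(mat, index=genes, columns=[f"ref{i:02d}" for i in range(n_samples)])


def gen_funnel_references(
    config: SimConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
    high_frac: float = 0.20,
    immune_frac: float = 0.30,
) -> dict:
    """Consistent aux stand-ins for the funnel's three reference filters.

    Cell-line and EV matrices carry the planted markers (plus filler genes
    up to ``high_frac`` of the universe) as their highly expressed cluster;
    the immune matrix elevates a disjoint ``immune_frac`` gene set, so
    planted markers are expressed in tumor cells and EVs but not in blood.
    The high cluster sits 4 log2 units above background; ``high_frac``
    stays below and ``immune_frac`` above the filters' default quantile
    tails so the thresholds land between the two expression clusters.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = config.gene_ids
    planted = list(truth.planted_markers)
    others = [g for g in genes if g not in planted]
    n_extra = max(0, int(high_frac * len(genes)) - len(planted))
    extra = list(rng.choice(others, size=n_extra, replace=False))
    remaining = [g for g in others if g not in extra]
    immune = list(
        rng.choice(remaining, size=min(len(remaining), int(immune_frac * len(genes))), replace=False)
    )
    s = int(rng.integers(0, 2**31 - 3))
    return {
        "ccle": gen_reference_matrix(genes, planted + extra, seed=s),
        "dmap": gen_reference_matrix(genes, immune, seed=s + 1),
        "exo": gen_reference_matrix(genes, planted + extra, seed=s + 2),
        "immune_genes": immune,
        "tumor_high_genes": planted + extra,
    }
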