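"""ROC machinery, DeLong inference, Youden cutoffs, power simulation, linearity QC.

The AUROC is the Mann–Whitney pairwise-concordance estimator (ties credit
0.5).  Confidence intervals and paired comparisons use DeLong's structural
components; the power calculation is a Monte-Carlo exercise of the paired
DeLong test under a binormal model with a Gaussian-copula correlation
between the two assays on the same subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCSummary",
    "PowerSpec",
    "LinearityFit",
    "auroc",
    "delong_ci",
    "delong_paired",
    "youden_cutoff",
    "confusion_metrics",
    "accuracy_from_sens_spec",
    "power_paired_auroc",
    "linearity_fit",
    "group_compare",
    "roc_summary",
]


@dataclass
class ROCSummary:
    """AUROC with DeLong CI plus confusion metrics at the Youden cutoff."""

    auroc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_pos: int
    n_neg: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auroc + 1e-12 and self.auroc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the AUROC")

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "flags": list(self.flags),
        }


@dataclass
class PowerSpec:
    """Design of a paired-AUROC power simulation.

    ``auroc_a``/``auroc_b`` are the assumed discriminations of the two
    assays, ``corr`` the within-subject correlation of their scores, and
    ``n_pos``/``n_neg`` the case/control counts per replicate.
    """

    auroc_a: float
    auroc_b: float
    corr: float
    n_pos: int
    n_neg: int
    alpha: float = 0.05
    reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.auroc_a, self.auroc_b):
            if not 0.5 < a < 1.0:
                raise ValueError("assay AUROCs must lie in (0.5, 1)")
        if not 0.0 <= self.corr <= 1.0:
            raise ValueError("corr must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps < 100:
            raise ValueError("reps must be >= 100 for a meaningful power estimate")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 cases and 2 controls")


@dataclass
class LinearityFit:
    """Per-gene ordinary least squares fit of copies on spike-in level."""

    gene: str
    slope: float
    intercept: float
    r_squared: float


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    return y


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: P(pos > neg) + 0.5 P(pos = neg) over all pairs."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus DeLong structural components V10 (cases), V01 (controls)."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_variance(scores, labels) -> float:
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Wald interval on the AUROC scale using the DeLong variance, clipped to [0, 1].

    Perfect separation has zero structural variance; the interval then
    degenerates to (auroc, auroc) and a warning is issued.
    """
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 observations per class for a variance")
    auc = auroc(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0.0:
        warnings.warn("zero DeLong variance (perfect separation); degenerate CI")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired(scores_a, scores_b, labels) -> float:
    """Two-sided p-value of the paired DeLong test for AUROC(a) vs AUROC(b).

    Both score vectors must be measured on the same subjects (same labels).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10a, v01a = _delong_components(a, labels)
    auc_b, v10b, v01b = _delong_components(b, labels)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 observations per class")
    # covariance matrix of (auc_a, auc_b)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0.0:
        if not np.isclose(auc_a, auc_b):
            warnings.warn("zero variance of AUROC difference; p-value set to 1")
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints of adjacent distinct sorted
    scores plus ±inf; a positive call is score >= threshold.  Ties in J are
    broken by higher specificity, then by lower threshold.
    """
    pos, neg = _split(scores, labels)
    distinct = np.unique(np.concatenate([pos, neg]))
    candidates = [-np.inf]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(np.inf)
    best = None
    for t in candidates:
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (j, spec, -t)  # maximize J, then specificity, then prefer lower t
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


def confusion_metrics(calls, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of binary calls against labels."""
    c = _as_binary(calls)
    y = _as_binary(labels)
    if len(c) == 0:
        raise ValueError("empty input")
    if c.shape != y.shape:
        raise ValueError("calls and labels must have the same length")
    tp = int(np.sum(c & y))
    tn = int(np.sum(~c & ~y))
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    acc = (tp + tn) / len(y)
    return float(sens), float(spec), float(acc)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def accuracy_from_sens_spec(sens: float, spec: float, n_pos: int, n_neg: int) -> float:
    """Accuracy implied by reported sensitivity/specificity and group sizes.

    Confusion counts are recovered by half-up rounding: TP = round(sens *
    n_pos), TN = round(spec * n_neg).
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = _round_half_up(sens * n_pos)
    tn = _round_half_up(spec * n_neg)
    return float((tp + tn) / (n_pos + n_neg))


def power_paired_auroc(spec: PowerSpec) -> tuple[float, float]:
    """Monte-Carlo power of the two-sided paired DeLong test.

    Per replicate, case scores for the two assays are bivariate normal with
    unit variances, correlation ``corr``, and per-assay mean shift
    delta = sqrt(2) * Phi^-1(AUROC); controls share the correlation with
    zero means.  Returns (power, binomial Monte-Carlo SE).
    """
    rng = np.random.default_rng(spec.seed)
    d_a = np.sqrt(2.0) * stats.norm.ppf(spec.auroc_a)
    d_b = np.sqrt(2.0) * stats.norm.ppf(spec.auroc_b)
    labels = np.concatenate(
        [np.ones(spec.n_pos, dtype=bool), np.zeros(spec.n_neg, dtype=bool)]
    )
    n_total = spec.n_pos + spec.n_neg
    resid = np.sqrt(max(0.0, 1.0 - spec.corr**2))  # corr=1 stays valid
    rejections = 0
    for _ in range(spec.reps):
        z1 = rng.standard_normal(n_total)
        z2 = spec.corr * z1 + resid * rng.standard_normal(n_total)
        z = np.column_stack([z1, z2])
        z[: spec.n_pos, 0] += d_a
        z[: spec.n_pos, 1] += d_b
        p = delong_paired(z[:, 0], z[:, 1], labels)
        if p < spec.alpha:
            rejections += 1
    power = rejections / spec.reps
    mc_se = float(np.sqrt(power * (1.0 - power) / spec.reps))
    return float(power), mc_se


def linearity_fit(series: pd.DataFrame) -> list[LinearityFit]:
    """OLS of measured copies on spike-in level, per gene.

    ``series`` needs columns (level, gene, copies) with >= 3 distinct
    levels per gene.  R^2 = 1 − SS_res / SS_tot.
    """
    required = {"level", "gene", "copies"}
    if not required.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(required)}")
    fits = []
    for gene, sub in series.groupby("gene", sort=True):
        x = sub["level"].to_numpy(dtype=float)
        y = sub["copies"].to_numpy(dtype=float)
        if len(np.unique(x)) < 3:
            raise ValueError(f"gene {gene}: need >= 3 distinct levels")
        if np.allclose(y.var(), 0.0):
            raise ValueError(f"gene {gene}: zero response variance, R^2 undefined")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        fits.append(
            LinearityFit(
                gene=str(gene),
                slope=float(slope),
                intercept=float(intercept),
                r_squared=1.0 - ss_res / ss_tot,
            )
        )
    return fits


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Mann–Whitney U with normal approximation and tie correction, two-sided."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(1.0, res.pvalue))


def roc_summary(scores, labels, level: float = 0.95) -> ROCSummary:
    """Full ROC report: AUROC, DeLong CI, Youden cutoff and metrics there."""
    pos, neg = _split(scores, labels)
    auc = auroc(scores, labels)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        low, high = delong_ci(scores, labels, level)
    if caught:
        flags.append("degenerate_ci")
    cutoff, sens, spec = youden_cutoff(scores, labels)
    calls = np.asarray(scores, dtype=float) >= cutoff
    _, _, acc = confusion_metrics(calls, labels)
    return ROCSummary(
        auroc=auc,
        ci_low=low,
        ci_high=high,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n_pos=len(pos),
        n_neg=len(neg),
        flags=tuple(flags),
    )
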