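"""Development/validation statistics for the risk models.

Covers the TRIPOD-style evaluation used when the models were built:
a stratified 0.66:0.34 train/test split on the outcome, discrimination via
the AUROC with DeLong confidence intervals, calibration via the
Hosmer–Lemeshow chi-squared test and per-score calibration tables, and
Wilson (proportions) / Koopman (proportion-ratio) confidence intervals for
test-performance measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)


@dataclass
class SplitResult:
    training_ids: list
    testing_ids: list
    ratio: float
    seed: int


@dataclass
class ValidationReport:
    """Discrimination, calibration and optional threshold metrics for one model."""

    model_name: str
    dataset_name: str
    n: int
    auroc: float
    auroc_ci: tuple[float, float]
    hl_stat: float
    hl_df: int
    hl_p: float
    calibration: list[dict] = field(default_factory=list)
    threshold_metrics: dict | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "dataset": self.dataset_name,
            "n": self.n,
            "auroc": self.auroc,
            "ci_low": self.auroc_ci[0],
            "ci_high": self.auroc_ci[1],
            "hl_stat": self.hl_stat,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "calibration": self.calibration,
            "threshold_metrics": self.threshold_metrics,
        }


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    ids,
    outcome,
    ratio: float = 0.66,
    seed: int = 0,
) -> SplitResult:
    """Random train/test partition stratified on a binary outcome.

    Within each outcome stratum, ``round(ratio × n)`` episodes go to
    training.  Strata smaller than 2 go entirely to training with a warning.
    Reproducible under ``seed``.
    """
    ids = np.asarray(ids)
    outcome = np.asarray(outcome)
    if len(ids) != len(outcome):
        raise ValueError("ids and outcome must align")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for level in np.unique(outcome):
        stratum = ids[outcome == level]
        if len(stratum) < 2:
            log.warning("stratum %r has <2 episodes; all assigned to training", level)
            train.extend(stratum.tolist())
            continue
        perm = rng.permutation(len(stratum))
        n_train = int(round(ratio * len(stratum)))
        train.extend(stratum[perm[:n_train]].tolist())
        test.extend(stratum[perm[n_train:]].tolist())
    return SplitResult(training_ids=train, testing_ids=test, ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# AUROC with DeLong confidence interval
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc_delong(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC via the Mann–Whitney construction with a DeLong Wald CI.

    The variance comes from DeLong's structural components (per-case and
    per-control placement values); the CI is truncated to [0, 1].  Raises if
    only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    all_ranks = _midranks(np.concatenate([cases, controls]))
    case_ranks = _midranks(cases)
    control_ranks = _midranks(controls)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values (structural components)
    v10 = (all_ranks[:m] - case_ranks) / n  # per case
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per control
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (max(0.0, float(auc - half)), min(1.0, float(auc + half)))


# ---------------------------------------------------------------------------
# Hosmer–Lemeshow calibration test
# ---------------------------------------------------------------------------

def hosmer_lemeshow(
    predicted,
    observed,
    groups: int = 10,
    group_labels=None,
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow chi-squared goodness-of-fit test.

    Groups are deciles of predicted risk by default (ties at a boundary go
    to the lower group); ``group_labels`` overrides with explicit groups, as
    when grouping an integer score by its values.  Groups whose expected
    count is zero are merged into their neighbour.  The statistic is
    ``Σ (O−E)² / (E(1−E/n_g))`` with df = (final groups) − 2, the reference
    distribution when the probabilities come from a model fitted to the same
    data.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any((predicted <= 0) | (predicted >= 1)):
        raise ValueError("predicted probabilities must lie in (0, 1)")
    if len(predicted) < groups:
        raise ValueError("need at least as many observations as groups")
    if group_labels is not None:
        labels = np.asarray(group_labels)
    else:
        edges = np.quantile(predicted, np.linspace(0, 1, groups + 1)[1:-1])
        labels = np.searchsorted(edges, predicted, side="left")
    # per-group totals
    rows = []
    for g in np.unique(labels):
        mask = labels == g
        rows.append([mask.sum(), observed[mask].sum(), predicted[mask].sum()])
    rows = [r for r in rows if r[0] > 0]
    # merge zero-expected groups into the previous (or next) group
    merged = []
    for r in rows:
        if merged and (r[2] == 0 or merged[-1][2] == 0):
            log.info("merging calibration group with zero expected count")
            merged[-1] = [a + b for a, b in zip(merged[-1], r)]
        else:
            merged.append(r)
    stat = 0.0
    for n_g, o_g, e_g in merged:
        denom = e_g * (1.0 - e_g / n_g)
        if denom <= 0:
            continue
        stat += (o_g - e_g) ** 2 / denom
    df = max(1, len(merged) - 2)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), df, p


# ---------------------------------------------------------------------------
# Calibration tables (per integer score, per dataset)
# ---------------------------------------------------------------------------

def calibration_table(
    scores_by_dataset: dict[str, np.ndarray],
    outcomes_by_dataset: dict[str, np.ndarray],
    predicted_risk_fn,
    max_score: int | None = None,
) -> pd.DataFrame:
    """One row per integer score: predicted risk and observed k/n per dataset.

    ``predicted_risk_fn(score)`` supplies the model risk; predicted risk is
    rounded to 2 dp for presentation.  Empty score groups report n = 0 with a
    blank observed rate.
    """
    if set(scores_by_dataset) != set(outcomes_by_dataset):
        raise ValueError("datasets must match between scores and outcomes")
    if max_score is None:
        max_score = max(int(np.max(s)) for s in scores_by_dataset.values())
    rows = []
    for score in range(max_score + 1):
        row: dict = {"score": score, "predicted_risk": round(predicted_risk_fn(score), 2)}
        for name, s in scores_by_dataset.items():
            s = np.asarray(s)
            y = np.asarray(outcomes_by_dataset[name])
            mask = s == score
            n = int(mask.sum())
            k = int(y[mask].sum())
            row[f"{name}_events"] = k
            row[f"{name}_n"] = n
            row[f"{name}_observed"] = round(k / n, 3) if n else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Confidence intervals for proportions and proportion ratios
# ---------------------------------------------------------------------------

def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def _koopman_stat(theta: float, k1: int, n1: int, k2: int, n2: int) -> float:
    """Score statistic for H0: p1/p2 = theta (constrained-MLE chi-squared)."""
    # constrained MLE of p2 under p1 = theta * p2 (Koopman 1984, closed form)
    a = theta * (n1 + n2)
    b = -(theta * (n1 + k2) + k1 + n2)
    c = k1 + k2
    disc = max(b * b - 4 * a * c, 0.0)
    p2 = (-b - np.sqrt(disc)) / (2 * a)
    p2 = min(max(p2, 1e-12), 1 - 1e-12)
    p1 = min(theta * p2, 1 - 1e-12)
    stat = 0.0
    stat += (k1 - n1 * p1) ** 2 / (n1 * p1 * (1 - p1))
    stat += (k2 - n2 * p2) ** 2 / (n2 * p2 * (1 - p2))
    return stat


def koopman_ci(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Koopman chi-squared-inversion CI for the ratio p1/p2 of two proportions.

    The interval is the set of ratios whose score statistic stays below the
    chi-squared(1) critical value.  ``k1 = 0`` gives a lower bound of 0;
    ``k2 = 0`` gives an open upper bound (``inf``).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n < 1:
            raise ValueError("need 0 <= k <= n and n >= 1 for both samples")
    crit = stats.chi2.ppf(1 - alpha, 1)
    f = lambda theta: _koopman_stat(theta, k1, n1, k2, n2) - crit

    if k2 == 0:
        upper = np.inf
    else:
        ratio = (k1 / n1) / (k2 / n2) if k1 > 0 else 0.0
        hi = max(ratio, 1e-6) * 2 + 1.0
        while f(hi) < 0 and hi < 1e12:
            hi *= 10
        upper = float(optimize.brentq(f, max(ratio, 1e-9), hi)) if hi < 1e12 else np.inf
    if k1 == 0:
        lower = 0.0
    else:
        ratio = (k1 / n1) / (k2 / n2) if k2 > 0 else np.inf
        anchor = ratio if np.isfinite(ratio) else 1e6
        lo = anchor / 2
        while f(lo) < 0 and lo > 1e-12:
            lo /= 10
        lower = float(optimize.brentq(f, lo, anchor)) if lo > 1e-12 else 0.0
    return lower, upper


def threshold_metrics(
    scores, labels, cutoff: float, alpha: float = 0.05
) -> dict:
    """Sensitivity/specificity/predictive values (Wilson CIs) and likelihood
    ratios (Koopman CIs) at ``score >= cutoff``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores >= cutoff
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    tn = int(np.sum(~pos & (labels == 0)))
    out = {"cutoff": cutoff, "tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def prop(name, k, n):
        if n:
            out[name] = k / n
            out[f"{name}_ci"] = wilson_ci(k, n, alpha)
        else:
            out[name] = None
            out[f"{name}_ci"] = None

    prop("sensitivity", tp, tp + fn)
    prop("specificity", tn, tn + fp)
    prop("ppv", tp, tp + fp)
    prop("npv", tn, tn + fn)
    # LR+ = (tp/(tp+fn)) / (fp/(fp+tn)); LR- = (fn/(tp+fn)) / (tn/(fp+tn))
    if tp + fn and fp + tn:
        out["lr_pos"] = (tp / (tp + fn)) / (fp / (fp + tn)) if fp else np.inf
        out["lr_pos_ci"] = koopman_ci(tp, tp + fn, fp, fp + tn, alpha)
        out["lr_neg"] = (fn / (tp + fn)) / (tn / (fp + tn)) if tn else np.inf
        out["lr_neg_ci"] = koopman_ci(fn, tp + fn, tn, fp + tn, alpha)
    return out
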