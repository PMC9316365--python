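"""Classification and evaluation of interface likelihoods.

Likelihoods become binary calls through a *dynamic cutoff*: for each query
protein the N top-ranked residues are called interfacial, with

    N = round(6.1 * R**0.3)

where R is the protein's surface-exposed residue count (an empirical rule
tracing back to template-based interface prediction).  Single-threshold
quality is summarized by precision, recall, F-score and the Matthews
correlation coefficient; threshold-free quality by ROC and precision-recall
curves with trapezoidal AUC.  Because interfaces are rare (typically 10-20%
of residues), PR curves are the more informative of the two.

Kolmogorov–Smirnov helpers support the distributional comparisons used when
reporting per-protein F-scores: a one-sample test against a normal reference
(F-scores are generally not normal) and a two-sample test between methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .table import ScoreTable

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "Curve",
    "dynamic_cutoff",
    "classify_top_n",
    "confusion",
    "metrics",
    "roc_pr_curves",
    "ks_one_sample",
    "ks_two_sample",
    "auc_difference_test",
    "evaluate_model",
    "EvaluationReport",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricSet:
    precision: float
    recall: float
    fscore: float
    mcc: float
    #: metrics whose denominator was zero and were defined 0 by convention
    undefined: tuple[str, ...] = ()


@dataclass
class Curve:
    """An ROC or PR curve: ordered points plus their trapezoidal AUC."""

    kind: str  # "ROC" | "PR"
    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        names = {"ROC": ("fpr", "tpr"), "PR": ("recall", "precision")}[self.kind]
        thr = self.thresholds
        if len(thr) < len(self.x):  # leading anchor point has no threshold
            thr = np.concatenate([[np.nan] * (len(self.x) - len(thr)), thr])
        return pd.DataFrame({names[0]: self.x, names[1]: self.y, "threshold": thr})


def dynamic_cutoff(R: int, mode: str = "round") -> int:
    """Number of residues to call positive for a protein with R
    surface-exposed residues: N = 6.1 * R**0.3, rounded (half-up by
    default; ``mode`` in {"round", "floor", "ceil"}), floored at 1."""
    if R <= 0:
        raise ValueError("R must be a positive integer")
    raw = 6.1 * R ** 0.3
    if mode == "round":
        n = math.floor(raw + 0.5)
    elif mode == "floor":
        n = math.floor(raw)
    elif mode == "ceil":
        n = math.ceil(raw)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return max(1, n)


def classify_top_n(scores: Sequence[float], N: int) -> np.ndarray:
    """Call the N highest-scoring residues positive.

    Exactly ``min(N, len(scores))`` calls are positive; ties at rank N are
    broken by position in the input (earlier rows win), which makes the
    classification deterministic.
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    scores = np.asarray(scores, dtype=float)
    calls = np.zeros(len(scores), dtype=int)
    k = min(N, len(scores))
    if k:
        order = np.argsort(-scores, kind="stable")  # stable: input order on ties
        calls[order[:k]] = 1
    return calls


def confusion(calls: Sequence[int], labels: Sequence[int]) -> ConfusionCounts:
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    for name, v in (("calls", calls), ("labels", labels)):
        if not np.isin(v, [0, 1]).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((calls == 1) & (labels == 1))),
        FP=int(np.sum((calls == 1) & (labels == 0))),
        FN=int(np.sum((calls == 0) & (labels == 1))),
        TN=int(np.sum((calls == 0) & (labels == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Precision, recall, F-score and MCC from a confusion matrix.

    Any metric with a zero denominator is defined as 0 and flagged in
    ``undefined`` so that averages over proteins remain well defined.
    """
    TP, FP, FN, TN = counts.TP, counts.FP, counts.FN, counts.TN
    undefined: list[str] = []

    if TP + FP == 0:
        precision, und_p = 0.0, True
    else:
        precision, und_p = TP / (TP + FP), False
    if und_p:
        undefined.append("precision")

    if TP + FN == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = TP / (TP + FN)

    if precision + recall == 0:
        fscore = 0.0
        undefined.append("fscore")
    else:
        fscore = 2 * precision * recall / (precision + recall)

    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom == 0:
        mcc = 0.0
        undefined.append("mcc")
    else:
        mcc = (TP * TN - FP * FN) / math.sqrt(denom)

    return MetricSet(precision, recall, fscore, mcc, tuple(undefined))


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP over distinct score thresholds, high to low."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep the last index of each run of equal scores: one point per distinct threshold
    distinct = np.r_[s[1:] != s[:-1], True]
    return s[distinct], tp[distinct], fp[distinct]


def roc_pr_curves(
    scores: Sequence[float],
    labels: Sequence[int],
    pooling: str = "pooled",
    groups: Sequence[str] | None = None,
) -> tuple[Curve, Curve]:
    """ROC and PR curves from a threshold sweep over all distinct scores.

    ``pooling="pooled"`` (default) treats the inputs as one concatenated set;
    ``"per_protein"`` averages the per-protein curves on a common recall/FPR
    grid (``groups`` required).  AUC is the trapezoidal integral of the
    stored points; the PR curve is anchored at recall 0 with the precision of
    its first point and is not otherwise interpolated.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if pooling == "per_protein":
        if groups is None:
            raise ValueError("per_protein pooling requires groups")
        groups = np.asarray(groups)
        grid = np.linspace(0, 1, 101)
        roc_ys, pr_ys = [], []
        for g in dict.fromkeys(groups):
            m = groups == g
            if labels[m].min() == labels[m].max():
                continue
            roc, pr = roc_pr_curves(scores[m], labels[m], "pooled")
            roc_ys.append(np.interp(grid, roc.x, roc.y))
            pr_ys.append(np.interp(grid, pr.x, pr.y))
        if not roc_ys:
            raise ValueError("no protein with both classes present")
        roc_y = np.mean(roc_ys, axis=0)
        pr_y = np.mean(pr_ys, axis=0)
        roc = Curve("ROC", grid, roc_y, np.array([]), float(np.trapezoid(roc_y, grid)))
        pr = Curve("PR", grid, pr_y, np.array([]), float(np.trapezoid(pr_y, grid)))
        return roc, pr

    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw curves")

    thr, tp, fp = _sweep(scores, labels)
    tpr = tp / n_pos
    fpr = fp / n_neg
    roc_x = np.r_[0.0, fpr]
    roc_y = np.r_[0.0, tpr]
    roc = Curve("ROC", roc_x, roc_y, thr, float(np.trapezoid(roc_y, roc_x)))

    precision = tp / (tp + fp)
    recall = tpr
    pr_x = np.r_[0.0, recall]
    pr_y = np.r_[precision[0], precision]
    # integrate along ascending recall
    pr = Curve("PR", pr_x, pr_y, thr, float(np.trapezoid(pr_y, pr_x)))
    return roc, pr


def ks_one_sample(
    values: Sequence[float],
    mean: float | None = None,
    sd: float | None = None,
    lilliefors: bool = False,
) -> tuple[float, float]:
    """One-sample KS test of ``values`` against a normal reference.

    With ``mean``/``sd`` given, the reference is that exact normal and the
    classical KS p-value is valid.  When they are estimated from the sample
    (the default) the classical p-value is conservative — set
    ``lilliefors=True`` for the correction appropriate to estimated
    parameters.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("one-sample KS needs n >= 5")
    if values.min() == values.max():
        raise ValueError("constant sample has no distribution to test")
    if lilliefors:
        if mean is not None or sd is not None:
            raise ValueError("lilliefors correction estimates mean/sd itself")
        from statsmodels.stats.diagnostic import lilliefors as _lf

        D, p = _lf(values, dist="norm")
        return float(D), float(p)
    m = values.mean() if mean is None else mean
    s = values.std(ddof=1) if sd is None else sd
    res = stats.kstest(values, "norm", args=(m, s))
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| with asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("two-sample KS needs n >= 3 in each sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def auc_difference_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    groups: Sequence[str],
    reps: int = 1000,
    seed: int = 0,
    kind: str = "ROC",
) -> tuple[float, float]:
    """Paired bootstrap test for a difference in pooled AUC between two
    scorers evaluated on the same residues.

    Proteins (``groups``) are resampled with replacement; the p-value is the
    two-sided fraction of bootstrap replicates whose AUC difference crosses
    zero.  Deterministic given ``seed``.
    """
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    idx = 1 if kind == "PR" else 0

    def _auc(mask: np.ndarray, scores: np.ndarray) -> float:
        return roc_pr_curves(scores[mask], labels[mask], "pooled")[idx].auc

    all_mask = np.ones(len(labels), bool)
    delta = _auc(all_mask, scores_a) - _auc(all_mask, scores_b)

    ids = list(dict.fromkeys(groups))
    rows = {g: np.flatnonzero(groups == g) for g in ids}
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(reps):
        pick = rng.choice(len(ids), size=len(ids), replace=True)
        take = np.concatenate([rows[ids[i]] for i in pick])
        ys = labels[take]
        if ys.min() == ys.max():
            continue
        a = roc_pr_curves(scores_a[take], ys, "pooled")[idx].auc
        b = roc_pr_curves(scores_b[take], ys, "pooled")[idx].auc
        boot.append(a - b)
    boot = np.asarray(boot)
    if len(boot) == 0:
        raise ValueError("bootstrap produced no valid replicate")
    p = 2 * min(np.mean(boot <= 0), np.mean(boot >= 0))
    return float(delta), float(min(1.0, p))


@dataclass
class EvaluationReport:
    """Per-protein single-threshold metrics plus pooled curves for one scorer."""

    per_protein: pd.DataFrame
    averages: dict[str, float]
    roc: Curve
    pr: Curve


def evaluate_model(
    table: ScoreTable,
    score_column: str,
    surface_counts: Mapping[str, int],
    rounding: str = "round",
) -> EvaluationReport:
    """Evaluate one likelihood column against the table's labels.

    Per protein: N = dynamic_cutoff(R), the N top-scoring residues are
    called positive, and precision/recall/F/MCC are computed; the summary
    averages the per-protein metrics unweighted.  Curves pool residues
    across all proteins.
    """
    if score_column not in table.frame.columns:
        raise ValueError(f"no score column {score_column!r} in table")
    y_all = table.y()
    rows = []
    for pid, part in table.frame.groupby("protein_id", sort=False):
        if pid not in surface_counts:
            raise ValueError(f"protein {pid!r} missing a surface residue count R")
        R = int(surface_counts[pid])
        N = dynamic_cutoff(R, rounding)
        calls = classify_top_n(part[score_column].to_numpy(), N)
        m = metrics(confusion(calls, part["label"].to_numpy().astype(int)))
        rows.append(
            {
                "protein_id": pid,
                "n_residues": len(part),
                "R": R,
                "N": N,
                "precision": m.precision,
                "recall": m.recall,
                "fscore": m.fscore,
                "mcc": m.mcc,
                "undefined": ";".join(m.undefined),
            }
        )
    per_protein = pd.DataFrame(rows)
    averages = {
        k: float(per_protein[k].mean()) for k in ("precision", "recall", "fscore", "mcc")
    }
    roc, pr = roc_pr_curves(table.frame[score_column].to_numpy(), y_all, "pooled")
    averages["roc_auc"] = roc.auc
    averages["pr_auc"] = pr.auc
    return EvaluationReport(per_protein, averages, roc, pr)
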