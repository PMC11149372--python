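"""Evaluation metrics and disparity-detection/mitigation statistics.

Per-model metrics: AUROC, AUPR, Tjur's R^2 (coefficient of discrimination),
Youden-index threshold with the derived sensitivity/specificity/PPV/NPV,
and prevalence-adjusted predictive values.

Cross-experiment statistics over replicate runs: the disparity gap
G = mean AUROC_EUR - mean AUROC_DDP, transfer-learning improvements I over
the Mix2/Ind2/NT baselines, the DL-vs-LR transfer difference D, with
one-sided Wilcoxon rank-sum p-values across runs (exact enumeration for
small run counts, normal approximation with tie correction otherwise) and
one-sided signed-rank tests across matched dataset/run pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    tjur_r2: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    adjusted_ppv: float | None = None
    adjusted_npv: float | None = None
    prevalence: float | None = None


@dataclass
class DisparitySummary:
    """Run-mean AUROC differences with one-sided Wilcoxon p-values."""

    G: dict[str, float]
    I: dict[str, float]
    D: float | None
    p_values: dict[str, float]


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return y


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random case outscores a random control; ties count 1/2."""
    y = _check_two_class(labels)
    return float(roc_auc_score(y, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration."""
    y = _check_two_class(labels)
    return float(average_precision_score(y, scores))


def tjur_r2(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean predicted probability among cases minus mean among controls."""
    y = _check_two_class(labels)
    p = np.asarray(probabilities, dtype=float)
    return float(p[y == 1].mean() - p[y == 0].mean())


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the observed scores; a point is called positive when its
    score is >= the threshold. Ties on J break toward the lowest threshold.
    Returns (threshold, sensitivity, specificity).
    """
    y = _check_two_class(labels)
    s = np.asarray(scores, dtype=float)
    cand = np.unique(s)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    # vectorized scan: for each candidate t, sens = P(s>=t | case)
    sens = np.array([(s[y == 1] >= t).sum() for t in cand]) / n_pos
    spec = np.array([(s[y == 0] < t).sum() for t in cand]) / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) candidate on ties
    return float(cand[best]), float(sens[best]), float(spec[best])


def confusion_ppv_npv(scores, labels, threshold: float) -> tuple[float, float]:
    """Raw predictive values at a threshold (positive when score >= thr)."""
    y = np.asarray(labels)
    pred = np.asarray(scores) >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return ppv, npv


def adjusted_ppv_npv(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Predictive values recomputed at a population prevalence.

    PPV = sens*prev / (sens*prev + (1-spec)(1-prev));
    NPV = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev).
    Undefined denominators yield NaN.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    d1 = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    d2 = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / d1 if d1 > 0 else float("nan")
    npv = specificity * (1 - prevalence) / d2 if d2 > 0 else float("nan")
    return ppv, npv


def metric_report(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    prevalence: float | None = None,
) -> MetricReport:
    """All per-model metrics in one pass.

    ``threshold`` lets the caller supply a Youden threshold tuned on another
    split (validation by default in the schemes); when None it is tuned on
    the scored data itself.
    """
    if threshold is None:
        thr, sens, spec = youden_threshold(scores, labels)
    else:
        thr = threshold
        y = np.asarray(labels)
        s = np.asarray(scores)
        sens = float((s[y == 1] >= thr).mean())
        spec = float((s[y == 0] < thr).mean())
    ppv, npv = confusion_ppv_npv(scores, labels, thr)
    adj_ppv = adj_npv = None
    if prevalence is not None:
        adj_ppv, adj_npv = adjusted_ppv_npv(sens, spec, prevalence)
    return MetricReport(
        auroc=auroc(scores, labels),
        aupr=aupr(scores, labels),
        tjur_r2=tjur_r2(scores, labels),
        youden_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        adjusted_ppv=adj_ppv,
        adjusted_npv=adj_npv,
        prevalence=prevalence,
    )


# ---------------------------------------------------------------------------
# Wilcoxon tests across runs


def rank_sum_test(x: np.ndarray, y: np.ndarray, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value for x vs y.

    Exact enumeration of all label assignments when both groups have <= 12
    observations; otherwise the normal approximation with tie correction
    (scipy's Mann-Whitney U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= 12 and len(y) <= 12:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[: len(x)].sum()
        n = len(pooled)
        count = 0
        total = 0
        for idx in combinations(range(n), len(x)):
            w = ranks[list(idx)].sum()
            if alternative == "greater":
                count += w >= obs - 1e-9
            else:
                count += w <= obs + 1e-9
            total += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def signed_rank_test(diff: np.ndarray, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank test on matched differences."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    mode = "exact" if diff.size <= 25 else "approx"
    return float(stats.wilcoxon(diff, alternative=alternative, mode=mode).pvalue)


def sign_test(diff: np.ndarray, alternative: str = "greater") -> float:
    """One-sided exact sign test on matched differences (zeros discarded)."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    k = int((diff > 0).sum()) if alternative == "greater" else int((diff < 0).sum())
    return float(stats.binomtest(k, diff.size, 0.5, alternative="greater").pvalue)


def disparity_stats(
    auroc_by_experiment: dict[str, np.ndarray],
) -> DisparitySummary:
    """G / I / D statistics from per-run AUROC vectors keyed by experiment.

    Expected keys follow the "<experiment>_<model>" convention, e.g.
    "Mix1_LR", "Ind2_DL", "TL_DL", "NT_LR". Only the comparisons whose
    operands are present are computed.
    """
    a = {k: np.asarray(v, dtype=float) for k, v in auroc_by_experiment.items()}

    def mean_diff(hi: str, lo: str) -> float | None:
        if hi in a and lo in a:
            return float(a[hi].mean() - a[lo].mean())
        return None

    G, I, p = {}, {}, {}
    for model in ("LR", "DL"):
        for scheme, eur, ddp in (
            (f"Mix_{model}", f"Mix1_{model}", f"Mix2_{model}"),
            (f"Ind_{model}", f"Ind1_{model}", f"Ind2_{model}"),
        ):
            d = mean_diff(eur, ddp)
            if d is not None:
                G[scheme] = d
                p[f"G_{scheme}"] = rank_sum_test(a[eur], a[ddp])
        for base in ("Mix2", "Ind2", "NT"):
            d = mean_diff(f"TL_{model}", f"{base}_{model}")
            if d is not None:
                key = f"{base}_{model}"
                I[key] = d
                p[f"I_{key}"] = rank_sum_test(a[f"TL_{model}"], a[key])
    D = mean_diff("TL_DL", "TL_LR")
    if D is not None:
        p["D"] = rank_sum_test(a["TL_DL"], a["TL_LR"])
    return DisparitySummary(G=G, I=I, D=D, p_values=p)
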