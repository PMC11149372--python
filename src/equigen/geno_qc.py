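"""Genotype quality control, LD pruning and association-based feature selection.

Operates on additively coded dosage matrices (0/1/2, NaN = missing).
Filters mirror standard GWAS practice: drop SNPs by missing rate, minor
allele frequency and a Hardy–Weinberg exact test; drop samples by per-row
missing rate; prune linkage disequilibrium with a sliding window of squared
Pearson correlations; rank surviving SNPs by one-way ANOVA F between cases
and controls and keep the top K.

All statistics that use labels are meant to be computed on the training
split only; the callers enforce that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif


@dataclass
class SnpQCReport:
    """Per-SNP QC statistics and keep/drop verdicts."""

    missing_rate: np.ndarray
    maf: np.ndarray
    hwe_p: np.ndarray
    kept: np.ndarray
    reason: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "missing_rate": self.missing_rate,
                "maf": self.maf,
                "hwe_p": self.hwe_p,
                "kept": self.kept,
                "reason": self.reason,
            }
        )


@dataclass
class FeatureRanking:
    """ANOVA-F association ranking with a top-K selection mask."""

    f_values: np.ndarray
    p_values: np.ndarray
    rank_order: np.ndarray  # SNP indices, best first
    selected: np.ndarray  # boolean mask over SNPs


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg p-value (mid-less two-sided, Wigginton-style).

    Enumerates the conditional distribution of heterozygote counts given the
    observed allele counts and sums the probabilities of all configurations
    no more likely than the observed one.
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure "minor" really is minor
        n_minor = 2 * n - n_minor
    # heterozygote count shares parity with the minor-allele count
    het_min = n_minor % 2
    probs: dict[int, float] = {}
    # unnormalized probabilities by the standard two-way recurrence,
    # starting from the (approximate) modal heterozygote count
    mid = int(round(n_minor * (2 * n - n_minor) / (2.0 * n)))
    if mid % 2 != het_min:
        mid += 1
    mid = min(mid, n_minor)
    probs[mid] = 1.0
    cur = 1.0
    for h in range(mid, het_min, -2):
        hom_r = (n_minor - h) // 2
        hom_c = n - h - hom_r
        cur *= h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[h - 2] = cur
    cur = 1.0
    for h in range(mid, n_minor - 1, 2):
        hom_r = (n_minor - h) // 2
        hom_c = n - h - hom_r
        cur *= 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = cur
    total = sum(probs.values())
    obs = n_het if n_het in probs else min(probs, key=lambda k: abs(k - n_het))
    p_obs = probs[obs]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / total)


def hwe_chi2_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-degree-of-freedom chi-square HWE test (fallback flavor)."""
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    q = (2 * n_hom_minor + n_het) / (2.0 * n)
    exp = np.array([n * q * q, 2 * n * q * (1 - q), n * (1 - q) ** 2])
    obs = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    nz = exp > 0
    chi2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    X: np.ndarray,
    missing_max: float = 0.20,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    exact_hwe: bool = True,
    y: np.ndarray | None = None,
    hwe_controls_only: bool = False,
) -> SnpQCReport:
    """Flag SNPs failing missing-rate, MAF or HWE thresholds.

    Drop rules (any one suffices): missing rate > missing_max,
    MAF < maf_min, HWE p < hwe_p_min. A SNP with all entries missing is
    dropped with reason "all_missing". HWE is computed on the full sample
    by default; ``hwe_controls_only`` restricts it to y == 0 individuals
    (disease-associated loci can be out of equilibrium among cases).
    """
    X = np.asarray(X, dtype=float)
    X_hwe = X
    if hwe_controls_only:
        if y is None:
            raise ValueError("hwe_controls_only requires labels y")
        X_hwe = X[np.asarray(y) == 0]
    n, m = X.shape
    missing = np.isnan(X)
    miss_rate = missing.mean(axis=0)
    maf = np.empty(m)
    hwe_p = np.empty(m)
    kept = np.ones(m, dtype=bool)
    reason = [""] * m
    test = hwe_exact_test if exact_hwe else hwe_chi2_test
    for j in range(m):
        col = X[~missing[:, j], j]
        if col.size == 0:
            maf[j] = np.nan
            hwe_p[j] = np.nan
            kept[j] = False
            reason[j] = "all_missing"
            continue
        freq = col.sum() / (2.0 * col.size)
        maf[j] = min(freq, 1.0 - freq)
        hcol = X_hwe[~np.isnan(X_hwe[:, j]), j]
        n2 = int((hcol == 2).sum())
        n1 = int((hcol == 1).sum())
        n0 = int((hcol == 0).sum())
        if freq <= 0.5:
            hwe_p[j] = test(n2, n1, n0)
        else:
            hwe_p[j] = test(n0, n1, n2)
        if miss_rate[j] > missing_max:
            kept[j] = False
            reason[j] = "missing_rate"
        elif maf[j] < maf_min:
            kept[j] = False
            reason[j] = "maf"
        elif hwe_p[j] < hwe_p_min:
            kept[j] = False
            reason[j] = "hwe"
    return SnpQCReport(miss_rate, maf, hwe_p, kept, reason)


def sample_filter(X: np.ndarray, missing_max: float = 0.20) -> np.ndarray:
    """Keep individuals whose per-row missing fraction is <= missing_max."""
    X = np.asarray(X, dtype=float)
    keep = np.isnan(X).mean(axis=1) <= missing_max
    if not keep.any():
        raise ValueError("sample filter removed every individual")
    return keep


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    X: np.ndarray,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
    p_values: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns a kept-SNP boolean mask.

    Within each window position, pairs with r^2 > r2_max are scanned in
    (i < j) index order; the member with the higher association p-value is
    dropped (the later-indexed one when no p-values are supplied), and the
    scan restarts until the window is clean.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    kept = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = [j for j in range(start, min(start + window, m)) if kept[j]]
        dirty = True
        while dirty:
            dirty = False
            for a in range(len(idx)):
                i = idx[a]
                if not kept[i]:
                    continue
                for b in range(a + 1, len(idx)):
                    j = idx[b]
                    if not kept[j]:
                        continue
                    if _pairwise_r2(X[:, i], X[:, j]) > r2_max:
                        if p_values is not None and p_values[i] > p_values[j]:
                            kept[i] = False
                        else:
                            kept[j] = False
                        dirty = True
                        break
                if dirty:
                    break
            idx = [j for j in idx if kept[j]]
        if start + window >= m:
            break
    return kept


def rank_and_select(X_train: np.ndarray, y_train: np.ndarray, K: int) -> FeatureRanking:
    """Rank SNPs by one-way ANOVA F between cases and controls; keep top K.

    Constant columns get F = 0 (rank last); ties break toward the lower
    column index. Missing dosages are mean-imputed per column for the F
    computation only.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X = X.copy()
        X[inds] = np.take(col_mean, inds[1])
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        f, p = f_classif(X, y)
    f = np.where(np.isnan(f), 0.0, f)  # constant columns: F undefined -> 0
    p = np.where(np.isnan(p), 1.0, p)
    order = np.lexsort((np.arange(len(f)), -f))
    selected = np.zeros(len(f), dtype=bool)
    selected[order[: min(K, len(f))]] = True
    return FeatureRanking(f_values=f, p_values=p, rank_order=order, selected=selected)
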