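"""Nonparametric group comparison of lipid features.

The testing chain mirrors common MALDI profiling practice: a
Kolmogorov-Smirnov normality gate motivates rank tests; two-condition
contrasts use the Wilcoxon rank-sum (Mann-Whitney U) test, multi-condition
contrasts the Kruskal-Wallis test; fold changes are ratios of group means of
normalized intensities; hierarchical clustering uses Spearman correlation
distance and PCA a centered SVD.  Raw p-values drive the significance rule
(p < alpha and symmetric fold change > threshold); Benjamini-Hochberg
adjusted p-values are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureMatrix

__all__ = [
    "DifferentialConfig",
    "ks_normality",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fold_change",
    "differential_features",
    "spearman_hclust",
    "pca_scores",
]


@dataclass(frozen=True)
class DifferentialConfig:
    alpha: float = 0.05
    fc_threshold: float = 2.0
    fc_pseudocount: float | None = None  # None -> half the smallest nonzero value
    use_fc_rule: bool = True
    report_bh: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")


def ks_normality(values: Sequence[float]) -> float:
    """One-sample Kolmogorov-Smirnov p against a normal with sample moments.

    Constant input returns 0 by convention (a point mass is maximally
    non-normal for this gate) with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant input: returning p = 0 by convention", stacklevel=2)
        return 0.0
    res = sps.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return float(res.pvalue)


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p).

    ``auto`` uses the exact U distribution when n_a + n_b <= 12 and the data
    are tie-free, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _kw_statistic(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start: start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else float("nan")


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its p-value.

    ``asymptotic`` takes p from chi-squared with k - 1 degrees of freedom;
    ``exact`` enumerates all assignments of the pooled observations to the
    group sizes (intended for total n <= ~10) and reports
    P(H >= H_observed).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    h_obs = _kw_statistic(gs)
    if method == "asymptotic":
        p = float(sps.chi2.sf(h_obs, df=len(gs) - 1))
        # identical groups give H = 0 -> p = 1 (sf(0) = 1), consistent
        return float(h_obs), min(p, 1.0)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]
    n = pooled.size
    idx_all = frozenset(range(n))

    count_ge = 0
    total = 0

    def recurse(remaining: frozenset, gi: int, chosen: list[np.ndarray]) -> None:
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            last = pooled[sorted(remaining)]
            h = _kw_statistic(chosen + [last])
            total += 1
            if h >= h_obs - 1e-12:
                count_ge += 1
            return
        for comb in combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - set(comb), gi + 1, chosen + [pooled[list(comb)]])

    recurse(idx_all, 0, [])
    return float(h_obs), count_ge / total


def fold_change(
    mean_a: float, mean_b: float, pseudocount: float = 0.0
) -> float:
    """Ratio (mean_a + c) / (mean_b + c) of group means."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = mean_b + pseudocount
    if denom == 0:
        raise ValueError("fold change undefined: zero denominator and no pseudocount")
    return (mean_a + pseudocount) / denom


def _average_replicates(fm: FeatureMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Average technical replicates per biological sample (if mapped)."""
    if "bio_sample" not in fm.samples.columns:
        return fm.values, fm.samples
    meta = fm.samples.groupby("bio_sample", sort=False).first().reset_index()
    rows = []
    for bio in meta["bio_sample"]:
        ix = np.flatnonzero(fm.samples["bio_sample"] == bio)
        rows.append(fm.values[ix].mean(axis=0))
    meta["sample_id"] = meta["bio_sample"].astype(str)
    return np.vstack(rows), meta


def differential_features(
    fm: FeatureMatrix,
    contrast: str = "group",
    cfg: DifferentialConfig = DifferentialConfig(),
) -> pd.DataFrame:
    """Per-feature rank test + fold change + significance call.

    Two groups use the Wilcoxon rank-sum test, more use Kruskal-Wallis.
    Technical replicates (shared ``bio_sample``) are averaged before testing.
    The fold change is the ratio of group means (first group over second, in
    metadata order) with a pseudocount of half the smallest nonzero matrix
    value unless configured; significance requires raw p < alpha and, when
    the rule is enabled, max(FC, 1/FC) > fc_threshold.
    """
    values, meta = _average_replicates(fm)
    if contrast not in meta.columns:
        raise ValueError(f"sample metadata lacks a {contrast!r} column")
    group_names = list(pd.unique(meta[contrast]))
    if len(group_names) < 2:
        raise ValueError("contrast needs at least two groups")
    group_ix = [np.flatnonzero(meta[contrast] == g) for g in group_names]

    if cfg.fc_pseudocount is None:
        nonzero = values[values > 0]
        pseudo = 0.5 * float(nonzero.min()) if nonzero.size else 0.0
    else:
        pseudo = cfg.fc_pseudocount

    rows = []
    for j, mz in enumerate(fm.feature_mz):
        col = values[:, j]
        gvals = [col[ix] for ix in group_ix]
        means = [float(g.mean()) for g in gvals]
        flagged = False
        if np.all(col == 0):
            stat, p = float("nan"), 1.0
            flagged = True
        elif len(gvals) == 2:
            stat, p = wilcoxon_rank_sum(gvals[0], gvals[1])
        else:
            stat, p = kruskal_wallis(gvals)
        fc = fold_change(means[0], means[1], pseudo) if not flagged else 1.0
        sym_fc = max(fc, 1.0 / fc) if fc > 0 else float("inf")
        significant = p < cfg.alpha and (not cfg.use_fc_rule or sym_fc > cfg.fc_threshold)
        rows.append(
            {
                "mz": float(mz),
                "p_raw": p,
                "statistic": stat,
                **{f"mean_{g}": m for g, m in zip(group_names, means)},
                "fc": fc,
                "direction": "up" if fc > 1 else ("down" if fc < 1 else "flat"),
                "significant": bool(significant and not flagged),
                "degenerate": flagged,
            }
        )
    table = pd.DataFrame(rows)
    if cfg.report_bh and len(table):
        table["p_bh"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    return table


def spearman_hclust(
    fm: FeatureMatrix | np.ndarray, on: str = "features", k: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average-linkage hierarchical clustering on 1 - Spearman correlation.

    Returns (scipy linkage matrix, k-cut labels or None).  Constant items
    have undefined correlation; their distances are set to 1 with a warning.
    """
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if on == "features":
        x = x.T
    elif on != "samples":
        raise ValueError("on must be 'features' or 'samples'")
    if x.shape[0] < 3:
        raise ValueError("clustering needs at least three items")
    rho = pd.DataFrame(x.T).corr(method="spearman").to_numpy()
    if np.isnan(rho).any():
        warnings.warn("constant items: undefined correlations set to 0", stacklevel=2)
        rho = np.nan_to_num(rho, nan=0.0)
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust") - 1 if k else None
    return z, labels


def pca_scores(
    fm: FeatureMatrix | np.ndarray, n_components: int = 2, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered (optionally unit-variance) PCA by SVD.

    Returns (scores, loadings, explained variance ratio).  The sign of each
    component is fixed so its largest-|loading| element is positive.
    """
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    xc = x - x.mean(axis=0)
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    total_var = (xc**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return scores, vt.T, explained
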