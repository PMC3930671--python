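"""Patch typology and group-comparison statistics.

Patch typing follows the classic ordination-plus-clustering recipe: build
a patch feature matrix (mean/max/sd of DBH, trees per patch, tree density,
patch area, patch perimeter), standardize each column to zero mean and
unit variance (the features mix cm, stems/ha and m², so raw Euclidean
distances would be meaningless), then run principal components on the
standardized (correlation-scale) matrix and agglomerative clustering with
Euclidean distances and Ward's linkage.  The number of groups is either
fixed or chosen automatically in 3–6 by the largest relative merge-height
elongation ("branch elongation" in the dendrogram).

Group comparisons: one-way ANOVA computed from first-principles sums of
squares with Shapiro–Wilk (residual normality) and Levene (equal
variance) screens at α = 0.05 and an automatic log₁₀ fallback, followed
by Bonferroni-adjusted pairwise comparisons summarized as a compact
letter display; and the Kruskal–Wallis rank test with tie correction,
gated Nemenyi pairwise comparisons (studentized range on mean ranks).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .mosaic import MosaicPartition

__all__ = [
    "PatchFeatureMatrix",
    "PatchGrouping",
    "AnovaResult",
    "KruskalResult",
    "patch_features",
    "pca_patch_structure",
    "cluster_patch_types",
    "compare_groups_anova",
    "kruskal_nemenyi",
    "compact_letters",
]

FEATURE_COLUMNS = (
    "dbh_mean", "dbh_max", "dbh_sd", "trees_per_patch",
    "tree_density", "patch_area", "patch_perimeter",
)


@dataclass
class PatchFeatureMatrix:
    """Standardized patch features plus the centre/scale record."""

    data: pd.DataFrame  # raw values, one row per patch
    centre: pd.Series
    scale: pd.Series

    @property
    def standardized(self) -> np.ndarray:
        return ((self.data - self.centre) / self.scale).to_numpy()


def patch_features(partition: MosaicPartition) -> PatchFeatureMatrix:
    """Feature matrix of a mosaic's patches (no missing cells; the sd of a
    2-tree patch is the sample sd of its two diameters)."""
    rows = []
    for p in partition.patches:
        d = p.dbh
        rows.append({
            "dbh_mean": d.mean(), "dbh_max": d.max(),
            "dbh_sd": d.std(ddof=1),
            "trees_per_patch": p.n_trees,
            "tree_density": p.density,
            "patch_area": p.area,
            "patch_perimeter": p.perimeter,
        })
    data = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    centre = data.mean()
    scale = data.std(ddof=1)
    bad = scale[scale == 0].index.tolist()
    if bad:
        raise ValueError(f"constant feature column(s): {bad}")
    return PatchFeatureMatrix(data, centre, scale)


@dataclass
class PCAResult:
    loadings: np.ndarray  # (p, p), columns are components
    variance_fraction: np.ndarray
    scores: np.ndarray  # (n, p)
    columns: tuple[str, ...]


def pca_patch_structure(features: PatchFeatureMatrix) -> PCAResult:
    """Principal components of the standardized feature matrix.

    Variance-explained fractions sum to 1; score covariance is diagonal.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive (deterministic orientation).
    """
    X = features.standardized
    if X.shape[0] < 3:
        raise ValueError("need at least 3 patches for PCA")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (X.shape[0] - 1)
    load = vt.T
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    load = load * flip
    return PCAResult(
        loadings=load,
        variance_fraction=ev / ev.sum(),
        scores=Xc @ load,
        columns=tuple(features.data.columns),
    )


@dataclass
class PatchGrouping:
    labels: np.ndarray  # 1..k per patch
    k: int
    merge_heights: np.ndarray  # full Ward merge-height sequence
    linkage_matrix: np.ndarray
    selection: str  # 'manual' or rationale text for automatic k


def cluster_patch_types(
    features: PatchFeatureMatrix,
    k: int | None = None,
    k_range: tuple[int, int] = (3, 6),
) -> PatchGrouping:
    """Ward clustering of standardized patch features.

    With ``k`` given, cuts the dendrogram at that many groups; otherwise
    scores candidate k in ``k_range`` by relative branch elongation — the
    ratio of the merge height that reduces k groups to k−1 over the
    previous merge height — and picks the k with the largest ratio.
    """
    X = features.standardized
    n = X.shape[0]
    if k is not None and k > n:
        raise ValueError("k cannot exceed the number of patches")
    Z = linkage(X, method="ward")
    heights = Z[:, 2]
    if k is None:
        lo, hi = k_range
        hi = min(hi, n - 1)
        ratios = {}
        for kk in range(lo, hi + 1):
            # merging from kk groups to kk-1 happens at heights[n-kk]
            h_next = heights[n - kk]
            h_prev = heights[n - kk - 1] if n - kk - 1 >= 0 else h_next
            ratios[kk] = h_next / h_prev if h_prev > 0 else np.inf
        k = max(ratios, key=ratios.get)
        selection = (
            f"automatic: branch elongation ratios {ratios}; chose k={k}"
        )
    else:
        selection = "manual"
    labels = fcluster(Z, t=k, criterion="maxclust")
    return PatchGrouping(labels=labels, k=int(k), merge_heights=heights,
                         linkage_matrix=Z, selection=selection)


# ---------------------------------------------------------------------------
# ANOVA + Bonferroni letters


def compact_letters(names: list, different: set[tuple]) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different.  ``different`` holds unordered pairs declared different.

    Insert-and-absorb: start with one letter covering everything and split
    it for every significant pair, then drop letter sets contained in
    others.
    """
    sets: list[set] = [set(names)]
    for a, b in different:
        new_sets: list[set] = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        sets = new_sets
        # absorb subsets
        sets = [s for s in sets
                if s and not any(s < t for t in sets)]
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    order = {n: i for i, n in enumerate(names)}
    sets.sort(key=lambda s: min(order[n] for n in s))
    letters = {n: "" for n in names}
    for letter, s in zip(string.ascii_lowercase, sets):
        for n in names:
            if n in s:
                letters[n] += letter
    return letters


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    log_transformed: bool
    letters: dict
    pairwise_p: dict  # Bonferroni-adjusted
    screens: dict  # shapiro/levene p-values on the analysis scale


def _anova_ss(groups: dict[str, np.ndarray]) -> tuple[float, float, int, int]:
    """First-principles one-way ANOVA sums of squares."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return ss_between, ss_within, df_b, df_w


def compare_groups_anova(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    auto_log: bool = True,
) -> AnovaResult:
    """One-way ANOVA with assumption screens, log₁₀ fallback, and
    Bonferroni pairwise letters.

    Normality is screened with Shapiro–Wilk on the pooled residuals and
    equal variance with Levene's test, both at α = 0.05; failing either
    re-runs the analysis on log₁₀ values (requires positive data) and
    flags the transform.  Pairwise comparisons use two-sample t tests on
    the pooled within-group mean square with Bonferroni-adjusted p.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")

    def _screens(gs):
        resid = np.concatenate([v - v.mean() for v in gs.values()])
        if np.allclose(resid, 0.0):
            return {"shapiro_p": 1.0, "levene_p": 1.0}
        sh = stats.shapiro(resid).pvalue
        lv = stats.levene(*gs.values()).pvalue
        return {"shapiro_p": float(sh), "levene_p": float(lv)}

    screens = _screens(groups)
    log_flag = False
    work = groups
    if auto_log and (screens["shapiro_p"] < alpha or screens["levene_p"] < alpha):
        if all((v > 0).all() for v in groups.values()):
            work = {k: np.log10(v) for k, v in groups.items()}
            log_flag = True
            screens = _screens(work)

    ssb, ssw, df_b, df_w = _anova_ss(work)
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    mse = ssw / df_w if df_w > 0 else np.nan
    names = list(work)
    m = len(names) * (len(names) - 1) // 2
    pairwise_p = {}
    different = set()
    for a, b in itertools.combinations(names, 2):
        va, vb = work[a], work[b]
        if mse == 0.0:
            praw = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            t = (va.mean() - vb.mean()) / np.sqrt(
                mse * (1.0 / len(va) + 1.0 / len(vb))
            )
            praw = 2.0 * stats.t.sf(abs(t), df_w)
        padj = min(1.0, praw * m)
        pairwise_p[(a, b)] = padj
        if padj < alpha:
            different.add((a, b))
    letters = compact_letters(names, different)
    return AnovaResult(float(f), p, df_b, df_w, log_flag, letters,
                       pairwise_p, screens)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Nemenyi


@dataclass
class KruskalResult:
    h: float
    p: float
    nemenyi_p: dict | None  # pairwise, only when H significant
    letters: dict | None


def kruskal_nemenyi(samples: dict[str, np.ndarray],
                    alpha: float = 0.05) -> KruskalResult:
    """Kruskal–Wallis H (tie-corrected) with gated Nemenyi comparisons.

    The Nemenyi test (the non-parametric analogue of Tukey's HSD) is run
    only when the overall H is significant at ``alpha``; it compares mean
    ranks with the studentized-range critical scale
    q/√2 · √(N(N+1)/12 · (1/nᵢ + 1/nⱼ)).
    """
    samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(samples) < 2 or any(len(v) < 2 for v in samples.values()):
        raise ValueError("need >= 2 samples per site and >= 2 sites")
    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, None, None)
    h, p = stats.kruskal(*samples.values())

    if p >= alpha:
        return KruskalResult(float(h), float(p), None, None)

    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for k, v in samples.items():
        mean_ranks[k] = ranks[i:i + len(v)].mean()
        i += len(v)
    # tie correction factor for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
    names = list(samples)
    k_groups = len(names)
    nem = {}
    different = set()
    for a, b in itertools.combinations(names, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt(n_tot * (n_tot + 1) / 12.0 * (1.0 / na + 1.0 / nb) * tie)
        q = abs(mean_ranks[a] - mean_ranks[b]) / se * np.sqrt(2.0)
        pv = float(stats.studentized_range.sf(q, k_groups, np.inf))
        if not np.isfinite(pv):
            pv = float(stats.studentized_range.sf(q, k_groups, 1e6))
        nem[(a, b)] = pv
        if pv < alpha:
            different.add((a, b))
    letters = compact_letters(names, different)
    return KruskalResult(float(h), float(p), nem, letters)
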