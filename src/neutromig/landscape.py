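"""The 2-D migration landscape, phenotype classification, group statistics.

Normalized experiment profiles are projected to two dimensions with UMAP
("the landscape"); clusters in the embedding are called with DBSCAN, a
reproducible substitute for visual cluster delineation. Donors are
classified by serum phenotype:

* Th1-high — both IL-2 and IFN-g strictly above their cohort 75% quantiles
  (computed over donors with valid readouts for both analytes); Th1-low —
  neither elevated; intermediate — exactly one; not_evaluable — missing
  readouts. Healthy controls are labeled but excluded from Th1 contrasts.
* ICS dose class — daily inhaled-corticosteroid dose as fluticasone
  equivalent: naive (no dose, no on-demand use), low (< 200 ug/day under
  12 years, < 250 ug/day from 12 years, or on-demand-only use), high
  (at or above; medium and high doses pooled), control for healthy donors.

Group comparisons use a two-sided Welch t-test or the Wilcoxon rank-sum
test, starred at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("neutromig.landscape")

__all__ = [
    "LandscapeEmbedding",
    "GroupComparison",
    "embed_landscape",
    "cluster_landscape",
    "flag_embedding_outliers",
    "classify_th1",
    "classify_ics",
    "compare_groups",
    "significance_stars",
    "plot_landscape",
    "IL2",
    "IFNG",
]

IL2 = "IL-2"
IFNG = "IFN-g"


@dataclass
class LandscapeEmbedding:
    """2-D coordinates per experiment plus the parameters that made them."""

    coords: pd.DataFrame              # columns u1, u2, index = experiments
    n_neighbors: int
    min_dist: float
    seed: int
    cluster_labels: pd.Series | None = field(default=None)


@dataclass(frozen=True)
class GroupComparison:
    """One feature's two-group test result."""

    feature: str
    groups: tuple[str, str]
    test: str                  # 't' or 'wilcoxon'
    statistic: float
    p: float
    stars: str
    n: tuple[int, int]


def embed_landscape(matrix: pd.DataFrame, n_neighbors: int = 15,
                    min_dist: float = 0.1, seed: int = 0) -> LandscapeEmbedding:
    """UMAP projection of normalized profiles to two dimensions.

    Euclidean metric; a fixed seed gives identical coordinates. Requires
    at least ``n_neighbors + 1`` rows.
    """
    import umap  # deferred: heavy import (numba compilation)

    if len(matrix) < n_neighbors + 1:
        raise ValueError(
            f"embedding needs at least n_neighbors + 1 = {n_neighbors + 1} rows, "
            f"got {len(matrix)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a seed disables parallelism
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, metric="euclidean",
                            random_state=seed)
        emb = reducer.fit_transform(matrix.to_numpy(dtype=float))
    coords = pd.DataFrame(emb, index=matrix.index, columns=["u1", "u2"])
    return LandscapeEmbedding(coords=coords, n_neighbors=n_neighbors,
                              min_dist=min_dist, seed=seed)


def cluster_landscape(embedding: LandscapeEmbedding, eps: float | None = None,
                      min_pts: int = 5) -> pd.Series:
    """Density-based cluster labels on the 2-D embedding (-1 = noise).

    When ``eps`` is not given it defaults to 1.5x the median distance to
    the ``min_pts``-th nearest neighbor (the k-dist elbow heuristic), a
    scale-free stand-in for visual cluster calls that keeps cluster tails
    attached without bridging well-separated groups. Labels are stored on
    the embedding and returned.
    """
    pts = embedding.coords.to_numpy(dtype=float)
    if eps is None:
        if len(pts) < 2:
            eps = 1.0
        else:
            k = min(min_pts, len(pts) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
            dists, _ = nn.kneighbors(pts)
            med = float(np.median(dists[:, k]))
            eps = 1.5 * med if med > 0 else 1e-12
    eps = max(float(eps), 1e-300)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    series = pd.Series(labels, index=embedding.coords.index, name="cluster")
    embedding.cluster_labels = series
    return series


def flag_embedding_outliers(embedding: LandscapeEmbedding, k: int = 5,
                            factor: float = 3.0) -> pd.Series:
    """Flag points whose mean distance to their k nearest neighbors exceeds
    ``factor`` x the cohort median of that quantity. Off by default in the
    pipeline; mirrors manual removal of a single extreme profile."""
    pts = embedding.coords.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(pts))).fit(pts)
    dists, _ = nn.kneighbors(pts)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = factor * np.median(mean_d)
    return pd.Series(mean_d > thresh, index=embedding.coords.index, name="outlier")


# ---------------------------------------------------------------------------
# phenotype classification
# ---------------------------------------------------------------------------

def classify_th1(cytokines: pd.DataFrame, is_control: pd.Series | None = None,
                 quantile: float = 0.75, il2_col: str = IL2,
                 ifng_col: str = IFNG) -> pd.DataFrame:
    """Th1 serum phenotype per donor from a normalized cytokine matrix.

    The 75% quantiles of IL-2 and IFN-g (type-7, linear interpolation) are
    computed over donors with valid readouts for both analytes. A donor is
    ``high`` iff both values lie strictly above their quantiles, ``low``
    iff neither does, ``intermediate`` otherwise, and ``not_evaluable``
    with missing readouts. Controls are classified too but flagged for
    exclusion from Th1 contrasts.
    """
    for col in (il2_col, ifng_col):
        if col not in cytokines.columns:
            raise KeyError(f"cytokine matrix lacks required analyte column {col!r}")
    il2 = cytokines[il2_col]
    ifng = cytokines[ifng_col]
    valid = il2.notna() & ifng.notna()
    if not valid.any():
        raise ValueError("no donor has valid readouts for both IL-2 and IFN-g")
    q_il2 = float(np.quantile(il2[valid], quantile))     # numpy default = type 7
    q_ifng = float(np.quantile(ifng[valid], quantile))

    hi2 = il2 > q_il2
    hig = ifng > q_ifng
    th1 = pd.Series("not_evaluable", index=cytokines.index, name="th1_class")
    th1[valid & hi2 & hig] = "high"
    th1[valid & ~hi2 & ~hig] = "low"
    th1[valid & (hi2 ^ hig)] = "intermediate"

    ctrl = (is_control.reindex(cytokines.index).fillna(False).astype(bool)
            if is_control is not None
            else pd.Series(False, index=cytokines.index))
    return pd.DataFrame({
        "th1_class": th1,
        "is_control": ctrl,
        "in_th1_contrast": valid & ~ctrl & th1.isin(["high", "low"]),
    })


def classify_ics(dose_ug: float, age_years: float, on_demand: bool = False,
                 is_control: bool = False) -> str:
    """ICS dose class from the daily fluticasone-equivalent dose.

    * ``control`` — healthy donor (no asthma medication by definition);
    * ``naive`` — asthmatic, zero dose and no on-demand use;
    * ``low`` — dose below 200 ug/day (age < 12) or 250 ug/day (age >= 12),
      or on-demand-only use;
    * ``high`` — at/above the low-dose cutoff (medium and high pooled).
    """
    if dose_ug < 0:
        raise ValueError(f"ICS dose must be >= 0, got {dose_ug}")
    if is_control:
        return "control"
    if dose_ug == 0:
        return "low" if on_demand else "naive"
    cutoff = 200.0 if age_years < 12 else 250.0
    return "low" if dose_ug < cutoff else "high"


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
                   test: str = "t", feature: str = "") -> GroupComparison:
    """Two-sided two-group comparison: Welch t-test or Wilcoxon rank-sum."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = pd.unique(labels[~pd.isna(labels)])
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    a = values[labels == names[0]]
    b = values[labels == names[1]]
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if test == "t":
        if min(len(a), len(b)) < 2:
            raise ValueError("t-test requires at least 2 observations per group")
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        if min(len(a), len(b)) < 1:
            raise ValueError("rank-sum test requires non-empty groups")
        res = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown test {test!r}; use 't' or 'wilcoxon'")
    p = float(res.pvalue)
    return GroupComparison(
        feature=feature, groups=(str(names[0]), str(names[1])), test=test,
        statistic=float(res.statistic), p=p, stars=significance_stars(p),
        n=(len(a), len(b)))


def plot_landscape(embedding: LandscapeEmbedding, color_by: pd.Series | None = None,
                   path=None, title: str = "Migration landscape"):
    """Scatter of the landscape, optionally colored by a grouping; saves to
    ``path`` if given and returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    coords = embedding.coords
    if color_by is None:
        ax.scatter(coords["u1"], coords["u2"], s=25)
    else:
        groups = color_by.reindex(coords.index)
        for g in pd.unique(groups.dropna()):
            sel = groups == g
            ax.scatter(coords.loc[sel, "u1"], coords.loc[sel, "u2"], s=25, label=str(g))
        ax.legend(frameon=False)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
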