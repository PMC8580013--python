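"""Vaginal community-state typing by hierarchical clustering.

The primary recipe is Ward-linkage agglomeration computed directly on the
Bray-Curtis dissimilarities (the ``hclust ward.D`` convention: the
Lance-Williams Ward update applied to the dissimilarities as given, not to
their squares; a ``ward.D2``-style variant is available). Cluster labels
come from cutting the dendrogram at a requested ``k`` — or at the ``k``
maximizing mean silhouette width when asked to choose — and are renamed
CT-A, CT-B, ... in decreasing cluster-size order, so the most prevalent
community type is always CT-A.

A Spearman-correlation / complete-linkage clustering is provided as a
robustness check, with agreement reported as adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, spearmanr
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

LACTO_DOMINANCE_CUTOFF = 0.95  # "Lactobacillus-dominated" membership bar


def filter_prevalent_genera(
    rel_abundance: pd.DataFrame, min_abundance: float = 0.001
) -> pd.DataFrame:
    """Keep genus i iff its relative abundance reaches ``min_abundance``
    (default 0.1%) in at least one sample."""
    keep = rel_abundance.max(axis=1) >= min_abundance
    if not keep.any():
        raise ValueError("no genus passes the prevalence filter")
    return rel_abundance.loc[keep]


def ward_cluster(dm: DistanceMatrix | np.ndarray, variant: str = "D") -> np.ndarray:
    """Ward-linkage tree over a precomputed dissimilarity matrix.

    ``variant='D'`` applies the Lance-Williams Ward update to the
    dissimilarities as given (hclust ``ward.D``); ``'D2'`` applies it to
    their squares (``ward.D2``). Returns a SciPy linkage matrix; ties break
    deterministically toward the lowest-index pair.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    if variant == "D":
        # SciPy's 'ward' runs the update on squared input distances, so
        # feeding sqrt(d) realises the update on d itself; heights are
        # squared back to the original scale.
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2
    elif variant == "D2":
        z = linkage(condensed, method="ward")
    else:
        raise ValueError("variant must be 'D' or 'D2'")
    return z


def cut_clusters(linkage_matrix: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into ``k`` flat clusters (1-based integer labels)."""
    n = linkage_matrix.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    return fcluster(linkage_matrix, t=k, criterion="maxclust")


def choose_k(
    linkage_matrix: np.ndarray,
    dm: DistanceMatrix | np.ndarray,
    k_range=range(2, 11),
) -> int:
    """Pick ``k`` maximizing mean silhouette width; ties -> smallest k."""
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    k_range = list(k_range)
    if len(k_range) == 1:
        return k_range[0]
    best_k, best_s = None, -np.inf
    for k in sorted(k_range):
        labels = cut_clusters(linkage_matrix, k)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(d, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("silhouette undefined for every k (degenerate distances)")
    return best_k


def spearman_complete_cluster(
    rel_abundance: pd.DataFrame, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Robustness clustering: distance 1 - Spearman rho (range [0, 2]),
    complete linkage. Returns (labels, linkage matrix)."""
    rho = spearmanr(rel_abundance.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    z = linkage(squareform(d, checks=False), method="complete")
    return cut_clusters(z, k), z


def name_cts(labels: np.ndarray) -> pd.Series:
    """Rename integer cluster labels CT-A, CT-B, ... by decreasing size."""
    counts = pd.Series(labels).value_counts()
    letters = [chr(ord("A") + i) for i in range(len(counts))]
    mapping = {lab: f"CT-{letter}" for lab, letter in zip(counts.index, letters)}
    return pd.Series([mapping[v] for v in labels])


@dataclass
class CommunityTypeAssignment:
    labels: pd.Series  # sample id -> CT label
    linkage: np.ndarray
    k: int
    method: str  # 'ward-BC' or 'spearman-complete'


def assign_community_types(
    rel_abundance: pd.DataFrame,
    k: int | str = 7,
    min_abundance: float = 0.001,
    metric: str = "braycurtis",
    variant: str = "D",
) -> CommunityTypeAssignment:
    """Full typing recipe: prevalence filter, Bray-Curtis distances, Ward
    clustering, cut at ``k`` (or silhouette-chosen when ``k='auto'``)."""
    from microstab.diversity import distance_matrix

    filtered = filter_prevalent_genera(rel_abundance, min_abundance)
    dm = distance_matrix(filtered, metric=metric)
    z = ward_cluster(dm, variant=variant)
    if k == "auto":
        k = choose_k(z, dm)
    labels = name_cts(cut_clusters(z, int(k)))
    labels.index = list(rel_abundance.columns)
    return CommunityTypeAssignment(labels=labels, linkage=z, k=int(k), method="ward-BC")


def characterize_cts(
    rel_abundance: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series | None = None,
    n_dominant: int = 3,
) -> pd.DataFrame:
    """Per-CT summary: counts, share of all typed samples, cohort split,
    dominant genera and Lactobacillus-dominance fraction.

    Percentages use one decimal with denominator = all typed samples (the
    CT share) or the CT's own size (cohort split). When cohorts are given,
    each CT gets a Fisher exact p for cohort enrichment (CT vs rest x
    cancer vs healthy).
    """
    labels = labels.loc[rel_abundance.columns]
    total = len(labels)
    rows = []
    for ct in sorted(labels.unique()):
        members = labels.index[labels == ct]
        sub = rel_abundance[members]
        mean_abund = sub.mean(axis=1).sort_values(ascending=False)
        dominant = ", ".join(mean_abund.index[:n_dominant])
        lacto = (
            (sub.loc["Lactobacillus"] > LACTO_DOMINANCE_CUTOFF).mean()
            if "Lactobacillus" in sub.index
            else np.nan
        )
        row = {
            "CT": ct,
            "n": len(members),
            "pct_of_total": round(100.0 * len(members) / total, 1),
            "dominant_genera": dominant,
            "lacto_dominance_fraction": lacto,
        }
        if cohorts is not None:
            coh = cohorts.loc[members]
            n_cancer = int((coh == "cancer").sum())
            n_healthy = int((coh == "healthy").sum())
            row["n_cancer"] = n_cancer
            row["n_healthy"] = n_healthy
            row["pct_cancer_of_ct"] = round(100.0 * n_cancer / len(members), 1)
            row["pct_healthy_of_ct"] = round(100.0 * n_healthy / len(members), 1)
            all_cancer = int((cohorts.loc[labels.index] == "cancer").sum())
            all_healthy = int((cohorts.loc[labels.index] == "healthy").sum())
            table = [
                [n_cancer, n_healthy],
                [all_cancer - n_cancer, all_healthy - n_healthy],
            ]
            row["fisher_p"] = float(fisher_exact(table)[1])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("CT")
    assert out["n"].sum() == total
    return out


def ct_share_percentages(ct_counts: dict[str, int] | pd.Series) -> pd.Series:
    """Recompute each CT's share (%) of all typed samples from its counts,
    rounded to one decimal — the arithmetic behind a CT summary table."""
    s = pd.Series(ct_counts, dtype=float)
    return (100.0 * s / s.sum()).round(1)
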