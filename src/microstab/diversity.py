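"""Normalization and diversity estimation.

Cumulative-sum scaling (CSS) corrects for sequencing depth by dividing each
sample's counts by the cumulative sum of its counts up to a chosen quantile
of the positive counts, rather than by the total — reducing the leverage of
a few dominant taxa on the scaling factor.

Alpha diversity is computed on raw integer counts (Chao1 needs exact
singleton/doubleton counts): observed richness, bias-corrected Chao1,
Shannon entropy (natural log), Pielou evenness, and Faith's phylogenetic
diversity against a rooted genus tree. Beta diversity (Bray-Curtis or
presence/absence Jaccard) is computed on relative abundances of the
CSS-normalized table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as skbio_alpha

from microstab.tables import GenusCountTable

DEFAULT_CSS_SCALE = 1000.0

ALPHA_METRICS = ["observed_richness", "chao1", "shannon", "pielou", "faith_pd"]


# --------------------------------------------------------------------------
# CSS normalization
# --------------------------------------------------------------------------

@dataclass
class NormalizedTable:
    """Real-valued genus x sample table after CSS normalization."""

    data: pd.DataFrame
    scaling_factors: pd.Series  # s_j per sample
    quantile: float
    scale: float

    def relative_abundance(self) -> pd.DataFrame:
        return self.data / self.data.sum(axis=0)


def css_scaling_factor(counts: np.ndarray, quantile: float = 0.5) -> float:
    """Sum of a sample's counts at or below the ``quantile``-th quantile of
    its positive counts."""
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError("sample has no positive counts")
    q = np.quantile(positive, quantile)
    s = float(counts[(counts > 0) & (counts <= q)].sum())
    if s <= 0:
        raise ValueError(f"CSS scaling factor is 0 at quantile {quantile}")
    return s


def css_normalize(
    table: GenusCountTable,
    quantile: float = 0.5,
    scale: float = DEFAULT_CSS_SCALE,
) -> NormalizedTable:
    """Cumulative-sum-scaling normalization, fixed quantile (default median).

    Normalized value is ``y_ij / s_j * scale`` where ``s_j`` sums the counts
    of sample ``j`` that are <= the quantile of its positive counts; ties at
    the quantile are included.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    factors = {}
    for sid in table.samples:
        factors[sid] = css_scaling_factor(table.data[sid].to_numpy(), quantile)
    s = pd.Series(factors)
    norm = table.data / s * scale
    return NormalizedTable(data=norm, scaling_factors=s, quantile=quantile, scale=scale)


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def observed_richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + f1(f1-1) / (2(f2+1))``."""
    c = np.asarray(counts)
    if c.sum() == 0:
        raise ValueError("empty sample")
    return float(skbio_alpha.chao1(c.astype(int), bias_corrected=True))


def shannon(counts) -> float:
    """Shannon entropy in nats over the positive proportions."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("empty sample")
    return float(skbio_alpha.shannon(c, base=np.e))


def pielou(counts) -> float:
    """Pielou evenness ``H / ln(S_obs)``; NaN when fewer than two taxa."""
    s_obs = observed_richness(counts)
    if s_obs <= 1:
        return float("nan")
    return shannon(counts) / np.log(s_obs)


def parse_tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def faith_pd(counts, genera: list[str], tree: TreeNode | str) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    rooted subtree spanning the observed genera.

    Computed as the union of root-to-tip branch sets of the observed
    leaves, so multifurcating roots (star trees) are handled.
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    c = np.asarray(counts)
    observed = set(g for g, x in zip(genera, c) if x > 0)
    if not observed:
        raise ValueError("no observed genera; PD undefined")
    tip_nodes = {t.name: t for t in tree.tips()}
    missing = sorted(observed - set(tip_nodes))
    if missing:
        raise KeyError(f"observed genera missing from tree: {missing}")
    spanned: set[int] = set()
    total = 0.0
    for name in observed:
        node = tip_nodes[name]
        while node.parent is not None and id(node) not in spanned:
            spanned.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def alpha_diversity_table(
    table: GenusCountTable, tree: TreeNode | str | None = None
) -> pd.DataFrame:
    """All alpha metrics per sample, computed on raw counts."""
    if isinstance(tree, str):
        tree = parse_tree(tree)
    rows = {}
    genera = table.genera
    for sid in table.samples:
        c = table.data[sid].to_numpy()
        rows[sid] = {
            "observed_richness": observed_richness(c),
            "chao1": chao1(c),
            "shannon": shannon(c),
            "pielou": pielou(c),
            "faith_pd": faith_pd(c, genera, tree) if tree is not None else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# --------------------------------------------------------------------------
# beta diversity
# --------------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """``1 - 2 sum(min(x_i, y_i)) / (sum x + sum y)``, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both profiles are empty")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(
    table: GenusCountTable | NormalizedTable | pd.DataFrame,
    metric: str = "braycurtis",
) -> DistanceMatrix:
    """Pairwise sample dissimilarities on relative abundances.

    ``metric`` is ``braycurtis`` (abundance-weighted) or ``jaccard``
    (presence/absence).
    """
    if isinstance(table, (GenusCountTable, NormalizedTable)):
        rel = table.relative_abundance()
    else:
        rel = table / table.sum(axis=0)
    ids = list(rel.columns)
    x = rel.to_numpy().T
    if metric in ("braycurtis", "bray", "bray-curtis"):
        condensed = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        condensed = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=ids)


# --------------------------------------------------------------------------
# group comparison dispatch
# --------------------------------------------------------------------------

def compare_alpha(
    values: pd.Series, grouping: pd.Series, paired: bool = False
) -> dict:
    """Compare an alpha metric between groups.

    Independent groups -> Kruskal-Wallis; paired timepoints -> Wilcoxon
    signed-rank on the within-pair differences. A Kolmogorov-Smirnov
    normality check on the pooled values is reported alongside.
    """
    values = values.astype(float)
    groups = [values[grouping == g].dropna().to_numpy() for g in pd.unique(grouping)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sd = values.std(ddof=1)
    if sd > 0:
        z = (values - values.mean()) / sd
        ks_stat, ks_p = stats.kstest(z.dropna(), "norm")
    else:
        ks_stat, ks_p = 0.0, 1.0
    if paired:
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("paired comparison needs two equal-size groups")
        diffs = groups[0] - groups[1]
        if np.all(diffs == 0):
            raise ValueError("all paired differences are zero; Wilcoxon degenerate")
        stat, p = stats.wilcoxon(groups[0], groups[1])
        test = "wilcoxon_signed_rank"
    else:
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # identical values: H = 0 by convention
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups)
        test = "kruskal_wallis"
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "ks_normality_stat": float(ks_stat),
        "ks_normality_p": float(ks_p),
        "n_groups": len(groups),
    }
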