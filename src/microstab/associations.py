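"""Inferential layer: contingency and rank tests, PERMANOVA, forward-AIC
GLM with deviance partitioning, and a univariate taxon-symptom screen.

PERMANOVA follows the distance-based linear-model formulation: the
dissimilarity matrix is Gower-centered, term sums of squares are obtained
sequentially (Type I) from hat matrices of the accumulated design, and
significance comes from permuting sample identities. The forward-AIC GLM
mirrors stepwise selection followed by a sequential analysis of deviance,
reporting per-term deviance drop, a chi-square p-value on the estimated
dispersion scale, and percent of null deviance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    test: str
    term: str
    statistic: float
    df: float | None = None
    p: float | None = None
    p_adjusted: float | None = None
    adjust_method: str | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "test": self.test, "term": self.term, "statistic": self.statistic,
            "df": self.df, "p": self.p, "p_adjusted": self.p_adjusted,
            "adjust_method": self.adjust_method,
        }
        d.update(self.extras)
        return d


# --------------------------------------------------------------------------
# basic tests
# --------------------------------------------------------------------------

def fisher_exact(table) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table (sum of hypergeometric
    probabilities <= that of the observed table)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return AssociationResult("fisher_exact", "2x2", float(odds), p=float(p))


def fisher_exact_enumeration(table) -> float:
    """Independent brute-force two-sided Fisher p by enumerating the full
    hypergeometric support of the fixed margins."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)))


def kruskal_wallis(values: pd.Series, grouping: pd.Series) -> AssociationResult:
    groups = [values[grouping == g].dropna().to_numpy() for g in pd.unique(grouping)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return AssociationResult("kruskal_wallis", "grouping", float(h),
                             df=len(groups) - 1, p=float(p))


def wilcoxon_signed_rank(x, y=None) -> AssociationResult:
    """Paired signed-rank test; exact null when n <= 25 and no ties/zeros."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; test degenerate")
    nz = d[d != 0]
    exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) and (d != 0).all()
    method = "exact" if exact_ok else "approx"
    w, p = stats.wilcoxon(d, method=method)
    return AssociationResult("wilcoxon_signed_rank", "paired", float(w), p=float(p),
                             extras={"method": method})


def kolmogorov_smirnov(values) -> AssociationResult:
    """One-sample KS normality check on standardized values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    sd = v.std(ddof=1)
    if sd == 0:
        return AssociationResult("kolmogorov_smirnov", "normality", 0.0, p=1.0)
    stat, p = stats.kstest((v - v.mean()) / sd, "norm")
    return AssociationResult("kolmogorov_smirnov", "normality", float(stat), p=float(p))


def students_t(values: pd.Series, grouping: pd.Series) -> AssociationResult:
    levels = pd.unique(grouping)
    if len(levels) != 2:
        raise ValueError("t-test needs exactly two groups")
    a = values[grouping == levels[0]].dropna()
    b = values[grouping == levels[1]].dropna()
    t, p = stats.ttest_ind(a, b)
    return AssociationResult("students_t", "grouping", float(t),
                             df=len(a) + len(b) - 2, p=float(p))


def adjust_p(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment; ``bonferroni`` or ``BH`` (step-up FDR)."""
    method = {"bonferroni": "bonferroni", "BH": "fdr_bh", "fdr_bh": "fdr_bh"}[method]
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]


# --------------------------------------------------------------------------
# PERMANOVA (sequential, multi-factor)
# --------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design_columns(factors: pd.DataFrame) -> tuple[list[np.ndarray], list[int]]:
    """Dummy-code each factor (drop-first for categoricals); returns one
    column block and its df per term."""
    blocks, dfs = [], []
    for col in factors.columns:
        s = factors[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"factor {col!r} has a single level")
            blocks.append(dummies)
            dfs.append(dummies.shape[1])
        else:
            v = s.to_numpy(dtype=float)[:, None]
            if np.ptp(v) == 0:
                raise ValueError(f"factor {col!r} has zero variance")
            blocks.append(v)
            dfs.append(1)
    return blocks, dfs


def permanova(
    dm: DistanceMatrix | np.ndarray,
    factors: pd.DataFrame | pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sequential (Type I) permutational multivariate ANOVA on a
    dissimilarity matrix.

    Returns one row per term with df, sums of squares, pseudo-F and the
    permutation p-value ``(1 + #{F* >= F}) / (1 + n_perm)``. Deterministic
    under a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = dm.data
        factors = factors.loc[ids]
    else:
        d = np.asarray(dm, dtype=float)
    n = d.shape[0]
    if len(factors) != n:
        raise ValueError("factor rows must match distance matrix size")
    for col in factors.columns:
        counts = factors[col].value_counts()
        if factors[col].dtype.kind in "OUSb" and (len(counts) < 2 or (counts == 0).any()):
            raise ValueError(f"factor {col!r} needs >= 2 non-empty levels")

    blocks, term_dfs = _design_columns(factors)
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    intercept = np.ones((n, 1))
    hats = []  # hat matrix of accumulated design up to each term
    x = intercept
    for b in blocks:
        x = np.hstack([x, b])
        hats.append(_hat(x))
    h_full = hats[-1]
    df_resid = n - x.shape[1]
    if df_resid <= 0:
        raise ValueError("model saturates the samples; no residual df")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        tr = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_terms = np.diff(np.concatenate([[0.0], tr]))
        ss_res = float(np.trace(gmat)) - tr[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = term_stats(g)
    ms_res = ss_res / df_resid
    f_obs = (ss_terms / np.array(term_dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(blocks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_t, ss_r = term_stats(gp)
        f_perm = (ss_t / np.array(term_dfs)) / (ss_r / df_resid)
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, col in enumerate(factors.columns):
        rows.append({
            "term": col, "df": term_dfs[i], "SumOfSqs": ss_terms[i],
            "R2": ss_terms[i] / ss_total, "pseudo_F": f_obs[i], "p": pvals[i],
        })
    rows.append({"term": "Residual", "df": df_resid, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total, "pseudo_F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total,
                 "R2": 1.0, "pseudo_F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------------------
# forward-AIC GLM with sequential analysis of deviance
# --------------------------------------------------------------------------

def _fit_glm(y: np.ndarray, x: np.ndarray, family) -> sm.GLM:
    return sm.GLM(y, x, family=family).fit()


def forward_aic_glm(
    response: pd.Series,
    candidates: pd.DataFrame,
    family: str = "gaussian",
    mode: str = "stop",
) -> pd.DataFrame:
    """Greedy forward selection by AIC, then sequential analysis of deviance.

    ``mode='stop'`` halts when no candidate lowers the AIC; ``mode='full'``
    enters every candidate in greedy AIC order regardless of improvement.
    Complete cases only: rows with any missing value are dropped.

    Output columns match an analysis-of-deviance layout: ``Df``,
    ``Deviance`` (residual deviance after the term enters), ``Pr(>Chi)``
    (chi-square on the dispersion-scaled per-term deviance drop) and
    ``Variation Explained (%)`` (per-term drop over the null deviance), with
    a final ``Residuals`` row carrying the unexplained percentage.
    """
    if mode not in ("stop", "full"):
        raise ValueError("mode must be 'stop' or 'full'")
    fam = {"gaussian": sm.families.Gaussian(), "binomial": sm.families.Binomial()}[family]
    data = candidates.copy()
    data["_y"] = response
    data = data.dropna()
    if len(data) <= 1:
        raise ValueError("too few complete cases")
    y = data["_y"].to_numpy(dtype=float)

    blocks: dict[str, np.ndarray] = {}
    dfs: dict[str, int] = {}
    dropped: list[str] = []
    for col in candidates.columns:
        s = data[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummy = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            if dummy.shape[1] == 0 or np.ptp(dummy) == 0:
                dropped.append(col)
                continue
            blocks[col] = dummy
            dfs[col] = dummy.shape[1]
        else:
            v = s.to_numpy(dtype=float)
            if np.ptp(v) == 0:
                dropped.append(col)
                continue
            blocks[col] = v[:, None]
            dfs[col] = 1
    if dropped:
        import warnings

        warnings.warn(f"zero-variance candidates excluded: {dropped}", stacklevel=2)

    n = len(y)
    intercept = np.ones((n, 1))
    current_x = intercept
    current_fit = _fit_glm(y, current_x, fam)
    null_deviance = float(current_fit.deviance)
    order: list[str] = []
    remaining = list(blocks)
    while remaining:
        best, best_aic, best_x = None, np.inf, None
        for col in remaining:
            x_try = np.hstack([current_x, blocks[col]])
            if n <= x_try.shape[1]:
                continue
            aic = _fit_glm(y, x_try, fam).aic
            if aic < best_aic - 1e-12:
                best, best_aic, best_x = col, aic, x_try
        if best is None:
            break
        if mode == "stop" and best_aic >= current_fit.aic - 1e-12:
            break
        current_x, current_fit = best_x, _fit_glm(y, best_x, fam)
        order.append(best)
        remaining.remove(best)

    # sequential analysis of deviance along the entry order
    rows = []
    x = intercept
    prev_dev = null_deviance
    fits = []
    for col in order:
        x = np.hstack([x, blocks[col]])
        fit = _fit_glm(y, x, fam)
        fits.append((col, fit, prev_dev - float(fit.deviance)))
        prev_dev = float(fit.deviance)
    full_fit = fits[-1][1] if fits else current_fit
    df_resid = n - (intercept.shape[1] + sum(dfs[c] for c in order))
    dispersion = float(full_fit.deviance) / df_resid if df_resid > 0 else np.nan
    for col, fit, drop in fits:
        chi = drop / dispersion if dispersion and dispersion > 0 else np.nan
        p = float(stats.chi2.sf(chi, dfs[col])) if np.isfinite(chi) else np.nan
        rows.append({
            "term": col, "Df": dfs[col], "Deviance": float(fit.deviance),
            "AIC": float(fit.aic), "Pr(>Chi)": p,
            "Variation Explained (%)": 100.0 * drop / null_deviance,
        })
    resid_pct = 100.0 * (float(full_fit.deviance) / null_deviance) if order else 100.0
    rows.append({
        "term": "Residuals", "Df": df_resid, "Deviance": float(full_fit.deviance),
        "AIC": np.nan, "Pr(>Chi)": np.nan, "Variation Explained (%)": resid_pct,
    })
    return pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------------------
# taxon-symptom screen
# --------------------------------------------------------------------------

def taxon_symptom_screen(
    rel_abundance: pd.DataFrame,
    symptom: pd.Series,
    ordinal: bool = True,
    q_method: str = "BH",
) -> pd.DataFrame:
    """Univariate per-genus screen against one symptom.

    Ordinal symptoms use Spearman rank correlation; binary ones a
    Mann-Whitney rank-sum between present/absent groups. Benjamini-Hochberg
    adjusted across genera; all-zero genera are skipped with a warning.
    """
    import warnings

    ids = [s for s in rel_abundance.columns if s in symptom.index]
    x = rel_abundance[ids]
    y = symptom.loc[ids]
    rows = []
    for genus in x.index:
        v = x.loc[genus].to_numpy(dtype=float)
        if np.all(v == 0):
            warnings.warn(f"all-zero genus skipped: {genus}", stacklevel=2)
            continue
        if ordinal:
            rho, p = stats.spearmanr(v, y.to_numpy(dtype=float))
            stat, direction = rho, np.sign(rho)
        else:
            yy = y.astype(bool).to_numpy()
            if yy.all() or (~yy).all():
                raise ValueError("binary symptom has a single level")
            u, p = stats.mannwhitneyu(v[yy], v[~yy], alternative="two-sided")
            direction = np.sign(np.median(v[yy]) - np.median(v[~yy]))
            stat = u
        rows.append({"genus": genus, "statistic": float(stat),
                     "direction": float(direction), "p": float(p)})
    out = pd.DataFrame(rows).set_index("genus")
    out["q"] = adjust_p(out["p"], method=q_method)
    return out.sort_values("q")
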