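"""Per-subject longitudinal stability statistics.

Three Bray-Curtis-based metrics summarise how much a subject's community
composition moves over the year of follow-up:

* overall stability (ABC) — the average Bray-Curtis dissimilarity over all
  unordered pairs of the subject's timepoints (with the maximum pairwise
  value kept alongside);
* resistance — BC between baseline T0 and T1 (short-term shift across the
  treatment window);
* resilience — BC between T0 and T3 (long-term return toward baseline).

Each value is categorized as high / intermediate / low stability on the
0-0.5 / 0.5-0.75 / 0.75-1 ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from microstab.diversity import bray_curtis

STABILITY_CUTOFFS = (0.5, 0.75)  # high < 0.5 <= intermediate < 0.75 <= low


def categorize(value: float) -> str:
    """Map a Bray-Curtis stability value to {high, intermediate, low}.

    The printed ranges overlap at their boundaries; boundaries are assigned
    half-open upward: [0, 0.5) high, [0.5, 0.75) intermediate, [0.75, 1] low.
    """
    if np.isnan(value):
        return "missing"
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"Bray-Curtis value {value} outside [0, 1]")
    lo, hi = STABILITY_CUTOFFS
    if value < lo:
        return "high"
    if value < hi:
        return "intermediate"
    return "low"


def overall_stability(
    profiles: dict[str, np.ndarray], consecutive_only: bool = False
) -> tuple[float, float]:
    """(ABC, max BC) over a subject's timepoint profiles.

    ``profiles`` maps timepoint label -> composition vector. By default all
    unordered pairs enter the average; ``consecutive_only`` restricts to
    adjacent timepoints in label order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two timepoints for stability")
    tps = sorted(profiles)
    if consecutive_only:
        pairs = list(zip(tps[:-1], tps[1:]))
    else:
        pairs = list(combinations(tps, 2))
    bcs = [bray_curtis(profiles[a], profiles[b]) for a, b in pairs]
    return float(np.mean(bcs)), float(np.max(bcs))


def resistance(profiles: dict[str, np.ndarray]) -> float:
    """BC between T0 and T1; NaN when either anchor is missing."""
    if "T0" not in profiles or "T1" not in profiles:
        return float("nan")
    return bray_curtis(profiles["T0"], profiles["T1"])


def resilience(profiles: dict[str, np.ndarray]) -> float:
    """BC between T0 and T3; NaN when either anchor is missing."""
    if "T0" not in profiles or "T3" not in profiles:
        return float("nan")
    return bray_curtis(profiles["T0"], profiles["T3"])


@dataclass
class StabilityProfile:
    subject: str
    overall: float
    max_bc: float
    resistance: float
    resilience: float
    n_timepoints: int

    @property
    def categories(self) -> dict[str, str]:
        return {
            "overall": categorize(self.overall),
            "resistance": categorize(self.resistance),
            "resilience": categorize(self.resilience),
        }


def subject_profiles(
    rel_abundance: pd.DataFrame, sample_index: pd.DataFrame
) -> dict[str, dict[str, np.ndarray]]:
    """Group per-sample composition vectors by subject and timepoint."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for sid in rel_abundance.columns:
        subject = sample_index.loc[sid, "subject"]
        tp = sample_index.loc[sid, "timepoint"]
        out.setdefault(subject, {})[tp] = rel_abundance[sid].to_numpy()
    return out


def stability_table(
    rel_abundance: pd.DataFrame,
    sample_index: pd.DataFrame,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    """Per-subject stability metrics and categories.

    Subjects with a single timepoint are dropped. ABC uses every available
    pair; resistance/resilience strictly require their anchor timepoints
    and come out NaN (category 'missing') otherwise — flagged via
    ``n_timepoints``.
    """
    rows = []
    for subject, profiles in subject_profiles(rel_abundance, sample_index).items():
        if len(profiles) < 2:
            continue
        abc, mx = overall_stability(profiles, consecutive_only=consecutive_only)
        prof = StabilityProfile(
            subject=subject,
            overall=abc,
            max_bc=mx,
            resistance=resistance(profiles),
            resilience=resilience(profiles),
            n_timepoints=len(profiles),
        )
        cats = prof.categories
        rows.append({
            "subject": subject,
            "overall_stability": prof.overall,
            "max_bc": prof.max_bc,
            "resistance": prof.resistance,
            "resilience": prof.resilience,
            "overall_category": cats["overall"],
            "resistance_category": cats["resistance"],
            "resilience_category": cats["resilience"],
            "n_timepoints": prof.n_timepoints,
        })
    if not rows:
        raise ValueError("no subject has two or more timepoints")
    return pd.DataFrame(rows).set_index("subject")


def compare_stability_groups(
    values: pd.Series, grouping: pd.Series
) -> dict:
    """Kruskal-Wallis comparison of a stability metric between groups
    (e.g. cancer vs healthy, or against an external reference cohort)."""
    groups = [values[grouping == g].dropna().to_numpy() for g in pd.unique(grouping)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups)
    return {
        "test": "kruskal_wallis",
        "statistic": float(stat),
        "p": float(p),
        "group_sizes": [len(g) for g in groups],
        "group_medians": [float(np.median(g)) for g in groups],
    }
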