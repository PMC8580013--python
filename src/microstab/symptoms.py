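"""Symptom-instrument encoding and persistence scoring.

Three instruments are reduced to presence/absence per subject-timepoint:

* clinician CTCAE grades 0-3: present when grade >= 1;
* patient-reported PRO-CTCAE grades 0-4: present when grade >= 1;
* FSFI domain scores 0-6 (higher = better function): the symptom is
  present when the domain score falls below 4.2, and a composite score
  below 26 flags sexual dysfunction;
* vaginal pH 4.0-7.7: below 5 is 'normal', otherwise 'high'.

Presence across the four assessments is collapsed to a persistence
category. The default encoding is: never (0 of 4), occasional (exactly 1),
frequent (2-3), constant (all 4). An alternative coarser 'figure' encoding
(never / occasional = 1-2 / persistent = 3-4) is available.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

FSFI_DOMAIN_CUTOFF = 4.2
FSFI_DYSFUNCTION_CUTOFF = 26.0
PH_CUTOFF = 5.0

CTCAE_SYMPTOMS = ["dyspareunia", "vaginal_pain", "dryness", "hemorrhage",
                  "inflammation", "vaginismus"]
PRO_SYMPTOMS = ["dryness", "itching", "discharge", "bleeding"]


def dichotomize_ctcae(grade: int) -> bool:
    """CTCAE grade -> presence: any non-zero grade counts as present."""
    if not 0 <= grade <= 3:
        raise ValueError(f"CTCAE grade {grade} outside 0-3")
    return grade >= 1


def dichotomize_pro(grade: int) -> bool:
    """PRO-CTCAE grade (0 none ... 4 very severe) -> presence."""
    if not 0 <= grade <= 4:
        raise ValueError(f"PRO-CTCAE grade {grade} outside 0-4")
    return grade >= 1


def fsfi_symptom(domain_score: float) -> bool:
    """FSFI domain score below 4.2 (of 6) marks the symptom present."""
    if not 0.0 <= domain_score <= 6.0:
        raise ValueError(f"FSFI domain score {domain_score} outside 0-6")
    return domain_score < FSFI_DOMAIN_CUTOFF


def fsfi_dysfunction(composite: float) -> bool:
    """Composite FSFI below the validated cutoff of 26 flags dysfunction."""
    if not 0.0 <= composite <= 36.0:
        raise ValueError(f"FSFI composite {composite} outside 0-36")
    return composite < FSFI_DYSFUNCTION_CUTOFF


def ph_category(ph: float) -> str:
    """pH below 5 is 'normal'; 5 and above is 'high'."""
    return "normal" if ph < PH_CUTOFF else "high"


def persistence_score(presence: Sequence[bool], scheme: str = "methods") -> str:
    """Collapse a presence series over assessments to a persistence category.

    ``scheme='methods'``: 0 -> never, 1 -> occasional, 2-3 -> frequent,
    all -> constant. ``scheme='figure'``: 0 -> never, 1-2 -> occasional,
    3-4 -> persistent. With fewer than four assessments the count-based
    mapping is applied to what is available (callers should flag this via
    the returned category together with ``len(presence)``).
    """
    presence = list(presence)
    if not presence:
        raise ValueError("empty presence series")
    n = len(presence)
    k = int(sum(bool(x) for x in presence))
    if scheme == "methods":
        if k == 0:
            return "never"
        if k == 1:
            return "occasional"
        if k < n:
            return "frequent"
        return "constant"
    if scheme == "figure":
        if k == 0:
            return "never"
        if k <= 2 and k < n:
            return "occasional"
        return "persistent"
    raise ValueError(f"unknown persistence scheme {scheme!r}")


def behavior_frequency(series: Sequence[bool], scheme: str = "methods") -> str:
    """Behavioral booleans over assessments use the same categories."""
    return persistence_score(series, scheme=scheme)


# --------------------------------------------------------------------------
# panel-level operations
# --------------------------------------------------------------------------

def presence_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Per sample (subject x timepoint) presence flags for every symptom.

    Expects columns ``ctcae_<name>``, ``pro_<name>``, ``fsfi_<domain>``
    and ``pH`` as produced by the symptom readers/generator.
    """
    out = pd.DataFrame(index=panel.index)
    for s in CTCAE_SYMPTOMS:
        col = f"ctcae_{s}"
        if col in panel:
            out[col] = panel[col].astype(int).map(dichotomize_ctcae)
    for s in PRO_SYMPTOMS:
        col = f"pro_{s}"
        if col in panel:
            out[col] = panel[col].astype(int).map(dichotomize_pro)
    for dom in ["lubrication", "pain"]:  # the two FSFI proxies of vaginal health
        col = f"fsfi_{dom}"
        if col in panel:
            out[col] = panel[col].astype(float).map(fsfi_symptom)
    if "pH" in panel:
        out["ph_high"] = panel["pH"].astype(float).map(lambda v: ph_category(v) == "high")
    return out


def persistence_table(
    presence: pd.DataFrame,
    subjects: pd.Series,
    scheme: str = "methods",
) -> pd.DataFrame:
    """Persistence category per subject x symptom, plus assessments used."""
    rows = {}
    for subject, idx in presence.groupby(subjects).groups.items():
        sub = presence.loc[idx]
        rows[subject] = {
            col: persistence_score(sub[col].tolist(), scheme=scheme)
            for col in presence.columns
        }
        rows[subject]["n_assessments"] = len(sub)
    return pd.DataFrame.from_dict(rows, orient="index")


def symptom_prevalence(
    presence: pd.DataFrame,
    cohorts: pd.Series,
    timepoints: pd.Series,
    timepoint: str,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Cohort symptom proportions at one timepoint with two-proportion
    z-tests, multiplicity-adjusted across symptoms."""
    mask = timepoints == timepoint
    sub = presence.loc[mask]
    coh = cohorts.loc[mask]
    levels = sorted(coh.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two cohorts, found {levels}")
    rows = []
    for col in sub.columns:
        counts = np.array([int(sub.loc[coh == g, col].sum()) for g in levels])
        nobs = np.array([int((coh == g).sum()) for g in levels])
        if (nobs == 0).any():
            raise ValueError(f"empty cohort at timepoint {timepoint}")
        props = counts / nobs
        if props[0] == props[1]:
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest(counts, nobs)
        rows.append({
            "symptom": col, "timepoint": timepoint,
            f"prop_{levels[0]}": props[0], f"prop_{levels[1]}": props[1],
            "z": float(z), "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("symptom")
    out["p_adj"] = multipletests(out["p"], method=adjust)[1]
    return out


def symptom_correlations(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise phi correlations between presence flags.

    Constant flags have undefined correlation and yield NaN.
    """
    x = presence.astype(float)
    cols = list(x.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            va, vb = x[a], x[b]
            if va.std(ddof=0) == 0 or vb.std(ddof=0) == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(va, vb)[0])
            out.loc[a, b] = out.loc[b, a] = r
    return out
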