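"""Dataset-quality gate: coverage, low-yield exclusion, blank screening.

The screening logic mirrors a blank-anchored QC policy: estimate per-sample
Good's coverage, exclude any dataset whose total yield falls below the
largest blank yield (all blanks are excluded from analysis by
construction), and report — without removing — the genera observed in
blanks together with their prevalence in real samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microstab.tables import GenusCountTable

DEFAULT_LOW_YIELD = 3200  # fallback read cutoff when no blanks are supplied


def goods_coverage(counts) -> float:
    """Good's coverage estimator ``1 - f1/N``.

    ``f1`` is the number of genera observed exactly once and ``N`` the
    total reads; the result estimates the probability that the next read
    belongs to an already-observed genus.
    """
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty count vector")
    n = c.sum()
    if n <= 0:
        raise ValueError("total reads must be positive")
    f1 = int((c == 1).sum())
    return 1.0 - f1 / n


def chao_corrected_coverage(counts) -> float:
    """Chao's sample-size-corrected variant: ``1 - (f1/N) * ((N-1)f1 / ((N-1)f1 + 2 f2))``."""
    c = np.asarray(counts)
    n = c.sum()
    if n <= 0:
        raise ValueError("total reads must be positive")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        return 1.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))


@dataclass
class QCReport:
    totals: pd.Series  # per-sample total reads
    coverage: pd.Series  # per-sample Good's coverage
    threshold: float
    excluded: list[str]  # sample ids removed, with reasons
    exclusion_reasons: dict[str, str]
    contaminants: pd.DataFrame = field(default_factory=pd.DataFrame)
    max_blank_yield: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"total_reads": self.totals, "goods_coverage": self.coverage})
        df["excluded"] = [s in set(self.excluded) for s in df.index]
        df["reason"] = [self.exclusion_reasons.get(s, "") for s in df.index]
        return df


def filter_low_yield(
    table: GenusCountTable,
    threshold: float | None = None,
    blanks: GenusCountTable | None = None,
) -> tuple[GenusCountTable, list[str]]:
    """Drop samples whose total yield is below ``threshold`` reads.

    The default threshold is the maximum total yield observed among the
    supplied blanks (falling back to 3,200 when none are given), so every
    dataset no better than a sequencing blank is removed. Comparison is
    strict: a total of exactly ``threshold`` is retained. Blank columns in
    ``table`` itself are always excluded from the analysis table.
    """
    if threshold is None:
        if blanks is not None and blanks.data.shape[1] > 0:
            threshold = float(blanks.totals().max())
        else:
            threshold = float(DEFAULT_LOW_YIELD)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = table.totals()
    idx = table.sample_index
    keep, excluded = [], []
    for sid in table.samples:
        if idx.loc[sid, "is_blank"] or totals[sid] < threshold:
            excluded.append(sid)
        else:
            keep.append(sid)
    if not keep:
        raise ValueError("low-yield filter excluded every sample")
    return table.subset_samples(keep), excluded


def screen_contaminants(
    table: GenusCountTable, blanks: GenusCountTable | None
) -> pd.DataFrame:
    """Report genera observed in blanks, with occurrence counts.

    Report-only: nothing is subtracted from the sample table. For each
    genus present in at least one blank, the report gives the number of
    blanks containing it, the number of real samples containing it, and a
    ``blank_exclusive`` flag for genera never seen in any real sample.
    """
    if blanks is None or blanks.data.shape[1] == 0:
        warnings.warn("no blanks supplied; contamination screen is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["n_blanks_present", "n_samples_present", "blank_exclusive"]
        )
    present_blank = (blanks.data > 0).sum(axis=1)
    flagged = present_blank[present_blank > 0]
    shared = table.data.reindex(flagged.index, fill_value=0)
    present_samples = (shared > 0).sum(axis=1)
    report = pd.DataFrame(
        {
            "n_blanks_present": flagged.astype(int),
            "n_samples_present": present_samples.astype(int),
        }
    )
    report["blank_exclusive"] = report["n_samples_present"] == 0
    return report.sort_values("n_blanks_present", ascending=False)


def qc_screen(
    table: GenusCountTable,
    blanks: GenusCountTable | None = None,
    threshold: float | None = None,
) -> tuple[GenusCountTable, QCReport]:
    """Full QC pass: coverage, low-yield exclusion, contaminant report."""
    totals = table.totals()
    coverage = pd.Series(
        {s: goods_coverage(table.data[s].to_numpy()) for s in table.samples if totals[s] > 0}
    )
    max_blank = float(blanks.totals().max()) if blanks is not None and blanks.data.shape[1] else None
    filtered, excluded = filter_low_yield(table, threshold=threshold, blanks=blanks)
    idx = table.sample_index
    reasons = {
        s: "blank" if idx.loc[s, "is_blank"] else "low_yield" for s in excluded
    }
    report = QCReport(
        totals=totals,
        coverage=coverage,
        threshold=threshold if threshold is not None else (max_blank or DEFAULT_LOW_YIELD),
        excluded=excluded,
        exclusion_reasons=reasons,
        contaminants=screen_contaminants(table, blanks) if blanks is not None else pd.DataFrame(),
        max_blank_yield=max_blank,
    )
    return filtered, report
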