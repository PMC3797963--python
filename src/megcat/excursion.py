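"""Excursion significance test and group-level p-value combination.

An excursion is a maximal run of consecutive time bins whose χ²
discriminability exceeds a threshold; runs of a single bin are pruned as
isolated events.  Each excursion's mass is the sum of the statistic over
its bins.  Significance is assessed by recomputing excursions on
label-shuffled null traces and ranking an observed summary (maximum
region mass by default) within the null summaries:

    p = (1 + #{null >= observed}) / (n_perm + 1),

so the smallest attainable p with 100 permutations is 1/101.  Independent
subject-level p-values are combined with Fisher's method,
-2 Σ ln p_i ~ χ²(2k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .discriminability import DiscriminabilityTrace, NullTraceSet

DEFAULT_THRESHOLD = 20.0
MIN_RUN_BINS = 2
SUMMARIES = ("max_mass", "total_mass")


@dataclass
class ExcursionRegions:
    """Contiguous supra-threshold temporal regions of one trace."""

    regions: list[tuple[int, int]]  # inclusive [start_bin, end_bin]
    masses: np.ndarray
    threshold: float
    bin_centers_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.regions) != self.masses.size:
            raise ValueError("one mass per region required")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def summary(self, kind: str = "max_mass") -> float:
        """Scalar summary for the permutation ranking; 0.0 when empty."""
        if kind not in SUMMARIES:
            raise ValueError(f"summary must be one of {SUMMARIES}")
        if self.masses.size == 0:
            return 0.0
        return float(self.masses.max() if kind == "max_mass" else self.masses.sum())

    def regions_ms(self) -> list[tuple[float, float]]:
        """Regions as (start_ms, end_ms) using the bin centres of the endpoints."""
        if self.bin_centers_ms is None:
            raise ValueError("no bin grid attached")
        return [
            (float(self.bin_centers_ms[a]), float(self.bin_centers_ms[b]))
            for a, b in self.regions
        ]


@dataclass
class ExcursionTestResult:
    observed: ExcursionRegions
    null_summaries: np.ndarray
    p_value: float
    summary: str = "max_mass"

    def to_dict(self) -> dict:
        out = {
            "threshold": self.observed.threshold,
            "summary": self.summary,
            "observed_summary": self.observed.summary(self.summary),
            "n_perm": int(self.null_summaries.size),
            "p_value": self.p_value,
            "regions_bins": [list(r) for r in self.observed.regions],
            "masses": self.observed.masses.tolist(),
        }
        if self.observed.bin_centers_ms is not None:
            out["regions_ms"] = [list(r) for r in self.observed.regions_ms()]
        return out


@dataclass(frozen=True)
class GroupCombination:
    """Fisher's-method combination of independent subject p-values."""

    subject_p_values: np.ndarray
    fisher_statistic: float
    combined_p: float
    df: int

    def to_dict(self) -> dict:
        return {
            "subject_p_values": np.asarray(self.subject_p_values).tolist(),
            "fisher_statistic": self.fisher_statistic,
            "df": self.df,
            "combined_p": self.combined_p,
        }


def find_excursions(
    trace: DiscriminabilityTrace | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> ExcursionRegions:
    """Maximal runs of >= 2 consecutive supra-threshold bins and their masses."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(trace, DiscriminabilityTrace):
        values = trace.chi2
        centers = trace.bin_centers_ms
    else:
        values = np.asarray(trace, dtype=float)
        centers = None
    above = values > threshold
    regions: list[tuple[int, int]] = []
    masses: list[float] = []
    start = None
    for k, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= MIN_RUN_BINS:  # prune isolated single-bin events
                regions.append((start, k - 1))
                masses.append(float(values[start:k].sum()))
            start = None
    return ExcursionRegions(
        regions=regions, masses=np.array(masses), threshold=threshold,
        bin_centers_ms=centers,
    )


def excursion_pvalue(
    observed: ExcursionRegions | DiscriminabilityTrace,
    nulls: NullTraceSet,
    threshold: float = DEFAULT_THRESHOLD,
    summary: str = "max_mass",
) -> ExcursionTestResult:
    """Permutation p-value for the observed excursions against null traces.

    Per permutation, excursions are recomputed on the null trace and the
    same summary recorded (0 when no excursion survives).  An empty
    observed region set yields p = 1.
    """
    if isinstance(observed, DiscriminabilityTrace):
        observed = find_excursions(observed, threshold)
    obs = observed.summary(summary)
    null_summaries = np.array(
        [find_excursions(nulls.traces[i], threshold).summary(summary)
         for i in range(nulls.n_perm)]
    )
    if observed.n_regions == 0:
        p = 1.0
    else:
        p = (1.0 + np.sum(null_summaries >= obs)) / (nulls.n_perm + 1.0)
    return ExcursionTestResult(
        observed=observed, null_summaries=null_summaries,
        p_value=float(p), summary=summary,
    )


def fisher_combine(p_values) -> GroupCombination:
    """Fisher's method: -2 Σ ln p_i referred to the χ²(2k) upper tail."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    combined = float(stats.chi2.sf(statistic, df))
    return GroupCombination(
        subject_p_values=p, fisher_statistic=statistic, combined_p=combined, df=df
    )
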