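"""Percentile-rank scores against reference cohort distributions.

A polygenic risk score is a relative quantity: it only becomes
interpretable next to the score distribution of a reference cohort of
similar ancestry.  This module holds precomputed cohort distributions,
ranks query scores against them with the mid-rank percentile convention
(strictly-below count plus half the ties), and emits distribution
summaries.  Under mid-rank, ranking a cohort against itself averages to
the 50th percentile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DISTRIBUTION_COLUMNS = ["cohort", "studyID", "sampleID", "score"]


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    min: float
    max: float
    mean: float
    median: float
    q1: float
    q3: float


class CohortDistribution:
    """Sorted score vector of one (cohort, study) reference population."""

    def __init__(self, cohort: str, study_id: str, scores: Sequence[float]):
        arr = np.sort(np.asarray(scores, dtype=float))
        if arr.size == 0:
            raise ValueError("cohort distribution must contain at least one score")
        self.cohort = cohort
        self.study_id = study_id
        self.scores = arr

    @property
    def n(self) -> int:
        return int(self.scores.size)

    def summary(self) -> DistributionSummary:
        return summarize_distribution(self.scores)


def percentile_rank(score: float, distribution: CohortDistribution) -> float:
    """Mid-rank percentile of ``score`` within the cohort, in [0, 100].

    percentile = 100 × (#strictly below + ½·#equal) / n.  Ties contribute
    half a rank, so a score equal to every cohort member sits at 50.
    """
    arr = distribution.scores
    below = int(np.searchsorted(arr, score, side="left"))
    equal = int(np.searchsorted(arr, score, side="right")) - below
    return 100.0 * (below + 0.5 * equal) / arr.size


def summarize_distribution(scores: Sequence[float]) -> DistributionSummary:
    """Min/max/mean/median and linearly interpolated quartiles."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return DistributionSummary(
        n=int(arr.size), min=float(arr.min()), max=float(arr.max()),
        mean=float(arr.mean()), median=float(med), q1=float(q1), q3=float(q3),
    )


def read_distributions(path: str | Path) -> dict[tuple[str, str], CohortDistribution]:
    """Read a cohort-distribution TSV (cohort, studyID, sampleID, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"cohort": str, "studyID": str,
                                            "sampleID": str})
    missing = [c for c in DISTRIBUTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"distribution file missing column(s): {missing}")
    out: dict[tuple[str, str], CohortDistribution] = {}
    for (cohort, study_id), grp in df.groupby(["cohort", "studyID"], sort=True):
        out[(cohort, study_id)] = CohortDistribution(
            cohort, study_id, grp["score"].to_numpy()
        )
    return out


def write_distributions(
    path: str | Path, distributions: dict[tuple[str, str], "CohortDistribution"],
    sample_ids: dict[tuple[str, str], Sequence[str]] | None = None,
) -> None:
    rows = []
    for (cohort, study_id), dist in sorted(distributions.items()):
        ids = (sample_ids or {}).get((cohort, study_id))
        for i, score in enumerate(dist.scores):
            rows.append({
                "cohort": cohort, "studyID": study_id,
                "sampleID": ids[i] if ids is not None else f"s{i}",
                "score": score,
            })
    pd.DataFrame(rows, columns=DISTRIBUTION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_summaries(
    path: str | Path, distributions: dict[tuple[str, str], CohortDistribution]
) -> None:
    """Summary-statistics table, one row per (cohort, study).

    Quartiles use linear interpolation between order statistics (recorded
    here so downstream consumers know the convention).
    """
    rows = []
    for (cohort, study_id), dist in sorted(distributions.items()):
        s = dist.summary()
        rows.append({
            "cohort": cohort, "studyID": study_id, "n": s.n,
            "min": s.min, "q1": s.q1, "median": s.median, "q3": s.q3,
            "max": s.max, "mean": s.mean, "quantileConvention": "linear",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
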