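"""Group-separation scans over per-study score tables.

Given polygenic risk scores for many studies and a binary labeling of the
samples (e.g. a threshold on a clinical rating), each study's two score
distributions are compared with a Mann-Whitney U test (the default, since
risk-score distributions are frequently non-normal by a Kolmogorov-Smirnov
check) or a Welch two-sample t-test, under a Bonferroni-corrected family
significance level.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated; beyond it (or with ties) the normal
#: approximation with tie and continuity corrections is used.
EXACT_MWU_LIMIT = 12


@dataclass(frozen=True)
class GroupedScores:
    study_id: str
    trait: str
    group_a: np.ndarray
    group_b: np.ndarray
    grouping_rule: str = ""


@dataclass(frozen=True)
class ScanResult:
    study_id: str
    trait: str
    test: str
    statistic: float
    p_value: float
    adjusted_alpha: float
    significant: bool
    n_a: int
    n_b: int


def ks_normality(scores: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test of normality with fitted mean and SD.

    D is the supremum gap between the empirical CDF and the normal CDF
    with the sample's mean and (ddof=1) standard deviation; the p-value
    comes from the asymptotic KS distribution.  No small-sample
    (Lilliefors) correction is applied.  A zero-variance sample is
    non-normal by convention: returns (1.0, 0.0) with a warning.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 5:
        raise ValueError("KS normality test requires at least 5 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance sample: non-normal by convention")
        return 1.0, 0.0
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), sd), mode="asymp")
    return float(res.statistic), float(res.pvalue)


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: Σ over pairs of [aᵢ > bⱼ] + ½·[aᵢ = bⱼ] (via ranks)."""
    n_a = a.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:n_a].sum())
    return r_a - n_a * (n_a + 1) / 2.0


def _mwu_exact_p(u: float, n_a: int, n_b: int, combined: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n_a+n_b, n_a) labelings."""
    total = 0
    count_le = 0
    count_ge = 0
    idx = range(combined.size)
    for subset in itertools.combinations(idx, n_a):
        mask = np.zeros(combined.size, dtype=bool)
        mask[list(subset)] = True
        u_perm = _mwu_statistic(combined[mask], combined[~mask])
        total += 1
        if u_perm <= u + 1e-9:
            count_le += 1
        if u_perm >= u - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided; returns (U for group a, p).

    The exact null distribution is enumerated when the combined sample
    size is at most 12 and there are no ties; otherwise the normal
    approximation with tie correction and a 0.5 continuity correction is
    used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    u = _mwu_statistic(a, b)
    has_ties = np.unique(combined).size < combined.size
    if n_a + n_b <= EXACT_MWU_LIMIT and not has_ties:
        return u, _mwu_exact_p(u, n_a, n_b, combined)
    n = n_a + n_b
    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0  # all observations tied: no evidence either way
    # continuity correction pulls |U - mean| toward the null by 0.5
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return u, float(2.0 * stats.norm.sf(z))


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, two-sided p, Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test requires at least 2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, float(a.size + b.size - 2)
        raise ValueError("both groups constant with unequal means: t undefined")
    se2_a, se2_b = va / a.size, vb / b.size
    t = float((np.mean(a) - np.mean(b)) / math.sqrt(se2_a + se2_b))
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (a.size - 1) + se2_b**2 / (b.size - 1)
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, float(df)


def group_scores(
    scores: pd.DataFrame, labels: Mapping[str, object], grouping_rule: str = ""
) -> list[GroupedScores]:
    """Split a long-form score table (sample, studyID, trait, score) by label.

    ``labels`` maps sample ID to one of exactly two group values; the
    lexicographically smaller group value becomes group A.  Samples
    without a label are ignored.
    """
    values = sorted({str(v) for v in labels.values()})
    if len(values) != 2:
        raise ValueError(f"labels must define exactly 2 groups, got {values}")
    grp_a, grp_b = values
    out = []
    for (study_id, trait), grp in scores.groupby(["studyID", "trait"], sort=True):
        lab = grp["sample"].map(lambda s: str(labels.get(s)) if s in labels else None)
        a = grp.loc[lab == grp_a, "score"].to_numpy(dtype=float)
        b = grp.loc[lab == grp_b, "score"].to_numpy(dtype=float)
        out.append(GroupedScores(study_id, trait, a, b, grouping_rule))
    return out


def threshold_labels(ratings: Mapping[str, float], threshold: float) -> dict[str, str]:
    """Binary labels from a clinical rating: 'high' if rating ≥ threshold."""
    return {s: ("high" if r >= threshold else "low") for s, r in ratings.items()}


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column label TSV (sampleID, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sampleID", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"label file missing column(s): {missing}")
    return dict(zip(df["sampleID"], df["group"]))


def scan_studies(
    grouped: Sequence[GroupedScores],
    test: str = "mann_whitney",
    family_alpha: float = 0.05,
) -> list[ScanResult]:
    """Test every study's group separation under Bonferroni correction.

    The adjusted significance level is family_alpha divided by the number
    of studies actually tested; studies with fewer than two scores in
    either group are skipped (and do not count toward the divisor).
    Results are sorted by ascending p-value.
    """
    if test not in ("mann_whitney", "welch_t"):
        raise ValueError(f"unknown test {test!r}")
    testable = []
    for g in grouped:
        if g.group_a.size < 2 or g.group_b.size < 2:
            warnings.warn(
                f"{g.study_id}/{g.trait}: fewer than 2 scores in a group; skipped"
            )
            continue
        testable.append(g)
    if not testable:
        return []
    adjusted_alpha = bonferroni_alpha(family_alpha, len(testable))
    results = []
    for g in testable:
        if test == "mann_whitney":
            stat, p = mann_whitney(g.group_a, g.group_b)
        else:
            stat, p, _ = welch_t(g.group_a, g.group_b)
        results.append(ScanResult(
            study_id=g.study_id, trait=g.trait, test=test,
            statistic=stat, p_value=p, adjusted_alpha=adjusted_alpha,
            significant=p < adjusted_alpha,
            n_a=int(g.group_a.size), n_b=int(g.group_b.size),
        ))
    return sorted(results, key=lambda r: (r.p_value, r.study_id, r.trait))


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level under Bonferroni correction."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


def write_scan_results(path: str | Path, results: Sequence[ScanResult]) -> None:
    pd.DataFrame([
        {
            "studyID": r.study_id, "trait": r.trait, "test": r.test,
            "statistic": r.statistic, "p": r.p_value,
            "adjustedAlpha": r.adjusted_alpha, "significant": r.significant,
            "nGroupA": r.n_a, "nGroupB": r.n_b,
        }
        for r in results
    ]).to_csv(path, sep="\t", index=False)
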