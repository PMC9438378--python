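"""The clump-and-threshold additive scoring engine.

For each GWA study the engine: thresholds associations on the GWAS p-value,
optionally filters on minor allele frequency, matches associations to the
target genotypes (by rsID first, then by chromosome and position, so merged
or relabeled accessions still match), resolves LD clumps by keeping the
most significant variant per clump, imputes missing genotypes as
2 × risk-allele frequency, and averages effects into one score per sample:

* beta study:        score = (Σ βᵢ·dᵢ) / M
* odds-ratio study:  score = exp((Σ ln ORᵢ·dᵢ) / M)

with dᵢ the risk-allele dosage and M the number of variants retained after
clumping.  A genome with zero risk alleles therefore scores exactly 1.0
(odds ratios) or 0.0 (betas).  Sample×study entries whose imputed fraction
exceeds a threshold (default one half) are excluded from output.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from prskit.ldclump import ClumpTable, ReferencePanel, normalize_chrom
from prskit.sumstats import COMPLEMENT, AssociationRecord


class DosageStatus(enum.Enum):
    OBSERVED = "observed"
    MISSING = "missing"
    UNMATCHED_ALLELE = "unmatched_allele"


class TargetSite(Protocol):
    """One biallelic site of the target genotypes (see prskit.io)."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    alt_dosage: np.ndarray  # per-sample alt count, NaN = missing


class TargetGenotypes(Protocol):
    samples: Sequence[str]
    sites: Sequence[TargetSite]

    def lookup(self, rsid: str, chrom: str, pos: int) -> int | None: ...


@dataclass
class MatchedVariant:
    """An association joined to a target site (or flagged absent)."""

    association: AssociationRecord
    site_index: int | None  # None = absent from target
    clump_id: int = 0

    @property
    def absent(self) -> bool:
        return self.site_index is None


@dataclass
class ScoreEntry:
    """One (sample, study) row of the score report."""

    sample: str
    study_id: str
    trait: str
    build: str
    population: str
    effect_type: str
    score: float
    n_included: int
    n_imputed: int
    risk_variants: list[str] = field(default_factory=list)
    protective_variants: list[str] = field(default_factory=list)
    clumped_out: list[str] = field(default_factory=list)
    imputed_variants: list[str] = field(default_factory=list)
    percentile: float | None = None
    excluded: bool = False
    exclude_reason: str = ""


def apply_pvalue_threshold(
    associations: Iterable[AssociationRecord], cutoff: float
) -> list[AssociationRecord]:
    """Keep associations with GWAS p-value ≤ cutoff; cutoff must be in (0, 1]."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"p-value cutoff must be in (0, 1], got {cutoff}")
    return [a for a in associations if a.p_value <= cutoff]


def apply_maf_filter(
    associations: Iterable[AssociationRecord],
    min_maf: float,
    panel: ReferencePanel | None = None,
) -> list[AssociationRecord]:
    """Drop associations whose minor-allele frequency is below ``min_maf``.

    The reported risk-allele frequency is used (folded to the minor side);
    when absent, the reference panel frequency; a record with no frequency
    from either source is kept with a warning.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {min_maf}")
    kept = []
    for a in associations:
        freq = a.ref_allele_freq
        if freq is None and panel is not None:
            freq = panel.risk_allele_freq(a.rsid, a.risk_allele)
        if freq is None:
            warnings.warn(f"{a.rsid}: no allele frequency available; kept despite MAF filter")
            kept.append(a)
        elif min(freq, 1.0 - freq) >= min_maf:
            kept.append(a)
    return kept


def match_variants(
    associations: Iterable[AssociationRecord], target: TargetGenotypes
) -> list[MatchedVariant]:
    """Join associations to target sites: rsID first, then (chrom, pos).

    Associations matching no target site are flagged absent; their
    genotypes are imputed downstream rather than dropped.
    """
    return [
        MatchedVariant(a, target.lookup(a.rsid, a.chrom, a.pos))
        for a in associations
    ]


def extract_dosage(
    site: TargetSite, risk_allele: str, sample: int
) -> tuple[float | None, DosageStatus]:
    """Risk-allele dosage for one sample at one biallelic site.

    Risk allele equal to ALT counts alt alleles; equal to REF counts
    2 − alt.  A strand mismatch between summary statistics and target is
    tolerated: the complement of the risk allele is tried when the allele
    itself matches neither REF nor ALT.  Missing genotypes return
    (None, MISSING); an allele matching neither strand returns
    (None, UNMATCHED_ALLELE) and is imputed downstream.
    """
    allele = risk_allele
    if allele not in (site.ref, site.alt):
        allele = COMPLEMENT.get(allele, "")
    if allele not in (site.ref, site.alt):
        # text-genotype pseudo-sites list the complete genotype, so an
        # unlisted allele is genuinely absent (zero copies), not dropout
        if getattr(site, "zero_when_unmatched", False):
            return 0.0, DosageStatus.OBSERVED
        return None, DosageStatus.UNMATCHED_ALLELE
    raw = site.alt_dosage[sample]
    if np.isnan(raw):
        return None, DosageStatus.MISSING
    d = float(raw) if allele == site.alt else 2.0 - float(raw)
    return d, DosageStatus.OBSERVED


def assign_clumps(
    matches: Sequence[MatchedVariant],
    clump_table: ClumpTable | None,
    population: str,
    build: str,
) -> None:
    """Fill clump IDs in place; variants absent from the table form singletons."""
    known = []
    for m in matches:
        cid = None
        if clump_table is not None:
            cid = clump_table.clump_id(population, build, rsid=m.association.rsid,
                                       chrom=m.association.chrom, pos=m.association.pos)
        if cid is not None:
            known.append(cid)
        m.clump_id = cid if cid is not None else 0
    # singleton IDs start past the table's range so they never collide
    next_singleton = (max(known) if known else 0) + 1
    for m in matches:
        if m.clump_id == 0:
            m.clump_id = next_singleton
            next_singleton += 1


def resolve_clumps(
    matches: Sequence[MatchedVariant],
) -> tuple[list[MatchedVariant], list[MatchedVariant]]:
    """Keep one variant per clump: the most significant GWAS p-value.

    Ties break by (chrom, pos), then lexicographic rsID.  Returns
    (retained, clumped_out); the union is the input set.
    """
    def sort_key(m: MatchedVariant):
        a = m.association
        return (a.p_value, normalize_chrom(a.chrom), a.pos, a.rsid)

    best: dict[int, MatchedVariant] = {}
    for m in matches:
        cur = best.get(m.clump_id)
        if cur is None or sort_key(m) < sort_key(cur):
            best[m.clump_id] = m
    retained = [m for m in matches if best[m.clump_id] is m]
    clumped_out = [m for m in matches if best[m.clump_id] is not m]
    return retained, clumped_out


def impute_missing(
    association: AssociationRecord,
    maf_source: str,
    sample_freq: float | None,
    panel_freq: float | None,
) -> float | None:
    """Imputed dosage for a missing genotype: 2 × risk-allele frequency.

    ``maf_source`` picks which frequency is preferred ("sample" = frequency
    in the target cohort's non-missing calls, "reference" = reference-panel
    frequency); the other source, then the association's reported
    frequency, serve as fallbacks.  Returns None when no frequency is
    available from any source (the variant is then dropped from that
    sample's score).
    """
    if maf_source not in ("sample", "reference"):
        raise ValueError(f"unknown MAF source {maf_source!r}")
    order = (sample_freq, panel_freq) if maf_source == "sample" else (panel_freq, sample_freq)
    for freq in (*order, association.ref_allele_freq):
        if freq is not None:
            return 2.0 * float(freq)
    return None


def compute_score(
    effects: Sequence[tuple[float, str]], dosages: Sequence[float]
) -> float:
    """Average retained effects weighted by dosage into one sample's score.

    ``effects`` is a sequence of (effect_value, effect_type) homogeneous in
    type.  Beta studies average βᵢ·dᵢ; odds-ratio studies average in
    ln-OR space and exponentiate, which centres the null score at 1.0.
    """
    if not effects:
        raise ValueError("no variants to score")
    if len(effects) != len(dosages):
        raise ValueError("effects and dosages must align")
    types = {t for _, t in effects}
    if len(types) > 1:
        raise ValueError(f"mixed effect types in one study: {sorted(types)}")
    effect_type = types.pop()
    m = len(effects)
    if effect_type == "odds_ratio":
        total = sum(math.log(v) * d for (v, _), d in zip(effects, dosages))
        return math.exp(total / m)
    total = sum(v * d for (v, _), d in zip(effects, dosages))
    return total / m


def sample_risk_allele_freq(site: TargetSite, risk_allele: str) -> float | None:
    """Risk-allele frequency over the target cohort's non-missing calls."""
    allele = risk_allele
    if allele not in (site.ref, site.alt):
        allele = COMPLEMENT.get(allele, "")
    if allele not in (site.ref, site.alt):
        return None
    d = site.alt_dosage[~np.isnan(site.alt_dosage)]
    if d.size == 0:
        return None
    alt_freq = float(d.sum()) / (2 * d.size)
    return alt_freq if allele == site.alt else 1.0 - alt_freq


def apply_imputation_threshold(
    entries: Iterable[ScoreEntry], max_imputed_fraction: float = 0.5
) -> tuple[list[ScoreEntry], list[ScoreEntry]]:
    """Exclude entries whose imputed fraction exceeds the threshold.

    The boundary case (imputed fraction exactly equal to the threshold) is
    retained: with the default of one half, at least half of the genotypes
    entering the score must come from the sample itself.
    """
    if not (0.0 <= max_imputed_fraction <= 1.0):
        raise ValueError("imputation threshold must be in [0, 1]")
    kept: list[ScoreEntry] = []
    excluded: list[ScoreEntry] = []
    for e in entries:
        if e.n_included > 0 and e.n_imputed / e.n_included > max_imputed_fraction:
            e.excluded = True
            e.exclude_reason = "imputation_threshold"
            excluded.append(e)
        else:
            kept.append(e)
    return kept, excluded


def score_study(
    associations: Sequence[AssociationRecord],
    target: TargetGenotypes,
    *,
    study_id: str,
    trait: str,
    build: str,
    population: str,
    clump_table: ClumpTable | None = None,
    panel: ReferencePanel | None = None,
    p_cutoff: float = 0.05,
    maf_threshold: float = 0.0,
    maf_source: str = "sample",
) -> list[ScoreEntry]:
    """Score every target sample for one study's associations.

    Runs the full per-study C+T pipeline (threshold → MAF filter → match →
    clump resolution → dosage extraction with imputation → averaging) and
    returns one entry per sample.  Entries are not yet filtered by the
    imputation threshold; see :func:`apply_imputation_threshold`.
    """
    assocs = apply_pvalue_threshold(associations, p_cutoff)
    if maf_threshold > 0:
        assocs = apply_maf_filter(assocs, maf_threshold, panel)
    matches = match_variants(assocs, target)
    assign_clumps(matches, clump_table, population, build)
    retained, clumped_out = resolve_clumps(matches)
    clumped_rsids = sorted(m.association.rsid for m in clumped_out)

    # per-variant frequencies shared across samples
    freqs: list[tuple[float | None, float | None]] = []
    for m in retained:
        a = m.association
        sfreq = (sample_risk_allele_freq(target.sites[m.site_index], a.risk_allele)
                 if m.site_index is not None else None)
        pfreq = panel.risk_allele_freq(a.rsid, a.risk_allele) if panel is not None else None
        freqs.append((sfreq, pfreq))

    entries: list[ScoreEntry] = []
    for s, sample in enumerate(target.samples):
        effects: list[tuple[float, str]] = []
        dosages: list[float] = []
        imputed: list[str] = []
        risk: list[str] = []
        protective: list[str] = []
        for m, (sfreq, pfreq) in zip(retained, freqs):
            a = m.association
            if m.site_index is not None:
                d, status = extract_dosage(target.sites[m.site_index], a.risk_allele, s)
            else:
                d, status = None, DosageStatus.MISSING
            if status is not DosageStatus.OBSERVED:
                d = impute_missing(a, maf_source, sfreq, pfreq)
                if d is None:
                    warnings.warn(
                        f"{a.rsid}: no frequency from any source; dropped for {sample}"
                    )
                    continue
                imputed.append(a.rsid)
            effects.append((a.effect_value, a.effect_type))
            dosages.append(d)
            if d > 0:
                increases = (a.effect_value > 1.0 if a.effect_type == "odds_ratio"
                             else a.effect_value > 0.0)
                decreases = (a.effect_value < 1.0 if a.effect_type == "odds_ratio"
                             else a.effect_value < 0.0)
                if increases:
                    risk.append(a.rsid)
                elif decreases:
                    protective.append(a.rsid)
        effect_type = retained[0].association.effect_type if retained else ""
        if not effects:
            entries.append(ScoreEntry(
                sample=sample, study_id=study_id, trait=trait, build=build,
                population=population, effect_type=effect_type,
                score=float("nan"), n_included=0, n_imputed=0,
                clumped_out=clumped_rsids, excluded=True,
                exclude_reason="no_variants",
            ))
            continue
        entries.append(ScoreEntry(
            sample=sample, study_id=study_id, trait=trait, build=build,
            population=population, effect_type=effect_type,
            score=compute_score(effects, dosages),
            n_included=len(effects), n_imputed=len(imputed),
            risk_variants=sorted(risk), protective_variants=sorted(protective),
            clumped_out=clumped_rsids, imputed_variants=sorted(imputed),
        ))
    return entries


def score_cohort(
    associations: Sequence[AssociationRecord],
    target: TargetGenotypes,
    *,
    build: str,
    population: str,
    clump_table: ClumpTable | None = None,
    panel: ReferencePanel | None = None,
    p_cutoff: float = 0.05,
    maf_threshold: float = 0.0,
    maf_source: str = "sample",
    max_imputed_fraction: float = 0.5,
    study_ids: Sequence[str] | None = None,
) -> tuple[list[ScoreEntry], list[ScoreEntry]]:
    """Score every (sample, study) pair; apply the imputation threshold.

    Associations are grouped by (study_id, trait); each group is scored
    independently.  Returns (kept, excluded) entries, each sorted by
    (study_id, trait, sample) for reproducible output.
    """
    groups: dict[tuple[str, str], list[AssociationRecord]] = {}
    for a in associations:
        groups.setdefault((a.study_id, a.trait), []).append(a)
    if study_ids is not None:
        wanted = set(study_ids)
        groups = {k: v for k, v in groups.items() if k[0] in wanted}
    entries: list[ScoreEntry] = []
    for (study_id, trait) in sorted(groups):
        entries.extend(score_study(
            groups[(study_id, trait)], target,
            study_id=study_id, trait=trait, build=build, population=population,
            clump_table=clump_table, panel=panel, p_cutoff=p_cutoff,
            maf_threshold=maf_threshold, maf_source=maf_source,
        ))
    kept, excluded = apply_imputation_threshold(entries, max_imputed_fraction)
    key = lambda e: (e.study_id, e.trait, e.sample)
    return sorted(kept, key=key), sorted(excluded, key=key)
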