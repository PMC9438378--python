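"""GWAS summary-statistic parsing, filtering and strand harmonization.

Summary statistics arrive as a tab-separated table with one row per
variant-trait association.  Rows are filtered to associations that carry a
risk allele, an effect size (odds ratio or beta, exactly one) and a p-value;
multi-variant risk haplotypes and sex-specific associations are excluded.
Risk alleles reported on the reverse strand are flipped to the forward
strand by checking the reported allele, then its Watson-Crick complement,
against the registry of known alleles for the variant; variants that cannot
be resolved this way are excluded as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

BUILDS = ("hg38", "hg19", "hg18", "hg17")

#: Watson-Crick complement for unambiguous bases; anything else is non-SNP.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Separators that mark a multi-variant risk haplotype in the risk-allele
#: field (GWAS Catalog convention, e.g. "rs1-A; rs2-G" or "rs1-A x rs2-G").
_HAPLOTYPE_SEPARATORS = (";", "x")

#: Mandatory header columns of the summary-statistics dialect.
SUMSTATS_COLUMNS = [
    "studyID", "pubMedID", "trait", "rsID", "chrom",
    "pos_hg38", "pos_hg19", "pos_hg18", "pos_hg17",
    "riskAllele", "oddsRatio", "beta", "pValue", "riskAlleleFreq",
    "sexSpecific", "cohortAncestry",
    "initialSampleSize", "replicationSampleSize", "altmetricScore",
]

REGISTRY_COLUMNS = [
    "rsID", "knownAlleles", "chrom",
    "pos_hg38", "pos_hg19", "pos_hg18", "pos_hg17",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-trait association from a GWA study."""

    study_id: str
    trait: str
    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    effect_value: float
    effect_type: str  # "odds_ratio" or "beta"
    p_value: float
    ref_allele_freq: float | None = None
    sex_specific: bool = False
    flipped: bool = False


@dataclass(frozen=True)
class StudyRecord:
    """Study-level metadata for one (study, trait) combination."""

    study_id: str
    pubmed_id: str
    trait: str
    cohort_ancestry: str
    initial_sample_size: int
    replication_sample_size: int
    altmetric_score: float | None = None
    build: str = "hg38"

    @property
    def total_cohort(self) -> int:
        """Initial plus replication sample size."""
        return self.initial_sample_size + self.replication_sample_size


@dataclass(frozen=True)
class Rejection:
    """A record excluded from analysis, with the reason why."""

    rsid: str
    study_id: str
    reason: str
    line: int | None = None


class AlleleRegistry:
    """rsID -> known forward-strand alleles and per-build positions.

    Stands in for a dbSNP lookup: maps each variant accession to the set
    of alleles observed on the forward strand and its coordinates on each
    genome build.
    """

    def __init__(
        self,
        alleles: Mapping[str, frozenset[str]],
        positions: Mapping[str, Mapping[str, tuple[str, int]]] | None = None,
    ):
        self._alleles = {r: frozenset(a) for r, a in alleles.items()}
        self._positions = {r: dict(p) for r, p in (positions or {}).items()}
        for rsid, known in self._alleles.items():
            if not known:
                raise ValueError(f"registry entry {rsid} has no known alleles")

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._alleles

    def __len__(self) -> int:
        return len(self._alleles)

    def known_alleles(self, rsid: str) -> frozenset[str]:
        return self._alleles[rsid]

    def position(self, rsid: str, build: str) -> tuple[str, int] | None:
        return self._positions.get(rsid, {}).get(build)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleRegistry":
        """Read the registry TSV dialect (rsID, knownAlleles, positions per build)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ("rsID", "knownAlleles") if c not in df.columns]
        if missing:
            raise ValueError(f"allele registry missing mandatory column(s): {missing}")
        alleles: dict[str, frozenset[str]] = {}
        positions: dict[str, dict[str, tuple[str, int]]] = {}
        for row in df.itertuples(index=False):
            rsid = row.rsID
            alleles[rsid] = frozenset(
                a.strip().upper() for a in str(row.knownAlleles).split(",") if a.strip()
            )
            pos: dict[str, tuple[str, int]] = {}
            for build in BUILDS:
                raw = getattr(row, f"pos_{build}", None)
                if raw is not None and not pd.isna(raw) and str(raw).strip():
                    pos[build] = (str(row.chrom), int(float(raw)))
            if pos:
                positions[rsid] = pos
        return cls(alleles, positions)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for rsid in sorted(self._alleles):
            pos = self._positions.get(rsid, {})
            any_chrom = next((c for c, _ in pos.values()), "")
            row = {
                "rsID": rsid,
                "knownAlleles": ",".join(sorted(self._alleles[rsid])),
                "chrom": any_chrom,
            }
            for build in BUILDS:
                row[f"pos_{build}"] = pos.get(build, ("", ""))[1]
            rows.append(row)
        pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class ParseResult:
    associations: list[AssociationRecord]
    studies: list[StudyRecord]
    rejections: list[Rejection] = field(default_factory=list)


def _parse_float(value, default=None):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    s = str(value).strip()
    if not s:
        return default
    return float(s)


def _truthy(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def parse_sumstats(path: str | Path, build: str = "hg38") -> ParseResult:
    """Parse a summary-statistics TSV into association and study records.

    Positions are taken from the ``pos_<build>`` column of the declared
    genome build.  Rows missing an effect size, a risk allele or a p-value,
    and rows with unparsable numeric fields, are excluded and reported in
    the rejection log with their 1-based data line number.

    Raises ``ValueError`` if a mandatory header column is absent.
    """
    if build not in BUILDS:
        raise ValueError(f"unknown genome build {build!r}; expected one of {BUILDS}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty summary-statistics file")
        return ParseResult([], [])
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing mandatory column(s): {missing}")

    associations: list[AssociationRecord] = []
    rejections: list[Rejection] = []
    studies: dict[tuple[str, str], StudyRecord] = {}
    pos_col = f"pos_{build}"

    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rsid = str(row.rsID).strip()
        study_id = str(row.studyID).strip()
        try:
            odds = _parse_float(row.oddsRatio)
            beta = _parse_float(row.beta)
            p_value = _parse_float(row.pValue)
            freq = _parse_float(row.riskAlleleFreq)
            pos = _parse_float(getattr(row, pos_col))
        except ValueError:
            rejections.append(Rejection(rsid, study_id, "unparsable_numeric", line))
            continue
        if (odds is None) == (beta is None):
            reason = "missing_effect" if odds is None else "two_effect_values"
            rejections.append(Rejection(rsid, study_id, reason, line))
            continue
        if p_value is None:
            rejections.append(Rejection(rsid, study_id, "missing_p_value", line))
            continue
        risk_allele = str(row.riskAllele).strip() if not pd.isna(row.riskAllele) else ""
        if not risk_allele:
            rejections.append(Rejection(rsid, study_id, "missing_risk_allele", line))
            continue
        if pos is None:
            rejections.append(Rejection(rsid, study_id, f"missing_{pos_col}", line))
            continue
        associations.append(
            AssociationRecord(
                study_id=study_id,
                trait=str(row.trait).strip(),
                rsid=rsid,
                chrom=str(row.chrom).strip(),
                pos=int(pos),
                risk_allele=risk_allele.upper(),
                effect_value=odds if odds is not None else beta,
                effect_type="odds_ratio" if odds is not None else "beta",
                p_value=p_value,
                ref_allele_freq=freq,
                sex_specific=_truthy(row.sexSpecific),
            )
        )
        key = (study_id, str(row.trait).strip())
        if key not in studies:
            try:
                altmetric = _parse_float(row.altmetricScore)
                initial = int(_parse_float(row.initialSampleSize, 0.0))
                replication = int(_parse_float(row.replicationSampleSize, 0.0))
            except ValueError:
                altmetric, initial, replication = None, 0, 0
            studies[key] = StudyRecord(
                study_id=study_id,
                pubmed_id=str(row.pubMedID).strip(),
                trait=str(row.trait).strip(),
                cohort_ancestry=str(row.cohortAncestry).strip()
                if not pd.isna(row.cohortAncestry) else "",
                initial_sample_size=initial,
                replication_sample_size=replication,
                altmetric_score=altmetric,
                build=build,
            )

    if not associations and not rejections:
        warnings.warn(f"{path}: no data rows")
    return ParseResult(associations, list(studies.values()), rejections)


def is_haplotype(risk_allele_field: str) -> bool:
    """True if the risk-allele field names more than one variant."""
    return any(sep in risk_allele_field.lower() for sep in _HAPLOTYPE_SEPARATORS)


def filter_associations(
    records: Iterable[AssociationRecord],
) -> tuple[list[AssociationRecord], list[Rejection]]:
    """Exclude risk haplotypes and sex-specific associations.

    Every input record lands in exactly one of the returned lists; each
    rejection carries its reason ("haplotype", "sex_specific", or a
    missing-field reason for defensively re-checked mandatory fields).
    """
    kept: list[AssociationRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        if is_haplotype(rec.risk_allele):
            rejected.append(Rejection(rec.rsid, rec.study_id, "haplotype"))
        elif rec.sex_specific:
            rejected.append(Rejection(rec.rsid, rec.study_id, "sex_specific"))
        elif not rec.risk_allele:
            rejected.append(Rejection(rec.rsid, rec.study_id, "missing_risk_allele"))
        else:
            kept.append(rec)
    return kept, rejected


def harmonize_strand(
    record: AssociationRecord, registry: AlleleRegistry
) -> AssociationRecord | Rejection:
    """Flip a reverse-strand risk allele to the forward strand.

    The reported risk allele is checked against the registry's known
    alleles; if absent, its complement is checked and, when found, used
    instead (the record is flagged ``flipped``).  Variants unresolvable by
    this procedure are excluded as ambiguous; variants missing from the
    registry are excluded since their strand cannot be verified.
    """
    allele = record.risk_allele
    if allele not in COMPLEMENT:
        return Rejection(record.rsid, record.study_id, "non_snp")
    if record.rsid not in registry:
        return Rejection(record.rsid, record.study_id, "unknown_variant")
    known = registry.known_alleles(record.rsid)
    if allele in known:
        return record
    complement = COMPLEMENT[allele]
    if complement in known:
        return replace(record, risk_allele=complement, flipped=True)
    return Rejection(record.rsid, record.study_id, "ambiguous")


def harmonize_all(
    records: Iterable[AssociationRecord], registry: AlleleRegistry
) -> tuple[list[AssociationRecord], list[Rejection]]:
    """Apply :func:`harmonize_strand` to every record."""
    kept: list[AssociationRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        out = harmonize_strand(rec, registry)
        (kept if isinstance(out, AssociationRecord) else rejected).append(out)
    return kept, rejected


@dataclass(frozen=True)
class StudyFilters:
    """User-facing study selection: value filters plus a selection mode.

    mode "highest_altmetric" keeps, per trait, the study with the maximal
    Altmetric score; "largest_cohort" keeps the study with the largest
    initial + replication sample size; ties break to the lexicographically
    smallest study ID.
    """

    traits: Sequence[str] = ()
    study_ids: Sequence[str] = ()
    ancestry_contains: str = ""
    mode: str = "all"  # all | highest_altmetric | largest_cohort


def select_studies(
    studies: Sequence[StudyRecord], filters: StudyFilters = StudyFilters()
) -> list[StudyRecord]:
    """Filter study records by trait/ID/ancestry and the selection mode."""
    if filters.mode not in {"all", "highest_altmetric", "largest_cohort"}:
        raise ValueError(f"unknown study-selection mode {filters.mode!r}")
    out = list(studies)
    if filters.traits:
        wanted = {t.lower() for t in filters.traits}
        out = [s for s in out if s.trait.lower() in wanted]
    if filters.study_ids:
        wanted_ids = set(filters.study_ids)
        out = [s for s in out if s.study_id in wanted_ids]
    if filters.ancestry_contains:
        needle = filters.ancestry_contains.lower()
        out = [s for s in out if needle in s.cohort_ancestry.lower()]
    if filters.mode == "all":
        if not out:
            warnings.warn("study selection produced no studies")
        return out

    def keyfun(s: StudyRecord) -> tuple[float, str]:
        if filters.mode == "highest_altmetric":
            score = s.altmetric_score if s.altmetric_score is not None else float("-inf")
        else:
            score = float(s.total_cohort)
        return score, s.study_id

    best: dict[str, StudyRecord] = {}
    for s in out:
        cur = best.get(s.trait)
        if cur is None:
            best[s.trait] = s
            continue
        s_score, s_id = keyfun(s)
        c_score, c_id = keyfun(cur)
        # higher score wins; ties go to the smaller study_id
        if s_score > c_score or (s_score == c_score and s_id < c_id):
            best[s.trait] = s
    result = [best[t] for t in sorted(best)]
    if not result:
        warnings.warn("study selection produced no studies")
    return result
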