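"""Target-genotype readers, report writers, and the two-step pipeline.

Target genotypes come either from a multi-sample VCF (chromosome names
normalized, multiallelic records split into biallelic sites) or from a
plain-text list of "rsID:A1,A2" lines treated as a single sample.  Score
reports are written as condensed TSV (one row per study, one score column
per sample), verbose TSV (one row per sample × study with variant lists
and percentiles), or JSON.

The pipeline runs in one step or two: ``prepare`` bundles the filtered,
harmonized summary statistics and the relevant clump-table slice into a
self-contained working directory; ``calculate`` consumes only that
directory plus the target genotypes, enabling large runs on machines
without access to the original inputs.  Both routes produce byte-identical
output.
"""

from __future__ import annotations

import json
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from prskit import contextualize, scoring, sumstats as ss
from prskit.ldclump import (
    SUPERPOPULATIONS, ClumpTable, ReferencePanel, normalize_chrom,
    read_clump_table, write_clump_table,
)
from prskit.scoring import ScoreEntry
from prskit.sumstats import BUILDS, AssociationRecord, StudyRecord, StudyFilters

OUTPUT_FORMATS = ("condensed_tsv", "verbose_tsv", "json")

VERBOSE_COLUMNS = [
    "sample", "studyID", "trait", "build", "population", "score",
    "effectType", "nIncluded", "nImputed", "percentile",
    "riskVariants", "protectiveVariants", "clumpedOut", "imputedVariants",
]


@dataclass
class TargetSite:
    """One biallelic target site with per-sample alt dosages (NaN missing)."""

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    alt_dosage: np.ndarray
    zero_when_unmatched: bool = False


class TargetData:
    """Target genotypes indexed by rsID and by (chrom, pos)."""

    def __init__(self, samples: Sequence[str], sites: Sequence[TargetSite]):
        self.samples = list(samples)
        self.sites = list(sites)
        self._by_rsid: dict[str, int] = {}
        self._by_pos: dict[tuple[str, int], int] = {}
        for i, site in enumerate(self.sites):
            if site.rsid and site.rsid != ".":
                self._by_rsid.setdefault(site.rsid, i)
            key = (normalize_chrom(site.chrom), site.pos)
            if key in self._by_pos:
                if key != ("", 0):
                    warnings.warn(f"duplicate target site at {key}; keeping first")
            else:
                self._by_pos[key] = i

    def lookup(self, rsid: str, chrom: str, pos: int) -> int | None:
        """rsID match first; fall back to (chrom, pos) for merged accessions."""
        i = self._by_rsid.get(rsid)
        if i is not None:
            return i
        return self._by_pos.get((normalize_chrom(chrom), pos))


def read_target_vcf(path: str | Path, build: str = "hg38") -> TargetData:
    """Read target genotypes from a (possibly gzipped) multi-sample VCF.

    Multiallelic records are split into one biallelic site per ALT allele;
    half-calls and "./." become missing.  Sites with "." IDs remain
    reachable through their (chrom, pos) key.
    """
    from cyvcf2 import VCF

    if build not in BUILDS:
        raise ValueError(f"unknown genome build {build!r}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    sites: list[TargetSite] = []
    for rec in vcf:
        gts = rec.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            dos = (gts == alt_idx).astype(float).sum(axis=1)
            dos[np.isnan(gts).any(axis=1)] = np.nan
            sites.append(TargetSite(
                chrom=normalize_chrom(rec.CHROM), pos=rec.POS,
                rsid=rec.ID if rec.ID not in (None, ".") else ".",
                ref=rec.REF, alt=alt, alt_dosage=dos,
            ))
    vcf.close()
    return TargetData(samples, sites)


def read_text_genotypes(source: str | Path, sample_name: str = "sample1") -> TargetData:
    """Parse "rsID:A1,A2" lines as one sample's genotypes (hg38 context).

    Risk-allele dosage downstream counts occurrences of the risk allele
    (or, failing a direct match, its complement) among the two listed
    alleles; an allele matching neither counts as zero copies, since the
    listed pair is the complete genotype.
    """
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    sites: list[TargetSite] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rsid, alleles = line.split(":")
            a1, a2 = (a.strip().upper() for a in alleles.split(","))
        except ValueError:
            raise ValueError(f"line {lineno}: expected 'rsID:A1,A2', got {line!r}")
        if a1 not in "ACGT" or a2 not in "ACGT" or len(a1) != 1 or len(a2) != 1:
            raise ValueError(f"line {lineno}: alleles must be single bases A/C/G/T")
        rsid = rsid.strip()
        if rsid in seen:
            raise ValueError(f"line {lineno}: duplicate rsID {rsid}")
        seen.add(rsid)
        # encode the allele pair as a pseudo-site: REF = first allele,
        # ALT = second; alt dosage = #ALT among the pair
        sites.append(TargetSite(
            chrom="", pos=0, rsid=rsid, ref=a1, alt=a2,
            alt_dosage=np.array([2.0 if a1 == a2 else 1.0]),
            zero_when_unmatched=True,
        ))
    return TargetData([sample_name], sites)


def _fmt6(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.6g}"


def _verbose_record(e: ScoreEntry) -> dict:
    return {
        "sample": e.sample, "studyID": e.study_id, "trait": e.trait,
        "build": e.build, "population": e.population,
        "score": _fmt6(e.score), "effectType": e.effect_type,
        "nIncluded": e.n_included, "nImputed": e.n_imputed,
        "percentile": _fmt6(e.percentile),
        "riskVariants": ";".join(e.risk_variants),
        "protectiveVariants": ";".join(e.protective_variants),
        "clumpedOut": ";".join(e.clumped_out),
        "imputedVariants": ";".join(e.imputed_variants),
    }


def write_outputs(
    path: str | Path,
    entries: Sequence[ScoreEntry],
    output_format: str = "verbose_tsv",
    excluded: Sequence[ScoreEntry] = (),
) -> None:
    """Write the score report; excluded entries go to a sidecar log.

    Rows are sorted by (studyID, trait, sample); scores render with six
    significant digits.  Entries removed by the imputation threshold (or
    scoring no variants) are listed with reasons in ``<path>.rejected.tsv``.
    """
    if output_format not in OUTPUT_FORMATS:
        raise ValueError(f"unknown output format {output_format!r}")
    path = Path(path)
    entries = sorted(entries, key=lambda e: (e.study_id, e.trait, e.sample))
    if output_format == "condensed_tsv":
        samples = sorted({e.sample for e in entries})
        lines = ["\t".join(["studyID", "trait"] + samples)]
        by_study: dict[tuple[str, str], dict[str, str]] = {}
        for e in entries:
            by_study.setdefault((e.study_id, e.trait), {})[e.sample] = _fmt6(e.score)
        for (study_id, trait) in sorted(by_study):
            row = by_study[(study_id, trait)]
            lines.append("\t".join([study_id, trait]
                                   + [row.get(s, "") for s in samples]))
        path.write_text("\n".join(lines) + "\n")
    elif output_format == "verbose_tsv":
        lines = ["\t".join(VERBOSE_COLUMNS)]
        for e in entries:
            rec = _verbose_record(e)
            lines.append("\t".join(str(rec[c]) for c in VERBOSE_COLUMNS))
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps([_verbose_record(e) for e in entries], indent=2)
                        + "\n")
    if excluded:
        side = path.with_name(path.name + ".rejected.tsv")
        lines = ["sample\tstudyID\ttrait\treason"]
        for e in sorted(excluded, key=lambda e: (e.study_id, e.trait, e.sample)):
            lines.append(f"{e.sample}\t{e.study_id}\t{e.trait}\t{e.exclude_reason}")
        side.write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; enums validated up front."""

    input_path: str = ""
    output_path: str = "prs_output.tsv"
    output_format: str = "verbose_tsv"
    p_cutoff: float = 0.05
    build: str = "hg38"
    population: str = "EUR"
    sumstats_path: str = ""
    registry_path: str | None = None
    clumps_path: str | None = None
    panel_path: str | None = None
    traits: tuple[str, ...] = ()
    study_ids: tuple[str, ...] = ()
    ancestry: str = ""
    study_mode: str = "all"
    impute_threshold: float = 0.5
    maf_threshold: float = 0.0
    maf_source: str = "sample"
    threads: int = 1
    step: str = "all"
    workdir: str | None = None
    seed: int = 0
    distributions_path: str | None = None
    context_cohort: str | None = None

    def __post_init__(self):
        if self.output_format not in OUTPUT_FORMATS:
            raise ValueError(f"unknown output format {self.output_format!r}")
        if self.build not in BUILDS:
            raise ValueError(f"unknown genome build {self.build!r}")
        if self.population not in SUPERPOPULATIONS:
            raise ValueError(f"unknown superpopulation {self.population!r}")
        if self.study_mode not in ("all", "highest_altmetric", "largest_cohort"):
            raise ValueError(f"unknown study-selection mode {self.study_mode!r}")
        if self.maf_source not in ("sample", "reference"):
            raise ValueError(f"unknown MAF source {self.maf_source!r}")
        if self.step not in ("all", "prepare", "calculate"):
            raise ValueError(f"unknown step {self.step!r}")
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ValueError("p-value cutoff must be in (0, 1]")
        if not (0.0 <= self.impute_threshold <= 1.0):
            raise ValueError("imputation threshold must be in [0, 1]")
        if not (0.0 <= self.maf_threshold <= 0.5):
            raise ValueError("MAF threshold must be in [0, 0.5]")
        if self.threads < 1:
            raise ValueError("thread count must be ≥ 1")


def _associations_to_tsv(
    path: Path, associations: Sequence[AssociationRecord],
    studies: Sequence[StudyRecord], build: str,
) -> None:
    """Serialize harmonized associations back into the sumstats dialect."""
    meta = {(s.study_id, s.trait): s for s in studies}
    lines = ["\t".join(ss.SUMSTATS_COLUMNS)]
    for a in associations:
        s = meta.get((a.study_id, a.trait))
        pos_cols = {b: "" for b in BUILDS}
        pos_cols[build] = str(a.pos)
        lines.append("\t".join([
            a.study_id, s.pubmed_id if s else "", a.trait, a.rsid, a.chrom,
            pos_cols["hg38"], pos_cols["hg19"], pos_cols["hg18"], pos_cols["hg17"],
            a.risk_allele,
            _fmt6(a.effect_value) if a.effect_type == "odds_ratio" else "",
            _fmt6(a.effect_value) if a.effect_type == "beta" else "",
            repr(a.p_value),
            _fmt6(a.ref_allele_freq) if a.ref_allele_freq is not None else "",
            "false",
            s.cohort_ancestry if s else "",
            str(s.initial_sample_size) if s else "0",
            str(s.replication_sample_size) if s else "0",
            _fmt6(s.altmetric_score) if s and s.altmetric_score is not None else "",
        ]))
    path.write_text("\n".join(lines) + "\n")


def prepare_workdir(config: RunConfig) -> Path:
    """Step 1: bundle filtered, harmonized inputs into a working directory.

    Writes ``sumstats.tsv`` (parsed, filtered, strand-harmonized when a
    registry is supplied, and study-selected), ``clumps.tsv`` (the slice
    of the clump table for the configured population and build), and a
    ``prepare.json`` snapshot.  The directory is self-contained: the
    calculate step reads nothing else besides the target genotypes.
    """
    if not config.workdir:
        raise ValueError("prepare step requires a working directory")
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    parsed = ss.parse_sumstats(config.sumstats_path, config.build)
    kept, _ = ss.filter_associations(parsed.associations)
    if config.registry_path:
        registry = ss.AlleleRegistry.from_tsv(config.registry_path)
        kept, _ = ss.harmonize_all(kept, registry)
    selected = ss.select_studies(parsed.studies, StudyFilters(
        traits=config.traits, study_ids=config.study_ids,
        ancestry_contains=config.ancestry, mode=config.study_mode,
    ))
    wanted = {(s.study_id, s.trait) for s in selected}
    kept = [a for a in kept if (a.study_id, a.trait) in wanted]
    _associations_to_tsv(workdir / "sumstats.tsv", kept, selected, config.build)

    if config.clumps_path:
        full = read_clump_table(config.clumps_path)
        sliced = ClumpTable()
        for a in kept:
            cid = full.clump_id(config.population, config.build, rsid=a.rsid,
                                chrom=a.chrom, pos=a.pos)
            if cid is not None:
                sliced.add(config.population, config.build, a.chrom, a.pos,
                           a.rsid, cid)
        write_clump_table(workdir / "clumps.tsv", sliced)
    (workdir / "prepare.json").write_text(json.dumps({
        "build": config.build, "population": config.population,
        "has_clumps": bool(config.clumps_path),
    }, indent=2) + "\n")
    return workdir


def calculate_from_workdir(config: RunConfig) -> tuple[list[ScoreEntry], list[ScoreEntry]]:
    """Step 2: score the target genotypes using only the prepared bundle."""
    if not config.workdir:
        raise ValueError("calculate step requires a working directory")
    workdir = Path(config.workdir)
    snapshot_path = workdir / "prepare.json"
    if not snapshot_path.exists():
        raise FileNotFoundError(
            f"{workdir} has no prepare.json — run the prepare step first"
        )
    snapshot = json.loads(snapshot_path.read_text())
    build = snapshot["build"]
    parsed = ss.parse_sumstats(workdir / "sumstats.tsv", build)
    clump_table = (read_clump_table(workdir / "clumps.tsv")
                   if snapshot.get("has_clumps") else None)
    if str(config.input_path).endswith((".txt", ".text")):
        target = read_text_genotypes(config.input_path)
    else:
        target = read_target_vcf(config.input_path, build)
    panel = (ReferencePanel.from_vcf(config.panel_path)
             if config.panel_path else None)
    kept, excluded = score_parallel(
        parsed.associations, target, config, clump_table=clump_table, panel=panel,
    )
    if config.distributions_path and config.context_cohort:
        dists = contextualize.read_distributions(config.distributions_path)
        for e in kept:
            dist = dists.get((config.context_cohort, e.study_id))
            if dist is not None:
                e.percentile = contextualize.percentile_rank(e.score, dist)
    return kept, excluded


def score_parallel(
    associations: Sequence[AssociationRecord],
    target: TargetData,
    config: RunConfig,
    clump_table: ClumpTable | None = None,
    panel: ReferencePanel | None = None,
) -> tuple[list[ScoreEntry], list[ScoreEntry]]:
    """Score all studies, partitioning work by study across threads.

    Each study is scored independently with no shared mutable state, so
    the thread count never changes the result; entries are canonically
    sorted afterwards.
    """
    groups: dict[tuple[str, str], list[AssociationRecord]] = {}
    for a in associations:
        groups.setdefault((a.study_id, a.trait), []).append(a)

    def run_one(key: tuple[str, str]) -> list[ScoreEntry]:
        study_id, trait = key
        return scoring.score_study(
            groups[key], target, study_id=study_id, trait=trait,
            build=config.build, population=config.population,
            clump_table=clump_table, panel=panel, p_cutoff=config.p_cutoff,
            maf_threshold=config.maf_threshold, maf_source=config.maf_source,
        )

    keys = sorted(groups)
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            chunks = list(pool.map(run_one, keys))
    else:
        chunks = [run_one(k) for k in keys]
    entries = [e for chunk in chunks for e in chunk]
    kept, excluded = scoring.apply_imputation_threshold(entries, config.impute_threshold)
    key = lambda e: (e.study_id, e.trait, e.sample)
    return sorted(kept, key=key), sorted(excluded, key=key)


def run_pipeline(config: RunConfig) -> Path | None:
    """Dispatch on the configured step; returns the output path when scoring.

    ``step="all"`` runs prepare then calculate through the identical code
    path as the two-step route, so the outputs are byte-identical.
    """
    import dataclasses
    import tempfile

    if config.step == "prepare":
        prepare_workdir(config)
        return None
    if config.step == "calculate":
        kept, excluded = calculate_from_workdir(config)
        write_outputs(config.output_path, kept, config.output_format, excluded)
        return Path(config.output_path)
    # step == "all"
    if config.workdir:
        prepare_workdir(config)
        kept, excluded = calculate_from_workdir(config)
    else:
        with tempfile.TemporaryDirectory() as tmp:
            cfg = dataclasses.replace(config, workdir=tmp)
            prepare_workdir(cfg)
            kept, excluded = calculate_from_workdir(cfg)
    write_outputs(config.output_path, kept, config.output_format, excluded)
    return Path(config.output_path)
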