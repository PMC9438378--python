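"""Seeded generators for every input the scoring pipeline consumes.

The generators stand in for the large external resources a C+T pipeline
normally draws on (a reference genotype panel, a GWAS summary-statistics
catalog with a dbSNP-style allele registry, and a labeled target cohort),
with transparent ground truth:

* LD blocks are built from a shared latent haplotype allele copied with
  per-variant flip noise, giving an analytically controlled pairwise
  dosage correlation (for flip probability ε and latent frequency ½ the
  expected r² between block-mates is (1−2ε)⁴, so ε = (1 − t^¼)/2 hits a
  target t);
* a stated fraction of summary-statistic risk alleles is written as
  reverse-strand complements, a fraction as unresolvable (neither-allele)
  reports, and a fraction as multi-variant haplotype rows — each planting
  recorded exactly;
* case genotypes shift the risk-allele frequency additively at the causal
  study's variants, so group separation in downstream scores has a known
  cause and direction.

Everything is a pure function of the :class:`SimSpec` (same spec, same
bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from prskit.sumstats import COMPLEMENT, REGISTRY_COLUMNS, SUMSTATS_COLUMNS

#: REF/ALT pairs that are not strand-palindromic, so a reverse-strand
#: report is always recoverable by complementing.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


@dataclass(frozen=True)
class LDBlock:
    """A run of variants sharing a latent haplotype allele."""

    chrom: str
    start: int
    n_variants: int
    spacing_bp: int = 10_000
    r2_target: float = 0.8


def _default_blocks() -> list[LDBlock]:
    # singleton blocks 1 Mb apart: mutually unlinked and outside any
    # plausible clumping window
    return [LDBlock(chrom="1", start=10_000 + i * 1_000_000, n_variants=1)
            for i in range(250)]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study system.

    Defaults describe a modest but well-powered bench-scale system: a
    200-sample single-population reference panel over 250 independent
    variants, five 50-variant odds-ratio studies with disjoint variant
    sets, and a 200-case / 200-control cohort in which the first study's
    variants have their risk-allele frequency shifted by +0.10 in cases.
    """

    seed: int = 0
    populations: tuple[str, ...] = ("EUR",)
    n_panel_samples: int = 200
    ld_blocks: tuple[LDBlock, ...] = field(default_factory=lambda: tuple(_default_blocks()))
    n_studies: int = 5
    variants_per_study: int = 50
    effect_type: str = "odds_ratio"
    log_or_mean: float = 0.18   # mean OR ≈ 1.20
    log_or_sd: float = 0.05
    beta_mean: float = 0.18
    beta_sd: float = 0.05
    n_cases: int = 200
    n_controls: int = 200
    enrichment: float = 0.10    # additive risk-allele frequency shift in cases
    causal_study_index: int = 0
    missing_rate: float = 0.02
    strand_flip_rate: float = 0.10
    ambiguous_rate: float = 0.02
    haplotype_rate: float = 0.02
    build: str = "hg38"

    def __post_init__(self):
        for name in ("missing_rate", "strand_flip_rate", "ambiguous_rate",
                     "haplotype_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for b in self.ld_blocks:
            if b.r2_target > 0.99:
                raise ValueError(
                    f"r2_target {b.r2_target} infeasible (must be ≤ 0.99)"
                )


@dataclass(frozen=True)
class SimVariant:
    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    block: int


@dataclass
class PanelSim:
    """Generated reference panel: VCF text plus per-sample population labels."""

    vcf_text: str
    labels: dict[str, str]
    variants: list[SimVariant]
    alt_freqs: dict[str, float]  # empirical alt frequency per rsid (pooled)

    def write(self, vcf_path: str | Path, labels_path: str | Path | None = None) -> None:
        Path(vcf_path).write_text(self.vcf_text)
        if labels_path is not None:
            lines = ["sampleID\tpopulation"]
            lines += [f"{s}\t{p}" for s, p in self.labels.items()]
            Path(labels_path).write_text("\n".join(lines) + "\n")


@dataclass
class SumstatsSim:
    """Generated summary statistics + registry, with planting ground truth."""

    sumstats_text: str
    registry_text: str
    study_variants: dict[str, list[str]]   # studyID -> rsids (incl. planted rows)
    causal_rsids: list[str]
    effect_sign: dict[str, float]          # rsid -> +1/-1 risk direction (causal study)
    planted_flipped: set[str]
    planted_ambiguous: set[str]
    planted_haplotypes: set[str]

    def write(self, sumstats_path: str | Path, registry_path: str | Path) -> None:
        Path(sumstats_path).write_text(self.sumstats_text)
        Path(registry_path).write_text(self.registry_text)


@dataclass
class CohortSim:
    """Generated target cohort: VCF text plus case/control labels."""

    vcf_text: str
    labels: dict[str, str]

    def write(self, vcf_path: str | Path, labels_path: str | Path) -> None:
        Path(vcf_path).write_text(self.vcf_text)
        lines = ["sampleID\tgroup"]
        lines += [f"{s}\t{g}" for s, g in self.labels.items()]
        Path(labels_path).write_text("\n".join(lines) + "\n")


def _spec_variants(spec: SimSpec, rng: np.random.Generator) -> list[SimVariant]:
    variants = []
    counter = 1
    for b_idx, block in enumerate(spec.ld_blocks):
        for i in range(block.n_variants):
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            variants.append(SimVariant(
                chrom=block.chrom, pos=block.start + i * block.spacing_bp,
                rsid=f"rs{counter}", ref=ref, alt=alt, block=b_idx,
            ))
            counter += 1
    return variants


def _gt_string(dosage: float) -> str:
    if np.isnan(dosage):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(dosage)]


def _vcf_text(variants: Sequence[SimVariant], samples: Sequence[str],
              dosages: np.ndarray) -> str:
    chroms = sorted({v.chrom for v in variants})
    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    lines = [_VCF_HEADER + contigs
             + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    for i in order:
        v = variants[i]
        gts = "\t".join(_gt_string(d) for d in dosages[i])
        lines.append(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    return "\n".join(lines) + "\n"


def _block_dosages(spec: SimSpec, variants: Sequence[SimVariant],
                   n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Alt-dosage matrix (variants × samples) with within-block LD."""
    n_v = len(variants)
    dosages = np.zeros((n_v, n_samples))
    by_block: dict[int, list[int]] = {}
    for i, v in enumerate(variants):
        by_block.setdefault(v.block, []).append(i)
    for b_idx, var_idx in by_block.items():
        block = spec.ld_blocks[b_idx]
        # two haplotypes per sample share a latent allele per block
        latent = rng.random((2, n_samples)) < 0.5
        eps = (1.0 - block.r2_target ** 0.25) / 2.0 if len(var_idx) > 1 else 0.5
        for i in var_idx:
            if len(var_idx) > 1:
                flip = rng.random((2, n_samples)) < eps
                hap = latent ^ flip
            else:
                hap = rng.random((2, n_samples)) < 0.5  # independent singleton
            dosages[i] = hap.sum(axis=0)
    return dosages


def make_reference_panel(spec: SimSpec) -> PanelSim:
    """Generate the multi-population reference panel VCF and labels.

    Within-block genotypes share latent haplotype alleles so empirical
    dosage r² between block-mates tracks the block's target; cross-block
    variants are independent.  Each population gets its own independent
    draw of ``n_panel_samples`` samples.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    variants = _spec_variants(spec, rng)
    samples: list[str] = []
    labels: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for pop in spec.populations:
        pop_dos = _block_dosages(spec, variants, spec.n_panel_samples, rng)
        cols.append(pop_dos)
        for i in range(spec.n_panel_samples):
            name = f"{pop}_{i:04d}"
            samples.append(name)
            labels[name] = pop
    dosages = np.hstack(cols)
    alt_freqs = {v.rsid: float(dosages[i].mean() / 2.0)
                 for i, v in enumerate(variants)}
    return PanelSim(_vcf_text(variants, samples, dosages), labels, variants, alt_freqs)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def make_sumstats(spec: SimSpec, panel: PanelSim) -> SumstatsSim:
    """Generate the summary-statistics and allele-registry TSVs.

    Studies receive disjoint variant sets (partitioned in panel order) so
    planted case enrichment at the causal study's variants cannot leak
    into other studies.  The risk allele is the panel ALT allele; planted
    reverse-strand rows report its complement, planted ambiguous rows
    report an allele unresolvable against the registry, and planted
    haplotype rows encode a multi-variant risk-allele field.
    """
    rng = np.random.default_rng([int(spec.seed), 22])
    needed = spec.n_studies * spec.variants_per_study
    if needed > len(panel.variants):
        raise ValueError(
            f"{needed} study variants requested but panel has {len(panel.variants)}"
        )
    perm = rng.permutation(len(panel.variants))[:needed]
    header = "\t".join(SUMSTATS_COLUMNS)
    rows = [header]
    reg_rows = ["\t".join(REGISTRY_COLUMNS)]
    study_variants: dict[str, list[str]] = {}
    causal_rsids: list[str] = []
    effect_sign: dict[str, float] = {}
    flipped: set[str] = set()
    ambiguous: set[str] = set()
    haplotypes: set[str] = set()

    for j in range(spec.n_studies):
        study_id = f"SYN{j + 1:03d}"
        trait = f"trait_{j + 1}"
        idx = perm[j * spec.variants_per_study:(j + 1) * spec.variants_per_study]
        study_variants[study_id] = [panel.variants[i].rsid for i in idx]
        for i in idx:
            v = panel.variants[i]
            if spec.effect_type == "odds_ratio":
                effect = float(np.exp(rng.normal(spec.log_or_mean, spec.log_or_sd)))
                odds, beta = _fmt(effect), ""
                sign = 1.0 if effect >= 1.0 else -1.0
            else:
                effect = float(rng.normal(spec.beta_mean, spec.beta_sd))
                odds, beta = "", _fmt(effect)
                sign = 1.0 if effect >= 0.0 else -1.0
            p_value = 10.0 ** (-float(rng.uniform(4, 10)))
            freq = panel.alt_freqs[v.rsid]
            if j == spec.causal_study_index:
                causal_rsids.append(v.rsid)
                effect_sign[v.rsid] = sign

            risk_field = v.alt
            known = f"{v.ref},{v.alt}"
            u = rng.random()
            if u < spec.haplotype_rate:
                risk_field = f"{v.rsid}-{v.alt}; rsx-{v.ref}"
                haplotypes.add(v.rsid)
            elif u < spec.haplotype_rate + spec.ambiguous_rate:
                # registry omits ALT: reported allele and its complement are
                # both absent from the known list -> unresolvable
                known = v.ref
                ambiguous.add(v.rsid)
            elif u < spec.haplotype_rate + spec.ambiguous_rate + spec.strand_flip_rate:
                risk_field = COMPLEMENT[v.alt]
                flipped.add(v.rsid)

            rows.append("\t".join([
                study_id, f"{30000000 + j}", trait, v.rsid, v.chrom,
                str(v.pos), str(v.pos), str(v.pos), str(v.pos),
                risk_field, odds, beta, _fmt(p_value), _fmt(freq),
                "false", "European",
                str(10000 + 1000 * j), str(5000), _fmt(100.0 + 10.0 * j),
            ]))
            reg_rows.append("\t".join([
                v.rsid, known, v.chrom,
                str(v.pos), str(v.pos), str(v.pos), str(v.pos),
            ]))
    return SumstatsSim(
        "\n".join(rows) + "\n", "\n".join(reg_rows) + "\n",
        study_variants, causal_rsids, effect_sign, flipped, ambiguous, haplotypes,
    )


def make_cohort(spec: SimSpec, panel: PanelSim, sumstats: SumstatsSim) -> CohortSim:
    """Generate the labeled target cohort VCF.

    Control genotypes are drawn binomially at the panel's alt-allele
    frequency; cases shift the frequency at the causal study's variants by
    the spec's enrichment, in the direction of the planted effect sign
    (clipped to [0, 1] with a warning).  Missing genotypes are planted
    uniformly at the missing rate.
    """
    import warnings

    rng = np.random.default_rng([int(spec.seed), 33])
    samples = ([f"case_{i:04d}" for i in range(spec.n_cases)]
               + [f"ctrl_{i:04d}" for i in range(spec.n_controls)])
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    causal = set(sumstats.causal_rsids)
    n = len(samples)
    dosages = np.zeros((len(panel.variants), n))
    for i, v in enumerate(panel.variants):
        f_ctrl = panel.alt_freqs[v.rsid]
        f_case = f_ctrl
        if v.rsid in causal and spec.enrichment != 0.0:
            shifted = f_ctrl + spec.enrichment * sumstats.effect_sign.get(v.rsid, 1.0)
            f_case = min(max(shifted, 0.0), 1.0)
            if f_case != shifted:
                warnings.warn(f"{v.rsid}: enrichment clipped frequency to [0, 1]")
        row = np.concatenate([
            rng.binomial(2, f_case, size=spec.n_cases).astype(float),
            rng.binomial(2, f_ctrl, size=spec.n_controls).astype(float),
        ])
        if spec.missing_rate > 0:
            row[rng.random(n) < spec.missing_rate] = np.nan
        dosages[i] = row
    return CohortSim(_vcf_text(panel.variants, samples, dosages), labels)


def simulate_all(spec: SimSpec) -> tuple[PanelSim, SumstatsSim, CohortSim]:
    """Generate panel, summary statistics and cohort in one call."""
    panel = make_reference_panel(spec)
    sumstats = make_sumstats(spec, panel)
    cohort = make_cohort(spec, panel, sumstats)
    return panel, sumstats, cohort


def null_spec(spec: SimSpec) -> SimSpec:
    """The same system with zero planted enrichment (null labeling)."""
    return replace(spec, enrichment=0.0)
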