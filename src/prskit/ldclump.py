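"""Population-specific LD clumping from a reference genotype panel.

Variants in high linkage disequilibrium carry the same association signal;
including several of them in an additive risk score double-counts that
signal.  The standard remedy is greedy clumping: visit variants from most
to least significant, let each not-yet-assigned variant found a clump, and
pull into that clump every unassigned variant on the same chromosome within
a distance window whose genotype r-squared with the index exceeds a cutoff.
Defaults follow common practice: r² ≥ 0.25 within ±500 kb.

r² here is the squared Pearson correlation of unphased alt-allele dosages
(0/1/2) over the panel samples, with pairwise-complete deletion of missing
genotypes.  Pairs whose correlation is undefined (fewer than two complete
pairs, or a constant vector) are treated as unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

CLUMP_COLUMNS = ["population", "build", "chrom", "pos", "rsID", "clumpID"]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so hg19/hg38 style names compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class PanelVariant:
    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str


class ReferencePanel:
    """Reference genotypes: variant metadata plus an alt-dosage matrix.

    ``dosages`` is a (n_variants, n_samples) float array of alt-allele
    counts in {0, 1, 2} with NaN for missing genotypes.
    """

    def __init__(self, variants: Sequence[PanelVariant], dosages: np.ndarray,
                 samples: Sequence[str]):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(variants), len(samples)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        self.variants = list(variants)
        self.dosages = dosages
        self.samples = list(samples)
        self._by_rsid = {v.rsid: i for i, v in enumerate(self.variants)}
        self._by_pos = {(normalize_chrom(v.chrom), v.pos): i
                        for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def index_of(self, rsid: str | None = None,
                 chrom: str | None = None, pos: int | None = None) -> int | None:
        if rsid is not None and rsid in self._by_rsid:
            return self._by_rsid[rsid]
        if chrom is not None and pos is not None:
            return self._by_pos.get((normalize_chrom(chrom), pos))
        return None

    def dosage_vector(self, rsid: str) -> np.ndarray:
        return self.dosages[self._by_rsid[rsid]]

    def risk_allele_freq(self, rsid: str, allele: str) -> float | None:
        """Frequency of ``allele`` at a panel variant over non-missing calls.

        Returns None if the variant is absent, the allele matches neither
        REF nor ALT, or every genotype is missing.
        """
        i = self._by_rsid.get(rsid)
        if i is None:
            return None
        v = self.variants[i]
        d = self.dosages[i]
        d = d[~np.isnan(d)]
        if d.size == 0:
            return None
        alt_freq = float(d.sum()) / (2 * d.size)
        if allele == v.alt:
            return alt_freq
        if allele == v.ref:
            return 1.0 - alt_freq
        return None

    def subset_samples(self, samples: Sequence[str]) -> "ReferencePanel":
        idx = [self.samples.index(s) for s in samples]
        return ReferencePanel(self.variants, self.dosages[:, idx], list(samples))

    @classmethod
    def from_vcf(cls, path: str | Path) -> "ReferencePanel":
        """Load a multi-sample VCF (GT field) into a dosage panel.

        Multiallelic records are split into one biallelic entry per ALT
        allele; for a split entry, genotypes carrying a different ALT are
        treated as missing for that entry's dosage.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        variants: list[PanelVariant] = []
        rows: list[np.ndarray] = []
        for rec in vcf:
            gts = rec.genotype.array()[:, :2].astype(float)  # diploid GT pairs
            gts[gts < 0] = np.nan
            for alt_idx, alt in enumerate(rec.ALT, start=1):
                dos = np.where(np.isnan(gts), np.nan, (gts == alt_idx).astype(float))
                row = dos.sum(axis=1)
                row[np.isnan(gts).any(axis=1)] = np.nan
                variants.append(PanelVariant(
                    chrom=normalize_chrom(rec.CHROM), pos=rec.POS,
                    rsid=rec.ID if rec.ID not in (None, ".") else f"{normalize_chrom(rec.CHROM)}:{rec.POS}",
                    ref=rec.REF, alt=alt,
                ))
                rows.append(row)
        vcf.close()
        dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
        return cls(variants, dosages, samples)


def compute_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Missing pairs (NaN in either vector) are dropped.  Returns None when
    r² is undefined — fewer than two complete pairs, or either remaining
    vector constant — which callers treat as "unlinked".
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


class _HasVariantFields(Protocol):
    rsid: str
    chrom: str
    pos: int
    p_value: float


@dataclass(frozen=True)
class ClumpAssignment:
    rsid: str
    chrom: str
    pos: int
    clump_id: int
    is_index: bool
    no_panel_data: bool = False


def greedy_clump(
    variants: Iterable[_HasVariantFields],
    panel: ReferencePanel,
    r2_cutoff: float = 0.25,
    window_kb: int = 500,
) -> list[ClumpAssignment]:
    """Assign every variant to exactly one LD clump for one population.

    Variants are visited by ascending p-value (ties by chromosome,
    position, then rsID).  Each unassigned variant founds a new clump and
    becomes its index; all still-unassigned variants on the same
    chromosome within ±``window_kb`` whose panel r² with the index reaches
    ``r2_cutoff`` join the clump.  Variants with no panel genotypes become
    singleton clumps flagged ``no_panel_data``.  Clump IDs count up from 1
    in index-discovery order, so the output is deterministic.
    """
    uniq: dict[str, _HasVariantFields] = {}
    for v in variants:
        uniq.setdefault(v.rsid, v)
    order = sorted(
        uniq.values(),
        key=lambda v: (v.p_value, normalize_chrom(v.chrom), v.pos, v.rsid),
    )
    window_bp = window_kb * 1000
    assigned: dict[str, ClumpAssignment] = {}
    next_id = 1
    for idx_var in order:
        if idx_var.rsid in assigned:
            continue
        cid = next_id
        next_id += 1
        pidx = panel.index_of(idx_var.rsid, idx_var.chrom, idx_var.pos)
        assigned[idx_var.rsid] = ClumpAssignment(
            idx_var.rsid, normalize_chrom(idx_var.chrom), idx_var.pos,
            cid, is_index=True, no_panel_data=pidx is None,
        )
        if pidx is None:
            continue  # singleton: LD unknown without panel genotypes
        index_dos = panel.dosages[pidx]
        for cand in order:
            if cand.rsid in assigned:
                continue
            if normalize_chrom(cand.chrom) != normalize_chrom(idx_var.chrom):
                continue
            if abs(cand.pos - idx_var.pos) > window_bp:
                continue
            cidx = panel.index_of(cand.rsid, cand.chrom, cand.pos)
            if cidx is None:
                continue
            r2 = compute_r2(index_dos, panel.dosages[cidx])
            if r2 is not None and r2 >= r2_cutoff:
                assigned[cand.rsid] = ClumpAssignment(
                    cand.rsid, normalize_chrom(cand.chrom), cand.pos,
                    cid, is_index=False,
                )
    return [assigned[v.rsid] for v in order]


class ClumpTable:
    """Variant → clump ID, keyed by (superpopulation, genome build).

    Lookup works by rsID or by (chrom, pos); within one population/build a
    variant has exactly one clump ID.
    """

    def __init__(self):
        self._by_rsid: dict[tuple[str, str], dict[str, int]] = {}
        self._by_pos: dict[tuple[str, str], dict[tuple[str, int], int]] = {}
        self._rows: list[tuple[str, str, str, int, str, int]] = []

    def add(self, population: str, build: str, chrom: str, pos: int,
            rsid: str, clump_id: int) -> None:
        if population not in SUPERPOPULATIONS:
            raise ValueError(f"unknown population code {population!r}")
        key = (population, build)
        self._by_rsid.setdefault(key, {})[rsid] = clump_id
        self._by_pos.setdefault(key, {})[(normalize_chrom(chrom), pos)] = clump_id
        self._rows.append((population, build, normalize_chrom(chrom), pos, rsid, clump_id))

    def add_assignments(self, population: str, build: str,
                        assignments: Iterable[ClumpAssignment]) -> None:
        for a in assignments:
            self.add(population, build, a.chrom, a.pos, a.rsid, a.clump_id)

    def clump_id(self, population: str, build: str, rsid: str | None = None,
                 chrom: str | None = None, pos: int | None = None) -> int | None:
        key = (population, build)
        if rsid is not None:
            cid = self._by_rsid.get(key, {}).get(rsid)
            if cid is not None:
                return cid
        if chrom is not None and pos is not None:
            return self._by_pos.get(key, {}).get((normalize_chrom(chrom), pos))
        return None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=CLUMP_COLUMNS)
        return df.sort_values(CLUMP_COLUMNS[:5], kind="mergesort").reset_index(drop=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClumpTable):
            return NotImplemented
        return sorted(self._rows) == sorted(other._rows)

    def __len__(self) -> int:
        return len(self._rows)


def write_clump_table(path: str | Path, table: ClumpTable) -> None:
    """Write a clump table as TSV (population, build, chrom, pos, rsID, clumpID)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_clump_table(path: str | Path) -> ClumpTable:
    """Read a clump-table TSV; unknown population codes are fatal."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "population": str,
                                            "build": str, "rsID": str})
    missing = [c for c in CLUMP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clump table missing column(s): {missing}")
    table = ClumpTable()
    for row in df.itertuples(index=False):
        table.add(row.population, row.build, str(row.chrom), int(row.pos),
                  row.rsID, int(row.clumpID))
    return table


def build_clump_table(
    variants: Iterable[_HasVariantFields],
    panels: Mapping[str, ReferencePanel],
    build: str,
    r2_cutoff: float = 0.25,
    window_kb: int = 500,
) -> ClumpTable:
    """Run greedy clumping for each population panel into one table."""
    variants = list(variants)
    table = ClumpTable()
    for population in sorted(panels):
        assignments = greedy_clump(variants, panels[population],
                                   r2_cutoff=r2_cutoff, window_kb=window_kb)
        table.add_assignments(population, build, assignments)
    return table
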