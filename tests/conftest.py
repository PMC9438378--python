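"""Shared fixtures and tiny builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from prskit.io import TargetData, TargetSite
from prskit.ldclump import PanelVariant, ReferencePanel
from prskit.sumstats import AlleleRegistry, AssociationRecord


@dataclass(frozen=True)
class VariantP:
    """Minimal variant-with-p-value record for clumping tests."""

    rsid: str
    chrom: str
    pos: int
    p_value: float


def make_assoc(
    rsid="rs1", chrom="1", pos=100, risk_allele="A", effect_value=1.2,
    effect_type="odds_ratio", p_value=1e-8, study_id="S1", trait="t",
    ref_allele_freq=None, sex_specific=False,
) -> AssociationRecord:
    return AssociationRecord(
        study_id=study_id, trait=trait, rsid=rsid, chrom=chrom, pos=pos,
        risk_allele=risk_allele, effect_value=effect_value,
        effect_type=effect_type, p_value=p_value,
        ref_allele_freq=ref_allele_freq, sex_specific=sex_specific,
    )


def make_target(sites_spec, samples=("s1",)) -> TargetData:
    """Build TargetData from (chrom, pos, rsid, ref, alt, dosages) tuples."""
    sites = [
        TargetSite(chrom=c, pos=p, rsid=r, ref=ref, alt=alt,
                   alt_dosage=np.asarray(d, dtype=float))
        for (c, p, r, ref, alt, d) in sites_spec
    ]
    return TargetData(list(samples), sites)


def make_panel(dosage_rows, chrom="1", start=100, spacing=1000,
               rsids=None) -> ReferencePanel:
    """Reference panel from a list of per-variant dosage rows."""
    dosages = np.asarray(dosage_rows, dtype=float)
    n_v, n_s = dosages.shape
    rsids = rsids or [f"rs{i + 1}" for i in range(n_v)]
    variants = [
        PanelVariant(chrom=chrom, pos=start + i * spacing, rsid=rsids[i],
                     ref="A", alt="G")
        for i in range(n_v)
    ]
    return ReferencePanel(variants, dosages, [f"p{j}" for j in range(n_s)])


#: Shared immutable registry; import directly in hypothesis-driven tests
#: (function-scoped fixtures and @given do not mix).
REGISTRY = AlleleRegistry({
    "rs1": frozenset({"A", "G"}),
    "rs2": frozenset({"C", "A"}),
    "rs3": frozenset({"A", "T"}),
    "rs4": frozenset({"G", "T"}),
})


@pytest.fixture
def registry() -> AlleleRegistry:
    return REGISTRY
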