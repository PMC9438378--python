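"""Generate a complete synthetic input set for the scoring pipeline.

Builds a reference panel with two LD blocks, summary statistics with
planted strand errors, and a labeled case/control cohort, then prints
what was planted where.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from prskit.synthdata import LDBlock, SimSpec, simulate_all

spec = SimSpec(
    seed=7,
    n_panel_samples=100,
    ld_blocks=(LDBlock("1", 10_000, 4, 20_000, 0.8),      # one 4-variant block
               *(LDBlock("1", 2_000_000 + i * 1_000_000, 1) for i in range(46))),
    n_studies=2, variants_per_study=25,
    n_cases=50, n_controls=50, enrichment=0.10,
    strand_flip_rate=0.2,
)
panel, sumstats, cohort = simulate_all(spec)

with TemporaryDirectory() as tmp:
    d = Path(tmp)
    panel.write(d / "panel.vcf", d / "panel_populations.tsv")
    sumstats.write(d / "sumstats.tsv", d / "registry.tsv")
    cohort.write(d / "cohort.vcf", d / "cohort_labels.tsv")
    print("files written:", sorted(p.name for p in d.iterdir()))

print(f"panel: {len(panel.variants)} variants x {len(panel.labels)} samples")
print(f"planted reverse-strand reports: {len(sumstats.planted_flipped)}")
print(f"planted unresolvable reports:   {len(sumstats.planted_ambiguous)}")
print(f"causal variants (study SYN001): {len(sumstats.causal_rsids)}")
# The planted sets are the ground truth the harmonizer and the group scan
# are expected to recover exactly (flips) or statistically (enrichment).
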