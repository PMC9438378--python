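# Methods

This note records the scientific and numerical choices behind prskit: the
scoring model and its assumptions, the conventions chosen where the
standard C+T (clumping + thresholding) recipe leaves room, what the
synthetic-data generators emulate, and the known limitations.

## Scoring model

prskit implements the simple additive PRS. For a study with effects on
the odds-ratio scale, aggregation happens in log space and is
exponentiated:

    score = exp( (Σ_i ln(OR_i) · d_i) / M )

and for beta-scale studies:

    score = (Σ_i β_i · d_i) / M

where `d_i` is the risk-allele dosage (0–2, fractional when imputed) and
`M` is the number of variants retained after thresholding and clump
resolution. Averaging is **per variant** (denominator M), not per allele
slot (2M); either convention appears in the field, and the per-variant
mean was fixed here because it keeps the null genome at exactly 1.0
(odds ratios) / 0.0 (betas) and matches the additive-mean convention of
the common C+T tools this package is interoperable with. A study's
effects must be homogeneously odds-ratio or beta; mixing is an error
rather than a silent conversion.

The model is deliberately additive: no dominance, no gene–gene or
gene–environment terms, no shrinkage of effect sizes, and no ancestry
correction. Scores are relative quantities; they only carry meaning
against a reference distribution (see Contextualization).

## Harmonization

Associations must carry a risk allele, exactly one effect value and a
p-value. Multi-variant risk haplotypes (risk-allele field containing a
";" or "x" separator, the common catalog encoding) and sex-specific
associations (an explicit boolean column in the input dialect) are
excluded — each exclusion is logged with its reason, and
|kept| + |rejected| always equals the input size.

Strand harmonization checks the reported risk allele against the
registry's known forward-strand alleles; if absent, the Watson–Crick
complement is checked and, when found, substituted (the record is flagged
`flipped`). Unresolvable reports are excluded as ambiguous, as are
variants missing from the registry entirely (their strand cannot be
verified) and non-ACGT alleles. The procedure is idempotent. The registry
is build-agnostic: allele sets are not stratified by genome build.

## LD clumping

Clumping is greedy index-variant selection: variants sorted by ascending
GWAS p-value (ties: chromosome, position, rsID); each unassigned variant
founds a clump and captures all still-unassigned variants on the same
chromosome within an index-centred, inclusive ±500 kb window whose r²
with the index reaches 0.25. Both defaults are the values commonly used
with this recipe and are configurable.

The r² estimator is the **squared Pearson correlation of unphased
genotype dosages** over the panel samples, with pairwise-complete
deletion of missing genotypes — not an EM haplotype-frequency r². The
dosage correlation is deterministic, needs no phase information, and is
directly checkable against a brute-force oracle; at clumping-cutoff
resolution the two estimators agree in practice. Pairs whose correlation
is undefined (under two complete pairs, or a constant vector) are treated
as unlinked. Variants with no panel genotypes become singleton clumps
flagged `no_panel_data` rather than being dropped: absence of LD evidence
is not evidence of independence, but dropping the variant would silently
change the score.

Clump IDs are integers assigned in index-discovery order within one
(population, build), which makes tables reproducible byte for byte. Each
build's table is computed (or supplied) independently; no coordinate
liftover is attempted.

## Matching and dosage extraction

Associations match target sites by rsID first, then by (chromosome,
position) — accessions get merged and relabeled, and position matching
recovers those cases. Chromosome names are normalized ("chr" prefix
stripped); multiallelic records are split into biallelic sites before
matching; duplicate sites at one position keep the first occurrence with
a warning.

At a matched site, a risk allele equal to ALT counts alt alleles in the
genotype, equal to REF counts 2 − alt; when it matches neither, its
complement is tried (summary statistics and target may disagree on
strand); if still unmatched, the genotype is treated like assay dropout
and imputed. For plain-text genotype input (`rsID:A1,A2`, one sample,
hg38 context) the listed pair is the complete genotype, so an unlisted
allele counts as zero copies instead.

## Imputation

A missing genotype contributes `2 × freq(risk allele)` copies. The
frequency source defaults to the target sample itself (non-missing calls
at that site), falling back to the reference panel, then to the
association's reported frequency; `maf_source="reference"` swaps the
first two. A variant with no frequency from any source is dropped from
that sample's score with a warning.

Per (sample, study) entry, when imputed genotypes exceed half of the
retained variants the entry is excluded from output (reason
`imputation_threshold`, listed in a sidecar log); the boundary case —
exactly half — is retained, so at least half of the genotypes entering a
reported score come from the sample. The accounting is per entry over
retained variants and counts absent-site and missing-call imputations
alike, since they are indistinguishable in effect. The threshold is
configurable in [0, 1].

The p-value threshold default is 0.05 (any value in (0, 1] accepted); the
optional MAF filter folds the reported risk-allele frequency to the minor
side and keeps records with no available frequency (with a warning)
rather than silently dropping them.

## Contextualization

Percentiles use the mid-rank convention: `100 × (#below + ½·#ties) / n`.
The tie rule matters — mid-rank is symmetric, so ranking a cohort against
itself averages to exactly the 50th percentile, which makes the
convention testable. Distribution summaries report min/max/mean/median
and quartiles with linear interpolation between order statistics (the
convention is recorded in the summary output).

## Cohort scans

The scan tests, per study, whether scores separate two labeled groups.
Mann–Whitney U is the default (risk-score distributions are frequently
non-normal): U counts pairs with `a > b` plus half-ties; the p-value is
exact by full labeling enumeration when the combined sample size is ≤ 12
with no ties (keeping the enumeration oracle feasible), otherwise the
normal approximation with tie correction and a 0.5 continuity correction.
Two-sided exact p is `min(1, 2·min(P(U≤u), P(U≥u)))`. Welch's t with
Satterthwaite degrees of freedom is available for near-normal scores; two
equal constant groups give t = 0, p = 1 by convention.

The normality check is a one-sample KS test against a normal with the
sample's mean and SD (ddof = 1), p from the asymptotic KS distribution,
without a Lilliefors small-sample correction — using fitted parameters
makes the test conservative, which the test suite verifies empirically. A
zero-variance sample is non-normal by convention (p = 0, with a warning).

Multiple testing uses Bonferroni — family alpha divided by the number of
studies actually tested (studies with under two scores in a group are
skipped and do not inflate the divisor). Bonferroni rather than FDR
because the scan's purpose is family-wise control over a fixed set of
planned comparisons.

## Synthetic data

The generators are pure functions of a `SimSpec` (same spec → identical
bytes) and emulate three inputs:

- **Reference panel.** LD blocks share a latent haplotype allele at
  frequency ½; each variant copies the latent allele with flip
  probability ε. Two such variants have expected dosage correlation
  (1−2ε)², hence r² = (1−2ε)⁴, so ε = (1 − t^¼)/2 hits a target r² = t
  analytically. Targets above 0.99 are rejected as infeasible.
  Cross-block variants are independent draws.
- **Summary statistics + registry.** Studies receive disjoint variant
  sets so planted signals cannot leak between studies. REF/ALT pairs are
  never strand-palindromic, so a planted reverse-strand report (the ALT
  complement) is always recoverable, and plantings are exact ground
  truth: a stated fraction of rows is written flipped, a fraction as
  unresolvable reports (the registry entry omits the reported allele and
  its complement), and a fraction as haplotype rows.
- **Cohort.** Control genotypes are binomial at the panel allele
  frequency; cases shift the frequency at the causal study's variants
  additively (default +0.10, clipped to [0, 1] with a warning), in the
  direction of the planted effect sign. Missing genotypes are planted
  uniformly.

Default conditions — 200 panel samples, 250 independent variants, five
50-variant odds-ratio studies (log-OR ~ N(0.18, 0.05), i.e. mean OR
≈ 1.2), a 200/200 cohort with +0.10 enrichment at the first study's 50
variants, 2% missingness, 10% planted strand flips — are a bench-scale
system with high power for the planted contrast. These are conventional
small-simulation magnitudes: common-variant effect sizes around OR 1.2
and a frequency contrast large enough that a 50-variant score separates
groups reliably at n = 400.

What the generators do **not** emulate: realistic human LD maps or
demography (blocks are exchangeable and phase-free), liability-threshold
phenotypes (enrichment is a direct frequency shift), genotyping error
beyond uniform missingness, and relatedness. Passing tests therefore
demonstrate the machinery's correctness and power under transparent
conditions — not calibration on real cohorts.

## Numerical and interface choices

- Scores render with 6 significant digits in all outputs; rows sort by
  (study, trait, sample), making runs byte-comparable.
- Work is partitioned by study across threads with no shared mutable
  state, so thread count never changes output.
- The two-step mode serializes the filtered, harmonized associations and
  the clump-table slice into a self-contained directory; the single-step
  route runs through the identical code path, so outputs are
  byte-identical.
- Ties everywhere break deterministically: p-value ties by (chromosome,
  position, rsID); study-selection ties by smallest study ID.
- Problem sizes in the test suite (panels ≤ 30 samples for oracle
  equivalence, 50-seed end-to-end replicates, 500 enumeration instances)
  were chosen to give tight brute-force cross-checks at desk scale.

## Limitations

- Genotype-dosage r² ignores phase; for rare variants it can differ from
  haplotype r², shifting marginal clumping decisions near the cutoff.
- The registry is build-agnostic and SNP-only; indels and multi-allelic
  risk alleles are excluded as `non_snp`.
- Percentile contextualization assumes the reference cohort was scored
  with the same study, threshold and clumping settings; nothing enforces
  this.
- Bonferroni is conservative when study scores are correlated (shared
  variants or LD), which is common in dense catalogs.
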