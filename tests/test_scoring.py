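"""The C+T scoring engine: matching, thresholds, clump resolution,
imputation, score aggregation and the imputation threshold."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prskit.scoring import (
    DosageStatus,
    MatchedVariant,
    ScoreEntry,
    apply_imputation_threshold,
    apply_maf_filter,
    apply_pvalue_threshold,
    assign_clumps,
    compute_score,
    extract_dosage,
    impute_missing,
    match_variants,
    resolve_clumps,
    score_study,
)
from tests.conftest import make_assoc, make_panel, make_target


class TestMatchVariants:
    def test_rsid_match(self):
        target = make_target([("1", 500, "rs10", "A", "G", [1])])
        matches = match_variants([make_assoc(rsid="rs10", chrom="1", pos=500)], target)
        assert matches[0].site_index == 0

    def test_position_fallback_for_merged_accessions(self):
        # same site named differently in the target: position match succeeds
        target = make_target([("6", 32578772, "rsNew", "A", "G", [1])])
        matches = match_variants(
            [make_assoc(rsid="rsOld", chrom="6", pos=32578772)], target)
        assert matches[0].site_index == 0

    def test_absent_site_flagged(self):
        target = make_target([("1", 500, "rs10", "A", "G", [1])])
        matches = match_variants([make_assoc(rsid="rs99", chrom="2", pos=7)], target)
        assert matches[0].absent


class TestThresholds:
    def test_vacuous_pvalue_cutoff_keeps_all(self):
        recs = [make_assoc(rsid=f"rs{i}", p_value=p)
                for i, p in enumerate([1e-9, 1e-6, 0.04])]
        assert len(apply_pvalue_threshold(recs, 1.0)) == 3

    def test_genomewide_cutoff_keeps_one(self):
        recs = [make_assoc(rsid=f"rs{i}", p_value=p)
                for i, p in enumerate([1e-9, 1e-6, 0.04])]
        kept = apply_pvalue_threshold(recs, 5e-8)
        assert [r.p_value for r in kept] == [1e-9]

    def test_zero_cutoff_fatal(self):
        with pytest.raises(ValueError):
            apply_pvalue_threshold([], 0.0)

    def test_maf_zero_keeps_all(self):
        recs = [make_assoc(rsid=f"rs{i}", ref_allele_freq=f)
                for i, f in enumerate([0.01, 0.20, 0.45])]
        assert len(apply_maf_filter(recs, 0.0)) == 3

    def test_maf_filter_folds_to_minor_side(self):
        recs = [make_assoc(rsid=f"rs{i}", ref_allele_freq=f)
                for i, f in enumerate([0.01, 0.20, 0.45])]
        kept = apply_maf_filter(recs, 0.05)
        assert [r.ref_allele_freq for r in kept] == [0.20, 0.45]
        # a frequency of 0.97 is a MAF of 0.03
        assert not apply_maf_filter([make_assoc(ref_allele_freq=0.97)], 0.05)

    def test_missing_frequency_kept_with_warning(self):
        with pytest.warns(UserWarning, match="frequency"):
            kept = apply_maf_filter([make_assoc(ref_allele_freq=None)], 0.05)
        assert len(kept) == 1


class TestExtractDosage:
    def _site(self, dosages):
        return make_target([("1", 100, "rs1", "A", "G", dosages)]).sites[0]

    def test_het_risk_alt(self):
        d, status = extract_dosage(self._site([1]), "G", 0)
        assert (d, status) == (1.0, DosageStatus.OBSERVED)

    def test_hom_alt_risk_ref(self):
        d, status = extract_dosage(self._site([2]), "A", 0)
        assert (d, status) == (0.0, DosageStatus.OBSERVED)

    def test_missing_genotype(self):
        d, status = extract_dosage(self._site([np.nan]), "G", 0)
        assert d is None and status is DosageStatus.MISSING

    def test_complement_fallback_matches_alt(self):
        # risk C complements to G = ALT
        d, status = extract_dosage(self._site([2]), "C", 0)
        assert (d, status) == (2.0, DosageStatus.OBSERVED)

    def test_unmatched_allele(self):
        # site A/G: T complements to A... pick a site where neither matches
        site = make_target([("1", 100, "rs1", "A", "T", [1])]).sites[0]
        d, status = extract_dosage(site, "G", 0)
        assert d is None and status is DosageStatus.UNMATCHED_ALLELE


class TestResolveClumps:
    def _match(self, rsid, pos, p, clump_id):
        m = MatchedVariant(make_assoc(rsid=rsid, pos=pos, p_value=p), 0)
        m.clump_id = clump_id
        return m

    def test_most_significant_p_retained(self):
        m1 = self._match("rs1", 100, 1e-12, 1)
        m2 = self._match("rs2", 200, 1e-9, 1)
        retained, out = resolve_clumps([m2, m1])
        assert retained == [m1] and out == [m2]

    def test_all_singletons_retained(self):
        ms = [self._match(f"rs{i}", i * 100, 1e-8, i) for i in range(1, 4)]
        retained, out = resolve_clumps(ms)
        assert retained == ms and not out

    def test_p_tie_breaks_by_position(self):
        m1 = self._match("rsB", 200, 1e-8, 1)
        m2 = self._match("rsA", 100, 1e-8, 1)
        retained, _ = resolve_clumps([m1, m2])
        assert retained[0].association.pos == 100

    def test_retained_set_never_shares_clump_id(self):
        ms = [self._match(f"rs{i}", i * 10, 10.0**-(i % 5 + 4), i % 3)
              for i in range(12)]
        retained, clumped = resolve_clumps(ms)
        ids = [m.clump_id for m in retained]
        assert len(ids) == len(set(ids))
        assert len(retained) + len(clumped) == len(ms)

    def test_assign_clumps_singletons_never_collide_with_table(self):
        from prskit.ldclump import ClumpTable

        table = ClumpTable()
        table.add("EUR", "hg38", "1", 100, "rs1", 7)
        ms = [MatchedVariant(make_assoc(rsid="rs1", pos=100), 0),
              MatchedVariant(make_assoc(rsid="rs_absent", pos=900), 0)]
        assign_clumps(ms, table, "EUR", "hg38")
        assert ms[0].clump_id == 7
        assert ms[1].clump_id > 7


class TestImputation:
    def test_worked_example_frequency_0_2(self):
        # missing genotype at risk-allele frequency 0.2 contributes
        # 0.2 × 2 = 0.4 allele copies
        assert impute_missing(make_assoc(), "sample", 0.2, None) == 0.4

    @pytest.mark.parametrize("freq,expected", [(0.0, 0.0), (0.5, 1.0)])
    def test_boundary_frequencies(self, freq, expected):
        assert impute_missing(make_assoc(), "sample", freq, None) == expected

    def test_source_preference_and_fallback(self):
        rec = make_assoc(ref_allele_freq=0.1)
        assert impute_missing(rec, "sample", 0.2, 0.3) == 0.4
        assert impute_missing(rec, "reference", 0.2, 0.3) == 0.6
        assert impute_missing(rec, "sample", None, 0.3) == 0.6
        assert impute_missing(rec, "sample", None, None) == 0.2
        assert impute_missing(make_assoc(), "sample", None, None) is None

    def test_unknown_source_fatal(self):
        with pytest.raises(ValueError):
            impute_missing(make_assoc(), "panel", 0.2, None)


class TestComputeScore:
    def test_odds_ratio_zero_dosage_centres_at_one(self):
        effects = [(1.5, "odds_ratio"), (0.8, "odds_ratio")]
        assert compute_score(effects, [0.0, 0.0]) == pytest.approx(1.0)

    def test_single_or_variant_hand_value(self):
        assert compute_score([(1.5, "odds_ratio")], [2.0]) == pytest.approx(2.25)

    def test_beta_hand_value(self):
        effects = [(0.1, "beta"), (-0.3, "beta")]
        assert compute_score(effects, [2.0, 1.0]) == pytest.approx(-0.05)

    def test_mixed_effect_types_fatal(self):
        with pytest.raises(ValueError, match="mixed"):
            compute_score([(1.5, "odds_ratio"), (0.1, "beta")], [1.0, 1.0])

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            compute_score([], [])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_dosage(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 8))
        ors = np.exp(rng.normal(0, 0.3, size=m))
        dosages = rng.uniform(0, 2, size=m)
        effects = [(float(v), "odds_ratio") for v in ors]
        base = compute_score(effects, list(dosages))
        i = int(rng.integers(0, m))
        bumped = dosages.copy()
        bumped[i] = min(2.0, bumped[i] + 0.5)
        new = compute_score(effects, list(bumped))
        if ors[i] > 1:
            assert new >= base - 1e-12
        elif ors[i] < 1:
            assert new <= base + 1e-12
        assert base > 0  # odds-ratio scores are strictly positive


class TestScoreStudy:
    def _inputs(self):
        # two variants, two samples; rs2 missing for sample 2
        target = make_target([
            ("1", 100, "rs1", "A", "G", [1, 2]),
            ("1", 2_000_000, "rs2", "T", "C", [2, np.nan]),
        ], samples=("s1", "s2"))
        assocs = [
            make_assoc(rsid="rs1", pos=100, risk_allele="G",
                       effect_value=1.5, p_value=1e-9),
            make_assoc(rsid="rs2", pos=2_000_000, risk_allele="C",
                       effect_value=0.8, p_value=1e-7),
        ]
        return target, assocs

    def test_scores_match_hand_computation(self):
        target, assocs = self._inputs()
        entries = score_study(assocs, target, study_id="S1", trait="t",
                              build="hg38", population="EUR")
        by_sample = {e.sample: e for e in entries}
        s1 = by_sample["s1"]
        expected = math.exp((math.log(1.5) * 1 + math.log(0.8) * 2) / 2)
        assert s1.score == pytest.approx(expected, rel=1e-12)
        assert s1.n_imputed == 0
        # sample 2: rs2 missing -> imputed from sample frequency of C
        # (non-missing calls: only s1 with dosage 2 -> freq 1.0 -> dosage 2.0)
        s2 = by_sample["s2"]
        expected2 = math.exp((math.log(1.5) * 2 + math.log(0.8) * 2.0) / 2)
        assert s2.score == pytest.approx(expected2, rel=1e-12)
        assert s2.imputed_variants == ["rs2"]

    def test_risk_and_protective_classification(self):
        target, assocs = self._inputs()
        entries = score_study(assocs, target, study_id="S1", trait="t",
                              build="hg38", population="EUR")
        s1 = {e.sample: e for e in entries}["s1"]
        assert s1.risk_variants == ["rs1"]       # OR 1.5, dosage 1
        assert s1.protective_variants == ["rs2"]  # OR 0.8, dosage 2

    def test_imputation_consistency_with_observed_frequency(self):
        # replacing an observed dosage d by an imputed 2·(d/2) is a no-op
        target = make_target([("1", 100, "rs1", "A", "G", [1])])
        assoc = make_assoc(rsid="rs1", pos=100, risk_allele="G",
                           effect_value=1.4, ref_allele_freq=0.5)
        observed = score_study([assoc], target, study_id="S", trait="t",
                               build="hg38", population="EUR")[0].score
        gone = make_target([("1", 100, "rs1", "A", "G", [np.nan])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imputed = score_study([assoc], gone, study_id="S", trait="t",
                                  build="hg38", population="EUR")[0].score
        assert imputed == pytest.approx(observed, rel=1e-12)


class TestImputationThreshold:
    def _entry(self, n_included, n_imputed):
        return ScoreEntry(sample="s", study_id="S1", trait="t", build="hg38",
                          population="EUR", effect_type="odds_ratio",
                          score=1.0, n_included=n_included, n_imputed=n_imputed)

    def test_six_of_ten_removed_at_default(self):
        kept, excluded = apply_imputation_threshold([self._entry(10, 6)])
        assert not kept
        assert excluded[0].exclude_reason == "imputation_threshold"

    def test_zero_imputed_retained(self):
        kept, excluded = apply_imputation_threshold([self._entry(10, 0)])
        assert kept and not excluded

    def test_boundary_half_retained(self):
        kept, excluded = apply_imputation_threshold([self._entry(10, 5)])
        assert kept and not excluded
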