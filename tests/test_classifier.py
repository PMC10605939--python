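"""Five-tier rule engine, IHC concordance, mechanism tree, crypt evidence."""

import pytest

from mmr_vclass.classify import (
    Concordance,
    EvidenceProfile,
    FiveTierClass,
    MechanismLabel,
    RuleSet,
    build_evidence_profile,
    classify_acmg_insight,
    cohort_summary,
    combine_tumor_lr,
    final_tumor_classification,
    ihc_concordance,
    integrate_crypt_evidence,
    mlh1_methylation_call,
)
from mmr_vclass.core import (
    Cohort,
    CryptScreenRecord,
    IHCPattern,
    MethylationResult,
)
from mmr_vclass.somatic import SecondHit


class TestIHCConcordance:
    @pytest.mark.parametrize(
        "gene, ihc, expected",
        [
            ("MLH1", "MLH1/PMS2", Concordance.concordant),
            ("MLH1", "MLH1+/PMS2", Concordance.concordant),  # patchy counts as loss
            ("PMS2", "MLH1/PMS2", Concordance.discordant),  # partner-driven loss
            ("MSH6", "Normal", Concordance.no_loss),
            ("MSH6", "MLH1/PMS2", Concordance.discordant),
            ("MSH6", "MSH6", Concordance.concordant),
            ("MSH2", "MSH6", Concordance.discordant),  # solitary MSH6 is not MSH2 pattern
            ("PMS2", "PMS2", Concordance.concordant),
        ],
    )
    def test_dimer_pattern_rule(self, gene, ihc, expected):
        assert ihc_concordance(gene, IHCPattern.parse(ihc)) is expected

    def test_not_tested_excluded(self):
        assert ihc_concordance("MLH1", None) is None


class TestMethylationCall:
    def test_pmr_at_threshold_positive(self):
        assert mlh1_methylation_call(MethylationResult(methylight_pmr=12.0))
        assert mlh1_methylation_call(MethylationResult(methylight_pmr=10.0))

    def test_both_low_negative(self):
        assert not mlh1_methylation_call(
            MethylationResult(methylight_pmr=0.0, mshrm_percent=0.0)
        )

    def test_hrm_rule_fires_below_pmr_threshold(self):
        assert mlh1_methylation_call(
            MethylationResult(methylight_pmr=9.9, mshrm_percent=5.0)
        )


class TestCombineTumorLR:
    def test_empty_is_neutral(self):
        assert combine_tumor_lr([]) == 1.0

    def test_two_identical_tumors(self):
        assert round(combine_tumor_lr([6.52, 6.52]), 2) == 42.51

    def test_product(self):
        assert combine_tumor_lr([2.0, 3.0]) == pytest.approx(6.0)

    def test_associative_and_order_invariant(self):
        lrs = [0.41, 6.52, 1.96, 0.11]
        a = combine_tumor_lr(lrs)
        b = combine_tumor_lr(lrs[::-1])
        c = combine_tumor_lr([combine_tumor_lr(lrs[:2]), combine_tumor_lr(lrs[2:])])
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            combine_tumor_lr([6.52, 0.0])


class TestEvidenceProfile:
    def test_common_allele_is_not_rare(self, cohort):
        profile = build_evidence_profile(cohort.variants["V20"], cohort)
        assert profile.rare_in_population is False  # AF 0.00786 >= 1/50,000

    def test_vanishingly_rare_allele(self, cohort):
        profile = build_evidence_profile(cohort.variants["V09"], cohort)
        assert profile.rare_in_population is True  # AF 3.98e-6

    def test_absent_af_leaves_rarity_unknown(self, cohort):
        profile = build_evidence_profile(cohort.variants["V03"], cohort)
        assert profile.rare_in_population is None

    def test_neutral_evidence_keeps_prior(self):
        profile = EvidenceProfile(
            variant_id="x", prior_probability=0.5,
            tumor_lr_combined=1.0, seg_lr_combined=1.0,
        )
        from mmr_vclass.classify import _posterior
        assert _posterior(profile) == pytest.approx(0.5)

    def test_bystander_detected_for_co_carried_discordant_variant(self, cohort):
        assert build_evidence_profile(cohort.variants["V03"], cohort).bystander_evidence
        assert not build_evidence_profile(cohort.variants["V02"], cohort).bystander_evidence


class TestFiveTierEngine:
    def test_reproduces_all_curated_classes(self, cohort, fixture_analysis):
        """Calibration: the rule engine reproduces all 25 recorded classes."""
        results, _ = fixture_analysis
        got = {vid: k.klass for vid, k in results.variant_classes.items()}
        want = {vid: rec.printed_class for vid, rec in cohort.evidence.items()}
        assert got == want

    def test_class_distribution(self, fixture_analysis):
        results, _ = fixture_analysis
        counts = {}
        for k in results.variant_classes.values():
            counts[k.klass] = counts.get(k.klass, 0) + 1
        assert counts == {1: 1, 2: 2, 3: 15, 4: 7}

    def test_high_posterior_without_functional_data_stays_lp(self):
        profile = EvidenceProfile(
            variant_id="x", prior_probability=0.96, tumor_lr_combined=153.04,
            seg_lr_combined=1.96, seg_family_count=5,
        )
        from mmr_vclass.classify import _posterior
        profile.posterior_probability = _posterior(profile)
        assert profile.posterior_probability > 0.99
        assert classify_acmg_insight(profile).klass == 4  # never class 5 without function

    def test_empty_profile_is_vus(self):
        assert classify_acmg_insight(EvidenceProfile(variant_id="x")).klass == 3

    def test_label_matches_class(self):
        assert FiveTierClass(4).label.value == "LP"
        with pytest.raises(ValueError):
            FiveTierClass(4, "B")

    @pytest.mark.parametrize("vid", ["V05", "V14", "V16", "V21", "V25"])
    def test_monotone_in_tumor_lr(self, cohort, vid):
        """Scaling up the tumor odds never lowers the assigned class."""
        from mmr_vclass.classify import _posterior
        base = build_evidence_profile(cohort.variants[vid], cohort)
        previous = 0
        for factor in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0):
            profile = EvidenceProfile(**{**base.__dict__})
            if profile.tumor_lr_combined is not None:
                profile.tumor_lr_combined *= factor
            profile.posterior_probability = _posterior(profile)
            klass = classify_acmg_insight(profile).klass
            assert klass >= previous
            previous = klass


class TestFinalTumorClassification:
    def test_reproduces_all_curated_labels(self, fixture_analysis):
        """Decision tree concordance on all 29 recorded assessments."""
        results, _ = fixture_analysis
        for res in results.assessments:
            got = res.final.label.value if res.final.label else "UNRESOLVED"
            if res.final.implicated_gene:
                got += f"|{res.final.implicated_gene}"
            assert got == res.assessment.printed_final, res.assessment.tumor.tumor_id

    def test_methylation_precedes_everything(self):
        label = final_tumor_classification(
            "MSH2", IHCPattern.parse("MLH1/PMS2+"), SecondHit(False, []), [],
            msi_high=False, concordance=Concordance.discordant,
            methylation_positive=True,
        )
        assert label.label is MechanismLabel.dmmr_mlh1_methylation
        assert label.implicated_gene == "MLH1"

    def test_false_negative_ihc_still_calls_second_hit(self):
        label = final_tumor_classification(
            "MLH1", IHCPattern(), SecondHit(True, ["loh"]), [],
            msi_high=True, concordance=Concordance.no_loss,
        )
        assert label.label is MechanismLabel.dmmr_vus_plus_second_hit

    def test_ihc_matched_double_somatic_beats_discordant_second_hit(self):
        # solitary PMS2 loss + PMS2 double somatic outweighs an MSH6 hit
        label = final_tumor_classification(
            "MSH6", IHCPattern.parse("PMS2"), SecondHit(True, ["mut"]), ["PMS2"],
            msi_high=True, concordance=Concordance.discordant,
        )
        assert label.label is MechanismLabel.dmmr_double_somatic
        assert label.implicated_gene == "PMS2"

    def test_same_gene_double_somatic_sets_ambiguity_flag(self):
        label = final_tumor_classification(
            "MSH2", IHCPattern.parse("MSH2/MSH6"), SecondHit(True, ["mut", "mut"]),
            ["MSH2"], msi_high=True, concordance=Concordance.concordant,
        )
        assert label.label is MechanismLabel.dmmr_vus_plus_second_hit
        assert label.ambiguity_flag

    def test_mss_tumor_is_pmmr(self):
        label = final_tumor_classification(
            "PMS2", IHCPattern(), SecondHit(False, []), [],
            msi_high=False, concordance=Concordance.no_loss,
        )
        assert label.label is MechanismLabel.pmmr

    def test_unmatched_dmmr_forces_diagnostic(self):
        label = final_tumor_classification(
            "MLH1", IHCPattern.parse("MSH2/MSH6"), SecondHit(False, []), [],
            msi_high=True, concordance=Concordance.discordant,
        )
        assert label.label is None
        assert "no mechanism" in label.diagnostic


class TestCryptEvidence:
    def test_matching_gland_supports_pathogenicity(self):
        screen = CryptScreenRecord(
            carrier_id="c", tissue="endometrium", outcome="found",
            deficient_protein="MSH2",
        )
        report = integrate_crypt_evidence(FiveTierClass(3), screen, "MSH2")
        assert report.supports_pathogenic

    def test_negative_screen_never_downgrades(self, cohort, fixture_analysis):
        results, _ = fixture_analysis
        for screen in cohort.crypt_screens:
            if screen.variant_id is None or screen.outcome.value == "found":
                continue
            before = results.variant_classes[screen.variant_id]
            gene = cohort.variants[screen.variant_id].gene
            report = integrate_crypt_evidence(before, screen, gene)
            assert report.klass == before
            assert not report.supports_pathogenic

    def test_failed_stain_is_neutral(self):
        screen = CryptScreenRecord(
            carrier_id="c", tissue="endometrium", outcome="failed"
        )
        report = integrate_crypt_evidence(FiveTierClass(4), screen, "PMS2")
        assert report.klass.klass == 4 and not report.supports_pathogenic


class TestCohortSummary:
    def test_empty_cohort_gives_all_zero_summary(self):
        from mmr_vclass.classify import CohortResults
        summary = cohort_summary(Cohort(), CohortResults())
        assert summary.n_variants == 0
        assert summary.n_tumors_sequenced == 0
        assert all(v == 0 for v in summary.class_counts.values())

    def test_summary_equals_recount_oracle(self, cohort, fixture_analysis):
        """Each summary field equals a direct recount over the raw results."""
        results, summary = fixture_analysis
        primaries = [r for r in results.assessments if r.is_primary]
        assert summary.n_tumors_sequenced == len(primaries)
        assert summary.n_msi_high == sum(r.msi_high for r in primaries)
        assert summary.n_ihc_concordant_tumors == sum(
            r.concordance is Concordance.concordant for r in primaries
        )
        assert summary.n_double_somatic_carriers == len(
            {
                r.assessment.tumor.carrier_id
                for r in results.assessments
                if r.final.label is MechanismLabel.dmmr_double_somatic
            }
        )

    def test_summary_recount_on_synthetic_cohort(self, synthetic_run):
        run = synthetic_run
        assert run.summary.n_tumors_sequenced == len(run.per_tumor)
        assert run.summary.n_msi_high == sum(
            r.msi_high for r in run.results.assessments if r.is_primary
        )
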