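"""Consensus filtering, LOH testing, second hits and mutation burden."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mmr_vclass.core import Consequence, EventKind, GermlineVariant, SomaticCall, SomaticEvent
from mmr_vclass.somatic import (
    FilterConfig,
    LOHConfig,
    call_loh,
    classify_somatic_events,
    consensus_filter,
    detect_double_somatic,
    detect_second_hit,
    is_inactivating,
    passes_consensus_filter,
    tumor_mutation_burden,
)


def make_call(**kw):
    base = dict(
        chrom="chr_panel", pos=100, ref="A", alt="T", gene="MLH1",
        consequence=Consequence.missense, pass_caller_a=True, pass_caller_b=True,
        tumor_depth=100, normal_depth=100, tumor_alt=30, normal_alt=0,
    )
    base.update(kw)
    return SomaticCall(**base)


call_strategy = st.builds(
    make_call,
    pos=st.integers(1, 2_000),
    pass_caller_a=st.booleans(),
    pass_caller_b=st.booleans(),
    tumor_depth=st.integers(1, 200),
    normal_depth=st.integers(0, 200),
    tumor_alt=st.just(0),
).map(lambda c: (setattr(c, "tumor_alt", c.tumor_depth // 3), c)[1])


class TestConsensusFilter:
    def test_passing_call_retained(self):
        cfg = FilterConfig()
        call = make_call(tumor_depth=60, normal_depth=60, tumor_alt=8)  # VAF 0.133
        assert consensus_filter([call], cfg) == [call]

    def test_vaf_threshold_is_inclusive(self):
        cfg = FilterConfig()
        at_cutoff = make_call(tumor_depth=100, tumor_alt=10)  # exactly 10%
        below = make_call(tumor_depth=100, tumor_alt=9)
        assert consensus_filter([at_cutoff, below], cfg) == [at_cutoff]

    def test_empty_input(self):
        assert consensus_filter([], FilterConfig()) == []

    def test_single_caller_dropped(self):
        call = make_call(pass_caller_b=False)
        assert consensus_filter([call], FilterConfig()) == []

    def test_panel_restriction(self):
        cfg = FilterConfig(panel_region=(("chr_panel", 1, 1_000),))
        inside = make_call(pos=500)
        outside = make_call(pos=5_000)
        assert consensus_filter([inside, outside], cfg) == [inside]

    def test_zero_depth_logged_not_raised(self, caplog):
        call = make_call(tumor_depth=0, tumor_alt=0, normal_depth=60)
        with caplog.at_level("WARNING"):
            assert consensus_filter([call], FilterConfig()) == []
        assert any("zero-depth" in r.message for r in caplog.records)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(calls=st.lists(call_strategy, max_size=100))
    def test_matches_predicate_oracle_and_is_idempotent(self, calls):
        cfg = FilterConfig(min_depth=50, min_vaf=0.10)
        out = consensus_filter(calls, cfg)
        oracle = [c for c in calls if passes_consensus_filter(c, cfg)]
        assert out == oracle
        assert consensus_filter(out, cfg) == out


def fisher_two_sided(a, b, c, d):
    """Independent exact-test oracle: hypergeometric enumeration."""
    n1, k_total, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (
            math.comb(n1, k) * math.comb(n - n1, k_total - k) / math.comb(n, k_total)
        )

    p_obs = pmf(a)
    lo, hi = max(0, k_total - (n - n1)), min(n1, k_total)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def het_site(gene, tumor_alt, tumor_depth, normal_alt, normal_depth):
    return SomaticCall(
        chrom="1", pos=1, ref="G", alt="A", gene=gene, consequence=Consequence.other,
        tumor_depth=tumor_depth, tumor_alt=tumor_alt,
        normal_depth=normal_depth, normal_alt=normal_alt,
    )


class TestCallLOH:
    def test_identical_proportions_no_loh(self):
        site = het_site("MLH1", 100, 200, 100, 200)
        res = {r.gene: r for r in call_loh([site])}
        assert res["MLH1"].loh_flag is False

    def test_strong_shift_flagged_and_p_matches_enumeration_oracle(self):
        site = het_site("MSH2", 180, 200, 100, 200)
        res = {r.gene: r for r in call_loh([site])}
        assert res["MSH2"].loh_flag is True
        p_oracle = fisher_two_sided(180, 20, 100, 100)
        assert res["MSH2"].min_p == pytest.approx(p_oracle, rel=1e-6)
        assert p_oracle < 0.01

    def test_effect_size_gate_blocks_small_shifts(self):
        # delta VAF 0.05 < 0.15: never LOH regardless of p
        site = het_site("MLH1", 110, 200, 100, 200)
        res = {r.gene: r for r in call_loh([site])}
        assert res["MLH1"].loh_flag is False

    def test_no_informative_markers_is_untestable_not_false(self):
        # normal VAF 0.9: not heterozygous, so the gene cannot be assessed
        site = het_site("PMS2", 100, 200, 180, 200)
        res = {r.gene: r for r in call_loh([site])}
        assert res["PMS2"].loh_flag is None

    @pytest.mark.parametrize("t_alt,n_alt", [(180, 100), (30, 90), (100, 100)])
    def test_ref_alt_relabeling_symmetry(self, t_alt, n_alt):
        """Swapping which allele is 'alt' cannot change the LOH call."""
        site = het_site("MLH1", t_alt, 200, n_alt, 200)
        flipped = het_site("MLH1", 200 - t_alt, 200, 200 - n_alt, 200)
        res = {r.gene: r for r in call_loh([site])}
        res_f = {r.gene: r for r in call_loh([flipped])}
        assert res["MLH1"].loh_flag == res_f["MLH1"].loh_flag
        assert res["MLH1"].min_p == pytest.approx(res_f["MLH1"].min_p, rel=1e-9)


class TestClassifyEvents:
    def test_loh_plus_inactivating_mutation_gives_two_events(self):
        from mmr_vclass.somatic import LOHResult
        call = make_call(gene="MSH2", consequence=Consequence.nonsense)
        events = classify_somatic_events([call], [LOHResult("MSH2", True)])
        assert [(e.gene, e.kind) for e in events] == [
            ("MSH2", EventKind.single_mutation),
            ("MSH2", EventKind.loh),
        ]
        assert all(e.inactivating for e in events)

    def test_synonymous_unannotated_call_is_not_inactivating(self):
        call = make_call(gene="MSH6", consequence=Consequence.synonymous)
        events = classify_somatic_events([call])
        assert len(events) == 1 and not events[0].inactivating

    def test_non_mmr_gene_gives_no_event(self):
        call = make_call(gene="APC")
        assert classify_somatic_events([call]) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.builds(
                make_call,
                gene=st.sampled_from(["MLH1", "MSH2", "MSH6", "PMS2", "APC"]),
                consequence=st.sampled_from(list(Consequence)),
                acmg_class=st.one_of(st.none(), st.integers(1, 5)),
            ),
            max_size=20,
        )
    )
    def test_matches_rule_table_oracle(self, calls):
        events = classify_somatic_events(calls)
        mmr = [c for c in calls if c.gene in ("MLH1", "MSH2", "MSH6", "PMS2")]
        assert len(events) == len(mmr)
        for event, call in zip(events, mmr):
            if call.acmg_class is not None:
                expected = call.acmg_class >= 4
            else:
                expected = call.consequence in (
                    Consequence.nonsense, Consequence.frameshift, Consequence.splice
                )
            assert event.inactivating == expected


VUS_MSH2 = GermlineVariant(variant_id="v", gene="MSH2", hgvs_c="c.1A>G",
                           variant_type="missense")


class TestSecondHitAndDoubleSomatic:
    def test_hit_in_same_gene(self):
        events = [SomaticEvent(gene="MSH2", kind="single_mutation")]
        hit = detect_second_hit(VUS_MSH2, events)
        assert hit.present and hit.kinds == [EventKind.single_mutation]

    def test_hits_only_in_other_genes_are_absent(self):
        events = [
            SomaticEvent(gene="MSH6", kind="single_mutation"),
            SomaticEvent(gene="PMS2", kind="single_mutation"),
        ]
        assert not detect_second_hit(VUS_MSH2, events).present

    def test_no_events(self):
        assert not detect_second_hit(VUS_MSH2, []).present

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.builds(
                SomaticEvent,
                gene=st.sampled_from(["MLH1", "MSH2", "MSH6", "PMS2"]),
                kind=st.sampled_from(list(EventKind)),
                inactivating=st.booleans(),
            ),
            max_size=8,
        )
    )
    def test_second_hit_monotone_under_added_events(self, events):
        """Adding an inactivating event in the VUS gene never flips present->absent."""
        before = detect_second_hit(VUS_MSH2, events).present
        more = events + [SomaticEvent(gene="MSH2", kind="single_mutation")]
        after = detect_second_hit(VUS_MSH2, more).present
        assert after and (not before or after)

    def test_double_somatic_two_mutations(self):
        events = [SomaticEvent(gene="MLH1", kind="single_mutation")] * 2
        assert detect_double_somatic(events) == ["MLH1"]

    def test_double_somatic_loh_plus_mutation(self):
        events = [
            SomaticEvent(gene="MSH2", kind="loh"),
            SomaticEvent(gene="MSH2", kind="single_mutation"),
        ]
        assert detect_double_somatic(events) == ["MSH2"]

    def test_single_event_is_not_double(self):
        assert detect_double_somatic([SomaticEvent(gene="MSH2", kind="loh")]) == []

    def test_gene_order_is_deterministic(self):
        events = [
            SomaticEvent(gene="PMS2", kind="single_mutation"),
            SomaticEvent(gene="PMS2", kind="loh"),
            SomaticEvent(gene="MLH1", kind="loh"),
            SomaticEvent(gene="MLH1", kind="single_mutation"),
        ]
        assert detect_double_somatic(events) == ["MLH1", "PMS2"]


class TestTumorMutationBurden:
    def test_zero_calls(self):
        assert tumor_mutation_burden([], FilterConfig(target_megabases=2.0)) == 0.0

    def test_arithmetic(self):
        calls = [make_call()] * 100
        assert tumor_mutation_burden(calls, FilterConfig(target_megabases=2.0)) == 50.0

    def test_panel_footprint(self):
        calls = [make_call()] * 222
        tmb = tumor_mutation_burden(calls, FilterConfig())
        assert round(tmb, 1) == 110.7

    def test_linear_in_call_count(self):
        cfg = FilterConfig()
        one = tumor_mutation_burden([make_call()], cfg)
        assert tumor_mutation_burden([make_call()] * 7, cfg) == pytest.approx(7 * one)

    def test_invalid_target_size_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(target_megabases=0.0)
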