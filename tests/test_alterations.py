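import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverscape import alterations as alt
from driverscape import pipeline as pipe
from driverscape import synthetic as syn


def mut(sample="S1", gene="G1", effect="missense", votes=0, splice=0,
        hotspot=False, pos=None):
    return alt.MutationRecord(sample, gene, effect, votes, splice, hotspot, pos)


class TestClassifyMutation:
    @pytest.mark.parametrize("effect", ["stopgain", "stoploss", "frameshift"])
    def test_truncating_is_lof(self, effect):
        assert alt.classify_mutation(mut(effect=effect)) == "lof_damaging"

    @pytest.mark.parametrize("votes,expected", [
        (7, "lof_damaging"),   # at the 7-of-10 predictor threshold
        (6, "not_damaging"),   # just below
        (10, "lof_damaging"),
        (0, "not_damaging"),
    ])
    def test_missense_vote_threshold(self, votes, expected):
        assert alt.classify_mutation(mut(effect="missense", votes=votes)) == expected

    @pytest.mark.parametrize("splice,expected", [
        (1, "lof_damaging"),   # one of two splicing methods suffices
        (0, "not_damaging"),
        (2, "lof_damaging"),
    ])
    def test_splicing_vote_threshold(self, splice, expected):
        assert alt.classify_mutation(mut(effect="splicing", splice=splice)) == expected

    def test_hotspot_takes_precedence_over_damaging_votes(self):
        m = mut(effect="missense", votes=10, hotspot=True)
        assert alt.classify_mutation(m) == "gof_hotspot"

    def test_other_class_not_damaging(self):
        assert alt.classify_mutation(mut(effect="other")) == "not_damaging"

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError):
            mut(effect="nonsense_mediated")

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=10),
           st.integers(min_value=0, max_value=10))
    def test_vote_threshold_monotonicity(self, votes, threshold):
        """Raising the missense vote threshold never creates new LoF calls."""
        m = mut(effect="missense", votes=votes)
        lo = alt.classify_mutation(m, alt.Thresholds(missense_votes_min=threshold))
        hi = alt.classify_mutation(
            m, alt.Thresholds(missense_votes_min=min(threshold + 1, 11)))
        assert not (lo == "not_damaging" and hi == "lof_damaging")


class TestSegmentMapping:
    def _gene_models(self):
        return pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"],
                             "start": [0], "end": [1000]})

    def _segments(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "cn"])

    def test_quarter_coverage_emitted(self):
        out = alt.map_segments_to_genes(
            self._segments([("S1", "chr1", 0, 250, 2.0)]), self._gene_models())
        assert len(out) == 1
        assert out[0].covered_fraction == pytest.approx(0.25)

    def test_below_quarter_coverage_dropped(self):
        out = alt.map_segments_to_genes(
            self._segments([("S1", "chr1", 0, 240, 2.0)]), self._gene_models())
        assert out == []

    def test_coverage_weighted_cn(self):
        out = alt.map_segments_to_genes(
            self._segments([("S1", "chr1", 0, 300, 4.0),
                            ("S1", "chr1", 500, 800, 2.0)]), self._gene_models())
        assert len(out) == 1
        assert out[0].covered_fraction == pytest.approx(0.6)
        assert out[0].cn == pytest.approx(3.0)

    def test_zero_length_gene_rejected(self):
        gm = pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"],
                           "start": [100], "end": [100]})
        with pytest.raises(ValueError, match="G1"):
            alt.map_segments_to_genes(self._segments([]), gm)

    def test_multi_block_gene_sums_transcribed_length(self):
        gm = pd.DataFrame({"gene": ["G1", "G1"], "chrom": ["chr1", "chr1"],
                           "start": [0, 2000], "end": [500, 2500]})
        out = alt.map_segments_to_genes(
            self._segments([("S1", "chr1", 0, 500, 1.0)]), gm)
        assert out[0].covered_fraction == pytest.approx(0.5)


class TestCnvState:
    def _profile(self, ploidy=2.0, purity=0.6, fpkm=None):
        return alt.SampleProfile("S1", ploidy, purity, fpkm or {})

    def _cn(self, cn):
        return alt.GeneCN("S1", "G1", cn, 1.0)

    def test_gain_above_twice_ploidy(self):
        assert alt.call_cnv_state(self._cn(5.0), self._profile()) == "gain_candidate"

    def test_exactly_twice_ploidy_is_not_gain(self):
        assert alt.call_cnv_state(self._cn(4.0), self._profile()) == "neutral"

    def test_homozygous_loss_low_expression(self):
        p = self._profile(fpkm={"G1": 0.3})
        assert alt.call_cnv_state(self._cn(0.0), p) == "homozygous_loss"

    def test_cn_zero_rescued_by_expression(self):
        # FPKM/purity = 2.0 > 1: the deletion call is downgraded
        p = self._profile(fpkm={"G1": 1.2})
        assert alt.call_cnv_state(self._cn(0.0), p) == "heterozygous_loss"

    def test_purity_corrected_expression_at_boundary(self):
        # FPKM/purity just below vs exactly 1
        p = self._profile(purity=0.5, fpkm={"G1": 0.4999})
        assert alt.call_cnv_state(self._cn(0.0), p) == "homozygous_loss"
        p_eq = self._profile(purity=0.5, fpkm={"G1": 0.5})
        assert alt.call_cnv_state(self._cn(0.0), p_eq) == "neutral"

    def test_cn_one_with_tolerance(self):
        assert alt.call_cnv_state(self._cn(1.05), self._profile()) == "heterozygous_loss"
        assert alt.call_cnv_state(self._cn(1.2), self._profile()) == "neutral"

    def test_missing_expression_at_cn_zero_rejected(self):
        with pytest.raises(ValueError, match="G1"):
            alt.call_cnv_state(self._cn(0.0), self._profile())

    def test_cell_line_preset_bands(self):
        t = alt.PRESETS["cell_line"]
        # homozygous: CN < 0.25 x ploidy and expression < 1 TPM
        p = self._profile(ploidy=2.0, fpkm={"G1": 0.5})
        assert alt.call_cnv_state(self._cn(0.4), p, t) == "homozygous_loss"
        p_hi = self._profile(ploidy=2.0, fpkm={"G1": 2.0})
        assert alt.call_cnv_state(self._cn(0.4), p_hi, t) == "heterozygous_loss"
        # heterozygous band 0.25-0.75 x ploidy
        assert alt.call_cnv_state(self._cn(1.0), p, t) == "heterozygous_loss"
        assert alt.call_cnv_state(self._cn(1.6), p, t) == "neutral"
        assert alt.call_cnv_state(self._cn(5.0), p, t) == "gain_candidate"


class TestGainExpressionFilter:
    def test_extreme_separation_retained(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(40)]
        lo = rng.uniform(1, 2, 20)
        hi = rng.uniform(10, 20, 20)
        expr = pd.DataFrame([np.concatenate([hi, lo])], index=["G1"],
                            columns=samples)
        retained, table = alt.filter_gains_by_expression(
            {"G1": set(samples[:20])}, expr)
        assert retained == {"G1"}
        assert (table["fdr"] < 0.05).all()

    def test_identical_distributions_not_retained(self):
        expr = pd.DataFrame([[5.0] * 10], index=["G1"],
                            columns=[f"S{i}" for i in range(10)])
        retained, _ = alt.filter_gains_by_expression({"G1": {"S0", "S1"}}, expr)
        assert retained == set()

    def test_small_sample_exact_p_blocks_retention(self):
        # gains {4,5,6} vs rest {1,2,3}: exact two-sided p = 0.1 > 0.05
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["G1"],
                            columns=[f"S{i}" for i in range(6)])
        retained, table = alt.filter_gains_by_expression(
            {"G1": {"S3", "S4", "S5"}}, expr)
        assert table["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert retained == set()

    def test_higher_median_required(self):
        # significantly *lower* expression in gain samples must not pass
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(40)]
        lo = rng.uniform(1, 2, 20)
        hi = rng.uniform(10, 20, 20)
        expr = pd.DataFrame([np.concatenate([lo, hi])], index=["G1"],
                            columns=samples)
        retained, _ = alt.filter_gains_by_expression({"G1": set(samples[:20])}, expr)
        assert retained == set()


class TestAssignAlterations:
    def test_double_hit(self):
        calls = alt.assign_alterations(
            [mut(effect="stopgain")], {("G1", "S1"): "heterozygous_loss"},
            gene_cn={("G1", "S1"): 1.0})
        assert len(calls) == 1
        assert calls[0].category == "lof"
        assert "double_hit" in calls[0].evidence

    def test_het_loss_alone_is_no_call(self):
        calls = alt.assign_alterations([], {("G1", "S1"): "heterozygous_loss"})
        assert calls == []

    def test_hotspot_with_neutral_cn_is_gof(self):
        calls = alt.assign_alterations(
            [mut(effect="missense", votes=2, hotspot=True)],
            {("G1", "S1"): "neutral"})
        assert [(c.category, set(c.evidence)) for c in calls] == [("gof", {"hotspot"})]

    def test_non_damaging_mutation_no_call(self):
        calls = alt.assign_alterations([mut(effect="other")], {})
        assert calls == []

    def test_retained_gain_is_gof(self):
        calls = alt.assign_alterations(
            [], {("G1", "S1"): "gain_candidate"}, retained_gains={"G1"})
        assert [(c.category, set(c.evidence)) for c in calls] == [
            ("gof", {"gain_with_expression"})]

    def test_unretained_gain_is_no_call(self):
        calls = alt.assign_alterations([], {("G1", "S1"): "gain_candidate"})
        assert calls == []

    def test_pair_with_both_kinds_of_evidence_yields_two_calls(self):
        calls = alt.assign_alterations(
            [mut(effect="stopgain"),
             mut(effect="missense", votes=0, hotspot=True)],
            {("G1", "S1"): "homozygous_loss"})
        cats = sorted(c.category for c in calls)
        assert cats == ["gof", "lof"]

    def test_category_event_partition(self, small_cohort):
        """Every damaged (gene, sample, category) appears exactly once and
        the category totals add to the overall event count."""
        _, tables = small_cohort
        result = pipe.classify_cohort(tables)
        keys = [(c.gene, c.sample_id, c.category) for c in result["calls"]]
        assert len(keys) == len(set(keys))
        assert result["n_lof_events"] + result["n_gof_events"] == len(keys)


class TestRoles:
    @pytest.mark.parametrize("n_lof,n_gof,expected", [
        (30, 5, "putative_tsg"),
        (5, 30, "putative_og"),
        (10, 10, "unclassified"),
        (0, 0, "unclassified"),
    ])
    def test_strict_majority_rule(self, n_lof, n_gof, expected):
        calls = [alt.AlterationCall(f"S{i}", "G1", "lof", frozenset({"truncating"}))
                 for i in range(n_lof)]
        calls += [alt.AlterationCall(f"T{i}", "G1", "gof", frozenset({"hotspot"}))
                  for i in range(n_gof)]
        roles = alt.infer_putative_role(calls, genes=["G1"])
        assert roles[0].putative_role == expected

    def test_samples_counted_distinctly(self):
        # two LoF calls in the same sample count once
        calls = [
            alt.AlterationCall("S1", "G1", "lof", frozenset({"truncating"})),
            alt.AlterationCall("S1", "G1", "lof", frozenset({"homozygous_deletion"})),
            alt.AlterationCall("S2", "G1", "gof", frozenset({"hotspot"})),
        ]
        role = alt.infer_putative_role(calls)[0]
        assert (role.n_lof_samples, role.n_gof_samples) == (1, 1)
        assert role.putative_role == "unclassified"


class TestBurden:
    def test_counts_and_fractions(self):
        calls = [
            alt.AlterationCall("S1", "TP53", "lof", frozenset({"truncating"})),
            alt.AlterationCall("S1", "KRAS", "gof", frozenset({"hotspot"})),
            alt.AlterationCall("S2", "TP53", "lof", frozenset({"truncating"})),
        ]
        df, frac = alt.sample_driver_burden(
            calls, ["S1", "S2", "S3", "S4"], {"TP53", "KRAS"},
            canonical_genes={"TP53", "KRAS"}, healthy_genes={"KRAS"})
        burdens = dict(zip(df["sample"], df["n_drivers"]))
        assert burdens == {"S1": 2, "S2": 1, "S3": 0, "S4": 0}
        assert frac["frac_zero"] == pytest.approx(0.5)
        assert frac["frac_lt5_all"] == pytest.approx(1.0)
        assert frac["frac_ge2_with_healthy"] == pytest.approx(0.25)

    def test_gene_counts_once_per_sample(self):
        calls = [
            alt.AlterationCall("S1", "TP53", "lof", frozenset({"truncating"})),
            alt.AlterationCall("S1", "TP53", "gof", frozenset({"hotspot"})),
        ]
        df, _ = alt.sample_driver_burden(calls, ["S1"], {"TP53"})
        assert df["n_drivers"].iloc[0] == 1

    def test_burden_fraction_enumeration(self):
        # burdens {0, 1, 5, 7} -> half the cohort has < 5 damaged drivers
        calls = []
        for s, n in zip(["S1", "S2", "S3", "S4"], [0, 1, 5, 7]):
            calls += [alt.AlterationCall(s, f"G{i}", "lof",
                                         frozenset({"truncating"}))
                      for i in range(n)]
        genes = {f"G{i}" for i in range(8)}
        _, frac = alt.sample_driver_burden(calls, ["S1", "S2", "S3", "S4"], genes)
        assert frac["frac_lt5_all"] == pytest.approx(0.5)


class TestNaiveHotspots:
    def test_recurrent_position_flagged(self):
        muts = [mut(sample=f"S{i}", effect="missense", votes=1, pos=42)
                for i in range(3)]
        muts.append(mut(sample="S9", effect="missense", votes=1, pos=7))
        out = alt.naive_hotspots(muts, min_samples=3)
        assert [m.hotspot_flag for m in out] == [True, True, True, False]

    def test_recurrence_requires_distinct_samples(self):
        muts = [mut(sample="S1", effect="missense", pos=42) for _ in range(5)]
        out = alt.naive_hotspots(muts, min_samples=3)
        assert not any(m.hotspot_flag for m in out)


class TestRecordValidation:
    def test_vote_ranges_enforced(self):
        with pytest.raises(ValueError):
            mut(votes=11)
        with pytest.raises(ValueError):
            mut(splice=3)

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            alt.SampleProfile("S", 0.0, 0.5)
        with pytest.raises(ValueError):
            alt.SampleProfile("S", 2.0, 1.5)

    def test_evidence_category_consistency(self):
        with pytest.raises(ValueError):
            alt.AlterationCall("S", "G", "lof", frozenset({"hotspot"}))
        with pytest.raises(ValueError):
            alt.AlterationCall("S", "G", "gof", frozenset())
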