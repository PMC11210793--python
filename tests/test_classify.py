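"""Valence calls, |DD| quartile rubric, channel-dependence classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import chemotax as ct
from chemotax.stats import EffectSize, PAdjustRecord


def eff(mean, lo, hi):
    return EffectSize(
        mean_difference=mean, ci_low=lo, ci_high=hi, n_test=100, n_control=100,
        n_resamples=5000, seed=0, p_value=0.01 if (lo > 0 or hi < 0) else 0.5,
    )


RUBRIC = ct.RubricConfig(median_threshold=3.02, quartile_edges=(1.5, 3.02, 7.0))


def panel(tax4_wt, osm9_wt, double_wt, tax4_double, osm9_double):
    return {
        "tax4_vs_wt": tax4_wt,
        "osm9_vs_wt": osm9_wt,
        "double_vs_wt": double_wt,
        "tax4_vs_double": tax4_double,
        "osm9_vs_double": osm9_double,
    }


class TestValence:
    def test_significant_positive_vs_both_nulls_is_attractant(self):
        call = ct.classify_valence(eff(3.5, 2, 5), eff(3.0, 1.5, 4.5))
        assert call.chemoactive and call.valence == "attractant"
        assert not call.putative_false_positive

    def test_ci_straddling_zero_is_inactive(self):
        call = ct.classify_valence(eff(0.2, -1, 1), eff(0.1, -1, 1))
        assert not call.chemoactive and call.valence == "inactive"

    def test_negative_effect_is_repellent(self):
        call = ct.classify_valence(eff(-4, -5, -3), eff(-4, -5, -3))
        assert call.valence == "repellent"

    def test_single_null_significance_suffices(self):
        call = ct.classify_valence(eff(2, -0.5, 4.5), eff(2.5, 1, 4))
        assert call.chemoactive
        assert call.vs_null_flags == {"DMSO:DMSO": False, "DMSO:water": True}

    def test_conflicting_signs_flagged_ambiguous(self):
        call = ct.classify_valence(eff(2, 1, 3), eff(-2, -3, -1))
        assert call.ambiguous and call.valence == "attractant"

    def test_lost_after_fdr_marks_putative_false_positive(self):
        padj = PAdjustRecord(raw_p=0.03, adjusted_p=0.11, rejected=False)
        call = ct.classify_valence(eff(1.2, 0.2, 2.2), eff(1.0, -0.1, 2.1), padj)
        assert call.chemoactive and call.putative_false_positive


class TestQuartileRubric:
    def test_four_values_median(self):
        rub = ct.quartile_rubric([1.0, 2.0, 3.0, 4.0])
        assert rub.median_threshold == 2.5

    @given(st.lists(st.floats(0, 20), min_size=4, max_size=100))
    def test_matches_sorting_oracle(self, vals):
        rub = ct.quartile_rubric(vals)
        expect = np.percentile(np.sort(np.asarray(vals)), [25, 50, 75])
        assert np.allclose(rub.quartile_edges, expect)
        assert rub.median_threshold == rub.quartile_edges[1]

    def test_bins_span_quartiles(self):
        assert [RUBRIC.bin_of(v) for v in (0.5, 2.0, 5.0, 10.0)] == [0, 1, 2, 3]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ct.quartile_rubric([1.0, 2.0])


class TestDependence:
    def test_all_zero_is_unclassified(self):
        call = ct.classify_dependence(panel(0, 0, 0, 0, 0), RUBRIC)
        assert call.dependence_class == "unclassified" and not call.inversion

    def test_tax4_primary_rubric(self):
        call = ct.classify_dependence(panel(10, 1, 9, 1, 8), RUBRIC, compound_id="f")
        assert call.dependence_class == "tax4_primary"

    def test_osm9_primary_rubric(self):
        call = ct.classify_dependence(panel(1, 10, 9, 8, 1), RUBRIC)
        assert call.dependence_class == "osm9_primary"

    def test_both_required_when_singles_phenocopy_double(self):
        call = ct.classify_dependence(panel(8, 9, 10, 1, 1), RUBRIC)
        assert call.dependence_class == "both_required"

    def test_redundant_when_singles_phenocopy_wild_type(self):
        call = ct.classify_dependence(panel(1, 1, 10, 8, 9), RUBRIC)
        assert call.dependence_class == "redundant"

    def test_partial_when_everything_differs(self):
        call = ct.classify_dependence(panel(8, 9, 10, 6, 7), RUBRIC)
        assert call.dependence_class == "partial"

    def test_missing_comparison_named_in_error(self):
        bad = panel(1, 1, 1, 1, 1)
        del bad["osm9_vs_double"]
        with pytest.raises(KeyError, match="osm9_vs_double"):
            ct.classify_dependence(bad, RUBRIC)

    def test_accepts_delta_delta_objects(self):
        dd = ct.DeltaDelta(delta1=0, delta2=10, delta_delta=-10, ci_low=-12,
                           ci_high=-8, n_resamples=100, seed=0)
        call = ct.classify_dependence(
            {**panel(0, 1, 9, 1, 8), "tax4_vs_wt": dd}, RUBRIC
        )
        assert call.quartile_bins["tax4_vs_wt"] == 3

    def test_order_invariance(self):
        """Calls depend only on values, not on dict insertion order."""
        p1 = panel(10, 1, 9, 1, 8)
        p2 = dict(reversed(list(p1.items())))
        c1 = ct.classify_dependence(p1, RUBRIC)
        c2 = ct.classify_dependence(p2, RUBRIC)
        assert c1.dependence_class == c2.dependence_class


class TestInversion:
    @pytest.mark.parametrize(
        "wt_sig,wt_sign,mut_sig,mut_sign,expected",
        [
            (True, +1, True, -1, True),
            (True, -1, True, +1, True),
            (True, +1, True, +1, False),
            (True, +1, False, -1, False),
            (False, +1, True, -1, False),
        ],
    )
    def test_sign_truth_table(self, wt_sig, wt_sign, mut_sig, mut_sign, expected):
        def mk(sig, sign):
            m = 3.0 * sign
            return eff(m, m - 1, m + 1) if sig else eff(m, m - 5, m + 5)

        assert ct.detect_inversion(mk(wt_sig, wt_sign), {"m": mk(mut_sig, mut_sign)}) \
            is expected

    def test_any_single_mutant_can_flip(self):
        wt = eff(2, 1, 3)
        muts = {"tax4": eff(2, 1, 3), "osm9": eff(-2, -3, -1)}
        assert ct.detect_inversion(wt, muts)
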