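"""Crossing-design logic: enumeration, prediction, validation, McNemar."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from bayesase.crossdesign import (
    Cross,
    CrossDesign,
    TestcrossTriple,
    ai_percentage,
    design_size,
    detect_poo,
    enumerate_testcrosses,
    mcnemar_sex_difference,
    predict_divergent,
    reciprocal_pairs,
    validate_predictions,
)


def full_grid(lines=("A", "B", "C")):
    return CrossDesign(
        tuple(Cross(f"{m}x{p}", m, p) for m in lines for p in lines if m != p)
    )


class TestDesignSize:
    def test_printed_direct_example(self):
        assert design_size(10, "direct") == 45

    def test_two_alleles_one_cross(self):
        assert design_size(2, "direct") == 1

    def test_testcross_is_linear(self):
        assert design_size(10, "testcross") == 10

    def test_too_few_alleles_error(self):
        with pytest.raises(ValueError):
            design_size(1, "direct")

    @pytest.mark.parametrize("n", range(3, 30))
    def test_direct_dominates_testcross_from_three(self, n):
        direct, test = design_size(n, "direct"), design_size(n, "testcross")
        assert direct >= test
        assert (direct == test) == (n == 3)


class TestEnumerateTestcrosses:
    def test_three_line_grid_yields_six_triples(self):
        triples = enumerate_testcrosses(full_grid())
        assert len(triples) == 6
        assert {(t.tester, t.parental_role) for t in triples} == {
            (l, r) for l in "ABC" for r in ("maternal", "paternal")
        }

    def test_single_cross_empty(self):
        d = CrossDesign((Cross("AxB", "A", "B"),))
        assert enumerate_testcrosses(d) == []

    def test_two_lines_both_reciprocals_empty(self):
        d = CrossDesign((Cross("AxB", "A", "B"), Cross("BxA", "B", "A")))
        assert enumerate_testcrosses(d) == []

    def test_tester_role_consistent_within_triple(self):
        for t in enumerate_testcrosses(full_grid()):
            assert t.nontester_a != t.nontester_b

    def test_reciprocal_pairs_of_full_grid(self):
        pairs = reciprocal_pairs(full_grid())
        assert len(pairs) == 3


def fits_frame(comp, ev_h3=None, ev_h1=None):
    n = len(ev_h3 if ev_h3 is not None else ev_h1)
    df = pd.DataFrame({"FEATURE_ID": [f"g{i}" for i in range(n)], "COMPARISON": comp})
    if ev_h3 is not None:
        df["EV_H3"] = ev_h3
    if ev_h1 is not None:
        df["EV_H1"] = ev_h1
    return df


TRIPLE = TestcrossTriple("A", "B", "C", "maternal", "AxB", "AxC")


class TestPredictDivergent:
    def test_threshold_rule(self):
        fits = fits_frame("AxB_vs_AxC", ev_h3=[0.01, 0.5, 0.04])
        pred = predict_divergent(TRIPLE, fits, alpha=0.05)
        assert pred.tolist() == [1, 0, 1]

    def test_low_coverage_masked(self):
        fits = fits_frame("AxB_vs_AxC", ev_h3=[0.01, 0.01])
        pred = predict_divergent(TRIPLE, fits, alpha=0.05, low_coverage={"g0"})
        assert pred.tolist() == [0, 1]

    def test_missing_comparison_names_triple(self):
        with pytest.raises(KeyError, match="B vs C"):
            predict_divergent(TRIPLE, fits_frame("other", ev_h3=[0.5]), 0.05)


class TestDetectPoo:
    PAIR = (Cross("BxC", "B", "C"), Cross("CxB", "C", "B"))

    def test_threshold(self):
        fits = fits_frame("BxC_vs_CxB", ev_h3=[0.001, 0.9])
        poo = detect_poo(fits, "BxC_vs_CxB", self.PAIR, 0.05)
        assert poo.tolist() == [1, 0]

    def test_non_reciprocal_error(self):
        bad = (Cross("BxC", "B", "C"), Cross("AxB", "A", "B"))
        with pytest.raises(ValueError, match="not reciprocal"):
            detect_poo(fits_frame("x", ev_h3=[0.5]), "x", bad, 0.05)


class TestValidatePredictions:
    def _inputs(self, ev_direct_a, ev_direct_b, predicted, poo=None):
        n = len(predicted)
        idx = [f"g{i}" for i in range(n)]
        pred = pd.Series(predicted, index=idx, name="predicted_divergent")
        poo = pd.Series(poo if poo is not None else [0] * n, index=idx)
        direct = [
            fits_frame("d1", ev_h1=ev_direct_a),
            fits_frame("d2", ev_h1=ev_direct_b),
        ]
        return pred, direct, poo

    def test_percentage_arithmetic(self):
        pred, direct, poo = self._inputs(
            [0.01, 0.01, 0.01, 0.9, 0.9], [0.9] * 5, [1, 1, 1, 1, 0]
        )
        rep = validate_predictions(pred, direct, poo)
        assert rep.n_total == 4
        assert rep.pct_validated_total == pytest.approx(75.0)

    def test_either_reciprocal_validates(self):
        pred, direct, poo = self._inputs([0.9], [0.01], [1])
        assert validate_predictions(pred, direct, poo).pct_validated_total == 100.0

    def test_strict_both_reciprocals_flag(self):
        pred, direct, poo = self._inputs([0.9], [0.01], [1])
        rep = validate_predictions(pred, direct, poo, require_both=True)
        assert rep.pct_validated_total == 0.0

    def test_empty_prediction_set_reports_absent(self):
        pred, direct, poo = self._inputs([0.01], [0.01], [0])
        rep = validate_predictions(pred, direct, poo)
        assert rep.n_total == 0
        assert rep.pct_validated_total is None and rep.pct_validated_poo is None

    def test_poo_subset_aggregates(self):
        pred, direct, poo = self._inputs(
            [0.01, 0.9, 0.01], [0.9, 0.9, 0.9], [1, 1, 1], poo=[1, 1, 0]
        )
        rep = validate_predictions(pred, direct, poo)
        assert rep.n_poo == 2 and rep.n_poo <= rep.n_total
        assert rep.pct_validated_poo == pytest.approx(50.0)


class TestAiPercentage:
    @pytest.mark.parametrize(
        "ev,expected", [([0.01] * 8 + [0.5] * 92, 8.0), ([0.9] * 10, 0.0), ([0.0] * 4, 100.0)]
    )
    def test_percentages(self, ev, expected):
        assert ai_percentage(fits_frame("c", ev_h1=ev)) == pytest.approx(expected)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ai_percentage(fits_frame("c", ev_h1=[]))


class TestMcnemar:
    def test_balanced_discordance(self):
        m = [1] * 10 + [0] * 10
        f = [0] * 10 + [1] * 10
        b, c, p = mcnemar_sex_difference(m, f)
        assert (b, c) == (10, 10) and p == pytest.approx(1.0)

    def test_exact_binomial_example(self):
        m = [1] * 15 + [0] * 5 + [1, 0] * 10
        f = [0] * 15 + [1] * 5 + [1, 0] * 10
        b, c, p = mcnemar_sex_difference(m, f)
        assert (b, c) == (15, 5)
        assert p == pytest.approx(0.0414, abs=5e-4)

    def test_no_discordance_degenerate(self):
        assert mcnemar_sex_difference([1, 0], [1, 0]) == (0, 0, 1.0)

    def test_matches_statsmodels_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(0, 2, 60)
            f = rng.integers(0, 2, 60)
            b, c, p = mcnemar_sex_difference(m, f)
            table = [[np.sum((m == 1) & (f == 1)), b], [c, np.sum((m == 0) & (f == 0))]]
            ref = sm_mcnemar(table, exact=True).pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            mcnemar_sex_difference([1, 0], [1])
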