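"""TIMBR scoring: expression filtering, GPR summarization, weight
transforms, production bounds, demands, scores and validation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timbr import (
    ExpressionChanges,
    Timbr,
    classify_predictions,
    compare_species,
    classify_correlations,
    compound_suitability,
    evaluate_calls,
    filter_significant,
    make_irreversible,
    normalize_scores,
    parse_gpr,
    production_bound,
    raw_production_score,
    summarize_gpr,
    summarize_network,
    timbr_weights,
)
from timbr.fixtures import FixtureSpec, planted_expression, toy_network
from timbr.scoring import condition_weights, default_weights


def expr_table(rows, **kwargs) -> ExpressionChanges:
    return ExpressionChanges(
        pd.DataFrame(rows, columns=["gene_id", "log2fc", "qvalue"]), **kwargs)


class TestSignificanceFilter:
    def test_rowwise_behaviour(self):
        expr = expr_table([("a", 2.0, 0.5), ("b", 2.0, 0.05), ("c", -1.0, 0.1)])
        out = filter_significant(expr, 0.1)
        got = out.data.set_index("gene_id")["log2fc"]
        # q >= threshold zeroed (boundary inclusive), significant kept
        assert got["a"] == 0.0 and got["c"] == 0.0
        assert got["b"] == 2.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        rows = [(f"g{i}", float(rng.normal()), float(rng.uniform()))
                for i in range(200)]
        out = filter_significant(expr_table(rows), 0.1)
        for (gid, fc, q), got in zip(rows, out.data["log2fc"]):
            assert got == (fc if q < 0.1 else 0.0)


class TestSuitability:
    def test_below_threshold_unsuitable(self):
        genes = {f"g{i}" for i in range(2000)}
        rows = [(f"g{i}", 1.0, 0.01) for i in range(10)]
        ok, n = compound_suitability(expr_table(rows), genes)
        assert not ok and n == 10

    def test_one_percent_boundary_inclusive(self):
        genes = {f"g{i}" for i in range(2000)}
        rows = [(f"g{i}", 1.0, 0.01) for i in range(20)]
        ok, n = compound_suitability(expr_table(rows), genes)
        assert ok and n == 20

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compound_suitability(expr_table([("a", 1.0, 0.01)]), set())


class TestSummarizeGPR:
    def test_isozyme_dilution(self):
        # one significant isozyme averaged with an unaffected partner
        assert summarize_gpr(parse_gpr("A or B"), {"A": 1.0}) == \
            pytest.approx(0.5)

    def test_complex_takes_largest_magnitude(self):
        assert summarize_gpr(parse_gpr("A and B"),
                             {"A": 0.5, "B": -2.0}) == pytest.approx(-2.0)

    def test_nested_rule_hand_evaluation(self):
        # AND(OR(A,B), C): mean(2, 0) = 1 vs |-0.5| -> +1
        value = summarize_gpr(parse_gpr("(A or B) and C"),
                              {"A": 2.0, "B": 0.0, "C": -0.5})
        assert value == pytest.approx(1.0)

    def test_magnitude_tie_prefers_positive(self):
        assert summarize_gpr(parse_gpr("A and B"),
                             {"A": -1.0, "B": 1.0}) == pytest.approx(1.0)

    def test_absent_genes_contribute_zero(self):
        assert summarize_gpr(parse_gpr("A or B"), {}) == 0.0


class TestWeights:
    def test_transform_examples(self):
        trt, ctl = timbr_weights(1.0, 1.0)
        assert (trt, ctl) == (0.5, 2.0)
        trt, ctl = timbr_weights(1.0, 0.0)
        assert (trt, ctl) == (1.0, 1.0)
        trt, ctl = timbr_weights(2.0, -1.0)
        assert (trt, ctl) == (4.0, 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.5, 8.0), st.floats(-8.0, 8.0))
    def test_reciprocity(self, w_default, r):
        trt, ctl = timbr_weights(w_default, r)
        assert trt * ctl == pytest.approx(w_default ** 2, rel=1e-9)
        if r == 0.0:
            assert trt == ctl == w_default

    def test_default_weight_table(self):
        net = toy_network(FixtureSpec(seed=0, gpr_profile=("single",)))
        irrev = make_irreversible(net)
        expr = expr_table([(g, 1.0, 0.01) for g in net.genes])
        summaries = summarize_network(net, expr)
        w = default_weights(irrev, summaries)
        by_col = {irrev.columns[j]: w[j] for j in range(irrev.n_columns)}
        # gene-associated transport with data -> 2
        assert by_col[("T1_in", 1)] == 2.0
        # gene-associated biochemical with data -> 1
        assert by_col[("B1_1", 1)] == 1.0
        # non-enzymatic exchange -> transport default 2, doubled
        assert by_col[("EX_P1", 1)] == 4.0
        # non-enzymatic biochemical (biomass) -> 1 doubled
        assert by_col[("biomass", 1)] == 2.0

    def test_no_platform_data_doubles_weight(self):
        net = toy_network(FixtureSpec(seed=0, gpr_profile=("single",)))
        irrev = make_irreversible(net)
        # platform covers no model genes at all
        expr = expr_table([("off_platform_gene", 1.0, 0.01)])
        summaries = summarize_network(net, expr)
        w = default_weights(irrev, summaries)
        by_col = {irrev.columns[j]: w[j] for j in range(irrev.n_columns)}
        assert by_col[("B1_1", 1)] == 2.0

    def test_split_directions_share_weight(self):
        net = toy_network(FixtureSpec(seed=0, fraction_reversible=1.0))
        irrev = make_irreversible(net)
        expr = planted_expression(net, "P1[e]", "up", seed=0)
        summaries = summarize_network(net, filter_significant(expr))
        _, trt, ctl = condition_weights(irrev, summaries)
        j_fwd, j_rev = irrev.column("B1_1", 1), irrev.column("B1_1", -1)
        assert trt[j_fwd] == trt[j_rev]
        assert ctl[j_fwd] == ctl[j_rev]


class TestProductionBound:
    def test_fva_branch(self):
        net = toy_network(FixtureSpec(seed=0, uptake_bound=50.0))
        irrev = make_irreversible(net)
        assert production_bound(irrev, "P1[e]") == pytest.approx(45.0)

    def test_cap_branch(self):
        net = toy_network(FixtureSpec(seed=0, uptake_bound=500.0))
        irrev = make_irreversible(net)
        assert production_bound(irrev, "P1[e]") == pytest.approx(100.0)

    def test_unproducible_returns_none(self):
        net = toy_network(FixtureSpec(seed=0))
        irrev = make_irreversible(net)
        # A1 is only consumed, never produced
        assert production_bound(irrev, "A1[e]") is None

    def test_non_exchangeable_rejected(self):
        net = toy_network(FixtureSpec(seed=0))
        irrev = make_irreversible(net)
        with pytest.raises(ValueError, match="no exchange"):
            production_bound(irrev, "P1[c]")


class TestScores:
    def test_equal_demands_score_zero(self):
        assert raw_production_score(5.0, 5.0) == 0.0

    def test_third_demand_scores_half(self):
        assert raw_production_score(2.0, 6.0) == pytest.approx(0.5)

    def test_antisymmetry(self):
        assert raw_production_score(3.0, 7.0) == \
            pytest.approx(-raw_production_score(7.0, 3.0))

    def test_uniform_demand_scaling_invariance(self):
        assert raw_production_score(4.0, 6.0) == \
            pytest.approx(raw_production_score(4.0 * 3.7, 6.0 * 3.7))

    def test_nonpositive_demand_rejected(self):
        with pytest.raises(ValueError):
            raw_production_score(0.0, 1.0)

    def test_znormalization_arithmetic(self):
        # sample sd of {1,2,3} is exactly 1
        assert normalize_scores(np.array([1.0, 2.0, 3.0])) == \
            pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = normalize_scores(np.array([2.0, 2.0, 2.0]))
        assert (out == 0).all()

    def test_normalized_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = normalize_scores(rng.normal(size=100))
        assert abs(out.mean()) < 1e-12
        assert out.std(ddof=1) == pytest.approx(1.0)


class TestTimbrPipeline:
    def test_null_expression_gives_all_zero_raw_scores(self):
        net = toy_network(FixtureSpec(seed=2))
        expr = ExpressionChanges(pd.DataFrame(
            [(g, 0.5, 0.9) for g in net.genes],
            columns=["gene_id", "log2fc", "qvalue"]))
        res = Timbr(net, expr).fit()
        scored = res.scored
        assert len(scored) >= 2
        assert np.allclose(scored["demand_treatment"],
                           scored["demand_control"])
        assert np.allclose(scored["raw_score"], 0.0)

    @pytest.mark.parametrize("direction, extreme",
                             [("up", "first"), ("down", "last")])
    def test_planted_signal_recovery(self, direction, extreme):
        net = toy_network(FixtureSpec(seed=11, n_pathways=3))
        expr = planted_expression(net, "P2[e]", direction, seed=11)
        res = Timbr(net, expr).fit()
        ranked = res.score_series().sort_values(ascending=False)
        target_pos = list(ranked.index).index("P2[e]")
        assert target_pos == (0 if extreme == "first" else len(ranked) - 1)

    def test_scores_invariant_to_uniform_weight_scaling(self):
        """Linearity of the demand LP plus the ratio form of the raw
        score makes production scores invariant to scaling all default
        weights by a common factor."""
        net = toy_network(FixtureSpec(seed=7))
        expr = planted_expression(net, "P1[e]", "up", seed=7)
        irrev = make_irreversible(net)
        summaries = summarize_network(net, filter_significant(expr))
        _, trt, ctl = condition_weights(irrev, summaries)
        from timbr.engine import min_weighted_flux

        ex = irrev.column(net.exchange_for("P1[e]"), 1)
        bound = production_bound(irrev, "P1[e]")
        raw = raw_production_score(
            min_weighted_flux(irrev, trt, ex, bound).demand,
            min_weighted_flux(irrev, ctl, ex, bound).demand)
        raw_scaled = raw_production_score(
            min_weighted_flux(irrev, 5.0 * trt, ex, bound).demand,
            min_weighted_flux(irrev, 5.0 * ctl, ex, bound).demand)
        assert raw_scaled == pytest.approx(raw, rel=1e-9)

    def test_demand_matches_path_enumeration_oracle(self):
        """On an acyclic fixture the optimal weighted demand equals
        min over synthesis routes of rate x (sum of route weights),
        enumerated by hand over the reaction chain."""
        net = toy_network(FixtureSpec(seed=13, n_pathways=1,
                                      pathway_length=4,
                                      fraction_reversible=0.0))
        assert len(net.reactions) <= 12
        expr = planted_expression(net, "P1[e]", "up", seed=13)
        irrev = make_irreversible(net)
        summaries = summarize_network(net, filter_significant(expr))
        _, trt, _ = condition_weights(irrev, summaries)
        from timbr.engine import min_weighted_flux

        rate = production_bound(irrev, "P1[e]")
        res = min_weighted_flux(
            irrev, trt, irrev.column(net.exchange_for("P1[e]"), 1), rate)
        route = ["EX_A1", "T1_in", "B1_1", "B1_2", "T1_out", "EX_P1"]
        # both split directions of a reaction share one weight, so the
        # route cost is rate times the sum of per-reaction weights
        weight_of = {rid: trt[j] for j, (rid, _) in enumerate(irrev.columns)}
        expected = rate * sum(weight_of[rid] for rid in route)
        assert res.demand == pytest.approx(expected, rel=1e-9)

    def test_summary_prints_scores(self):
        net = toy_network(FixtureSpec(seed=2))
        expr = planted_expression(net, "P1[e]", "up", seed=2)
        res = Timbr(net, expr).fit()
        text = res.summary()
        assert "P1[e]" in text and "scored" in text


class TestComparisonAndValidation:
    def test_identical_and_negated_vectors(self):
        s = pd.Series([1.0, -0.5, 0.3, 2.0, -1.2],
                      index=list("abcde"))
        rec_pos = compare_species(s, s)
        rec_neg = compare_species(s, -s)
        classify_correlations([rec_pos, rec_neg], fdr=0.1)
        assert rec_pos.r == pytest.approx(1.0)
        assert rec_pos.label == "positive"
        assert rec_neg.r == pytest.approx(-1.0)
        assert rec_neg.label == "negative"

    def test_too_few_pairs_undefined(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        assert compare_species(s, s).label == "undefined"

    def test_quantile_calls_boundary_inclusive(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        calls = classify_predictions(scores)
        assert (calls[scores <= scores.quantile(0.25)] == "reduced").all()
        assert (calls[scores >= scores.quantile(0.75)] == "elevated").all()
        assert (calls[(scores > scores.quantile(0.25))
                      & (scores < scores.quantile(0.75))] == "unchanged").all()

    def test_perfect_calls_give_mcc_one(self):
        truth = pd.Series(["elevated", "reduced", "unchanged", "unchanged"],
                          index=list("abcd"))
        ev = evaluate_calls(truth.copy(), truth)
        assert ev.mcc == pytest.approx(1.0)

    def test_all_unchanged_calls_have_zero_sensitivity(self):
        truth = pd.Series(["elevated", "unchanged"], index=["a", "b"])
        calls = pd.Series(["unchanged", "unchanged"], index=["a", "b"])
        ev = evaluate_calls(calls, truth)
        assert ev.sensitivity == 0.0

    def test_mcc_denominator_zero_reported(self):
        truth = pd.Series(["elevated", "reduced"], index=["a", "b"])
        calls = pd.Series(["elevated", "elevated"], index=["a", "b"])
        assert evaluate_calls(calls, truth).mcc is None
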