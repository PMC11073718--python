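"""Group decision pipeline: weights, aggregation, normalization, ranking."""

import pytest

from phfcorr import (
    Criterion,
    DecisionProblem,
    Expert,
    GroupHFMatrix,
    GroupPHFMatrix,
    PHFElement,
    PHFValidationError,
    criteria_weights,
    evaluate,
    group_matrix,
    ideal_alternative,
    load_fixture,
    normalize,
    rank,
    saaty_value,
    to_phf_matrix,
    weighted_numeric_matrices,
)

TOL = 5e-5


@pytest.fixture(scope="module")
def case():
    fx = load_fixture("case-study")
    return fx


@pytest.fixture(scope="module")
def case_result(case):
    return evaluate(case.payload["problem"], rounding="paper")


class TestSaatyScale:
    def test_endpoints_and_middle(self):
        assert saaty_value("VL") == 1
        assert saaty_value("M") == 5
        assert saaty_value("VH") == 9

    def test_scale_is_strictly_increasing_one_to_nine(self):
        vals = [saaty_value(t) for t in ("VL", "VLL", "L", "ML", "M", "MH", "H", "HVH", "VH")]
        assert vals == list(range(1, 10))

    def test_unknown_term_rejected(self):
        with pytest.raises(PHFValidationError):
            saaty_value("XXL")


class TestCriteriaWeights:
    def test_case_study_integration(self, case):
        problem = case.payload["problem"]
        integrated, normalized = criteria_weights(
            problem.importance, [0.25] * 4, [e.name for e in problem.experts]
        )
        # first criterion: 0.25*(5+5+3+5) = 4.5, transcribed term by term
        assert integrated[0] == pytest.approx(
            0.25 * saaty_value("M") * 3 + 0.25 * saaty_value("L"), abs=1e-12
        )
        assert integrated == pytest.approx((4.5, 6.75, 8.0, 2.0), abs=1e-12)
        total = 4.5 + 6.75 + 8.0 + 2.0
        assert normalized == pytest.approx(
            (4.5 / total, 6.75 / total, 8.0 / total, 2.0 / total), abs=1e-12
        )
        assert sum(normalized) == pytest.approx(1.0, abs=1e-12)

    def test_sequence_input_equivalent_to_mapping(self):
        rows = [("M", "H"), ("L", "VH")]
        i1, n1 = criteria_weights(rows, [0.5, 0.5])
        i2, n2 = criteria_weights({"a": rows[0], "b": rows[1]}, [0.5, 0.5], ["a", "b"])
        assert i1 == i2 and n1 == n2
        assert i1 == (4.0, 8.0)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(PHFValidationError):
            criteria_weights([("M", "H")], [0.5, 0.5])
        with pytest.raises(PHFValidationError):
            criteria_weights([("M", "H"), ("L",)], [0.5, 0.5])


class TestNumericAndGroupMatrices:
    def test_saaty_times_expert_weight(self, case):
        problem = case.payload["problem"]
        numeric = weighted_numeric_matrices(problem)
        # D1 rates A1 under C1 as VH: 9 * 0.25 = 2.25
        assert numeric["D1"][0][0] == pytest.approx(2.25)
        # D3 rates A1 under C1 as HVH: 8 * 0.25 = 2.0
        assert numeric["D3"][0][0] == pytest.approx(2.0)

    def test_group_cells_collect_all_experts_sorted(self, case):
        problem = case.payload["problem"]
        numeric = weighted_numeric_matrices(problem)
        g = group_matrix(numeric, problem.alternatives, problem.criteria)
        # A1/C1 across D1..D4: VH, VH, HVH, HVH -> (2.0, 2.0, 2.25, 2.25)
        assert g.cells[0][0] == pytest.approx((2.0, 2.0, 2.25, 2.25))
        # every cell has one value per expert, ascending
        for row in g.cells:
            for cell in row:
                assert len(cell) == len(problem.experts)
                assert list(cell) == sorted(cell)

    def test_mismatched_grid_shapes_rejected(self):
        crit = (Criterion("C1", "benefit"),)
        with pytest.raises(PHFValidationError):
            group_matrix({"a": [[1.0]], "b": [[1.0, 2.0]]}, ("A1",), crit)


class TestNormalize:
    def test_benefit_column_divided_by_max(self, case):
        problem = case.payload["problem"]
        g = group_matrix(
            weighted_numeric_matrices(problem), problem.alternatives, problem.criteria
        )
        n = normalize(g, rounding="paper")
        # A1/C1 = (2, 2, 2.25, 2.25) over column max 2.25 -> 0.89, 0.89, 1, 1
        assert n.cells[0][0] == pytest.approx((0.89, 0.89, 1.0, 1.0))

    def test_cost_column_min_over_value(self, case):
        problem = case.payload["problem"]
        g = group_matrix(
            weighted_numeric_matrices(problem), problem.alternatives, problem.criteria
        )
        n = normalize(g, rounding="paper")
        # C2 is cost with column minimum 0.75 (term L); A1's values are
        # (1, 1, 1, 1.25) -> 0.75/v = (0.75, 0.75, 0.75, 0.6); inversion
        # reverses the raw ascending order, merge re-sorts downstream
        assert sorted(n.cells[0][1]) == pytest.approx((0.6, 0.75, 0.75, 0.75))

    def test_all_values_in_unit_interval_with_column_top_at_one(self, case_result):
        n = case_result.normalized
        for j, crit in enumerate(n.criteria):
            col = n.column(j)
            assert all(0.0 < v <= 1.0 + 1e-12 for v in col)
            assert max(col) == pytest.approx(1.0, abs=0.005)  # rounded mode

    def test_precise_mode_keeps_full_precision(self, case):
        problem = case.payload["problem"]
        g = group_matrix(
            weighted_numeric_matrices(problem), problem.alternatives, problem.criteria
        )
        n = normalize(g, rounding="precise")
        assert n.cells[0][0][0] == pytest.approx(2.0 / 2.25, abs=1e-15)

    def test_half_up_rounding(self):
        # 0.625 must round to 0.63 (half-up), not 0.62 (banker's)
        crit = (Criterion("C1", "benefit"),)
        g = GroupHFMatrix(("A1", "A2"), crit, (((0.625, 1.0),), ((1.0, 1.0),)))
        n = normalize(g, rounding="paper")
        assert n.cells[0][0] == (0.63, 1.0)

    def test_unknown_rounding_mode_rejected(self):
        crit = (Criterion("C1", "benefit"),)
        g = GroupHFMatrix(("A1",), crit, (((1.0,),),))
        with pytest.raises(PHFValidationError):
            normalize(g, rounding="approximate")

    def test_nonpositive_cost_column_rejected(self):
        crit = (Criterion("C1", "cost"),)
        g = GroupHFMatrix(("A1",), crit, (((0.0, 1.0),),))
        with pytest.raises(ZeroDivisionError):
            normalize(g)


class TestToPHFMatrix:
    def test_equal_values_merge_with_frequency_probability(self):
        crit = (Criterion("C1", "benefit"),)
        g = GroupHFMatrix(("A1",), crit, (((0.32, 0.32, 0.56, 0.72),),))
        phf = to_phf_matrix(g)
        assert phf.cells[0][0].entries == ((0.32, 0.5), (0.56, 0.25), (0.72, 0.25))

    def test_all_equal_collapses_to_certainty(self):
        crit = (Criterion("C1", "benefit"),)
        g = GroupHFMatrix(("A1",), crit, (((0.5, 0.5, 0.5),),))
        phf = to_phf_matrix(g)
        assert phf.cells[0][0].entries == ((0.5, 1.0),)

    def test_case_study_matches_published_cells(self, case_result):
        published = {
            "A1": (((0.89, 0.5), (1.0, 0.5)), ((0.6, 0.25), (0.75, 0.75))),
            "A3": (((0.67, 0.25), (0.78, 0.75)), ((0.33, 0.5), (0.43, 0.5))),
        }
        phf = case_result.phf
        for name, cells in published.items():
            i = phf.alternatives.index(name)
            for j, want in enumerate(cells):
                got = phf.cells[i][j].entries
                assert len(got) == len(want)
                for (gv, gp), (wv, wp) in zip(got, want):
                    assert gv == pytest.approx(wv, abs=0.005)
                    assert gp == pytest.approx(wp, abs=1e-12)


class TestIdealAlternative:
    def test_case_study_ideal(self, case_result):
        want = (
            ((0.89, 0.5), (1.0, 0.5)),
            ((0.75, 0.5), (1.0, 0.5)),
            ((0.88, 1.0),),
            ((0.78, 0.5), (1.0, 0.5)),
        )
        for got, entries in zip(case_result.ideal, want):
            assert len(got.entries) == len(entries)
            for (gm, gp), (wm, wp) in zip(got.entries, entries):
                assert gm == pytest.approx(wm, abs=1e-12)
                assert gp == pytest.approx(wp, abs=1e-12)

    def test_score_tie_broken_by_lower_deviation(self):
        crit = (Criterion("C1", "benefit"),)
        spread = PHFElement([(0.2, 0.6), (0.8, 0.4)])   # score 0.44, dev 0.0864
        tight = PHFElement([(0.6, 0.2), (0.4, 0.8)])    # score 0.44, dev 0.0064
        m = GroupPHFMatrix(("A1", "A2"), crit, ((spread,), (tight,)))
        assert ideal_alternative(m)[0] is tight
        m2 = GroupPHFMatrix(("A1", "A2"), crit, ((tight,), (spread,)))
        assert ideal_alternative(m2)[0] is tight

    def test_remaining_tie_keeps_lowest_index(self):
        crit = (Criterion("C1", "benefit"),)
        e1 = PHFElement([(0.5, 1.0)])
        e2 = PHFElement([(0.5, 1.0)])
        m = GroupPHFMatrix(("A1", "A2"), crit, ((e1,), (e2,)))
        assert ideal_alternative(m)[0] is e1


class TestRank:
    def test_case_study_coefficients_and_order(self, case_result):
        r = case_result.ranking
        assert r.coefficients == pytest.approx(
            (0.7708, 0.8932, 0.9589, 0.6794, 0.4699), abs=TOL
        )
        assert r.order == ("A3", "A2", "A1", "A4", "A5")
        assert r.best == "A3" and r.worst == "A5"
        assert str(r) == "A3 > A2 > A1 > A4 > A5"

    def test_sensitivity_fourth_weight_vector_flips_a1_a2(self, case_result):
        r = rank(case_result.phf, (0.4, 0.3, 0.2, 0.1), case_result.ideal)
        assert r.coefficients == pytest.approx(
            (0.8432, 0.8080, 0.9240, 0.7912, 0.4805), abs=TOL
        )
        assert r.order == ("A3", "A1", "A2", "A4", "A5")

    def test_order_follows_coefficients_descending(self, case_result):
        r = case_result.ranking
        by_name = dict(zip(r.alternatives, r.coefficients))
        vals = [by_name[a] for a in r.order]
        assert vals == sorted(vals, reverse=True)

    def test_exact_tie_reported(self):
        crit = (Criterion("C1", "benefit"),)
        e = PHFElement([(0.5, 1.0)])
        m = GroupPHFMatrix(("A1", "A2"), crit, ((e,), (e,)))
        r = rank(m, (1.0,))
        assert r.order == ("A1", "A2")
        assert r.ties == (("A1", "A2"),)

    def test_rank_reversal_fixtures_preserve_relative_order(self):
        for fid in ("rank-reversal-A6", "rank-reversal-A6plus"):
            fx = load_fixture(fid)
            r = rank(fx.payload["matrix"], fx.payload["weights"])
            assert r.order == fx.expected["ranking"]
            filtered = tuple(
                a for a in r.order if a in fx.expected["original_order"]
            )
            assert filtered == fx.expected["original_order"]


class TestEvaluateEndToEnd:
    def test_result_carries_all_intermediates(self, case_result):
        assert case_result.integrated_weights is None  # explicit weights supplied
        assert case_result.criteria_weights == (0.21, 0.31, 0.39, 0.09)
        assert set(case_result.numeric_matrices) == {"D1", "D2", "D3", "D4"}
        assert len(case_result.phf.cells) == 5

    def test_derived_weights_used_when_not_supplied(self, case):
        problem = case.payload["problem"]
        p2 = DecisionProblem(
            alternatives=problem.alternatives,
            criteria=problem.criteria,
            experts=problem.experts,
            matrices=problem.matrices,
            importance=problem.importance,
        )
        res = evaluate(p2, rounding="paper")
        assert res.integrated_weights == pytest.approx((4.5, 6.75, 8.0, 2.0))
        assert res.criteria_weights == pytest.approx(
            (0.21176470588235294, 0.3176470588235294,
             0.3764705882352941, 0.09411764705882353),
            abs=1e-12,
        )
        # exact weights still put A3 first and A5 last
        assert res.ranking.best == "A3" and res.ranking.worst == "A5"

    def test_precise_mode_same_top_and_bottom(self, case):
        res = evaluate(case.payload["problem"], rounding="precise")
        assert res.ranking.best == "A3" and res.ranking.worst == "A5"


class TestProblemValidation:
    def _base(self, **over):
        kw = dict(
            alternatives=("A1",),
            criteria=(Criterion("C1", "benefit"),),
            experts=(Expert("D1", 1.0),),
            matrices={"D1": (("M",),)},
            weights=(1.0,),
        )
        kw.update(over)
        return kw

    def test_valid_problem_constructs(self):
        DecisionProblem(**self._base())

    @pytest.mark.parametrize(
        "over",
        [
            {"matrices": {}},
            {"matrices": {"D1": ()}},
            {"matrices": {"D1": (("M", "M"),)}},
            {"matrices": {"D1": (("BOGUS",),)}},
            {"experts": (Expert("D1", 0.6),)},
            {"weights": None},
            {"weights": (0.5,)},
        ],
    )
    def test_malformed_problems_rejected(self, over):
        with pytest.raises(PHFValidationError):
            DecisionProblem(**self._base(**over))

    def test_bad_criterion_direction_rejected(self):
        with pytest.raises(PHFValidationError):
            Criterion("C1", "sideways")
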