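"""The transformation QP: weights, mapping, solving, reporting."""

import numpy as np
import pandas as pd
import pytest

import qm2ta as q
from qm2ta.exceptions import DomainError, ModelLookupError
from qm2ta.model_core import check_flux, model_bounds, stoichiometric_matrix
from qm2ta.qp import DiagQP
from qm2ta.synthetic import qp_oracle
from qm2ta.transform import (
    TransformationProblem,
    _quadratic_coefficients,
    evaluate_objective,
)


def make_ref(model, values):
    series = pd.Series({r.id: 0.0 for r in model.reactions})
    for k, v in values.items():
        series[k] = v
    return q.FluxVector(series, label="reference")


def de_frame(rows):
    return pd.DataFrame(rows, columns=["measure_id", "kind", "fc", "p_adj"])


class TestComputeWeight:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.025, 1.0), (0.25, 0.0), (0.0025, 2.0), (0.5, 0.0), (1.0, 0.0)],
    )
    def test_decades_below_threshold(self, p, expected):
        assert q.compute_weight(p, 0.25) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing_in_p(self):
        grid = np.logspace(-6, -0.01, 40)
        weights = [q.compute_weight(p, 0.25) for p in grid]
        assert all(w1 >= w2 - 1e-12 for w1, w2 in zip(weights, weights[1:]))

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_domain_p_rejected(self, p):
        with pytest.raises(DomainError):
            q.compute_weight(p, 0.25)


class TestMapMeasures:
    def test_gene_measure_maps_through_gpr(self, toy6):
        de = de_frame([("g1", "gene", 2.0, 0.025)])
        measures, ru, dropped = q.map_measures(toy6, de)
        assert len(measures) == 1 and dropped == 0
        m = measures[0]
        assert m.reactions == frozenset({"R1"})
        assert m.weight == pytest.approx(1.0)
        assert set(ru) == {r.id for r in toy6.reactions} - {"R1"}

    def test_metabolite_measure_maps_to_sink(self, toy6):
        met = de_frame([("C", "metabolite", 0.5, 0.01)])
        measures, ru, _ = q.map_measures(toy6, de_frame([]), met)
        assert measures[0].reactions == frozenset({"SK_C"})
        assert "SK_C" in toy6.reactions  # sink added in place

    def test_insignificant_measures_leave_everything_unmeasured(self, toy6):
        de = de_frame([("g1", "gene", 2.0, 0.3), ("g2", "gene", 0.5, 0.9)])
        measures, ru, dropped = q.map_measures(toy6, de)
        assert measures == [] and dropped == 2
        assert set(ru) == {r.id for r in toy6.reactions}

    def test_unmapped_gene_dropped_with_warning(self, toy6):
        de = de_frame([("ghost", "gene", 2.0, 0.01)])
        with pytest.warns(UserWarning, match="ghost"):
            measures, _, dropped = q.map_measures(toy6, de)
        assert measures == [] and dropped == 1


class TestDrugConstraint:
    def _problem(self, toy6, ref):
        return TransformationProblem(toy6, ref, (), tuple(r.id for r in toy6.reactions))

    @pytest.mark.parametrize("vref,fraction,expected", [(8.0, 0.5, 4.0), (8.0, 1.0, 8.0), (0.0, 0.5, 0.0)])
    def test_cap_at_fraction_of_reference(self, toy6, vref, fraction, expected):
        ref = make_ref(toy6, {"R2": vref})
        problem = self._problem(toy6, ref)
        constrained = q.apply_drug_constraint(problem, "R2", fraction)
        assert constrained.model.reactions.R2.upper_bound == pytest.approx(expected)
        # original model untouched
        assert toy6.reactions.R2.upper_bound == 1000

    def test_unknown_reaction_rejected(self, toy6):
        ref = make_ref(toy6, {})
        with pytest.raises(ModelLookupError):
            q.apply_drug_constraint(self._problem(toy6, ref), "GLS", 0.5)


class TestSolveQM2TA:
    def reference(self, toy6):
        # a feasible interior reference: half the flux per route
        return make_ref(
            toy6, {"EX_A": 8.0, "R1": 3.0, "R2": 5.0, "R3": 3.0, "EX_B": 0.0, "BM": 8.0}
        )

    def test_no_measures_returns_feasible_reference(self, toy6):
        ref = self.reference(toy6)
        problem = q.build_problem(toy6, ref, de_frame([]))
        res = q.solve_qm2ta(problem)
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.v_res.values.values, ref.values.values, atol=1e-6)

    def test_infeasible_reference_projected(self, toy6):
        ref = self.reference(toy6)
        toy6.reactions.EX_A.upper_bound = 6.0  # reference uptake 8 now illegal
        problem = q.build_problem(toy6, ref, de_frame([]))
        res = q.solve_qm2ta(problem)
        assert res.v_res["EX_A"] <= 6.0 + 1e-9
        assert res.objective > 0
        check_flux(problem.model, res.v_res)

    def test_achievable_target_reached_exactly(self, toy6):
        ref = self.reference(toy6)
        de = de_frame([("g2", "gene", 1.2, 0.025)])  # R2: 5 -> 6, slack exists
        problem = q.build_problem(toy6, ref, de)
        res = q.solve_qm2ta(problem)
        # target reachable only by moving Ru reactions (EX_A or R1/R3), so
        # the optimum trades a small Ru deviation against the measure term;
        # residual must be far below the untreated deviation
        assert res.residuals["g2"] < 0.5
        assert res.v_res["R2"] > 5.0

    def test_jointly_feasible_target_gives_zero_objective(self, toy6):
        # route flux can swap between R2 and R1+R3 at constant exchange:
        # targets R2: 5->6 and R1,R3: 3->2 are jointly consistent
        ref = self.reference(toy6)
        de = de_frame(
            [("g2", "gene", 1.2, 0.025), ("g1", "gene", 2 / 3, 0.01),
             ("g3", "gene", 2 / 3, 0.01)]
        )
        problem = q.build_problem(toy6, ref, de)
        res = q.solve_qm2ta(problem)
        assert res.objective == pytest.approx(0.0, abs=1e-8)
        assert res.v_res["R2"] == pytest.approx(6.0, abs=1e-5)
        assert res.v_res["R1"] == pytest.approx(2.0, abs=1e-5)

    def test_objective_matches_independent_evaluation(self, toy6):
        ref = self.reference(toy6)
        de = de_frame([("g1", "gene", 2.0, 0.025), ("g2", "gene", 0.5, 0.005)])
        problem = q.build_problem(toy6, ref, de)
        res = q.solve_qm2ta(problem)
        independent = evaluate_objective(problem, res.v_res.values)
        assert res.objective == pytest.approx(independent, rel=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimum_matches_kkt_oracle(self, toy6, seed):
        rng = np.random.default_rng(seed)
        ref = make_ref(
            toy6,
            {"EX_A": 8.0, "R1": rng.uniform(1, 4), "R2": rng.uniform(3, 6),
             "R3": rng.uniform(1, 4), "EX_B": rng.uniform(0, 1), "BM": 7.0},
        )
        de = de_frame(
            [("g1", "gene", rng.uniform(0.3, 3), rng.uniform(0.001, 0.2)),
             ("g2", "gene", rng.uniform(0.3, 3), rng.uniform(0.001, 0.2))]
        )
        problem = q.build_problem(toy6, ref, de)
        res = q.solve_qm2ta(problem)
        a, b, const = _quadratic_coefficients(problem)
        S = stoichiometric_matrix(problem.model)
        lb, ub = model_bounds(problem.model)
        _, oracle_obj = qp_oracle(DiagQP(S, a, b, lb, ub, const))
        assert res.objective == pytest.approx(oracle_obj, rel=1e-6, abs=1e-9)

    def test_scale_invariance(self, toy6):
        ref = self.reference(toy6)
        de = de_frame([("g1", "gene", 2.0, 0.05), ("g2", "gene", 0.6, 0.01)])
        problem = q.build_problem(toy6, ref, de)
        res = q.solve_qm2ta(problem)

        c = 3.7
        scaled_model = toy6.copy()
        for rxn in scaled_model.reactions:
            rxn.bounds = (rxn.lower_bound * c, rxn.upper_bound * c)
        scaled_ref = q.FluxVector(ref.values * c, "reference")
        scaled_problem = q.build_problem(scaled_model, scaled_ref, de)
        scaled_res = q.solve_qm2ta(scaled_problem)
        assert scaled_res.objective == pytest.approx(res.objective, rel=1e-5)
        assert np.allclose(
            scaled_res.v_res.values.values, c * res.v_res.values.values,
            rtol=1e-5, atol=1e-6,
        )

    def test_lower_p_never_raises_own_residual(self, toy6):
        ref = self.reference(toy6)
        residuals = []
        for p in [0.2, 0.1, 0.02, 0.002]:
            de = de_frame(
                [("g2", "gene", 1.6, p), ("g1", "gene", 0.5, 0.05)]
            )
            problem = q.build_problem(toy6, ref, de)
            res = q.solve_qm2ta(problem)
            residuals.append(res.residuals["g2"] / q.compute_weight(p, 0.25))
        # unweighted squared deviation of the measure shrinks as p drops
        assert all(r1 >= r2 - 1e-9 for r1, r2 in zip(residuals, residuals[1:]))


class TestFluxFoldChanges:
    def test_forced_category_counts(self):
        ref = q.FluxVector(pd.Series({f"R{i}": 1.0 for i in range(5)}))
        res = q.FluxVector(
            pd.Series(
                {"R0": 1.3, "R1": 1.25, "R2": 1.0, "R3": 0.76, "R4": 0.7}
            ),
            "qm2ta",
        )
        table, counts = q.flux_fold_changes(res, ref)
        assert counts == {"up": 2, "down": 1, "unchanged": 2}
        assert table.loc["R1", "category"] == "up"      # inclusive at 1.25
        assert table.loc["R3", "category"] == "unchanged"

    def test_identity_is_all_unchanged(self, toy6):
        ref = q.FluxVector(pd.Series({r.id: 2.0 for r in toy6.reactions}))
        _, counts = q.flux_fold_changes(ref, ref)
        assert counts == {"up": 0, "down": 0, "unchanged": len(toy6.reactions)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_independent_recount(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"R{i}" for i in range(50)]
        ref = q.FluxVector(pd.Series(rng.uniform(0.5, 5, 50), index=ids))
        res = q.FluxVector(
            pd.Series(ref.values.values * rng.lognormal(0, 0.5, 50), index=ids),
            "qm2ta",
        )
        table, counts = q.flux_fold_changes(res, ref)
        up = down = unchanged = 0
        for rid in ids:
            fc = abs(res[rid]) / abs(ref[rid])
            if fc >= 1.25:
                up += 1
            elif fc <= 0.75:
                down += 1
            else:
                unchanged += 1
        assert counts == {"up": up, "down": down, "unchanged": unchanged}


class TestPathwaySummary:
    def test_doubled_pathway_flux_is_one_log2_unit(self):
        ref = q.FluxVector(pd.Series({"R1": 1.0, "R2": 3.0, "R3": 2.0}))
        res = q.FluxVector(pd.Series({"R1": 2.0, "R2": 6.0, "R3": 2.0}), "qm2ta")
        out = q.pathway_flux_summary(res, ref, {"R1": "gly", "R2": "gly", "R3": "tca"})
        assert out["gly"] == pytest.approx(1.0)
        assert out["tca"] == pytest.approx(0.0)

    def test_identity_gives_zero_everywhere(self, toy6):
        ref = q.FluxVector(pd.Series({r.id: 1.5 for r in toy6.reactions}))
        pathway_map = {r.id: r.subsystem for r in toy6.reactions if r.subsystem}
        out = q.pathway_flux_summary(ref, ref, pathway_map)
        assert np.allclose(out.values, 0.0)

    def test_hand_summed_oracle_on_toy6(self, toy6):
        ref = q.FluxVector(
            pd.Series({"EX_A": 8, "R1": 3, "R2": 5, "R3": 3, "EX_B": 0, "BM": 8.0})
        )
        res = q.FluxVector(
            pd.Series({"EX_A": 8, "R1": 6, "R2": 2, "R3": 6, "EX_B": 0, "BM": 8.0}),
            "qm2ta",
        )
        pathway_map = {"R1": "upper", "R3": "upper", "R2": "lower"}
        out = q.pathway_flux_summary(res, ref, pathway_map)
        assert out["upper"] == pytest.approx(np.log2(12 / 6))
        assert out["lower"] == pytest.approx(np.log2(2 / 5))

    def test_zero_reference_pathway_is_nan_not_inf(self):
        ref = q.FluxVector(pd.Series({"R1": 0.0}))
        res = q.FluxVector(pd.Series({"R1": 1.0}), "qm2ta")
        out = q.pathway_flux_summary(res, ref, {"R1": "p"})
        assert np.isnan(out["p"])

    def test_empty_map_rejected(self, toy6):
        ref = q.FluxVector(pd.Series({r.id: 1.0 for r in toy6.reactions}))
        with pytest.raises(DomainError):
            q.pathway_flux_summary(ref, ref, {})
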