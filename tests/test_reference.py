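"""Reference flux chain: weighted minimization, FVA restriction, sampling."""

import numpy as np
import pytest

import qm2ta as q
from qm2ta.exceptions import InfeasibleError, UnboundedError
from qm2ta.model_core import (
    biomass_reaction_id,
    check_flux,
    model_bounds,
    stoichiometric_matrix,
)
from qm2ta.reference import gime3_weights, prepare_reference_model
from qm2ta.synthetic import lp_oracle


class TestGime3Minimize:
    def test_low_expression_route_avoided(self, toy6):
        # g3 barely expressed, g2 highly: weighted minimization should route
        # A -> C directly through R2 and leave R3 unused
        expr = {"g1": 5.0, "g2": 100.0, "g3": 0.01}
        constrained, _ = prepare_reference_model(toy6, 0.95)
        flux, _ = q.gime3_minimize(constrained, expr)
        assert flux["R3"] == pytest.approx(0.0, abs=1e-8)
        assert flux["R2"] >= 0.95 * 10 - 1e-6
        check_flux(constrained, flux)

    def test_uniform_expression_reduces_to_flux_minimization(self, toy6):
        expr = {"g1": 1.0, "g2": 1.0, "g3": 1.0}
        constrained, opt = prepare_reference_model(toy6, 1.0)
        flux, _ = q.gime3_minimize(constrained, expr)
        # minimum total flux at full biomass: EX_A=BM=10 via the direct route
        total = flux.values.abs().sum()
        # oracle: weighted (uniform) LP over split variables, via vertex
        # enumeration on the same polytope with the biomass bound applied
        S = stoichiometric_matrix(constrained)
        lb, ub = model_bounds(constrained)
        w = gime3_weights(constrained, expr)
        best = min(
            float(np.abs(v) @ w) for v in _all_vertices(S, lb, ub)
        )
        assert float(flux.values.abs() @ w) == pytest.approx(best, rel=1e-6)
        assert total == pytest.approx(30.0, rel=1e-6)  # EX_A + R2 + BM

    def test_biomass_fraction_one_pins_optimum(self, toy6):
        constrained, opt = prepare_reference_model(toy6, 1.0)
        flux, _ = q.gime3_minimize(constrained, {"g1": 1, "g2": 1, "g3": 1})
        assert flux["BM"] == pytest.approx(opt, rel=1e-9)

    def test_infeasible_floor_reported(self, toy6):
        constrained, _ = prepare_reference_model(toy6, 0.95)
        constrained.reactions.EX_A.upper_bound = 1.0  # biomass floor 9.5 > 1
        with pytest.raises(InfeasibleError):
            q.gime3_minimize(constrained, {"g1": 1, "g2": 1, "g3": 1})


def _all_vertices(S, lb, ub):
    from qm2ta.synthetic import _vertices

    return list(_vertices(S, lb, ub))


class TestRestrictToFVA:
    def test_fraction_zero_recovers_bounds(self, toy6):
        constrained, _ = prepare_reference_model(toy6, 0.95)
        expr = {"g1": 1, "g2": 1, "g3": 1}
        w = gime3_weights(constrained, expr)
        _, obj = q.gime3_minimize(constrained, expr)
        restricted = q.restrict_to_fva(constrained, w, obj, fva_fraction=0.0)
        # without the budget the FVA ranges equal the plain feasible ranges
        plain = q.fva(constrained, fraction=0.0)
        for rxn in restricted.reactions:
            assert rxn.lower_bound == pytest.approx(
                max(plain.loc[rxn.id, "minimum"],
                    constrained.reactions.get_by_id(rxn.id).lower_bound),
                abs=1e-6,
            )

    def test_fraction_one_collapses_to_optimal_face(self, toy6):
        expr = {"g1": 1.0, "g2": 100.0, "g3": 1.0}
        constrained, _ = prepare_reference_model(toy6, 1.0)
        w = gime3_weights(constrained, expr)
        _, obj = q.gime3_minimize(constrained, expr)
        restricted = q.restrict_to_fva(constrained, w, obj, fva_fraction=1.0)
        # on the optimal face the cheap route is forced: R3 pinned near zero
        assert restricted.reactions.R3.upper_bound <= 1e-6

    def test_tightened_bounds_match_oracle_budget_fva(self):
        # two parallel routes with different expression, 4 reactions total:
        # small enough for vertex enumeration over the split variables
        import cobra

        model = cobra.Model("par")
        model.add_metabolites(
            [cobra.Metabolite(m, compartment="c") for m in ("A", "B")]
        )
        for rid, stoich, gpr in [
            ("EX_A", {"A": 1}, ""),
            ("R1", {"A": -1, "B": 1}, "g1"),
            ("R2", {"A": -1, "B": 1}, "g2"),
            ("BM", {"B": -1}, ""),
        ]:
            rxn = cobra.Reaction(rid, lower_bound=0, upper_bound=10)
            model.add_reactions([rxn])
            rxn.add_metabolites(
                {model.metabolites.get_by_id(m): c for m, c in stoich.items()}
            )
            if gpr:
                rxn.gene_reaction_rule = gpr
        model.objective = "BM"
        expr = {"g1": 2.0, "g2": 50.0}
        constrained, _ = prepare_reference_model(model, 0.95)
        w = gime3_weights(constrained, expr)
        _, obj = q.gime3_minimize(constrained, expr)
        restricted = q.restrict_to_fva(constrained, w, obj, fva_fraction=0.99)
        # oracle: vertex enumeration on the split-variable polytope with the
        # weighted-flux budget as an extra inequality (-w|v| >= -budget)
        S = stoichiometric_matrix(constrained)
        lb, ub = model_bounds(constrained)
        n = len(lb)
        S_split = np.hstack([S, -S])
        lb_s = np.concatenate([np.maximum(lb, 0), np.maximum(-ub, 0)])
        ub_s = np.concatenate([np.maximum(ub, 0), np.maximum(-lb, 0)])
        budget = obj / 0.99
        row = -np.concatenate([w, w])
        ids = [r.id for r in constrained.reactions]
        for k, rid in enumerate(ids):
            c = np.zeros(2 * n)
            c[k], c[n + k] = 1.0, -1.0
            _, vmin = lp_oracle(S_split, c, lb_s, ub_s, sense="min",
                                extra_ineq=(row, -budget))
            _, vmax = lp_oracle(S_split, c, lb_s, ub_s, sense="max",
                                extra_ineq=(row, -budget))
            rxn = restricted.reactions.get_by_id(rid)
            assert rxn.lower_bound == pytest.approx(vmin, abs=1e-6)
            assert rxn.upper_bound == pytest.approx(vmax, abs=1e-6)


class TestACHRSampling:
    def test_segment_mean_near_centroid(self):
        import cobra

        model = cobra.Model("segment")
        model.add_metabolites([cobra.Metabolite("X", compartment="c")])
        src = cobra.Reaction("RX", lower_bound=2, upper_bound=6)
        model.add_reactions([src])
        src.add_metabolites({model.metabolites.X: 1})
        drain = cobra.Reaction("DRAIN", lower_bound=0, upper_bound=100)
        model.add_reactions([drain])
        drain.add_metabolites({model.metabolites.X: -1})
        model.objective = "DRAIN"
        samples = q.achr_sample(model, n_samples=400, thinning=10, seed=3)
        mean = samples.samples["RX"].mean()
        se = samples.samples["RX"].std() / np.sqrt(len(samples.samples))
        assert abs(mean - 4.0) <= 3 * max(se, 0.05)

    def test_seed_determinism_is_bitwise(self, toy6):
        s1 = q.achr_sample(toy6, 50, thinning=5, seed=42)
        s2 = q.achr_sample(toy6, 50, thinning=5, seed=42)
        assert (s1.samples.values == s2.samples.values).all()

    def test_samples_satisfy_constraints(self, toy6):
        samples = q.achr_sample(toy6, 100, thinning=5, seed=0)
        S = stoichiometric_matrix(toy6)
        lb, ub = model_bounds(toy6)
        V = samples.samples.values
        assert np.abs(S @ V.T).max() <= 1e-6
        assert (V >= lb - 1e-6).all() and (V <= ub + 1e-6).all()

    def test_unbounded_polytope_rejected(self):
        import cobra

        model = cobra.Model("open")
        model.add_metabolites([cobra.Metabolite("X", compartment="c")])
        r1 = cobra.Reaction("IN", lower_bound=0, upper_bound=np.inf)
        model.add_reactions([r1])
        r1.add_metabolites({model.metabolites.X: 1})
        r2 = cobra.Reaction("OUT", lower_bound=0, upper_bound=np.inf)
        model.add_reactions([r2])
        r2.add_metabolites({model.metabolites.X: -1})
        model.objective = "OUT"
        with pytest.raises(UnboundedError):
            q.achr_sample(model, 10, thinning=2, seed=0)


class TestComputeReference:
    def test_degenerate_polytope_returns_unique_point(self, toy6):
        toy6.reactions.EX_A.lower_bound = 10.0  # pin uptake
        toy6.reactions.R1.upper_bound = 0.0
        toy6.reactions.R3.upper_bound = 0.0
        toy6.reactions.EX_B.upper_bound = 0.0
        cfg = q.ReferenceConfig(n_samples=20, thinning=5, seed=0)
        ref, _ = q.compute_reference(toy6, {"g2": 1.0}, cfg)
        assert ref["R2"] == pytest.approx(10.0, abs=1e-6)
        assert ref["BM"] == pytest.approx(10.0, abs=1e-6)

    def test_reference_reproducible_for_fixed_seed(self, toy6):
        cfg = q.ReferenceConfig(n_samples=60, thinning=5, seed=9)
        expr = {"g1": 5.0, "g2": 5.0, "g3": 5.0}
        ref1, _ = q.compute_reference(toy6.copy(), expr, cfg)
        ref2, _ = q.compute_reference(toy6.copy(), expr, cfg)
        assert (ref1.values.values == ref2.values.values).all()

    def test_reference_biomass_exceeds_stacked_fractions(self, toy6):
        cfg = q.ReferenceConfig(n_samples=100, thinning=5, seed=4)
        expr = {"g1": 2.0, "g2": 8.0, "g3": 1.0}
        _, opt = q.fba(toy6)
        ref, _ = q.compute_reference(toy6, expr, cfg)
        bm = biomass_reaction_id(toy6)
        assert ref[bm] >= 0.95 * 0.99 * opt - 1e-9

    def test_reference_satisfies_sampling_constraints(self, route_reference, route_model):
        ref, restricted = route_reference
        check_flux(restricted, ref, steady_state=1e-6)

    def test_standard_error_shrinks_with_sample_size(self, toy6):
        expr = {"g1": 1.0, "g2": 1.0, "g3": 1.0}
        means = {n: [] for n in (100, 400)}
        for n in means:
            for seed in range(4):
                cfg = q.ReferenceConfig(n_samples=n, thinning=5, seed=seed)
                ref, _ = q.compute_reference(toy6.copy(), expr, cfg)
                means[n].append(ref["R1"])
        spread100 = np.std(means[100])
        spread400 = np.std(means[400])
        assert spread400 <= spread100 + 1e-9
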