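"""FBA, Pareto-frontier, knockout-coupling and regression tests."""

import numpy as np
import pandas as pd
import pytest
import cobra

from secrecon import (ConstraintSet, KnockoutCoupling, ParetoCurve,
                      PSIMEntry, ToyModelSpec, UnitConversionConfig,
                      expression_coupling_ratio,
                      feature_productivity_regression, flux_to_productivity,
                      knockout_compare, make_toy_metabolic_model,
                      pareto_frontier, predict_growth_at_qp,
                      scale_biomass_protein, solve_fba, tradeoff_delta)
from secrecon.analysis import InfeasibleProblemError

from conftest import lp_oracle_optimum, random_toy_spec


def add_product(model: cobra.Model, aa: float = 1.0, atp: float = 2.0,
                rxn_id: str = "PROD") -> str:
    """Attach a product reaction consuming amino acid + ATP, plus a demand."""
    product = cobra.Metabolite(f"{rxn_id.lower()}_c", compartment="c")
    model.add_metabolites([product])
    mets = {model.metabolites.get_by_id("aa_c"): -aa, product: 1.0}
    if atp:
        mets.update({model.metabolites.get_by_id("atp_c"): -atp,
                     model.metabolites.get_by_id("h2o_c"): -atp,
                     model.metabolites.get_by_id("adp_c"): atp,
                     model.metabolites.get_by_id("pi_c"): atp})
    rxn = cobra.Reaction(rxn_id, lower_bound=0, upper_bound=1000)
    rxn.add_metabolites(mets)
    demand = cobra.Reaction(f"DM_{rxn_id}", lower_bound=0, upper_bound=1000)
    demand.add_metabolites({product: -1.0})
    model.add_reactions([rxn, demand])
    return f"DM_{rxn_id}"


class TestFBA:
    def test_toy_optimum_matches_hand_lp(self, toy_model):
        # glucose<=5 at 2 ATP each, aa<=3, biomass = 1 aa + 1 ATP -> 3
        sol = solve_fba(toy_model, objective="BIOMASS")
        assert sol.objective_value == pytest.approx(3.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(
            lp_oracle_optimum(toy_model, "BIOMASS"), abs=1e-6)

    def test_zero_exchange_bounds_give_zero(self, toy_model):
        cons = ConstraintSet(bounds={"SRC_glc": (0, 0), "SRC_aa": (0, 0)})
        assert solve_fba(toy_model, cons).objective_value == pytest.approx(
            0.0, abs=1e-9)

    def test_missing_objective_is_an_error(self, toy_model):
        with pytest.raises(KeyError):
            solve_fba(toy_model, objective="NO_SUCH_RXN")

    def test_constraint_set_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            ConstraintSet(bounds={"r": (1.0, 0.0)})

    def test_steady_state_holds_in_solution(self, toy_model):
        sol = solve_fba(toy_model, objective="BIOMASS")
        S = cobra.util.array.create_stoichiometric_matrix(toy_model)
        residual = S @ sol.fluxes.reindex(
            [r.id for r in toy_model.reactions]).to_numpy()
        assert np.max(np.abs(residual)) < 1e-6


class TestGrowthAtProductivity:
    def test_zero_productivity_equals_base_optimum(self, toy_model):
        demand = add_product(toy_model)
        entry = PSIMEntry("prod", 100, 150000)
        mu = predict_growth_at_qp(toy_model, None, demand, 0.0, entry)
        assert mu == pytest.approx(3.0, abs=1e-9)

    def test_hand_lp_with_fixed_demand(self, toy_model):
        # product consumes 1 aa + 2 ATP; demand 1 leaves 2 aa and 8 ATP
        demand = add_product(toy_model)
        entry = PSIMEntry("prod", 100, 150000)
        qp = flux_to_productivity(1.0, entry.molecular_weight)
        mu = predict_growth_at_qp(toy_model, None, demand, qp, entry)
        assert mu == pytest.approx(2.0, abs=1e-6)

    def test_excess_productivity_reports_product_limited(self, toy_model):
        demand = add_product(toy_model)
        entry = PSIMEntry("prod", 100, 150000)
        qp = flux_to_productivity(10.0, entry.molecular_weight)
        with pytest.raises(InfeasibleProblemError, match="product-limited"):
            predict_growth_at_qp(toy_model, None, demand, qp, entry)


class TestPareto:
    def test_linear_tradeoff_is_straight(self, toy_model):
        # Remove the ATP term so biomass and product compete for one
        # resource only; the frontier is then the line mu = 3 - qp.
        spec = ToyModelSpec(biomass_atp=0.0)
        model = make_toy_metabolic_model(spec)
        demand = add_product(model, aa=1.0, atp=0.0)
        curve = pareto_frontier(model, None, demand, "BIOMASS", n_points=11)
        assert curve.qp[-1] == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(curve.mu, 3.0 - curve.qp, atol=1e-6)

    def test_endpoints_match_single_objective_optima(self, toy_model):
        demand = add_product(toy_model)
        curve = pareto_frontier(toy_model, None, demand, "BIOMASS",
                                n_points=2)
        assert len(curve.qp) == 2
        assert curve.mu[0] == pytest.approx(
            solve_fba(toy_model, objective="BIOMASS").objective_value,
            abs=1e-6)
        assert curve.qp[-1] == pytest.approx(
            solve_fba(toy_model, objective=demand).objective_value, abs=1e-6)

    def test_monotone_against_pointwise_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            model = make_toy_metabolic_model(random_toy_spec(rng))
            demand = add_product(model, aa=float(rng.uniform(0.2, 2.0)),
                                 atp=float(rng.uniform(0.0, 3.0)))
            curve = pareto_frontier(model, None, demand, "BIOMASS",
                                    n_points=8)
            assert np.all(np.diff(curve.mu) <= 1e-9)
            for q, mu in zip(curve.qp, curve.mu):
                oracle = lp_oracle_optimum(model, "BIOMASS",
                                           extra_bounds={demand: (q, q)})
                assert mu == pytest.approx(oracle, abs=1e-6)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParetoCurve(qp=[0.0, 1.0], mu=[1.0, 2.0])
        with pytest.raises(ValueError):
            ParetoCurve(qp=[1.0, 0.5], mu=[1.0, 0.5])


class TestTradeoffDelta:
    def test_identical_curves_give_zero(self):
        curve = ParetoCurve(qp=[0.0, 1.0, 2.0], mu=[2.0, 1.0, 0.0])
        assert tradeoff_delta(curve, curve).delta == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_unit_antidiagonal_has_length_sqrt2(self):
        curve = ParetoCurve(qp=[0.0, 1.0], mu=[1.0, 0.0])
        comparison = tradeoff_delta(curve, curve)
        assert comparison.length_wt == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_uniformly_scaled_curve_gives_exact_delta(self):
        wt = ParetoCurve(qp=[0.0, 1.0, 2.0], mu=[1.0, 0.6, 0.0])
        ko = ParetoCurve(qp=wt.qp * 1.18, mu=wt.mu * 1.18)
        assert tradeoff_delta(wt, ko).delta == pytest.approx(0.18, rel=1e-12)

    def test_degenerate_wild_type_rejected(self):
        point = ParetoCurve(qp=[1.0], mu=[1.0])
        with pytest.raises(ValueError, match="zero length"):
            tradeoff_delta(point, point)


class TestCoupling:
    def test_equal_footprints_give_half(self):
        assert expression_coupling_ratio(10.0, 6.0, 4.0).ratio == pytest.approx(0.5)

    def test_published_late_phase_footprints(self):
        # ribosome footprints on day 6: competitor 25,679 RPKM against a
        # combined light+heavy product footprint of 13,356 RPKM
        coupling = expression_coupling_ratio(25679.0, 13356.0, 0.0)
        assert coupling.ratio == pytest.approx(25679 / (2 * 13356), rel=1e-12)
        assert coupling.ratio == pytest.approx(0.9613, abs=5e-5)

    def test_zero_competitor_gives_zero(self):
        assert expression_coupling_ratio(0.0, 5.0, 5.0).ratio == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            expression_coupling_ratio(1.0, 0.0, 0.0)


class TestScaleBiomass:
    def test_coefficients_scale_exactly(self, toy_model):
        scaled = scale_biomass_protein(toy_model, 0.8, "BIOMASS", ["aa_c"])
        met = scaled.metabolites.get_by_id("aa_c")
        coef = scaled.reactions.get_by_id("BIOMASS").metabolites[met]
        assert coef == pytest.approx(-0.8, rel=1e-12)
        # the original model is untouched
        met0 = toy_model.metabolites.get_by_id("aa_c")
        assert toy_model.reactions.get_by_id("BIOMASS").metabolites[met0] == -1.0

    def test_factor_one_is_identity(self, toy_model):
        scaled = scale_biomass_protein(toy_model, 1.0, "BIOMASS", ["aa_c"])
        assert scaled.slim_optimize() == pytest.approx(
            toy_model.slim_optimize(), abs=1e-9)

    def test_aa_coefficient_sum_scales_by_factor(self):
        model = make_toy_metabolic_model(ToyModelSpec(all_20_amino_acids=True))
        aa_ids = [m.id for m in model.metabolites if m.id.startswith("aa_")]
        biomass = model.reactions.get_by_id("BIOMASS")
        before = sum(c for m, c in biomass.metabolites.items()
                     if m.id in aa_ids)
        scaled = scale_biomass_protein(model, 0.8, "BIOMASS", aa_ids)
        after = sum(c for m, c in
                    scaled.reactions.get_by_id("BIOMASS").metabolites.items()
                    if m.id in aa_ids)
        assert after == pytest.approx(0.8 * before, rel=1e-12)

    def test_requires_amino_acid_participants(self, toy_model):
        with pytest.raises(ValueError, match="consumes none"):
            scale_biomass_protein(toy_model, 0.8, "BIOMASS", ["glc_c"])


def shared_resource_model():
    """Product and competitor drawing on one limiting amino-acid pool."""
    model = make_toy_metabolic_model(ToyModelSpec(biomass_aa=0.0,
                                                  biomass_atp=1.0))
    product_demand = add_product(model, aa=1.0, atp=0.0, rxn_id="PROD")
    add_product(model, aa=1.0, atp=0.0, rxn_id="COMP")
    return model, product_demand, "COMP"


class TestKnockout:
    def test_zero_ratio_changes_nothing(self):
        model, demand, comp = shared_resource_model()
        result = knockout_compare(model, None, demand, comp, 0.0,
                                  with_pareto=False)
        assert result.qp_knockout == pytest.approx(result.qp_coupled,
                                                   abs=1e-6)
        assert result.relative_increase == pytest.approx(0.0, abs=1e-6)

    def test_unit_ratio_knockout_doubles_product(self):
        # aa <= 3 split 50/50 under coupling -> 1.5; knockout frees all 3
        model, demand, comp = shared_resource_model()
        result = knockout_compare(model, None, demand, comp, 1.0,
                                  with_pareto=False)
        assert result.qp_coupled == pytest.approx(1.5, abs=1e-6)
        assert result.qp_knockout == pytest.approx(3.0, abs=1e-6)
        assert result.relative_increase == pytest.approx(1.0, abs=1e-6)

    def test_increase_non_negative_over_random_ratios(self):
        model, demand, comp = shared_resource_model()
        rng = np.random.default_rng(3)
        for ratio in rng.uniform(0.0, 3.0, size=10):
            result = knockout_compare(model, None, demand, comp,
                                      float(ratio), with_pareto=False)
            assert result.qp_knockout >= result.qp_coupled - 1e-9

    def test_pareto_delta_positive_for_coupled_competitor(self):
        model, demand, comp = shared_resource_model()
        result = knockout_compare(model, None, demand, comp, 1.0,
                                  objective="BIOMASS", n_points=12)
        assert result.comparison is not None
        assert result.comparison.delta > 0


class TestRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(60, 3)),
                         columns=["ng", "dsb", "tmd"])
        beta = np.array([2.0, -1.0, 0.5])
        y = 4.0 + X.to_numpy() @ beta
        fit = feature_productivity_regression(X, y)
        assert fit.params["const"] == pytest.approx(4.0, abs=1e-8)
        np.testing.assert_allclose(fit.params[["ng", "dsb", "tmd"]], beta,
                                   atol=1e-8)

    def test_identity_predictor(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        fit = feature_productivity_regression(pd.DataFrame({"x": x}), x)
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)

    def test_null_responses_give_null_band_z_scores(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(500, 4)),
                         columns=list("abcd"))
        y = rng.normal(size=500)
        fit = feature_productivity_regression(X, y)
        z = (fit.params[list("abcd")] / fit.bse[list("abcd")]).abs()
        assert (z < 4.0).all()

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "k": [5.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            feature_productivity_regression(X, [1.0, 2.0, 3.0, 4.0])

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear"):
            feature_productivity_regression(X, rng.normal(size=30))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 5.0]})
        with pytest.raises(ValueError, match="rows"):
            feature_productivity_regression(X, [1.0, 2.0])
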