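"""Linear-programming analyses on secretory-expanded metabolic models.

Flux balance analysis (FBA), growth prediction at a fixed specific
productivity, growth-productivity Pareto frontiers with an arc-length
trade-off statistic, expression-coupled competitor (selection-marker)
knockout simulation, biomass amino-acid rescaling for recombinant lines, and
an ordinary-least-squares regression of productivity on protein features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import cobra

from .psim import PSIMEntry
from .rates import UnitConversionConfig, productivity_to_flux

__all__ = [
    "ConstraintSet",
    "FluxSolution",
    "ParetoCurve",
    "ParetoComparison",
    "KnockoutCoupling",
    "KnockoutResult",
    "InfeasibleProblemError",
    "UnboundedProblemError",
    "solve_fba",
    "predict_growth_at_qp",
    "pareto_frontier",
    "tradeoff_delta",
    "expression_coupling_ratio",
    "scale_biomass_protein",
    "knockout_compare",
    "feature_productivity_regression",
    "read_constraint_table",
]

#: Absolute tolerance for comparing LP objective values.
OBJECTIVE_TOL = 1e-6


class InfeasibleProblemError(RuntimeError):
    pass


class UnboundedProblemError(RuntimeError):
    pass


@dataclass
class ConstraintSet:
    """Reaction bounds (mmol/gDW/h) applied on top of a model's own bounds."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for rxn, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(f"{rxn}: lower bound {lb} exceeds upper {ub}")

    def items(self):
        return self.bounds.items()


def read_constraint_table(path: str | Path,
                          provenance: str = "") -> ConstraintSet:
    """Read a TSV constraint table with columns reaction_id, lb, ub."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("reaction_id", "lb", "ub"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    return ConstraintSet(
        bounds={r.reaction_id: (float(r.lb), float(r.ub))
                for r in df.itertuples()},
        provenance=provenance or str(path),
    )


@dataclass
class FluxSolution:
    """An optimal FBA solution."""

    objective_value: float
    fluxes: pd.Series
    status: str


def _apply_constraints(model: cobra.Model,
                       constraints: ConstraintSet | None) -> None:
    if constraints is None:
        return
    for rxn_id, (lb, ub) in constraints.items():
        if not model.reactions.has_id(rxn_id):
            raise KeyError(f"constraint references unknown reaction {rxn_id!r}")
        model.reactions.get_by_id(rxn_id).bounds = (lb, ub)


def solve_fba(model: cobra.Model,
              constraints: ConstraintSet | None = None,
              objective: str | None = None,
              sense: str = "max") -> FluxSolution:
    """Optimize one reaction flux subject to steady state and bounds.

    Raises :class:`InfeasibleProblemError` (with the applied constraints
    listed) or :class:`UnboundedProblemError` on solver failure.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with model as m:
        _apply_constraints(m, constraints)
        if objective is not None:
            if not m.reactions.has_id(objective):
                raise KeyError(f"objective reaction {objective!r} not in model")
            m.objective = objective
        m.objective_direction = sense
        solution = m.optimize()
        if solution.status == "infeasible":
            applied = list(constraints.bounds) if constraints else []
            raise InfeasibleProblemError(
                f"FBA infeasible (applied constraints: {applied})"
            )
        if solution.status == "unbounded":
            raise UnboundedProblemError("FBA unbounded")
        if solution.status != "optimal":
            raise RuntimeError(f"solver status {solution.status!r}")
        return FluxSolution(objective_value=float(solution.objective_value),
                            fluxes=solution.fluxes, status=solution.status)


def predict_growth_at_qp(model: cobra.Model,
                         constraints: ConstraintSet | None,
                         product_demand: str,
                         qp_pg_per_cell_day: float,
                         entry: PSIMEntry,
                         conv: UnitConversionConfig = UnitConversionConfig(),
                         objective: str | None = None) -> float:
    """Maximum growth rate (1/h) with the product demand fixed at q_p.

    The measured specific productivity is converted to a demand flux via the
    protein molecular weight and cell dry weight, the demand is pinned to
    that flux, and biomass is maximized. On infeasibility the error reports
    whether q_p alone exceeds the feasible product maximum (product-limited)
    or the medium constraints themselves are inconsistent.
    """
    if qp_pg_per_cell_day < 0:
        raise ValueError("qp must be >= 0")
    flux = productivity_to_flux(qp_pg_per_cell_day, entry.molecular_weight,
                                conv)
    with model as m:
        _apply_constraints(m, constraints)
        m.reactions.get_by_id(product_demand).bounds = (flux, flux)
        if objective is not None:
            m.objective = objective
        m.objective_direction = "max"
        solution = m.optimize()
        if solution.status == "optimal":
            return float(solution.objective_value)
    # Diagnose the failure cause.
    try:
        qp_max = solve_fba(model, constraints, product_demand,
                           "max").objective_value
    except InfeasibleProblemError:
        raise InfeasibleProblemError(
            "media constraints are infeasible even without the product demand"
        ) from None
    if flux > qp_max + OBJECTIVE_TOL:
        raise InfeasibleProblemError(
            f"product-limited: requested demand flux {flux:.4g} exceeds "
            f"feasible maximum {qp_max:.4g}"
        )
    raise InfeasibleProblemError("FBA infeasible at the requested productivity")


@dataclass
class ParetoCurve:
    """Sampled growth-productivity frontier.

    Product flux (or q_p) is strictly increasing along the curve and growth
    is non-increasing.
    """

    qp: np.ndarray
    mu: np.ndarray
    qp_units: str = "mmol/gDW/h"

    def __post_init__(self) -> None:
        self.qp = np.asarray(self.qp, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.qp.shape != self.mu.shape or self.qp.ndim != 1:
            raise ValueError("qp and mu must be 1-D arrays of equal length")
        if len(self.qp) == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.qp) <= 0) and len(self.qp) > 1:
            raise ValueError("qp must be strictly increasing along the curve")
        if np.any(np.diff(self.mu) > OBJECTIVE_TOL):
            raise ValueError("mu must be non-increasing along the curve")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.qp.tolist(), self.mu.tolist()))


def pareto_frontier(model: cobra.Model,
                    constraints: ConstraintSet | None,
                    product_demand: str,
                    objective: str,
                    n_points: int = 50) -> ParetoCurve:
    """Growth-maximizing sweep of the product demand from 0 to its maximum.

    The demand is fixed on an even grid of ``n_points`` values spanning
    [0, q_max] (q_max from a single-objective product maximization) and the
    growth objective is maximized at each; the endpoints therefore equal the
    two single-objective optima.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    qp_max = solve_fba(model, constraints, product_demand, "max").objective_value
    qp_max = max(qp_max, 0.0)
    grid = np.linspace(0.0, qp_max, n_points)
    mu = np.empty_like(grid)
    with model as m:
        _apply_constraints(m, constraints)
        m.objective = objective
        m.objective_direction = "max"
        demand = m.reactions.get_by_id(product_demand)
        for i, q in enumerate(grid):
            demand.bounds = (q, q)
            solution = m.optimize()
            if solution.status != "optimal":
                raise InfeasibleProblemError(
                    f"frontier point q={q:.4g} infeasible"
                )
            mu[i] = solution.objective_value
    # Clamp solver jitter so the non-increasing invariant holds exactly.
    mu = np.minimum.accumulate(np.maximum(mu, 0.0))
    if qp_max == 0.0:
        return ParetoCurve(qp=grid[:1], mu=mu[:1])
    return ParetoCurve(qp=grid, mu=mu)


@dataclass
class ParetoComparison:
    """Arc-length comparison of two frontiers (wild type vs knockout)."""

    curve_wt: ParetoCurve
    curve_ko: ParetoCurve
    length_wt: float
    length_ko: float

    @property
    def delta(self) -> float:
        """Relative trade-off improvement (L_KO - L_WT) / L_WT."""
        return (self.length_ko - self.length_wt) / self.length_wt


def _arc_length(curve: ParetoCurve, qp_scale: float, mu_scale: float) -> float:
    q = curve.qp / qp_scale
    m = curve.mu / mu_scale
    return float(np.sum(np.hypot(np.diff(q), np.diff(m))))


def tradeoff_delta(curve_wt: ParetoCurve,
                   curve_ko: ParetoCurve) -> ParetoComparison:
    """Compare frontier arc lengths after normalizing by the WT axis maxima.

    Both curves are normalized by the wild-type curve's maximum productivity
    and maximum growth (shared normalization keeps them comparable), arc
    length is the sum of Euclidean segment lengths, and
    delta = (L_KO - L_WT) / L_WT. A single-point curve has length 0; a
    zero-length wild-type curve leaves delta undefined.
    """
    qp_scale = float(np.max(curve_wt.qp))
    mu_scale = float(np.max(curve_wt.mu))
    if qp_scale <= 0:
        qp_scale = 1.0
    if mu_scale <= 0:
        mu_scale = 1.0
    l_wt = _arc_length(curve_wt, qp_scale, mu_scale)
    l_ko = _arc_length(curve_ko, qp_scale, mu_scale)
    if l_wt == 0.0:
        raise ValueError("wild-type curve has zero length; delta undefined")
    return ParetoComparison(curve_wt=curve_wt, curve_ko=curve_ko,
                            length_wt=l_wt, length_ko=l_ko)


@dataclass(frozen=True)
class KnockoutCoupling:
    """Expression-proportional coupling of a competitor translation flux.

    The competitor (e.g. a selection-marker peptide) is translated at
    ``ratio`` times the product translation flux, where the ratio comes from
    ribosome-footprint RPKM values: for an IgG product with separate light-
    and heavy-chain genes, ratio = RPKM_competitor / (2 (RPKM_light +
    RPKM_heavy)) — the factor 2 because each IgG molecule requires two
    copies of each chain.
    """

    rpkm_competitor: float
    rpkm_light: float
    rpkm_heavy: float

    def __post_init__(self) -> None:
        for name in ("rpkm_competitor", "rpkm_light", "rpkm_heavy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rpkm_light + self.rpkm_heavy <= 0:
            raise ValueError("combined product RPKM must be positive")

    @property
    def ratio(self) -> float:
        return self.rpkm_competitor / (2.0 * (self.rpkm_light + self.rpkm_heavy))


def expression_coupling_ratio(rpkm_competitor: float, rpkm_light: float,
                              rpkm_heavy: float) -> KnockoutCoupling:
    """Build the coupling from ribosome-footprint RPKM values.

    A combined light+heavy footprint can be passed as ``rpkm_light`` with
    ``rpkm_heavy = 0``.
    """
    return KnockoutCoupling(rpkm_competitor=rpkm_competitor,
                            rpkm_light=rpkm_light, rpkm_heavy=rpkm_heavy)


def scale_biomass_protein(model: cobra.Model, factor: float,
                          biomass_reaction: str,
                          amino_acid_ids: Sequence[str]) -> cobra.Model:
    """Scale the biomass reaction's amino-acid coefficients by ``factor``.

    Used when a recombinant product claims a share of total cell protein
    (product at 20% of cell protein -> factor 0.8). Only amino-acid
    reactant coefficients change; the original model is not modified.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    scaled = model.copy()
    biomass = scaled.reactions.get_by_id(biomass_reaction)
    aa_set = set(amino_acid_ids)
    targets = {met: coef for met, coef in biomass.metabolites.items()
               if met.id in aa_set and coef < 0}
    if not targets:
        raise ValueError(
            f"biomass reaction {biomass_reaction!r} consumes none of the "
            "given amino-acid metabolites"
        )
    biomass.add_metabolites(
        {met: coef * (factor - 1.0) for met, coef in targets.items()},
        combine=True,
    )
    return scaled


@dataclass
class KnockoutResult:
    """Paired productivity optima with and without the coupled competitor."""

    qp_coupled: float
    qp_knockout: float
    comparison: ParetoComparison | None

    @property
    def relative_increase(self) -> float:
        if self.qp_coupled == 0:
            return math.inf if self.qp_knockout > 0 else 0.0
        return (self.qp_knockout - self.qp_coupled) / self.qp_coupled


def knockout_compare(model: cobra.Model,
                     constraints: ConstraintSet | None,
                     product_demand: str,
                     competitor_reaction: str,
                     coupling: KnockoutCoupling | float,
                     objective: str | None = None,
                     n_points: int = 50,
                     with_pareto: bool = True) -> KnockoutResult:
    """Maximum product flux with the competitor coupled vs knocked out.

    The coupling is the equality constraint v_competitor = ratio * v_product
    (an extra LP row, so it holds at every point of a Pareto sweep); the
    knockout fixes the competitor flux to zero. Also reports the arc-length
    delta between the two growth-productivity frontiers when an ``objective``
    (growth) reaction is given and ``with_pareto`` is set.
    """
    ratio = coupling.ratio if isinstance(coupling, KnockoutCoupling) else float(coupling)
    if ratio < 0:
        raise ValueError("coupling ratio must be >= 0")
    if not model.reactions.has_id(competitor_reaction):
        raise KeyError(f"competitor reaction {competitor_reaction!r} not in model")

    def _with_coupling(m: cobra.Model) -> None:
        comp = m.reactions.get_by_id(competitor_reaction)
        prod = m.reactions.get_by_id(product_demand)
        cons = m.problem.Constraint(
            comp.flux_expression - ratio * prod.flux_expression,
            lb=0.0, ub=0.0, name="competitor_coupling",
        )
        m.add_cons_vars(cons)

    with model as m:
        _with_coupling(m)
        qp_coupled = solve_fba(m, constraints, product_demand,
                               "max").objective_value
    with model as m:
        m.reactions.get_by_id(competitor_reaction).bounds = (0.0, 0.0)
        qp_ko = solve_fba(m, constraints, product_demand, "max").objective_value

    comparison = None
    if with_pareto and objective is not None:
        with model as m:
            _with_coupling(m)
            curve_wt = pareto_frontier(m, constraints, product_demand,
                                       objective, n_points)
        with model as m:
            m.reactions.get_by_id(competitor_reaction).bounds = (0.0, 0.0)
            curve_ko = pareto_frontier(m, constraints, product_demand,
                                       objective, n_points)
        comparison = tradeoff_delta(curve_wt, curve_ko)
    return KnockoutResult(qp_coupled=qp_coupled, qp_knockout=qp_ko,
                          comparison=comparison)


@dataclass
class RegressionResult:
    """OLS fit of productivity on protein features."""

    params: pd.Series
    bse: pd.Series
    rsquared: float
    results: object  # statsmodels RegressionResults

    def summary(self) -> str:
        return str(self.results.summary())


def feature_productivity_regression(features: pd.DataFrame,
                                    qp_max: Sequence[float] | pd.Series
                                    ) -> RegressionResult:
    """Multivariate OLS of maximum specific productivity on protein features.

    Features are PSIM-derived predictors (PTM counts, transmembrane domains,
    amino-acid composition, ...). An intercept is added; constant or
    collinear predictor columns are rejected by name.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(features).astype(float)
    y = np.asarray(qp_max, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and responses differ in length")
    if len(X) < X.shape[1] + 1:
        raise ValueError(
            f"need >= {X.shape[1] + 1} rows for {X.shape[1]} predictors"
        )
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); most "
            f"collinear pair: {worst}"
        )
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    return RegressionResult(params=fit.params, bse=fit.bse,
                            rsquared=float(fit.rsquared), results=fit)
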