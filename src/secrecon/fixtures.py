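"""Self-contained toy models and synthetic datasets.

Everything here is generated programmatically and deterministically from a
seed, so the rest of the package is testable without any external model or
omics download. The toy metabolic model stands in for a genome-scale host
network: a glucose-fed energy stub, amino-acid uptake, currency-nucleotide
recycling, free precursor stubs for core glycans/GPI/oxidizing equivalents,
and a biomass objective whose unconstrained optimum has a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import cobra
from scipy import stats

from .costs import CostParameters, VesicleParameters
from .omics import ExpressionTable
from .pathway import CurrencyMap
from .psim import AMINO_ACIDS, LOCATIONS, PSIMEntry, SecretomeTable
from .rates import TimeCourse

__all__ = [
    "ToyModelSpec",
    "SyntheticConfig",
    "make_toy_metabolic_model",
    "make_synthetic_psim",
    "make_synthetic_timecourse",
    "make_synthetic_expression",
    "spearman_to_pearson",
]


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the toy host model.

    With biomass consuming ``biomass_aa`` amino acids and ``biomass_atp`` ATP
    per unit flux, the unconstrained biomass optimum is
    min(aa_bound / biomass_aa, glc_bound * atp_per_glucose / biomass_atp)
    (one term dropping out if its coefficient is zero).
    """

    glucose_uptake_bound: float = 5.0
    atp_per_glucose: float = 2.0
    amino_acid_uptake_bound: float = 3.0
    biomass_aa: float = 1.0
    biomass_atp: float = 1.0
    all_20_amino_acids: bool = False

    def __post_init__(self) -> None:
        for name in ("glucose_uptake_bound", "atp_per_glucose",
                     "amino_acid_uptake_bound", "biomass_aa", "biomass_atp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.biomass_aa == 0 and self.biomass_atp == 0:
            raise ValueError("biomass must consume at least one species")

    @property
    def biomass_optimum(self) -> float:
        limits = []
        if self.biomass_aa > 0:
            limits.append(self.amino_acid_uptake_bound / self.biomass_aa)
        if self.biomass_atp > 0:
            limits.append(self.glucose_uptake_bound * self.atp_per_glucose
                          / self.biomass_atp)
        return min(limits)


def make_toy_metabolic_model(spec: ToyModelSpec = ToyModelSpec(),
                             currency_map: CurrencyMap = CurrencyMap()
                             ) -> cobra.Model:
    """Build the toy host model; its optimum is asserted at build time.

    The model declares every currency/precursor species the pathway
    templates reference (single-compartment energy currency, aggregate or
    per-amino-acid uptake, free stubs for core N-/O-glycan, GPI and
    disulfide-oxidizing equivalents) plus a biomass objective.
    """
    cm = currency_map
    model = cobra.Model("toy_host")
    model.compartments = {"c": "cytosol", "r": "ER", "g": "Golgi",
                          "m": "membrane", "e": "extracellular"}

    def met(mid: str) -> cobra.Metabolite:
        comp = mid.rsplit("_", 1)[-1]
        m = cobra.Metabolite(mid, compartment=comp if comp in "crgme" else "c")
        model.add_metabolites([m])
        return m

    glc = met("glc_c")
    atp, adp, amp = met(cm.atp), met(cm.adp), met(cm.amp)
    gtp, gdp = met(cm.gtp), met(cm.gdp)
    pi, h2o = met(cm.pi), met(cm.h2o)
    ng, og = met(cm.n_glycan_precursor), met(cm.o_glycan_precursor)
    gpi, oxeq = met(cm.gpi_precursor), met(cm.oxidizing_equivalent)
    biomass_met = met("biomass_c")

    def rxn(rid: str, stoich: Mapping[cobra.Metabolite, float],
            lb: float = 0.0, ub: float = 1000.0) -> cobra.Reaction:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        model.add_reactions([r])
        return r

    rxn("SRC_glc", {glc: 1.0}, ub=spec.glucose_uptake_bound)
    # Substrate-level energy stub: glucose phosphorylates ADP directly.
    rxn("ENERGY", {glc: -1.0, adp: -spec.atp_per_glucose,
                   pi: -spec.atp_per_glucose, atp: spec.atp_per_glucose,
                   h2o: spec.atp_per_glucose})
    rxn("NDK", {atp: -1.0, gdp: -1.0, adp: 1.0, gtp: 1.0}, lb=-1000.0)
    rxn("ADK", {atp: -1.0, amp: -1.0, adp: 2.0}, lb=-1000.0)
    rxn("SRC_h2o", {h2o: 1.0}, lb=-1000.0)
    rxn("SINK_pi", {pi: -1.0})
    for stub_met, rid in ((ng, "SRC_ngcore"), (og, "SRC_ogcore"),
                          (gpi, "SRC_gpiprec"), (oxeq, "SRC_oxeq")):
        rxn(rid, {stub_met: 1.0})

    biomass_stoich: dict[cobra.Metabolite, float] = {biomass_met: 1.0}
    if spec.biomass_atp > 0:
        biomass_stoich.update({atp: -spec.biomass_atp, h2o: -spec.biomass_atp,
                               adp: spec.biomass_atp, pi: spec.biomass_atp})
    aa_ids: list[str] = []
    if spec.all_20_amino_acids:
        per_aa_bound = spec.amino_acid_uptake_bound
        for letter in AMINO_ACIDS:
            aa_met = met(cm.amino_acid_id(letter))
            aa_ids.append(aa_met.id)
            rxn(f"SRC_aa_{letter}", {aa_met: 1.0}, ub=per_aa_bound)
            if spec.biomass_aa > 0:
                biomass_stoich[aa_met] = -spec.biomass_aa / 20.0
    else:
        aa_met = met(cm.aa)
        aa_ids.append(aa_met.id)
        rxn("SRC_aa", {aa_met: 1.0}, ub=spec.amino_acid_uptake_bound)
        if spec.biomass_aa > 0:
            biomass_stoich[aa_met] = -spec.biomass_aa
    rxn("BIOMASS", biomass_stoich)
    rxn("DM_biomass", {biomass_met: -1.0})
    model.objective = "BIOMASS"

    optimum = model.slim_optimize()
    expected = spec.biomass_optimum
    if spec.all_20_amino_acids and spec.biomass_aa > 0:
        expected = min(spec.amino_acid_uptake_bound * 20.0 / spec.biomass_aa
                       if spec.biomass_aa else math.inf,
                       spec.glucose_uptake_bound * spec.atp_per_glucose
                       / spec.biomass_atp if spec.biomass_atp else math.inf)
    if abs(optimum - expected) > 1e-6:
        raise AssertionError(
            f"toy model optimum {optimum:.6g} != closed form {expected:.6g}"
        )
    if expected == 0:
        import warnings
        warnings.warn("toy model has zero biomass optimum", stacklevel=2)
    return model


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic batch-culture generator parameters.

    Defaults mirror a seed-train CHO batch: inoculation at 3e5 cells/mL,
    exponential growth at 0.03 1/h, specific productivity 16 pg/cell/day,
    glucose at 30 mM consumed at 0.05 mmol/gDW/h, multiplicative lognormal
    noise with sigma 0.05.
    """

    seed: int = 0
    mu_per_h: float = 0.03
    qp_pg_per_cell_day: float = 16.0
    initial_vcd: float = 3.0e5
    duration_h: float = 96.0
    dt_h: float = 6.0
    noise_sigma: float = 0.05
    cell_dry_weight_pg: float = 456.3
    metabolite_rates_mmol_gdw_h: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": -0.05})
    metabolite_initial_mM: Mapping[str, float] = field(
        default_factory=lambda: {"glucose": 30.0})

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.initial_vcd <= 0 or self.duration_h <= 0 or self.dt_h <= 0:
            raise ValueError("culture dimensions must be positive")


def make_synthetic_timecourse(config: SyntheticConfig = SyntheticConfig()
                              ) -> TimeCourse:
    """Generate an exponential batch culture with known rates.

    VCD grows exponentially at the configured mu; titer accumulates as
    q_p times cumulative cell-hours; metabolite concentrations change
    linearly in cumulative biomass at the configured exchange rates.
    Multiplicative lognormal noise (sigma) perturbs every observed series.
    Generator parameters are recoverable from the returned object's
    ``replicate_id`` metadata string.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_h + 0.5 * config.dt_h, config.dt_h)
    vcd_true = config.initial_vcd * np.exp(config.mu_per_h * t)
    # Cumulative cell-hours per mL on the sampling grid (trapezoidal), the
    # discrete counterpart of "q_p times integrated viable cells".
    cum_cell_h = np.concatenate(
        [[0.0], np.cumsum(0.5 * (vcd_true[1:] + vcd_true[:-1]) * np.diff(t))]
    )
    qp_per_h = config.qp_pg_per_cell_day / 24.0
    titer_true = qp_per_h * cum_cell_h / 1.0e6  # pg/mL -> mg/L (1 mg/L = 1e6 pg/mL)
    gdw_per_l_h = cum_cell_h * 1.0e3 * config.cell_dry_weight_pg * 1.0e-12

    def noisy(series: np.ndarray) -> np.ndarray:
        if config.noise_sigma == 0:
            return series.copy()
        return series * rng.lognormal(mean=0.0, sigma=config.noise_sigma,
                                      size=series.shape)

    mets = {}
    for name, rate in config.metabolite_rates_mmol_gdw_h.items():
        x0 = config.metabolite_initial_mM.get(name, 30.0)
        conc = x0 + rate * gdw_per_l_h
        if np.any(conc < 0):
            raise ValueError(f"{name} concentration goes negative; shorten "
                             "the culture or reduce the rate")
        mets[name] = noisy(conc)
    meta = ",".join(f"{k}={v}" for k, v in (
        ("seed", config.seed), ("mu", config.mu_per_h),
        ("qp", config.qp_pg_per_cell_day), ("sigma", config.noise_sigma)))
    return TimeCourse(times=t, vcd=noisy(vcd_true), titer=noisy(titer_true),
                      metabolites=mets, replicate_id=f"synthetic[{meta}]")


def make_synthetic_psim(n: int, seed: int = 0,
                        secretory_fraction: float = 0.8) -> SecretomeTable:
    """Generate n valid PSIM entries emulating a mammalian secretome.

    Lengths are log-uniform in [50, 3000]; MW is ~110 Da per residue with
    multiplicative jitter (ratio kept within [90, 140]); PTM counts come
    from sparse Poisson distributions; locations are drawn consistently
    with the signal-peptide flag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    sec_locations = [loc for loc in LOCATIONS if loc != "other"]
    for i in range(n):
        length = int(round(np.exp(rng.uniform(np.log(50), np.log(3000)))))
        ratio = float(np.clip(110.0 * rng.lognormal(0.0, 0.05), 95.0, 135.0))
        mw = length * ratio
        has_sp = bool(rng.random() < secretory_fraction)
        dsb = min(int(rng.poisson(2.0)), length // 2)
        ng = min(int(rng.poisson(1.2)), length)
        og = int(rng.poisson(0.6))
        gpi = bool(rng.random() < 0.05)
        tmd = int(rng.poisson(0.4))
        if has_sp:
            location = str(rng.choice(sec_locations))
        else:
            location = "other"
            dsb = ng = og = tmd = 0
            gpi = False
        entry = PSIMEntry(
            protein_id=f"SYN{i:05d}", length=length, molecular_weight=mw,
            has_signal_peptide=has_sp, disulfide_bonds=dsb,
            has_gpi_anchor=gpi, n_glycans=ng, o_glycans=og,
            transmembrane_domains=tmd, location=location,
        )
        assert not entry.violations(), entry.violations()
        entries.append(entry)
    return SecretomeTable(entries=entries, source_taxon="cho")


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian copula achieving a target
    Spearman correlation: rho = 2 sin(pi rho_s / 6)."""
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("target Spearman correlation must lie in [-1, 1]")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def make_synthetic_expression(costs: Mapping[str, float] | "pd.Series",
                              target_rho: float, seed: int = 0,
                              log_mean: float = 2.0,
                              log_sigma: float = 1.5) -> ExpressionTable:
    """Expression levels with a target Spearman correlation against cost.

    A Gaussian copula is drawn against the normal scores of the cost ranks
    with the Pearson parameter calibrated via rho = 2 sin(pi rho_s / 6), and
    mapped through a lognormal marginal to positive RPKM values.
    """
    costs = pd.Series(costs, dtype=float)
    n = len(costs)
    if n < 2:
        raise ValueError("need >= 2 cost entries")
    rng = np.random.default_rng(seed)
    rho = spearman_to_pearson(target_rho)
    ranks = stats.rankdata(costs.to_numpy(), method="average")
    z_cost = stats.norm.ppf(ranks / (n + 1.0))
    z_cost = (z_cost - z_cost.mean()) / z_cost.std()
    noise = rng.standard_normal(n)
    if abs(rho) == 1.0:
        z = math.copysign(1.0, rho) * z_cost
    else:
        z = rho * z_cost + math.sqrt(1.0 - rho * rho) * noise
    levels = np.exp(log_mean + log_sigma * z)
    return ExpressionTable(levels=pd.Series(levels, index=costs.index),
                           label=f"synthetic[rho_s={target_rho},seed={seed}]")
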