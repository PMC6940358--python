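"""Shared fixtures: published biotherapeutic PSIM rows, toy models, and an
independent scipy-based LP oracle for cross-checking cobra FBA optima."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from secrecon import PSIMEntry, ToyModelSpec, make_toy_metabolic_model

# Published feature rows for eight biotherapeutics: (length, MW, disulfide
# bonds, N-glycans, O-glycans, published integer ATP cost). EPO's published
# total (1801) is inconsistent with the stated formulas (which give ~801)
# and is kept separately.
BIOTHERAPEUTICS = {
    "IFNB1": (187, 22294, 1, 1, 0, 777),
    "BMP2": (396, 44702, 4, 5, 0, 1618),
    "BMP7": (431, 49313, 4, 4, 0, 1759),
    "tPA": (562, 61917, 17, 3, 1, 2286),
    "Etanercept": (934, 102470, 7, 6, 26, 3784),
    "Rituximab": (1328, 143860, 17, 2, 0, 5370),
    "F8": (2351, 267009, 8, 22, 0, 9488),
}
EPO_ROW = (193, 21037, 2, 3, 1, 1801)


def make_entry(name: str, row=None) -> PSIMEntry:
    length, mw, dsb, ng, og, _ = row if row is not None else BIOTHERAPEUTICS[name]
    return PSIMEntry(
        protein_id=name, length=length, molecular_weight=mw,
        has_signal_peptide=True, disulfide_bonds=dsb, n_glycans=ng,
        o_glycans=og, location="secreted",
    )


@pytest.fixture(scope="session")
def biotherapeutic_entries() -> dict[str, PSIMEntry]:
    return {name: make_entry(name) for name in BIOTHERAPEUTICS}


@pytest.fixture()
def toy_model():
    return make_toy_metabolic_model(ToyModelSpec())


def lp_oracle_optimum(model, objective_id: str, sense: str = "max",
                      extra_bounds: dict | None = None) -> float:
    """Independent FBA optimum via scipy.optimize.linprog (HiGHS).

    Builds the stoichiometric matrix and bounds directly from the model
    structure without using cobra's solver stack.
    """
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    rxns = list(model.reactions)
    S = np.zeros((len(mets), len(rxns)))
    bounds = []
    for j, r in enumerate(rxns):
        for met, coef in r.metabolites.items():
            S[mets[met.id], j] = coef
        lb, ub = r.bounds
        if extra_bounds and r.id in extra_bounds:
            lb, ub = extra_bounds[r.id]
        bounds.append((lb, ub))
    c = np.zeros(len(rxns))
    c[[r.id for r in rxns].index(objective_id)] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    if not res.success:
        raise RuntimeError(f"oracle LP failed: {res.message}")
    return -res.fun if sense == "max" else res.fun


def random_toy_spec(rng: np.random.Generator) -> ToyModelSpec:
    return ToyModelSpec(
        glucose_uptake_bound=float(rng.uniform(0.5, 20.0)),
        atp_per_glucose=float(rng.uniform(0.5, 30.0)),
        amino_acid_uptake_bound=float(rng.uniform(0.5, 20.0)),
        biomass_aa=float(rng.uniform(0.1, 5.0)),
        biomass_atp=float(rng.uniform(0.1, 5.0)),
    )
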