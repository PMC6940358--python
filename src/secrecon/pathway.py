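"""Protein-specific secretory reaction pathways for constraint-based models.

Given one PSIM row, this module generates the ordered chain of stoichiometric
template reactions that synthesize, process and export that protein —
translation, ER translocation, signal-peptide degradation, disulfide-bond
formation, core N-/O-glycosylation, GPI attachment, COPII (ER-to-Golgi) and
secretory-vesicle transport, and a terminal demand — and splices the chain
into a base genome-scale metabolic model (a :class:`cobra.Model`).

Template reactions are model-agnostic: stoichiometry is expressed over
species *ids* and a :class:`CurrencyMap` binds the template's currency and
precursor species (ATP, GTP, amino acids, core-glycan precursors, ...) to the
ids the base model uses. Protein intermediates are named
``<protein_id>_<stage>_<compartment>`` over five compartments: c (cytosol),
r (ER), g (Golgi), m (membrane), e (extracellular).

Every processing reaction converts exactly one unit of the upstream protein
species into one unit of the downstream species, so the protein moiety is
conserved along the chain, and the summed ATP+GTP consumption of a pathway at
unit flux equals the cost engine's raw total for the same PSIM entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import cobra

from .costs import (CostParameters, VesicleParameters, protein_volume,
                    vesicular_transport_cost)
from .psim import AMINO_ACIDS, PSIMEntry

__all__ = [
    "SUBSYSTEMS",
    "CurrencyMap",
    "TemplateReaction",
    "ProteinPathway",
    "BindingError",
    "CollisionError",
    "build_translation_reaction",
    "build_processing_reactions",
    "build_pathway",
    "expand_model",
    "validate_expansion",
    "pathway_atp_equivalents",
    "read_model",
    "write_model",
]

#: The twelve functional modules of the secretory-pathway reconstruction.
SUBSYSTEMS = (
    "translation",
    "translocation",
    "protein folding",
    "disulfide-bond formation",
    "N-glycosylation",
    "O-glycosylation",
    "GPI biosynthesis/attachment",
    "ERAD",
    "COPII vesicle formation",
    "Golgi processing",
    "vesicle secretion",
    "proteasomal degradation",
)

COMPARTMENTS = ("c", "r", "g", "m", "e")


class BindingError(KeyError):
    """A template species could not be bound to a base-model metabolite."""


class CollisionError(ValueError):
    """An id to be added already exists in the base model."""


@dataclass(frozen=True)
class CurrencyMap:
    """Binding of template currency/precursor species to model metabolite ids.

    ``amino_acids`` maps one-letter codes to metabolite ids for per-residue
    stoichiometry; when a sequence composition is unavailable the aggregate
    ``aa`` pseudo-metabolite is consumed instead.
    """

    atp: str = "atp_c"
    adp: str = "adp_c"
    amp: str = "amp_c"
    gtp: str = "gtp_c"
    gdp: str = "gdp_c"
    pi: str = "pi_c"
    h2o: str = "h2o_c"
    aa: str = "aa_c"
    n_glycan_precursor: str = "ngcore_r"
    o_glycan_precursor: str = "ogcore_r"
    gpi_precursor: str = "gpiprec_r"
    oxidizing_equivalent: str = "oxeq_r"
    amino_acids: Mapping[str, str] | None = None

    def amino_acid_id(self, one_letter: str) -> str:
        if self.amino_acids is not None and one_letter in self.amino_acids:
            return self.amino_acids[one_letter]
        return f"aa_{one_letter}_c"

    def currency_ids(self) -> set[str]:
        ids = {self.atp, self.adp, self.amp, self.gtp, self.gdp,
               self.pi, self.h2o, self.aa,
               self.n_glycan_precursor, self.o_glycan_precursor,
               self.gpi_precursor, self.oxidizing_equivalent}
        if self.amino_acids:
            ids |= set(self.amino_acids.values())
        ids |= {f"aa_{a}_c" for a in AMINO_ACIDS}
        return ids


@dataclass
class TemplateReaction:
    """One stoichiometric step of a protein-specific secretory pathway."""

    rxn_id: str
    subsystem: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS and self.subsystem != "demand":
            raise ValueError(f"unknown subsystem {self.subsystem!r}")
        coefs = list(self.stoichiometry.values())
        if not coefs or not any(c < 0 for c in coefs):
            raise ValueError(f"{self.rxn_id}: needs >= 1 negative coefficient")
        if self.subsystem != "demand" and not any(c > 0 for c in coefs):
            raise ValueError(f"{self.rxn_id}: needs >= 1 positive coefficient")
        for met, c in self.stoichiometry.items():
            if c == 0 or not math.isfinite(c):
                raise ValueError(f"{self.rxn_id}: coefficient for {met} is {c}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.rxn_id}: lower bound exceeds upper bound")

    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class ProteinPathway:
    """Ordered, connected reaction chain secreting one protein."""

    entry: PSIMEntry
    reactions: list[TemplateReaction]
    demand_reaction_id: str
    protein_species: list[str] = field(default_factory=list)

    def reaction_ids(self) -> list[str]:
        return [r.rxn_id for r in self.reactions]


def _species(entry: PSIMEntry, stage: str, compartment: str) -> str:
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    return f"{entry.protein_id}_{stage}_{compartment}"


def build_translation_reaction(
    entry: PSIMEntry,
    composition: Mapping[str, int] | None = None,
    currency_map: CurrencyMap = CurrencyMap(),
    cost_params: CostParameters = CostParameters(),
) -> TemplateReaction:
    """Translation template: amino acids + 4L ATP equivalents -> cytosolic protein.

    The 4L energy budget is split per mechanism: 2L ATP hydrolyzed to AMP
    during tRNA charging, 2 GTP for initiation + termination, L-1 GTP for
    peptide-bond formation and L-1 GTP for ribosomal translocation. With a
    known residue composition each amino acid is consumed by its count;
    otherwise L units of the aggregate amino-acid pseudo-metabolite are used.
    """
    L = entry.length
    if L < 1:
        raise ValueError("entry length must be >= 1")
    if composition is not None:
        total = sum(composition.values())
        if total != L:
            raise ValueError(
                f"composition totals {total} but entry length is {L}"
            )
        if not composition:
            raise ValueError("empty composition")

    cm = currency_map
    atp_charging = 2.0 * L
    gtp_init_term = 2.0
    gtp_bonds = float(L - 1)
    gtp_ribosome = float(L - 1)
    gtp_total = gtp_init_term + gtp_bonds + gtp_ribosome
    assert atp_charging + gtp_total == cost_params.translation_atp_per_residue * L

    stoich: dict[str, float] = {}
    if composition is None:
        stoich[cm.aa] = -float(L)
    else:
        for aa, count in composition.items():
            if count:
                stoich[cm.amino_acid_id(aa)] = -float(count)
    stoich[cm.atp] = -atp_charging
    stoich[cm.gtp] = -gtp_total
    stoich[cm.h2o] = -(atp_charging + gtp_total)
    stoich[cm.amp] = atp_charging
    stoich[cm.gdp] = gtp_total
    # ATP->AMP releases pyrophosphate (counted as 2 Pi), GTP->GDP one Pi.
    stoich[cm.pi] = 2.0 * atp_charging + gtp_total
    stoich[_species(entry, "nascent", "c")] = 1.0
    return TemplateReaction(
        rxn_id=f"TRANS_{entry.protein_id}",
        subsystem="translation",
        stoichiometry=stoich,
    )


def build_processing_reactions(
    entry: PSIMEntry,
    ves_params: VesicleParameters = VesicleParameters(),
    currency_map: CurrencyMap = CurrencyMap(),
    cost_params: CostParameters = CostParameters(),
    include_degradation: bool = False,
) -> list[TemplateReaction]:
    """Post-translational processing chain, gated on the PSIM flags.

    For a signal-peptide bearer the chain is: ER translocation (2 + L/40
    GTP), signal-peptide degradation (22 ATP), then conditionally disulfide
    formation (DSB oxidizing equivalents), core N- and O-glycosylation
    (NG/OG precursor units), GPI attachment, COPII transport, secretory
    vesicle transport, and a terminal demand in the destination compartment
    (extracellular, or membrane for TMD/GPI/organelle-routed proteins).
    A protein without a signal peptide gets only a cytosolic demand.

    ERAD/proteasomal templates are emitted zero-bounded when
    ``include_degradation`` is set (no misfolding fraction is modeled).
    """
    bad = entry.violations()
    if bad:
        raise ValueError(
            f"invalid PSIM entry {entry.protein_id}: " + "; ".join(bad)
        )
    cm = currency_map
    pid = entry.protein_id
    reactions: list[TemplateReaction] = []
    current = _species(entry, "nascent", "c")

    if not entry.has_signal_peptide:
        reactions.append(TemplateReaction(
            rxn_id=f"DM_{pid}", subsystem="demand",
            stoichiometry={current: -1.0},
        ))
        return reactions

    def step(rxn_id: str, subsystem: str, stage: str, compartment: str,
             extra: dict[str, float]) -> None:
        nonlocal current
        nxt = _species(entry, stage, compartment)
        stoich = {current: -1.0, nxt: 1.0}
        stoich.update(extra)
        reactions.append(TemplateReaction(rxn_id=rxn_id, subsystem=subsystem,
                                          stoichiometry=stoich))
        current = nxt

    L = entry.length
    transloc_gtp = (cost_params.translocon_activation_gtp
                    + L / cost_params.bip_residues_per_gtp)
    step(f"TLC_{pid}", "translocation", "presp", "r", {
        cm.gtp: -transloc_gtp, cm.h2o: -transloc_gtp,
        cm.gdp: transloc_gtp, cm.pi: transloc_gtp,
    })
    sp_atp = cost_params.signal_peptide_degradation_atp
    step(f"SPDEG_{pid}", "protein folding", "proc", "r", {
        cm.atp: -sp_atp, cm.h2o: -sp_atp,
        cm.adp: sp_atp, cm.pi: sp_atp,
    })
    if entry.disulfide_bonds > 0:
        step(f"DSB_{pid}", "disulfide-bond formation", "dsb", "r", {
            cm.oxidizing_equivalent: -float(entry.disulfide_bonds),
        })
    if entry.n_glycans > 0:
        step(f"NGLY_{pid}", "N-glycosylation", "nglyc", "r", {
            cm.n_glycan_precursor: -float(entry.n_glycans),
        })
    if entry.o_glycans > 0:
        step(f"OGLY_{pid}", "O-glycosylation", "oglyc", "r", {
            cm.o_glycan_precursor: -float(entry.o_glycans),
        })
    if entry.has_gpi_anchor:
        step(f"GPI_{pid}", "GPI biosynthesis/attachment", "gpi", "r", {
            cm.gpi_precursor: -1.0,
        })

    copii_gtp, sec_gtp = vesicular_transport_cost(entry.molecular_weight,
                                                  ves_params)
    step(f"COPII_{pid}", "COPII vesicle formation", "golgi", "g", {
        cm.gtp: -copii_gtp, cm.h2o: -copii_gtp,
        cm.gdp: copii_gtp, cm.pi: copii_gtp,
    })
    destination = "m" if entry.is_membrane_bound else "e"
    step(f"SECV_{pid}", "vesicle secretion", "mature", destination, {
        cm.gtp: -sec_gtp, cm.h2o: -sec_gtp,
        cm.gdp: sec_gtp, cm.pi: sec_gtp,
    })
    reactions.append(TemplateReaction(
        rxn_id=f"DM_{pid}", subsystem="demand",
        stoichiometry={current: -1.0},
    ))

    if include_degradation:
        # Zero-bounded templates: no per-protein misfolding fraction is known.
        erad_src = _species(entry, "proc", "r")
        reactions.append(TemplateReaction(
            rxn_id=f"ERAD_{pid}", subsystem="ERAD",
            stoichiometry={erad_src: -1.0,
                           _species(entry, "misfolded", "c"): 1.0},
            lower_bound=0.0, upper_bound=0.0,
        ))
        deg_atp = float(entry.length)
        reactions.append(TemplateReaction(
            rxn_id=f"PROTDEG_{pid}", subsystem="proteasomal degradation",
            stoichiometry={_species(entry, "misfolded", "c"): -1.0,
                           cm.atp: -deg_atp, cm.h2o: -deg_atp,
                           cm.adp: deg_atp, cm.pi: deg_atp,
                           cm.aa: float(entry.length)},
            lower_bound=0.0, upper_bound=0.0,
        ))
    return reactions


def build_pathway(
    entry: PSIMEntry,
    composition: Mapping[str, int] | None = None,
    currency_map: CurrencyMap = CurrencyMap(),
    cost_params: CostParameters = CostParameters(),
    ves_params: VesicleParameters = VesicleParameters(),
    include_degradation: bool = False,
) -> ProteinPathway:
    """Full pathway for one PSIM entry: translation plus processing chain."""
    reactions = [build_translation_reaction(entry, composition, currency_map,
                                            cost_params)]
    reactions += build_processing_reactions(entry, ves_params, currency_map,
                                            cost_params, include_degradation)
    currency = currency_map.currency_ids()
    species: list[str] = []
    for rxn in reactions:
        for met in rxn.stoichiometry:
            if met not in currency and met not in species:
                species.append(met)
    return ProteinPathway(entry=entry, reactions=reactions,
                          demand_reaction_id=f"DM_{entry.protein_id}",
                          protein_species=species)


def pathway_atp_equivalents(pathway: ProteinPathway,
                            currency_map: CurrencyMap = CurrencyMap()) -> float:
    """Summed ATP + GTP consumption of the pathway at unit flux.

    Zero-bounded degradation templates are excluded; the result equals
    :func:`secrecon.costs.total_secretion_cost` ``.total_raw`` for the same
    entry and parameters.
    """
    energy = {currency_map.atp, currency_map.gtp}
    total = 0.0
    for rxn in pathway.reactions:
        if rxn.upper_bound == 0 and rxn.lower_bound == 0:
            continue
        for met, coef in rxn.stoichiometry.items():
            if met in energy and coef < 0:
                total -= coef
    return total


def _compartment_of(met_id: str) -> str:
    suffix = met_id.rsplit("_", 1)[-1]
    return suffix if suffix in COMPARTMENTS else "c"


def expand_model(base: cobra.Model, pathway: ProteinPathway,
                 currency_map: CurrencyMap = CurrencyMap()) -> cobra.Model:
    """Splice a protein pathway into a copy of the base model.

    Currency and precursor species must already exist in the base model
    (unbound ids raise :class:`BindingError` listing all missing ids);
    protein intermediates are created fresh. The base objective is left
    untouched and the terminal demand is bounded [0, inf).
    """
    collisions = [r.rxn_id for r in pathway.reactions
                  if base.reactions.has_id(r.rxn_id)]
    if collisions:
        raise CollisionError(f"reaction id(s) already in model: {collisions}")

    currency = currency_map.currency_ids()
    referenced_currency = {met for rxn in pathway.reactions
                           for met in rxn.stoichiometry if met in currency}
    missing = sorted(m for m in referenced_currency
                     if not base.metabolites.has_id(m))
    if missing:
        raise BindingError(
            f"base model lacks currency/precursor species: {missing}"
        )

    model = base.copy()
    new_mets = {}
    for sp in pathway.protein_species:
        if model.metabolites.has_id(sp):
            raise CollisionError(f"metabolite id already in model: {sp}")
        new_mets[sp] = cobra.Metabolite(sp, compartment=_compartment_of(sp))
    model.add_metabolites(list(new_mets.values()))

    cobra_rxns = []
    for t in pathway.reactions:
        rxn = cobra.Reaction(t.rxn_id,
                             lower_bound=-1000.0 if t.reversible else t.lower_bound,
                             upper_bound=t.upper_bound if math.isfinite(t.upper_bound) else 1000.0)
        rxn.subsystem = t.subsystem
        rxn.add_metabolites({
            model.metabolites.get_by_id(met): coef
            for met, coef in t.stoichiometry.items()
        })
        cobra_rxns.append(rxn)
    model.add_reactions(cobra_rxns)
    dm = model.reactions.get_by_id(pathway.demand_reaction_id)
    dm.bounds = (0.0, 1000.0)
    return model


@dataclass
class ExpansionReport:
    """Structural diagnostics for an expanded model."""

    violations: list[str]
    dead_end_metabolites: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_expansion(model: cobra.Model,
                       pathway: ProteinPathway | None = None) -> ExpansionReport:
    """Check structural invariants of an expanded model.

    Verifies bounds ordering, reports dead-end metabolites, and — when the
    pathway is supplied — that every processing step conserves the protein
    moiety 1:1 along the chain.
    """
    violations: list[str] = []
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            violations.append(f"{rxn.id}: lower bound exceeds upper bound")
        for met, coef in rxn.metabolites.items():
            if coef == 0 or not math.isfinite(coef):
                violations.append(f"{rxn.id}: coefficient {coef} for {met.id}")

    dead_ends = []
    for met in model.metabolites:
        produced = any(
            (c > 0 and r.upper_bound > 0) or (c < 0 and r.lower_bound < 0)
            for r in met.reactions for m, c in r.metabolites.items() if m is met
        )
        consumed = any(
            (c < 0 and r.upper_bound > 0) or (c > 0 and r.lower_bound < 0)
            for r in met.reactions for m, c in r.metabolites.items() if m is met
        )
        if not (produced and consumed):
            dead_ends.append(met.id)

    if pathway is not None:
        species = set(pathway.protein_species)
        for t in pathway.reactions:
            ins = [c for m, c in t.stoichiometry.items()
                   if m in species and c < 0]
            outs = [c for m, c in t.stoichiometry.items()
                    if m in species and c > 0]
            if t.subsystem == "translation":
                if outs != [1.0]:
                    violations.append(f"{t.rxn_id}: must produce 1 protein unit")
            elif t.subsystem == "demand":
                if ins != [-1.0] or outs:
                    violations.append(f"{t.rxn_id}: must consume 1 protein unit")
            else:
                if ins != [-1.0] or outs != [1.0]:
                    violations.append(
                        f"{t.rxn_id}: protein moiety not conserved 1:1"
                    )
    return ExpansionReport(violations=violations,
                           dead_end_metabolites=sorted(dead_ends))


def read_model(path: str) -> cobra.Model:
    """Load a model from COBRA JSON or SBML L3+FBC, by file extension."""
    path = str(path)
    if path.endswith(".json"):
        return cobra.io.load_json_model(path)
    return cobra.io.read_sbml_model(path)


def write_model(model: cobra.Model, path: str) -> None:
    """Write a model as COBRA JSON or SBML L3+FBC, by file extension."""
    path = str(path)
    if path.endswith(".json"):
        cobra.io.save_json_model(model, path)
    else:
        cobra.io.write_sbml_model(model, path)
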