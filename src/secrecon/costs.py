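"""Per-protein ATP-equivalent synthesis-and-secretion costs.

The bioenergetic cost of making and exporting one molecule of a secreted
protein of length L residues and molecular weight MW daltons is tallied over
five mechanisms, all expressed in ATP equivalents (GTP counted 1:1):

* translation: 4L — tRNA charging (2L, ATP to AMP), initiation + termination
  (2 GTP), L-1 peptide-bond GTPs, L-1 ribosome-translocation GTPs;
* signal-peptide degradation: 22 (the mean signal peptide is ~22 residues and
  each peptide bond costs one ATP to hydrolyze);
* ER translocation: L/40 + 2 — two GTPs to activate the translocon, then one
  BiP-bound GTP per 40 residues threaded through the pore;
* COPII (ER-to-Golgi) transport: 192 GTP per vesicle, shared over the number
  of protein molecules a vesicle holds;
* secretory (clathrin-coated, Golgi-to-surface) transport: 44 GTP per
  vesicle, shared likewise.

Vesicle sharing treats the cargo as a globular particle of volume
V_P = MW x 0.00121 nm^3 packed into a sphere at 70% occupancy, so each
vesicle leg costs gtp_per_vesicle / (V_vesicle x 0.7 / V_P), evaluated
continuously. Proteins without a signal peptide incur the translation term
only. Disulfide bonds, glycans and GPI anchors carry no ATP line-item here;
their material demands appear as metabolite consumption in the generated
pathway reactions (:mod:`secrecon.pathway`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .psim import PSIMEntry, SecretomeTable

__all__ = [
    "CostParameters",
    "VesicleParameters",
    "CostBreakdown",
    "VesicleCapacityError",
    "translation_cost",
    "sp_degradation_cost",
    "translocation_cost",
    "protein_volume",
    "sphere_volume",
    "vesicular_transport_cost",
    "total_secretion_cost",
    "basal_cost",
    "secretome_cost_table",
]


class VesicleCapacityError(ValueError):
    """Protein volume exceeds the usable volume of a vesicle class."""


@dataclass(frozen=True)
class CostParameters:
    """Translation/translocation energetics (ATP equivalents, GTP counted 1:1)."""

    translation_atp_per_residue: float = 4.0
    signal_peptide_degradation_atp: float = 22.0
    translocon_activation_gtp: float = 2.0
    bip_residues_per_gtp: float = 40.0

    def __post_init__(self) -> None:
        for name in ("translation_atp_per_residue", "signal_peptide_degradation_atp",
                     "translocon_activation_gtp", "bip_residues_per_gtp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class VesicleParameters:
    """Vesicle geometry and per-vesicle GTP budgets.

    Diameters default to 50 nm (COPII) and 100 nm (secretory vesicle), with
    70% of the spherical volume usable by cargo and a globular-protein
    specific volume of 0.00121 nm^3 per dalton.
    """

    copii_gtp_per_vesicle: float = 192.0
    secretory_gtp_per_vesicle: float = 44.0
    copii_diameter_nm: float = 50.0
    secretory_diameter_nm: float = 100.0
    occupancy_fraction: float = 0.7
    volume_per_dalton: float = 0.00121

    def __post_init__(self) -> None:
        if self.copii_diameter_nm <= 0 or self.secretory_diameter_nm <= 0:
            raise ValueError("vesicle diameters must be positive")
        if not 0 < self.occupancy_fraction <= 1:
            raise ValueError("occupancy_fraction must lie in (0, 1]")
        if self.volume_per_dalton <= 0:
            raise ValueError("volume_per_dalton must be positive")

    @property
    def copii_volume_nm3(self) -> float:
        return sphere_volume(self.copii_diameter_nm)

    @property
    def secretory_volume_nm3(self) -> float:
        return sphere_volume(self.secretory_diameter_nm)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-mechanism ATP-equivalent costs for one protein molecule."""

    protein_id: str
    translation: float
    sp_degradation: float
    translocation: float
    copii_transport: float
    secretory_transport: float
    protein_volume_nm3: float

    @property
    def total_raw(self) -> float:
        return (self.translation + self.sp_degradation + self.translocation
                + self.copii_transport + self.secretory_transport)

    @property
    def total_rounded(self) -> int:
        return round_half_up(self.total_raw)

    def as_dict(self) -> dict[str, float]:
        return {
            "protein_id": self.protein_id,
            "translation": self.translation,
            "sp_degradation": self.sp_degradation,
            "translocation": self.translocation,
            "copii_transport": self.copii_transport,
            "secretory_transport": self.secretory_transport,
            "protein_volume_nm3": self.protein_volume_nm3,
            "total_raw": self.total_raw,
            "total_rounded": self.total_rounded,
        }


def rounding_sensitivity(total_raw: float) -> dict[str, int]:
    """Integer totals under alternative rounding conventions.

    Published per-protein totals are integers; this reports the raw total
    rounded half-up (the package convention), half-even, floor and ceiling
    so users can see which totals are robust to the convention choice.
    """
    return {
        "half_up": round_half_up(total_raw),
        "half_even": int(round(total_raw)),
        "floor": int(math.floor(total_raw)),
        "ceil": int(math.ceil(total_raw)),
    }


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sphere_volume(diameter_nm: float) -> float:
    return math.pi * diameter_nm**3 / 6.0


def translation_cost(length: int, params: CostParameters = CostParameters()) -> float:
    """Cost of translating L residues: 4L ATP equivalents (no proofreading)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return params.translation_atp_per_residue * length


def sp_degradation_cost(has_sp: bool,
                        params: CostParameters = CostParameters()) -> float:
    """Mean cost of degrading the cleaved signal peptide (22 ATP), or 0."""
    return params.signal_peptide_degradation_atp if has_sp else 0.0


def translocation_cost(length: int, has_sp: bool,
                       params: CostParameters = CostParameters()) -> float:
    """ER translocation cost L/40 + 2 GTP for signal-peptide bearers, else 0.

    Kept as an exact real; no per-term rounding.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not has_sp:
        return 0.0
    return length / params.bip_residues_per_gtp + params.translocon_activation_gtp


def protein_volume(molecular_weight: float,
                   params: VesicleParameters = VesicleParameters()) -> float:
    """Globular-protein volume V_P = MW x 0.00121 nm^3."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return molecular_weight * params.volume_per_dalton


def vesicular_transport_cost(
    molecular_weight: float,
    params: VesicleParameters = VesicleParameters(),
) -> tuple[float, float]:
    """Per-molecule GTP cost of the COPII and secretory vesicle legs.

    Each leg costs gtp_per_vesicle / (V_vesicle x occupancy / V_P) with
    fractional cargo capacity (no integer flooring).
    """
    v_p = protein_volume(molecular_weight, params)
    costs = []
    for label, volume, gtp in (
        ("COPII", params.copii_volume_nm3, params.copii_gtp_per_vesicle),
        ("secretory", params.secretory_volume_nm3, params.secretory_gtp_per_vesicle),
    ):
        usable = volume * params.occupancy_fraction
        if v_p >= usable:
            raise VesicleCapacityError(
                f"protein volume {v_p:.3g} nm^3 exceeds usable {label} vesicle "
                f"volume {usable:.3g} nm^3"
            )
        costs.append(gtp * v_p / usable)
    return costs[0], costs[1]


def total_secretion_cost(
    entry: PSIMEntry,
    cost_params: CostParameters = CostParameters(),
    ves_params: VesicleParameters = VesicleParameters(),
) -> CostBreakdown:
    """Full cost breakdown for one PSIM entry.

    Signal-peptide bearers (secreted and membrane proteins alike) traverse
    both vesicle legs; cytosolic proteins incur translation only. For
    assembled multimers the signal-peptide and translocon-activation terms
    are charged once on the total length.
    """
    bad = entry.violations()
    if bad:
        raise ValueError(f"invalid PSIM entry {entry.protein_id}: " + "; ".join(bad))
    secretory = entry.has_signal_peptide
    copii = sec = 0.0
    if secretory:
        copii, sec = vesicular_transport_cost(entry.molecular_weight, ves_params)
    return CostBreakdown(
        protein_id=entry.protein_id,
        translation=translation_cost(entry.length, cost_params),
        sp_degradation=sp_degradation_cost(secretory, cost_params),
        translocation=translocation_cost(entry.length, secretory, cost_params),
        copii_transport=copii,
        secretory_transport=sec,
        protein_volume_nm3=protein_volume(entry.molecular_weight, ves_params),
    )


def basal_cost(entry: PSIMEntry,
               cost_params: CostParameters = CostParameters()) -> float:
    """Translation-only cost (4L): the comparator for secretory-overhead analyses.

    Glycan-precursor material costs are identical under both accountings and
    cancel in the full-vs-basal comparison.
    """
    bad = entry.violations()
    if bad:
        raise ValueError(f"invalid PSIM entry {entry.protein_id}: " + "; ".join(bad))
    return translation_cost(entry.length, cost_params)


def secretome_cost_table(
    table: SecretomeTable,
    cost_params: CostParameters = CostParameters(),
    ves_params: VesicleParameters = VesicleParameters(),
) -> tuple[list[CostBreakdown], dict[str, str]]:
    """Cost every entry; rank descending by raw total, ties by protein id.

    Returns (ranked breakdowns, {protein_id: error message} for entries whose
    costing failed — failures are collected, not fatal).
    """
    if len(table) == 0:
        raise ValueError("empty secretome table")
    breakdowns: list[CostBreakdown] = []
    failures: dict[str, str] = {}
    for entry in table:
        try:
            breakdowns.append(total_secretion_cost(entry, cost_params, ves_params))
        except (ValueError, VesicleCapacityError) as exc:
            failures[entry.protein_id] = str(exc)
    breakdowns.sort(key=lambda b: (-b.total_raw, b.protein_id))
    return breakdowns, failures
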