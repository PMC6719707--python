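"""Fallback TMF estimation for data-poor chemicals.

When no field TMF study exists, a TMF can be approximated from other
bioaccumulation measures, in descending order of preference: (1) take
a one-TL-step biomagnification factor (BMF) as the TMF; (2) derive the
fish whole-organism biotransformation rate k_M from a laboratory
bioconcentration factor (BCF) by mass balance, then generate biota
concentrations with a steady-state food-web model and regress them on
diet-weighted trophic levels; (3) the same food-web route with an
externally estimated k_M.

The food-web model here is a deliberately small steady-state
mass-balance: producers (and sediment) sit at equilibrium partitioning
with the freely dissolved water concentration, and each consumer
balances gill uptake plus dietary uptake against gill elimination,
egestion, growth dilution, and (for fish) biotransformation:

    C_i = (k1·C_w + kD·Σ_j p_ij·C_j) / (k2 + kE + kG + kM)

with k1 = gill_uptake_coeff / W^0.25 (allometric), k2 = k1/(lipid·K_OW)
(lipid–water partitioning), kD = assimilation efficiency × feeding
rate, and kE = egestion_ratio × kD.  All coefficients are exposed in
the configuration; the contract of this model is directional and limit
behaviour (equilibrium-partitioning limit gives TMF = 1; large k_M
gives trophic dilution), not agreement with any particular calibrated
food-web code.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .quality import ChemicalClass
from .trophic import diet_weighted_trophic_levels

#: Default allometric gill uptake coefficient (L/kg/d at 1 kg body weight).
DEFAULT_GILL_UPTAKE_COEFF = 20.0


class NodeKind(str, enum.Enum):
    sediment = "sediment"
    producer = "producer"
    invertebrate = "invertebrate"
    fish = "fish"


class ChemicalProfile(BaseModel):
    """What is known about a chemical's bioaccumulation behaviour."""

    name: str
    log_kow: float
    bcf_ww: Optional[float] = Field(default=None, gt=0)  # L/kg wet weight
    bcf_species: Optional[str] = None
    bcf_fish_weight: Optional[float] = Field(default=None, gt=0)  # kg
    bmf: Optional[float] = Field(default=None, gt=0)
    bmf_species: Optional[str] = None
    km: Optional[float] = Field(default=None, ge=0)  # per day
    chemical_class: Optional[ChemicalClass] = None

    @model_validator(mode="after")
    def _sanity(self):
        if not (0.0 <= self.log_kow <= 10.0):
            warnings.warn(
                f"log Kow {self.log_kow} outside the usual 0–10 window",
                stacklevel=2,
            )
        return self


class FoodWebNode(BaseModel):
    id: str
    kind: NodeKind
    weight: float = Field(gt=0)  # kg
    lipid_fraction: float = Field(gt=0, lt=1)  # organic-carbon fraction for sediment
    diet: dict[str, float] = Field(default_factory=dict)
    feeding_rate: float = Field(default=0.0, ge=0)  # kg food / kg body / d
    growth_rate: float = Field(default=0.0, ge=0)  # per day


class FoodWebModelConfig(BaseModel):
    nodes: list[FoodWebNode]
    water_conc: float = Field(gt=0)  # µg/L freely dissolved
    temperature: Optional[float] = None  # °C, annotation only
    gill_uptake_coeff: float = DEFAULT_GILL_UPTAKE_COEFF
    diet_assimilation_eff: float = Field(default=0.8, gt=0, le=1)
    egestion_ratio: float = Field(default=0.3, ge=0)

    @model_validator(mode="after")
    def _check_structure(self):
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        idset = set(ids)
        for n in self.nodes:
            if n.kind in (NodeKind.sediment, NodeKind.producer):
                if n.diet:
                    raise ValueError(f"{n.kind.value} node {n.id!r} must have no diet")
            else:
                if not n.diet:
                    raise ValueError(f"consumer node {n.id!r} has an empty diet")
                total = sum(n.diet.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"diet fractions of {n.id!r} sum to {total}, expected 1"
                    )
                unknown = set(n.diet) - idset
                if unknown:
                    raise ValueError(f"node {n.id!r} eats unknown prey {unknown}")
        return self


def gill_uptake_rate(weight: float, gill_uptake_coeff: float = DEFAULT_GILL_UPTAKE_COEFF) -> float:
    """Allometric gill uptake rate k1 = coeff / W^0.25 (L/kg/d)."""
    if weight <= 0:
        raise ValueError("body weight must be positive")
    return gill_uptake_coeff / weight ** 0.25


def km_from_bcf(
    profile: ChemicalProfile,
    fish: FoodWebNode,
    gill_uptake_coeff: float = DEFAULT_GILL_UPTAKE_COEFF,
) -> float:
    """Biotransformation rate from a BCF by fish mass balance (per day).

    At steady state under water-only exposure, BCF = k1/(k2 + kG + kM),
    so kM = k1/BCF − k2 − kG with k2 = k1/(lipid·K_OW).  A negative
    result (BCF at or above the no-metabolism prediction) is clipped to
    0 with a warning — metabolism is then not identifiable from the BCF.
    """
    if profile.bcf_ww is None:
        raise ValueError(
            f"chemical {profile.name!r} has no BCF: route back to the "
            "decision tree (estimated k_M or no recommendation)"
        )
    k1 = gill_uptake_rate(fish.weight, gill_uptake_coeff)
    k2 = k1 / (fish.lipid_fraction * 10.0 ** profile.log_kow)
    km = k1 / profile.bcf_ww - k2 - fish.growth_rate
    if km < 0:
        warnings.warn(
            f"BCF {profile.bcf_ww} exceeds the no-metabolism steady state; "
            "metabolism not identifiable, k_M clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return float(km)


@dataclass
class FoodWebModelResult:
    tmf: float
    slope_log10: float
    trophic_levels: dict[str, float]
    concentrations_ww: dict[str, float]  # µg/kg wet weight
    concentrations_lipid: dict[str, float]  # µg/kg lipid
    km_by_node: dict[str, float]


def steady_state_foodweb_tmf(
    config: FoodWebModelConfig,
    profile: ChemicalProfile,
    km: Optional[float] = None,
) -> FoodWebModelResult:
    """Steady-state food-web concentrations and the model-derived TMF.

    ``km`` (per day) applies to fish nodes; it defaults to
    ``profile.km`` (0 if unset).  Trophic levels are diet-weighted with
    producers and sediment at TL 1; the TMF is the base-10 antilog of
    the regression slope of log lipid-normalized concentration on TL
    over biota nodes (sediment is excluded — the TMF is defined over
    biota).
    """
    if km is None:
        km = profile.km or 0.0
    kow = 10.0 ** profile.log_kow

    producers = {n.id for n in config.nodes if n.kind == NodeKind.producer}
    sediments = {n.id for n in config.nodes if n.kind == NodeKind.sediment}
    diet_matrix = {n.id: n.diet for n in config.nodes if n.diet}
    tls = diet_weighted_trophic_levels(diet_matrix, producers, detritus=sediments)
    for n in config.nodes:  # isolated producers/sediment still get TL 1
        tls.setdefault(n.id, 1.0)

    conc: dict[str, float] = {}
    km_by_node: dict[str, float] = {}
    order = sorted(config.nodes, key=lambda n: tls[n.id])
    for node in order:
        if node.kind in (NodeKind.producer, NodeKind.sediment):
            conc[node.id] = config.water_conc * node.lipid_fraction * kow
            km_by_node[node.id] = 0.0
            continue
        k1 = gill_uptake_rate(node.weight, config.gill_uptake_coeff)
        k2 = k1 / (node.lipid_fraction * kow)
        kd = config.diet_assimilation_eff * node.feeding_rate
        ke = config.egestion_ratio * kd
        node_km = km if node.kind == NodeKind.fish else 0.0
        km_by_node[node.id] = node_km
        diet_intake = sum(frac * conc[p] for p, frac in node.diet.items())
        conc[node.id] = (k1 * config.water_conc + kd * diet_intake) / (
            k2 + ke + node.growth_rate + node_km
        )

    biota = [n for n in config.nodes if n.kind != NodeKind.sediment]
    x = np.array([tls[n.id] for n in biota])
    clip = {n.id: conc[n.id] / n.lipid_fraction for n in config.nodes}
    y = np.log10([clip[n.id] for n in biota])
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct trophic levels among biota")
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    return FoodWebModelResult(
        tmf=10.0 ** slope,
        slope_log10=slope,
        trophic_levels={k: float(v) for k, v in tls.items()},
        concentrations_ww=conc,
        concentrations_lipid=clip,
        km_by_node=km_by_node,
    )


@dataclass
class KmScanResult:
    tmf_by_km: dict[float, float]
    threshold_km: Optional[float]  # smallest grid k_M with TMF <= 1


def km_threshold_scan(
    config: FoodWebModelConfig,
    profile: ChemicalProfile,
    km_grid: Sequence[float],
) -> KmScanResult:
    """Model TMF across a grid of biotransformation rates.

    The estimated TMF is non-increasing in k_M (it only adds to fish
    elimination), so the returned threshold — the smallest grid k_M
    with TMF ≤ 1 — is well defined when any grid point prevents
    magnification.
    """
    grid = [float(k) for k in km_grid]
    if any(k < 0 for k in grid):
        raise ValueError("k_M grid must be nonnegative")
    if sorted(grid) != grid:
        raise ValueError("k_M grid must be sorted ascending")
    tmf_by_km = {k: steady_state_foodweb_tmf(config, profile, km=k).tmf for k in grid}
    threshold = next((k for k in grid if tmf_by_km[k] <= 1.0), None)
    return KmScanResult(tmf_by_km=tmf_by_km, threshold_km=threshold)


def tmf_from_bmf(bmf: float) -> dict:
    """First fallback: assume TMF equals a one-TL-step BMF.

    Returns the value with its provenance tag rather than a bare float,
    so downstream reports keep the uncertainty pedigree.
    """
    if bmf <= 0:
        raise ValueError("BMF must be positive")
    return {
        "tmf": float(bmf),
        "provenance": "approximated_from_bmf",
        "uncertainty": "fallback_tier_1",
    }


def default_lake_foodweb(
    water_conc: float = 1e-3,
    include_sediment: bool = True,
) -> FoodWebModelConfig:
    """A five-node lake food web: sediment, phytoplankton, zooplankton,
    forage fish, piscivorous fish, as a linear pelagic chain (the
    piscivore sits at TL 4 by diet).

    Body weights, lipid fractions and feeding rates are generic
    temperate-lake values; all are plain config fields meant to be
    overridden for a site of interest.
    """
    nodes = [
        FoodWebNode(
            id="phytoplankton", kind=NodeKind.producer, weight=1e-9, lipid_fraction=0.01
        ),
        FoodWebNode(
            id="zooplankton",
            kind=NodeKind.invertebrate,
            weight=1e-6,
            lipid_fraction=0.02,
            diet={"phytoplankton": 1.0},
            feeding_rate=0.10,
            growth_rate=0.01,
        ),
        FoodWebNode(
            id="forage_fish",
            kind=NodeKind.fish,
            weight=0.01,
            lipid_fraction=0.05,
            diet={"zooplankton": 1.0},
            feeding_rate=0.025,
            growth_rate=0.002,
        ),
        FoodWebNode(
            id="piscivorous_fish",
            kind=NodeKind.fish,
            weight=1.0,
            lipid_fraction=0.05,
            diet={"forage_fish": 1.0},
            feeding_rate=0.015,
            growth_rate=0.001,
        ),
    ]
    if include_sediment:
        nodes.insert(
            0,
            FoodWebNode(
                id="sediment", kind=NodeKind.sediment, weight=1.0, lipid_fraction=0.02
            ),
        )
    return FoodWebModelConfig(nodes=nodes, water_conc=water_conc)
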