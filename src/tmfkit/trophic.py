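"""Trophic-level assignment.

Two routes are supported: the stable-isotope route, where an organism's
trophic level (TL) is computed from its δ15N relative to a designated
baseline primary consumer,

    TL = baseline_tl + (δ15N_consumer − δ15N_baseline) / Δ15N,

with Δ15N the trophic enrichment factor (typically 3.4‰ per TL step);
and the diet route, where TLs are solved from a diet-fraction matrix as
1 + the diet-weighted mean prey TL, with producers (and detrital pools)
anchored at TL 1.
"""

from __future__ import annotations

import enum
import graphlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .datamodel import (
    NONVERTEBRATE_GROUPS,
    BiotaSample,
    FoodWebDataset,
    TaxonGroup,
)

DEFAULT_ENRICHMENT_FACTOR = 3.4  # ‰ per TL step
DEFAULT_BASELINE_TL = 2.0


class AssignmentMethod(str, enum.Enum):
    isotope_baseline = "isotope_baseline"
    diet_weighted = "diet_weighted"
    supplied = "supplied"


@dataclass(frozen=True)
class TrophicAssignment:
    sample_id: str
    tl: float
    method: AssignmentMethod = AssignmentMethod.isotope_baseline


class DietStructureError(ValueError):
    """Cyclic diet graph or prey fractions that do not sum to one."""


def trophic_level_from_d15n(
    d15n_consumer: float,
    d15n_baseline: float,
    enrichment_factor: float = DEFAULT_ENRICHMENT_FACTOR,
    baseline_tl: float = DEFAULT_BASELINE_TL,
) -> float:
    """TL of a consumer from its δ15N relative to the baseline.

    Accepts scalars or numpy arrays for ``d15n_consumer``.  Values below
    ``baseline_tl`` are returned as-is (they indicate a baseline choice
    worth re-examining, and clipping would hide that).
    """
    if enrichment_factor <= 0:
        raise ValueError("enrichment factor must be positive (‰ per TL step)")
    return baseline_tl + (d15n_consumer - d15n_baseline) / enrichment_factor


def assign_trophic_levels(
    dataset: FoodWebDataset, warn_below_baseline: bool = True
) -> list[TrophicAssignment]:
    """Isotope-baseline TL for every sample in a dataset.

    The baseline δ15N is the arithmetic mean over the baseline species'
    samples.  Samples of the baseline species itself are pinned to
    ``baseline_tl`` exactly (their individual δ15N scatter is part of
    the baseline, not a trophic signal).
    """
    base = dataset.baseline_samples()
    d15n_baseline = float(np.mean([s.d15n for s in base]))
    out: list[TrophicAssignment] = []
    n_below = 0
    for s in dataset.samples:
        if s.species == dataset.baseline_species:
            tl = dataset.baseline_tl
        else:
            tl = trophic_level_from_d15n(
                s.d15n, d15n_baseline, dataset.enrichment_factor, dataset.baseline_tl
            )
            if tl < dataset.baseline_tl:
                n_below += 1
        out.append(TrophicAssignment(s.sample_id, float(tl)))
    if n_below and warn_below_baseline:
        warnings.warn(
            f"{n_below} sample(s) assigned TL below the baseline TL "
            f"{dataset.baseline_tl}; check the baseline designation",
            stacklevel=2,
        )
    return out


def diet_weighted_trophic_levels(
    diet_matrix: Mapping[str, Mapping[str, float]],
    producers: Iterable[str],
    detritus: Iterable[str] = (),
    atol: float = 1e-9,
) -> dict[str, float]:
    """Solve TLs from a diet matrix: TL = 1 + Σ_j p_ij · TL_j.

    ``diet_matrix`` maps each consumer to its prey fractions; producers
    and detritus/sediment pools are anchored at TL 1.0.  The diet graph
    (ignoring detrital nodes) must be acyclic.
    """
    producers = set(producers)
    detritus = set(detritus)
    tls: dict[str, float] = {n: 1.0 for n in producers | detritus}

    consumers = {c: dict(prey) for c, prey in diet_matrix.items() if c not in tls}
    for c, prey in consumers.items():
        total = sum(prey.values())
        if abs(total - 1.0) > atol:
            raise DietStructureError(
                f"diet fractions of {c!r} sum to {total}, expected 1"
            )
    graph = {
        c: {p for p in prey if p not in detritus} for c, prey in consumers.items()
    }
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise DietStructureError(f"cyclic diet graph: {exc.args[1]}") from exc

    for node in order:
        if node in tls:
            continue
        prey = consumers.get(node)
        if prey is None:
            raise DietStructureError(
                f"node {node!r} appears as prey but has no diet and is not a producer"
            )
        unknown = [p for p in prey if p not in tls]
        if unknown:
            raise DietStructureError(f"prey {unknown} of {node!r} are undefined")
        tls[node] = 1.0 + sum(frac * tls[p] for p, frac in prey.items())
    return tls


@dataclass(frozen=True)
class TLRange:
    """Food-web TL span used for study-quality screening.

    ``width`` is the difference between the highest-TL fish species mean
    and the lowest-TL nonvertebrate taxon mean; ``defined`` is False
    (with ``reason``) for degenerate datasets.
    """

    defined: bool
    width: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    low_species: Optional[str] = None
    high_species: Optional[str] = None
    reason: Optional[str] = None


def tl_range(
    dataset: FoodWebDataset, assignments: Iterable[TrophicAssignment]
) -> TLRange:
    """TL range width between top fish and bottom nonvertebrate taxa.

    Species-level TLs are arithmetic means of per-sample assignments.
    """
    tl_by_id = {a.sample_id: a.tl for a in assignments}
    by_species: dict[str, list[float]] = {}
    group_by_species: dict[str, TaxonGroup] = {}
    for s in dataset.samples:
        if s.sample_id not in tl_by_id:
            continue
        by_species.setdefault(s.species, []).append(tl_by_id[s.sample_id])
        group_by_species[s.species] = s.taxon_group

    fish = {
        sp: float(np.mean(v))
        for sp, v in by_species.items()
        if group_by_species[sp] == TaxonGroup.fish
    }
    nonvert = {
        sp: float(np.mean(v))
        for sp, v in by_species.items()
        if group_by_species[sp] in NONVERTEBRATE_GROUPS
    }
    if not fish:
        return TLRange(defined=False, reason="no fish species")
    if not nonvert:
        return TLRange(defined=False, reason="no nonvertebrate taxa")
    hi_sp = max(fish, key=fish.get)
    lo_sp = min(nonvert, key=nonvert.get)
    return TLRange(
        defined=True,
        width=fish[hi_sp] - nonvert[lo_sp],
        low=nonvert[lo_sp],
        high=fish[hi_sp],
        low_species=lo_sp,
        high_species=hi_sp,
    )


def tl_range_from_d15n(
    d15n_high: float, d15n_low: float, enrichment_factor: float = DEFAULT_ENRICHMENT_FACTOR
) -> float:
    """TL range width from a δ15N spread: Δδ15N / EF."""
    if enrichment_factor <= 0:
        raise ValueError("enrichment factor must be positive")
    return (d15n_high - d15n_low) / enrichment_factor
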