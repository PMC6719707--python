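"""Core domain types for food-web bioaccumulation data.

A food-web contaminant study consists of biota samples — organisms or
pooled composites — each carrying a stable-nitrogen-isotope signature
(δ15N, used to place the organism in the food web) and a contaminant
concentration on some reporting basis (wet, dry, lipid or protein
weight).  A :class:`FoodWebDataset` bundles the samples for one site
with the baseline designation needed to turn δ15N into trophic levels.
"""

from __future__ import annotations

import enum
import warnings
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class TaxonGroup(str, enum.Enum):
    phytoplankton = "phytoplankton"
    zooplankton = "zooplankton"
    benthic_invertebrate = "benthic_invertebrate"
    mollusk = "mollusk"
    crustacean = "crustacean"
    fish = "fish"
    bird = "bird"
    mammal = "mammal"
    other = "other"


#: Taxon groups counted as endotherms (excluded from water-respiring TMFs).
ENDOTHERM_GROUPS = frozenset({TaxonGroup.bird, TaxonGroup.mammal})

#: Taxon groups counted as nonvertebrate, lower-trophic-level taxa.
NONVERTEBRATE_GROUPS = frozenset(
    {
        TaxonGroup.phytoplankton,
        TaxonGroup.zooplankton,
        TaxonGroup.benthic_invertebrate,
        TaxonGroup.mollusk,
        TaxonGroup.crustacean,
    }
)


class Tissue(str, enum.Enum):
    whole_body = "whole_body"
    muscle_fillet = "muscle_fillet"
    liver = "liver"
    plasma = "plasma"
    other = "other"


class Habitat(str, enum.Enum):
    pelagic = "pelagic"
    benthic = "benthic"
    coupled = "coupled"
    unknown = "unknown"


class Basis(str, enum.Enum):
    wet_weight = "wet_weight"
    dry_weight = "dry_weight"
    lipid_weight = "lipid_weight"
    protein_weight = "protein_weight"


class Ecosystem(str, enum.Enum):
    lake = "lake"
    river = "river"
    marine = "marine"
    estuary = "estuary"
    other = "other"


class LatitudeClass(str, enum.Enum):
    polar = "polar"
    temperate = "temperate"
    tropical = "tropical"
    unknown = "unknown"


class BiotaSample(BaseModel):
    """One measured organism or pooled composite.

    ``concentration`` is present only for detected samples; nondetects
    carry ``detection_limit`` instead (left-censored observation).
    ``endotherm`` must be consistent with ``taxon_group``: birds and
    mammals are endotherms, everything else is not.
    """

    sample_id: str
    species: str
    taxon_group: TaxonGroup
    endotherm: bool
    tissue: Tissue = Tissue.whole_body
    habitat: Habitat = Habitat.unknown
    d15n: float
    d13c: Optional[float] = None
    d34s: Optional[float] = None
    concentration: Optional[float] = None  # µg/kg on `basis`
    basis: Basis = Basis.wet_weight
    lipid_fraction: Optional[float] = None
    water_fraction: Optional[float] = None
    detected: bool = True
    detection_limit: Optional[float] = None  # µg/kg, required when not detected
    pool_size: int = Field(default=1, ge=1)
    season: Optional[str] = None
    location: Optional[str] = None

    @field_validator("lipid_fraction", "water_fraction")
    @classmethod
    def _fraction_open_interval(cls, v, info):
        if v is not None and not (0.0 < v < 1.0):
            raise ValueError(f"{info.field_name} must lie in (0, 1), got {v}")
        return v

    @model_validator(mode="after")
    def _check_invariants(self):
        if self.endotherm != (self.taxon_group in ENDOTHERM_GROUPS):
            raise ValueError(
                f"endotherm={self.endotherm} inconsistent with "
                f"taxon_group={self.taxon_group.value}"
            )
        if self.detected:
            if self.concentration is None or self.concentration <= 0:
                raise ValueError(
                    "detected samples require a positive concentration"
                )
        else:
            if self.detection_limit is None or self.detection_limit <= 0:
                raise ValueError(
                    "nondetect samples require a positive detection_limit"
                )
            if self.concentration is not None:
                raise ValueError(
                    "nondetect samples must not carry a concentration"
                )
        return self


class FoodWebDataset(BaseModel):
    """All samples from one site plus what is needed for TL assignment.

    ``baseline_species`` names the primary-consumer taxon anchoring the
    isotopic baseline (assumed trophic level ``baseline_tl``, 2.0 by
    convention); ``enrichment_factor`` is the per-TL-step δ15N increase
    (Δ15N), typically 3.4‰ for aquatic poikilotherm food webs.
    """

    samples: list[BiotaSample]
    baseline_species: str
    baseline_tl: float = 2.0
    enrichment_factor: float = 3.4  # ‰ per TL step
    ecosystem: Ecosystem = Ecosystem.other
    latitude_class: LatitudeClass = LatitudeClass.unknown
    sampling_window: Optional[str] = None

    @model_validator(mode="after")
    def _check_dataset(self):
        if not any(s.species == self.baseline_species for s in self.samples):
            raise ValueError(
                f"no sample belongs to baseline species {self.baseline_species!r}"
            )
        if not (3.0 <= self.enrichment_factor <= 5.0):
            warnings.warn(
                f"enrichment factor {self.enrichment_factor}‰ outside the "
                "typical 3.0–5.0‰ per TL step",
                stacklevel=2,
            )
        return self

    def baseline_samples(self) -> list[BiotaSample]:
        return [s for s in self.samples if s.species == self.baseline_species]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.species, None)
        return list(seen)
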