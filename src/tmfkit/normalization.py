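"""Concentration-basis conversions.

Contaminants partition into different tissue compartments: nonpolar
organics into lipid, mercury and PFOS into protein.  Comparing burdens
across a food web therefore requires expressing concentrations on a
common basis — lipid weight, dry weight, or a protein proxy — and,
where fish were sampled as muscle fillet, converting to a whole-body
equivalent.  All conversions are multiplicative, so a species-constant
factor shifts a log-regression intercept but never its slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .datamodel import Basis, BiotaSample, TaxonGroup

#: Literature default water fractions by taxon group, used when a sample
#: carries no measured water content (fish 0.74, zooplankton 0.90,
#: chironomids 0.79, other invertebrates 0.80).
DEFAULT_WATER_FRACTIONS: dict[TaxonGroup, float] = {
    TaxonGroup.fish: 0.74,
    TaxonGroup.zooplankton: 0.90,
    TaxonGroup.phytoplankton: 0.90,
    TaxonGroup.benthic_invertebrate: 0.80,
    TaxonGroup.mollusk: 0.80,
    TaxonGroup.crustacean: 0.80,
    TaxonGroup.bird: 0.70,
    TaxonGroup.mammal: 0.70,
    TaxonGroup.other: 0.80,
}

#: Default water fraction for chironomid larvae specifically, available
#: for species-level overrides of the benthic-invertebrate default.
CHIRONOMID_WATER_FRACTION = 0.79

#: Default fillet→whole-body conversion factor (literature ratios cluster
#: around 3, range roughly 2.6–4.9); whole_body = factor × fillet.
DEFAULT_FILLET_TO_WHOLE_BODY = 3.0

#: Conventional nitrogen→protein mass conversion factor.
DEFAULT_N_TO_PROTEIN = 6.25


def to_lipid_weight(c_ww: float, lipid_fraction: float) -> float:
    """Wet-weight → lipid-weight: c / lipid_fraction (µg/kg lw)."""
    if not (0.0 < lipid_fraction < 1.0):
        raise ValueError(f"lipid_fraction must lie in (0, 1), got {lipid_fraction}")
    return c_ww / lipid_fraction


def to_dry_weight(c_ww: float, water_fraction: float) -> float:
    """Wet-weight → dry-weight: c / (1 − water_fraction) (µg/kg dw)."""
    if not (0.0 <= water_fraction < 1.0):
        raise ValueError(f"water_fraction must lie in [0, 1), got {water_fraction}")
    return c_ww / (1.0 - water_fraction)


def fillet_to_whole_body(
    c_fillet: float, factor: float = DEFAULT_FILLET_TO_WHOLE_BODY
) -> float:
    """Muscle-fillet → whole-body equivalent: factor × c_fillet.

    The factor direction is whole_body = factor × fillet, i.e. factors
    above 1 mean the chemical is depleted in muscle relative to the
    whole body (the usual situation for lipophilic chemicals such as
    PBDEs, whose fillet-based TMFs would otherwise be underestimated).
    Factors are species- and chemical-specific; override per case.
    """
    if factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return factor * c_fillet


def to_protein_proxy(
    c_ww: float,
    nitrogen_fraction: float,
    n_to_protein: float = DEFAULT_N_TO_PROTEIN,
) -> float:
    """Wet-weight → protein-normalized, using %N as a protein proxy.

    Protein content is approximated as nitrogen_fraction × n_to_protein
    (6.25 is the conventional N→protein factor).
    """
    if not (0.0 < nitrogen_fraction < 1.0):
        raise ValueError(
            f"nitrogen_fraction must lie in (0, 1), got {nitrogen_fraction}"
        )
    if n_to_protein <= 0:
        raise ValueError(f"n_to_protein must be positive, got {n_to_protein}")
    return c_ww / (nitrogen_fraction * n_to_protein)


@dataclass(frozen=True)
class NormalizedConcentration:
    """A concentration on a target basis plus how it got there."""

    sample_id: str
    value: float  # µg/kg on `basis`
    basis: Basis
    provenance: dict = field(default_factory=dict)


def _water_fraction_for(
    sample: BiotaSample, water_by_taxon: Optional[Mapping[TaxonGroup, float]]
) -> float:
    if sample.water_fraction is not None:
        return sample.water_fraction
    table = water_by_taxon or DEFAULT_WATER_FRACTIONS
    return table[sample.taxon_group]


def convert_sample(
    sample: BiotaSample,
    to_basis: Basis,
    water_by_taxon: Optional[Mapping[TaxonGroup, float]] = None,
    fillet_factor: Optional[float] = None,
) -> NormalizedConcentration:
    """Express a sample's concentration (or detection limit) on ``to_basis``.

    Conversion runs through the wet-weight basis as pivot; lipid
    conversions need the sample's ``lipid_fraction``, dry-weight
    conversions fall back to :data:`DEFAULT_WATER_FRACTIONS` when the
    sample has no measured water content.  If ``fillet_factor`` is given
    and the sample is a muscle fillet, the whole-body conversion is
    applied first and flagged in the provenance.  Censored samples are
    converted on their detection limit so the censoring threshold stays
    on the analysis basis.
    """
    value = sample.concentration if sample.detected else sample.detection_limit
    provenance: dict = {"original_basis": sample.basis.value, "factors": {}}

    if fillet_factor is not None and sample.tissue.value == "muscle_fillet":
        value = fillet_to_whole_body(value, fillet_factor)
        provenance["factors"]["fillet_to_whole_body"] = fillet_factor
        provenance["converted"] = True

    if sample.basis != to_basis:
        # to wet weight
        if sample.basis == Basis.lipid_weight:
            if sample.lipid_fraction is None:
                raise ValueError(f"sample {sample.sample_id}: lipid_fraction required")
            value = value * sample.lipid_fraction
            provenance["factors"]["lipid_fraction"] = sample.lipid_fraction
        elif sample.basis == Basis.dry_weight:
            wf = _water_fraction_for(sample, water_by_taxon)
            value = value * (1.0 - wf)
            provenance["factors"]["water_fraction"] = wf
        elif sample.basis == Basis.protein_weight:
            raise ValueError(
                "protein-weight inputs need an explicit nitrogen fraction; "
                "use to_protein_proxy directly"
            )
        # from wet weight to target
        if to_basis == Basis.lipid_weight:
            if sample.lipid_fraction is None:
                raise ValueError(f"sample {sample.sample_id}: lipid_fraction required")
            value = to_lipid_weight(value, sample.lipid_fraction)
            provenance["factors"]["lipid_fraction"] = sample.lipid_fraction
        elif to_basis == Basis.dry_weight:
            wf = _water_fraction_for(sample, water_by_taxon)
            value = to_dry_weight(value, wf)
            provenance["factors"]["water_fraction"] = wf
        elif to_basis == Basis.protein_weight:
            raise ValueError(
                "protein-weight targets need an explicit nitrogen fraction; "
                "use to_protein_proxy directly"
            )

    return NormalizedConcentration(
        sample_id=sample.sample_id, value=value, basis=to_basis, provenance=provenance
    )
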