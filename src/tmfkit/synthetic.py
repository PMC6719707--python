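"""Synthetic food-web generation.

The generator emulates the structure assumed by the TMF regression: on
the lipid basis, log10 concentration is linear in trophic level with
slope log10(TMF) plus Normal residual noise.  δ15N values are
back-computed from species TLs through the isotope-baseline relation,
wet-weight concentrations follow from a configurable lipid gradient,
and left-censoring replaces the lowest observations with a detection
limit.  Every run is fully determined by its seed.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .datamodel import (
    Basis,
    BiotaSample,
    Ecosystem,
    FoodWebDataset,
    LatitudeClass,
    TaxonGroup,
    ENDOTHERM_GROUPS,
)
from .normalization import DEFAULT_WATER_FRACTIONS

LipidSpec = Union[float, Callable[[float], float], Sequence[tuple[float, float]], None]


def default_lipid_by_tl(tl: float) -> float:
    """Default lipid gradient: ~1% at TL 2 rising to ~10% at TL 4.

    Mirrors the common pattern in lake food webs (zooplankton ~0.5–2%
    lipid, top-predator fish ~5–15%), which is what makes wet-weight
    TMFs exceed lipid-normalized ones for nonpolar organics.
    """
    return float(np.clip(0.01 + 0.045 * (tl - 2.0), 0.005, 0.25))


def _lipid_function(spec: LipidSpec) -> Callable[[float], float]:
    if spec is None:
        return default_lipid_by_tl
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        const = float(spec)
        return lambda tl: const
    pairs = sorted((float(t), float(f)) for t, f in spec)
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    return lambda tl: float(np.interp(tl, xs, ys))


def _taxon_for_tl(tl: float) -> TaxonGroup:
    if tl <= 2.4:
        return TaxonGroup.zooplankton
    if tl < 3.0:
        return TaxonGroup.benthic_invertebrate
    return TaxonGroup.fish


def generate_synthetic_foodweb(
    n_species: int = 12,
    samples_per_species: Union[int, Sequence[int]] = 5,
    tl_range: tuple[float, float] = (2.0, 4.0),
    true_tmf: float = 2.0,
    resid_sd: float = 0.3,
    lipid_by_tl: LipidSpec = None,
    water_by_taxon: Optional[Mapping[TaxonGroup, float]] = None,
    censor_fraction: float = 0.0,
    seed: int = 0,
    intercept_log10: float = 1.0,
    baseline_d15n: float = 8.0,
    enrichment_factor: float = 3.4,
    species_sd: float = 0.0,
    n_endotherm_species: int = 0,
    ecosystem: Ecosystem = Ecosystem.lake,
    latitude_class: LatitudeClass = LatitudeClass.temperate,
) -> FoodWebDataset:
    """Generate a food-web dataset with known true TMF.

    Parameters
    ----------
    n_species, samples_per_species
        Species are placed at evenly spaced TLs across ``tl_range``;
        ``samples_per_species`` is either one count for all species or a
        list of per-species counts (length ``n_species``), allowing
        unbalanced designs.
    true_tmf, resid_sd, intercept_log10
        Lipid-basis concentrations satisfy
        log10(C_lipid) = intercept + log10(true_tmf)·TL + N(0, resid_sd²),
        in log10 µg/kg.
    lipid_by_tl
        Constant, callable TL→fraction, or (TL, fraction) pairs for
        interpolation; defaults to :func:`default_lipid_by_tl`.
    censor_fraction
        Detection limit set at this quantile of the *noiseless*
        wet-weight concentration distribution; observations below it
        become nondetects carrying that limit.
    species_sd
        SD of a per-species random intercept (log10 units), for
        emulating species-level departures from the food-web line.
    n_endotherm_species
        Extra bird species appended above ``tl_range`` continuing the
        same log-linear law (for endotherm-exclusion experiments).

    The lowest-TL species is the baseline species and the dataset's
    ``baseline_tl`` is ``tl_range[0]``.
    """
    if true_tmf <= 0:
        raise ValueError("true_tmf must be positive")
    lo, hi = float(tl_range[0]), float(tl_range[1])
    if not (1.0 <= lo < hi <= 6.0):
        raise ValueError("tl_range must be an increasing interval within [1, 6]")
    if not (0.0 <= censor_fraction < 1.0):
        raise ValueError("censor_fraction must lie in [0, 1)")

    if isinstance(samples_per_species, int):
        counts = [samples_per_species] * n_species
    else:
        counts = [int(c) for c in samples_per_species]
        if len(counts) != n_species:
            raise ValueError(
                f"samples_per_species has length {len(counts)}, expected {n_species}"
            )

    rng = np.random.default_rng(seed)
    lipid_fn = _lipid_function(lipid_by_tl)
    water_table = dict(DEFAULT_WATER_FRACTIONS)
    if water_by_taxon:
        water_table.update(water_by_taxon)

    species_tls = list(np.linspace(lo, hi, n_species))
    species_names = [f"species_{i + 1:02d}" for i in range(n_species)]
    taxa = [_taxon_for_tl(tl) for tl in species_tls]
    taxa[0] = TaxonGroup.zooplankton  # baseline is always a primary consumer

    if n_endotherm_species:
        step = (hi - lo) / max(n_species - 1, 1)
        mean_count = max(1, round(float(np.mean(counts))))
        for j in range(n_endotherm_species):
            species_tls.append(hi + step * (j + 1))
            species_names.append(f"bird_{j + 1:02d}")
            taxa.append(TaxonGroup.bird)
            counts.append(mean_count)

    slope = float(np.log10(true_tmf))
    baseline_tl = lo

    species_offsets = (
        rng.normal(0.0, species_sd, size=len(species_tls))
        if species_sd > 0
        else np.zeros(len(species_tls))
    )

    records: list[dict] = []
    noiseless_ww: list[float] = []
    sid = 0
    for name, tl, taxon, count, offset in zip(
        species_names, species_tls, taxa, counts, species_offsets
    ):
        lipid = lipid_fn(tl)
        if not (0.0 < lipid < 1.0):
            raise ValueError(f"lipid_by_tl returned {lipid} at TL {tl}")
        d15n = baseline_d15n + (tl - baseline_tl) * enrichment_factor
        mu = intercept_log10 + slope * tl
        for _ in range(count):
            sid += 1
            log10_clipid = mu + offset + (
                rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0
            )
            c_lipid = 10.0 ** log10_clipid
            c_ww = c_lipid * lipid
            records.append(
                {
                    "sample_id": f"S{sid:04d}",
                    "species": name,
                    "taxon_group": taxon,
                    "endotherm": taxon in ENDOTHERM_GROUPS,
                    "d15n": d15n,
                    "concentration": c_ww,
                    "lipid_fraction": lipid,
                    "water_fraction": water_table[taxon],
                    "tl": tl,
                }
            )
            noiseless_ww.append(10.0 ** mu * lipid)

    detection_limit = None
    if censor_fraction > 0:
        detection_limit = float(np.quantile(noiseless_ww, censor_fraction))

    samples: list[BiotaSample] = []
    for rec in records:
        tl = rec.pop("tl")
        if detection_limit is not None and rec["concentration"] < detection_limit:
            rec["concentration"] = None
            samples.append(
                BiotaSample(
                    **{k: v for k, v in rec.items() if v is not None},
                    basis=Basis.wet_weight,
                    detected=False,
                    detection_limit=detection_limit,
                )
            )
        else:
            samples.append(
                BiotaSample(**rec, basis=Basis.wet_weight, detected=True)
            )

    return FoodWebDataset(
        samples=samples,
        baseline_species=species_names[0],
        baseline_tl=baseline_tl,
        enrichment_factor=enrichment_factor,
        ecosystem=ecosystem,
        latitude_class=latitude_class,
    )
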