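"""Fallback models: BMF identity, BCF mass balance, steady-state food web."""

import numpy as np
import pytest
from pydantic import ValidationError

from tmfkit import (
    ChemicalProfile,
    FoodWebModelConfig,
    FoodWebNode,
    NodeKind,
    default_lake_foodweb,
    km_from_bcf,
    km_threshold_scan,
    steady_state_foodweb_tmf,
    tmf_from_bmf,
)
from tmfkit.bioaccumulation import gill_uptake_rate

DICOFOL = ChemicalProfile(
    name="dicofol", log_kow=5.02, bcf_ww=3100.0, bcf_species="carp"
)


def test_tmf_from_bmf_identity_with_provenance():
    out = tmf_from_bmf(2.5)
    assert out["tmf"] == 2.5
    assert out["provenance"] == "approximated_from_bmf"
    assert out["uncertainty"] == "fallback_tier_1"
    assert tmf_from_bmf(1.0)["tmf"] == 1.0
    with pytest.raises(ValueError):
        tmf_from_bmf(0.0)


def _fish(weight=1.0, lipid=0.05, growth=0.001):
    return FoodWebNode(
        id="fish", kind=NodeKind.fish, weight=weight, lipid_fraction=lipid,
        diet={"x": 1.0}, growth_rate=growth,
    )


def test_km_from_bcf_no_metabolism_fixed_point():
    fish = _fish()
    k1 = gill_uptake_rate(fish.weight)
    k2 = k1 / (fish.lipid_fraction * 10.0 ** DICOFOL.log_kow)
    bcf_nometab = k1 / (k2 + fish.growth_rate)
    prof = DICOFOL.model_copy(update={"bcf_ww": bcf_nometab})
    assert km_from_bcf(prof, fish) == pytest.approx(0.0, abs=1e-15)
    # halving the BCF implies k_M equal to the other loss rates
    prof2 = DICOFOL.model_copy(update={"bcf_ww": bcf_nometab / 2.0})
    assert km_from_bcf(prof2, fish) == pytest.approx(k2 + fish.growth_rate)


def test_km_from_bcf_clips_negative_with_warning():
    prof = DICOFOL.model_copy(update={"bcf_ww": 1e9})
    with pytest.warns(UserWarning, match="not identifiable"):
        assert km_from_bcf(prof, _fish()) == 0.0


def test_km_from_bcf_dicofol_order_of_magnitude():
    """Carp BCF + log Kow 5.02 put the derived biotransformation rate in
    the low 1e-3–1e-2 per day range."""
    km = km_from_bcf(DICOFOL, _fish())
    assert 1e-3 < km < 1e-2


def test_missing_bcf_routes_back():
    prof = ChemicalProfile(name="nodata", log_kow=5.0)
    with pytest.raises(ValueError, match="decision tree"):
        km_from_bcf(prof, _fish())


def test_two_node_chain_matches_hand_algebra():
    """One producer, one fish: the steady state has a closed form that the
    test recomputes from scratch."""
    algae = FoodWebNode(
        id="algae", kind=NodeKind.producer, weight=1e-9, lipid_fraction=0.01
    )
    fish = FoodWebNode(
        id="fish", kind=NodeKind.fish, weight=0.25, lipid_fraction=0.04,
        diet={"algae": 1.0}, feeding_rate=0.02, growth_rate=0.001,
    )
    cfg = FoodWebModelConfig(
        nodes=[algae, fish], water_conc=2e-3, gill_uptake_coeff=30.0,
        diet_assimilation_eff=0.7, egestion_ratio=0.25,
    )
    prof = ChemicalProfile(name="x", log_kow=5.0)
    res = steady_state_foodweb_tmf(cfg, prof, km=0.004)

    kow = 10.0**5.0
    c_algae = 2e-3 * 0.01 * kow
    k1 = 30.0 / 0.25**0.25
    k2 = k1 / (0.04 * kow)
    kd = 0.7 * 0.02
    ke = 0.25 * kd
    c_fish = (k1 * 2e-3 + kd * c_algae) / (k2 + ke + 0.001 + 0.004)
    assert res.concentrations_ww["fish"] == pytest.approx(c_fish, rel=1e-12)
    expected_tmf = 10.0 ** (np.log10(c_fish / 0.04) - np.log10(c_algae / 0.01))
    assert res.tmf == pytest.approx(expected_tmf, rel=1e-12)


def test_equilibrium_partitioning_limit_gives_tmf_one():
    """No feeding, no growth, no egestion, no metabolism: every node sits
    at lipid–water equilibrium and the TMF is exactly 1."""
    nodes = []
    for n in default_lake_foodweb().nodes:
        d = n.model_dump()
        d["feeding_rate"] = 0.0
        d["growth_rate"] = 0.0
        nodes.append(FoodWebNode(**d))
    cfg = FoodWebModelConfig(nodes=nodes, water_conc=1e-3, egestion_ratio=0.0)
    res = steady_state_foodweb_tmf(cfg, ChemicalProfile(name="x", log_kow=5.0), km=0.0)
    assert res.tmf == pytest.approx(1.0, abs=1e-9)
    vals = list(res.concentrations_lipid.values())
    assert np.allclose(vals, vals[0], rtol=1e-12)


def test_rapid_metabolism_causes_trophic_dilution():
    res = steady_state_foodweb_tmf(default_lake_foodweb(), DICOFOL, km=10.0)
    assert res.tmf < 1.0


def test_tmf_invariant_to_water_concentration():
    prof = ChemicalProfile(name="x", log_kow=5.0)
    web = default_lake_foodweb(water_conc=1e-3)
    web100 = default_lake_foodweb(water_conc=0.1)
    r1 = steady_state_foodweb_tmf(web, prof, km=0.003)
    r2 = steady_state_foodweb_tmf(web100, prof, km=0.003)
    assert r2.tmf == pytest.approx(r1.tmf, rel=1e-12)
    ratio = r2.concentrations_ww["piscivorous_fish"] / r1.concentrations_ww[
        "piscivorous_fish"
    ]
    assert ratio == pytest.approx(100.0, rel=1e-12)


def test_default_web_piscivore_sits_at_tl_4():
    res = steady_state_foodweb_tmf(default_lake_foodweb(), DICOFOL, km=0.007)
    assert res.trophic_levels["piscivorous_fish"] == 4.0
    assert res.trophic_levels["sediment"] == 1.0
    assert res.tmf < 1.0  # dicofol-band biotransformation prevents magnification


def test_dicofol_band_dilution_and_no_metabolism_magnification():
    web = default_lake_foodweb()
    assert steady_state_foodweb_tmf(web, DICOFOL, km=0.0).tmf > 1.0
    for km in (0.0062, 0.0083):
        assert steady_state_foodweb_tmf(web, DICOFOL, km=km).tmf < 1.0


def test_km_scan_monotone_with_finite_threshold():
    grid = [0.0, 0.01, 0.025, 0.05, 0.1]
    scan = km_threshold_scan(default_lake_foodweb(), DICOFOL, grid)
    tmfs = [scan.tmf_by_km[k] for k in grid]
    assert all(a >= b for a, b in zip(tmfs, tmfs[1:]))
    assert scan.threshold_km == 0.01
    assert scan.tmf_by_km[0.025] < 1.0  # ~0.025/d prevents magnification here


def test_km_scan_threshold_zero_when_already_diluting():
    web = default_lake_foodweb()
    cfg = FoodWebModelConfig(nodes=web.nodes, water_conc=1e-3, egestion_ratio=2.0)
    scan = km_threshold_scan(cfg, ChemicalProfile(name="x", log_kow=5.0), [0.0, 0.01])
    assert scan.threshold_km == 0.0


def test_km_scan_rejects_bad_grids():
    web = default_lake_foodweb()
    with pytest.raises(ValueError):
        km_threshold_scan(web, DICOFOL, [0.01, 0.0])
    with pytest.raises(ValueError):
        km_threshold_scan(web, DICOFOL, [-0.1, 0.0])


@pytest.mark.parametrize(
    "mutate",
    [
        lambda n: {**n, "diet": {"forage_fish": 0.6}},  # sum != 1
        lambda n: {**n, "diet": {"kraken": 1.0}},  # unknown prey
        lambda n: {**n, "diet": {}},  # consumer without a diet
    ],
)
def test_config_structure_validation(mutate):
    web = default_lake_foodweb()
    nodes = [n.model_dump() for n in web.nodes]
    pisc = next(n for n in nodes if n["id"] == "piscivorous_fish")
    nodes[nodes.index(pisc)] = mutate(pisc)
    with pytest.raises(ValidationError):
        FoodWebModelConfig(nodes=nodes, water_conc=1e-3)


def test_cycle_detected_at_solve_time():
    """Mutual predation passes per-node checks but must fail the solve."""
    a = FoodWebNode(id="a", kind=NodeKind.fish, weight=1.0, lipid_fraction=0.05,
                    diet={"b": 1.0}, feeding_rate=0.01)
    b = FoodWebNode(id="b", kind=NodeKind.fish, weight=1.0, lipid_fraction=0.05,
                    diet={"a": 1.0}, feeding_rate=0.01)
    cfg = FoodWebModelConfig(nodes=[a, b], water_conc=1e-3)
    with pytest.raises(Exception, match="cyclic"):
        steady_state_foodweb_tmf(cfg, DICOFOL)


def test_log_kow_sanity_warning():
    with pytest.warns(UserWarning, match="Kow"):
        ChemicalProfile(name="odd", log_kow=12.0)
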