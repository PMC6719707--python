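"""Study screening criteria, similarity tiering, and the selection tree."""

import pytest

from tmfkit import (
    Action,
    BMFRecord,
    ChemicalClass,
    CriteriaThresholds,
    DietLinkageEvidence,
    Ecosystem,
    Fallback,
    LatitudeClass,
    Overall,
    SiteContext,
    StudyRecord,
    Tier,
    Tissue,
    Verdict,
    balance_index,
    evaluate_study,
    generate_synthetic_foodweb,
    select_tmf,
    tier_match,
)
from tmfkit.bioaccumulation import ChemicalProfile
from tmfkit.quality import CRITERIA


def make_record(**overrides) -> StudyRecord:
    """A study satisfying every design criterion, for perturbation."""
    base = dict(
        study_id="study-A",
        chemical="PCB153",
        tmf=2.0,
        ecosystem=Ecosystem.lake,
        latitude_class=LatitudeClass.temperate,
        species_list=["Salvelinus namaycush", "Mysis relicta"],
        tissue=Tissue.whole_body,
        basis="lipid_weight",
        tl_range_width=2.2,
        n_obs=60,
        n_nonvertebrate_taxa=4,
        balance_index=0.35,
        diet_linkage_evidence=DietLinkageEvidence.gut_contents,
        same_habitat=True,
        baseline_used=True,
        censored_fraction=0.0,
        single_season=True,
        includes_endotherms=False,
    )
    base.update(overrides)
    return StudyRecord(**base)


LAKE_SITE = SiteContext(
    ecosystem=Ecosystem.lake,
    latitude_class=LatitudeClass.temperate,
    target_species="Salvelinus namaycush",
    chemical="PCB153",
)


def test_perfect_study_meets_criteria():
    rep = evaluate_study(make_record())
    assert rep.overall == Overall.meets_criteria
    assert rep.deficiency_actions == []
    assert set(rep.verdicts) == set(CRITERIA)
    assert all(v == Verdict.passed for v in rep.verdicts.values())


def test_heavy_censoring_fails_detection_criterion():
    rep = evaluate_study(make_record(censored_fraction=0.70))
    assert rep.verdicts["detection_limits"] == Verdict.failed
    assert Action.expert_judgment_censoring in rep.deficiency_actions
    assert rep.overall == Overall.expert_judgment_required


def test_unlinked_organisms_terminate_evaluation():
    rep = evaluate_study(
        make_record(diet_linkage_evidence=DietLinkageEvidence.none, same_habitat=False)
    )
    assert rep.overall == Overall.reject
    assert rep.deficiency_actions == [Action.do_not_proceed]


def test_endotherms_trigger_recalculation():
    rep = evaluate_study(make_record(includes_endotherms=True))
    assert rep.verdicts["no_endotherms"] == Verdict.failed
    assert rep.deficiency_actions == [Action.recalc_excluding_endotherms]
    assert rep.overall == Overall.usable_after_recalc


def test_unbalanced_design_routes_to_mixed_model():
    rep = evaluate_study(make_record(balance_index=0.55))
    assert Action.recalc_mixed_model in rep.deficiency_actions
    assert rep.overall == Overall.usable_after_recalc


def test_fillet_tissue_asks_for_conversion():
    rep = evaluate_study(make_record(tissue=Tissue.muscle_fillet))
    assert Action.convert_fillet in rep.deficiency_actions
    th = CriteriaThresholds(fillet_conversion_possible=False)
    rep2 = evaluate_study(make_record(tissue=Tissue.muscle_fillet), th)
    assert Action.lipid_normalize_fillet in rep2.deficiency_actions


def test_small_tl_range_and_few_taxa_need_expert_judgment():
    rep = evaluate_study(make_record(tl_range_width=1.5, n_nonvertebrate_taxa=1))
    assert Action.expert_judgment_tl_range in rep.deficiency_actions
    assert Action.expert_judgment_low_taxa in rep.deficiency_actions
    assert rep.overall == Overall.expert_judgment_required


def test_unknown_fields_never_pass_silently():
    rep = evaluate_study(make_record(single_season=None, tl_range_width=None))
    assert rep.verdicts["single_season"] == Verdict.unknown
    assert rep.verdicts["tl_range"] == Verdict.unknown
    assert rep.overall != Overall.meets_criteria


def test_balance_index_from_dataset():
    ds = generate_synthetic_foodweb(
        n_species=10, samples_per_species=[3] * 9 + [27], seed=0
    )
    assert balance_index(ds) >= 0.5
    assert balance_index(make_record(balance_index=0.4)) == 0.4


@pytest.mark.parametrize(
    "overrides,expected",
    [
        ({}, Tier.similar_ecosystem_and_species),
        ({"species_list": ["Esox lucius"]}, Tier.similar_ecosystem),
        ({"ecosystem": Ecosystem.river, "species_list": ["Esox lucius"]}, Tier.other),
        ({"ecosystem": Ecosystem.marine}, Tier.similar_species),
        ({"system_id": "paguchi"}, Tier.similar_ecosystem_and_species),
    ],
)
def test_tier_match_rule_table(overrides, expected):
    assert tier_match(make_record(**overrides), LAKE_SITE) == expected


def test_same_system_outranks_everything():
    site = LAKE_SITE.model_copy(update={"system_id": "paguchi"})
    assert tier_match(make_record(system_id="paguchi"), site) == Tier.same_system


def test_genus_level_species_overlap():
    rec = make_record(species_list=["Salvelinus alpinus"])
    assert tier_match(rec, LAKE_SITE) in (
        Tier.similar_ecosystem_and_species,
    )


# ---- selection tree ------------------------------------------------------


def test_pooling_by_geometric_mean():
    a = make_record(study_id="A", tmf=2.0)
    b = make_record(study_id="B", tmf=8.0)
    out = select_tmf([a, b], LAKE_SITE)
    assert out.selected_tmf == pytest.approx(4.0)
    assert sorted(out.pooled_from) == ["A", "B"]
    assert out.fallback == Fallback.none


def test_bcf_fallback_for_data_poor_chemical():
    profile = ChemicalProfile(name="dicofol", log_kow=5.02, bcf_ww=3100.0)
    out = select_tmf([], LAKE_SITE, profile=profile)
    assert out.selected_tmf is None
    assert out.fallback == Fallback.use_bcf_model
    assert any("fallback" in step for step in out.decision_path)


def test_trophic_dilution_flags_tmf_use_as_not_advisable():
    site = LAKE_SITE.model_copy(
        update={"chemical": "total PAH",
                "chemical_class": ChemicalClass.readily_metabolized}
    )
    studies = [
        make_record(study_id="W1", chemical="total PAH", tmf=0.30),
        make_record(study_id="W2", chemical="total PAH", tmf=0.24),
    ]
    out = select_tmf(studies, site)
    assert out.fallback == Fallback.not_advisable_trophic_dilution
    assert out.selected_tmf is None
    assert any("bivalves" in n for n in out.notes)


def test_decision_path_is_deterministic():
    a = make_record(study_id="A", tmf=2.0)
    b = make_record(study_id="B", tmf=8.0)
    first = select_tmf([a, b], LAKE_SITE)
    second = select_tmf([b, a], LAKE_SITE)  # order must not matter
    assert first.decision_path == second.decision_path
    assert first.selected_tmf == second.selected_tmf


def test_failing_study_never_changes_selection():
    good = make_record(study_id="A", tmf=2.0)
    bad = make_record(
        study_id="Z", tmf=50.0,
        diet_linkage_evidence=DietLinkageEvidence.none, same_habitat=False,
    )
    assert (
        select_tmf([good], LAKE_SITE).selected_tmf
        == select_tmf([good, bad], LAKE_SITE).selected_tmf
    )
    assert select_tmf([good, bad], LAKE_SITE).reports["Z"].overall == Overall.reject


def test_better_tier_restricts_the_pool():
    local = make_record(study_id="L", tmf=2.0)
    remote = make_record(
        study_id="R", tmf=16.0, ecosystem=Ecosystem.river, species_list=["Esox lucius"]
    )
    out = select_tmf([local, remote], LAKE_SITE)
    assert out.pooled_from == ["L"] and out.selected_tmf == pytest.approx(2.0)
    assert out.tier == Tier.similar_ecosystem_and_species


def test_bmf_fallback_prefers_species_of_interest():
    bmfs = [
        BMFRecord(species="Esox lucius", bmf=5.0),
        BMFRecord(species="Salvelinus namaycush", bmf=2.5),
    ]
    out = select_tmf([], LAKE_SITE, bmf_records=bmfs)
    assert out.fallback == Fallback.use_bmf
    assert out.selected_tmf == 2.5  # species of interest beats any fish


def test_slope_only_record_converts_to_tmf():
    rec = make_record(tmf=None, slope=0.3)
    out = select_tmf([rec], LAKE_SITE)
    assert out.selected_tmf == pytest.approx(10**0.3)


def test_no_data_at_all_gives_no_recommendation():
    out = select_tmf([], LAKE_SITE)
    assert out.selected_tmf is None and out.fallback == Fallback.none
    assert any("no recommendation" in step for step in out.decision_path)
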