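"""Study quality screening and TMF selection.

Published TMF studies vary widely in design quality, and a TMF applied
to regulatory monitoring data should come from a study that actually
characterizes trophic transfer at a comparable site.  This module
encodes that screening as an auditable rules engine:

* ``evaluate_study`` scores a study record against eleven design
  criteria (TL range, tissues, normalization, taxa coverage, balance,
  diet linkage, habitat, isotope baseline, detection limits, season,
  endotherms) and maps deficiencies to remediation actions.
* ``tier_match`` ranks a study's similarity to the site of interest
  (ecosystem and species overlap).
* ``select_tmf`` walks the full decision tree: filter candidates, keep
  the best similarity tier, pool by geometric mean, and — when nothing
  qualifies — fall back through BMF ≈ TMF, BCF-derived mass-balance
  modelling, and estimated-biotransformation modelling, recording every
  node visited so the decision can be audited.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .datamodel import Basis, Ecosystem, LatitudeClass, Tissue
from .regression import geometric_mean_tmf, tl_balance_index, tmf_from_slope, LogBase
from .trophic import TrophicAssignment
from .datamodel import FoodWebDataset


class DietLinkageEvidence(str, enum.Enum):
    gut_contents = "gut_contents"
    d13c = "d13c"
    d34s = "d34s"
    none = "none"


class ChemicalClass(str, enum.Enum):
    lipophilic = "lipophilic"
    protein_associated = "protein_associated"
    readily_metabolized = "readily_metabolized"


class Verdict(str, enum.Enum):
    passed = "pass"
    failed = "fail"
    unknown = "unknown"


class Action(str, enum.Enum):
    convert_fillet = "convert_fillet"
    lipid_normalize_fillet = "lipid_normalize_fillet"
    do_not_proceed = "do_not_proceed"
    expert_judgment_tl_range = "expert_judgment_tl_range"
    expert_judgment_low_taxa = "expert_judgment_low_taxa"
    recalc_excluding_endotherms = "recalc_excluding_endotherms"
    recalc_mixed_model = "recalc_mixed_model"
    expert_judgment_censoring = "expert_judgment_censoring"


class Overall(str, enum.Enum):
    meets_criteria = "meets_criteria"
    usable_after_recalc = "usable_after_recalc"
    expert_judgment_required = "expert_judgment_required"
    reject = "reject"


class Tier(str, enum.Enum):
    same_system = "same_system"
    similar_ecosystem_and_species = "similar_ecosystem_and_species"
    similar_ecosystem = "similar_ecosystem"
    similar_species = "similar_species"
    other = "other"


#: Preference order for study similarity (best first).
TIER_ORDER = [
    Tier.same_system,
    Tier.similar_ecosystem_and_species,
    Tier.similar_ecosystem,
    Tier.similar_species,
    Tier.other,
]


class Fallback(str, enum.Enum):
    none = "none"
    use_bmf = "use_bmf"
    use_bcf_model = "use_bcf_model"
    use_estimated_km_model = "use_estimated_km_model"
    not_advisable_trophic_dilution = "not_advisable_trophic_dilution"


#: Names of the eleven study-design criteria, in reporting order.
CRITERIA = [
    "tl_range",
    "whole_body_tissue",
    "normalization",
    "nonvertebrate_taxa",
    "sample_balance",
    "diet_linkage",
    "same_habitat",
    "isotope_baseline",
    "detection_limits",
    "single_season",
    "no_endotherms",
]


class StudyRecord(BaseModel):
    """Curated metadata of one published TMF study."""

    study_id: str
    chemical: str
    tmf: Optional[float] = Field(default=None, gt=0)
    slope: Optional[float] = None
    log_base: LogBase = LogBase.log10
    slope_se: Optional[float] = None
    ecosystem: Ecosystem = Ecosystem.other
    latitude_class: LatitudeClass = LatitudeClass.unknown
    system_id: Optional[str] = None  # for same-system identification
    species_list: list[str] = Field(default_factory=list)
    tissue: Tissue = Tissue.whole_body
    basis: Basis = Basis.lipid_weight
    tl_range_width: Optional[float] = None
    n_obs: Optional[int] = None
    n_nonvertebrate_taxa: Optional[int] = None
    balance_index: Optional[float] = None
    diet_linkage_evidence: Optional[DietLinkageEvidence] = None
    same_habitat: Optional[bool] = None
    baseline_used: Optional[bool] = None
    censored_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    single_season: Optional[bool] = None
    includes_endotherms: Optional[bool] = None

    def effective_tmf(self) -> Optional[float]:
        if self.tmf is not None:
            return self.tmf
        if self.slope is not None:
            return tmf_from_slope(self.slope, self.log_base)
        return None


class SiteContext(BaseModel):
    """The monitoring site and chemical a TMF is being selected for."""

    ecosystem: Ecosystem
    latitude_class: LatitudeClass = LatitudeClass.unknown
    system_id: Optional[str] = None
    target_species: Optional[str] = None
    target_tl: Optional[float] = None  # defaults: 4 freshwater, 5 marine
    chemical: str = ""
    chemical_class: Optional[ChemicalClass] = None

    def resolved_target_tl(self) -> float:
        if self.target_tl is not None:
            return self.target_tl
        return 5.0 if self.ecosystem == Ecosystem.marine else 4.0


class CriteriaThresholds(BaseModel):
    """Configurable numeric cut-offs for the study criteria."""

    min_tl_range: float = 2.0
    min_nonvertebrate_taxa: int = 3  # "several" lower-TL taxa
    balance_flag: float = 0.5  # share of samples in one TL bin
    censor_warn: float = 0.2
    censor_fail: float = 0.5
    fillet_conversion_possible: bool = True
    chemical_is_nonionic_organic: bool = True


@dataclass
class QualityReport:
    verdicts: dict[str, Verdict]
    deficiency_actions: list[Action]
    overall: Overall
    notes: list[str] = field(default_factory=list)


def balance_index(
    source: "StudyRecord | FoodWebDataset",
    assignments: Optional[Iterable[TrophicAssignment]] = None,
) -> float:
    """Largest unit-TL-bin sample share, from a record or a dataset."""
    if isinstance(source, StudyRecord):
        if source.balance_index is None:
            raise ValueError(f"study {source.study_id} carries no balance index")
        return source.balance_index
    if assignments is None:
        from .trophic import assign_trophic_levels

        assignments = assign_trophic_levels(source)
    return tl_balance_index([a.tl for a in assignments])


def _score(condition: Optional[bool]) -> Verdict:
    if condition is None:
        return Verdict.unknown
    return Verdict.passed if condition else Verdict.failed


def evaluate_study(
    record: StudyRecord, thresholds: Optional[CriteriaThresholds] = None
) -> QualityReport:
    """Score a study against the design criteria and derive actions.

    Unknown fields yield ``unknown`` verdicts, never silent passes.
    Failing diet linkage or habitat is terminal (the organisms are not
    one food chain — do not proceed); other deficiencies map to
    recalculation or expert-judgment actions.
    """
    th = thresholds or CriteriaThresholds()
    v: dict[str, Verdict] = {}
    actions: list[Action] = []
    notes: list[str] = []

    v["tl_range"] = _score(
        None if record.tl_range_width is None
        else record.tl_range_width >= th.min_tl_range
    )
    v["whole_body_tissue"] = _score(record.tissue == Tissue.whole_body)
    v["normalization"] = _score(record.basis != Basis.wet_weight)
    v["nonvertebrate_taxa"] = _score(
        None if record.n_nonvertebrate_taxa is None
        else record.n_nonvertebrate_taxa >= th.min_nonvertebrate_taxa
    )
    v["sample_balance"] = _score(
        None if record.balance_index is None
        else record.balance_index <= th.balance_flag
    )
    v["diet_linkage"] = _score(
        None if record.diet_linkage_evidence is None
        else record.diet_linkage_evidence != DietLinkageEvidence.none
    )
    v["same_habitat"] = _score(record.same_habitat)
    v["isotope_baseline"] = _score(record.baseline_used)
    if record.censored_fraction is None:
        v["detection_limits"] = Verdict.unknown
    else:
        v["detection_limits"] = (
            Verdict.passed
            if record.censored_fraction <= th.censor_warn
            else Verdict.failed
        )
        if record.censored_fraction > th.censor_fail:
            notes.append(
                f"censored fraction {record.censored_fraction:.0%} exceeds "
                f"{th.censor_fail:.0%}: high uncertainty"
            )
    v["single_season"] = _score(record.single_season)
    v["no_endotherms"] = _score(
        None if record.includes_endotherms is None else not record.includes_endotherms
    )

    # terminal failure: not one food chain
    if v["diet_linkage"] == Verdict.failed or v["same_habitat"] == Verdict.failed:
        actions.append(Action.do_not_proceed)
        return QualityReport(v, actions, Overall.reject, notes)

    if v["whole_body_tissue"] == Verdict.failed and record.tissue == Tissue.muscle_fillet:
        if th.fillet_conversion_possible:
            actions.append(Action.convert_fillet)
        elif th.chemical_is_nonionic_organic:
            actions.append(Action.lipid_normalize_fillet)
        else:
            notes.append("fillet data cannot be converted or lipid-normalized")
    if v["tl_range"] == Verdict.failed:
        actions.append(Action.expert_judgment_tl_range)
    if v["nonvertebrate_taxa"] == Verdict.failed:
        actions.append(Action.expert_judgment_low_taxa)
    if v["no_endotherms"] == Verdict.failed:
        actions.append(Action.recalc_excluding_endotherms)
    if v["sample_balance"] == Verdict.failed:
        actions.append(Action.recalc_mixed_model)
    if v["detection_limits"] == Verdict.failed:
        actions.append(Action.expert_judgment_censoring)

    if all(verdict == Verdict.passed for verdict in v.values()):
        overall = Overall.meets_criteria
    elif any(a.value.startswith("expert_judgment") for a in actions):
        overall = Overall.expert_judgment_required
    elif actions and all(
        a in (Action.recalc_excluding_endotherms, Action.recalc_mixed_model,
              Action.convert_fillet, Action.lipid_normalize_fillet)
        for a in actions
    ):
        overall = Overall.usable_after_recalc
    else:
        # unknown verdicts or unfixable deficiencies without a mapped action
        overall = Overall.expert_judgment_required
    return QualityReport(v, actions, overall, notes)


def _genus(name: str) -> str:
    return name.strip().split()[0].lower() if name.strip() else ""


def tier_match(record: StudyRecord, site: SiteContext) -> Tier:
    """Similarity tier of a study for a site (deterministic rule table)."""
    if (
        record.system_id is not None
        and site.system_id is not None
        and record.system_id == site.system_id
    ):
        return Tier.same_system
    eco = (
        record.ecosystem == site.ecosystem
        and record.latitude_class == site.latitude_class
        and record.latitude_class != LatitudeClass.unknown
    )
    species = False
    if site.target_species:
        target = site.target_species.strip().lower()
        names = [s.strip().lower() for s in record.species_list]
        species = target in names or _genus(site.target_species) in {
            _genus(s) for s in record.species_list
        }
    if eco and species:
        return Tier.similar_ecosystem_and_species
    if eco:
        return Tier.similar_ecosystem
    if species:
        return Tier.similar_species
    return Tier.other


class BMFRecord(BaseModel):
    """A biomagnification factor for one predator–prey TL step."""

    species: str
    bmf: float = Field(gt=0)
    is_fish: bool = True
    tl_step: float = 1.0


@dataclass
class SelectionOutcome:
    selected_tmf: Optional[float]
    pooled_from: list[str]
    decision_path: list[str]
    fallback: Fallback
    tier: Optional[Tier] = None
    reports: dict[str, QualityReport] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_tmf": self.selected_tmf,
            "pooled_from": self.pooled_from,
            "decision_path": self.decision_path,
            "fallback": self.fallback.value,
            "tier": self.tier.value if self.tier else None,
            "reports": {
                k: {
                    "verdicts": {c: r.verdicts[c].value for c in r.verdicts},
                    "actions": [a.value for a in r.deficiency_actions],
                    "overall": r.overall.value,
                }
                for k, r in self.reports.items()
            },
            "notes": self.notes,
        }


def select_tmf(
    candidates: Sequence[StudyRecord],
    site: SiteContext,
    thresholds: Optional[CriteriaThresholds] = None,
    profile=None,
    bmf_records: Optional[Sequence[BMFRecord]] = None,
) -> SelectionOutcome:
    """Walk the TMF selection decision tree for one chemical and site.

    Qualifying studies (meets criteria or usable after recalculation)
    are restricted to the best available similarity tier and pooled by
    geometric mean.  For readily metabolized chemicals whose pooled TMF
    is below 1 (trophic dilution), TL adjustment of monitoring data is
    flagged as not advisable and compliance in lower-TL taxa (bivalves,
    crustaceans) is recommended instead.  With no qualifying study, the
    fallback chain is: BMF for the species of interest, BMF for a
    similar species, BMF for any fish, then BCF-derived mass-balance
    modelling, then modelling with an estimated biotransformation rate
    (``profile`` is a :class:`~tmfkit.bioaccumulation.ChemicalProfile`
    supplying BCF / k_M availability).
    """
    th = thresholds or CriteriaThresholds()
    path: list[str] = [f"chemical={site.chemical or 'unspecified'}"]
    reports: dict[str, QualityReport] = {}
    notes: list[str] = []

    path.append(f"screen:evaluate {len(candidates)} candidate stud(ies)")
    qualifying: list[StudyRecord] = []
    for rec in sorted(candidates, key=lambda r: r.study_id):
        rep = evaluate_study(rec, th)
        reports[rec.study_id] = rep
        path.append(f"screen:{rec.study_id}:{rep.overall.value}")
        if rep.overall in (Overall.meets_criteria, Overall.usable_after_recalc):
            if rec.effective_tmf() is None:
                path.append(f"screen:{rec.study_id}:no TMF value, excluded")
            else:
                qualifying.append(rec)

    if qualifying:
        tiers = {rec.study_id: tier_match(rec, site) for rec in qualifying}
        best = min(
            (tiers[r.study_id] for r in qualifying), key=TIER_ORDER.index
        )
        pool = [r for r in qualifying if tiers[r.study_id] == best]
        path.append(f"tier:best={best.value} ({len(pool)} study/ies)")
        pooled = geometric_mean_tmf([r.effective_tmf() for r in pool])
        path.append(f"pool:geometric_mean={pooled:.6g}")
        if (
            site.chemical_class == ChemicalClass.readily_metabolized
            and pooled < 1.0
        ):
            path.append("pool:trophic_dilution:TL-adjustment not advisable")
            notes.append(
                "readily metabolized chemical with pooled TMF < 1 (trophic "
                "dilution): do not adjust monitoring data by TMF; apply the "
                "EQS in lower-TL taxa such as bivalves and crustaceans"
            )
            return SelectionOutcome(
                selected_tmf=None,
                pooled_from=[r.study_id for r in pool],
                decision_path=path,
                fallback=Fallback.not_advisable_trophic_dilution,
                tier=best,
                reports=reports,
                notes=notes,
            )
        return SelectionOutcome(
            selected_tmf=pooled,
            pooled_from=[r.study_id for r in pool],
            decision_path=path,
            fallback=Fallback.none,
            tier=best,
            reports=reports,
            notes=notes,
        )

    # Section 5 fallback chain
    path.append("fallback:no qualifying TMF study")
    bmfs = list(bmf_records or [])
    if profile is not None and getattr(profile, "bmf", None):
        bmfs.append(
            BMFRecord(species=getattr(profile, "bmf_species", "") or "unspecified",
                      bmf=profile.bmf)
        )
    if bmfs:
        target = (site.target_species or "").strip().lower()
        chosen = None
        if target:
            exact = [b for b in bmfs if b.species.strip().lower() == target]
            similar = [
                b for b in bmfs if _genus(b.species) == _genus(site.target_species)
            ]
            if exact:
                chosen, label = exact[0], "species_of_interest"
            elif similar:
                chosen, label = similar[0], "similar_species"
        if chosen is None:
            any_fish = [b for b in bmfs if b.is_fish]
            if any_fish:
                chosen, label = any_fish[0], "any_fish"
        if chosen is not None:
            path.append(f"fallback:bmf:{label}:{chosen.species}")
            notes.append(
                f"TMF approximated by BMF={chosen.bmf} ({label}); BMF must "
                "reflect one TL step (fallback_tier_1)"
            )
            return SelectionOutcome(
                selected_tmf=chosen.bmf,
                pooled_from=[],
                decision_path=path,
                fallback=Fallback.use_bmf,
                reports=reports,
                notes=notes,
            )
    path.append("fallback:no usable BMF")
    if profile is not None and getattr(profile, "bcf_ww", None):
        path.append("fallback:bcf_available:derive k_M and model the food web")
        notes.append(
            "derive the biotransformation rate from the BCF by fish mass "
            "balance, then estimate the TMF with a steady-state food-web model"
        )
        return SelectionOutcome(
            selected_tmf=None,
            pooled_from=[],
            decision_path=path,
            fallback=Fallback.use_bcf_model,
            reports=reports,
            notes=notes,
        )
    path.append("fallback:no BCF")
    if profile is not None and getattr(profile, "km", None) is not None:
        path.append("fallback:estimated k_M available:model the food web")
        return SelectionOutcome(
            selected_tmf=None,
            pooled_from=[],
            decision_path=path,
            fallback=Fallback.use_estimated_km_model,
            reports=reports,
            notes=notes,
        )
    path.append("fallback:no bioaccumulation data: no recommendation")
    notes.append("no TMF, BMF, BCF, or biotransformation estimate available")
    return SelectionOutcome(
        selected_tmf=None,
        pooled_from=[],
        decision_path=path,
        fallback=Fallback.none,
        reports=reports,
        notes=notes,
    )
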