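"""Response classification: RECIST 1.1, mRECIST, and AFP-composite criteria.

The composite rules layer a serum alpha-fetoprotein (AFP) condition onto a
base imaging criterion.  Two AFP components exist — the fractional change
AFP_delta = (AFP_fu - AFP_bl)/AFP_bl against a decrease cutoff (default
-0.76, i.e. a >=76% drop), and the baseline level against an absolute cutoff
(default 54.4 ng/ml) — each combinable with the base responder flag by OR or
AND.  ``alpha-RECIST`` names the OR combination of RECIST 1.1 with the AFP
change rule, the variant selected for its survival separation.

Composites are binary responder/non-responder rules on top of the base
category: base PD (new lesions or progression) vetoes response; responders
are labeled PR (CR is preserved when the base criterion itself reached CR
and, for AND combinations, the AFP condition also holds); non-responders
are labeled SD.  A patient whose AFP is missing is *non-evaluable* under an
AFP composite (returned as ``None``), never silently SD.

All thresholds are inclusive and compared on exact fractions; percentages
are a display convention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import pandas as pd

from .cohort import (
    Cohort,
    LesionMeasurement,
    NontargetStatus,
    PatientRecord,
    Timepoint,
    TARGET_MIN_DIAMETER_MM,
    MAX_TARGETS_PER_ORGAN,
    MAX_TARGETS_TOTAL,
)

__all__ = [
    "ResponseCategory",
    "CriterionSpec",
    "ChangeSummary",
    "CRITERIA",
    "resolve_criterion",
    "select_target_lesions",
    "summarize_changes",
    "afp_delta",
    "classify_recist11",
    "classify_mrecist",
    "classify_composite",
    "classify",
    "evaluate_cohort",
    "category_counts",
    "NoTargetLesionError",
]

NON_EVALUABLE = "NE"  # table rendering of a missing-AFP composite outcome


class NoTargetLesionError(ValueError):
    """No baseline lesion is eligible as a target lesion."""


class ResponseCategory(IntEnum):
    """Ordered response categories; the order backs agreement weighting."""

    CR = 0
    PR = 1
    SD = 2
    PD = 3

    @property
    def responder(self) -> bool:
        """CR or PR."""
        return self in (ResponseCategory.CR, ResponseCategory.PR)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class CriterionSpec:
    """A named response rule: base imaging criterion + optional AFP component.

    ``afp_delta_cutoff`` is a signed fraction (-0.76 means a 76% decrease
    qualifies); ``afp_bl_cutoff`` is in ng/ml; size cutoffs are signed
    fractions of the baseline (PR) / nadir (PD) sum of diameters, with
    ``pd_abs_mm`` the additional absolute-growth requirement of RECIST 1.1.
    """

    name: str
    base: str  # "RECIST11" | "mRECIST"
    afp_component: str = "none"  # "none" | "delta" | "baseline"
    combiner: str = "none"  # "none" | "or" | "and"
    afp_delta_cutoff: float = -0.76
    afp_bl_cutoff: float = 54.4
    size_pr_cutoff: float = -0.30
    size_pd_cutoff: float = 0.20
    pd_abs_mm: float = 5.0

    def __post_init__(self):
        if self.base not in ("RECIST11", "mRECIST"):
            raise ValueError(f"unknown base criterion {self.base!r}")
        if self.afp_component not in ("none", "delta", "baseline"):
            raise ValueError(f"unknown afp_component {self.afp_component!r}")
        if (self.afp_component == "none") != (self.combiner == "none"):
            raise ValueError("afp_component and combiner must both be set or both none")
        if not (self.size_pr_cutoff < 0.0 < self.size_pd_cutoff):
            raise ValueError("size_pr_cutoff must be negative and size_pd_cutoff positive")


def _registry() -> dict[str, CriterionSpec]:
    specs = [
        CriterionSpec("RECIST11", "RECIST11"),
        CriterionSpec("mRECIST", "mRECIST"),
    ]
    for base in ("RECIST11", "mRECIST"):
        suffix = "RECIST" if base == "RECIST11" else "mRECIST"
        specs.append(CriterionSpec(f"αΔ-{suffix}", base, "delta", "or"))
        specs.append(CriterionSpec(f"α&Δ-{suffix}", base, "delta", "and"))
        specs.append(CriterionSpec(f"αBL-{suffix}", base, "baseline", "or"))
        specs.append(CriterionSpec(f"α&BL-{suffix}", base, "baseline", "and"))
    return {s.name: s for s in specs}


#: The ten named criteria, keyed by their canonical (Greek-letter) names.
CRITERIA: dict[str, CriterionSpec] = _registry()

#: ASCII aliases accepted anywhere a criterion name is taken.
ALIASES: dict[str, str] = {
    "recist": "RECIST11",
    "recist11": "RECIST11",
    "recist-1.1": "RECIST11",
    "mrecist": "mRECIST",
    "alpha-recist": "αΔ-RECIST",  # the selected criterion
    "alpha-delta-recist": "αΔ-RECIST",
    "alpha-delta-mrecist": "αΔ-mRECIST",
    "alpha-and-delta-recist": "α&Δ-RECIST",
    "alpha-and-delta-mrecist": "α&Δ-mRECIST",
    "alpha-bl-recist": "αBL-RECIST",
    "alpha-bl-mrecist": "αBL-mRECIST",
    "alpha-and-bl-recist": "α&BL-RECIST",
    "alpha-and-bl-mrecist": "α&BL-mRECIST",
}


def resolve_criterion(name: str) -> CriterionSpec:
    """Look up a criterion by canonical name or ASCII alias."""
    if name in CRITERIA:
        return CRITERIA[name]
    key = name.strip().lower()
    if key in ALIASES:
        return CRITERIA[ALIASES[key]]
    for canon in CRITERIA:
        if key == canon.lower():
            return CRITERIA[canon]
    raise KeyError(
        f"unknown criterion {name!r}; known: {sorted(CRITERIA)} "
        f"or aliases {sorted(ALIASES)}"
    )


@dataclass(frozen=True)
class ChangeSummary:
    """Per-patient sums of diameters and their fractional changes."""

    sld_bl: float
    sld_fu: float
    sld_change: float
    viable_sld_bl: float
    viable_sld_fu: float
    viable_change: Optional[float]
    afp_delta: Optional[float]


def select_target_lesions(lesions: list[LesionMeasurement]) -> list[str]:
    """Choose target lesions from the baseline measurements.

    Eligible lesions have baseline longest diameter >= 10 mm; the largest
    are kept, at most two per organ and five overall.  Deterministic:
    ties broken by organ then lesion id.
    """
    eligible = [
        l
        for l in lesions
        if l.timepoint is Timepoint.BASELINE
        and l.longest_diameter >= TARGET_MIN_DIAMETER_MM
    ]
    if not eligible:
        raise NoTargetLesionError(
            f"no baseline lesion reaches the {TARGET_MIN_DIAMETER_MM:g} mm "
            "target-lesion limit"
        )
    eligible.sort(key=lambda l: (-l.longest_diameter, l.organ, l.lesion_id))
    chosen: list[str] = []
    per_organ: dict[str, int] = {}
    for les in eligible:
        if len(chosen) >= MAX_TARGETS_TOTAL:
            break
        if per_organ.get(les.organ, 0) >= MAX_TARGETS_PER_ORGAN:
            continue
        chosen.append(les.lesion_id)
        per_organ[les.organ] = per_organ.get(les.organ, 0) + 1
    return chosen


def afp_delta(afp) -> float:
    """Fractional AFP change (afp_fu - afp_bl) / afp_bl."""
    if afp.afp_bl <= 0:
        raise ValueError("afp_bl must be positive to form the AFP change ratio")
    return (afp.afp_fu - afp.afp_bl) / afp.afp_bl


def summarize_changes(record: PatientRecord) -> ChangeSummary:
    """Sum target-lesion diameters at baseline/follow-up and derive changes.

    Target lesions are the ones flagged ``is_target`` at baseline (the
    cohort validator guarantees each has a matched follow-up row).  The
    viable change is ``None`` when no target lesion has a measurable
    enhancing portion at baseline.
    """
    targets = {l.lesion_id: l for l in record.baseline_lesions() if l.is_target}
    if not targets:
        raise NoTargetLesionError(f"patient {record.patient_id}: no target lesions")
    fu = {l.lesion_id: l for l in record.followup_lesions() if l.lesion_id in targets}
    missing = set(targets) - set(fu)
    if missing:
        raise ValueError(
            f"patient {record.patient_id}: no follow-up measurement for "
            f"target lesion(s) {sorted(missing)}"
        )

    sld_bl = sum(l.longest_diameter for l in targets.values())
    sld_fu = sum(fu[i].longest_diameter for i in targets)
    if sld_bl <= 0:
        raise ValueError(
            f"patient {record.patient_id}: baseline sum of diameters is zero "
            "(no measurable disease)"
        )
    v_bl = sum(l.viable_diameter for l in targets.values())
    v_fu = sum(fu[i].viable_diameter for i in targets)

    return ChangeSummary(
        sld_bl=sld_bl,
        sld_fu=sld_fu,
        sld_change=(sld_fu - sld_bl) / sld_bl,
        viable_sld_bl=v_bl,
        viable_sld_fu=v_fu,
        viable_change=(v_fu - v_bl) / v_bl if v_bl > 0 else None,
        afp_delta=afp_delta(record.afp) if record.afp is not None else None,
    )


def _classify_size(
    sld_bl: float,
    sld_fu: float,
    change_from_baseline: float,
    change_from_nadir: float,
    abs_increase_mm: Optional[float],
    new_lesions: bool,
    nontarget_status: NontargetStatus,
    spec: CriterionSpec,
) -> ResponseCategory:
    """Shared CR/PR/SD/PD cascade over a size quantity.

    ``abs_increase_mm`` carries the RECIST 1.1 five-millimetre absolute
    requirement; pass ``None`` to disable it (mRECIST's PD row states only
    the percentage condition).
    """
    size_pd = change_from_nadir >= spec.size_pd_cutoff and (
        abs_increase_mm is None or abs_increase_mm >= spec.pd_abs_mm
    )
    if new_lesions or nontarget_status is NontargetStatus.PD or size_pd:
        return ResponseCategory.PD
    if (
        sld_fu == 0
        and nontarget_status in (NontargetStatus.CR, NontargetStatus.ABSENT)
    ):
        return ResponseCategory.CR
    if change_from_baseline <= spec.size_pr_cutoff:
        return ResponseCategory.PR
    return ResponseCategory.SD


def classify_recist11(
    summary: ChangeSummary,
    new_lesions: bool,
    nontarget_status: NontargetStatus = NontargetStatus.ABSENT,
    spec: CriterionSpec | None = None,
) -> ResponseCategory:
    """RECIST 1.1 category from total-diameter changes.

    PD needs a >=20% increase over the nadir *and* an absolute increase of
    at least 5 mm, or new lesions / non-target progression.  With a single
    follow-up the nadir is the baseline.
    """
    spec = spec or CRITERIA["RECIST11"]
    return _classify_size(
        summary.sld_bl,
        summary.sld_fu,
        summary.sld_change,
        summary.sld_change,  # nadir = baseline with one follow-up
        summary.sld_fu - summary.sld_bl,
        new_lesions,
        nontarget_status,
        spec,
    )


def classify_mrecist(
    summary: ChangeSummary,
    new_lesions: bool,
    nontarget_status: NontargetStatus = NontargetStatus.ABSENT,
    spec: CriterionSpec | None = None,
) -> ResponseCategory:
    """mRECIST category from viable (arterially enhancing) diameter changes.

    CR is the disappearance of all intra-tumoral arterial enhancement
    (viable sum 0 at follow-up).  A patient with no enhancing tissue at
    baseline already satisfies CR's condition trivially only if follow-up
    enhancement is also absent; otherwise the viable change is undefined
    and the category falls back to SD (no measurable viable disease).
    """
    spec = spec or CRITERIA["mRECIST"]
    if new_lesions or nontarget_status is NontargetStatus.PD:
        return ResponseCategory.PD
    if summary.viable_sld_fu == 0:
        if nontarget_status in (NontargetStatus.CR, NontargetStatus.ABSENT):
            return ResponseCategory.CR
    if summary.viable_change is None:
        return ResponseCategory.SD
    return _classify_size(
        summary.viable_sld_bl,
        summary.viable_sld_fu,
        summary.viable_change,
        summary.viable_change,
        None,
        new_lesions,
        nontarget_status,
        spec,
    )


def _base_category(record: PatientRecord, spec: CriterionSpec) -> ResponseCategory:
    summary = summarize_changes(record)
    if spec.base == "RECIST11":
        return classify_recist11(summary, record.new_lesions, record.nontarget_status, spec)
    return classify_mrecist(summary, record.new_lesions, record.nontarget_status, spec)


def classify_composite(
    record: PatientRecord, spec: CriterionSpec
) -> Optional[ResponseCategory]:
    """Category under an AFP-composite criterion; ``None`` = non-evaluable.

    Base PD (including new lesions) vetoes response.  Otherwise the
    responder flag is the OR/AND combination of the base responder flag
    and the AFP condition; responders are PR (CR preserved where the base
    reached CR and the combination logic allows), non-responders SD.
    """
    base = _base_category(record, spec)
    if spec.afp_component == "none":
        return base
    if base is ResponseCategory.PD:
        return ResponseCategory.PD
    if record.afp is None:
        return None  # non-evaluable: the AFP component cannot be assessed

    if spec.afp_component == "delta":
        afp_ok = afp_delta(record.afp) <= spec.afp_delta_cutoff
    else:  # baseline level, implemented exactly as the rule is stated
        afp_ok = record.afp.afp_bl >= spec.afp_bl_cutoff

    size_ok = base.responder
    responder = (size_ok or afp_ok) if spec.combiner == "or" else (size_ok and afp_ok)
    if not responder:
        return ResponseCategory.SD
    if base is ResponseCategory.CR and (spec.combiner == "or" or afp_ok):
        return ResponseCategory.CR
    return ResponseCategory.PR


def classify(record: PatientRecord, spec: CriterionSpec) -> Optional[ResponseCategory]:
    """Category of one patient under any registered criterion."""
    return classify_composite(record, spec)


def evaluate_cohort(
    cohort: Cohort, specs: list[CriterionSpec] | None = None
) -> pd.DataFrame:
    """Classify every patient under every criterion.

    Returns a DataFrame indexed by patient_id with one category column per
    criterion (values CR/PR/SD/PD or ``NE`` for non-evaluable) plus
    ``responder_<name>`` booleans (``NE`` rows get pandas NA).
    """
    specs = list(CRITERIA.values()) if specs is None else specs
    rows = {}
    for record in cohort:
        row = {}
        for spec in specs:
            cat = classify_composite(record, spec)
            row[spec.name] = NON_EVALUABLE if cat is None else cat.name
            row[f"responder_{spec.name}"] = pd.NA if cat is None else cat.responder
        rows[record.patient_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    for spec in specs:
        out[f"responder_{spec.name}"] = out[f"responder_{spec.name}"].astype("boolean")
    return out


def category_counts(response_table: pd.DataFrame) -> pd.DataFrame:
    """Marginal CR/PR/SD/PD/NE counts per criterion column."""
    cats = [c.name for c in ResponseCategory] + [NON_EVALUABLE]
    crit_cols = [c for c in response_table.columns if not c.startswith("responder_")]
    counts = {
        col: {cat: int((response_table[col] == cat).sum()) for cat in cats}
        for col in crit_cols
    }
    out = pd.DataFrame(counts).T[cats]
    out.index.name = "criterion"
    return out
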