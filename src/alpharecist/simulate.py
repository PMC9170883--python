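"""Synthetic cohort generator for hepatocellular-carcinoma response studies.

Emulates the data structure the analysis consumes: per-lesion total and
arterially enhancing (viable) longest diameters at baseline and one
follow-up, a baseline/follow-up serum AFP pair, censored recurrence-free
and overall survival, an independent pathology read, and optionally a
second reader's categories.

Each patient carries a latent responder flag.  Responders draw larger
size and AFP decreases and (in ``latent`` mode) a proportionally reduced
recurrence hazard; in ``step-hazard`` mode the hazard reduction instead
applies to patients whose AFP change falls at or below a planted cutoff,
which is what the cutpoint search is expected to recover.

Default calibration anchors (cohort-level, loose by design):
  - about half the patients have baseline AFP >= 200 ng/ml
    (lognormal mu=5.25, sigma=1.5);
  - median baseline tumor burden 70 mm (lognormal around ln 70, sigma 0.45);
  - non-responder median recurrence-free survival 20 months (exponential),
    so 1-year non-responder RFS is about 66%;
  - responder hazard ratio 0.31;
  - uniform censoring over 12-60 months; overall survival is recurrence
    time plus an exponential increment of mean 12 months.

Survival is exponential for analytic tractability of the recovery tests;
change fractions are normal draws clipped at -1 (a tumor or AFP level
cannot lose more than all of itself), which leaves a small atom at -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    AFPPair,
    Cohort,
    LesionMeasurement,
    NontargetStatus,
    PathologyRecord,
    PatientRecord,
    SurvivalOutcome,
    Timepoint,
)
from .criteria import CriterionSpec, ResponseCategory, classify_composite

__all__ = ["GeneratorParams", "SimulatedCohort", "generate_cohort", "generate_reader_pair"]

LATENT = "latent"
STEP_HAZARD = "step-hazard"


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the simulator; the seed is mandatory."""

    n: int
    seed: int
    responder_prob: float = 0.5
    size_change_responder: tuple[float, float] = (-0.35, 0.12)  # mean, sd
    size_change_nonresponder: tuple[float, float] = (-0.05, 0.10)
    afp_bl_lognormal: tuple[float, float] = (5.25, 1.5)  # log-mean, log-sd
    afp_delta_responder: tuple[float, float] = (-0.85, 0.10)
    afp_delta_nonresponder: tuple[float, float] = (-0.30, 0.25)
    baseline_sld_lognormal: tuple[float, float] = (math.log(70.0), 0.45)
    responder_hr: float = 0.31
    base_median_rfs_months: float = 20.0
    censor_window: tuple[float, float] = (12.0, 60.0)
    mode: str = LATENT  # or "step-hazard"
    planted_afp_cutoff: float = -0.76
    second_lesion_prob: float = 0.05
    viable_fraction_range: tuple[float, float] = (0.6, 0.95)
    viable_extra_shrink_responder: float = 0.15
    viable_extra_shrink_nonresponder: float = 0.02
    viable_shrink_sd: float = 0.05
    os_increment_mean_months: float = 12.0
    reader2_flip_prob: float = 0.025

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        for name in ("responder_prob", "second_lesion_prob", "reader2_flip_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "size_change_responder",
            "size_change_nonresponder",
            "afp_bl_lognormal",
            "afp_delta_responder",
            "afp_delta_nonresponder",
            "baseline_sld_lognormal",
        ):
            _, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")
        if not (0 < self.responder_hr):
            raise ValueError("responder_hr must be positive")
        if self.base_median_rfs_months <= 0:
            raise ValueError("base_median_rfs_months must be positive")
        lo, hi = self.censor_window
        if not (0 < lo <= hi):
            raise ValueError("censor_window must be 0 < low <= high")
        if self.mode not in (LATENT, STEP_HAZARD):
            raise ValueError(f"mode must be '{LATENT}' or '{STEP_HAZARD}'")
        flo, fhi = self.viable_fraction_range
        if not (0 < flo <= fhi <= 1):
            raise ValueError("viable_fraction_range must lie in (0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus the latent per-patient truth."""

    cohort: Cohort
    latent: pd.DataFrame  # patient_id, responder, size_change, afp_delta, hazard_group


def _clip_change(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, -1.0)


def generate_cohort(params: GeneratorParams) -> SimulatedCohort:
    """Draw a cohort; deterministic given the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    responder = rng.random(n) < params.responder_prob
    mu_s = np.where(responder, params.size_change_responder[0],
                    params.size_change_nonresponder[0])
    sd_s = np.where(responder, params.size_change_responder[1],
                    params.size_change_nonresponder[1])
    size_change = _clip_change(rng.normal(mu_s, sd_s))

    afp_bl = rng.lognormal(*params.afp_bl_lognormal, size=n)
    mu_a = np.where(responder, params.afp_delta_responder[0],
                    params.afp_delta_nonresponder[0])
    sd_a = np.where(responder, params.afp_delta_responder[1],
                    params.afp_delta_nonresponder[1])
    afp_delta = _clip_change(rng.normal(mu_a, sd_a))
    afp_fu = afp_bl * (1.0 + afp_delta)

    # survival: exponential recurrence with a hazard drop for the "good" group
    lam0 = math.log(2.0) / params.base_median_rfs_months
    if params.mode == LATENT:
        good = responder
    else:
        good = afp_delta <= params.planted_afp_cutoff
    lam = lam0 * np.where(good, params.responder_hr, 1.0)
    t_rec = rng.exponential(1.0 / lam)
    t_death = t_rec + rng.exponential(params.os_increment_mean_months, size=n)
    c = rng.uniform(*params.censor_window, size=n)
    rfs_months = np.minimum(t_rec, c)
    rfs_event = t_rec <= c
    os_months = np.minimum(t_death, c)
    os_event = t_death <= c

    # lesions: mostly a single target lesion, occasionally a second in-organ one
    d1 = np.maximum(rng.lognormal(*params.baseline_sld_lognormal, size=n), 10.0)
    has_second = rng.random(n) < params.second_lesion_prob
    d2 = np.maximum(d1 * rng.uniform(0.3, 0.6, size=n), 10.0)
    vfrac = rng.uniform(*params.viable_fraction_range, size=n)
    extra = np.where(responder, params.viable_extra_shrink_responder,
                     params.viable_extra_shrink_nonresponder)
    viable_change = _clip_change(
        size_change - extra + rng.normal(0.0, params.viable_shrink_sd, size=n)
    )

    pathology = rng.uniform(0.05, 0.95, size=n)  # independent of response

    records: list[PatientRecord] = []
    for i in range(n):
        diams = [d1[i]] + ([d2[i]] if has_second[i] else [])
        lesions: list[LesionMeasurement] = []
        for j, d in enumerate(diams):
            lid = f"L{j + 1}"
            fu_ld = max(d * (1.0 + size_change[i]), 0.0)
            v_bl = d * vfrac[i]
            fu_v = min(max(v_bl * (1.0 + viable_change[i]), 0.0), fu_ld)
            lesions.append(LesionMeasurement(
                lesion_id=lid, organ="liver", timepoint=Timepoint.BASELINE,
                longest_diameter=float(d), viable_diameter=float(v_bl),
                is_target=True))
            lesions.append(LesionMeasurement(
                lesion_id=lid, organ="liver", timepoint=Timepoint.FOLLOWUP,
                longest_diameter=float(fu_ld), viable_diameter=float(fu_v),
                is_target=True))
        records.append(PatientRecord(
            patient_id=f"P{i + 1:04d}",
            lesions=tuple(lesions),
            new_lesions=False,
            nontarget_status=NontargetStatus.ABSENT,
            survival=SurvivalOutcome(
                rfs_months=float(rfs_months[i]), rfs_event=bool(rfs_event[i]),
                os_months=float(os_months[i]), os_event=bool(os_event[i])),
            afp=AFPPair(afp_bl=float(afp_bl[i]), afp_fu=float(afp_fu[i])),
            pathology=PathologyRecord(percent_viable=float(pathology[i])),
        ))

    cohort = Cohort(
        records=records,
        provenance={"generator": "alpharecist.simulate", "seed": int(params.seed),
                    "n": int(n), "mode": params.mode},
    )
    latent = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "responder": responder,
        "size_change": size_change,
        "afp_delta": afp_delta,
        "hazard_group": good,
    })
    return SimulatedCohort(cohort=cohort, latent=latent)


def generate_reader_pair(
    cohort: Cohort,
    criterion: CriterionSpec,
    flip_prob: float,
    seed: int,
) -> Cohort:
    """Attach reader categories: reader 1 = the true classification,
    reader 2 = reader 1 with adjacent-category flips at ``flip_prob``.

    Flips move one step along CR < PR < SD < PD (inward at the ends).
    """
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_records = []
    for record in cohort:
        cat = classify_composite(record, criterion)
        if cat is None:
            readers = None
        else:
            r2 = cat
            if rng.random() < flip_prob:
                if cat is ResponseCategory.CR:
                    r2 = ResponseCategory.PR
                elif cat is ResponseCategory.PD:
                    r2 = ResponseCategory.SD
                else:
                    step = 1 if rng.random() < 0.5 else -1
                    r2 = ResponseCategory(cat.value + step)
            readers = {"reader1": cat.name, "reader2": r2.name}
        new_records.append(replace(record, reader_categories=readers))
    return Cohort(records=new_records,
                  provenance={**cohort.provenance,
                              "reader_pair": {"criterion": criterion.name,
                                              "flip_prob": flip_prob,
                                              "seed": int(seed)}})
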