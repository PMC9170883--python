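"""End-to-end analysis orchestration and publication-style CSV exports.

Stages: classify every patient under the requested criteria, discover
marker cutoffs against the chosen endpoint, validate each criterion's
responder split by Kaplan–Meier/log-rank/Cox, tabulate inter-reader
agreement and the response–pathology correlation.  All canonical outputs
are CSV; a JSON manifest records the configuration, seed and row counts
so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    confusion_matrix,
    pathologic_category,
    spearman_correlation,
    weighted_kappa,
)
from .cohort import Cohort, load_cohort, write_cohort
from .criteria import (
    CRITERIA,
    CriterionSpec,
    category_counts,
    evaluate_cohort,
    resolve_criterion,
    summarize_changes,
)
from .cutpoint import NoValidCutpointError, optimal_cutpoint
from .survival import cox_univariate, km_curve, logrank_test, reverse_km_followup, survival_at
from .simulate import GeneratorParams, generate_cohort

log = logging.getLogger("alpharecist")

__all__ = ["AnalysisConfig", "run_full_analysis", "waterfall_table",
           "marker_frame", "survival_summary"]


@dataclass
class AnalysisConfig:
    """Configuration of a full run; either a cohort path or generator params."""

    input_path: Optional[str] = None
    generator: Optional[GeneratorParams] = None
    criteria: list[str] = field(default_factory=lambda: list(CRITERIA))
    endpoint: str = "rfs"  # or "os"
    cutpoint_min_frac: float = 0.10
    cutpoint_correction: bool = True
    out_dir: str = "alpharecist-output"
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator must be set")
        if self.endpoint not in ("rfs", "os"):
            raise ValueError("endpoint must be 'rfs' or 'os'")
        for name in self.criteria:
            resolve_criterion(name)


def marker_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-patient change quantities (missing AFP stays missing)."""
    rows = []
    for r in cohort:
        s = summarize_changes(r)
        rows.append({
            "patient_id": r.patient_id,
            "sld_bl": s.sld_bl,
            "sld_fu": s.sld_fu,
            "sld_change": s.sld_change,
            "viable_change": np.nan if s.viable_change is None else s.viable_change,
            "afp_bl": np.nan if r.afp is None else r.afp.afp_bl,
            "afp_delta": np.nan if s.afp_delta is None else s.afp_delta,
        })
    return pd.DataFrame(rows).set_index("patient_id")


_THRESHOLDS = {
    "sld_change": (-0.30, 0.20),
    "viable_change": (-0.30, 0.20),
    "afp_delta": (-0.76, None),
}


def waterfall_table(cohort: Cohort, quantity: str) -> pd.DataFrame:
    """Rows sorted descending by the chosen change quantity, with
    threshold-crossing flags; ties keep the input (cohort) order, and
    patients with a missing value are listed last with ``missing=True``."""
    if quantity not in _THRESHOLDS:
        raise ValueError(f"quantity must be one of {sorted(_THRESHOLDS)}")
    mf = marker_frame(cohort)[[quantity]].reset_index()
    mf["missing"] = mf[quantity].isna()
    lo, hi = _THRESHOLDS[quantity]
    mf["below_decrease_threshold"] = mf[quantity] <= lo
    if hi is not None:
        mf["above_increase_threshold"] = mf[quantity] >= hi
    mf = mf.sort_values(quantity, ascending=False, kind="stable", na_position="last")
    return mf.reset_index(drop=True)


def survival_summary(cohort: Cohort, responder: pd.Series, endpoint: str) -> dict:
    """KM / log-rank / Cox comparison of responders vs non-responders.

    ``responder`` is a boolean Series indexed by patient_id; NA entries
    (non-evaluable patients) are dropped.
    """
    tcol, ecol = (("rfs_months", "rfs_event") if endpoint == "rfs"
                  else ("os_months", "os_event"))
    rows = []
    for r in cohort:
        flag = responder.get(r.patient_id, pd.NA)
        if pd.isna(flag):
            continue
        rows.append((bool(flag), getattr(r.survival, tcol), getattr(r.survival, ecol)))
    df = pd.DataFrame(rows, columns=["responder", "time", "event"])
    out: dict = {"n": len(df), "n_responder": int(df["responder"].sum())}
    if df.empty or df["responder"].nunique() < 2 or df["event"].sum() == 0:
        out["status"] = "not comparable (one group empty or no events)"
        return out

    grp = [
        (df.loc[df.responder, "time"], df.loc[df.responder, "event"]),
        (df.loc[~df.responder, "time"], df.loc[~df.responder, "event"]),
    ]
    lr = logrank_test(grp)
    out["logrank_chi2"] = lr.chi_square
    out["logrank_p"] = lr.p_value
    try:
        cox = cox_univariate(df["responder"].to_numpy(), df["time"], df["event"])
        out.update(hr=cox.hazard_ratio, hr_ci_low=cox.ci_low,
                   hr_ci_high=cox.ci_high, hr_p=cox.p_value)
    except Exception as exc:  # monotone likelihood etc.; keep the stage alive
        out["cox_status"] = f"not estimable: {exc}"

    for label, sub in (("responder", df[df.responder]), ("nonresponder", df[~df.responder])):
        curve = km_curve(sub["time"], sub["event"])
        for yr in (1, 2, 3):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[f"{label}_{yr}y_rate"] = survival_at(curve, 12.0 * yr)
    return out


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the CSV bundle; returns in-memory results."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        cohort = load_cohort(config.input_path)
        source = {"input_path": str(config.input_path)}
    else:
        cohort = generate_cohort(config.generator).cohort
        write_cohort(cohort, out_dir / "cohort.csv")
        source = {"generator": config.generator.__dict__.copy()}
    log.info("cohort loaded: %d patients", len(cohort))

    specs = [resolve_criterion(n) for n in config.criteria]
    results: dict = {}

    # (a) classification + marginal counts
    table = evaluate_cohort(cohort, specs)
    table.to_csv(out_dir / "response_table.csv")
    counts = category_counts(table)
    counts.to_csv(out_dir / "response_counts.csv")
    results["response_table"] = table
    results["response_counts"] = counts
    log.info("classified %d patients under %d criteria", len(table), len(specs))

    # (b) waterfall tables
    for q in ("sld_change", "viable_change", "afp_delta"):
        wf = waterfall_table(cohort, q)
        wf.to_csv(out_dir / f"waterfall_{q}.csv", index=False)
        results[f"waterfall_{q}"] = wf

    # (c) cutpoint discovery on the AFP markers
    mf = marker_frame(cohort)
    tcol = "rfs_months" if config.endpoint == "rfs" else "os_months"
    ecol = "rfs_event" if config.endpoint == "rfs" else "os_event"
    surv = pd.DataFrame(
        {
            "time": [getattr(r.survival, tcol) for r in cohort],
            "event": [getattr(r.survival, ecol) for r in cohort],
        },
        index=pd.Index(cohort.patient_ids(), name="patient_id"),
    )
    cut_rows = []
    for marker in ("afp_delta", "afp_bl"):
        ok = mf[marker].notna()
        try:
            res = optimal_cutpoint(
                mf.loc[ok, marker], surv.loc[ok, "time"], surv.loc[ok, "event"],
                min_frac=config.cutpoint_min_frac,
                correction=config.cutpoint_correction)
            cut_rows.append({
                "marker": marker, "cutoff": res.cutoff,
                "chi_square": res.chi_square, "naive_p": res.naive_p,
                "corrected_p": res.corrected_p,
                "n_low": res.group_sizes[0], "n_high": res.group_sizes[1]})
            pd.DataFrame({"cutoff": res.candidates,
                          "chi_square": res.chi_squares}).to_csv(
                out_dir / f"cutpoint_scan_{marker}.csv", index=False)
            results[f"cutpoint_{marker}"] = res
        except (NoValidCutpointError, ValueError) as exc:
            cut_rows.append({"marker": marker, "status": str(exc)})
    pd.DataFrame(cut_rows).to_csv(out_dir / "cutpoints.csv", index=False)

    # (d) survival validation per criterion
    surv_rows = []
    for spec in specs:
        summary = survival_summary(cohort, table[f"responder_{spec.name}"],
                                   config.endpoint)
        surv_rows.append({"criterion": spec.name, **summary})
    surv_df = pd.DataFrame(surv_rows)
    surv_df.to_csv(out_dir / "survival_by_criterion.csv", index=False)
    results["survival_by_criterion"] = surv_df

    followup = reverse_km_followup(surv["time"], surv["event"])
    results["median_followup_months"] = followup

    # (e) inter-reader agreement (only when reader columns are present)
    readers = [(r.reader_categories or {}) for r in cohort]
    if all("reader1" in d and "reader2" in d for d in readers) and readers:
        cm = confusion_matrix([d["reader1"] for d in readers],
                              [d["reader2"] for d in readers])
        kap = weighted_kappa(cm)
        pd.DataFrame([{
            "n": cm.total, "agreement_n": int(np.trace(cm.counts)),
            "agreement_pct": 100.0 * cm.percent_agreement,
            "kappa": kap.kappa, "kappa_ci_low": kap.ci_low,
            "kappa_ci_high": kap.ci_high, "weighting": kap.weighting,
        }]).to_csv(out_dir / "agreement.csv", index=False)
        results["agreement"] = kap

    # (f) pathology concordance for the selected criterion (alpha-RECIST)
    alpha = resolve_criterion("alpha-recist")
    if alpha.name in table.columns:
        rows = []
        for r in cohort:
            if r.pathology is None:
                continue
            cat = table.loc[r.patient_id, alpha.name]
            if cat == "NE":
                continue
            rows.append({
                "patient_id": r.patient_id,
                "response": cat,
                "responder": table.loc[r.patient_id, f"responder_{alpha.name}"],
                "pathology": pathologic_category(r.pathology.percent_viable),
            })
        pc = pd.DataFrame(rows)
        if not pc.empty:
            pc.to_csv(out_dir / "pathology_concordance.csv", index=False)
            xt = pd.crosstab(pc["response"], pc["pathology"])
            xt.to_csv(out_dir / "pathology_crosstab.csv")
            results["pathology_crosstab"] = xt
            path_rank = pc["pathology"].map({"complete": 0, "major": 1, "minor": 2})
            resp_rank = pc["responder"].map({True: 0, False: 1}).astype(int)
            if path_rank.nunique() > 1 and resp_rank.nunique() > 1:
                results["pathology_spearman"] = spearman_correlation(
                    resp_rank, path_rank)

    manifest = {
        "version": __version__,
        "source": source,
        "criteria": [s.name for s in specs],
        "endpoint": config.endpoint,
        "n_patients": len(cohort),
        "median_followup_months": followup,
        "config_hash": hashlib.sha256(
            json.dumps({"criteria": config.criteria,
                        "endpoint": config.endpoint,
                        "min_frac": config.cutpoint_min_frac,
                        "source": source}, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    log.info("analysis complete; outputs in %s", out_dir)
    return results
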