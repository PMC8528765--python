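"""End-to-end monitoring pipeline on a (synthetic) cohort.

generate → score → expected-trajectory boundary → OT/NOT classification →
domain alerts → group statistics, with tidy CSV reports.  Every stage is a
pure function of (config, seed), so two runs with the same seed produce
byte-identical reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alerts as alerts_mod
from . import stats as stats_mod
from .classify import ReliableChangeCriterion, classify_cohort
from .instruments import (Catalog, RiskAssessment, ScaleScore,
                          default_catalog)
from .synthetic import (Cohort, CohortConfig, battery_session_list,
                        generate_archival, generate_cohort)
from .trajectory import (FailureBoundary, ReferencePool, TrajectoryConfig,
                         dynamic_boundary_sequence)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "write_reports", "score_long", "risk_by_session",
           "build_model_dataset"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs besides the seed."""

    cohort: CohortConfig = CohortConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    reliability: float = 0.87
    rci_z: float = 1.96
    screen_alpha: float = 0.10
    n_quad: int = 15
    run_model_building: bool = True
    run_item_report: bool = True


# ---------------------------------------------------------------------------
# vectorized scoring of the long item table
# ---------------------------------------------------------------------------

def score_long(items: pd.DataFrame,
               catalog: Catalog | None = None) -> pd.DataFrame:
    """Score every scale for every (patient, session) present in ``items``.

    Vectorized equivalent of ``instruments.score_scale`` applied after
    ``recode_reversed``: reversed items are recoded 6 − v, a score is valid
    when strictly more than 80% of the scale's items are observed, missing
    items are mean-imputed.  Returns tidy rows
    (patient_id, session, scale, value, n_observed, valid).
    """
    catalog = catalog or default_catalog()
    out = []
    for name, scale in catalog.scales.items():
        sub = items[(items["instrument"] == scale.instrument.value)
                    & (items["item"].isin(scale.item_ids))].copy()
        if sub.empty:
            continue
        rev = sub["item"].isin(scale.reversed_item_ids)
        sub.loc[rev, "value"] = 6.0 - sub.loc[rev, "value"]
        g = sub.groupby(["patient_id", "session"])["value"]
        agg = g.agg(n_observed="count", mean="mean").reset_index()
        k = len(scale.item_ids)
        agg["valid"] = agg["n_observed"] / k > 0.80
        value = agg["mean"] * (k if scale.aggregation == "sum" else 1.0)
        agg["value"] = np.where(agg["valid"], value, np.nan)
        agg["scale"] = name
        out.append(agg[["patient_id", "session", "scale", "value",
                        "n_observed", "valid"]])
    return pd.concat(out, ignore_index=True)


def risk_by_session(items: pd.DataFrame,
                    catalog: Catalog | None = None) -> pd.DataFrame:
    """Per-session risk assessment with carry-forward of the OQ items.

    The HSCL suicidal-ideation item refreshes every session; the OQ-30 items
    are observed only at battery sessions and carry their last battery value
    forward.  Returns (patient_id, session, severity, flag, immediate).
    """
    catalog = catalog or default_catalog()
    specs = catalog.risk_items
    frames = {}
    for label, spec in zip(("hscl_suicide", "oq5", "oq18"), specs):
        sub = items[(items["instrument"] == spec.instrument.value)
                    & (items["item"] == spec.item_id)]
        frames[label] = sub.set_index(["patient_id", "session"])["value"]
    sessions = (items[["patient_id", "session"]].drop_duplicates()
                .sort_values(["patient_id", "session"]))
    df = sessions.set_index(["patient_id", "session"])
    for label in frames:
        df[label] = frames[label]
    df = df.reset_index().sort_values(["patient_id", "session"])
    for label in ("oq5", "oq18"):
        df[label] = df.groupby("patient_id")[label].ffill()
    crossings = []
    for label, spec in zip(("hscl_suicide", "oq5", "oq18"), specs):
        crossings.append((df[label] >= spec.cutoff).fillna(False))
    df["severity"] = np.sum(crossings, axis=0).astype(int)
    df["flag"] = df["severity"] > 0
    immediate_spec = specs[0]
    df["immediate"] = (df["hscl_suicide"] >= immediate_spec.cutoff).fillna(False)
    return df[["patient_id", "session", "hscl_suicide", "oq5", "oq18",
               "severity", "flag", "immediate"]]


# ---------------------------------------------------------------------------
# model-building dataset
# ---------------------------------------------------------------------------

def build_model_dataset(scores: pd.DataFrame,
                        risk: pd.DataFrame,
                        statuses: dict,
                        truth: pd.DataFrame,
                        window: tuple[int, int] = (6, 30)) -> pd.DataFrame:
    """One row per classified session with carried-forward predictors.

    Outcome: the per-session NOT indicator from the track classifier.
    Predictors: session number, risk severity (0–3), and the ASC/ASQ domain
    scores from the most recent battery at or before the session.  Emotion
    regulation enters as the mean of the three ASQ subscale means.
    """
    ther = truth.set_index("patient_id")["therapist_id"]
    wide = scores.pivot_table(index=["patient_id", "session"],
                              columns="scale", values="value",
                              aggfunc="first")
    wide["emotion_regulation"] = wide[
        ["ASQ_concealing", "ASQ_tolerating", "ASQ_adjusting"]].mean(axis=1)
    rows = []
    risk_idx = risk.set_index(["patient_id", "session"])["severity"]
    for pid, status in statuses.items():
        batt = wide.loc[pid] if pid in wide.index.get_level_values(0) else None
        if batt is None:
            continue
        batt = batt.sort_index().ffill()
        for session, state in status.states.items():
            if not (window[0] <= session <= window[1]):
                continue
            last_batt = batt.loc[:session]
            if last_batt.empty:
                continue
            b = last_batt.iloc[-1]
            rows.append({
                "patient_id": pid,
                "therapist_id": int(ther.loc[pid]),
                "session": session,
                "not_on_track": int(state == "NOT"),
                "risk": float(risk_idx.get((pid, session), np.nan)),
                "motivation": b.get("ASC_MO", np.nan),
                "alliance": b.get("ASC_TA", np.nan),
                "life_events": b.get("ASC_LE", np.nan),
                "social_support": b.get("ASC_SS", np.nan),
                "emotion_regulation": b.get("emotion_regulation", np.nan),
            })
    df = pd.DataFrame(rows)
    return df.dropna().reset_index(drop=True)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: Cohort
    pool: ReferencePool
    scores: pd.DataFrame
    risk: pd.DataFrame
    boundaries: dict[int, FailureBoundary]
    statuses: dict
    not_labels: dict[int, bool]
    session6_table: pd.DataFrame
    session6_tests: pd.DataFrame
    model_dataset: pd.DataFrame
    model_building: stats_mod.ModelBuildingResult | None
    item_report: pd.DataFrame | None
    summary: dict


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 seed: int = 0) -> PipelineResult:
    """Run the complete monitoring chain on one synthetic cohort."""
    pool = generate_archival(config.cohort, seed)
    cohort = generate_cohort(config.cohort, seed)
    catalog = default_catalog()
    scores = score_long(cohort.items, catalog)
    risk = risk_by_session(cohort.items, catalog)

    hscl = scores[(scores["scale"] == "HSCL_total") & scores["valid"]]
    observations = {
        pid: dict(zip(grp["session"], grp["value"]))
        for pid, grp in hscl.groupby("patient_id")
    }
    totals = cohort.truth.set_index("patient_id")["total_sessions"]

    lo, _ = config.trajectory.session_window
    boundaries = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, history in observations.items():
            if max(history) < lo:
                continue  # fewer than six sessions: excluded from analysis
            boundaries[pid] = dynamic_boundary_sequence(
                pid, history, pool, config.trajectory,
                total_sessions=int(totals.loc[pid]),
            )

    crit = ReliableChangeCriterion(sd=pool.intake_sd(),
                                   reliability=config.reliability,
                                   z=config.rci_z)
    statuses = classify_cohort(boundaries, observations, crit,
                               min_sessions=lo)
    not_labels = {pid: st.ever_not for pid, st in statuses.items()}

    # session-six comparison: battery from session 5, risk items at session 6
    batt = scores[scores["session"] == 5]
    risk6 = risk[risk["session"] == 6].set_index("patient_id")
    crossings = _domain_crossings(batt, risk6, statuses, catalog)
    session6 = alerts_mod.session6_signal_table(crossings, not_labels)
    session6_tests = _session6_chi2(session6)

    model_dataset = build_model_dataset(scores, risk, statuses, cohort.truth,
                                        config.trajectory.session_window)
    building = None
    if config.run_model_building and not model_dataset.empty \
            and model_dataset["not_on_track"].nunique() > 1:
        building = stats_mod.model_building(
            model_dataset, screen_alpha=config.screen_alpha,
            spec=stats_mod.ModelSpec(n_quad=config.n_quad),
        )

    item_report = None
    if config.run_item_report:
        item_report = _session6_item_report(cohort, not_labels, catalog)

    n_not = sum(not_labels.values())
    summary = {
        "n_classified": len(statuses),
        "n_not": n_not,
        "not_fraction": n_not / len(statuses) if statuses else math.nan,
    }
    return PipelineResult(
        cohort=cohort, pool=pool, scores=scores, risk=risk,
        boundaries=boundaries, statuses=statuses, not_labels=not_labels,
        session6_table=session6, session6_tests=session6_tests,
        model_dataset=model_dataset, model_building=building,
        item_report=item_report, summary=summary,
    )


def _domain_crossings(battery_scores: pd.DataFrame, risk6: pd.DataFrame,
                      statuses: dict, catalog: Catalog) -> pd.DataFrame:
    rows = {}
    wide = battery_scores.pivot_table(index="patient_id", columns="scale",
                                      values="value", aggfunc="first")
    valid = battery_scores.pivot_table(index="patient_id", columns="scale",
                                       values="valid", aggfunc="first")
    for pid in statuses:
        scores = {}
        if pid in wide.index:
            for name in catalog.scales:
                if name in wide.columns and valid.loc[pid].get(name, False) \
                        and np.isfinite(wide.loc[pid, name]):
                    scores[name] = ScaleScore(name, float(wide.loc[pid, name]),
                                              len(catalog[name].item_ids), True)
        risk = None
        if pid in risk6.index:
            r = risk6.loc[pid]
            risk = RiskAssessment(int(r["severity"]), bool(r["flag"]),
                                  bool(r["immediate"]))
        rows[pid] = alerts_mod.map_domains(scores, risk, catalog)
    return pd.DataFrame.from_dict(rows, orient="index")


def _session6_chi2(session6: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for domain, r in session6.iterrows():
        try:
            res = stats_mod.crossing_table(
                int(r["ot_crossed"]), int(r["ot_total"]),
                int(r["not_crossed"]), int(r["not_total"]))
            chi2, p = res.chi2, res.pvalue
        except ValueError:
            chi2, p = np.nan, np.nan
        rows.append({"domain": domain, "chi2": chi2, "df": 1, "p": p})
    return pd.DataFrame(rows).set_index("domain")


def _session6_item_report(cohort: Cohort, not_labels: dict,
                          catalog: Catalog) -> pd.DataFrame:
    items = cohort.items[cohort.items["session"] == 5].copy()
    # recode reversed items so comparisons run on the functioning scale
    cutoffs = {}
    for name, scale in catalog.scales.items():
        for item in scale.item_ids:
            rev = items["item"].isin(scale.reversed_item_ids) \
                & (items["instrument"] == scale.instrument.value)
            if scale.item_cutoff is not None:
                cutoffs[(scale.instrument.value, item)] = (
                    scale.item_cutoff, scale.cutoff_direction)
        items.loc[rev, "value"] = 6.0 - items.loc[rev, "value"]
    for spec in catalog.risk_items:
        cutoffs[(spec.instrument.value, spec.item_id)] = (spec.cutoff,
                                                          "at_or_above")
    keep = items[items["instrument"].isin(["ASC", "ASQ"])
                 | ((items["instrument"] == "OQ30")
                    & items["item"].isin([5, 18]))
                 | ((items["instrument"] == "HSCL11") & (items["item"] == 11))]
    return stats_mod.item_comparison_report(keep, not_labels, cutoffs)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_reports(result: PipelineResult, out_dir) -> list[Path]:
    """Write the tidy CSV reports; byte-stable for a fixed (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for pid, fb in sorted(result.boundaries.items()):
        obs = result.scores[(result.scores["patient_id"] == pid)
                            & (result.scores["scale"] == "HSCL_total")]
        obs_map = dict(zip(obs["session"], obs["value"]))
        for s, e, u in zip(fb.sessions, fb.expected, fb.upper):
            rows.append({"patient_id": pid, "session": s,
                         "observed": obs_map.get(s, np.nan),
                         "expected": e, "upper": u})
    frames = {
        "boundaries.csv": pd.DataFrame(rows),
        "signal_log.csv": pd.DataFrame(
            [(pid, s, ev) for pid, st in sorted(result.statuses.items())
             for s, ev in st.signal_log],
            columns=["patient_id", "session", "event"]),
        "track_labels.csv": pd.DataFrame(
            sorted(result.not_labels.items()),
            columns=["patient_id", "not_on_track"]),
        "session6_table.csv": result.session6_table.reset_index(),
        "session6_tests.csv": result.session6_tests.reset_index(),
    }
    if result.model_building is not None:
        mb = result.model_building
        frames["model_trace.csv"] = pd.DataFrame({"step": mb.trace})
        frames["final_model.csv"] = mb.final.summary_frame().reset_index(
            names="term")
    if result.item_report is not None:
        frames["item_comparison.csv"] = result.item_report
    for name, df in frames.items():
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
        written.append(path)
    return written
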