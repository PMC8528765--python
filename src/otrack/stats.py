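"""Group comparisons: multilevel logistic model building, chi-square tests,
t-tests and effect sizes.

Three analyses are reproduced on a classified cohort:

* **Model building for NOT prediction** — a per-session binary not-on-track
  indicator is regressed on session number and the clinical-domain scores in
  a nested random-intercept logistic model (sessions in patients in
  therapists).  An empty model (Model 1) is compared with a time-only model
  (Model 2) by AIC; each domain is then screened one at a time (time +
  domain) at a liberal p <= .10, and the retained domains enter the final
  model (Model 3).  Continuous predictors are grand-mean centered.
* **Cut-off crossings at session six** — Pearson chi-square tests (no
  continuity correction) on 2x2 tables of domain crossing by OT/NOT group.
* **Item-level comparisons** — pooled-variance (Student) t-tests per item
  with pairwise deletion, plus the percentage crossing the item cut-off per
  group, and pooled-SD Cohen's d for descriptive contrasts.

No multiple-testing correction is applied anywhere; the screening and test
thresholds are deliberate analysis choices, not configurable corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import NestedLogisticResult, fit_nested_logistic_arrays

__all__ = [
    "ModelSpec",
    "ContingencyResult",
    "ModelBuildingResult",
    "grand_mean_center",
    "fit_nested_logistic",
    "model_building",
    "pearson_chi2",
    "two_sample_t",
    "cohens_d",
    "item_comparison_report",
]

#: Domain-score columns recognized by the model-building procedure.
DOMAIN_PREDICTORS = (
    "risk",
    "motivation",
    "alliance",
    "life_events",
    "social_support",
    "emotion_regulation",
)

SCREEN_ALPHA = 0.10


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the nested logistic model.

    The outcome column must be a per-session 0/1 not-on-track indicator;
    continuous predictors are grand-mean centered before fitting.
    """

    outcome: str = "not_on_track"
    fixed_effects: tuple[str, ...] = ()
    patient_col: str = "patient_id"
    therapist_col: str | None = "therapist_id"
    center: bool = True
    n_quad: int = 15


def grand_mean_center(values) -> np.ndarray:
    """Subtract the overall mean (idempotent on already-centered data)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot center an empty vector")
    return arr - arr.mean()


def fit_nested_logistic(data: pd.DataFrame,
                        spec: ModelSpec) -> NestedLogisticResult:
    """Fit the random-intercept logistic model described by ``spec``."""
    cols = list(spec.fixed_effects)
    y = data[spec.outcome].to_numpy(dtype=float)
    X = [np.ones(len(data))]
    for c in cols:
        v = data[c].to_numpy(dtype=float)
        X.append(grand_mean_center(v) if spec.center else v)
    X = np.column_stack(X)
    ther = (data[spec.therapist_col].to_numpy()
            if spec.therapist_col is not None else None)
    return fit_nested_logistic_arrays(
        y, X, data[spec.patient_col].to_numpy(), ther,
        param_names=("intercept", *cols), n_quad=spec.n_quad,
    )


@dataclass
class ModelBuildingResult:
    """Trace of the staged model-building procedure."""

    model1: NestedLogisticResult
    model2: NestedLogisticResult
    base_model_name: str                  # winner of model1 vs model2 by AIC
    domain_models: dict[str, NestedLogisticResult]
    domain_pvalues: dict[str, float]
    retained_domains: tuple[str, ...]
    model3: NestedLogisticResult | None
    final_model_name: str
    trace: list[str] = field(default_factory=list)

    @property
    def final(self) -> NestedLogisticResult:
        if self.final_model_name == "model3":
            return self.model3
        return self.model2 if self.base_model_name == "model2" else self.model1

    def significant_in_final(self, alpha: float = 0.05) -> tuple[str, ...]:
        """Domains significant at ``alpha`` in the final model."""
        if self.model3 is None:
            return ()
        fr = self.model3.summary_frame()
        return tuple(d for d in self.retained_domains if fr.loc[d, "p"] <= alpha)


def model_building(data: pd.DataFrame,
                   domains: Sequence[str] = DOMAIN_PREDICTORS,
                   time_col: str = "session",
                   screen_alpha: float = SCREEN_ALPHA,
                   spec: ModelSpec = ModelSpec()) -> ModelBuildingResult:
    """Staged predictor selection for the not-on-track outcome.

    1. Model 1: random intercepts only.  Model 2: + session number.  The
       better AIC wins and carries forward.
    2. One model per domain (time + domain); domains with p <= ``screen_alpha``
       on their own coefficient are retained.
    3. Model 3: time + all retained domains, compared with the step-1 winner
       by AIC.

    The procedure is deterministic: identical data yield an identical trace.
    """
    trace: list[str] = []
    m1 = fit_nested_logistic(data, _with_effects(spec, ()))
    m2 = fit_nested_logistic(data, _with_effects(spec, (time_col,)))
    base = "model2" if m2.aic <= m1.aic else "model1"
    trace.append(f"model1 AIC={m1.aic:.1f} BIC={m1.bic:.1f}")
    trace.append(f"model2 AIC={m2.aic:.1f} BIC={m2.bic:.1f}; base={base}")

    domain_models: dict[str, NestedLogisticResult] = {}
    domain_p: dict[str, float] = {}
    retained = []
    for d in domains:
        fit = fit_nested_logistic(data, _with_effects(spec, (time_col, d)))
        pv = float(fit.summary_frame().loc[d, "p"])
        domain_models[d] = fit
        domain_p[d] = pv
        if pv <= screen_alpha:
            retained.append(d)
        trace.append(f"screen {d}: p={pv:.4f} "
                     f"{'retained' if pv <= screen_alpha else 'dropped'}")

    model3 = None
    final = base
    if retained:
        model3 = fit_nested_logistic(
            data, _with_effects(spec, (time_col, *retained)))
        base_aic = m2.aic if base == "model2" else m1.aic
        final = "model3" if model3.aic <= base_aic else base
        trace.append(f"model3 AIC={model3.aic:.1f} BIC={model3.bic:.1f}; "
                     f"final={final}")
    return ModelBuildingResult(
        model1=m1, model2=m2, base_model_name=base,
        domain_models=domain_models, domain_pvalues=domain_p,
        retained_domains=tuple(retained), model3=model3,
        final_model_name=final, trace=trace,
    )


def _with_effects(spec: ModelSpec, effects: tuple[str, ...]) -> ModelSpec:
    return ModelSpec(outcome=spec.outcome, fixed_effects=effects,
                     patient_col=spec.patient_col,
                     therapist_col=spec.therapist_col,
                     center=spec.center, n_quad=spec.n_quad)


# ---------------------------------------------------------------------------
# contingency tables, t-tests, effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    pvalue: float


def pearson_chi2(table) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, without continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(
        table=tuple(map(tuple, t.astype(int))),
        chi2=float(chi2), df=int(df), pvalue=float(p),
    )


def crossing_table(crossed_a: int, total_a: int,
                   crossed_b: int, total_b: int) -> ContingencyResult:
    """Chi-square for crossed/not-crossed counts in two groups."""
    return pearson_chi2([[crossed_a, total_a - crossed_a],
                         [crossed_b, total_b - crossed_b]])


def two_sample_t(group_a, group_b) -> tuple[float, float, float]:
    """Student's t-test (pooled variance), two-sided.

    Returns (t, df, p).  Zero pooled variance with equal means gives t = 0,
    p = 1; with unequal means the statistic is undefined and rejected.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(df), float(p)


def cohens_d(m1: float, sd1: float, n1: int,
             m2: float, sd2: float, n2: int) -> float:
    """Pooled-SD Cohen's d from group moments, reported as a magnitude."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2)
                       / (n1 + n2 - 2))
    if pooled == 0.0:
        raise ValueError("zero pooled SD: d undefined")
    return abs(m2 - m1) / pooled


def item_comparison_report(items: pd.DataFrame,
                           not_labels: Mapping[int, bool],
                           item_cutoffs: Mapping[tuple[str, int], tuple[float, str]]
                           ) -> pd.DataFrame:
    """Per-item OT-vs-NOT comparison at the session-six battery.

    ``items`` holds one row per (patient, instrument, item) with a ``value``
    column of recoded responses; pairwise deletion applies (each item uses
    the patients observed on it).  ``item_cutoffs`` maps (instrument, item)
    to (cutoff, direction) for the percent-crossing columns.  Items observed
    in only one group are skipped with a note.
    """
    labels = pd.Series(not_labels, dtype=bool)
    rows = []
    for (instrument, item), grp in items.groupby(["instrument", "item"],
                                                 sort=True):
        grp = grp.dropna(subset=["value"])
        grp = grp[grp["patient_id"].isin(labels.index)]
        is_not = labels.loc[grp["patient_id"]].to_numpy()
        a = grp.loc[~is_not, "value"].to_numpy(dtype=float)  # OT
        b = grp.loc[is_not, "value"].to_numpy(dtype=float)   # NOT
        row = {"instrument": instrument, "item": item,
               "n_ot": a.size, "n_not": b.size}
        if a.size < 2 or b.size < 2:
            row.update(t=np.nan, df=np.nan, p=np.nan,
                       note="observed in one group only")
        else:
            try:
                t, df, p = two_sample_t(a, b)
            except ValueError:
                t, df, p = np.nan, np.nan, np.nan
            row.update(t=t, df=df, p=p, note="")
        cutoff = item_cutoffs.get((instrument, item))
        if cutoff is not None:
            c, direction = cutoff
            crossed = (lambda v: v <= c) if direction == "at_or_below" \
                else (lambda v: v >= c)
            row["pct_crossed_ot"] = (100.0 * np.mean(crossed(a))
                                     if a.size else np.nan)
            row["pct_crossed_not"] = (100.0 * np.mean(crossed(b))
                                      if b.size else np.nan)
        else:
            row["pct_crossed_ot"] = np.nan
            row["pct_crossed_not"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
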