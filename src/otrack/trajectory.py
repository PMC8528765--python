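"""Nearest-neighbor expected recovery curves and the dynamic failure boundary.

For each index patient, the expected treatment response is modeled from the
archival patients most similar to them.  The steps, repeated at every session
from 6 to 30:

1. Filter the archival pool to *improving* patients — those whose HSCL-11
   impairment falls over log-time (negative OLS coefficient on ln(session)).
2. Rank the remaining archival patients by root-mean-square distance between
   the index patient's observed HSCL scores from intake up to the current
   session and the archival scores at the same sessions; keep the ``k``
   nearest.
3. Fit a two-level linear mixed model on the neighbors' sessions: HSCL
   regressed on ln(session), total sessions T, and their interaction, with a
   random intercept per neighbor.
4. The failure boundary at session ``s`` is the upper limit of the 90%
   confidence interval of a *new patient's* score:
   ``upper = expected + z_0.95 * SE`` with
   ``SE² = x' cov(β̂) x + σ²_patient + σ²_residual``.

A new-observation prediction interval (rather than a mean-only confidence
band) is used deliberately: a mean band narrows with neighbor count and
would flag nearly every patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TrajectoryConfig",
    "ArchivalPatient",
    "ReferencePool",
    "ExpectedTrajectoryModel",
    "FailureBoundary",
    "fit_patient_slope",
    "select_neighbors",
    "fit_expected_model",
    "boundary",
    "dynamic_boundary_sequence",
]

#: Classification window: boundary defined from session 6 through session 30.
SESSION_WINDOW = (6, 30)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Tunables of the expected-response model.

    k
        Neighbor count (default 50).
    level
        One-sided coverage of the failure boundary; 0.95 puts the boundary at
        the upper limit of the two-sided 90% interval (z ≈ 1.645).
    improving_only
        Restrict the pool to archival patients with improving trajectories.
    t_query
        How to choose the total-sessions covariate for the index patient when
        their planned length is unknown: "known" uses the supplied value,
        "pool_median" falls back to the median archival length.
    """

    k: int = 50
    level: float = 0.95
    improving_only: bool = True
    t_query: str = "known"
    session_window: tuple[int, int] = SESSION_WINDOW


@dataclass(frozen=True)
class ArchivalPatient:
    """One archival trajectory: session-wise HSCL plus derived quantities."""

    patient_id: int
    sessions: tuple[int, ...]
    hscl: tuple[float, ...]
    total_sessions: int
    slope: float | None  # OLS coefficient on ln(session); None if < 3 sessions
    intake: float

    @property
    def improving(self) -> bool:
        """Successful course of treatment = falling impairment over log-time."""
        return self.slope is not None and self.slope < 0


class ReferencePool:
    """Archival trajectories queried by the nearest-neighbor selection."""

    def __init__(self, patients: Sequence[ArchivalPatient]):
        self.patients = list(patients)
        self._by_id = {p.patient_id: p for p in self.patients}

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id: int) -> ArchivalPatient:
        return self._by_id[patient_id]

    @classmethod
    def from_trajectories(
        cls, trajectories: Mapping[int, Mapping[int, float]]
    ) -> "ReferencePool":
        """Build a pool from {patient_id: {session: hscl}} mappings."""
        patients = []
        for pid, traj in trajectories.items():
            sessions = tuple(sorted(traj))
            scores = tuple(float(traj[s]) for s in sessions)
            slope = fit_patient_slope(sessions, scores)
            patients.append(
                ArchivalPatient(
                    patient_id=pid,
                    sessions=sessions,
                    hscl=scores,
                    total_sessions=max(sessions),
                    slope=slope,
                    intake=scores[0],
                )
            )
        return cls(patients)

    def improving(self) -> list[ArchivalPatient]:
        return [p for p in self.patients if p.improving]

    def median_total_sessions(self) -> float:
        return float(np.median([p.total_sessions for p in self.patients]))

    def intake_sd(self) -> float:
        """SD of archival intake scores (feeds the reliable-change criterion)."""
        return float(np.std([p.intake for p in self.patients], ddof=1))


def fit_patient_slope(sessions: Sequence[int],
                      hscl: Sequence[float]) -> float | None:
    """OLS coefficient of HSCL impairment on ln(session).

    Negative = improvement.  Returns ``None`` with fewer than 3 observed
    sessions (such patients are excluded from the pool).
    """
    s = np.asarray(sessions, dtype=float)
    y = np.asarray(hscl, dtype=float)
    if s.size < 3:
        return None
    x = np.log(s)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return 0.0
    return float(xc @ (y - y.mean()) / denom)


def select_neighbors(patient_history: Mapping[int, float],
                     pool: ReferencePool,
                     k: int,
                     improving_only: bool = True) -> list[int]:
    """Ids of the ``k`` archival patients nearest to the observed history.

    Distance is the root-mean-square difference over the query's observed
    sessions (intake through the current session); scaling by the number of
    shared sessions keeps early and late queries comparable.  Archival
    patients lacking any required session are excluded before ranking.  Ties
    break on archival id.  If fewer than ``k`` candidates remain, all are
    returned with a warning; zero candidates is an error (the boundary is
    undefined for that session).
    """
    required = sorted(patient_history)
    q = np.array([patient_history[s] for s in required], dtype=float)
    candidates = pool.improving() if improving_only else pool.patients
    scored: list[tuple[float, int]] = []
    for p in candidates:
        idx = {s: i for i, s in enumerate(p.sessions)}
        if any(s not in idx for s in required):
            continue
        a = np.array([p.hscl[idx[s]] for s in required])
        dist = float(np.sqrt(np.mean((q - a) ** 2)))
        scored.append((dist, p.patient_id))
    if not scored:
        raise ValueError("no eligible archival neighbors; boundary undefined")
    scored.sort()
    if len(scored) < k:
        warnings.warn(
            f"only {len(scored)} eligible neighbors (requested {k}); using all",
            stacklevel=2,
        )
    return [pid for _, pid in scored[:k]]


@dataclass
class ExpectedTrajectoryModel:
    """Fitted neighbor model: fixed effects over {1, ln s, T, ln s · T}.

    ``has_T_terms`` is False when the design was rank-deficient (all
    neighbors sharing one T) and the T columns were dropped.
    """

    params: np.ndarray
    cov_params: np.ndarray
    var_patient: float
    var_resid: float
    neighbor_ids: tuple[int, ...]
    has_T_terms: bool = True
    pooled_ols: bool = False

    def design_row(self, session: float, T: float) -> np.ndarray:
        ln_s = np.log(session)
        if self.has_T_terms:
            return np.array([1.0, ln_s, T, ln_s * T])
        return np.array([1.0, ln_s])

    def predict(self, session: float, T: float) -> float:
        return float(self.design_row(session, T) @ self.params)


def fit_expected_model(pool: ReferencePool,
                       neighbor_ids: Sequence[int]) -> ExpectedTrajectoryModel:
    """Fit the expected-response mixed model on the selected neighbors.

    Sessions nested in neighbors with a random intercept; falls back to
    pooled OLS (with a warning) when the intercept variance is estimated at
    zero or the mixed fit fails to converge.
    """
    rows = []
    for pid in neighbor_ids:
        p = pool[pid]
        for s, y in zip(p.sessions, p.hscl):
            rows.append((pid, float(s), float(y), float(p.total_sessions)))
    if len({pool[pid].patient_id for pid in neighbor_ids}) < 2:
        # single-neighbor degenerate case: plain OLS on that trajectory
        return _fit_ols(rows, neighbor_ids)
    n_sess = pd.Series([r[0] for r in rows]).value_counts()
    if (n_sess < 2).all():
        raise ValueError("need neighbors with >=2 sessions each")

    df = pd.DataFrame(rows, columns=["pid", "session", "y", "T"])
    df["ln_s"] = np.log(df["session"])
    has_T = df["T"].nunique() > 1
    if not has_T:
        warnings.warn("all neighbors share one total-session count; "
                      "dropping T and interaction terms", stacklevel=2)
        X = df[["ln_s"]].to_numpy()
    else:
        X = np.column_stack([df["ln_s"], df["T"], df["ln_s"] * df["T"]])
    exog = sm.add_constant(X, has_constant="add")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["y"].to_numpy(), exog,
                               groups=df["pid"].to_numpy())
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        var_patient = float(np.asarray(res.cov_re)[0, 0])
        if not np.isfinite(var_patient) or var_patient <= 1e-10:
            raise np.linalg.LinAlgError("degenerate random-intercept variance")
        return ExpectedTrajectoryModel(
            params=np.asarray(res.fe_params, dtype=float),
            cov_params=np.asarray(res.cov_params())[: exog.shape[1], : exog.shape[1]],
            var_patient=var_patient,
            var_resid=float(res.scale),
            neighbor_ids=tuple(neighbor_ids),
            has_T_terms=has_T,
        )
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("mixed fit degenerate; falling back to pooled OLS",
                      stacklevel=2)
        return _fit_ols(rows, neighbor_ids, has_T=has_T)


def _fit_ols(rows, neighbor_ids, has_T: bool | None = None) -> ExpectedTrajectoryModel:
    df = pd.DataFrame(rows, columns=["pid", "session", "y", "T"])
    df["ln_s"] = np.log(df["session"])
    if has_T is None:
        has_T = df["T"].nunique() > 1
    if has_T:
        X = np.column_stack([df["ln_s"], df["T"], df["ln_s"] * df["T"]])
    else:
        X = df[["ln_s"]].to_numpy()
    exog = sm.add_constant(X, has_constant="add")
    res = sm.OLS(df["y"].to_numpy(), exog).fit()
    return ExpectedTrajectoryModel(
        params=np.asarray(res.params, dtype=float),
        cov_params=np.asarray(res.cov_params(), dtype=float),
        var_patient=0.0,
        var_resid=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        neighbor_ids=tuple(neighbor_ids),
        has_T_terms=bool(has_T),
        pooled_ols=True,
    )


def boundary(model: ExpectedTrajectoryModel, T_query: float, session: int,
             level: float = 0.95,
             session_window: tuple[int, int] = SESSION_WINDOW
             ) -> tuple[float, float]:
    """Expected value and failure boundary at one session.

    ``upper = expected + z_level * SE`` where the SE is a new-patient
    prediction standard error (fixed-effect uncertainty + patient intercept
    variance + residual variance).  Defined only inside the session window.
    """
    lo, hi = session_window
    if not (lo <= session <= hi):
        raise ValueError(f"boundary undefined outside sessions [{lo}, {hi}]")
    x = model.design_row(session, T_query)
    expected = float(x @ model.params)
    var = float(x @ model.cov_params @ x) + model.var_patient + model.var_resid
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(level))
    return expected, expected + z * se


@dataclass
class FailureBoundary:
    """Per-session expected value and upper failure boundary for one patient."""

    patient_id: int
    sessions: tuple[int, ...]
    expected: tuple[float, ...]
    upper: tuple[float, ...]

    def at(self, session: int) -> tuple[float, float] | None:
        try:
            i = self.sessions.index(session)
        except ValueError:
            return None
        return self.expected[i], self.upper[i]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_id, "session": self.sessions,
             "expected": self.expected, "upper": self.upper}
        )


def dynamic_boundary_sequence(patient_id: int,
                              history: Mapping[int, float],
                              pool: ReferencePool,
                              config: TrajectoryConfig = TrajectoryConfig(),
                              total_sessions: int | None = None
                              ) -> FailureBoundary:
    """Re-select neighbors and refit the model at every classified session.

    ``history`` maps session -> observed HSCL.  For each session ``s`` in the
    window (up to the last observed session), neighbors are selected on the
    history *up to* ``s``, the model refit, and the boundary recorded at
    ``s``.  The total-sessions covariate is the patient's own count when
    known, else the pool median.
    """
    lo, hi = config.session_window
    observed = sorted(history)
    if len([s for s in observed if s >= lo]) == 0 or max(observed) < lo:
        raise ValueError(f"patient needs sessions through {lo} for a boundary")
    if total_sessions is None or config.t_query == "pool_median":
        T_query = pool.median_total_sessions()
    else:
        T_query = float(total_sessions)
    sessions, exp_vals, up_vals = [], [], []
    last = min(hi, max(observed))
    for s in range(lo, last + 1):
        hist = {t: v for t, v in history.items() if t <= s}
        ids = select_neighbors(hist, pool, config.k, config.improving_only)
        model = fit_expected_model(pool, ids)
        e, u = boundary(model, T_query, s, config.level, config.session_window)
        sessions.append(s)
        exp_vals.append(e)
        up_vals.append(u)
    return FailureBoundary(patient_id, tuple(sessions), tuple(exp_vals),
                           tuple(up_vals))
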