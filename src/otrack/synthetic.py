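"""Synthetic archival pools and study cohorts.

No clinical data accompany this package, so every downstream stage is
exercised on synthetic cohorts that reproduce the structure the analysis
assumes:

* three levels — sessions nested in patients nested in therapists;
* HSCL-11 impairment following a log-time recovery law
  ``y = b0 + u_therapist + u_patient + b1*ln(s) + b2*T + b3*ln(s)*T + eps``
  with total sessions ``T`` drawn from a truncated normal;
* a latent *not-on-track* subpopulation that (a) receives an additive
  deterioration bump on the HSCL trajectory from a random onset session and
  (b) shows shifted battery-score distributions: more risk endorsement, more
  life events, less social support, slightly lower motivation, and longer
  treatments (standardized difference ~0.56 on session count);
* item-level Likert responses obtained by discretizing latent Gaussian
  scores, so reversal, imputation and item cut-off logic are all exercised
  (set ``discretize_items=False`` for exact continuous trajectories in
  numerical tests);
* batteries (ASC, ASQ, OQ risk items) at intake and every fifth session.

Default sizes mirror the study setting (413 patients, 65 therapists,
archival pool of 1234); the latent-group battery means are calibrated so
that roughly a quarter of on-track and 40% of not-on-track patients endorse
risk, and the other domain crossing rates fall in the mid single digits to
~45% — the regime the method is meant to operate in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .trajectory import ArchivalPatient, ReferencePool, fit_patient_slope

__all__ = ["CohortConfig", "Cohort", "generate_archival", "generate_cohort",
           "simulate_glmm_dataset", "write_long_csv", "read_long_csv"]

BATTERY_SCALES = ("ASC_TA", "ASC_SS", "ASC_MO", "ASC_LE",
                  "ASQ_concealing", "ASQ_tolerating", "ASQ_adjusting")

# (instrument, item ids, items per point of the generated score)
_SCALE_ITEMS = {
    "ASC_TA": ("ASC", tuple(range(1, 12)), "sum"),
    "ASC_SS": ("ASC", tuple(range(12, 23)), "sum"),
    "ASC_MO": ("ASC", tuple(range(23, 32)), "sum"),
    "ASC_LE": ("ASC", tuple(range(32, 41)), "sum"),
    "ASQ_concealing": ("ASQ", tuple(range(1, 9)), "mean"),
    "ASQ_tolerating": ("ASQ", tuple(range(9, 14)), "mean"),
    "ASQ_adjusting": ("ASQ", tuple(range(14, 21)), "mean"),
}

# reversed items are written back on the raw (pre-recoding) scale
_REVERSED = {
    "ASC": frozenset({4, 8, 18, 22, 25, 27}) | frozenset(range(32, 41)),
    "ASQ": frozenset(range(1, 9)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the generator (defaults = study setting)."""

    n_therapists: int = 65
    n_patients: int = 413
    archival_n: int = 1234
    not_prevalence: float = 140 / 413

    # fixed effects of the log-time recovery law (HSCL units)
    beta0: float = 1.65
    beta_ln_s: float = -0.50
    beta_T: float = 0.005
    beta_ln_s_T: float = 0.006

    # variance components (standard deviations, HSCL units)
    sigma_therapist: float = 0.10
    sigma_patient: float = 0.45
    #: SD of the per-patient random slope on ln(session): patients recover at
    #: different rates, which keeps archival neighbors heterogeneous even
    #: after matching on early-course scores
    sigma_slope: float = 0.15
    sigma_resid: float = 0.15
    #: lag-1 autocorrelation of the session residuals (symptom states
    #: persist across neighbouring sessions; marginal SD stays sigma_resid)
    resid_ar1: float = 0.6

    # total-session distribution (truncated normal, rounded to integers)
    sessions_mean_ot: float = 24.09
    sessions_mean_not: float = 32.07
    sessions_sd: float = 14.2
    sessions_min: int = 1
    sessions_max: int = 80
    archival_sessions_mean: float = 27.0
    archival_sessions_sd: float = 15.0
    archival_sessions_min: int = 3
    archival_nonimproving_frac: float = 0.20
    archival_deterioration_slope: float = 0.15

    # not-on-track deterioration bump
    bump_magnitude: float = 0.8           # = 4 x sigma_resid by default
    onset_range: tuple[int, int] = (4, 20)

    # battery-score distributions per latent group
    battery_means_ot: Mapping[str, float] = field(default_factory=lambda: {
        "ASC_TA": 49.0, "ASC_SS": 30.0, "ASC_MO": 41.0, "ASC_LE": 31.0,
        "ASQ_concealing": 3.01, "ASQ_tolerating": 2.97, "ASQ_adjusting": 2.45,
    })
    battery_sds: Mapping[str, float] = field(default_factory=lambda: {
        "ASC_TA": 5.0, "ASC_SS": 5.2, "ASC_MO": 5.0, "ASC_LE": 4.9,
        "ASQ_concealing": 0.74, "ASQ_tolerating": 0.68, "ASQ_adjusting": 0.75,
    })
    battery_shifts_not: Mapping[str, float] = field(default_factory=lambda: {
        "ASC_TA": -2.5, "ASC_SS": -2.2, "ASC_MO": -0.8, "ASC_LE": -2.8,
        "ASQ_concealing": -0.07, "ASQ_tolerating": -0.07,
        "ASQ_adjusting": -0.07,
    })
    #: P(response category) for the three risk items, per latent group.
    risk_probs_ot: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "hscl_suicide": (0.70, 0.18, 0.08, 0.04),       # values 0..3
            "oq5": (0.60, 0.28, 0.07, 0.03, 0.02),          # values 1..5
            "oq18": (0.75, 0.19, 0.03, 0.02, 0.01),
        })
    risk_probs_not: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "hscl_suicide": (0.60, 0.20, 0.13, 0.07),
            "oq5": (0.55, 0.29, 0.09, 0.04, 0.03),
            "oq18": (0.70, 0.21, 0.055, 0.025, 0.015),
        })

    item_noise_hscl: float = 0.5
    item_noise_battery: float = 0.6
    battery_session_noise_frac: float = 0.30
    discretize_items: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.not_prevalence <= 1.0):
            raise ValueError("not_prevalence must lie in [0, 1]")
        for s in (self.sigma_therapist, self.sigma_patient, self.sigma_resid):
            if s < 0:
                raise ValueError("variance components must be >= 0")

    @property
    def target_sessions_d(self) -> float:
        """Standardized latent-group difference in session count."""
        return abs(self.sessions_mean_not - self.sessions_mean_ot) / self.sessions_sd


def _trunc_normal_int(rng, mean, sd, lo, hi, size):
    """Truncated-normal draw rounded to integers (resampling tails)."""
    out = np.empty(size, dtype=int)
    remaining = np.arange(size)
    draws = rng.normal(mean, sd, size)
    for _ in range(1000):
        ok = (draws >= lo) & (draws <= hi)
        out[remaining[ok]] = np.round(draws[ok]).astype(int)
        remaining = remaining[~ok]
        if remaining.size == 0:
            break
        draws = rng.normal(mean, sd, remaining.size)
    else:
        out[remaining] = int(np.clip(np.round(mean), lo, hi))
    return out


def _latent_curve(cfg: CohortConfig, sessions: np.ndarray, T: int,
                  u_t: float, u_p: float, u_s: float = 0.0) -> np.ndarray:
    ln_s = np.log(sessions)
    return (cfg.beta0 + u_t + u_p + (cfg.beta_ln_s + u_s) * ln_s
            + cfg.beta_T * T + cfg.beta_ln_s_T * ln_s * T)


def _resid_series(rng, cfg: CohortConfig, n: int) -> np.ndarray:
    """Stationary AR(1) session residuals with marginal SD ``sigma_resid``."""
    rho = cfg.resid_ar1
    eps = rng.normal(0.0, cfg.sigma_resid, n)
    if rho == 0.0 or n == 0:
        return eps
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return out


def _hscl_items_one_session(rng, cfg: CohortConfig, latent: float,
                            suicide_probs) -> np.ndarray:
    """The 11 HSCL item responses for one session.

    Items 1-10 discretize the latent impairment; item 11 (suicidal ideation)
    is drawn from its own categorical distribution.  The archival pool and
    the study cohort share this measurement process, so the residual
    variance the neighbor model estimates matches the noise of the scores it
    is asked to bound.
    """
    vals = _discretize(rng, np.full(10, latent), 0, 3,
                       cfg.item_noise_hscl, cfg.discretize_items)
    p = np.asarray(suicide_probs)
    if cfg.discretize_items:
        sui = float(rng.choice(len(p), p=p / p.sum()))
    else:
        sui = float(np.clip(latent, 0.0, 3.0))
    return np.append(vals.astype(float), sui)


def generate_archival(config: CohortConfig, seed: int) -> ReferencePool:
    """Generate the archival reference pool of HSCL trajectories.

    Each archival patient has complete session-wise HSCL scores for sessions
    1..T; a configurable fraction follows a mildly deteriorating course (and
    is therefore excluded by the improving-patients filter downstream).  The
    pool carries a ``truth`` attribute with the generating random effects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    cfg = config
    T = _trunc_normal_int(rng, cfg.archival_sessions_mean,
                          cfg.archival_sessions_sd,
                          cfg.archival_sessions_min, cfg.sessions_max,
                          cfg.archival_n)
    therapist = rng.integers(0, cfg.n_therapists, cfg.archival_n)
    u_ther = rng.normal(0.0, cfg.sigma_therapist, cfg.n_therapists)
    u_pat = rng.normal(0.0, cfg.sigma_patient, cfg.archival_n)
    u_slope = rng.normal(0.0, cfg.sigma_slope, cfg.archival_n)
    deteriorating = rng.random(cfg.archival_n) < cfg.archival_nonimproving_frac
    patients, truth_rows = [], []
    for i in range(cfg.archival_n):
        sessions = np.arange(1, T[i] + 1)
        if deteriorating[i]:
            c = replace(cfg, beta_ln_s=cfg.archival_deterioration_slope,
                        beta_ln_s_T=0.0)
        else:
            c = cfg
        y = _latent_curve(c, sessions, T[i], u_ther[therapist[i]], u_pat[i],
                          u_slope[i])
        y = y + _resid_series(rng, cfg, sessions.size)
        y = np.clip(y, 0.0, 3.0)
        if cfg.discretize_items:
            # same measurement process as the study cohort: score = item mean
            y = np.array([
                _hscl_items_one_session(
                    rng, cfg, y[k], cfg.risk_probs_ot["hscl_suicide"]).mean()
                for k in range(sessions.size)
            ])
        slope = fit_patient_slope(sessions, y)
        patients.append(ArchivalPatient(
            patient_id=i, sessions=tuple(int(s) for s in sessions),
            hscl=tuple(float(v) for v in y), total_sessions=int(T[i]),
            slope=slope, intake=float(y[0]),
        ))
        truth_rows.append((i, int(therapist[i]),
                           float(u_ther[therapist[i]]), float(u_pat[i]),
                           bool(deteriorating[i])))
    pool = ReferencePool(patients)
    pool.truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "therapist_id", "u_therapist", "u_patient",
                 "deteriorating"],
    )
    return pool


@dataclass
class Cohort:
    """Generated study cohort: long-format item responses + generator truth."""

    items: pd.DataFrame   # patient_id, therapist_id, session, instrument, item, value
    truth: pd.DataFrame   # patient_id, therapist_id, latent_status, onset, total_sessions
    config: CohortConfig

    def battery_sessions(self, total: int) -> list[int]:
        return [s for s in ([1] + list(range(5, total + 1, 5)))]


def battery_session_list(total: int) -> list[int]:
    """Battery pattern: intake plus every fifth session — {1, 5, 10, 15, ...}."""
    return [1] + [s for s in range(5, total + 1, 5)]


def _discretize(rng, target: np.ndarray, lo: int, hi: int,
                noise: float, discretize: bool) -> np.ndarray:
    if not discretize:
        return np.clip(target, lo, hi)
    vals = rng.normal(target, noise)
    return np.clip(np.round(vals), lo, hi).astype(int)


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate a full study cohort in the long item-response format.

    HSCL-11 items appear at every session; ASC/ASQ items and the two OQ-30
    risk items at intake and every fifth session.  The ``truth`` table holds
    the latent OT/NOT label, bump onset and total session count per patient
    (generator truth, for evaluation only).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    therapist = rng.integers(0, cfg.n_therapists, cfg.n_patients)
    u_ther = rng.normal(0.0, cfg.sigma_therapist, cfg.n_therapists)
    u_pat = rng.normal(0.0, cfg.sigma_patient, cfg.n_patients)
    u_slope = rng.normal(0.0, cfg.sigma_slope, cfg.n_patients)
    is_not = rng.random(cfg.n_patients) < cfg.not_prevalence
    T = np.where(
        is_not,
        _trunc_normal_int(rng, cfg.sessions_mean_not, cfg.sessions_sd,
                          cfg.sessions_min, cfg.sessions_max, cfg.n_patients),
        _trunc_normal_int(rng, cfg.sessions_mean_ot, cfg.sessions_sd,
                          cfg.sessions_min, cfg.sessions_max, cfg.n_patients),
    )
    # deterioration onset inside the patient's observable window, so every
    # latent-NOT patient with >= 6 sessions actually deteriorates on record
    onset_hi = np.maximum(cfg.onset_range[0],
                          np.minimum(cfg.onset_range[1], T - 1))
    onset = rng.integers(cfg.onset_range[0], onset_hi + 1, cfg.n_patients)

    recs: list[tuple] = []
    truth_rows = []
    for i in range(cfg.n_patients):
        t_i = int(T[i])
        sessions = np.arange(1, t_i + 1)
        latent = _latent_curve(cfg, sessions, t_i, u_ther[therapist[i]],
                               u_pat[i], u_slope[i])
        latent = latent + _resid_series(rng, cfg, t_i)
        if is_not[i]:
            latent = latent + cfg.bump_magnitude * (sessions >= onset[i])
        latent = np.clip(latent, 0.0, 3.0)

        group_probs = cfg.risk_probs_not if is_not[i] else cfg.risk_probs_ot
        # HSCL items 1-10 from the latent curve, item 11 = suicidal ideation
        for s_idx, s in enumerate(sessions):
            vals = _hscl_items_one_session(rng, cfg, latent[s_idx],
                                           group_probs["hscl_suicide"])
            for item, v in enumerate(vals, start=1):
                recs.append((i, therapist[i], int(s), "HSCL11", item, float(v)))

        # battery traits stay stable within patient; small per-battery noise
        traits = {}
        for scale in BATTERY_SCALES:
            mean = cfg.battery_means_ot[scale]
            if is_not[i]:
                mean += cfg.battery_shifts_not[scale]
            sd = cfg.battery_sds[scale]
            noise_sd = cfg.battery_session_noise_frac * sd
            trait_sd = np.sqrt(max(sd ** 2 - noise_sd ** 2, 0.0))
            traits[scale] = (rng.normal(mean, trait_sd), noise_sd)

        for s in battery_session_list(t_i):
            for scale in BATTERY_SCALES:
                instrument, item_ids, agg = _SCALE_ITEMS[scale]
                trait, noise_sd = traits[scale]
                score = rng.normal(trait, noise_sd)
                per_item = score / len(item_ids) if agg == "sum" else score
                vals = _discretize(rng, np.full(len(item_ids), per_item),
                                   1, 5, cfg.item_noise_battery,
                                   cfg.discretize_items)
                for item, v in zip(item_ids, vals):
                    raw = 6 - v if item in _REVERSED[instrument] else v
                    recs.append((i, therapist[i], int(s), instrument,
                                 int(item), float(raw)))
            for key, item in (("oq5", 5), ("oq18", 18)):
                p = np.asarray(group_probs[key])
                v = 1 + int(rng.choice(len(p), p=p / p.sum()))
                recs.append((i, therapist[i], int(s), "OQ30", item, float(v)))

        truth_rows.append((i, int(therapist[i]),
                           "NOT_latent" if is_not[i] else "OT_latent",
                           int(onset[i]) if is_not[i] else -1, t_i,
                           float(u_pat[i])))

    items = pd.DataFrame(
        recs, columns=["patient_id", "therapist_id", "session", "instrument",
                       "item", "value"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "therapist_id", "latent_status",
                             "onset_session", "total_sessions", "u_patient"],
    )
    return Cohort(items=items, truth=truth, config=cfg)


def simulate_glmm_dataset(n_patients: int = 400,
                          n_therapists: int = 40,
                          sessions_per_patient: int = 12,
                          beta: Mapping[str, float] | None = None,
                          sigma_patient: float = 1.5,
                          sigma_therapist: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate per-session data directly from the nested logistic model.

    Used by parameter-recovery and calibration studies of the group
    statistics.  ``beta`` maps predictor names to true log-odds effects;
    recognized predictors are ``session`` (6, 7, ...), ``risk`` (0-3 count,
    Binomial(3, 0.15) per session) and any other name, generated as a
    patient-level standard-normal trait constant across sessions (the
    carried-forward battery score pattern).  ``intercept`` sets the baseline.
    """
    beta = dict(beta or {})
    b0 = beta.pop("intercept", -2.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    ther_of_pat = rng.integers(0, n_therapists, n_patients)
    u_t = rng.normal(0.0, sigma_therapist, n_therapists)
    u_p = rng.normal(0.0, sigma_patient, n_patients)
    rows = []
    sessions = np.arange(6, 6 + sessions_per_patient)
    for i in range(n_patients):
        eta = np.full(sessions.size, b0 + u_t[ther_of_pat[i]] + u_p[i])
        cols = {}
        for name, b in beta.items():
            if name == "session":
                x = sessions.astype(float)
            elif name == "risk":
                x = rng.binomial(3, 0.15, sessions.size).astype(float)
            else:
                x = np.full(sessions.size, rng.normal())
            cols[name] = x
            eta = eta + b * x
        y = rng.random(sessions.size) < 1.0 / (1.0 + np.exp(-eta))
        for j, s in enumerate(sessions):
            rows.append({"patient_id": i, "therapist_id": int(ther_of_pat[i]),
                         "session": int(s), "not_on_track": int(y[j]),
                         **{k: v[j] for k, v in cols.items()}})
    return pd.DataFrame(rows)


def write_long_csv(cohort: Cohort, path, truth_path=None) -> None:
    """Write the long-format item CSV (and optionally the truth sidecar)."""
    cohort.items.to_csv(path, index=False)
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, index=False)


def read_long_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"patient_id", "therapist_id", "session", "instrument",
                "item", "value"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns: {sorted(missing)}")
    return df
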