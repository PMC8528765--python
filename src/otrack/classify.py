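"""On-track / not-on-track state machine with the reliable-change return rule.

A patient starts on track (OT).  From session 6 onward, whenever the observed
HSCL-11 impairment *strictly* exceeds the failure boundary the patient goes
not-on-track (NOT) and a warning signal is logged.  To return on track two
conditions must hold simultaneously: the observation falls below the boundary
AND the improvement relative to the impairment level at the first boundary
crossing is reliable — a Jacobson–Truax reliable change index of at least
1.96, with the standard error of the difference built from the archival
intake SD and the instrument's internal consistency (HSCL-11 α = .87 here).

For group analyses a patient counts as NOT if any session in the 6–30 window
was NOT ("ever-NOT"); patients with fewer than six sessions are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .trajectory import FailureBoundary

__all__ = [
    "ReliableChangeCriterion",
    "TrackStatus",
    "reliable_change_index",
    "step",
    "classify_cohort",
    "OT",
    "NOT",
]

OT = "OT"
NOT = "NOT"


@dataclass(frozen=True)
class ReliableChangeCriterion:
    """Jacobson–Truax reliable-change parameters.

    ``s_diff = sd * sqrt(2) * sqrt(1 - reliability)``; change / s_diff ≥ z
    counts as reliable improvement.  ``reliability`` must be in (0, 1):
    a perfectly reliable instrument gives s_diff = 0 and is rejected.
    """

    sd: float
    reliability: float = 0.87
    z: float = 1.96

    def __post_init__(self) -> None:
        if not (0.0 < self.reliability < 1.0):
            raise ValueError("reliability must lie strictly in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @property
    def s_diff(self) -> float:
        return self.sd * math.sqrt(2.0) * math.sqrt(1.0 - self.reliability)


def reliable_change_index(x_ref: float, x_now: float,
                          crit: ReliableChangeCriterion) -> float:
    """RCI = (x_ref − x_now) / s_diff; positive for improvement (falling HSCL)."""
    return (x_ref - x_now) / crit.s_diff


@dataclass
class TrackStatus:
    """Per-patient OT/NOT history with the signal log.

    ``signal_log`` holds (session, event) pairs with events
    ``went_off_track``, ``stayed_off_track`` and ``back_on_track``.
    """

    patient_id: int
    state: str = OT
    states: dict[int, str] = field(default_factory=dict)
    first_crossing_session: int | None = None
    impairment_at_first_crossing: float = math.nan
    signal_log: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ever_not(self) -> bool:
        return any(v == NOT for v in self.states.values())

    @property
    def flag_color(self) -> str:
        """Case flag at the latest classified session: orange while NOT."""
        return "orange" if self.state == NOT else "green"


def step(status: TrackStatus, session: int, observed: float | None,
         boundary: tuple[float, float] | None,
         crit: ReliableChangeCriterion) -> TrackStatus:
    """Advance the state machine by one classified session (mutates status).

    * OT → NOT when the observation strictly exceeds the upper boundary
      (a tie stays OT); the first crossing's impairment level is recorded.
    * NOT → OT only when the observation is below the boundary AND the
      improvement since the first crossing is reliable (RCI ≥ z).
    * A missing observation or undefined boundary carries the state forward
      without an event.
    """
    if observed is None or boundary is None or not math.isfinite(observed):
        status.states[session] = status.state
        return status
    _, upper = boundary
    if status.state == OT:
        if observed > upper:
            status.state = NOT
            if status.first_crossing_session is None:
                status.first_crossing_session = session
                status.impairment_at_first_crossing = observed
            status.signal_log.append((session, "went_off_track"))
    else:
        back = (
            observed < upper
            and reliable_change_index(
                status.impairment_at_first_crossing, observed, crit
            ) >= crit.z
        )
        if back:
            status.state = OT
            status.signal_log.append((session, "back_on_track"))
        else:
            status.signal_log.append((session, "stayed_off_track"))
    status.states[session] = status.state
    return status


def classify_cohort(boundaries: Mapping[int, FailureBoundary],
                    observations: Mapping[int, Mapping[int, float]],
                    crit: ReliableChangeCriterion,
                    min_sessions: int = 6) -> dict[int, TrackStatus]:
    """Run the state machine for every patient with enough sessions.

    Patients whose observed sessions never reach ``min_sessions`` are
    excluded (classification starts at session six).  Returns one
    ``TrackStatus`` per retained patient; ``status.ever_not`` is the NOT
    group label used by the statistical comparisons.
    """
    out: dict[int, TrackStatus] = {}
    for pid in sorted(boundaries):
        obs = observations[pid]
        if max(obs) < min_sessions:
            continue
        fb = boundaries[pid]
        status = TrackStatus(patient_id=pid)
        for session in fb.sessions:
            b = fb.at(session)
            observed = obs.get(session)
            step(status, session, observed, b, crit)
        out[pid] = status
    return out
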