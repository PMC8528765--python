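"""Clinical-support-tool decision flow: per-domain orange/green flags.

The battery's scales are grouped into six clinical domains:

1. risk/suicidality (HSCL suicide item + OQ-30 items 5 and 18),
2. motivation (ASC MO),
3. therapeutic alliance (ASC TA),
4. life events (ASC LE),
5. social support (ASC SS),
6. emotion regulation (the three ASQ styles; the domain crosses when any
   constituent subscale crosses).

A domain is flagged orange — unlocking the corresponding clinical support
tool with its critical items — only for a patient who is currently NOT *and*
crosses the domain's cut-off.  For OT patients every flag stays green and no
tool is accessible, whatever the scores.  The one exception is the immediate
suicide alert (HSCL suicide item at/above its cut-off), which is raised
independently of track status as a separate event, not a domain flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .instruments import (Catalog, Instrument, RiskAssessment, ScaleScore,
                          default_catalog, domain_flag)

__all__ = [
    "DOMAINS",
    "DomainAlert",
    "CSTView",
    "map_domains",
    "evaluate",
    "session6_signal_table",
]

DOMAINS = (
    "risk_suicidality",
    "motivation",
    "therapeutic_alliance",
    "life_events",
    "social_support",
    "emotion_regulation",
)

#: Scales feeding each domain's cut-off decision.
DOMAIN_SCALES: dict[str, tuple[str, ...]] = {
    "motivation": ("ASC_MO",),
    "therapeutic_alliance": ("ASC_TA",),
    "life_events": ("ASC_LE",),
    "social_support": ("ASC_SS",),
    "emotion_regulation": ("ASQ_concealing", "ASQ_tolerating", "ASQ_adjusting"),
}


@dataclass(frozen=True)
class DomainAlert:
    """Flag state of one domain; the support tool opens only on orange."""

    domain: str
    flag: str  # "orange" | "green"
    cst_accessible: bool
    critical_items: frozenset[tuple[str, int]] = frozenset()

    def __post_init__(self) -> None:
        if self.cst_accessible != (self.flag == "orange"):
            raise ValueError("CST accessibility must mirror the orange flag")


@dataclass(frozen=True)
class CSTView:
    """Item-level view of an opened tool: critical items marked red."""

    domain: str
    items: tuple[tuple[str, int], ...]
    critical: frozenset[tuple[str, int]]
    reflection_prompt: str = ""

    def __post_init__(self) -> None:
        if not self.critical <= set(self.items):
            raise ValueError("critical items must belong to the domain's items")


def map_domains(scores: Mapping[str, ScaleScore],
                risk: RiskAssessment | None,
                catalog: Catalog | None = None) -> dict[str, bool | None]:
    """Reduce one battery's scale scores to per-domain cut-off inputs.

    Returns True/False per domain, or None where every constituent score is
    invalid (input missing).  Emotion regulation crosses when any of the
    three ASQ subscales crosses.
    """
    catalog = catalog or default_catalog()
    out: dict[str, bool | None] = {}
    out["risk_suicidality"] = risk.flag if risk is not None else None
    for domain, scale_names in DOMAIN_SCALES.items():
        flags = []
        for name in scale_names:
            sc = scores.get(name)
            if sc is None:
                continue
            f = domain_flag(sc, catalog[name])
            if f is not None:
                flags.append(f)
        out[domain] = any(flags) if flags else None
    return out


def evaluate(is_not: bool,
             domain_inputs: Mapping[str, bool | None],
             critical_items: Mapping[str, Iterable[tuple[str, int]]] | None = None,
             immediate_suicide: bool = False
             ) -> tuple[list[DomainAlert], list[str]]:
    """Apply the decision flow at one battery session.

    Returns the six domain alerts plus a list of status-independent events
    (currently only ``"immediate_suicide_alert"``, the red-bar signal).
    OT patients get green flags everywhere regardless of their scores.
    """
    critical_items = critical_items or {}
    alerts = []
    for domain in DOMAINS:
        crossed = bool(domain_inputs.get(domain))
        orange = is_not and crossed
        items = frozenset(critical_items.get(domain, ())) if orange else frozenset()
        alerts.append(
            DomainAlert(domain=domain, flag="orange" if orange else "green",
                        cst_accessible=orange, critical_items=items)
        )
    events = ["immediate_suicide_alert"] if immediate_suicide else []
    return alerts, events


def session6_signal_table(domain_crossings: pd.DataFrame,
                          not_labels: Mapping[int, bool]) -> pd.DataFrame:
    """Cross-tabulate domain cut-off crossings against OT/NOT at session six.

    ``domain_crossings`` holds one row per patient with boolean columns named
    after ``DOMAINS`` (the battery administered at session five, paired with
    the session-six track status) indexed by patient id.  Returns per domain
    — plus an ``any_domain`` aggregate — the 2×2 counts that feed the
    chi-square comparison.
    """
    df = domain_crossings.copy()
    labels = pd.Series(not_labels, dtype=bool)
    df = df.loc[df.index.intersection(labels.index)]
    labels = labels.loc[df.index]
    rows = []
    domains = list(DOMAINS) + ["any_domain"]
    crossing = df[list(DOMAINS)].fillna(False).astype(bool)
    crossing["any_domain"] = crossing.any(axis=1)
    for domain in domains:
        c = crossing[domain]
        rows.append({
            "domain": domain,
            "ot_crossed": int((c & ~labels).sum()),
            "ot_total": int((~labels).sum()),
            "not_crossed": int((c & labels).sum()),
            "not_total": int(labels.sum()),
        })
    out = pd.DataFrame(rows).set_index("domain")
    out["ot_pct"] = 100.0 * out["ot_crossed"] / out["ot_total"]
    out["not_pct"] = 100.0 * out["not_crossed"] / out["not_total"]
    return out
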