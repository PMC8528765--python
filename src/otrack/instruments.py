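"""Scoring and cut-off logic for the routine outcome monitoring battery.

Four self-report instruments are supported:

* **HSCL-11** — 11 items of depressive/anxious symptom distress on a 0–3
  Likert scale, answered before every session.  Scored as the item mean, so
  the total lives on the item scale (0–3) and partial batteries remain
  comparable.  Higher values indicate higher impairment.
* **ASC** (Assessment for Signal Clients) — 40 items on a 1–5 scale forming
  four subscales: therapeutic alliance (TA, 11 items), social support
  (SS, 11), motivation (MO, 9), and life events (LE, 9).  Subscales are item
  sums; after recoding reversed items, high values indicate high functioning.
  Published warning cut-offs: TA ≤ 39, SS ≤ 23, MO ≤ 32, LE ≤ 23; item
  cut-off ≤ 2.
* **ASQ** (Affective Style Questionnaire) — 20 items, 1–5, three emotion
  regulation styles: concealing (8 items, reversed), tolerating (5),
  adjusting (7).  Subscales are item means; cut-offs are mean − 1 SD of an
  archival outpatient sample (2.27 / 2.29 / 1.70); item cut-off ≤ 2.
* **OQ-30** — only items 5 (suicidal ideation) and 18 (criticism of
  drinking/drug use) are used here, as risk indicators with cut-off ≥ 3.

A suicidal-ideation HSCL item (cut-off ≥ 2) plus the two OQ-30 items form
the risk/suicidality domain; ``risk_assessment`` combines them.

Missing data follow the battery's scoring rule: a scale score is valid only
when strictly more than 80% of its items were answered, in which case
missing items are imputed with the mean of the observed items of that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Instrument",
    "ItemResponse",
    "ScaleDefinition",
    "ScaleScore",
    "RiskAssessment",
    "Catalog",
    "load_catalog",
    "default_catalog",
    "recode_reversed",
    "score_scale",
    "domain_flag",
    "item_flags",
    "compute_asq_cutoffs",
    "asq_cutoff_from_moments",
    "risk_assessment",
    "MIN_OBSERVED_FRACTION",
]

#: A scale score is valid only if n_observed / n_items exceeds this fraction.
MIN_OBSERVED_FRACTION = 0.80


class Instrument(str, Enum):
    HSCL11 = "HSCL11"
    ASC = "ASC"
    ASQ = "ASQ"
    OQ30 = "OQ30"


#: Inclusive Likert response range per instrument.
ITEM_RANGES: dict[Instrument, tuple[int, int]] = {
    Instrument.HSCL11: (0, 3),
    Instrument.ASC: (1, 5),
    Instrument.ASQ: (1, 5),
    Instrument.OQ30: (1, 5),
}


@dataclass(frozen=True)
class ItemResponse:
    """A single Likert item response; ``missing=True`` means unanswered."""

    instrument: Instrument
    item_id: int
    raw_value: int | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        if self.raw_value is None and not self.missing:
            object.__setattr__(self, "missing", True)
        if not self.missing:
            lo, hi = ITEM_RANGES[self.instrument]
            if not (lo <= self.raw_value <= hi):
                raise ValueError(
                    f"{self.instrument.value} item {self.item_id}: response "
                    f"{self.raw_value} outside [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class ScaleDefinition:
    """Item membership, reversal set, aggregation and cut-offs of one scale."""

    name: str
    instrument: Instrument
    item_ids: tuple[int, ...]
    reversed_item_ids: frozenset[int]
    aggregation: str  # "sum" | "mean"
    domain_cutoff: float | None
    cutoff_direction: str  # "at_or_below" | "at_or_above"
    item_cutoff: float | None

    def __post_init__(self) -> None:
        if not set(self.reversed_item_ids) <= set(self.item_ids):
            raise ValueError(f"{self.name}: reversed items not a subset of items")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError(f"{self.name}: unknown aggregation {self.aggregation}")
        if self.cutoff_direction not in ("at_or_below", "at_or_above"):
            raise ValueError(f"{self.name}: bad cutoff_direction")


@dataclass(frozen=True)
class ScaleScore:
    """Aggregated scale value with the missing-data bookkeeping.

    ``value`` is NaN when ``valid`` is False (fewer than the required
    fraction of items observed).
    """

    scale: str
    value: float
    n_observed: int
    valid: bool


@dataclass(frozen=True)
class RiskAssessment:
    """Combined risk/suicidality evaluation.

    severity
        Count of risk items at or above their cut-offs (0–3, higher = worse).
    flag
        True if any risk item crosses its cut-off.
    immediate
        True if the session-wise suicidal-ideation item crosses its cut-off;
        signalled independently of track status.
    """

    severity: int
    flag: bool
    immediate: bool


@dataclass(frozen=True)
class RiskItemSpec:
    instrument: Instrument
    item_id: int
    cutoff: float
    immediate: bool


class Catalog:
    """Versioned instrument catalog: scale definitions plus risk items."""

    def __init__(self, version: int, scales: dict[str, ScaleDefinition],
                 risk_items: tuple[RiskItemSpec, ...]):
        self.version = version
        self.scales = scales
        self.risk_items = risk_items

    def __getitem__(self, name: str) -> ScaleDefinition:
        return self.scales[name]

    @property
    def asc_scales(self) -> tuple[str, ...]:
        return ("ASC_TA", "ASC_SS", "ASC_MO", "ASC_LE")

    @property
    def asq_scales(self) -> tuple[str, ...]:
        return ("ASQ_concealing", "ASQ_tolerating", "ASQ_adjusting")


def load_catalog(path: str | None = None) -> Catalog:
    """Load the instrument catalog (the packaged one unless ``path`` given)."""
    if path is None:
        text = resources.files("otrack.data").joinpath("catalog.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    scales = {}
    for name, s in raw["scales"].items():
        scales[name] = ScaleDefinition(
            name=name,
            instrument=Instrument(s["instrument"]),
            item_ids=tuple(s["items"]),
            reversed_item_ids=frozenset(s["reversed"]),
            aggregation=s["aggregation"],
            domain_cutoff=s["domain_cutoff"],
            cutoff_direction=s["cutoff_direction"],
            item_cutoff=s["item_cutoff"],
        )
    risk = tuple(
        RiskItemSpec(Instrument(r["instrument"]), r["item"], r["cutoff"],
                     r["immediate"])
        for r in raw["risk_items"]
    )
    return Catalog(raw["version"], scales, risk)


_DEFAULT_CATALOG: Catalog | None = None


def default_catalog() -> Catalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog()
    return _DEFAULT_CATALOG


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------

def recode_reversed(responses: Iterable[ItemResponse],
                    scale: ScaleDefinition) -> list[ItemResponse]:
    """Recode reversed items so that high values indicate high functioning.

    On the 1–5 Likert scales a reversed response ``v`` becomes ``6 - v``
    (an involution; the midpoint 3 is fixed).  Missing responses and
    non-reversed items pass through unchanged.  Responses whose item id does
    not belong to the scale are rejected.
    """
    out = []
    ids = set(scale.item_ids)
    for r in responses:
        if r.instrument != scale.instrument or r.item_id not in ids:
            raise ValueError(
                f"item {r.instrument.value}:{r.item_id} does not belong to "
                f"scale {scale.name}"
            )
        if r.item_id in scale.reversed_item_ids and not r.missing:
            lo, hi = ITEM_RANGES[scale.instrument]
            if (lo, hi) != (1, 5):
                raise ValueError(
                    f"reversal defined only for 1-5 scales, not {scale.instrument}"
                )
            out.append(replace(r, raw_value=6 - r.raw_value))
        else:
            out.append(r)
    return out


def score_scale(responses: Iterable[ItemResponse],
                scale: ScaleDefinition) -> ScaleScore:
    """Aggregate item responses into a scale score with mean imputation.

    Reversals must already be applied.  If strictly more than 80% of the
    scale's items are observed, missing items are replaced by the mean of the
    observed items and the configured aggregation (sum or mean) is applied;
    otherwise the score is invalid (value NaN).
    """
    by_id: dict[int, float | None] = {i: None for i in scale.item_ids}
    for r in responses:
        if r.item_id not in by_id:
            raise ValueError(f"item {r.item_id} not in scale {scale.name}")
        if not r.missing:
            by_id[r.item_id] = float(r.raw_value)
    observed = [v for v in by_id.values() if v is not None]
    n_obs = len(observed)
    k = len(scale.item_ids)
    if n_obs / k <= MIN_OBSERVED_FRACTION:
        return ScaleScore(scale.name, float("nan"), n_obs, False)
    fill = float(np.mean(observed))
    values = [v if v is not None else fill for v in by_id.values()]
    agg = float(np.sum(values)) if scale.aggregation == "sum" else float(np.mean(values))
    return ScaleScore(scale.name, agg, n_obs, True)


def domain_flag(score: ScaleScore,
                scale: ScaleDefinition | None = None) -> bool | None:
    """Evaluate a domain cut-off: ``True`` when the score crosses it.

    ASC/ASQ functioning scales cross at-or-below their cut-off; risk-type
    scales at-or-above.  Invalid scores yield ``None`` (flag undefined).
    """
    if scale is None:
        scale = default_catalog()[score.scale]
    if scale.domain_cutoff is None:
        raise ValueError(f"scale {scale.name} has no domain cut-off")
    if not score.valid:
        return None
    if scale.cutoff_direction == "at_or_below":
        return score.value <= scale.domain_cutoff
    return score.value >= scale.domain_cutoff


def item_flags(responses: Iterable[ItemResponse],
               scale: ScaleDefinition) -> set[int]:
    """Items crossing the item cut-off (after recoding); missing never flag."""
    if scale.item_cutoff is None:
        return set()
    flagged = set()
    for r in responses:
        if r.missing:
            continue
        if scale.cutoff_direction == "at_or_below":
            if r.raw_value <= scale.item_cutoff:
                flagged.add(r.item_id)
        else:
            if r.raw_value >= scale.item_cutoff:
                flagged.add(r.item_id)
    return flagged


def compute_asq_cutoffs(
    archival_scores: Mapping[str, Sequence[float]]
) -> dict[str, float]:
    """Derive ASQ subscale cut-offs as mean − 1 SD of archival samples.

    The SD uses the n−1 denominator.  Samples of size < 2 are rejected.
    With archival moments mean 3.01 / SD 0.74 (concealing), 2.97 / 0.68
    (tolerating) and 2.45 / 0.75 (adjusting) this yields 2.27, 2.29, 1.70.
    """
    out = {}
    for name, sample in archival_scores.items():
        arr = np.asarray(sample, dtype=float)
        if arr.size < 2:
            raise ValueError(f"{name}: need at least 2 archival scores")
        out[name] = asq_cutoff_from_moments(float(arr.mean()),
                                            float(arr.std(ddof=1)))
    return out


def asq_cutoff_from_moments(mean: float, sd: float) -> float:
    """Cut-off = mean − 1·SD."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return mean - sd


def risk_assessment(hscl_suicide: ItemResponse | None,
                    oq5: ItemResponse | None,
                    oq18: ItemResponse | None,
                    catalog: Catalog | None = None) -> RiskAssessment:
    """Combine the three risk/suicidality indicator items.

    ``flag`` is true when any item reaches its cut-off (HSCL suicidal
    ideation ≥ 2; OQ-30 items 5/18 ≥ 3); ``severity`` counts the items at or
    above their cut-offs; ``immediate`` mirrors the HSCL item alone and is
    raised regardless of track status.  Missing items do not contribute;
    if all three are missing the assessment is undefined.
    """
    catalog = catalog or default_catalog()
    given = (hscl_suicide, oq5, oq18)
    if all(r is None or r.missing for r in given):
        raise ValueError("risk assessment undefined: all risk items missing")
    severity = 0
    immediate = False
    for spec, resp in zip(catalog.risk_items, given):
        if resp is None or resp.missing:
            continue
        if resp.instrument != spec.instrument or resp.item_id != spec.item_id:
            raise ValueError(
                f"expected {spec.instrument.value} item {spec.item_id}, got "
                f"{resp.instrument.value} item {resp.item_id}"
            )
        if resp.raw_value >= spec.cutoff:
            severity += 1
            if spec.immediate:
                immediate = True
    return RiskAssessment(severity=severity, flag=severity > 0,
                          immediate=immediate)
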