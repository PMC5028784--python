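"""Questionnaire scoring for the pain/resilience cohort instruments.

Four instruments are scored:

* **Resilience Scale (RS)** — 25 items on a 1–7 Likert scale (range 25–175).
* **CD-RISC** — 25 items on a 0–4 scale (range 0–100).
* **Brief Pain Inventory (BPI)** — worst/least/current pain intensity (0–10)
  and seven interference items whose arithmetic mean is the overall
  interference score.  The "average pain" item is omitted by design: the
  concept does not translate validly for this cohort.
* **EQ5D-3L** — five domains at three levels plus a 0–100 health VAS.

Translated (isiZulu) versions of the resilience scales retain fewer items
(23 of 25 RS items, 24 of 25 CD-RISC items) after psychometric pruning, so
their raw totals are rescaled by the exact ratio ``n_full / n_retained``
(25/23 ≈ 1.09 and 25/24 ≈ 1.04) to remain comparable with the full English
versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BPIResponse",
    "EQ5DResponse",
    "ResilienceResponse",
    "ScoredScales",
    "normalize_truncated_score",
    "truncation_factor",
    "score_resilience",
    "score_bpi",
    "score_eq5d",
    "rescale_vas",
    "classify_chronic_pain",
    "score_cohort",
    "RS_RANGE",
    "CDRISC_RANGE",
    "WORRY_ITEMS",
]

RS_RANGE = (1, 7)
CDRISC_RANGE = (0, 4)
RS_N_FULL = 25
CDRISC_N_FULL = 25
RS_N_ISIZULU = 23
CDRISC_N_ISIZULU = 24

#: worry-frequency stressors, each coded 0 ("not at all") .. 4 ("nearly all
#: the time")
WORRY_ITEMS = ("health", "money", "food", "family")

_INTERFERENCE_ITEMS = (
    "general_activity",
    "mood",
    "walking",
    "work",
    "relations",
    "sleep",
    "enjoyment",
)


@dataclass(frozen=True)
class BPIResponse:
    """Brief Pain Inventory response (the "average pain" item is absent)."""

    worst: int
    least: int
    current: int
    interference: Sequence[int]

    def __post_init__(self) -> None:
        for name in ("worst", "least", "current"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValueError(f"BPI {name} pain must be in 0-10, got {v}")
        if len(self.interference) != 7:
            raise ValueError(
                f"BPI interference needs 7 items ({', '.join(_INTERFERENCE_ITEMS)}), "
                f"got {len(self.interference)}"
            )
        for i, v in enumerate(self.interference):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(
                    f"missing BPI interference item {i} ({_INTERFERENCE_ITEMS[i]}); "
                    "no imputation is performed"
                )
            if not 0 <= v <= 10:
                raise ValueError(
                    f"BPI interference item {i} ({_INTERFERENCE_ITEMS[i]}) "
                    f"must be in 0-10, got {v}"
                )


@dataclass(frozen=True)
class EQ5DResponse:
    """EQ5D-3L response: five domain levels in {1,2,3} and a 0-100 VAS."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int
    vas: int

    def __post_init__(self) -> None:
        for name in (
            "mobility",
            "self_care",
            "usual_activities",
            "pain_discomfort",
            "anxiety_depression",
        ):
            v = getattr(self, name)
            if v not in (1, 2, 3):
                raise ValueError(f"EQ5D domain {name} level must be 1, 2 or 3, got {v}")
        if not 0 <= self.vas <= 100:
            raise ValueError(f"EQ5D VAS must be in 0-100, got {self.vas}")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )


@dataclass(frozen=True)
class ResilienceResponse:
    """One participant's resilience-scale item responses.

    ``scale_id`` is ``"RS"`` (items 1-7) or ``"CDRISC"`` (items 0-4);
    ``language`` is ``"english"`` (25 items) or ``"isizulu"`` (23 RS items /
    24 CD-RISC items).
    """

    scale_id: str
    language: str
    items: Sequence[int]

    def __post_init__(self) -> None:
        if self.scale_id not in ("RS", "CDRISC"):
            raise ValueError(f"unknown scale_id {self.scale_id!r}")
        if self.language not in ("english", "isizulu"):
            raise ValueError(f"unknown language {self.language!r}")
        expected = {
            ("RS", "english"): RS_N_FULL,
            ("RS", "isizulu"): RS_N_ISIZULU,
            ("CDRISC", "english"): CDRISC_N_FULL,
            ("CDRISC", "isizulu"): CDRISC_N_ISIZULU,
        }[(self.scale_id, self.language)]
        if len(self.items) != expected:
            raise ValueError(
                f"{self.language} {self.scale_id} requires {expected} items, "
                f"got {len(self.items)}"
            )
        lo, hi = RS_RANGE if self.scale_id == "RS" else CDRISC_RANGE
        for i, v in enumerate(self.items):
            if not lo <= v <= hi:
                raise ValueError(
                    f"{self.scale_id} item {i} out of range [{lo}, {hi}]: {v}"
                )


@dataclass
class ScoredScales:
    """Scored questionnaire battery for one participant."""

    rs_total_normalized: float
    cdrisc_total_normalized: float
    bpi_worst: float | None = None
    bpi_least: float | None = None
    bpi_current: float | None = None
    bpi_interference_mean: float | None = None
    eq5d_levels: tuple[int, ...] | None = None
    eq5d_vas: int | None = None
    worry_levels: dict[str, int] = field(default_factory=dict)


def truncation_factor(n_items_retained: int, n_items_full: int) -> float:
    """Exact rescaling factor ``n_full / n_retained`` for a truncated scale.

    The published presentations 1.09 (= 25/23) and 1.04 (= 25/24) are
    rounded versions of this ratio; the exact rational value is used.
    """
    if n_items_retained <= 0 or n_items_full <= 0:
        raise ValueError("item counts must be positive")
    if n_items_retained > n_items_full:
        raise ValueError(
            f"retained items ({n_items_retained}) exceed full scale ({n_items_full})"
        )
    return n_items_full / n_items_retained


def normalize_truncated_score(
    raw_total: float, n_items_retained: int, n_items_full: int
) -> float:
    """Rescale a truncated-scale raw total onto the full scale's range."""
    return raw_total * truncation_factor(n_items_retained, n_items_full)


def score_resilience(resp: ResilienceResponse) -> float:
    """Total score, rescaled onto the full 25-item range for isiZulu versions."""
    raw = float(sum(resp.items))
    if resp.language == "english":
        return raw
    n_full = RS_N_FULL if resp.scale_id == "RS" else CDRISC_N_FULL
    return normalize_truncated_score(raw, len(resp.items), n_full)


def score_bpi(resp: BPIResponse) -> tuple[float, float, float, float]:
    """Return (worst, least, current, interference mean)."""
    interference_mean = float(np.mean(resp.interference))
    return float(resp.worst), float(resp.least), float(resp.current), interference_mean


def rescale_vas(vas: float, compress_n: int | None = None) -> float:
    """Map a 0-100 VAS onto (0, 1) for beta regression.

    With ``compress_n`` given, boundary values are compressed with the
    standard ``(y * (n - 1) + 0.5) / n`` transform so the result lies
    strictly inside the unit interval.
    """
    if not 0 <= vas <= 100:
        raise ValueError(f"VAS must be in 0-100, got {vas}")
    y = vas / 100.0
    if compress_n is not None:
        y = (y * (compress_n - 1) + 0.5) / compress_n
    return y


def score_eq5d(resp: EQ5DResponse) -> tuple[tuple[int, ...], int]:
    """Validated pass-through of EQ5D domain levels and VAS."""
    return resp.levels, resp.vas


def classify_chronic_pain(
    pain_present: bool, pain_most_days: bool, duration_months: float
) -> str:
    """Chronic pain: pain on most days for at least the past three months.

    An acute episode (< 3 months) does not qualify, so such participants
    fall in the NoCP group.
    """
    if duration_months < 0:
        raise ValueError(f"pain duration cannot be negative: {duration_months}")
    if pain_present and pain_most_days and duration_months >= 3:
        return "CP"
    return "NoCP"


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort table (one row per participant) in bulk.

    Expects the column layout written by :mod:`actipain.synthdata`:
    ``rs_item_*`` / ``cdrisc_item_*`` responses (NaN for items absent from a
    participant's language version), a ``language`` column, BPI columns for
    chronic-pain participants, EQ5D columns and ``worry_*`` columns.
    Returns a copy with ``rs_score``, ``cdrisc_score`` and
    ``bpi_interference`` columns appended.
    """
    out = cohort.copy()
    rs_cols = sorted(
        (c for c in cohort.columns if c.startswith("rs_item_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    cd_cols = sorted(
        (c for c in cohort.columns if c.startswith("cdrisc_item_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    rs_scores = np.empty(len(cohort))
    cd_scores = np.empty(len(cohort))
    for i, (_, row) in enumerate(cohort.iterrows()):
        lang = row["language"]
        rs_items = [int(v) for v in row[rs_cols] if not pd.isna(v)]
        cd_items = [int(v) for v in row[cd_cols] if not pd.isna(v)]
        rs_scores[i] = score_resilience(
            ResilienceResponse("RS", lang, rs_items)
        )
        cd_scores[i] = score_resilience(
            ResilienceResponse("CDRISC", lang, cd_items)
        )
    out["rs_score"] = rs_scores
    out["cdrisc_score"] = cd_scores

    if "bpi_worst" in cohort.columns:
        interf_cols = [f"bpi_interference_{name}" for name in _INTERFERENCE_ITEMS]
        means = np.full(len(cohort), np.nan)
        for i, (_, row) in enumerate(cohort.iterrows()):
            if pd.isna(row["bpi_worst"]):
                continue  # instrument administered to the chronic-pain group only
            resp = BPIResponse(
                worst=int(row["bpi_worst"]),
                least=int(row["bpi_least"]),
                current=int(row["bpi_current"]),
                interference=[int(row[c]) for c in interf_cols],
            )
            means[i] = score_bpi(resp)[3]
        out["bpi_interference"] = means
    return out
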