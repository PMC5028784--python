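"""Synthetic cohort and accelerometer-trace generator with known truth.

The generator emulates the data structure of a two-group (chronic pain /
no chronic pain) HIV-clinic cohort so that every downstream stage —
questionnaire scoring, scale validation, actigraphy phenotyping, resampling
inference and forest modelling — can be exercised end to end with a known
ground truth and no external data.

Structure emulated:

* two groups (~50 % chronic pain), demographics loosely matching the study
  population (age, sex, education, employment, BMI);
* a single latent resilience trait driving 25 seven-category RS items and
  25 five-category CD-RISC items through a graded-response model
  (``category = #{thresholds below loading * theta + N(0,1) noise}``), with
  a configurable group shift on the latent trait; isiZulu-language
  participants answer the truncated 23/24-item versions;
* four 5-category worry-frequency items from a proportional-odds model with
  a group log-odds shift;
* EQ5D-3L domains + VAS and BPI intensity/interference (chronic-pain group
  only);
* bout-structured diurnal activity traces: an 8-h jittered sleep block and,
  while awake, alternating active/inactive bouts from a two-state
  semi-Markov (geometric-duration) process at 5-minute resolution, with
  right-skewed gamma counts scaled to a per-device calibration maximum.
  The process is initialised at stationarity so the expected extracted
  active minutes per day equal ``true_mean_active_minutes`` exactly; the
  group difference in activity defaults to null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .actigraphy import EpochSeries, MINUTES_PER_DAY

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "DeviceSpec",
    "generate_cohort",
    "generate_trace",
    "inject_nonwear",
    "write_cohort",
    "read_cohort",
]

WINDOW = 5
WINDOWS_PER_DAY = MINUTES_PER_DAY // WINDOW  # 288
SLEEP_WINDOWS = 96  # 8 h
WAKE_MINUTES = 960.0

# default per-item category cut probabilities (cumulative, latent scale);
# right-shifted to emulate a highly resilient cohort
_RS_CUM = (0.01, 0.02, 0.05, 0.10, 0.22, 0.45)
_CDRISC_CUM = (0.02, 0.07, 0.25, 0.55)

# worry-frequency baseline (no-pain group) category probabilities,
# categories 0 "not at all" .. 4 "nearly all the time"
_WORRY_BASE = {
    "health": (0.27, 0.10, 0.34, 0.08, 0.21),
    "money": (0.07, 0.04, 0.28, 0.06, 0.55),
    "food": (0.40, 0.06, 0.23, 0.08, 0.23),
    "family": (0.23, 0.03, 0.22, 0.08, 0.44),
}

_EQ5D_DOMAINS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")
# per-group level probabilities (levels 1..3) for each EQ5D domain
_EQ5D_PROBS = {
    "CP": {
        "mobility": (0.60, 0.40, 0.00),
        "self_care": (0.95, 0.05, 0.00),
        "usual_activities": (0.59, 0.40, 0.01),
        "pain_discomfort": (0.06, 0.72, 0.22),
        "anxiety_depression": (0.75, 0.22, 0.03),
    },
    "NoCP": {
        "mobility": (0.94, 0.06, 0.00),
        "self_care": (1.00, 0.00, 0.00),
        "usual_activities": (0.96, 0.04, 0.00),
        "pain_discomfort": (0.95, 0.04, 0.01),
        "anxiety_depression": (0.91, 0.09, 0.00),
    },
}

_EDUCATION_PROBS = {"CP": (0.23, 0.42, 0.28, 0.07), "NoCP": (0.06, 0.46, 0.41, 0.07)}
_EMPLOYMENT_PROBS = {"CP": (0.37, 0.18, 0.45), "NoCP": (0.54, 0.13, 0.33)}


@dataclass(frozen=True)
class DeviceSpec:
    device_id: str
    max_count: float

    def __post_init__(self) -> None:
        if self.max_count <= 0:
            raise ValueError("device max_count must be positive")


@dataclass(frozen=True)
class TruthRecord:
    participant_id: str
    group: str
    theta_resilience: float
    true_mean_active_minutes: float
    device_id: str


@dataclass(frozen=True)
class CohortConfig:
    n_total: int = 197
    pain_fraction: float = 0.5
    seed: int = 0
    language_isizulu_fraction: float = 0.77
    #: latent-trait shift in SD units, CP minus NoCP
    resilience_group_shift: float = -0.7
    #: proportional change in the CP group's active-bout rate (null default)
    activity_group_shift: float = 0.0
    #: common loading, or mapping scale -> per-item loadings
    item_loadings: float | dict = 0.7
    #: mapping scale -> per-item threshold arrays on the latent-response scale
    item_threshold_sets: dict | None = None
    #: log-odds shift of the CP group on every worry item
    worry_or_shift: float = 1.4
    mean_active_minutes: float = 360.0
    sd_active_minutes: float = 80.0
    device_max_range: tuple[float, float] = (800.0, 1200.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pain_fraction <= 1.0:
            raise ValueError("pain_fraction must be in [0, 1]")
        if not 0.0 <= self.language_isizulu_fraction <= 1.0:
            raise ValueError("language_isizulu_fraction must be in [0, 1]")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if self.item_threshold_sets:
            for scale, sets in self.item_threshold_sets.items():
                for i, t in enumerate(sets):
                    t = np.asarray(t, dtype=float)
                    if np.any(np.diff(t) <= 0):
                        raise ValueError(
                            f"{scale} item {i}: thresholds must be strictly increasing"
                        )


def _loadings(config: CohortConfig, scale: str, n_items: int) -> np.ndarray:
    if isinstance(config.item_loadings, dict):
        lam = np.asarray(config.item_loadings[scale], dtype=float)
        if lam.shape != (n_items,):
            raise ValueError(f"{scale} loadings must have length {n_items}")
    else:
        lam = np.full(n_items, float(config.item_loadings))
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("item loadings must be in [0, 1]")
    return lam


def _threshold_sets(config: CohortConfig, scale: str, lam: np.ndarray) -> list[np.ndarray]:
    if config.item_threshold_sets and scale in config.item_threshold_sets:
        return [np.asarray(t, dtype=float) for t in config.item_threshold_sets[scale]]
    cum = np.asarray(_RS_CUM if scale == "RS" else _CDRISC_CUM)
    base = ndtri(cum)
    # latent response loading*theta + N(0,1) has SD sqrt(1 + loading^2)
    return [base * np.sqrt(1.0 + l * l) for l in lam]


def _graded_items(
    theta: np.ndarray, lam: np.ndarray, thresholds: list[np.ndarray], rng
) -> np.ndarray:
    n, p = len(theta), len(lam)
    z = theta[:, None] * lam[None, :] + rng.standard_normal((n, p))
    out = np.zeros((n, p), dtype=int)
    for j in range(p):
        out[:, j] = np.searchsorted(thresholds[j], z[:, j], side="right")
    return out


def generate_cohort(config: CohortConfig):
    """Generate a cohort table with matching truth records and device specs.

    Returns ``(cohort, truths, devices)``: a one-row-per-participant
    DataFrame, a list of :class:`TruthRecord` and a dict
    ``device_id -> DeviceSpec``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_total
    n_cp = int(round(n * config.pain_fraction))
    group = np.array(["CP"] * n_cp + ["NoCP"] * (n - n_cp))
    is_cp = group == "CP"
    pid = np.array([f"P{i:04d}" for i in range(n)])

    theta = rng.standard_normal(n) + np.where(is_cp, config.resilience_group_shift, 0.0)
    language = np.where(
        rng.random(n) < config.language_isizulu_fraction, "isizulu", "english"
    )

    # resilience items (graded-response model); isiZulu versions truncated
    rs_lam = _loadings(config, "RS", 25)
    cd_lam = _loadings(config, "CDRISC", 25)
    rs = _graded_items(theta, rs_lam, _threshold_sets(config, "RS", rs_lam), rng) + 1
    cd = _graded_items(theta, cd_lam, _threshold_sets(config, "CDRISC", cd_lam), rng)
    rs_f = rs.astype(float)
    cd_f = cd.astype(float)
    zulu = language == "isizulu"
    rs_f[zulu, 23:] = np.nan  # last 2 RS statements absent from the isiZulu form
    cd_f[zulu, 24:] = np.nan  # last CD-RISC statement absent

    # worry items: proportional odds with CP log-odds shift
    worry = {}
    for item, probs in _WORRY_BASE.items():
        cuts = np.log(np.cumsum(probs)[:-1] / (1.0 - np.cumsum(probs)[:-1]))
        u = rng.logistic(loc=np.where(is_cp, config.worry_or_shift, 0.0))
        worry[item] = (u[:, None] > cuts[None, :]).sum(axis=1)

    # demographics
    age = np.round(rng.normal(np.where(is_cp, 44.0, 40.0), 10.0)).clip(18, 90)
    female = rng.random(n) < np.where(is_cp, 0.66, 0.78)
    bmi = rng.normal(np.where(is_cp, 28.0, 26.0), 6.0).clip(15, 60).round(1)
    education = np.empty(n, dtype=int)
    employment = np.empty(n, dtype=int)
    for g, mask in (("CP", is_cp), ("NoCP", ~is_cp)):
        k = int(mask.sum())
        education[mask] = rng.choice(4, size=k, p=_EDUCATION_PROBS[g])
        employment[mask] = rng.choice(3, size=k, p=_EMPLOYMENT_PROBS[g])

    # EQ5D
    eq5d = {}
    for dom in _EQ5D_DOMAINS:
        lv = np.empty(n, dtype=int)
        for g, mask in (("CP", is_cp), ("NoCP", ~is_cp)):
            lv[mask] = rng.choice(3, size=int(mask.sum()), p=_EQ5D_PROBS[g][dom]) + 1
        eq5d[dom] = lv
    vas = np.round(rng.normal(np.where(is_cp, 50.0, 80.0), np.where(is_cp, 20.0, 15.0)))
    vas = vas.clip(0, 100).astype(int)

    # pain history; BPI administered to the chronic-pain group only
    duration = np.where(
        is_cp,
        3.0 + rng.gamma(2.0, 22.5, n),  # mean ~48 months
        np.where(rng.random(n) < 0.05, rng.uniform(0.1, 2.9, n), 0.0),
    ).round(1)
    bpi = {
        "bpi_worst": np.round(rng.normal(8.0, 1.5, n)).clip(0, 10),
        "bpi_least": np.round(rng.normal(4.0, 2.0, n)).clip(0, 10),
        "bpi_current": np.round(rng.normal(5.0, 2.0, n)).clip(0, 10),
    }
    for nm in (
        "general_activity",
        "mood",
        "walking",
        "work",
        "relations",
        "sleep",
        "enjoyment",
    ):
        bpi[f"bpi_interference_{nm}"] = np.round(rng.normal(5.0, 2.0, n)).clip(0, 10)
    for k in bpi:
        bpi[k] = np.where(is_cp, bpi[k], np.nan)

    # activity truth + devices
    active_min = rng.normal(config.mean_active_minutes, config.sd_active_minutes, n)
    active_min = active_min.clip(30.0, WAKE_MINUTES - 10.0)
    active_min = np.where(is_cp, active_min * (1.0 + config.activity_group_shift), active_min)
    active_min = active_min.clip(0.0, WAKE_MINUTES)
    device_ids = np.array([f"D{i:04d}" for i in range(n)])
    lo, hi = config.device_max_range
    devices = {
        d: DeviceSpec(d, float(m))
        for d, m in zip(device_ids, np.round(rng.uniform(lo, hi, n)))
    }

    cohort = pd.DataFrame(
        {
            "participant_id": pid,
            "group": group,
            "age": age,
            "female": female.astype(int),
            "education": education,
            "employment": employment,
            "bmi": bmi,
            "language": language,
            "pain_duration_months": duration,
            "eq5d_vas": vas,
            "device_id": device_ids,
        }
    )
    for dom in _EQ5D_DOMAINS:
        cohort[f"eq5d_{dom}"] = eq5d[dom]
    for item in _WORRY_BASE:
        cohort[f"worry_{item}"] = worry[item]
    for k, v in bpi.items():
        cohort[k] = v
    for j in range(25):
        cohort[f"rs_item_{j + 1}"] = rs_f[:, j]
    for j in range(25):
        cohort[f"cdrisc_item_{j + 1}"] = cd_f[:, j]

    truths = [
        TruthRecord(
            participant_id=pid[i],
            group=group[i],
            theta_resilience=float(theta[i]),
            true_mean_active_minutes=float(active_min[i]),
            device_id=device_ids[i],
        )
        for i in range(n)
    ]
    return cohort, truths, devices


# ---------------------------------------------------------------------------
# trace generation


def _sleep_mask(n_windows: int, days: int, rng) -> np.ndarray:
    """True over sleep windows: an 8-h block with onset 22:00 +- Gaussian
    jitter (SD 30 min), per night, allowed to cross midnight."""
    mask = np.zeros(n_windows, dtype=bool)
    onset_base = 264  # 22:00 in 5-min windows
    for d in range(-1, days):
        jitter = int(round(rng.normal(0.0, 6.0)))
        start = d * WINDOWS_PER_DAY + onset_base + jitter
        lo = max(start, 0)
        hi = min(start + SLEEP_WINDOWS, n_windows)
        if lo < hi:
            mask[lo:hi] = True
    return mask


def _active_windows(n_wake: int, p_active: float, rng) -> np.ndarray:
    """Two-state chain over wake windows with geometric bout durations,
    initialised at stationarity so the active fraction is unbiased."""
    if p_active <= 0.0:
        return np.zeros(n_wake, dtype=bool)
    if p_active >= 1.0:
        return np.ones(n_wake, dtype=bool)
    mean_active = 2.0 if p_active <= 2.0 / 3.0 else p_active / (1.0 - p_active)
    mean_inactive = mean_active * (1.0 - p_active) / p_active
    leave_a = 1.0 / mean_active
    leave_i = 1.0 / mean_inactive
    u = rng.random(n_wake)
    state = np.empty(n_wake, dtype=bool)
    state[0] = u[0] < p_active
    for t in range(1, n_wake):
        state[t] = (not state[t - 1]) if u[t] < (leave_a if state[t - 1] else leave_i) else state[t - 1]
    return state


def generate_trace(
    truth: TruthRecord,
    device: DeviceSpec,
    days: int = 14,
    seed=None,
    start: str = "2015-01-05",
) -> EpochSeries:
    """Simulate a 1-minute epoch trace for one participant.

    Active 5-minute windows draw gamma(3) epoch counts with mean 25 % of the
    device maximum (99.9th percentile ~ the maximum); inactive wake windows
    contain occasional low "fidget" counts below the 2.5 % activity
    threshold; sleep windows are zero.  Expected extracted active minutes
    per day equal ``truth.true_mean_active_minutes``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    target = truth.true_mean_active_minutes
    if not 0.0 <= target <= WAKE_MINUTES:
        raise ValueError(f"true_mean_active_minutes must be in [0, {WAKE_MINUTES:g}]")
    rng = np.random.default_rng(seed)
    n_windows = days * WINDOWS_PER_DAY
    sleep = _sleep_mask(n_windows, days, rng)
    wake_idx = np.where(~sleep)[0]
    active = np.zeros(n_windows, dtype=bool)
    active[wake_idx] = _active_windows(len(wake_idx), target / WAKE_MINUTES, rng)

    n_epochs = n_windows * WINDOW
    counts = np.zeros(n_epochs)
    epoch_active = np.repeat(active, WINDOW)
    n_act = int(epoch_active.sum())
    counts[epoch_active] = rng.gamma(3.0, device.max_count / 12.0, n_act)
    epoch_wake_inactive = np.repeat(~active & ~sleep, WINDOW)
    n_fid = int(epoch_wake_inactive.sum())
    fidget = np.where(
        rng.random(n_fid) < 0.3, rng.uniform(0.0, 0.02 * device.max_count, n_fid), 0.0
    )
    counts[epoch_wake_inactive] = fidget
    counts = np.round(counts.clip(0.0, device.max_count))

    timestamps = pd.date_range(start=start, periods=n_epochs, freq="min")
    return EpochSeries(
        participant_id=truth.participant_id,
        device_id=device.device_id,
        timestamps=timestamps,
        counts=counts,
        worn=np.ones(n_epochs, dtype=bool),
        device_max=device.max_count,
    )


def inject_nonwear(series: EpochSeries, episodes) -> EpochSeries:
    """Mark non-wear episodes (device removed, e.g. for bathing): epochs are
    flagged not-worn and counts zeroed.  ``episodes`` is a list of
    ``(start, duration_minutes)`` with ``start`` a timestamp or epoch index.
    Episodes must lie within the recording and not overlap.
    """
    n = len(series)
    flags = np.zeros(n, dtype=bool)
    for start, dur in episodes:
        if dur <= 0:
            raise ValueError("episode duration must be positive")
        if isinstance(start, (int, np.integer)):
            i0 = int(start)
        else:
            ts = pd.Timestamp(start)
            loc = series.timestamps.get_indexer([ts])
            if loc[0] < 0:
                raise ValueError(f"episode start {ts} not in the recording")
            i0 = int(loc[0])
        i1 = i0 + int(dur)
        if i0 < 0 or i1 > n:
            raise ValueError(f"episode ({start}, {dur}) outside the recording span")
        if flags[i0:i1].any():
            raise ValueError("overlapping non-wear episodes")
        flags[i0:i1] = True
    counts = series.counts.copy()
    counts[flags] = 0.0
    worn = series.worn & ~flags
    return EpochSeries(
        participant_id=series.participant_id,
        device_id=series.device_id,
        timestamps=series.timestamps,
        counts=counts,
        worn=worn,
        device_max=series.device_max,
        normalized=series.normalized,
    )


# ---------------------------------------------------------------------------
# I/O


def write_cohort(cohort: pd.DataFrame, devices: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "devices.json", "w") as fh:
        json.dump({d: spec.max_count for d, spec in devices.items()}, fh, indent=1)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
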