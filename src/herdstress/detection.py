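"""Day/night change detection, THI, vet binarization and stress labeling.

The reconstructed circadian component of each 36 h window is split by
clock time into a day subseries A (06:00-18:00) and a night subseries B
(18:00-06:00), both z-normalized with the cow's baseline statistics, and
their contrast is summarized by the root-mean-square distance

    d_t = sqrt( (1/n) * sum_t (A_t - B_t)^2 ),   n = 12.

Per-cow thresholds T1 = mean + sd and T2 = mean + 2*sd of d_t over
event-free baseline days place the normal/mild and mild/high cuts at
roughly the 84th and 97.5th percentiles of an approximately Gaussian
baseline. A window is labeled mild/high only when its distance tier is
exceeded AND at least one contextual flag (veterinary finding, THI above
the comfort zone, or circadian deviation) fires within a +-1 h tolerance;
otherwise it stays normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MARKED_SIGNS

__all__ = [
    "DayNightPair",
    "BaselineThresholds",
    "StressLabel",
    "split_day_night",
    "d_rms",
    "fit_thresholds",
    "compute_thi",
    "thi_category",
    "binarize_vet",
    "label_stress",
    "rollup_cow_day",
    "build_covariates",
]

DAY_START, NIGHT_START = 6, 18  # civil clock; [06,18) is day, [18,06) night


@dataclass(frozen=True)
class DayNightPair:
    cow_id: str | None
    date: object | None
    A: np.ndarray  # 12 z-normalized values, clock hours 06..17
    B: np.ndarray  # 12 z-normalized values, clock hours 18..05
    complete: bool = True

    @property
    def n(self) -> int:
        return len(self.A)


@dataclass(frozen=True)
class BaselineThresholds:
    cow_id: str | None
    x_bar: float
    s: float
    n_baseline: int

    @property
    def T1(self) -> float:
        return self.x_bar + self.s

    @property
    def T2(self) -> float:
        return self.x_bar + 2.0 * self.s


@dataclass(frozen=True)
class StressLabel:
    label: int  # 0 normal, 1 mild, 2 high
    d_tier: int
    vet_flag: bool
    thi_flag: bool
    circadian_deviation_flag: bool
    tolerance_h: int = 1


def split_day_night(
    values: np.ndarray,
    start_clock_hour: int,
    norm_mean: float,
    norm_sd: float,
    cow_id: str | None = None,
    date: object | None = None,
) -> DayNightPair:
    """Split 24 hourly circadian values into the day/night pair.

    ``values`` are consecutive hourly samples of s_circ beginning at clock
    hour ``start_clock_hour``; membership is by clock: [06:00, 18:00) is
    day, [18:00, 06:00) night (so 18:00 belongs to B and 06:00 to A). Both
    subseries are z-normalized with the cow's baseline mean/sd.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != 24:
        raise ValueError(f"need 24 hourly values, got {len(values)}")
    if norm_sd <= 0:
        raise ValueError("baseline sd must be positive")
    z = (values - norm_mean) / norm_sd
    clock = (start_clock_hour + np.arange(24)) % 24
    day_mask = (clock >= DAY_START) & (clock < NIGHT_START)
    # order each subseries by clock hour so A[0] is 06:00 and B[0] is 18:00
    day_order = np.argsort(clock[day_mask])
    night_clock = (clock[~day_mask] - NIGHT_START) % 24
    night_order = np.argsort(night_clock)
    return DayNightPair(
        cow_id=cow_id, date=date, A=z[day_mask][day_order], B=z[~day_mask][night_order]
    )


def d_rms(pair: DayNightPair) -> float:
    """Root-mean-square day-night distance; dimensionless and >= 0."""
    if len(pair.A) != len(pair.B):
        raise ValueError(f"subseries lengths differ: {len(pair.A)} vs {len(pair.B)}")
    diff = pair.A - pair.B
    return float(np.sqrt(np.mean(diff * diff)))


def fit_thresholds(
    d_values: np.ndarray, cow_id: str | None = None, min_baseline: int = 14
) -> BaselineThresholds:
    """Per-cow thresholds from event-free baseline distances (sample sd, ddof=1)."""
    d_values = np.asarray(d_values, dtype=float)
    if len(d_values) < min_baseline:
        raise ValueError(
            f"only {len(d_values)} baseline values; need at least {min_baseline}"
        )
    s = float(np.std(d_values, ddof=1))
    if s <= 0:
        raise ValueError("degenerate baseline: zero spread in d_t")
    return BaselineThresholds(
        cow_id=cow_id, x_bar=float(np.mean(d_values)), s=s, n_baseline=len(d_values)
    )


def compute_thi(temp_c, rh_pct):
    """Temperature-humidity index.

    THI = (1.8*T + 32) - (0.55 - 0.0055*RH) * (1.8*T - 26), T in Celsius,
    RH in percent. At RH = 100 the humidity term vanishes; at
    T = 26/1.8 ~ 14.44 C the THI is 58 regardless of RH.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    rh_pct = np.asarray(rh_pct, dtype=float)
    if np.any((rh_pct < 0) | (rh_pct > 100)):
        raise ValueError("relative humidity outside [0, 100]%")
    thi = (1.8 * temp_c + 32.0) - (0.55 - 0.0055 * rh_pct) * (1.8 * temp_c - 26.0)
    return thi if thi.shape else float(thi)


def thi_category(thi):
    """normal: THI <= 68; mild: 68 < THI <= 72; high: THI > 72."""
    thi = np.asarray(thi, dtype=float)
    cat = np.where(thi > 72.0, "high", np.where(thi > 68.0, "mild", "normal"))
    return cat if cat.shape else str(cat)


def binarize_vet(records: pd.DataFrame | list[dict]) -> tuple[int, bool]:
    """Collapse one cow-day of veterinary rounds to an ordinal 0/1/2.

    No signs -> 0. Signs in exactly one round (none marked) -> 1. Signs in
    both rounds, or any sign with functional repercussion (marked) -> 2.
    Returns (level, persistence) where persistence means both rounds were
    positive. More than two rounds per day is a data error.
    """
    if isinstance(records, list):
        records = pd.DataFrame(records, columns=["cow_id", "date", "round", "signs", "level"])
    records = records[records["signs"].fillna("").astype(str).str.len() > 0]
    rounds = records["round"].unique()
    if len(records["round"]) > 2 or len(rounds) > 2:
        raise ValueError("more than two veterinary rounds in one cow-day")
    if len(records) == 0:
        return 0, False
    persistence = len(rounds) == 2
    signs = set()
    for cell in records["signs"]:
        signs.update(str(cell).split(";"))
    marked = bool(signs & MARKED_SIGNS)
    if persistence or marked:
        return 2, persistence
    return 1, persistence


def label_stress(
    d_t: float,
    thresholds: BaselineThresholds,
    vet_flag: bool,
    thi_flag: bool,
    circadian_deviation_flag: bool,
    tolerance_h: int = 1,
) -> StressLabel:
    """Triangulated labeling rule.

    d_t <= T1 -> normal unconditionally. T1 < d_t <= T2 -> mild only if at
    least one flag fires; d_t > T2 -> high only if at least one flag fires.
    With no supporting flag the window stays normal. A flag can never raise
    severity above the distance tier.
    """
    if thresholds is None:
        raise ValueError("thresholds not fitted")
    if d_t <= thresholds.T1:
        tier = 0
    elif d_t <= thresholds.T2:
        tier = 1
    else:
        tier = 2
    any_flag = bool(vet_flag or thi_flag or circadian_deviation_flag)
    return StressLabel(
        label=tier if any_flag else 0,
        d_tier=tier,
        vet_flag=bool(vet_flag),
        thi_flag=bool(thi_flag),
        circadian_deviation_flag=bool(circadian_deviation_flag),
        tolerance_h=tolerance_h,
    )


def rollup_cow_day(hourly_labels: np.ndarray) -> tuple[int, list[tuple[int, int, int]]]:
    """Cow-day label (max hourly severity) plus descriptive episode runs.

    Episodes are maximal runs of identical nonzero hourly labels, returned
    as (start index, length, label) and used descriptively only.
    """
    hourly_labels = np.asarray(hourly_labels, dtype=int)
    if len(hourly_labels) == 0:
        raise ValueError("need at least one labeled hour")
    episodes = []
    i = 0
    while i < len(hourly_labels):
        if hourly_labels[i] == 0:
            i += 1
            continue
        j = i
        while j < len(hourly_labels) and hourly_labels[j] == hourly_labels[i]:
            j += 1
        episodes.append((i, j - i, int(hourly_labels[i])))
        i = j
    return int(hourly_labels.max()), episodes


def build_covariates(
    daily_features: pd.DataFrame,
    vet_daily: pd.DataFrame,
    milk: pd.DataFrame,
    exam_hour: int = 18,
) -> pd.DataFrame:
    """Leakage-safe context covariates per cow-day.

    vas
        Veterinary anomaly score (declared proxy; the reference protocol
        leaves it unspecified): cow-standardized mean absolute z-deviation
        of circadian amplitude and coherence, taken from the most recent
        daily summary whose 36 h data span ends strictly before the
        clinical exam at ``exam_hour`` — never from the vet outcome itself.
    milk_lag
        Previous-day milk yield in kg.
    vet_lag
        Previous-day binarized vet indicator.

    Days without sufficient history are excluded. The summary anchored at
    06:00 of day d draws on data through 18:00 of day d+1, so for an
    evening exam the lag is one day and for a morning exam two days.
    """
    vas_lag_days = 1 if exam_hour >= 18 else 2
    frames = []
    for cow, grp in daily_features.groupby("cow_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        amp = grp["amplitude"].to_numpy(dtype=float)
        coh = grp["coherence"].to_numpy(dtype=float)

        def _causal_absz(x: np.ndarray) -> np.ndarray:
            # standardize each summary against its own past only
            out = np.full(len(x), np.nan)
            for j in range(1, len(x)):
                hist = x[: j + 1]
                mu = np.nanmean(hist)
                sd = np.nanstd(hist, ddof=1)
                tiny = 1e-9 * (abs(mu) + 1.0)  # constant series up to rounding
                if np.isfinite(sd):
                    out[j] = abs((x[j] - mu) / sd) if sd > tiny else 0.0
            return out

        vas = 0.5 * (_causal_absz(amp) + _causal_absz(coh))
        vas_lag = np.full(len(grp), np.nan)
        vas_lag[vas_lag_days:] = vas[:-vas_lag_days]

        mk = milk[milk["cow_id"] == cow].copy()
        mk["date"] = pd.to_datetime(mk["date"]).dt.date
        mk = mk.set_index("date")["yield_kg"]
        vd = vet_daily[vet_daily["cow_id"] == cow].copy()
        vd["date"] = pd.to_datetime(vd["date"]).dt.date
        vd = vd.set_index("date")["vet_level"]

        dates = pd.to_datetime(grp["date"]).dt.date
        prev = pd.to_datetime(grp["date"]) - pd.Timedelta(days=1)
        prev = prev.dt.date
        milk_lag = np.array([mk.get(d, np.nan) for d in prev], dtype=float)
        vet_lag = np.array([float(vd.get(d, 0.0)) for d in prev], dtype=float)
        out = pd.DataFrame(
            {
                "cow_id": cow,
                "date": dates,
                "vas": vas_lag,
                "milk_lag": milk_lag,
                "vet_lag": vet_lag,
            }
        )
        frames.append(out[out["vas"].notna()])  # leading days lack history
    if not frames:
        return pd.DataFrame(columns=["cow_id", "date", "vas", "milk_lag", "vet_lag"])
    return pd.concat(frames, ignore_index=True)
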