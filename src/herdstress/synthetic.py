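"""Synthetic herd generator.

Produces hourly behavior budgets, weather, veterinary observations, daily
milk yield and a latent ground-truth stress track for a small dairy herd,
with the statistical structure the downstream pipeline assumes:

* each cow has a 24 h-periodic behavioral budget with a cow-specific
  modulation depth ("circadian amplitude", normalized scale) and acrophase;
* latent stress episodes arrive as a Poisson process per cow and severity,
  last a contiguous run of hours, depress the circadian amplitude into the
  operational mild/high bands, shift the acrophase and cut rumination;
* weather follows a sinusoidal diurnal temperature cycle with AR(1)
  day-to-day drift and anti-phase relative humidity, so the
  temperature-humidity index (THI) crosses the 68/72 stress cuts in a
  realistic fraction of hours;
* an imperfect veterinary observer samples the latent state twice daily
  (06:00 and 18:00) with configurable sensitivity/specificity;
* milk yield is a per-cow baseline minus a penalty during and after
  episodes.

All randomness flows from ``SimConfig.seed``; identical configs give
identical outputs (and byte-identical CSV fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EpisodeEffect",
    "WeatherParams",
    "SimConfig",
    "HerdDataset",
    "ConfigError",
    "simulate_herd",
    "write_fixtures",
    "read_dataset",
    "STATE_NAMES",
    "MARKED_SIGNS",
    "TRANSIENT_SIGNS",
]

STATE_NAMES = ("normal", "mild", "high")

#: signs whose presence alone indicates a marked/functional finding
MARKED_SIGNS = frozenset(
    {"respiratory_distress", "anorexia", "severe_lameness", "recumbency"}
)
TRANSIENT_SIGNS = (
    "restlessness",
    "reduced_appetite",
    "mild_lameness",
    "social_withdrawal",
)

# mean hourly budget (minutes/hour); sums to 60
_MEAN_BUDGET = {"eat": 12.0, "rest": 22.0, "ruminate": 19.0, "other": 7.0}
# diurnal modulation of each behavior relative to the cow's depth m:
# eating peaks in the day, resting/rumination at night.
_MODULATION = {"eat": 1.0, "rest": -0.8, "ruminate": -0.5, "other": 0.6}

BEHAVIOR_COLUMNS = ["eat_min", "rest_min", "ruminate_min", "other_min"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class EpisodeEffect:
    """How a stress episode reshapes behavior while it lasts.

    rumination_cut
        Fractional reduction of rumination minutes, drawn uniformly per
        episode from this closed interval.
    amplitude_target
        Target circadian amplitude on the normalized 0-1 scale (the same
        scale as ``SimConfig.base_amplitude``), drawn uniformly per episode.
    phase_shift_h
        Acrophase displacement in hours (sign randomized per episode).
    """

    rumination_cut: tuple[float, float]
    amplitude_target: tuple[float, float]
    phase_shift_h: tuple[float, float]


@dataclass(frozen=True)
class WeatherParams:
    # highland defaults: daily THI peak sits just under the 68 comfort line,
    # crossing it on warm-drift days (roughly a quarter of days) and 72 rarely
    temp_mean_c: float = 14.5
    temp_diurnal_range_c: float = 12.0
    temp_drift_sd_c: float = 1.5
    temp_drift_ar1: float = 0.7
    temp_noise_sd_c: float = 0.5
    rh_mean_pct: float = 70.0
    rh_diurnal_range_pct: float = 25.0
    rh_noise_sd_pct: float = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic herd.

    Defaults emulate the reference study: 10 cows followed for a full
    365-day (non-leap) year, a latent stress mix of roughly 72% normal /
    21% mild / 7% high at the cow-hour level, mild episodes cutting
    rumination by 15-25% and depressing circadian amplitude into
    [0.45, 0.60), high episodes cutting rumination by more than 40% with
    amplitude below 0.45.
    """

    n_cows: int = 10
    n_days: int = 365
    seed: int = 0
    start_date: str = "2023-01-01"
    base_amplitude: float = 0.75
    amplitude_jitter_sd: float = 0.06
    acrophase_hour_mean: float = 14.0
    acrophase_jitter_sd: float = 1.0
    noise_sd: float = 3.0
    # episodes per cow per 30 days; rates give 21%/7% stationary occupancy
    # for uniform 24-72 h durations after Poisson overlap correction
    episode_rate_mild: float = 3.84
    episode_rate_high: float = 1.09
    episode_duration_hours: tuple[int, int] = (24, 72)
    mild_effect: EpisodeEffect = EpisodeEffect(
        rumination_cut=(0.15, 0.25),
        amplitude_target=(0.45, 0.60),
        phase_shift_h=(2.0, 4.0),
    )
    high_effect: EpisodeEffect = EpisodeEffect(
        rumination_cut=(0.42, 0.60),
        amplitude_target=(0.25, 0.45),
        phase_shift_h=(3.0, 6.0),
    )
    vet_sensitivity: float = 0.80
    vet_specificity: float = 0.95
    vet_marked_prob: float = 0.70
    weather: WeatherParams = field(default_factory=WeatherParams)
    milk_baseline_kg: float = 28.0
    milk_between_cow_sd: float = 2.0
    milk_noise_sd: float = 1.0
    milk_penalty_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_cows < 0 or self.n_days <= 0:
            raise ConfigError(
                f"dimensions must be n_cows >= 0, n_days >= 1; "
                f"got n_cows={self.n_cows}, n_days={self.n_days}"
            )
        for name in ("vet_sensitivity", "vet_specificity", "vet_marked_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.base_amplitude <= 1.0:
            raise ConfigError("base_amplitude must lie in (0, 1]")
        lo, hi = self.episode_duration_hours
        if not (0 < lo <= hi):
            raise ConfigError("episode_duration_hours must satisfy 0 < lo <= hi")
        m, h = self.mild_effect, self.high_effect
        if not (0.15 <= m.rumination_cut[0] <= m.rumination_cut[1] <= 0.25):
            raise ConfigError("mild rumination cut must stay within [0.15, 0.25]")
        # uniform draws on [lo, hi) keep the band half-open at 0.60
        if not (0.45 <= m.amplitude_target[0] <= m.amplitude_target[1] <= 0.60):
            raise ConfigError("mild amplitude target must stay within [0.45, 0.60)")
        if h.rumination_cut[0] <= 0.40:
            raise ConfigError("high rumination cut must exceed 0.40")
        if h.amplitude_target[1] > 0.45:
            raise ConfigError("high amplitude target must stay below 0.45")


@dataclass
class HerdDataset:
    """In-memory container for one simulated (or loaded) herd.

    behavior : one row per cow-hour with the four budget columns
    weather  : one row per hour (temp_c, rh_pct)
    vet      : positive veterinary findings only (absence means level 0)
    milk     : one row per cow-day (yield_kg)
    truth    : latent stress state per cow-hour (absent for real data)
    """

    behavior: pd.DataFrame
    weather: pd.DataFrame
    vet: pd.DataFrame
    milk: pd.DataFrame
    truth: pd.DataFrame | None = None
    config: SimConfig | None = None

    @property
    def cow_ids(self) -> list[str]:
        return sorted(self.behavior["cow_id"].unique())


def _cow_id(i: int) -> str:
    return f"cow_{i + 1:02d}"


def _episode_track(
    rng: np.random.Generator, config: SimConfig, n_hours: int
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Latent state per hour (0/1/2) plus the episode list (start, dur, sev)."""
    state = np.zeros(n_hours, dtype=np.int8)
    episodes: list[tuple[int, int, int]] = []
    lo, hi = config.episode_duration_hours
    for severity, rate in ((1, config.episode_rate_mild), (2, config.episode_rate_high)):
        n_ep = rng.poisson(rate * config.n_days / 30.0)
        starts = rng.integers(0, n_hours, size=n_ep)
        durs = rng.integers(lo, hi + 1, size=n_ep)
        for s, d in zip(starts, durs):
            episodes.append((int(s), int(d), severity))
    # overlapping episodes merge to the higher severity
    for s, d, sev in sorted(episodes):
        end = min(s + d, n_hours)
        state[s:end] = np.maximum(state[s:end], sev)
    return state, episodes


def _episode_params(
    rng: np.random.Generator, config: SimConfig, state: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-hour (amplitude, phase shift, rumination cut) from contiguous runs.

    Draws one parameter triple per contiguous non-normal run so an episode
    behaves consistently across its whole span.
    """
    n = len(state)
    amp = np.full(n, np.nan)
    shift = np.zeros(n)
    cut = np.zeros(n)
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        eff = config.mild_effect if state[i] == 1 else config.high_effect
        amp[i:j] = rng.uniform(*eff.amplitude_target)
        shift[i:j] = rng.uniform(*eff.phase_shift_h) * rng.choice([-1.0, 1.0])
        cut[i:j] = rng.uniform(*eff.rumination_cut)
        i = j
    return amp, shift, cut


def _cow_budgets(
    rng: np.random.Generator,
    config: SimConfig,
    state: np.ndarray,
    n_hours: int,
) -> pd.DataFrame:
    depth = float(np.clip(
        rng.normal(config.base_amplitude, config.amplitude_jitter_sd), 0.30, 0.95
    ))
    phase = rng.normal(config.acrophase_hour_mean, config.acrophase_jitter_sd) % 24.0

    amp_ep, shift_ep, cut_ep = _episode_params(rng, config, state)
    hour = np.arange(n_hours)
    m = np.where(np.isnan(amp_ep), depth, amp_ep)
    theta = 2.0 * np.pi * ((hour % 24) - (phase + shift_ep)) / 24.0
    cosine = np.cos(theta)

    cols = {}
    for name, mu in _MEAN_BUDGET.items():
        cols[name] = mu * (1.0 + _MODULATION[name] * m * cosine)
    # rumination cut with proportional redistribution to the other three
    deficit = cols["ruminate"] * cut_ep
    cols["ruminate"] = cols["ruminate"] - deficit
    other_sum = cols["eat"] + cols["rest"] + cols["other"]
    for name in ("eat", "rest", "other"):
        cols[name] = cols[name] * (1.0 + deficit / other_sum)

    x = np.column_stack([cols["eat"], cols["rest"], cols["ruminate"], cols["other"]])
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
    x = np.clip(x, 0.05, None)
    x = x * (60.0 / x.sum(axis=1, keepdims=True))
    return pd.DataFrame(x, columns=BEHAVIOR_COLUMNS)


def _weather(rng: np.random.Generator, config: SimConfig, n_hours: int) -> pd.DataFrame:
    wp = config.weather
    n_days = (n_hours + 23) // 24
    drift = np.zeros(n_days)
    eps = rng.normal(0.0, wp.temp_drift_sd_c, size=n_days)
    for d in range(1, n_days):
        drift[d] = wp.temp_drift_ar1 * drift[d - 1] + eps[d]
    drift[0] = eps[0]
    hour = np.arange(n_hours)
    diurnal = np.cos(2.0 * np.pi * ((hour % 24) - 15) / 24.0)
    temp = (
        wp.temp_mean_c
        + drift[hour // 24]
        + 0.5 * wp.temp_diurnal_range_c * diurnal
        + rng.normal(0.0, wp.temp_noise_sd_c, size=n_hours)
    )
    rh = (
        wp.rh_mean_pct
        - 0.5 * wp.rh_diurnal_range_pct * diurnal
        + rng.normal(0.0, wp.rh_noise_sd_pct, size=n_hours)
    )
    return pd.DataFrame(
        {"temp_c": temp, "rh_pct": np.clip(rh, 5.0, 100.0)}
    )


def _vet_records(
    rng: np.random.Generator,
    config: SimConfig,
    cow: str,
    state: np.ndarray,
    timestamps: pd.DatetimeIndex,
) -> list[dict]:
    records = []
    n_hours = len(state)
    for h in range(n_hours):
        clock = timestamps[h].hour
        if clock not in (6, 18):
            continue
        latent = int(state[h])
        signs: list[str] = []
        level = 0
        if latent == 0:
            if rng.random() > config.vet_specificity:
                signs = [str(rng.choice(TRANSIENT_SIGNS))]
                level = 1
        elif rng.random() < config.vet_sensitivity:
            if latent == 2 and rng.random() < config.vet_marked_prob:
                signs = [str(rng.choice(sorted(MARKED_SIGNS)))]
                level = 2
            else:
                signs = [str(rng.choice(TRANSIENT_SIGNS))]
                level = 1
        if signs:
            records.append(
                {
                    "cow_id": cow,
                    "date": timestamps[h].date().isoformat(),
                    "round": f"{clock:02d}:00",
                    "signs": ";".join(signs),
                    "level": level,
                }
            )
    return records


def simulate_herd(config: SimConfig) -> HerdDataset:
    """Simulate one herd under the given study conditions.

    Returns a :class:`HerdDataset`; an ``n_cows=0`` config yields empty
    (but correctly typed) frames.
    """
    rng = np.random.default_rng(config.seed)
    n_hours = config.n_days * 24
    timestamps = pd.date_range(config.start_date, periods=n_hours, freq="h")

    weather = _weather(rng, config, n_hours)
    weather.insert(0, "timestamp", timestamps)

    behavior_parts, truth_parts, vet_rows, milk_rows = [], [], [], []
    for i in range(config.n_cows):
        cow = _cow_id(i)
        cow_rng = np.random.default_rng([config.seed, 1000 + i])
        state, _ = _episode_track(cow_rng, config, n_hours)
        budgets = _cow_budgets(cow_rng, config, state, n_hours)
        budgets.insert(0, "timestamp", timestamps)
        budgets.insert(0, "cow_id", cow)
        behavior_parts.append(budgets)
        truth_parts.append(
            pd.DataFrame(
                {
                    "cow_id": cow,
                    "timestamp": timestamps,
                    "state": np.array(STATE_NAMES)[state],
                }
            )
        )
        vet_rows.extend(_vet_records(cow_rng, config, cow, state, timestamps))

        base = cow_rng.normal(config.milk_baseline_kg, config.milk_between_cow_sd)
        day_state = state[: config.n_days * 24].reshape(config.n_days, 24)
        any_high = (day_state == 2).any(axis=1)
        any_mild = (day_state == 1).any(axis=1)
        penalty = np.where(any_high, 1.0, np.where(any_mild, 0.5, 0.0))
        # lingering half-penalty the day after an episode
        after = np.zeros(config.n_days)
        after[1:] = 0.5 * penalty[:-1]
        y = (
            base * (1.0 - config.milk_penalty_frac * np.maximum(penalty, after))
            + cow_rng.normal(0.0, config.milk_noise_sd, size=config.n_days)
        )
        dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
        milk_rows.append(
            pd.DataFrame({"cow_id": cow, "date": dates.date, "yield_kg": y})
        )

    empty = config.n_cows == 0
    behavior = (
        pd.concat(behavior_parts, ignore_index=True)
        if not empty
        else pd.DataFrame(columns=["cow_id", "timestamp"] + BEHAVIOR_COLUMNS)
    )
    truth = (
        pd.concat(truth_parts, ignore_index=True)
        if not empty
        else pd.DataFrame(columns=["cow_id", "timestamp", "state"])
    )
    vet = pd.DataFrame(vet_rows, columns=["cow_id", "date", "round", "signs", "level"])
    milk = (
        pd.concat(milk_rows, ignore_index=True)
        if not empty
        else pd.DataFrame(columns=["cow_id", "date", "yield_kg"])
    )
    return HerdDataset(
        behavior=behavior, weather=weather, vet=vet, milk=milk, truth=truth,
        config=config,
    )


def write_fixtures(dataset: HerdDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as CSV fixtures; returns the file paths.

    Files: behavior.csv, weather.csv, vet.csv, milk.csv and (when a truth
    track exists) truth.csv. Float formatting is fixed so identical seeds
    give byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _dump(name: str, frame: pd.DataFrame) -> None:
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path

    _dump("behavior", dataset.behavior)
    _dump("weather", dataset.weather)
    _dump("vet", dataset.vet)
    _dump("milk", dataset.milk)
    if dataset.truth is not None:
        _dump("truth", dataset.truth)
    return paths


def read_dataset(directory: str | Path) -> HerdDataset:
    """Read CSV fixtures written by :func:`write_fixtures`."""
    directory = Path(directory)
    behavior = pd.read_csv(directory / "behavior.csv", parse_dates=["timestamp"])
    weather = pd.read_csv(directory / "weather.csv", parse_dates=["timestamp"])
    vet = pd.read_csv(
        directory / "vet.csv",
        dtype={"cow_id": str, "date": str, "round": str, "signs": str},
    )
    if "level" in vet.columns and len(vet):
        vet["level"] = vet["level"].astype(int)
    milk = pd.read_csv(directory / "milk.csv", dtype={"cow_id": str, "date": str})
    truth_path = directory / "truth.csv"
    truth = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path, parse_dates=["timestamp"])
    return HerdDataset(behavior=behavior, weather=weather, vet=vet, milk=milk, truth=truth)


def latent_state_mix(truth: pd.DataFrame) -> dict[str, float]:
    """Realized latent-state proportions at the cow-hour level."""
    if len(truth) == 0:
        return {name: float("nan") for name in STATE_NAMES}
    counts = truth["state"].value_counts()
    n = len(truth)
    return {name: float(counts.get(name, 0)) / n for name in STATE_NAMES}
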