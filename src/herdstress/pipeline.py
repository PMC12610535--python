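"""End-to-end labeling pipeline.

Chains the activity index, sliding spectral analysis and change detection
into hourly and cow-day stress labels for a whole herd, and derives the
causal hourly feature table used by the sequence models.

Timeline conventions
--------------------
* A window starting at hour ``s`` spans ``[s, s+36h)``; its day/night pair
  uses the first 24 h ``[s, s+24h)``.
* The window's label is indexed by its *reference time* ``t = s + 24h``
  (the exclusive end of the day/night span): it describes the stress state
  as of hour ``t`` based on the preceding 24 h of circadian contrast.
  Contextual flags are evaluated within ``[t-1h, t+1h]`` and do not
  propagate further.
* Cow-day labels roll up the hourly labels by the reference time's
  calendar date (maximum severity of the day).
* Model features at hour ``t`` come from the window *ending* at ``t``
  (start ``t-35h``), so every feature channel is causal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityWeights, calibrate_weights, compute_activity
from .detection import (
    BaselineThresholds,
    binarize_vet,
    compute_thi,
    fit_thresholds,
    label_stress,
    rollup_cow_day,
)
from .spectral import SpectralConfig, analyze_series
from .synthetic import HerdDataset

__all__ = ["LabelingConfig", "PipelineResult", "run_pipeline", "recovery_metrics"]

_STATE_TO_INT = {"normal": 0, "mild": 1, "high": 2}


@dataclass(frozen=True)
class LabelingConfig:
    calibration_days: int = 14
    calibration_mode: str = "contrast"  # compositional budgets need a contrast
    min_baseline_days: int = 14
    thi_comfort_max: float = 68.0
    tolerance_h: int = 1
    # circadian-deviation flag: acrophase shift beyond this many hours from
    # the cow's event-free median, or amplitude below this fraction of the
    # cow's event-free median amplitude
    phase_shift_max_h: float = 3.0
    amplitude_drop_frac: float = 0.45
    # ablation switches: drop the veterinary / thermal flag from labeling
    use_vet: bool = True
    use_thi: bool = True
    spectral: SpectralConfig = field(default_factory=SpectralConfig)


@dataclass
class PipelineResult:
    weights: ActivityWeights
    activity: pd.DataFrame
    window_features: pd.DataFrame  # per (cow, window start): spectra + d + flags + label
    hourly_labels: pd.DataFrame    # per (cow, reference hour)
    daily_labels: pd.DataFrame     # per (cow, date): rollup + episode segments
    daily_features: pd.DataFrame   # 06:00-anchored per cow-day summaries
    thresholds: dict[str, BaselineThresholds]
    norm_stats: dict[str, tuple[float, float]]
    stability: dict[str, float]
    model_features: pd.DataFrame   # causal hourly channels for the classifiers


def _event_free_dates(
    dataset: HerdDataset, cow: str, thi_hot_dates: set, vet_pos_dates: set
) -> set:
    """Dates with no vet finding, all THI in the comfort zone and (when a
    truth track exists) a normal latent state all day."""
    all_dates = set(
        pd.to_datetime(
            dataset.behavior.loc[dataset.behavior["cow_id"] == cow, "timestamp"]
        ).dt.date
    )
    ok = all_dates - thi_hot_dates - vet_pos_dates
    if dataset.truth is not None and len(dataset.truth):
        tr = dataset.truth[dataset.truth["cow_id"] == cow]
        bad = set(
            pd.to_datetime(tr.loc[tr["state"] != "normal", "timestamp"]).dt.date
        )
        ok = ok - bad
    return ok


def _circular_shift_h(a: np.ndarray, b: float) -> np.ndarray:
    """Absolute circular distance between clock hours, in [0, 12]."""
    d = np.abs(a - b) % 24.0
    return np.minimum(d, 24.0 - d)


def run_pipeline(
    dataset: HerdDataset,
    config: LabelingConfig | None = None,
    weights: ActivityWeights | None = None,
) -> PipelineResult:
    """Label a herd from raw budgets, weather and vet records."""
    config = config or LabelingConfig()
    N = config.spectral.N
    if weights is None:
        weights = calibrate_weights(
            dataset.behavior, config.calibration_days, mode=config.calibration_mode
        )
    activity = compute_activity(dataset.behavior, weights)
    features, recons, _ = analyze_series(activity, config.spectral)

    weather = dataset.weather.sort_values("timestamp")
    thi = compute_thi(weather["temp_c"].to_numpy(), weather["rh_pct"].to_numpy())
    hot = pd.Series(thi > config.thi_comfort_max, index=pd.DatetimeIndex(weather["timestamp"]))
    thi_hot_dates = set(hot.index[hot.to_numpy()].date)

    vet = dataset.vet
    vet_pos_times: set[pd.Timestamp] = set()
    vet_pos_dates_by_cow: dict[str, set] = {}
    vet_daily_rows = []
    if len(vet):
        for (cow, date), grp in vet.groupby(["cow_id", "date"], sort=True):
            level, persistence = binarize_vet(grp)
            vet_daily_rows.append(
                {"cow_id": cow, "date": date, "vet_level": level, "persistence": persistence}
            )
            if level > 0:
                vet_pos_dates_by_cow.setdefault(str(cow), set()).add(
                    pd.Timestamp(date).date()
                )
                for rnd in grp["round"]:
                    vet_pos_times.add(pd.Timestamp(f"{date} {rnd}"))

    win_parts, hourly_parts, daily_parts, daily_feat_parts = [], [], [], []
    thresholds: dict[str, BaselineThresholds] = {}
    norm_stats: dict[str, tuple[float, float]] = {}
    stability: dict[str, float] = {}
    model_parts = []

    for cow in dataset.cow_ids:
        fcow = features[features["cow_id"] == cow].reset_index(drop=True)
        rec = recons[cow]
        starts = pd.DatetimeIndex(fcow["start"])
        n_win = len(fcow)
        first24 = rec[:, :24]

        ef_dates = _event_free_dates(
            dataset, cow, thi_hot_dates, vet_pos_dates_by_cow.get(cow, set())
        )
        start_dates = starts.date
        end_dates = (starts + pd.Timedelta(hours=23)).date
        ef_window = np.array(
            [sd in ef_dates and ed in ef_dates for sd, ed in zip(start_dates, end_dates)]
        )
        if ef_window.sum() < config.min_baseline_days:
            raise ValueError(
                f"cow {cow}: only {int(ef_window.sum())} event-free windows; "
                f"need at least {config.min_baseline_days}"
            )

        # per-cow z-normalization of s_circ from the event-free baseline
        base_vals = first24[ef_window].ravel()
        mu, sd = float(base_vals.mean()), float(base_vals.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"cow {cow}: degenerate baseline s_circ")
        norm_stats[cow] = (mu, sd)
        z = (first24 - mu) / sd

        # vectorized day/night RMS distance, grouped by start clock hour
        d = np.empty(n_win)
        clocks = starts.hour.to_numpy()
        for c in np.unique(clocks):
            rows = np.flatnonzero(clocks == c)
            ia = (np.arange(6, 18) - c) % 24
            ib = (np.arange(18, 30) - c) % 24
            diff = z[np.ix_(rows, ia)] - z[np.ix_(rows, ib)]
            d[rows] = np.sqrt(np.mean(diff * diff, axis=1))

        thr = fit_thresholds(d[ef_window], cow, config.min_baseline_days)
        thresholds[cow] = thr

        amp = fcow["amplitude"].to_numpy(dtype=float)
        acro = fcow["acrophase_h"].to_numpy(dtype=float)
        amp_med = float(np.nanmedian(amp[ef_window]))
        acro_base = acro[ef_window]
        acro_med = float(np.nanmedian(acro_base[np.isfinite(acro_base)]))
        circ_flag = (amp < config.amplitude_drop_frac * amp_med) | (
            _circular_shift_h(acro, acro_med) > config.phase_shift_max_h
        )

        t_ref = starts + pd.Timedelta(hours=24)
        tol = config.tolerance_h
        near = [t_ref + pd.Timedelta(hours=k) for k in range(-tol, tol + 1)]
        thi_flag = np.zeros(n_win, dtype=bool)
        vet_flag = np.zeros(n_win, dtype=bool)
        for stamps in near:
            thi_flag |= hot.reindex(stamps, fill_value=False).to_numpy()
            vet_flag |= np.array([pd.Timestamp(t) in vet_pos_times for t in stamps])
        if not config.use_thi:
            thi_flag[:] = False
        if not config.use_vet:
            vet_flag[:] = False

        labels = np.empty(n_win, dtype=int)
        tiers = np.empty(n_win, dtype=int)
        for w in range(n_win):
            lab = label_stress(
                d[w], thr, vet_flag[w], thi_flag[w], bool(circ_flag[w]), tol
            )
            labels[w], tiers[w] = lab.label, lab.d_tier

        frac = float(np.mean(fcow["clear_peak"].to_numpy() & fcow["in_band"].to_numpy()))
        stability[cow] = frac

        wf = fcow.copy()
        wf["d_t"] = d
        wf["T1"], wf["T2"] = thr.T1, thr.T2
        wf["event_free"] = ef_window
        wf["vet_flag"], wf["thi_flag"], wf["circ_flag"] = vet_flag, thi_flag, circ_flag
        wf["d_tier"], wf["label"] = tiers, labels
        wf["t_ref"] = t_ref
        win_parts.append(wf)

        hourly = pd.DataFrame(
            {"cow_id": cow, "timestamp": t_ref, "label": labels, "d_t": d}
        )
        hourly_parts.append(hourly)
        for date, grp in hourly.groupby(hourly["timestamp"].dt.date):
            day_label, episodes = rollup_cow_day(grp["label"].to_numpy())
            daily_parts.append(
                {
                    "cow_id": cow,
                    "date": date,
                    "label": day_label,
                    "n_hours": len(grp),
                    "n_episodes": len(episodes),
                }
            )

        # 06:00-anchored daily summaries
        at6 = np.flatnonzero(clocks == 6)
        df6 = fcow.iloc[at6].copy()
        df6["date"] = starts[at6].date
        df6["d_t"] = d[at6]
        df6["stability_fraction"] = frac
        daily_feat_parts.append(
            df6[
                [
                    "cow_id", "date", "amplitude", "acrophase_h", "coherence",
                    "stability_fraction", "k_star", "snr_db", "d_t",
                ]
            ]
        )

        # causal hourly model features: window ending at hour t
        feat_t = starts + pd.Timedelta(hours=N - 1)
        model_parts.append(
            pd.DataFrame(
                {
                    "cow_id": cow,
                    "timestamp": feat_t,
                    "s_circ": rec[:, N - 1],
                    "amplitude": amp,
                    "acrophase_h": acro,
                    "coherence": fcow["coherence"].to_numpy(),
                }
            )
        )

    window_features = pd.concat(win_parts, ignore_index=True)
    hourly_labels = pd.concat(hourly_parts, ignore_index=True)
    daily_labels = pd.DataFrame(daily_parts)
    daily_features = pd.concat(daily_feat_parts, ignore_index=True)
    # attach the composite index and the z-scored budget channels
    from .synthetic import BEHAVIOR_COLUMNS

    zb = dataset.behavior[["cow_id", "timestamp"]].copy()
    for col in BEHAVIOR_COLUMNS:
        zb[f"z_{col}"] = (
            dataset.behavior[col] - weights.calibration_means[col]
        ) / weights.calibration_sds[col]
    model_features = (
        pd.concat(model_parts, ignore_index=True)
        .merge(activity, on=["cow_id", "timestamp"], how="left")
        .merge(zb, on=["cow_id", "timestamp"], how="left")
    )
    return PipelineResult(
        weights=weights,
        activity=activity,
        window_features=window_features,
        hourly_labels=hourly_labels,
        daily_labels=daily_labels,
        daily_features=daily_features,
        thresholds=thresholds,
        norm_stats=norm_stats,
        stability=stability,
        model_features=model_features,
    )


def recovery_metrics(
    daily_labels: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Cow-day recovery of injected episodes against the latent truth.

    A truth cow-day is *high* when any hour of the day is latently high,
    *stressed* when any hour is non-normal. Reports:

    - sensitivity_high: truth-high days predicted high
    - sensitivity_any: truth-stressed days predicted non-normal
    - specificity: fully-normal truth days predicted normal
    """
    tr = truth.copy()
    tr["date"] = pd.to_datetime(tr["timestamp"]).dt.date
    tr["state_int"] = tr["state"].map(_STATE_TO_INT)
    truth_day = tr.groupby(["cow_id", "date"])["state_int"].max().rename("truth")
    merged = daily_labels.merge(truth_day, on=["cow_id", "date"], how="inner")
    high = merged["truth"] == 2
    stressed = merged["truth"] > 0
    normal = merged["truth"] == 0
    out = {
        "sensitivity_high": float((merged.loc[high, "label"] == 2).mean())
        if high.any()
        else float("nan"),
        "sensitivity_any": float((merged.loc[stressed, "label"] > 0).mean())
        if stressed.any()
        else float("nan"),
        "specificity": float((merged.loc[normal, "label"] == 0).mean())
        if normal.any()
        else float("nan"),
        "n_days": float(len(merged)),
    }
    return out
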