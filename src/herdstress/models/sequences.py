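"""Sequence dataset construction for the stress classifiers.

Each sample is a 24 h sliding window of hourly feature channels for one
cow, anchored at its last hour ``t``; the target is the stress label at
``t`` (contemporary classification) or ``t + 1 h`` (prospective
prediction). Feature channels never include the veterinary indicator, the
THI or the distance statistic d_t — those drive the labels and would leak
the answer — and never any value recorded after the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SequenceData", "ChannelScaler", "make_sequences", "BEHAVIOR_CHANNELS", "FFT_CHANNELS"]

BEHAVIOR_CHANNELS = ["z_eat_min", "z_rest_min", "z_ruminate_min", "z_other_min"]
#: spectral channels; acrophase enters as (sin, cos) to avoid the 24 h wrap
FFT_CHANNELS = ["s_circ", "amplitude", "acro_sin", "acro_cos", "coherence"]


@dataclass
class SequenceData:
    X: np.ndarray          # (n, window, channels)
    y: np.ndarray          # (n,) int labels at anchor + horizon
    cow_ids: np.ndarray    # (n,) str
    anchors: np.ndarray    # (n,) datetime64 anchor times
    channels: list[str]
    horizon: int

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "SequenceData":
        return SequenceData(
            X=self.X[mask], y=self.y[mask], cow_ids=self.cow_ids[mask],
            anchors=self.anchors[mask], channels=self.channels, horizon=self.horizon,
        )


class ChannelScaler:
    """Per-channel standardization fitted on training samples only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ChannelScaler":
        self.mean_ = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (X - self.mean_) / self.sd_


def make_sequences(
    model_features: pd.DataFrame,
    hourly_labels: pd.DataFrame,
    horizon: int = 0,
    window: int = 24,
    stride: int = 1,
    with_fft: bool = True,
) -> SequenceData:
    """Build sliding 24 h sequence samples per cow.

    ``model_features`` must carry the causal hourly channels (z-scored
    budgets plus the spectral channels); ``hourly_labels`` the hourly
    labels. For ``T`` gap-free feature hours and stride 1 the builder
    yields ``T - window - horizon + 1`` samples. Samples whose feature
    window or target crosses a gap, or whose target label is missing, are
    dropped.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    channels = list(BEHAVIOR_CHANNELS) + (list(FFT_CHANNELS) if with_fft else [])

    feats = model_features.copy()
    acro = np.deg2rad(feats["acrophase_h"].to_numpy(dtype=float) * 15.0)  # h -> deg
    feats["acro_sin"] = np.sin(acro)
    feats["acro_cos"] = np.cos(acro)

    lab = hourly_labels.set_index(["cow_id", "timestamp"])["label"]

    Xs, ys, cows, anchors = [], [], [], []
    for cow, grp in feats.groupby("cow_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        ts = pd.DatetimeIndex(grp["timestamp"])
        contiguous = np.ones(len(grp), dtype=bool)
        contiguous[1:] = (ts[1:] - ts[:-1]) == pd.Timedelta(hours=1)
        mat = grp[channels].to_numpy(dtype=float)
        for end in range(window - 1, len(grp), stride):
            startI = end - window + 1
            if not contiguous[startI + 1 : end + 1].all():
                continue
            block = mat[startI : end + 1]
            if not np.all(np.isfinite(block)):
                continue
            target_time = ts[end] + pd.Timedelta(hours=horizon)
            y = lab.get((cow, target_time))
            if y is None or (isinstance(y, float) and np.isnan(y)):
                continue
            Xs.append(block)
            ys.append(int(y))
            cows.append(str(cow))
            anchors.append(ts[end].to_datetime64())
    if not Xs:
        return SequenceData(
            X=np.empty((0, window, len(channels))), y=np.empty(0, dtype=int),
            cow_ids=np.empty(0, dtype=object), anchors=np.empty(0, dtype="datetime64[ns]"),
            channels=channels, horizon=horizon,
        )
    return SequenceData(
        X=np.stack(Xs), y=np.array(ys, dtype=int), cow_ids=np.array(cows, dtype=object),
        anchors=np.array(anchors), channels=channels, horizon=horizon,
    )
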