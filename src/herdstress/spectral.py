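"""Sliding-window circadian spectral analysis.

A 36-sample (36 h at 1 h sampling) rectangular window slides along each
cow's activity series with a 1 h step. Each window is Fourier-transformed
(unnormalized forward DFT, ``S[k] = sum_t s[t] e^{-i 2 pi k t / N}``), the
dominant non-DC peak is screened with prominence/SNR criteria, the
circadian band (bins 1-2, i.e. 36 h and 18 h periods straddling the 24 h
line at f = 1/24 h^-1) plus any clearly peaked harmonics (bins 3-4) is
retained, and the inverse transform reconstructs the smooth circadian
component s_circ(t). Per-window features are:

amplitude
    single-sided amplitude 2|S[k]|/N of the strongest retained bin — equal
    to the cosine amplitude for an on-bin tone (the off-bin 24 h tone is
    underestimated by scalloping; see docs/methods.md);
acrophase
    clock time of the reconstruction's maximum within the central 24 h of
    the window;
coherence
    circadian-band share of non-DC spectral power, in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralConfig",
    "SpectrumWindow",
    "PeakDetection",
    "CircadianProfile",
    "count_windows",
    "bin_frequencies",
    "fft_window",
    "detect_dominant_peak",
    "stability_fraction",
    "circadian_filter",
    "reconstruct",
    "circadian_features",
    "analyze_series",
]


@dataclass(frozen=True)
class SpectralConfig:
    N: int = 36
    dt: float = 1.0
    step: int = 1
    circadian_bins: tuple[int, ...] = (1, 2)
    harmonic_bins: tuple[int, ...] = (3, 4)
    prominence_mad_mult: float = 2.0
    snr_db_min: float = 6.0
    stability_min_fraction: float = 0.60
    include_harmonics: str = "auto"  # auto | always | never

    def __post_init__(self) -> None:
        if self.N < 2 or self.dt <= 0 or self.step < 1:
            raise ValueError("need N >= 2, dt > 0, step >= 1")
        # the window must span at least 1.5 circadian cycles
        if self.N * self.dt < 1.5 * 24.0 * 0.999:
            raise ValueError(
                f"window of {self.N * self.dt:g} h is shorter than 1.5 x 24 h"
            )
        if any(b >= self.N / 2 for b in self.circadian_bins + self.harmonic_bins):
            raise ValueError("band bins must lie below N/2")
        if self.include_harmonics not in ("auto", "always", "never"):
            raise ValueError("include_harmonics must be auto|always|never")


@dataclass
class SpectrumWindow:
    """One windowed signal slice and its complex DFT."""

    s: np.ndarray
    S: np.ndarray
    dt: float = 1.0
    cow_id: str | None = None
    start: pd.Timestamp | None = None
    retained_bins: tuple[int, ...] | None = None  # set by circadian_filter

    @property
    def N(self) -> int:
        return len(self.s)

    @property
    def bin_freqs(self) -> np.ndarray:
        return bin_frequencies(self.N, self.dt)


@dataclass(frozen=True)
class PeakDetection:
    k_star: int
    magnitude: float
    prominence_mads: float
    snr_db: float
    is_clear_peak: bool
    in_circadian_band: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CircadianProfile:
    amplitude: float
    acrophase: float | None  # clock hours in [0, 24); None for an all-zero window
    coherence: float
    cow_id: str | None = None
    start: pd.Timestamp | None = None


def count_windows(T: int, N: int, step: int = 1) -> int:
    """Number of sliding-window start positions: (T - N)//step + 1."""
    if T < N:
        raise ValueError(f"series of {T} h is shorter than one {N} h window")
    return (T - N) // step + 1


def bin_frequencies(N: int, dt: float = 1.0) -> np.ndarray:
    """DFT bin frequencies f_k = k/(N*dt), k = 0..N-1, in cycles/hour."""
    if N < 2 or dt <= 0:
        raise ValueError("need N >= 2 and dt > 0")
    return np.arange(N) / (N * dt)


def fft_window(
    s: np.ndarray,
    dt: float = 1.0,
    cow_id: str | None = None,
    start: pd.Timestamp | None = None,
) -> SpectrumWindow:
    """Unnormalized forward DFT of one window (the inverse carries the 1/N)."""
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        bad = np.flatnonzero(~np.isfinite(s))
        where = f"cow {cow_id}, window start {start}, " if cow_id else ""
        raise ValueError(f"non-finite samples ({where}offsets {bad.tolist()})")
    return SpectrumWindow(s=s, S=np.fft.fft(s), dt=dt, cow_id=cow_id, start=start)


def _bin_peak_stats(mags: np.ndarray, k: int, N: int) -> tuple[float, float, bool]:
    """Prominence (in MADs) and SNR (dB) of bin ``k`` vs its +-2-bin
    neighborhood restricted to 1..N//2 (edge neighborhoods truncate)."""
    lo, hi = max(1, k - 2), min(N // 2, k + 2)
    neigh = np.array([mags[j] for j in range(lo, hi + 1) if j != k])
    med = float(np.median(neigh))
    mad = float(np.median(np.abs(neigh - med)))
    degenerate = False
    if mad == 0.0:
        degenerate = True
        prominence = math.inf if mags[k] > med else 0.0
    else:
        prominence = (mags[k] - med) / mad
    if med <= 0.0:
        snr = math.inf if mags[k] > 0 else 0.0
    else:
        snr = 20.0 * math.log10(mags[k] / med) if mags[k] > 0 else -math.inf
    return prominence, snr, degenerate


def detect_dominant_peak(window: SpectrumWindow, config: SpectralConfig) -> PeakDetection:
    """Locate the dominant non-DC peak and screen it.

    The search runs over k = 1..N//2 (the DC bin is excluded; the activity
    index is already centered). A peak is *clear* when its prominence is at
    least ``prominence_mad_mult`` MADs above the local median and its SNR
    (20 log10 of magnitude over local median) reaches ``snr_db_min`` dB.
    """
    mags = np.abs(window.S)
    N = window.N
    k_star = int(np.argmax(mags[1 : N // 2 + 1]) + 1)
    prominence, snr, degenerate = _bin_peak_stats(mags, k_star, N)
    clear = prominence >= config.prominence_mad_mult and snr >= config.snr_db_min
    return PeakDetection(
        k_star=k_star,
        magnitude=float(mags[k_star]),
        prominence_mads=prominence,
        snr_db=snr,
        is_clear_peak=bool(clear),
        in_circadian_band=k_star in config.circadian_bins,
        degenerate=degenerate,
    )


def stability_fraction(
    peaks: list[PeakDetection], config: SpectralConfig | None = None
) -> tuple[float, bool]:
    """Fraction of windows whose clear peak sits in the circadian band,
    plus the pass/fail verdict at the configured threshold (default 0.60)."""
    if not peaks:
        raise ValueError("need at least one window")
    frac = sum(p.is_clear_peak and p.in_circadian_band for p in peaks) / len(peaks)
    threshold = config.stability_min_fraction if config is not None else 0.60
    return frac, frac >= threshold


def _retained_bins(window: SpectrumWindow, config: SpectralConfig) -> tuple[int, ...]:
    bins = list(config.circadian_bins)
    if config.include_harmonics == "always":
        bins += list(config.harmonic_bins)
    elif config.include_harmonics == "auto":
        mags = np.abs(window.S)
        for h in config.harmonic_bins:
            prominence, snr, _ = _bin_peak_stats(mags, h, window.N)
            if prominence >= config.prominence_mad_mult and snr >= config.snr_db_min:
                bins.append(h)
    return tuple(sorted(set(bins)))


def circadian_filter(
    window: SpectrumWindow,
    config: SpectralConfig,
    peak: PeakDetection | None = None,
) -> SpectrumWindow:
    """Band-pass the spectrum around the circadian frequency.

    Keeps the circadian bins (and, in ``auto`` mode, harmonic bins that
    individually satisfy the clear-peak criteria) together with their
    conjugate mirrors N-k; the DC bin and everything else is zeroed, so the
    filter is idempotent and the reconstruction stays real.
    """
    bins = _retained_bins(window, config)
    N = window.N
    mask = np.zeros(N, dtype=bool)
    for k in bins:
        mask[k] = True
        mask[N - k] = True
    S_f = np.where(mask, window.S, 0.0)
    return SpectrumWindow(
        s=window.s, S=S_f, dt=window.dt, cow_id=window.cow_id, start=window.start,
        retained_bins=bins,
    )


def reconstruct(filtered: SpectrumWindow) -> np.ndarray:
    """Inverse DFT of the filtered spectrum; asserts the result is real."""
    x = np.fft.ifft(filtered.S)
    scale = max(float(np.abs(filtered.S).max()), 1.0)
    if float(np.abs(x.imag).max()) > 1e-9 * scale:
        raise RuntimeError(
            "reconstruction has imaginary residue: filtered spectrum is not "
            "conjugate-symmetric (filter bug)"
        )
    return x.real


def circadian_features(
    filtered: SpectrumWindow,
    reconstruction: np.ndarray,
    unfiltered: SpectrumWindow | None = None,
) -> CircadianProfile:
    """Amplitude, acrophase and coherence of one filtered window.

    ``unfiltered`` supplies the full spectrum for the coherence denominator;
    when omitted, the FFT of ``filtered.s`` is used.
    """
    N = filtered.N
    bins = filtered.retained_bins or ()
    mags = np.abs(filtered.S)
    if bins:
        k_best = max(bins, key=lambda k: mags[k])
        amplitude = 2.0 * float(mags[k_best]) / N
    else:
        amplitude = 0.0

    full_S = unfiltered.S if unfiltered is not None else np.fft.fft(filtered.s)
    total = float(np.sum(np.abs(full_S[1:]) ** 2))
    band = float(np.sum(np.abs(filtered.S[1:]) ** 2))
    coherence = band / total if total > 0 else 0.0

    acrophase: float | None
    if amplitude <= 0.0 or not np.any(reconstruction):
        acrophase = None
    else:
        # read the peak from the central 24 h to dodge window-edge effects
        n24 = int(round(24.0 / filtered.dt))
        lo = (N - n24) // 2
        seg = reconstruction[lo : lo + n24]
        offset = lo + int(np.argmax(seg))
        start_clock = float(filtered.start.hour) if filtered.start is not None else 0.0
        acrophase = (start_clock + offset * filtered.dt) % 24.0
    return CircadianProfile(
        amplitude=amplitude,
        acrophase=acrophase,
        coherence=min(coherence, 1.0),
        cow_id=filtered.cow_id,
        start=filtered.start,
    )


def analyze_series(
    activity: pd.DataFrame,
    config: SpectralConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, pd.Timestamp]]:
    """Run the sliding spectral analysis for every cow.

    Parameters
    ----------
    activity : frame with columns cow_id, timestamp, activity (gap-free,
        hourly, per cow).
    config : spectral configuration (defaults throughout).

    Returns
    -------
    features : one row per (cow, window start) with columns
        cow_id, start, k_star, magnitude, prominence_mads, snr_db,
        clear_peak, in_band, amplitude, acrophase_h, coherence.
    reconstructions : per cow, array of shape (n_windows, N) holding
        s_circ for each window.
    starts : per cow, the first window-start timestamp.
    """
    config = config or SpectralConfig()
    rows = []
    recons: dict[str, np.ndarray] = {}
    starts: dict[str, pd.Timestamp] = {}
    for cow, grp in activity.groupby("cow_id", sort=True):
        grp = grp.sort_values("timestamp")
        s = grp["activity"].to_numpy(dtype=float)
        ts = grp["timestamp"].reset_index(drop=True)
        n_win = count_windows(len(s), config.N, config.step)
        rec = np.empty((n_win, config.N))
        starts[str(cow)] = ts.iloc[0]
        for w in range(n_win):
            i = w * config.step
            win = fft_window(s[i : i + config.N], config.dt, str(cow), ts.iloc[i])
            peak = detect_dominant_peak(win, config)
            filt = circadian_filter(win, config, peak)
            rec[w] = reconstruct(filt)
            prof = circadian_features(filt, rec[w], unfiltered=win)
            rows.append(
                {
                    "cow_id": cow,
                    "start": ts.iloc[i],
                    "k_star": peak.k_star,
                    "magnitude": peak.magnitude,
                    "prominence_mads": peak.prominence_mads,
                    "snr_db": peak.snr_db,
                    "clear_peak": peak.is_clear_peak,
                    "in_band": peak.in_circadian_band,
                    "amplitude": prof.amplitude,
                    "acrophase_h": np.nan if prof.acrophase is None else prof.acrophase,
                    "coherence": prof.coherence,
                }
            )
        recons[str(cow)] = rec
    features = pd.DataFrame(rows)
    return features, recons, starts
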