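"""Spectral post-processing and EEG-band classification.

Welch power spectra of simulated membrane-potential series, dominant-peak
extraction, and mapping of dominant frequencies onto the standard EEG
bands::

    delta [1, 4) Hz   theta [4, 8) Hz   alpha [8, 12) Hz
    beta [12, 30) Hz  gamma [30, inf) Hz

Band edges are half-open (4 Hz is theta, 8 Hz alpha, 12 Hz beta, 30 Hz
gamma).  Signals whose dominant frequency falls below 1 Hz are labelled
``"none"``; series whose peak-to-peak amplitude exceeds a (heuristic,
configurable) threshold are labelled ``"h.s."`` (hyper signal) regardless
of frequency — such large nonlinear excursions are not representative of
any EEG component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "BANDS",
    "HYPER_SIGNAL_THRESHOLD",
    "power_spectrum",
    "dominant_frequency",
    "classify_band",
    "spectral_peak_ratio",
    "trim_transient",
    "save_band_map",
    "plot_band_map",
    "plot_series",
]

#: ordered (label, lo_hz, hi_hz); half-open [lo, hi), partitioning [1, inf)
BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, np.inf),
)

#: peak-to-peak amplitude (V) above which a membrane-potential series is
#: classified as a hyper signal; heuristic, tune per model if needed
HYPER_SIGNAL_THRESHOLD = 0.05

#: Welch settings: 2-s windows with 50% overlap give <= 0.5 Hz resolution
WELCH_WINDOW_SECONDS = 2.0


def trim_transient(series: np.ndarray, time: np.ndarray,
                   transient: float = 1.0) -> np.ndarray:
    """Drop the initial transient (default: the first second)."""
    series = np.asarray(series)
    return series[np.asarray(time) > transient]


def power_spectrum(series: np.ndarray, sampling_rate: float,
                   window_seconds: float = WELCH_WINDOW_SECONDS,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Welch-averaged power spectral density of a sampled series.

    Mean-detrended, ``window_seconds`` segments with 50% overlap; frequency
    resolution is ``1/window_seconds`` Hz.  Raises on series shorter than
    two windows or containing non-finite values.
    """
    x = np.asarray(series, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    nperseg = int(round(window_seconds * sampling_rate))
    if x.size < 2 * nperseg:
        raise ValueError(
            f"series too short for spectral analysis: {x.size} samples, "
            f"need at least {2 * nperseg} (two {window_seconds}-s windows)")
    freqs, power = sp_signal.welch(x, fs=sampling_rate, nperseg=nperseg,
                                   noverlap=nperseg // 2, detrend="constant")
    return freqs, power


def dominant_frequency(freqs: np.ndarray, power: np.ndarray,
                       f_min: float = 0.5) -> float:
    """Frequency of maximum spectral power above ``f_min`` (excludes DC)."""
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    mask = freqs > f_min
    if not mask.any():
        raise ValueError(f"no spectral estimates above f_min={f_min} Hz")
    return float(freqs[mask][np.argmax(power[mask])])


def spectral_peak_ratio(freqs: np.ndarray, power: np.ndarray,
                        band: Tuple[float, float] = (1.0, 60.0)) -> float:
    """Max-to-median power ratio within a band — peakedness measure.

    Flat (noise-like) spectra give small ratios; a clear oscillatory peak
    gives ratios orders of magnitude above the in-band median.
    """
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("band contains no spectral estimates")
    med = np.median(power[mask])
    if med == 0:
        return np.inf
    return float(power[mask].max() / med)


def classify_band(dominant: float,
                  series: Optional[np.ndarray] = None,
                  hyper_threshold: float = HYPER_SIGNAL_THRESHOLD) -> str:
    """Band label for a dominant frequency, with hyper-signal override.

    When ``series`` is given and its peak-to-peak amplitude exceeds
    ``hyper_threshold``, the label is ``"h.s."`` regardless of frequency.
    Dominant frequencies below 1 Hz map to ``"none"``.
    """
    if series is not None:
        series = np.asarray(series)
        if series.size and float(np.ptp(series)) > hyper_threshold:
            return "h.s."
    if not np.isfinite(dominant) or dominant < BANDS[0][1]:
        return "none"
    for label, lo, hi in BANDS:
        if lo <= dominant < hi:
            return label
    return "none"                            # pragma: no cover


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def save_band_map(band_map: pd.DataFrame, path: str) -> None:
    """Write a band-label matrix (rows/cols = parameter values) as CSV."""
    band_map.to_csv(path)


def plot_band_map(band_map: pd.DataFrame, path: Optional[str] = None,
                  title: str = "dominant frequency band"):
    """Categorical heat map of band labels (PNG when ``path`` given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [b[0] for b in BANDS] + ["none", "h.s."]
    lookup = {lab: i for i, lab in enumerate(labels)}
    data = band_map.map(lambda v: lookup.get(v, len(labels)))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data.to_numpy(), origin="lower", aspect="auto",
                   cmap="viridis", vmin=0, vmax=len(labels) - 1)
    ax.set_xticks(range(len(band_map.columns)),
                  [f"{c:g}" if isinstance(c, float) else str(c)
                   for c in band_map.columns])
    ax.set_yticks(range(len(band_map.index)),
                  [f"{r:g}" if isinstance(r, float) else str(r)
                   for r in band_map.index])
    ax.set_xlabel(band_map.columns.name or "")
    ax.set_ylabel(band_map.index.name or "")
    ax.set_title(title)
    cbar = fig.colorbar(im, ticks=range(len(labels)))
    cbar.ax.set_yticklabels(labels)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_series(time: np.ndarray, series: np.ndarray,
                path: Optional[str] = None, ylabel: str = "V",
                title: str = ""):
    """Simple time-series plot (PNG when ``path`` given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(time, series, lw=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
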