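"""Signal-domain cleaning of raw multichannel EEG.

High-pass filtering of slow baseline drift, Butterworth notch removal of
mains noise, bad-channel detection from per-partition log-variance and
Hurst-exponent z-scores, and common-average re-referencing that excludes
the detected bad channels from the reference mean.

All filters are applied forward-backward (zero-phase) so epoch timing is
not shifted by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RawEEG",
    "highpass_baseline",
    "notch_line_noise",
    "hurst_exponent",
    "detect_bad_channels",
    "common_average_reference",
]


@dataclass
class RawEEG:
    """Continuous multichannel recording.

    ``samples`` is (n_channels, n_samples) in microvolts. ``partition_boundaries``
    are the two mid-session break points (sample indices) splitting the
    recording into three sections for bad-channel statistics. ``events``
    holds marker rows (column ``sample`` at minimum).
    """

    channels: list[str]
    samples: np.ndarray
    sfreq: float
    partition_boundaries: tuple[int, int] | None = None
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.partition_boundaries is not None:
            b1, b2 = self.partition_boundaries
            if not 0 < b1 < b2 < self.samples.shape[1]:
                raise ValueError(
                    "partition boundaries must be strictly increasing and "
                    "inside the recording"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def partitions(self) -> list[slice]:
        if self.partition_boundaries is None:
            n = self.n_samples
            return [slice(0, n // 3), slice(n // 3, 2 * n // 3),
                    slice(2 * n // 3, n)]
        b1, b2 = self.partition_boundaries
        return [slice(0, b1), slice(b1, b2), slice(b2, self.n_samples)]


def _sosfiltfilt(sos: np.ndarray, raw: RawEEG) -> RawEEG:
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    return replace(raw, samples=filtered)


def highpass_baseline(raw: RawEEG, cutoff_hz: float = 0.1,
                      order: int = 2) -> RawEEG:
    """Zero-phase Butterworth high-pass removing slow baseline drift."""
    nyq = raw.sfreq / 2
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=raw.sfreq,
                        output="sos")
    return _sosfiltfilt(sos, raw)


def notch_line_noise(raw: RawEEG, stop_band: tuple[float, float] = (58.0, 62.0),
                     order: int = 4) -> RawEEG:
    """Fourth-order Butterworth band-stop filter for mains line noise."""
    nyq = raw.sfreq / 2
    lo, hi = stop_band
    if not 0 < lo < hi < nyq:
        raise ValueError("stop band must lie inside (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=raw.sfreq,
                        output="sos")
    return _sosfiltfilt(sos, raw)


def hurst_exponent(series: np.ndarray, min_window: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent of a 1-D series.

    Splits the series into non-overlapping windows at dyadic sizes, computes
    the rescaled range R/S per window, and returns the least-squares slope of
    log(mean R/S) against log(window size). White noise gives about 0.5 and
    a random walk about 1.0. Scale-invariant: hurst(a*x) == hurst(x).
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 256:
        raise ValueError("series must have at least 256 samples")
    if np.ptp(x) == 0:
        raise ValueError("Hurst exponent undefined for a constant series")
    sizes = []
    m = min_window
    while m <= n // 2:
        sizes.append(m)
        m *= 2
    log_rs = []
    log_m = []
    for m in sizes:
        k = n // m
        seg = x[: k * m].reshape(k, m)
        mean = seg.mean(axis=1, keepdims=True)
        dev = np.cumsum(seg - mean, axis=1)
        r = dev.max(axis=1) - dev.min(axis=1)
        s = seg.std(axis=1)
        ok = s > 0
        if not np.any(ok):
            continue
        rs = np.mean(r[ok] / s[ok])
        if rs > 0:
            log_rs.append(np.log(rs))
            log_m.append(np.log(m))
    if len(log_m) < 2:
        raise ValueError("not enough valid window sizes for R/S regression")
    slope = np.polyfit(log_m, log_rs, 1)[0]
    return float(slope)


def detect_bad_channels(
    raw: RawEEG,
    z_threshold: float = 3.0,
    detection_highpass_hz: float = 0.5,
    eog_mask: np.ndarray | None = None,
) -> set[str]:
    """Flag channels with outlying log-variance or Hurst exponent.

    A copy of the recording is high-pass filtered at 0.5 Hz (detection
    only). Within each of the three partitions, log-variance and Hurst
    exponent are z-scored across non-EOG channels; a channel is bad if its
    |z(log-variance)| exceeds the threshold or its z(Hurst) exceeds the
    threshold in any partition. Flags are the union over partitions. The
    statistics are invariant to rescaling all channels by a common factor.
    """
    n_ch = len(raw.channels)
    if eog_mask is None:
        eog_mask = np.zeros(n_ch, dtype=bool)
    eog_mask = np.asarray(eog_mask, dtype=bool)
    idx = np.flatnonzero(~eog_mask)
    if idx.size < 3:
        raise ValueError("need at least 3 non-EOG channels for z-scores")
    hp = highpass_baseline(raw, cutoff_hz=detection_highpass_hz)
    bad: set[str] = set()
    for part in hp.partitions():
        seg = hp.samples[idx, part]
        log_var = np.log(np.var(seg, axis=1))
        hurst = np.array([hurst_exponent(seg[i]) for i in range(len(idx))])
        for stats, two_sided in ((log_var, True), (hurst, False)):
            sd = stats.std()
            if sd == 0:
                continue
            z = (stats - stats.mean()) / sd
            if two_sided:
                flagged = np.abs(z) > z_threshold
            else:
                flagged = z > z_threshold
            bad.update(raw.channels[idx[i]] for i in np.flatnonzero(flagged))
    return bad


def common_average_reference(raw: RawEEG, bad_channels: set[str] | None = None
                             ) -> RawEEG:
    """Re-reference to the mean of the good channels at every sample.

    Bad channels are excluded from the reference mean but are themselves
    re-referenced (the mean is subtracted from every channel). After this,
    the mean over good channels is zero at every sample, and adding any
    constant to all good channels leaves the output unchanged.
    """
    bad_channels = bad_channels or set()
    unknown = bad_channels - set(raw.channels)
    if unknown:
        raise ValueError(f"bad channels not in recording: {sorted(unknown)}")
    good = np.array([c not in bad_channels for c in raw.channels])
    if not np.any(good):
        raise ValueError("all channels are bad; reference undefined")
    ref = raw.samples[good].mean(axis=0, keepdims=True)
    return replace(raw, samples=raw.samples - ref)
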