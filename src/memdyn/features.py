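"""Spectral feature construction for encoding and retrieval epochs.

Power is estimated on the 29-frequency grid (2 Hz spacing over 4-26 Hz,
6 Hz spacing over 32-128 Hz) with a DPSS multitaper estimator applied to a
500 ms window sliding in 50 ms steps. Per-event features are the mean
spectral pattern over the 23 window centers spanning 250-1350 ms after word
onset (encoding) or the single window centered 250 ms before vocalization
onset (retrieval). Within each session, log power is z-scored across events
at every frequency x channel pair, separately per phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

__all__ = [
    "FeatureTensor",
    "frequency_grid",
    "window_centers",
    "ENCODING_CENTERS",
    "RETRIEVAL_CENTER",
    "multitaper_power",
    "encoding_feature",
    "retrieval_feature",
    "zscore_log_power",
    "tensor_from_simulated",
    "features_from_raw",
]


def frequency_grid() -> np.ndarray:
    """The 29-frequency grid: {4, 6, ..., 26} Hz union {32, 38, ..., 128} Hz.

    The boundary frequency 26 Hz belongs to the 2 Hz-spaced segment; the
    6 Hz-spaced segment therefore starts at 32 Hz, which is the only
    reading that yields 29 distinct frequencies.
    """
    return np.concatenate(
        [np.arange(4.0, 26.0 + 1e-9, 2.0), np.arange(32.0, 128.0 + 1e-9, 6.0)]
    )


def window_centers(start_s: float, stop_s: float, step_s: float = 0.05
                   ) -> np.ndarray:
    """Window centers from start to stop inclusive, at the given step."""
    n = int(round((stop_s - start_s) / step_s)) + 1
    return start_s + step_s * np.arange(n)


#: The 23 encoding window centers, 250-1350 ms after word onset.
ENCODING_CENTERS: np.ndarray = window_centers(0.25, 1.35, 0.05)
#: The single retrieval window center, 250 ms before vocalization onset.
RETRIEVAL_CENTER: float = -0.25


def _dpss_tapers(n_samples: int, half_bandwidth_hz: float, window_s: float,
                 min_eigenvalue: float = 0.9) -> np.ndarray:
    """DPSS tapers with time-bandwidth product W*T, eigenvalue-filtered."""
    nw = half_bandwidth_hz * window_s  # = 2 for the default 0.5 s window
    kmax = max(1, int(2 * nw - 1) + 1)
    tapers, ratios = windows.dpss(n_samples, nw, Kmax=kmax, return_ratios=True)
    keep = ratios > min_eigenvalue
    if not np.any(keep):
        keep[0] = True
    return tapers[keep]


def multitaper_power(
    segment: np.ndarray,
    sfreq: float,
    centers: np.ndarray,
    grid: np.ndarray | None = None,
    window_s: float = 0.5,
    t0: float = 0.0,
    half_bandwidth_hz: float = 4.0,
) -> np.ndarray:
    """Sliding-window multitaper power of one epoch.

    Parameters
    ----------
    segment : ndarray, shape (n_channels, n_samples)
        Epoch samples; the first sample is at time ``t0`` relative to the
        event onset.
    sfreq : float
        Sampling rate in Hz.
    centers : array of float
        Window centers (seconds, relative to event onset).
    grid : array of float, optional
        Frequencies at which to evaluate power; defaults to the 29-bin grid.
    window_s : float
        Window length in seconds (500 ms default).
    half_bandwidth_hz : float
        Multitaper half-bandwidth W; tapers with concentration eigenvalue
        above 0.9 are retained and averaged non-adaptively.

    Returns
    -------
    ndarray, shape (n_windows, n_freqs, n_channels)
        Nonnegative power estimates.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if grid is None:
        grid = frequency_grid()
    grid = np.asarray(grid, dtype=float)
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    m = int(round(window_s * sfreq))
    n_samples = segment.shape[1]
    tapers = _dpss_tapers(m, half_bandwidth_hz, window_s)
    t = np.arange(m) / sfreq
    # exact-frequency DFT kernels: (F, M)
    kernel = np.exp(-2j * np.pi * grid[:, None] * t[None, :])
    out = np.empty((len(centers), len(grid), segment.shape[0]))
    for wi, c in enumerate(centers):
        s0 = int(round((c - t0) * sfreq)) - m // 2
        if s0 < 0 or s0 + m > n_samples:
            raise ValueError(
                f"window centered at {c:.3f} s extends past the segment"
            )
        x = segment[:, s0 : s0 + m]  # (C, M)
        tapered = tapers[:, None, :] * x[None, :, :]  # (K, C, M)
        coef = tapered @ kernel.T.conj()  # (K, C, F)
        power = np.mean(np.abs(coef) ** 2, axis=0) / (sfreq * m)
        out[wi] = power.T
    return out


def encoding_feature(power_timeseries: np.ndarray, centers: np.ndarray
                     ) -> np.ndarray:
    """Mean spectral pattern over the 23 encoding window centers.

    ``power_timeseries`` is (n_windows, n_freqs, n_channels) with windows
    at ``centers`` (seconds after word onset). Raises if any of the
    250-1350 ms centers is missing.
    """
    centers = np.asarray(centers, dtype=float)
    idx = []
    for c in ENCODING_CENTERS:
        match = np.flatnonzero(np.isclose(centers, c, atol=1e-6))
        if match.size == 0:
            raise ValueError(f"missing window center at {c:.3f} s")
        idx.append(match[0])
    return power_timeseries[idx].mean(axis=0)


def retrieval_feature(power_timeseries: np.ndarray, centers: np.ndarray
                      ) -> np.ndarray:
    """Spectral pattern of the single window centered at -250 ms."""
    centers = np.asarray(centers, dtype=float)
    match = np.flatnonzero(np.isclose(centers, RETRIEVAL_CENTER, atol=1e-6))
    if match.size == 0:
        raise ValueError("missing window centered at -250 ms")
    return power_timeseries[match[0]]


@dataclass
class FeatureTensor:
    """Z-scored log-power features for one session and phase.

    ``values`` is (n_events, n_freqs, n_channels); within the session and
    phase every frequency x channel column has mean 0 and population sd 1
    across events. ``events`` metadata rows align with ``values``.
    """

    values: np.ndarray
    freqs: np.ndarray
    channels: list[str]
    events: pd.DataFrame
    session: int
    phase: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (events, freqs, channels)")
        if self.values.shape[0] != len(self.events):
            raise ValueError("one metadata row per event required")
        if self.phase not in ("encoding", "retrieval"):
            raise ValueError("phase must be 'encoding' or 'retrieval'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain non-finite values")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def matrix(self, channel_indices: np.ndarray | None = None) -> np.ndarray:
        """Flattened (n_events, n_freqs * n_channels) design matrix."""
        v = self.values
        if channel_indices is not None:
            v = v[:, :, channel_indices]
        return v.reshape(v.shape[0], -1)

    def check_invariant(self, atol: float = 1e-6) -> bool:
        cols = self.values.reshape(self.n_events, -1)
        return bool(
            np.allclose(cols.mean(axis=0), 0.0, atol=atol)
            and np.allclose(cols.std(axis=0), 1.0, atol=atol)
        )


def zscore_log_power(
    powers: np.ndarray,
    events: pd.DataFrame,
    freqs: np.ndarray,
    channels: list[str],
    session: int,
    phase: str,
    log_transform: bool = True,
    ddof: int = 0,
) -> FeatureTensor:
    """Log-transform and z-score power across events per (freq, channel).

    ``powers`` is (n_events, n_freqs, n_channels) of raw power (or already
    log-scale values with ``log_transform=False``). Z-scoring uses the
    population standard deviation by default. Mixing phases in one call is
    an error: all metadata rows must carry the same phase as declared.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.ndim != 3:
        raise ValueError("powers must be (events, freqs, channels)")
    if powers.shape[0] < 2:
        raise ValueError("need at least 2 events per session and phase")
    if "phase" in events.columns and not (events["phase"] == phase).all():
        raise ValueError(
            "event metadata mixes phases; z-scoring is per session x phase"
        )
    x = np.log(powers) if log_transform else powers.copy()
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column; cannot z-score")
    x = (x - mean) / sd
    meta = events.copy().reset_index(drop=True)
    meta["phase"] = phase
    return FeatureTensor(
        values=x, freqs=np.asarray(freqs, dtype=float), channels=list(channels),
        events=meta, session=session, phase=phase,
    )


def tensor_from_simulated(sim, phase: str) -> FeatureTensor:
    """Build a FeatureTensor from generator feature-space output.

    The generator emits pre-z-score log-power directly, so the multitaper
    stage is bypassed and only the per-session z-scoring is applied.
    """
    if phase == "encoding":
        powers, events = sim.encoding_power, sim.encoding_events
    elif phase == "retrieval":
        powers, events = sim.retrieval_power, sim.retrieval_events
    else:
        raise ValueError("phase must be 'encoding' or 'retrieval'")
    return zscore_log_power(
        powers, events, sim.freqs, list(sim.montage.names),
        session=sim.session, phase=phase, log_transform=False,
    )


def features_from_raw(
    raw,
    phase: str,
    session: int = 0,
    grid: np.ndarray | None = None,
    item_duration_s: float = 1.6,
) -> FeatureTensor:
    """Epoch a continuous recording and build the per-event feature tensor.

    Encoding epochs cover [0, item_duration] after each ``encoding`` marker
    and are averaged over the 23 window centers; retrieval epochs cover
    [-0.5, 0] s before each ``vocalization`` marker and use the single
    -250 ms window. Epochs extending past the recording are dropped.
    """
    if grid is None:
        grid = frequency_grid()
    if phase == "encoding":
        kind, centers = "encoding", ENCODING_CENTERS
        t0, t1 = 0.0, item_duration_s
    elif phase == "retrieval":
        kind, centers = "vocalization", np.array([RETRIEVAL_CENTER])
        t0, t1 = -0.5, 0.0
    else:
        raise ValueError("phase must be 'encoding' or 'retrieval'")
    if raw.events is None:
        raise ValueError("recording has no event markers")
    markers = raw.events[raw.events["kind"] == kind]
    n0, n1 = int(t0 * raw.sfreq), int(np.ceil(t1 * raw.sfreq))
    feats, rows = [], []
    n_dropped = 0
    for _, row in markers.iterrows():
        s = int(row["sample"])
        if s + n0 < 0 or s + n1 > raw.n_samples:
            n_dropped += 1
            continue
        seg = raw.samples[:, s + n0 : s + n1]
        p = multitaper_power(seg, raw.sfreq, centers, grid=grid, t0=t0)
        if phase == "encoding":
            feats.append(encoding_feature(p, centers))
        else:
            feats.append(retrieval_feature(p, centers))
        rows.append(row)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d %s epochs extending past the recording", n_dropped,
            kind,
        )
    powers = np.stack(feats)
    events = pd.DataFrame(rows).reset_index(drop=True)
    return zscore_log_power(
        powers, events, grid, list(raw.channels), session=session, phase=phase
    )
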