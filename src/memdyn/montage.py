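"""Synthetic electrode montages and their region-of-interest structure.

Scalp channels are grouped into eight regions of interest (ROIs) formed by
crossing hemisphere (left/right), anterior/posterior, and inferior/superior:
LAI, LAS, LPI, LPS, RAI, RAS, RPI, RPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical ROI order used for all (frequency x ROI) maps.
ROI_NAMES: tuple[str, ...] = (
    "LAI", "LAS", "LPI", "LPS", "RAI", "RAS", "RPI", "RPS",
)


@dataclass
class Montage:
    """Channel layout: names, 3-D positions on a unit sphere, ROI labels.

    Parameters
    ----------
    names : list of str
        Channel identifiers.
    positions : ndarray, shape (n_channels, 3)
        Cartesian sensor positions; x = right, y = anterior, z = superior.
    roi : ndarray of str, shape (n_channels,)
        ROI label per channel (one of :data:`ROI_NAMES`).
    periocular : ndarray of bool
        Channels close to the face/neck, excluded from decoding features.
    eog : ndarray of bool
        Electrooculogram-like channels, excluded from bad-channel statistics.
    """

    names: list[str]
    positions: np.ndarray
    roi: np.ndarray
    periocular: np.ndarray = field(default=None)  # type: ignore[assignment]
    eog: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        self.roi = np.asarray(self.roi, dtype=object)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n_channels, 3)")
        if self.roi.shape != (n,):
            raise ValueError("one ROI label per channel required")
        unknown = set(self.roi) - set(ROI_NAMES)
        if unknown:
            raise ValueError(f"unknown ROI labels: {sorted(unknown)}")
        if self.periocular is None:
            self.periocular = np.zeros(n, dtype=bool)
        if self.eog is None:
            self.eog = np.zeros(n, dtype=bool)
        self.periocular = np.asarray(self.periocular, dtype=bool)
        self.eog = np.asarray(self.eog, dtype=bool)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def roi_channel_indices(self) -> dict[str, np.ndarray]:
        """Map each ROI name to the indices of its channels."""
        return {r: np.flatnonzero(self.roi == r) for r in ROI_NAMES}

    def included_indices(self) -> np.ndarray:
        """Indices of channels retained for decoding (non-periocular)."""
        return np.flatnonzero(~self.periocular)


def octant_roi(positions: np.ndarray) -> np.ndarray:
    """Assign each position to an ROI by its octant on the head sphere."""
    pos = np.asarray(positions, dtype=float)
    lr = np.where(pos[:, 0] < 0, "L", "R")
    ap = np.where(pos[:, 1] >= 0, "A", "P")
    si = np.where(pos[:, 2] >= 0, "S", "I")
    return np.array([h + a + s for h, a, s in zip(lr, ap, si)], dtype=object)


def make_sphere_montage(
    n_channels: int = 64,
    seed: int = 0,
    n_periocular: int = 4,
) -> Montage:
    """Build a synthetic whole-head montage of ``n_channels`` sensors.

    Channels are placed quasi-uniformly on the unit sphere (Fibonacci
    lattice, jittered by ``seed``) and assigned to the eight octant ROIs.
    The ``n_periocular`` most antero-inferior channels are flagged as
    face/neck sensors, mirroring the exclusion of periocular electrodes
    from decoding features.
    """
    if n_channels < 8:
        raise ValueError("need at least one channel per ROI octant")
    rng = np.random.default_rng(seed)
    if n_channels == 8:
        # one sensor per octant, at the octant centroids
        sgn = np.array(
            [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)],
            dtype=float,
        )
        pos = sgn / np.sqrt(3.0)
    else:
        i = np.arange(n_channels, dtype=float)
        golden = (1 + np.sqrt(5.0)) / 2
        z = 1 - 2 * (i + 0.5) / n_channels
        theta = 2 * np.pi * i / golden
        r = np.sqrt(np.maximum(0.0, 1 - z**2))
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        pos += rng.normal(scale=1e-3, size=pos.shape)  # break octant ties
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    roi = octant_roi(pos)
    # guarantee every ROI is populated by nudging orphan octants
    for name in ROI_NAMES:
        if not np.any(roi == name):
            j = rng.integers(n_channels)
            sx = -1 if name[0] == "L" else 1
            sy = 1 if name[1] == "A" else -1
            sz = 1 if name[2] == "S" else -1
            pos[j] = np.array([sx, sy, sz]) / np.sqrt(3.0)
            roi = octant_roi(pos)
    names = [f"E{k + 1:03d}" for k in range(n_channels)]
    periocular = np.zeros(n_channels, dtype=bool)
    if n_periocular > 0 and n_channels > 8:
        # most anterior-inferior sensors approximate face/neck placement
        score = pos[:, 1] - pos[:, 2]
        periocular[np.argsort(score)[-n_periocular:]] = True
    return Montage(names=names, positions=pos, roi=roi, periocular=periocular)
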