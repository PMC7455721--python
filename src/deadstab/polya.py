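"""Bulk poly(A) tail gel densitometry: size calibration and tail-length mass.

A densitogram is a lane-intensity profile over a migration coordinate. A
ladder of marker bands with known lengths calibrates the lane: log(length)
is interpolated piecewise-linearly in migration position (longer tails
migrate less far). The headline summary is the fraction of total lane
intensity at tail lengths above a threshold (50 nt by default), the readout
under which impaired deadenylation shifts mass upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, FormatError


@dataclass
class DensitogramProfile:
    """Lane intensity over migration position, with marker anchors."""

    position: np.ndarray
    intensity: np.ndarray
    marker: list[tuple[float, float]]  # (length_nt, position) pairs

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.position.shape != self.intensity.shape:
            raise FormatError("position and intensity must have equal length")
        if (np.diff(self.position) <= 0).any():
            raise FormatError("migration positions must be strictly increasing")
        if (self.intensity < 0).any():
            raise FormatError("negative intensity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.position, "intensity": self.intensity})


@dataclass
class Calibration:
    """Monotone position -> tail length mapping from marker anchors."""

    positions: np.ndarray   # ascending
    log_lengths: np.ndarray  # descending (longer nt migrate less far)

    def length_at(self, position) -> tuple[np.ndarray, np.ndarray]:
        """Tail length (nt) at given positions plus an extrapolation flag."""
        pos = np.atleast_1d(np.asarray(position, float))
        extrapolated = (pos < self.positions[0]) | (pos > self.positions[-1])
        # np.interp clamps; extend linearly beyond the anchors instead
        ll = np.interp(pos, self.positions, self.log_lengths)
        lo_slope = (self.log_lengths[1] - self.log_lengths[0]) / (
            self.positions[1] - self.positions[0]
        )
        hi_slope = (self.log_lengths[-1] - self.log_lengths[-2]) / (
            self.positions[-1] - self.positions[-2]
        )
        below = pos < self.positions[0]
        above = pos > self.positions[-1]
        ll[below] = self.log_lengths[0] + lo_slope * (pos[below] - self.positions[0])
        ll[above] = self.log_lengths[-1] + hi_slope * (pos[above] - self.positions[-1])
        return np.exp(ll), extrapolated

    def position_at(self, length_nt: float) -> float:
        """Inverse mapping (log-linear), for a length inside the anchor range."""
        ll = np.log(float(length_nt))
        # log_lengths descending: interpolate on the reversed arrays
        return float(np.interp(ll, self.log_lengths[::-1], self.positions[::-1]))


def calibrate(marker) -> Calibration:
    """Build the log-linear size calibration from >= 2 (length_nt, position) anchors."""
    marker = sorted(((float(l), float(p)) for l, p in marker), key=lambda lp: lp[1])
    if len(marker) < 2:
        raise ConfigError("calibration needs at least two marker anchors")
    lengths = np.array([l for l, _ in marker])
    positions = np.array([p for _, p in marker])
    if (np.diff(positions) <= 0).any() or (np.diff(lengths) >= 0).any():
        raise ConfigError(
            "marker must be strictly monotone: longer lengths at smaller positions"
        )
    if (lengths <= 0).any():
        raise ConfigError("marker lengths must be positive")
    return Calibration(positions=positions, log_lengths=np.log(lengths))


def subtract_baseline(profile: DensitogramProfile, window: int = 51) -> DensitogramProfile:
    """Optional rolling-minimum background subtraction before integration."""
    s = pd.Series(profile.intensity)
    base = s.rolling(window, center=True, min_periods=1).min()
    return DensitogramProfile(
        profile.position, np.maximum(s - base, 0.0).to_numpy(), profile.marker
    )


def fraction_above(
    profile: DensitogramProfile,
    calibration: Calibration | None = None,
    threshold_nt: float = 50.0,
) -> float:
    """Fraction of total lane intensity at tail lengths above ``threshold_nt``.

    Trapezoidal mass above the threshold divided by total mass, in [0, 1];
    invariant to positive rescaling of the intensity. The integration grid
    is split exactly at the threshold's migration position.
    """
    if calibration is None:
        calibration = calibrate(profile.marker)
    pos, inten = profile.position, profile.intensity
    total = float(np.trapezoid(inten, pos))
    if total <= 0:
        raise ConfigError("zero total intensity")
    lengths, _ = calibration.length_at(pos)
    if lengths.max() <= threshold_nt:
        return 0.0
    if lengths.min() > threshold_nt:
        return 1.0
    cut = calibration.position_at(threshold_nt)
    # longer tails sit at smaller positions: integrate [start, cut]
    left = pos <= cut
    xs = np.append(pos[left], cut)
    ys = np.append(inten[left], np.interp(cut, pos, inten))
    above = float(np.trapezoid(ys, xs))
    return min(max(above / total, 0.0), 1.0)
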