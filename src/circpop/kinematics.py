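"""Heading angles, angular velocities, and behavioral-mode segmentation
from trajectory data.

Two trajectory flavors are supported: 3D positions sampled at a fixed rate
(flight; headings derived from consecutive displacements) and head-angle
series (crawling; azimuth/pitch given directly).  Angular velocities are
absolute wrapped first differences times the sampling rate, combined across
dimensions as ``sqrt(v_az^2 + v_pitch^2)``.

Azimuth convention: mathematical angle of the horizontal displacement
``(dx, dy)`` — 0 deg along +x, counter-clockwise positive.  Pitch is the
elevation of ``dz`` against the horizontal displacement magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySeries",
    "KinematicsSeries",
    "heading_from_positions",
    "angular_velocities",
    "flight_mode_segmentation",
    "crawl_velocity_split",
    "read_trajectory_csv",
    "read_head_angles_csv",
]


@dataclass
class TrajectorySeries:
    """Timestamped positions (x, y, z, meters) or head angles (degrees)."""

    timestamps: np.ndarray  # seconds, strictly increasing
    positions: np.ndarray | None = None  # (n, 3)
    head_angles: np.ndarray | None = None  # (n, 2) azimuth, pitch in degrees

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if (self.positions is None) == (self.head_angles is None):
            raise ValueError("provide exactly one of positions or head_angles")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.timestamps.size, 3):
                raise ValueError("positions must be (n, 3)")
        else:
            self.head_angles = np.asarray(self.head_angles, dtype=float)
            if self.head_angles.shape != (self.timestamps.size, 2):
                raise ValueError("head_angles must be (n, 2)")

    @property
    def sampling_rate(self) -> float:
        dt = np.diff(self.timestamps)
        return float(1.0 / np.median(dt))


@dataclass
class KinematicsSeries:
    """Derived heading/velocity series aligned to trajectory samples.

    Heading samples sit between consecutive positions; masked entries (NaN)
    mark undefined headings (zero displacement) and are excluded from
    velocities, which are never computed across a gap.
    """

    timestamps: np.ndarray
    azimuth_deg: np.ndarray
    pitch_deg: np.ndarray
    v_azimuth: np.ndarray  # deg/s, absolute
    v_pitch: np.ndarray
    v_combined: np.ndarray
    speed: np.ndarray | None = None  # m/s, for position-based trajectories

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t": self.timestamps,
            "azimuth_deg": self.azimuth_deg,
            "pitch_deg": self.pitch_deg,
            "v_azimuth_deg_s": self.v_azimuth,
            "v_pitch_deg_s": self.v_pitch,
            "v_combined_deg_s": self.v_combined,
        }
        if self.speed is not None:
            data["speed_m_s"] = self.speed
        return pd.DataFrame(data)


def heading_from_positions(trajectory: TrajectorySeries):
    """Azimuth/pitch heading series (degrees) from consecutive displacements.

    Azimuth is the angle of ``dx + i*dy``; pitch the angle of
    ``sqrt(dx^2 + dy^2) + i*dz``.  Zero horizontal displacement masks the
    azimuth sample (NaN); zero total displacement masks both.
    """
    if trajectory.positions is None:
        raise ValueError("heading_from_positions requires a position trajectory")
    d = np.diff(trajectory.positions, axis=0)
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    horiz = np.hypot(dx, dy)
    total = np.sqrt(horiz**2 + dz**2)
    azimuth = np.degrees(np.angle(dx + 1j * dy)) % 360.0
    pitch = np.degrees(np.angle(horiz + 1j * dz)) % 360.0
    azimuth = np.where(horiz > 0, azimuth, np.nan)
    pitch = np.where(total > 0, pitch, np.nan)
    return azimuth, pitch


def _wrapped_abs_diff_deg(angles_deg):
    """Absolute shorter-arc difference between consecutive angles (degrees);
    NaN across masked samples."""
    d = np.diff(angles_deg)
    return np.abs((d + 180.0) % 360.0 - 180.0)


def angular_velocities(
    azimuth_deg, pitch_deg, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absolute angular velocities (deg/s) per dimension and combined."""
    v_az = _wrapped_abs_diff_deg(np.asarray(azimuth_deg, dtype=float)) * sampling_rate
    v_pi = _wrapped_abs_diff_deg(np.asarray(pitch_deg, dtype=float)) * sampling_rate
    v_comb = np.sqrt(v_az**2 + v_pi**2)
    return v_az, v_pi, v_comb


def compute_kinematics(trajectory: TrajectorySeries) -> KinematicsSeries:
    """Full kinematics series for either trajectory flavor."""
    rate = trajectory.sampling_rate
    if trajectory.positions is not None:
        az, pi = heading_from_positions(trajectory)
        t = trajectory.timestamps[1:]
        d = np.diff(trajectory.positions, axis=0)
        dt = np.diff(trajectory.timestamps)
        speed = np.linalg.norm(d, axis=1) / dt
    else:
        az = trajectory.head_angles[:, 0] % 360.0
        pi = trajectory.head_angles[:, 1] % 360.0
        t = trajectory.timestamps
        speed = None
    v_az, v_pi, v_comb = angular_velocities(az, pi, rate)
    pad = np.full(1, np.nan)
    return KinematicsSeries(
        timestamps=t,
        azimuth_deg=az,
        pitch_deg=pi,
        v_azimuth=np.concatenate([pad, v_az]),
        v_pitch=np.concatenate([pad, v_pi]),
        v_combined=np.concatenate([pad, v_comb]),
        speed=speed,
    )


def horizontal_displacement(trajectory: TrajectorySeries, window_s: float = 20.0):
    """Net Euclidean distance traversed in the horizontal plane over a
    trailing window of ``window_s`` seconds, per sample."""
    if trajectory.positions is None:
        raise ValueError("horizontal displacement requires positions")
    rate = trajectory.sampling_rate
    lag = max(int(round(window_s * rate)), 1)
    xy = trajectory.positions[:, :2]
    disp = np.full(xy.shape[0], np.nan)
    disp[lag:] = np.linalg.norm(xy[lag:] - xy[:-lag], axis=1)
    return disp


def flight_mode_segmentation(
    trajectory: TrajectorySeries,
    speed_min: float = 0.5,
    window_s: float = 20.0,
    bins: int = 50,
    smooth_bins: int = 5,
) -> pd.DataFrame:
    """Label flight samples as navigation (large horizontal displacement)
    or maneuvering (small displacement).

    Samples slower than ``speed_min`` m/s are excluded.  The threshold is the
    minimum of the (smoothed) displacement histogram between its two largest
    modes; a unimodal histogram raises with diagnostics.
    """
    kin = compute_kinematics(trajectory)
    disp = horizontal_displacement(trajectory, window_s)[1:]  # align to headings
    valid = np.isfinite(disp) & np.isfinite(kin.speed) & (kin.speed > speed_min)
    if valid.sum() < 10:
        raise ValueError("too few valid samples above the speed threshold")
    counts, edges = np.histogram(disp[valid], bins=bins)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")
    peaks = [
        i
        for i in range(1, bins - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    if len(peaks) < 2:
        raise ValueError(
            "displacement histogram appears unimodal; cannot place a "
            f"navigation/maneuvering threshold (peaks found: {len(peaks)})"
        )
    ranked = sorted(peaks, key=lambda i: -smooth[i])
    first = ranked[0]
    second = next((i for i in ranked if abs(i - first) >= smooth_bins), None)
    if second is None:
        raise ValueError(
            "displacement histogram appears unimodal; cannot place a "
            "navigation/maneuvering threshold (single mode found)"
        )
    lo, hi = sorted((first, second))
    between = np.arange(lo, hi + 1)
    cut_idx = between[np.argmin(smooth[lo : hi + 1])]
    valley = smooth[cut_idx]
    if valley > 0.5 * min(smooth[lo], smooth[hi]):
        raise ValueError(
            "displacement histogram appears unimodal (no clear valley between "
            f"modes: valley {valley:.1f} vs peaks {smooth[lo]:.1f}/{smooth[hi]:.1f})"
        )
    threshold = 0.5 * (edges[cut_idx] + edges[cut_idx + 1])

    mode = np.full(disp.size, "excluded", dtype=object)
    mode[valid & (disp >= threshold)] = "navigation"
    mode[valid & (disp < threshold)] = "maneuvering"
    out = kin.to_frame()
    out["horizontal_displacement_m"] = disp
    out["mode"] = mode
    out.attrs["displacement_threshold_m"] = float(threshold)
    return out


def crawl_velocity_split(
    kinematics: KinematicsSeries, cutoff: float = 10.0
) -> pd.DataFrame:
    """Label samples by combined angular velocity: low (< cutoff) or high
    (>= cutoff, boundary inclusive in the fast bin).  Masked samples are
    labeled 'excluded'."""
    v = kinematics.v_combined
    label = np.full(v.size, "excluded", dtype=object)
    label[np.isfinite(v) & (v < cutoff)] = "low"
    label[np.isfinite(v) & (v >= cutoff)] = "high"
    out = kinematics.to_frame()
    out["velocity_label"] = label
    dt = (
        float(np.median(np.diff(kinematics.timestamps)))
        if kinematics.timestamps.size > 1
        else 1.0
    )
    occ = {
        lab: float(np.sum(label == lab) * dt) for lab in ("low", "high", "excluded")
    }
    out.attrs["occupancy_s"] = occ
    out.attrs["cutoff_deg_s"] = float(cutoff)
    return out


# -- CSV interfaces ---------------------------------------------------------


def read_trajectory_csv(path) -> TrajectorySeries:
    """Read a position trajectory CSV with columns t, x, y, z."""
    df = pd.read_csv(path)
    return TrajectorySeries(
        timestamps=df["t"].to_numpy(),
        positions=df[["x", "y", "z"]].to_numpy(),
    )


def read_head_angles_csv(path) -> TrajectorySeries:
    """Read a head-angle CSV with columns t, azimuth, pitch (degrees)."""
    df = pd.read_csv(path)
    return TrajectorySeries(
        timestamps=df["t"].to_numpy(),
        head_angles=df[["azimuth", "pitch"]].to_numpy(),
    )
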