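"""Synthetic trajectories and head-direction recordings.

The behavioral generator is a two-state switching process (a slow
"navigation-like" mode and a fast "maneuvering-like" mode) whose azimuth and
pitch heading increments are drawn from a correlated bivariate normal with
per-mode velocity scales.  It is a statistical stand-in for real tracking
data, not a model of flight dynamics.  Spike trains are inhomogeneous
Poisson: the rate follows the cell's tuning evaluated along the trajectory,
optionally gated by angular velocity so a cell can, e.g., be pure at low
velocity and conjunctive at high velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .hd_analysis import Session
from .kinematics import TrajectorySeries, angular_velocities

__all__ = [
    "BehaviorSpec",
    "CellSpec",
    "generate_trajectory",
    "generate_session",
]


@dataclass
class BehaviorSpec:
    """Two-mode behavioral statistics for the synthetic trajectory generator.

    Velocity scales are the per-dimension standard deviations (deg/s) of the
    heading increments in each mode; ``velocity_correlation`` couples
    azimuth and pitch increments.  Mode dwell times are geometric with the
    given means.  ``flight_speed`` only matters when integrating 3D
    positions.
    """

    slow_scale_deg_s: float = 6.0
    fast_scale_deg_s: float = 35.0
    velocity_correlation: float = 0.26
    mean_dwell_slow_s: float = 30.0
    mean_dwell_fast_s: float = 10.0
    flight_speed_m_s: float = 8.0
    sampling_rate_hz: float = 25.0
    pitch_limit_deg: float | None = 45.0  # reflect pitch at +/- this bound
    persistence_tau_s: float = 1.0  # AR(1) time constant of heading velocity
    seed: int | None = None

    def __post_init__(self):
        if self.slow_scale_deg_s < 0 or self.fast_scale_deg_s < 0:
            raise ValueError("velocity scales must be non-negative")
        if not -1.0 < self.velocity_correlation < 1.0:
            raise ValueError("velocity correlation must lie in (-1, 1)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class CellSpec:
    """Ground-truth tuning of one synthetic cell.

    ``label`` gives the base tuning; ``gate_label``/``gate_threshold_deg_s``
    optionally switch the effective tuning when the combined angular
    velocity is at or above the threshold (e.g. a pure cell that becomes
    conjunctive during fast turns).
    """

    cell_id: str
    label: str  # untuned | pure_azimuth | pure_pitch | conjunctive
    preferred_azimuth_deg: float = 0.0
    preferred_pitch_deg: float = 0.0
    kappa: float = 9.11
    peak_rate_hz: float = 1.0
    baseline_rate_hz: float = 0.0
    gate_label: str | None = None  # effective label at/above the threshold
    gate_threshold_deg_s: float | None = None


def _abs_corr(rho):
    """Pearson correlation of |X|, |Y| for standard bivariate normal (X, Y)
    with correlation ``rho``."""
    num = (2.0 / np.pi) * (np.sqrt(1 - rho**2) + rho * np.arcsin(rho)) - 2.0 / np.pi
    return num / (1.0 - 2.0 / np.pi)


def _gaussian_rho_for_velocity_correlation(target: float) -> float:
    """Invert :func:`_abs_corr`: the Gaussian increment correlation that
    yields the requested correlation between absolute angular velocities."""
    if target == 0.0:
        return 0.0
    from scipy.optimize import brentq

    sign = np.sign(target)
    return sign * float(brentq(lambda r: _abs_corr(r) - abs(target), 0.0, 0.999999))


def _mode_sequence(n, p_switch_slow, p_switch_fast, rng):
    modes = np.zeros(n, dtype=int)
    m = 0
    for i in range(1, n):
        p = p_switch_slow if m == 0 else p_switch_fast
        if rng.random() < p:
            m = 1 - m
        modes[i] = m
    return modes


def generate_trajectory(
    spec: BehaviorSpec,
    duration_s: float = 600.0,
    kind: str = "crawl",
    rng: np.random.Generator | None = None,
) -> tuple[TrajectorySeries, pd.DataFrame]:
    """Generate a two-mode heading trajectory (and 3D positions for flight).

    Returns the trajectory plus a ground-truth frame with the mode sequence
    and instantaneous angular velocities.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rate = spec.sampling_rate_hz
    n = int(round(duration_s * rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    dt = 1.0 / rate
    modes = _mode_sequence(
        n, dt / spec.mean_dwell_slow_s, dt / spec.mean_dwell_fast_s, rng
    )
    scales = np.where(modes == 0, spec.slow_scale_deg_s, spec.fast_scale_deg_s) * dt
    # velocity_correlation targets the correlation of the *absolute*
    # per-dimension velocities; convert to the Gaussian increment correlation
    rho = _gaussian_rho_for_velocity_correlation(spec.velocity_correlation)
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    # persistent (AR(1)) heading velocity: unit-variance stationary process so
    # the per-mode scale still sets the marginal velocity std, while the
    # persistence lets the heading sweep the whole circle over a session
    from scipy.signal import lfilter

    a = float(np.exp(-dt / spec.persistence_tau_s))
    innov = np.sqrt(1.0 - a**2)
    v = lfilter([innov], [1.0, -a], z, axis=0)
    v[0] = z[0]
    inc = v * scales[:, None]

    azimuth = np.cumsum(inc[:, 0])
    azimuth += rng.uniform(0, 360.0)
    azimuth %= 360.0
    pitch_raw = np.cumsum(inc[:, 1]) + (
        0.0 if spec.pitch_limit_deg is None else rng.uniform(-20, 20)
    )
    if spec.pitch_limit_deg is not None:
        # reflect at +/- limit (triangle-wave fold), keeping pitch in bounds
        L = spec.pitch_limit_deg
        pitch = np.abs((pitch_raw + L) % (4 * L) - 2 * L) - L
    else:
        pitch = pitch_raw % 360.0
    timestamps = np.arange(n) * dt

    v_az, v_pi, v_comb = angular_velocities(azimuth, pitch % 360.0, rate)
    truth = pd.DataFrame(
        {
            "t": timestamps,
            "mode": np.where(modes == 0, "slow", "fast"),
            "v_combined_deg_s": np.concatenate([[np.nan], v_comb]),
        }
    )

    if kind == "flight":
        az_r = np.deg2rad(azimuth)
        pi_r = np.deg2rad(pitch)
        step = spec.flight_speed_m_s * dt
        d = np.stack(
            [
                step * np.cos(pi_r) * np.cos(az_r),
                step * np.cos(pi_r) * np.sin(az_r),
                step * np.sin(pi_r),
            ],
            axis=1,
        )
        positions = np.vstack([[0.0, 0.0, 100.0], np.cumsum(d, axis=0) + [0, 0, 100.0]])
        traj = TrajectorySeries(
            timestamps=np.arange(n + 1) * dt, positions=positions
        )
    elif kind == "crawl":
        traj = TrajectorySeries(
            timestamps=timestamps,
            head_angles=np.stack([azimuth, pitch % 360.0], axis=1),
        )
    else:
        raise ValueError(f"kind must be 'crawl' or 'flight', got {kind!r}")
    return traj, truth


def _effective_rates(spec: CellSpec, azimuth_deg, pitch_deg, v_combined):
    """Rate series for one cell, honoring an optional velocity gate.

    ``peak_rate_hz`` is interpreted as the peak of the cell's *marginal* 1D
    tuning (how peak rates are reported for recorded cells): for pure cells
    this equals the joint peak, while for conjunctive tuning the joint peak
    is scaled up by ``exp(kappa)/I0(kappa)``, the uniform-occupancy
    marginalization factor over the other dimension.
    """
    from scipy.special import i0e

    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    pi = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    pref_a = np.deg2rad(spec.preferred_azimuth_deg)
    pref_p = np.deg2rad(spec.preferred_pitch_deg)
    conj_scale = 1.0 / float(i0e(spec.kappa))
    fa = np.exp(spec.kappa * (np.cos(az - pref_a) - 1.0))
    fp = np.exp(spec.kappa * (np.cos(pi - pref_p) - 1.0))
    factors = {
        "untuned": np.ones_like(fa),
        "pure_azimuth": fa,
        "pure_pitch": fp,
        "conjunctive": conj_scale * fa * fp,
    }
    label = np.full(az.size, spec.label, dtype=object)
    if spec.gate_label is not None and spec.gate_threshold_deg_s is not None:
        v = np.asarray(v_combined, dtype=float)
        gated = np.isfinite(v) & (v >= spec.gate_threshold_deg_s)
        label[gated] = spec.gate_label
    rate = np.empty(az.size)
    for lab, f in factors.items():
        mask = label == lab
        if mask.any():
            rate[mask] = spec.peak_rate_hz * f[mask]
    return rate + spec.baseline_rate_hz


def generate_session(
    behavior: BehaviorSpec,
    cells: list[CellSpec],
    duration_s: float = 1200.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Full synthetic recording: head angles plus per-cell spike trains.

    Spikes are drawn as an inhomogeneous Poisson process with the rate held
    constant within each behavioral frame (a Poisson count per frame with
    spike times jittered uniformly inside it — exact for a piecewise-
    constant rate).  Returns ``(session, truth)`` where ``truth`` carries
    the generator's mode sequence and per-cell ground-truth parameters.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    traj, mode_truth = generate_trajectory(behavior, duration_s, "crawl", rng)
    azimuth = traj.head_angles[:, 0]
    pitch = traj.head_angles[:, 1]
    dt = 1.0 / behavior.sampling_rate_hz
    v_comb = mode_truth["v_combined_deg_s"].to_numpy()

    spike_times = {}
    for spec in cells:
        rate = _effective_rates(spec, azimuth, pitch, v_comb)
        counts = rng.poisson(rate * dt)
        frames = np.repeat(np.arange(counts.size), counts)
        times = (frames + rng.uniform(size=frames.size)) * dt
        spike_times[spec.cell_id] = np.sort(times)

    session = Session(
        timestamps=traj.timestamps,
        azimuth_deg=azimuth,
        pitch_deg=pitch,
        spike_times=spike_times,
    )
    truth = {
        "modes": mode_truth,
        "cells": {c.cell_id: asdict(c) for c in cells},
    }
    return session, truth


def session_to_csv(session: Session, truth, out_dir):
    """Write head angles, per-cell spike times, and the ground-truth manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t": session.timestamps,
            "azimuth": session.azimuth_deg,
            "pitch": session.pitch_deg,
        }
    ).to_csv(out / "head_angles.csv", index=False)
    for cell, times in session.spike_times.items():
        pd.DataFrame({"spike_time_s": times}).to_csv(
            out / f"spikes_{cell}.csv", index=False
        )
    manifest = {"cells": truth["cells"]}
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1))
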