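"""Von-Mises tuning curves and neuron populations.

A pure cell is tuned to a single circular stimulus dimension, a conjunctive
cell to all ``D`` dimensions jointly (separable product of von-Mises factors
with, by default, equal concentration along every dimension).  Peak rates are
modulation depths above baseline: the rate at the preferred direction equals
``peak_rate + baseline_rate``.

Two peak-rate normalization schemes relate matched pure and conjunctive
populations:

``equal_population_rate``
    both populations emit the same expected number of spikes,
    ``R_conj = R_pure * exp((D-1)*kappa) / I0(kappa)**(D-1)``.

``equal_fisher_information``
    both populations carry the same Fisher information,
    ``R_conj = R_pure * exp((D-1)*kappa) / (I0(kappa)**(D-1) * D)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from ._angles import TWO_PI, wrap_angle

__all__ = [
    "VonMises1D",
    "VonMises2D",
    "Population",
    "kappa_from_width",
    "width_from_kappa",
    "rate_1d",
    "rate_2d",
    "conjunctive_peak_rate",
    "build_population",
]

_SCHEMES = ("equal_population_rate", "equal_fisher_information", "explicit")
_KINDS = ("pure", "conjunctive", "mixed")


def kappa_from_width(width_deg: float) -> float:
    """Concentration parameter from full tuning width at half-height (degrees).

    Solves ``exp(kappa * (cos(width/2) - 1)) = 1/2``, i.e.
    ``kappa = ln(2) / (1 - cos(width/2))``.
    """
    width_deg = float(width_deg)
    if not 0.0 < width_deg < 360.0:
        raise ValueError(
            f"width at half-height must lie in (0, 360) degrees, got {width_deg}"
        )
    half = np.deg2rad(width_deg) / 2.0
    return float(np.log(2.0) / (1.0 - np.cos(half)))


def width_from_kappa(kappa: float) -> float:
    """Full width at half-height (degrees) of a von-Mises curve; inverse of
    :func:`kappa_from_width`."""
    kappa = float(kappa)
    if kappa <= np.log(2.0) / 2.0:
        raise ValueError(
            f"kappa must exceed ln(2)/2 for the half-height width to exist, got {kappa}"
        )
    return float(np.rad2deg(2.0 * np.arccos(1.0 - np.log(2.0) / kappa)))


@dataclass(frozen=True)
class VonMises1D:
    """One-dimensional von-Mises tuning curve.

    ``rate(s) = peak_rate * exp(kappa * (cos(s - preferred) - 1)) + baseline``.
    """

    preferred_direction: float  # radians
    kappa: float
    peak_rate: float  # Hz, modulation depth above baseline
    baseline_rate: float = 0.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")

    def rate(self, stimulus):
        return rate_1d(self, stimulus)


@dataclass(frozen=True)
class VonMises2D:
    """Separable two-dimensional von-Mises tuning curve (azimuth x pitch)."""

    preferred_azimuth: float
    preferred_pitch: float
    kappa_azimuth: float
    kappa_pitch: float
    peak_rate: float
    baseline_rate: float = 0.0

    def __post_init__(self):
        if self.kappa_azimuth < 0 or self.kappa_pitch < 0:
            raise ValueError("kappas must be non-negative")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")

    def rate(self, azimuth, pitch):
        return rate_2d(self, azimuth, pitch)


def rate_1d(curve: VonMises1D, stimulus):
    """Firing rate (Hz) of a 1D von-Mises curve at the given stimulus angle."""
    s = wrap_angle(np.asarray(stimulus, dtype=float))
    return (
        curve.peak_rate
        * np.exp(curve.kappa * (np.cos(s - curve.preferred_direction) - 1.0))
        + curve.baseline_rate
    )


def rate_2d(curve: VonMises2D, azimuth, pitch):
    """Firing rate (Hz) of a separable 2D von-Mises curve."""
    a = wrap_angle(np.asarray(azimuth, dtype=float))
    p = wrap_angle(np.asarray(pitch, dtype=float))
    log_mod = curve.kappa_azimuth * (np.cos(a - curve.preferred_azimuth) - 1.0)
    log_mod = log_mod + curve.kappa_pitch * (np.cos(p - curve.preferred_pitch) - 1.0)
    return curve.peak_rate * np.exp(log_mod) + curve.baseline_rate


def conjunctive_peak_rate(
    R_pure: float, kappa: float, D: int = 2, scheme: str = "equal_population_rate"
) -> float:
    """Peak rate of conjunctive cells matched to pure cells of peak rate ``R_pure``.

    ``equal_population_rate`` matches the expected population spike counts;
    ``equal_fisher_information`` matches the Fisher information (a further
    factor ``1/D``).
    """
    if D < 2:
        raise ValueError("conjunctive cells require D >= 2")
    if scheme not in ("equal_population_rate", "equal_fisher_information"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    if R_pure <= 0 or kappa < 0:
        raise ValueError("R_pure must be positive and kappa non-negative")
    # exp((D-1)*kappa) / I0(kappa)**(D-1) computed with exponentially scaled
    # Bessel functions to stay finite at large kappa.
    factor = special.i0e(kappa) ** -(D - 1)
    if scheme == "equal_fisher_information":
        factor /= D
    return float(R_pure * factor)


@dataclass
class Population:
    """A population of tuned neurons over a D-dimensional circular stimulus.

    Tuning is stored as flat arrays: ``preferred[i, d]`` and ``kappa[i, d]``
    are meaningful only where ``tuned[i, d]`` is True.  ``group[i]`` labels
    the sub-population the neuron belongs to (pure sub-populations 0..D-1 by
    tuned dimension; conjunctive cells form group D).  The group structure
    drives shared-gain draws and the block structure of noise correlations.
    """

    preferred: np.ndarray  # (N, D) radians
    kappa: np.ndarray  # (N, D)
    tuned: np.ndarray  # (N, D) bool
    peak_rate: np.ndarray  # (N,) Hz
    baseline_rate: np.ndarray  # (N,) Hz
    kind: str
    D: int
    normalization: str = "explicit"
    seed: int | None = None

    def __post_init__(self):
        self.preferred = np.atleast_2d(np.asarray(self.preferred, dtype=float))
        self.kappa = np.atleast_2d(np.asarray(self.kappa, dtype=float))
        self.tuned = np.atleast_2d(np.asarray(self.tuned, dtype=bool))
        self.peak_rate = np.asarray(self.peak_rate, dtype=float)
        self.baseline_rate = np.asarray(self.baseline_rate, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.normalization not in _SCHEMES:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        n, d = self.preferred.shape
        if d != self.D:
            raise ValueError("preferred directions must have D columns")

    @property
    def size(self) -> int:
        return self.preferred.shape[0]

    @property
    def group(self) -> np.ndarray:
        """Sub-population index per neuron: tuned dimension for single-dimension
        cells, ``D`` for conjunctive cells."""
        n_tuned = self.tuned.sum(axis=1)
        g = np.full(self.size, self.D, dtype=int)
        single = n_tuned == 1
        g[single] = np.argmax(self.tuned[single], axis=1)
        return g

    def rates(self, stimulus) -> np.ndarray:
        """Firing rates (Hz) of all neurons at a D-vector stimulus (radians)."""
        s = np.atleast_1d(np.asarray(stimulus, dtype=float))
        if s.shape != (self.D,):
            raise ValueError(f"stimulus must be a {self.D}-vector")
        log_mod = np.where(
            self.tuned, self.kappa * (np.cos(s[None, :] - self.preferred) - 1.0), 0.0
        ).sum(axis=1)
        return self.peak_rate * np.exp(log_mod) + self.baseline_rate

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "kind": self.kind,
            "D": self.D,
            "normalization": self.normalization,
            "seed": self.seed,
            "preferred_deg": np.rad2deg(self.preferred).tolist(),
            "kappa": self.kappa.tolist(),
            "tuned": self.tuned.astype(int).tolist(),
            "peak_rate_hz": self.peak_rate.tolist(),
            "baseline_rate_hz": self.baseline_rate.tolist(),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Population":
        doc = json.loads(text)
        return cls(
            preferred=np.deg2rad(np.asarray(doc["preferred_deg"], dtype=float)),
            kappa=np.asarray(doc["kappa"], dtype=float),
            tuned=np.asarray(doc["tuned"], dtype=bool),
            peak_rate=np.asarray(doc["peak_rate_hz"], dtype=float),
            baseline_rate=np.asarray(doc["baseline_rate_hz"], dtype=float),
            kind=doc["kind"],
            D=int(doc["D"]),
            normalization=doc["normalization"],
            seed=doc["seed"],
        )


def build_population(
    N: int,
    kind: str,
    D: int = 2,
    kappa: float | Sequence[float] = 9.11,
    R_pure: float = 1.0,
    scheme: str = "equal_population_rate",
    seed: int | None = None,
    pure_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Build a population with uniformly drawn preferred directions.

    ``kind='pure'`` splits ``N`` into ``D`` sub-populations of ``N/D`` cells,
    each tuned to a single dimension; ``kind='conjunctive'`` tunes all ``N``
    cells to every dimension with peak rate set by ``scheme``;
    ``kind='mixed'`` allocates ``round(N * pure_fraction)`` cells to a pure
    population (split over dimensions) and the rest to conjunctive cells.

    Reproducible for a fixed ``seed`` (or an explicit ``rng``).
    """
    if N <= 0 or D < 1:
        raise ValueError("N and D must be positive")
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    kap = np.broadcast_to(np.asarray(kappa, dtype=float), (D,)).copy()
    if np.any(kap <= 0):
        raise ValueError("kappa must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    def _pure_block(n):
        if n % D != 0:
            raise ValueError(
                f"pure population size {n} must be divisible by D={D} "
                "(equal sub-populations per dimension)"
            )
        per = n // D
        tuned = np.zeros((n, D), dtype=bool)
        for d in range(D):
            tuned[d * per : (d + 1) * per, d] = True
        pref = rng.uniform(0.0, TWO_PI, size=(n, D))
        pref[~tuned] = 0.0
        return pref, np.tile(kap, (n, 1)), tuned, np.full(n, float(R_pure))

    def _conj_block(n):
        r_conj = (
            float(R_pure)
            if scheme == "explicit"
            else conjunctive_peak_rate(R_pure, float(kap[0]), D, scheme)
        )
        pref = rng.uniform(0.0, TWO_PI, size=(n, D))
        return pref, np.tile(kap, (n, 1)), np.ones((n, D), dtype=bool), np.full(n, r_conj)

    if kind == "pure":
        pref, kaps, tuned, peak = _pure_block(N)
    elif kind == "conjunctive":
        if D < 2:
            raise ValueError("conjunctive populations require D >= 2")
        pref, kaps, tuned, peak = _conj_block(N)
    else:
        if pure_fraction is None or not 0.0 <= pure_fraction <= 1.0:
            raise ValueError("mixed populations require pure_fraction in [0, 1]")
        n_pure = int(round(N * pure_fraction))
        n_pure -= n_pure % D  # keep sub-populations equal
        blocks = []
        if n_pure > 0:
            blocks.append(_pure_block(n_pure))
        if N - n_pure > 0:
            blocks.append(_conj_block(N - n_pure))
        pref = np.concatenate([b[0] for b in blocks])
        kaps = np.concatenate([b[1] for b in blocks])
        tuned = np.concatenate([b[2] for b in blocks])
        peak = np.concatenate([b[3] for b in blocks])

    return Population(
        preferred=pref,
        kappa=kaps,
        tuned=tuned,
        peak_rate=peak,
        baseline_rate=np.zeros(pref.shape[0]),
        kind=kind,
        D=D,
        normalization=scheme,
        seed=seed,
    )
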