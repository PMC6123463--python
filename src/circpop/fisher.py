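"""Closed-form Fisher information and Cramér–Rao bounds.

For uniformly distributed preferred directions the Fisher-information matrix
of both pure and conjunctive populations is proportional to the identity, so
a single scalar ``J`` per population captures the per-dimension information
and ``1/sqrt(J)`` is the per-dimension Cramér–Rao bound.

Closed forms (``Iv`` = modified Bessel function of the first kind):

* pure, D sub-populations of N/D cells:
  ``J_pure = (N/D) * R_pure * T * kappa * exp(-kappa) * I1(kappa)``
* conjunctive, N cells, D dimensions:
  ``J_conj = N * R_conj * T * kappa * exp(-D*kappa) * I0(kappa)**(D-1) * I1(kappa)``
* expected spike counts:
  ``n_pure = N * T * R_pure * exp(-kappa) * I0(kappa)``,
  ``n_conj = N * T * R_conj * exp(-D*kappa) * I0(kappa)**D``.

Exponentially scaled Bessel evaluations (``i0e``, ``i1e``) keep everything
finite at large concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import special

from .tuning import conjunctive_peak_rate

__all__ = [
    "FisherResult",
    "fi_pure",
    "fi_conj",
    "mean_spikes",
    "cr_bound",
    "fisher_summary",
]


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive, got {value}")


def fi_pure(N, R_pure, T, kappa, D: int = 2):
    """Per-dimension Fisher information (rad^-2) of a pure population of
    total size ``N`` split evenly over ``D`` dimensions."""
    _check_positive(N=N, R_pure=R_pure, T=T, kappa=kappa, D=D)
    return (N / D) * R_pure * T * kappa * special.i1e(kappa)


def fi_conj(N, R_conj, T, kappa, D: int = 2):
    """Per-dimension Fisher information (rad^-2) of ``N`` conjunctive cells
    tuned to ``D`` dimensions."""
    _check_positive(N=N, R_conj=R_conj, T=T, kappa=kappa)
    if D < 2:
        raise ValueError("conjunctive cells require D >= 2")
    return N * R_conj * T * kappa * special.i0e(kappa) ** (D - 1) * special.i1e(kappa)


def mean_spikes(N, R, T, kappa, kind: str = "pure", D: int = 2):
    """Expected total spike count of the population over decoding time ``T``."""
    _check_positive(N=N, R=R, T=T, kappa=kappa)
    if kind == "pure":
        return N * T * R * special.i0e(kappa)
    if kind == "conjunctive":
        if D < 2:
            raise ValueError("conjunctive cells require D >= 2")
        return N * T * R * special.i0e(kappa) ** D
    raise ValueError(f"kind must be 'pure' or 'conjunctive', got {kind!r}")


def cr_bound(J):
    """Per-dimension Cramér–Rao bound ``1/sqrt(J)`` in degrees."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("Fisher information must be positive")
    return np.rad2deg(1.0 / np.sqrt(J))


def cr_bound_scalar(J, D: int = 2):
    """Cramér–Rao bound on the combined scalar error (root of summed squared
    per-dimension errors): ``sqrt(D) / sqrt(J)`` in degrees."""
    return np.sqrt(D) * cr_bound(J)


@dataclass(frozen=True)
class FisherResult:
    """Closed-form information summary for matched pure/conjunctive populations."""

    N: int
    T: float
    kappa: float
    D: int
    normalization: str
    R_pure: float
    R_conj: float
    J_pure: float
    J_conj: float
    cr_bound_pure_deg: float
    cr_bound_conj_deg: float
    mean_spikes_pure: float
    mean_spikes_conj: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def fisher_summary(
    N: int,
    T: float,
    kappa: float,
    D: int = 2,
    R_pure: float = 1.0,
    scheme: str = "equal_population_rate",
) -> FisherResult:
    """Evaluate all closed forms for a matched pure/conjunctive pair."""
    R_conj = conjunctive_peak_rate(R_pure, kappa, D, scheme)
    J_p = fi_pure(N, R_pure, T, kappa, D)
    J_c = fi_conj(N, R_conj, T, kappa, D)
    return FisherResult(
        N=int(N),
        T=float(T),
        kappa=float(kappa),
        D=int(D),
        normalization=scheme,
        R_pure=float(R_pure),
        R_conj=float(R_conj),
        J_pure=float(J_p),
        J_conj=float(J_c),
        cr_bound_pure_deg=float(cr_bound(J_p)),
        cr_bound_conj_deg=float(cr_bound(J_c)),
        mean_spikes_pure=float(mean_spikes(N, R_pure, T, kappa, "pure")),
        mean_spikes_conj=float(mean_spikes(N, R_conj, T, kappa, "conjunctive", D)),
    )
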