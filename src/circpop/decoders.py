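"""Stimulus estimation from spike counts: maximum likelihood, population
vector, and a correlation-aware Gaussian-approximation likelihood.

The Poisson log-likelihood of a trial splits into a count-weighted term (the
population-vector term) and a count-independent "lattice" term that only
depends on the population's preferred directions.  Decoding therefore
pre-computes the lattice once per population and grid, making repeated
decoding of many trials cheap: each trial costs a handful of dot products
over the grid plus a local continuous refinement.

Errors follow the shorter-arc convention: signed per-dimension errors in
(-180, 180] degrees, and a combined scalar error equal to the square root of
the sum of squared per-dimension errors.  Trials in which the relevant
(sub-)population emitted no spikes are flagged degenerate and assigned an
error of 180 degrees (pi) per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

from ._angles import TWO_PI, rad2deg, wrap_angle, wrap_diff
from .spiking import CorrelationStructure, SpikeCountMatrix
from .tuning import Population

__all__ = [
    "DecodeResult",
    "GridSpec",
    "ml_decode",
    "ml_decode_pure",
    "ml_decode_conj",
    "pv_decode",
    "ml_decode_gaussian_nc",
    "circular_error",
]


@dataclass
class GridSpec:
    """Grid resolution (degrees) for the dense search stage."""

    step_1d: float = 1.0
    step_2d: float = 2.0
    refine: bool = True
    refine_tol: float = 1e-4  # radians


@dataclass
class DecodeResult:
    """Per-trial estimates and errors for one decoding run."""

    estimates: np.ndarray  # (trials, D) radians; NaN on degenerate dims
    errors_deg: np.ndarray  # (trials, D) signed, shorter arc
    scalar_error_deg: np.ndarray  # (trials,)
    degenerate: np.ndarray  # (trials, D) bool
    decoder: str

    @property
    def mean_scalar_error(self) -> float:
        return float(np.mean(self.scalar_error_deg))

    def to_frame(self, truth=None):
        import pandas as pd

        trials, D = self.estimates.shape
        data = {"trial": np.arange(trials)}
        for d in range(D):
            data[f"estimate_deg_{d}"] = np.rad2deg(self.estimates[:, d])
            data[f"error_deg_{d}"] = self.errors_deg[:, d]
            data[f"degenerate_{d}"] = self.degenerate[:, d]
        data["scalar_error_deg"] = self.scalar_error_deg
        data["decoder"] = self.decoder
        return pd.DataFrame(data)


def circular_error(estimate, truth):
    """Signed per-dimension errors (degrees, shorter arc) and the combined
    scalar error ``sqrt(sum_d err_d^2)``.

    Accepts (D,) or (trials, D) arrays of angles in radians.
    """
    est = np.atleast_2d(np.asarray(estimate, dtype=float))
    tru = np.broadcast_to(np.atleast_2d(np.asarray(truth, dtype=float)), est.shape)
    err = rad2deg(wrap_diff(est - tru))
    scalar = np.sqrt(np.sum(err**2, axis=1))
    if np.asarray(estimate).ndim == 1:
        return err[0], float(scalar[0])
    return err, scalar


def _finalize(estimates, truth, degenerate, decoder):
    """Apply the error-pi convention on degenerate dimensions and package."""
    est = np.array(estimates, dtype=float)
    err, _ = circular_error(est, truth)
    err = np.where(degenerate, 180.0, err)
    est[degenerate] = np.nan
    scalar = np.sqrt(np.sum(err**2, axis=1))
    return DecodeResult(
        estimates=est,
        errors_deg=err,
        scalar_error_deg=scalar,
        degenerate=degenerate,
        decoder=decoder,
    )


# ---------------------------------------------------------------------------
# Poisson maximum likelihood
# ---------------------------------------------------------------------------


class MLObjective:
    """Pre-computed grid lattice + per-trial Poisson log-likelihood terms.

    The log-likelihood (up to count-only constants) is
    ``sum_i n_i * sum_d kappa_id cos(s_d - pref_id) - T * sum_i R_i(s)``.
    The second (lattice) term is count-independent and cached on the grid.
    """

    def __init__(self, population: Population, T: float, grid: GridSpec | None = None):
        if T <= 0:
            raise ValueError("T must be positive")
        self.population = population
        self.T = T
        self.grid = grid or GridSpec()
        self.D = population.D
        self._group = population.group
        self._is_pure_only = bool(np.all(self._group < self.D))
        self._has_conj = bool(np.any(self._group == self.D))
        self._build_grids()

    def _build_grids(self):
        pop, T = self.population, self.T
        step = self.grid.step_1d if self._is_pure_only else self.grid.step_2d
        G = max(int(round(360.0 / step)), 8)
        self.phi = TWO_PI * np.arange(G) / G  # shared axis for all dims
        self.G = G
        # per-dimension factors exp(kappa_id * (cos(phi - pref_id) - 1)) for
        # every cell tuned to that dimension
        self._dim_idx = []
        self._dim_factors = []
        for d in range(self.D):
            idx = np.flatnonzero(pop.tuned[:, d])
            f = np.exp(
                pop.kappa[idx, d]
                * (np.cos(self.phi[:, None] - pop.preferred[idx, d][None, :]) - 1.0)
            )  # (G, n_d)
            self._dim_idx.append(idx)
            self._dim_factors.append(f)

        if self._is_pure_only or self.D != 2:
            # separable lattices per dimension (pure cells only contribute to
            # their own dimension)
            self._lattice_1d = []
            for d in range(self.D):
                idx = self._dim_idx[d]
                pure_mask = self._group[idx] == d
                lat = T * (self._dim_factors[d][:, pure_mask] @ self.population.peak_rate[idx[pure_mask]])
                base = self.population.baseline_rate[idx[pure_mask]].sum() * T
                self._lattice_1d.append(lat + base)
        if self.D == 2 and not self._is_pure_only:
            # joint 2D lattice: conjunctive product part + separable pure parts
            lat = np.zeros((self.G, self.G))
            conj = np.flatnonzero(self._group == self.D)
            if conj.size:
                a = self._factor_for(conj, 0)  # (G, n_c)
                b = self._factor_for(conj, 1)
                lat += self.T * (a * self.population.peak_rate[conj][None, :]) @ b.T
            for d, axis in ((0, 0), (1, 1)):
                idx = self._dim_idx[d]
                pure_mask = self._group[idx] == d
                if not pure_mask.any():
                    continue
                contrib = self.T * (
                    self._dim_factors[d][:, pure_mask]
                    @ self.population.peak_rate[idx[pure_mask]]
                )
                lat += contrib[:, None] if axis == 0 else contrib[None, :]
            lat += self.T * self.population.baseline_rate.sum()
            self._lattice_2d = lat

    def _factor_for(self, cells, d):
        """(G, len(cells)) tuning factor along dimension d for given cells."""
        pop = self.population
        return np.exp(
            pop.kappa[cells, d][None, :]
            * (np.cos(self.phi[:, None] - pop.preferred[cells, d][None, :]) - 1.0)
        )

    # -- continuous objective (single trial) -------------------------------
    def loglik(self, counts, stimulus):
        """Continuous Poisson log-likelihood (up to constants) of one trial."""
        pop = self.population
        s = np.atleast_1d(np.asarray(stimulus, dtype=float))
        rates = pop.rates(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.where(counts > 0, np.log(np.clip(rates * self.T, 1e-300, None)), 0.0)
        return float(np.sum(counts * logr) - self.T * rates.sum())

    # -- per-dimension weighted resultants ----------------------------------
    def _data_curves(self, counts, dims=None):
        """Count-weighted term on the grid per dimension: (D, G)."""
        pop = self.population
        out = []
        for d in range(self.D) if dims is None else dims:
            idx = self._dim_idx[d]
            w = counts[idx] * pop.kappa[idx, d]
            C = float(np.sum(w * np.cos(pop.preferred[idx, d])))
            S = float(np.sum(w * np.sin(pop.preferred[idx, d])))
            out.append(C * np.cos(self.phi) + S * np.sin(self.phi))
        return out

    # -- decoding -----------------------------------------------------------
    def decode_trial(self, counts):
        """Estimate (D,) and degeneracy flags (D,) for one trial's counts."""
        pop = self.population
        degenerate = np.zeros(self.D, dtype=bool)
        est = np.zeros(self.D)
        if self._has_conj and counts.sum() == 0:
            return est, np.ones(self.D, dtype=bool)
        if self._is_pure_only:
            for d in range(self.D):
                idx = self._dim_idx[d]
                if counts[idx].sum() == 0:
                    degenerate[d] = True
                    continue
                curve = self._data_curves(counts, dims=[d])[0] - self._lattice_1d[d]
                est[d] = self._refine_1d(curve, counts, d)
            return est, degenerate
        if self.D == 2:
            curves = self._data_curves(counts)
            obj = curves[0][:, None] + curves[1][None, :] - self._lattice_2d
            i, j = np.unravel_index(np.argmax(obj), obj.shape)
            start = np.array([self.phi[i], self.phi[j]])
            est = self._refine_nd(start, counts)
            return est, degenerate
        # D > 2: multi-start local refinement from PV initialisation
        start = _pv_estimate(counts, pop)[0]
        est = self._refine_nd(np.where(np.isnan(start), 0.0, start), counts)
        return est, degenerate

    def _refine_1d(self, grid_curve, counts, d):
        k = int(np.argmax(grid_curve))
        best = self.phi[k]
        if not self.grid.refine:
            return best
        h = TWO_PI / self.G
        pop = self.population
        idx = self._dim_idx[d]
        pure_mask = self._group[idx] == d
        cells = idx[pure_mask]
        n = counts[cells]
        kapp = pop.kappa[cells, d]
        pref = pop.preferred[cells, d]
        peak = pop.peak_rate[cells]

        def neg(x):
            dphi = x - pref
            return -(
                np.sum(n * kapp * np.cos(dphi))
                - self.T * np.sum(peak * np.exp(kapp * (np.cos(dphi) - 1.0)))
            )

        res = optimize.minimize_scalar(
            neg, bounds=(best - h, best + h), method="bounded",
            options={"xatol": self.grid.refine_tol},
        )
        return wrap_angle(float(res.x))

    def _refine_nd(self, start, counts):
        if not self.grid.refine:
            return wrap_angle(start)
        step = np.deg2rad(self.grid.step_2d)

        def neg(x):
            return -self.loglik(counts, x)

        res = optimize.minimize(
            neg,
            start,
            method="Nelder-Mead",
            options={
                "xatol": self.grid.refine_tol,
                "fatol": 1e-8,
                "initial_simplex": start[None, :]
                + np.vstack([np.zeros(self.D), np.eye(self.D) * step]),
                "maxiter": 200 * self.D,
            },
        )
        return wrap_angle(res.x)


def ml_decode(
    matrix: SpikeCountMatrix,
    population: Population,
    grid: GridSpec | None = None,
    objective: MLObjective | None = None,
) -> DecodeResult:
    """Maximum-likelihood decoding of every trial in ``matrix``.

    Pass a pre-built :class:`MLObjective` to reuse grid lattices across many
    stimulus conditions of the same population and ``T``.
    """
    obj = objective or MLObjective(population, matrix.T, grid)
    trials = matrix.trials
    est = np.zeros((trials, population.D))
    degen = np.zeros((trials, population.D), dtype=bool)
    for t in range(trials):
        est[t], degen[t] = obj.decode_trial(matrix.counts[t])
    return _finalize(est, matrix.stimulus, degen, "ml")


def ml_decode_pure(matrix, population, grid=None, objective=None):
    """ML decoding for a pure population (per-dimension separable objective)."""
    if not np.all(population.group < population.D):
        raise ValueError("ml_decode_pure requires a pure population")
    res = ml_decode(matrix, population, grid, objective)
    return DecodeResult(
        res.estimates, res.errors_deg, res.scalar_error_deg, res.degenerate, "ml"
    )


def ml_decode_conj(matrix, population, grid=None, objective=None):
    """ML decoding for a conjunctive population (joint D-dimensional search)."""
    if not np.any(population.group == population.D):
        raise ValueError("ml_decode_conj requires conjunctive cells")
    return ml_decode(matrix, population, grid, objective)


# ---------------------------------------------------------------------------
# Population vector
# ---------------------------------------------------------------------------


def _pv_estimate(counts, population: Population):
    """PV estimate per dimension for one trial; NaN where resultant is zero."""
    est = np.full(population.D, np.nan)
    degen = np.zeros(population.D, dtype=bool)
    for d in range(population.D):
        idx = np.flatnonzero(population.tuned[:, d])
        n = counts[idx]
        C = np.sum(n * np.cos(population.preferred[idx, d]))
        S = np.sum(n * np.sin(population.preferred[idx, d]))
        if n.sum() == 0 or np.hypot(C, S) < 1e-9 * n.sum():
            degen[d] = True
            continue
        est[d] = np.arctan2(S, C) % TWO_PI
    return est, degen


def pv_decode(matrix: SpikeCountMatrix, population: Population) -> DecodeResult:
    """Population-vector decoding: per dimension, the angle of the
    spike-count-weighted sum of preferred-direction unit vectors."""
    trials = matrix.trials
    est = np.zeros((trials, population.D))
    degen = np.zeros((trials, population.D), dtype=bool)
    for t in range(trials):
        e, dg = _pv_estimate(matrix.counts[t], population)
        est[t] = np.where(dg, 0.0, e)
        degen[t] = dg
    return _finalize(est, matrix.stimulus, degen, "pv")


# ---------------------------------------------------------------------------
# Gaussian-approximation likelihood with known noise correlations
# ---------------------------------------------------------------------------


def ml_decode_gaussian_nc(
    matrix: SpikeCountMatrix,
    population: Population,
    structure: CorrelationStructure,
    coarse_step_deg: float = 10.0,
    ridge: float = 1e-8,
) -> DecodeResult:
    """Decode under a Gaussian approximation of the correlated likelihood.

    The mean is ``rate(s) * T`` and the covariance
    ``Sigma_ij(s) = c_ij * sqrt(mu_i(s) * mu_j(s)) + ridge * delta_ij``,
    matching the copula generator's second moments.  A coarse grid search is
    followed by Nelder-Mead refinement.  O(N^3) per grid point — intended
    for moderate population sizes.
    """
    T = matrix.T
    c = structure.correlation

    def neg_loglik(s, counts):
        mu = population.rates(wrap_angle(s)) * T
        sd = np.sqrt(np.clip(mu, 1e-12, None))
        sigma = c * np.outer(sd, sd)
        sigma[np.diag_indices_from(sigma)] = mu + ridge
        resid = counts - mu
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            sigma[np.diag_indices_from(sigma)] += 1e-6 * (1 + mu.max())
            chol = np.linalg.cholesky(sigma)
        y = solve_triangular(chol, resid, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return 0.5 * (y @ y + logdet)

    G = max(int(round(360.0 / coarse_step_deg)), 8)
    axis = TWO_PI * np.arange(G) / G
    grids = np.meshgrid(*([axis] * population.D), indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=1)

    trials = matrix.trials
    est = np.zeros((trials, population.D))
    degen = np.zeros((trials, population.D), dtype=bool)
    for t in range(trials):
        counts = matrix.counts[t]
        if counts.sum() == 0:
            degen[t] = True
            continue
        vals = np.array([neg_loglik(p, counts) for p in points])
        start = points[int(np.argmin(vals))]
        res = optimize.minimize(
            lambda s: neg_loglik(s, counts),
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8},
        )
        est[t] = wrap_angle(res.x)
    return _finalize(est, matrix.stimulus, degen, "ml_gaussian_nc")
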