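"""Spike-count generation: independent Poisson and dependent variants.

Four ways of introducing dependencies between neurons are supported:

* distance-structured noise correlations, sampled through a Gaussian copula
  whose correlation matrix follows ``c_ij = (1/4) cos(2 d_ij) exp(-d_ij^2)``
  as a function of preferred-direction distance ``d_ij`` (radians), with
  zero correlation across sub-populations;
* a shared additive gain, one uniform(-0.2, 0.2) shift of the normalized
  tuning per sub-population per trial, with negative Poisson parameters
  clamped to zero;
* a shared multiplicative gain, one log-normal(mu=-1/2, sigma^2=1) factor
  per sub-population per trial (mean exactly 1);
* a two-layer feed-forward pooling model in which downstream pure and
  conjunctive cells pool Poisson spike counts from evenly spaced upstream
  populations, which induces correlations without an explicit copula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from ._angles import TWO_PI, circ_dist
from .tuning import Population

__all__ = [
    "SpikeCountMatrix",
    "CorrelationStructure",
    "PoolingNetwork",
    "sample_independent",
    "correlation_from_distance",
    "sample_correlated",
    "additive_gain_rates",
    "multiplicative_gain_rates",
    "sample_with_gain",
    "build_pooling_network",
    "pooled_rates",
    "sample_pooled",
    "counts_to_frame",
]

NOISE_MODELS = (
    "independent",
    "correlated",
    "additive_gain",
    "multiplicative_gain",
    "pooled",
)


@dataclass
class SpikeCountMatrix:
    """Trials x neurons integer spike counts for one stimulus condition."""

    counts: np.ndarray  # (trials, N) int
    stimulus: np.ndarray  # (D,) radians
    T: float
    noise_model: str
    seed: int | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be trials x neurons")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def trials(self) -> int:
        return self.counts.shape[0]


def counts_to_frame(matrix: SpikeCountMatrix):
    """Long-format DataFrame (trial, neuron_id, count) for CSV export."""
    import pandas as pd

    trials, n = matrix.counts.shape
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(trials), n),
            "neuron_id": np.tile(np.arange(n), trials),
            "count": matrix.counts.ravel(),
        }
    )


def _resolve_rng(seed, rng):
    return rng if rng is not None else np.random.default_rng(seed)


def sample_independent(
    population: Population,
    stimulus,
    T: float,
    trials: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpikeCountMatrix:
    """Independent Poisson counts with mean ``rate * T`` per neuron and trial."""
    if T <= 0:
        raise ValueError("T must be positive")
    rng = _resolve_rng(seed, rng)
    mu = population.rates(stimulus) * T
    counts = rng.poisson(mu, size=(trials, population.size))
    return SpikeCountMatrix(counts, np.atleast_1d(stimulus), T, "independent", seed)


# ---------------------------------------------------------------------------
# Distance-structured noise correlations (Gaussian copula)
# ---------------------------------------------------------------------------


@dataclass
class CorrelationStructure:
    """Pairwise preferred-direction distances and target count correlations."""

    distance: np.ndarray  # (N, N) radians
    correlation: np.ndarray  # (N, N) in [-1, 1], unit diagonal

    def __post_init__(self):
        c = self.correlation
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")


def correlation_from_distance(population: Population) -> CorrelationStructure:
    """Correlation structure from preferred-direction distances.

    Same-dimension pure pairs use the 1D shorter-arc distance; conjunctive
    pairs the Euclidean combination of per-dimension shorter arcs.  Cells in
    distinct sub-populations are uncorrelated.
    """
    group = population.group
    n = population.size
    # per-dimension shorter-arc distances, then combine per tuned dims
    dist = np.zeros((n, n))
    same_group = group[:, None] == group[None, :]
    for d in range(population.D):
        pd_ = population.preferred[:, d]
        tuned_d = population.tuned[:, d]
        mask = tuned_d[:, None] & tuned_d[None, :] & same_group
        dd = circ_dist(pd_[:, None], pd_[None, :])
        dist += np.where(mask, dd**2, 0.0)
    dist = np.sqrt(dist)

    corr = 0.25 * np.cos(2.0 * dist) * np.exp(-(dist**2))
    corr = np.where(same_group, corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationStructure(distance=dist, correlation=corr)


def nearest_psd(c: np.ndarray, eig_floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clip)
    and restore the unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() >= eig_floor:
        return c
    w = np.clip(w, eig_floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def sample_correlated(
    population: Population,
    stimulus,
    T: float,
    trials: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    structure: CorrelationStructure | None = None,
) -> SpikeCountMatrix:
    """Correlated Poisson counts via a Gaussian copula.

    Correlated standard normals with the target correlation matrix are mapped
    through the normal CDF and then the inverse Poisson CDF, which guarantees
    Poisson marginals with mean ``rate * T`` while approximately preserving
    the correlation structure.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    rng = _resolve_rng(seed, rng)
    if structure is None:
        structure = correlation_from_distance(population)
    c = nearest_psd(structure.correlation)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(c.shape[0]))
    z = rng.standard_normal(size=(trials, population.size)) @ chol.T
    q = stats.norm.cdf(z)
    mu = population.rates(stimulus) * T
    counts = stats.poisson.ppf(q, mu[None, :]).astype(np.int64)
    return SpikeCountMatrix(counts, np.atleast_1d(stimulus), T, "correlated", seed)


# ---------------------------------------------------------------------------
# Shared gains
# ---------------------------------------------------------------------------


def _group_draws(population: Population, trials: int, rng, draw):
    """One shared draw per sub-population per trial, broadcast to neurons."""
    group = population.group
    groups = np.unique(group)
    per_group = draw(size=(trials, groups.size))
    col = np.searchsorted(groups, group)
    return per_group[:, col], per_group


def additive_gain_rates(
    population: Population,
    stimulus,
    trials: int,
    rng: np.random.Generator,
    delta_range: float = 0.2,
):
    """Trial rates under a shared additive shift of the normalized tuning.

    The shifted rate is ``peak_rate * (f(stimulus) + Delta)`` where ``f`` is
    the unit-peak tuning factor and ``Delta ~ U(-delta_range, delta_range)``
    is shared within each sub-population; negative values clamp to zero.
    """
    base = population.rates(stimulus)
    tuning = (base - population.baseline_rate) / population.peak_rate
    deltas, _ = _group_draws(
        population, trials, rng, lambda size: rng.uniform(-delta_range, delta_range, size)
    )
    rates = population.peak_rate[None, :] * (tuning[None, :] + deltas)
    rates += population.baseline_rate[None, :]
    return np.clip(rates, 0.0, None)


def multiplicative_gain_rates(
    population: Population,
    stimulus,
    trials: int,
    rng: np.random.Generator,
    mu: float = -0.5,
    sigma: float = 1.0,
):
    """Trial rates scaled by a shared log-normal gain with unit mean
    (``mu = -sigma^2/2`` by default)."""
    base = population.rates(stimulus)
    alphas, _ = _group_draws(
        population, trials, rng, lambda size: rng.lognormal(mu, sigma, size)
    )
    return alphas * base[None, :]


def sample_with_gain(
    population: Population,
    stimulus,
    T: float,
    trials: int = 1,
    gain: str = "multiplicative",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpikeCountMatrix:
    """Poisson counts under a shared additive or multiplicative gain."""
    if T <= 0:
        raise ValueError("T must be positive")
    rng = _resolve_rng(seed, rng)
    if gain == "additive":
        rates = additive_gain_rates(population, stimulus, trials, rng)
        model = "additive_gain"
    elif gain == "multiplicative":
        rates = multiplicative_gain_rates(population, stimulus, trials, rng)
        model = "multiplicative_gain"
    else:
        raise ValueError(f"gain must be 'additive' or 'multiplicative', got {gain!r}")
    counts = rng.poisson(rates * T)
    return SpikeCountMatrix(counts, np.atleast_1d(stimulus), T, model, seed)


# ---------------------------------------------------------------------------
# Feed-forward pooling model
# ---------------------------------------------------------------------------


@dataclass
class PoolingNetwork:
    """Two-layer model: evenly spaced upstream populations (one per stimulus
    dimension) feeding downstream pure and conjunctive populations.

    Downstream Poisson means are
    ``r_pure_i  = A_pure * sum_j m_j * exp(kappa * cos(pref_i - a_j))`` and
    ``r_conj_i  = (A_conj / T) * prod_d sum_j m_jd * exp(kappa * cos(pref_id - a_j))``
    where ``m_jd`` are upstream counts and ``a_j = 2*pi*j/N0``.  The division
    by ``T`` keeps conjunctive expected counts linear in ``T``.  ``A_pure``
    and ``A_conj`` are calibrated so the two downstream populations emit the
    same expected number of spikes.
    """

    N0: int  # upstream cells per dimension
    kappa: float
    R_upstream: float  # upstream peak rate, Hz
    pure: Population
    conj: Population
    A_pure: float = 1.0
    A_conj: float = 1.0

    _weights_cache: dict = field(default_factory=dict, repr=False)

    @property
    def upstream_angles(self) -> np.ndarray:
        return TWO_PI * np.arange(self.N0) / self.N0

    def upstream_rates(self, stimulus) -> np.ndarray:
        """(D, N0) upstream firing rates at the stimulus."""
        s = np.atleast_1d(np.asarray(stimulus, dtype=float))
        return self.R_upstream * np.exp(
            self.kappa * (np.cos(s[:, None] - self.upstream_angles[None, :]) - 1.0)
        )


def _pooling_weights(network: PoolingNetwork, population: Population):
    """Per-dimension pooling weight matrices exp(kappa*cos(pref - a_j)).

    Returns a list of (neurons_d, N0) arrays and the per-dimension neuron
    index arrays.  Cached on the network (preferred directions are fixed
    once the network is built).
    """
    key = id(population)
    if key in network._weights_cache:
        return network._weights_cache[key]
    angles = network.upstream_angles
    weights, indices = [], []
    for d in range(population.D):
        idx = np.flatnonzero(population.tuned[:, d])
        pref = population.preferred[idx, d]
        w = np.exp(network.kappa * np.cos(pref[:, None] - angles[None, :]))
        weights.append(w)
        indices.append(idx)
    network._weights_cache[key] = (weights, indices)
    return weights, indices


def build_pooling_network(
    N: int,
    N0: int = 4000,
    kappa: float = 9.1,
    R_upstream: float | None = None,
    D: int = 2,
    T_calibration: float = 10.0,
    target_rate: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    calibration_stimuli: int = 64,
) -> PoolingNetwork:
    """Build and calibrate a pooling network with ``N`` downstream cells per kind.

    ``A_pure`` is set so the downstream pure population emits, on average,
    ``target_rate`` spikes per second (default: the expected rate of a
    matched independent-Poisson pure population with unit peak rate), and
    ``A_conj`` so the conjunctive downstream population matches the pure one.
    Calibration averages the exact conditional expectations over uniformly
    drawn stimuli (upstream noise enters linearly, so upstream means suffice).

    ``R_upstream`` defaults to ``N / N0``, which gives every upstream
    population the same total firing rate as each downstream population
    (matched rates throughout the network).
    """
    rng = _resolve_rng(seed, rng)
    if R_upstream is None:
        R_upstream = N / N0
    from .tuning import build_population

    pure = build_population(N, "pure", D=D, kappa=kappa, R_pure=1.0, rng=rng)
    conj = build_population(
        N, "conjunctive", D=D, kappa=kappa, R_pure=1.0, scheme="explicit", rng=rng
    )
    net = PoolingNetwork(
        N0=N0, kappa=kappa, R_upstream=R_upstream, pure=pure, conj=conj
    )
    if target_rate is None:
        target_rate = N * 1.0 * float(special.i0e(kappa))  # spikes/s, matched model

    T = T_calibration
    w_pure, _ = _pooling_weights(net, pure)
    w_conj, _ = _pooling_weights(net, conj)
    stimuli = rng.uniform(0.0, TWO_PI, size=(calibration_stimuli, D))
    pure_tot = 0.0
    conj_tot = 0.0
    for s in stimuli:
        m_mean = net.upstream_rates(s) * T  # (D, N0)
        pure_tot += sum(w_pure[d] @ m_mean[d] for d in range(D)).sum() / len(stimuli)
        conj_factors = [w_conj[d] @ m_mean[d] for d in range(D)]
        conj_tot += (np.prod(conj_factors, axis=0) / T).sum() / len(stimuli)
    # expected downstream spikes over T: pure A*pure_tot, conj A*conj_tot
    net.A_pure = float(target_rate * T / pure_tot)
    net.A_conj = float(target_rate * T / conj_tot)
    return net


def pooled_rates(network: PoolingNetwork, stimulus, T: float, rng: np.random.Generator):
    """Draw upstream counts and return downstream Poisson means for one trial.

    Returns ``(r_pure, r_conj)`` where each entry is the Poisson mean of the
    downstream spike count over the window ``T`` (counts, not Hz).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    m = rng.poisson(network.upstream_rates(stimulus) * T)  # (D, N0)
    D = network.pure.D
    w_pure, idx_pure = _pooling_weights(network, network.pure)
    r_pure = np.zeros(network.pure.size)
    for d in range(D):
        r_pure[idx_pure[d]] = network.A_pure * (w_pure[d] @ m[d])
    w_conj, _ = _pooling_weights(network, network.conj)
    conj_factors = [w_conj[d] @ m[d] for d in range(D)]
    r_conj = network.A_conj / T * np.prod(conj_factors, axis=0)
    return r_pure, r_conj


def sample_pooled(
    network: PoolingNetwork,
    stimulus,
    T: float,
    trials: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Downstream spike counts for both kinds; returns a pair of
    :class:`SpikeCountMatrix` (pure, conjunctive)."""
    rng = _resolve_rng(seed, rng)
    D = network.pure.D
    w_pure, idx_pure = _pooling_weights(network, network.pure)
    w_conj, _ = _pooling_weights(network, network.conj)
    counts_pure = np.zeros((trials, network.pure.size), dtype=np.int64)
    counts_conj = np.zeros((trials, network.conj.size), dtype=np.int64)
    for t in range(trials):
        m = rng.poisson(network.upstream_rates(stimulus) * T)
        r_pure = np.zeros(network.pure.size)
        for d in range(D):
            r_pure[idx_pure[d]] = network.A_pure * (w_pure[d] @ m[d])
        conj_factors = [w_conj[d] @ m[d] for d in range(D)]
        r_conj = network.A_conj / T * np.prod(conj_factors, axis=0)
        counts_pure[t] = rng.poisson(r_pure)
        counts_conj[t] = rng.poisson(r_conj)
    s = np.atleast_1d(stimulus)
    return (
        SpikeCountMatrix(counts_pure, s, T, "pooled", seed),
        SpikeCountMatrix(counts_conj, s, T, "pooled", seed),
    )
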