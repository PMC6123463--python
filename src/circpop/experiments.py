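"""Simulation drivers: error surfaces over (N, T), regime maps and critical
population sizes, 2D/1D error ratios and distributions, spike-conditioned
errors, mixed-population synergy, and the empirical error-vs-FI collapse.

All drivers share :func:`simulate_errors`, which repeatedly draws a stimulus
uniformly at random, samples spike counts under the chosen noise model, and
decodes.  Preferred directions are redrawn every ``repeats_per_population``
trials (1 by default, i.e. a fresh population per trial); the grid lattice
of the ML objective depends only on the population and ``T``, so batching
trials per population amortizes its construction without biasing means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._angles import TWO_PI
from . import spiking
from .decoders import GridSpec, MLObjective, ml_decode, pv_decode
from .fisher import cr_bound_scalar, fisher_summary
from .tuning import Population, build_population

__all__ = [
    "SimulationResult",
    "ErrorSurface",
    "RegimeMap",
    "MixedPopulationResult",
    "ConditionalErrorResult",
    "simulate_errors",
    "error_surface",
    "regime_map",
    "n_critical",
    "ratio_2d_1d",
    "error_distribution",
    "conditional_error",
    "mixed_error",
    "error_vs_fi_characterization",
]

RANDOM_GUESS_1D_DEG = 90.0
RANDOM_GUESS_2D_DEG = 137.74  # E[sqrt(e1^2+e2^2)], e uniform on [-180, 180]


def saturated_mean_error(J, D: int = 2) -> float:
    """Expected mean scalar error (degrees) of a CR-saturated unbiased
    decoder: per-dimension errors Gaussian with variance 1/J, so the scalar
    error follows a chi distribution with D degrees of freedom."""
    from scipy.special import gamma

    from .fisher import cr_bound

    sigma = float(cr_bound(J))  # per-dimension bound, degrees
    return float(sigma * np.sqrt(2.0) * gamma((D + 1) / 2) / gamma(D / 2))


@dataclass
class SimulationResult:
    """Raw per-trial output of one (kind, N, T) simulation cell."""

    kind: str
    N: int
    T: float
    scalar_error_deg: np.ndarray  # (repeats,)
    errors_deg: np.ndarray  # (repeats, D)
    subpop_spikes: np.ndarray  # (repeats, n_groups) spike totals per group
    degenerate: np.ndarray  # (repeats, D)

    @property
    def mean_scalar_error(self) -> float:
        return float(np.mean(self.scalar_error_deg))

    @property
    def sem_scalar_error(self) -> float:
        n = self.scalar_error_deg.size
        return float(np.std(self.scalar_error_deg, ddof=1) / np.sqrt(n)) if n > 1 else np.nan


def _sample_counts(population, stimulus, T, trials, noise_model, rng):
    if noise_model == "independent":
        return spiking.sample_independent(population, stimulus, T, trials, rng=rng)
    if noise_model == "correlated":
        return spiking.sample_correlated(population, stimulus, T, trials, rng=rng)
    if noise_model == "additive_gain":
        return spiking.sample_with_gain(population, stimulus, T, trials, "additive", rng=rng)
    if noise_model == "multiplicative_gain":
        return spiking.sample_with_gain(
            population, stimulus, T, trials, "multiplicative", rng=rng
        )
    raise ValueError(f"unsupported noise model {noise_model!r}")


def simulate_errors(
    kind: str,
    N: int,
    T: float,
    repeats: int,
    D: int = 2,
    kappa: float = 9.11,
    R_pure: float = 1.0,
    scheme: str = "equal_population_rate",
    decoder: str = "ml",
    noise_model: str = "independent",
    grid: GridSpec | None = None,
    repeats_per_population: int = 1,
    pure_fraction: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SimulationResult:
    """Mean decoding error of one population kind at a single (N, T) cell."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    scalar = np.zeros(repeats)
    errors = np.zeros((repeats, D))
    degen = np.zeros((repeats, D), dtype=bool)
    n_groups = D + 1
    spikes = np.zeros((repeats, n_groups))
    done = 0
    while done < repeats:
        batch = min(repeats_per_population, repeats - done)
        pop = build_population(
            N, kind, D=D, kappa=kappa, R_pure=R_pure, scheme=scheme,
            pure_fraction=pure_fraction, rng=rng,
        )
        obj = MLObjective(pop, T, grid) if decoder == "ml" else None
        group = pop.group
        for b in range(batch):
            stim = rng.uniform(0.0, TWO_PI, size=D)
            mat = _sample_counts(pop, stim, T, 1, noise_model, rng)
            res = (
                ml_decode(mat, pop, objective=obj)
                if decoder == "ml"
                else pv_decode(mat, pop)
            )
            t = done + b
            scalar[t] = res.scalar_error_deg[0]
            errors[t] = res.errors_deg[0]
            degen[t] = res.degenerate[0]
            for g in range(n_groups):
                spikes[t, g] = mat.counts[0, group == g].sum()
        done += batch
    return SimulationResult(kind, N, T, scalar, errors, spikes, degen)


# ---------------------------------------------------------------------------
# Error surfaces and regime maps
# ---------------------------------------------------------------------------


@dataclass
class ErrorSurface:
    kind: str
    N_grid: np.ndarray
    T_grid: np.ndarray
    mean_scalar_error: np.ndarray  # (nN, nT) degrees
    sem: np.ndarray
    repeats: int
    seed: int | None

    def to_frame(self):
        import pandas as pd

        nn, nt = np.meshgrid(self.N_grid, self.T_grid, indexing="ij")
        return pd.DataFrame(
            {
                "kind": self.kind,
                "N": nn.ravel().astype(int),
                "T": nt.ravel(),
                "mean_scalar_error_deg": self.mean_scalar_error.ravel(),
                "sem_deg": self.sem.ravel(),
            }
        )


def default_grids():
    """Desk-scale defaults: log2-spaced N, log-spaced T in [0.01, 10] s."""
    N_grid = np.array([26, 50, 100, 200, 400, 800, 1600])
    T_grid = np.logspace(-2, 1, 7)
    return N_grid, T_grid


def error_surface(
    kind: str,
    N_grid=None,
    T_grid=None,
    repeats: int = 200,
    seed: int | None = None,
    **kwargs,
) -> ErrorSurface:
    """Mean scalar decoding error over an (N, T) grid for one population kind."""
    if repeats < 30:
        warnings.warn("fewer than 30 repeats per cell gives unstable contours")
    if N_grid is None or T_grid is None:
        dn, dt = default_grids()
        N_grid = dn if N_grid is None else np.asarray(N_grid)
        T_grid = dt if T_grid is None else np.asarray(T_grid)
    N_grid = np.asarray(N_grid, dtype=int)
    T_grid = np.asarray(T_grid, dtype=float)
    rng = np.random.default_rng(seed)
    mean = np.zeros((N_grid.size, T_grid.size))
    sem = np.zeros_like(mean)
    for i, n in enumerate(N_grid):
        for j, t in enumerate(T_grid):
            res = simulate_errors(kind, int(n), float(t), repeats, rng=rng, **kwargs)
            mean[i, j] = res.mean_scalar_error
            sem[i, j] = res.sem_scalar_error
    return ErrorSurface(kind, N_grid, T_grid, mean, sem, repeats, seed)


@dataclass
class RegimeMap:
    """Pure/conjunctive error-ratio map with regime labels.

    Regime 1: ratio within ``delta`` of sqrt(D) (both errors CR-saturated);
    regime 2: ratio below sqrt(D) - delta (relative advantage of pure cells);
    regime 3: ratio above sqrt(D) + delta (conjunctive advantage at short T).
    """

    N_grid: np.ndarray
    T_grid: np.ndarray
    ratio: np.ndarray  # (nN, nT) eps_pure / eps_conj
    regime: np.ndarray  # (nN, nT) int in {1, 2, 3}
    delta: float
    D: int
    N_cr: int | None  # largest N with ratio < 1 at T = 10 s


def regime_map(surface_pure: ErrorSurface, surface_conj: ErrorSurface,
               delta: float = 0.02, D: int = 2) -> RegimeMap:
    if not (
        np.array_equal(surface_pure.N_grid, surface_conj.N_grid)
        and np.allclose(surface_pure.T_grid, surface_conj.T_grid)
    ):
        raise ValueError("pure and conjunctive surfaces must share (N, T) grids")
    ratio = surface_pure.mean_scalar_error / surface_conj.mean_scalar_error
    root = np.sqrt(D)
    regime = np.where(
        np.abs(ratio - root) <= delta, 1, np.where(ratio < root - delta, 2, 3)
    )
    N_cr = None
    t_idx = np.argmin(np.abs(surface_pure.T_grid - 10.0))
    if np.isclose(surface_pure.T_grid[t_idx], 10.0, rtol=0.2):
        below = np.flatnonzero(ratio[:, t_idx] < 1.0)
        if below.size:
            N_cr = int(surface_pure.N_grid[below.max()])
    return RegimeMap(
        surface_pure.N_grid, surface_pure.T_grid, ratio, regime, delta, D, N_cr
    )


def n_critical(
    kappa_list,
    D_list,
    N_grid=None,
    T: float = 10.0,
    repeats: int = 100,
    seed: int | None = None,
    **kwargs,
):
    """Critical population size per (kappa, D): the largest simulated N for
    which pure cells outperform conjunctive cells in absolute error at long
    decoding time."""
    if N_grid is None:
        N_grid = np.array([10, 20, 40, 80, 160, 320])
    rng = np.random.default_rng(seed)
    rows = []
    for D in D_list:
        for kappa in kappa_list:
            ncr = int(min(N_grid))
            for n in sorted(int(x) for x in N_grid):
                n_eff = n - n % D
                if n_eff < D:
                    continue
                pure = simulate_errors(
                    "pure", n_eff, T, repeats, D=D, kappa=kappa, rng=rng, **kwargs
                )
                conj = simulate_errors(
                    "conjunctive", n_eff, T, repeats, D=D, kappa=kappa, rng=rng, **kwargs
                )
                if pure.mean_scalar_error < conj.mean_scalar_error:
                    ncr = n_eff
            rows.append({"kappa": kappa, "D": D, "N_cr": ncr})
    import pandas as pd

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2D/1D ratios and error distributions
# ---------------------------------------------------------------------------


def ratio_2d_1d(
    kind: str,
    N: int,
    T_grid,
    repeats: int = 300,
    seed: int | None = None,
    **kwargs,
):
    """Ratio of the mean combined 2D error to the mean per-dimension error,
    per decoding time.  Approaches pi/2 at long T (Gaussian errors); rises
    above it for pure cells at short T (heavy-tailed per-dimension errors)."""
    rng = np.random.default_rng(seed)
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        res = simulate_errors(kind, N, T, repeats, rng=rng, **kwargs)
        mean_2d = res.mean_scalar_error
        mean_1d = float(np.mean(np.abs(res.errors_deg)))
        per_trial_ratio_sem = _ratio_sem(res)
        rows.append(
            {
                "kind": kind,
                "N": N,
                "T": T,
                "mean_error_2d_deg": mean_2d,
                "mean_error_1d_deg": mean_1d,
                "ratio": mean_2d / mean_1d,
                "ratio_sem": per_trial_ratio_sem,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)


def _ratio_sem(res: SimulationResult) -> float:
    """Delta-method standard error of mean2D/mean1D from per-trial samples."""
    a = res.scalar_error_deg
    b = np.abs(res.errors_deg).mean(axis=1)
    n = a.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1) / n, b.var(ddof=1) / n
    cov = np.cov(a, b, ddof=1)[0, 1] / n
    r = ma / mb
    return float(abs(r) * np.sqrt(va / ma**2 + vb / mb**2 - 2 * cov / (ma * mb)))


def error_distribution(
    kind: str, N: int, T: float, repeats: int = 500, seed: int | None = None, **kwargs
):
    """Per-dimension error marginals and excess kurtosis at one (N, T) cell."""
    from scipy import stats

    res = simulate_errors(kind, N, T, repeats, seed=seed, **kwargs)
    errs = res.errors_deg
    return {
        "kind": kind,
        "N": N,
        "T": T,
        "errors_deg": errs,
        "var_per_dim": errs.var(axis=0, ddof=1),
        "excess_kurtosis": stats.kurtosis(errs, axis=0, fisher=True, bias=False),
        "mean_scalar_error": res.mean_scalar_error,
    }


# ---------------------------------------------------------------------------
# Conditional errors
# ---------------------------------------------------------------------------


@dataclass
class ConditionalErrorResult:
    N: int
    T: float
    n_min: np.ndarray
    mean_error_pure: np.ndarray  # conditioned on each sub-population >= n_min
    mean_error_conj: np.ndarray  # conditioned on total >= 2 * n_min
    retention_pure: np.ndarray
    retention_conj: np.ndarray

    @property
    def ratio(self):
        return self.mean_error_pure / self.mean_error_conj


def conditional_error(
    N: int,
    T: float,
    n_min_list=(0, 1, 2, 3, 4),
    repeats: int = 2000,
    D: int = 2,
    seed: int | None = None,
    **kwargs,
) -> ConditionalErrorResult:
    """Mean errors conditioned on minimum spike counts.

    Pure trials are retained when every sub-population emitted at least
    ``n_min`` spikes; conjunctive trials when the population emitted at
    least ``D * n_min`` spikes, which keeps the comparison's mean firing
    rate matched."""
    rng = np.random.default_rng(seed)
    pure = simulate_errors("pure", N, T, repeats, D=D, rng=rng, **kwargs)
    conj = simulate_errors("conjunctive", N, T, repeats, D=D, rng=rng, **kwargs)
    n_min = np.asarray(n_min_list, dtype=int)
    mp, mc, rp, rc = (np.zeros(n_min.size) for _ in range(4))
    pure_sub = pure.subpop_spikes[:, :D]
    conj_tot = conj.subpop_spikes[:, D]
    for k, m in enumerate(n_min):
        keep_p = np.all(pure_sub >= m, axis=1)
        keep_c = conj_tot >= D * m
        mp[k] = pure.scalar_error_deg[keep_p].mean() if keep_p.any() else np.nan
        mc[k] = conj.scalar_error_deg[keep_c].mean() if keep_c.any() else np.nan
        rp[k] = keep_p.mean()
        rc[k] = keep_c.mean()
    return ConditionalErrorResult(N, T, n_min, mp, mc, rp, rc)


# ---------------------------------------------------------------------------
# Mixed populations
# ---------------------------------------------------------------------------


@dataclass
class MixedPopulationResult:
    N: int
    T: float
    pure_fraction: np.ndarray
    error_mix: np.ndarray
    error_pure_sub: np.ndarray
    error_conj_sub: np.ndarray
    error_mix_independent: np.ndarray
    synergy_ratio: np.ndarray  # error_mix / error_mix_independent


def mix_independent_error(eps_pure, eps_conj):
    """Expected mixed-population error if the sub-populations contributed
    independently: ``eps_p * eps_c / sqrt(eps_p^2 + eps_c^2)``."""
    eps_pure = np.asarray(eps_pure, dtype=float)
    eps_conj = np.asarray(eps_conj, dtype=float)
    return eps_pure * eps_conj / np.sqrt(eps_pure**2 + eps_conj**2)


def _subset_population(pop: Population, idx) -> Population:
    return Population(
        preferred=pop.preferred[idx],
        kappa=pop.kappa[idx],
        tuned=pop.tuned[idx],
        peak_rate=pop.peak_rate[idx],
        baseline_rate=pop.baseline_rate[idx],
        kind="mixed",
        D=pop.D,
        normalization=pop.normalization,
    )


def mixed_error(
    pure_fraction_grid,
    N: int,
    T: float,
    repeats: int = 300,
    D: int = 2,
    kappa: float = 9.11,
    R_pure: float = 1.0,
    scheme: str = "equal_population_rate",
    grid: GridSpec | None = None,
    repeats_per_population: int = 1,
    seed: int | None = None,
) -> MixedPopulationResult:
    """Decoding error of mixed pure/conjunctive populations over a fraction
    grid, with the independent-contribution prediction from the errors of
    the two sub-populations decoded alone on the same trials."""
    rng = np.random.default_rng(seed)
    fracs = np.asarray(pure_fraction_grid, dtype=float)
    e_mix = np.zeros(fracs.size)
    e_pure = np.zeros(fracs.size)
    e_conj = np.zeros(fracs.size)
    for k, f in enumerate(fracs):
        mix_err = np.zeros(repeats)
        pure_err = np.full(repeats, np.nan)
        conj_err = np.full(repeats, np.nan)
        done = 0
        while done < repeats:
            batch = min(repeats_per_population, repeats - done)
            pop = build_population(
                N, "mixed", D=D, kappa=kappa, R_pure=R_pure, scheme=scheme,
                pure_fraction=f, rng=rng,
            )
            group = pop.group
            pure_idx = np.flatnonzero(group < D)
            conj_idx = np.flatnonzero(group == D)
            obj_mix = MLObjective(pop, T, grid)
            sub_p = _subset_population(pop, pure_idx) if pure_idx.size else None
            sub_c = _subset_population(pop, conj_idx) if conj_idx.size else None
            obj_p = MLObjective(sub_p, T, grid) if sub_p else None
            obj_c = MLObjective(sub_c, T, grid) if sub_c else None
            for b in range(batch):
                stim = rng.uniform(0.0, TWO_PI, size=D)
                mat = spiking.sample_independent(pop, stim, T, 1, rng=rng)
                t = done + b
                mix_err[t] = ml_decode(mat, pop, objective=obj_mix).scalar_error_deg[0]
                if sub_p is not None:
                    sm = spiking.SpikeCountMatrix(
                        mat.counts[:, pure_idx], stim, T, "independent"
                    )
                    pure_err[t] = ml_decode(sm, sub_p, objective=obj_p).scalar_error_deg[0]
                if sub_c is not None:
                    sm = spiking.SpikeCountMatrix(
                        mat.counts[:, conj_idx], stim, T, "independent"
                    )
                    conj_err[t] = ml_decode(sm, sub_c, objective=obj_c).scalar_error_deg[0]
            done += batch
        e_mix[k] = mix_err.mean()
        e_pure[k] = np.nanmean(pure_err) if np.isfinite(pure_err).any() else np.nan
        e_conj[k] = np.nanmean(conj_err) if np.isfinite(conj_err).any() else np.nan
    with np.errstate(invalid="ignore"):
        e_indep = mix_independent_error(e_pure, e_conj)
        # degenerate mixtures: only one sub-population present
        e_indep = np.where(np.isnan(e_pure), e_conj, e_indep)
        e_indep = np.where(np.isnan(e_conj), e_pure, e_indep)
    return MixedPopulationResult(
        N, T, fracs, e_mix, e_pure, e_conj, e_indep, e_mix / e_indep
    )


# ---------------------------------------------------------------------------
# Error vs Fisher-information collapse
# ---------------------------------------------------------------------------


def error_vs_fi_characterization(
    kind: str = "pure",
    NT_pairs=None,
    repeats: int = 300,
    D: int = 1,
    kappa: float = 9.11,
    R_pure: float = 1.0,
    seed: int | None = None,
    **kwargs,
):
    """Empirical error as a function of Fisher information.

    Simulates the listed (N, T) cells, computes each cell's analytic FI, and
    reports the mean error and its ratio to the Cramér–Rao bound.  Cells with
    equal FI but different (N, T) should collapse onto the same error; the
    maximum relative spread among equal-FI groups quantifies the collapse.
    """
    if NT_pairs is None:
        NT_pairs = [(250, 0.4), (500, 0.2), (1000, 0.1), (250, 4.0), (1000, 1.0)]
    rng = np.random.default_rng(seed)
    rows = []
    for N, T in NT_pairs:
        fs = fisher_summary(N, T, kappa, D=max(D, 2), R_pure=R_pure)
        J = fs.J_pure if kind == "pure" else fs.J_conj
        if D == 1:
            from .fisher import fi_pure

            J = float(fi_pure(N, R_pure, T, kappa, D=1))
        res = simulate_errors(
            kind, N, T, repeats, D=D, kappa=kappa, R_pure=R_pure, rng=rng, **kwargs
        )
        bound = float(cr_bound_scalar(J, D=D))
        saturated = saturated_mean_error(J, D=D)
        rows.append(
            {
                "kind": kind,
                "N": N,
                "T": T,
                "fisher_information": J,
                "mean_error_deg": res.mean_scalar_error,
                "sem_deg": res.sem_scalar_error,
                "cr_bound_deg": bound,
                "saturated_mean_error_deg": saturated,
                "error_over_bound": res.mean_scalar_error / saturated,
            }
        )
    import pandas as pd

    df = pd.DataFrame(rows)
    groups = df.groupby(df["fisher_information"].round(6))["mean_error_deg"]
    spread = (groups.max() - groups.min()) / groups.mean()
    df.attrs["max_equal_fi_spread"] = float(spread.max())
    return df
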