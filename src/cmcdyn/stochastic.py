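"""Stochastic amplitude dynamics on a potential landscape.

The slow amplitude obeys the overdamped SDE ``dI = -U'(I) dt + sigma dB_t``
with a reflecting boundary at I = 0 (the amplitude is non-negative by
construction).  The associated Fokker-Planck equation has the stationary
density ``p_st = Z^{-1} exp(-2 U / sigma^2)``.  The minima of U partition the
amplitude axis into semi-stable states separated by the maxima; the stationary
mass inside a state interval is its occupancy probability, and the mean time
to escape over a barrier is approximated by the overdamped Kramers formula

.. math::

    \\langle t \\rangle = \\frac{2\\pi}{\\sqrt{U''(x_{min})\\,|U''(x_{max})|}}
        \\, e^{2 [U(x_{max}) - U(x_{min})] / \\sigma^2},

validated here against a direct first-passage Monte-Carlo oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .exceptions import (
    DegenerateExtremumError,
    GridMismatchError,
    NoBarrierError,
    StabilityError,
    TailMassError,
)
from .reduction import PotentialProfile

try:  # compiled kernels; a vectorized numpy fallback covers their absence
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _fp_kernel(drift, h, x0, xb, from_left, sigma, dt, n_escapes, seed, max_steps):
    """First-passage times by scalar Euler-Maruyama, reflecting at 0.

    The drift is tabulated on a uniform grid of spacing ``h``; linear
    interpolation in the kernel.  Returns (times, total_steps); unfinished
    walkers hold NaN.
    """
    np.random.seed(seed)
    times = np.full(n_escapes, np.nan)
    total = 0
    sq = sigma * np.sqrt(dt)
    ntab = drift.shape[0]
    for w in range(n_escapes):
        x = x0
        k = 0
        while True:
            k += 1
            total += 1
            if total > max_steps:
                return times, total
            i = int(x / h)
            if i > ntab - 2:
                i = ntab - 2
            d = drift[i] + (x - i * h) * (drift[i + 1] - drift[i]) / h
            x += dt * d + sq * np.random.normal()
            if x < 0.0:
                x = -x
            if (from_left and x >= xb) or ((not from_left) and x <= xb):
                times[w] = k * dt
                break
    return times, total


@njit(cache=False)
def _ensemble_kernel(drift, h, x0, sigma, dt, n_steps, n_walkers, seed, thin):
    """Fixed-horizon ensemble of reflecting paths, recorded every ``thin`` steps."""
    np.random.seed(seed)
    n_rec = n_steps // thin + 1
    out = np.empty((n_rec, n_walkers))
    ntab = drift.shape[0]
    sq = sigma * np.sqrt(dt)
    for w in range(n_walkers):
        x = x0[w]
        out[0, w] = x
        rec = 1
        for k in range(1, n_steps + 1):
            i = int(x / h)
            if i > ntab - 2:
                i = ntab - 2
            d = drift[i] + (x - i * h) * (drift[i + 1] - drift[i]) / h
            x += dt * d + sq * np.random.normal()
            if x < 0.0:
                x = -x
            if k % thin == 0:
                out[rec, w] = x
                rec += 1
    return out

__all__ = [
    "AmplitudeSDEConfig",
    "StationaryDensity",
    "State",
    "StateSet",
    "ExitTimeEstimate",
    "simulate_amplitude_sde",
    "simulate_amplitude_ensemble",
    "stationary_density",
    "define_states",
    "state_probability",
    "kramers_exit_time",
    "exact_mean_exit_time",
    "mc_first_passage",
]


@dataclass(frozen=True)
class AmplitudeSDEConfig:
    """Configuration of the amplitude-level Euler-Maruyama integration."""

    sigma: float
    dt: float
    t_max: float
    boundary: str = "reflect"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.dt <= 0 or self.t_max <= 0:
            raise ValueError("sigma >= 0 and dt, t_max > 0 required")
        if self.boundary != "reflect":
            raise ValueError("only the reflecting boundary at R = 0 is supported")

    def check_stability(self, profile: PotentialProfile) -> None:
        spacing = float(np.min(np.diff(profile.R_grid)))
        gmax = float(np.max(np.abs(profile.drift)))
        if self.dt * gmax >= 0.1 * spacing:
            raise StabilityError(
                f"dt * max|U'| = {self.dt * gmax:.3e} exceeds 0.1 * grid spacing "
                f"= {0.1 * spacing:.3e}; reduce dt"
            )


def _em_path(grid, drift, x0, sigma, dt, n_steps, rng, record=True):
    """Scalar Euler-Maruyama with reflection at 0; drift looked up on the grid."""
    x = float(x0)
    out = np.empty(n_steps + 1) if record else None
    if record:
        out[0] = x
    sq = sigma * np.sqrt(dt)
    # draw in blocks to keep the python loop lean
    block = 65536
    drawn = rng.standard_normal(block)
    ptr = 0
    for k in range(n_steps):
        if ptr == block:
            drawn = rng.standard_normal(block)
            ptr = 0
        x = x + dt * np.interp(x, grid, drift) + sq * drawn[ptr]
        ptr += 1
        if x < 0.0:
            x = -x
        if record:
            out[k + 1] = x
    return out if record else x


def simulate_amplitude_sde(
    profile: PotentialProfile, cfg: AmplitudeSDEConfig, init: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single seed-deterministic Euler-Maruyama path of dI = -U' dt + sigma dB.

    Returns ``(times, path)``.  Reflecting at 0; exiting the grid upper bound
    raises with a suggestion to enlarge the grid.
    """
    if not (0.0 <= init <= profile.R_upper):
        raise ValueError("initial amplitude must lie inside the grid")
    cfg.check_stability(profile)
    n_steps = int(np.ceil(cfg.t_max / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    path = _em_path(
        profile.R_grid, profile.drift, init, cfg.sigma, cfg.dt, n_steps, rng
    )
    if np.max(path) >= profile.R_upper:
        raise RuntimeError(
            "the path reached the grid upper bound; rebuild the potential on a larger grid"
        )
    times = cfg.dt * np.arange(n_steps + 1)
    return times, path


def _uniform_drift_table(profile: PotentialProfile, n: int = 4096):
    """Drift resampled on a uniform grid for the compiled kernels."""
    h = profile.R_upper / (n - 1)
    xs = np.linspace(0.0, profile.R_upper, n)
    return np.interp(xs, profile.R_grid, profile.drift), h


def simulate_amplitude_ensemble(
    profile: PotentialProfile,
    sigma: float,
    dt: float,
    n_steps: int,
    n_walkers: int,
    init,
    seed: int,
    thin: int = 1,
) -> np.ndarray:
    """Ensemble of reflecting Euler-Maruyama paths (seed-deterministic).

    ``init`` may be a scalar or one value per walker.  Returns the recorded
    positions with shape ``(n_steps//thin + 1, n_walkers)``.  Used for
    occupancy statistics and histogram checks.
    """
    x0 = np.broadcast_to(np.asarray(init, dtype=float), (n_walkers,)).copy()
    if _HAVE_NUMBA:
        table, h = _uniform_drift_table(profile)
        return _ensemble_kernel(
            table, h, x0, sigma, dt, n_steps, n_walkers, seed % 2**32, thin
        )
    rng = np.random.default_rng(seed)
    grid, drift = profile.R_grid, profile.drift
    x = x0
    sq = sigma * np.sqrt(dt)
    n_rec = n_steps // thin + 1
    out = np.empty((n_rec, n_walkers))
    out[0] = x
    rec = 1
    for k in range(1, n_steps + 1):
        x = x + dt * np.interp(x, grid, drift) + sq * rng.standard_normal(n_walkers)
        np.abs(x, out=x)
        if k % thin == 0:
            out[rec] = x
            rec += 1
    return out[:rec]


@dataclass
class StationaryDensity:
    """Normalized stationary density of the amplitude SDE on a grid."""

    R_grid: np.ndarray
    p_st: np.ndarray
    Z: float
    sigma: float

    def probability(self, lo: float, hi: float) -> float:
        """Mass of the density on [lo, hi] by quadrature."""
        grid, p = self.R_grid, self.p_st
        lo = max(lo, grid[0])
        hi = min(hi, grid[-1])
        mask = (grid > lo) & (grid < hi)
        xs = np.concatenate([[lo], grid[mask], [hi]])
        ps = np.concatenate([[np.interp(lo, grid, p)], p[mask], [np.interp(hi, grid, p)]])
        return float(simpson(ps, x=xs))


def stationary_density(profile: PotentialProfile, sigma: float) -> StationaryDensity:
    """Stationary Fokker-Planck density ``p_st = Z^{-1} exp(-2U/sigma^2)``.

    Fails if the density carries non-negligible mass at the grid upper bound
    (the landscape must confine the dynamics inside the tabulated range).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not np.all(np.isfinite(profile.U)):
        raise ValueError("U must be finite on the grid")
    logp = -2.0 * profile.U / sigma**2
    logp -= logp.max()
    unnorm = np.exp(logp)
    if unnorm[-1] > 1e-10:
        raise TailMassError(
            "stationary density is not negligible at the grid upper bound; "
            "rebuild the potential with a larger R_upper"
        )
    # Z in the same units as the un-shifted density exp(-2U/sigma^2)
    Z_shift = simpson(unnorm, x=profile.R_grid)
    p = unnorm / Z_shift
    Z = float(Z_shift * np.exp((-2.0 * profile.U / sigma**2).max()))
    return StationaryDensity(profile.R_grid, p, Z, sigma)


@dataclass(frozen=True)
class State:
    """A basin of attraction: an interval of the amplitude axis with its minimum."""

    index: int
    lower: float
    upper: float
    minimum: float
    curvature: float


@dataclass
class StateSet:
    """Ordered partition of [0, R_upper) into basins separated by maxima of U."""

    states: list
    R_upper: float

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i) -> State:
        return self.states[i]


def define_states(profile: PotentialProfile) -> StateSet:
    """One state per non-degenerate minimum, bounded by the interior maxima."""
    minima = sorted(profile.minima, key=lambda e: e.location)
    if not minima:
        raise ValueError("profile has no minima")
    for e in minima + profile.maxima:
        if e.degenerate:
            raise DegenerateExtremumError(
                f"extremum at R = {e.location} is degenerate (U'' ~ 0)"
            )
    boundaries = sorted(
        e.location for e in profile.maxima if 0.0 < e.location < profile.R_upper
    )
    edges = [0.0] + boundaries + [profile.R_upper]
    states = []
    for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
        inside = [m for m in minima if lo <= m.location < hi or (lo == 0.0 and m.location == 0.0)]
        if len(inside) != 1:
            raise ValueError(
                f"state [{lo}, {hi}) contains {len(inside)} minima; "
                "the landscape does not partition cleanly"
            )
        states.append(State(k, lo, hi, inside[0].location, inside[0].curvature))
    return StateSet(states, profile.R_upper)


def state_probability(density: StationaryDensity, states: StateSet) -> np.ndarray:
    """Occupancy probability of each state: quadrature of p_st over its interval."""
    probs = np.array([density.probability(s.lower, s.upper) for s in states.states])
    if abs(probs.sum() - 1.0) > 1e-6:
        raise GridMismatchError(
            "state probabilities do not sum to 1; density and states use different grids"
        )
    return probs / probs.sum()


@dataclass
class ExitTimeEstimate:
    state_index: int
    sigma: float
    mean_exit_time: float
    method: str  # "kramers" | "monte_carlo"
    barrier_height: float
    standard_error: float | None = None
    barrier_location: float | None = None
    samples: np.ndarray | None = field(default=None, repr=False)


def _escape_barrier(profile: PotentialProfile, states: StateSet, state_id: int):
    """The barrier the state escapes over: its bounding interior maximum.

    If both interval edges are interior maxima the lower barrier dominates the
    escape rate and is used.
    """
    s = states[state_id]
    candidates = []
    for e in profile.maxima:
        if abs(e.location - s.lower) < 1e-9 and s.lower > 0.0:
            candidates.append(e)
        if abs(e.location - s.upper) < 1e-9 and s.upper < profile.R_upper:
            candidates.append(e)
    if not candidates:
        raise NoBarrierError(
            f"state {state_id} has no adjacent interior maximum to escape over"
        )
    Umin = profile.U_of(s.minimum)
    best = min(candidates, key=lambda e: profile.U_of(e.location) - Umin)
    return s, best


def kramers_exit_time(
    profile: PotentialProfile, states: StateSet, state_id: int, sigma: float
) -> ExitTimeEstimate:
    """Kramers-approximate mean first-passage time to the state's barrier top.

    ``<t> = pi / sqrt(U''(x_min) |U''(x_max)|) * exp(2 dU / sigma^2)`` with
    diffusion D = sigma^2/2.  This is the absorbing-at-barrier convention:
    walkers are counted as exited on first *reaching* the barrier top, which
    is half the classic over-the-barrier escape time (from the top, re-entry
    and escape are equally likely).  A well whose minimum sits at the
    reflecting origin holds only half the harmonic well mass, so its
    prefactor is halved again.  Both factors are fixed by the first-passage
    Monte-Carlo oracle and by the exact mean-exit-time quadrature
    (:func:`exact_mean_exit_time`).  A warning is issued when
    ``2 dU/sigma^2 < 3`` (outside the asymptotic regime).
    """
    s, barrier = _escape_barrier(profile, states, state_id)
    if s.curvature <= 0:
        raise DegenerateExtremumError("state minimum has non-positive curvature")
    if barrier.curvature >= 0:
        raise DegenerateExtremumError("barrier has non-negative curvature")
    dU = float(profile.U_of(barrier.location) - profile.U_of(s.minimum))
    expo = 2.0 * dU / sigma**2
    if expo < 3.0:
        warnings.warn(
            f"2*dU/sigma^2 = {expo:.2f} < 3: Kramers asymptotics are unreliable here"
        )
    prefactor = np.pi / np.sqrt(s.curvature * abs(barrier.curvature))
    if s.minimum == 0.0:
        prefactor *= 0.5  # half-well at the reflecting origin
    return ExitTimeEstimate(
        state_index=state_id,
        sigma=sigma,
        mean_exit_time=float(prefactor * np.exp(expo)),
        method="kramers",
        barrier_height=dU,
        barrier_location=barrier.location,
    )


def exact_mean_exit_time(
    profile: PotentialProfile, states: StateSet, state_id: int, sigma: float
) -> ExitTimeEstimate:
    """Exact mean first-passage time to the barrier top, by double quadrature.

    For exit rightward from ``x0`` with reflection at 0,

    ``t = (2/sigma^2) int_{x0}^{b} e^{2U(y)/sigma^2}
          int_0^y e^{-2U(z)/sigma^2} dz dy``;

    leftward exits mirror the inner integral toward the upper grid bound.
    Deterministic; the sharp reference against which both the Kramers
    approximation and the Monte-Carlo oracle can be checked.
    """
    from scipy.integrate import cumulative_simpson

    s, barrier = _escape_barrier(profile, states, state_id)
    R, U = profile.R_grid, profile.U
    s2 = sigma**2
    x0, xb = s.minimum, barrier.location
    if xb > x0:
        inner = cumulative_simpson(np.exp(-2 * U / s2), x=R, initial=0.0)
        mask = (R >= x0) & (R <= xb)
    else:
        inner = cumulative_simpson(
            np.exp(-2 * U / s2)[::-1], x=-R[::-1], initial=0.0
        )[::-1]
        mask = (R >= xb) & (R <= x0)
    integrand = np.exp(2 * U / s2) * inner
    t = 2.0 / s2 * np.trapezoid(integrand[mask], R[mask])
    return ExitTimeEstimate(
        state_index=state_id,
        sigma=sigma,
        mean_exit_time=float(t),
        method="exact_quadrature",
        barrier_height=float(profile.U_of(xb) - profile.U_of(x0)),
        barrier_location=xb,
    )


def mc_first_passage(
    profile: PotentialProfile,
    states: StateSet,
    state_id: int,
    sigma: float,
    n_escapes: int = 2000,
    seed: int = 0,
    dt: float | None = None,
    max_total_steps: int = 100_000_000,
) -> ExitTimeEstimate:
    """First-passage Monte-Carlo oracle for the mean exit time.

    Walkers start at the state's minimum and are absorbed at the barrier top
    (the same absorbing-at-barrier convention as the Kramers derivation);
    returns the sample mean with its standard error.  Seed-deterministic.
    """
    if n_escapes < 100:
        raise ValueError("need at least 100 escapes")
    s, barrier = _escape_barrier(profile, states, state_id)
    if dt is None:
        curv = max(s.curvature, abs(barrier.curvature))
        dt = 0.01 / curv
    xb = barrier.location
    from_left = s.minimum < xb
    if _HAVE_NUMBA:
        table, h = _uniform_drift_table(profile)
        times, total = _fp_kernel(
            table, h, s.minimum, xb, from_left, sigma, dt, n_escapes,
            seed % 2**32, max_total_steps,
        )
        if np.any(np.isnan(times)):
            done = int(np.sum(~np.isnan(times)))
            raise RuntimeError(
                f"step cap reached with {done}/{n_escapes} escapes observed"
            )
    else:
        rng = np.random.default_rng(seed)
        grid, drift = profile.R_grid, profile.drift
        x = np.full(n_escapes, s.minimum)
        alive = np.arange(n_escapes)
        times = np.empty(n_escapes)
        sq = sigma * np.sqrt(dt)
        steps_done = 0
        k = 0
        while alive.size:
            k += 1
            steps_done += alive.size
            if steps_done > max_total_steps:
                done = n_escapes - alive.size
                raise RuntimeError(
                    f"step cap reached with {done}/{n_escapes} escapes observed"
                )
            x = x + dt * np.interp(x, grid, drift) + sq * rng.standard_normal(x.size)
            np.abs(x, out=x)
            crossed = (x >= xb) if from_left else (x <= xb)
            if np.any(crossed):
                times[alive[crossed]] = k * dt
                keep = ~crossed
                x = x[keep]
                alive = alive[keep]
    mean = float(np.mean(times))
    se = float(np.std(times, ddof=1) / np.sqrt(n_escapes))
    return ExitTimeEstimate(
        state_index=state_id,
        sigma=sigma,
        mean_exit_time=mean,
        method="monte_carlo",
        barrier_height=float(profile.U_of(xb) - profile.U_of(s.minimum)),
        standard_error=se,
        barrier_location=xb,
        samples=times,
    )
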