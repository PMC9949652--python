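"""Adiabatic reduction of the CMC model to slow amplitude dynamics.

The fast oscillations are averaged over one period ``T`` of the unperturbed
torus flow (the least common period of the four bands).  To first order in the
current-coupling scale ``mu`` the amplitude of population *i* drifts as

.. math::

    \\frac{dR_i}{dt} = \\mu\\,\\omega_i g_{ii}
        \\sum_{r\\ge 1} B_r \\frac{R_i^{2r-1}}{2^{2r-1}} \\binom{2r-1}{r-1},

where ``B_r`` are the odd-power Taylor coefficients of the current coupling
``P``.  Only the self connections ``g_ii`` survive the averaging at first
order; potential couplings (``S``) and off-diagonal current couplings average
out.  Aggregating over populations by averaging over the constant-amplitude
surfaces ``sum a_i^2 R_i^2 = n R_s^2`` yields a one-dimensional gradient flow
``dR_s/dt = -U'(R_s)`` on a potential ``U`` whose minima are the semi-stable
oscillatory states of the column.

Two independent routes to the drift are provided: the truncated closed-form
series above (fast, limited to its convergence radius) and direct numerical
averaging (orbit averaging of the full flow; quadrature/Monte-Carlo surface
averages), which remains valid at all amplitudes and is used to validate the
series constants.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.integrate import cumulative_simpson
from scipy.optimize import brentq

from .exceptions import ConvergenceRadiusError, DegenerateExtremumError
from .model import FullState, simulate_ode
from .params import CMCParameters, CouplingFunction

__all__ = [
    "AveragingConfig",
    "DriftModel",
    "Extremum",
    "PotentialProfile",
    "fast_period",
    "taylor_coefficients",
    "population_drift_series",
    "population_drift_exact",
    "orbit_average_drift",
    "total_drift",
    "total_drift_exact",
    "mc_spherical_average",
    "build_potential",
]

_MAX_CYCLES = 200  # cap for the averaging window with incommensurate bands


@dataclass(frozen=True)
class AveragingConfig:
    """Averaging period for the fast torus flow."""

    T: float
    n_subdivisions: int = 64
    commensurate: bool = True
    tol: float = 1e-9

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.n_subdivisions < 64:
            raise ValueError("need at least 64 subdivisions per cycle")


@dataclass(frozen=True)
class DriftModel:
    """Truncated odd-power drift series with its convergence bookkeeping.

    ``coefficients[r-1]`` holds ``B_r``, the coefficient of ``x**(2r-1)`` in
    the Taylor expansion of the current coupling ``P``.
    """

    coefficients: np.ndarray
    r_max: int
    tolerance: float = 1e-8

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.size != self.r_max:
            raise ValueError("need exactly r_max coefficients")
        object.__setattr__(self, "coefficients", c)

    def series_terms(self, R: float) -> np.ndarray:
        r = np.arange(1, self.r_max + 1)
        comb = np.array([math.comb(2 * k - 1, k - 1) for k in r], dtype=float)
        return self.coefficients * comb * R ** (2 * r - 1) / 2.0 ** (2 * r - 1)

    def check_convergence(self, R: float) -> bool:
        """Last-term test: the truncated tail must be negligible at R."""
        terms = self.series_terms(abs(R))
        total = np.sum(terms)
        if total == 0.0:
            return bool(abs(terms[-1]) < self.tolerance)
        return bool(abs(terms[-1]) / max(abs(total), 1e-300) < self.tolerance)

    def convergence_radius(self) -> float:
        """Largest R (coarse scan) at which the last-term test passes."""
        lo = 0.0
        for R in np.linspace(0.05, 50, 1000):
            if not self.check_convergence(R):
                break
            lo = R
        return lo


def fast_period(omegas, tol: float = 1e-9) -> AveragingConfig:
    """Least common period of the bands: smallest T with every omega_i*T = 2*pi*k.

    If the frequency ratios are rational within ``tol`` the period is exact and
    ``commensurate`` is set; otherwise the best window no longer than
    200 cycles of the slowest band is returned, flagged approximate.
    """
    w = np.asarray(omegas, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all omegas must be positive")
    wmin = w.min()
    ratios = w / wmin
    fracs = [Fraction(r).limit_denominator(_MAX_CYCLES) for r in ratios]
    L = math.lcm(*(f.denominator for f in fracs))
    nums = [int(f * L) for f in fracs]
    g = math.gcd(*nums)
    s = Fraction(L, g)
    if s <= _MAX_CYCLES:
        T = 2 * np.pi * float(s) / wmin
        phases = w * T / (2 * np.pi)
        if np.max(np.abs(phases - np.round(phases))) < tol:
            return AveragingConfig(T=T, commensurate=True, tol=tol)
    # incommensurate: scan candidate windows (multiples of the slowest cycle)
    base = 2 * np.pi / wmin
    best_k, best_res = 1, np.inf
    for k in range(1, _MAX_CYCLES + 1):
        phases = w * k * base / (2 * np.pi)
        res = np.max(np.abs(phases - np.round(phases)))
        if res < best_res:
            best_k, best_res = k, res
            if res < tol:
                break
    return AveragingConfig(T=best_k * base, commensurate=bool(best_res < tol), tol=tol)


def _tanh_taylor(r_max: int) -> np.ndarray:
    """Odd-power Maclaurin coefficients of tanh via Bernoulli numbers."""
    import sympy

    out = np.empty(r_max)
    for m in range(1, r_max + 1):
        b = sympy.bernoulli(2 * m)
        c = sympy.Rational(2**(2 * m) * (2**(2 * m) - 1), math.factorial(2 * m)) * b
        out[m - 1] = float(c)
    return out


def taylor_coefficients(coupling: CouplingFunction, r_max: int) -> DriftModel:
    """Odd-power Taylor coefficients B_r of a coupling, f(x) = sum B_r x^(2r-1).

    Computed symbolically for the known sigmoid forms.  Non-odd couplings are
    rejected since the whole drift-series structure assumes odd symmetry.
    """
    xs = np.linspace(0.1, 2.0, 7)
    if np.max(np.abs(coupling(xs) + coupling(-xs))) > 1e-10:
        raise ValueError("coupling is not odd; the drift series requires f(-x) = -f(x)")
    r = np.arange(1, r_max + 1)
    if coupling.kind == "linear":
        coeffs = np.zeros(r_max)
        coeffs[0] = coupling.gain
    elif coupling.kind == "tanh":
        base = _tanh_taylor(r_max)
        coeffs = coupling.gain * coupling.slope ** (2 * r - 1) * base
    elif coupling.kind == "tanh_sum":
        base = _tanh_taylor(r_max)
        coeffs = np.zeros(r_max)
        for w_k, s_k in coupling.components:
            coeffs += w_k * s_k ** (2.0 * r - 1) * base
    else:  # pragma: no cover - params validates kinds
        raise ValueError(f"unsupported coupling kind {coupling.kind}")
    return DriftModel(coeffs, r_max)


def population_drift_series(
    R_i: float, i: int, params: CMCParameters, drift: DriftModel
) -> float:
    """First-order amplitude drift of population *i* from the truncated series.

    Depends only on the self connection ``g_ii``, the current-coupling scale
    ``mu``, the band frequency and the P-coupling coefficients.
    """
    if R_i < 0:
        raise ValueError("amplitude must be non-negative")
    g_ii = params.G[i, i]
    if g_ii == 0.0 or params.mu == 0.0 or R_i == 0.0:
        return 0.0
    if not drift.check_convergence(R_i):
        raise ConvergenceRadiusError(
            f"R = {R_i} is outside the convergence radius of the truncated series; "
            "use orbit_average_drift or the exact quadrature drift instead"
        )
    return float(params.mu * params.omegas[i] * g_ii * np.sum(drift.series_terms(R_i)))


_GL_NODES, _GL_WEIGHTS = leggauss(96)


def _angular_average(P, rho):
    """<P(rho sin t) sin t> over one cycle, by Gauss-Legendre on [0, pi/2]."""
    t = (_GL_NODES + 1) * (np.pi / 4)
    w = _GL_WEIGHTS * (np.pi / 4)
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    st = np.sin(t)
    vals = P(rho[..., None] * st) * st
    return (2 / np.pi) * vals @ w


def population_drift_exact(R_i, i: int, params: CMCParameters):
    """First-order amplitude drift by direct angular quadrature.

    Evaluates ``mu * omega_i * g_ii * <P(R sin t) sin t>`` exactly (to
    quadrature precision); valid at every amplitude, unlike the truncated
    series.  Accepts scalar or array R_i.
    """
    out = params.mu * params.omegas[i] * params.G[i, i] * _angular_average(params.P, R_i)
    return float(out[0]) if np.isscalar(R_i) else out


def orbit_average_drift(
    R: np.ndarray, params: CMCParameters, cfg: AveragingConfig, tol: float = 1e-12
) -> np.ndarray:
    """Amplitude drift averaged along the true flow over one torus period.

    Integrates the full equations of motion from the phase origin of the torus
    (all phase deviations zero) for one period ``T`` and returns
    ``(|z_i(T)| - |z_i(0)|) / T``.  This is the normative numerical definition
    of the slow drift; it agrees with the first-order series up to O(mu^2),
    O(epsilon^2) corrections.
    """
    R = np.asarray(R, dtype=float)
    init = FullState(R.copy(), np.zeros_like(R))
    traj = simulate_ode(
        params, init, (0.0, cfg.T), tol=tol, atol=tol * 1e-2,
        t_eval=np.array([0.0, cfg.T]),
    )
    mods = traj.moduli(params)
    return (mods[-1] - mods[0]) / cfg.T


def _sector_moment(r: int, d: int) -> float:
    """E[v_1^(2r)] for v uniform on the unit sphere in R^d: (2r-1)!!/prod(d+2k-2)."""
    num = 1.0
    for k in range(1, r + 1):
        num *= (2 * k - 1) / (d + 2 * k - 2)
    return num


def _active(params: CMCParameters):
    a = params.leadfield
    return np.flatnonzero(a > 1e-12)


def total_drift(R_s: float, params: CMCParameters, drift: DriftModel) -> float:
    """Closed-form surface-averaged drift of the aggregate amplitude.

    Averages ``R_s dR_s/dt = (1/n) sum a_i^2 R_i dR_i/dt`` over the
    constant-amplitude surface ``sum a_i^2 R_i^2 = n R_s^2`` (uniform in the
    coordinates ``u_i = a_i R_i``), giving per term

    ``mu * omega_i * g_ii * B_r * C(2r-1, r-1) * (2r-1)!!/(2r+2)!! * a_i^(2-2r)
    * n^(r-1) * m_r(d) ... * R_s^(2r-1)``

    with sector moments ``m_r(d)`` for the ``d`` observed populations.  For
    equal lead-field weights and n = 4 this reproduces the printed constants of
    the spherical-average drift; the Monte-Carlo sector average
    (:func:`mc_spherical_average`) is the normative cross-check.
    """
    if R_s < 0:
        raise ValueError("amplitude must be non-negative")
    if R_s == 0.0:
        return 0.0
    n = params.n_populations
    act = _active(params)
    d = act.size
    a = params.leadfield
    r = np.arange(1, drift.r_max + 1)
    comb = np.array([math.comb(2 * k - 1, k - 1) for k in r], dtype=float)
    moments = np.array([_sector_moment(int(k), d) for k in r])
    total = 0.0
    for i in act:
        if params.G[i, i] == 0.0:
            continue
        rho_max = np.sqrt(n) * R_s / a[i]  # largest series argument on the surface
        if not drift.check_convergence(rho_max):
            raise ConvergenceRadiusError(
                f"surface radius {rho_max:.3g} for population {i + 1} exceeds the "
                "series convergence radius; use total_drift_exact instead"
            )
        terms = (
            drift.coefficients
            * comb
            * 2.0 ** (1 - 2 * r)
            * a[i] ** (2.0 - 2 * r)
            * float(n) ** (r - 1)
            * moments
            * R_s ** (2 * r - 1)
        )
        total += params.mu * params.omegas[i] * params.G[i, i] * np.sum(terms)
    return float(total)


def _sector_directions(d: int, n_directions: int, seed: int) -> np.ndarray:
    """Directions uniform on the positive sector of the unit sphere in R^d."""
    rng = np.random.default_rng(seed)
    g = np.abs(rng.standard_normal((n_directions, d)))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def total_drift_exact(
    R_s,
    params: CMCParameters,
    directions: np.ndarray | None = None,
    n_directions: int = 4096,
    seed: int = 0,
):
    """Surface-averaged drift using the exact angular-quadrature population drift.

    With a single observed population the surface degenerates to a point and
    the value is exact and deterministic; with several, the sector average uses
    a fixed set of common random directions so the resulting drift curve is a
    smooth deterministic function of ``R_s``.  Accepts scalar or array input.
    """
    scalar = np.isscalar(R_s)
    R_arr = np.atleast_1d(np.asarray(R_s, dtype=float))
    n = params.n_populations
    a = params.leadfield
    act = _active(params)
    d = act.size
    if d == 1:
        # the surface is the single point u = sqrt(n) R_s, so the average is
        # exact: (1/(n R_s)) a_i u f(u/a_i) = mu w_i g_ii (a_i/sqrt(n)) H(rho)
        i = int(act[0])
        rho = np.sqrt(n) * R_arr / a[i]
        out = params.mu * params.omegas[i] * params.G[i, i] * (
            a[i] / np.sqrt(n)
        ) * _angular_average(params.P, rho)
    else:
        if directions is None:
            directions = _sector_directions(d, n_directions, seed)
        out = np.zeros_like(R_arr)
        for m, Rv in enumerate(R_arr):
            if Rv == 0.0:
                continue
            u = np.sqrt(n) * Rv * directions  # (n_dir, d)
            acc = 0.0
            for col, i in enumerate(act):
                rho = u[:, col] / a[i]
                f = params.mu * params.omegas[i] * params.G[i, i] * _angular_average(
                    params.P, rho
                )
                acc += np.mean(a[i] * u[:, col] * f)
            out[m] = acc / (n * Rv)
    return float(out[0]) if scalar else out


def mc_spherical_average(
    R_s: float,
    params: CMCParameters,
    drift: DriftModel,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo sector average of the series drift: estimate and standard error.

    Samples points uniformly on the positive sector of the constant-amplitude
    surface (in the coordinates ``u_i = a_i R_i``) and averages the projected
    per-population series drift ``(1/(n R_s)) sum a_i u_i f_i(u_i / a_i)``.
    This is the oracle that fixes the constants of :func:`total_drift`.
    """
    if n_samples < 10_000:
        raise ValueError("need at least 1e4 samples")
    if R_s == 0.0:
        return 0.0, 0.0
    n = params.n_populations
    a = params.leadfield
    act = _active(params)
    d = act.size
    v = _sector_directions(d, n_samples, seed)
    u = np.sqrt(n) * R_s * v
    r = np.arange(1, drift.r_max + 1)
    comb = np.array([math.comb(2 * k - 1, k - 1) for k in r], dtype=float)
    series_c = drift.coefficients * comb / 2.0 ** (2 * r - 1)
    samples = np.zeros(n_samples)
    chunk = 100_000  # keep the power matrix small
    for col, i in enumerate(act):
        if params.G[i, i] == 0.0:
            continue
        rho = u[:, col] / a[i]
        rho_max = float(rho.max())
        if not drift.check_convergence(rho_max):
            raise ConvergenceRadiusError(
                f"sample radius {rho_max:.3g} exceeds the series convergence radius"
            )
        scale = params.mu * params.omegas[i] * params.G[i, i] * a[i]
        for lo in range(0, n_samples, chunk):
            sl = slice(lo, min(lo + chunk, n_samples))
            powers = rho[sl, None] ** (2 * r - 1)
            samples[sl] += scale * u[sl, col] * (powers @ series_c)
    samples /= n * R_s
    est = float(np.mean(samples))
    se = float(np.std(samples, ddof=1) / np.sqrt(n_samples))
    return est, se


@dataclass(frozen=True)
class Extremum:
    location: float
    curvature: float  # U'' at the extremum
    degenerate: bool = False


@dataclass
class PotentialProfile:
    """Tabulated potential U(R) with located extrema.

    ``U(0) = 0`` by normalization; ``drift`` holds ``-U'`` on the same grid.
    All downstream stochastic analysis (stationary density, basins, exit
    times) runs on this object.
    """

    R_grid: np.ndarray
    U: np.ndarray
    drift: np.ndarray
    minima: list = field(default_factory=list)
    maxima: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.R_grid = np.asarray(self.R_grid, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        if self.R_grid[0] != 0.0:
            raise ValueError("the amplitude grid must start at 0")
        if np.any(np.diff(self.R_grid) <= 0):
            raise ValueError("the amplitude grid must be strictly increasing")
        if abs(self.U[0]) > 1e-12:
            raise ValueError("U must be normalized to U(0) = 0")

    # -- interpolators ----------------------------------------------------
    def U_of(self, R):
        return np.interp(R, self.R_grid, self.U)

    def dU(self, R):
        """U'(R) = -drift(R), linear interpolation on the grid."""
        return -np.interp(R, self.R_grid, self.drift)

    @property
    def R_upper(self) -> float:
        return float(self.R_grid[-1])

    def plot(self, ax=None, annotate=True):
        """Draw the landscape with its extrema marked."""
        from .plotting import plot_potential

        return plot_potential(self, ax=ax, annotate=annotate)

    # -- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"R": self.R_grid, "U": self.U, "drift": self.drift}).to_csv(
            path, index=False
        )
        sidecar = {
            "minima": [
                {"location": e.location, "curvature": e.curvature, "degenerate": e.degenerate}
                for e in self.minima
            ],
            "maxima": [
                {"location": e.location, "curvature": e.curvature, "degenerate": e.degenerate}
                for e in self.maxima
            ],
            "provenance": self.provenance,
        }
        path.with_suffix(".extrema.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "PotentialProfile":
        path = Path(path)
        df = pd.read_csv(path)
        side = json.loads(path.with_suffix(".extrema.json").read_text())
        mk = lambda d: Extremum(d["location"], d["curvature"], d["degenerate"])
        return cls(
            df["R"].to_numpy(),
            df["U"].to_numpy(),
            df["drift"].to_numpy(),
            minima=[mk(d) for d in side["minima"]],
            maxima=[mk(d) for d in side["maxima"]],
            provenance=side.get("provenance", {}),
        )


def _locate_extrema(F, R_grid, Fvals):
    """Classify zeros of the drift F = -U' into minima and maxima of U."""
    minima, maxima = [], []
    span = R_grid[-1]
    h = 1e-5 * span

    def curvature(x):
        # U'' = -F'; one-sided at the origin using oddness of the drift
        if x < h:
            return -(F(x + h) - F(max(x - h, 0.0))) / (h + min(x, h))
        return -(F(x + h) - F(x - h)) / (2 * h)

    # origin: always a stationary point of the drift
    c0 = -(F(h) - 0.0) / h
    deg0 = abs(c0) < 1e-10
    if c0 > 0 or deg0:
        minima.append(Extremum(0.0, float(c0), bool(deg0)))
    else:
        maxima.append(Extremum(0.0, float(c0), False))
    # interior sign changes
    sgn = np.sign(Fvals)
    for k in range(1, len(R_grid) - 1):
        if sgn[k] == 0 or sgn[k] * sgn[k + 1] >= 0:
            continue
        x = brentq(F, R_grid[k], R_grid[k + 1], xtol=1e-10)
        c = curvature(x)
        deg = abs(c) < 1e-10
        if sgn[k] > 0:  # drift + -> -: U minimum
            minima.append(Extremum(float(x), float(c), bool(deg)))
        else:
            maxima.append(Extremum(float(x), float(c), bool(deg)))
    return minima, maxima


def build_potential(
    params: CMCParameters,
    R_grid: np.ndarray,
    method: str = "oracle",
    r_max: int = 30,
    n_directions: int = 4096,
    seed: int = 0,
) -> PotentialProfile:
    """Construct U(R) = -integral of the surface-averaged drift.

    ``method="oracle"`` uses the exact quadrature drift (valid at all R);
    ``method="series"`` uses the truncated closed-form series and fails with
    :class:`ConvergenceRadiusError` if the grid extends beyond its radius.
    Extrema are located by sign changes of the drift refined with a root
    finder, and curvatures by centred differences of the drift.
    """
    R_grid = np.asarray(R_grid, dtype=float)
    if R_grid.size < 500:
        raise ValueError("use at least 500 grid points to resolve the potential")
    if R_grid[0] != 0.0:
        raise ValueError("the grid must start at R = 0")
    if method == "oracle":
        act = _active(params)
        dirs = (
            None
            if act.size == 1
            else _sector_directions(act.size, n_directions, seed)
        )
        F_vec = lambda R: total_drift_exact(R, params, directions=dirs)
        F_scalar = lambda x: float(total_drift_exact(np.array([x]), params, directions=dirs)[0])
    elif method == "series":
        dm = taylor_coefficients(params.P, r_max)
        F_scalar = lambda x: total_drift(float(x), params, dm)
        F_vec = lambda R: np.array([F_scalar(x) for x in R])
    else:
        raise ValueError("method must be 'oracle' or 'series'")
    Fvals = F_vec(R_grid)
    if not np.all(np.isfinite(Fvals)):
        bad = R_grid[~np.isfinite(Fvals)][0]
        raise RuntimeError(f"drift evaluation failed at R = {bad}")
    U = -cumulative_simpson(Fvals, x=R_grid, initial=0.0)
    minima, maxima = _locate_extrema(F_scalar, R_grid, Fvals)
    # alternation sanity: between consecutive minima there is exactly one maximum
    locs = sorted(
        [(e.location, "min") for e in minima] + [(e.location, "max") for e in maxima]
    )
    kinds = [k for _, k in locs]
    for a_k, b_k in zip(kinds, kinds[1:]):
        if a_k == b_k:
            warnings.warn("extrema of U do not alternate; check grid resolution")
    return PotentialProfile(
        R_grid,
        U,
        Fvals,
        minima=minima,
        maxima=maxima,
        provenance={"method": method, "params": params.to_dict(), "seed": seed},
    )
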