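"""Reference parameter sets with verified qualitative structure.

The figure-generating connectivity matrices of the original study came from
software priors and are not printed anywhere, so this module provides
explicit, version-controlled parameter sets whose potential landscapes have a
declared number of semi-stable states (mono-, bi- and tri-stable), plus
generators for a synthetic exit-time dataset and a bursting EEG trace.
Generation *verifies* the declared structure and fails loudly if the built
potential does not match.

The multistable sets observe a single population (lead field concentrated on
the superficial pyramidal population) whose self connection carries the
dynamics; the current coupling ``P`` is a signed sum of tanh components
(parallel excitatory/inhibitory subpopulation gains with different
sensitivities) whose weights were fitted once, by least squares on the
orbit-averaged drift, to target landscapes with the declared minima, and are
frozen here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CMCParameters, CouplingFunction, save_config
from .reduction import build_potential
from .stochastic import (
    AmplitudeSDEConfig,
    define_states,
    kramers_exit_time,
    simulate_amplitude_sde,
)

__all__ = [
    "FixtureSpec",
    "monostable_parameters",
    "bistable_parameters",
    "tristable_parameters",
    "default_grid",
    "count_transitions",
    "make_exit_time_dataset",
    "make_bursting_trace",
    "generate_fixtures",
]

_OMEGAS = (2 * np.pi, 4 * np.pi, 6 * np.pi, 8 * np.pi)

# frozen tanh-sum weights (weight, slope) for the current coupling P
_BISTABLE_P = (
    (0.192510, 6.0),
    (-3.217437, 2.4),
    (7.659346, 1.2),
    (-8.826711, 0.55),
    (6.189099, 0.25),
    (-3.170102, 0.1),
)
# minima of U near R = 0 and R = 1.69, barrier near R = 0.80; the drift stays
# negative beyond the outer well (checked to R = 14), so the landscape
# confines the dynamics at every noise level used here

_TRISTABLE_P = (
    (1.216789, 10.0),
    (-8.621261, 5.0),
    (26.511787, 2.5),
    (-62.682768, 1.25),
    (164.038231, 0.6),
    (-343.373691, 0.3),
    (309.343848, 0.15),
)
# minima of U near R = 0, 0.73 and 2.02; barriers near 0.33 and 1.36.  The
# slowest components saturate far outside the working range, so this landscape
# is only confining up to R ~ 4; use it for state structure, not for
# large-noise stationary statistics


def _single_population_params(P, mu, sigma, g11=1.0, epsilon=0.05):
    G = np.zeros((4, 4))
    G[0, 0] = g11
    return CMCParameters(
        omegas=np.array(_OMEGAS),
        G=G,
        epsilon=epsilon,
        mu=mu,
        S=CouplingFunction("tanh", gain=1.0, slope=1.0),
        P=P,
        leadfield=np.array([2.0, 0.0, 0.0, 0.0]),
        sigma=sigma,
    )


def monostable_parameters(mu: float = 0.05, sigma: float = 0.25) -> CMCParameters:
    """Inhibitory self connection, plain tanh coupling: single minimum at 0."""
    return _single_population_params(
        CouplingFunction("tanh", gain=1.0, slope=1.0), mu, sigma, g11=-1.0
    )


def bistable_parameters(mu: float = 0.05, sigma: float = 0.25) -> CMCParameters:
    """Semi-stable suppression (R = 0) and high-amplitude oscillation (R ~ 1.75)."""
    return _single_population_params(
        CouplingFunction("tanh_sum", components=_BISTABLE_P), mu, sigma
    )


def tristable_parameters(mu: float = 0.05, sigma: float = 0.25) -> CMCParameters:
    """Three oscillatory states: R = 0, R ~ 0.73 and R ~ 2.0."""
    return _single_population_params(
        CouplingFunction("tanh_sum", components=_TRISTABLE_P), mu, sigma
    )


def default_grid(R_upper: float = 3.5, n: int = 1400) -> np.ndarray:
    return np.linspace(0.0, R_upper, n)


@dataclass(frozen=True)
class FixtureSpec:
    """A named parameter set with its declared landscape structure."""

    name: str
    params: CMCParameters
    expected_minima: int
    seed: int = 0

    def verify(self):
        """Build the potential and check the declared number of minima."""
        profile = build_potential(self.params, default_grid(), method="oracle")
        found = len(profile.minima)
        if found != self.expected_minima:
            raise RuntimeError(
                f"fixture {self.name!r} declares {self.expected_minima} minima "
                f"but its potential has {found}"
            )
        return profile


def standard_fixtures(seed: int = 0) -> list[FixtureSpec]:
    return [
        FixtureSpec("monostable", monostable_parameters(), 1, seed),
        FixtureSpec("bistable", bistable_parameters(), 2, seed),
        FixtureSpec("tristable", tristable_parameters(), 3, seed),
    ]


def count_transitions(path: np.ndarray, states, hysteresis: float = 0.5) -> int:
    """Number of state switches along an amplitude path, with hysteresis.

    The label switches to a state only once the path comes within
    ``hysteresis`` of the way from the barrier to that state's minimum, which
    suppresses double counts from barrier-top jitter.
    """
    if len(states) < 2:
        return 0
    s1, s2 = states[0], states[1]
    b = s1.upper
    th_low = b - hysteresis * (b - s1.minimum)
    th_high = b + hysteresis * (s2.minimum - b)
    label = 0 if path[0] < b else 1
    n = 0
    for x in path:
        if label == 0 and x > th_high:
            label = 1
            n += 1
        elif label == 1 and x < th_low:
            label = 0
            n += 1
    return n


def make_exit_time_dataset(
    params: CMCParameters | None = None,
    sigmas=(0.068, 0.072, 0.077, 0.083, 0.09),
    state_id: int = 1,
    noise_level: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Kramers exit-time curve from the bistable landscape, optionally noisy."""
    params = params if params is not None else bistable_parameters()
    profile = build_potential(params, default_grid(), method="oracle")
    states = define_states(profile)
    rows = []
    rng = np.random.default_rng(seed)
    for s in sigmas:
        est = kramers_exit_time(profile, states, state_id, s)
        t = est.mean_exit_time * np.exp(noise_level * rng.standard_normal())
        rows.append({"sigma": s, "mean_exit": t, "se": noise_level * t})
    return pd.DataFrame(rows)


def make_bursting_trace(
    params: CMCParameters | None = None,
    t_max: float = 2500.0,
    dt_path: float = 0.0025,
    dt_eeg: float = 0.01,
    seed: int = 0,
    min_transitions: int = 5,
):
    """Bistable amplitude path resynthesized as a bursting EEG trace.

    Simulates the amplitude SDE on the bistable landscape, verifies that the
    path switches state at least ``min_transitions`` times, and maps the
    amplitude back through the lead field:  with the single observed
    population, ``y(t) = a_1 R_1(t) cos(omega_1 t)`` with ``R_1 = R_s``.

    Returns ``(times, y, path_times, path, n_transitions)``.
    """
    params = params if params is not None else bistable_parameters()
    # wider grid than the default: at the bursting noise level the path makes
    # excursions well beyond the outer minimum
    profile = build_potential(params, default_grid(R_upper=6.0, n=2400), method="oracle")
    states = define_states(profile)
    cfg = AmplitudeSDEConfig(
        sigma=params.sigma, dt=dt_path, t_max=t_max, seed=seed
    )
    ptimes, path = simulate_amplitude_sde(profile, cfg, init=states[1].minimum)
    n_trans = count_transitions(path, states)
    if n_trans < min_transitions:
        raise RuntimeError(
            f"bursting trace shows only {n_trans} transitions "
            f"(needs {min_transitions}); increase t_max or sigma"
        )
    times = np.arange(0.0, t_max, dt_eeg)
    R_s = np.interp(times, ptimes, path)
    a1 = params.leadfield[0]
    y = a1 * R_s * np.cos(params.omegas[0] * times)
    return times, y, ptimes, path, n_trans


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write all verified fixtures to ``out_dir``; returns a manifest.

    Produces mono-/bi-/tri-stable YAML configs, the bistable potential CSV,
    a synthetic exit-time dataset across five noise amplitudes, and a bursting
    EEG trace.  Every artifact is verified against its declared structure at
    generation time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": {}}
    for spec in standard_fixtures(seed):
        profile = spec.verify()
        cfg_path = out / f"{spec.name}.yaml"
        save_config(spec.params, cfg_path)
        manifest["files"][spec.name] = {
            "config": cfg_path.name,
            "n_minima": len(profile.minima),
            "minima": [e.location for e in profile.minima],
            "maxima": [e.location for e in profile.maxima],
        }
        if spec.name == "bistable":
            profile.to_csv(out / "bistable_potential.csv")
            manifest["files"]["bistable"]["potential"] = "bistable_potential.csv"
    df = make_exit_time_dataset(seed=seed)
    df.to_csv(out / "exit_times_bistable.csv", index=False)
    manifest["files"]["exit_times"] = {
        "path": "exit_times_bistable.csv",
        "n_sigmas": len(df),
    }
    times, y, _, _, n_trans = make_bursting_trace(seed=seed)
    pd.DataFrame({"time": times, "y": y}).to_csv(out / "bursting_eeg.csv", index=False)
    manifest["files"]["bursting_eeg"] = {
        "path": "bursting_eeg.csv",
        "n_transitions": n_trans,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
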