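"""Convenience plots for landscapes, densities and inversion fits.

All functions draw on a supplied matplotlib axes (or create one) and return
it, so they compose with user figure layouts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_potential", "plot_density", "plot_exit_time_fit"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_potential(profile, ax=None, annotate=True):
    """Potential landscape U(R) with its minima and barriers marked."""
    ax = _ax(ax)
    ax.plot(profile.R_grid, profile.U, lw=1.5)
    if annotate:
        for e in profile.minima:
            ax.plot(e.location, profile.U_of(e.location), "o", color="tab:green")
        for e in profile.maxima:
            ax.plot(e.location, profile.U_of(e.location), "^", color="tab:red")
    ax.set_xlabel("amplitude R")
    ax.set_ylabel("U(R)")
    return ax


def plot_density(density, states=None, ax=None):
    """Stationary density, optionally shading the state intervals."""
    ax = _ax(ax)
    ax.plot(density.R_grid, density.p_st, lw=1.5)
    if states is not None:
        for k, s in enumerate(states.states):
            ax.axvspan(s.lower, s.upper, alpha=0.12 if k % 2 else 0.05, color="gray")
    ax.set_xlabel("amplitude R")
    ax.set_ylabel("stationary density")
    return ax


def plot_exit_time_fit(results, ax=None):
    """Observed exit times with prior- and posterior-predicted curves."""
    ax = _ax(ax)
    data = results.model.data
    ax.semilogy(data.sigmas, data.mean_exit_times, "k:o", label="data")
    ax.semilogy(data.sigmas, results.predicted_prior, "b-", label="prior")
    ax.semilogy(data.sigmas, results.predicted_posterior, "r-", label="posterior")
    ax.set_xlabel("noise amplitude sigma")
    ax.set_ylabel("mean exit time")
    ax.legend()
    return ax
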