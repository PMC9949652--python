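# cmcdyn

Slow amplitude dynamics, multistability and exit-time inversion for the
canonical microcircuit (CMC) neural mass model.

## The scientific problem

EEG and MEG recordings switch between recognizable modes of activity —
background rhythms, bursts, spindles, epileptic discharges — on time scales
far slower than the oscillations themselves. Neural mass models of a cortical
column can reproduce this *itinerancy*, but fitting them to data usually
requires linearizing around a single fixed point, which discards exactly the
transitions one wants to explain.

`cmcdyn` implements an analysis chain that makes those transitions tractable:

1. **Full model.** A cortical column as four coupled neuronal populations,
   each a nonlinear oscillator:

   ṗᵢ = −ωᵢ²qᵢ + ε ωᵢ² Σⱼ gᵢⱼ S(qⱼ) + μ ωᵢ² Σⱼ gᵢⱼ P(pⱼ/ωⱼ),  q̇ᵢ = pᵢ,

   with potentials qᵢ, currents pᵢ, connectivity gains gᵢⱼ, sigmoid couplings
   S (potential → drive) and P (current → drive), and perturbation scales
   ε, μ. The measured signal is y(t) = Σᵢ aᵢ Rᵢ cos ωᵢt through a lead
   field a.
2. **Adiabatic reduction.** Averaging the fast phases over one period of the
   frequency torus leaves a slow drift of the envelope amplitudes, to first
   order dRᵢ/dt = μωᵢgᵢᵢ Σᵣ Bᵣ Rᵢ^(2r−1) 2^(1−2r) C(2r−1, r−1), where Bᵣ are
   the odd Taylor coefficients of P — only the *self* connections gᵢᵢ
   survive the averaging. Averaging again over surfaces of constant total
   amplitude gives a one-dimensional gradient flow Ṙ = −U′(R) on a potential
   U shaped by the synaptic gains.
3. **Stochastic states.** With amplitude noise, dI = −U′(I)dt + σdBₜ, the
   stationary density is p_st = Z⁻¹exp(−2U/σ²); minima of U are semi-stable
   states, their occupancy is the density mass in each basin, and the mean
   exit time over a barrier follows the Kramers form
   ⟨t⟩ ∝ [U″(x_min)|U″(x_max)|]^(−1/2) · exp(2ΔU/σ²).
4. **Inversion.** Because exit times depend exponentially on the barrier, an
   observed exit-time-versus-noise curve is a sharp data feature for the
   underlying connectivity. A variational Laplace scheme (Gauss–Newton
   ascent on a free-energy bound) recovers log-scalings of the self
   connections from such curves.

Every closed-form step is validated in-package against an independent
numerical oracle: orbit averaging of the full flow, Monte-Carlo surface
averages, first-passage simulation, and an exact mean-first-passage-time
quadrature.

## Worked example

```python
import numpy as np
from cmcdyn import (bistable_parameters, build_potential, define_states,
                    stationary_density, state_probability, kramers_exit_time,
                    forward_exit_curve, ExitTimeData, ExitTimeModel)
from cmcdyn.fixtures import default_grid

params = bistable_parameters()                       # one active self connection
profile = build_potential(params, default_grid())    # U(R) by orbit averaging
print([round(e.location, 3) for e in profile.minima])  # [0.0, 1.693]

states = define_states(profile)                      # 2 basins split at R=0.797
dens = stationary_density(profile, sigma=0.08)
print(np.round(state_probability(dens, states), 4))  # [0.7354 0.2646]

t2 = kramers_exit_time(profile, states, 1, sigma=0.08)
print(round(t2.mean_exit_time, 1))                   # 2373.1

# invert a synthetic exit-time curve generated at g11 -> g11 * exp(0.3)
sig = np.array([0.068, 0.072, 0.077, 0.083, 0.09])
curve = forward_exit_curve(params, [0.3], sig)
res = ExitTimeModel(ExitTimeData(sig, curve, obs_variance=1e-4), params).fit()
print(res.summary())
```

The landscape has semi-stable states at R = 0 (suppressed activity) and
R ≈ 1.69 (high-amplitude oscillation) separated by a barrier at R ≈ 0.80; at
noise σ = 0.08 the system spends 74% of its time suppressed and dwells about
2.4·10³ time units per visit to the oscillatory state. The inversion returns
the posterior `g11 = 0.3000 ± 0.0008` from the exit-time curve alone — the
connectivity scaling used to generate the data.

The same chain is scriptable from the shell:

```bash
cmc fixtures --out-dir fx            # verified mono-/bi-/tri-stable configs
cmc potential --config fx/bistable.yaml --rmax 3.5 --n 900 --out pot.csv
cmc density --potential pot.csv --sigma 0.08 --out dens.csv
cmc exit-times --potential pot.csv --sigmas 0.07,0.08 --out exits.csv
cmc invert --config fx/bistable.yaml --data fx/exit_times_bistable.csv --out post.json
cmc pipeline --config fx/bistable.yaml --out-dir run1 --sigma 0.1
```

## Layout

| module | contents |
| --- | --- |
| `cmcdyn.params` | `CMCParameters`, coupling functions, YAML/JSON config I/O |
| `cmcdyn.model` | 8-D ODE/SDE simulation, complex representation, EEG synthesis, envelope extraction |
| `cmcdyn.reduction` | averaging period, drift series and oracles, `PotentialProfile` |
| `cmcdyn.stochastic` | amplitude SDE, stationary density, states, occupancy, exit times |
| `cmcdyn.inversion` | `ExitTimeModel` / `ExitTimeResults` (variational Laplace) |
| `cmcdyn.fixtures` | verified mono-/bi-/tri-stable parameter sets and datasets |
| `cmcdyn.pipeline`, `cmcdyn.cli` | end-to-end runs and the `cmc` command |

See `docs/methods.md` for the model derivation, numerical choices and
limitations.
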