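# Methods

## Model

The canonical microcircuit (CMC) is modelled as four neuronal populations of
a cortical column, each a second-order oscillator with natural angular
frequency ωᵢ, written as eight first-order equations

ṗᵢ = −ωᵢ²qᵢ + ε ωᵢ² Σⱼ gᵢⱼ S(qⱼ) + μ ωᵢ² Σⱼ gᵢⱼ P(pⱼ/ωⱼ),   q̇ᵢ = pᵢ,

where qᵢ is the population potential and pᵢ its current. The connectivity
gains gᵢⱼ carry the synaptic structure; S maps presynaptic potential to
postsynaptic drive and P parametrizes spike-rate variability as a function of
presynaptic current. Both couplings are centered, odd and (except for the
linear idealization) bounded; this is what makes the origin a fixed point and
restricts the averaged drift to odd powers. In the complex variable
zᵢ = qᵢ + i pᵢ/ωᵢ the unperturbed (ε = μ = 0) flow is żᵢ = −iωᵢzᵢ: circles of
constant amplitude Rᵢ = |zᵢ| traversed at rate −ωᵢ.

### Coupling functions

Three forms are provided: `tanh` (gain·tanh(slope·x)), `linear` (gain·x, the
small-signal idealization) and `tanh_sum`, a signed mixture
Σₖ wₖ tanh(sₖx). The mixture is how the multistable reference landscapes are
realized: physiologically it reads as parallel excitatory and inhibitory
subpopulation gains with different sensitivities, and mathematically it is
the minimal odd bounded family whose orbit-averaged drift can change sign
more than once.

## Adiabatic reduction

Amplitudes move a factor O(1/μ) slower than phases, so the phase variables
can be averaged out over one period T of the torus flow — the least common
period of the four bands (`fast_period`; frequency ratios are resolved as
rationals when a common period of at most 200 slow cycles exists, otherwise
the best approximate window is used and flagged). The default frequency
stack (2π, 4π, 6π, 8π) rad per unit time has T = 1 exactly.

Averaging the radial component of the flow at frozen amplitudes gives, per
population and to first order in μ,

dRᵢ/dt = μ ωᵢ gᵢᵢ Σᵣ Bᵣ Rᵢ^(2r−1) 2^(1−2r) C(2r−1, r−1),

with Bᵣ the odd Maclaurin coefficients of P (for tanh these follow from
Bernoulli numbers; `taylor_coefficients`). Two facts drive everything
downstream: potential couplings S average to zero at first order, and
off-diagonal current couplings average out because distinct bands decohere —
only the self connections gᵢᵢ shape the slow dynamics. The series derivation
uses ⟨sin²ʳθ⟩ = C(2r, r)/2^2r over one cycle.

Truncated at r_max terms the series converges only for R below roughly
π/(2·slope); every evaluator checks a last-term criterion (relative tail
< 1e−8) and refuses to extrapolate. Beyond the radius the drift is computed
exactly by 96-node Gauss–Legendre quadrature of ⟨P(R sin θ) sin θ⟩
(`population_drift_exact`), which is the form used to build potentials.

### Aggregate amplitude and the potential

The measured amplitude satisfies R² = Σ aᵢ²Rᵢ² with the lead field
normalized to Σ aᵢ² = n. We work with the root-mean-square amplitude R_s,
nR_s² = Σ aᵢ²Rᵢ², and average the drift over the constant-amplitude surface,
taken uniform in the coordinates uᵢ = aᵢRᵢ (a sphere of radius √n·R_s). With
sector moments m_r(d) = (2r−1)!!/∏ₖ(d+2k−2) over the d observed populations
this yields the closed form implemented in `total_drift`; for n = 4 and equal
lead-field weights the constants reduce to
Bᵣ·4R^(2r−1)/((2r+1)2^2r)·C(2r−1, r−1)·(2r+1)!!/(2r+2)!! per band. The
Monte-Carlo sector average (`mc_spherical_average`) is the normative
definition against which the constant grouping is validated; the closed form
agrees with it to sampling error at every tested amplitude. With a single
observed population the surface degenerates to a point and the reduction is
exact: R_s equals the envelope of the observed population.

The potential is U(R) = −∫₀ᴿ drift, by cumulative Simpson quadrature with
U(0) = 0; extrema are sign changes of the drift refined by Brent root-finding
and curvatures are centred differences of the drift. Degenerate extrema
(|U″| < 1e−10) are flagged and refused by the exit-time machinery.

### Validation oracles

`orbit_average_drift` integrates the *true* flow over one period from frozen
amplitudes and returns (|zᵢ(T)|−|zᵢ(0)|)/T. This is the reference the series
is tested against: the discrepancy scales as O(μ²) (measured log-log slope
1.998 over μ ∈ [1e−4, 1e−2]), and with μ = 0 the residual drift from
arbitrary off-diagonal couplings is bounded by O(ε²). An end-to-end check
integrates the full 8-D system on the bistable landscape at μ = 0.02 and
finds the envelope tracking the 1-D gradient flow within 2.1% over the whole
relaxation (tolerance 10%).

## Stochastic analysis

The slow amplitude with noise obeys dI = −U′(I)dt + σdBₜ, reflecting at
I = 0 (amplitudes are non-negative). The stationary Fokker–Planck density is
p_st = Z⁻¹exp(−2U/σ²), normalized by quadrature; construction fails if the
density at the grid upper bound exceeds 1e−10 of its maximum, and the
pipeline then doubles the grid until the landscape confines the dynamics.

States are the basins of the minima, split at the interior maxima. Occupancy
probabilities are quadrature masses of p_st per basin; they are checked
against time fractions of simulated ensembles (3-standard-error agreement).

### Exit times

Three estimators are provided and cross-validated:

* `kramers_exit_time`: ⟨t⟩ = π·[U″(x_min)|U″(x_max)|]^(−1/2)·exp(2ΔU/σ²),
  the overdamped asymptotic for the mean first passage *to the barrier top*
  (half the classic over-the-barrier escape time, since from the top re-entry
  and escape are equally likely). A well whose minimum sits at the reflecting
  origin holds half the harmonic well mass, so its prefactor is halved again.
  A warning marks 2ΔU/σ² < 3 as outside the asymptotic regime.
* `exact_mean_exit_time`: the exact 1-D MFPT double quadrature
  t = (2/σ²)∫ e^{2U/σ²}∫ e^{−2U/σ²}; deterministic and sharp at any barrier.
* `mc_first_passage`: Euler–Maruyama walkers started at the minimum and
  absorbed at the barrier top; compiled (numba) kernels with a numpy
  fallback; the step is 0.01/max curvature. Escape-time samples carry
  standard errors and have coefficient of variation ≈ 1 in the high-barrier
  regime, as expected for memoryless escape.

On the bistable landscape at 2ΔU/σ² ∈ [5, 6] the Kramers form sits at
0.81–0.89 of the Monte-Carlo mean (band [0.75, 1.33]), approaching 1 as the
barrier grows; the exact quadrature confirms the residual deficit is the
anharmonicity of the wells, not the prefactor convention.

The full-model SDE (`simulate_full_sde`) adds innovations to the current
equations, scaled by ωᵢ², and uses semi-implicit (symplectic) Euler–Maruyama:
currents first, then potentials with the new currents. The explicit scheme
inflates oscillation amplitudes measurably at any usable step; the
semi-implicit splitting keeps the fast subsystem neutrally stable.

## Envelope extraction

Per-band envelopes are magnitudes of analytic signals after a zero-phase FFT
band-pass centred on each ωᵢ (total width `bandwidth`, raised-cosine edge
tapers of a quarter band). An FFT window is used instead of an IIR design
because at these narrow relative bands a 4th-order Butterworth shows a ≈1%
passband gain bias, which is the same order as the accuracy target. The
signal is mirror-extended before the transform, and samples within
max(5% of the series, 20/bandwidth time units) of either end are flagged
edge-contaminated; tests and users should mask them.

## Inversion

The generative model maps log-scalings λₖ of the nonzero self connections
(gᵢᵢ → gᵢᵢ·e^λ) to Kramers exit-time curves over a noise grid; observations
are Gaussian on log exit times (exit times span decades). `ExitTimeModel.fit`
runs variational Laplace: Gauss–Newton ascent on the free energy with
Levenberg–Marquardt damping, finite-difference sensitivities (step 1e−4),
convergence when |ΔF| < 1e−4 on three consecutive accepted steps (at most
64). Forward failures (a scaling that destroys the requested state) are
treated as rejected steps. The default prior is N(0, 1/16) per λ. Results
report the posterior mean and covariance, its condition number, strongly
correlated parameter pairs, the free-energy trace (non-decreasing across
accepted steps by construction), and prior/posterior predicted curves.

With the bistable reference landscape the noiseless inverse crime recovers a
0.3 log-scaling to 3e−8; with 10% log-normal observation noise the posterior
error is below half the prior error in 10/10 seeded replicates. Note that
with a single active self connection e^λ rescales U uniformly, so the
λ-sensitivity of the curve comes entirely from the exponent 2ΔU/σ² — this is
what makes the exit-time feature so informative.

## Reference landscapes

The multistable parameter sets observe one population (lead field
(2, 0, 0, 0)) whose self connection carries the dynamics; the weights of the
tanh-sum current coupling were fitted once by linear least squares to target
drifts with the declared root structure and then frozen. The bistable
landscape has minima at R = 0 and R ≈ 1.69 (barrier R ≈ 0.80; barrier heights
0.0203 from the origin and 0.0136 from the outer well at μ = 0.05) and a
drift verified negative out to R = 14, so it confines the dynamics at every
noise level used. The tristable landscape (minima near 0, 0.73, 2.02) is
confining only up to R ≈ 4 and is used for state-structure checks, not
large-noise stationary statistics. Fixture generation rebuilds each potential
and fails loudly if the declared number of minima is not found.

## Problem sizes and defaults

Chosen once as the package's study conditions: potentials on ≥ 500-point
grids (default 900–3600 points over R ≤ 3.5–9); orbit averages at integrator
tolerance 1e−12; spherical-average oracles at 4·10⁵–10⁶ samples; density
histograms from 10 walkers × 10⁵ steps (10⁶ total, 20% burn-in) at σ = 0.2;
exit-time oracles at 2000 escapes; recovery experiments over five noise
amplitudes σ ∈ [0.068, 0.09] with 10 seeded replicates at 10% observation
noise; bursting traces of 2500 time units at σ = 0.25 (≈ 60–70 state
transitions). All stochastic operations take explicit seeds; no global
random state is used.

## What the synthetic data do and do not show

The reference landscapes emulate the qualitative repertoire of the reduced
model — mono-, bi- and tri-stable amplitude dynamics, noise-driven
switching, bursting measurement traces — with explicit, reproducible
parameters. They do not emulate real EEG: no measurement noise floor, no 1/f
background, no non-stationary connectivity, a single cortical column, and a
lead field concentrated on one population. Passing tests therefore
demonstrate the internal correctness of the reduction–statistics–inversion
chain under its own assumptions (time-scale separation, weak coupling,
additive amplitude noise), not that those assumptions hold for any given
recording. Fitting to real data, cross-column coupling and higher-order
perturbation terms are out of scope.

## Known limitations

* The amplitude reduction is first order in μ; second-order terms (which
  re-introduce off-diagonal connectivity) are not represented.
* The Kramers estimate under-predicts by 10–20% at moderate barriers
  (2ΔU/σ² ≈ 5); use `exact_mean_exit_time` when sharpness matters.
* The truncated drift series diverges outside its radius; the quadrature
  drift is the general-purpose evaluator.
* Exit-time inversion identifies products that shape ΔU and the curvatures;
  with several free scalings the posterior can be strongly correlated — the
  results object reports the correlated pairs rather than hiding them.
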