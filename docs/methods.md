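# Methods

## Model and scope

The package simulates and analyses random recurrent rate networks of
two-variable neurons,

    dx_i/dt = −x_i + a_i + Σ_j J_ij φ(x_j) + I_i(t)
    da_i/dt = −γ_i a_i + β_i x_i,

with φ = tanh (a linear activation is available for oracle tests),
`J_ij ~ N(0, g²/N)` off the diagonal and `J_ii = 0`.  Time is
dimensionless, with the activity leak fixed at rate 1; `γ_i` (1/time) is
the decay rate of the auxiliary variable and `β_i` (1/time) the feedback
strength.  `γ_i > β_i` is required for the isolated neuron to be
non-divergent; sampled populations violating it raise unless explicitly
overridden.  With `β > 0` and `γ` slightly above `β`, the neuron holds a
graded plateau whose level integrates the pulse history
(graded-persistent activity, GPA); with large `γ` it is an ordinary
leaky unit; with `β < 0` the auxiliary variable implements adaptation.

Out of scope by design: the self-consistent mean-field autocorrelation
dynamics (we implement only the spectral transition condition),
random-matrix theory for the eigenvalue bulk, sparse or sign-constrained
connectivity, spiking dynamics, delays, and nonlinear readouts for the
memory measurements.

## Transition theory

In the large-N limit the recurrent drive becomes a Gaussian mean field,
but per-neuron intrinsic parameters survive as a family of linear
filters.  In Fourier space each neuron relates its activity PSD to the
mean-field PSD through the squared-magnitude transfer gain

    G(ω; γ, β) = (ω² + γ²) / (ω⁴ + (γ² + 2β + 1)ω² + (γ − β)²),

which we re-derived independently from the two-variable linear system
(eliminate the auxiliary amplitude, take |·|²).  Averaging over the
population and using |φ(x)| ≤ |x| yields the transition condition
`max_ω Ḡ(ω) · g_c² = 1` with `Ḡ = E_{γ,β}[G]`.

Implementation choices:

* **Expectations.**  Discrete parameter families enter as exact finite
  mixtures.  Continuous families use fixed-order Gauss–Legendre
  quadrature against the density (64 nodes per dimension by default,
  tensor product for joint heterogeneity); convergence is asserted in
  tests by node doubling.  Truncated-normal sampling is inverse-CDF on
  the truncated range — exact, no rejection loop.
* **Frequency maximization.**  When the whole support satisfies
  γ > β ≥ 0, every neuron's gain — hence the average — peaks at ω = 0,
  where `G(0) = γ²/(γ−β)²`; the maximum is evaluated there directly.
  Otherwise (adaptation, β < 0, where the peak moves off zero) the
  candidates are ω = 0 plus a 200-point log-spaced grid on [1e−3, 1e3],
  refined by bounded scalar minimization between the best candidate's
  grid neighbours; ties break toward smaller ω.  Self-consistency
  `g_c² Ḡ(ω*) = 1` holds to 1e−8 relative on the search path.
* **Singular supports.**  If the supports of γ and β can touch
  (γ = β has mass or sits on the boundary), the averaged gain diverges
  at ω = 0 and the computation raises rather than returning a clipped
  value.
* **Two-point closed form.**  For γ ∈ {γ_low (prob p), γ_high} and
  constant β, `g_c = (p (γl/(γl−β))² + (1−p)(γh/(γh−β))²)^(−1/2)`,
  strictly decreasing in p; at p = 0 it reduces to `1 − β/γ_high` and to
  the classical `g_c = 1` as β → 0 or γ_high → ∞.
* **Naive Gaussian comparison.**  The earlier treatment that absorbs a
  Gaussian spread of β into an extra mean field gives
  `G_β = G/(1 − σ_β²/(γ²+ω²)·G)`; where its denominator turns
  non-positive on the scan the routine raises a breakdown error instead
  of extrapolating, since the approximation has left its domain of
  validity (that domain is not characterized analytically).

## Simulation

Fixed-step explicit Euler, default dt = 0.02; under shared white noise
the increment enters as Euler–Maruyama with per-step input
N(0, σ_in² dt) through fixed per-neuron weights.  An adaptive stepper is
deliberately avoided so the noise path is well defined.  First-order
convergence is verified against the matrix-exponential solution of the
uncoupled linear neuron.  Any |x| or |a| beyond 1e6 aborts with a
structured divergence error carrying the first bad step.

Free-running (phase-diagram) initial conditions: x(0) i.i.d. standard
normal, a(0) = 0, from a dedicated "init" seed stream.  All sampling is
split from one master seed into named streams (gamma, beta, coupling,
init, input) so individual streams can be varied independently.  The
first part of every free run (default 150 time units, doubled near a
known boundary) is discarded before statistics.

## Order parameter and classification

Spectra are Welch estimates (Hann window, segments of 2¹⁰ stored
samples, 50% overlap, mean removal) on per-neuron series, averaged over
the population; the order parameter is max over ω of the mean PSD.
Stored samples are thinned to 0.1 time units (Nyquist ≈ 31 rad/time),
ample for the low-frequency band where the transition expresses itself.

Classifying a finite run as silent vs dynamic needs two guards:

* an amplitude floor ε, calibrated per condition as 5× the max PSD the
  identical pipeline produces on the final quarter of a matched
  uncoupled (g = 0) run — a pure numerical floor; and
* a decay-ratio guard: the RMS of the last tenth of the measurement
  window must be at least half the RMS of the first tenth.  Slightly
  subcritical networks decay arbitrarily slowly near the boundary, and a
  finite window of such a transient can carry PSD far above any floor;
  the ratio separates sustained activity (measured ≥ 0.88 across our
  grids) from decaying transients (≤ 0.36).

The empirical boundary for a heterogeneity level is the geometric mean
of the last silent and first dynamic g on the grid.  At N = 500 on a
6×12 (p, g) grid this recovers the closed-form two-point boundary within
15% at every p (typically within 3–8%).

## Stability diagnostics

The origin Jacobian is the 2N×2N block matrix
[[φ′(0)J − I, I], [diag(β), −diag(γ)]]; its spectral abscissa diagnoses
linear stability of the quiescent state (dense eigendecomposition,
guarded at N ≤ 5000).

The maximum Lyapunov exponent uses the Benettin tangent-vector method:
the nonlinear system and its exact tangent dynamics (Jacobian along the
trajectory) are co-integrated with the same Euler step; the tangent
vector starts uniformly on the unit sphere and is renormalized every 1.0
time units.  Log norms are accumulated only after a 20-time-unit tangent
warm-up (renormalized but not counted), which removes the
initial-misalignment bias; with the warm-up the estimator matches the
linear-system exponent to ~1e−6.  Defaults: 10 random initial
conditions, mean and standard deviation reported; one coupling matrix
per (g, seed) pair.  The λ(g) zero-crossing is located by linear
interpolation between bracketing grid points of the mean curve.

A caveat established while validating: just above the origin
instability, finite networks (N ≲ 1500 in the two-point family we
tested) frequently settle on non-chaotic attractors — limit cycles with
discrete spectral lines, or nonzero fixed points — so λ_max sits at or
below zero over a band of g above g_c while the spectral abscissa is
already positive.  The band shrinks with N (at N = 2000, λ at 1.3 g_c
was positive in all probes).  Sign agreement between the two diagnostics
at a fixed multiplier of g_c above the transition is therefore a
large-N statement, not one that holds realization-wise at small N; the
two boundaries themselves still converge as N grows, which is the trend
the tests assert.

## Memory capacity

The network is driven by one shared scalar Gaussian white-noise signal
(σ_in = 0.1 by default) through i.i.d. standard-normal input weights.
States are sampled every 10 integrator steps (0.2 time units), and the
input value attached to a sample is the noise accumulated over the
preceding 0.2-unit block: a single integrator-step increment is not
linearly recoverable from a state that integrates it, while the block
increment — the input signal at the delay-grid resolution — is.  For
each delay (multiples of 0.2 up to 20 time units) a ridge-regularized
linear readout (penalty 1e−6, trace-normalized) maps the state to the
delayed input, fitted on the first half of the samples chronologically
and scored as the squared Pearson correlation on the second half — the
standard linear memory function, summed over delays for the total
capacity.  These readout conventions (weights, delays, aggregation,
regularization, score) are package choices, documented here because
several of them admit reasonable alternatives; a delay-line surrogate
and a normal-equations oracle pin the implementation in the tests.

Where the capacity peaks depends on the heterogeneity level.  With
moderate feedback spread (γ = 3, β ~ U[0, 1], N = 300) intrinsic filter
memory is short and recurrence near the transition extends the memory
horizon: the capacity curve rises from ≈4 at small g to ≈7.5 at
0.85 g_c and collapses in the chaotic regime — the edge-of-chaos peak.
With very broad spread (β ~ U[0, 2.9]) the slowest intrinsic filters
(timescales of tens of time units) already store the input at g ≈ 0 and
recurrent interference only degrades the readout, so capacity decreases
monotonically in g.  The edge-of-chaos statement is about networks
whose memory is recurrence-limited, not filter-limited.

## Synthetic data and what the tests show

There is no external data: networks, parameters and inputs are all
generated by the package itself, which is also how the underlying theory
is framed (quenched random couplings, distribution-specified intrinsic
parameters).  Test conditions use the parameter sets above at reduced
network sizes (N = 100–1000 instead of 3000–5000) and run lengths
(hundreds of time units), so finite-size displacement of empirical
boundaries is larger than in the headline setting; the tests therefore
assert banded agreement and monotone trends rather than exact
coincidence.  Passing tests show the implementation is internally
consistent and reproduces the theory's predictions at these scales; they
do not probe biological realism of the rate model itself (no spiking,
no Dale's law, no structured connectivity).

## Known limitations

* Euler at dt = 0.02 biases PSD ratios at high ω (band-limited checks
  are used); halving dt halves the bias.
* The ε/decay-ratio classification can misread a cell within ~5% of the
  boundary in either direction; boundary estimates inherit one grid
  step of uncertainty, reduced by the geometric-mean interpolation.
* The naive-comparison routine reports breakdown for large σ_β rather
  than characterizing the breakdown surface.
* Memory capacity targets only the noise increments at sampled times;
  reconstructing between-sample increments is not attempted.
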