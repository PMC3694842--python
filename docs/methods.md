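# Methods

## Model reduction

The module is modeled at three levels that share one parameter set.

**Full mass-action picture.** Each feedback loop comprises nine
reactions: NF-κB binding/unbinding its inhibitor's promoter, delayed
constitutive and induced synthesis of the inhibitor, inhibitor–NF-κB
association/dissociation, constitutive degradation of the free
inhibitor, and IKK-driven degradation of free and complexed inhibitor
(the latter releasing NF-κB). Total NF-κB is conserved.

**Reduced deterministic model.** Three assumptions close the system on
the total inhibitor levels alone: (i) promoter-bound NF-κB is negligible
against the total (a few molecules versus ~10^5); (ii) promoter binding
and inhibitor–NF-κB binding are fast and sit at quasi-equilibrium;
(iii) the transcription/translation/transport pipeline of each inhibitor
is collapsed into a discrete delay on its synthesis term. Free (nuclear)
NF-κB is then the nonnegative root of
`x^2 + (kc + y_a + y_e - nf_tot) x - nf_tot kc = 0`, evaluated in a
cancellation-free form, and each total inhibitor level obeys one
delay-differential equation (see the package README for the form). The
reduced right-hand side is verified in the test suite against an
independently coded sum of the full system's slow fluxes at
quasi-equilibrium, and the free-NF-κB root against a damped fixed-point
iteration on the binding relations.

**Delay convention.** IκBα synthesis reads nuclear NF-κB at `t - tau1`.
IκBε synthesis reads it at `t - (tau1 + tau2)`: `tau2` is the *increment*
of the ε pipeline over the α pipeline, the quantity the damping analysis
scans. This convention is forced by the dynamics: a second same-sign
delayed loop is maximally *destabilizing* when its absolute delay sits at
half the oscillation period and stabilizing near zero or a full period
(two-delay characteristic equation `λ + a + b1 e^{-λτa} + b2 e^{-λτe}`,
confirmed by root tracking and nonlinear scans), so a 45-min damping
optimum together with a ~90-min period is only possible if the 45 min are
measured on top of the α delay. It is also the natural biology: ε
induction trails α induction by tens of minutes.

**Stochastic model.** The discrete networks restore the binding steps
explicitly (one binary promoter per gene) and convert deterministic
rates through the system size `omega = n_molecules / nf_tot`. Delayed
synthesis follows the initiate-now/complete-later scheme: initiations
fire at the current promoter-state propensity, the product count updates
one delay later, and nothing is consumed at initiation, so completions
fire even if the promoter state has changed meanwhile. Input switch
times are barrier events at which the clock advances and propensities
are re-evaluated (exact by memorylessness). The pending-completion queue
is *warm-started* at t = 0 with Poisson-distributed completions of
pre-simulation initiations at the basal mean propensity; without this
the first `delay` minutes of a run have no synthesis at all, which
biases the early response by tens of molecules.

The association rates for binding steps (`BINDING_ON_RATE`,
`PROMOTER_ON_RATE`) are fidelity knobs of the stochastic layer, not
model parameters — the reduced models eliminate them by
quasi-equilibrium. Defaults (0.5 and 3.0 /nM/min) keep binding fast
against the minutes-scale turnover at tolerable event counts;
quantitative SSA-versus-DDE comparisons use faster rates (4 and
9 /nM/min, i.e. second-scale promoter dwell times, in line with
FRAP-type evidence for transcription-factor residence) so the discrete
system tracks the quasi-equilibrium reduction closely.

## Reference configuration and calibration

All concentrations are nM, times minutes, `K` dimensionless. The shipped
reference set was seeded from order-of-magnitude biochemical values
(total NF-κB on the 10^5-molecules scale, nM-range binding constants,
minutes-scale IKK-driven degradation) and then calibrated — the
parameters are compound/effective constants of a reduced model, not
single-step rate measurements — against three behavioral anchors:

- single-loop oscillation period ≈ 90 min under persistent stimulation,
- peak IκBα : peak IκBε ratio = 3.9 when the ε loop is given the α
  loop's full induced synthesis strength (`eps = 1`),
- damping optimum at an ε-delay increment of 45 min.

The constitutive IκBα synthesis rate is fixed at 0.00185 nM/min. The
reference ε feedback strength `eps = 0.64` is obtained by inverting the
model's monotone ratio(eps) curve at the measured peak-protein ratio
(379,800 / 71,300 ≈ 5.33 molecules per cell). Calibration used a bounded
derivative-free (Powell) search on tolerance-normalized anchor
residuals; the same machinery is exposed as
`synth.calibrate_parameters`. Two structural consequences of the
anchors are worth naming: the stimulated fixed point must sit where the
delayed feedback gain roughly balances the instantaneous removal rate
(weakly damped single loop), and the isoform peak asymmetry requires
free IκBε to be much less stable than free IκBα (`deg_e = 1.15/min`
versus `deg_a = 0.009/min`) — the ε synthesis wave arrives in the
NF-κB trough, where inhibitor pools are largely free and exposed, which
is exactly what lets an equally strong ε loop produce a 3.9-fold lower
peak.

## Analyses

**Linear stability.** In the stimulated regime (induced synthesis and
degradation dominating basal ones; total NF-κB large against the binding
constants) the coefficients of the linearized scalar DDE have closed
forms (`a = rho r_ikk K`, `b = c1 kp / (kp + nf_tot - y*)^2` with `y*`
from an explicit quadratic); the default analysis uses them, and a
full-form linearization (central differences of the exact right-hand
side about the numeric fixed point) is available via `form="full"` for
cross-checks. The principal Lambert-W branch yields the rightmost
eigenvalue for the real arguments arising here; the test suite verifies
this against a Newton search started from a complex grid. Analytic
period and decay are validated against small-perturbation (2%)
relaxations of the nonlinear DDE; the perturbation protocol matters,
because large-amplitude transients mix nonlinear relaxation into the
measured decay.

**DDE integration.** Method of steps with an adaptive RK45 and dense
output; chunk boundaries include input switch times and two generations
of their delay images, and chunks never exceed the smallest positive
delay so delayed lookups read completed segments only. Default
tolerances 1e-8/1e-10; pre-stimulus history defaults to the basal
steady state (resting cells), computed by reducing the two steady-state
balances to one scalar root in nuclear NF-κB.

**Damping metric.** Largest nuclear-NF-κB peak-minus-following-trough
difference after 6 h of persistent stimulation, with peak prominence 1%
of total NF-κB to reject integrator ripple. The (tau2, eps) surface has
its minimum at tau2 = 45 min across the tested eps range; at the
reference eps the optimum beats the eps = 0 metric roughly tenfold.

**Duration encoding.** Response duration is the total time nuclear
NF-κB exceeds 50 nM, with bracketed root refinement at the crossings.
In the reference calibration the short-pulse floor is ~44 min
(tau1-dominated shutdown); the single loop quantizes longer inputs onto
oscillation-locked plateaus while the dual loop, whose damped plateau
sits above the threshold, grades them with slope ~1 beyond about two
periods. A 60-min short-pulse floor, the scale reported for the real
module, is not attainable jointly with the 90-min period in this
reduction: the shutdown is delay-dominated (duration ≈ tau1 + 1/a)
while the period obeys P ≥ 2 tau1, capping the floor near
P/2 ≈ 45-50 min — verified over ~1000 configurations across four
dynamical regimes.

**Noise metrics.** Intrinsic variability is quantified across SSA
ensembles as sd/mean per time point; extrinsic variability across
deterministic parameter families (total NF-κB or input level varied
±25%, the stated measurement-error scale, endpoints-plus-midpoint by
default) as half-range (max−min)/(max+min), with sd/mean available via
a flag. Peak CV is read at the mean trajectory's first-peak time; the
late phase starts at the following trough. Single-cell versus
population damping magnitudes (`a_single`: mean of per-trajectory late
peak-trough maxima; `a_population`: the same metric on the pointwise
mean) separate when trajectories desynchronize, with
`a_population ≤ a_single` structurally.

**Ensemble-versus-deterministic comparisons** are made over the
phase-coherent first oscillation after stimulus onset. Two genuine
finite-size effects separate the ensemble mean from the DDE at later
times at n = 1000: an O(1/n) positive bias in the troughs
(sequestration-curve convexity times synthesis burst variance) and a
~0.1%-per-cycle stochastic period shift that accumulates into a phase
offset. These are physics of the discrete system, not simulation error;
the late-time divergence of the undamped single loop is precisely the
desynchronization that the noise metrics quantify.

**Auto-repressor comparison circuit.** A self-repressing gene (delayed
synthesis from the unbound promoter, activated by the input) with
synthesis chosen so its mean peak matches the NF-κB networks' peak copy
number at n = 1000, delay equal to tau1, and deliberately slow
promoter binding (first-arrival jitter of the repression onset is what
makes its first peak noisy). It isolates the design principle the
comparison demonstrates: signaling by release of a sequestered pool is
far more reproducible than signaling by de novo transcription.

## Synthetic observables

The generators emulate quantitated band intensities: a logistic
basal-to-peak mRNA induction crossing half-maximum at the true delay
(the estimator is shape-agnostic; only a monotone rise matters),
multiplicative lognormal noise of specified CV (band intensities are
positive; additive-Gaussian mode behind a flag), sampled noisy nuclear
NF-κB trajectories, and replicate basal/peak protein abundances with
25% multiplicative error. They reproduce the sampling grid (15-min
spacing) and replicate counts (N = 10) of the corresponding wet-lab
readouts but none of their systematic artifacts (gel background,
saturation, loading variation); passing recovery tests therefore shows
estimator correctness and noise-level adequacy, not robustness to real
assay pathologies.

## Numerical choices and degenerate inputs

Zero delays reduce the DDE to an ODE and are integrated directly;
`eps = 0` silences the ε equations exactly; trajectories are clamped at
zero for reporting (integrator excursions below zero are bounded by the
absolute tolerance); tie-breaks in peak detection go to the earliest
time; CV is undefined (NaN) where the mean is nonpositive; the
calibration reports per-anchor residuals and the worst anchor rather
than raising on failure. Floats are serialized with 12 significant
digits so repeated writes are bit-stable.

## Known limitations

- No nuclear/cytoplasmic compartments, no IKK-cascade dynamics, no
  explicit mRNA species: the delays absorb them, so the model cannot
  resolve mechanisms inside the synthesis pipeline.
- The short-pulse response-duration floor is structurally ~P/2 (see
  above), below the ~60 min the full biology shows.
- The quasi-equilibrium reduction breaks down transiently during the
  fast post-stimulus release; the stochastic layer exposes this as a
  binding-rate-dependent lag, which is why fidelity comparisons pin the
  binding rates.
- Parameters are effective constants of the reduced model. In
  particular the free-IκBε instability that the peak-ratio anchor
  demands should not be read as a single-step in vivo half-life.
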