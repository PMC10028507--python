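# Methods

## Model

Three populations — local governments, consortium hospitals, patients — each
mix between two pure strategies.  The state (x, y, z) ∈ [0, 1]³ holds the
fraction of governments pushing EHR integration hard, of hospitals
participating actively, and of patients actively supervising.  Payoffs come
from a 2×2×2 matrix over the eight pure profiles, parameterized by twelve
nonnegative scalars in abstract payoff units (no monetary calibration is
attempted; the baseline is an expert-style assignment, and the scenario
generator exists precisely because such assignments are judgement calls).

All algebra is derived from the payoff matrix and nothing else.  Expected
payoffs exist in two forms: a brute-force probability-weighted enumeration
over the eight cells (the oracle) and closed forms used by the integrators.
Their equivalence is a polynomial identity, checked symbolically with sympy
and numerically on thousands of random (state, parameter) pairs.  Because
sign-slipped transcriptions of these equations circulate, `derivation_audit`
and `table3_audit` keep the known variants verbatim and report the exact
symbolic residual of each against the derivation — five equation variants
and two rows of the det/tr reference table fail the audit; the package never
uses the flagged forms.

Dynamics are standard replicator equations, u̇ = u(1 − u) g_u per
population.  Two structural consequences drive the whole analysis: every
cube vertex is an exact fixed point, and the Jacobian at a vertex is
diagonal with eigenvalues ±g_u, so vertex stability reduces to three sign
checks of closed-form expressions.

### Stability classification

A vertex is *stable* iff all three eigenvalues are negative, *unstable* iff
all are positive, *non-hyperbolic* if any eigenvalue lies within 1e-9 of
zero (this tolerance matters only for knife-edge parameter choices such as
Fp = Cp, where the zero is exact), otherwise a *saddle*.  The traditional
det(J) > 0 ∧ tr(J) < 0 shortcut is computed and reported for comparability
but never trusted: in three dimensions a stable point has det(J) < 0 (the
product of three negative eigenvalues), so the shortcut — a planar-systems
rule — can never confirm stability here and its positive hits are saddles.
The equilibrium reports carry both verdicts so the disagreement is visible
rather than silently resolved.

## Integrators and numerical choices

The reference integrator is explicit fixed-step Euler with a 0.125-year step
over a 20-year horizon, mirroring a conventional stock-and-flow
system-dynamics run.  At the baseline payoff magnitudes (gains of order
40–66) this step overshoots the unit cube: from y = 0.35 a single Euler step
can carry y past 1.  The integrator therefore projects the state back onto
[0, 1]³ after every step and records the largest projection applied
(`Trajectory.max_clamp`, about 0.95 on the baseline run).  Projection is
benign for the qualitative questions asked of this scheme — the cube faces
are invariant and the projected point lands on the face the exact flow
approaches — but it saturates transients, so `clamp_tolerance` defaults to
`None` (diagnose, don't fail); setting it to a number turns any larger
projection into a `StepTooCoarseError` naming the offending time, which is
the right mode when the fixed-step trajectory itself is the object of
interest.

The accuracy reference is `scipy.integrate.solve_ivp` with LSODA (rtol 1e-8,
atol 1e-10), sampled on the same grid.  The cube is invariant for the
continuous flow, so only roundoff-level projection occurs there.  The
right-hand side handed to the adaptive solver evaluates the rates on the
state projected onto the cube: inside the cube this changes nothing, but it
keeps trial steps from entering the region outside [0, 1]³ where the cubic
vector field diverges (without it, LSODA can be dragged to overflow on
strongly driven parameter draws).  Both integrators agree on every converged
vertex tested; quantitative experiments (sweeps, threshold experiments, the
basin study) default to the adaptive scheme because Euler's saturation ties
time-to-threshold metrics across nearby parameter values, while the scenario
reproduction and the headline baseline run use Euler as the reference.

Convergence detection declares a vertex only when the final state is within
sup-norm tolerance (default 1e-3) *and* the distance to that vertex is
nonincreasing over the last 10% of samples, so a trajectory merely passing
near a vertex is not misread as converged.  Threshold-crossing times are
linearly interpolated between grid samples.  Exact-boundary coordinates are
invariant under the replicator flow; scenario runs that start on a face are
therefore executed both as given and nudged 1e-6 into the interior, with
both verdicts reported.

## Experiments

* **Labelled scenarios** (A–F): six initial conditions, four interior and
  two on a face.  All interior ones converge to (1, 1, 1) at baseline, with
  hospitals reaching full participation before patients reach full
  supervision (the hospital gain ≈ 48–66 dwarfs the patient gain ≈ 1–5).
  Scenario D (x = 0) settles at (0, 1, 0): with the government absent the
  hospital gain Rh + Kh − Ch = 48 is still positive, so hospitals cooperate
  anyway while unrewarded supervision dies out.  A narrative in which
  hospitals defect under a passive government is not reproducible from this
  payoff matrix at the baseline — the summary report says so explicitly
  instead of tuning toward it.
* **One-at-a-time sweeps**: each parameter swept over {0.5×, 1×, 2×} its
  baseline value by default (the underlying sensitivity figures print no
  axis values, so the bracket is the package's own choice), holding the rest
  fixed, from the common interior start (0.45, 0.35, 0.4).  Metrics:
  time-to-threshold (default 0.99), final state, or converged vertex.
  Values that break a strict-mode ordering (e.g. Kg swept up to Cg) are
  flagged in the result, never silently dropped.  The derived directions —
  Rg, Fg, Kg, Mh accelerate x and Cg delays it; Rh, Kh, Fh, Mh accelerate y
  and Ch delays it; Fp accelerates z and Cp delays it; Rh leaves the chosen
  vertex unchanged while Rh + Kh > Ch — are asserted as tests.  Only the
  government's gain carries Fp and Fh jointly with the rest: symbolic
  coefficient extraction shows 7 of the 12 parameters enter g_x, 5 enter
  g_y, 3 enter g_z.
* **Patient threshold**: the z-eigenvalue at (1, 1, 1) is −(Fp − Cp), so the
  patients' limit flips from z → 1 (Fp > Cp) to z → 0 (Fp < Cp), with a
  non-hyperbolic freeze on Fp = Cp.  The experiment integrates all three
  regimes from a common start and reports limits, eigenvalues and
  classifications.
* **Penalty marginal effect**: time for y to reach 0.99 against increasing
  hospital penalties Mh, with per-unit improvements.  The gain is affine in
  Mh while the crossing time is convexly decreasing in the gain, so the
  per-unit speed-up shrinks — at the baseline, where Rh + Kh − Ch = 48
  already dominates, the absolute effect of Mh is small from the outset.

## Scenario generation and the basin study

`sample_parameters` draws the twelve parameters uniformly and independently
from per-parameter ranges, by default [0.25×, 4×] the baseline value —
deliberately wide, to stress the claim that the qualitative conclusion
survives reparameterization — with rejection sampling conditioning on
Cg > Kg and Ch > Kh and an up-front feasibility check on the ranges.
Initial states are uniform on [margin, 1 − margin]³ (default margin 0.05).
Everything is deterministic per seed (numpy `default_rng`; one master seed
spawns independent child streams for parameters and states; package default
seed 20230306).

The basin-agreement study is the pipeline's own oracle: for every generated
parameter set with a unique eigenvalue-stable vertex it integrates the
adaptive scheme from every generated start (horizon 200 years, doubled up to
3200 for slow runs whose leading eigenvalue is small) and checks that the
simulated limit matches the linearization's prediction.  Parameter sets with
zero or multiple stable vertices are excluded from the denominator and
listed; every disagreement is returned with full context.  On 100 scenarios
× 5 starts at the default ranges the observed agreement is 100% (4 parameter
sets excluded for lacking a unique stable vertex).

What the generator does *not* emulate: correlated expert judgements (real
assignments trade parameters off against each other), heavy-tailed or
log-scale uncertainty, and any empirical grounding of payoff magnitudes.
Passing tests therefore show internal consistency of the model and
robustness of the (1, 1, 1) conclusion across independent uniform
parameter draws — not that real EHR-integration programmes behave this way.

## Problem sizes

Default analyses are desk-scale by construction: 161-point trajectories
(0.125-year step over 20 years), eight vertices, 100 × 5 scenario–start
pairs in the basin study, 1000 random pairs in the oracle-equivalence
battery.  The full test suite runs in a few seconds on one CPU.

## Known limitations

* The interior (mixed-strategy) equilibrium is intentionally out of scope;
  only the eight vertices are classified.
* Euler-with-projection is faithful to common system-dynamics practice but
  not to the continuous flow during fast transients; use `adaptive-rk` for
  anything quantitative.
* Payoff units are abstract; nothing here estimates parameters from data.
* The patient payoff cells of the matrix are kept exactly as transcribed
  even where the surrounding incentive narrative could suggest harmonizing
  them (e.g. whether social damage Rp also hits a supervising patient under
  a negative government); the audit layer exists to make such choices
  visible rather than to resolve them.
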