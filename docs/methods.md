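# Methods

## Model class and ODE generation

A reaction-based model is the tuple (A, B, K, X0, t): M×N reactant and
product stoichiometry matrices with non-negative integer entries,
M positive kinetic constants, N non-negative initial concentrations
and a strictly increasing list of sampling instants whose last element
is the horizon t_max.  Mass-action kinetics turns this into the
polynomial system

    dX/dt = f(X) = (B − A)^T [ K ∘ X^A ].

Reactions are restricted to first and second order: every row of A
sums to 1 or 2 (a termolecular encounter has essentially zero
probability, and the restriction keeps every monomial of degree ≤ 2).
Zero-order source reactions are rejected by default; `parse_model` and
`validate_model` accept an `allow_zero_order` flag for users who want
inflow reactions, and the evaluation path handles the resulting empty
reactant span (the monomial is the empty product, 1).

Products are not restricted: degradation (empty right-hand side) and
product rows summing to more than 2 are structurally valid, although
the random generator only emits 1–2 product molecules.

## Compressed encoding

The non-zero structure of H = (B − A)^T and A is stored in four flat
arrays mirroring a compact 16-bit/short storage layout:

* `vh_entries`: one quadruple `(species j, monomial row, h_ji,
  kinetic index)` per non-zero of H, species-major, ascending reaction
  within a species;
* `oh_offsets`: per species an inclusive `(first, last)` span into
  `vh_entries` (empty span: `last = first − 1`);
* `va_entries`: one pair `(reactant species, exponent ∈ {1, 2})` per
  non-zero of A, reaction-major, ascending species;
* `oa_offsets`: per monomial row an inclusive span into `va_entries`.

A dimerization reactant 2A is a single exponent-2 entry and the rate
is the plain mass-action k·X_A² (no combinatorial ½ factor).  The
monomial row and kinetic index coincide under mass action but are kept
as separate fields of the quadruple.  The fixed entry orderings make
the encoding — and therefore whole simulations — bit-reproducible.

`compact_mode` is a validation mode emulating 16-bit indices: N, M and
both entry-list lengths must stay below 65,536 or a `CapacityError` is
raised.  Storage itself remains wide; the limit is a property of the
compact layout being modelled, not of the arithmetic.

Derivative evaluation is vectorized: reactant factors are gathered per
`va` entry, squared where the exponent is 2, multiplied per monomial
with a segmented product over the `oa` spans, scaled by h_ji·k_i and
segment-summed per species.  The Jacobian is exact symbolic
differentiation of each monomial (degree ≤ 2, so an exponent-1 factor
drops and X_r² contributes 2X_r); no numerical differencing anywhere.
The kinetic constants are copied into the encoding at build time;
mutating the model afterwards requires rebuilding.

## Explicit integration and error control

The explicit method is the classical Fehlberg 4(5) embedded pair: six
derivative stages l1..l6 per trial step yield a fifth-order estimate
`u` and a fourth-order companion `w`.  `u` is the accepted state
(local extrapolation).  The controller works per species:

    ER = |w − u| / dt,      δ = 0.84 (ε / ER)^{1/4},

with δ clamped to `delta_max` (default 4), which also absorbs the
ER = 0 division at fixed points.  A step is accepted iff ER_j ≤ ε_j
for all j.  On rejection the step-size becomes dt·min_j δ_j; if that
falls below the switching threshold ε_s the system is declared stiff.
The step-size also grows on acceptance by the same capped factor —
without growth the solver would never recover after a stiff transient
— and is clamped to `dt_max`, defaulting to the current inter-sample
interval, so the controller never extrapolates far beyond the sampling
resolution.  Whether an upstream implementation of this scheme grows
dt on acceptance, and which member of the pair it propagates, are not
fixed by the published description; both choices here are recorded
deliberately and covered by tests (ER scales as dt⁴, so the measured
step-halving ratio in [8, 32] pins the pair's order).

A trial step whose stages overflow to non-finite values (possible on a
wildly unstable step before the controller has any ER to look at) is
treated as a rejection with a fixed 4× shrink, feeding the same
retry-or-switch decision.

## Stiff integration

When stiffness is detected the driver takes implicit BDF macro-steps
of user-defined length `dt_bdf` (default 0.1):

    sum_{i=0}^{q} α_i X(t − i·dt) = dt β_0 f(X(t)),   α_0 = 1.

Coefficients for q = 1..6 are stored as exact rationals and satisfy
Σ α_i = 0 and β_0 = −Σ i·α_i exactly (exactness on constants and
linear functions); orders above 6 are refused as numerically unstable.
Multi-step formulae require uniformly spaced history, so the t_i are
i·dt and, when q > 1 is configured, the order ramps up from 1 by one
per completed macro-step; if the macro-step length changes (it is
clamped to the distance to the next sampling instant) the history
resets to order 1.  The default order is 1 (backward Euler), matching
the reference parameterization.

Each implicit step solves G(z) = z + Σ_{i≥1} α_i X_hist,i −
dt β_0 f(z) = 0 by a modified Newton–Raphson iteration: the iteration
matrix I − dt β_0 J is LU-factorized (partial pivoting, via
`scipy.linalg.lu_factor`) once at the initial guess — the most recent
state — and the factors are reused across iterations.  Convergence is
declared when the max-norm of the update drops below ε_NR; if the
update norms stagnate (successive ratio > 0.9 three times in a row)
the matrix is re-evaluated and re-factorized once before the iteration
may fail.  A failed macro-step is retried once at a tenfold smaller
step and order 1; a second failure aborts the simulation with a
diagnostic rather than silently continuing.

After each stiff phase (one macro-step by default,
`bdf_steps_per_switch` to take more) the driver returns to the
explicit method at the initial step-size dt₀.  The published workflow
loops without stating a return condition; retry-after-one-macro-step
keeps the explicit method authoritative about whether stiffness
persists, at the cost of one rejected trial step per macro-step while
it does.

## Sampling and the driver loop

The state is recorded exactly at every sampling instant: the step-size
is clamped so integration lands on each instant, and no interpolation
is performed.  Terminal time is the last instant.  Negative
concentrations are not clipped — the ODE flow, not a projection,
defines the dynamics — but an excursion below −1e-9 is logged.  All
arithmetic is double precision, and two runs with identical inputs are
bit-identical (no internal randomness, fixed evaluation order).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| ε_j (`eps_rkf`) | 1e-12 | per-species tolerance on ER (units: concentration/time) |
| q (`bdf_order`) | 1 | BDF order in stiff phases |
| `dt_bdf` | 0.1 | implicit macro-step length (time) |
| ε_NR (`eps_nr`) | 1e-6 | Newton update tolerance (max-norm) |
| `max_it` | 10⁴ | Newton iteration cap |
| dt₀ (`dt0`) | 1e-3 | initial/restart explicit step (time) |
| ε_s (`eps_s`) | 1e-6 | step-size threshold declaring stiffness (time) |
| `delta_max` | 4 | growth cap of the step multiplier |
| `dt_max` | next-sample interval | absolute step cap (time) |

These are the reference parameterization under which all benchmark
simulations in the test suite are run.

## Synthetic benchmark models

The generator draws, per reaction, a reactant count r ∈ {1, 2} and a
product count p ∈ {1, 2} uniformly, then species uniformly with
replacement (dimerizations and duplicated products allowed); null
reactions (identical sides) are resampled.  A post-pass wires every
otherwise-unmentioned species into the product side of a random
reaction — into a free product slot when available, otherwise by
displacing a product unit that keeps at least one other occurrence —
and refuses specs that cannot cover all species (more species than
4·M reaction slots).  Initial concentrations are uniform in [0, 1),
kinetic constants log-uniform in [10⁻⁸, 1) (log₁₀ k uniform in
[−8, 0)), and the sampling grid is `linspace(0, t_max, n_samples)`
with t_max = 50 and 10 samples by default ("samples at regular
intervals"; the grid includes t = 0).  One seeded PRNG
(`numpy.random.default_rng`) governs the whole model and the seed is
recorded in the model metadata, so generation is byte-reproducible.

What these models exercise — sparse random topology, rate constants
spanning eight decades, sub-unit concentrations — is the scaling
structure of the method, not the biology of any curated pathway: they
have no conservation laws by construction, no modular or scale-free
topology, and no thermodynamic consistency between forward and
backward constants.  Tests passing on them demonstrate numerical
correctness of the pipeline under the stated distributions, not
predictive validity for a specific curated network.

## Verification strategy and measured behaviour

* The compressed evaluation is checked against an independently coded
  dense brute-force of (B − A)^T [K ∘ X^A] (20 seeded 16×16 models,
  1e-12 relative), and the analytic Jacobian against central finite
  differences (10 seeded 32×32 models, 1e-6 relative).
* Integrator structure and orders: six stages per explicit step;
  ER(dt)/ER(dt/2) in [8, 32] (the dt⁴ signature of the embedded
  pair); backward Euler global error halving in [1.7, 2.3] on
  dX/dt = −X; BDF identities exact on rationals.
* End-to-end: thirty seeded 64×64 models (10 samples, t_max = 50,
  defaults) against `scipy`'s LSODA at rtol = 1e-10, atol = 1e-14 on
  the dense right-hand side; the maximum relative deviation (absolute
  floor 1e-8) stays below 1e-4 at every sample.  The LSODA tolerances
  are deliberately much tighter than typical production settings so
  that the reference acts as an accuracy oracle and the measured
  deviation is dominated by this package's own error.
* Physical invariants: closed-network conservation to 1e-9 over
  [0, 50]; the A⇌B equilibrium (0.5, 0.5) to 1e-6; the stiffness
  detector fires on a k = 10⁴ / 10⁻² two-timescale pair and stays
  silent on a k ≈ 1 model.

Problem sizes in the test suite (16–64 species, 5–30 model replicates)
are chosen as the smallest sets that exercise every code path and
distributional claim; the generator and simulator accept arbitrary
M×N.

## Known limitations

* Only mass-action rate laws; no Michaelis–Menten or Hill kinetics,
  no SBML import, no rule-based model expansion.
* No variable-order/variable-step BDF in the LSODA sense: the stiff
  path uses fixed macro-steps of `dt_bdf`, so accuracy inside stiff
  phases is O(dt_bdf^q) and governed by that user choice, not by the
  explicit tolerance ε.
* The per-species tolerance ε is absolute (on ER); trajectories with
  very large concentrations make the explicit controller take
  correspondingly small steps.
* Step-sizes never exceed the inter-sample interval by default, so
  extremely sparse sampling grids trade speed for none of the usual
  dense-output machinery.
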