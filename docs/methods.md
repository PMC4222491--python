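# Methods

## The model class

`hiersd` analyses metabolic pathways that are regulated at two levels at once:

* **metabolically** — metabolite concentrations act directly on enzyme
  activities (substrate/product effects, allosteric feedback inhibition,
  feed-forward activation); and
* **through gene expression** — a sensed metabolite modulates transcription,
  and the resulting changes in enzyme concentration re-scale whole reaction
  rates on a slower time scale.

A `PathwayModel` holds metabolites, enzymes and mRNAs (`Species`), reactions
with modular rate laws (`Reaction`/`RateLaw`), and `GeneExpressionUnit`s.  The
metabolic layer follows `dX/dt = N·v(X, E)` with the stoichiometry matrix `N`
and rates proportional to the catalysing enzyme concentration.  A gene unit
with an explicit mRNA follows

    dR/dt = g_Trsc(x) − k_RD·R
    dE/dt = k_Trnl·R − k⁰ − k_ED·E ,          k_ED = μ + k¹_proteolysis

where `x` is the regulator, `k_RD` the mRNA turnover constant, `μ` dilution by
growth, `k¹` first-order and `k⁰` zero-order proteolysis.  Without an explicit
mRNA the two steps collapse to `dE/dt = g(x) − k⁰ − k_ED·E`.  Several enzymes
may share one mRNA (an operon).  Boundary species are clamped rather than
removed; moiety sums (e.g. ATP + ADP = C) are declared and respected by
construction.

The helper `dilution_rate(T) = ln2/T` converts a doubling time to the growth
dilution rate; for the fastest bacterial growth (T = 20 min) it is
5.8·10⁻⁴ s⁻¹, which is why dilution-dominated enzyme turnover is slow compared
with metabolism and gene-expression loops look *almost* integral.

### Sign conventions for the zero-order term

The zero-order proteolysis constant plays two roles.  As written it is a
degradation term, gated off (hard switch at E ≤ 1e-12) so that it cannot
consume protein that is not there.  But the same constant can be moved across
the enzyme balance and read as a constant synthesis contribution; a *negative*
`k⁰` is exactly that bookkeeping.  The ATP-module calibration exploits this:
holding the designed steady state and the synthesis constant `k_a` fixed while
sweeping the first-order degradation constant `k_b` forces
`k⁰ = k_a·ADP_ss − k_b·E_ss`, which turns negative for large `k_b`.  The
negative value is admitted explicitly (`allow_negative_k0`); the gate only
applies to positive `k⁰`.  Without this convention the fragility of the ADP
concentration could not reach its documented ceiling, the ATP/(ADP+ATP) ratio.

## Steady states and stability

`find_steady_state` relaxes the ODE system (LSODA) until a residual tolerance
of 1e-6 is met and then polishes with a root solve (Levenberg–Marquardt first,
`hybr` as fallback) to 1e-10.  Two numerical choices matter:

* **Scaled residuals.**  Residuals are measured per species relative to
  `max(1, Σ|rate contributions|)`.  On O(1) models this is the plain max-norm;
  on deliberately stiff calibrations (k_b = 1e6) the enzyme balance cancels
  O(1e6) terms and an absolute 1e-10 would sit below float cancellation noise.
* **Rank-deficient Jacobians are expected.**  Under ideal integral control an
  operon's enzymes obey identical balance equations, so differences like
  E₁−E₂ are conserved and the steady state is a manifold, not a point.
  Levenberg–Marquardt takes minimal-norm steps on such systems, and starting
  the relaxation from the pre-perturbation state keeps every perturbation
  experiment on its physical branch.  Zero eigenvalues from these neutral
  directions count as stable; the stability flag only rejects eigenvalues with
  real part above 1e-7.

Moiety conservation is enforced by eliminating one species per declared sum
(the largest-coefficient member, last on ties) before the Newton step.
Relaxation gives up early when the residual shows no decade-scale decrease
(drift, e.g. a pathway without a sink) or when the integrator exceeds its
evaluation budget (sliding along the zero-order degradation switch).  The
integration budget is 1e6 time units.

The end-product template additionally admits a one-dimensional construction:
the steady end-metabolite concentration solves
`f₁(x̄₁, x_n)·g(x_n)/k_ED = f_n(x_n)`, supply falling and demand rising in
`x_n`, so the root is unique and is found by bracketing/`brentq` (1e-12).
`validate_model` samples both curves on a grid to confirm the monotonicity
this relies on.

## Elasticities, control, robustness

Direct elasticities `ε = ∂ln v/∂ln x` are central log-differences of the
isolated rate law (relative step 1e-5, one Richardson extrapolation).  For
members of a conserved cycle the variation moves along the conservation sum —
that is what makes the demand elasticity of the ATP module equal
`−ADP/(C−ADP)` rather than 0.

Control coefficients `∂ln(target)/∂ln(activity)` are computed by scaling a
process activity to `1±1e-4` and re-solving the steady state on both sides.
The *scope* defines the system: `metabolic` freezes enzymes and mRNAs at
their steady levels (classical MCA), `hierarchical` lets gene expression
respond (HCA), `local` isolates a declared block with its boundary species
clamped.  Fragility F is identical to the hierarchical coefficient;
robustness ℜ = 1/F is reported as infinite below 1e-8 (the numeric noise
floor of the two-sided scheme).

Theorem-based shortcuts — the four supply–demand coefficients from two block
elasticities, local chain flux control from summation + connectivity rows,
and the hierarchical supply–demand coefficient

    H_s^X = 1 / (ε_X^d − ε_X^s − ε_Es^s·ε_X^a/(ε_Es^b − ε_Es^a)) = −H_d^X

— are implemented independently of the numeric route and the two are held to
agree to 1e-3 (relative) in the test suite.  When enzyme synthesis and
degradation are both zero order in the enzyme the indirect term diverges and
H_s^X is exactly zero: gene expression absorbs the whole perturbation.  The
supply–demand formulas assume the linear supply→X→demand orientation; the
ATP module, whose supply *consumes* the controlled species, is handled by the
numeric path and its own closed forms rather than by forcing an orientation.

## The ATP-module oracle

For the two-step ATP/ADP module everything has a closed form
(`hiersd.atp_oracle`), parameterized by the design target `ADP_ss`:

* steady state `E_ss = k_d(C−ADP_ss)/(k_s·ADP_ss)`,
  `k⁰ = k_a·ADP_ss − k_b·E_ss`;
* hierarchical control `H^E = 1 − 1/(1+φ)`, `H^J = 1 − (ADP_ss/C)/(1+φ)` with
  `φ = k_s·ADP_ss²·k_a/(k_d·C·k_b)`; both 1 in the zero-order limit k_b = 0
  (robust perfect adaptation);
* fragility `F = (C−ADP_ss)/(C + ADP_ss²·k_s·k_a/(k_d·k_b))`, a hyperbola in
  k_b with ceiling `(C−ADP_ss)/C` and half-maximum at
  `k_b = (ADP_ss²/C)·k_s·k_a/k_d`, where `H^E = 1/2`;
* the elasticity decomposition `1/H_d^ADP = C/(C−ADP_ss) + 1/ε_E^b`, equal to
  the kinetic expression identically (held to 1e-12 in tests).

Sweeps over k_b recalibrate `k⁰` (k_a fixed) by default, so every point keeps
the designed steady state; `k_b = 0` is a first-class value returning the
exact limits, not an epsilon hack.

## Adaptation, tracking, classification

`adaptation_report` steps a parameter, re-solves, and calls adaptation
*perfect* when every designated controlled variable returns to within 1e-6
(relative) of its pre-perturbation value; the raw deviations are reported so
users can re-threshold.  `tracking_report` steps the zero-order proteolysis
constant — the loop's reference signal r — and compares the steady mRNA level
with `r/k_Trnl` (ideal tracking) and with the always-valid identity
`(k_ED·E_ss + r)/k_Trnl`.  `classify_control_loop` is deliberately *not*
structural: the category follows from the elasticity of total enzyme
degradation w.r.t. the enzyme, `ε_E^b` — 0 means ideal integral control,
positive means a leaky pseudo-integral loop, and a unit that does not sense a
system metabolite (constant transcription, clamped regulator, or a unit
sensing its own product) leaves only direct (proportional-like) regulation.
Whether a biological loop is an integrator is a question about kinetic
orders, not about whether protein synthesis takes time.

`linear_decomposition` splits the moiety-reduced Jacobian into the
proportional block (metabolite responses with enzymes frozen), the
metabolite–enzyme coupling and the integral-path gain (sensitivity of the
enzyme balances to the metabolites), and re-derives the proportional block
independently with frozen gene expression as a self-check (agreement ~1e-8).

## Fixture models and what they do (not) show

All fixture kinetics are this package's own synthetic choices — none are
fitted to data or taken from published models.  Hill forms with coefficient 2
implement the monotone regulation the theory requires without switch-like
steepness; defaults are chosen so that every fixture has a stable, strictly
positive steady state with concentrations of order one, verified at
construction.  Problem sizes are deliberately small (2–9 species), which is
what the theory targets: supply–demand thinking compresses a pathway to the
blocks around one linking metabolite.

* `atp` / `atp_integral`: k_s = k_d = C = k_a = 1, ADP_ss = 0.5, k_b = 0.25
  (k⁰ = 0.25) / k_b = 0 (k⁰ = 0.5).
* `end_product` / `end_product_integral`: S = 1 clamped, three unit-k_cat
  conversions with the first Hill-inhibited by x₃ (K_I = 1, h = 2), linear
  demand k = 1, operon transcription `1/(1+x₃²)`, k_RD = k_Trnl = 1,
  k⁰ = 0.5, k_ED ∈ {0, 0.2, 0.4}.  With k_ED = 0 the steady state is
  (x₃, mRNA, E) = (1, 0.5, 2) exactly, and the reference step 0.5→0.4 moves
  the steady mRNA from 0.5 to 0.4.  Because the first reaction is
  product-insensitive and the demand uncatalysed, the end metabolite is
  rigorously independent of the intermediate conversions — so perturbation
  experiments that are meant to move x₃ target the *demand* activity, while
  perturbing an intermediate step demonstrates the independence property.
* `initial_product`: v₀ = 1, Hill-activated synthesis of the consuming enzyme
  (k = 0.4, K_A = 1, h = 2), k_ED = 0.2; steady state x₁ = x₂ = E₁ = 1.
  Feed-forward activation of a downstream enzyme acts as negative feedback:
  raising E₁ depletes x₁ which lowers E₁ synthesis.
* `leucine`: a three-step biosynthetic skeleton (committed step inhibited by
  the end product; two downstream enzymes gene-activated by the first
  intermediate; dilution-only turnover μ = 1e-2).  It reproduces the
  qualitative behaviour of such pathways — small but nonzero supply control
  of the intermediate, imperfect but attenuated adaptation — not any
  published parameterization.

Passing tests on these fixtures demonstrate the internal consistency of the
framework (theorems vs. numerics, closed forms vs. simulation, the
equivalence of "perfect adaptation", "ideal integral" and "zero fragility"),
and the qualitative laws that are parameter-free (monotonicity in the leak
rate k_ED, the hyperbolic fragility curve, the kinetic-order criterion).
They do not validate any particular organism's kinetics: real pathways have
crowded, saturable, multi-substrate kinetics, correlated noise and
growth-rate feedback onto μ, none of which the generators emulate.

## Known limitations

* No SBML/Antimony import, no spatial or stochastic kinetics, no
  thermodynamic (Haldane) constraints.
* No frequency-domain analysis: the fast-metabolic/slow-genetic division of
  labour is only visible here as time-scale separation in trajectories.
* No derivative-control detection and no bifurcation analysis beyond the
  steady-state stability flag.
* Control coefficients are numeric (re-solving steady states); symbolic
  derivation for arbitrary networks is out of scope.
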