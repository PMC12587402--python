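# Methods

## Problem and model

The package optimizes three formulation-stability objectives of a
monoclonal antibody simultaneously — melting temperature Tm (°C),
diffusion interaction parameter kD (mL/g) and retained monomer after
agitation RM (%) — over six independent variables: sorbitol (0–550 mM),
arginine (0–250 mM), pH (4.5–7.5) and the fractions of aspartic acid,
glutamic acid and HCl in the pH-adjustment acid mix (acetic acid is the
simplex remainder). Histidine buffer is fixed at 10 mM. All three
objectives are maximized. Two constraints define feasibility: the acid
fractions must sum to at most one, and the estimated osmolality must lie
in the injectable window 100–600 mOsm/kg.

## Chemistry

Every component is modeled as a polyprotic acid/base with a pKa ladder
and the charge of its fully protonated form; speciation is classical
alpha-fraction chemistry with Kw = 1e-14. The shipped pKa set (editable
`SPECIES_DB`) uses standard CRC/biochemistry values: His 1.82/6.04/9.17,
Arg 2.03/9.00/12.10, Asp 1.99/3.90/9.90, Glu 2.10/4.07/9.47, acetic
4.76; HCl fully dissociated. Histidine and arginine enter as free bases
titrated by the added acids. Activity coefficients, ionic-strength pKa
corrections and temperature dependence are out of scope; with a
different pKa convention the feasibility boundary shifts slightly, which
is why the database is a plain editable table.

The forward solver finds the pH zeroing the charge balance by Brent
root-finding on [0, 14] (|residual| < 1e-10 M). The inverse problem —
the total acid concentration C reaching a target pH at given fractions —
exploits the fact that at fixed pH all speciation fractions are
constants, so the charge balance is *linear* in C and has a closed form
C = −(base charge + [H⁺] − [OH⁻]) / Σ f_x·q_x(pH). A negative C (target
above the acid-free pH) or C beyond a 2 M cap is reported as an
infeasible target. The closed form makes constraint evaluation cheap
(~40 µs per design point), which matters because the NSGA-II rejection
loop evaluates it tens of thousands of times per batch; tests verify it
against an independent bisection oracle on the forward solver and a
1 µM local grid search.

Osmolality is the ideal sum of analytical solute particles: sorbitol +
histidine + arginine + total acid (each weak acid's conjugate pair
counts once; HCl contributes its chloride), with molar taken as molal
and no osmotic coefficients. This is the simplest defensible model and
is isolated behind `estimate_osmolality` so it can be swapped.

A derived acetic fraction below zero marks the point infeasible
("fraction simplex violated"); it is never clipped silently.

## Surrogates

One independent `ObjectiveGP` per objective: targets standardized to
zero mean/unit variance (floor 1e-8 on the sd, with a warning, for
degenerate constant targets), Matérn 5/2 kernel with per-dimension
length scales (bounds [1e-2, 1e2] on the unit cube) times an output
variance, plus a learned white-noise term (floor 1e-8) — triplicate
measurements imply observation noise, so the noise level is estimated
jointly by MLE rather than fixed. The marginal-likelihood optimization
uses 10 starts (1 + 9 restarts), seeded. Replicates are averaged to one
target per formulation before fitting. Predictions are de-standardized
to raw units. The numerical backend is scikit-learn's
`GaussianProcessRegressor`; tests check the posterior against an
independent hand-rolled Matérn 5/2 linear-algebra path at fixed
hyperparameters.

## Pareto search and hypervolume

NSGA-II is implemented directly (non-dominated sorting, crowding
distance, binary tournament) with canonical operator defaults the
method itself leaves open: simulated binary crossover (η = 15,
p = 0.9), polynomial mutation (η = 20, p = 1/d). Constraints are
handled strictly by discard-and-retry of genetic moves (retry cap 1000
per slot), never by penalties, so the population is feasible at all
times. Default budget is population 100 × 100 generations; the
closed-loop tests and the worked example use 40 × 40, which reaches the
same qualitative fronts at desk scale. The returned front is the final
population's mutually non-dominated, de-duplicated subset.

Hypervolume uses an exact sweep algorithm for up to three objectives
(maximization convention) and is cross-checked against a 10⁶-sample
Monte-Carlo oracle. The reference point for traces is the per-objective
minimum of the standardized observations minus 0.5, fixed once per
report so the trace is comparable across iterations; absolute
hypervolume values depend on this choice, only the monotone shape is
meaningful.

## Acquisition

Each suggestion draws a route: exploitation with probability 0.75,
exploration otherwise (per-suggestion draws, so a batch of five averages
about four exploit picks and one explore pick). Exploitation picks the
Pareto-front candidate maximizing w·d_obj + (1−w)·d_var, where d_var /
d_obj are minimum Euclidean distances to prior observations in variable
space and standardized objective space, each divided by its maximum
over the front; w = 0.5 is the symmetric default since only "linearly
combined" is prescribed. Ties break to the lowest candidate index.

Exploration minimizes the Steinerberger proximity sum
S(x) = Σ_p Π_d (1 − log(2 sin(π|x_d − p_d|))) — the product-form
low-discrepancy energy kernel, isolated behind one function so an
alternative kernel is a one-line swap — by bounded Nelder–Mead from 20
random feasible starts (200 iterations each); infeasible iterates get a
1e12 sentinel, which also replaces the +∞ of the log singularity at a
coordinate coincidence. The best feasible point ever evaluated is
returned.

Batches are greedy Kriging believer: after each pick, every objective
GP is refit (hyperparameters re-estimated) on its training data plus
the pick's posterior mean, and the pick joins a fantasy history used by
both routes, so a batch of n retrains each model n−1 times. A duplicate
pick is perturbed (σ = 1e-3) and re-checked once, then raises.

## Campaign

Initialization draws 13 uniform unit-cube points rejection-sampled to
feasibility (uniform-and-reject keeps the marginal uniform on the
feasible region; all initial points must be measurable). The ledger —
iteration index, route label, the 14 formulation columns, three
objectives — is the single source of truth; models are derived
artifacts, never authoritative state. Hypervolume traces standardize
over the full current ledger and are rebuilt from scratch at each
report. The MAE trace refits surrogates on iterations < t and scores
iteration t in raw units. Spearman correlations use mid-ranks
(scipy). Determinism: one `numpy` Generator seeded from the config
drives route draws, NSGA-II, exploration restarts and the GP restart
seeds, so a fixed config + seed + virtual lab reproduces the ledger
byte-for-byte.

## Virtual lab

The generator emulates the qualitative response structure of real mAb
excipient screens: Tm = 66 + 1.2(pH−4.5) + 3s/(s+150) − 2a/250;
kD = −25 + 18(7.5−pH) + 15(2r−r²) − 0.2a with r = s/324;
RM = min(100, 70 + 28·logistic(0.01s − 0.03a + 1)), s = sorbitol mM,
a = arginine mM. So: Tm rises with pH and (saturating) sorbitol; kD
falls with pH, peaks at 324 mM sorbitol and drops 0.2 mL/g per mM
arginine; RM plateaus at 90–100%. Coefficients are synthetic fixtures
chosen so the best achievable values sit near realistic optimized
magnitudes (kD ≈ 44 mL/g, Tm ≈ 72 °C); they are not fitted to any
measured data set, and passing tests demonstrate the algorithm recovers
*this* structure, not that it would reproduce any particular wet-lab
campaign. Real-data features deliberately absent: acid-identity effects
on the objectives, multi-transition melt curves, heteroscedastic or
correlated replicate noise, plate/batch effects.

Simulated measurements go through the real assay code: a logistic melt
curve (baseline 0.80, amplitude 0.30, width 2 °C, 0.5 °C grid from 25
to 90 °C) whose midpoint is the true Tm plus N(0, 0.2 °C) per
replicate; a DLS dilution series at 2/3.25/4.5/5.75/7 mg/mL with
D₀ = 60 (arbitrary consistent units — kD only uses slope/intercept),
per-replicate slope jitter N(0, 1.5 mL/g) and 0.5% multiplicative point
noise; agitation concentrations (c_ref = 1 mg/mL) implying the true RM
plus N(0, 2 pp). Three replicates are averaged. With all noise at zero
the pipeline recovers the surfaces to the assay-grid tolerances
(Tm ± 0.25 °C from the 0.5 °C grid, kD ± 1e-6, RM ± 1e-9), which is the
core round-trip check for the assay module.

## Assay numerics

Tm extraction smooths the ratio with a Savitzky–Golay filter (window 9,
order 3 — the vendor software's smoothing is unspecified, so a standard
choice), takes the central-difference derivative, returns the *global*
maximum (multi-transition disambiguation is left to the caller) refined
by a three-point quadratic, and raises if the maximum derivative is
below a prominence floor of 5e-3 ratio units/°C. kD is an ordinary
least-squares fit of D on c; slope/intercept in mL/mg is scaled by 1000
to mL/g; a constant series gives kD = 0 with R² = 0 by convention; a
non-positive intercept is an error. RM above 100% (shaken concentration
exceeding the reference) is returned as-is for the caller to flag.

## Problem sizes used in tests

Unit tests run NSGA-II at populations 10–24 over 3–15 generations and
micro-campaigns of 5 + 2 observations; the end-to-end acceptance
campaign uses the full 13 + 4×5 design at NSGA-II 40 × 40, which runs
in well under five minutes on one CPU. The 100,000-draw route-frequency
check uses the 3σ binomial band (±0.41 percentage points around 75%).

## Known limitations

- The chemistry module assumes ideal solutions; absolute feasibility
  boundaries depend on the pKa set and osmolality model chosen.
- Exact numeric identity with other Steinerberger-sum or
  distance-weight conventions is not claimable; both are configurable.
- Hypervolume is exact only to three objectives.
- The virtual lab is a test harness, not a mechanistic biophysics
  model; no preferential-exclusion or electrostatic theory is encoded.
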