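# formubo

Constrained multiobjective Bayesian optimization for antibody (mAb)
formulation design.

Monoclonal-antibody drug products must trade off several stability
objectives at once — thermal stability (melting temperature *T*ₘ, °C),
colloidal stability (the diffusion interaction parameter *k*_D, mL/g;
positive means net repulsive self-interactions), and interfacial
stability (retained monomer after agitation stress, RM %). The
formulation variables are excipient levels and pH, and the chemistry
imposes hard constraints: the acid fractions used for pH adjustment must
form a simplex, and the osmolality of an injectable must stay within
100–600 mOsm/kg. `formubo` is for formulation scientists who want to run
such a campaign sequentially: measure a small batch, update the models,
and let the algorithm propose the next batch.

## Method

- **Design space** (6 independent variables): sorbitol 0–550 mM,
  arginine 0–250 mM, pH 4.5–7.5, and the relative fractions
  *f*_Asp, *f*_Glu, *f*_HCl of the pH-adjustment acids (acetic acid is
  the simplex remainder); histidine buffer fixed at 10 mM. The total
  acid concentration is implicit: it is whatever titrates the base
  mixture to the target pH, found from alpha-fraction speciation and
  charge balance (`formubo.chemistry`).
- **Surrogates**: one independent Gaussian process per objective,
  Matérn 5/2 kernel with per-dimension length scales on the unit
  hypercube, standardized targets, hyperparameters (including a noise
  term) by multi-restart maximum marginal likelihood
  (`formubo.surrogate`).
- **Exploitation (p = 0.75)**: NSGA-II (population 100, 100 generations;
  constraint-violating genetic moves are discarded and retried) evolves
  a Pareto front of the surrogate means; the selected experiment is the
  front member maximizing a 50/50 combination of its max-normalized
  minimum distances to prior observations in variable space and in
  standardized objective space (`formubo.pareto`, `formubo.acquisition`).
- **Exploration (p = 0.25)**: minimize the Steinerberger proximity sum
  S(x) = Σ_p Π_d (1 − log(2 sin(π|x_d − p_d|))) over the feasible region
  from 20 random starts, yielding a space-filling point.
- **Batching**: greedy Kriging believer — after each of the 5 picks,
  every surrogate is refit with its posterior mean at the pick treated
  as a real observation.
- **Campaign**: 13 uniform feasible initialization points, then batch
  iterations; convergence is tracked by the hypervolume of the
  standardized objective vectors (exact ≤3-D algorithm), model quality
  by a per-iteration mean-absolute-error trace, and excipient effects by
  Spearman correlations (`formubo.campaign`).
- **Measurement models** (`formubo.assays`): *T*ₘ from the maximum first
  derivative of the 350/330 nm fluorescence ratio; *k*_D from the linear
  fit D = D₀(1 + k_D c) over a 2–7 mg/mL dilution series;
  RM% = 100 − (c_ref − c_shaken)/c_ref × 100.
- **Virtual lab** (`formubo.virtual_lab`): synthetic ground-truth
  response surfaces with the field's qualitative structure (pH↑ → Tm↑
  and kD↓; sorbitol optimum near 300 mM; arginine strongly detrimental
  to kD; RM plateau 90–100%) plus replicate noise, feeding raw simulated
  instrument data through the real assay pipeline so full closed-loop
  campaigns run without a wet lab.

## Worked example

Run a full simulated campaign (13 + 4×5 = 33 experiments; NSGA-II at
population 40 / 40 generations for desk-scale speed) and build the
report:

```bash
cat > config.yaml <<EOF
pop: 40
gens: 40
seed: 1
EOF
formubo simulate-campaign --config config.yaml --out ledger.csv
formubo report --config config.yaml --ledger ledger.csv --outdir report/
```

Output:

```
wrote 33-row ledger to ledger.csv
wrote report to report/
```

`report/hypervolume_trace.csv` shows the dominated objective-space
volume (standardized objectives, fixed reference point) growing at every
iteration — the optimizer keeps finding formulations that extend the
Pareto front:

```
iteration,hypervolume
0,39.66937796890618
1,46.3000639793753
2,48.3284948620227
3,49.483871304187474
4,50.278127694817336
```

The ledger itself shows the campaign discovering the structure of the
problem: the best colloidal stability found is kD = 43.5 mL/g at pH 4.50
with 0 mM arginine and 316 mM sorbitol (arginine eliminated, sorbitol
near its ~320 mM optimum, pH at the acidic edge where electrostatic
repulsion is strongest), while the best thermal stability is
Tm = 72.0 °C at pH 7.50 — the classic Tm/kD pH trade-off. The MAE trace
(`report/mae_trace.csv`) shows the Tm surrogate's one-iteration-ahead
error shrinking from 0.30 to 0.10 °C as data accumulate.

For a real (non-simulated) campaign the same loop is `formubo init` →
measure → `formubo record` → `formubo suggest` → repeat, with the ledger
CSV as the single source of truth.

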