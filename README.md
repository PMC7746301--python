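# loopstate

Structure and bistability analysis of a six-variable positive-feedback-loop
ODE model of motor-neuron energy metabolism, in which a constant input
(mutant SOD1) disturbs mitochondrial oxidative phosphorylation and three
overlapping positive loops couple OXPHOS, AMPK, PFK3, the pentose phosphate
pathway, glutamate and APC-Cdh1.

The package has two faces:

* **Parameter-free structural analysis** of the signed interaction graph:
  the interaction sign matrix, input sign vector, simple-loop census with
  loop signs, candidate-multistationarity (all loops positive), monotone
  gauge detection (variable sign flips making the Jacobian pattern
  Metzler), and the structural influence matrix — the sign pattern of
  adj(−J), computed symbolically by term expansion with the remaining
  entries resolved by the monotone/stability theorem, and cross-checked by
  a Monte-Carlo determinant oracle restricted to Hurwitz realizations.
* **Numerical dynamics** for concrete Hill-function parameterizations:
  stiff simulation, multistart equilibrium finding with stability and
  healthy/pathological labeling, numerical verification of every influence
  sign by perturbation experiments, a closed-form knockout steady state,
  bifurcation sweeps of the strength `mu` of the shared PFK3 ⊣ PPP edge
  (fold detection, bistable window, hysteresis), and a random-instance
  search for bistable regimes.

Since no measured kinetic parameters exist for this model, the shipped
reference instance uses unit scales/saturations/time constants, Hill
exponent 4 and input level u = 2; its `mu`-sweep shows the 1 → 3 → 1
fold pair (window ≈ [1.02, 1.64]) and the pinned bistable pair at
`mu = 1.3` is frozen in `loopstate.scenario`.

Note on orientation: with the modeled form `h5(k) = mu * h(k)`, raising
`mu` *increases* PPP production, so stable-branch PFK3 is nonincreasing in
`mu` (this follows from the influence matrix). The pathogenic direction —
strengthening the PFK3 ⊣ PPP inhibition — therefore corresponds to
decreasing `mu`: the quasi-static down-sweep is the one that falls onto
the unique high-PFK3, low-OXPHOS (pathological) branch.

## Command line

```bash
loopstate structure --builtin als --tables        # sign matrices, loops, gauge, influence
loopstate equilibria --builtin als --seed 1       # all equilibria + health labels
loopstate simulate --builtin als --t-end 100 --out traj.csv
loopstate bifurcate --builtin als --out diagram.csv --summary summary.json [--plot fig.png]
loopstate knockout --builtin als --edge h5        # remove the shared edge
loopstate hysteresis --builtin als                # quasi-static up/down sweep
loopstate verify-influence --builtin als          # perturbation check of influence signs
loopstate search-bistable --n 100 --seed 0        # random bistable instances
loopstate reproduce --out-dir reproduction        # run + assert every claim
```

Any command accepts `--model spec.yaml` instead of `--builtin als`; the
schema is documented in `loopstate/cli_io.py` and a spec for the built-in
model can be produced with `loopstate.cli_io.save_model_spec`.

## Layout

```
src/loopstate/
  model_core.py           network, Hill responses, rhs, Jacobian
  structural_analysis.py  sign matrices, loops, gauge, influence
  dynamics.py             simulation, equilibria, health, verification
  bifurcation.py          knockout closed form, mu sweeps, hysteresis
  scenario.py             random sampling, bistable search, pinned fixture
  cli_io.py               model-spec IO, reports, claim reproduction
  cli.py                  click entry point
tests/                    unit + property tests, tests/test_acceptance.py
scripts/acceptance.py     standalone acceptance report
```
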