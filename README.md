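# canningsim

Forward simulation and branching-process analysis of Cannings population
models with selection, built on Dirichlet-type paintbox weights
`W_i = Y_i / (Y_1 + ... + Y_N)` with i.i.d. positive `Y_i`.  The package
estimates fixation probabilities of a single beneficial mutant, provides
exact small-chain and generating-function oracles, and checks the
first-order prediction `2s / rho^2` (with `rho^2 = E[Y^2]/E[Y]^2`) and its
finite-N refinement `1/N + 2s/rho^2` at desk scale.

## Layout

- `canningsim.offspring_laws` — laws of the positive variable `Y`
  (deterministic, gamma, lognormal, pareto, two-point, table) with exact
  moments, samplers, `rho^2`, and an exponential-moment feasibility flag.
- `canningsim.paintbox` — per-generation exchangeable weights, multinomial
  offspring, the variance identity `Var(nu_1) = N(N-1)E[W_1^2]`, and
  concentration diagnostics for the weights.
- `canningsim.cannings` — the frequency process of the beneficial type:
  scalar and vectorized simulation, Monte-Carlo fixation estimates with
  Wilson intervals, an exact dense-solve oracle for deterministic weights,
  and the skewed-weight counterexample scheme.
- `canningsim.galton_watson` — slightly supercritical branching machinery:
  mixed-Poisson / mixed-binomial / two-point / explicit offspring laws,
  survival probabilities via pgf fixed points, immortal-line (skeleton)
  offspring laws, an exact two-point DP with lumped overflow, and the
  threshold-generation rule.
- `canningsim.experiments` — ratio sweeps, the three-phase decomposition of
  fixation, the counterexample experiment, and CSV/JSON output.

## CLI

```sh
canningsim simulate --n 2000 --cb 1,0.3 --y gamma:2 --scheme dirichlet_type \
    --x0 1 --reps 20000 --seed 1 --out results.csv
canningsim sweep --grid '[[500, [1.0, 0.3], "gamma:2", "dirichlet_type"]]' \
    --reps 10000 --seed 1 --out sweep.csv
canningsim phases --n 2000 --cb 1,0.3 --y gamma:2 \
    --levels b+delta:0.1,eps:0.02 --reps 20000 --seed 1
canningsim counterexample --n 10000 --gamma 0.1 --cb 1,0.3 --reps 300000
canningsim gw survival --y gamma:2 --s 0.01
canningsim gw dp-bounds --beta 0.5 --s 0.2 --delta 0.5
```

`sweep`, `phases` and `counterexample` also accept `--config config.json`
whose keys override the flags (same names as the flags).

Y laws are written `family:param[,param]`, e.g. `gamma:2`,
`deterministic:1`, `pareto:3`, `two_point:0.5,1.5`, `table:1@0.5,3@0.5`;
they are normalized to mean one by default.

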