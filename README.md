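# prosofix

Exact fixation probabilities for producers of social goods on
graph-structured populations, at **arbitrary selection intensity**.

Most theory on the evolution of cooperation on graphs lives in the
weak-selection limit, where payoffs barely perturb reproduction. Between
the extremes of pure drift and deterministic selection, richer things
happen: stochastic payoff schemes decouple from their mean-field
analogues, the way mutants first appear starts to matter, and global
competition for reproduction — usually hostile to altruism — can develop
a "sweet spot" of intermediate selection where producers of social goods
are favored. `prosofix` is a small toolkit for exploring exactly this
regime, intended for researchers in evolutionary game theory and
population dynamics who want exact (not simulated, not linearized)
numbers for finite structured populations.

## The model

A population of `N` individuals occupies the nodes of a connected,
symmetric, weighted graph with adjacency `w_ij` and random-walk step
probabilities `p_ij = w_ij / Σ_k w_ik`. Each individual is a producer
(`C`) or non-producer (`D`). Producers create a social good of benefit
`b` at cost `c`, distributed in one of three ways:

| scheme | cost to producer | benefit to neighbor `j` |
| ------ | ---------------- | ----------------------- |
| `pp`   | `c` per neighbor | `b` to every neighbor |
| `ff`   | `c` total        | `b·p_ij` (evenly divided) |
| `cf`   | `c` total        | whole `b` to **one** neighbor drawn with probability `p_ij` |

`cf`-goods make payoffs a stochastic function of the configuration;
`ff`-goods are their mean-field analogue (the expected `cf` payoff
vector equals the `ff` payoff vector exactly — the dynamics coincide
only under weak selection).

Payoff `u` becomes fecundity through `F(u) = e^{δu}` with selection
intensity `δ ≥ 0` — the unique map (up to rescaling `δ`) that is
nonnegative, non-decreasing, continuous, and makes competition invariant
under adding a constant payoff to all competitors. Competition is the
softmax `F_i / Σ_{j∈I} F_j`, evaluated in shifted-exponent form so
nothing overflows. If selection acts on survival instead, the weight is
`e^{−δu}`.

Two update rules: **death-Birth** (`dB`: a uniformly random individual
dies; its neighbors compete, proportionally to fecundity, to fill the
vacancy) and **Birth-death** (`Bd`: an individual reproduces with
probability proportional to fecundity over the whole population; the
offspring replaces a random neighbor). For stochastic payoffs,
transition probabilities take the expectation of the competition *ratio*
over recipient scenarios.

The fate of a rare mutant is its fixation probability `ρ`, obtained by
solving `ρ = Pρ` over the chain's state space with absorbing
monomorphic boundaries. Mean fixation probabilities `ρ_C^μ, ρ_D^μ`
weight the single-mutant states by the mutant-appearance distribution:
`uniform` (1/N per node) or `temperature` (proportional to each node's
replacement rate in the resident monomorphic state). Four conditions
classify the effect of selection at each `δ`:

- `A0`: `ρ_C(δ) > ρ_C(0)` — favored absolutely vs. neutral drift;
- `A′`: `ρ_C′(δ) > 0` — favored absolutely vs. intensity `δ`;
- `R0`: `ρ_C(δ) > ρ_D(δ)` — favored relative to `D` (equivalently the
  rare-mutation stationary fraction `ρ_C/(ρ_C+ρ_D)` exceeds 1/2);
- `R′`: `ρ_C′ρ_D > ρ_Cρ_D′` — the stationary fraction is increasing.

Engines: an exact reduced chain for the cycle under `dB` (cluster-size
states), an exact reduced chain for the star under `Bd` (hub trait ×
producer-leaf count), a brute-force `2^N` chain for any graph (small
`N`), an `O(N)` closed form for `ff`-goods on the star built from
conditioned transition probabilities `P̃_{x→y} = P_{x→y}/(1−P_{x→x})`,
and a seeded Monte Carlo sampler for cross-checks.

## Worked example

Producers of `ff`-goods on a star of 10 nodes under Birth-death
updating, temperature initialization, `b = 5`, `c = 1`:

```python
from prosofix import EvolutionModel, GoodsScheme, sweep, evaluate_conditions

model = EvolutionModel("star", "Bd", GoodsScheme("ff", 5, 1), N=10,
                       init="temperature")
sr = sweep(model, [0.1, 0.5, 1.0, 2.0, 5.0])
print(f"neutral rho_C = rho_D = {sr.rho_C0:.6f}")
for d, rc, rd, ratio in zip(sr.grid, sr.rho_C, sr.rho_D, sr.ratio_to_neutral):
    print(f"delta={d:4.1f}  rho_C={rc:.6f}  rho_D={rd:.6f}  x{ratio:5.2f} neutral")
```

prints

```
neutral rho_C = rho_D = 0.021951
delta= 0.1  rho_C=0.018393  rho_D=0.073342  x 0.84 neutral
delta= 0.5  rho_C=0.031594  rho_D=0.000000  x 1.44 neutral
delta= 1.0  rho_C=0.017769  rho_D=0.000000  x 0.81 neutral
delta= 2.0  rho_C=0.004398  rho_D=0.000000  x 0.20 neutral
delta= 5.0  rho_C=0.000042  rho_D=0.000000  x 0.00 neutral
```

Weak selection (`δ = 0.1`) *disfavors* producers (`ρ_C` below its
neutral value 0.0220 and far below `ρ_D`), as classical results for
Birth-death updating predict. But at `δ = 0.5` producers are favored
both absolutely (1.44× neutral) and relative to non-producers, whose
fixation probability has collapsed — the drift/selection sweet spot.
Push selection harder and producer fixation dies away again.
`evaluate_conditions(model, delta)` returns the `A0/A′/R0/R′` flags with
their raw margins and the finite-difference step used.

The same computation from the shell, writing
`star_sweep.csv`, `star_conditions.csv` and `star_meta.json`:

```
prosofix star-bd --N 10 --scheme ff --b 5 --c 1 --init temperature \
    --delta-grid 1e-3:10:200 --out star
```

`prosofix cycle-db` and `prosofix general --graph adj.txt --rule Bd`
work the same way (the latter accepts any whitespace-delimited symmetric
adjacency matrix), and `prosofix mc-check` replays a configuration
through the Monte Carlo sampler and compares against the exact solver.

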