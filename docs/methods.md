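# Methods

## Model and assumptions

The population is a fixed, connected, symmetric weighted graph on `N`
nodes; one individual per node; two heritable types, producer `C` and
non-producer `D`; no mutation during an invasion (the rare-mutation
regime, where each invasion resolves to fixation or extinction before
the next mutant appears). Selection enters only through payoffs: payoff
`u` maps to fecundity `e^{δu}` (reproduction mode) or to the death
weight `e^{−δu}` (survival mode). The exponential form is not an
arbitrary choice from a family: it is the only map that is nonnegative,
non-decreasing, continuous, treats `δ` as a payoff amplifier, and makes
every within-group competition `F_i/Σ_j F_j` invariant under a common
payoff shift. The package implements that conclusion and tests the
invariance property; it does not carry the derivation symbolically.

All competition ratios are computed as shifted-exponent softmax
(equivalently in log space), so quantities stay finite for `δ·|u|` up to
at least 1e4. Kernel entries are assembled in linear space from those
outputs; entries may be clipped into `[0, 1]` only within 1e-14, and
larger violations raise rather than clip, to separate rounding dust from
logic errors.

## Payoff schemes, including stochastic goods

`pp`: producer `i` pays `c·s_i` (`s_i` = weighted degree) and donates
`b·w_ij` to each neighbor. `ff`: producer pays `c` and donates
`b·p_ij`. `cf`: producer pays `c` and donates the whole `b` to a single
neighbor drawn with probability `p_ij`, independently at every time
step. The classical model is unweighted; the `p_ij` generalization is
this package's choice for weighted graphs (it reduces to "a uniformly random
neighbor" and "divided evenly" when weights are equal) and is the one
place the interface goes beyond the published setting.

A `PayoffDistribution` enumerates the joint recipient assignments of the
producers as (probability, payoff-vector) scenarios, merging assignments
with identical payoff vectors. Expectations are always of the
competition *ratio* per scenario — never softmax of the expected
payoffs; the tests include a case where the two differ. Because only
producers adjacent to a competing group can change that group's payoffs,
kernel construction passes a relevance set and enumerates just those
producers (the skipped producers contribute their expected donation,
which cannot affect the queried entries). This keeps exact `cf`
computation to ≤ `Π deg` scenarios over a handful of boundary producers
on the cycle and ≤ `N − 1` scenarios on the star. Exhaustive enumeration
beyond a configurable cap (default 20 enumerated producers with more
than one neighbor, or 1e6 scenarios) is refused with a pointer to the
Monte Carlo sampler.

## State spaces and kernels

* **Cycle, dB** — from a single mutant the producer set stays one
  contiguous arc (a death inside a uniform stretch is refilled by
  like-typed neighbors), so the chain reduces to the cluster size
  `n ∈ {0..N}` with `n → n±1` moves. The builder walks every possible
  dying node of a canonical cluster configuration, which automatically
  handles the shared boundary individual at `n ∈ {1, N−1}`. General
  (non-contiguous) cycle configurations go through the full chain.
* **Star, Bd** — states `(m, n)`: hub trait and producer-leaf count
  (2N states). Reproducer drawn over the whole population; hub
  offspring hits a uniformly random leaf, leaf offspring hits the hub.
* **Full chain** — all `2^N` configurations on any graph (cap
  `N ≤ 12`), implementing both update rules verbatim; used as the
  brute-force oracle. An exact-lumpability check (`lump`) verifies that
  aggregating the full chain by rotation/leaf-permutation orbits
  reproduces both reduced kernels entrywise, for all three schemes.

The dB-on-star and Bd-on-cycle reduced chains are deliberately not
implemented; those combinations route through the full chain.

## Fixation solves

`ρ_C` solves `(I − Q)ρ = P[:, all-C]` on the transient block by direct
sparse LU; the residual `‖ρ − Pρ‖_∞` must come in under 1e-10 or the
solver raises with a condition-number diagnostic. `ρ_D = 1 − ρ_C`
statewise.

Mean fixation probabilities weight single-mutant states by the
initialization distribution. Uniform and temperature initialization
coincide under dB (replacement is uniform by construction). Under Bd
the temperature weights come from the death rates
`d_i = Σ_j r_j p_ji` with `r` the expected reproduction probabilities in
the resident monomorphic state; per-node masses are aggregated onto
lumped states by orbit (star: hub vs. all leaves). Temperature
initialization is exposed for reproduction-mode selection only; with
selection on survival the resident-state replacement rates are not
defined by the model as published, and inventing semantics here seemed
worse than refusing.

## Closed form for the star (ff, Bd)

With conditioned transitions `P̃_{x→y} = P_{x→y}/(1 − P_{x→x})`, the
single-mutant fixation probabilities are

    ρ_C(1,0) = P̃_(1,0)→(1,1) / D,   ρ_C(0,1) = P̃_(0,1)→(1,1) / D,
    D = 1 + Σ_{i=1}^{N−2} P̃_(1,i)→(0,i) Π_{j=1}^{i} P̃_(0,j)→(0,j−1) / P̃_(1,j)→(1,j+1),

with, for ff-goods (derived from the chain, all verified against the
linear-solve oracle to 1e-9 and better),

    P̃_(1,i)→(1,i+1) = expit( δ(i·b − c − b/(N−1)) − log(N−1) ),  i = 0..N−2
    P̃_(0,j)→(0,j−1) = expit( δ(j·b + c) − log(N−1) ),            j = 1..N−1

(the `i = 0` case reproduces `e^{−δc}/(e^{−δc} + (N−1)e^{δb/(N−1)})`).
The i-sum of j-products is accumulated with `log_expit` and `logsumexp`,
keeping everything finite for `N = 5000`, `δ = 50`. As an analytic
anchor, at `δ = 0` the formula gives `ρ_C(1,0) = 1/(N²−2N+2)` and
`ρ_C(0,1) = (N−1)/(N²−2N+2)`, whose uniform-init mean is exactly `1/N`.

A companion `O(N)` engine (`star_ff_profile`) solves the embedded jump
chain built from the same conditioned probabilities — conditioning on
leaving a state does not change hitting probabilities — which yields
`ρ_C` at *all* 2N states, hence also the non-producer quantities
`ρ_D(0,N−1)` and `ρ_D(1,N−2)` without assembling the O(N³) kernel. The
closed-form engine is the default for star/Bd/ff models above `N = 200`;
below that the kernel solve is used (both agree to 1e-9 in the tests,
and to machine precision in practice).

## Selection conditions, sweeps, peaks

Derivatives in `A′`/`R′` use central finite differences with default
step `min(max(1e-4, 1e-3·δ), δ/2)` (one-sided at `δ = 0`); the step is
recorded in every report, and a user-supplied step that crosses zero is
rejected. Inequalities are strict with zero tolerance — the raw margins
are in the report for anyone who wants their own threshold. At exactly
`δ = 0` all four conditions are reported `False`: `A0`/`R0` reduce to
equalities by the C/D label symmetry of neutral drift, and the interface
treats the two derivative conditions the same way at the neutral
reference point, while still reporting the one-sided derivative so the
weak-selection trend is visible.

Default δ-grids are log-spaced: 200 points on `[1e-3, 10]` for `N ≤
200`, and 400 points on `[1e-4, 5]` above (dense enough to separate the
two peaks of the large star). A local maximum is an interior grid point
strictly above both neighbors after merging plateaus (ties within
1e-14); endpoints never count. Optional refinement runs a
golden-section search between the bracketing neighbors against the
model's own `ρ_C(δ)` — with the closed-form engine this makes peak
locations grid-independent.

## Monte Carlo sampler

`simulate_fixation` draws concrete `cf` recipients afresh each step
(matching the kernels' per-step expectations), supports both rules and
both selection modes, is reproducible from a seed, and reports censoring
explicitly instead of dropping unfinished runs. Validation uses 10⁴
replicates per configuration on `N = 6` cycles/stars — small enough to
keep the suite quick, large enough that the 3-standard-error binomial
band is a few times 10⁻² wide — plus a neutral `1/N` check on the
`N = 10` cycle. The sampler also verifies by trajectory inspection that
dB dynamics on the cycle keep the producer set contiguous.

## What the defaults represent

The shipped parameter choices mirror the study conditions the package is
built around: cycle `N = 10` with `b = 4, c = 1` (dB comparisons of the
three goods), star `N = 10` with `b = 5, c = 1` (Bd sweet-spot
behavior under both initializations), and the large star `N = 2000`,
`b = 5, c = 1`, temperature initialization, whose peak producer
fixation probability is ~140-fold its neutral value with two distinct
local maxima. These are exact finite-population computations: they show
the qualitative phenomena faithfully for the stated structures and
sizes, not asymptotics for other graphs, and nothing here addresses
fixation times, metastable transients, or mutation-selection balance
beyond the rare-mutation ratio `ρ_C/(ρ_C+ρ_D)`.

## Known limitations

* Exact `cf` enumeration scales with the producers adjacent to the
  competition group; dense graphs with many high-degree producers must
  fall back to Monte Carlo.
* The full chain is capped at `N = 12` (4096 states) by design.
* Directed and time-varying graphs are out of scope; weighted graphs use
  the `p_ij` conventions described above.
* Survival-mode selection is wired through payoffs and kernels but not
  through temperature initialization (see above).
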