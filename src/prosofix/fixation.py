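"""Fixation probabilities: linear solves, initialization, closed forms.

The probability ``ρ_C(x)`` of reaching the all-producer state from
state ``x`` satisfies ``ρ_C = P ρ_C`` with boundary conditions
``ρ_C(all-C) = 1`` and ``ρ_C(all-D) = 0``; complementarily
``ρ_D(x) = 1 − ρ_C(x)``.  Mean fixation probabilities weight the
single-mutant states by a mutant-appearance distribution: uniform
(each node 1/N) or "temperature" (proportional to each node's
replacement rate in the resident monomorphic state, the rare-mutation
limit of mutation-at-birth).

For ff-goods on the star under Bd updating the single-mutant fixation
probabilities also have an explicit product form over conditioned
transition probabilities ``P̃_{x→y} = P_{x→y}/(1 − P_{x→x})``; it is
evaluated in log space, which keeps it finite for populations of
thousands and selection intensities of order 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import spsolve
from scipy.special import expit, log_expit, logsumexp

from .errors import SolverError
from .goods import FecundityMap, GoodsScheme, expected_competition, payoff_distribution
from .graphs import GraphStructure
from .kernels import StateSpace, TransitionKernel

__all__ = [
    "FixationResult",
    "InitializationDistribution",
    "solve_fixation",
    "death_rates",
    "initialization",
    "mean_fixation",
    "closed_form_star_ff",
    "star_ff_profile",
]

_RESIDUAL_TOL = 1e-10
INIT_MODES = ("uniform", "temperature")


@dataclass(frozen=True)
class FixationResult:
    """State-wise fixation probabilities on a state space."""

    space: StateSpace
    rho_C: np.ndarray
    rho_D: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.rho_C, self.rho_D):
            if v.shape != (self.space.n_states,):
                raise ValueError("fixation vectors must match the state space size")


@dataclass(frozen=True)
class InitializationDistribution:
    """Mutant-appearance masses over single-mutant starting states.

    ``mu_C[s]`` is the probability that a producer mutant's invasion
    starts in state ``s`` (mass is zero off the single-producer states);
    ``mu_D`` likewise for non-producer mutants.  When ``space`` is None
    the vectors are per-node appearance probabilities instead.
    """

    mode: str
    mu_C: np.ndarray
    mu_D: np.ndarray
    space: StateSpace | None = None

    def __post_init__(self) -> None:
        for v in (self.mu_C, self.mu_D):
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError("initialization masses must sum to 1")


def solve_fixation(kernel: TransitionKernel) -> FixationResult:
    """Solve ``ρ_C = P ρ_C`` with the two absorbing boundary conditions.

    Direct sparse LU factorization on the transient block; raises
    :class:`SolverError` with a condition diagnostic if the residual
    ``‖ρ − Pρ‖_∞`` exceeds 1e-10.
    """
    P = kernel.P.tocsr()
    n = kernel.space.n_states
    i_C, i_D = kernel.space.i_all_C, kernel.space.i_all_D
    transient = np.array([i for i in range(n) if i not in (i_C, i_D)], dtype=int)
    rho = np.zeros(n)
    rho[i_C] = 1.0
    if transient.size:
        Q = P[transient][:, transient]
        rhs = np.asarray(P[transient][:, i_C].todense()).ravel()
        A = (identity(transient.size, format="csc") - Q).tocsc()
        try:
            sol = spsolve(A, rhs)
        except Exception as exc:  # pragma: no cover - singular systems
            raise SolverError(f"sparse solve failed: {exc}") from exc
        rho[transient] = sol
    residual = np.abs(rho - P @ rho).max()
    if not np.isfinite(rho).all() or residual > _RESIDUAL_TOL:
        cond = np.linalg.cond(A.toarray()) if transient.size <= 2000 else float("nan")
        raise SolverError(
            f"fixation solve residual {residual:.3e} exceeds {_RESIDUAL_TOL:.0e} "
            f"(condition estimate {cond:.3e})"
        )
    rho = np.clip(rho, 0.0, 1.0)
    return FixationResult(kernel.space, rho, 1.0 - rho)


def death_rates(
    g: GraphStructure,
    rule: str,
    resident: str,
    scheme: GoodsScheme,
    m: FecundityMap,
) -> np.ndarray:
    """Per-node replacement probabilities in a monomorphic state.

    dB updating replaces a uniformly chosen individual, so all rates are
    1/N regardless of structure or selection.  Bd updating gives
    ``d_i = Σ_j E[F_j / Σ_k F_k] p_ji`` with fecundities from the
    resident state (``resident`` in {'C', 'D'}); the rates sum to 1.
    """
    if resident not in ("C", "D"):
        raise ValueError("resident type must be 'C' or 'D'")
    N = g.N
    if rule == "dB":
        return np.full(N, 1.0 / N)
    if rule != "Bd":
        raise ValueError(f"unknown update rule {rule!r}")
    traits = np.full(N, resident == "C", dtype=bool)
    dist = payoff_distribution(g, traits, scheme)
    r = expected_competition(dist, np.arange(N), m)
    return g.step_probabilities.T @ r


def _project_single_mutant_masses(
    node_mass_C: np.ndarray, node_mass_D: np.ndarray, space: StateSpace, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-node mutant masses onto single-mutant states by orbit."""
    mu_C = np.zeros(space.n_states)
    mu_D = np.zeros(space.n_states)
    if space.encoding == "full":
        for i in range(N):
            mu_C[space.index(1 << i)] += node_mass_C[i]
            mu_D[space.index(((1 << N) - 1) & ~(1 << i))] += node_mass_D[i]
    elif space.encoding == "cycle-cluster":
        mu_C[space.index(1)] = node_mass_C.sum()
        mu_D[space.index(N - 1)] = node_mass_D.sum()
    elif space.encoding == "star-pair":
        mu_C[space.index((1, 0))] = node_mass_C[0]
        mu_C[space.index((0, 1))] = node_mass_C[1:].sum()
        mu_D[space.index((0, N - 1))] = node_mass_D[0]
        mu_D[space.index((1, N - 2))] = node_mass_D[1:].sum()
    else:
        raise ValueError(f"cannot project initialization onto encoding {space.encoding!r}")
    return mu_C, mu_D


def initialization(
    g: GraphStructure,
    rule: str,
    scheme: GoodsScheme,
    m: FecundityMap,
    mode: str,
    space: StateSpace | None = None,
) -> InitializationDistribution:
    """Mutant-appearance distribution, per node or projected onto a space.

    ``uniform``: 1/N per node.  ``temperature``: a producer mutant
    appears at node i with probability proportional to the node's death
    rate in the all-non-producer state (and vice versa).  Under dB
    updating the two modes coincide.  Temperature initialization is
    defined for selection on reproduction; survival-mode maps are not
    wired in here.
    """
    if mode not in INIT_MODES:
        raise ValueError(f"mode must be one of {INIT_MODES}")
    N = g.N
    if mode == "uniform":
        node_C = node_D = np.full(N, 1.0 / N)
    else:
        if m.mode != "reproduction":
            raise ValueError("temperature initialization is defined for reproduction-mode selection")
        d_D = death_rates(g, rule, "D", scheme, m)
        d_C = death_rates(g, rule, "C", scheme, m)
        node_C = d_D / d_D.sum()
        node_D = d_C / d_C.sum()
    if space is None:
        return InitializationDistribution(mode, node_C, node_D, None)
    mu_C, mu_D = _project_single_mutant_masses(node_C, node_D, space, N)
    return InitializationDistribution(mode, mu_C, mu_D, space)


def mean_fixation(fr: FixationResult, init: InitializationDistribution) -> tuple[float, float]:
    """Mean fixation probabilities ``ρ_C^μ = Σ_s μ_C[s] ρ_C[s]`` and likewise for D."""
    if init.space is None or init.space.n_states != fr.space.n_states:
        raise ValueError("initialization distribution must be projected onto the kernel's state space")
    return float(init.mu_C @ fr.rho_C), float(init.mu_D @ fr.rho_D)


def _star_ff_log_conditioned(N: int, b: float, c: float, delta: float):
    """Log-odds of the conditioned up/down moves of the star ff chain.

    ``a_up[i]`` (i = 0..N−2) are the log-odds of the conditioned move
    (1,i) → (1,i+1) versus (1,i) → (0,i); ``a_down[j]`` (j = 1..N−1,
    stored from index 1) those of (0,j) → (0,j−1) versus (0,j) → (1,j).
    """
    i = np.arange(N - 1, dtype=float)
    a_up = delta * (i * b - c - b / (N - 1)) - np.log(N - 1)
    j = np.arange(N, dtype=float)  # index 0 unused
    a_down = delta * (j * b + c) - np.log(N - 1)
    return a_up, a_down


def closed_form_star_ff(N: int, b: float, c: float, delta: float) -> tuple[float, float]:
    """Single-mutant producer fixation probabilities on the star (ff, Bd).

    Returns ``(ρ_C from the hub, ρ_C from a leaf)`` via the explicit
    product form over conditioned transitions,

    ``ρ_C(1,0) = P̃_(1,0)→(1,1) / D`` and ``ρ_C(0,1) = P̃_(0,1)→(1,1) / D``
    with ``D = 1 + Σ_{i=1}^{N−2} P̃_(1,i)→(0,i)
    Π_{j=1}^{i} P̃_(0,j)→(0,j−1) / P̃_(1,j)→(1,j+1)``.

    The i-sum of j-products is accumulated in log space (all terms are
    positive), so the result is finite for N of several thousand and
    δ of order 50.
    """
    if N < 3:
        raise ValueError("star requires N >= 3")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    a_up, a_down = _star_ff_log_conditioned(N, b, c, delta)
    log_u = log_expit(a_up)  # log P~(1,i)->(1,i+1), i=0..N-2
    log_one_minus_u = log_expit(-a_up)  # log P~(1,i)->(0,i)
    log_v = log_expit(a_down)  # log P~(0,j)->(0,j-1), j>=1
    # cumulative log of prod_{j=1}^{i} v_j / u_j
    log_ratio = log_v[1 : N - 1] - log_u[1 : N - 1]
    terms = log_one_minus_u[1 : N - 1] + np.cumsum(log_ratio)
    log_D = logsumexp(np.concatenate(([0.0], terms)))
    rho_hub = float(np.exp(log_u[0] - log_D))
    rho_leaf = float(np.exp(log_expit(-a_down[1]) - log_D))
    return rho_hub, rho_leaf


def star_ff_profile(N: int, b: float, c: float, delta: float) -> FixationResult:
    """Fixation probabilities from every star state (ff, Bd) in O(N).

    Solves the embedded jump chain built from the same conditioned
    transition probabilities as :func:`closed_form_star_ff` (conditioning
    on leaving a state does not change hitting probabilities).  Useful
    for large populations where assembling the 2N-state kernel row by
    row would be wasteful, and for the non-producer mutant states, since
    ``ρ_D(x) = 1 − ρ_C(x)``.
    """
    labels = tuple((h, n) for h in (0, 1) for n in range(N))
    space = StateSpace(labels, "star-pair", i_all_D=0, i_all_C=2 * N - 1)
    a_up, a_down = _star_ff_log_conditioned(N, b, c, delta)
    u = expit(a_up)
    v = expit(a_down)
    rows, cols, vals = [], [], []

    def idx(h, n):
        return h * N + n

    rows += [idx(0, 0), idx(1, N - 1)]
    cols += [idx(0, 0), idx(1, N - 1)]
    vals += [1.0, 1.0]
    for i in range(N - 1):  # states (1, i), i = 0..N-2
        rows += [idx(1, i), idx(1, i)]
        cols += [idx(1, i + 1), idx(0, i)]
        vals += [u[i], 1.0 - u[i]]
    for j in range(1, N):  # states (0, j), j = 1..N-1
        rows += [idx(0, j), idx(0, j)]
        cols += [idx(0, j - 1), idx(1, j)]
        vals += [v[j], 1.0 - v[j]]
    P = csr_matrix((vals, (rows, cols)), shape=(2 * N, 2 * N))
    kernel = TransitionKernel(P, space, "Bd")
    return solve_fixation(kernel)
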