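"""Exact transition kernels for dB and Bd updating, and a Monte Carlo sampler.

Two reduced chains mirror the structures for which exact computation
scales: the cycle under death-Birth updating (state = size of the
contiguous producer cluster; valid for single-mutant starts, which stay
contiguous) and the star under Birth-death updating (state = hub trait
and number of producer leaves).  ``kernel_full`` builds the chain on all
``2^N`` trait configurations of an arbitrary graph and serves as the
brute-force oracle for both.

All competition probabilities are assembled in linear space from
log-domain softmax outputs; entries are clipped to [0, 1] only within
1e-14 slack — larger violations raise, to distinguish numerical dust
from logic bugs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix, issparse
from scipy.special import softmax

from .errors import LumpingError
from .goods import FecundityMap, GoodsScheme, expected_competition, payoff_distribution
from .graphs import GraphStructure, make_cycle, make_star

__all__ = [
    "StateSpace",
    "TransitionKernel",
    "kernel_cycle_db",
    "kernel_star_bd",
    "kernel_full",
    "lump",
    "simulate_fixation",
    "estimate_fixation",
    "SimulationOutcome",
    "export_kernel_csv",
]

UPDATE_RULES = ("dB", "Bd")

_ROW_TOL = 1e-10
_CLIP_SLACK = 1e-14


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels with the two absorbing monomorphic states.

    Encodings: ``cycle-cluster`` labels are producer-cluster sizes
    ``0..N``; ``star-pair`` labels are ``(hub trait, producer leaves)``;
    ``full`` labels are bitmasks over nodes (bit i set = node i is a
    producer); ``lumped`` holds labels produced by :func:`lump`.
    """

    labels: tuple
    encoding: str
    i_all_D: int
    i_all_C: int

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self._index[label]
        except AttributeError:
            object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})
            return self._index[label]


@dataclass(frozen=True)
class TransitionKernel:
    """Row-stochastic transition matrix over a :class:`StateSpace`."""

    P: csr_matrix
    space: StateSpace
    rule: str

    def __post_init__(self) -> None:
        P = self.P
        if not issparse(P):
            P = csr_matrix(np.asarray(P, dtype=float))
        else:
            P = P.tocsr()
        data = P.data
        if data.size and (data.min() < -_CLIP_SLACK or data.max() > 1.0 + _CLIP_SLACK):
            raise ValueError(
                f"kernel entries outside [0,1] beyond slack: min={data.min()}, max={data.max()}"
            )
        np.clip(data, 0.0, 1.0, out=data)
        rows = np.asarray(P.sum(axis=1)).ravel()
        if np.abs(rows - 1.0).max() > _ROW_TOL:
            raise ValueError(f"kernel rows must sum to 1 (max deviation {np.abs(rows - 1.0).max()})")
        for idx in (self.space.i_all_D, self.space.i_all_C):
            row = P.getrow(idx)
            if row.nnz != 1 or row.indices[0] != idx or abs(row.data[0] - 1.0) > _ROW_TOL:
                raise ValueError("absorbing rows must be identity rows")
        if self.rule not in UPDATE_RULES:
            raise ValueError(f"rule must be one of {UPDATE_RULES}")
        object.__setattr__(self, "P", P)

    def dense(self) -> np.ndarray:
        return self.P.toarray()


def _cluster_traits(N: int, n: int) -> np.ndarray:
    x = np.zeros(N, dtype=bool)
    x[:n] = True
    return x


def kernel_cycle_db(N: int, scheme: GoodsScheme, m: FecundityMap) -> TransitionKernel:
    """Reduced chain for the cycle under dB updating.

    State ``n`` is the size of the contiguous producer cluster.  A step
    picks a dying individual uniformly (1/N each); only deaths on the
    producer/non-producer boundary can change the state, with the
    vacancy resolved by a two-neighbor competition (expectation over cf
    recipient scenarios).  For ``n ∈ {1, N−1}`` the two boundaries share
    an individual; the generic per-node construction covers that case.
    """
    g = make_cycle(N)
    n_states = N + 1
    P = np.zeros((n_states, n_states))
    P[0, 0] = 1.0
    P[N, N] = 1.0
    for n in range(1, N):
        traits = _cluster_traits(N, n)
        for i in range(N):
            left, right = (i - 1) % N, (i + 1) % N
            tl, tr = traits[left], traits[right]
            if tl == tr:
                if tl != traits[i]:
                    P[n, n + 1 if tl else n - 1] += 1.0 / N
                continue
            dist = payoff_distribution(g, traits, scheme, relevant=(left, right))
            win = expected_competition(dist, (left, right), m)
            for w, t in zip(win, (tl, tr)):
                if t != traits[i]:
                    P[n, n + 1 if t else n - 1] += w / N
        P[n, n] = 1.0 - P[n, n - 1] - P[n, n + 1]
    space = StateSpace(tuple(range(n_states)), "cycle-cluster", i_all_D=0, i_all_C=N)
    return TransitionKernel(csr_matrix(P), space, "dB")


def _star_traits(N: int, state: tuple[int, int]) -> np.ndarray:
    hub, n = state
    x = np.zeros(N, dtype=bool)
    x[0] = bool(hub)
    x[1 : n + 1] = True
    return x


def kernel_star_bd(N: int, scheme: GoodsScheme, m: FecundityMap) -> TransitionKernel:
    """Reduced chain for the star under Bd updating.

    State ``(m, n)``: hub trait (1 = producer) and number of producer
    leaves.  A reproducer is drawn proportionally to fecundity over the
    whole population (expectation of the softmax ratio over cf
    scenarios); the hub's offspring replaces a uniformly random leaf and
    a leaf's offspring replaces the hub.
    """
    labels = tuple((h, n) for h in (0, 1) for n in range(N))
    index = {lab: i for i, lab in enumerate(labels)}
    g = make_star(N)
    P = np.zeros((2 * N, 2 * N))
    for lab in labels:
        hub, n = lab
        row = index[lab]
        if lab in ((0, 0), (1, N - 1)):
            P[row, row] = 1.0
            continue
        traits = _star_traits(N, lab)
        dist = payoff_distribution(g, traits, scheme)
        r = expected_competition(dist, np.arange(N), m)
        r_hub = r[0]
        r_c_leaves = r[1 : n + 1].sum()
        r_d_leaves = r[n + 1 :].sum()
        if hub == 1:
            P[row, index[(1, n + 1)]] += r_hub * (N - 1 - n) / (N - 1)
        else:
            P[row, index[(0, n - 1)]] += r_hub * n / (N - 1)
        if hub == 0:
            P[row, index[(1, n)]] += r_c_leaves
        if hub == 1:
            P[row, index[(0, n)]] += r_d_leaves
        P[row, row] = 1.0 - P[row].sum()
    space = StateSpace(labels, "star-pair", i_all_D=index[(0, 0)], i_all_C=index[(1, N - 1)])
    return TransitionKernel(csr_matrix(P), space, "Bd")


def _mask_traits(mask: int, N: int) -> np.ndarray:
    return np.array([(mask >> i) & 1 for i in range(N)], dtype=bool)


def kernel_full(
    g: GraphStructure,
    rule: str,
    scheme: GoodsScheme,
    m: FecundityMap,
    *,
    max_nodes: int = 12,
) -> TransitionKernel:
    """Brute-force chain over all ``2^N`` trait configurations.

    dB: the dying node is uniform, its neighbors compete proportionally
    to fecundity.  Bd: the reproducer is drawn proportionally to
    fecundity over the whole population and its offspring disperses to
    neighbor ``k`` with probability ``p_jk``.  cf expectations enumerate
    only producers adjacent to the competing group.
    """
    if rule not in UPDATE_RULES:
        raise ValueError(f"rule must be one of {UPDATE_RULES}")
    N = g.N
    if N > max_nodes:
        raise ValueError(f"full state space of 2^{N} states exceeds the cap (max_nodes={max_nodes})")
    n_states = 1 << N
    all_C = n_states - 1
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    p_step = g.step_probabilities
    for mask in range(n_states):
        if mask in (0, all_C):
            rows.append(mask)
            cols.append(mask)
            vals.append(1.0)
            continue
        traits = _mask_traits(mask, N)
        acc: dict[int, float] = {}
        if rule == "dB":
            for i in range(N):
                nbrs = g.neighbors(i)
                ts = traits[nbrs]
                if ts.all() or not ts.any():
                    t = bool(ts[0])
                    target = mask | (1 << i) if t else mask & ~(1 << i)
                    acc[target] = acc.get(target, 0.0) + 1.0 / N
                    continue
                dist = payoff_distribution(g, traits, scheme, relevant=nbrs)
                win = expected_competition(dist, nbrs, m)
                for j, w in zip(nbrs, win):
                    target = mask | (1 << i) if traits[j] else mask & ~(1 << i)
                    acc[target] = acc.get(target, 0.0) + w / N
        else:  # Bd
            dist = payoff_distribution(g, traits, scheme)
            r = expected_competition(dist, np.arange(N), m)
            for j in range(N):
                for k in g.neighbors(j):
                    target = mask | (1 << k) if traits[j] else mask & ~(1 << k)
                    acc[target] = acc.get(target, 0.0) + r[j] * p_step[j, k]
        for target, v in acc.items():
            rows.append(mask)
            cols.append(target)
            vals.append(v)
    P = csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    space = StateSpace(tuple(range(n_states)), "full", i_all_D=0, i_all_C=all_C)
    return TransitionKernel(P, space, rule)


def lump(kernel: TransitionKernel, classify: Callable, *, tol: float = 1e-10) -> TransitionKernel:
    """Aggregate a kernel by a state classification, verifying lumpability.

    ``classify(label)`` maps each state label to a class label.  Every
    state in a class must produce the same class-aggregated row (within
    ``tol``); otherwise the partition is not exactly lumpable and a
    :class:`LumpingError` is raised.
    """
    labels = kernel.space.labels
    classes: list = []
    class_index: dict = {}
    membership = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        cls = classify(lab)
        if cls not in class_index:
            class_index[cls] = len(classes)
            classes.append(cls)
        membership[i] = class_index[cls]
    n_cls = len(classes)
    P = kernel.P.tocsr()
    agg = np.zeros((len(labels), n_cls))
    for i in range(len(labels)):
        row = P.getrow(i)
        np.add.at(agg[i], membership[row.indices], row.data)
    reduced = np.zeros((n_cls, n_cls))
    seen = np.zeros(n_cls, dtype=bool)
    for i in range(len(labels)):
        ci = membership[i]
        if not seen[ci]:
            reduced[ci] = agg[i]
            seen[ci] = True
        elif np.abs(agg[i] - reduced[ci]).max() > tol:
            raise LumpingError(
                f"states in class {classes[ci]!r} have aggregated rows differing by "
                f"{np.abs(agg[i] - reduced[ci]).max():.3e} (> {tol})"
            )
    space = StateSpace(
        tuple(classes),
        "lumped",
        i_all_D=membership[kernel.space.i_all_D],
        i_all_C=membership[kernel.space.i_all_C],
    )
    return TransitionKernel(csr_matrix(reduced), space, kernel.rule)


@dataclass(frozen=True)
class SimulationOutcome:
    outcome: str  # 'fixed_C' | 'fixed_D' | 'censored'
    steps: int
    trajectory: tuple | None = None


def _realized_payoffs(
    g: GraphStructure, x: np.ndarray, scheme: GoodsScheme, rng: np.random.Generator
) -> np.ndarray:
    """One concrete payoff vector; cf recipients are drawn afresh."""
    b, c = scheme.b, scheme.c
    if scheme.kind == "pp":
        return b * (g.weights @ x) - c * g.strengths * x
    if scheme.kind == "ff":
        return b * (g.step_probabilities.T @ x) - c * x
    u = -c * x.astype(float)
    for i in np.flatnonzero(x):
        nbrs = g.neighbors(i)
        if nbrs.size == 1:
            u[nbrs[0]] += b
        else:
            u[rng.choice(nbrs, p=g.step_probabilities[i, nbrs])] += b
    return u


def simulate_fixation(
    g: GraphStructure,
    rule: str,
    scheme: GoodsScheme,
    m: FecundityMap,
    x0,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_steps: int = 10_000_000,
    record_trajectory: bool = False,
) -> SimulationOutcome:
    """Sample one trajectory to absorption.

    cf recipients are re-drawn independently at every time step, so the
    sampler matches the per-step expectations taken by the exact
    kernels.  Returns ``censored`` (never silently drops the run) if no
    absorption occurs within ``max_steps``.
    """
    if rule not in UPDATE_RULES:
        raise ValueError(f"rule must be one of {UPDATE_RULES}")
    if max_steps <= 0:
        raise ValueError("max_steps must be positive")
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an explicit rng for reproducibility")
        rng = np.random.default_rng(seed)
    N = g.N
    x = np.asarray(x0, dtype=bool).copy()
    if x.shape != (N,):
        raise ValueError(f"x0 must have length {N}")
    n_c = int(x.sum())
    neutral = m.delta == 0.0
    traj = [tuple(x)] if record_trajectory else None
    for step in range(max_steps + 1):
        if n_c == 0:
            return SimulationOutcome("fixed_D", step, tuple(traj) if traj else None)
        if n_c == N:
            return SimulationOutcome("fixed_C", step, tuple(traj) if traj else None)
        if step == max_steps:
            break
        if rule == "dB":
            i = int(rng.integers(N))
            nbrs = g.neighbor_lists[i]
            ts = x[nbrs]
            if ts.all() or not ts.any():
                new_t = bool(ts[0])
            elif neutral:
                new_t = bool(x[nbrs[rng.integers(nbrs.size)]])
            else:
                u = _realized_payoffs(g, x, scheme, rng)
                w = softmax(m.sign * m.delta * u[nbrs])
                new_t = bool(x[rng.choice(nbrs, p=w)])
            if new_t != x[i]:
                x[i] = new_t
                n_c += 1 if new_t else -1
        else:  # Bd
            if neutral:
                j = int(rng.integers(N))
            else:
                u = _realized_payoffs(g, x, scheme, rng)
                w = softmax(m.sign * m.delta * u)
                j = int(rng.choice(N, p=w))
            nbrs = g.neighbor_lists[j]
            if nbrs.size == 1:
                k = int(nbrs[0])
            else:
                k = int(rng.choice(nbrs, p=g.step_probabilities[j, nbrs]))
            if x[k] != x[j]:
                x[k] = x[j]
                n_c += 1 if x[j] else -1
        if record_trajectory:
            traj.append(tuple(x))
    return SimulationOutcome("censored", max_steps, tuple(traj) if traj else None)


def estimate_fixation(
    g: GraphStructure,
    rule: str,
    scheme: GoodsScheme,
    m: FecundityMap,
    x0,
    *,
    n_runs: int,
    seed: int,
    max_steps: int = 10_000_000,
) -> dict:
    """Monte Carlo fixation fraction over ``n_runs`` independent trajectories."""
    rng = np.random.default_rng(seed)
    counts = {"fixed_C": 0, "fixed_D": 0, "censored": 0}
    for _ in range(n_runs):
        out = simulate_fixation(g, rule, scheme, m, x0, rng=rng, max_steps=max_steps)
        counts[out.outcome] += 1
    frac = counts["fixed_C"] / n_runs
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_runs))
    return {"fraction_C": frac, "se": se, "n_runs": n_runs, **counts}


def export_kernel_csv(kernel: TransitionKernel, path) -> None:
    """Write (from_state, to_state, probability) triples with state labels."""
    P = kernel.P.tocoo()
    labels = kernel.space.labels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["from_state", "to_state", "probability"])
        for i, j, v in zip(P.row, P.col, P.data):
            writer.writerow([labels[i], labels[j], repr(float(v))])
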