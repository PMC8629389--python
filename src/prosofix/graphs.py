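"""Population graphs and random-walk step probabilities.

The arena for both interaction and dispersal is a symmetric, weighted
graph on ``N`` individuals.  Node indexing is 0-based everywhere; for the
star, node 0 is the hub.  Weights generalize the unweighted graphs of the
classical model: all per-neighbor quantities are expressed through the
one-step random-walk probabilities ``p_ij = w_ij / sum_k w_ik``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import InvalidGraphError

__all__ = [
    "GraphStructure",
    "StepMatrix",
    "make_cycle",
    "make_star",
    "step_matrix",
    "load_adjacency",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class GraphStructure:
    """A connected population graph.

    Parameters
    ----------
    weights
        Square nonnegative symmetric matrix with zero diagonal.  Every
        node must have at least one neighbor and the graph must be
        connected (fixation is undefined across components, so a
        disconnected input is a hard error).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidGraphError(f"adjacency matrix must be square, got shape {W.shape}")
        if W.shape[0] < 2:
            raise InvalidGraphError("population must contain at least two individuals")
        scale = max(np.abs(W).max(), 1.0)
        if np.abs(W - W.T).max() > _SYMMETRY_TOL * scale:
            raise InvalidGraphError("adjacency matrix is not symmetric")
        W = 0.5 * (W + W.T)
        if np.any(np.diag(W) != 0.0):
            raise InvalidGraphError("self-loops are not allowed (diagonal must be zero)")
        if np.any(W < 0.0):
            raise InvalidGraphError("edge weights must be nonnegative")
        if np.any(W.sum(axis=1) <= 0.0):
            raise InvalidGraphError("every node must have at least one neighbor")
        n_comp, _ = connected_components(csr_matrix(W > 0), directed=False)
        if n_comp != 1:
            raise InvalidGraphError(f"graph must be connected (found {n_comp} components)")
        W.setflags(write=False)
        object.__setattr__(self, "weights", W)

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @cached_property
    def strengths(self) -> np.ndarray:
        """Row sums of the weight matrix (degree on unweighted graphs)."""
        return self.weights.sum(axis=1)

    @cached_property
    def step_probabilities(self) -> np.ndarray:
        """One-step random-walk matrix ``p_ij = w_ij / sum_k w_ik``."""
        p = self.weights / self.strengths[:, None]
        p.setflags(write=False)
        return p

    @cached_property
    def neighbor_lists(self) -> tuple[np.ndarray, ...]:
        return tuple(np.flatnonzero(row) for row in self.weights)

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the neighbors of node ``i``."""
        return self.neighbor_lists[i]


@dataclass(frozen=True)
class StepMatrix:
    """Row-stochastic one-step random-walk probabilities of a graph."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-12:
            raise InvalidGraphError("step matrix rows must sum to 1")
        p.setflags(write=False)
        object.__setattr__(self, "p", p)


@lru_cache(maxsize=32)
def make_cycle(N: int) -> GraphStructure:
    """Cycle of size ``N``: node ``i`` linked to ``(i±1) mod N`` with weight 1.

    Every individual has exactly two neighbors (for ``N = 3`` the cycle is
    the complete graph on three nodes).
    """
    if N < 3:
        raise InvalidGraphError(f"a cycle needs at least 3 nodes, got N={N}")
    W = np.zeros((N, N))
    idx = np.arange(N)
    W[idx, (idx + 1) % N] = 1.0
    W[idx, (idx - 1) % N] = 1.0
    return GraphStructure(W)


@lru_cache(maxsize=32)
def make_star(N: int) -> GraphStructure:
    """Star of size ``N``: hub (node 0) linked to ``N − 1`` leaves."""
    if N < 3:
        raise InvalidGraphError(f"a star needs at least 3 nodes, got N={N}")
    W = np.zeros((N, N))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return GraphStructure(W)


def step_matrix(g: GraphStructure) -> StepMatrix:
    """Random-walk step probabilities ``p_ij = w_ij / sum_k w_ik``."""
    return StepMatrix(g.step_probabilities)


def load_adjacency(path) -> GraphStructure:
    """Read a whitespace-delimited square adjacency matrix from a text file.

    Symmetry is verified on load (tolerance 1e-9); asymmetric, disconnected
    or otherwise invalid matrices raise :class:`InvalidGraphError`.
    """
    try:
        W = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise InvalidGraphError(f"could not parse adjacency matrix from {path}: {exc}") from exc
    return GraphStructure(W)
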