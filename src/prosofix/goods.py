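"""Social-goods payoffs and the exponential payoff-to-fecundity map.

Three payoff schemes for producers (type ``C``) versus non-producers
(type ``D``):

``pp``
    The classical donation game: a producer donates ``b`` to each
    neighbor at a per-neighbor cost ``c`` — total benefit and cost are
    proportional to the number of neighbors.
``ff``
    Fixed benefit, fixed cost: a producer pays ``c`` once and divides
    ``b`` evenly among its neighbors (``b·p_ij`` to neighbor ``j``).
``cf``
    Concentrated benefit, fixed cost: a producer pays ``c`` once and
    confers the entire ``b`` on a single neighbor chosen with
    probability ``p_ij``.  Payoffs are a *stochastic* function of the
    trait configuration; the expected payoff vector coincides with the
    ``ff`` vector, so ``ff`` is the mean-field analogue of ``cf``.

Payoff ``u`` maps to fecundity ``F(u) = e^{δu}`` — the unique map (up to
rescaling the selection intensity ``δ``) that is nonnegative,
non-decreasing, continuous, and makes competition invariant under adding
a constant payoff to all competitors.  When selection acts on survival
instead, the weight is ``e^{−δu}``.  Competition probabilities are
softmax ratios computed in shifted-exponent form, so they are finite for
``δ·|u|`` at least up to 1e4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import softmax

from .errors import EnumerationLimitError
from .graphs import GraphStructure

__all__ = [
    "GoodsScheme",
    "FecundityMap",
    "PayoffDistribution",
    "payoff_distribution",
    "fecundity",
    "competition_probabilities",
    "expected_competition",
]

GOODS_KINDS = ("pp", "ff", "cf")
FECUNDITY_MODES = ("reproduction", "survival")

#: hard cap on the number of enumerated cf scenarios, independent of the
#: per-producer cap (guards dense graphs with few but high-degree producers)
_MAX_SCENARIOS = 1_000_000


@dataclass(frozen=True)
class GoodsScheme:
    """A goods kind together with its benefit ``b`` and cost ``c``."""

    kind: str
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.kind not in GOODS_KINDS:
            raise ValueError(f"unknown goods kind {self.kind!r}; expected one of {GOODS_KINDS}")
        if self.b < 0 or self.c < 0:
            raise ValueError("benefit b and cost c must be nonnegative")


@dataclass(frozen=True)
class FecundityMap:
    """Exponential payoff-to-fecundity map at selection intensity ``delta``.

    ``mode='reproduction'`` weights competitors by ``e^{δu}``;
    ``mode='survival'`` weights candidates for death by ``e^{−δu}``.
    """

    delta: float
    mode: str = "reproduction"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("selection intensity delta must be nonnegative")
        if self.mode not in FECUNDITY_MODES:
            raise ValueError(f"mode must be one of {FECUNDITY_MODES}, got {self.mode!r}")

    @property
    def sign(self) -> float:
        return 1.0 if self.mode == "reproduction" else -1.0


@dataclass(frozen=True)
class PayoffDistribution:
    """Finite mixture of payoff vectors for one trait configuration.

    ``probs[s]`` is the probability of scenario ``s`` and ``payoffs[s]``
    the corresponding payoff vector over all ``N`` individuals.  For the
    deterministic schemes (``pp``, ``ff``) there is exactly one scenario
    with probability 1.
    """

    probs: np.ndarray
    payoffs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        payoffs = np.atleast_2d(np.asarray(self.payoffs, dtype=float))
        if probs.shape[0] != payoffs.shape[0]:
            raise ValueError("probs and payoffs disagree on the number of scenarios")
        if np.any(probs <= 0) or np.any(probs > 1):
            raise ValueError("scenario probabilities must lie in (0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("scenario probabilities must sum to 1")
        probs.setflags(write=False)
        payoffs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "payoffs", payoffs)

    @property
    def n_scenarios(self) -> int:
        return self.probs.shape[0]

    @property
    def expected_payoffs(self) -> np.ndarray:
        return self.probs @ self.payoffs


def _as_traits(traits, N: int) -> np.ndarray:
    x = np.asarray(traits, dtype=bool)
    if x.shape != (N,):
        raise ValueError(f"trait configuration must have length {N}, got shape {x.shape}")
    return x


def payoff_distribution(
    g: GraphStructure,
    traits,
    scheme: GoodsScheme,
    *,
    relevant: Iterable[int] | None = None,
    max_enumerated: int = 20,
) -> PayoffDistribution:
    """Payoff scenarios for a trait configuration under a goods scheme.

    ``traits`` is a boolean vector (True = producer).  For ``cf`` goods,
    recipient assignments are enumerated exhaustively (product over
    producers of their neighbor choices), merging assignments that yield
    identical payoff vectors.

    ``relevant`` optionally restricts enumeration to producers with a
    neighbor in the given node set — the only producers whose recipient
    choice can affect those nodes' payoffs.  Skipped producers
    contribute their *expected* donation ``b·p_ij`` instead, so entries
    of the payoff vectors are scenario-exact on ``relevant`` (and on all
    producers' own costs) but mean-field elsewhere.

    Raises :class:`EnumerationLimitError` when more than
    ``max_enumerated`` producers with several neighbors would need
    enumeration; Monte Carlo (`simulate_fixation`) handles such cases.
    """
    N = g.N
    x = _as_traits(traits, N)
    b, c = scheme.b, scheme.c
    W = g.weights
    P = g.step_probabilities

    if scheme.kind == "pp":
        u = b * (W @ x) - c * g.strengths * x
        return PayoffDistribution(np.array([1.0]), u[None, :])
    if scheme.kind == "ff":
        u = b * (P.T @ x) - c * x
        return PayoffDistribution(np.array([1.0]), u[None, :])

    # cf goods: enumerate recipient choices of the relevant producers.
    producers = np.flatnonzero(x)
    base = -c * x.astype(float)
    if relevant is None:
        enumerated = list(producers)
    else:
        rel = np.zeros(N, dtype=bool)
        rel[np.asarray(list(relevant), dtype=int)] = True
        enumerated = [i for i in producers if rel[g.neighbors(i)].any()]
        passive = [i for i in producers if not rel[g.neighbors(i)].any()]
        if passive:
            base = base + b * P[passive, :].sum(axis=0)

    choice_sets = [g.neighbors(i) for i in enumerated]
    n_random = sum(1 for nbr in choice_sets if nbr.size > 1)
    n_scen = 1
    for nbr in choice_sets:
        n_scen *= nbr.size
    if n_random > max_enumerated or n_scen > _MAX_SCENARIOS:
        raise EnumerationLimitError(
            f"cf enumeration needs {n_scen} scenarios over {n_random} producers with "
            f"several neighbors (limit {max_enumerated}); use Monte Carlo "
            "(kernels.simulate_fixation) instead"
        )

    merged: dict[bytes, tuple[float, np.ndarray]] = {}
    for assignment in itertools.product(*(range(nbr.size) for nbr in choice_sets)):
        u = base.copy()
        prob = 1.0
        for producer, nbrs, k in zip(enumerated, choice_sets, assignment):
            u[nbrs[k]] += b
            prob *= P[producer, nbrs[k]]
        key = u.tobytes()
        if key in merged:
            merged[key] = (merged[key][0] + prob, merged[key][1])
        else:
            merged[key] = (prob, u)
    probs = np.array([p for p, _ in merged.values()])
    payoffs = np.array([u for _, u in merged.values()])
    return PayoffDistribution(probs / probs.sum(), payoffs)


def fecundity(u, m: FecundityMap):
    """Fecundity ``e^{δu}`` (or death-weight ``e^{−δu}`` in survival mode).

    Direct evaluation; competition probabilities are computed in the log
    domain instead, so use :func:`competition_probabilities` whenever a
    normalized quantity is wanted.
    """
    return np.exp(m.sign * m.delta * np.asarray(u, dtype=float))


def competition_probabilities(payoffs, m: FecundityMap) -> np.ndarray:
    """Probability that each member of a competing group wins.

    Computes ``F_i / Σ_j F_j`` as a shifted-exponent softmax, hence
    shift-invariant under ``u → u + K`` and finite for arbitrarily large
    ``δ·|u|``.
    """
    u = np.atleast_1d(np.asarray(payoffs, dtype=float))
    if u.size == 0:
        raise ValueError("competition requires a nonempty group")
    return softmax(m.sign * m.delta * u)


def expected_competition(
    dist: PayoffDistribution, group: Sequence[int], m: FecundityMap
) -> np.ndarray:
    """Expected win probabilities over the scenarios of a payoff distribution.

    Expectation of the softmax ratio (never the ratio of expectations):
    ``Σ_s prob_s · softmax(δ·u_s[group])``.
    """
    idx = np.atleast_1d(np.asarray(group, dtype=int))
    if idx.size == 0:
        raise ValueError("competition requires a nonempty group")
    z = m.sign * m.delta * dist.payoffs[:, idx]
    return dist.probs @ softmax(z, axis=1)
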