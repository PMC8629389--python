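"""Model specification binding structure, update rule, goods and initialization.

An :class:`EvolutionModel` names everything needed to compute mean
fixation probabilities at a given selection intensity: the population
structure (built-in cycle/star or a user graph), the update rule, the
goods scheme, the mutant-initialization mode, and whether selection acts
on reproduction or survival.  Dispatch picks the cheapest exact engine:

* cycle + dB → reduced producer-cluster chain (size N+1);
* star + Bd → reduced (hub, leaf-count) chain (size 2N), or the O(N)
  closed form for ff-goods (default above N = 200);
* anything else → brute-force chain over all 2^N configurations
  (small N only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .fixation import (
    closed_form_star_ff,
    initialization,
    mean_fixation,
    solve_fixation,
    star_ff_profile,
)
from .goods import FecundityMap, GoodsScheme
from .graphs import GraphStructure, make_cycle, make_star
from .kernels import kernel_cycle_db, kernel_full, kernel_star_bd

__all__ = ["EvolutionModel", "MeanFixation", "mean_rho"]

STRUCTURES = ("cycle", "star", "general")
ENGINES = ("auto", "kernel", "closed-form")

#: population size above which star/Bd/ff sweeps default to the closed form
CLOSED_FORM_DEFAULT_N = 200


@dataclass(frozen=True)
class MeanFixation:
    """Mean fixation probabilities, with per-orbit components when available."""

    rho_C: float
    rho_D: float
    components: dict | None = None


@dataclass(frozen=True)
class EvolutionModel:
    structure: str
    rule: str
    scheme: GoodsScheme
    N: int | None = None
    graph: GraphStructure | None = None
    init: str = "uniform"
    mode: str = "reproduction"
    engine: str = "auto"

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.rule not in ("dB", "Bd"):
            raise ValueError("rule must be 'dB' or 'Bd'")
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if self.structure == "general":
            if self.graph is None:
                raise ValueError("a general model requires an explicit graph")
            object.__setattr__(self, "N", self.graph.N)
        elif self.N is None:
            raise ValueError("cycle/star models require N")

    def population_graph(self) -> GraphStructure:
        if self.structure == "cycle":
            return make_cycle(self.N)
        if self.structure == "star":
            return make_star(self.N)
        return self.graph

    def fecundity_map(self, delta: float) -> FecundityMap:
        return FecundityMap(delta, self.mode)

    @property
    def uses_closed_form(self) -> bool:
        return (
            self.structure == "star"
            and self.rule == "Bd"
            and self.scheme.kind == "ff"
            and self.mode == "reproduction"
            and (self.engine == "closed-form" or (self.engine == "auto" and self.N > CLOSED_FORM_DEFAULT_N))
        )


def _star_orbit_masses(model: EvolutionModel, delta: float) -> tuple[tuple, tuple]:
    """(hub, leaves) masses of mu_C and mu_D for the star under Bd.

    Closed expressions avoiding the O(N^2) graph build: in the all-D
    state payoffs vanish, so mu_C is the neutral temperature profile
    (hub replaced with probability 1 − 1/N); in the all-C ff state the
    hub reproduces with probability
    expit(δ·b·(N−1 − 1/(N−1)) − log(N−1)), which fixes mu_D.
    Cross-checked against the generic `initialization` in the tests.
    """
    N = model.N
    if model.init == "uniform":
        return (1.0 / N, (N - 1) / N), (1.0 / N, (N - 1) / N)
    mu_C = ((N - 1) / N, 1.0 / N)
    b = model.scheme.b
    r_hub = float(expit(delta * b * ((N - 1) - 1.0 / (N - 1)) - np.log(N - 1)))
    mu_D = (1.0 - r_hub, r_hub)
    return mu_C, mu_D


def _mean_via_kernel(model: EvolutionModel, delta: float) -> MeanFixation:
    m = model.fecundity_map(delta)
    g = model.population_graph()
    if model.structure == "cycle" and model.rule == "dB":
        kernel = kernel_cycle_db(model.N, model.scheme, m)
    elif model.structure == "star" and model.rule == "Bd":
        kernel = kernel_star_bd(model.N, model.scheme, m)
    else:
        kernel = kernel_full(g, model.rule, model.scheme, m)
    fr = solve_fixation(kernel)
    init = initialization(g, model.rule, model.scheme, m, model.init, space=kernel.space)
    rho_C, rho_D = mean_fixation(fr, init)
    components = None
    if kernel.space.encoding == "star-pair":
        components = {
            "hub": float(fr.rho_C[kernel.space.index((1, 0))]),
            "leaf": float(fr.rho_C[kernel.space.index((0, 1))]),
        }
    return MeanFixation(rho_C, rho_D, components)


def _mean_via_closed_form(model: EvolutionModel, delta: float) -> MeanFixation:
    N = model.N
    b, c = model.scheme.b, model.scheme.c
    rho_hub, rho_leaf = closed_form_star_ff(N, b, c, delta)
    (wC_hub, wC_leaf), (wD_hub, wD_leaf) = _star_orbit_masses(model, delta)
    profile = star_ff_profile(N, b, c, delta)
    rho_D_hub = float(profile.rho_D[profile.space.index((0, N - 1))])
    rho_D_leaf = float(profile.rho_D[profile.space.index((1, N - 2))])
    return MeanFixation(
        wC_hub * rho_hub + wC_leaf * rho_leaf,
        wD_hub * rho_D_hub + wD_leaf * rho_D_leaf,
        {"hub": rho_hub, "leaf": rho_leaf},
    )


def mean_rho(model: EvolutionModel, delta: float) -> MeanFixation:
    """Mean producer and non-producer fixation probabilities at ``delta``."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if model.uses_closed_form:
        return _mean_via_closed_form(model, delta)
    return _mean_via_kernel(model, delta)
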