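"""Monte-Carlo random-walk vertex weighting.

The clustering signal is produced by many short seeded random walks.
Unlike a classical random walk that records only its endpoints, every
step of every walk is recorded and weighted: a walk of length ``N``
contributes a weight of ``N`` at its start vertex, decreasing by one per
step, down to ``1`` at the final step.  Contributions are divided by a
degree penalty ``(deg(v)/d̄)**beta`` (``d̄`` = mean degree over
non-isolated vertices) so that aggregated weights are not dominated by
hub visitation, then averaged over ``R`` replicate walks started from
every vertex.  Vertices whose aggregated weight lies strictly above a
chosen quantile of the weight distribution are selected as module
candidates.

The penalty exponent is deliberately fractional by default (``beta=0.5``):
a random walk visits vertices roughly in proportion to their degree, so
some down-weighting of hubs is needed, but a full ``beta=1`` correction
also divides the constant start-weight ``N`` that every vertex pays to
itself, which hands low-degree peripheral vertices a ``d̄/deg(v)`` boost
large enough to invert the ranking.  The half-power compromises between
the two failure modes; both the exponent and the selection quantile are
ordinary config fields.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .errors import ContractError
from .graph_io import StageNetwork


@dataclass(frozen=True)
class WalkConfig:
    """Tunable parameters of the walk stage.

    walk_length_N
        Basic weight and walk length: the start vertex weighs ``N`` and the
        last possible step weighs 1, so a full walk takes ``N-1`` steps.
    walks_per_vertex_R
        Monte-Carlo replicates started from every vertex.
    penalty_exponent_beta
        Exponent of the relative-degree divisor; 0 disables the penalty.
    vertex_weight_quantile
        Empirical quantile of the weight distribution above which vertices
        are selected (strict inequality).
    rng_seed
        Master seed; every individual walk derives its own substream from
        (seed, stage, start vertex, replicate), so execution order cannot
        change results.
    """

    walk_length_N: int = 20
    walks_per_vertex_R: int = 100
    penalty_exponent_beta: float = 0.5
    vertex_weight_quantile: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_length_N < 2:
            raise ContractError("walk_length_N must be >= 2")
        if self.walks_per_vertex_R < 1:
            raise ContractError("walks_per_vertex_R must be >= 1")
        if not (0.0 <= self.vertex_weight_quantile < 1.0):
            raise ContractError("vertex_weight_quantile must lie in [0, 1)")


@dataclass
class WalkRecord:
    """One recorded walk: every visit with its step index."""

    start_vertex: str
    visited: List[Tuple[str, int]]
    truncated: bool


@dataclass
class VertexWeightTable:
    """Aggregated, penalty-adjusted walk weights for one stage."""

    stage_id: str
    weights: Dict[str, float]
    provenance: WalkConfig


def step_weight(t: int, config: WalkConfig) -> float:
    """Weight of the visit at step ``t``: ``N - t``, linear decay to 1."""
    n = config.walk_length_N
    if not (0 <= t <= n - 1):
        raise ContractError(f"step index {t} outside [0, {n - 1}]")
    return float(n - t)


def penalty_coefficient(vertex: str, network: StageNetwork, config: WalkConfig) -> float:
    """Relative-degree divisor ``(deg(v)/d̄)**beta``; isolates get 1.

    ``d̄`` averages over non-isolated vertices only, so sprinkling isolates
    into a network does not change the penalty of its connected part.
    """
    g = network.graph
    deg = g.degree(vertex)
    if deg == 0:
        return 1.0
    degrees = [d for _, d in g.degree() if d > 0]
    mean_deg = sum(degrees) / len(degrees)
    return float((deg / mean_deg) ** config.penalty_exponent_beta)


def walk_rng(config: WalkConfig, stage_id: str, start: str, replicate: int) -> np.random.Generator:
    """Deterministic per-walk substream, independent of execution order."""
    key = str(config.rng_seed).encode()
    digest = hashlib.blake2b(
        f"{stage_id}|{start}|{replicate}".encode(), digest_size=8, key=key
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def run_walk(
    network: StageNetwork, start: str, config: WalkConfig, rng: np.random.Generator
) -> WalkRecord:
    """Walk up to ``N-1`` uniform-random neighbor steps from ``start``.

    Revisits are allowed and recorded; a vertex with no neighbors ends the
    walk early (``truncated=True``).
    """
    g = network.graph
    if start not in g:
        raise KeyError(f"start vertex {start!r} not in stage network")
    visited = [(start, 0)]
    current = start
    truncated = False
    for t in range(1, config.walk_length_N):
        neighbors = sorted(g.neighbors(current))
        if not neighbors:
            truncated = True
            break
        current = neighbors[rng.integers(len(neighbors))]
        visited.append((current, t))
    return WalkRecord(start_vertex=start, visited=visited, truncated=truncated)


def raw_contribution(record: WalkRecord, config: WalkConfig) -> float:
    """Total pre-penalty weight of one walk: ``N(N+1)/2`` when not truncated."""
    return sum(step_weight(t, config) for _, t in record.visited)


def accumulate_weights(network: StageNetwork, config: WalkConfig) -> VertexWeightTable:
    """Run ``R`` walks from every vertex and aggregate penalized visit weights.

    ``weight(v) = (1/R) * sum over visits of (N - t) / penalty(v)``; dividing
    by ``R`` keeps tables comparable across replicate counts.
    """
    g = network.graph
    penalties = {v: penalty_coefficient(v, network, config) for v in g}
    weights = {v: 0.0 for v in g}
    for start in sorted(g.nodes):
        for rep in range(config.walks_per_vertex_R):
            rng = walk_rng(config, network.stage_id, start, rep)
            record = run_walk(network, start, config, rng)
            for vertex, t in record.visited:
                weights[vertex] += step_weight(t, config) / penalties[vertex]
    r = config.walks_per_vertex_R
    return VertexWeightTable(
        stage_id=network.stage_id,
        weights={v: w / r for v, w in weights.items()},
        provenance=config,
    )


def select_vertices(table: VertexWeightTable, config: WalkConfig) -> set:
    """Vertices strictly above the configured quantile of the weight distribution."""
    if not table.weights:
        raise ContractError("cannot select from an empty weight table")
    values = np.fromiter(table.weights.values(), dtype=float)
    threshold = float(np.quantile(values, config.vertex_weight_quantile))
    return {v for v, w in table.weights.items() if w > threshold}
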