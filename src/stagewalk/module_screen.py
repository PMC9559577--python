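"""From selected vertices to modules.

Selected (high-weight) vertices are screened pairwise: for each pair the
closed neighborhoods of the two vertices, restricted to the selected set,
are intersected and united; pairs whose overlap ratio exceeds a threshold
contribute their neighborhood union.  Overlapping unions are merged
transitively, and each merged vertex list is split into the connected
components it induces on the original stage network.  Components with at
least five vertices (configurable) become modules.

Restricting neighborhoods to the selected set means an unselected
low-weight vertex never re-enters a module; if removing such a bridge
vertex disconnects a candidate cluster, the component split below handles
it — each surviving connected piece is kept or dropped by the size rule
on its own.

Two calibration points matter.  A passing pair contributes the pair
itself to the merge (``union_mode="pair"``), so clusters are connected
components of the pairwise-overlap relation, in the spirit of
shared-nearest-neighbor clustering; contributing full neighborhood
unions instead lets a single spurious inter-module edge chain two dense
regions into one cluster.  And the default overlap threshold (1/3) sits
strictly above the bare-adjacency baseline: an adjacent pair with no
shared selected neighbor scores exactly 2/|A∪B| <= 1/3 once the two
neighborhoods contain four or more distinct vertices, so adjacency alone
is never sufficient evidence and merging requires genuinely shared
neighborhoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Set, Tuple

import networkx as nx

from .errors import ContractError
from .graph_io import StageNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """overlap_threshold: strict lower bound on the pairwise overlap ratio;
    min_module_size: smallest vertex count a module may have (default 5);
    union_mode: what a passing pair contributes to the merge step —
    ``"pair"`` (default) contributes the two vertices themselves, so
    clusters are connected components of the pairwise-overlap relation;
    ``"neighborhood"`` contributes the full neighborhood union, which is
    more aggressive: one spurious edge between two dense regions then
    chains them into a single cluster."""

    overlap_threshold: float = 1 / 3
    min_module_size: int = 5
    union_mode: str = "pair"

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ContractError("overlap_threshold must lie in [0, 1]")
        if self.min_module_size < 1:
            raise ContractError("min_module_size must be positive")
        if self.union_mode not in ("pair", "neighborhood"):
            raise ContractError("union_mode must be 'pair' or 'neighborhood'")


@dataclass(frozen=True)
class Module:
    """A connected vertex set within one stage; the unit of all downstream networks."""

    stage_id: str
    module_id: str
    members: FrozenSet[str]
    induced_edges: FrozenSet[Tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        """Globally unique node label of the form S<i>M<k>."""
        return f"{self.stage_id}{self.module_id}"


def _closed_neighborhood(v: str, selected: Set[str], g: nx.Graph) -> Set[str]:
    return ({v} | set(g.neighbors(v))) & selected


def pair_overlap(
    u: str, v: str, selected: Set[str], network: StageNetwork
) -> Tuple[float, Set[str]]:
    """Overlap ratio and union of the selected-restricted closed neighborhoods.

    The union always contains ``u`` and ``v``, so the ratio is well defined.
    """
    if u not in selected or v not in selected:
        raise ContractError("pair_overlap arguments must both be selected vertices")
    if u == v:
        raise ContractError("pair_overlap requires two distinct vertices")
    a = _closed_neighborhood(u, selected, network.graph)
    b = _closed_neighborhood(v, selected, network.graph)
    union = a | b
    return len(a & b) / len(union), union


def screen_pairs(
    selected: Set[str], network: StageNetwork, config: ScreenConfig
) -> List[Set[str]]:
    """Vertex sets contributed by all selected pairs whose overlap ratio
    strictly exceeds the threshold.  At threshold 1 nothing survives; at
    threshold 0 any pair with non-empty neighborhood intersection does.
    In ``pair`` mode a passing pair contributes {u, v}; in
    ``neighborhood`` mode it contributes the full neighborhood union."""
    if len(selected) < 2:
        raise ContractError("screen_pairs requires at least two selected vertices")
    ordered = sorted(selected)
    retained: List[Set[str]] = []
    for i, u in enumerate(ordered):
        for v in ordered[i + 1 :]:
            ratio, union = pair_overlap(u, v, selected, network)
            if ratio > config.overlap_threshold:
                retained.append({u, v} if config.union_mode == "pair" else union)
    return retained


def merge_unions(unions: Sequence[Set[str]]) -> List[Set[str]]:
    """Transitive closure of the overlap relation via union-find.

    Output sets are pairwise disjoint, cover exactly the input union, and do
    not depend on input order (canonically sorted by smallest member).
    """
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def link(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for s in unions:
        items = sorted(s)
        for x in items:
            parent.setdefault(x, x)
        for x in items[1:]:
            link(items[0], x)
    groups: dict = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    return sorted(groups.values(), key=lambda s: min(s))


def finalize_modules(
    merged: Sequence[Set[str]], network: StageNetwork, config: ScreenConfig
) -> List[Module]:
    """Split merged vertex lists into connected components on the original
    stage network and keep components with ``min_module_size`` or more
    vertices.  Modules are numbered M1.. in descending size order, ties
    broken by smallest member id; sub-components that fail the size rule
    are logged and discarded."""
    g = network.graph
    kept: List[Tuple[Set[str], Set[Tuple[str, str]]]] = []
    for vertex_set in merged:
        sub = g.subgraph(vertex_set)
        for component in nx.connected_components(sub):
            if len(component) >= config.min_module_size:
                edges = {
                    tuple(sorted(e)) for e in g.subgraph(component).edges
                }
                kept.append((set(component), edges))
            else:
                logger.info(
                    "%s: dropping sub-component of size %d (< %d): %s",
                    network.stage_id,
                    len(component),
                    config.min_module_size,
                    sorted(component),
                )
        # vertices isolated inside their merged set are size-1 components,
        # handled by the same rule above
    kept.sort(key=lambda pair: (-len(pair[0]), min(pair[0])))
    return [
        Module(
            stage_id=network.stage_id,
            module_id=f"M{i}",
            members=frozenset(members),
            induced_edges=frozenset(edges),
        )
        for i, (members, edges) in enumerate(kept, start=1)
    ]


def modules_from_members(
    members_by_id: dict, network: StageNetwork
) -> List[Module]:
    """Rebuild Module objects from a module_id -> member-set mapping by
    re-inducing edges on the stage network (used when loading a module
    table from disk)."""
    g = network.graph
    modules = []
    for module_id in sorted(members_by_id, key=lambda m: (len(m), m)):
        members = set(members_by_id[module_id])
        edges = {tuple(sorted(e)) for e in g.subgraph(members).edges}
        modules.append(
            Module(
                stage_id=network.stage_id,
                module_id=module_id,
                members=frozenset(members),
                induced_edges=frozenset(edges),
            )
        )
    return modules


def screen_modules(
    selected: Set[str], network: StageNetwork, config: ScreenConfig
) -> List[Module]:
    """Full screening chain: pair overlap -> union merge -> component split."""
    if len(selected) < 2:
        return []
    unions = screen_pairs(selected, network, config)
    merged = merge_unions(unions)
    return finalize_modules(merged, network, config)
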