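"""The global module network.

Modules become nodes labelled ``S<i>M<k>``.  Two modules of the same
stage are linked when the stage network contains at least one edge
crossing between them; the edge weight is the raw cross-edge count.
Modules of *adjacent* stages (S1-S2, S2-S3, S3-S4) are linked by the
Jaccard coefficient of their member sets; non-adjacent stage pairs are
never connected.  Module identity is never assumed across stages — S1M1
and S2M1 are distinct nodes related only through inter-stage edges.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx

from .errors import ContractError
from .graph_io import STAGES, StageNetwork
from .module_screen import Module


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|A∩B| / |A∪B|; two empty sets give 0 by convention."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def intra_stage_edges(
    modules: Sequence[Module], network: StageNetwork
) -> List[Tuple[Module, Module, int]]:
    """Count stage-network edges crossing each module pair; zero counts are
    suppressed."""
    for mod in modules:
        if mod.stage_id != network.stage_id:
            raise ContractError(
                f"module {mod.label} does not belong to stage {network.stage_id}"
            )
    g = network.graph
    edges = []
    for ma, mb in combinations(modules, 2):
        count = sum(1 for u in ma.members for v in g.neighbors(u) if v in mb.members)
        if count >= 1:
            edges.append((ma, mb, count))
    return edges


def _require_adjacent(stage_a: str, stage_b: str) -> None:
    ia, ib = STAGES.index(stage_a), STAGES.index(stage_b)
    if ib - ia != 1:
        raise ContractError(
            f"stages {stage_a} and {stage_b} are not consecutive in {'->'.join(STAGES)}"
        )


def inter_stage_edges(
    modules_a: Sequence[Module],
    modules_b: Sequence[Module],
    min_jaccard: float = 0.0,
) -> List[Tuple[Module, Module, float]]:
    """Jaccard links between modules of two consecutive stages.

    Emits pairs with ``J > min_jaccard`` (default keeps every positive
    overlap; the stricter inclusive >= 0.1 cut belongs to core-evolution
    extraction, not here).
    """
    if modules_a and modules_b:
        _require_adjacent(modules_a[0].stage_id, modules_b[0].stage_id)
    edges = []
    for ma in modules_a:
        for mb in modules_b:
            j = jaccard(set(ma.members), set(mb.members))
            if j > min_jaccard:
                edges.append((ma, mb, j))
    return edges


def build_global_module_network(
    modules_by_stage: Dict[str, Sequence[Module]],
    networks: Dict[str, StageNetwork],
    min_jaccard: float = 0.0,
) -> nx.Graph:
    """Assemble the full module-level graph over all stages.

    Node attributes: ``stage``, ``module_id``, ``size``.
    Edge attributes: ``edge_class`` in {intra, inter} and ``weight``
    (cross-edge count for intra, Jaccard for inter).
    """
    g = nx.Graph(network_class="global_module_network")
    for stage in STAGES:
        for mod in modules_by_stage.get(stage, []):
            g.add_node(mod.label, stage=stage, module_id=mod.module_id, size=mod.size)
    for stage, mods in modules_by_stage.items():
        if stage not in networks:
            raise ContractError(f"no stage network supplied for {stage}")
        for ma, mb, count in intra_stage_edges(list(mods), networks[stage]):
            g.add_edge(ma.label, mb.label, edge_class="intra", weight=int(count))
    for stage_a, stage_b in zip(STAGES, STAGES[1:]):
        pairs = inter_stage_edges(
            list(modules_by_stage.get(stage_a, [])),
            list(modules_by_stage.get(stage_b, [])),
            min_jaccard,
        )
        for ma, mb, j in pairs:
            g.add_edge(ma.label, mb.label, edge_class="inter", weight=float(j))
    return g
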