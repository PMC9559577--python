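"""Comprehensive and core evolution networks.

The comprehensive network is the union of the global module network and
the functional interaction network, joined by module-function edges
wherever a term passed the enrichment screen for a module.  Function
nodes are instantiated per (stage, term) so the stage structure of the
module side carries over; function-function edges connect term pairs
within the same stage, while cross-stage function "evolution" edges are
introduced only in the core network.

Core modules are module nodes whose total degree in the comprehensive
network (all three edge classes) reaches a threshold, 5 by default; core
functions are function nodes adjacent to at least one core module.  The
core evolution network is the induced subgraph on core nodes with
inter-stage module edges filtered to Jaccard >= 0.1 (inclusive) and
function-evolution edges between adjacent stages added for identical
terms or sufficiently similar gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Set, Tuple

import networkx as nx
from scipy.stats import norm

from .errors import ContractError, NetworkValidationError
from .enrichment import EnrichmentResult, FunctionalNetwork, GeneSetCollection
from .graph_io import STAGES
from .stage_network import jaccard


@dataclass(frozen=True)
class CoreConfig:
    """core_degree_min: inclusive degree threshold for core modules;
    evolution_jaccard_min: inclusive Jaccard bound for inter-stage core
    edges and similarity-based function-evolution edges."""

    core_degree_min: int = 5
    evolution_jaccard_min: float = 0.1
    link_same_term: bool = True
    link_similar_terms: bool = True

    def __post_init__(self) -> None:
        if self.core_degree_min < 0:
            raise ContractError("core_degree_min must be >= 0")
        if not (0.0 <= self.evolution_jaccard_min <= 1.0):
            raise ContractError("evolution_jaccard_min must lie in [0, 1]")


def function_node(stage: str, term: str) -> str:
    """Node label of a per-stage function instance."""
    return f"{stage}|{term}"


def build_comprehensive(
    gmn: nx.Graph,
    fn: FunctionalNetwork,
    results: Sequence[EnrichmentResult],
) -> nx.Graph:
    """Union of module and function networks plus module-function edges.

    Module nodes keep their attributes from the global module network with
    ``node_class='module'``; each (stage, term) with a passing result
    becomes a function node with the stage's minimum q.  Edge classes:
    ``intra``/``inter`` (module-module), ``function`` (same-stage
    function-function) and ``module-function``.
    """
    g = nx.Graph(network_class="comprehensive_network")
    for node, data in gmn.nodes(data=True):
        g.add_node(node, node_class="module", **data)
    for a, b, data in gmn.edges(data=True):
        g.add_edge(a, b, **data)

    for term, stage_qs in fn.q_by_stage.items():
        for stage, q in stage_qs.items():
            g.add_node(
                function_node(stage, term),
                node_class="function",
                stage=stage,
                term=term,
                q=float(q),
            )
    # same-stage function-function edges inherited from the term-level network
    for ta, tb, data in fn.graph.edges(data=True):
        shared_stages = set(fn.q_by_stage[ta]) & set(fn.q_by_stage[tb])
        for stage in shared_stages:
            g.add_edge(
                function_node(stage, ta),
                function_node(stage, tb),
                edge_class="function",
                weight=float(data.get("jaccard", data.get("weight", 0.0))),
            )
    for r in results:
        module_node = f"{r.stage_id}{r.module_id}"
        fnode = function_node(r.stage_id, r.term)
        if module_node not in g:
            raise NetworkValidationError(
                f"enrichment result references unknown module {module_node}"
            )
        if fnode not in g:
            raise NetworkValidationError(
                f"enrichment result references unknown function instance {fnode}"
            )
        g.add_edge(module_node, fnode, edge_class="module-function", weight=1.0)
    return g


def module_nodes(net: nx.Graph) -> list:
    return [n for n, d in net.nodes(data=True) if d.get("node_class") == "module"]


def function_nodes(net: nx.Graph) -> list:
    return [n for n, d in net.nodes(data=True) if d.get("node_class") == "function"]


def degree_summary(net: nx.Graph, threshold: int = 5) -> Tuple[float, float]:
    """Fraction of module nodes with degree below ``threshold``, paired with
    the analytic one-sigma mass of the standard normal (the three-sigma-rule
    reference the threshold is compared against).  The normal mass is
    computed from the distribution, not hard-coded."""
    mods = module_nodes(net)
    if not mods:
        raise ContractError("degree_summary requires at least one module node")
    below = sum(1 for n in mods if net.degree(n) < threshold)
    one_sigma = float(norm.cdf(1.0) - norm.cdf(-1.0))
    return below / len(mods), one_sigma


def select_core(net: nx.Graph, config: CoreConfig) -> Tuple[Set[str], Set[str]]:
    """Core modules: total degree >= core_degree_min (all edge classes).
    Core functions: function nodes adjacent to >= 1 core module."""
    core_modules = {
        n for n in module_nodes(net) if net.degree(n) >= config.core_degree_min
    }
    core_functions = {
        n
        for n in function_nodes(net)
        if any(nb in core_modules for nb in net.neighbors(n))
    }
    return core_modules, core_functions


def build_core_evolution(
    net: nx.Graph,
    core_sets: Tuple[Set[str], Set[str]],
    collection: GeneSetCollection,
    config: CoreConfig,
) -> nx.Graph:
    """Induced subgraph on core nodes with the evolution-specific edits.

    Inter-stage module edges below ``evolution_jaccard_min`` (strict) are
    removed; a pair at exactly the bound is retained.  Function-evolution
    edges (class ``function-evolution``) are added between function
    instances of adjacent stages that carry the same term, or whose
    annotated gene sets have Jaccard >= the same bound.
    """
    core_modules, core_functions = core_sets
    keep = set(core_modules) | set(core_functions)
    g = nx.Graph(network_class="core_evolution_network")
    for node in keep:
        g.add_node(node, **net.nodes[node])
    for a, b, data in net.edges(data=True):
        if a not in keep or b not in keep:
            continue
        if data.get("edge_class") == "inter" and float(data.get("weight", 0.0)) < config.evolution_jaccard_min:
            continue
        g.add_edge(a, b, **data)

    by_stage: Dict[str, list] = {}
    for n in core_functions:
        by_stage.setdefault(net.nodes[n]["stage"], []).append(n)
    for stage_a, stage_b in zip(STAGES, STAGES[1:]):
        for fa in by_stage.get(stage_a, []):
            for fb in by_stage.get(stage_b, []):
                term_a, term_b = net.nodes[fa]["term"], net.nodes[fb]["term"]
                same = config.link_same_term and term_a == term_b
                similar = False
                if config.link_similar_terms and not same:
                    try:
                        j = jaccard(
                            set(collection.members(term_a)), set(collection.members(term_b))
                        )
                    except KeyError:
                        raise NetworkValidationError(
                            f"term {term_a!r} or {term_b!r} missing from the collection"
                        ) from None
                    similar = j >= config.evolution_jaccard_min
                if same or similar:
                    g.add_edge(fa, fb, edge_class="function-evolution", weight=1.0)
    return g


def core_summary_table(net: nx.Graph):
    """Tidy per-node summary of a core evolution network."""
    import pandas as pd

    rows = []
    for n, d in sorted(net.nodes(data=True)):
        rows.append(
            {
                "node": n,
                "node_class": d.get("node_class"),
                "stage": d.get("stage"),
                "degree": net.degree(n),
                "size": d.get("size", ""),
                "q": d.get("q", ""),
            }
        )
    return pd.DataFrame(rows, columns=["node", "node_class", "stage", "degree", "size", "q"])
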