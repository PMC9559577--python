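"""Over-representation analysis of modules against GMT gene sets.

This is a local stand-in for web-based annotation services: module
members are tested against each gene set with a one-sided (upper-tail)
hypergeometric test, p-values are adjusted per stage with
Benjamini-Hochberg, and functions with q <= 0.05 are screened as
module-related.  Passing terms form the functional interaction network,
whose edges carry the Jaccard coefficient of the terms' annotated gene
sets.  A comparison routine contrasts three ways of feeding molecules to
the same test — everything in a stage at once, all selected vertices
pooled, or per-module — on the scale Q' = -ln q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, InputFormatError
from .graph_io import STAGES, StageNetwork
from .module_screen import Module
from .stage_network import jaccard

DEFAULT_Q_MAX = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets plus the annotation universe they live in.

    Unless an explicit universe is supplied, the universe is the union of
    all set members.
    """

    sets: Dict[str, Tuple[str, FrozenSet[str]]]
    universe: FrozenSet[str]

    def members(self, term: str) -> FrozenSet[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (module, term) over-representation test."""

    stage_id: str
    module_id: str
    term: str
    overlap_count: int
    p_value: float
    q_value: float
    overlap_members: FrozenSet[str]


def read_gmt(path: str, universe: Optional[Set[str]] = None) -> GeneSetCollection:
    """Read a standard GMT file: term, description, then members, tab-separated.

    Empty sets are skipped with a warning; a duplicate term id is an error.
    """
    import logging

    logger = logging.getLogger(__name__)
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputFormatError(f"{path}:{lineno}: expected >= 2 columns")
            term, description = parts[0], parts[1]
            members = frozenset(p.strip() for p in parts[2:] if p.strip())
            if not members:
                logger.warning("%s:%d: skipping empty gene set %r", path, lineno, term)
                continue
            if term in sets:
                raise InputFormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = (description, members)
    if universe is None:
        universe_set: FrozenSet[str] = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    else:
        universe_set = frozenset(universe)
    for term, (_, members) in sets.items():
        if not members <= universe_set:
            raise InputFormatError(f"gene set {term!r} has members outside the universe")
    return GeneSetCollection(sets=sets, universe=universe_set)


def read_universe(path: str) -> Set[str]:
    """Optional one-id-per-line universe file."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def hypergeom_test(module_members: Set[str], term_set: Set[str], universe: Set[str]) -> float:
    """Upper-tail hypergeometric probability P(X >= observed overlap).

    The module is intersected with the universe first; drawing
    ``|module ∩ universe|`` balls from ``|universe|`` with ``|term_set|``
    successes.
    """
    if not universe:
        raise ContractError("enrichment universe must be non-empty")
    if not set(term_set) <= set(universe):
        raise ContractError("term set must be a subset of the universe")
    in_universe = set(module_members) & set(universe)
    k = len(in_universe & set(term_set))
    m_total = len(universe)
    n_term = len(term_set)
    n_draw = len(in_universe)
    return float(hypergeom.sf(k - 1, m_total, n_term, n_draw))


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ContractError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _module_test_ids(
    module: Module,
    collection: GeneSetCollection,
    molecule_kinds: Optional[Mapping[str, str]],
    genes_only: bool,
) -> Set[str]:
    members = set(module.members)
    if genes_only and molecule_kinds is not None:
        members = {v for v in members if molecule_kinds.get(v) == "gene"}
    return members


def enrich_modules(
    modules: Sequence[Module],
    collection: GeneSetCollection,
    q_max: float = DEFAULT_Q_MAX,
    molecule_kinds: Optional[Mapping[str, str]] = None,
    genes_only: bool = True,
    global_correction: bool = False,
) -> List[EnrichmentResult]:
    """Test every (module, term) pair with non-empty overlap and screen at
    ``q <= q_max``.

    BH correction is applied across all tests within a stage (the per-stage
    screening narrative); ``global_correction=True`` corrects across stages
    instead.  By default only gene-kind members enter the test, matching
    gene-centric annotation; pass ``genes_only=False`` for fully synthetic
    mixed-kind runs or when no kind map is available.
    """
    tests: List[Tuple[str, Module, str, int, FrozenSet[str], float]] = []
    for module in modules:
        members = _module_test_ids(module, collection, molecule_kinds, genes_only)
        in_universe = members & set(collection.universe)
        for term in sorted(collection.sets):
            overlap = in_universe & set(collection.members(term))
            if not overlap:
                continue
            p = hypergeom_test(members, collection.members(term), collection.universe)
            tests.append((module.stage_id, module, term, len(overlap), frozenset(overlap), p))

    results: List[EnrichmentResult] = []
    groups: Dict[str, List[int]]
    if global_correction:
        groups = {"all": list(range(len(tests)))}
    else:
        groups = {}
        for i, t in enumerate(tests):
            groups.setdefault(t[0], []).append(i)
    for indices in groups.values():
        qs = bh_fdr([tests[i][5] for i in indices])
        for i, q in zip(indices, qs):
            stage, module, term, count, overlap, p = tests[i]
            if q <= q_max:
                results.append(
                    EnrichmentResult(
                        stage_id=stage,
                        module_id=module.module_id,
                        term=term,
                        overlap_count=count,
                        p_value=p,
                        q_value=float(q),
                        overlap_members=overlap,
                    )
                )
    results.sort(key=lambda r: (r.stage_id, r.module_id, r.q_value, r.term))
    return results


@dataclass
class FunctionalNetwork:
    """Passing terms as nodes; edges weighted by gene-set Jaccard.

    A term passing in several stages is a single node whose ``stages``
    attribute lists them all; per-stage minimum q-values are kept in
    ``q_by_stage``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    q_by_stage: Dict[str, Dict[str, float]] = field(default_factory=dict)


def build_functional_network(
    results: Sequence[EnrichmentResult], collection: GeneSetCollection
) -> FunctionalNetwork:
    """Nodes are screened terms; edges connect term pairs whose annotated
    gene sets intersect, weighted by their Jaccard coefficient."""
    q_by_stage: Dict[str, Dict[str, float]] = {}
    for r in results:
        stage_qs = q_by_stage.setdefault(r.term, {})
        stage_qs[r.stage_id] = min(stage_qs.get(r.stage_id, 1.0), r.q_value)
    g = nx.Graph(network_class="functional_network")
    for term, stage_qs in sorted(q_by_stage.items()):
        stages = sorted(stage_qs, key=STAGES.index)
        g.add_node(
            term,
            stages=",".join(stages),
            min_q=float(min(stage_qs.values())),
        )
    terms = sorted(q_by_stage)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1 :]:
            j = jaccard(set(collection.members(ta)), set(collection.members(tb)))
            if j > 0:
                g.add_edge(ta, tb, jaccard=float(j), weight=float(j))
    return FunctionalNetwork(graph=g, q_by_stage=q_by_stage)


def q_prime(q: Optional[float]) -> float:
    """Comparison index Q' = -ln q, with 0 encoding absence or q = 1."""
    if q is None or q >= 1.0:
        return 0.0
    if q <= 0.0:
        raise ContractError("q-values must lie in (0, 1]")
    return -math.log(q)


def _pooled_q_values(
    id_sets: Dict[str, Set[str]], collection: GeneSetCollection
) -> Dict[Tuple[str, str], float]:
    """q per (stage, term) for one gene list per stage, BH within stage."""
    out: Dict[Tuple[str, str], float] = {}
    for stage, ids in id_sets.items():
        in_universe = set(ids) & set(collection.universe)
        terms = [
            t
            for t in sorted(collection.sets)
            if in_universe & set(collection.members(t))
        ]
        if not terms:
            continue
        ps = [hypergeom_test(ids, collection.members(t), collection.universe) for t in terms]
        for t, q in zip(terms, bh_fdr(ps)):
            out[(stage, t)] = float(q)
    return out


def compare_designs(
    stage_networks: Mapping[str, StageNetwork],
    selected: Mapping[str, Set[str]],
    modules_by_stage: Mapping[str, Sequence[Module]],
    collection: GeneSetCollection,
    molecule_kinds: Optional[Mapping[str, str]] = None,
    genes_only: bool = True,
) -> pd.DataFrame:
    """Tabulate Q' = -ln q for three designs per stage.

    Design1 feeds every stage vertex to the test at once; Design2 feeds the
    walk-selected vertices pooled; the modular design tests per module and
    keeps each term's minimum q over modules.  Rows are terms, columns a
    (method, stage) MultiIndex; 0 encodes absence or q = 1.
    """

    def kind_filter(ids: Set[str]) -> Set[str]:
        if genes_only and molecule_kinds is not None:
            return {v for v in ids if molecule_kinds.get(v) == "gene"}
        return set(ids)

    design1 = _pooled_q_values(
        {s: kind_filter(net.vertices) for s, net in stage_networks.items()}, collection
    )
    design2 = _pooled_q_values(
        {s: kind_filter(set(ids)) for s, ids in selected.items()}, collection
    )
    all_modules = [m for mods in modules_by_stage.values() for m in mods]
    ours_results = enrich_modules(
        all_modules,
        collection,
        q_max=1.0,
        molecule_kinds=molecule_kinds,
        genes_only=genes_only,
    )
    ours: Dict[Tuple[str, str], float] = {}
    for r in ours_results:
        key = (r.stage_id, r.term)
        ours[key] = min(ours.get(key, 1.0), r.q_value)

    methods = [("Design1", design1), ("Design2", design2), ("ours", ours)]
    stages = [s for s in STAGES if s in stage_networks]
    terms = sorted({t for _, qmap in methods for (_, t) in qmap})
    columns = pd.MultiIndex.from_tuples(
        [(name, s) for name, _ in methods for s in stages], names=["method", "stage"]
    )
    table = pd.DataFrame(0.0, index=pd.Index(terms, name="term"), columns=columns)
    for name, qmap in methods:
        for (stage, term), q in qmap.items():
            table.loc[term, (name, stage)] = q_prime(q)
    return table


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str) -> None:
    """Long-format TSV: (stage, module, term, overlap, p, q)."""
    rows = [
        {
            "stage": r.stage_id,
            "module": r.module_id,
            "term": r.term,
            "overlap": r.overlap_count,
            "p": r.p_value,
            "q": r.q_value,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["stage", "module", "term", "overlap", "p", "q"]).to_csv(
        path, sep="\t", index=False
    )
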