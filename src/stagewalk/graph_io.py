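"""Readers, writers and validation for staged molecular networks.

A stage network is an undirected simple graph whose vertices are
differentially expressed molecules of three kinds (gene, miRNA, lncRNA)
and whose edges are restricted to four kinds of molecular interaction:
gene-gene, miRNA-lncRNA, gene-miRNA and gene-lncRNA.  Any other endpoint
combination (e.g. miRNA-miRNA) is rejected at read time.

Input format: a 2-column TSV edge list (one file per stage) plus a
2-column TSV molecule-type sidecar mapping every id to its kind.  Lines
starting with ``#`` are ignored.  Molecules present in the type map but
absent from every edge are retained as isolated vertices.

All derived networks in the package are plain :class:`networkx.Graph`
objects with string node ids and scalar attributes, so a single pair of
writers (GraphML and TSV) serves every network type.  The TSV writer
emits an edge table at ``path`` and a node table at ``path`` with a
``.nodes.tsv`` suffix so that isolated vertices and node attributes
survive a round trip.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import InputFormatError, NetworkValidationError

logger = logging.getLogger(__name__)

MOLECULE_KINDS = ("gene", "miRNA", "lncRNA")

STAGES = ("S1", "S2", "S3", "S4")

#: the four permitted endpoint-kind combinations, keyed by the (unordered)
#: pair of endpoint kinds, valued by the canonical edge-kind label.
ALLOWED_EDGE_KINDS: Mapping[frozenset, str] = {
    frozenset({"gene"}): "gene-gene",
    frozenset({"miRNA", "lncRNA"}): "miRNA-lncRNA",
    frozenset({"gene", "miRNA"}): "gene-miRNA",
    frozenset({"gene", "lncRNA"}): "gene-lncRNA",
}


def edge_kind(kind_a: str, kind_b: str) -> str:
    """Canonical edge-kind label for a pair of endpoint kinds.

    Raises
    ------
    NetworkValidationError
        If the combination is not one of the four permitted kinds.
    """
    key = frozenset({kind_a, kind_b})
    try:
        return ALLOWED_EDGE_KINDS[key]
    except KeyError:
        raise NetworkValidationError(
            f"edge kind {kind_a}-{kind_b} is not one of the four permitted kinds"
        ) from None


@dataclass(frozen=True)
class Molecule:
    """A typed vertex of a stage network."""

    id: str
    kind: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputFormatError("molecule id must be non-empty")
        if self.kind not in MOLECULE_KINDS:
            raise InputFormatError(
                f"unknown molecule kind {self.kind!r} for id {self.id!r}; "
                f"expected one of {MOLECULE_KINDS}"
            )


@dataclass
class StageNetwork:
    """One stage's heterogeneous molecular interaction graph.

    ``graph`` is an undirected simple :class:`networkx.Graph`; every node
    carries a ``kind`` attribute and every edge an ``edge_kind`` attribute.
    """

    stage_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if self.stage_id not in STAGES:
            raise InputFormatError(
                f"unknown stage id {self.stage_id!r}; expected one of {STAGES}"
            )

    @property
    def vertices(self) -> set:
        return set(self.graph.nodes)

    def kind_of(self, vertex: str) -> str:
        return self.graph.nodes[vertex]["kind"]

    def add_molecule(self, mol: Molecule) -> None:
        existing = self.graph.nodes.get(mol.id)
        if existing is not None and existing.get("kind") != mol.kind:
            raise NetworkValidationError(
                f"molecule {mol.id!r} declared with conflicting kinds"
            )
        self.graph.add_node(mol.id, kind=mol.kind)

    def add_edge(self, a: str, b: str) -> None:
        """Add an undirected edge, enforcing the four-kind whitelist."""
        if a == b:
            raise NetworkValidationError(f"self-loop on {a!r} is not permitted")
        for v in (a, b):
            if v not in self.graph:
                raise NetworkValidationError(f"edge endpoint {v!r} has no declared kind")
        kind = edge_kind(self.kind_of(a), self.kind_of(b))
        self.graph.add_edge(a, b, edge_kind=kind)

    def validate(self) -> None:
        """Re-check every structural invariant; raise on the first violation."""
        for v, data in self.graph.nodes(data=True):
            Molecule(v, data.get("kind", ""))
        for a, b, data in self.graph.edges(data=True):
            if a == b:
                raise NetworkValidationError(f"self-loop on {a!r}")
            expected = edge_kind(self.kind_of(a), self.kind_of(b))
            if data.get("edge_kind") != expected:
                raise NetworkValidationError(
                    f"edge ({a},{b}) labelled {data.get('edge_kind')!r}, expected {expected!r}"
                )


def _data_lines(path: str):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_type_map(path: str) -> dict:
    """Read the 2-column id -> kind TSV sidecar."""
    kinds: dict = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputFormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        mol = Molecule(parts[0].strip(), parts[1].strip())
        if mol.id in kinds and kinds[mol.id] != mol.kind:
            raise InputFormatError(f"{path}:{lineno}: conflicting kind for {mol.id!r}")
        kinds[mol.id] = mol.kind
    return kinds


def read_stage_network(edge_path: str, type_path: str, stage_id: str) -> StageNetwork:
    """Read and validate one stage's edge list against its molecule-type map.

    Duplicate lines and reversed duplicates collapse to a single undirected
    edge.  Ids present only in the type map become isolated vertices (they
    can still serve as walk starts) and are counted in the log.
    """
    kinds = read_type_map(type_path)
    net = StageNetwork(stage_id)
    for mol_id, kind in kinds.items():
        net.add_molecule(Molecule(mol_id, kind))
    for lineno, line in _data_lines(edge_path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputFormatError(f"{edge_path}:{lineno}: expected 2 tab-separated columns")
        a, b = parts[0].strip(), parts[1].strip()
        for v in (a, b):
            if v not in kinds:
                raise InputFormatError(
                    f"{edge_path}:{lineno}: id {v!r} missing from type map {type_path}"
                )
        try:
            net.add_edge(a, b)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"{edge_path}:{lineno}: {exc}") from None
    n_isolates = sum(1 for v in net.graph if net.graph.degree(v) == 0)
    if n_isolates:
        logger.info("%s: %d isolated vertices retained", stage_id, n_isolates)
    return net


# ---------------------------------------------------------------------------
# generic writers / readers for every network type


def _as_graph(network) -> nx.Graph:
    from .errors import ContractError

    if isinstance(network, nx.Graph):
        return network
    graph = getattr(network, "graph", None)
    if isinstance(graph, nx.Graph):
        return graph
    raise ContractError(f"cannot interpret {type(network).__name__} as a network")


def _nodes_path(path: str) -> str:
    stem, ext = os.path.splitext(path)
    return f"{stem}.nodes{ext or '.tsv'}"


def write_network(network, path: str, format: str = "graphml") -> None:
    """Write any of the package's networks to GraphML or TSV.

    TSV writes two files: the edge table at ``path`` (columns ``src``,
    ``dst``, then each edge attribute) and a node table alongside it.
    """
    g = _as_graph(network)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv":
        edge_attrs = sorted({k for _, _, d in g.edges(data=True) for k in d})
        node_attrs = sorted({k for _, d in g.nodes(data=True) for k in d})
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(["src", "dst", *edge_attrs]) + "\n")
            for a, b in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
                a, b = sorted((a, b), key=str)
                d = g.edges[a, b]
                fh.write("\t".join([str(a), str(b), *[repr(d.get(k, "")) for k in edge_attrs]]) + "\n")
        with open(_nodes_path(path), "w", encoding="utf-8") as fh:
            fh.write("\t".join(["node", *node_attrs]) + "\n")
            for v in sorted(g.nodes, key=str):
                d = g.nodes[v]
                fh.write("\t".join([str(v), *[repr(d.get(k, "")) for k in node_attrs]]) + "\n")
    else:
        raise InputFormatError(f"unknown format {format!r}; expected 'graphml' or 'tsv'")


def _parse_repr(text: str):
    import ast

    if text == "''":
        return ""
    try:
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def read_network(path: str, format: str = "graphml") -> nx.Graph:
    """Inverse of :func:`write_network`; returns a plain attribute graph."""
    if format == "graphml":
        return nx.read_graphml(path)
    if format != "tsv":
        raise InputFormatError(f"unknown format {format!r}")
    g = nx.Graph()
    with open(_nodes_path(path), encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            attrs = {k: _parse_repr(v) for k, v in zip(header, parts[1:]) if v != "''"}
            g.add_node(parts[0], **attrs)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            attrs = {k: _parse_repr(v) for k, v in zip(header, parts[2:]) if v != "''"}
            g.add_edge(parts[0], parts[1], **attrs)
    return g


def write_weight_table(weights: Mapping[str, float], kinds: Mapping[str, str], path: str) -> None:
    """Export a vertex weight distribution as (vertex, kind, weight) TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("vertex\tkind\tweight\n")
        for v in sorted(weights):
            fh.write(f"{v}\t{kinds.get(v, '')}\t{weights[v]!r}\n")


def read_weight_table(path: str) -> dict:
    """Inverse of :func:`write_weight_table`; returns vertex -> weight."""
    weights: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("vertex\t"):
            raise InputFormatError(f"{path}: not a weight table")
        for line in fh:
            vertex, _, weight = line.rstrip("\n").split("\t")
            weights[vertex] = float(weight)
    return weights


def read_module_table(path: str) -> dict:
    """Inverse of :func:`write_module_table`.

    Returns stage -> module_id -> set of member ids; induced edges are not
    stored in the table and must be re-derived from the stage network.
    """
    table: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("stage\tmodule_id"):
            raise InputFormatError(f"{path}: not a module table")
        for line in fh:
            stage, module_id, vertex, _ = line.rstrip("\n").split("\t")
            table.setdefault(stage, {}).setdefault(module_id, set()).add(vertex)
    return table


def write_module_table(modules: Iterable, kinds: Mapping[str, str], path: str) -> None:
    """Export modules as a long-format (stage, module_id, vertex, kind) TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\tmodule_id\tvertex\tkind\n")
        for mod in modules:
            for v in sorted(mod.members):
                fh.write(f"{mod.stage_id}\t{mod.module_id}\t{v}\t{kinds.get(v, '')}\n")
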