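"""Synthetic multi-stage fixtures with planted, drifting modules.

The generator emulates what the upstream data preparation would deliver:
four stage-specific molecular networks over a shared vertex universe,
with K planted modules per stage (dense Bernoulli(p_in) subgraphs on a
sparse Bernoulli(p_out) background), a molecule-type map, and a matched
GMT collection containing one gene set per planted module lineage plus
random decoy sets.  Between adjacent stages each module resamples a
fraction of its members from the background, so lineages drift while
staying recognisable — the regime the Jaccard-based inter-stage linking
is meant to detect.

Planted members are genes throughout (so intra-module edges always
satisfy the gene-gene whitelist rule and the gene-centric enrichment
path is exercised); miRNA and lncRNA vertices live in the background per
``type_fractions``.  Candidate background edges whose endpoint kinds are
not among the four permitted combinations are rejected outright — a
fixed vertex pair cannot be resampled into a legal kind, so rejection
without replacement is the faithful reading.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from .errors import ContractError
from .enrichment import GeneSetCollection
from .graph_io import ALLOWED_EDGE_KINDS, STAGES, Molecule, StageNetwork


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic benchmark.

    Defaults define the standard fixture used throughout the test suite:
    4 stages, K=4 planted modules of m=12 vertices on b=40 background
    vertices, intra-module edge probability 0.6 against background 0.02,
    a quarter of each module resampled between adjacent stages, and 15
    decoy gene sets next to the 4 planted ones.
    """

    n_stages: int = 4
    modules_per_stage: int = 4
    module_size: int = 12
    background_vertices: int = 40
    p_in: float = 0.6
    p_out: float = 0.02
    drift_rho: float = 0.25
    type_fractions: Tuple[float, float, float] = (0.4, 0.3, 0.3)
    n_noise_sets: int = 15
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ContractError("require 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.drift_rho <= 1.0):
            raise ContractError("drift_rho must lie in [0, 1]")
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ContractError("type_fractions must sum to 1")
        if self.n_stages < 1 or self.n_stages > len(STAGES):
            raise ContractError(f"n_stages must lie in [1, {len(STAGES)}]")
        if self.modules_per_stage < 1 or self.module_size < 1:
            raise ContractError("modules_per_stage and module_size must be positive")

    @property
    def replacements_per_module(self) -> int:
        return math.ceil(self.drift_rho * self.module_size)


@dataclass
class SyntheticData:
    """Everything the generator emits, in memory."""

    spec: SyntheticSpec
    networks: Dict[str, StageNetwork]
    #: stage -> vertex -> planted lineage (1-based); background vertices absent
    memberships: Dict[str, Dict[str, int]]
    collection: GeneSetCollection
    term_by_lineage: Dict[int, str]
    kinds: Dict[str, str]

    def lineage_members(self, stage: str, lineage: int) -> FrozenSet[str]:
        return frozenset(
            v for v, k in self.memberships[stage].items() if k == lineage
        )


def _background_type_counts(spec: SyntheticSpec) -> Tuple[int, int, int]:
    b = spec.background_vertices
    n_gene = round(spec.type_fractions[0] * b)
    n_mirna = round(spec.type_fractions[1] * b)
    n_lncrna = b - n_gene - n_mirna
    if n_lncrna < 0:
        raise ContractError("type_fractions incompatible with background size")
    return n_gene, n_mirna, n_lncrna


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Build the staged networks, planted truth, and GMT collection.

    Deterministic: the same spec (including seed) yields identical output,
    independent of call order, because every random purpose draws from its
    own derived substream.
    """
    k, m = spec.modules_per_stage, spec.module_size
    n_module_slots = k * m
    n_bg_gene, n_bg_mirna, n_bg_lncrna = _background_type_counts(spec)

    if spec.drift_rho > 0 and k * spec.replacements_per_module > n_bg_gene:
        raise ContractError(
            "infeasible spec: drift needs more background genes than exist "
            f"({k * spec.replacements_per_module} > {n_bg_gene})"
        )

    planted_genes = [f"G{i:04d}" for i in range(1, n_module_slots + 1)]
    bg_genes = [f"G{i:04d}" for i in range(n_module_slots + 1, n_module_slots + n_bg_gene + 1)]
    mirnas = [f"MIR{i:03d}" for i in range(1, n_bg_mirna + 1)]
    lncrnas = [f"LNC{i:03d}" for i in range(1, n_bg_lncrna + 1)]
    kinds: Dict[str, str] = {}
    for v in planted_genes + bg_genes:
        kinds[v] = "gene"
    for v in mirnas:
        kinds[v] = "miRNA"
    for v in lncrnas:
        kinds[v] = "lncRNA"
    universe = sorted(kinds)

    stages = list(STAGES[: spec.n_stages])

    # --- membership drift -------------------------------------------------
    drift_rng = np.random.default_rng([spec.rng_seed, 1])
    memberships: Dict[str, Dict[str, int]] = {}
    current: Dict[int, List[str]] = {
        lineage: planted_genes[(lineage - 1) * m : lineage * m]
        for lineage in range(1, k + 1)
    }
    memberships[stages[0]] = {
        v: lineage for lineage, members in current.items() for v in members
    }
    for stage in stages[1:]:
        assigned = {v for members in current.values() for v in members}
        pool = sorted(v for v in planted_genes + bg_genes if v not in assigned)
        new: Dict[int, List[str]] = {}
        for lineage in range(1, k + 1):
            members = sorted(current[lineage])
            n_rep = spec.replacements_per_module
            drop_idx = drift_rng.choice(len(members), size=n_rep, replace=False)
            dropped = {members[i] for i in drop_idx}
            entering_idx = drift_rng.choice(len(pool), size=n_rep, replace=False)
            entering = [pool[i] for i in sorted(entering_idx)]
            pool = [p for i, p in enumerate(pool) if i not in set(entering_idx)]
            new[lineage] = sorted((set(members) - dropped) | set(entering))
        current = new
        memberships[stage] = {
            v: lineage for lineage, members in current.items() for v in members
        }

    # --- per-stage edges --------------------------------------------------
    networks: Dict[str, StageNetwork] = {}
    for si, stage in enumerate(stages):
        edge_rng = np.random.default_rng([spec.rng_seed, 2, si])
        net = StageNetwork(stage)
        for v in universe:
            net.add_molecule(Molecule(v, kinds[v]))
        member_of = memberships[stage]
        for a, b in combinations(universe, 2):
            same_module = (
                a in member_of and b in member_of and member_of[a] == member_of[b]
            )
            p = spec.p_in if same_module else spec.p_out
            if frozenset({kinds[a], kinds[b]}) not in ALLOWED_EDGE_KINDS:
                continue  # a fixed forbidden pair cannot become legal; reject
            if edge_rng.random() < p:
                net.add_edge(a, b)
        networks[stage] = net

    # --- GMT collection ---------------------------------------------------
    gmt_rng = np.random.default_rng([spec.rng_seed, 3])
    genes = sorted(v for v in universe if kinds[v] == "gene")
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    term_by_lineage: Dict[int, str] = {}
    for lineage in range(1, k + 1):
        members = frozenset().union(
            *[
                {v for v, l_ in memberships[stage].items() if l_ == lineage}
                for stage in stages
            ]
        )
        term = f"PLANTED_L{lineage}"
        sets[term] = (f"planted module lineage {lineage}", frozenset(members))
        term_by_lineage[lineage] = term
    for i in range(1, spec.n_noise_sets + 1):
        size = int(gmt_rng.integers(5, 16))
        idx = gmt_rng.choice(len(genes), size=size, replace=False)
        sets[f"NOISE_{i:02d}"] = (
            f"decoy gene set {i}",
            frozenset(genes[j] for j in idx),
        )
    collection = GeneSetCollection(sets=sets, universe=frozenset(genes))

    return SyntheticData(
        spec=spec,
        networks=networks,
        memberships=memberships,
        collection=collection,
        term_by_lineage=term_by_lineage,
        kinds=kinds,
    )


def write_fixture(data: SyntheticData, outdir: str) -> Dict[str, str]:
    """Write the fixture in the exact on-disk formats the readers consume.

    Returns a name -> path map.  Output is byte-identical for identical
    specs (sorted iteration everywhere).
    """
    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}
    for stage, net in sorted(data.networks.items()):
        path = os.path.join(outdir, f"edges_{stage}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# molecule_a\tmolecule_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\t{b}\n")
        paths[f"edges_{stage}"] = path
    path = os.path.join(outdir, "types.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# molecule\tkind\n")
        for v in sorted(data.kinds):
            fh.write(f"{v}\t{data.kinds[v]}\n")
    paths["types"] = path
    path = os.path.join(outdir, "genesets.gmt")
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(data.collection.sets):
            desc, members = data.collection.sets[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
    paths["gmt"] = path
    path = os.path.join(outdir, "truth_modules.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\tvertex\tlineage\n")
        for stage in sorted(data.memberships):
            for v, lineage in sorted(data.memberships[stage].items()):
                fh.write(f"{stage}\t{v}\t{lineage}\n")
    paths["truth_modules"] = path
    path = os.path.join(outdir, "truth_terms.tsv")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lineage\tterm\n")
        for lineage, term in sorted(data.term_by_lineage.items()):
            fh.write(f"{lineage}\t{term}\n")
    paths["truth_terms"] = path
    return paths


def null_fixture(
    n_modules: int = 80,
    module_size: int = 12,
    universe_size: int = 400,
    n_sets: int = 80,
    set_size: Tuple[int, int] = (10, 30),
    rng_seed: int = 0,
) -> Tuple[List[FrozenSet[str]], GeneSetCollection]:
    """Random vertex sets plus an independent GMT collection.

    Under this null no module is related to any term, so the fraction of
    (module, term) tests passing a q <= alpha screen estimates the
    procedure's false discovery behaviour.
    """
    rng = np.random.default_rng([rng_seed, 4])
    genes = [f"G{i:04d}" for i in range(1, universe_size + 1)]
    modules = []
    for _ in range(n_modules):
        idx = rng.choice(universe_size, size=module_size, replace=False)
        modules.append(frozenset(genes[i] for i in idx))
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        idx = rng.choice(universe_size, size=size, replace=False)
        sets[f"RAND_{i:03d}"] = (f"random set {i}", frozenset(genes[j] for j in idx))
    return modules, GeneSetCollection(sets=sets, universe=frozenset(genes))
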