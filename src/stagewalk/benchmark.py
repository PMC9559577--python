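"""Evaluation of recovered modules against planted truth.

The walk pipeline deliberately screens a weight quantile, so it assigns
only a subset of the vertices; recovery quality is therefore scored over
the assigned vertices (Adjusted Rand Index between the recovered module
labels and the planted lineage labels, with unplanted vertices carrying
a shared background label), while coverage is reported separately.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
from sklearn.metrics import adjusted_rand_score

from .module_screen import Module

BACKGROUND = 0  # truth label for vertices outside every planted module


def module_recovery_ari(
    modules: Sequence[Module], truth: Mapping[str, int]
) -> float:
    """ARI between recovered assignment and planted lineages, over the
    vertices the pipeline assigned to modules."""
    labels_true = []
    labels_pred = []
    for mod in modules:
        for v in sorted(mod.members):
            labels_true.append(truth.get(v, BACKGROUND))
            labels_pred.append(mod.module_id)
    if not labels_pred:
        return 0.0
    return float(adjusted_rand_score(labels_true, labels_pred))


def assignment_coverage(
    modules: Sequence[Module], truth: Mapping[str, int]
) -> float:
    """Fraction of planted vertices that the recovered modules cover."""
    planted = {v for v, lineage in truth.items() if lineage != BACKGROUND}
    if not planted:
        return 0.0
    assigned = {v for mod in modules for v in mod.members}
    return len(planted & assigned) / len(planted)


def match_modules_to_lineages(
    modules: Sequence[Module], truth: Mapping[str, int]
) -> Dict[int, Module]:
    """Greedy best match: each lineage gets the recovered module with the
    largest member overlap (ties to the smaller module id); lineages with
    no overlapping module are absent from the result."""
    best: Dict[int, Tuple[int, str, Module]] = {}
    for mod in modules:
        counts: Dict[int, int] = {}
        for v in mod.members:
            lineage = truth.get(v, BACKGROUND)
            if lineage != BACKGROUND:
                counts[lineage] = counts.get(lineage, 0) + 1
        for lineage, count in counts.items():
            key = (-count, mod.module_id)
            if lineage not in best or key < (-best[lineage][0], best[lineage][1]):
                best[lineage] = (count, mod.module_id, mod)
    return {lineage: mod for lineage, (_, _, mod) in best.items()}


def lineage_interstage_jaccards(
    modules_by_stage: Mapping[str, Sequence[Module]],
    memberships: Mapping[str, Mapping[str, int]],
    gmn: nx.Graph,
) -> Dict[Tuple[int, str, str], float]:
    """Inter-stage edge weight carried by each planted lineage.

    For every lineage and every adjacent stage pair, look up the recovered
    modules matched to the lineage in both stages and report the Jaccard
    weight of the global-module-network edge between them (0 when either
    match or the edge is missing).
    """
    from .graph_io import STAGES

    stages = [s for s in STAGES if s in memberships]
    matches = {
        stage: match_modules_to_lineages(modules_by_stage.get(stage, []), memberships[stage])
        for stage in stages
    }
    lineages = sorted({l for truth in memberships.values() for l in truth.values()})
    out: Dict[Tuple[int, str, str], float] = {}
    for stage_a, stage_b in zip(stages, stages[1:]):
        for lineage in lineages:
            ma = matches[stage_a].get(lineage)
            mb = matches[stage_b].get(lineage)
            weight = 0.0
            if ma is not None and mb is not None and gmn.has_edge(ma.label, mb.label):
                data = gmn.edges[ma.label, mb.label]
                if data.get("edge_class") == "inter":
                    weight = float(data.get("weight", 0.0))
            out[(lineage, stage_a, stage_b)] = weight
    return out
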