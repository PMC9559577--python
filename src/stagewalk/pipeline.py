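"""End-to-end orchestration: networks -> walks -> modules -> evolution networks.

`run_pipeline` is the library entry point behind the command-line `run`
subcommand.  It consumes a `RunConfig`, executes every stage of the
method in order, writes all artifacts (weight tables, module table,
three GraphML networks, enrichment and design-comparison TSVs) into the
output directory, and records a manifest with the config echo, seed and
per-stage counts so any run can be reproduced from its output directory
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import __version__
from .core_evolution import (
    CoreConfig,
    build_comprehensive,
    build_core_evolution,
    core_summary_table,
    degree_summary,
    select_core,
)
from .enrichment import (
    DEFAULT_Q_MAX,
    GeneSetCollection,
    build_functional_network,
    compare_designs,
    enrich_modules,
    read_gmt,
    read_universe,
    write_enrichment_table,
)
from .errors import StagewalkError
from .graph_io import (
    STAGES,
    StageNetwork,
    read_stage_network,
    write_module_table,
    write_network,
    write_weight_table,
)
from .module_screen import ScreenConfig, screen_modules
from .rw_cluster import WalkConfig, accumulate_weights, select_vertices
from .stage_network import build_global_module_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input paths plus every stage's parameters."""

    edge_paths: Dict[str, str]
    type_path: str
    gmt_path: str
    out_dir: str
    universe_path: Optional[str] = None
    walk: WalkConfig = field(default_factory=WalkConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    core: CoreConfig = field(default_factory=CoreConfig)
    q_max: float = DEFAULT_Q_MAX
    genes_only: bool = True

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [*self.edge_paths.values(), self.type_path, self.gmt_path]
            if not os.path.exists(p)
        ]
        if self.universe_path and not os.path.exists(self.universe_path):
            missing.append(self.universe_path)
        if missing:
            raise StagewalkError(f"missing input file(s): {', '.join(sorted(missing))}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        return cls(
            edge_paths={s: resolve(p) for s, p in raw["edge_paths"].items()},
            type_path=resolve(raw["type_path"]),
            gmt_path=resolve(raw["gmt_path"]),
            out_dir=resolve(raw["out_dir"]),
            universe_path=resolve(raw["universe_path"]) if raw.get("universe_path") else None,
            walk=WalkConfig(**raw.get("walk", {})),
            screen=ScreenConfig(**raw.get("screen", {})),
            core=CoreConfig(**raw.get("core", {})),
            q_max=raw.get("q_max", DEFAULT_Q_MAX),
            genes_only=raw.get("genes_only", True),
        )


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full method and write artifacts into ``config.out_dir``.

    Returns the in-memory results (networks, modules, enrichment, core
    network) so callers can continue working with them.
    """
    config.validate_paths()
    os.makedirs(config.out_dir, exist_ok=True)

    networks: Dict[str, StageNetwork] = {}
    for stage in STAGES:
        if stage not in config.edge_paths:
            continue
        logger.info("reading stage %s", stage)
        networks[stage] = read_stage_network(
            config.edge_paths[stage], config.type_path, stage
        )
    kinds = {
        v: net.kind_of(v) for net in networks.values() for v in net.vertices
    }

    universe = read_universe(config.universe_path) if config.universe_path else None
    collection = read_gmt(config.gmt_path, universe=universe)

    selected: Dict[str, set] = {}
    modules_by_stage: Dict[str, list] = {}
    counts: Dict[str, Dict[str, int]] = {}
    for stage, net in networks.items():
        logger.info("stage %s: accumulating walk weights", stage)
        table = accumulate_weights(net, config.walk)
        write_weight_table(
            table.weights, kinds, os.path.join(config.out_dir, f"weights_{stage}.tsv")
        )
        selected[stage] = select_vertices(table, config.walk)
        modules_by_stage[stage] = screen_modules(selected[stage], net, config.screen)
        counts[stage] = {
            "vertices": net.graph.number_of_nodes(),
            "edges": net.graph.number_of_edges(),
            "selected": len(selected[stage]),
            "modules": len(modules_by_stage[stage]),
        }
        logger.info("stage %s: %s", stage, counts[stage])

    all_modules = [m for mods in modules_by_stage.values() for m in mods]
    write_module_table(all_modules, kinds, os.path.join(config.out_dir, "modules.tsv"))

    gmn = build_global_module_network(modules_by_stage, networks)
    write_network(gmn, os.path.join(config.out_dir, "global_module_network.graphml"))

    results = enrich_modules(
        all_modules,
        collection,
        q_max=config.q_max,
        molecule_kinds=kinds,
        genes_only=config.genes_only,
    )
    write_enrichment_table(results, os.path.join(config.out_dir, "enrichment.tsv"))
    fn = build_functional_network(results, collection)
    write_network(fn.graph, os.path.join(config.out_dir, "functional_network.graphml"))

    comprehensive = build_comprehensive(gmn, fn, results)
    write_network(
        comprehensive, os.path.join(config.out_dir, "comprehensive_network.graphml")
    )
    if any(d.get("node_class") == "module" for _, d in comprehensive.nodes(data=True)):
        frac_below, one_sigma = degree_summary(comprehensive, config.core.core_degree_min)
    else:
        frac_below, one_sigma = float("nan"), float("nan")
    core_sets = select_core(comprehensive, config.core)
    core_net = build_core_evolution(comprehensive, core_sets, collection, config.core)
    write_network(core_net, os.path.join(config.out_dir, "core_evolution_network.graphml"))
    core_summary_table(core_net).to_csv(
        os.path.join(config.out_dir, "core_summary.tsv"), sep="\t", index=False
    )

    comparison = compare_designs(
        networks, selected, modules_by_stage, collection,
        molecule_kinds=kinds, genes_only=config.genes_only,
    )
    comparison.to_csv(os.path.join(config.out_dir, "design_comparison.tsv"), sep="\t")

    manifest = {
        "stagewalk_version": __version__,
        "python": platform.python_version(),
        "seed": config.walk.rng_seed,
        "walk": dataclasses.asdict(config.walk),
        "screen": dataclasses.asdict(config.screen),
        "core": dataclasses.asdict(config.core),
        "q_max": config.q_max,
        "genes_only": config.genes_only,
        "inputs": {
            "edge_paths": config.edge_paths,
            "type_path": config.type_path,
            "gmt_path": config.gmt_path,
            "universe_path": config.universe_path,
        },
        "per_stage_counts": counts,
        "fraction_modules_below_core_degree": frac_below,
        "one_sigma_normal_mass": one_sigma,
        "n_core_modules": len(core_sets[0]),
        "n_core_functions": len(core_sets[1]),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "networks": networks,
        "kinds": kinds,
        "selected": selected,
        "modules_by_stage": modules_by_stage,
        "global_module_network": gmn,
        "enrichment": results,
        "functional_network": fn,
        "comprehensive": comprehensive,
        "core_sets": core_sets,
        "core_evolution": core_net,
        "design_comparison": comparison,
        "manifest": manifest,
    }
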