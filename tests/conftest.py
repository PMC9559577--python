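import os

import pytest
from hypothesis import settings

import stagewalk as sw

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


@pytest.fixture(scope="session")
def table1_gmt_path() -> str:
    return os.path.join(DATA_DIR, "table1.gmt")


@pytest.fixture(scope="session")
def default_data() -> sw.SyntheticData:
    """The standard planted-module benchmark fixture."""
    return sw.generate(sw.SyntheticSpec())


@pytest.fixture(scope="session")
def default_walk_config() -> sw.WalkConfig:
    return sw.WalkConfig(rng_seed=7)


@pytest.fixture(scope="session")
def pipeline_result(default_data, default_walk_config):
    """Walk -> select -> screen -> link -> enrich on the benchmark fixture.

    Session-scoped: the walk accumulation is the expensive part and many
    tests only inspect its downstream products.
    """
    data = default_data
    screen_cfg = sw.ScreenConfig()
    selected, modules_by_stage = {}, {}
    for stage, net in data.networks.items():
        table = sw.accumulate_weights(net, default_walk_config)
        selected[stage] = sw.select_vertices(table, default_walk_config)
        modules_by_stage[stage] = sw.screen_modules(selected[stage], net, screen_cfg)
    gmn = sw.build_global_module_network(modules_by_stage, data.networks)
    all_modules = [m for mods in modules_by_stage.values() for m in mods]
    results = sw.enrich_modules(
        all_modules, data.collection, molecule_kinds=data.kinds, genes_only=True
    )
    fn = sw.build_functional_network(results, data.collection)
    comprehensive = sw.build_comprehensive(gmn, fn, results)
    return {
        "data": data,
        "selected": selected,
        "modules_by_stage": modules_by_stage,
        "all_modules": all_modules,
        "gmn": gmn,
        "enrichment": results,
        "fn": fn,
        "comprehensive": comprehensive,
    }


def make_stage_network(edges, kinds=None, stage="S1", isolates=()):
    """Small-network builder used across test modules."""
    net = sw.StageNetwork(stage)
    kinds = kinds or {}
    vertices = {v for e in edges for v in e} | set(isolates)
    for v in sorted(vertices):
        net.add_molecule(sw.Molecule(v, kinds.get(v, "gene")))
    for a, b in edges:
        net.add_edge(a, b)
    return net
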