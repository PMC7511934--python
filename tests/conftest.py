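"""Shared fixtures: one default synthetic world reused across the suite.

The expensive pipeline objects (genome, probes, ligation libraries, calls)
are session-scoped so each is built once.
"""

from dataclasses import replace
from types import SimpleNamespace

import pytest

from capcraft import (
    SyntheticScenario,
    build_bin_map,
    call_pirs,
    design_probe_set,
    define_promoter_windows,
    digest_genome,
    estimate_distance_decay,
    generate_genome,
    merge_bait_bins,
    pairs_to_chinput,
    simulate_capture,
    simulate_ligation_products,
)
from capcraft.downsample import combine_chinputs

GENOME_SEED = 1
REPLICATE_PAIR_SEEDS = (100, 101, 102)
REPLICATE_CAPTURE_SEEDS = (200, 201, 202)
BACKGROUND_SEED = 5


def build_world(scenario, genome_seed):
    gen = generate_genome(scenario, genome_seed)
    fragments = digest_genome(gen.genome)
    promoters = define_promoter_windows(gen.genes, gen.chrom_sizes)
    probes, report = design_probe_set(promoters, fragments, gen.genome)
    bins = build_bin_map(gen.chrom_sizes, scenario.bin_size)
    baits = merge_bait_bins(bins, probes)
    return SimpleNamespace(
        scenario=scenario,
        gen=gen,
        fragments=fragments,
        promoters=promoters,
        probes=probes,
        report=report,
        bins=bins,
        baits=baits,
    )


def build_library(world, pair_seed, capture_seed, n_products=None):
    pairs = simulate_ligation_products(world.gen, world.scenario, pair_seed, n_products=n_products)
    captured = simulate_capture(pairs, world.bins, world.baits, world.probes, world.scenario, capture_seed)
    chinput = pairs_to_chinput(captured, world.bins, world.baits)
    return SimpleNamespace(pairs=pairs, captured=captured, chinput=chinput)


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario()


@pytest.fixture(scope="session")
def world(default_scenario):
    """Default scenario: genome, fragment map, probes, bins and baits."""
    return build_world(default_scenario, GENOME_SEED)


@pytest.fixture(scope="session")
def libraries(world):
    """Three independent replicate libraries (pairs, captured pairs, chinput)."""
    return [
        build_library(world, ps, cs)
        for ps, cs in zip(REPLICATE_PAIR_SEEDS, REPLICATE_CAPTURE_SEEDS)
    ]


@pytest.fixture(scope="session")
def replicates(libraries):
    """Three independent captured replicate chinput tables."""
    return [lib.chinput for lib in libraries]


@pytest.fixture(scope="session")
def combined(world, replicates):
    """Replicate-pooled chinput with its decay profile and PIR calls."""
    table = combine_chinputs(replicates)
    profile = estimate_distance_decay(table, world.bins, world.baits)
    calls = call_pirs(table, profile, world.bins, world.baits)
    return SimpleNamespace(chinput=table, profile=profile, calls=calls)


@pytest.fixture(scope="session")
def background_run():
    """Pure-background scenario (no planted loops) with its calls."""
    scenario = replace(
        SyntheticScenario(), n_enhancer_loops=0, n_ctcf_loops=0, loop_enrichment=1.0
    )
    w = build_world(scenario, BACKGROUND_SEED)
    lib = build_library(w, BACKGROUND_SEED + 1, BACKGROUND_SEED + 2)
    profile = estimate_distance_decay(lib.chinput, w.bins, w.baits)
    calls = call_pirs(lib.chinput, profile, w.bins, w.baits)
    return SimpleNamespace(world=w, library=lib, profile=profile, calls=calls)
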