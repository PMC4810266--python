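"""Shared fixtures: simulated families at two scales.

The session-scoped batch of 20 desk-scale families backs the end-to-end
recovery, AAI-calibration and pan/core-law tests so the (dominant)
alignment cost is paid once.
"""

from __future__ import annotations

import pytest

from gvlineage.pipeline import analyze_family
from gvlineage.simulate import SimulationConfig, simulate_family

BATCH_SEEDS = list(range(1, 21))


@pytest.fixture(scope="session")
def family_run():
    """One desk-scale family (seed 42) analysed end to end with markers."""
    cfg = SimulationConfig.desk_scale(42)
    genomes, truth = simulate_family(cfg)
    res = analyze_family(genomes, marker_seeds=truth.marker_seeds)
    return cfg, genomes, truth, res


@pytest.fixture(scope="session")
def family_batch():
    """Twenty desk-scale families (seeds 1-20), analysed without phylogeny."""
    out = []
    for seed in BATCH_SEEDS:
        cfg = SimulationConfig.desk_scale(seed)
        genomes, truth = simulate_family(cfg)
        res = analyze_family(genomes, do_phylogeny=False)
        out.append((cfg, genomes, truth, res))
    return out


@pytest.fixture(scope="session")
def tiny_family():
    """A very small family for cheap unit tests (not the study conditions)."""
    cfg = SimulationConfig.desk_scale(
        7, ancestral_gene_count=40, orfan_count=3, paralog_n_families=3
    )
    genomes, truth = simulate_family(cfg)
    return cfg, genomes, truth
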