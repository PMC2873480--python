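"""Shared fixtures: one default-condition simulation + pipeline run per session.

The default SimulationConfig/DiscoveryConfig values are the study conditions;
tests observe their outputs rather than re-tuning them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutmir import (
    ArrayConfig,
    DiscoveryConfig,
    PreprocessConfig,
    SimulationConfig,
    build_stacks,
    call_detection,
    clip_adapter,
    collapse_reads,
    discover,
    filter_contigs,
    filter_multimappers,
    map_reads,
    normalize,
    simulate_catalog,
    simulate_reads,
)
from gutmir.simulate import build_genome, simulate_array

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim():
    """Default-condition simulation: genome, truth, reads, catalog, arrays."""
    config = SimulationConfig()
    genome, truth = build_genome(config)
    reads = simulate_reads(genome, truth, config)
    catalog = simulate_catalog(truth, config)
    arrays = simulate_array(truth, config)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "catalog": catalog,
        "arrays": arrays,
    }


@pytest.fixture(scope="session")
def pipeline(sim):
    """Preprocessing + discovery run at default study conditions."""
    pp = PreprocessConfig()
    inserts, clip_report = clip_adapter(sim["reads"], pp)
    collapsed = collapse_reads(inserts)
    contigs = filter_contigs(sim["genome"], pp)
    hits = map_reads(collapsed, contigs)
    kept_hits = filter_multimappers(hits, pp)
    stacks = build_stacks(kept_hits)
    reads_by_id = {r.id: r for r in collapsed}
    partition, control, windows = discover(
        contigs, stacks, kept_hits, reads_by_id, sim["catalog"], DiscoveryConfig()
    )
    return {
        "preprocess": pp,
        "inserts": inserts,
        "clip_report": clip_report,
        "collapsed": collapsed,
        "contigs": contigs,
        "hits": hits,
        "kept_hits": kept_hits,
        "stacks": stacks,
        "reads_by_id": reads_by_id,
        "partition": partition,
        "control": control,
        "windows": windows,
        "passing": partition["known"] + partition["novel"],
    }


@pytest.fixture(scope="session")
def normalized(sim):
    """glog-normalized array matrix and detection calls at defaults."""
    matrix = normalize(sim["arrays"], ArrayConfig())
    calls = call_detection(matrix, ArrayConfig())
    return {"matrix": matrix, "calls": calls}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
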