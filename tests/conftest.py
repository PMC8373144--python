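"""Shared fixtures: a small genome with planted repeats, and one
session-scoped run of the bundled demonstration pipeline."""

from __future__ import annotations

import pytest

from breakscan import pipeline, simdata


@pytest.fixture(scope="session")
def small_genome():
    """20-kb single-chromosome genome with a (CTG)10 and a (GAA)10 run."""
    params = simdata.SimParams(seed=11, n_reads=0)
    genome, loci = simdata.make_genome(
        params,
        n_chrom=1,
        lengths=[20_000],
        loci_spec=[
            simdata.Locus("ctg10", "chrI", 5_000, 5_030, "+", "microsatellite", "CTG", 10),
            simdata.Locus("gaa10", "chrI", 12_000, 12_030, "+", "microsatellite", "GAA", 10),
        ],
    )
    return genome, loci


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run of the bundled demo experiment (seed 1)."""
    outdir = tmp_path_factory.mktemp("demo")
    cfg = pipeline.demo_config(seed=1)
    manifest = pipeline.run_pipeline(cfg, str(outdir))
    return cfg, manifest, outdir
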