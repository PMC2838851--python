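"""Shared fixtures: simulations are generated once per session."""

from __future__ import annotations

import pytest

from mirkit import pipeline, simulate
from mirkit.preprocess import ReadRecord


def as_read_records(sim_reads):
    return [ReadRecord(r.read_id, r.sequence, r.quality) for r in sim_reads]


def run_discovery(genome, ann, ref, reads, cfg, seed):
    return pipeline.discover(
        {lib: as_read_records(rs) for lib, rs in reads.items()},
        genome,
        ann,
        ref,
        adapter3=cfg.adapter3,
        adapter5=cfg.adapter5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions: 2 x 100 kb chromosomes, 30 true
    miRNAs, 10 TE miRNAs, 20 ncRNA decoys, 3 libraries."""
    cfg = simulate.SimConfig(seed=1)
    genome, ann, ref, truth = simulate.build_reference(cfg)
    reads, counts = simulate.simulate_reads(genome, truth, cfg, n_libraries=3)
    return cfg, genome, ann, ref, truth, reads, counts


@pytest.fixture(scope="session")
def default_run(default_sim):
    cfg, genome, ann, ref, truth, reads, counts = default_sim
    result = run_discovery(genome, ann, ref, reads, cfg, seed=1)
    return cfg, genome, ann, ref, truth, reads, counts, result


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulation for cheap integration tests."""
    cfg = simulate.SimConfig(
        seed=5,
        chrom_length=40_000,
        n_true_mirnas=6,
        n_te_mirnas=2,
        n_decoy_ncrna=6,
        n_gene_models=3,
        n_noise_loci=2,
    )
    genome, ann, ref, truth = simulate.build_reference(cfg)
    reads, counts = simulate.simulate_reads(genome, truth, cfg, n_libraries=2)
    return cfg, genome, ann, ref, truth, reads, counts


def overlaps(rec, locus, same_strand=True):
    """Ground-truth record vs called locus interval overlap."""
    if rec.chrom != locus.chrom:
        return False
    if same_strand and rec.strand != locus.strand:
        return False
    return min(rec.end, locus.end) - max(rec.start, locus.start) > 0
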