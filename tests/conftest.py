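import io
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tdnascope.pipeline import PipelineConfig, run_pipeline, write_fasta
from tdnascope.presets import yl_replica_spec
from tdnascope.reads import ReadSimParams, simulate_reads
from tdnascope.simulate import (
    VECTOR_SOURCE,
    Walk,
    WalkBlock,
    build_reference,
    build_vector,
    plant_architecture,
)

REPLICA_SEED = 1
VECTOR_SEED = 2


@pytest.fixture(scope="session")
def replica_truth():
    """Planted full-scale (4 x 500 kb) replica architecture."""
    ref = build_reference(4, [500_000] * 4, 0.36, seed=REPLICA_SEED)
    vector = build_vector(seed=VECTOR_SEED)
    return plant_architecture(ref, vector, yl_replica_spec(ref, vector))


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-scale (4 x 200 kb) replica for cheaper tests."""
    ref = build_reference(4, [200_000] * 4, 0.36, seed=REPLICA_SEED)
    vector = build_vector(seed=VECTOR_SEED)
    return plant_architecture(ref, vector, yl_replica_spec(ref, vector))


def control_walks(truth):
    return [
        Walk(f"control{h}_{name}", h, [WalkBlock(name, 0, len(seq), False, 0, len(seq))], seq)
        for h in (0, 1)
        for name, seq in truth.reference.chromosomes
    ]


def _run_replica_pipeline(truth, tmp_path, sub_rate: float, seed: int):
    d = tmp_path
    write_fasta(str(d / "reference.fasta"), truth.reference.chromosomes)
    write_fasta(str(d / "vector.fasta"), [(VECTOR_SOURCE, truth.vector.sequence)])
    params = ReadSimParams(
        mean_depth=15, read_mean=12_000, read_sd=5_000, sub_rate=sub_rate, seed=seed
    )
    with open(d / "reads.fastq", "w") as fq, open(d / "origin.tsv", "w") as og:
        simulate_reads(truth.walks, params, fq, og)
    config = PipelineConfig(
        reads=str(d / "reads.fastq"),
        reference=str(d / "reference.fasta"),
        vector=str(d / "vector.fasta"),
        out=str(d / "out"),
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def replica_report(replica_truth, tmp_path_factory):
    """Full pipeline on error-free ~30x (diploid) reads over the replica."""
    return _run_replica_pipeline(
        replica_truth, tmp_path_factory.mktemp("replica_clean"), 0.0, seed=5
    )


@pytest.fixture(scope="session")
def replica_report_noisy(replica_truth, tmp_path_factory):
    """Full pipeline at 1% substitution error, ~30x diploid."""
    return _run_replica_pipeline(
        replica_truth, tmp_path_factory.mktemp("replica_noisy"), 0.01, seed=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
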