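import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdnascope.align import LocalAlignment, TargetIndex, align_to_index

from tdnascope.reads import ReadSimParams, simulate_reads
from tdnascope.segment import SegmentParams, classify_reads, segment_read
from tdnascope.simulate import (
    ArchitectureSpec,
    IntactInsertion,
    JunctionSignatureSpec,
    TdnaFragmentSpec,
    VECTOR_SOURCE,
    build_reference,
    build_vector,
    plant_architecture,
)

BLUNT = JunctionSignatureSpec()


@pytest.fixture(scope="module")
def insertion_scene():
    ref = build_reference(1, [60_000], 0.45, seed=21)
    vector = build_vector(seed=22)
    spec = ArchitectureSpec(
        [IntactInsertion("chr1", 30_000, (TdnaFragmentSpec(2454, 10524),), (BLUNT, BLUNT))]
    )
    truth = plant_architecture(ref, vector, spec)
    targets = truth.reference.as_dict()
    targets[VECTOR_SOURCE] = truth.vector.sequence
    return truth, TargetIndex(targets, 15)


def _segment(read_id, seq, index, params=None):
    alns = align_to_index(read_id, seq, index)
    return segment_read(read_id, len(seq), alns, params or SegmentParams())


def test_read_spanning_junction_two_segments(insertion_scene):
    truth, index = insertion_scene
    walk = truth.haplotype_walks(0)[0]
    read = walk.sequence[26_000 : 32_000]  # crosses chr1 -> vector junction
    sr = _segment("r1", read, index)
    assert [s.source for s in sr.segments] == ["chr1", VECTOR_SOURCE]
    assert sr.segments[0].source_end == 30_000
    assert sr.segments[1].source_start == 2453
    assert sr.segments[1].strand == "+"


def test_read_with_no_alignment(insertion_scene):
    _, index = insertion_scene
    sr = segment_read("r0", 500, [], SegmentParams())
    assert sr.segments == []
    assert sr.gaps == [(0, 500)]


def test_six_fragment_bridge_read_has_eight_segments(replica_truth):
    targets = replica_truth.reference.as_dict()
    targets[VECTOR_SOURCE] = replica_truth.vector.sequence
    index = TargetIndex(targets, 15)
    bridge_walk = next(
        w
        for w in replica_truth.walks
        if len([b for b in w.blocks if b.fragment is not None]) == 6
    )
    frag_blocks = [b for b in bridge_walk.blocks if b.fragment is not None]
    lo = frag_blocks[0].walk_start - 1500
    hi = frag_blocks[-1].walk_end + 1500
    read = bridge_walk.sequence[lo:hi]
    sr = _segment("bridge", read, index)
    assert len(sr.segments) == 8
    sources = [s.source for s in sr.segments]
    assert sources[0] != VECTOR_SOURCE and sources[-1] != VECTOR_SOURCE
    assert all(s == VECTOR_SOURCE for s in sources[1:-1])
    specs = [s.fragment_spec() for s in sr.segments[1:-1]]
    assert [(f.start, f.end) for f in specs] == [
        (b.fragment.start, b.fragment.end) for b in frag_blocks
    ]


def test_classify_reads_trivial_cases():
    alns = [
        LocalAlignment("r_vec", 0, 500, VECTOR_SOURCE, 100, 600, "+", 0.99, 1000),
        LocalAlignment("r_gen", 0, 500, "chr1", 100, 600, "+", 0.99, 1000),
        LocalAlignment("r_short", 0, 100, VECTOR_SOURCE, 100, 200, "+", 0.99, 200),
        LocalAlignment("r_bad", 0, 500, VECTOR_SOURCE, 100, 600, "+", 0.5, 300),
    ]
    ids = ["r_vec", "r_gen", "r_short", "r_bad", "r_none"]
    vc, passthrough = classify_reads(ids, alns)
    assert vc == {"r_vec"}
    assert passthrough == {"r_gen", "r_short", "r_bad", "r_none"}


def test_classify_reads_recovery_against_origin_oracle(insertion_scene):
    truth, index = insertion_scene
    params = ReadSimParams(mean_depth=8, read_mean=4000, read_sd=800, seed=23)
    fq = io.StringIO()
    origins = simulate_reads(truth.walks, params, fq)
    reads = {}
    lines = fq.getvalue().splitlines()
    for i in range(0, len(lines), 4):
        reads[lines[i][1:]] = lines[i + 1]
    sp = SegmentParams()
    alns = []
    for rid, seq in reads.items():
        alns.extend(align_to_index(rid, seq, index))
    vc, _ = classify_reads(reads.keys(), alns, sp)
    # origin-log oracle: the inserted tract occupies this walk interval
    walk = truth.haplotype_walks(0)[0]
    frag = next(b for b in walk.blocks if b.fragment is not None)
    expected = {
        o.read_id
        for o in origins
        if o.walk == walk.name
        and min(o.end, frag.walk_end) - max(o.start, frag.walk_start) >= sp.min_vector_span
    }
    assert expected == vc


def test_segment_cover_and_gaps_partition_read(insertion_scene):
    truth, index = insertion_scene
    walk = truth.haplotype_walks(0)[0]
    rng = np.random.default_rng(3)
    for _ in range(10):
        lo = int(rng.integers(0, len(walk.sequence) - 5000))
        read = walk.sequence[lo : lo + 5000]
        sr = _segment("r", read, index)
        covered = sorted(
            [(s.read_start, s.read_end) for s in sr.segments] + list(sr.gaps)
        )
        # exact partition: intervals abut and span [0, len)
        assert covered[0][0] == 0
        assert covered[-1][1] == 5000
        for (a, b), (c, d) in zip(covered[:-1], covered[1:]):
            assert b == c


@settings(max_examples=30, deadline=None)
@given(st.data())
def test_schedule_prefers_high_scoring_nonredundant_tilings(data):
    """Selected alignments never overlap more than merge_overlap and each
    contributes positive net score (property of the tiling DP)."""
    n = data.draw(st.integers(1, 8))
    cands = []
    for i in range(n):
        start = data.draw(st.integers(0, 4000))
        length = data.draw(st.integers(60, 2000))
        score = 2.0 * length * data.draw(st.floats(0.5, 1.0))
        cands.append(
            LocalAlignment(f"r", start, start + length, "t", 0, length, "+", 0.9, score)
        )
    sr = segment_read("r", 8000, cands, SegmentParams())
    for s1, s2 in zip(sr.segments[:-1], sr.segments[1:]):
        assert s1.read_end <= s2.read_start  # trimmed to disjoint
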