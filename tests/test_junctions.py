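import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdnascope.junctions import (
    Junction,
    JunctionParams,
    Observation,
    call_breakpoints,
    classify_events,
    cluster_observations,
    concatemer_length,
    build_fragment_graph,
    insertion_loci,
    _letters,
)
from tdnascope.junctions import ConcatemerArchitecture
from tdnascope.segment import ReadSegment, SegmentedRead
from tdnascope.simulate import JunctionSide, TdnaFragmentSpec, build_reference

from oracles import single_linkage_clusters


def _read_with_junction(read_id, coord_a, coord_b, jitter_a=0, jitter_b=0):
    return SegmentedRead(
        read_id,
        4000,
        [
            ReadSegment(0, 2000, "chr1", coord_a - 2000 + jitter_a, coord_a + jitter_a, "+"),
            ReadSegment(2000, 4000, "chr2", coord_b + jitter_b, coord_b + 2000 + jitter_b, "+"),
        ],
        [],
    )


def test_cluster_with_jitter_single_junction():
    rng = np.random.default_rng(1)
    reads = [
        _read_with_junction(f"r{i}", 10_000, 5_000, int(rng.integers(-3, 4)), int(rng.integers(-3, 4)))
        for i in range(12)
    ]
    junctions = call_breakpoints(reads, JunctionParams(cluster_tol=20, min_support=3))
    assert len(junctions) == 1
    j = junctions[0]
    assert j.support == 12
    assert abs(j.side_a.coord - 10_000) <= 3
    assert abs(j.side_b.coord - 5_000) <= 3
    assert j.label == "a"


def test_distant_observations_two_junctions():
    reads = [_read_with_junction(f"r{i}", 10_000, 5_000) for i in range(3)]
    reads += [_read_with_junction(f"s{i}", 11_000, 5_000) for i in range(3)]
    junctions = call_breakpoints(reads, JunctionParams(cluster_tol=20, min_support=3))
    assert len(junctions) == 2


def test_empty_input():
    assert call_breakpoints([], JunctionParams()) == []


def test_min_support_filters():
    reads = [_read_with_junction(f"r{i}", 10_000, 5_000) for i in range(2)]
    assert call_breakpoints(reads, JunctionParams(min_support=3)) == []


@pytest.mark.parametrize("seed", range(5))
def test_clustering_matches_single_linkage_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    centers = rng.integers(0, 100_000, size=(max(2, n // 20), 2))
    points = []
    for _ in range(n):
        c = centers[rng.integers(0, len(centers))]
        points.append(
            (int(c[0] + rng.integers(-15, 16)), int(c[1] + rng.integers(-15, 16)))
        )
    tol = 20
    observations = [
        Observation(
            JunctionSide("chr1", a, "left"), JunctionSide("chr2", b, "right"),
            f"r{i}", 100, "+",
        )
        for i, (a, b) in enumerate(points)
    ]
    clusters = cluster_observations(observations, tol)
    mine = sorted(
        sorted(int(o.read_id[1:]) for o in members) for members in clusters
    )
    oracle = sorted(sorted(c) for c in single_linkage_clusters(points, tol))
    assert mine == oracle


# ---------------------------------------------------------------------------
# concatemer length
# ---------------------------------------------------------------------------


def test_concatemer_length_printed_lists():
    assert concatemer_length([(9144, 10320), (7240, 2523), (2467, 7239), (7919, 7305)]) == 11_279
    assert concatemer_length(
        [(9854, 10334), (5396, 2476), (9014, 10354), (10404, 8306), (4099, 7239), (7919, 2697)]
    ) == 15_200


def test_concatemer_length_degenerate():
    assert concatemer_length([(100, 100)]) == 0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 11_000), st.integers(1, 11_000)), min_size=1, max_size=8
    )
)
def test_concatemer_length_reversal_invariant(frags):
    flipped = [(e, s) for s, e in reversed(frags)]
    assert concatemer_length(frags) == concatemer_length(flipped)
    assert concatemer_length(TdnaFragmentSpec(s, e) for s, e in frags) == concatemer_length(frags)


# ---------------------------------------------------------------------------
# fragment graph and event classification
# ---------------------------------------------------------------------------


def test_graph_no_junctions_one_node_per_chromosome():
    ref = build_reference(3, [10_000, 20_000, 30_000], 0.5, seed=2)
    graph = build_fragment_graph([], ref)
    assert [n.name for n in graph.nodes] == ["chr1", "chr2", "chr3"]
    assert graph.edges == []


def test_graph_partition_conserves_length():
    ref = build_reference(2, [50_000, 50_000], 0.5, seed=3)
    junctions = [
        Junction(JunctionSide("chr1", 10_000, "left"), JunctionSide("chr2", 20_000, "left"), 5),
        Junction(JunctionSide("chr1", 30_000, "left"), JunctionSide("vector", 100, "right"), 5),
    ]
    graph = build_fragment_graph(junctions, ref)
    for chrom in ("chr1", "chr2"):
        nodes = [n for n in graph.nodes if n.chrom == chrom]
        assert sum(n.end - n.start for n in nodes) == ref.length(chrom)
    assert [n.name for n in graph.nodes if n.chrom == "chr1"] == ["chr1-1", "chr1-2", "chr1-3"]


def test_bare_junction_creates_bare_edge():
    ref = build_reference(2, [50_000, 50_000], 0.5, seed=3)
    junctions = [
        Junction(JunctionSide("chr1", 10_000, "left"), JunctionSide("chr2", 20_000, "left"), 5)
    ]
    graph = build_fragment_graph(junctions, ref)
    assert len(graph.edges) == 1
    assert graph.edges[0].kind == "bare"


def _arch(left, right, n_frags=1):
    return ConcatemerArchitecture(left, right, [TdnaFragmentSpec(100, 200)] * n_frags)


def test_classify_events_cases():
    ref = build_reference(2, [50_000, 50_000], 0.5, seed=4)
    graph = build_fragment_graph([], ref)
    archs = [
        _arch(JunctionSide("chr1", 10_000, "left"), JunctionSide("chr1", 10_020, "right")),
        _arch(JunctionSide("chr1", 20_000, "left"), None),
        _arch(JunctionSide("chr1", 30_000, "left"), JunctionSide("chr2", 5_000, "right")),
        _arch(JunctionSide("chr1", 40_000, "left"), JunctionSide("chr1", 45_000, "right")),
    ]
    bare = [
        Junction(JunctionSide("chr1", 12_000, "left"), JunctionSide("chr2", 9_000, "left"), 4)
    ]
    events = classify_events(graph, archs, bare, gap_tol=100)
    assert [e.case for e in events] == [
        "intact_insertion", "truncation", "translocation", "translocation", "bare_translocation",
    ]


def test_insertion_loci_merging():
    junctions = [
        Junction(JunctionSide("chr1", 5_000, "left"), JunctionSide("vector", 10, "right"), 5),
        Junction(JunctionSide("chr1", 5_020, "right"), JunctionSide("vector", 900, "left"), 5),
        Junction(JunctionSide("chr2", 9_000, "left"), JunctionSide("vector", 10, "right"), 5),
    ]
    loci = insertion_loci(junctions, gap_tol=100)
    assert len(loci) == 2


def test_labels_deterministic():
    assert [_letters(i) for i in (0, 1, 25, 26)] == ["a", "b", "z", "aa"]
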