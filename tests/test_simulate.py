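import numpy as np
import pytest

from tdnascope.dna import gc_fraction, revcomp
from tdnascope.junctions import concatemer_length
from tdnascope.presets import (
    FOUR_FRAGMENT_COORDS,
    SIX_FRAGMENT_COORDS,
    designated_junctions,
    replica_loci,
    yl_replica_spec,
)
from tdnascope.simulate import (
    ArchitectureSpec,
    BareTranslocation,
    GenomeSide,
    IntactInsertion,
    JunctionSignatureSpec,
    SpecError,
    TdnaFragmentSpec,
    Translocation,
    VECTOR_SOURCE,
    build_reference,
    build_vector,
    plant_architecture,
)

BLUNT = JunctionSignatureSpec()


def test_build_reference_forced_length():
    ref = build_reference(1, [1000], 0.5, seed=7)
    assert ref.names == ["chr1"]
    assert ref.length("chr1") == 1000


def test_build_reference_deterministic():
    a = build_reference(2, [5000, 5000], 0.4, seed=9)
    b = build_reference(2, [5000, 5000], 0.4, seed=9)
    assert a.chromosomes == b.chromosomes


def test_build_reference_gc_content():
    # derived oracle: count G+C over the output
    ref = build_reference(1, [300_000], 0.36, seed=1)
    assert 0.34 <= gc_fraction(ref.sequence("chr1")) <= 0.38


def test_build_reference_invalid():
    with pytest.raises(ValueError):
        build_reference(1, [0], 0.5, seed=0)
    with pytest.raises(ValueError):
        build_reference(2, [100], 0.5, seed=0)


@pytest.fixture(scope="module")
def tiny_ref():
    return build_reference(2, [20_000, 20_000], 0.5, seed=11)


@pytest.fixture(scope="module")
def vector():
    return build_vector(seed=12)


def test_intact_insertion_additivity(tiny_ref, vector):
    tdna = TdnaFragmentSpec(2454, 10524)
    spec = ArchitectureSpec(
        [IntactInsertion("chr1", 5000, (tdna,), (BLUNT, BLUNT), deletion_len=0)]
    )
    truth = plant_architecture(tiny_ref, vector, spec)
    walk = truth.haplotype_walks(0)[0]
    assert len(walk.sequence) == 20_000 + (10524 - 2454 + 1)
    # intact haplotype untouched
    assert truth.haplotype_walks(1)[0].sequence == truth.reference.sequence("chr1")


def test_translocation_truth_has_one_genome_vector_junction_per_side(tiny_ref, vector):
    spec = ArchitectureSpec(
        [
            Translocation(
                GenomeSide("chr1", 8000, "left"),
                GenomeSide("chr2", 9000, "right"),
                (TdnaFragmentSpec(3000, 4000),),
                (BLUNT, BLUNT),
            )
        ]
    )
    truth = plant_architecture(tiny_ref, vector, spec)
    gv = [j for j in truth.junctions if j.category == "genome-vector"]
    assert len(gv) == 2
    genome_sides = sorted(j.genome_sides[0].source for j in gv)
    assert genome_sides == ["chr1", "chr2"]


def test_filler_planted_verbatim(tiny_ref, vector):
    filler = "TTGACCAAGGTTCCAAGGTTCC"[:22]
    spec = ArchitectureSpec(
        [
            IntactInsertion(
                "chr1", 5000, (TdnaFragmentSpec(2454, 10524),),
                (JunctionSignatureSpec(filler_seq=filler), BLUNT),
            )
        ]
    )
    truth = plant_architecture(tiny_ref, vector, spec)
    walk = truth.haplotype_walks(0)[0]
    left_flank = truth.reference.sequence("chr1")[4970:5000]
    vec_head = truth.vector.sequence[2453 : 2453 + 30]
    assert left_flank + filler + vec_head in walk.sequence


def test_overlapping_events_rejected(tiny_ref, vector):
    frag = (TdnaFragmentSpec(3000, 4000),)
    spec = ArchitectureSpec(
        [
            Translocation(
                GenomeSide("chr1", 8000, "left"), GenomeSide("chr2", 9000, "right"),
                frag, (BLUNT, BLUNT), haplotype=0,
            ),
            Translocation(
                GenomeSide("chr1", 8000, "left"), GenomeSide("chr2", 3000, "right"),
                frag, (BLUNT, BLUNT), haplotype=0,
            ),
        ]
    )
    with pytest.raises(SpecError, match="overlap"):
        plant_architecture(tiny_ref, vector, spec)


def test_fragment_outside_vector_rejected(tiny_ref, vector):
    spec = ArchitectureSpec(
        [
            IntactInsertion(
                "chr1", 5000, (TdnaFragmentSpec(2454, len(vector.sequence) + 10),),
                (BLUNT, BLUNT),
            )
        ]
    )
    with pytest.raises(SpecError):
        plant_architecture(tiny_ref, vector, spec)


def test_homozygous_event_on_both_haplotypes(tiny_ref, vector):
    from tdnascope.simulate import Deletion

    spec = ArchitectureSpec([Deletion("chr1", 4000, 6000, zygosity="homozygous")])
    truth = plant_architecture(tiny_ref, vector, spec)
    for h in (0, 1):
        walk = [w for w in truth.haplotype_walks(h) if w.blocks[0].source == "chr1"][0]
        assert len(walk.sequence) == 18_000
    assert truth.losses == [("chr1", 4000, 6000, "homozygous")]


def test_heterozygous_event_on_one_haplotype(tiny_ref, vector):
    from tdnascope.simulate import Deletion

    spec = ArchitectureSpec([Deletion("chr1", 4000, 6000, haplotype=1)])
    truth = plant_architecture(tiny_ref, vector, spec)
    lens = {
        h: len([w for w in truth.haplotype_walks(h) if w.blocks[0].source == "chr1"][0].sequence)
        for h in (0, 1)
    }
    assert lens == {0: 20_000, 1: 18_000}


# ---------------------------------------------------------------------------
# round-trip invariant: junctions re-derived from emitted sequences
# ---------------------------------------------------------------------------


def _verify_roundtrip(truth):
    for j in truth.junctions:
        sig = j.signature
        m = sig.merge_len
        lf, rf = truth.junction_flanks(j, max(m + 30, 60))
        obs = truth.observed_junction_window(j, max(m, 60) + 120)
        core = lf[-30:] + sig.filler_seq + rf[m : m + 30]
        assert core in obs or core in revcomp(obs), (j.side_a, j.side_b)
        if m:
            assert lf[-m:] == rf[:m]


def test_replica_roundtrip(replica_truth):
    _verify_roundtrip(replica_truth)


def test_random_architecture_roundtrip(tiny_ref, vector):
    spec = ArchitectureSpec(
        [
            Translocation(
                GenomeSide("chr1", 7000, "left"),
                GenomeSide("chr2", 11_000, "right"),
                (TdnaFragmentSpec(9000, 10_000), TdnaFragmentSpec(6000, 5000)),
                (
                    JunctionSignatureSpec(microhomology_len=6),
                    JunctionSignatureSpec(filler_seq="TAGGA"),
                    JunctionSignatureSpec(homology_len=120),
                ),
                haplotype=0,
            ),
            BareTranslocation(
                GenomeSide("chr1", 12_000, "right"),
                GenomeSide("chr2", 2_000, "left"),
                JunctionSignatureSpec(microhomology_len=3),
                haplotype=1,
            ),
        ]
    )
    truth = plant_architecture(tiny_ref, vector, spec)
    _verify_roundtrip(truth)


# ---------------------------------------------------------------------------
# bundled replica architecture
# ---------------------------------------------------------------------------


def test_replica_has_six_insertion_loci(replica_truth):
    gv = [j for j in replica_truth.junctions if j.category == "genome-vector"]
    loci = set()
    for j in gv:
        side = j.genome_sides[0]
        loci.add((side.source, round(side.coord, -3)))
    assert len(loci) == 6


def test_replica_bridge_fragment_lists(replica_truth):
    frag_lists = []
    for walk in replica_truth.walks:
        frags = [
            (b.fragment.start, b.fragment.end)
            for b in walk.blocks
            if b.fragment is not None
        ]
        if frags:
            frag_lists.append(frags)
    assert FOUR_FRAGMENT_COORDS in frag_lists
    assert SIX_FRAGMENT_COORDS in frag_lists


def test_replica_bridge_lengths(replica_truth):
    assert concatemer_length(FOUR_FRAGMENT_COORDS) == 11_279
    assert concatemer_length(SIX_FRAGMENT_COORDS) == 15_200


def test_replica_designated_junctions(replica_truth):
    des = designated_junctions(replica_truth)
    assert len(des["a"][0].signature.filler_seq) == 22
    assert len(des["j"][0].signature.filler_seq) == 3
    assert des["k"][0].signature.homology_len == 254
    assert des["f"][0].signature.homology_len == 254


def test_replica_requires_four_large_chromosomes(vector):
    small = build_reference(4, [100_000] * 4, 0.4, seed=1)
    with pytest.raises(SpecError):
        yl_replica_spec(small, vector)
    few = build_reference(3, [300_000] * 3, 0.4, seed=1)
    with pytest.raises(SpecError):
        yl_replica_spec(few, vector)


def test_replica_loss_structure(replica_truth):
    loci = replica_loci(replica_truth.reference)
    zyg = {(c, s, e): z for c, s, e, z in replica_truth.losses}
    tb, is2 = loci["TB"][1], loci["IS2"][1]
    assert zyg[("chr1", tb, is2)] == "homozygous"
    is5 = loci["IS5"][1]
    assert zyg[("chr3", 0, is5)] == "heterozygous"
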