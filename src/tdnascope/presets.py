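"""Bundled benchmark architecture ("yl-replica"): a transgenic genome in
which tandem vector concatemers caused translocations, a chromosome
truncation, and heterozygous/homozygous losses.

The vector fragment coordinate lists and junction signature values (22-bp
and 3-bp fillers, 254-bp homology, 4-7 bp micro-homologies) are fixed
benchmark constants; chromosomal loci are placed proportionally onto the
synthetic reference.
"""

from __future__ import annotations

from .dna import random_dna
from .simulate import (
    ArchitectureSpec,
    BareTranslocation,
    GenomeSide,
    IntactInsertion,
    JunctionSignatureSpec,
    ReferenceGenome,
    SpecError,
    TdnaFragmentSpec,
    Translocation,
    Truncation,
    TruthJunction,
    TruthSet,
    VectorAnnotation,
)

import numpy as np

#: printed fragment lists of the two concatemer bridges (1-based inclusive,
#: start > end = reverse orientation)
FOUR_FRAGMENT_COORDS: list[tuple[int, int]] = [
    (9144, 10320),
    (7240, 2523),
    (2467, 7239),
    (7919, 7305),
]
SIX_FRAGMENT_COORDS: list[tuple[int, int]] = [
    (9854, 10334),
    (5396, 2476),
    (9014, 10354),
    (10404, 8306),
    (4099, 7239),
    (7919, 2697),
]
#: truncation tract fragments (artifact-chosen; not printed values)
TRUNCATION_FRAGMENT_COORDS: list[tuple[int, int]] = [(2600, 4000), (8200, 7200)]

INTACT_TDNA = (2454, 10524)  # RB start .. LB end

LONG_HOMOLOGY_LEN = 254
FILLER_LONG_LEN = 22
FILLER_SHORT_LEN = 3
MICROHOMOLOGY_LENS = (4, 5, 7)
DEFAULT_INTACT_DELETION = 20  # size of the small deletion at the intact locus

# proportional positions of the planted breakpoints (fraction of chromosome)
_F_IS1, _F_TB, _F_IS2, _F_ISB = 0.46, 0.52, 0.536, 0.62  # chromosome 1
_F_IS3, _F_IS4 = 0.104, 0.354  # chromosome 2
_F_IS5 = 0.334  # chromosome 3
_F_IS6 = 0.184  # chromosome 4

_FILLER_SEED = 20190423


def _fillers() -> tuple[str, str]:
    rng = np.random.default_rng(_FILLER_SEED)
    return random_dna(FILLER_LONG_LEN, rng), random_dna(FILLER_SHORT_LEN, rng)


def yl_replica_spec(
    ref: ReferenceGenome,
    vector: VectorAnnotation,
    intact_deletion_len: int = DEFAULT_INTACT_DELETION,
) -> ArchitectureSpec:
    """Scaled replica architecture on the first four chromosomes of ``ref``.

    Plants: one truncation (two-fragment tract, 254-bp homology at both of
    its junctions), one six-fragment and one four-fragment concatemer bridge
    between different chromosomes (22-bp and 3-bp fillers at the designated
    junctions), one bare chromosome-chromosome translocation, one intact
    border-to-border insertion with a small deletion, one heterozygous
    terminal loss and one homozygous interior deletion.
    """
    if len(ref.chromosomes) < 4:
        raise SpecError("replica needs at least 4 chromosomes")
    for name, seq in ref.chromosomes[:4]:
        if len(seq) < 200_000:
            raise SpecError(f"replica chromosome {name} shorter than 200 kb")

    c1, c2, c3, c4 = ref.names[:4]
    L1, L2, L3, L4 = (ref.length(c) for c in (c1, c2, c3, c4))
    is1, tb, is2, isb = (int(f * L1) for f in (_F_IS1, _F_TB, _F_IS2, _F_ISB))
    is3, is4 = int(_F_IS3 * L2), int(_F_IS4 * L2)
    is5 = int(_F_IS5 * L3)
    is6 = int(_F_IS6 * L4)

    hom = JunctionSignatureSpec(homology_len=LONG_HOMOLOGY_LEN)
    blunt = JunctionSignatureSpec()
    filler_long, filler_short = _fillers()
    mh4, mh5, mh7 = (JunctionSignatureSpec(microhomology_len=m) for m in MICROHOMOLOGY_LENS)

    frag = TdnaFragmentSpec
    events = [
        # one-ended capture: chromosome 1 truncated at IS1, tract dangles
        Truncation(
            side=GenomeSide(c1, is1, "left"),
            fragments=tuple(frag(*c) for c in TRUNCATION_FRAGMENT_COORDS),
            signatures=(hom, hom),
            lost=((c1, is1, L1),),
            haplotype=0,
        ),
        # six-fragment bridge joining chromosome 2 to chromosome 3; the
        # fragment left behind on chromosome 3 is the heterozygous terminal loss
        Translocation(
            side_a=GenomeSide(c2, is4, "left"),
            side_b=GenomeSide(c3, is5, "right"),
            fragments=tuple(frag(*c) for c in SIX_FRAGMENT_COORDS),
            signatures=(
                JunctionSignatureSpec(filler_seq=filler_long),
                blunt, blunt, blunt, blunt, blunt, blunt,
            ),
            lost=((c3, 0, is5),),
            haplotype=0,
        ),
        # intact border-to-border insertion with a small deletion at the locus
        IntactInsertion(
            chrom=c4,
            pos=is6,
            fragments=(frag(*INTACT_TDNA),),
            signatures=(mh5, mh7),
            deletion_len=intact_deletion_len,
            haplotype=0,
        ),
        # bare translocation; the skipped interval is the homozygous deletion
        # (the other haplotype lacks it via the IS1 truncation)
        BareTranslocation(
            side_a=GenomeSide(c1, tb, "left"),
            side_b=GenomeSide(c2, is3, "left"),
            signature=mh4,
            lost=((c1, tb, is2),),
            haplotype=1,
        ),
        # four-fragment bridge joining chromosome 1 to chromosome 2
        Translocation(
            side_a=GenomeSide(c1, isb, "left"),
            side_b=GenomeSide(c2, is3, "right"),
            fragments=tuple(frag(*c) for c in FOUR_FRAGMENT_COORDS),
            signatures=(
                blunt, blunt,
                JunctionSignatureSpec(filler_seq=filler_short),
                blunt, blunt,
            ),
            haplotype=1,
        ),
    ]
    return ArchitectureSpec(events)


def replica_loci(ref: ReferenceGenome) -> dict[str, tuple[str, int]]:
    """Planted breakpoint loci of the replica, keyed by short name."""
    c1, c2, c3, c4 = ref.names[:4]
    L1, L2, L3, L4 = (ref.length(c) for c in (c1, c2, c3, c4))
    return {
        "IS1": (c1, int(_F_IS1 * L1)),
        "TB": (c1, int(_F_TB * L1)),
        "IS2": (c1, int(_F_IS2 * L1)),
        "ISB": (c1, int(_F_ISB * L1)),
        "IS3": (c2, int(_F_IS3 * L2)),
        "IS4": (c2, int(_F_IS4 * L2)),
        "IS5": (c3, int(_F_IS5 * L3)),
        "IS6": (c4, int(_F_IS6 * L4)),
    }


def designated_junctions(truth: TruthSet) -> dict[str, list[TruthJunction]]:
    """Map the designated junction labels to planted truth junctions.

    ``a``: the long (22-bp) filler junction; ``j``: the short (3-bp) filler;
    ``k``/``f``: the two long-homology junctions (genome-vector first).
    """
    out: dict[str, list[TruthJunction]] = {"a": [], "j": [], "k": [], "f": []}
    homologies = []
    for j in truth.junctions:
        sig = j.signature
        if len(sig.filler_seq) == FILLER_LONG_LEN:
            out["a"].append(j)
        elif len(sig.filler_seq) == FILLER_SHORT_LEN:
            out["j"].append(j)
        elif sig.homology_len == LONG_HOMOLOGY_LEN:
            homologies.append(j)
    homologies.sort(key=lambda j: j.category != "genome-vector")
    if homologies:
        out["k"] = homologies[:1]
        out["f"] = homologies[1:2]
    return out
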