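"""Synthetic rearranged diploid genomes with planted transgene architectures.

A planted architecture is a list of events (insertions, truncations,
vector-bridged and bare translocations, deletions). Compilation cuts the
reference chromosomes into pieces, wires the pieces together through the
event "bridges" (optionally threading vector fragments between them), and
realizes every junction according to its repair-signature spec:

* micro-homology / long homology: the two sides share ``m`` identical bases
  written once at the join (the reference copy is patched where needed so
  the identity genuinely exists);
* filler: extra bases inserted verbatim between the sides;
* blunt: plain concatenation.

The emitted :class:`TruthSet` is the round-trip oracle for the whole
analysis stack: junction table with exact coordinates, per-haplotype walks,
and lost intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .dna import random_dna, revcomp

VECTOR_SOURCE = "vector"

Direction = Literal["left", "right"]
Zygosity = Literal["heterozygous", "homozygous"]


class SpecError(ValueError):
    """Invalid architecture specification."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT characters")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    def length(self, name: str) -> int:
        return len(self.sequence(name))

    def as_dict(self) -> dict[str, str]:
        return dict(self.chromosomes)


@dataclass
class VectorAnnotation:
    """Circular vector sequence with annotated transfer-DNA borders (1-based)."""

    sequence: str
    lb_interval: tuple[int, int]
    rb_interval: tuple[int, int]
    tdna_span: tuple[int, int]
    canonical_tdna_length_range: tuple[int, int] = (8031, 8080)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for lo, hi in (self.lb_interval, self.rb_interval, self.tdna_span):
            if not (1 <= lo <= hi <= n):
                raise ValueError("vector interval out of bounds")

    def segment(self, start: int, end: int) -> str:
        """Vector subsequence for a 1-based inclusive fragment (start>end = reverse)."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return revcomp(self.sequence[end - 1 : start])


@dataclass(frozen=True)
class TdnaFragmentSpec:
    """Vector fragment in 1-based inclusive coordinates; start > end = reverse."""

    start: int
    end: int

    @property
    def forward(self) -> bool:
        return self.start <= self.end

    @property
    def length(self) -> int:
        """Fragment length under the reporting convention |end - start|."""
        return abs(self.end - self.start)

    @property
    def interval0(self) -> tuple[int, int]:
        """Occupied vector interval, 0-based half-open forward coordinates."""
        lo, hi = sorted((self.start, self.end))
        return lo - 1, hi

    def validate(self, vector: VectorAnnotation) -> None:
        lo, hi = self.interval0
        if lo < 0 or hi > len(vector.sequence):
            raise SpecError(f"fragment {self} outside vector")

    def entry_side(self) -> tuple[str, int, Direction]:
        """Junction side where a walk enters this fragment."""
        if self.forward:
            return (VECTOR_SOURCE, self.start - 1, "right")
        return (VECTOR_SOURCE, self.start, "left")

    def exit_side(self) -> tuple[str, int, Direction]:
        """Junction side where a walk leaves this fragment."""
        if self.forward:
            return (VECTOR_SOURCE, self.end, "left")
        return (VECTOR_SOURCE, self.end - 1, "right")


@dataclass(frozen=True)
class JunctionSignatureSpec:
    """Repair signature planted at one junction.

    ``merge_len`` bases shared by both sides are written once (micro-homology
    when small, long homology when large); filler is inserted verbatim. The
    two are mutually exclusive.
    """

    microhomology_len: int = 0
    filler_seq: str = ""
    homology_len: int = 0

    def __post_init__(self) -> None:
        if self.microhomology_len < 0 or self.homology_len < 0:
            raise SpecError("negative signature length")
        active = sum(
            (self.microhomology_len > 0, bool(self.filler_seq), self.homology_len > 0)
        )
        if active > 1:
            raise SpecError("micro-homology, filler and long homology are mutually exclusive")

    @property
    def merge_len(self) -> int:
        return self.microhomology_len or self.homology_len

    @property
    def kind(self) -> str:
        if self.filler_seq:
            return "filler"
        if self.homology_len:
            return "long_homology"
        if self.microhomology_len:
            return "microhomology"
        return "blunt"


BLUNT = JunctionSignatureSpec()


@dataclass(frozen=True)
class GenomeSide:
    """One chromosomal end of an event: breakpoint ``pos`` (0-based), keeping
    the sequence on ``keep`` side of it."""

    chrom: str
    pos: int
    keep: Direction


@dataclass(frozen=True)
class IntactInsertion:
    chrom: str
    pos: int
    fragments: tuple[TdnaFragmentSpec, ...]
    signatures: tuple[JunctionSignatureSpec, ...]
    deletion_len: int = 0
    zygosity: Zygosity = "heterozygous"
    haplotype: int = 0


@dataclass(frozen=True)
class Truncation:
    side: GenomeSide
    fragments: tuple[TdnaFragmentSpec, ...]
    signatures: tuple[JunctionSignatureSpec, ...]
    lost: tuple[tuple[str, int, int], ...] = ()
    zygosity: Zygosity = "heterozygous"
    haplotype: int = 0


@dataclass(frozen=True)
class Translocation:
    side_a: GenomeSide
    side_b: GenomeSide
    fragments: tuple[TdnaFragmentSpec, ...]
    signatures: tuple[JunctionSignatureSpec, ...]
    lost: tuple[tuple[str, int, int], ...] = ()
    zygosity: Zygosity = "heterozygous"
    haplotype: int = 0


@dataclass(frozen=True)
class BareTranslocation:
    side_a: GenomeSide
    side_b: GenomeSide
    signature: JunctionSignatureSpec = BLUNT
    lost: tuple[tuple[str, int, int], ...] = ()
    zygosity: Zygosity = "heterozygous"
    haplotype: int = 0


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int
    signature: JunctionSignatureSpec = BLUNT
    zygosity: Zygosity = "heterozygous"
    haplotype: int = 0


Event = IntactInsertion | Truncation | Translocation | BareTranslocation | Deletion


@dataclass
class ArchitectureSpec:
    events: list[Event]

    def events_for(self, haplotype: int) -> list[Event]:
        return [
            e
            for e in self.events
            if e.zygosity == "homozygous" or e.haplotype == haplotype
        ]


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionSide:
    source: str  # chromosome name or "vector"
    coord: int  # 0-based breakpoint offset
    direction: Direction  # side of coord on which the retained sequence lies

    def key(self) -> tuple:
        return (self.source == VECTOR_SOURCE, self.source, self.coord, self.direction)


@dataclass
class TruthJunction:
    side_a: JunctionSide
    side_b: JunctionSide
    signature: JunctionSignatureSpec
    zygosity: Zygosity
    haplotypes: set[int] = field(default_factory=set)
    # (walk name, offset of the first base right of the junction point)
    walk_positions: list[tuple[str, int]] = field(default_factory=list)

    def canonical(self) -> "TruthJunction":
        """Sides in canonical order; filler re-oriented to match (a filler
        reads reverse-complemented when the junction is traversed b->a)."""
        if self.side_a.key() > self.side_b.key():
            sig = self.signature
            if sig.filler_seq:
                sig = JunctionSignatureSpec(filler_seq=revcomp(sig.filler_seq))
            return TruthJunction(
                self.side_b, self.side_a, sig, self.zygosity,
                self.haplotypes, self.walk_positions,
            )
        return self

    @property
    def category(self) -> str:
        av = self.side_a.source == VECTOR_SOURCE
        bv = self.side_b.source == VECTOR_SOURCE
        if av and bv:
            return "vector-vector"
        if av or bv:
            return "genome-vector"
        return "genome-genome"

    @property
    def genome_sides(self) -> list[JunctionSide]:
        return [s for s in (self.side_a, self.side_b) if s.source != VECTOR_SOURCE]


@dataclass
class WalkBlock:
    source: str
    start: int  # source coords, 0-based half-open (fragment interval for vector)
    end: int
    flipped: bool
    walk_start: int  # emitted interval within the walk sequence
    walk_end: int
    fragment: TdnaFragmentSpec | None = None


@dataclass
class Walk:
    name: str
    haplotype: int
    blocks: list[WalkBlock]
    sequence: str


@dataclass
class TruthSet:
    reference: ReferenceGenome  # patched reference used for realization
    vector: VectorAnnotation  # patched vector
    walks: list[Walk]
    junctions: list[TruthJunction]
    losses: list[tuple[str, int, int, Zygosity]]

    def to_json(self) -> str:
        def side(s: JunctionSide) -> dict:
            return {"source": s.source, "coord": s.coord, "direction": s.direction}

        payload = {
            "junctions": [
                {
                    "side_a": side(j.side_a),
                    "side_b": side(j.side_b),
                    "signature": {
                        "kind": j.signature.kind,
                        "microhomology_len": j.signature.microhomology_len,
                        "filler_seq": j.signature.filler_seq,
                        "homology_len": j.signature.homology_len,
                    },
                    "zygosity": j.zygosity,
                    "haplotypes": sorted(j.haplotypes),
                    "walk_positions": j.walk_positions,
                }
                for j in self.junctions
            ],
            "losses": [list(l) for l in self.losses],
            "walks": [
                {
                    "name": w.name,
                    "haplotype": w.haplotype,
                    "blocks": [
                        {
                            "source": b.source,
                            "start": b.start,
                            "end": b.end,
                            "flipped": b.flipped,
                            "walk_start": b.walk_start,
                            "walk_end": b.walk_end,
                            "fragment": [b.fragment.start, b.fragment.end]
                            if b.fragment
                            else None,
                        }
                        for b in w.blocks
                    ],
                }
                for w in self.walks
            ],
        }
        import json

        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        """Rebuild a (sequence-free) truth set from its JSON form."""
        import json

        payload = json.loads(text)
        junctions = []
        for j in payload["junctions"]:
            sig = j["signature"]
            junctions.append(
                TruthJunction(
                    JunctionSide(**j["side_a"]),
                    JunctionSide(**j["side_b"]),
                    JunctionSignatureSpec(
                        microhomology_len=sig["microhomology_len"],
                        filler_seq=sig["filler_seq"],
                        homology_len=sig["homology_len"],
                    ),
                    j["zygosity"],
                    set(j["haplotypes"]),
                    [tuple(x) for x in j["walk_positions"]],
                )
            )
        walks = [
            Walk(
                w["name"],
                w["haplotype"],
                [
                    WalkBlock(
                        b["source"], b["start"], b["end"], b["flipped"],
                        b["walk_start"], b["walk_end"],
                        TdnaFragmentSpec(*b["fragment"]) if b["fragment"] else None,
                    )
                    for b in w["blocks"]
                ],
                "",
            )
            for w in payload["walks"]
        ]
        losses = [tuple(l) for l in payload["losses"]]
        return cls(None, None, walks, junctions, losses)  # type: ignore[arg-type]

    def haplotype_walks(self, haplotype: int) -> list[Walk]:
        return [w for w in self.walks if w.haplotype == haplotype]

    def junction_flanks(
        self, junction: TruthJunction, length: int
    ) -> tuple[str, str]:
        """Planted flank sequences meeting at a junction, junction-oriented.

        The left flank ends at the junction point; the right flank starts at
        it. Merged homology bases appear in both flanks (written once in the
        realized sequence); filler appears in neither.
        """
        return (
            _side_flank(self.reference, self.vector, junction.side_a, length, "left"),
            _side_flank(self.reference, self.vector, junction.side_b, length, "right"),
        )

    def observed_junction_window(
        self, junction: TruthJunction, radius: int
    ) -> str | None:
        """Realized sequence around the junction, from the first carrier walk."""
        if not junction.walk_positions:
            return None
        wname, off = junction.walk_positions[0]
        walk = next(w for w in self.walks if w.name == wname)
        return walk.sequence[max(0, off - radius) : off + radius]


def _side_flank(
    ref: ReferenceGenome,
    vector: VectorAnnotation,
    side: JunctionSide,
    length: int,
    role: Direction,
) -> str:
    """Sequence on the retained side of a junction, oriented so that the
    junction sits at the right end (role=left) or left end (role=right)."""
    seq = vector.sequence if side.source == VECTOR_SOURCE else ref.sequence(side.source)
    if side.direction == "left":
        chunk = seq[max(0, side.coord - length) : side.coord]
        oriented = chunk  # retained part read toward the junction
        return oriented if role == "left" else revcomp(oriented)
    chunk = seq[side.coord : side.coord + length]
    return chunk if role == "right" else revcomp(chunk)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_reference(
    n_chromosomes: int,
    lengths: Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
) -> ReferenceGenome:
    """Random multi-chromosome reference with the requested GC content."""
    if n_chromosomes <= 0 or len(lengths) != n_chromosomes:
        raise ValueError("need one positive length per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms = [
        (f"chr{i + 1}", random_dna(length, rng, gc))
        for i, length in enumerate(lengths)
    ]
    return ReferenceGenome(chroms)


def build_vector(length: int = 11600, seed: int = 0) -> VectorAnnotation:
    """Random binary-vector stand-in with fixed border annotation."""
    if length < 10524:
        raise ValueError("vector must be at least 10524 bp to hold the borders")
    rng = np.random.default_rng(seed)
    return VectorAnnotation(
        sequence=random_dna(length, rng),
        lb_interval=(10509, 10524),
        rb_interval=(2454, 2478),
        tdna_span=(2454, 10524),
    )


# -- architecture compilation ------------------------------------------------


@dataclass
class _Piece:
    chrom: str
    start: int
    end: int
    # bridge attachment slots, one per end
    left_bridge: int | None = None
    right_bridge: int | None = None


@dataclass
class _Bridge:
    """A join created by one event: endpoint -> fragments -> endpoint."""

    end_a: GenomeSide | None
    end_b: GenomeSide | None
    fragments: tuple[TdnaFragmentSpec, ...]
    signatures: tuple[JunctionSignatureSpec, ...]


def _event_bridges_and_cuts(
    event: Event, ref: ReferenceGenome
) -> tuple[list[_Bridge], list[tuple[str, int]], list[tuple[str, int, int]]]:
    """Bridges, cut positions and lost intervals contributed by one event."""
    cuts: list[tuple[str, int]] = []
    lost: list[tuple[str, int, int]] = list(getattr(event, "lost", ()) or ())
    if isinstance(event, IntactInsertion):
        if len(event.signatures) != len(event.fragments) + 1:
            raise SpecError("insertion needs len(fragments)+1 signatures")
        p2 = event.pos + event.deletion_len
        cuts += [(event.chrom, event.pos), (event.chrom, p2)]
        if event.deletion_len:
            lost.append((event.chrom, event.pos, p2))
        bridge = _Bridge(
            GenomeSide(event.chrom, event.pos, "left"),
            GenomeSide(event.chrom, p2, "right"),
            event.fragments,
            event.signatures,
        )
        return [bridge], cuts, lost
    if isinstance(event, Truncation):
        if len(event.signatures) != len(event.fragments):
            raise SpecError("truncation needs one signature per fragment")
        if not event.fragments:
            raise SpecError("truncation needs at least one fragment")
        cuts.append((event.side.chrom, event.side.pos))
        return (
            [_Bridge(event.side, None, event.fragments, event.signatures)],
            cuts,
            lost,
        )
    if isinstance(event, Translocation):
        if len(event.signatures) != len(event.fragments) + 1:
            raise SpecError("translocation needs len(fragments)+1 signatures")
        cuts += [(event.side_a.chrom, event.side_a.pos), (event.side_b.chrom, event.side_b.pos)]
        return (
            [_Bridge(event.side_a, event.side_b, event.fragments, event.signatures)],
            cuts,
            lost,
        )
    if isinstance(event, BareTranslocation):
        cuts += [(event.side_a.chrom, event.side_a.pos), (event.side_b.chrom, event.side_b.pos)]
        return (
            [_Bridge(event.side_a, event.side_b, (), (event.signature,))],
            cuts,
            lost,
        )
    if isinstance(event, Deletion):
        if not (0 <= event.start < event.end <= ref.length(event.chrom)):
            raise SpecError("deletion interval out of bounds")
        cuts += [(event.chrom, event.start), (event.chrom, event.end)]
        lost.append((event.chrom, event.start, event.end))
        return (
            [
                _Bridge(
                    GenomeSide(event.chrom, event.start, "left"),
                    GenomeSide(event.chrom, event.end, "right"),
                    (),
                    (event.signature,),
                )
            ],
            cuts,
            lost,
        )
    raise SpecError(f"unknown event type {type(event).__name__}")


def _validate_spec(ref: ReferenceGenome, vector: VectorAnnotation, spec: ArchitectureSpec) -> None:
    for event in spec.events:
        for frag in getattr(event, "fragments", ()) or ():
            frag.validate(vector)
        if isinstance(event, IntactInsertion):
            if not (0 <= event.pos <= ref.length(event.chrom)):
                raise SpecError("insertion locus outside chromosome")
        for side_attr in ("side", "side_a", "side_b"):
            side = getattr(event, side_attr, None)
            if side is not None and not (0 <= side.pos <= ref.length(side.chrom)):
                raise SpecError(f"breakpoint {side} outside chromosome")
        if event.zygosity == "heterozygous" and event.haplotype not in (0, 1):
            raise SpecError("haplotype must be 0 or 1")


class _Patcher:
    """Mutable copies of reference/vector sequences, patched so that planted
    merge signatures (micro-homology, long homology) genuinely exist."""

    def __init__(self, ref: ReferenceGenome, vector: VectorAnnotation):
        self.chrom_seqs = {n: list(s) for n, s in ref.chromosomes}
        self.vector_seq = list(vector.sequence)
        self.names = ref.names

    def get(self, source: str) -> list[str]:
        return self.vector_seq if source == VECTOR_SOURCE else self.chrom_seqs[source]

    def patched_reference(self) -> ReferenceGenome:
        return ReferenceGenome([(n, "".join(self.chrom_seqs[n])) for n in self.names])

    def patched_vector(self, vector: VectorAnnotation) -> VectorAnnotation:
        return VectorAnnotation(
            "".join(self.vector_seq),
            vector.lb_interval,
            vector.rb_interval,
            vector.tdna_span,
            vector.canonical_tdna_length_range,
        )

    def side_tail(self, side: JunctionSide, m: int) -> str:
        """The ``m`` bases of the retained sequence adjacent to the junction,
        in junction orientation (approaching the junction)."""
        seq = self.get(side.source)
        if side.direction == "left":
            return "".join(seq[side.coord - m : side.coord])
        return revcomp("".join(seq[side.coord : side.coord + m]))

    def side_head(self, side: JunctionSide, m: int) -> str:
        """The ``m`` retained bases leaving the junction, junction-oriented."""
        seq = self.get(side.source)
        if side.direction == "right":
            return "".join(seq[side.coord : side.coord + m])
        return revcomp("".join(seq[side.coord - m : side.coord]))

    def write_tail(self, side: JunctionSide, value: str) -> None:
        seq = self.get(side.source)
        m = len(value)
        if side.direction == "left":
            seq[side.coord - m : side.coord] = list(value)
        else:
            seq[side.coord : side.coord + m] = list(revcomp(value))

    def write_head(self, side: JunctionSide, value: str) -> None:
        seq = self.get(side.source)
        m = len(value)
        if side.direction == "right":
            seq[side.coord : side.coord + m] = list(value)
        else:
            seq[side.coord - m : side.coord] = list(revcomp(value))


def _apply_merge_patch(patcher: _Patcher, junction: TruthJunction) -> None:
    m = junction.signature.merge_len
    if m == 0:
        return
    a, b = junction.side_a, junction.side_b
    if patcher.side_tail(a, m) == patcher.side_head(b, m):
        return
    # prefer patching a genome side so vector content stays pristine
    if a.source != VECTOR_SOURCE:
        patcher.write_tail(a, patcher.side_head(b, m))
    elif b.source != VECTOR_SOURCE:
        patcher.write_head(b, patcher.side_tail(a, m))
    else:
        patcher.write_head(b, patcher.side_tail(a, m))
    if patcher.side_tail(a, m) != patcher.side_head(b, m):  # self-overlap degeneracy
        raise SpecError(f"cannot realize merge signature of {m} bp at {a}~{b}")


_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _decollide(patcher: _Patcher, junctions: list[TruthJunction], max_rounds: int = 12) -> None:
    """Remove chance micro-matches at junction boundaries.

    A junction planted with merge length ``m`` (0 for blunt/filler) must not
    exhibit a longer apparent overlap by accident: the base continuing side A
    past its breakpoint must differ from the first emitted base after the
    junction, and the base preceding side B's block must differ from the last
    read base that side B's alignment could chain through. Offending bases —
    always *outside* the joined blocks — are rewritten. Iterated to a fixed
    point because a patched base can sit next to another junction.
    """

    def continuation_pos(side: JunctionSide) -> tuple[str, int, bool] | None:
        """(source, position, complemented) of the base just past the retained
        block, in junction orientation; None when out of bounds."""
        seq = patcher.get(side.source)
        if side.direction == "left":
            if side.coord >= len(seq):
                return None
            return side.source, side.coord, False
        if side.coord - 1 < 0:
            return None
        return side.source, side.coord - 1, True

    def precursor_pos(side: JunctionSide) -> tuple[str, int, bool] | None:
        """Base just before side B's block in junction orientation."""
        seq = patcher.get(side.source)
        if side.direction == "right":
            if side.coord - 1 < 0:
                return None
            return side.source, side.coord - 1, False
        if side.coord >= len(seq):
            return None
        return side.source, side.coord, True

    for _ in range(max_rounds):
        dirty = False
        forbidden: dict[tuple[str, int], set[str]] = {}
        for j in junctions:
            sig = j.signature
            m = sig.merge_len
            head = patcher.side_head(j.side_b, m + 1)
            tail = patcher.side_tail(j.side_a, m + 1)
            if len(head) < m + 1 or len(tail) < m + 1:
                continue
            x1 = sig.filler_seq[0] if sig.filler_seq else head[m]
            x2 = sig.filler_seq[-1] if sig.filler_seq else tail[0]
            for pos, x in ((continuation_pos(j.side_a), x1), (precursor_pos(j.side_b), x2)):
                if pos is None:
                    continue
                src, i, comp = pos
                forbidden.setdefault((src, i), set()).add(_COMP1[x] if comp else x)
        for (src, i), banned in sorted(forbidden.items()):
            seq = patcher.get(src)
            if seq[i] in banned:
                if len(banned) >= 4:
                    raise SpecError("over-constrained junction boundary base")
                seq[i] = next(b for b in "ACGT" if b not in banned)
                dirty = True
        # merge patches may have been disturbed by boundary rewrites
        for j in junctions:
            if j.signature.merge_len:
                before = patcher.side_tail(j.side_a, j.signature.merge_len)
                _apply_merge_patch(patcher, j)
                if patcher.side_tail(j.side_a, j.signature.merge_len) != before:
                    dirty = True
        if not dirty:
            return
    raise SpecError("junction boundary decollision did not converge")


def plant_architecture(
    ref: ReferenceGenome,
    vector: VectorAnnotation,
    spec: ArchitectureSpec,
) -> TruthSet:
    """Compile an architecture spec into a realized mutant diploid + truth set."""
    _validate_spec(ref, vector, spec)

    # collect junctions first so sequence patches exist before realization
    patcher = _Patcher(ref, vector)
    hap_plans: list[list[tuple[_Bridge, list[TruthJunction]]]] = []
    hap_cuts: list[dict[str, list[int]]] = []
    hap_lost: list[list[tuple[str, int, int]]] = []
    for h in (0, 1):
        bridges: list[tuple[_Bridge, list[TruthJunction]]] = []
        cuts: dict[str, list[int]] = {n: [] for n in ref.names}
        lost: list[tuple[str, int, int]] = []
        for event in spec.events_for(h):
            ev_bridges, ev_cuts, ev_lost = _event_bridges_and_cuts(event, ref)
            for chrom, pos in ev_cuts:
                cuts[chrom].append(pos)
            lost.extend(ev_lost)
            for bridge in ev_bridges:
                bridges.append((bridge, _bridge_junctions(bridge, event.zygosity, h)))
        hap_plans.append(bridges)
        hap_cuts.append({c: sorted(set(p)) for c, p in cuts.items()})
        hap_lost.append(lost)

    # dedupe junctions across haplotypes (homozygous events appear twice)
    junction_registry: dict[tuple, TruthJunction] = {}
    for bridges in hap_plans:
        for _, junctions in bridges:
            for j in junctions:
                key = (j.side_a, j.side_b, j.signature)
                if key in junction_registry:
                    junction_registry[key].haplotypes |= j.haplotypes
                else:
                    junction_registry[key] = j

    for j in junction_registry.values():
        _apply_merge_patch(patcher, j)
    _decollide(patcher, list(junction_registry.values()))

    patched_ref = patcher.patched_reference()
    patched_vec = patcher.patched_vector(vector)

    walks: list[Walk] = []
    for h in (0, 1):
        walks.extend(
            _assemble_haplotype(
                h,
                patched_ref,
                patched_vec,
                hap_plans[h],
                hap_cuts[h],
                hap_lost[h],
                junction_registry,
            )
        )

    losses = _derive_losses(patched_ref, walks)
    return TruthSet(
        reference=patched_ref,
        vector=patched_vec,
        walks=walks,
        junctions=[j for j in junction_registry.values()],
        losses=losses,
    )


def _bridge_junctions(
    bridge: _Bridge, zygosity: Zygosity, haplotype: int
) -> list[TruthJunction]:
    sides: list[JunctionSide] = []
    if bridge.end_a is not None:
        sides.append(_genome_side_junction(bridge.end_a))
    for frag in bridge.fragments:
        sides.append(JunctionSide(*frag.entry_side()))
        sides.append(JunctionSide(*frag.exit_side()))
    if bridge.end_b is not None:
        sides.append(_genome_side_junction(bridge.end_b))
    elif bridge.fragments:
        sides.pop()  # truncation: last fragment end dangles, no junction
    if len(sides) % 2 != 0:
        raise SpecError("internal: unbalanced junction sides")
    out = []
    # sides alternate [exit0, entry1, exit1, entry2, ...]; junction i joins
    # sides[2i] and sides[2i+1]
    for i, (sa, sb) in enumerate(zip(sides[0::2], sides[1::2])):
        out.append(
            TruthJunction(
                side_a=sa,
                side_b=sb,
                signature=bridge.signatures[i],
                zygosity=zygosity,
                haplotypes={haplotype},
            ).canonical()
        )
    return out


def _genome_side_junction(side: GenomeSide) -> JunctionSide:
    return JunctionSide(side.chrom, side.pos, side.keep)


def _assemble_haplotype(
    haplotype: int,
    ref: ReferenceGenome,
    vector: VectorAnnotation,
    bridges: list[tuple[_Bridge, list[TruthJunction]]],
    cuts: dict[str, list[int]],
    lost: list[tuple[str, int, int]],
    junction_registry: dict[tuple, TruthJunction],
) -> list[Walk]:
    # build pieces
    pieces: list[_Piece] = []
    piece_by_end: dict[tuple[str, int, Direction], int] = {}
    for chrom in ref.names:
        length = ref.length(chrom)
        positions = [0] + [p for p in cuts.get(chrom, []) if 0 < p < length] + [length]
        for a, b in zip(positions[:-1], positions[1:]):
            idx = len(pieces)
            pieces.append(_Piece(chrom, a, b))
            piece_by_end[(chrom, b, "left")] = idx  # piece ending at b
            piece_by_end[(chrom, a, "right")] = idx  # piece starting at a

    # attach bridges
    attach: dict[tuple[int, str], tuple[int, str]] = {}  # (piece, end) -> (bridge, which)
    for bi, (bridge, _junctions) in enumerate(bridges):
        for which, side in (("a", bridge.end_a), ("b", bridge.end_b)):
            if side is None:
                continue
            key = (side.chrom, side.pos, side.keep)
            if key not in piece_by_end:
                raise SpecError(f"no piece matches breakpoint {side}")
            pi = piece_by_end[key]
            end = "R" if side.keep == "left" else "L"
            if (pi, end) in attach:
                raise SpecError(f"overlapping events at {side}")
            attach[(pi, end)] = (bi, which)

    bridge_other: dict[tuple[int, str], tuple[int, str] | None] = {}
    for bi, (bridge, _j) in enumerate(bridges):
        ends = []
        for which, side in (("a", bridge.end_a), ("b", bridge.end_b)):
            if side is not None:
                key = (side.chrom, side.pos, side.keep)
                pi = piece_by_end[key]
                end = "R" if side.keep == "left" else "L"
                ends.append((which, (pi, end)))
        if len(ends) == 2:
            bridge_other[(bi, ends[0][0])] = ends[1][1]
            bridge_other[(bi, ends[1][0])] = ends[0][1]
        elif len(ends) == 1:
            bridge_other[(bi, ends[0][0])] = None

    lost_sorted = sorted(lost)

    def trimmed(piece: _Piece) -> tuple[int, int] | None:
        a, b = piece.start, piece.end
        for chrom, lo, hi in lost_sorted:
            if chrom != piece.chrom:
                continue
            if lo <= a and b <= hi:
                return None
            if lo <= a < hi:
                a = hi
            if lo < b <= hi:
                b = lo
            if a < hi and lo < b and a < lo and hi < b:
                raise SpecError(
                    f"lost interval ({chrom},{lo},{hi}) interior to piece "
                    f"({piece.chrom},{piece.start},{piece.end}); use a Deletion event"
                )
        return (a, b) if a < b else None

    visited: set[int] = set()
    walks: list[Walk] = []

    def walk_from(start_piece: int, flipped: bool) -> None:
        name = f"hap{haplotype}_w{len(walks):02d}"
        blocks: list[WalkBlock] = []
        seq_parts: list[str] = []
        pos = 0
        pending_merge = 0  # bases of the next block to skip (merged homology)
        pending_filler = ""

        def emit(source: str, s: int, e: int, flip: bool, raw: str, frag=None) -> None:
            nonlocal pos, pending_merge, pending_filler
            if pending_filler:
                seq_parts.append(pending_filler)
                pos += len(pending_filler)
                pending_filler = ""
            if pending_merge:
                raw = raw[pending_merge:]
                pending_merge = 0
            blocks.append(WalkBlock(source, s, e, flip, pos, pos + len(raw), frag))
            seq_parts.append(raw)
            pos += len(raw)

        def register_junction(j_sides: tuple[JunctionSide, JunctionSide], sig) -> None:
            nonlocal pending_merge, pending_filler
            # locate the truth junction to record walk position
            cand = TruthJunction(j_sides[0], j_sides[1], sig, "heterozygous").canonical()
            key = (cand.side_a, cand.side_b, cand.signature)
            junction_registry[key].walk_positions.append((name, pos))
            if sig.merge_len:
                pending_merge = sig.merge_len
            elif sig.filler_seq:
                pending_filler = sig.filler_seq

        pi: int | None = start_piece
        flip = flipped
        while pi is not None and pi not in visited:
            visited.add(pi)
            piece = pieces[pi]
            tr = trimmed(piece)
            if tr is not None:
                raw = ref.sequence(piece.chrom)[tr[0] : tr[1]]
                if flip:
                    raw = revcomp(raw)
                emit(piece.chrom, tr[0], tr[1], flip, raw)
            out_end = "L" if flip else "R"
            hook = attach.get((pi, out_end))
            if hook is None:
                break
            bi, which = hook
            bridge, junctions = bridges[bi]
            frags = bridge.fragments
            sigs = bridge.signatures
            if which == "b":  # traversing the bridge backwards
                frags = tuple(TdnaFragmentSpec(f.end, f.start) for f in reversed(frags))
                sigs = tuple(
                    JunctionSignatureSpec(filler_seq=revcomp(s.filler_seq))
                    if s.filler_seq
                    else s
                    for s in reversed(sigs)
                )
            # junction sides along traversal
            prev_side = JunctionSide(
                piece.chrom,
                piece.end if out_end == "R" else piece.start,
                "left" if out_end == "R" else "right",
            )
            for k, frag in enumerate(frags):
                entry = JunctionSide(*frag.entry_side())
                register_junction((prev_side, entry), sigs[k])
                raw = vector.segment(frag.start, frag.end)
                lo, hi = frag.interval0
                emit(VECTOR_SOURCE, lo, hi, not frag.forward, raw, frag)
                prev_side = JunctionSide(*frag.exit_side())
            nxt = bridge_other[(bi, which)]
            if nxt is None:
                if len(sigs) > len(frags):  # dangling signature without partner
                    pass
                break
            npi, nend = nxt
            npiece = pieces[npi]
            entry_side = JunctionSide(
                npiece.chrom,
                npiece.start if nend == "L" else npiece.end,
                "right" if nend == "L" else "left",
            )
            register_junction((prev_side, entry_side), sigs[len(frags)])
            flip = nend == "R"
            pi = npi
        if seq_parts:
            walks.append(Walk(name, haplotype, blocks, "".join(seq_parts)))

    # deterministic traversal: free left ends first, then remaining free ends
    for pi, piece in enumerate(pieces):
        if pi in visited:
            continue
        if (pi, "L") not in attach:
            walk_from(pi, False)
    for pi, piece in enumerate(pieces):
        if pi in visited:
            continue
        if (pi, "R") not in attach:
            walk_from(pi, True)
    for pi in range(len(pieces)):
        if pi not in visited:
            raise SpecError("cyclic architecture is not supported")
    return walks


def _derive_losses(
    ref: ReferenceGenome, walks: list[Walk]
) -> list[tuple[str, int, int, Zygosity]]:
    losses: list[tuple[str, int, int, Zygosity]] = []
    per_hap_missing: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for h in (0, 1):
        cover: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}
        for walk in walks:
            if walk.haplotype != h:
                continue
            for blk in walk.blocks:
                if blk.source != VECTOR_SOURCE:
                    cover[blk.source].append((blk.start, blk.end))
        missing: dict[str, list[tuple[int, int]]] = {}
        for chrom in ref.names:
            ivs = sorted(cover[chrom])
            gaps = []
            prev = 0
            for a, b in ivs:
                if a > prev:
                    gaps.append((prev, a))
                prev = max(prev, b)
            if prev < ref.length(chrom):
                gaps.append((prev, ref.length(chrom)))
            missing[chrom] = gaps
        per_hap_missing[h] = missing
    for chrom in ref.names:
        boundaries = sorted(
            {p for iv in per_hap_missing[0][chrom] + per_hap_missing[1][chrom] for p in iv}
        )
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            in0 = any(x <= a and b <= y for x, y in per_hap_missing[0][chrom])
            in1 = any(x <= a and b <= y for x, y in per_hap_missing[1][chrom])
            if in0 and in1:
                losses.append((chrom, a, b, "homozygous"))
            elif in0 or in1:
                losses.append((chrom, a, b, "heterozygous"))
    # merge adjacent same-zygosity intervals
    losses.sort()
    merged: list[tuple[str, int, int, Zygosity]] = []
    for item in losses:
        if merged and merged[-1][0] == item[0] and merged[-1][2] == item[1] and merged[-1][3] == item[3]:
            merged[-1] = (item[0], merged[-1][1], item[2], item[3])
        else:
            merged.append(item)
    return merged
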