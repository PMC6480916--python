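"""Breakpoint clustering, concatemer reconstruction, fragment graph and
integration-event classification.

Per-read adjacent segment pairs yield breakpoint observations; observations
sharing sources/directions cluster by single linkage within ``cluster_tol``
on both coordinates (representative = per-side median). Concatemer
architectures are reconstructed by walking junction adjacencies along
supporting reads with longest-context matching, which keeps distinct
bridges apart even when they share an identical vector-vector joint.
"""

from __future__ import annotations

import statistics
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .segment import ReadSegment, SegmentedRead
from .simulate import (
    JunctionSide,
    ReferenceGenome,
    TdnaFragmentSpec,
    VECTOR_SOURCE,
)


@dataclass(frozen=True)
class JunctionParams:
    cluster_tol: int = 20
    min_support: int = 3
    gap_tol: int = 100  # case-1 same-break test and breakpoint merging
    max_obs_gap: int = 100  # max unaligned bases between adjacent segments


@dataclass(frozen=True)
class Observation:
    """One per-read breakpoint: read traverses side_a into side_b ('+')
    or side_b into side_a ('-') at read offset ``read_pos``."""

    side_a: JunctionSide
    side_b: JunctionSide
    read_id: str
    read_pos: int
    orient: str


@dataclass
class Junction:
    side_a: JunctionSide
    side_b: JunctionSide
    support: int
    observations: list[Observation] = field(default_factory=list)
    label: str = ""

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
class ConcatemerArchitecture:
    locus_left: JunctionSide | None
    locus_right: JunctionSide | None
    fragments: list[TdnaFragmentSpec]
    junction_path: list[int] = field(default_factory=list)  # indices into junction list
    ambiguous: bool = False
    notes: str = ""


@dataclass(frozen=True)
class GraphNode:
    chrom: str
    start: int
    end: int
    name: str


@dataclass
class GraphEdge:
    node_a: str
    node_b: str
    kind: str  # "vector" or "bare"
    detail: str = ""


@dataclass
class FragmentGraph:
    nodes: list[GraphNode]
    edges: list[GraphEdge]
    lost_nodes: list[str] = field(default_factory=list)


@dataclass
class IntegrationEvent:
    case: str  # intact_insertion | truncation | translocation | bare_translocation | complex
    architecture: ConcatemerArchitecture | None
    junction: Junction | None = None
    notes: str = ""


# ---------------------------------------------------------------------------
# breakpoint observations and clustering
# ---------------------------------------------------------------------------


def _exit_side(seg: ReadSegment) -> JunctionSide:
    if seg.strand == "+":
        return JunctionSide(seg.source, seg.source_end, "left")
    return JunctionSide(seg.source, seg.source_start, "right")


def _entry_side(seg: ReadSegment) -> JunctionSide:
    if seg.strand == "+":
        return JunctionSide(seg.source, seg.source_start, "right")
    return JunctionSide(seg.source, seg.source_end, "left")


def extract_observations(
    segmented_reads: Iterable[SegmentedRead], max_obs_gap: int = 100
) -> list[Observation]:
    out: list[Observation] = []
    for sr in segmented_reads:
        for s1, s2 in zip(sr.segments[:-1], sr.segments[1:]):
            if s2.read_start - s1.read_end > max_obs_gap:
                continue
            a, b = _exit_side(s1), _entry_side(s2)
            pos = (s1.read_end + s2.read_start) // 2
            if a.key() <= b.key():
                out.append(Observation(a, b, sr.read_id, pos, "+"))
            else:
                out.append(Observation(b, a, sr.read_id, pos, "-"))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_observations(
    observations: Sequence[Observation], cluster_tol: int
) -> list[list[Observation]]:
    """Single-linkage clustering within ``cluster_tol`` on both coordinates,
    among observations sharing sources and directions on both sides."""
    groups: dict[tuple, list[Observation]] = {}
    for obs in observations:
        key = (
            obs.side_a.source,
            obs.side_a.direction,
            obs.side_b.source,
            obs.side_b.direction,
        )
        groups.setdefault(key, []).append(obs)
    clusters: list[list[Observation]] = []
    for group in groups.values():
        group.sort(key=lambda o: (o.side_a.coord, o.side_b.coord))
        uf = _UnionFind(len(group))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].side_a.coord - group[i].side_a.coord > cluster_tol:
                    break
                if abs(group[j].side_b.coord - group[i].side_b.coord) <= cluster_tol:
                    uf.union(i, j)
        members: dict[int, list[Observation]] = {}
        for i, obs in enumerate(group):
            members.setdefault(uf.find(i), []).append(obs)
        clusters.extend(members.values())
    return clusters


def call_breakpoints(
    segmented_reads: Iterable[SegmentedRead],
    params: JunctionParams | None = None,
) -> list[Junction]:
    """Cluster per-read breakpoints into supported junctions with labels."""
    params = params or JunctionParams()
    observations = extract_observations(segmented_reads, params.max_obs_gap)
    clusters = cluster_observations(observations, params.cluster_tol)
    junctions: list[Junction] = []
    for members in clusters:
        reads = {m.read_id for m in members}
        if len(reads) < params.min_support:
            continue
        ca = int(statistics.median(m.side_a.coord for m in members))
        cb = int(statistics.median(m.side_b.coord for m in members))
        m0 = members[0]
        junctions.append(
            Junction(
                side_a=JunctionSide(m0.side_a.source, ca, m0.side_a.direction),
                side_b=JunctionSide(m0.side_b.source, cb, m0.side_b.direction),
                support=len(reads),
                observations=sorted(members, key=lambda m: (m.read_id, m.read_pos)),
            )
        )
    junctions.sort(key=lambda j: (j.side_a.key(), j.side_b.key()))
    for i, j in enumerate(junctions):
        j.label = _letters(i)
    return junctions


def _letters(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = string.ascii_lowercase[r] + out
    return out


# ---------------------------------------------------------------------------
# concatemer reconstruction
# ---------------------------------------------------------------------------


def concatemer_length(fragments: Iterable[TdnaFragmentSpec | tuple[int, int]]) -> int:
    """Total tract length under the reporting convention sum(|end - start|)."""
    total = 0
    for frag in fragments:
        if isinstance(frag, TdnaFragmentSpec):
            total += frag.length
        else:
            total += abs(frag[1] - frag[0])
    return total


@dataclass
class _ReadSeq:
    """One read's junction traversal in a fixed direction, plus the vector
    extent (bp) the read still covers beyond its final junction."""

    elems: list[tuple[int, str]]
    tail_extent: int


def _read_junction_walks(
    junctions: Sequence[Junction],
) -> dict[str, list[tuple[int, int, str]]]:
    """Per read: ordered (read_pos, junction index, orient) traversals."""
    walks: dict[str, list[tuple[int, int, str]]] = {}
    for ji, junction in enumerate(junctions):
        for obs in junction.observations:
            walks.setdefault(obs.read_id, []).append((obs.read_pos, ji, obs.orient))
    for read_id in walks:
        walks[read_id].sort()
    return walks


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _oriented_sequences(
    walks: Mapping[str, list[tuple[int, int, str]]],
    segmented_by_id: Mapping[str, SegmentedRead] | None = None,
) -> list[_ReadSeq]:
    """Each read's junction sequence in both traversal directions."""
    seqs: list[_ReadSeq] = []
    for read_id, items in walks.items():
        fwd = [(ji, orient) for _, ji, orient in items]
        head_ext = tail_ext = 0
        if segmented_by_id is not None and read_id in segmented_by_id:
            segs = segmented_by_id[read_id].segments
            first_pos, last_pos = items[0][0], items[-1][0]
            for seg in segs:
                if seg.is_vector and seg.read_start >= last_pos - 5:
                    tail_ext = seg.source_end - seg.source_start
                    break
            for seg in reversed(segs):
                if seg.is_vector and seg.read_end <= first_pos + 5:
                    head_ext = seg.source_end - seg.source_start
                    break
        seqs.append(_ReadSeq(fwd, tail_ext))
        seqs.append(_ReadSeq([(ji, _flip(o)) for ji, o in reversed(fwd)], head_ext))
    return seqs


def _implied_fragment_len(
    junctions: Sequence[Junction], last: tuple[int, str], nxt: tuple[int, str]
) -> int | None:
    """|end - start| of the vector fragment between two consecutive junctions."""
    _, entry = _traversal_sides(junctions[last[0]], last[1])
    exit_, _ = _traversal_sides(junctions[nxt[0]], nxt[1])
    if entry.source != VECTOR_SOURCE or exit_.source != VECTOR_SOURCE:
        return None
    s, _ = _vector_entry_fragment_start(entry)
    e, _ = _vector_exit_fragment_end(exit_)
    return abs(e - s)


def _extend_path(
    path: list[tuple[int, str]],
    seqs: list[_ReadSeq],
    junctions: Sequence[Junction],
    extent_tol: int = 50,
) -> tuple[list[tuple[int, str]], int, bool]:
    """Best continuation of ``path`` ranked by (context length, read count).

    Candidates whose implied next fragment is shorter than the vector extent
    observed in reads that end inside the next block (after matching the
    path context) are vetoed: such reads prove the true fragment is longer.
    """
    last = path[-1]
    candidates: dict[tuple[int, str], tuple[int, int]] = {}
    context_extent = 0
    for rs in seqs:
        seq = rs.elems
        for i, elem in enumerate(seq):
            if elem != last:
                continue
            ctx = 0
            while ctx <= i and ctx < len(path) and seq[i - ctx] == path[-1 - ctx]:
                ctx += 1
            if i + 1 < len(seq):
                nxt = seq[i + 1]
                best_ctx, count = candidates.get(nxt, (0, 0))
                if ctx > best_ctx:
                    candidates[nxt] = (ctx, 1)
                elif ctx == best_ctx:
                    candidates[nxt] = (ctx, count + 1)
            elif ctx >= 2:
                context_extent = max(context_extent, rs.tail_extent)
    if not candidates:
        return [], 0, False
    if context_extent > 0:
        unvetoed = {}
        for nxt, stats in candidates.items():
            flen = _implied_fragment_len(junctions, last, nxt)
            if flen is not None and flen + extent_tol < context_extent:
                continue
            unvetoed[nxt] = stats
        if unvetoed:
            candidates = unvetoed
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    ambiguous = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
    return [ranked[0][0]], ranked[0][1][1], ambiguous


def _vector_entry_fragment_start(side: JunctionSide) -> tuple[int, bool]:
    """1-based fragment start + forwardness from the side entering a fragment."""
    if side.direction == "right":
        return side.coord + 1, True
    return side.coord, False


def _vector_exit_fragment_end(side: JunctionSide) -> tuple[int, bool]:
    if side.direction == "left":
        return side.coord, True
    return side.coord + 1, False


def _traversal_sides(junction: Junction, orient: str) -> tuple[JunctionSide, JunctionSide]:
    if orient == "+":
        return junction.side_a, junction.side_b
    return junction.side_b, junction.side_a


def reconstruct_concatemer(
    junctions: Sequence[Junction],
    segmented_reads: Iterable[SegmentedRead],
    locus_junction: int,
    _seqs: list[_ReadSeq] | None = None,
) -> ConcatemerArchitecture:
    """Walk vector fragments outward from one genome-vector junction.

    ``locus_junction`` indexes into ``junctions`` and must be genome-vector
    (genome side is canonical side_a). Forks are resolved by longest read
    context, then by read support; ties flag the architecture ambiguous.
    """
    start = junctions[locus_junction]
    if start.category != "genome-vector":
        raise ValueError("locus junction must join genome and vector")
    segmented_reads = list(segmented_reads)
    if _seqs is None:
        _seqs = _oriented_sequences(
            _read_junction_walks(junctions), {sr.read_id: sr for sr in segmented_reads}
        )
    path: list[tuple[int, str]] = [(locus_junction, "+")]  # genome -> vector
    ambiguous = False
    notes: list[str] = []
    for _ in range(200):
        last_j, last_o = path[-1]
        _, into = _traversal_sides(junctions[last_j], last_o)
        if into.source != VECTOR_SOURCE:
            break  # reached the far genome side
        step, _support, amb = _extend_path(path, _seqs, junctions)
        if not step:
            break
        ambiguous |= amb
        path.append(step[0])

    fragments: list[TdnaFragmentSpec] = []
    for (j1, o1), (j2, o2) in zip(path[:-1], path[1:]):
        _, entry = _traversal_sides(junctions[j1], o1)
        exit_, _ = _traversal_sides(junctions[j2], o2)
        if entry.source != VECTOR_SOURCE or exit_.source != VECTOR_SOURCE:
            ambiguous = True
            notes.append("non-vector block inside tract")
            continue
        s, fwd_s = _vector_entry_fragment_start(entry)
        e, fwd_e = _vector_exit_fragment_end(exit_)
        if fwd_s != fwd_e or (fwd_s and e < s) or (not fwd_s and e > s):
            ambiguous = True
            notes.append(f"inconsistent fragment orientation at {entry}~{exit_}")
        fragments.append(TdnaFragmentSpec(s, e))

    locus_left = start.side_a
    last_j, last_o = path[-1]
    _, final_into = _traversal_sides(junctions[last_j], last_o)
    locus_right = final_into if final_into.source != VECTOR_SOURCE else None
    if locus_right is None:
        # one-ended tract: the last fragment dangles with no further junction;
        # recover its extent from the supporting reads' terminal segments
        dangling = _dangling_fragment(
            final_into, junctions[last_j], segmented_reads
        )
        if dangling is not None:
            fragments.append(dangling)
    arch = ConcatemerArchitecture(
        locus_left=locus_left,
        locus_right=locus_right,
        fragments=fragments,
        junction_path=[j for j, _ in path],
        ambiguous=ambiguous,
        notes="; ".join(notes),
    )
    return _canonical_architecture(arch)


def _dangling_fragment(
    entry: JunctionSide,
    last_junction: Junction,
    segmented_reads: Iterable[SegmentedRead],
    tol: int = 20,
) -> TdnaFragmentSpec | None:
    """Extent of a tract's terminal fragment from reads supporting its entry."""
    support = {o.read_id for o in last_junction.observations}
    s, fwd = _vector_entry_fragment_start(entry)
    far: int | None = None
    for sr in segmented_reads:
        if sr.read_id not in support:
            continue
        for seg in sr.segments:
            if not seg.is_vector:
                continue
            if fwd and abs(seg.source_start - (s - 1)) <= tol:
                far = seg.source_end if far is None else max(far, seg.source_end)
            elif not fwd and abs(seg.source_end - s) <= tol:
                far = seg.source_start if far is None else min(far, seg.source_start)
    if far is None:
        return None
    frag = TdnaFragmentSpec(s, far) if fwd else TdnaFragmentSpec(s, far + 1)
    return frag if frag.length > 0 else None


def _canonical_architecture(arch: ConcatemerArchitecture) -> ConcatemerArchitecture:
    """Orient two-ended architectures left-to-right by genomic locus order."""
    if arch.locus_right is None:
        return arch
    if arch.locus_left.key() <= arch.locus_right.key():
        return arch
    return ConcatemerArchitecture(
        locus_left=arch.locus_right,
        locus_right=arch.locus_left,
        fragments=[TdnaFragmentSpec(f.end, f.start) for f in reversed(arch.fragments)],
        junction_path=list(reversed(arch.junction_path)),
        ambiguous=arch.ambiguous,
        notes=arch.notes,
    )


def reconstruct_architectures(
    junctions: Sequence[Junction],
    segmented_reads: Iterable[SegmentedRead],
) -> list[ConcatemerArchitecture]:
    """One architecture per insertion tract, deduplicated across end loci."""
    segmented_reads = list(segmented_reads)
    seqs = _oriented_sequences(
        _read_junction_walks(junctions), {sr.read_id: sr for sr in segmented_reads}
    )
    out: list[ConcatemerArchitecture] = []
    seen: set[tuple] = set()
    for ji, junction in enumerate(junctions):
        if junction.category != "genome-vector":
            continue
        arch = reconstruct_concatemer(junctions, segmented_reads, ji, _seqs=seqs)
        key = (
            arch.locus_left,
            arch.locus_right,
            tuple((f.start, f.end) for f in arch.fragments),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(arch)
    return out


# ---------------------------------------------------------------------------
# fragment graph and event classification
# ---------------------------------------------------------------------------


def _merge_positions(positions: list[int], tol: int) -> list[int]:
    if not positions:
        return []
    positions = sorted(positions)
    merged: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - merged[-1][-1] <= tol:
            merged[-1].append(p)
        else:
            merged.append([p])
    return [int(statistics.median(g)) for g in merged]


def build_fragment_graph(
    junctions: Sequence[Junction],
    reference: ReferenceGenome,
    architectures: Sequence[ConcatemerArchitecture] = (),
    losses: Sequence[tuple[str, int, int, str]] = (),
    gap_tol: int = 100,
) -> FragmentGraph:
    """Partition chromosomes at genome-side breakpoints into named nodes;
    connect nodes through vector-bridged architectures and bare junctions."""
    breaks: dict[str, list[int]] = {n: [] for n in reference.names}
    for junction in junctions:
        for side in junction.genome_sides:
            if side.coord not in (0, reference.length(side.source)):
                breaks[side.source].append(side.coord)
    # loss-call boundaries add breakpoints only where no junction already
    # explains them (depth resolution is coarse: snap within loss_snap)
    loss_snap = max(gap_tol, 2000)
    for chrom, start, end, _zyg in losses:
        for p in (start, end):
            if p in (0, reference.length(chrom)):
                continue
            if any(abs(p - q) <= loss_snap for q in breaks[chrom]):
                continue
            breaks[chrom].append(p)

    nodes: list[GraphNode] = []
    node_lookup: dict[str, list[GraphNode]] = {}
    for chrom in reference.names:
        positions = _merge_positions(breaks[chrom], gap_tol)
        bounds = [0] + positions + [reference.length(chrom)]
        chrom_nodes = [
            GraphNode(chrom, a, b, f"{chrom}-{i + 1}")
            for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
            if b > a
        ]
        if len(chrom_nodes) == 1:
            chrom_nodes = [GraphNode(chrom, 0, reference.length(chrom), chrom)]
        nodes.extend(chrom_nodes)
        node_lookup[chrom] = chrom_nodes

    def node_for(side: JunctionSide) -> GraphNode | None:
        for node in node_lookup.get(side.source, []):
            if side.direction == "left" and abs(node.end - side.coord) <= gap_tol:
                return node
            if side.direction == "right" and abs(node.start - side.coord) <= gap_tol:
                return node
        # fall back to containment
        for node in node_lookup.get(side.source, []):
            if node.start <= side.coord <= node.end:
                return node
        return None

    edges: list[GraphEdge] = []
    for junction in junctions:
        if junction.category == "genome-genome":
            na, nb = node_for(junction.side_a), node_for(junction.side_b)
            if na and nb:
                edges.append(GraphEdge(na.name, nb.name, "bare", junction.label))
    for arch in architectures:
        if arch.locus_left is None or arch.locus_right is None:
            continue
        na, nb = node_for(arch.locus_left), node_for(arch.locus_right)
        if na and nb:
            edges.append(
                GraphEdge(na.name, nb.name, "vector", f"{len(arch.fragments)} fragments")
            )

    lost = []
    connected = {e.node_a for e in edges} | {e.node_b for e in edges}
    for chrom, start, end, zyg in losses:
        for node in node_lookup.get(chrom, []):
            if start <= node.start and node.end <= end and node.name not in connected:
                lost.append(node.name)
    return FragmentGraph(nodes, edges, lost)


def classify_events(
    graph: FragmentGraph,
    architectures: Sequence[ConcatemerArchitecture],
    junctions: Sequence[Junction] = (),
    gap_tol: int = 100,
) -> list[IntegrationEvent]:
    """Assign each architecture to one of the integration cases.

    Case rules: both genome sides flank one break on the same chromosome
    (within ``gap_tol``) -> intact_insertion; a single genome side ->
    truncation; sides on different chromosomes or distant loci ->
    translocation. Bare genome-genome junctions -> bare_translocation.
    """
    events: list[IntegrationEvent] = []
    for arch in architectures:
        left, right = arch.locus_left, arch.locus_right
        if left is None and right is None:
            events.append(IntegrationEvent("complex", arch, notes="no genome side"))
            continue
        if left is None or right is None:
            events.append(IntegrationEvent("truncation", arch))
            continue
        same_chrom = left.source == right.source
        close = same_chrom and abs(left.coord - right.coord) <= gap_tol
        dirs = {left.direction, right.direction}
        if close and dirs == {"left", "right"}:
            events.append(IntegrationEvent("intact_insertion", arch))
        elif close:
            events.append(
                IntegrationEvent("complex", arch, notes="same break, same directions")
            )
        else:
            events.append(IntegrationEvent("translocation", arch))
    for junction in junctions:
        if junction.category == "genome-genome":
            events.append(IntegrationEvent("bare_translocation", None, junction=junction))
    return events


def insertion_loci(
    junctions: Sequence[Junction], gap_tol: int = 100
) -> list[tuple[str, int]]:
    """Distinct genome loci carrying at least one genome-vector junction."""
    per_chrom: dict[str, list[int]] = {}
    for junction in junctions:
        if junction.category != "genome-vector":
            continue
        side = junction.genome_sides[0]
        per_chrom.setdefault(side.source, []).append(side.coord)
    loci = []
    for chrom in sorted(per_chrom):
        for pos in _merge_positions(per_chrom[chrom], gap_tol):
            loci.append((chrom, pos))
    return loci
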