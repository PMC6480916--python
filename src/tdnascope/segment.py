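"""Selection of vector-containing reads and tiling of each read into an
ordered walk of vector/genome segments.

Tiling is weighted interval scheduling over the read's local alignments
(weight = alignment score). Compatible alignments may overlap on the read up
to ``merge_overlap`` bases — merged long-homology junctions legitimately
produce overlapping segments — and any residual overlap is trimmed at the
midpoint of the conflicted region, so emitted segments partition the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import LocalAlignment
from .simulate import TdnaFragmentSpec, VECTOR_SOURCE


@dataclass(frozen=True)
class SegmentParams:
    min_vector_span: int = 200
    min_identity: float = 0.8
    min_segment_len: int = 50
    overlap_tol: int = 30
    #: scheduling overlap allowance; must exceed the longest merged homology
    merge_overlap: int = 400


@dataclass(frozen=True)
class ReadSegment:
    read_start: int
    read_end: int
    source: str  # "vector" or chromosome name
    source_start: int
    source_end: int
    strand: str

    @property
    def is_vector(self) -> bool:
        return self.source == VECTOR_SOURCE

    def fragment_spec(self) -> TdnaFragmentSpec:
        """Vector segment as a 1-based fragment (reverse: start > end)."""
        if not self.is_vector:
            raise ValueError("not a vector segment")
        if self.strand == "+":
            return TdnaFragmentSpec(self.source_start + 1, self.source_end)
        return TdnaFragmentSpec(self.source_end, self.source_start + 1)


@dataclass
class SegmentedRead:
    read_id: str
    read_length: int
    segments: list[ReadSegment]
    gaps: list[tuple[int, int]]


def classify_reads(
    read_ids: Iterable[str],
    alignments: Iterable[LocalAlignment],
    params: SegmentParams | None = None,
    vector_id: str = VECTOR_SOURCE,
) -> tuple[set[str], set[str]]:
    """Split reads into (vector_containing, passthrough).

    A read is vector-containing iff some alignment to the vector spans at
    least ``min_vector_span`` read bases at identity >= ``min_identity``.
    """
    params = params or SegmentParams()
    vector_hits: set[str] = set()
    for aln in alignments:
        if (
            aln.target_id == vector_id
            and aln.read_span >= params.min_vector_span
            and aln.identity >= params.min_identity
        ):
            vector_hits.add(aln.read_id)
    all_ids = set(read_ids)
    return vector_hits & all_ids, all_ids - vector_hits


def segment_read(
    read_id: str,
    read_length: int,
    alignments: Sequence[LocalAlignment],
    params: SegmentParams | None = None,
) -> SegmentedRead:
    """Maximal-score consistent tiling of one read's alignments."""
    params = params or SegmentParams()
    cands = sorted(
        (a for a in alignments if a.read_id == read_id and a.read_span >= params.min_segment_len),
        key=lambda a: (a.read_end, a.read_start, a.target_id, a.target_start),
    )
    chosen = _schedule(cands, params.merge_overlap)
    chosen.sort(key=lambda a: (a.read_start, a.read_end))
    segments = _trim_overlaps(chosen, params.min_segment_len)
    gaps = _complement(segments, read_length)
    return SegmentedRead(read_id, read_length, segments, gaps)


def _schedule(cands: Sequence[LocalAlignment], slack: int) -> list[LocalAlignment]:
    """Maximal-score chain of alignments over the read.

    Consecutive chain members may overlap up to ``slack`` bases on the read
    (merged long-homology junctions need this), but every overlapping base
    is penalized at the match score, so redundant alignments that merely
    re-cover already-claimed read bases never enter the tiling. Ties resolve
    deterministically via the stable candidate ordering (leftmost start
    preferred).
    """
    n = len(cands)
    if n == 0:
        return []
    best = [a.score for a in cands]
    parent = [-1] * n
    for i, a in enumerate(cands):
        for j in range(i):
            b = cands[j]
            ov = min(b.read_end, a.read_end) - max(b.read_start, a.read_start)
            if ov > slack:
                continue
            if b.read_end > a.read_end or b.read_start >= a.read_start:
                continue  # keep chain strictly advancing along the read
            cand_score = best[j] + a.score - 2.0 * max(0, ov)
            if cand_score > best[i]:
                best[i] = cand_score
                parent[i] = j
    i = max(range(n), key=lambda k: best[k])
    out: list[LocalAlignment] = []
    while i >= 0:
        out.append(cands[i])
        i = parent[i]
    out.reverse()
    return out


def _trim_overlaps(
    chosen: Sequence[LocalAlignment], min_segment_len: int
) -> list[ReadSegment]:
    bounds: list[list[int]] = [[a.read_start, a.read_end] for a in chosen]
    for i in range(len(chosen) - 1):
        ov = bounds[i][1] - bounds[i + 1][0]
        if ov > 0:
            mid = bounds[i + 1][0] + ov // 2
            bounds[i][1] = mid
            bounds[i + 1][0] = mid
    segments: list[ReadSegment] = []
    for a, (rs, re) in zip(chosen, bounds):
        if re - rs < min_segment_len:
            continue
        head = rs - a.read_start  # bases trimmed from read start
        tail = a.read_end - re
        # map trims onto target coords; segments are treated as collinear
        # (error-scale indel drift is absorbed by junction clustering)
        if a.strand == "+":
            ts = a.target_start + head
            te = a.target_end - tail
        else:
            ts = a.target_start + tail
            te = a.target_end - head
        if te - ts <= 0:
            continue
        segments.append(ReadSegment(rs, re, a.target_id, ts, te, a.strand))
    return segments


def _complement(segments: Sequence[ReadSegment], read_length: int) -> list[tuple[int, int]]:
    gaps = []
    prev = 0
    for seg in segments:
        if seg.read_start > prev:
            gaps.append((prev, seg.read_start))
        prev = max(prev, seg.read_end)
    if prev < read_length:
        gaps.append((prev, read_length))
    return gaps


def segments_to_tsv(reads: Iterable[SegmentedRead]) -> str:
    lines = ["read_id\torder\tread_start\tread_end\tsource\tsource_start\tsource_end\tstrand"]
    for sr in reads:
        for i, seg in enumerate(sr.segments):
            lines.append(
                f"{sr.read_id}\t{i}\t{seg.read_start}\t{seg.read_end}"
                f"\t{seg.source}\t{seg.source_start}\t{seg.source_end}\t{seg.strand}"
            )
    return "\n".join(lines) + "\n"
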