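"""Local alignment of reads against vector and reference sequences.

Two engines sit behind one interface:

* an exact local aligner (Smith-Waterman with affine gaps, delegated to
  :class:`Bio.Align.PairwiseAligner`) used whenever the DP matrix is small
  enough, with iterative query masking to recover multiple alignments;
* a seed-chain-extend heuristic (sorted k-mer index, diagonal clustering,
  longest-increasing-subsequence chaining, exact terminal extension) for
  read-scale problems.

Scoring is fixed package-wide: match +2, mismatch -4, and a gap of length
``g`` costs ``4 + 2*g`` (open -4 charged once, plus -2 per gapped base).
Coordinates are 0-based half-open; minus-strand alignments store the target
interval in forward target coordinates and the read interval in original
read coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import Align as _bioalign

from .dna import encode, kmer_codes, revcomp

MATCH = 2
MISMATCH = -4
GAP_OPEN = -4  # charged once per gap, on top of the per-base extension
GAP_EXTEND = -2


@dataclass(frozen=True)
class AlignParams:
    k: int = 15
    min_chain_anchors: int = 3
    min_score: int = 50
    max_gap: int = 500
    seed_stride: int = 3
    max_hits: int = 16
    diag_band: int = 64
    dp_max_cells: int = 4_000_000

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a read interval onto a target interval."""

    read_id: str
    read_start: int
    read_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str  # '+' or '-'
    identity: float
    score: float

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def validate(self) -> None:
        if self.read_start >= self.read_end or self.target_start >= self.target_end:
            raise ValueError("alignment intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (math.isnan(self.identity) or 0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


def _make_pairwise(mode: str) -> _bioalign.PairwiseAligner:
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_LOCAL_ALIGNER = _make_pairwise("local")
_GLOBAL_ALIGNER = _make_pairwise("global")


@dataclass
class _Tally:
    matches: int = 0
    mismatches: int = 0
    gap_events: int = 0
    gap_bases: int = 0

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_bases

    @property
    def score(self) -> int:
        s = MATCH * self.matches + MISMATCH * self.mismatches
        if self.gap_bases:
            s -= abs(GAP_OPEN) * self.gap_events + abs(GAP_EXTEND) * self.gap_bases
        return s

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _block_stats(target: str, query: str, alignment) -> tuple[_Tally, int, int, int, int]:
    """Tally + (qs, qe, ts, te) over the aligned blocks of a Bio.Align alignment.

    Gap events/bases are counted between blocks only (local mode trims ends).
    """
    tblocks, qblocks = alignment.aligned
    tally = _Tally()
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        a = np.frombuffer(target[ts:te].encode(), dtype=np.uint8)
        b = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
        m = int(np.count_nonzero(a == b))
        tally.matches += m
        tally.mismatches += (te - ts) - m
        if prev_t is not None:
            if ts > prev_t:
                tally.gap_events += 1
                tally.gap_bases += ts - prev_t
            if qs > prev_q:
                tally.gap_events += 1
                tally.gap_bases += qs - prev_q
        prev_t, prev_q = te, qe
    return tally, int(qblocks[0][0]), int(qblocks[-1][1]), int(tblocks[0][0]), int(tblocks[-1][1])


def _global_gap_stats(tpiece: str, qpiece: str) -> _Tally:
    """Globally align two inter-anchor pieces and tally them (ends included)."""
    tally = _Tally()
    if not tpiece and not qpiece:
        return tally
    if not tpiece or not qpiece:
        tally.gap_events = 1
        tally.gap_bases = max(len(tpiece), len(qpiece))
        return tally
    alignment = next(iter(_GLOBAL_ALIGNER.align(tpiece, qpiece)))
    inner, qs, qe, ts, te = _block_stats(tpiece, qpiece, alignment)
    tally.matches = inner.matches
    tally.mismatches = inner.mismatches
    tally.gap_events = inner.gap_events
    tally.gap_bases = inner.gap_bases
    # leading / trailing gaps are not part of .aligned blocks in global mode
    if ts > 0 or qs > 0:
        tally.gap_events += int(ts > 0) + int(qs > 0)
        tally.gap_bases += ts + qs
    if te < len(tpiece) or qe < len(qpiece):
        tally.gap_events += int(te < len(tpiece)) + int(qe < len(qpiece))
        tally.gap_bases += (len(tpiece) - te) + (len(qpiece) - qe)
    return tally


def _dp_scan(
    read_id: str,
    query: str,
    target_id: str,
    target: str,
    strand: str,
    min_score: float,
    max_rounds: int = 32,
) -> list[LocalAlignment]:
    """Exact local alignment with iterative query masking."""
    out: list[LocalAlignment] = []
    q = query if strand == "+" else revcomp(query)
    qlen = len(q)
    work = q
    for _ in range(max_rounds):
        score = _LOCAL_ALIGNER.score(target, work)
        if score < min_score:
            break
        alignment = next(iter(_LOCAL_ALIGNER.align(target, work)))
        tally, qs, qe, ts, te = _block_stats(target, work, alignment)
        if qe <= qs:
            break
        if strand == "+":
            rs, re = qs, qe
        else:
            rs, re = qlen - qe, qlen - qs
        out.append(
            LocalAlignment(
                read_id=read_id,
                read_start=rs,
                read_end=re,
                target_id=target_id,
                target_start=ts,
                target_end=te,
                strand=strand,
                identity=tally.identity,
                score=float(score),
            )
        )
        work = work[:qs] + "X" * (qe - qs) + work[qe:]
    return out


class TargetIndex:
    """Sorted k-mer index over a set of named target sequences."""

    def __init__(self, targets: Mapping[str, str], k: int = 15):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.names: list[str] = list(targets)
        self.seqs: dict[str, str] = dict(targets)
        self._codes_cache: dict[str, np.ndarray] = {}
        codes_parts, tid_parts, pos_parts = [], [], []
        for tid, name in enumerate(self.names):
            seq = targets[name]
            if not seq:
                raise ValueError(f"target {name!r} is empty")
            kc = kmer_codes(encode(seq), k)
            keep = kc >= 0
            codes_parts.append(kc[keep])
            pos_parts.append(np.flatnonzero(keep).astype(np.int64))
            tid_parts.append(np.full(int(keep.sum()), tid, dtype=np.int32))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.tids = np.concatenate(tid_parts)[order] if tid_parts else np.empty(0, np.int32)
        self.pos = np.concatenate(pos_parts)[order] if pos_parts else np.empty(0, np.int64)

    def target_codes(self, name: str) -> np.ndarray:
        if name not in self._codes_cache:
            self._codes_cache[name] = encode(self.seqs[name])
        return self._codes_cache[name]

    def lookup(
        self, query_codes: np.ndarray, max_hits: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Anchor triples (qpos, tid, tpos) for a query k-mer code array."""
        qpos_all = np.flatnonzero(query_codes >= 0)
        qk = query_codes[qpos_all]
        lo = np.searchsorted(self.codes, qk, side="left")
        hi = np.searchsorted(self.codes, qk, side="right")
        lens = hi - lo
        keep = (lens > 0) & (lens <= max_hits)
        lo, lens, qpos_all = lo[keep], lens[keep], qpos_all[keep]
        total = int(lens.sum())
        if total == 0:
            return (np.empty(0, np.int64),) * 3
        starts = np.repeat(lo, lens)
        offsets = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        idx = starts + offsets
        return np.repeat(qpos_all, lens), self.tids[idx].astype(np.int64), self.pos[idx]


def _lis_chain(tpos: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly-increasing subsequence of ``tpos``.

    Input must already be sorted by query position (ties broken by tpos).
    """
    n = len(tpos)
    tails: list[int] = []
    tail_t: list[int] = []
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        t = int(tpos[i])
        lo, hi = 0, len(tail_t)
        while lo < hi:
            mid = (lo + hi) // 2
            if tail_t[mid] < t:
                lo = mid + 1
            else:
                hi = mid
        if lo > 0:
            parent[i] = tails[lo - 1]
        if lo == len(tail_t):
            tail_t.append(t)
            tails.append(i)
        else:
            tail_t[lo] = t
            tails[lo] = i
    chain = []
    i = tails[-1] if tails else -1
    while i >= 0:
        chain.append(i)
        i = parent[i]
    return np.array(chain[::-1], dtype=np.int64)


def _extend_exact(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the common prefix of two code arrays."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    neq = a[:n] != b[:n]
    idx = np.flatnonzero(neq)
    return int(idx[0]) if len(idx) else n


def _chain_to_alignment(
    read_id: str,
    q: str,
    qcodes: np.ndarray,
    target_id: str,
    t: str,
    tcodes: np.ndarray,
    qpos: np.ndarray,
    tpos: np.ndarray,
    k: int,
    strand: str,
    qlen_full: int,
) -> LocalAlignment:
    """Assemble an alignment from chained anchors (coords in strand frame)."""
    # collapse the chain into maximal co-diagonal runs
    runs: list[list[int]] = []  # [qstart, tstart, length]
    for qi, ti in zip(qpos.tolist(), tpos.tolist()):
        if runs:
            rq, rt, rl = runs[-1]
            if ti - qi == rt - rq and qi <= rq + rl:
                runs[-1][2] = max(rl, qi + k - rq)
                continue
            if qi < rq + rl or ti < rt + rl:  # conflicting anchor, skip
                continue
        runs.append([qi, ti, k])

    tally = _Tally()
    qs, ts = runs[0][0], runs[0][1]
    qe, te = qs + runs[0][2], ts + runs[0][2]
    tally.matches += runs[0][2]
    for rq, rt, rl in runs[1:]:
        qgap, tgap = rq - qe, rt - te
        if qgap == tgap:
            sub = int(np.count_nonzero(qcodes[qe:rq] != tcodes[te:rt]))
            tally.matches += qgap - sub
            tally.mismatches += sub
        else:
            tally_gap = _global_gap_stats(t[te:rt], q[qe:rq])
            tally.matches += tally_gap.matches
            tally.mismatches += tally_gap.mismatches
            tally.gap_events += tally_gap.gap_events
            tally.gap_bases += tally_gap.gap_bases
        tally.matches += rl
        qe, te = rq + rl, rt + rl

    left = _extend_exact(qcodes[:qs][::-1], tcodes[:ts][::-1])
    right = _extend_exact(qcodes[qe:], tcodes[te:])
    qs, ts, qe, te = qs - left, ts - left, qe + right, te + right
    tally.matches += left + right

    if strand == "+":
        rs, re = qs, qe
    else:
        rs, re = qlen_full - qe, qlen_full - qs
    return LocalAlignment(
        read_id=read_id,
        read_start=rs,
        read_end=re,
        target_id=target_id,
        target_start=ts,
        target_end=te,
        strand=strand,
        identity=tally.identity,
        score=float(tally.score),
    )


def _heuristic_scan(
    read_id: str,
    query: str,
    index: TargetIndex,
    params: AlignParams,
) -> list[LocalAlignment]:
    out: list[LocalAlignment] = []
    qlen = len(query)
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        qcodes = encode(q)
        kq = kmer_codes(qcodes, params.k)
        stride = params.seed_stride
        strided = np.full_like(kq, -1)
        strided[::stride] = kq[::stride]
        qpos, tids, tpos = index.lookup(strided, params.max_hits)
        if len(qpos) == 0:
            continue
        diag = tpos - qpos
        order = np.lexsort((qpos, diag, tids))
        qpos, tids, tpos, diag = qpos[order], tids[order], tpos[order], diag[order]
        # split into clusters on target change or diagonal jump
        brk = np.flatnonzero(
            (np.diff(tids) != 0) | (np.abs(np.diff(diag)) > params.diag_band)
        )
        bounds = np.concatenate(([0], brk + 1, [len(qpos)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < params.min_chain_anchors:
                continue
            tid = int(tids[a])
            cq, ct = qpos[a:b], tpos[a:b]
            sub = np.lexsort((ct, cq))
            cq, ct = cq[sub], ct[sub]
            chain = _lis_chain(ct)
            if len(chain) < params.min_chain_anchors:
                continue
            tname = index.names[tid]
            aln = _chain_to_alignment(
                read_id,
                q,
                qcodes,
                tname,
                index.seqs[tname],
                index.target_codes(tname),
                cq[chain],
                ct[chain],
                params.k,
                strand,
                qlen,
            )
            if aln.score >= params.min_score:
                out.append(aln)
    return _prune(out, params.max_gap)


def _prune(alignments: list[LocalAlignment], slack: int) -> list[LocalAlignment]:
    """Keep a best-first subset whose query intervals overlap at most ``slack``.

    ``slack`` must accommodate merged long-homology junctions, where the two
    true segments legitimately share up to a few hundred query bases.
    """
    order = sorted(
        alignments, key=lambda a: (-a.score, a.read_start, a.target_id, a.target_start)
    )
    kept: list[LocalAlignment] = []
    for aln in order:
        ok = True
        for other in kept:
            ov = min(aln.read_end, other.read_end) - max(aln.read_start, other.read_start)
            if ov > slack:
                ok = False
                break
        if ok:
            kept.append(aln)
    kept.sort(key=lambda a: (a.read_start, a.read_end, a.target_id, a.target_start))
    return kept


def align_local(
    query: str,
    target: str,
    params: AlignParams | None = None,
    *,
    read_id: str = "query",
    target_id: str = "target",
) -> list[LocalAlignment]:
    """Local alignments of ``query`` against ``target``.

    Uses exact DP (optimal under the package scoring scheme) when the matrix
    fits in ``params.dp_max_cells``, otherwise the seed-chain-extend engine.
    """
    params = params or AlignParams()
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    if len(query) * len(target) <= params.dp_max_cells:
        out = _dp_scan(read_id, query, target_id, target, "+", params.min_score)
        out += _dp_scan(read_id, query, target_id, target, "-", params.min_score)
        return _prune(out, params.max_gap)
    index = TargetIndex({target_id: target}, params.k)
    return _heuristic_scan(read_id, query, index, params)


def align_to_index(
    read_id: str, query: str, index: TargetIndex, params: AlignParams | None = None
) -> list[LocalAlignment]:
    """Heuristic alignment of one read against an indexed target set."""
    params = params or AlignParams(k=index.k)
    if not query:
        raise ValueError("query must be non-empty")
    return _heuristic_scan(read_id, query, index, params)


# ---------------------------------------------------------------------------
# interoperability: PAF / SAM
# ---------------------------------------------------------------------------


def ingest_alignments(path: str, fmt: str) -> list[LocalAlignment]:
    """Load alignments from a PAF or SAM file, normalized to package conventions."""
    fmt = fmt.upper()
    if fmt == "PAF":
        return _ingest_paf(path)
    if fmt == "SAM":
        return _ingest_sam(path)
    raise ValueError(f"unsupported alignment format: {fmt!r}")


def _ingest_paf(path: str) -> list[LocalAlignment]:
    out: list[LocalAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: PAF record has {len(fields)} fields (< 12)")
            try:
                qs, qe = int(fields[2]), int(fields[3])
                strand = fields[4]
                ts, te = int(fields[7]), int(fields[8])
                matches, alen = int(fields[9]), int(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF record: {exc}") from None
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            out.append(
                LocalAlignment(
                    read_id=fields[0],
                    read_start=qs,
                    read_end=qe,
                    target_id=fields[5],
                    target_start=ts,
                    target_end=te,
                    strand=strand,
                    identity=matches / alen if alen else 0.0,
                    score=float(matches),
                )
            )
    return out


def _ingest_sam(path: str) -> list[LocalAlignment]:
    import pysam

    out: list[LocalAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            lead = trail = 0
            cig = rec.cigartuples
            # 4 = soft clip, 5 = hard clip
            i = 0
            while i < len(cig) and cig[i][0] in (4, 5):
                lead += cig[i][1]
                i += 1
            j = len(cig) - 1
            while j >= 0 and cig[j][0] in (4, 5):
                trail += cig[j][1]
                j -= 1
            qalen = sum(ln for op, ln in cig if op in (0, 1, 7, 8))  # M, I, =, X
            read_len = lead + qalen + trail
            if rec.is_reverse:
                rs, re = trail, trail + qalen
            else:
                rs, re = lead, lead + qalen
            columns = sum(ln for op, ln in cig if op in (0, 1, 2, 7, 8))
            ins = sum(ln for op, ln in cig if op == 1)
            dele = sum(ln for op, ln in cig if op == 2)
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
                sub = max(int(nm) - ins - dele, 0)
                matches = columns - ins - dele - sub
                identity = matches / columns if columns else 0.0
            else:
                identity = float("nan")
            out.append(
                LocalAlignment(
                    read_id=rec.query_name,
                    read_start=rs,
                    read_end=re,
                    target_id=rec.reference_name,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    identity=identity,
                    score=float(rec.mapping_quality),
                )
            )
    return out


def to_paf_line(aln: LocalAlignment, read_len: int, target_len: int) -> str:
    """Serialize one alignment as a PAF record."""
    columns = max(aln.read_span, aln.target_span)
    matches = int(round(aln.identity * columns)) if not math.isnan(aln.identity) else 0
    return "\t".join(
        str(x)
        for x in (
            aln.read_id,
            read_len,
            aln.read_start,
            aln.read_end,
            aln.strand,
            aln.target_id,
            target_len,
            aln.target_start,
            aln.target_end,
            matches,
            columns,
            60,
        )
    )


def write_paf(
    alignments: Iterable[LocalAlignment],
    path: str,
    read_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(
                to_paf_line(aln, read_lengths[aln.read_id], target_lengths[aln.target_id]) + "\n"
            )
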