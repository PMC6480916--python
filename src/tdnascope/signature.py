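"""Repair-signature classification at junctions: blunt joins, micro-homology,
filler insertions, and long homology.

The classifier anchors the two reference flanks inside an observed junction
sequence and extends each anchor by maximal exact match toward the junction.
With flanks that overshoot the nominal breakpoint, the extension lands on
the true boundaries regardless of where overlap trimming placed the called
coordinate, so midpoint-trimmed calls still classify correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dna import decode, encode, revcomp
from .junctions import Junction, _traversal_sides
from .simulate import ReferenceGenome, VectorAnnotation, VECTOR_SOURCE, JunctionSide


class UnanchoredJunctionError(ValueError):
    """The flanks could not be located in the observed sequence."""


@dataclass(frozen=True)
class SignatureParams:
    mh_max: int = 20  # split between micro-homology and long homology
    flank_anchor: int = 30  # exact anchor length required for each flank
    flank_len: int = 250  # flank context before the breakpoint
    overshoot: int = 300  # flank context past the called breakpoint
    window: int = 600  # consensus half-window around the junction
    min_side_cover: int = 150  # spanning read must cover this much per side


@dataclass(frozen=True)
class JunctionSignature:
    kind: str  # blunt | microhomology | filler | long_homology | uncalled
    microhomology_len: int = 0
    filler_seq: str = ""
    homology_len: int = 0

    def __post_init__(self) -> None:
        if self.kind == "blunt" and (
            self.microhomology_len or self.filler_seq or self.homology_len
        ):
            raise ValueError("blunt signature must have zero-length features")


def _anchor_left(flank: str, observed: str, anchor: int) -> tuple[int, int] | None:
    """(end position, matched length) of the maximal match of ``flank`` in
    ``observed``.

    The flank's first ``anchor`` bases must occur exactly; among occurrences
    the longest extension wins, ties by rightmost end (innermost placement).
    """
    probe = flank[:anchor]
    best = None
    start = observed.find(probe)
    while start >= 0:
        n = min(len(flank), len(observed) - start)
        ext = _common_prefix(flank[:n], observed[start : start + n])
        cand = (ext, start + ext)
        if best is None or cand > best:
            best = cand
        start = observed.find(probe, start + 1)
    return (best[1], best[0]) if best else None


def _anchor_right(flank: str, observed: str, anchor: int) -> tuple[int, int] | None:
    """(start position, matched length) of the maximal match of ``flank``,
    anchored on the flank's last ``anchor`` bases, extended leftward."""
    probe = flank[-anchor:]
    best = None
    start = observed.find(probe)
    while start >= 0:
        stop = start + anchor
        n = min(len(flank), stop)
        ext = _common_suffix(flank[-n:], observed[stop - n : stop])
        cand = (ext, -(stop - ext))
        if best is None or cand > best:
            best = cand
        start = observed.find(probe, start + 1)
    return (-best[1], best[0]) if best else None


def _common_prefix(a: str, b: str) -> int:
    x, y = encode(a), encode(b)
    n = min(len(x), len(y))
    neq = np.flatnonzero(x[:n] != y[:n])
    return int(neq[0]) if len(neq) else n


def _common_suffix(a: str, b: str) -> int:
    return _common_prefix(a[::-1], b[::-1])


def classify_junction(
    left_ref_flank: str,
    right_ref_flank: str,
    observed_junction_seq: str,
    mh_max: int = 20,
    flank_anchor: int = 30,
) -> JunctionSignature:
    """Classify the repair signature joining two flanks in an observed sequence.

    ``left_ref_flank`` approaches the junction (junction at its right end, or
    within it when the flank overshoots); ``right_ref_flank`` leaves it. If
    the flanks anchor only in the reverse complement of the observed
    sequence, it is flipped automatically.
    """
    if len(left_ref_flank) < flank_anchor or len(right_ref_flank) < flank_anchor:
        raise ValueError("flanks shorter than the anchor length")
    # fragments overlapping in vector space can make the flanks cross-anchor
    # in the wrong orientation; the true anchoring matches more flank bases
    candidates = []
    for observed in (observed_junction_seq, revcomp(observed_junction_seq)):
        left_hit = _anchor_left(left_ref_flank, observed, flank_anchor)
        right_hit = _anchor_right(right_ref_flank, observed, flank_anchor)
        if left_hit is None or right_hit is None:
            continue
        p, ext_l = left_hit
        q, ext_r = right_hit
        candidates.append((ext_l + ext_r, -abs(p - q), p, q, observed))
    if not candidates:
        raise UnanchoredJunctionError("flanks not found in observed junction sequence")
    _, _, p, q, observed = max(candidates)
    overlap = p - q
    if overlap == 0:
        return JunctionSignature("blunt")
    if overlap > 0:
        if overlap <= mh_max:
            return JunctionSignature("microhomology", microhomology_len=overlap)
        return JunctionSignature("long_homology", homology_len=overlap)
    return JunctionSignature("filler", filler_seq=observed[p:q])


# ---------------------------------------------------------------------------
# consensus over spanning reads
# ---------------------------------------------------------------------------


def consensus_window(windows: Sequence[str], max_shift: int = 16) -> str:
    """Majority-vote consensus of junction windows.

    Windows are extracted around per-read junction positions that jitter by a
    few bases under sequencing error, so each window is first re-anchored
    against a backbone (best offset within ``max_shift``) before per-column
    voting. Substitution-only errors then vote out cleanly.
    """
    if not windows:
        return ""
    if len(windows) == 1:
        return windows[0]
    backbone = max(windows, key=len)
    n = len(backbone)
    bb = encode(backbone)
    votes = np.zeros((n, 4), dtype=np.int32)
    for w in windows:
        ww = encode(w)
        best_shift, best_matches = 0, -1
        for shift in range(-max_shift, max_shift + 1):
            # compare ww offset by `shift` against the backbone
            b0, b1 = max(0, shift), min(n, len(ww) + shift)
            if b1 - b0 < 50:
                continue
            seg = ww[b0 - shift : b1 - shift]
            matches = int(np.count_nonzero(seg == bb[b0:b1]))
            if matches > best_matches:
                best_matches, best_shift = matches, shift
        b0, b1 = max(0, best_shift), min(n, len(ww) + best_shift)
        seg = ww[b0 - best_shift : b1 - best_shift]
        cols = np.arange(b0, b1)
        ok = seg < 4
        votes[cols[ok], seg[ok]] += 1
    covered = votes.sum(axis=1) > 0
    out = votes.argmax(axis=1).astype(np.uint8)
    return decode(out[covered])


def side_context(
    reference: ReferenceGenome,
    vector: VectorAnnotation,
    side: JunctionSide,
    role: str,
    flank_len: int,
    overshoot: int,
) -> str:
    """Reference context for one junction side, overshooting the breakpoint.

    role "left": sequence approaching the junction (breakpoint at offset
    ``flank_len`` from the right end minus overshoot); role "right":
    sequence leaving it.
    """
    seq = vector.sequence if side.source == VECTOR_SOURCE else reference.sequence(side.source)
    if role == "left":
        if side.direction == "left":
            return seq[max(0, side.coord - flank_len) : side.coord + overshoot]
        return revcomp(seq[max(0, side.coord - overshoot) : side.coord + flank_len])
    if side.direction == "right":
        return seq[max(0, side.coord - overshoot) : side.coord + flank_len]
    return revcomp(seq[max(0, side.coord - flank_len) : side.coord + overshoot])


@dataclass
class SignatureRow:
    label: str
    signature: JunctionSignature
    support: int
    n_windows: int
    consensus: str


def signature_table(
    junctions: Sequence[Junction],
    reference: ReferenceGenome,
    vector: VectorAnnotation,
    read_seqs: Mapping[str, str],
    params: SignatureParams | None = None,
) -> list[SignatureRow]:
    """Per-junction signatures from read consensus at each called junction."""
    params = params or SignatureParams()
    rows: list[SignatureRow] = []
    for junction in junctions:
        windows: list[str] = []
        for obs in junction.observations:
            seq = read_seqs.get(obs.read_id)
            if seq is None:
                continue
            lo = obs.read_pos - params.window
            hi = obs.read_pos + params.window
            if obs.read_pos < params.min_side_cover or len(seq) - obs.read_pos < params.min_side_cover:
                continue
            window = seq[max(0, lo) : hi]
            if obs.orient == "-":
                window = revcomp(window)
            windows.append(window)
        if not windows:
            rows.append(
                SignatureRow(junction.label, JunctionSignature("uncalled"), junction.support, 0, "")
            )
            continue
        cons = consensus_window(windows)
        left = side_context(
            reference, vector, junction.side_a, "left", params.flank_len, params.overshoot
        )
        right = side_context(
            reference, vector, junction.side_b, "right", params.flank_len, params.overshoot
        )
        try:
            sig = classify_junction(
                left, right, cons, params.mh_max, params.flank_anchor
            )
        except UnanchoredJunctionError:
            sig = JunctionSignature("uncalled")
        rows.append(SignatureRow(junction.label, sig, junction.support, len(windows), cons))
    return rows


def signatures_to_tsv(rows: Iterable[SignatureRow]) -> str:
    lines = ["label\tkind\tmicrohomology_len\tfiller_seq\thomology_len\tsupport\tn_windows"]
    for r in rows:
        s = r.signature
        lines.append(
            f"{r.label}\t{s.kind}\t{s.microhomology_len}\t{s.filler_seq}"
            f"\t{s.homology_len}\t{r.support}\t{r.n_windows}"
        )
    return "\n".join(lines) + "\n"
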