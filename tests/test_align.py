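import numpy as np
import pytest

from tdnascope.align import (
    AlignParams,
    TargetIndex,
    align_local,
    align_to_index,
    ingest_alignments,
    to_paf_line,
)
from tdnascope.dna import random_dna, revcomp

from oracles import longest_common_substring, smith_waterman_score


def test_identical_sequences_full_alignment(rng):
    t = random_dna(1000, rng)
    alns = align_local(t, t)
    a = alns[0]
    assert (a.read_start, a.read_end) == (0, 1000)
    assert (a.target_start, a.target_end) == (0, 1000)
    assert a.identity == 1.0
    assert a.score == 2000


def test_no_shared_kmer_empty(rng):
    q = random_dna(300, rng)
    t = "ACGT" * 5
    assert align_local(q, t, AlignParams(min_score=100)) == []


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        align_local("", "ACGT" * 10)
    with pytest.raises(ValueError):
        align_local("ACGT" * 10, "")


def test_k_below_8_rejected():
    with pytest.raises(ValueError):
        AlignParams(k=7)


def test_planted_exact_match_interval(rng):
    # oracle: the longest common substring defines the maximal local alignment
    target = random_dna(2000, rng)
    query = random_dna(75, rng) + target[900:1050] + random_dna(75, rng)
    length, qs, ts = longest_common_substring(query, target)
    assert length >= 150
    alns = align_local(query, target)
    best = max(alns, key=lambda a: a.score)
    assert (best.read_start, best.read_end) == (qs, qs + length)
    assert (best.target_start, best.target_end) == (ts, ts + length)
    assert best.identity == 1.0


@pytest.mark.parametrize("seed", range(12))
def test_dp_score_matches_smith_waterman_oracle(seed):
    rng = np.random.default_rng(seed)
    t = random_dna(int(rng.integers(80, 400)), rng)
    lo = int(rng.integers(0, max(1, len(t) - 60)))
    hi = min(len(t), lo + int(rng.integers(40, 200)))
    piece = list(t[lo:hi])
    for i in range(len(piece)):  # ~5% substitutions
        if rng.random() < 0.05:
            piece[i] = "ACGT"[int(rng.integers(0, 4))]
    q = random_dna(20, rng) + "".join(piece) + random_dna(20, rng)
    oracle = smith_waterman_score(t, q)
    alns = align_local(q, t, AlignParams(min_score=20))
    assert alns, "expected an alignment for a planted similar region"
    assert max(a.score for a in alns) == pytest.approx(oracle)


@pytest.mark.parametrize("seed", range(4))
def test_strand_symmetry(seed):
    rng = np.random.default_rng(100 + seed)
    t = random_dna(1500, rng)
    q = random_dna(60, rng) + t[400:900] + random_dna(60, rng)
    fwd = max(align_local(q, t), key=lambda a: a.score)
    rev = max(align_local(revcomp(q), t), key=lambda a: a.score)
    assert fwd.strand != rev.strand
    assert (fwd.target_start, fwd.target_end) == (rev.target_start, rev.target_end)
    assert (fwd.read_start, fwd.read_end) == (
        len(q) - rev.read_end,
        len(q) - rev.read_start,
    )


def test_heuristic_recovers_read_placement(rng):
    genome = random_dna(200_000, rng)
    index = TargetIndex({"chr1": genome}, 15)
    start = 50_000
    read = genome[start : start + 9_000]
    alns = align_to_index("r1", read, index)
    best = max(alns, key=lambda a: a.score)
    assert best.target_id == "chr1"
    assert abs(best.target_start - start) <= 25
    assert abs(best.target_end - (start + 9_000)) <= 25
    assert best.identity > 0.999


def test_heuristic_split_read_two_targets(rng):
    a = random_dna(8_000, rng)
    b = random_dna(8_000, rng)
    read = a[2000:5000] + revcomp(b[1000:4000])
    index = TargetIndex({"A": a, "B": b}, 15)
    alns = align_to_index("r1", read, index)
    by_target = {x.target_id: x for x in alns}
    assert set(by_target) == {"A", "B"}
    assert by_target["A"].strand == "+"
    assert by_target["B"].strand == "-"
    assert abs(by_target["B"].target_start - 1000) <= 25


# ---------------------------------------------------------------------------
# interoperability
# ---------------------------------------------------------------------------


def test_paf_roundtrip(tmp_path, rng):
    t = random_dna(2000, rng)
    q = t[300:1200]
    aln = align_local(q, t)[0]
    path = tmp_path / "a.paf"
    path.write_text(to_paf_line(aln, len(q), len(t)) + "\n")
    back = ingest_alignments(str(path), "PAF")[0]
    assert (back.read_start, back.read_end) == (aln.read_start, aln.read_end)
    assert (back.target_start, back.target_end) == (aln.target_start, aln.target_end)
    assert back.strand == aln.strand


def test_paf_minus_strand_convention(tmp_path):
    line = "r1\t100\t10\t90\t-\tchr1\t5000\t1000\t1080\t80\t80\t60\n"
    path = tmp_path / "a.paf"
    path.write_text(line)
    aln = ingest_alignments(str(path), "PAF")[0]
    assert aln.strand == "-"
    assert (aln.target_start, aln.target_end) == (1000, 1080)  # forward coords
    assert aln.identity == 1.0


def test_paf_malformed_reports_line(tmp_path):
    path = tmp_path / "bad.paf"
    path.write_text("r1\t100\t10\n")
    with pytest.raises(ValueError, match=":1:"):
        ingest_alignments(str(path), "PAF")


def test_paf_empty_file(tmp_path):
    path = tmp_path / "empty.paf"
    path.write_text("")
    assert ingest_alignments(str(path), "PAF") == []


def _write_sam(path, flag, cigar, seq_len=60):
    header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
    seq = "A" * seq_len
    rec = f"r1\t{flag}\tchr1\t101\t60\t{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:2\n"
    path.write_text(header + rec)


def test_sam_soft_clips_excluded(tmp_path):
    from oracles import cigar_read_interval

    path = tmp_path / "a.sam"
    _write_sam(path, 0, "10S40M10S")
    aln = ingest_alignments(str(path), "SAM")[0]
    rs, re, _total = cigar_read_interval([("S", 10), ("M", 40), ("S", 10)], False)
    assert (aln.read_start, aln.read_end) == (rs, re) == (10, 50)
    assert (aln.target_start, aln.target_end) == (100, 140)
    assert aln.identity == pytest.approx((40 - 2) / 40)


def test_sam_reverse_strand_read_coords(tmp_path):
    from oracles import cigar_read_interval

    path = tmp_path / "a.sam"
    _write_sam(path, 16, "5S50M5S")
    aln = ingest_alignments(str(path), "SAM")[0]
    rs, re, _ = cigar_read_interval([("S", 5), ("M", 50), ("S", 5)], True)
    assert (aln.read_start, aln.read_end) == (rs, re)
    assert aln.strand == "-"


def test_sam_unknown_format_rejected():
    with pytest.raises(ValueError):
        ingest_alignments("whatever", "BAM")
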