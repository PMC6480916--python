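import numpy as np
import pytest

from tdnascope.dna import random_dna, revcomp
from tdnascope.signature import (
    JunctionSignature,
    UnanchoredJunctionError,
    classify_junction,
    consensus_window,
)


def _flanks(rng, n=300):
    return random_dna(n, rng), random_dna(n, rng)


def test_blunt(rng):
    left, right = _flanks(rng)
    sig = classify_junction(left, right, left + right)
    assert sig.kind == "blunt"
    assert (sig.microhomology_len, sig.filler_seq, sig.homology_len) == (0, "", 0)


def test_filler_22(rng):
    left, right = _flanks(rng)
    filler = random_dna(22, rng)
    sig = classify_junction(left, right, left + filler + right)
    assert sig.kind == "filler"
    assert sig.filler_seq == filler


def test_long_homology_254(rng):
    block = random_dna(254, rng)
    left = random_dna(200, rng) + block
    right = block + random_dna(200, rng)
    observed = left + right[254:]  # block written once
    sig = classify_junction(left, right, observed)
    assert sig.kind == "long_homology"
    assert sig.homology_len == 254


def test_microhomology_4(rng):
    block = random_dna(4, rng)
    left = random_dna(200, rng) + block
    right = block + random_dna(200, rng)
    sig = classify_junction(left, right, left + right[4:])
    assert sig.kind == "microhomology"
    assert sig.microhomology_len == 4


def test_reverse_complement_observed(rng):
    left, right = _flanks(rng)
    filler = random_dna(5, rng)
    sig = classify_junction(left, right, revcomp(left + filler + right))
    assert sig.kind == "filler"
    assert sig.filler_seq == filler


def test_unanchored_raises(rng):
    left, right = _flanks(rng)
    with pytest.raises(UnanchoredJunctionError):
        classify_junction(left, right, random_dna(800, rng))


def test_short_flanks_rejected(rng):
    with pytest.raises(ValueError):
        classify_junction("ACGT", "ACGT", "ACGTACGT")


def test_blunt_signature_invariant():
    with pytest.raises(ValueError):
        JunctionSignature("blunt", microhomology_len=2)


def test_parameter_recovery_exhaustive():
    """Planted (microhomology, filler) recovered exactly over 200 random junctions."""
    rng = np.random.default_rng(77)
    cases = [(m, f) for m in range(8) for f in (0, 3, 22)]
    count = 0
    while count < 200:
        m, f = cases[count % len(cases)]
        if m > 0 and f > 0:
            count += 1
            continue
        block = random_dna(m, rng)
        left = random_dna(200, rng) + block
        right = block + random_dna(200, rng)
        filler = random_dna(f, rng)
        # avoid degenerate ambiguity: filler edges must not extend a match
        if f and m == 0:
            if filler[0] == right[0] or filler[-1] == left[-1]:
                count += 1
                continue
        if f == 0 and m > 0:
            # planted micro-homology must be maximal by construction
            if left[-m - 1] == right[m] if m < len(right) else False:
                count += 1
                continue
        observed = left + filler + right[m:]
        sig = classify_junction(left, right, observed)
        expected_mh = m if m else 0
        assert sig.microhomology_len == expected_mh, (m, f)
        assert len(sig.filler_seq) == (f if m == 0 else 0), (m, f)
        count += 1


def test_microhomology_maximality(rng):
    """The reported overlap cannot be extended by one base on either side."""
    for _ in range(20):
        m = int(rng.integers(1, 8))
        block = random_dna(m, rng)
        left = random_dna(100, rng) + block
        right = block + random_dna(100, rng)
        sig = classify_junction(left, right, left + right[m:])
        k = sig.microhomology_len
        # maximality: extending the overlap by one base breaks the identity
        assert left[-k:] == right[:k]
        if k < min(len(left), len(right)):
            assert left[-(k + 1):] != right[: k + 1]


def test_consensus_equal_windows_votes_out_errors(rng):
    base = random_dna(1000, rng)
    windows = []
    for i in range(15):
        arr = list(base)
        for pos in rng.integers(0, 1000, size=10):
            arr[pos] = "ACGT"[int(rng.integers(0, 4))]
        windows.append("".join(arr))
    assert consensus_window(windows) == base


def test_consensus_reanchors_shifted_windows(rng):
    base = random_dna(1000, rng)
    windows = [base]
    for shift in (-4, -2, 2, 3, 5):
        w = base[max(0, shift) : 1000 + min(0, shift)]
        windows.append(w)
    cons = consensus_window(windows)
    assert base[8:992] in cons


def test_consensus_trivial():
    assert consensus_window([]) == ""
    assert consensus_window(["ACGT"]) == "ACGT"
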