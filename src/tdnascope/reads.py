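"""Long-read simulation over realized haplotype walks.

Log-normal read lengths, uniform start positions (reads clipped at walk
ends), optional per-base substitution/insertion/deletion errors, fixed
phred-33 quality. Every read is logged with its true origin (walk, interval,
strand) so downstream stages can be scored against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from .align import LocalAlignment
from .dna import decode, encode
from .simulate import Walk

_CHUNK = 512


@dataclass(frozen=True)
class ReadSimParams:
    mean_depth: float = 30.0
    read_mean: int = 12_000
    read_sd: int = 5_000
    read_min: int = 500
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.read_min <= 0 or self.read_mean < self.read_min:
            raise ValueError("invalid read length parameters")
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= rate <= 0.2):
                raise ValueError("error rates must be in [0, 0.2]")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @property
    def quality_char(self) -> str:
        if self.total_error <= 0:
            return "I"  # Q40
        q = min(40, int(round(-10 * math.log10(self.total_error))))
        return chr(33 + q)


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    walk: str
    start: int
    end: int
    strand: str


def _mutate(codes: np.ndarray, params: ReadSimParams, rng: np.random.Generator) -> np.ndarray:
    n = len(codes)
    if params.sub_rate > 0:
        mask = rng.random(n) < params.sub_rate
        k = int(mask.sum())
        if k:
            codes = codes.copy()
            codes[mask] = (codes[mask] + rng.integers(1, 4, k)) % 4
    if params.del_rate > 0 or params.ins_rate > 0:
        keep = (
            rng.random(n) >= params.del_rate
            if params.del_rate > 0
            else np.ones(n, dtype=bool)
        )
        ins = (
            rng.random(n) < params.ins_rate
            if params.ins_rate > 0
            else np.zeros(n, dtype=bool)
        )
        counts = keep.astype(np.int64) + ins
        out = np.repeat(codes, counts)
        if ins.any():
            cum = np.cumsum(counts)
            idx = cum[ins] - 1
            out = out.copy()
            out[idx] = rng.integers(0, 4, len(idx))
        return out
    return codes


def simulate_reads(
    walks: Sequence[Walk] | Sequence[tuple[str, str]],
    params: ReadSimParams,
    fastq: TextIO,
    origin: TextIO | None = None,
) -> list[ReadOrigin]:
    """Write simulated reads as FASTQ; return (and optionally write) origins.

    Deterministic for a fixed seed. Expected coverage of every walk position
    approaches ``mean_depth``; reads are clipped at walk boundaries.
    """
    named: list[tuple[str, str]] = [
        (w.name, w.sequence) if isinstance(w, Walk) else (w[0], w[1]) for w in walks
    ]
    if not named or any(not seq for _, seq in named):
        raise ValueError("genome must contain non-empty sequences")
    rng = np.random.default_rng(params.seed)
    sigma2 = math.log(1.0 + (params.read_sd / params.read_mean) ** 2)
    mu = math.log(params.read_mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)
    qc = params.quality_char

    origins: list[ReadOrigin] = []
    if origin is not None:
        origin.write("read_id\twalk\tstart\tend\tstrand\n")
    counter = 0
    for wname, seq in named:
        L = len(seq)
        codes_full = encode(seq)
        target = params.mean_depth * L
        emitted = 0.0
        while emitted < target:
            lens = np.exp(rng.normal(mu, sigma, _CHUNK))
            lens = np.clip(lens.astype(np.int64), params.read_min, None)
            min_eff = min(params.read_min, L)
            starts = rng.integers(-(lens - min_eff), L - min_eff + 1)
            strands = rng.random(_CHUNK) < 0.5
            for ln, st, rev in zip(lens.tolist(), starts.tolist(), strands.tolist()):
                a = max(0, st)
                b = min(L, st + ln)
                if b - a < min_eff:
                    continue
                codes = codes_full[a:b]
                if rev:
                    codes = (3 - codes)[::-1]
                codes = _mutate(codes, params, rng)
                rid = f"read_{counter:07d}"
                counter += 1
                fastq.write(f"@{rid}\n{decode(codes)}\n+\n{qc * len(codes)}\n")
                rec = ReadOrigin(rid, wname, a, b, "-" if rev else "+")
                origins.append(rec)
                if origin is not None:
                    origin.write(f"{rid}\t{wname}\t{a}\t{b}\t{'-' if rev else '+'}\n")
                emitted += b - a
                if emitted >= target:
                    break
    return origins


def read_origin_log(path: str) -> list[ReadOrigin]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, walk, start, end, strand = line.rstrip("\n").split("\t")
            out.append(ReadOrigin(rid, walk, int(start), int(end), strand))
    return out


def project_origins(
    walks: Iterable[Walk], origins: Iterable[ReadOrigin]
) -> list[LocalAlignment]:
    """Project true read placements through walk blocks onto source coordinates.

    Produces ideal (error-free placement) alignments — the origin-log oracle
    for coverage and recall checks, independent of the aligner.
    """
    by_name = {w.name: w for w in walks}
    out: list[LocalAlignment] = []
    for o in origins:
        walk = by_name[o.walk]
        for blk in walk.blocks:
            lo = max(o.start, blk.walk_start)
            hi = min(o.end, blk.walk_end)
            if hi <= lo:
                continue
            skip = (blk.end - blk.start) - (blk.walk_end - blk.walk_start)
            if not blk.flipped:
                ts = blk.start + skip + (lo - blk.walk_start)
                te = blk.start + skip + (hi - blk.walk_start)
                strand = "+"
            else:
                te = blk.end - skip - (lo - blk.walk_start)
                ts = blk.end - skip - (hi - blk.walk_start)
                strand = "-"
            if o.strand == "-":
                strand = "-" if strand == "+" else "+"
            out.append(
                LocalAlignment(
                    read_id=o.read_id,
                    read_start=lo - o.start,
                    read_end=hi - o.start,
                    target_id=blk.source,
                    target_start=ts,
                    target_end=te,
                    strand=strand,
                    identity=1.0,
                    score=float(2 * (hi - lo)),
                )
            )
    return out
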