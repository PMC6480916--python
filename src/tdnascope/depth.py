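"""Binned depth profiles and depth-ratio loss calling (heterozygous vs
homozygous) of a mutant sample against a control."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import LocalAlignment


@dataclass(frozen=True)
class DepthParams:
    bin_size: int = 1000
    het_band: tuple[float, float] = (0.35, 0.65)
    hom_max: float = 0.1
    min_event_bins: int = 5
    #: het excursions are only significant over roughly a read length of bins
    het_min_event_bins: int = 12
    #: same-zygosity runs separated by this many unclassified bins are bridged
    merge_gap_bins: int = 3
    min_control_depth: float = 10.0
    smooth_bins: int = 5  # centered moving average applied to the ratio track


@dataclass
class DepthProfile:
    bin_size: int
    bins: dict[str, np.ndarray]  # per-chromosome mean depth per bin
    total_mapped_bases: int = 0

    def chrom_mean(self, chrom: str) -> float:
        return float(self.bins[chrom].mean())

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        b0 = start // self.bin_size
        b1 = max(b0 + 1, -(-end // self.bin_size))
        return float(self.bins[chrom][b0:b1].mean())


@dataclass(frozen=True)
class LossCall:
    chrom: str
    start: int
    end: int
    zygosity: str  # heterozygous | homozygous
    mutant_depth: float
    control_depth: float
    ratio: float


def compute_depth(
    alignments: Iterable[LocalAlignment],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1000,
) -> DepthProfile:
    """Aligned-base depth per bin: overlapping bases / bin width."""
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100")
    per_base = {c: np.zeros(l, dtype=np.float64) for c, l in chrom_lengths.items()}
    total = 0
    for aln in alignments:
        track = per_base.get(aln.target_id)
        if track is None:
            continue
        a = max(0, aln.target_start)
        b = min(len(track), aln.target_end)
        if b > a:
            track[a:b] += 1.0
            total += b - a
    bins: dict[str, np.ndarray] = {}
    for chrom, track in per_base.items():
        n_bins = -(-len(track) // bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[: len(track)] = track
        bins[chrom] = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    return DepthProfile(bin_size, bins, total)


def call_losses(
    mutant: DepthProfile,
    control: DepthProfile,
    params: DepthParams | None = None,
) -> list[LossCall]:
    """Depth-ratio loss calls: runs of >= ``min_event_bins`` bins with
    mutant/control ratio in the heterozygous band or below ``hom_max``.

    Bins with control depth below ``min_control_depth`` are masked and break
    runs; adjacent same-zygosity runs are merged.
    """
    params = params or DepthParams(bin_size=mutant.bin_size)
    if mutant.bin_size != control.bin_size or set(mutant.bins) != set(control.bins):
        raise ValueError("profiles must share binning and chromosomes")
    calls: list[LossCall] = []
    lo, hi = params.het_band
    for chrom in mutant.bins:
        m = mutant.bins[chrom]
        c = control.bins[chrom]
        n = min(len(m), len(c))
        m, c = m[:n], c[:n]
        valid = c >= params.min_control_depth
        raw = np.divide(m, c, out=np.full(n, np.nan), where=valid)
        # homozygous absence is essentially noise-free: use the raw ratio;
        # the heterozygous band needs smoothing against coverage noise
        ratio = _smooth(raw, params.smooth_bins)
        valid &= ~np.isnan(ratio)
        state = np.zeros(n, dtype=np.int8)  # 0 none, 1 het, 2 hom, -1 masked
        state[~valid] = -1
        state[valid & (ratio >= lo) & (ratio <= hi)] = 1
        state[valid & (raw <= params.hom_max)] = 2
        runs = _runs(state)
        merged = _merge_runs(
            runs, params.min_event_bins, params.het_min_event_bins, params.merge_gap_bins
        )
        for zyg_code, b0, b1 in merged:
            start = b0 * mutant.bin_size
            end = b1 * mutant.bin_size
            md = float(m[b0:b1].mean())
            cd = float(c[b0:b1].mean())
            calls.append(
                LossCall(
                    chrom,
                    start,
                    end,
                    "heterozygous" if zyg_code == 1 else "homozygous",
                    md,
                    cd,
                    md / cd if cd else float("nan"),
                )
            )
    calls.sort(key=lambda x: (x.chrom, x.start))
    return calls


def _smooth(ratio: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centered moving average."""
    if window <= 1 or len(ratio) == 0:
        return ratio
    half = window // 2
    out = np.full_like(ratio, np.nan)
    finite = np.isfinite(ratio)
    vals = np.where(finite, ratio, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    n = len(ratio)
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
    return out


def _runs(state: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    i = 0
    n = len(state)
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        out.append((int(state[i]), i, j))
        i = j
    return out


def _merge_runs(
    runs: list[tuple[int, int, int]],
    min_event_bins: int,
    het_min_event_bins: int,
    merge_gap_bins: int,
) -> list[tuple[int, int, int]]:
    # bridge same-zygosity runs across short unclassified ('none') gaps first,
    # then apply the per-zygosity minimum length
    classified = [(s, a, b) for s, a, b in runs if s in (1, 2)]
    gaps_ok: dict[tuple[int, int], bool] = {}
    for s, a, b in runs:
        if s == 0 and b - a <= merge_gap_bins:
            gaps_ok[(a, b)] = True
    merged: list[tuple[int, int, int]] = []
    for s, a, b in classified:
        if merged and merged[-1][0] == s and (
            merged[-1][2] == a or gaps_ok.get((merged[-1][2], a), False)
        ):
            merged[-1] = (s, merged[-1][1], b)
        else:
            merged.append((s, a, b))
    out = []
    for s, a, b in merged:
        need = het_min_event_bins if s == 1 else min_event_bins
        if b - a >= need:
            out.append((s, a, b))
    return out


def depth_to_tsv(profile: DepthProfile) -> str:
    lines = ["chrom\tbin_start\tdepth"]
    for chrom in profile.bins:
        for i, d in enumerate(profile.bins[chrom]):
            lines.append(f"{chrom}\t{i * profile.bin_size}\t{d:.4f}")
    return "\n".join(lines) + "\n"


def ratio_bedgraph(mutant: DepthProfile, control: DepthProfile) -> str:
    lines = []
    for chrom in mutant.bins:
        m, c = mutant.bins[chrom], control.bins[chrom]
        for i in range(min(len(m), len(c))):
            if c[i] > 0:
                lines.append(
                    f"{chrom}\t{i * mutant.bin_size}\t{(i + 1) * mutant.bin_size}"
                    f"\t{m[i] / c[i]:.4f}"
                )
    return "\n".join(lines) + "\n"


def calls_to_bed(calls: Sequence[LossCall]) -> str:
    lines = []
    for call in calls:
        lines.append(
            f"{call.chrom}\t{call.start}\t{call.end}\t{call.zygosity}"
            f"\t{call.ratio:.3f}"
        )
    return "\n".join(lines) + "\n"
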