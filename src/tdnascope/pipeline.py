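"""End-to-end orchestration: simulate -> align -> segment -> junctions ->
signatures -> depth, with reproducible on-disk intermediates and a
machine-readable rearrangement report."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO

from . import __version__
from .align import (
    AlignParams,
    LocalAlignment,
    TargetIndex,
    align_to_index,
    ingest_alignments,
    write_paf,
)
from .depth import (
    DepthParams,
    DepthProfile,
    LossCall,
    call_losses,
    calls_to_bed,
    compute_depth,
    depth_to_tsv,
    ratio_bedgraph,
)
from .junctions import (
    ConcatemerArchitecture,
    FragmentGraph,
    IntegrationEvent,
    Junction,
    JunctionParams,
    build_fragment_graph,
    call_breakpoints,
    classify_events,
    concatemer_length,
    insertion_loci,
    reconstruct_architectures,
)
from .segment import SegmentParams, classify_reads, segment_read, segments_to_tsv
from .signature import SignatureParams, SignatureRow, signature_table, signatures_to_tsv
from .simulate import (
    JunctionSide,
    ReferenceGenome,
    TruthSet,
    VectorAnnotation,
    VECTOR_SOURCE,
)


@dataclass
class PipelineParams:
    align: AlignParams = field(default_factory=AlignParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    signature: SignatureParams = field(default_factory=SignatureParams)
    depth: DepthParams = field(default_factory=DepthParams)


@dataclass
class PipelineConfig:
    reads: str
    reference: str
    vector: str
    out: str
    control_reads: str | None = None
    alignments: str | None = None  # optional pre-computed PAF/SAM
    alignments_format: str = "PAF"
    lb_interval: tuple[int, int] = (10509, 10524)
    rb_interval: tuple[int, int] = (2454, 2478)
    tdna_span: tuple[int, int] = (2454, 10524)
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for path in (self.reads, self.reference, self.vector):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.control_reads and not os.path.exists(self.control_reads):
            raise FileNotFoundError(self.control_reads)
        if self.alignments and not os.path.exists(self.alignments):
            raise FileNotFoundError(self.alignments)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = raw.pop("params", {}) or {}
        pp = PipelineParams(
            align=AlignParams(**params.get("align", {})),
            segment=SegmentParams(**params.get("segment", {})),
            junction=JunctionParams(**params.get("junction", {})),
            signature=SignatureParams(**params.get("signature", {})),
            depth=DepthParams(**params.get("depth", {})),
        )
        for key in ("lb_interval", "rb_interval", "tdna_span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(params=pp, **raw)


@dataclass
class RearrangementReport:
    config_digest: str
    version: str
    insertion_loci: list[tuple[str, int]]
    junctions: list[dict]
    architectures: list[dict]
    events: list[dict]
    signatures: list[dict]
    losses: list[dict]
    graph: dict
    timings: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_fastx(path: str) -> dict[str, str]:
    fmt = "fastq" if path.endswith((".fq", ".fastq")) else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, fmt)}


def write_fasta(path: str, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _side_dict(side: JunctionSide | None) -> dict | None:
    if side is None:
        return None
    # report coordinates 1-based (position of the last/first retained base)
    coord1 = side.coord if side.direction == "left" else side.coord + 1
    return {
        "source": side.source,
        "coord0": side.coord,
        "coord1": coord1,
        "direction": side.direction,
    }


def junctions_to_bedpe(junctions: Iterable[Junction]) -> str:
    lines = []
    for j in junctions:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    j.side_a.source, max(0, j.side_a.coord - 1), j.side_a.coord + 1,
                    j.side_b.source, max(0, j.side_b.coord - 1), j.side_b.coord + 1,
                    j.label, j.support,
                    "+" if j.side_a.direction == "left" else "-",
                    "+" if j.side_b.direction == "left" else "-",
                )
            )
        )
    return "\n".join(lines) + "\n"


def junctions_to_tsv(junctions: Iterable[Junction]) -> str:
    lines = ["label\tsource_a\tcoord_a\tdir_a\tsource_b\tcoord_b\tdir_b\tcategory\tsupport"]
    for j in junctions:
        lines.append(
            f"{j.label}\t{j.side_a.source}\t{j.side_a.coord}\t{j.side_a.direction}"
            f"\t{j.side_b.source}\t{j.side_b.coord}\t{j.side_b.direction}"
            f"\t{j.category}\t{j.support}"
        )
    return "\n".join(lines) + "\n"


def graph_to_dot(graph: FragmentGraph) -> str:
    lines = ["graph fragments {"]
    for node in graph.nodes:
        attrs = f'label="{node.name}\\n{node.start}-{node.end}"'
        if node.name in graph.lost_nodes:
            attrs += ' style=dashed color=gray'
        lines.append(f'  "{node.name}" [{attrs}];')
    for edge in graph.edges:
        style = "bold" if edge.kind == "vector" else "dotted"
        lines.append(
            f'  "{edge.node_a}" -- "{edge.node_b}" [style={style} label="{edge.kind}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> RearrangementReport:
    """Run every stage on the configured inputs; write all intermediates."""
    config.validate()
    os.makedirs(config.out, exist_ok=True)
    params = config.params
    timings: dict[str, float] = {}
    digest = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    t0 = time.time()
    reference = ReferenceGenome(
        [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(config.reference, "fasta")]
    )
    vector_seq = next(SeqIO.parse(config.vector, "fasta"))
    vector = VectorAnnotation(
        str(vector_seq.seq).upper(),
        config.lb_interval,
        config.rb_interval,
        config.tdna_span,
    )
    reads = load_fastx(config.reads)
    timings["load"] = time.time() - t0

    targets = reference.as_dict()
    targets[VECTOR_SOURCE] = vector.sequence

    t0 = time.time()
    if config.alignments:
        alignments = ingest_alignments(config.alignments, config.alignments_format)
    else:
        alignments = align_reads(reads, targets, params.align)
    timings["align"] = time.time() - t0
    target_lengths = {n: len(s) for n, s in targets.items()}
    write_paf(
        alignments,
        os.path.join(config.out, "alignments.paf"),
        {r: len(s) for r, s in reads.items()},
        target_lengths,
    )

    t0 = time.time()
    by_read: dict[str, list[LocalAlignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    segmented = [
        segment_read(rid, len(reads[rid]), by_read.get(rid, []), params.segment)
        for rid in sorted(reads)
    ]
    vector_ids, _pass = classify_reads(reads.keys(), alignments, params.segment)
    timings["segment"] = time.time() - t0
    with open(os.path.join(config.out, "segments.tsv"), "w") as fh:
        fh.write(segments_to_tsv(sr for sr in segmented if len(sr.segments) > 1))

    t0 = time.time()
    junctions = call_breakpoints(segmented, params.junction)
    architectures = reconstruct_architectures(junctions, segmented)
    timings["junctions"] = time.time() - t0

    t0 = time.time()
    rows = signature_table(junctions, reference, vector, reads, params.signature)
    timings["signatures"] = time.time() - t0

    t0 = time.time()
    chrom_lengths = {n: reference.length(n) for n in reference.names}
    mutant_depth = compute_depth(alignments, chrom_lengths, params.depth.bin_size)
    losses: list[LossCall] = []
    control_depth = None
    if config.control_reads:
        control_reads = load_fastx(config.control_reads)
        control_alns = align_reads(control_reads, targets, params.align)
        control_depth = compute_depth(control_alns, chrom_lengths, params.depth.bin_size)
        losses = call_losses(mutant_depth, control_depth, params.depth)
    timings["depth"] = time.time() - t0

    graph = build_fragment_graph(
        junctions,
        reference,
        architectures,
        [(c.chrom, c.start, c.end, c.zygosity) for c in losses],
        params.junction.gap_tol,
    )
    events = classify_events(graph, architectures, junctions, params.junction.gap_tol)

    _write_text(config.out, "junctions.tsv", junctions_to_tsv(junctions))
    _write_text(config.out, "junctions.bedpe", junctions_to_bedpe(junctions))
    _write_text(config.out, "signatures.tsv", signatures_to_tsv(rows))
    _write_text(config.out, "depth_mutant.tsv", depth_to_tsv(mutant_depth))
    if control_depth is not None:
        _write_text(config.out, "depth_control.tsv", depth_to_tsv(control_depth))
        _write_text(config.out, "ratio.bedgraph", ratio_bedgraph(mutant_depth, control_depth))
        _write_text(config.out, "losses.bed", calls_to_bed(losses))
    _write_text(config.out, "fragment_graph.dot", graph_to_dot(graph))

    report = RearrangementReport(
        config_digest=digest,
        version=__version__,
        insertion_loci=insertion_loci(junctions, params.junction.gap_tol),
        junctions=[
            {
                "label": j.label,
                "side_a": _side_dict(j.side_a),
                "side_b": _side_dict(j.side_b),
                "category": j.category,
                "support": j.support,
            }
            for j in junctions
        ],
        architectures=[
            {
                "locus_left": _side_dict(a.locus_left),
                "locus_right": _side_dict(a.locus_right),
                "fragments": [(f.start, f.end) for f in a.fragments],
                "tract_length": concatemer_length(a.fragments),
                "ambiguous": a.ambiguous,
                "notes": a.notes,
            }
            for a in architectures
        ],
        events=[
            {
                "case": e.case,
                "loci": [
                    _side_dict(s)
                    for s in (
                        (e.architecture.locus_left, e.architecture.locus_right)
                        if e.architecture
                        else (e.junction.side_a, e.junction.side_b)
                    )
                    if s is not None
                ],
                "n_fragments": len(e.architecture.fragments) if e.architecture else 0,
                "notes": e.notes,
            }
            for e in events
        ],
        signatures=[
            {
                "label": r.label,
                "kind": r.signature.kind,
                "microhomology_len": r.signature.microhomology_len,
                "filler_len": len(r.signature.filler_seq),
                "filler_seq": r.signature.filler_seq,
                "homology_len": r.signature.homology_len,
                "support": r.support,
            }
            for r in rows
        ],
        losses=[asdict(c) for c in losses],
        graph={
            "nodes": [asdict(n) for n in graph.nodes],
            "edges": [asdict(e) for e in graph.edges],
            "lost_nodes": graph.lost_nodes,
        },
        timings=timings,
    )
    _write_text(config.out, "report.json", report.to_json())
    _write_text(config.out, "report.txt", _text_summary(report))
    return report


def align_reads(
    reads: Mapping[str, str], targets: Mapping[str, str], params: AlignParams
) -> list[LocalAlignment]:
    index = TargetIndex(targets, params.k)
    out: list[LocalAlignment] = []
    for rid in sorted(reads):
        out.extend(align_to_index(rid, reads[rid], index, params))
    return out


def _write_text(out_dir: str, name: str, text: str) -> None:
    with open(os.path.join(out_dir, name), "w") as fh:
        fh.write(text)


def _text_summary(report: RearrangementReport) -> str:
    lines = [
        f"tdnascope {report.version} report (config {report.config_digest})",
        "",
        f"insertion loci ({len(report.insertion_loci)}):",
    ]
    for chrom, pos in report.insertion_loci:
        lines.append(f"  {chrom}:{pos + 1}")
    lines.append("")
    lines.append(f"junctions ({len(report.junctions)}):")
    for j in report.junctions:
        a, b = j["side_a"], j["side_b"]
        lines.append(
            f"  {j['label']}: {a['source']}:{a['coord1']}({a['direction']})"
            f" ~ {b['source']}:{b['coord1']}({b['direction']})"
            f" [{j['category']}, support {j['support']}]"
        )
    lines.append("")
    lines.append(f"architectures ({len(report.architectures)}):")
    for a in report.architectures:
        frag_text = ", ".join(f"{s}..{e}" for s, e in a["fragments"])
        lines.append(
            f"  {len(a['fragments'])} fragment(s), tract {a['tract_length']} bp: {frag_text}"
        )
    lines.append("")
    lines.append("events:")
    for e in report.events:
        lines.append(f"  {e['case']} ({e['n_fragments']} fragments) {e['notes']}")
    lines.append("")
    lines.append(f"loss calls ({len(report.losses)}):")
    for c in report.losses:
        lines.append(
            f"  {c['chrom']}:{c['start']}-{c['end']} {c['zygosity']}"
            f" ratio {c['ratio']:.3f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scoring against a truth set
# ---------------------------------------------------------------------------


def compare_to_truth(
    report: RearrangementReport, truth: TruthSet, tol: int = 20
) -> dict:
    """Junction precision/recall + architecture and loss recovery scorecard.

    A called junction matches a planted one when sources and directions agree
    and both coordinates are within ``tol`` (merged homology/micro-homology
    at a junction relaxes its tolerance by half the merged length, the
    inherent placement ambiguity of a shared block).
    """
    called = [(j["side_a"], j["side_b"]) for j in report.junctions]
    matched_truth = set()
    matched_called = set()
    coord_errors = []
    for ti, tj in enumerate(truth.junctions):
        t_tol = tol + (tj.signature.merge_len + 1) // 2
        for ci, (ca, cb) in enumerate(called):
            if ci in matched_called:
                continue
            if _side_match(tj.side_a, ca, t_tol) and _side_match(tj.side_b, cb, t_tol):
                matched_truth.add(ti)
                matched_called.add(ci)
                coord_errors.append(
                    abs(tj.side_a.coord - ca["coord0"]) + abs(tj.side_b.coord - cb["coord0"])
                )
                break
    recall = len(matched_truth) / len(truth.junctions) if truth.junctions else 1.0
    precision = len(matched_called) / len(called) if called else 1.0

    truth_archs = _truth_architectures(truth)
    called_archs = {tuple(map(tuple, a["fragments"])) for a in report.architectures}
    arch_exact = []
    for fr in truth_archs:
        flipped = tuple((e, s) for s, e in reversed(fr))
        arch_exact.append(tuple(fr) in called_archs or flipped in called_archs)

    loss_scores = []
    for chrom, start, end, zyg in truth.losses:
        best = 0.0
        for c in report.losses:
            if c["chrom"] != chrom or c["zygosity"] != zyg:
                continue
            inter = min(end, c["end"]) - max(start, c["start"])
            union = max(end, c["end"]) - min(start, c["start"])
            if union > 0:
                best = max(best, inter / union)
        loss_scores.append({"chrom": chrom, "start": start, "end": end,
                            "zygosity": zyg, "overlap": best})

    return {
        "junction_precision": precision,
        "junction_recall": recall,
        "mean_coord_error": float(np.mean(coord_errors)) if coord_errors else float("nan"),
        "architecture_exact": arch_exact,
        "loss_overlap": loss_scores,
    }


def _side_match(side: JunctionSide, called: dict, tol: int) -> bool:
    return (
        called["source"] == side.source
        and called["direction"] == side.direction
        and abs(called["coord0"] - side.coord) <= tol
    )


def _truth_architectures(truth: TruthSet) -> list[list[tuple[int, int]]]:
    """Planted fragment lists (in canonical left-to-right orientation)."""
    out = []
    for walk in truth.walks:
        frags = [
            (b.fragment.start, b.fragment.end) for b in walk.blocks if b.fragment is not None
        ]
        if frags:
            out.append(frags)
    return out
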