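"""Coordinate-preserving variation graph built from a reference plus an
INS/DEL catalog, serialized as GFA 1.0.

The reference of each chromosome is split at every SV breakpoint into
segment nodes that tile it without overlap, so linear coordinates remain
recoverable from the node metadata. A DEL contributes an edge bypassing the
deleted segment(s); an INS contributes an alternate node spliced in after
its anchor POS. One path is written per chromosome (the reference spelling)
plus one per haplotype traversing the alternate branch of every SV it
carries. Inversions and translocations are not modeled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .models import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Node:
    id: int
    seq: str
    chrom: str
    #: 1-based inclusive reference span for reference segments; None for
    #: inserted-allele nodes.
    start: int | None = None
    end: int | None = None

    @property
    def is_reference(self) -> bool:
        return self.start is not None


@dataclass
class VariationGraph:
    nodes: dict[int, Node] = field(default_factory=dict)
    edges: list[tuple[int, int]] = field(default_factory=list)
    paths: dict[str, list[int]] = field(default_factory=dict)

    def spell(self, path_name: str) -> str:
        return "".join(self.nodes[n].seq for n in self.paths[path_name])

    def validate(self, ref_seqs: Mapping[str, str] | None = None) -> None:
        node_ids = set(self.nodes)
        for a, b in self.edges:
            if a not in node_ids or b not in node_ids:
                raise ValidationError(f"edge ({a},{b}) references missing node")
        for name, path in self.paths.items():
            for n in path:
                if n not in node_ids:
                    raise ValidationError(f"path {name} references missing node {n}")
        if ref_seqs is not None:
            for chrom, seq in ref_seqs.items():
                if chrom not in self.paths:
                    raise ValidationError(f"missing reference path for {chrom}")
                if self.spell(chrom) != seq:
                    raise ValidationError(
                        f"reference path for {chrom} does not spell the input sequence"
                    )

    def reference_tiling(self, chrom: str) -> list[tuple[int, int]]:
        return [
            (self.nodes[n].start, self.nodes[n].end)
            for n in self.paths[chrom]
            if self.nodes[n].is_reference
        ]


def _check_haplotype_conflicts(hap: str, carried: Sequence) -> None:
    """Reject overlapping carried intervals: DEL/DEL overlap, INS inside a
    carried DEL, or two INS at the same anchor."""
    dels = sorted(
        (sv for sv in carried if sv.svtype == "DEL"), key=lambda s: s.pos
    )
    for a, b in zip(dels, dels[1:]):
        if b.pos <= a.pos + a.length - 1:
            raise ValidationError(
                f"haplotype {hap} carries overlapping deletions "
                f"{a.id} and {b.id} on {a.chrom}"
            )
    ins_pos: set[int] = set()
    for sv in carried:
        if sv.svtype != "INS":
            continue
        if sv.pos in ins_pos:
            raise ValidationError(
                f"haplotype {hap} carries two insertions anchored at "
                f"{sv.chrom}:{sv.pos}"
            )
        ins_pos.add(sv.pos)
        for d in dels:
            if d.pos <= sv.pos <= d.pos + d.length - 1:
                raise ValidationError(
                    f"haplotype {hap} carries insertion {sv.id} inside "
                    f"deletion {d.id}"
                )


def build_graph(
    ref_seqs: Mapping[str, str],
    catalog: Sequence,
    haplotypes: Sequence[str],
) -> VariationGraph:
    """Build the variation graph from reference sequences and a catalog of
    INS/DEL entries with carrier sets (INV/TRA entries are skipped with a
    log message).

    Node numbering is stable: by chromosome, then coordinate, with inserted
    alleles right after their left flanking segment.
    """
    entries = []
    for sv in catalog:
        if sv.svtype not in ("INS", "DEL"):
            logger.info("graph: skipping %s entry %s", sv.svtype, sv.id)
            continue
        if sv.chrom not in ref_seqs:
            raise ValidationError(f"{sv.id}: unknown chromosome {sv.chrom}")
        if sv.svtype == "INS" and not sv.alt_seq:
            raise ValidationError(f"insertion {sv.id} lacks an alternate sequence")
        if sv.svtype == "INS" and len(sv.alt_seq) != sv.length:
            raise ValidationError(f"insertion {sv.id}: alt_seq length != SV length")
        if sv.svtype == "DEL" and sv.pos + sv.length - 1 > len(ref_seqs[sv.chrom]):
            raise ValidationError(f"deletion {sv.id} extends past {sv.chrom} end")
        entries.append(sv)

    # Global overlapping-deletion check keeps the segmentation unambiguous.
    by_chrom: dict[str, list] = {c: [] for c in ref_seqs}
    for sv in entries:
        by_chrom[sv.chrom].append(sv)
    for chrom, svs in by_chrom.items():
        dels = sorted((s for s in svs if s.svtype == "DEL"), key=lambda s: s.pos)
        for a, b in zip(dels, dels[1:]):
            if b.pos <= a.pos + a.length - 1:
                raise ValidationError(
                    f"overlapping deletions {a.id} and {b.id} on {chrom}"
                )

    graph = VariationGraph()
    next_id = 1
    # per chrom bookkeeping for path construction
    segments_by_chrom: dict[str, list[Node]] = {}
    ins_nodes: dict[tuple[str, int, str], Node] = {}  # (chrom, pos, sv_id) -> node

    for chrom in sorted(ref_seqs):
        seq = ref_seqs[chrom]
        length = len(seq)
        cuts: set[int] = {1, length + 1}  # segment start positions
        for sv in by_chrom[chrom]:
            if sv.svtype == "DEL":
                cuts.add(sv.pos)
                cuts.add(sv.pos + sv.length)
            else:
                cuts.add(sv.pos + 1)
        bounds = sorted(p for p in cuts if 1 <= p <= length + 1)
        ins_by_anchor: dict[int, list] = {}
        for sv in by_chrom[chrom]:
            if sv.svtype == "INS":
                ins_by_anchor.setdefault(sv.pos, []).append(sv)
        segments: list[Node] = []
        for s, e_next in zip(bounds, bounds[1:]):
            node = Node(next_id, seq[s - 1 : e_next - 1], chrom, s, e_next - 1)
            next_id += 1
            graph.nodes[node.id] = node
            segments.append(node)
            for sv in sorted(ins_by_anchor.get(e_next - 1, []), key=lambda s: s.id):
                alt = Node(next_id, sv.alt_seq, chrom)
                next_id += 1
                graph.nodes[alt.id] = alt
                ins_nodes[(chrom, sv.pos, sv.id)] = alt
        segments_by_chrom[chrom] = segments

        seg_by_start = {n.start: n for n in segments}
        seg_by_end = {n.end: n for n in segments}
        for a, b in zip(segments, segments[1:]):
            graph.edges.append((a.id, b.id))
        for sv in sorted(by_chrom[chrom], key=lambda s: (s.pos, s.id)):
            if sv.svtype == "DEL":
                left = seg_by_end.get(sv.pos - 1)
                right = seg_by_start.get(sv.pos + sv.length)
                if left is not None and right is not None:
                    graph.edges.append((left.id, right.id))
            else:
                alt = ins_nodes[(chrom, sv.pos, sv.id)]
                left = seg_by_end.get(sv.pos)
                right = seg_by_start.get(sv.pos + 1)
                if left is not None:
                    graph.edges.append((left.id, alt.id))
                if right is not None:
                    graph.edges.append((alt.id, right.id))
        graph.paths[chrom] = [n.id for n in segments]

    # haplotype paths: alternate branch for every carried SV, reference
    # elsewhere; chromosomes concatenated in sorted order.
    for hap in haplotypes:
        path: list[int] = []
        for chrom in sorted(ref_seqs):
            carried = [sv for sv in by_chrom[chrom] if hap in sv.carriers]
            _check_haplotype_conflicts(hap, carried)
            del_ivs = [
                (sv.pos, sv.pos + sv.length - 1)
                for sv in carried
                if sv.svtype == "DEL"
            ]
            ins_at = {
                sv.pos: ins_nodes[(chrom, sv.pos, sv.id)]
                for sv in carried
                if sv.svtype == "INS"
            }
            for node in segments_by_chrom[chrom]:
                deleted = any(s <= node.start <= e for s, e in del_ivs)
                if not deleted:
                    path.append(node.id)
                if node.end in ins_at:
                    path.append(ins_at[node.end].id)
        graph.paths[hap] = path
    return graph


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_gfa(graph: VariationGraph, path) -> None:
    """Serialize as GFA 1.0: S-lines with sequences (reference segments tag
    their origin with SN/SO), L-lines with 0M overlaps, P-lines per path."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for node_id in sorted(graph.nodes):
            node = graph.nodes[node_id]
            tags = ""
            if node.is_reference:
                tags = f"\tSN:Z:{node.chrom}\tSO:i:{node.start - 1}"
            fh.write(f"S\t{node.id}\t{node.seq}{tags}\n")
        for a, b in graph.edges:
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\n")
        for name, path_nodes in graph.paths.items():
            walk = ",".join(f"{n}+" for n in path_nodes)
            fh.write(f"P\t{name}\t{walk}\t*\n")


def read_gfa(path) -> VariationGraph:
    """Parse a GFA 1.0 file written by :func:`write_gfa`."""
    graph = VariationGraph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                node_id, seq = int(parts[1]), parts[2]
                chrom, start = "", None
                for tag in parts[3:]:
                    if tag.startswith("SN:Z:"):
                        chrom = tag[5:]
                    elif tag.startswith("SO:i:"):
                        start = int(tag[5:]) + 1
                end = start + len(seq) - 1 if start is not None else None
                graph.nodes[node_id] = Node(node_id, seq, chrom, start, end)
            elif parts[0] == "L":
                graph.edges.append((int(parts[1]), int(parts[3])))
            elif parts[0] == "P":
                graph.paths[parts[1]] = [
                    int(step.rstrip("+-")) for step in parts[2].split(",") if step
                ]
    return graph
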