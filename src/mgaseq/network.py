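"""Amplicon structure assembly and the oncogene coamplification network.

Focally amplified regions become segments; split-read breakpoints landing
at segment boundaries become junction edges; walking junctions end-to-end
reconstructs the amplicon's repeating unit (linear, circular, or
head-to-tail tandem). Independently, every junction-joined segment pair is
an edge of the coamplification network, weighted by normalized chromatin
contact strength between the two regions.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .contacts import ContactMatrix
from .genome import Region
from .sv import BreakpointCall, BreakpointEnd

logger = logging.getLogger(__name__)

L = "L"
R = "R"


@dataclass(frozen=True)
class Segment:
    """An amplified region acting as an assembly unit with two ends (L/R)."""

    id: str
    region: Region
    label: str = ""

    @property
    def left_pos(self) -> int:
        """1-based coordinate of the left boundary."""
        return self.region.start + 1

    @property
    def right_pos(self) -> int:
        """1-based coordinate of the right boundary (last base)."""
        return self.region.end


@dataclass(frozen=True)
class JunctionEdge:
    """A split-read-supported join between two segment ends."""

    end_from: tuple[str, str]  # (segment id, 'L' | 'R')
    end_to: tuple[str, str]
    support: int

    def key(self) -> tuple:
        return tuple(sorted([self.end_from, self.end_to]))


@dataclass
class AmpliconPath:
    """An assembled walk through segments: the amplicon's repeating unit."""

    members: list[tuple[str, str]]  # (segment id, orientation '+'|'-')
    topology: str  # 'linear' | 'circular'
    tandem: bool = False
    ambiguous_ends: list[tuple[str, str]] = field(default_factory=list)


def segments_from_regions(
    regions: list[Region], labels: list[str] | None = None
) -> list[Segment]:
    """Name regions A, B, C, ... in genome order, as assembly segments."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    segs = []
    for i, reg in enumerate(ordered):
        sid = _alpha_id(i)
        lab = labels[i] if labels else ""
        segs.append(Segment(sid, reg, lab))
    return segs


def _alpha_id(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def _match_end(
    end: BreakpointEnd, segments: list[Segment], tol: int
) -> tuple[str, str] | None:
    """Map a breakpoint end to the nearest compatible segment boundary.

    A 'right'-sided end (segment retained leftward) matches R boundaries, a
    'left'-sided end matches L boundaries; ends with no recorded side try
    both. Returns None when nothing is within tolerance.
    """
    best: tuple[int, str, str] | None = None
    for seg in segments:
        if seg.region.chrom != end.chrom:
            continue
        candidates = []
        if end.side in ("left", None, ""):
            candidates.append((abs(end.pos - seg.left_pos), seg.id, L))
        if end.side in ("right", None, ""):
            candidates.append((abs(end.pos - seg.right_pos), seg.id, R))
        for dist, sid, which in candidates:
            if dist <= tol and (best is None or dist < best[0]):
                best = (dist, sid, which)
    if best is None:
        return None
    return best[1], best[2]


def match_junctions_to_boundaries(
    breakpoints: list[BreakpointCall],
    segments: list[Segment],
    boundary_tol_bp: int = 1000,
) -> list[JunctionEdge]:
    """Turn boundary-proximal breakpoints into segment junction edges.

    A breakpoint becomes an edge only when both of its ends fall within
    ``boundary_tol_bp`` of a segment boundary; ends landing inside a
    segment body (or outside all segments) are excluded and logged. Edges
    joining the same end pair are merged with summed support.
    """
    for i, a in enumerate(segments):
        for b in segments[i + 1:]:
            if a.region.overlaps(b.region):
                raise ValueError(
                    f"segments {a.id} and {b.id} overlap: {a.region.label} "
                    f"vs {b.region.label}"
                )
    merged: dict[tuple, JunctionEdge] = {}
    for bp in breakpoints:
        ma = _match_end(bp.end_a, segments, boundary_tol_bp)
        mb = _match_end(bp.end_b, segments, boundary_tol_bp)
        if ma is None or mb is None:
            for end, m in ((bp.end_a, ma), (bp.end_b, mb)):
                if m is None:
                    logger.info(
                        "breakpoint end %s:%d not at any segment boundary "
                        "(tol %d bp); excluded", end.chrom, end.pos,
                        boundary_tol_bp,
                    )
            continue
        edge = JunctionEdge(ma, mb, bp.support)
        key = edge.key()
        if key in merged:
            merged[key] = JunctionEdge(
                merged[key].end_from, merged[key].end_to,
                merged[key].support + bp.support,
            )
        else:
            merged[key] = edge
    return sorted(merged.values(), key=lambda e: e.key())


def assemble_amplicon(
    segments: list[Segment], edges: list[JunctionEdge]
) -> list[AmpliconPath]:
    """Walk junction edges into maximal amplicon paths.

    Each segment end may retain at most one junction edge (highest support
    wins; losing ends are reported as ambiguous). The walk alternates
    segment-internal traversal (entering at one end, leaving at the other)
    with junction edges; a walk returning to its start is circular, and a
    circular walk whose closing junction joins the last segment's R end to
    the first segment's L end is a head-to-tail tandem. Circular paths are
    canonicalized to start at the lexicographically smallest segment id;
    linear paths to the direction with the smaller first id.
    """
    if not segments:
        return []
    seg_ids = {s.id for s in segments}
    # retain one edge per end (top support; deterministic tie-break on key)
    incident: dict[tuple[str, str], list[JunctionEdge]] = {}
    for e in edges:
        if e.end_from[0] not in seg_ids or e.end_to[0] not in seg_ids:
            raise ValueError(f"edge {e} references unknown segment")
        incident.setdefault(e.end_from, []).append(e)
        if e.end_to != e.end_from:
            incident.setdefault(e.end_to, []).append(e)
    chosen: dict[tuple[str, str], JunctionEdge] = {}
    ambiguous: list[tuple[str, str]] = []
    for end, cand in incident.items():
        cand = sorted(cand, key=lambda e: (-e.support, e.key()))
        chosen[end] = cand[0]
        if len(cand) > 1:
            ambiguous.append(end)
    partner: dict[tuple[str, str], tuple[str, str]] = {}
    for e in set(chosen.values()):
        # retained only if both its ends elected it
        if chosen.get(e.end_from) is e and chosen.get(e.end_to) is e:
            partner[e.end_from] = e.end_to
            partner[e.end_to] = e.end_from
    paths: list[AmpliconPath] = []
    visited: set[str] = set()
    for start_seg in sorted(seg_ids):
        if start_seg in visited:
            continue
        cur = _chain_start(start_seg, partner)
        members, topology, tandem = _walk(cur, partner, visited)
        members, tandem = _canonicalize(members, topology, tandem)
        paths.append(AmpliconPath(members, topology, tandem, []))
    amb_sorted = sorted(ambiguous)
    for p in paths:
        ids = {sid for sid, _ in p.members}
        p.ambiguous_ends = [e for e in amb_sorted if e[0] in ids]
    paths.sort(key=lambda p: p.members[0][0])
    return paths


def _other(end: str) -> str:
    return R if end == L else L


def _chain_start(seg: str, partner: dict) -> tuple[str, str]:
    """Entry end from which a full walk covers this component.

    Follow junctions backwards from (seg, L) until an end with no partner
    (linear chain start) or until we loop back (cycle: start anywhere).
    """
    cur_seg, entry = seg, L
    seen = {(cur_seg, entry)}
    while True:
        back = partner.get((cur_seg, entry))
        if back is None:
            return cur_seg, entry
        nxt = (back[0], _other(back[1]))
        if nxt in seen or back in seen:
            return seg, L  # cycle; canonicalization fixes the phase
        seen.add(nxt)
        seen.add(back)
        cur_seg, entry = nxt


def _walk(
    start: tuple[str, str], partner: dict, visited: set[str]
) -> tuple[list[tuple[str, str]], str, bool]:
    members: list[tuple[str, str]] = []
    seg, entry = start
    while True:
        members.append((seg, "+" if entry == L else "-"))
        visited.add(seg)
        exit_end = (seg, _other(entry))
        nxt = partner.get(exit_end)
        if nxt is None:
            return members, "linear", False
        if nxt == start:
            tandem = exit_end[1] == R and start[1] == L
            return members, "circular", tandem
        seg, entry = nxt


def _canonicalize(
    members: list[tuple[str, str]], topology: str, tandem: bool
) -> tuple[list[tuple[str, str]], bool]:
    def flipped(ms: list[tuple[str, str]]) -> list[tuple[str, str]]:
        return [(sid, "+" if o == "-" else "-") for sid, o in reversed(ms)]

    if topology == "linear":
        if len(members) > 1 and flipped(members)[0][0] < members[0][0]:
            return flipped(members), tandem
        return members, tandem
    # circular: all rotations of both directions; pick lexicographically
    # smallest starting at the smallest segment id
    best = None
    for ms in (members, flipped(members)):
        for k in range(len(ms)):
            rot = ms[k:] + ms[:k]
            if best is None or rot < best:
                best = rot
    return best, tandem


# ---------------------------------------------------------------------------
# Coamplification network


def build_coamp_network(
    segments: list[Segment],
    edges: list[JunctionEdge],
    matrix: ContactMatrix,
    min_support: int = 1,
) -> nx.Graph:
    """Graph of segments joined by junctions, weighted by contact strength.

    Nodes carry region coordinates and optional gene labels; an edge exists
    for each segment pair joined by junction edges with total split support
    >= min_support, and carries contact_strength = total contacts between
    the two regions divided by the number of bin pairs (size-normalized,
    hence symmetric).
    """
    g = nx.Graph()
    genome = matrix.genome
    seg_bins: dict[str, np.ndarray] = {}
    for seg in segments:
        if seg.region.chrom not in genome.lengths:
            raise ValueError(
                f"segment {seg.id} on {seg.region.chrom} not in matrix genome"
            )
        seg_bins[seg.id] = genome.bins_for_region(seg.region)
        g.add_node(
            seg.id,
            chrom=seg.region.chrom,
            start=seg.region.start,
            end=seg.region.end,
            label=seg.label,
        )
    pair_support: dict[tuple[str, str], int] = {}
    for e in edges:
        a, b = sorted([e.end_from[0], e.end_to[0]])
        pair_support[(a, b)] = pair_support.get((a, b), 0) + e.support
    for (a, b), support in sorted(pair_support.items()):
        if support < min_support:
            continue
        bins_a, bins_b = seg_bins[a], seg_bins[b]
        if a == b:
            blk = matrix.block(bins_a, bins_b)
            total = (np.triu(blk)).sum()
            n_pairs = len(bins_a) * (len(bins_a) + 1) / 2
        else:
            total = matrix.block(bins_a, bins_b).sum()
            n_pairs = len(bins_a) * len(bins_b)
        g.add_edge(
            a, b,
            split_support=support,
            contact_strength=float(total / n_pairs),
        )
    return g


def write_network(g: nx.Graph, paths: list[AmpliconPath], outdir) -> None:
    """Serialize nodes/edges/paths as TSV plus a JSON summary."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "nodes.tsv"), "w") as fh:
        fh.write("#id\tchrom\tstart\tend\tlabel\n")
        for n, d in sorted(g.nodes(data=True)):
            fh.write(f"{n}\t{d['chrom']}\t{d['start']}\t{d['end']}\t{d['label']}\n")
    with open(os.path.join(outdir, "edges.tsv"), "w") as fh:
        fh.write("#segA\tsegB\tsplit_support\tcontact_strength\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{d['split_support']}\t{d['contact_strength']:.6g}\n"
            )
    with open(os.path.join(outdir, "paths.tsv"), "w") as fh:
        fh.write("#path\ttopology\ttandem\tmembers\n")
        for i, p in enumerate(paths):
            mem = ",".join(f"{sid}{o}" for sid, o in p.members)
            fh.write(f"path{i + 1}\t{p.topology}\t{int(p.tandem)}\t{mem}\n")
    summary = {
        "n_segments": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "paths": [
            {
                "topology": p.topology,
                "tandem": p.tandem,
                "members": [f"{sid}{o}" for sid, o in p.members],
            }
            for p in paths
        ],
    }
    with open(os.path.join(outdir, "network.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
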