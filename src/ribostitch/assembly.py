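"""Per-cluster iterative subassembly and the final guided assembly.

The built-in assembler is a single-k de Bruijn graph over read k-mers
(both orientations stored, so the graph is its own reverse complement).
Guide sequences ("pseudocontigs") are threaded through the compacted
graph: at each branching unitig the guide records which in-link pairs
with which out-link, and final contigs are extracted as maximal paths
that follow those pairings. This is what lets identical repeat copies be
spelled once per copy, each in its own flanking context.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Literal, Sequence

from . import align
from .config import PipelineConfig, auto_k
from .mapping import KmerIndex, ReadPartition, map_reads, partition_reads
from .seqio import GenomeRecord, ReadRecord, revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class Pseudocontig:
    cluster_id: int
    iteration: int
    sequence: str
    expected_length: int
    qc_status: Literal["accepted", "too_short", "too_long"] = "accepted"
    trust: Literal["trusted", "untrusted"] = "trusted"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class Pseudogenome:
    sequence: str
    spacer_length: int
    layout: list[tuple[int, int, int]]  # (cluster_id, start, end)
    record_id: str = "pseudogenome"


@dataclasses.dataclass
class AssemblyResult:
    contigs: list[GenomeRecord]
    mode: Literal["de_novo", "de_fere_novo"]
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def n50(self) -> int:
        lengths = sorted((len(c.sequence) for c in self.contigs), reverse=True)
        total = sum(lengths)
        acc = 0
        for length in lengths:
            acc += length
            if acc * 2 >= total:
                return length
        return 0


def qc_pseudocontig(length: int, expected_length: int, min_length: int = 6000,
                    max_factor: float = 3.0) -> str:
    if length < min_length:
        return "too_short"
    if length > max_factor * expected_length:
        return "too_long"
    return "accepted"


# ---------------------------------------------------------------------------
# k-mer graph

class KmerGraph:
    """De Bruijn graph over read k-mers; every k-mer and its reverse
    complement are both stored (k must be odd, so no k-mer is its own
    reverse complement)."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str, weight: int = 1) -> None:
        k = self.k
        counts = self.counts
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                if "N" in kmer:
                    continue
                counts[kmer] = counts.get(kmer, 0) + weight

    def filter_min_count(self, min_count: int) -> None:
        if min_count <= 1:
            return
        self.counts = {km: c for km, c in self.counts.items() if c >= min_count}

    def add_kmer(self, kmer: str, count: int = 1) -> None:
        self.counts[kmer] = max(self.counts.get(kmer, 0), count)
        rc = revcomp(kmer)
        self.counts[rc] = max(self.counts.get(rc, 0), count)

    def remove_kmers(self, kmers: Iterable[str]) -> None:
        for kmer in kmers:
            self.counts.pop(kmer, None)
            self.counts.pop(revcomp(kmer), None)

    def succ(self, kmer: str) -> list[str]:
        stem = kmer[1:]
        counts = self.counts
        return [stem + b for b in "ACGT" if stem + b in counts]

    def pred(self, kmer: str) -> list[str]:
        stem = kmer[:-1]
        counts = self.counts
        return [b + stem for b in "ACGT" if b + stem in counts]

    def __len__(self) -> int:
        return len(self.counts)


def _unitig_paths(graph: KmerGraph) -> list[list[str]]:
    """Maximal non-branching k-mer paths, one orientation per unitig."""
    visited: set[str] = set()
    paths: list[list[str]] = []

    def consume(path: list[str]) -> None:
        for km in path:
            visited.add(km)
            visited.add(revcomp(km))
        paths.append(path)

    for kmer in graph.counts:
        if kmer in visited:
            continue
        preds = graph.pred(kmer)
        is_start = len(preds) != 1 or len(graph.succ(preds[0])) != 1
        if not is_start:
            continue
        path = [kmer]
        cur = kmer
        while True:
            nxts = graph.succ(cur)
            if len(nxts) != 1:
                break
            nxt = nxts[0]
            if len(graph.pred(nxt)) != 1 or nxt == path[0] or nxt in visited:
                break
            path.append(nxt)
            cur = nxt
        consume(path)
    # leftover pure cycles
    for kmer in graph.counts:
        if kmer in visited:
            continue
        path = [kmer]
        cur = kmer
        while True:
            nxts = graph.succ(cur)
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == path[0] or nxt in visited:
                break
            path.append(nxt)
            cur = nxt
        consume(path)
    return paths


def _spell(path: Sequence[str]) -> str:
    return path[0] + "".join(km[-1] for km in path[1:])


def clip_tips(graph: KmerGraph, tip_length: int, max_rounds: int = 8) -> int:
    """Remove short dead-end unitigs hanging off branching nodes."""
    removed_total = 0
    for _ in range(max_rounds):
        removed: list[str] = []
        for path in _unitig_paths(graph):
            seq_len = len(path) + graph.k - 1
            if seq_len >= tip_length:
                continue
            first, last = path[0], path[-1]
            preds = graph.pred(first)
            succs = graph.succ(last)
            start_dead = not preds
            end_dead = not succs
            if start_dead == end_dead:
                continue  # isolated or internal
            anchor_branches = (
                any(len(graph.succ(p)) > 1 for p in preds)
                if end_dead
                else any(len(graph.pred(s)) > 1 for s in succs)
            )
            if anchor_branches:
                removed.extend(path)
        if not removed:
            break
        graph.remove_kmers(removed)
        removed_total += len(removed)
    return removed_total


def pop_bubbles(graph: KmerGraph, bubble_identity: float = 0.9,
                max_rounds: int = 4) -> int:
    """Collapse pairs of short alternative paths between the same two
    branch nodes, keeping the higher-coverage branch."""
    popped_total = 0
    for _ in range(max_rounds):
        paths = _unitig_paths(graph)
        by_ends: dict[tuple, list[list[str]]] = {}
        for path in paths:
            preds = graph.pred(path[0])
            succs = graph.succ(path[-1])
            if len(preds) == 1 and len(succs) == 1:
                by_ends.setdefault((preds[0], succs[0]), []).append(path)
        removed: list[str] = []
        for (src, dst), branches in by_ends.items():
            if len(branches) < 2:
                continue
            branches.sort(
                key=lambda p: (-sum(graph.counts.get(km, 0) for km in p) / len(p),
                               _spell(p)),
            )
            keeper = _spell(branches[0])
            for branch in branches[1:]:
                seq = _spell(branch)
                if abs(len(seq) - len(keeper)) > graph.k:
                    continue
                if len(seq) == len(keeper):
                    a, b = align.encode(seq), align.encode(keeper)
                    identity = align.ungapped_matches(a, b) / len(seq)
                else:
                    try:
                        identity = align.banded_global(seq, keeper, band=graph.k).identity
                    except ValueError:
                        continue
                if identity >= bubble_identity:
                    removed.extend(branch)
        if not removed:
            break
        graph.remove_kmers(removed)
        popped_total += len(removed)
    return popped_total


def build_read_graph(
    reads: Sequence[ReadRecord] | Sequence[str],
    k: int,
    min_kmer_count: int = 2,
    tip_length: int | None = None,
    bubble_identity: float = 0.9,
) -> KmerGraph:
    graph = KmerGraph(k)
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        graph.add_sequence(seq)
    graph.filter_min_count(min_kmer_count)
    if tip_length is None:
        tip_length = 2 * k
    if len(graph):
        clip_tips(graph, tip_length)
        pop_bubbles(graph, bubble_identity)
    return graph


# ---------------------------------------------------------------------------
# compacted (unitig) graph

@dataclasses.dataclass(frozen=True)
class Oriented:
    uid: int
    sign: int  # +1 forward, -1 reverse

    def flip(self) -> "Oriented":
        return Oriented(self.uid, -self.sign)


class CompactedGraph:
    """Unitig-level view of a :class:`KmerGraph` with oriented links."""

    def __init__(self, graph: KmerGraph):
        self.k = graph.k
        paths = _unitig_paths(graph)
        # deterministic unitig order: longest first, then lexicographic
        paths.sort(key=lambda p: (-len(p), p[0]))
        self.units: list[str] = [_spell(p) for p in paths]
        self.coverage: list[float] = [
            sum(graph.counts.get(km, 0) for km in p) / len(p) for p in paths
        ]
        self.n_kmers: list[int] = [len(p) for p in paths]
        self.kmap: dict[str, tuple[int, int]] = {}
        for uid, path in enumerate(paths):
            for off, km in enumerate(path):
                self.kmap[km] = (uid, off)
        self.out_links: dict[Oriented, list[Oriented]] = {}
        self.in_links: dict[Oriented, list[Oriented]] = {}
        for uid in range(len(self.units)):
            for sign in (1, -1):
                node = Oriented(uid, sign)
                last = self.oriented_seq(node)[-self.k:]
                for nxt in graph.succ(last):
                    target = self.locate(nxt)
                    if target is None:
                        continue
                    t_node, t_off = target
                    if t_off == 0:
                        self.out_links.setdefault(node, []).append(t_node)
                        self.in_links.setdefault(t_node, []).append(node)
        for links in self.out_links.values():
            links.sort(key=lambda n: (n.uid, -n.sign))
        for links in self.in_links.values():
            links.sort(key=lambda n: (n.uid, -n.sign))

    def oriented_seq(self, node: Oriented) -> str:
        seq = self.units[node.uid]
        return seq if node.sign > 0 else revcomp(seq)

    def locate(self, kmer: str) -> tuple[Oriented, int] | None:
        """Oriented (node, kmer-offset) of a k-mer, or None."""
        hit = self.kmap.get(kmer)
        if hit is not None:
            return Oriented(hit[0], 1), hit[1]
        hit = self.kmap.get(revcomp(kmer))
        if hit is not None:
            uid, off = hit
            return Oriented(uid, -1), self.n_kmers[uid] - 1 - off
        return None

    def outs(self, node: Oriented) -> list[Oriented]:
        return self.out_links.get(node, [])

    def ins(self, node: Oriented) -> list[Oriented]:
        return self.in_links.get(node, [])

    def branching(self, node: Oriented) -> bool:
        return len(self.outs(node)) > 1 or len(self.ins(node)) > 1

    def spell_path(self, path: Sequence[Oriented]) -> str:
        seq = self.oriented_seq(path[0])
        for node in path[1:]:
            seq += self.oriented_seq(node)[self.k - 1:]
        return seq


# ---------------------------------------------------------------------------
# guide threading

def patch_guide_gaps(graph: KmerGraph, guide: str, max_gap: int = 2,
                     count: int = 1) -> int:
    """Insert runs of <= ``max_gap`` missing guide k-mers that are flanked
    by k-mers present in the graph (trusted guides only)."""
    k = graph.k
    kmers = [guide[i:i + k] for i in range(len(guide) - k + 1)]
    present = [km in graph.counts for km in kmers]
    patched = 0
    i = 0
    n = len(kmers)
    while i < n:
        if present[i]:
            i += 1
            continue
        j = i
        while j < n and not present[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            for t in range(i, j):
                if "N" not in kmers[t]:
                    graph.add_kmer(kmers[t], count)
                    patched += 1
        i = j
    return patched


def project_guide(cgraph: CompactedGraph, guide: str) -> list[list[Oriented]]:
    """Project a guide sequence onto oriented-unitig path segments.

    A segment breaks wherever a guide k-mer is absent from the graph or
    the walk does not follow a valid link.
    """
    k = cgraph.k
    segments: list[list[Oriented]] = []
    current: list[Oriented] = []
    prev: tuple[Oriented, int] | None = None
    for i in range(len(guide) - k + 1):
        kmer = guide[i:i + k]
        hit = cgraph.locate(kmer) if "N" not in kmer else None
        if hit is None:
            if current:
                segments.append(current)
            current = []
            prev = None
            continue
        node, off = hit
        if prev is None:
            current = [node]
        else:
            p_node, p_off = prev
            if node == p_node and off == p_off + 1:
                pass
            elif p_off == cgraph.n_kmers[p_node.uid] - 1 and off == 0 and (
                node in cgraph.outs(p_node)
            ):
                current.append(node)
            else:
                segments.append(current)
                current = [node]
        prev = (node, off)
    if current:
        segments.append(current)
    return segments


def thread_guide(
    cgraph: CompactedGraph,
    guide: str,
    trusted: bool = True,
    pair_support: Counter | None = None,
    min_contradiction: int = 5,
) -> list[list[Oriented]]:
    """Thread a guide through the graph, returning the oriented-unitig
    path segments it supports.

    Untrusted guides only vote at junctions that spanning read pairs do
    not contradict (``pair_support`` counts read pairs linking unitig
    ids); a contradicted junction splits the segment there, removing the
    vote. The resulting paths drive repeat resolution in
    :func:`resolve_paths`.
    """
    segments = project_guide(cgraph, guide)
    if not any(len(seg) >= 2 for seg in segments):
        logger.warning("guide contributes no junction information (too few graph k-mers)")
    if trusted or pair_support is None:
        return segments
    vetted: list[list[Oriented]] = []
    for seg in segments:
        current = [seg[0]] if seg else []
        for idx in range(1, len(seg) - 1):
            P, V, N = seg[idx - 1], seg[idx], seg[idx + 1]
            current.append(V)
            if not cgraph.branching(V):
                continue
            own = pair_support.get(_ulink(P, N), 0)
            contradiction = max(
                (
                    pair_support.get(_ulink(P, alt), 0)
                    for alt in cgraph.outs(V)
                    if alt != N
                ),
                default=0,
            )
            if contradiction >= min_contradiction and contradiction > own:
                logger.info(
                    "untrusted guide pairing rejected at unitig %d "
                    "(contradicted by %d read pairs)", V.uid, contradiction,
                )
                # drop the junction from both directions: neither V->N nor
                # (by mirror) rc(N)->rc(V) survives as a vote
                vetted.append(current)
                current = []
        if len(seg) >= 2:
            if current:
                current.append(seg[-1])
            else:
                current = [seg[-1]]
        if current:
            vetted.append(current)
    return vetted


def junction_choices(
    cgraph: CompactedGraph, segments: Sequence[Sequence[Oriented]]
) -> set[tuple[Oriented, Oriented, Oriented]]:
    """(in-link, junction, out-link) triples a guide resolves at branching
    unitigs (reported for diagnostics/tests)."""
    choices: set[tuple[Oriented, Oriented, Oriented]] = set()
    for seg in segments:
        for idx in range(1, len(seg) - 1):
            P, V, N = seg[idx - 1], seg[idx], seg[idx + 1]
            if cgraph.branching(V):
                choices.add((P, V, N))
                choices.add((N.flip(), V.flip(), P.flip()))
    return choices


def _ulink(a: Oriented, b: Oriented) -> tuple[int, int]:
    return (min(a.uid, b.uid), max(a.uid, b.uid))


def pair_support_counter(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]], cgraph: CompactedGraph
) -> Counter:
    """Count read pairs whose mates land on two different unitigs."""
    support: Counter = Counter()
    k = cgraph.k
    for r1, r2 in pairs:
        uids = []
        for read in (r1, r2):
            seq = read.sequence
            if len(seq) < k:
                uids.append(None)
                continue
            mid = (len(seq) - k) // 2
            hit = None
            for i in (mid, 0, len(seq) - k):
                hit = cgraph.locate(seq[i:i + k])
                if hit is not None:
                    break
            uids.append(hit[0] if hit else None)
        a, b = uids
        if a is not None and b is not None and a.uid != b.uid:
            support[_ulink(a, b)] += 1
    return support


# ---------------------------------------------------------------------------
# path resolution

def resolve_paths(
    cgraph: CompactedGraph, guide_paths: Sequence[Sequence[Oriented]]
) -> list[str]:
    """Extract maximal contig paths, using guide paths to choose branches.

    At a junction, every guide occurrence of the current unitig is scored
    by the length of its path context matching the walk's suffix; the
    extension is taken only when the best-context candidates agree. This
    longest-suffix rule lets a walk carry flanking context *through* a
    collapsed repeat, spelling each repeat copy in its own context.
    """
    paths: list[list[Oriented]] = []
    for seg in guide_paths:
        seg = list(seg)
        if not seg:
            continue
        paths.append(seg)
        paths.append([node.flip() for node in reversed(seg)])
    occurrence: dict[Oriented, list[tuple[int, int]]] = {}
    for pidx, seg in enumerate(paths):
        for pos, node in enumerate(seg):
            occurrence.setdefault(node, []).append((pidx, pos))

    def step(walk_path: list[Oriented]) -> Oriented | None:
        node = walk_path[-1]
        outs = cgraph.outs(node)
        if not outs:
            return None
        converging = len(cgraph.ins(node)) > 1
        has_context = len(walk_path) > 1
        candidates: dict[Oriented, int] = {}
        for pidx, pos in occurrence.get(node, ()):  # guide-context extension
            seg = paths[pidx]
            if pos + 1 >= len(seg):
                continue
            score = 1
            while (
                score <= pos
                and score < len(walk_path)
                and seg[pos - score] == walk_path[-1 - score]
            ):
                score += 1
            if pos >= 1 and has_context and score == 1:
                continue  # guide context exists and contradicts the walk
            if converging and has_context and score < 2:
                # context-less guide stub cannot vouch for this entry
                continue
            nxt = seg[pos + 1]
            if nxt in outs:
                candidates[nxt] = max(candidates.get(nxt, 0), score)
        if candidates:
            best = max(candidates.values())
            top = [n for n, s in sorted(candidates.items(),
                                        key=lambda kv: (kv[0].uid, -kv[0].sign))
                   if s == best]
            if len(top) == 1:
                return top[0]
            return None  # guides ambiguous here
        if len(outs) != 1:
            return None
        nxt = outs[0]
        if len(cgraph.ins(nxt)) == 1:
            return nxt
        if nxt in occurrence:
            # converging node covered by guides: enter, context may resolve it
            return nxt
        return None

    max_steps = 4 * len(cgraph.units) + 4 * sum(len(p) for p in paths) + 64

    def walk(start: Oriented) -> list[Oriented]:
        walk_path = [start]
        while len(walk_path) < max_steps:
            nxt = step(walk_path)
            if nxt is None:
                break
            walk_path.append(nxt)
        return walk_path

    contigs: list[str] = []
    emitted: set[str] = set()
    for uid in range(len(cgraph.units)):
        fwd = Oriented(uid, 1)
        back = walk(fwd.flip())
        start = back[-1].flip()
        path = walk(start)
        seq = cgraph.spell_path(path)
        canon = min(seq, revcomp(seq))
        if canon not in emitted:
            emitted.add(canon)
            contigs.append(seq)
    # drop contigs wholly contained in another emitted contig (a unitig
    # whose copies were all resolved into longer paths)
    contigs.sort(key=lambda s: (-len(s), s))
    kept: list[str] = []
    for seq in contigs:
        rc = revcomp(seq)
        if any(seq in other or rc in other for other in kept):
            continue
        kept.append(seq)
    return kept


# ---------------------------------------------------------------------------
# public assembly operations

def debruijn_assemble(
    reads: Sequence[ReadRecord] | Sequence[str],
    k: int,
    min_kmer_count: int = 2,
    tip_length: int | None = None,
    bubble_identity: float = 0.9,
) -> list[str]:
    """Plain de novo assembly: cleaned de Bruijn graph unitigs."""
    graph = build_read_graph(reads, k, min_kmer_count, tip_length, bubble_identity)
    if not len(graph):
        logger.warning("no k-mers survive filtering; empty assembly")
        return []
    cgraph = CompactedGraph(graph)
    return resolve_paths(cgraph, [])


def guided_assemble(
    reads: Sequence[ReadRecord] | Sequence[str],
    guides: Sequence[tuple[str, bool]],
    k: int,
    min_kmer_count: int = 2,
    tip_length: int | None = None,
    bubble_identity: float = 0.9,
    pairs: Sequence[tuple[ReadRecord, ReadRecord]] | None = None,
) -> list[str]:
    """Assemble reads with guide sequences threaded through the graph.

    ``guides`` is a list of (sequence, trusted). Trusted guides patch
    small graph gaps with their own sequence; untrusted guides only vote
    at junctions where read pairs do not contradict them.
    """
    graph = build_read_graph(reads, k, min_kmer_count, tip_length, bubble_identity)
    if not len(graph):
        logger.warning("no k-mers survive filtering; empty assembly")
        return []
    for seq, trusted in guides:
        if trusted:
            patch_guide_gaps(graph, seq, max_gap=2, count=min_kmer_count)
    cgraph = CompactedGraph(graph)
    support = None
    if pairs is not None and any(not trusted for _, trusted in guides):
        support = pair_support_counter(pairs, cgraph)
    guide_paths: list[list[Oriented]] = []
    for seq, trusted in guides:
        guide_paths.extend(thread_guide(cgraph, seq, trusted, pair_support=support))
    return resolve_paths(cgraph, guide_paths)


def subassemble_cluster(
    partition: ReadPartition,
    reference_region: str,
    k: int,
    cluster=None,
    iteration: int = 1,
    flank: int = 1000,
    trust_threshold: float = 0.8,
    min_length: int = 6000,
    max_factor: float = 3.0,
    min_kmer_count: int = 2,
) -> Pseudocontig:
    """Subassemble one cluster's baited reads into a pseudocontig.

    The reference region is threaded as a trusted guide when the
    partition's mean mapping identity reaches ``trust_threshold``,
    otherwise the reads are assembled alone. The longest contig becomes
    the pseudocontig, QC'd on length against the expected region size.
    """
    if cluster is not None:
        expected = (cluster.span_end - cluster.span_start) + 2 * flank
        cid = cluster.cluster_id
    else:
        expected = len(reference_region)
        cid = partition.cluster_id
    trusted = partition.mean_identity >= trust_threshold
    if not partition.reads:
        pc = Pseudocontig(cid, iteration, "", expected, "too_short",
                          "trusted" if trusted else "untrusted")
        logger.warning("cluster %d: empty partition; pseudocontig failed QC", cid)
        return pc
    if trusted:
        contigs = guided_assemble(
            partition.reads, [(reference_region, True)], k,
            min_kmer_count=min_kmer_count,
        )
    else:
        contigs = debruijn_assemble(partition.reads, k, min_kmer_count=min_kmer_count)
    sequence = contigs[0] if contigs else ""
    status = qc_pseudocontig(len(sequence), expected, min_length, max_factor)
    pc = Pseudocontig(cid, iteration, sequence, expected, status,
                      "trusted" if trusted else "untrusted")
    if status != "accepted":
        logger.warning(
            "cluster %d iteration %d: pseudocontig length %d failed QC (%s; "
            "expected ~%d)", cid, iteration, len(sequence), status, expected,
        )
    return pc


def build_pseudogenome(
    pseudocontigs: Sequence[Pseudocontig], spacer_length: int = 1000
) -> Pseudogenome:
    """Concatenate accepted pseudocontigs (ascending cluster id) separated
    by exact runs of N."""
    accepted = sorted(
        (pc for pc in pseudocontigs if pc.qc_status == "accepted"),
        key=lambda pc: pc.cluster_id,
    )
    if not accepted:
        raise ValueError("no accepted pseudocontigs to concatenate")
    parts: list[str] = []
    layout: list[tuple[int, int, int]] = []
    cursor = 0
    for i, pc in enumerate(accepted):
        if i:
            parts.append("N" * spacer_length)
            cursor += spacer_length
        layout.append((pc.cluster_id, cursor, cursor + len(pc.sequence)))
        parts.append(pc.sequence)
        cursor += len(pc.sequence)
    return Pseudogenome("".join(parts), spacer_length, layout)


@dataclasses.dataclass
class _Region:
    """Lightweight baiting target (mirrors the cluster region contract)."""
    cluster_id: int
    record_id: str
    region_start: int
    region_end: int


@dataclasses.dataclass
class IterationStats:
    iteration: int
    cluster_id: int
    n_reads: int
    mapped_fraction: float
    mean_identity: float
    mean_depth: float
    pseudocontig_length: int
    qc_status: str
    trust: str


def seed_iterate(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    reference: Sequence[GenomeRecord],
    clusters,
    iterations: int = 3,
    k: int | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[Pseudocontig], list[IterationStats]]:
    """Iterative baiting/subassembly.

    Iteration 1 maps reads to the reference and baits on cluster regions;
    later iterations map to the previous pseudogenome, one region per
    pseudocontig with no extra flank. Clusters whose pseudocontig fails QC
    are frozen at their last accepted version (or dropped if never
    accepted). Returns the final pseudocontigs and per-(cluster,
    iteration) statistics.
    """
    cfg = config or PipelineConfig()
    reads = [r for pair in pairs for r in pair]
    if k is None:
        k = cfg.k or auto_k(max(len(r.sequence) for r in reads))
    ref_seqs = {rec.record_id: rec.sequence for rec in reference}
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to seed")
    accepted: dict[int, Pseudocontig] = {}
    frozen: set[int] = set()
    stats: list[IterationStats] = []

    for iteration in range(1, iterations + 1):
        if iteration == 1:
            targets = list(reference)
            regions = [
                _Region(cl.cluster_id, cl.record_id, cl.region_start, cl.region_end)
                for cl in clusters
            ]
            region_seq = {
                cl.cluster_id: ref_seqs[cl.record_id][cl.region_start:cl.region_end]
                for cl in clusters
            }
        else:
            pg = build_pseudogenome(list(accepted.values()), cfg.spacer)
            targets = [GenomeRecord(pg.record_id, pg.sequence)]
            regions = [
                _Region(cid, pg.record_id, start, end)
                for cid, start, end in pg.layout
                if cid not in frozen
            ]
            region_seq = {pc.cluster_id: pc.sequence for pc in accepted.values()}
        active = [r for r in regions if r.cluster_id not in frozen]
        if not active:
            break
        index = KmerIndex(targets, cfg.map_k)
        mappings = map_reads(
            reads, index, min_identity=cfg.min_identity,
            max_seed_hits=cfg.max_seed_hits, band=cfg.band,
        )
        partitions = partition_reads(mappings, reads, active, cfg.min_identity)
        cluster_by_id = {cl.cluster_id: cl for cl in clusters}
        for region, partition in zip(active, partitions):
            cl = cluster_by_id[region.cluster_id]
            pc = subassemble_cluster(
                partition,
                region_seq[region.cluster_id],
                k,
                cluster=cl,
                iteration=iteration,
                flank=cfg.flank,
                trust_threshold=cfg.trust_identity,
                min_length=cfg.min_length,
                max_factor=cfg.max_factor,
                min_kmer_count=cfg.min_kmer_count,
            )
            stats.append(
                IterationStats(
                    iteration, region.cluster_id, len(partition.reads),
                    partition.mapped_fraction, partition.mean_identity,
                    partition.mean_depth, len(pc.sequence), pc.qc_status, pc.trust,
                )
            )
            logger.info(
                "iteration %d cluster %d: %d reads baited, mapped_fraction=%.3f, "
                "mean_identity=%.3f, depth=%.1fx, pseudocontig=%d bp (%s, %s)",
                iteration, region.cluster_id, len(partition.reads),
                partition.mapped_fraction, partition.mean_identity,
                partition.mean_depth, len(pc.sequence), pc.qc_status, pc.trust,
            )
            if pc.qc_status == "accepted":
                accepted[pc.cluster_id] = pc
            else:
                frozen.add(pc.cluster_id)
        if not accepted:
            raise RuntimeError(
                "all clusters failed pseudocontig QC in iteration "
                f"{iteration}; check flank size, k, or reference choice"
            )
    return sorted(accepted.values(), key=lambda pc: pc.cluster_id), stats


def final_assembly(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    pseudocontigs: Sequence[Pseudocontig],
    k: int | None = None,
    config: PipelineConfig | None = None,
) -> tuple[AssemblyResult, AssemblyResult]:
    """Final assemblies: guided (de fere novo) and the de novo control.

    Both use the same graph parameters; the only difference is threading
    of the pseudocontigs.
    """
    cfg = config or PipelineConfig()
    reads = [r for pair in pairs for r in pair]
    if k is None:
        k = cfg.k or auto_k(max(len(r.sequence) for r in reads))
    provenance = {
        "k": k,
        "min_kmer_count": cfg.min_kmer_count,
        "bubble_identity": cfg.bubble_identity,
        "n_pseudocontigs": len(pseudocontigs),
    }
    de_novo_seqs = debruijn_assemble(
        reads, k, cfg.min_kmer_count, bubble_identity=cfg.bubble_identity
    )
    guides = [
        (pc.sequence, pc.trust == "trusted")
        for pc in pseudocontigs
        if pc.qc_status == "accepted" and pc.sequence
    ]
    if guides:
        de_fere_seqs = guided_assemble(
            reads, guides, k, cfg.min_kmer_count,
            bubble_identity=cfg.bubble_identity, pairs=pairs,
        )
    else:
        de_fere_seqs = list(de_novo_seqs)

    def wrap(seqs: list[str], mode: str) -> AssemblyResult:
        contigs = [
            GenomeRecord(f"contig_{i}", seq, description=f"{mode} contig")
            for i, seq in enumerate(seqs, 1)
        ]
        return AssemblyResult(contigs, mode, dict(provenance))

    return wrap(de_fere_seqs, "de_fere_novo"), wrap(de_novo_seqs, "de_novo")


# ---------------------------------------------------------------------------
# swap

def swap(
    de_fere_contigs: Sequence[GenomeRecord],
    de_novo_contigs: Sequence[GenomeRecord],
    bad_contig_id: str,
    min_identity: float = 0.95,
    min_length_fraction: float = 0.5,
    k: int = 21,
) -> tuple[list[GenomeRecord], list[dict]]:
    """Replace a suspect guided-assembly contig with the syntenic de novo
    contigs (those matching it at >= ``min_identity`` over >=
    ``min_length_fraction`` of their length)."""
    by_id = {c.record_id: c for c in de_fere_contigs}
    if bad_contig_id not in by_id:
        raise KeyError(f"contig {bad_contig_id!r} not in the guided assembly")
    bad = by_id[bad_contig_id]
    bad_arr = align.encode(bad.sequence)
    bad_kmers: dict[str, list[int]] = {}
    seq = bad.sequence
    for i in range(len(seq) - k + 1):
        bad_kmers.setdefault(seq[i:i + k], []).append(i)

    replacements: list[GenomeRecord] = []
    report: list[dict] = []
    for contig in de_novo_contigs:
        best = None
        for strand, cand in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
            diag_votes: Counter = Counter()
            for i in range(0, max(1, len(cand) - k + 1), 4):
                for pos in bad_kmers.get(cand[i:i + k], []):
                    diag_votes[pos - i] += 1
            if not diag_votes:
                continue
            diag, _ = diag_votes.most_common(1)[0]
            arr = align.encode(cand)
            matches, overlap, q_start, q_end = align.place_ungapped(arr, bad_arr, diag)
            if overlap == 0:
                continue
            identity = matches / overlap
            if best is None or matches > best[0]:
                best = (matches, identity, overlap, strand, diag + q_start)
        if best is None:
            continue
        matches, identity, overlap, strand, start = best
        if identity >= min_identity and overlap >= min_length_fraction * len(contig.sequence):
            replacements.append(contig)
            report.append(
                {
                    "contig_id": contig.record_id,
                    "strand": strand,
                    "bad_contig_start": start,
                    "bad_contig_end": start + overlap,
                    "identity": identity,
                }
            )
    if not replacements:
        raise RuntimeError(
            f"no syntenic de novo contig found for {bad_contig_id!r}; assembly left unchanged"
        )
    edited = [c for c in de_fere_contigs if c.record_id != bad_contig_id]
    edited.extend(replacements)
    return edited, report
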