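"""Built-in seed-and-extend read mapper used for read baiting.

Exact k-mer seeds vote for candidate diagonals; candidates are evaluated
by vectorized ungapped comparison, with a banded gapped fallback. An
external mapper can be substituted by ingesting its SAM output.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
from typing import Iterable, Literal, Sequence

import numpy as np
import pysam

from . import align
from .seqio import GenomeRecord, ReadRecord, revcomp

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MappingRecord:
    read_id: str
    mate: Literal["single", "first", "second"]
    record_id: str | None          # None => unmapped
    pos: int = 0                   # 0-based leftmost reference position
    strand: Literal["+", "-"] = "+"
    cigar: list[tuple[str, int]] = dataclasses.field(default_factory=list)
    identity: float = 0.0          # matches / aligned columns
    score: int = 0
    paired_proper: bool = False
    co_best: list[tuple[str, int, str]] = dataclasses.field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return self.record_id is not None

    @property
    def ref_end(self) -> int:
        return self.pos + align.cigar_ref_length(self.cigar)

    def intervals(self) -> list[tuple[str, int, int]]:
        """All co-best placements as (record_id, start, end)."""
        if not self.mapped:
            return []
        span = align.cigar_ref_length(self.cigar)
        out = [(self.record_id, self.pos, self.pos + span)]
        for rec_id, pos, _strand in self.co_best:
            if (rec_id, pos) != (self.record_id, self.pos):
                out.append((rec_id, pos, pos + span))
        return out


@dataclasses.dataclass
class ReadPartition:
    cluster_id: int
    reads: list[ReadRecord]
    mapped_fraction: float = 0.0
    mean_identity: float = 0.0
    mean_depth: float = 0.0


class KmerIndex:
    """Exact-match positional k-mer index over the forward strand.

    Reverse-strand hits are found by querying the reverse complement of
    the read, so each genomic k-mer is stored once.
    """

    def __init__(self, genome: Sequence[GenomeRecord], k: int = 21):
        if k % 2 == 0 or not 11 <= k <= 31:
            raise ValueError("k must be odd and in [11, 31]")
        self.k = k
        self.records = list(genome)
        if any(len(rec.sequence) < k for rec in self.records):
            raise ValueError(f"genome record shorter than k={k}")
        self.encoded = [align.encode(rec.sequence) for rec in self.records]
        self.positions: dict[str, list[tuple[int, int]]] = {}
        for ridx, rec in enumerate(self.records):
            seq = rec.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self.positions.setdefault(kmer, []).append((ridx, i))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.positions.get(kmer, [])


def _seed_positions(read_len: int, k: int, n_seeds: int = 8) -> list[int]:
    last = read_len - k
    if last <= 0:
        return []
    if n_seeds == 1:
        return [0]
    step = max(1, last // (n_seeds - 1))
    positions = list(range(0, last + 1, step))
    if positions[-1] != last:
        positions.append(last)
    return positions


def _evaluate_candidate(
    arr: np.ndarray, ref: np.ndarray, offset: int
) -> tuple[float, int, int, int, int]:
    matches, overlap, q_start, q_end = align.place_ungapped(arr, ref, offset)
    if overlap == 0:
        return 0.0, 0, 0, 0, 0
    identity = matches / overlap
    score = 2 * matches - overlap  # match +1 / mismatch -1
    return identity, score, overlap, q_start, q_end


def map_reads(
    reads: Sequence[ReadRecord],
    index: KmerIndex,
    min_identity: float = 0.8,
    max_seed_hits: int = 50,
    band: int = 15,
    gapped_fallback: bool = True,
    rescue_mates: bool = True,
) -> list[MappingRecord]:
    """Map reads against the indexed genome.

    Per read, seed hits vote for (record, diagonal, strand) candidates;
    the best-scoring placement is reported if its identity reaches
    ``min_identity``, ties broken by leftmost (record, pos); co-best
    placements are retained for repeat-aware partitioning. When exactly
    one mate of a pair maps, the other is sought within an insert window
    of mean + 4 sd (estimated from proper pairs) and rescued even below
    the identity threshold.
    """
    k = index.k
    out: list[MappingRecord] = []
    for read in reads:
        seq = read.sequence
        rl = len(seq)
        if rl < k:
            out.append(MappingRecord(read.read_id, read.mate, None))
            continue
        arr_fw = align.encode(seq)
        rc = revcomp(seq)
        arr_rc = align.encode(rc)
        votes: dict[tuple[int, int, str], int] = {}
        for strand, s, arr in (("+", seq, arr_fw), ("-", rc, arr_rc)):
            for i in _seed_positions(rl, k):
                hits = index.lookup(s[i:i + k])
                if not hits or len(hits) > max_seed_hits:
                    continue
                for ridx, pos in hits:
                    key = (ridx, pos - i, strand)
                    votes[key] = votes.get(key, 0) + 1
        if not votes:
            out.append(MappingRecord(read.read_id, read.mate, None))
            continue
        candidates = sorted(votes, key=lambda c: (-votes[c], c[0], c[1]))[:12]
        best: list[tuple] = []  # (score, identity, ridx, offset, strand, cigar)
        for ridx, offset, strand in candidates:
            arr = arr_fw if strand == "+" else arr_rc
            ref = index.encoded[ridx]
            identity, score, overlap, q_start, q_end = _evaluate_candidate(arr, ref, offset)
            if overlap == 0:
                continue
            cigar: list[tuple[str, int]] = []
            if q_start:
                cigar.append(("S", q_start))
            cigar.append(("M", q_end - q_start))
            if rl - q_end:
                cigar.append(("S", rl - q_end))
            pos = offset + q_start
            want_gapped = identity < min_identity and (
                votes[(ridx, offset, strand)] >= 2
                or identity >= min_identity - 0.2
            )
            if gapped_fallback and want_gapped:
                window_start = max(0, offset - band)
                window_end = min(len(ref), offset + rl + band)
                ref_window = index.records[ridx].sequence[window_start:window_end]
                q = seq if strand == "+" else rc
                try:
                    res = align.banded_global(q, ref_window, band=band)
                except ValueError:
                    res = None
                if res is not None:
                    g_cigar = [(op, n) for op, n in res.cigar]
                    # leading/trailing D consume reference only: shift pos
                    # and drop their columns from the identity denominator
                    g_pos = window_start
                    trimmed = 0
                    if g_cigar and g_cigar[0][0] == "D":
                        g_pos += g_cigar[0][1]
                        trimmed += g_cigar[0][1]
                        g_cigar = g_cigar[1:]
                    if g_cigar and g_cigar[-1][0] == "D":
                        trimmed += g_cigar[-1][1]
                        g_cigar = g_cigar[:-1]
                    g_columns = res.columns - trimmed
                    g_identity = res.matches / g_columns if g_columns else 0.0
                    g_score = 2 * res.matches - g_columns
                    if g_identity > identity:
                        identity, score, cigar, pos = g_identity, g_score, g_cigar, g_pos
            best.append((score, identity, ridx, pos, strand, cigar))
        if not best:
            out.append(MappingRecord(read.read_id, read.mate, None))
            continue
        best.sort(key=lambda t: (-t[0], t[2], t[3]))
        top_score = best[0][0]
        co = [t for t in best if t[0] == top_score]
        score, identity, ridx, pos, strand, cigar = co[0]
        if identity < min_identity:
            out.append(MappingRecord(read.read_id, read.mate, None))
            continue
        rec = MappingRecord(
            read.read_id, read.mate, index.records[ridx].record_id, pos, strand,
            cigar, identity, score,
            co_best=[(index.records[t[2]].record_id, t[3], t[4]) for t in co],
        )
        out.append(rec)

    _flag_proper_pairs(out)
    if rescue_mates:
        _rescue_mates(reads, out, index)
    return out


def _pair_key(mate: str) -> str:
    return {"first": "second", "second": "first"}.get(mate, "")


def _flag_proper_pairs(mappings: Sequence[MappingRecord], max_insert: int = 2000) -> None:
    by_id: dict[tuple[str, str], MappingRecord] = {
        (m.read_id, m.mate): m for m in mappings
    }
    for m in mappings:
        if not m.mapped or m.mate == "single":
            continue
        other = by_id.get((m.read_id, _pair_key(m.mate)))
        if (
            other is not None
            and other.mapped
            and other.record_id == m.record_id
            and other.strand != m.strand
            and abs(other.pos - m.pos) <= max_insert
        ):
            m.paired_proper = True


def _estimate_insert(mappings: Sequence[MappingRecord]) -> tuple[float, float]:
    by_id: dict[str, dict[str, MappingRecord]] = {}
    for m in mappings:
        if m.mapped and m.mate in ("first", "second"):
            by_id.setdefault(m.read_id, {})[m.mate] = m
    inserts = []
    for mates in by_id.values():
        if len(mates) == 2:
            m1, m2 = mates["first"], mates["second"]
            if m1.record_id == m2.record_id and m1.strand != m2.strand:
                left, right = sorted((m1, m2), key=lambda m: m.pos)
                insert = right.ref_end - left.pos
                if 0 < insert <= 2000:
                    inserts.append(insert)
    if len(inserts) < 2:
        return 300.0, 10.0
    return statistics.fmean(inserts), statistics.stdev(inserts)


def _rescue_mates(
    reads: Sequence[ReadRecord],
    mappings: list[MappingRecord],
    index: KmerIndex,
    min_rescue_identity: float = 0.5,
) -> None:
    mean_insert, sd_insert = _estimate_insert(mappings)
    window = int(mean_insert + 4 * sd_insert)
    read_lookup = {(r.read_id, r.mate): r for r in reads}
    mapping_lookup = {(m.read_id, m.mate): i for i, m in enumerate(mappings)}
    for i, m in enumerate(mappings):
        if m.mapped or m.mate == "single":
            continue
        j = mapping_lookup.get((m.read_id, _pair_key(m.mate)))
        if j is None:
            continue
        anchor = mappings[j]
        if not anchor.mapped:
            continue
        read = read_lookup.get((m.read_id, m.mate))
        if read is None:
            continue
        ridx = next(
            (x for x, rec in enumerate(index.records) if rec.record_id == anchor.record_id),
            None,
        )
        if ridx is None:
            continue
        ref = index.encoded[ridx]
        rl = len(read.sequence)
        # the rescued mate sits downstream of a '+' anchor (and is reverse
        # complemented), upstream of a '-' anchor
        if anchor.strand == "+":
            lo = anchor.pos
            hi = min(len(ref) - rl, anchor.pos + window - rl)
            arr = align.encode(revcomp(read.sequence))
            strand = "-"
        else:
            lo = max(0, anchor.ref_end - window)
            hi = anchor.ref_end - rl
            arr = align.encode(read.sequence)
            strand = "+"
        if hi < lo:
            continue
        best_matches, best_pos = -1, None
        for offset in range(lo, hi + 1):
            matches = align.ungapped_matches(arr, ref[offset:offset + rl])
            if matches > best_matches:
                best_matches, best_pos = matches, offset
        if best_pos is None:
            continue
        identity = best_matches / rl
        if identity < min_rescue_identity:
            continue
        mappings[i] = MappingRecord(
            m.read_id, m.mate, anchor.record_id, best_pos, strand,
            [("M", rl)], identity, 2 * best_matches - rl, paired_proper=True,
        )
        anchor.paired_proper = True


def partition_reads(
    mappings: Sequence[MappingRecord],
    reads: Sequence[ReadRecord],
    clusters,
    min_identity: float = 0.8,
) -> list[ReadPartition]:
    """Bait reads per cluster: a read (and its mate) joins every cluster
    whose [region_start, region_end) its alignment interval (any co-best
    placement) overlaps by at least 1 bp.
    """
    read_lookup = {(r.read_id, r.mate): r for r in reads}
    mapping_by_key = {(m.read_id, m.mate): m for m in mappings}
    partitions = []
    for cl in clusters:
        keys: set[tuple[str, str]] = set()
        for m in mappings:
            if not m.mapped:
                continue
            for rec_id, start, end in m.intervals():
                if rec_id != cl.record_id:
                    continue
                if start < cl.region_end and end > cl.region_start:
                    keys.add((m.read_id, m.mate))
                    mate = _pair_key(m.mate)
                    if mate and (m.read_id, mate) in read_lookup:
                        keys.add((m.read_id, mate))
                    break
        members = [read_lookup[key] for key in sorted(keys) if key in read_lookup]
        identities = []
        n_mapped = 0
        covered = 0
        for key in sorted(keys):
            m = mapping_by_key.get(key)
            if m is not None and m.mapped:
                identities.append(m.identity)
                if m.identity >= min_identity:
                    n_mapped += 1
                for rec_id, start, end in m.intervals():
                    if rec_id == cl.record_id:
                        covered += max(
                            0, min(end, cl.region_end) - max(start, cl.region_start)
                        )
                        break
        region_len = max(1, cl.region_end - cl.region_start)
        partitions.append(
            ReadPartition(
                cl.cluster_id,
                members,
                mapped_fraction=n_mapped / len(members) if members else 0.0,
                mean_identity=statistics.fmean(identities) if identities else 0.0,
                mean_depth=covered / region_len,
            )
        )
    return partitions


_MATE_FLAGS = {"single": 0, "first": 0x1 | 0x40, "second": 0x1 | 0x80}


def write_sam(
    mappings: Sequence[MappingRecord],
    reads: Sequence[ReadRecord],
    genome: Sequence[GenomeRecord],
    path: str,
) -> None:
    """Serialize mappings as plain SAM (QNAME/FLAG/RNAME/POS/MAPQ/CIGAR)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rec.record_id, "LN": len(rec.sequence)} for rec in genome],
    }
    tid = {rec.record_id: i for i, rec in enumerate(genome)}
    read_lookup = {(r.read_id, r.mate): r for r in reads}
    with pysam.AlignmentFile(path, "w", header=header) as handle:
        for m in mappings:
            read = read_lookup.get((m.read_id, m.mate))
            if read is None:
                continue
            seg = pysam.AlignedSegment(handle.header)
            seg.query_name = m.read_id
            flag = _MATE_FLAGS[m.mate]
            seq = read.sequence
            quals = list(read.qualities)
            if m.mapped:
                if m.strand == "-":
                    flag |= 0x10
                    seq = revcomp(seq)
                    quals = quals[::-1]
                if m.paired_proper:
                    flag |= 0x2
                seg.reference_id = tid[m.record_id]
                seg.reference_start = m.pos
                seg.mapping_quality = 60 if len(m.co_best) <= 1 else 0
                seg.cigarstring = align.cigar_to_string(m.cigar)
            else:
                flag |= 0x4
                seg.mapping_quality = 0
            seg.flag = flag
            seg.query_sequence = seq
            seg.query_qualities = quals
            seg.set_tag("XI", round(m.identity, 6))
            handle.write(seg)


def read_sam(path: str, genome: Sequence[GenomeRecord]) -> list[MappingRecord]:
    """Ingest external alignments; identity is recomputed from CIGAR + reference."""
    seqs = {rec.record_id: rec.sequence for rec in genome}
    out: list[MappingRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as handle:
        for seg in handle:
            if seg.is_paired:
                mate = "first" if seg.is_read1 else "second"
            else:
                mate = "single"
            if seg.is_unmapped or seg.reference_name not in seqs:
                out.append(MappingRecord(seg.query_name, mate, None))
                continue
            strand = "-" if seg.is_reverse else "+"
            cigar: list[tuple[str, int]] = []
            for op_code, length in seg.cigartuples or []:
                op = "MIDNSHP=X"[op_code]
                if op in "=X":
                    op = "M"
                elif op == "H":
                    op = "S"
                elif op not in "MIDS":
                    raise ValueError(f"unsupported CIGAR op {op!r} in {path}")
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + length)
                else:
                    cigar.append((op, length))
            ref = seqs[seg.reference_name]
            query = seg.query_sequence or ""
            matches = columns = 0
            qi, ri = 0, seg.reference_start
            for op, length in cigar:
                if op == "M":
                    for t in range(length):
                        if qi + t < len(query) and query[qi + t] == ref[ri + t]:
                            matches += 1
                    qi += length
                    ri += length
                    columns += length
                elif op == "I":
                    qi += length
                    columns += length
                elif op == "D":
                    ri += length
                    columns += length
                else:
                    qi += length
            identity = matches / columns if columns else 0.0
            out.append(
                MappingRecord(
                    seg.query_name, mate, seg.reference_name, seg.reference_start,
                    strand, cigar, identity, 2 * matches - columns,
                    paired_proper=seg.is_proper_pair,
                )
            )
    _flag_proper_pairs(out)
    return out


def depth_array(
    mappings: Iterable[MappingRecord], genome: Sequence[GenomeRecord]
) -> dict[str, np.ndarray]:
    """Per-base primary-alignment depth over each reference record."""
    depth = {rec.record_id: np.zeros(len(rec.sequence), dtype=np.int32) for rec in genome}
    for m in mappings:
        if not m.mapped or m.record_id not in depth:
            continue
        arr = depth[m.record_id]
        arr[m.pos:min(len(arr), m.ref_end)] += 1
    return depth
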