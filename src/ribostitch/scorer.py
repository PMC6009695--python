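"""Classify each reference rDNA region in an assembly by flank matching.

Each cluster's upstream and downstream reference flanks are located in
the assembly with the built-in local aligner (BLAST-like thresholds). The
geometry of the matches determines the call: correct, unassembled,
incorrect or ambiguous. Also counts substitutions between two assemblies
over the rDNA regions.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import Literal, Sequence

from . import align
from .seqio import GenomeRecord, revcomp

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FlankMatch:
    cluster_id: int
    side: Literal["upstream", "downstream"]
    contig_id: str
    contig_start: int
    contig_end: int
    strand: Literal["+", "-"]
    identity: float
    coverage_of_flank: float
    flank_start_offset: int = 0  # first flank base included in the match


@dataclasses.dataclass
class JunctionCall:
    cluster_id: int
    category: Literal["correct", "unassembled", "incorrect", "ambiguous"]
    evidence: list[FlankMatch]
    note: str = ""


def _find_local_matches(
    flank: str,
    contig: GenomeRecord,
    k: int = 21,
    min_identity: float = 0.95,
    min_coverage: float = 0.5,
    band: int = 15,
    stride: int = 3,
) -> list[dict]:
    """All placements of ``flank`` within one contig passing thresholds."""
    hits: list[dict] = []
    cseq = contig.sequence
    c_arr = align.encode(cseq)
    contig_kmers: dict[str, list[int]] = {}
    for i in range(len(cseq) - k + 1):
        contig_kmers.setdefault(cseq[i:i + k], []).append(i)
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        if len(query) < k:
            continue
        votes: Counter = Counter()
        for i in range(0, len(query) - k + 1, stride):
            for pos in contig_kmers.get(query[i:i + k], []):
                votes[pos - i] += 1
        if not votes:
            continue
        # cluster nearby diagonals into candidate placements
        diags = sorted(votes)
        groups: list[list[int]] = [[diags[0]]]
        for d in diags[1:]:
            if d - groups[-1][-1] <= band:
                groups[-1].append(d)
            else:
                groups.append([d])
        q_arr = align.encode(query)
        for group in groups:
            diag = max(group, key=lambda d: votes[d])
            matches, overlap, q_start, q_end = align.place_ungapped(q_arr, c_arr, diag)
            if overlap == 0:
                continue
            identity = matches / overlap
            if identity < min_identity and identity >= min_identity - 0.1 and len(group) > 1:
                # possible indel: banded alignment over the local window
                w_start = max(0, diag - band)
                w_end = min(len(cseq), diag + len(query) + band)
                try:
                    res = align.banded_global(query, cseq[w_start:w_end], band=band)
                except ValueError:
                    res = None
                if res is not None and res.identity > identity:
                    identity = res.identity
                    q_start, q_end = 0, len(query)
                    diag = w_start
                    overlap = len(query)
            coverage = overlap / len(flank)
            if identity >= min_identity and coverage >= min_coverage:
                start = diag + q_start
                end = diag + q_end
                if strand == "+":
                    flank_offset = q_start
                else:
                    flank_offset = len(query) - q_end
                hits.append(
                    {
                        "contig_id": contig.record_id,
                        "contig_start": start,
                        "contig_end": end,
                        "strand": strand,
                        "identity": identity,
                        "coverage": coverage,
                        "flank_offset": flank_offset,
                    }
                )
    # dedupe placements that landed on the same spot
    unique: dict[tuple, dict] = {}
    for hit in hits:
        key = (hit["contig_id"], hit["strand"], hit["contig_start"] // (band + 1))
        if key not in unique or hit["identity"] > unique[key]["identity"]:
            unique[key] = hit
    return list(unique.values())


def match_flanks(
    reference: Sequence[GenomeRecord],
    clusters,
    assembly: Sequence[GenomeRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.5,
    min_flank_length: int = 100,
) -> list[FlankMatch]:
    """Locate each cluster's reference flanks in the assembly contigs.

    All qualifying hits are retained; multiplicity matters for the
    ambiguity call downstream.
    """
    ref_seqs = {rec.record_id: rec.sequence for rec in reference}
    matches: list[FlankMatch] = []
    for cl in clusters:
        seq = ref_seqs[cl.record_id]
        flanks = {
            "upstream": seq[cl.region_start:cl.span_start],
            "downstream": seq[cl.span_end:cl.region_end],
        }
        for side, flank in flanks.items():
            if len(flank) < min_flank_length:
                logger.warning(
                    "cluster %d %s flank is only %d bp after clamping; skipped",
                    cl.cluster_id, side, len(flank),
                )
                continue
            for contig in assembly:
                for hit in _find_local_matches(
                    flank, contig, min_identity=min_identity, min_coverage=min_coverage
                ):
                    matches.append(
                        FlankMatch(
                            cl.cluster_id, side, hit["contig_id"],
                            hit["contig_start"], hit["contig_end"], hit["strand"],
                            hit["identity"], hit["coverage"], hit["flank_offset"],
                        )
                    )
    return matches


def _pair_geometry(up: FlankMatch, down: FlankMatch, span: int,
                   tolerance: float) -> tuple[bool, bool, bool]:
    """(same_orientation, reference_order, span_ok) for an up/down pair on
    one contig."""
    same_orientation = up.strand == down.strand
    if up.strand == "+":
        gap = down.contig_start - up.contig_end
    else:
        gap = up.contig_start - down.contig_end
    reference_order = gap > -(tolerance * span + 50)
    span_ok = abs(gap - span) <= tolerance * span
    return same_orientation, reference_order, span_ok


def _truncated_by_contig_end(
    match: FlankMatch, contig_lengths: dict[str, int], span: int,
    flank_length: int, min_extension: float,
) -> bool:
    """True if, projecting the rDNA region through this match, a contig
    end falls strictly inside it (the assembly stops in the region)."""
    length = contig_lengths.get(match.contig_id)
    if length is None:
        return False
    needed = int(0.8 * span)
    inward = (match.side == "upstream") == (match.strand == "+")
    if inward:
        remaining = length - match.contig_end
    else:
        remaining = match.contig_start
    if match.coverage_of_flank < min_extension:
        # flank itself cut short: truncation only if the cut is at a contig end
        at_end = match.contig_start <= 2 or match.contig_end >= length - 2
        if at_end:
            return True
    return remaining < needed


def classify_junction(
    cluster,
    matches: Sequence[FlankMatch],
    rdna_span_length: int | None = None,
    flank_length: int | None = None,
    min_extension: float = 0.9,
    span_tolerance: float = 0.2,
    contig_lengths: dict[str, int] | None = None,
    foreign_matches: Sequence[FlankMatch] = (),
) -> JunctionCall:
    """Call one cluster's junction from its flank matches.

    correct: both flanks on one contig, same orientation, reference
    order, separated by ~ the rDNA span (within ``span_tolerance``), each
    covering >= ``min_extension`` of the flank. incorrect: a same-contig
    pairing contradicting that geometry, or a flank paired across the
    rDNA with a different cluster's flank. unassembled: a contig end falls
    inside the projected region. ambiguous: anything the evidence cannot
    distinguish (including multiple conflicting correct candidates).
    """
    if rdna_span_length is None:
        rdna_span_length = cluster.span_end - cluster.span_start
    if flank_length is None:
        flank_length = getattr(cluster, "flank", 1000)
    if contig_lengths is None:
        contig_lengths = {}
    cid = cluster.cluster_id
    own = [m for m in matches if m.cluster_id == cid]
    ups = [m for m in own if m.side == "upstream"]
    downs = [m for m in own if m.side == "downstream"]

    if not own:
        return JunctionCall(cid, "unassembled", [], "no flank matches in assembly")

    valid_pairs: list[tuple[FlankMatch, FlankMatch]] = []
    bad_pairs: list[tuple[FlankMatch, FlankMatch, str]] = []
    for up in ups:
        for down in downs:
            if up.contig_id != down.contig_id:
                continue
            same_orientation, reference_order, span_ok = _pair_geometry(
                up, down, rdna_span_length, span_tolerance
            )
            covered = (
                up.coverage_of_flank >= min_extension
                and down.coverage_of_flank >= min_extension
            )
            if same_orientation and reference_order and span_ok and covered:
                valid_pairs.append((up, down))
            elif not same_orientation or (same_orientation and not reference_order):
                if covered:
                    bad_pairs.append((up, down, "orientation/order conflict"))

    if len(valid_pairs) == 1:
        up, down = valid_pairs[0]
        return JunctionCall(cid, "correct", [up, down], "flanks syntenous across rDNA")
    if len(valid_pairs) > 1:
        placements = {
            (u.contig_id, u.contig_start // 50, u.strand) for u, _ in valid_pairs
        }
        if len(placements) == 1:
            up, down = valid_pairs[0]
            return JunctionCall(cid, "correct", [up, down], "flanks syntenous across rDNA")
        return JunctionCall(
            cid, "ambiguous",
            [m for pair in valid_pairs for m in pair],
            "multiple co-best junction placements",
        )

    # cross-cluster chimera: one of our flanks sits across the rDNA span
    # from a different cluster's flank on the same contig
    for mine in own:
        if mine.coverage_of_flank < min_extension:
            continue
        for other in foreign_matches:
            if other.cluster_id == cid or other.contig_id != mine.contig_id:
                continue
            if mine.side == "upstream" and other.side == "downstream":
                up, down = mine, other
            elif mine.side == "downstream" and other.side == "upstream":
                up, down = other, mine
            else:
                continue
            same_orientation, reference_order, span_ok = _pair_geometry(
                up, down, rdna_span_length, span_tolerance
            )
            if same_orientation and reference_order and span_ok and (
                other.coverage_of_flank >= min_extension
            ):
                return JunctionCall(
                    cid, "incorrect", [mine, other],
                    f"flank joined across rDNA to cluster {other.cluster_id}",
                )

    if bad_pairs:
        up, down, note = bad_pairs[0]
        return JunctionCall(cid, "incorrect", [up, down], note)

    truncated = [
        m for m in own
        if _truncated_by_contig_end(
            m, contig_lengths, rdna_span_length, flank_length, min_extension
        )
    ]
    if truncated:
        return JunctionCall(
            cid, "unassembled", truncated, "contig end inside rDNA region"
        )
    if not ups or not downs:
        return JunctionCall(
            cid, "unassembled", own, "one flank absent from assembly"
        )
    return JunctionCall(cid, "ambiguous", own, "evidence does not distinguish")


def score_assembly(
    reference: Sequence[GenomeRecord],
    clusters,
    assembly: Sequence[GenomeRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.5,
    min_extension: float = 0.9,
    span_tolerance: float = 0.2,
) -> tuple[list[JunctionCall], dict[str, int]]:
    """One junction call per cluster plus summary counts."""
    clusters = list(clusters)
    if not assembly:
        calls = [
            JunctionCall(cl.cluster_id, "unassembled", [], "empty assembly")
            for cl in clusters
        ]
    else:
        matches = match_flanks(
            reference, clusters, assembly, min_identity, min_coverage
        )
        contig_lengths = {c.record_id: len(c.sequence) for c in assembly}
        calls = []
        for cl in clusters:
            own = [m for m in matches if m.cluster_id == cl.cluster_id]
            foreign = [m for m in matches if m.cluster_id != cl.cluster_id]
            calls.append(
                classify_junction(
                    cl, own,
                    min_extension=min_extension,
                    span_tolerance=span_tolerance,
                    contig_lengths=contig_lengths,
                    foreign_matches=foreign,
                )
            )
    summary = {"correct": 0, "unassembled": 0, "incorrect": 0, "ambiguous": 0}
    for call in calls:
        summary[call.category] += 1
    return calls, summary


def write_score_tsv(calls: Sequence[JunctionCall], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "cluster_id\tcategory\tcontigs\tidentities\textension_fractions\tnote\n"
        )
        for call in calls:
            contigs = ",".join(dict.fromkeys(m.contig_id for m in call.evidence)) or "-"
            idents = ",".join(f"{m.identity:.4f}" for m in call.evidence) or "-"
            exts = ",".join(f"{m.coverage_of_flank:.3f}" for m in call.evidence) or "-"
            handle.write(
                f"{call.cluster_id}\t{call.category}\t{contigs}\t{idents}\t{exts}\t{call.note}\n"
            )


# ---------------------------------------------------------------------------
# region SNP counting

@dataclasses.dataclass
class RegionSnps:
    cluster_id: int
    region_start: int
    region_end: int
    substitutions: list[tuple[int, str, str]]  # pos in assembly_a coords
    indels: int
    alignable: bool


def count_region_snps(
    assembly_a: Sequence[GenomeRecord],
    assembly_b: Sequence[GenomeRecord],
    clusters,
    flank: int = 1000,
    k: int = 21,
    band: int = 50,
) -> tuple[list[RegionSnps], int]:
    """Substitutions between two assemblies over each rDNA region +/- flank.

    Regions are taken from ``assembly_a`` via the cluster coordinates, the
    best local placement is found in ``assembly_b``, and substitution
    columns are listed in assembly_a coordinates. Indels are tallied
    separately and not counted as SNPs. Regions aligning below 80%
    identity are marked unalignable and excluded from the total.
    """
    a_seqs = {rec.record_id: rec.sequence for rec in assembly_a}
    results: list[RegionSnps] = []
    total = 0
    for cl in clusters:
        seq_a = a_seqs[cl.record_id]
        start = max(0, cl.span_start - flank)
        end = min(len(seq_a), cl.span_end + flank)
        region = seq_a[start:end]
        best = None  # (matches, contig, strand, offset, q_start, q_end)
        for contig in assembly_b:
            cseq = contig.sequence
            contig_kmers: dict[str, list[int]] = {}
            for i in range(len(cseq) - k + 1):
                contig_kmers.setdefault(cseq[i:i + k], []).append(i)
            for strand, query in (("+", region), ("-", revcomp(region))):
                votes: Counter = Counter()
                for i in range(0, len(query) - k + 1, 7):
                    for pos in contig_kmers.get(query[i:i + k], []):
                        votes[pos - i] += 1
                if not votes:
                    continue
                diag, _ = votes.most_common(1)[0]
                q_arr = align.encode(query)
                c_arr = align.encode(cseq)
                matches, overlap, q_start, q_end = align.place_ungapped(
                    q_arr, c_arr, diag
                )
                if overlap == 0:
                    continue
                if best is None or matches > best[0]:
                    best = (matches, contig, strand, diag, q_start, q_end)
        if best is None:
            logger.warning("cluster %d region unalignable in second assembly", cl.cluster_id)
            results.append(RegionSnps(cl.cluster_id, start, end, [], 0, False))
            continue
        matches, contig, strand, diag, q_start, q_end = best
        query = region if strand == "+" else revcomp(region)
        overlap = q_end - q_start
        identity = matches / overlap if overlap else 0.0
        subs: list[tuple[int, str, str]] = []
        indels = 0
        if identity >= 0.995 and overlap == len(region):
            target = contig.sequence[diag:diag + len(query)]
            for i, (qa, tb) in enumerate(zip(query, target)):
                if qa != tb:
                    pos = start + i if strand == "+" else start + len(region) - 1 - i
                    base_a = region[pos - start]
                    base_b = tb if strand == "+" else revcomp(tb)
                    subs.append((pos, base_a, base_b))
        else:
            w_start = max(0, diag - band)
            w_end = min(len(contig.sequence), diag + len(query) + band)
            try:
                res = align.banded_global(
                    query, contig.sequence[w_start:w_end], band=band
                )
            except ValueError:
                res = None
            if res is None or res.identity < 0.8:
                logger.warning(
                    "cluster %d region aligns below 80%% identity; excluded",
                    cl.cluster_id,
                )
                results.append(RegionSnps(cl.cluster_id, start, end, [], 0, False))
                continue
            qi = ri = 0
            target = contig.sequence[w_start:w_end]
            for op, length in res.cigar:
                if op == "M":
                    for t in range(length):
                        qa, tb = query[qi + t], target[ri + t]
                        if qa != tb:
                            i = qi + t
                            pos = (
                                start + i if strand == "+"
                                else start + len(region) - 1 - i
                            )
                            base_a = region[pos - start]
                            base_b = tb if strand == "+" else revcomp(tb)
                            subs.append((pos, base_a, base_b))
                    qi += length
                    ri += length
                elif op == "I":
                    qi += length
                    indels += 1
                else:
                    ri += length
                    indels += 1
        subs.sort()
        results.append(RegionSnps(cl.cluster_id, start, end, subs, indels, True))
        total += len(subs)
    return results, total
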