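"""Generative machinery for validation: synthetic multi-operon genomes,
artificial chromosomes, reference mutation models, and a paired-end short
read simulator. Every generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import FeatureAnnotation, GenomeRecord, ReadRecord, revcomp

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class SimulationConfig:
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: float = 10.0
    coverage: float = 30.0
    per_base_error: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be < insert_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclasses.dataclass
class MutationLog:
    model: Literal["uniform", "flanking_only"]
    frequency: float
    substitutions: list[tuple[int, str, str]]  # (position, ref_base, alt_base)

    def __len__(self) -> int:
        return len(self.substitutions)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def synth_operon_genome(
    n_operons: int,
    operon_length: int = 5000,
    flank_length: int = 1500,
    genome_length: int | None = None,
    divergence_between_flanks: float | None = None,
    seed: int = 0,
) -> tuple[GenomeRecord, list[FeatureAnnotation]]:
    """Random genome with ``n_operons`` identical rRNA operon copies.

    Each copy is planted at a well-separated position and surrounded by
    its own unique random flanks of ``flank_length``; the rest is random
    background. Emits 16S/23S/5S features (3 per operon). If
    ``divergence_between_flanks`` is given, flanks are mutated copies of a
    shared template at that per-base divergence instead of independent
    random sequence.
    """
    rng = np.random.default_rng(seed)
    block = operon_length + 2 * flank_length
    if genome_length is None:
        genome_length = n_operons * block + (n_operons + 1) * max(500, flank_length // 2)
    if n_operons * block > genome_length:
        raise ValueError(
            f"cannot pack {n_operons} operons of {block} bp into {genome_length} bp"
        )

    operon = _random_dna(rng, operon_length)
    # subunit layout inside the operon, scaled to its length
    s16 = max(1, int(operon_length * 0.30))
    s23 = max(1, int(operon_length * 0.55))
    s5 = max(1, int(operon_length * 0.03))
    gap1 = max(0, int(operon_length * 0.05))
    off16 = (0, s16)
    off23 = (s16 + gap1, s16 + gap1 + s23)
    off5 = (off23[1] + gap1, min(operon_length, off23[1] + gap1 + s5))

    flank_template = None
    if divergence_between_flanks is not None:
        flank_template = _random_dna(rng, flank_length)

    def make_flank() -> str:
        if flank_template is None:
            return _random_dna(rng, flank_length)
        arr = np.frombuffer(flank_template.encode(), dtype=np.uint8).copy()
        hits = rng.random(flank_length) < divergence_between_flanks
        for i in np.flatnonzero(hits):
            choices = BASES[BASES != arr[i]]
            arr[i] = rng.choice(choices)
        return arr.tobytes().decode("ascii")

    spare = genome_length - n_operons * block
    gap = spare // (n_operons + 1)
    parts: list[str] = []
    features: list[FeatureAnnotation] = []
    cursor = 0
    record_id = "synthetic_genome"
    for i in range(n_operons):
        bg = _random_dna(rng, gap)
        parts.append(bg)
        cursor += len(bg)
        up = make_flank()
        parts.append(up)
        cursor += flank_length
        operon_start = cursor
        parts.append(operon)
        for (s, e), kind in ((off16, "rRNA_16S"), (off23, "rRNA_23S"), (off5, "rRNA_5S")):
            features.append(
                FeatureAnnotation(
                    record_id, operon_start + s, operon_start + e, "+", kind,
                    f"{kind[5:]} ribosomal RNA (copy {i + 1})",
                )
            )
        cursor += operon_length
        parts.append(make_flank())
        cursor += flank_length
    tail = genome_length - cursor
    parts.append(_random_dna(rng, tail))
    genome = GenomeRecord(record_id, "".join(parts), description="synthetic multi-operon genome")
    assert len(genome.sequence) == genome_length
    return genome, features


def build_artificial_chromosome(
    genome: GenomeRecord,
    clusters,
    flank: int = 5000,
) -> tuple[GenomeRecord, list[dict]]:
    """Concatenate each cluster's span +/- ``flank`` into one chromosome.

    Overlapping extracted regions are merged with a warning. Returns the
    chromosome and a truth table mapping each extracted region (and its
    source coordinates) to chromosome coordinates.
    """
    length = len(genome.sequence)
    raw = []
    for cl in clusters:
        start = max(0, cl.span_start - flank)
        end = min(length, cl.span_end + flank)
        raw.append((start, end, [cl.cluster_id]))
    raw.sort()
    merged: list[list] = []
    for start, end, ids in raw:
        if merged and start < merged[-1][1]:
            logger.warning("extracted regions overlap; merging clusters %s and %s",
                           merged[-1][2], ids)
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2].extend(ids)
        else:
            merged.append([start, end, list(ids)])
    parts = []
    truth = []
    cursor = 0
    for start, end, ids in merged:
        seq = genome.sequence[start:end]
        truth.append(
            {
                "cluster_ids": ids,
                "source_start": start,
                "source_end": end,
                "chrom_start": cursor,
                "chrom_end": cursor + len(seq),
            }
        )
        parts.append(seq)
        cursor += len(seq)
    chrom = GenomeRecord(
        "artificial_chromosome", "".join(parts),
        description=f"concatenated rDNA regions +/-{flank} bp",
    )
    return chrom, truth


def mutate(
    genome: GenomeRecord,
    frequency: float,
    model: Literal["uniform", "flanking_only"] = "uniform",
    rdna_spans: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> tuple[GenomeRecord, MutationLog]:
    """Substitute bases at geometrically distributed gaps (rate ``frequency``).

    ``uniform`` draws substitution positions across the whole sequence;
    ``flanking_only`` runs the same process but skips positions inside any
    rDNA span, leaving those bases untouched. The substituted base is
    drawn uniformly from the three alternatives.
    """
    if not 0.0 <= frequency <= 0.3:
        raise ValueError("frequency must be in [0, 0.3]")
    log = MutationLog(model, frequency, [])
    if frequency == 0.0:
        return GenomeRecord(genome.record_id, genome.sequence, genome.topology,
                            genome.description), log
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    length = len(arr)
    in_rdna = np.zeros(length, dtype=bool)
    for start, end in rdna_spans:
        in_rdna[max(0, start):min(length, end)] = True
    pos = -1
    while True:
        pos += int(rng.geometric(frequency))
        if pos >= length:
            break
        if model == "flanking_only" and in_rdna[pos]:
            continue
        old = arr[pos]
        choices = BASES[BASES != old]
        new = rng.choice(choices)
        arr[pos] = new
        log.substitutions.append((pos, chr(old), chr(new)))
    mutated = GenomeRecord(
        genome.record_id, arr.tobytes().decode("ascii"), genome.topology,
        f"{genome.description} (mutated f={frequency} model={model})".strip(),
    )
    return mutated, log


def _error_quality(per_base_error: float) -> int:
    if per_base_error <= 0:
        return 40
    return min(40, max(2, round(-10.0 * math.log10(per_base_error))))


def simulate_reads(
    genome: GenomeRecord,
    config: SimulationConfig,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[dict]]:
    """Simulate paired-end reads from a genome.

    Pair count = round(coverage * L / (2 * read_length)). Fragment starts
    are uniform; insert sizes are Normal(insert_mean, insert_sd), rounded
    and clamped into [read_length, L]. Mate 1 is the fragment 5' end on
    the forward strand; mate 2 is the reverse complement of the fragment
    3' end. Bases are substituted independently at per_base_error; quality
    strings are constant at the Phred score of that error rate. Truth
    placements are returned for mapper tests.
    """
    rng = np.random.default_rng(config.seed)
    seq = genome.sequence
    length = len(seq)
    if length <= config.insert_mean + 4 * config.insert_sd:
        raise ValueError("genome too short for configured insert size")
    rl = config.read_length
    n_pairs = round(config.coverage * length / (2 * rl))
    qual = _error_quality(config.per_base_error)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs)).astype(int)
    inserts = np.clip(inserts, rl, length)
    starts = (rng.random(n_pairs) * (length - inserts + 1)).astype(int)

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truth: list[dict] = []
    quals = [qual] * rl
    for idx in range(n_pairs):
        start = int(starts[idx])
        insert = int(inserts[idx])
        frag1 = arr[start:start + rl].copy()
        frag2 = arr[start + insert - rl:start + insert].copy()
        if config.per_base_error > 0:
            for frag in (frag1, frag2):
                hits = np.flatnonzero(rng.random(rl) < config.per_base_error)
                for i in hits:
                    choices = BASES[BASES != frag[i]]
                    frag[i] = rng.choice(choices)
        seq1 = frag1.tobytes().decode("ascii")
        seq2 = revcomp(frag2.tobytes().decode("ascii"))
        rid = f"sim_{idx}"
        pairs.append(
            (
                ReadRecord(rid, seq1, list(quals), "first"),
                ReadRecord(rid, seq2, list(quals), "second"),
            )
        )
        truth.append(
            {
                "read_id": rid,
                "fragment_start": start,
                "insert": insert,
                "mate1_start": start,
                "mate2_start": start + insert - rl,
            }
        )
    return pairs, truth


def flatten_pairs(pairs: Iterable[tuple[ReadRecord, ReadRecord]]) -> list[ReadRecord]:
    reads: list[ReadRecord] = []
    for r1, r2 in pairs:
        reads.append(r1)
        reads.append(r2)
    return reads
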