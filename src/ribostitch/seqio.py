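"""Sequence/feature I/O and the coordinate conventions used pipeline-wide.

All internal coordinates are 0-based half-open. Conversion to/from the
1-based inclusive conventions of GFF3 and GenBank happens only here, at
the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Literal

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


@dataclasses.dataclass
class GenomeRecord:
    record_id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class FeatureAnnotation:
    record_id: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    strand: Literal["+", "-"]
    kind: Literal["rRNA_16S", "rRNA_23S", "rRNA_5S", "other"]
    source_label: str = ""

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclasses.dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int]
    mate: Literal["single", "first", "second"] = "single"

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and map IUPAC ambiguity codes (other than N) to N.

    Returns the normalized sequence and the number of bases changed to N.
    """
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq, 0
    normalized = []
    n_changed = 0
    for ch in seq:
        if ch in DNA_ALPHABET:
            normalized.append(ch)
        else:
            normalized.append("N")
            n_changed += 1
    return "".join(normalized), n_changed


def _header_line_numbers(path: Path) -> dict[str, int]:
    numbers: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith(">"):
                rid = line[1:].split()[0] if line[1:].strip() else ""
                numbers.setdefault(rid, lineno)
    return numbers


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Parse a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; non-ACGTN characters become N (count
    logged). Duplicate ids and empty sequences are parse errors that name
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = _header_line_numbers(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    total_normalized = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        lineno = lines.get(rec.id, 0)
        if not rec.id:
            raise ParseError(f"{path}:{lineno}: FASTA record with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq, n_changed = normalize_sequence(str(rec.seq))
        total_normalized += n_changed
        if not seq:
            raise ParseError(f"{path}:{lineno}: record {rec.id!r} has empty sequence")
        records.append(GenomeRecord(rec.id, seq, description=rec.description))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if total_normalized:
        logger.info("%s: normalized %d non-ACGTN bases to N", path, total_normalized)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, line_width: int = 70) -> None:
    records = list(records)
    if not records:
        raise ValueError("refusing to write empty FASTA")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.record_id}"
            if rec.description and rec.description != rec.record_id:
                desc = rec.description
                if desc.startswith(rec.record_id):
                    desc = desc[len(rec.record_id):].strip()
                if desc:
                    header += f" {desc}"
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), line_width):
                handle.write(rec.sequence[i:i + line_width] + "\n")


def read_fastq(path: str | Path, mate: str = "single") -> list[ReadRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq, _ = normalize_sequence(str(rec.seq))
        reads.append(ReadRecord(rec.id, seq, rec.letter_annotations["phred_quality"], mate))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[tuple[ReadRecord, ReadRecord]]:
    first = read_fastq(path1, mate="first")
    second = read_fastq(path2, mate="second")
    if len(first) != len(second):
        raise ParseError(
            f"paired FASTQ files differ in read count ({len(first)} vs {len(second)})"
        )
    return list(zip(first, second))


def classify_rrna_label(label: str) -> str:
    """Map a feature product/name string onto an rRNA subunit kind."""
    text = label.upper()
    for token, kind in (("16S", "rRNA_16S"), ("23S", "rRNA_23S"), ("5S", "rRNA_5S")):
        if token in text:
            return kind
    return "other"


def _check_bounds(feat: FeatureAnnotation, lengths: dict[str, int] | None, source: str) -> None:
    if lengths is None or feat.record_id not in lengths:
        return
    if not (0 <= feat.start < feat.end <= lengths[feat.record_id]):
        raise ParseError(
            f"{source}: feature {feat.source_label!r} at [{feat.start}, {feat.end}) "
            f"exceeds bounds of {feat.record_id} (length {lengths[feat.record_id]})"
        )


def read_features(
    path: str | Path,
    dialect: Literal["gff3", "genbank"] = "gff3",
    sequence_lengths: dict[str, int] | None = None,
) -> list[FeatureAnnotation]:
    """Read rRNA (and other) features from GFF3 or GenBank.

    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open. rRNA features are classified into 16S/23S/5S by
    case-insensitive substring match on the product/name text; an rRNA
    feature without a recognizable subunit becomes kind=other with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    feats: list[FeatureAnnotation] = []
    if dialect == "gff3":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for f in db.all_features():
            label_bits = []
            for key in ("product", "Name", "name", "gene", "ID"):
                if key in f.attributes:
                    label_bits.extend(f.attributes[key])
            label = " ".join(label_bits) or f.featuretype
            if f.featuretype.lower() == "rrna" or "rRNA" in label:
                kind = classify_rrna_label(label)
                if kind == "other":
                    logger.warning("%s: rRNA feature %r has no recognizable subunit", path, label)
            else:
                kind = "other"
            strand = "-" if f.strand == "-" else "+"
            feat = FeatureAnnotation(f.seqid, f.start - 1, f.end, strand, kind, label)
            _check_bounds(feat, sequence_lengths, str(path))
            feats.append(feat)
    elif dialect == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            for f in rec.features:
                if f.type.lower() != "rrna":
                    continue
                label = " ".join(
                    f.qualifiers.get("product", []) + f.qualifiers.get("gene", [])
                ) or f.type
                kind = classify_rrna_label(label)
                if kind == "other":
                    logger.warning("%s: rRNA feature %r has no recognizable subunit", path, label)
                strand = "-" if f.location.strand == -1 else "+"
                feat = FeatureAnnotation(
                    rec.id, int(f.location.start), int(f.location.end), strand, kind, label
                )
                _check_bounds(feat, {rec.id: len(rec.seq)}, str(path))
                _check_bounds(feat, sequence_lengths, str(path))
                feats.append(feat)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return feats


_GFF_KIND_LABEL = {
    "rRNA_16S": "16S ribosomal RNA",
    "rRNA_23S": "23S ribosomal RNA",
    "rRNA_5S": "5S ribosomal RNA",
    "other": "ribosomal RNA",
}


def write_gff3(features: Iterable[FeatureAnnotation], path: str | Path, source: str = "ribostitch") -> None:
    """Write features as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, feat in enumerate(features, 1):
            product = _GFF_KIND_LABEL.get(feat.kind, feat.kind)
            attrs = f"ID=rrna_{i};product={product}"
            handle.write(
                "\t".join(
                    [
                        feat.record_id,
                        source,
                        "rRNA",
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (record_id, start, end, name) intervals as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for record_id, start, end, name in intervals:
            handle.write(f"{record_id}\t{start}\t{end}\t{name}\n")


def genome_lengths(genome: Iterable[GenomeRecord]) -> dict[str, int]:
    return {rec.record_id: len(rec.sequence) for rec in genome}


def clamp_interval(start: int, end: int, length: int) -> tuple[int, int]:
    """Clamp an interval to [0, length); used for circular-origin features."""
    clamped = (max(0, start), min(length, end))
    if clamped != (start, end):
        logger.warning(
            "interval [%d, %d) clamped to sequence bounds [0, %d)", start, end, length
        )
    return clamped
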