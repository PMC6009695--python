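"""Obtain and normalize rRNA annotations on the reference (scan step).

Annotations can come from a provided feature file (the documented path
for real genomes: a Barrnap or RefSeq GFF), or from a built-in
exemplar-based k-mer detector intended for synthetic genomes and small
test cases.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .seqio import (
    FeatureAnnotation,
    GenomeRecord,
    classify_rrna_label,
    revcomp,
)

logger = logging.getLogger(__name__)

RRNA_KINDS = ("rRNA_16S", "rRNA_23S", "rRNA_5S")


class NoRRNAError(RuntimeError):
    pass


def _detect_exemplar(
    genome: GenomeRecord,
    exemplar: GenomeRecord,
    kind: str,
    k: int,
    density: float,
    min_fraction: float,
    merge_gap: int | None = None,
) -> list[FeatureAnnotation]:
    """Find intervals of ``genome`` sharing dense exact k-mers with ``exemplar``."""
    if merge_gap is None:
        # tolerate runs of broken k-mers between surviving seeds: at a few
        # percent divergence, gaps of several k are common
        merge_gap = 10 * k
    ex = exemplar.sequence
    ex_len = len(ex)
    if ex_len < k:
        return []
    kmers_fw = {ex[i:i + k] for i in range(ex_len - k + 1)}
    ex_rc = revcomp(ex)
    kmers_rc = {ex_rc[i:i + k] for i in range(ex_len - k + 1)}

    seq = genome.sequence
    hits: dict[str, list[int]] = {"+": [], "-": []}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in kmers_fw:
            hits["+"].append(i)
        if kmer in kmers_rc:
            hits["-"].append(i)

    features: list[FeatureAnnotation] = []
    for strand, positions in hits.items():
        if not positions:
            continue
        # merge hit positions into runs separated by at most merge_gap
        runs: list[list[int]] = [[positions[0]]]
        for pos in positions[1:]:
            if pos - runs[-1][-1] <= merge_gap:
                runs[-1].append(pos)
            else:
                runs.append([pos])
        for run in runs:
            start, end = run[0], run[-1] + k
            covered = 0
            prev_end = start
            for pos in run:
                covered += max(0, min(pos + k, end) - max(pos, prev_end))
                prev_end = max(prev_end, pos + k)
            interval_len = end - start
            if interval_len < min_fraction * ex_len:
                continue
            if covered / interval_len < density:
                continue
            features.append(
                FeatureAnnotation(
                    genome.record_id, start, end, strand, kind,
                    f"detected {kind.removeprefix('rRNA_')} rRNA",
                )
            )
    return features


def _merge_same_kind(features: list[FeatureAnnotation]) -> list[FeatureAnnotation]:
    """Merge overlapping detections of the same kind on a record."""
    merged: list[FeatureAnnotation] = []
    for feat in sorted(features, key=lambda f: (f.record_id, f.kind, f.start)):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.record_id == feat.record_id
            and prev.kind == feat.kind
            and feat.start < prev.end
        ):
            prev.end = max(prev.end, feat.end)
        else:
            merged.append(feat)
    return merged


def exemplar_kind(record: GenomeRecord) -> str:
    """Infer the subunit kind an exemplar record represents from its header."""
    label = f"{record.record_id} {record.description}"
    return classify_rrna_label(label)


def scan(
    genome: Sequence[GenomeRecord],
    features: Sequence[FeatureAnnotation] | None = None,
    exemplars: Sequence[GenomeRecord] | None = None,
    k: int = 31,
    density: float = 0.5,
    min_fraction: float = 0.8,
) -> list[FeatureAnnotation]:
    """Return normalized rRNA features for the reference genome.

    With ``features`` given, filters to the 16S/23S/5S kinds (features of
    kind=other are dropped with a warning). Otherwise detects rRNAs by
    exact k-mer sharing with the provided ``exemplars``: maximal intervals
    with shared-k-mer density >= ``density`` and merged length >=
    ``min_fraction`` of the exemplar length, strand from the k-mer
    orientation. Zero rRNAs found is a hard error.
    """
    if features is None and exemplars is None:
        raise ValueError("provide rRNA features or exemplar sequences")
    lengths = {g.record_id: len(g.sequence) for g in genome}

    result: list[FeatureAnnotation] = []
    if features is not None:
        for feat in features:
            if feat.kind in RRNA_KINDS:
                if feat.record_id in lengths and feat.end > lengths[feat.record_id]:
                    raise ValueError(
                        f"feature {feat.source_label!r} exceeds bounds of {feat.record_id}"
                    )
                result.append(feat)
            elif "rRNA" in feat.source_label or feat.kind == "other":
                logger.warning(
                    "dropping unclassifiable rRNA feature %r", feat.source_label
                )
    else:
        for rec in genome:
            for ex in exemplars:
                kind = exemplar_kind(ex)
                if kind == "other":
                    logger.warning(
                        "exemplar %r has no recognizable subunit in its header; "
                        "treating as kind=other", ex.record_id,
                    )
                result.extend(
                    _detect_exemplar(rec, ex, kind, k, density, min_fraction)
                )
        result = _merge_same_kind(result)
        result.sort(key=lambda f: (f.record_id, f.start))
    if not result:
        raise NoRRNAError(
            "no rRNA features found; supply annotations (e.g. a Barrnap GFF) "
            "with --features"
        )
    return result
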