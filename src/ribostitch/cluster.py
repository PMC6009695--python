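"""Group rRNA features into rDNA operon clusters.

One-dimensional clustering of feature midpoints with the exact
Fisher-Jenks natural-breaks dynamic program; the class count is the
number of 16S features on the record. The resulting cluster file is plain
text and may be hand-edited before assembly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import FeatureAnnotation, GenomeRecord, clamp_interval

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OperonCluster:
    cluster_id: int
    record_id: str
    members: list[FeatureAnnotation]
    span_start: int
    span_end: int
    flank: int = 1000
    region_start: int = 0
    region_end: int = 0

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start


def _prefix_stats(values: Sequence[float]):
    pref = [0.0]
    pref_sq = [0.0]
    for v in values:
        pref.append(pref[-1] + v)
        pref_sq.append(pref_sq[-1] + v * v)

    def cost(i: int, j: int) -> float:
        """Within-class sum of squared deviations of values[i:j]."""
        n = j - i
        if n <= 1:
            return 0.0
        s = pref[j] - pref[i]
        sq = pref_sq[j] - pref_sq[i]
        return sq - s * s / n

    return cost


def jenks_breaks(values: Sequence[float], n_classes: int) -> list[list[float]]:
    """Partition sorted ``values`` into ``n_classes`` contiguous groups
    minimizing the total within-class sum of squared deviations.

    Exact O(k n^2) dynamic program. Tie-break: among optimal partitions,
    the one with lexicographically smallest break positions.
    """
    values = list(values)
    if any(values[i] > values[i + 1] for i in range(len(values) - 1)):
        raise ValueError("values must be sorted ascending")
    n = len(values)
    distinct = len(set(values))
    if not 1 <= n_classes <= n:
        raise ValueError(f"n_classes must be in [1, {n}], got {n_classes}")
    if n_classes > distinct:
        raise ValueError(
            f"n_classes ({n_classes}) exceeds number of distinct values ({distinct})"
        )
    cost = _prefix_stats(values)

    # suffix DP: best[i][m] = minimal cost partitioning values[i:] into m classes.
    # Reconstructing left-to-right while preferring the smallest split index
    # yields the lexicographically smallest break positions among optima.
    INF = float("inf")
    best = [[INF] * (n_classes + 1) for _ in range(n + 1)]
    best[n][0] = 0.0
    for m in range(1, n_classes + 1):
        for i in range(n - 1, -1, -1):
            acc = INF
            # class values[i:j], then m-1 classes over values[j:]
            for j in range(i + 1, n + 1):
                rest = best[j][m - 1]
                if rest == INF:
                    continue
                total = cost(i, j) + rest
                if total < acc:
                    acc = total
            best[i][m] = acc

    groups: list[list[float]] = []
    i = 0
    eps = 1e-9
    for m in range(n_classes, 0, -1):
        target = best[i][m]
        for j in range(i + 1, n + 1):
            if best[j][m - 1] == INF:
                continue
            if cost(i, j) + best[j][m - 1] <= target + eps:
                groups.append(values[i:j])
                i = j
                break
    return groups


def select(
    features: Sequence[FeatureAnnotation],
    genome: Sequence[GenomeRecord] | None = None,
    flank: int = 1000,
) -> list[OperonCluster]:
    """Infer operon clusters from rRNA features, per record.

    The number of classes on each record is its 16S count (fallback:
    max(23S count, 1) with a warning if no 16S is present). Clusters are
    numbered 1..n by ascending span start, globally across records.
    """
    rrna = [f for f in features if f.kind in ("rRNA_16S", "rRNA_23S", "rRNA_5S")]
    if not rrna:
        raise ValueError("no rRNA features to cluster")
    lengths = {g.record_id: len(g.sequence) for g in genome} if genome else {}

    by_record: dict[str, list[FeatureAnnotation]] = {}
    for feat in rrna:
        by_record.setdefault(feat.record_id, []).append(feat)

    clusters: list[OperonCluster] = []
    for record_id in sorted(by_record):
        feats = sorted(by_record[record_id], key=lambda f: (f.midpoint, f.start))
        n16 = sum(1 for f in feats if f.kind == "rRNA_16S")
        if n16 == 0:
            n23 = sum(1 for f in feats if f.kind == "rRNA_23S")
            n_classes = max(n23, 1)
            logger.warning(
                "record %s has rRNAs but no 16S; falling back to %d classes",
                record_id, n_classes,
            )
        else:
            n_classes = n16
        midpoints = [f.midpoint for f in feats]
        n_classes = min(n_classes, len(set(midpoints)))
        groups = jenks_breaks(midpoints, n_classes)
        idx = 0
        record_clusters: list[OperonCluster] = []
        for group in groups:
            members = feats[idx: idx + len(group)]
            idx += len(group)
            span_start = min(f.start for f in members)
            span_end = max(f.end for f in members)
            record_clusters.append(
                OperonCluster(0, record_id, members, span_start, span_end, flank)
            )
        record_clusters.sort(key=lambda c: c.span_start)
        # merge spatially overlapping spans (pathological inputs)
        merged: list[OperonCluster] = []
        for cl in record_clusters:
            if merged and cl.span_start < merged[-1].span_end:
                logger.warning(
                    "clusters overlap on %s; merging spans [%d,%d) and [%d,%d)",
                    record_id, merged[-1].span_start, merged[-1].span_end,
                    cl.span_start, cl.span_end,
                )
                prev = merged[-1]
                prev.members.extend(cl.members)
                prev.span_end = max(prev.span_end, cl.span_end)
            else:
                merged.append(cl)
        clusters.extend(merged)

    clusters.sort(key=lambda c: (c.record_id, c.span_start))
    for i, cl in enumerate(clusters, 1):
        cl.cluster_id = i
        length = lengths.get(cl.record_id)
        start = cl.span_start - flank
        end = cl.span_end + flank
        if length is not None:
            start, end = clamp_interval(start, end, length)
        else:
            start = max(0, start)
        cl.region_start, cl.region_end = start, end
    return clusters


def _descriptor(feat: FeatureAnnotation) -> str:
    kind = feat.kind.removeprefix("rRNA_")
    return f"{kind}:{feat.start}-{feat.end}:{feat.strand}"


def write_cluster_file(clusters: Iterable[OperonCluster], path: str | Path) -> None:
    """One cluster per line: record_id, cluster_id, member descriptors."""
    with open(path, "w") as handle:
        for cl in clusters:
            desc = ",".join(_descriptor(f) for f in cl.members)
            handle.write(f"{cl.record_id}\t{cl.cluster_id}\t{desc}\n")


def load_cluster_file(
    path: str | Path,
    features: Sequence[FeatureAnnotation],
    genome: Sequence[GenomeRecord] | None = None,
    flank: int = 1000,
) -> list[OperonCluster]:
    """Rebuild clusters exactly as a (possibly hand-edited) file specifies.

    Features are matched by (record, kind, start, end, strand). A feature
    claimed by two clusters, or a descriptor with no matching feature, is
    an error.
    """
    lookup: dict[tuple, FeatureAnnotation] = {}
    for feat in features:
        kind = feat.kind.removeprefix("rRNA_")
        lookup[(feat.record_id, kind, feat.start, feat.end, feat.strand)] = feat

    lengths = {g.record_id: len(g.sequence) for g in genome} if genome else {}
    claimed: set[tuple] = set()
    clusters: list[OperonCluster] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        record_id, cid_text, desc_text = parts
        members = []
        for desc in desc_text.split(","):
            try:
                kind, coords, strand = desc.split(":")
                start_s, end_s = coords.split("-")
                key = (record_id, kind, int(start_s), int(end_s), strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad descriptor {desc!r}") from exc
            if key not in lookup:
                raise ValueError(f"{path}:{lineno}: descriptor {desc!r} matches no feature")
            if key in claimed:
                raise ValueError(f"{path}:{lineno}: feature {desc!r} claimed by two clusters")
            claimed.add(key)
            members.append(lookup[key])
        span_start = min(f.start for f in members)
        span_end = max(f.end for f in members)
        cl = OperonCluster(int(cid_text), record_id, members, span_start, span_end, flank)
        length = lengths.get(record_id)
        start = span_start - flank
        end = span_end + flank
        if length is not None:
            start, end = clamp_interval(start, end, length)
        else:
            start = max(0, start)
        cl.region_start, cl.region_end = start, end
        clusters.append(cl)
    if not clusters:
        raise ValueError(f"{path}: no clusters found")
    return clusters
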