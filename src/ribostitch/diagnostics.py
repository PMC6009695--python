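"""Diagnostics: per-column entropy over aligned rDNA regions (snag) and
rDNA-vs-background coverage comparison (stack)."""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from . import align as _align
from .seqio import GenomeRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EntropyProfile:
    columns: list[tuple[int, float, int]]  # (position, entropy_bits, consensus_depth)
    smoothing_window: int = 351

    @property
    def entropies(self) -> np.ndarray:
        return np.array([c[1] for c in self.columns])

    def smoothed(self) -> np.ndarray:
        return smooth(self.entropies, self.smoothing_window)


@dataclasses.dataclass
class CoverageComparison:
    rdna_mean_depth: float
    background_mean_depth: float
    ratio: float
    n_background_samples: int
    flag: bool
    background_intervals: list[tuple[int, int]] = dataclasses.field(default_factory=list)


def column_entropy(column: Sequence[str]) -> tuple[float, int]:
    """Shannon entropy (bits) of one alignment column over {A,C,G,T}.

    Gaps and N are excluded from both the distribution and the consensus
    depth; an all-gap column is (0, 0).
    """
    if len(column) == 0:
        raise ValueError("empty column")
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for ch in column:
        if ch in counts:
            counts[ch] += 1
    depth = sum(counts.values())
    if depth == 0:
        return 0.0, 0
    entropy = 0.0
    for n in counts.values():
        if n:
            p = n / depth
            entropy -= p * math.log2(p)
    return entropy, depth


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; at the edges the window shrinks
    symmetrically so it always fits."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    length = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(length)
    for i in range(length):
        h = min(half, i, length - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def snag(
    sequences: Sequence[GenomeRecord],
    window: int = 351,
    aligned: bool = True,
) -> EntropyProfile:
    """Per-column entropy + consensus depth over aligned sequences.

    With ``aligned=False`` a small built-in center-star aligner is used
    (intended for <= 10 sequences of <= 20 kb; for real data supply an
    external alignment).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = [rec.sequence for rec in sequences]
    if not aligned:
        seqs = center_star_align(seqs)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    columns = []
    for i in range(lengths.pop()):
        entropy, depth = column_entropy([s[i] for s in seqs])
        columns.append((i, entropy, depth))
    return EntropyProfile(columns, window)


def write_entropy_tsv(profile: EntropyProfile, path: str | Path) -> None:
    smoothed = profile.smoothed()
    with open(path, "w") as handle:
        handle.write("position\tentropy_bits\tconsensus_depth\tsmoothed_entropy\n")
        for (pos, entropy, depth), sm in zip(profile.columns, smoothed):
            handle.write(f"{pos}\t{entropy:.6f}\t{depth}\t{sm:.6f}\n")


def center_star_align(seqs: Sequence[str], band: int = 100) -> list[str]:
    """Center-star multiple alignment for small fixture inputs.

    The longest sequence is the center; every other sequence is aligned
    to it with the banded global aligner and the gap patterns merged.
    """
    if len(seqs) > 10 or max(len(s) for s in seqs) > 20000:
        raise ValueError(
            "built-in aligner is limited to <= 10 sequences of <= 20 kb; "
            "supply an external alignment"
        )
    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_idx]
    pairwise = []
    for i, seq in enumerate(seqs):
        if i == center_idx:
            continue
        res = _align.banded_global(seq, center, band=band)
        pairwise.append((i, res.cigar))

    # gap pattern of the center: per center base, max insertion length before it
    ins_before = [0] * (len(center) + 1)
    for _, cigar in pairwise:
        ci = 0
        for op, length in cigar:
            if op == "M" or op == "D":
                ci += length
            else:  # I: insertion relative to center, placed before center pos ci
                ins_before[ci] = max(ins_before[ci], length)
    col_of = [0] * (len(center) + 1)
    col = 0
    for ci in range(len(center) + 1):
        col += ins_before[ci]
        col_of[ci] = col
        col += 1
    total_cols = col_of[len(center)]  # column index just past last center base

    def render(seq: str, cigar) -> str:
        out = ["-"] * total_cols
        qi = ci = 0
        for op, length in cigar:
            if op == "M":
                for t in range(length):
                    out[col_of[ci + t]] = seq[qi + t]
                qi += length
                ci += length
            elif op == "D":
                ci += length
            else:  # I
                base_col = col_of[ci] - ins_before[ci]
                for t in range(length):
                    out[base_col + t] = seq[qi + t]
                qi += length
        return "".join(out)

    aligned = [""] * len(seqs)
    center_cigar = [("M", len(center))]
    aligned[center_idx] = render(center, center_cigar)
    for i, cigar in pairwise:
        aligned[i] = render(seqs[i], cigar)
    return aligned


def stack(
    clusters,
    depth: dict[str, np.ndarray],
    n_samples: int = 10,
    flag_ratio: float = 1.5,
    seed: int = 0,
) -> CoverageComparison:
    """Compare mean read depth inside rDNA cluster regions against
    randomly sampled non-rDNA background intervals of the same size.

    A ratio >= ``flag_ratio`` flags the reference as likely carrying fewer
    rDNA copies than the sequenced isolate.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters")
    rng = np.random.default_rng(seed)

    rdna_values: list[np.ndarray] = []
    region_lengths = []
    excluded: dict[str, list[tuple[int, int]]] = {}
    for cl in clusters:
        arr = depth[cl.record_id]
        rdna_values.append(arr[cl.region_start:cl.region_end])
        region_lengths.append(cl.region_end - cl.region_start)
        excluded.setdefault(cl.record_id, []).append((cl.region_start, cl.region_end))
    rdna_mean = float(np.concatenate(rdna_values).mean())
    sample_len = int(round(sum(region_lengths) / len(region_lengths)))

    # candidate background start positions: intervals that avoid all rDNA regions
    def find_candidates(size: int) -> list[tuple[str, int]]:
        found: list[tuple[str, int]] = []
        for record_id, arr in depth.items():
            length = len(arr)
            blocked = np.zeros(length, dtype=bool)
            for start, end in excluded.get(record_id, []):
                blocked[max(0, start):min(length, end)] = True
            bad_cum = np.concatenate([[0], np.cumsum(blocked)])
            for start in range(0, length - size + 1):
                if bad_cum[start + size] - bad_cum[start] == 0:
                    found.append((record_id, start))
        return found

    candidates = find_candidates(sample_len)
    if not candidates:
        # shrink to the largest rDNA-free run
        longest = 0
        for record_id, arr in depth.items():
            blocked = np.zeros(len(arr), dtype=bool)
            for start, end in excluded.get(record_id, []):
                blocked[max(0, start):min(len(arr), end)] = True
            run = 0
            for flag in blocked:
                run = 0 if flag else run + 1
                longest = max(longest, run)
        if longest == 0:
            raise ValueError("genome has no rDNA-free interval")
        logger.warning(
            "no rDNA-free interval of %d bp; shrinking background sample "
            "length to %d and reducing samples", sample_len, longest,
        )
        sample_len = longest
        candidates = find_candidates(sample_len)
    n = n_samples
    if n > len(candidates):
        n = len(candidates)
        logger.warning("only %d background intervals available; reduced n_samples", n)
    picks = rng.choice(len(candidates), size=n, replace=False)
    intervals = []
    values = []
    for idx in sorted(int(p) for p in picks):
        record_id, start = candidates[idx]
        intervals.append((start, start + sample_len))
        values.append(depth[record_id][start:start + sample_len])
    background_mean = float(np.concatenate(values).mean())
    if background_mean <= 0:
        raise ValueError("background depth is zero; cannot compute coverage ratio")
    ratio = rdna_mean / background_mean
    return CoverageComparison(
        rdna_mean, background_mean, ratio, n, ratio >= flag_ratio, intervals
    )
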