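"""End-to-end orchestration: scan -> select -> seed -> score, with a JSON
run manifest capturing parameters, input checksums and per-stage summaries."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from . import annotate, assembly, cluster as cluster_mod, scorer
from .config import PipelineConfig, auto_k
from .seqio import (
    FeatureAnnotation,
    GenomeRecord,
    ReadRecord,
    write_fasta,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    clusters: list
    pseudocontigs: list[assembly.Pseudocontig]
    iteration_stats: list[assembly.IterationStats]
    de_fere_novo: assembly.AssemblyResult
    de_novo: assembly.AssemblyResult
    de_fere_calls: list[scorer.JunctionCall]
    de_fere_summary: dict[str, int]
    de_novo_calls: list[scorer.JunctionCall]
    de_novo_summary: dict[str, int]


def run_de_fere_novo(
    reference: Sequence[GenomeRecord],
    features: Sequence[FeatureAnnotation],
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    config: PipelineConfig | None = None,
    truth: Sequence[GenomeRecord] | None = None,
) -> PipelineResult:
    """Run scan/select/seed/score in-process.

    ``truth``, when given, is the genome the reads were drawn from and is
    used for scoring instead of the (possibly divergent) reference; this
    mirrors scoring an assembly against the sequenced isolate.
    """
    cfg = config or PipelineConfig()
    rrna = annotate.scan(reference, features=features)
    clusters = cluster_mod.select(rrna, genome=reference, flank=cfg.flank)
    k = cfg.k or auto_k(max(len(r.sequence) for pair in pairs for r in pair))
    pseudocontigs, stats = assembly.seed_iterate(
        pairs, reference, clusters, iterations=cfg.iterations, k=k, config=cfg
    )
    de_fere, de_novo = assembly.final_assembly(pairs, pseudocontigs, k=k, config=cfg)

    score_ref = list(truth) if truth is not None else list(reference)
    if truth is not None:
        truth_rrna = annotate.scan(truth, features=features) if _features_fit(
            features, truth
        ) else rrna
        score_clusters = cluster_mod.select(truth_rrna, genome=truth, flank=cfg.flank)
    else:
        score_clusters = clusters
    fd_calls, fd_summary = scorer.score_assembly(
        score_ref, score_clusters, de_fere.contigs,
        min_identity=cfg.score_min_identity, min_coverage=cfg.score_min_coverage,
        min_extension=cfg.min_extension, span_tolerance=cfg.span_tolerance,
    )
    dn_calls, dn_summary = scorer.score_assembly(
        score_ref, score_clusters, de_novo.contigs,
        min_identity=cfg.score_min_identity, min_coverage=cfg.score_min_coverage,
        min_extension=cfg.min_extension, span_tolerance=cfg.span_tolerance,
    )
    return PipelineResult(
        clusters, pseudocontigs, stats, de_fere, de_novo,
        fd_calls, fd_summary, dn_calls, dn_summary,
    )


def _features_fit(features, genome) -> bool:
    lengths = {g.record_id: len(g.sequence) for g in genome}
    return all(
        f.record_id in lengths and f.end <= lengths[f.record_id] for f in features
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_from_files(
    genome_path: str | Path,
    reads_paths: Sequence[str | Path],
    out_dir: str | Path,
    features_path: str | Path | None = None,
    exemplars_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    timestamp: str | None = None,
) -> dict:
    """File-level pipeline run; writes outputs and the JSON manifest under
    ``out_dir`` and returns the manifest dict."""
    from . import seqio

    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
        "status": "running",
    }
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    manifest_path = out_dir / "manifest.json"

    def fail(stage: str, exc: Exception):
        manifest["status"] = f"failed at {stage}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise exc

    for label, path in (
        ("genome", genome_path),
        ("features", features_path),
        ("exemplars", exemplars_path),
    ):
        if path is None:
            continue
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{label} file not found: {path}")
        manifest["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}
    for i, rp in enumerate(reads_paths, 1):
        rp = Path(rp)
        if not rp.exists():
            raise FileNotFoundError(f"reads file not found: {rp}")
        manifest["inputs"][f"reads_{i}"] = {"path": str(rp), "sha256": _sha256(rp)}

    genome = seqio.read_fasta(genome_path)
    if len(reads_paths) == 2:
        pairs = seqio.read_paired_fastq(reads_paths[0], reads_paths[1])
    elif len(reads_paths) == 1:
        singles = seqio.read_fastq(reads_paths[0])
        # single-end: treat consecutive reads as pseudo-pairs for the
        # graph; pairing-specific logic degrades gracefully
        pairs = [
            (singles[i], singles[i + 1]) for i in range(0, len(singles) - 1, 2)
        ]
    else:
        raise ValueError("expected 1 or 2 FASTQ files")

    features = None
    if features_path is not None:
        features = seqio.read_features(
            features_path, "gff3", seqio.genome_lengths(genome)
        )
    exemplars = (
        seqio.read_fasta(exemplars_path) if exemplars_path is not None else None
    )

    try:
        rrna = annotate.scan(genome, features=features, exemplars=exemplars,
                             k=cfg.detect_k, density=cfg.detect_density,
                             min_fraction=cfg.detect_min_fraction)
        seqio.write_gff3(rrna, out_dir / "scanned.gff3")
        manifest["stages"]["scan"] = {"n_rrna": len(rrna)}
    except Exception as exc:
        fail("scan", exc)

    try:
        clusters = cluster_mod.select(rrna, genome=genome, flank=cfg.flank)
        cluster_mod.write_cluster_file(clusters, out_dir / "clusters.txt")
        manifest["stages"]["select"] = {"n_clusters": len(clusters)}
    except Exception as exc:
        fail("select", exc)

    try:
        k = cfg.k or auto_k(max(len(r.sequence) for pair in pairs for r in pair))
        pseudocontigs, stats = assembly.seed_iterate(
            pairs, genome, clusters, iterations=cfg.iterations, k=k, config=cfg
        )
        by_iter: dict[int, list] = {}
        for pc in pseudocontigs:
            by_iter.setdefault(pc.iteration, []).append(pc)
        for iteration, pcs in by_iter.items():
            write_fasta(
                [
                    GenomeRecord(f"pseudocontig_{pc.cluster_id}", pc.sequence,
                                 description=f"iteration {pc.iteration} {pc.trust}")
                    for pc in pcs
                ],
                out_dir / f"pseudocontigs_iter{iteration}.fasta",
            )
        pg = assembly.build_pseudogenome(pseudocontigs, cfg.spacer)
        write_fasta(
            [GenomeRecord(pg.record_id, pg.sequence)],
            out_dir / "pseudogenome_final.fasta",
        )
        de_fere, de_novo = assembly.final_assembly(pairs, pseudocontigs, k=k, config=cfg)
        write_fasta(de_fere.contigs, out_dir / "de_fere_novo.fasta")
        write_fasta(de_novo.contigs, out_dir / "de_novo.fasta")
        manifest["stages"]["seed"] = {
            "k": k,
            "iterations": [dataclasses.asdict(s) for s in stats],
            "n_pseudocontigs": len(pseudocontigs),
            "de_fere_novo": {"n_contigs": len(de_fere.contigs), "n50": de_fere.n50},
            "de_novo": {"n_contigs": len(de_novo.contigs), "n50": de_novo.n50},
        }
    except Exception as exc:
        fail("seed", exc)

    try:
        calls, summary = scorer.score_assembly(
            genome, clusters, de_fere.contigs,
            min_identity=cfg.score_min_identity, min_coverage=cfg.score_min_coverage,
            min_extension=cfg.min_extension, span_tolerance=cfg.span_tolerance,
        )
        scorer.write_score_tsv(calls, out_dir / "score_de_fere_novo.tsv")
        dn_calls, dn_summary = scorer.score_assembly(
            genome, clusters, de_novo.contigs,
            min_identity=cfg.score_min_identity, min_coverage=cfg.score_min_coverage,
            min_extension=cfg.min_extension, span_tolerance=cfg.span_tolerance,
        )
        scorer.write_score_tsv(dn_calls, out_dir / "score_de_novo.tsv")
        manifest["stages"]["score"] = {
            "de_fere_novo": summary,
            "de_novo": dn_summary,
        }
    except Exception as exc:
        fail("score", exc)

    manifest["status"] = "ok"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
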