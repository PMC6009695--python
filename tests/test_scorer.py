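import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribostitch import scorer
from ribostitch.scorer import (
    FlankMatch,
    classify_junction,
    count_region_snps,
    match_flanks,
    score_assembly,
)
from ribostitch.seqio import GenomeRecord, revcomp


@dataclasses.dataclass
class _Cluster:
    cluster_id: int
    record_id: str
    span_start: int
    span_end: int
    region_start: int
    region_end: int
    flank: int = 1000


@pytest.fixture(scope="module")
def self_setup(repeat_fixture, repeat_clusters):
    return repeat_fixture["genome"], repeat_clusters


class TestMatchFlanks:
    def test_self_match(self, self_setup):
        genome, clusters = self_setup
        matches = match_flanks([genome], clusters, [genome])
        assert len(matches) == 2 * len(clusters)
        for m in matches:
            assert m.identity == 1.0
            assert m.coverage_of_flank == 1.0

    def test_flank_absent(self, self_setup):
        genome, clusters = self_setup
        rng = np.random.default_rng(0)
        decoy = GenomeRecord("d", "".join(rng.choice(list("ACGT"), 5000)))
        assert match_flanks([genome], clusters, [decoy]) == []

    def test_duplicate_flank_multiplicity(self, self_setup):
        genome, clusters = self_setup
        cl = clusters[0]
        flank = genome.sequence[cl.region_start:cl.span_start]
        rng = np.random.default_rng(1)
        bg = "".join(rng.choice(list("ACGT"), 3000))
        planted = GenomeRecord("p", flank + bg + flank)
        ups = [
            m for m in match_flanks([genome], [cl], [planted])
            if m.side == "upstream"
        ]
        assert len(ups) == 2

    def test_short_flank_skipped(self, self_setup, caplog):
        genome, _ = self_setup
        cl = _Cluster(1, genome.record_id, 2500, 7500, 2450, 7550, flank=50)
        with caplog.at_level("WARNING"):
            matches = match_flanks([genome], [cl], [genome])
        assert matches == []
        assert "skipped" in caplog.text

    def test_reverse_strand_match(self, self_setup):
        genome, clusters = self_setup
        rc_assembly = GenomeRecord("rc", revcomp(genome.sequence))
        matches = match_flanks([genome], clusters[:1], [rc_assembly])
        assert matches
        assert all(m.strand == "-" for m in matches)


class TestClassifyJunction:
    def test_self_scoring_all_correct(self, self_setup):
        genome, clusters = self_setup
        calls, summary = score_assembly([genome], clusters, [genome])
        assert summary == {
            "correct": len(clusters), "unassembled": 0, "incorrect": 0, "ambiguous": 0
        }

    def test_split_at_rdna_midpoint_unassembled(self, self_setup):
        genome, clusters = self_setup
        g = genome.sequence
        contigs = []
        prev = 0
        for i, cl in enumerate(clusters):
            mid = (cl.span_start + cl.span_end) // 2
            contigs.append(GenomeRecord(f"c{i}", g[prev:mid]))
            prev = mid
        contigs.append(GenomeRecord("clast", g[prev:]))
        _, summary = score_assembly([genome], clusters, contigs)
        assert summary["unassembled"] == len(clusters)
        assert summary["correct"] == 0

    def test_cross_cluster_chimera_incorrect(self, self_setup):
        genome, clusters = self_setup
        g = genome.sequence
        c1, c2 = clusters[0], clusters[1]
        chimera = (
            g[c1.region_start:c1.span_end]  # cluster 1 upstream flank + rDNA
            + g[c2.span_end:c2.region_end]  # cluster 2 downstream flank
        )
        calls, _ = score_assembly([genome], clusters, [GenomeRecord("chim", chimera)])
        call1 = next(c for c in calls if c.cluster_id == c1.cluster_id)
        assert call1.category == "incorrect"

    def test_empty_assembly_all_unassembled(self, self_setup):
        genome, clusters = self_setup
        calls, summary = score_assembly([genome], clusters, [])
        assert summary["unassembled"] == len(clusters)
        assert all(c.category == "unassembled" for c in calls)

    def test_summary_conservation(self, repeat_pipeline, self_setup):
        genome, clusters = self_setup
        for summary in (repeat_pipeline.de_fere_summary, repeat_pipeline.de_novo_summary):
            assert sum(summary.values()) == len(clusters)

    def test_pipeline_fixture_summaries(self, repeat_pipeline, self_setup):
        _, clusters = self_setup
        n = len(clusters)
        assert repeat_pipeline.de_fere_summary["correct"] == n
        assert repeat_pipeline.de_novo_summary == {
            "correct": 0, "unassembled": n, "incorrect": 0, "ambiguous": 0
        }

    @settings(max_examples=200, deadline=None)
    @given(
        matches=st.lists(
            st.builds(
                FlankMatch,
                cluster_id=st.integers(1, 3),
                side=st.sampled_from(["upstream", "downstream"]),
                contig_id=st.sampled_from(["c1", "c2", "c3"]),
                contig_start=st.integers(0, 20000),
                contig_end=st.integers(0, 20000),
                strand=st.sampled_from(["+", "-"]),
                identity=st.floats(0.0, 1.0),
                coverage_of_flank=st.floats(0.0, 1.0),
            ),
            max_size=8,
        )
    )
    def test_total_and_deterministic_over_fuzzed_evidence(self, matches):
        cluster = _Cluster(1, "chr", 5000, 10000, 4000, 11000)
        lengths = {"c1": 20000, "c2": 15000, "c3": 8000}
        own = [m for m in matches if m.cluster_id == 1]
        foreign = [m for m in matches if m.cluster_id != 1]
        call_a = classify_junction(cluster, own, contig_lengths=lengths,
                                   foreign_matches=foreign)
        call_b = classify_junction(cluster, own, contig_lengths=lengths,
                                   foreign_matches=foreign)
        assert call_a.category in ("correct", "unassembled", "incorrect", "ambiguous")
        assert call_a.category == call_b.category


class TestWriteScoreTsv:
    def test_columns(self, self_setup, tmp_path):
        genome, clusters = self_setup
        calls, _ = score_assembly([genome], clusters, [genome])
        p = tmp_path / "score.tsv"
        scorer.write_score_tsv(calls, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("cluster_id\tcategory")
        assert len(lines) == len(clusters) + 1


class TestCountRegionSnps:
    def test_identical_assemblies(self, self_setup):
        genome, clusters = self_setup
        _, total = count_region_snps([genome], [genome], clusters)
        assert total == 0

    def test_single_planted_substitution(self, self_setup):
        genome, clusters = self_setup
        cl = clusters[0]
        pos = cl.span_start + 137
        g = genome.sequence
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[g[pos]]
        other = GenomeRecord("other", g[:pos] + alt + g[pos + 1:])
        results, total = count_region_snps([genome], [other], clusters)
        assert total == 1
        (sub,) = results[0].substitutions
        assert sub == (pos, g[pos], alt)

    def test_ten_substitutions_across_two_regions(self, self_setup):
        genome, clusters = self_setup
        g = list(genome.sequence)
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}
        planted = []
        rng = np.random.default_rng(42)
        for cl, count in zip(clusters[:2], (4, 6)):
            offsets = rng.choice(cl.span_end - cl.span_start, count, replace=False)
            for off in offsets:
                pos = cl.span_start + int(off)
                planted.append(pos)
                g[pos] = alt[g[pos]]
        other = GenomeRecord("other", "".join(g))
        results, total = count_region_snps([genome], [other], clusters)
        assert total == 10
        assert len(results[0].substitutions) == 4
        assert len(results[1].substitutions) == 6
        assert sorted(p for r in results for p, _, _ in r.substitutions) == sorted(planted)

    def test_substitution_symmetry(self, self_setup):
        genome, clusters = self_setup
        cl = clusters[0]
        pos = cl.span_start + 500
        g = genome.sequence
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[g[pos]]
        other = GenomeRecord(genome.record_id, g[:pos] + alt + g[pos + 1:])
        _, forward = count_region_snps([genome], [other], clusters)
        _, backward = count_region_snps([other], [genome], clusters)
        assert forward == backward == 1

    def test_unalignable_region_excluded(self, self_setup, caplog):
        genome, clusters = self_setup
        rng = np.random.default_rng(3)
        junk = GenomeRecord("junk", "".join(rng.choice(list("ACGT"), 2000)))
        with caplog.at_level("WARNING"):
            results, total = count_region_snps([genome], [junk], clusters)
        assert total == 0
        assert all(not r.alignable for r in results)
        assert "unalignable" in caplog.text

    def test_indels_reported_separately(self, self_setup):
        genome, clusters = self_setup
        cl = clusters[0]
        pos = cl.span_start + 800
        g = genome.sequence
        other = GenomeRecord("other", g[:pos] + g[pos + 3:])  # 3 bp deletion
        results, total = count_region_snps([genome], [other], clusters[:1])
        assert total == 0
        assert results[0].indels >= 1
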