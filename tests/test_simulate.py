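import numpy as np
import pytest
from scipy import stats as sp_stats

from ribostitch import annotate, cluster as cmod
from ribostitch.seqio import revcomp
from ribostitch.simulate import (
    SimulationConfig,
    build_artificial_chromosome,
    mutate,
    simulate_reads,
    synth_operon_genome,
)


class TestSynthOperonGenome:
    def test_feature_count(self):
        _, feats = synth_operon_genome(3, genome_length=28000, seed=0)
        assert len(feats) == 9
        assert sum(f.kind == "rRNA_16S" for f in feats) == 3

    def test_identical_operon_copies_distinct_flanks(self):
        genome, feats = synth_operon_genome(
            3, operon_length=5000, flank_length=1500, genome_length=28000, seed=4
        )
        g = genome.sequence
        spans = []
        for i in range(3):
            trio = feats[3 * i:3 * i + 3]
            spans.append((min(f.start for f in trio), max(f.end for f in trio)))
        starts = [s for s, _ in spans]
        copies = [g[s:s + 5000] for s in starts]
        assert copies[0] == copies[1] == copies[2]
        flanks = [g[s - 1500:s] for s in starts]
        for i in range(3):
            for j in range(i + 1, 3):
                identity = sum(a == b for a, b in zip(flanks[i], flanks[j])) / 1500
                assert identity < 0.6

    def test_single_operon_assembles_de_novo(self):
        from ribostitch.assembly import debruijn_assemble

        genome, _ = synth_operon_genome(1, 3000, 1000, 12000, seed=5)
        pairs, _ = simulate_reads(
            genome, SimulationConfig(coverage=40, per_base_error=0.0, seed=5)
        )
        reads = [r.sequence for p in pairs for r in p]
        contigs = debruijn_assemble(reads, k=55, min_kmer_count=2)
        # no repeat: the longest contig covers nearly the whole genome
        assert len(contigs[0]) >= 0.97 * len(genome.sequence)

    def test_infeasible_packing(self):
        with pytest.raises(ValueError, match="pack"):
            synth_operon_genome(5, 5000, 1500, genome_length=10000)

    def test_seed_determinism(self):
        a, fa = synth_operon_genome(2, genome_length=20000, seed=11)
        b, fb = synth_operon_genome(2, genome_length=20000, seed=11)
        c, _ = synth_operon_genome(2, genome_length=20000, seed=12)
        assert a.sequence == b.sequence
        assert fa == fb
        assert c.sequence != a.sequence


class TestArtificialChromosome:
    @pytest.fixture()
    def genome_clusters(self):
        genome, feats = synth_operon_genome(3, genome_length=40000, seed=6)
        clusters = cmod.select(annotate.scan([genome], features=feats),
                               genome=[genome], flank=1000)
        return genome, clusters

    def test_truth_table_inversion(self, genome_clusters):
        genome, clusters = genome_clusters
        chrom, truth = build_artificial_chromosome(genome, clusters, flank=2000)
        for entry in truth:
            chrom_slice = chrom.sequence[entry["chrom_start"]:entry["chrom_end"]]
            source_slice = genome.sequence[entry["source_start"]:entry["source_end"]]
            assert chrom_slice == source_slice

    def test_total_length(self, genome_clusters):
        genome, clusters = genome_clusters
        chrom, truth = build_artificial_chromosome(genome, clusters, flank=2000)
        expected = sum(
            min(len(genome.sequence), cl.span_end + 2000)
            - max(0, cl.span_start - 2000)
            for cl in clusters
        )
        assert len(chrom.sequence) == expected

    def test_single_cluster(self, genome_clusters):
        genome, clusters = genome_clusters
        chrom, truth = build_artificial_chromosome(genome, clusters[:1], flank=1000)
        cl = clusters[0]
        assert chrom.sequence == genome.sequence[cl.span_start - 1000:cl.span_end + 1000]

    def test_overlapping_regions_merged(self, genome_clusters, caplog):
        genome, clusters = genome_clusters
        with caplog.at_level("WARNING"):
            chrom, truth = build_artificial_chromosome(genome, clusters, flank=20000)
        assert "merging" in caplog.text
        assert len(truth) < len(clusters)


@pytest.fixture(scope="module")
def mutate_genome():
    genome, _ = synth_operon_genome(2, genome_length=100000, seed=7)
    return genome


@pytest.fixture(scope="module")
def reads_genome():
    genome, _ = synth_operon_genome(1, 3000, 1000, 100000, seed=13)
    return genome


class TestMutate:

    def test_zero_frequency_identity(self, mutate_genome):
        mutated, log = mutate(mutate_genome, 0.0, "uniform", seed=1)
        assert mutated.sequence == mutate_genome.sequence
        assert len(log) == 0

    def test_uniform_substitution_count_binomial(self, mutate_genome):
        f, L = 0.01, len(mutate_genome.sequence)
        lo, hi = sp_stats.binom.ppf([0.005, 0.995], L, f)
        _, log = mutate(mutate_genome, f, "uniform", seed=8)
        assert lo <= len(log) <= hi

    def test_flanking_only_preserves_rdna(self, mutate_genome):
        spans = [(10000, 18000), (60000, 68000)]
        mutated, log = mutate(mutate_genome, 0.1, "flanking_only", spans, seed=9)
        for start, end in spans:
            assert mutated.sequence[start:end] == mutate_genome.sequence[start:end]
        for pos, _, _ in log.substitutions:
            assert not any(s <= pos < e for s, e in spans)

    def test_log_consistency(self, mutate_genome):
        mutated, log = mutate(mutate_genome, 0.02, "uniform", seed=10)
        positions = [p for p, _, _ in log.substitutions]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)
        for pos, ref, alt in log.substitutions:
            assert mutate_genome.sequence[pos] == ref
            assert mutated.sequence[pos] == alt
            assert ref != alt

    def test_realized_rate_converges(self, mutate_genome):
        f = 0.05
        _, log = mutate(mutate_genome, f, "uniform", seed=11)
        realized = len(log) / len(mutate_genome.sequence)
        assert realized == pytest.approx(f, rel=0.1)

    def test_frequency_bounds(self, mutate_genome):
        with pytest.raises(ValueError):
            mutate(mutate_genome, 0.5, "uniform")

    def test_determinism(self, mutate_genome):
        a = mutate(mutate_genome, 0.01, "uniform", seed=12)[0].sequence
        b = mutate(mutate_genome, 0.01, "uniform", seed=12)[0].sequence
        assert a == b


class TestSimulateReads:

    def test_pair_count_formula(self, reads_genome):
        pairs, _ = simulate_reads(
            reads_genome, SimulationConfig(coverage=30, per_base_error=0.0, seed=0)
        )
        assert len(pairs) == round(30 * 100000 / (2 * 100))

    def test_error_free_reads_are_substrings(self, reads_genome):
        pairs, _ = simulate_reads(
            reads_genome, SimulationConfig(coverage=1, per_base_error=0.0, seed=1)
        )
        g = reads_genome.sequence
        for r1, r2 in pairs[:200]:
            assert r1.sequence in g
            assert revcomp(r2.sequence) in g

    def test_truth_placements(self, reads_genome):
        pairs, truth = simulate_reads(
            reads_genome, SimulationConfig(coverage=1, per_base_error=0.0, seed=2)
        )
        g = reads_genome.sequence
        for (r1, r2), entry in zip(pairs, truth):
            assert g[entry["mate1_start"]:entry["mate1_start"] + 100] == r1.sequence
            assert g[entry["mate2_start"]:entry["mate2_start"] + 100] == revcomp(r2.sequence)

    def test_insert_mean_clt_bound(self, reads_genome):
        pairs, truth = simulate_reads(
            reads_genome, SimulationConfig(coverage=10, per_base_error=0.0, seed=3)
        )
        inserts = np.array([t["insert"] for t in truth])
        assert abs(inserts.mean() - 300) <= 3 * 10 / np.sqrt(len(inserts))

    def test_coverage_within_5pct(self, reads_genome):
        pairs, truth = simulate_reads(
            reads_genome, SimulationConfig(coverage=30, per_base_error=0.0, seed=4)
        )
        total_bases = 2 * 100 * len(pairs)
        mean_cov = total_bases / len(reads_genome.sequence)
        assert mean_cov == pytest.approx(30, rel=0.05)

    def test_error_rate_applied(self, reads_genome):
        pairs, truth = simulate_reads(
            reads_genome, SimulationConfig(coverage=2, per_base_error=0.01, seed=5)
        )
        g = reads_genome.sequence
        n_err = n_bases = 0
        for (r1, r2), entry in zip(pairs, truth):
            true1 = g[entry["mate1_start"]:entry["mate1_start"] + 100]
            n_err += sum(a != b for a, b in zip(r1.sequence, true1))
            n_bases += 100
        assert n_err / n_bases == pytest.approx(0.01, rel=0.3)

    def test_quality_encodes_error_rate(self, reads_genome):
        pairs, _ = simulate_reads(
            reads_genome, SimulationConfig(coverage=0.1, per_base_error=0.001, seed=6)
        )
        assert all(q == 30 for q in pairs[0][0].qualities)

    def test_byte_determinism(self, reads_genome):
        cfg = SimulationConfig(coverage=2, per_base_error=0.005, seed=7)
        a, _ = simulate_reads(reads_genome, cfg)
        b, _ = simulate_reads(reads_genome, cfg)
        assert [(r1.sequence, r2.sequence) for r1, r2 in a] == [
            (r1.sequence, r2.sequence) for r1, r2 in b
        ]

    def test_genome_too_short(self):
        genome, _ = synth_operon_genome(1, 100, 50, 320, seed=1)
        with pytest.raises(ValueError, match="too short"):
            simulate_reads(genome, SimulationConfig(coverage=10, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(read_length=400)
        with pytest.raises(ValueError):
            SimulationConfig(coverage=0)
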