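import numpy as np
import pytest

from ribostitch.assembly import (
    CompactedGraph,
    Pseudocontig,
    build_pseudogenome,
    build_read_graph,
    debruijn_assemble,
    final_assembly,
    guided_assemble,
    junction_choices,
    qc_pseudocontig,
    seed_iterate,
    swap,
    thread_guide,
)
from ribostitch.seqio import GenomeRecord, revcomp
from ribostitch import simulate as sim


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _tile_reads(seq, read_len=100, step=3):
    """Error-free reads tiling a sequence end to end (covers terminal
    k-mers, unlike a random-fragment simulator)."""
    reads = [seq[i:i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    if (len(seq) - read_len) % step:
        reads.append(seq[-read_len:])
    return reads


def _canon(seq):
    return min(seq, revcomp(seq))


class TestDebruijnAssemble:
    @pytest.mark.parametrize("seed", range(50))
    def test_reconstructs_repeat_free_sequence(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5000, 20001))
        seq = _random_dna(rng, length)
        contigs = debruijn_assemble(_tile_reads(seq), k=31, min_kmer_count=1)
        assert len(contigs) == 1
        assert _canon(contigs[0]) == _canon(seq)

    def test_internal_repeat_fragments_assembly(self):
        rng = np.random.default_rng(77)
        repeat = _random_dna(rng, 500)
        seq = (
            _random_dna(rng, 2000) + repeat + _random_dna(rng, 2000)
            + repeat + _random_dna(rng, 2000)
        )
        contigs = debruijn_assemble(_tile_reads(seq), k=31, min_kmer_count=1)
        assert len(contigs) >= 3
        # no contig spans a full copy of the repeat plus both its contexts
        for contig in contigs:
            assert len(contig) < 2000 + 500 + 2000

    def test_single_read(self):
        read = "ACGTAGGCATTTACCGGATAGCATGCAAGCTAGCTAGGCTA"
        contigs = debruijn_assemble([read], k=21, min_kmer_count=1)
        assert len(contigs) == 1
        assert _canon(contigs[0]) == _canon(read)

    def test_empty_after_filtering_warns(self, caplog):
        rng = np.random.default_rng(123)
        with caplog.at_level("WARNING"):
            contigs = debruijn_assemble([_random_dna(rng, 40)], k=21,
                                        min_kmer_count=2)
        assert contigs == []
        assert "no k-mers" in caplog.text

    def test_contig_kmers_subset_of_read_kmers(self):
        rng = np.random.default_rng(8)
        seq = _random_dna(rng, 5000)
        reads = _tile_reads(seq)
        contigs = debruijn_assemble(reads, k=31, min_kmer_count=1)
        read_kmers = set()
        for read in reads:
            for i in range(len(read) - 30):
                read_kmers.add(read[i:i + 31])
                read_kmers.add(revcomp(read[i:i + 31]))
        for contig in contigs:
            for i in range(len(contig) - 30):
                assert contig[i:i + 31] in read_kmers


class TestQc:
    def test_too_short(self):
        assert qc_pseudocontig(5000, 7000) == "too_short"

    def test_too_long(self):
        assert qc_pseudocontig(25000, 7000) == "too_long"

    def test_accepted(self):
        assert qc_pseudocontig(7500, 7000) == "accepted"

    def test_boundaries(self):
        assert qc_pseudocontig(6000, 7000) == "accepted"
        assert qc_pseudocontig(21000, 7000) == "accepted"
        assert qc_pseudocontig(21001, 7000) == "too_long"


class TestPseudogenome:
    def _pc(self, cid, seq):
        return Pseudocontig(cid, 1, seq, len(seq))

    def test_two_contigs_spacer(self):
        rng = np.random.default_rng(1)
        a, b = _random_dna(rng, 7000), _random_dna(rng, 8000)
        pg = build_pseudogenome([self._pc(1, a), self._pc(2, b)], spacer_length=1000)
        assert len(pg.sequence) == 16000
        assert pg.sequence[7000:8000] == "N" * 1000
        assert "N" not in pg.sequence[:7000]

    def test_single_contig_no_spacer(self):
        pg = build_pseudogenome([self._pc(1, "ACGT" * 2000)])
        assert pg.sequence == "ACGT" * 2000

    def test_layout_inverts(self):
        rng = np.random.default_rng(2)
        seqs = {i: _random_dna(rng, 6000 + i * 13) for i in (1, 2, 3)}
        pg = build_pseudogenome([self._pc(i, s) for i, s in seqs.items()])
        for cid, start, end in pg.layout:
            assert pg.sequence[start:end] == seqs[cid]

    def test_rejected_contigs_excluded(self):
        ok = self._pc(1, "A" * 7000)
        bad = Pseudocontig(2, 1, "A" * 100, 7000, "too_short")
        pg = build_pseudogenome([ok, bad])
        assert pg.layout == [(1, 0, 7000)]

    def test_no_accepted_error(self):
        with pytest.raises(ValueError):
            build_pseudogenome([Pseudocontig(1, 1, "", 7000, "too_short")])


class TestThreading:
    def test_guide_identical_to_unitig_is_noop(self):
        rng = np.random.default_rng(3)
        seq = _random_dna(rng, 3000)
        graph = build_read_graph(_tile_reads(seq), 31, 1)
        cg = CompactedGraph(graph)
        segments = thread_guide(cg, seq, trusted=True)
        assert junction_choices(cg, segments) == set()

    def test_guide_without_graph_kmers_warns(self, caplog):
        rng = np.random.default_rng(4)
        graph = build_read_graph(_tile_reads(_random_dna(rng, 2000)), 31, 1)
        cg = CompactedGraph(graph)
        with caplog.at_level("WARNING"):
            segments = thread_guide(cg, _random_dna(rng, 500), trusted=True)
        assert "no junction information" in caplog.text
        assert junction_choices(cg, segments) == set()

    def test_three_copy_repeat_resolved_by_guides(self):
        rng = np.random.default_rng(5)
        repeat = _random_dna(rng, 5000)
        flanks = [_random_dna(rng, 1500) for _ in range(6)]
        genome = (
            flanks[0] + repeat + flanks[1]
            + flanks[2] + repeat + flanks[3]
            + flanks[4] + repeat + flanks[5]
        )
        reads = _tile_reads(genome, step=2)
        de_novo = debruijn_assemble(reads, k=55, min_kmer_count=1)
        assert all(len(c) < 1500 + 5000 + 1500 for c in de_novo)
        guides = [
            (flanks[0][-1200:] + repeat + flanks[1][:1200], True),
            (flanks[2][-1200:] + repeat + flanks[3][:1200], True),
            (flanks[4][-1200:] + repeat + flanks[5][:1200], True),
        ]
        contigs = guided_assemble(reads, guides, k=55, min_kmer_count=1)
        assert _canon(contigs[0]) == _canon(genome)

    def test_untrusted_chimeric_pairing_rejected(self):
        rng = np.random.default_rng(6)
        repeat = _random_dna(rng, 150)
        a, b, c, d = (_random_dna(rng, 3000) for _ in range(4))
        genome1 = GenomeRecord("g1", a + repeat + b)
        genome2 = GenomeRecord("g2", c + repeat + d)
        cfg = sim.SimulationConfig(coverage=30, per_base_error=0.0, seed=6)
        pairs = sim.simulate_reads(genome1, cfg)[0] + sim.simulate_reads(genome2, cfg)[0]
        reads = [r for p in pairs for r in p]
        chimera = a[-1000:] + repeat + d[:1000]
        # untrusted: read pairs spanning the repeat contradict the chimera
        contigs = guided_assemble(reads, [(chimera, False)], k=55, pairs=pairs)
        assert all(_canon(chimera) not in _canon(ctg) for ctg in contigs)
        # trusted: no veto, the chimeric junction is followed
        contigs_t = guided_assemble(reads, [(chimera, True)], k=55, pairs=pairs)
        assert any(_canon(chimera) in _canon(ctg) for ctg in contigs_t)


class TestSeedIterate:
    def test_stable_core_on_clean_fixture(self, repeat_fixture, repeat_clusters):
        # on a perfect reference with error-free reads the rDNA-region core
        # of each pseudocontig is stable across iterations; ends may grow
        # by up to ~one insert per iteration as mates of newly baited
        # boundary reads are pulled in
        pairs = repeat_fixture["pairs"]
        genome = [repeat_fixture["genome"]]
        one, _ = seed_iterate(pairs, genome, repeat_clusters, iterations=1, k=55)
        three, _ = seed_iterate(pairs, genome, repeat_clusters, iterations=3, k=55)
        by_id_one = {pc.cluster_id: pc.sequence for pc in one}
        insert = 300
        for pc in three:
            first = by_id_one[pc.cluster_id]
            assert first in pc.sequence or revcomp(first) in pc.sequence
            assert len(pc.sequence) <= len(first) + 2 * 2 * insert

    def test_stats_logged_per_cluster_iteration(self, repeat_fixture, repeat_clusters):
        pairs = repeat_fixture["pairs"]
        _, stats = seed_iterate(
            pairs, [repeat_fixture["genome"]], repeat_clusters, iterations=2, k=55
        )
        seen = {(s.iteration, s.cluster_id) for s in stats}
        expected = {
            (i, cl.cluster_id) for i in (1, 2) for cl in repeat_clusters
        }
        assert seen == expected
        assert all(s.mean_depth > 0 for s in stats)

    def test_pseudocontigs_cover_regions(self, repeat_fixture, repeat_clusters):
        pairs = repeat_fixture["pairs"]
        pcs, _ = seed_iterate(
            pairs, [repeat_fixture["genome"]], repeat_clusters, iterations=1, k=55
        )
        genome_seq = repeat_fixture["genome"].sequence
        for pc, cl in zip(pcs, repeat_clusters):
            assert pc.qc_status == "accepted"
            assert pc.trust == "trusted"
            region = genome_seq[cl.region_start:cl.region_end]
            # pseudocontig covers >= 90% of its region
            assert _overlap_length(pc.sequence, region) >= 0.9 * len(region)

    def test_empty_clusters_error(self, repeat_fixture):
        with pytest.raises(ValueError):
            seed_iterate(repeat_fixture["pairs"], [repeat_fixture["genome"]], [],
                         iterations=1, k=55)


def _overlap_length(contig, region):
    """Longest common substring proxy: count region positions covered by
    exact 101-mers shared with the contig (either strand)."""
    k = 101
    contig_kmers = set()
    for s in (contig, revcomp(contig)):
        for i in range(len(s) - k + 1):
            contig_kmers.add(s[i:i + k])
    covered = np.zeros(len(region), dtype=bool)
    for i in range(len(region) - k + 1):
        if region[i:i + k] in contig_kmers:
            covered[i:i + k] = True
    return int(covered.sum())


class TestFinalAssembly:
    def test_zero_pseudocontigs_degenerate_equality(self, repeat_fixture):
        de_fere, de_novo = final_assembly(repeat_fixture["pairs"][:600], [], k=55)
        assert [c.sequence for c in de_fere.contigs] == [
            c.sequence for c in de_novo.contigs
        ]
        assert de_fere.mode == "de_fere_novo"
        assert de_novo.mode == "de_novo"

    def test_repeat_fixture_n50_improves(self, repeat_pipeline):
        assert repeat_pipeline.de_fere_novo.n50 > repeat_pipeline.de_novo.n50

    def test_contig_ordering_and_ids(self, repeat_pipeline):
        contigs = repeat_pipeline.de_fere_novo.contigs
        lengths = [len(c.sequence) for c in contigs]
        assert lengths == sorted(lengths, reverse=True)
        assert [c.record_id for c in contigs] == [
            f"contig_{i}" for i in range(1, len(contigs) + 1)
        ]

    def test_determinism(self, repeat_fixture, repeat_clusters):
        pairs = repeat_fixture["pairs"]
        genome = [repeat_fixture["genome"]]
        pcs, _ = seed_iterate(pairs, genome, repeat_clusters, iterations=1, k=55)
        a_fere, a_novo = final_assembly(pairs, pcs, k=55)
        b_fere, b_novo = final_assembly(pairs, pcs, k=55)
        assert [c.sequence for c in a_fere.contigs] == [c.sequence for c in b_fere.contigs]
        assert [c.sequence for c in a_novo.contigs] == [c.sequence for c in b_novo.contigs]


class TestSwap:
    def test_concatenated_bad_contig_replaced_by_both_parts(self):
        rng = np.random.default_rng(9)
        part1, part2 = _random_dna(rng, 2000), _random_dna(rng, 2500)
        de_fere = [
            GenomeRecord("contig_1", part1 + part2),
            GenomeRecord("contig_2", _random_dna(rng, 1500)),
        ]
        de_novo = [GenomeRecord("dn_1", part1), GenomeRecord("dn_2", part2)]
        edited, report = swap(de_fere, de_novo, "contig_1")
        ids = [c.record_id for c in edited]
        assert "contig_1" not in ids
        assert {"dn_1", "dn_2"} <= set(ids)
        assert "contig_2" in ids
        assert len(report) == 2
        for entry in report:
            assert entry["identity"] >= 0.95
            assert entry["bad_contig_end"] > entry["bad_contig_start"]

    def test_missing_bad_contig_id(self):
        with pytest.raises(KeyError):
            swap([GenomeRecord("c1", "ACGT" * 100)], [], "nope")

    def test_no_syntenic_contig_error(self):
        rng = np.random.default_rng(10)
        de_fere = [GenomeRecord("c1", _random_dna(rng, 2000))]
        de_novo = [GenomeRecord("d1", _random_dna(rng, 2000))]
        with pytest.raises(RuntimeError, match="no syntenic"):
            swap(de_fere, de_novo, "c1")
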