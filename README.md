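# ribostitch

Resolve repeated ribosomal RNA operon (rDNA) regions in prokaryotic
short-read assemblies.

Bacterial genomes carry 1–15 near-identical rDNA operons (16S/23S/5S).
Plain de Bruijn assembly collapses them, breaking the assembly at every
copy. ribostitch exploits two facts: the *flanking* sequence of each
operon is unique within a genome, and both operons and flanks are
conserved between related genomes. It therefore:

1. **scan** — normalizes rRNA annotations on a related reference genome
   (from a GFF3/GenBank file, or a built-in exemplar k-mer detector for
   synthetic genomes),
2. **select** — groups the rRNA features into operon clusters with an
   exact Fisher–Jenks natural-breaks partition (class count = number of
   16S genes), writing a hand-editable cluster file,
3. **seed** — maps the isolate's reads to the reference, baits the reads
   overlapping each cluster ±1 kb, subassembles each subset into a
   *pseudocontig*, iterates (mapping against the concatenated
   N-spacered *pseudogenome*), and finally threads the pseudocontigs
   through the full-read de Bruijn graph so each repeat copy is spelled
   in its own flanking context ("de fere novo" assembly, with a plain de
   novo control),
4. **score** — classifies every rDNA region of the result as
   correct / unassembled / incorrect / ambiguous by locating the
   reference flanks in the assembly and checking their geometry.

Helper commands: **snag** (per-column Shannon entropy + consensus depth
of aligned rDNA regions), **stack** (rDNA vs. background coverage ratio,
flagging references with collapsed rDNA copies), **swap** (replace a
suspect guided contig with syntenic de novo contigs), and **simulate**
(synthetic multi-operon genomes, the uniform / flanking-only reference
mutation models, and a paired-end read simulator) so the whole pipeline
is testable offline.

Everything is pure Python on numpy/biopython/pysam/gffutils: the mapper
is a seed-and-extend k-mer mapper (external aligners can be substituted
via SAM input), the assembler a single-k de Bruijn graph with tip
clipping, bubble popping and guide-path repeat resolution.

## Test

```
python -m pytest -q tests/
```

The suite (≈250 tests, ~4 min) includes `tests/test_acceptance.py`, which
runs the end-to-end acceptance criteria: the 3-operon repeat fixture
(guided assembly resolves 3/3 junctions, de novo 0/3), an exhaustive
Jenks oracle, entropy unit values, mutation-model recovery against
binomial intervals, the reference-divergence degradation curve, and
collapsed-reference coverage recovery.

## CLI

```
ribostitch simulate genome --n-operons 3 --genome-length 28000 --seed 1 \
    --out-fasta ref.fasta --out-gff ref.gff3
ribostitch simulate reads --genome ref.fasta --coverage 30 --seed 1 \
    --out1 r1.fastq --out2 r2.fastq

ribostitch run --genome ref.fasta --features ref.gff3 \
    --reads r1.fastq --reads r2.fastq --out rundir/
```

`run` executes scan → select → seed → score and writes a JSON manifest
(parameters, input checksums, per-stage summaries) plus all intermediate
FASTA/GFF3/TSV outputs under `rundir/`. Each stage is also available as
its own subcommand (`scan`, `select`, `map`, `seed`, `score`, `snag`,
`stack`, `swap`); see `ribostitch <cmd> --help`. Parameters may live in a
flat `key = value` config file (`--config`); flags override file values.

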