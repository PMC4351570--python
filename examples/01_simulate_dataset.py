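"""Simulate a benchmark data set: reference, diploid truth, paired reads.

Builds a 200-kb synthetic contig, mutates it into two haplotypes under the
default mutation model (0.1% per-base mutation rate, 10% indels of 1-24 bp,
half heterozygous), simulates a 20x paired-end 100-bp library with a
500+/-50 bp insert, and writes the FASTQ pair, truth VCF, high-confidence
BED and origins sidecar that a mapper/caller benchmark consumes.
"""

from collections import Counter

import gcatbench as gb

ref = gb.generate_reference(length=200_000, gc_content=0.41, seed=11)
genome = gb.mutate_diploid(ref, gb.MutationModel(), seed=11)
sim = gb.simulate_reads(genome, gb.LibraryModel(), seed=11)

classes = Counter(v.vclass for v in genome.truth)
zygosity = Counter(v.genotype for v in genome.truth)
print(f"reference: {ref.name}, {ref.length:,} bp")
print(f"truth variants: {len(genome.truth)} "
      f"({classes['SNP']} SNPs, {classes['insertion']} insertions, "
      f"{classes['deletion']} deletions; "
      f"{zygosity['het']} het / {zygosity['hom-alt']} hom-alt)")
print(f"read pairs: {len(sim.reads1):,} "
      f"(= round(20 * {ref.length:,} / 200), the coverage closed form)")
print(f"first read name: {sim.reads1[0].name}")
print("  -> decodes to", gb.decode_read_name(sim.reads1[0].name))

gb.write_reference_fasta(ref, "sim.ref.fasta")
gb.write_truth(genome.truth, [(ref.name, 0, ref.length)],
               {ref.name: ref.length}, "sim.truth.vcf", "sim.regions.bed")
gb.write_fastq(sim.reads1, "sim_1.fastq.gz")
gb.write_fastq(sim.reads2, "sim_2.fastq.gz")
gb.write_origins(sim.origins, "sim.origins.tsv")
print("wrote sim.ref.fasta, sim.truth.vcf, sim.regions.bed, "
      "sim_{1,2}.fastq.gz, sim.origins.tsv")
# The truth-variant count divided by the reference length estimates the
# 0.001 mutation rate; the read-pair count is exact by construction.
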