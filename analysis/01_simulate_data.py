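#!/usr/bin/env python
"""Generate the synthetic study data every later step consumes.

Builds a seeded 20-gene toy genome (60 GT..AG introns, each with a planted
branchpoint, ~10% labelled U12), simulates an error-free read mix of 1000
branchpoint read-through lariat reads, 1000 linear reads and 100
intron-circle reads, and writes genome FASTA, annotation GTF, reads FASTQ
and the ground-truth table under results/.
"""

from pathlib import Path

from lariatseq.simulate import (SimulationConfig, make_toy_genome,
                                simulate_reads, write_fastq)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(seed=SEED, n_genes=20, introns_per_gene=3,
                           error_rate=0.0, indel_rate=0.0,
                           n_lariat_reads=1000, n_linear_reads=1000,
                           n_circle_reads=100, u12_fraction=0.1)
    bundle = make_toy_genome(cfg)
    reads, truth = simulate_reads(bundle, cfg)

    bundle.write_fasta(OUT / "toy_genome.fa")
    bundle.write_gtf(OUT / "toy_genome.gtf")
    write_fastq(reads, OUT / "reads.fastq")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    n_u12 = sum(iv.intron_class == "U12" for iv in bundle.introns)
    print(f"genome: {sum(len(s) for s in bundle.sequences.values())} nt, "
          f"{len(bundle.genes)} genes, {len(bundle.introns)} introns "
          f"({n_u12} U12)")
    print(f"reads: {len(reads)} "
          f"({truth.cls.value_counts().to_dict()})")
    print(f"wrote toy_genome.fa/.gtf, reads.fastq, truth.tsv under {OUT}")


if __name__ == "__main__":
    main()
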