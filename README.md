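# lariatseq

Intron lariats — the branched, looped RNAs excised by the spliceosome — are
normally turned over within minutes by the debranching enzyme Dbr1. When
debranching is lost, lariats accumulate, and sequencing them reveals both
branchpoint positions genome-wide and the sequence preferences of the
debranching machinery. `lariatseq` is a tested reimplementation of that
analysis stack for people who work on splicing and lariat turnover:

- **two lariat read mappers** that call branchpoints from the inverted
  alignment of branchpoint read-through cDNAs: an *iterative read-splitting*
  mapper and a *splice-site-probe* mapper, both with explicit intron-circle
  filtering;
- **lariat quantification**: recovery rates per million reads, per-intron
  knockout/wild-type fold changes (U12 vs U2 stratification), branchpoint
  base composition, sequence-logo matrices, positional chi-square
  enrichment, spliced:unspliced junction ratios and ADAR-timestamp editing
  rates;
- **a branchpoint reporter assay (MPRA) module**: library design over all
  4096 branchpoint hexamers with barcode prefiltering, splicing-efficiency
  computation and branchpoint functional scores;
- **feature-response analytics**: stratifying introns by RBP binding sites
  or motif matches, response ratios with bootstrap CIs, lariat-loop topology
  distances, PWM scanning and the co-IP spectral-count hit filter;
- **a synthetic-data module** that generates toy genomes, reads of known
  class (lariat / linear / intron circle / decoy), reporter counts with
  known hexamer effects, planted binding sites and edited amplicons, so
  every stage is testable end-to-end against ground truth.

## The core computations

A lariat read-through cDNA crosses the 2'–5' branch, so the read is the
concatenation of an intron segment ending exactly at the branch nucleotide
followed by a segment starting at the intron's first base. Both mappers
discard reads with a full linear genome mapping, then find this inverted
two-segment alignment; the genomic position of the downstream segment's last
aligned base is the branchpoint call. Candidates whose downstream segment
ends at the intron's 3' terminus are intron circles and are filtered out.
The splice-site mapper applies the printed edit filters to the trimmed
prefix: at most 5 mismatches, mismatch rate at most 10%, and at most one
indel of at most 3 nt.

Reporter splicing efficiency for species *j* with output/input read counts
*o<sub>j</sub>*, *i<sub>j</sub>* is

    SE_j = ((o_j + 1) / (i_j + 1)) / ( Σ_k (o_k + 1) / Σ_k (i_k + 1) )

and a hexamer's **branchpoint functional score** is log₂ of its mean SE
across barcode pairs and replicates. The identity
Σ<sub>j</sub> SE<sub>j</sub>(i<sub>j</sub>+1) = Σ<sub>j</sub>(i<sub>j</sub>+1)
is asserted on every computation.

Lariat recovery rate is lariat reads per million (total or linearly mapped)
reads; fold changes are pseudocounted on the rate scale,
FC = (rate<sub>KO</sub> + p)/(rate<sub>WT</sub> + p).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known ground truth, writing tables under `results/`:

```bash
python analysis/01_simulate_data.py       # toy genome + read mix + truth
python analysis/02_map_lariats.py         # both mappers vs ground truth
python analysis/03_lariat_quantification.py
python analysis/04_mpra_scoring.py
python analysis/05_feature_response.py
```

Step 02 prints, for a 20-gene / 60-intron genome with 1000 lariat, 1000
linear and 100 intron-circle reads (error-free, seed 1):

```
split mapper: 1000 calls (1000/1000 lariat reads at the exact true branchpoint, 0 non-lariat calls, 100 circle-filtered)
ss mapper: 1000 calls (1000/1000 lariat reads at the exact true branchpoint, 0 non-lariat calls, 100 circle-filtered)
cross-mapper: 1000/1000 dual-called reads concordant
```

i.e. every simulated lariat read is recovered at its exact planted
branchpoint, no linear or circle read produces a call, and the two mappers
agree read-by-read. Step 04 prints:

```
library: 4096 hexamers x 4 barcode pairs = 16384 species
score recovery vs planted log2 efficiencies: Spearman rho = 0.996 over 4096 hexamers
```

the complete reporter library passes the barcode prefilters, and functional
scores recovered from simulated counts at depth 10⁷ rank the planted
16-fold efficiency range almost perfectly. Step 05 recovers a planted 3×
bound-vs-control lariat response (ratio 2.94, 95% bootstrap CI 2.56–3.39)
and a planted 10%-over-2% editing rate as 7.9% corrected.

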