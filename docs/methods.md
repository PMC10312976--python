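# Methods

## Coordinates and conventions

All genomic intervals are 0-based half-open (BED convention). A branchpoint
is reported as the 0-based genomic position of the branch nucleotide itself,
which removes the ±1 ambiguity that plagues branchpoint catalogues. Intron
sequences are always handled in transcription orientation: minus-strand
introns are reverse-complemented before any probe extraction, tail indexing
or branchpoint arithmetic, and coordinates are mapped back at the end.

## Read anatomy and the two mappers

A branchpoint read-through cDNA crosses the 2'–5' branch, producing a read
that is the concatenation of (i) an intron segment whose last base is the
branch nucleotide and (ii) a segment starting at the intron's first base.
An intron circle produces the same anatomy except that the first segment
ends at the intron's last base; it must not be called as a branchpoint.

**Iterative read-splitting mapper** (`split_mapper`). Reads with a full
linear genome mapping are discarded. Each surviving read (and its reverse
complement) is split at every offset leaving both parts ≥ 16 nt ("longer
than 15 bp" read strictly). A split is accepted when the tail matches some
intron's first bases exactly (the 5'SS anchor; a mismatch budget is
configurable but defaults to 0) and the head aligns within that same intron.
The head alignment's end, minus one, is the candidate branchpoint.

**Splice-site-probe mapper** (`ss_mapper`). Reads with > 5% ambiguous
characters are dropped (strictly greater: a 100-nt read with exactly 5 Ns
survives), then linearly mapping reads are discarded. The first 20 nt of
every annotated intron form the probe set; identical 20-mers are collapsed
into a single probe and the read-level uniqueness rule ("only one 5' splice
site maps") is applied at the distinct-sequence level, with the intron-id
level tally also reported in the run summary. Probes are located by exact
substring search; a read matching two distinct probe sequences is dropped.
The read is trimmed from the probe match onward and prefixes < 20 nt are
dropped. When one probe occurs at several positions in a read, the
*rightmost* occurrence is used: the 5'SS segment is the read's final
segment, and a branchpoint close to the intron start legitimately places
the intron's first bases inside the upstream segment too. The prefix is
then aligned to the last 250 nt of every intron (whole intron if shorter),
filtered (≤ 5 mismatches, ≤ 10% mismatch rate, at most one indel of ≤ 3 nt
— all boundaries exactly as stated), restricted to introns of the probe's
gene(s) and to placements at least a probe length downstream of the intron
start (the inverted mapping order of a genuine lariat), and the end of the
highest-scoring surviving alignment is the branchpoint. Score ties are
dropped as ambiguous.

**Shared rules.**

- *Full linear mapping* (the discard criterion): an alignment covering at
  least the read length minus 2 bases. The linear pass's edit budget
  defaults to ungapped with ≤ 5 mismatches, like the end-to-end short-read
  aligners such a first pass uses. This choice matters: with a gapped
  budget, the ≤ 2-nt clip allowance plus a 3-nt indel plus 5 mismatches can
  absorb most of a 20-nt 5'SS tail, and about one in a thousand simulated
  lariat reads is then falsely discarded as linear.
- *Circle margin*: head/prefix alignments ending within 2 nt of the
  intron's last base are filtered as intron circles. "Maps to the end of an
  intron" needs a width; 2 nt absorbs AG-boundary ambiguity. Simulated
  branchpoints sit ≥ 5 nt from the 3' end, so true calls are never clipped.
- *Best-hit semantics*: within each intron, only the top-scoring
  placement(s) of the head/prefix are candidates, mirroring an aligner that
  reports best hits. Without this, a suboptimal one-indel placement of a
  circle read's head ends a few bases short of the terminus and evades the
  circle filter (observed on simulated circles).
- *Tie-breaking*: among surviving (intron, branchpoint) candidates the
  highest combined alignment score wins; residual ties drop the read as
  ambiguous — conservative for branchpoint annotation.
- Alignment score: matches − 2·mismatches − 3·(indel opens); the
  splice-site mapper additionally subtracts the indel length. The mismatch
  rate's denominator is aligned read bases, gap columns excluded from both
  numerator and denominator.

## The built-in aligner

`align.align_exhaustive` enumerates every placement of a read on a
reference within an explicit budget of substitutions plus at most one indel
of bounded length — exact and complete at toy-genome scale. The no-indel
pass compares the read against all reference windows at once (vectorised);
the one-indel pass uses prefix/suffix mismatch cumulative sums so that, for
each window start, indel type and indel length, the best indel position
falls out of a single argmin. Alignments are canonicalised as one record
per (reference, strand, start, indel signature), keeping the
fewest-mismatch (leftmost on ties) indel position. A brute-force
enumeration oracle checks this equivalence in the test suite.

`filter_linear` pre-screens each read with a bit-parallel infix aligner
(edlib) to nominate candidate loci before the exact aligner adjudicates
them with the clip allowance; edlib only generates candidates and never
scores. Externally produced SAM alignments can be imported in place of the
built-in aligner; records must carry NM-style edit information and are
rejected otherwise.

## Synthetic data: what it emulates, and what it does not

The simulator defines the study conditions all tests run under:

- **Genome**: 20 genes × 3 introns by default (single chromosome, plus
  strand unless a minus-strand fraction is set). Intron lengths uniform in
  150–400 nt, exons 80–160 nt. Every intron starts GT and ends AG; the
  branch base is drawn A-rich (A 0.75, T 0.15, C 0.06, G 0.04), echoing the
  canonical A-branch preference; the branchpoint sits 20–40 nt from the 3'
  splice site — the range where mammalian branchpoints concentrate.
- **Reads**: 150 nt, constant quality. Lariat/circle reads use the anatomy
  above with the split point uniform subject to both segments ≥ 20 nt (so
  every simulated read is eligible for both mappers); linear reads are
  contiguous genomic substrings; optional decoys join a random exonic
  segment to an intron start (template-switch artifacts, off by default).
  Substitutions are uniform over the three alternatives at a configurable
  rate (default 0.1%, a typical Illumina substitution scale); at most one
  1–3-nt indel per read at a configurable probability (default 0).
- **Reporter counts**: input counts multinomial over 4096 × 4 species at
  the stated depth; output counts multinomial with weights input × true
  efficiency, gamma-overdispersed per species (mean 1, variance =
  dispersion). True efficiencies used in tests span a 16-fold range.
- **Feature sites**: planted over a configurable intron fraction, either
  uniform-intronic or near-branchpoint (lariat-loop distance ≤ 50 nt).
  Planted knockout/wild-type count tables are Poisson with a base fold
  change of 2 and an extra 3× response on bound introns.
- **Edited amplicons**: each adenosine independently converted to G per
  read at the stated rate (10% signal over a 2% baseline in tests).

Deliberately not emulated: position-dependent error profiles, quality-score
variation, paired ends, expression-level structure, polyA artifacts,
GC bias and multimapping repeat structure. Passing tests therefore
demonstrate algorithmic correctness against a known truth, not robustness
to every artifact of real libraries; on real data the linear filter and the
edit filters carry the burden the simulator does not exercise.

## Quantification

- Recovery rate = Σ counts / denominator × 10⁶, with both normalisations
  (total reads; linearly mapped reads) available — output headers flag
  which was used (default per-mapped).
- Fold change per intron = (rate_KO + p)/(rate_WT + p), pseudocount on the
  rate scale (default 1 per million; analyses at toy depths use a one-read
  equivalent instead and say so). For the minor-spliceosome comparison the
  U2 background is restricted to genes containing ≥ 1 U12 intron.
- Logos: one window per distinct anchor; information content per column is
  2 + Σ f log₂ f bits against a uniform background. Default windows:
  branchpoint [−8, +15] (covers the YTNAY motif and the downstream
  pyrimidine signal), 5'SS [−3, +8]; both configurable. `top_n` restricts
  to the best-supported anchors before matrix construction.
- Positional chi-square: Pearson, 1 df, no continuity correction; a flag
  marks expected cells < 1. Reads from one intron share their splice-site
  sequence, so independent units are distinct sites, not reads — the
  analysis scripts deduplicate accordingly.
- Junction ratio: spliced = two consecutive blocks abutting the intron with
  ≥ 6 nt aligned on both sides; unspliced = one block crossing either
  boundary with the same overhang (standard junction-counting practice);
  0/0 is missing, spliced-only is reported as +inf.
- Editing: raw rate = edited / covered target adenosines (T→C on the minus
  strand); corrected = max(0, transfected − control) as a percent. The
  clamp exists because a negative corrected rate is uninterpretable; the
  subtraction is aggregate by default, per-site available.

## Reporter library and scoring

Barcode prefilter: (1) no TAA/TGA/TCA anywhere in the 11-mer (potential
alternative branch sites); (2) for each of five hexamer activity tables
(ESE/ISE scores, supplied as plain hexamer→score TSVs; seeded synthetic
stand-ins ship for testing), barcodes are ranked by the sum of squared
scores of their six overlapping hexamers and only the bottom half of every
ranking survives. With five roughly independent rankings ~3% of random
barcodes pass, so the default pool is 3·10⁶ (the 11-mer space holds
4.2·10⁶). The branchpoint hexamer occupies positions −3..+2 relative to the
branch nucleotide (branch at hexamer position 4); that frame is recorded
and reused when scanning an 11-nt window around mapped branchpoints for the
maximum functional score. Hexamer scores are log₂(mean SE over all barcode
pair × replicate observations); the mean-of-per-replicate-logs ordering is
also emitted for comparison since the two can differ.

## Feature response

Bound = ≥ 1 nt strand-matched overlap with a site (standard intersect
semantics; containment not required). Control = unbound introns from genes
containing a bound intron, so both sets share a gene background. The
response ratio is FC(bound)/FC(control) on aggregate recovery rates, with a
seeded 1000-resample bootstrap over introns for the CI. Motif construction
greedily aligns weighted 5-mers (offsets −4..+4, ties to the smallest
absolute then positive offset) into a PFM; scanning adds a 0.01
pseudofrequency, scores log-odds against a uniform background on both
strands, and thresholds at 80% of the maximum score by default — the
threshold semantics are explicit because upstream web-server defaults are
not reproducible. The co-IP filter takes hits with control mean < 3 and IP
mean > 10, replaces zero means with 0.1 for fold changes, and attaches a
two-tailed Welch t-test (pooled-variance optional); Welch is the safer
default at n = 3.

## Problem sizes and determinism

The default test and acceptance conditions are: 20 genes / 60 introns,
1000 + 1000 + 100 reads for the mapper checks; depth 10⁷ with dispersion
0.05 for reporter-score recovery; coverage 10⁴ for editing recovery;
1000 bootstrap resamples for response CIs. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configuration and seed give byte-identical FASTA/FASTQ/BED/TSV outputs.

## Known limitations

- The exhaustive aligner is O(genome × read) per read and meant for
  toy-scale references; real libraries would come in via the SAM import.
- At most one indel per alignment; recursive or multi-way read splits and
  branchpoints in unannotated introns are out of scope.
- The 5-mer enrichment procedure that produces weighted k-mer lists is an
  upstream input, not reimplemented.
- Reads containing two lariat junctions, trans-spliced artifacts anchoring
  to another gene's 5'SS, and probabilistic branchpoint rescue are not
  handled; trans anchoring is deliberately excluded (the head must lie in
  the tail's intron).
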