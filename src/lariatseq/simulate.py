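"""Synthetic ground-truth data for every downstream stage.

The simulator emits toy genomes with annotated introns, reads of known class
(lariat / linear / intron-circle / decoy) with a truth table, reporter-assay
count tables with known per-hexamer splicing efficiencies, intronic feature
sites with a planted lariat-response structure, and A-to-G edited amplicons.

Lariat read anatomy mirrors branchpoint read-through cDNAs: the read is the
concatenation of an intron segment ending exactly at the branch nucleotide
followed by a segment starting at the intron's first base. Intron-circle
reads use the same construction with the first segment ending at the intron's
last base. All randomness flows from a single seed; a fixed config yields
byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBundle, Gene, Exon, Intron, revcomp

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_genes: int = 20
    introns_per_gene: int = 3
    intron_length_range: tuple[int, int] = (150, 400)
    exon_length_range: tuple[int, int] = (80, 160)
    intergenic_length_range: tuple[int, int] = (60, 120)
    read_length: int = 150
    error_rate: float = 0.001  # substitutions per base
    indel_rate: float = 0.0    # probability of one short indel per read
    n_lariat_reads: int = 1000
    n_linear_reads: int = 1000
    n_circle_reads: int = 100
    n_decoy_reads: int = 0
    bp_offset_from_3ss_range: tuple[int, int] = (20, 40)
    u12_fraction: float = 0.1
    min_segment: int = 20   # minimum length of either lariat-read segment
    minus_strand_fraction: float = 0.0  # strand-aware mode when > 0
    # branch nucleotide distribution (A-rich, mirroring the canonical motif)
    bp_base_probs: tuple[float, float, float, float] = (0.75, 0.06, 0.04, 0.15)

    def validate(self) -> None:
        lo, hi = self.intron_length_range
        olo, ohi = self.bp_offset_from_3ss_range
        if lo < 40 or hi < lo:
            raise ValueError("intron lengths must be >= 40 nt")
        if olo < 5 or ohi < olo:
            raise ValueError("branchpoint offset from 3' end must be >= 5 nt")
        if ohi >= lo:
            raise ValueError("branchpoint offset range exceeds minimum intron")
        if not 0 <= self.u12_fraction <= 1:
            raise ValueError("u12_fraction must be in [0, 1]")
        if self.read_length < 2 * self.min_segment:
            raise ValueError("read length must fit two minimum segments")
        if abs(sum(self.bp_base_probs) - 1) > 1e-9:
            raise ValueError("bp_base_probs must sum to 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Flat ``key = value`` text config; tuples as comma pairs."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        defaults = cls()
        for lineno, line in enumerate(open(path), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, tuple):
                parts = [p.strip() for p in val.split(",")]
                kwargs[key] = tuple(type(default[0])(p) for p in parts)
            else:
                kwargs[key] = type(default)(val)
        return cls(**kwargs)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_toy_genome(config: SimulationConfig) -> GenomeBundle:
    """A single-chromosome genome of multi-intron genes.

    Every intron starts GT and ends AG on its annotated strand; each carries a
    class label (U2/U12) and a designated true branchpoint whose base is drawn
    from the configured A-rich distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    genes, exons, introns = [], [], []

    def emit(seq: str) -> int:
        nonlocal pos
        pieces.append(seq)
        start = pos
        pos += len(seq)
        return start

    for gi in range(config.n_genes):
        emit(_random_seq(rng, int(rng.integers(*config.intergenic_length_range))))
        gene_id = f"gene{gi + 1}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        gene_start = pos
        # features in transcription order; laid onto the genome left-to-right
        # for '+', right-to-left (reverse-complemented) for '-'
        feats: list[tuple[str, str, dict]] = []
        for k in range(config.introns_per_gene + 1):
            feats.append(("exon", _random_seq(
                rng, int(rng.integers(*config.exon_length_range))), {}))
            if k < config.introns_per_gene:
                ilen = int(rng.integers(*config.intron_length_range))
                off3 = int(rng.integers(*config.bp_offset_from_3ss_range))
                body = list(_random_seq(rng, ilen))
                body[0:2] = "GT"
                body[-2:] = "AG"
                bp_rel = ilen - 1 - off3
                body[bp_rel] = BASES[rng.choice(4, p=config.bp_base_probs)]
                iclass = "U12" if rng.random() < config.u12_fraction else "U2"
                feats.append(("intron", "".join(body),
                              {"bp_rel": bp_rel, "class": iclass, "k": k + 1}))
        if strand == "-":
            genomic_feats = [(t, revcomp(s), m) for t, s, m in feats[::-1]]
        else:
            genomic_feats = feats
        for ftype, fseq, meta in genomic_feats:
            fstart = emit(fseq)
            fend = fstart + len(fseq)
            if ftype == "exon":
                exons.append(Exon(gene_id, chrom, fstart, fend, strand))
            else:
                if strand == "+":
                    bp = fstart + meta["bp_rel"]
                else:
                    bp = fend - 1 - meta["bp_rel"]
                introns.append(Intron(
                    intron_id=f"{gene_id}_intron{meta['k']}", gene_id=gene_id,
                    chrom=chrom, start=fstart, end=fend, strand=strand,
                    intron_class=meta["class"], branchpoint=bp))
        genes.append(Gene(gene_id, chrom, gene_start, pos, strand))
    emit(_random_seq(rng, int(rng.integers(*config.intergenic_length_range))))
    bundle = GenomeBundle({chrom: "".join(pieces)}, genes, exons, introns)
    bundle.introns.sort(key=lambda iv: (iv.chrom, iv.start))
    return bundle


def _apply_noise(seq: str, rng: np.random.Generator,
                 config: SimulationConfig) -> str:
    arr = np.array(list(seq))
    if config.error_rate > 0:
        hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
        for i in hits:
            alts = [b for b in "ACGT" if b != arr[i]]
            arr[i] = alts[rng.integers(0, 3)]
    seq = "".join(arr)
    if config.indel_rate > 0 and rng.random() < config.indel_rate:
        # at most one indel per read, length 1..3
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5 and len(seq) > length + 2:
            p = int(rng.integers(1, len(seq) - length))
            seq = seq[:p] + seq[p + length:]
        else:
            p = int(rng.integers(1, len(seq)))
            seq = seq[:p] + _random_seq(rng, length) + seq[p:]
    return seq


def simulate_reads(bundle: GenomeBundle, config: SimulationConfig
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Reads plus a truth table.

    Returns ``(reads, truth)`` where reads are (id, sequence) pairs and the
    truth table records per read: class, intron id, the true branchpoint
    (0-based genomic) and the segment boundary within the read.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    introns = bundle.introns
    chrom_ids = sorted(bundle.sequences)
    rl, ms = config.read_length, config.min_segment

    def add(read_id: str, seq: str, **truth) -> None:
        noisy = _apply_noise(seq, rng, config)
        reads.append((read_id, noisy))
        rows.append({"read_id": read_id, **truth})

    for i in range(config.n_lariat_reads):
        iv = introns[int(rng.integers(len(introns)))]
        iseq = bundle.intron_seq(iv)
        bp_rel = bundle.bp_intron_offset(iv)
        head_max = min(rl - ms, bp_rel + 1)
        if head_max < ms:
            warnings.warn(f"intron {iv.intron_id}: read length {rl} does not "
                          f"fit around its branchpoint; read skipped")
            continue
        head_len = int(rng.integers(ms, head_max + 1))
        tail_len = rl - head_len
        seq = iseq[bp_rel + 1 - head_len: bp_rel + 1] + iseq[:tail_len]
        add(f"lariat_{i}", seq, cls="lariat", intron_id=iv.intron_id,
            chrom=iv.chrom, branchpoint=iv.branchpoint, split_point=head_len)

    for i in range(config.n_circle_reads):
        iv = introns[int(rng.integers(len(introns)))]
        iseq = bundle.intron_seq(iv)
        head_len = int(rng.integers(ms, rl - ms + 1))
        seq = iseq[len(iseq) - head_len:] + iseq[: rl - head_len]
        add(f"circle_{i}", seq, cls="circle", intron_id=iv.intron_id,
            chrom=iv.chrom, branchpoint=-1, split_point=head_len)

    for i in range(config.n_linear_reads):
        chrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
        gseq = bundle.sequences[chrom]
        start = int(rng.integers(0, len(gseq) - rl + 1))
        seq = gseq[start:start + rl]
        if config.minus_strand_fraction > 0 and rng.random() < 0.5:
            seq = revcomp(seq)
        add(f"linear_{i}", seq, cls="linear", intron_id="",
            chrom=chrom, branchpoint=-1, split_point=-1)

    for i in range(config.n_decoy_reads):
        # template-switch artifact: random exonic segment joined to a 5'SS start
        iv = introns[int(rng.integers(len(introns)))]
        ex = bundle.exons[int(rng.integers(len(bundle.exons)))]
        head_len = int(rng.integers(ms, rl - ms + 1))
        ex_seq = bundle.fetch(ex.chrom, ex.start, ex.end, ex.strand)
        if len(ex_seq) < head_len:
            continue
        estart = int(rng.integers(0, len(ex_seq) - head_len + 1))
        seq = ex_seq[estart:estart + head_len] + \
            bundle.intron_seq(iv)[: rl - head_len]
        add(f"decoy_{i}", seq, cls="decoy", intron_id=iv.intron_id,
            chrom=iv.chrom, branchpoint=-1, split_point=head_len)

    truth = pd.DataFrame(
        rows, columns=["read_id", "cls", "intron_id", "chrom", "branchpoint",
                       "split_point"])
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Phred33 constant-quality FASTQ."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    try:
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:
        raise ValueError(f"unparseable FASTQ {path}: {exc}") from exc


# -- reporter-assay counts ------------------------------------------------

def simulate_mpra_counts(true_efficiency_per_hexamer: "pd.Series | dict",
                         n_barcode_pairs: int = 4, depth: int = 10_000_000,
                         dispersion: float = 0.0, seed: int = 0,
                         n_replicates: int = 3) -> pd.DataFrame:
    """Input/output reporter counts with known hexamer effects.

    Input counts are multinomial over species at ``depth``; output counts are
    multinomial with weights proportional to input x true efficiency,
    gamma-overdispersed per species when ``dispersion`` > 0 (mean 1, variance
    ``dispersion``).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    eff = pd.Series(true_efficiency_per_hexamer, dtype=float)
    if (eff <= 0).any():
        raise ValueError("true efficiencies must be positive")
    rng = np.random.default_rng(seed)
    hexamers = np.repeat(eff.index.to_numpy(), n_barcode_pairs)
    pairs = np.tile(np.arange(1, n_barcode_pairs + 1), len(eff))
    eff_vec = np.repeat(eff.to_numpy(), n_barcode_pairs)
    n_species = len(hexamers)
    frames = []
    for rep in range(1, n_replicates + 1):
        inp = rng.multinomial(depth, np.full(n_species, 1.0 / n_species))
        w = inp.astype(float) * eff_vec
        if dispersion > 0:
            w *= rng.gamma(1.0 / dispersion, dispersion, size=n_species)
        total = w.sum()
        out = (rng.multinomial(depth, w / total) if total > 0
               else np.zeros(n_species, dtype=int))
        frames.append(pd.DataFrame({
            "species_id": [f"{h}_bc{p}" for h, p in zip(hexamers, pairs)],
            "hexamer": hexamers, "barcode_pair": pairs, "replicate": rep,
            "input_count": inp, "output_count": out}))
    return pd.concat(frames, ignore_index=True)


# -- intronic feature sites ----------------------------------------------

def simulate_feature_sites(bundle: GenomeBundle, bound_fraction: float,
                           placement: str = "near_branchpoint", seed: int = 0,
                           max_distance: int = 50, site_width: int = 10,
                           source: str = "eclip"):
    """Planted binding sites over a fraction of introns.

    ``near_branchpoint`` places each site so its lariat-loop distance to the
    intron's branchpoint is at most ``max_distance``; ``uniform_intronic``
    places sites anywhere inside the intron. Returns (FeatureSiteSet,
    bound-intron-id set).
    """
    from .features import FeatureSiteSet

    if not 0 <= bound_fraction <= 1:
        raise ValueError("bound_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bound = int(round(bound_fraction * len(bundle.introns)))
    order = rng.permutation(len(bundle.introns))[:n_bound]
    rows = []
    bound_ids = set()
    for j, idx in enumerate(sorted(order)):
        iv = bundle.introns[idx]
        bp_rel = bundle.bp_intron_offset(iv)
        if placement == "near_branchpoint":
            # site ends g+1 nt upstream of the branch nucleotide (loop side)
            g = int(rng.integers(0, max_distance - 1))
            end_rel = bp_rel - g          # exclusive, transcript-relative
            start_rel = end_rel - site_width
            if start_rel < 0:
                start_rel, end_rel = 0, site_width
        elif placement == "uniform_intronic":
            start_rel = int(rng.integers(0, iv.length - site_width + 1))
            end_rel = start_rel + site_width
        else:
            raise ValueError(f"unknown placement {placement!r}")
        a = bundle.genomic_pos(iv, start_rel)
        b = bundle.genomic_pos(iv, end_rel - 1)
        gstart, gend = (a, b + 1) if iv.strand == "+" else (b, a + 1)
        rows.append({"chrom": iv.chrom, "start": gstart, "end": gend,
                     "name": f"site_{j}", "score": 100, "strand": iv.strand})
        bound_ids.add(iv.intron_id)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    return FeatureSiteSet(df, source=source), bound_ids


def simulate_lariat_count_tables(bundle: GenomeBundle, responsive_introns: set,
                                 wt_mean: float = 20.0, base_fc: float = 2.0,
                                 extra_fc: float = 3.0, denominator: int = 10**6,
                                 seed: int = 0):
    """Planted KO/WT per-intron lariat counts.

    WT counts are Poisson(wt_mean); KO counts are Poisson(wt_mean x base_fc),
    multiplied by ``extra_fc`` for introns in ``responsive_introns`` — the
    planted bound-versus-control response. Returns (ko_table, wt_table).
    """
    from .metrics import SampleLariatTable

    rng = np.random.default_rng(seed)
    ids = [iv.intron_id for iv in bundle.introns]
    lam_wt = np.full(len(ids), wt_mean)
    lam_ko = lam_wt * base_fc * np.array(
        [extra_fc if i in responsive_introns else 1.0 for i in ids])
    wt = pd.Series(rng.poisson(lam_wt), index=ids)
    ko = pd.Series(rng.poisson(lam_ko), index=ids)
    return (SampleLariatTable("KO", ko, total_reads=denominator,
                              mapped_reads=denominator),
            SampleLariatTable("WT", wt, total_reads=denominator,
                              mapped_reads=denominator))


# -- edited amplicons -----------------------------------------------------

def simulate_edited_amplicons(amplicon: str, per_base_edit_rate: float,
                              baseline_rate: float, coverage: int,
                              seed: int = 0
                              ) -> tuple[list[str], list[str]]:
    """A-to-G edited amplicon reads for transfected and non-transfected pools.

    Each adenosine is independently converted to G at the stated per-read
    rate; other bases are untouched.
    """
    if "A" not in amplicon.upper():
        raise ValueError("amplicon contains no adenosine")
    rng = np.random.default_rng(seed)
    base = np.array(list(amplicon.upper()))
    a_pos = np.nonzero(base == "A")[0]

    def pool(rate: float) -> list[str]:
        out = []
        for _ in range(coverage):
            arr = base.copy()
            arr[a_pos[rng.random(len(a_pos)) < rate]] = "G"
            out.append("".join(arr))
        return out

    return pool(per_base_edit_rate), pool(baseline_rate)
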