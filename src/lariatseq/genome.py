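"""Reference sequences plus gene/exon/intron annotation.

All coordinates are 0-based half-open genomic intervals. The branchpoint of an
intron, where known, is stored as the 0-based genomic position of the branch
nucleotide itself. Intron class labels distinguish major-spliceosome (U2) from
minor-spliceosome (U12) introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class Exon:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class Intron:
    """One annotated intron.

    ``branchpoint`` is the genomic position of the branch nucleotide when the
    annotation carries one (toy genomes always do; real annotations usually do
    not). ``intron_class`` is ``"U2"`` or ``"U12"``.
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    intron_class: str = "U2"
    branchpoint: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length intron {self.intron_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """Reference sequences and annotation — the coordinate backbone.

    ``sequences`` maps reference id to an upper-case nucleotide string.
    """

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    exons: list[Exon] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self):
        for feats in (self.genes, self.exons, self.introns):
            for f in feats:
                if f.end <= f.start:
                    raise ValueError(f"zero-length feature in {type(f).__name__}")
        gene_span = {g.gene_id: (g.start, g.end) for g in self.genes}
        for iv in self.introns:
            if iv.gene_id in gene_span:
                gs, ge = gene_span[iv.gene_id]
                if iv.start < gs or iv.end > ge:
                    raise ValueError(
                        f"intron {iv.intron_id} not nested in gene {iv.gene_id}"
                    )

    # -- sequence access -------------------------------------------------

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic slice; minus strand returns the reverse complement."""
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def intron_seq(self, intron: Intron) -> str:
        """Intron sequence in transcription orientation (starts GT, ends AG)."""
        return self.fetch(intron.chrom, intron.start, intron.end, intron.strand)

    def base_at(self, chrom: str, pos: int, strand: str = "+") -> str:
        return self.fetch(chrom, pos, pos + 1, strand)

    def bp_intron_offset(self, intron: Intron) -> int:
        """Branchpoint position relative to the intron's first (5') base."""
        if intron.branchpoint is None:
            raise ValueError(f"intron {intron.intron_id} has no branchpoint")
        if intron.strand == "+":
            return intron.branchpoint - intron.start
        return intron.end - 1 - intron.branchpoint

    def genomic_pos(self, intron: Intron, offset: int) -> int:
        """Genomic coordinate of transcript-relative intron ``offset``."""
        if intron.strand == "+":
            return intron.start + offset
        return intron.end - 1 - offset

    def introns_by_gene(self) -> dict[str, list[Intron]]:
        out: dict[str, list[Intron]] = {}
        for iv in self.introns:
            out.setdefault(iv.gene_id, []).append(iv)
        return out

    def intron_map(self) -> dict[str, Intron]:
        return {iv.intron_id: iv for iv in self.introns}

    # -- serialisation ---------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.sequences.items())
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_gtf(self, path: str | Path) -> None:
        """Minimal GTF (1-based closed coordinates) with custom attributes
        carrying intron class and branchpoint."""
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(_gtf_line(g.chrom, "gene", g.start, g.end, g.strand,
                                   f'gene_id "{g.gene_id}";'))
            for e in self.exons:
                fh.write(_gtf_line(e.chrom, "exon", e.start, e.end, e.strand,
                                   f'gene_id "{e.gene_id}";'))
            for iv in self.introns:
                attrs = (f'gene_id "{iv.gene_id}"; intron_id "{iv.intron_id}"; '
                         f'intron_class "{iv.intron_class}";')
                if iv.branchpoint is not None:
                    attrs += f' branchpoint "{iv.branchpoint}";'
                fh.write(_gtf_line(iv.chrom, "intron", iv.start, iv.end,
                                   iv.strand, attrs))

    @classmethod
    def from_files(cls, fasta: str | Path, annotation: str | Path) -> "GenomeBundle":
        """Load from FASTA plus minimal GTF or BED12 annotation."""
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        annotation = Path(annotation)
        if annotation.suffix.lower() in {".bed", ".bed12"}:
            genes, exons, introns = _read_bed12(annotation)
        else:
            genes, exons, introns = _read_gtf(annotation)
        return cls(sequences=sequences, genes=genes, exons=exons, introns=introns)


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    return (f"{chrom}\tlariatseq\t{feature}\t{start + 1}\t{end}\t.\t"
            f"{strand}\t.\t{attrs}\n")


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    out = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _read_gtf(path: Path):
    genes, exons, introns = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_s = parts[:9]
            start, end = int(start) - 1, int(end)
            attrs = _parse_gtf_attrs(attr_s)
            gid = attrs.get("gene_id", "")
            if feature == "gene":
                genes.append(Gene(gid, chrom, start, end, strand))
            elif feature == "exon":
                exons.append(Exon(gid, chrom, start, end, strand))
            elif feature == "intron":
                bp = attrs.get("branchpoint")
                introns.append(Intron(
                    intron_id=attrs.get("intron_id", f"{gid}_intron{len(introns)}"),
                    gene_id=gid, chrom=chrom, start=start, end=end, strand=strand,
                    intron_class=attrs.get("intron_class", "U2"),
                    branchpoint=int(bp) if bp is not None else None,
                ))
    return genes, exons, introns


def _read_bed12(path: Path):
    """BED12: one gene per line, exon blocks; introns are the gaps between
    blocks. Intron class/branchpoint are not representable in BED12 and
    default to U2/None."""
    genes, exons, introns = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, _end, name, _, strand = parts[:6]
            start = int(start)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offs = [int(x) for x in parts[11].rstrip(",").split(",")]
            genes.append(Gene(name, chrom, start, int(_end), strand))
            block_ivs = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            for bs, be in block_ivs:
                exons.append(Exon(name, chrom, bs, be, strand))
            gaps = [(block_ivs[i][1], block_ivs[i + 1][0])
                    for i in range(len(block_ivs) - 1)]
            # intron numbering follows transcription order
            if strand == "-":
                gaps = gaps[::-1]
            for k, (gs, ge) in enumerate(gaps, 1):
                introns.append(Intron(f"{name}_intron{k}", name, chrom,
                                      gs, ge, strand))
    return genes, exons, introns
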