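"""Quantification of lariat calls.

Recovery rates per million reads, per-intron fold changes between conditions
(knockout vs wild type), branchpoint nucleotide composition, position
frequency matrices / information content for sequence logos, position-wise
chi-square enrichment between call sets, spliced:unspliced junction-read
ratios, and A-to-G editing rates for timestamp amplicons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeBundle, revcomp


@dataclass
class SampleLariatTable:
    """Per-sample, per-intron lariat read counts plus normalisation
    denominators (total reads and linearly mapped reads)."""

    sample_id: str
    counts: pd.Series  # index: intron id, values: nonnegative int
    total_reads: int
    mapped_reads: int

    def __post_init__(self):
        self.counts = pd.Series(self.counts)
        if (self.counts < 0).any():
            raise ValueError("lariat counts must be nonnegative")

    def denominator(self, mode: str) -> int:
        if mode == "per_total":
            return self.total_reads
        if mode == "per_mapped":
            return self.mapped_reads
        raise ValueError(f"unknown normalisation mode {mode!r}")


def table_from_calls(calls_df: pd.DataFrame, sample_id: str,
                     total_reads: int, mapped_reads: int,
                     intron_ids: Sequence[str] | None = None) -> SampleLariatTable:
    """Aggregate a call table by intron into a SampleLariatTable."""
    counts = calls_df.groupby("intron_id").size()
    if intron_ids is not None:
        counts = counts.reindex(list(intron_ids), fill_value=0)
    return SampleLariatTable(sample_id, counts.astype(int),
                             total_reads, mapped_reads)


def recovery_rate(table: SampleLariatTable, mode: str = "per_mapped") -> float:
    """Lariat reads per million (total or linearly mapped) reads."""
    denom = table.denominator(mode)
    if denom <= 0:
        raise ValueError("normalisation denominator must be positive")
    return float(table.counts.sum()) / denom * 1e6


def _mean_rates(tables: Sequence[SampleLariatTable], mode: str) -> pd.Series:
    per_sample = []
    universe = None
    for t in tables:
        if universe is None:
            universe = set(t.counts.index)
        elif set(t.counts.index) != universe:
            diff = sorted(universe ^ set(t.counts.index))
            raise ValueError(f"mismatched intron universes: {diff}")
        per_sample.append(t.counts / t.denominator(mode) * 1e6)
    return pd.concat(per_sample, axis=1).mean(axis=1)


def intron_fold_change(ko: "SampleLariatTable | Sequence[SampleLariatTable]",
                       wt: "SampleLariatTable | Sequence[SampleLariatTable]",
                       pseudocount: float = 1.0,
                       mode: str = "per_mapped") -> pd.DataFrame:
    """Per-intron fold change in lariat recovery rate, KO over WT.

    The pseudocount is applied on the rate scale (reads per million):
    FC = (rate_KO + p) / (rate_WT + p).
    """
    ko = [ko] if isinstance(ko, SampleLariatTable) else list(ko)
    wt = [wt] if isinstance(wt, SampleLariatTable) else list(wt)
    rate_ko = _mean_rates(ko, mode)
    rate_wt = _mean_rates(wt, mode).reindex(rate_ko.index)
    if rate_wt.isna().any():
        diff = sorted(set(rate_ko.index) ^ set(wt[0].counts.index))
        raise ValueError(f"mismatched intron universes: {diff}")
    fc = (rate_ko + pseudocount) / (rate_wt + pseudocount)
    return pd.DataFrame({"rate_ko": rate_ko, "rate_wt": rate_wt,
                         "fold_change": fc})


def fold_change_by_class(fc: pd.DataFrame, bundle: GenomeBundle,
                         restrict_to_u12_genes: bool = True) -> pd.DataFrame:
    """Summarise fold changes by intron class (U12 vs U2).

    For the minor-spliceosome comparison the U2 set is restricted to introns
    from genes that themselves contain at least one U12 intron, so the two
    classes share a gene background.
    """
    info = pd.DataFrame(
        [(iv.intron_id, iv.gene_id, iv.intron_class) for iv in bundle.introns],
        columns=["intron_id", "gene_id", "intron_class"]).set_index("intron_id")
    merged = fc.join(info, how="inner")
    if restrict_to_u12_genes:
        u12_genes = set(merged.loc[merged.intron_class == "U12", "gene_id"])
        merged = merged[merged.gene_id.isin(u12_genes)]
    return merged.groupby("intron_class")["fold_change"].agg(
        ["count", "mean", "median"])


# -- branchpoint sequence composition ------------------------------------

def bp_composition(calls_df: pd.DataFrame, bundle: GenomeBundle,
                   filter_single_bp: bool = False) -> dict[str, float]:
    """Proportions of the reference base at each call's branchpoint.

    With ``filter_single_bp``, calls from introns with more than one distinct
    recovered branchpoint are excluded first.
    """
    df = calls_df
    if filter_single_bp:
        n_bp = df.groupby("intron_id")["branchpoint"].nunique()
        df = df[df.intron_id.map(n_bp) == 1]
    if len(df) == 0:
        raise ValueError("no calls contribute to the composition")
    bases = [bundle.base_at(r.chrom, r.branchpoint, r.strand)
             for r in df.itertuples()]
    counts = pd.Series(bases).value_counts()
    return {b: float(counts.get(b, 0)) / len(bases) for b in "ACGT"}


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over a window relative to an anchor, with
    information content in bits against a uniform background."""

    counts: pd.DataFrame  # index: window position, columns: A C G T
    n_sequences: int

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def information_content(self) -> pd.Series:
        freq = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(freq > 0, freq * np.log2(freq), 0.0)
        return pd.Series(2.0 + term.sum(axis=1), index=self.counts.index)


def logo_pfm(calls_df: pd.DataFrame, bundle: GenomeBundle,
             anchor: str = "branchpoint",
             window: tuple[int, int] | None = None,
             top_n: int | None = None) -> PositionFrequencyMatrix:
    """Position frequency matrix around branchpoints or 5' splice sites.

    One window per distinct anchor position; with ``top_n``, only the n
    anchors with the highest supporting read counts contribute. Default
    windows: branchpoint [-8, +15], 5'SS [-3, +8] (transcript orientation;
    position 0 is the anchor base).
    """
    if anchor == "branchpoint":
        window = window or (-8, 15)
        anchor_col = "branchpoint"
    elif anchor == "five_prime_ss":
        window = window or (-3, 8)
        anchor_col = "five_prime_ss"
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    lo, hi = window
    grouped = calls_df.groupby(["chrom", "strand", anchor_col]).size()
    if top_n is not None:
        grouped = grouped.sort_values(ascending=False, kind="stable")[:top_n]
    positions = list(range(lo, hi + 1))
    counts = pd.DataFrame(0, index=positions, columns=list("ACGT"))
    n = 0
    for (chrom, strand, pos), _ in grouped.items():
        if strand == "+":
            gs, ge = pos + lo, pos + hi + 1
            seq = None
            if gs >= 0 and ge <= len(bundle.sequences[chrom]):
                seq = bundle.fetch(chrom, gs, ge, "+")
        else:
            gs, ge = pos - hi, pos - lo + 1
            seq = None
            if gs >= 0 and ge <= len(bundle.sequences[chrom]):
                seq = bundle.fetch(chrom, gs, ge, "-")
        if seq is None:
            import warnings
            warnings.warn(f"anchor at {chrom}:{pos} window out of bounds; "
                          "dropped")
            continue
        for p, b in zip(positions, seq):
            if b in "ACGT":
                counts.loc[p, b] += 1
        n += 1
    return PositionFrequencyMatrix(counts, n)


# -- position-wise chi-square --------------------------------------------

def positionwise_chi2(setA: pd.DataFrame, setB: pd.DataFrame,
                      bundle: GenomeBundle, position: int, base: str,
                      anchor: str = "five_prime_ss"
                      ) -> tuple[float, float, np.ndarray, bool]:
    """Pearson chi-square (1 df, no continuity correction) testing whether
    ``base`` at ``position`` relative to the anchor differs between two call
    sets. Returns (statistic, p, 2x2 table, low-expected-count flag)."""
    if len(setA) == 0 or len(setB) == 0:
        raise ValueError("both call sets must be nonempty")

    def tally(df: pd.DataFrame) -> tuple[int, int]:
        hit = other = 0
        for r in df.itertuples():
            pos = getattr(r, anchor)
            gpos = pos + position if r.strand == "+" else pos - position
            b = bundle.base_at(r.chrom, gpos, r.strand)
            if b == base:
                hit += 1
            else:
                other += 1
        return hit, other

    table = np.array([tally(setA), tally(setB)], dtype=float)
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), table, bool((expected < 1).any())


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table, dtype=float),
                                           correction=False)
    return float(stat), float(p)


# -- spliced : unspliced junction reads ----------------------------------

def spliced_unspliced_ratio(alignments: Iterable, bundle: GenomeBundle,
                            overhang: int = 6) -> pd.DataFrame:
    """Per-intron ratio of spliced (exon-exon) to unspliced (exon-intron or
    intron-exon) junction reads.

    ``alignments`` yields (chrom, strand, blocks) with blocks a sequence of
    0-based half-open aligned intervals, or a SAM path. A read is spliced for
    an intron when two consecutive blocks abut the intron's ends with at
    least ``overhang`` aligned bases on both sides; unspliced when one block
    crosses either intron boundary with the same overhang. 0/0 is reported
    as NaN, spliced-only as +inf.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "suffix"):
        import pysam
        parsed = []
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                parsed.append((rec.reference_name,
                               "-" if rec.is_reverse else "+",
                               rec.get_blocks()))
        alignments = parsed
    spliced = {iv.intron_id: 0 for iv in bundle.introns}
    unspliced = {iv.intron_id: 0 for iv in bundle.introns}
    by_chrom: dict[str, list] = {}
    for iv in bundle.introns:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, strand, blocks in alignments:
        blocks = list(blocks)
        for iv in by_chrom.get(chrom, []):
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if (e1 == iv.start and s2 == iv.end
                        and e1 - s1 >= overhang and e2 - s2 >= overhang):
                    spliced[iv.intron_id] += 1
            for (s, e) in blocks:
                for boundary in (iv.start, iv.end):
                    if s <= boundary - overhang and e >= boundary + overhang:
                        unspliced[iv.intron_id] += 1
    rows = []
    for iv in bundle.introns:
        sp, un = spliced[iv.intron_id], unspliced[iv.intron_id]
        if sp == 0 and un == 0:
            ratio = math.nan
        elif un == 0:
            ratio = math.inf
        else:
            ratio = sp / un
        rows.append({"intron_id": iv.intron_id, "spliced": sp,
                     "unspliced": un, "ratio": ratio})
    return pd.DataFrame(rows).set_index("intron_id")


# -- timestamp editing rate ----------------------------------------------

def raw_editing_rate(reads: Iterable[str], amplicon: str,
                     strand: str = "+") -> float:
    """Fraction of edited target adenosines across all reads.

    On the plus strand an edit is A->G at amplicon A positions; on the minus
    strand, T->C. Reads are full-length copies of the amplicon (or (seq,
    offset) pairs for partial coverage).
    """
    ref_base, edited_base = ("A", "G") if strand == "+" else ("T", "C")
    amplicon = amplicon.upper()
    covered = edited = 0
    for item in reads:
        seq, off = item if isinstance(item, tuple) else (item, 0)
        for i, b in enumerate(seq.upper()):
            if amplicon[off + i] == ref_base:
                covered += 1
                if b == edited_base:
                    edited += 1
    if covered == 0:
        raise ValueError("no target-base-covering positions in reads")
    return edited / covered


def editing_rate(transfected: Iterable[str], nt_control: Iterable[str],
                 amplicon: str, strand: str = "+") -> float:
    """Background-corrected percent of edited adenosines.

    corrected = max(0, raw_transfected - raw_control), as a percentage; the
    clamp keeps a noisier control from producing a negative rate.
    """
    raw_t = raw_editing_rate(transfected, amplicon, strand)
    raw_c = raw_editing_rate(nt_control, amplicon, strand)
    return max(0.0, raw_t - raw_c) * 100.0
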