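"""Branchpoint observations shared by both lariat mappers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class LariatCall:
    """One branchpoint observation from a single read.

    ``branchpoint`` is the 0-based genomic position of the branch nucleotide;
    ``five_prime_ss`` the genomic position of the intron's first transcribed
    base. ``method`` tags the mapper that produced the call ('split' or 'ss').
    """

    read_id: str
    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    five_prime_ss: int
    branchpoint: int
    head_mismatches: int
    tail_mismatches: int
    method: str

    def __post_init__(self):
        if not self.intron_start <= self.branchpoint < self.intron_end:
            raise ValueError(
                f"{self.read_id}: branchpoint outside intron bounds")


CALL_COLUMNS = ["read_id", "chrom", "strand", "gene_id", "intron_id",
                "intron_start", "intron_end", "five_prime_ss", "branchpoint",
                "head_mismatches", "tail_mismatches", "method"]


def calls_to_dataframe(calls: list[LariatCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(call, c) for c in CALL_COLUMNS} for call in calls],
        columns=CALL_COLUMNS)


def write_calls_tsv(calls_df: pd.DataFrame, path: str | Path) -> None:
    calls_df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def calls_to_bed6(calls_df: pd.DataFrame, path: str | Path) -> None:
    """Branchpoints as single-base BED6 intervals."""
    with open(path, "w") as fh:
        for row in calls_df.itertuples():
            fh.write(f"{row.chrom}\t{row.branchpoint}\t{row.branchpoint + 1}\t"
                     f"{row.read_id}\t0\t{row.strand}\n")
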