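"""Branchpoint reporter library design and functional scoring.

The reporter library replaces the 6-nt window around a minigene intron's
branchpoint (positions -3..+2 relative to the branch nucleotide, so the
branch sits at hexamer position 4) with all 4096 hexamers, each carried by
four intronic/exonic barcode pairs. Splicing efficiency of species j is the
pseudocounted output:input ratio normalised by the library-wide ratio,

    SE_j = ((o_j + 1) / (i_j + 1)) / (sum_k (o_k + 1) / sum_k (i_k + 1)),

and a hexamer's branchpoint functional score is log2 of its mean splicing
efficiency across barcode pairs and replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBundle, revcomp

HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
HEX_INDEX = {h: i for i, h in enumerate(HEXAMERS)}
BARCODE_LEN = 11
STOP_MOTIFS = ("TAA", "TGA", "TCA")  # potential alternative branch sites
INTRON_TAIL_LEN = 98
EXON_HEAD_LEN = 30
# hexamer frame: branch nucleotide at position 4 of the 6-mer (-3..+2)
BP_HEXAMER_OFFSET = 3

_B4 = {b: i for i, b in enumerate("ACGT")}


def _encode_barcodes(barcodes: np.ndarray) -> np.ndarray:
    """(n, 11) uint8 base codes from an array of 11-mer strings."""
    arr = np.asarray(barcodes).astype(f"S{BARCODE_LEN}")
    ascii_codes = arr.view(np.uint8).reshape(-1, BARCODE_LEN)
    code = np.zeros(256, dtype=np.uint8)
    for b, i in _B4.items():
        code[ord(b)] = i
    return code[ascii_codes]


def generate_barcode_pool(n: int, seed: int = 0) -> np.ndarray:
    """Seeded random 11-mer barcode pool (unique)."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(int(n * 1.05), BARCODE_LEN),
                         dtype=np.uint8)
    ascii_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    pool = np.unique(np.ascontiguousarray(ascii_codes)
                     .view(f"S{BARCODE_LEN}").ravel())
    rng.shuffle(pool)
    return pool[:n].astype(f"U{BARCODE_LEN}")


def synthetic_hexamer_score_tables(seed: int = 0,
                                   n_tables: int = 5) -> dict[str, pd.Series]:
    """Synthetic stand-ins for published ESE/ISE hexamer activity tables.

    The real tables are prior publications' data supplied as TSV inputs
    (hexamer, score); these seeded normal draws have the same schema and are
    for testing and demonstration only.
    """
    rng = np.random.default_rng(seed)
    names = ["exon_inclusion", "alt3_exonic", "alt5_exonic",
             "alt3_intronic", "alt5_intronic"][:n_tables]
    return {name: pd.Series(rng.normal(0, 1, len(HEXAMERS)), index=HEXAMERS)
            for name in names}


def load_hexamer_score_table(path: str) -> pd.Series:
    """TSV schema: two columns, hexamer and score, no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["hexamer", "score"])
    return df.set_index("hexamer")["score"].astype(float)


def _contains_stop_motif(codes: np.ndarray) -> np.ndarray:
    """Boolean per barcode: contains TAA/TGA/TCA."""
    tri = (codes[:, :-2] * 16 + codes[:, 1:-1] * 4 + codes[:, 2:])
    bad = {sum(_B4[b] * 4 ** (2 - i) for i, b in enumerate(m))
           for m in STOP_MOTIFS}
    mask = np.zeros(codes.shape[0], dtype=bool)
    for v in bad:
        mask |= (tri == v).any(axis=1)
    return mask


def filter_barcodes(pool: np.ndarray,
                    score_tables: dict[str, pd.Series]) -> np.ndarray:
    """The barcode prefilter.

    (1) Reject barcodes containing a TAA/TGA/TCA motif. (2) For each hexamer
    activity table, rank the remaining barcodes by the sum of squared scores
    of their six overlapping hexamers and keep only barcodes in the bottom
    50% of every ranking.
    """
    pool = np.asarray(pool)
    codes = _encode_barcodes(pool)
    keep = ~_contains_stop_motif(codes)
    pool, codes = pool[keep], codes[keep]
    powers = 4 ** np.arange(5, -1, -1)
    hex_idx = np.zeros((codes.shape[0], BARCODE_LEN - 5), dtype=np.int64)
    for k in range(6):
        hex_idx += codes[:, k:k + BARCODE_LEN - 5].astype(np.int64) * powers[k]
    ok = np.ones(codes.shape[0], dtype=bool)
    for name, table in score_tables.items():
        scores = table.reindex(HEXAMERS).to_numpy(dtype=float)
        sumsq = (scores[hex_idx] ** 2).sum(axis=1)
        ok &= sumsq <= np.median(sumsq)
    return pool[ok]


def design_library(barcode_pool: np.ndarray,
                   score_tables: dict[str, pd.Series],
                   n_barcode_pairs: int = 4, seed: int = 0) -> pd.DataFrame:
    """Enumerate 4096 hexamers x ``n_barcode_pairs`` barcode pairs.

    Barcodes are prefiltered (stop-motif and activity-rank filters), shuffled
    deterministically, and assigned pairwise to species. Raises when the
    filtered pool cannot supply two distinct barcodes per species.
    """
    passed = filter_barcodes(barcode_pool, score_tables)
    n_species = len(HEXAMERS) * n_barcode_pairs
    if len(passed) < 2 * n_species:
        raise ValueError(
            f"barcode pool exhausted: {len(passed)} barcodes pass the "
            f"stop-motif and activity-rank filters, {2 * n_species} needed")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(passed))[: 2 * n_species]
    chosen = passed[order]
    rows = []
    for si, (hexamer, pair) in enumerate(
            itertools.product(HEXAMERS, range(1, n_barcode_pairs + 1))):
        rows.append({"species_id": f"{hexamer}_bc{pair}", "hexamer": hexamer,
                     "barcode_pair": pair,
                     "intronic_barcode": chosen[2 * si],
                     "exonic_barcode": chosen[2 * si + 1]})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReporterContext:
    """Constant flanks of every species: the minigene intron tail (98 nt,
    branchpoint hexamer window inside it) and exon head (30 nt)."""

    intron_tail: str    # last 98 nt of the minigene intron
    exon_head: str      # first 30 nt of the downstream exon
    bp_tail_offset: int  # branch nucleotide position within intron_tail

    def __post_init__(self):
        if len(self.intron_tail) != INTRON_TAIL_LEN:
            raise ValueError("intron tail must be 98 nt")
        if len(self.exon_head) != EXON_HEAD_LEN:
            raise ValueError("exon head must be 30 nt")


def synthetic_context(seed: int = 99) -> ReporterContext:
    """Seeded random stand-in for the minigene context sequences (the real
    APRT intron-2/exon-3 flanks are genomic data not shipped here)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    tail = list(bases[rng.integers(0, 4, INTRON_TAIL_LEN)])
    tail[-2:] = "AG"
    exon = "".join(bases[rng.integers(0, 4, EXON_HEAD_LEN)])
    bp_off = INTRON_TAIL_LEN - 25  # branch 24 nt upstream of the 3'SS
    return ReporterContext("".join(tail), exon, bp_off)


def species_sequences(library: pd.DataFrame,
                      context: ReporterContext) -> pd.DataFrame:
    """Unspliced (input minigene) and expected spliced reference per species.

    The hexamer replaces tail positions bp-3..bp+2 (branch at hexamer
    position 4). Layout: [intronic barcode][intron tail][exon head]
    [exonic barcode]; the spliced product drops the intron and its barcode.
    """
    lo = context.bp_tail_offset - BP_HEXAMER_OFFSET
    out = []
    for row in library.itertuples():
        tail = (context.intron_tail[:lo] + row.hexamer
                + context.intron_tail[lo + 6:])
        unspliced = (row.intronic_barcode + tail + context.exon_head
                     + row.exonic_barcode)
        spliced = context.exon_head + row.exonic_barcode
        out.append({"species_id": row.species_id, "unspliced": unspliced,
                    "spliced": spliced})
    return pd.DataFrame(out)


def assign_reads_to_species(reads: list[str], references: pd.DataFrame,
                            ) -> pd.DataFrame:
    """Count reads per species by unique exact match to a reference.

    A read matching references of two different species (or both classes) is
    discarded as multimapping.
    """
    lookup: dict[str, tuple[str, str] | None] = {}
    for row in references.itertuples():
        for cls in ("unspliced", "spliced"):
            seq = getattr(row, cls)
            tag = (row.species_id, "input" if cls == "unspliced" else "output")
            if seq in lookup and lookup[seq] != tag:
                lookup[seq] = None  # shared sequence: never assignable
            else:
                lookup.setdefault(seq, tag)
    counts = {(row.species_id, cls): 0 for row in references.itertuples()
              for cls in ("input", "output")}
    for read in reads:
        tag = lookup.get(read)
        if tag is not None:
            counts[tag] += 1
    rows = [{"species_id": sid,
             "input_count": counts[(sid, "input")],
             "output_count": counts[(sid, "output")]}
            for sid in references["species_id"]]
    return pd.DataFrame(rows)


def splicing_efficiency(counts: pd.DataFrame,
                        group_col: str | None = "replicate") -> pd.DataFrame:
    """Per-species splicing efficiency, exactly the printed formula.

    A pseudocount of 1 is added to every count; each species' output:input
    ratio is divided by the library-wide ratio (computed within each
    ``group_col`` group, normally a replicate). The algebraic identity
    sum_j SE_j (i_j + 1) = sum_j (i_j + 1) is asserted on every computation.
    """
    df = counts.copy()

    def _se(sub: pd.DataFrame) -> pd.Series:
        o1 = sub["output_count"].to_numpy(dtype=float) + 1.0
        i1 = sub["input_count"].to_numpy(dtype=float) + 1.0
        lib_ratio = o1.sum() / i1.sum()
        se = (o1 / i1) / lib_ratio
        assert np.isclose((se * i1).sum(), i1.sum(), rtol=1e-12), \
            "splicing-efficiency normalisation identity violated"
        return pd.Series(se, index=sub.index)

    if group_col is not None and group_col in df.columns:
        se = pd.Series(np.nan, index=df.index)
        for _, idx in df.groupby(group_col).groups.items():
            se.loc[idx] = _se(df.loc[idx])
        df["se"] = se
    else:
        df["se"] = _se(df)
    return df


def bp_functional_score(se_table: pd.DataFrame,
                        library: pd.DataFrame | None = None) -> pd.DataFrame:
    """Branchpoint functional score per hexamer.

    score = log2(mean SE over all barcode-pair x replicate observations);
    the mean and standard deviation of those observations are reported
    alongside, as are per-ordering variants (mean-then-log and
    mean-of-per-replicate-logs) for comparison.
    """
    if "hexamer" not in se_table.columns:
        if library is None:
            raise ValueError("need hexamer column or a library to join on")
        se_table = se_table.merge(
            library[["species_id", "hexamer"]], on="species_id")
    grouped = se_table.groupby("hexamer")["se"]
    out = pd.DataFrame({
        "mean_se": grouped.mean(),
        "sd_se": grouped.std(ddof=1),
        "n_obs": grouped.size(),
    })
    out["score"] = np.log2(out["mean_se"])
    if "replicate" in se_table.columns:
        per_rep = (se_table.groupby(["hexamer", "replicate"])["se"].mean()
                   .groupby("hexamer").apply(lambda s: np.log2(s).mean()))
        out["score_mean_of_rep_logs"] = per_rep
    return out


def annotate_bp_window_score(branchpoints: pd.DataFrame, bundle: GenomeBundle,
                             scores: "pd.Series | dict", window: int = 11
                             ) -> pd.DataFrame:
    """Maximum branchpoint functional score in a window centred on each
    branchpoint.

    ``branchpoints`` needs chrom / branchpoint / strand columns. All hexamers
    fully contained in the (strand-aware) window are scored; branchpoints too
    close to a contig edge are annotated over the truncated window and
    flagged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    scores = pd.Series(scores)
    half = window // 2
    rows = []
    for r in branchpoints.itertuples():
        ref_len = len(bundle.sequences[r.chrom])
        lo, hi = r.branchpoint - half, r.branchpoint + half + 1
        truncated = lo < 0 or hi > ref_len
        lo, hi = max(0, lo), min(ref_len, hi)
        seq = bundle.fetch(r.chrom, lo, hi, r.strand)
        best = -np.inf
        for k in range(len(seq) - 5):
            val = scores.get(seq[k:k + 6])
            if val is not None and val > best:
                best = float(val)
        rows.append({"chrom": r.chrom, "branchpoint": r.branchpoint,
                     "strand": r.strand,
                     "max_window_score": best if np.isfinite(best) else np.nan,
                     "truncated_window": truncated})
    return pd.DataFrame(rows)
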