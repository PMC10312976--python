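"""Alignment contract shared by both lariat mappers.

The built-in aligner enumerates *every* placement of a read on a reference
within an explicit edit budget (substitutions plus at most a configurable
number of short indels), which is adequate and exact on toy-genome scales.
Alignments are canonicalised as one record per (reference, strand, start,
indel signature); for a given indel signature the placement with the fewest
mismatches (leftmost on ties) is reported.

Externally produced SAM records may be imported in place of the built-in
aligner; they must carry NM-style edit information.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib
import numpy as np

from .genome import GenomeBundle, revcomp

_BASE_CODE = np.full(256, 250, dtype=np.uint8)  # non-ACGT codes never match
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_SENTINEL = 255


def encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Read:
    """A sequencing read; the ambiguous fraction is derived, never stored."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id} has empty sequence")

    @property
    def ambiguous_fraction(self) -> float:
        n_bad = sum(1 for c in self.sequence.upper() if c not in "ACGT")
        return n_bad / len(self.sequence)


@dataclass(frozen=True)
class Indel:
    """``kind`` 'D': read is missing ``length`` reference bases at read offset
    ``read_pos``; 'I': read carries ``length`` extra bases there."""

    read_pos: int
    length: int
    kind: str  # 'D' | 'I'


@dataclass(frozen=True)
class AlignmentParams:
    max_mismatches: int = 5
    max_indels: int = 1
    max_indel_len: int = 3
    max_mismatch_rate: float | None = None  # None: no rate filter
    mismatch_penalty: int = 2
    gap_open_penalty: int = 3
    gap_extend_penalty: int = 0
    both_strands: bool = True

    @property
    def edit_budget(self) -> int:
        return self.max_mismatches + self.max_indels * self.max_indel_len


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    indels: tuple[Indel, ...]
    score: int
    aligned_read_bases: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")
        if self.mismatches > self.aligned_read_bases:
            raise ValueError("mismatch count exceeds aligned length")

    @property
    def mismatch_rate(self) -> float:
        return self.mismatches / self.aligned_read_bases


def _score(matches: int, mismatches: int, indels: Sequence[Indel],
           params: AlignmentParams) -> int:
    s = matches - params.mismatch_penalty * mismatches
    for ind in indels:
        s -= params.gap_open_penalty + params.gap_extend_penalty * ind.length
    return s


def align_to_reference(read_seq: str, ref_seq: str, params: AlignmentParams,
                       read_id: str = "", ref_id: str = "",
                       strand: str = "+") -> list[AlignmentRecord]:
    """All placements of ``read_seq`` (as given) on the forward ``ref_seq``
    within the edit budget. Complete for 0 or 1 indel."""
    m, n = len(read_seq), len(ref_seq)
    if m < 1 or n < m:
        return []
    out: list[AlignmentRecord] = []
    read_arr = encode(read_seq)
    pad = params.max_indel_len if params.max_indels >= 1 else 0
    ref_arr = np.full(n + pad, _SENTINEL, dtype=np.uint8)
    ref_arr[:n] = encode(ref_seq)

    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, m)
    mism_mat = (windows != read_arr)  # (n_starts, m) bool
    mm_total = mism_mat.sum(axis=1, dtype=np.int32)

    # no-indel placements
    for s in np.nonzero(mm_total[: n - m + 1] <= params.max_mismatches)[0]:
        mm = int(mm_total[s])
        out.append(AlignmentRecord(
            read_id=read_id, ref_id=ref_id, start=int(s), end=int(s) + m,
            strand=strand, mismatches=mm, indels=(),
            score=_score(m - mm, mm, (), params), aligned_read_bases=m))

    if params.max_indels >= 1 and m >= 2:
        # prefix-mismatch cumsums: P[s, p] = mismatches of read[:p] vs ref[s:s+p]
        P = np.zeros((mism_mat.shape[0], m + 1), dtype=np.int32)
        np.cumsum(mism_mat, axis=1, dtype=np.int32, out=P[:, 1:])
        for L in range(1, params.max_indel_len + 1):
            out.extend(_one_indel_pass(P, m, n, L, "D", read_id, ref_id,
                                       strand, params))
            if m - L >= 2:
                out.extend(_one_indel_pass(P, m, n, L, "I", read_id, ref_id,
                                           strand, params))
    return out


def _one_indel_pass(P: np.ndarray, m: int, n: int, L: int, kind: str,
                    read_id: str, ref_id: str, strand: str,
                    params: AlignmentParams) -> list[AlignmentRecord]:
    out = []
    if kind == "D":
        # read missing L ref bases after read offset p: columns
        # read[:p]~ref[s:s+p], read[p:]~ref[s+p+L:s+m+L]; valid s+m+L<=n
        hi = n - m - L
        if hi < 0:
            return out
        ss = np.arange(hi + 1)
        diff = P[ss][:, 1:m] - P[ss + L][:, 1:m]  # p in 1..m-1
        best_p = np.argmin(diff, axis=1)
        total = diff[np.arange(len(ss)), best_p] + P[ss + L, m]
        aligned = m
        span = m + L
    else:
        # read has L extra bases at offset p: read[:p]~ref[s:s+p],
        # read[p+L:]~ref[s+p:s+m-L]; valid L<=s<=n-m+L
        lo, hi = L, n - m + L
        if hi < lo:
            return out
        ss = np.arange(lo, hi + 1)
        p_hi = m - L  # p in 1..m-L-1
        diff = P[ss][:, 1:p_hi] - P[ss - L][:, 1 + L:p_hi + L]
        if diff.shape[1] == 0:
            return out
        best_p = np.argmin(diff, axis=1)
        total = diff[np.arange(len(ss)), best_p] + P[ss - L, m]
        aligned = m - L
        span = m - L
    ok = np.nonzero(total <= params.max_mismatches)[0]
    for k in ok:
        s = int(ss[k])
        mm = int(total[k])
        p = int(best_p[k]) + 1
        ind = (Indel(read_pos=p, length=L, kind=kind),)
        out.append(AlignmentRecord(
            read_id=read_id, ref_id=ref_id, start=s, end=s + span,
            strand=strand, mismatches=mm, indels=ind,
            score=_score(aligned - mm, mm, ind, params),
            aligned_read_bases=aligned))
    return out


def align_exhaustive(read: Read, bundle: GenomeBundle,
                     params: AlignmentParams | None = None) -> list[AlignmentRecord]:
    """All alignments of ``read`` on every reference (both strands unless
    disabled), sorted by (reference id, start, strand)."""
    params = params or AlignmentParams()
    if not bundle.sequences:
        raise ValueError("empty reference set")
    if len(read.sequence) < 16:
        raise ValueError("reads shorter than 16 nt are not alignable here")
    out: list[AlignmentRecord] = []
    for ref_id in sorted(bundle.sequences):
        ref_seq = bundle.sequences[ref_id]
        out.extend(align_to_reference(read.sequence, ref_seq, params,
                                      read.id, ref_id, "+"))
        if params.both_strands:
            out.extend(align_to_reference(revcomp(read.sequence), ref_seq,
                                          params, read.id, ref_id, "-"))
    if params.max_mismatch_rate is not None:
        out = [r for r in out if r.mismatch_rate <= params.max_mismatch_rate]
    out.sort(key=lambda r: (r.ref_id, r.start, r.strand, r.end,
                            tuple((i.kind, i.read_pos, i.length) for i in r.indels)))
    return out


def edit_stats(read_seq: str, ref_seq: str, offset: int,
               indels: Iterable[Indel] = ()) -> tuple[int, float, list[Indel]]:
    """Mismatch count, mismatch rate and indel list for an explicit placement.

    The rate denominator is the number of aligned read bases; gap columns are
    excluded from both numerator and denominator.
    """
    indels = sorted(indels, key=lambda i: i.read_pos)
    if offset < 0:
        raise IndexError("placement before reference start")
    mism = 0
    aligned = 0
    rp, gp = 0, offset
    events = {i.read_pos: i for i in indels}
    m = len(read_seq)
    while rp < m:
        if rp in events:
            ev = events.pop(rp)
            if ev.kind == "D":
                gp += ev.length
            else:
                rp += ev.length
                continue
        if gp >= len(ref_seq):
            raise IndexError("placement runs past reference end")
        if read_seq[rp].upper() != ref_seq[gp].upper():
            mism += 1
        aligned += 1
        rp += 1
        gp += 1
    rate = mism / aligned if aligned else 0.0
    return mism, rate, list(indels)


def passes_edit_filters(record: AlignmentRecord, params: AlignmentParams) -> bool:
    """The printed per-alignment filters, boundaries exactly as stated:
    mismatches <= max, rate <= max (when set), indel count <= max, every
    indel length <= max."""
    if record.mismatches > params.max_mismatches:
        return False
    if (params.max_mismatch_rate is not None
            and record.mismatch_rate > params.max_mismatch_rate):
        return False
    if len(record.indels) > params.max_indels:
        return False
    if any(i.length > params.max_indel_len for i in record.indels):
        return False
    return True


# -- full-linear-mapping detection --------------------------------------

FULL_LINEAR_CLIP = 2  # soft-clips of <=2 nt still count as a full linear map


def has_full_linear_alignment(read: Read, bundle: GenomeBundle,
                              params: AlignmentParams | None = None) -> bool:
    """True if the read maps linearly over at least its length minus
    ``FULL_LINEAR_CLIP`` bases within the edit budget.

    A bit-parallel infix pre-screen (edlib) nominates candidate loci; the
    exact aligner then adjudicates each locus, trying every terminal-clip
    combination up to the allowance.
    """
    params = params or AlignmentParams()
    seq = read.sequence.upper()
    k = params.edit_budget + FULL_LINEAR_CLIP
    m = len(seq)
    for ref_id in sorted(bundle.sequences):
        ref = bundle.sequences[ref_id]
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            if not params.both_strands and strand == "-":
                continue
            res = edlib.align(query, ref, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                continue
            for loc_start, loc_end in res["locations"]:
                lo = max(0, loc_start - params.max_indel_len - FULL_LINEAR_CLIP)
                hi = min(len(ref), loc_end + 1 + params.max_indel_len
                         + FULL_LINEAR_CLIP)
                window = ref[lo:hi]
                for c0 in range(FULL_LINEAR_CLIP + 1):
                    for c1 in range(FULL_LINEAR_CLIP + 1 - c0):
                        sub = query[c0: m - c1]
                        if len(sub) < 16:
                            continue
                        for rec in align_to_reference(sub, window, params):
                            if passes_edit_filters(rec, params):
                                return True
    return False


# -- SAM import ----------------------------------------------------------

def import_sam(path: str, params: AlignmentParams | None = None) -> list[AlignmentRecord]:
    """Import externally produced alignments (SAM) as AlignmentRecords.

    Coordinates are converted to 0-based half-open. Records without an NM tag
    are rejected: the edit filters cannot be evaluated without it.
    """
    import pysam

    params = params or AlignmentParams()
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise ValueError(
                    f"SAM record {rec.query_name} lacks NM edit information")
            nm = rec.get_tag("NM")
            indels = []
            read_pos = 0
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    read_pos += length
                elif op == 1:  # I
                    indels.append(Indel(read_pos, length, "I"))
                    read_pos += length
                elif op == 2:  # D
                    indels.append(Indel(read_pos, length, "D"))
                elif op in (4, 5):  # clips
                    read_pos += length if op == 4 else 0
            indel_bases = sum(i.length for i in indels)
            mism = int(nm) - indel_bases
            if mism < 0:
                raise ValueError(
                    f"SAM record {rec.query_name}: NM inconsistent with CIGAR")
            aligned = sum(l for op, l in (rec.cigartuples or ())
                          if op in (0, 7, 8))
            out.append(AlignmentRecord(
                read_id=rec.query_name, ref_id=rec.reference_name,
                start=rec.reference_start, end=rec.reference_end,
                strand="-" if rec.is_reverse else "+", mismatches=mism,
                indels=tuple(indels),
                score=_score(aligned - mism, mism, indels, params),
                aligned_read_bases=aligned))
    return out
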