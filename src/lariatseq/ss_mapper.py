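"""Splice-site-probe lariat mapper.

Reads with over 5% ambiguous characters are removed, then linearly mapping
reads are discarded. The first 20 nt of every annotated intron form a probe
set (identical 20-mers collapsed into one probe); probes are located in the
remaining reads by exact substring search. A read matched by two or more
distinct probe sequences is dropped; otherwise it is trimmed from the start
of the probe match to its end, and trimmed prefixes shorter than 20 nt are
dropped. Each surviving prefix is aligned to the last 250 nt of every
annotated intron under explicit edit filters (<=5 mismatches, <=10% mismatch
rate, at most one indel of <=3 nt); survivors are restricted to introns of
the probe's gene(s) with the inverted mapping order expected of a lariat, and
the end of the highest-scoring alignment is the branchpoint call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import (AlignmentParams, Read, align_to_reference,
                    passes_edit_filters)
from .calls import LariatCall, calls_to_dataframe
from .genome import GenomeBundle, Intron, revcomp
from .split_mapper import SplitMapperParams, filter_linear

logger = logging.getLogger(__name__)

PROBE_LEN = 20
TAIL_LEN = 250


@dataclass(frozen=True)
class SpliceSiteMapperParams:
    max_ambiguous_fraction: float = 0.05
    min_prefix: int = 20
    circle_margin: int = 2
    tail: AlignmentParams = field(default_factory=lambda: AlignmentParams(
        max_mismatches=5, max_indels=1, max_indel_len=3,
        max_mismatch_rate=0.10, gap_extend_penalty=1, both_strands=False))
    linear: AlignmentParams = field(default_factory=lambda: AlignmentParams(
        max_mismatches=5, max_indels=0))
    try_reverse_complement: bool = True


@dataclass(frozen=True)
class FivePrimeProbe:
    """One distinct 20-mer taken from the start of one or more introns."""

    sequence: str
    intron_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequence) != PROBE_LEN:
            raise ValueError("probe must be exactly 20 nt")


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    prefix: str
    probe: FivePrimeProbe
    match_start: int   # probe offset within the (possibly re-oriented) read
    orientation: str   # '+' read as given, '-' reverse-complemented


def filter_ambiguous(reads: list[Read],
                     max_fraction: float = 0.05) -> list[Read]:
    """Drop reads with strictly more than ``max_fraction`` non-ACGT bases."""
    kept = [r for r in reads if r.ambiguous_fraction <= max_fraction]
    logger.info("filter_ambiguous: discarded %d of %d reads",
                len(reads) - len(kept), len(reads))
    return kept


def build_5ss_probes(bundle: GenomeBundle) -> list[FivePrimeProbe]:
    """First 20 nt of each annotated intron, strand-aware, deduplicated."""
    by_seq: dict[str, list[Intron]] = {}
    for iv in bundle.introns:
        if iv.length < PROBE_LEN:
            logger.warning("intron %s shorter than %d nt: no probe",
                           iv.intron_id, PROBE_LEN)
            continue
        by_seq.setdefault(bundle.intron_seq(iv)[:PROBE_LEN], []).append(iv)
    return [FivePrimeProbe(seq,
                           tuple(iv.intron_id for iv in ivs),
                           tuple(sorted({iv.gene_id for iv in ivs})))
            for seq, ivs in sorted(by_seq.items())]


def match_and_trim(read: Read, probes: list[FivePrimeProbe],
                   params: SpliceSiteMapperParams | None = None
                   ) -> TrimmedRead | None:
    """Locate the unique probe in the read and trim from its start onward.

    Exact substring search of every probe against the read (and its reverse
    complement when enabled). Reads matched by two or more distinct probe
    sequences are dropped; so are prefixes shorter than the minimum. When
    one probe occurs at several positions the rightmost is used: the 5'SS
    segment is the read's final segment in a branchpoint read-through, so a
    branchpoint close to the intron start can legitimately place the
    intron's first bases inside the upstream segment as well.
    """
    params = params or SpliceSiteMapperParams()
    orientations = [("+", read.sequence)]
    if params.try_reverse_complement:
        orientations.append(("-", revcomp(read.sequence)))
    hits: list[tuple[str, str, int, FivePrimeProbe]] = []
    for orient, seq in orientations:
        for probe in probes:
            pos = seq.rfind(probe.sequence)
            if pos >= 0:
                hits.append((orient, seq, pos, probe))
    if len({h[3].sequence for h in hits}) != 1:
        return None  # zero probes, or more than one distinct 5'SS sequence
    orient, seq, pos, probe = hits[0]
    prefix = seq[:pos]
    if len(prefix) < params.min_prefix:
        return None
    return TrimmedRead(read.id, prefix, probe, pos, orient)


def build_intron_tails(bundle: GenomeBundle) -> dict[str, tuple[Intron, int, str]]:
    """Last 250 nt of every intron (whole intron if shorter), transcription
    orientation. Maps intron id -> (intron, tail transcript offset, tail)."""
    tails = {}
    for iv in bundle.introns:
        iseq = bundle.intron_seq(iv)
        off = max(0, len(iseq) - TAIL_LEN)
        tails[iv.intron_id] = (iv, off, iseq[off:])
    return tails


def write_tail_fasta(bundle: GenomeBundle, path: str | Path) -> None:
    """Materialise the intron-tail index; headers carry intron id and the
    tail's transcript offset."""
    with open(path, "w") as fh:
        for intron_id, (iv, off, tail) in sorted(
                build_intron_tails(bundle).items()):
            fh.write(f">{intron_id}|offset={off}\n{tail}\n")


def map_trimmed_to_tails(trimmed: TrimmedRead, bundle: GenomeBundle,
                         params: SpliceSiteMapperParams | None = None,
                         tails: dict | None = None
                         ) -> tuple[LariatCall | None, str]:
    """Align the trimmed prefix to every intron tail and call the branchpoint.

    Returns (call | None, status) with status in ``called``, ``no_survivor``,
    ``circle_filtered``, ``ambiguous``.
    """
    params = params or SpliceSiteMapperParams()
    if tails is None:
        tails = build_intron_tails(bundle)
    probe_genes = set(trimmed.probe.gene_ids)
    saw_circle = False
    best: dict[tuple[str, int], tuple[int, LariatCall]] = {}
    for intron_id, (iv, off, tail) in tails.items():
        recs = []
        for rec in align_to_reference(trimmed.prefix, tail, params.tail):
            if not passes_edit_filters(rec, params.tail):
                logger.debug("%s vs %s: candidate fails edit filters",
                             trimmed.read_id, intron_id)
                continue
            recs.append(rec)
        if not recs:
            continue
        # best-hit semantics per tail: a suboptimal gapped placement must not
        # slip a circle read's prefix past the intron-terminus margin
        top_score = max(r.score for r in recs)
        for rec in recs:
            if rec.score < top_score:
                continue
            if iv.gene_id not in probe_genes:
                logger.debug("%s vs %s: different gene from the 5'SS probe",
                             trimmed.read_id, intron_id)
                continue
            bp_rel = off + rec.end - 1
            # inverted mapping order: the prefix must land genomically
            # downstream of the 5'SS block it precedes in the read
            if bp_rel < PROBE_LEN:
                continue
            if bp_rel >= iv.length - 1 - params.circle_margin:
                saw_circle = True
                continue
            call = LariatCall(
                read_id=trimmed.read_id, intron_id=iv.intron_id,
                gene_id=iv.gene_id, chrom=iv.chrom, strand=iv.strand,
                intron_start=iv.start, intron_end=iv.end,
                five_prime_ss=bundle.genomic_pos(iv, 0),
                branchpoint=bundle.genomic_pos(iv, bp_rel),
                head_mismatches=rec.mismatches, tail_mismatches=0,
                method="ss")
            key = (iv.intron_id, bp_rel)
            if key not in best or rec.score > best[key][0]:
                best[key] = (rec.score, call)
    if not best:
        return None, ("circle_filtered" if saw_circle else "no_survivor")
    top = max(s for s, _ in best.values())
    winners = [c for s, c in best.values() if s == top]
    if len(winners) > 1:
        return None, "ambiguous"
    return winners[0], "called"


def run_ss_pipeline(reads: "list[Read] | str | Path", bundle: GenomeBundle,
                    params: SpliceSiteMapperParams | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Whole splice-site-probe procedure; returns (calls table, summary).

    The summary reports probe-uniqueness tallies both at the distinct-sequence
    level (the filter actually applied) and at the intron-id level.
    """
    params = params or SpliceSiteMapperParams()
    if not isinstance(reads, list):
        from .simulate import read_fastq
        reads = [Read(rid, seq) for rid, seq in read_fastq(reads)]
    summary = {"input": len(reads), "ambiguous_char_filtered": 0,
               "linear_discarded": 0, "probe_matched": 0,
               "unique_probe_sequence": 0, "unique_probe_intron": 0,
               "short_prefix_or_multi_probe": 0, "no_survivor": 0,
               "circle_filtered": 0, "ambiguous": 0, "called": 0}
    clean = filter_ambiguous(reads, params.max_ambiguous_fraction)
    summary["ambiguous_char_filtered"] = len(reads) - len(clean)
    linear_params = SplitMapperParams(linear=params.linear)
    survivors = filter_linear(clean, bundle, linear_params)
    summary["linear_discarded"] = len(clean) - len(survivors)
    probes = build_5ss_probes(bundle)
    tails = build_intron_tails(bundle)
    calls = []
    for read in survivors:
        trimmed = match_and_trim(read, probes, params)
        if trimmed is None:
            summary["short_prefix_or_multi_probe"] += 1
            continue
        summary["probe_matched"] += 1
        summary["unique_probe_sequence"] += 1
        if len(trimmed.probe.intron_ids) == 1:
            summary["unique_probe_intron"] += 1
        call, status = map_trimmed_to_tails(trimmed, bundle, params, tails)
        summary[status] += 1
        if call is not None:
            calls.append(call)
    return calls_to_dataframe(calls), summary
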