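"""Iterative read-splitting lariat mapper.

Reads with a full linear mapping are discarded. Each surviving read is split
into every head/tail pair with both parts over the minimum segment length; a
split is accepted when the tail aligns beginning exactly at some intron's
first base and the head aligns within the same intron, ending strictly
upstream of the intron-circle margin. The genomic position of the head
alignment's last base is the branchpoint call. Candidates whose head ends at
the intron's 3' terminus are intron circles and are filtered out; reads with
multiple surviving (intron, branchpoint) candidates at the best combined
alignment score are dropped as ambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .align import (AlignmentParams, AlignmentRecord, Read, align_to_reference,
                    has_full_linear_alignment, passes_edit_filters)
from .calls import LariatCall, calls_to_dataframe
from .genome import GenomeBundle, Intron, revcomp

logger = logging.getLogger(__name__)

_ANCHOR_KEY = 16  # tail-anchor index key length (= minimum segment length)


@dataclass(frozen=True)
class SplitMapperParams:
    min_segment: int = 16        # ">15 bp" read as >=16 nt, strictly as printed
    circle_margin: int = 2       # head ends within this of the 3' end -> circle
    anchor_max_mismatches: int = 0  # 5'SS tail anchor: exact by default
    # linear-discard pass: ungapped, like the short-read aligners typically
    # used for a first end-to-end pass; a gapped budget here lets the junk
    # tail of a chimeric read be absorbed by clip+indel+mismatch allowances
    linear: AlignmentParams = field(default_factory=lambda: AlignmentParams(
        max_mismatches=5, max_indels=0))
    head: AlignmentParams = field(default_factory=lambda: AlignmentParams(
        max_mismatch_rate=0.10, both_strands=False))
    try_reverse_complement: bool = True


@dataclass(frozen=True)
class SplitCandidate:
    read_id: str
    split_point: int
    head: str
    tail: str

    def __post_init__(self):
        if len(self.head) < 16 or len(self.tail) < 16:
            raise ValueError("head and tail must both be >= 16 nt")


def enumerate_splits(read: Read, min_segment: int = 16) -> list[SplitCandidate]:
    """All head/tail splits with both parts at least ``min_segment`` nt."""
    seq = read.sequence
    return [SplitCandidate(read.id, p, seq[:p], seq[p:])
            for p in range(min_segment, len(seq) - min_segment + 1)]


def build_anchor_index(bundle: GenomeBundle) -> dict[str, list[Intron]]:
    """First-16-mer of every intron (transcription orientation) -> introns."""
    index: dict[str, list[Intron]] = {}
    for iv in bundle.introns:
        if iv.length < _ANCHOR_KEY:
            continue
        key = bundle.intron_seq(iv)[:_ANCHOR_KEY]
        index.setdefault(key, []).append(iv)
    return index


def filter_linear(reads: list[Read], bundle: GenomeBundle,
                  params: SplitMapperParams | None = None) -> list[Read]:
    """Exactly the reads with no full linear alignment under the budget."""
    params = params or SplitMapperParams()
    kept = [r for r in reads
            if not has_full_linear_alignment(r, bundle, params.linear)]
    logger.info("filter_linear: discarded %d of %d reads",
                len(reads) - len(kept), len(reads))
    return kept


def _tail_anchors(tail: str, index: dict[str, list[Intron]],
                  bundle: GenomeBundle, max_mm: int) -> list[tuple[Intron, int]]:
    """Introns whose first bases the tail matches, with mismatch counts."""
    out = []
    for iv in index.get(tail[:_ANCHOR_KEY], []):
        iseq = bundle.intron_seq(iv)
        if len(tail) > len(iseq):
            continue
        mm = sum(1 for a, b in zip(tail, iseq) if a != b)
        if mm <= max_mm:
            out.append((iv, mm))
    return out


def call_lariat_splitread(read: Read, bundle: GenomeBundle,
                          params: SplitMapperParams | None = None,
                          anchor_index: dict | None = None
                          ) -> tuple[LariatCall | None, str]:
    """Branchpoint call for one read, plus a status label.

    Status is one of ``called``, ``too_short``, ``no_candidate``,
    ``circle_filtered`` (only circle-margin candidates found) or
    ``ambiguous`` (several introns/branchpoints tie at the best score).
    """
    params = params or SplitMapperParams()
    if len(read.sequence) < 2 * params.min_segment:
        return None, "too_short"
    if anchor_index is None:
        anchor_index = build_anchor_index(bundle)

    # (intron_id, bp_rel) -> (score, call fields)
    best: dict[tuple[str, int], tuple[int, LariatCall]] = {}
    saw_circle = False
    orientations = [read.sequence]
    if params.try_reverse_complement:
        orientations.append(revcomp(read.sequence))
    for seq in orientations:
        for cand in enumerate_splits(Read(read.id, seq), params.min_segment):
            for iv, tail_mm in _tail_anchors(cand.tail, anchor_index, bundle,
                                             params.anchor_max_mismatches):
                iseq = bundle.intron_seq(iv)
                recs = [r for r in align_to_reference(cand.head, iseq,
                                                      params.head)
                        if passes_edit_filters(r, params.head)]
                if not recs:
                    continue
                # best-hit semantics: only the aligner's top-scoring
                # placement(s) of the head within this intron are candidates;
                # a suboptimal gapped placement must not rescue a read whose
                # best head alignment ends at the intron terminus (a circle)
                top_score = max(r.score for r in recs)
                for rec in recs:
                    if rec.score < top_score:
                        continue
                    bp_rel = rec.end - 1
                    if bp_rel >= len(iseq) - 1 - params.circle_margin:
                        saw_circle = True
                        continue
                    if bp_rel < 1:
                        continue
                    tail_score = len(cand.tail) - 2 * tail_mm
                    score = rec.score + tail_score
                    call = LariatCall(
                        read_id=read.id, intron_id=iv.intron_id,
                        gene_id=iv.gene_id, chrom=iv.chrom, strand=iv.strand,
                        intron_start=iv.start, intron_end=iv.end,
                        five_prime_ss=bundle.genomic_pos(iv, 0),
                        branchpoint=bundle.genomic_pos(iv, bp_rel),
                        head_mismatches=rec.mismatches, tail_mismatches=tail_mm,
                        method="split")
                    key = (iv.intron_id, bp_rel)
                    if key not in best or score > best[key][0]:
                        best[key] = (score, call)
    if not best:
        return None, ("circle_filtered" if saw_circle else "no_candidate")
    top = max(s for s, _ in best.values())
    winners = [c for s, c in best.values() if s == top]
    if len(winners) > 1:
        logger.debug("read %s: %d tied branchpoint candidates, dropped",
                     read.id, len(winners))
        return None, "ambiguous"
    return winners[0], "called"


def run_split_pipeline(reads: "list[Read] | str | Path", bundle: GenomeBundle,
                       params: SplitMapperParams | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Whole split-read procedure: linear filter, split enumeration,
    branchpoint calling. Returns (calls table, run summary)."""
    params = params or SplitMapperParams()
    if not isinstance(reads, list):
        from .simulate import read_fastq
        reads = [Read(rid, seq) for rid, seq in read_fastq(reads)]
    summary = {"input": len(reads), "linear_discarded": 0,
               "split_candidates": 0, "circle_filtered": 0, "ambiguous": 0,
               "no_candidate": 0, "too_short": 0, "called": 0}
    survivors = filter_linear(reads, bundle, params)
    summary["linear_discarded"] = len(reads) - len(survivors)
    anchor_index = build_anchor_index(bundle)
    calls = []
    for read in survivors:
        summary["split_candidates"] += max(
            0, len(read.sequence) - 2 * params.min_segment + 1)
        call, status = call_lariat_splitread(read, bundle, params, anchor_index)
        summary[status] += 1
        if call is not None:
            calls.append(call)
    df = calls_to_dataframe(calls)
    return df, summary


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
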