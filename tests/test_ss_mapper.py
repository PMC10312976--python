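import numpy as np
import pytest

from lariatseq.align import AlignmentParams, Read
from lariatseq.ss_mapper import (SpliceSiteMapperParams, build_5ss_probes,
                                 build_intron_tails, filter_ambiguous,
                                 map_trimmed_to_tails, match_and_trim,
                                 run_ss_pipeline, TrimmedRead,
                                 write_tail_fasta)


def mutate(seq, pos):
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + alt + seq[pos + 1:]


def by_class(reads, truth, cls):
    ids = set(truth[truth.cls == cls].index)
    return [r for r in reads if r.id in ids]


# -- ambiguity filter -----------------------------------------------------

def test_ambiguous_filter_boundary_exact():
    six = Read("six", "N" * 6 + "A" * 94)     # 6% ambiguous: removed
    five = Read("five", "N" * 5 + "A" * 95)   # 5%: kept (strict >)
    clean = Read("clean", "ACGT" * 25)
    assert filter_ambiguous([six, five, clean]) == [five, clean]


# -- probes ---------------------------------------------------------------

def test_probes_dedup_and_short_intron_skip(toy_bundle, caplog):
    probes = build_5ss_probes(toy_bundle)
    seqs = [p.sequence for p in probes]
    assert len(seqs) == len(set(seqs))
    assert all(len(s) == 20 for s in seqs)
    covered = {i for p in probes for i in p.intron_ids}
    assert covered == {iv.intron_id for iv in toy_bundle.introns}


def test_probe_is_transcription_strand_sequence():
    from lariatseq.simulate import SimulationConfig, make_toy_genome
    from lariatseq.genome import revcomp
    cfg = SimulationConfig(seed=31, n_genes=3, minus_strand_fraction=1.0)
    bundle = make_toy_genome(cfg)
    probes = {i: p.sequence for p in build_5ss_probes(bundle)
              for i in p.intron_ids}
    for iv in bundle.introns:
        genomic = bundle.sequences[iv.chrom][iv.end - 20: iv.end]
        assert probes[iv.intron_id] == revcomp(genomic)
        assert probes[iv.intron_id].startswith("GT")


def test_shared_probe_collapsed():
    """Two introns starting with the same 20-mer share one probe."""
    from lariatseq.genome import GenomeBundle, Gene, Intron
    start20 = "GT" + "ACGTA" * 3 + "CGA"
    seq = "C" * 10 + start20 + "A" * 40 + "AG" + "T" * 10 \
        + start20 + "C" * 40 + "AG" + "G" * 10
    g = GenomeBundle(
        {"c": seq},
        genes=[Gene("g1", "c", 0, len(seq), "+")],
        introns=[Intron("i1", "g1", "c", 10, 72, "+"),
                 Intron("i2", "g1", "c", 82, 144, "+")])
    probes = build_5ss_probes(g)
    assert len(probes) == 1
    assert set(probes[0].intron_ids) == {"i1", "i2"}


# -- match and trim -------------------------------------------------------

def test_match_and_trim_prefix_rules(toy_bundle):
    probes = build_5ss_probes(toy_bundle)
    probe = probes[0]
    rng = np.random.default_rng(0)
    rand = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    t = match_and_trim(Read("a", rand(30) + probe.sequence + rand(10)), probes)
    assert t is not None and len(t.prefix) == 30
    assert t.probe.sequence == probe.sequence
    # 19-nt prefix: filtered
    assert match_and_trim(Read("b", rand(19) + probe.sequence), probes) is None
    # two distinct probe sequences in one read: filtered
    two = rand(25) + probe.sequence + probes[1].sequence
    assert match_and_trim(Read("c", two), probes) is None
    # no probe at all
    assert match_and_trim(Read("d", rand(60)), probes) is None


# -- tail mapping ---------------------------------------------------------

def _true_prefix(bundle, iv, n=50):
    iseq = bundle.intron_seq(iv)
    bp_rel = bundle.bp_intron_offset(iv)
    return iseq[bp_rel + 1 - n: bp_rel + 1], bp_rel


def _trimmed_for(bundle, iv, prefix):
    probes = build_5ss_probes(bundle)
    probe = next(p for p in probes if iv.intron_id in p.intron_ids)
    return TrimmedRead("t", prefix, probe, len(prefix), "+")


def test_trimmed_prefix_maps_to_true_branchpoint(toy_bundle):
    iv = toy_bundle.introns[0]
    prefix, _ = _true_prefix(toy_bundle, iv)
    call, status = map_trimmed_to_tails(_trimmed_for(toy_bundle, iv, prefix),
                                        toy_bundle)
    assert status == "called" and call.branchpoint == iv.branchpoint
    assert call.method == "ss"


def test_six_mismatches_rejected_five_accepted(toy_bundle):
    iv = toy_bundle.introns[0]
    prefix, _ = _true_prefix(toy_bundle, iv)
    five = prefix
    for p in (2, 12, 22, 32, 42):
        five = mutate(five, p)
    call, _ = map_trimmed_to_tails(_trimmed_for(toy_bundle, iv, five),
                                   toy_bundle)
    assert call is not None and call.head_mismatches == 5
    six = mutate(five, 47)
    call, _ = map_trimmed_to_tails(_trimmed_for(toy_bundle, iv, six),
                                   toy_bundle)
    assert call is None


def test_four_nt_indel_rejected_three_accepted(toy_bundle):
    iv = toy_bundle.introns[0]
    prefix, _ = _true_prefix(toy_bundle, iv, n=54)
    three = prefix[:20] + prefix[23:]   # one 3-nt deletion
    call, _ = map_trimmed_to_tails(_trimmed_for(toy_bundle, iv, three),
                                   toy_bundle)
    assert call is not None and call.branchpoint == iv.branchpoint
    four = prefix[:20] + prefix[24:]    # one 4-nt deletion
    call, _ = map_trimmed_to_tails(_trimmed_for(toy_bundle, iv, four),
                                   toy_bundle)
    assert call is None


def test_filter_monotonicity(toy_bundle):
    """Loosening any single threshold never shrinks the called set."""
    iv = toy_bundle.introns[1]
    prefix, _ = _true_prefix(toy_bundle, iv)
    noisy = prefix
    for p in (2, 12, 22, 32, 42, 47):
        noisy = mutate(noisy, p)  # 6 mismatches: fails the default budget
    trimmed = _trimmed_for(toy_bundle, iv, noisy)
    strict = SpliceSiteMapperParams()
    loose = SpliceSiteMapperParams(tail=AlignmentParams(
        max_mismatches=6, max_indels=1, max_indel_len=3,
        max_mismatch_rate=0.15, gap_extend_penalty=1, both_strands=False))
    call_strict, _ = map_trimmed_to_tails(trimmed, toy_bundle, strict)
    call_loose, _ = map_trimmed_to_tails(trimmed, toy_bundle, loose)
    assert call_strict is None and call_loose is not None


def test_tail_fasta_index(tmp_path, toy_bundle):
    p = tmp_path / "tails.fa"
    write_tail_fasta(toy_bundle, p)
    lines = p.read_text().splitlines()
    headers = [l for l in lines if l.startswith(">")]
    assert len(headers) == len(toy_bundle.introns)
    tails = build_intron_tails(toy_bundle)
    for h, s in zip(headers, lines[1::2]):
        intron_id, off = h[1:].split("|offset=")
        assert tails[intron_id][2] == s
        assert len(s) <= 250


# -- whole pipeline -------------------------------------------------------

def test_ss_pipeline_full_mix(toy_bundle, toy_reads):
    reads, truth = toy_reads
    calls, summary = run_ss_pipeline(reads, toy_bundle)
    assert summary["called"] == (truth.cls == "lariat").sum()
    assert summary["circle_filtered"] == (truth.cls == "circle").sum()
    merged = calls.set_index("read_id").join(truth, rsuffix="_t")
    assert (merged.branchpoint == merged.branchpoint_t).all()


def test_ss_pipeline_linear_only_zero_calls(toy_bundle, toy_reads):
    reads, truth = toy_reads
    calls, _ = run_ss_pipeline(by_class(reads, truth, "linear"), toy_bundle)
    assert len(calls) == 0


def test_cross_mapper_concordance(toy_bundle, toy_reads):
    """Reads eligible for both pipelines get identical branchpoints."""
    from lariatseq.split_mapper import run_split_pipeline
    reads, truth = toy_reads
    lariats = by_class(reads, truth, "lariat")
    split_calls, _ = run_split_pipeline(lariats, toy_bundle)
    ss_calls, _ = run_ss_pipeline(lariats, toy_bundle)
    merged = split_calls.merge(ss_calls, on="read_id",
                               suffixes=("_split", "_ss"))
    assert len(merged) > 0
    assert (merged.branchpoint_split == merged.branchpoint_ss).all()
    assert (merged.intron_id_split == merged.intron_id_ss).all()
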