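import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lariatseq.features import (FeatureSiteSet, classify_intronic,
                                coip_hit_filter, lariat_topology_distance,
                                motif_pfm_from_kmers, partition_bound_introns,
                                pwm_scan, rbp_lariat_response)
from lariatseq.genome import GenomeBundle, Gene, Intron, revcomp
from lariatseq.metrics import SampleLariatTable


def site_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


@pytest.fixture(scope="module")
def two_gene_bundle():
    return GenomeBundle(
        {"c": "A" * 2000},
        genes=[Gene("g1", "c", 0, 1000, "+"), Gene("g2", "c", 1000, 2000, "+")],
        introns=[Intron("i1", "g1", "c", 100, 300, "+"),
                 Intron("i2", "g1", "c", 400, 600, "+"),
                 Intron("i3", "g2", "c", 1100, 1300, "+")])


# -- partitioning ---------------------------------------------------------

def test_partition_bound_and_same_gene_control(two_gene_bundle):
    sites = FeatureSiteSet(site_df([("c", 150, 160, "s1", 0, "+")]))
    bound, control = partition_bound_introns(two_gene_bundle, sites)
    assert bound == {"i1"}
    assert control == {"i2"}  # same gene; i3's gene has no bound intron


def test_exonic_site_binds_nothing(two_gene_bundle):
    sites = FeatureSiteSet(site_df([("c", 320, 330, "s1", 0, "+"),
                                    ("c", 450, 455, "s2", 0, "+")]))
    bound, control = partition_bound_introns(two_gene_bundle, sites)
    assert bound == {"i2"} and control == {"i1"}


def test_empty_sites_partition(two_gene_bundle):
    bound, control = partition_bound_introns(
        two_gene_bundle, FeatureSiteSet(site_df([])))
    assert bound == set() == control


def test_partition_exhaustive(toy_bundle):
    from lariatseq.simulate import simulate_feature_sites
    sites, _ = simulate_feature_sites(toy_bundle, 0.4, seed=8)
    bound, control = partition_bound_introns(toy_bundle, sites)
    bound_genes = {iv.gene_id for iv in toy_bundle.introns
                   if iv.intron_id in bound}
    rest = {iv.intron_id for iv in toy_bundle.introns
            if iv.intron_id not in bound | control}
    # bound, control and unbound-in-unbound-genes cover all introns once
    assert len(bound) + len(control) + len(rest) == len(toy_bundle.introns)
    assert all(iv.gene_id not in bound_genes for iv in toy_bundle.introns
               if iv.intron_id in rest)


# -- response -------------------------------------------------------------

def test_identical_tables_give_unit_response(two_gene_bundle):
    t = SampleLariatTable("s", pd.Series({"i1": 5, "i2": 7, "i3": 2}),
                          10**6, 10**6)
    out = rbp_lariat_response({"i1"}, {"i2"}, t, t, n_boot=50, seed=1)
    assert out["fc_bound"] == pytest.approx(1.0)
    assert out["response_ratio"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        rbp_lariat_response({"i1"}, set(), t, t)


def test_planted_response_recovered(toy_bundle):
    from lariatseq.simulate import (simulate_feature_sites,
                                    simulate_lariat_count_tables)
    sites, bound_truth = simulate_feature_sites(toy_bundle, 0.5, seed=41)
    bound, control = partition_bound_introns(toy_bundle, sites)
    assert bound == bound_truth
    ko, wt = simulate_lariat_count_tables(toy_bundle, bound, extra_fc=3.0,
                                          seed=42)
    out = rbp_lariat_response(bound, control, ko, wt, seed=43)
    assert out["ci_low"] <= 3.0 <= out["ci_high"]
    assert out["response_ratio"] == pytest.approx(3.0, rel=0.4)


# -- motif PFM and scanning ----------------------------------------------

def test_identical_kmers_one_hot():
    pfm = motif_pfm_from_kmers([("ACGTA", 1.0)] * 5)
    assert pfm.consensus == "ACGTA"
    assert len(pfm.matrix) == 5
    assert (pfm.matrix.max(axis=1) == 1.0).all()


def test_offset_kmers_align_into_longer_consensus():
    pfm = motif_pfm_from_kmers([("ACGTA", 2.0), ("CGTAC", 1.0)])
    assert pfm.consensus == "ACGTAC"
    assert len(pfm.matrix) == 6


def test_single_kmer_pfm():
    pfm = motif_pfm_from_kmers([("GATTA", 1.0)])
    assert pfm.consensus == "GATTA"
    with pytest.raises(ValueError):
        motif_pfm_from_kmers([])


def test_pwm_scan_exact_consensus():
    pfm = motif_pfm_from_kmers([("ACGTA", 1.0)] * 3)
    hits = pwm_scan({"s": "ACGTA"}, pfm, threshold=0.99)
    assert hits.df[["start", "strand"]].values.tolist() == [[0, "+"]]
    assert len(pwm_scan({"s": ""}, pfm).df) == 0


def test_pwm_scan_finds_planted_occurrences():
    rng = np.random.default_rng(3)
    bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
    motif = "GCGCA"
    pos = [100, 400, 900, 1500, 2100, 2400, 2600, 2750, 2800, 2900]
    seq = list(bg)
    for p in pos:
        seq[p:p + 5] = motif
    seq = "".join(seq)
    pfm = motif_pfm_from_kmers([(motif, 1.0)] * 4)
    hits = pwm_scan({"s": seq}, pfm, threshold=0.999, both_strands=False)
    starts = set(hits.df.start)
    assert set(pos) <= starts and len(starts) >= 10


def test_pwm_scan_matches_bruteforce_log_odds():
    rng = np.random.default_rng(9)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    pfm = motif_pfm_from_kmers([("ACGTA", 3.0), ("CGTAC", 2.0),
                                ("ACGTC", 1.0)])
    lo = pfm.log_odds
    width = len(lo)
    cut = 0.6 * pfm.max_score
    expected = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - width + 1):
            score = sum(lo.loc[lo.index[k], s[i + k]] for k in range(width))
            if score >= cut:
                start = i if strand == "+" else len(s) - i - width
                expected.add((start, strand))
    got = {(r.start, r.strand)
           for r in pwm_scan({"s": seq}, pfm, threshold=0.6).df.itertuples()}
    assert got == expected


# -- lariat-loop topology -------------------------------------------------

def mk_site(start, end, name="s"):
    return site_df([("c", start, end, name, 0, "+")]).iloc[0]


INTRON = Intron("i", "g", "c", 0, 1000, "+")


@pytest.mark.parametrize("start,end,bp,side,dist", [
    (0, 10, 800, "five_prime_loop", 0),
    (760, 770, 800, "branch_loop", 31),
    (850, 860, 800, "tail", 50),
    (795, 805, 800, "branch_loop", 0),   # straddles the branchpoint
])
def test_topology_distance_rules(start, end, bp, side, dist):
    td = lariat_topology_distance(mk_site(start, end), INTRON, bp)
    assert (td.side, td.distance) == (side, dist)


def test_topology_distance_minus_strand_mirrors():
    minus = Intron("i", "g", "c", 0, 1000, "-")
    # transcript-relative: bp at offset 199 -> genomic 800
    td = lariat_topology_distance(mk_site(990, 1000), minus, 800)
    assert (td.side, td.distance) == ("five_prime_loop", 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 999), st.integers(1, 998))
def test_point_site_loop_distance_bound(pos, bp):
    """min-side distance of a 1-nt site never exceeds half the loop."""
    td = lariat_topology_distance(mk_site(pos, pos + 1), INTRON, bp)
    if td.side != "tail":
        assert 0 <= td.distance <= (bp + 1) // 2 + 1


def test_topology_site_must_overlap_intron():
    with pytest.raises(ValueError):
        lariat_topology_distance(mk_site(1500, 1600), INTRON, 800)


# -- co-IP hit filter -----------------------------------------------------

def coip_df(rows):
    return pd.DataFrame(rows, columns=["protein", "c1", "c2", "c3",
                                       "ip1", "ip2", "ip3"])


def test_coip_worked_examples():
    out = coip_hit_filter(coip_df([
        ("enriched", 0, 0, 0, 12, 11, 13),
        ("dirty_control", 5, 5, 5, 50, 51, 49),
        ("weak_ip", 0, 0, 0, 9, 10, 8),
    ])).set_index("protein")
    assert bool(out.loc["enriched", "hit"])
    assert out.loc["enriched", "fold_change"] == pytest.approx(120.0)
    assert not out.loc["dirty_control", "hit"]   # control mean >= 3
    assert not out.loc["weak_ip", "hit"]         # IP mean <= 10
    assert 0 <= out.loc["enriched", "p_value"] < 0.01


def test_coip_permuting_replicates_changes_nothing():
    a = coip_hit_filter(coip_df([("p", 1, 0, 2, 30, 20, 25)]))
    b = coip_hit_filter(coip_df([("p", 2, 1, 0, 25, 30, 20)]))
    for col in ("hit", "fold_change", "control_mean", "ip_mean"):
        assert a.loc[0, col] == b.loc[0, col]


# -- intronic classification ----------------------------------------------

def test_classify_intronic_containment(two_gene_bundle):
    sites = FeatureSiteSet(site_df([
        ("c", 150, 170, "inside", 0, "+"),
        ("c", 290, 310, "straddles", 0, "+"),
        ("c", 700, 720, "exonic", 0, "+"),
    ]), source="mirna")
    flags = classify_intronic(sites, two_gene_bundle)
    assert flags.to_dict() == {"inside": True, "straddles": False,
                               "exonic": False}
    empty = classify_intronic(FeatureSiteSet(site_df([])), two_gene_bundle)
    assert len(empty) == 0
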