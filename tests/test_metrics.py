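import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lariatseq.genome import GenomeBundle, Gene, Intron
from lariatseq.metrics import (PositionFrequencyMatrix, SampleLariatTable,
                               bp_composition, chi2_2x2, editing_rate,
                               fold_change_by_class, intron_fold_change,
                               logo_pfm, positionwise_chi2, raw_editing_rate,
                               recovery_rate, spliced_unspliced_ratio,
                               table_from_calls)


def table(counts, sample="s", total=10**6, mapped=10**6):
    return SampleLariatTable(sample, pd.Series(counts), total, mapped)


# -- recovery rate --------------------------------------------------------

@pytest.mark.parametrize("counts,denom,expect", [
    ({"i1": 10}, 1_000_000, 10.0),
    ({"i1": 0, "i2": 0}, 1_000_000, 0.0),
    ({"i1": 20, "i2": 5}, 5_000_000, 5.0),
])
def test_recovery_rate_per_million(counts, denom, expect):
    assert recovery_rate(table(counts, mapped=denom)) == expect


def test_recovery_rate_modes_and_errors():
    t = SampleLariatTable("s", pd.Series({"i": 10}), total_reads=2_000_000,
                          mapped_reads=1_000_000)
    assert recovery_rate(t, "per_total") == 5.0
    assert recovery_rate(t, "per_mapped") == 10.0
    with pytest.raises(ValueError):
        recovery_rate(t, "per_banana")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 1000), st.integers(1, 50))
def test_rate_linearity_under_doubling(count, scale):
    a = recovery_rate(table({"i": count}, mapped=1_000_000))
    b = recovery_rate(table({"i": count * scale}, mapped=1_000_000 * scale))
    assert math.isclose(a, b)


# -- fold changes ---------------------------------------------------------

def test_fold_change_examples():
    ko = table({"i1": 20, "i2": 1, "i3": 20})
    wt = table({"i1": 1, "i2": 1, "i3": 0})
    fc = intron_fold_change(ko, wt, pseudocount=1.0)
    assert fc.loc["i1", "fold_change"] == pytest.approx(21 / 2)  # 10.5
    assert fc.loc["i2", "fold_change"] == pytest.approx(1.0)
    assert fc.loc["i3", "fold_change"] == pytest.approx(21.0)


def test_fold_change_symmetry_and_universe_check():
    ko, wt = table({"i1": 30, "i2": 4}), table({"i1": 3, "i2": 9})
    ab = intron_fold_change(ko, wt)["fold_change"]
    ba = intron_fold_change(wt, ko)["fold_change"]
    assert np.allclose(ab * ba, 1.0)
    with pytest.raises(ValueError, match="i3"):
        intron_fold_change(ko, table({"i1": 1, "i3": 1}))


def test_fold_change_by_class_restricts_to_u12_genes():
    bundle = GenomeBundle(
        {"c": "A" * 1000},
        genes=[Gene("g1", "c", 0, 500, "+"), Gene("g2", "c", 500, 1000, "+")],
        introns=[
            Intron("a", "g1", "c", 10, 110, "+", "U12"),
            Intron("b", "g1", "c", 200, 300, "+", "U2"),
            Intron("d", "g2", "c", 600, 700, "+", "U2"),
        ])
    fc = intron_fold_change(table({"a": 40, "b": 20, "d": 99}),
                            table({"a": 1, "b": 1, "d": 1}))
    grouped = fold_change_by_class(fc, bundle, restrict_to_u12_genes=True)
    # gene g2 has no U12 intron: its U2 intron is excluded
    assert grouped.loc["U2", "count"] == 1
    assert grouped.loc["U12", "count"] == 1


# -- composition and logos ------------------------------------------------

def comp_bundle():
    #            0123456789
    return GenomeBundle({"c": "AAACGTAAAC" * 10})


def calls_at(positions, intron_ids=None):
    return pd.DataFrame({
        "read_id": [f"r{i}" for i in range(len(positions))],
        "chrom": "c", "strand": "+",
        "intron_id": intron_ids or ["x"] * len(positions),
        "branchpoint": positions,
        "five_prime_ss": [0] * len(positions)})


def test_bp_composition_counts():
    b = comp_bundle()
    assert bp_composition(calls_at([0, 1, 2]), b) == \
        {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}
    got = bp_composition(calls_at([0, 1, 2, 3]), b)
    assert got == {"A": 0.75, "C": 0.25, "G": 0.0, "T": 0.0}


def test_bp_composition_single_bp_filter():
    b = comp_bundle()
    calls = calls_at([0, 0, 3, 4], intron_ids=["x", "x", "y", "y"])
    got = bp_composition(calls, b, filter_single_bp=True)
    assert got == {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}  # y excluded


def test_logo_pfm_information_content():
    b = GenomeBundle({"c": "ACGTACGTAC" + "ACGTACGTAC"})
    # identical windows: 2 bits everywhere
    pfm = logo_pfm(calls_at([4, 14]), b, anchor="branchpoint", window=(-2, 2))
    assert pfm.n_sequences == 2
    assert np.allclose(pfm.information_content, 2.0)
    assert (pfm.counts.sum(axis=1) == pfm.n_sequences).all()


def test_logo_pfm_half_split_gives_one_bit():
    b = GenomeBundle({"c": "AAAAA" + "AACAA" + "T" * 10})
    pfm = logo_pfm(calls_at([2, 7]), b, anchor="branchpoint", window=(-2, 2))
    ic = pfm.information_content
    assert ic.loc[0] == pytest.approx(1.0)
    assert ic.drop(0).eq(2.0).all()


def test_logo_pfm_top_n():
    b = GenomeBundle({"c": "ACGT" * 50})
    calls = calls_at([10] * 5 + [20] * 3 + [30] * 1)
    pfm = logo_pfm(calls, b, anchor="branchpoint", window=(-1, 1), top_n=2)
    assert pfm.n_sequences == 2  # only the two best-supported anchors


# -- chi-square -----------------------------------------------------------

def test_chi2_identical_sets_is_zero():
    stat, p = chi2_2x2([[25, 25], [25, 25]])
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi2_worked_example():
    stat, p = chi2_2x2([[30, 10], [10, 30]])
    assert stat == pytest.approx(20.0)


def closed_form(t):
    (a, b), (c, d) = t
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def test_chi2_matches_closed_form_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        t = rng.integers(1, 60, size=(2, 2))
        stat, _ = chi2_2x2(t)
        assert stat == pytest.approx(closed_form(t), rel=1e-9)


def test_positionwise_chi2_g_enrichment():
    b = GenomeBundle({"c": "TTGTT" * 40})
    setA = calls_at([0] * 30)          # position +2 is G for every call
    setA["five_prime_ss"] = 0
    setB = setA.copy()
    setB["five_prime_ss"] = 1          # position +2 is T
    stat, p, tab, low = positionwise_chi2(setA, setB, b, position=2, base="G")
    assert tab.tolist() == [[30.0, 0.0], [0.0, 30.0]]
    assert p < 1e-10 and not low
    with pytest.raises(ValueError):
        positionwise_chi2(setA, setA.iloc[:0], b, 2, "G")


# -- junction ratios ------------------------------------------------------

def junction_bundle():
    return GenomeBundle(
        {"c": "A" * 500},
        genes=[Gene("g", "c", 0, 500, "+")],
        exons=[],
        introns=[Intron("i", "g", "c", 100, 200, "+")])


def test_spliced_unspliced_ratio_counts():
    b = junction_bundle()
    spliced = [("c", "+", [(80, 100), (200, 220)])] * 10
    left = [("c", "+", [(90, 110)])] * 5
    right = [("c", "+", [(190, 210)])] * 5
    out = spliced_unspliced_ratio(spliced + left + right, b)
    row = out.loc["i"]
    assert (row.spliced, row.unspliced, row.ratio) == (10, 10, 1.0)


def test_spliced_only_gives_inf_and_empty_gives_nan():
    b = junction_bundle()
    out = spliced_unspliced_ratio([("c", "+", [(80, 100), (200, 220)])], b)
    assert out.loc["i", "ratio"] == math.inf
    out = spliced_unspliced_ratio([], b)
    assert math.isnan(out.loc["i", "ratio"])


def test_junction_overhang_rule():
    b = junction_bundle()
    # 3-nt overhang on the left block: counted in neither class at o=6
    out = spliced_unspliced_ratio([("c", "+", [(97, 100), (200, 220)]),
                                   ("c", "+", [(98, 103)])], b, overhang=6)
    assert out.loc["i", ["spliced", "unspliced"]].tolist() == [0, 0]


# -- editing rates --------------------------------------------------------

def test_editing_rate_subtraction_and_clamp():
    amp = "AAAA"
    tr = ["GAAA"] * 10            # raw 25%
    nt = ["AAAA"] * 9 + ["GAAA"]  # raw 2.5%
    assert editing_rate(tr, nt, amp) == pytest.approx(22.5)
    assert editing_rate(nt, nt, amp) == 0.0
    assert editing_rate(nt, tr, amp) == 0.0  # clamped


def test_editing_rate_minus_strand_counts_t_to_c():
    amp = "TTTT"
    assert raw_editing_rate(["CTTT"], amp, strand="-") == pytest.approx(0.25)
    with pytest.raises(ValueError):
        raw_editing_rate(["GGGG"], "GGGG")


def test_corrected_editing_recovery_from_simulator():
    from lariatseq.simulate import simulate_edited_amplicons
    amp = ("GATTACA" * 30)
    tr, nt = simulate_edited_amplicons(amp, 0.10, 0.02, 10_000, seed=17)
    assert editing_rate(tr, nt, amp) == pytest.approx(8.0, abs=1.0)


# -- aggregation ----------------------------------------------------------

def test_table_from_calls_counts_by_intron():
    calls = pd.DataFrame({"read_id": list("abcd"),
                          "intron_id": ["i1", "i1", "i2", "i1"]})
    t = table_from_calls(calls, "s", 100, 50, intron_ids=["i1", "i2", "i3"])
    assert t.counts.tolist() == [3, 1, 0]
    with pytest.raises(ValueError):
        SampleLariatTable("s", pd.Series({"i": -1}), 1, 1)
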