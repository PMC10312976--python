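"""RBP/motif feature stratification of introns and lariat response.

Introns are partitioned into a feature-bound set and a matched control set
(unbound introns from the same genes); each set's aggregate fold change in
lariat recovery between knockout and wild type gives a response ratio with a
bootstrap confidence interval. Also here: a greedy 5-mer alignment into a
binding-motif PFM, log-odds PWM scanning, lariat-loop topology distances of
sites to the branchpoint, the co-IP spectral-count hit filter, and intronic
classification of small-RNA features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeBundle, Intron, revcomp
from .metrics import SampleLariatTable

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class FeatureSiteSet:
    """Genomic intervals (0-based half-open BED6) with a source tag."""

    df: pd.DataFrame
    source: str = "eclip"  # eclip | motif | mirna | snorna

    def __post_init__(self):
        self.df = pd.DataFrame(self.df, columns=BED6_COLUMNS)
        if len(self.df) and (self.df.end <= self.df.start).any():
            raise ValueError("feature intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.df)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, source: str = "eclip") -> "FeatureSiteSet":
        df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS,
                         comment="#")
        return cls(df, source=source)


def _overlaps(site, iv: Intron, strand_matched: bool = True) -> bool:
    if site.chrom != iv.chrom:
        return False
    if strand_matched and site.strand in "+-" and site.strand != iv.strand:
        return False
    return site.start < iv.end and site.end > iv.start


def partition_bound_introns(bundle: GenomeBundle, sites: FeatureSiteSet
                            ) -> tuple[set[str], set[str]]:
    """Feature-bound introns and their matched controls.

    Bound: any overlap of at least 1 nt with a site (strand-matched).
    Control: introns with zero overlap whose gene contains a bound intron —
    the same-gene background the response comparison needs.
    """
    bound: set[str] = set()
    for iv in bundle.introns:
        if any(_overlaps(s, iv) for s in sites.df.itertuples()):
            bound.add(iv.intron_id)
    bound_genes = {iv.gene_id for iv in bundle.introns
                   if iv.intron_id in bound}
    control = {iv.intron_id for iv in bundle.introns
               if iv.intron_id not in bound and iv.gene_id in bound_genes}
    return bound, control


def _set_fold_change(intron_ids: list[str], ko: SampleLariatTable,
                     wt: SampleLariatTable, pseudocount: float,
                     mode: str) -> float:
    rate_ko = ko.counts.reindex(intron_ids).fillna(0).sum() \
        / ko.denominator(mode) * 1e6
    rate_wt = wt.counts.reindex(intron_ids).fillna(0).sum() \
        / wt.denominator(mode) * 1e6
    return (rate_ko + pseudocount) / (rate_wt + pseudocount)


def rbp_lariat_response(bound: set[str], control: set[str],
                        ko: SampleLariatTable, wt: SampleLariatTable,
                        pseudocount: float = 1.0, mode: str = "per_mapped",
                        n_boot: int = 1000, seed: int = 0) -> dict:
    """Aggregate KO/WT recovery-rate fold change per intron set and their
    ratio, with a seeded bootstrap CI (resampling introns within each set)."""
    if not bound or not control:
        raise ValueError("bound and control intron sets must be nonempty")
    bound_l, control_l = sorted(bound), sorted(control)
    fc_bound = _set_fold_change(bound_l, ko, wt, pseudocount, mode)
    fc_control = _set_fold_change(control_l, ko, wt, pseudocount, mode)
    ratio = fc_bound / fc_control
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = [bound_l[i] for i in rng.integers(0, len(bound_l), len(bound_l))]
        rc = [control_l[i]
              for i in rng.integers(0, len(control_l), len(control_l))]
        boots[b] = (_set_fold_change(rb, ko, wt, pseudocount, mode)
                    / _set_fold_change(rc, ko, wt, pseudocount, mode))
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {"fc_bound": fc_bound, "fc_control": fc_control,
            "response_ratio": ratio, "ci_low": float(lo), "ci_high": float(hi),
            "n_bound": len(bound_l), "n_control": len(control_l),
            "n_boot": n_boot}


# -- motif construction and scanning -------------------------------------

@dataclass
class MotifPFM:
    """Position frequency matrix from aligned k-mers.

    ``matrix`` columns A/C/G/T sum to 1 per row; the log-odds matrix adds a
    0.01 pseudofrequency and scores against a uniform background.
    """

    matrix: pd.DataFrame

    def __post_init__(self):
        if len(self.matrix) < 5:
            raise ValueError("motif must span at least 5 positions")

    @property
    def consensus(self) -> str:
        return "".join(self.matrix.idxmax(axis=1))

    @property
    def log_odds(self) -> pd.DataFrame:
        freq = self.matrix + 0.01
        freq = freq.div(freq.sum(axis=1), axis=0)
        return np.log2(freq / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def motif_pfm_from_kmers(kmers: list[tuple[str, float]]) -> MotifPFM:
    """Greedy progressive alignment of weighted 5-mers into a PFM.

    The top-weight 5-mer seeds the profile; each subsequent 5-mer is placed
    at the integer offset (-4..+4) maximising position-wise agreement with
    the current weighted counts (ties to the smallest absolute, then
    positive, offset). The PFM averages weights over covered positions.
    """
    if not kmers:
        raise ValueError("need at least one 5-mer")
    kmers = sorted(kmers, key=lambda kw: (-kw[1], kw[0]))
    counts: dict[int, dict[str, float]] = {}

    def add(kmer: str, weight: float, offset: int) -> None:
        for i, b in enumerate(kmer):
            col = counts.setdefault(offset + i, dict.fromkeys("ACGT", 0.0))
            col[b] += weight

    add(*kmers[0], offset=0)
    for kmer, weight in kmers[1:]:
        def agreement(off: int) -> float:
            return sum(counts[off + i][b] for i, b in enumerate(kmer)
                       if off + i in counts)
        offsets = sorted(range(-4, 5), key=lambda o: (abs(o), o < 0))
        best = max(offsets, key=agreement)
        add(kmer, weight, best)
    positions = sorted(counts)
    mat = pd.DataFrame([counts[p] for p in positions], index=positions,
                       columns=list("ACGT"))
    mat = mat.div(mat.sum(axis=1), axis=0)
    return MotifPFM(mat)


def pwm_scan(sequences: "GenomeBundle | dict[str, str]", pfm: MotifPFM,
             threshold: float = 0.8, absolute: bool = False,
             both_strands: bool = True) -> FeatureSiteSet:
    """All window positions whose log-odds score reaches the threshold.

    ``threshold`` is a fraction of the maximum attainable log-odds score
    unless ``absolute``. Scores are reported in the BED score column.
    """
    if isinstance(sequences, GenomeBundle):
        sequences = sequences.sequences
    lo_mat = pfm.log_odds.to_numpy()
    width = lo_mat.shape[0]
    cut = threshold if absolute else threshold * pfm.max_score
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    lo_ext = np.hstack([lo_mat, np.full((width, 1), -np.inf)])
    rows = []
    for name in sorted(sequences):
        seq = sequences[name].upper()
        for strand in ("+", "-") if both_strands else ("+",):
            s = seq if strand == "+" else revcomp(seq)
            if len(s) < width:
                continue
            idx = code[np.frombuffer(s.encode(), dtype=np.uint8)]
            wins = np.lib.stride_tricks.sliding_window_view(idx, width)
            scores = lo_ext[np.arange(width), wins].sum(axis=1)
            for pos in np.nonzero(scores >= cut)[0]:
                if strand == "+":
                    start = int(pos)
                else:
                    start = len(s) - int(pos) - width
                rows.append({"chrom": name, "start": start,
                             "end": start + width,
                             "name": f"motif_{name}_{start}_{strand}",
                             "score": round(float(scores[pos]), 4),
                             "strand": strand})
    df = pd.DataFrame(rows, columns=BED6_COLUMNS).sort_values(
        ["chrom", "start", "strand"], kind="stable").reset_index(drop=True)
    return FeatureSiteSet(df, source="motif")


# -- lariat-loop topology -------------------------------------------------

@dataclass(frozen=True)
class TopologyDistance:
    intron_id: str
    site_name: str
    side: str       # five_prime_loop | branch_loop | tail
    distance: int   # nt along the lariat loop (or past the branch, for tail)

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("topology distance must be nonnegative")


def lariat_topology_distance(site, intron: Intron,
                             branchpoint: int) -> TopologyDistance:
    """Distance of a site to the branchpoint along the circular lariat loop.

    Within the loop (site entirely at or before the branch nucleotide) the
    distance is the smaller of the 5'SS-side gap and the branch-side gap;
    sites past the branchpoint lie on the lariat tail. Coordinates are
    evaluated in transcript orientation, so minus-strand introns work too.
    """
    name = getattr(site, "name", "site")
    if intron.strand == "+":
        s_rel = site.start - intron.start
        e_rel = site.end - intron.start
        bp_rel = branchpoint - intron.start
    else:
        s_rel = intron.end - site.end
        e_rel = intron.end - site.start
        bp_rel = intron.end - 1 - branchpoint
    if s_rel < 0 or e_rel > intron.length:
        raise ValueError("site must overlap the intron")
    if not 0 <= bp_rel < intron.length:
        raise ValueError("branchpoint must lie inside the intron")
    if e_rel - 1 <= bp_rel:  # entirely within the loop
        d5 = s_rel
        db = bp_rel - e_rel + 1
        if d5 <= db:
            return TopologyDistance(intron.intron_id, name,
                                    "five_prime_loop", d5)
        return TopologyDistance(intron.intron_id, name, "branch_loop", db)
    if s_rel > bp_rel:       # entirely on the tail
        return TopologyDistance(intron.intron_id, name, "tail",
                                s_rel - bp_rel)
    return TopologyDistance(intron.intron_id, name, "branch_loop", 0)


# -- co-IP spectral-count hit filter -------------------------------------

def coip_hit_filter(records: pd.DataFrame, control_max_mean: float = 3.0,
                    ip_min_mean: float = 10.0, pseudocount: float = 0.1,
                    welch: bool = True) -> pd.DataFrame:
    """Spectral-count enrichment filter for co-IP hits.

    A protein is a hit when its control mean is below ``control_max_mean``
    and its IP mean above ``ip_min_mean``. The fold change replaces a zero
    mean with ``pseudocount``; a two-tailed two-sample t-test (Welch by
    default) supplies the p-value.

    Expected columns: protein, c1..c3, ip1..ip3 (counts configurable in
    number but not name prefix).
    """
    c_cols = [c for c in records.columns if c.startswith("c")
              and c != "protein"]
    ip_cols = [c for c in records.columns if c.startswith("ip")]
    if not c_cols or not ip_cols:
        raise ValueError("need c* control and ip* IP count columns")
    ctrl = records[c_cols].to_numpy(dtype=float)
    ip = records[ip_cols].to_numpy(dtype=float)
    ctrl_mean = ctrl.mean(axis=1)
    ip_mean = ip.mean(axis=1)
    fc = np.maximum(ip_mean, pseudocount) / np.maximum(ctrl_mean, pseudocount)
    tt = stats.ttest_ind(ip, ctrl, axis=1, equal_var=not welch)
    out = records[["protein"]].copy()
    out["control_mean"] = ctrl_mean
    out["ip_mean"] = ip_mean
    out["hit"] = (ctrl_mean < control_max_mean) & (ip_mean > ip_min_mean)
    out["fold_change"] = fc
    out["p_value"] = tt.pvalue
    return out


def classify_intronic(features: FeatureSiteSet,
                      bundle: GenomeBundle) -> pd.Series:
    """True per feature iff its interval is fully contained in an annotated
    intron (strand-matched when the feature carries a strand)."""
    flags = []
    for site in features.df.itertuples():
        contained = any(
            site.chrom == iv.chrom and iv.start <= site.start
            and site.end <= iv.end
            and (site.strand not in "+-" or site.strand == iv.strand)
            for iv in bundle.introns)
        flags.append(contained)
    return pd.Series(flags, index=features.df["name"], name="intronic")
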