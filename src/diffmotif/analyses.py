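"""Downstream analyses: SELEX enrichment scoring, aggregate hit logos,
peak-overlap partitions, peak-strength associations, and logistic baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .convnet import SplitSpec, auprc
from .motifops import PFM, Background
from .scanner import MotifHit, ScanConfig, best_hit_feature, encode_indices, scan
from .seqio import GenomicInterval
from .stats import TestResult, bonferroni, fisher_r_to_z_compare, wilcoxon_rank_sum


@dataclass
class ReadPool:
    """Fixed-length DNA reads from one SELEX cycle."""

    reads: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.reads}
        if len(lengths) > 1:
            raise ValueError("reads in a pool must have uniform length")


@dataclass
class PeakPartition:
    overlapping: list = field(default_factory=list)
    non_overlapping: list = field(default_factory=list)


def selex_read_score(read: str, query: PFM) -> float:
    """Maximum dot product of the one-hot read (either orientation) with the
    query PFM over every full-overlap alignment.

    When the query is wider than the read, the read slides within the query
    instead. Each aligned column contributes the query probability of the
    read base (N contributes 0).
    """
    if len(read) < 1:
        raise ValueError("empty read")
    q = query.matrix
    w = q.shape[1]
    best = -np.inf
    for idx in (encode_indices(read), 3 - encode_indices(read)[::-1]):
        idx = np.asarray(idx)
        n = idx.size
        safe = np.where((idx >= 0) & (idx <= 3), idx, 0).astype(np.intp)
        known = ((idx >= 0) & (idx <= 3)).astype(float)
        if n >= w:
            for off in range(n - w + 1):
                sl = slice(off, off + w)
                best = max(best, float((q[safe[sl], np.arange(w)] * known[sl]).sum()))
        else:
            for off in range(w - n + 1):
                cols = np.arange(off, off + n)
                best = max(best, float((q[safe, cols] * known).sum()))
    return best


def selex_enrichment_test(cycle0: ReadPool, cycle_k: ReadPool, query: PFM) -> TestResult:
    """One-sided Wilcoxon rank-sum test that late-cycle reads score higher
    against the query than cycle-0 reads."""
    if not cycle0.reads or not cycle_k.reads:
        raise ValueError("both read pools must be nonempty")
    s0 = [selex_read_score(r, query) for r in cycle0.reads]
    sk = [selex_read_score(r, query) for r in cycle_k.reads]
    return wilcoxon_rank_sum(sk, s0, sidedness="one", alternative="greater")


def aggregate_hit_logo(
    reads: ReadPool,
    query: PFM,
    bg: Background,
    q_cutoffs: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001),
) -> dict[float, PFM | None]:
    """Average one-hot read segments at motif hits, per q-value cutoff.

    Reads are scanned with the query in emit-all mode (joint BH q-values);
    for each cutoff, hit segments (minus-strand hits reverse-complemented)
    are averaged into a PFM of the query width. Cutoffs with no hits map to
    None.
    """
    from .seqio import one_hot, revcomp

    seqs = {f"read{i}": r for i, r in enumerate(reads.reads)}
    hits = scan(seqs, query, bg, ScanConfig(emit_all=True))
    out: dict[float, PFM | None] = {}
    w = query.width
    for cutoff in q_cutoffs:
        mats = []
        for h in hits:
            if h.q <= cutoff:
                seg = seqs[h.seq_id][h.offset : h.offset + w]
                if h.strand == "-":
                    seg = revcomp(seg)
                mats.append(one_hot(seg))
        if not mats:
            out[cutoff] = None
            continue
        mean = np.mean(mats, axis=0)
        mean = mean / np.maximum(mean.sum(axis=0, keepdims=True), 1e-12)
        out[cutoff] = PFM(mean, name=f"aggregate_q{cutoff}")
    return out


def _overlaps_any(peak: GenomicInterval, others: dict[str, tuple[np.ndarray, np.ndarray]]) -> bool:
    if peak.chrom not in others:
        return False
    starts, max_end_prefix = others[peak.chrom]
    k = int(np.searchsorted(starts, peak.end, side="left"))  # others with start < end
    return k > 0 and max_end_prefix[k - 1] > peak.start


def _interval_index(intervals: list[GenomicInterval]):
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: v.start)
        starts = np.array([v.start for v in ivs])
        ends = np.maximum.accumulate(np.array([v.end for v in ivs]))
        out[chrom] = (starts, ends)
    return out


def partition_by_overlap(
    peaks_a: list[GenomicInterval],
    strict_b: list[GenomicInterval],
    relaxed_b: list[GenomicInterval],
) -> PeakPartition:
    """Partition peaks_a into those overlapping strict_b (>= 1 bp) and those
    with zero overlap with relaxed_b; peaks matching neither rule (e.g.
    overlapping only a relaxed peak) are excluded from both sides."""
    strict_idx = _interval_index(strict_b)
    relaxed_idx = _interval_index(relaxed_b)
    part = PeakPartition()
    for peak in peaks_a:
        if _overlaps_any(peak, strict_idx):
            part.overlapping.append(peak)
        elif not _overlaps_any(peak, relaxed_idx):
            part.non_overlapping.append(peak)
    return part


def compare_partition_pvalues(
    seqs_overlapping: dict[str, str],
    seqs_non_overlapping: dict[str, str],
    megamotif: PFM,
    bg: Background,
) -> TestResult:
    """Two-sided Wilcoxon comparison of per-peak best motif-hit p-values
    (as -log10 p; no hit means p = 1) between the two peak subsets."""
    if not seqs_overlapping or not seqs_non_overlapping:
        raise ValueError("both partition sides must be nonempty")
    feats = []
    for seqs in (seqs_overlapping, seqs_non_overlapping):
        hits = scan(seqs, megamotif, bg, ScanConfig(emit_all=True))
        f = best_hit_feature(hits, list(seqs), mode="neglog10_p_or_one")
        feats.append(np.array([f[k] for k in sorted(seqs)]))
    return wilcoxon_rank_sum(feats[0], feats[1], sidedness="two")


def build_strength_table(
    seqs: dict[str, str],
    signal: dict[str, float],
    motifs: dict[str, PFM],
    bg: Background,
) -> pd.DataFrame:
    """Per-peak strength table: ln(narrowPeak signal), and per motif the best
    hit's p, q and -log10 q feature (scanned in emit-all mode)."""
    ids = sorted(seqs)
    df = pd.DataFrame({"peak_id": ids, "ln_signal": [np.log(signal[i]) for i in ids]})
    for name, pfm in motifs.items():
        hits = scan(seqs, pfm, bg, ScanConfig(emit_all=True))
        best_p: dict[str, float] = {}
        best_q: dict[str, float] = {}
        for h in hits:
            if h.seq_id not in best_p or h.p < best_p[h.seq_id]:
                best_p[h.seq_id] = h.p
            if h.seq_id not in best_q or h.q < best_q[h.seq_id]:
                best_q[h.seq_id] = h.q
        df[f"{name}_p"] = [best_p.get(i, 1.0) for i in ids]
        df[f"{name}_q"] = [best_q.get(i, 1.0) for i in ids]
        df[f"{name}_neglog10q"] = -np.log10(np.maximum(df[f"{name}_q"], 1e-300))
    return df


def strength_association(
    table: pd.DataFrame,
    core: str = "core",
    downstream: str = "downstream",
    core_downstream: str = "core_downstream",
    cutoff_mode: str = "p1e-4",
    m: int = 6,
) -> dict:
    """Peak strength for core-only peaks vs core-followed-by-downstream peaks.

    Motif presence uses FIMO-style cutoffs (p < 1e-4, or q < 0.05 in the
    strict mode). Group A: a core hit and no downstream-motif hit; group B: a
    hit of the core+downstream mega-motif. Two-sided Wilcoxon on ln peak
    strength, Bonferroni-corrected (x ``m``).
    """
    if cutoff_mode == "p1e-4":
        hit = lambda name: table[f"{name}_p"] < 1e-4  # noqa: E731
    elif cutoff_mode == "q0.05":
        hit = lambda name: table[f"{name}_q"] < 0.05  # noqa: E731
    else:
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    group_a = table[hit(core) & ~hit(downstream)]
    group_b = table[hit(core_downstream)]
    if len(group_a) == 0 or len(group_b) == 0:
        return {"group_a": group_a, "group_b": group_b, "test": None, "p_adjusted": None}
    res = wilcoxon_rank_sum(group_a["ln_signal"], group_b["ln_signal"], sidedness="two")
    return {
        "group_a": group_a,
        "group_b": group_b,
        "test": res,
        "p_adjusted": float(bonferroni([res.p], m=m)[0]),
    }


def strength_correlation_comparison(
    table: pd.DataFrame, motif_x: str, motif_y: str, m: int = 6
) -> dict:
    """Compare Pearson correlations of ln peak strength with each motif's
    best-hit -log10 q (all peaks, no-hit feature 0) by a one-sided Fisher
    r-to-z test (alternative: motif_y more correlated), Bonferroni x ``m``."""
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 peaks")
    y = table["ln_signal"].to_numpy()
    rs = {}
    for name in (motif_x, motif_y):
        x = table[f"{name}_neglog10q"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant feature for {name}")
        rs[name] = float(np.corrcoef(x, y)[0, 1])
    res = fisher_r_to_z_compare(rs[motif_y], n, rs[motif_x], n, sidedness="one")
    return {
        "r_x": rs[motif_x],
        "r_y": rs[motif_y],
        "test": res,
        "p_adjusted": float(bonferroni([res.p], m=m)[0]),
    }


def logistic_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    chroms: np.ndarray,
    split: SplitSpec,
    l2: float = 1.0,
):
    """L2 logistic regression on motif features, fit on the train+validation
    chromosomes and scored by AUPRC on the test chromosomes.

    ``l2`` maps to scikit-learn's inverse regularization strength C.
    Returns (fitted model, test AUPRC).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != len(labels):
        features = features.T
    fit_mask = np.isin(chroms, list(split.train_chroms | split.val_chroms))
    test_mask = np.isin(chroms, list(split.test_chroms))
    for name, mask in (("train+val", fit_mask), ("test", test_mask)):
        sub = np.asarray(labels)[mask]
        if sub.size == 0 or sub.min() == sub.max():
            raise ValueError(f"{name} split must contain both classes")
    model = LogisticRegression(C=l2, tol=1e-8, max_iter=1000)  # l2 penalty default
    model.fit(features[fit_mask], np.asarray(labels)[fit_mask])
    scores = model.predict_proba(features[test_mask])[:, 1]
    return model, auprc(scores, np.asarray(labels)[test_mask])
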