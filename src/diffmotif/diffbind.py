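"""Differential binding: summit merging, shifted 5'-end read counting, a
median-of-ratios + pooled-dispersion negative-binomial Wald test, and
positive/negative labeling.

Peaks from wild-type and mutant datasets are merged when summits fall within
``radius`` (default 50) bp by single-linkage chaining, and the merged summit
is the rounded mean of member summits. Counts are compared WT vs mutant;
``log2FC`` is mutant-over-WT, so a peak significantly stronger in the
wild-type has log2FC < 0, and the label rule is: positive iff q < 0.05 and
log2FC < -1; negative iff log2FC >= 0; excluded otherwise. An external
differential table (e.g. from DESeq2) can be ingested in place of the
built-in test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqio import GenomicInterval
from .stats import bh_adjust

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
FC_PSEUDOCOUNT = 0.5


@dataclass
class SummitPeak:
    chrom: str
    summit: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.summit < 0:
            raise ValueError("summit must be >= 0")


@dataclass
class MergedPeak:
    chrom: str
    summit: int
    members: list[SummitPeak] = field(default_factory=list)
    flank: int = 100

    @property
    def interval(self) -> GenomicInterval:
        start = max(0, self.summit - self.flank)
        return GenomicInterval(self.chrom, start, self.summit + self.flank)

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.summit}"


@dataclass
class CountMatrix:
    peaks: list[MergedPeak]
    samples: list[tuple[str, str]]  # (condition, replicate id)
    counts: np.ndarray  # peaks x samples

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError("count matrix shape does not match peaks x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.array([j for j, (c, _) in enumerate(self.samples) if c == condition])


def merge_summit_peaks(
    peaks: list[SummitPeak], radius: int = 50, flank: int = 100
) -> list[MergedPeak]:
    """Single-linkage merge of summit peaks within ``radius`` bp, per chromosome.

    The merged summit is the arithmetic mean of member summits rounded half-up;
    output is sorted by (chrom, summit). Merging is idempotent.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    by_chrom: dict[str, list[SummitPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[MergedPeak] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda p: p.summit)
        cluster = [members[0]]
        for p in members[1:]:
            if p.summit - cluster[-1].summit <= radius:
                cluster.append(p)
            else:
                merged.append(_finalize_cluster(chrom, cluster, flank))
                cluster = [p]
        merged.append(_finalize_cluster(chrom, cluster, flank))
    merged.sort(key=lambda m: (m.chrom, m.summit))
    return merged


def _finalize_cluster(chrom: str, cluster: list[SummitPeak], flank: int) -> MergedPeak:
    mean = sum(p.summit for p in cluster) / len(cluster)
    return MergedPeak(chrom, int(math.floor(mean + 0.5)), list(cluster), flank)


def shifted_fiveprime_counts(
    reads: list[tuple[str, int, str, int]],
    peaks: list[MergedPeak],
    strand_aware: bool = True,
) -> np.ndarray:
    """Count shifted read 5' ends per merged peak (one sample column).

    Each read's 5' end is shifted by floor(fragment_length / 2): to the right
    on the + strand and (in the default strand-aware mode) to the left on the
    - strand; ``strand_aware=False`` reproduces a literal shift-right for both
    strands. A read is counted in every peak whose interval contains the
    shifted position. Reads on chromosomes without peaks contribute nothing;
    negative shifted positions are clipped to 0 with a warning.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, pk in enumerate(peaks):
        by_chrom.setdefault(pk.chrom, []).append(i)
    index = {}
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: peaks[i].interval.start)
        starts = np.array([peaks[i].interval.start for i in idxs])
        ends = np.array([peaks[i].interval.end for i in idxs])
        index[chrom] = (np.array(idxs), starts, ends)
    counts = np.zeros(len(peaks), dtype=np.int64)
    n_clipped = 0
    for chrom, pos, strand, fraglen in reads:
        if fraglen <= 0:
            raise ValueError("fragment_length must be positive")
        shift = fraglen // 2
        shifted = pos - shift if (strand_aware and strand == "-") else pos + shift
        if shifted < 0:
            shifted = 0
            n_clipped += 1
        if chrom not in index:
            continue
        idxs, starts, ends = index[chrom]
        lo = np.searchsorted(ends, shifted, side="right")
        hi = np.searchsorted(starts, shifted, side="right")
        if hi > lo:
            counts[idxs[lo:hi]] += 1
    if n_clipped:
        logger.warning("%d shifted read positions clipped to 0", n_clipped)
    return counts


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq normalization).

    factor_j = median over all-positive peak rows of counts[i, j] divided by
    the row's geometric mean. Raises when no peak has all-positive counts.
    """
    counts = np.asarray(counts, dtype=float)
    allpos = np.all(counts > 0, axis=1)
    if not np.any(allpos):
        raise ValueError("no peak with positive counts in every sample")
    log_counts = np.log(counts[allpos])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_counts - log_geomean, axis=0))


def _pooled_dispersions(
    norm: np.ndarray, cond_cols: list[np.ndarray], inv_sf_mean: float, n_bins: int = 20
) -> np.ndarray:
    """Method-of-moments NB dispersions pooled across peaks in mean bins."""
    n_total = sum(len(c) for c in cond_cols)
    resid_ss = np.zeros(norm.shape[0])
    for cols in cond_cols:
        mu_c = norm[:, cols].mean(axis=1, keepdims=True)
        resid_ss += ((norm[:, cols] - mu_c) ** 2).sum(axis=1)
    df = n_total - len(cond_cols)
    var = resid_ss / max(df, 1)
    mu = norm.mean(axis=1)
    alpha = np.full(norm.shape[0], DISPERSION_FLOOR)
    pos = mu > 0
    if not np.any(pos):
        return alpha
    ranks = np.argsort(np.argsort(mu[pos]))
    bins = (ranks * n_bins) // max(pos.sum(), 1)
    excess = var[pos] - mu[pos] * inv_sf_mean
    musq = mu[pos] ** 2
    pooled = np.empty(pos.sum())
    for b in np.unique(bins):
        m = bins == b
        # ratio-of-sums estimator: unbiased pooling of the per-peak
        # method-of-moments excess variance over the squared mean
        pooled[m] = excess[m].sum() / musq[m].sum()
    alpha[pos] = np.maximum(pooled, DISPERSION_FLOOR)
    return alpha


def nb_wald_test(cm: CountMatrix, size_factors: np.ndarray | None = None) -> pd.DataFrame:
    """Simplified negative-binomial Wald test of WT vs mutant counts.

    Counts are normalized by median-of-ratios size factors; per-peak
    log2FC = log2((mu_mut + 0.5) / (mu_WT + 0.5)) (mutant over wild-type, so
    "stronger in WT" means log2FC < 0); NB dispersions are method-of-moments
    estimates pooled across peaks in 20 mean bins and floored at 1e-8; the
    Wald z uses a delta-method standard error, p is two-sided normal, and q
    is BH over tested (not all-zero) peaks. All-zero peaks get p = 1 and
    log2FC = 0.
    """
    wt = cm.condition_columns("WT")
    mut = np.array([j for j in range(len(cm.samples)) if j not in set(wt)])
    if wt.size == 0 or mut.size == 0:
        raise ValueError("need at least one WT and one mutant sample")
    counts = cm.counts.astype(float)
    sf = estimate_size_factors(counts) if size_factors is None else np.asarray(size_factors, float)
    norm = counts / sf[None, :]
    mu_wt = norm[:, wt].mean(axis=1)
    mu_mut = norm[:, mut].mean(axis=1)
    lfc = np.log2((mu_mut + FC_PSEUDOCOUNT) / (mu_wt + FC_PSEUDOCOUNT))

    alpha = _pooled_dispersions(norm, [wt, mut], float(np.mean(1 / sf)))

    def group_var(mu: np.ndarray, cols: np.ndarray) -> np.ndarray:
        per_sample = mu[:, None] / sf[None, cols] + alpha[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / cols.size**2

    ln2_sq = np.log(2) ** 2
    var_lfc = (
        group_var(mu_mut, mut) / (mu_mut + FC_PSEUDOCOUNT) ** 2
        + group_var(mu_wt, wt) / (mu_wt + FC_PSEUDOCOUNT) ** 2
    ) / ln2_sq
    se = np.sqrt(var_lfc)
    tested = counts.sum(axis=1) > 0
    z = np.zeros(len(lfc))
    np.divide(lfc, se, out=z, where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    p[~tested] = 1.0
    lfc[~tested] = 0.0
    q = np.ones(len(p))
    if np.any(tested):
        q[tested] = bh_adjust(p[tested])
    return pd.DataFrame(
        {
            "peak_id": [pk.peak_id for pk in cm.peaks],
            "baseMean": norm.mean(axis=1),
            "log2FC": lfc,
            "se": se,
            "pvalue": p,
            "qvalue": q,
        }
    )


def label_differential(results: pd.DataFrame) -> pd.Series:
    """Label peaks positive / negative / excluded from a differential table.

    positive iff q < 0.05 and log2FC < -1 (significantly stronger in WT);
    negative iff log2FC >= 0; excluded otherwise. The three classes
    partition the peaks.
    """
    lfc = results["log2FC"].to_numpy()
    q = results["qvalue"].to_numpy()
    labels = np.where(
        (q < 0.05) & (lfc < -1), "positive", np.where(lfc >= 0, "negative", "excluded")
    )
    return pd.Series(labels, index=results.index, name="label")


def read_external_diff(path) -> pd.DataFrame:
    """Ingest an external differential table (peak_id, log2FC, pvalue, qvalue)."""
    df = pd.read_csv(path, sep="\t")
    required = {"peak_id", "log2FC", "pvalue", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external differential table missing columns: {sorted(missing)}")
    return df


def read_reads_tsv(path) -> list[tuple[str, int, str, int]]:
    """Read a 4-column read TSV: chrom, 5'-end position, strand, fragment length."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, strand, fraglen = line.split()[:4]
            out.append((chrom, int(pos), strand, int(fraglen)))
    return out


def write_counts_tsv(cm: CountMatrix, path) -> None:
    cols = [f"{c}_{r}" for c, r in cm.samples]
    df = pd.DataFrame(cm.counts, columns=cols)
    df.insert(0, "peak_id", [pk.peak_id for pk in cm.peaks])
    df.to_csv(path, sep="\t", index=False)
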