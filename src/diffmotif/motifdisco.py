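"""Seqlet-based motif discovery from attribution tracks.

High-attribution windows ("seqlets") are extracted against an empirical-FDR
null built from position-shuffled tracks, aligned pairwise by an exhaustive
offset/orientation scan of their hypothetical-score matrices, grouped by
greedy leader clustering, and aggregated into width-50 motifs: a PFM
(averaged aligned one-hot sequence) and an importance matrix (averaged
aligned hypothetical scores), ranked by seqlet support.

This is a transparent stand-in for TF-MoDISco's discovery phases (which use a
gapped-k-mer embedding and graph clustering); it keeps the same inputs,
thresholding semantics (seqlet FDR 0.2, minimum 200 supporting seqlets, final
width 50) and outputs, but makes no claim of output-level fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribution import AttributionTrack, HypotheticalTrack
from .motifops import PFM
from .seqio import BASES


@dataclass
class Seqlet:
    peak_id: str
    offset: int  # start within the peak window
    width: int
    onehot: np.ndarray  # 4 x width
    scores: np.ndarray  # 4 x width actual contributions
    hyp: np.ndarray  # 4 x width hypothetical scores
    orientation: str = "fwd"

    @property
    def total_score(self) -> float:
        return float(np.abs(self.scores).sum())


@dataclass
class SeqletCluster:
    # members are (seqlet, offset relative to leader, orientation vs leader)
    members: list[tuple[Seqlet, int, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DiscoveredMotif:
    pfm: np.ndarray  # 4 x out_width; columns sum to 1 where covered, else 0
    importance: np.ndarray  # 4 x out_width averaged hypothetical scores
    n_seqlets: int
    rank: int = 0
    coverage: np.ndarray | None = None  # members covering each column

    def consensus(self) -> str:
        from .seqio import decode_one_hot

        return decode_one_hot(self.pfm)

    def to_pfm(self, name: str = "motif", min_coverage_frac: float = 0.5) -> PFM:
        """Well-covered central slice as a PFM.

        Columns averaged over fewer than ``min_coverage_frac`` of the peak
        coverage are dropped: few-member edge columns are too noisy for
        probability-threshold operations like trimming.
        """
        covered = self.pfm.sum(axis=0) > 0
        if self.coverage is not None and self.coverage.max() > 0:
            covered &= self.coverage >= min_coverage_frac * self.coverage.max()
        if not np.any(covered):
            raise ValueError("motif has no covered columns")
        lo, hi = np.flatnonzero(covered)[[0, -1]]
        return PFM(self.pfm[:, lo : hi + 1], name=name)


def _window_sums(values: np.ndarray, width: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(values)])
    return c[width:] - c[:-width]


def _block_shuffle(values: np.ndarray, rng: np.random.Generator, block: int = 2) -> np.ndarray:
    """Permute positions in blocks of ``block`` (pads the tail block)."""
    n = values.size
    n_blocks = -(-n // block)
    padded = np.concatenate([values, np.zeros(n_blocks * block - n)])
    blocks = padded.reshape(n_blocks, block)
    return blocks[rng.permutation(n_blocks)].ravel()[:n]


def extract_seqlets(
    tracks: list[AttributionTrack],
    hyps: list[HypotheticalTrack],
    peak_ids: list[str] | None = None,
    width: int = 21,
    fdr: float = 0.2,
    seed: int = 0,
) -> list[Seqlet]:
    """Extract high-attribution seqlets at an empirical FDR threshold.

    Per-position importance is the summed absolute contribution; candidate
    windows are scored by their summed importance. The null distribution
    comes from the same windows computed on per-peak position-shuffled
    tracks (blocks of two positions); the threshold is the smallest window
    score whose empirical FDR (null tail fraction over real tail fraction)
    is <= ``fdr``. Overlapping passing windows are resolved by greedy
    non-maximum suppression keeping the highest-scoring window and
    suppressing windows overlapping it by more than 50%.
    """
    if not tracks:
        raise ValueError("no attribution tracks supplied")
    if peak_ids is None:
        peak_ids = [f"peak{i}" for i in range(len(tracks))]
    rng = np.random.default_rng(seed)
    real_sums, null_sums, per_track = [], [], []
    for track in tracks:
        imp = np.abs(track.contributions).sum(axis=0)
        if imp.size < width:
            per_track.append(None)
            continue
        sums = _window_sums(imp, width)
        per_track.append(sums)
        real_sums.append(sums)
        null_sums.append(_window_sums(_block_shuffle(imp, rng), width))
    if not real_sums:
        return []
    real = np.concatenate(real_sums)
    null = np.sort(np.concatenate(null_sums))
    positive = np.sort(np.unique(real[real > 0]))
    if positive.size == 0:
        return []
    # empirical FDR for each candidate threshold (vectorized tail counts)
    n_real_ge = real.size - np.searchsorted(np.sort(real), positive, side="left")
    n_null_ge = null.size - np.searchsorted(null, positive, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        efdr = (n_null_ge / null.size) / np.maximum(n_real_ge / real.size, 1e-300)
    passing = np.flatnonzero(efdr <= fdr)
    if passing.size == 0:
        return []
    threshold = positive[passing[0]]

    seqlets: list[Seqlet] = []
    for track, hyp, pid, sums in zip(tracks, hyps, peak_ids, per_track):
        if sums is None:
            continue
        cand = np.flatnonzero(sums >= threshold)
        if cand.size == 0:
            continue
        imp = np.abs(track.contributions).sum(axis=0)
        length = imp.size

        def recenter(off: int) -> int:
            # center the window on its importance centroid so that seqlets
            # covering the same motif instance register consistently (window
            # sums are flat-topped around a compact motif, so the raw argmax
            # offset is tie-break dependent)
            w_imp = imp[off : off + width]
            centroid = int(round(float((w_imp * np.arange(width)).sum() / w_imp.sum())))
            return int(np.clip(off + centroid - width // 2, 0, length - width))

        kept: list[int] = []
        for off in cand[np.argsort(-sums[cand], kind="stable")]:
            start = recenter(int(off))
            if all(
                min(start + width, k + width) - max(start, k) <= width / 2
                for k in kept
            ):
                kept.append(start)
        for start in sorted(kept):
            seqlets.append(
                Seqlet(
                    peak_id=pid,
                    offset=start,
                    width=width,
                    onehot=np.asarray(track.input)[:, start : start + width].astype(float),
                    scores=track.contributions[:, start : start + width].copy(),
                    hyp=hyp.hypothetical[:, start : start + width].copy(),
                )
            )
    return seqlets


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return mat[::-1, ::-1]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float((a * b).sum() / (na * nb))


def best_alignment(a_hyp: np.ndarray, b_hyp: np.ndarray) -> tuple[float, int, str]:
    """Best (similarity, offset, orientation) of b against a.

    Similarity is the overlap-fraction-weighted cosine of the hypothetical
    matrices over all relative offsets within +/- width/2 and both
    orientations; offset is b's shift relative to a in a's frame.
    """
    w = a_hyp.shape[1]
    if b_hyp.shape[1] != w:
        raise ValueError("seqlet widths must match")
    best = (-np.inf, 0, "fwd")
    max_shift = w // 2
    for orient, mat in (("fwd", b_hyp), ("rev", _revcomp_matrix(b_hyp))):
        for off in range(-max_shift, max_shift + 1):
            a_lo, a_hi = max(0, off), min(w, w + off)
            b_lo, b_hi = max(0, -off), min(w, w - off)
            overlap = a_hi - a_lo
            if overlap <= 0:
                continue
            sim = _cosine(a_hyp[:, a_lo:a_hi], mat[:, b_lo:b_hi]) * overlap / w
            if sim > best[0]:
                best = (sim, off, orient)
    return best


def seqlet_similarity(a: Seqlet, b: Seqlet) -> float:
    """Similarity in [-1, 1]: overlap-weighted cosine at the best alignment."""
    return best_alignment(a.hyp, b.hyp)[0]


def cluster_seqlets(
    seqlets: list[Seqlet], sim_threshold: float = 0.8, min_seqlets: int = 200
) -> list[SeqletCluster]:
    """Greedy leader clustering on descending total attribution.

    Each seqlet joins the first existing cluster whose leader it matches at
    similarity >= ``sim_threshold`` (recording the best offset and
    orientation), otherwise founds a new cluster. Clusters smaller than
    ``min_seqlets`` are discarded; output is sorted by size descending.
    Deterministic given the input (ties broken by input order).
    """
    order = sorted(range(len(seqlets)), key=lambda i: (-seqlets[i].total_score, i))
    clusters: list[SeqletCluster] = []
    for i in order:
        s = seqlets[i]
        placed = False
        for cl in clusters:
            leader = cl.members[0][0]
            sim, off, orient = best_alignment(leader.hyp, s.hyp)
            if sim >= sim_threshold:
                cl.members.append((s, off, orient))
                placed = True
                break
        if not placed:
            clusters.append(SeqletCluster(members=[(s, 0, "fwd")]))
    clusters = [c for c in clusters if c.size >= min_seqlets]
    clusters.sort(key=lambda c: -c.size)
    return clusters


def aggregate_cluster(cluster: SeqletCluster, out_width: int = 50) -> DiscoveredMotif:
    """Average aligned member one-hots and hypothetical scores into a motif.

    Members are placed in a common ``out_width`` frame (the leader centered),
    reverse-orientation members are reverse-complemented first, and each
    column is the mean over the members covering it; uncovered columns are
    zero, covered PFM columns sum to 1.
    """
    if cluster.size == 0:
        raise ValueError("cannot aggregate an empty cluster")
    w = cluster.members[0][0].width
    center = (out_width - w) // 2
    pfm_sum = np.zeros((4, out_width))
    imp_sum = np.zeros((4, out_width))
    coverage = np.zeros(out_width)
    for seqlet, off, orient in cluster.members:
        onehot, hyp = seqlet.onehot, seqlet.hyp
        if orient == "rev":
            onehot, hyp = _revcomp_matrix(onehot), _revcomp_matrix(hyp)
        start = center + off
        src_lo = max(0, -start)
        src_hi = min(w, out_width - start)
        if src_hi <= src_lo:
            continue
        dst = slice(start + src_lo, start + src_hi)
        pfm_sum[:, dst] += onehot[:, src_lo:src_hi]
        imp_sum[:, dst] += hyp[:, src_lo:src_hi]
        coverage[dst] += 1
    covered = coverage > 0
    pfm = np.zeros_like(pfm_sum)
    imp = np.zeros_like(imp_sum)
    pfm[:, covered] = pfm_sum[:, covered] / coverage[covered]
    imp[:, covered] = imp_sum[:, covered] / coverage[covered]
    # renormalize against one-hot rounding drift so covered columns sum to 1
    colsum = pfm.sum(axis=0)
    norm = covered & (colsum > 0)
    pfm[:, norm] /= colsum[norm]
    return DiscoveredMotif(
        pfm=pfm, importance=imp, n_seqlets=cluster.size, coverage=coverage.copy()
    )


def discover_motifs(
    tracks: list[AttributionTrack],
    hyps: list[HypotheticalTrack],
    peak_ids: list[str] | None = None,
    width: int = 21,
    fdr: float = 0.2,
    sim_threshold: float = 0.8,
    min_seqlets: int = 200,
    out_width: int = 50,
    seed: int = 0,
) -> list[DiscoveredMotif]:
    """Seqlet extraction, clustering and aggregation in one call; motifs are
    ranked (rank 0 = most supporting seqlets)."""
    seqlets = extract_seqlets(tracks, hyps, peak_ids, width=width, fdr=fdr, seed=seed)
    clusters = cluster_seqlets(seqlets, sim_threshold=sim_threshold, min_seqlets=min_seqlets)
    motifs = [aggregate_cluster(c, out_width=out_width) for c in clusters]
    for rank, motif in enumerate(motifs):
        motif.rank = rank
    return motifs


def seqlet_bed_lines(seqlets: list[Seqlet]) -> list[str]:
    return [
        f"{s.peak_id}\t{s.offset}\t{s.offset + s.width}\tseqlet\t0\t+"
        for s in seqlets
    ]
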