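"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure of a wild-type vs
DBD-mutant differential ChIP-seq study: summit-centered peaks on a
multi-chromosome genome (chr1..chr19 + chrX, so the standard chromosome
split applies), an i.i.d. background at a given GC content, a ~19 bp core
motif planted near every peak summit, a secondary GAGCCA motif planted 2 bp
downstream of the core in "stronger in wild-type" peaks only,
negative-binomial read counts with sample-specific size factors and a
planted log2 fold-change on positive peaks, and 20 bp SELEX read pools with
or without query-motif enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffbind import CountMatrix, MergedPeak
from .motifops import PFM
from .seqio import BASES, GenomeSequence

CORE_CONSENSUS = "CCAGCAGGGGGCGCTACTA"  # 19 bp core, CTCF-like sharpness
DOWNSTREAM_CONSENSUS = "GAGCCA"


def consensus_pfm(consensus: str, sharpness: float = 0.85, name: str = "motif") -> PFM:
    """Sharpened-consensus PFM: the consensus base gets ``sharpness``, the
    rest share the remainder equally."""
    mat = np.full((4, len(consensus)), (1 - sharpness) / 3)
    for j, b in enumerate(consensus):
        mat[BASES.index(b), j] = sharpness
    return PFM(mat, name=name)


@dataclass
class SimConfig:
    n_chroms: int = 20
    chrom_length: int = 75_000
    gc: float = 0.42
    n_peaks: int = 4000
    flank: int = 100
    core_pfm: PFM = field(default_factory=lambda: consensus_pfm(CORE_CONSENSUS, name="core"))
    downstream_pfm: PFM = field(
        default_factory=lambda: consensus_pfm(DOWNSTREAM_CONSENSUS, 0.9, name="downstream")
    )
    spacer: int = 2
    spacer_range: tuple[int, int] | None = None  # variable-spacing mode
    fraction_positive: float = 0.3
    planted_log2fc: float = -2.0
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    baseline_log_sd: float = 0.5
    n_replicates: int = 3
    summit_jitter: int = 10
    selex_read_length: int = 20
    selex_enrichment: float = 0.3

    def __post_init__(self) -> None:
        if self.n_peaks < 10:
            raise ValueError("need at least 10 peaks")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")

    @property
    def chrom_names(self) -> list[str]:
        names = [f"chr{i}" for i in range(1, self.n_chroms)]
        return names + ["chrX"]

    def base_probs(self) -> np.ndarray:
        at = (1 - self.gc) / 2
        return np.array([at, self.gc / 2, self.gc / 2, at])


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=probs)


def _sample_from_pfm(rng: np.random.Generator, pfm: PFM) -> np.ndarray:
    return np.array([rng.choice(4, p=pfm.matrix[:, j]) for j in range(pfm.width)])


def simulate_genome_and_peaks(
    cfg: SimConfig, seed: int = 0
) -> tuple[GenomeSequence, list[MergedPeak], pd.DataFrame]:
    """Background genome with planted motifs and the ground-truth manifest.

    Peaks are laid out at non-overlapping summit positions across all
    chromosomes. Every peak carries a core-motif instance centered near the
    summit with +/- ``summit_jitter`` bp of jitter; positive peaks
    additionally carry the downstream motif ``spacer`` bp after the core
    (or at a spacing drawn uniformly from ``spacer_range``). The manifest
    records label, insert coordinates, spacing and true log2FC per peak.
    """
    rng = np.random.default_rng(seed)
    probs = cfg.base_probs()
    chroms = cfg.chrom_names
    per_chrom = -(-cfg.n_peaks // len(chroms))
    margin = cfg.flank + cfg.summit_jitter + 40
    spacing = (cfg.chrom_length - 2 * margin) // per_chrom
    if spacing < 2 * cfg.flank + 2 * cfg.summit_jitter:
        raise ValueError("peaks do not fit the chromosome; increase chrom_length")

    seqs = {c: _random_seq(rng, cfg.chrom_length, probs) for c in chroms}
    n_pos_total = int(round(cfg.fraction_positive * cfg.n_peaks))
    is_positive = np.zeros(cfg.n_peaks, dtype=bool)
    is_positive[rng.choice(cfg.n_peaks, size=n_pos_total, replace=False)] = True

    rows = []
    peaks: list[MergedPeak] = []
    k = 0
    for chrom in chroms:
        for i in range(per_chrom):
            if k >= cfg.n_peaks:
                break
            summit = margin + i * spacing + int(rng.integers(-5, 6))
            positive = bool(is_positive[k])
            core = _sample_from_pfm(rng, cfg.core_pfm)
            if positive:
                if cfg.spacer_range is not None:
                    spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
                else:
                    spacer = cfg.spacer
                down = _sample_from_pfm(rng, cfg.downstream_pfm)
                insert = np.concatenate(
                    [core, _random_seq(rng, spacer, probs), down]
                )
            else:
                spacer = -1
                insert = core
            jitter = int(rng.integers(-cfg.summit_jitter, cfg.summit_jitter + 1))
            start = summit - insert.size // 2 + jitter
            seqs[chrom][start : start + insert.size] = insert
            peaks.append(MergedPeak(chrom, summit, flank=cfg.flank))
            rows.append(
                {
                    "peak_id": f"{chrom}:{summit}",
                    "chrom": chrom,
                    "summit": summit,
                    "true_label": "positive" if positive else "negative",
                    "insert_start": start,
                    "insert_end": start + insert.size,
                    "spacer": spacer,
                    "true_log2fc": cfg.planted_log2fc if positive else 0.0,
                }
            )
            k += 1

    genome = GenomeSequence()
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for chrom in chroms:
        genome.add(chrom, base_arr[seqs[chrom]].tobytes().decode())
    return genome, peaks, pd.DataFrame(rows)


def simulate_counts(
    cfg: SimConfig, peaks: list[MergedPeak], manifest: pd.DataFrame, seed: int = 0
) -> tuple[CountMatrix, np.ndarray]:
    """Negative-binomial count matrix for WT and mutant replicates.

    Per-peak baselines are log-normal around ``nb_mean``; mutant means are
    scaled by 2^true_log2fc for positive peaks; per-sample size factors are
    drawn log-uniform on [0.5, 2]. Returns the counts and the true size
    factors.
    """
    rng = np.random.default_rng(seed)
    n = len(peaks)
    samples = [("WT", f"rep{i + 1}") for i in range(cfg.n_replicates)] + [
        ("mutant", f"rep{i + 1}") for i in range(cfg.n_replicates)
    ]
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
    baseline = cfg.nb_mean * np.exp(
        rng.normal(0, cfg.baseline_log_sd, size=n) - cfg.baseline_log_sd**2 / 2
    )
    lfc = manifest["true_log2fc"].to_numpy()
    mu = np.empty((n, len(samples)))
    for j, (cond, _) in enumerate(samples):
        cond_mu = baseline * (2.0**lfc) if cond == "mutant" else baseline
        mu[:, j] = cond_mu * sf[j]
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    return CountMatrix(peaks=peaks, samples=samples, counts=counts), sf


def simulate_selex_pools(
    cfg: SimConfig, query: PFM, seed: int = 0, n_reads: int = 5000
) -> tuple["ReadPool", "ReadPool", pd.DataFrame]:
    """Cycle-0 (background) and late-cycle SELEX read pools.

    The late cycle contains ``selex_enrichment`` fraction of reads carrying
    a query-PFM sample at a uniform offset in a random orientation; the
    manifest records which late-cycle reads are planted.
    """
    from .analyses import ReadPool
    from .seqio import revcomp

    if query.width > cfg.selex_read_length:
        raise ValueError("query wider than the read length")
    rng = np.random.default_rng(seed)
    probs = cfg.base_probs()
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)

    def bg_read() -> np.ndarray:
        return _random_seq(rng, cfg.selex_read_length, probs)

    cycle0 = ReadPool(
        [base_arr[bg_read()].tobytes().decode() for _ in range(n_reads)], label="cycle0"
    )
    planted = rng.random(n_reads) < cfg.selex_enrichment
    reads_k, rows = [], []
    for i in range(n_reads):
        arr = bg_read()
        if planted[i]:
            inst = _sample_from_pfm(rng, query)
            off = int(rng.integers(0, cfg.selex_read_length - query.width + 1))
            arr[off : off + query.width] = inst
        read = base_arr[arr].tobytes().decode()
        if planted[i] and rng.random() < 0.5:
            read = revcomp(read)
        reads_k.append(read)
        rows.append({"read_index": i, "planted": bool(planted[i])})
    return cycle0, ReadPool(reads_k, label="cycle4"), pd.DataFrame(rows)


def windows_for_peaks(
    genome: GenomeSequence, peaks: list[MergedPeak], labels: dict[str, str], flank: int
) -> dict[str, tuple[str, str, int]]:
    """Windows dict {peak_id: (sequence, chrom, 0/1 label)} for the CNN,
    keeping only positive/negative peaks whose window fits the chromosome."""
    from .seqio import extract_window

    out = {}
    n_dropped = 0
    for pk in peaks:
        label = labels.get(pk.peak_id, "excluded")
        if label not in ("positive", "negative"):
            continue
        try:
            seq = extract_window(genome, pk.chrom, pk.summit, flank)
        except (ValueError, KeyError):
            n_dropped += 1
            continue
        out[pk.peak_id] = (seq, pk.chrom, 1 if label == "positive" else 0)
    import logging

    logger = logging.getLogger(__name__)
    if n_dropped:
        logger.warning("dropped %d peaks with out-of-bounds windows", n_dropped)
    if out:
        n_frac = np.mean([seq.count("N") / len(seq) for seq, _, _ in out.values()])
        logger.info("%d windows, mean N fraction %.4f", len(out), n_frac)
    return out
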