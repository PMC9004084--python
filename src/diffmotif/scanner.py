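"""FIMO-style PWM scanning with exact order-0 p-values and BH q-values.

The null score distribution under the order-0 background is computed exactly
(full enumeration of the 4^W score distribution, vectorized) for motifs up to
``EXACT_MAX_WIDTH`` columns, and by an integer-lattice dynamic program with
consistently discretized query scores for wider motifs (e.g. 30-50 bp
mega-motifs). The background is symmetrized over strands so a single table
serves both scan orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifops import PFM, Background, pfm_to_pwm
from .seqio import BASES
from .stats import bh_adjust

EXACT_MAX_WIDTH = 10

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i


def encode_indices(seq: str) -> np.ndarray:
    """Encode DNA into base indices 0..3 (A,C,G,T); N and unknowns become 4."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifHit:
    seq_id: str
    offset: int  # 0-based, on the forward strand
    strand: str
    score: float
    p: float
    q: float = np.nan


@dataclass
class ScanConfig:
    p_threshold: float = 1e-4
    emit_all: bool = False
    bins: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


class PValueTable:
    """Null distribution of PWM scores under an order-0 background.

    ``pvalue(s) = P_bg(score >= s)``. For widths <= ``EXACT_MAX_WIDTH`` the
    distribution is enumerated exactly; beyond that, per-column scores are
    rounded onto an integer lattice (``bins`` steps over the total score
    range) and a convolution DP is run; query k-mers are then scored with the
    same integer matrix, so table lookups stay internally consistent.
    """

    def __init__(self, pwm: np.ndarray, bg: Background, bins: int = 1000):
        pwm = np.asarray(pwm, dtype=float)
        if not np.all(np.isfinite(pwm)):
            raise ValueError("PWM entries must be finite")
        self.pwm = pwm
        self.width = pwm.shape[1]
        # strand-symmetrized background: one table serves both orientations
        p0 = bg.order0
        self.bg0 = (p0 + p0[::-1]) / 2
        self.exact = self.width <= EXACT_MAX_WIDTH
        if self.exact:
            vals = pwm[:, 0].copy()
            probs = self.bg0.copy()
            for j in range(1, self.width):
                vals = np.add.outer(vals, pwm[:, j]).ravel()
                probs = np.multiply.outer(probs, self.bg0).ravel()
            order = np.argsort(vals)
            self._vals = vals[order]
            # tail[i] = P(score >= vals[i]); clip cumulative roundoff
            self._tail = np.minimum(np.cumsum(probs[order][::-1])[::-1], 1.0)
        else:
            mins = pwm.min(axis=0)
            total_range = float((pwm.max(axis=0) - mins).sum())
            self._scale = bins / max(total_range, 1e-12)
            self.ipwm = np.rint((pwm - mins[None, :]) * self._scale).astype(np.int64)
            max_sum = int(self.ipwm.max(axis=0).sum())
            dist = np.zeros(max_sum + 1)
            dist[0] = 1.0
            for j in range(self.width):
                nxt = np.zeros_like(dist)
                for b in range(4):
                    s = self.ipwm[b, j]
                    nxt[s:] += self.bg0[b] * dist[: dist.size - s if s else None]
                dist = nxt
            self._tail_int = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)

    def int_scores(self, windows: np.ndarray) -> np.ndarray:
        cols = np.arange(self.width)
        return self.ipwm[windows, cols].sum(axis=1)

    def pvalue_of_scores(self, scores, int_scores=None) -> np.ndarray:
        """p-values for float scores (exact mode) or lattice scores (DP mode)."""
        if self.exact:
            scores = np.atleast_1d(np.asarray(scores, dtype=float))
            idx = np.searchsorted(self._vals, scores - 1e-9, side="left")
            p = np.ones_like(scores)
            inside = idx < self._vals.size
            p[inside] = self._tail[idx[inside]]
            return p
        if int_scores is None:
            raise ValueError("lattice mode requires integer scores")
        s = np.clip(np.atleast_1d(int_scores), 0, self._tail_int.size - 1)
        return self._tail_int[s]


def hit_pvalue_table(pwm: np.ndarray, bg: Background, bins: int = 1000) -> PValueTable:
    return PValueTable(pwm, bg, bins=bins)


def _window_scores(idx: np.ndarray, pwm: np.ndarray):
    """Scores of every window of a base-index sequence; N windows are masked."""
    w = pwm.shape[1]
    if idx.size < w:
        return None, None
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows).astype(np.intp)
    scores = pwm[safe, np.arange(w)].sum(axis=1)
    return safe, (scores, valid)


def scan(
    seqs: dict[str, str],
    pfm: PFM,
    bg: Background,
    cfg: ScanConfig | None = None,
    table: PValueTable | None = None,
) -> list[MotifHit]:
    """Scan sequences with a PFM on both strands, with p- and BH q-values.

    Minus-strand hits score the reverse-complement k-mer against the same
    PWM. Hits with p <= ``cfg.p_threshold`` are retained (all hits in
    ``emit_all`` mode); q-values are BH-adjusted across all retained hits of
    the scan jointly. Output order is (sequence, offset, strand + first).
    Sequences shorter than the motif simply yield no hits.
    """
    cfg = cfg or ScanConfig()
    pwm = pfm_to_pwm(pfm, bg)
    if table is None:
        table = PValueTable(pwm, bg, bins=cfg.bins)
    pwm_rc = pwm[::-1, ::-1]
    hits: list[MotifHit] = []
    for seq_id, seq in seqs.items():
        idx = encode_indices(seq)
        for strand, mat in (("+", pwm), ("-", pwm_rc)):
            safe, res = _window_scores(idx, mat)
            if res is None:
                continue
            scores, valid = res
            if table.exact:
                pvals = table.pvalue_of_scores(scores)
            else:
                cols = np.arange(table.width)
                imat = table.ipwm if strand == "+" else table.ipwm[::-1, ::-1]
                ints = imat[safe, cols].sum(axis=1)
                pvals = table.pvalue_of_scores(scores, int_scores=ints)
            keep = valid if cfg.emit_all else (valid & (pvals <= cfg.p_threshold))
            for off in np.flatnonzero(keep):
                hits.append(
                    MotifHit(seq_id, int(off), strand, float(scores[off]), float(pvals[off]))
                )
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    if hits:
        qvals = bh_adjust([h.p for h in hits])
        for h, q in zip(hits, qvals):
            h.q = float(q)
    return hits


def best_hit_feature(
    hits: list[MotifHit], seq_ids: list[str], mode: str = "neglog10_q_cap"
) -> dict[str, float]:
    """Per-sequence best-hit summary feature.

    ``neglog10_q_cap``: -log10 of the smallest q-value if it is < 0.5, else 0.
    ``neglog10_p_or_one``: -log10 of the smallest p-value, treating a
    sequence with no hits as p = 1 (feature 0).
    Ties are broken by (offset, + strand first) via the scan's ordering.
    """
    best_q: dict[str, float] = {}
    best_p: dict[str, float] = {}
    for h in hits:
        if h.seq_id not in best_q or h.q < best_q[h.seq_id]:
            best_q[h.seq_id] = h.q
        if h.seq_id not in best_p or h.p < best_p[h.seq_id]:
            best_p[h.seq_id] = h.p
    out: dict[str, float] = {}
    for sid in seq_ids:
        if mode == "neglog10_q_cap":
            q = best_q.get(sid, 1.0)
            out[sid] = -np.log10(max(q, 1e-300)) if q < 0.5 else 0.0
        elif mode == "neglog10_p_or_one":
            p = best_p.get(sid, 1.0)
            out[sid] = -np.log10(max(p, 1e-300)) if p < 1.0 else 0.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def write_fimo_tsv(hits: list[MotifHit], path, motif_id: str, seqs: dict[str, str], width: int) -> None:
    """Write hits in FIMO's TSV dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\tmatched_sequence\n"
        )
        for h in hits:
            matched = seqs[h.seq_id][h.offset : h.offset + width]
            if h.strand == "-":
                from .seqio import revcomp

                matched = revcomp(matched)
            fh.write(
                f"{motif_id}\t{h.seq_id}\t{h.offset + 1}\t{h.offset + width}\t"
                f"{h.strand}\t{h.score:.4f}\t{h.p:.3g}\t{h.q:.3g}\t{matched}\n"
            )
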