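"""Position-frequency-matrix operations: trimming, backgrounds, log-odds
conversion, mega-motif assembly, and MEME minimal-format I/O.

Motif trimming removes degenerate flanks from a discovered motif. Three
parameterizations are used in the pipeline (cutoffs 0.60 / 0.40 / 0.35; start
at one passing position or two consecutive; scan from either end; stop at the
second degenerate position or at a max-probability drop), all expressed by
:class:`TrimRule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import BASES

GC_MOUSE = 0.42  # genomic G+C fraction used for background spacer columns


@dataclass
class PFM:
    """4 x W column-stochastic position frequency matrix (rows A,C,G,T)."""

    matrix: np.ndarray
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PFM must be 4 x W with W >= 1")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValueError("PFM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))


@dataclass
class Background:
    """Order-0 base probabilities with an optional order-1 transition matrix.

    ``order1[i, j]`` is P(next base = j | current base = i).
    """

    order0: np.ndarray
    order1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order0 = np.asarray(self.order0, dtype=float)
        if self.order0.shape != (4,):
            raise ValueError("order-0 background must have 4 entries")
        if np.any(self.order0 <= 0) or abs(self.order0.sum() - 1) > 1e-6:
            raise ValueError("order-0 background must be strictly positive and sum to 1")
        if self.order1 is not None:
            self.order1 = np.asarray(self.order1, dtype=float)
            if self.order1.shape != (4, 4):
                raise ValueError("order-1 background must be 4 x 4")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_gc(cls, gc: float = GC_MOUSE) -> "Background":
        at = (1 - gc) / 2
        return cls(np.array([at, gc / 2, gc / 2, at]))


@dataclass
class TrimRule:
    cutoff: float
    start_requirement: str = "one_position"  # or "two_consecutive"
    direction: str = "upstream_to_downstream"  # or "downstream_to_upstream"
    stop_mode: str = "second_degenerate_position"  # or "max_prob_drop"
    drop: float = 0.35

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if not 0 < self.drop < 1:
            raise ValueError("drop must be in (0, 1)")


# The three trimming procedures used on discovered motifs: a 0.60 cutoff for
# the upstream motif, 0.40 with a two-consecutive-base start for the core, and
# 0.35 scanning from the downstream end with a >0.35 max-probability-drop stop.
UPSTREAM_TRIM = TrimRule(cutoff=0.60)
CORE_TRIM = TrimRule(cutoff=0.40, start_requirement="two_consecutive")
DOWNSTREAM_TRIM = TrimRule(
    cutoff=0.35,
    direction="downstream_to_upstream",
    stop_mode="max_prob_drop",
    drop=0.35,
)


def trim_pfm(pfm: PFM, rule: TrimRule) -> PFM:
    """Trim degenerate flanks from ``pfm`` according to ``rule``.

    Scanning in ``rule.direction``: the kept region starts at the first
    position (or the first of two consecutive positions) whose maximum base
    probability exceeds ``rule.cutoff``. With ``second_degenerate_position``
    the scan tolerates one interior degenerate position and ends before the
    second; with ``max_prob_drop`` it ends before the first position whose
    maximum probability falls by more than ``rule.drop`` relative to the
    previously kept position. The returned slice is contiguous and keeps the
    input orientation.
    """
    maxp = pfm.matrix.max(axis=0)
    reverse = rule.direction == "downstream_to_upstream"
    scan = maxp[::-1] if reverse else maxp
    n = scan.size

    passing = scan > rule.cutoff
    if rule.start_requirement == "two_consecutive":
        starts = np.flatnonzero(passing[:-1] & passing[1:])
    else:
        starts = np.flatnonzero(passing)
    if starts.size == 0:
        raise ValueError("motif empty after trim: no position passes the cutoff")
    start = int(starts[0])

    end = n
    if rule.stop_mode == "second_degenerate_position":
        n_degenerate = 0
        for i in range(start, n):
            if scan[i] <= rule.cutoff:
                n_degenerate += 1
                if n_degenerate == 2:
                    end = i
                    break
    elif rule.stop_mode == "max_prob_drop":
        for i in range(start + 1, n):
            if scan[i - 1] - scan[i] > rule.drop:
                end = i
                break
    else:
        raise ValueError(f"unknown stop_mode {rule.stop_mode!r}")

    if reverse:
        lo, hi = n - end, n - start
    else:
        lo, hi = start, end
    return PFM(pfm.matrix[:, lo:hi], name=f"{pfm.name}_trimmed")


def background_from_sequences(seqs: list[str], pseudocount: float = 0.1) -> Background:
    """Estimate order-0 and order-1 backgrounds from sequences.

    Both strands are pooled (so the order-0 background is strand-symmetric),
    an additive pseudocount of 0.1 is applied, and k-mers containing N are
    skipped.
    """
    from .seqio import revcomp

    counts0 = np.full(4, pseudocount)
    counts1 = np.full((4, 4), pseudocount)
    idx = {b: i for i, b in enumerate(BASES)}
    any_base = False
    for seq in seqs:
        for s in (seq.upper(), revcomp(seq.upper())):
            for a, b in zip(s, s[1:]):
                if a in idx and b in idx:
                    counts1[idx[a], idx[b]] += 1
            for a in s:
                if a in idx:
                    counts0[idx[a]] += 1
                    any_base = True
    if not any_base:
        raise ValueError("no countable (non-N) bases in input sequences")
    order1 = counts1 / counts1.sum(axis=1, keepdims=True)
    return Background(counts0 / counts0.sum(), order1)


def pfm_to_pwm(pfm: PFM, bg: Background, pseudocount: float = 0.001) -> np.ndarray:
    """Convert a PFM to a 4 x W log2-odds PWM against an order-0 background.

    pwm[b, j] = log2((p[b, j] + pc * bg[b]) / ((1 + pc) * bg[b])), the
    standard FIMO-style pseudocounted conversion.
    """
    bg0 = bg.order0[:, None]
    return np.log2((pfm.matrix + pseudocount * bg0) / ((1 + pseudocount) * bg0))


def background_columns(bg: Background, k: int) -> np.ndarray:
    return np.tile(bg.order0[:, None], (1, k))


@dataclass
class MegaMotif:
    """A PFM assembled from motif parts separated by background spacers."""

    parts: list = field(default_factory=list)  # PFM | int (spacer width)
    pfm: PFM | None = None


def build_megamotif(parts: list[PFM], spacers: list[int], bg: Background, name: str = "megamotif") -> MegaMotif:
    """Concatenate motif parts with background-probability spacer columns."""
    if len(spacers) != len(parts) - 1:
        raise ValueError("need exactly len(parts) - 1 spacers")
    if any(s < 0 for s in spacers):
        raise ValueError("spacers must be >= 0")
    blocks: list[np.ndarray] = [parts[0].matrix]
    structure: list = [parts[0]]
    for spacer, part in zip(spacers, parts[1:]):
        if spacer:
            blocks.append(background_columns(bg, spacer))
            structure.append(spacer)
        blocks.append(part.matrix)
        structure.append(part)
    return MegaMotif(parts=structure, pfm=PFM(np.hstack(blocks), name=name))


def megamotif_presets(core: PFM, upstream: PFM, downstream: PFM, bg: Background) -> dict[str, MegaMotif]:
    """The six mega-motif presets: each single motif, upstream + 7 bp + core,
    core + 2 bp + downstream, and upstream + 7 bp + core + 2 bp + downstream."""
    return {
        "core": build_megamotif([core], [], bg, "core"),
        "upstream": build_megamotif([upstream], [], bg, "upstream"),
        "downstream": build_megamotif([downstream], [], bg, "downstream"),
        "upstream_core": build_megamotif([upstream, core], [7], bg, "upstream_core"),
        "core_downstream": build_megamotif([core, downstream], [2], bg, "core_downstream"),
        "upstream_core_downstream": build_megamotif(
            [upstream, core, downstream], [7, 2], bg, "upstream_core_downstream"
        ),
    }


def build_selex_query(core: PFM, downstream: PFM, bg: Background) -> PFM:
    """Partial core+downstream combination sized for short (20 bp) reads.

    The downstream-most 10 bp of the core motif, 2 background-probability
    spacer columns, then the upstream-most 4 bp of the downstream motif:
    width exactly 16.
    """
    if core.width < 10:
        raise ValueError("core motif must be at least 10 bp wide")
    if downstream.width < 4:
        raise ValueError("downstream motif must be at least 4 bp wide")
    mat = np.hstack(
        [core.matrix[:, -10:], background_columns(bg, 2), downstream.matrix[:, :4]]
    )
    return PFM(mat, name="selex_query")


def write_meme(pfms: list[PFM], path, bg: Background | None = None) -> None:
    """Write motifs in MEME minimal format (version 4)."""
    bg = bg or Background.uniform()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, bg.order0)) + "\n\n")
        for pfm in pfms:
            fh.write(f"MOTIF {pfm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pfm.matrix.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PFM]:
    """Read motifs from a MEME minimal-format file."""
    pfms: list[PFM] = []
    name, rows, width = None, [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                width = int(line.split("w=")[1].split()[0])
                rows = []
            elif name is not None and width is not None and line and line[0] in "0123456789.":
                rows.append([float(v) for v in line.split()])
                if len(rows) == width:
                    mat = np.array(rows).T
                    pfms.append(PFM(mat / mat.sum(axis=0, keepdims=True), name=name))
                    name, rows, width = None, [], None
    return pfms


def write_background(bg: Background, path) -> None:
    """Write a background in fasta-get-markov's format (order 0 and 1)."""
    with open(path, "w") as fh:
        fh.write("# order 0\n")
        for b, p in zip(BASES, bg.order0):
            fh.write(f"{b} {p:.3e}\n")
        if bg.order1 is not None:
            fh.write("# order 1\n")
            for i, a in enumerate(BASES):
                for j, b in enumerate(BASES):
                    # joint dinucleotide frequency, as fasta-get-markov emits
                    fh.write(f"{a}{b} {bg.order0[i] * bg.order1[i, j]:.3e}\n")
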