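"""Seqlet extraction, alignment similarity, clustering and aggregation."""

import numpy as np
import pytest

from diffmotif.attribution import AttributionTrack, HypotheticalTrack
from diffmotif.motifdisco import (
    Seqlet,
    aggregate_cluster,
    best_alignment,
    cluster_seqlets,
    discover_motifs,
    extract_seqlets,
    seqlet_similarity,
)
from diffmotif.seqio import one_hot


def track_pair(contribs, onehot=None):
    contribs = np.asarray(contribs, dtype=float)
    if onehot is None:
        onehot = (np.abs(contribs) > 0).astype(np.float32)
    return (
        AttributionTrack(contribs, onehot, 0.0, 0.0),
        HypotheticalTrack(contribs.copy()),
    )


def spike_track(length, pos, width=6, value=5.0, seed=0):
    """Zero track with one contiguous block of high contribution."""
    rng = np.random.default_rng(seed)
    c = np.zeros((4, length))
    rows = rng.integers(0, 4, width)
    c[rows, np.arange(pos, pos + width)] = value
    return track_pair(c)


class TestExtraction:
    def test_isolated_spike_yields_one_centered_seqlet(self):
        tracks, hyps = zip(*[spike_track(200, 90, seed=i) for i in range(30)])
        seqlets = extract_seqlets(list(tracks), list(hyps), width=21, fdr=0.2)
        by_peak = {}
        for s in seqlets:
            by_peak.setdefault(s.peak_id, []).append(s)
        assert len(seqlets) == 30
        for s in seqlets:
            # spike block [90, 96) centered at ~93; seqlet centered on it
            assert abs((s.offset + s.width // 2) - 92) <= 3

    def test_all_zero_tracks_yield_nothing(self):
        tracks, hyps = zip(*[track_pair(np.zeros((4, 100))) for _ in range(5)])
        assert extract_seqlets(list(tracks), list(hyps)) == []

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            extract_seqlets([], [])

    def test_planted_sites_recovered(self):
        rng = np.random.default_rng(3)
        tracks, hyps, positions = [], [], []
        for i in range(200):
            pos = int(rng.integers(30, 160))
            c = rng.normal(0, 0.05, (4, 200)) * (rng.random((4, 200)) < 0.25)
            c[rng.integers(0, 4, 6), np.arange(pos, pos + 6)] += 3.0
            t, h = track_pair(c)
            tracks.append(t)
            hyps.append(h)
            positions.append(pos)
        seqlets = extract_seqlets(tracks, hyps, width=21, fdr=0.2, seed=0)
        recovered = 0
        by_peak = {}
        for s in seqlets:
            by_peak.setdefault(s.peak_id, []).append(s)
        for i, pos in enumerate(positions):
            center = pos + 3
            hits = by_peak.get(f"peak{i}", [])
            if any(abs(s.offset + s.width // 2 - center) <= 3 for s in hits):
                recovered += 1
        assert recovered / len(positions) >= 0.95


class TestSimilarity:
    def _seqlet(self, hyp, pid="p"):
        hyp = np.asarray(hyp, dtype=float)
        return Seqlet(pid, 0, hyp.shape[1], np.zeros_like(hyp), hyp.copy(), hyp.copy())

    def test_identical_seqlets_similarity_one(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(4, 21))
        a, b = self._seqlet(h), self._seqlet(h)
        assert seqlet_similarity(a, b) == pytest.approx(1.0)
        sim, off, orient = best_alignment(a.hyp, b.hyp)
        assert (off, orient) == (0, "fwd")

    def test_similarity_bounded_and_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = self._seqlet(rng.normal(size=(4, 15)))
            b = self._seqlet(rng.normal(size=(4, 15)))
            s_ab, s_ba = seqlet_similarity(a, b), seqlet_similarity(b, a)
            assert -1 <= s_ab <= 1
            assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_sign_flip_scores_below_self_similarity(self):
        # the best alignment of a sign-flipped copy is strictly worse than the
        # perfect self-match (at full overlap its cosine is exactly -1, but
        # partial-overlap alignments may score closer to zero)
        rng = np.random.default_rng(2)
        h = rng.normal(size=(4, 21))
        a = self._seqlet(h)
        flipped = seqlet_similarity(a, self._seqlet(-h))
        assert flipped < seqlet_similarity(a, a) - 0.5
        x = h / np.linalg.norm(h)
        assert ((x * -x).sum()) == pytest.approx(-1.0)

    def test_shifted_seqlet_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(4, 21))
        shifted = np.roll(h, 3, axis=1)
        a, b = self._seqlet(h), self._seqlet(shifted)
        w = 21

        def oracle():
            best = -np.inf
            for orient in (b.hyp, b.hyp[::-1, ::-1]):
                for off in range(-w // 2, w // 2 + 1):
                    alo, ahi = max(0, off), min(w, w + off)
                    blo, bhi = max(0, -off), min(w, w - off)
                    if ahi <= alo:
                        continue
                    x, y = a.hyp[:, alo:ahi], orient[:, blo:bhi]
                    denom = np.linalg.norm(x) * np.linalg.norm(y)
                    if denom == 0:
                        continue
                    best = max(best, (x * y).sum() / denom * (ahi - alo) / w)
            return best

        assert seqlet_similarity(a, b) == pytest.approx(oracle(), abs=1e-12)

    def test_revcomp_orientation_detected(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(4, 21))
        b_hyp = h[::-1, ::-1].copy()
        sim, off, orient = best_alignment(h, b_hyp)
        assert sim == pytest.approx(1.0)
        assert orient == "rev"


class TestClustering:
    def _seqlet(self, hyp, score=1.0, pid="p"):
        hyp = np.asarray(hyp, dtype=float)
        return Seqlet(
            pid, 0, hyp.shape[1], np.zeros_like(hyp), score * np.ones_like(hyp), hyp
        )

    def test_copies_form_single_cluster(self):
        rng = np.random.default_rng(5)
        h = rng.normal(size=(4, 21))
        seqlets = [self._seqlet(h, pid=f"p{i}") for i in range(12)]
        clusters = cluster_seqlets(seqlets, min_seqlets=2)
        assert len(clusters) == 1
        assert clusters[0].size == 12

    def test_dissimilar_motifs_split(self):
        rng = np.random.default_rng(6)
        h1 = rng.normal(size=(4, 21))
        h2 = rng.normal(size=(4, 21))
        assert seqlet_similarity(self._seqlet(h1), self._seqlet(h2)) < 0.5
        seqlets = [self._seqlet(h1, pid=f"a{i}") for i in range(8)] + [
            self._seqlet(h2, pid=f"b{i}") for i in range(8)
        ]
        clusters = cluster_seqlets(seqlets, sim_threshold=0.8, min_seqlets=2)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [8, 8]

    def test_min_seqlets_filters_everything(self):
        rng = np.random.default_rng(7)
        seqlets = [self._seqlet(rng.normal(size=(4, 21)))] * 5
        assert cluster_seqlets(seqlets, min_seqlets=6) == []

    def test_cluster_sizes_bounded_by_seqlet_count(self):
        rng = np.random.default_rng(8)
        seqlets = [self._seqlet(rng.normal(size=(4, 11))) for _ in range(30)]
        clusters = cluster_seqlets(seqlets, sim_threshold=0.3, min_seqlets=1)
        assert sum(c.size for c in clusters) <= 30


class TestAggregation:
    def test_identical_seqlets_give_indicator_pfm(self):
        oh = one_hot("GAGCCAGAGCCAGAGCCAGAG").astype(float)
        hyp = oh * 2.0
        s = Seqlet("p", 0, 21, oh, hyp, hyp)
        from diffmotif.motifdisco import SeqletCluster

        cluster = SeqletCluster(members=[(s, 0, "fwd")] * 5)
        motif = aggregate_cluster(cluster, out_width=50)
        covered = motif.pfm.sum(axis=0) > 0
        assert covered.sum() == 21
        np.testing.assert_allclose(motif.pfm[:, covered], oh)

    def test_mixed_column_averages(self):
        a = one_hot("A" * 21).astype(float)
        c = one_hot("C" * 21).astype(float)
        from diffmotif.motifdisco import SeqletCluster

        cluster = SeqletCluster(
            members=[(Seqlet("p", 0, 21, a, a, a), 0, "fwd"), (Seqlet("q", 0, 21, c, c, c), 0, "fwd")]
        )
        motif = aggregate_cluster(cluster)
        covered = motif.pfm.sum(axis=0) > 0
        np.testing.assert_allclose(motif.pfm[0, covered], 0.5)
        np.testing.assert_allclose(motif.pfm[1, covered], 0.5)

    def test_pfm_columns_sum_to_one_or_zero(self):
        rng = np.random.default_rng(9)
        from diffmotif.motifdisco import SeqletCluster

        members = []
        for i in range(6):
            seq = "".join(rng.choice(list("ACGT"), 21))
            oh = one_hot(seq).astype(float)
            members.append((Seqlet(f"p{i}", 0, 21, oh, oh, oh), int(rng.integers(-5, 6)), "fwd"))
        motif = aggregate_cluster(SeqletCluster(members=members))
        sums = motif.pfm.sum(axis=0)
        assert np.all((np.abs(sums - 1) < 1e-9) | (np.abs(sums) < 1e-9))


def test_discover_motifs_end_to_end_on_planted_pattern():
    """Planted identical high-scoring blocks cluster into one top motif whose
    consensus contains the planted 6-mer."""
    rng = np.random.default_rng(10)
    motif_oh = one_hot("GAGCCA").astype(float)
    tracks, hyps = [], []
    for i in range(60):
        pos = int(rng.integers(40, 140))
        seq = "".join(rng.choice(list("ACGT"), 200))
        oh = one_hot(seq).astype(float)
        oh[:, pos : pos + 6] = motif_oh
        c = np.zeros((4, 200))
        c += oh * rng.normal(0.02, 0.01, (1, 200)).clip(0)
        c[:, pos : pos + 6] = motif_oh * 4.0
        tracks.append(AttributionTrack(c, oh, 0.0, 0.0))
        h = np.tile(c.sum(axis=0, keepdims=True) * 0.1, (4, 1))
        h[:, pos : pos + 6] = (motif_oh * 2 - 0.5) * 4.0
        hyps.append(HypotheticalTrack(h))
    motifs = discover_motifs(tracks, hyps, min_seqlets=10, sim_threshold=0.6)
    assert motifs
    assert motifs[0].rank == 0
    assert motifs[0].n_seqlets >= 30
    consensus = motifs[0].consensus()
    from diffmotif.seqio import revcomp

    assert "GAGCCA" in consensus or "GAGCCA" in revcomp(consensus)
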