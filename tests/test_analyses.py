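"""SELEX scoring/enrichment, hit logos, overlap partitions, strength tests,
and the logistic baseline."""

import numpy as np
import pandas as pd
import pytest

from diffmotif.analyses import (
    ReadPool,
    aggregate_hit_logo,
    build_strength_table,
    compare_partition_pvalues,
    logistic_baseline,
    partition_by_overlap,
    selex_enrichment_test,
    selex_read_score,
    strength_association,
    strength_correlation_comparison,
)
from diffmotif.convnet import SplitSpec
from diffmotif.motifops import PFM, Background, build_selex_query
from diffmotif.seqio import GenomicInterval, revcomp
from diffmotif.synthetic import SimConfig, consensus_pfm, simulate_selex_pools


def indicator_pfm(consensus):
    mat = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = 1.0
    return PFM(mat)


class TestSelexScore:
    def test_consensus_read_scores_full_width(self):
        q = indicator_pfm("GAGCCAGAGCCAGAGC")
        assert selex_read_score("GAGCCAGAGCCAGAGC", q) == pytest.approx(16.0)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(0)
        q = PFM(rng.dirichlet(np.ones(4), size=16).T)
        for _ in range(25):
            read = "".join(rng.choice(list("ACGT"), 20))
            assert selex_read_score(read, q) == pytest.approx(
                selex_read_score(revcomp(read), q)
            )

    def test_matches_exhaustive_alignment_oracle(self):
        rng = np.random.default_rng(1)
        q = PFM(rng.dirichlet(np.ones(4), size=16).T)

        def oracle(read):
            best = -np.inf
            for r in (read, revcomp(read)):
                idx = ["ACGT".index(c) for c in r]
                for off in range(len(r) - 16 + 1):
                    best = max(
                        best,
                        sum(q.matrix[idx[off + j], j] for j in range(16)),
                    )
            return best

        for _ in range(1000):
            read = "".join(rng.choice(list("ACGT"), 20))
            assert selex_read_score(read, q) == pytest.approx(oracle(read), abs=1e-12)

    def test_query_wider_than_read_slides_read(self):
        q = indicator_pfm("AAAACCCCGGGGTTTT")
        # a 4-bp read aligned inside the 16-bp query
        assert selex_read_score("CCCC", q) == pytest.approx(4.0)


class TestSelexEnrichment:
    def test_planted_enrichment_detected(self):
        cfg = SimConfig(selex_enrichment=0.3)
        query = build_selex_query(
            consensus_pfm("CCAGCAGGGGGCGCTACTA"), consensus_pfm("GAGCCA", 0.9), Background.from_gc(0.42)
        )
        c0, ck, _ = simulate_selex_pools(cfg, query, seed=5, n_reads=2000)
        res = selex_enrichment_test(c0, ck, query)
        assert res.p < 1e-6

    def test_null_is_roughly_uniform(self):
        cfg = SimConfig(selex_enrichment=0.0)
        query = build_selex_query(
            consensus_pfm("CCAGCAGGGGGCGCTACTA"), consensus_pfm("GAGCCA", 0.9), Background.from_gc(0.42)
        )
        ps = []
        for seed in range(20):
            c0, ck, _ = simulate_selex_pools(cfg, query, seed=seed, n_reads=300)
            ps.append(selex_enrichment_test(c0, ck, query).p)
        assert 0.2 < np.median(ps) < 0.8

    def test_empty_pool_errors(self):
        q = indicator_pfm("ACGT")
        with pytest.raises(ValueError):
            selex_enrichment_test(ReadPool([]), ReadPool(["ACGT"]), q)


class TestAggregateLogo:
    def test_identical_perfect_hits_give_indicator(self):
        q = consensus_pfm("GAGCCATT", 0.9)
        read = "AACCGAGCCATTACCGGTAA"
        pool = ReadPool([read] * 30)
        logos = aggregate_hit_logo(pool, q, Background.uniform(), q_cutoffs=(0.05,))
        logo = logos[0.05]
        assert logo is not None
        assert logo.consensus() == "GAGCCATT"

    def test_no_hits_flagged_empty(self):
        q = consensus_pfm("GGGGGGGG", 0.97)
        pool = ReadPool(["A" * 20] * 10)
        logos = aggregate_hit_logo(pool, q, Background.uniform(), q_cutoffs=(0.001,))
        assert logos[0.001] is None

    def test_noisy_consensus_recovered(self):
        rng = np.random.default_rng(2)
        q = consensus_pfm("GAGCCATT", 0.9)
        reads = []
        for _ in range(300):
            arr = list("GAGCCATT")
            for j in range(8):
                if rng.random() < 0.1:
                    arr[j] = rng.choice(list("ACGT"))
            flank = "".join(rng.choice(list("ACGT"), 12))
            reads.append(flank[:6] + "".join(arr) + flank[6:])
        logos = aggregate_hit_logo(ReadPool(reads), q, Background.uniform())
        logo = logos[0.05]
        assert logo is not None
        assert (logo.matrix.max(axis=0) >= 0.8).all()


class TestOverlapPartition:
    def test_one_bp_overlap_counts(self):
        a = [GenomicInterval("chr1", 0, 100)]
        part = partition_by_overlap(a, [GenomicInterval("chr1", 99, 150)], [])
        assert part.overlapping == a

    def test_touching_is_not_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        part = partition_by_overlap(a, [], [GenomicInterval("chr1", 100, 200)])
        assert part.non_overlapping == a

    def test_relaxed_only_overlap_excluded_from_both(self):
        a = [GenomicInterval("chr1", 0, 100)]
        strict = [GenomicInterval("chr1", 500, 600)]
        relaxed = [GenomicInterval("chr1", 50, 70), GenomicInterval("chr1", 500, 600)]
        part = partition_by_overlap(a, strict, relaxed)
        assert part.overlapping == []
        assert part.non_overlapping == []

    def test_sides_disjoint_when_strict_subset_of_relaxed(self):
        rng = np.random.default_rng(3)
        a = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 5000, 100)
        ]
        strict = [
            GenomicInterval("chr1", int(s), int(s) + 40)
            for s in rng.integers(0, 5000, 20)
        ]
        relaxed = strict + [
            GenomicInterval("chr1", int(s), int(s) + 40)
            for s in rng.integers(0, 5000, 30)
        ]
        part = partition_by_overlap(a, strict, relaxed)
        ids = lambda ivs: {(iv.chrom, iv.start, iv.end) for iv in ivs}  # noqa: E731
        assert not (ids(part.overlapping) & ids(part.non_overlapping))


class TestPartitionComparison:
    def test_planted_motif_separates_sides(self):
        rng = np.random.default_rng(4)
        mega = consensus_pfm("GGTGGCGCTAAT", 0.9)
        with_motif, without = {}, {}
        for i in range(120):
            seq = "".join(rng.choice(list("ACGT"), 120))
            without[f"n{i}"] = seq
            pos = int(rng.integers(10, 90))
            with_motif[f"p{i}"] = seq[:pos] + "GGTGGCGCTAAT" + seq[pos + 12 :]
        res = compare_partition_pvalues(with_motif, without, mega, Background.uniform())
        assert res.p < 1e-10

    def test_identical_content_is_null(self):
        rng = np.random.default_rng(5)
        mega = consensus_pfm("GGTGGCGC", 0.9)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 100)) for i in range(60)}
        other = {f"t{i}": s for i, s in enumerate(seqs.values())}
        res = compare_partition_pvalues(seqs, other, mega, Background.uniform())
        assert res.p > 0.9

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            compare_partition_pvalues({}, {"a": "ACGT"}, consensus_pfm("ACGT"), Background.uniform())


def _strength_table(seed=6, n=400, shift=0.0):
    """Synthetic strength table: half the peaks carry a 10 bp downstream
    motif (wide enough that p < 1e-4 hits are reachable) after the core."""
    rng = np.random.default_rng(seed)
    core, down = "CCAGCAGGGGGCGCTACTA", "GAGCCATTCG"
    from diffmotif.motifops import build_megamotif

    bg = Background.from_gc(0.42)
    core_pfm = consensus_pfm(core, 0.85)
    down_pfm = consensus_pfm(down, 0.9)
    mega = build_megamotif([core_pfm, down_pfm], [2], bg, "core_downstream").pfm
    seqs, signal = {}, {}
    has_down = {}
    def noisy(s):
        return "".join(
            rng.choice(list("ACGT")) if rng.random() < 0.12 else c for c in s
        )

    for i in range(n):
        with_down = i % 2 == 0
        insert = noisy(core) + ("TT" + noisy(down) if with_down else "")
        seq = "".join(rng.choice(list("ACGT"), 200))
        pos = int(rng.integers(10, 120))
        seq = (seq[:pos] + insert + seq[pos + len(insert) :])[:200]
        pid = f"peak{i:04d}"
        seqs[pid] = seq
        base = rng.lognormal(2.0, 0.3)
        signal[pid] = base * np.exp(shift if with_down else 0.0)
        has_down[pid] = with_down
    table = build_strength_table(
        seqs, signal, {"core": core_pfm, "downstream": down_pfm, "core_downstream": mega}, bg
    )
    return table, has_down


class TestStrength:
    def test_association_detects_shift(self):
        table, _ = _strength_table(seed=7, n=400, shift=0.8)
        res = strength_association(table)
        assert res["test"] is not None
        assert res["p_adjusted"] < 1e-6
        assert len(res["group_a"]) > 0 and len(res["group_b"]) > 0

    def test_association_null_not_significant(self):
        table, _ = _strength_table(seed=8, n=300, shift=0.0)
        res = strength_association(table)
        assert res["p_adjusted"] > 0.05

    def test_cutoff_mode_changes_groups_not_test(self):
        table, _ = _strength_table(seed=9, n=200, shift=0.3)
        res_p = strength_association(table, cutoff_mode="p1e-4")
        res_q = strength_association(table, cutoff_mode="q0.05")
        assert res_p["test"].sidedness == res_q["test"].sidedness == "two"

    def test_correlation_comparison_identity_is_half(self):
        table, _ = _strength_table(seed=10, n=100)
        res = strength_correlation_comparison(table, "core", "core")
        assert res["test"].statistic == 0.0
        assert res["test"].p == pytest.approx(0.5)

    def test_correlation_comparison_detects_dependence(self):
        table, has_down = _strength_table(seed=11, n=2000, shift=0.0)
        # make strength depend on the downstream-motif feature
        feat = table["core_downstream_neglog10q"].to_numpy()
        rng = np.random.default_rng(12)
        table = table.copy()
        table["ln_signal"] = 0.5 * feat + rng.normal(0, 0.5, len(table))
        res = strength_correlation_comparison(table, "core", "core_downstream")
        assert res["p_adjusted"] < 0.01
        # Pearson r oracle
        x = table["core_downstream_neglog10q"].to_numpy()
        y = table["ln_signal"].to_numpy()
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["r_y"] == pytest.approx(r_oracle, abs=1e-12)


class TestLogisticBaseline:
    def _chroms(self, n, rng):
        pool = [f"chr{i}" for i in range(1, 20)] + ["chrX"]
        return rng.choice(pool, n)

    def test_label_feature_gives_perfect_auprc(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 400)
        chroms = self._chroms(400, rng)
        _, ap = logistic_baseline(y.astype(float).reshape(-1, 1), y, chroms, SplitSpec())
        assert ap == pytest.approx(1.0)

    def test_independent_feature_near_prevalence(self):
        rng = np.random.default_rng(14)
        y = (rng.random(2000) < 0.3).astype(int)
        x = rng.normal(size=(2000, 1))
        chroms = self._chroms(2000, rng)
        _, ap = logistic_baseline(x, y, chroms, SplitSpec())
        test_mask = np.isin(chroms, ["chr1", "chr2"])
        prevalence = y[test_mask].mean()
        assert abs(ap - prevalence) < 0.1

    def test_single_class_split_errors(self):
        with pytest.raises(ValueError):
            logistic_baseline(
                np.zeros((4, 1)),
                np.array([1, 1, 1, 1]),
                np.array(["chr3", "chr3", "chr1", "chr1"]),
                SplitSpec(),
            )
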