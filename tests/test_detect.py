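"""Clustering, scoring, filtering and the topology export of the caller."""

import math

import numpy as np
import pytest

from binbreak.core import BinAccumulator, PairClass
from binbreak.detect import (
    CallConfig,
    SVCall,
    call_svs,
    cluster_cells,
    cluster_size_distribution,
    local_topology_tree,
    pass1,
    score_feature,
)
from binbreak.rules import RuleConfig


def _acc_with_cells(seqdict, cells):
    """Accumulator with hand-placed 2D cells: (chromA, binA, chromB, binB, cls, names)."""
    acc = BinAccumulator(seqdict)
    from binbreak.core import Cell2D, canonical_2d_key

    for ca, ba, cb, bb, cls, names in cells:
        key = canonical_2d_key((ca, ba), (cb, bb), seqdict)
        cell = acc.counts2d.setdefault(key, Cell2D())
        for n in names:
            cell.add(cls, n, 60)
    return acc


class TestClusterCells:
    def test_adjacent_cells_merge(self, seqdict):
        acc = _acc_with_cells(
            seqdict,
            [
                ("chr1", 5, "chr2", 7, PairClass.INTERCHROM, ["a", "b"]),
                ("chr1", 6, "chr2", 7, PairClass.INTERCHROM, ["c"]),
            ],
        )
        cands = cluster_cells(acc)
        assert len(cands) == 1
        c = cands[0]
        assert c.binsA == (5, 6) and c.binsB == (7, 7)
        assert set(c.support) == {"a", "b", "c"}

    def test_cells_beyond_radius_stay_separate(self, seqdict):
        acc = _acc_with_cells(
            seqdict,
            [
                ("chr1", 5, "chr2", 7, PairClass.INTERCHROM, ["a"]),
                ("chr1", 8, "chr2", 7, PairClass.INTERCHROM, ["b"]),
            ],
        )
        assert len(cluster_cells(acc)) == 2

    def test_classes_never_mix(self, seqdict):
        acc = _acc_with_cells(
            seqdict,
            [
                ("chr1", 5, "chr1", 9, PairClass.WINDOW_DISTANCE, ["a", "b", "c"]),
                ("chr1", 5, "chr1", 9, PairClass.ORIENTATION, ["d", "e", "f"]),
            ],
        )
        cands = cluster_cells(acc)
        assert len(cands) == 2
        assert {c.sv_class for c in cands} == {
            PairClass.WINDOW_DISTANCE, PairClass.ORIENTATION,
        }

    def test_matches_brute_force_single_linkage(self, seqdict, mkrec, rules):
        """Binned-plus-adjacency clustering equals brute-force single linkage
        (linkage distance = bin size) for tight, isolated clusters."""
        bin_size = 1000
        n_checked = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pairs = []
            # well-separated tight clusters of interchromosomal pairs
            n_clusters = int(rng.integers(1, 6))
            centers = []
            for _ in range(n_clusters):
                while True:
                    ca = int(rng.integers(10_000, 9_000_000))
                    cb = int(rng.integers(10_000, 7_000_000))
                    if all(
                        abs(ca - x) > 5 * bin_size or abs(cb - y) > 5 * bin_size
                        for x, y in centers
                    ):
                        break
                centers.append((ca, cb))
                span = int(rng.integers(1, bin_size))  # cluster span < bin_size
                for _ in range(int(rng.integers(2, 8))):
                    pairs.append(
                        mkrec(
                            "chr1", ca + int(rng.integers(0, span)), "+",
                            "chr2", cb + int(rng.integers(0, span)), "-",
                        )
                    )
            # brute-force single linkage on raw coordinates
            pts = [(p.posA, p.posB) for p in pairs]
            parent = list(range(len(pts)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    if (
                        abs(pts[i][0] - pts[j][0]) <= bin_size
                        and abs(pts[i][1] - pts[j][1]) <= bin_size
                    ):
                        parent[find(i)] = find(j)
            brute: dict[int, set[str]] = {}
            for i, p in enumerate(pairs):
                brute.setdefault(find(i), set()).add(p.name)

            acc = pass1(pairs, seqdict, rules, bin_size=bin_size)
            binned = [set(c.support) for c in cluster_cells(acc)]
            for members in brute.values():
                span_a = max(pts[i][0] for i, p in enumerate(pairs) if p.name in members) - \
                    min(pts[i][0] for i, p in enumerate(pairs) if p.name in members)
                if span_a >= bin_size:
                    continue
                assert members in binned
                n_checked += 1
        assert n_checked > 200  # the comparison actually exercised many clusters


class TestScoreFeature:
    def test_closed_forms(self):
        assert score_feature([0]) == 0.0
        assert score_feature([10, 10]) == pytest.approx(0.99, abs=1e-12)
        assert score_feature([30, 30, 30]) == pytest.approx(1 - 1e-9, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_feature([])

    def test_monotone_in_count_and_quality(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            qs = list(rng.integers(0, 61, size=rng.integers(1, 10)))
            s = score_feature(qs)
            assert 0.0 <= s <= 1.0
            # adding any read with q > 0 strictly increases the score
            assert score_feature(qs + [int(rng.integers(1, 61))]) > s or s == 1.0
            # raising one quality never decreases it
            i = int(rng.integers(len(qs)))
            bumped = qs.copy()
            bumped[i] = min(bumped[i] + 10, 60)
            assert score_feature(bumped) >= s

    def test_zero_only_when_all_mapq_zero(self):
        assert score_feature([0, 0, 0]) == 0.0
        assert score_feature([0, 0, 1]) > 0.0


class TestCallSvs:
    def _planted_acc(self, seqdict, mkrec, rules, n_support, n_background):
        recs = [
            mkrec("chr1", 5_000_100 + i, "+", "chr2", 3_000_200 + i, "-")
            for i in range(n_support)
        ]
        recs += [
            mkrec("chr1", 5_000_000 + (i % 900), "+",
                  "chr1", 5_000_300 + (i % 900), "-")
            for i in range(n_background)
        ]
        return pass1(recs, seqdict, rules)

    def test_two_supports_rejected_at_defaults(self, seqdict, mkrec, rules):
        acc = self._planted_acc(seqdict, mkrec, rules, n_support=2, n_background=5)
        assert call_svs(acc, CallConfig(), rules) == []

    def test_min_support_two_flag_admits_pairs_of_two(self, seqdict, mkrec, rules):
        acc = self._planted_acc(seqdict, mkrec, rules, n_support=2, n_background=5)
        calls = call_svs(acc, CallConfig(min_support=2), rules)
        assert len(calls) == 1 and calls[0].n_support == 2

    def test_support_fraction_thresholds(self, seqdict, mkrec, rules):
        # 10 supports over local coverage 40 -> fraction 0.25, called
        acc = self._planted_acc(seqdict, mkrec, rules, n_support=10, n_background=30)
        calls = call_svs(acc, CallConfig(), rules)
        assert len(calls) == 1
        assert calls[0].support_fraction == pytest.approx(10 / 40)
        # 10 supports over local coverage 500 -> fraction 0.02 < 0.05, rejected
        acc = self._planted_acc(seqdict, mkrec, rules, n_support=10, n_background=490)
        assert call_svs(acc, CallConfig(), rules) == []

    def test_beyond_window_excluded_by_default(self, seqdict, mkrec):
        rules = RuleConfig()
        recs = [
            mkrec("chr1", 100_000 + i, "+", "chr1", 112_000 + i, "-")
            for i in range(8)
        ]
        acc = pass1(recs, seqdict, rules)
        assert call_svs(acc, CallConfig(), rules) == []
        permissive = RuleConfig(count_beyond_window=True)
        acc = pass1(recs, seqdict, permissive)
        calls = call_svs(acc, CallConfig(), permissive)
        assert len(calls) == 1 and calls[0].sv_class is PairClass.BEYOND_WINDOW

    def test_call_fields_and_score(self, seqdict, mkrec, rules):
        acc = self._planted_acc(seqdict, mkrec, rules, n_support=6, n_background=10)
        (call,) = call_svs(acc, CallConfig(), rules, sample_id="s1")
        assert call.sv_class is PairClass.INTERCHROM
        assert call.n_support == 6
        assert call.score == pytest.approx(1 - (1e-6) ** 6)
        assert call.regionA[1] % 1000 == 0 and call.regionA[2] % 1000 == 0
        assert call.sample_id == "s1"


class TestClusterSizeDistribution:
    def test_planted_events(self, seqdict, mkrec, rules):
        recs = []
        for k in range(5):
            recs += [
                mkrec("chr1", 1_000_000 * (k + 1) + i, "+",
                      "chr2", 500_000 * (k + 1) + i, "-")
                for i in range(8)
            ]
        acc = pass1(recs, seqdict, rules)
        dist = cluster_size_distribution(acc)
        row = dist[(dist["sv_class"] == "INTERCHROM") & (dist["size"] == 8)]
        assert int(row["count"].iloc[0]) == 5

    def test_conservation(self, seqdict, random_stream, rules):
        recs = random_stream(800, seed=13)
        acc = pass1(recs, seqdict, rules)
        dist = cluster_size_distribution(acc)
        total_in_hist = int((dist["size"] * dist["count"]).sum())
        total_odd = sum(acc.total_odd_1d().values())
        assert total_in_hist == total_odd  # names are unique in this stream

    def test_noise_only_mass_at_size_one(self, seqdict, mkrec, rules):
        rng = np.random.default_rng(4)
        recs = [
            mkrec("chr1", int(rng.integers(0, 9_000_000)), "+",
                  "chr2", int(rng.integers(0, 7_000_000)), "-")
            for _ in range(30)
        ]
        dist = cluster_size_distribution(pass1(recs, seqdict, rules))
        assert (dist["size"] == 1).all()


def _call(ra, rb, n=5):
    return SVCall(
        regionA=ra, regionB=rb, sv_class=PairClass.INTERCHROM,
        n_support=n, local_coverage=20, support_fraction=n / 20, score=0.999,
    )


class TestTopologyTree:
    def test_no_overlap_single_node(self, seqdict):
        tree = local_topology_tree(
            [_call(("chr2", 0, 1000), ("chr3", 0, 1000))],
            ("chr1", 0, 10_000), 3, seqdict,
        )
        assert tree["children"] == []
        assert tree["region"] == ["chr1", 0, 10_000]

    def test_translocation_child(self, seqdict):
        calls = [_call(("chr1", 5000, 6000), ("chr2", 100_000, 101_000))]
        tree = local_topology_tree(calls, ("chr1", 0, 10_000), 3, seqdict)
        assert len(tree["children"]) == 1
        child = tree["children"][0]
        assert child["region"] == ["chr2", 100_000, 101_000]
        assert child["n_support"] == 5 and child["children"] == []

    def test_cycle_broken_each_edge_once(self, seqdict):
        calls = [
            _call(("chr1", 0, 1000), ("chr2", 0, 1000)),
            _call(("chr1", 0, 1000), ("chr2", 0, 1000), n=7),
        ]
        tree = local_topology_tree(calls, ("chr1", 0, 1000), 10, seqdict)

        def count_edges(node):
            return len(node["children"]) + sum(
                count_edges(c) for c in node["children"]
            )

        assert count_edges(tree) == 2  # both calls used exactly once

    def test_depth_bound(self, seqdict):
        calls = [
            _call(("chr1", 0, 1000), ("chr2", 0, 1000)),
            _call(("chr2", 0, 1000), ("chr3", 0, 1000)),
        ]
        tree = local_topology_tree(calls, ("chr1", 0, 1000), 1, seqdict)
        assert len(tree["children"]) == 1
        assert tree["children"][0]["children"] == []

    def test_unknown_anchor_chromosome(self, seqdict):
        with pytest.raises(ValueError):
            local_topology_tree([], ("chr9", 0, 1000), 2, seqdict)
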