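"""Sphere and message-passing clustering over Levenshtein distance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bclink import (
    BarcodeCount,
    BarcodeSpec,
    ClusteringConfig,
    ReadSimConfig,
    build_library,
    build_lookup_table,
    cluster,
    consensus_and_purity,
    generate_unique_barcodes,
    group_by_barcode,
    levenshtein,
    library_overlap,
    message_passing_cluster,
    sphere_cluster,
    split_singlets,
    subsample_reads,
    validate_clustering,
)
from bclink.clustering import _levenshtein_dp

from conftest import make_range, oracle_levenshtein


def _counts(d):
    return [BarcodeCount(s, c) for s, c in d.items()]


def _total(result):
    return sum(c.total_count for c in result.clusters) + \
        sum(m.count for m in result.discarded)


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,d", [
        ("", "", 0), ("AAA", "AAA", 0), ("kitten", "sitting", 3),
        ("ACGT", "AGT", 1), ("AAAA", "TTTT", 4), ("AC", "CA", 2),
    ])
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b, cap=10) == d
        assert _levenshtein_dp(a, b, cap=10) == d
        assert oracle_levenshtein(a, b) == d

    def test_cap_early_exit(self):
        assert levenshtein("AAAAAAAA", "TTTTTTTT", cap=3) == 4
        assert _levenshtein_dp("AAAAAAAA", "TTTTTTTT", cap=3) == 4

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", max_size=12),
           st.text(alphabet="ACGT", max_size=12),
           st.integers(min_value=0, max_value=12))
    def test_capped_distance_matches_full_dp_oracle(self, a, b, cap):
        expected = oracle_levenshtein(a, b)
        expected = expected if expected <= cap else cap + 1
        assert levenshtein(a, b, cap) == expected
        assert _levenshtein_dp(a, b, cap) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACG", max_size=8),
           st.text(alphabet="ACG", max_size=8),
           st.text(alphabet="ACG", max_size=8))
    def test_metric_properties(self, a, b, c):
        dab = oracle_levenshtein(a, b)
        assert dab == oracle_levenshtein(b, a)
        assert dab <= oracle_levenshtein(a, c) + oracle_levenshtein(c, b)
        assert levenshtein(a, b, 20) == dab


class TestSphereCluster:
    def _cfg(self, d):
        return ClusteringConfig(algorithm="sphere", max_dist=d)

    def test_highest_count_claims_neighbours(self):
        res = sphere_cluster(_counts({"AAA": 10, "AAT": 2, "TTT": 5}),
                             self._cfg(1))
        got = {c.centroid: sorted(m.sequence for m in c.members)
               for c in res.clusters}
        assert got == {"AAA": ["AAA", "AAT"], "TTT": ["TTT"]}
        assert res.discarded == []

    def test_equidistant_tie_discarded(self):
        res = sphere_cluster(_counts({"AAC": 10, "AAG": 10, "AAT": 1}),
                             self._cfg(1))
        assert sorted(c.centroid for c in res.clusters) == ["AAC", "AAG"]
        assert [m.sequence for m in res.discarded] == ["AAT"]

    def test_zero_radius_identity(self):
        counts = _counts({"AAA": 3, "AAT": 2, "CCC": 1})
        res = sphere_cluster(counts, self._cfg(0))
        assert res.n_clusters == 3 and not res.discarded

    def test_claims_resolved_against_brute_force(self, rng):
        """Randomised check against a literal re-execution of the rule."""
        for _ in range(50):
            seqs = {}
            while len(seqs) < 8:
                s = "".join(rng.choice(list("AC"), size=4))
                seqs.setdefault(s, int(rng.integers(1, 20)))
            d = int(rng.integers(1, 3))
            res = sphere_cluster(_counts(seqs), self._cfg(d))
            # literal brute-force reference
            order = sorted(seqs, key=lambda s: (-seqs[s], s))
            centroids, assign, discarded = [], {}, []
            for s in order:
                cands = [c for c in centroids if seqs[c] > seqs[s]
                         and oracle_levenshtein(s, c) <= d]
                if cands:
                    dm = min(oracle_levenshtein(s, c) for c in cands)
                    best = [c for c in cands
                            if oracle_levenshtein(s, c) == dm]
                    if len(best) == 1:
                        assign[s] = best[0]
                    else:
                        discarded.append(s)
                else:
                    centroids.append(s)
                    assign[s] = s
            got_assign = res.assignment()
            assert got_assign == assign
            assert sorted(m.sequence for m in res.discarded) == \
                sorted(discarded)


class TestMessagePassing:
    def _cfg(self, d):
        return ClusteringConfig(algorithm="message_passing", max_dist=d)

    def test_error_halo_collapses_to_root(self, rng):
        root = "ACGTACGTACGTACGTACGT"
        counts = {root: 100}
        while len(counts) < 11:
            pos = int(rng.integers(0, 20))
            b = "ACGT"[int(rng.integers(0, 4))]
            derived = root[:pos] + b + root[pos + 1:]
            if derived not in counts:
                counts[derived] = int(rng.integers(1, 4))
        res = message_passing_cluster(_counts(counts), self._cfg(2))
        assert res.n_clusters == 1
        assert res.clusters[0].centroid == root
        assert _total(res) == sum(counts.values())
        assert res.clusters[0].total_count == sum(counts.values())

    def test_distant_roots_stay_separate(self, rng):
        a = "A" * 20
        b = "C" * 10 + "G" * 10  # distance 20 from a
        counts = {a: 50, b: 40}
        for root in (a, b):
            for pos in range(0, 6, 2):
                other = "T"
                derived = root[:pos] + other + root[pos + 1:]
                counts[derived] = 2
        res = message_passing_cluster(_counts(counts), self._cfg(3))
        assert res.n_clusters == 2
        assert {c.centroid for c in res.clusters} == {a, b}

    def test_zero_radius_identity(self):
        counts = _counts({"AAAA": 5, "AAAT": 4, "CCCC": 1})
        res = message_passing_cluster(counts, self._cfg(0))
        assert res.n_clusters == 3 and not res.discarded

    def test_counts_chain_transitively_to_root(self):
        # AATT (1) -> AAAT (3) -> AAAA (10): transfers chain to the root
        res = message_passing_cluster(
            _counts({"AAAA": 10, "AAAT": 3, "AATT": 1}), self._cfg(1))
        assert res.n_clusters == 1
        assert res.clusters[0].total_count == 14

    def test_residual_tie_discarded_with_descendants(self):
        # G and T sit at distance 1 from both equal-count roots
        res = message_passing_cluster(
            _counts({"AAAC": 5, "AAAG": 5, "AAAT": 1}), self._cfg(1))
        assert sorted(c.centroid for c in res.clusters) == ["AAAC", "AAAG"]
        assert [m.sequence for m in res.discarded] == ["AAAT"]

    def test_matches_component_oracle_on_well_separated_input(self, spec):
        """With halos narrower than half the root separation, clusters are
        exactly the connected components of the capped-distance graph."""
        rng = np.random.default_rng(13)
        roots = generate_unique_barcodes(30, spec, rng)
        counts = {r: 50 for r in roots}
        for r in roots:
            for _ in range(4):
                pos = int(rng.integers(0, 20))
                derived = r[:pos] + "ACGT"[int(rng.integers(0, 4))] + r[pos + 1:]
                if derived not in counts:
                    counts[derived] = int(rng.integers(1, 5))
        res = message_passing_cluster(_counts(counts), self._cfg(2))
        # oracle: union-find over all pairs within distance 2
        seqs = sorted(counts)
        parent = {s: s for s in seqs}

        def find(s):
            while parent[s] != s:
                parent[s] = parent[parent[s]]
                s = parent[s]
            return s

        for a, b in itertools.combinations(seqs, 2):
            if oracle_levenshtein(a, b) <= 2:
                parent[find(a)] = find(b)
        comps = {}
        for s in seqs:
            comps.setdefault(find(s), []).append(s)
        expected = {max(ms, key=lambda s: counts[s]):
                    sorted(ms) for ms in comps.values()}
        got = {c.centroid: sorted(m.sequence for m in c.members)
               for c in res.clusters}
        assert not res.discarded
        assert got == expected


class TestInvariantsBothAlgorithms:
    @pytest.mark.parametrize("algorithm", ["sphere", "message_passing"])
    def test_count_conservation_random_inputs(self, algorithm, rng):
        for _ in range(60):
            seqs = {}
            for _ in range(int(rng.integers(2, 15))):
                s = "".join(rng.choice(list("ACGT"),
                                       size=int(rng.integers(3, 7))))
                seqs[s] = int(rng.integers(1, 30))
            counts = _counts(seqs)
            for d in (0, 1, 2, 3):
                res = cluster(counts, ClusteringConfig(algorithm=algorithm,
                                                       max_dist=d))
                assert _total(res) == sum(seqs.values())
                member_seqs = [m.sequence for c in res.clusters
                               for m in c.members]
                disc = [m.sequence for m in res.discarded]
                assert sorted(member_seqs + disc) == sorted(seqs)
                for c in res.clusters:
                    assert c.centroid in {m.sequence for m in c.members}

    @pytest.mark.parametrize("algorithm", ["sphere", "message_passing"])
    def test_cluster_count_monotone_in_radius(self, algorithm, rng):
        for _ in range(20):
            seqs = {}
            for _ in range(12):
                s = "".join(rng.choice(list("ACG"),
                                       size=int(rng.integers(4, 6))))
                seqs[s] = int(rng.integers(1, 20))
            counts = _counts(seqs)
            sizes = [cluster(counts, ClusteringConfig(algorithm=algorithm,
                                                      max_dist=d)).n_clusters
                     for d in range(0, 5)]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_order_independence(self, rng):
        seqs = {"".join(rng.choice(list("ACGT"), size=5)): int(c)
                for c in rng.integers(1, 20, size=10)}
        counts = _counts(seqs)
        shuffled = list(counts)[::-1]
        for algorithm in ("sphere", "message_passing"):
            cfg = ClusteringConfig(algorithm=algorithm, max_dist=2)
            a = cluster(counts, cfg)
            b = cluster(shuffled, cfg)
            assert a.assignment() == b.assignment()


class TestValidateClustering:
    def test_halo_only_clustering_preserves_purity(self, spec):
        rng = np.random.default_rng(17)
        roots = generate_unique_barcodes(20, spec, rng)
        pairs = []
        for i, r in enumerate(roots):
            rng_i = make_range(i * 10, i * 10 + 50)
            pairs += [(r, rng_i)] * 10
            err = r[:3] + ("A" if r[3] != "A" else "C") + r[4:]
            pairs.append((err, rng_i))  # halo read, same fragment
        counts_in = {}
        for bc, _ in pairs:
            counts_in[bc] = counts_in.get(bc, 0) + 1
        res = cluster(_counts(counts_in),
                      ClusteringConfig(algorithm="message_passing", max_dist=2))
        table, summary = validate_clustering(res, pairs)
        assert summary["mean"] == 1.0
        assert len(table) == 20

    def test_false_merge_drops_purity_to_weighted_share(self):
        # two real barcodes forced into one cluster: purity = max share
        pairs = [("AAAAC", make_range(0, 50))] * 6 + \
                [("AAAAG", make_range(300, 350))] * 4
        res = cluster(_counts({"AAAAC": 6, "AAAAG": 4}),
                      ClusteringConfig(algorithm="sphere", max_dist=1))
        assert res.n_clusters == 1
        _, summary = validate_clustering(res, pairs)
        assert summary["mean"] == pytest.approx(0.6)

    def test_zero_radius_identity_readout(self):
        pairs = [("AAAAA", make_range(0, 50))] * 3 + \
                [("CCCCC", make_range(100, 150))] * 2
        res = cluster(_counts({"AAAAA": 3, "CCCCC": 2}),
                      ClusteringConfig(algorithm="sphere", max_dist=0))
        table, summary = validate_clustering(res, pairs)
        assert summary["mean"] == 1.0 and len(table) == 2
        assert not res.discarded


class TestSubsampleReads:
    def _pairs(self, n):
        return [(f"BC{i % 7}", make_range(0, 50, read_id=str(i)))
                for i in range(n)]

    def test_fraction_one_identity(self):
        pairs = self._pairs(100)
        assert subsample_reads(pairs, 1.0, seed=1) == pairs

    def test_kept_count_within_binomial_interval(self):
        from scipy import stats
        n = 10_000
        kept = len(subsample_reads(self._pairs(n), 0.5, seed=2))
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= kept <= hi

    def test_same_seed_same_subset(self):
        pairs = self._pairs(500)
        assert subsample_reads(pairs, 0.3, seed=7) == \
            subsample_reads(pairs, 0.3, seed=7)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            subsample_reads(self._pairs(5), 0.0)


class TestLibraryOverlap:
    def _table(self, items):
        groups = group_by_barcode(
            [(bc, make_range(s, s + 50)) for bc, s, c in items
             for _ in range(c)])
        _, multis = split_singlets(groups)
        return build_lookup_table([consensus_and_purity(g) for g in multis])

    def test_disjoint_tables(self):
        a = self._table([("A" * 20, 0, 3)])
        b = self._table([("C" * 20, 0, 3)])
        assert library_overlap(a, b) == (0, pytest.approx(float("nan"), nan_ok=True))

    def test_identical_tables_full_overlap_correlation_one(self):
        items = [("A" * 20, 0, 3), ("C" * 20, 10, 5), ("G" * 20, 20, 8),
                 ("T" * 20, 30, 2)]
        a, b = self._table(items), self._table(items)
        shared, corr = library_overlap(a, b)
        assert shared == 4
        assert corr == pytest.approx(1.0)

    def test_independent_simulated_libraries_nearly_disjoint(self, spec):
        a = self._table([(bc, 0, 2) for bc in generate_unique_barcodes(
            20_000, spec, np.random.default_rng(100))])
        b = self._table([(bc, 0, 2) for bc in generate_unique_barcodes(
            20_000, spec, np.random.default_rng(200))])
        shared, _ = library_overlap(a, b)
        assert shared <= 5
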