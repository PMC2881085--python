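"""Neighbor search: exact agreement with brute force, symmetry, counters."""

import numpy as np
import pytest

from decoyclust import (
    CaseCounters,
    build_groups,
    find_neighbors,
    make_ensemble,
    precompute_metrics,
    rmsd_matrix,
    within_threshold,
)


def neighbor_sets_equal(a, b):
    return len(a) == len(b) and all(
        x.owner == y.owner and np.array_equal(x.members, y.members) for x, y in zip(a, b)
    )


def brute_sets(D, d):
    return [np.nonzero(D[i] <= d)[0] for i in range(D.shape[0])]


class TestWithinThreshold:
    def test_self_is_neighbor(self, small_ensemble):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        assert within_threshold(m, decoys.coords, 4, 4, 0.0)

    def test_zero_threshold_distinct_decoys(self, small_ensemble, small_matrix):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        x, y = 0, 50  # different planted clusters, surely distinct
        assert small_matrix[x, y] > 0
        assert not within_threshold(m, decoys.coords, x, y, 0.0)

    def test_agrees_with_exact_comparison(self, small_ensemble, small_matrix, rng):
        decoys, _ = small_ensemble
        m = precompute_metrics(decoys)
        counters = CaseCounters()
        for _ in range(500):
            x, y = rng.integers(0, len(decoys), size=2)
            d = float(rng.uniform(0, 12))
            got = within_threshold(m, decoys.coords, int(x), int(y), d, counters)
            assert got == (small_matrix[x, y] <= d)
        assert counters.total() == 500


@pytest.fixture(scope="module")
def sixty():
    decoys, _ = make_ensemble(
        n_clusters=3, members_per_cluster=18, n_outliers=6, n_residues=30,
        noise_sigma=0.6, separation=6.0, seed=11,
    )
    return decoys, rmsd_matrix(decoys.coords)


class TestFindNeighbors:
    def run(self, decoys, d, **kw):
        m = precompute_metrics(decoys)
        g = build_groups(decoys, r=0.5 * d, metrics=m)
        counters = CaseCounters()
        return find_neighbors(decoys, g, m, d, counters, **kw), counters

    def test_huge_threshold_everyone_neighbors(self, sixty):
        decoys, D = sixty
        d = D.max() + 1.0
        nsets, _ = self.run(decoys, d)
        for ns in nsets:
            assert ns.size == len(decoys)

    def test_tiny_threshold_only_self(self, sixty):
        decoys, D = sixty
        d = 0.9 * D[np.triu_indices(len(decoys), 1)].min()
        nsets, _ = self.run(decoys, d)
        for ns in nsets:
            assert np.array_equal(ns.members, [ns.owner])

    @pytest.mark.parametrize("percentile", [10, 50, 90])
    def test_matches_brute_force_oracle(self, sixty, percentile):
        decoys, D = sixty
        d = float(np.percentile(D[np.triu_indices(len(decoys), 1)], percentile))
        nsets, counters = self.run(decoys, d)
        expected = brute_sets(D, d)
        for ns, exp in zip(nsets, expected):
            assert np.array_equal(ns.members, exp)
        # symmetry across the collection
        member_sets = [set(ns.members.tolist()) for ns in nsets]
        for x in range(len(decoys)):
            for y in member_sets[x]:
                assert x in member_sets[y]
        # every ordered pair decision is accounted for exactly once
        assert counters.total() == len(decoys) ** 2

    @pytest.mark.parametrize("kw", [{"use_bounds": False}, {"use_groups": False},
                                    {"use_bounds": False, "use_groups": False}])
    def test_ablations_stay_exact(self, sixty, kw):
        decoys, D = sixty
        d = float(np.percentile(D[np.triu_indices(len(decoys), 1)], 15))
        nsets, counters = self.run(decoys, d, **kw)
        for ns, exp in zip(nsets, brute_sets(D, d)):
            assert np.array_equal(ns.members, exp)
        assert counters.total() == len(decoys) ** 2

    def test_count_only_matches_member_lists(self, sixty):
        decoys, D = sixty
        d = float(np.percentile(D[np.triu_indices(len(decoys), 1)], 25))
        nsets, _ = self.run(decoys, d)
        counts, _ = self.run(decoys, d, count_only=True)
        assert np.array_equal(counts, [ns.size for ns in nsets])

    def test_case_soundness_audit(self, sixty):
        """Wholesale admissions/rejections agree with the exact RMSD."""
        decoys, D = sixty
        d = float(np.percentile(D[np.triu_indices(len(decoys), 1)], 30))
        nsets, _ = self.run(decoys, d)
        for ns in nsets:
            inside = np.zeros(len(decoys), bool)
            inside[ns.members] = True
            assert np.array_equal(inside, D[ns.owner] <= d)

    def test_counters_table_format(self, sixty):
        decoys, D = sixty
        _, counters = self.run(decoys, 2.0)
        table = counters.as_table()
        assert table.splitlines()[0] == "case\tcount\tpercent"
        assert len(table.splitlines()) == 11
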