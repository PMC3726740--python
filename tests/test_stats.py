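import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats

from geoaxes.geodata import CountTable, DissimilarityMatrix, GeodataError
from geoaxes.layout import CompiledTree, minimum_crossings
from geoaxes.stats import (
    bray_curtis,
    cophenetic_distances,
    linear_regression,
    mantel,
    null_critical_value,
    permutation_test,
    upgma,
)
from geoaxes.sweep import project_and_order
from geoaxes.synth import make_null_dataset

from conftest import ordering_from_ids


def exact_null(tree, ordering):
    """Exact crossing distribution over all assignments of the observed
    site-position multiset to the leaves (enumeration oracle)."""
    compiled = CompiledTree(tree)
    base = compiled.positions_for(ordering)
    return [
        minimum_crossings(compiled, list(perm))
        for perm in itertools.permutations(base)
    ]


class TestPermutationTest:
    def test_star_tree_p_is_one(self):
        tree, locs = make_null_dataset(5, 6, topology="star", seed=1)
        res = permutation_test(tree, project_and_order(locs, 90.0),
                               n_permutations=200, seed=0)
        assert res.observed_crossings == 0
        assert set(res.null_crossings) == {0}
        assert res.p_value == 1.0

    def test_p_equals_proportion_rule(self):
        tree, locs = make_null_dataset(6, 8, seed=2)
        res = permutation_test(tree, project_and_order(locs, 90.0),
                               n_permutations=300, seed=7)
        b = sum(1 for v in res.null_crossings
                if v <= res.observed_crossings)
        assert res.p_value == b / 300
        assert len(res.null_crossings) == 300

    def test_observed_at_maximum_gives_p_one(self):
        # choose the site ordering realizing the worst attainable
        # crossing number, so every permutation scores <= observed
        from conftest import tree_on_sites

        tree = tree_on_sites("((A,B),(C,D));")
        compiled = CompiledTree(tree)
        worst_order = max(
            itertools.permutations("ABCD"),
            key=lambda ids: minimum_crossings(
                compiled, compiled.positions_for(ordering_from_ids(ids))),
        )
        ordering = ordering_from_ids(worst_order)
        res = permutation_test(tree, ordering, n_permutations=500, seed=1)
        assert res.observed_crossings == max(res.null_crossings)
        assert res.p_value == 1.0

    def test_seed_fixes_null_distribution(self):
        tree, locs = make_null_dataset(6, 8, seed=4)
        ordering = project_and_order(locs, 90.0)
        a = permutation_test(tree, ordering, n_permutations=100, seed=11)
        b = permutation_test(tree, ordering, n_permutations=100, seed=11)
        c = permutation_test(tree, ordering, n_permutations=100, seed=12)
        assert a.null_crossings == b.null_crossings
        assert a.null_crossings != c.null_crossings

    def test_conservative_variant(self):
        tree, locs = make_null_dataset(5, 6, topology="star", seed=1)
        res = permutation_test(tree, project_and_order(locs, 90.0),
                               n_permutations=99, seed=0,
                               conservative=True)
        assert res.p_value == pytest.approx(1.0)

    def test_sampled_p_matches_exact_enumeration(self):
        tree, ordering = _small_instance()
        exact = exact_null(tree, ordering)
        compiled = CompiledTree(tree)
        observed = minimum_crossings(compiled,
                                     compiled.positions_for(ordering))
        p_exact = sum(1 for v in exact if v <= observed) / len(exact)
        res = permutation_test(tree, ordering, n_permutations=10_000,
                               seed=5)
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-12


def _small_instance():
    """4-leaf binary tree over 4 distinct sites (enumeration-friendly)."""
    from conftest import tree_on_sites

    tree = tree_on_sites("((A,B),(C,D));")
    return tree, ordering_from_ids(["B", "D", "A", "C"])


class TestNullCriticalValue:
    def test_star_tree_critical_value_zero(self):
        tree, locs = make_null_dataset(5, 6, topology="star", seed=1)
        assert null_critical_value(tree, locs, alpha=0.001,
                                   n_permutations=500, seed=0) == 0

    def test_high_alpha_reaches_top_of_distribution(self):
        tree, locs = make_null_dataset(6, 8, seed=2)
        crit = null_critical_value(tree, locs, alpha=0.999,
                                   n_permutations=500, seed=0)
        null = sorted(_null_for(tree, locs, 500, 0))
        assert crit == null[-1]

    def test_matches_exact_quantile_of_enumerated_null(self):
        from conftest import line_locations
        from geoaxes.geodata import georeference, read_newick

        tree = read_newick("((A,B),(C,D));")
        locs = line_locations(["B", "D", "A", "C"])
        tree = georeference(tree, locs)
        ordering = project_and_order(locs, 90.0)
        exact = sorted(exact_null(tree, ordering))
        m = len(exact)
        for alpha in (0.05, 0.3, 0.6):
            expected = exact[min(int(alpha * m), m - 1)]
            got = null_critical_value(tree, locs, alpha=alpha,
                                      n_permutations=20_000, seed=3)
            assert got == expected

    def test_tie_groups_emit_warning(self):
        tree, locs = make_null_dataset(4, 6, seed=9,
                                       degeneracies=("duplicate",))
        with pytest.warns(UserWarning, match="tie groups"):
            null_critical_value(tree, locs, alpha=0.1,
                                n_permutations=50, seed=0)

    def test_alpha_bounds(self):
        tree, locs = make_null_dataset(4, 5, seed=0)
        with pytest.raises(ValueError):
            null_critical_value(tree, locs, alpha=0.0, n_permutations=10)


def _null_for(tree, locs, n, seed):
    from geoaxes.stats import null_crossing_distribution

    return null_crossing_distribution(tree, locs, n, seed)


def random_dissimilarity(rng, n, ids=None):
    pts = rng.uniform(0, 1, size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DissimilarityMatrix(ids or [f"s{i}" for i in range(n)], d)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        A = random_dissimilarity(rng, 6)
        res = mantel(A, A, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        A = random_dissimilarity(rng, 6)
        B = DissimilarityMatrix(A.ids, 2.5 * A.values)
        assert mantel(A, B, n_permutations=99,
                      seed=0).r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        A = DissimilarityMatrix(["a", "b", "c"],
                                np.array([[0, 1, 1], [1, 0, 1],
                                          [1, 1, 0]], float))
        B = random_dissimilarity(np.random.default_rng(0), 3,
                                 ids=["a", "b", "c"])
        with pytest.raises(GeodataError, match="constant"):
            mantel(A, B, 99, 0)

    def test_mismatched_ids_rejected(self, rng):
        A = random_dissimilarity(rng, 4, ids=list("abcd"))
        B = random_dissimilarity(rng, 4, ids=list("abce"))
        with pytest.raises(GeodataError):
            mantel(A, B, 99, 0)

    def test_sampled_p_matches_exact_enumeration_n4(self, rng):
        A = random_dissimilarity(rng, 4)
        B = random_dissimilarity(rng, 4)
        iu = np.triu_indices(4, k=1)
        a = A.values[iu]
        r_obs = np.corrcoef(a, B.values[iu])[0, 1]
        rs = []
        for perm in itertools.permutations(range(4)):
            idx = np.array(perm)
            rs.append(np.corrcoef(a, B.values[np.ix_(idx, idx)][iu])[0, 1])
        p_exact = np.mean([r >= r_obs - 1e-12 for r in rs])
        res = mantel(A, B, n_permutations=10_000, seed=1)
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_value - p_exact) <= 3 * se + 1e-12

    def test_agrees_with_skbio_statistic(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        for _ in range(5):
            A = random_dissimilarity(rng, 7)
            B = random_dissimilarity(rng, 7)
            r_skbio, _, _ = skbio_stats.mantel(
                skbio_stats.DistanceMatrix(A.values, A.ids),
                skbio_stats.DistanceMatrix(B.values, B.ids),
                method="pearson", permutations=0,
            )
            assert mantel(A, B, 9, 0).r == pytest.approx(float(r_skbio))

    def test_two_sided_alternative(self, rng):
        # perfectly anti-correlated matrices: one-sided p is large,
        # two-sided p picks up the negative association
        A = random_dissimilarity(rng, 5)
        B = DissimilarityMatrix(
            A.ids, (A.values.max() + 0.1) * (A.values > 0) - A.values
        )
        one = mantel(A, B, 999, 0, alternative="greater")
        two = mantel(A, B, 999, 0, alternative="two-sided")
        assert one.r < 0
        assert two.p_value <= one.p_value


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_regression(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_textbook_five_points(self):
        # hand-computed normal equations for (1,2),(2,3),(3,5),(4,4),(5,6)
        x = [1, 2, 3, 4, 5]
        y = [2, 3, 5, 4, 6]
        # Sxy = 9, Sxx = 10 -> slope 0.9, intercept 4 - 0.9*3 = 1.3
        res = linear_regression(x, y)
        assert res.slope == pytest.approx(0.9)
        assert res.intercept == pytest.approx(1.3)
        # r^2 = Sxy^2/(Sxx*Syy) = 81/(10*10.0) = 0.81
        assert res.r_squared == pytest.approx(0.81)
        assert res.n == 5

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            pvals.append(linear_regression(x, y).p_value)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CountTable(pd.DataFrame([[3, 1], [3, 1]], index=["a", "b"],
                                    columns=["t1", "t2"]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_taxa_one(self):
        t = CountTable(pd.DataFrame([[3, 0], [0, 7]], index=["a", "b"],
                                    columns=["t1", "t2"]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t = CountTable(pd.DataFrame([[2, 2], [4, 0]], index=["u", "v"],
                                    columns=["t1", "t2"]))
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.5)

    def test_all_zero_row_rejected(self):
        t = CountTable(pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"],
                                    columns=["t1", "t2"]))
        with pytest.raises(GeodataError, match="a"):
            bray_curtis(t)

    def test_values_in_unit_interval(self, rng):
        from geoaxes.synth import make_count_table_data

        counts = make_count_table_data(8, 15, seed=int(rng.integers(1000)))
        t = CountTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(8)],
            columns=[f"t{j}" for j in range(15)]))
        D = bray_curtis(t)
        assert np.all(D.values >= 0) and np.all(D.values <= 1)


class TestUpgma:
    def test_three_taxon_worked_example(self):
        D = DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = upgma(D)
        coph = cophenetic_distances(tree).to_frame()
        assert coph.loc["A", "B"] == pytest.approx(2.0)  # joined at height 1
        assert coph.loc["A", "C"] == pytest.approx(4.0)  # joined at height 2
        assert coph.loc["B", "C"] == pytest.approx(4.0)
        # root at height 2, first join at height 1
        root = tree.root
        assert sorted(c.length for c in root.children) == \
            pytest.approx([1.0, 2.0])

    def test_two_taxa_join_at_half_distance(self):
        D = DissimilarityMatrix(["x", "y"],
                                np.array([[0, 3.0], [3.0, 0]]))
        tree = upgma(D)
        assert cophenetic_distances(tree).values[0, 1] == pytest.approx(3.0)
        assert all(c.length == pytest.approx(1.5)
                   for c in tree.root.children)

    def test_ultrametric_input_reproduced_exactly(self, rng):
        base = random_dissimilarity(rng, 6)
        ultra = cophenetic_distances(upgma(base))
        again = cophenetic_distances(upgma(ultra))
        order = np.argsort(ultra.ids)
        np.testing.assert_allclose(
            again.to_frame().loc[ultra.ids, ultra.ids].to_numpy(),
            ultra.values, atol=1e-12)

    def test_output_is_ultrametric(self, rng):
        for _ in range(10):
            D = random_dissimilarity(rng, 7)
            coph = cophenetic_distances(upgma(D))
            v = coph.values
            n = len(coph.ids)
            for i, j, k in itertools.combinations(range(n), 3):
                assert v[i, j] <= max(v[i, k], v[j, k]) + 1e-9

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.spatial.distance import squareform

        for _ in range(10):
            D = random_dissimilarity(rng, 8)
            Z = sch.linkage(squareform(D.values), method="average")
            coph_scipy = squareform(sch.cophenet(Z))
            mine = cophenetic_distances(upgma(D))
            frame = mine.to_frame().loc[D.ids, D.ids].to_numpy()
            np.testing.assert_allclose(frame, coph_scipy, atol=1e-9)

    def test_deterministic_under_ties(self):
        # fully tied distances: merge order fixed by lexicographic labels
        ids = ["d", "b", "a", "c"]
        vals = np.ones((4, 4)) - np.eye(4)
        t1 = upgma(DissimilarityMatrix(ids, vals))
        t2 = upgma(DissimilarityMatrix(ids, vals))
        from geoaxes.geodata import write_newick

        assert write_newick(t1) == write_newick(t2)
        # first merge is the lexicographically smallest pair (a, b)
        labels = {c.label for c in _first_merge(t1)}
        assert labels == {"a", "b"}


def _first_merge(tree):
    # the internal node whose children are both leaves and heights lowest
    best = None
    for node in tree.nodes:
        if not node.is_leaf and all(c.is_leaf for c in node.children):
            best = node
    return best.children
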