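import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import silhouette_samples as sk_silhouette

from dysbionet import (
    AbundanceProfile,
    DistanceMatrix,
    bonferroni,
    bray_curtis,
    choose_k,
    distance_matrix,
    one_way_anova,
    pam_cluster,
    permanova,
    silhouette_samples,
    simper,
    sqrt_transform,
    t_test,
)
from conftest import random_profile


# ---------------------------------------------------------------------------
# Independent brute-force PERMANOVA oracle
# ---------------------------------------------------------------------------

def brute_force_permanova(d: np.ndarray, labels: list) -> tuple[float, float]:
    """Plain-loop pseudo-F and exact enumeration p over all assignments."""

    def pseudo_F(lab):
        n = len(lab)
        groups = sorted(set(lab), key=str)
        sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in groups:
            idx = [i for i, l in enumerate(lab) if l == g]
            ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        a = len(groups)
        ssb = sst - ssw
        return (ssb / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf

    F_obs = pseudo_F(labels)
    n = len(labels)
    hits = count = 0
    for perm in set(itertools.permutations(labels)):
        count += 1
        if pseudo_F(list(perm)) >= F_obs - 1e-12:
            hits += 1
    return F_obs, hits / count


def _random_distance(n, seed):
    p = random_profile(n, 10, seed=seed)
    return distance_matrix(p)


class TestPermanova:
    def test_pure_between_group_variance(self):
        # two duplicated points per group: zero within, positive between
        x = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        d = DistanceMatrix(list("abcd"), np.array(
            [[bray_curtis(u, v) if not np.array_equal(u, v) else 0.0 for v in x] for u in x]))
        res = permanova(d, ["g1", "g1", "g2", "g2"], exhaustive=True)
        assert res.r2 == pytest.approx(1.0)
        assert np.isinf(res.pseudo_F)

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_matches_brute_force(self, seed):
        d = _random_distance(6, seed)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, labels, exhaustive=True)
        F_ref, p_ref = brute_force_permanova(d.d, labels)
        assert res.pseudo_F == pytest.approx(F_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.n_perm == 20  # C(6,3) labeled assignments

    def test_sampled_close_to_exhaustive(self):
        d = _random_distance(6, seed=42)
        labels = ["a"] * 3 + ["b"] * 3
        exact = permanova(d, labels, exhaustive=True)
        sampled = permanova(d, labels, n_perm=10_000, seed=7)
        assert abs(sampled.p - exact.p) <= 0.02

    def test_matches_reference_implementation(self, small_distance):
        skbio = pytest.importorskip("skbio")
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(small_distance, labels, n_perm=999, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(small_distance.d, small_distance.ids),
            grouping=labels, permutations=999)
        assert res.pseudo_F == pytest.approx(ref["test statistic"])
        assert abs(res.p - ref["p-value"]) < 0.06

    def test_errors(self, small_distance):
        with pytest.raises(ValueError, match="2 samples"):
            permanova(small_distance, ["a"] + ["b"] * 11)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(small_distance, ["a"] * 12)
        zero = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            permanova(zero, ["a", "a", "b", "b"])


class TestSimper:
    def test_single_otu_contributes_everything(self):
        from dysbionet import Scale

        p = AbundanceProfile(["s1", "s2"], ["only"], np.array([[1.0], [0.5]]), Scale.SQRT)
        res = simper(p, ["A", "B"], transform="none")
        assert res.table.percent.iloc[0] == pytest.approx(100.0)
        assert res.overall_dissimilarity == pytest.approx(0.5 / 1.5)

    def test_hand_computed_two_otus(self):
        p = AbundanceProfile(["s1", "s2"], ["o1", "o2"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        res = simper(p, ["A", "B"], transform="none")
        assert res.overall_dissimilarity == pytest.approx(1.0)
        assert sorted(res.table.percent) == pytest.approx([50.0, 50.0])

    @given(st.integers(0, 200))
    @settings(max_examples=25, deadline=None)
    def test_conservation_identity(self, seed):
        """Sum of contributions equals mean between-group Bray-Curtis on the
        transformed data; percents sum to 100."""
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 5, size=2)
        p = random_profile(int(n_a + n_b), int(rng.integers(2, 10)), seed=seed)
        labels = ["A"] * n_a + ["B"] * n_b
        res = simper(p, labels, transform="sqrt")
        Y = sqrt_transform(p).values
        ref = np.mean([bray_curtis(Y[i], Y[j])
                       for i in range(n_a) for j in range(n_a, n_a + n_b)])
        assert abs(res.table.contribution.sum() - ref) < 1e-10
        assert res.table.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_rejects_more_than_two_groups(self, small_profile):
        with pytest.raises(ValueError, match="two groups"):
            simper(small_profile, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)


class TestPam:
    def _two_blob_distance(self):
        # 2 blocks of duplicated points, far apart
        x = np.array([[1.0, 0, 0]] * 4 + [[0, 0, 1.0]] * 4)
        x = x + 1e-6
        x /= x.sum(1, keepdims=True)
        return distance_matrix(AbundanceProfile(
            [f"s{i}" for i in range(8)], list("abc"), x))

    def test_separated_blobs(self):
        d = self._two_blob_distance()
        res = pam_cluster(d, 2)
        assert res.avg_silhouette > 0.99
        assert len(set(res.labels[:4])) == 1 and len(set(res.labels[4:])) == 1
        assert res.labels[0] != res.labels[4]
        # medoids are members of their own clusters
        for m in res.medoids:
            i = d.ids.index(m)
            assert res.labels[i] == res.labels[i]

    def test_k_bounds_and_pigeonhole(self, small_distance):
        with pytest.raises(ValueError):
            pam_cluster(small_distance, 1)
        with pytest.raises(ValueError):
            pam_cluster(small_distance, small_distance.n)
        res = pam_cluster(small_distance, small_distance.n - 1)
        sizes = np.bincount(res.labels)
        assert (sizes >= 1).all() and (sizes == 2).sum() == 1  # one pair, rest singletons

    def test_deterministic(self, small_distance):
        a = pam_cluster(small_distance, 3, seed=1)
        b = pam_cluster(small_distance, 3, seed=99)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_silhouette_matches_sklearn(self, small_distance):
        res = pam_cluster(small_distance, 3)
        if len(set(res.labels)) > 1 and np.bincount(res.labels).min() > 1:
            ref = sk_silhouette(small_distance.d, res.labels, metric="precomputed")
            np.testing.assert_allclose(res.silhouettes, ref, atol=1e-12)


class TestChooseK:
    def test_three_planted_blobs(self):
        rng = np.random.default_rng(0)
        centers = np.eye(3) * 0.8 + 0.05
        x = np.vstack([np.abs(c + rng.normal(0, 0.02, (6, 3))) for c in centers])
        x /= x.sum(1, keepdims=True)
        d = distance_matrix(AbundanceProfile(
            [f"s{i}" for i in range(18)], list("abc"), x))
        sel = choose_k(d, range(2, 7))
        assert sel.k_best == 3
        assert set(sel.silhouettes) == {2, 3, 4, 5, 6}
        assert len(sel.table) == 5  # full silhouette-vs-k table preserved

    def test_degenerate_identical_points(self):
        x = np.full((6, 3), 1 / 3)
        d = distance_matrix(AbundanceProfile([f"s{i}" for i in range(6)], list("abc"), x))
        sel = choose_k(d, range(2, 5))
        assert sel.k_best == 2  # tie -> smallest k
        assert all(v == 0.0 for v in sel.silhouettes.values())

    def test_empty_range(self, small_distance):
        with pytest.raises(ValueError):
            choose_k(small_distance, range(2, 2))


class TestUnivariate:
    def test_identical_vectors(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        res0 = t_test([2.0, 2.0], [2.0, 2.0])
        assert (res0.statistic, res0.p) == (0.0, 1.0)

    def test_bonferroni(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0

    def test_log_transform_guard(self):
        with pytest.raises(ValueError, match="positive"):
            t_test([1.0, 2.0], [0.0, 3.0], transform="log10")

    def test_anova_identical_groups(self):
        res = one_way_anova([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.p == 1.0

    def test_anova_detects_separation(self):
        res = one_way_anova([[1.0, 1.1, 0.9], [5.0, 5.1, 4.9]])
        assert res.p < 0.001
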