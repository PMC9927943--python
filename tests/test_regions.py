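import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from dnmeth.regions import (
    RegionCountMatrix,
    adjust_covariates,
    bh_qvalues,
    call_dmrs,
    cluster_dmr_profiles,
    estimate_dispersion,
    nb_exact_test,
    normalize_log_cpm,
    sample_pca,
)
from dnmeth.synthetic import RegionSimConfig, simulate_region_counts

from conftest import tiny_matrix


def exact_test_oracle(counts_a, counts_b, phi):
    """Independent enumeration over all splits of the pooled total."""
    na, nb = len(counts_a), len(counts_b)
    S = int(sum(counts_a) + sum(counts_b))
    if S == 0:
        return 1.0
    mu = S / (na + nb)
    if phi == 0:
        pa = np.array([stats.poisson.pmf(x, na * mu) for x in range(S + 1)])
        pb = np.array([stats.poisson.pmf(S - x, nb * mu) for x in range(S + 1)])
    else:
        ra, rb = na / phi, nb / phi
        pa = np.array([stats.nbinom.pmf(x, ra, ra / (ra + na * mu)) for x in range(S + 1)])
        pb = np.array([stats.nbinom.pmf(S - x, rb, rb / (rb + nb * mu)) for x in range(S + 1)])
    joint = pa * pb
    obs = joint[int(sum(counts_a))]
    return float(joint[joint <= obs * (1 + 1e-12)].sum() / joint.sum())


class TestNormalizeLogCpm:
    def test_single_count(self):
        m = tiny_matrix([[1], [0]], ["a"])
        m.library_sizes = np.array([1e6])
        out = normalize_log_cpm(m, pseudocount=0.5)
        assert out[0, 0] == pytest.approx(np.log2(1.5))

    def test_zero_count_gives_log_pseudocount(self):
        m = tiny_matrix([[0], [3]], ["a"])
        m.library_sizes = np.array([1e6])
        out = normalize_log_cpm(m, pseudocount=0.5)
        assert out[0, 0] == pytest.approx(np.log2(0.5))

    def test_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=(50, 6))
        m = tiny_matrix(counts, ["a"] * 3 + ["b"] * 3)
        out = normalize_log_cpm(m, pseudocount=0.5)
        lib = counts.sum(axis=0)
        for i in range(50):
            for j in range(6):
                expected = np.log2(counts[i, j] / lib[j] * 1e6 + 0.5)
                assert abs(out[i, j] - expected) < 1e-12

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            tiny_matrix(np.zeros((3, 2), dtype=int), ["a", "b"]).library_sizes = None
            RegionCountMatrix(
                regions=pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]}),
                counts=np.array([[0, 0]]),
                design=pd.DataFrame({"group": ["a", "b"]}),
                library_sizes=np.array([0.0, 1.0]),
            )


class TestEstimateDispersion:
    def test_poisson_data_near_zero(self):
        cfg = RegionSimConfig(n_regions=5000, n_per_group=10, baseline_mean=50,
                              dispersion=0.0, group_labels=("a", "b"), seed=3)
        matrix, _ = simulate_region_counts(cfg)
        assert estimate_dispersion(matrix) <= 0.02

    def test_recovers_planted_dispersion(self):
        cfg = RegionSimConfig(n_regions=5000, n_per_group=10, baseline_mean=50,
                              dispersion=0.2, group_labels=("a", "b"), seed=4)
        matrix, _ = simulate_region_counts(cfg)
        assert 0.15 <= estimate_dispersion(matrix) <= 0.25

    def test_constant_counts_clip_to_zero(self):
        m = tiny_matrix(np.full((10, 4), 7), ["a", "a", "b", "b"])
        assert estimate_dispersion(m) == 0.0

    def test_single_sample_group_rejected(self):
        m = tiny_matrix(np.ones((5, 3), dtype=int), ["a", "a", "b"])
        with pytest.raises(ValueError):
            estimate_dispersion(m)


class TestNbExactTest:
    def test_balanced_split_is_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert nb_exact_test([5, 5], [5, 5], phi) == 1.0

    def test_matches_enumeration_oracle(self):
        p = nb_exact_test([5, 2, 1], [1, 0, 1], 0.1)
        assert p == pytest.approx(exact_test_oracle([5, 2, 1], [1, 0, 1], 0.1), abs=1e-10)

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            na, nb = rng.integers(2, 5, size=2)
            ca = rng.integers(0, 6, size=na)
            cb = rng.integers(0, 6, size=nb)
            for phi in (0.0, 0.05, 0.3):
                assert nb_exact_test(ca, cb, phi) == pytest.approx(
                    exact_test_oracle(ca, cb, phi), abs=1e-10)

    def test_poisson_limit_equals_conditional_binomial(self):
        ca, cb = [3, 4, 1], [0, 2, 1]
        S = sum(ca) + sum(cb)
        pm = stats.binom.pmf(np.arange(S + 1), S, 0.5)
        obs = pm[sum(ca)]
        expected = pm[pm <= obs * (1 + 1e-12)].sum()
        assert nb_exact_test(ca, cb, 0.0) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_imbalance(self):
        # fixed total 20, n=2 per group: p non-increasing as split grows lopsided
        prev = 1.1
        for split in range(10, 21):
            a, b = split, 20 - split
            p = nb_exact_test([a], [b], 0.1)
            assert p <= prev + 1e-12
            prev = p

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1, 2], [1, 1], 0.1)
        with pytest.raises(ValueError):
            nb_exact_test([1, 2], [1, 1], -0.1)


class TestAdjustCovariates:
    def test_constant_covariates_center(self):
        rng = np.random.default_rng(1)
        log_cpm = rng.normal(5, 1, size=(20, 8))
        design = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4, "age": [50.0] * 8})
        resid = adjust_covariates(log_cpm, design)
        expected = log_cpm - log_cpm.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(resid, expected, atol=1e-10)

    def test_planted_covariate_effect_removed(self):
        rng = np.random.default_rng(2)
        n = 40
        age = rng.normal(45, 8, n)
        log_cpm = rng.normal(5, 1, size=(30, n)) + 1.0 * age[np.newaxis, :]
        design = pd.DataFrame({"group": ["a"] * 20 + ["b"] * 20, "age": age})
        resid = adjust_covariates(log_cpm, design)
        for i in range(30):
            r = np.corrcoef(resid[i], age)[0, 1]
            assert abs(r) < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        log_cpm = rng.normal(size=(10, 12))
        design = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6,
                               "age": rng.normal(45, 5, 12)})
        once = adjust_covariates(log_cpm, design)
        twice = adjust_covariates(once, design)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        age = rng.normal(45, 5, 10)
        design = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                               "age": age, "age2": 2 * age})
        with pytest.raises(ValueError):
            adjust_covariates(rng.normal(size=(5, 10)), design)


class TestCallDmrs:
    def test_alpha_one_returns_everything(self, small_matrix):
        records = call_dmrs(small_matrix, alpha=1.0)
        assert all(r.significant for r in records)

    def test_alpha_out_of_range(self, small_matrix):
        with pytest.raises(ValueError):
            call_dmrs(small_matrix, alpha=0.0)
        with pytest.raises(ValueError):
            call_dmrs(small_matrix, alpha=1.5)

    def test_planted_recovery(self, planted_region_data):
        matrix, truth = planted_region_data
        records = call_dmrs(matrix, alpha=0.01)
        hits = sum(
            1 for _, row in truth.iterrows()
            if records[row["region"]].significant
            and records[row["region"]].direction == row["direction"]
        )
        assert hits / len(truth) >= 0.8

    def test_direction_consistent_with_fold(self, planted_region_data):
        matrix, _ = planted_region_data
        for r in call_dmrs(matrix, alpha=0.01):
            if r.direction == "hypo":
                assert min(r.log2_fold.values()) < 0
            elif r.direction == "hyper":
                assert max(r.log2_fold.values()) > 0

    def test_hyper_dmrs_get_shared_cluster(self, planted_region_data):
        matrix, truth = planted_region_data
        records = call_dmrs(matrix, alpha=0.01)
        n_cases = len(matrix.groups) - 1
        hyper = truth[truth["direction"] == "hyper"]
        labels = [records[i].cluster for i in hyper["region"]
                  if records[i].significant and records[i].direction == "hyper"]
        assert labels and all(lab == n_cases + 1 for lab in labels)


class TestBhQvalues:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        q = bh_qvalues(p)
        assert (q <= 1).all() and (q >= p).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(10)
        p = rng.random(100)
        np.testing.assert_allclose(bh_qvalues(p), sm.multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


class TestClusterProfiles:
    def test_identical_profiles_merge_first(self):
        profiles = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                             [3.0, 1.0, -1.0], [0.0, 5.0, 1.0]])
        labels, Z = cluster_dmr_profiles(profiles, k=2)
        # rows 0 and 1 are perfectly correlated: distance 0, merged first
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert labels[0] == labels[1]

    def test_anticorrelated_distance_two(self):
        from dnmeth.regions import correlation_distance_matrix

        d = correlation_distance_matrix(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        assert d[0] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_profile_warns(self):
        profiles = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]])
        with pytest.warns(UserWarning):
            labels, _ = cluster_dmr_profiles(profiles, k=2)
        assert len(labels) == 3

    def test_recovers_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        archetypes = np.array([
            [0.0, -2.0, -2.0, -2.0], [0.0, 0.0, -2.0, -2.0],
            [0.0, 0.0, 0.0, -2.0], [0.0, 2.0, 2.0, 2.0],
        ])
        truth, rows = [], []
        for k, arch in enumerate(archetypes):
            for _ in range(40):
                rows.append(arch + rng.normal(0, 0.15, size=4))
                truth.append(k)
        labels, _ = cluster_dmr_profiles(np.array(rows), k=4)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_labels_invariant_under_reordering(self):
        rng = np.random.default_rng(8)
        profiles = rng.normal(size=(30, 5))
        labels, _ = cluster_dmr_profiles(profiles, k=3)
        perm = rng.permutation(30)
        labels_perm, _ = cluster_dmr_profiles(profiles[perm], k=3)
        # same partition after inverting the permutation
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0


class TestSamplePca:
    def test_separates_planted_groups(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.5, size=(100, 10))
        b = rng.normal(4, 0.5, size=(100, 10))
        data = np.hstack([a, b])  # regions x samples
        scores, _, _ = sample_pca(data)
        pc1 = scores[:, 0]
        gap = abs(pc1[:10].mean() - pc1[10:].mean())
        within = max(pc1[:10].std(), pc1[10:].std())
        assert gap > 3 * within

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(50, 5))
        data = np.hstack([data, data[:, [0]]])
        scores, _, _ = sample_pca(data)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-8)

    def test_variance_conserved(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(40, 8))
        scores, _, _ = sample_pca(data, n_components=8)
        X = data.T
        Xc = X - X.mean(axis=0, keepdims=True)
        assert np.sum(scores**2) == pytest.approx(np.sum(Xc**2), abs=1e-8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sample_pca(np.zeros((10, 5)))
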