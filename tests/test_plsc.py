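import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractamorph import plsc, synthetic as syn
from fractamorph.exceptions import DegenerateModelError, ValidationError


def direct_singular_values(R):
    """Independent oracle: sqrt of the eigenvalues of R R' computed via
    an explicit Gram matrix, not via SVD."""
    q = R.shape[0]
    gram = np.empty((q, q))
    for i in range(q):
        for j in range(q):
            gram[i, j] = float(np.dot(R[i], R[j]))
    eig = np.linalg.eigvalsh(gram)
    return np.sqrt(np.clip(eig[::-1], 0.0, None))


class TestPreprocess:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, size=(12, 4))
        Y = rng.normal(-2, 0.5, size=(12, 3))
        Xz, Yz = plsc.preprocess(X, Y)
        for M in (Xz, Yz):
            assert np.allclose(M.mean(axis=0), 0.0, atol=1e-12)
            assert np.allclose(M.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        Xz, _ = plsc.preprocess(X, rng.standard_normal((30, 2)))
        assert np.allclose(Xz, X, atol=1e-12)

    def test_constant_column_named(self):
        X = np.ones((6, 3))
        X[:, 0] = np.arange(6)
        X[:, 2] = np.arange(6) * 2
        with pytest.raises(ValidationError, match="col_b"):
            plsc.preprocess(X, np.random.default_rng(0).normal(size=(6, 2)),
                            block_names=("col_a", "col_b", "col_c"))

    def test_missing_values_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValidationError):
            plsc.preprocess(X, np.random.default_rng(1).normal(size=(6, 2)))

    def test_too_few_subjects(self):
        with pytest.raises(ValidationError):
            plsc.preprocess(np.ones((2, 3)), np.ones((2, 2)))


class TestFitPlsc:
    def test_oracle_equivalence_hand_matrix(self):
        # Y = X: singular values of Xz'Xz equal eigenvalues of the Gram
        # matrix of the standardized columns
        X = np.array([[1.0, 2.0, 0.5, -1.0, 3.0],
                      [0.0, 1.0, 1.5, -2.0, 2.0],
                      [2.0, 0.0, -0.5, 1.0, 1.0],
                      [1.5, 1.0, 0.0, 0.0, -1.0],
                      [-1.0, 2.5, 2.0, 1.0, 0.0],
                      [0.5, -1.0, 1.0, 2.0, 1.5]])
        Xz, _ = plsc.preprocess(X, X)
        model = plsc.fit_plsc(Xz, Xz)
        eig = np.linalg.eigvalsh(Xz.T @ Xz)[::-1]
        assert np.allclose(model.singular_values, eig, atol=1e-10)
        # first component recovers the dominant principal direction
        _, vecs = np.linalg.eigh(Xz.T @ Xz)
        lead = vecs[:, -1]
        assert abs(np.dot(model.V[:, 0], lead)) == pytest.approx(1.0,
                                                                 abs=1e-10)

    def test_singular_values_match_direct_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            Xz, Yz = plsc.preprocess(rng.normal(size=(8, 4)),
                                     rng.normal(size=(8, 3)))
            model = plsc.fit_plsc(Xz, Yz)
            oracle = direct_singular_values(Yz.T @ Xz)
            assert np.allclose(model.singular_values, oracle, atol=1e-10)

    def test_cov_explained_closed_form(self):
        model = plsc.PLSCModel(
            U=np.eye(3), V=np.eye(3),
            singular_values=np.array([2.0, 1.0, 1.0]),
            cov_explained=np.array([4 / 6, 1 / 6, 1 / 6]))
        assert model.cov_explained.sum() == pytest.approx(1.0)
        # and the fitting path produces the same normalization
        rng = np.random.default_rng(2)
        Xz, Yz = plsc.preprocess(rng.normal(size=(10, 6)),
                                 rng.normal(size=(10, 3)))
        fitted = plsc.fit_plsc(Xz, Yz)
        s = fitted.singular_values
        assert np.allclose(fitted.cov_explained, s**2 / np.sum(s**2))
        assert fitted.cov_explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_cohort_recovery(self, planted_cohort):
        Xz, Yz = plsc.preprocess(planted_cohort.X, planted_cohort.Y)
        model = plsc.fit_plsc(Xz, Yz)
        assert abs(model.V[:, 0] @ planted_cohort.salience_img) > 0.9
        assert abs(model.U[:, 0] @ planted_cohort.salience_beh) > 0.9

    def test_unit_norm_and_ordering(self):
        rng = np.random.default_rng(3)
        Xz, Yz = plsc.preprocess(rng.normal(size=(15, 8)),
                                 rng.normal(size=(15, 4)))
        model = plsc.fit_plsc(Xz, Yz)
        assert np.allclose(np.linalg.norm(model.U, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(model.V, axis=0), 1.0)
        assert (np.diff(model.singular_values) <= 1e-12).all()

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        Xz, Yz = plsc.preprocess(rng.normal(size=(12, 5)),
                                 rng.normal(size=(12, 3)))
        model = plsc.fit_plsc(Xz, Yz)
        for comp in range(model.V.shape[1]):
            j = np.argmax(np.abs(model.V[:, comp]))
            assert model.V[j, comp] > 0

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(DegenerateModelError):
            plsc.fit_plsc(np.zeros((5, 3)), np.zeros((5, 2)))

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_feature_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        Xz, Yz = plsc.preprocess(rng.normal(size=(10, 6)),
                                 rng.normal(size=(10, 3)))
        perm = rng.permutation(6)
        base = plsc.fit_plsc(Xz, Yz)
        permuted = plsc.fit_plsc(Xz[:, perm], Yz)
        assert np.allclose(base.singular_values, permuted.singular_values,
                           atol=1e-10)
        assert np.allclose(np.abs(base.V[perm]), np.abs(permuted.V),
                           atol=1e-8)


class TestPermutationTest:
    def test_planted_signal_significant(self):
        cohort = syn.make_cohort(syn.CohortSpec(
            n_subjects=40, group_sizes=(20, 20), effect=3.0, noise_sd=1.0,
            seed=7))
        Xz, _ = plsc.preprocess(cohort.X, cohort.Y)
        p = plsc.permutation_test(Xz, cohort.Y, n_perm=500, seed=7)
        assert p[0] <= 0.01

    def test_add_one_estimator_bounds(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=0.0, seed=3))
        Xz, _ = plsc.preprocess(cohort.X, cohort.Y)
        p = plsc.permutation_test(Xz, cohort.Y, n_perm=100, seed=3)
        assert (p >= 1 / 101).all()
        assert (p <= 1.0).all()

    def test_deterministic_given_seed(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=1.0, seed=5))
        Xz, _ = plsc.preprocess(cohort.X, cohort.Y)
        a = plsc.permutation_test(Xz, cohort.Y, n_perm=200, seed=11)
        b = plsc.permutation_test(Xz, cohort.Y, n_perm=200, seed=11)
        assert np.array_equal(a, b)

    def test_small_n_perm_rejected(self):
        cohort = syn.make_cohort(syn.CohortSpec(seed=1))
        Xz, _ = plsc.preprocess(cohort.X, cohort.Y)
        with pytest.raises(ValidationError):
            plsc.permutation_test(Xz, cohort.Y, n_perm=50)

    def test_null_not_grossly_anticonservative(self):
        # cheap sanity check; the full calibration lives in the
        # acceptance suite
        rejections = 0
        for seed in range(50):
            cohort = syn.make_cohort(syn.CohortSpec(effect=0.0,
                                                    seed=9_000 + seed))
            Xz, _ = plsc.preprocess(cohort.X, cohort.Y)
            p = plsc.permutation_test(Xz, cohort.Y, n_perm=200, seed=seed)
            rejections += p[0] <= 0.05
        assert rejections / 50 <= 0.14


class TestBootstrapStability:
    def test_planted_vs_noise_features(self, support_saliences):
        sal_img, sal_beh = support_saliences
        cohort = syn.make_cohort(syn.CohortSpec(
            n_subjects=100, group_sizes=(50, 50), effect=3.0, noise_sd=1.0,
            salience_img=sal_img, salience_beh=sal_beh, seed=21))
        boot = plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=200,
                                        seed=21)
        stable = boot["stable_img"][:, 0]
        assert stable[:6].all()
        assert stable[6:].mean() <= 0.25

    def test_infinite_threshold_flags_nothing(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=2.0, seed=4))
        boot = plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=100,
                                        seed=4, threshold=np.inf)
        assert not boot["stable_img"].any()
        assert not boot["stable_beh"].any()

    def test_deterministic_given_seed(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=2.0, seed=6))
        a = plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=100, seed=9)
        b = plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=100, seed=9)
        assert np.array_equal(a["bsr_img"], b["bsr_img"])
        assert np.array_equal(a["stable_beh"], b["stable_beh"])

    def test_small_n_boot_rejected(self):
        cohort = syn.make_cohort(syn.CohortSpec(seed=2))
        with pytest.raises(ValidationError):
            plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=50)

    def test_stable_iff_bsr_exceeds_threshold(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=2.0, seed=8))
        boot = plsc.bootstrap_stability(cohort.X, cohort.Y, n_boot=150,
                                        seed=8, threshold=2.0)
        assert np.array_equal(boot["stable_img"],
                              np.abs(boot["bsr_img"]) >= 2.0)


class TestScoresAndLoadings:
    def test_projection_identity_on_orthonormal_columns(self):
        # orthonormal Xz columns + identity-like V reproduce the columns
        n = 8
        Q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(n, 3)))
        V = np.eye(3)
        model = plsc.PLSCModel(U=np.eye(3), V=V,
                               singular_values=np.ones(3),
                               cov_explained=np.full(3, 1 / 3))
        out = plsc.scores_and_loadings(model, Q, Q, Q, Q)
        assert np.allclose(out.scores_img, Q)

    def test_proportional_feature_loading_is_one(self):
        cohort = syn.make_cohort(syn.CohortSpec(effect=3.0, seed=5))
        Xz, Yz = plsc.preprocess(cohort.X, cohort.Y)
        model = plsc.fit_plsc(Xz, Yz)
        scores = Xz @ model.V
        X_aug = np.column_stack([cohort.X, 2.0 * scores[:, 0] + 1.0])
        out = plsc._column_correlations(X_aug, scores)
        assert out[-1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_scores_positively_correlated(self, planted_cohort):
        model = plsc.plsc_analysis(planted_cohort, n_perm=100, n_boot=100,
                                   seed=0)
        r = np.corrcoef(model.scores_img[:, 0], model.scores_beh[:, 0])[0, 1]
        assert r > 0.5


class TestPlscAnalysis:
    def test_full_analysis_fields_populated(self, planted_cohort):
        model = plsc.plsc_analysis(planted_cohort, n_perm=100, n_boot=100,
                                   seed=1)
        assert model.perm_p is not None and len(model.perm_p) == 5
        assert model.bsr_img.shape == (34, 5)
        assert model.loadings_beh.shape == (5, 5)
        assert model.scores_img.shape == (100, 5)
        assert model.cov_explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert model.perm_p[0] <= 0.01

    def test_to_dict_json_serializable(self, planted_cohort):
        import json

        model = plsc.plsc_analysis(planted_cohort, n_perm=100, n_boot=100,
                                   seed=1)
        json.dumps(model.to_dict())
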