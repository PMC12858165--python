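"""Ridge solver, cross-validation, shared penalty and fit orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import faceenc as fe
from faceenc.features import ResponseMatrix
from faceenc.model import Dataset, cv_curve, make_datasets
from faceenc.preproc import SubjectRecord
from faceenc.synthetic import region_channels
from conftest import SEED, make_channels


def ridge_oracle(X, y, alpha):
    """Independent solve of the regularized normal equations with an
    explicit, unpenalized intercept column."""
    n, p = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    penalty = np.eye(p + 1) * alpha
    penalty[p, p] = 0.0
    coef = np.linalg.solve(Xa.T @ Xa + penalty, Xa.T @ y)
    return coef[:p], coef[p]


class TestRidgeSolve:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1e-3, 1e4))
    def test_matches_normal_equation_oracle(self, seed, alpha):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 50), rng.integers(1, 20)
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        w, b = fe.ridge_solve(X, y, alpha)
        w0, b0 = ridge_oracle(X, y, alpha)
        scale = max(1.0, np.abs(w0).max())
        assert np.abs(w - w0).max() < 1e-8 * scale
        assert abs(b - b0) < 1e-8 * max(1.0, abs(b0))

    def test_infinite_penalty_limit(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30) + 5.0
        w, b = fe.ridge_solve(X, y, 1e12)
        assert np.linalg.norm(w) < 1e-6
        assert abs(b - y.mean()) < 1e-4

    def test_ols_limit_orthonormal(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((40, 5)))
        X = q  # orthonormal, zero-ish column means after centering below
        X = X - X.mean(axis=0)
        q2, _ = np.linalg.qr(X)
        X = q2
        y = rng.standard_normal(40)
        w, _ = fe.ridge_solve(X, y, 0.0)
        np.testing.assert_allclose(w, X.T @ (y - y.mean()), atol=1e-10)

    def test_monotone_shrinkage(self, rng):
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        norms = [np.linalg.norm(fe.ridge_solve(X, y, a)[0])
                 for a in [0.0, 1.0, 10.0, 100.0, 1e4]]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_non_finite_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fe.ridge_solve(X, y, 1.0)


class TestConcatenateContacts:
    def test_tiling_shapes(self, rng):
        X = rng.standard_normal((360, 10))
        Y = rng.standard_normal((360, 4))
        Xs, ys, ids = fe.concatenate_contacts(X, Y)
        assert Xs.shape == (1440, 10) and ys.shape == (1440,)
        np.testing.assert_array_equal(Xs[360:720], X)
        np.testing.assert_array_equal(ys[360:720], Y[:, 1])
        assert list(np.bincount(ids)) == [360] * 4

    def test_single_contact_identity(self, rng):
        X = rng.standard_normal((100, 5))
        Y = rng.standard_normal((100, 1))
        Xs, ys, _ = fe.concatenate_contacts(X, Y)
        assert Xs is X
        np.testing.assert_array_equal(ys, Y[:, 0])

    def test_identical_contacts_equal_single_fit(self, rng):
        X = rng.standard_normal((200, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(200)
        Xs, ys, _ = fe.concatenate_contacts(X, np.tile(y[:, None], (1, 3)))
        w_single, b_single = fe.ridge_solve(X, y, 5.0)
        w_stack, b_stack = fe.ridge_solve(Xs, ys, 3 * 5.0)
        # 3x the rows with 3x the penalty reproduces the single-contact fit
        np.testing.assert_allclose(w_stack, w_single, atol=1e-10)
        assert b_stack == pytest.approx(b_single)

    def test_average_mode(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 4))
        Xs, ys, _ = fe.concatenate_contacts(X, Y, mode="average")
        assert Xs is X
        np.testing.assert_allclose(ys, Y.mean(axis=1))


class TestFolds:
    def test_partition_contiguous_and_aligned(self):
        ids = np.repeat([0, 1], 100)
        folds = fe.contiguous_folds(ids, 5)
        all_rows = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_rows, np.arange(200))
        for k, fold in enumerate(folds):
            own = fold[fold < 100]
            assert np.array_equal(own, np.arange(own[0], own[-1] + 1))
            # aligned across contacts: same within-contact positions
            np.testing.assert_array_equal(fold[fold >= 100] - 100, own)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fe.contiguous_folds(np.zeros(3, dtype=int), 5)


class TestCrossval:
    def test_noiseless_signal_recovered(self, rng):
        X = rng.uniform(0, 1, (300, 12))
        y = X @ rng.standard_normal(12)
        fit = fe.crossval_fit(X, y, 1e-6)
        assert fit.mean_r > 0.99
        assert len(fit.fold_r) == 5
        assert fit.weights.shape == (5, 12)

    def test_null_mean_r_centered_on_zero(self, rng):
        """Over 100 independent noise responses, mean_r averages ~0."""
        X = rng.uniform(0, 1, (240, 10))
        folds = fe.contiguous_folds(np.zeros(240, dtype=int), 5)
        means = [fe.cv_mean_r_batch(X[None], rng.standard_normal(240),
                                    folds, 10.0)[0] for _ in range(100)]
        assert abs(np.mean(means)) < 0.05

    def test_fold_order_irrelevant(self, rng):
        X = rng.standard_normal((100, 4))
        y = rng.standard_normal(100)
        folds = fe.contiguous_folds(np.zeros(100, dtype=int), 5)
        a = fe.crossval_fit(X, y, 2.0, folds=folds)
        b = fe.crossval_fit(X, y, 2.0, folds=folds[::-1])
        assert a.mean_r == pytest.approx(b.mean_r)

    def test_degenerate_fold_reported_nan(self, rng, caplog):
        X = rng.standard_normal((100, 3))
        y = rng.standard_normal(100)
        y[:20] = 7.0  # first fold's held-out values constant
        fit = fe.crossval_fit(X, y, 1.0)
        assert np.isnan(fit.fold_r[0])
        assert np.isfinite(fit.mean_r)

    def test_batch_matches_loop(self, rng):
        X = rng.standard_normal((5, 150, 20))
        y = rng.standard_normal(150)
        folds = fe.contiguous_folds(np.zeros(150, dtype=int), 5)
        batch = fe.cv_mean_r_batch(X, y, folds, 7.0)
        loop = [fe.crossval_fit(X[i], y, 7.0, folds=folds).mean_r
                for i in range(5)]
        np.testing.assert_allclose(batch, loop, atol=1e-10)


class TestSharedAlpha:
    def _dataset(self, X, y, sid="s"):
        return Dataset(subject=SubjectRecord(sid, 30, "post_childhood"),
                       region="pSTC", condition="speech", X=X, y=y,
                       contact_ids=np.zeros(len(y), dtype=int),
                       n_contacts=1, column_labels=[])

    def test_single_dataset_argmax_of_own_curve(self, rng, config):
        X = rng.uniform(0, 1, (300, 20))
        y = X @ rng.standard_normal(20) + 3 * rng.standard_normal(300)
        ds = self._dataset(X, y)
        alpha, curve = fe.select_shared_alpha([ds], config.alpha_grid)
        folds = fe.contiguous_folds(ds.contact_ids, 5)
        own = cv_curve(X, y, config.alpha_grid, folds)
        assert alpha == config.alpha_grid[np.nanargmax(own)]
        np.testing.assert_allclose(curve, own, atol=1e-12)

    def test_compromise_between_opposed_datasets(self, rng, config):
        """Two datasets with opposite penalty preferences: the selected
        value maximizes the average curve (verified by brute force)."""
        grid = config.alpha_grid
        # low-noise dataset prefers small alpha; high-noise prefers large
        X1 = rng.uniform(0, 1, (200, 30))
        y1 = X1 @ rng.standard_normal(30) + 0.1 * rng.standard_normal(200)
        X2 = rng.uniform(0, 1, (200, 30))
        y2 = X2 @ (0.1 * rng.standard_normal(30)) + 3 * rng.standard_normal(200)
        d1, d2 = self._dataset(X1, y1, "a"), self._dataset(X2, y2, "b")
        alpha, mean_curve = fe.select_shared_alpha([d1, d2], grid)
        folds = fe.contiguous_folds(d1.contact_ids, 5)
        brute = (cv_curve(X1, y1, grid, folds)
                 + cv_curve(X2, y2, grid, folds)) / 2
        assert alpha == grid[np.nanargmax(brute)]
        np.testing.assert_allclose(mean_curve, brute, atol=1e-12)
        # and the compromise differs from at least one solo preference
        solo1 = grid[np.nanargmax(cv_curve(X1, y1, grid, folds))]
        solo2 = grid[np.nanargmax(cv_curve(X2, y2, grid, folds))]
        assert solo1 != solo2

    def test_deterministic(self, rng, config):
        X = rng.uniform(0, 1, (150, 10))
        y = rng.standard_normal(150)
        ds = self._dataset(X, y)
        a1, _ = fe.select_shared_alpha([ds], config.alpha_grid)
        a2, _ = fe.select_shared_alpha([ds], config.alpha_grid)
        assert a1 == a2

    def test_empty_rejected(self, config):
        with pytest.raises(ValueError):
            fe.select_shared_alpha([], config.alpha_grid)


class TestFitAll:
    def _bundle(self, rng, design, subject, regions):
        channels = pd.concat(
            [region_channels(r, 2, n_other=0) for r in regions],
            ignore_index=True)
        channels["name"] = [f"{subject.id}_{i}" for i in range(len(channels))]
        Y = rng.standard_normal((design.X.shape[0], len(channels)))
        return fe.SubjectBundle(subject=subject, response=ResponseMatrix(
            Y=Y, row_meta=design.row_meta.copy(), channels=channels))

    def test_fit_count_regions_times_conditions(self, rng, features, config):
        design = fe.build_design_matrix(features, config.lags)
        bundles = [
            self._bundle(rng, design,
                         SubjectRecord(f"s{i}", 20 + i, "post_childhood"),
                         ["DLPFC", "pSTC"])
            for i in range(2)]
        bundles.append(self._bundle(
            rng, design, SubjectRecord("s9", 8, "childhood"), ["pSTC"]))
        fits, alpha, datasets = fe.fit_all(design, bundles, config)
        assert len(fits) == 2 * 4 + 2
        assert alpha in config.alpha_grid
        assert all(f.alpha == alpha for f in fits)
        s9 = [(f.region, f.condition) for f in fits if f.subject_id == "s9"]
        assert sorted(s9) == [("pSTC", "music"), ("pSTC", "speech")]

    def test_min_contacts_enforced(self, rng, features, config):
        design = fe.build_design_matrix(features, config.lags)
        bundle = self._bundle(rng, design,
                              SubjectRecord("s1", 20, "post_childhood"),
                              ["pSTC"])
        strict = fe.PipelineConfig(min_contacts=4)
        datasets = make_datasets(design, bundle, strict)
        assert datasets == []

    def test_parameter_recovery_at_unit_snr(self, features, config):
        """With 720 stacked rows at 50% feature-driven variance, |w|
        estimates correlate > 0.8 with the ground truth across columns."""
        from faceenc.synthetic import GroundTruth, simulate_response, \
            _sparse_weights
        rng = np.random.default_rng(SEED)
        amps = {f: 0.25 for f in
                config.effective_complex_group + config.basic_group}
        W = _sparse_weights(rng, config.feature_names, amps, config.lags)
        truth = GroundTruth(weights={"speech": W, "music": W},
                            coupling_snr=1.0, ar_coef=0.3)
        Y, row_meta = simulate_response(features, truth, config.lags,
                                        n_contacts=2, seed=SEED)
        resp = ResponseMatrix(Y=Y, row_meta=row_meta,
                              channels=region_channels("pSTC", 2, 0))
        design = fe.build_design_matrix(features, config.lags)
        bundle = fe.SubjectBundle(
            subject=SubjectRecord("s1", 30, "post_childhood"), response=resp)
        fits, _, _ = fe.fit_all(design, [bundle], config)
        w_est = np.abs(np.vstack([f.weights for f in fits])).mean(axis=0)
        r = np.corrcoef(w_est, np.abs(W.reshape(-1)))[0, 1]
        assert r > 0.8
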