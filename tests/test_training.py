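"""Training protocol: split, standardization, balancing, selection, fits."""

import datetime as dt
import warnings

import numpy as np
import pytest

import preictal as p

T0 = dt.datetime(2021, 3, 1, 0, 0, 0)


def _fm(values, window_s=5.0, labels=None):
    values = np.asarray(values, dtype=float)
    return p.FeatureMatrix(
        values=values,
        feature_names=[f"f{i}" for i in range(values.shape[1])],
        window_start_s=np.arange(values.shape[0]) * window_s,
        window_s=window_s, start_time=T0, labels=labels,
    )


# -- chronological split -----------------------------------------------------

def test_split_five_seizures(rng):
    fm = _fm(rng.standard_normal((2000, 3)))
    onsets = np.array([1000.0, 3000.0, 5000.0, 7000.0, 9000.0])
    sp = p.chronological_split(fm, onsets)
    assert list(sp.train_onsets_s) == [1000.0, 3000.0, 5000.0]
    assert list(sp.test_onsets_s) == [7000.0, 9000.0]
    assert sp.train.window_start_s.max() < sp.split_time_s
    assert sp.test.window_start_s.min() >= sp.split_time_s
    assert sp.train.n_windows + sp.test.n_windows == fm.n_windows


def test_split_four_seizures_single_test(rng):
    fm = _fm(rng.standard_normal((2000, 3)))
    sp = p.chronological_split(fm, [1000.0, 3000.0, 5000.0, 7000.0])
    assert len(sp.test_onsets_s) == 1


def test_split_three_seizures_rejected(rng):
    fm = _fm(rng.standard_normal((100, 3)))
    with pytest.raises(ValueError, match="at least 4"):
        p.chronological_split(fm, [50.0, 150.0, 250.0])


# -- standardizer ------------------------------------------------------------

def test_standardizer_train_statistics(rng):
    X = rng.standard_normal((500, 4)) * 3.0 + 5.0
    std = p.Standardizer().fit(X)
    Z = std.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)


def test_standardizer_drops_constant_column(rng):
    X = rng.standard_normal((100, 3))
    X[:, 1] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        std = p.Standardizer().fit(X)
    assert list(std.kept_) == [0, 2]
    assert std.transform(X).shape == (100, 2)


def test_standardizer_test_uses_train_params(rng):
    train, test = rng.standard_normal((200, 2)), rng.standard_normal((50, 2)) + 10
    std = p.Standardizer().fit(train)
    Z = std.transform(test)
    assert Z.mean() > 5.0  # shifted test set stays shifted


# -- class weights -----------------------------------------------------------

def test_class_weights_inverse_frequency():
    y = np.array([1] * 360 + [0] * 3600)
    w = p.lr_class_weights(y)
    assert w[1] / w[0] == pytest.approx(10.0)


def test_class_weights_balanced_and_minimal():
    assert p.lr_class_weights([0, 1]) == {0: 1.0, 1: 1.0}
    w = p.lr_class_weights([0, 0, 1, 1])
    assert w[0] == w[1] == 1.0
    with pytest.raises(ValueError, match="both classes"):
        p.lr_class_weights([1, 1, 1])


# -- interictal subsampling --------------------------------------------------

def test_segment_subsample_covers_deciles():
    idx = np.arange(3600)
    sub = p.segment_subsample(idx, n_segments=10, per_segment=36, rng=0)
    assert len(sub) == 360
    for d in range(10):
        assert np.any((sub >= d * 360) & (sub < (d + 1) * 360))


def test_segment_subsample_deterministic():
    idx = np.arange(500)
    a = p.segment_subsample(idx, 10, 20, rng=42)
    b = p.segment_subsample(idx, 10, 20, rng=42)
    np.testing.assert_array_equal(a, b)


def test_segment_subsample_empty_and_short():
    assert len(p.segment_subsample(np.arange(100), 10, 0, rng=0)) == 0
    with pytest.warns(UserWarning, match="shorter"):
        sub = p.segment_subsample(np.arange(25), 10, 5, rng=0)
    assert len(sub) == 25


# -- forest feature selection ------------------------------------------------

def test_forest_selects_planted_feature(rng):
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        y = np.repeat([0, 1], 150)
        X = r.standard_normal((300, 51))
        X[y == 1, 7] += 2.0  # planted 2-sigma class shift
        sel = p.forest_feature_selection(X, y, n_keep=5, n_trees=50, seed=seed)
        hits += 7 in sel
    assert hits >= 19


def test_forest_identity_and_bounds(rng):
    X, y = rng.standard_normal((50, 6)), np.repeat([0, 1], 25)
    assert list(p.forest_feature_selection(X, y, 6, seed=0)) == list(range(6))
    with pytest.raises(ValueError, match="exceeds"):
        p.forest_feature_selection(X, y, 7, seed=0)


# -- logistic regression -----------------------------------------------------

def test_logistic_separable_toy():
    X = np.array([[-2.0, 0], [-1.5, 1], [2.0, 0], [1.7, -1]])
    y = np.array([0, 0, 1, 1])
    lr = p.train_logistic(X, y)
    assert (lr.predict(X) == y).all()


def test_logistic_label_flip_negates_coefficients(rng):
    X = rng.standard_normal((200, 3))
    y = (X[:, 0] + 0.5 * rng.standard_normal(200) > 0).astype(int)
    a = p.train_logistic(X, y)
    b = p.train_logistic(X, 1 - y)
    np.testing.assert_allclose(a.coef_, -b.coef_, atol=1e-5)


def _irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent iteratively-reweighted-least-squares oracle."""
    Xd = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = Xd.T @ (y - mu)
        H = (Xd * W[:, None]).T @ Xd
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def test_logistic_matches_irls_oracle(rng):
    X = rng.standard_normal((50, 3))
    y = (X @ np.array([1.0, -0.5, 0.2]) + rng.standard_normal(50) > 0).astype(int)
    lr = p.train_logistic(X, y, C=np.inf, tol=1e-10)
    beta = _irls_logistic(X, y.astype(float))
    np.testing.assert_allclose(lr.intercept_[0], beta[0], atol=1e-6)
    np.testing.assert_allclose(lr.coef_[0], beta[1:], atol=1e-6)


# -- SVM ensemble ------------------------------------------------------------

def _separable_training_set(rng, n=400):
    y = (np.arange(n) % 5 == 0).astype(np.int8)  # interleaved in time
    X = rng.standard_normal((n, 8))
    X[y == 1, 2] += 4.0
    return X, y


def test_ensemble_deterministic_from_master_seed(rng):
    X, y = _separable_training_set(rng)
    names = [f"f{i}" for i in range(X.shape[1])]
    t = p.SvmEnsembleTrainer(n_models=5, n_keep=4, n_trees=20)
    Xt = rng.standard_normal((100, 8))
    m1 = t.fit(X, y, names, seed=99)
    m2 = t.fit(X, y, names, seed=99)
    np.testing.assert_array_equal(m1.member_outputs(Xt), m2.member_outputs(Xt))
    assert m1.member_seeds == m2.member_seeds


def test_ensemble_single_member_degenerates(rng):
    X, y = _separable_training_set(rng)
    names = [f"f{i}" for i in range(X.shape[1])]
    m = p.SvmEnsembleTrainer(n_models=1, n_keep=None).fit(X, y, names, seed=0)
    Xt = rng.standard_normal((50, 8))
    np.testing.assert_array_equal(m.predict(Xt), m.member_outputs(Xt)[0])


def test_ensemble_members_agree_on_separable_data(rng):
    X, y = _separable_training_set(rng, n=600)
    names = [f"f{i}" for i in range(X.shape[1])]
    m = p.SvmEnsembleTrainer(n_models=15, n_keep=4, n_trees=20).fit(
        X, y, names, seed=1)
    Xt = rng.standard_normal((200, 8))
    Xt[:100, 2] += 4.0
    outs = m.member_outputs(Xt)
    agree = (outs == outs[0]).all(axis=0).mean()
    assert agree >= 0.95


class _FakeMember:
    def __init__(self, out):
        self.out = np.asarray(out, dtype=float)

    def decision_function(self, Z):
        return np.resize(self.out, Z.shape[0])


def _fake_ensemble(member_votes):
    std = p.Standardizer().fit(np.random.default_rng(0).standard_normal((10, 2)))
    members = [(_FakeMember(1.0 if v else -1.0), np.array([0]))
               for v in member_votes]
    return p.SvmEnsemble(members=members, standardizer=std,
                         feature_names=["f0", "f1"], member_seeds=[0] * len(members))


@pytest.mark.parametrize("votes,expected", [
    ([1] * 15, 1),
    ([1] * 8 + [0] * 7, 1),
    ([1] * 7 + [0] * 8, 0),
])
def test_majority_vote_rule(votes, expected):
    ens = _fake_ensemble(votes)
    assert ens.predict(np.zeros((3, 2)))[0] == expected


def test_predict_windows_feature_mismatch(rng):
    X, y = _separable_training_set(rng)
    model = p.LogisticTrainer(n_keep=None).fit(X, y, [f"f{i}" for i in range(8)])
    with pytest.raises(ValueError, match="feature count"):
        p.predict_windows(model, np.zeros((5, 9)))


# -- grid search -------------------------------------------------------------

def _grid_features(rng, onsets, n_win=2400):
    X = rng.standard_normal((n_win, 4))
    return _fm(X)


class _ConstantTrainer:
    """Scores every window identically: forces exact AUC ties."""

    def fit(self, X, y, names, seed=0, preictal_min=None):
        class M:
            def decision_function(self, X):
                return np.zeros(len(X))

            def predict(self, X):
                return np.zeros(len(X), dtype=np.int8)
        return M()


def test_grid_single_candidate(rng):
    fm = _grid_features(rng, None)
    onsets = np.array([3000.0, 6000.0, 9000.0])
    res = p.grid_search_preictal(fm, onsets, grid=(40.0,),
                                 trainer=_ConstantTrainer())
    assert res.best_min == 40.0


def test_grid_tie_breaks_to_shortest(rng):
    fm = _grid_features(rng, None)
    onsets = np.array([3000.0, 6000.0, 9000.0])
    res = p.grid_search_preictal(fm, onsets, trainer=_ConstantTrainer())
    assert res.best_min == 30.0
    assert all(v == pytest.approx(0.0) for v in res.scores.values())


def test_grid_empty_rejected(rng):
    fm = _grid_features(rng, None)
    with pytest.raises(ValueError, match="empty"):
        p.grid_search_preictal(fm, [3000.0, 6000.0, 9000.0], grid=())


def test_grid_recovers_true_preictal(small_patient):
    cfg, rec, ann, truth = small_patient
    fm = p.extract_features(rec, bands=p.bands_for_fs(rec.fs),
                            families=("rel_power", "band_ratios"))
    res = p.grid_search_preictal(fm, ann.onsets_s(rec.start_time)[:3],
                                 seed=0)
    assert res.best_min == cfg.true_preictal_min
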