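import numpy as np
import pytest

from brtsdm import (
    FitConfig,
    auc,
    cv_select_trees,
    fit_brt,
    model_from_json,
    model_to_json,
    partial_dependence,
    predict_brt,
    relative_influence,
)
from brtsdm.brt_core import BoostedTreesModel, _Node, bernoulli_deviance
from brtsdm.errors import ConfigurationError, DegenerateFitError, UndefinedStatisticError

from conftest import make_feature_table


def _signal_data(n=300, seed=0, beta=(2.0, 0.5)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    logit = beta[0] * X[:, 0] + beta[1] * X[:, 1]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    return make_feature_table(X, y)


def test_no_signal_fit_predicts_prevalence():
    """Labels independent of predictors: mean p near prevalence, CV AUC near 0.5."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 3))
    y = (rng.uniform(size=200) < 0.4).astype(int)
    data = make_feature_table(X, y)
    cfg = FitConfig(learning_rate=0.05, seed=2, max_trees=100)
    model = fit_brt(data, cfg, n_trees=50)
    probs = predict_brt(model, data)
    assert abs(probs.mean() - y.mean()) < 0.05
    cv = cv_select_trees(data, cfg)
    assert 0.3 <= cv.cv_auc <= 0.7


def test_perfect_separator_reaches_training_auc_one():
    rng = np.random.default_rng(3)
    x_sep = np.repeat([0.0, 1.0], 100)
    noise = rng.normal(size=200)
    y = x_sep.astype(int)
    data = make_feature_table(np.column_stack([x_sep, noise]), y)
    model = fit_brt(data, FitConfig(seed=0), n_trees=200)
    assert auc(predict_brt(model, data), y) == 1.0


def test_refit_with_same_seed_is_bit_identical():
    data = _signal_data(seed=5)
    cfg = FitConfig(learning_rate=0.05, seed=11)
    a = fit_brt(data, cfg, n_trees=40)
    b = fit_brt(data, cfg, n_trees=40)
    assert model_to_json(a) == model_to_json(b)


def test_single_class_labels_rejected():
    data = _signal_data(seed=0)
    data.labels[:] = 1
    with pytest.raises(DegenerateFitError):
        fit_brt(data, FitConfig(), n_trees=5)


def test_zero_learning_rate_rejected():
    data = _signal_data(seed=0)
    with pytest.raises(ConfigurationError):
        fit_brt(data, FitConfig(learning_rate=0.0), n_trees=5)


def test_zero_tree_model_is_constant_prevalence():
    data = _signal_data(seed=6)
    prevalence = data.labels.mean()
    model = BoostedTreesModel(
        feature_names=data.predictors, kinds=data.kinds,
        initial_score=float(np.log(prevalence / (1 - prevalence))),
        trees=[], learning_rate=0.005, tree_complexity=4, bag_fraction=0.75,
        n_trees_used=0,
    )
    probs = predict_brt(model, data)
    assert np.allclose(probs, prevalence)


def test_all_zero_leaf_tree_changes_nothing():
    data = _signal_data(seed=7)
    model = fit_brt(data, FitConfig(learning_rate=0.05, seed=1), n_trees=10)
    before = predict_brt(model, data)
    dead = _Node()  # a leaf-only tree with value 0
    model.trees.append(dead)
    model.n_trees_used += 1
    assert np.array_equal(predict_brt(model, data), before)


def test_matches_reference_gradient_boosting_within_auc_margin():
    """Cross-implementation check against scikit-learn's binomial GBM."""
    from sklearn.ensemble import GradientBoostingClassifier

    train = _signal_data(n=400, seed=8)
    test = _signal_data(n=400, seed=9)
    cfg = FitConfig(learning_rate=0.1, bag_fraction=1.0, min_obs_in_node=10, seed=0)
    ours = fit_brt(train, cfg, n_trees=100)
    ours_auc = auc(predict_brt(ours, test), test.labels)
    ref = GradientBoostingClassifier(
        n_estimators=100, learning_rate=0.1, max_leaf_nodes=5,
        min_samples_leaf=10, random_state=0,
    ).fit(train.frame.to_numpy(), train.labels)
    ref_auc = auc(ref.predict_proba(test.frame.to_numpy())[:, 1], test.labels)
    assert abs(ours_auc - ref_auc) <= 0.02


def test_training_deviance_non_increasing_without_bagging():
    data = _signal_data(n=200, seed=10)
    cfg = FitConfig(learning_rate=0.05, bag_fraction=1.0, seed=0)
    model = fit_brt(data, cfg, n_trees=60)
    X = data.frame.to_numpy()
    devs = []
    for k in range(0, 61, 10):
        model.n_trees_used = k
        devs.append(bernoulli_deviance(data.labels.astype(float), model.predict_proba(X)))
    assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))


def test_categorical_split_and_unseen_code_routing():
    rng = np.random.default_rng(12)
    codes = rng.integers(1, 4, size=240).astype(float)
    y = (codes == 2).astype(int)
    data = make_feature_table(codes[:, None], y, names=["soil"],
                              kinds={"soil": "categorical"})
    model = fit_brt(data, FitConfig(learning_rate=0.1, seed=0), n_trees=100)
    assert auc(predict_brt(model, data), y) == 1.0
    novel = make_feature_table(np.array([[9.0]]), [0], names=["soil"],
                               kinds={"soil": "categorical"})
    probs = predict_brt(model, novel)  # routed to the heavier child, not an error
    assert 0.0 < probs[0] < 1.0
    assert model.unseen_code_count > 0


# -- cross-validated size selection -------------------------------------------

def test_cv_optimum_is_multiple_of_step_size():
    data = _signal_data(n=120, seed=13)
    cfg = FitConfig(learning_rate=0.05, step_size=10, max_trees=100, n_folds=5, seed=3)
    cv = cv_select_trees(data, cfg)
    assert cv.n_trees_optimal % 10 == 0
    assert cv.n_trees_optimal <= 100


def test_cv_auc_high_on_separable_data():
    rng = np.random.default_rng(14)
    x = np.concatenate([rng.normal(-3, 0.5, 100), rng.normal(3, 0.5, 100)])
    y = np.repeat([0, 1], 100)
    data = make_feature_table(x[:, None], y)
    cv = cv_select_trees(data, FitConfig(learning_rate=0.05, max_trees=200, seed=0))
    assert cv.cv_auc >= 0.95


def test_cv_on_pure_noise_stops_early_with_chance_auc():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(200, 3))
    y = rng.integers(0, 2, size=200)
    data = make_feature_table(X, y)
    cfg = FitConfig(learning_rate=0.05, step_size=10, max_trees=500, patience=5, seed=1)
    cv = cv_select_trees(data, cfg)
    # early stopping keeps the optimum near the minimum allowed tree count
    assert cv.n_trees_optimal <= 100
    assert 0.35 <= cv.cv_auc <= 0.65


# -- relative influence --------------------------------------------------------

def test_influence_concentrates_on_the_only_informative_predictor():
    rng = np.random.default_rng(16)
    x = rng.normal(size=300)
    y = (x > 0).astype(int)
    data = make_feature_table(x[:, None], y, names=["only"])
    model = fit_brt(data, FitConfig(learning_rate=0.1, seed=0), n_trees=30)
    ri = relative_influence(model)
    assert ri["only"] == pytest.approx(100.0, abs=1e-9)


def test_influence_sums_to_100():
    model = fit_brt(_signal_data(seed=17), FitConfig(learning_rate=0.05, seed=2), 40)
    assert sum(relative_influence(model).values()) == pytest.approx(100.0, abs=1e-9)


def test_influence_undefined_without_splits():
    data = _signal_data(seed=18)
    model = fit_brt(data, FitConfig(learning_rate=0.05, seed=0), n_trees=5)
    model.trees = [_Node()]
    model.n_trees_used = 1
    with pytest.raises(UndefinedStatisticError):
        relative_influence(model)


def test_stronger_predictor_ranks_higher_in_most_replicates():
    """Predictor with 4x the effect size out-ranks the weaker one >= 18/20 times."""
    wins = 0
    for rep in range(20):
        rng = np.random.default_rng(100 + rep)
        X = rng.normal(size=(250, 2))
        logit = 2.0 * X[:, 0] + 0.5 * X[:, 1]
        y = (rng.uniform(size=250) < 1 / (1 + np.exp(-logit))).astype(int)
        data = make_feature_table(X, y, names=["strong", "weak"])
        model = fit_brt(data, FitConfig(learning_rate=0.1, seed=rep), n_trees=40)
        ri = relative_influence(model)
        wins += ri["strong"] > ri["weak"]
    assert wins >= 18


def test_influence_invariant_to_zero_improvement_trees():
    data = _signal_data(seed=19)
    model = fit_brt(data, FitConfig(learning_rate=0.05, seed=0), n_trees=20)
    before = relative_influence(model)
    model.trees.append(_Node())
    model.n_trees_used += 1
    assert relative_influence(model) == before


# -- partial dependence --------------------------------------------------------

def _brute_force_pd(model, predictor, data, grid):
    X = data.frame[model.feature_names].to_numpy(dtype=float)
    j = model.feature_names.index(predictor)
    out = []
    for v in grid:
        vals = []
        for i in range(len(X)):
            row = X[i].copy()
            row[j] = v
            vals.append(model.predict_proba(row[None, :])[0])
        out.append(np.mean(vals))
    return np.array(out)


def test_partial_dependence_equals_row_by_row_forcing():
    data = _signal_data(n=80, seed=20)
    model = fit_brt(data, FitConfig(learning_rate=0.1, seed=1), n_trees=15)
    grid, curve = partial_dependence(model, "x0", data, n_points=7)
    assert np.allclose(curve, _brute_force_pd(model, "x0", data, grid))
    assert np.all((curve > 0) & (curve < 1))


def test_partial_dependence_constant_for_unsplit_predictor():
    rng = np.random.default_rng(21)
    x = rng.normal(size=200)
    inert = np.zeros(200)  # constant column, never splittable
    y = (x > 0).astype(int)
    data = make_feature_table(np.column_stack([x, inert]), y, names=["active", "inert"])
    model = fit_brt(data, FitConfig(learning_rate=0.1, seed=0), n_trees=20)
    assert relative_influence(model)["inert"] == 0.0
    _, curve = partial_dependence(model, "inert", data, n_points=5)
    mean_pred = predict_brt(model, data).mean()
    assert np.allclose(curve, mean_pred)


def test_single_split_tree_gives_two_level_step(tiny_stack):
    x = np.concatenate([np.zeros(30), np.ones(30)])
    y = x.astype(int)
    data = make_feature_table(x[:, None], y, names=["x"])
    model = fit_brt(data, FitConfig(tree_complexity=1, learning_rate=0.1,
                                    bag_fraction=1.0, seed=0), n_trees=1)
    grid, curve = partial_dependence(model, "x", data, n_points=2)
    assert len(np.unique(np.round(curve, 12))) == 2
    assert curve[1] > curve[0]  # step up at the split


# -- serialization and raster prediction ---------------------------------------

def test_model_json_roundtrip_preserves_predictions():
    data = _signal_data(seed=22)
    model = fit_brt(data, FitConfig(learning_rate=0.05, seed=4), n_trees=25)
    clone = model_from_json(model_to_json(model))
    assert np.array_equal(predict_brt(model, data), predict_brt(clone, data))


def test_raster_prediction_propagates_nodata(tiny_stack):
    rng = np.random.default_rng(23)
    cells = tiny_stack.valid_cells()
    X = tiny_stack.cell_values(cells)
    y = (X[:, 1] > 1200).astype(int)  # split on elevation
    data = make_feature_table(X, y, names=tiny_stack.names, kinds=tiny_stack.kinds)
    model = fit_brt(data, FitConfig(learning_rate=0.1, min_obs_in_node=5, seed=0), 30)
    out = predict_brt(model, tiny_stack)
    assert out.values.shape == (8, 8)
    assert np.array_equal(out.mask, tiny_stack.joint_mask)
    assert np.all((out.values[~out.mask] > 0) & (out.values[~out.mask] < 1))
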