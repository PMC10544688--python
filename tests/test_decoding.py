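import numpy as np
import pytest
from scipy.stats import norm

import touchdecode as td
from touchdecode.decoding import (
    decode_pair,
    fit_svd_projection,
    lda_accuracy,
    results_to_frame,
    significance_tier,
    split_balanced,
)
from touchdecode.preprocess import normalize_by_baseline, rebin


# ------------------------------------------------------------------ splits
def test_balanced_split_halves_each_class():
    labels = np.repeat(["a", "b"], 70)
    tr, te = split_balanced(labels, np.random.default_rng(0))
    assert len(tr) == len(te) == 70
    for cls in "ab":
        assert np.sum(labels[tr] == cls) == 35
        assert np.sum(labels[te] == cls) == 35
    assert len(set(tr) & set(te)) == 0


def test_two_trials_per_class_split_one_one():
    labels = np.array(["a", "a", "b", "b"])
    tr, te = split_balanced(labels, np.random.default_rng(0))
    assert len(tr) == len(te) == 2


def test_odd_class_size_drops_remainder():
    labels = np.array(["a"] * 5 + ["b"] * 4)
    tr, te = split_balanced(labels, np.random.default_rng(0))
    assert np.sum(labels[tr] == "a") == 2 and np.sum(labels[te] == "a") == 2


def test_split_sequence_deterministic():
    labels = np.repeat(["a", "b"], 20)
    s1 = [split_balanced(labels, np.random.default_rng(7)) for _ in range(3)]
    s2 = [split_balanced(labels, np.random.default_rng(7)) for _ in range(3)]
    for (a1, b1), (a2, b2) in zip(s1, s2):
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


def test_singleton_class_rejected():
    with pytest.raises(ValueError):
        split_balanced(np.array(["a", "b", "b"]), np.random.default_rng(0))


# --------------------------------------------------------------------- SVD
def test_rank_deficient_data_truncates():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 96))   # rank 2
    proj = fit_svd_projection(X, k=40)
    assert proj.components.shape[0] == 2
    Z = proj.transform(X)
    recon = Z @ proj.components + proj.mean
    assert np.allclose(recon, X, atol=1e-8)


def test_full_rank_projection_preserves_distances():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 8))
    proj = fit_svd_projection(X, k=8)
    Z = proj.transform(X)
    d_x = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    d_z = np.linalg.norm(Z[:, None] - Z[None, :], axis=-1)
    assert np.allclose(d_x, d_z, atol=1e-8)


def test_variance_captured_matches_singular_values():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(100, 20)) * np.linspace(3, 0.1, 20)
    k = 5
    proj = fit_svd_projection(X, k)
    captured = proj.transform(X).var(axis=0, ddof=1).sum()
    s = np.linalg.svd(X - X.mean(0), compute_uv=False)
    expected = (s[:k] ** 2).sum() / (len(X) - 1)
    assert captured == pytest.approx(expected)


# --------------------------------------------------------------------- LDA
def test_widely_separated_classes_perfect():
    rng = np.random.default_rng(0)
    Xa = rng.normal(0, 1, (40, 5)); Xa[:, 0] += 20.0
    Xb = rng.normal(0, 1, (40, 5))
    X = np.vstack([Xa, Xb]); y = np.repeat(["a", "b"], 40)
    acc = lda_accuracy(X, y, X, y)
    assert acc == 1.0


def test_identical_distributions_near_chance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(140, 10))
    y = np.repeat(["a", "b"], 70)
    res = decode_pair(X, y, n_splits=200, n_dims=10, seed=0)
    lo, hi = res.ci(0.95)
    assert lo <= 0.5 <= hi


def test_accuracy_approaches_bayes_rate():
    # mean separation d along one axis, unit isotropic noise: Bayes
    # accuracy Phi(d/2); estimation loss at p=4, n=70 stays small
    rng = np.random.default_rng(2)
    d = 2.0
    accs = []
    for rep in range(8):
        Xa = rng.normal(0, 1, (70, 4)); Xa[:, 0] += d
        Xb = rng.normal(0, 1, (70, 4))
        X = np.vstack([Xa, Xb]); y = np.repeat(["a", "b"], 70)
        accs.append(decode_pair(X, y, n_splits=100, n_dims=4,
                                seed=rep).mean_accuracy)
    assert np.mean(accs) == pytest.approx(norm.cdf(d / 2), abs=0.03)


def test_duplicated_feature_no_failure():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 3))
    X = np.hstack([X, X[:, :1]])       # exactly collinear
    y = np.repeat(["a", "b"], 20)
    X[y == "a", 1] += 5.0
    acc = lda_accuracy(X, y, X, y)
    assert 0.9 <= acc <= 1.0


def test_swap_classes_leaves_accuracy_unchanged():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 6)); y = np.repeat(["a", "b"], 30)
    X[y == "a", 0] += 1.0
    tr = np.arange(0, 60, 2); te = np.arange(1, 60, 2)
    a1 = lda_accuracy(X[tr], y[tr], X[te], y[te])
    y_sw = np.where(y == "a", "b", "a")
    a2 = lda_accuracy(X[tr], y_sw[tr], X[te], y_sw[te])
    assert a1 == a2


def test_tie_broken_toward_first_class():
    X = np.array([[1.0], [-1.0]])
    y = np.array(["a", "b"])
    # test point exactly on the boundary scores 0 -> class a
    assert lda_accuracy(X, y, np.array([[0.0]]), np.array(["a"])) == 1.0
    assert lda_accuracy(X, y, np.array([[0.0]]), np.array(["b"])) == 0.0


def test_rotation_invariance_with_full_rank_projection():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(80, 6)); y = np.repeat(["a", "b"], 40)
    X[y == "a", 0] += 1.5
    Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
    r1 = decode_pair(X, y, n_splits=50, n_dims=6, seed=9)
    r2 = decode_pair(X @ Q, y, n_splits=50, n_dims=6, seed=9)
    assert np.allclose(r1.accuracies, r2.accuracies)


# ---------------------------------------------------------------- tiers
def test_tier_extremes():
    ones = np.ones(500)
    half = np.full(500, 0.5)
    assert significance_tier(ones, half) == "***"
    assert significance_tier(half, half) == "ns"


def test_tier_borderline_is_star_not_double_star():
    # uniform grids make percentile CIs exact: separated at 95% but
    # overlapping at 97.5%
    result = np.linspace(0.5, 1.0, 1001)
    null = np.linspace(0.0, 0.513, 1001)
    assert significance_tier(result, null) == "*"


def test_empty_distribution_rejected():
    with pytest.raises(ValueError):
        significance_tier(np.empty(0), np.ones(3))


# ----------------------------------------------------------- run_pairwise
@pytest.fixture(scope="module")
def planted_two_cond():
    design = td.make_task_design(conditions=("FPa", "BLa"),
                                 runs_per_condition=7)
    truth = td.make_ground_truth(design, n_channels=48,
                                 gains={"FPa": (list(range(15)), 3.0)})
    raw, _ = td.simulate_session(design, truth, seed=21)
    return rebin(normalize_by_baseline(raw.drop_catch()), 0.5)


def test_planted_pair_significant_post_onset(planted_two_cond):
    results = td.run_pairwise(planted_two_cond, window=(-0.5, 0.5),
                              n_splits=100, seed=0)
    by_bin = {r.bin_center: r for r in results}
    assert by_bin[0.25].tier == "***"
    assert by_bin[0.25].mean_accuracy > 0.9
    assert by_bin[-0.25].mean_accuracy < 0.65


def test_unknown_condition_rejected(planted_two_cond):
    with pytest.raises(KeyError):
        td.run_pairwise(planted_two_cond, pairs=[("FPa", "XXX")])


def test_null_mean_near_chance(planted_two_cond):
    res = td.run_pairwise(planted_two_cond, window=(0.0, 0.5),
                          n_splits=200, seed=1)[0]
    # binomial sampling error of the mean over 200 x 70 test trials
    assert abs(np.mean(res.null_accuracies) - 0.5) < 0.02


def test_results_frame_columns(planted_two_cond):
    res = td.run_pairwise(planted_two_cond, window=(0.0, 0.5),
                          n_splits=20, seed=2)
    frame = results_to_frame(res)
    assert set(frame.columns) >= {"class_a", "class_b", "bin_center",
                                  "mean_acc", "ci_lo", "ci_hi", "tier"}


# ------------------------------------------------------- generalization
def _location_code_bundle(shared: bool, seed: int):
    """TP and FP conditions; location code on shared or disjoint channels."""
    design = td.make_task_design(
        conditions=("TPa", "TPf", "FPa", "FPf"), runs_per_condition=7,
    )
    if shared:
        gains = {"TPa": (list(range(0, 12)), 2.5),
                 "FPa": (list(range(0, 12)), 2.5),
                 "TPf": (list(range(12, 24)), 2.5),
                 "FPf": (list(range(12, 24)), 2.5)}
    else:
        gains = {"TPa": (list(range(0, 12)), 2.5),
                 "TPf": (list(range(12, 24)), 2.5),
                 "FPa": (list(range(24, 36)), 2.5),
                 "FPf": (list(range(36, 48)), 2.5)}
    truth = td.make_ground_truth(design, n_channels=48, gains=gains)
    raw, _ = td.simulate_session(design, truth, seed=seed)
    return rebin(normalize_by_baseline(raw.drop_catch()), 0.5)


def test_shared_location_code_generalizes():
    bundle = _location_code_bundle(shared=True, seed=31)
    res = td.run_generalization(
        bundle, (["TPa"], ["TPf"]), (["FPa"], ["FPf"]),
        window=(0.0, 0.5), n_splits=100, seed=0,
    )[0]
    assert res.mean_accuracy > 0.9
    assert res.tier == "***"


def test_orthogonal_location_code_does_not_generalize():
    bundle = _location_code_bundle(shared=False, seed=32)
    res = td.run_generalization(
        bundle, (["TPa"], ["TPf"]), (["FPa"], ["FPf"]),
        window=(0.0, 0.5), n_splits=100, seed=0,
    )[0]
    lo, hi = res.ci(0.95)
    assert lo <= 0.5 <= hi


def test_self_generalization_matches_pairwise():
    bundle = _location_code_bundle(shared=True, seed=33)
    gen = td.run_generalization(
        bundle, (["TPa"], ["TPf"]), (["TPa"], ["TPf"]),
        window=(0.0, 0.5), n_splits=100, seed=5,
    )[0]
    sub = bundle.select_conditions(["TPa", "TPf"])
    pair = td.run_pairwise(sub, pairs=[("TPa", "TPf")], window=(0.0, 0.5),
                           n_splits=100, seed=5)[0]
    lo, hi = pair.ci(0.95)
    assert lo - 0.05 <= gen.mean_accuracy <= hi + 0.05


def test_overlapping_selectors_rejected():
    bundle = _location_code_bundle(shared=True, seed=34)
    with pytest.raises(ValueError):
        td.run_generalization(bundle, (["TPa"], ["TPf"]),
                              (["TPa"], ["FPf"]), n_splits=2)
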