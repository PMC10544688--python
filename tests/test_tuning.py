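import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import touchdecode as td
from touchdecode.tuning import (
    bootstrap_tuned_counts,
    detect_onset_offset,
    fit_channel_tuning,
    fit_tuning,
    holm_correct,
    overlap_sets,
    tuning_design_matrix,
)

from conftest import make_flat_bundle


# -------------------------------------------------------------- regression
def _tuned_bundle(gain=3.0, n_channels=4, seed=1):
    design = td.make_task_design(conditions=("FPa", "BLa"),
                                 runs_per_condition=7)
    truth = td.make_ground_truth(design, n_channels=n_channels,
                                 gains={"FPa": ([0, 1], gain)})
    raw, truth = td.simulate_session(design, truth, seed=seed)
    return td.normalize_by_baseline(raw.drop_catch()), truth


def test_regression_matches_statsmodels():
    import statsmodels.api as sm
    from touchdecode.preprocess import rebin

    bundle, _ = _tuned_bundle()
    coarse = rebin(bundle, 0.5)
    j = coarse.bin_slice((0.0, 0.5)).start
    got = fit_channel_tuning(coarse, channel=0, time_bin=j,
                             baseline_bundle=bundle)
    # independent fit of the same augmented system
    conds = coarse.conditions
    labels = coarse.labels
    order = np.concatenate([np.flatnonzero(labels == c) for c in conds])
    counts = [int(np.sum(labels == c)) for c in conds]
    F = coarse.rates[0, order, j]
    base = bundle.rates[0, :, bundle.bin_slice((-4.0, -2.5))].mean()
    F = np.concatenate([F, np.full(max(counts), base)])
    X = tuning_design_matrix(counts, max(counts))
    fit = sm.OLS(F, X).fit()
    assert np.allclose(got["beta"], fit.params[1:], atol=1e-10)
    assert np.allclose(got["t"], fit.tvalues[1:], atol=1e-8)
    assert np.allclose(got["p"], fit.pvalues[1:], atol=1e-10)


def test_strong_gain_coefficient_near_two():
    # 3x baseline => normalized response ~3, beta ~ 2 above baseline 1
    bundle, _ = _tuned_bundle(gain=3.0)
    from touchdecode.preprocess import rebin
    coarse = rebin(bundle, 0.5)
    j = coarse.bin_slice((0.0, 0.5)).start
    res = fit_channel_tuning(coarse, channel=0, time_bin=j,
                             baseline_bundle=bundle)
    row = res[res["condition"] == "FPa"].iloc[0]
    assert row["beta"] == pytest.approx(2.0, abs=0.3)
    assert row["p"] < 1e-6


def test_condition_at_baseline_not_tuned():
    bundle, _ = _tuned_bundle(gain=3.0)
    from touchdecode.preprocess import rebin
    coarse = rebin(bundle, 0.5)
    j = coarse.bin_slice((0.0, 0.5)).start
    res = fit_channel_tuning(coarse, channel=3, time_bin=j,
                             baseline_bundle=bundle)
    assert (res["p"] > 0.05).all()


def test_null_rejection_rate_matches_alpha():
    # unmodulated session: per-test rejection rate of the raw p-values ~ alpha
    design = td.make_task_design(conditions=("FPa", "BLa", "VrFPa"),
                                 runs_per_condition=7)
    truth = td.make_ground_truth(design, n_channels=48)
    raw, _ = td.simulate_session(design, truth, seed=3)
    bundle = td.normalize_by_baseline(raw.drop_catch())
    table = fit_tuning(bundle)
    rate = np.mean(table.p < 0.05)
    n = table.p.size
    assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n) + 0.02


# -------------------------------------------------------------------- Holm
def test_holm_single_p():
    assert holm_correct(np.array([0.04])).tolist() == [True]


def test_holm_hand_enumerated_step_down():
    # m=3: 0.01 <= 0.05/3, 0.02 <= 0.05/2, 0.9 > 0.05
    got = holm_correct(np.array([0.01, 0.02, 0.9]))
    assert got.tolist() == [True, True, False]
    # step-down stops at first failure even if later p would pass
    got = holm_correct(np.array([0.03, 0.026, 0.04]))
    assert got.tolist() == [False, False, False]


def test_holm_all_ones_no_rejections():
    assert not holm_correct(np.ones(5)).any()


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(0, 0.2, size=rng.integers(1, 12))
        got = holm_correct(p, alpha=0.05)
        want = multipletests(p, alpha=0.05, method="holm")[0]
        assert np.array_equal(got, want)


def test_holm_2d_families_independent():
    p = np.array([[0.01, 0.9], [0.9, 0.01]])
    got = holm_correct(p, axis=-1)
    assert got.tolist() == [[True, False], [False, True]]


@settings(deadline=None, max_examples=60)
@given(hnp.arrays(float, st.integers(1, 8),
                  elements=st.floats(0.0, 1.0)))
def test_holm_at_least_as_powerful_as_bonferroni(p):
    holm = holm_correct(p, alpha=0.05)
    bonf = p <= 0.05 / len(p)
    assert np.all(holm[bonf])        # every Bonferroni rejection survives


@settings(deadline=None, max_examples=60)
@given(hnp.arrays(float, st.integers(2, 8),
                  elements=st.floats(0.0, 1.0)),
       st.randoms(use_true_random=False))
def test_holm_permutation_invariant(p, rnd):
    perm = np.array(rnd.sample(range(len(p)), len(p)))
    got = holm_correct(p[perm], alpha=0.05)
    want = holm_correct(p, alpha=0.05)[perm]
    assert np.array_equal(got, want)


# ---------------------------------------------------------------- bootstrap
def test_single_iteration_matches_point_estimate():
    bundle, _ = _tuned_bundle()
    boot = bootstrap_tuned_counts(bundle, n_iter=1, seed=0)
    table = fit_tuning(bundle)
    assert np.array_equal(boot.point, table.counts.to_numpy())


def test_planted_count_difference_tiered():
    design = td.make_task_design(conditions=("FPa", "BLa"),
                                 runs_per_condition=7)
    truth = td.make_ground_truth(
        design, n_channels=48,
        gains={"FPa": (list(range(30)), 3.0), "BLa": (list(range(5)), 3.0)},
    )
    raw, _ = td.simulate_session(design, truth, seed=5)
    bundle = td.normalize_by_baseline(raw.drop_catch())
    boot = bootstrap_tuned_counts(bundle, n_iter=200, seed=1)
    # Holm controls the familywise rate per channel, so a few false-
    # positive channels across 48 are expected on top of the planted sets
    assert abs(boot.point[0] - 30) <= 4 and abs(boot.point[1] - 5) <= 4
    assert boot.point[0] > boot.point[1]
    tiers = boot.pairwise_tiers()
    assert tiers.iloc[0]["tier"] in {"*", "**", "***"}


# ------------------------------------------------------------ overlap sets
def _table_from_tuned(tuned_any, conditions):
    from touchdecode.tuning import TuningTable

    t = tuned_any[:, :, None]
    z = np.zeros_like(t, dtype=float)
    return TuningTable(beta=z, t=z, p=z, tuned=t, conditions=conditions,
                       bin_centers=np.array([0.25]))


def test_overlap_membership_classes():
    conds = ["FPa", "FPf", "BLa", "BLf"]
    tuned = np.zeros((5, 4), dtype=bool)
    tuned[0, 0] = True                 # FPa only -> arm-only
    tuned[1, [0, 1]] = True            # FPa+FPf -> both
    tuned[2, 1] = True                 # FPf -> finger-only
    tuned[3, [2, 3]] = True            # BLa+BLf -> both
    report = overlap_sets(_table_from_tuned(tuned, conds))
    mem = report.per_channel["membership"].tolist()
    assert mem == ["arm-only", "both", "finger-only", "both", "untuned"]
    assert report.by_touch_type["FP"] == {"arm-only": 1, "finger-only": 1,
                                          "both": 1}


def test_overlap_counts_partition_tuned_channels():
    rng = np.random.default_rng(6)
    conds = ["FPa", "FPf", "BLa", "BLf", "Obj"]
    tuned = rng.random((96, 5)) < 0.3
    report = overlap_sets(_table_from_tuned(tuned, conds))
    n_tuned = int(tuned.any(axis=1).sum())
    assert int(report.counts.sum()) == n_tuned


def test_array_layout_positions():
    conds = ["FPa"]
    tuned = np.zeros((96, 1), dtype=bool)
    report = overlap_sets(_table_from_tuned(tuned, conds))
    pc = report.per_channel
    assert pc["array"].tolist() == [0] * 48 + [1] * 48
    assert pc.loc[0, ["row", "col"]].tolist() == [0, 0]
    assert pc.loc[47, ["row", "col"]].tolist() == [5, 7]
    with pytest.raises(ValueError):
        overlap_sets(_table_from_tuned(tuned, conds), array_shape=(2, 2))


# ----------------------------------------------------------- onset/offset
def _step_bundle(step_bin=82, value=2.0, n_trials=20, n_bins=120):
    """Noiseless traces at 1.0 stepping to ``value`` at bin ``step_bin``
    (50 ms grid over [-4, 2); bin 80 starts at t=0)."""
    vals = np.ones((2, n_trials, n_bins))
    vals[:, :, step_bin:] = value
    return make_flat_bundle(vals, ["FPa"], n_trials, n_runs=2,
                            bin_edges=np.arange(n_bins + 1) * 0.05 - 4.0)


def test_noiseless_step_onset_at_bin_midpoint():
    # step at t=0.10 s -> first bin above threshold is [0.10, 0.15)
    est = detect_onset_offset(_step_bundle(step_bin=82), np.array([0, 1]),
                              "FPa", n_boot=50, seed=0)
    assert est.onset_ms == pytest.approx(125.0)
    assert est.offset_ms is None       # never dips back below


def test_flat_trace_has_undefined_onset():
    est = detect_onset_offset(_step_bundle(value=1.0), np.array([0, 1]),
                              "FPa", n_boot=10, seed=0)
    assert est.onset_ms is None and est.offset_ms is None


def test_onset_shift_equivariance():
    e1 = detect_onset_offset(_step_bundle(step_bin=82), np.array([0, 1]),
                             "FPa", n_boot=10, seed=0)
    e2 = detect_onset_offset(_step_bundle(step_bin=85), np.array([0, 1]),
                             "FPa", n_boot=10, seed=0)
    assert e2.onset_ms - e1.onset_ms == pytest.approx(3 * 50.0)


def test_offset_after_peak_and_pulse_is_bounded():
    vals = np.ones((1, 10, 120))
    vals[:, :, 81:90] = 3.0            # pulse from t=0.05 to t=0.45
    vals[:, :, 90:] = 0.9              # strictly below threshold afterwards
    bundle = make_flat_bundle(vals, ["FPa"], 10, n_runs=2,
                              bin_edges=np.arange(121) * 0.05 - 4.0)
    est = detect_onset_offset(bundle, np.array([0]), "FPa", n_boot=10, seed=0)
    assert est.onset_ms == pytest.approx(75.0)
    # pulse ends at bin [0.50, 0.55): first below-threshold bin after peak
    assert est.offset_ms == pytest.approx(525.0)
    assert est.offset_ms > est.onset_ms


def test_onset_recovered_from_simulated_session(planted_session):
    bundle, truth = planted_session
    table = fit_tuning(bundle)
    chans = table.tuned_channels("FPa")
    assert len(chans) == 30
    est = detect_onset_offset(bundle, chans, "FPa", n_boot=300, seed=2)
    # planted latency 125 ms falls in bin [0.10, 0.15) -> midpoint 125 ms
    assert est.onset_ms == pytest.approx(125.0)
    lo, hi = est.onset_ci_ms
    assert lo - 1e-6 <= 125.0 <= hi + 1e-6


def test_no_tuned_channels_rejected(planted_session):
    bundle, _ = planted_session
    with pytest.raises(ValueError):
        detect_onset_offset(bundle, np.array([]), "FPa")
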