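"""Per-channel condition tuning, bootstrap counts, and response latencies.

Tuning is assessed per channel and 0.5 s bin by ordinary least squares on
``F = b0 + b1 X1 + ... + bC XC``: F stacks the normalized single-trial
rates with 70 appended baseline entries (the channel's mean pre-touch
rate, one per trial-per-condition), X one-hot-encodes condition identity,
and each ``bc`` is t-tested against zero.  A channel is tuned to a
condition when any bin's coefficient survives Bonferroni-Holm correction
over the channel's full (condition x bin) family.  Tuned-channel counts
are bootstrapped over trials; response onset/offset is the midpoint of
the first 50 ms bin where the tuned-channel average crosses the 95th
percentile of its baseline distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import SessionBundle
from .design import ANALYSIS_WINDOW, BASELINE_WINDOW
from .preprocess import rebin

TIER_LEVELS = ((0.99, "***"), (0.975, "**"), (0.95, "*"))


# ------------------------------------------------------------------- OLS
def _ols_tstats(X: np.ndarray, F: np.ndarray):
    """Vectorized OLS of ``F`` (n x channels) on ``X`` (n x p).

    Returns (beta, t, p), each (p, channels); p-values are two-sided and
    NaN for channels with zero residual variance.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ F
    resid = F - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(sigma2[None, :], 0, None) * np.diag(XtX_inv)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals[~np.isfinite(t)] = np.nan
    return beta, t, pvals


def tuning_design_matrix(counts: list[int], n_baseline: int) -> np.ndarray:
    """Design matrix: intercept + one one-hot column per condition, for
    trial rows grouped by condition, then ``n_baseline`` baseline rows
    (intercept only)."""
    n_trials = sum(counts)
    C = len(counts)
    X = np.zeros((n_trials + n_baseline, C + 1))
    X[:, 0] = 1.0
    r = 0
    for j, c in enumerate(counts):
        X[r:r + c, j + 1] = 1.0
        r += c
    return X


def fit_channel_tuning(
    bundle: SessionBundle,
    channel: int,
    time_bin: int,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    baseline_bundle: SessionBundle | None = None,
) -> pd.DataFrame:
    """Tuning regression for one channel at one bin of a (0.5 s-binned,
    normalized) bundle.

    Returns a per-condition frame with ``beta``, ``t`` and two-sided ``p``
    for the null hypothesis beta = 0 (condition no different from
    baseline).  ``baseline_bundle`` may supply a finer-binned bundle for
    the baseline entries; by default the bundle itself is used.
    """
    src = baseline_bundle if baseline_bundle is not None else bundle
    base_sl = src.bin_slice(baseline_window)
    conds = bundle.conditions
    labels = bundle.labels
    order = np.concatenate([np.flatnonzero(labels == c) for c in conds])
    counts = [int(np.sum(labels == c)) for c in conds]
    n_baseline = max(counts)
    F_trials = bundle.rates[channel, order, time_bin]
    base_val = src.rates[channel, :, base_sl].mean()
    F = np.concatenate([F_trials, np.full(n_baseline, base_val)])
    X = tuning_design_matrix(counts, n_baseline)
    beta, t, p = _ols_tstats(X, F[:, None])
    return pd.DataFrame({
        "condition": conds,
        "beta": beta[1:, 0],
        "t": t[1:, 0],
        "p": p[1:, 0],
    })


# ------------------------------------------------------------------- Holm
def holm_correct(p_values: np.ndarray, alpha: float = 0.05, axis: int = -1) -> np.ndarray:
    """Bonferroni-Holm step-down rejection decisions.

    Sorted ascending, p(i) is rejected while ``p(i) <= alpha / (m - i)``
    (0-based), stopping at the first failure.  Implemented via the
    step-down adjusted p-values (running maximum of ``(m - i) * p(i)``).
    NaN p-values are never rejected.  Works along ``axis`` for stacked
    families.
    """
    p = np.asarray(p_values, dtype=float)
    p = np.moveaxis(p, axis, -1)
    m = p.shape[-1]
    order = np.argsort(np.where(np.isnan(p), np.inf, p), axis=-1, kind="stable")
    p_sorted = np.take_along_axis(p, order, axis=-1)
    mult = (m - np.arange(m)).astype(float)
    adj = p_sorted * mult
    adj = np.maximum.accumulate(adj, axis=-1)
    with np.errstate(invalid="ignore"):
        reject_sorted = adj <= alpha
    reject = np.zeros_like(reject_sorted)
    np.put_along_axis(reject, order, reject_sorted, axis=-1)
    return np.moveaxis(reject, -1, axis)


# ----------------------------------------------------------- tuning table
@dataclass
class TuningTable:
    """Tuned flags and statistics per channel x condition x bin."""

    beta: np.ndarray           # (channels, C, B)
    t: np.ndarray
    p: np.ndarray
    tuned: np.ndarray          # Holm-corrected rejections, same shape
    conditions: list
    bin_centers: np.ndarray
    alpha: float = 0.05

    @property
    def tuned_any(self) -> np.ndarray:
        """(channels, C): tuned in at least one bin."""
        return self.tuned.any(axis=2)

    @property
    def n_bins_tuned(self) -> np.ndarray:
        return self.tuned.sum(axis=2)

    @property
    def counts(self) -> pd.Series:
        """Channels tuned (any bin) per condition."""
        return pd.Series(self.tuned_any.sum(axis=0), index=self.conditions)

    def tuned_channels(self, condition: str) -> np.ndarray:
        j = self.conditions.index(condition)
        return np.flatnonzero(self.tuned_any[:, j])


def _prepare_tuning_inputs(
    bundle: SessionBundle,
    window: tuple[float, float],
    tuning_bin_width: float,
    baseline_window: tuple[float, float],
):
    if not bundle.normalized:
        raise ValueError("tuning expects a normalized bundle")
    coarse = rebin(bundle, tuning_bin_width)
    sl = coarse.bin_slice(window)
    centers = coarse.bin_centers[sl]
    conds = bundle.conditions
    labels = bundle.labels
    idx_by_cond = [np.flatnonzero(labels == c) for c in conds]
    base_sl = bundle.bin_slice(baseline_window)
    # per-channel per-trial baseline-window mean (50 ms resolution)
    trial_base = bundle.rates[:, :, base_sl].mean(axis=2)    # (ch, trials)
    resp = coarse.rates[:, :, sl]                            # (ch, trials, B)
    return conds, idx_by_cond, trial_base, resp, centers


def fit_tuning(
    bundle: SessionBundle,
    window: tuple[float, float] = ANALYSIS_WINDOW,
    tuning_bin_width: float = 0.5,
    alpha: float = 0.05,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> TuningTable:
    """Fit the tuning regression for every channel and bin and apply the
    Holm correction over each channel's (condition x bin) family."""
    conds, idx_by_cond, trial_base, resp, centers = _prepare_tuning_inputs(
        bundle, window, tuning_bin_width, baseline_window
    )
    beta, t, p = _fit_counts(conds, idx_by_cond, trial_base, resp)
    tuned = holm_correct(
        p.reshape(p.shape[0], -1), alpha=alpha, axis=-1
    ).reshape(p.shape)
    return TuningTable(
        beta=beta, t=t, p=p, tuned=tuned,
        conditions=list(conds), bin_centers=centers, alpha=alpha,
    )


def _fit_counts(conds, idx_by_cond, trial_base, resp):
    """Vectorized regression across channels and bins for given per-
    condition trial indices (supports bootstrap resamples)."""
    counts = [len(ix) for ix in idx_by_cond]
    n_baseline = max(counts)
    X = tuning_design_matrix(counts, n_baseline)
    order = np.concatenate(idx_by_cond)
    n_ch, _, B = resp.shape
    C = len(conds)
    base_val = trial_base[:, order].mean(axis=1)            # (ch,)
    beta = np.empty((n_ch, C, B))
    t = np.empty((n_ch, C, B))
    p = np.empty((n_ch, C, B))
    base_rows = np.repeat(base_val[None, :], n_baseline, axis=0)
    for b in range(B):
        F = np.concatenate([resp[:, order, b].T, base_rows], axis=0)
        bb, tt, pp = _ols_tstats(X, F)
        beta[:, :, b] = bb[1:].T
        t[:, :, b] = tt[1:].T
        p[:, :, b] = pp[1:].T
    return beta, t, p


def bootstrap_tuned_counts(
    bundle: SessionBundle,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    window: tuple[float, float] = ANALYSIS_WINDOW,
    tuning_bin_width: float = 0.5,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> "BootstrapCounts":
    """Bootstrap the number of tuned channels per condition.

    Each iteration resamples every condition's trials with replacement to
    its original count, refits the full tuning machinery, and counts
    channels tuned (any bin, Holm-corrected).  CIs are percentile
    intervals; condition pairs are tiered by CI non-overlap at
    {95, 97.5, 99}%.
    """
    conds, idx_by_cond, trial_base, resp, centers = _prepare_tuning_inputs(
        bundle, window, tuning_bin_width, baseline_window
    )
    rng = np.random.default_rng(seed)
    C = len(conds)
    counts = np.empty((n_iter, C), dtype=int)
    for it in range(n_iter):
        res_idx = [ix[rng.integers(len(ix), size=len(ix))] for ix in idx_by_cond]
        _, _, p = _fit_counts(conds, res_idx, trial_base, resp)
        tuned = holm_correct(
            p.reshape(p.shape[0], -1), alpha=alpha, axis=-1
        ).reshape(p.shape)
        counts[it] = tuned.any(axis=2).sum(axis=0)
    _, _, p = _fit_counts(conds, idx_by_cond, trial_base, resp)
    tuned = holm_correct(p.reshape(p.shape[0], -1), alpha=alpha, axis=-1).reshape(p.shape)
    point = tuned.any(axis=2).sum(axis=0)
    return BootstrapCounts(
        conditions=list(conds), point=point, samples=counts,
    )


@dataclass
class BootstrapCounts:
    """Bootstrap distribution of tuned-channel counts per condition."""

    conditions: list
    point: np.ndarray               # (C,) full-data counts
    samples: np.ndarray             # (n_iter, C)

    def ci(self, level: float = 0.95) -> np.ndarray:
        q = (1.0 - level) / 2.0
        return np.quantile(self.samples, [q, 1.0 - q], axis=0).T

    def pairwise_tiers(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.conditions)):
            for j in range(i + 1, len(self.conditions)):
                tier = "ns"
                for level, label in TIER_LEVELS:
                    q = (1.0 - level) / 2.0
                    a = np.quantile(self.samples[:, i], [q, 1.0 - q])
                    b = np.quantile(self.samples[:, j], [q, 1.0 - q])
                    if a[0] > b[1] or a[1] < b[0]:
                        tier = label
                        break
                rows.append({
                    "cond_a": self.conditions[i], "cond_b": self.conditions[j],
                    "tier": tier,
                })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        ci = self.ci(0.95)
        return pd.DataFrame({
            "condition": self.conditions,
            "n_tuned": self.point,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
        })


# ----------------------------------------------------------- overlap sets
def _location_of(condition: str) -> str:
    if condition.endswith("a"):
        return "arm"
    if condition.endswith("f"):
        return "finger"
    return "other"


def overlap_sets(
    table: TuningTable,
    array_size: int = 48,
    array_shape: tuple[int, int] = (6, 8),
) -> "OverlapReport":
    """Per-channel condition-membership sets and array-map layout.

    Classifies each tuned channel as arm-only / finger-only / both from
    the locations of the conditions it is tuned to, overall and within
    each touch type, and assigns each channel a position on one of the
    electrode-array grids.
    """
    if array_shape[0] * array_shape[1] < array_size:
        raise ValueError("array_shape too small for array_size")
    tuned_any = table.tuned_any
    conds = table.conditions
    rows = []
    for ch in range(tuned_any.shape[0]):
        members = {conds[j] for j in np.flatnonzero(tuned_any[ch])}
        locs = {_location_of(c) for c in members} - {"other"}
        if not members:
            cls = "untuned"
        elif locs == {"arm"}:
            cls = "arm-only"
        elif locs == {"finger"}:
            cls = "finger-only"
        elif locs >= {"arm", "finger"}:
            cls = "both"
        else:
            cls = "other-only"
        arr = ch // array_size
        within = ch % array_size
        rows.append({
            "channel": ch,
            "conditions": ",".join(sorted(members)),
            "membership": cls,
            "array": arr,
            "row": within // array_shape[1],
            "col": within % array_shape[1],
        })
    frame = pd.DataFrame(rows)
    by_type = {}
    types = sorted({c[:-1] for c in conds if _location_of(c) != "other"})
    for t in types:
        pair = [c for c in conds if c[:-1] == t]
        cols = [conds.index(c) for c in pair]
        sub = tuned_any[:, cols]
        arm = np.array([_location_of(c) == "arm" for c in pair])
        has_arm = sub[:, arm].any(axis=1)
        has_fin = sub[:, ~arm].any(axis=1)
        by_type[t] = {
            "arm-only": int(np.sum(has_arm & ~has_fin)),
            "finger-only": int(np.sum(~has_arm & has_fin)),
            "both": int(np.sum(has_arm & has_fin)),
        }
    return OverlapReport(per_channel=frame, by_touch_type=by_type)


@dataclass
class OverlapReport:
    per_channel: pd.DataFrame
    by_touch_type: dict

    @property
    def counts(self) -> pd.Series:
        tuned = self.per_channel[self.per_channel["membership"] != "untuned"]
        return tuned["membership"].value_counts()


# ---------------------------------------------------------- onset / offset
@dataclass
class OnsetEstimate:
    """Tuned-response onset/offset (bin midpoints, ms re touch onset)."""

    condition: str
    onset_ms: float | None
    offset_ms: float | None
    onset_ci_ms: tuple | None
    offset_ci_ms: tuple | None
    threshold: float
    n_tuned: int
    n_boot_defined: int = 0


def _trace_onset_offset(
    trace: np.ndarray,
    centers: np.ndarray,
    threshold: float,
    search: slice,
    from_peak: bool,
):
    seg = trace[search]
    above = seg > threshold
    if not above.any():
        return None, None
    k_on = int(np.argmax(above))
    onset = float(centers[search][k_on])
    start = int(np.argmax(seg)) if from_peak else k_on
    below = seg[start + 1:] < threshold
    if below.any():
        k_off = start + 1 + int(np.argmax(below))
        offset = float(centers[search][k_off])
    else:
        offset = None
    return onset, offset


def detect_onset_offset(
    bundle: SessionBundle,
    tuned_channels: np.ndarray,
    condition: str,
    n_boot: int = 10000,
    seed: int = 0,
    threshold_pct: float = 95.0,
    search_window: tuple[float, float] = ANALYSIS_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    from_peak: bool = True,
) -> OnsetEstimate:
    """Onset/offset of the tuned-channel average response to a condition.

    The per-trial traces of the tuned channels are averaged (50 ms bins,
    normalized); the threshold is the ``threshold_pct`` percentile of the
    across-trial distribution of baseline-window values of that average.
    Onset is the midpoint of the first bin above threshold in the search
    window; offset the midpoint of the first bin after the peak
    (``from_peak=False``: after onset) to fall below it.  CIs bootstrap
    over trials, re-deriving the threshold each resample.
    """
    tuned_channels = np.asarray(tuned_channels, dtype=int)
    if tuned_channels.size == 0:
        raise ValueError("need at least one tuned channel")
    sub = bundle.select_conditions([condition])
    traces = sub.rates[tuned_channels].mean(axis=0)      # (trials, bins)
    base_sl = sub.bin_slice(baseline_window)
    search = sub.bin_slice(search_window)
    centers = sub.bin_centers

    def estimate(idx: np.ndarray):
        tr = traces[idx]
        thr = float(np.percentile(tr[:, base_sl].ravel(), threshold_pct))
        trace = tr.mean(axis=0)
        on, off = _trace_onset_offset(trace, centers, thr, search, from_peak)
        return on, off, thr

    all_idx = np.arange(traces.shape[0])
    onset, offset, thr = estimate(all_idx)
    rng = np.random.default_rng(seed)
    ons, offs = [], []
    for _ in range(n_boot):
        idx = rng.integers(len(all_idx), size=len(all_idx))
        o, f, _ = estimate(idx)
        if o is not None:
            ons.append(o)
        if f is not None:
            offs.append(f)
    to_ms = lambda v: None if v is None else v * 1000.0
    ci = lambda vals: (
        tuple(np.percentile(vals, [2.5, 97.5]) * 1000.0) if vals else None
    )
    return OnsetEstimate(
        condition=condition,
        onset_ms=to_ms(onset),
        offset_ms=to_ms(offset),
        onset_ci_ms=ci(ons),
        offset_ci_ms=ci(offs),
        threshold=thr,
        n_tuned=int(tuned_channels.size),
        n_boot_defined=len(ons),
    )
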