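"""Spike extraction, binning, baseline normalization and stability checks.

Multi-unit events are threshold crossings of the broadband voltage at
``-3.5 x RMS`` (no spike sorting), binned at 50 ms aligned to touch onset,
and each channel is normalized per run by its mean rate over the pre-touch
baseline window (-4 to -2.5 s).  ``stability_report`` computes the two
waveform SNR metrics and the ITI firing-rate comparisons used to check
that the signal is stable across the two collection sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import SessionBundle
from .design import BASELINE_WINDOW, ITI_WINDOW
from .simulate import BroadbandSnippet


# ------------------------------------------------------------ spike events
def detect_threshold_crossings(
    snippet: BroadbandSnippet | np.ndarray,
    k: float = -3.5,
    lockout: float = 1.0e-3,
    fs: float | None = None,
    robust_rms: bool = False,
) -> np.ndarray:
    """Sample indices of negative threshold crossings at ``k x noise RMS``.

    The threshold is ``k * RMS`` of the trace itself (``robust_rms=True``
    uses the median-absolute-deviation estimate ``median(|x|)/0.6745``
    instead, which is insensitive to the spikes).  An event is the first
    sample below threshold; subsequent crossings within the refractory
    ``lockout`` (default 1 ms) are ignored so one waveform is not counted
    twice.
    """
    if isinstance(snippet, BroadbandSnippet):
        trace = snippet.trace
        fs = snippet.fs if fs is None else fs
    else:
        trace = np.asarray(snippet, dtype=float)
        if fs is None:
            fs = 30000.0
    if trace.size == 0:
        raise ValueError("empty trace")
    if k >= 0:
        raise ValueError("threshold multiplier k must be negative")
    if robust_rms:
        rms = np.median(np.abs(trace)) / 0.6745
    else:
        rms = float(np.sqrt(np.mean(trace**2)))
    if rms == 0.0:
        return np.empty(0, dtype=int)
    threshold = k * rms
    below = trace < threshold
    onsets = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    if onsets.size == 0:
        return onsets
    lock = max(int(round(lockout * fs)), 1)
    kept = [int(onsets[0])]
    for s in onsets[1:]:
        if s - kept[-1] >= lock:
            kept.append(int(s))
    return np.asarray(kept, dtype=int)


def extract_waveforms(
    trace: np.ndarray,
    events: np.ndarray,
    pre: int = 10,
    post: int = 22,
) -> np.ndarray:
    """Event-aligned waveform snippets, (n_events, pre + post) samples."""
    out = []
    for s in np.asarray(events, dtype=int):
        if s - pre < 0 or s + post > len(trace):
            continue
        out.append(trace[s - pre:s + post])
    return np.asarray(out) if out else np.empty((0, pre + post))


def bin_events(
    event_times,
    onset_times,
    epoch: tuple[float, float],
    bin_width: float,
) -> np.ndarray:
    """Bin per-trial event times into touch-onset-aligned rates (Hz).

    ``event_times`` is a sequence (one entry per trial) of event times in
    seconds on the same clock as ``onset_times``.  Bins are half-open
    ``[t, t + width)``; an event exactly at onset falls in ``[0, width)``.
    Events outside the epoch are silently dropped.  Counts are divided by
    the bin width, so 5 events in one 50 ms bin give 100 Hz.
    """
    t0, t1 = epoch
    n_bins = (t1 - t0) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("epoch length must be an integer number of bins")
    n_bins = round(n_bins)
    onset_times = np.asarray(onset_times, dtype=float)
    rates = np.zeros((len(onset_times), n_bins))
    for i, (events, onset) in enumerate(zip(event_times, onset_times)):
        rel = np.asarray(events, dtype=float) - onset
        idx = np.floor((rel - t0) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins) & (rel >= t0) & (rel < t1 - 1e-12)
        np.add.at(rates[i], idx[ok], 1.0)
    return rates / bin_width


# ----------------------------------------------------------- normalization
def normalize_by_baseline(
    bundle: SessionBundle,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> SessionBundle:
    """Divide each channel's rates, within each run, by the across-trial
    mean of the baseline window.

    Channels whose baseline mean is zero in any run are excluded from the
    returned bundle (division undefined; the indices are recorded in
    ``meta['excluded_channels']``).  After normalization the across-trial
    mean of baseline-window bins is exactly 1 per channel per run.
    """
    if bundle.normalized:
        raise ValueError("bundle is already normalized")
    sl = bundle.bin_slice(baseline_window)
    rates = bundle.rates.copy()
    runs = bundle.run_id
    zero_channels: set[int] = set()
    for run in np.unique(runs):
        in_run = runs == run
        base = rates[:, in_run, sl].mean(axis=(1, 2))          # (channels,)
        zero = np.flatnonzero(base == 0)
        zero_channels.update(int(z) for z in zero)
        safe = np.where(base == 0, 1.0, base)
        rates[:, in_run, :] /= safe[:, None, None]
    keep = np.array([c for c in range(bundle.n_channels) if c not in zero_channels])
    meta = dict(bundle.meta)
    meta["excluded_channels"] = sorted(zero_channels)
    meta["kept_channels"] = keep.tolist()
    return SessionBundle(
        rates=rates[keep],
        bin_edges=bundle.bin_edges.copy(),
        trials=bundle.trials.copy(),
        normalized=True,
        meta=meta,
    )


def rebin(bundle: SessionBundle, new_width: float) -> SessionBundle:
    """Rebin to ``new_width`` (an integer multiple of the current width) by
    averaging constituent bins; normalized values stay on the same scale."""
    ratio = new_width / bundle.bin_width
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"new width {new_width} is not an integer multiple of "
            f"{bundle.bin_width}"
        )
    if factor == 1:
        return bundle
    n_bins = bundle.n_bins
    usable = (n_bins // factor) * factor
    rates = bundle.rates[:, :, :usable]
    shape = rates.shape[:2] + (usable // factor, factor)
    rates = rates.reshape(shape).mean(axis=3)
    edges = bundle.bin_edges[: usable + 1 : factor]
    return SessionBundle(
        rates=rates,
        bin_edges=edges,
        trials=bundle.trials.copy(),
        normalized=bundle.normalized,
        meta=dict(bundle.meta),
    )


# -------------------------------------------------------- stability checks
@dataclass
class SnrReport:
    """Across-set signal-stability report.

    metric1: per-channel ratio of the mean waveform's trough magnitude to
    the noise RMS.  metric2: per-channel ratio of the mean waveform's
    trough magnitude to the across-event SD at the trough sample.  Both
    are averaged across runs within each set and compared across sets with
    a paired Wilcoxon sign-rank test, as are the normalized ITI firing-
    rate means and SDs.
    """

    metric1: dict = field(default_factory=dict)      # set -> (channels,) array
    metric2: dict = field(default_factory=dict)
    iti_mean: dict = field(default_factory=dict)
    iti_sd: dict = field(default_factory=dict)
    p_metric1: float = np.nan
    p_metric2: float = np.nan
    p_iti_mean: float = np.nan
    p_iti_sd: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, per_set, p in (
            ("snr_peak_over_rms", self.metric1, self.p_metric1),
            ("snr_peak_over_sd", self.metric2, self.p_metric2),
            ("iti_mean", self.iti_mean, self.p_iti_mean),
            ("iti_sd", self.iti_sd, self.p_iti_sd),
        ):
            if not per_set:
                continue
            for s, vals in per_set.items():
                rows.append({
                    "metric": name, "set": s,
                    "mean": float(np.nanmean(vals)), "p_signrank": p,
                })
        return pd.DataFrame(rows)


def _signrank(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Wilcoxon sign-rank p; 1.0 when all differences are zero."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[np.isfinite(d)]
    if d.size == 0 or np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d).pvalue)


def snr_metrics(waveforms_by_run) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel SNR metrics from per-run waveform arrays.

    ``waveforms_by_run``: sequence over runs of sequences over channels of
    (n_events, n_samples) arrays.  Returns (metric1, metric2), each of
    shape (n_channels,), averaged across runs with >= 1 event.
    """
    n_ch = len(waveforms_by_run[0])
    m1 = np.full((len(waveforms_by_run), n_ch), np.nan)
    m2 = np.full((len(waveforms_by_run), n_ch), np.nan)
    for r, per_channel in enumerate(waveforms_by_run):
        for ch, wf in enumerate(per_channel):
            wf = np.asarray(wf, float)
            if wf.size == 0 or wf.shape[0] == 0:
                continue
            mean_wf = wf.mean(axis=0)
            trough = int(np.argmin(mean_wf))
            peak = abs(mean_wf[trough])
            resid = wf - mean_wf
            noise_rms = float(np.sqrt(np.mean(resid**2)))
            sd_trough = float(wf[:, trough].std(ddof=1)) if wf.shape[0] > 1 else np.nan
            m1[r, ch] = peak / noise_rms if noise_rms > 0 else np.inf
            m2[r, ch] = peak / sd_trough if sd_trough and sd_trough > 0 else np.inf
    with np.errstate(invalid="ignore"):
        return np.nanmean(m1, axis=0), np.nanmean(m2, axis=0)


def iti_statistics(
    bundle: SessionBundle,
    iti_window: tuple[float, float] = ITI_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD of run-baseline-normalized ITI rates,
    averaged across trials and runs (computed on an unnormalized bundle)."""
    sl_iti = bundle.bin_slice(iti_window)
    sl_base = bundle.bin_slice(baseline_window)
    runs = bundle.run_id
    means, sds = [], []
    for run in np.unique(runs):
        in_run = runs == run
        base = bundle.rates[:, in_run, sl_base].mean(axis=(1, 2))
        safe = np.where(base == 0, np.nan, base)
        norm = bundle.rates[:, in_run, sl_iti] / safe[:, None, None]
        means.append(norm.mean(axis=(1, 2)))
        sds.append(norm.std(axis=(1, 2), ddof=1))
    return np.nanmean(means, axis=0), np.nanmean(sds, axis=0)


def stability_report(
    bundle_set1: SessionBundle,
    bundle_set2: SessionBundle,
    waveforms_set1=None,
    waveforms_set2=None,
) -> SnrReport:
    """Compare signal fundamentals across the two collection sets.

    Waveform arguments (per-run, per-channel snippet arrays; optional)
    drive the two SNR metrics; the ITI comparisons come from the bundles'
    unnormalized rates.  Channels must match across sets.
    """
    if bundle_set1.n_channels != bundle_set2.n_channels:
        raise ValueError("channel count differs between sets")
    report = SnrReport()
    if waveforms_set1 is not None and waveforms_set2 is not None:
        m1_a, m2_a = snr_metrics(waveforms_set1)
        m1_b, m2_b = snr_metrics(waveforms_set2)
        report.metric1 = {1: m1_a, 2: m1_b}
        report.metric2 = {1: m2_a, 2: m2_b}
        report.p_metric1 = _signrank(m1_a, m1_b)
        report.p_metric2 = _signrank(m2_a, m2_b)
    mean1, sd1 = iti_statistics(bundle_set1)
    mean2, sd2 = iti_statistics(bundle_set2)
    report.iti_mean = {1: mean1, 2: mean2}
    report.iti_sd = {1: sd1, 2: sd2}
    report.p_iti_mean = _signrank(mean1, mean2)
    report.p_iti_sd = _signrank(sd1, sd2)
    return report
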