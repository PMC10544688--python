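"""Synthetic session generator with planted, recoverable structure.

Emulates a 96-channel (two 48-channel arrays) intracortical multi-unit
recording during the visuotactile touch task: per channel and condition a
multiplicative response gain, an onset latency, and an exponential decay
after touch offset, riding on a per-channel baseline rate with shared
across-channel Gaussian noise.  The planted parameters (``GroundTruth``)
are returned alongside the data so every downstream analysis can be scored
against what was actually injected.

The response kernel is rectangular-rise / exponential-decay: zero before
the latency, one from latency until touch offset, then ``exp(-(t-D)/tau)``.
Within each bin the kernel is integrated analytically, so a latency that
falls mid-bin elevates that bin by the covered fraction — this is what
makes sub-bin latencies recoverable at the correct bin midpoint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import SessionBundle
from .design import TaskDesign


@dataclass
class GroundTruth:
    """Planted generative parameters of one simulated session.

    ``gain`` is multiplicative response amplitude (1 = no modulation);
    entries with ``gain >= tuned_threshold`` define the planted tuned mask.
    """

    baseline_rate: np.ndarray            # (n_channels,) Hz
    gain: np.ndarray                     # (n_channels, n_conditions)
    latency: np.ndarray                  # (n_channels, n_conditions) s
    decay_tau: np.ndarray                # (n_channels, n_conditions) s
    noise_cov: np.ndarray                # (n_channels, n_channels) Hz^2
    tuned_threshold: float = 1.2
    n_arrays: int = 2

    def __post_init__(self) -> None:
        self.baseline_rate = np.atleast_1d(np.asarray(self.baseline_rate, float))
        self.gain = np.asarray(self.gain, float)
        self.latency = np.asarray(self.latency, float)
        self.decay_tau = np.asarray(self.decay_tau, float)
        self.noise_cov = np.asarray(self.noise_cov, float)
        n_ch = self.baseline_rate.shape[0]
        for name in ("gain", "latency", "decay_tau"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[0] != n_ch:
                raise ValueError(f"{name} must be (n_channels, n_conditions)")
        if self.noise_cov.shape != (n_ch, n_ch):
            raise ValueError("noise_cov must be (n_channels, n_channels)")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        eigmin = np.linalg.eigvalsh(self.noise_cov)[0]
        if eigmin < -1e-8 * max(1.0, np.abs(self.noise_cov).max()):
            raise ValueError("noise_cov must be positive semi-definite")

    @property
    def n_channels(self) -> int:
        return self.baseline_rate.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.gain.shape[1]

    @property
    def tuned_mask(self) -> np.ndarray:
        """Boolean (channel, condition): planted gain above threshold."""
        return self.gain >= self.tuned_threshold


def make_ground_truth(
    design: TaskDesign,
    n_channels: int = 96,
    baseline_rate: float = 10.0,
    noise_sd: float = 3.0,
    noise_corr: float = 0.2,
    latency: float = 0.0,
    decay_tau: float = 0.3,
    gains: dict | None = None,
    latencies: dict | None = None,
    tuned_threshold: float = 1.2,
) -> GroundTruth:
    """Construct a GroundTruth with uniform defaults and planted effects.

    ``gains`` / ``latencies`` map condition code -> either a scalar (applied
    to all channels) or an ``(channel_indices, value)`` pair planting the
    effect on a subset of channels.  All unspecified entries stay at gain 1
    (no modulation) and the default latency.

    The default noise covariance is ``noise_sd**2 * ((1-c) I + c J)`` — a
    shared (uniformly correlated, c = ``noise_corr``) Gaussian rate noise
    across channels, emulating common-mode fluctuations of an array.
    """
    n_cond = design.n_conditions
    cond_index = {c: i for i, c in enumerate(design.conditions)}
    gain = np.ones((n_channels, n_cond))
    lat = np.full((n_channels, n_cond), float(latency))
    tau = np.full((n_channels, n_cond), float(decay_tau))
    for source, target in ((gains, gain), (latencies, lat)):
        if not source:
            continue
        for cond, value in source.items():
            j = cond_index[cond]
            if isinstance(value, tuple):
                channels, v = value
                target[np.asarray(channels), j] = v
            else:
                target[:, j] = value
    if np.any(lat < -design.visual_lead - 1e-12):
        raise ValueError("latency may not precede the visual lead window")
    cov = noise_sd**2 * (
        (1.0 - noise_corr) * np.eye(n_channels)
        + noise_corr * np.ones((n_channels, n_channels))
    )
    return GroundTruth(
        baseline_rate=np.full(n_channels, float(baseline_rate)),
        gain=gain,
        latency=lat,
        decay_tau=tau,
        noise_cov=cov,
        tuned_threshold=tuned_threshold,
    )


def response_fraction(
    bin_edges: np.ndarray,
    latency: float,
    touch_duration: float,
    decay_tau: float,
) -> np.ndarray:
    """Mean of the response kernel over each bin (exact integrals).

    Kernel: 0 for t < latency, 1 for latency <= t < D, exp(-(t-D)/tau)
    for t >= D, with D = touch_duration.
    """
    t0 = np.asarray(bin_edges[:-1], float)
    t1 = np.asarray(bin_edges[1:], float)
    width = t1 - t0
    D = touch_duration
    rect = np.clip(np.minimum(t1, D) - np.maximum(t0, latency), 0.0, None)
    lo = np.maximum(t0, D)
    decay = np.where(
        t1 > D,
        decay_tau * (np.exp(-(lo - D) / decay_tau) - np.exp(-(t1 - D) / decay_tau)),
        0.0,
    )
    # the decay integral only applies once the response has begun
    decay = np.where(latency < t1, decay, 0.0)
    return (rect + decay) / width


def simulate_session(
    design: TaskDesign,
    truth: GroundTruth,
    seed: int,
    poisson: bool = False,
    set2_rate_drift: float = 1.0,
    set2_noise_drift: float = 1.0,
) -> tuple[SessionBundle, GroundTruth]:
    """Simulate one session bundle under ``design`` with planted ``truth``.

    Noise-free rate: ``baseline * (1 + (gain-1) * kernel(t))`` for the
    trial's condition, plus correlated Gaussian noise drawn independently
    per (trial, bin) from ``truth.noise_cov``, floored at zero.  With
    ``poisson=True`` the rates additionally pass through a Poisson count
    stage at the bin width.

    Two optional across-set drifts exercise the stability checks:
    ``set2_rate_drift`` multiplies all rates of set-2 trials (removed by
    run-wise baseline normalization, visible in raw rates), and
    ``set2_noise_drift`` scales their noise amplitude (visible in the
    normalized ITI variability).

    Catch trials (one per run, labelled with a different condition and
    flagged ``is_catch``) are generated but meant to be excluded from every
    analysis.  Identical ``(design, truth, seed)`` give a bit-identical
    bundle.
    """
    if truth.n_conditions != design.n_conditions:
        raise ValueError(
            "GroundTruth condition axis does not match the design "
            f"({truth.n_conditions} != {design.n_conditions})"
        )
    rng = np.random.default_rng(seed)
    n_ch = truth.n_channels
    n_bins = design.n_bins
    edges = np.asarray(design.bin_edges)
    conds = design.conditions
    n_cond = len(conds)

    # noise-free per-condition templates: (cond, channel, bin)
    template = np.empty((n_cond, n_ch, n_bins))
    for j in range(n_cond):
        for ch in range(n_ch):
            frac = response_fraction(
                edges, truth.latency[ch, j], design.touch_duration,
                truth.decay_tau[ch, j],
            )
            template[j, ch] = truth.baseline_rate[ch] * (
                1.0 + (truth.gain[ch, j] - 1.0) * frac
            )

    # trial schedule: runs interleaved across conditions, one catch per run
    rows = []
    trial_conditions = []
    clock = 0.0
    trial_id = 0
    run_global = 0
    for run_in_cond in range(design.runs_per_condition):
        for j, cond in enumerate(conds):
            n_in_run = design.trials_per_run + design.catch_per_run
            catch_slots = (
                rng.choice(n_in_run, size=design.catch_per_run, replace=False)
                if design.catch_per_run else np.empty(0, int)
            )
            for slot in range(n_in_run):
                is_catch = slot in catch_slots
                if is_catch:
                    others = [c for c in conds if c != cond] or [cond]
                    trial_cond = others[int(rng.integers(len(others)))]
                else:
                    trial_cond = cond
                jit = rng.uniform(*design.iti_jitter)
                clock += design.iti + jit
                rows.append(
                    (trial_id, trial_cond, run_global, design.set_of(cond),
                     bool(is_catch), clock)
                )
                trial_conditions.append(trial_cond)
                clock += design.touch_duration + 1.0
                trial_id += 1
            run_global += 1
    trials = pd.DataFrame(
        rows, columns=["trial_id", "condition", "run", "set", "is_catch",
                       "onset_time"],
    )

    cond_index = {c: i for i, c in enumerate(conds)}
    cond_idx = np.array([cond_index[c] for c in trial_conditions])
    n_trials = len(cond_idx)

    # mean rates (channel, trial, bin), then correlated noise per (trial, bin)
    rates = template[cond_idx].transpose(1, 0, 2).copy()
    scale = np.trace(truth.noise_cov) / n_ch
    if scale > 0:
        chol = np.linalg.cholesky(
            truth.noise_cov + 1e-10 * scale * np.eye(n_ch)
        )
        z = rng.standard_normal((n_trials * n_bins, n_ch))
        noise = (z @ chol.T).T.reshape(n_ch, n_trials, n_bins)
    else:
        noise = np.zeros_like(rates)
    in_set2 = trials["set"].to_numpy() == 2
    if set2_noise_drift != 1.0:
        noise[:, in_set2, :] *= set2_noise_drift
    rates = np.clip(rates + noise, 0.0, None)
    if set2_rate_drift != 1.0:
        rates[:, in_set2, :] *= set2_rate_drift
    if poisson:
        counts = rng.poisson(rates * design.bin_width)
        rates = counts / design.bin_width

    bundle = SessionBundle(
        rates=rates,
        bin_edges=edges,
        trials=trials,
        normalized=False,
        meta={"design": design.to_dict(), "seed": int(seed)},
    )
    return bundle, truth


# --------------------------------------------------------------- broadband
@dataclass
class BroadbandSnippet:
    """Short 30 kHz voltage trace with planted spike waveforms."""

    trace: np.ndarray
    fs: float = 30000.0
    planted_spike_times: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    noise_rms: float = 0.0


def spike_template(fs: float = 30000.0, duration: float = 1.0e-3) -> np.ndarray:
    """Stereotyped extracellular waveform, normalized to a minimum of -1.

    One-sample downstroke to the trough (so a threshold crossing pins the
    planted time to within a sample), then an exponential recovery with a
    small positive rebound, ~1 ms long.
    """
    n = max(int(round(duration * fs)), 8)
    t = np.arange(n, dtype=float)
    w = np.zeros(n)
    w[1:] = -np.exp(-(t[1:] - 1.0) / (0.15e-3 * fs)) \
        + 0.25 * np.exp(-(t[1:] - 1.0) / (0.45e-3 * fs)) \
        * (1.0 - np.exp(-(t[1:] - 1.0) / (0.1e-3 * fs)))
    return w / -w.min()


def simulate_broadband(
    spike_times,
    n_samples: int,
    noise_rms: float,
    spike_amp: float,
    seed: int = 0,
    fs: float = 30000.0,
) -> BroadbandSnippet:
    """White noise of the stated RMS with negative spikes planted at
    ``spike_times`` (sample indices of the waveform trough).

    ``spike_amp`` is the trough voltage (negative).  Overlapping waveforms
    are rejected so planted events can be scored one-to-one against
    detections.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=int))
    if spike_amp > 0:
        raise ValueError("spike_amp must be negative (trough voltage)")
    template = spike_amp * -spike_template(fs)  # trough = spike_amp
    trough = int(np.argmin(template))
    n_w = len(template)
    if spike_times.size:
        if spike_times.min() - trough < 0 or spike_times.max() - trough + n_w > n_samples:
            raise ValueError("spike times out of range for the trace length")
        if np.any(np.diff(spike_times) < n_w):
            raise ValueError("planted spike waveforms overlap; space them out")
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_rms, size=n_samples) if noise_rms > 0 else np.zeros(n_samples)
    for s in spike_times:
        start = s - trough
        trace[start:start + n_w] += template
    return BroadbandSnippet(
        trace=trace, fs=fs,
        planted_spike_times=spike_times,
        noise_rms=float(noise_rms),
    )
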