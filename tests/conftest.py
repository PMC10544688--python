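"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import touchdecode as td
from touchdecode.bundle import SessionBundle


@pytest.fixture(scope="session")
def small_design():
    """Three-condition design, cheap to simulate."""
    return td.make_task_design(
        conditions=("FPa", "FPf", "BLa"), runs_per_condition=3,
    )


@pytest.fixture(scope="session")
def planted_session():
    """Full-size session with a strong planted response to FPa.

    Gain 3 on channels 0-29, latency 125 ms; everything else unmodulated.
    Returned pre-normalized with catch trials dropped, alongside truth.
    """
    design = td.make_task_design()
    truth = td.make_ground_truth(
        design,
        gains={"FPa": (list(range(30)), 3.0)},
        latencies={"FPa": (list(range(30)), 0.125)},
    )
    raw, truth = td.simulate_session(design, truth, seed=11)
    bundle = td.normalize_by_baseline(raw.drop_catch())
    return bundle, truth


def make_flat_bundle(values, conditions, trials_per_cond, n_runs=2,
                     bin_edges=None, normalized=True):
    """Hand-built bundle: ``values`` is (channels, trials, bins)."""
    values = np.asarray(values, dtype=float)
    n_trials = values.shape[1]
    labels = np.repeat(conditions, trials_per_cond)
    assert len(labels) == n_trials
    per_run = max(trials_per_cond // n_runs, 1)
    runs = []
    for c_i in range(len(conditions)):
        for j in range(trials_per_cond):
            runs.append(c_i * n_runs + min(j // per_run, n_runs - 1))
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": labels,
        "run": runs,
        "set": 1,
        "is_catch": False,
        "onset_time": np.arange(n_trials, dtype=float) * 10.0,
    })
    if bin_edges is None:
        bin_edges = np.arange(values.shape[2] + 1) * 0.5
    return SessionBundle(rates=values, bin_edges=bin_edges, trials=trials,
                         normalized=normalized)
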