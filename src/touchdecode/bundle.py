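"""SessionBundle: the trial-aligned tensor of binned multi-unit rates.

All analyses consume this container: a ``channel x trial x bin`` array of
firing rates aligned to touch onset, a per-trial table (condition, run,
set, catch flag, onset time) and the bin grid.  Bins are half-open
``[t, t + width)`` with a boundary exactly at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["trial_id", "condition", "run", "set", "is_catch", "onset_time"]


@dataclass
class SessionBundle:
    """Binned, touch-onset-aligned firing rates plus per-trial labels."""

    rates: np.ndarray                 # (n_channels, n_trials, n_bins)
    bin_edges: np.ndarray             # (n_bins + 1,) seconds rel. touch onset
    trials: pd.DataFrame              # one row per trial (TRIAL_COLUMNS)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (channels, trials, bins)")
        n_ch, n_tr, n_bins = self.rates.shape
        if len(self.bin_edges) != n_bins + 1:
            raise ValueError("bin_edges length must be n_bins + 1")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bins must be strictly increasing and uniform")
        if len(self.trials) != n_tr:
            raise ValueError("trials table length must match rates axis 1")
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trials table missing columns: {sorted(missing)}")
        self.trials = self.trials.reset_index(drop=True)

    # ------------------------------------------------------------------ shape
    @property
    def n_channels(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def conditions(self) -> list[str]:
        """Condition codes present, in first-appearance order."""
        return list(dict.fromkeys(self.trials["condition"]))

    @property
    def labels(self) -> np.ndarray:
        return self.trials["condition"].to_numpy()

    @property
    def run_id(self) -> np.ndarray:
        return self.trials["run"].to_numpy()

    @property
    def set_id(self) -> np.ndarray:
        return self.trials["set"].to_numpy()

    # -------------------------------------------------------------- selection
    def bin_slice(self, window: tuple[float, float]) -> slice:
        """Index slice of bins whose full extent lies inside ``window``."""
        lo = int(np.searchsorted(self.bin_edges, window[0] - 1e-9))
        hi = int(np.searchsorted(self.bin_edges, window[1] + 1e-9)) - 1
        if hi <= lo:
            raise ValueError(f"window {window} contains no complete bin")
        return slice(lo, hi)

    def drop_catch(self) -> "SessionBundle":
        """Remove catch trials; analyses operate on the result."""
        keep = ~self.trials["is_catch"].to_numpy(dtype=bool)
        return SessionBundle(
            rates=self.rates[:, keep, :],
            bin_edges=self.bin_edges.copy(),
            trials=self.trials.loc[keep].reset_index(drop=True),
            normalized=self.normalized,
            meta=dict(self.meta),
        )

    def select_trials(self, mask: np.ndarray) -> "SessionBundle":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            full = np.zeros(self.n_trials, dtype=bool)
            full[mask] = True
            mask = full
        return SessionBundle(
            rates=self.rates[:, mask, :],
            bin_edges=self.bin_edges.copy(),
            trials=self.trials.loc[mask].reset_index(drop=True),
            normalized=self.normalized,
            meta=dict(self.meta),
        )

    def select_conditions(self, conditions) -> "SessionBundle":
        unknown = set(conditions) - set(self.trials["condition"])
        if unknown:
            raise KeyError(f"unknown condition code(s): {sorted(unknown)}")
        return self.select_trials(self.trials["condition"].isin(conditions).to_numpy())

    def select_channels(self, channels: np.ndarray) -> "SessionBundle":
        return SessionBundle(
            rates=self.rates[np.asarray(channels), :, :],
            bin_edges=self.bin_edges.copy(),
            trials=self.trials.copy(),
            normalized=self.normalized,
            meta=dict(self.meta),
        )

    # --------------------------------------------------------------------- IO
    def save(self, directory) -> Path:
        """Write the bundle as a directory: JSON metadata + NPY tensor + CSV
        trials table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "rates.npy", self.rates)
        self.trials.to_csv(directory / "trials.csv", index=False)
        meta = {
            "bin_edges": self.bin_edges.tolist(),
            "normalized": bool(self.normalized),
            "meta": _jsonable(self.meta),
        }
        with open(directory / "bundle.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        return directory

    @classmethod
    def load(cls, directory, for_analysis: bool = False) -> "SessionBundle":
        """Load a bundle directory; ``for_analysis=True`` drops catch trials."""
        directory = Path(directory)
        with open(directory / "bundle.json") as fh:
            meta = json.load(fh)
        bundle = cls(
            rates=np.load(directory / "rates.npy"),
            bin_edges=np.asarray(meta["bin_edges"]),
            trials=pd.read_csv(directory / "trials.csv"),
            normalized=meta["normalized"],
            meta=meta.get("meta", {}),
        )
        return bundle.drop_catch() if for_analysis else bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
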