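"""Task design: conditions, trial counts and the trial timeline.

The paradigm delivers 1-second stroking touches to the arm, the finger, or
an object under nine multisensory conditions (seen physical touch, blind
physical touch, purely visual touch in VR, observed third-person touch, and
observed object touch).  Each condition is collected as 7 runs of 10 trials
plus one catch trial per run, for 70 analyzable trials per condition.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

#: Canonical condition codes: modality x location.  Suffix "a" = arm,
#: "f" = finger.  FP = seen physical touch, BL = blindfolded physical touch,
#: VrFP = virtual (visual-only) touch, TP = observed third-person touch,
#: Obj = observed object touch.
CONDITIONS: tuple[str, ...] = (
    "FPa", "FPf", "BLa", "BLf", "VrFPa", "VrFPf", "TPa", "TPf", "Obj",
)

#: Conditions with a physical touch component.
PHYSICAL_CONDITIONS: frozenset[str] = frozenset({"FPa", "FPf", "BLa", "BLf"})

#: Collection-epoch ("set") membership: first-person, third-person and object
#: touches were collected in set 1; blind and VR touches in set 2.
SET_OF_CONDITION: dict[str, int] = {
    "FPa": 1, "FPf": 1, "TPa": 1, "TPf": 1, "Obj": 1,
    "BLa": 2, "BLf": 2, "VrFPa": 2, "VrFPf": 2,
}

#: Pre-touch window used for baseline normalization (s, touch-onset aligned).
BASELINE_WINDOW: tuple[float, float] = (-4.0, -2.5)

#: Window over which tuning, onsets and decoding are assessed.
ANALYSIS_WINDOW: tuple[float, float] = (-1.0, 2.0)

#: Inter-trial-interval window used for the stability checks.
ITI_WINDOW: tuple[float, float] = (-4.0, -1.0)


@dataclass(frozen=True)
class TaskDesign:
    """Immutable description of the trial structure of one session bundle.

    Defaults reproduce the study design: 9 conditions x 7 runs x 10 trials
    (+1 catch per run), 50 ms bins over a [-4, +2] s epoch around touch
    onset, 5 s ITI with 0-3 s jitter, 1 s touch, and visual-approach
    information starting 0.5 s before onset in visual conditions.
    """

    conditions: tuple[str, ...] = CONDITIONS
    runs_per_condition: int = 7
    trials_per_run: int = 10
    catch_per_run: int = 1
    bin_width: float = 0.05
    epoch: tuple[float, float] = (-4.0, 2.0)
    iti: float = 5.0
    iti_jitter: tuple[float, float] = (0.0, 3.0)
    touch_duration: float = 1.0
    visual_lead: float = 0.5

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        if not self.conditions:
            raise ValueError("at least one condition required")
        if self.runs_per_condition < 1 or self.trials_per_run < 1:
            raise ValueError("runs_per_condition and trials_per_run must be >= 1")
        if self.catch_per_run < 0:
            raise ValueError("catch_per_run must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        t0, t1 = self.epoch
        if t1 <= t0:
            raise ValueError("epoch end must exceed epoch start")
        n = (t1 - t0) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"bin_width {self.bin_width} does not divide epoch {self.epoch}"
            )
        if t0 > BASELINE_WINDOW[0] or t1 < ANALYSIS_WINDOW[1]:
            raise ValueError(
                "epoch must contain the baseline window [-4, -2.5] and the "
                "analysis window [-1, +2]"
            )

    @property
    def n_bins(self) -> int:
        return round((self.epoch[1] - self.epoch[0]) / self.bin_width)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def trials_per_condition(self) -> int:
        """Analyzable (non-catch) trials per condition."""
        return self.runs_per_condition * self.trials_per_run

    @property
    def n_trials(self) -> int:
        """Total trials including catch trials."""
        per_run = self.trials_per_run + self.catch_per_run
        return self.n_conditions * self.runs_per_condition * per_run

    @property
    def bin_edges(self) -> "list[float]":
        t0 = self.epoch[0]
        return [t0 + i * self.bin_width for i in range(self.n_bins + 1)]

    def set_of(self, condition: str) -> int:
        return SET_OF_CONDITION.get(condition, 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["epoch"] = list(self.epoch)
        d["iti_jitter"] = list(self.iti_jitter)
        return d


def make_task_design(**overrides) -> TaskDesign:
    """Build a :class:`TaskDesign`, overriding any subset of its fields.

    Raises ``TypeError`` for unknown field names and ``ValueError`` for
    inconsistent values (e.g. a bin width that does not divide the epoch).
    """
    known = {f.name for f in dataclasses.fields(TaskDesign)}
    unknown = set(overrides) - known
    if unknown:
        raise TypeError(f"unknown TaskDesign field(s): {sorted(unknown)}")
    for key in ("conditions", "epoch", "iti_jitter"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    return TaskDesign(**overrides)
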