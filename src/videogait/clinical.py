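"""Condition-specific clinical metrics and aggregation.

Step parameters follow the paretic/left convention used for hemiparetic
gait: a paretic (or left) step ends at the paretic/left heel-strike, its
step time running from the preceding non-paretic/right heel-strike and its
torso-travel step length covering the same interval. Asymmetry indices are
(side A − side B)/(side A + side B) with side A the paretic (or left) side,
so 0 is symmetric and the sign marks the larger side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvents

#: Step parameters summarized at trial and session level.
STEP_PARAMETERS = ("step_time_s", "step_length_m", "speed_mps")


def asymmetry(values_a, values_b) -> float:
    """Asymmetry index (mean_a − mean_b)/(mean_a + mean_b).

    Side A is the paretic (stroke) or left side. Undefined (error) when the
    sum of the side means is not positive.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sides need at least one step")
    ma, mb = float(np.nanmean(a)), float(np.nanmean(b))
    if ma + mb <= 0:
        raise ValueError("asymmetry undefined for nonpositive side means")
    return (ma - mb) / (ma + mb)


def assign_step_sides(events: GaitEvents) -> pd.DataFrame:
    """Label steps by the side of the terminating heel-strike.

    Returns one row per consecutive heel-strike pair with the step time and
    side; pairs of same-side strikes are flagged invalid rather than
    silently dropped.
    """
    times, sides = events.merged_heel_strikes()
    rows = []
    for k in range(1, times.size):
        rows.append(
            {
                "side": str(sides[k]),
                "t_start_s": float(times[k - 1]),
                "t_end_s": float(times[k]),
                "step_time_s": float(times[k] - times[k - 1]),
                "valid": bool(sides[k] != sides[k - 1]),
            }
        )
    return pd.DataFrame(
        rows, columns=["side", "t_start_s", "t_end_s", "step_time_s", "valid"]
    )


@dataclass
class SessionSummary:
    """Session-level averages of one condition (preferred or fast speed)."""

    condition: str
    parameters: dict[str, float]
    n_trials: int
    n_steps: int
    per_trial: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_trials": self.n_trials,
            "n_steps": self.n_steps,
            **self.parameters,
        }


def trial_means(steps: pd.DataFrame) -> pd.DataFrame:
    """Mean of each step parameter per trial (valid steps only)."""
    valid = steps[steps["valid"]] if "valid" in steps else steps
    cols = [c for c in STEP_PARAMETERS if c in valid.columns]
    grouped = valid.groupby("trial_id")[cols].mean()
    grouped["n_steps"] = valid.groupby("trial_id").size()
    for side_col, side in (("asymmetry_step_length", "step_length_m"),
                           ("asymmetry_step_time", "step_time_s")):
        if side in valid.columns and "side" in valid.columns:
            vals = {}
            for trial_id, grp in valid.groupby("trial_id"):
                left = grp.loc[grp["side"] == "left", side]
                right = grp.loc[grp["side"] == "right", side]
                if len(left) and len(right):
                    vals[trial_id] = asymmetry(left, right)
                else:
                    vals[trial_id] = np.nan
            grouped[side_col] = pd.Series(vals)
    return grouped


def session_summary(
    trials: list[pd.DataFrame] | pd.DataFrame,
    condition: str = "preferred",
    *,
    pooled: bool = False,
) -> SessionSummary:
    """Session-level averages over gait trials.

    Default aggregation is the mean of trial means (every trial weighted
    equally, matching a clinical session of repeated walking bouts);
    ``pooled=True`` instead averages over all steps of the session, the
    step-level alternative. Asymmetry indices are computed per trial and
    averaged, in either mode.
    """
    if isinstance(trials, list):
        if not trials:
            raise ValueError("session_summary needs at least one trial")
        steps = pd.concat(trials, ignore_index=True)
    else:
        steps = trials
    if "condition" in steps.columns:
        steps = steps[steps["condition"] == condition]
    valid = steps[steps["valid"]] if "valid" in steps else steps
    if valid.empty:
        raise ValueError(f"no valid steps for condition {condition!r}")
    per_trial = trial_means(valid)
    params: dict[str, float] = {}
    for col in per_trial.columns:
        if col == "n_steps":
            continue
        if pooled and col in STEP_PARAMETERS:
            params[col] = float(valid[col].mean())
        else:
            params[col] = float(per_trial[col].mean())
    if "inclination_deg" in valid.columns:
        per_trial_incl = valid.groupby("trial_id")["inclination_deg"].mean()
        params["inclination_deg"] = float(per_trial_incl.mean())
    return SessionSummary(
        condition=condition,
        parameters=params,
        n_trials=int(per_trial.shape[0]),
        n_steps=int(valid.shape[0]),
        per_trial=per_trial,
    )


@dataclass
class SpeedChange:
    """Fast-minus-preferred deltas of the session parameters."""

    deltas: dict[str, float]

    def to_dict(self) -> dict:
        return dict(self.deltas)


def speed_change(pref: SessionSummary, fast: SessionSummary) -> SpeedChange:
    """Elementwise fast − preferred of the session-level parameters.

    Parameters present in only one condition are omitted from the output.
    """
    deltas = {
        key: fast.parameters[key] - pref.parameters[key]
        for key in pref.parameters
        if key in fast.parameters
        and np.isfinite(pref.parameters[key])
        and np.isfinite(fast.parameters[key])
    }
    return SpeedChange(deltas=deltas)
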