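"""Between-system agreement statistics: Bland–Altman style differences,
errors, 95% limits of agreement, Pearson correlation, and mean absolute
error of time-normalized kinematic waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Gait-cycle phase grid: 0–100% in 1% increments.
CYCLE_SAMPLES = 101


@dataclass
class AgreementReport:
    """Summary of paired differences between two measurement systems.

    Differences are ``x − y``. The 95% limits of agreement are
    ``mean_diff ± 1.96 · sd_diff`` and are expected to contain 95% of
    between-system differences under normality.
    """

    mean_diff: float
    sd_diff: float
    mean_abs_error: float
    sd_abs_error: float
    loa_low: float
    loa_high: float
    pearson_r: float  # NaN when undefined (zero variance)
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "mean_abs_error": self.mean_abs_error,
            "sd_abs_error": self.sd_abs_error,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "n": self.n,
        }


def agreement(x, y) -> AgreementReport:
    """Agreement statistics on paired measurements of the same quantity.

    ``x`` and ``y`` must be equal-length (n ≥ 2) and paired by matched
    cycles, trials, or sessions. Pearson r is reported as NaN when either
    input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("agreement needs at least 2 pairs")
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    abs_err = np.abs(d)
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return AgreementReport(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mean_abs_error=float(np.mean(abs_err)),
        sd_abs_error=float(np.std(abs_err, ddof=1)),
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        n=int(x.size),
    )


def normalize_cycle(
    t: np.ndarray, values: np.ndarray, t_start: float, t_end: float, n: int = CYCLE_SAMPLES
) -> np.ndarray:
    """Resample one gait cycle onto a 0–100% phase grid of ``n`` points by
    linear interpolation."""
    if t_end <= t_start:
        raise ValueError("cycle end must follow cycle start")
    phase_t = np.linspace(t_start, t_end, n)
    return np.interp(phase_t, t, values)


def kinematic_mae(
    wave_a: np.ndarray,
    wave_b: np.ndarray,
    fps: float,
    cycles: list[tuple[float, float]],
    n: int = CYCLE_SAMPLES,
) -> float:
    """Mean absolute error between two angle waveforms over matched cycles.

    Each cycle ``(t_start, t_end)`` — typically consecutive same-side
    heel-strikes matched across systems — is resampled to ``n`` phase points
    on both waveforms; the MAE is averaged over points, then over cycles.
    Returns NaN when no cycle is usable.
    """
    wave_a = np.asarray(wave_a, dtype=float)
    wave_b = np.asarray(wave_b, dtype=float)
    if wave_a.shape != wave_b.shape:
        raise ValueError("waveforms must share length (common clock)")
    t = np.arange(wave_a.size) / fps
    maes = []
    for t0, t1 in cycles:
        a = normalize_cycle(t, wave_a, t0, t1, n)
        b = normalize_cycle(t, wave_b, t0, t1, n)
        if np.isfinite(a).all() and np.isfinite(b).all():
            maes.append(float(np.mean(np.abs(a - b))))
    return float(np.mean(maes)) if maes else float("nan")


def waveform_mae_table(
    angles_a, angles_b, cycles_by_side: dict[str, list[tuple[float, float]]]
) -> pd.DataFrame:
    """Per-joint, per-side kinematic MAE between two
    :class:`~videogait.sagittal.JointAngleSeries` on a common clock."""
    rows = []
    for joint in ("hip", "knee", "ankle"):
        for side, cycles in cycles_by_side.items():
            rows.append(
                {
                    "joint": joint,
                    "side": side,
                    "mae_deg": kinematic_mae(
                        angles_a.get(joint, side),
                        angles_b.get(joint, side),
                        angles_a.fps,
                        cycles,
                    ),
                    "n_cycles": len(cycles),
                }
            )
    return pd.DataFrame(rows, columns=["joint", "side", "mae_deg", "n_cycles"])


def normalized_cycle_table(
    angles, cycles_by_side: dict[str, list[tuple[float, float]]], n: int = CYCLE_SAMPLES
) -> pd.DataFrame:
    """Time-normalized joint-angle cycles as a long table.

    Each matched cycle of a :class:`~videogait.sagittal.JointAngleSeries`
    is resampled to ``n`` points of gait-cycle phase (0–100%); one row per
    phase sample with columns joint, side, cycle index, phase_pct, angle_deg.
    """
    t = np.arange(angles.hip_left.size) / angles.fps
    phase = np.linspace(0.0, 100.0, n)
    rows = []
    for joint in ("hip", "knee", "ankle"):
        for side, cycles in cycles_by_side.items():
            series = angles.get(joint, side)
            for k, (t0, t1) in enumerate(cycles):
                values = normalize_cycle(t, series, t0, t1, n)
                rows.append(pd.DataFrame({
                    "joint": joint, "side": side, "cycle": k,
                    "phase_pct": phase, "angle_deg": values,
                }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["joint", "side", "cycle", "phase_pct", "angle_deg"]
    )


def cycles_from_matches(pairs: list[tuple[float, float]], *, use: int = 0) -> list[tuple[float, float]]:
    """Build gait cycles from consecutive matched same-side heel-strikes.

    ``pairs`` are (time_a, time_b) matches from cross-referencing; ``use``
    selects which system's clock defines the cycle boundaries (0 = a, 1 = b).
    """
    times = sorted(p[use] for p in pairs)
    return [(times[i], times[i + 1]) for i in range(len(times) - 1)]
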