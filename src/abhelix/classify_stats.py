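"""Conformation classes, endpoint groups, histograms and summary statistics.

Per-frame classification uses the middle-region backbone RMSD against
the initial structure: class 1 (helical) for RMSD < 2.0 A, class 2
(moderately unwound) for 2.0 <= RMSD < 4.0 A, class 3 (highly unwound)
for RMSD >= 4.0 A.  Per-trajectory endpoint groups A/B/C apply the same
intervals to the last-2-ns averages; the alpha-HB ranges attached to the
groups (A: 2-6, B: 1-4, C: ~0) overlap, so the RMSD interval is the
discriminating condition and the alpha-HB range is reported as a
consistency flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_SMALL",
    "CLASS_LARGE",
    "FrameMetrics",
    "TrajectorySummary",
    "ClassContactStats",
    "classify_frame",
    "last_window_average",
    "classify_group",
    "second_half_mask",
    "histogram_rmsd",
    "histogram_ahb",
    "class_contact_stats",
    "binding_timeline",
    "column_summary",
]

CLASS_SMALL = 2.0  # A; below: helical (class 1)
CLASS_LARGE = 4.0  # A; at/above: highly unwound (class 3)

_GROUP_AHB_RANGE = {"A": (2.0, 6.0), "B": (1.0, 4.0)}
_GROUP_C_AHB_MAX = 0.5  # operationalization of "alpha-HB approximately 0"


@dataclass(frozen=True)
class TrajectorySummary:
    """Last-window averages and endpoint group of one trajectory."""

    avg_rmsd_last: float
    avg_ahb_last: float
    group: str
    consistent: bool
    window_ns: float = 2.0


@dataclass(frozen=True)
class ClassContactStats:
    """Per-conformation-class binding fractions and bound-frame averages."""

    fraction_polar: dict[int, float]
    fraction_nonpolar: dict[int, float]
    mean_hb: dict[int, float]
    sd_hb: dict[int, float]
    mean_nonpolar: dict[int, float]
    sd_nonpolar: dict[int, float]
    class_frames: dict[int, int]


# FrameMetrics is represented as a pandas DataFrame with these columns
FrameMetrics = pd.DataFrame
FRAME_METRIC_COLUMNS = [
    "time_ps", "rmsd_mid", "rg_mid", "n_alpha_hb", "n_ligand_hb",
    "n_nonpolar", "conf_class", "polar_bound", "nonpolar_bound",
    "dual_bound",
]


def classify_frame(rmsd_mid: float,
                   small: float = CLASS_SMALL,
                   large: float = CLASS_LARGE) -> int:
    """Conformation class 1/2/3 from the middle-region backbone RMSD."""
    if not math.isfinite(rmsd_mid) or rmsd_mid < 0:
        raise ValueError(f"RMSD must be finite and >= 0, got {rmsd_mid}")
    if rmsd_mid < small:
        return 1
    if rmsd_mid < large:
        return 2
    return 3


def last_window_average(times_ps: np.ndarray, values: np.ndarray,
                        window_ns: float = 2.0) -> float:
    """Mean over frames with time > (end - window)."""
    times_ps = np.asarray(times_ps, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_ps.ndim != 1 or times_ps.shape != values.shape:
        raise ValueError("times and values must be 1-D and equally long")
    window_ps = window_ns * 1000.0
    span = times_ps[-1] - times_ps[0]
    if span < window_ps:
        raise ValueError(
            f"series spans {span / 1000.0:.3f} ns, shorter than the "
            f"{window_ns} ns window"
        )
    mask = times_ps > times_ps[-1] - window_ps
    return float(values[mask].mean())


def classify_group(avg_rmsd: float, avg_ahb: float,
                   small: float = CLASS_SMALL,
                   large: float = CLASS_LARGE) -> tuple[str, bool]:
    """Endpoint group A/B/C plus an alpha-HB consistency flag.

    The group follows the RMSD interval; the flag is False when the
    alpha-HB average falls outside the range associated with that group.
    """
    if not (math.isfinite(avg_rmsd) and math.isfinite(avg_ahb)):
        raise ValueError("inputs must be finite")
    if avg_rmsd < 0 or not (0 <= avg_ahb <= 6):
        raise ValueError("avg_rmsd must be >= 0 and avg_ahb in [0, 6]")
    group = {1: "A", 2: "B", 3: "C"}[classify_frame(avg_rmsd, small, large)]
    if group == "C":
        consistent = avg_ahb < _GROUP_C_AHB_MAX
    else:
        lo, hi = _GROUP_AHB_RANGE[group]
        consistent = lo <= avg_ahb <= hi
    return group, consistent


def summarize_trajectory(metrics: FrameMetrics,
                         window_ns: float = 2.0) -> TrajectorySummary:
    """Last-window averages of RMSD and alpha-HB count plus the group."""
    t = metrics["time_ps"].to_numpy()
    avg_rmsd = last_window_average(t, metrics["rmsd_mid"].to_numpy(),
                                   window_ns)
    avg_ahb = last_window_average(t, metrics["n_alpha_hb"].to_numpy(),
                                  window_ns)
    group, consistent = classify_group(avg_rmsd, avg_ahb)
    return TrajectorySummary(avg_rmsd, avg_ahb, group, consistent, window_ns)


def second_half_mask(times_ps: np.ndarray) -> np.ndarray:
    """Frames with time strictly greater than (t_first + t_last) / 2."""
    times_ps = np.asarray(times_ps, dtype=float)
    return times_ps > (times_ps[0] + times_ps[-1]) / 2.0


def _window_frames(metrics_list: list[FrameMetrics],
                   window: str) -> pd.DataFrame:
    if window not in ("whole", "second_half"):
        raise ValueError(f"unknown window {window!r}")
    parts = []
    for m in metrics_list:
        if window == "second_half":
            parts.append(m[second_half_mask(m["time_ps"].to_numpy())])
        else:
            parts.append(m)
    combined = pd.concat(parts, ignore_index=True)
    if combined.empty:
        raise ValueError("no frames in the requested window")
    return combined


def histogram_rmsd(metrics_list: list[FrameMetrics],
                   window: str = "whole") -> np.ndarray:
    """Relative frequencies of conformation classes 1/2/3 over all frames."""
    combined = _window_frames(metrics_list, window)
    counts = np.array([
        int((combined["conf_class"] == c).sum()) for c in (1, 2, 3)
    ], dtype=float)
    return counts / counts.sum()


def histogram_ahb(metrics_list: list[FrameMetrics],
                  window: str = "whole") -> np.ndarray:
    """Relative frequencies of alpha-HB counts 0..6 over all frames."""
    combined = _window_frames(metrics_list, window)
    counts = np.array([
        int((combined["n_alpha_hb"] == n).sum()) for n in range(7)
    ], dtype=float)
    return counts / counts.sum()


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return mean, sd


def class_contact_stats(metrics_list: list[FrameMetrics] | FrameMetrics,
                        ) -> ClassContactStats:
    """Binding fractions and bound-frame averages per conformation class.

    Fractions divide bound frames in a class by the frames in that
    class; averages run over bound frames only.  Classes with no frames
    are reported as NaN (undefined), not zero.
    """
    if isinstance(metrics_list, pd.DataFrame):
        metrics_list = [metrics_list]
    combined = pd.concat(metrics_list, ignore_index=True)
    fraction_polar, fraction_nonpolar = {}, {}
    mean_hb, sd_hb, mean_np, sd_np, nframes = {}, {}, {}, {}, {}
    for c in (1, 2, 3):
        sub = combined[combined["conf_class"] == c]
        nframes[c] = len(sub)
        if len(sub) == 0:
            fraction_polar[c] = float("nan")
            fraction_nonpolar[c] = float("nan")
            mean_hb[c] = sd_hb[c] = float("nan")
            mean_np[c] = sd_np[c] = float("nan")
            continue
        fraction_polar[c] = float(sub["polar_bound"].mean())
        fraction_nonpolar[c] = float(sub["nonpolar_bound"].mean())
        mean_hb[c], sd_hb[c] = _mean_sd(
            sub.loc[sub["polar_bound"], "n_ligand_hb"].to_numpy(float)
        )
        mean_np[c], sd_np[c] = _mean_sd(
            sub.loc[sub["nonpolar_bound"], "n_nonpolar"].to_numpy(float)
        )
    return ClassContactStats(fraction_polar, fraction_nonpolar,
                             mean_hb, sd_hb, mean_np, sd_np, nframes)


def binding_timeline(metrics: FrameMetrics) -> pd.DataFrame:
    """Maximal constant-bound intervals with per-frame classes retained.

    Returns a DataFrame with columns start_ps, end_ps, bound, classes
    (tuple of per-frame conformation classes inside the interval).  The
    total bound duration equals stride times the bound-frame count.
    """
    t = metrics["time_ps"].to_numpy(float)
    bound = metrics["polar_bound"].to_numpy(bool)
    cls = metrics["conf_class"].to_numpy(int)
    if len(t) == 0:
        raise ValueError("empty metrics")
    rows = []
    start = 0
    for k in range(1, len(t) + 1):
        if k == len(t) or bound[k] != bound[start]:
            rows.append({
                "start_ps": t[start],
                "end_ps": t[k - 1],
                "bound": bool(bound[start]),
                "classes": tuple(int(x) for x in cls[start:k]),
            })
            start = k
    return pd.DataFrame(rows)


def column_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a column."""
    arr = np.asarray(list(values), dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan")
    return mean, sd
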