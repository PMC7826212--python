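"""MRM trace representation, peak detection, integration and S/N estimation.

Traces are uniformly sampled time/intensity series for one MRM transition.
Peak picking follows the usual targeted-GC recipe: light smoothing (5-point
moving average) for apex finding, boundaries at the surrounding minima or at
baseline return, trapezoidal integration of the *raw* intensities above a
linear baseline drawn between the boundary points, and a robust
(MAD-based) noise scale for signal-to-noise ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import NoiseEstimationError, TraceError
from .pesticide_db import MRMTransition

SMOOTH_WINDOW = 5  # points; fixed moving-average width for apex search
MAD_TO_SIGMA = 1.4826  # normal-consistency factor for the MAD


@dataclass(frozen=True)
class MRMTrace:
    """One transition's time/intensity series for one sample."""

    transition: MRMTransition | None
    times: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if times.ndim != 1 or times.size < 2 or intens.shape != times.shape:
            raise TraceError("times/intensities must be 1-D, equal length >= 2")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise TraceError("times must be strictly increasing")
        if dt.max() > 1.01 * dt.min():
            raise TraceError("sampling must be uniform to within 1%")
        if np.any(intens < 0):
            raise TraceError("intensities must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak."""

    apex_rt: float
    height: float
    area: float
    left_rt: float
    right_rt: float
    snr: float

    def __post_init__(self):
        if not (self.left_rt < self.apex_rt < self.right_rt):
            raise TraceError("require left_rt < apex_rt < right_rt")
        if self.height <= 0 or self.area <= 0 or self.snr < 0:
            raise TraceError("require height > 0, area > 0, snr >= 0")

    @property
    def width(self) -> float:
        return self.right_rt - self.left_rt


def estimate_noise(
    trace: MRMTrace,
    exclusion_zones: Sequence[tuple[float, float]] = (),
) -> float:
    """Robust baseline noise scale: 1.4826 x MAD of points outside the
    exclusion zones (typically the predicted-RT windows of panel compounds).

    Raises
    ------
    NoiseEstimationError
        If fewer than 20 points remain outside the exclusion zones.
    """
    mask = np.ones(trace.times.size, dtype=bool)
    for lo, hi in exclusion_zones:
        mask &= ~((trace.times >= lo) & (trace.times <= hi))
    baseline = trace.intensities[mask]
    if baseline.size < 20:
        raise NoiseEstimationError(
            f"only {baseline.size} baseline points outside exclusion zones (need >= 20)"
        )
    med = np.median(baseline)
    return float(MAD_TO_SIGMA * np.median(np.abs(baseline - med)))


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    kernel = np.ones(window) / window
    padded = np.pad(y, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def integrate_peak(trace: MRMTrace, left_rt: float, right_rt: float) -> float:
    """Trapezoidal area (counts*min) above a linear baseline drawn between
    the interpolated boundary intensities."""
    if not left_rt < right_rt:
        raise TraceError(f"inverted bounds: {left_rt} >= {right_rt}")
    t0, t1 = trace.times[0], trace.times[-1]
    if left_rt < t0 - 1e-12 or right_rt > t1 + 1e-12:
        raise TraceError("integration bounds outside trace span")
    lo = np.searchsorted(trace.times, left_rt, side="left")
    hi = np.searchsorted(trace.times, right_rt, side="right")
    t = trace.times[lo:hi]
    y = trace.intensities[lo:hi]
    # include the exact boundary points by interpolation
    yl = float(np.interp(left_rt, trace.times, trace.intensities))
    yr = float(np.interp(right_rt, trace.times, trace.intensities))
    t = np.concatenate([[left_rt], t, [right_rt]])
    y = np.concatenate([[yl], y, [yr]])
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t, y = t[keep], y[keep]
    baseline = yl + (yr - yl) * (t - left_rt) / (right_rt - left_rt)
    return float(np.trapezoid(y - baseline, t))


def detect_peaks(
    trace: MRMTrace,
    min_snr: float = 3.0,
    min_width: float = 0.01,
    noise: float | None = None,
) -> list[Peak]:
    """Find peaks in a trace.

    Local maxima of the 5-point-smoothed trace whose baseline-corrected
    height exceeds ``min_snr`` times the noise scale and whose base width is
    at least ``min_width`` minutes.  Boundaries are placed at the
    surrounding minima of the smoothed trace or where it returns to the
    baseline; integration always uses the raw intensities.

    Parameters
    ----------
    noise
        Noise scale to use for S/N; estimated from the whole trace (MAD)
        when omitted.
    """
    y = trace.intensities
    if y.size < SMOOTH_WINDOW:
        raise TraceError(
            f"trace of {y.size} points is shorter than the smoothing window"
        )
    s = _smooth(y)
    if noise is None:
        med = np.median(y)
        noise = float(MAD_TO_SIGMA * np.median(np.abs(y - med)))
    idx, _ = find_peaks(s)
    floor = np.median(s) + noise  # baseline-return level for boundary search
    peaks: list[Peak] = []
    for i in idx:
        lo = i
        while lo > 0 and s[lo - 1] < s[lo] and s[lo] > floor:
            lo -= 1
        while lo > 0 and s[lo - 1] <= s[lo] and s[lo] > floor:
            lo -= 1
        hi = i
        while hi < s.size - 1 and s[hi + 1] < s[hi] and s[hi] > floor:
            hi += 1
        while hi < s.size - 1 and s[hi + 1] <= s[hi] and s[hi] > floor:
            hi += 1
        if hi - lo < 2:
            continue
        # apex from the raw trace inside the boundaries
        apex = lo + int(np.argmax(y[lo : hi + 1]))
        if apex in (lo, hi):
            continue
        left_rt, right_rt = float(trace.times[lo]), float(trace.times[hi])
        apex_rt = float(trace.times[apex])
        base = y[lo] + (y[hi] - y[lo]) * (apex_rt - left_rt) / (right_rt - left_rt)
        height = float(y[apex] - base)
        if height <= 0:
            continue
        snr = float(height / noise) if noise > 0 else float("inf")
        if snr < min_snr:
            continue
        if right_rt - left_rt < min_width:
            continue
        area = integrate_peak(trace, left_rt, right_rt)
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=apex_rt,
                height=height,
                area=area,
                left_rt=left_rt,
                right_rt=right_rt,
                snr=snr,
            )
        )
    # deduplicate candidates that collapsed onto the same apex
    uniq: dict[float, Peak] = {}
    for p in peaks:
        uniq[p.apex_rt] = p
    return sorted(uniq.values(), key=lambda p: p.apex_rt)


# ---------------------------------------------------------------------------
# plain-text I/O

TRACE_CSV_COLUMNS = ["sample_id", "precursor", "product", "time_min", "intensity"]
PEAK_CSV_COLUMNS = [
    "sample_id", "precursor", "product",
    "apex_rt", "height", "area", "snr", "left_rt", "right_rt",
]


def write_traces(traces: Iterable[MRMTrace], path: str | Path) -> None:
    """Write traces to the long CSV format
    ``sample_id,precursor,product,time_min,intensity``."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "precursor": tr.transition.precursor_mz if tr.transition else np.nan,
                    "product": tr.transition.product_mz if tr.transition else np.nan,
                    "time_min": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[MRMTrace]:
    """Read traces from the long CSV format (one trace per
    sample/transition/contiguous block)."""
    df = pd.read_csv(path)
    missing = set(TRACE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TraceError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (sid, prec, prod), grp in df.groupby(
        ["sample_id", "precursor", "product"], sort=False
    ):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy()
        y = grp["intensity"].to_numpy()
        # a transition monitored in several disjoint time segments yields one
        # trace per contiguous block
        dt = np.median(np.diff(t)) if t.size > 1 else 0.0
        breaks = np.flatnonzero(np.diff(t) > 5 * dt) + 1 if t.size > 2 else []
        for chunk_t, chunk_y in zip(np.split(t, breaks), np.split(y, breaks)):
            if chunk_t.size < 2:
                continue
            traces.append(
                MRMTrace(
                    transition=MRMTransition(float(prec), float(prod)),
                    times=chunk_t,
                    intensities=chunk_y,
                    sample_id=str(sid),
                )
            )
    return traces


def peaks_to_frame(
    peaks_by_transition: dict[MRMTransition, list[Peak]], sample_id: str = ""
) -> pd.DataFrame:
    rows = []
    for tr, pks in peaks_by_transition.items():
        for p in pks:
            rows.append(
                {
                    "sample_id": sample_id,
                    "precursor": tr.precursor_mz,
                    "product": tr.product_mz,
                    "apex_rt": p.apex_rt,
                    "height": p.height,
                    "area": p.area,
                    "snr": p.snr,
                    "left_rt": p.left_rt,
                    "right_rt": p.right_rt,
                }
            )
    return pd.DataFrame(rows, columns=PEAK_CSV_COLUMNS)
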