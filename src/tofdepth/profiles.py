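"""Temporal-profile extraction, normalization and timing features.

A temporal profile (TP) is the photon count versus gate delay for a pixel or
spatially averaged ROI.  Profiles are normalized between an estimate of the
pulse maximum (mean of the ``n_top`` most intense gate steps) and the
baseline (mean of the last ``n_tail`` steps, where no signal remains), which
maps the pulse onto roughly [0, 1] independent of acquisition gain.

Reflectance profiles carry the timing features used for calibration and
cross-acquisition alignment: a linear fit of the pulse rising (or falling)
edge whose zero crossing serves as a time reference, and the interpolated
time at which the normalized pulse crosses a small threshold (2% of maximum
by default), whose shift between media tracks the scattering level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .core import TimeProfile, TimeScan
from .errors import DegenerateProfileError, EdgeFitError
from .stacks import _roi_slice

__all__ = [
    "EdgeFit",
    "ReflectanceTiming",
    "extract_profile",
    "normalize_profile",
    "smooth_profile",
    "fit_edge",
    "align_to_reference",
    "threshold_time",
]


@dataclass(frozen=True)
class EdgeFit:
    """Linear fit of a pulse edge: ``value = slope * (t - t_ref)``."""

    slope_per_ps: float
    intercept: float
    fit_window: Tuple[int, int]
    t_ref_ps: float
    edge: str = "rising"


@dataclass(frozen=True)
class ReflectanceTiming:
    """Threshold-crossing time of a normalized reflectance pulse."""

    delta_refl_ps: float
    crossing_time_ps: float
    threshold_level: float = 0.02
    edge: str = "rising"
    reference_sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_level < 1:
            raise ValueError("threshold level must lie in (0, 1)")


def extract_profile(scan: TimeScan, roi: Tuple[int, int, int, int]) -> TimeProfile:
    """Spatially averaged profile over ``roi = (row0, col0, height, width)``."""
    rs, cs = _roi_slice(roi, scan.shape[:2])
    vals = scan.counts[rs, cs, :].mean(axis=(0, 1))
    return TimeProfile(vals, scan.axis, modality=scan.modality, roi=roi)


def normalize_profile(
    tp: TimeProfile, n_top: int = 200, n_tail: int = 200
) -> TimeProfile:
    """Normalize between the pulse-maximum and baseline estimates.

    ``M`` is the mean of the ``n_top`` largest sample values (ties broken by
    earlier index), ``m`` the mean of the last ``n_tail`` samples; the result
    is ``(v - m) / (M - m)``.
    """
    n = len(tp.values)
    if not 1 <= n_top <= n or not 1 <= n_tail <= n:
        raise ValueError(f"n_top/n_tail must lie in [1, {n}]")
    order = np.argsort(-tp.values, kind="stable")  # stable: earlier index wins ties
    m_top = float(tp.values[order[:n_top]].mean())
    m_tail = float(tp.values[-n_tail:].mean())
    if not m_top > m_tail:
        raise DegenerateProfileError(
            "profile maximum estimate does not exceed baseline estimate: "
            "no usable pulse"
        )
    out = (tp.values - m_tail) / (m_top - m_tail)
    return tp.with_values(out, normalized=True)


def smooth_profile(tp: TimeProfile, window: int = 35) -> TimeProfile:
    """Centered moving average with shrinking symmetric windows at the edges.

    Near the boundaries the half-width shrinks so the window stays symmetric
    around each sample; this avoids biasing the pulse tails that the
    normalization relies on.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    n = len(tp.values)
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    if window == 1:
        return tp.with_values(tp.values.copy())
    h = window // 2
    out = np.convolve(tp.values, np.ones(window) / window, mode="same")
    for i in range(h):  # recompute edge samples with symmetric shrunk windows
        hi = min(i, n - 1 - i)
        out[i] = tp.values[i - hi : i + hi + 1].mean()
        j = n - 1 - i
        hj = min(j, n - 1 - j)
        out[j] = tp.values[j - hj : j + hj + 1].mean()
    return tp.with_values(out)


def _edge_samples(
    values: np.ndarray, edge: str, level_lo: float, level_hi: float
) -> np.ndarray:
    """Indices of the in-band samples on the selected pulse edge."""
    imax = int(np.argmax(values))
    if edge == "rising":
        seg = np.arange(0, imax + 1)
    elif edge == "falling":
        seg = np.arange(imax, len(values))
    else:
        raise ValueError(f"edge must be 'rising' or 'falling', got {edge!r}")
    in_band = seg[(values[seg] >= level_lo) & (values[seg] <= level_hi)]
    if in_band.size == 0:
        raise EdgeFitError(
            f"no samples within [{level_lo}, {level_hi}] on the {edge} edge"
        )
    # contiguous run adjacent to the peak (first rising / last falling crossing)
    breaks = np.where(np.diff(in_band) > 1)[0]
    if edge == "rising":
        run = in_band[breaks[-1] + 1 :] if breaks.size else in_band
    else:
        run = in_band[: breaks[0] + 1] if breaks.size else in_band
    return run


def fit_edge(
    tp: TimeProfile,
    edge: str = "rising",
    level_lo: float = 0.2,
    level_hi: float = 0.8,
) -> EdgeFit:
    """Least-squares line through the edge samples with values in the band.

    The zero crossing of the fitted line, ``t_ref``, serves as the time
    reference for aligning acquisitions.
    """
    if not tp.normalized:
        raise ValueError("fit_edge expects a normalized profile")
    run = _edge_samples(tp.values, edge, level_lo, level_hi)
    if run.size < 3:
        raise EdgeFitError(
            f"only {run.size} samples within [{level_lo}, {level_hi}] on the "
            f"{edge} edge; need >= 3"
        )
    diffs = np.diff(tp.values[run])
    if edge == "rising" and np.any(diffs < -0.5 * (level_hi - level_lo)):
        raise EdgeFitError("rising edge is not monotone within the fit band")
    if edge == "falling" and np.any(diffs > 0.5 * (level_hi - level_lo)):
        raise EdgeFitError("falling edge is not monotone within the fit band")
    t = tp.times_ps[run]
    slope, intercept = np.polyfit(t, tp.values[run], 1)
    if edge == "rising" and slope <= 0:
        raise EdgeFitError("fitted rising-edge slope is not positive")
    if edge == "falling" and slope >= 0:
        raise EdgeFitError("fitted falling-edge slope is not negative")
    return EdgeFit(
        slope_per_ps=float(slope),
        intercept=float(intercept),
        fit_window=(int(run[0]), int(run[-1])),
        t_ref_ps=float(-intercept / slope),
        edge=edge,
    )


def align_to_reference(
    fluo: TimeProfile, refl_ref: EdgeFit, refl_new: EdgeFit
) -> TimeProfile:
    """Time-correct a fluorescence profile to its reflectance reference.

    Setup changes (working distance, sample surface) delay both modalities
    equally; shifting by ``dt = refl_ref.t_ref - refl_new.t_ref`` removes the
    common delay so profiles from different acquisitions are comparable.
    Sub-sample shifts use linear interpolation.
    """
    shift_ps = refl_ref.t_ref_ps - refl_new.t_ref_ps
    if abs(shift_ps) > 0.25 * fluo.axis.span_ps:
        raise ValueError(
            f"alignment shift {shift_ps:.0f} ps exceeds 25% of the axis span: "
            "implausible geometry change"
        )
    t = fluo.times_ps
    out = np.interp(t - shift_ps, t, fluo.values)
    return fluo.with_values(
        out, provenance=(fluo.provenance + f" shifted {shift_ps:+.3f} ps").strip()
    )


def threshold_time(
    tp: TimeProfile,
    level: float = 0.02,
    edge: str = "rising",
    reference: Union[None, float, TimeProfile] = None,
    reference_sample_id: Optional[str] = None,
) -> ReflectanceTiming:
    """Interpolated time at which the pulse crosses ``level``.

    For ``edge='rising'`` the first up-crossing is used; for ``'falling'``
    the last down-crossing.  ``delta_refl`` is the crossing time relative to
    ``reference`` (another profile, whose crossing is computed the same way,
    or an absolute time in ps; 0 if omitted).
    """
    if not tp.normalized:
        raise ValueError("threshold_time expects a normalized profile")
    if not 0 < level < 1:
        raise ValueError("threshold level must lie in (0, 1)")
    v = tp.values
    t = tp.times_ps
    if edge == "rising":
        idx = np.where((v[:-1] < level) & (v[1:] >= level))[0]
        if idx.size == 0:
            raise EdgeFitError(f"profile never rises through level {level}")
        i = int(idx[0])
    elif edge == "falling":
        idx = np.where((v[:-1] >= level) & (v[1:] < level))[0]
        if idx.size == 0:
            raise EdgeFitError(f"profile never falls through level {level}")
        i = int(idx[-1])
    else:
        raise ValueError(f"edge must be 'rising' or 'falling', got {edge!r}")
    frac = (level - v[i]) / (v[i + 1] - v[i])
    t_cross = float(t[i] + frac * (t[i + 1] - t[i]))
    if reference is None:
        t_ref = 0.0
    elif isinstance(reference, TimeProfile):
        t_ref = threshold_time(reference, level=level, edge=edge).crossing_time_ps
    else:
        t_ref = float(reference)
    return ReflectanceTiming(
        delta_refl_ps=t_cross - t_ref,
        crossing_time_ps=t_cross,
        threshold_level=level,
        edge=edge,
        reference_sample_id=reference_sample_id,
    )
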