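"""Core containers for time-gated single-photon acquisitions.

A time-gated SPAD acquisition sweeps a short detection gate across the
arrival-time axis in fixed steps, accumulating binary frames at each gate
position.  The resulting data are 3D stacks of photon counts
(rows x cols x gate steps); a 1D trace along the gate axis is a temporal
profile (TP).  These containers carry the timing metadata every downstream
stage needs: the gate step ``dt`` (ps), the gate offset ``t0`` from the
laser sync, and the number of gate positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import AxisError

#: Recognised acquisition modalities.
MODALITIES = ("fluorescence", "reflectance", "irf", "darkfield")

#: Default gate step between subsequent gate positions (ps).
DEFAULT_DT_PS = 17.857
#: Default number of gate positions in a full time scan.
DEFAULT_N_STEPS = 1400
#: Default acquisition gate width (ns).
DEFAULT_GATE_WIDTH_NS = 10.8


@dataclass(frozen=True)
class GateTimeAxis:
    """Gate-delay axis of a time scan.

    Parameters
    ----------
    t0_ps
        Gate offset from the laser sync pulse, in picoseconds.  All profile
        times are reported on this absolute axis; the delay of light through
        air is absorbed into the instrument response function, so ``t0`` is
        an instrument setting, not a physical reference.
    dt_ps
        Gate step (delay between subsequent gate positions), ps.
    n_steps
        Number of gate positions.
    gate_width_ns
        Width of the detection gate, ns.  Informational: the gate is much
        wider than the step, so the step alone sets the sampling resolution.
    """

    t0_ps: float = 0.0
    dt_ps: float = DEFAULT_DT_PS
    n_steps: int = DEFAULT_N_STEPS
    gate_width_ns: float = DEFAULT_GATE_WIDTH_NS

    def __post_init__(self) -> None:
        if not self.dt_ps > 0:
            raise AxisError(f"gate step must be positive, got {self.dt_ps}")
        if self.n_steps < 2:
            raise AxisError(f"need at least 2 gate steps, got {self.n_steps}")

    @property
    def span_ps(self) -> float:
        """Total time window covered by the scan (ps)."""
        return self.dt_ps * self.n_steps

    @property
    def times_ps(self) -> np.ndarray:
        """Absolute gate-delay times, shape ``(n_steps,)``."""
        return self.t0_ps + self.dt_ps * np.arange(self.n_steps)

    def to_dict(self) -> dict:
        return {
            "t0_ps": self.t0_ps,
            "dt_ps": self.dt_ps,
            "n_steps": self.n_steps,
            "gate_width_ns": self.gate_width_ns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GateTimeAxis":
        return cls(
            t0_ps=float(d["t0_ps"]),
            dt_ps=float(d["dt_ps"]),
            n_steps=int(d["n_steps"]),
            gate_width_ns=float(d.get("gate_width_ns", DEFAULT_GATE_WIDTH_NS)),
        )


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return modality


@dataclass
class TimeProfile:
    """A 1D counts-versus-time trace for a pixel or ROI.

    ``values`` are raw photon counts unless ``normalized`` is set, in which
    case they are dimensionless and map the pulse roughly onto [0, 1].
    """

    values: np.ndarray
    axis: GateTimeAxis
    normalized: bool = False
    modality: Optional[str] = None
    roi: Optional[tuple] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if len(self.values) != self.axis.n_steps:
            raise AxisError(
                f"profile length {len(self.values)} != axis n_steps {self.axis.n_steps}"
            )
        if self.modality is not None:
            _check_modality(self.modality)

    @property
    def times_ps(self) -> np.ndarray:
        return self.axis.times_ps

    def with_values(self, values: np.ndarray, **changes) -> "TimeProfile":
        """Copy of this profile with new sample values (same axis)."""
        out = replace(self, **changes)
        out.values = np.asarray(values, dtype=float)
        return out

    def to_csv(self, path) -> None:
        """Write as a 2-column CSV (time_ps, value)."""
        arr = np.column_stack([self.times_ps, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_ps,value", comments="")


@dataclass
class TimeScan:
    """3D photon-count stack: rows x cols x gate steps.

    ``counts`` holds non-negative integers for raw acquisitions; averaging
    replicates produces real-valued counts, flagged with ``is_averaged``.
    """

    counts: np.ndarray
    axis: GateTimeAxis
    modality: str
    provenance: str = ""
    is_averaged: bool = False
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("scan counts must be rows x cols x steps")
        if self.counts.shape[2] != self.axis.n_steps:
            raise AxisError(
                f"scan has {self.counts.shape[2]} gate steps but axis declares "
                f"{self.axis.n_steps}"
            )
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        _check_modality(self.modality)

    @property
    def shape(self) -> tuple:
        return self.counts.shape


@dataclass
class IntensityImage:
    """Per-pixel mean counts over a window of gate steps."""

    values: np.ndarray
    n_frames_averaged: int
    modality: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity image must be 2D")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")
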