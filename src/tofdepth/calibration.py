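"""Linear depth calibration and intensity correction.

The fitted relative TOF grows linearly with inclusion depth,
``delta_tissue = k_fluo * depth + c_fluo``, but the slope depends on the
medium's scattering level.  With Intralipid (IL) concentration as the pivot
scattering index, three more linear relations close the chain:

* ``delta_refl = k_refl * IL + c_refl`` — threshold timing of reflectance
  pulses versus IL (reflectance branch);
* ``mu_s' = k_sfdi * IL + c_sfdi`` — reduced scattering from structured
  light imaging versus IL (SFDI branch);
* ``k_fluo = k_corr * IL + c_corr`` — the TOF-depth slope versus IL.

Either branch inverts a measured ``delta_tissue`` plus a medium feature
(``delta_refl`` or ``mu_s'``) to depth:

    depth = (delta_tissue - c_fluo) / (k_corr * (feature - c) / k + c_corr)

Depth then corrects the measured surface intensity for round-trip diffuse
attenuation, ``I = L * exp(-2 * mu_eff * z)`` with
``mu_eff = sqrt(3 * mu_a * (mu_a + mu_s'))``, recovering the luminance ``L``
at the inclusion.

For media that are not Intralipid, IL acts purely as a latent scattering
index: the chain only ever uses it internally, between two linear maps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError

__all__ = [
    "OpticalProperties",
    "CalibrationChain",
    "DepthEstimate",
    "fit_linear",
    "build_chain",
    "depth_from_tof",
    "mu_eff",
    "correct_intensity",
    "attenuate_intensity",
]

#: Column names for calibration input tables.
DEPTH_TABLE_COLUMNS = ("il_percent", "depth_mm", "delta_tissue_ps")
MEDIUM_TABLE_COLUMNS = ("il_percent", "delta_refl_ps", "mu_s_prime_per_mm")


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk absorption and reduced scattering of the medium (per mm)."""

    mu_a_per_mm: float
    mu_s_prime_per_mm: float
    wavelength_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu_a_per_mm < 0:
            raise ValueError("mu_a must be >= 0")
        if not self.mu_s_prime_per_mm > 0:
            raise ValueError("mu_s_prime must be > 0")

    @property
    def mu_eff_per_mm(self) -> float:
        return mu_eff(self)


def mu_eff(props: OpticalProperties) -> float:
    """Effective attenuation coefficient sqrt(3 * mu_a * (mu_a + mu_s'))."""
    return float(
        np.sqrt(3.0 * props.mu_a_per_mm * (props.mu_a_per_mm + props.mu_s_prime_per_mm))
    )


@dataclass
class CalibrationChain:
    """Fitted coefficients enabling TOF-to-depth inversion.

    ``branch`` selects the medium-feature relation used at inversion time:
    ``'reflectance'`` (threshold timing) or ``'sfdi'`` (reduced scattering).
    """

    branch: str
    k_corr: float
    c_corr: float
    c_fluo_ps: float
    k_refl: Optional[float] = None
    c_refl: Optional[float] = None
    k_sfdi: Optional[float] = None
    c_sfdi: Optional[float] = None
    k_fluo_per_il: Dict[float, float] = field(default_factory=dict)
    r_squared: Dict[str, float] = field(default_factory=dict)
    valid_depth_range_mm: Tuple[float, float] = (1.0, 5.0)

    def __post_init__(self) -> None:
        if self.branch not in ("reflectance", "sfdi"):
            raise CalibrationError(f"unknown branch {self.branch!r}")
        need = ("k_refl", "c_refl") if self.branch == "reflectance" else ("k_sfdi", "c_sfdi")
        for name in need:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise CalibrationError(f"{self.branch} branch requires finite {name}")
        if len(self.k_fluo_per_il) and len(self.k_fluo_per_il) < 2:
            raise CalibrationError("k_fluo table needs >= 2 Intralipid levels")

    def infer_il(self, medium_feature: float) -> float:
        """Latent scattering index from the branch's medium feature."""
        if self.branch == "reflectance":
            return (medium_feature - self.c_refl) / self.k_refl
        return (medium_feature - self.c_sfdi) / self.k_sfdi

    def k_fluo_at(self, medium_feature: float) -> float:
        """TOF-depth slope (ps/mm) for a medium with the given feature."""
        return self.k_corr * self.infer_il(medium_feature) + self.c_corr

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        d = asdict(self)
        d["k_fluo_per_il"] = {str(k): v for k, v in self.k_fluo_per_il.items()}
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CalibrationChain":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["k_fluo_per_il"] = {float(k): v for k, v in d.get("k_fluo_per_il", {}).items()}
        d["valid_depth_range_mm"] = tuple(d.get("valid_depth_range_mm", (1.0, 5.0)))
        return cls(**d)


@dataclass(frozen=True)
class DepthEstimate:
    """Inverted depth for one measurement."""

    depth_mm: float
    delta_tissue_in_ps: float
    medium_feature_in: float
    branch: str
    valid: bool
    extrapolated: bool = False
    reason: str = ""


def fit_linear(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float]:
    """Ordinary least-squares line: returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise CalibrationError("need >= 2 distinct x values for a linear fit")
    if np.ptp(y) == 0:  # constant y: exact horizontal line
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _as_depth_frame(depth_series) -> pd.DataFrame:
    if isinstance(depth_series, pd.DataFrame):
        missing = [c for c in DEPTH_TABLE_COLUMNS if c not in depth_series.columns]
        if missing:
            raise CalibrationError(f"depth table missing columns: {missing}")
        return depth_series[list(DEPTH_TABLE_COLUMNS)].copy()
    rows = []
    for il, (depths, deltas) in depth_series.items():
        for d, dt in zip(depths, deltas):
            rows.append((float(il), float(d), float(dt)))
    return pd.DataFrame(rows, columns=list(DEPTH_TABLE_COLUMNS))


def build_chain(
    depth_series,
    medium_series,
    branch: str = "sfdi",
    depth_range_mm: Optional[Tuple[float, float]] = None,
    valid_depth_range_mm: Tuple[float, float] = (1.0, 5.0),
) -> CalibrationChain:
    """Fit the full calibration chain from phantom series.

    Parameters
    ----------
    depth_series
        Per-IL depth calibration data: either a DataFrame with columns
        ``(il_percent, depth_mm, delta_tissue_ps)`` or a mapping
        ``{il: (depths, delta_tissues)}``.  Needs >= 2 IL levels with
        >= 2 depths each.
    medium_series
        ``(il_values, feature_values)`` pair or DataFrame with
        ``il_percent`` plus ``delta_refl_ps`` (reflectance branch) or
        ``mu_s_prime_per_mm`` (SFDI branch).
    depth_range_mm
        If given, only depths inside this closed interval enter the
        regressions (e.g. ``(1, 5)`` to drop a poorly controlled first
        millimetre).
    valid_depth_range_mm
        Depths outside this span are flagged as extrapolation at inversion
        time.

    ``c_fluo`` — in principle a pure geometry constant — is estimated as the
    mean intercept of the per-IL depth regressions.
    """
    df = _as_depth_frame(depth_series)
    if depth_range_mm is not None:
        lo, hi = depth_range_mm
        df = df[(df.depth_mm >= lo) & (df.depth_mm <= hi)]
    ils = sorted(df.il_percent.unique())
    if len(ils) < 2:
        raise CalibrationError(
            f"need >= 2 Intralipid levels to relate k_fluo to scattering; got {len(ils)}"
        )
    k_fluo_per_il: Dict[float, float] = {}
    intercepts = []
    r2: Dict[str, float] = {}
    for il in ils:
        sub = df[df.il_percent == il]
        if len(sub) < 2 or sub.depth_mm.nunique() < 2:
            raise CalibrationError(
                f"IL={il}%: need >= 2 distinct depths, got {sub.depth_mm.nunique()}"
            )
        k, c, r = fit_linear(sub.depth_mm, sub.delta_tissue_ps)
        k_fluo_per_il[float(il)] = k
        intercepts.append(c)
        r2[f"k_fluo@IL{il}"] = r
    c_fluo = float(np.mean(intercepts))
    k_corr, c_corr, r_corr = fit_linear(ils, [k_fluo_per_il[il] for il in ils])
    r2["k_corr"] = r_corr

    if isinstance(medium_series, pd.DataFrame):
        col = "delta_refl_ps" if branch == "reflectance" else "mu_s_prime_per_mm"
        if "il_percent" not in medium_series.columns or col not in medium_series.columns:
            raise CalibrationError(
                f"medium table must carry columns ('il_percent', {col!r})"
            )
        m_il, m_feat = medium_series["il_percent"], medium_series[col]
    else:
        m_il, m_feat = medium_series
    k_med, c_med, r_med = fit_linear(m_il, m_feat)
    r2["medium"] = r_med

    kwargs = dict(
        branch=branch,
        k_corr=k_corr,
        c_corr=c_corr,
        c_fluo_ps=c_fluo,
        k_fluo_per_il=k_fluo_per_il,
        r_squared=r2,
        valid_depth_range_mm=tuple(valid_depth_range_mm),
    )
    if branch == "reflectance":
        kwargs.update(k_refl=k_med, c_refl=c_med)
    else:
        kwargs.update(k_sfdi=k_med, c_sfdi=c_med)
    return CalibrationChain(**kwargs)


def depth_from_tof(
    delta_tissue_ps: float,
    medium_feature: float,
    chain: CalibrationChain,
) -> DepthEstimate:
    """Invert a fitted relative TOF to inclusion depth.

    The medium feature (``delta_refl`` for the reflectance branch, ``mu_s'``
    for SFDI) fixes the latent scattering index, hence the local TOF-depth
    slope.  A non-positive slope marks the estimate invalid (extrapolation
    beyond the calibrated scattering range) rather than raising.
    """
    k = chain.k_fluo_at(medium_feature)
    if not np.isfinite(k) or k <= 0:
        return DepthEstimate(
            depth_mm=float("nan"),
            delta_tissue_in_ps=delta_tissue_ps,
            medium_feature_in=medium_feature,
            branch=chain.branch,
            valid=False,
            reason=f"inferred TOF-depth slope {k:.4g} ps/mm is not positive",
        )
    depth = (delta_tissue_ps - chain.c_fluo_ps) / k
    lo, hi = chain.valid_depth_range_mm
    return DepthEstimate(
        depth_mm=float(depth),
        delta_tissue_in_ps=delta_tissue_ps,
        medium_feature_in=medium_feature,
        branch=chain.branch,
        valid=True,
        extrapolated=not (lo <= depth <= hi),
    )


def attenuate_intensity(
    luminance: float, depth_mm: float, props: OpticalProperties,
    convention: str = "round-trip",
) -> float:
    """Forward attenuation: surface intensity of a source at depth z."""
    return luminance * np.exp(-_exponent(depth_mm, props, convention))


def correct_intensity(
    surface_intensity: float,
    depth_mm: float,
    props: OpticalProperties,
    convention: str = "round-trip",
) -> float:
    """Recover luminance at depth from the measured surface intensity.

    Inverts ``I = L * exp(-2 * mu_eff * z)`` (diffuse round trip over 2z).
    ``convention='squared'`` selects the alternative ``exp(-mu_eff**2 * z)``
    reading of the attenuation exponent.
    """
    return surface_intensity * np.exp(_exponent(depth_mm, props, convention))


def _exponent(depth_mm: float, props: OpticalProperties, convention: str) -> float:
    if depth_mm < 0:
        raise ValueError("depth must be >= 0")
    me = mu_eff(props)
    if convention == "round-trip":
        return 2.0 * me * depth_mm
    if convention == "squared":
        return me**2 * depth_mm
    raise ValueError(f"unknown attenuation convention {convention!r}")
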