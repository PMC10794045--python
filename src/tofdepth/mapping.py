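"""Per-pixel fitting and map post-processing.

Full-resolution per-pixel fits are noisy and slow; binning the stack into
superpixels (8x8 by default, turning a 256x472 sensor area into a 32x59
map) pools photons before fitting.  Each superpixel's profile is normalized
and fitted against the matching superpixel of the IRF scan, yielding maps of
``delta_tissue`` (the TOF surrogate), ``sigma``, ``A`` and R^2.  Maps are
cleaned by intensity masking (fits are meaningless where nothing fluoresces)
and mask-aware Gaussian smoothing, and the TOF map converts to a relative
topology through the calibration chain.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationChain, depth_from_tof
from .core import IntensityImage, TimeScan
from .errors import DataQualityWarning, DegenerateProfileError
from .fitting import fit_fluorescence, fit_reflectance
from .profiles import extract_profile, normalize_profile

__all__ = [
    "ParameterMap",
    "bin_scan",
    "fit_map",
    "mask_by_intensity",
    "smooth_map",
    "tof_to_topology",
]


@dataclass
class ParameterMap:
    """Grid of one fitted quantity with a validity mask (True = valid)."""

    values: np.ndarray
    mask: np.ndarray
    name: str
    bin_factor: int = 1
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("map values and mask must be 2D and congruent")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write as (row, col, value, valid) rows."""
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["row", "col", "value", "valid"])
            for r in range(self.values.shape[0]):
                for c in range(self.values.shape[1]):
                    w.writerow([r, c, self.values[r, c], int(self.mask[r, c])])

    def to_tiff(self, path: Union[str, Path]) -> None:
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], name: str = "map", bin_factor: int = 1
    ) -> "ParameterMap":
        """Read a map written by :meth:`to_csv`."""
        rows, cols, vals, valid = [], [], [], []
        with open(path, newline="") as f:
            for rec in csv.DictReader(f):
                rows.append(int(rec["row"]))
                cols.append(int(rec["col"]))
                vals.append(float(rec["value"]))
                valid.append(bool(int(rec["valid"])))
        shape = (max(rows) + 1, max(cols) + 1)
        values = np.full(shape, np.nan)
        mask = np.zeros(shape, dtype=bool)
        for r, c, v, ok in zip(rows, cols, vals, valid):
            values[r, c] = v
            mask[r, c] = ok
        return cls(values, mask, name, bin_factor, provenance=str(path))


def bin_scan(scan: TimeScan, factor: int = 8) -> TimeScan:
    """Sum non-overlapping ``factor x factor`` pixel blocks per gate step.

    Summing (rather than averaging) preserves photon statistics; profile
    normalization removes the scale later.  Trailing rows/columns that do
    not fill a block are dropped.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    rows, cols, n = scan.shape
    if factor > rows or factor > cols:
        raise ValueError(f"bin factor {factor} exceeds scan shape {rows}x{cols}")
    if factor == 1:
        return scan
    br, bc = rows // factor, cols // factor
    trimmed = scan.counts[: br * factor, : bc * factor, :]
    binned = trimmed.reshape(br, factor, bc, factor, n).sum(axis=(1, 3))
    return TimeScan(
        binned,
        scan.axis,
        modality=scan.modality,
        provenance=scan.provenance + f" binned{factor}x{factor}",
        is_averaged=scan.is_averaged,
        ground_truth=scan.ground_truth,
    )


def fit_map(
    scan: TimeScan,
    irf_scan: TimeScan,
    tau_ns: float = 0.7,
    chain: Optional[CalibrationChain] = None,
    medium_feature: Optional[float] = None,
    n_top: int = 200,
    n_tail: int = 200,
    bin_factor: int = 1,
    r2_mask_threshold: float = 0.5,
) -> Dict[str, ParameterMap]:
    """Fit every superpixel's profile; emit parameter maps.

    ``scan`` and ``irf_scan`` must share axis and (already binned) shape.
    Each superpixel is fitted against its own IRF superpixel, which absorbs
    pixel-to-pixel timing skew and illumination variation.  Failed or
    degenerate fits are masked, never abort the map.  With a calibration
    ``chain`` (and its ``medium_feature``), a depth map is added.
    """
    if scan.axis != irf_scan.axis:
        raise ValueError("scan and IRF scan must share the gate-time axis")
    if scan.shape[:2] != irf_scan.shape[:2]:
        raise ValueError(
            f"scan plane {scan.shape[:2]} != IRF plane {irf_scan.shape[:2]}"
        )
    rows, cols = scan.shape[:2]
    out = {
        k: np.full((rows, cols), np.nan)
        for k in ("delta_tissue_ps", "sigma_ps", "A", "r_squared")
    }
    mask = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            roi = (r, c, 1, 1)
            irf_tp = extract_profile(irf_scan, roi)
            try:
                tp = normalize_profile(extract_profile(scan, roi), n_top, n_tail)
                if scan.modality == "reflectance":
                    res = fit_reflectance(tp, irf_tp)
                else:
                    res = fit_fluorescence(tp, irf_tp, tau_ns=tau_ns)
            except (DegenerateProfileError, ValueError):
                continue
            if not res.converged:
                continue
            out["delta_tissue_ps"][r, c] = res.delta_tissue_ps
            out["sigma_ps"][r, c] = res.sigma_ps
            out["A"][r, c] = res.A
            out["r_squared"][r, c] = res.r_squared
            # a converged fit on signal-free pixels still explains ~nothing
            mask[r, c] = res.r_squared >= r2_mask_threshold
    prov = f"fit_map of [{scan.provenance}]"
    maps = {
        name: ParameterMap(vals, mask.copy(), name, bin_factor, prov)
        for name, vals in out.items()
    }
    if chain is not None:
        if medium_feature is None:
            raise ValueError("a calibration chain requires a medium_feature")
        depth = np.full((rows, cols), np.nan)
        dmask = mask.copy()
        for r, c in zip(*np.nonzero(mask)):
            est = depth_from_tof(out["delta_tissue_ps"][r, c], medium_feature, chain)
            if est.valid:
                depth[r, c] = est.depth_mm
            else:
                dmask[r, c] = False
        maps["depth_mm"] = ParameterMap(depth, dmask, "depth_mm", bin_factor, prov)
    return maps


def mask_by_intensity(
    pmap: ParameterMap,
    intensity: IntensityImage,
    threshold: float = 2.0,
    background_roi: Optional[Tuple[int, int, int, int]] = None,
) -> ParameterMap:
    """Mask map entries whose fluorescence intensity fails a threshold.

    With ``background_roi`` the rule is SNR-style: keep pixels whose
    intensity exceeds the background mean by at least ``threshold``
    background standard deviations.  Without it, ``threshold`` is an
    absolute intensity level.
    """
    if intensity.values.shape != pmap.values.shape:
        raise ValueError(
            f"intensity shape {intensity.values.shape} != map shape {pmap.values.shape}"
        )
    if background_roi is not None:
        r0, c0, h, w = background_roi
        bg = intensity.values[r0 : r0 + h, c0 : c0 + w]
        cut = bg.mean() + threshold * bg.std(ddof=1)
    else:
        cut = threshold
    keep = intensity.values >= cut
    new_mask = pmap.mask & keep
    if not new_mask.any():
        warnings.warn(
            "intensity threshold masked every pixel", DataQualityWarning, stacklevel=2
        )
    vals = pmap.values.copy()
    vals[~new_mask] = np.nan
    return replace(pmap, values=vals, mask=new_mask)


def smooth_map(pmap: ParameterMap, gaussian_sigma_px: float = 1.0) -> ParameterMap:
    """Mask-aware Gaussian smoothing (normalized convolution).

    Masked entries contribute nothing and stay masked; valid values are
    re-normalized by the smoothed mask so holes do not drag values down.
    """
    if gaussian_sigma_px < 0:
        raise ValueError("sigma must be >= 0")
    if gaussian_sigma_px == 0:
        return replace(pmap, values=pmap.values.copy(), mask=pmap.mask.copy())
    filled = np.where(pmap.mask, pmap.values, 0.0)
    num = gaussian_filter(filled, gaussian_sigma_px, truncate=6.0)
    den = gaussian_filter(pmap.mask.astype(float), gaussian_sigma_px, truncate=6.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 1e-12, num / den, np.nan)
    sm[~pmap.mask] = np.nan
    return replace(pmap, values=sm, mask=pmap.mask.copy())


def tof_to_topology(
    delta_map: ParameterMap,
    chain: CalibrationChain,
    medium_feature: float,
) -> ParameterMap:
    """Convert a TOF map to a relative depth (topology) map.

    The TOF map is re-referenced so its minimum valid value maps to zero —
    the shortest inclusion-to-surface distance defines the surface — then
    inverted through the calibration chain.  Output depths are relative to
    that reference point, suitable for 3D rendering.
    """
    if not delta_map.mask.any():
        raise ValueError("TOF map has no valid pixels")
    dmin = float(np.nanmin(delta_map.values[delta_map.mask]))
    depth = np.full_like(delta_map.values, np.nan)
    mask = delta_map.mask.copy()
    for r, c in zip(*np.nonzero(delta_map.mask)):
        # offset so the re-referenced TOF passes through the chain's intercept
        est = depth_from_tof(
            delta_map.values[r, c] - dmin + chain.c_fluo_ps, medium_feature, chain
        )
        if est.valid:
            depth[r, c] = est.depth_mm
        else:
            mask[r, c] = False
    if not mask.any():
        raise ValueError("no valid depth estimates in topology")
    return ParameterMap(
        depth, mask, "relative_depth_mm", delta_map.bin_factor,
        provenance=f"topology of [{delta_map.provenance}]",
    )


def render_overlay(
    pmap: ParameterMap,
    intensity: IntensityImage,
    path: Union[str, Path],
    equalize: bool = True,
    cmap: str = "viridis",
) -> None:
    """Cosmetic overlay of a map on a (histogram-equalized) intensity image.

    Display helper only; equalization is standard global histogram
    equalization and carries no quantitative meaning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage import exposure

    bg = intensity.values
    if equalize:
        rng = np.ptp(bg)
        bg = exposure.equalize_hist(bg) if rng > 0 else bg
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(bg, cmap="gray")
    overlay = np.ma.masked_where(~pmap.mask, pmap.values)
    im = ax.imshow(overlay, cmap=cmap, alpha=0.7)
    fig.colorbar(im, ax=ax, label=pmap.name)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
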