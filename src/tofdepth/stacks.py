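"""Read/write time-scan stacks and apply acquisition-level corrections.

On-disk layouts (both lossless round trips):

* multi-page TIFF, one page per gate step (16-bit unsigned), with a JSON
  sidecar ``<file>.json`` carrying the timing metadata and, for synthetic
  data, the ground-truth scene;
* HDF5 with a dataset ``scan`` and attributes ``t0_ps, dt_ps, n_steps,
  gate_width_ns, modality``.

Coordinates are 0-based ``(row, col, step)``; ROIs are
``(row0, col0, height, width)``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import tifffile

from .core import GateTimeAxis, IntensityImage, TimeScan
from .errors import DataQualityWarning, ScanFormatError

__all__ = [
    "read_scan",
    "write_scan",
    "darkfield_subtract",
    "average_scans",
    "intensity_image",
    "snr",
]

_REQUIRED_META = ("t0_ps", "dt_ps", "n_steps", "modality")


def _meta_from_scan(scan: TimeScan) -> dict:
    meta = scan.axis.to_dict()
    meta["modality"] = scan.modality
    meta["provenance"] = scan.provenance
    meta["is_averaged"] = scan.is_averaged
    if scan.ground_truth is not None:
        meta["ground_truth"] = scan.ground_truth
    return meta


def _scan_from_counts(counts: np.ndarray, meta: dict, source: str) -> TimeScan:
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise ScanFormatError(
            f"{source}: missing required timing metadata field(s): {', '.join(missing)}"
        )
    axis = GateTimeAxis.from_dict(meta)
    if counts.shape[2] != axis.n_steps:
        raise ScanFormatError(
            f"{source}: file holds {counts.shape[2]} gate steps but metadata "
            f"declares n_steps={axis.n_steps}"
        )
    return TimeScan(
        counts,
        axis,
        modality=str(meta["modality"]),
        provenance=str(meta.get("provenance", source)),
        is_averaged=bool(meta.get("is_averaged", False)),
        ground_truth=meta.get("ground_truth"),
    )


def write_scan(scan: TimeScan, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a scan as multi-page TIFF (+ JSON sidecar) or HDF5."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff"
    meta = _meta_from_scan(scan)
    if format == "tiff":
        if scan.is_averaged:
            data = scan.counts.astype(np.float32)
        else:
            data = scan.counts.astype(np.uint16)
        # pages along the gate axis
        tifffile.imwrite(path, np.moveaxis(data, 2, 0))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("scan", data=scan.counts)
            for k, v in meta.items():
                if k == "ground_truth":
                    dset.attrs["ground_truth_json"] = json.dumps(v)
                else:
                    dset.attrs[k] = v
    else:
        raise ValueError(f"unknown format {format!r}")


def read_scan(path: Union[str, Path], format: Optional[str] = None) -> TimeScan:
    """Read a scan written by :func:`write_scan` (lossless round trip)."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff"
    if format == "tiff":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ScanFormatError(
                f"{path}: missing JSON sidecar {sidecar.name}; required attributes: "
                + ", ".join(_REQUIRED_META)
            )
        meta = json.loads(sidecar.read_text())
        counts = np.moveaxis(tifffile.imread(path), 0, 2)
        return _scan_from_counts(counts, meta, str(path))
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "scan" not in f:
                raise ScanFormatError(f"{path}: no 'scan' dataset")
            dset = f["scan"]
            meta = {k: dset.attrs[k] for k in dset.attrs if k != "ground_truth_json"}
            if "ground_truth_json" in dset.attrs:
                meta["ground_truth"] = json.loads(dset.attrs["ground_truth_json"])
            counts = dset[()]
        return _scan_from_counts(counts, meta, str(path))
    raise ValueError(f"unknown format {format!r}")


def darkfield_subtract(
    scan: TimeScan, dark: Union[TimeScan, IntensityImage]
) -> TimeScan:
    """Subtract a darkfield acquisition, clamping at zero.

    ``dark`` may be a full time scan (per-step subtraction) or a single
    intensity image (same dark level subtracted from every gate step).
    """
    if isinstance(dark, TimeScan):
        if dark.shape != scan.shape:
            raise ValueError(f"dark shape {dark.shape} != scan shape {scan.shape}")
        dark_arr = dark.counts
    else:
        if dark.values.shape != scan.shape[:2]:
            raise ValueError(
                f"dark image shape {dark.values.shape} != scan plane {scan.shape[:2]}"
            )
        dark_arr = dark.values[:, :, None]
    if np.all(np.asarray(dark_arr) >= scan.counts) and scan.counts.sum() > 0:
        warnings.warn(
            "darkfield is at least as bright as the scan everywhere; "
            "inputs may be swapped",
            DataQualityWarning,
            stacklevel=2,
        )
    out = np.clip(scan.counts.astype(float) - dark_arr, 0, None)
    if not scan.is_averaged:
        out = out.astype(scan.counts.dtype)
    return TimeScan(
        out,
        scan.axis,
        modality=scan.modality,
        provenance=scan.provenance + " -dark",
        is_averaged=scan.is_averaged,
        ground_truth=scan.ground_truth,
    )


def average_scans(scans: Sequence[TimeScan]) -> TimeScan:
    """Element-wise mean of replicate scans (reduces thermal and shot noise)."""
    if len(scans) == 0:
        raise ValueError("cannot average an empty list of scans")
    first = scans[0]
    for s in scans[1:]:
        if s.shape != first.shape:
            raise ValueError("scans to average must share shape")
        if s.axis != first.axis:
            raise ValueError("scans to average must share the gate-time axis")
        if s.modality != first.modality:
            raise ValueError(
                f"cannot average mixed modalities {first.modality!r} and {s.modality!r}"
            )
    mean = np.mean([s.counts for s in scans], axis=0)
    return TimeScan(
        mean,
        first.axis,
        modality=first.modality,
        provenance=f"mean of {len(scans)} scans",
        is_averaged=True,
        ground_truth=first.ground_truth,
    )


def intensity_image(
    scan: TimeScan, frame_window: Optional[Tuple[int, int]] = None
) -> IntensityImage:
    """Per-pixel mean counts over a window of gate steps ``[start, stop)``."""
    if frame_window is None:
        frame_window = (0, scan.axis.n_steps)
    start, stop = frame_window
    if start < 0 or stop > scan.axis.n_steps or stop <= start:
        raise ValueError(
            f"frame window {frame_window} empty or outside axis of "
            f"{scan.axis.n_steps} steps"
        )
    vals = scan.counts[:, :, start:stop].mean(axis=2)
    return IntensityImage(vals, n_frames_averaged=stop - start, modality=scan.modality)


def _roi_slice(roi: Tuple[int, int, int, int], shape: Tuple[int, int]):
    r0, c0, h, w = roi
    if h <= 0 or w <= 0:
        raise ValueError(f"empty ROI {roi}")
    if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
        raise ValueError(f"ROI {roi} outside image of shape {shape}")
    return slice(r0, r0 + h), slice(c0, c0 + w)


def snr(
    image: IntensityImage,
    signal_roi: Tuple[int, int, int, int],
    background_roi: Tuple[int, int, int, int],
) -> float:
    """Signal-to-noise ratio: mean(signal ROI) / sd(background ROI).

    The background must be a region adjacent to the object where no light
    emission occurs; its standard deviation uses the unbiased (n-1)
    estimator.
    """
    srs, scs = _roi_slice(signal_roi, image.values.shape)
    brs, bcs = _roi_slice(background_roi, image.values.shape)
    if (srs, scs) == (brs, bcs):
        raise ValueError("signal and background ROIs must differ")
    bg = image.values[brs, bcs]
    if bg.size < 2:
        raise ValueError("background ROI needs at least 2 pixels")
    sd = float(np.std(bg, ddof=1))
    if sd == 0:
        raise ValueError("background ROI is constant: SNR undefined")
    return float(np.mean(image.values[srs, scs]) / sd)
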