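"""Synthetic time-gated acquisitions with known ground truth.

The forward model mirrors how a gated SPAD camera sees a fluorescent
inclusion buried in a scattering medium.  A temporal profile (TP) is the
convolution of three terms:

* the instrument response function (IRF) — laser pulse, detector and gate
  jitter, measured off a Lambertian target;
* a Gaussian medium transfer function with amplitude ``A``, mean
  ``delta_tissue`` (the relative time of flight, the depth surrogate) and
  standard deviation ``sigma`` (temporal dispersion from scattering);
* for fluorescence, a causal mono-exponential decay ``exp(-t/tau)`` for the
  fluorophore lifetime.

The Gaussian * exponential product has a closed form — the exponentially
modified Gaussian (EMG) — so the medium/fluorophore kernel is sampled
analytically on the gate grid and only the IRF convolution is performed
discretely.  Photon statistics follow the binary-frame accumulation of the
sensor: each gate position accumulates ``frames_per_gate_sequence`` binary
frames, so detected counts are Binomial(N, 1 - exp(-lambda/N)), which is
Poisson at low flux and saturates (pile-up) at high flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.special import erfcx

from .core import GateTimeAxis, TimeProfile, TimeScan
from .errors import AxisError, ModelResolutionWarning

__all__ = [
    "FluorophoreModel",
    "MediumTransfer",
    "SensorResponse",
    "PhantomScene",
    "make_irf",
    "forward_profile",
    "add_photon_noise",
    "simulate_scan",
    "two_cylinder_scene",
    "gaussian_pdf",
    "emg_pdf",
]

#: FWHM / sigma ratio of a Gaussian.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# ---------------------------------------------------------------------------
# Default scene constants for the synthetic phantoms.  The slope of the
# TOF-vs-depth line grows linearly with Intralipid concentration
# (k_fluo = K_CORR_TRUE * IL + C_CORR_TRUE); these synthetic constants are of
# realistic magnitude (tens of ps per mm: a ballistic round trip in tissue
# already costs ~9 ps/mm, scattering multiplies the effective path) but are
# not measured values.
K_CORR_TRUE_PS_PER_MM_PER_IL = 12.0
C_CORR_TRUE_PS_PER_MM = 15.0
#: Reduced scattering per percent Intralipid at ~650 nm (1/mm per IL%).
MU_S_PRIME_PER_IL = 1.0
#: Baseline temporal dispersion of a shallow inclusion (ps).
SIGMA0_PS = 120.0
#: Dispersion growth with depth and scattering, ps per (mm * mm^-1).
DISPERSION_PS_PER_MM_MUSP = 25.0
#: Reflectance-pulse dispersion: baseline and growth with mu_s' (ps, ps*mm).
REFL_SIGMA0_PS = 80.0
REFL_SIGMA_PER_MUSP = 15.0
#: Reflectance-pulse delay growth with mu_s' (ps*mm); early photons shift
#: only slightly with scattering.
REFL_DELTA_PER_MUSP = 5.0


@dataclass(frozen=True)
class FluorophoreModel:
    """Mono-exponential fluorophore: lifetime ``tau`` (ns)."""

    tau_ns: float = 0.7
    quantum_yield_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_ns > 0:
            raise ValueError(f"fluorescence lifetime must be positive, got {self.tau_ns}")


@dataclass(frozen=True)
class MediumTransfer:
    """Gaussian medium transfer function (amplitude, mean, sd in ps)."""

    A: float
    delta_tissue_ps: float
    sigma_ps: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"amplitude must be positive, got {self.A}")
        if not self.sigma_ps > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma_ps}")


@dataclass(frozen=True)
class SensorResponse:
    """Binary-frame accumulation model of the gated SPAD sensor."""

    exposure_per_binary_frame_us: float = 4.0
    frames_per_gate_sequence: int = 256
    linear_range_ceiling: float = 200.0
    dark_count_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.frames_per_gate_sequence < 1:
            raise ValueError("frames_per_gate_sequence must be >= 1")
        if not 0 < self.linear_range_ceiling <= self.frames_per_gate_sequence:
            raise ValueError(
                "linear_range_ceiling must lie in (0, frames_per_gate_sequence]"
            )

    @property
    def dark_counts_per_step(self) -> float:
        """Expected dark counts accumulated per gate position."""
        return (
            self.dark_count_rate_hz
            * self.exposure_per_binary_frame_us
            * 1e-6
            * self.frames_per_gate_sequence
        )


# ---------------------------------------------------------------------------
# Analytic kernels


def gaussian_pdf(t_ps: np.ndarray, mean_ps: float, sigma_ps: float) -> np.ndarray:
    """Unit-area Gaussian density evaluated at ``t_ps``."""
    z = (np.asarray(t_ps, dtype=float) - mean_ps) / sigma_ps
    return np.exp(-0.5 * z * z) / (sigma_ps * np.sqrt(2.0 * np.pi))


def emg_pdf(
    t_ps: np.ndarray, mean_ps: float, sigma_ps: float, tau_ps: float
) -> np.ndarray:
    """Exponentially modified Gaussian density.

    Convolution of a Gaussian (mean, sigma) with a causal unit-area
    exponential ``exp(-t/tau)/tau``; evaluated in the numerically stable
    ``erfcx`` form so the long decay tail neither under- nor overflows.
    """
    t = np.asarray(t_ps, dtype=float)
    u = (t - mean_ps) / sigma_ps
    b = (sigma_ps / tau_ps - u) / np.sqrt(2.0)
    out = np.empty_like(t)
    safe = b > -25.0
    # exp(a)*erfc(b) = erfcx(b)*exp(a - b^2) with a - b^2 = -u^2/2
    out[safe] = (
        erfcx(b[safe]) * np.exp(-0.5 * u[safe] ** 2) / (2.0 * tau_ps)
    )
    # far right tail: erfc -> 2, pure exponential decay
    far = ~safe
    if np.any(far):
        out[far] = (
            np.exp(0.5 * (sigma_ps / tau_ps) ** 2 - (t[far] - mean_ps) / tau_ps)
            / tau_ps
        )
    return out


# ---------------------------------------------------------------------------
# Operations


def make_irf(
    axis: GateTimeAxis,
    pulse_fwhm_ps: float = 120.0,
    amplitude: float = 1.0,
    center_ps: Optional[float] = None,
) -> TimeProfile:
    """Noise-free instrument response: a Gaussian pulse on the gate grid.

    The instrument only bounds the laser pulse (< 120 ps FWHM); a smooth
    unimodal Gaussian is this package's model of the combined laser, detector
    and gate response.  The pulse integrates to ``amplitude`` and peaks near
    the start of the axis (a few sigma in, so the pulse is fully sampled).

    Raises
    ------
    AxisError
        If the FWHM spans fewer than 3 gate steps (under-sampled pulse).
    """
    if not pulse_fwhm_ps > 0:
        raise ValueError(f"pulse FWHM must be positive, got {pulse_fwhm_ps}")
    if pulse_fwhm_ps < 3.0 * axis.dt_ps:
        raise AxisError(
            f"IRF FWHM {pulse_fwhm_ps} ps spans fewer than 3 gate steps of "
            f"{axis.dt_ps} ps: pulse not resolvable on this axis"
        )
    sigma = pulse_fwhm_ps / FWHM_TO_SIGMA
    if center_ps is None:
        center_ps = axis.t0_ps + 4.0 * sigma
    t = axis.times_ps
    values = gaussian_pdf(t, center_ps, sigma)
    total = values.sum()
    if amplitude == 0 or total == 0:
        values = np.zeros_like(values)
    else:
        values = values * (amplitude / total)
    return TimeProfile(values, axis, modality="irf", provenance="synthetic Gaussian IRF")


def forward_profile(
    irf: TimeProfile,
    medium: MediumTransfer,
    fluor: Optional[FluorophoreModel] = None,
) -> TimeProfile:
    """Expected (noise-free) profile: IRF * Gaussian [* exponential].

    The medium kernel — a unit-area Gaussian, or its convolution with the
    causal lifetime exponential (an EMG) — is sampled analytically on a
    zero-padded extension of the gate grid (3x the axis length on each side)
    and convolved discretely with the IRF, then cropped back to the axis.
    """
    dt = irf.axis.dt_ps
    n = irf.axis.n_steps
    if medium.sigma_ps < dt / 2.0:
        warnings.warn(
            f"sigma {medium.sigma_ps} ps is below half a gate step ({dt} ps): "
            "the medium kernel is under-resolved on this axis",
            ModelResolutionWarning,
            stacklevel=2,
        )
    m = 3 * n
    t_rel = np.arange(-m, m + 1, dtype=float) * dt
    if fluor is None:
        kern = gaussian_pdf(t_rel, medium.delta_tissue_ps, medium.sigma_ps)
    else:
        kern = emg_pdf(
            t_rel, medium.delta_tissue_ps, medium.sigma_ps, fluor.tau_ns * 1000.0
        )
        kern = kern * fluor.quantum_yield_scale
    kern = kern * (medium.A * dt)
    full = signal.fftconvolve(irf.values, kern)
    out = full[m : m + n]
    return irf.with_values(
        out,
        modality="fluorescence" if fluor is not None else "reflectance",
        provenance="forward model",
    )


def _pixel_rng(seed: int, pixel_key: int) -> np.random.Generator:
    """Counter-based per-pixel stream: same pixel, same seed -> same draws."""
    return np.random.Generator(np.random.Philox(key=[int(seed), int(pixel_key)]))


def add_photon_noise(
    profile: TimeProfile,
    sensor: SensorResponse,
    seed: int,
    pixel_key: int = 0,
    include_dark: bool = True,
) -> TimeProfile:
    """Draw detected counts from the binary-frame accumulation model.

    Per gate step with expected photon count ``lam``, the detected count is
    ``Binomial(N, 1 - exp(-lam/N))`` with ``N = frames_per_gate_sequence``:
    Poisson-like at low flux, pile-up-saturated (clamped at N) at high flux.
    Deterministic given ``(seed, pixel_key)``.
    """
    lam = np.asarray(profile.values, dtype=float)
    # tolerate convolution round-off, reject genuinely negative expectations
    tol = 1e-9 * max(float(np.abs(lam).max()), 1.0)
    if np.any(lam < -tol):
        raise ValueError("expected counts must be non-negative")
    lam = np.clip(lam, 0.0, None)
    if include_dark:
        lam = lam + sensor.dark_counts_per_step
    n = sensor.frames_per_gate_sequence
    p = -np.expm1(-lam / n)
    rng = _pixel_rng(seed, pixel_key)
    counts = rng.binomial(n, p).astype(float)
    return profile.with_values(counts, provenance=profile.provenance + " +noise")


# ---------------------------------------------------------------------------
# Phantom scenes


@dataclass
class PhantomScene:
    """A synthetic phantom: fluorescent inclusions in a scattering medium.

    ``depth_mm`` holds the inclusion depth below the surface per pixel; NaN
    marks background (no inclusion).  The scene records the ground-truth
    linear TOF-depth map (``delta_tissue = k_fluo * depth + c_fluo``) so
    every downstream estimate can be checked against it.  ``il_percent`` is
    the Intralipid concentration controlling scattering; for non-Intralipid
    media it acts as a latent scattering index.
    """

    depth_mm: np.ndarray
    il_percent: float = 2.0
    mu_a_per_mm: float = 0.005
    mu_s_prime_per_mm: Optional[float] = None
    k_fluo_ps_per_mm: Optional[float] = None
    c_fluo_ps: float = 20.0
    fluor: FluorophoreModel = field(default_factory=FluorophoreModel)
    amplitude: float = 1500.0
    irf_amplitude: Optional[float] = None  # IRF acquisitions are attenuated to stay linear
    background_amplitude: float = 0.0
    sigma0_ps: float = SIGMA0_PS
    dispersion_ps_per_mm_musp: float = DISPERSION_PS_PER_MM_MUSP

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.depth_mm.ndim != 2:
            raise ValueError("depth map must be 2D")
        finite = np.isfinite(self.depth_mm)
        if np.any(self.depth_mm[finite] < 0):
            raise ValueError("inclusion depths must be >= 0")
        if self.mu_a_per_mm < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime_per_mm is None:
            self.mu_s_prime_per_mm = MU_S_PRIME_PER_IL * self.il_percent
        if not self.mu_s_prime_per_mm > 0:
            raise ValueError("mu_s_prime must be > 0")
        if self.k_fluo_ps_per_mm is None:
            self.k_fluo_ps_per_mm = (
                K_CORR_TRUE_PS_PER_MM_PER_IL * self.il_percent + C_CORR_TRUE_PS_PER_MM
            )
        if self.irf_amplitude is None:
            self.irf_amplitude = self.amplitude / 5.0

    @property
    def shape(self) -> tuple:
        return self.depth_mm.shape

    @property
    def mu_eff_per_mm(self) -> float:
        return float(
            np.sqrt(3.0 * self.mu_a_per_mm * (self.mu_a_per_mm + self.mu_s_prime_per_mm))
        )

    def delta_tissue_ps(self, depth_mm: float) -> float:
        """Ground-truth relative TOF for an inclusion at ``depth_mm``."""
        return self.k_fluo_ps_per_mm * depth_mm + self.c_fluo_ps

    def sigma_ps(self, depth_mm: float) -> float:
        """Ground-truth dispersion: grows with depth and scattering."""
        return self.sigma0_ps + self.dispersion_ps_per_mm_musp * self.mu_s_prime_per_mm * depth_mm

    def surface_amplitude(self, depth_mm: float) -> float:
        """Expected surface photon yield: luminance attenuated over 2*depth."""
        return self.amplitude * np.exp(-self.mu_eff_per_mm * 2.0 * depth_mm)

    def refl_sigma_ps(self) -> float:
        return REFL_SIGMA0_PS + REFL_SIGMA_PER_MUSP * self.mu_s_prime_per_mm

    def refl_delta_ps(self) -> float:
        return REFL_DELTA_PER_MUSP * self.mu_s_prime_per_mm

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "il_percent": self.il_percent,
            "mu_a_per_mm": self.mu_a_per_mm,
            "mu_s_prime_per_mm": self.mu_s_prime_per_mm,
            "k_fluo_ps_per_mm": self.k_fluo_ps_per_mm,
            "c_fluo_ps": self.c_fluo_ps,
            "tau_ns": self.fluor.tau_ns,
            "amplitude": self.amplitude,
            "sigma0_ps": self.sigma0_ps,
            "dispersion_ps_per_mm_musp": self.dispersion_ps_per_mm_musp,
            "depths_mm_unique": sorted(
                float(v) for v in np.unique(self.depth_mm[np.isfinite(self.depth_mm)])
            ),
        }


def uniform_scene(shape: tuple, depth_mm: float, il_percent: float = 2.0, **kw) -> PhantomScene:
    """Scene with a single uniform inclusion covering the full field."""
    return PhantomScene(np.full(shape, float(depth_mm)), il_percent=il_percent, **kw)


def two_cylinder_scene(
    shape: tuple = (32, 48),
    depths_mm: tuple = (2.5, 5.6),
    il_percent: float = 2.0,
    band_rows: int = 8,
    **kw,
) -> PhantomScene:
    """Two buried cylindrical inclusions seen from above as parallel bands.

    Mimics the tissue-like phantom with fluorescent tubes at depths of
    2.5 and 5.6 mm; the tubes run along the column axis so each projects to
    a horizontal band ``band_rows`` high.
    """
    rows, cols = shape
    depth = np.full(shape, np.nan)
    centers = (rows // 4, 3 * rows // 4)
    for z, rc in zip(depths_mm, centers):
        r0 = max(rc - band_rows // 2, 0)
        depth[r0 : r0 + band_rows, cols // 8 : cols - cols // 8] = z
    return PhantomScene(depth, il_percent=il_percent, **kw)


def simulate_scan(
    scene: PhantomScene,
    axis: GateTimeAxis,
    sensor: SensorResponse,
    modality: str,
    seed: int,
    irf_fwhm_ps: float = 120.0,
    noise: bool = True,
) -> TimeScan:
    """Simulate a full time scan of a phantom scene.

    fluorescence
        Pixels over an inclusion get the EMG forward model with
        ``delta_tissue = k_fluo * depth + c_fluo``, dispersion growing with
        depth and scattering, and surface intensity attenuated by
        ``exp(-2 * mu_eff * depth)``.  Background pixels get dark counts only.
    reflectance
        Every pixel returns the surface backscatter: a Gaussian medium
        kernel whose delay and width grow with the medium's mu_s'.
    irf
        Every pixel sees the bare instrument response.

    Same seed -> bit-identical stack (per-pixel counter-based streams).
    """
    if modality not in ("fluorescence", "reflectance", "irf"):
        raise ValueError(f"cannot simulate modality {modality!r}")
    rows, cols = scene.shape
    irf = make_irf(axis, pulse_fwhm_ps=irf_fwhm_ps, amplitude=1.0)

    cache: dict = {}

    def expected_for(z: float) -> np.ndarray:
        key = (modality, None if np.isnan(z) else float(z))
        if key in cache:
            return cache[key]
        if modality == "irf":
            vals = irf.values * scene.irf_amplitude
        elif modality == "reflectance":
            med = MediumTransfer(
                A=scene.amplitude,
                delta_tissue_ps=scene.refl_delta_ps(),
                sigma_ps=scene.refl_sigma_ps(),
            )
            vals = forward_profile(irf, med, None).values
        elif np.isnan(z):
            vals = np.full(axis.n_steps, scene.background_amplitude / axis.n_steps)
        else:
            med = MediumTransfer(
                A=scene.surface_amplitude(z),
                delta_tissue_ps=scene.delta_tissue_ps(z),
                sigma_ps=scene.sigma_ps(z),
            )
            vals = forward_profile(irf, med, scene.fluor).values
        vals = np.clip(vals, 0.0, None)
        cache[key] = vals
        return vals

    counts = np.empty((rows, cols, axis.n_steps), dtype=np.uint16)
    template = TimeProfile(np.zeros(axis.n_steps), axis)
    for r in range(rows):
        for c in range(cols):
            lam = expected_for(scene.depth_mm[r, c])
            if noise:
                noisy = add_photon_noise(
                    template.with_values(lam), sensor, seed, pixel_key=r * cols + c
                )
                counts[r, c] = noisy.values.astype(np.uint16)
            else:
                counts[r, c] = np.round(lam).astype(np.uint16)
    return TimeScan(
        counts,
        axis,
        modality=modality,
        provenance=f"simulated seed={seed}",
        ground_truth=scene.to_dict(),
    )
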