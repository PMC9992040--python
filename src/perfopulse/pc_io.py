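"""Data model and I/O for 2D cine phase-contrast (PC) MRI.

A velocity-encoded 2D-PC acquisition yields, for every reconstructed cardiac
phase, a magnitude image and a phase image.  The pixel phase is proportional
to the through-plane blood velocity: a phase of pi corresponds to the
velocity-encoding limit (venc), so ``v = venc * phase / pi``.

Series are stored on disk as a pair of uncompressed-or-gzipped NIfTI volumes
(``<prefix>_mag.nii.gz`` and ``<prefix>_phase.nii.gz``, spatial dims first,
cardiac phase last) plus a YAML sidecar (``<prefix>.yaml``) carrying the
acquisition metadata that NIfTI headers do not hold (venc, heart rate, grid
kind).  ROI masks are single 2D NIfTI (or PNG) rasters on the reconstructed
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "CinePCSeries",
    "ROIMask",
    "ConfigurationError",
    "FormatError",
    "phase_to_velocity",
    "zero_fill_reconstruct",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "wrap_phase",
]

SIDECAR_KEYS = ("venc_cm_s", "pixel_spacing_mm", "n_cardiac_phases", "grid_kind")


class ConfigurationError(ValueError):
    """Required acquisition metadata is missing or unusable."""


class FormatError(ValueError):
    """On-disk data do not match the expected layout or metadata."""


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into [-pi, pi)."""
    return np.mod(np.asarray(phase, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class CinePCSeries:
    """Magnitude and phase image stacks over one cardiac cycle.

    Arrays are indexed ``[cardiac_phase, row, col]``.  ``phase`` is stored in
    radians in [-pi, pi); values outside the range are wrapped on
    construction.  ``grid_kind`` distinguishes the acquired grid from the
    zero-filled reconstructed grid on which detection operates.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    venc_cm_s: float
    heart_rate_bpm: float | None = None
    grid_kind: str = "reconstructed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = wrap_phase(np.asarray(self.phase, dtype=float))
        if self.magnitude.ndim != 3:
            raise FormatError("magnitude must be 3-D [cardiac_phase, row, col]")
        if self.magnitude.shape != self.phase.shape:
            raise FormatError(
                f"magnitude shape {self.magnitude.shape} != phase shape {self.phase.shape}"
            )
        if np.any(self.magnitude < 0):
            raise FormatError("magnitude must be non-negative")
        n = self.magnitude.shape[0]
        if not 2 <= n <= 64:
            raise FormatError(f"n_cardiac_phases={n} outside supported range [2, 64]")
        self.pixel_spacing_mm = (float(self.pixel_spacing_mm[0]), float(self.pixel_spacing_mm[1]))
        if min(self.pixel_spacing_mm) <= 0:
            raise FormatError("pixel_spacing_mm must be positive")
        if self.grid_kind not in ("acquired", "reconstructed"):
            raise FormatError(f"unknown grid_kind {self.grid_kind!r}")

    @property
    def n_cardiac_phases(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape

    @property
    def complex_signal(self) -> np.ndarray:
        """Complex image stack ``magnitude * exp(i*phase)``."""
        return self.magnitude * np.exp(1j * self.phase)

    def velocity(self) -> np.ndarray:
        """Velocity stack in cm/s (see :func:`phase_to_velocity`)."""
        return phase_to_velocity(self)


@dataclass
class ROIMask:
    """Binary search region (e.g. basal ganglia) on the reconstructed grid."""

    mask: np.ndarray
    label: str = "ROI"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise FormatError("ROI mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def phase_to_velocity(series: CinePCSeries) -> np.ndarray:
    """Convert the phase stack to through-plane velocity in cm/s.

    Uses the standard PC-MRI relation ``v = venc * phase / pi``: a phase of
    +/-pi maps to +/-venc.  Velocities beyond venc alias and cannot be
    represented.
    """
    if series.venc_cm_s is None or not series.venc_cm_s > 0:
        raise ConfigurationError("venc_cm_s must be a positive number")
    return series.venc_cm_s * series.phase / np.pi


def _zero_fill_frame(frame: np.ndarray, n_new: tuple[int, int]) -> np.ndarray:
    """Sinc-interpolate one complex frame to a finer grid via k-space padding.

    The padded spectrum is evaluated at the *pixel centers* of the new grid
    under the convention that pixel (r, c) sits at ((r+0.5)*spacing,
    (c+0.5)*spacing): a linear phase ramp shifts the interpolant by the
    half-pixel offset between the two grids, so old and new pixel-center
    coordinate systems agree physically.
    """
    n_r, n_c = frame.shape
    n_new_r, n_new_c = n_new
    spec = np.fft.fftshift(np.fft.fft2(frame))
    kr = np.arange(n_r) - n_r // 2
    kc = np.arange(n_c) - n_c // 2
    # shift (in old-pixel units) between old and new pixel-center conventions
    du_r = 0.5 * (n_r / n_new_r - 1.0)
    du_c = 0.5 * (n_c / n_new_c - 1.0)
    ramp = np.exp(2j * np.pi * kr * du_r / n_r)[:, None] * np.exp(
        2j * np.pi * kc * du_c / n_c
    )[None, :]
    out = np.zeros((n_new_r, n_new_c), dtype=complex)
    sr = n_new_r // 2 - n_r // 2
    sc = n_new_c // 2 - n_c // 2
    out[sr : sr + n_r, sc : sc + n_c] = spec * ramp
    return np.fft.ifft2(np.fft.ifftshift(out)) * (n_new_r * n_new_c) / (n_r * n_c)


def zero_fill_reconstruct(
    series: CinePCSeries, target_spacing_mm: float | tuple[float, float]
) -> CinePCSeries:
    """Zero-fill the series in k-space to a finer reconstructed grid.

    Each complex frame is Fourier transformed, symmetrically zero padded and
    inverse transformed.  The spatial mean of every frame is preserved to
    numerical precision (only zeros are added around the spectrum) and values
    at the original sample positions are reproduced exactly, since zero
    filling evaluates the same band-limited interpolant on a denser grid.

    The matrix size is rounded *up* when the field of view is not an integer
    multiple of the requested spacing; the actual spacing achieved is
    recorded in ``meta['zero_fill']``.
    """
    if series.grid_kind != "acquired":
        raise ConfigurationError("zero_fill_reconstruct expects an acquired-grid series")
    if np.isscalar(target_spacing_mm):
        target = (float(target_spacing_mm), float(target_spacing_mm))
    else:
        target = (float(target_spacing_mm[0]), float(target_spacing_mm[1]))
    sp = series.pixel_spacing_mm
    if target[0] > sp[0] + 1e-12 or target[1] > sp[1] + 1e-12:
        raise ConfigurationError(
            f"target spacing {target} must not exceed acquired spacing {sp}"
        )
    n_phases, n_r, n_c = series.shape
    fov = (n_r * sp[0], n_c * sp[1])
    n_new = (int(np.ceil(fov[0] / target[0] - 1e-9)), int(np.ceil(fov[1] / target[1] - 1e-9)))
    actual = (fov[0] / n_new[0], fov[1] / n_new[1])
    stack = np.empty((n_phases, *n_new), dtype=complex)
    cplx = series.complex_signal
    for t in range(n_phases):
        stack[t] = _zero_fill_frame(cplx[t], n_new)
    meta = dict(series.meta)
    meta["zero_fill"] = {
        "requested_spacing_mm": target,
        "actual_spacing_mm": actual,
        "acquired_matrix": (n_r, n_c),
        "reconstructed_matrix": n_new,
    }
    return CinePCSeries(
        magnitude=np.abs(stack),
        phase=np.angle(stack),
        pixel_spacing_mm=actual,
        venc_cm_s=series.venc_cm_s,
        heart_rate_bpm=series.heart_rate_bpm,
        grid_kind="reconstructed",
        meta=meta,
    )


# ---------------------------------------------------------------------------
# On-disk format


def _spatial_affine(spacing: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    return aff


def write_series(series: CinePCSeries, prefix: str | Path) -> dict[str, Path]:
    """Write a series as ``<prefix>_mag.nii.gz``/``<prefix>_phase.nii.gz`` + YAML sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _spatial_affine(series.pixel_spacing_mm)
    paths = {
        "magnitude": prefix.parent / f"{prefix.name}_mag.nii.gz",
        "phase": prefix.parent / f"{prefix.name}_phase.nii.gz",
        "sidecar": prefix.parent / f"{prefix.name}.yaml",
    }
    # NIfTI wants spatial dims first; store [row, col, cardiac_phase]
    nib.save(nib.Nifti1Image(np.moveaxis(series.magnitude, 0, -1), aff), paths["magnitude"])
    nib.save(nib.Nifti1Image(np.moveaxis(series.phase, 0, -1), aff), paths["phase"])
    sidecar = {
        "venc_cm_s": float(series.venc_cm_s),
        "pixel_spacing_mm": [float(s) for s in series.pixel_spacing_mm],
        "heart_rate_bpm": None if series.heart_rate_bpm is None else float(series.heart_rate_bpm),
        "n_cardiac_phases": int(series.n_cardiac_phases),
        "grid_kind": series.grid_kind,
    }
    paths["sidecar"].write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return paths


def read_series(prefix: str | Path) -> CinePCSeries:
    """Read a series written by :func:`write_series`.

    Raises :class:`FormatError` naming the offending field when the sidecar
    is missing, incomplete, or inconsistent with the image volumes.  Phase
    values stored outside [-pi, pi) are wrapped with a logged warning.
    """
    prefix = Path(prefix)
    sidecar_path = prefix.parent / f"{prefix.name}.yaml"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    if not isinstance(sidecar, dict):
        raise FormatError(f"sidecar {sidecar_path} is not a mapping")
    for key in SIDECAR_KEYS:
        if key not in sidecar:
            raise FormatError(f"sidecar missing required field {key!r}")
    mag_path = prefix.parent / f"{prefix.name}_mag.nii.gz"
    phase_path = prefix.parent / f"{prefix.name}_phase.nii.gz"
    for p in (mag_path, phase_path):
        if not p.exists():
            raise FormatError(f"missing image volume {p}")
    mag = np.moveaxis(np.asarray(nib.load(mag_path).get_fdata()), -1, 0)
    phase = np.moveaxis(np.asarray(nib.load(phase_path).get_fdata()), -1, 0)
    if mag.shape != phase.shape:
        raise FormatError("field 'phase': shape differs from magnitude volume")
    if mag.shape[0] != int(sidecar["n_cardiac_phases"]):
        raise FormatError(
            "field 'n_cardiac_phases': sidecar says "
            f"{sidecar['n_cardiac_phases']}, volume has {mag.shape[0]}"
        )
    if np.any(phase < -np.pi) or np.any(phase >= np.pi):
        log.warning("phase values outside [-pi, pi) in %s; wrapping", phase_path)
        phase = wrap_phase(phase)
    return CinePCSeries(
        magnitude=mag,
        phase=phase,
        pixel_spacing_mm=tuple(sidecar["pixel_spacing_mm"]),
        venc_cm_s=float(sidecar["venc_cm_s"]),
        heart_rate_bpm=(
            None if sidecar.get("heart_rate_bpm") is None else float(sidecar["heart_rate_bpm"])
        ),
        grid_kind=str(sidecar["grid_kind"]),
    )


def write_mask(roi: ROIMask, path: str | Path, pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)) -> Path:
    """Write an ROI mask as a NIfTI (``.nii``/``.nii.gz``) or PNG raster."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (roi.mask.astype(np.uint8) * 255))
    else:
        nib.save(
            nib.Nifti1Image(roi.mask.astype(np.uint8), _spatial_affine(pixel_spacing_mm)), path
        )
    return path


def read_mask(path: str | Path, label: str | None = None) -> ROIMask:
    """Read a binary ROI mask from NIfTI or PNG; any nonzero pixel is in-mask."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing mask file {path}")
    if path.suffix == ".png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # collapse RGB(A)
            data = data[..., :3].max(axis=-1)
    else:
        data = np.asarray(nib.load(path).get_fdata())
        data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(f"mask in {path} is not a single 2-D raster")
    return ROIMask(mask=data > 0, label=label or path.stem)
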