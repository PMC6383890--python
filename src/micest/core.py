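"""Core domain types shared across the pipeline.

Containers for proton pools, saturation pulses, scanner context, z-spectra,
CEST image stacks, B0 maps and rectangular regions of interest. All frequency
offsets are in ppm relative to the bulk-water resonance; image geometry is in
mm; B1 amplitudes in microtesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "NumericalError",
    "PoolParameters",
    "SaturationPulse",
    "ScannerContext",
    "ZSpectrum",
    "ImageGeometry",
    "CestStack",
    "B0Map",
    "RoiSpec",
    "GAMMA_BAR_MHZ_PER_T",
]

#: Proton gyromagnetic ratio / 2pi, MHz/T (equivalently Hz/uT).
GAMMA_BAR_MHZ_PER_T = 42.577


class ConfigurationError(ValueError):
    """Invalid pool, pulse, ROI or study configuration."""


class NumericalError(RuntimeError):
    """A solver failed to produce a usable result."""


@dataclass(frozen=True)
class PoolParameters:
    """One proton pool of the Bloch-McConnell exchange model.

    Parameters
    ----------
    name : str
        Label ("water", "hydroxyl", ...).
    t1, t2 : float
        Longitudinal / transverse relaxation times, seconds.
    shift : float
        Chemical shift relative to water, ppm. Water must be 0.
    fraction : float
        Equilibrium magnetization relative to water (water = 1).
        0 is allowed and denotes an absent (degenerate) pool.
    k_exchange : float
        Solute->water exchange rate, 1/s (0 for water). The reverse
        water->solute rate is always ``fraction * k_exchange`` (detailed
        balance) and is never stored.
    """

    name: str
    t1: float
    t2: float
    shift: float = 0.0
    fraction: float = 1.0
    k_exchange: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ConfigurationError(
                f"pool {self.name!r}: relaxation times must be positive"
            )
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(
                f"pool {self.name!r}: fraction must be in [0, 1]"
            )
        if self.k_exchange < 0:
            raise ConfigurationError(
                f"pool {self.name!r}: exchange rate must be >= 0"
            )

    def is_water_like(self) -> bool:
        return self.shift == 0.0 and self.fraction == 1.0


@dataclass(frozen=True)
class SaturationPulse:
    """Constant-amplitude (hard) saturation pulse: ``b1`` uT for ``duration`` s."""

    b1: float
    duration: float
    shape: str = "hard"

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ConfigurationError("pulse amplitude must be >= 0 uT")
        if self.duration <= 0:
            raise ConfigurationError("pulse duration must be positive")
        if self.shape != "hard":
            raise ConfigurationError("only hard (constant) pulses are supported")


@dataclass(frozen=True)
class ScannerContext:
    """Static field context; converts ppm to Hz.

    At 9.4 T, 1 ppm = 9.4 * 42.577 ~= 400.2 Hz.
    """

    field_strength: float = 9.4
    gamma_bar: float = GAMMA_BAR_MHZ_PER_T

    def __post_init__(self) -> None:
        if self.field_strength <= 0:
            raise ConfigurationError("field strength must be positive")

    @property
    def hz_per_ppm(self) -> float:
        return self.field_strength * self.gamma_bar


class ZSpectrum:
    """Normalized saturated signal M_sat/M_0 versus offset (ppm).

    Offsets must be strictly increasing. Values are expected in
    [0, 1 + noise_allowance]; small negative excursions from noise are
    clipped-checked, not clipped.
    """

    __slots__ = ("offsets", "values")

    def __init__(
        self,
        offsets: Sequence[float] | np.ndarray,
        values: Sequence[float] | np.ndarray,
        noise_allowance: float = 0.1,
    ) -> None:
        offsets = np.asarray(offsets, dtype=float)
        values = np.asarray(values, dtype=float)
        if offsets.ndim != 1 or offsets.shape != values.shape:
            raise ConfigurationError("offsets and values must be matching 1-D arrays")
        if offsets.size == 0:
            raise ConfigurationError("z-spectrum needs at least one offset")
        if np.any(np.diff(offsets) <= 0):
            raise ConfigurationError("offsets must be strictly increasing")
        if np.any(~np.isfinite(values)):
            raise ConfigurationError("z-spectrum values must be finite")
        if np.any(values < -noise_allowance) or np.any(values > 1.0 + noise_allowance):
            raise ConfigurationError(
                "z-spectrum values outside [0, 1] beyond the noise allowance"
            )
        self.offsets = offsets
        self.values = values

    def __len__(self) -> int:
        return self.offsets.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ZSpectrum({self.offsets.size} offsets, "
            f"[{self.offsets[0]:+.2f}, {self.offsets[-1]:+.2f}] ppm)"
        )


@dataclass(frozen=True)
class ImageGeometry:
    """In-plane geometry of a 2-D acquisition."""

    fov_mm: tuple[float, float] = (20.0, 20.0)
    matrix: tuple[int, int] = (128, 128)
    slice_thickness_mm: float = 2.0

    def __post_init__(self) -> None:
        if min(self.fov_mm) <= 0 or min(self.matrix) <= 0:
            raise ConfigurationError("geometry must be positive")
        if self.slice_thickness_mm <= 0:
            raise ConfigurationError("slice thickness must be positive")

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])


@dataclass
class CestStack:
    """Per-offset saturated images plus the unsaturated reference.

    ``volumes`` has shape (n_offsets, ny, nx); ``reference`` (ny, nx);
    ``offsets_ppm`` is the sidecar offset table, one entry per volume.
    """

    volumes: np.ndarray
    offsets_ppm: np.ndarray
    reference: np.ndarray
    geometry: ImageGeometry = field(default_factory=ImageGeometry)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.volumes.ndim != 3:
            raise ConfigurationError("volumes must be (n_offsets, ny, nx)")
        if self.volumes.shape[0] != self.offsets_ppm.size:
            raise ConfigurationError("one volume per offset required")
        if self.reference.shape != self.volumes.shape[1:]:
            raise ConfigurationError("reference grid must match the volumes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape


@dataclass
class B0Map:
    """Per-voxel water frequency shift (ppm) with a validity mask.

    Invalid voxels carry NaN in ``shift``.
    """

    shift: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.shift.shape != self.valid.shape:
            raise ConfigurationError("shift and valid mask must share a shape")
        self.shift = np.where(self.valid, self.shift, np.nan)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular ROI in image-plane mm coordinates (origin: top-left corner).

    The study convention is a 1.25 x 1.25 mm square over an injection site;
    with a 20 mm / 128 px field of view that is an 8 x 8 pixel window.
    """

    center_mm: tuple[float, float]
    width_mm: float = 1.25
    height_mm: float = 1.25
    side: str = ""

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ConfigurationError("ROI dimensions must be positive")

    def to_slices(self, geometry: ImageGeometry) -> tuple[slice, slice]:
        """Whole-pixel (row, col) window for this ROI on ``geometry``'s grid."""
        py, px = geometry.pixel_size_mm[1], geometry.pixel_size_mm[0]
        cy = self.center_mm[1] / py
        cx = self.center_mm[0] / px
        hy = max(1, round(self.height_mm / py))
        hx = max(1, round(self.width_mm / px))
        r0 = int(round(cy - hy / 2))
        c0 = int(round(cx - hx / 2))
        ny, nx = geometry.matrix[1], geometry.matrix[0]
        if r0 < 0 or c0 < 0 or r0 + hy > ny or c0 + hx > nx:
            raise ConfigurationError(
                f"ROI {self.side or self.center_mm} falls outside the field of view"
            )
        return slice(r0, r0 + hy), slice(c0, c0 + hx)

    def overlaps(self, other: "RoiSpec", geometry: ImageGeometry) -> bool:
        ra, ca = self.to_slices(geometry)
        rb, cb = other.to_slices(geometry)
        return not (
            ra.stop <= rb.start
            or rb.stop <= ra.start
            or ca.stop <= cb.start
            or cb.stop <= ca.start
        )
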