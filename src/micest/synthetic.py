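"""Synthetic-data generators: CEST/WASSR phantoms, histology slides and
metabolite tables.

Every generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs. Each returns a ground-truth bundle sufficient to
score the downstream pipeline without re-deriving anything.

The CEST phantom emulates the in vivo design: a "lesion" ROI (injection
site) with an elevated hydroxyl solute fraction, a contralateral control
ROI, a smooth polynomial B0 field (optionally with a localized susceptibility
artifact mimicking tissue-air interfaces), and additive Gaussian noise on the
magnitude images (Rician optional). The histology generator draws dark
elliptical microglial somata with thin radiating processes on an uneven
bright background. The metabolite generator produces LCModel-style rows
(concentration, %SD, linewidth, SNR) for an LPS side and a vehicle side per
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .bloch import zspectrum_values
from .core import (
    CestStack,
    ConfigurationError,
    ImageGeometry,
    PoolParameters,
    RoiSpec,
    SaturationPulse,
    ScannerContext,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SyntheticSlideSpec",
    "default_pools",
    "default_offsets_cest",
    "default_offsets_wassr",
    "make_cest_phantom",
    "make_slide",
    "make_metabolite_table",
    "LESION_FRACTION_SCALE",
]

#: hydroxyl-fraction multiplier in the lesion ROI of the default phantom,
#: calibrated so the noiseless ROI asymmetry at 0.6 ppm is ~10.7% against a
#: ~8.2% control — the scale of the in vivo contrast between the LPS and
#: vehicle injection sites.
LESION_FRACTION_SCALE = 1.4079


def default_pools(solute_fraction: float = 0.0037324) -> list[PoolParameters]:
    """Three-pool set at 9.4 T: water, hydroxyl (+0.6 ppm, k=600/s), broad
    macromolecular pool (-2.4 ppm). Plausible defaults, not measured values."""
    return [
        PoolParameters("water", t1=1.8, t2=0.040),
        PoolParameters(
            "hydroxyl", t1=1.0, t2=0.010, shift=0.6,
            fraction=solute_fraction, k_exchange=600.0,
        ),
        PoolParameters(
            "macromolecular", t1=1.0, t2=0.0005, shift=-2.4,
            fraction=0.001, k_exchange=40.0,
        ),
    ]


def default_offsets_cest() -> np.ndarray:
    """Saturation offsets spanning +/-4 ppm at 0.2 ppm intervals.

    41 offsets including 0 ppm; the acquisition protocol states 40 offsets at
    0.2 ppm intervals in +/-4 ppm, which is geometrically ambiguous, so the
    generator takes the symmetric 0.2-ppm comb and keeps the list explicit.
    """
    return np.round(np.linspace(-4.0, 4.0, 41), 10)


def default_offsets_wassr(n: int = 35) -> np.ndarray:
    """35 uniformly spaced WASSR offsets in +/-1 ppm (spacing unstated in the
    protocol; uniform is the generator default, count configurable)."""
    return np.linspace(-1.0, 1.0, n)


DEFAULT_CEST_PULSE = SaturationPulse(b1=0.9, duration=1.6)
DEFAULT_WASSR_PULSE = SaturationPulse(b1=0.1, duration=0.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, lesion layout, B0 field, and noise of a CEST phantom."""

    grid: tuple[int, int] = (128, 128)
    fov_mm: tuple[float, float] = (20.0, 20.0)
    lesion_roi: RoiSpec = field(
        default_factory=lambda: RoiSpec((6.25, 10.0), side="LPS")
    )
    control_roi: RoiSpec = field(
        default_factory=lambda: RoiSpec((13.75, 10.0), side="PBS")
    )
    lesion_fraction_scale: float = LESION_FRACTION_SCALE
    control_fraction_scale: float = 1.0
    #: polynomial B0 coefficients (ppm) over normalized coords u,v in [-1,1]:
    #: b0 = c0 + c1*u + c2*v + c3*u*v + c4*u^2 + c5*v^2
    b0_poly: tuple[float, ...] = (0.01, 0.03, 0.02, 0.015, -0.02, 0.01)
    #: optional localized Gaussian artifact (amplitude ppm, cx, cy mm, sigma mm)
    b0_artifact: tuple[float, float, float, float] | None = None
    noise_sd: float = 0.01
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        geom = self.geometry
        self.lesion_roi.to_slices(geom)
        self.control_roi.to_slices(geom)
        if self.lesion_roi.overlaps(self.control_roi, geom):
            raise ConfigurationError("lesion and control ROIs overlap")

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(fov_mm=self.fov_mm, matrix=self.grid)

    def b0_field(self) -> np.ndarray:
        nx, ny = self.grid
        u = np.linspace(-1.0, 1.0, nx)[None, :]
        v = np.linspace(-1.0, 1.0, ny)[:, None]
        c = self.b0_poly + (0.0,) * (6 - len(self.b0_poly))
        f = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u**2 + c[5] * v**2
        f = np.broadcast_to(f, (ny, nx)).copy()
        if self.b0_artifact is not None:
            amp, cx, cy, sigma = self.b0_artifact
            px = self.geometry.pixel_size_mm
            x = (np.arange(nx) + 0.5) * px[0]
            y = (np.arange(ny) + 0.5) * px[1]
            dx = (x[None, :] - cx) ** 2
            dy = (y[:, None] - cy) ** 2
            f += amp * np.exp(-(dx + dy) / (2.0 * sigma**2))
        return f

    def fraction_scale_map(self) -> np.ndarray:
        nx, ny = self.grid
        m = np.ones((ny, nx))
        geom = self.geometry
        r, c = self.lesion_roi.to_slices(geom)
        m[r, c] = self.lesion_fraction_scale
        r, c = self.control_roi.to_slices(geom)
        m[r, c] = self.control_fraction_scale
        return m


@dataclass
class PhantomTruth:
    """Everything needed to score the pipeline on a phantom."""

    fraction_scale_map: np.ndarray
    b0_field: np.ndarray
    solute_fraction_base: float
    asym_lesion_percent: float
    asym_control_percent: float
    asym_difference_percent: float
    delta_ppm: float = 0.6


def _scale_pools(pools: Sequence[PoolParameters], scale: float) -> list[PoolParameters]:
    out = [pools[0]]
    for p in pools[1:]:
        if p.name == "hydroxyl":
            out.append(replace(p, fraction=min(1.0, p.fraction * scale)))
        else:
            out.append(p)
    return out


def _voxelwise_z(
    pools: Sequence[PoolParameters],
    pulse: SaturationPulse,
    offsets: np.ndarray,
    fraction_scale: np.ndarray,
    b0: np.ndarray,
    context: ScannerContext,
    mode: str,
) -> np.ndarray:
    """(n_off, ny, nx) noiseless z-values; offsets are shifted per voxel so a
    voxel with B0 shift b sees its water dip at +b."""
    ny, nx = b0.shape
    out = np.empty((offsets.size, ny, nx))
    flat_scale = fraction_scale.ravel()
    flat_b0 = b0.ravel()
    for s in np.unique(flat_scale):
        idx = np.nonzero(flat_scale == s)[0]
        p = _scale_pools(pools, float(s))
        # chunk to bound the stacked-matrix memory footprint
        for start in range(0, idx.size, 2048):
            sub = idx[start : start + 2048]
            offs = offsets[None, :] - flat_b0[sub][:, None]
            z = zspectrum_values(pools=p, pulse=pulse, offsets_ppm=offs.ravel(),
                                 context=context, mode=mode)
            out.reshape(offsets.size, -1)[:, sub] = z.reshape(sub.size, offsets.size).T
    return out


def _add_noise(signal: np.ndarray, sd: float, rng: np.random.Generator,
               rician: bool) -> np.ndarray:
    if sd == 0:
        return signal
    if rician:
        re = signal + rng.normal(0.0, sd, signal.shape)
        im = rng.normal(0.0, sd, signal.shape)
        return np.hypot(re, im)
    return signal + rng.normal(0.0, sd, signal.shape)


def make_cest_phantom(
    spec: PhantomSpec,
    pools: Sequence[PoolParameters] | None = None,
    cest_pulse: SaturationPulse = DEFAULT_CEST_PULSE,
    wassr_pulse: SaturationPulse = DEFAULT_WASSR_PULSE,
    context: ScannerContext | None = None,
    cest_offsets: np.ndarray | None = None,
    wassr_offsets: np.ndarray | None = None,
    mode: str = "steady_state",
    reference_intensity: float = 1000.0,
) -> tuple[CestStack, CestStack, PhantomTruth]:
    """Simulate paired CEST and WASSR stacks with known ground truth.

    Per voxel, z-values come from the Bloch-McConnell engine with the voxel's
    hydroxyl-fraction multiplier and with offsets shifted by the voxel's B0
    field; the reference image is the unsaturated intensity; noise is seeded
    by ``spec.seed``. The truth bundle records the fraction map, the B0
    field, and the noiseless ROI asymmetry contrast at 0.6 ppm.
    """
    if pools is None:
        pools = default_pools()
    if context is None:
        context = ScannerContext()
    if cest_offsets is None:
        cest_offsets = default_offsets_cest()
    if wassr_offsets is None:
        wassr_offsets = default_offsets_wassr()
    if len(pools) < 2:
        raise ConfigurationError("phantom needs a solute pool to modulate")

    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    b0 = spec.b0_field()
    fmap = spec.fraction_scale_map()

    s0 = reference_intensity
    z_cest = _voxelwise_z(pools, cest_pulse, cest_offsets, fmap, b0, context, mode)
    z_wassr = _voxelwise_z(pools, wassr_pulse, wassr_offsets, fmap, b0, context, mode)
    sd = spec.noise_sd * s0
    cest = CestStack(
        volumes=_add_noise(z_cest * s0, sd, rng, spec.rician),
        offsets_ppm=cest_offsets,
        reference=_add_noise(np.full(b0.shape, s0), sd, rng, spec.rician),
        geometry=geom,
    )
    wassr = CestStack(
        volumes=_add_noise(z_wassr * s0, sd, rng, spec.rician),
        offsets_ppm=wassr_offsets,
        reference=_add_noise(np.full(b0.shape, s0), sd, rng, spec.rician),
        geometry=geom,
    )

    delta = 0.6
    asym = {}
    for label, scale in (
        ("lesion", spec.lesion_fraction_scale),
        ("control", spec.control_fraction_scale),
    ):
        p = _scale_pools(pools, scale)
        z = zspectrum_values(p, cest_pulse, np.array([-delta, delta]), context, mode)
        asym[label] = 100.0 * float(z[0] - z[1])
    truth = PhantomTruth(
        fraction_scale_map=fmap,
        b0_field=b0,
        solute_fraction_base=pools[1].fraction,
        asym_lesion_percent=asym["lesion"],
        asym_control_percent=asym["control"],
        asym_difference_percent=asym["lesion"] - asym["control"],
        delta_ppm=delta,
    )
    return cest, wassr, truth


# ---------------------------------------------------------------------------
# histology slides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Layout of a synthetic Iba-1 slide: dark somata on uneven background."""

    size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.46
    n_somata: int = 50
    soma_area_mean_um2: float = 40.0
    soma_area_sd_um2: float = 8.0
    processes_per_soma: float = 3.0
    background_level: float = 0.75
    background_gradient: float = 0.15
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel size must be positive")
        if self.soma_area_mean_um2 <= 0:
            raise ConfigurationError("soma areas must be positive")
        if self.n_somata < 0 or self.noise_sd < 0:
            raise ConfigurationError("invalid slide spec")


def make_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a slide and its ground-truth soma table.

    Somata are non-overlapping ellipses (the ground truth is the rasterized
    ellipse only); thin radiating processes are distractors a segmenter must
    reject by size. Returns ``(image, table)`` with image values in [0, 1]
    and columns soma_id, centroid_x_px, centroid_y_px, area_px, area_um2.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.size_px
    # uneven background: linear gradient plus a smooth low-order bump
    x = np.linspace(0.0, 1.0, nx)[None, :]
    y = np.linspace(0.0, 1.0, ny)[:, None]
    img = spec.background_level * np.ones((ny, nx))
    img += spec.background_gradient * (x - 0.5)
    img += 0.3 * spec.background_gradient * np.sin(2.1 * np.pi * y) * np.cos(1.3 * np.pi * x)
    background = img.copy()

    px2 = spec.pixel_size_um**2
    centers: list[tuple[float, float]] = []
    rows = []
    max_r = np.sqrt((spec.soma_area_mean_um2 + 4 * spec.soma_area_sd_um2) / np.pi) / spec.pixel_size_um
    margin = max(3.0, 1.6 * max_r)
    attempts = 0
    soma_id = 0
    while soma_id < spec.n_somata and attempts < 200 * max(1, spec.n_somata):
        attempts += 1
        cy = rng.uniform(margin, ny - margin)
        cx = rng.uniform(margin, nx - margin)
        if any((cy - a) ** 2 + (cx - b) ** 2 < (3.2 * max_r) ** 2 for a, b in centers):
            continue
        area_um2 = max(spec.soma_area_mean_um2 / 4.0,
                       rng.normal(spec.soma_area_mean_um2, spec.soma_area_sd_um2))
        r_px = np.sqrt(area_um2 / np.pi) / spec.pixel_size_um
        ecc = rng.uniform(0.85, 1.18)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = draw_ellipse(cy, cx, r_px * ecc, r_px / ecc, shape=img.shape,
                              rotation=theta)
        if rr.size == 0:
            continue
        img[rr, cc] = background[rr, cc] * 0.30
        centers.append((cy, cx))
        rows.append(
            {
                "soma_id": soma_id,
                "centroid_y_px": float(np.mean(rr)),
                "centroid_x_px": float(np.mean(cc)),
                "area_px": int(rr.size),
                "area_um2": float(rr.size * px2),
            }
        )
        # thin processes radiating from the soma; 1 px wide, fainter
        n_proc = rng.poisson(spec.processes_per_soma)
        for _ in range(n_proc):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            length = rng.uniform(2.0, 5.0) * r_px
            ey = int(np.clip(cy + length * np.sin(ang), 0, ny - 1))
            ex = int(np.clip(cx + length * np.cos(ang), 0, nx - 1))
            pr, pc = draw_line(int(cy), int(cx), ey, ex)
            keep = img[pr, pc] > background[pr, pc] * 0.5  # don't carve somata
            img[pr[keep], pc[keep]] = background[pr[keep], pc[keep]] * 0.55
        soma_id += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    table = pd.DataFrame(
        rows,
        columns=["soma_id", "centroid_y_px", "centroid_x_px", "area_px", "area_um2"],
    )
    return img, table


# ---------------------------------------------------------------------------
# metabolite tables
# ---------------------------------------------------------------------------

#: baseline concentrations (arbitrary mM-scale) giving mI/tCr = 0.70, the
#: vehicle-side level of the in vivo study; total creatine = Cr + PCr = 8.
BASELINE_CONCENTRATIONS = {
    "mI": 5.6,
    "Cr": 4.0,
    "PCr": 4.0,
    "NAA": 8.0,
    "Glu": 9.0,
    "Gln": 3.5,
    "Cho": 1.5,
    "Tau": 10.0,
}

#: typical reported %SD (Cramér-Rao bound) per metabolite
BASELINE_CRLB = {
    "mI": 5.0, "Cr": 4.0, "PCr": 5.0, "NAA": 3.0,
    "Glu": 6.0, "Gln": 9.0, "Cho": 6.0, "Tau": 5.0,
}

#: default LPS-side relative mI change in an effect subject: 0.82/0.70 - 1,
#: matching the in vivo mI/tCr contrast between the LPS and vehicle sides.
DEFAULT_MI_EFFECT = 0.82 / 0.70 - 1.0


def make_metabolite_table(
    n_subjects: int,
    effect: float = 0.0,
    crlb_sd: float = 1.0,
    seed: int = 0,
    linewidth_mean_hz: float = 12.9,
    linewidth_sd_hz: float = 0.8,
    snr_mean: float = 8.9,
    snr_sd: float = 0.6,
    linewidth_fail: Sequence[tuple[int, str]] = (),
    crlb_fail: Sequence[tuple[int, str, str]] = (),
) -> pd.DataFrame:
    """LCModel-style concentration table for a paired LPS/vehicle cohort.

    Two spectra (sides "LPS" and "PBS") per subject, one row per metabolite,
    with concentration, %SD (Cramér-Rao bound), per-spectrum linewidth and
    SNR. ``effect`` is the relative mI increase on the LPS side.
    Concentrations carry multiplicative noise with sd = reported %SD / 100;
    reported %SD itself jitters with sd ``crlb_sd``. Spectra listed in
    ``linewidth_fail`` get a linewidth above the 25 Hz gate; rows in
    ``crlb_fail`` get %SD above the 10% gate.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    lw_fail = set(linewidth_fail)
    cr_fail = set(crlb_fail)
    rows = []
    for subj in range(n_subjects):
        for side in ("LPS", "PBS"):
            lw = rng.normal(linewidth_mean_hz, linewidth_sd_hz)
            if (subj, side) in lw_fail:
                lw = rng.uniform(26.0, 32.0)
            snr = rng.normal(snr_mean, snr_sd)
            for met, conc0 in BASELINE_CONCENTRATIONS.items():
                true = conc0 * (1.0 + effect) if (met == "mI" and side == "LPS") else conc0
                crlb = max(1.0, rng.normal(BASELINE_CRLB[met], crlb_sd))
                if (subj, side, met) in cr_fail:
                    crlb = rng.uniform(12.0, 20.0)
                conc = true * (1.0 + rng.normal(0.0, crlb / 100.0))
                rows.append(
                    {
                        "subject": subj,
                        "side": side,
                        "metabolite": met,
                        "concentration": max(conc, 0.0),
                        "crlb_percent": crlb,
                        "linewidth_hz": lw,
                        "snr": snr,
                    }
                )
    return pd.DataFrame(rows)
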