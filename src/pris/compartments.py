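"""Intratumoral and peritumoral compartment construction.

The peritumoral region is the annular band extending 15 mm radially out
from the tumor boundary on each axial slice, split into three 5-mm rings
(0-5, 5-10, 10-15 mm).  Dilation is two-dimensional: head-and-neck CT is
thick-slice anisotropic, so through-plane "rings" would mix tissue at very
different physical distances.  Air (< -900 HU) is excluded from the
peritumoral compartments because its texture carries no tissue signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pris.imaging import CTVolume, TumorMask, validate_tumor_size

logger = logging.getLogger(__name__)

RING_NAMES = ("ring_0_5", "ring_5_10", "ring_10_15")
COMPARTMENT_NAMES = ("intratumoral",) + RING_NAMES


@dataclass(frozen=True)
class CompartmentConfig:
    """Geometric and cleaning parameters for compartment construction.

    dilation_mm
        Total radial extent of the peritumoral band (mm).
    ring_width_mm
        Width of each ring; ``dilation_mm`` must be three ring widths.
    air_hu_threshold
        Pixels below this HU are treated as air and removed from the
        peritumoral rings.
    dead_pixel_window
        Side of the square in-slice neighborhood whose mean replaces a
        dead pixel.
    dead_sentinel_hu
        Optional HU value at or below which a pixel is considered dead
        (in addition to non-finite pixels).  None disables the sentinel.
    min_tumor_pixels
        Inclusion threshold on total tumor voxel count.
    excluded_slices
        Axial slice indices to drop entirely (stands in for manual
        exclusion of e.g. dental-artifact slices).
    """

    dilation_mm: float = 15.0
    ring_width_mm: float = 5.0
    air_hu_threshold: float = -900.0
    dead_pixel_window: int = 9
    dead_sentinel_hu: float | None = None
    min_tumor_pixels: int = 200
    excluded_slices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not np.isclose(self.dilation_mm, 3 * self.ring_width_mm):
            raise ValueError(
                f"dilation_mm ({self.dilation_mm}) must equal 3 x ring_width_mm "
                f"({self.ring_width_mm})"
            )
        if self.dead_pixel_window % 2 != 1 or self.dead_pixel_window < 3:
            raise ValueError("dead_pixel_window must be odd and >= 3")


@dataclass
class CompartmentSet:
    """The four disjoint analysis masks on one resampled grid.

    ``slice_counts[name][z]`` holds the pixel count of compartment
    ``name`` on axial slice ``z`` (only slices with tumor appear).
    """

    intratumoral: np.ndarray
    ring_0_5: np.ndarray
    ring_5_10: np.ndarray
    ring_10_15: np.ndarray
    slice_counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        if name not in COMPARTMENT_NAMES:
            raise KeyError(f"unknown compartment {name!r}")
        return getattr(self, name)

    def masks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in COMPARTMENT_NAMES}

    def labels(self) -> np.ndarray:
        """Single label volume: 1=intratumoral, 2/3/4=rings, 0=background."""
        lab = np.zeros(self.intratumoral.shape, dtype=np.uint8)
        for i, name in enumerate(COMPARTMENT_NAMES, start=1):
            lab[self.mask(name)] = i
        return lab


def dilation_pixels(pixel_size_mm: float, dilation_mm: float = 15.0) -> int:
    """Number of pixels the tumor mask is dilated per slice.

    pixels = round(dilation_mm / pixel_size_mm); at the 1-mm working
    resolution this is 15 pixels.
    """
    if pixel_size_mm <= 0:
        raise ValueError(f"pixel size must be > 0, got {pixel_size_mm}")
    return int(round(dilation_mm / pixel_size_mm))


def clean_dead_pixels(vol: CTVolume, cfg: CompartmentConfig | None = None) -> CTVolume:
    """Replace dead pixels by the mean of their in-slice square neighborhood.

    A pixel is dead when it is non-finite, or at/below
    ``cfg.dead_sentinel_hu`` when a sentinel is configured.  A dead pixel
    whose whole neighborhood is also dead falls back to the slice median
    of live pixels (with a logged warning).
    """
    cfg = cfg or CompartmentConfig()
    vox = np.asarray(vol.voxels, dtype=np.float64)
    dead = ~np.isfinite(vox)
    if cfg.dead_sentinel_hu is not None:
        dead |= vox <= cfg.dead_sentinel_hu
    if not dead.any():
        return CTVolume(vox.copy(), vol.spacing, vol.origin)

    out = vox.copy()
    w = cfg.dead_pixel_window
    kernel = np.ones((w, w))
    for z in range(vox.shape[2]):
        dz = dead[:, :, z]
        if not dz.any():
            continue
        sl = vox[:, :, z]
        live_vals = np.where(dz, 0.0, sl)
        live_cnt = (~dz).astype(np.float64)
        nb_sum = ndimage.convolve(live_vals, kernel, mode="constant", cval=0.0)
        nb_cnt = ndimage.convolve(live_cnt, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            nb_mean = nb_sum / nb_cnt
        fix = out[:, :, z]
        fix[dz] = nb_mean[dz]
        orphan = dz & (nb_cnt < 0.5)
        if orphan.any():
            live = sl[~dz]
            fallback = float(np.median(live)) if live.size else 0.0
            logger.warning(
                "slice %d: %d dead pixels with fully dead neighborhoods; "
                "using slice median %.1f HU", z, int(orphan.sum()), fallback,
            )
            fix[orphan] = fallback
    return CTVolume(out, vol.spacing, vol.origin)


def build_compartments(
    vol: CTVolume, mask: TumorMask, cfg: CompartmentConfig | None = None
) -> CompartmentSet:
    """Construct the intratumoral region and the three peritumoral rings.

    Per axial slice with tumor, the tumor is dilated in 2D by
    ``dilation_pixels`` and the tumor subtracted, giving the 0-15 mm band;
    the band is partitioned at one- and two-thirds of the dilation radius
    (5 and 10 mm at 1 mm pixels) using the Euclidean distance from the
    tumor, which is exactly the disk-structuring-element dilation but
    order-independent.  Air pixels are then removed from every ring.
    """
    cfg = cfg or CompartmentConfig()
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    if not validate_tumor_size(mask, cfg.min_tumor_pixels):
        raise ValueError(
            f"tumor has {mask.pixel_count()} pixels, below the "
            f"{cfg.min_tumor_pixels}-pixel inclusion threshold"
        )
    px = vol.pixel_size_mm
    r_out = dilation_pixels(px, cfg.dilation_mm)
    r_mid = 2.0 * r_out / 3.0
    r_in = r_out / 3.0

    tumor = mask.voxels
    shape = tumor.shape
    rings = {name: np.zeros(shape, dtype=bool) for name in RING_NAMES}
    slice_counts: dict[str, dict[int, int]] = {name: {} for name in COMPARTMENT_NAMES}

    air = np.asarray(vol.voxels) < cfg.air_hu_threshold
    for z in range(shape[2]):
        if z in cfg.excluded_slices:
            continue
        tz = tumor[:, :, z]
        if not tz.any():
            continue
        # Euclidean distance (pixels) of each background pixel to the tumor
        dist = ndimage.distance_transform_edt(~tz)
        near_border = (dist > r_out) & (dist <= r_out + 1)
        if np.any(near_border & _border_mask(tz.shape)) or np.any(
            (dist <= r_out) & ~tz & _border_mask(tz.shape)
        ):
            logger.info("slice %d: peritumoral band clipped at the image border", z)
        band = ~tz & (dist <= r_out)
        rz = {
            "ring_0_5": band & (dist <= r_in),
            "ring_5_10": band & (dist > r_in) & (dist <= r_mid),
            "ring_10_15": band & (dist > r_mid),
        }
        az = air[:, :, z]
        for name in RING_NAMES:
            keep = rz[name] & ~az
            rings[name][:, :, z] = keep
            slice_counts[name][z] = int(keep.sum())
        slice_counts["intratumoral"][z] = int(tz.sum())

    intratumoral = tumor.copy()
    if cfg.excluded_slices:
        intratumoral = intratumoral.copy()
        for z in cfg.excluded_slices:
            if 0 <= z < shape[2]:
                intratumoral[:, :, z] = False
    return CompartmentSet(
        intratumoral=intratumoral,
        ring_0_5=rings["ring_0_5"],
        ring_5_10=rings["ring_5_10"],
        ring_10_15=rings["ring_10_15"],
        slice_counts=slice_counts,
    )


def _border_mask(shape2d: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape2d, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m
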