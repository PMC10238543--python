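"""Per-pixel 2D texture operators: Laws, Gabor, Haralick GLCM, CoLlAGe, intensity.

Every operator maps an axial HU slice to one scalar response per pixel and
is evaluated at the pixels of one compartment.  Convolutional families
(Laws, Gabor, the intensity gradients) use full-image context; the
co-occurrence families (Haralick, CoLlAGe) build their per-pixel matrices
from pixel pairs that lie inside the compartment, so tissue outside the
region of interest never enters the counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

# 1D Laws vectors: level, edge, spot, wave, ripple
LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

HARALICK_NAMES = (
    "entropy", "energy", "inertia", "idm", "correlation",
    "imc1", "imc2", "sum_average", "sum_variance", "sum_entropy",
    "diff_average", "diff_variance", "diff_entropy",
)

INTENSITY_NAMES = (
    "raw", "win_mean", "win_median", "win_std", "win_range",
    "win_entropy", "win_energy", "win_skewness", "win_kurtosis",
    "grad_x", "grad_y", "grad_mag", "laplacian",
)

# unit offsets pooled into every co-occurrence matrix (0, 45, 90, 135 deg)
_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _deg_tag(deg: float) -> str:
    s = f"{deg:g}".replace(".", "_")
    return s


@dataclass
class FilterBank:
    """The fixed filter bank of the extraction pipeline.

    25 Laws kernels (outer products of the five 1D vectors, row filter
    applied along y), 48 Gabor kernels (6 wavelengths x 8 orientations),
    and the window size shared by the windowed operators.
    """

    gabor_wavelengths_px: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    gabor_orientations_deg: tuple[float, ...] = (
        0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5)
    window_size: int = 5
    glcm_levels: int = 64
    collage_bins: int = 64
    laws_kernels: dict[str, np.ndarray] = field(init=False, repr=False)
    gabor_kernels: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.window_size % 2 != 1 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        self.laws_kernels = {
            f"{a}{b}": np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
            for a in LAWS_VECTORS for b in LAWS_VECTORS
        }
        from skimage.filters import gabor_kernel

        self.gabor_kernels = {}
        for w in self.gabor_wavelengths_px:
            for o in self.gabor_orientations_deg:
                k = np.asarray(gabor_kernel(frequency=1.0 / w, theta=np.deg2rad(o)))
                # remove the DC leakage of the discretized kernel so flat
                # regions respond identically at every orientation
                k = k - k.mean()
                self.gabor_kernels[f"w{w:g}_o{_deg_tag(o)}"] = k
        assert len(self.laws_kernels) == 25
        assert len(self.gabor_kernels) == len(self.gabor_wavelengths_px) * len(
            self.gabor_orientations_deg)
        for name, kern in self.laws_kernels.items():
            if not (name[0] == name[2] == "L"):
                # any kernel with a zero-sum factor sums to zero
                assert abs(kern.sum()) < 1e-9, name


def laws_maps(slice2d: np.ndarray, compartment: np.ndarray,
              bank: FilterBank) -> dict[str, np.ndarray]:
    """Convolution responses of the 25 Laws kernels at compartment pixels.

    Kernel ``AB`` applies vector ``A`` along y (rows) and ``B`` along x
    (columns); a constant image is annihilated by every kernel with a
    zero-sum factor and scaled by (sum A)(sum B) otherwise.
    """
    _check_slice(slice2d, compartment)
    idx = compartment
    out = {}
    for name, kern in bank.laws_kernels.items():
        resp = ndimage.convolve(slice2d.astype(np.float64), kern, mode="nearest")
        out[name] = resp[idx]
    return out


def gabor_maps(slice2d: np.ndarray, compartment: np.ndarray,
               bank: FilterBank) -> dict[str, np.ndarray]:
    """Gabor magnitude responses at compartment pixels, one per (wavelength,
    orientation) pair in the bank."""
    _check_slice(slice2d, compartment)
    img = slice2d.astype(np.float64)
    idx = compartment
    out = {}
    for name, kern in bank.gabor_kernels.items():
        # edge-replicating pad so image borders behave like flat tissue,
        # not like an abrupt step to zero
        ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
        padded = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
        resp = signal.fftconvolve(padded, kern, mode="same")[ph:ph + img.shape[0],
                                                             pw:pw + img.shape[1]]
        out[name] = np.abs(resp)[idx]
    return out


def quantize(slice2d: np.ndarray, compartment: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a slice to integer gray levels over the compartment's HU range.

    Values outside the compartment are clipped into the same range so that
    window pixels shared between compartments stay comparable.
    """
    vals = slice2d[compartment]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(slice2d.shape, dtype=np.int32)
    q = np.floor((slice2d - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def haralick_maps(slice2d: np.ndarray, compartment: np.ndarray,
                  bank: FilterBank) -> dict[str, np.ndarray]:
    """13 Haralick descriptors of the per-pixel windowed GLCM.

    For each compartment pixel, a symmetric normalized co-occurrence
    matrix is built from unit-offset gray-level pairs (4 directions
    pooled) inside the window, restricted to compartment pixels, and the
    13 classical descriptors are emitted.
    """
    _check_slice(slice2d, compartment)
    q = quantize(slice2d, compartment, bank.glcm_levels)
    return _windowed_cooccurrence(q, compartment, bank.window_size, bank.glcm_levels)


def collage_maps(slice2d: np.ndarray, compartment: np.ndarray,
                 bank: FilterBank) -> dict[str, np.ndarray]:
    """13 CoLlAGe descriptors: Haralick statistics of the dominant-gradient-
    orientation image.

    The dominant orientation per pixel is the first principal direction of
    the x/y intensity gradients in the window, sign-aligned with the mean
    gradient so it spans [0, 360).  The orientation image is quantized and
    fed through the same windowed co-occurrence machinery as Haralick.
    """
    _check_slice(slice2d, compartment)
    theta = dominant_orientation(slice2d, bank.window_size)
    q = np.floor(theta / 360.0 * bank.collage_bins).astype(np.int32)
    q = np.clip(q, 0, bank.collage_bins - 1)
    return _windowed_cooccurrence(q, compartment, bank.window_size, bank.collage_bins)


def dominant_orientation(slice2d: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel dominant intensity-gradient orientation in degrees [0, 360).

    The principal axis of the windowed gradient second-moment matrix gives
    the orientation modulo 180 deg; the sign of the windowed mean gradient
    resolves it to a full 360-deg direction.  A window with no gradient is
    assigned 0 deg.
    """
    img = slice2d.astype(np.float64)
    gy, gx = np.gradient(img)
    size = (window, window)
    sxx = ndimage.uniform_filter(gx * gx, size, mode="nearest")
    syy = ndimage.uniform_filter(gy * gy, size, mode="nearest")
    sxy = ndimage.uniform_filter(gx * gy, size, mode="nearest")
    mx = ndimage.uniform_filter(gx, size, mode="nearest")
    my = ndimage.uniform_filter(gy, size, mode="nearest")
    # principal axis of the 2x2 structure tensor, in (-pi/2, pi/2]
    phi = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    vx, vy = np.cos(phi), np.sin(phi)
    flip = vx * mx + vy * my < 0
    vx = np.where(flip, -vx, vx)
    vy = np.where(flip, -vy, vy)
    theta = np.degrees(np.arctan2(vy, vx)) % 360.0
    degenerate = sxx + syy < 1e-24
    if degenerate.any():
        logger.debug("%d pixels with zero-gradient windows assigned 0 deg",
                     int(degenerate.sum()))
        theta = np.where(degenerate, 0.0, theta)
    return theta


def intensity_maps(slice2d: np.ndarray, compartment: np.ndarray,
                   bank: FilterBank) -> dict[str, np.ndarray]:
    """13 gray-level intensity maps at compartment pixels.

    Raw HU; windowed mean/median/std/range/entropy/energy/skewness/
    kurtosis; x/y/combined gradients; Laplacian.
    """
    _check_slice(slice2d, compartment)
    img = slice2d.astype(np.float64)
    w = bank.window_size
    size = (w, w)
    m1 = ndimage.uniform_filter(img, size, mode="nearest")
    m2 = ndimage.uniform_filter(img * img, size, mode="nearest")
    m3 = ndimage.uniform_filter(img ** 3, size, mode="nearest")
    m4 = ndimage.uniform_filter(img ** 4, size, mode="nearest")
    var = np.maximum(m2 - m1 * m1, 0.0)
    std = np.sqrt(var)
    # central moments from raw moments
    mu3 = m3 - 3 * m1 * m2 + 2 * m1 ** 3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1 ** 2 * m2 - 3 * m1 ** 4
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(std > 1e-12, mu3 / np.maximum(std, 1e-300) ** 3, 0.0)
        kurt = np.where(var > 1e-12, mu4 / np.maximum(var, 1e-300) ** 2 - 3.0, 0.0)
    rng = (ndimage.maximum_filter(img, size, mode="nearest")
           - ndimage.minimum_filter(img, size, mode="nearest"))
    ent, eng = _windowed_hist_entropy_energy(img, compartment, w)
    gy, gx = np.gradient(img)
    maps = {
        "raw": img,
        "win_mean": m1,
        "win_median": ndimage.median_filter(img, size, mode="nearest"),
        "win_std": std,
        "win_range": rng,
        "win_entropy": ent,
        "win_energy": eng,
        "win_skewness": skew,
        "win_kurtosis": kurt,
        "grad_x": gx,
        "grad_y": gy,
        "grad_mag": np.hypot(gx, gy),
        "laplacian": ndimage.laplace(img, mode="nearest"),
    }
    idx = compartment
    return {name: arr[idx] for name, arr in maps.items()}


def _windowed_hist_entropy_energy(img, compartment, window, levels=32):
    """Per-pixel histogram entropy (nats) and energy over the window."""
    q = quantize(img, compartment, levels)
    size = (window, window)
    ent = np.zeros(img.shape)
    eng = np.zeros(img.shape)
    for lev in range(levels):
        p = ndimage.uniform_filter((q == lev).astype(np.float64), size, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            ent -= np.where(p > 0, p * np.log(p), 0.0)
        eng += p * p
    return ent, eng


def _check_slice(slice2d: np.ndarray, compartment: np.ndarray) -> None:
    if slice2d.ndim != 2 or compartment.shape != slice2d.shape:
        raise ValueError("slice and compartment must be matching 2D arrays")
    if not compartment.any():
        raise ValueError("compartment is empty on this slice")


# ---------------------------------------------------------------------------
# windowed co-occurrence machinery (shared by Haralick and CoLlAGe)
# ---------------------------------------------------------------------------

def _windowed_cooccurrence(q: np.ndarray, valid: np.ndarray, window: int,
                           levels: int) -> dict[str, np.ndarray]:
    """Evaluate the 13 co-occurrence descriptors per valid pixel.

    Pairs are formed at the four unit offsets between pixels that are both
    inside the window *and* inside ``valid``; the matrix is symmetrized
    and normalized per pixel.  A pixel whose window contributes no valid
    pair gets all-zero descriptors (except energy = 1, the single-cell
    convention is approached by a lone pixel with itself excluded: we
    define the empty case as energy 1, entropy 0, matching a point mass).
    """
    half = window // 2
    ys, xs = np.nonzero(valid)
    n = ys.size
    out = {name: np.zeros(n) for name in HARALICK_NAMES}
    H, W = q.shape
    for i in range(n):
        y, x = ys[i], xs[i]
        y0, y1 = max(0, y - half), min(H, y + half + 1)
        x0, x1 = max(0, x - half), min(W, x + half + 1)
        qw = q[y0:y1, x0:x1]
        vw = valid[y0:y1, x0:x1]
        codes = _pair_codes(qw, vw, levels)
        desc = cooccurrence_descriptors_from_codes(codes, levels)
        for name in HARALICK_NAMES:
            out[name][i] = desc[name]
    return out


def _pair_codes(qw: np.ndarray, vw: np.ndarray, levels: int) -> np.ndarray:
    """Flat codes i*levels+j of all symmetric unit-offset pairs in a patch."""
    chunks = []
    for dy, dx in _GLCM_OFFSETS:
        if dy >= 0:
            a_q = qw[: qw.shape[0] - dy or None, :]
            a_v = vw[: vw.shape[0] - dy or None, :]
            b_q = qw[dy:, :]
            b_v = vw[dy:, :]
        if dx > 0:
            a_q, a_v = a_q[:, : a_q.shape[1] - dx], a_v[:, : a_v.shape[1] - dx]
            b_q, b_v = b_q[:, dx:], b_v[:, dx:]
        elif dx < 0:
            a_q, a_v = a_q[:, -dx:], a_v[:, -dx:]
            b_q, b_v = b_q[:, : b_q.shape[1] + dx], b_v[:, : b_v.shape[1] + dx]
        ok = a_v & b_v
        if ok.any():
            ai = a_q[ok].astype(np.int64)
            bi = b_q[ok].astype(np.int64)
            chunks.append(ai * levels + bi)
            chunks.append(bi * levels + ai)  # symmetric counts
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def cooccurrence_descriptors_from_codes(codes: np.ndarray, levels: int) -> dict[str, float]:
    """The 13 Haralick descriptors of a normalized symmetric GLCM given as
    flat pair codes.  Logs use the natural base."""
    if codes.size == 0:
        return dict(zip(HARALICK_NAMES,
                        (0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                         0.0, 0.0, 0.0)))
    uniq, cnt = np.unique(codes, return_counts=True)
    p = cnt / cnt.sum()
    i = uniq // levels
    j = uniq % levels
    return cooccurrence_descriptors(i, j, p, levels)


def cooccurrence_descriptors(i: np.ndarray, j: np.ndarray, p: np.ndarray,
                             levels: int) -> dict[str, float]:
    """Descriptors from a sparse normalized GLCM given as (i, j, p) triples."""
    logp = np.log(p)
    entropy = float(-(p * logp).sum())
    energy = float((p * p).sum())
    d = (i - j).astype(np.float64)
    inertia = float(((d * d) * p).sum())
    idm = float((p / (1.0 + d * d)).sum())

    px = np.bincount(i, weights=p, minlength=levels)
    py = np.bincount(j, weights=p, minlength=levels)
    lev = np.arange(levels, dtype=np.float64)
    mx, my = float((lev * px).sum()), float((lev * py).sum())
    vx = float(((lev - mx) ** 2 * px).sum())
    vy = float(((lev - my) ** 2 * py).sum())
    if vx > 1e-18 and vy > 1e-18:
        correlation = float(((i * j * p).sum() - mx * my) / np.sqrt(vx * vy))
    else:
        correlation = 0.0

    # marginal entropies and cross terms for the information measures
    nz_x, nz_y = px > 0, py > 0
    hx = float(-(px[nz_x] * np.log(px[nz_x])).sum())
    hy = float(-(py[nz_y] * np.log(py[nz_y])).sum())
    pxy_prod = px[i] * py[j]
    good = pxy_prod > 0
    hxy1 = float(-(p[good] * np.log(pxy_prod[good])).sum())
    outer = np.outer(px[nz_x], py[nz_y]).ravel()
    outer = outer[outer > 0]
    hxy2 = float(-(outer * np.log(outer)).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 1e-18 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    ksum = i + j
    psum = np.bincount(ksum, weights=p, minlength=2 * levels - 1)
    ks = np.arange(psum.size, dtype=np.float64)
    sum_average = float((ks * psum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    nz = psum > 0
    sum_entropy = float(-(psum[nz] * np.log(psum[nz])).sum())

    kdiff = np.abs(i - j)
    pdiff = np.bincount(kdiff, weights=p, minlength=levels)
    kd = np.arange(pdiff.size, dtype=np.float64)
    diff_average = float((kd * pdiff).sum())
    diff_variance = float(((kd - diff_average) ** 2 * pdiff).sum())
    nz = pdiff > 0
    diff_entropy = float(-(pdiff[nz] * np.log(pdiff[nz])).sum())

    return {
        "entropy": entropy, "energy": energy, "inertia": inertia, "idm": idm,
        "correlation": correlation, "imc1": imc1, "imc2": imc2,
        "sum_average": sum_average, "sum_variance": sum_variance,
        "sum_entropy": sum_entropy, "diff_average": diff_average,
        "diff_variance": diff_variance, "diff_entropy": diff_entropy,
    }
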