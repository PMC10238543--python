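"""Synthetic CT phantoms and simulated survival cohorts.

The phantom generator emulates the imaging conditions the pipeline
assumes: a textured ellipsoidal tumor in soft tissue (~40 HU), a
distinctly textured peritumoral shell, optional sub-air blocks
(< -900 HU), optional dead pixels, anisotropic voxel spacing typical of
head-and-neck planning CT (thin in-plane, 3-mm slices).

The cohort generator draws feature vectors and proportional-hazards
Weibull survival with a planted treatment-by-risk interaction: the
chemotherapy benefit is confined to the high-risk stratum defined by the
median of the true linear predictor, mirroring the median-cutoff logic of
the analysis itself.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from pris.imaging import CTVolume, TumorMask

HU_MIN, HU_MAX = -1024.0, 3071.0


class SpecError(ValueError):
    """Generator specification violates an invariant."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of a CT phantom.

    Distances are mm; the tumor must fit in-plane with a full 15-mm
    peritumoral margin.  ``air_block_mm`` is an axis-aligned box
    ((x0,x1),(y0,y1),(z0,z1)) in mm filled with -1000 HU.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 5)   # (y, x, z)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.0)  # (x, y, z)
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radii_mm: tuple[float, float, float] = (8.0, 8.0, 4.5)
    tumor_contrast_hu: float = 60.0
    tumor_correlation_mm: float = 2.0
    peritumoral_contrast_hu: float = 25.0
    peritumoral_correlation_mm: float = 4.0
    background_hu: float = 40.0
    noise_std_hu: float = 10.0
    air_block_mm: tuple[tuple[float, float], ...] | None = None
    dead_pixel_fraction: float = 0.0
    margin_mm: float = 15.0
    seed: int = 0


def _phantom_coords(spec: PhantomSpec):
    ny, nx, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    y = np.arange(ny) * sy
    x = np.arange(nx) * sx
    z = np.arange(nz) * sz
    return np.meshgrid(y, x, z, indexing="ij")


def _correlated_field(rng: np.random.Generator, shape, spacing, corr_mm) -> np.ndarray:
    """Stationary Gaussian random field with ~unit variance."""
    white = rng.standard_normal(shape)
    sig = (corr_mm / spacing[1], corr_mm / spacing[0], corr_mm / spacing[2])
    f = ndimage.gaussian_filter(white, sigma=sig, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, TumorMask, np.ndarray]:
    """Generate a CT phantom, its tumor mask, and ground-truth compartments.

    Returns
    -------
    (CTVolume, TumorMask, labels)
        ``labels`` is a per-voxel ground truth on the native grid:
        1 = tumor, 2/3/4 = 0-5 / 5-10 / 10-15 mm in-plane rings, 0 = rest.
    """
    ny, nx, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    extent = (nx * sx, ny * sy, nz * sz)
    center = spec.tumor_center_mm or (extent[0] / 2, extent[1] / 2, extent[2] / 2)
    rx, ry, rz = spec.tumor_radii_mm
    for c, r, e in ((center[0], rx, extent[0]), (center[1], ry, extent[1])):
        if c - r - spec.margin_mm < 0 or c + r + spec.margin_mm > e:
            raise SpecError(
                f"tumor (center {c} mm, radius {r} mm) leaves < {spec.margin_mm} mm "
                f"in-plane margin inside the {e} mm field of view")

    yy, xx, zz = _phantom_coords(spec)
    tumor = (((xx - center[0]) / rx) ** 2 + ((yy - center[1]) / ry) ** 2
             + ((zz - center[2]) / rz) ** 2) <= 1.0
    if not tumor.any():
        raise SpecError("tumor radii too small for the voxel grid")

    rng = np.random.default_rng(spec.seed)
    vox = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    if spec.noise_std_hu > 0:
        vox += rng.standard_normal(spec.grid_shape) * spec.noise_std_hu
    # peritumoral shell: textured ring out to the margin, in-plane geometry
    labels = ground_truth_labels(tumor, (sx, sy), spec.margin_mm)
    shell = labels >= 2
    peri_field = _correlated_field(rng, spec.grid_shape, spec.spacing_mm,
                                   spec.peritumoral_correlation_mm)
    vox[shell] += spec.peritumoral_contrast_hu * peri_field[shell]
    tum_field = _correlated_field(rng, spec.grid_shape, spec.spacing_mm,
                                  spec.tumor_correlation_mm)
    vox[tumor] += spec.tumor_contrast_hu * tum_field[tumor]

    if spec.air_block_mm is not None:
        (x0, x1), (y0, y1), (z0, z1) = spec.air_block_mm
        box = ((xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
               & (zz >= z0) & (zz < z1))
        vox[box] = -1000.0
    vox = np.clip(vox, HU_MIN, HU_MAX)
    if spec.dead_pixel_fraction > 0:
        dead = rng.random(spec.grid_shape) < spec.dead_pixel_fraction
        vox[dead] = np.nan

    vol = CTVolume(vox, spec.spacing_mm)
    mask = TumorMask(tumor, spec.spacing_mm)
    return vol, mask, labels


def ground_truth_labels(tumor: np.ndarray, inplane_spacing_mm: tuple[float, float],
                        margin_mm: float = 15.0) -> np.ndarray:
    """Analytic compartment labels from per-slice distance to the tumor."""
    sx, sy = inplane_spacing_mm
    labels = np.zeros(tumor.shape, dtype=np.uint8)
    third = margin_mm / 3.0
    for z in range(tumor.shape[2]):
        tz = tumor[:, :, z]
        if not tz.any():
            continue
        dist = ndimage.distance_transform_edt(~tz, sampling=(sy, sx))
        lz = labels[:, :, z]
        lz[tz] = 1
        lz[~tz & (dist <= third)] = 2
        lz[(dist > third) & (dist <= 2 * third)] = 3
        lz[(dist > 2 * third) & (dist <= margin_mm)] = 4
    return labels


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated proportional-hazards cohort.

    Event times follow a Weibull baseline (shape ``weibull_shape``, scale
    ``weibull_scale`` years) under the linear predictor

        eta = X beta + gamma * treat + delta * treat * 1[X beta > median]

    so ``delta`` < 0 plants a chemotherapy benefit confined to the
    high-risk stratum.  Censoring is independent Uniform(0, c) with c
    calibrated to the requested censoring fraction.
    """

    n_patients: int = 400
    n_features: int = 50
    beta: tuple[float, ...] = ()
    treatment_prob: float = 0.5
    gamma: float = 0.0
    delta: float = 0.0
    weibull_shape: float = 1.5
    weibull_scale: float = 10.0
    censoring_rate: float = 0.3
    stage2_prob: float = 0.55
    interaction_stages: tuple[str, ...] = ("I", "II")
    seed: int = 0

    def beta_vector(self) -> np.ndarray:
        b = np.zeros(self.n_features)
        bb = np.asarray(self.beta, dtype=np.float64)
        if bb.size > self.n_features:
            raise SpecError("beta longer than n_features")
        b[: bb.size] = bb
        return b


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort of feature vectors + clinical covariates + survival.

    Columns: ``f000..`` standardized features, demographic/staging
    covariates, ``treatment`` (0 = radiotherapy alone, 1 = chemoradiation),
    OS and DFS (time, event) pairs, and hidden ground truth (``true_eta``,
    ``true_high_risk``).
    """
    if not 0 <= spec.censoring_rate < 1:
        raise SpecError(f"censoring rate must be in [0, 1), got {spec.censoring_rate}")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features
    X = rng.standard_normal((n, p))
    beta = spec.beta_vector()
    risk = X @ beta
    high = (risk > np.median(risk)).astype(int)
    treat = (rng.random(n) < spec.treatment_prob).astype(int)
    stage = np.where(rng.random(n) < spec.stage2_prob, "II", "I")
    interacts = np.isin(stage, spec.interaction_stages)
    eta = risk + spec.gamma * treat + spec.delta * treat * high * interacts

    u = rng.random(n)
    t_event = spec.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / spec.weibull_shape)
    if spec.censoring_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        uc = rng.random(n)
        c_max = _calibrate_censoring(t_event, uc, spec.censoring_rate)
        c = uc * c_max
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    if event.sum() == 0:
        raise SpecError("no events observed after censoring; relax censoring_rate")

    dfs_time = time * rng.uniform(0.85, 1.0, n)

    df = pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(p)])
    df.insert(0, "patient_id", np.arange(n))
    df["age"] = np.clip(rng.normal(59.0, 9.0, n), 30, 90)
    df["gender"] = np.where(rng.random(n) < 0.83, "male", "female")
    df["subsite"] = rng.choice(
        ["base_of_tongue", "tonsillar_complex", "posterior_wall"], n,
        p=[0.46, 0.50, 0.04])
    df["smoking_py"] = np.round(rng.gamma(0.8, 18.0, n), 1)
    df["t_stage"] = rng.choice(["T1", "T2", "T3"], n, p=[0.27, 0.45, 0.28])
    df["n_stage"] = rng.choice(["N0", "N1", "N2"], n, p=[0.14, 0.52, 0.34])
    df["ajcc_stage"] = stage
    df["recurrence"] = (rng.random(n) < 0.12).astype(int)
    df["treatment"] = treat
    df["time_os"] = time
    df["event_os"] = event
    df["time_dfs"] = dfs_time
    df["event_dfs"] = event
    df["time"] = time
    df["event"] = event
    df["true_eta"] = eta
    df["true_high_risk"] = high
    return df


def _calibrate_censoring(t_event: np.ndarray, uc: np.ndarray, rate: float) -> float:
    """Bisect the Uniform(0, c) upper bound to the target censored fraction."""
    def censored_frac(c):
        return float(np.mean(t_event > uc * c))

    lo, hi = 1e-9, float(t_event.max()) * 4.0 / max(uc.min(), 1e-9)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# balanced training split
# ---------------------------------------------------------------------------

def balanced_cohort_split(
    cohort: pd.DataFrame,
    pool: np.ndarray | list[int] | None = None,
    k: int = 60,
    iters: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    continuous_vars: tuple[str, ...] = ("age",),
    categorical_vars: tuple[str, ...] = ("gender", "ajcc_stage", "recurrence"),
) -> np.ndarray:
    """Select a covariate-balanced training subset by repeated sampling.

    Per iteration, ``k`` patients are drawn from ``pool`` (defaults to the
    whole cohort) and compared against the remaining cohort: rank-sum
    tests on the continuous variables, chi-square on the categorical ones.
    Iterations in which no test rejects at ``alpha`` increment each
    selected patient's count; the ``k`` patients with the largest counts
    (ties broken by patient id) form the training set.
    """
    ids = cohort["patient_id"].to_numpy()
    pool = ids if pool is None else np.asarray(pool)
    if pool.size < k:
        raise ValueError(f"pool has {pool.size} patients, need >= k = {k}")
    if pool.size == k:
        return np.sort(pool)
    rng = np.random.default_rng(seed)
    counts = {int(pid): 0 for pid in pool}
    indexed = cohort.set_index("patient_id")
    n_balanced = 0
    for _ in range(iters):
        sel = rng.choice(pool, size=k, replace=False)
        rest = ids[~np.isin(ids, sel)]
        if _is_balanced(indexed, sel, rest, alpha, continuous_vars, categorical_vars):
            n_balanced += 1
            for pid in sel:
                counts[int(pid)] += 1
    if n_balanced == 0:
        raise RuntimeError(
            "no balanced iteration found; increase iters or relax alpha")
    order = sorted(counts, key=lambda pid: (-counts[pid], pid))
    return np.sort(np.array(order[:k]))


def _is_balanced(indexed, sel, rest, alpha, continuous_vars, categorical_vars) -> bool:
    a, b = indexed.loc[sel], indexed.loc[rest]
    for var in continuous_vars:
        va, vb = a[var].to_numpy(), b[var].to_numpy()
        if np.ptp(np.concatenate([va, vb])) == 0:
            continue
        p = sstats.ranksums(va, vb).pvalue
        if np.isfinite(p) and p < alpha:
            return False
    for var in categorical_vars:
        tab = pd.crosstab(
            pd.concat([a[var], b[var]]),
            np.repeat(["sel", "rest"], [len(a), len(b)]))
        if tab.shape[0] < 2:
            continue
        p = sstats.chi2_contingency(tab.to_numpy()).pvalue
        if np.isfinite(p) and p < alpha:
            return False
    return True
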