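"""Assembly of the per-patient radiomic feature vector.

Four texture families (25 Laws, 48 Gabor, 13 Haralick, 13 CoLlAGe) are
evaluated in all four compartments and the 13 gray-level intensity maps
in the intratumoral compartment only; five statistics (mean, median, std,
skewness, kurtosis) of the pooled per-pixel responses give

    (4 x 99 + 13) x 5 = 2045

named entries ``family.operator.compartment.statistic``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from pris import texture
from pris.compartments import (COMPARTMENT_NAMES, CompartmentConfig,
                               CompartmentSet, build_compartments,
                               clean_dead_pixels)
from pris.imaging import CTVolume, TumorMask, resample_isotropic

logger = logging.getLogger(__name__)

STATISTICS = ("mean", "median", "std", "skewness", "kurtosis")

# FeatureVector: an ordered, named per-patient descriptor.  Represented as
# a pandas Series indexed by the canonical feature names.
FeatureVector = pd.Series

_FAMILY_FUNCS = {
    "intensity": texture.intensity_maps,
    "laws": texture.laws_maps,
    "gabor": texture.gabor_maps,
    "haralick": texture.haralick_maps,
    "collage": texture.collage_maps,
}


def family_operators(bank: texture.FilterBank | None = None) -> dict[str, tuple[str, ...]]:
    """Operator names per family, in canonical order."""
    bank = bank or texture.FilterBank()
    return {
        "intensity": texture.INTENSITY_NAMES,
        "laws": tuple(bank.laws_kernels),
        "gabor": tuple(bank.gabor_kernels),
        "haralick": texture.HARALICK_NAMES,
        "collage": texture.HARALICK_NAMES,
    }


def family_compartments(family: str) -> tuple[str, ...]:
    # intensity is intratumoral-only; textures run in all four compartments
    return ("intratumoral",) if family == "intensity" else COMPARTMENT_NAMES


def feature_names(bank: texture.FilterBank | None = None) -> list[str]:
    """The canonical 2045-entry feature-name order."""
    ops = family_operators(bank)
    names = []
    for family in ("intensity", "laws", "gabor", "haralick", "collage"):
        for comp in family_compartments(family):
            for op in ops[family]:
                for stat in STATISTICS:
                    names.append(f"{family}.{op}.{comp}.{stat}")
    return names


def pooled_statistics(values: np.ndarray) -> dict[str, float]:
    """The five summary statistics of a pool of per-pixel responses.

    Skewness is the (biased) third standardized moment and kurtosis its
    excess-fourth-moment analogue; both are defined as 0 for a constant
    pool, so degenerate regions contribute neutral shape values.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return {s: np.nan for s in STATISTICS}
    std = float(values.std())
    if std < 1e-12:
        skew = kurt = 0.0
    else:
        skew = float(sstats.skew(values, bias=True))
        kurt = float(sstats.kurtosis(values, fisher=True, bias=True))
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
    }


def compute_compartment_maps(
    vol: CTVolume, comps: CompartmentSet, bank: texture.FilterBank | None = None
) -> dict[tuple[str, str, str], list[np.ndarray]]:
    """Per-pixel responses for every (family, operator, compartment).

    Returns per-slice 1D arrays so that either aggregation mode (pooled
    pixels or slice-mean-then-average) can be applied downstream.
    """
    bank = bank or texture.FilterBank()
    masks = comps.masks()
    out: dict[tuple[str, str, str], list[np.ndarray]] = {}
    nz = sorted({z for counts in comps.slice_counts.values() for z in counts})
    for z in nz:
        sl = np.asarray(vol.voxels[:, :, z], dtype=np.float64)
        for comp in COMPARTMENT_NAMES:
            cz = masks[comp][:, :, z]
            if not cz.any():
                continue
            for family, func in _FAMILY_FUNCS.items():
                if comp not in family_compartments(family):
                    continue
                for op, vals in func(sl, cz, bank).items():
                    out.setdefault((family, op, comp), []).append(vals)
    return out


def aggregate(
    maps: dict[tuple[str, str, str], list[np.ndarray]],
    bank: texture.FilterBank | None = None,
    mode: str = "pooled",
) -> FeatureVector:
    """Reduce per-slice pixel responses to the 2045-entry feature vector.

    mode='pooled' (default) pools pixels over all slices of a compartment
    before taking the five statistics; mode='slice_mean' computes each
    statistic per slice and averages across slices unweighted.  Entries of
    an empty compartment (e.g. a fully air-excluded ring) are NaN and a
    warning names them.
    """
    if mode not in ("pooled", "slice_mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    bank = bank or texture.FilterBank()
    series = pd.Series(np.nan, index=feature_names(bank), dtype=np.float64)
    missing = set()
    ops = family_operators(bank)
    for family in _FAMILY_FUNCS:
        for comp in family_compartments(family):
            for op in ops[family]:
                key = (family, op, comp)
                chunks = maps.get(key, [])
                if not chunks:
                    missing.add(comp)
                    continue
                if mode == "pooled":
                    stat_vals = pooled_statistics(np.concatenate(chunks))
                else:
                    per_slice = [pooled_statistics(c) for c in chunks]
                    stat_vals = {s: float(np.mean([d[s] for d in per_slice]))
                                 for s in STATISTICS}
                for stat, v in stat_vals.items():
                    series[f"{family}.{op}.{comp}.{stat}"] = v
    if missing:
        logger.warning("empty compartments flagged as missing: %s", sorted(missing))
    return series


def extract_features(
    vol: CTVolume,
    mask: TumorMask,
    compartment_cfg: CompartmentConfig | None = None,
    bank: texture.FilterBank | None = None,
    target_mm: float = 1.0,
    mode: str = "pooled",
) -> FeatureVector:
    """End-to-end extraction for one patient.

    Cleans dead pixels, resamples image and mask to an isotropic
    ``target_mm`` grid, builds the four compartments, computes every
    per-pixel texture map and aggregates to the named feature vector.
    """
    compartment_cfg = compartment_cfg or CompartmentConfig()
    bank = bank or texture.FilterBank()
    vol = clean_dead_pixels(vol, compartment_cfg)
    vol, mask = resample_isotropic(vol, mask, target_mm)
    comps = build_compartments(vol, mask, compartment_cfg)
    maps = compute_compartment_maps(vol, comps, bank)
    return aggregate(maps, bank, mode=mode)


# ---------------------------------------------------------------------------
# z-score normalization (training-cohort parameters applied everywhere)
# ---------------------------------------------------------------------------

def zscore_fit(train: pd.DataFrame, columns: list[str] | None = None) -> dict:
    """Estimate per-feature mean/std on the training cohort.

    Zero-variance features cannot be standardized and are dropped with a
    warning.
    """
    cols = list(columns) if columns is not None else list(train.columns)
    if len(train) < 2:
        raise ValueError("need >= 2 training patients to estimate std")
    mu = train[cols].mean()
    sd = train[cols].std(ddof=1)
    dead = sd[~(sd > 0)].index.tolist()
    if dead:
        logger.warning("dropping %d zero-variance features: %s...",
                       len(dead), dead[:5])
        cols = [c for c in cols if c not in dead]
    return {"columns": cols, "mean": mu[cols], "std": sd[cols]}


def zscore_apply(df: pd.DataFrame, params: dict) -> pd.DataFrame:
    """Apply training-derived standardization to any cohort."""
    cols = params["columns"]
    return (df[cols] - params["mean"]) / params["std"]


def zscore_fit_apply(train: pd.DataFrame, *others: pd.DataFrame,
                     columns: list[str] | None = None):
    """Fit on ``train``, transform train and every other cohort."""
    params = zscore_fit(train, columns)
    out = [zscore_apply(train, params)] + [zscore_apply(o, params) for o in others]
    return (params, *out)
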