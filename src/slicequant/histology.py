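"""Stained-section quantification: color deconvolution, necrotic fraction,
positive-area fractions and depth profiles.

Brightfield RGB images of H&E or DAB-IHC stained sections are unmixed into
per-stain concentration maps via Beer-Lambert optical densities, and
morphology is quantified as area fractions over a tissue mask.  Depth
profiles assemble per-slice fractions along the cutting axis for the
correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import closing, disk, opening

from .synthetic import HDAB_VECTORS, HE_VECTORS

__all__ = [
    "separate_stains",
    "NecrosisResult",
    "necrotic_fraction",
    "positive_area_fraction",
    "build_depth_profile",
    "tissue_mask_from_od",
    "HE_VECTORS",
    "HDAB_VECTORS",
]

_EPS = 1.0 / 255.0


def _to_od(rgb: np.ndarray, white: float = 255.0) -> np.ndarray:
    """Optical density per channel: OD = -log10((I + eps) / white)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return -np.log10(np.clip(rgb, _EPS * white, None) / white)


def separate_stains(
    rgb: np.ndarray, stain_vectors: np.ndarray, white: float = 255.0
) -> np.ndarray:
    """Unmix an RGB raster into per-stain concentration maps.

    Pixel optical densities are decomposed by least squares onto the given
    unit stain absorption vectors (two or three rows); negative
    concentrations are clipped at zero.  Returns an (H, W, n_stains) array.
    """
    stain_vectors = np.asarray(stain_vectors, dtype=float)
    if stain_vectors.ndim != 2 or stain_vectors.shape[1] != 3:
        raise ValueError("stain_vectors must be (n_stains, 3)")
    if np.linalg.matrix_rank(stain_vectors) < stain_vectors.shape[0]:
        raise ValueError("stain vectors must be linearly independent")
    v = stain_vectors / np.linalg.norm(stain_vectors, axis=1, keepdims=True)
    od = _to_od(rgb, white=white)
    h, w, _ = od.shape
    if np.all(np.asarray(rgb) <= _EPS * white):
        raise ValueError("all-black image: optical densities are saturated")
    # least squares: conc @ v ~= od  =>  conc = od @ pinv(v)
    conc = od.reshape(-1, 3) @ np.linalg.pinv(v)
    return np.clip(conc.reshape(h, w, v.shape[0]), 0.0, None)


def tissue_mask_from_od(rgb: np.ndarray, od_threshold: float = 0.10) -> np.ndarray:
    """Tissue = pixels whose total optical density exceeds the background
    threshold (white background carries ~zero OD)."""
    od = _to_od(rgb)
    return od.sum(axis=2) > od_threshold


@dataclass
class NecrosisResult:
    """Necrotic-fraction measurement on an H&E section."""

    fraction: float  # NaN when undefined (no tissue)
    tissue_mask: np.ndarray
    necrosis_mask: np.ndarray
    defined: bool


def necrotic_fraction(
    he_rgb: np.ndarray,
    *,
    stain_vectors: np.ndarray | None = None,
    od_threshold: float = 0.10,
    hematoxylin_max: float = 0.45,
    eosin_min: float = 0.45,
    opening_radius: int = 2,
) -> NecrosisResult:
    """Necrotic area fraction of an H&E-stained section.

    Necrosis presents as eosin-dominant "light pink" regions that have lost
    their hematoxylin-stained nuclei: tissue pixels with hematoxylin
    concentration below ``hematoxylin_max`` and eosin above ``eosin_min``,
    cleaned by morphological opening and closing.  The fraction is necrotic
    pixels over tissue pixels; with an empty tissue mask the result is
    flagged undefined (NaN) with a warning.
    """
    vectors = HE_VECTORS if stain_vectors is None else np.asarray(stain_vectors)
    tissue = tissue_mask_from_od(he_rgb, od_threshold)
    if not tissue.any():
        warnings.warn("no tissue detected: necrotic fraction undefined")
        return NecrosisResult(float("nan"), tissue, np.zeros_like(tissue), False)
    conc = separate_stains(he_rgb, vectors)
    hema, eosin = conc[..., 0], conc[..., 1]
    necrosis = tissue & (hema < hematoxylin_max) & (eosin > eosin_min)
    if opening_radius > 0:
        footprint = disk(opening_radius)
        necrosis = closing(opening(necrosis, footprint), footprint)
        necrosis &= tissue
    fraction = float(necrosis.sum() / tissue.sum())
    return NecrosisResult(fraction, tissue, necrosis, True)


def positive_area_fraction(
    stain_raster: np.ndarray, tissue_mask: np.ndarray, threshold: float
) -> float:
    """Fraction of tissue pixels with stain concentration (or fluorescence
    signal) strictly above ``threshold`` — used for both the DAB-positive and
    the DAPI-positive area."""
    stain_raster = np.asarray(stain_raster, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if stain_raster.shape != tissue_mask.shape:
        raise ValueError("stain raster and tissue mask shapes differ")
    n_tissue = tissue_mask.sum()
    if n_tissue == 0:
        raise ValueError("empty tissue mask: positive fraction undefined")
    return float((stain_raster[tissue_mask] > threshold).mean())


def build_depth_profile(
    per_slice: pd.DataFrame | list[dict],
    slice_thickness: float = 500.0,
    index_col: str = "slice",
) -> pd.DataFrame:
    """Assemble ordered per-slice morphology into a depth profile.

    Slices are totally ordered by their integer index (skin-side slice
    first); depth of slice i is ``i * slice_thickness`` with the origin at
    the first slice.  Input row order is irrelevant; duplicate indices are an
    error.
    """
    df = pd.DataFrame(per_slice).copy()
    if index_col not in df.columns:
        raise ValueError(f"missing slice index column {index_col!r}")
    if df[index_col].duplicated().any():
        dupes = sorted(df.loc[df[index_col].duplicated(), index_col].unique())
        raise ValueError(f"duplicate slice indices: {dupes}")
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    df = df.sort_values(index_col).reset_index(drop=True)
    order = df[index_col].rank(method="dense").astype(int) - 1
    df["depth_um"] = order * float(slice_thickness)
    frac_cols = [c for c in df.columns if c.endswith("_fraction")]
    for c in frac_cols:
        vals = df[c].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"column {c!r} has values outside [0, 1]")
    return df
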