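"""Synthetic scene, plate and table generators with exact ground truth.

Every input consumed by the quantification pipeline can be produced here
with a machine-readable truth record, so that segmentation, foci counting,
stain quantification, assay arithmetic and the statistics can all be tested
end-to-end without any real specimen.

All generators take an explicit integer ``seed`` and hold no global state:
identical seed and parameters give bit-identical rasters and tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian
from skimage.morphology import disk, erosion

__all__ = [
    "FociSceneTruth",
    "NucleusTruth",
    "StainSceneTruth",
    "AssayTruth",
    "AssayPlate",
    "TSC_MORPHOLOGY_CORRELATIONS",
    "HE_VECTORS",
    "HDAB_VECTORS",
    "generate_foci_scene",
    "generate_stain_scene",
    "generate_assay_series",
    "generate_paired_counts",
    "generate_depth_profile",
]


# ---------------------------------------------------------------------------
# fluorescence scenes (DAPI + gamma-H2AX)
# ---------------------------------------------------------------------------

#: nucleus classes: normal nuclei carry countable foci; apoptotic and mitotic
#: nuclei are rendered "pan-bright" in the damage channel (uniformly high
#: signal, no resolvable spots) and must be excluded from foci counting.
NUCLEUS_CLASSES = ("normal", "apoptotic", "mitotic")


@dataclass
class NucleusTruth:
    """Ground truth for one rendered nucleus."""

    label: int
    center: tuple[float, float]  # (x, y) px
    axes: tuple[float, float]  # semi-axes, px
    angle: float  # radians
    area_px: int  # pixel count of the rendered mask
    area_um2: float
    nucleus_class: str  # one of NUCLEUS_CLASSES
    foci_xy: list[tuple[int, int]] = field(default_factory=list)

    @property
    def foci_count(self) -> int:
        return len(self.foci_xy)


@dataclass
class FociSceneTruth:
    """Exact truth for a rendered two-channel fluorescence scene."""

    shape: tuple[int, int]
    pixel_size: float  # um / px
    labels: np.ndarray  # ground-truth label raster, 0 = background
    nuclei: list[NucleusTruth]

    @property
    def nucleus_count(self) -> int:
        return len(self.nuclei)

    @property
    def total_foci(self) -> int:
        return sum(n.foci_count for n in self.nuclei)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [n.label for n in self.nuclei],
                "x": [n.center[0] for n in self.nuclei],
                "y": [n.center[1] for n in self.nuclei],
                "area_um2": [n.area_um2 for n in self.nuclei],
                "nucleus_class": [n.nucleus_class for n in self.nuclei],
                "foci_count": [n.foci_count for n in self.nuclei],
            }
        )


def _resolve_count_law(law, rng: np.random.Generator, n: int) -> np.ndarray:
    """Foci-per-nucleus law: int (fixed), ('poisson', mu), or callable(rng, n)."""
    if callable(law):
        counts = np.asarray(law(rng, n), dtype=int)
    elif np.isscalar(law):
        counts = np.full(n, int(law))
    else:
        name, *params = law
        if name == "poisson":
            counts = rng.poisson(params[0], size=n)
        elif name == "fixed":
            counts = np.full(n, int(params[0]))
        else:
            raise ValueError(f"unknown foci count law {law!r}")
    if (counts < 0).any():
        raise ValueError("foci counts must be non-negative")
    return counts


def _resolve_area_law(law, rng: np.random.Generator, n: int) -> np.ndarray:
    """Nucleus area law in um^2: float, ('lognormal', median, sigma) or callable."""
    if callable(law):
        areas = np.asarray(law(rng, n), dtype=float)
    elif np.isscalar(law):
        areas = np.full(n, float(law))
    else:
        name, *params = law
        if name == "lognormal":
            median, sigma = params
            areas = median * np.exp(rng.normal(0.0, sigma, size=n))
        elif name == "uniform":
            lo, hi = params
            areas = rng.uniform(lo, hi, size=n)
        else:
            raise ValueError(f"unknown nucleus area law {law!r}")
    if (areas <= 0).any():
        raise ValueError("nucleus areas must be positive")
    return areas


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radii: np.ndarray,
    touching_fraction: float,
    margin_px: float,
) -> np.ndarray:
    """Rejection-sample nucleus centers.

    Non-touching nuclei keep a clearance of ``margin_px`` between bounding
    circles; a ``touching_fraction`` share is placed as deliberately
    overlapping pairs (center distance 0.8x the radius sum) to stress the
    watershed splitter.
    """
    h, w = shape
    n = len(radii)
    centers = np.full((n, 2), np.nan)
    n_pair_members = int(round(touching_fraction * n)) // 2 * 2
    placed: list[int] = []

    def collides(c, r, skip=()):
        for j in placed:
            if j in skip:
                continue
            d = np.hypot(*(c - centers[j]))
            if d < r + radii[j] + margin_px:
                return True
        return False

    i = 0
    while i < n:
        r = radii[i]
        is_pair_lead = i < n_pair_members and i % 2 == 0
        for attempt in range(4000):
            c = rng.uniform([r + 2, r + 2], [w - r - 2, h - r - 2])
            if not collides(c, r):
                break
        else:
            raise ValueError(
                f"could not place nucleus {i} without overlap; "
                "reduce n_nuclei or nucleus areas"
            )
        centers[i] = c
        placed.append(i)
        if is_pair_lead:
            # partner deliberately overlapping the lead
            r2 = radii[i + 1]
            for attempt in range(4000):
                theta = rng.uniform(0, 2 * np.pi)
                d = 0.8 * (r + r2)
                c2 = c + d * np.array([np.cos(theta), np.sin(theta)])
                inside = (r2 + 1 <= c2).all() and (c2 <= [w - r2 - 2, h - r2 - 2]).all()
                if inside and not collides(c2, r2, skip=(i,)):
                    break
            else:
                raise ValueError("could not place touching partner nucleus")
            centers[i + 1] = c2
            placed.append(i + 1)
            i += 2
        else:
            i += 1
    return centers


def _sample_foci(
    rng: np.random.Generator,
    mask: np.ndarray,
    k: int,
    min_separation: float,
    interior_margin_px: int,
) -> list[tuple[int, int]]:
    """Sample ``k`` focus positions inside an eroded nucleus mask with a
    pairwise minimum separation.  Raises when the constraint is unsatisfiable
    instead of silently crowding spots together."""
    if k == 0:
        return []
    interior = mask
    if interior_margin_px > 0:
        interior = erosion(mask, disk(interior_margin_px))
    ys, xs = np.nonzero(interior)
    if len(ys) == 0:
        raise ValueError(
            "nucleus too small to hold foci at the requested interior margin"
        )
    # greedy dart throwing over a shuffled pixel list reaches near-maximal
    # packing, so failure genuinely means the density is unsatisfiable
    chosen: list[tuple[int, int]] = []
    order = rng.permutation(len(ys))
    for j in order:
        p = (int(xs[j]), int(ys[j]))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_separation for q in chosen):
            chosen.append(p)
            if len(chosen) == k:
                return chosen
    raise ValueError(
        f"could not place {k} foci with min separation {min_separation} px "
        "inside the nucleus; the requested density is unsatisfiable"
    )


def generate_foci_scene(
    n_nuclei: int,
    foci_distribution=("poisson", 8.0),
    nucleus_area_law=("lognormal", 120.0, 0.25),
    foci_sigma: float = 2.0,
    min_foci_separation: float | None = None,
    noise_level: float = 0.02,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.25,
    touching_fraction: float = 0.0,
    class_probs: tuple[float, float, float] = (1.0, 0.0, 0.0),
    foci_amplitude: float = 1.0,
    nucleus_level: float = 1.0,
    background: float = 0.05,
    gamma_baseline: float = 0.10,
    panbright_level: float = 0.9,
    edge_sigma: float = 0.8,
    foci_margin_px: int | None = None,
) -> tuple[np.ndarray, np.ndarray, FociSceneTruth]:
    """Render a co-registered DAPI / gamma-H2AX scene with exact ground truth.

    Nuclei are filled ellipses with Gaussian-blurred edges in the DAPI
    channel; each normal nucleus receives a dim pan-nuclear baseline plus
    additive Gaussian spots of width ``foci_sigma`` in the damage channel.
    Apoptotic/mitotic nuclei are rendered pan-bright in the damage channel
    with no resolvable spots.  Noise is Gaussian with intensity-proportional
    standard deviation (``noise_level`` is the relative SD), a shot-noise
    approximation.

    Parameters
    ----------
    foci_distribution : int, ('poisson', mu), ('fixed', k) or callable(rng, n)
        Law for the number of foci per normal nucleus.
    nucleus_area_law : float, ('lognormal', median_um2, sigma), ('uniform', lo, hi)
        Law for nucleus cross-sectional areas in um^2.
    min_foci_separation : float, optional
        Pairwise minimum spot separation in px; default ``4 * foci_sigma``
        so rendered spots stay individually resolvable.

    Returns
    -------
    (dapi, gamma, truth)
        Two float32 rasters in arbitrary intensity units and the
        :class:`FociSceneTruth` record (label raster, per-nucleus areas,
        classes and focus positions).
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if foci_sigma <= 0:
        raise ValueError("foci_sigma must be > 0")
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("raster shape must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if min_foci_separation is None:
        min_foci_separation = 4.0 * foci_sigma

    rng = np.random.default_rng(seed)
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    dapi = np.full(shape, background, dtype=np.float64)
    gamma = np.full(shape, background * 0.6, dtype=np.float64)
    nuclei: list[NucleusTruth] = []

    if n_nuclei > 0:
        areas_um2 = _resolve_area_law(nucleus_area_law, rng, n_nuclei)
        areas_px = areas_um2 / pixel_size**2
        # ellipse with aspect q in [0.6, 1]: a = sqrt(area/(pi q)), b = q a
        aspect = rng.uniform(0.6, 1.0, size=n_nuclei)
        a_ax = np.sqrt(areas_px / (np.pi * aspect))
        b_ax = aspect * a_ax
        radii = a_ax  # bounding radius = major semi-axis
        if 2 * radii.max() > min(h, w) - 6:
            raise ValueError("nuclei too large for the requested raster")
        centers = _place_centers(rng, shape, radii, touching_fraction, margin_px=3.0)
        angles = rng.uniform(0, np.pi, size=n_nuclei)
        classes = rng.choice(NUCLEUS_CLASSES, size=n_nuclei, p=class_probs)
        counts = _resolve_count_law(foci_distribution, rng, n_nuclei)

        yy, xx = np.ogrid[:h, :w]
        for i in range(n_nuclei):
            cx, cy = centers[i]
            rr, cc = draw_ellipse(
                cy, cx, b_ax[i], a_ax[i], shape=shape, rotation=angles[i]
            )
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            mask &= labels == 0  # overlapping pairs: first placed wins the pixel
            label = i + 1
            labels[mask] = label
            dapi[mask] = nucleus_level * rng.uniform(0.85, 1.05)
            cls = str(classes[i])
            truth = NucleusTruth(
                label=label,
                center=(float(cx), float(cy)),
                axes=(float(a_ax[i]), float(b_ax[i])),
                angle=float(angles[i]),
                area_px=int(mask.sum()),
                area_um2=float(mask.sum()) * pixel_size**2,
                nucleus_class=cls,
            )
            if cls == "normal":
                gamma[mask] += gamma_baseline
                # keep spots away from the nucleus rim so blur does not push
                # their maxima outside the mask
                margin = (
                    int(np.ceil(2 * foci_sigma))
                    if foci_margin_px is None
                    else foci_margin_px
                )
                truth.foci_xy = _sample_foci(
                    rng, mask, int(counts[i]), min_foci_separation, margin
                )
                for fx, fy in truth.foci_xy:
                    _add_gaussian_spot(gamma, fx, fy, foci_sigma, foci_amplitude)
            else:
                gamma[mask] += panbright_level
            nuclei.append(truth)

    if edge_sigma > 0:
        dapi = gaussian(dapi, sigma=edge_sigma, preserve_range=True)
    if noise_level > 0:
        dapi = dapi + rng.normal(0.0, 1.0, shape) * (noise_level * np.abs(dapi))
        gamma = gamma + rng.normal(0.0, 1.0, shape) * (
            noise_level * np.maximum(np.abs(gamma), background)
        )

    truth = FociSceneTruth(
        shape=(h, w), pixel_size=pixel_size, labels=labels, nuclei=nuclei
    )
    return dapi.astype(np.float32), gamma.astype(np.float32), truth


def _add_gaussian_spot(img: np.ndarray, x: int, y: int, sigma: float, amp: float):
    """Add an isotropic Gaussian spot in-place, evaluated on a 4-sigma window."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2)
    )


# ---------------------------------------------------------------------------
# brightfield stained-section scenes
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: Ruifrok & Johnston absorption vectors (RGB optical density, unit norm).
HE_VECTORS = np.array([_unit([0.650, 0.704, 0.286]), _unit([0.072, 0.990, 0.105])])
HDAB_VECTORS = np.array([_unit([0.650, 0.704, 0.286]), _unit([0.268, 0.570, 0.776])])


@dataclass
class StainSceneTruth:
    """Truth for a Beer-Lambert rendered stained-tissue scene.

    ``class_mask`` partitions the raster: 0 = background (no tissue),
    1 = first tissue class, 2 = second tissue class.  For H&E mode the
    classes are viable / necrotic; for DAB mode negative / positive.
    """

    mode: str  # "he" or "dab"
    class_mask: np.ndarray
    stain_vectors: np.ndarray  # (n_stains, 3), unit rows
    class_concentrations: np.ndarray  # (3 classes, n_stains)
    noise_sd: float  # OD units

    @property
    def tissue_fraction(self) -> float:
        return float((self.class_mask > 0).mean())

    def class_fraction(self, cls: int) -> float:
        """Fraction of *tissue* pixels in the given class; NaN with a warning
        when the scene contains no tissue."""
        tissue = self.class_mask > 0
        if not tissue.any():
            warnings.warn("scene contains no tissue; class fraction undefined")
            return float("nan")
        return float((self.class_mask[tissue] == cls).mean())


# per-class stain concentrations (rows: background, class1, class2)
_HE_CONCENTRATIONS = np.array(
    [
        [0.0, 0.0],  # background: unstained
        [0.85, 0.35],  # viable: strong hematoxylin, moderate eosin
        [0.10, 0.90],  # necrotic: "light pink" = eosin-dominant, little hematoxylin
    ]
)
_DAB_CONCENTRATIONS = np.array(
    [
        [0.0, 0.0],
        [0.70, 0.03],  # negative: hematoxylin only
        [0.45, 0.80],  # positive: brown DAB over nuclear counterstain
    ]
)


def make_layout(shape: tuple[int, int], kind: str, seed: int = 0, **kw) -> np.ndarray:
    """Build a class-label raster for :func:`generate_stain_scene`.

    kinds
    -----
    ``empty``       all background.
    ``halves``      left half class 1, right half class 2 (class-2 fraction 0.5).
    ``fraction``    tissue everywhere; a centered disk of class 2 covering
                    ``fraction`` of the raster (kw: fraction).
    ``blobs``       tissue everywhere; random class-2 blobs with expected area
                    fraction ``fraction`` (kw: fraction, n_blobs).
    """
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint8)
    if kind == "empty":
        return mask
    if kind == "halves":
        mask[:, : w // 2] = 1
        mask[:, w // 2 :] = 2
        return mask
    if kind == "fraction":
        frac = kw.get("fraction", 0.3)
        mask[:] = 1
        r = np.sqrt(frac * h * w / np.pi)
        yy, xx = np.ogrid[:h, :w]
        mask[(yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r**2] = 2
        return mask
    if kind == "blobs":
        rng = np.random.default_rng(seed)
        frac = kw.get("fraction", 0.3)
        n_blobs = kw.get("n_blobs", 12)
        mask[:] = 1
        r = np.sqrt(frac * h * w / (np.pi * n_blobs))
        yy, xx = np.ogrid[:h, :w]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(r, h - r), rng.uniform(r, w - r)
            mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 2
        return mask
    raise ValueError(f"unknown layout kind {kind!r}")


def generate_stain_scene(
    layout: np.ndarray,
    mode: str = "he",
    stain_vectors: np.ndarray | None = None,
    class_concentrations: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, StainSceneTruth]:
    """Render an RGB brightfield raster by Beer-Lambert stain mixing.

    Each pixel's optical density is the class's stain-concentration vector
    times the stain absorption matrix, plus Gaussian noise in OD space;
    transmitted RGB is ``255 * 10**(-OD)``, returned as uint8.

    ``layout`` is a class-label raster (see :func:`make_layout`): 0 background,
    1/2 the two tissue classes.
    """
    layout = np.asarray(layout)
    if layout.ndim != 2:
        raise ValueError("layout must be a 2-D class raster")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if stain_vectors is None:
        stain_vectors = HE_VECTORS if mode == "he" else HDAB_VECTORS
    stain_vectors = np.asarray(stain_vectors, dtype=float)
    if np.linalg.matrix_rank(stain_vectors) < stain_vectors.shape[0]:
        raise ValueError("stain vectors must be linearly independent")
    stain_vectors = stain_vectors / np.linalg.norm(stain_vectors, axis=1, keepdims=True)
    if class_concentrations is None:
        class_concentrations = (
            _HE_CONCENTRATIONS if mode == "he" else _DAB_CONCENTRATIONS
        )
    class_concentrations = np.asarray(class_concentrations, dtype=float)

    rng = np.random.default_rng(seed)
    conc = class_concentrations[layout]  # (h, w, n_stains)
    od = conc @ stain_vectors  # (h, w, 3)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, od.shape)
    od = np.clip(od, 0.0, None)
    rgb = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    truth = StainSceneTruth(
        mode=mode,
        class_mask=layout.astype(np.uint8),
        stain_vectors=stain_vectors,
        class_concentrations=class_concentrations,
        noise_sd=float(noise_sd),
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# LDH release kinetics
# ---------------------------------------------------------------------------

@dataclass
class AssayTruth:
    """Ground truth for a simulated LDH release series.

    ``daily_lysed_fraction[i]`` is the fraction of the initial cell pool lysed
    on day i+1 (1-based days); the residual fraction is released by the
    terminal detergent lysis step.  ``scale`` is the proportionality constant
    between lysed fraction and blank-corrected absorbance.
    """

    daily_lysed_fraction: np.ndarray
    noise_sd: float = 0.0  # absorbance units
    scale: float = 1.0  # AU per unit fraction
    baseline: float = 0.08  # shared 490/680 baseline absorbance

    def __post_init__(self):
        self.daily_lysed_fraction = np.asarray(self.daily_lysed_fraction, dtype=float)
        if (self.daily_lysed_fraction < 0).any():
            raise ValueError("daily lysed fractions must be non-negative")
        if self.daily_lysed_fraction.sum() > 1.0 + 1e-12:
            raise ValueError("daily lysed fractions must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    @property
    def residual_fraction(self) -> float:
        return float(1.0 - self.daily_lysed_fraction.sum())

    @property
    def surviving_fraction(self) -> np.ndarray:
        return 1.0 - np.cumsum(self.daily_lysed_fraction)


@dataclass
class AssayPlate:
    """Absorbance plate: long-format daily readings plus terminal-lysis and
    medium-only control readings.

    ``readings`` columns: sample, day (1-based, contiguous), wavelength_nm,
    absorbance.  ``lysis`` columns: sample, wavelength_nm, absorbance.
    ``medium_controls`` maps wavelength_nm -> absorbance.
    """

    readings: pd.DataFrame
    lysis: pd.DataFrame
    medium_controls: dict[int, float]

    def sample_ids(self) -> list[str]:
        return sorted(self.readings["sample"].unique())

    def daily_pairs(self, sample: str) -> pd.DataFrame:
        """Wide per-day table with one column per wavelength."""
        sub = self.readings[self.readings["sample"] == sample]
        wide = sub.pivot(index="day", columns="wavelength_nm", values="absorbance")
        if wide.isna().any().any():
            raise ValueError(f"sample {sample!r} is missing wavelength readings")
        days = wide.index.to_numpy()
        if not np.array_equal(days, np.arange(days.min(), days.max() + 1)):
            raise ValueError(f"days for sample {sample!r} are not contiguous")
        return wide.sort_index()

    def lysis_pair(self, sample: str) -> dict[int, float]:
        sub = self.lysis[self.lysis["sample"] == sample]
        return dict(zip(sub["wavelength_nm"], sub["absorbance"]))


def generate_assay_series(
    truth: AssayTruth,
    n_days: int | None = None,
    seed: int = 0,
    sample: str = "S1",
) -> AssayPlate:
    """Simulate daily LDH supernatant readings plus the terminal lysis step.

    The 490 nm absorbance on day i is ``baseline + scale * f_i + noise``
    where f_i is the true lysed fraction; 680 nm carries only baseline and
    noise, so the blank-corrected signal is proportional to f_i.  The final
    detergent-lysis reading is proportional to the residual intracellular
    fraction.
    """
    f = truth.daily_lysed_fraction
    if n_days is None:
        n_days = len(f)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if n_days != len(f):
        raise ValueError("n_days must match the truth series length")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_days):
        noise = rng.normal(0.0, truth.noise_sd, size=2) if truth.noise_sd else (0.0, 0.0)
        a490 = truth.baseline + truth.scale * f[i] + noise[0]
        a680 = truth.baseline + noise[1]
        rows.append((sample, i + 1, 490, a490))
        rows.append((sample, i + 1, 680, a680))
    readings = pd.DataFrame(rows, columns=["sample", "day", "wavelength_nm", "absorbance"])
    noise = rng.normal(0.0, truth.noise_sd, size=2) if truth.noise_sd else (0.0, 0.0)
    lysis = pd.DataFrame(
        [
            (sample, 490, truth.baseline + truth.scale * truth.residual_fraction + noise[0]),
            (sample, 680, truth.baseline + noise[1]),
        ],
        columns=["sample", "wavelength_nm", "absorbance"],
    )
    medium = {490: truth.baseline, 680: truth.baseline}
    return AssayPlate(readings=readings, lysis=lysis, medium_controls=medium)


# ---------------------------------------------------------------------------
# paired counters
# ---------------------------------------------------------------------------

def _apply_error_law(rng: np.random.Generator, truth: np.ndarray, law) -> np.ndarray:
    """Additive error law: 0 / ('none',), ('offset', c), ('gaussian', sd)."""
    if law is None or law == 0 or law == ("none",):
        noisy = truth.astype(float)
    elif isinstance(law, tuple) and law[0] == "offset":
        noisy = truth + float(law[1])
    elif isinstance(law, tuple) and law[0] == "gaussian":
        noisy = truth + rng.normal(0.0, float(law[1]), size=len(truth))
    else:
        raise ValueError(f"unknown error law {law!r}")
    return np.maximum(np.round(noisy), 0).astype(int)


def generate_paired_counts(
    true_counts,
    error_law_a=("gaussian", 5.0),
    error_law_b=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two noisy integer re-counts of the same true foci numbers, emulating
    paired observers (or observer vs algorithm).

    Errors are additive per the given law, then rounded to the nearest
    non-negative integer.  Returns columns ``truth``, ``counter_a``,
    ``counter_b``.
    """
    truth = np.asarray(true_counts)
    if truth.size == 0:
        raise ValueError("true_counts must be non-empty")
    if (truth < 0).any():
        raise ValueError("true_counts must be non-negative")
    rng = np.random.default_rng(seed)
    a = _apply_error_law(rng, truth, error_law_a)
    b = _apply_error_law(rng, truth, error_law_b)
    return pd.DataFrame({"truth": truth.astype(int), "counter_a": a, "counter_b": b})


# ---------------------------------------------------------------------------
# depth-ordered morphology profiles (Gaussian copula)
# ---------------------------------------------------------------------------

#: Pairwise Pearson correlations of slice morphology measured on the HNSCC
#: tumor slices, variable order (depth, necrotic, cd44, dapi).
TSC_MORPHOLOGY_CORRELATIONS = pd.DataFrame(
    [
        [1.00, -0.88, 0.67, 0.83],
        [-0.88, 1.00, -0.61, -0.71],
        [0.67, -0.61, 1.00, 0.76],
        [0.83, -0.71, 0.76, 1.00],
    ],
    index=["depth", "necrotic", "cd44", "dapi"],
    columns=["depth", "necrotic", "cd44", "dapi"],
)

#: realistic output ranges for the morphology fractions (uniform marginals
#: are mapped affinely into these intervals)
_FRACTION_RANGES = {
    "necrotic": (0.20, 0.80),  # scene mean ~0.5, matching the reported 49.5%
    "cd44": (0.10, 0.70),
    "dapi": (0.30, 0.90),
}


def _latent_from_target(rho: np.ndarray) -> np.ndarray:
    """Invert the Gaussian-copula Pearson relation for uniform marginals:
    rho_out = (6/pi) asin(rho_latent / 2)  =>  rho_latent = 2 sin(pi rho_out / 6).
    Affine maps of the uniforms preserve Pearson correlation, so hitting the
    target on the uniform scale hits it on the fraction scale too."""
    lat = 2.0 * np.sin(np.pi * rho / 6.0)
    np.fill_diagonal(lat, 1.0)
    return lat


def generate_depth_profile(
    n_slices: int,
    slice_thickness: float = 500.0,
    correlation_targets: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-slice morphology fractions along tissue depth with a
    prescribed Pearson correlation structure.

    A Gaussian copula is used: the depth variable's latent coordinate is the
    deterministic normal-score grid of the ordered slices, the remaining
    variables are drawn from the conditional multivariate normal, and all
    latents are mapped through the normal CDF to bounded fractions.  The
    latent correlation is pre-adjusted (arcsine relation) so the *output*
    Pearson correlations converge to the requested targets as n_slices grows.

    Returns a table with columns slice, depth_um, necrotic_fraction,
    cd44_fraction, dapi_fraction; depth = slice index x thickness from the
    skin-side slice at depth 0.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if correlation_targets is None:
        correlation_targets = TSC_MORPHOLOGY_CORRELATIONS
    target = np.asarray(correlation_targets, dtype=float)
    if target.shape != (4, 4):
        raise ValueError("correlation_targets must be 4x4 (depth, necrotic, cd44, dapi)")
    if not np.allclose(target, target.T):
        raise ValueError("correlation_targets must be symmetric")
    if not np.allclose(np.diag(target), 1.0):
        raise ValueError("correlation_targets must have unit diagonal")
    eigmin = np.linalg.eigvalsh(target).min()
    if eigmin < -1e-10:
        raise ValueError(f"correlation_targets not positive semi-definite (eigmin={eigmin:.3g})")

    latent = _latent_from_target(target)
    # the arcsine adjustment can nudge an admissible target slightly outside
    # the PSD cone; repair by eigenvalue clipping and diagonal rescaling
    if np.linalg.eigvalsh(latent).min() < 0:
        evals, evecs = np.linalg.eigh(latent)
        latent = evecs @ np.diag(np.clip(evals, 1e-8, None)) @ evecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)

    rng = np.random.default_rng(seed)
    n = n_slices
    if n == 1:
        warnings.warn("single slice: correlations are undefined for this profile")
    # deterministic stratified normal scores for depth
    z_d = stats.norm.ppf((np.arange(n) + 0.5) / n)
    # conditional MVN of the 3 fraction variables given the depth latent
    s_do = latent[0, 1:]
    s_oo = latent[1:, 1:]
    cond_mean = np.outer(z_d, s_do)  # (n, 3)
    cond_cov = s_oo - np.outer(s_do, s_do)
    # cond_cov is PSD; use eigh for a robust square root
    evals, evecs = np.linalg.eigh(cond_cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    z_o = cond_mean + rng.standard_normal((n, 3)) @ root.T

    u = stats.norm.cdf(z_o)
    out = pd.DataFrame({"slice": np.arange(n), "depth_um": np.arange(n) * slice_thickness})
    for j, name in enumerate(["necrotic", "cd44", "dapi"]):
        lo, hi = _FRACTION_RANGES[name]
        out[f"{name}_fraction"] = lo + (hi - lo) * u[:, j]
    return out
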