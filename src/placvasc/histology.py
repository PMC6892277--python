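"""Micrograph quantification: three-class pixel segmentation, particle
analysis with area/circularity filters, vascular fill and density, and the
fill-based block inclusion rule.

Pixels of an H&E micrograph of contrast-perfused tissue fall into three
classes: perfused vessel lumen together with slide background (contrast
agent plus the white shrinkage space around it), unperfused lumen (red
cells), and villous tissue.  Vessel lumens are measured as connected
components ("particles") retained when their area lies in [60, 1e6] um^2
and their circularity 4*pi*A/P^2 in [0.20, 1.00] — the same filters remove
the background and mis-segmented slivers.

Vascular fill — the perfused share of total lumen area above a size cutoff
(10,000 um^2 for whole-placenta-scale vessels, 200 um^2 for block-scale
vessels) — is a perfusion-quality measure; blocks with fill below 75% at
the 200 um^2 cutoff are excluded from density analysis.  Histological
vascular density is total lumen area over villous-plus-lumen area, x100.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import DataError
from .phantom import (
    CLASS_COLOURS,
    CLASS_NAMES,
    MICROFIL_COLOUR,
    PhantomSpec2D,
    generate_micrograph_phantom,
    random_micrograph_spec,
)

DEFAULT_AREA_RANGE_UM2 = (60.0, 1_000_000.0)
DEFAULT_CIRC_RANGE = (0.20, 1.00)
FILL_CUTOFFS_UM2 = (10_000.0, 200.0)
MIN_FILL_PCT = 75.0

_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


# ---------------------------------------------------------------------------
# pixel classification
# ---------------------------------------------------------------------------


def render_class_image(labels: np.ndarray) -> np.ndarray:
    """RGB rendering of a 0/1/2 label image in the canonical class colours."""
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for name, idx in _CLASS_INDEX.items():
        out[labels == idx] = CLASS_COLOURS[name]
    return out


def labels_from_colours(image: np.ndarray) -> np.ndarray | None:
    """Exact colour -> class mapping for pre-made label images.

    Returns None when the image contains colours outside the canonical
    palette (then the trained classifier must be used).
    """
    image = np.asarray(image)
    palette = {
        CLASS_COLOURS["perfused"]: 0,
        MICROFIL_COLOUR: 0,
        CLASS_COLOURS["unperfused"]: 1,
        CLASS_COLOURS["villous"]: 2,
    }
    labels = np.full(image.shape[:2], -1, dtype=np.int8)
    for colour, idx in palette.items():
        hit = np.all(image == np.array(colour, dtype=image.dtype), axis=-1)
        labels[hit] = idx
    if (labels < 0).any():
        return None
    return labels.astype(np.uint8)


def _features(image: np.ndarray) -> np.ndarray:
    """Colour + local-texture features: raw RGB plus two Gaussian scales."""
    img = np.asarray(image, dtype=np.float64)
    feats = [img[..., c] for c in range(3)]
    for sigma in (1.0, 3.0):
        for c in range(3):
            feats.append(ndi.gaussian_filter(img[..., c], sigma))
    return np.stack(feats, axis=-1)


def _training_phantom(seed: int) -> PhantomSpec2D:
    """Fixed training scene covering all three classes and the background."""
    spec = random_micrograph_spec(
        seed=seed,
        shape=(384, 384),
        n_villi=4,
        lumens_per_villus=(2, 3),
        perfused_probability=0.6,
        lumen_radius_px=(8.0, 20.0),
    )
    spec.noise_sd = 3.0
    return spec


@lru_cache(maxsize=4)
def train_default_classifier(seed: int = 0):
    """A deterministic pixel classifier fit on a packaged phantom scene.

    A small random forest over colour/texture features; the training
    fixture is generated programmatically, so the classifier is fully
    reproducible from the seed alone.
    """
    from sklearn.ensemble import RandomForestClassifier

    img, masks, _ = generate_micrograph_phantom(_training_phantom(seed))
    truth = np.zeros(img.shape[:2], dtype=np.uint8)  # background -> class 0
    truth[masks["villous"]] = _CLASS_INDEX["villous"]
    truth[masks["unperfused"]] = _CLASS_INDEX["unperfused"]
    truth[masks["perfused"]] = _CLASS_INDEX["perfused"]
    feats = _features(img).reshape(-1, 9)
    y = truth.ravel()
    rng = np.random.default_rng(seed)
    idx = []
    for cls in range(3):
        pool = np.flatnonzero(y == cls)
        take = min(len(pool), 15_000)
        idx.append(rng.choice(pool, size=take, replace=False))
    idx = np.concatenate(idx)
    clf = RandomForestClassifier(
        n_estimators=40, max_depth=12, random_state=seed, n_jobs=1
    )
    clf.fit(feats[idx], y[idx])
    return clf


def classify_pixels(
    image: np.ndarray, classifier=None, seed: int = 0
) -> np.ndarray:
    """Assign every pixel to one of the three classes (0 perfused+background,
    1 unperfused, 2 villous).

    Images already rendered in the canonical class colours are mapped
    exactly (so classification is idempotent on its own label renderings);
    anything else goes through the trained classifier.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise DataError("micrograph must be an RGB image")
    exact = labels_from_colours(image)
    if exact is not None:
        return exact
    if classifier is None:
        classifier = train_default_classifier(seed)
    feats = _features(image).reshape(-1, 9)
    return classifier.predict(feats).reshape(image.shape[:2]).astype(np.uint8)


# ---------------------------------------------------------------------------
# particle analysis
# ---------------------------------------------------------------------------

PARTICLE_COLUMNS = [
    "particle_class", "area_um2", "perimeter_um", "circularity",
    "centroid_y", "centroid_x",
]


def analyse_particles(
    class_mask: np.ndarray,
    um_per_px: float,
    particle_class: str = "perfused",
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE_UM2,
    circ_range: tuple[float, float] = DEFAULT_CIRC_RANGE,
) -> pd.DataFrame:
    """Connected-component particle table after area/circularity filtering.

    Circularity is 4*pi*A/P^2 with the perimeter from the weighted
    boundary-step estimator, capped at 1.0 (digitisation can nudge compact
    shapes above the analytic maximum).
    """
    if um_per_px <= 0:
        raise DataError("missing or invalid scale (um per pixel)")
    labels = cc_label(np.asarray(class_mask, dtype=bool), connectivity=2)
    rows = []
    for rp in regionprops(labels):
        area_um2 = rp.area * um_per_px**2
        perim_px = rp.perimeter
        circ = 1.0 if perim_px == 0 else min(1.0, 4.0 * np.pi * rp.area / perim_px**2)
        if not (area_range_um2[0] <= area_um2 <= area_range_um2[1]):
            continue
        if not (circ_range[0] <= circ <= circ_range[1]):
            continue
        rows.append(
            {
                "particle_class": particle_class,
                "area_um2": area_um2,
                "perimeter_um": perim_px * um_per_px,
                "circularity": circ,
                "centroid_y": rp.centroid[0],
                "centroid_x": rp.centroid[1],
            }
        )
    return pd.DataFrame(rows, columns=PARTICLE_COLUMNS)


def vascular_fill(particles: pd.DataFrame, area_cutoff_um2: float) -> float:
    """Perfused share (%) of total lumen area above the cutoff.

    NaN when no vessel above the cutoff qualifies (undefined fill).
    """
    big = particles[particles["area_um2"] > area_cutoff_um2]
    total = big["area_um2"].sum()
    if total == 0 or len(big) == 0:
        return float("nan")
    perfused = big.loc[big["particle_class"] == "perfused", "area_um2"].sum()
    return 100.0 * float(perfused) / float(total)


def vascular_density_histology(
    particles: pd.DataFrame, villous_area_um2: float
) -> float:
    """Total lumen area as % of villous-plus-lumen area."""
    vessel = float(particles["area_um2"].sum())
    if villous_area_um2 <= 0 and vessel == 0:
        raise DataError("no villous tissue and no vessels: density undefined")
    return 100.0 * vessel / (villous_area_um2 + vessel)


# ---------------------------------------------------------------------------
# per-micrograph and per-block bookkeeping
# ---------------------------------------------------------------------------


def analyse_micrograph(
    image: np.ndarray,
    um_per_px: float,
    classifier=None,
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE_UM2,
    circ_range: tuple[float, float] = DEFAULT_CIRC_RANGE,
) -> tuple[pd.DataFrame, float]:
    """Classify one micrograph and measure its particles.

    Returns the combined perfused+unperfused particle table and the villous
    class area in um^2.
    """
    labels = classify_pixels(image, classifier=classifier)
    tables = []
    for name in ("perfused", "unperfused"):
        mask = labels == _CLASS_INDEX[name]
        if name == "perfused":
            # detach the slide background (touches the image border) from
            # the lumens before particle filtering
            mask = _drop_border_component(mask)
        tables.append(
            analyse_particles(mask, um_per_px, name, area_range_um2, circ_range)
        )
    villous_area = float((labels == _CLASS_INDEX["villous"]).sum()) * um_per_px**2
    non_empty = [t for t in tables if len(t)]
    combined = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=PARTICLE_COLUMNS)
    )
    return combined, villous_area


def _drop_border_component(mask: np.ndarray) -> np.ndarray:
    """Remove connected components touching the image border (background)."""
    labels = cc_label(mask, connectivity=2)
    border = np.unique(
        np.concatenate(
            [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
        )
    )
    border = border[border > 0]
    return mask & ~np.isin(labels, border)


@dataclass
class BlockHistology:
    """Per-block histology summary with the fill-based inclusion flag."""

    placenta_id: str
    block_id: str
    fill_10000_pct: float
    fill_200_pct: float
    density_pct: float
    included: bool


def summarise_block(
    placenta_id: str,
    block_id: str,
    particle_tables: list[pd.DataFrame],
    villous_areas_um2: list[float],
    basal: list[bool] | None = None,
    min_fill_pct: float = MIN_FILL_PCT,
) -> BlockHistology:
    """Aggregate a block's micrographs into fill, density and inclusion.

    The >200 um^2 fill uses only basal-half micrographs (the compartment
    analysed at block-imaging scale) when positions are given; the
    >10,000 um^2 fill and the density use all micrographs.
    """
    if basal is None:
        basal = [True] * len(particle_tables)
    all_particles = pd.concat(particle_tables, ignore_index=True)
    basal_particles = pd.concat(
        [t for t, b in zip(particle_tables, basal) if b],
        ignore_index=True,
    ) if any(basal) else all_particles.iloc[0:0]
    fill_10000 = vascular_fill(all_particles, FILL_CUTOFFS_UM2[0])
    fill_200 = vascular_fill(basal_particles, FILL_CUTOFFS_UM2[1])
    density = vascular_density_histology(all_particles, float(np.sum(villous_areas_um2)))
    included = bool(np.isfinite(fill_200) and fill_200 >= min_fill_pct)
    return BlockHistology(
        placenta_id, block_id, fill_10000, fill_200, density, included
    )


def apply_inclusion_rule(
    blocks: pd.DataFrame, min_fill_pct: float = MIN_FILL_PCT
) -> pd.DataFrame:
    """Keep blocks whose >200 um^2 vascular fill is at least the minimum
    (non-strict at the boundary; undefined fill is excluded)."""
    if blocks.empty:
        return blocks.copy()
    ok = blocks["fill_200_pct"].ge(min_fill_pct) & blocks["fill_200_pct"].notna()
    return blocks[ok].copy()
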