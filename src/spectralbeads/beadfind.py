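"""Bead identification and per-bead region segmentation from bright-field images.

Hydrogel beads appear under bright-field illumination as dark rings on a
bright background.  Finding them therefore reduces to locating ring pixels by
adaptive (locally referenced) thresholding, filling the enclosed interiors,
and splitting touching beads with a seeded watershed so that every pixel
belongs to at most one bead.  Each bead is then described by four region
masks sharing one integer label:

``whole``
    all pixels of the bead (ring plus core);
``ring``
    the dark-edge pixels, where bound fluorescent probe localizes;
``core``
    the enclosed interior, where the embedded spectral code is read;
``background``
    an annulus just outside the ring used for local background subtraction,
    never overlapping any bead.

Thresholding follows the dark-object convention: a pixel is foreground when
its intensity falls below the Gaussian-weighted local mean minus a fixed
offset (default block size 15 px, offset 11 counts, tuned for beads that
subtend roughly 10-20 px).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation, transform

logger = logging.getLogger(__name__)

__all__ = [
    "BeadMaskSet",
    "BeadMorphology",
    "adaptive_threshold",
    "segment_beads",
    "find_circles",
    "circles_to_masks",
    "morphology_table",
]

_STRUCT4 = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class BeadMaskSet:
    """Labeled region images for one field of view.

    All four label grids share one shape and one label space: label ``k > 0``
    denotes bead ``k`` in every mask type, label 0 is non-bead background.
    """

    whole: np.ndarray
    core: np.ndarray
    ring: np.ndarray
    background: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of bead labels present in the whole mask."""
        return np.unique(self.whole[self.whole > 0])

    def validate(self) -> None:
        """Assert the region-partition invariants; raise AssertionError on breach."""
        for name in ("core", "ring", "background"):
            assert getattr(self, name).shape == self.whole.shape, name
        # core and ring partition whole, per label
        assert np.array_equal(
            np.where(self.core > 0, self.core, self.ring), self.whole
        ), "core ∪ ring != whole"
        assert not np.any((self.core > 0) & (self.ring > 0)), "core ∩ ring != ∅"
        assert not np.any(
            (self.background > 0) & (self.whole > 0)
        ), "background overlaps a bead"
        labels = set(self.labels.tolist())
        for name in ("core", "ring"):
            assert set(np.unique(getattr(self, name))) - {0} == labels, (
                f"label set of {name} differs from whole"
            )

    def region(self, name: str) -> np.ndarray:
        if name not in ("whole", "core", "ring", "background"):
            raise KeyError(f"unknown region {name!r}")
        return getattr(self, name)


@dataclass
class BeadMorphology:
    """Shape descriptors of one identified bead."""

    label: int
    centroid: tuple[float, float]  # (row, col)
    area: float
    equivalent_diameter: float
    eccentricity: float
    file_index: int | None = None
    set_name: str | None = None


def morphology_table(morphologies: list[BeadMorphology]) -> pd.DataFrame:
    """Tabulate morphology records (one row per bead)."""
    return pd.DataFrame(
        {
            "set": [m.set_name for m in morphologies],
            "file": [m.file_index for m in morphologies],
            "label": [m.label for m in morphologies],
            "centroid_row": [m.centroid[0] for m in morphologies],
            "centroid_col": [m.centroid[1] for m in morphologies],
            "area": [m.area for m in morphologies],
            "diameter": [m.equivalent_diameter for m in morphologies],
            "eccentricity": [m.eccentricity for m in morphologies],
        }
    )


def adaptive_threshold(
    bright_field: np.ndarray,
    block_size: int = 15,
    offset: float = 11.0,
    dark_objects: bool = True,
) -> np.ndarray:
    """Binary mask of bead-edge pixels by adaptive Gaussian thresholding.

    A pixel is foreground iff its intensity is below (for dark objects) the
    Gaussian-weighted mean of its ``block_size`` neighbourhood minus
    *offset*.  The Gaussian window uses sigma = (block_size - 1) / 6 with
    reflective boundary handling.
    """
    if block_size % 2 == 0 or block_size < 3:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    img = np.asarray(bright_field, dtype=float)
    local_mean = filters.threshold_local(img, block_size, method="gaussian")
    if dark_objects:
        return img < local_mean - offset
    return img > local_mean + offset


def _interior_seeds(edge_mask: np.ndarray) -> np.ndarray:
    """Labeled interior regions: pixels fully enclosed by ring pixels.

    Hole filling and seed labeling use 4-connectivity; filled blobs touching
    the image border are discarded (a bead cut by the frame cannot be
    quantified).
    """
    filled = ndi.binary_fill_holes(edge_mask, structure=_STRUCT4)
    filled = segmentation.clear_border(filled)
    seeds = filled & ~edge_mask
    labels, _ = ndi.label(seeds, structure=_STRUCT4)
    return labels, filled


def segment_beads(
    edge_mask: np.ndarray,
    expected_diameter_px: tuple[float, float] = (10.0, 20.0),
    area_bounds: tuple[float, float] = (0.5, 1.5),
    ecc_max: float = 0.65,
    background_annulus_px: int = 3,
) -> tuple[BeadMaskSet, list[BeadMorphology]]:
    """Segment the edge mask into per-bead whole/core/ring/background regions.

    Interior seed regions (pixels fully enclosed by ring pixels) are expanded
    by a watershed over the negated distance transform, so each pixel of a
    filled blob is assigned to exactly one seed; fronts stop where they meet.
    Candidate regions are then filtered on area — within
    ``area_bounds`` times the accepted bead area, a circle at the midpoint of
    *expected_diameter_px* — and on eccentricity (``<= ecc_max``).
    Survivors are renumbered in row-major centroid order.  The background
    region is an annulus of *background_annulus_px* outside each ring,
    excluding every other bead's pixels (nearest bead wins where annuli
    would overlap).

    An empty edge mask, or one where every candidate is filtered out, yields
    an empty (all-zero) mask set rather than an error.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    lo, hi = area_bounds
    dmin, dmax = expected_diameter_px
    if dmin <= 0 or dmax <= 0:
        raise ValueError("expected_diameter_px must be positive")
    accepted_area = math.pi * ((dmin + dmax) / 4.0) ** 2

    seeds, filled = _interior_seeds(edge_mask)
    zeros = np.zeros(edge_mask.shape, dtype=np.int32)
    if seeds.max() == 0:
        return BeadMaskSet(zeros, zeros.copy(), zeros.copy(), zeros.copy()), []

    distance = ndi.distance_transform_edt(filled)
    whole = segmentation.watershed(-distance, markers=seeds, mask=filled)

    props = measure.regionprops(whole)
    survivors = [
        p
        for p in props
        if lo * accepted_area <= p.area <= hi * accepted_area
        and p.eccentricity <= ecc_max
    ]
    n_filtered = len(props) - len(survivors)
    if n_filtered:
        logger.info(
            "segment_beads: %d/%d candidate regions filtered "
            "(area outside [%.0f, %.0f] px or eccentricity > %.2f)",
            n_filtered, len(props), lo * accepted_area, hi * accepted_area, ecc_max,
        )
    if not survivors:
        return BeadMaskSet(zeros, zeros.copy(), zeros.copy(), zeros.copy()), []

    # renumber by position: row-major centroid order
    survivors.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    relabel = np.zeros(whole.max() + 1, dtype=np.int32)
    for new, p in enumerate(survivors, start=1):
        relabel[p.label] = new
    whole = relabel[whole]

    ring = np.where(edge_mask, whole, 0).astype(np.int32)
    core = np.where(~edge_mask, whole, 0).astype(np.int32)
    expanded = segmentation.expand_labels(whole, distance=background_annulus_px)
    background = np.where(whole == 0, expanded, 0).astype(np.int32)

    morphologies = [
        BeadMorphology(
            label=new,
            centroid=tuple(p.centroid),
            area=float(p.area),
            equivalent_diameter=float(p.equivalent_diameter_area),
            eccentricity=float(p.eccentricity),
        )
        for new, p in enumerate(survivors, start=1)
    ]
    return BeadMaskSet(whole.astype(np.int32), core, ring, background), morphologies


def find_circles(
    bright_field: np.ndarray,
    radius_range: tuple[int, int],
    max_circles: int = 10_000,
    canny_sigma: float = 1.5,
    accumulator_threshold: float = 0.5,
) -> list[tuple[tuple[float, float], float]]:
    """Detect circular beads with a circular Hough transform.

    Returns a list of ``((row, col), radius)`` detections.  This is the
    simple fallback detector: unlike the watershed route it yields idealized
    circles and preserves no morphological information (eccentricity, exact
    area), so filtered segmentation should be preferred when bead shapes
    matter.  An empty list (blank image) is not an error.
    """
    rmin, rmax = int(radius_range[0]), int(radius_range[1])
    if rmin <= 0 or rmax < rmin:
        raise ValueError(f"bad radius range {radius_range}")
    img = np.asarray(bright_field, dtype=float)
    span = img.max() - img.min()
    if span == 0:
        return []
    edges = feature.canny((img - img.min()) / span, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(rmin, rmax + 1)
    accum = transform.hough_circle(edges, radii)
    peaks = transform.hough_circle_peaks(
        accum,
        radii,
        min_xdistance=rmin,
        min_ydistance=rmin,
        threshold=accumulator_threshold * accum.max(),
        total_num_peaks=max_circles,
    )
    _, cx, cy, rr = peaks
    return [((float(y), float(x)), float(r)) for x, y, r in zip(cx, cy, rr)]


def circles_to_masks(
    circles: list[tuple[tuple[float, float], float]],
    shape: tuple[int, int],
    ring_width_px: int = 2,
    background_annulus_px: int = 3,
) -> BeadMaskSet:
    """Convert circle detections into a synthetic-circle BeadMaskSet.

    Labels follow row-major centroid order; overlapping circles keep the
    lower label (first writer wins is avoided by assigning in reverse order).
    """
    whole = np.zeros(shape, dtype=np.int32)
    ring = np.zeros(shape, dtype=np.int32)
    core = np.zeros(shape, dtype=np.int32)
    ordered = sorted(circles, key=lambda c: (c[0][0], c[0][1]))
    rows, cols = np.indices(shape)
    for label, ((r0, c0), radius) in reversed(list(enumerate(ordered, start=1))):
        dist = np.hypot(rows - r0, cols - c0)
        inside = dist <= radius
        is_ring = inside & (dist > radius - ring_width_px)
        whole[inside] = label
        ring[is_ring] = label
        core[inside & ~is_ring] = label
    # re-derive core/ring consistency where overlaps overwrote whole
    ring = np.where(whole == ring, ring, 0)
    core = np.where(whole == core, core, 0)
    core = np.where((whole > 0) & (ring == 0), whole, core)
    expanded = segmentation.expand_labels(whole, distance=background_annulus_px)
    background = np.where(whole == 0, expanded, 0).astype(np.int32)
    return BeadMaskSet(whole, core, ring, background)
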