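"""Tumor-region masks and patch membership.

The pathologist draws loops around tumor; scoring must restrict patch
probabilities to patches inside those loops.  Two equivalent routes are
provided:

* :func:`rasterize` — burn the annotation into a full-resolution binary
  raster (pixel set iff the pixel *centre* is inside the polygon set under
  the even-odd rule, holes subtracting), then :func:`patch_in_tumor` looks
  up the patch's centre pixel.
* :func:`patch_membership` — test patch centre points against the polygon
  directly, skipping the raster.  Exactly equivalent by construction and
  much cheaper for whole-slide grids; the equivalence is asserted in the
  test suite.

Membership rule: a patch belongs to the tumor iff its centre pixel
``(x + patch_size // 2, y + patch_size // 2)`` is tumor.  A minimum-overlap
alternative is available via ``min_overlap`` but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .io import PatchRecord, TumorAnnotation

__all__ = ["TumorMask", "annotation_geometry", "rasterize", "patch_in_tumor",
           "patch_membership"]

logger = logging.getLogger(__name__)


@dataclass
class TumorMask:
    """Binary tumor raster for one image (1 = tumor), row-major [y, x]."""

    image_id: str
    bitmap: np.ndarray  # (height, width) uint8 in {0, 1}

    @property
    def height(self) -> int:
        return self.bitmap.shape[0]

    @property
    def width(self) -> int:
        return self.bitmap.shape[1]

    @property
    def n_tumor_pixels(self) -> int:
        return int(self.bitmap.sum())


def annotation_geometry(annotation: TumorAnnotation):
    """Shapely geometry for an annotation under the even-odd fill rule.

    Even-odd = symmetric difference of all ring interiors: a point is tumor
    iff a ray from it crosses an odd number of ring edges.  For the usual
    case (disjoint outer loops, holes nested inside them) this coincides
    with "outer minus holes"; for annotation-tool exports with overlapping
    loops it is the unambiguous reading.
    """
    rings: list[Polygon] = []
    for outer, holes in annotation.polygons:
        rings.append(Polygon(outer))
        rings.extend(Polygon(h) for h in holes)
    geom = None
    for ring in rings:
        if not ring.is_valid:
            ring = ring.buffer(0)
        geom = ring if geom is None else geom.symmetric_difference(ring)
    return geom if geom is not None else MultiPolygon([])


def rasterize(
    annotation: TumorAnnotation,
    width: int,
    height: int,
    clip: bool = True,
) -> TumorMask:
    """Burn a tumor annotation into a (height, width) binary mask.

    Pixel (i, j) is set iff its centre (j + 0.5, i + 0.5) lies inside the
    polygon set (even-odd rule; holes subtract).  Vertices outside
    [0, width] x [0, height] are tolerated with a warning — the raster is
    simply the clipped view.
    """
    verts = annotation.all_vertices()
    if clip and len(verts) and (
        (verts[:, 0] < 0).any()
        or (verts[:, 1] < 0).any()
        or (verts[:, 0] > width).any()
        or (verts[:, 1] > height).any()
    ):
        logger.warning(
            "annotation %s has vertices outside the %dx%d raster; clipping",
            annotation.image_id, width, height,
        )
    geom = annotation_geometry(annotation)
    if geom.is_empty or geom.area == 0:
        raise ValueError(f"empty tumor region for image {annotation.image_id!r}")
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(geom)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    bitmap = inside.reshape(height, width).astype(np.uint8)
    return TumorMask(image_id=annotation.image_id, bitmap=bitmap)


def patch_in_tumor(mask: TumorMask, patch: PatchRecord, patch_size: int) -> int:
    """1 iff the patch's centre pixel is tumor in the raster mask."""
    cx = patch.x + patch_size // 2
    cy = patch.y + patch_size // 2
    if not (0 <= cx < mask.width and 0 <= cy < mask.height):
        logger.debug(
            "patch (%d, %d) centre outside %dx%d mask %s; counted out of tumor",
            patch.x, patch.y, mask.width, mask.height, mask.image_id,
        )
        return 0
    return int(mask.bitmap[cy, cx])


def patch_membership(
    annotation: TumorAnnotation,
    coords: np.ndarray,
    patch_size: int,
    min_overlap: float | None = None,
) -> np.ndarray:
    """Vectorized tumor membership for patches given their upper-left vertices.

    Default rule tests the centre of the patch's centre pixel,
    ``(x + patch_size//2 + 0.5, y + patch_size//2 + 0.5)``, against the
    polygon — identical to rasterizing and reading the centre pixel.  With
    ``min_overlap`` in (0, 1], a patch is instead in-tumor iff at least that
    fraction of its box area intersects the tumor geometry.

    Parameters
    ----------
    coords : (n, 2) integer array of patch upper-left (x, y).

    Returns
    -------
    (n,) boolean array.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    geom = annotation_geometry(annotation)
    if geom.is_empty or geom.area == 0:
        raise ValueError(f"empty tumor region for image {annotation.image_id!r}")
    if min_overlap is None:
        shapely.prepare(geom)
        cx = coords[:, 0] + patch_size // 2 + 0.5
        cy = coords[:, 1] + patch_size // 2 + 0.5
        return shapely.contains_xy(geom, cx, cy)
    boxes = shapely.box(
        coords[:, 0], coords[:, 1],
        coords[:, 0] + patch_size, coords[:, 1] + patch_size,
    )
    inter = shapely.area(shapely.intersection(boxes, geom))
    return inter >= min_overlap * float(patch_size) ** 2
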