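"""Geometric quadrant grading from binary fibrosis masks.

Given a binary mask of the spinal canal / epidural evaluation area, a binary
mask of fibrosis pixels, and the center of the dural sac, the canal is split
into four quadrants by two perpendicular lines through the center.  At
laminectomy levels an optional posterior border line (between the most
posterior bony remnants) clips the evaluation area.  Per-quadrant affected
fractions then feed :func:`efgrade.grading.grade_from_fraction`.

Conventions
-----------
Images are (row, column) rasters displayed radiologically: anterior is up
(smaller row index) and the patient's right is image-left (smaller column
index).  Quadrant A is right anterior, B left anterior, C right posterior,
D left posterior.  Pixels exactly on a dividing line are assigned to the
anterior / patient-right side, i.e. with priority A > B > C > D.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .grading import (
    DEFAULT_TRACE_THRESHOLD,
    QUADRANTS,
    SliceAssessment,
    grade_from_fraction,
)

__all__ = [
    "SliceGeometry",
    "QuadrantFractions",
    "partition_quadrants",
    "quadrant_fractions",
    "grade_slice_from_masks",
    "load_mask",
    "save_mask",
]


class GeometryError(ValueError):
    """Invalid mask geometry (center, border, or mask consistency)."""


Point = tuple[float, float]  # (row, column), 0-based pixel coordinates


@dataclass(frozen=True)
class SliceGeometry:
    """Masks and landmarks needed to grade one axial slice geometrically.

    Parameters
    ----------
    canal_mask
        Boolean raster marking the evaluation area (epidural space region).
    fibrosis_mask
        Boolean raster of fibrosis pixels; must be a subset of ``canal_mask``.
    center
        Dural-sac center as (row, column) in pixel units.
    posterior_border
        Optional pair of (row, column) points; the infinite line through them
        bounds the evaluation area posteriorly (pixels strictly posterior are
        excluded, pixels on the line are kept).
    rotation_deg
        Rotation of the dividing lines, counter-clockwise in the image plane,
        for non-standard display orientations.  Default 0 (axis-aligned).
    """

    canal_mask: np.ndarray
    fibrosis_mask: np.ndarray
    center: Point
    posterior_border: tuple[Point, Point] | None = None
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        canal = np.asarray(self.canal_mask, dtype=bool)
        fib = np.asarray(self.fibrosis_mask, dtype=bool)
        object.__setattr__(self, "canal_mask", canal)
        object.__setattr__(self, "fibrosis_mask", fib)
        if canal.ndim != 2:
            raise GeometryError("masks must be 2-D rasters")
        if canal.shape != fib.shape:
            raise GeometryError(
                f"mask shapes differ: canal {canal.shape} vs fibrosis {fib.shape}"
            )
        if np.any(fib & ~canal):
            raise GeometryError("fibrosis mask has pixels outside the canal mask")
        r, c = self.center
        nrows, ncols = canal.shape
        if not (0 <= r <= nrows - 1 and 0 <= c <= ncols - 1):
            raise GeometryError(
                f"center {self.center} lies outside the {canal.shape} raster"
            )
        if self.posterior_border is not None:
            (r1, c1), (r2, c2) = self.posterior_border
            if r1 == r2 and c1 == c2:
                raise GeometryError("posterior border points coincide")


@dataclass(frozen=True)
class QuadrantFractions:
    """Affected fraction of each quadrant's evaluation area, in [0, 1]."""

    fractions: Mapping[str, float]
    pixel_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for q in QUADRANTS:
            f = self.fractions.get(q)
            if f is None or not 0.0 <= f <= 1.0:
                raise GeometryError(f"fraction for quadrant {q} invalid: {f}")

    def __getitem__(self, quadrant: str) -> float:
        return self.fractions[quadrant]


def _posterior_exclusion(
    shape: tuple[int, int], border: tuple[Point, Point]
) -> np.ndarray:
    """Boolean raster of pixels strictly posterior to the border line."""
    (r1, c1), (r2, c2) = border
    dr, dc = r2 - r1, c2 - c1
    # Normal to the line with positive row component points posteriorly
    # (rows increase toward posterior).  The two candidate normals are
    # (dc, -dr) and (-dc, dr).
    nr, nc = (dc, -dr) if dc > 0 or (dc == 0 and -dr > 0) else (-dc, dr)
    if nr == 0:
        raise GeometryError(
            "posterior border is parallel to the anterior-posterior axis; "
            "no posterior half-plane exists"
        )
    rows, cols = np.indices(shape)
    side = nr * (rows - r1) + nc * (cols - c1)
    return side > 0


def evaluation_area(geometry: SliceGeometry) -> np.ndarray:
    """Canal mask with any posterior-border clipping applied."""
    area = geometry.canal_mask.copy()
    if geometry.posterior_border is not None:
        area &= ~_posterior_exclusion(area.shape, geometry.posterior_border)
    return area


def partition_quadrants(geometry: SliceGeometry) -> np.ndarray:
    """Label every evaluation-area pixel with its quadrant A-D.

    Returns an array of single-character labels (``''`` outside the
    evaluation area).  The dividing lines are perpendicular through the
    dural-sac center, axis-aligned unless ``rotation_deg`` is set.
    """
    area = evaluation_area(geometry)
    rows, cols = np.indices(area.shape)
    dr = rows - geometry.center[0]
    dc = cols - geometry.center[1]
    if geometry.rotation_deg:
        theta = math.radians(geometry.rotation_deg)
        dr, dc = (
            math.cos(theta) * dr - math.sin(theta) * dc,
            math.sin(theta) * dr + math.cos(theta) * dc,
        )
    anterior = dr <= 0  # ties on the transverse line go anterior
    right = dc <= 0  # ties on the sagittal line go to the patient's right
    labels = np.full(area.shape, "", dtype="<U1")
    labels[area & anterior & right] = "A"
    labels[area & anterior & ~right] = "B"
    labels[area & ~anterior & right] = "C"
    labels[area & ~anterior & ~right] = "D"
    return labels


def quadrant_fractions(geometry: SliceGeometry) -> QuadrantFractions:
    """Affected fraction of each quadrant: fibrosis pixels / area pixels.

    A quadrant with no evaluation-area pixels gets fraction 0.
    """
    labels = partition_quadrants(geometry)
    fib = geometry.fibrosis_mask
    fracs: dict[str, float] = {}
    counts: dict[str, int] = {}
    for q in QUADRANTS:
        inq = labels == q
        n = int(inq.sum())
        counts[q] = n
        fracs[q] = float((fib & inq).sum() / n) if n else 0.0
    return QuadrantFractions(fractions=fracs, pixel_counts=counts)


def grade_slice_from_masks(
    geometry: SliceGeometry,
    trace_threshold: float = DEFAULT_TRACE_THRESHOLD,
) -> SliceAssessment:
    """Grade one slice geometrically: per-quadrant fractions to 0-4 grades."""
    fracs = quadrant_fractions(geometry)
    return SliceAssessment.from_grades(
        {q: grade_from_fraction(fracs[q], trace_threshold) for q in QUADRANTS}
    )


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from PNG/TIFF or a plain-text 0/1 matrix.

    Image files are binarized at half the maximum value; multi-channel
    images use the first channel.
    """
    path = Path(path)
    if path.suffix.lower() in {".txt", ".tsv", ".csv", ".dat"}:
        arr = np.loadtxt(path, dtype=float, delimiter="," if path.suffix.lower() == ".csv" else None)
        return arr > 0.5
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    top = img.max()
    return img > (top / 2 if top else 0)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as PNG/TIFF (0/255) or a text 0/1 matrix."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() in {".txt", ".tsv", ".dat"}:
        np.savetxt(path, mask.astype(np.uint8), fmt="%d")
        return
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8)) * 255)


def load_geometry(
    mask_path: str | Path,
    fibrosis_path: str | Path,
    sidecar: str | Path | Mapping,
    patient_id: str | None = None,
    slice_index: int | None = None,
) -> SliceGeometry:
    """Assemble a :class:`SliceGeometry` from mask files and a JSON sidecar.

    The sidecar is either a JSON object with keys ``center`` (``[row, col]``)
    and optional ``posterior_border`` (``[[r1, c1], [r2, c2]]``) and
    ``rotation_deg``, or a list of such objects keyed by ``patient_id`` and
    ``slice_index``.
    """
    if not isinstance(sidecar, Mapping):
        with open(sidecar) as fh:
            sidecar = json.load(fh)
    if "center" not in sidecar:
        records = sidecar.get("slices", sidecar)
        if not isinstance(records, list):
            raise GeometryError("sidecar lacks 'center' and is not a record list")
        matches = [
            rec
            for rec in records
            if (patient_id is None or rec.get("patient_id") == patient_id)
            and (slice_index is None or rec.get("slice_index") == slice_index)
        ]
        if len(matches) != 1:
            raise GeometryError(
                f"sidecar lookup for patient={patient_id!r} slice={slice_index!r} "
                f"matched {len(matches)} records"
            )
        sidecar = matches[0]
    border = sidecar.get("posterior_border")
    return SliceGeometry(
        canal_mask=load_mask(mask_path),
        fibrosis_mask=load_mask(fibrosis_path),
        center=tuple(sidecar["center"]),
        posterior_border=tuple(map(tuple, border)) if border else None,
        rotation_deg=float(sidecar.get("rotation_deg", 0.0)),
    )
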