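"""Skeleton-based branch morphometry.

Given a per-pixel class mask (0 = background, 1 = trunk, 2 = branch),
the pipeline

1. splits each non-background class into 8-connected components and
   discards fragments below an area threshold (mis-segmentation noise),
2. thins every surviving component to its skeleton,
3. reports the component's length as the skeleton pixel count, and
4. fits a straight line to the skeleton pixels by total least squares
   (the principal axis of the coordinates, i.e. the line minimizing the
   summed squared orthogonal Euclidean distances) and reports the
   inclination angle of that line.

Angles are measured in degrees from the horizontal image axis with y
pointing up, in [0, 180): 0 is a horizontal branch, 90 a vertical one,
and values above 90 lean left.  Overlapping strokes of the same class
form a single connected component and are measured as one target; a
2-D image cannot disambiguate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .thinning import zhang_suen_thin

__all__ = [
    "TRUNK",
    "BRANCH",
    "CLASS_NAMES",
    "InstanceMask",
    "LineFit",
    "BranchMeasurement",
    "split_instances",
    "branch_length",
    "fit_line",
    "inclination",
    "measure_all",
]

TRUNK = 1
BRANCH = 2
CLASS_NAMES = {TRUNK: "trunk", BRANCH: "branch"}

#: 8-connectivity structuring element; thin diagonal branches must not fragment.
_STRUCTURE8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class InstanceMask:
    """One connected trunk or branch target."""

    mask: np.ndarray
    class_label: int
    instance_id: int

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def top_left(self) -> tuple[int, int]:
        """First foreground pixel in raster order (used for stable ordering)."""
        rows, cols = np.nonzero(self.mask)
        i = np.lexsort((cols, rows))[0]
        return int(rows[i]), int(cols[i])


@dataclass(frozen=True)
class LineFit:
    """Total-least-squares line through a pixel set.

    ``direction`` is a unit vector in (row, col) image coordinates,
    normalized so d_col >= 0 (and d_row <= 0 for vertical lines).
    ``slope`` is expressed in mathematical y-up coordinates and is None
    for vertical lines.  ``degenerate`` flags isotropic pixel sets with
    no unique principal axis.
    """

    centroid: tuple[float, float]
    direction: tuple[float, float]
    slope: float | None
    degenerate: bool = False

    @property
    def vertical(self) -> bool:
        return self.slope is None


@dataclass(frozen=True)
class BranchMeasurement:
    """Morphometric record for one instance."""

    instance_id: int
    class_label: int
    length_px: int
    inclination_deg: float
    area_px: int = 0
    degenerate: bool = False

    @property
    def class_name(self) -> str:
        return CLASS_NAMES.get(self.class_label, str(self.class_label))


def split_instances(class_mask: np.ndarray, min_area: int = 50) -> list[InstanceMask]:
    """Split a class mask into per-instance binary masks.

    For each non-background class the 8-connected components are
    extracted, components smaller than ``min_area`` pixels are
    discarded as segmentation noise, and the survivors are relabelled
    with sequential ids ordered by (class, top-left pixel).
    """
    cm = np.asarray(class_mask)
    if cm.ndim != 2:
        raise ValueError(f"expected a 2-D class mask, got shape {cm.shape}")
    instances: list[InstanceMask] = []
    for class_label in sorted(CLASS_NAMES):
        binary = cm == class_label
        labelled, n = ndimage.label(binary, structure=_STRUCTURE8)
        if n == 0:
            continue
        areas = ndimage.sum_labels(binary, labelled, index=np.arange(1, n + 1))
        keep = [k + 1 for k in range(n) if areas[k] >= min_area]
        comps = [
            InstanceMask((labelled == k).astype(np.uint8), class_label, -1)
            for k in keep
        ]
        comps.sort(key=lambda c: c.top_left)
        instances.extend(comps)
    return [
        InstanceMask(c.mask, c.class_label, i) for i, c in enumerate(instances)
    ]


def branch_length(inst: InstanceMask) -> int:
    """Length of one instance: the pixel count of its skeleton."""
    if inst.area == 0:
        raise ValueError("cannot measure an empty instance mask")
    return int(zhang_suen_thin(inst.mask).sum())


def fit_line(skeleton: np.ndarray) -> LineFit:
    """Fit a straight line to skeleton pixels by total least squares.

    The line passes through the centroid along the principal eigenvector
    of the coordinate scatter matrix, which minimizes the sum of squared
    orthogonal distances from the pixels to the line.
    """
    rows, cols = np.nonzero(np.asarray(skeleton))
    if rows.size < 2:
        raise ValueError("line fit needs at least 2 skeleton pixels")
    pts = np.column_stack([rows, cols]).astype(float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues; the principal axis is the last.
    degenerate = bool(np.isclose(eigvals[0], eigvals[1]))
    d_row, d_col = eigvecs[:, 1]
    if d_col < 0 or (d_col == 0 and d_row > 0):
        d_row, d_col = -d_row, -d_col
    if np.isclose(d_col, 0.0):
        d_row, d_col = (-1.0 if d_row <= 0 else 1.0), 0.0
        slope = None
    else:
        # y-up slope: y = -row, so dy/dx = -d_row / d_col.
        slope = float(-d_row / d_col)
    return LineFit(
        centroid=(float(centroid[0]), float(centroid[1])),
        direction=(float(d_row), float(d_col)),
        slope=slope,
        degenerate=degenerate,
    )


def inclination(fit: LineFit) -> float:
    """Inclination angle of a fitted line, degrees in [0, 180).

    Measured from the horizontal image axis with y pointing up, via the
    arctangent of the direction vector.
    """
    if fit.degenerate:
        raise ValueError("inclination undefined for a degenerate (isotropic) fit")
    d_row, d_col = fit.direction
    theta = np.degrees(np.arctan2(-d_row, d_col))
    if theta < 0:
        theta += 180.0
    return float(theta % 180.0)


def measure_all(class_mask: np.ndarray, min_area: int = 50) -> list[BranchMeasurement]:
    """Run the full morphometry pipeline on a class mask.

    Each surviving instance is thinned, its skeleton pixels counted as
    the length, and the skeleton's principal axis converted into an
    inclination angle.  Instances whose skeleton admits no unique axis
    (isotropic pixel sets) are returned flagged degenerate with an
    inclination of NaN rather than aborting the batch.
    """
    records: list[BranchMeasurement] = []
    for inst in split_instances(class_mask, min_area=min_area):
        skeleton = zhang_suen_thin(inst.mask)
        length = int(skeleton.sum())
        try:
            angle = inclination(fit_line(skeleton))
            degenerate = False
        except ValueError:
            angle = float("nan")
            degenerate = True
        records.append(
            BranchMeasurement(
                instance_id=inst.instance_id,
                class_label=inst.class_label,
                length_px=length,
                inclination_deg=angle,
                area_px=inst.area,
                degenerate=degenerate,
            )
        )
    return records
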