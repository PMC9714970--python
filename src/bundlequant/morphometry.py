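"""Object-level morphometry: vesicle calls, bundle measures, cell counts.

Vesicles are connected components of a lysosome-marker mask (6-connected
in 3-D by default).  Each component's equivalent diameter is that of the
sphere with the same volume; a component is called *enlarged* iff this
diameter strictly exceeds the threshold (default 2 µm).  Cells are
flagged when at least one enlarged vesicle's centroid lies inside their
mask, and group-wise flag counts assemble into 2×2 contingency tables.

Bundle length is the extent of the 2-D mask along its principal
(second-moment) axis; width is the perpendicular extent measured in a
one-pixel slab at mid-length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .stack import SegmentationMask

__all__ = [
    "VesicleCall",
    "VesicleDetector",
    "detect_vesicles",
    "flag_cells",
    "assign_and_flag_cells",
    "ContingencyTable2x2",
    "contingency_from_flags",
    "BundleMeasure",
    "measure_bundle",
    "count_cells",
    "vesicle_table",
]


@dataclass
class VesicleCall:
    """One connected component of a vesicle mask."""

    component_id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    volume_um3: float
    equivalent_diameter_um: float
    enlarged: bool
    cell_id: int | None = None


class VesicleDetector(BaseEstimator):
    """Connected-component vesicle detection with an enlarged-diameter rule.

    Parameters
    ----------
    diameter_threshold_um : float
        A component is *enlarged* iff its equivalent diameter is strictly
        greater than this (µm).
    connectivity : int
        scipy connectivity order; 1 = 6-neighbourhood (face-adjacent).
    """

    def __init__(self, diameter_threshold_um: float = 2.0, connectivity: int = 1):
        self.diameter_threshold_um = diameter_threshold_um
        self.connectivity = connectivity

    def fit(self, X=None, y=None):
        return self

    def transform(
        self,
        mask: SegmentationMask | np.ndarray,
        voxel_size: Sequence[float],
    ) -> list[VesicleCall]:
        m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {m.shape}")
        if any(v <= 0 for v in voxel_size):
            raise ValueError("voxel size components must be > 0")
        structure = ndimage.generate_binary_structure(3, self.connectivity)
        labels, n = ndimage.label(m, structure=structure)
        if n == 0:
            return []
        voxel_vol = float(np.prod(voxel_size))
        counts = np.bincount(labels.ravel())[1:]
        centroids = ndimage.center_of_mass(m, labels, index=range(1, n + 1))
        calls = []
        for comp_id, (count, cen) in enumerate(zip(counts, centroids), start=1):
            volume = float(count) * voxel_vol
            eq_diam = (6.0 * volume / math.pi) ** (1.0 / 3.0)
            centroid_um = tuple(
                (c + 0.5) * v for c, v in zip(cen, voxel_size)
            )
            calls.append(
                VesicleCall(
                    component_id=comp_id,
                    centroid_um=centroid_um,
                    volume_um3=volume,
                    equivalent_diameter_um=eq_diam,
                    enlarged=eq_diam > self.diameter_threshold_um,
                )
            )
        return calls


def detect_vesicles(
    mask: SegmentationMask | np.ndarray,
    voxel_size: Sequence[float],
    diameter_threshold_um: float = 2.0,
    connectivity: int = 1,
) -> list[VesicleCall]:
    """Functional wrapper over :class:`VesicleDetector`."""
    return VesicleDetector(diameter_threshold_um, connectivity).transform(mask, voxel_size)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = outcome
    (e.g. enlarged-lysosome cell present / absent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def flag_cells(
    vesicles: Iterable[VesicleCall],
    cell_masks: Mapping[int, np.ndarray],
    voxel_size: Sequence[float],
) -> tuple[dict[int, bool], list[VesicleCall]]:
    """Per-cell enlarged flag by centroid containment.

    A cell is flagged iff at least one *enlarged* vesicle's centroid voxel
    lies inside its mask.  Vesicles whose centroid falls in no cell are
    returned as unassigned and excluded from counts.  Cell masks must be
    pairwise disjoint.
    """
    ids = list(cell_masks)
    arr = [np.asarray(cell_masks[i], bool) for i in ids]
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            if (arr[i] & arr[j]).any():
                raise ValueError(f"cell masks {ids[i]} and {ids[j]} overlap")
    flags = {i: False for i in ids}
    unassigned: list[VesicleCall] = []
    for ves in vesicles:
        idx = tuple(
            int(c / v) for c, v in zip(ves.centroid_um, voxel_size)
        )
        owner = None
        for i, m in zip(ids, arr):
            if all(0 <= k < s for k, s in zip(idx, m.shape)) and m[idx]:
                owner = i
                break
        ves.cell_id = owner
        if owner is None:
            unassigned.append(ves)
        elif ves.enlarged:
            flags[owner] = True
    return flags, unassigned


def contingency_from_flags(
    flags_group1: Iterable[bool], flags_group2: Iterable[bool]
) -> ContingencyTable2x2:
    """Assemble group-wise flag counts as [[flagged, not], [flagged, not]]."""
    f1 = [bool(x) for x in flags_group1]
    f2 = [bool(x) for x in flags_group2]
    return ContingencyTable2x2(
        a=sum(f1), b=len(f1) - sum(f1), c=sum(f2), d=len(f2) - sum(f2)
    )


def assign_and_flag_cells(
    vesicles: Iterable[VesicleCall],
    cell_masks_by_group: Mapping[str, Mapping[int, np.ndarray]],
    voxel_size: Sequence[float],
) -> tuple[dict[str, dict[int, bool]], dict[tuple[str, str], ContingencyTable2x2]]:
    """Flag cells group-wise and build one 2×2 table per group pair."""
    vesicles = list(vesicles)
    flags_by_group: dict[str, dict[int, bool]] = {}
    for group, masks in cell_masks_by_group.items():
        flags, _ = flag_cells(vesicles, masks, voxel_size)
        flags_by_group[group] = flags
    groups = list(flags_by_group)
    tables = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            tables[(g1, g2)] = contingency_from_flags(
                flags_by_group[g1].values(), flags_by_group[g2].values()
            )
    return flags_by_group, tables


@dataclass
class BundleMeasure:
    """Length/width of a hair bundle's 2-D projection (µm)."""

    length_um: float
    width_um: float
    orientation_deg: float
    bundle_id: int = 0

    def __post_init__(self) -> None:
        if not self.length_um >= self.width_um > 0:
            raise ValueError(
                f"require length >= width > 0, got {self.length_um}, {self.width_um}"
            )


def measure_bundle(
    mask2d: np.ndarray,
    pixel_size: Sequence[float],
    bundle_id: int = 0,
) -> BundleMeasure:
    """Principal-axis length and mid-length width of one 2-D mask.

    Length is the extent of pixel centres projected onto the mask's
    second-moment principal axis (plus one pixel to account for pixel
    footprints); width is the perpendicular extent over a one-pixel slab
    around mid-length.  The mask must be a single connected component.
    """
    m = np.asarray(mask2d, bool)
    if m.ndim != 2 or not m.any():
        raise ValueError("mask must be a non-empty 2-D array")
    _, n = ndimage.label(m)
    if n > 1:
        raise ValueError(
            f"mask has {n} connected components; label and measure each bundle separately"
        )
    py, px = float(pixel_size[0]), float(pixel_size[1])
    yy, xx = np.nonzero(m)
    pts = np.column_stack(((yy + 0.5) * py, (xx + 0.5) * px))
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]  # unit vector (y, x) of the long axis
    perp = np.array([-axis[1], axis[0]])
    proj = centered @ axis
    pproj = centered @ perp
    pix = (abs(axis[0]) * py + abs(axis[1]) * px)  # pixel footprint along axis
    length = float(proj.max() - proj.min() + pix)
    mid = (proj.max() + proj.min()) / 2.0
    slab = np.abs(proj - mid) <= pix  # one-footprint slab around mid-length
    # centre extent plus the mean perpendicular spacing of projected centre
    # rows (pixel area / footprint): exact for axis-aligned rectangles and
    # robust to the jagged edges a rotated mask acquires on the pixel grid
    width = float(pproj[slab].max() - pproj[slab].min()) + py * px / pix
    orientation = math.degrees(math.atan2(axis[1], axis[0]))
    if width > length:
        length, width = width, length
        orientation += 90.0
    return BundleMeasure(length, width, orientation % 180.0, bundle_id)


def count_cells(
    labels: np.ndarray,
    pixel_size: Sequence[float],
    region_center_um: tuple[float, float] | None = None,
    region_size_um: tuple[float, float] = (50.0, 50.0),
) -> int:
    """Count labelled cells whose centroid falls inside a physical region.

    The region is a box (default 50 × 50 µm) centred on
    ``region_center_um`` (image centre when None).  A cell whose pixels
    overlap the region but whose centroid lies outside is not counted.
    """
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("labels must be a 2-D image")
    if (lab < 0).any():
        raise ValueError("labels must be non-negative integers")
    py, px = float(pixel_size[0]), float(pixel_size[1])
    h_um, w_um = lab.shape[0] * py, lab.shape[1] * px
    cy, cx = region_center_um if region_center_um is not None else (h_um / 2, w_um / 2)
    ry, rx = region_size_um
    lo = (cy - ry / 2.0, cx - rx / 2.0)
    hi = (cy + ry / 2.0, cx + rx / 2.0)
    if lo[0] < -1e-9 or lo[1] < -1e-9 or hi[0] > h_um + 1e-9 or hi[1] > w_um + 1e-9:
        raise ValueError(
            f"region [{lo} .. {hi}] µm lies outside the {h_um} x {w_um} µm image"
        )
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return 0
    centroids = ndimage.center_of_mass(lab > 0, lab, index=ids)
    count = 0
    for cen in centroids:
        y_um, x_um = (cen[0] + 0.5) * py, (cen[1] + 0.5) * px
        if lo[0] <= y_um < hi[0] and lo[1] <= x_um < hi[1]:
            count += 1
    return count


def vesicle_table(calls: Iterable[VesicleCall]) -> pd.DataFrame:
    """Vesicle calls as a tidy table (coordinates in µm)."""
    rows = [
        {
            "id": c.component_id,
            "z_um": c.centroid_um[0],
            "y_um": c.centroid_um[1],
            "x_um": c.centroid_um[2],
            "volume_um3": c.volume_um3,
            "eq_diam_um": c.equivalent_diameter_um,
            "enlarged": c.enlarged,
            "cell_id": c.cell_id,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "z_um", "y_um", "x_um", "volume_um3", "eq_diam_um", "enlarged", "cell_id",
        ],
    )
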