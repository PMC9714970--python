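"""Adaptive-threshold segmentation and fluorescence quantification.

Segmentation follows the local-mean convention: a voxel is foreground iff
its intensity exceeds the mean over a surrounding window of physical size
``window_um`` by more than a multiplicative offset, i.e.

    I(v) > local_mean(v) * (1 + offset_frac)

Windows are 2-D within each optical section by default (confocal data are
quantified slice-wise), switchable to full 3-D.  Quantification reports
voxel counts, sums and means over bounding boxes and masks, the
total/recruited decomposition used for sterol-stain imaging, and the
stereocilium-versus-basolateral compartment enrichment expressed both as
a within-channel percentage and as the cross-channel fold
("ratio of ratios": probe ratio ÷ reference-membrane-probe ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .stack import IntensitySummary, RoiBox, SegmentationMask, VolumeStack

__all__ = [
    "AdaptiveSegmenter",
    "segment_adaptive",
    "quantify_roi",
    "total_and_recruited",
    "compartment_enrichment",
    "fold_enrichment",
    "quantify_group_stacks",
    "split_mask_at_z",
    "estimate_fold_enrichment",
    "EnrichmentResult",
]


class AdaptiveSegmenter(BaseEstimator):
    """Local-mean adaptive thresholding of one stack channel.

    Parameters
    ----------
    window_um : float
        Physical edge length of the averaging window (µm). Must cover at
        least one voxel along every in-window axis.
    offset_frac : float
        Multiplicative offset; a voxel is kept iff its intensity exceeds
        ``local_mean * (1 + offset_frac)``. Larger values can only shrink
        the mask.
    mode : {"2d", "3d"}
        "2d" averages within each z-slice; "3d" uses a volumetric window.
    """

    def __init__(self, window_um: float = 5.0, offset_frac: float = 0.10, mode: str = "2d"):
        self.window_um = window_um
        self.offset_frac = offset_frac
        self.mode = mode

    def fit(self, X=None, y=None):  # stateless; present for API conformance
        return self

    def transform(self, stack: VolumeStack, channel: str | int = 0) -> SegmentationMask:
        if self.window_um <= 0:
            raise ValueError("window_um must be > 0")
        if self.offset_frac < 0:
            raise ValueError("offset_frac must be >= 0")
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        img = stack.channel(channel).astype(np.float64)
        dz, dy, dx = stack.voxel_size
        sizes = [
            max(int(round(self.window_um / v)), 0) for v in (dz, dy, dx)
        ]
        if self.mode == "2d":
            sizes[0] = 1
        if any(s < 1 for s in sizes):
            raise ValueError(
                f"window of {self.window_um} µm spans less than one voxel at "
                f"voxel size {stack.voxel_size} µm"
            )
        local_mean = ndimage.uniform_filter(img, size=sizes, mode="nearest")
        mask = img > local_mean * (1.0 + self.offset_frac)
        provenance = {
            "method": "adaptive_local_mean",
            "window_um": self.window_um,
            "offset_frac": self.offset_frac,
            "mode": self.mode,
            "window_voxels": sizes,
            "channel": stack.channel_names[stack.channel_index(channel)],
        }
        return SegmentationMask(mask, provenance)


def segment_adaptive(
    stack: VolumeStack,
    channel: str | int = 0,
    window_um: float = 5.0,
    offset_frac: float = 0.10,
    mode: str = "2d",
) -> SegmentationMask:
    """Functional wrapper over :class:`AdaptiveSegmenter`."""
    return AdaptiveSegmenter(window_um, offset_frac, mode).transform(stack, channel)


def quantify_roi(
    stack: VolumeStack,
    roi: RoiBox,
    mask: SegmentationMask | np.ndarray | None = None,
    channel: str | int | None = None,
) -> IntensitySummary:
    """Sum/mean of a channel over a bounding box, optionally ∩ a mask.

    A zero-voxel selection yields sum 0 and an explicitly undefined mean.
    """
    ch = channel if channel is not None else (roi.channel if roi.channel is not None else 0)
    img = stack.channel(ch)
    zs, ys, xs = roi.to_slices(stack.voxel_size, stack.shape)
    sub = img[zs, ys, xs]
    if mask is not None:
        m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
        if m.shape != stack.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match stack shape {stack.shape}"
            )
        msub = m[zs, ys, xs]
    else:
        msub = np.ones(sub.shape, dtype=bool)
    per_slice = np.array(
        [float(sub[k][msub[k]].sum()) for k in range(sub.shape[0])]
    )
    return IntensitySummary.from_values(sub[msub], per_slice)


class TotalRecruited(NamedTuple):
    total_sum: float
    recruited_mean: float
    recruited_defined: bool


def total_and_recruited(
    stack: VolumeStack,
    signal_channel: str | int,
    marker_channel: str | int | None = None,
    marker_mask: SegmentationMask | np.ndarray | None = None,
    segmenter: AdaptiveSegmenter | None = None,
) -> TotalRecruited:
    """Whole-field signal sum plus mean signal within the marker mask.

    "Total" is the sum of every voxel of the signal channel; "recruited"
    is the mean of the signal channel restricted to marker-positive
    voxels.  The marker mask is either supplied directly or derived from
    ``marker_channel`` by adaptive thresholding.
    """
    signal = stack.channel(signal_channel).astype(np.float64)
    if marker_mask is None:
        if marker_channel is None:
            raise ValueError("provide marker_mask or marker_channel")
        seg = segmenter or AdaptiveSegmenter()
        marker_mask = seg.transform(stack, marker_channel)
    m = (
        marker_mask.mask
        if isinstance(marker_mask, SegmentationMask)
        else np.asarray(marker_mask, bool)
    )
    if m.shape != stack.shape:
        raise ValueError(f"marker mask shape {m.shape} != stack shape {stack.shape}")
    total = float(signal.sum())
    n = int(m.sum())
    if n == 0:
        return TotalRecruited(total, float("nan"), False)
    return TotalRecruited(total, float(signal[m].mean()), True)


@dataclass
class EnrichmentResult:
    """Compartment morphometry and fluorescence enrichment of two channels.

    ``ratio_pct[channel]`` is 100 × (stereocilium mean / basolateral mean)
    within that channel; ``ratio_of_ratios`` is the probe channel's ratio
    divided by the reference channel's ratio (fold units).
    """

    volumes_um3: dict[str, float]
    means: dict[str, dict[str, float]]  # channel -> compartment -> mean
    ratio_pct: dict[str, float]
    probe_channel: str
    reference_channel: str
    ratio_of_ratios: float


def fold_enrichment(probe_ratio_pct: float, reference_ratio_pct: float) -> float:
    """Cross-channel fold: probe percentage ÷ reference percentage."""
    if reference_ratio_pct <= 0:
        raise ValueError("reference ratio must be > 0")
    return probe_ratio_pct / reference_ratio_pct


def compartment_enrichment(
    stack: VolumeStack,
    stereocilia_mask: SegmentationMask | np.ndarray,
    basolateral_mask: SegmentationMask | np.ndarray,
    channels: tuple[str | int, str | int] = (1, 0),
) -> EnrichmentResult:
    """Stereocilium-vs-basolateral enrichment of a probe against a reference.

    ``channels`` is ``(probe, reference)``.  Masks must be non-empty and
    disjoint.
    """
    sm = (
        stereocilia_mask.mask
        if isinstance(stereocilia_mask, SegmentationMask)
        else np.asarray(stereocilia_mask, bool)
    )
    bm = (
        basolateral_mask.mask
        if isinstance(basolateral_mask, SegmentationMask)
        else np.asarray(basolateral_mask, bool)
    )
    if sm.shape != stack.shape or bm.shape != stack.shape:
        raise ValueError("masks must match the stack's spatial shape")
    if not sm.any() or not bm.any():
        raise ValueError("compartment masks must be non-empty")
    if (sm & bm).any():
        raise ValueError("stereocilia and basolateral masks overlap")

    vol = stack.voxel_volume_um3
    volumes = {
        "stereocilia": float(sm.sum()) * vol,
        "basolateral": float(bm.sum()) * vol,
    }
    probe, ref = channels
    names = [
        stack.channel_names[stack.channel_index(c)] for c in (probe, ref)
    ]
    means: dict[str, dict[str, float]] = {}
    ratio_pct: dict[str, float] = {}
    for c, name in zip((probe, ref), names):
        img = stack.channel(c).astype(np.float64)
        s_mean = float(img[sm].mean())
        b_mean = float(img[bm].mean())
        if b_mean <= 0:
            raise ValueError(f"channel {name!r}: basolateral mean is not positive")
        means[name] = {"stereocilia": s_mean, "basolateral": b_mean}
        ratio_pct[name] = 100.0 * s_mean / b_mean
    rr = fold_enrichment(ratio_pct[names[0]], ratio_pct[names[1]])
    return EnrichmentResult(
        volumes_um3=volumes,
        means=means,
        ratio_pct=ratio_pct,
        probe_channel=names[0],
        reference_channel=names[1],
        ratio_of_ratios=rr,
    )


def split_mask_at_z(
    mask: SegmentationMask | np.ndarray,
    z_um: float,
    voxel_size: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask at a z-plane: (above/apical part, below part).

    Voxels whose centre lies at z < ``z_um`` go to the first (apical)
    mask.  In the phantom geometry stereocilia sit above the cell apex,
    so splitting the segmentation at the apex plane separates the bundle
    from the basolateral membrane.
    """
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    zc = (np.arange(m.shape[0]) + 0.5) * voxel_size[0]
    above = m & (zc < z_um)[:, None, None]
    below = m & ~(zc < z_um)[:, None, None]
    return above, below


def estimate_fold_enrichment(
    stack: VolumeStack,
    apex_z_um: float,
    probe: str | int = 1,
    reference: str | int = 0,
    segmenter: AdaptiveSegmenter | None = None,
) -> EnrichmentResult:
    """Full pipeline: segment the reference channel, split at the apex
    plane into stereocilium/basolateral compartments, and measure the
    cross-channel fold enrichment."""
    seg = segmenter or AdaptiveSegmenter()
    mask = seg.transform(stack, reference)
    stereo, baso = split_mask_at_z(mask, apex_z_um, stack.voxel_size)
    return compartment_enrichment(stack, stereo, baso, channels=(probe, reference))


def quantify_group_stacks(
    stacks: Iterable[tuple[str, str, VolumeStack]],
    roi: RoiBox | None,
    channel: str | int,
    segmenter: AdaptiveSegmenter | None = None,
    auto_center_channel: str | int | None = None,
    roi_extent_um: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Batch quantification: one row per stack (sample_id, group, channel,
    voxel_count, sum, mean), in input order.

    The ROI is either a fixed :class:`RoiBox` applied to every stack, or
    auto-centred per stack on the intensity centroid of
    ``auto_center_channel`` with extent ``roi_extent_um``.  An empty batch
    yields an empty table.
    """
    rows = []
    for sample_id, group, stack in stacks:
        try:
            ch_name = stack.channel_names[stack.channel_index(channel)]
        except KeyError:
            raise KeyError(
                f"stack {sample_id!r}: channel {channel!r} not present "
                f"(has {list(stack.channel_names)})"
            ) from None
        if roi is not None:
            box = roi
        elif auto_center_channel is not None and roi_extent_um is not None:
            box = _auto_centered_roi(stack, auto_center_channel, roi_extent_um)
        else:
            extents = tuple(n * v for n, v in zip(stack.shape, stack.voxel_size))
            box = RoiBox((0.0, 0.0, 0.0), extents)
        mask = segmenter.transform(stack, channel) if segmenter is not None else None
        summary = quantify_roi(stack, box, mask=mask, channel=channel)
        rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "channel": ch_name,
                "voxel_count": summary.voxel_count,
                "sum": summary.sum,
                "mean": summary.mean,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "channel", "voxel_count", "sum", "mean"]
    )


def _auto_centered_roi(
    stack: VolumeStack,
    channel: str | int,
    extent_um: tuple[float, float, float],
) -> RoiBox:
    """Box of the given extent centred on the channel's intensity centroid,
    clipped to remain inside the stack."""
    img = stack.channel(channel).astype(np.float64)
    total = img.sum()
    if total <= 0:
        centroid = [n / 2.0 * v for n, v in zip(stack.shape, stack.voxel_size)]
    else:
        idx = ndimage.center_of_mass(img)
        centroid = [(c + 0.5) * v for c, v in zip(idx, stack.voxel_size)]
    origin = []
    for c, e, n, v in zip(centroid, extent_um, stack.shape, stack.voxel_size):
        o = min(max(c - e / 2.0, 0.0), max(n * v - e, 0.0))
        origin.append(o)
    return RoiBox(tuple(origin), tuple(extent_um), channel=channel)
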