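"""Tongue extraction and region partitioning.

The tongue mask is found by a chromaticity rule — tongue tissue is strongly
red-dominant, so pixels whose Lab a* exceeds a threshold are foreground —
followed by largest-connected-component selection and hole filling. The mask
is then split into the four regions of the extended ratio-based partition
(edge, posterior, middle, apex): the posterior band is the top fraction of
the mask's bounding box, the apex band the bottom fraction, and within the
remaining rows the outermost fraction of each row's tongue run on both sides
is the edge, the rest the middle. Images are assumed upright: tongue root at
the top of the frame, apex at the bottom.

Region labels are small integers (see ``REGION_LABELS``); 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import measure

from .colorimetry import LabColor, rgb_to_lab

__all__ = [
    "REGION_LABELS",
    "REGION_NAMES",
    "PartitionRatios",
    "SegmentationConfig",
    "RegionPartition",
    "SegmentationError",
    "DegeneratePartitionError",
    "segment_tongue",
    "partition_regions",
    "region_mean_lab",
]

#: region name -> integer label in partition arrays (0 = background)
REGION_LABELS: dict[str, int] = {"edge": 1, "posterior": 2, "middle": 3, "apex": 4}
REGION_NAMES: dict[int, str] = {v: k for k, v in REGION_LABELS.items()}


class SegmentationError(ValueError):
    """No tongue foreground could be found."""


class DegeneratePartitionError(ValueError):
    """Mask too small to populate all four regions."""


@dataclass(frozen=True)
class PartitionRatios:
    """Ratio parameters of the four-region partition.

    edge_band_fraction: fraction of each row's half-run assigned to the
    lateral edge band (each side). posterior_fraction / apex_fraction:
    fractions of the mask bounding-box height forming the top (posterior)
    and bottom (apex) bands. The central remainder is the middle. The
    division ratios of the underlying method are published only as a
    drawing, so these defaults are provisional and every report should
    carry the ratios actually used.
    """

    edge_band_fraction: float = 0.15
    posterior_fraction: float = 0.20
    apex_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("edge_band_fraction", "posterior_fraction", "apex_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.posterior_fraction + self.apex_fraction >= 1.0:
            raise ValueError("posterior_fraction + apex_fraction must be < 1")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for the chromaticity-based tongue finder.

    a_star_threshold: minimum Lab a* for a pixel to count as tongue tissue
    (red dominance; neutral backgrounds sit near 0, tongue tissue near
    20-35). min_lightness rejects near-black pixels that can acquire spurious
    chromaticity.
    """

    a_star_threshold: float = 12.0
    min_lightness: float = 5.0
    white_point: str = "D65"


@dataclass(frozen=True)
class RegionPartition:
    """Label map over an image: 0 background, 1-4 the four tongue regions."""

    labels: np.ndarray
    ratios: PartitionRatios

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGION_LABELS:
            raise KeyError(f"unknown region {region!r}; one of {sorted(REGION_LABELS)}")
        return self.labels == REGION_LABELS[region]

    def region_sizes(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == lab))
            for name, lab in REGION_LABELS.items()
        }


def segment_tongue(
    image: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> np.ndarray:
    """Extract a boolean tongue mask from an RGB image.

    Pixels with Lab a* above the configured threshold (and lightness above
    the floor) are foreground; the largest 8-connected component is kept and
    its holes filled. Deterministic for a fixed image and config.

    Raises ``SegmentationError`` if no pixel passes the criterion.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("image must be an array of shape (H, W, 3)")
    lab = rgb_to_lab(img, white_point=config.white_point)
    fg = (lab[..., 1] > config.a_star_threshold) & (lab[..., 0] > config.min_lightness)
    if not fg.any():
        raise SegmentationError("no tongue found: no pixel passes the chromaticity criterion")
    comp = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(comp == largest)
    return mask


def partition_regions(
    mask: np.ndarray, ratios: PartitionRatios = PartitionRatios()
) -> RegionPartition:
    """Partition a tongue mask into edge / posterior / middle / apex.

    Every mask pixel receives exactly one region label; background stays 0.
    Raises ``DegeneratePartitionError`` if the mask is empty or too small for
    all four regions to be non-empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D boolean array")
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise DegeneratePartitionError("empty mask")
    top, bottom = int(rows[0]), int(rows[-1])
    height = bottom - top + 1

    n_post = int(round(ratios.posterior_fraction * height))
    n_apex = int(round(ratios.apex_fraction * height))
    post_end = top + n_post            # rows [top, post_end) are posterior
    apex_start = bottom + 1 - n_apex   # rows [apex_start, bottom] are apex

    labels = np.zeros(mask.shape, dtype=np.uint8)
    for r in range(top, bottom + 1):
        cols = np.flatnonzero(mask[r])
        if cols.size == 0:
            continue
        if r < post_end:
            labels[r, cols] = REGION_LABELS["posterior"]
        elif r >= apex_start:
            labels[r, cols] = REGION_LABELS["apex"]
        else:
            # per-row edge band: outermost fraction of this row's run, each side
            n_edge = int(round(ratios.edge_band_fraction * cols.size))
            labels[r, cols] = REGION_LABELS["middle"]
            if n_edge > 0:
                labels[r, cols[:n_edge]] = REGION_LABELS["edge"]
                labels[r, cols[-n_edge:]] = REGION_LABELS["edge"]

    part = RegionPartition(labels=labels, ratios=ratios)
    sizes = part.region_sizes()
    empty = [name for name, n in sizes.items() if n == 0]
    if empty:
        raise DegeneratePartitionError(
            f"mask too small: region(s) {empty} received no pixels"
        )
    return part


def region_mean_lab(
    image: np.ndarray,
    partition: RegionPartition,
    region: str,
    white_point: str = "D65",
    statistic: str = "mean",
) -> LabColor:
    """Mean (or median) Lab color over one region's pixels.

    Each region pixel is converted to Lab individually and the channel-wise
    arithmetic mean is returned; ``statistic="median"`` gives the channel-wise
    median instead.
    """
    sel = partition.region_mask(region)
    if not sel.any():
        raise ValueError(f"region {region!r} is empty")
    img = np.asarray(image, dtype=float)
    lab = rgb_to_lab(img[sel], white_point=white_point)
    if statistic == "mean":
        out = lab.mean(axis=0)
    elif statistic == "median":
        out = np.median(lab, axis=0)
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    return LabColor(*out)
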