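"""Shared container types for the segmentation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SLOW = "slow"
FAST = "fast"

#: Columns of the per-fiber table produced by :func:`myonet.segmentation.extract_fibers`.
FIBER_COLUMNS = (
    "id", "x", "y", "area_A2", "major", "minor", "angle",
    "convexity", "eccentricity", "type", "border_flag", "mean_red",
)


@dataclass
class BiopsyImage:
    """An RGB biopsy image with an optional rectangular region of interest.

    ``rgb`` is a (H, W, 3) array; ``roi`` is (row0, row1, col0, col1) in
    half-open pixel coordinates, or None for the full frame.
    """

    rgb: np.ndarray
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
        self.rgb = rgb

    def cropped(self) -> np.ndarray:
        if self.roi is None:
            return self.rgb
        r0, r1, c0, c1 = self.roi
        return self.rgb[r0:r1, c0:c1]

    def channel(self, tag: str) -> np.ndarray:
        """Return one channel ('R', 'G' or 'B') of the ROI as float64."""
        idx = {"R": 0, "G": 1, "B": 2}[tag]
        return self.cropped()[..., idx].astype(np.float64)


@dataclass
class MarkerSet:
    """Internal (fiber seed) and external (background mosaic) watershed markers."""

    internal: np.ndarray  # bool grid, one connected component per fiber candidate
    external: np.ndarray  # bool grid, ridge lines between candidates

    def __post_init__(self) -> None:
        if self.internal.shape != self.external.shape:
            raise ValueError("internal/external marker shape mismatch")
        if np.any(self.internal & self.external):
            raise ValueError("internal and external markers must be disjoint")


@dataclass
class LabelMap:
    """Integer label grid: 0 = boundary/collagen, k >= 1 = fiber k."""

    labels: np.ndarray
    border_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def compute_border_labels(self) -> frozenset[int]:
        lab = self.labels
        edge = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        return frozenset(int(v) for v in np.unique(edge) if v > 0)
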