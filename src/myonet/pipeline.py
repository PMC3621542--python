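"""End-to-end orchestration: image -> segmentation -> network -> features."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from myonet.core import BiopsyImage, LabelMap
from myonet.features import FeatureVector, feature_table, feature_vector
from myonet.network import build_network, expand_fibers
from myonet.segmentation import DEFAULT_MIN_MARKER_AREA, segment_image

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All per-image pipeline parameters, JSON round-trippable."""

    h_override: float | None = None
    min_marker_area: int = DEFAULT_MIN_MARKER_AREA
    typing: str | float = "auto"
    min_contact_px: int = 1
    roi: tuple[int, int, int, int] | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if d.get("roi") is not None:
            d["roi"] = tuple(d["roi"])
        return cls(**d)


@dataclass
class ImageResult:
    image_id: str
    label_map: LabelMap
    fibers: pd.DataFrame
    network: "object"
    a1: dict[int, int]
    features: FeatureVector


def analyze_image(image: BiopsyImage | np.ndarray,
                  config: PipelineConfig | None = None,
                  image_id: str = "") -> ImageResult:
    """Run segmentation, network construction and feature extraction."""
    config = config or PipelineConfig()
    if not isinstance(image, BiopsyImage):
        image = BiopsyImage(rgb=np.asarray(image))
    if config.roi is not None and image.roi is None:
        image = BiopsyImage(rgb=image.rgb, roi=config.roi)
    lmap, fibers = segment_image(
        image, min_marker_area=config.min_marker_area,
        h_override=config.h_override, typing=config.typing)
    mosaic, a1 = expand_fibers(lmap)
    net = build_network(mosaic, fibers, a1,
                        min_contact_px=config.min_contact_px)
    fv = feature_vector(fibers, net, a1, image_id=image_id)
    return ImageResult(image_id=image_id, label_map=lmap, fibers=fibers,
                       network=net, a1=a1, features=fv)


def analyze_cohort(images: list[tuple[str, BiopsyImage]],
                   config: PipelineConfig | None = None,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Analyze many images; failures are logged and skipped.

    ``images`` pairs each image id with a BiopsyImage or with a callable
    returning one (lazy loading, so unreadable files are skipped too).
    Returns the feature table (one row per successful image) and the list
    of skipped image ids.
    """
    vectors, skipped = [], []
    for image_id, img in images:
        try:
            if callable(img):
                img = img()
            res = analyze_image(img, config, image_id=image_id)
            vectors.append(res.features)
        except Exception as exc:  # per-image failures must not kill the run
            logger.warning("skipping %s: %s", image_id, exc)
            skipped.append(image_id)
    table = feature_table(vectors) if vectors else pd.DataFrame()
    return table, skipped


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """(n_images, 82) float matrix from a feature table (NaN = undefined)."""
    cols = [f"f{i:02d}" for i in range(1, 83)]
    return table[cols].to_numpy(dtype=float)


def save_result(res: ImageResult, outdir: str | Path) -> None:
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = res.image_id or "image"
    tifffile.imwrite(outdir / f"{stem}_labels.tif",
                     res.label_map.labels.astype(np.uint16))
    res.fibers.to_csv(outdir / f"{stem}_fibers.csv", index=False)
    from myonet.network import write_network
    write_network(res.network, outdir / f"{stem}_edges.csv",
                  outdir / f"{stem}_nodes.csv")
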