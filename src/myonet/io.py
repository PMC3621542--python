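"""Standard-format readers/writers for images, manifests and tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread

from myonet.core import BiopsyImage


def read_image(path: str | Path,
               roi: tuple[int, int, int, int] | None = None) -> BiopsyImage:
    """Read an 8/16-bit RGB TIFF or PNG as a BiopsyImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path} is not an RGB image (shape {arr.shape})")
    return BiopsyImage(rgb=arr, roi=roi)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns path, label, severity_param, seed).

    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    df["path"] = [str(p if Path(p).is_absolute() else base / Path(p).name)
                  if not Path(p).exists() else str(p)
                  for p in df["path"]]
    return df


def load_cohort_images(manifest: pd.DataFrame) -> list:
    """Pairs of (image id, lazy loader); decoding errors surface per image
    during analysis, not while building the list."""
    return [(Path(p).stem, (lambda q=p: read_image(q)))
            for p in manifest["path"]]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
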