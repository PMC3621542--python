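"""Synthetic muscle-biopsy image generator with full ground truth.

A transverse section of healthy skeletal muscle is a mosaic of polygonal,
roughly equal-sized fibers separated by a thin endomysial collagen mesh.
The generator emulates this with a Voronoi tessellation of a jittered
hexagonal lattice and renders the three stain channels used by the
analysis pipeline: collagen VI in green, slow (type I) myosin in red,
fast (type II) fibers dark.

Pathological phenotypes are reached through four dials:

* ``fibrosis`` — half-width (px) of the collagen band around every fiber
  (endomysial collagen proliferation, the dystrophic hallmark);
* ``size_cv`` — lattice jitter driving fiber-size heterogeneity;
* ``roundness`` — morphological corner-rounding of fibers (rounded
  atrophic fibers of dystrophies);
* ``grouping`` — spatial correlation of the fiber-type mosaic (fiber-type
  grouping after reinnervation, the neurogenic hallmark).

Every image carries a :class:`GroundTruth` (fiber label map, types,
adjacency, and a scalar ``severity_param``) so each downstream stage can
be validated without clinical material.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imwrite
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from myonet.core import BiopsyImage, FAST, SLOW

# Stain rendering levels (8-bit), chosen with a wide margin so that the
# fiber-typing threshold and the G-channel valley search are unambiguous.
COLLAGEN_GREEN = 200
FIBER_GREEN = 20
SLOW_RED = 200
FAST_RED = 30
COLLAGEN_RED = 20
BASE_BLUE = 10

#: Reference scale used to min-max normalize ``fibrosis`` into [0, 1] for
#: ``severity_param`` (band half-widths used anywhere in the package stay
#: well below 10 px at the default frame size).
FIBROSIS_REF_MAX = 10.0

_CROSS = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic biopsy image."""

    width: int = 320
    height: int = 320
    n_fibers: int = 49
    fibrosis: float = 2.0
    size_cv: float = 0.15
    roundness: float = 0.1
    slow_fraction: float = 0.4
    grouping: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibers < 4:
            raise ValueError("n_fibers must be >= 4")
        for name in ("size_cv", "roundness", "slow_fraction", "grouping"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fibrosis < 0:
            raise ValueError("fibrosis must be >= 0")
        if self.fibrosis >= min(self.width, self.height) / 10:
            raise ValueError(
                f"fibrosis={self.fibrosis} too large for a "
                f"{self.width}x{self.height} frame"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def severity_param(self) -> float:
        """Scalar pathology load in [0, 1]: mean of the normalized
        (fibrosis, size_cv, roundness) dials."""
        f = min(self.fibrosis / FIBROSIS_REF_MAX, 1.0)
        return float(np.mean([f, self.size_cv, self.roundness]))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """Per-image ground truth: fiber label map, cell map, types, adjacency."""

    label_map: np.ndarray                     # 0 = collagen, k >= 1 = fiber k
    cell_map: np.ndarray                      # full Voronoi partition, k >= 1
    types: dict[int, str]                     # fiber id -> slow | fast
    adjacency: set[tuple[int, int]]           # unordered (i < j) cell contacts
    severity_param: float
    border_ids: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_fibers(self) -> int:
        return len(self.types)

    def fiber_areas(self) -> dict[int, int]:
        counts = np.bincount(self.label_map.ravel())
        return {k: int(counts[k]) for k in self.types if k < len(counts)}


class DegenerateTessellationError(ValueError):
    pass


def _hex_seeds(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice seeds, (n_fibers, 2) as (x, y)."""
    aspect = spec.width / spec.height
    cols = max(2, int(round(np.sqrt(spec.n_fibers * aspect))))
    rows = int(np.ceil(spec.n_fibers / cols))
    sx = spec.width / cols
    sy = spec.height / rows
    pts = []
    for r in range(rows):
        for c in range(cols):
            x = (c + 0.25 + 0.5 * (r % 2)) * sx
            y = (r + 0.5) * sy
            pts.append((x, y))
    pts = np.asarray(pts[: spec.n_fibers], dtype=float)
    jitter_amp = spec.size_cv * 0.5 * min(sx, sy)
    pts += rng.uniform(-jitter_amp, jitter_amp, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 1.0, spec.width - 2.0)
    pts[:, 1] = np.clip(pts[:, 1], 1.0, spec.height - 2.0)
    return pts


def _voronoi_labels(seeds: np.ndarray, width: int, height: int) -> np.ndarray:
    """Rasterized nearest-seed partition, labels 1..n."""
    yy, xx = np.mgrid[0:height, 0:width]
    pix = np.column_stack([xx.ravel() + 0.0, yy.ravel() + 0.0])
    _, idx = cKDTree(seeds).query(pix)
    return (idx + 1).astype(np.int32).reshape(height, width)


def _cell_adjacency(cells: np.ndarray) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for a, b in ((cells[:, :-1], cells[:, 1:]), (cells[:-1, :], cells[1:, :])):
        diff = a != b
        for i, j in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((int(min(i, j)), int(max(i, j))))
    return pairs


def _assign_types(spec: SyntheticSpec, seeds: np.ndarray,
                  rng: np.random.Generator) -> dict[int, str]:
    """Fiber typing: blend of iid noise and a smooth spatial field.

    ``grouping=0`` gives a random mosaic; ``grouping=1`` thresholds a
    low-frequency random field, producing contiguous same-type patches.
    The slow count is fixed at round(slow_fraction * n) in both regimes.
    """
    n = len(seeds)
    u = rng.uniform(size=n)
    scale = min(spec.width, spec.height)
    fld = np.zeros(n)
    # Wavelengths span several fiber diameters so that thresholding the
    # field yields patches of contiguous same-type fibers, not stripes of
    # single-fiber width.
    for _ in range(2):
        theta = rng.uniform(0, 2 * np.pi)
        lam = rng.uniform(1.0, 2.0) * scale
        phase = rng.uniform(0, 2 * np.pi)
        proj = seeds[:, 0] * np.cos(theta) + seeds[:, 1] * np.sin(theta)
        fld += np.cos(2 * np.pi * proj / lam + phase)
    rank = np.empty(n)
    rank[np.argsort(fld, kind="stable")] = np.arange(n)
    rf = rank / max(n - 1, 1)
    value = (1.0 - spec.grouping) * u + spec.grouping * rf
    n_slow = int(round(spec.slow_fraction * n))
    order = np.argsort(value, kind="stable")
    types = {k + 1: FAST for k in range(n)}
    for k in order[:n_slow]:
        types[int(k) + 1] = SLOW
    return types


def _carve_fibers(cells: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Erode each Voronoi cell by ``fibrosis`` px and round its corners.

    Corner rounding is a morphological opening with a disk whose radius is
    ``roundness`` times half the erosion margin left in the cell.
    """
    h, w = cells.shape
    base = np.zeros((h, w), dtype=bool)          # one-sided 1-px cell boundary
    base[:, 1:] |= cells[:, :-1] != cells[:, 1:]
    base[1:, :] |= cells[:-1, :] != cells[1:, :]

    label_map = np.zeros((h, w), dtype=np.int32)
    objects = ndi.find_objects(cells)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, h)
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, w)
        cell = cells[r0:r1, c0:c1] == k
        dist = ndi.distance_transform_edt(cell)
        max_d = dist.max()
        if max_d <= spec.fibrosis:
            raise DegenerateTessellationError(
                f"fiber {k} vanishes after erosion: fibrosis={spec.fibrosis}, "
                f"n_fibers={spec.n_fibers}, frame {spec.width}x{spec.height}"
            )
        mask = dist > spec.fibrosis
        r = spec.roundness * 0.5 * (max_d - spec.fibrosis)
        if r >= 1.0:
            inner = ndi.distance_transform_edt(mask) > r
            if inner.any():
                mask = ndi.distance_transform_edt(~inner) <= r
        mask &= ~base[r0:r1, c0:c1]
        if not mask.any():
            raise DegenerateTessellationError(
                f"fiber {k} vanishes after rounding: fibrosis={spec.fibrosis}, "
                f"roundness={spec.roundness}"
            )
        label_map[r0:r1, c0:c1][mask] = k
    return label_map


def _render(label_map: np.ndarray, types: dict[int, str], spec: SyntheticSpec,
            rng: np.random.Generator) -> np.ndarray:
    h, w = label_map.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    collagen = label_map == 0
    img[..., 0] = COLLAGEN_RED
    img[..., 1] = np.where(collagen, COLLAGEN_GREEN, FIBER_GREEN)
    img[..., 2] = BASE_BLUE
    red = np.full(max(label_map.max() + 1, 1), float(COLLAGEN_RED))
    for k, t in types.items():
        red[k] = SLOW_RED if t == SLOW else FAST_RED
    img[..., 0] = red[label_map]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_biopsy(spec: SyntheticSpec) -> tuple[BiopsyImage, GroundTruth]:
    """Generate one synthetic biopsy image and its ground truth.

    Deterministic given ``spec.seed``: the same spec always yields a
    bit-identical image and ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seeds = _hex_seeds(spec, rng)
    cells = _voronoi_labels(seeds, spec.width, spec.height)
    adjacency = _cell_adjacency(cells)
    types = _assign_types(spec, seeds, rng)
    label_map = _carve_fibers(cells, spec)
    img = _render(label_map, types, spec, rng)
    edge = np.concatenate([cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]])
    border = frozenset(int(v) for v in np.unique(edge))
    truth = GroundTruth(
        label_map=label_map,
        cell_map=cells,
        types=types,
        adjacency=adjacency,
        severity_param=spec.severity_param,
        border_ids=border,
    )
    return BiopsyImage(rgb=img), truth


# ---------------------------------------------------------------------------
# Cohorts

def make_spec(phenotype: str, severity: float = 0.0, *, seed: int = 0,
              **overrides) -> SyntheticSpec:
    """Build a spec for a named phenotype at a given severity in [0, 1].

    ``control`` ignores severity; ``md`` (dystrophic) ramps fibrosis,
    size heterogeneity and rounding; ``na`` (neurogenic) ramps fiber-type
    grouping with grouped atrophy.
    """
    if phenotype == "control":
        base = dict(fibrosis=2.0, size_cv=0.12, roundness=0.05, grouping=0.0)
    elif phenotype == "md":
        base = dict(
            fibrosis=1.5 + 6.5 * severity,
            size_cv=min(0.10 + 0.70 * severity, 1.0),
            roundness=min(0.10 + 0.80 * severity, 1.0),
            grouping=0.0,
        )
    elif phenotype == "na":
        # grouping-dominated: geometric dials stay near control levels so
        # that control-vs-NA discrimination rests on fiber-type topology
        base = dict(
            fibrosis=2.0 + 0.5 * severity,
            size_cv=min(0.12 + 0.18 * severity, 1.0),
            roundness=min(0.05 + 0.15 * severity, 1.0),
            grouping=min(0.3 + 0.7 * severity, 1.0),
        )
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    base.update(overrides)
    return SyntheticSpec(seed=seed, **base)


def generate_cohort(specs: list[SyntheticSpec], labels: list[str],
                    outdir: str | Path, names: list[str] | None = None,
                    ) -> pd.DataFrame:
    """Write a cohort of images plus ground truth and return the manifest.

    The manifest (also written to ``outdir/manifest.csv``) has columns
    path, label, severity_param, seed. Ground truth for image ``x.png``
    is stored as ``x_truth.tif`` (16-bit label map) and ``x_truth.json``
    (types, adjacency, border ids).
    """
    if len(specs) != len(labels):
        raise ValueError("specs and labels must have equal length")
    allowed = {"control", "MD", "NA"}
    bad = set(labels) - allowed
    if bad:
        raise ValueError(f"labels must be in {allowed}, got {bad}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if names is None:
        names = [f"img_{i:03d}_{lab}" for i, (lab) in enumerate(labels)]
    if len(set(names)) != len(names):
        raise ValueError("duplicate output paths in cohort")

    rows = []
    for spec, label, name in zip(specs, labels, names):
        img, truth = generate_biopsy(spec)
        path = outdir / f"{name}.png"
        imwrite(path, img.rgb)
        tifffile.imwrite(outdir / f"{name}_truth.tif",
                         truth.label_map.astype(np.uint16))
        meta = {
            "types": {str(k): v for k, v in truth.types.items()},
            "adjacency": sorted(list(p) for p in truth.adjacency),
            "border_ids": sorted(truth.border_ids),
            "severity_param": truth.severity_param,
            "spec": dataclasses.asdict(spec),
        }
        (outdir / f"{name}_truth.json").write_text(json.dumps(meta))
        rows.append({
            "path": str(path),
            "label": label,
            "severity_param": spec.severity_param,
            "seed": spec.seed,
        })
    manifest = pd.DataFrame(rows, columns=["path", "label", "severity_param", "seed"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_truth(image_path: str | Path) -> GroundTruth:
    """Reload the ground truth written next to a cohort image."""
    p = Path(image_path)
    stem = p.with_suffix("")
    label_map = tifffile.imread(f"{stem}_truth.tif").astype(np.int32)
    meta = json.loads(Path(f"{stem}_truth.json").read_text())
    return GroundTruth(
        label_map=label_map,
        cell_map=label_map,  # cell partition is not round-tripped
        types={int(k): v for k, v in meta["types"].items()},
        adjacency={(int(a), int(b)) for a, b in meta["adjacency"]},
        severity_param=float(meta["severity_param"]),
        border_ids=frozenset(int(v) for v in meta["border_ids"]),
    )
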