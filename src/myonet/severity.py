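"""Severity scoring: PCA projection and distance to the control centroid.

The selected features of every training image are z-scored and projected
onto 2 or 3 principal components; the control images' mean projection is
the control centroid. An image's severity score is the Euclidean
distance of its projection from that centroid, which is correlated
(Pearson) against pathologist grades 1-4 when available. Classification
of new images runs one Fuzzy-ARTMAP per comparison (triple
control/MD/NA, pairwise control-vs-MD and control-vs-NA), mirroring the
diagnostic workflow of pairwise confirmation after a triple screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.decomposition import PCA

from myonet.artmap import ARTMAPParams, FuzzyARTMAP

CONTROL_LABEL = "control"


@dataclass
class SeverityModel:
    """Selected features, standardization, PCA basis and control centroid."""

    selected: list[int]               # 0-based column indices into the table
    mean_: np.ndarray
    sd_: np.ndarray
    components_: np.ndarray | None    # (n_components, n_selected); None = identity
    explained_variance_ratio_: np.ndarray
    centroid: np.ndarray
    artmap: FuzzyARTMAP | None = None
    pathological_distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_components(self) -> int:
        return len(self.centroid)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.selected]
        if np.isnan(X).any():
            raise ValueError("missing selected features in input")
        Z = (X - self.mean_) / self.sd_
        if self.components_ is None:
            return Z
        return Z @ self.components_.T


def fit_severity(X: np.ndarray, labels, selected: list[int],
                 n_components: int | None = None,
                 params: ARTMAPParams | None = None,
                 fit_on: str = "all", standardize: bool = True) -> SeverityModel:
    """Fit standardization + PCA + control centroid (+ ARTMAP) on training data.

    ``selected`` holds 0-based feature columns. ``n_components`` defaults
    to 3 when at least 4 features are selected, else 2; when the selected
    set is no larger than the component count the standardized features
    are used unprojected. ``fit_on`` chooses whether the PCA basis is fit
    on all training images (default) or on controls only.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 classes")
    control = labels == CONTROL_LABEL
    if control.sum() < 3:
        raise ValueError("need at least 3 control images")
    if not selected:
        raise ValueError("empty selected feature set")
    if n_components is None:
        n_components = 3 if len(selected) >= 4 else 2

    Xs = X[:, selected]
    if standardize:
        mean = Xs.mean(axis=0)
        sd = Xs.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean = np.zeros(Xs.shape[1])
        sd = np.ones(Xs.shape[1])
    Z = (Xs - mean) / sd

    if len(selected) <= n_components:
        components = None
        evr = np.ones(0)
        proj = Z
    else:
        basis_rows = Z if fit_on == "all" else Z[control]
        pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
        pca.fit(basis_rows)
        components = pca.components_
        evr = pca.explained_variance_ratio_
        proj = Z @ components.T

    centroid = proj[control].mean(axis=0)
    artmap = FuzzyARTMAP(params).fit(Xs, labels)
    path_d = np.linalg.norm(proj[~control] - centroid, axis=1)
    return SeverityModel(selected=list(selected), mean_=mean, sd_=sd,
                         components_=components,
                         explained_variance_ratio_=np.asarray(evr),
                         centroid=centroid, artmap=artmap,
                         pathological_distances=path_d)


def score(model: SeverityModel, X: np.ndarray) -> np.ndarray:
    """Euclidean distance of each image's projection to the control centroid."""
    proj = model.transform(X)
    return np.linalg.norm(proj - model.centroid, axis=1)


def correlate(distances, grades) -> tuple[float, float]:
    """Pearson R (and two-sided p, t-distribution with n-2 df) between
    pathologist grade and centroid distance. Returns (nan, nan) on
    zero-variance input."""
    d = np.asarray(distances, dtype=float)
    g = np.asarray(grades, dtype=float)
    if len(d) != len(g) or len(d) < 3:
        raise ValueError("need >= 3 graded images")
    if np.any((g < 1) | (g > 4)):
        raise ValueError("grades must be integers within 1..4")
    if d.std() == 0 or g.std() == 0:
        return float("nan"), float("nan")
    r, p = sstats.pearsonr(g, d)
    return float(r), float(p)


def classify_new(models: dict[str, SeverityModel], x: np.ndarray) -> dict:
    """Classify one image by the triple and the two pairwise comparisons.

    ``models`` must provide 'triple' (control/MD/NA), 'md' (control vs MD)
    and 'na' (control vs NA), each with its own selected features and a
    trained ARTMAP. The report carries the triple label (C/D/N), the
    pairwise verdicts, a mixed-pattern flag when they disagree, and a
    near-boundary flag when the triple-comparison distance falls below
    the 10th percentile of the pathological training distances.
    """
    for key in ("triple", "md", "na"):
        if key not in models:
            raise ValueError(f"missing model for comparison {key!r}")
        if models[key].artmap is None:
            raise ValueError(f"comparison {key!r} has no trained classifier")
    x = np.asarray(x, dtype=float)
    short = {CONTROL_LABEL: "C", "MD": "D", "NA": "N"}

    triple_raw = models["triple"].artmap.predict(
        np.atleast_2d(x)[:, models["triple"].selected])[0]
    triple = short.get(str(triple_raw), str(triple_raw))
    md_raw = models["md"].artmap.predict(
        np.atleast_2d(x)[:, models["md"].selected])[0]
    na_raw = models["na"].artmap.predict(
        np.atleast_2d(x)[:, models["na"].selected])[0]
    md_verdict = "D" if str(md_raw) == "MD" else "No D"
    na_verdict = "N" if str(na_raw) == "NA" else "No N"

    dist = float(score(models["triple"], x[None, :])[0])
    path_d = models["triple"].pathological_distances
    near = bool(len(path_d) and dist < np.percentile(path_d, 10))
    mixed = ((triple == "C" and (md_verdict == "D" or na_verdict == "N"))
             or (triple == "D" and na_verdict == "N")
             or (triple == "N" and md_verdict == "D"))
    return {
        "triple": triple,
        "md_verdict": md_verdict,
        "na_verdict": na_verdict,
        "distance": dist,
        "near_boundary": near,
        "mixed_pattern": mixed,
    }
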