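"""Validation experiments on synthetic cohorts.

Each function generates its own synthetic study material from a seed,
runs the relevant pipeline stage end to end, and returns the measured
quantities. They double as the package's reproducibility suite: the
acceptance tests assert on their outputs and ``scripts/acceptance.py``
reports them.

Problem sizes (20-image cohorts, 320x320 frames with ~49 fibers,
two-decade severity ramps) are the package's standard desk-scale study
conditions; they are deliberately small enough to re-run routinely.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from myonet.artmap import FuzzyARTMAP
from myonet.features import N_FEATURES, catalog
from myonet.pipeline import analyze_image
from myonet.segmentation import segment_image
from myonet.selection import cv_error, sfs
from myonet.severity import correlate, fit_severity, score
from myonet.synthetic import SyntheticSpec, generate_biopsy, make_spec


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 10_000 + k) % (2**31 - 1))


def catalog_counts() -> dict:
    """Structural counts of the feature catalog as emitted by the extractor."""
    cat = catalog()
    return {
        "n_features": len(cat),
        "n_geometric": int((cat["group"].isin(["size", "shape", "collagen"])).sum()),
        "n_graph": int((cat["group"] == "graph").sum()),
        "n_beyond_pathologist": int((cat.index > 24).sum()),
    }


def match_fibers(truth, label_map) -> np.ndarray:
    """Best-overlap IoU of every ground-truth fiber against the segmentation."""
    gt = truth.label_map
    seg = label_map.labels
    ious = []
    for k in truth.types:
        m = gt == k
        vals, counts = np.unique(seg[m], return_counts=True)
        counts = counts[vals > 0]
        vals = vals[vals > 0]
        if len(vals) == 0:
            ious.append(0.0)
            continue
        best = vals[np.argmax(counts)]
        inter = int(counts.max())
        union = int(m.sum()) + int((seg == best).sum()) - inter
        ious.append(inter / union)
    return np.asarray(ious)


def segmentation_recovery(seed: int = 0, n_images: int = 20) -> dict:
    """Fiber recovery on a synthetic cohort (fibrosis 2-6, noise up to 10).

    Returns the fraction of ground-truth fibers matched at IoU >= 0.7 and
    the worst relative fiber-count error.
    """
    matched = total = 0
    count_errs = []
    for i in range(n_images):
        spec = SyntheticSpec(fibrosis=[2.0, 4.0, 6.0][i % 3],
                             noise_sd=[5.0, 10.0][i % 2],
                             seed=_sub_seed(seed, i))
        img, truth = generate_biopsy(spec)
        lmap, _ = segment_image(img)
        ious = match_fibers(truth, lmap)
        matched += int((ious >= 0.7).sum())
        total += len(ious)
        count_errs.append(abs(lmap.n_labels - truth.n_fibers) / truth.n_fibers)
    return {
        "match_pct": 100.0 * matched / total,
        "max_count_err_pct": 100.0 * max(count_errs),
        "n_images": n_images,
    }


def fibrosis_ramp(seed: int = 0,
                  levels: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)) -> list[float]:
    """Mean A1/A2 (feature 15) along a fibrosis ramp at fixed seed."""
    out = []
    for f in levels:
        img, _ = generate_biopsy(SyntheticSpec(fibrosis=f, noise_sd=5.0,
                                               seed=_sub_seed(seed, 17)))
        out.append(analyze_image(img.rgb).features[15])
    return out


def grouping_effect(seed: int = 0, n_pairs: int = 20,
                    levels: tuple = (0.0, 0.5, 1.0)) -> dict:
    """Same-type neighbor counts (features 21 and 24) along a grouping ramp.

    Images are paired by seed across grouping levels; the one-sided sign
    test compares the extreme levels.
    """
    f21 = {g: [] for g in levels}
    f24 = {g: [] for g in levels}
    for i in range(n_pairs):
        for g in levels:
            spec = SyntheticSpec(grouping=g, slow_fraction=0.5,
                                 seed=_sub_seed(seed, 100 + i))
            img, _ = generate_biopsy(spec)
            fv = analyze_image(img.rgb).features
            f21[g].append(fv[21])
            f24[g].append(fv[24])
    lo, hi = levels[0], levels[-1]
    res = {"means_21": [float(np.mean(f21[g])) for g in levels],
           "means_24": [float(np.mean(f24[g])) for g in levels]}
    for name, d in (("21", f21), ("24", f24)):
        wins = sum(int(b > a) for a, b in zip(d[lo], d[hi]))
        ties = sum(int(b == a) for a, b in zip(d[lo], d[hi]))
        n_eff = n_pairs - ties
        p = binomtest(wins, n_eff, 0.5, alternative="greater").pvalue \
            if n_eff else 1.0
        res[f"sign_p_{name}"] = float(p)
    return res


def artmap_contract(seed: int = 0, n_datasets: int = 200) -> dict:
    """Fast-learning resubstitution accuracy on random consistent datasets,
    plus exact learning of the XOR pattern."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_datasets):
        n = int(rng.integers(5, 40))
        m = int(rng.integers(1, 6))
        X = rng.uniform(size=(n, m))
        y = rng.integers(0, int(rng.integers(2, 4)), size=n)
        model = FuzzyARTMAP().fit(X, y)
        accs.append(model.score(X, y))
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
    y = np.array([0, 1, 1, 0])
    xor_model = FuzzyARTMAP().fit(X, y)
    return {
        "resubstitution_pct": 100.0 * float(np.mean(accs)),
        "xor_accuracy_pct": 100.0 * xor_model.score(X, y),
        "n_datasets": n_datasets,
    }


def selection_sanity(seed: int = 0, n_runs: int = 10,
                     n_null_seeds: int = 50) -> dict:
    """Planted-separator recovery and the permuted-label error null.

    A perfectly separating feature is hidden among 20 noise features; SFS
    should pick it first in every seeded run. With labels permuted, the
    mean cross-validated error over balanced two-class data must sit at
    the 0.5 chance level.
    """
    hits = 0
    for r in range(n_runs):
        rng = np.random.default_rng(_sub_seed(seed, 300 + r))
        n = 40
        y = np.array(["A"] * 20 + ["B"] * 20)
        X = rng.uniform(size=(n, 21))
        planted = 7
        X[:, planted] = np.where(y == "A", rng.uniform(0.0, 0.4, n),
                                 rng.uniform(0.6, 1.0, n))
        res = sfs(X, y, k=4, seed=_sub_seed(seed, 300 + r))
        hits += int(res.order[0] == planted)
    null_errs = []
    for r in range(n_null_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 600 + r))
        X = rng.uniform(size=(40, 3))
        y = rng.permutation(np.array(["A"] * 20 + ["B"] * 20))
        null_errs.append(cv_error([0, 1, 2], X, y, k=4,
                                  seed=_sub_seed(seed, 600 + r)))
    return {
        "planted_hits": hits,
        "n_runs": n_runs,
        "null_error_mean": float(np.mean(null_errs)),
    }


def varied_spec(rng: np.random.Generator, kind: str, seed: int) -> SyntheticSpec:
    """Draw one cohort member with realistic within-class variability.

    Controls and neurogenic (NA) images share the same geometric ranges —
    only the fiber-type grouping dial separates them — while dystrophic
    (MD) images shift fibrosis, size heterogeneity and rounding.
    """
    if kind == "control":
        return SyntheticSpec(fibrosis=float(rng.uniform(1.5, 3.0)),
                             size_cv=float(rng.uniform(0.10, 0.30)),
                             roundness=float(rng.uniform(0.05, 0.20)),
                             grouping=0.0, seed=seed)
    if kind == "MD":
        return SyntheticSpec(fibrosis=float(rng.uniform(5.0, 8.0)),
                             size_cv=float(rng.uniform(0.35, 0.65)),
                             roundness=float(rng.uniform(0.30, 0.60)),
                             grouping=0.0, seed=seed)
    if kind == "NA":
        return SyntheticSpec(fibrosis=float(rng.uniform(1.5, 3.0)),
                             size_cv=float(rng.uniform(0.10, 0.30)),
                             roundness=float(rng.uniform(0.05, 0.20)),
                             grouping=float(rng.uniform(0.7, 1.0)), seed=seed)
    raise ValueError(f"unknown class {kind!r}")


def fit_comparison_models(seed: int = 0, n_control: int = 8, n_path: int = 6):
    """Train the triple and the two pairwise comparison models on a
    synthetic three-class cohort (SFS selection per comparison)."""
    rng = np.random.default_rng(seed)
    specs = ([varied_spec(rng, "control", _sub_seed(seed, i))
              for i in range(n_control)]
             + [varied_spec(rng, "MD", _sub_seed(seed, 200 + i))
                for i in range(n_path)]
             + [varied_spec(rng, "NA", _sub_seed(seed, 300 + i))
                for i in range(n_path)])
    y = np.array(["control"] * n_control + ["MD"] * n_path + ["NA"] * n_path)
    X = cohort_feature_matrix(specs)

    def fit_one(mask):
        Xs, ys = X[mask], y[mask]
        usable = [j for j in range(N_FEATURES) if not np.isnan(Xs[:, j]).any()]
        sel = sfs(Xs, ys, k=4, seed=seed, candidates=usable)
        return fit_severity(Xs, ys, sel.selected)

    return {
        "triple": fit_one(np.ones(len(y), bool)),
        "md": fit_one(y != "NA"),
        "na": fit_one(y != "MD"),
    }


def cohort_feature_matrix(specs) -> np.ndarray:
    """Full pipeline (segmentation -> network -> features) on each spec."""
    return np.array([analyze_image(generate_biopsy(s)[0].rgb).features.values
                     for s in specs])


def severity_recovery(seed: int = 0, n_seeds: int = 5, n_md: int = 20,
                      n_control: int = 12) -> dict:
    """End-to-end parameter recovery on dystrophic severity ramps.

    For each cohort seed: generate controls plus an MD severity ramp, run
    the whole pipeline, select features by SFS (control vs MD), fit the
    severity model, and correlate centroid distances of the MD images
    with grades 1-4 discretized from the generator severity parameter.
    """
    rs = []
    for k in range(n_seeds):
        base = _sub_seed(seed, 1000 + k)
        ctrl = [make_spec("control", seed=_sub_seed(base, i))
                for i in range(n_control)]
        sev = np.linspace(0.0, 0.9, n_md)
        md = [make_spec("md", severity=float(s), seed=_sub_seed(base, 100 + i))
              for i, s in enumerate(sev)]
        X = cohort_feature_matrix(ctrl + md)
        y = np.array(["control"] * n_control + ["MD"] * n_md)
        usable = [j for j in range(N_FEATURES) if not np.isnan(X[:, j]).any()]
        sel = sfs(X, y, k=4, seed=base, candidates=usable)
        model = fit_severity(X, y, sel.selected)
        d = score(model, X[n_control:])
        sp = np.array([m.severity_param for m in md])
        grade = 1 + np.minimum(
            3, (4 * (sp - sp.min()) / (sp.max() - sp.min())).astype(int))
        r, _ = correlate(d, grade)
        rs.append(r)
    return {"median_r": float(np.median(rs)),
            "per_seed_r": [float(r) for r in rs]}
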