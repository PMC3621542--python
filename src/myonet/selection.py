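"""Wrapper feature selection: SFS/SBS with cross-validated ARTMAP error.

Subset quality is the mean held-out error of a Fuzzy-ARTMAP classifier
over a stratified k-fold split (per-class disjoint subsets rotated
through as validation sets; default k = 4). Sequential forward selection
(SFS) adds the feature whose inclusion minimizes this error and stops
when the best addition strictly increases it (or the error reaches
zero); sequential backward selection (SBS) is the top-down mirror.
Greedy search can miss jointly-informative feature pairs (e.g. an XOR
pair); results are nonetheless deterministic given the fold seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from myonet.artmap import ARTMAPParams, FuzzyARTMAP

DEFAULT_K = 4


@dataclass
class SelectionResult:
    method: str                       # "SFS" | "SBS"
    selected: list[int]               # catalog order (sorted column indices)
    order: list[int]                  # indices in pick/drop order
    trajectory: list[float]           # CV error after each accepted step
    k: int = DEFAULT_K
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        return cls(**json.loads(text))


def _check_classes(y: np.ndarray, k: int) -> None:
    vals, counts = np.unique(y, return_counts=True)
    for v, c in zip(vals, counts):
        if c < k:
            raise ValueError(f"class {v!r} has {c} samples, fewer than k={k} folds")


def cv_error(features, X: np.ndarray, y: np.ndarray, k: int = DEFAULT_K,
             params: ARTMAPParams | None = None, seed: int = 0) -> float:
    """Mean stratified k-fold held-out error of ARTMAP on a feature subset.

    ``features`` indexes columns of X. ARTMAP's min-max rescaling is fit
    inside each training fold, so there is no scaling leakage.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    features = list(features)
    if not features:
        raise ValueError("empty feature set")
    _check_classes(y, k)
    Xs = X[:, features]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errors = []
    for train_idx, test_idx in skf.split(Xs, y):
        model = FuzzyARTMAP(params)
        model.fit(Xs[train_idx], y[train_idx])
        errors.append(1.0 - model.score(Xs[test_idx], y[test_idx]))
    return float(np.mean(errors))


def sfs(X: np.ndarray, y: np.ndarray, k: int = DEFAULT_K,
        params: ARTMAPParams | None = None, seed: int = 0,
        candidates: list[int] | None = None) -> SelectionResult:
    """Greedy bottom-up search; ties broken by lowest feature index."""
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    remaining = list(range(n_feat)) if candidates is None else list(candidates)
    current: list[int] = []
    trajectory: list[float] = []
    current_err = np.inf
    while remaining:
        errs = [(cv_error(current + [f], X, y, k, params, seed), f)
                for f in remaining]
        best_err, best_f = min(errs, key=lambda t: (t[0], t[1]))
        if current and best_err > current_err:
            break  # the best addition strictly increases the error
        current.append(best_f)
        remaining.remove(best_f)
        trajectory.append(best_err)
        current_err = best_err
        if current_err == 0.0:
            break  # nothing left to improve
    return SelectionResult(method="SFS", selected=sorted(current),
                           order=current, trajectory=trajectory, k=k, seed=seed)


def sbs(X: np.ndarray, y: np.ndarray, k: int = DEFAULT_K,
        params: ARTMAPParams | None = None, seed: int = 0,
        candidates: list[int] | None = None) -> SelectionResult:
    """Greedy top-down search; the least discriminant feature is discarded
    while its removal does not increase the CV error."""
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    current = list(range(n_feat)) if candidates is None else list(candidates)
    order: list[int] = []
    current_err = cv_error(current, X, y, k, params, seed)
    trajectory = [current_err]
    while len(current) > 1:
        errs = [(cv_error([f for f in current if f != g], X, y, k, params, seed), g)
                for g in current]
        best_err, worst_f = min(errs, key=lambda t: (t[0], t[1]))
        if best_err > current_err:
            break  # removing anything else increases the error
        current.remove(worst_f)
        order.append(worst_f)
        trajectory.append(best_err)
        current_err = best_err
    return SelectionResult(method="SBS", selected=sorted(current),
                           order=order, trajectory=trajectory, k=k, seed=seed)
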