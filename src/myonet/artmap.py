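"""Fuzzy-ARTMAP: supervised adaptive-resonance classifier.

The simplified (one-ART) Fuzzy-ARTMAP for classification: analog inputs
are min-max rescaled and complement coded, category nodes compete through
the fuzzy choice function T_j = |I ^ w_j| / (alpha + |w_j|) (^ is the
componentwise minimum, |.| the L1 sum), resonance requires the match
|I ^ w_j| / M to clear the vigilance rho, and a class mismatch triggers
match tracking (rho is raised just above the current match and the search
continues). Learning moves the winner toward I ^ w; with fast learning
(beta = 1) a category's weight box simply grows to enclose every input it
has coded, and every component of every weight is non-increasing over
training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARTMAPParams:
    """Fuzzy-ARTMAP hyperparameters (fast-learning defaults)."""

    alpha: float = 0.001       # choice parameter, > 0
    beta: float = 1.0          # learning rate in (0, 1]
    rho_baseline: float = 0.0  # baseline vigilance in [0, 1]
    epsilon: float = 0.001     # match-tracking increment, > 0
    max_epochs: int = 10

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if not 0 <= self.rho_baseline <= 1:
            raise ValueError("rho_baseline must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class FuzzyARTMAP:
    """Fuzzy-ARTMAP classifier with scikit-learn-like fit/predict.

    Parameters
    ----------
    params:
        Hyperparameters; defaults use fast learning (beta = 1).
    shuffle:
        If True, presentation order is shuffled once per fit using
        ``random_state``; otherwise dataset order is used.
    """

    def __init__(self, params: ARTMAPParams | None = None, *,
                 shuffle: bool = False, random_state: int | None = None):
        self.params = params or ARTMAPParams()
        self.params.validate()
        self.shuffle = shuffle
        self.random_state = random_state
        self.w_: np.ndarray | None = None       # (n_categories, 2M)
        self.labels_: np.ndarray | None = None  # map field
        self.bounds_: tuple[np.ndarray, np.ndarray] | None = None
        self.M_: int | None = None

    # -- preprocessing -----------------------------------------------------

    def _rescale(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds_
        span = np.where(hi > lo, hi - lo, 1.0)
        a = (x - lo) / span
        n_clipped = int(np.sum((a < 0) | (a > 1)))
        if n_clipped:
            logger.debug("clipped %d out-of-bounds components", n_clipped)
        return np.clip(a, 0.0, 1.0)

    def complement_code(self, x: np.ndarray) -> np.ndarray:
        """Rescale to [0,1] per feature and emit (a, 1 - a); sums to M."""
        a = self._rescale(np.asarray(x, dtype=float))
        return np.concatenate([a, 1.0 - a], axis=-1)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FuzzyARTMAP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, M) with matching labels")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.M_ = X.shape[1]
        self.bounds_ = (X.min(axis=0), X.max(axis=0))
        coded = self.complement_code(X)

        order = np.arange(len(X))
        if self.shuffle:
            order = np.random.default_rng(self.random_state).permutation(len(X))

        p = self.params
        M = float(self.M_)
        w: list[np.ndarray] = []
        labels: list = []
        seen: dict[bytes, object] = {}
        n_contradictions = 0
        for _ in range(p.max_epochs):
            changed = False
            for i in order:
                inp = coded[i]
                target = y[i]
                key = inp.tobytes()
                if key in seen and seen[key] != target:
                    n_contradictions += 1
                seen[key] = target

                rho = p.rho_baseline
                if w:
                    wa = np.array(w)
                    act = np.minimum(inp, wa).sum(axis=1)
                    T = act / (p.alpha + wa.sum(axis=1))
                else:
                    wa = None
                    act = T = np.empty(0)
                t_unc = M / (p.alpha + 2.0 * M)

                committed = len(w)
                # stable descending T; ties -> lowest category index
                cand = sorted(range(committed), key=lambda j: (-T[j], j))
                learned = False
                for j in cand:
                    if T[j] < t_unc:
                        break  # uncommitted node wins the competition
                    match = act[j] / M
                    if match < rho:
                        continue
                    if labels[j] == target:
                        new_w = p.beta * np.minimum(inp, w[j]) \
                            + (1 - p.beta) * w[j]
                        if not np.array_equal(new_w, w[j]):
                            changed = True
                        w[j] = new_w
                        learned = True
                        break
                    rho = match + p.epsilon  # match tracking
                    if rho > 1.0:
                        break
                if not learned:
                    w.append(inp.copy())
                    labels.append(target)
                    changed = True
            if not changed:
                break
        if n_contradictions:
            logger.debug("%d contradictory duplicate presentations during fit",
                         n_contradictions)
        self.w_ = np.array(w)
        self.labels_ = np.array(labels)
        return self

    # -- prediction --------------------------------------------------------

    def _choice(self, coded: np.ndarray) -> np.ndarray:
        act = np.minimum(coded[:, None, :], self.w_[None, :, :]).sum(axis=2)
        return act / (self.params.alpha + self.w_.sum(axis=1)[None, :])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Winner-take-all over committed categories (ties -> lowest index)."""
        if self.w_ is None or len(self.w_) == 0:
            raise ValueError("model is not trained")
        coded = self.complement_code(np.atleast_2d(np.asarray(X, dtype=float)))
        T = self._choice(coded)
        winners = np.argmax(T, axis=1)  # argmax returns the first (lowest) index
        return self.labels_[winners]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    @property
    def n_categories(self) -> int:
        return 0 if self.w_ is None else len(self.w_)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        if self.w_ is None:
            raise ValueError("model is not trained")
        return json.dumps({
            "params": asdict(self.params),
            "weights": self.w_.tolist(),
            "labels": self.labels_.tolist(),
            "bounds": [self.bounds_[0].tolist(), self.bounds_[1].tolist()],
            "M": self.M_,
        })

    @classmethod
    def from_json(cls, text: str) -> "FuzzyARTMAP":
        d = json.loads(text)
        model = cls(ARTMAPParams(**d["params"]))
        model.w_ = np.asarray(d["weights"], dtype=float)
        model.labels_ = np.asarray(d["labels"])
        model.bounds_ = (np.asarray(d["bounds"][0], dtype=float),
                         np.asarray(d["bounds"][1], dtype=float))
        model.M_ = d["M"]
        return model


def vote_predict(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
                 params: ARTMAPParams | None = None, voters: int = 5,
                 seed: int = 0) -> np.ndarray:
    """Majority vote over ``voters`` models trained on shuffled orders.

    Presentation-order sensitivity is inherent to ARTMAP; voting over a
    few seeded shuffles stabilizes the prediction.
    """
    votes = []
    for v in range(voters):
        m = FuzzyARTMAP(params, shuffle=True, random_state=seed + v)
        m.fit(X_train, y_train)
        votes.append(m.predict(X_test))
    votes = np.array(votes)
    out = []
    for col in votes.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append(vals[np.argmax(counts)])
    return np.array(out)
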