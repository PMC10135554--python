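"""IDOX wrapper selection of an optimal deep-feature subset.

A candidate subset is encoded as a real vector, decoded through a sigmoid
threshold into a bit mask (with all-zero repair), and scored by the error of a
fast reference classifier — regularized logistic regression under stratified
3-fold cross-validation — plus a sparsity penalty proportional to the selected
fraction. The IDOX search minimizes this cost; the classifier restricted to
the winning columns feeds the downstream BiLSTM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from .idox import IDOX, IDOXConfig, SearchSpace, decode_binary


@dataclass
class FeatureMask:
    """Binary selection mask over the concatenated feature columns."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, int)
        if self.bits.ndim != 1 or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask must be a flat 0/1 vector")
        if self.bits.sum() < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def _reference_classifier():
    return LogisticRegression(C=1.0, max_iter=300)


def selection_fitness(
    mask,
    X,
    y,
    penalty: float = 0.01,
    cv: int = 3,
    seed: int = 0,
) -> float:
    """Cost of a mask: (1 - mean stratified CV accuracy) + penalty * fraction kept."""
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask, int)
    if bits.sum() < 1:
        raise ValueError("empty mask cannot be scored; repair it first")
    X = np.asarray(X, float)
    cols = np.flatnonzero(bits)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    acc = cross_val_score(
        _reference_classifier(), X[:, cols], y, cv=skf, scoring="accuracy"
    ).mean()
    return float(1.0 - acc + penalty * bits.sum() / len(bits))


class IDOXFeatureSelector(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper selector; ``fit`` runs the IDOX subset search.

    Fitted attributes: ``support_`` (boolean mask), ``mask_`` (FeatureMask),
    ``cost_`` (winning fitness), ``history_`` (optimizer trace).
    """

    def __init__(
        self,
        population_size: int = 5,
        iterations: int = 5,
        penalty: float = 0.01,
        cv: int = 3,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.iterations = iterations
        self.penalty = penalty
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y).reshape(-1)
        d = X.shape[1]
        self.n_features_in_ = d
        if d == 1:
            self.mask_ = FeatureMask(np.ones(1, int))
            self.support_ = self.mask_.bits.astype(bool)
            self.cost_ = selection_fitness(
                self.mask_, X, y, self.penalty, self.cv, self.random_state
            )
            self.history_ = [self.cost_]
            return self

        cache: dict[bytes, float] = {}

        def objective(pos: np.ndarray) -> float:
            bits = decode_binary(pos)
            key = bits.tobytes()
            if key not in cache:
                cache[key] = selection_fitness(
                    bits, X, y, self.penalty, self.cv, self.random_state
                )
            return cache[key]

        cfg = IDOXConfig(
            population_size=self.population_size,
            max_iterations=self.iterations,
            seed=self.random_state,
        )
        space = SearchSpace(d, -4.0, 4.0, encoding="binary")
        result = IDOX(space, cfg).optimize(objective)
        bits = decode_binary(result.best_position)
        cost = result.best_fitness

        def scored(candidate):
            key = candidate.tobytes()
            if key not in cache:
                cache[key] = selection_fitness(
                    candidate, X, y, self.penalty, self.cv, self.random_state
                )
            return cache[key]

        # memetic polish: steepest-descent over single (and, for small d,
        # pairwise) bit flips until no move improves the cost
        moves = [(j,) for j in range(d)]
        if d <= 16:
            moves += [(a, b) for a in range(d) for b in range(a + 1, d)]
        improved = True
        while improved:
            improved = False
            for mv in moves:
                cand = bits.copy()
                for j in mv:
                    cand[j] ^= 1
                if cand.sum() == 0:
                    continue
                c = scored(cand)
                if c < cost - 1e-12:
                    bits, cost, improved = cand, c, True

        self.mask_ = FeatureMask(bits)
        self.support_ = bits.astype(bool)
        self.cost_ = cost
        self.history_ = result.fitness_history + [cost]
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got {X.shape[1]}"
            )
        return X[:, self.support_]


def select_features(
    X, y, idox_config: IDOXConfig | None = None, penalty: float = 0.01, cv: int = 3
) -> FeatureMask:
    """Functional surface over :class:`IDOXFeatureSelector`."""
    cfg = idox_config or IDOXConfig(population_size=5, max_iterations=5)
    sel = IDOXFeatureSelector(
        population_size=cfg.population_size,
        iterations=cfg.max_iterations,
        penalty=penalty,
        cv=cv,
        random_state=cfg.seed,
    ).fit(X, y)
    return sel.mask_
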