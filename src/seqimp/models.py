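"""Pluggable categorical imputation models.

Both model families share one contract: fit on a matrix of categorical
predictor columns (state codes, one-hot expanded internally against the
panel alphabet) plus an optional fixed-covariate block, and return, for
any predictor row, a probability vector over the *full* alphabet.
Categories never seen in the response get probability 0 (imputation can
therefore not invent states absent from the training windows), except in
the degenerate single-category case where the protection contract
requires every probability to stay strictly below 1.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

#: blending weight of the perfect-prediction protection
PROTECT_EPS = 1e-6


def encode_covariates(df) -> np.ndarray:
    """One-hot encode a fixed-covariate frame (categorical columns) into
    a dense matrix with one row per sequence."""
    import pandas as pd

    blocks = []
    for col in df.columns:
        cats = pd.Categorical(df[col].astype(str))
        blocks.append(one_hot(cats.codes[:, None].astype(int),
                              len(cats.categories)))
    return np.hstack(blocks)


def one_hot(X: np.ndarray, n_states: int) -> np.ndarray:
    """One-hot expand a matrix of state codes column-block-wise.

    Codes outside ``0..n_states-1`` (e.g. an unseen category) map to the
    all-zeros block, never an error.
    """
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    out = np.zeros((n, p * n_states), dtype=np.float64)
    rows = np.repeat(np.arange(n), p)
    cols = (np.arange(p) * n_states)[None, :] + X
    valid = (X >= 0) & (X < n_states)
    out[rows[valid.ravel()], cols[valid]] = 1.0
    return out


class _BaseModel:
    kind: str

    def __init__(self, n_states: int):
        self.n_states = n_states
        self.categories_seen_: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability matrix (rows x n_states); rows sum to 1."""
        raise NotImplementedError

    def _expand(self, proba_seen: np.ndarray) -> np.ndarray:
        out = np.zeros((proba_seen.shape[0], self.n_states))
        out[:, self.categories_seen_] = proba_seen
        return out


class MultinomialModel(_BaseModel):
    """Ridge-penalised softmax regression over one-hot predictors.

    ``protect`` guards against perfect prediction: fitted probabilities
    for categories seen in training are kept strictly inside (0, 1) by
    the combination of the L2 penalty (``lam``, weights only) and an
    eps-blend toward the uniform distribution over seen categories.
    """

    kind = "multinomial"

    def __init__(self, n_states: int, protect: bool = True, lam: float = 1e-3,
                 max_iter: int = 200):
        super().__init__(n_states)
        self.protect = protect
        self.lam = lam
        self.max_iter = max_iter

    def fit(self, X_codes: np.ndarray, y: np.ndarray,
            extra: np.ndarray | None = None) -> "MultinomialModel":
        y = np.asarray(y)
        if y.size == 0:
            raise ValueError("empty training set: caller must fall back")
        self.categories_seen_ = np.unique(y)
        self._single = self.categories_seen_.size == 1
        if not self._single:
            Xd = one_hot(X_codes, self.n_states)
            if extra is not None:
                Xd = np.hstack([Xd, extra])
            self._clf = LogisticRegression(
                C=1.0 / self.lam, max_iter=self.max_iter, solver="lbfgs",
            )
            with warnings.catch_warnings():
                # near-separable training windows legitimately stop at
                # max_iter; the ridge penalty bounds the solution
                warnings.simplefilter("ignore", ConvergenceWarning)
                self._clf.fit(Xd, y)
        return self

    def predict_proba(self, X_codes: np.ndarray,
                      extra: np.ndarray | None = None) -> np.ndarray:
        X_codes = np.atleast_2d(np.asarray(X_codes))
        m = X_codes.shape[0]
        if self._single:
            out = np.zeros((m, self.n_states))
            out[:, self.categories_seen_[0]] = 1.0
            if self.protect and self.n_states > 1:
                # degenerate response: leak eps so the seen category
                # stays strictly below 1
                out *= 1.0 - PROTECT_EPS
                out[out == 0.0] = PROTECT_EPS / (self.n_states - 1)
            return out
        Xd = one_hot(X_codes, self.n_states)
        if extra is not None:
            Xd = np.hstack([Xd, extra])
        p = self._clf.predict_proba(Xd)
        out = self._expand(p)
        if self.protect:
            k = self.categories_seen_.size
            out[:, self.categories_seen_] = (
                (1.0 - PROTECT_EPS) * out[:, self.categories_seen_]
                + PROTECT_EPS / k
            )
        return out


class RandomForestModel(_BaseModel):
    """Random forest with class probabilities = fraction of tree votes."""

    kind = "random_forest"

    def __init__(self, n_states: int, n_trees: int = 100, seed: int | None = None):
        super().__init__(n_states)
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X_codes: np.ndarray, y: np.ndarray,
            extra: np.ndarray | None = None) -> "RandomForestModel":
        y = np.asarray(y)
        if y.size == 0:
            raise ValueError("empty training set: caller must fall back")
        self.categories_seen_ = np.unique(y)
        Xd = one_hot(X_codes, self.n_states)
        if extra is not None:
            Xd = np.hstack([Xd, extra])
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees, max_features="sqrt",
            random_state=self.seed,
        )
        self._rf.fit(Xd, y)
        return self

    def predict_proba(self, X_codes: np.ndarray,
                      extra: np.ndarray | None = None) -> np.ndarray:
        X_codes = np.atleast_2d(np.asarray(X_codes))
        Xd = one_hot(X_codes, self.n_states)
        if extra is not None:
            Xd = np.hstack([Xd, extra])
        # hard votes: each tree predicts one class, probability is the
        # fraction of trees voting for it (not sklearn's averaged leaf
        # probabilities)
        votes = np.zeros((Xd.shape[0], self.n_states))
        classes = self._rf.classes_
        for tree in self._rf.estimators_:
            pred = classes[np.argmax(tree.predict_proba(Xd), axis=1)]
            votes[np.arange(Xd.shape[0]), pred.astype(int)] += 1.0
        return votes / len(self._rf.estimators_)


class MarginalModel(_BaseModel):
    """Marginal (predictor-free) draw distribution; final fallback rung."""

    kind = "marginal"

    def fit(self, y: np.ndarray) -> "MarginalModel":
        y = np.asarray(y)
        if y.size == 0:
            raise ValueError("empty training set for marginal model")
        counts = np.bincount(y, minlength=self.n_states).astype(float)
        self.categories_seen_ = np.flatnonzero(counts)
        self._p = counts / counts.sum()
        return self

    def predict_proba(self, X_codes=None, extra=None) -> np.ndarray:
        m = 1 if X_codes is None else np.atleast_2d(np.asarray(X_codes)).shape[0]
        return np.tile(self._p, (m, 1))


def fit_multinomial(X_codes, y, n_states, protect: bool = True,
                    lam: float = 1e-3) -> MultinomialModel:
    return MultinomialModel(n_states, protect=protect, lam=lam).fit(X_codes, y)


def fit_random_forest(X_codes, y, n_states, n_trees: int = 100,
                      seed: int | None = None) -> RandomForestModel:
    return RandomForestModel(n_states, n_trees=n_trees, seed=seed).fit(X_codes, y)


def draw_states(proba: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one state code per row of a probability matrix."""
    proba = np.atleast_2d(proba)
    cum = np.cumsum(proba, axis=1)
    cum[:, -1] = 1.0  # guard against float round-off
    u = rng.random(proba.shape[0])
    return np.argmax(cum >= u[:, None], axis=1).astype(np.int32)


def draw_state(model: _BaseModel, x, rng: np.random.Generator,
               extra: np.ndarray | None = None) -> int:
    """Sample one state from ``model.predict_proba(x)``."""
    p = model.predict_proba(np.atleast_2d(x), extra=extra)
    return int(draw_states(p, rng)[0])
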