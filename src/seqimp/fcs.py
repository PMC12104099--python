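"""Fully conditional specification (chained equations) for a
univariate categorical panel.

Each time point is treated as one categorical variable.  Missing cells
are first filled from their column's observed marginal; the sampler
then cycles over the columns (ascending time), refitting for each
originally incomplete column a model on the rows originally observed
there — predictors being the *current working values* of the chosen
predictor set — and redraws the originally missing cells.  The last
iteration's values are kept; the whole pass repeats independently for
each of the M imputations.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import models as _m
from .mict import MultipleImputation
from .panel import MISSING, SequencePanel

#: named predictor sets: target time t maps to a list of 1-based times
PREDICTOR_SETS = ("P1", "PF1", "P5", "PF5", "all", "past")


def resolve_predictors(name: str, t: int, T: int) -> list[int]:
    """1-based predictor times for target time ``t`` under a named set;
    indices falling outside 1..T are dropped."""
    if name == "P1":
        cand = [t - 1]
    elif name == "PF1":
        cand = [t - 1, t + 1]
    elif name == "P5":
        cand = list(range(t - 5, t))
    elif name == "PF5":
        cand = list(range(t - 5, t)) + list(range(t + 1, t + 6))
    elif name == "all":
        cand = [u for u in range(1, T + 1) if u != t]
    elif name == "past":
        cand = list(range(1, t))
    else:
        raise ValueError(f"unknown predictor set {name!r}")
    return [u for u in cand if 1 <= u <= T]


class FCSImputer(TransformerMixin, BaseEstimator):
    """Chained-equations imputer for state-sequence panels.

    Parameters
    ----------
    predictors : str
        One of ``P1, PF1, P5, PF5, all, past``.
    model : {"multinomial", "random_forest"}
    n_iterations : int
        Number of full passes over the columns after the initial
        marginal fill; 0 keeps the marginal fill.
    protect, lam, n_trees, min_train_rows, random_state :
        As in :class:`~seqimp.mict.MICTImputer`.
    """

    _method_name = "fcs"

    def __init__(self, predictors: str = "PF5", model: str = "multinomial",
                 n_iterations: int = 10, protect: bool = True,
                 lam: float = 1e-3, n_trees: int = 100,
                 min_train_rows: int = 10, random_state: int | None = None):
        self.predictors = predictors
        self.model = model
        self.n_iterations = n_iterations
        self.protect = protect
        self.lam = lam
        self.n_trees = n_trees
        self.min_train_rows = min_train_rows
        self.random_state = random_state

    def _as_panel(self, X) -> SequencePanel:
        from .mict import MICTImputer
        return MICTImputer._as_panel(self, X)

    def fit(self, X, y=None):
        if self.predictors not in PREDICTOR_SETS:
            raise ValueError(f"unknown predictor set {self.predictors!r}")
        self.n_features_in_ = self._as_panel(X).T
        self.fit_log_ = []
        return self

    def transform(self, X) -> np.ndarray:
        return self.impute(self._as_panel(X), M=1).panels[0].data

    def _new_model(self, K: int, rng) -> _m._BaseModel:
        if self.model == "multinomial":
            return _m.MultinomialModel(K, protect=self.protect, lam=self.lam)
        if self.model == "random_forest":
            return _m.RandomForestModel(K, n_trees=self.n_trees,
                                        seed=int(rng.integers(2**31 - 1)))
        raise ValueError(f"unknown model kind {self.model!r}")

    def impute(self, panel: SequencePanel, M: int = 1) -> MultipleImputation:
        if M < 1:
            raise ValueError("M must be >= 1")
        if panel.is_complete():
            raise ValueError("nothing to impute: the panel is complete")
        if self.predictors not in PREDICTOR_SETS:
            raise ValueError(f"unknown predictor set {self.predictors!r}")
        K = panel.n_states
        T = panel.T
        miss = panel.missing_mask()
        miss_cols = np.flatnonzero(miss.any(axis=0))  # 0-based columns
        # column marginals of the observed data
        marginals = []
        for t0 in range(T):
            col = panel.data[:, t0]
            counts = np.bincount(col[col >= 0], minlength=K).astype(float)
            if counts.sum() == 0:
                counts[:] = 1.0  # fully missing column: uniform start
            marginals.append(counts / counts.sum())
        cov = (None if panel.covariates is None
               else _m.encode_covariates(panel.covariates))
        fit_log: list[dict] = []
        panels = []
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(M):
            rng = np.random.default_rng(child)
            W = panel.data.copy()
            for t0 in miss_cols:
                rows = np.flatnonzero(miss[:, t0])
                W[rows, t0] = rng.choice(K, size=rows.size, p=marginals[t0])
            for _ in range(self.n_iterations):
                for t0 in miss_cols:
                    self._visit_column(W, miss, t0, K, T, rng, fit_log, cov)
            assert not (W == MISSING).any()
            panels.append(panel.copy(data=W))
        self.fit_log_ = fit_log
        return MultipleImputation(panels=panels, method=self._method_name,
                                  config=self.get_params(),
                                  seed=self.random_state, fit_log=fit_log)

    def _visit_column(self, W, miss, t0, K, T, rng, fit_log, cov=None) -> None:
        pred_times = resolve_predictors(self.predictors, t0 + 1, T)
        obs_rows = np.flatnonzero(~miss[:, t0])
        mis_rows = np.flatnonzero(miss[:, t0])
        if not pred_times or obs_rows.size < max(2, self.min_train_rows):
            # no usable predictors (e.g. t=1 under a past-only set) or
            # too few originally observed rows: marginal redraw
            y = W[obs_rows, t0]
            if y.size == 0:
                y = W[:, t0]
            model = _m.MarginalModel(K).fit(y)
            fit_log.append({"stage": "fcs", "t": t0 + 1, "rows": int(y.size),
                            "fallback": "marginal"})
            W[mis_rows, t0] = _m.draw_states(
                model.predict_proba(np.zeros((mis_rows.size, 1))), rng)
            return
        cols = [u - 1 for u in pred_times]
        model = self._new_model(K, rng)
        model.fit(W[np.ix_(obs_rows, cols)], W[obs_rows, t0],
                  extra=None if cov is None else cov[obs_rows])
        fit_log.append({"stage": "fcs", "t": t0 + 1,
                        "rows": int(obs_rows.size), "fallback": "none"})
        proba = model.predict_proba(W[np.ix_(mis_rows, cols)],
                                    extra=None if cov is None else cov[mis_rows])
        W[mis_rows, t0] = _m.draw_states(proba, rng)


def fcs_impute(panel: SequencePanel, M: int = 1, **params) -> MultipleImputation:
    """Functional wrapper over :class:`FCSImputer`."""
    return FCSImputer(**params).impute(panel, M=M)
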