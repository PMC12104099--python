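"""Multiple Imputation for Categorical Time series (MICT).

MICT fills each missing-data gap recursively from its edges: gaps are
processed by decreasing remaining length, and at each length one
imputation model predicts the first (leftmost) still-missing cell of
every gap of that length from the ``np`` cells immediately before it
(observed or previously imputed) and the ``nf`` cells just beyond the
gap's right edge.  The model is trained on every fully observed
displacement window of the same shape found anywhere in the panel.
Internal gaps go first, then initial/terminal gaps (one-sided models),
and finally the rarer edge-constrained gaps with reduced windows.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import models as _m
from .panel import MISSING, SequencePanel, classify_gaps

#: the published predictor-set presets: (past, future) window sizes
PRESETS: dict[str, tuple[int, int]] = {
    "P1": (1, 0),
    "PF1": (1, 1),
    "P5": (5, 0),
    "PF5": (5, 5),
}


@dataclasses.dataclass
class TrainingWindowSet:
    """Design matrix of fully observed displacement windows.

    For remaining gap length ``G``, predictors sit at offsets
    ``-np..-1`` and ``+G..+G+nf-1`` relative to the target cell.
    """

    X: np.ndarray            # (rows, np+nf) predictor state codes
    y: np.ndarray            # (rows,) target state codes
    t: np.ndarray            # (rows,) 1-based target time of each row
    rows: np.ndarray         # (rows,) source sequence index
    G: int
    np_past: int
    nf_future: int


@dataclasses.dataclass
class MultipleImputation:
    """M completed panels plus provenance."""

    panels: list[SequencePanel]
    method: str
    config: dict
    seed: int | None
    fit_log: list[dict]

    @property
    def M(self) -> int:
        return len(self.panels)


def build_training_windows(
    panel: SequencePanel | np.ndarray,
    G: int,
    np_past: int,
    nf_future: int,
    position_filter: Sequence[int] | None = None,
) -> TrainingWindowSet:
    """Harvest all fully observed displacement windows for gap length G.

    A row exists for every (sequence, t) with ``t-np >= 1``,
    ``t+G+nf-1 <= T`` and every cell of
    ``{t-np..t-1, t, t+G..t+G+nf-1}`` observed; ``position_filter``
    (1-based target times) restricts the harvested targets.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    data = panel.data if isinstance(panel, SequencePanel) else np.asarray(panel)
    n, T = data.shape
    offs = np.concatenate(
        [np.arange(-np_past, 0), np.arange(G, G + nf_future)]
    ).astype(int)
    lo, hi = np_past + 1, T - G - nf_future + 1  # 1-based target bounds
    ts = np.arange(lo, hi + 1)
    if position_filter is not None:
        ts = ts[np.isin(ts, np.asarray(list(position_filter)))]
    p = offs.size
    if ts.size == 0:
        empty = np.empty((0, p), dtype=np.int32)
        return TrainingWindowSet(empty, np.empty(0, np.int32), np.empty(0, int),
                                 np.empty(0, int), G, np_past, nf_future)
    idx = (ts - 1)[:, None] + offs[None, :]          # (nt, p) 0-based
    sub = data[:, idx]                               # (n, nt, p)
    ysub = data[:, ts - 1]                           # (n, nt)
    ok = (sub >= 0).all(axis=2) & (ysub >= 0)
    rows, which = np.nonzero(ok)
    return TrainingWindowSet(
        X=sub[ok].astype(np.int32),
        y=ysub[ok].astype(np.int32),
        t=ts[which],
        rows=rows,
        G=G,
        np_past=np_past,
        nf_future=nf_future,
    )


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _FittedStep:
    """A fitted imputation model plus the window shape it expects."""

    __slots__ = ("model", "np_used", "nf_used", "kind", "uses_cov")

    def __init__(self, model, np_used, nf_used, kind, uses_cov=False):
        self.model = model
        self.np_used = np_used
        self.nf_used = nf_used
        self.kind = kind
        self.uses_cov = uses_cov


class _MictEngine:
    """One imputation pass over a panel; shared by MICT and MICT-timing.

    ``radius=None`` reproduces plain MICT (one model per remaining gap
    length, windows unrestricted in time); an integer radius activates
    the timing variant: one model per target position, trained only on
    windows whose target lies within ``radius`` of it.
    """

    def __init__(self, panel: SequencePanel, np_past: int, nf_future: int,
                 model_kind: str, min_train_rows: int, protect: bool,
                 lam: float, n_trees: int, radius: int | None,
                 fit_log: list[dict]):
        if np_past + nf_future < 1:
            raise ValueError("np_past + nf_future must be >= 1")
        self.panel = panel
        self.data0 = panel.data            # original incomplete data (training source)
        self.K = panel.n_states
        self.T = panel.T
        self.np_past = np_past
        self.nf_future = nf_future
        self.model_kind = model_kind
        self.min_train_rows = min_train_rows
        self.protect = protect
        self.lam = lam
        self.n_trees = n_trees
        self.radius = radius
        self.fit_log = fit_log
        self._all_observed = self.data0[self.data0 >= 0]
        self._cache: dict[tuple, _FittedStep] = {}
        # fixed covariates enter the primary and reduced-window fits;
        # the Markov/marginal fallback rungs stay sequence-only
        self._cov = (None if panel.covariates is None
                     else _m.encode_covariates(panel.covariates))

    # -- model fitting with the sparse-training fallback ladder -----------
    def _new_model(self, rng):
        if self.model_kind == "multinomial":
            return _m.MultinomialModel(self.K, protect=self.protect, lam=self.lam)
        if self.model_kind == "random_forest":
            return _m.RandomForestModel(
                self.K, n_trees=self.n_trees,
                seed=int(rng.integers(2**31 - 1)))
        raise ValueError(f"unknown model kind {self.model_kind!r}")

    def _position_filter(self, t: int, radius: int) -> set[int]:
        return set(range(max(1, t - radius), min(self.T, t + radius) + 1))

    def _fit_step(self, G: int, np_w: int, nf_w: int, stage: str,
                  target_t: int | None, rng) -> _FittedStep:
        """Fit one imputation model (cached per distinct step within the
        pass), descending the fallback ladder when the training set is
        too small.  ``target_t`` (1-based) activates the timing
        position filter."""
        key = (stage, G, np_w, nf_w, target_t)
        if key in self._cache:
            return self._cache[key]
        step = self._fit_step_uncached(G, np_w, nf_w, stage, target_t, rng)
        self._cache[key] = step
        return step

    def _fit_step_uncached(self, G: int, np_w: int, nf_w: int, stage: str,
                           target_t: int | None, rng) -> _FittedStep:
        def windows(npw, nfw, radius):
            pf = None
            if radius is not None and target_t is not None:
                pf = self._position_filter(target_t, radius)
            return build_training_windows(self.data0, G, npw, nfw, pf)

        radius = self.radius
        tw = windows(np_w, nf_w, radius)
        widened = 0
        if radius is not None:
            # timing ladder rung 0: widen the time frame before touching
            # the window shape
            while tw.y.size < self.min_train_rows and radius < self.T - 1:
                radius += 1
                widened += 1
                tw = windows(np_w, nf_w, radius)
        fallback = None
        if tw.y.size < self.min_train_rows:
            np_r, nf_r = min(np_w, 1), min(nf_w, 1)
            if (np_r, nf_r) != (np_w, nf_w):
                tw2 = windows(np_r, nf_r, radius)
                if tw2.y.size >= self.min_train_rows:
                    tw, fallback = tw2, "reduced_window"
                    np_w, nf_w = np_r, nf_r
        if fallback is None and tw.y.size < self.min_train_rows:
            # pooled first-order Markov over all adjacent observed pairs
            a, b = self.data0[:, :-1], self.data0[:, 1:]
            if np_w >= 1:
                ok = (a >= 0) & (b >= 0)
                X, y = a[ok][:, None], b[ok]
                np_w, nf_w = 1, 0
            else:
                ok = (a >= 0) & (b >= 0)
                X, y = b[ok][:, None], a[ok]
                np_w, nf_w = 0, 1
            if y.size >= self.min_train_rows:
                step = _FittedStep(self._new_model(rng).fit(X, y), np_w, nf_w,
                                   "markov1")
                self._log(stage, G, np_w, nf_w, int(y.size), "markov1",
                          target_t, widened)
                return step
            fallback = "marginal"
        if fallback == "marginal" or (tw.y.size < self.min_train_rows):
            model = _m.MarginalModel(self.K).fit(self._all_observed)
            self._log(stage, G, 0, 0, int(self._all_observed.size),
                      "marginal", target_t, widened)
            return _FittedStep(model, 0, 0, "marginal")
        extra = None if self._cov is None else self._cov[tw.rows]
        model = self._new_model(rng).fit(tw.X, tw.y, extra=extra)
        self._log(stage, G, np_w, nf_w, int(tw.y.size),
                  fallback or "none", target_t, widened)
        return _FittedStep(model, np_w, nf_w, "primary" if fallback is None
                           else fallback, uses_cov=self._cov is not None)

    def _log(self, stage, G, npw, nfw, rows, fallback, target_t, widened):
        self.fit_log.append({
            "stage": stage, "G": G, "np": npw, "nf": nfw, "rows": rows,
            "fallback": fallback, "target_t": target_t,
            "radius_widened": widened,
        })

    # -- generic batched draw ---------------------------------------------
    def _impute_cells(self, W: np.ndarray, step: _FittedStep,
                      items: list[list[int]], rng) -> None:
        """Impute the leftmost missing cell (index ``s``) of each item
        ``[s, e, row]`` using ``step``'s window shape; writes into W."""
        if step.kind == "marginal":
            proba = step.model.predict_proba(np.zeros((len(items), 1)))
        else:
            X = np.empty((len(items), step.np_used + step.nf_used),
                         dtype=np.int32)
            for k, (s, e, i) in enumerate(items):
                past = W[i, s - step.np_used:s] if step.np_used else \
                    np.empty(0, np.int32)
                fut = W[i, e + 1:e + 1 + step.nf_used] if step.nf_used else \
                    np.empty(0, np.int32)
                X[k] = np.concatenate([past, fut])
            extra = None
            if step.uses_cov:
                extra = self._cov[[i for _, _, i in items]]
            proba = step.model.predict_proba(X, extra=extra)
        draws = _m.draw_states(proba, rng)
        for k, (s, e, i) in enumerate(items):
            W[i, s] = draws[k]

    # -- stages ------------------------------------------------------------
    def run(self, W: np.ndarray, gaps, rng) -> None:
        internal = [g for g in gaps if g.gap_type == "internal"]
        initial = [g for g in gaps if g.gap_type == "initial"]
        terminal = [g for g in gaps if g.gap_type == "terminal"]
        edge = [g for g in gaps if g.gap_type in
                ("left_hand", "right_hand", "both_hand")]
        self._stage_internal(W, internal, rng)
        self._stage_initial(W, initial, rng)
        self._stage_terminal(W, terminal, rng)
        self._stage_edge(W, edge, rng)

    def _stage_internal(self, W, gaps, rng, stage="internal",
                        windows=None) -> None:
        """Decreasing-remaining-length sweep.  ``windows`` optionally
        maps a gap to its (np', nf') pair (edge-constrained stage)."""
        active = []
        for g in gaps:
            npw, nfw = (windows[id(g)] if windows is not None
                        else (self.np_past, self.nf_future))
            active.append([g.start - 1, g.end - 1, g.seq_index, npw, nfw])
        while active:
            Gmax = max(e - s + 1 for s, e, *_ in active)
            batch = [a for a in active if a[1] - a[0] + 1 == Gmax]
            groups: dict[tuple, list[list[int]]] = {}
            for s, e, i, npw, nfw in batch:
                key = (npw, nfw, (s + 1) if self.radius is not None else None)
                groups.setdefault(key, []).append([s, e, i])
            for (npw, nfw, tpos), items in sorted(
                    groups.items(), key=lambda kv: kv[0][:2] + (kv[0][2] or 0,)):
                step = self._fit_step(Gmax, npw, nfw, stage, tpos, rng)
                self._impute_cells(W, step, items, rng)
            for a in active:
                if a[1] - a[0] + 1 == Gmax:
                    a[0] += 1
            active = [a for a in active if a[0] <= a[1]]

    def _stage_initial(self, W, gaps, rng) -> None:
        # future predictors; past-only presets fall back to their past
        # window size since the future is the only side available
        k = self.nf_future if self.nf_future >= 1 else self.np_past
        for g in gaps:
            for t0 in range(g.end - 1, g.start - 2, -1):  # far right to left
                avail = 0
                j = t0 + 1
                while j < self.T and W[g.seq_index, j] >= 0 and avail < k:
                    avail += 1
                    j += 1
                kk = max(1, avail)
                step = self._fit_step(
                    1, 0, kk, "initial",
                    (t0 + 1) if self.radius is not None else None, rng)
                self._impute_cells(W, step, [[t0, t0, g.seq_index]], rng)

    def _stage_terminal(self, W, gaps, rng) -> None:
        k = self.np_past if self.np_past >= 1 else self.nf_future
        for g in gaps:
            for t0 in range(g.start - 1, g.end):  # far left to right
                avail = 0
                j = t0 - 1
                while j >= 0 and W[g.seq_index, j] >= 0 and avail < k:
                    avail += 1
                    j -= 1
                kk = max(1, avail)
                step = self._fit_step(
                    1, kk, 0, "terminal",
                    (t0 + 1) if self.radius is not None else None, rng)
                self._impute_cells(W, step, [[t0, t0, g.seq_index]], rng)

    def _stage_edge(self, W, gaps, rng) -> None:
        windows = {}
        for g in gaps:
            if g.gap_type == "left_hand":
                windows[id(g)] = (g.n_before, self.nf_future)
            elif g.gap_type == "right_hand":
                windows[id(g)] = (self.np_past, g.n_after)
            else:
                windows[id(g)] = (g.n_before, g.n_after)
        self._stage_internal(W, gaps, rng, stage="edge", windows=windows)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class MICTImputer(TransformerMixin, BaseEstimator):
    """MICT gap imputer with a scikit-learn transformer surface.

    Parameters
    ----------
    np_past, nf_future : int
        Predictor-window sizes before / after the gap.
    predictors : str, optional
        Named preset overriding (np_past, nf_future): one of
        ``P1`` (1,0), ``PF1`` (1,1), ``P5`` (5,0), ``PF5`` (5,5).
    model : {"multinomial", "random_forest"}
    min_train_rows : int
        Below this training size the sparse-data fallback ladder kicks
        in (reduced window, then pooled first-order Markov, then
        marginal draw); every fallback is recorded in the fit log.
    protect : bool
        Perfect-prediction protection for the multinomial model.
    lam : float
        L2 penalty of the multinomial model.
    n_trees : int
        Forest size for ``model="random_forest"``.
    random_state : int, optional
    """

    _method_name = "mict"

    def __init__(self, np_past: int = 5, nf_future: int = 5,
                 predictors: str | None = None,
                 model: str = "multinomial", min_train_rows: int = 10,
                 protect: bool = True, lam: float = 1e-3, n_trees: int = 100,
                 random_state: int | None = None):
        self.np_past = np_past
        self.nf_future = nf_future
        self.predictors = predictors
        self.model = model
        self.min_train_rows = min_train_rows
        self.protect = protect
        self.lam = lam
        self.n_trees = n_trees
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _window(self) -> tuple[int, int]:
        if self.predictors is not None:
            try:
                return PRESETS[self.predictors]
            except KeyError:
                raise ValueError(f"unknown preset {self.predictors!r}")
        return self.np_past, self.nf_future

    def _engine(self, panel: SequencePanel, fit_log: list[dict]) -> _MictEngine:
        npw, nfw = self._window()
        return _MictEngine(panel, npw, nfw, self.model, self.min_train_rows,
                           self.protect, self.lam, self.n_trees,
                           radius=None, fit_log=fit_log)

    def _as_panel(self, X) -> SequencePanel:
        if isinstance(X, SequencePanel):
            return X
        from .panel import Alphabet
        X = np.asarray(X, dtype=np.int32)
        K = int(X.max()) + 1
        return SequencePanel(X, Alphabet(tuple(str(i) for i in range(K))))

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y=None):
        panel = self._as_panel(X)
        npw, nfw = self._window()
        if npw < 0 or nfw < 0 or npw + nfw < 1:
            raise ValueError("need np_past, nf_future >= 0 and their sum >= 1")
        self.n_features_in_ = panel.T
        self.fit_log_ = []
        return self

    def transform(self, X) -> np.ndarray:
        """Single imputation; returns the completed code matrix."""
        res = self.impute(self._as_panel(X), M=1)
        return res.panels[0].data

    # -- multiple imputation -------------------------------------------------
    def impute(self, panel: SequencePanel, M: int = 1) -> MultipleImputation:
        """Run the full staging M independent times."""
        if M < 1:
            raise ValueError("M must be >= 1")
        if panel.is_complete():
            raise ValueError("nothing to impute: the panel is complete")
        npw, nfw = self._window()
        gaps = classify_gaps(panel, npw, nfw)
        fit_log: list[dict] = []
        panels = []
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(M):
            rng = np.random.default_rng(child)
            engine = self._make_engine(panel, fit_log)
            W = panel.data.copy()
            engine.run(W, gaps, rng)
            assert (W[panel.data >= 0] == panel.data[panel.data >= 0]).all()
            panels.append(panel.copy(data=W))
        self.fit_log_ = fit_log
        return MultipleImputation(
            panels=panels, method=self._method_name,
            config=self.get_params(), seed=self.random_state,
            fit_log=fit_log)

    def _make_engine(self, panel, fit_log):
        return self._engine(panel, fit_log)


def mict_impute(panel: SequencePanel, M: int = 1, **params) -> MultipleImputation:
    """Functional wrapper over :class:`MICTImputer`."""
    return MICTImputer(**params).impute(panel, M=M)
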