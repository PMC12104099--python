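"""Missing-data generators (amputation) for complete panels.

Three mechanisms mirror common longitudinal missingness:

* **MAR gaps** — a gap opens at the first wave with probability 0.06;
  later, with probability 0.20 when the previous (true) state is in a
  configured high-risk list and 0.03 otherwise; an open gap continues
  with probability 0.66 per step.
* **Attrition** — from just past the middle of the sequence, dropout
  triggers with probability 0.10 after a high-risk state and 0.015
  otherwise; once triggered, everything to the end is missing.
* **Small sample** — subsample 200 sequences, then apply the MAR model.

All mechanisms first protect a randomly chosen 40% of sequences, which
stay fully observed, and regenerate any sequence whose missing fraction
exceeds 75% (the redo rule).  Hazards are evaluated against the *true*
pre-amputation states: the generator sees complete data.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from .panel import MISSING, SequencePanel

_MAX_REDO = 1000


class _BaseAmputer(BaseEstimator):
    """Shared protection / redo scaffolding."""

    def _resolve_high_risk(self, panel: SequencePanel) -> np.ndarray:
        if self.high_risk_states is None:
            raise ValueError("high_risk_states must be configured")
        codes = []
        for s in self.high_risk_states:
            if s not in panel.alphabet.states:
                raise ValueError(f"high-risk state {s!r} not in alphabet")
            codes.append(panel.alphabet.code(s))
        mask = np.zeros(panel.n_states, dtype=bool)
        mask[codes] = True
        return mask

    def _protected(self, n: int, rng: np.random.Generator) -> np.ndarray:
        k = math.ceil(self.complete_fraction * n)
        prot = np.zeros(n, dtype=bool)
        if k:
            prot[rng.choice(n, size=k, replace=False)] = True
        return prot

    def _mask_with_redo(self, row: np.ndarray, rng, make_mask) -> np.ndarray:
        mask = make_mask(row, rng)
        if not self.enforce_redo:
            return mask
        tries = 0
        while mask.mean() > self.max_missing_fraction:
            tries += 1
            if tries > _MAX_REDO:
                raise RuntimeError(
                    "redo rule exceeded 1000 attempts for one sequence; "
                    "check the amputation probabilities")
            mask = make_mask(row, rng)
        return mask

    def _run(self, panel: SequencePanel, make_mask,
             rng: np.random.Generator) -> SequencePanel:
        if not panel.is_complete():
            raise ValueError("amputation requires a complete panel")
        high = self._resolve_high_risk(panel)
        self._high = high
        out = panel.data.copy()
        prot = self._protected(panel.n, rng)
        for i in range(panel.n):
            if prot[i]:
                continue
            mask = self._mask_with_redo(panel.data[i], rng, make_mask)
            out[i, mask] = MISSING
        return SequencePanel(out, panel.alphabet, ids=panel.ids,
                             covariates=panel.covariates, validate=False)

    def fit(self, X, y=None):
        return self

    def fit_transform(self, X, y=None):
        return self.transform(X)


class MARAmputer(_BaseAmputer):
    """State-dependent gap generator (MAR mechanism).

    Parameters hold the published hazards; ``high_risk_states`` (labels)
    is required — it plays the role of the study's predefined
    missingness-prone state list.
    """

    def __init__(self, high_risk_states=None, p_init_gap: float = 0.06,
                 p_start_hi: float = 0.20, p_start_lo: float = 0.03,
                 p_continue: float = 0.66, complete_fraction: float = 0.40,
                 max_missing_fraction: float = 0.75,
                 enforce_redo: bool = True, random_state: int | None = None):
        self.high_risk_states = high_risk_states
        self.p_init_gap = p_init_gap
        self.p_start_hi = p_start_hi
        self.p_start_lo = p_start_lo
        self.p_continue = p_continue
        self.complete_fraction = complete_fraction
        self.max_missing_fraction = max_missing_fraction
        self.enforce_redo = enforce_redo
        self.random_state = random_state

    def _make_mask(self, row: np.ndarray, rng) -> np.ndarray:
        T = row.size
        mask = np.zeros(T, dtype=bool)
        u = rng.random(T)
        in_gap = u[0] < self.p_init_gap
        mask[0] = in_gap
        for t in range(1, T):
            if in_gap:
                in_gap = u[t] < self.p_continue
            else:
                p = self.p_start_hi if self._high[row[t - 1]] else self.p_start_lo
                in_gap = u[t] < p
            mask[t] = in_gap
        return mask

    def transform(self, X) -> SequencePanel:
        panel = X if isinstance(X, SequencePanel) else SequencePanel.from_dataframe(X)
        rng = np.random.default_rng(self.random_state)
        return self._run(panel, self._make_mask, rng)


class AttritionAmputer(_BaseAmputer):
    """Permanent-dropout generator: monotone missing suffixes."""

    def __init__(self, high_risk_states=None, p_attr_hi: float = 0.10,
                 p_attr_lo: float = 0.015, complete_fraction: float = 0.40,
                 max_missing_fraction: float = 0.75,
                 enforce_redo: bool = True, random_state: int | None = None):
        self.high_risk_states = high_risk_states
        self.p_attr_hi = p_attr_hi
        self.p_attr_lo = p_attr_lo
        self.complete_fraction = complete_fraction
        self.max_missing_fraction = max_missing_fraction
        self.enforce_redo = enforce_redo
        self.random_state = random_state

    def _make_mask(self, row: np.ndarray, rng) -> np.ndarray:
        T = row.size
        mask = np.zeros(T, dtype=bool)
        first = math.ceil(T / 2) + 1  # 1-based first eligible trigger time
        for t in range(first, T + 1):
            p = self.p_attr_hi if self._high[row[t - 2]] else self.p_attr_lo
            if rng.random() < p:
                mask[t - 1:] = True
                break
        return mask

    def transform(self, X) -> SequencePanel:
        panel = X if isinstance(X, SequencePanel) else SequencePanel.from_dataframe(X)
        rng = np.random.default_rng(self.random_state)
        return self._run(panel, self._make_mask, rng)


class SmallSampleAmputer(MARAmputer):
    """Uniform subsample of ``small_n`` sequences followed by MAR
    amputation (protection applies within the subsample)."""

    def __init__(self, high_risk_states=None, small_n: int = 200,
                 p_init_gap: float = 0.06, p_start_hi: float = 0.20,
                 p_start_lo: float = 0.03, p_continue: float = 0.66,
                 complete_fraction: float = 0.40,
                 max_missing_fraction: float = 0.75,
                 enforce_redo: bool = True, random_state: int | None = None):
        super().__init__(high_risk_states=high_risk_states,
                         p_init_gap=p_init_gap, p_start_hi=p_start_hi,
                         p_start_lo=p_start_lo, p_continue=p_continue,
                         complete_fraction=complete_fraction,
                         max_missing_fraction=max_missing_fraction,
                         enforce_redo=enforce_redo, random_state=random_state)
        self.small_n = small_n

    def transform(self, X) -> SequencePanel:
        panel = X if isinstance(X, SequencePanel) else SequencePanel.from_dataframe(X)
        if panel.n < self.small_n:
            raise ValueError(
                f"panel has {panel.n} sequences, fewer than small_n={self.small_n}")
        rng = np.random.default_rng(self.random_state)
        rows = rng.choice(panel.n, size=self.small_n, replace=False)
        sub = SequencePanel(panel.data[rows], panel.alphabet,
                            ids=[panel.ids[i] for i in rows],
                            covariates=None if panel.covariates is None
                            else panel.covariates.iloc[rows],
                            validate=False)
        return self._run(sub, self._make_mask, rng)


# -- functional wrappers ------------------------------------------------------

def ampute_mar(panel: SequencePanel, high_risk_states, rng=None,
               **params) -> SequencePanel:
    amp = MARAmputer(high_risk_states=high_risk_states, **params)
    if rng is not None:
        amp.random_state = rng
    return amp.transform(panel)


def ampute_attrition(panel: SequencePanel, high_risk_states, rng=None,
                     **params) -> SequencePanel:
    amp = AttritionAmputer(high_risk_states=high_risk_states, **params)
    if rng is not None:
        amp.random_state = rng
    return amp.transform(panel)


def ampute_small_sample(panel: SequencePanel, high_risk_states, rng=None,
                        **params) -> SequencePanel:
    amp = SmallSampleAmputer(high_risk_states=high_risk_states, **params)
    if rng is not None:
        amp.random_state = rng
    return amp.transform(panel)
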