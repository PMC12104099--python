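"""Synthetic state-sequence panels.

Markov-chain generators emulating the archetypes of real life-course
panels: near-constant calendar-time trajectories (civil status),
volatile ones (health satisfaction), strongly process-time-heterogeneous
ones (cohabitation / professional careers), monthly school-to-work
sequences with seasonal transition spikes, and near-irreversible ordered
processes.  Presets are calibrated to the published transition
percentages (about 1.6% for the most stable archetype up to 36.5% for
the most volatile), not to any proprietary microdata.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .panel import MISSING, Alphabet, SequencePanel


@dataclasses.dataclass
class GeneratorSpec:
    """Markov generator: initial distribution plus per-time transition rule.

    ``transition`` is either a single row-stochastic matrix (time
    homogeneous) or a callable ``t -> matrix`` giving the matrix used
    for the step into 1-based time ``t`` (t = 2..T).
    """

    n: int
    T: int
    states: tuple[str, ...]
    init: np.ndarray
    transition: np.ndarray | Callable[[int], np.ndarray]

    def matrix_at(self, t: int) -> np.ndarray:
        P = self.transition(t) if callable(self.transition) else self.transition
        return np.asarray(P, dtype=float)

    def validate(self) -> None:
        K = len(self.states)
        init = np.asarray(self.init, dtype=float)
        if init.shape != (K,) or not np.isclose(init.sum(), 1.0):
            raise ValueError("initial distribution must be a length-K simplex vector")
        for t in range(2, self.T + 1):
            P = self.matrix_at(t)
            if P.shape != (K, K) or (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError(f"transition matrix at t={t} is not row-stochastic")


def generate_panel(spec: GeneratorSpec, rng: np.random.Generator) -> SequencePanel:
    """Simulate a complete panel from a :class:`GeneratorSpec`."""
    spec.validate()
    K = len(spec.states)
    data = np.empty((spec.n, spec.T), dtype=np.int32)
    init = np.asarray(spec.init, dtype=float)
    data[:, 0] = rng.choice(K, size=spec.n, p=init)
    for t in range(2, spec.T + 1):
        P = spec.matrix_at(t)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(spec.n)
        data[:, t - 1] = np.argmax(cum[data[:, t - 2]] >= u[:, None], axis=1)
    return SequencePanel(data, Alphabet(spec.states))


def _sticky_matrix(K: int, stay: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Row-stochastic matrix with constant stay probability and moves
    distributed over the other states (uniformly unless weighted)."""
    P = np.full((K, K), 0.0)
    for i in range(K):
        w = np.ones(K) if weights is None else weights.copy()
        w[i] = 0.0
        w = w / w.sum()
        P[i] = (1.0 - stay) * w
        P[i, i] = stay
    return P


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: transition pair whose occurrences the seasonal preset concentrates on
#: the spike months (multiples of 12)
SEASONAL_PAIR = ("school", "employment")
SEASONAL_SPIKES = tuple(range(12, 73, 12))


def preset(name: str, n: int = 2000) -> GeneratorSpec:
    """Named generator archetypes.

    ``stable_calendar``      5 states, T=21, ~1.6% transitions.
    ``volatile_calendar``    4 ordered states, T=21, ~36.5% transitions.
    ``process_time_strong``  4 states, T=26, early-life transition burst.
    ``seasonal_monthly``     6 states, T=72, school-to-employment moves
                             concentrated at months 12, 24, ..., 72.
    ``ordered_irreversible`` 4 states, forward-only transitions (ANV=1).
    ``small_template``       4 states, T=15, moderate mixing; intended to
                             be subsampled for small-sample experiments.
    """
    if name == "stable_calendar":
        K = 5
        return GeneratorSpec(
            n=n, T=21,
            states=("married", "separated", "divorced", "widowed", "single"),
            init=np.array([0.55, 0.01, 0.06, 0.03, 0.35]),
            transition=_sticky_matrix(K, stay=1.0 - 0.016),
        )
    if name == "volatile_calendar":
        K = 4
        # ordered satisfaction scale; moves favour adjacent levels
        P = np.zeros((K, K))
        stay = 1.0 - 0.365
        for i in range(K):
            w = np.array([1.0 / (1 + abs(i - j)) ** 2 if j != i else 0.0 for j in range(K)])
            P[i] = (1 - stay) * w / w.sum()
            P[i, i] = stay
        return GeneratorSpec(
            n=n, T=21,
            states=("low", "average", "high", "very_high"),
            init=np.array([0.04, 0.11, 0.49, 0.36]),
            transition=P,
        )
    if name == "process_time_strong":
        K = 4
        early = _sticky_matrix(K, stay=0.80)
        late = _sticky_matrix(K, stay=0.985)
        return GeneratorSpec(
            n=n, T=26,
            states=("education", "full_time", "part_time", "non_working"),
            init=np.array([0.85, 0.09, 0.03, 0.03]),
            transition=lambda t: early if t <= 10 else late,
        )
    if name == "seasonal_monthly":
        states = ("school", "further_edu", "higher_edu", "training",
                  "employment", "joblessness")
        K = len(states)
        base = _sticky_matrix(K, stay=0.99)
        # off the spikes, school almost never feeds employment directly
        i_school, i_emp = 0, 4
        base[i_school] = 0.0
        base[i_school, i_school] = 0.99
        base[i_school, 1] = 0.004
        base[i_school, 2] = 0.003
        base[i_school, 3] = 0.002
        base[i_school, i_emp] = 0.0005
        base[i_school, 5] = 0.0005
        spike = base.copy()
        spike[i_school] = 0.0
        spike[i_school, i_school] = 0.55
        spike[i_school, 1] = 0.04
        spike[i_school, 2] = 0.03
        spike[i_school, 3] = 0.02
        spike[i_school, i_emp] = 0.33
        spike[i_school, 5] = 0.03
        spikes = set(SEASONAL_SPIKES)
        return GeneratorSpec(
            n=n, T=72, states=states,
            init=np.array([0.55, 0.12, 0.05, 0.08, 0.12, 0.08]),
            transition=lambda t: spike if t in spikes else base,
        )
    if name == "ordered_irreversible":
        states = ("stage1", "stage2", "stage3", "stage4")
        K = 4
        P = np.eye(K)
        h = 0.08  # forward hazard
        for i in range(K - 1):
            P[i, i] = 1 - h
            P[i, i + 1] = h
        return GeneratorSpec(
            n=n, T=26, states=states,
            init=np.array([1.0, 0.0, 0.0, 0.0]),
            transition=P,
        )
    if name == "small_template":
        K = 4
        return GeneratorSpec(
            n=n, T=15,
            states=("A", "B", "C", "D"),
            init=np.full(K, 0.25),
            transition=_sticky_matrix(K, stay=0.85),
        )
    raise ValueError(f"unknown preset {name!r}")


def toy_two_sequence_panel() -> SequencePanel:
    """Two length-15 sequences over {A, B} used by the worked example
    tests of the window builder: sequence 1 has one internal gap at
    times 4-7; sequence 2 is fully observed (synthetic idealization)."""
    A, B, M = 0, 1, MISSING
    s1 = [A, A, B, M, M, M, M, B, A, A, B, B, A, A, B]
    s2 = [A, B, A, A, B, B, A, B, B, A, A, B, A, B, A]
    return SequencePanel(
        np.array([s1, s2], dtype=np.int32),
        Alphabet(("A", "B")),
        ids=["seq1", "seq2"],
    )
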