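"""Estimands for completed panels: timing, duration, sequencing.

* **timing** — the proportion of sequences in state *s* at time *t*.
* **duration** — the mean spell (maximal-run) length of each state,
  pooled over sequences.
* **sequencing** — the relative risk of the transition a→b,
  ``RR = P(next=b | cur=a) / P(next=b | cur!=a)``, pooled over time.

All three are functions of per-sequence counts, so bootstrap variances
over sequences are computed by resampling a weight vector against a
precomputed row-statistics matrix instead of re-scanning the panel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import SequencePanel

#: sentinel used to cap an infinite relative risk
RR_CAP = 1e6


@dataclasses.dataclass
class RowStats:
    """Per-sequence sufficient statistics; ``matrix`` is (n, d)."""

    matrix: np.ndarray
    K: int
    T: int

    # column layout offsets
    @property
    def _off(self):
        K, T = self.K, self.T
        timing = 0
        time_in = timing + K * T
        spells = time_in + K
        trans = spells + K
        from_tot = trans + K * K
        return timing, time_in, spells, trans, from_tot


def row_statistics(panel: SequencePanel) -> RowStats:
    if not panel.is_complete():
        raise ValueError("estimands are defined on complete panels")
    data = panel.data
    n, T = data.shape
    K = panel.n_states
    onehot = (data[:, :, None] == np.arange(K)).astype(np.float64)  # (n,T,K)
    timing = onehot.transpose(0, 2, 1).reshape(n, K * T)
    time_in = onehot.sum(axis=1)                                    # (n,K)
    starts = np.ones((n, T), dtype=bool)
    starts[:, 1:] = data[:, 1:] != data[:, :-1]
    spells = np.zeros((n, K))
    np.add.at(spells, (np.nonzero(starts)[0], data[starts]), 1.0)
    a, b = data[:, :-1], data[:, 1:]
    trans = np.zeros((n, K * K))
    rows = np.repeat(np.arange(n), T - 1)
    np.add.at(trans, (rows, (a * K + b).ravel()), 1.0)
    from_tot = onehot[:, :-1, :].sum(axis=1)                        # (n,K)
    return RowStats(np.hstack([timing, time_in, spells, trans, from_tot]),
                    K, T)


def estimand_index(panel: SequencePanel) -> pd.DataFrame:
    """Tidy index of every estimand of a panel's shape (family, state,
    state2, time; time and state2 empty where not applicable)."""
    rows = []
    for s in panel.alphabet.states:
        for t in range(1, panel.T + 1):
            rows.append(("timing", s, "", t))
    for s in panel.alphabet.states:
        rows.append(("duration", s, "", 0))
    for s1 in panel.alphabet.states:
        for s2 in panel.alphabet.states:
            if s1 != s2:
                rows.append(("sequencing", s1, s2, 0))
    return pd.DataFrame(rows, columns=["family", "state", "state2", "time"])


def _estimates_from_agg(agg: np.ndarray, rs: RowStats,
                        n_eff: float) -> np.ndarray:
    K, T = rs.K, rs.T
    o_timing, o_time_in, o_spells, o_trans, o_from = rs._off
    out = []
    out.append(agg[o_timing:o_timing + K * T] / n_eff)              # timing
    time_in = agg[o_time_in:o_time_in + K]
    spells = agg[o_spells:o_spells + K]
    with np.errstate(divide="ignore", invalid="ignore"):
        dur = np.where(spells > 0, time_in / np.maximum(spells, 1), np.nan)
    out.append(dur)
    C = agg[o_trans:o_trans + K * K].reshape(K, K)
    from_tot = agg[o_from:o_from + K]
    total_from = from_tot.sum()
    rr = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            denom_to = from_tot[i]
            other_from = total_from - from_tot[i]
            other_to_j = C[:, j].sum() - C[i, j]
            if denom_to == 0 or other_from == 0:
                continue  # conditioning event unobserved
            p1 = C[i, j] / denom_to
            p0 = other_to_j / other_from
            if p0 == 0:
                rr[i, j] = RR_CAP if p1 > 0 else np.nan
            else:
                rr[i, j] = p1 / p0
    out.append(rr[~np.eye(K, dtype=bool)])
    return np.concatenate(out)


def estimands(panel: SequencePanel,
              families: tuple[str, ...] = ("timing", "duration", "sequencing")
              ) -> pd.DataFrame:
    """All estimand point estimates of a complete panel (tidy frame)."""
    rs = row_statistics(panel)
    agg = rs.matrix.sum(axis=0)
    est = _estimates_from_agg(agg, rs, float(panel.n))
    df = estimand_index(panel)
    df["estimate"] = est
    return df[df["family"].isin(families)].reset_index(drop=True)


def timing_estimands(panel: SequencePanel) -> pd.DataFrame:
    return estimands(panel, families=("timing",))


def duration_estimands(panel: SequencePanel) -> pd.DataFrame:
    """Mean spell lengths; states without spells carry NaN (the
    "no spells" sentinel — deliberately not 0.0)."""
    return estimands(panel, families=("duration",))


def sequencing_estimands(panel: SequencePanel) -> pd.DataFrame:
    """Pooled transition relative risks; infinite RRs are capped at
    :data:`RR_CAP`, undefined conditioning events are NaN."""
    return estimands(panel, families=("sequencing",))


def bootstrap_variance(panel: SequencePanel, estimand_fn=None, B: int = 1000,
                       rng: np.random.Generator | None = None,
                       families: tuple[str, ...] = ("timing", "duration",
                                                    "sequencing")
                       ) -> pd.DataFrame:
    """Bootstrap (over sequences) variance of each estimand.

    With the default ``estimand_fn=None`` the fast sufficient-statistics
    path is used; otherwise ``estimand_fn(panel) -> 1-D array`` is
    re-evaluated on every resampled panel.  Returns the tidy estimand
    frame with ``estimate``, ``variance`` and an ``unreliable`` flag for
    estimands undefined in more than half of the replicates.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    n = panel.n
    if estimand_fn is not None:
        reps = np.stack([
            np.asarray(estimand_fn(panel.copy(
                data=panel.data[rng.integers(0, n, size=n)])), dtype=float)
            for _ in range(B)])
        var = np.nanvar(reps, axis=0, ddof=1)
        frac_nan = np.isnan(reps).mean(axis=0)
        return pd.DataFrame({"variance": var, "unreliable": frac_nan > 0.5})
    rs = row_statistics(panel)
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
    agg = W @ rs.matrix                      # (B, d)
    reps = np.stack([_estimates_from_agg(agg[b], rs, float(n))
                     for b in range(B)])
    df = estimand_index(panel)
    base = rs.matrix.sum(axis=0)
    df["estimate"] = _estimates_from_agg(base, rs, float(n))
    with np.errstate(invalid="ignore"):
        df["variance"] = np.nanvar(reps, axis=0, ddof=1)
    df["unreliable"] = np.isnan(reps).mean(axis=0) > 0.5
    return df[df["family"].isin(families)].reset_index(drop=True)
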