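"""Empirical recovery of the amputation-model constants.

Given the complete panel and its amputated counterpart, these helpers
re-estimate the generator's hazards from the realized missingness
masks: the initial gap rate, the state-dependent gap-start hazards, the
gap continuation rate, and the attrition trigger hazard.  Used for
generator validation.
"""

from __future__ import annotations

import math

import numpy as np

from .panel import SequencePanel


def _hr_mask(panel: SequencePanel, high_risk_states) -> np.ndarray:
    codes = [panel.alphabet.code(s) for s in high_risk_states]
    return np.isin(panel.data, codes)


def mar_hazard_stats(complete: SequencePanel, amputed: SequencePanel,
                     high_risk_states) -> dict[str, dict[str, float]]:
    """Empirical MAR-generator rates with the event counts behind them.

    Returns per-rate ``{"value": .., "n": ..}``: ``init_gap`` (first
    cell missing), ``start_hi`` / ``start_lo`` (gap opening at t>1 after
    a high-/low-risk true state, among steps not already in a gap) and
    ``continuation`` (gap persisting one more step).
    """
    m = amputed.missing_mask()
    hr = _hr_mask(complete, high_risk_states)
    prev_in_gap = m[:, :-1]
    at_risk = ~prev_in_gap
    prev_hr = hr[:, :-1]
    started = m[:, 1:]
    n_hi = int((at_risk & prev_hr).sum())
    n_lo = int((at_risk & ~prev_hr).sum())
    n_gap = int(prev_in_gap.sum())
    return {
        "init_gap": {"value": float(m[:, 0].mean()), "n": int(m.shape[0])},
        "start_hi": {"value": float(started[at_risk & prev_hr].mean()),
                     "n": n_hi},
        "start_lo": {"value": float(started[at_risk & ~prev_hr].mean()),
                     "n": n_lo},
        "continuation": {"value": float(started[prev_in_gap].mean()),
                         "n": n_gap},
    }


def attrition_hazard_stats(complete: SequencePanel, amputed: SequencePanel,
                           high_risk_states) -> dict[str, dict[str, float]]:
    """Empirical attrition trigger hazards after high- and low-risk
    states, among eligible steps (second half, not yet triggered)."""
    m = amputed.missing_mask()
    hr = _hr_mask(complete, high_risk_states)
    T = complete.T
    first = math.ceil(T / 2) + 1  # 1-based first eligible trigger time
    counts = {"hi": [0, 0], "lo": [0, 0]}
    for t in range(first, T + 1):
        eligible = ~m[:, t - 2]  # monotone mask: no earlier trigger
        for key, sel in (("hi", hr[:, t - 2]), ("lo", ~hr[:, t - 2])):
            at_risk = eligible & sel
            counts[key][0] += int((m[:, t - 1] & at_risk).sum())
            counts[key][1] += int(at_risk.sum())
    return {
        "trigger_hi": {"value": counts["hi"][0] / counts["hi"][1],
                       "n": counts["hi"][1]},
        "trigger_lo": {"value": counts["lo"][0] / counts["lo"][1],
                       "n": counts["lo"][1]},
    }
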