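"""Core data model for categorical state-sequence panels.

A panel holds ``n`` individual trajectories observed at ``T`` equally
spaced time points.  Cells are integer state codes into an
:class:`Alphabet`; missing cells carry the sentinel :data:`MISSING` and
structural padding (for ragged input) carries :data:`PAD`.  All public
time indices are 1-based inclusive; internal storage is 0-based.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel code for a missing (imputable) cell
MISSING: int = -1
#: sentinel code for structural padding (void, never imputed, excluded
#: from every statistic)
PAD: int = -2

_GAP_TYPES = ("internal", "initial", "terminal", "left_hand", "right_hand", "both_hand")


@dataclasses.dataclass(frozen=True)
class Alphabet:
    """Ordered set of state labels plus the reserved missing token."""

    states: tuple[str, ...]
    missing_token: str = ""

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("alphabet needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("alphabet states must be distinct")
        if self.missing_token in self.states:
            raise ValueError("missing token cannot be a state label")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))

    def __len__(self) -> int:
        return len(self.states)

    def code(self, label: str) -> int:
        return self.states.index(label)

    def label(self, code: int) -> str:
        if code == MISSING:
            return self.missing_token
        return self.states[code]


@dataclasses.dataclass(frozen=True)
class Gap:
    """One maximal run of missing cells in one sequence.

    ``start``/``end`` are 1-based inclusive time indices.  ``n_before`` /
    ``n_after`` count contiguous observed cells immediately flanking the
    gap, capped at the predictor-window sizes used for classification.
    """

    seq_index: int
    start: int
    end: int
    n_before: int
    n_after: int
    gap_type: str

    def __post_init__(self) -> None:
        if self.gap_type not in _GAP_TYPES:
            raise ValueError(f"unknown gap type {self.gap_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class SequencePanel:
    """An n x T matrix of categorical state codes with an alphabet.

    Parameters
    ----------
    data : array-like of int, shape (n, T)
        State codes in ``0..len(alphabet)-1``, or :data:`MISSING` /
        :data:`PAD`.
    alphabet : Alphabet
    ids : sequence of identifiers, optional
    covariates : pandas.DataFrame, optional
        Fixed (time-constant) categorical covariates, one row per
        sequence.
    validate : bool
        When true (default) reject panels containing a sequence without
        a single observed cell.
    """

    def __init__(
        self,
        data,
        alphabet: Alphabet,
        ids: Sequence | None = None,
        covariates: pd.DataFrame | None = None,
        validate: bool = True,
    ) -> None:
        data = np.asarray(data, dtype=np.int32)
        if data.ndim != 2:
            raise ValueError("panel data must be 2-D (sequences x time)")
        n, T = data.shape
        if n < 1 or T < 2:
            raise ValueError("panel needs n >= 1 sequences and T >= 2 time points")
        bad = (data >= len(alphabet)) | ((data < 0) & (data != MISSING) & (data != PAD))
        if bad.any():
            raise ValueError("panel contains codes outside the alphabet")
        if validate:
            empty = ~((data >= 0).any(axis=1))
            if empty.any():
                which = np.flatnonzero(empty)[:5].tolist()
                raise ValueError(
                    f"sequences with no observed cell are not allowed: rows {which}"
                )
        self.data = data
        self.alphabet = alphabet
        self.ids = list(ids) if ids is not None else list(range(n))
        if len(self.ids) != n:
            raise ValueError("ids length must match number of sequences")
        if covariates is not None and len(covariates) != n:
            raise ValueError("covariates must have one row per sequence")
        self.covariates = covariates

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def observed_mask(self) -> np.ndarray:
        return self.data >= 0

    def is_complete(self) -> bool:
        return not (self.data == MISSING).any()

    def copy(self, data: np.ndarray | None = None) -> "SequencePanel":
        return SequencePanel(
            self.data.copy() if data is None else data,
            self.alphabet,
            ids=self.ids,
            covariates=self.covariates,
            validate=False,
        )

    # -- conversion / IO --------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        labels = np.empty(self.data.shape, dtype=object)
        for c, s in enumerate(self.alphabet.states):
            labels[self.data == c] = s
        labels[self.data == MISSING] = self.alphabet.missing_token
        labels[self.data == PAD] = "*"
        return pd.DataFrame(
            labels, index=self.ids, columns=[f"t{t}" for t in range(1, self.T + 1)]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        alphabet: Alphabet | None = None,
        missing_tokens: Iterable[str] = ("", "NA"),
        validate: bool = True,
    ) -> "SequencePanel":
        raw = df.astype(object).where(df.notna(), "")
        cells = raw.to_numpy(dtype=object)
        missing_tokens = set(missing_tokens)
        if alphabet is None:
            seen = sorted(
                {
                    str(v)
                    for v in cells.ravel()
                    if str(v) not in missing_tokens and str(v) != "*"
                }
            )
            alphabet = Alphabet(tuple(seen), missing_token="")
        lookup = {s: i for i, s in enumerate(alphabet.states)}
        data = np.empty(cells.shape, dtype=np.int32)
        for i in range(cells.shape[0]):
            for j in range(cells.shape[1]):
                v = str(cells[i, j])
                if v in missing_tokens or v == alphabet.missing_token:
                    data[i, j] = MISSING
                elif v == "*":
                    data[i, j] = PAD
                else:
                    try:
                        data[i, j] = lookup[v]
                    except KeyError:
                        raise ValueError(f"unknown state label {v!r} at row {i}")
        return cls(data, alphabet, ids=list(df.index), validate=validate)

    @classmethod
    def read_csv(cls, path, alphabet: Alphabet | None = None, **kw) -> "SequencePanel":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        return cls.from_dataframe(df, alphabet=alphabet, **kw)

    @classmethod
    def read_long_csv(
        cls, path, id_col="id", time_col="time", state_col="state", **kw
    ) -> "SequencePanel":
        """Read (id, time, state) long format and pivot to wide."""
        long = pd.read_csv(path, dtype={state_col: str}, keep_default_na=False)
        wide = long.pivot(index=id_col, columns=time_col, values=state_col)
        wide = wide.reindex(sorted(wide.columns), axis=1)
        return cls.from_dataframe(wide, **kw)


# ---------------------------------------------------------------------------
# Gap detection and typology
# ---------------------------------------------------------------------------

def classify_gaps(panel: SequencePanel, np_past: int, nf_future: int) -> list[Gap]:
    """Detect maximal missing runs and classify them into the six types.

    ``np_past``/``nf_future`` are the predictor-window sizes: a gap is
    *internal* when at least ``np_past`` contiguous observed cells
    precede it and ``nf_future`` follow it; deficits on either side map
    to the left-/right-/both-hand types; gaps touching the sequence
    edges are *initial* / *terminal*.
    """
    if np_past < 0 or nf_future < 0 or np_past + nf_future < 1:
        raise ValueError("need np_past >= 0, nf_future >= 0, np_past + nf_future >= 1")
    gaps: list[Gap] = []
    data = panel.data
    T = panel.T
    for i in range(panel.n):
        row = data[i]
        if not (row >= 0).any():
            raise ValueError(
                f"sequence {panel.ids[i]!r} (row {i}) is fully missing"
            )
        j = 0
        while j < T:
            if row[j] != MISSING:
                j += 1
                continue
            start = j
            while j < T and row[j] == MISSING:
                j += 1
            end = j - 1  # 0-based inclusive
            # contiguous observed counts, capped at window sizes
            nb = 0
            k = start - 1
            while k >= 0 and row[k] >= 0 and nb < np_past:
                nb += 1
                k -= 1
            na = 0
            k = end + 1
            while k < T and row[k] >= 0 and na < nf_future:
                na += 1
                k += 1
            if start == 0:
                gtype = "initial"
            elif end == T - 1:
                gtype = "terminal"
            else:
                short_before = nb < np_past
                short_after = na < nf_future
                if short_before and short_after:
                    gtype = "both_hand"
                elif short_before:
                    gtype = "left_hand"
                elif short_after:
                    gtype = "right_hand"
                else:
                    gtype = "internal"
            gaps.append(Gap(i, start + 1, end + 1, nb, na, gtype))
    return gaps


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def transition_rate(panel: SequencePanel) -> float:
    """Fraction of adjacent observed pairs whose states differ."""
    a = panel.data[:, :-1]
    b = panel.data[:, 1:]
    both = (a >= 0) & (b >= 0)
    n_pairs = int(both.sum())
    if n_pairs == 0:
        raise ValueError("no adjacent observed pair in the panel")
    return float(((a != b) & both).sum() / n_pairs)


def _row_spell_states(row: np.ndarray) -> np.ndarray:
    """States of the maximal runs of one fully observed row."""
    keep = row >= 0
    row = row[keep]
    if row.size == 0:
        return row
    starts = np.ones(row.size, dtype=bool)
    starts[1:] = row[1:] != row[:-1]
    return row[starts]


def anv(panel: SequencePanel) -> float:
    """Mean over sequences of the average number of visits (ANV).

    Per sequence: number of spells divided by the number of distinct
    visited states; 1 when no state is ever revisited, up to T/2 for a
    strict two-state alternation.  Defined on complete panels only.
    """
    if not panel.is_complete():
        raise ValueError("ANV is defined on complete panels only")
    vals = []
    for i in range(panel.n):
        spells = _row_spell_states(panel.data[i])
        vals.append(spells.size / np.unique(spells).size)
    return float(np.mean(vals))


def spell_stats(panel: SequencePanel, state: str) -> float | None:
    """Mean length of maximal runs of ``state``, pooled over sequences.

    Returns ``None`` (a "no spells" sentinel, deliberately distinct from
    0.0) when the state never occurs.
    """
    if state not in panel.alphabet.states:
        raise ValueError(f"state {state!r} not in alphabet")
    if not panel.is_complete():
        raise ValueError("spell statistics require a complete panel")
    code = panel.alphabet.code(state)
    n_spells = 0
    total = 0
    for i in range(panel.n):
        row = panel.data[i]
        spells = _row_spell_states(row)
        n_spells += int((spells == code).sum())
        total += int((row == code).sum())
    if n_spells == 0:
        return None
    return total / n_spells
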