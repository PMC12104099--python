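import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqimp import (Alphabet, MISSING, SequencePanel, anv, classify_gaps,
                    spell_stats, transition_rate)


class TestAlphabet:
    def test_rejects_duplicate_states(self):
        with pytest.raises(ValueError):
            Alphabet(("A", "A"))

    def test_rejects_missing_token_in_states(self):
        with pytest.raises(ValueError):
            Alphabet(("A", "NA"), missing_token="NA")


class TestClassifyGaps:
    def test_internal_gap_worked_example(self, make_panel):
        # missing 4-7 in a length-15 sequence with 2 observed on each side
        p = make_panel(["AAB....BAABBAAB"], states=("A", "B"))
        gaps = classify_gaps(p, 2, 2)
        assert len(gaps) == 1
        g = gaps[0]
        assert (g.start, g.end, g.gap_type) == (4, 7, "internal")
        assert (g.n_before, g.n_after) == (2, 2)

    def test_fully_observed_gives_empty_list(self, make_panel):
        p = make_panel(["ABABABABABABABA"], states=("A", "B"))
        assert classify_gaps(p, 2, 2) == []

    @pytest.mark.parametrize("row,expected", [
        ("...BAABBAABBAAB", "initial"),          # missing 1-3
        ("AABBAABBAABB...", "terminal"),          # missing 13-15
        ("A..BAABBAABBAAB", "left_hand"),         # 1 observed before
        ("AABBAABBAABB..B", "right_hand"),        # 1 observed after
        ("A..BAABBAABB..B", None),                # two gaps, tested below
    ])
    def test_gap_typology(self, make_panel, row, expected):
        p = make_panel([row], states=("A", "B"))
        gaps = classify_gaps(p, 2, 2)
        if expected is None:
            assert sorted(g.gap_type for g in gaps) == ["left_hand", "right_hand"]
        else:
            assert [g.gap_type for g in gaps] == [expected]

    def test_both_hand_gap(self, make_panel):
        p = make_panel(["A..B..AABBAABBA"], states=("A", "B"))
        types = {(g.start, g.gap_type) for g in classify_gaps(p, 2, 2)}
        # second gap has 1 observed before (truncated by first gap) and
        # plenty after -> left_hand; first has 1 before and 1 after
        assert (2, "both_hand") in types
        assert (5, "left_hand") in types

    def test_gaps_partition_missing_cells(self, make_panel, rng):
        data = rng.integers(0, 2, size=(20, 15)).astype(np.int32)
        mask = rng.random((20, 15)) < 0.3
        mask[:, 0] = False  # keep one observed cell per row
        data[mask] = MISSING
        p = SequencePanel(data, Alphabet(("A", "B")))
        gaps = classify_gaps(p, 2, 2)
        cells = set()
        for g in gaps:
            for t in range(g.start, g.end + 1):
                assert (g.seq_index, t) not in cells
                cells.add((g.seq_index, t))
        missing = {(i, t + 1) for i, t in zip(*np.nonzero(mask))}
        assert cells == missing

    def test_fully_missing_sequence_rejected(self):
        data = np.array([[0, 1, 0], [MISSING, MISSING, MISSING]], dtype=np.int32)
        p = SequencePanel(data, Alphabet(("A", "B")), validate=False)
        with pytest.raises(ValueError, match="row 1"):
            classify_gaps(p, 1, 1)

    def test_zero_window_rejected(self, make_panel):
        p = make_panel(["A.B"], states=("A", "B"))
        with pytest.raises(ValueError):
            classify_gaps(p, 0, 0)


class TestStatistics:
    def test_transition_rate_constant_and_alternating(self, make_panel):
        assert transition_rate(make_panel(["AAAA"])) == 0.0
        assert transition_rate(make_panel(["ABAB"])) == 1.0

    def test_transition_rate_enumeration(self, make_panel):
        # A,A,B: 2 adjacent pairs, 1 change
        assert transition_rate(make_panel(["AAB"])) == pytest.approx(0.5)

    def test_anv_bounds_and_examples(self, make_panel):
        assert anv(make_panel(["AAAA"])) == 1.0
        assert anv(make_panel(["ABABAB"])) == 3.0  # L/2 for strict alternation
        assert anv(make_panel(["AABBA"])) == pytest.approx(1.5)

    def test_anv_requires_complete(self, make_panel):
        with pytest.raises(ValueError):
            anv(make_panel(["A.B"]))

    def test_spell_stats(self, make_panel):
        p = make_panel(["AAB"])
        assert spell_stats(p, "A") == 2.0
        assert spell_stats(p, "B") == 1.0
        assert spell_stats(make_panel(["ABAB"]), "A") == 1.0

    def test_spell_stats_absent_state_is_sentinel(self, make_panel):
        p = make_panel(["AAAA"], states=("A", "B"))
        assert spell_stats(p, "B") is None

    def test_spell_stats_unknown_state(self, make_panel):
        with pytest.raises(ValueError):
            spell_stats(make_panel(["AAB"]), "Z")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 3, size=(12, 9)).astype(np.int32)
        p = SequencePanel(data, Alphabet(("A", "B", "C")))
        perm = rng.permutation(12)
        q = SequencePanel(data[perm], Alphabet(("A", "B", "C")))
        assert transition_rate(p) == pytest.approx(transition_rate(q))
        assert anv(p) == pytest.approx(anv(q))
        assert 1.0 <= anv(p) <= p.T / 2


class TestIO:
    def test_wide_csv_round_trip(self, tmp_path, make_panel):
        p = make_panel(["AAB.BA", "BB..AA"], states=("A", "B"))
        path = tmp_path / "panel.csv"
        p.to_csv(path)
        q = SequencePanel.read_csv(path, alphabet=p.alphabet, validate=True)
        assert np.array_equal(p.data, q.data)
        assert q.alphabet.states == ("A", "B")

    def test_long_csv_reader(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "id,time,state\n1,1,A\n1,2,B\n2,1,B\n2,2,\n")
        p = SequencePanel.read_long_csv(path)
        assert p.data[0].tolist() == [0, 1]
        assert p.data[1].tolist() == [1, MISSING]

    def test_empty_and_na_both_missing(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("id,t1,t2,t3\nx,A,,B\ny,NA,A,B\n")
        p = SequencePanel.read_csv(path)
        assert (p.data == MISSING).sum() == 2

    def test_rejects_fully_missing_row_at_load(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("id,t1,t2\nx,A,B\ny,,\n")
        with pytest.raises(ValueError):
            SequencePanel.read_csv(path)
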