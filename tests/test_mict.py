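import numpy as np
import pytest

from seqimp import (MICTImputer, SequencePanel, build_training_windows,
                    mict_impute, toy_two_sequence_panel)
from seqimp.mict import PRESETS


class TestTrainingWindows:
    def test_worked_example_sequence_counts(self):
        panel = toy_two_sequence_panel()
        tw = build_training_windows(panel, G=4, np_past=2, nf_future=2)
        # gapped sequence contributes exactly one window...
        s1 = tw.rows == 0
        assert s1.sum() == 1
        # ...predicting t=10 from times 8, 9, 14, 15
        assert tw.t[s1][0] == 10
        idx = np.nonzero(s1)[0][0]
        expect = panel.data[0, [7, 8, 13, 14]]
        assert np.array_equal(tw.X[idx], expect)
        assert tw.y[idx] == panel.data[0, 9]
        # the fully observed sequence contributes 8 windows (t = 3..10)
        assert (tw.rows == 1).sum() == 8
        assert sorted(tw.t[tw.rows == 1]) == list(range(3, 11))

    def test_no_window_fits_when_too_short(self, make_panel):
        p = make_panel(["ABAB"], states=("A", "B"))
        tw = build_training_windows(p, G=2, np_past=2, nf_future=2)
        assert tw.y.size == 0

    def test_position_filter_subsets(self, small_panel):
        full = build_training_windows(small_panel, 2, 1, 1)
        part = build_training_windows(small_panel, 2, 1, 1,
                                      position_filter={5, 6})
        assert part.y.size < full.y.size
        assert set(part.t) <= {5, 6}

    def test_presets(self):
        assert PRESETS == {"P1": (1, 0), "PF1": (1, 1),
                           "P5": (5, 0), "PF5": (5, 5)}


def _alternating_panel(n=40, T=12):
    """Period-2 panels of both phases: the state at t is determined by
    either neighbour."""
    rows = []
    for i in range(n):
        phase = i % 2
        rows.append([(t + phase) % 2 for t in range(T)])
    return np.array(rows, dtype=np.int32)


class TestMictImputation:
    def test_complete_panel_is_an_error(self, make_panel):
        with pytest.raises(ValueError, match="nothing to impute"):
            mict_impute(make_panel(["ABAB"], states=("A", "B")), M=1)

    def test_observed_cells_never_altered(self, small_panel, rng):
        from seqimp import MARAmputer
        inc = MARAmputer(high_risk_states=["A", "B"], random_state=0
                         ).transform(small_panel)
        res = MICTImputer(predictors="PF1", random_state=1).impute(inc, M=3)
        obs = inc.data >= 0
        for p in res.panels:
            assert np.array_equal(p.data[obs], inc.data[obs])
            assert p.is_complete()

    def test_multiple_imputations_reproducible(self, small_panel):
        from seqimp import MARAmputer
        inc = MARAmputer(high_risk_states=["A"], random_state=0
                         ).transform(small_panel)
        r1 = MICTImputer(predictors="PF1", random_state=7).impute(inc, M=3)
        r2 = MICTImputer(predictors="PF1", random_state=7).impute(inc, M=3)
        assert all(np.array_equal(a.data, b.data)
                   for a, b in zip(r1.panels, r2.panels))
        # imputations are exchangeable draws, not copies of each other
        assert any(not np.array_equal(r1.panels[0].data, p.data)
                   for p in r1.panels[1:])

    def test_periodic_truth_recovered(self):
        from seqimp.panel import Alphabet, MISSING
        data = _alternating_panel()
        truth = data.copy()
        data[3, 5] = MISSING
        data[8, 4:7] = MISSING
        panel = SequencePanel(data, Alphabet(("A", "B")))
        res = MICTImputer(np_past=1, nf_future=1, random_state=3
                          ).impute(panel, M=1)
        assert np.array_equal(res.panels[0].data, truth)

    def test_shared_model_across_equal_length_gaps(self, make_panel):
        # one length-4 and one length-2 internal gap: lengths 4,3,2,1 are
        # each fit once; the reduced length-4 gap and the length-2 gap
        # share the G=2 and G=1 models
        p = make_panel(["AAB....BAABBAAB",
                        "ABAA..BBAABBABA",
                        "ABAABABBAABBABA"], states=("A", "B"))
        imp = MICTImputer(np_past=2, nf_future=2, random_state=0)
        res = imp.impute(p, M=1)
        internal = [f for f in res.fit_log if f["stage"] == "internal"]
        assert [f["G"] for f in internal] == [4, 3, 2, 1]

    def test_initial_gap_imputed_right_to_left(self):
        # deterministic cyclic chain: X_t = (X_{t+1} - 1) mod 3 so the
        # backward model is an exact rule; recovery proves the
        # right-to-left order
        from seqimp.panel import Alphabet, MISSING
        T, n = 10, 60
        rows = [[(t + i) % 3 for t in range(T)] for i in range(n)]
        data = np.array(rows, dtype=np.int32)
        truth = data.copy()
        data[0, :3] = MISSING
        data[1, :2] = MISSING
        panel = SequencePanel(data, Alphabet(("A", "B", "C")))
        res = MICTImputer(np_past=1, nf_future=1, random_state=5
                          ).impute(panel, M=1)
        assert np.array_equal(res.panels[0].data, truth)

    def test_terminal_gap_imputed_left_to_right(self):
        from seqimp.panel import Alphabet, MISSING
        T, n = 10, 60
        rows = [[(t + i) % 3 for t in range(T)] for i in range(n)]
        data = np.array(rows, dtype=np.int32)
        truth = data.copy()
        data[0, -3:] = MISSING
        panel = SequencePanel(data, Alphabet(("A", "B", "C")))
        res = MICTImputer(np_past=1, nf_future=1, random_state=5
                          ).impute(panel, M=1)
        assert np.array_equal(res.panels[0].data, truth)

    def test_past_only_preset_still_handles_initial_gaps(self, small_panel):
        from seqimp.panel import MISSING
        data = small_panel.data.copy()
        data[0, :2] = MISSING
        panel = small_panel.copy(data=data)
        res = MICTImputer(predictors="P1", random_state=0).impute(panel, M=1)
        assert res.panels[0].is_complete()

    def test_edge_constrained_windows_reduced(self, make_panel):
        # one observed cell before the gap under (2,2): np reduced to 1
        p = make_panel(["A..BAABBAABBAAB",
                        "ABAABABBAABBABA",
                        "BABBABAABBAABBA"], states=("A", "B"))
        imp = MICTImputer(np_past=2, nf_future=2, random_state=0)
        res = imp.impute(p, M=1)
        edge = [f for f in res.fit_log if f["stage"] == "edge"]
        assert edge and all(f["np"] == 1 and f["nf"] == 2 for f in edge)

    def test_marginal_recovery_on_markov_panel(self, markov_panel):
        from seqimp import MARAmputer
        inc = MARAmputer(high_risk_states=["A"], random_state=2
                         ).transform(markov_panel)
        res = MICTImputer(predictors="PF1", random_state=3).impute(inc, M=1)
        comp = res.panels[0]
        freq = np.bincount(comp.data.ravel(), minlength=3) / comp.data.size
        truth = np.bincount(markov_panel.data.ravel(), minlength=3) \
            / markov_panel.data.size
        se = np.sqrt(truth * (1 - truth) / comp.data.size)
        assert np.all(np.abs(freq - truth) < 3 * se + 1e-3)

    def test_sklearn_surface(self, small_panel):
        from seqimp.panel import MISSING
        data = small_panel.data.copy()
        data[0, 5] = MISSING
        imp = MICTImputer(predictors="PF1", random_state=0)
        params = imp.get_params()
        assert params["predictors"] == "PF1"
        out = imp.fit(data).transform(data)
        assert out.shape == data.shape
        assert (out >= 0).all()


def test_completes_at_missingness_cap(small_panel):
    """Stress: amputation pushed to the 75% per-sequence cap still
    yields complete imputations."""
    from seqimp import MARAmputer
    amp = MARAmputer(high_risk_states=["A", "B", "C", "D"],
                     p_start_hi=0.5, p_continue=0.9, enforce_redo=True,
                     random_state=0)
    inc = amp.transform(small_panel)
    assert inc.missing_mask().mean(axis=1).max() <= 0.75
    res = MICTImputer(predictors="PF1", random_state=1).impute(inc, M=1)
    assert res.panels[0].is_complete()
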