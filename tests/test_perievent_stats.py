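"""Pointwise scan, epoch rule, window averaging, factorial window models."""

import numpy as np
import pandas as pd
import pytest

from oscimp import perievent_stats as pes
from oscimp.datatypes import PeriEventTensor

OFFSETS = np.round(np.arange(-13, 14) / 25.0, 10)  # 27-point 25 Hz grid incl. 0


def make_tensors(
    n_rats=3,
    n_trials=36,
    outcome_effect=0.0,
    effect_window=(0.0, 0.3),
    noise=0.5,
    seed=0,
    with_velocity=True,
):
    """Per-rat tensors with a known outcome effect injected in one interval.

    Outcomes cycle correct/incorrect/premature and previous reward alternates,
    so every factorial cell is populated. The effect raises 'correct' trials
    by ``outcome_effect`` inside ``effect_window``.
    """
    rng = np.random.default_rng(seed)
    in_win = (OFFSETS >= effect_window[0]) & (OFFSETS <= effect_window[1])
    tensors = []
    outcomes = np.array(["correct", "incorrect", "premature"])
    for r in range(n_rats):
        ec = pd.DataFrame(
            {
                "channel_id": [f"r{r}e{i}" for i in range(4)],
                "rat_id": f"rat{r}",
                "region": ["PRL", "PRL", "NAcbC", "NAcbC"],
            }
        )
        tc = pd.DataFrame(
            {
                "trial_id": [f"rat{r}:{i}" for i in range(n_trials)],
                "outcome": outcomes[np.arange(n_trials) % 3],
                "prev_rewarded": (np.arange(n_trials) % 2).astype(bool),
            }
        )
        values = noise * rng.standard_normal((n_trials, 4, OFFSETS.size))
        values += 0.2 * rng.standard_normal()  # rat-level intercept
        boost = (tc["outcome"] == "correct").to_numpy()[:, None, None]
        values += outcome_effect * boost * in_win[None, None, :]
        vel = (
            np.abs(1 + 0.3 * rng.standard_normal((n_trials, OFFSETS.size)))
            if with_velocity
            else None
        )
        tensors.append(
            PeriEventTensor(
                values=values,
                offsets=OFFSETS,
                trial_covariates=tc,
                electrode_covariates=ec,
                velocity=vel,
                measure="gamma60",
                event="wait_start",
            )
        )
    return tensors


class TestFindEpochs:
    TIMES = np.round(np.arange(0, 76) / 25 - 1, 10)

    def _p(self, sig_idx):
        p = np.ones(76)
        p[sig_idx] = 1e-6
        return p

    def test_seven_point_run_is_shortest_reportable(self):
        """(n-1)/25 must exceed 0.2 s: 7 points = 0.24 s passes."""
        epochs = pes.find_epochs(self.TIMES, self._p(range(10, 17)))
        assert len(epochs) == 1
        start, end = epochs[0]
        assert end - start == pytest.approx(0.24)

    def test_six_point_run_rejected(self):
        """6 points = exactly 0.20 s, not strictly longer -> no epoch."""
        assert pes.find_epochs(self.TIMES, self._p(range(10, 16))) == []

    def test_p_equal_to_threshold_not_significant(self):
        p = np.full(76, pes.POINTWISE_THRESHOLD)
        assert pes.find_epochs(self.TIMES, p) == []

    def test_two_separated_epochs_both_found(self):
        epochs = pes.find_epochs(
            self.TIMES, self._p(list(range(5, 13)) + list(range(40, 50)))
        )
        assert len(epochs) == 2

    def test_run_reaching_array_end_is_closed(self):
        epochs = pes.find_epochs(self.TIMES, self._p(range(66, 76)))
        assert epochs == [(pytest.approx(self.TIMES[66]), pytest.approx(2.0))]

    def test_threshold_value(self):
        assert pes.POINTWISE_THRESHOLD == pytest.approx(0.01 / 75)
        assert f"{pes.POINTWISE_THRESHOLD:.5f}" == "0.00013"


class TestWindowAverage:
    def test_matches_hand_mean_over_closed_window(self):
        tensors = make_tensors(n_rats=1, n_trials=6, seed=1)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 0.0, 0.2)
        table = pes.window_average(tensors[0], win)
        sel = (OFFSETS >= 0.0) & (OFFSETS <= 0.2)
        assert sel.sum() == 6  # closed interval includes both endpoints
        expected = tensors[0].values[0, 0, sel].mean()
        got = table[(table["trial_id"] == "rat0:0") & (table["channel_id"] == "r0e0")]
        assert got["value"].iloc[0] == pytest.approx(expected)

    def test_velocity_window_mean_carried(self):
        tensors = make_tensors(n_rats=1, n_trials=6, seed=2)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", -0.52, 0.52)
        table = pes.window_average(tensors[0], win)
        expected = tensors[0].velocity[3].mean()
        row = table[table["trial_id"] == "rat0:3"].iloc[0]
        assert row["velocity"] == pytest.approx(expected)

    def test_list_input_concatenates_rats(self):
        tensors = make_tensors(n_rats=2, n_trials=6, seed=3)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 0.0, 0.2)
        table = pes.window_average(tensors, win)
        assert table["rat_id"].nunique() == 2
        assert len(table) == 2 * 6 * 4

    def test_window_outside_grid_rejected(self):
        tensors = make_tensors(n_rats=1, n_trials=6)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 1.5, 2.0)
        with pytest.raises(ValueError):
            pes.window_average(tensors[0], win)


class TestPointwiseScan:
    def test_injected_effect_found_null_factor_clean(self):
        """Outcome epoch overlaps the injected interval; the un-manipulated
        previous-reward factor reports no epochs."""
        tensors = make_tensors(outcome_effect=1.2, effect_window=(0.0, 0.3), seed=4)
        scan = pes.pointwise_scan(tensors)
        assert len(scan.epochs["outcome"]) >= 1
        start, end = scan.epochs["outcome"][0]
        assert start >= -0.1 and end <= 0.42  # within one grid step + smoothing
        assert scan.epochs["prev_rewarded"] == []

    def test_null_tensor_reports_nothing(self):
        tensors = make_tensors(outcome_effect=0.0, seed=5)
        scan = pes.pointwise_scan(tensors)
        assert all(v == [] for v in scan.epochs.values())

    def test_table_covers_grid_and_factors(self):
        tensors = make_tensors(n_rats=2, n_trials=12, seed=6)
        scan = pes.pointwise_scan(tensors)
        assert set(scan.table["factor"]) == {
            "velocity",
            "outcome",
            "prev_rewarded",
            "region",
        }
        assert scan.table.groupby("factor")["time"].count().eq(OFFSETS.size).all()
        assert ((scan.table["p"] >= 0) & (scan.table["p"] <= 1)).all()


class TestWindowedModel:
    def _fit(self, effect, seed, **kw):
        tensors = make_tensors(outcome_effect=effect, effect_window=(0.0, 0.3), seed=seed, **kw)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 0.0, 0.3)
        table = pes.window_average(tensors, win)
        return pes.windowed_model(table, win)

    def test_injected_main_effect_survives_bonferroni(self):
        res = self._fit(1.2, seed=7)
        terms = res.terms.set_index("term")
        assert terms.loc["C(outcome, Sum)", "p_corrected"] < 0.01
        # un-manipulated factor stays clean after correction
        assert terms.loc["C(prev_rewarded, Sum)", "p_corrected"] > 0.05

    def test_bonferroni_is_ninefold(self):
        res = self._fit(0.4, seed=8)
        t = res.terms
        expected = np.minimum(1.0, 9 * t["p"])
        assert np.allclose(t["p_corrected"], expected)

    def test_posthoc_identifies_elevated_level(self):
        res = self._fit(1.2, seed=9)
        ph = res.posthoc["outcome"]
        assert len(ph) == 3  # all pairs of 3 levels
        correct_rows = ph[
            ph["contrast"].str.split(" - ").map(lambda p: "correct" in p)
        ]
        assert (correct_rows["p_adjusted"] < 0.01).all()
        # signed estimates point the right way
        for _, row in correct_rows.iterrows():
            a, b = row["contrast"].split(" - ")
            assert row["estimate"] > 0 if a == "correct" else row["estimate"] < 0

    def test_single_rat_single_channel_falls_back_to_ols(self):
        tensors = make_tensors(n_rats=1, n_trials=24, outcome_effect=0.5, seed=10)
        t = tensors[0]
        solo = PeriEventTensor(
            values=t.values[:, :1, :],
            offsets=t.offsets,
            trial_covariates=t.trial_covariates,
            electrode_covariates=t.electrode_covariates.iloc[:1],
            velocity=t.velocity,
        )
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 0.0, 0.3)
        res = pes.windowed_model(pes.window_average(solo, win), win)
        assert res.fallback == "fixed_effects"

    def test_empty_cell_drops_interactions_with_warning(self):
        tensors = make_tensors(n_rats=2, n_trials=12, seed=11)
        win = pes.AnalysisWindow("w", "wait_start", "gamma60", 0.0, 0.3)
        table = pes.window_average(tensors, win)
        # empty one factorial cell
        table = table[~((table["outcome"] == "premature") & table["prev_rewarded"])]
        with pytest.warns(UserWarning, match="cell"):
            res = pes.windowed_model(table, win)
        assert not res.terms["term"].str.contains(":").any()


class TestPairwiseContrastOracle:
    def test_ols_contrasts_equal_group_mean_differences(self):
        """With a single factor and OLS fallback, each pairwise estimate must
        equal the difference of raw group means (balanced design)."""
        rng = np.random.default_rng(12)
        n = 60
        outcomes = np.array(["correct", "incorrect", "premature"])[np.arange(n) % 3]
        df = pd.DataFrame(
            {
                "value": rng.standard_normal(n)
                + np.where(outcomes == "correct", 1.0, 0.0),
                "outcome": outcomes,
                "prev_rewarded": False,
                "region": "PRL",
                "rat_id": "r0",
                "channel_id": "c0",
            }
        )
        res = pes.windowed_model(df)
        assert res.fallback == "fixed_effects"
        means = df.groupby("outcome")["value"].mean()
        for _, row in res.posthoc["outcome"].iterrows():
            a, b = row["contrast"].split(" - ")
            assert row["estimate"] == pytest.approx(means[a] - means[b])


class TestBuildTensor:
    def test_shapes_alignment_and_drop_count(self):
        fs = 250.0
        n_e = 2
        x = np.tile(np.arange(int(10 * fs)) / fs, (n_e, 1))  # value = t
        events = np.array([3.0, 5.0, 9.8])  # last one has a partial window
        tc = pd.DataFrame(
            {
                "trial_id": ["a", "b", "c"],
                "outcome": ["correct", "premature", "correct"],
                "prev_rewarded": [True, False, True],
            }
        )
        ec = pd.DataFrame(
            {"channel_id": ["c0", "c1"], "rat_id": "r0", "region": ["PRL", "PRL"]}
        )
        vel = np.ones(int(10 * 25.0))
        tens = pes.build_tensor(x, fs, events, tc, ec, velocity_series=vel)
        assert tens.values.shape == (2, 2, 76)
        assert tens.n_dropped == 1
        assert list(tens.trial_covariates["trial_id"]) == ["a", "b"]
        # the series equals time, so values reproduce event + offset
        assert np.allclose(tens.values[0, 0], 3.0 + tens.offsets)
        assert np.allclose(tens.values[1, 1], 5.0 + tens.offsets)
        assert tens.velocity.shape == (2, 76)
        assert np.allclose(tens.velocity, 1.0)
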