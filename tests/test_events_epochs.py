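"""Event streams, epoch extraction, baselines and lag distributions."""

import numpy as np
import pandas as pd
import pytest

from overlapfrp import (
    EventStream,
    Kernel,
    Recording,
    TimeWindow,
    baseline_correct,
    epoch_window_for_participant,
    extract_epochs,
    ifi_summary,
    lag_distribution,
    select_ranks,
)


def stream(rows):
    return EventStream(
        pd.DataFrame(rows, columns=["trial_id", "class", "onset_ms", "rank"])
    )


class TestEventStream:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            stream([(0, "fixation", 300, 1), (0, "fixation", 300, 2)])
        with pytest.raises(ValueError, match="consecutive"):
            stream([(0, "fixation", 300, 1), (0, "fixation", 600, 3)])

    def test_csv_round_trip(self, tmp_path):
        ev = stream([(0, "stimulus", 0, 1), (0, "fixation", 310, 1),
                     (0, "fixation", 600, 2)])
        path = tmp_path / "events.csv"
        ev.to_csv(path)
        back = EventStream.from_csv(path)
        pd.testing.assert_frame_equal(ev.df, back.df)


def impulse_recording(fs=1000.0, n=4000, trial_onsets=None):
    rec = Recording(np.zeros((2, n)), fs, ["oz", "pz"], trial_onsets or {0: 1000.0})
    return rec


class TestExtractEpochs:
    def test_impulse_lands_at_its_lag(self):
        rec = impulse_recording()
        ev = stream([(0, "fixation", 500, 1)])
        # impulse 100 ms after the lock event (abs 1000 + 500 + 100)
        rec.data[0, 1600] = 42.0
        ep = extract_epochs(rec, ev, "fixation", TimeWindow(-250, 600))
        idx = 100 - (-250)
        assert ep.data[0, idx, 0] == 42.0
        assert ep.data[0, idx, 1] == 0.0

    def test_no_lock_events_is_an_error(self):
        rec = impulse_recording()
        ev = stream([(0, "stimulus", 0, 1)])
        with pytest.raises(ValueError, match="no events of lock class"):
            extract_epochs(rec, ev, "fixation", TimeWindow(-250, 600))

    def test_edge_epochs_rejected_and_counted(self):
        rec = impulse_recording(n=2500)
        ev = stream([(0, "fixation", 100, 1), (0, "fixation", 500, 2),
                     (0, "fixation", 1400, 3)])
        # onsets at abs 1100/1500/2400 ms; last one's +600 ms exceeds n=2500
        ep = extract_epochs(rec, ev, "fixation", TimeWindow(-250, 600))
        assert ep.n_epochs == 2
        assert ep.n_rejected == 1

    def test_all_rejected_raises(self):
        rec = impulse_recording(n=300)
        ev = stream([(0, "fixation", 100, 1)])
        with pytest.raises(ValueError, match="rejected"):
            extract_epochs(rec, ev, "fixation", TimeWindow(-250, 600))

    def test_cooccurring_events_recorded_with_lags(self):
        rec = impulse_recording()
        ev = stream([(0, "stimulus", 0, 1), (0, "fixation", 500, 1),
                     (0, "fixation", 800, 2)])
        ep = extract_epochs(rec, ev, "fixation", TimeWindow(-250, 600))
        first = ep.epoch_events(0)
        assert set(first["lag_ms"]) == {-500.0, 0.0, 300.0}
        assert first.loc[first["lag_ms"] == 0, "is_lock"].all()


class TestBaselineCorrect:
    bl = TimeWindow(-200, -100)

    def test_constant_becomes_zero(self):
        k = Kernel(TimeWindow(-250, 600), np.full((851, 2), 3.7))
        out = baseline_correct(k, self.bl)
        assert np.allclose(out.values, 0.0)

    def test_linear_ramp_shifts_by_analytic_mean(self):
        w = TimeWindow(-250, 600)
        t = w.times_ms()
        k = Kernel(w, t[:, None].astype(float))
        out = baseline_correct(k, self.bl)
        # mean of t over [-200, -100] is -150, so output is r(t) + 150
        assert np.allclose(out.values[:, 0], t + 150.0)

    def test_random_epochs_have_zero_baseline_mean(self, mid_epochs):
        out = baseline_correct(mid_epochs, TimeWindow(-200, -100, 200.0))
        m = out.window.mask_ms(-200, -100)
        assert np.allclose(out.data[:, m, :].mean(axis=1), 0.0, atol=1e-12)

    def test_baseline_outside_window_names_both(self):
        k = Kernel(TimeWindow(0, 600), np.zeros((601, 1)))
        with pytest.raises(ValueError,
                           match=r"\[-200, -100\] ms outside window \[0, 600\]"):
            baseline_correct(k, self.bl)


class TestLagDistribution:
    def test_unit_mass_at_single_lag(self):
        rec = impulse_recording(n=6000, trial_onsets={0: 1000.0, 1: 3500.0})
        ev = stream([(t, "fixation", on, r + 1)
                     for t in (0, 1)
                     for r, on in enumerate((400, 700, 1000))])
        ep = extract_epochs(rec, ev, "fixation", TimeWindow(-450, 800),
                            lock_events=ev.subset(
                                ev.df.index[ev.df["rank"] == 2]))
        q = lag_distribution(ep, "fixation", +1)
        assert q.total_mass == pytest.approx(1.0)
        assert q.mass[np.where(q.lags_ms == 300)[0][0]] == pytest.approx(1.0)

    def test_counts_match_brute_force(self, mid_epochs):
        for rel in (-2, -1, 1, 2):
            q = lag_distribution(mid_epochs, "fixation", rel)
            # brute force per epoch
            expected = np.zeros_like(q.mass)
            for i in range(mid_epochs.n_epochs):
                ev = mid_epochs.epoch_events(i)
                lags = np.sort(ev.loc[ev["class"] == "fixation",
                                      "lag_samples"].to_numpy())
                side = lags[lags < 0][::-1] if rel < 0 else lags[lags > 0]
                k = abs(rel) - 1
                if k < side.size:
                    idx = int(side[k]) - q.start_sample
                    if 0 <= idx < expected.size:
                        expected[idx] += 1.0 / mid_epochs.n_epochs
            assert np.allclose(q.mass, expected)
            assert q.total_mass <= 1.0 + 1e-12

    def test_adjacent_mass_sums_to_one_when_always_present(self, mid_epochs):
        # lock ranks 3-9 always have a previous fixation inside the window
        q = lag_distribution(mid_epochs, "fixation", -1)
        assert q.total_mass == pytest.approx(1.0)

    def test_lock_itself_is_unit_mass_at_zero(self, mid_epochs):
        q = lag_distribution(mid_epochs, "fixation", 0)
        assert q.total_mass == pytest.approx(1.0)
        assert q.mean_lag_ms() == 0.0


class TestEpochWindow:
    def test_constant_ifi(self):
        ev = stream([(0, "fixation", 300 + 400 * k, k + 1) for k in range(5)])
        w = epoch_window_for_participant(ev, TimeWindow(-250, 600))
        assert (w.start_ms, w.end_ms) == (-650, 1000)

    def test_tau_rounds_up_to_ten_ms(self):
        # IFIs drawn so mean + sd lands between 400 and 410
        ev = stream(
            [(0, "fixation", on, r + 1)
             for r, on in enumerate(np.cumsum([300, 350, 380, 380, 410]))]
        )
        mean, sd, tau = ifi_summary(ev)
        assert 400 < tau < 410
        w = epoch_window_for_participant(ev, TimeWindow(-250, 600))
        assert (w.start_ms, w.end_ms) == (-660, 1010)
        assert w.n_samples == 1671

    def test_no_ifis_raises(self):
        ev = stream([(0, "fixation", 300, 1)])
        with pytest.raises(ValueError, match="inter-fixation"):
            epoch_window_for_participant(ev, TimeWindow(-250, 600))


class TestSelectRanks:
    def events(self, n_trials=8, n_fix=10):
        rows = []
        for t in range(n_trials):
            rows.append((t, "stimulus", 0, 1))
            rows += [(t, "fixation", 300 + 289 * k, k + 1) for k in range(n_fix)]
        return stream(rows)

    def test_low_equals_high_selects_that_rank(self):
        sel = select_ranks(self.events(), 3, 3, 1, seed=0)
        assert (sel.df["rank"] == 3).all()
        assert len(sel) == 8

    def test_seed_reproducibility(self):
        a = select_ranks(self.events(), 3, 9, 3, seed=42)
        b = select_ranks(self.events(), 3, 9, 3, seed=42)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_draws_stay_in_range_and_unique(self):
        sel = select_ranks(self.events(), 3, 9, 3, seed=1)
        for _, grp in sel.df.groupby("trial_id"):
            ranks = grp["rank"].to_numpy(int)
            assert np.all((ranks >= 3) & (ranks <= 9))
            assert len(ranks) == len(set(ranks)) <= 3

    def test_short_trials_skipped(self):
        ev = self.events(n_trials=3, n_fix=2)  # max rank 2 < low
        with pytest.raises(ValueError, match="no trials"):
            select_ranks(ev, 3, 9, 3, seed=0)
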