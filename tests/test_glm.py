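"""Sparse Toeplitz designs, least-squares deconvolution, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from overlapfrp import (
    ClassConfig,
    EventStream,
    Recording,
    TimeWindow,
    average_epochs,
    bootstrap_variance,
    build_design,
    extract_epochs,
    gram_condition_number,
    solve_glm,
)
from overlapfrp.glm_deconv import _parse_rank_spec

FS = 200.0
STIM_WIN = TimeWindow(-200, 1500, FS)
FIX_WIN = TimeWindow(-200, 800, FS)


def onset_classes(n):
    if n == 1:
        return [ClassConfig("s", "stimulus", STIM_WIN)]
    if n == 2:
        return [ClassConfig("s", "stimulus", STIM_WIN),
                ClassConfig("a1p", "fixation", FIX_WIN)]
    return [ClassConfig("s", "stimulus", STIM_WIN),
            ClassConfig("a1", "fixation", FIX_WIN, ranks=1),
            ClassConfig("a2p", "fixation", FIX_WIN, ranks=">=2")]


class TestRankSpecs:
    @pytest.mark.parametrize("spec,rank,expected", [
        (None, None, True), (1, 1, True), (1, 2, False),
        ("1", 1, True), (">=2", 2, True), (">=2", 1, False),
        ("2+", 5, True), ("3-9", 3, True), ("3-9", 10, False),
        ("3-9", None, False),
    ])
    def test_matching(self, spec, rank, expected):
        assert _parse_rank_spec(spec)(rank) is expected

    def test_unparseable(self):
        with pytest.raises(ValueError):
            _parse_rank_spec("second")


class TestBuildDesign:
    def test_single_event_at_lag_zero_full_window_is_identity(self):
        rec = Recording(np.zeros((1, 3000)), FS, trial_onsets_ms={0: 5000.0})
        ev = EventStream(pd.DataFrame(
            [(0, "stimulus", 0, 1)],
            columns=["trial_id", "class", "onset_ms", "rank"]))
        ep = extract_epochs(rec, ev, "stimulus", STIM_WIN)
        d = build_design(ep, onset_classes(1))
        assert d.shape == (STIM_WIN.n_samples, STIM_WIN.n_samples)
        assert (d.matrix != sp.identity(STIM_WIN.n_samples)).nnz == 0

    def test_three_class_column_count(self, onset_epochs):
        d = build_design(onset_epochs, onset_classes(3))
        assert d.shape[1] == STIM_WIN.n_samples + 2 * FIX_WIN.n_samples

    def test_design_times_truth_reproduces_noiseless_epochs(self, onset_session,
                                                            onset_epochs):
        d = build_design(onset_epochs, onset_classes(3))
        truth = np.vstack([
            onset_session.kernels["stimulus"].values,
            onset_session.kernels["fixation_first"].values,
            onset_session.kernels["fixation_rest"].values,
        ])
        x = onset_epochs.data.reshape(-1, onset_epochs.n_channels)
        assert np.abs(d.matrix @ truth - x).max() < 1e-12

    def test_event_matched_by_two_classes_rejected(self, onset_epochs):
        bad = [ClassConfig("a", "fixation", FIX_WIN),
               ClassConfig("b", "fixation", FIX_WIN, ranks=1)]
        with pytest.raises(ValueError, match="multiple classes"):
            build_design(onset_epochs, bad)

    def test_entries_are_binary_stripes(self, onset_epochs):
        d = build_design(onset_epochs, onset_classes(2))
        assert set(np.unique(d.matrix.data)) == {1.0}


class TestSolveGlm:
    def test_noiseless_full_rank_recovers_all_kernels(self, onset_session,
                                                      onset_epochs):
        d = build_design(onset_epochs, onset_classes(3))
        res = solve_glm(d, onset_epochs)
        for name, key in [("s", "stimulus"), ("a1", "fixation_first"),
                          ("a2p", "fixation_rest")]:
            err = np.abs(res.kernels[name].values
                         - onset_session.kernels[key].values).max()
            assert err < 1e-7
        assert not res.rank_deficient

    def test_one_class_lag_zero_design_equals_average(self, onset_epochs):
        d = build_design(onset_epochs, onset_classes(1))
        res = solve_glm(d, onset_epochs, compute_condition=False)
        av = average_epochs(onset_epochs)
        assert np.abs(res.kernels["s"].values - av.values).max() < 1e-10

    def test_small_random_instance_matches_pseudoinverse(self):
        rng = np.random.default_rng(4)
        n, p = 60, 12
        dense = (rng.uniform(size=(n, p)) < 0.3).astype(float)
        x = rng.normal(size=(n, 2))
        from scipy.sparse.linalg import lsqr

        coef = np.column_stack([
            lsqr(sp.csr_matrix(dense), x[:, c], atol=1e-12, btol=1e-12)[0]
            for c in range(2)
        ])
        expected = np.linalg.pinv(dense) @ x
        assert np.allclose(coef, expected, atol=1e-8)

    def test_dimension_mismatch(self, onset_epochs, mid_epochs):
        d = build_design(onset_epochs, onset_classes(1))
        with pytest.raises(ValueError, match="rows"):
            solve_glm(d, mid_epochs)


class TestGramCondition:
    def test_averaging_design_condition_is_exactly_one(self, onset_epochs):
        d = build_design(onset_epochs, onset_classes(1))
        assert gram_condition_number(d) == 1.0

    def test_orthonormal_design_condition_is_one(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(40, 10)))
        assert gram_condition_number(sp.csr_matrix(q)) == pytest.approx(1.0)

    def test_matches_dense_eigenvalue_ratio(self, onset_epochs):
        d = build_design(onset_epochs, onset_classes(2))
        gram = np.asarray((d.matrix.T @ d.matrix).todense())
        ev = np.linalg.eigvalsh(gram)
        assert gram_condition_number(d) == pytest.approx(ev[-1] / ev[0], rel=1e-8)

    def test_singular_design_reports_infinity(self):
        dense = np.zeros((10, 3))
        dense[:, 0] = 1.0
        dense[:, 1] = 1.0  # duplicated column
        dense[:, 2] = np.arange(10)
        assert gram_condition_number(sp.csr_matrix(dense)) == np.inf


class TestBootstrap:
    def _identical_epochs(self):
        rec = Recording(np.zeros((1, 30000)), FS,
                        trial_onsets_ms={i: 5000.0 + 9000.0 * i for i in range(4)})
        rows = [(i, "stimulus", 0, 1) for i in range(4)]
        ev = EventStream(pd.DataFrame(
            rows, columns=["trial_id", "class", "onset_ms", "rank"]))
        rec.data[0, :] = 1.0
        return extract_epochs(rec, ev, "stimulus", STIM_WIN)

    def test_identical_epochs_zero_variance(self):
        ep = self._identical_epochs()
        rep = bootstrap_variance(ep, onset_classes(1), replications=50, seed=0)
        assert rep.summary["s"] == pytest.approx(0.0, abs=1e-20)

    def test_variance_of_the_mean_for_iid_noise(self):
        # one event per epoch at lag 0, white noise sd sigma: the GLM is the
        # mean and its bootstrap variance approaches sigma^2 (E-1) / E^2
        rng = np.random.default_rng(6)
        sigma, e_n = 3.0, 100
        win = TimeWindow(0, 45, FS)  # 10 samples
        slot = 1000.0
        rec = Recording(
            rng.normal(0, sigma, (1, int(slot * e_n * FS / 1000))), FS,
            trial_onsets_ms={i: 200.0 + slot * i for i in range(e_n)})
        ev = EventStream(pd.DataFrame(
            [(i, "stimulus", 0, 1) for i in range(e_n)],
            columns=["trial_id", "class", "onset_ms", "rank"]))
        ep = extract_epochs(rec, ev, "stimulus", win)
        rep = bootstrap_variance(
            ep, [ClassConfig("s", "stimulus", win)], replications=3000, seed=1)
        expected = sigma**2 * (e_n - 1) / e_n**2
        assert rep.summary["s"] == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self, onset_epochs):
        a = bootstrap_variance(onset_epochs, onset_classes(1), 30, seed=9)
        b = bootstrap_variance(onset_epochs, onset_classes(1), 30, seed=9)
        assert np.array_equal(a.variance["s"], b.variance["s"])

    def test_replications_validated(self, onset_epochs):
        with pytest.raises(ValueError, match="replications"):
            bootstrap_variance(onset_epochs, onset_classes(1), 1)
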