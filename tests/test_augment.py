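"""Channel ranking, augmentation, RMSECV curve and elbow selection."""

import warnings

import numpy as np
import pytest

from aclscal import augment, core
from aclscal.types import (
    ComponentMatrix,
    DegenerateInputError,
    SpectraMatrix,
    WavenumberAxis,
)
from conftest import make_problem


def _spectra(X, wn=None):
    X = np.asarray(X, dtype=float)
    wn = np.asarray(wn, dtype=float) if wn is not None else 100.0 + np.arange(X.shape[1])
    return SpectraMatrix(X, WavenumberAxis(wn))


class TestChannelR2:
    def test_identical_and_constant_channels(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([y, np.full(4, 7.0), -2 * y + 5])
        r2 = augment.channel_r2(_spectra(X), y).r2
        np.testing.assert_allclose(r2, [1.0, 0.0, 1.0], atol=1e-12)

    def test_hand_computed_value(self):
        # corr([1,2,3],[1,2,2]) = sqrt(3)/2, r2 = 0.75
        y = np.array([1.0, 2.0, 3.0])
        X = np.array([[1.0, 5.0], [2.0, 5.0], [2.0, 5.0]])
        r2 = augment.channel_r2(_spectra(X), y).r2
        np.testing.assert_allclose(r2, [0.75, 0.0], atol=1e-12)

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(DegenerateInputError, match="constant"):
            augment.channel_r2(_spectra(X), np.ones(5))


class TestRankCandidates:
    def test_ascending_r2_order(self):
        corr = augment.ChannelCorrelation(np.array([0.9, 0.05, 0.10, 0.5, 0.01, 0.3]))
        axis = WavenumberAxis(np.array([100.0, 101, 102, 103, 104, 105]))
        order = augment.rank_candidates(corr, axis, r2_threshold=0.2, min_spacing=0.0)
        assert order == [4, 1, 2]

    def test_no_candidate_below_threshold(self):
        corr = augment.ChannelCorrelation(np.array([0.5, 0.9]))
        axis = WavenumberAxis(np.array([100.0, 200.0]))
        with pytest.raises(DegenerateInputError):
            augment.rank_candidates(corr, axis, r2_threshold=0.2)

    def test_spacing_suppresses_neighbours(self):
        corr = augment.ChannelCorrelation(np.array([0.01, 0.02]))
        axis = WavenumberAxis(np.array([1000.0, 1002.0]))
        order = augment.rank_candidates(corr, axis, r2_threshold=0.2, min_spacing=100.0)
        assert order == [0]


class TestAugmentMatrix:
    def test_empty_channel_list_is_identity(self, rng):
        A, C, _ = make_problem(rng)
        assert augment.augment_concentration_matrix(C, A, []) is C

    def test_appended_column_equals_channel(self, rng):
        A, C, _ = make_problem(rng, M=1, noise=0.05)
        out = augment.augment_concentration_matrix(C, A, [3])
        assert out.n_components == 2
        np.testing.assert_array_equal(out.values[:, 1], A.intensities[:, 3])
        assert out.column_kinds[1] == "pseudo"
        assert out.source_channels[1] == 3
        assert out.target_column == C.target_column

    def test_collinear_channel_dropped_with_warning(self, rng):
        # a channel that is an exact linear combination of existing columns
        L = 10
        Cv = rng.uniform(0.1, 1.0, (L, 2))
        X = np.column_stack([Cv @ [1.0, 2.0], rng.normal(size=L)])
        A = _spectra(X)
        C = ComponentMatrix(Cv, ("a", "b"))
        with pytest.warns(UserWarning, match="collinear"):
            out = augment.augment_concentration_matrix(C, A, [0])
        assert out.n_components == 2

    def test_overfit_guard(self, rng):
        A, C, _ = make_problem(rng, L=5, M=3, P=10)
        with pytest.raises(DegenerateInputError, match="fewer samples"):
            augment.augment_concentration_matrix(C, A, [0, 1, 2])


def naive_loo_rmsecv(A, C, channels):
    """Independent oracle: explicit per-fold refit loop at one fixed m."""
    C_m = augment.augment_concentration_matrix(C, A, channels)
    L = A.n_samples
    preds = np.empty(L)
    for i in range(L):
        keep = [j for j in range(L) if j != i]
        A_tr, C_tr = A.take(np.array(keep)), C_m.take(np.array(keep))
        A_c, C_c, state = core.mean_center(A_tr, C_tr)
        K = core.fit_cls(C_c, A_c)
        target, _ = core.predict_cls(A.take(np.array([i])), K, state, C_m.target_column)
        preds[i] = target[0]
    return float(np.sqrt(np.mean((preds - C.target_values) ** 2)))


class TestLooRmsecvCurve:
    def test_matches_naive_refit_oracle(self, rng):
        A, C, _ = make_problem(rng, L=10, M=2, P=15, noise=0.02)
        candidates = [14, 7, 3]
        curve = augment.loo_rmsecv_curve(A, C, candidates, m_max=3)
        for m in range(4):
            assert curve[m] == pytest.approx(naive_loo_rmsecv(A, C, candidates[:m]), abs=1e-10)

    def test_noiseless_full_information_curve_starts_at_zero(self, rng):
        A, C, _ = make_problem(rng, L=10, M=3, P=15, noise=0.0)
        curve = augment.loo_rmsecv_curve(A, C, [0, 1], m_max=0)
        assert curve[0] == pytest.approx(0.0, abs=1e-9)

    def test_univariate_toy_hand_check(self):
        # L=4, one analyte, channels proportional to it: LOO error 0
        c = np.array([[1.0], [2.0], [3.0], [5.0]])
        A = _spectra(np.hstack([2.0 * c, 3.0 * c]))
        C = ComponentMatrix(c, ("x",))
        curve = augment.loo_rmsecv_curve(A, C, [], m_max=0)
        assert curve[0] == pytest.approx(0.0, abs=1e-10)


class TestChooseAugmentationSize:
    def test_linear_curve_returns_zero(self):
        assert augment.choose_augmentation_size(np.linspace(1.0, 0.2, 6)) == 0

    def test_documented_elbow(self):
        assert augment.choose_augmentation_size(np.array([1.0, 0.9, 0.1, 0.09, 0.08])) == 2

    def test_flat_after_k(self):
        curve = np.array([1.0, 0.62, 0.25, 0.25, 0.25, 0.25])
        assert augment.choose_augmentation_size(curve) == 2

    def test_override_honored(self):
        assert augment.choose_augmentation_size(np.array([1.0, 0.5, 0.2]), override=1) == 1

    def test_all_missing_rejected(self):
        with pytest.raises(DegenerateInputError):
            augment.choose_augmentation_size(np.full(5, np.nan))

    def test_fallback_when_elbow_worse_than_unaugmented(self):
        curve = np.array([0.1, 0.4, 0.12, 0.3])
        with pytest.warns(UserWarning, match="falling back"):
            assert augment.choose_augmentation_size(curve) == 0


class TestFitACLS:
    @staticmethod
    def _interfered_problem(rng, L=24, P=30):
        """Two analytes plus one unmodeled component with a clean proxy channel."""
        c = rng.uniform(0.1, 1.0, (L, 2))
        g = rng.uniform(0.0, 0.5, L)
        K = rng.normal(size=(2, P))
        v = np.zeros(P)
        v[25] = 1.0  # the proxy channel: carries only the interferent
        v[20] = 0.6
        A = c @ K + np.outer(g, v)
        return _spectra(A), ComponentMatrix(c, ("t", "o")), g

    def test_equals_manual_composition(self, rng):
        A, C, _ = self._interfered_problem(rng)
        model = augment.fit_acls(A, C, min_spacing=2.0, m_max=4)
        corr = augment.channel_r2(A, C.target_values)
        cands = augment.rank_candidates(corr, A.axis, 0.2, 2.0)
        m_cap = min(4, len(cands), A.n_samples - C.n_components - 2)
        curve = augment.loo_rmsecv_curve(A, C, cands, m_cap)
        m = augment.choose_augmentation_size(curve)
        C_aug = augment.augment_concentration_matrix(C, A, cands[:m])
        A_c, C_c, state = core.mean_center(A, C_aug)
        K = core.fit_cls(C_c, A_c)
        np.testing.assert_allclose(model.pure_spectra.rows, K.rows, atol=1e-12)
        assert model.selection.chosen_m == m
        np.testing.assert_allclose(model.selection.rmsecv_curve, curve, atol=1e-12)

    def test_selected_channels_satisfy_constraints(self, rng):
        A, C, _ = self._interfered_problem(rng)
        model = augment.fit_acls(A, C, min_spacing=3.0, m_max=5)
        sel = model.selection
        wn = A.axis.values
        chans = list(sel.chosen_channels)
        assert chans == list(sel.candidate_order[: sel.chosen_m])
        assert all(sel.r2[j] < sel.r2_threshold for j in chans)
        for i, a in enumerate(chans):
            for b in chans[i + 1 :]:
                assert abs(wn[a] - wn[b]) >= 3.0

    def test_deterministic(self, rng):
        A, C, _ = self._interfered_problem(rng)
        m1 = augment.fit_acls(A, C, min_spacing=2.0, m_max=4)
        m2 = augment.fit_acls(A, C, min_spacing=2.0, m_max=4)
        assert m1.selection.candidate_order == m2.selection.candidate_order
        assert m1.selection.chosen_m == m2.selection.chosen_m
        assert m1.selection.chosen_channels == m2.selection.chosen_channels
        np.testing.assert_array_equal(
            m1.selection.rmsecv_curve, m2.selection.rmsecv_curve
        )
        np.testing.assert_array_equal(m1.pure_spectra.rows, m2.pure_spectra.rows)

    def test_override_skips_elbow(self, rng):
        A, C, _ = self._interfered_problem(rng)
        model = augment.fit_acls(A, C, min_spacing=2.0, m_max=4, m_override=1)
        assert model.selection.chosen_m == 1
        assert np.isfinite(model.selection.rmsecv_curve[1])

    def test_orthogonal_pseudo_columns_leave_prediction_unchanged(self, rng):
        """Columns orthogonal to every concentration column add nothing and
        cost nothing on noiseless data."""
        A, C, K_true = make_problem(rng, L=20, M=3, P=40)
        Q, _ = np.linalg.qr(np.hstack([C.values, rng.normal(size=(20, 2))]))
        V = Q[:, 3:5]
        base = core.fit_cls(C, A)
        t_base, _ = core.predict_cls(A, base, None, 0)
        C_aug = C.append_pseudo_columns(V, ["v1", "v2"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero pseudo rows: min-norm path
            K_aug = core.fit_cls(C_aug, A)
            t_aug, _ = core.predict_cls(A, K_aug, None, 0)
        np.testing.assert_allclose(t_aug, t_base, atol=1e-8)
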