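"""Unit tests for evoked removal, VAR fitting and spectral GC estimation."""

import numpy as np
import pytest

from reachnet.granger import (
    BivariateVARFit,
    build_gc_matrices,
    default_gc_freqs,
    extract_windows,
    fit_bivariate_var,
    gc_spectrum,
    normalize_matrix,
    remove_evoked,
    GCMatrix,
)
from reachnet.ersp import band_mask
from reachnet.synthetic import analytic_spectral_gc, build_var_model, simulate_var
from conftest import make_epochs


class TestRemoveEvoked:
    def test_identical_trials_become_zero(self):
        tpl = np.sin(np.linspace(0, 6, 2048))
        ep = make_epochs(np.tile(tpl, (6, 2, 1)))
        out = remove_evoked(ep, group_by_target=False)
        assert np.allclose(out.data, 0.0)

    def test_template_plus_noise_leaves_noise(self, rng):
        tpl = np.sin(np.linspace(0, 20, 2048)) * 5
        noise = rng.standard_normal((80, 1, 2048))
        ep = make_epochs(tpl[None, None, :] + noise)
        out = remove_evoked(ep, group_by_target=False)
        corr = np.corrcoef(out.data.mean(axis=(0, 1)), tpl)[0, 1]
        assert abs(corr) < 0.1
        # residual trials stay close to their own noise realizations
        resid = out.data - (noise - noise.mean(axis=0, keepdims=True))
        assert np.abs(resid).max() < 1e-10

    def test_across_trial_mean_is_zero_per_group(self, rng):
        ep = make_epochs(rng.standard_normal((12, 2, 256)),
                         targets=np.repeat([1, 2, 3], 4))
        out = remove_evoked(ep, group_by_target=True)
        for t in (1, 2, 3):
            assert np.allclose(out.data[out.targets == t].mean(axis=0), 0.0,
                               atol=1e-12)

    def test_single_trial_group_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((3, 1, 64)), targets=[1, 1, 2])
        with pytest.raises(ValueError, match="at least 2 trials"):
            remove_evoked(ep)


class TestExtractWindows:
    def test_one_second_window_at_512hz_gives_512_samples(self, rng):
        ep = make_epochs(rng.standard_normal((5, 3, 2048)))
        seg = extract_windows(ep, (-1.0, 0.0))
        assert seg.shape == (5, 3, 512)
        seg2 = extract_windows(ep, (1.0, 2.0))
        assert seg2.shape == seg.shape
        assert np.allclose(seg.mean(axis=2), 0.0, atol=1e-12)

    def test_window_outside_epoch_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((2, 1, 2048)))
        with pytest.raises(ValueError, match="outside epoch"):
            extract_windows(ep, (2.5, 3.5))


class TestFitBivariateVar:
    def test_recovers_known_var2_coefficients(self):
        m = build_var_model(
            2, 2, edges=[(0, 1, 1, 0.4), (1, 0, 2, -0.3)],
            self_decay=(0.5, -0.2), fs=512.0,
        )
        x = simulate_var(m, 60_000, seed=12)[0]
        segs = x.reshape(2, 60, 1000).swapaxes(0, 1)
        segs = segs - segs.mean(axis=2, keepdims=True)
        fit = fit_bivariate_var(segs[:, 0], segs[:, 1], order=2)
        assert np.abs(fit.coeffs - m.coeffs).max() < 0.05
        assert np.abs(fit.resid_cov - np.eye(2)).max() < 0.05

    def test_white_noise_has_no_cross_structure(self, rng):
        x = rng.standard_normal((30, 800))
        y = rng.standard_normal((30, 800))
        fit = fit_bivariate_var(x, y, order=5)
        assert np.abs(fit.coeffs).max() < 0.05
        assert abs(fit.resid_cov[0, 1]) < 0.05
        assert fit.resid_cov[0, 0] == pytest.approx(1.0, abs=0.05)

    def test_underdetermined_rejected(self, rng):
        x = rng.standard_normal((1, 100))
        with pytest.raises(ValueError):
            fit_bivariate_var(x, x + 0.0, order=200)

    def test_no_lag_spans_a_segment_boundary(self):
        # two constant-valued segments with different levels: if lags crossed
        # the boundary the design would see a spurious jump; within-segment
        # demeaned constants give an exactly zero design instead
        a = np.vstack([np.full(50, 3.0), np.full(50, -3.0)])
        seg = a - a.mean(axis=1, keepdims=True)
        with pytest.raises(ValueError, match="ill-conditioned|rows"):
            fit_bivariate_var(seg, seg, order=2)


class TestGcSpectrum:
    freqs = default_gc_freqs()

    def test_zero_cross_terms_give_zero_gc(self):
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = np.diag([0.5, -0.3])
        fit = BivariateVARFit(order=2, coeffs=coeffs, resid_cov=np.eye(2),
                              n_effective=1000, fs=512.0)
        s_xy, s_yx = gc_spectrum(fit, self.freqs)
        assert np.allclose(s_xy.values, 0.0, atol=1e-14)
        assert np.allclose(s_yx.values, 0.0, atol=1e-14)

    def test_oracle_identity_at_true_coefficients(self):
        m = build_var_model(2, 1, edges=[(0, 1, 1, 0.9)], self_decay=0.5, fs=512.0)
        fit = BivariateVARFit(order=1, coeffs=m.coeffs, resid_cov=m.noise_cov,
                              n_effective=1000, fs=512.0)
        s_xy, s_yx = gc_spectrum(fit, self.freqs)
        ana = analytic_spectral_gc(m, self.freqs)
        assert np.abs(s_xy.values - ana[0, 1]).max() < 1e-10
        assert np.abs(s_yx.values - ana[1, 0]).max() < 1e-10

    def test_correlated_innovations_partialized(self):
        # with correlated residuals the causal variance is
        # Sigma_jj - Sigma_ij^2 / Sigma_ii, checked against the oracle
        sig = np.array([[1.0, 0.4], [0.4, 2.0]])
        m = build_var_model(2, 1, edges=[(0, 1, 1, 0.6)], self_decay=0.3,
                            noise_cov=sig, fs=512.0)
        fit = BivariateVARFit(order=1, coeffs=m.coeffs, resid_cov=sig,
                              n_effective=1000, fs=512.0)
        s_xy, _ = gc_spectrum(fit, self.freqs)
        ana = analytic_spectral_gc(m, self.freqs)
        assert np.abs(s_xy.values - ana[0, 1]).max() < 1e-10

    def test_estimated_fit_consistent_with_analytic_band_average(self):
        m = build_var_model(2, 1, edges=[(0, 1, 1, 0.9)], self_decay=0.5, fs=512.0)
        x = simulate_var(m, 512 * 60, seed=77)[0]
        segs = x.reshape(2, 60, 512).swapaxes(0, 1)
        segs = segs - segs.mean(axis=2, keepdims=True)
        fit = fit_bivariate_var(segs[:, 0], segs[:, 1], order=30, fs=512.0)
        s_xy, s_yx = gc_spectrum(fit, self.freqs)
        am = band_mask(self.freqs, (8.0, 13.0))
        ana = analytic_spectral_gc(m, self.freqs)
        assert abs(s_xy.values[am].mean() - ana[0, 1][am].mean()) < 0.05
        assert s_yx.values[am].mean() < 0.01

    def test_nyquist_guard(self):
        fit = BivariateVARFit(order=1, coeffs=np.zeros((1, 2, 2)),
                              resid_cov=np.eye(2), n_effective=10, fs=512.0)
        with pytest.raises(ValueError, match="Nyquist"):
            gc_spectrum(fit, [400.0])

    def test_nonnegative_after_clamping(self, rng):
        x = rng.standard_normal((20, 400))
        y = rng.standard_normal((20, 400))
        fit = fit_bivariate_var(x, y, order=10, fs=512.0)
        s_xy, s_yx = gc_spectrum(fit, self.freqs)
        assert np.all(s_xy.values >= 0) and np.all(s_yx.values >= 0)


@pytest.fixture(scope="module")
def three_node_epochs():
    """Short 3-ROI dataset from a VAR with a known 0 -> 1 edge."""
    m = build_var_model(3, 2, edges=[(0, 1, 1, 0.6)], self_decay=(0.5, -0.2),
                        fs=512.0)
    data = simulate_var(m, 2048, n_trials=30, seed=5)
    return make_epochs(data, fs=512.0, labels=["A", "B", "C"],
                       targets=np.repeat([1, 2, 3], 10)), m


class TestBuildGcMatrices:
    def test_shapes_bands_and_conventions(self, three_node_epochs):
        ep, _ = three_node_epochs
        mats = build_gc_matrices(ep, order=10)
        assert set(mats) == {("alpha", "baseline"), ("alpha", "post_cue_late"),
                             ("beta", "baseline"), ("beta", "post_cue_late")}
        for m in mats.values():
            assert m.values.shape == (3, 3)
            assert np.all(np.diag(m.values) == 0)
            assert np.all(m.values >= 0)

    def test_matches_pairwise_fit_route(self, three_node_epochs):
        # block-assembled normal equations must equal the direct per-pair fit
        ep, _ = three_node_epochs
        freqs = default_gc_freqs()
        mats = build_gc_matrices(ep, order=10, freqs=freqs)
        seg = extract_windows(ep, (-1.0, 0.0))
        fit = fit_bivariate_var(seg[:, 0], seg[:, 1], order=10, fs=512.0)
        s_xy, s_yx = gc_spectrum(fit, freqs)
        am = band_mask(freqs, (8.0, 13.0))
        assert mats[("alpha", "baseline")].values[0, 1] == pytest.approx(
            s_xy.values[am].mean(), rel=1e-9)
        assert mats[("alpha", "baseline")].values[1, 0] == pytest.approx(
            s_yx.values[am].mean(), rel=1e-9)

    def test_planted_edge_dominates_its_band(self, three_node_epochs):
        ep, m = three_node_epochs
        mats = build_gc_matrices(ep, order=10)
        vals = mats[("alpha", "baseline")].values
        off = [vals[j, i] for j in range(3) for i in range(3) if i != j]
        assert vals[0, 1] == pytest.approx(max(off))


class TestNormalizeMatrix:
    def make(self, values):
        return GCMatrix(values=np.asarray(values, float), band="alpha",
                        condition="baseline", roi_labels=["a", "b"], order=2)

    def test_offdiagonal_sum_becomes_one(self):
        nm = normalize_matrix(self.make([[0.0, 3.0], [1.0, 0.0]]))
        assert nm.offdiag_sum() == pytest.approx(1.0, abs=1e-12)
        assert nm.values[0, 1] == pytest.approx(0.75)
        assert nm.values[1, 0] == pytest.approx(0.25)

    def test_idempotence(self):
        nm = normalize_matrix(self.make([[0.0, 0.6], [0.4, 0.0]]))
        nm2 = normalize_matrix(nm)
        assert np.allclose(nm.values, nm2.values)

    def test_scale_invariance(self, rng):
        a = np.abs(rng.standard_normal((4, 4)))
        np.fill_diagonal(a, 0.0)
        m = GCMatrix(values=a, band="beta", condition="baseline",
                     roi_labels=list("abcd"), order=2)
        m_scaled = GCMatrix(values=7.3 * a, band="beta", condition="baseline",
                            roi_labels=list("abcd"), order=2)
        assert np.allclose(normalize_matrix(m).values,
                           normalize_matrix(m_scaled).values, atol=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            normalize_matrix(self.make(np.zeros((2, 2))))

    def test_digraph_view_preserves_weights(self):
        nm = normalize_matrix(self.make([[0.0, 3.0], [1.0, 0.0]]))
        g = nm.to_digraph()
        assert g["a"]["b"]["weight"] == pytest.approx(0.75)
        assert g.in_degree("b", weight="weight") == pytest.approx(0.75)
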