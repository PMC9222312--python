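"""Dual-Q morphological component analysis via SALSA."""

from dataclasses import replace

import numpy as np
import pytest

from fwavekit.decompose import (
    DualQConfig,
    calibrate_regularization,
    decompose,
    default_lambda_grid,
    mca_salsa,
    objective,
    soft_threshold,
)
from fwavekit.decompose import _make_spec
from fwavekit.metrics import nmse
from fwavekit.simulate import compose_record, make_fwave_params
from fwavekit.tqwt import subband_wavelet_norms, tqwt_forward, tqwt_inverse

FAST = dict(n_iter=60, tol=0.0)


def small_cfg(**kw):
    base = dict(lambda_osc=0.05, lambda_trn=0.05, osc_band_hz=None)
    base.update(FAST)
    base.update(kw)
    return DualQConfig(**base)


class TestSoftThreshold:
    def test_reference_values(self):
        assert soft_threshold(0.5, 1.0) == 0.0
        assert soft_threshold(-3.0, 1.0) == -2.0
        x = np.array([-2.0, 0.3, 5.0])
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_infinite_threshold_zeroes(self):
        np.testing.assert_array_equal(soft_threshold(np.array([1.0, -4.0]), np.inf), 0.0)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestObjective:
    def test_zero_coefficients_give_signal_energy(self, rng):
        x = rng.standard_normal(256)
        cfg = small_cfg()
        p_osc, p_trn = cfg.params_for(256)
        w1 = tqwt_forward(np.zeros(256), p_osc)
        w2 = tqwt_forward(np.zeros(256), p_trn)
        assert objective(x, w1, w2, cfg) == pytest.approx(np.sum(x * x), rel=1e-12)

    def test_matches_brute_force_assembly(self, rng):
        """Independent evaluation: fidelity via inverse transforms + weighted l1."""
        x = rng.standard_normal(256)
        cfg = small_cfg(lambda_osc=0.7, lambda_trn=0.3)
        p_osc, p_trn = cfg.params_for(256)
        w1 = tqwt_forward(rng.standard_normal(256), p_osc)
        w2 = tqwt_forward(rng.standard_normal(256), p_trn)
        no = subband_wavelet_norms(p_osc, 256)
        nt = subband_wavelet_norms(p_trn, 256)
        resid = x - tqwt_inverse(w1) - tqwt_inverse(w2)
        expected = float(np.sum(resid**2))
        expected += sum(0.7 * nj * np.abs(b).sum() for b, nj in zip(w1.subbands, no))
        expected += sum(0.3 * nj * np.abs(b).sum() for b, nj in zip(w2.subbands, nt))
        assert objective(x, w1, w2, cfg) == pytest.approx(expected, rel=1e-12)


class TestDecompose:
    def test_zeros_in_zeros_out(self):
        res = decompose(np.zeros(256), small_cfg())
        assert np.all(res.x_osc == 0) and np.all(res.x_trn == 0)

    def test_huge_lambda_kills_both_components(self, rng):
        x = rng.standard_normal(256)
        lam = 10.0 * np.linalg.norm(x)
        res = decompose(x, small_cfg(lambda_osc=lam, lambda_trn=lam, mu=2.0, n_iter=200))
        assert np.linalg.norm(res.x_osc) <= 1e-8 * np.linalg.norm(x)
        assert np.linalg.norm(res.x_trn) <= 1e-8 * np.linalg.norm(x)
        np.testing.assert_allclose(res.residual, x, atol=1e-10)

    def test_additivity_exact(self, rng):
        x = rng.standard_normal(500)
        res = decompose(x, small_cfg())
        # residual is defined as x - x_osc - x_trn, bit for bit
        np.testing.assert_array_equal(res.residual, x - res.x_osc - res.x_trn)
        np.testing.assert_allclose(x, res.x_osc + res.x_trn + res.residual, atol=1e-12)

    def test_component_separation(self, short_mixture):
        """The premise of resonance decomposition: sustained oscillation and
        sparse pulses end up in different components."""
        osc, trn, x, _ = short_mixture
        res = decompose(x, DualQConfig(lambda_osc=0.05, lambda_trn=0.05, n_iter=150, tol=0))
        assert np.corrcoef(res.x_osc, osc)[0, 1] >= 0.9
        assert np.corrcoef(res.x_trn, trn)[0, 1] >= 0.9

    def test_objective_trace_decreases_to_stationarity(self, rng):
        """Final objective below initial; final iterations nearly stationary."""
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(512)
            res = decompose(x, small_cfg(lambda_osc=0.3, lambda_trn=0.3, n_iter=300))
            tr = res.objective_trace
            assert tr[-1] <= tr[0]
            slope = abs(tr[-10] - tr[-1]) / (9 * abs(tr[-1]))
            assert slope < 1e-4

    def test_dictionary_swap_symmetry(self, short_mixture):
        """Swapping the two dictionary specs swaps the returned components."""
        _, _, x, _ = short_mixture
        cfg = small_cfg()
        p_osc, p_trn = cfg.params_for(len(x))
        sa = _make_spec(p_osc, 0.05, len(x), cfg.mu, cfg.fs, None)
        sb = _make_spec(p_trn, 0.05, len(x), cfg.mu, cfg.fs, None)
        w1, w2, _ = mca_salsa(x, sa, sb, cfg.mu, 60)
        v2, v1, _ = mca_salsa(x, sb, sa, cfg.mu, 60)
        np.testing.assert_allclose(tqwt_inverse(w1), tqwt_inverse(v1), atol=1e-10)
        np.testing.assert_allclose(tqwt_inverse(w2), tqwt_inverse(v2), atol=1e-10)

    def test_lambda_osc_monotonically_shrinks_component(self, short_mixture):
        _, _, x, _ = short_mixture
        energies = []
        for lam in [0.02, 0.06, 0.2, 0.6, 2.0]:
            res = decompose(x, small_cfg(lambda_osc=lam, lambda_trn=0.1, n_iter=150))
            energies.append(np.linalg.norm(res.x_osc))
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decompose(np.zeros(32), small_cfg())
        with pytest.raises(ValueError):
            DualQConfig(q_high=1.2, q_low=1.3)
        with pytest.raises(ValueError):
            DualQConfig(mu=0.0)


class TestCalibration:
    @staticmethod
    def _records(n, noise=0.0):
        return [
            compose_record(
                make_fwave_params("B", "II"),
                noise_level=noise,
                duration_s=2.0,
                seed=100 + i,
            )
            for i in range(n)
        ]

    def test_single_pair_grid(self):
        recs = self._records(1)
        cfg = DualQConfig(n_iter=20, tol=0)
        assert calibrate_regularization(recs, [(1.0, 2.0)], cfg) == (1.0, 2.0)

    def test_degenerate_pair_loses(self):
        recs = self._records(2)
        cfg = DualQConfig(n_iter=40, tol=0)
        huge = 100.0 * float(np.linalg.norm(recs[0].x))
        got = calibrate_regularization(recs, [(huge, huge), (2.0, 1.5)], cfg)
        assert got == (2.0, 1.5)

    def test_argmin_matches_exhaustive_oracle(self):
        recs = self._records(3)
        cfg = DualQConfig(n_iter=30, tol=0)
        grid = [(lo, lt) for lo in (1.0, 4.0, 16.0) for lt in (1.0, 4.0, 16.0)]
        got = calibrate_regularization(recs, grid, cfg)
        scores = {
            pair: np.mean(
                [
                    nmse(
                        r.fwave_truth,
                        decompose(r.x, replace(cfg, lambda_osc=pair[0], lambda_trn=pair[1])).x_osc,
                    )
                    for r in recs
                ]
            )
            for pair in grid
        }
        assert got == min(scores, key=scores.get)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_regularization(self._records(1), [], DualQConfig())

    def test_default_grid_shape(self):
        grid = default_lambda_grid(100.0, n=3)
        assert len(grid) == 9
        assert min(v for pair in grid for v in pair) == pytest.approx(1.0)
        assert max(v for pair in grid for v in pair) == pytest.approx(100.0)
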