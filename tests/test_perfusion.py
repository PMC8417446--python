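"""Decoding, quality metrics, fitting, PVC, ROI summaries."""

import numpy as np
import pytest

from hadasl.cohort import M0Set, simulate_encoded_series
from hadasl.kinetics import AcquisitionModel, subbolus_signals
from hadasl.perfusion import (
    DecodedSeries,
    DegenerateInputError,
    FitPriors,
    apply_pvc,
    bolus_transit_curve,
    compute_tsnr,
    decode,
    fit_voxelwise,
    prepare_m0,
    roi_means,
)


def make_decoded(pw, scheme):
    """Wrap a (..., n_blocks, n_cycles) array as a DecodedSeries."""
    return DecodedSeries(pw=np.asarray(pw, dtype=float),
                         effective_plds=scheme.effective_plds, scheme=scheme)


class TestDecode:
    def test_identity_on_random_vectors(self, scheme):
        """Encoding arbitrary sub-bolus vectors and decoding recovers them
        (the pruned Hadamard decode is the pseudoinverse up to 2/n)."""
        rng = np.random.default_rng(42)
        matrix = np.asarray(scheme.encoding_matrix, dtype=float)
        dm = rng.uniform(0.1, 5.0, (1000, 7))
        encoded = 123.4 + 0.5 * dm @ matrix.T  # static offset cancels
        pw = decode(encoded.reshape(1000, 1, 1, 8), scheme).cycle_mean()
        assert np.max(np.abs(pw.reshape(1000, 7) / dm - 1)) < 1e-10

    def test_all_zero_input(self, scheme):
        out = decode(np.zeros((2, 2, 2, 56)), scheme)
        assert out.pw.shape == (2, 2, 2, 7, 7)
        assert np.all(out.pw == 0)

    def test_axis_mismatch_rejected(self, scheme):
        with pytest.raises(ValueError, match="divisible"):
            decode(np.zeros((2, 2, 2, 55)), scheme)


class TestTsnr:
    def test_monte_carlo_convergence(self, scheme):
        """Constant signal mu plus noise sigma across many cycles converges
        to mu/sigma."""
        rng = np.random.default_rng(7)
        mu, sigma, n_cycles = 3.0, 1.5, 4000
        pw = mu + rng.normal(0, sigma, (50, 1, 1, 7, n_cycles))
        val = compute_tsnr(make_decoded(pw, scheme), np.ones((50, 1, 1), bool))
        assert val == pytest.approx(mu / sigma, rel=0.03)

    def test_duplicate_cycles_degenerate(self, scheme):
        pw = np.tile(np.arange(1.0, 8.0), (2, 2, 2, 3, 1)).swapaxes(-1, -2)
        with pytest.raises(DegenerateInputError):
            compute_tsnr(make_decoded(pw, scheme), np.ones((2, 2, 2), bool))

    def test_single_cycle_degenerate(self, scheme):
        with pytest.raises(DegenerateInputError):
            compute_tsnr(make_decoded(np.ones((2, 2, 2, 7, 1)), scheme),
                         np.ones((2, 2, 2), bool))

    def test_default_simulation_brackets_study_value(self, phantom, scheme):
        acq = simulate_encoded_series(phantom, scheme, seed=5)
        gm = phantom.tissue_mask("gm", 0.9)
        val = compute_tsnr(decode(acq), gm)
        assert 1.1 < val < 2.3


class TestBolusTransitCurve:
    def test_max_is_one(self, phantom, scheme):
        acq = simulate_encoded_series(phantom, scheme, seed=2)
        plds, curve = bolus_transit_curve(decode(acq),
                                          phantom.tissue_mask("gm"))
        assert curve.max() == pytest.approx(1.0)
        assert len(curve) == 7

    def test_compensated_curve_is_flat_when_label_arrived(self, phantom):
        # full arrival before the shortest PLD and matched decay rates:
        # equal delivered signal per block -> near-horizontal curve
        from hadasl.scheme import EncodingScheme

        scheme = EncodingScheme.reference_seven_block()
        m = AcquisitionModel(t1_blood=1.65, t1_tissue=1.65)
        att = np.where(phantom.truth_att > 0, 0.45, 0.0)
        acq = simulate_encoded_series(phantom, scheme, m, noise_sigma=0.0,
                                      seed=0, att=att)
        _, curve = bolus_transit_curve(decode(acq), phantom.tissue_mask("gm"))
        assert curve.max() - curve.min() < 0.05

    def test_uncompensated_curve_decays(self, phantom):
        # equal block durations (no T1 compensation): later-played blocks
        # keep more signal, so the curve decays toward long effective PLDs
        from hadasl.scheme import EncodingScheme

        scheme = EncodingScheme(0.5, (0.5,) * 7)
        att = np.where(phantom.truth_att > 0, 0.45, 0.0)
        acq = simulate_encoded_series(phantom, scheme, noise_sigma=0.0,
                                      seed=0, att=att)
        _, curve = bolus_transit_curve(decode(acq), phantom.tissue_mask("gm"))
        # play order = farthest from readout first: curve increases along
        # play order, i.e. strictly decays with increasing effective PLD
        assert np.all(np.diff(curve) > 0)

    def test_all_zero_rejected(self, scheme):
        with pytest.raises(ValueError, match="all-zero"):
            bolus_transit_curve(
                make_decoded(np.zeros((2, 2, 2, 7, 2)), scheme),
                np.ones((2, 2, 2), bool),
            )


class TestPrepareM0:
    def test_dummy_does_not_leak(self):
        base = np.full((4, 4, 2), 100.0)
        vols = np.stack([base * 5, base, base, base, base], axis=-1)
        out = prepare_m0(M0Set(volumes=vols))
        assert np.allclose(out, 100.0)

    def test_polarity_average(self):
        base = np.ones((2, 2, 2))
        vols = np.stack([base, base * 80, base * 80, base * 120, base * 120],
                        axis=-1)
        assert np.allclose(prepare_m0(M0Set(volumes=vols)), 100.0)

    def test_missing_polarity_rejected(self):
        vols = np.ones((2, 2, 2, 3))
        with pytest.raises(ValueError, match="polarity"):
            prepare_m0(M0Set(volumes=vols, labels=("dummy", "ap", "ap")))


class TestFitVoxelwise:
    def make_voxels(self, scheme, model, f, att, noise_sd, n_cycles, seed):
        """Decoded series + M0 for isolated voxels with known truth."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        att = np.atleast_1d(np.asarray(att, dtype=float))
        m0a = 1000.0 / model.lambda_partition
        dm = subbolus_signals(scheme, f, att, model) * m0a
        rng = np.random.default_rng(seed)
        pw = dm[:, None, None, :, None] + rng.normal(
            0, noise_sd, (f.size, 1, 1, 7, n_cycles))
        m0 = np.full((f.size, 1, 1), 1000.0)
        return make_decoded(pw, scheme), m0

    def test_noiseless_recovery(self, scheme, model):
        dec, m0 = self.make_voxels(scheme, model, 60.0, 1.3, 0.0, 1, 0)
        maps = fit_voxelwise(dec, m0, model)
        assert maps.cbf[0, 0, 0] == pytest.approx(60.0, rel=0.005)
        assert maps.att[0, 0, 0] == pytest.approx(1.3, rel=0.005)
        assert maps.converged[0, 0, 0]

    def test_all_zero_signal_returns_prior_mean(self, scheme, model):
        dec = make_decoded(np.zeros((1, 1, 1, 7, 1)), scheme)
        maps = fit_voxelwise(dec, np.full((1, 1, 1), 1000.0), model)
        assert maps.cbf[0, 0, 0] == 0.0
        assert maps.att[0, 0, 0] == pytest.approx(1.3, abs=1e-6)

    def test_optimum_beats_coarse_grid_oracle(self, scheme, model):
        """Exhaustive 50x50 (f, att) grid never improves on the fitter."""
        rng = np.random.default_rng(3)
        f = rng.uniform(30, 90, 20)
        att = rng.uniform(0.8, 1.8, 20)
        noise_sd = 0.6
        dec, m0 = self.make_voxels(scheme, model, f, att, noise_sd, 7, 1)
        priors = FitPriors()
        maps = fit_voxelwise(dec, m0, model, priors, noise_sd=noise_sd)

        m0a = 1000.0 / model.lambda_partition
        y = dec.cycle_mean()[:, 0, 0, :] / m0a
        s_norm = noise_sd / m0a

        def objective(fv, attv, yv):
            u = np.ravel(subbolus_signals(scheme, 1.0, attv, model))
            resid = yv - fv * u
            pen = (s_norm * (attv - priors.att_mean) / priors.att_sd) ** 2
            return float(resid @ resid + pen)

        f_grid = np.linspace(0, 300, 50)
        a_grid = np.linspace(0.3, 2.8, 50)
        for v in range(20):
            grid_best = min(objective(fv, av, y[v])
                            for fv in f_grid for av in a_grid)
            fit_obj = objective(maps.cbf[v, 0, 0], maps.att[v, 0, 0], y[v])
            assert fit_obj <= grid_best + 1e-6

    def test_misaligned_m0_rejected(self, scheme, model):
        dec = make_decoded(np.zeros((2, 2, 2, 7, 1)), scheme)
        with pytest.raises(ValueError, match="aligned"):
            fit_voxelwise(dec, np.ones((3, 3, 3)), model)

    def test_empty_mask_rejected(self, scheme, model):
        dec = make_decoded(np.zeros((2, 2, 2, 7, 1)), scheme)
        with pytest.raises(ValueError, match="mask"):
            fit_voxelwise(dec, np.ones((2, 2, 2)), model,
                          mask=np.zeros((2, 2, 2), bool))


class TestPvc:
    def _maps(self, cbf, converged=None):
        from hadasl.perfusion import PerfusionMaps

        shape = cbf.shape
        conv = np.ones(shape, bool) if converged is None else converged
        return PerfusionMaps(
            cbf=cbf, att=np.full(shape, 1.3),
            residual_norm=np.zeros(shape), converged=conv,
            mask=np.ones(shape, bool),
        )

    def test_pure_gm_region_unchanged(self):
        cbf = np.full((6, 6, 6), 70.0)
        out = apply_pvc(self._maps(cbf), np.ones((6, 6, 6)),
                        np.zeros((6, 6, 6)))
        inner = out.cbf_gm_pvc[1:-1, 1:-1, 1:-1]
        assert np.allclose(inner, 70.0)

    def test_checkerboard_exact_recovery(self):
        rng = np.random.default_rng(0)
        pv_gm = rng.uniform(0.1, 0.9, (8, 8, 4))
        pv_wm = 1.0 - pv_gm
        cbf = pv_gm * 70.0 + pv_wm * 28.0
        out = apply_pvc(self._maps(cbf), pv_gm, pv_wm)
        ok = ~out.pvc_flagged
        assert ok.any()
        assert np.allclose(out.cbf_gm_pvc[ok], 70.0, atol=1e-8)
        assert np.allclose(out.cbf_wm_pvc[ok], 28.0, atol=1e-8)

    def test_single_voxel_kernel_on_mixed_voxel_flagged(self):
        pv_gm = np.full((3, 3, 3), 0.5)
        pv_wm = np.full((3, 3, 3), 0.5)
        cbf = np.full((3, 3, 3), 49.0)
        out = apply_pvc(self._maps(cbf), pv_gm, pv_wm, kernel=(1, 1, 1))
        assert out.pvc_flagged.all()
        assert np.all(np.isnan(out.cbf_gm_pvc))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            apply_pvc(self._maps(np.ones((3, 3, 3))), np.ones((3, 3, 3)),
                      np.ones((3, 3, 3)), kernel=(2, 3, 3))


class TestRoiMeans:
    def test_uniform_map_returns_value(self, phantom):
        from hadasl.perfusion import PerfusionMaps

        shape = phantom.dims
        maps = PerfusionMaps(
            cbf=np.full(shape, 42.0), att=np.full(shape, 1.1),
            residual_norm=np.zeros(shape),
            converged=np.ones(shape, bool), mask=np.ones(shape, bool),
        )
        table = roi_means(maps, phantom)
        assert np.allclose(table.cbf_ml_100g_min, 42.0)
        assert np.allclose(table.att_s, 1.1)
        assert (table.n_voxels > 0).all()

    def test_threshold_above_max_pv_names_roi(self, phantom):
        from copy import deepcopy
        from hadasl.perfusion import PerfusionMaps

        ph = deepcopy(phantom)
        ph.pv_wm = np.clip(ph.pv_wm, 0, 0.85)
        shape = ph.dims
        maps = PerfusionMaps(
            cbf=np.ones(shape), att=np.ones(shape),
            residual_norm=np.zeros(shape),
            converged=np.ones(shape, bool), mask=np.ones(shape, bool),
        )
        with pytest.raises(ValueError, match="white_matter"):
            roi_means(maps, ph, pv_threshold=0.9)

    def test_end_to_end_noiseless_gm_within_one_percent(
            self, phantom, scheme, model):
        acq = simulate_encoded_series(phantom, scheme, model,
                                      noise_sigma=0.0, seed=1)
        maps = fit_voxelwise(decode(acq), prepare_m0(acq.m0), model,
                             mask=(phantom.pv_gm + phantom.pv_wm) > 0.05)
        table = roi_means(maps, phantom).set_index("roi")
        gm = phantom.roi_mask("gray_matter")
        truth = phantom.truth_cbf[gm].mean()
        assert table.loc["gray_matter", "cbf_ml_100g_min"] == pytest.approx(
            truth, rel=0.01)
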