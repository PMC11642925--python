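"""SRTM / FRTM / Feng-1TC forward models: oracles, collapses, and invariances."""

import numpy as np
import pytest
from mpmath import mp
from mpmath import exp as mexp

from simbaref.curves import numeric_convolve_exp
from simbaref.kinetics import (
    BatchRefCurves,
    FengOneTCParams,
    FengParams,
    FRTMParams,
    FrameSchedule,
    InvalidParameterError,
    OneTissueIRF,
    ScheduleError,
    SRTMParams,
    feng1tc_predict,
    feng_input,
    frtm_curve,
    frtm_predict,
    srtm_curve,
    srtm_predict,
    srtm_predict_batch,
)

GRID = np.arange(0.0, 90.0001, 0.002)


# ------------------------------------------------------------------ Feng input
class TestFengInput:
    def test_zero_before_onset(self, ref_params):
        assert feng_input(ref_params.feng, ref_params.feng.t0 - 1.0) == 0.0

    def test_continuous_at_onset(self, ref_params):
        # (A1*0 - A2 - A3) + A2 + A3 = 0, so the curve rises from exactly zero
        eps = 1e-9
        assert feng_input(ref_params.feng, ref_params.feng.t0 + eps) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_value_matches_arbitrary_precision_formula(self):
        """Direct high-precision evaluation of the tri-exponential form."""
        p = FengParams(100.0, 1.0, 0.5, 4.0, 0.5, 0.05, 0.5)
        mp.dps = 40
        d = mp.mpf("0.5")  # t=1.0 minus t0=0.5
        expected = float(
            (100 * d - 1 - mp.mpf("0.5")) * mexp(-4 * d)
            + 1 * mexp(-d / 2)
            + mp.mpf("0.5") * mexp(-d / 20)
        )
        assert feng_input(p, 1.0) == pytest.approx(expected, rel=1e-14)

    def test_canonical_ordering_swaps_exchangeable_pair(self):
        a = FengParams(10.0, 1.0, 0.5, 4.0, 0.05, 0.5, 0.2)  # lambda2 < lambda3
        assert a.lambda2 == 0.5 and a.lambda3 == 0.05
        assert a.A2 == 0.5 and a.A3 == 1.0
        b = FengParams(10.0, 0.5, 1.0, 4.0, 0.5, 0.05, 0.2)
        t = np.linspace(0, 30, 60)
        assert np.allclose(feng_input(a, t), feng_input(b, t))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            FengParams(np.nan, 1, 1, 1, 0.5, 0.1, 0.0)
        with pytest.raises(InvalidParameterError):
            FengParams(1, 1, 1, 1, 0.5, 0.1, -0.5)


# -------------------------------------------------------------------- Feng-1TC
class TestFeng1TC:
    def test_nine_free_parameters(self, ref_params):
        assert FengOneTCParams.N_FREE_PARAMETERS == 9
        assert ref_params.to_array().shape == (9,)
        with pytest.raises(InvalidParameterError):
            FengOneTCParams.from_array(np.zeros(8))

    def test_zero_delivery_gives_zero_curve(self, ref_params, frames):
        p = FengOneTCParams(ref_params.feng, OneTissueIRF(0.0, 0.1))
        assert np.allclose(feng1tc_predict(p, frames), 0.0)

    def test_against_numeric_convolution_oracle(self, ref_params):
        feng_vals = ref_params.feng.curve()(GRID)
        num = ref_params.irf.K1ref * numeric_convolve_exp(
            feng_vals, GRID, ref_params.irf.k2ref
        )
        ana = ref_params.curve()(GRID)
        mask = GRID > ref_params.feng.t0 + 0.5
        scale = np.max(np.abs(ana[mask]))
        assert np.max(np.abs(ana[mask] - num[mask])) < 1e-4 * scale

    def test_schedule_validation(self):
        with pytest.raises(ScheduleError):
            FrameSchedule(np.array([0.0, 1.0]), np.array([2.0, 1.0]))  # overlap
        with pytest.raises(ScheduleError):
            FrameSchedule(np.array([0.0, 1.0]), np.array([1.0, -1.0]))


# ------------------------------------------------------------------- SRTM/FRTM
class TestSRTM:
    def test_collapses_onto_reference(self, ref_params, frames):
        p = SRTMParams(R1=1.0, k2prime=0.11, BPND=0.0)
        ct = srtm_predict(p, ref_params, frames)
        cr = feng1tc_predict(ref_params, frames)
        assert np.allclose(ct, cr, rtol=1e-12)

    def test_no_delivery_gives_zero(self, ref_params, frames):
        assert np.allclose(srtm_predict(SRTMParams(0.0, 0.1, 1.0), ref_params, frames), 0.0)

    def test_against_numeric_convolution_oracle(self, ref_params):
        p = SRTMParams(0.9, 0.12, 1.5)
        cr_vals = ref_params.curve()(GRID)
        num = p.R1 * cr_vals + (p.k2 - p.R1 * p.k2a) * numeric_convolve_exp(
            cr_vals, GRID, p.k2a
        )
        ana = srtm_curve(p, ref_params)(GRID)
        mask = GRID > ref_params.feng.t0 + 0.5
        scale = np.max(np.abs(ana[mask]))
        assert np.max(np.abs(ana[mask] - num[mask])) < 1e-4 * scale

    def test_reparameterisation_invariance(self, ref_params, frames):
        """(R1, k2prime, BPND) and (R1, k2, k2a) describe the same curve."""
        p = SRTMParams(0.85, 0.13, 2.2)
        k2, k2a = p.k2, p.k2a
        # reconstruct the standard parameters from the rate parameterisation
        p2 = SRTMParams(R1=p.R1, k2prime=k2 / p.R1, BPND=k2 / k2a - 1.0)
        assert np.allclose(
            srtm_predict(p, ref_params, frames), srtm_predict(p2, ref_params, frames),
            rtol=1e-12,
        )

    def test_invalid_bpnd_rejected(self):
        with pytest.raises(InvalidParameterError):
            SRTMParams(1.0, 0.1, -1.5)


class TestFRTM:
    def test_nests_srtm_at_zero_binding(self, ref_params, frames):
        for k4 in (0.01, 0.05, 0.3):
            f = frtm_predict(FRTMParams(0.9, 0.12, 0.0, k4), ref_params, frames)
            s = srtm_predict(SRTMParams(0.9, 0.12, 0.0), ref_params, frames)
            assert np.max(np.abs(f - s)) < 1e-10

    def test_collapses_onto_reference(self, ref_params, frames):
        ct = frtm_predict(FRTMParams(1.0, 0.1, 0.0, 0.05), ref_params, frames)
        assert np.allclose(ct, feng1tc_predict(ref_params, frames), rtol=1e-10)

    def test_against_numeric_convolution_oracle(self, ref_params, frames):
        p = FRTMParams(0.85, 0.12, 2.0, 0.05)
        k2, k3 = p.R1 * p.k2prime, p.BPND * p.k4
        s = k2 + k3 + p.k4
        root = np.sqrt(s * s - 4 * k2 * p.k4)
        alpha, beta = (s - root) / 2, (s + root) / 2
        c1 = p.k2prime - k2
        c0 = p.k2prime * (k3 + p.k4) - k2 * p.k4
        a_coef = (c0 - alpha * c1) / (beta - alpha)
        b_coef = (beta * c1 - c0) / (beta - alpha)
        cr_vals = ref_params.curve()(GRID)
        num = p.R1 * (
            cr_vals
            + a_coef * numeric_convolve_exp(cr_vals, GRID, alpha)
            + b_coef * numeric_convolve_exp(cr_vals, GRID, beta)
        )
        ana = frtm_curve(p, ref_params)(GRID)
        mask = GRID > ref_params.feng.t0 + 0.5
        scale = np.max(np.abs(ana[mask]))
        assert np.max(np.abs(ana[mask] - num[mask])) < 1e-4 * scale

    def test_degenerate_roots_do_not_crash(self, ref_params, frames):
        # k2 == k4 makes the rate roots collide; the limit form must engage
        p = FRTMParams(1.0, 0.05, 0.0, 0.05)
        vals = frtm_predict(p, ref_params, frames)
        assert np.all(np.isfinite(vals))


# ----------------------------------------------------------------- batch paths
class TestBatch:
    def test_batch_matches_scalar_srtm(self, ref_params, frames):
        rng = np.random.default_rng(0)
        other = FengOneTCParams(
            FengParams(80, 2, 0.3, 3, 0.4, 0.04, 0.7), OneTissueIRF(0.8, 0.08)
        )
        refs = [ref_params, other]
        batch = BatchRefCurves(refs)
        T = 12
        R1 = rng.uniform(0.5, 1.3, T)
        k2p = rng.uniform(0.04, 0.2, T)
        bp = rng.uniform(0.05, 3.5, T)
        idx = rng.integers(2, size=T)
        got = srtm_predict_batch(R1, k2p, bp, batch, idx, frames.midpoints)
        for t in range(T):
            expect = srtm_predict(SRTMParams(R1[t], k2p[t], bp[t]), refs[idx[t]], frames)
            assert np.max(np.abs(got[t] - expect)) < 1e-10

    def test_closed_form_tracks_numeric_for_random_draws(self, ref_params):
        """100 random valid SRTM parameter sets: closed form vs numeric convolution."""
        rng = np.random.default_rng(42)
        cr_vals = ref_params.curve()(GRID)
        mids = default_mids = np.linspace(1.0, 89.0, 45)
        idx = np.searchsorted(GRID, mids)
        batch = BatchRefCurves([ref_params])
        for _ in range(100):
            p = SRTMParams(
                rng.uniform(0.3, 1.5), rng.uniform(0.02, 0.3), rng.uniform(0.0, 6.0)
            )
            num = p.R1 * cr_vals + (p.k2 - p.R1 * p.k2a) * numeric_convolve_exp(
                cr_vals, GRID, p.k2a
            )
            ana = srtm_predict_batch(
                np.array([p.R1]), np.array([p.k2prime]), np.array([p.BPND]),
                batch, np.array([0]), mids,
            )[0]
            assert np.max(np.abs(ana - num[idx]) / np.maximum(np.abs(ana), 1e-6)) < 1e-4


def test_predictions_zero_before_onset(ref_params):
    frames = FrameSchedule(np.array([0.0, 0.2, 5.0]), np.array([0.2, 0.2, 5.0]))
    # first two frame midpoints (0.1, 0.3) fall at or before t0 = 0.5
    ct = srtm_predict(SRTMParams(0.9, 0.1, 1.0), ref_params, frames)
    assert ct[0] == 0.0 and ct[1] == 0.0 and ct[2] > 0.0
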