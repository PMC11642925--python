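"""Synthetic-data generator: counts, effects, noise structure, reproducibility."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from simbaref.kinetics import BatchRefCurves, srtm_predict_batch
from simbaref.simulate import (
    NoiseModel,
    default_truth_parameters,
    make_reference_library,
    simulate_dataset,
)


class TestReferenceLibrary:
    def test_requested_size(self, library):
        assert len(library) == 50

    def test_zero_noise_degenerate_case(self):
        """With every noise scale at zero the measured curve equals the truth
        and the refit reproduces it to numerical precision."""
        noise = NoiseModel(
            sd_log_measurement=0.0, sd_log_subject=0.0, sd_log_region=0.0,
            smooth_amplitude=0.0,
        )
        lib = make_reference_library(
            n=2, noise=noise, seed=1, ref_log_sigma_mean=-np.inf, fit_n_starts=3
        )
        for e in lib.entries:
            assert np.array_equal(e.measured_curve, e.true_curve)
            from simbaref.kinetics import feng1tc_predict

            pred = feng1tc_predict(e.estimated_params, e.frames)
            rel = np.sqrt(np.mean((pred - e.true_curve) ** 2) / np.mean(e.true_curve**2))
            assert rel < 1e-3

    def test_measurement_level_noise_scale_widens_residual_spread(self):
        """Doubling the measurement-to-measurement log-sigma SD increases the
        between-entry variance of the per-entry residual SD."""
        def entry_sds(sd_log, seed):
            noise = NoiseModel(sd_log_measurement=sd_log)
            lib = make_reference_library(n=200, noise=noise, seed=seed, refit=False)
            return np.array([
                np.std(e.measured_curve - e.true_curve) for e in lib.entries
            ])

        narrow = np.log(entry_sds(0.15, 3))
        wide = np.log(entry_sds(0.30, 3))
        assert np.var(wide) > np.var(narrow)


class TestSimulatedDataset:
    def test_tac_count_arithmetic(self, library):
        """n_per_group=10, two groups, two measurements, nine regions -> 360."""
        design = replace(default_truth_parameters(), n_per_group=10, seed=2)
        table, truth, ref_fits = simulate_dataset(design, library)
        assert len(truth) == 10 * 2 * 2 * 9
        assert len(ref_fits) == 10 * 2 * 2
        # the table additionally carries one reference TAC per measurement
        per_meas = table.frames.groupby(["subject_id", "measurement_id"])["region"].nunique()
        assert (per_meas == 10).all()

    def test_seeded_bit_reproducibility(self, library):
        design = replace(default_truth_parameters(), n_per_group=3, seed=9)
        t1, truth1, _ = simulate_dataset(design, library)
        t2, truth2, _ = simulate_dataset(design, library)
        pd.testing.assert_frame_equal(t1.frames, t2.frames)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_group_effect_on_log_binding(self, library):
        """Patients sit ~0.08 lower in mean true logBPND at baseline."""
        design = replace(default_truth_parameters(), n_per_group=400, seed=4)
        _, truth, _ = simulate_dataset(design, library)
        pre = truth[truth.condition == "pre"]
        diff = (
            pre[pre.group == "patient"].true_logBPND.mean()
            - pre[pre.group == "control"].true_logBPND.mean()
        )
        mc_se = pre.groupby("group").true_logBPND.std().mean() / np.sqrt(400)
        assert diff == pytest.approx(-0.08, abs=4 * mc_se)

    def test_placebo_arm_null_before_tac_deviations(self, library):
        """Controls' pre/post difference is exactly zero once TAC-level
        deviations are subtracted: placebo adds nothing to the mean."""
        design = replace(default_truth_parameters(), n_per_group=6, seed=12)
        _, truth, _ = simulate_dataset(design, library)
        ctl = truth[truth.group == "control"].copy()
        ctl["structural"] = ctl.true_logBPND - ctl.tac_dev_logBPND
        wide = ctl.pivot_table(
            index=["subject_id", "region"], columns="condition", values="structural"
        )
        assert np.allclose(wide["post"] - wide["pre"], 0.0, atol=1e-12)

    def test_subject_deviation_covariance_converges(self, library):
        """Empirical covariance of subject deviations approaches the design
        covariance, with Frobenius distance shrinking as n grows."""
        def frob(n, seed):
            design = replace(default_truth_parameters(), n_per_group=n, seed=seed,
                             regions=default_truth_parameters().regions[:2])
            _, truth, _ = simulate_dataset(design, library)
            subj = truth.groupby("subject_id")[
                ["subj_dev_logR1", "subj_dev_logk2prime", "subj_dev_logBPND"]
            ].first()
            emp = np.cov(subj.to_numpy().T)
            return float(np.linalg.norm(emp - default_truth_parameters().sigma_subject))

        assert frob(1000, 8) < frob(30, 8)
        assert frob(1000, 8) < 0.01

    def test_noise_model_duration_coefficient_recovered(self, library):
        """Regressing log |residual| on centred log frame duration recovers the
        configured duration coefficient within 2 standard errors."""
        import statsmodels.api as sm

        design = replace(default_truth_parameters(), n_per_group=20, seed=6)
        table, truth, _ = simulate_dataset(design, library)
        frames = design.frames
        # reconstruct the noiseless target curves from the stored truth
        resids, durs, smooths = [], [], []
        for (sid, mid), g in truth.groupby(["subject_id", "measurement_id"]):
            entry = library.entries[int(g.library_entry.iloc[0])]
            batch = BatchRefCurves([entry.true_params])
            mu = srtm_predict_batch(
                g.true_R1.to_numpy(), g.true_k2prime.to_numpy(), g.true_BPND.to_numpy(),
                batch, np.zeros(len(g), dtype=int), frames.midpoints,
            )
            rows = table.frames[
                (table.frames.subject_id == sid)
                & (table.frames.measurement_id == mid)
                & (table.frames.region != "cerebellum")
            ]
            y = rows.pivot_table(
                index="region", columns="frame_start", values="activity", sort=True
            ).loc[sorted(g.region)].to_numpy()
            mu_sorted = mu[np.argsort(g.region.to_numpy(), kind="stable")]
            resids.append((y - mu_sorted).ravel())
            durs.append(np.tile(frames.frame_duration, len(g)))
            smooths.append(np.tile(design.noise.smooth(frames.midpoints), len(g)))
        resid = np.concatenate(resids)
        clog_dur = np.log(np.concatenate(durs))
        clog_dur -= clog_dur.mean()
        keep = np.abs(resid) > 1e-12
        # remove the known smooth-over-time log-sigma term: early frames are
        # both short and inside the smooth bump, which would otherwise
        # confound the duration coefficient
        response = np.log(np.abs(resid[keep])) - np.concatenate(smooths)[keep]
        fit = sm.OLS(response, sm.add_constant(clog_dur[keep])).fit()
        assert fit.params[1] == pytest.approx(
            design.noise.c_duration, abs=2 * fit.bse[1] + 0.02
        )

    def test_design_validation(self, library):
        with pytest.raises(ValueError, match="positive definite"):
            replace(default_truth_parameters(), sigma_tac=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="subject per group"):
            replace(default_truth_parameters(), n_per_group=0)

    def test_default_truth_template_is_valid(self):
        design = default_truth_parameters()
        assert np.min(np.linalg.eigvalsh(design.sigma_subject)) > 0
        assert np.min(np.linalg.eigvalsh(design.sigma_tac)) > 0
        names = design.region_names
        assert len(names) == 9 and "DBS" in names
        bp = np.exp([r.logBPND_mean for r in design.regions])
        assert bp.max() / bp.min() >= 10.0  # binding spans an order of magnitude
        dbs = next(r for r in design.regions if r.name == "DBS")
        assert dbs.volume_ml == min(r.volume_ml for r in design.regions)
        assert np.exp(dbs.logBPND_mean) <= 0.5  # small, low-binding region
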