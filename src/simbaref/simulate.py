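"""Simulation of realistic reference-tissue PET datasets with known ground truth.

The generator mirrors how real multi-subject PET studies arise:

1. A *reference TAC library* is built by sampling Feng-1TC parameter sets
   (the "true" reference curves), adding structured measurement noise frame
   by frame, and refitting each noisy curve — so that, exactly as in real
   analyses, the model downstream sees an *estimated* reference curve while
   the target data were generated from the *true* one.
2. PK parameters for every subject x measurement x region follow the same
   log-scale hierarchy the model assumes: fixed regional means, multivariate
   normal subject deviations, multivariate normal TAC deviations, plus
   design effects (patients shifted in logBPND; active treatment shifting
   logBPND at the post measurement; placebo shifting nothing).
3. Target TACs are the closed-form SRTM predictions at the true parameters
   plus heteroscedastic Gaussian noise from a structured log-sigma model
   (frame duration, region volume, injected dose, a smooth-in-time bump,
   and subject / region / measurement log-sigma deviations).

Defaults emulate a two-group (control vs patient) pre/post design on a
93-minute, 38-frame acquisition with nine regions whose mean binding spans
an order of magnitude, including a small low-binding brain-stem region
where conventional per-TAC estimation struggles most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TAC, TACTable, REFERENCE_REGION
from .kinetics import (
    BatchRefCurves,
    FengOneTCParams,
    FengParams,
    FrameSchedule,
    OneTissueIRF,
    feng1tc_predict,
    srtm_predict_batch,
)
from .reffit import RefFit, fit_feng1tc

PK_ORDER = ("logR1", "logk2prime", "logBPND")


def default_frame_schedule() -> FrameSchedule:
    """93-minute, 38-frame schedule with increasing frame durations (minutes)."""
    dur = np.array([1 / 6] * 6 + [0.5] * 4 + [1.0] * 6 + [2.0] * 6 + [3.0] * 8 + [6.0] * 8)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


def default_base_feng_fits() -> list[FengOneTCParams]:
    """Plausible Feng-1TC parameter sets for cerebellum-like reference curves.

    Each produces a curve rising to a peak of roughly 5-9 concentration
    units within the first minutes and washing out over the scan.
    """
    return [
        FengOneTCParams(FengParams(100.0, 1.0, 0.5, 4.0, 0.50, 0.050, 0.50), OneTissueIRF(1.0, 0.10)),
        FengOneTCParams(FengParams(140.0, 1.5, 0.7, 5.0, 0.60, 0.040, 0.70), OneTissueIRF(0.9, 0.12)),
        FengOneTCParams(FengParams(80.0, 0.8, 0.4, 3.5, 0.40, 0.060, 0.40), OneTissueIRF(1.1, 0.09)),
    ]


# ------------------------------------------------------------------ sigma model
@dataclass
class NoiseModel:
    """Structured log-sigma model used to generate measurement error.

    ``log sigma = log_mean + c_duration*clog(dur) + c_volume*clog(vol)
    + c_dose*clog(dose) + smooth(t) + subject + region + measurement``
    with the deviations drawn Normal(0, sd). Volume and dose terms are
    relative to reference values so the default scale is interpretable.
    """

    log_mean: float = float(np.log(0.30))
    c_duration: float = -0.5
    c_volume: float = -0.3
    c_dose: float = -0.2
    smooth_amplitude: float = 0.4
    smooth_centre_min: float = 5.0
    smooth_width_min: float = 10.0
    sd_log_measurement: float = 0.2
    sd_log_subject: float = 0.15
    sd_log_region: float = 0.10
    ref_volume_ml: float = 12.0
    ref_dose: float = 300.0

    def smooth(self, t: np.ndarray) -> np.ndarray:
        return self.smooth_amplitude * np.exp(
            -(((t - self.smooth_centre_min) / self.smooth_width_min) ** 2)
        )

    def frame_log_sigma(
        self,
        frames: FrameSchedule,
        volume_ml: float = None,
        dose: float = None,
    ) -> np.ndarray:
        dur = frames.frame_duration
        clog_dur = np.log(dur) - np.mean(np.log(dur))
        out = self.log_mean + self.c_duration * clog_dur + self.smooth(frames.midpoints)
        if volume_ml is not None:
            out = out + self.c_volume * (np.log(volume_ml) - np.log(self.ref_volume_ml))
        if dose is not None:
            out = out + self.c_dose * (np.log(dose) - np.log(self.ref_dose))
        return out


# ---------------------------------------------------------------- study design
@dataclass
class RegionSpec:
    name: str
    logBPND_mean: float
    logR1_mean: float
    logk2prime_offset: float
    volume_ml: float


@dataclass
class SimDesign:
    """The study conditions for one simulated dataset.

    Two equal groups ("control", "patient"), each subject measured pre and
    post; patients sit ``group_effect_logBPND`` lower in logBPND and receive
    active treatment (``treatment_effect_logBPND`` added at post); controls
    receive placebo (``placebo_effect_logBPND``, zero by default). Effects
    are additive on the log scale.
    """

    n_per_group: int = 10
    regions: list[RegionSpec] = field(default_factory=lambda: [
        RegionSpec("ACC", np.log(1.2), np.log(1.00), 0.03, 12.0),
        RegionSpec("AMG", np.log(0.9), np.log(0.85), -0.04, 4.0),
        RegionSpec("DBS", np.log(0.30), np.log(0.90), 0.00, 2.0),
        RegionSpec("FC", np.log(1.3), np.log(0.95), 0.05, 90.0),
        RegionSpec("HIP", np.log(0.60), np.log(0.85), -0.08, 8.0),
        RegionSpec("INS", np.log(1.1), np.log(0.95), 0.02, 15.0),
        RegionSpec("OC", np.log(3.0), np.log(1.05), 0.04, 40.0),
        RegionSpec("THA", np.log(0.50), np.log(0.90), -0.02, 16.0),
        RegionSpec("VSTR", np.log(1.5), np.log(0.95), 0.00, 6.0),
    ])
    logk2prime_mean: float = float(np.log(0.09))
    group_effect_logBPND: float = -0.08
    treatment_effect_logBPND: float = 0.04
    placebo_effect_logBPND: float = 0.0
    sigma_subject: np.ndarray = field(default_factory=lambda: _cov(
        sds=(0.05, 0.10, 0.20), corr=((1.0, 0.3, 0.5), (0.3, 1.0, 0.2), (0.5, 0.2, 1.0))
    ))
    sigma_tac: np.ndarray = field(default_factory=lambda: _cov(
        sds=(0.02, 0.02, 0.03), corr=np.eye(3)
    ))
    noise: NoiseModel = field(default_factory=NoiseModel)
    frames: FrameSchedule = field(default_factory=default_frame_schedule)
    dose_mean: float = 300.0
    dose_sd_log: float = 0.15
    volume_sd_log: float = 0.2
    age_mean: float = 40.0
    age_sd: float = 12.0
    centre: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in (("sigma_subject", self.sigma_subject), ("sigma_tac", self.sigma_tac)):
            c = np.asarray(c, float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.min(np.linalg.eigvalsh(c)) <= 0:
                raise ValueError(f"{name} must be positive definite")
        if self.n_per_group < 1:
            raise ValueError("need at least 1 subject per group")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]


def _cov(sds, corr) -> np.ndarray:
    s = np.asarray(sds, float)
    c = np.asarray(corr, float)
    return c * np.outer(s, s)


def default_truth_parameters() -> SimDesign:
    """The default study conditions (a complete, valid :class:`SimDesign`)."""
    return SimDesign()


# ------------------------------------------------------------ reference library
@dataclass
class RefLibraryEntry:
    """One simulated reference measurement: truth, noisy data, and its refit."""

    true_params: FengOneTCParams
    true_curve: np.ndarray
    measured_curve: np.ndarray
    estimated_params: FengOneTCParams
    frames: FrameSchedule
    refit: RefFit | None


@dataclass
class RefLibrary:
    entries: list[RefLibraryEntry]
    frames: FrameSchedule

    def __len__(self) -> int:
        return len(self.entries)


def make_reference_library(
    base_fits: list[FengOneTCParams] | None = None,
    n: int = 500,
    noise: NoiseModel | None = None,
    seed: int = 0,
    frames: FrameSchedule | None = None,
    ref_log_sigma_mean: float = float(np.log(0.15)),
    fit_n_starts: int = 10,
    retry_cap: int = 5,
    refit: bool = True,
) -> RefLibrary:
    """Build a library of noisy reference TACs with known truth and refits.

    Noise is layered in log-sigma: (1) per-frame offsets from the frame-
    duration coefficient and the smooth-over-time term, (2) the mean
    reference noise scale ``ref_log_sigma_mean`` (the reference region is
    large, hence quieter than typical target regions), (3) a
    measurement-to-measurement deviation Normal(0, sd_log_measurement), (4)
    all summed in log-sigma before drawing per-frame Gaussian noise. Each
    noisy curve is refit with the Feng-1TC model; fits that fail or remain
    flagged as underfit after restarts are regenerated with a fresh noise
    draw, up to ``retry_cap`` times per entry. ``refit=False`` skips the
    refitting step (estimated parameters are set to the truth) for studies
    of the noise process itself.
    """
    if base_fits is None:
        base_fits = default_base_feng_fits()
    if not base_fits:
        raise ValueError("base_fits must be non-empty")
    if n < 1:
        raise ValueError("library size must be >= 1")
    noise = noise if noise is not None else NoiseModel()
    frames = frames if frames is not None else default_frame_schedule()
    rng = np.random.default_rng(seed)
    dur = frames.frame_duration
    clog_dur = np.log(dur) - np.mean(np.log(dur))
    base_log_sigma = (
        ref_log_sigma_mean + noise.c_duration * clog_dur + noise.smooth(frames.midpoints)
    )
    entries: list[RefLibraryEntry] = []
    for i in range(n):
        true = base_fits[rng.integers(len(base_fits))]
        true_curve = feng1tc_predict(true, frames)
        if not refit:
            pet_dev = rng.normal(0.0, noise.sd_log_measurement)
            measured = true_curve + rng.normal(0.0, np.exp(base_log_sigma + pet_dev))
            entries.append(
                RefLibraryEntry(
                    true_params=true, true_curve=true_curve, measured_curve=measured,
                    estimated_params=true, frames=frames, refit=None,
                )
            )
            continue
        fit, measured = None, None
        for attempt in range(retry_cap + 1):
            pet_dev = rng.normal(0.0, noise.sd_log_measurement)
            sigma = np.exp(base_log_sigma + pet_dev)
            candidate = true_curve + rng.normal(0.0, sigma)
            tac = TAC("lib", f"e{i}", REFERENCE_REGION, frames, candidate)
            try:
                cand_fit = fit_feng1tc(
                    tac, n_starts=fit_n_starts, seed=int(rng.integers(2**31))
                )
            except Exception:
                continue
            fit, measured = cand_fit, candidate
            if not fit.underfit_flag:
                break
        if fit is None:
            raise RuntimeError(
                f"reference library entry {i}: no converged fit in {retry_cap + 1} attempts"
            )
        entries.append(
            RefLibraryEntry(
                true_params=true,
                true_curve=true_curve,
                measured_curve=measured,
                estimated_params=fit.params,
                frames=frames,
                refit=fit,
            )
        )
    return RefLibrary(entries=entries, frames=frames)


# --------------------------------------------------------------------- dataset
def simulate_dataset(
    design: SimDesign,
    library: RefLibrary,
    seed: int | None = None,
) -> tuple[TACTable, pd.DataFrame, dict[tuple[str, str], FengOneTCParams]]:
    """Simulate a full pre/post two-group dataset from a reference library.

    Returns ``(table, truth, ref_fits)``: the TAC table (including the noisy
    reference TAC of the sampled library entry for each measurement), the
    ground-truth table (one row per TAC with the deviation decomposition),
    and the mapping measurement -> *estimated* Feng-1TC parameters to be
    used by downstream fitting — the true parameters generated the data.
    """
    if len(library) == 0:
        raise ValueError("reference library is empty")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    frames = design.frames
    if len(frames) != len(library.frames) or not np.allclose(
        frames.frame_start, library.frames.frame_start
    ):
        raise ValueError("design frame schedule must match the reference library")

    regions = design.regions
    R = len(regions)
    groups = ["control"] * design.n_per_group + ["patient"] * design.n_per_group
    n_sub = len(groups)
    width = len(str(n_sub))
    frame_rows = []
    truth_rows = []
    ref_fits: dict[tuple[str, str], FengOneTCParams] = {}
    meta_rows = []

    region_logBP = np.array([r.logBPND_mean for r in regions])
    region_logR1 = np.array([r.logR1_mean for r in regions])
    region_logk2p = design.logk2prime_mean + np.array(
        [r.logk2prime_offset for r in regions]
    )
    vol_means = np.array([r.volume_ml for r in regions])

    for j, group in enumerate(groups):
        sid = f"s{j + 1:0{width}d}"
        age = float(np.clip(rng.normal(design.age_mean, design.age_sd), 18.0, 80.0))
        subj_dev = rng.multivariate_normal(np.zeros(3), design.sigma_subject)
        subj_sigma_dev = rng.normal(0.0, design.noise.sd_log_subject)
        region_sigma_dev = rng.normal(0.0, design.noise.sd_log_region, R)
        vols = np.exp(np.log(vol_means) + rng.normal(0.0, design.volume_sd_log, R))
        for occ, condition in enumerate(["pre", "post"]):
            mid = f"m{occ + 1}"
            entry_idx = int(rng.integers(len(library)))
            entry = library.entries[entry_idx]
            dose = float(np.exp(np.log(design.dose_mean) + rng.normal(0.0, design.dose_sd_log)))
            tac_dev = rng.multivariate_normal(np.zeros(3), design.sigma_tac, R)
            effect = design.group_effect_logBPND if group == "patient" else 0.0
            if condition == "post":
                effect += (
                    design.treatment_effect_logBPND
                    if group == "patient"
                    else design.placebo_effect_logBPND
                )
            logR1 = region_logR1 + subj_dev[0] + tac_dev[:, 0]
            logk2p = region_logk2p + subj_dev[1] + tac_dev[:, 1]
            logBP = region_logBP + subj_dev[2] + tac_dev[:, 2] + effect

            batch = BatchRefCurves([entry.true_params])
            mu = srtm_predict_batch(
                np.exp(logR1), np.exp(logk2p), np.exp(logBP),
                batch, np.zeros(R, dtype=int), frames.midpoints,
            )
            meas_dev = rng.normal(0.0, design.noise.sd_log_measurement)
            for k, reg in enumerate(regions):
                log_sig = (
                    design.noise.frame_log_sigma(frames, vols[k], dose)
                    + subj_sigma_dev + region_sigma_dev[k] + meas_dev
                )
                y = mu[k] + rng.normal(0.0, np.exp(log_sig))
                frame_rows.append(pd.DataFrame({
                    "subject_id": sid, "measurement_id": mid, "centre": design.centre,
                    "region": reg.name, "frame_start": frames.frame_start,
                    "frame_duration": frames.frame_duration, "activity": y,
                }))
                truth_rows.append({
                    "subject_id": sid, "measurement_id": mid, "region": reg.name,
                    "group": group, "condition": condition, "age": age,
                    "true_R1": float(np.exp(logR1[k])),
                    "true_k2prime": float(np.exp(logk2p[k])),
                    "true_BPND": float(np.exp(logBP[k])),
                    "true_logBPND": float(logBP[k]),
                    "subj_dev_logR1": subj_dev[0], "subj_dev_logk2prime": subj_dev[1],
                    "subj_dev_logBPND": subj_dev[2],
                    "tac_dev_logR1": tac_dev[k, 0], "tac_dev_logk2prime": tac_dev[k, 1],
                    "tac_dev_logBPND": tac_dev[k, 2],
                    "library_entry": entry_idx,
                })
            frame_rows.append(pd.DataFrame({
                "subject_id": sid, "measurement_id": mid, "centre": design.centre,
                "region": REFERENCE_REGION, "frame_start": frames.frame_start,
                "frame_duration": frames.frame_duration,
                "activity": entry.measured_curve,
            }))
            ref_fits[(sid, mid)] = entry.estimated_params
            meta_rows.append({
                "subject_id": sid, "measurement_id": mid, "centre": design.centre,
                "injected_dose": dose, "age": age, "group": group,
                "condition": condition,
                "region_volumes": {r.name: float(v) for r, v in zip(regions, vols)},
            })

    table = TACTable(
        frames=pd.concat(frame_rows, ignore_index=True),
        meta=pd.DataFrame(meta_rows),
    )
    truth = pd.DataFrame(truth_rows)
    return table, truth, ref_fits
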