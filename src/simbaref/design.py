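"""Model specification and design-matrix construction for the hierarchical model.

The hierarchical model places a linear predictor on the natural log of each
PK parameter: a global intercept, unpooled (fixed-effect) covariates, and
partially pooled deviations for subject, region and TAC
(subject x measurement x region). Regional differences in logR1 and logBPND
are heterogeneous across the brain, so they enter as unpooled dummy
covariates; regional variation in logk2prime — theoretically absent — is
partially pooled towards zero instead. The measurement-error model predicts
log sigma per frame from a global level, subject and region deviations, the
centred logs of frame duration / region volume / injected dose, and a smooth
function of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .io import TACTable
from .kinetics import BatchRefCurves, FengOneTCParams, FrameSchedule
from .reffit import RefFit

KNOWN_TERMS = ("age", "group", "post", "group:post", "age:group", "centre", "centre:region")


class DesignError(ValueError):
    """The dataset cannot support the requested design."""


# ------------------------------------------------------------------------ spec
@dataclass
class Priors:
    """Prior hyper-parameters, all on the log-parameter scale.

    Scale (SD) parameters get half-normal priors with the scales below;
    correlation matrices get LKJ(eta) priors. ``intercept_mu`` sets the
    location of the moderately-informative intercept priors and must cover
    every PK parameter in the spec. ``sigma_mu=None`` means the log-sigma
    intercept prior is centred at a data-scale heuristic (5% of the mean
    peak activity) when the model is built.
    """

    intercept_mu: dict[str, float] = field(
        default_factory=lambda: {"logR1": -0.1, "logk2prime": -2.2, "logBPND": 0.0}
    )
    intercept_sd: float = 0.25
    subject_sd: dict[str, float] = field(
        default_factory=lambda: {"logR1": 0.3, "logk2prime": 0.1, "logBPND": 0.3, "logk4": 0.1}
    )
    region_sd: dict[str, float] = field(
        default_factory=lambda: {"logR1": 0.3, "logk2prime": 0.1, "logBPND": 0.3, "logk4": 0.1}
    )
    tac_sd: float = 0.025
    region_dummy_sd: float = 2.5
    centre_sd: float = 0.1
    age_sd: float = 0.1
    clinical_sd: float = 0.05
    slope_sd_scale: float = 0.1
    lkj_eta: float = 2.0
    logk4_mu: float = float(np.log(0.05))
    sigma_mu: float | None = None
    sigma_mu_sd: float = 1.5
    sigma_coef_sd: float = 0.5
    sigma_spline_sd: float = 0.5
    sigma_dev_sd: float = 0.3


@dataclass
class MCMCOptions:
    """Sampler settings: chains, warmup/sampling sweeps, seed, adaptation targets."""

    chains: int = 3
    warmup: int = 1000
    samples: int = 1000
    seed: int = 1
    target_accept_block: float = 0.3
    target_accept_joint: float = 0.25
    mix_reps: int = 8  # repetitions of the likelihood-free interweaving moves per sweep
    loglik_thin: int = 1
    progress: bool = False


@dataclass
class SimbaSpec:
    """Full model specification: PK parameters, covariates, priors, MCMC options.

    ``covariates`` maps a PK parameter to fixed-effect terms drawn from
    ``{"age", "group", "post", "group:post", "age:group", "centre",
    "centre:region"}``; region dummies are controlled separately via
    ``region_dummies``. ``region_age_slopes`` lists PK parameters that get
    partially pooled region x age random slopes on top of the global age
    effect.
    """

    pk_parameters: tuple[str, ...] = ("logR1", "logk2prime", "logBPND")
    region_dummies: tuple[str, ...] = ("logR1", "logBPND")
    covariates: dict[str, list[str]] = field(default_factory=dict)
    region_age_slopes: tuple[str, ...] = ()
    sigma_spline_df: int = 8
    frame_average: bool = False
    priors: Priors = field(default_factory=Priors)
    mcmc: MCMCOptions = field(default_factory=MCMCOptions)

    def __post_init__(self) -> None:
        for p, terms in self.covariates.items():
            if p not in self.pk_parameters:
                raise DesignError(f"covariates given for unknown PK parameter '{p}'")
            for t in terms:
                if t not in KNOWN_TERMS:
                    raise DesignError(f"unknown covariate term '{t}'")
        for p in self.pk_parameters:
            if p not in self.priors.intercept_mu and p != "logk4":
                raise DesignError(f"priors.intercept_mu missing entry for '{p}'")

    @property
    def m(self) -> int:
        return len(self.pk_parameters)

    @property
    def uses_frtm(self) -> bool:
        return "logk4" in self.pk_parameters


# --------------------------------------------------------------- spline basis
def bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Low-rank smooth basis: cubic B-splines with quantile-spaced knots, centred columns."""
    x = np.asarray(x, float)
    n_internal = df - degree - 1
    if n_internal < 0:
        raise DesignError(f"spline df={df} too small for degree {degree}")
    qs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.quantile(x, qs) if n_internal else np.array([])
    lo, hi = x.min(), x.max() + 1e-9
    knots = np.r_[[lo] * (degree + 1), internal, [hi] * (degree + 1)]
    basis = BSpline.design_matrix(x, knots, degree).toarray()
    return basis - basis.mean(axis=0, keepdims=True)


# --------------------------------------------------------------------- design
@dataclass
class FixedEffects:
    """Fixed-effect design for one PK parameter."""

    names: list[str]
    X: np.ndarray  # (T, p)
    prior_sd: np.ndarray  # (p,)


@dataclass
class Design:
    """Packed arrays driving the likelihood: the bridge from tables to the sampler."""

    spec: SimbaSpec
    y: np.ndarray  # (T, F) measured activities
    frames: FrameSchedule
    subjects: list[str]
    regions: list[str]
    meas_keys: list[tuple[str, str]]
    subject_idx: np.ndarray  # (T,)
    region_idx: np.ndarray  # (T,)
    meas_idx: np.ndarray  # (T,)
    tac_keys: pd.DataFrame  # subject_id, measurement_id, region per TAC row
    fixed: dict[str, FixedEffects]
    ref_batch: BatchRefCurves
    age_decades: np.ndarray  # (T,) centred
    clog_duration: np.ndarray  # (F,) centred
    clog_volume: np.ndarray  # (T,) centred
    clog_dose: np.ndarray  # (T,) centred
    spline: np.ndarray  # (F, df)

    @property
    def n_tacs(self) -> int:
        return self.y.shape[0]

    @property
    def n_frames(self) -> int:
        return self.y.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _require_meta(meta: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in meta.columns or meta[c].isna().all()]
    if missing:
        raise DesignError(f"metadata column(s) missing: {', '.join(missing)}")


def _levels(series: pd.Series, what: str, need: int = 2) -> list:
    lv = sorted(series.dropna().unique().tolist())
    if len(lv) < need:
        raise DesignError(f"covariate '{what}' has a single level; cannot enter the design")
    return lv


def build_design(
    dataset: TACTable,
    ref_fits: dict[tuple[str, str], RefFit | FengOneTCParams],
    spec: SimbaSpec,
) -> Design:
    """Assemble design matrices and index maps from a TAC table.

    Requirements: at least 2 subjects and 2 target regions, complete
    metadata for every requested covariate, a reference fit per measurement,
    and a frame schedule shared by all measurements (the packed likelihood
    evaluates every TAC on a common grid).
    """
    tacs = list(dataset.iter_tacs())
    if not tacs:
        raise DesignError("dataset contains no target TACs")
    frames = tacs[0].frames
    for t in tacs:
        if len(t.frames) != len(frames) or not np.allclose(
            t.frames.frame_start, frames.frame_start
        ):
            raise DesignError("all measurements must share one frame schedule")

    subjects = sorted({t.subject_id for t in tacs})
    regions = sorted({t.region for t in tacs})
    if len(subjects) < 2 or len(regions) < 2:
        raise DesignError("need at least 2 subjects and 2 target regions")
    meas_keys = sorted({(t.subject_id, t.measurement_id) for t in tacs})
    for key in meas_keys:
        if key not in ref_fits:
            raise DesignError(f"missing reference fit for measurement {key}")

    s_map = {s: i for i, s in enumerate(subjects)}
    r_map = {r: i for i, r in enumerate(regions)}
    m_map = {k: i for i, k in enumerate(meas_keys)}

    y = np.stack([t.activity for t in tacs])
    subject_idx = np.array([s_map[t.subject_id] for t in tacs])
    region_idx = np.array([r_map[t.region] for t in tacs])
    meas_idx = np.array([m_map[(t.subject_id, t.measurement_id)] for t in tacs])
    tac_keys = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in tacs],
            "measurement_id": [t.measurement_id for t in tacs],
            "region": [t.region for t in tacs],
        }
    )

    # ---- per-TAC metadata
    meta_df = pd.DataFrame([t.metadata for t in tacs])
    needed = set()
    for terms in spec.covariates.values():
        for term in terms:
            needed.update(term.split(":"))
    if spec.region_age_slopes:
        needed.add("age")
    col_of = {"age": "age", "group": "group", "post": "condition", "centre": "centre"}
    _require_meta(meta_df, [col_of[n] for n in needed if n != "region"])

    T = len(tacs)
    if "age" in needed:
        age_raw = meta_df["age"].to_numpy(float)
        # centre over measurements (not TAC rows) so region counts don't bias it
        meas_age = pd.DataFrame({"m": meas_idx, "age": age_raw}).groupby("m")["age"].first()
        age_decades = (age_raw - meas_age.mean()) / 10.0
    else:
        age_decades = np.zeros(T)

    def column(term: str) -> tuple[list[str], np.ndarray, float]:
        pr = spec.priors
        if term == "age":
            return ["age"], age_decades[:, None], pr.age_sd
        if term == "group":
            lv = _levels(meta_df["group"], "group")
            cols = [(meta_df["group"] == g).to_numpy(float) for g in lv[1:]]
            return [f"group_{g}" for g in lv[1:]], np.column_stack(cols), pr.clinical_sd
        if term == "post":
            lv = _levels(meta_df["condition"], "condition")
            x = (meta_df["condition"] == "post").to_numpy(float)
            return ["post"], x[:, None], pr.clinical_sd
        if term == "group:post":
            lv = _levels(meta_df["group"], "group")
            post = (meta_df["condition"] == "post").to_numpy(float)
            cols, names = [], []
            for g in lv[1:]:
                cols.append((meta_df["group"] == g).to_numpy(float) * post)
                names.append(f"group_{g}:post")
            return names, np.column_stack(cols), pr.clinical_sd
        if term == "age:group":
            lv = _levels(meta_df["group"], "group")
            cols, names = [], []
            for g in lv[1:]:
                cols.append((meta_df["group"] == g).to_numpy(float) * age_decades)
                names.append(f"age:group_{g}")
            return names, np.column_stack(cols), pr.age_sd
        if term == "centre":
            lv = _levels(meta_df["centre"], "centre")
            cols = [(meta_df["centre"] == c).to_numpy(float) for c in lv[1:]]
            return [f"centre_{c}" for c in lv[1:]], np.column_stack(cols), pr.centre_sd
        if term == "centre:region":
            lv = _levels(meta_df["centre"], "centre")
            cols, names = [], []
            for c in lv[1:]:
                cc = (meta_df["centre"] == c).to_numpy(float)
                for r in regions[1:]:
                    cols.append(cc * (region_idx == r_map[r]))
                    names.append(f"centre_{c}:region_{r}")
            return names, np.column_stack(cols), pr.centre_sd
        raise DesignError(f"unknown covariate term '{term}'")

    fixed: dict[str, FixedEffects] = {}
    for p in spec.pk_parameters:
        names: list[str] = []
        blocks: list[np.ndarray] = []
        sds: list[np.ndarray] = []
        if p in spec.region_dummies:
            for r in regions[1:]:
                names.append(f"region_{r}")
                blocks.append((region_idx == r_map[r]).astype(float)[:, None])
                sds.append(np.array([spec.priors.region_dummy_sd]))
        for term in spec.covariates.get(p, []):
            nm, X, sd = column(term)
            names.extend(nm)
            blocks.append(X)
            sds.append(np.full(X.shape[1], sd))
        X = np.hstack(blocks) if blocks else np.zeros((T, 0))
        fixed[p] = FixedEffects(names=names, X=X, prior_sd=np.concatenate(sds) if sds else np.zeros(0))

    # ---- sigma-model covariates
    clog_dur = np.log(frames.frame_duration)
    clog_dur = clog_dur - clog_dur.mean()
    vols = meta_df.get("region_volume", pd.Series(np.ones(T))).to_numpy(float)
    vols = np.where(np.isfinite(vols) & (vols > 0), vols, 1.0)
    clog_vol = np.log(vols)
    clog_vol = clog_vol - clog_vol.mean()
    doses = meta_df.get("injected_dose", pd.Series(np.ones(T))).to_numpy(float)
    doses = np.where(np.isfinite(doses) & (doses > 0), doses, 1.0)
    clog_dose = np.log(doses)
    clog_dose = clog_dose - clog_dose.mean()
    spline = bspline_basis(frames.midpoints, spec.sigma_spline_df)

    refs = [
        (rf.params if isinstance(rf, RefFit) else rf) for rf in (ref_fits[k] for k in meas_keys)
    ]
    return Design(
        spec=spec,
        y=y,
        frames=frames,
        subjects=subjects,
        regions=regions,
        meas_keys=meas_keys,
        subject_idx=subject_idx,
        region_idx=region_idx,
        meas_idx=meas_idx,
        tac_keys=tac_keys,
        fixed=fixed,
        ref_batch=BatchRefCurves(refs),
        age_decades=age_decades,
        clog_duration=clog_dur,
        clog_volume=clog_vol,
        clog_dose=clog_dose,
        spline=spline,
    )
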