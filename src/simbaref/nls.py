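"""Conventional per-TAC SRTM quantification by bounded nonlinear least squares.

This is the two-stage comparator: each target TAC is fit independently
against the fitted reference curve, and the resulting (R1, k2prime, BPND)
estimates are analysed downstream in a separate statistical model. No
information is shared between TACs — the contrast with the simultaneous
hierarchical model is the point.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import TAC, TACTable
from .kinetics import FengOneTCParams, SRTMParams, srtm_predict
from .reffit import RefFit, _weights

#: Default parameter box: R1, k2prime (1/min), BPND.
DEFAULT_BOUNDS = (np.array([0.01, 0.005, 0.0]), np.array([5.0, 1.0, 20.0]))


@dataclass
class NLSEstimate:
    """Best-of-starts bounded SRTM fit for one TAC."""

    tac_id: tuple[str, str, str]  # (subject, measurement, region)
    params: SRTMParams
    standard_errors: np.ndarray
    rss: float
    converged: bool

    def as_row(self) -> dict:
        s, m, r = self.tac_id
        return {
            "subject_id": s,
            "measurement_id": m,
            "region": r,
            "R1": self.params.R1,
            "k2prime": self.params.k2prime,
            "BPND": self.params.BPND,
            "se_R1": self.standard_errors[0],
            "se_k2prime": self.standard_errors[1],
            "se_BPND": self.standard_errors[2],
            "rss": self.rss,
            "converged": self.converged,
        }


def _standard_errors(jac: np.ndarray, resid: np.ndarray, n_params: int) -> np.ndarray:
    dof = max(len(resid) - n_params, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se


def fit_srtm_nls(
    tac: TAC,
    ref: RefFit | FengOneTCParams,
    weights: str = "duration",
    n_starts: int = 5,
    seed: int = 0,
    bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_BOUNDS,
    frame_average: bool = False,
) -> NLSEstimate:
    """Fit SRTM parameters (R1, k2prime, BPND) to one target TAC.

    ``ref`` is the fitted parametric reference curve (a :class:`RefFit` or
    its parameters); the target and reference must share a frame schedule.
    Starts are log-uniform draws inside the bounds, deterministic given
    ``seed``; the best (lowest weighted RSS) converged start wins.
    """
    ref_params = ref.params if isinstance(ref, RefFit) else ref
    ref_curve = ref_params.curve()
    lo, hi = bounds
    w = np.sqrt(_weights(tac, weights))
    y = tac.activity
    frames = tac.frames

    def residuals(x: np.ndarray) -> np.ndarray:
        p = SRTMParams(x[0], x[1], x[2])
        return w * (srtm_predict(p, ref_curve, frames, frame_average=frame_average) - y)

    rng = np.random.default_rng(seed)
    x_first = np.array([0.9, 0.1, 1.0])  # physiological mid-range start
    best_sol = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.clip(x_first, lo + 1e-6, hi - 1e-6)
        else:
            x0 = np.exp(rng.uniform(np.log(lo + 1e-6), np.log(hi)))
            x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", max_nfev=300)
        if best_sol is None or (sol.success and sol.cost < best_sol.cost):
            best_sol = sol
    converged = bool(best_sol.success)
    params = SRTMParams(*best_sol.x)
    se = _standard_errors(best_sol.jac, best_sol.fun, 3) if converged else np.full(3, np.nan)
    return NLSEstimate(
        tac_id=(tac.subject_id, tac.measurement_id, tac.region),
        params=params,
        standard_errors=se,
        rss=float(2 * best_sol.cost),
        converged=converged,
    )


def fit_dataset_nls(
    dataset: TACTable,
    ref_fits: dict[tuple[str, str], RefFit | FengOneTCParams],
    weights: str = "duration",
    n_starts: int = 5,
    seed: int = 0,
    subset: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit every target TAC in a dataset; one tidy row per TAC.

    ``ref_fits`` maps (subject_id, measurement_id) to the reference fit for
    that measurement. Results are order-independent: the per-TAC seed is
    derived from the TAC key, not the iteration order. Missing references
    are recorded as failed rows rather than silently dropped.
    ``subset`` optionally restricts fitting to the (subject_id,
    measurement_id, region) keys it contains.
    """
    rows = []
    wanted = None
    if subset is not None:
        wanted = set(map(tuple, subset[["subject_id", "measurement_id", "region"]].to_numpy()))
    for tac in dataset.iter_tacs():
        key = (tac.subject_id, tac.measurement_id, tac.region)
        if wanted is not None and key not in wanted:
            continue
        ref = ref_fits.get((tac.subject_id, tac.measurement_id))
        if ref is None:
            rows.append(
                {
                    "subject_id": key[0],
                    "measurement_id": key[1],
                    "region": key[2],
                    "converged": False,
                    "error": "missing reference fit",
                }
            )
            continue
        key_hash = zlib.crc32("|".join(key).encode())  # stable across runs
        tac_seed = (seed * 1000003 + key_hash) % (2**31)
        est = fit_srtm_nls(
            tac, ref, weights=weights, n_starts=n_starts, seed=int(tac_seed)
        )
        rows.append(est.as_row())
    out = pd.DataFrame(rows).sort_values(["subject_id", "measurement_id", "region"])
    return out.reset_index(drop=True)
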