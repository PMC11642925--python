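"""Forward kinetic models for reference-tissue PET quantification.

The measured quantity is a time-activity curve (TAC): decay-corrected
radioactivity concentration averaged over acquisition frames. Target-region
TACs are predicted from a reference-region curve via the simplified (SRTM)
or full (FRTM) reference tissue model; the reference curve itself is
represented parametrically by a "Feng-1TC" model — a Feng-type tri-exponential
input shape convolved with a one-tissue-compartment impulse response, plus an
onset time t0. The Feng-1TC parameters are purely descriptive (they are fit
to the reference TAC and carry no biological meaning); their value is that the
resulting curve is a polynomial-exponential mixture, so every downstream
convolution has an exact closed form (see :mod:`simbaref.curves`).

Units: time in minutes, rates in 1/min, activities in any consistent
concentration unit (kBq/mL recommended) — the PK parameters depend only on
ratios of activities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .curves import ExpMixCurve, REPEATED_RATE_TOL


class InvalidParameterError(ValueError):
    """A kinetic parameter is outside its mathematical domain."""


class ScheduleError(ValueError):
    """A frame schedule violates its invariants."""


# --------------------------------------------------------------------- schedule
@dataclass(frozen=True)
class FrameSchedule:
    """PET acquisition frames: start times and durations in minutes.

    Frames are half-open intervals ``[start, start + duration)`` measured from
    injection; they must not overlap and must be in chronological order.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ScheduleError("frame_start and frame_duration must be equal-length vectors")
        if np.any(dur <= 0):
            raise ScheduleError("frame durations must be positive")
        if np.any(np.diff(start) < 0):
            raise ScheduleError("frame starts must be non-decreasing")
        if np.any(start[1:] < start[:-1] + dur[:-1] - 1e-9):
            raise ScheduleError("frames overlap")

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    def __len__(self) -> int:
        return self.n_frames


# ----------------------------------------------------------------- parameters
def _check_finite(name: str, *values: float) -> None:
    if not all(np.isfinite(v) for v in values):
        raise InvalidParameterError(f"non-finite value in {name}")


@dataclass(frozen=True)
class FengParams:
    """Feng input-shape parameters: ``(A1*D - A2 - A3) e^{-l1 D} + A2 e^{-l2 D} + A3 e^{-l3 D}``
    with ``D = t - t0``, zero for ``t <= t0``.

    The (A2, lambda2) and (A3, lambda3) terms play symmetric roles, so
    construction canonicalises to ``lambda2 >= lambda3`` by swapping them.
    """

    A1: float
    A2: float
    A3: float
    lambda1: float
    lambda2: float
    lambda3: float
    t0: float

    def __post_init__(self) -> None:
        _check_finite(
            "FengParams", self.A1, self.A2, self.A3,
            self.lambda1, self.lambda2, self.lambda3, self.t0,
        )
        if self.t0 < 0:
            raise InvalidParameterError("t0 must be >= 0")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise InvalidParameterError("decay rates must be >= 0")
        if self.lambda3 > self.lambda2:  # exchangeable pair -> canonical order
            l2, l3, a2, a3 = self.lambda3, self.lambda2, self.A3, self.A2
            object.__setattr__(self, "lambda2", l2)
            object.__setattr__(self, "lambda3", l3)
            object.__setattr__(self, "A2", a2)
            object.__setattr__(self, "A3", a3)

    def curve(self) -> ExpMixCurve:
        rates = np.array([self.lambda1, self.lambda2, self.lambda3])
        coefs = np.array(
            [[-self.A2 - self.A3, self.A1], [self.A2, 0.0], [self.A3, 0.0]]
        )
        return ExpMixCurve(self.t0, rates, coefs).merged()


@dataclass(frozen=True)
class OneTissueIRF:
    """One-tissue impulse response ``K1ref * exp(-k2ref t)`` (descriptive, not biological)."""

    K1ref: float
    k2ref: float

    def __post_init__(self) -> None:
        _check_finite("OneTissueIRF", self.K1ref, self.k2ref)
        if self.K1ref < 0:
            raise InvalidParameterError("K1ref must be >= 0")
        if self.k2ref <= 0:
            raise InvalidParameterError("k2ref must be > 0")


@dataclass(frozen=True)
class FengOneTCParams:
    """The 9-parameter Feng-1TC reference-curve model (6 input-shape + 2 IRF + t0)."""

    feng: FengParams
    irf: OneTissueIRF

    N_FREE_PARAMETERS = 9

    def curve(self) -> ExpMixCurve:
        """Closed-form reference curve: Feng input convolved with the 1TC IRF."""
        return self.feng.curve().convolve_exp(self.irf.k2ref) * self.irf.K1ref

    def to_array(self) -> np.ndarray:
        f, irf = self.feng, self.irf
        return np.array(
            [f.A1, f.A2, f.A3, f.lambda1, f.lambda2, f.lambda3, f.t0, irf.K1ref, irf.k2ref]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "FengOneTCParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (9,):
            raise InvalidParameterError("Feng-1TC parameter vector must have length 9")
        return cls(
            FengParams(x[0], x[1], x[2], x[3], x[4], x[5], x[6]),
            OneTissueIRF(x[7], x[8]),
        )


@dataclass(frozen=True)
class SRTMParams:
    """Simplified reference tissue model parameters.

    R1 is relative delivery (target K1 over reference K1'), k2prime the
    reference-tissue clearance rate (1/min) and BPND the non-displaceable
    binding potential. Derived rates: ``k2 = R1 * k2prime`` and
    ``k2a = k2 / (1 + BPND)``.
    """

    R1: float
    k2prime: float
    BPND: float

    def __post_init__(self) -> None:
        _check_finite("SRTMParams", self.R1, self.k2prime, self.BPND)
        if self.R1 < 0:
            raise InvalidParameterError("R1 must be >= 0")
        if self.k2prime <= 0:
            raise InvalidParameterError("k2prime must be > 0")
        if self.BPND <= -1:
            raise InvalidParameterError("BPND must be > -1")

    @property
    def k2(self) -> float:
        return self.R1 * self.k2prime

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BPND)


@dataclass(frozen=True)
class FRTMParams:
    """Full reference tissue model parameters: SRTM set plus dissociation rate k4.

    Derived: ``k2 = R1 * k2prime``, ``k3 = BPND * k4``.
    """

    R1: float
    k2prime: float
    BPND: float
    k4: float

    def __post_init__(self) -> None:
        _check_finite("FRTMParams", self.R1, self.k2prime, self.BPND, self.k4)
        if self.R1 < 0:
            raise InvalidParameterError("R1 must be >= 0")
        if self.k2prime <= 0:
            raise InvalidParameterError("k2prime must be > 0")
        if self.BPND < 0:
            raise InvalidParameterError("FRTM BPND must be >= 0")
        if self.k4 <= 0:
            raise InvalidParameterError("k4 must be > 0")


# ------------------------------------------------------------------ predictions
def feng_input(p: FengParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the Feng input shape at times ``t`` (minutes)."""
    return p.curve()(t)


def _frame_values(curve: ExpMixCurve, frames: FrameSchedule, frame_average: bool) -> np.ndarray:
    if frame_average:
        return curve.frame_average(frames.frame_start, frames.frame_duration)
    return np.asarray(curve(frames.midpoints), dtype=float)


def feng1tc_predict(
    p: FengOneTCParams, frames: FrameSchedule, frame_average: bool = False
) -> np.ndarray:
    """Reference-curve prediction per frame (midpoint convention by default)."""
    return _frame_values(p.curve(), frames, frame_average)


def srtm_curve(p: SRTMParams, ref: FengOneTCParams | ExpMixCurve) -> ExpMixCurve:
    """Closed-form SRTM target curve.

    ``CT = R1*CR + (k2 - R1*k2a) * (CR (x) exp(-k2a t))`` with
    ``k2 = R1*k2prime`` and ``k2a = k2/(1+BPND)``.
    """
    cr = ref.curve() if isinstance(ref, FengOneTCParams) else ref
    if p.R1 == 0.0:
        return ExpMixCurve.zero(cr.t0)
    washout = p.k2 - p.R1 * p.k2a
    out = cr * p.R1
    if abs(washout) > 0:
        out = out + cr.convolve_exp(p.k2a) * washout
    return out


def srtm_predict(
    p: SRTMParams,
    ref: FengOneTCParams | ExpMixCurve,
    frames: FrameSchedule,
    frame_average: bool = False,
) -> np.ndarray:
    """SRTM target-region TAC prediction per frame."""
    return _frame_values(srtm_curve(p, ref), frames, frame_average)


def frtm_curve(p: FRTMParams, ref: FengOneTCParams | ExpMixCurve) -> ExpMixCurve:
    """Closed-form FRTM target curve.

    In the Laplace domain ``CT = R1 (s+k2prime)(s+k3+k4) / ((s+alpha)(s+beta)) CR``
    with ``alpha*beta = k2*k4`` and ``alpha+beta = k2+k3+k4``, which expands to
    ``R1*[CR + A (CR (x) e^{-alpha t}) + B (CR (x) e^{-beta t})]``. Degenerate
    roots (alpha ~ beta) are handled by a repeated convolution (the
    ``t e^{-alpha t}`` limit kernel), never by failure.
    """
    cr = ref.curve() if isinstance(ref, FengOneTCParams) else ref
    if p.R1 == 0.0:
        return ExpMixCurve.zero(cr.t0)
    k2 = p.R1 * p.k2prime
    k3 = p.BPND * p.k4
    s = k2 + k3 + p.k4
    disc = max(s * s - 4.0 * k2 * p.k4, 0.0)
    root = np.sqrt(disc)
    alpha = 0.5 * (s - root)
    beta = 0.5 * (s + root)
    c1 = p.k2prime - k2
    c0 = p.k2prime * (k3 + p.k4) - k2 * p.k4
    out = cr * 1.0
    if beta - alpha < REPEATED_RATE_TOL:
        # (c1 s + c0)/(s+alpha)^2 -> c1 e^{-alpha t} + (c0 - c1 alpha) t e^{-alpha t}
        conv1 = cr.convolve_exp(alpha)
        out = out + conv1 * c1 + conv1.convolve_exp(alpha) * (c0 - c1 * alpha)
    else:
        a_coef = (c0 - alpha * c1) / (beta - alpha)
        b_coef = (beta * c1 - c0) / (beta - alpha)
        if alpha > 0:
            out = out + cr.convolve_exp(alpha) * a_coef
        elif abs(a_coef) > 0:  # alpha == 0 only when k2*k4 == 0
            raise InvalidParameterError("degenerate FRTM rate alpha = 0")
        out = out + cr.convolve_exp(beta) * b_coef
    return out * p.R1


def frtm_predict(
    p: FRTMParams,
    ref: FengOneTCParams | ExpMixCurve,
    frames: FrameSchedule,
    frame_average: bool = False,
) -> np.ndarray:
    """FRTM target-region TAC prediction per frame."""
    return _frame_values(frtm_curve(p, ref), frames, frame_average)


# -------------------------------------------------------------------- batch SRTM
class BatchRefCurves:
    """Per-measurement reference curves packed into arrays for vectorised SRTM.

    Each Feng-1TC reference curve is a polynomial-exponential mixture with a
    common structure (rates ``lambda1, lambda2, lambda3, k2ref``; only the
    lambda1 term carries a degree-1 coefficient). Packing coefficients into
    dense arrays lets :func:`srtm_predict_batch` evaluate all target TACs of a
    dataset in a handful of numpy broadcasts — the inner loop of the MCMC.
    """

    def __init__(self, refs: list[FengOneTCParams]) -> None:
        self.n = len(refs)
        curves = [r.curve() for r in refs]
        k = max(len(c.rates) for c in curves)
        d = max(c.degree for c in curves)
        self.rates = np.zeros((self.n, k))
        self.p = np.zeros((self.n, k, d + 1))
        self.t0 = np.array([c.t0 for c in curves])
        for i, c in enumerate(curves):
            self.rates[i, : len(c.rates)] = c.rates
            self.p[i, : len(c.rates), : c.degree + 1] = c.coefs


def _batch_cr_and_conv(
    a: np.ndarray,
    p: np.ndarray,
    delta: np.ndarray,
    theta: np.ndarray,
    tol: float = REPEATED_RATE_TOL,
    need_cr: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate packed reference curves and their convolution with ``exp(-theta t)``.

    ``a``: rates (T, K); ``p``: poly coefs (T, K, D); ``delta``: times past
    onset (T, F); ``theta``: per-TAC rate (T,). Returns ``(cr, conv)`` each
    (T, F). Repeated-rate collisions use the same limit form as
    :meth:`ExpMixCurve.convolve_exp`.
    """
    E_a = np.exp(-a[:, :, None] * delta[:, None, :])  # (T, K, F)
    E_th = np.exp(-theta[:, None] * delta)  # (T, F)
    D = p.shape[2]
    cr = np.zeros_like(delta)
    conv = np.zeros_like(delta)
    r = theta[:, None] - a  # (T, K)
    degen = np.abs(r) < tol
    r_safe = np.where(degen, 1.0, r)
    for n in range(D):
        pn = p[:, :, n]  # (T, K)
        if need_cr:
            cr += np.sum(pn[:, :, None] * delta[:, None, :] ** n * E_a, axis=1)
        # generic convolution of D^n e^{-aD} with e^{-theta D}
        pn_gen = np.where(degen, 0.0, pn)
        fact_n = math.factorial(n)
        for m in range(n + 1):
            coef = (-1.0) ** m * fact_n / (math.factorial(n - m) * r_safe ** (m + 1))
            conv += np.sum(
                (coef * pn_gen)[:, :, None] * delta[:, None, :] ** (n - m) * E_a, axis=1
            )
        theta_coef = np.sum((-1.0) ** (n + 1) * fact_n / r_safe ** (n + 1) * pn_gen, axis=1)
        conv += theta_coef[:, None] * E_th
        # degenerate limit: D^{n+1}/(n+1) e^{-aD}
        conv += np.sum(
            np.where(degen, pn / (n + 1.0), 0.0)[:, :, None]
            * delta[:, None, :] ** (n + 1)
            * E_a,
            axis=1,
        )
    return cr, conv


def srtm_predict_batch(
    R1: np.ndarray,
    k2prime: np.ndarray,
    BPND: np.ndarray,
    ref: BatchRefCurves,
    ref_index: np.ndarray,
    frame_times: np.ndarray,
    tol: float = REPEATED_RATE_TOL,
) -> np.ndarray:
    """Vectorised SRTM predictions for many TACs sharing a frame grid.

    Parameters
    ----------
    R1, k2prime, BPND
        Parameter vectors, shape ``(T,)`` — one entry per TAC.
    ref, ref_index
        Packed reference curves and the measurement index of each TAC.
    frame_times
        Evaluation times (frame midpoints), shape ``(F,)`` or ``(T, F)``.

    Returns
    -------
    Predicted activities, shape ``(T, F)``, agreeing with
    :func:`srtm_predict` applied TAC by TAC.
    """
    R1 = np.asarray(R1, float)
    k2 = R1 * k2prime
    k2a = k2 / (1.0 + BPND)  # (T,)
    washout = k2 - R1 * k2a
    idx = np.asarray(ref_index)
    ft = np.asarray(frame_times, float)
    if ft.ndim == 1:
        ft = np.broadcast_to(ft[None, :], (len(idx), len(ft)))
    t0 = ref.t0[idx]
    delta = np.maximum(ft - t0[:, None], 0.0)
    cr, conv = _batch_cr_and_conv(ref.rates[idx], ref.p[idx], delta, k2a, tol)
    out = R1[:, None] * cr + washout[:, None] * conv
    return np.where(ft > t0[:, None], out, 0.0)


def frtm_predict_batch(
    R1: np.ndarray,
    k2prime: np.ndarray,
    BPND: np.ndarray,
    k4: np.ndarray,
    ref: BatchRefCurves,
    ref_index: np.ndarray,
    frame_times: np.ndarray,
    tol: float = REPEATED_RATE_TOL,
) -> np.ndarray:
    """Vectorised FRTM predictions; see :func:`frtm_curve` for the algebra."""
    R1 = np.asarray(R1, float)
    k2 = R1 * k2prime
    k3 = BPND * k4
    s = k2 + k3 + k4
    root = np.sqrt(np.maximum(s * s - 4.0 * k2 * k4, 0.0))
    alpha = 0.5 * (s - root)
    beta = 0.5 * (s + root)
    # keep the two kernels numerically distinct; the partial-fraction pair is
    # continuous across the near-degenerate region at this separation
    sep = np.maximum(10 * tol - (beta - alpha), 0.0)
    alpha = alpha - 0.5 * sep
    beta = beta + 0.5 * sep
    c1 = k2prime - k2
    c0 = k2prime * (k3 + k4) - k2 * k4
    a_coef = (c0 - alpha * c1) / (beta - alpha)
    b_coef = (beta * c1 - c0) / (beta - alpha)
    idx = np.asarray(ref_index)
    ft = np.asarray(frame_times, float)
    if ft.ndim == 1:
        ft = np.broadcast_to(ft[None, :], (len(idx), len(ft)))
    t0 = ref.t0[idx]
    delta = np.maximum(ft - t0[:, None], 0.0)
    a, p = ref.rates[idx], ref.p[idx]
    cr, conv_a = _batch_cr_and_conv(a, p, delta, alpha, tol)
    _, conv_b = _batch_cr_and_conv(a, p, delta, beta, tol, need_cr=False)
    out = R1[:, None] * (cr + a_coef[:, None] * conv_a + b_coef[:, None] * conv_b)
    return np.where(ft > t0[:, None], out, 0.0)
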