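"""Closed-form algebra for sums of polynomial-times-exponential terms.

All reference-tissue kinetic models in this package reduce to curves of
the form

    C(t) = sum_i  p_i(t - t0) * exp(-lambda_i * (t - t0))    for t > t0
    C(t) = 0                                                  for t <= t0

where ``p_i`` is a low-degree polynomial. This family is closed under
addition, scalar multiplication and — crucially — convolution with a
single exponential ``exp(-theta * t)``, which is the only convolution the
reference-tissue models require. Working in this basis turns every model
prediction into an exact closed-form evaluation, avoiding numerical
convolution inside fitting and MCMC loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc

#: Rates closer than this (1/min) are treated as equal and handled with the
#: polynomial limit form rather than the generic partial-fraction form.
REPEATED_RATE_TOL = 1e-6


class InvalidRateError(ValueError):
    """Raised when a convolution rate is non-positive or non-finite."""


@dataclass
class ExpMixCurve:
    """A curve ``sum_i p_i(D) exp(-rate_i D)`` with ``D = t - t0``, zero for ``t <= t0``.

    Parameters
    ----------
    t0
        Onset time (minutes). The curve is identically zero at and before ``t0``.
    rates
        Decay rates, shape ``(k,)``, units 1/min. Must be >= 0.
    coefs
        Polynomial coefficients, shape ``(k, d+1)``; ``coefs[i, n]`` multiplies
        ``D**n * exp(-rates[i] * D)``.
    """

    t0: float
    rates: np.ndarray
    coefs: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        if self.coefs.shape[0] != self.rates.shape[0]:
            raise ValueError("coefs must have one row per rate")
        if not np.all(np.isfinite(self.rates)) or not np.all(np.isfinite(self.coefs)):
            raise ValueError("non-finite curve parameters")
        if np.any(self.rates < 0):
            raise ValueError("negative decay rate")

    # ------------------------------------------------------------------ algebra
    @classmethod
    def zero(cls, t0: float = 0.0) -> "ExpMixCurve":
        return cls(t0, np.zeros(1), np.zeros((1, 1)))

    @property
    def degree(self) -> int:
        return self.coefs.shape[1] - 1

    def __mul__(self, scalar: float) -> "ExpMixCurve":
        return ExpMixCurve(self.t0, self.rates.copy(), self.coefs * float(scalar))

    __rmul__ = __mul__

    def __add__(self, other: "ExpMixCurve") -> "ExpMixCurve":
        if abs(other.t0 - self.t0) > 1e-12:
            raise ValueError("can only add curves sharing an onset time")
        d = max(self.degree, other.degree)
        ca = np.zeros((len(self.rates), d + 1))
        ca[:, : self.degree + 1] = self.coefs
        cb = np.zeros((len(other.rates), d + 1))
        cb[:, : other.degree + 1] = other.coefs
        return ExpMixCurve(
            self.t0, np.concatenate([self.rates, other.rates]), np.vstack([ca, cb])
        ).merged()

    def merged(self, tol: float = REPEATED_RATE_TOL) -> "ExpMixCurve":
        """Combine terms whose rates agree within ``tol``."""
        order = np.argsort(self.rates)
        rates, coefs = self.rates[order], self.coefs[order]
        out_r: list[float] = []
        out_c: list[np.ndarray] = []
        for r, c in zip(rates, coefs):
            if out_r and abs(r - out_r[-1]) < tol:
                out_c[-1] = out_c[-1] + c
            else:
                out_r.append(r)
                out_c.append(c.copy())
        return ExpMixCurve(self.t0, np.array(out_r), np.vstack(out_c))

    # --------------------------------------------------------------- evaluation
    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        delta = np.maximum(t - self.t0, 0.0)
        powers = delta[..., None] ** np.arange(self.coefs.shape[1])  # (..., d+1)
        poly = powers @ self.coefs.T  # (..., k)
        vals = np.sum(poly * np.exp(-np.outer(delta.ravel(), self.rates)).reshape(
            delta.shape + (len(self.rates),)
        ), axis=-1)
        vals = np.where(t > self.t0, vals, 0.0)
        return vals if vals.shape else float(vals)

    def _partial_integral(self, x: np.ndarray) -> np.ndarray:
        """``int_0^x D^n exp(-a D) dD`` summed over terms; x >= 0."""
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for a, poly in zip(self.rates, self.coefs):
            for n, c in enumerate(poly):
                if c == 0.0:
                    continue
                if a * np.max(x, initial=0.0) < 1e-12:
                    total = total + c * x ** (n + 1) / (n + 1)
                else:
                    # int_0^x D^n e^{-aD} dD = n!/a^{n+1} * P(n+1, a x)
                    total = total + c * math.factorial(n) / a ** (n + 1) * gammainc(
                        n + 1, a * x
                    )
        return total

    def frame_average(self, start: np.ndarray, duration: np.ndarray) -> np.ndarray:
        """Exact average of the curve over frames ``[start, start+duration)``."""
        start = np.asarray(start, dtype=float)
        duration = np.asarray(duration, dtype=float)
        lo = np.maximum(start - self.t0, 0.0)
        hi = np.maximum(start + duration - self.t0, 0.0)
        return (self._partial_integral(hi) - self._partial_integral(lo)) / duration

    # -------------------------------------------------------------- convolution
    def convolve_exp(self, theta: float, tol: float = REPEATED_RATE_TOL) -> "ExpMixCurve":
        """Exact convolution with the kernel ``exp(-theta * t)`` (t >= 0).

        The convolution of ``D^n exp(-a D)`` (onset t0) with ``exp(-theta t)``
        is, with ``r = theta - a``,

            sum_{m=0}^{n} (-1)^m n!/((n-m)! r^{m+1}) D^{n-m} e^{-aD}
              + (-1)^{n+1} n!/r^{n+1} e^{-theta D}

        falling back to ``D^{n+1}/(n+1) e^{-aD}`` when ``|r| < tol`` (the
        repeated-rate limit).
        """
        theta = float(theta)
        if not np.isfinite(theta) or theta <= 0:
            raise InvalidRateError(f"convolution rate must be positive, got {theta}")
        d = self.degree
        rates: list[float] = []
        coefs: list[np.ndarray] = []
        theta_coef = np.zeros(d + 2)
        for a, poly in zip(self.rates, self.coefs):
            r = theta - a
            row = np.zeros(d + 2)
            if abs(r) < tol:
                for n, c in enumerate(poly):
                    row[n + 1] += c / (n + 1)
            else:
                for n, c in enumerate(poly):
                    if c == 0.0:
                        continue
                    for m in range(n + 1):
                        row[n - m] += (
                            c * (-1) ** m * math.factorial(n)
                            / (math.factorial(n - m) * r ** (m + 1))
                        )
                    theta_coef[0] += c * (-1) ** (n + 1) * math.factorial(n) / r ** (n + 1)
            rates.append(a)
            coefs.append(row)
        rates.append(theta)
        coefs.append(theta_coef)
        return ExpMixCurve(self.t0, np.array(rates), np.vstack(coefs)).merged(tol)


def numeric_convolve_exp(
    curve_values: np.ndarray, grid: np.ndarray, theta: float
) -> np.ndarray:
    """Trapezoidal numeric convolution of tabulated values with ``exp(-theta t)``.

    Used as an independent cross-check of :meth:`ExpMixCurve.convolve_exp`
    and of the closed-form model predictions. ``grid`` must be uniform.
    """
    from scipy.signal import fftconvolve

    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt):
        raise ValueError("numeric convolution requires a uniform grid")
    kernel = np.exp(-theta * (grid - grid[0]))
    n = len(grid)
    full = fftconvolve(curve_values, kernel)[:n] * dt
    # trapezoid end-correction: subtract half the two endpoint rectangles
    full -= 0.5 * dt * (curve_values * kernel[0] + curve_values[0] * kernel)
    return full
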