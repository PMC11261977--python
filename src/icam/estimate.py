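"""Secondary-electron yield estimators and yield maps.

Two pixelwise estimators of the SE yield eta from the measurement tuple
``(M_tilde, U_1..U_M~)``:

* conventional — uses only the summed voltage,
  ``eta_conv = (V / c_mu) / lambda``;
* ion count-aided (ICA) — replaces the dose in the denominator with the
  best estimate of the actual ion count,
  ``eta_ica = (V / c_mu) / (M_corr + lambda * e^-eta_ica)``,
  an implicit equation solved per pixel.

The ICA denominator substitutes the observed pulse count (pile-up
corrected) plus the expected number of undetected ions, which removes
most of the source shot noise from the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams

__all__ = [
    "YieldMap",
    "eta_conv_pixel",
    "eta_ica_pixel",
    "eta_ica_solve",
    "estimate_map",
    "lambda_sensitivity",
    "lambda_sensitivity_conventional",
]


@dataclass(frozen=True)
class YieldMap:
    """Per-pixel eta estimates with provenance.

    ``convergence_flags`` is 0 where the pixel solver converged, 1 where
    it fell back to the conventional estimate.
    """

    eta_values: np.ndarray
    estimator: str
    params_used: ModelParams
    convergence_flags: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.eta_values)
        if not np.all(np.isfinite(ev)) or np.any(ev < 0):
            raise ValueError("eta_values must be finite and >= 0")

    @property
    def n_fallback(self) -> int:
        return int(np.sum(self.convergence_flags != 0))


def eta_conv_pixel(total_voltage: float, c_mu: float, dose: float) -> float:
    """Conventional estimate ``(V / c_mu) / lambda``."""
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if c_mu <= 0:
        raise ValueError("c_mu must be > 0")
    if total_voltage < 0:
        total_voltage = 0.0
    return (total_voltage / c_mu) / dose


def _ica_objective(eta: float, r: float, m_corr: float, dose: float) -> float:
    return eta * (m_corr + dose * math.exp(-eta)) - r


def eta_ica_pixel(
    total_voltage: float,
    m_corr: float,
    c_mu: float,
    dose: float,
    *,
    tol: float = 1e-9,
    uniqueness_points: int = 32,
) -> float:
    """Ion-count-aided estimate: the root of
    ``eta * (M_corr + lambda * e^-eta) = V / c_mu``.

    Solved by bracketed Brent iteration on
    ``[(V/c_mu)/(M_corr+lambda), (V/c_mu)/max(M_corr, eps)]``; the
    objective is sampled at 32 interior points and multiple sign changes
    raise (ambiguous root).  Returns 0 when V = 0.

    Raises ``RuntimeError`` on non-convergence/ambiguity; callers that
    must always produce a value catch it and fall back (see
    :func:`estimate_map`).
    """
    if dose <= 0 or c_mu <= 0:
        raise ValueError("dose and c_mu must be > 0")
    if m_corr < 0:
        raise ValueError("m_corr must be >= 0")
    r = max(total_voltage, 0.0) / c_mu
    if r == 0.0:
        return 0.0
    if m_corr == 0.0:
        # eta * dose * e^-eta = r has zero or two roots; never a unique one
        raise RuntimeError("V > 0 with zero corrected count: no unique ICA root")
    eps = 1e-12
    # tiny relative inflation guards against the root falling one ulp
    # outside the analytic bracket
    lo = r / (m_corr + dose) * (1.0 - 1e-9)
    hi = r / max(m_corr, eps) * (1.0 + 1e-9)
    flo = _ica_objective(lo, r, m_corr, dose)
    fhi = _ica_objective(hi, r, m_corr, dose)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise RuntimeError("ICA objective does not change sign on the bracket")
    grid = np.linspace(lo, hi, uniqueness_points)
    vals = grid * (m_corr + dose * np.exp(-grid)) - r
    if np.count_nonzero(np.diff(np.sign(vals[vals != 0]))) > 1:
        raise RuntimeError("multiple sign changes: ambiguous ICA root")
    return float(brentq(_ica_objective, lo, hi, args=(r, m_corr, dose),
                        xtol=tol, maxiter=200))


def eta_ica_solve(
    total_voltage: np.ndarray,
    m_corr: np.ndarray,
    c_mu: float,
    dose: float,
    *,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ICA solve over pixel arrays.

    Damped fixed-point iteration ``eta <- R / (M_corr + lambda*e^-eta)``
    (a contraction at all realistic operating points); pixels that fail
    to converge are re-solved with the scalar bracketed routine.  Returns
    ``(eta, flags)`` with flag 1 where the fallback to the conventional
    estimate was needed.
    """
    v_in = np.asarray(total_voltage, float)
    v = v_in.ravel()
    mc = np.asarray(m_corr, float).ravel()
    r = np.maximum(v, 0.0) / c_mu
    eta = np.where(r > 0, r / (mc + dose), 0.0)
    flags = np.zeros(v.shape, dtype=np.uint8)
    # V > 0 with no detected pulse is outside the model: conventional fallback
    bad = (r > 0) & (mc <= 0)
    if bad.any():
        eta[bad] = r[bad] / dose
        flags[bad] = 1
    active = (r > 0) & ~bad
    for _ in range(max_iter):
        if not active.any():
            break
        new = r[active] / (mc[active] + dose * np.exp(-eta[active]))
        delta = np.abs(new - eta[active])
        eta[active] = new
        still = delta >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    for i in np.flatnonzero(active):
        try:
            eta[i] = eta_ica_pixel(float(v[i]), float(mc[i]), c_mu, dose)
        except RuntimeError:
            eta[i] = eta_conv_pixel(float(v[i]), c_mu, dose)
            flags[i] = 1
    return eta.reshape(v_in.shape), flags.reshape(v_in.shape)


def estimate_map(
    total_voltage: np.ndarray,
    m_corr: np.ndarray | None,
    params: ModelParams,
    estimator: str = "ica",
    *,
    apply_dqe: bool = False,
) -> YieldMap:
    """Apply a pixel estimator over a measurement grid.

    ``apply_dqe=True`` divides the output by ``params.dqe`` to report
    absolute yields (the raw scale is implicitly multiplied by the DQE).
    """
    v = np.asarray(total_voltage, float)
    if estimator == "conventional":
        eta = np.maximum(v, 0.0) / (params.c_mu * params.dose)
        flags = np.zeros(v.shape, dtype=np.uint8)
    elif estimator == "ica":
        if m_corr is None:
            raise ValueError("ICA estimation requires corrected pulse counts")
        eta, flags = eta_ica_solve(v, np.asarray(m_corr, float), params.c_mu, params.dose)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if apply_dqe:
        eta = eta / params.dqe
    return YieldMap(eta_values=eta, estimator=estimator, params_used=params,
                    convergence_flags=flags)


def lambda_sensitivity(eta: float, rel_error: float, *, dose: float = 21.0) -> float:
    """Relative change in the ICA estimate from a misspecified dose.

    Holds the measurement statistics at their model expectations for the
    true dose (``V/c_mu = lambda*eta``, ``M_corr = lambda*(1-e^-eta)``),
    re-solves the ICA equation with ``lambda`` replaced by
    ``(1+rel_error)*lambda`` in the explicit correction term only (the
    pulse count is data and is untouched), and returns ``|d eta| / eta``.

    The result is independent of the absolute dose to first order; the
    default matches the canonical operating point.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if rel_error == 0:
        return 0.0
    r = dose * eta
    m_corr = dose * -math.expm1(-eta)
    dose_wrong = (1.0 + rel_error) * dose

    def obj(e: float) -> float:
        return e * (m_corr + dose_wrong * math.exp(-e)) - r

    lo, hi = 1e-9, r / max(m_corr, 1e-12) + 1.0
    eta_hat = brentq(obj, lo, hi, xtol=1e-12)
    return abs(eta_hat - eta) / eta


def lambda_sensitivity_conventional(rel_error: float) -> float:
    """Conventional analogue: since ``eta_conv`` is inversely proportional
    to lambda, the log-derivative ``|d ln eta / d ln lambda|`` is exactly
    1, so a relative dose uncertainty propagates one-to-one."""
    return abs(rel_error)
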