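"""Detector calibration from pulse-height distributions (PHDs).

The peak-height density of detected pulses is a zero-truncated-Poisson
mixture of Gaussians parameterized by (eta, c_mu, c_sigma).  Because
c_mu and c_sigma are detector properties, fits at different effective
yields must agree on them — the key self-consistency check of the model.

Two routes:

* :func:`fit_phd` — unbinned maximum likelihood in all three parameters
  (log-parameterized for positivity), with observed-information standard
  errors.
* :func:`cmu_low_yield` — quick mode-of-KDE estimate of c_mu from a
  low-yield acquisition, where nearly every pulse carries one SE and the
  PHD is close to a single Gaussian peaked at c_mu.  Biased upward at
  higher yields (multi-SE pulses drag the mode right).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.signal import argrelmax

from .model import pulse_height_density

__all__ = ["PHDFit", "fit_phd", "cmu_low_yield"]


@dataclass(frozen=True)
class PHDFit:
    """Maximum-likelihood PHD fit result (natural scale)."""

    eta_hat: float
    c_mu_hat: float
    c_sigma_hat: float
    log_likelihood: float
    n_pulses: int
    standard_errors: dict[str, float]

    def __post_init__(self) -> None:
        if min(self.eta_hat, self.c_mu_hat, self.c_sigma_hat) <= 0:
            raise ValueError("fitted parameters must be positive")


def _nll(theta: np.ndarray, heights: np.ndarray) -> float:
    eta, c_mu, c_sigma = np.exp(theta)
    dens = pulse_height_density(heights, eta, c_mu, c_sigma)
    dens = np.maximum(dens, 1e-300)
    return -float(np.sum(np.log(dens)))


def fit_phd(
    peak_heights: np.ndarray,
    init: tuple[float, float, float] | None = None,
) -> PHDFit:
    """Joint MLE of (eta, c_mu, c_sigma) from raw peak heights.

    Unbinned likelihood only (binning is reserved for display).  A
    Nelder-Mead pass, which tolerates the series-truncation noise of the
    mixture density, is refined by L-BFGS-B on the log-parameters;
    standard errors come from the inverse observed information
    (finite-difference Hessian), delta-method-transformed to the natural
    scale.
    """
    h = np.asarray(peak_heights, float)
    if len(h) < 50:
        raise ValueError("at least 50 pulses required for a PHD fit")
    if np.ptp(h) == 0:
        raise ValueError("zero-variance heights are inconsistent with c_sigma > 0")
    if len(h) < 1000:
        warnings.warn("fewer than 1000 pulses: PHD fit will be imprecise")
    if init is None:
        c_mu0 = cmu_low_yield(h, warn_multimodal=False)
        # method of moments on the truncated mixture, crude but adequate as a start
        mean_j = max(np.mean(h) / c_mu0, 1.05)
        eta0 = _eta_from_truncated_mean(mean_j)
        c_sig0 = max(np.std(h) / math.sqrt(mean_j) * 0.7, 0.2 * c_mu0)
        init = (eta0, c_mu0, c_sig0)
    theta0 = np.log(np.asarray(init, float))
    nm = optimize.minimize(_nll, theta0, args=(h,), method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    res = optimize.minimize(_nll, nm.x, args=(h,), method="L-BFGS-B",
                            options={"maxiter": 500})
    theta = res.x if res.fun <= nm.fun else nm.x
    fun = min(res.fun, nm.fun)
    if not (nm.success or res.success):
        raise RuntimeError(f"PHD fit did not converge: {nm.message} / {res.message}")
    hess = _numerical_hessian(lambda t: _nll(t, h), theta)
    try:
        cov_log = np.linalg.inv(hess)
        if np.any(np.diag(cov_log) <= 0):
            raise np.linalg.LinAlgError
        se_log = np.sqrt(np.diag(cov_log))
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; SEs unreliable")
        se_log = np.full(3, np.nan)
    eta, c_mu, c_sigma = np.exp(theta)
    # delta method: se(exp(t)) = exp(t) * se(t)
    ses = dict(zip(("eta", "c_mu", "c_sigma"), np.exp(theta) * se_log))
    return PHDFit(eta_hat=float(eta), c_mu_hat=float(c_mu), c_sigma_hat=float(c_sigma),
                  log_likelihood=-float(fun), n_pulses=len(h), standard_errors=ses)


def _eta_from_truncated_mean(mean_j: float) -> float:
    """Invert mean_j = eta / (1 - e^-eta) numerically."""
    if mean_j <= 1.0:
        return 0.05
    f = lambda e: e / -math.expm1(-e) - mean_j
    return optimize.brentq(f, 1e-6, 50.0)


def _numerical_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    return H


def cmu_low_yield(peak_heights: np.ndarray, *, warn_multimodal: bool = True) -> float:
    """Per-SE gain from a low-yield PHD: the mode of a Gaussian KDE.

    At low eta almost every pulse carries exactly one SE, so the PHD
    peaks at c_mu.  At higher yields multi-SE components shift the mode
    upward; this estimator is then biased and :func:`fit_phd` should be
    used instead.
    """
    h = np.asarray(peak_heights, float)
    if len(h) < 50:
        raise ValueError("at least 50 pulses required")
    kde = stats.gaussian_kde(h)
    grid = np.linspace(h.min(), h.max(), 2048)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])
    if warn_multimodal:
        locs = argrelmax(dens)[0]
        comparable = [i for i in locs if dens[i] > 0.5 * dens.max()]
        if len(comparable) > 1:
            warnings.warn("PHD KDE has multiple comparable modes; c_mu ambiguous")
    return mode
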