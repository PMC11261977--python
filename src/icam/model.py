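"""Linear probabilistic model of secondary-electron imaging.

The generative model underlying every other module:

* The number of incident ions at a pixel is ``M ~ Poisson(lambda)``,
  where ``lambda`` is the dose in ions per pixel.
* Ion *i* liberates ``X_i ~ Poisson(eta)`` secondary electrons (SEs),
  where ``eta`` is the SE yield of the material under the beam.
* The total SE count ``Y = sum_i X_i`` therefore follows a
  Poisson-stopped-sum (Neyman Type A) law with ``E[Y] = lambda*eta`` and
  ``var(Y) = lambda*eta*(eta+1)``.
* An ion is *detected* iff it produced at least one SE, so the number of
  detected pulses is a thinned Poisson,
  ``M_tilde ~ Poisson(lambda*(1 - exp(-eta)))``, and the SE count of a
  detected ion is zero-truncated Poisson.
* The detector (scintillator + photomultiplier) responds to each SE with
  an independent Gaussian voltage of mean ``c_mu`` and standard deviation
  ``c_sigma``; a pulse carrying ``j`` SEs has peak height
  ``N(j*c_mu, j*c_sigma**2)``.

Everything here is pure computation on scalars and arrays; simulation
lives in :mod:`icam.synth` and estimation in :mod:`icam.estimate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ELEMENTARY_CHARGE",
    "ModelParams",
    "PixelTruth",
    "PixelMeasurement",
    "zero_truncated_poisson_pmf",
    "pulse_height_density",
    "total_se_pmf",
    "detected_count_mean",
    "conditional_ion_mean",
    "dose_from_settings",
    "series_cutoff",
]

#: Elementary charge in coulombs (2019 SI exact value).
ELEMENTARY_CHARGE = 1.602176634e-19


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the SE-imaging generative model.

    Parameters
    ----------
    dose
        Mean number of incident ions per pixel (lambda, dimensionless).
    yield_eta
        Mean number of SEs per incident ion (eta).
    c_mu
        Mean detector voltage per SE, volts.
    c_sigma
        Standard deviation of the detector voltage per SE, volts.
    beam_current, dwell_time, dose_rate
        Optional acquisition settings; if ``beam_current`` and
        ``dwell_time`` are both given they must be consistent with
        ``dose`` through ``dose = I_b * t_d / e``.
    dqe
        Detection quantum efficiency of the SED in (0, 1].  Reported
        yields are implicitly multiplied by the DQE; it is used only to
        rescale yields on output, never inside the likelihood.
    """

    dose: float
    yield_eta: float
    c_mu: float = 0.163
    c_sigma: float = 0.097
    beam_current: float | None = None
    dwell_time: float | None = None
    dose_rate: float | None = field(default=None)
    dqe: float = 1.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.yield_eta < 0:
            raise ValueError("yield_eta must be >= 0")
        if self.c_mu <= 0:
            raise ValueError("c_mu must be > 0")
        if self.c_sigma < 0:
            raise ValueError("c_sigma must be >= 0")
        if not (0.0 < self.dqe <= 1.0):
            raise ValueError("dqe must be in (0, 1]")
        if self.beam_current is not None and self.dwell_time is not None:
            implied = dose_from_settings(self.beam_current, self.dwell_time)
            if implied > 0 and abs(self.dose - implied) > 1e-9 * implied:
                raise ValueError(
                    f"dose={self.dose} inconsistent with I_b*t_d/e={implied}"
                )
        if self.dose_rate is None and self.dwell_time is not None:
            object.__setattr__(self, "dose_rate", self.dose / self.dwell_time)


@dataclass(frozen=True)
class PixelTruth:
    """Latent ground truth for one pixel."""

    ion_count: int
    se_counts: tuple[int, ...]
    total_se: int

    def __post_init__(self) -> None:
        if len(self.se_counts) != self.ion_count:
            raise ValueError("se_counts must have one entry per ion")
        if self.total_se != sum(self.se_counts):
            raise ValueError("total_se must equal sum(se_counts)")


@dataclass(frozen=True)
class PixelMeasurement:
    """Observables for one pixel: pulse count, peak heights, summed voltage."""

    pulse_count: int
    peak_heights: tuple[float, ...]
    total_voltage: float
    corrected_count: float | None = None

    def __post_init__(self) -> None:
        if len(self.peak_heights) != self.pulse_count:
            raise ValueError("peak_heights must have one entry per pulse")
        if self.peak_heights and not math.isclose(
            self.total_voltage, sum(self.peak_heights), rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("total_voltage must equal sum(peak_heights)")
        if self.corrected_count is None:
            object.__setattr__(self, "corrected_count", float(self.pulse_count))
        elif self.corrected_count < self.pulse_count:
            raise ValueError("corrected_count must be >= pulse_count")


def series_cutoff(mean: float, sd: float, floor: int = 50, sd_mult: float = 10.0) -> int:
    """Truncation index for series over SE / pulse counts.

    Sums run to ``ceil(mean + sd_mult*sd)`` with a floor so that the
    omitted tail is negligible relative to estimator noise.
    """
    return max(floor, math.ceil(mean + sd_mult * sd))


def zero_truncated_poisson_pmf(j, eta: float):
    """P(X = j | X >= 1) for X ~ Poisson(eta): the SE count of a detected ion.

    ``e^-eta / (1 - e^-eta) * eta^j / j!`` for integer ``j >= 1``.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0 for the zero-truncated law")
    j_arr = np.asarray(j)
    if np.any(j_arr < 1) or not np.issubdtype(j_arr.dtype, np.integer) and np.any(
        j_arr != np.floor(j_arr)
    ):
        raise ValueError("j must be integer >= 1 (truncation removes j=0)")
    logp = -eta - np.log1p(-np.exp(-eta)) + j_arr * np.log(eta) - gammaln(j_arr + 1)
    out = np.exp(logp)
    return float(out) if np.isscalar(j) else out


def pulse_height_density(u, eta: float, c_mu: float, c_sigma: float, *, tol_sd_mult: float = 10.0):
    """Density of a detected pulse's peak height (volts^-1).

    A zero-truncated-Poisson mixture of Gaussians: component ``j`` has
    weight ``P_ztp(j; eta)``, mean ``j*c_mu`` and variance
    ``j*c_sigma**2``.  The series is truncated adaptively at
    ``max(50, ceil(mean + tol_sd_mult*sd))`` terms of the truncated law.
    """
    if eta <= 0 or c_mu <= 0:
        raise ValueError("eta and c_mu must be > 0")
    if c_sigma <= 0:
        raise ValueError(
            "c_sigma = 0 gives a purely atomic height law (atoms at j*c_mu); "
            "a density cannot be evaluated"
        )
    p_det = -np.expm1(-eta)
    mean_j = eta / p_det
    var_j = mean_j * (eta + 1 - mean_j)
    jmax = series_cutoff(mean_j, math.sqrt(max(var_j, mean_j)), sd_mult=tol_sd_mult)
    j = np.arange(1, jmax + 1)
    logw = -eta - np.log(p_det) + j * np.log(eta) - gammaln(j + 1)
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    # log-sum-exp over mixture components for numerical range
    logphi = (
        -0.5 * ((u_arr[:, None] - j[None, :] * c_mu) ** 2) / (j[None, :] * c_sigma**2)
        - 0.5 * np.log(2 * np.pi * j[None, :] * c_sigma**2)
    )
    lse = logw[None, :] + logphi
    m = lse.max(axis=1, keepdims=True)
    out = np.exp(m[:, 0]) * np.exp(lse - m).sum(axis=1)
    return float(out[0]) if np.isscalar(u) else out


def total_se_pmf(n, dose: float, eta: float):
    """P(Y = n) for the total SE count Y (Neyman Type A distribution).

    Uses the stable two-stage recursion for a Poisson-stopped Poisson sum

    ``p_n = (lambda*eta*e^-eta / n) * sum_{j=0}^{n-1} eta^j/j! * p_{n-1-j}``

    with ``p_0 = exp(-lambda*(1 - e^-eta))``.
    """
    n_arr = np.atleast_1d(np.asarray(n))
    if np.any(n_arr < 0) or np.any(n_arr != np.floor(n_arr)):
        raise ValueError("n must be a nonnegative integer")
    if dose < 0 or eta < 0:
        raise ValueError("dose and eta must be >= 0")
    nmax = int(n_arr.max())
    p = np.zeros(nmax + 1)
    if dose == 0 or eta == 0:
        p[0] = 1.0
    else:
        p[0] = math.exp(-dose * -math.expm1(-eta))
        if nmax >= 1:
            a = dose * eta * math.exp(-eta)
            jj = np.arange(nmax)
            w = np.exp(jj * math.log(eta) - gammaln(jj + 1))
            for k in range(1, nmax + 1):
                p[k] = (a / k) * float(np.dot(w[:k], p[k - 1 :: -1]))
    out = p[n_arr.astype(int)]
    return float(out[0]) if np.isscalar(n) else out


def detected_count_mean(dose: float, eta: float) -> float:
    """Mean number of detected pulses, ``lambda*(1 - e^-eta)``.

    Only ions producing at least one SE register a pulse, so the pulse
    count is a thinned Poisson.
    """
    if dose < 0 or eta < 0:
        raise ValueError("dose and eta must be >= 0")
    return dose * -math.expm1(-eta)


def conditional_ion_mean(pulse_count: float, dose: float, eta: float) -> float:
    """``E[M | M_tilde] = M_tilde + lambda*e^-eta``.

    The additive term is the mean number of ions that produced zero SEs
    and therefore went undetected; it is the optimal correction for
    missed ions under the model.
    """
    if pulse_count < 0 or dose < 0 or eta < 0:
        raise ValueError("arguments must be >= 0")
    return pulse_count + dose * math.exp(-eta)


def dose_from_settings(beam_current: float, dwell_time: float) -> float:
    """Dose in ions per pixel from beam current (A) and dwell time (s):
    ``lambda = I_b * t_d / e``."""
    if beam_current < 0:
        raise ValueError("beam_current must be >= 0")
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    return beam_current * dwell_time / ELEMENTARY_CHARGE
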