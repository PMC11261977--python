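"""Synthetic data generation: per-pixel measurement tuples, phantoms, and
sampled detector waveforms.

The generator draws from exactly the model in :mod:`icam.model`: Poisson
ion arrivals, per-ion zero-truncated-Poisson SE bursts (via Poisson draws
with the zero class dropped), Gaussian per-SE voltage response, and — for
waveforms — finite-width pulse kernels on a uniform time base with white
Gaussian baseline noise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .model import ModelParams, PixelMeasurement, PixelTruth

__all__ = [
    "WaveformConfig",
    "Waveform",
    "Phantom",
    "simulate_pixel",
    "simulate_pixels",
    "simulate_waveform",
    "make_phantom",
    "simulate_image",
    "write_waveform_h5",
    "read_waveform_h5",
    "write_phantom",
]

#: Canonical detector/digitizer settings: 10 ns sampling, ~160 ns FWHM pulses.
DEFAULT_SAMPLE_INTERVAL = 10e-9
DEFAULT_PULSE_FWHM = 160e-9


@dataclass(frozen=True)
class WaveformConfig:
    """Digitizer and pulse-shape settings for waveform synthesis."""

    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    pulse_fwhm: float = DEFAULT_PULSE_FWHM
    pulse_shape: str = "gaussian"
    baseline_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.pulse_fwhm < self.sample_interval:
            raise ValueError("pulse_fwhm must be >= sample_interval")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.pulse_shape not in ("gaussian", "biexponential"):
            raise ValueError(f"unknown pulse_shape {self.pulse_shape!r}")


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled SED voltage trace with pixel dwell boundaries.

    ``pixel_boundaries`` holds ``n_pixels + 1`` sample indices; pixel ``k``
    occupies the half-open interval ``[b[k], b[k+1])``.
    """

    samples: np.ndarray
    sample_interval: float
    pixel_boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.pixel_boundaries)
        if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("pixel_boundaries must be strictly increasing")
        if b[0] < 0 or b[-1] > len(self.samples):
            raise ValueError("pixel_boundaries out of range")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_boundaries) - 1


@dataclass(frozen=True)
class Phantom:
    """Ground-truth SE-yield map (2-D grid of eta values)."""

    eta_map: np.ndarray
    pixel_size: float = 1e-9
    pattern: str = "custom"

    def __post_init__(self) -> None:
        em = np.asarray(self.eta_map)
        if em.size == 0 or em.ndim != 2:
            raise ValueError("eta_map must be a non-empty 2-D grid")
        if np.any(em < 0):
            raise ValueError("eta values must be >= 0")


def simulate_pixel(params: ModelParams, rng: np.random.Generator) -> tuple[PixelTruth, PixelMeasurement]:
    """Draw one pixel's latent truth and its measurement tuple.

    Ions with zero SEs produce no pulse; each detected ion contributes a
    peak height ``N(X_i*c_mu, X_i*c_sigma**2)``.
    """
    m = int(rng.poisson(params.dose))
    x = rng.poisson(params.yield_eta, m).astype(int)
    detected = x >= 1
    heights = rng.normal(
        x[detected] * params.c_mu, np.sqrt(x[detected]) * params.c_sigma
    )
    truth = PixelTruth(ion_count=m, se_counts=tuple(int(v) for v in x), total_se=int(x.sum()))
    meas = PixelMeasurement(
        pulse_count=int(detected.sum()),
        peak_heights=tuple(float(h) for h in heights),
        total_voltage=float(heights.sum()),
    )
    return truth, meas


def simulate_pixels(
    params: ModelParams,
    n_pixels: int,
    rng: np.random.Generator,
    *,
    eta: np.ndarray | float | None = None,
    return_pulses: bool = False,
) -> dict:
    """Vectorized tuple-level simulation of many pixels.

    Returns arrays ``m`` (true ion count), ``y`` (true total SE count),
    ``m_tilde`` (detected pulse count) and ``v`` (summed peak voltage).
    With ``return_pulses=True`` also returns the flat array of peak
    heights and the pixel index of each pulse.

    ``eta`` may be a scalar or per-pixel array overriding
    ``params.yield_eta`` (used for phantom simulation).
    """
    if eta is None:
        eta = params.yield_eta
    eta_px = np.broadcast_to(np.asarray(eta, float), (n_pixels,))
    m = rng.poisson(params.dose, n_pixels)
    ion_pixel = np.repeat(np.arange(n_pixels), m)
    x = rng.poisson(eta_px[ion_pixel])
    det = x >= 1
    h = np.zeros(len(x))
    h[det] = rng.normal(x[det] * params.c_mu, np.sqrt(x[det]) * params.c_sigma)
    out = {
        "m": m,
        "y": np.bincount(ion_pixel, weights=x, minlength=n_pixels).astype(int),
        "m_tilde": np.bincount(ion_pixel, weights=det, minlength=n_pixels).astype(int),
        "v": np.bincount(ion_pixel, weights=h, minlength=n_pixels),
    }
    if return_pulses:
        out["pulse_heights"] = h[det]
        out["pulse_pixel"] = ion_pixel[det]
    return out


def _gaussian_kernel(fwhm: float, dt: float) -> np.ndarray:
    sd = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = int(math.ceil(5 * sd / dt))
    t = np.arange(-half, half + 1) * dt
    return np.exp(-0.5 * (t / sd) ** 2), half


def _biexponential_kernel(fwhm: float, dt: float) -> np.ndarray:
    """Unit-peak rise/decay kernel ``e^-t/tau_f - e^-t/tau_r`` with the decay
    constant solved numerically so the FWHM matches."""
    from scipy.optimize import brentq

    tau_r = fwhm / 10.0

    def kernel_fwhm(tau_f: float) -> float:
        t = np.linspace(0, 20 * tau_f, 4000)
        k = np.exp(-t / tau_f) - np.exp(-t / tau_r)
        k /= k.max()
        above = t[k >= 0.5]
        return above[-1] - above[0]

    tau_f = brentq(lambda tf: kernel_fwhm(tf) - fwhm, 1.05 * tau_r, fwhm * 20)
    t = np.arange(0, math.ceil(12 * tau_f / dt)) * dt
    k = np.exp(-t / tau_f) - np.exp(-t / tau_r)
    k /= k.max()
    # prepend zeros so the peak index is well inside the support
    peak = int(np.argmax(k))
    return k, peak


def simulate_waveform(
    pulse_amplitudes: list[np.ndarray],
    config: WaveformConfig,
    dwell_time: float,
    rng: np.random.Generator,
    *,
    return_arrivals: bool = False,
) -> Waveform:
    """Render per-pixel detected-pulse amplitude lists into a sampled trace.

    Each pixel occupies ``round(dwell_time / sample_interval)`` samples.
    Arrival times are uniform within the dwell interval (the order
    statistics of a homogeneous Poisson process given the count), each
    detected ion adds one unit-peak kernel scaled to its amplitude, pulses
    add linearly, and white Gaussian baseline noise is added.
    """
    dt = config.sample_interval
    if config.pulse_fwhm < 2 * dt:
        warnings.warn("pulse FWHM < 2 samples: peaks will be undersampled")
    ns_pixel = int(round(dwell_time / dt))
    if ns_pixel < 1:
        raise ValueError("dwell_time shorter than one sample")
    n_pixels = len(pulse_amplitudes)
    n_samples = ns_pixel * n_pixels
    if config.pulse_shape == "gaussian":
        kernel, peak_idx = _gaussian_kernel(config.pulse_fwhm, dt)
    else:
        kernel, peak_idx = _biexponential_kernel(config.pulse_fwhm, dt)
    klen = len(kernel)
    pad = klen  # margin so kernels at the edges fit
    trace = np.zeros(n_samples + 2 * pad)

    counts = np.array([len(a) for a in pulse_amplitudes])
    total = int(counts.sum())
    arrivals = np.empty(0)
    if total:
        amps = np.concatenate([np.asarray(a, float) for a in pulse_amplitudes])
        pixel_of = np.repeat(np.arange(n_pixels), counts)
        t_in_pixel = rng.uniform(0.0, dwell_time, total)
        arrivals = np.sort(pixel_of * dwell_time + t_in_pixel)
        centers = pad + pixel_of * ns_pixel + np.round(t_in_pixel / dt).astype(int)
        starts = centers - peak_idx
        offs = np.arange(klen)
        idx = (starts[:, None] + offs[None, :]).ravel()
        vals = (amps[:, None] * kernel[None, :]).ravel()
        np.add.at(trace, idx, vals)
    trace = trace[pad : pad + n_samples]
    if config.baseline_sd > 0:
        trace = trace + rng.normal(0.0, config.baseline_sd, n_samples)
    boundaries = np.arange(n_pixels + 1) * ns_pixel
    wf = Waveform(samples=trace, sample_interval=dt, pixel_boundaries=boundaries)
    return (wf, arrivals) if return_arrivals else wf


_PATTERNS = ("uniform", "squares", "scratch", "custom")


def make_phantom(
    pattern: str,
    shape: tuple[int, int] = (64, 64),
    *,
    eta_background: float = 1.82,
    eta_foreground: float = 2.75,
    eta: float | None = None,
    eta_map: np.ndarray | None = None,
    square_size: int | None = None,
    pixel_size: float = 1e-9,
) -> Phantom:
    """Deterministic ground-truth eta maps.

    ``squares`` places bright squares (default eta 2.75, the gold value)
    on a darker background (default eta 1.82, silicon); ``scratch`` puts a
    darker diagonal groove on the background; ``uniform`` is constant.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {_PATTERNS}")
    h, w = shape
    if pattern == "custom":
        if eta_map is None:
            raise ValueError("custom pattern requires eta_map")
        return Phantom(np.asarray(eta_map, float), pixel_size, pattern)
    if pattern == "uniform":
        val = eta_background if eta is None else eta
        return Phantom(np.full(shape, float(val)), pixel_size, pattern)
    grid = np.full(shape, float(eta_background))
    if pattern == "squares":
        s = square_size or max(2, min(h, w) // 4)
        step = 2 * s
        for r0 in range(s // 2, h - s + 1, step):
            for c0 in range(s // 2, w - s + 1, step):
                grid[r0 : r0 + s, c0 : c0 + s] = eta_foreground
    else:  # scratch: diagonal groove of reduced yield
        rr, cc = np.mgrid[0:h, 0:w]
        groove = np.abs((rr - h / 2) - 0.3 * (cc - w / 2)) < max(1, h // 16)
        grid[groove] = 0.6 * eta_background
    return Phantom(grid, pixel_size, pattern)


def simulate_image(
    phantom: Phantom,
    params: ModelParams,
    rng: np.random.Generator,
    emit: str = "tuples",
    config: WaveformConfig | None = None,
) -> dict | Waveform:
    """Pixelwise simulation over a phantom, raster order (row-major).

    ``emit='tuples'`` returns the dict from :func:`simulate_pixels` with
    arrays reshaped to the phantom grid (plus flat pulse lists);
    ``emit='waveform'`` renders the detected pulses into a sampled trace
    (requires ``params.dwell_time``).
    """
    shape = phantom.eta_map.shape
    n = phantom.eta_map.size
    res = simulate_pixels(
        params, n, rng, eta=phantom.eta_map.ravel(), return_pulses=True
    )
    if emit == "tuples":
        out = {k: res[k].reshape(shape) for k in ("m", "y", "m_tilde", "v")}
        out["pulse_heights"] = res["pulse_heights"]
        out["pulse_pixel"] = res["pulse_pixel"]
        return out
    if emit != "waveform":
        raise ValueError("emit must be 'tuples' or 'waveform'")
    if params.dwell_time is None:
        raise ValueError("waveform emission requires params.dwell_time")
    config = config or WaveformConfig()
    per_pixel = np.split(
        res["pulse_heights"], np.cumsum(np.bincount(res["pulse_pixel"], minlength=n))[:-1]
    )
    return simulate_waveform(per_pixel, config, params.dwell_time, rng)


# ---------------------------------------------------------------------------
# I/O

def write_waveform_h5(path: str | Path, wf: Waveform, params: dict | None = None) -> None:
    """Write a waveform to HDF5 (datasets: samples, sample_interval,
    pixel_boundaries) with a JSON parameter sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=wf.samples)
        f.create_dataset("sample_interval", data=wf.sample_interval)
        f.create_dataset("pixel_boundaries", data=wf.pixel_boundaries)
    if params is not None:
        path.with_suffix(".json").write_text(json.dumps(params, indent=2))


def read_waveform_h5(path: str | Path) -> Waveform:
    import h5py

    with h5py.File(path, "r") as f:
        return Waveform(
            samples=f["samples"][()],
            sample_interval=float(f["sample_interval"][()]),
            pixel_boundaries=f["pixel_boundaries"][()],
        )


def write_phantom(path: str | Path, phantom: Phantom) -> None:
    """Write a phantom eta map as 32-bit float TIFF plus a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, phantom.eta_map.astype(np.float32))
    sidecar = {
        "pattern": phantom.pattern,
        "pixel_size_m": phantom.pixel_size,
        "shape": list(phantom.eta_map.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
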