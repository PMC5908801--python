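"""Electron optics: wavelength, CTF, phase flipping, Thon-ring defocus fitting.

Sign conventions (shared by the simulator and the reconstruction):

* defocus is underfocus-positive, in Å;
* ``CTF(s) = -sqrt(1 - A^2) sin(chi) - A cos(chi)`` with
  ``chi(s) = pi lambda df s^2 - (pi/2) Cs lambda^3 s^4 + phase_shift``,
  so ``CTF(0) = -A`` and the low-frequency lobe of an underfocused CTF is
  negative (protein appears dark on a bright background);
* no astigmatism anywhere — the scalar-defocus model is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticsModel",
    "CTFParams",
    "DefocusFitError",
    "electron_wavelength",
    "ctf_2d",
    "ctf_1d",
    "phase_flip",
    "radial_power_spectrum",
    "fit_defocus",
]


class DefocusFitError(RuntimeError):
    """Raised when no Thon-ring signal can be fitted (flat correlation)."""


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV.

    lambda = 12.2639 / sqrt(V + 0.97845e-6 V^2), V in volts.
    """
    if voltage_kv <= 0:
        raise ValueError(f"acceleration voltage must be positive, got {voltage_kv}")
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)


@dataclass(frozen=True)
class OpticsModel:
    """Microscope parameters; ``wavelength`` is derived from the voltage
    unless given explicitly (an explicit value supports scaled regimes where
    the wavelength is treated as a free parameter)."""

    voltage: float = 300.0        # kV
    cs: float = 2.7               # spherical aberration, mm
    amplitude_contrast: float = 0.07
    pixel_size: float = 1.0       # Å/px
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength is None:
            object.__setattr__(self, "wavelength", electron_wavelength(self.voltage))
        if not 0.0 <= self.amplitude_contrast < 1.0:
            raise ValueError("amplitude contrast must lie in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    def with_pixel_size(self, pixel_size: float) -> "OpticsModel":
        return OpticsModel(self.voltage, self.cs, self.amplitude_contrast,
                           pixel_size, self.wavelength)


@dataclass(frozen=True)
class CTFParams:
    defocus: float                # Å, underfocus positive
    phase_shift: float = 0.0     # radians


def _chi(optics: OpticsModel, params: CTFParams, s2: np.ndarray) -> np.ndarray:
    lam = optics.wavelength
    cs_angstrom = optics.cs * 1e7
    return (np.pi * lam * params.defocus * s2
            - 0.5 * np.pi * cs_angstrom * lam ** 3 * s2 * s2
            + params.phase_shift)


def ctf_2d(optics: OpticsModel, params: CTFParams, shape: tuple[int, int]) -> np.ndarray:
    """CTF evaluated on the (unshifted) FFT frequency grid of ``shape``."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=optics.pixel_size)[:, None]
    fx = np.fft.fftfreq(nx, d=optics.pixel_size)[None, :]
    s2 = fx * fx + fy * fy
    return _ctf_from_s2(optics, params, s2)


def ctf_1d(optics: OpticsModel, params: CTFParams, s: np.ndarray) -> np.ndarray:
    """CTF on an explicit 1-D spatial-frequency axis (Å^-1)."""
    return _ctf_from_s2(optics, params, np.asarray(s, float) ** 2)


def _ctf_from_s2(optics, params, s2):
    a = optics.amplitude_contrast
    chi = _chi(optics, params, s2)
    return -math.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)


def phase_flip(image_ft: np.ndarray, ctf: np.ndarray) -> np.ndarray:
    """Multiply Fourier components by sign(CTF); amplitudes are untouched.

    Zero-CTF pixels map to zero sign; applying the same flip twice restores
    the original everywhere the CTF is non-zero.
    """
    return image_ft * np.sign(ctf)


def radial_power_spectrum(image: np.ndarray) -> np.ndarray:
    """Rotationally averaged |FT|^2 over integer-radius frequency shells.

    Returns a 1-D array of length ``n // 2 + 1``; entry ``k`` is the mean
    power of pixels whose FFT-grid radius rounds to ``k``.
    """
    image = np.asarray(image, float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2-D image")
    n = image.shape[0]
    power = np.abs(np.fft.fft2(image)) ** 2
    k = np.fft.fftfreq(n) * n
    r = np.rint(np.hypot(k[:, None], k[None, :])).astype(int)
    nshell = n // 2 + 1
    mask = (r < nshell).ravel()
    sums = np.bincount(r.ravel()[mask], weights=power.ravel()[mask], minlength=nshell)
    counts = np.bincount(r.ravel()[mask], minlength=nshell)
    return sums / np.maximum(counts, 1)


def _subtract_baseline(profile: np.ndarray, window: int) -> np.ndarray:
    """Moving-minimum envelope followed by box smoothing, then subtracted."""
    n = len(profile)
    pad = window // 2
    padded = np.pad(profile, pad, mode="edge")
    env = np.array([padded[i:i + window].min() for i in range(n)])
    kernel = np.ones(window) / window
    env = np.convolve(np.pad(env, pad, mode="edge"), kernel, mode="same")[pad:pad + n]
    return profile - env


def _model_ctf2_profile(optics: OpticsModel, defocus: float, n: int,
                        shells: np.ndarray) -> np.ndarray:
    """Radially averaged model CTF^2 on the same shells as the data profile.

    Averaging CTF^2 within each shell (rather than evaluating at the shell
    centre) keeps the model faithful where rings oscillate faster than the
    shell width.
    """
    s = np.arange(n // 2 + 1) / (n * optics.pixel_size)
    # oversample each shell 8x in radius for the in-shell average
    fine = np.linspace(-0.5, 0.5, 8, endpoint=False) + 0.5 / 8
    sample = s[shells][:, None] + fine[None, :] / (n * optics.pixel_size)
    sample = np.clip(sample, 0, None)
    ctf = ctf_1d(optics, CTFParams(defocus), sample)
    return (ctf ** 2).mean(axis=1)


def fit_defocus(image: np.ndarray, optics: OpticsModel,
                search_min: float = 8000.0, search_max: float = 35000.0,
                step: float = 50.0,
                band: tuple[float, float] = (1 / 30.0, 1 / 5.0),
                min_correlation: float = 0.3,
                min_zscore: float = 3.3) -> float:
    """Measure defocus (Å) by fitting Thon rings with model CTF^2.

    The rotationally averaged power spectrum is background-subtracted
    (moving-minimum envelope plus smoothing) and correlated, over the
    frequency ``band`` in Å^-1, against the shell-averaged model CTF^2 on a
    defocus grid from ``search_min`` to ``search_max`` (Å, ``step`` spacing);
    the grid optimum is refined by parabolic interpolation.

    Raises :class:`DefocusFitError` when the correlation peak is weak in
    absolute terms (below ``min_correlation``) or does not stand out from
    the score distribution over the defocus grid (peak z-score below
    ``min_zscore``): white noise can reach sizeable correlations against
    *some* candidate of a large oscillatory model family, but its best score
    is not an outlier of that family.
    """
    n = image.shape[0]
    profile = radial_power_spectrum(image)
    s = np.arange(len(profile)) / (n * optics.pixel_size)
    lo, hi = band
    hi = min(hi, 0.5 / optics.pixel_size)
    sel = np.nonzero((s >= lo) & (s <= hi))[0]
    if len(sel) < 8:
        raise DefocusFitError("frequency band too narrow for this box size")
    window = max(5, len(sel) // 8) | 1
    data = _subtract_baseline(np.log1p(profile[sel] / profile[sel].mean()), window)
    data = data - data.mean()
    dnorm = np.linalg.norm(data)
    if dnorm == 0:
        raise DefocusFitError("power spectrum is flat in the fitted band")
    data = data / dnorm

    def _scores(grid):
        out = np.empty(len(grid))
        for i, df in enumerate(grid):
            model = _model_ctf2_profile(optics, df, n, sel)
            model = model - model.mean()
            mnorm = np.linalg.norm(model)
            out[i] = float(data @ model) / mnorm if mnorm > 0 else 0.0
        return out

    grid = np.arange(search_min, search_max + 0.5 * step, step)
    scores = _scores(grid)
    best = int(np.argmax(scores))
    # ring-evidence gate on a fixed broad grid, independent of the search
    # range: a genuine peak is an outlier of the whole model family, while
    # noise correlates comparably with many candidates
    null = _scores(np.arange(2000.0, 50001.0, 200.0))
    spread = null.std()
    zscore = (null.max() - null.mean()) / spread if spread > 0 else 0.0
    if scores[best] < min_correlation or zscore < min_zscore:
        raise DefocusFitError(
            f"no Thon-ring signal: peak correlation {scores[best]:.3f} "
            f"(family z = {zscore:.2f}) below acceptance gate")
    # parabolic refinement around the grid optimum
    if 0 < best < len(grid) - 1:
        y0, y1, y2 = scores[best - 1], scores[best], scores[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            best_df = grid[best] + 0.5 * step * (y0 - y2) / denom
            return float(best_df)
    return float(grid[best])
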