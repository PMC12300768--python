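"""Absorption coefficient alpha(omega)*n'(omega) and complex permittivity.

Two equivalent routes produce the absorption coefficient from collective
dipole dynamics (one-sided Laplace convention throughout; a Fourier-route
implementation would differ by a factor of two because the autocorrelation
is even):

* the *current route* transforms the rotational-current autocorrelation
  ``C_JJ(t) = <J_D(0).J_D(t)>``:

      alpha*n'(omega) = 1/(3 V k_B T c eps0) * Int_0^inf C_JJ(t) cos(wt) dt

  It needs no baseline correction and is the preferred route.

* the *moment route* transforms the moment autocorrelation ``Phi_D(t)``
  with an additional ``omega^2`` prefactor, which acts as a parabolic noise
  amplifier at high frequency.

The discrete transform is a direct cosine quadrature (trapezoidal rule)
over the retained lag window, with no zero padding of the correlation tail.
When the correlation metadata records that the current came from central
differences at spacing dt, the transform divides out the filter's
``sinc^2(omega dt)`` transfer function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import argrelextrema, savgol_filter

from .collective import CorrelationFunction
from .constants import C_CM_PER_PS, EPS_PREFACTOR, omega_from_wavenumber

__all__ = [
    "Spectrum",
    "Permittivity",
    "spectrum_from_current",
    "spectrum_from_moment",
    "permittivity",
    "smooth_and_scale",
    "classify_200cm_peak",
]


@dataclass
class Spectrum:
    """alpha*n' on a wavenumber grid (both cm^-1)."""

    wavenumbers: np.ndarray
    values: np.ndarray
    channel: str = "total"
    volume: float | None = None       # A^3
    temperature: float | None = None  # K
    n_molecules: int | None = None
    smoothing: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    @property
    def grid_step(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])


@dataclass
class Permittivity:
    """Complex eps(omega) - eps_inf and the static limit."""

    wavenumbers: np.ndarray
    values: np.ndarray               # complex, eps(omega) - eps_inf
    static: float                    # eps(0) - eps_inf, from <M_D^2>
    eps_inf: float = 1.0
    tail_decayed: bool = True


def _default_grid(corr: CorrelationFunction, wavenumbers) -> np.ndarray:
    if wavenumbers is not None:
        return np.asarray(wavenumbers, float)
    dt = corr.dt
    t_max = corr.lags[-1]
    nyquist = 1.0 / (2.0 * C_CM_PER_PS * dt)
    step = 1.0 / (2.0 * C_CM_PER_PS * t_max)
    return np.arange(0.0, nyquist + 0.5 * step, step)


def _cos_quadrature(corr: CorrelationFunction, nu: np.ndarray) -> np.ndarray:
    """Trapezoidal Int C(t) cos(w t) dt over the lag window, per wavenumber."""
    t = corr.lags
    omega = omega_from_wavenumber(nu)
    weights = np.full_like(t, corr.dt)
    weights[0] = weights[-1] = 0.5 * corr.dt
    return np.cos(np.outer(omega, t)) @ (weights * corr.values)


def _derivative_correction(corr: CorrelationFunction, nu: np.ndarray) -> np.ndarray:
    """Undo the central-difference transfer function sinc^2(omega dt)."""
    if corr.derivative_scheme != "central_difference":
        return np.ones_like(nu)
    x = omega_from_wavenumber(nu) * corr.dt
    sinc = np.where(x == 0, 1.0, np.sin(np.where(x == 0, 1.0, x)) / np.where(x == 0, 1.0, x))
    return 1.0 / sinc**2


def _check_uniform(corr: CorrelationFunction) -> None:
    if len(corr.lags) > 2 and not np.allclose(
        np.diff(corr.lags), corr.dt, rtol=0, atol=1e-9
    ):
        raise ValueError("non-uniform lag spacing")


def spectrum_from_current(
    corr: CorrelationFunction,
    volume: float,
    temperature: float,
    wavenumbers: np.ndarray | None = None,
    n_molecules: int | None = None,
) -> Spectrum:
    """alpha*n' from the rotational-current autocorrelation (D^2/ps^2).

    ``volume`` in A^3, ``temperature`` in K.  The default grid runs from 0
    to the Nyquist limit in steps of the natural resolution
    ``1/(2 c t_max)``.  The value at zero wavenumber is exactly zero: the
    rotational current carries no d.c. conductivity.
    """
    _check_uniform(corr)
    nu = _default_grid(corr, wavenumbers)
    integral = _cos_quadrature(corr, nu) * _derivative_correction(corr, nu)
    values = EPS_PREFACTOR / (volume * temperature * C_CM_PER_PS) * integral
    values[nu == 0.0] = 0.0
    return Spectrum(nu, values, volume=volume, temperature=temperature,
                    n_molecules=n_molecules, meta={"route": "current"})


def spectrum_from_moment(
    corr: CorrelationFunction,
    volume: float,
    temperature: float,
    wavenumbers: np.ndarray | None = None,
    n_molecules: int | None = None,
) -> Spectrum:
    """alpha*n' from the collective-moment autocorrelation Phi_D (D^2).

    Carries the omega^2 parabolic amplifier; agrees with the current route
    on smooth, fully decayed correlation functions (integration by parts)
    but requires baseline care on noisy input.
    """
    _check_uniform(corr)
    nu = _default_grid(corr, wavenumbers)
    omega = omega_from_wavenumber(nu)
    integral = _cos_quadrature(corr, nu)
    values = EPS_PREFACTOR / (volume * temperature * C_CM_PER_PS) * omega**2 * integral
    return Spectrum(nu, values, volume=volume, temperature=temperature,
                    n_molecules=n_molecules, meta={"route": "moment"})


def permittivity(
    corr: CorrelationFunction,
    volume: float,
    temperature: float,
    wavenumbers: np.ndarray | None = None,
    eps_inf: float = 1.0,
    tail_tolerance: float = 0.01,
) -> Permittivity:
    """Complex permittivity from the moment autocorrelation Phi_D (D^2).

        eps(w) - eps_inf = [<M_D^2> + i w Int Phi_D(t) e^{-iwt} dt]
                           / (3 V k_B T eps0)

    The static value comes from the <M_D^2> = Phi_D(0) term alone.  A
    correlation tail above ``tail_tolerance * Phi(0)`` flags the estimate
    (non-decayed within the lag window) with a warning.
    """
    _check_uniform(corr)
    nu = _default_grid(corr, wavenumbers)
    omega = omega_from_wavenumber(nu)
    pref = EPS_PREFACTOR / (volume * temperature)
    m2 = corr.values[0]
    cos_part = _cos_quadrature(corr, nu)
    t = corr.lags
    weights = np.full_like(t, corr.dt)
    weights[0] = weights[-1] = 0.5 * corr.dt
    sin_part = np.sin(np.outer(omega, t)) @ (weights * corr.values)
    # Laplace transform of -dPhi/dt by parts: Phi(0) - i w Int Phi e^{-iwt};
    # reported as eps' + i eps'' with the loss part positive, so
    # eps' = pref (m2 - w Int Phi sin), eps'' = pref w Int Phi cos
    # (this is the unique sign choice that reduces to the Debye form).
    values = pref * (m2 - omega * sin_part + 1j * omega * cos_part)
    decayed = abs(corr.values[-1]) < tail_tolerance * abs(m2)
    if not decayed:
        warnings.warn(
            "correlation tail has not decayed within the lag window; "
            "permittivity estimate flagged",
            stacklevel=2,
        )
    return Permittivity(nu, values, static=float(pref * m2), eps_inf=eps_inf,
                        tail_decayed=bool(decayed))


def smooth_and_scale(
    spec: Spectrum,
    window_pts: int = 21,
    poly_order: int = 3,
    scale: str = "none",
) -> Spectrum:
    """Savitzky-Golay smoothing, then optional scaling by the maximum."""
    if window_pts % 2 == 0 or window_pts <= poly_order:
        raise ValueError("window_pts must be odd and exceed poly_order")
    if window_pts > len(spec.values):
        raise ValueError("smoothing window larger than the spectral grid")
    values = savgol_filter(spec.values, window_pts, poly_order)
    record = dict(spec.smoothing)
    record.update(window_pts=window_pts, poly_order=poly_order, scale=scale)
    if scale == "max":
        peak = values.max()
        if peak <= 0:
            raise ValueError("cannot scale: non-positive maximum")
        values = values / peak
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    return replace(spec, values=values, smoothing=record)


def classify_200cm_peak(
    spec: Spectrum,
    window: tuple[float, float] = (150.0, 300.0),
    required_coverage: tuple[float, float] = (100.0, 400.0),
    smooth_window: int | None = None,
) -> str:
    """Classify the low-frequency feature as "yes", "shoulder" or "no".

    "yes": a strict local maximum of the (optionally smoothed) spectrum
    lies inside ``window``; "shoulder": no local maximum, but the first
    derivative has a local minimum there (inflection plateau); otherwise
    "no".  The grid must cover ``required_coverage``.
    """
    nu, vals = spec.wavenumbers, spec.values
    if nu[0] > required_coverage[0] or nu[-1] < required_coverage[1]:
        raise ValueError(
            f"insufficient spectral coverage: need {required_coverage}, "
            f"have ({nu[0]:.0f}, {nu[-1]:.0f}) cm^-1"
        )
    if smooth_window is not None:
        vals = savgol_filter(vals, smooth_window, 3)
    lo, hi = window
    in_window = (nu >= lo) & (nu <= hi)
    maxima = argrelextrema(vals, np.greater)[0]
    if any(in_window[i] for i in maxima):
        return "yes"
    deriv = np.gradient(vals, nu)
    dmin = argrelextrema(deriv, np.less)[0]
    if any(in_window[i] for i in dmin):
        return "shoulder"
    return "no"
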