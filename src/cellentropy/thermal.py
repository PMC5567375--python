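"""Intracellular Fourier temperature field and intercellular heat kernel.

The cell interior obeys the 1D heat equation with the cytoplasm initially at
the reference temperature ``T0`` and both walls clamped at the intercellular
baseline (taken as the zero of the temperature scale).  The solution is the
odd square-wave Fourier sine series

    T(x,t) = (4 T0 / pi) * sum_n sin[(2n-1) pi x / L] / (2n-1)
             * exp[-kappa (2n-1)^2 pi^2 t / L^2]

whose term-wise spatial derivative, the damped cosine series

    C(x,t) = sum_n cos[(2n-1) pi x / L] * exp[-kappa (2n-1)^2 pi^2 t / L^2],

drives the conductive heat flux (dT/dx = 4 T0 C / L).  Outside the cell the
free-space heat kernel centred on the wall describes the released heat.

Numerical evaluation
--------------------
Both series are theta functions of the dimensionless time a = kappa pi^2 t /
L^2 and the centre displacement d = x - L/2.  For a >= 1/2 the spectral sums
converge in a handful of terms; for a < 1/2 they suffer catastrophic
cancellation (the true values can be ~e^{-1/a} while individual terms are
O(1)), so the equivalent Poisson-resummed image form is used instead:

    C(x,t) = (L/2) (4 pi kappa t)^{-1/2} sum_j (-1)^j e^{-(x - j L)^2/(4 kappa t)}

(the method-of-images derivative of the square-wave heat solution).  Both
forms are written in terms of d so that, in floating point, T is exactly
even and C exactly odd about the cell centre.

Series truncation: the spectral tail is bounded by ``exp(-a (2n+1)^2)``; for
t >= 1 us and the built-in cell sizes, 200 terms put the truncation error
far below double precision.  Formal time-reversal probing (t < 0 behind the
``formal_time`` flag) always evaluates the spectral form verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CellGeometry, ThermalEnv

#: dimensionless-time crossover between the spectral and image forms
_A_SWITCH = 0.5


class DomainError(ValueError):
    """Evaluation requested outside the domain of validity of a field."""


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the Fourier series.

    ``n_terms`` caps the number of odd harmonics; ``tail_tol`` is the
    relative tail bound below which further terms are dropped.
    """

    n_terms: int = 200
    tail_tol: float = 1e-16

    def __post_init__(self):
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if not (self.tail_tol > 0):
            raise ValueError("tail_tol must be > 0")


DEFAULT_CONTROL = SeriesControl()


def _odd_harmonics(ctrl: SeriesControl, geom: CellGeometry, env: ThermalEnv,
                   t_min: float) -> np.ndarray:
    """Odd integers m = 2n-1 to keep, adaptively truncated by the tail bound."""
    m = np.arange(1, 2 * ctrl.n_terms, 2, dtype=float)
    if t_min > 0:
        decay = np.exp(-env.kappa * m**2 * np.pi**2 * t_min / geom.L**2)
        keep = decay >= ctrl.tail_tol * max(decay[0], np.finfo(float).tiny)
        m = m[: max(1, int(np.sum(keep)))]
    return m


def _check_domain(x, t, geom, *, formal_time: bool, allow_t0: bool):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0) or np.any(x > geom.L):
        raise DomainError("x must lie in [0, L]")
    if not formal_time:
        if allow_t0:
            if np.any(t < 0):
                raise DomainError("t must be >= 0 (pass formal_time=True to probe -t)")
        else:
            if np.any(t <= 0):
                raise DomainError("t must be > 0 (pass formal_time=True to probe -t)")
    return x, t


def _signed_harmonic_signs(m: np.ndarray) -> np.ndarray:
    # sin(m pi / 2) for odd m: +1, -1, +1, ... for m = 1, 3, 5, ...
    return np.where((m % 4) == 1, 1.0, -1.0)


def _sine_sum_spectral(d, t, geom, env, m):
    """T-series sum in displacement form: sum_m sin(m pi x/L)/m e^{-a m^2}
    = sum_m sin(m pi/2) cos(m pi d/L)/m e^{-a m^2}; exactly even in d."""
    sgn = _signed_harmonic_signs(m)
    phase = np.multiply.outer(d, m) * (np.pi / geom.L)
    damp = np.exp(np.multiply.outer(t, m**2) * (-env.kappa * np.pi**2 / geom.L**2))
    return np.sum(sgn / m * np.cos(phase) * damp, axis=-1)


def _cosine_sum_spectral(d, t, geom, env, m):
    """C-series in displacement form: sum_m cos(m pi x/L) e^{-a m^2}
    = -sum_m sin(m pi/2) sin(m pi d/L) e^{-a m^2}; exactly odd in d."""
    sgn = _signed_harmonic_signs(m)
    phase = np.multiply.outer(d, m) * (np.pi / geom.L)
    damp = np.exp(np.multiply.outer(t, m**2) * (-env.kappa * np.pi**2 / geom.L**2))
    return -np.sum(sgn * np.sin(phase) * damp, axis=-1)


def _image_range(s_over_L: float) -> np.ndarray:
    """Image indices j, symmetric under j -> 1-j, wide enough for the kernel tail.

    Mirror partners (j, 1-j) are kept adjacent so that at the cell centre,
    where their Gaussians coincide with opposite signs, the sum cancels
    exactly in floating point.
    """
    J = int(np.ceil(6.0 * s_over_L)) + 2
    pairs = [(k, 1 - k) for k in range(0, -J, -1)]
    return np.array([j for p in pairs for j in p], dtype=float)


def _cosine_sum_image(d, t, geom, env):
    """Image form of the C-series: (L/2)(4 pi kappa t)^{-1/2}
    sum_j (-1)^j e^{-(d + (1/2 - j) L)^2 / (4 kappa t)}; exactly odd in d."""
    s2 = 4.0 * env.kappa * t          # squared kernel width
    smax = float(np.sqrt(np.max(s2))) if np.ndim(s2) else float(np.sqrt(s2))
    j = _image_range(smax / geom.L)
    offs = (0.5 - j) * geom.L         # exact negation pairs under j -> 1-j
    sign = np.where(np.abs(j % 2.0) < 0.5, 1.0, -1.0)
    disp = d[..., None] + offs
    gauss = np.exp(-(disp**2) / s2[..., None])
    return geom.L / 2.0 / np.sqrt(4.0 * np.pi * env.kappa * t) * np.sum(sign * gauss, axis=-1)


def temperature(x, t, geom: CellGeometry, env: ThermalEnv,
                ctrl: SeriesControl = DEFAULT_CONTROL, *,
                formal_time: bool = False) -> np.ndarray:
    """Temperature T(x, t) in K; broadcasts over ``x`` and ``t``.

    At ``t = 0`` the Fourier limit of the square initial profile is returned:
    ``T0`` strictly inside the cell, 0 on the walls (where every sine term
    vanishes at all times).  Negative ``t`` is a domain error unless
    ``formal_time=True`` (time-reversal probing).
    """
    x, t = _check_domain(x, t, geom, formal_time=formal_time, allow_t0=True)
    x, t = np.broadcast_arrays(x, t)
    out = np.empty(x.shape, dtype=float)
    flat_x, flat_t, flat_o = x.ravel(), t.ravel(), out.ravel()

    boundary = (flat_x == 0.0) | (flat_x == geom.L)
    zero_t = flat_t == 0.0
    flat_o[boundary] = 0.0
    init = zero_t & ~boundary
    flat_o[init] = env.T0
    rest = ~(boundary | init)
    if np.any(rest):
        d = flat_x[rest] - geom.L / 2.0
        tt = flat_t[rest]
        tmin = np.min(np.abs(tt)) if formal_time else np.min(tt)
        m = _odd_harmonics(ctrl, geom, env, tmin)
        flat_o[rest] = (4.0 * env.T0 / np.pi) * _sine_sum_spectral(d, tt, geom, env, m)
    return out if out.shape else float(out)


def cosine_series(x, t, geom: CellGeometry, env: ThermalEnv,
                  ctrl: SeriesControl = DEFAULT_CONTROL, *,
                  formal_time: bool = False, _checked: bool = False) -> np.ndarray:
    """The damped cosine series (see module docstring); equals L dT/dx / (4 T0).

    Refused at ``t = 0``, where it diverges (delta-function limit).
    """
    if not _checked:
        x, t = _check_domain(x, t, geom, formal_time=formal_time, allow_t0=False)
    x, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(t, float))
    flat_x, flat_t = x.ravel(), t.ravel()
    d = flat_x - geom.L / 2.0
    out = np.empty(flat_x.shape, dtype=float)
    a = env.kappa * np.pi**2 * flat_t / geom.L**2
    spectral = (a >= _A_SWITCH) | (formal_time & (flat_t < 0))
    if np.any(spectral):
        tmin = np.min(np.abs(flat_t[spectral])) if formal_time else np.min(flat_t[spectral])
        m = _odd_harmonics(ctrl, geom, env, tmin)
        out[spectral] = _cosine_sum_spectral(d[spectral], flat_t[spectral], geom, env, m)
    img = ~spectral
    if np.any(img):
        out[img] = _cosine_sum_image(d[img], flat_t[img], geom, env)
    # flush magnitudes whose square would be subnormal: such values are pure
    # summation residue (the true series there is far smaller still) and
    # squaring them in the heat term would lose the force x flow identity
    out[np.abs(out) < 1e-150] = 0.0
    out = out.reshape(x.shape)
    return out if out.shape else float(out)


def temperature_gradient(x, t, geom: CellGeometry, env: ThermalEnv,
                         ctrl: SeriesControl = DEFAULT_CONTROL, *,
                         formal_time: bool = False) -> np.ndarray:
    """Term-wise spatial derivative dT/dx in K/m (antisymmetric about L/2)."""
    x, t = _check_domain(x, t, geom, formal_time=formal_time, allow_t0=False)
    return (4.0 * env.T0 / geom.L) * cosine_series(
        x, t, geom, env, ctrl, formal_time=formal_time, _checked=True
    )


def intercellular_temperature(x, t, geom: CellGeometry, env: ThermalEnv) -> np.ndarray:
    """Free-space heat-kernel temperature in the intercellular region, K.

    ``T_ic(x,t) = T0 x0 (4 pi kappa t)^{-1/2} exp[-(x-L)^2 / (4 kappa t)]``
    for ``x >= L``: the heat released at the wall spreads with no boundary
    conditions; ``x0`` normalizes the kernel to temperature units.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < geom.L):
        raise DomainError("intercellular temperature requires x >= L")
    if np.any(t <= 0):
        raise DomainError("t must be > 0")
    pref = env.T0 * geom.x0 / np.sqrt(4.0 * np.pi * env.kappa * t)
    out = pref * np.exp(-((x - geom.L) ** 2) / (4.0 * env.kappa * t))
    return out if np.ndim(out) else float(out)
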