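"""Bath correlation function G(t) for the Drude-Lorentz bath.

Two routes are provided:

* :func:`correlation_expansion` — the finite sum of complex exponentials
  (Drude pole + Matsubara terms) that every solver in the package shares,
  with an optional white-noise terminator for the truncated Matsubara
  tail;
* :func:`correlation_quadrature` — the direct frequency integral
  G(t) = ∫₀^∞ dω J(ω)[coth(βħω/2)·cos ωt − i·sin ωt], evaluated by
  adaptive quadrature.  This is deliberately kept free of the expansion
  machinery so it can act as an independent oracle.

All amplitudes are in (rad/fs)² and decay rates in fs⁻¹ (ħ = 1).
The imaginary part is exactly −λγ·e^{−γt} at any temperature: the
response function of the bath is temperature independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import sici

from .model import DimerModel
from .units import inverse_temperature_fs

__all__ = ["CorrelationExpansion", "correlation_expansion", "correlation_quadrature"]


@dataclass(frozen=True)
class CorrelationExpansion:
    """G(t) ≈ Σ_k c_k·e^{−ν_k t} (+ terminator_amplitude·δ(t)).

    ``c[0]``/``nu[0]`` is the Drude pole (ν₀ = γ in rad/fs ≡ fs⁻¹); the
    remaining K terms are Matsubara contributions with real amplitudes
    and ν_k = 2πk·k_BT/ħ.  ``terminator_amplitude`` is the Markovian
    weight Σ_{k>K} c_k/ν_k of the dropped tail (0 when disabled).
    """

    c: np.ndarray = field(repr=False)  # complex amplitudes, (rad/fs)²
    nu: np.ndarray = field(repr=False)  # decay rates, fs⁻¹
    K: int = 0
    terminator_amplitude: float = 0.0

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.c, dtype=complex))
        nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        if c.shape != nu.shape:
            raise ValueError("c and nu must have matching shapes")
        if np.any(nu <= 0):
            raise ValueError("all decay rates must be positive")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "nu", nu)

    @property
    def n_terms(self) -> int:
        return len(self.c)

    def evaluate(self, t):
        """G(t) from the exponential terms (terminator excluded)."""
        t = np.asarray(t, dtype=float)
        out = np.einsum("k,...k->...", self.c, np.exp(-np.multiply.outer(t, self.nu)))
        return out if out.ndim else complex(out)

    def __call__(self, t):
        return self.evaluate(t)


def _matsubara_tail_sum(beta: float, gamma: float, K: int) -> float:
    """Σ_{k>K} 1/(ν_k² − γ²) with ν_k = 2πk/β, via the analytic full sum."""
    a = beta * gamma / (2.0 * np.pi)
    if abs(a - round(a)) < 1e-9 and round(a) >= 1:
        raise ValueError(
            "γ coincides with a Matsubara frequency; terminator weight undefined"
        )
    # Σ_{k≥1} 1/(k²−a²) = (1 − πa·cot(πa))/(2a²), continued to a→0 as π²/6
    if abs(a) < 1e-8:
        full = np.pi**2 / 6.0 - np.pi**4 * a**2 / 15.0
    else:
        full = (1.0 - np.pi * a / np.tan(np.pi * a)) / (2.0 * a**2)
    scale = (beta / (2.0 * np.pi)) ** 2
    k = np.arange(1, K + 1)
    partial = np.sum(1.0 / ((2.0 * np.pi * k / beta) ** 2 - gamma**2)) if K else 0.0
    return scale * full - partial


def correlation_expansion(
    model: DimerModel, K: int = 10, *, terminator: bool = True
) -> CorrelationExpansion:
    """Drude + K-term Matsubara expansion of G(t).

    c₀ = λγ·(cot(βγ/2) − i), ν₀ = γ;
    c_k = (4λγ/β)·ν_k/(ν_k² − γ²), ν_k = 2πk/β  (k = 1…K),
    all in internal angular units.  With ``terminator=True`` the dropped
    tail Σ_{k>K} c_k·e^{−ν_k t} is summarized by its Markovian weight
    Σ_{k>K} c_k/ν_k (an Ishizaki-Tanimura-style white-noise closure).
    """
    if not isinstance(K, (int, np.integer)) or K < 0:
        raise ValueError(f"K must be a nonnegative integer, got {K}")
    lam, gamma = model.lam_ang, model.gamma_ang
    beta = inverse_temperature_fs(model.T)

    c = np.empty(K + 1, dtype=complex)
    nu = np.empty(K + 1, dtype=float)
    nu[0] = gamma
    c[0] = lam * gamma * (1.0 / np.tan(0.5 * beta * gamma) - 1j)
    k = np.arange(1, K + 1)
    nu[1:] = 2.0 * np.pi * k / beta
    with np.errstate(divide="raise"):
        c[1:] = (4.0 * lam * gamma / beta) * nu[1:] / (nu[1:] ** 2 - gamma**2)

    delta = 0.0
    if terminator and lam > 0:
        delta = (4.0 * lam * gamma / beta) * _matsubara_tail_sum(beta, gamma, K)
    return CorrelationExpansion(c=c, nu=nu, K=int(K), terminator_amplitude=float(delta))


def _drude_tail(x: float, t: float, pref: float, gamma: float):
    """Analytic ω > ω_max remainder of the G(t) integrals for t > 0.

    Beyond the cutoff, coth(βω/2) → 1 exponentially fast and
    J(ω) = pref·(1/ω − γ²/ω³ + O(ω⁻⁵)); the remaining cosine/sine
    integrals have closed forms in Si/Ci.  Returns (re_tail, im_tail).
    """
    si, ci = sici(x * t)
    cos_w1 = -ci                                    # ∫ₓ^∞ cos(ωt)/ω dω
    sin_w1 = np.pi / 2.0 - si                       # ∫ₓ^∞ sin(ωt)/ω dω
    sin_w2 = np.sin(x * t) / x - t * ci             # ∫ₓ^∞ sin(ωt)/ω² dω
    cos_w2 = np.cos(x * t) / x - t * sin_w1         # ∫ₓ^∞ cos(ωt)/ω² dω
    cos_w3 = np.cos(x * t) / (2 * x**2) - 0.5 * t * sin_w2
    sin_w3 = np.sin(x * t) / (2 * x**2) + 0.5 * t * cos_w2
    re = pref * (cos_w1 - gamma**2 * cos_w3)
    im = pref * (sin_w1 - gamma**2 * sin_w3)
    return re, im


def correlation_quadrature(
    t, model: DimerModel, *, cutoff_factor: float = 50.0, limit: int = 400
):
    """G(t) by direct adaptive quadrature over the spectral density.

    Integrates J(ω)·coth(βω/2) against cos(ωt) and J(ω) against sin(ωt)
    up to ω_max = cutoff_factor·max(γ, k_BT/ħ), then adds the analytic
    large-ω remainder (for t > 0; at exactly t = 0 the real part is
    logarithmically cutoff-regularized, which is inherent to the Drude
    model's short-time singularity).  Raises ``RuntimeError`` with
    diagnostics if the quadrature does not converge.  Scalar or array
    ``t`` (fs, ≥ 0).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("correlation function is evaluated for t ≥ 0")
    lam, gamma = model.lam_ang, model.gamma_ang
    if lam == 0.0:
        out = np.zeros(t_arr.shape, dtype=complex)
        return out if np.ndim(t) else complex(out[0])
    beta = inverse_temperature_fs(model.T)
    omega_max = cutoff_factor * max(gamma, 1.0 / beta)
    pref = 2.0 * lam * gamma / np.pi

    def dissipation(w):
        # J(ω)·coth(βω/2); finite (2/β·pref/γ²) limit at ω→0
        w = np.asarray(w, dtype=float)
        return np.where(
            w < 1e-12,
            pref * 2.0 / (beta * gamma**2),
            pref * w / (w**2 + gamma**2) / np.tanh(0.5 * beta * np.where(w < 1e-12, 1.0, w)),
        )

    def response(w):
        return pref * w / (w**2 + gamma**2)

    out = np.empty(t_arr.shape, dtype=complex)
    with warnings.catch_warnings():
        warnings.simplefilter("error", integrate.IntegrationWarning)
        for i, ti in enumerate(t_arr.ravel()):
            try:
                if ti == 0.0:
                    re, re_err = integrate.quad(
                        dissipation, 0.0, omega_max, limit=limit,
                        points=[gamma, 1.0 / beta],
                    )
                    im, im_err = integrate.quad(
                        response, 0.0, omega_max, limit=limit,
                        points=[gamma, 1.0 / beta],
                    )
                else:
                    re, re_err = integrate.quad(
                        dissipation, 0.0, omega_max, weight="cos", wvar=ti,
                        limit=limit, epsabs=1e-13, epsrel=1e-11,
                    )
                    im, im_err = integrate.quad(
                        response, 0.0, omega_max, weight="sin", wvar=ti,
                        limit=limit, epsabs=1e-13, epsrel=1e-11,
                    )
                    tail_re, tail_im = _drude_tail(omega_max, ti, pref, gamma)
                    re += tail_re
                    im += tail_im
            except integrate.IntegrationWarning as exc:  # pragma: no cover
                raise RuntimeError(
                    f"bath-correlation quadrature failed to converge at t={ti} fs "
                    f"(ω_max={omega_max:.4g} rad/fs, limit={limit}): {exc}"
                ) from exc
            out.ravel()[i] = re - 1j * im
    return out if np.ndim(t) else complex(out[0])
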