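"""Dual-input reversible two-tissue compartment model for FDG.

The tracer exchanges between blood and a free tissue pool (rates K1,
k2), and between the free pool and a phosphorylated (metabolised) pool
(rates k3, k4).  With a dual blood input C_B the measured tissue curve
is

    C_T(t) = (1 - Vb) * (h conv C_B)(t) + Vb * C_B(t)

where the impulse response of the two-tissue system is the
bi-exponential

    h(t) = K1/(T2 - T1) * [(k3 + k4 - T1) e^(-T1 t) + (T2 - k3 - k4) e^(-T2 t)]

and T1 <= T2 are the macro rates (eigenvalues), the roots of
lambda^2 - (k2+k3+k4) lambda + k2*k4 = 0.

Rates are per-minute (K1 in mL/min/mL); the sampling grid is in
seconds and converted at this boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .tac import DomainError, TimeFunction

__all__ = [
    "KineticParams",
    "MacroRates",
    "macro_rates",
    "impulse_response",
    "tissue_curve",
]


@dataclass(frozen=True)
class KineticParams:
    """Compartment-model parameter vector [K1, k2, k3, k4, HPI, Vb].

    Units: ``k1`` in mL/min/mL; ``k2``-``k4`` in 1/min; ``hpi`` and
    ``vb`` are unitless fractions.  ``k4`` may be 0 (irreversible
    trapping limit).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    hpi: float
    vb: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        for name in ("hpi", "vb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.hpi, self.vb])

    @classmethod
    def from_array(cls, theta) -> "KineticParams":
        k1, k2, k3, k4, hpi, vb = (float(x) for x in theta)
        return cls(k1, k2, k3, k4, hpi, vb)


@dataclass(frozen=True)
class MacroRates:
    """Eigenvalue pair of the two-tissue system, 0 <= t1 <= t2 (1/min)."""

    t1: float
    t2: float


def macro_rates(k2: float, k3: float, k4: float) -> MacroRates:
    """Macro rates T1, T2 from the micro rate constants.

    T1,T2 = ((k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)) / 2.  The
    discriminant is clamped at zero if negative within roundoff
    (-1e-12 relative); k4 = 0 yields T1 = 0 exactly.
    """
    if k2 < 0 or k3 < 0 or k4 < 0:
        raise DomainError("rate constants must be non-negative")
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:
        if disc < -1e-12 * max(1.0, s * s):  # pragma: no cover - algebra keeps disc >= 0
            raise DomainError("negative discriminant beyond roundoff")
        disc = 0.0
    root = np.sqrt(disc)
    if k4 == 0.0 or k2 == 0.0:
        # exact irreversible / no-washout limit: one eigenvalue is 0
        return MacroRates(0.0, s)
    return MacroRates((s - root) / 2.0, (s + root) / 2.0)


def impulse_response(p: KineticParams, t_min: np.ndarray) -> np.ndarray:
    """Tissue impulse response h(t) at times ``t_min`` (minutes).

    Uses the bi-exponential closed form for distinct macro rates and the
    analytic repeated-root limit ``K1 e^(-T1 t) (1 + (k3+k4-T1) t)``
    when T1 == T2 (within roundoff), rather than epsilon-jitter.
    h(0) = K1 in both branches.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise DomainError("impulse response requires t >= 0")
    mr = macro_rates(p.k2, p.k3, p.k4)
    t1, t2 = mr.t1, mr.t2
    if t2 - t1 <= 1e-12 * max(t2, 1.0):
        return p.k1 * np.exp(-t1 * t) * (1.0 + (p.k3 + p.k4 - t1) * t)
    c1 = p.k1 * (p.k3 + p.k4 - t1) / (t2 - t1)
    c2 = p.k1 * (t2 - (p.k3 + p.k4)) / (t2 - t1)
    return c1 * np.exp(-t1 * t) + c2 * np.exp(-t2 * t)


def _conv_trapezoid(h: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution (h conv g) on a uniform grid, trapezoid rule."""
    n = h.size
    nfft = next_fast_len(2 * n - 1)
    full = irfft(rfft(h, nfft) * rfft(g, nfft), nfft)[:n] * dt
    # trapezoid end-point correction of the rectangle-rule FFT sum
    full -= 0.5 * dt * (h[0] * g + h * g[0])
    return full


def tissue_curve(
    p: KineticParams,
    c_b: TimeFunction,
    t_grid_s: np.ndarray,
    check_causal: bool = True,
) -> np.ndarray:
    """Forward-model tissue concentration sampled on a fine grid.

    ``C_T = (1 - vb) * (h conv C_B) + vb * C_B`` with the convolution
    evaluated by trapezoidal quadrature on the uniform grid ``t_grid_s``
    (seconds, starting at 0, step <= 1 s recommended; a coarser step
    emits a warning).  The intracellular term C_I = C_E + C_M is carried
    implicitly by the convolution.
    """
    t = np.asarray(t_grid_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise DomainError("t_grid_s must be a 1-d grid with at least 2 points")
    if abs(t[0]) > 1e-9:
        raise DomainError("t_grid_s must start at 0 for a causal convolution")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
        raise DomainError("t_grid_s must be uniform")
    if dt > 1.0 + 1e-9:
        warnings.warn(
            f"convolution grid step {dt:.3g} s exceeds 1 s; first-pass frames "
            "need sub-second resolution",
            stacklevel=2,
        )
    cb = np.asarray(c_b(t), dtype=float)
    if check_causal:
        pre = np.asarray(c_b(np.array([-10.0, -1.0, -1e-3])), dtype=float)
        scale = max(float(np.max(np.abs(cb))), 1e-300)
        if np.any(np.abs(pre) > 1e-9 * scale):
            raise DomainError("C_B must vanish for t < 0 (non-causal input)")
    h = impulse_response(p, t / 60.0)
    conv = _conv_trapezoid(h, cb, dt / 60.0)
    return (1.0 - p.vb) * conv + p.vb * cb
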