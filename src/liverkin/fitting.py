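"""Weighted nonlinear least-squares estimation of kinetic parameters.

Two estimators share one machinery:

* the full dual-input model with six free parameters
  ``theta = [K1, k2, k3, k4, HPI, Vb]``;
* the combined model, where HPI is measured beforehand by the
  maximum-slope method and held fixed, leaving five free parameters
  ``theta = [K1, k2, k3, k4, Vb]``.

The objective is the weighted residual sum of squares

    WRSS(theta) = sum_i w_i * (c_i - C_T(t_i; theta))^2

over frame-averaged model predictions.  Default weights are uniform:
with SUV-scaled TACs the measurement noise grows with the signal, so
duration weighting would concentrate the objective on the late
high-activity frames and starve the first-pass frames that identify
HPI and Vb.  A duration-weights mode is provided.  The 6-parameter
landscape is
multi-modal, so the optimiser (bounded trust-region least squares) is
restarted from a seeded low-discrepancy sequence over the bounds, with
a fixed physiological first start.

Goodness of fit is summarised by R = 1 - sqrt(sum(y - yhat)^2 / sum y^2),
which is 1 for a perfect fit and 0 for a fit no better than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.optimize import least_squares
from scipy.stats import qmc

from .compartment import KineticParams, impulse_response
from .tac import DomainError, FrameSchedule, TimeActivityCurve, TimeFunction

__all__ = [
    "FitOptions",
    "FitResult",
    "FitError",
    "wrss",
    "goodness_of_fit",
    "fit_three_compartment",
    "fit_combined",
    "PARAM_BOUNDS",
]

#: Box bounds of the fitted parameters, in reported units.
PARAM_BOUNDS = {
    "k1": (0.0, 10.0),
    "k2": (0.0, 10.0),
    "k3": (0.0, 1.0),
    "k4": (0.0, 1.0),
    "hpi": (0.0, 1.0),
    "vb": (0.0, 1.0),
}

#: Physiological first start of the multi-start search.
DEFAULT_INIT = {"k1": 1.0, "k2": 1.0, "k3": 0.01, "k4": 0.01, "hpi": 0.5, "vb": 0.05}


class FitError(RuntimeError):
    """All optimiser starts failed; carries the best iterate found."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitOptions:
    """Optimiser configuration.

    ``n_starts`` counts the fixed physiological start plus Sobol draws
    over the bounds; ``seed`` makes the draws reproducible.
    ``grid_step_s`` is the forward-model convolution step.
    """

    n_starts: int = 10
    seed: int = 0
    weights: Literal["uniform", "duration"] = "uniform"
    grid_step_s: float = 0.5
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int = 500


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with fit diagnostics."""

    params: KineticParams
    wrss: float
    r_gof: float
    n_iter: int
    converged: bool
    model_kind: Literal["three_compartment", "combined"]
    predicted: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.wrss < 0:
            raise DomainError("wrss must be non-negative")


def wrss(observed, predicted, weights) -> float:
    """Weighted residual sum of squares, sum w_i (c_i - yhat_i)^2."""
    c = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.shape != y.shape or c.shape != w.shape:
        raise DomainError("observed, predicted and weights must share a shape")
    if np.any(w < 0):
        raise DomainError("weights must be non-negative")
    r = c - y
    return float(np.sum(w * r * r))


def goodness_of_fit(y, yhat) -> float:
    """R = 1 - sqrt(sum (y - yhat)^2 / sum y^2); 1 is a perfect fit."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise DomainError("y and yhat must share a shape")
    denom = float(np.sum(y * y))
    if denom <= 0:
        raise DomainError("goodness of fit undefined for all-zero data")
    return 1.0 - float(np.sqrt(np.sum((y - yhat) ** 2) / denom))


class _FramePredictor:
    """Frame-averaged forward model on a cached fine grid.

    Pre-computes the grid, the FFT of the arterial and portal input
    samples (the dual input is linear in them, so the mixed input's FFT
    is the HPI-weighted combination) and per-frame trapezoid quadrature
    indices, leaving one FFT of the impulse response per model
    evaluation.
    """

    def __init__(
        self,
        schedule: FrameSchedule,
        A: TimeFunction,
        V: TimeFunction,
        grid_step_s: float = 1.0,
    ):
        self.schedule = schedule
        dt = float(grid_step_s)
        end = schedule.total_end_s
        n = int(round(end / dt)) + 1
        self.t_s = np.linspace(0.0, n * dt - dt, n)
        self.dt_min = dt / 60.0
        self.a = np.asarray(A(self.t_s), dtype=float)
        self.v = np.asarray(V(self.t_s), dtype=float)
        self.nfft = next_fast_len(2 * n - 1)
        self._af = rfft(self.a, self.nfft)
        self._vf = rfft(self.v, self.nfft)
        self.n = n
        # frame boundaries snapped to grid indices (protocol frames are
        # integer-second aligned; snapping is exact there)
        i0 = np.rint(schedule.start_s / dt).astype(int)
        i1 = np.rint(schedule.end_s / dt).astype(int)
        if np.any(i1 > n - 1) or np.any(i1 <= i0):
            raise DomainError("schedule frames do not align with the model grid")
        self._slices = [(int(a), int(b)) for a, b in zip(i0, i1)]

    def cb(self, hpi: float) -> np.ndarray:
        return hpi * self.a + (1.0 - hpi) * self.v

    def _frame_means(self, curve: np.ndarray) -> np.ndarray:
        out = np.empty(len(self._slices))
        for k, (a, b) in enumerate(self._slices):
            seg = curve[a : b + 1]
            out[k] = (np.sum(seg) - 0.5 * (seg[0] + seg[-1])) / (b - a)
        return out

    def predict(self, p: KineticParams) -> np.ndarray:
        """Frame-averaged C_T for the given parameters."""
        h = impulse_response(p, self.t_s / 60.0)
        cbf = p.hpi * self._af + (1.0 - p.hpi) * self._vf
        conv = irfft(rfft(h, self.nfft) * cbf, self.nfft)[: self.n] * self.dt_min
        cb = self.cb(p.hpi)
        conv -= 0.5 * self.dt_min * (h[0] * cb + h * cb[0])
        ct = (1.0 - p.vb) * conv + p.vb * cb
        return self._frame_means(ct)


def _weights(schedule: FrameSchedule, mode: str) -> np.ndarray:
    if mode == "duration":
        return schedule.duration_s.copy()
    if mode == "uniform":
        return np.ones(schedule.n_frames)
    raise DomainError(f"unknown weights mode {mode!r}")


def _starts(
    names: list[str], opts: FitOptions, fixed: dict[str, float]
) -> np.ndarray:
    """Fixed physiological start plus Sobol draws over the bounds."""
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    x0 = np.array([DEFAULT_INIT[n] for n in names])
    rows = [x0]
    if opts.n_starts > 1:
        eng = qmc.Sobol(d=len(names), scramble=True, seed=opts.seed)
        m = int(np.ceil(np.log2(opts.n_starts - 1)))
        pts = eng.random_base2(max(m, 0))[: opts.n_starts - 1]
        rows.extend(lo + pts * (hi - lo))
    return np.vstack(rows), (lo, hi)


_XSCALE = {"k1": 1.0, "k2": 1.0, "k3": 0.05, "k4": 0.05, "hpi": 0.3, "vb": 0.05}


def _run_fit(
    tac: TimeActivityCurve,
    A: TimeFunction,
    V: TimeFunction,
    free: list[str],
    fixed: dict[str, float],
    model_kind: str,
    opts: FitOptions,
) -> FitResult:
    pred = _FramePredictor(tac.schedule, A, V, opts.grid_step_s)
    obs = tac.values
    w = _weights(tac.schedule, opts.weights)
    sw = np.sqrt(w)

    def to_params(x: np.ndarray) -> KineticParams:
        d = dict(fixed)
        d.update({n: float(np.clip(v, *PARAM_BOUNDS[n])) for n, v in zip(free, x)})
        return KineticParams(**d)

    def resid(x: np.ndarray) -> np.ndarray:
        return sw * (pred.predict(to_params(x)) - obs)

    x0s, (lo, hi) = _starts(free, opts, fixed)
    xscale = np.array([_XSCALE[n] for n in free])
    best = None
    best_cost = np.inf
    n_iter = 0
    any_ok = False
    for x0 in x0s:
        try:
            res = least_squares(
                resid,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                x_scale=xscale,
                ftol=opts.ftol,
                xtol=opts.xtol,
                gtol=None,
                max_nfev=opts.max_nfev,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        n_iter += int(res.nfev)
        any_ok = any_ok or bool(res.success)
        if 2.0 * res.cost < best_cost:
            best_cost = 2.0 * res.cost
            best = res
    if best is None:
        raise FitError("all optimiser starts failed")
    params = to_params(best.x)
    if model_kind == "combined":
        # carry the supplied HPI bit-exactly
        params = replace(params, hpi=fixed["hpi"])
    yhat = pred.predict(params)
    result = FitResult(
        params=params,
        wrss=wrss(obs, yhat, w),
        r_gof=goodness_of_fit(obs, yhat),
        n_iter=n_iter,
        converged=any_ok,
        model_kind=model_kind,
        predicted=yhat,
    )
    if not any_ok:
        raise FitError("no optimiser start converged", best=result)
    return result


def fit_three_compartment(
    tac: TimeActivityCurve,
    A: TimeFunction,
    V: TimeFunction,
    opts: FitOptions | None = None,
) -> FitResult:
    """Six-parameter fit theta = [K1, k2, k3, k4, HPI, Vb].

    ``A`` and ``V`` are continuous arterial and portal-vein input
    functions (typically image-derived, via
    :func:`liverkin.tac.continuous_from_frames`) covering the TAC's
    schedule.  Prediction path: dual input -> tissue curve ->
    frame average.
    """
    opts = opts or FitOptions()
    return _run_fit(
        tac, A, V,
        free=["k1", "k2", "k3", "k4", "hpi", "vb"],
        fixed={},
        model_kind="three_compartment",
        opts=opts,
    )


def fit_combined(
    tac: TimeActivityCurve,
    A: TimeFunction,
    V: TimeFunction,
    hpi_fixed: float,
    opts: FitOptions | None = None,
) -> FitResult:
    """Five-parameter fit with HPI measured externally and held fixed.

    ``hpi_fixed`` typically comes from
    :func:`liverkin.maxslope.perfusion_params`; the dual input is formed
    with this value and only [K1, k2, k3, k4, Vb] are estimated.
    """
    if not 0.0 <= hpi_fixed <= 1.0:
        raise DomainError(f"hpi_fixed must lie in [0, 1], got {hpi_fixed}")
    opts = opts or FitOptions()
    return _run_fit(
        tac, A, V,
        free=["k1", "k2", "k3", "k4", "vb"],
        fixed={"hpi": float(hpi_fixed)},
        model_kind="combined",
        opts=opts,
    )
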