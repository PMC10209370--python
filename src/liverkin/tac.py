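"""Frame schedules, time-activity curves and the dual blood-supply input.

Dynamic PET data are reconstructed as an ordered sequence of time frames.
A time-activity curve (TAC) holds one activity value per frame and is
interpreted as the *time-average* of the underlying tracer concentration
over the frame, which matches how PET frames are reconstructed.

The liver receives blood from both the hepatic artery and the portal
vein.  The model input is the perfusion-weighted mixture

    C_B(t) = HPI * A(t) + (1 - HPI) * V(t)

where ``HPI`` (hepatic perfusion index) is the arterial fraction of the
total hepatic blood supply.

Internal time unit is the second throughout this module; kinetic rate
constants elsewhere are per-minute and are converted at the model
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "FrameSchedule",
    "TimeActivityCurve",
    "BloodInput",
    "dual_input_curve",
    "continuous_from_frames",
    "frame_average",
    "ROI_KINDS",
]

#: Recognised region-of-interest kinds.
ROI_KINDS = ("tissue", "aorta", "portal_vein", "spleen")

#: A vectorised function of time (seconds) returning activity concentration.
TimeFunction = Callable[[np.ndarray], np.ndarray]


class DomainError(ValueError):
    """An argument violates a model-domain constraint."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames.

    Parameters
    ----------
    start_s, duration_s
        Frame start times and durations in seconds.  Frames must be
        sorted, non-overlapping and strictly positive in duration; gaps
        are permitted (the short-term protocol has a 55-min gap before
        its static frame).
    label
        Protocol name, e.g. ``"short_term"``.
    """

    start_s: np.ndarray
    duration_s: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise DomainError("schedule needs matching 1-d start/duration arrays")
        if np.any(dur <= 0):
            raise DomainError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise DomainError("frames must be sorted by start time")
        if np.any(start[1:] - (start[:-1] + dur[:-1]) < -1e-9):
            raise DomainError("frames must not overlap")

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def total_end_s(self) -> float:
        return float(self.end_s[-1])

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_frames

    def subset(self, indices: Sequence[int], label: str = "") -> "FrameSchedule":
        idx = np.asarray(indices, dtype=int)
        return FrameSchedule(self.start_s[idx], self.duration_s[idx], label or self.label)

    @classmethod
    def from_groups(
        cls,
        groups: str | Iterable[tuple[int, float]],
        label: str = "",
        extra_frames: Iterable[tuple[float, float]] = (),
        t0_s: float = 0.0,
    ) -> "FrameSchedule":
        """Build a schedule from ``count x seconds`` frame groups.

        ``groups`` may be a string such as ``"12x5,4x60"`` or an iterable
        of ``(count, duration_s)`` pairs.  ``extra_frames`` appends
        explicit ``(start_s, duration_s)`` frames (e.g. a late static
        frame).
        """
        if isinstance(groups, str):
            parsed = []
            for token in groups.split(","):
                m = re.fullmatch(r"\s*(\d+)\s*x\s*([0-9.]+)\s*", token)
                if not m:
                    raise DomainError(f"cannot parse frame group {token!r}")
                parsed.append((int(m.group(1)), float(m.group(2))))
            groups = parsed
        starts, durs = [], []
        t = float(t0_s)
        for count, dur in groups:
            for _ in range(int(count)):
                starts.append(t)
                durs.append(float(dur))
                t += float(dur)
        for s, d in extra_frames:
            starts.append(float(s))
            durs.append(float(d))
        return cls(np.array(starts), np.array(durs), label)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity values on a :class:`FrameSchedule`.

    ``values[i]`` is the mean activity concentration over frame ``i``,
    in the declared ``units`` (``"SUV"`` or ``"kBq/mL"``; the kinetic fit
    is scale-equivariant so the two are interchangeable up to unit
    bookkeeping).
    """

    schedule: FrameSchedule
    values: np.ndarray
    roi_kind: str = "tissue"
    units: str = "SUV"
    allow_negative: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.schedule.n_frames,):
            raise DomainError(
                f"expected {self.schedule.n_frames} frame values, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise DomainError("TAC values must be finite")
        if not self.allow_negative and np.any(vals < 0):
            raise DomainError("negative TAC values (set allow_negative to permit)")
        if self.roi_kind not in ROI_KINDS:
            raise DomainError(f"unknown roi_kind {self.roi_kind!r}")

    def with_values(self, values: np.ndarray, **kw) -> "TimeActivityCurve":
        opts = dict(
            roi_kind=self.roi_kind, units=self.units, allow_negative=self.allow_negative
        )
        opts.update(kw)
        return TimeActivityCurve(self.schedule, values, **opts)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.schedule.n_frames


@dataclass(frozen=True)
class BloodInput:
    """Dual blood-supply input: arterial and portal curves plus HPI."""

    arterial: TimeFunction
    portal: TimeFunction
    hpi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hpi <= 1.0:
            raise DomainError(f"hpi must lie in [0, 1], got {self.hpi}")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.hpi * np.asarray(self.arterial(t)) + (1.0 - self.hpi) * np.asarray(
            self.portal(t)
        )


def dual_input_curve(A: TimeFunction, V: TimeFunction, hpi: float) -> TimeFunction:
    """Perfusion-weighted dual input ``C_B = hpi*A + (1-hpi)*V``.

    ``hpi`` outside [0, 1] raises :class:`DomainError`.
    """
    return BloodInput(A, V, float(hpi))


def continuous_from_frames(
    tac: TimeActivityCurve, method: str = "midpoint-linear"
) -> TimeFunction:
    """Continuous-time reconstruction of a frame-sampled TAC.

    Default mode anchors each frame value at the frame midpoint,
    interpolates linearly between midpoints and extrapolates as a
    constant at the edges; the returned function reproduces the frame
    value exactly at each midpoint.
    """
    if method != "midpoint-linear":
        raise DomainError(f"unknown interpolation mode {method!r}")
    if tac.schedule.n_frames == 0:  # pragma: no cover - schedule forbids this
        raise DomainError("empty TAC")
    mids = tac.schedule.mid_s
    vals = tac.values

    def f(t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), mids, vals)

    return f


def frame_average(
    f: TimeFunction,
    schedule: FrameSchedule,
    step_s: float = 0.1,
    roi_kind: str = "tissue",
    units: str = "SUV",
    domain_end_s: float | None = None,
) -> TimeActivityCurve:
    """Time-average a continuous function over each acquisition frame.

    ``value_i = (1/duration_i) * integral of f over frame i`` computed by
    trapezoidal quadrature at a fixed step of at most ``step_s`` seconds.
    If ``domain_end_s`` is given, a schedule extending beyond it is an
    error.
    """
    if step_s <= 0:
        raise DomainError("quadrature step must be positive")
    if domain_end_s is not None and schedule.total_end_s > domain_end_s + 1e-9:
        raise DomainError("schedule extends beyond the function domain")
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        n = max(2, int(np.ceil(d / step_s)) + 1)
        ts = np.linspace(s, s + d, n)
        out[i] = np.trapezoid(np.asarray(f(ts), dtype=float), ts) / d
    return TimeActivityCurve(
        schedule, out, roi_kind=roi_kind, units=units, allow_negative=True
    )
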