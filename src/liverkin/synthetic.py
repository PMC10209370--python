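"""Synthetic input functions, subject TACs and two-group cohorts.

Nothing clinical ships with the package; every estimator is exercised
by parameter recovery on simulated data.  The generator emulates the
study design at desk scale:

* two acquisition protocols — a short-term scan (12 x 5 s + 4 x 60 s
  dynamic frames plus one 1-min static frame at 60 min post-injection)
  and a fully dynamic 60-min scan (12 x 5 s, 9 x 60 s, 10 x 120 s,
  6 x 300 s = 37 frames);
* an arterial input with a delayed linear rise to an aortic peak near
  30 s followed by tri-exponential washout;
* a portal-vein input formed by convolving the arterial curve with a
  25 s exponential dispersion kernel (the splanchnic transit);
* a spleen curve simulated as a high-flow one-compartment tissue fed by
  the artery (it marks the arterial-to-portal phase transition for the
  maximum-slope method);
* per-group truth distributions (truncated normals) whose means and SDs
  are the published HCC and background-liver parameter summaries.

Noise is Gaussian per frame with SD = noise_cv * value / sqrt(d_i/5 s),
so 5-s frames carry the nominal coefficient of variation and longer
frames are quieter, mimicking count averaging; noisy values are clipped
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import truncnorm

from .compartment import KineticParams, tissue_curve
from .tac import (
    DomainError,
    FrameSchedule,
    TimeActivityCurve,
    TimeFunction,
    dual_input_curve,
)

__all__ = [
    "InputFunctionParams",
    "GroupDistribution",
    "SubjectData",
    "Cohort",
    "make_schedule",
    "simulate_arterial_input",
    "simulate_portal_input",
    "simulate_subject",
    "simulate_cohort",
    "PROTOCOLS",
]

PROTOCOLS = ("short_term", "full_dynamic")


def make_schedule(protocol: str) -> FrameSchedule:
    """Acquisition schedule for a named protocol.

    ``short_term``: 16 dynamic frames (12 x 5 s, 4 x 60 s, ending at
    300 s) plus one static frame [3600, 3660] s — 17 frames in all.
    ``full_dynamic``: 37 frames (12 x 5 s, 9 x 60 s, 10 x 120 s,
    6 x 300 s) ending at 3600 s.  Both share the same first 16 frames.
    """
    if protocol == "short_term":
        return FrameSchedule.from_groups(
            "12x5,4x60", label="short_term", extra_frames=[(3600.0, 60.0)]
        )
    if protocol == "full_dynamic":
        return FrameSchedule.from_groups(
            "12x5,9x60,10x120,6x300", label="full_dynamic"
        )
    raise DomainError(f"unknown protocol {protocol!r}")


@dataclass(frozen=True)
class InputFunctionParams:
    """Parametric arterial input and portal dispersion settings.

    The arterial curve is zero until ``t_delay_s``, rises linearly for
    ``t_rise_s`` to its peak (the sum of the amplitudes), then washes
    out as ``sum_i A_i exp(-lambda_i (t - t_peak))`` with rates in
    1/min.  Defaults put the aortic peak near 30 s at a peak value of
    ~35 activity units.  ``tau_pv_s`` is the exponential dispersion
    time constant producing the portal-vein curve;
    ``spleen_flow_scale`` multiplies the splenic uptake rate.
    """

    amplitudes: tuple[float, float, float] = (28.0, 6.0, 1.2)
    decay_rates_per_min: tuple[float, float, float] = (3.0, 0.4, 0.012)
    t_delay_s: float = 8.0
    t_rise_s: float = 22.0
    tau_pv_s: float = 25.0
    spleen_flow_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.amplitudes) <= 0 or min(self.decay_rates_per_min) <= 0:
            raise DomainError("amplitudes and decay rates must be positive")
        if self.t_delay_s < 0 or self.t_rise_s <= 0 or self.tau_pv_s <= 0:
            raise DomainError("time constants must be positive")

    @property
    def peak_value(self) -> float:
        return float(sum(self.amplitudes))

    @property
    def t_peak_s(self) -> float:
        return self.t_delay_s + self.t_rise_s


def simulate_arterial_input(p: InputFunctionParams) -> TimeFunction:
    """Delayed linear-rise-to-peak, tri-exponential-washout arterial curve."""
    amps = np.asarray(p.amplitudes)
    lam = np.asarray(p.decay_rates_per_min) / 60.0  # per second
    td, tp, peak = p.t_delay_s, p.t_peak_s, p.peak_value

    def A(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rise = (t > td) & (t < tp)
        out[rise] = peak * (t[rise] - td) / p.t_rise_s
        wash = t >= tp
        if np.any(wash):
            dt = t[wash, None] - tp
            out[wash] = np.sum(amps[None, :] * np.exp(-lam[None, :] * dt), axis=1)
        return out

    return A


def simulate_portal_input(
    A: TimeFunction,
    tau_pv_s: float,
    grid_end_s: float = 3660.0,
    grid_step_s: float = 0.25,
) -> TimeFunction:
    """Portal-vein curve: arterial input dispersed by an exponential kernel.

    V = A conv (1/tau) exp(-t/tau); the kernel is mass-preserving, so
    the portal peak is strictly later and lower than the arterial peak.
    A ``tau_pv_s`` below the grid step degenerates to the identity
    (delta kernel) and returns ``A``.
    """
    if tau_pv_s <= 0:
        raise DomainError("tau_pv_s must be positive")
    dt = float(grid_step_s)
    if tau_pv_s < dt:
        return A
    t = np.arange(0.0, grid_end_s + dt, dt)
    a = np.asarray(A(t), dtype=float)
    kern = np.exp(-t / tau_pv_s) / tau_pv_s
    v = fftconvolve(a, kern)[: t.size] * dt
    v -= 0.5 * dt * (kern[0] * a + kern * a[0])  # trapezoid end correction
    v = np.clip(v, 0.0, None)

    def V(ts: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(ts, dtype=float), t, v, left=0.0)

    return V


#: Spleen emulated as high-flow one-compartment tissue (K1=1.0 mL/min/mL,
#: k2=1.2/min, Vb=0.3) fed by the artery.
_SPLEEN = dict(k1=1.0, k2=1.2, vb=0.3)


@dataclass(frozen=True)
class SubjectData:
    """Simulated four-ROI TAC set with its generating truth."""

    tissue: TimeActivityCurve
    aorta: TimeActivityCurve
    portal_vein: TimeActivityCurve
    spleen: TimeActivityCurve
    truth: KineticParams
    noise_cv: float
    seed: int | None = None
    group: str = ""
    subject_id: str = ""

    def tacs(self) -> dict[str, TimeActivityCurve]:
        return {
            "tissue": self.tissue,
            "aorta": self.aorta,
            "portal_vein": self.portal_vein,
            "spleen": self.spleen,
        }

    def subset(self, indices, label: str) -> "SubjectData":
        """Restrict all four TACs to a subset of frames."""
        def cut(tac: TimeActivityCurve) -> TimeActivityCurve:
            sched = tac.schedule.subset(indices, label=label)
            return TimeActivityCurve(
                sched, tac.values[np.asarray(indices, dtype=int)],
                roi_kind=tac.roi_kind, units=tac.units, allow_negative=True,
            )
        return replace(
            self, tissue=cut(self.tissue), aorta=cut(self.aorta),
            portal_vein=cut(self.portal_vein), spleen=cut(self.spleen),
        )


def _noisy(
    values: np.ndarray,
    duration_s: np.ndarray,
    noise_cv: float,
    rng: np.random.Generator,
    clip: bool = True,
) -> np.ndarray:
    """Duration-scaled Gaussian noise: SD_i = cv * value_i / sqrt(d_i/5)."""
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    if noise_cv == 0:
        return values.copy()
    sd = noise_cv * np.abs(values) / np.sqrt(duration_s / 5.0)
    out = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    return np.clip(out, 0.0, None) if clip else out


def _fine_grid(end_s: float, step_s: float = 0.5) -> np.ndarray:
    n = int(round(end_s / step_s)) + 1
    return np.linspace(0.0, (n - 1) * step_s, n)


def _frame_means_from_grid(
    curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    dt = t[1] - t[0]
    out = np.empty(schedule.n_frames)
    for k, (s, e) in enumerate(zip(schedule.start_s, schedule.end_s)):
        i0, i1 = int(round(s / dt)), int(round(e / dt))
        seg = curve[i0 : i1 + 1]
        out[k] = (np.sum(seg) - 0.5 * (seg[0] + seg[-1])) / (i1 - i0)
    return out


def simulate_subject(
    truth: KineticParams,
    ifp: InputFunctionParams | None = None,
    schedule: FrameSchedule | None = None,
    noise_cv: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid_step_s: float = 0.5,
) -> SubjectData:
    """Simulate the four ROI TACs of one subject on one schedule.

    The tissue curve is the compartment forward model under the dual
    input built from ``truth.hpi``; aorta and portal-vein TACs frame-
    average the input functions themselves; the spleen is a high-flow
    one-compartment tissue.  ``noise_cv = 0`` reproduces the noiseless
    frame averages exactly, and a fixed ``seed`` makes the noise
    reproducible.
    """
    ifp = ifp or InputFunctionParams()
    schedule = schedule if schedule is not None else make_schedule("short_term")
    if rng is None:
        rng = np.random.default_rng(seed)
    A = simulate_arterial_input(ifp)
    V = simulate_portal_input(A, ifp.tau_pv_s, grid_end_s=schedule.total_end_s)
    cb = dual_input_curve(A, V, truth.hpi)
    t = _fine_grid(schedule.total_end_s, grid_step_s)

    ct = tissue_curve(truth, cb, t, check_causal=False)
    spleen_p = KineticParams(
        k1=_SPLEEN["k1"] * ifp.spleen_flow_scale, k2=_SPLEEN["k2"],
        k3=0.0, k4=0.0, hpi=1.0, vb=_SPLEEN["vb"],
    )
    cs = tissue_curve(spleen_p, A, t, check_causal=False)

    def tac(curve: np.ndarray, kind: str) -> TimeActivityCurve:
        clean = _frame_means_from_grid(curve, t, schedule)
        vals = _noisy(clean, schedule.duration_s, noise_cv, rng)
        return TimeActivityCurve(schedule, vals, roi_kind=kind, allow_negative=True)

    return SubjectData(
        tissue=tac(ct, "tissue"),
        aorta=tac(np.asarray(A(t), dtype=float), "aorta"),
        portal_vein=tac(np.asarray(V(t), dtype=float), "portal_vein"),
        spleen=tac(cs, "spleen"),
        truth=truth,
        noise_cv=noise_cv,
        seed=seed,
    )


_PARAM_NAMES = ("k1", "k2", "k3", "k4", "hpi", "vb")

# Published group summaries (mean, SD) used as sampling distributions.
# "combined_*" hold the combined-model summaries (the default);
# "three_compartment_*" the six-parameter-model summaries.
_GROUP_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "combined_hcc": {
        "hpi": (0.7643, 0.1209), "k1": (1.52, 0.61), "k2": (1.84, 0.56),
        "k3": (0.046, 0.047), "k4": (0.021, 0.027), "vb": (0.052, 0.053),
    },
    "combined_liver": {
        "hpi": (0.4276, 0.1708), "k1": (1.00, 0.63), "k2": (1.01, 0.59),
        "k3": (0.005, 0.007), "k4": (0.023, 0.034), "vb": (0.003, 0.007),
    },
    "three_compartment_hcc": {
        "hpi": (0.7114, 0.2456), "k1": (1.67, 0.52), "k2": (2.01, 0.43),
        "k3": (0.051, 0.050), "k4": (0.019, 0.027), "vb": (0.081, 0.138),
    },
    "three_compartment_liver": {
        "hpi": (0.1678, 0.2029), "k1": (1.65, 0.73), "k2": (1.66, 0.73),
        "k3": (0.013, 0.021), "k4": (0.023, 0.036), "vb": (0.027, 0.056),
    },
}

# Truncation keeps draws physiological and identifiable: rates strictly
# positive (1e-3 floor for the small rates), fractions inside [0, 1].
_DEFAULT_TRUNCATION = {
    "k1": (0.05, 10.0), "k2": (0.05, 10.0), "k3": (1e-3, 1.0),
    "k4": (1e-3, 1.0), "hpi": (0.01, 0.99), "vb": (1e-3, 0.5),
}


@dataclass(frozen=True)
class GroupDistribution:
    """Truncated-normal sampling distribution of the kinetic parameters."""

    name: str
    moments: dict[str, tuple[float, float]]
    truncation: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRUNCATION)
    )

    def __post_init__(self) -> None:
        for p in _PARAM_NAMES:
            if p not in self.moments:
                raise DomainError(f"missing moments for parameter {p!r}")
            if self.moments[p][1] < 0:
                raise DomainError(f"negative SD for parameter {p!r}")

    @classmethod
    def from_table(cls, key: str) -> "GroupDistribution":
        """Named published group summary, e.g. ``"combined_hcc"``."""
        if key not in _GROUP_TABLES:
            raise DomainError(
                f"unknown group table {key!r}; choose from {sorted(_GROUP_TABLES)}"
            )
        return cls(name=key, moments=dict(_GROUP_TABLES[key]))

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw ``n`` truth parameter vectors as a DataFrame."""
        if n < 1:
            raise DomainError("need n >= 1 draws")
        cols = {}
        for p in _PARAM_NAMES:
            mu, sd = self.moments[p]
            lo, hi = self.truncation[p]
            if sd == 0:
                cols[p] = np.full(n, np.clip(mu, lo, hi))
            else:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                cols[p] = truncnorm.rvs(
                    a, b, loc=mu, scale=sd, size=n, random_state=rng
                )
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class Cohort:
    """Simulated two-group cohort: truth table plus per-subject TACs."""

    table: pd.DataFrame
    subjects_short: list[SubjectData]
    subjects_full: list[SubjectData]
    seed: int


def _union_schedule() -> FrameSchedule:
    """Full-dynamic frames plus the 60-min static frame (38 frames)."""
    return FrameSchedule.from_groups(
        "12x5,9x60,10x120,6x300", label="union", extra_frames=[(3600.0, 60.0)]
    )


def simulate_subject_both_protocols(
    truth: KineticParams,
    ifp: InputFunctionParams | None = None,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[SubjectData, SubjectData]:
    """One scan session read out on both protocols.

    Clinically both protocols come from the same list-mode acquisition,
    so the 16 shared early frames carry identical noisy measurements;
    only the static 60-min frame is an extra readout.  Simulates once
    on the 38-frame union schedule and slices.
    """
    union = _union_schedule()
    subj = simulate_subject(
        truth, ifp=ifp, schedule=union, noise_cv=noise_cv, rng=rng, seed=seed
    )
    short = subj.subset(list(range(16)) + [37], "short_term")
    full = subj.subset(list(range(37)), "full_dynamic")
    return short, full


def simulate_cohort(
    hcc_dist: GroupDistribution | None = None,
    liver_dist: GroupDistribution | None = None,
    n_per_group: int = 10,
    noise_cv: float = 0.05,
    seed: int = 0,
    ifp: InputFunctionParams | None = None,
) -> Cohort:
    """Two-group cohort (HCC vs background liver) on both protocols.

    Truths are truncated-normal draws from the group distributions
    (defaults: the combined-model published summaries); each subject is
    simulated once and read out on the short-term and full schedules.
    """
    if n_per_group < 2:
        raise DomainError("need n_per_group >= 2")
    hcc_dist = hcc_dist or GroupDistribution.from_table("combined_hcc")
    liver_dist = liver_dist or GroupDistribution.from_table("combined_liver")
    rng = np.random.default_rng(seed)
    rows = []
    shorts: list[SubjectData] = []
    fulls: list[SubjectData] = []
    for group, dist in (("hcc", hcc_dist), ("liver", liver_dist)):
        truths = dist.sample(n_per_group, rng)
        for i, row in truths.iterrows():
            truth = KineticParams(**{p: float(row[p]) for p in _PARAM_NAMES})
            sid = f"{group}_{i:03d}"
            short, full = simulate_subject_both_protocols(
                truth, ifp=ifp, noise_cv=noise_cv, rng=rng
            )
            short = replace(short, group=group, subject_id=sid)
            full = replace(full, group=group, subject_id=sid)
            shorts.append(short)
            fulls.append(full)
            rec = {"subject_id": sid, "group": group}
            rec.update({f"true_{p}": float(row[p]) for p in _PARAM_NAMES})
            rows.append(rec)
    return Cohort(
        table=pd.DataFrame(rows), subjects_short=shorts, subjects_full=fulls,
        seed=seed,
    )
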