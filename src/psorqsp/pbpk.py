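"""Two-compartment pharmacokinetics of subcutaneous biologic dosing.

The model has a skin depot (administration site) and a central blood
compartment (clearance site):

    dA_skin/dt = -ka * A_skin            (sc/oral doses add f_bio * amount)
    dC/dt      =  ka * A_skin / V - kel * C    (iv doses add amount / V)

The system is linear, so multi-dose profiles are the superposition of
single-dose Bateman curves; that closed form is the default simulation path
and the independent oracle for the fixed-step RK4 integrator.

Units: time in days, amounts in mg, volumes in L, concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "PKMetrics",
    "FitResult",
    "absorption_constant",
    "czp_regimen",
    "iv_bolus_regimen",
    "oral_regimen",
    "simulate",
    "fit_clearance",
    "individualize",
    "pk_metrics",
    "mass_balance_error",
    "blood_volume",
    "body_surface_area",
    "CZP_REFERENCE",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PKParameters:
    """Rate constants and volumes of the depot/central model."""

    ka: float  # absorption rate, 1/day
    kel: float  # elimination rate, 1/day
    v_blood: float  # central (blood) volume, L
    v_skin: float = 3.0  # depot (skin) volume, L; bookkeeping only
    f_bio: float = 1.0  # bioavailability fraction of sc/oral doses

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kel <= 0:
            raise ValueError("ka and kel must be > 0")
        if self.v_blood <= 0 or self.v_skin <= 0:
            raise ValueError("volumes must be > 0")
        if not 0 < self.f_bio <= 1:
            raise ValueError("f_bio must lie in (0, 1]")
        if self.ka == self.kel:
            # the Bateman form is singular at ka == kel; nudge apart
            object.__setattr__(self, "ka", self.ka * (1 + 1e-9) + 1e-15)


@dataclass(frozen=True)
class DoseEvent:
    time: float  # days from first dose
    amount: float  # mg
    route: str = "sc"  # sc | iv | oral

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0:
            raise ValueError("dose time and amount must be >= 0")
        if self.route not in ("sc", "iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    events: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray  # days, strictly increasing
    concentrations: np.ndarray  # mg/L in the central compartment
    patient_id: str = ""
    regimen: str = ""
    depot: np.ndarray | None = None  # mg remaining in the depot, if tracked

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(c < -1e-12):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class PKMetrics:
    cmax: float
    tmax: float
    auc: float
    half_life: float  # nan when no terminal phase exists
    trough_ss: float


@dataclass(frozen=True)
class FitResult:
    kel: float
    r_squared: float
    residuals: np.ndarray
    sse: float


def absorption_constant(tmax: float) -> float:
    """First-order absorption rate from the time of peak concentration,
    via the absorption-half-life approximation T1/2a ~ Tmax / 3:
    ka = ln 2 / (Tmax / 3)."""
    if tmax <= 0:
        raise ValueError("tmax must be > 0")
    return LN2 / (tmax / 3.0)


def czp_regimen(maintenance_mg: int, *, allow_any: bool = False) -> Regimen:
    """Approved certolizumab pegol psoriasis schedule: 400 mg sc loading
    doses at weeks 0, 2, 4, then ``maintenance_mg`` every two weeks through
    week 16 (days 42..112), nine administrations in total."""
    if maintenance_mg not in (200, 400) and not allow_any:
        raise ValueError(
            f"maintenance dose {maintenance_mg} mg is not an approved scheme "
            "(200 or 400); pass allow_any=True to override"
        )
    events = [DoseEvent(14.0 * i, 400.0, "sc") for i in range(3)]
    events += [DoseEvent(14.0 * i, float(maintenance_mg), "sc") for i in range(3, 9)]
    return Regimen(tuple(events), label=f"czp{maintenance_mg}")


def iv_bolus_regimen(times, amount: float, label: str = "iv") -> Regimen:
    """Single-compartment intravenous schedule (e.g. infliximab-style)."""
    return Regimen(tuple(DoseEvent(float(t), amount, "iv") for t in times), label)


def oral_regimen(times, amount: float, label: str = "oral-liver-clearance") -> Regimen:
    """Oral first-order absorption schedule with liver-clearance labelling;
    kinetically identical to the sc machinery."""
    return Regimen(tuple(DoseEvent(float(t), amount, "oral") for t in times), label)


def _grid(regimen: Regimen, t_end: float | None, dt: float) -> np.ndarray:
    if t_end is None:
        last = max((e.time for e in regimen.events), default=0.0)
        t_end = last + 28.0
    n = int(round(t_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _locate_events(times: np.ndarray, regimen: Regimen) -> list:
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    located = []
    for ev in regimen.events:
        idx = int(round((ev.time - times[0]) / dt))
        if idx < 0 or idx >= len(times) or abs(times[idx] - ev.time) > 1e-9:
            raise ValueError(
                f"dose event at t={ev.time} d does not fall on the simulation "
                f"grid (step {dt} d); refine the grid"
            )
        located.append((idx, ev))
    return located


def _bateman(params: PKParameters, regimen: Regimen, times: np.ndarray):
    """Closed-form superposition of single-dose responses."""
    ka, kel, v = params.ka, params.kel, params.v_blood
    conc = np.zeros_like(times)
    depot = np.zeros_like(times)
    for ev in regimen.events:
        tau = times - ev.time
        active = tau >= 0
        tau = np.where(active, tau, 0.0)
        if ev.route == "iv":
            conc += np.where(active, ev.amount / v * np.exp(-kel * tau), 0.0)
        else:
            dose = params.f_bio * ev.amount
            conc += np.where(
                active,
                dose * ka / (v * (ka - kel)) * (np.exp(-kel * tau) - np.exp(-ka * tau)),
                0.0,
            )
            depot += np.where(active, dose * np.exp(-ka * tau), 0.0)
    return conc, depot


def _rk4(params: PKParameters, regimen: Regimen, times: np.ndarray):
    ka, kel, v = params.ka, params.kel, params.v_blood
    located = dict()
    for idx, ev in _locate_events(times, regimen):
        located.setdefault(idx, []).append(ev)
    conc = np.zeros_like(times)
    depot = np.zeros_like(times)
    a, c = 0.0, 0.0
    for i, t in enumerate(times):
        for ev in located.get(i, ()):  # bolus applied at the node
            if ev.route == "iv":
                c += ev.amount / v
            else:
                a += params.f_bio * ev.amount
        depot[i], conc[i] = a, c
        if i + 1 < len(times):
            h = times[i + 1] - t

            def deriv(a_, c_):
                return -ka * a_, ka * a_ / v - kel * c_

            k1a, k1c = deriv(a, c)
            k2a, k2c = deriv(a + h / 2 * k1a, c + h / 2 * k1c)
            k3a, k3c = deriv(a + h / 2 * k2a, c + h / 2 * k2c)
            k4a, k4c = deriv(a + h * k3a, c + h * k3c)
            a += h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
            c += h / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
    return conc, depot


def simulate(
    params: PKParameters,
    regimen: Regimen,
    t_end: float | None = None,
    dt: float = 0.1,
    method: str = "analytic",
    patient_id: str = "",
) -> ConcentrationProfile:
    """Simulate the central-compartment concentration-time curve.

    ``method`` is ``"analytic"`` (Bateman superposition, exact) or ``"rk4"``
    (fixed-step Runge-Kutta); the two agree to ~1e-8 relative on the default
    grid and the analytic path serves as the oracle for the numeric one.
    """
    times = _grid(regimen, t_end, dt)
    if method == "analytic":
        _locate_events(times, regimen)  # enforce the grid contract
        conc, depot = _bateman(params, regimen, times)
    elif method == "rk4":
        conc, depot = _rk4(params, regimen, times)
    else:
        raise ValueError(f"unknown method {method!r}")
    conc = np.clip(conc, 0.0, None)
    return ConcentrationProfile(times, conc, patient_id, regimen.label, depot)


def mass_balance_error(profile: ConcentrationProfile, params: PKParameters,
                       regimen: Regimen) -> float:
    """Relative mass-balance defect at the end of the simulation:
    |input - (depot + central + eliminated)| / input."""
    dosed = sum(
        (params.f_bio if e.route != "iv" else 1.0) * e.amount for e in regimen.events
    )
    if dosed == 0:
        return 0.0
    eliminated = params.kel * params.v_blood * np.trapezoid(
        profile.concentrations, profile.times
    )
    depot_left = float(profile.depot[-1]) if profile.depot is not None else 0.0
    central = float(profile.concentrations[-1]) * params.v_blood
    return abs(dosed - (depot_left + central + eliminated)) / dosed


def fit_clearance(
    points: pd.DataFrame,
    params: PKParameters,
    regimen: Regimen,
    bounds: tuple = (1e-3, 1.0),
) -> FitResult:
    """Least-squares fit of the elimination rate ``kel`` to observed
    concentration points (columns ``time_day``, ``conc_mg_per_L``), holding
    the remaining parameters fixed."""
    if len(points) < 3:
        raise ValueError("need at least 3 concentration points")
    t_obs = points["time_day"].to_numpy(dtype=float)
    c_obs = points["conc_mg_per_L"].to_numpy(dtype=float)
    if np.any(t_obs <= 0):
        raise ValueError("observation times must be positive")
    if np.ptp(t_obs) == 0:
        raise ValueError("kel is not identifiable: all points share one time")

    def predict(kel: float) -> np.ndarray:
        p = replace(params, kel=float(kel))
        conc, _ = _bateman(p, regimen, t_obs)
        return conc

    def sse(kel: float) -> float:
        return float(np.sum((predict(kel) - c_obs) ** 2))

    res = optimize.minimize_scalar(sse, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-10})
    kel = float(res.x)
    resid = predict(kel) - c_obs
    ss_tot = float(np.sum((c_obs - c_obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(kel=kel, r_squared=r2, residuals=resid, sse=float(res.fun))


# ---------------------------------------------------------------------------
# individualization
# ---------------------------------------------------------------------------

def blood_volume(sex: str, height_cm: float, weight_kg: float) -> float:
    """Allometric total blood volume (L) from sex, height and weight
    (height enters in metres, cubed)."""
    h = height_cm / 100.0
    if sex == "male":
        return 0.3669 * h**3 + 0.03219 * weight_kg + 0.6041
    return 0.3561 * h**3 + 0.03308 * weight_kg + 0.1833


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area, m^2."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


# Reference parameters for the standard 75 kg / 170 cm / 40 y male patient:
# ka from Tmax ~ 5 d via the Tmax/3 rule, kel from a ~14 d terminal
# half-life, central volume from the allometric formula (4.821 L).
_REF_HEIGHT, _REF_WEIGHT = 170.0, 75.0
CZP_REFERENCE = PKParameters(
    ka=absorption_constant(5.0),
    kel=LN2 / 14.0,
    v_blood=blood_volume("male", _REF_HEIGHT, _REF_WEIGHT),
    v_skin=3.0,
    f_bio=1.0,
)
_REF_BSA = body_surface_area(_REF_HEIGHT, _REF_WEIGHT)


def individualize(patient, reference: PKParameters = CZP_REFERENCE,
                  volume_adjustment: float = 1.0) -> PKParameters:
    """Per-patient parameters: central volume from the allometric sex/height/
    weight formula scaled by a configurable distribution-volume adjustment
    (the biologic's apparent distribution volume can exceed plasma volume);
    depot volume scaled with body surface area; rates and bioavailability
    unchanged."""
    v_blood = blood_volume(patient.sex, patient.height, patient.weight)
    v_skin = reference.v_skin * body_surface_area(patient.height, patient.weight) / _REF_BSA
    return replace(
        reference,
        v_blood=v_blood * volume_adjustment,
        v_skin=v_skin,
    )


def pk_metrics(
    profile: ConcentrationProfile,
    regimen: Regimen | None = None,
    params: PKParameters | None = None,
) -> PKMetrics:
    """Summary exposure metrics of a simulated profile.

    ``half_life`` is ln2/kel when parameters are supplied, otherwise the
    terminal log-linear slope after the last dose (nan when the tail never
    decays).  ``trough_ss`` is the concentration immediately before the last
    dose (0 for single-dose or empty regimens).
    """
    if len(profile.times) == 0:
        raise ValueError("empty profile")
    c, t = profile.concentrations, profile.times
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc = float(np.trapezoid(c, t))

    if params is not None:
        half_life = LN2 / params.kel
    else:
        # terminal slope: log-linear fit over the final decaying stretch
        last_dose = max((e.time for e in regimen.events), default=0.0) if regimen else 0.0
        tail = t >= last_dose
        ct, tt = c[tail], t[tail]
        if len(ct) >= 3:
            j = int(np.argmax(ct))
            ct, tt = ct[j:], tt[j:]
        if len(ct) >= 3 and ct[-1] < ct[0] and np.all(ct > 0):
            slope = np.polyfit(tt, np.log(ct), 1)[0]
            half_life = float(-LN2 / slope) if slope < 0 else float("nan")
        else:
            half_life = float("nan")

    trough = 0.0
    if regimen is not None and len(regimen.events) > 1:
        t_last = regimen.events[-1].time
        before = t < t_last - 1e-12
        if before.any():
            trough = float(c[np.flatnonzero(before)[-1]])
    return PKMetrics(cmax=cmax, tmax=tmax, auc=auc, half_life=half_life,
                     trough_ss=trough)
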