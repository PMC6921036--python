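"""One-compartment IV-infusion pharmacokinetics.

Analytic solution for plasma concentration after a constant-rate
intravenous infusion into a single well-stirred compartment with linear
elimination:

    during infusion (0 <= t <= T_inf):
        C(t) = (F * R0 / CL) * (1 - exp(-k t)),   R0 = Dose / T_inf
    after infusion (t > T_inf):
        C(t) = C(T_inf) * exp(-k (t - T_inf))

with V = Vc_per_kg * body_weight, k = CL / V.  Units are mg, L and h
throughout; concentrations are reported in ug/mL (identically mg/L), so
AUC carries ug*h/mL and the mass-balance identity CL * AUC(0-inf) =
F * Dose holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

#: Default profile grid: one-minute resolution over 24 h.
DEFAULT_N_POINTS = 1441


@dataclass(frozen=True)
class PKParameters:
    """Inputs of the infusion model.

    dose (mg), infusion_duration (h), clearance (L/h), vc_per_kg (L/kg),
    body_weight (kg), bioavailable_fraction (0-1], sim_duration (h).
    ``annotations`` carries pass-through fields (plasma-protein binding,
    blood/plasma ratio, solubility...) that the model does not use.
    """

    dose: float
    infusion_duration: float
    clearance: float
    vc_per_kg: float
    body_weight: float = 70.0
    bioavailable_fraction: float = 1.0
    sim_duration: float = 24.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = {
            "dose": self.dose,
            "infusion_duration": self.infusion_duration,
            "clearance": self.clearance,
            "vc_per_kg": self.vc_per_kg,
            "body_weight": self.body_weight,
            "sim_duration": self.sim_duration,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not 0 < self.bioavailable_fraction <= 1:
            raise ValueError(
                f"bioavailable_fraction must be in (0, 1], "
                f"got {self.bioavailable_fraction}"
            )
        if self.infusion_duration > self.sim_duration:
            raise ValueError("infusion_duration exceeds sim_duration")

    @property
    def volume(self) -> float:
        """Central volume V = Vc_per_kg * body weight, L."""
        return self.vc_per_kg * self.body_weight

    @property
    def k_elim(self) -> float:
        """First-order elimination rate constant k = CL / V, 1/h."""
        return self.clearance / self.volume

    @property
    def infusion_rate(self) -> float:
        """R0 = Dose / T_inf, mg/h."""
        return self.dose / self.infusion_duration

    @classmethod
    def from_file(cls, path) -> "PKParameters":
        """Read parameters from a YAML or JSON mapping."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__ if f != "annotations"}
        kwargs = {k: v for k, v in data.items() if k in known}
        annotations = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, annotations=annotations)


def concentration(p: PKParameters, t) -> np.ndarray:
    """Closed-form plasma concentration C(t) in ug/mL at times t (h)."""
    t = np.asarray(t, dtype=float)
    k = p.k_elim
    plateau = p.bioavailable_fraction * p.infusion_rate / p.clearance
    c_end = plateau * (1.0 - np.exp(-k * p.infusion_duration))
    rising = plateau * (1.0 - np.exp(-k * np.clip(t, 0.0, None)))
    falling = c_end * np.exp(-k * (t - p.infusion_duration))
    return np.where(t <= p.infusion_duration, rising, falling)


@dataclass(frozen=True)
class PKProfile:
    """Simulated concentration-time curve with summary metrics."""

    times: np.ndarray
    concentrations: np.ndarray
    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float

    def summary(self) -> dict:
        return {
            "cmax_ug_per_ml": self.cmax,
            "tmax_h": self.tmax,
            "auc_0_t_ug_h_per_ml": self.auc_0_t,
            "auc_0_inf_ug_h_per_ml": self.auc_0_inf,
        }

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.concentrations]),
            delimiter=",",
            header="time_h,conc_ug_per_ml",
            comments="",
        )

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def auc_0_inf(p: PKParameters) -> float:
    """AUC extrapolated to infinity: F * Dose / CL (ug*h/mL).

    Independent of the distribution volume, body weight and infusion
    duration — the full bioavailable dose is eventually cleared.
    """
    return p.bioavailable_fraction * p.dose / p.clearance


def cmax(p: PKParameters) -> float:
    """Peak concentration (F R0 / CL)(1 - exp(-k T_inf)), at infusion end."""
    k = p.k_elim
    plateau = p.bioavailable_fraction * p.infusion_rate / p.clearance
    return plateau * (1.0 - np.exp(-k * p.infusion_duration))


def auc_0_t(profile: PKProfile) -> float:
    """Trapezoidal AUC over the simulated grid (ug*h/mL)."""
    t = np.asarray(profile.times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("profile needs at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return float(np.trapezoid(profile.concentrations, t))


def simulate_infusion(p: PKParameters, n_points: int = DEFAULT_N_POINTS) -> PKProfile:
    """Evaluate the analytic model on a grid over [0, sim_duration].

    The grid always contains t = 0, the infusion end (where Cmax is
    attained and the curve has its kink) and sim_duration.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    times = np.union1d(
        np.linspace(0.0, p.sim_duration, n_points), [p.infusion_duration]
    )
    conc = concentration(p, times)
    profile = PKProfile(
        times=times,
        concentrations=conc,
        cmax=cmax(p),
        tmax=p.infusion_duration,
        auc_0_t=0.0,
        auc_0_inf=auc_0_inf(p),
    )
    return PKProfile(**{**asdict(profile), "auc_0_t": auc_0_t(profile)})


#: Gemcitabine inputs as printed on the drug's label/simulation table:
#: 1250 mg over a 1 h infusion, clearance 168 L/h, central volume
#: 1.45 L/kg at 70 kg, bioavailability 99.949%.
GEMCITABINE = PKParameters(
    dose=1250.0,
    infusion_duration=1.0,
    clearance=168.0,
    vc_per_kg=1.45,
    body_weight=70.0,
    bioavailable_fraction=0.99949,
    sim_duration=24.0,
)
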