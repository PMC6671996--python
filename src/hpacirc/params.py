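"""Model parameters and light schedules.

The model couples a phototransduction cascade to a Goodwin-type
hypothalamic-pituitary-adrenal (HPA) oscillator with glucocorticoid-receptor
(GR) pharmacodynamics.  All rate constants are per hour; concentrations are in
arbitrary units.  Clock time is hours since midnight, modulo the schedule
period (24 h by default).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "LightSchedule",
    "STATE_NAMES",
    "N_STATE",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: Order of the dynamical variables everywhere in the package: a 3-compartment
#: transfer chain driven by the light square wave (synthesis arm), a parallel
#: 3-compartment chain (degradation arm), the delayed ``light_effect`` signal,
#: then the hormonal/receptor states.
STATE_NAMES = (
    "light_TCsynth1",
    "light_TCsynth2",
    "light_TCsynth3",
    "light_TCdeg1",
    "light_TCdeg2",
    "light_TCdeg3",
    "light_effect",
    "CRH",
    "ACTH",
    "CORT",
    "GR_mRNA",
    "GR",
    "DR",
    "DRN",
)
N_STATE = len(STATE_NAMES)

# Index of CORT, the calibrated observable, in the state vector.
CORT_INDEX = STATE_NAMES.index("CORT")

_PARAM_ORDER = (
    "k_p1",
    "K_p1",
    "k_p2",
    "K_p2",
    "k_p3",
    "V_d1",
    "K_d1",
    "V_d2",
    "K_d2",
    "V_d3",
    "K_d3",
    "k_syn_GRm",
    "IC50_GRm",
    "k_deg",
    "k_syn_GR",
    "k_deg_GR",
    "k_on",
    "k_T",
    "k_re",
    "r_f",
    "k_t",
    "k_us",
    "K_M_us",
    "n",
    "k_deg_us",
    "k_eff",
)


@dataclass(frozen=True)
class ModelParameters:
    """All rate and affinity constants of the coupled photic + HPA + GR model.

    The three regulatory parameters studied throughout the package are
    ``K_p1`` (hypothalamic feedback inhibition constant, smaller = stronger
    negative feedback), ``K_p2`` (pituitary feedback inhibition constant) and
    ``k_p3`` (adrenal sensitivity, the feedforward ACTH→CORT gain).  Chronic
    stress is represented by an elevated CRH drive ``k_p1``.
    """

    k_p1: float  # CRH zero-order synthesis rate (conc/h); chronic-stress drive
    K_p1: float  # hypothalamic feedback inhibition constant (conc)
    k_p2: float  # ACTH first-order synthesis rate (1/h)
    K_p2: float  # pituitary feedback inhibition constant (conc)
    k_p3: float  # adrenal sensitivity (1/h)
    V_d1: float  # CRH degradation Vmax (conc/h)
    K_d1: float  # CRH degradation Km (conc)
    V_d2: float  # ACTH degradation Vmax (conc/h)
    K_d2: float  # ACTH degradation Km (conc)
    V_d3: float  # CORT degradation Vmax (conc/h)
    K_d3: float  # CORT degradation Km (conc)
    k_syn_GRm: float  # GR mRNA synthesis rate (conc/h)
    IC50_GRm: float  # DR(N) level halving GR mRNA transcription (conc)
    k_deg: float  # GR mRNA degradation rate (1/h)
    k_syn_GR: float  # GR translation rate (1/h)
    k_deg_GR: float  # free-GR degradation rate (1/h)
    k_on: float  # CORT-GR binding rate (1/(conc h))
    k_T: float  # nuclear translocation rate of DR (1/h)
    k_re: float  # receptor recycling rate from DR(N) (1/h)
    r_f: float  # recycled fraction of DR(N) efflux (dimensionless, 0..1)
    k_t: float  # photic transfer-compartment rate (1/h); chain delay ~ 3/k_t
    k_us: float  # light_effect synthesis rate (1/h)
    K_M_us: float  # half-max constant of the phototransduction Hill term
    n: float  # Hill coefficient of phototransduction (ultrasensitivity)
    k_deg_us: float  # light_effect degradation rate (1/h)
    k_eff: float  # enhancement of light_effect degradation by the deg chain

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v <= 0 and f.name != "r_f":
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")
        if not 0.0 <= self.r_f <= 1.0:
            raise ValueError(f"r_f must lie in [0, 1], got {self.r_f}")
        if self.n < 1.0:
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")

    def to_array(self) -> np.ndarray:
        """Pack into the fixed-order float64 vector used by the integrator."""
        return np.array([getattr(self, k) for k in _PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in zip(_PARAM_ORDER, arr, strict=True)})

    def replace(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def with_triple(self, K_p1: float, K_p2: float, k_p3: float) -> "ModelParameters":
        """Copy with the three regulatory parameters set."""
        return replace(self, K_p1=K_p1, K_p2=K_p2, k_p3=k_p3)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _PARAM_ORDER}


@dataclass(frozen=True)
class LightSchedule:
    """A periodic square-wave light schedule with optional per-day overrides.

    ``lights_on``/``lights_off`` are clock times within one period.  A
    14L:10D schedule with lights on 07:00-21:00 (the default) has
    ``lights_on=7, lights_off=21``.  Schedules crossing midnight
    (``lights_on > lights_off``) are allowed.  ``overrides`` is an ordered
    list of ``(start_day, end_day, lights_on, lights_off)`` entries applying
    on days ``start_day <= day < end_day`` (day = floor(t / period)); later
    entries win.  ``strength`` scales the square wave's amplitude (entrainer
    strength 1 = the nominal light input).
    """

    lights_on: float = 7.0
    lights_off: float = 21.0
    period: float = 24.0
    overrides: tuple[tuple[float, float, float, float], ...] = field(default_factory=tuple)
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        for name in ("lights_on", "lights_off"):
            v = getattr(self, name)
            if not 0 <= v < self.period:
                raise ValueError(f"{name} must lie in [0, period), got {v}")
        if self.photoperiod <= 0 or self.photoperiod >= self.period:
            raise ValueError("photoperiod must lie strictly inside (0, period)")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        object.__setattr__(self, "overrides", tuple(tuple(o) for o in self.overrides))

    @property
    def photoperiod(self) -> float:
        """Length of the lit interval (h)."""
        if self.lights_on < self.lights_off:
            return self.lights_off - self.lights_on
        return self.period - (self.lights_on - self.lights_off)

    def window_for_day(self, day: int) -> tuple[float, float]:
        """(lights_on, lights_off) clock times in effect on the given day."""
        on, off = self.lights_on, self.lights_off
        for start, end, o_on, o_off in self.overrides:
            if start <= day < end:
                on, off = o_on, o_off
        return on, off

    def is_lit(self, t: float) -> bool:
        """Whether lights are on at absolute time ``t`` (h since t=0 midnight)."""
        day = int(np.floor(t / self.period))
        on, off = self.window_for_day(day)
        tau = t - day * self.period
        if on < off:
            return on <= tau < off
        return tau >= on or tau < off

    def light_value(self, t: float) -> float:
        return self.strength if self.is_lit(t) else 0.0

    def segments(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant representation of the light input on [t0, t1].

        Returns ``(edges, values)`` with ``edges`` of length m+1 spanning
        [t0, t1] and ``values`` of length m giving the light level on each
        interval.  Switch times are exact; the integrator restarts at each
        edge so the square wave never falls inside a step.
        """
        if t1 <= t0:
            raise ValueError("need t1 > t0")
        switches: list[float] = []
        day0 = int(np.floor(t0 / self.period))
        day1 = int(np.floor(t1 / self.period))
        for day in range(day0, day1 + 1):
            base = day * self.period
            on, off = self.window_for_day(day)
            for s in (base, base + on, base + off):
                if t0 < s < t1:
                    switches.append(s)
        edges = np.array(sorted({t0, t1, *switches}), dtype=float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        values = np.array([self.light_value(m) for m in mids], dtype=float)
        return edges, values

    def with_overrides(
        self, *overrides: tuple[float, float, float, float]
    ) -> "LightSchedule":
        return replace(self, overrides=self.overrides + tuple(overrides))

    def to_dict(self) -> dict:
        return {
            "lights_on": self.lights_on,
            "lights_off": self.lights_off,
            "period": self.period,
            "strength": self.strength,
            "overrides": [list(o) for o in self.overrides],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        return cls(
            lights_on=d.get("lights_on", 7.0),
            lights_off=d.get("lights_off", 21.0),
            period=d.get("period", 24.0),
            overrides=tuple(tuple(o) for o in d.get("overrides", ())),
            strength=d.get("strength", 1.0),
        )


def default_parameters() -> ModelParameters:
    """Repository-default parameter set (see ``data/default_params.yaml``).

    These values are repository defaults chosen so that the light-entrained
    system oscillates with a 24 h period, the free-running (constant-dark)
    period is close to but distinct from 24 h, corticosterone peaks near the
    light/dark transition (nocturnal phasing), and the photic pathway delays
    light onset effects by 1-2 h.
    """
    ref = importlib.resources.files("hpacirc.data") / "default_params.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_parameters(path)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a flat YAML mapping of parameter fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = dict(raw.get("parameters", raw))
    raw.pop("schedule", None)
    return ModelParameters(**{k: float(v) for k, v in raw.items()})


def save_parameters(
    p: ModelParameters, path: str | Path, schedule: LightSchedule | None = None
) -> None:
    doc: dict = {"parameters": p.to_dict()}
    if schedule is not None:
        doc["schedule"] = schedule.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
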