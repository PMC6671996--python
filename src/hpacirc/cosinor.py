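"""Single-component cosinor rhythmometry and the calibration acceptance test.

A cosinor fit summarizes a periodic trace by three parameters: the mesor
(rhythm-adjusted mean), the amplitude, and the acrophase (clock time of the
fitted peak).  Fitting uses the standard linear reparameterization

    y(t) = M + beta * cos(2*pi*t/P) + gamma * sin(2*pi*t/P)

solved by ordinary least squares, then back-transformed to (M, A, phi) with
A = sqrt(beta^2 + gamma^2) >= 0 and phi normalized to [0, P).  A simulated
parameter set is accepted when its fitted cosinor lies within +/-1 standard
deviation of the target on all three parameters, with the acrophase
compared circularly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateFit

__all__ = [
    "CosinorFit",
    "CalibrationTarget",
    "fit_cosinor",
    "passes_calibration",
    "circular_distance",
]


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # clock h in [0, period)
    period: float = 24.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not 0 <= self.acrophase < self.period:
            raise ValueError("acrophase must lie in [0, period)")

    def predict(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the fitted cosine at the given times."""
        t = np.asarray(times, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.acrophase) / self.period
        )


@dataclass(frozen=True)
class CalibrationTarget:
    """Target cosinor parameters with their +/-1 SD acceptance half-widths."""

    target: CosinorFit
    sd_mesor: float
    sd_amplitude: float
    sd_acrophase: float

    def __post_init__(self) -> None:
        if min(self.sd_mesor, self.sd_amplitude, self.sd_acrophase) <= 0:
            raise ValueError("all standard deviations must be positive")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "target": {
                "mesor": float(self.target.mesor),
                "amplitude": float(self.target.amplitude),
                "acrophase": float(self.target.acrophase),
                "period": float(self.target.period),
            },
            "sd": {
                "mesor": float(self.sd_mesor),
                "amplitude": float(self.sd_amplitude),
                "acrophase": float(self.sd_acrophase),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationTarget":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            target=CosinorFit(**{k: float(v) for k, v in doc["target"].items()}),
            sd_mesor=float(doc["sd"]["mesor"]),
            sd_amplitude=float(doc["sd"]["amplitude"]),
            sd_acrophase=float(doc["sd"]["acrophase"]),
        )


def fit_cosinor(
    times: np.ndarray, values: np.ndarray, period: float = 24.0
) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period.

    Requires at least 4 samples spanning at least one period.  Raises
    :class:`DegenerateFit` when the design matrix is rank-deficient (e.g.
    sampling aliased to exactly one sample per period).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(t) < 4:
        raise DegenerateFit("need at least 4 samples")
    # one period sampled hourly spans period - interval; accept that too
    if float(np.ptp(t)) < 0.75 * period:
        raise DegenerateFit("samples must span at least one period")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateFit("design matrix is rank-deficient (aliased sampling)")
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = float(np.hypot(beta, gamma))
    # y = M + A*cos(w*(t - phi)) with  A*cos(w*phi) = beta, A*sin(w*phi) = gamma
    acrophase = float((np.arctan2(gamma, beta) / w) % period)
    if acrophase >= period:  # float mod can round up to the period itself
        acrophase -= period
    if amplitude == 0.0:
        acrophase = 0.0
    return CosinorFit(mesor=mesor, amplitude=amplitude, acrophase=acrophase, period=period)


def circular_distance(a: float, b: float, period: float = 24.0) -> float:
    """Shortest distance between two clock times on a circle of given period."""
    d = abs(a - b) % period
    return min(d, period - d)


def passes_calibration(fit: CosinorFit, target: CalibrationTarget) -> bool:
    """True iff all three cosinor parameters lie within +/-1 SD of the target.

    The acrophase deviation is circular (minimum over the wrap-around).
    """
    t = target.target
    return (
        abs(fit.mesor - t.mesor) <= target.sd_mesor
        and abs(fit.amplitude - t.amplitude) <= target.sd_amplitude
        and circular_distance(fit.acrophase, t.acrophase, t.period)
        <= target.sd_acrophase
    )
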