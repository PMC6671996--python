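"""End-to-end study orchestration.

Runs the full pipeline from a single seed and configuration: synthetic
calibration target -> three stress-condition subspaces -> acute-stress
responses with symbolic partitioning -> light-schedule perturbation
protocols -> Arnold tongues on representative triples -> Floquet exponents
and their regression on the regulatory parameters -> a summary of the
qualitative trend findings.  Stage failures are isolated: downstream stages
that depend on a failed stage are skipped with the cause recorded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosinor import CalibrationTarget
from .entrainment import arnold_tongue
from .errors import InsufficientPoints, NoResync
from .floquet import floquet_exponents, regress_exponent_on_params
from .params import LightSchedule, ModelParameters, default_parameters
from .protocols import (
    AcuteStressor,
    acute_stress_response,
    resynchronization_time,
    symbolize,
    transient_inversion_phase_shift,
)
from .subspace import (
    AcceptedSubspace,
    SamplingBox,
    compare_conditions,
    sample_subspace,
    stress_conditions,
)
from .synthetic import SyntheticTargetSpec, make_calibration_target

__all__ = ["RunConfig", "run_study", "select_representative_triples"]


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for a study run."""

    seed: int = 0
    params: ModelParameters = field(default_factory=default_parameters)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    intermediate_factor: float = 1.5
    high_factor: float = 2.0
    box: SamplingBox = field(default_factory=SamplingBox)
    n_samples: int = 2000
    stress_onset: float = 14.0  # mid lights-on: middle of the inactive phase
    stress_fold: float = 5.0
    stress_duration: float = 1.0
    tongue_periods: tuple[float, ...] = tuple(np.arange(20.0, 28.01, 1.0))
    tongue_strengths: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0)
    n_representative: int = 9
    max_protocol_triples: int = 12
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 1.0 < self.intermediate_factor < self.high_factor:
            raise ValueError(
                "need 1 < intermediate_factor < high_factor "
                f"(got {self.intermediate_factor}, {self.high_factor})"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.tongue_periods) < 2 or len(self.tongue_strengths) < 2:
            raise ValueError("tongue grids need at least 2 points per axis")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "params": self.params.to_dict(),
            "schedule": self.schedule.to_dict(),
            "intermediate_factor": self.intermediate_factor,
            "high_factor": self.high_factor,
            "box": asdict(self.box),
            "n_samples": self.n_samples,
            "stress_onset": self.stress_onset,
            "stress_fold": self.stress_fold,
            "stress_duration": self.stress_duration,
            "tongue_periods": list(self.tongue_periods),
            "tongue_strengths": list(self.tongue_strengths),
            "n_representative": self.n_representative,
            "max_protocol_triples": self.max_protocol_triples,
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def select_representative_triples(
    sub: AcceptedSubspace,
    k_p3_levels: int = 3,
    per_level: int = 3,
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
) -> np.ndarray:
    """Pick ``k_p3_levels x per_level`` triples spanning the subspace.

    Three adrenal-sensitivity levels are taken at the given k_p3 quantiles;
    at each level the nearest accepted triples (by k_p3) are gathered and
    the ones spanning the (K_p1, K_p2) extent are kept: the minimum, median
    and maximum along the K_p1 ordering.  Duplicated triples are removed
    before selection; the result is deterministic.
    """
    if len(quantiles) != k_p3_levels:
        raise ValueError("need one quantile per k_p3 level")
    triples = np.unique(np.asarray(sub.triples, dtype=float), axis=0)
    need = k_p3_levels * per_level
    if len(triples) < need:
        raise InsufficientPoints(
            f"need at least {need} distinct accepted triples, have {len(triples)}"
        )
    qvals = np.quantile(triples[:, 2], quantiles)
    used = np.zeros(len(triples), dtype=bool)
    out = []
    for q in qvals:
        order = np.argsort(np.abs(triples[:, 2] - q) + 1e12 * used)
        pool = order[: max(per_level, min(2 * per_level + 1, (~used).sum()))]
        pool = [i for i in pool if not used[i]][: 2 * per_level + 1]
        pool = sorted(pool, key=lambda i: triples[i, 0])  # order along K_p1
        if len(pool) <= per_level:
            chosen = pool
        else:
            chosen = [pool[0], pool[len(pool) // 2], pool[-1]]
            k = 1
            while len(chosen) < per_level:  # per_level > 3: fill inward
                if pool[k] not in chosen:
                    chosen.append(pool[k])
                k += 1
        for i in chosen:
            used[i] = True
            out.append(triples[i])
    return np.array(out)


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# "
            + ", ".join(f"{k}={v}" for k, v in meta.items())
            + "\n"
        )
        df.to_csv(fh, index=False)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) a report."""
    meta = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
    }
    report: dict = {"meta": meta, "stages": {}, "errors": {}}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump({**config.to_dict(), "meta": meta}, fh, sort_keys=False)

    # --- stage 1: synthetic calibration target ---------------------------
    spec = SyntheticTargetSpec(
        params=config.params, schedule=config.schedule, seed=config.seed
    )
    target = make_calibration_target(spec)
    report["stages"]["target"] = {
        "mesor": target.target.mesor,
        "amplitude": target.target.amplitude,
        "acrophase": target.target.acrophase,
    }
    if out_dir:
        target.to_yaml(out_dir / "target.yaml")

    # --- stage 2: subspaces ----------------------------------------------
    conditions = stress_conditions(
        config.params, config.intermediate_factor, config.high_factor
    )
    subs: dict[str, AcceptedSubspace] = {}
    for cond in conditions:
        sub = sample_subspace(
            cond,
            target,
            config.params,
            schedule=config.schedule,
            box=config.box,
            n_samples=config.n_samples,
            seed=config.seed,
        )
        subs[cond.label] = sub
        if out_dir:
            _write_csv(sub.table, out_dir / f"subspace_{cond.label}.csv", meta)
    try:
        comparison = compare_conditions(
            subs["nominal"], subs["intermediate"], subs["high"]
        )
        report["stages"]["subspaces"] = comparison
    except ValueError as exc:
        report["errors"]["subspaces"] = str(exc)
        comparison = None

    # --- stage 3: acute stress + symbolization ---------------------------
    stressor = AcuteStressor(
        onset=config.stress_onset,
        duration=config.stress_duration,
        fold_increase=config.stress_fold,
    )
    try:
        rows = []
        for label, sub in subs.items():
            cond_p = sub.condition.apply(config.params)
            for triple in sub.triples[: config.max_protocol_triples]:
                d_auc = acute_stress_response(
                    cond_p.with_triple(*triple), stressor, config.schedule
                )
                rows.append(
                    {
                        "condition": label,
                        "K_p1": triple[0],
                        "K_p2": triple[1],
                        "k_p3": triple[2],
                        "delta_auc": d_auc,
                    }
                )
        acute = pd.DataFrame(rows)
        z, sym = symbolize(acute["delta_auc"].to_numpy())
        acute["z"] = z
        acute["symbol"] = sym
        report["stages"]["acute_stress"] = {
            "n": len(acute),
            "mean_delta_auc": {
                label: float(acute.loc[acute.condition == label, "delta_auc"].mean())
                for label in subs
            },
        }
        if out_dir:
            _write_csv(acute, out_dir / "acute_stress.csv", meta)
    except Exception as exc:  # stage isolation
        report["errors"]["acute_stress"] = str(exc)

    # --- stage 4: schedule perturbations (nominal subspace) --------------
    try:
        rows = []
        for triple in subs["nominal"].triples[: config.max_protocol_triples]:
            p = config.params.with_triple(*triple)
            shift = transient_inversion_phase_shift(p, config.schedule)
            try:
                resync = resynchronization_time(p, config.schedule)
            except NoResync:
                resync = np.nan
            rows.append(
                {
                    "K_p1": triple[0],
                    "K_p2": triple[1],
                    "k_p3": triple[2],
                    "max_phase_shift": shift,
                    "resync_days": resync,
                }
            )
        sched_df = pd.DataFrame(rows)
        report["stages"]["schedule_perturbations"] = {
            "n": len(sched_df),
            "mean_max_phase_shift": float(sched_df.max_phase_shift.mean()),
            "median_resync_days": float(np.nanmedian(sched_df.resync_days)),
        }
        if out_dir:
            _write_csv(sched_df, out_dir / "schedule_perturbations.csv", meta)
    except Exception as exc:
        report["errors"]["schedule_perturbations"] = str(exc)

    # --- stage 5: tongues + Floquet on representative triples ------------
    try:
        period_grid = np.array(config.tongue_periods)
        strength_grid = np.array(config.tongue_strengths)
        rows = []
        flo_rows = []
        for label, sub in subs.items():
            try:
                reps = select_representative_triples(
                    sub, per_level=config.n_representative // 3
                )
            except InsufficientPoints as exc:
                report["errors"][f"representative_{label}"] = str(exc)
                continue
            for triple in reps:
                p = sub.condition.apply(config.params).with_triple(*triple)
                tg = arnold_tongue(p, period_grid, strength_grid, config.schedule)
                rows.append(
                    {
                        "condition": label,
                        "K_p1": triple[0],
                        "K_p2": triple[1],
                        "k_p3": triple[2],
                        "tongue_area": tg.area(),
                        "intrinsic_period": tg.intrinsic_period,
                        "intrinsic_amplitude": tg.intrinsic_amplitude,
                    }
                )
                flo = floquet_exponents(p, config.schedule)
                flo_rows.append(
                    {
                        "condition": label,
                        "K_p1": triple[0],
                        "K_p2": triple[1],
                        "k_p3": triple[2],
                        "leading_exponent": flo.leading_exponent,
                    }
                )
        tongues = pd.DataFrame(rows)
        floquet_df = pd.DataFrame(flo_rows)
        report["stages"]["tongues"] = {
            "n": len(tongues),
            "mean_area": {
                label: float(tongues.loc[tongues.condition == label, "tongue_area"].mean())
                for label in tongues.condition.unique()
            },
        }
        if out_dir:
            _write_csv(tongues, out_dir / "tongues.csv", meta)
            _write_csv(floquet_df, out_dir / "floquet.csv", meta)

        regs = {}
        for label in floquet_df.condition.unique():
            sel = floquet_df[floquet_df.condition == label]
            if len(sel) >= 5:
                fit = regress_exponent_on_params(
                    sel[["K_p1", "K_p2", "k_p3"]].to_numpy(),
                    sel["leading_exponent"].to_numpy(),
                )
                regs[label] = {
                    "coefficients": fit.coefficients.tolist(),
                    "r_squared": fit.r_squared,
                }
        report["stages"]["floquet_regression"] = regs
    except Exception as exc:
        report["errors"]["tongues_floquet"] = str(exc)

    if out_dir:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
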