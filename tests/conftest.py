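"""Shared fixtures.

Heavy artifacts (calibration target, accepted subspaces over several seeds)
are session-scoped and shared between the unit suite and the acceptance
suite, so each expensive sampling run happens exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import hpacirc as h

#: Sample count per subspace sampling run.  Scaled so the whole suite,
#: including the multi-seed trend analyses, fits comfortably in a single
#: CPU test session; the sampling acceptance fraction is ~1-2%, giving
#: roughly 15-40 accepted triples per condition per seed.
N_SAMPLES = 2048

#: Seeds used for the multi-seed trend suite.
TREND_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def params() -> h.ModelParameters:
    return h.default_parameters()


@pytest.fixture(scope="session")
def schedule() -> h.LightSchedule:
    return h.LightSchedule()


@pytest.fixture(scope="session")
def dark_schedule() -> h.LightSchedule:
    return h.LightSchedule(strength=0.0)


@pytest.fixture(scope="session")
def target(params, schedule) -> h.CalibrationTarget:
    """Zero-noise synthetic calibration target from the default triple."""
    spec = h.SyntheticTargetSpec(params=params, schedule=schedule)
    return h.make_calibration_target(spec)


@pytest.fixture(scope="session")
def entrained_cycle(params, schedule):
    return h.integrate_to_limit_cycle(params, schedule, transient_days=40)


@pytest.fixture(scope="session")
def conditions(params):
    return h.stress_conditions(params)


@pytest.fixture(scope="session")
def subspaces_by_seed(params, schedule, target, conditions):
    """dict[(label, seed)] -> AcceptedSubspace over the trend seeds."""
    out = {}
    for seed in TREND_SEEDS:
        for cond in conditions:
            out[(cond.label, seed)] = h.sample_subspace(
                cond,
                target,
                params,
                schedule=schedule,
                n_samples=N_SAMPLES,
                seed=seed,
            )
    return out


@pytest.fixture(scope="session")
def nominal_subspace(subspaces_by_seed):
    """The largest nominal accepted set among the trend seeds."""
    best = None
    for (label, _seed), sub in subspaces_by_seed.items():
        if label == "nominal" and (best is None or len(sub) > len(best)):
            best = sub
    return best


def pooled_triples(subspaces_by_seed, label: str) -> np.ndarray:
    """All accepted triples for a condition pooled over the trend seeds."""
    parts = [
        sub.triples
        for (lab, _), sub in subspaces_by_seed.items()
        if lab == label and len(sub)
    ]
    if not parts:
        return np.empty((0, 3))
    return np.unique(np.concatenate(parts, axis=0), axis=0)
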