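"""Conditioned-place-preference (CPP) session simulation.

Emulates a 15-day two-sided CPP protocol with 30-min (1800 s) sessions:
initial preference assessment on day 1, two 4-day training blocks in which
drug (methamphetamine, MA) and saline (SAL) injections alternate between
the two contexts (D2-D5 and D9-D12, MA on D2/D4/D9/D11), rest days on
D6-D7 and D13-D14, and drug-free preference tests on D8 and D15. Time on
the drug-paired side is recorded only on test days (D1, D8, D15); total
distance traveled is recorded on every session day.

The generative model: each animal has a baseline bias *against* the
drug-paired side (a 2-6% fraction of session time, mirroring the
apparatus), a latent heritable *reward* trait that scales its conditioning
gain (applied equally on D8 and D15 — preference is maximal after the
first training block), and a latent heritable *activity* trait that drives
distances, with a multiplicative MA effect, optional sensitization across
MA exposures and habituation across drug-free exposures. An all-SAL
control schedule produces no conditioning gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .kinship import kinship_matrix
from .pedigree import Pedigree
from .simulate import GeneticParams, simulate_additive_phenotypes

__all__ = [
    "CPPDesign",
    "InvalidScheduleError",
    "PROTOCOL_SCHEDULE",
    "ALL_SAL_SCHEDULE",
    "TEST_DAYS",
    "MA_DAYS",
    "SAL_TRAINING_DAYS",
    "REST_DAYS",
    "simulate_cpp_sessions",
    "read_sessions_csv",
    "write_sessions_csv",
]

TEST_DAYS = (1, 8, 15)
MA_DAYS = (2, 4, 9, 11)
SAL_TRAINING_DAYS = (3, 5, 10, 12)
REST_DAYS = (6, 7, 13, 14)

#: canonical day -> treatment map (test days carry a SAL injection)
PROTOCOL_SCHEDULE: Mapping[int, str] = MappingProxyType(
    {
        d: ("MA" if d in MA_DAYS else "none" if d in REST_DAYS else "SAL")
        for d in range(1, 16)
    }
)

#: zero-effect control: both contexts paired with SAL
ALL_SAL_SCHEDULE: Mapping[int, str] = MappingProxyType(
    {d: ("none" if d in REST_DAYS else "SAL") for d in range(1, 16)}
)

SESSION_COLUMNS = [
    "animal_id",
    "family_id",
    "role",
    "generation",
    "sex",
    "day",
    "treatment",
    "time_drug_side",
    "distance",
]


class InvalidScheduleError(ValueError):
    """The day -> treatment map does not match the protocol pattern."""


def _validate_schedule(schedule: Mapping[int, str]) -> bool:
    """Return True when the schedule is the all-SAL control variant."""
    if sorted(schedule) != list(range(1, 16)):
        raise InvalidScheduleError("schedule must cover days 1-15")
    for d in REST_DAYS:
        if schedule[d] != "none":
            raise InvalidScheduleError(f"day {d} must be a rest day ('none')")
    for d in TEST_DAYS + SAL_TRAINING_DAYS:
        if schedule[d] != "SAL":
            raise InvalidScheduleError(f"day {d} must carry SAL treatment")
    ma = {schedule[d] for d in MA_DAYS}
    if ma == {"MA"}:
        return False
    if ma == {"SAL"}:
        return True
    raise InvalidScheduleError(
        "days 2/4/9/11 must be uniformly MA (protocol) or SAL (control)"
    )


@dataclass(frozen=True)
class CPPDesign:
    """Protocol layout and calibration of the session generator.

    All times are seconds within a ``session_length`` of 1800 s; distances
    are centimeters. ``initial_bias`` is the (low, high) range of the
    per-animal initial deficit for the drug-paired side as a fraction of
    session time; ``cpp_gain_mean``/``cpp_gain_sd`` place the conditioning
    gain in the 100-250 s range observed for this protocol.
    """

    session_length: float = 1800.0
    schedule: Mapping[int, str] = field(default_factory=lambda: dict(PROTOCOL_SCHEDULE))
    initial_bias: tuple[float, float] = (0.02, 0.06)
    cpp_gain_mean: float = 175.0
    cpp_gain_sd: float = 50.0
    pref_noise_sd: float = 100.0
    n_families: int = 10
    offspring_range: tuple[int, int] = (4, 11)
    baseline_distance_mean: float = 4000.0
    baseline_distance_sd: float = 800.0
    ma_multiplier: float = 2.0
    sensitization: float = 0.05
    habituation: float = 0.05
    distance_noise_sd: float = 400.0

    def __post_init__(self) -> None:
        lo, hi = self.initial_bias
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("initial_bias range must lie within [0, 0.5]")
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        for name in ("cpp_gain_sd", "pref_noise_sd", "distance_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        _validate_schedule(self.schedule)

    @property
    def is_control(self) -> bool:
        return _validate_schedule(self.schedule)

    @property
    def session_days(self) -> tuple[int, ...]:
        return tuple(d for d in range(1, 16) if self.schedule[d] != "none")


def simulate_cpp_sessions(
    design: CPPDesign,
    reward_params: GeneticParams,
    activity_params: GeneticParams,
    ped: Pedigree,
    cohort: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a long-format session table for a phenotyped cohort.

    ``cohort`` is the table produced by
    :func:`cppherit.ail.sample_study_cohort`; every ``animal_id`` must be
    present in ``ped`` (the latent reward and activity traits are drawn
    jointly over the cohort with covariance proportional to 2Phi).
    Deterministic given ``seed``: same seed, bit-identical table.
    """
    ids = cohort["animal_id"].tolist()
    for i in ids:
        ped[i]  # raises UnknownIdError if the cohort is not in the pedigree
    n = len(ids)
    ss = np.random.SeedSequence(seed)
    seed_reward, seed_activity, seed_noise = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    K = kinship_matrix(ped, ids)

    def standardized(params: GeneticParams, s: int) -> np.ndarray:
        y = simulate_additive_phenotypes(ped, ids, params, seed=s, kinship=K)
        return (y.to_numpy() - params.mu) / np.sqrt(params.var_total)

    z_reward = standardized(reward_params, seed_reward)
    z_activity = standardized(activity_params, seed_activity)

    rng = np.random.default_rng(seed_noise)
    lo, hi = design.initial_bias
    bias = rng.uniform(lo, hi, n)
    baseline_pref = design.session_length * (0.5 - bias)
    if design.is_control:
        gain = np.zeros(n)
    else:
        gain = np.clip(design.cpp_gain_mean + design.cpp_gain_sd * z_reward, 0.0, None)
    base_act = np.clip(
        design.baseline_distance_mean + design.baseline_distance_sd * z_activity,
        1.0,
        None,
    )

    records = []
    n_ma_prior = 0
    n_drugfree_prior = 0
    for day in design.session_days:
        treatment = design.schedule[day]
        is_ma = treatment == "MA"
        if is_ma:
            act = (
                base_act
                * design.ma_multiplier
                * (1.0 + design.sensitization) ** n_ma_prior
            )
            n_ma_prior += 1
        else:
            act = base_act * (1.0 - design.habituation) ** n_drugfree_prior
            n_drugfree_prior += 1
        distance = np.clip(act + rng.normal(0.0, design.distance_noise_sd, n), 0.0, None)
        if day in TEST_DAYS:
            expected = baseline_pref + (gain if day in (8, 15) else 0.0)
            time = np.clip(
                expected + rng.normal(0.0, design.pref_noise_sd, n),
                0.0,
                design.session_length,
            )
        else:
            time = np.full(n, np.nan)
        records.append(
            pd.DataFrame(
                {
                    "animal_id": ids,
                    "family_id": cohort["family_id"].to_numpy(),
                    "role": cohort["role"].to_numpy(),
                    "generation": cohort["generation"].to_numpy(),
                    "sex": cohort["sex"].to_numpy(),
                    "day": day,
                    "treatment": treatment,
                    "time_drug_side": time,
                    "distance": distance,
                }
            )
        )
    return pd.concat(records, ignore_index=True)[SESSION_COLUMNS]


def write_sessions_csv(sessions: pd.DataFrame, path) -> None:
    sessions.to_csv(path, index=False)


def read_sessions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "family_id": str})
    missing = set(SESSION_COLUMNS) - set(df.columns) - {"role"}
    if missing:
        raise ValueError(f"session table missing columns: {sorted(missing)}")
    return df
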