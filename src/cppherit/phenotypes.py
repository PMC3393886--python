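"""Derive per-animal CPP and locomotor traits from session records.

Traits (one row per animal):

* ``D1_pref`` — time on the drug-paired side on day 1 (s), initial preference;
* ``D8_CPP``, ``D15_CPP`` — time on the drug-paired side on the test days (s);
* ``D8_minus_D1`` — the conditioning contrast ``D8_CPP - D1_pref`` (s);
* ``D1_ACT``, ``D8_ACT`` — distance traveled on days 1 and 8 (cm);
* ``MA_ACT`` — mean distance over the first two drug training days D2, D4 (cm);
* ``SAL_ACT`` — mean distance over the first two saline training days D3, D5 (cm).

Only measures from the first training block (D1-D8) feed the correlation
and heritability analyses; D15 is retained because preference does not
increase further after D8.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .cpp import MA_DAYS, SAL_TRAINING_DAYS, TEST_DAYS

__all__ = [
    "TRAITS",
    "TRAIT_LABELS",
    "DuplicateRecordError",
    "MalformedScheduleError",
    "derive_phenotypes",
]

TRAITS = [
    "D1_pref",
    "D8_CPP",
    "D15_CPP",
    "D8_minus_D1",
    "D1_ACT",
    "D8_ACT",
    "MA_ACT",
    "SAL_ACT",
]

#: canonical printed labels for reports
TRAIT_LABELS = {
    "D1_pref": "D1 preference (s)",
    "D8_CPP": "D8 CPP (s)",
    "D15_CPP": "D15 CPP (s)",
    "D8_minus_D1": "D8-D1 CPP (s)",
    "D1_ACT": "D1 ACT (cm)",
    "D8_ACT": "D8 ACT (cm)",
    "MA_ACT": "MA-ACT (cm)",
    "SAL_ACT": "SAL-ACT (cm)",
}

REQUIRED_DAYS = (1, 2, 3, 4, 5, 8, 15)


class DuplicateRecordError(ValueError):
    """More than one record for the same (animal, day)."""


class MalformedScheduleError(ValueError):
    """Session treatments do not follow the protocol (or control) pattern."""


def derive_phenotypes(sessions: pd.DataFrame) -> pd.DataFrame:
    """One row of derived traits per animal.

    Animals missing any of the required days (1-5, 8, 15) are excluded
    with a warning naming them. Input row order does not matter.
    """
    df = sessions.copy()
    dup = df.duplicated(subset=["animal_id", "day"])
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "day"]].to_records(index=False).tolist()
        raise DuplicateRecordError(f"duplicate (animal, day) records: {pairs[:5]}")
    _check_treatments(df)

    time = df.pivot(index="animal_id", columns="day", values="time_drug_side")
    dist = df.pivot(index="animal_id", columns="day", values="distance")
    have = [d for d in REQUIRED_DAYS if d in time.columns or d in dist.columns]
    complete = pd.Series(True, index=time.index)
    for d in REQUIRED_DAYS:
        if d in TEST_DAYS:
            complete &= d in time.columns and time[d].notna()
        else:
            complete &= d in dist.columns and dist[d].notna()
    excluded = sorted(complete.index[~complete])
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} animal(s) with missing required days: "
            f"{excluded[:10]}",
            stacklevel=2,
        )
    keep = complete.index[complete]
    if len(keep) == 0:
        raise MalformedScheduleError(
            f"no animal has all required days {REQUIRED_DAYS}; days present: {have}"
        )

    meta_cols = [c for c in ("family_id", "role", "generation", "sex") if c in df.columns]
    meta = df.sort_values("day").groupby("animal_id")[meta_cols].first()

    out = pd.DataFrame(index=keep)
    out["D1_pref"] = time.loc[keep, 1]
    out["D8_CPP"] = time.loc[keep, 8]
    out["D15_CPP"] = time.loc[keep, 15]
    out["D8_minus_D1"] = out["D8_CPP"] - out["D1_pref"]
    out["D1_ACT"] = dist.loc[keep, 1]
    out["D8_ACT"] = dist.loc[keep, 8]
    out["MA_ACT"] = dist.loc[keep, [2, 4]].mean(axis=1)
    out["SAL_ACT"] = dist.loc[keep, [3, 5]].mean(axis=1)
    out = meta.loc[keep].join(out)
    out.index.name = "animal_id"
    return out.reset_index()


def _check_treatments(df: pd.DataFrame) -> None:
    by_day = df.groupby("day")["treatment"].agg(set)
    for d in TEST_DAYS + SAL_TRAINING_DAYS:
        if d in by_day.index and by_day[d] - {"SAL"}:
            raise MalformedScheduleError(f"day {d} must be SAL, got {by_day[d]}")
    ma = set().union(*(by_day[d] for d in MA_DAYS if d in by_day.index)) or {"MA"}
    if ma not in ({"MA"}, {"SAL"}):
        raise MalformedScheduleError(
            f"training days {MA_DAYS} must be uniformly MA or SAL, got {ma}"
        )
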