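"""Pedigree data model, validation, and delimited-file I/O.

A pedigree is a directed acyclic graph over individuals: each individual
either has both parents recorded (and both must appear in the pedigree at a
strictly earlier generation) or is a founder with no recorded parents.
Founders of a fully inbred laboratory strain are flagged ``founder_inbred``,
which makes their inbreeding coefficient 1 and their self-kinship 1.

File dialect: delimited text (comma or tab) with a header naming at least
``id``, ``sire``, ``dam``, ``sex`` and ``generation``; an optional
``founder_inbred`` column marks inbred founders. A missing parent is coded
``0`` or ``NA`` on read and written back as ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "DuplicateIdError",
    "UnknownParentError",
    "HalfParentError",
    "PedigreeCycleError",
    "GenerationOrderError",
    "UnknownIdError",
    "read_pedigree",
    "write_pedigree",
]

#: tokens accepted as "no parent recorded" on file read
MISSING_PARENT_TOKENS = {"0", "NA", "na", "", "nan", "NaN", "None", "none"}

SEXES = ("female", "male", "unknown")


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeError):
    """The same individual id appears more than once."""


class UnknownParentError(PedigreeError):
    """A record names a parent id that is absent from the pedigree."""


class HalfParentError(PedigreeError):
    """Exactly one parent is recorded; records need both parents or neither."""


class PedigreeCycleError(PedigreeError):
    """The parent graph contains a cycle (an individual is its own ancestor)."""


class GenerationOrderError(PedigreeError):
    """A parent's generation label is not strictly smaller than its child's."""


class UnknownIdError(PedigreeError):
    """A requested individual id is not in the pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record.

    Parameters
    ----------
    id : str
        Unique identifier.
    sire, dam : str or None
        Parent ids; both present or both ``None`` (founder).
    sex : {"female", "male", "unknown"}
    generation : int
        Non-negative generation index; founders are conventionally 0.
    founder_inbred : bool
        True for a founder drawn from a fully inbred strain (F = 1).
    """

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"
    generation: int = 0
    founder_inbred: bool = False

    def __post_init__(self) -> None:
        if (self.sire is None) != (self.dam is None):
            raise HalfParentError(
                f"individual {self.id!r}: sire and dam must both be present or both missing"
            )
        if self.sex not in SEXES:
            raise PedigreeError(f"individual {self.id!r}: invalid sex {self.sex!r}")
        if self.generation < 0:
            raise PedigreeError(f"individual {self.id!r}: negative generation")
        if self.founder_inbred and not self.is_founder:
            raise PedigreeError(
                f"individual {self.id!r}: founder_inbred set on a non-founder"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire is None


class Pedigree:
    """Validated, ordered collection of :class:`Individual`.

    Construction checks id uniqueness, referential integrity of parent ids,
    acyclicity of the parent graph, and that parents carry strictly smaller
    generation labels than their offspring. Input row order is preserved.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise DuplicateIdError(f"duplicate id {ind.id!r}")
            members[ind.id] = ind
        for ind in members.values():
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in members:
                    raise UnknownParentError(
                        f"individual {ind.id!r} references unknown parent {parent!r}"
                    )
        self._members = members
        self._check_acyclic()
        for ind in members.values():
            if ind.is_founder:
                continue
            for parent in (ind.sire, ind.dam):
                if members[parent].generation >= ind.generation:
                    raise GenerationOrderError(
                        f"parent {parent!r} (generation "
                        f"{members[parent].generation}) not older than child "
                        f"{ind.id!r} (generation {ind.generation})"
                    )

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on parent -> child edges
        children: dict[str, list[str]] = {i: [] for i in self._members}
        indeg: dict[str, int] = {}
        for ind in self._members.values():
            parents = {p for p in (ind.sire, ind.dam) if p is not None}
            indeg[ind.id] = len(parents)
            for p in parents:
                children[p].append(ind.id)
        queue = [i for i, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self._members):
            raise PedigreeCycleError("cycle detected in pedigree parent graph")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, id: object) -> bool:
        return id in self._members

    def __getitem__(self, id: str) -> Individual:
        try:
            return self._members[id]
        except KeyError:
            raise UnknownIdError(f"unknown individual id {id!r}") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    @property
    def founder_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self if i.is_founder)

    @property
    def max_generation(self) -> int:
        return max(i.generation for i in self)

    def generation_ids(self, generation: int) -> tuple[str, ...]:
        return tuple(i.id for i in self if i.generation == generation)

    # -- graph helpers ------------------------------------------------------

    def topological_ids(self) -> list[str]:
        """Ids sorted so that every parent precedes all its offspring.

        Ordering is by generation, then id, which is deterministic and valid
        because parents have strictly smaller generation labels.
        """
        return sorted(self._members, key=lambda i: (self._members[i].generation, i))

    def ancestor_closure(self, ids: Sequence[str]) -> list[str]:
        """All ancestors of ``ids`` (inclusive), in topological order."""
        keep: set[str] = set()
        stack = list(ids)
        while stack:
            i = stack.pop()
            if i in keep:
                continue
            ind = self[i]
            keep.add(i)
            if not ind.is_founder:
                stack.extend((ind.sire, ind.dam))
        return [i for i in self.topological_ids() if i in keep]

    def subset(self, ids: Sequence[str], include_ancestors: bool = True) -> "Pedigree":
        """Restriction to ``ids`` (by default with all their ancestors)."""
        keep = self.ancestor_closure(ids) if include_ancestors else list(ids)
        keep_set = set(keep)
        out = []
        for i in self:
            if i.id not in keep_set:
                continue
            if not include_ancestors and (i.sire not in keep_set or i.dam not in keep_set):
                # drop dangling parent references when ancestors are excluded
                i = Individual(i.id, None, None, i.sex, i.generation, i.founder_inbred)
            out.append(i)
        return Pedigree(out)

    def extended(self, new_individuals: Iterable[Individual]) -> "Pedigree":
        """A new pedigree with extra individuals appended (re-validated)."""
        return Pedigree(list(self) + list(new_individuals))

    # -- tabular conversion -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self],
                "sire": [i.sire for i in self],
                "dam": [i.dam for i in self],
                "sex": [i.sex for i in self],
                "generation": [i.generation for i in self],
                "founder_inbred": [i.founder_inbred for i in self],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        required = {"id", "sire", "dam", "sex", "generation"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        have_fi = "founder_inbred" in df.columns
        inds = []
        for row in df.itertuples(index=False):
            sire = _parse_parent(row.sire)
            dam = _parse_parent(row.dam)
            fi = _parse_bool(getattr(row, "founder_inbred")) if have_fi else False
            inds.append(
                Individual(
                    id=str(row.id).strip(),
                    sire=sire,
                    dam=dam,
                    sex=_parse_sex(row.sex),
                    generation=int(row.generation),
                    founder_inbred=fi,
                )
            )
        return cls(inds)

    def __repr__(self) -> str:
        return (
            f"<Pedigree of {len(self)} individuals, "
            f"generations 0..{self.max_generation}>"
        )


def _parse_parent(token: object) -> str | None:
    s = str(token).strip()
    return None if s in MISSING_PARENT_TOKENS else s


def _parse_sex(token: object) -> str:
    s = str(token).strip().lower()
    if s in ("f", "female", "2"):
        return "female"
    if s in ("m", "male", "1"):
        return "male"
    return "unknown"


def _parse_bool(token: object) -> bool:
    return str(token).strip().lower() in ("1", "true", "t", "yes")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree from delimited text (comma or tab, sniffed).

    The header must name ``id, sire, dam, sex, generation`` (any order,
    extra columns ignored except an optional ``founder_inbred``). Rows may
    list children before parents. Missing parents are coded ``0`` or ``NA``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path: str | Path, sep: str = ",") -> None:
    """Write a pedigree as delimited text; missing parents coded ``0``."""
    df = ped.to_frame()
    df["sire"] = df["sire"].fillna("0")
    df["dam"] = df["dam"].fillna("0")
    df["founder_inbred"] = df["founder_inbred"].astype(int)
    df.to_csv(path, sep=sep, index=False)
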