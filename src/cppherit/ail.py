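"""Advanced intercross line (AIL) breeding-scheme simulation.

An AIL starts from two fully inbred founder strains. The F1 generation is
produced by crossing the strains; every later generation is produced by
intercrossing the previous one while avoiding matings between close
relatives, which slows drift and accumulates recombinations for fine
mapping. Here the historical "systematic manner to minimize relatedness"
is operationalized as greedy minimum-kinship pairing: breeding pairs are
chosen in increasing order of pairwise kinship, full-sib matings are
forbidden (except for the unavoidable F1 x F1 cross, since all F1s share
the same two founder parents), and ties are broken by seeded randomness.

Kinship needed for pairing is propagated generation-to-generation, so the
simulator scales to the study's ~45 generations of 50-70 families without
materializing a full pedigree-sized kinship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree

__all__ = [
    "AILDesign",
    "InfeasibleDesignError",
    "simulate_ail_pedigree",
    "sample_study_cohort",
]


class InfeasibleDesignError(ValueError):
    """The requested breeding pairs cannot be formed under the constraints."""


@dataclass(frozen=True)
class AILDesign:
    """Breeding-scheme parameters for an AIL simulation.

    Defaults emulate the study population: ~45 intercross generations kept
    at 50-70 breeding families per generation.
    """

    n_generations: int = 45
    families_per_generation: tuple[int, int] = (50, 70)
    offspring_per_family: tuple[int, int] = (2, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        fl, fh = self.families_per_generation
        ol, oh = self.offspring_per_family
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (1 <= fl <= fh):
            raise ValueError("families_per_generation must be a positive (low, high) range")
        if not (1 <= ol <= oh) or oh < 2:
            raise ValueError("offspring_per_family range must be positive with high >= 2")


def _greedy_pairs(
    phi: np.ndarray,
    sib: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Greedy minimum-kinship pairing with forbidden sib matings.

    ``sib[i, j]`` marks full-sib pairs. If at some step only sib pairs
    remain available the pairing is infeasible, except when *every*
    candidate pair is sib (the F1 case), where sib mating is unavoidable
    and allowed.
    """
    m = phi.shape[0]
    if m < 2 * n_pairs:
        raise InfeasibleDesignError(
            f"need {2 * n_pairs} candidates to form {n_pairs} pairs, have {m}"
        )
    jitter = rng.uniform(0.0, 1e-9, size=(m, m))
    cost = phi + jitter + jitter.T
    all_sib = bool(sib[np.triu_indices(m, k=1)].all())
    if not all_sib:
        cost = np.where(sib, np.inf, cost)
    np.fill_diagonal(cost, np.inf)
    cost = np.triu(cost) + np.tril(np.full_like(cost, np.inf))
    pairs: list[tuple[int, int]] = []
    for _ in range(n_pairs):
        k = int(np.argmin(cost))
        i, j = divmod(k, m)
        if not np.isfinite(cost[i, j]):
            raise InfeasibleDesignError(
                "cannot form requested breeding pairs without sib mating"
            )
        pairs.append((i, j))
        cost[i, :] = np.inf
        cost[:, i] = np.inf
        cost[j, :] = np.inf
        cost[:, j] = np.inf
    return pairs


def simulate_ail_pedigree(design: AILDesign) -> Pedigree:
    """Simulate an AIL pedigree from two inbred founders.

    Generation 0 holds the two ``founder_inbred`` strain representatives;
    generation 1 the F1s (all offspring of the founder pair); each later
    generation is bred from greedy minimum-kinship pairs of the previous
    one. Family counts and per-family offspring counts are drawn uniformly
    from the configured ranges. Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    individuals = [
        Individual("A", sex="female", generation=0, founder_inbred=True),
        Individual("B", sex="male", generation=0, founder_inbred=True),
    ]
    fl, fh = design.families_per_generation
    ol, oh = design.offspring_per_family
    fam_counts = rng.integers(fl, fh + 1, size=max(design.n_generations - 1, 0))

    prev_ids = ["A", "B"]
    prev_phi = np.array([[1.0, 0.0], [0.0, 1.0]])
    prev_parents: list[tuple[str, str]] = [("", ""), ("", "")]  # founders: no parents

    for g in range(1, design.n_generations + 1):
        if g == 1:
            n_f1 = int(2 * fam_counts[0]) if design.n_generations >= 2 else int(
                rng.integers(max(ol, 2), oh + 1)
            )
            pairs = [(0, 1)]
            sizes = [n_f1]
        else:
            n_fam = int(fam_counts[g - 2])
            m = len(prev_ids)
            sib = np.zeros((m, m), dtype=bool)
            parent_keys = np.array([hash(p) for p in prev_parents])
            sib = parent_keys[:, None] == parent_keys[None, :]
            np.fill_diagonal(sib, False)
            pairs = _greedy_pairs(prev_phi, sib, n_fam, rng)
            sizes = rng.integers(ol, oh + 1, size=n_fam).tolist()

        sires = np.array([p[0] for p in pairs])
        dams = np.array([p[1] for p in pairs])
        child_sire_idx: list[int] = []
        child_dam_idx: list[int] = []
        new_ids: list[str] = []
        new_parents: list[tuple[str, str]] = []
        k = 0
        for (si, di), n_off in zip(pairs, sizes):
            for _ in range(int(n_off)):
                k += 1
                cid = f"F{g}_{k}"
                sex = "female" if rng.integers(0, 2) == 0 else "male"
                individuals.append(
                    Individual(cid, prev_ids[si], prev_ids[di], sex, generation=g)
                )
                new_ids.append(cid)
                new_parents.append((prev_ids[si], prev_ids[di]))
                child_sire_idx.append(si)
                child_dam_idx.append(di)

        # propagate kinship one generation: parents of gen g all lie in gen g-1
        S = np.array(child_sire_idx)
        D = np.array(child_dam_idx)
        new_phi = 0.25 * (
            prev_phi[np.ix_(S, S)]
            + prev_phi[np.ix_(S, D)]
            + prev_phi[np.ix_(D, S)]
            + prev_phi[np.ix_(D, D)]
        )
        np.fill_diagonal(new_phi, 0.5 * (1.0 + prev_phi[S, D]))
        prev_ids, prev_phi, prev_parents = new_ids, new_phi, new_parents

    return Pedigree(individuals)


def sample_study_cohort(
    ped: Pedigree,
    n_families: int = 10,
    offspring_range: tuple[int, int] = (4, 11),
    seed: int | None = None,
    distinct_parent_families: bool = True,
) -> tuple[Pedigree, pd.DataFrame]:
    """Draw a phenotyped parents+offspring cohort from the top generation.

    Mirrors the study cohort: ``2 * n_families`` parents are sampled from
    the pedigree's last generation (each from a different family when
    ``distinct_parent_families``), paired at random into ``n_families``
    breeding pairs, and each pair is given a number of offspring drawn
    uniformly from ``offspring_range``. The offspring extend the pedigree
    by one generation.

    Returns
    -------
    (pedigree, cohort)
        The extended pedigree and a cohort table with columns
        ``animal_id, family_id, role ("parent"/"offspring"), generation, sex``.
    """
    rng = np.random.default_rng(seed)
    top = ped.max_generation
    candidates = list(ped.generation_ids(top))
    if distinct_parent_families:
        by_family: dict[tuple[str | None, str | None], list[str]] = {}
        for cid in candidates:
            ind = ped[cid]
            by_family.setdefault((ind.sire, ind.dam), []).append(cid)
        families = list(by_family.values())
        if len(families) < 2 * n_families:
            raise InfeasibleDesignError(
                f"top generation has {len(families)} families; "
                f"{2 * n_families} distinct-family parents requested"
            )
        chosen = rng.choice(len(families), size=2 * n_families, replace=False)
        parents = [families[i][rng.integers(len(families[i]))] for i in chosen]
    else:
        if len(candidates) < 2 * n_families:
            raise InfeasibleDesignError("not enough top-generation candidates")
        parents = list(rng.choice(candidates, size=2 * n_families, replace=False))
    rng.shuffle(parents)

    ol, oh = offspring_range
    if not (1 <= ol <= oh):
        raise ValueError("offspring_range must be a positive (low, high) range")
    new_inds: list[Individual] = []
    rows: list[dict] = []
    for f in range(n_families):
        sire, dam = parents[2 * f], parents[2 * f + 1]
        fam = f"fam{f + 1:02d}"
        for pid in (sire, dam):
            rows.append(
                {
                    "animal_id": pid,
                    "family_id": fam,
                    "role": "parent",
                    "generation": top,
                    "sex": ped[pid].sex,
                }
            )
        n_off = int(rng.integers(ol, oh + 1))
        for k in range(n_off):
            cid = f"{fam}_o{k + 1}"
            sex = "female" if rng.integers(0, 2) == 0 else "male"
            new_inds.append(Individual(cid, sire, dam, sex, generation=top + 1))
            rows.append(
                {
                    "animal_id": cid,
                    "family_id": fam,
                    "role": "offspring",
                    "generation": top + 1,
                    "sex": sex,
                }
            )
    return ped.extended(new_inds), pd.DataFrame(rows)
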