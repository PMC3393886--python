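"""Kinship and inbreeding coefficients from a pedigree.

The kinship coefficient Phi(i, j) is the probability that one allele drawn
at random from i and one from j are identical by descent. It satisfies the
standard recursion (parents before offspring):

* founders: Phi = 0 between distinct founders; Phi(i, i) = 1 for a fully
  inbred founder, else 1/2;
* Phi(i, i) = (1 + Phi(sire_i, dam_i)) / 2;
* for i != j with i not an ancestor of j:
  Phi(i, j) = (Phi(sire_i, j) + Phi(dam_i, j)) / 2.

``kinship_matrix`` evaluates this by the tabular method over the ancestor
closure of the requested ids. ``gene_drop_kinship`` is an independent
Monte-Carlo oracle: founder allele labels are transmitted down the pedigree
and identity-by-descent is counted empirically.

The additive (numerator) relationship matrix used by the animal model is
A = 2 * Phi, with diagonal 1 + F.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UnknownIdError

__all__ = [
    "KinshipMatrix",
    "kinship_matrix",
    "inbreeding_coefficient",
    "gene_drop_kinship",
    "read_kinship_csv",
]


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric matrix of pairwise kinship coefficients over ``ids``."""

    ids: tuple[str, ...]
    values: np.ndarray  # Phi, shape (n, n)

    def __post_init__(self) -> None:
        n = len(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError(f"kinship values have shape {v.shape}, expected ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, id: str) -> int:
        try:
            return self.ids.index(id)
        except ValueError:
            raise UnknownIdError(f"id {id!r} not in kinship matrix") from None

    def phi(self, i: str, j: str) -> float:
        return float(self.values[self.index_of(i), self.index_of(j)])

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients F = 2*Phi(i,i) - 1."""
        return 2.0 * np.diag(self.values) - 1.0

    def additive(self) -> np.ndarray:
        """The additive relationship matrix A = 2 * Phi."""
        return 2.0 * self.values

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self.index_of(i) for i in ids]
        return KinshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)].copy())

    def min_additive_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.additive()).min())

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_triplets(self) -> pd.DataFrame:
        """Long-format upper triangle (including diagonal): id1, id2, phi."""
        iu, ju = np.triu_indices(len(self.ids))
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu],
                "id2": [self.ids[j] for j in ju],
                "phi": self.values[iu, ju],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    def write_triplets(self, path: str | Path) -> None:
        self.to_triplets().to_csv(path, index=False)


def read_kinship_csv(path: str | Path) -> KinshipMatrix:
    """Read a square kinship CSV written by :meth:`KinshipMatrix.write_csv`."""
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def kinship_matrix(ped: Pedigree, ids: Sequence[str] | None = None) -> KinshipMatrix:
    """Kinship coefficients Phi for ``ids`` (default: all individuals).

    The recursion is evaluated by the tabular method over the ancestor
    closure of ``ids``, in topological order (generation, then id), so
    parents always precede offspring.
    """
    ids = list(ids) if ids is not None else list(ped.ids)
    for i in ids:
        ped[i]  # raises UnknownIdError
    order = ped.ancestor_closure(ids)
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            phi[k, k] = 1.0 if ind.founder_inbred else 0.5
        else:
            s, d = index[ind.sire], index[ind.dam]
            if k:
                row = 0.5 * (phi[s, :k] + phi[d, :k])
                phi[k, :k] = row
                phi[:k, k] = row
            phi[k, k] = 0.5 * (1.0 + phi[s, d])
    sel = [index[i] for i in ids]
    return KinshipMatrix(tuple(ids), phi[np.ix_(sel, sel)].copy())


def inbreeding_coefficient(ped: Pedigree, id: str) -> float:
    """Inbreeding coefficient F of one individual.

    F equals the kinship of the individual's parents; fully inbred founders
    return 1, other founders 0.
    """
    km = kinship_matrix(ped, [id])
    return float(2.0 * km.values[0, 0] - 1.0)


def gene_drop_kinship(
    ped: Pedigree,
    ids: Sequence[str] | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> KinshipMatrix:
    """Monte-Carlo kinship estimate by gene dropping founder allele labels.

    Each replicate assigns two distinct allele labels to every non-inbred
    founder (a single label used twice for ``founder_inbred`` founders) and
    transmits one allele, chosen uniformly at random, from each parent to
    each offspring. The estimate Phi_hat(i, j) is the average over
    replicates of the probability that an allele drawn from i and an allele
    drawn from j are identical by descent (the mean of the four pairwise
    allele-identity indicators).

    Deterministic given ``seed``. Intended as an independent oracle for
    :func:`kinship_matrix`; Monte-Carlo standard error per entry is at most
    ``0.5 / sqrt(n_reps)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(ids) if ids is not None else list(ped.ids)
    for i in ids:
        ped[i]
    order = ped.ancestor_closure(ids)
    index = {iid: k for k, iid in enumerate(order)}
    rng = np.random.default_rng(seed)
    n = len(order)
    pat = np.empty((n, n_reps), dtype=np.int32)
    mat = np.empty((n, n_reps), dtype=np.int32)
    next_label = 0
    for k, iid in enumerate(order):
        ind = ped[iid]
        if ind.is_founder:
            if ind.founder_inbred:
                pat[k] = mat[k] = next_label
                next_label += 1
            else:
                pat[k] = next_label
                mat[k] = next_label + 1
                next_label += 2
        else:
            s, d = index[ind.sire], index[ind.dam]
            pick = rng.integers(0, 2, n_reps, dtype=np.int8).astype(bool)
            pat[k] = np.where(pick, pat[s], mat[s])
            pick = rng.integers(0, 2, n_reps, dtype=np.int8).astype(bool)
            mat[k] = np.where(pick, pat[d], mat[d])
    m = len(ids)
    sel = [index[i] for i in ids]
    phi = np.empty((m, m))
    for a in range(m):
        i = sel[a]
        for b in range(a, m):
            j = sel[b]
            ibd = (
                (pat[i] == pat[j]).mean()
                + (pat[i] == mat[j]).mean()
                + (mat[i] == pat[j]).mean()
                + (mat[i] == mat[j]).mean()
            )
            phi[a, b] = phi[b, a] = 0.25 * ibd
    return KinshipMatrix(tuple(ids), phi)
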