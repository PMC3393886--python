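"""Phenotype generators with known additive-genetic structure.

``simulate_additive_phenotypes`` draws a trait over an arbitrary pedigree
under the same model assumed by the ML estimator: y = mu + a + e with
a ~ N(0, var_a * 2Phi) jointly over individuals and e ~ N(0, var_e)
independent. Inbreeding inflates the diagonal of 2Phi (up to 2); the
generator uses 2Phi as-is rather than an outbred approximation.

``simulate_nuclear_families`` generates independent two-parent families on
the standardized scale (total phenotypic variance 1): parent phenotypes
P = A + E with Var(A) = h2, Var(E) = 1 - h2; each offspring's breeding
value is the midparent breeding value plus a Mendelian segregation deviate
of variance h2/2, and its phenotype adds independent environment of
variance 1 - h2. This is the generative model under which the expected
midparent-offspring regression slope equals h2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heritability import FamilyTable, NonPSDKinshipError
from .kinship import KinshipMatrix, kinship_matrix
from .pedigree import Pedigree

__all__ = [
    "GeneticParams",
    "simulate_additive_phenotypes",
    "simulate_nuclear_families",
]


@dataclass(frozen=True)
class GeneticParams:
    """Additive-genetic model parameters for one trait (trait units)."""

    mu: float = 0.0
    var_a: float = 0.0
    var_e: float = 1.0

    def __post_init__(self) -> None:
        if self.var_a < 0 or self.var_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def var_total(self) -> float:
        return self.var_a + self.var_e

    @property
    def h2(self) -> float:
        if self.var_total <= 0:
            raise ValueError("h2 undefined when var_a + var_e = 0")
        return self.var_a / self.var_total


def simulate_additive_phenotypes(
    ped: Pedigree,
    ids,
    params: GeneticParams,
    seed: int | None = None,
    kinship: KinshipMatrix | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    psd_tol: float = 1e-8,
) -> pd.Series:
    """Draw one additive trait for ``ids``; deterministic given ``seed``.

    ``kinship`` (Phi over exactly ``ids``) or ``eig`` (an eigendecomposition
    of 2Phi) can be supplied to skip recomputation in replicate studies.
    """
    ids = list(ids)
    if eig is None:
        K = kinship if kinship is not None else kinship_matrix(ped, ids)
        if list(K.ids) != ids:
            K = K.subset(ids)
        lam, U = np.linalg.eigh(K.additive())
    else:
        lam, U = eig
    if lam.min() < -psd_tol * max(1.0, float(lam.max())):
        raise NonPSDKinshipError(
            f"2*Phi has eigenvalue {lam.min():.3g} beyond PSD tolerance"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    n = len(ids)
    a = U @ (np.sqrt(params.var_a * lam) * rng.standard_normal(n))
    e = rng.normal(0.0, np.sqrt(params.var_e), n)
    return pd.Series(params.mu + a + e, index=ids, name="trait")


def simulate_nuclear_families(
    n_fam: int, n_off: int, h2: float, seed: int | None = None
) -> FamilyTable:
    """Independent nuclear families on the variance-1 scale.

    Parents are unrelated and non-inbred; every family contributes two
    parents and ``n_off`` offspring. Deterministic given ``seed``.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if n_fam < 1 or n_off < 1:
        raise ValueError("n_fam and n_off must be positive")
    rng = np.random.default_rng(seed)
    sa = np.sqrt(h2)
    se = np.sqrt(1.0 - h2)
    a_s = sa * rng.standard_normal(n_fam)
    a_d = sa * rng.standard_normal(n_fam)
    p_s = a_s + se * rng.standard_normal(n_fam)
    p_d = a_d + se * rng.standard_normal(n_fam)
    mid_a = 0.5 * (a_s + a_d)
    seg = np.sqrt(h2 / 2.0) * rng.standard_normal((n_fam, n_off))
    off = mid_a[:, None] + seg + se * rng.standard_normal((n_fam, n_off))
    fams = tuple(f"fam{k + 1}" for k in range(n_fam))
    return FamilyTable(fams, p_s, p_d, tuple(off[k] for k in range(n_fam)))
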