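"""Narrow-sense heritability estimators.

Two estimators of h² = σ²_a / (σ²_a + σ²_e):

* **Midparent-offspring regression** (:class:`MidparentRegression`): for an
  additive trait, the expected regression slope of offspring family means
  on midparent means equals h²; the reported standard error is the OLS
  standard error of the slope.

* **Kinship-based maximum likelihood** (:class:`KinshipVarianceComponents`):
  the animal model y ~ N(Xβ, σ²_a·A + σ²_e·I) with A = 2Φ the additive
  relationship matrix from the pedigree. The likelihood is profiled: for a
  candidate h², β is obtained by GLS and σ²_total in closed form, leaving a
  one-dimensional concave-in-practice problem over h² ∈ [0, 1] solved by a
  dense grid plus Brent refinement on a single eigendecomposition of A.
  Boundary solutions (σ²_a = 0, hence h² = 0) are legal and flagged.

Both estimators follow the sklearn estimator contract (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes).
:class:`KinshipVarianceComponents` takes the relationship matrix as ``X``
in ``fit(X, y)``, in the style of sklearn's precomputed-kernel estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator

from .kinship import KinshipMatrix
from .stats import DegenerateDataError

__all__ = [
    "FamilyTable",
    "H2Estimate",
    "NonPSDKinshipError",
    "MidparentRegression",
    "KinshipVarianceComponents",
    "midparent_offspring_h2",
    "ml_variance_components",
]


class NonPSDKinshipError(ValueError):
    """The additive relationship matrix is not positive semidefinite."""


@dataclass(frozen=True)
class FamilyTable:
    """Per-family parent and offspring phenotypes for midparent regression."""

    family_ids: tuple[str, ...]
    sire_values: np.ndarray
    dam_values: np.ndarray
    offspring_values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        n = len(self.family_ids)
        s = np.asarray(self.sire_values, dtype=float)
        d = np.asarray(self.dam_values, dtype=float)
        if s.shape != (n,) or d.shape != (n,):
            raise ValueError("sire/dam value arrays must have one entry per family")
        offs = tuple(np.asarray(o, dtype=float) for o in self.offspring_values)
        if len(offs) != n or any(o.size < 1 for o in offs):
            raise ValueError("every family needs at least one offspring value")
        object.__setattr__(self, "sire_values", s)
        object.__setattr__(self, "dam_values", d)
        object.__setattr__(self, "offspring_values", offs)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def midparent(self) -> np.ndarray:
        return 0.5 * (self.sire_values + self.dam_values)

    @property
    def offspring_means(self) -> np.ndarray:
        return np.array([o.mean() for o in self.offspring_values])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, fam in enumerate(self.family_ids):
            rows.append({"family_id": fam, "role": "sire", "value": self.sire_values[k]})
            rows.append({"family_id": fam, "role": "dam", "value": self.dam_values[k]})
            for v in self.offspring_values[k]:
                rows.append({"family_id": fam, "role": "offspring", "value": v})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyTable":
        fams, sires, dams, offs = [], [], [], []
        for fam, g in df.groupby("family_id", sort=True):
            fams.append(str(fam))
            sires.append(float(g.loc[g["role"] == "sire", "value"].iloc[0]))
            dams.append(float(g.loc[g["role"] == "dam", "value"].iloc[0]))
            offs.append(g.loc[g["role"] == "offspring", "value"].to_numpy(dtype=float))
        return cls(tuple(fams), np.array(sires), np.array(dams), tuple(offs))


@dataclass(frozen=True)
class H2Estimate:
    """A heritability point estimate with its uncertainty and diagnostics."""

    h2: float
    se: float
    method: str  # {"midparent_regression", "max_likelihood"}
    n_units: int
    var_a: float | None = None
    var_e: float | None = None
    log_likelihood: float | None = None
    converged: bool | None = None
    boundary: bool | None = None
    degenerate: bool = False
    raw_slope: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("se must be non-negative")


class MidparentRegression(BaseEstimator):
    """OLS regression of offspring family means on midparent means.

    Parameters
    ----------
    clip : bool, default True
        Report ``h2_`` clipped to [0, 1]; the raw slope is always kept in
        ``slope_``.

    Attributes
    ----------
    slope_, intercept_ : float
        Raw OLS fit.
    se_ : float
        Standard error of the slope.
    h2_ : float
        The heritability estimate (clipped slope if ``clip``).
    n_families_ : int
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("midparent and offspring-mean vectors differ in length")
        if x.size < 3:
            raise ValueError("need at least 3 families for midparent regression")
        if np.ptp(x) == 0.0:
            raise DegenerateDataError("midparent values are all equal")
        res = sps.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.se_ = float(res.stderr)
        self.h2_ = float(np.clip(self.slope_, 0.0, 1.0)) if self.clip else self.slope_
        self.n_families_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def slope_test(self, sided: str = "one") -> tuple[float, float, float]:
        """t-statistic, df, and p for H0: slope <= 0 (or = 0 if two-sided)."""
        if self.se_ == 0.0:
            return math_inf_sign(self.slope_), self.n_families_ - 2, 0.0
        t = self.slope_ / self.se_
        df = self.n_families_ - 2
        if sided == "one":
            p = float(sps.t.sf(t, df))
        elif sided == "two":
            p = float(2 * sps.t.sf(abs(t), df))
        else:
            raise ValueError("sided must be 'one' or 'two'")
        return float(t), float(df), p

    def to_estimate(self) -> H2Estimate:
        return H2Estimate(
            h2=self.h2_,
            se=self.se_,
            method="midparent_regression",
            n_units=self.n_families_,
            raw_slope=self.slope_,
        )


def math_inf_sign(x: float) -> float:
    return float("inf") if x > 0 else (float("-inf") if x < 0 else 0.0)


def midparent_offspring_h2(fams: FamilyTable) -> H2Estimate:
    """Midparent-offspring regression heritability for a family table."""
    est = MidparentRegression().fit(fams.midparent, fams.offspring_means)
    return est.to_estimate()


class KinshipVarianceComponents(BaseEstimator):
    """Animal-model variance components by (restricted) maximum likelihood.

    ``fit(X, y)`` takes ``X`` as the additive relationship matrix A = 2Φ
    (an ndarray, a :class:`KinshipMatrix`, or a precomputed
    eigendecomposition ``(eigenvalues, eigenvectors)`` of A for repeated
    fits on the same cohort) and ``y`` as the aligned trait vector.

    Parameters
    ----------
    reml : bool, default False
        Use REML instead of ML (the default matches the estimator named by
        classical variance-component heritability reports).
    grid_size : int, default 101
        Number of h² grid points scanned before Brent refinement.
    psd_tol : float, default 1e-8
        Relative tolerance on the most negative eigenvalue of A.

    Attributes
    ----------
    h2_, var_a_, var_e_ : float
    loglik_ : float
    beta_ : ndarray
        Fixed effects (intercept only by default).
    converged_, boundary_, degenerate_ : bool
    n_ : int
    """

    def __init__(self, reml: bool = False, grid_size: int = 101, psd_tol: float = 1e-8):
        self.reml = reml
        self.grid_size = grid_size
        self.psd_tol = psd_tol

    # -- likelihood machinery ---------------------------------------------

    @staticmethod
    def _decompose(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, KinshipMatrix):
            A = X.additive()
        elif isinstance(X, tuple) and len(X) == 2:
            lam, U = X
            return np.asarray(lam, dtype=float), np.asarray(U, dtype=float)
        else:
            A = np.asarray(X, dtype=float)
        lam, U = np.linalg.eigh(A)
        return lam, U

    def _profile(self, h2: float, lam, ytil, Xtil) -> tuple[float, float, np.ndarray]:
        """Profile log-likelihood, sigma²_total and beta at a fixed h²."""
        n, p = Xtil.shape
        w = np.maximum(h2 * lam + (1.0 - h2), 1e-12)
        Xw = Xtil / w[:, None]
        xtwx = Xtil.T @ Xw
        beta = np.linalg.solve(xtwx, Xw.T @ ytil)
        r = ytil - Xtil @ beta
        q = float(np.sum(r * r / w))
        if q <= 0.0:
            return np.inf, 0.0, beta  # y lies exactly in the fixed-effect space
        logw = float(np.sum(np.log(w)))
        if self.reml:
            s2 = q / (n - p)
            sign, logdet = np.linalg.slogdet(xtwx)
            ll = -0.5 * (
                (n - p) * (np.log(2 * np.pi * s2) + 1.0) + logw + logdet
            )
        else:
            s2 = q / n
            ll = -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + logw)
        return float(ll), float(s2), beta

    def loglik(self, h2: float) -> float:
        """Profile log-likelihood at a given h² (available after ``fit``)."""
        return self._profile(h2, self._lam, self._ytil, self._Xtil)[0]

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, covariates=None):
        y = np.asarray(y, dtype=float).reshape(-1)
        n = y.size
        if n < 10:
            raise ValueError("need at least 10 observations for ML variance components")
        lam, U = self._decompose(X)
        if lam.shape != (n,) or U.shape != (n, n):
            raise ValueError("relationship matrix not aligned with y")
        lmax = max(1.0, float(lam.max()))
        if lam.min() < -self.psd_tol * lmax:
            raise NonPSDKinshipError(
                f"additive relationship matrix has eigenvalue {lam.min():.3g} < 0"
            )
        lam = np.clip(lam, 0.0, None)
        if covariates is None:
            Xf = np.ones((n, 1))
        else:
            Xf = np.asarray(covariates, dtype=float)
            if Xf.ndim == 1:
                Xf = Xf[:, None]
            if not np.any(np.all(Xf == Xf[0], axis=0)):
                Xf = np.column_stack([np.ones(n), Xf])
        self._lam, self._ytil, self._Xtil = lam, U.T @ y, U.T @ Xf
        self.n_ = n

        spread = float(lam.max() - lam.min())
        if spread < 1e-10 * lmax:
            # A proportional to I: sigma²_a and sigma²_e are indistinguishable
            ll, s2, beta = self._profile(0.0, lam, self._ytil, self._Xtil)
            self._finish(0.0, ll, s2, beta, converged=True, degenerate=True)
            return self

        grid = np.linspace(0.0, 1.0, self.grid_size)
        lls = np.array([self._profile(h, lam, self._ytil, self._Xtil)[0] for h in grid])
        best = int(np.nanargmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, self.grid_size - 1)]
        res = optimize.minimize_scalar(
            lambda h: -self._profile(h, lam, self._ytil, self._Xtil)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h2 = float(res.x)
        ll = -float(res.fun)
        # keep whichever of the grid optimum / refined point is better
        if lls[best] > ll:
            h2, ll = float(grid[best]), float(lls[best])
        if h2 < 1e-6:
            h2 = 0.0
        elif h2 > 1.0 - 1e-6:
            h2 = 1.0
        ll, s2, beta = self._profile(h2, lam, self._ytil, self._Xtil)
        self._finish(h2, ll, s2, beta, converged=bool(res.success), degenerate=False)
        return self

    def _finish(self, h2, ll, s2, beta, converged, degenerate):
        self.h2_ = float(h2)
        self.var_a_ = float(h2 * s2)
        self.var_e_ = float((1.0 - h2) * s2)
        self.loglik_ = float(ll) if np.isfinite(ll) else float(ll)
        self.beta_ = beta
        self.converged_ = bool(converged)
        self.boundary_ = bool(h2 in (0.0, 1.0))
        self.degenerate_ = bool(degenerate)

    def to_estimate(self, se: float = 0.0) -> H2Estimate:
        return H2Estimate(
            h2=self.h2_,
            se=se,
            method="max_likelihood",
            n_units=self.n_,
            var_a=self.var_a_,
            var_e=self.var_e_,
            log_likelihood=self.loglik_,
            converged=self.converged_,
            boundary=self.boundary_,
            degenerate=self.degenerate_,
        )


def ml_variance_components(
    y,
    K: KinshipMatrix | np.ndarray | tuple,
    covariates=None,
    reml: bool = False,
    se: float = 0.0,
) -> H2Estimate:
    """Animal-model heritability by maximum likelihood.

    ``K`` may be a :class:`KinshipMatrix` (Φ), an additive relationship
    matrix A = 2Φ as an ndarray, or a precomputed ``(eigenvalues,
    eigenvectors)`` pair of A. ``se`` is typically supplied afterwards from
    :func:`cppherit.jackknife.jackknife_se`.
    """
    est = KinshipVarianceComponents(reml=reml).fit(K, y, covariates=covariates)
    return est.to_estimate(se=se)
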