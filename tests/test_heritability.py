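"""Midparent regression and ML variance-component estimators."""

import numpy as np
import pytest

from cppherit import (
    DegenerateDataError,
    FamilyTable,
    GeneticParams,
    KinshipVarianceComponents,
    MidparentRegression,
    midparent_offspring_h2,
    ml_variance_components,
    simulate_additive_phenotypes,
    simulate_nuclear_families,
)
from cppherit.heritability import NonPSDKinshipError

from conftest import outbred_family_pedigree


class TestMidparentRegression:
    def test_perfect_fit_slope_one(self):
        fams = FamilyTable(
            ("f1", "f2", "f3", "f4"),
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([2.0, 3.0, 4.0, 5.0]),
            tuple(np.array([m]) for m in [1.5, 2.5, 3.5, 4.5]),
        )
        est = midparent_offspring_h2(fams)
        assert est.h2 == pytest.approx(1.0) and est.se == pytest.approx(0.0, abs=1e-12)

    def test_flat_offspring_slope_zero(self):
        fams = FamilyTable(
            ("f1", "f2", "f3"),
            np.array([1.0, 2.0, 3.0]),
            np.array([1.0, 2.0, 3.0]),
            tuple(np.array([5.0, 5.0]) for _ in range(3)),
        )
        assert midparent_offspring_h2(fams).h2 == 0.0

    def test_negative_slope_clipped_with_raw_kept(self):
        est = MidparentRegression().fit([0.0, 1.0, 2.0], [2.0, 1.0, 0.0])
        assert est.h2_ == 0.0 and est.slope_ == pytest.approx(-1.0)

    def test_too_few_or_degenerate_families(self):
        with pytest.raises(ValueError):
            MidparentRegression().fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            MidparentRegression().fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("shift,scale", [(10.0, 1.0), (0.0, 3.5), (-7.0, 0.2)])
    def test_slope_invariant_under_affine_phenotype_transforms(self, shift, scale):
        fams = simulate_nuclear_families(200, 2, 0.4, seed=1)
        base = MidparentRegression().fit(fams.midparent, fams.offspring_means)
        trans = MidparentRegression().fit(
            shift + scale * fams.midparent, shift + scale * fams.offspring_means
        )
        assert trans.slope_ == pytest.approx(base.slope_, rel=1e-9)

    def test_sklearn_params_roundtrip(self):
        est = MidparentRegression(clip=False)
        assert est.get_params() == {"clip": False}
        est.set_params(clip=True)
        assert est.get_params()["clip"] is True


class TestMLVarianceComponents:
    def test_identity_relationship_is_degenerate(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 50)
        est = KinshipVarianceComponents().fit(np.eye(50), y)
        assert est.degenerate_ and est.boundary_ and est.h2_ == 0.0

    def test_nonpsd_rejected(self):
        A = -np.eye(12)
        with pytest.raises(NonPSDKinshipError):
            KinshipVarianceComponents().fit(A, np.zeros(12))

    def test_affine_invariance_of_h2(self, ail_500_cohort):
        lam, U = ail_500_cohort["eig"]
        y = simulate_additive_phenotypes(
            ail_500_cohort["pedigree"],
            ail_500_cohort["ids"],
            GeneticParams(0, 0.5, 0.5),
            seed=5,
            eig=(lam, U),
        ).to_numpy()
        a = KinshipVarianceComponents().fit((lam, U), y)
        b = KinshipVarianceComponents().fit((lam, U), 3.0 - 2.5 * y)
        assert b.h2_ == pytest.approx(a.h2_, abs=1e-5)
        assert b.var_a_ == pytest.approx(2.5**2 * a.var_a_, rel=1e-3)

    def test_local_optimality_on_h2_sigma_grid(self, ail_500_cohort):
        lam, U = ail_500_cohort["eig"]
        y = simulate_additive_phenotypes(
            ail_500_cohort["pedigree"],
            ail_500_cohort["ids"],
            GeneticParams(0, 0.3, 0.7),
            seed=9,
            eig=(lam, U),
        ).to_numpy()
        est = KinshipVarianceComponents().fit((lam, U), y)
        s2_opt = est.var_a_ + est.var_e_
        n = len(y)
        ytil = U.T @ (y - y.mean())

        def full_ll(h2, s2):
            w = np.maximum(h2 * np.clip(lam, 0, None) + (1 - h2), 1e-12) * s2
            return -0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(w)) + np.sum(ytil**2 / w))

        h2_grid = np.clip(np.linspace(est.h2_ - 0.05, est.h2_ + 0.05, 11), 0, 1)
        s2_grid = np.linspace(0.8 * s2_opt, 1.2 * s2_opt, 11)
        grid_best = max(full_ll(h, s) for h in h2_grid for s in s2_grid)
        assert est.loglik_ >= grid_best - 1e-6

    def test_pure_genetic_trait_hits_upper_boundary(self, ail_500_cohort):
        lam, U = ail_500_cohort["eig"]
        hats = []
        for rep in range(5):
            y = simulate_additive_phenotypes(
                ail_500_cohort["pedigree"],
                ail_500_cohort["ids"],
                GeneticParams(0, 1.0, 0.0),
                seed=600 + rep,
                eig=(lam, U),
            ).to_numpy()
            hats.append(KinshipVarianceComponents().fit((lam, U), y).h2_)
        assert min(hats) >= 0.95

    def test_recovery_on_outbred_related_cohort(self):
        ped = outbred_family_pedigree(60, 3)
        ids = list(ped.ids)
        from cppherit import kinship_matrix

        lam, U = np.linalg.eigh(kinship_matrix(ped, ids).additive())
        for h2 in (0.3, 0.7):
            hats = [
                KinshipVarianceComponents()
                .fit(
                    (lam, U),
                    simulate_additive_phenotypes(
                        ped, ids, GeneticParams(0, h2, 1 - h2), seed=int(1000 * h2) + r, eig=(lam, U)
                    ).to_numpy(),
                )
                .h2_
                for r in range(40)
            ]
            assert np.mean(hats) == pytest.approx(h2, abs=0.1)

    def test_function_wrapper_reports_diagnostics(self, ail_500_cohort):
        lam, U = ail_500_cohort["eig"]
        y = simulate_additive_phenotypes(
            ail_500_cohort["pedigree"],
            ail_500_cohort["ids"],
            GeneticParams(0, 0.5, 0.5),
            seed=21,
            eig=(lam, U),
        ).to_numpy()
        est = ml_variance_components(y, (lam, U))
        assert est.method == "max_likelihood"
        assert est.converged is not None
        assert est.var_a is not None and est.var_e is not None
        assert 0.0 <= est.h2 <= 1.0 and est.log_likelihood is not None
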