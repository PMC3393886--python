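"""Shared fixtures: small hand-built pedigrees and a simulated study cohort."""

import numpy as np
import pytest

from cppherit import (
    AILDesign,
    CPPDesign,
    GeneticParams,
    Individual,
    Pedigree,
    derive_phenotypes,
    kinship_matrix,
    sample_study_cohort,
    simulate_ail_pedigree,
    simulate_cpp_sessions,
)

REWARD = GeneticParams(mu=0.0, var_a=0.2, var_e=0.8)
ACTIVITY = GeneticParams(mu=0.0, var_a=0.5, var_e=0.5)


@pytest.fixture
def inbred_cross_pedigree():
    """Two inbred founders, two F1 full sibs, and an F2 from the F1 x F1 mating."""
    return Pedigree(
        [
            Individual("A", sex="female", founder_inbred=True),
            Individual("B", sex="male", founder_inbred=True),
            Individual("f1a", "A", "B", "female", 1),
            Individual("f1b", "A", "B", "male", 1),
            Individual("f2", "f1a", "f1b", "unknown", 2),
        ]
    )


@pytest.fixture
def outbred_sib_pedigree():
    """Two unrelated non-inbred parents with two full-sib offspring."""
    return Pedigree(
        [
            Individual("p1", sex="male"),
            Individual("p2", sex="female"),
            Individual("s1", "p1", "p2", "female", 1),
            Individual("s2", "p1", "p2", "male", 1),
        ]
    )


def outbred_family_pedigree(n_fam: int, n_off: int) -> Pedigree:
    """Independent outbred nuclear families (unrelated non-inbred parents)."""
    inds = []
    for f in range(n_fam):
        inds.append(Individual(f"s{f}", sex="male"))
        inds.append(Individual(f"d{f}", sex="female"))
        for k in range(n_off):
            inds.append(Individual(f"o{f}_{k}", f"s{f}", f"d{f}", generation=1))
    return Pedigree(inds)


@pytest.fixture(scope="session")
def small_ail():
    """An AIL pedigree small enough for the gene-drop oracle (< 200 individuals)."""
    design = AILDesign(
        n_generations=4,
        families_per_generation=(8, 10),
        offspring_per_family=(3, 5),
        seed=20,
    )
    return simulate_ail_pedigree(design)


@pytest.fixture(scope="session")
def study():
    """A full study-scale simulation: 10 families, ~105 animals, 15-day protocol."""
    ail = simulate_ail_pedigree(
        AILDesign(
            n_generations=8,
            families_per_generation=(50, 70),
            offspring_per_family=(2, 5),
            seed=101,
        )
    )
    ped, cohort = sample_study_cohort(ail, n_families=10, offspring_range=(4, 11), seed=102)
    design = CPPDesign()
    sessions = simulate_cpp_sessions(design, REWARD, ACTIVITY, ped, cohort, seed=103)
    phenos = derive_phenotypes(sessions)
    return {
        "pedigree": ped,
        "cohort": cohort,
        "design": design,
        "sessions": sessions,
        "phenotypes": phenos,
    }


@pytest.fixture(scope="session")
def ail_500_cohort():
    """An AIL-derived related cohort of ~500 phenotypable individuals.

    62 breeding pairs from the last AIL generation, 6 offspring each; both
    parents and offspring are in the cohort, mirroring the study's
    parents+offspring design at larger n.
    """
    ail = simulate_ail_pedigree(
        AILDesign(
            n_generations=3,
            families_per_generation=(60, 60),
            offspring_per_family=(3, 5),
            seed=42,
        )
    )
    ped, cohort = sample_study_cohort(
        ail, n_families=62, offspring_range=(6, 6), seed=1, distinct_parent_families=False
    )
    ids = cohort["animal_id"].tolist()
    A = kinship_matrix(ped, ids).additive()
    lam, U = np.linalg.eigh(A)
    return {"pedigree": ped, "ids": ids, "eig": (lam, U)}
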