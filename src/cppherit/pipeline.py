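"""End-to-end analysis pipeline driven by a YAML config.

A run either simulates a study (AIL pedigree -> phenotyped cohort -> CPP
sessions) or ingests session + pedigree CSVs, then derives phenotypes,
runs the behavioral comparisons and the trait correlation matrix, computes
pedigree kinship, estimates heritability per trait by both estimators
(midparent-offspring regression with its OLS slope SE; kinship-based ML
with a delete-d jackknife SE), and optionally runs a midparent-regression
power study. Every run writes its resolved config and seeds to a JSON run
log so results are exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .ail import AILDesign, sample_study_cohort, simulate_ail_pedigree
from .cpp import (
    ALL_SAL_SCHEDULE,
    CPPDesign,
    read_sessions_csv,
    simulate_cpp_sessions,
    write_sessions_csv,
)
from .heritability import (
    KinshipVarianceComponents,
    MidparentRegression,
    ml_variance_components,
)
from .jackknife import jackknife_se
from .kinship import kinship_matrix
from .pedigree import Pedigree, read_pedigree, write_pedigree
from .phenotypes import TRAIT_LABELS, TRAITS, derive_phenotypes
from .power import power_midparent_regression
from .simulate import GeneticParams
from .stats import bonferroni_alpha, correlation_matrix, display_alpha, paired_t, rm_anova

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

#: study-emulation defaults: 10 families, 105 animals, reward h2 = 0.2,
#: activity h2 = 0.5
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "ail": {
            "n_generations": 10,
            "families_per_generation": [50, 70],
            "offspring_per_family": [2, 5],
        },
        "cpp": {},
        "reward": {"mu": 0.0, "var_a": 0.2, "var_e": 0.8},
        "activity": {"mu": 0.0, "var_a": 0.5, "var_e": 0.5},
    },
    "analyses": ["phenotypes", "tests", "correlations", "kinship", "heritability"],
    "jackknife": {"n_subsets": 50, "d": 10},
    "heritability_traits": TRAITS,
}

KNOWN_KEYS = {
    "seed",
    "out_dir",
    "simulate",
    "data",
    "analyses",
    "jackknife",
    "heritability_traits",
    "power",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise PipelineError(f"invalid config keys: {sorted(unknown)}")
    if ("simulate" in cfg) == ("data" in cfg):
        raise PipelineError("config must specify exactly one of 'simulate' or 'data'")
    return cfg


def _as_tuple(v) -> tuple[int, int]:
    lo, hi = v
    return int(lo), int(hi)


@_stage("simulate")
def _simulate_study(cfg: dict, seed: int):
    sim = cfg["simulate"]
    ail_kwargs = dict(sim.get("ail", {}))
    for key in ("families_per_generation", "offspring_per_family"):
        if key in ail_kwargs:
            ail_kwargs[key] = _as_tuple(ail_kwargs[key])
    design = AILDesign(seed=seed, **{k: v for k, v in ail_kwargs.items() if k != "seed"})
    ped = simulate_ail_pedigree(design)

    cpp_kwargs = dict(sim.get("cpp", {}))
    if cpp_kwargs.pop("control", False):
        cpp_kwargs["schedule"] = dict(ALL_SAL_SCHEDULE)
    if "offspring_range" in cpp_kwargs:
        cpp_kwargs["offspring_range"] = _as_tuple(cpp_kwargs["offspring_range"])
    if "initial_bias" in cpp_kwargs:
        cpp_kwargs["initial_bias"] = tuple(cpp_kwargs["initial_bias"])
    cpp = CPPDesign(**cpp_kwargs)
    reward = GeneticParams(**sim.get("reward", DEFAULT_CONFIG["simulate"]["reward"]))
    activity = GeneticParams(**sim.get("activity", DEFAULT_CONFIG["simulate"]["activity"]))

    ped2, cohort = sample_study_cohort(
        ped, n_families=cpp.n_families, offspring_range=cpp.offspring_range, seed=seed + 1
    )
    sessions = simulate_cpp_sessions(cpp, reward, activity, ped2, cohort, seed=seed + 2)
    return ped2, sessions, cpp


@_stage("ingest")
def _ingest(cfg: dict):
    data = cfg["data"]
    ped = read_pedigree(data["pedigree"])
    sessions = read_sessions_csv(data["sessions"])
    return ped, sessions


@_stage("tests")
def _behavioral_tests(phenos: pd.DataFrame) -> dict:
    """Paired t of D8 and D15 vs D1 and the day RM-ANOVA, Bonferroni k=3."""
    alpha = bonferroni_alpha(0.05, 3)
    out: dict[str, Any] = {"alpha": alpha, "alpha_displayed": display_alpha(alpha)}
    t_d8 = paired_t(phenos["D8_CPP"], phenos["D1_pref"], alpha=alpha, name="D8_vs_D1")
    t_d15 = paired_t(phenos["D15_CPP"], phenos["D1_pref"], alpha=alpha, name="D15_vs_D1")
    t_d15_d8 = paired_t(phenos["D15_CPP"], phenos["D8_CPP"], alpha=alpha, name="D15_vs_D8")
    long = phenos.melt(
        id_vars=["animal_id"],
        value_vars=["D1_pref", "D8_CPP", "D15_CPP"],
        var_name="day",
        value_name="value",
    )
    anova = rm_anova(long, subject="animal_id", within="day", value="value")
    for res in (t_d8, t_d15, t_d15_d8, anova["within"]):
        out[res.name if res.name != "within" else "day_anova"] = {
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "significant": res.significant,
        }
    return out


@_stage("heritability")
def _heritability_tables(
    phenos: pd.DataFrame,
    ped: Pedigree,
    traits: list[str],
    jk: dict,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    ids = phenos["animal_id"].tolist()
    K = kinship_matrix(ped, ids)
    A = K.additive()
    rows = []
    diagnostics: dict[str, Any] = {}
    for trait in traits:
        y = phenos[trait].to_numpy(dtype=float)
        # midparent regression over families with parents and offspring
        mid = _midparent_for_trait(phenos, trait)
        # ML with jackknife SE over individuals
        lam, U = np.linalg.eigh(A)
        ml = ml_variance_components(y, (lam, U))
        idx = pd.DataFrame({"pos": np.arange(len(ids))})

        def refit(sub: pd.DataFrame) -> float:
            pos = sub["pos"].to_numpy()
            return (
                KinshipVarianceComponents()
                .fit(A[np.ix_(pos, pos)], y[pos])
                .h2_
            )

        se_ml = jackknife_se(
            refit, idx, n_subsets=jk.get("n_subsets", 50), d=jk.get("d", 10), seed=seed
        )
        rows.append(
            {
                "phenotype": TRAIT_LABELS.get(trait, trait),
                "h2 (SE): midparent-offspring regression": (
                    f"{mid.h2:.2f} ({mid.se:.2f})" if mid is not None else "NA"
                ),
                "h2 (SE): maximum likelihood": f"{ml.h2:.2f} ({se_ml:.2f})",
            }
        )
        diagnostics[trait] = {
            "midparent": None if mid is None else asdict(mid),
            "max_likelihood": {**asdict(ml), "se": se_ml},
        }
    return pd.DataFrame(rows), diagnostics


def _midparent_for_trait(phenos: pd.DataFrame, trait: str):
    if "role" not in phenos.columns:
        return None
    mids, offs = [], []
    for _, g in phenos.groupby("family_id"):
        parents = g.loc[g["role"] == "parent", trait].to_numpy(dtype=float)
        children = g.loc[g["role"] == "offspring", trait].to_numpy(dtype=float)
        if parents.size == 2 and children.size >= 1:
            mids.append(parents.mean())
            offs.append(children.mean())
    if len(mids) < 3:
        return None
    est = MidparentRegression().fit(np.array(mids), np.array(offs))
    return est.to_estimate()


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured pipeline; returns a manifest of output files."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "cppherit_run"))
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {"config": _jsonable(cfg), "seed": seed, "warnings": []}
    manifest: dict[str, str] = {}

    if "simulate" in cfg:
        ped, sessions, cpp = _simulate_study(cfg, seed)
        if cpp.is_control:
            msg = "all-SAL control schedule: the CPP contrast is null by design"
            logger.warning(msg)
            log["warnings"].append(msg)
        write_pedigree(ped, out / "pedigree.csv")
        write_sessions_csv(sessions, out / "sessions.csv")
        manifest["pedigree"] = str(out / "pedigree.csv")
        manifest["sessions"] = str(out / "sessions.csv")
    else:
        ped, sessions = _ingest(cfg)

    analyses = cfg.get("analyses", DEFAULT_CONFIG["analyses"])
    phenos = derive_phenotypes(sessions)
    if "phenotypes" in analyses:
        phenos.to_csv(out / "phenotypes.csv", index=False)
        manifest["phenotypes"] = str(out / "phenotypes.csv")

    if "tests" in analyses:
        tests = _behavioral_tests(phenos)
        (out / "tests.json").write_text(json.dumps(tests, indent=2))
        manifest["tests"] = str(out / "tests.json")

    if "correlations" in analyses:
        corr = correlation_matrix(phenos, [t for t in TRAITS if t != "D15_CPP"])
        corr.r.to_csv(out / "correlations_r.csv")
        corr.p.to_csv(out / "correlations_p.csv")
        manifest["correlations"] = str(out / "correlations_r.csv")

    if "kinship" in analyses:
        K = kinship_matrix(ped, phenos["animal_id"].tolist())
        K.write_csv(out / "kinship.csv")
        manifest["kinship"] = str(out / "kinship.csv")

    if "heritability" in analyses:
        traits = cfg.get("heritability_traits", TRAITS)
        table, diag = _heritability_tables(
            phenos, ped, traits, cfg.get("jackknife", {}), seed
        )
        table.to_csv(out / "heritability.csv", index=False)
        (out / "heritability_diagnostics.json").write_text(
            json.dumps(_jsonable(diag), indent=2)
        )
        manifest["heritability"] = str(out / "heritability.csv")

    if "power" in analyses or "power" in cfg:
        pw = cfg.get("power", {})
        res = power_midparent_regression(
            h2=float(pw.get("h2", 0.2)),
            n_families=int(pw.get("n_families", 100)),
            n_offspring=int(pw.get("n_offspring", 2)),
            alpha=float(pw.get("alpha", 0.05)),
            sided=pw.get("sided", "one"),
            n_reps=int(pw.get("n_reps", 5000)),
            seed=seed,
        )
        pd.DataFrame([asdict(res) | {"mc_se": res.mc_se}]).to_csv(
            out / "power.csv", index=False
        )
        manifest["power"] = str(out / "power.csv")

    log["outputs"] = manifest
    (out / "run_log.json").write_text(json.dumps(_jsonable(log), indent=2))
    manifest["run_log"] = str(out / "run_log.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
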