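"""Repeated-cohort calibration and recovery experiments.

These experiments quantify what the pipeline does under known truth:

* **Parameter recovery** — across many independently simulated cohorts with a
  planted standardized effect of the true polygenic score on one cell's
  volume change, the mean recovered regression coefficient should match the
  planted value, non-planted cells should reject at the nominal rate, and
  the permutation scan should detect the planted cell reliably.
* **Null calibration** — with no planted effect, the empirical permutation
  p-value should reject at the nominal rate.

They are used both by the test suite and by the acceptance script, with the
cohort conditions (60 subjects per group, planted effect -0.6) fixed by the
simulation defaults.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .assoc import (
    AssocConfig,
    fit_prs_model,
    permutation_pvalue,
    threshold_scan,
    usable_covariates,
)
from .genoqc import QCConfig, run_qc
from .phenoprep import volume_change
from .scoring import ScoringConfig, score_gene_sets
from .simdata import SimConfig, simulate_cohort, simulate_phenotypes

__all__ = ["run_single_cohort", "run_parameter_recovery", "run_null_calibration"]


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def run_single_cohort(
    sim_cfg: SimConfig,
    assoc_cfg: AssocConfig,
    qc_cfg: QCConfig | None = None,
    scoring_cfg: ScoringConfig | None = None,
) -> dict:
    """Simulate one cohort, run QC/scoring/associations, measure recovery.

    Returns the full scan table plus the planted-cell diagnostics: the
    coefficient of the within-group standardized *true* polygenic score
    (the generative exposure, so its estimate is not attenuated by scoring
    noise), the model R² of that fit, and per-gene-set optimal-threshold
    empirical p-values at the planted cell.
    """
    cohort = simulate_cohort(sim_cfg)
    clean, _report, pcs = run_qc(cohort.dosage, qc_cfg or QCConfig())
    profiles = score_gene_sets(
        cohort.stats, clean, cohort.annotation, cohort.sets,
        scoring_cfg or ScoringConfig(),
    )
    outcomes = volume_change(cohort.phenotypes)
    covariates = cohort.covariates.merge(pcs.reset_index(), on="subject_id")
    results, optimal = threshold_scan(profiles, outcomes, covariates, assoc_cfg)

    planted = cohort.truth.planted
    cell = outcomes[outcomes["group"] == planted["group"]].merge(
        covariates, on="subject_id"
    )
    prs = cohort.truth.true_prs.loc[cell["subject_id"]].to_numpy()
    z = (prs - prs.mean()) / prs.std(ddof=1)
    y = cell[f"z_{planted['hemisphere']}_{planted['subfield']}"].to_numpy()
    fit, _ = fit_prs_model(y, z, usable_covariates(cell[list(assoc_cfg.covariates)]))

    is_planted = (
        (results["group"] == planted["group"])
        & (results["subfield"] == planted["subfield"])
        & (results["hemisphere"] == planted["hemisphere"])
    )
    opt_planted = optimal[
        (optimal["group"] == planted["group"])
        & (optimal["subfield"] == planted["subfield"])
        & (optimal["hemisphere"] == planted["hemisphere"])
    ]
    return {
        "results": results,
        "optimal": optimal,
        "true_prs_coef": float(fit.params[1]),
        "true_prs_r2": float(fit.r2),
        "planted_optimal_p": {
            row["gene_set"]: float(row["p_empirical"])
            for _, row in opt_planted.iterrows()
        },
        "null_cells": results[~is_planted & results["p_empirical"].notna()],
    }


def run_parameter_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_perm: int = 1000,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Repeat the single-cohort experiment across independent seeds.

    Aggregates the recovered true-score coefficients, planted-cell model R²,
    per-gene-set detection power at the planted cell (optimal-threshold
    empirical p below 0.05), and the rejection rate over all non-planted
    cells.
    """
    sim_cfg = sim_cfg or SimConfig()
    seeds = _derive_seeds(base_seed, 2 * n_seeds).reshape(2, n_seeds)
    coefs, r2s = [], []
    detected: dict[str, int] = {}
    null_sig = 0
    null_total = 0
    for i in range(n_seeds):
        s_cfg = replace(sim_cfg, seed=int(seeds[0, i]))
        a_cfg = AssocConfig(n_perm=n_perm, seed=int(seeds[1, i]))
        res = run_single_cohort(s_cfg, a_cfg)
        coefs.append(res["true_prs_coef"])
        r2s.append(res["true_prs_r2"])
        for label, p in res["planted_optimal_p"].items():
            detected[label] = detected.get(label, 0) + int(p < 0.05)
        null_sig += int(res["null_cells"]["significant"].sum())
        null_total += len(res["null_cells"])
    coefs = np.asarray(coefs)
    return {
        "n_seeds": n_seeds,
        "coefs": coefs,
        "mean_coef": float(coefs.mean()),
        "sem_coef": float(coefs.std(ddof=1) / np.sqrt(n_seeds)),
        "mean_true_prs_r2": float(np.mean(r2s)),
        "power": {label: c / n_seeds for label, c in detected.items()},
        "null_sig_rate": null_sig / null_total if null_total else np.nan,
        "n_null_cells": null_total,
    }


def run_null_calibration(
    n_reps: int = 500,
    n_perm: int = 2000,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Permutation-test rejection rate with no planted effect.

    One cohort's genotypes, scores and covariates are held fixed; each
    repetition redraws the (null) phenotypes, rebuilds the outcome, and runs
    the permutation test for the exercising patient group's left CA4/DG
    volume change against the OPC score at the 0.05 threshold.
    """
    seeds = _derive_seeds(base_seed, 2 + n_reps)
    sim_cfg = SimConfig(seed=int(seeds[0]), prs_volume_effect=0.0)
    cohort = simulate_cohort(sim_cfg)
    clean, _report, pcs = run_qc(cohort.dosage)
    profiles = score_gene_sets(
        cohort.stats, clean, cohort.annotation, cohort.sets, ScoringConfig()
    )
    covariates = cohort.covariates.merge(pcs.reset_index(), on="subject_id")
    prof = profiles["OPC"]
    k = prof.thresholds.index(0.05)

    group = "SCZ-exercise"
    cov_cols = list(AssocConfig().covariates)
    rejections = 0
    for r in range(n_reps):
        rng = np.random.default_rng(int(seeds[2 + r]))
        pheno, _cov = simulate_phenotypes(cohort.truth, sim_cfg, rng)
        outcomes = volume_change(pheno)
        cell = outcomes[outcomes["group"] == group].merge(
            covariates, on="subject_id"
        )
        pos = {s: i for i, s in enumerate(prof.subjects)}
        raw = prof.raw[[pos[s] for s in cell["subject_id"]], k]
        z = (raw - raw.mean()) / raw.std(ddof=1)
        y = cell["z_left_CA4DG"].to_numpy()
        cov_mat = usable_covariates(cell[cov_cols]).to_numpy(dtype=float)
        x = np.column_stack([np.ones(len(y)), z, cov_mat])
        p = permutation_pvalue(y, x, j=1, n_perm=n_perm, seed=rng)
        rejections += int(p < alpha)
    return {
        "n_reps": n_reps,
        "n_perm": n_perm,
        "rejection_rate": rejections / n_reps,
    }
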