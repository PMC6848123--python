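"""Covariate-adjusted association of volume change with polygenic scores.

For every (gene set, subfield, hemisphere, group, threshold) cell the
standardized volume change is regressed on the standardized score plus
age, sex, height, handedness and the two ancestry principal components.
Statistical significance is assessed twice: nominally from the t
distribution, and empirically by permuting the raw outcome vector while
holding the whole design fixed and recording the permuted |t| of the score
coefficient.  The empirical p uses the add-one rule
``(1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm)`` so it can never be zero.

Permuting the raw outcome (rather than covariate-model residuals) is the
literal resampling scheme this pipeline targets; the Freedman-Lane residual
scheme is available as an option since the two differ once covariates enter
the model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import HEMISPHERES, SUBFIELDS, PRSProfile

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "height", "handedness", "PC1", "PC2")

RESULT_COLUMNS = [
    "gene_set", "subfield", "hemisphere", "group", "threshold",
    "n", "n_variants", "coef", "se", "t", "r2", "partial_r2",
    "p_nominal", "p_empirical", "significant",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; offending columns are named."""


@dataclass(frozen=True)
class AssocConfig:
    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    permute_residuals: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class OLSFit:
    names: list[str]
    params: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    r2: float
    rss: float
    tss: float
    xtx_inv: np.ndarray = field(repr=False, default=None)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    offenders = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            offenders.append(names[j])
    raise CollinearityError(
        f"design matrix rank {rank} < {x.shape[1]} columns; "
        f"collinear columns: {offenders}"
    )


def ols_fit(x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """Ordinary least squares with classical standard errors.

    Requires a full-rank design with more rows than columns; rank deficiency
    raises a CollinearityError naming the involved columns.  R² is computed
    against the centered total sum of squares (an intercept column is
    expected in the design).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    names = names or [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    _check_rank(x, names)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return OLSFit(
        names=list(names), params=beta, se=se, t=t, p=p, df_resid=df,
        r2=r2, rss=rss, tss=tss, xtx_inv=xtx_inv,
    )


def fit_prs_model(
    y: np.ndarray, prs: np.ndarray, covariates: pd.DataFrame
) -> tuple[OLSFit, float]:
    """Fit outcome ~ intercept + PRS + covariates; also return partial R².

    Partial R² of the score is the drop in residual sum of squares when the
    score joins the covariate-only model, over the total sum of squares.
    """
    names = ["intercept", "prs", *covariates.columns]
    x = np.column_stack([np.ones(len(y)), prs, covariates.to_numpy(dtype=float)])
    fit = ols_fit(x, y, names)
    x0 = np.delete(x, 1, axis=1)
    fit0 = ols_fit(x0, y, ["intercept", *covariates.columns])
    partial_r2 = (fit0.rss - fit.rss) / fit.tss if fit.tss > 0 else np.nan
    return fit, partial_r2


# ------------------------------------------------------------- permutations

def _perm_abs_t(
    y: np.ndarray, x: np.ndarray, j: int, perm_idx: np.ndarray
) -> np.ndarray:
    """|t| of column ``j`` for every row-permutation of ``y`` (vectorized).

    For fixed X, the permuted coefficient vector is ``(X'X)^-1 X' P y`` and
    the residual sum of squares follows from ``y'y - beta' X' P y``; one pair
    of matrix products covers all permutations.
    """
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    a = xtx_inv @ x.T                      # k x n
    yp = y[perm_idx].T                     # n x B
    betas = a @ yp                         # k x B
    xty = x.T @ yp                         # k x B
    rss = (y @ y) - np.einsum("kb,kb->b", betas, xty)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[j] / se, np.inf)
    return np.abs(t)


def permutation_pvalue(
    y: np.ndarray,
    x: np.ndarray,
    j: int,
    n_perm: int,
    seed,
    permute_residuals: bool = False,
    perm_idx: np.ndarray | None = None,
) -> float:
    """Empirical two-sided p for column ``j`` by outcome permutation.

    The observed |t| is compared against ``n_perm`` refits with the outcome
    randomly permuted (covariates and score fixed); the add-one formula keeps
    the result in ``[1/(n_perm+1), 1]``.  With ``permute_residuals`` the
    Freedman-Lane scheme permutes reduced-model residuals instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("degenerate outcome: zero variance")
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    fit = ols_fit(x, y)
    t_obs = abs(fit.t[j])
    if perm_idx is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perm_idx = rng.permuted(
            np.broadcast_to(np.arange(n), (n_perm, n)), axis=1
        )
    if permute_residuals:
        x0 = np.delete(x, j, axis=1)
        fit0 = ols_fit(x0, y)
        fitted0 = x0 @ fit0.params
        resid0 = y - fitted0
        ystar = fitted0[None, :] + resid0[perm_idx]
        # evaluate each permuted outcome against the full design
        t_perm = _perm_abs_t_rows(ystar, x, j)
    else:
        t_perm = _perm_abs_t(y, x, j, perm_idx)
    return float((1 + np.sum(t_perm >= t_obs)) / (1 + len(t_perm)))


def _perm_abs_t_rows(ystar: np.ndarray, x: np.ndarray, j: int) -> np.ndarray:
    """|t| of column j for each row of a (B, n) outcome matrix."""
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    a = xtx_inv @ x.T
    yp = ystar.T
    betas = a @ yp
    xty = x.T @ yp
    yty = np.einsum("bn,bn->b", ystar, ystar)
    rss = np.maximum(yty - np.einsum("kb,kb->b", betas, xty), 0.0)
    sigma2 = rss / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[j] / se, np.inf)
    return np.abs(t)


# ------------------------------------------------------------ threshold scan

def usable_covariates(cov: pd.DataFrame, context: str = "") -> pd.DataFrame:
    """Drop covariate columns that are constant in this stratum.

    A covariate with no variance within an analysis group (e.g. every subject
    right-handed) carries no adjustment information and would only make the
    design collinear with the intercept.
    """
    constant = [c for c in cov.columns if cov[c].nunique(dropna=True) <= 1]
    if constant:
        logger.info("dropping constant covariate(s) %s %s", constant, context)
        return cov.drop(columns=constant)
    return cov


def _standardize_columns(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    for k in range(out.shape[1]):
        sd = out[:, k].std(ddof=1) if out.shape[0] > 1 else 0.0
        if sd > 0:
            out[:, k] = (out[:, k] - out[:, k].mean()) / sd
        else:
            out[:, k] = 0.0
    return out


def threshold_scan(
    profiles: dict[str, PRSProfile],
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: AssocConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (gene set, subfield, hemisphere, group, threshold) regression.

    ``outcomes`` is the phenoprep table (``z_{hemi}_{subfield}`` columns);
    ``covariates`` must carry subject_id plus every configured covariate
    (including the ancestry PCs).  Subjects missing from any input are
    dropped with a log entry.  Scores are re-standardized within each
    analysis group before fitting.  Permutations share one index matrix
    across the thresholds of a cell group, spawned deterministically from the
    configured seed.

    Returns the full result table and the per-cell optimal-threshold table
    (smallest empirical p; ties broken by larger partial R², then smaller
    threshold).
    """
    cfg = cfg or AssocConfig()
    missing_cov = [c for c in cfg.covariates if c not in covariates.columns]
    if missing_cov:
        raise ValueError(f"covariate table lacks columns {missing_cov}")
    cov = covariates.set_index("subject_id")[list(cfg.covariates)]
    incomplete = cov.index[cov.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "%d subjects dropped for missing covariates: %s",
            len(incomplete), list(incomplete[:5]),
        )
        cov = cov.drop(index=incomplete)

    out = outcomes.set_index("subject_id")
    ss = np.random.SeedSequence(cfg.seed)
    rows: list[dict] = []
    groups = list(pd.unique(out["group"]))
    for group in groups:
        in_group = out.index[out["group"] == group]
        for label, prof in profiles.items():
            subj = [s for s in prof.subjects if s in set(in_group) and s in cov.index]
            if len(subj) <= len(cfg.covariates) + 2:
                logger.warning(
                    "cell group (%s, %s): only %d usable subjects; skipped",
                    label, group, len(subj),
                )
                continue
            pos = {s: i for i, s in enumerate(prof.subjects)}
            prs_raw = prof.raw[[pos[s] for s in subj], :]
            prs_std = _standardize_columns(prs_raw)
            cov_g = usable_covariates(
                cov.loc[subj], context=f"in group {group!r}"
            )
            for hemi in HEMISPHERES:
                for sub in SUBFIELDS:
                    y = out.loc[subj, f"z_{hemi}_{sub}"].to_numpy(dtype=float)
                    rng = np.random.default_rng(ss.spawn(1)[0])
                    perm_idx = rng.permuted(
                        np.broadcast_to(np.arange(len(subj)), (cfg.n_perm, len(subj))),
                        axis=1,
                    )
                    for k, t in enumerate(prof.thresholds):
                        rows.append(
                            _fit_cell(
                                y, prs_std[:, k], cov_g, cfg, perm_idx,
                                dict(
                                    gene_set=label, subfield=sub, hemisphere=hemi,
                                    group=group, threshold=t,
                                    n=len(subj), n_variants=prof.n_variants[k],
                                ),
                            )
                        )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    optimal = _optimal_thresholds(results)
    return results, optimal


def _fit_cell(
    y: np.ndarray,
    prs: np.ndarray,
    cov_g: pd.DataFrame,
    cfg: AssocConfig,
    perm_idx: np.ndarray,
    meta: dict,
) -> dict:
    row = dict(meta)
    if prs.std() == 0:
        # zero variants (or zero variance) at this threshold: nothing to test
        row.update(
            coef=np.nan, se=np.nan, t=np.nan, r2=np.nan, partial_r2=np.nan,
            p_nominal=np.nan, p_empirical=np.nan, significant=False,
        )
        return row
    fit, partial_r2 = fit_prs_model(y, prs, cov_g)
    x = np.column_stack([np.ones(len(y)), prs, cov_g.to_numpy(dtype=float)])
    p_emp = permutation_pvalue(
        y, x, j=1, n_perm=perm_idx.shape[0], seed=None,
        permute_residuals=cfg.permute_residuals, perm_idx=perm_idx,
    )
    row.update(
        coef=float(fit.params[1]), se=float(fit.se[1]), t=float(fit.t[1]),
        r2=float(fit.r2), partial_r2=float(partial_r2),
        p_nominal=float(fit.p[1]), p_empirical=p_emp,
        significant=bool(p_emp < cfg.alpha),
    )
    return row


def _optimal_thresholds(results: pd.DataFrame) -> pd.DataFrame:
    """Per (gene set, subfield, hemisphere, group): best threshold by empirical p."""
    rows = []
    keys = ["gene_set", "subfield", "hemisphere", "group"]
    for key, sub in results.groupby(keys, sort=False):
        usable = sub[sub["p_empirical"].notna()]
        if usable.empty:
            continue
        best = usable.sort_values(
            ["p_empirical", "partial_r2", "threshold"],
            ascending=[True, False, True],
            kind="mergesort",
        ).iloc[0]
        rows.append(best[RESULT_COLUMNS].to_dict())
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def residualize(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of the outcome on intercept + covariates (for plotting)."""
    x = np.column_stack(
        [np.ones(len(y)), covariates.to_numpy(dtype=float)]
    )
    fit = ols_fit(x, np.asarray(y, dtype=float))
    return np.asarray(y, dtype=float) - x @ fit.params
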