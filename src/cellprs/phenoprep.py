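"""From two-visit subfield volumes to the regression outcome.

Volumes are first normalized for head size with the intracranial-volume
proportions method (each visit's volume divided by that visit's ICV and
multiplied by the sample-average ICV).  The outcome is the corrected
visit-3 minus visit-1 difference, z-scored within each analysis group —
the stratum matching the per-group regressions downstream.  A one-sample
Kolmogorov-Smirnov check against a fitted normal is provided as a screening
step only: with estimated parameters it is anticonservative and is never
used as a gate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import HEMISPHERES, SUBFIELDS

VOLUME_COLUMNS = [
    f"{h}_{s}_{v}" for h in HEMISPHERES for s in SUBFIELDS for v in ("V1", "V3")
]
REQUIRED_COLUMNS = ["subject_id", "group", "icv_V1", "icv_V3", *VOLUME_COLUMNS]


class DegenerateVarianceError(ValueError):
    """Raised when a standardization stratum has zero change variance."""


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    vols = df[[c for c in REQUIRED_COLUMNS if c not in ("subject_id", "group")]]
    if (vols <= 0).any().any():
        raise ValueError("volumes and ICV must be strictly positive")
    return df


def icv_correct(volume, icv, mean_icv):
    """ICV proportions method: ``volume / icv * mean_icv``.

    ``mean_icv`` is computed once over all analyzed participants, so the
    correction is invariant to a common rescaling of every ICV.
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0) or mean_icv <= 0:
        raise ValueError("ICV values must be strictly positive")
    return volume / icv * mean_icv


def volume_change(
    pheno: pd.DataFrame,
    stratum: str = "group",
    mean_icv: float | None = None,
) -> pd.DataFrame:
    """Corrected V3 - V1 differences, standardized within each stratum.

    Returns one row per subject with, per subfield x hemisphere, the corrected
    visit volumes and the z-scored change (``z_{hemi}_{subfield}`` columns,
    sample SD with the n-1 denominator).  The pooled mean ICV defaults to the
    average over all analyzed participants and both visits.
    """
    df = validate_phenotypes(pheno).reset_index(drop=True)
    if mean_icv is None:
        mean_icv = float(pd.concat([df["icv_V1"], df["icv_V3"]]).mean())
    out = df[["subject_id", "group"]].copy()
    strata = df[stratum] if stratum in df.columns else pd.Series("all", index=df.index)
    for size in strata.value_counts().items():
        if size[1] < 3:
            raise ValueError(
                f"stratum {size[0]!r} has fewer than 3 subjects; cannot standardize"
            )
    for h in HEMISPHERES:
        for s in SUBFIELDS:
            c1 = icv_correct(df[f"{h}_{s}_V1"], df["icv_V1"], mean_icv)
            c3 = icv_correct(df[f"{h}_{s}_V3"], df["icv_V3"], mean_icv)
            change = c3 - c1
            z = np.full(len(df), np.nan)
            for g in strata.unique():
                sel = (strata == g).to_numpy()
                sd = change[sel].std(ddof=1)
                if sd == 0:
                    raise DegenerateVarianceError(
                        f"zero change variance in stratum {g!r} for {h} {s}"
                    )
                z[sel] = (change[sel] - change[sel].mean()) / sd
            out[f"corr_{h}_{s}_V1"] = c1
            out[f"corr_{h}_{s}_V3"] = c3
            out[f"z_{h}_{s}"] = z
    return out


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    note: str = "screening only: parameters estimated from the data"


def ks_normality(x) -> KSResult:
    """One-sample KS test of ``x`` against Normal(mean(x), sd(x)).

    The statistic is always in [0, 1]; the p-value uses the asymptotic KS
    distribution and, with estimated parameters, is anticonservative
    (a Lilliefors-type correction is deliberately not applied — this mirrors
    the screening use, not a formal test).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance sample")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return KSResult(statistic=float(stat), p_value=float(p))
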