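"""Variant- and subject-level quality control of imputed genotypes.

Filters run in a fixed, documented order — imputation INFO, variant call
rate, Hardy-Weinberg equilibrium, subject call rate, heterozygosity banding —
followed by report-only relatedness screening (identity-by-state) and an
LD-pruned ancestry PCA whose first components become regression covariates.
Thresholded comparisons follow the inclusion wording they implement: call
rates are kept on a strict ``>`` and a variant with INFO exactly at the
cutoff is retained.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DosageMatrix
from .scoring import ld_r2


@dataclass(frozen=True)
class QCConfig:
    snp_call_rate_min: float = 0.98
    subject_call_rate_min: float = 0.98
    hwe_p_min: float = 0.001
    het_sd: float = 3.0
    info_min: float = 0.7
    prune_window_variants: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.2
    relatedness_bound: float = 0.9
    n_pcs: int = 2

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "subject_call_rate_min", "info_min",
                     "prune_r2_max", "relatedness_bound"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if self.het_sd <= 0 or self.n_pcs <= 0:
            raise ValueError("het_sd and n_pcs must be positive")
        if self.prune_window_variants <= 0 or self.prune_step <= 0:
            raise ValueError("pruning window and step must be positive")


@dataclass
class QCReport:
    """Per-stage bookkeeping: what went in, what survived, what was dropped."""

    stages: list[dict] = field(default_factory=list)
    flagged_related_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    pca_variance_explained: list[float] = field(default_factory=list)

    def add_stage(self, name: str, axis: str, n_before: int, n_after: int,
                  dropped: list[str]) -> None:
        if n_before - n_after != len(dropped):
            raise ValueError(f"stage '{name}': dropped + retained != input")
        self.stages.append(
            {
                "stage": name,
                "axis": axis,
                "n_before": int(n_before),
                "n_after": int(n_after),
                "n_dropped": int(n_before - n_after),
                "dropped": list(dropped),
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": self.stages,
            "flagged_related_pairs": [
                {"a": a, "b": b, "ibs": ibs} for a, b, ibs in self.flagged_related_pairs
            ],
            "pca_variance_explained": self.pca_variance_explained,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_text(self) -> str:
        lines = ["genotype QC report", "==================", ""]
        for s in self.stages:
            lines.append(
                f"{s['stage']:<24s} {s['axis']:<8s} "
                f"{s['n_before']:>6d} -> {s['n_after']:>6d}  (-{s['n_dropped']})"
            )
        if self.flagged_related_pairs:
            lines.append("")
            lines.append("flagged related pairs (report only):")
            for a, b, ibs in self.flagged_related_pairs:
                lines.append(f"  {a} ~ {b}  IBS={ibs:.3f}")
        if self.pca_variance_explained:
            lines.append("")
            ve = ", ".join(f"{v:.4f}" for v in self.pca_variance_explained)
            lines.append(f"PCA variance explained: {ve}")
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------- filters

def filter_info(m: DosageMatrix, cfg: QCConfig) -> tuple[DosageMatrix, list[str]]:
    """Drop variants with imputation INFO strictly below the cutoff.

    A variant with unknown INFO (NaN) is kept: absence of the metric is not
    evidence of poor imputation for already-genotyped sites.
    """
    info = m.variants["info"].to_numpy()
    keep = np.isnan(info) | (info >= cfg.info_min)
    dropped = list(m.keys[~keep])
    return m.subset_variants(np.flatnonzero(keep)), dropped


def filter_call_rates(
    m: DosageMatrix, cfg: QCConfig
) -> tuple[DosageMatrix, list[str], list[str]]:
    """Variant call-rate filter first, then subject call-rate filter.

    Call rate is the non-missing fraction; both filters are strict
    (``rate > threshold`` survives).  The subject rates are computed on the
    post-variant-filter matrix.
    """
    v_keep = m.variant_call_rate() > cfg.snp_call_rate_min
    dropped_variants = list(m.keys[~v_keep])
    m2 = m.subset_variants(np.flatnonzero(v_keep))
    s_keep = m2.subject_call_rate() > cfg.subject_call_rate_min
    dropped_subjects = [s for s, k in zip(m2.subjects, s_keep) if not k]
    m3 = m2.subset_subjects(np.flatnonzero(s_keep))
    return m3, dropped_variants, dropped_subjects


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, each admissible heterozygote
    count ``h`` has probability proportional to the multinomial weight
    ``N! / (homref! het! homalt!) * 2**h``.  The p-value sums the
    probabilities of all configurations no more likely than the observed one.
    Weights are kept as exact integers so ties contribute exactly.
    """
    counts = (int(n_homref), int(n_het), int(n_homalt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_alt = 2 * counts[2] + counts[1]
    parity = n_alt % 2

    def weight(h: int) -> int:
        homalt = (n_alt - h) // 2
        homref = n - h - homalt
        if homalt < 0 or homref < 0:
            return 0
        return math.comb(n, homalt) * math.comb(n - homalt, h) * (2 ** h)

    w_obs = weight(counts[1])
    total = 0
    tail = 0
    for h in range(parity, min(n_alt, 2 * n - n_alt) + 1, 2):
        w = weight(h)
        total += w
        if w <= w_obs:
            tail += w
    return float(Fraction(tail, total))


def filter_hwe(
    m: DosageMatrix, cfg: QCConfig
) -> tuple[DosageMatrix, list[str]]:
    """Drop variants whose exact HWE p-value falls at or below the cutoff.

    The test runs on hard-called genotypes (rounded dosages), the natural
    substrate for array-style HWE screening.
    """
    hard = m.hardcalls()
    keep = np.ones(m.n_variants, dtype=bool)
    for j in range(m.n_variants):
        g = hard[:, j]
        g = g[~np.isnan(g)]
        if g.size == 0:
            continue
        counts = [(g == c).sum() for c in (0.0, 1.0, 2.0)]
        keep[j] = hwe_exact_test(*counts) > cfg.hwe_p_min
    dropped = list(m.keys[~keep])
    return m.subset_variants(np.flatnonzero(keep)), dropped


def heterozygosity_rates(m: DosageMatrix) -> np.ndarray:
    """Per-subject fraction of heterozygous hard calls among non-missing."""
    hard = m.hardcalls()
    het = hard == 1.0
    obs = ~np.isnan(hard)
    with np.errstate(invalid="ignore"):
        return np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), np.nan)


def filter_heterozygosity(
    m: DosageMatrix, cfg: QCConfig
) -> tuple[DosageMatrix, list[str]]:
    """Single-pass removal of subjects outside mean +/- k·SD heterozygosity.

    Mean and SD come from the input subject set once; the band is not
    re-estimated after removals.  With zero SD the band degenerates to the
    mean and nobody is removed.
    """
    rates = heterozygosity_rates(m)
    mean = np.nanmean(rates)
    sd = np.nanstd(rates, ddof=1) if m.n_subjects > 1 else 0.0
    lo, hi = mean - cfg.het_sd * sd, mean + cfg.het_sd * sd
    keep = (rates >= lo) & (rates <= hi)
    keep |= np.isnan(rates)
    dropped = [s for s, k in zip(m.subjects, keep) if not k]
    return m.subset_subjects(np.flatnonzero(keep)), dropped


# -------------------------------------------------------------- relatedness

def ibs_matrix(m: DosageMatrix) -> pd.DataFrame:
    """Identity-by-state similarity: ``1 - mean(|g_i - g_j|) / 2`` per pair.

    Computed on hard calls over co-observed variants; the diagonal is 1 and
    the matrix symmetric by construction.
    """
    hard = m.hardcalls()
    n = m.n_subjects
    out = np.ones((n, n))
    for i in range(n):
        gi = hard[i]
        for j in range(i + 1, n):
            gj = hard[j]
            ok = ~(np.isnan(gi) | np.isnan(gj))
            if ok.sum() == 0:
                val = np.nan
            else:
                val = 1.0 - np.abs(gi[ok] - gj[ok]).mean() / 2.0
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=m.subjects, columns=m.subjects)


def flag_related_pairs(
    ibs: pd.DataFrame, bound: float
) -> list[tuple[str, str, float]]:
    """Pairs above the relatedness bound, report-only (nobody is excluded)."""
    flagged = []
    subjects = list(ibs.index)
    vals = ibs.to_numpy()
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            if vals[i, j] > bound:
                flagged.append((subjects[i], subjects[j], float(vals[i, j])))
    return flagged


# ----------------------------------------------------------------- pruning

def ld_prune(m: DosageMatrix, cfg: QCConfig) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns surviving variant indices.

    Variants are processed per chromosome in position order.  Within each
    window of ``prune_window_variants`` variants, for every surviving pair
    with r² above the bound the later-positioned variant is dropped; the
    window then advances by ``prune_step``.  All surviving within-window
    pairs satisfy the r² bound.
    """
    order = m.variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    chroms = m.variants["chrom"].astype(str).to_numpy()
    removed = np.zeros(m.n_variants, dtype=bool)
    for c in pd.unique(chroms[order]):
        on_c = order[chroms[order] == c]
        start = 0
        while start < on_c.size:
            window = on_c[start : start + cfg.prune_window_variants]
            for a_i in range(len(window)):
                i = window[a_i]
                if removed[i]:
                    continue
                for a_j in range(a_i + 1, len(window)):
                    j = window[a_j]
                    if removed[j]:
                        continue
                    if ld_r2(m.dosages[:, i], m.dosages[:, j]) > cfg.prune_r2_max:
                        removed[j] = True
            if start + cfg.prune_window_variants >= on_c.size:
                break
            start += cfg.prune_step
    return np.flatnonzero(~removed)


# --------------------------------------------------------------------- PCA

def ancestry_pca(
    m: DosageMatrix, pruned: np.ndarray, cfg: QCConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of standardized dosages at the pruned variants.

    Each variant is centered at twice its ALT frequency and scaled by
    ``sqrt(2 f (1 - f))`` (zero-variance variants skipped, missing values set
    to the mean).  Scores are the top-``n_pcs`` left singular vectors scaled
    by their singular values; each component's sign is fixed so that its
    largest-magnitude variant loading is positive.  Returns the score table
    and the variance-explained fractions (non-increasing).
    """
    sub = m.subset_variants(pruned)
    d = sub.dosages.copy()
    f = sub.alt_frequency()
    scale = np.sqrt(2.0 * f * (1.0 - f))
    usable = np.isfinite(scale) & (scale > 0)
    d = d[:, usable]
    f = f[usable]
    scale = scale[usable]
    x = (d - 2.0 * f) / scale
    x = np.nan_to_num(x)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(cfg.n_pcs, s.size)
    scores = u[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            scores[:, c] = -scores[:, c]
    var_exp = (s[:k] ** 2) / (s ** 2).sum() if s.size else np.zeros(0)
    table = pd.DataFrame(
        scores,
        index=pd.Index(m.subjects, name="subject_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return table, var_exp


# ------------------------------------------------------------ orchestration

def run_qc(
    m: DosageMatrix, cfg: QCConfig | None = None
) -> tuple[DosageMatrix, QCReport, pd.DataFrame]:
    """Full QC pass: filters in fixed order, relatedness screen, ancestry PCA.

    Returns the cleaned matrix, the stage-by-stage report, and the per-subject
    principal-component scores (columns PC1..PCk).
    """
    cfg = cfg or QCConfig()
    report = QCReport()

    m1, dropped = filter_info(m, cfg)
    report.add_stage("info", "variants", m.n_variants, m1.n_variants, dropped)

    v_keep = m1.variant_call_rate() > cfg.snp_call_rate_min
    dv = list(m1.keys[~v_keep])
    m2 = m1.subset_variants(np.flatnonzero(v_keep))
    report.add_stage("variant_call_rate", "variants", m1.n_variants,
                     m2.n_variants, dv)

    m3, dropped = filter_hwe(m2, cfg)
    report.add_stage("hwe", "variants", m2.n_variants, m3.n_variants, dropped)

    s_keep = m3.subject_call_rate() > cfg.subject_call_rate_min
    ds = [s for s, k in zip(m3.subjects, s_keep) if not k]
    m3b = m3.subset_subjects(np.flatnonzero(s_keep))
    report.add_stage("subject_call_rate", "subjects", m3.n_subjects,
                     m3b.n_subjects, ds)

    m4, dropped = filter_heterozygosity(m3b, cfg)
    report.add_stage("heterozygosity", "subjects", m3b.n_subjects, m4.n_subjects,
                     dropped)

    ibs = ibs_matrix(m4)
    report.flagged_related_pairs = flag_related_pairs(ibs, cfg.relatedness_bound)

    pruned = ld_prune(m4, cfg)
    pcs, var_exp = ancestry_pca(m4, pruned, cfg)
    report.pca_variance_explained = [float(v) for v in var_exp]
    return m4, report, pcs
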