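"""Gene-set restricted polygenic risk scoring.

The score for one cell type is built in four steps: restrict the discovery
summary statistics to variants inside the cell type's genes (plus a flanking
window), orient each effect allele against the target cohort's REF/ALT
coding, thin the variants to approximately independent index signals by
greedy LD clumping, and finally sum ``dosage x log(odds ratio)`` per subject
at a ladder of discovery p-value thresholds.  Clumping runs once on the full
gene-set variant list; the thresholds then select nested subsets of the
clumped variants, so scored variant sets are nested across thresholds by
construction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AMBIGUOUS_PAIRS,
    DosageMatrix,
    GeneAnnotation,
    GeneSet,
    PRSProfile,
    SummaryStats,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class ScoringConfig:
    """Window, clumping and threshold parameters for score construction."""

    window_bp: int = 10_000
    clump_kb: int = 500
    clump_r2: float = 0.1
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    standardize_scores: bool = True
    keep_ambiguous: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if t[-1] != 1.0:
            raise ValueError("last threshold must be 1")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must lie in [0, 1]")


# ------------------------------------------------------------ gene windows

def variants_in_gene_windows(
    variants: pd.DataFrame,
    ann: GeneAnnotation,
    genes: list[str] | tuple[str, ...],
    window_bp: int,
) -> np.ndarray:
    """Boolean mask of variants inside any listed gene's flanked interval.

    A variant is in if its position lies in ``[start - window_bp,
    end + window_bp]`` (clipped at 1) on the gene's chromosome.  Unresolvable
    gene symbols are logged and skipped, never fatal.
    """
    wanted = set(genes)
    found = ann.table[ann.table["gene"].isin(wanted)]
    missing = wanted - set(found["gene"])
    if missing:
        logger.warning(
            "%d gene symbols not in the annotation (e.g. %s)",
            len(missing), sorted(missing)[:3],
        )
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    for c, sub in found.groupby("chrom", sort=False):
        lo = np.maximum(sub["start"].to_numpy() - window_bp, 1)
        hi = sub["end"].to_numpy() + window_bp
        on_c = chrom == str(c)
        if not on_c.any():
            continue
        p = pos[on_c]
        hit = np.zeros(p.size, dtype=bool)
        for a, b in zip(lo, hi):
            hit |= (p >= a) & (p <= b)
        mask[np.flatnonzero(on_c)[hit]] = True
    return mask


def map_geneset_to_variants(
    ann: GeneAnnotation,
    gs: GeneSet,
    stats: SummaryStats,
    cfg: ScoringConfig,
) -> np.ndarray:
    """Indices of summary-stat rows within the gene set's flanked intervals.

    Variants hit by several overlapping gene windows appear once.  An empty
    result is a warning, not an error: a small gene set may simply contain no
    genotyped variants.
    """
    mask = variants_in_gene_windows(
        stats.table[["chrom", "pos"]], ann, gs.genes, cfg.window_bp
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("gene set '%s' maps to no summary-stat variants", gs.label)
    return idx


def geneset_overlap(a: GeneSet, b: GeneSet):
    """Pairwise shared-gene percentage.

    For equal-size sets (the usual case: both are a top-x% list) this is
    ``100 * |a & b| / size``; for unequal sizes both directed percentages are
    returned as a tuple.
    """
    shared = len(a.members & b.members)
    if len(a) == len(b):
        return 100.0 * shared / len(a)
    return (100.0 * shared / len(a), 100.0 * shared / len(b))


# --------------------------------------------------------- allele alignment

def align_effect_alleles(
    stats: SummaryStats, m: DosageMatrix, keep_ambiguous: bool = False
) -> pd.DataFrame:
    """Orient summary-stat effect alleles against the cohort's REF/ALT coding.

    For each variant shared by position: if the effect allele is the cohort
    ALT the dosage is used as is; if it is the REF the dosage is
    complemented (``2 - dosage``) at scoring time, recorded here as
    ``flip=True``.  Allele pairs that do not match {REF, ALT} are dropped
    with a log entry, as are strand-ambiguous A/T and C/G pairs unless
    ``keep_ambiguous``.  Rows with a missing weight (unestimated odds ratio)
    are dropped too.  Returns a table with one row per scorable variant:
    key, chrom, pos, matrix column, weight (natural-log odds ratio on the
    effect allele), flip flag, and discovery p-value.
    """
    cohort = m.variants.reset_index().rename(columns={"index": "matrix_col"})
    merged = stats.table.merge(
        cohort, on=["chrom", "pos"], how="inner", suffixes=("", "_cohort")
    )
    n_unmatched = len(stats.table) - len(merged)
    if n_unmatched:
        logger.info("%d summary-stat variants absent from the cohort", n_unmatched)

    rows = []
    n_mismatch = n_ambig = n_noweight = 0
    for rec in merged.itertuples(index=False):
        pair = frozenset({rec.a1, rec.a2})
        if pair != frozenset({rec.ref, rec.alt}):
            n_mismatch += 1
            continue
        if pair in AMBIGUOUS_PAIRS and not keep_ambiguous:
            n_ambig += 1
            continue
        if not np.isfinite(rec.odds_ratio):
            n_noweight += 1
            continue
        rows.append(
            {
                "key": f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "matrix_col": rec.matrix_col,
                "weight": float(np.log(rec.odds_ratio)),
                "flip": rec.a1 == rec.ref,
                "p": float(rec.p),
            }
        )
    if n_mismatch:
        logger.warning("%d variants dropped: allele pair mismatch", n_mismatch)
    if n_ambig:
        logger.info("%d strand-ambiguous variants dropped", n_ambig)
    if n_noweight:
        logger.info("%d variants dropped: missing weight", n_noweight)
    cols = ["key", "chrom", "pos", "matrix_col", "weight", "flip", "p"]
    return pd.DataFrame(rows, columns=cols)


def oriented_dosages(m: DosageMatrix, aligned: pd.DataFrame) -> np.ndarray:
    """Effect-allele dosages for the aligned variants (flips applied)."""
    cols = aligned["matrix_col"].to_numpy()
    d = m.dosages[:, cols].copy()
    flip = aligned["flip"].to_numpy(dtype=bool)
    d[:, flip] = 2.0 - d[:, flip]
    return d


# ------------------------------------------------------------------- LD

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over co-observed subjects.

    Zero-variance input (monomorphic in the co-observed subset) is defined as
    r² = 0 with a warning; the pair then never blocks each other in clumping.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0.0 or y.std() == 0.0:
        warnings.warn("zero-variance dosage vector in ld_r2; returning 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    variants: pd.DataFrame, m: DosageMatrix, cfg: ScoringConfig
) -> pd.DataFrame:
    """Greedy LD clumping: best-p index variants absorb their LD neighbours.

    ``variants`` needs columns chrom, pos, p and matrix_col.  Repeatedly the
    unassigned variant with the smallest p (ties broken by chrom, pos) becomes
    an index; every unassigned variant on the same chromosome within
    +/- ``clump_kb`` kilobases with r² > ``clump_r2`` against the index is
    absorbed.  Returns the index variants sorted by (p, chrom, pos).
    """
    df = variants.reset_index(drop=True)
    order = df.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).index.to_numpy()
    window = cfg.clump_kb * 1000
    assigned = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    cols = df["matrix_col"].to_numpy()
    index_rows: list[int] = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        index_rows.append(i)
        near = np.flatnonzero(
            (~assigned)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        for j in near:
            if ld_r2(m.dosages[:, cols[i]], m.dosages[:, cols[j]]) > cfg.clump_r2:
                assigned[j] = True
    out = df.loc[index_rows]
    return out.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )


# ------------------------------------------------------------------ scores

def compute_prs(
    m: DosageMatrix,
    aligned: pd.DataFrame,
    clumped: pd.DataFrame,
    cfg: ScoringConfig,
    label: str = "PRS",
) -> PRSProfile:
    """Per-subject weighted dosage sums at each p-value threshold.

    ``score(subject, t) = sum over clumped variants with p <= t of
    effect-allele dosage x log(odds ratio)``.  A missing dosage at a variant
    is replaced by that variant's mean observed effect-allele dosage.  With
    ``standardize_scores`` each threshold column is z-scored across the
    subjects of the matrix; zero-variant (or zero-variance) columns stay at
    zero and are flagged.
    """
    sel = aligned[aligned["key"].isin(set(clumped_keys(clumped, aligned)))]
    sel = sel.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    d = oriented_dosages(m, sel)
    if d.size:
        col_mean = np.nanmean(d, axis=0)
        nan_at = np.isnan(d)
        d[nan_at] = np.broadcast_to(col_mean, d.shape)[nan_at]
    w = sel["weight"].to_numpy()
    p = sel["p"].to_numpy()
    thresholds = tuple(float(t) for t in cfg.thresholds)
    raw = np.zeros((m.n_subjects, len(thresholds)))
    counts: list[int] = []
    keys_per_t: list[list[str]] = []
    zero_flagged: list[float] = []
    for k, t in enumerate(thresholds):
        in_t = p <= t
        counts.append(int(in_t.sum()))
        keys_per_t.append(list(sel.loc[in_t, "key"]))
        if in_t.any():
            raw[:, k] = d[:, in_t] @ w[in_t]
        else:
            zero_flagged.append(t)
            logger.warning(
                "gene set '%s': no variants at threshold %g; zero column", label, t
            )
    scores = raw.copy()
    if cfg.standardize_scores:
        for k in range(len(thresholds)):
            sd = scores[:, k].std(ddof=1) if m.n_subjects > 1 else 0.0
            if sd > 0:
                scores[:, k] = (scores[:, k] - scores[:, k].mean()) / sd
            else:
                scores[:, k] = 0.0
                if thresholds[k] not in zero_flagged:
                    zero_flagged.append(thresholds[k])
    return PRSProfile(
        label=label,
        subjects=list(m.subjects),
        thresholds=thresholds,
        raw=raw,
        scores=scores,
        n_variants=counts,
        variant_keys=keys_per_t,
        zero_variance_thresholds=sorted(zero_flagged),
    )


def clumped_keys(clumped: pd.DataFrame, aligned: pd.DataFrame) -> list[str]:
    if "key" in clumped.columns:
        return list(clumped["key"])
    merged = clumped.merge(aligned, on=["chrom", "pos", "matrix_col"], how="left")
    return list(merged["key"])


def score_gene_set(
    stats: SummaryStats,
    m: DosageMatrix,
    ann: GeneAnnotation,
    gs: GeneSet,
    cfg: ScoringConfig,
) -> PRSProfile:
    """Full scoring path for one gene set: map, align, clump, sum."""
    idx = map_geneset_to_variants(ann, gs, stats, cfg)
    restricted = SummaryStats(table=stats.table.iloc[idx])
    aligned = align_effect_alleles(stats=restricted, m=m, keep_ambiguous=cfg.keep_ambiguous)
    if aligned.empty:
        logger.warning("gene set '%s': nothing scorable after alignment", gs.label)
        clumped = aligned
    else:
        clumped = clump(aligned, m, cfg)
    return compute_prs(m, aligned, clumped, cfg, label=gs.label)


def score_gene_sets(
    stats: SummaryStats,
    m: DosageMatrix,
    ann: GeneAnnotation,
    sets: list[GeneSet],
    cfg: ScoringConfig,
) -> dict[str, PRSProfile]:
    return {gs.label: score_gene_set(stats, m, ann, gs, cfg) for gs in sets}
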