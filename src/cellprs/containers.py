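"""Core in-memory containers shared across the pipeline.

The pipeline moves three kinds of data around: per-subject genotype dosages
(the target cohort), per-variant GWAS summary statistics (the discovery
cohort), and gene-level annotation restricting which variants enter a cell
type-specific score.  Each container is a light dataclass around numpy/pandas
structures with the invariants checked at construction time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: variant table columns carried by a DosageMatrix
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "info")

#: allele pairs that cannot be strand-resolved from summary statistics alone
AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: hippocampal subfields and hemispheres used throughout
SUBFIELDS = ("CA1", "CA23", "CA4DG")
HEMISPHERES = ("left", "right")

#: analysis groups: multi-episode patients with aerobic exercise, patients with
#: the non-aerobic control intervention, and healthy controls who exercised
GROUPS = ("SCZ-exercise", "SCZ-control", "HC-exercise")


def variant_key_series(df: pd.DataFrame, a1: str = "ref", a2: str = "alt") -> pd.Series:
    """``chrom:pos:allele1:allele2`` string key per row of a variant table."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df[a1].astype(str)
        + ":"
        + df[a2].astype(str)
    )


@dataclass
class DosageMatrix:
    """Subjects x variants expected ALT-allele counts in [0, 2].

    ``dosages`` is a float array with NaN marking missing calls.  ``variants``
    holds one row per variant with columns chrom, pos (1-based), ref, alt and
    the imputation INFO score (NaN when unknown).  Duplicate subject ids or
    variant keys are rejected, as are dosage values outside [0, 2].
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.variants = self.variants.reset_index(drop=True).copy()
        if "info" not in self.variants.columns:
            self.variants["info"] = np.nan
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        keys = variant_key_series(self.variants)
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant key {dup}")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and (observed.min() < 0.0 or observed.max() > 2.0):
            raise ValueError("dosage values outside [0, 2]")

    # ------------------------------------------------------------------ sizes
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def keys(self) -> pd.Series:
        return variant_key_series(self.variants)

    # ------------------------------------------------------------- statistics
    def hardcalls(self) -> np.ndarray:
        """Genotypes rounded to the nearest integer count; NaN preserved."""
        return np.rint(self.dosages)

    def alt_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency from observed dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subject_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    # ---------------------------------------------------------------- slicing
    def subset_variants(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(
            subjects=list(self.subjects),
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
        )

    def subset_subjects(self, index) -> "DosageMatrix":
        index = np.asarray(index)
        return DosageMatrix(
            subjects=[self.subjects[i] for i in index],
            variants=self.variants,
            dosages=self.dosages[index, :],
        )

    def equals(self, other: "DosageMatrix", atol: float = 0.0) -> bool:
        if self.subjects != other.subjects:
            return False
        if not self.keys.equals(other.keys):
            return False
        if not np.allclose(
            self.variants["info"].to_numpy(),
            other.variants["info"].to_numpy(),
            atol=max(atol, 1e-9),
            equal_nan=True,
        ):
            return False
        return np.allclose(self.dosages, other.dosages, atol=atol, equal_nan=True)


@dataclass
class SummaryStats:
    """Discovery-GWAS per-variant effect sizes.

    ``table`` columns: snp, chrom, pos, a1 (effect allele), a2 (other allele),
    odds_ratio, p, info.  A missing odds ratio (NaN) flags a variant whose
    weight could not be estimated (e.g. monomorphic in the discovery sample);
    such rows are carried along but never scored.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True).copy()
        required = ["snp", "chrom", "pos", "a1", "a2", "odds_ratio", "p"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics lack columns {missing}")
        if "info" not in self.table.columns:
            self.table["info"] = np.nan
        keys = variant_key_series(self.table, a1="a1", a2="a2")
        if keys.duplicated().any():
            raise ValueError("duplicate variant keys in summary statistics")
        has_or = self.table["odds_ratio"].notna()
        orr = self.table.loc[has_or, "odds_ratio"]
        if not np.all(np.isfinite(orr)) or (orr <= 0).any():
            raise ValueError("odds ratios must be finite and positive")
        pvals = self.table.loc[has_or, "p"]
        if ((pvals <= 0) | (pvals > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def weights(self) -> pd.Series:
        """Natural-log odds ratios (the per-allele score weights)."""
        return np.log(self.table["odds_ratio"])

    @property
    def n_variants(self) -> int:
        return len(self.table)


@dataclass
class GeneAnnotation:
    """Gene symbol -> genomic interval map (1-based inclusive coordinates)."""

    table: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True).copy()
        for c in ("gene", "chrom", "start", "end"):
            if c not in self.table.columns:
                raise ValueError(f"gene annotation lacks column '{c}'")
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate gene symbols in annotation")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene interval with start > end")

    @property
    def n_genes(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene symbols (one cell type's specific genes)."""

    label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set '{self.label}' is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set '{self.label}' contains duplicates")

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PRSProfile:
    """Per-subject polygenic scores for one gene set across p-value thresholds.

    ``raw`` holds the plain weighted dosage sums, ``scores`` the per-threshold
    z-scored columns actually used as the regression exposure.  Variant sets
    are nested across increasing thresholds by construction.
    """

    label: str
    subjects: list[str]
    thresholds: tuple[float, ...]
    raw: np.ndarray          # (n_subjects, n_thresholds)
    scores: np.ndarray       # standardized copy of raw (or raw when disabled)
    n_variants: list[int]    # per threshold
    variant_keys: list[list[str]]  # per threshold, nested
    zero_variance_thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_variants) < 0):
            raise ValueError("variant counts must be non-decreasing in threshold")

    def as_frame(self, standardized: bool = True) -> pd.DataFrame:
        mat = self.scores if standardized else self.raw
        cols = [f"pt_{t:g}" for t in self.thresholds]
        return pd.DataFrame(mat, index=pd.Index(self.subjects, name="subject_id"), columns=cols)


@dataclass
class GroundTruth:
    """Generative truth for one synthetic cohort.

    true_beta: per-variant true log odds ratio (index = variant key).
    true_prs:  per-subject dosage-weighted sum of true_beta (index = subject).
    groups:    per-subject analysis group label.
    planted:   dict with the planted regression coefficient and the single
               (group, subfield, hemisphere) cell it acts on.
    """

    true_beta: pd.Series
    true_prs: pd.Series
    groups: pd.Series
    planted: dict
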