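"""Synthetic cohort generator with planted ground truth.

Every downstream stage of the pipeline (genotype QC, gene-set restricted
scoring, phenotype preparation, permutation regression) is exercised on
cohorts produced here, so the generator plants a fully known truth:

* **Genotypes** follow a block-exchangeable haplotype-copying model: within
  each linkage block every panel haplotype copies one of a small number of
  founder haplotypes end to end (no recombination inside a block), plus a
  small mutation rate.  This produces strong within-block linkage
  disequilibrium and essentially independent blocks, which is the minimal
  structure that makes LD clumping non-trivial while keeping exact oracles
  tractable.
* **Summary statistics** are drawn around true per-variant log odds ratios
  with the standard error implied by a large discovery case/control sample,
  so genuinely causal variants surface at stringent p-value thresholds.
* **Gene sets** for the three cell types (radial glia ``Rad``, oligodendrocyte
  precursors ``OPC``, mature oligodendrocytes ``Oli``) are built with
  controlled pairwise overlap.
* **Phenotypes** are two-visit hippocampal subfield volumes whose
  ICV-scaled standardized change carries a planted regression coefficient of
  the true polygenic score in exactly one (group, subfield, hemisphere) cell
  — by default the left CA4/DG of the exercising patient group.

All randomness flows from a single seed through a spawned SeedSequence
hierarchy, so identical configurations give byte-identical output files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    GROUPS,
    HEMISPHERES,
    SUBFIELDS,
    DosageMatrix,
    GeneAnnotation,
    GeneSet,
    GroundTruth,
    SummaryStats,
)
from .scoring import variants_in_gene_windows

__all__ = [
    "SimConfig",
    "HaplotypePanel",
    "SimulatedCohort",
    "simulate_haplotype_panel",
    "simulate_genotypes",
    "simulate_annotation_and_sets",
    "simulate_summary_stats",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_two_population_genotypes",
    "build_gene_sets_with_overlap",
    "synthetic_reference_gene_sets",
]

#: non strand-ambiguous ordered REF/ALT pairs
_SAFE_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_ALLELE_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: baseline subfield volumes (mm^3), FreeSurfer-5.3-style magnitudes
_SUBFIELD_MEAN_MM3 = {"CA1": 322.0, "CA23": 976.0, "CA4DG": 556.0}
_ICV_REF_MM3 = 1.5e6

#: per-variant spacing and per-block offset; blocks sit on separate
#: chromosomes and far beyond the 500 kb clumping window in any case
_VARIANT_SPACING_BP = 1_000
_BLOCK_OFFSET_BP = 10_000_000

_CELL_TYPE_LABELS = ("Rad", "OPC", "Oli")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    The cohort emulates a three-group exercise-intervention study scored
    against a very large discovery GWAS.  Defaults give 60 subjects per group,
    20 independent 25-variant linkage blocks, a planted standardized effect of
    -0.6 of the true polygenic score on volume change in the left CA4/DG of
    the exercising patient group, and gene-set pairwise overlaps matching the
    published Rad-OPC / OPC-Oli / Rad-Oli fractions.
    """

    n_blocks: int = 20
    variants_per_block: int = 25
    n_haplotypes: int = 200
    n_founders: int = 8
    mutation_rate: float = 0.01
    maf_min: float = 0.05
    maf_max: float = 0.5
    n_subjects_per_group: int = 60
    groups: tuple[str, ...] = GROUPS
    n_cases_discovery: int = 40_675
    n_controls_discovery: int = 64_643
    causal_fraction: float = 0.3
    true_effect_sd: float = 0.05
    prs_volume_effect: float = -0.6
    residual_sd: float = 0.8
    planted_group: str = "SCZ-exercise"
    planted_subfield: str = "CA4DG"
    planted_hemisphere: str = "left"
    genes_per_block: int = 8
    set_size: int = 30
    pairwise_overlap_target: float | tuple[float, float, float] = (0.172, 0.199, 0.032)
    window_bp: int = 10_000
    info_low_fraction: float = 0.1
    effect_allele_flip_prob: float = 0.5
    ambiguous_fraction: float = 0.0
    dosage_noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("require 0 < maf_min <= maf_max <= 0.5")
        if not (0.0 <= self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in [0, 1]")
        for t in self.overlap_targets:
            if not (0.0 <= t < 1.0):
                raise ValueError("pairwise overlap targets must lie in [0, 1)")
        for name in ("n_blocks", "variants_per_block", "n_haplotypes",
                     "n_founders", "n_subjects_per_group", "genes_per_block",
                     "set_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_group not in self.groups:
            raise ValueError(f"planted_group {self.planted_group!r} not in groups")
        if self.planted_subfield not in SUBFIELDS:
            raise ValueError(f"unknown subfield {self.planted_subfield!r}")
        if self.planted_hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.planted_hemisphere!r}")

    @property
    def overlap_targets(self) -> tuple[float, float, float]:
        """Targets for the Rad-OPC, OPC-Oli and Rad-Oli shared fractions."""
        t = self.pairwise_overlap_target
        if np.isscalar(t):
            return (float(t),) * 3
        return tuple(float(x) for x in t)  # type: ignore[return-value]

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_group * len(self.groups)


@dataclass
class HaplotypePanel:
    """Ancestral haplotype panel: binary alleles plus variant coordinates."""

    alleles: np.ndarray          # (n_haplotypes, n_variants) in {0, 1}
    variants: pd.DataFrame       # chrom, pos, ref, alt
    block: np.ndarray            # block index per variant

    def __post_init__(self) -> None:
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def frequency(self) -> np.ndarray:
        """Panel ALT-allele frequency per variant."""
        return self.alleles.mean(axis=0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------------- panel

def simulate_haplotype_panel(
    cfg: SimConfig, seed=None, max_block_retries: int = 50
) -> HaplotypePanel:
    """Draw the ancestral haplotype panel.

    Per block: founder haplotypes are i.i.d. Bernoulli draws at frequencies
    uniform on [maf_min, maf_max]; each panel haplotype copies one founder
    end to end and then mutates each site independently.  Candidate variants
    whose realized minor-allele frequency leaves [maf_min, maf_max] are
    filtered out; a block that cannot supply enough in-bound variants after a
    capped number of redraws raises instead of retrying silently forever.
    """
    rng = _as_rng(cfg.seed if seed is None else seed)
    block_alleles: list[np.ndarray] = []
    rows: list[dict] = []
    oversample = 3
    for b in range(cfg.n_blocks):
        kept = None
        for _ in range(max_block_retries):
            n_cand = oversample * cfg.variants_per_block
            freqs = rng.uniform(cfg.maf_min, cfg.maf_max, size=n_cand)
            founders = (rng.random((cfg.n_founders, n_cand)) < freqs).astype(np.int8)
            picks = rng.integers(0, cfg.n_founders, size=cfg.n_haplotypes)
            haps = founders[picks]
            if cfg.mutation_rate > 0:
                flips = rng.random(haps.shape) < cfg.mutation_rate
                haps = np.where(flips, 1 - haps, haps).astype(np.int8)
            f = haps.mean(axis=0)
            maf = np.minimum(f, 1.0 - f)
            ok = np.flatnonzero((maf >= cfg.maf_min) & (maf <= cfg.maf_max))
            if ok.size >= cfg.variants_per_block:
                kept = haps[:, ok[: cfg.variants_per_block]]
                break
        if kept is None:
            raise ValueError(
                f"block {b}: could not realize {cfg.variants_per_block} variants "
                f"with MAF in [{cfg.maf_min}, {cfg.maf_max}] after "
                f"{max_block_retries} redraws; relax the bounds or enlarge the panel"
            )
        block_alleles.append(kept)
        for j in range(cfg.variants_per_block):
            if cfg.ambiguous_fraction > 0 and rng.random() < cfg.ambiguous_fraction:
                ref, alt = _AMBIGUOUS_ALLELE_PAIRS[
                    rng.integers(0, len(_AMBIGUOUS_ALLELE_PAIRS))
                ]
            else:
                ref, alt = _SAFE_ALLELE_PAIRS[rng.integers(0, len(_SAFE_ALLELE_PAIRS))]
            rows.append(
                {
                    "chrom": str(b + 1),
                    "pos": _BLOCK_OFFSET_BP * b + _VARIANT_SPACING_BP * j + 1,
                    "ref": ref,
                    "alt": alt,
                }
            )
    alleles = np.concatenate(block_alleles, axis=1)
    variants = pd.DataFrame(rows)
    block = np.repeat(np.arange(cfg.n_blocks), cfg.variants_per_block)
    return HaplotypePanel(alleles=alleles, variants=variants, block=block)


# --------------------------------------------------------------- genotypes

def simulate_genotypes(
    panel: HaplotypePanel,
    n_subjects: int,
    seed,
    dosage_noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    subject_prefix: str = "S",
) -> DosageMatrix:
    """Draw diploid subjects: two panel haplotypes with replacement each.

    Dosages are exact allele counts in {0, 1, 2}; optional Gaussian dosage
    noise (clipped to [0, 2], two-decimal precision, off by default) emulates
    imputation uncertainty, and ``missing_rate`` masks random calls.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if panel.n_variants == 0:
        raise ValueError("empty haplotype panel")
    rng = _as_rng(seed)
    idx = rng.integers(0, panel.n_haplotypes, size=(n_subjects, 2))
    dos = (panel.alleles[idx[:, 0]] + panel.alleles[idx[:, 1]]).astype(float)
    if dosage_noise_sd > 0:
        dos = np.clip(dos + rng.normal(0.0, dosage_noise_sd, size=dos.shape), 0.0, 2.0)
        dos = np.round(dos, 2)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    subjects = [f"{subject_prefix}{i + 1:04d}" for i in range(n_subjects)]
    variants = panel.variants.copy()
    variants["info"] = np.nan
    return DosageMatrix(subjects=subjects, variants=variants, dosages=dos)


def simulate_two_population_genotypes(
    cfg: SimConfig, n_per_pop: int, seed
) -> tuple[DosageMatrix, np.ndarray]:
    """Two diverged subpopulations sharing variant coordinates.

    Each subpopulation has its own independently drawn founder frequencies,
    giving large allele-frequency differences at most variants — a stress
    fixture for ancestry PCA.  Returns the stacked matrix and 0/1 labels.
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    panel_a = simulate_haplotype_panel(cfg, np.random.default_rng(kids[0]))
    panel_b = simulate_haplotype_panel(cfg, np.random.default_rng(kids[1]))
    ga = simulate_genotypes(panel_a, n_per_pop, np.random.default_rng(kids[2]),
                            subject_prefix="A")
    gb = simulate_genotypes(panel_b, n_per_pop, np.random.default_rng(kids[3]),
                            subject_prefix="B")
    dosages = np.vstack([ga.dosages, gb.dosages])
    m = DosageMatrix(
        subjects=ga.subjects + gb.subjects,
        variants=ga.variants,  # shared coordinates; panel A's alleles
        dosages=dosages,
    )
    labels = np.repeat([0, 1], n_per_pop)
    return m, labels


# ------------------------------------------------------- genes & gene sets

def build_gene_sets_with_overlap(
    pool: list[str],
    set_size: int,
    overlap_targets: tuple[float, float, float],
    rng: np.random.Generator,
    labels: tuple[str, str, str] = _CELL_TYPE_LABELS,
) -> list[GeneSet]:
    """Three equal-size gene sets with prescribed pairwise shared fractions.

    Shared genes are allocated to disjoint pairwise-intersection chunks (the
    triple intersection is empty), so each realized overlap equals
    ``round(target * set_size)`` genes exactly.
    """
    s_ab, s_bc, s_ac = (int(round(t * set_size)) for t in overlap_targets)
    uniq_a = set_size - s_ab - s_ac
    uniq_b = set_size - s_ab - s_bc
    uniq_c = set_size - s_bc - s_ac
    if min(uniq_a, uniq_b, uniq_c) < 0:
        raise ValueError("overlap targets exceed the set size")
    need = s_ab + s_bc + s_ac + uniq_a + uniq_b + uniq_c
    if need > len(pool):
        raise ValueError(
            f"gene pool of {len(pool)} cannot host three sets of {set_size} "
            f"with the requested overlaps ({need} distinct genes needed)"
        )
    order = rng.permutation(len(pool))
    it = iter(order)

    def take(k: int) -> list[str]:
        return [pool[next(it)] for _ in range(k)]

    ab, bc, ac = take(s_ab), take(s_bc), take(s_ac)
    a_only, b_only, c_only = take(uniq_a), take(uniq_b), take(uniq_c)
    sets = [
        GeneSet(label=labels[0], genes=tuple(sorted(a_only + ab + ac))),
        GeneSet(label=labels[1], genes=tuple(sorted(b_only + ab + bc))),
        GeneSet(label=labels[2], genes=tuple(sorted(c_only + bc + ac))),
    ]
    return sets


def simulate_annotation_and_sets(
    cfg: SimConfig, panel: HaplotypePanel, seed=None
) -> tuple[GeneAnnotation, list[GeneSet]]:
    """Tile non-overlapping genes over each block and draw the three sets."""
    rng = _as_rng(seed if seed is not None else cfg.seed)
    rows: list[dict] = []
    for b in range(cfg.n_blocks):
        in_block = panel.variants.loc[np.flatnonzero(panel.block == b)]
        chrom = in_block["chrom"].iloc[0]
        lo, hi = int(in_block["pos"].min()), int(in_block["pos"].max())
        span = max(hi - lo, cfg.genes_per_block)
        glen = span // cfg.genes_per_block
        for g in range(cfg.genes_per_block):
            start = lo + g * glen
            end = min(start + glen - 200, hi) if glen > 200 else start + glen - 1
            end = max(end, start)
            rows.append(
                {"gene": f"G{b + 1:02d}_{g + 1:02d}", "chrom": chrom,
                 "start": start, "end": end}
            )
    ann = GeneAnnotation(table=pd.DataFrame(rows))
    pool = list(ann.table["gene"])
    sets = build_gene_sets_with_overlap(
        pool, cfg.set_size, cfg.overlap_targets, rng
    )
    return ann, sets


def synthetic_reference_gene_sets(seed: int = 0) -> list[GeneSet]:
    """Synthetic stand-in for the published top-5% cell-type gene lists.

    The real supplementary lists behind the radial glia / OPC / mature
    oligodendrocyte sets are not redistributable here, so this constructs
    three synthetic 1000-gene lists whose pairwise shared-gene fractions are
    the published values (Rad-OPC 17.2%, OPC-Oli 19.9%, Rad-Oli 3.2%) exactly.
    """
    rng = np.random.default_rng(seed)
    pool = [f"GENE{i + 1:05d}" for i in range(3000)]
    return build_gene_sets_with_overlap(pool, 1000, (0.172, 0.199, 0.032), rng)


# ----------------------------------------------------------- ground truth

def simulate_true_effects(
    cfg: SimConfig,
    panel: HaplotypePanel,
    ann: GeneAnnotation,
    sets: list[GeneSet],
    seed,
) -> np.ndarray:
    """True per-variant log odds ratios: sparse effects in gene-set variants.

    A fixed fraction of the variants falling inside any gene-set member's
    +/- window receives a Gaussian log-odds effect; everything else is null.
    """
    rng = _as_rng(seed)
    union_genes: set[str] = set()
    for gs in sets:
        union_genes |= set(gs.genes)
    mask = variants_in_gene_windows(
        panel.variants, ann, sorted(union_genes), cfg.window_bp
    )
    candidates = np.flatnonzero(mask)
    n_causal = int(round(cfg.causal_fraction * candidates.size))
    beta = np.zeros(panel.n_variants)
    if n_causal > 0:
        chosen = rng.choice(candidates, size=n_causal, replace=False)
        beta[chosen] = rng.normal(0.0, cfg.true_effect_sd, size=n_causal)
    return beta


# --------------------------------------------------------- summary stats

def simulate_summary_stats(
    panel: HaplotypePanel, true_beta: np.ndarray, cfg: SimConfig, seed
) -> SummaryStats:
    """Noisy discovery-GWAS estimates around the true log odds ratios.

    The per-variant standard error follows the usual large-sample form
    ``se = 1 / sqrt(2 * N_eff * f * (1 - f))`` with the effective sample size
    ``N_eff = 4 / (1/n_cases + 1/n_controls)``; the reported p-value is the
    two-sided normal tail of estimate/se.  The reported effect allele is
    randomly either ALT (odds ratio as estimated) or REF (odds ratio
    inverted), exercising downstream allele alignment.  Monomorphic variants
    are emitted with missing weight rather than dropped.
    """
    rng = _as_rng(seed)
    f = panel.frequency()
    n_eff = 4.0 / (1.0 / cfg.n_cases_discovery + 1.0 / cfg.n_controls_discovery)
    mono = (f <= 0.0) | (f >= 1.0)
    with np.errstate(divide="ignore"):
        se = np.where(mono, np.nan, 1.0 / np.sqrt(2.0 * n_eff * f * (1.0 - f)))
    est = true_beta + np.where(mono, 0.0, rng.normal(0.0, 1.0, size=f.size)) * np.where(
        mono, 0.0, np.nan_to_num(se)
    )
    z = np.where(mono, np.nan, est / se)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)

    # fraction of variants re-drawn with a sub-0.7 INFO score
    low = rng.random(f.size) < cfg.info_low_fraction
    info = np.where(low, rng.uniform(0.3, 0.7, size=f.size),
                    rng.uniform(0.7, 1.0, size=f.size))
    info = np.round(info, 3)

    flip = rng.random(f.size) < cfg.effect_allele_flip_prob
    var = panel.variants
    a1 = np.where(flip, var["ref"], var["alt"])
    a2 = np.where(flip, var["alt"], var["ref"])
    reported = np.where(flip, -est, est)
    odds_ratio = np.where(mono, np.nan, np.exp(reported))
    table = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(f.size)],
            "chrom": var["chrom"].astype(str),
            "pos": var["pos"].astype(int),
            "a1": a1,
            "a2": a2,
            "odds_ratio": odds_ratio,
            "p": np.where(mono, np.nan, p),
            "info": info,
        }
    )
    return SummaryStats(table=table)


# -------------------------------------------------------------- phenotypes

def simulate_phenotypes(
    truth: GroundTruth, cfg: SimConfig, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-visit subfield volumes plus demographic covariates.

    The standardized volume change in each cell is built directly on the
    generative scale: small centered covariate effects plus Gaussian residual
    noise, plus ``prs_volume_effect * z(true PRS)`` in the single planted
    (group, subfield, hemisphere) cell.  Visit-3 volumes are reconstructed as
    ``V3 = V1 + change * 0.03 * subfield_mean``, and baseline volumes scale
    with the subject's intracranial volume, so the downstream ICV proportion
    correction and re-standardization recover the planted structure.
    """
    rng = _as_rng(seed)
    subjects = list(truth.true_prs.index)
    n = len(subjects)
    groups = truth.groups.loc[subjects].to_numpy()

    age = np.round(np.clip(rng.normal(35.0, 10.0, n), 18.0, 65.0), 1)
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    height = np.round(rng.normal(178.0, 7.0, n) - 13.0 * sex, 1)
    handed = (rng.random(n) < 0.9).astype(int)  # 1 = right-handed
    icv = np.round(np.clip(rng.normal(_ICV_REF_MM3, 1.2e5, n), 1.1e6, 1.9e6), 1)

    cov_term = (
        -0.005 * (age - 35.0)
        + 0.10 * (sex - 0.5)
        + 0.005 * (height - 171.5)
        + 0.05 * (handed - 0.9)
    )

    # within-group z of the true PRS drives the planted cell
    prs = truth.true_prs.loc[subjects].to_numpy()
    z_prs = np.zeros(n)
    for g in np.unique(groups):
        sel = groups == g
        sd = prs[sel].std(ddof=1)
        if sd > 0:
            z_prs[sel] = (prs[sel] - prs[sel].mean()) / sd

    pheno: dict[str, np.ndarray] = {
        "subject_id": np.array(subjects, dtype=object),
        "group": groups,
        "icv_V1": icv,
        "icv_V3": icv,
    }
    for hemi in HEMISPHERES:
        for sub in SUBFIELDS:
            base = _SUBFIELD_MEAN_MM3[sub]
            v1 = base * (icv / _ICV_REF_MM3) * (1.0 + rng.normal(0.0, 0.08, n))
            change = cov_term + rng.normal(0.0, cfg.residual_sd, n)
            if (
                hemi == cfg.planted_hemisphere
                and sub == cfg.planted_subfield
            ):
                sel = groups == cfg.planted_group
                change[sel] += cfg.prs_volume_effect * z_prs[sel]
            v3 = v1 + change * 0.03 * base
            pheno[f"{hemi}_{sub}_V1"] = np.round(v1, 3)
            pheno[f"{hemi}_{sub}_V3"] = np.round(v3, 3)

    phenotypes = pd.DataFrame(pheno)
    covariates = pd.DataFrame(
        {
            "subject_id": np.array(subjects, dtype=object),
            "group": groups,
            "age": age,
            "sex": sex,
            "height": height,
            "handedness": handed,
        }
    )
    return phenotypes, covariates


# ------------------------------------------------------------ orchestration

@dataclass
class SimulatedCohort:
    """Everything one synthetic cohort comprises, truth included."""

    cfg: SimConfig
    panel: HaplotypePanel
    dosage: DosageMatrix
    stats: SummaryStats
    annotation: GeneAnnotation
    sets: list[GeneSet]
    truth: GroundTruth
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full cohort from one configuration (and its seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    r_panel, r_sets, r_truth, r_geno, r_stats, r_pheno = (
        np.random.default_rng(k) for k in ss.spawn(6)
    )
    panel = simulate_haplotype_panel(cfg, r_panel)
    ann, sets = simulate_annotation_and_sets(cfg, panel, r_sets)
    true_beta = simulate_true_effects(cfg, panel, ann, sets, r_truth)
    dosage = simulate_genotypes(
        panel,
        cfg.n_subjects,
        r_geno,
        dosage_noise_sd=cfg.dosage_noise_sd,
        missing_rate=cfg.missing_rate,
    )
    stats = simulate_summary_stats(panel, true_beta, cfg, r_stats)
    dosage.variants["info"] = stats.table["info"].to_numpy()

    groups = pd.Series(
        np.repeat(list(cfg.groups), cfg.n_subjects_per_group),
        index=dosage.subjects,
        name="group",
    )
    filled = np.nan_to_num(dosage.dosages)  # truth PRS from observed calls
    true_prs = pd.Series(filled @ true_beta, index=dosage.subjects, name="true_prs")
    truth = GroundTruth(
        true_beta=pd.Series(true_beta, index=dosage.keys.to_numpy()),
        true_prs=true_prs,
        groups=groups,
        planted={
            "coefficient": cfg.prs_volume_effect,
            "group": cfg.planted_group,
            "subfield": cfg.planted_subfield,
            "hemisphere": cfg.planted_hemisphere,
        },
    )
    phenotypes, covariates = simulate_phenotypes(truth, cfg, r_pheno)
    return SimulatedCohort(
        cfg=cfg,
        panel=panel,
        dosage=dosage,
        stats=stats,
        annotation=ann,
        sets=sets,
        truth=truth,
        phenotypes=phenotypes,
        covariates=covariates,
    )
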