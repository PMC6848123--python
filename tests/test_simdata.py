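"""Generator behaviour: LD structure, determinism, planted effects."""
import numpy as np
import pandas as pd
import pytest

from cellprs.containers import GroundTruth
from cellprs.simdata import (
    HaplotypePanel,
    SimConfig,
    build_gene_sets_with_overlap,
    simulate_annotation_and_sets,
    simulate_cohort,
    simulate_genotypes,
    simulate_haplotype_panel,
    simulate_phenotypes,
    simulate_summary_stats,
)


def _constant_panel(value: int, n_haps: int = 10, n_var: int = 4) -> HaplotypePanel:
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * n_var,
            "pos": [1 + 1000 * j for j in range(n_var)],
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
        }
    )
    return HaplotypePanel(
        alleles=np.full((n_haps, n_var), value, dtype=np.int8),
        variants=variants,
        block=np.zeros(n_var, dtype=int),
    )


class TestHaplotypePanel:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(maf_min=0.3, maf_max=0.2)
        with pytest.raises(ValueError):
            SimConfig(causal_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(pairwise_overlap_target=1.0)

    def test_single_variant_panel_frequency_in_bounds(self):
        cfg = SimConfig(n_blocks=1, variants_per_block=1, maf_min=0.4, maf_max=0.5,
                        seed=3)
        panel = simulate_haplotype_panel(cfg)
        assert panel.n_variants == 1
        f = panel.frequency()[0]
        assert 0.4 <= min(f, 1 - f) <= 0.5

    def test_determinism(self):
        cfg = SimConfig(seed=7, n_blocks=3, variants_per_block=8)
        a = simulate_haplotype_panel(cfg)
        b = simulate_haplotype_panel(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.variants.equals(b.variants)

    def test_within_block_ld_exceeds_between(self):
        cfg = SimConfig(n_blocks=20, variants_per_block=25, n_haplotypes=200, seed=5)
        panel = simulate_haplotype_panel(cfg)
        corr = np.corrcoef(panel.alleles.T) ** 2
        same = panel.block[:, None] == panel.block[None, :]
        off_diag = ~np.eye(panel.n_variants, dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > 10 * between
        assert between < 5.0 / cfg.n_haplotypes  # ~1/n expectation

    def test_maf_bounds_respected(self):
        cfg = SimConfig(seed=2)
        panel = simulate_haplotype_panel(cfg)
        f = panel.frequency()
        maf = np.minimum(f, 1 - f)
        assert np.all(maf >= cfg.maf_min) and np.all(maf <= cfg.maf_max)

    def test_infeasible_bounds_fail_explicitly(self):
        cfg = SimConfig(n_haplotypes=7, maf_min=0.49, maf_max=0.5, seed=0)
        with pytest.raises(ValueError, match="MAF"):
            simulate_haplotype_panel(cfg, max_block_retries=3)


class TestGenotypes:
    def test_constant_panels(self):
        zeros = simulate_genotypes(_constant_panel(0), 5, seed=1)
        assert np.all(zeros.dosages == 0.0)
        ones = simulate_genotypes(_constant_panel(1), 5, seed=1)
        assert np.all(ones.dosages == 2.0)

    def test_mean_dosage_tracks_panel_frequency(self):
        cfg = SimConfig(n_blocks=2, variants_per_block=10, seed=9)
        panel = simulate_haplotype_panel(cfg)
        m = simulate_genotypes(panel, 100, seed=4)
        f = panel.frequency()
        se = np.sqrt(2 * f * (1 - f)) / np.sqrt(100)
        assert np.all(np.abs(m.dosages.mean(axis=0) - 2 * f) <= 4 * se)

    def test_invalid_subject_count(self):
        with pytest.raises(ValueError):
            simulate_genotypes(_constant_panel(0), 0, seed=1)


class TestSummaryStats:
    def test_null_pvalues_uniform(self):
        cfg = SimConfig(n_blocks=40, variants_per_block=25, seed=13)
        panel = simulate_haplotype_panel(cfg)
        stats = simulate_summary_stats(panel, np.zeros(panel.n_variants), cfg, seed=21)
        frac = (stats.table["p"] < 0.05).mean()
        half_width = 2.58 * np.sqrt(0.05 * 0.95 / panel.n_variants)
        assert abs(frac - 0.05) <= half_width

    def test_strong_effect_detected_with_correct_sign(self):
        cfg = SimConfig(n_blocks=1, variants_per_block=5, seed=3,
                        n_cases_discovery=10**7, n_controls_discovery=10**7)
        panel = simulate_haplotype_panel(cfg)
        beta = np.zeros(panel.n_variants)
        beta[2] = 1.0
        stats = simulate_summary_stats(panel, beta, cfg, seed=8)
        row = stats.table.iloc[2]
        assert row["p"] < 1e-20
        # reported odds ratio is oriented to the reported effect allele
        logor = np.log(row["odds_ratio"])
        expected_sign = 1.0 if row["a1"] == panel.variants.iloc[2]["alt"] else -1.0
        assert np.sign(logor) == expected_sign

    def test_determinism(self):
        cfg = SimConfig(n_blocks=2, variants_per_block=6, seed=1)
        panel = simulate_haplotype_panel(cfg)
        beta = np.zeros(panel.n_variants)
        a = simulate_summary_stats(panel, beta, cfg, seed=5).table
        b = simulate_summary_stats(panel, beta, cfg, seed=5).table
        assert a.equals(b)


class TestAnnotationAndSets:
    def test_disjoint_when_target_zero(self, small_cohort):
        cfg = SimConfig(pairwise_overlap_target=0.0, seed=1)
        panel = simulate_haplotype_panel(cfg)
        _, sets = simulate_annotation_and_sets(cfg, panel, seed=2)
        a, b, c = sets
        assert not (a.members & b.members)
        assert not (b.members & c.members)
        assert not (a.members & c.members)

    def test_exact_overlap_by_construction(self):
        pool = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        a, b, c = build_gene_sets_with_overlap(pool, 10, (0.2, 0.2, 0.2), rng)
        assert len(a.members & b.members) == 2
        assert len(b.members & c.members) == 2
        assert len(a.members & c.members) == 2

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            build_gene_sets_with_overlap(
                ["a", "b"], 2, (0.0, 0.0, 0.0), np.random.default_rng(0)
            )

    def test_gene_intervals_inside_block_bounds(self, small_cohort):
        ann = small_cohort.annotation.table
        panel = small_cohort.panel
        for chrom, sub in ann.groupby("chrom"):
            on_c = panel.variants[panel.variants["chrom"] == chrom]
            assert (sub["start"] >= on_c["pos"].min()).all()
            assert (sub["end"] <= on_c["pos"].max()).all()
        # genes never overlap each other
        for _, sub in ann.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()


class TestPhenotypes:
    @staticmethod
    def _null_truth(n: int, group: str = "SCZ-exercise") -> GroundTruth:
        subjects = [f"S{i:04d}" for i in range(n)]
        rng = np.random.default_rng(0)
        return GroundTruth(
            true_beta=pd.Series(dtype=float),
            true_prs=pd.Series(rng.normal(size=n), index=subjects),
            groups=pd.Series([group] * n, index=subjects),
            planted={},
        )

    def test_null_effect_gives_no_correlation(self):
        cfg = SimConfig(prs_volume_effect=0.0, n_subjects_per_group=100)
        truth = self._null_truth(100)
        pheno, _ = simulate_phenotypes(truth, cfg, seed=3)
        change = pheno["left_CA4DG_V3"] - pheno["left_CA4DG_V1"]
        r = np.corrcoef(truth.true_prs.to_numpy(), change)[0, 1]
        assert abs(r) < 4 / np.sqrt(100)

    def test_planted_slope_recovered(self):
        cfg = SimConfig(prs_volume_effect=-0.6, residual_sd=0.8,
                        n_subjects_per_group=200)
        truth = self._null_truth(200)
        pheno, _ = simulate_phenotypes(truth, cfg, seed=5)
        base = 556.0
        change = (pheno["left_CA4DG_V3"] - pheno["left_CA4DG_V1"]) / (0.03 * base)
        prs = truth.true_prs.to_numpy()
        z = (prs - prs.mean()) / prs.std(ddof=1)
        slope = np.polyfit(z, change, 1)[0]
        assert abs(slope - (-0.6)) < 0.15

    def test_unplanted_cells_show_no_systematic_slope(self):
        cfg = SimConfig(prs_volume_effect=-0.6, n_subjects_per_group=60)
        truth = self._null_truth(60)
        slopes = []
        for seed in range(50):
            pheno, _ = simulate_phenotypes(truth, cfg, seed=seed)
            change = pheno["right_CA1_V3"] - pheno["right_CA1_V1"]
            prs = truth.true_prs.to_numpy()
            z = (prs - prs.mean()) / prs.std(ddof=1)
            slopes.append(np.polyfit(z, change / (0.03 * 322.0), 1)[0])
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 2 * sem + 1e-12 or abs(slopes.mean()) < 0.05


class TestCohort:
    def test_true_prs_recomputable_from_dosages(self, small_cohort):
        beta = small_cohort.truth.true_beta.to_numpy()
        recomputed = np.nan_to_num(small_cohort.dosage.dosages) @ beta
        assert np.allclose(recomputed, small_cohort.truth.true_prs.to_numpy(),
                           atol=1e-12)

    def test_cohort_determinism(self, small_config, small_cohort):
        again = simulate_cohort(small_config)
        assert np.array_equal(again.dosage.dosages, small_cohort.dosage.dosages)
        assert again.stats.table.equals(small_cohort.stats.table)
        assert again.phenotypes.equals(small_cohort.phenotypes)
        assert again.covariates.equals(small_cohort.covariates)
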