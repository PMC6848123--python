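"""Gene-window mapping, allele alignment, LD clumping and score computation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellprs.containers import GeneAnnotation, GeneSet, SummaryStats
from cellprs.scoring import (
    ScoringConfig,
    align_effect_alleles,
    clump,
    compute_prs,
    geneset_overlap,
    ld_r2,
    map_geneset_to_variants,
    score_gene_set,
)

from conftest import make_dosage_matrix


def _stats(rows) -> SummaryStats:
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2",
                                     "odds_ratio", "p", "info"])
    return SummaryStats(table=df)


def clump_bruteforce(variants: pd.DataFrame, dosages: np.ndarray,
                     kb: int, r2_max: float) -> list[int]:
    """Independently coded greedy clumping oracle (original row indices)."""
    df = variants.reset_index(drop=True)
    remaining = set(df.index)
    indices = []
    while remaining:
        best = min(
            remaining,
            key=lambda i: (df.loc[i, "p"], str(df.loc[i, "chrom"]), df.loc[i, "pos"]),
        )
        remaining.discard(best)
        indices.append(best)
        for j in sorted(remaining):
            if str(df.loc[j, "chrom"]) != str(df.loc[best, "chrom"]):
                continue
            if abs(int(df.loc[j, "pos"]) - int(df.loc[best, "pos"])) > kb * 1000:
                continue
            x = dosages[:, df.loc[best, "matrix_col"]]
            y = dosages[:, df.loc[j, "matrix_col"]]
            sx, sy = np.std(x), np.std(y)
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1]) ** 2
            if r > r2_max:
                remaining.discard(j)
    return sorted(
        indices,
        key=lambda i: (df.loc[i, "p"], str(df.loc[i, "chrom"]), df.loc[i, "pos"]),
    )


class TestGeneWindows:
    def test_boundary_arithmetic(self):
        ann = GeneAnnotation(pd.DataFrame(
            [{"gene": "G1", "chrom": "1", "start": 100000, "end": 105000}]
        ))
        gs = GeneSet(label="Rad", genes=("G1",))
        positions = [90000, 89999, 115000, 115001]
        stats = _stats([
            (f"rs{i}", "1", p, "G", "A", 1.1, 0.5, 1.0)
            for i, p in enumerate(positions)
        ])
        idx = map_geneset_to_variants(ann, gs, stats, ScoringConfig())
        assert list(stats.table.iloc[idx]["pos"]) == [90000, 115000]

    def test_overlapping_windows_deduplicate(self):
        ann = GeneAnnotation(pd.DataFrame([
            {"gene": "G1", "chrom": "1", "start": 1000, "end": 2000},
            {"gene": "G2", "chrom": "1", "start": 2500, "end": 3500},
        ]))
        gs = GeneSet(label="Rad", genes=("G1", "G2"))
        stats = _stats([("rs0", "1", 2200, "G", "A", 1.1, 0.5, 1.0)])
        idx = map_geneset_to_variants(ann, gs, stats, ScoringConfig())
        assert list(idx) == [0]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        ann = GeneAnnotation(pd.DataFrame([
            {"gene": f"G{i}", "chrom": str(rng.integers(1, 4)),
             "start": int(s), "end": int(s) + int(rng.integers(100, 5000))}
            for i, s in enumerate(rng.integers(1, 10**6, size=12))
        ]))
        gs = GeneSet(label="Rad", genes=tuple(f"G{i}" for i in range(0, 12, 2)))
        stats = _stats([
            (f"rs{i}", str(rng.integers(1, 4)), int(rng.integers(1, 10**6)),
             "G", "A", 1.1, 0.5, 1.0)
            for i in range(200)
        ])
        cfg = ScoringConfig()
        got = set(map_geneset_to_variants(ann, gs, stats, cfg))
        want = set()
        genes = ann.table.set_index("gene")
        for i, row in stats.table.iterrows():
            for g in gs.genes:
                grow = genes.loc[g]
                if str(grow["chrom"]) != str(row["chrom"]):
                    continue
                lo = max(grow["start"] - cfg.window_bp, 1)
                hi = grow["end"] + cfg.window_bp
                if lo <= row["pos"] <= hi:
                    want.add(i)
        assert got == want


class TestOverlap:
    def test_examples(self):
        a = GeneSet(label="A", genes=("g1", "g2", "g3"))
        b = GeneSet(label="B", genes=("g3", "g4", "g5"))
        assert geneset_overlap(a, b) == pytest.approx(100.0 / 3.0)
        assert geneset_overlap(a, a) == 100.0
        c = GeneSet(label="C", genes=("x1", "x2", "x3"))
        assert geneset_overlap(a, c) == 0.0

    def test_unequal_sizes_report_both_directions(self):
        a = GeneSet(label="A", genes=("g1", "g2", "g3", "g4"))
        b = GeneSet(label="B", genes=("g1", "g2"))
        assert geneset_overlap(a, b) == (50.0, 100.0)


class TestAlignment:
    def test_effect_allele_orientation(self):
        m = make_dosage_matrix(np.array([[1.5], [0.5]]))
        # cohort variant is A/G at pos 1; effect allele reported as REF (A)
        stats = _stats([("rs0", "1", 1, "A", "G", np.exp(0.4), 0.01, 1.0)])
        aligned = align_effect_alleles(stats, m)
        assert aligned["flip"].iloc[0]
        clumped = clump(aligned, m, ScoringConfig())
        prof = compute_prs(m, aligned, clumped,
                           ScoringConfig(standardize_scores=False))
        # dosage 1.5 on ALT means 0.5 copies of the effect (REF) allele
        assert prof.raw[0, -1] == pytest.approx(0.5 * 0.4)
        assert prof.raw[1, -1] == pytest.approx(1.5 * 0.4)

    def test_mismatched_alleles_dropped(self):
        m = make_dosage_matrix(np.array([[1.0]]))
        stats = _stats([("rs0", "1", 1, "C", "T", 1.2, 0.01, 1.0)])
        aligned = align_effect_alleles(stats, m)
        assert aligned.empty

    def test_ambiguous_toggle(self):
        m = make_dosage_matrix(np.array([[1.0], [2.0]]))
        m.variants.loc[0, "ref"], m.variants.loc[0, "alt"] = "A", "T"
        stats = _stats([("rs0", "1", 1, "T", "A", 1.2, 0.01, 1.0)])
        assert align_effect_alleles(stats, m).empty
        kept = align_effect_alleles(stats, m, keep_ambiguous=True)
        assert len(kept) == 1


class TestLdR2:
    def test_identity_and_complement(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x = np.array([0.0, 1.0, 2.0, 0.0])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(x, y) == pytest.approx(r * r)

    def test_zero_variance_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert ld_r2(np.ones(5), np.array([0, 1, 2, 0, 1.0])) == 0.0


class TestClump:
    def test_traced_example(self):
        # v1 and v2 correlated within window; v3 on another chromosome
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 50).astype(float)
        noise = np.where(rng.random(50) < 0.1, rng.integers(0, 3, 50), base)
        other = rng.integers(0, 3, 50).astype(float)
        m = make_dosage_matrix(np.column_stack([base, noise, other]))
        variants = pd.DataFrame({
            "chrom": ["1", "1", "2"],
            "pos": [1000, 2000, 1000],
            "p": [1e-8, 1e-6, 1e-4],
            "matrix_col": [0, 1, 2],
        })
        assert ld_r2(base, noise) > 0.5
        out = clump(variants, m, ScoringConfig())
        assert list(out["p"]) == [1e-8, 1e-4]

    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(300, 5)).astype(float)
        m = make_dosage_matrix(d)
        variants = pd.DataFrame({
            "chrom": ["1"] * 5, "pos": [1000 * i for i in range(5)],
            "p": [0.1, 0.2, 0.3, 0.4, 0.5], "matrix_col": range(5),
        })
        out = clump(variants, m, ScoringConfig())
        assert len(out) == 5

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        cfg = ScoringConfig(clump_kb=5, clump_r2=0.1)
        for _ in range(30):
            n_var = int(rng.integers(5, 40))
            n_sub = 60
            base = rng.integers(0, 3, size=(n_sub, 3)).astype(float)
            cols = rng.integers(0, 3, size=n_var)
            flip = rng.random((n_sub, n_var)) < 0.2
            d = np.where(flip, rng.integers(0, 3, size=(n_sub, n_var)), base[:, cols])
            m = make_dosage_matrix(d.astype(float))
            variants = pd.DataFrame({
                "chrom": rng.integers(1, 3, n_var).astype(str),
                "pos": rng.integers(1, 20000, n_var),
                "p": np.round(rng.random(n_var), 3),
                "matrix_col": np.arange(n_var),
            })
            variants = variants.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
            variants["matrix_col"] = variants.index
            m2 = m.subset_variants(np.arange(len(variants)))
            got = clump(variants, m2, cfg)
            want = clump_bruteforce(variants, m2.dosages, cfg.clump_kb, cfg.clump_r2)
            assert list(got["pos"]) == list(variants.loc[want, "pos"])


class TestComputePRS:
    def _simple(self, dosages, weights, pvals):
        m = make_dosage_matrix(dosages)
        aligned = pd.DataFrame({
            "key": [f"1:{1 + 1000 * j}:A:G" for j in range(len(weights))],
            "chrom": "1",
            "pos": [1 + 1000 * j for j in range(len(weights))],
            "matrix_col": range(len(weights)),
            "weight": weights,
            "flip": False,
            "p": pvals,
        })
        return m, aligned

    def test_zero_dosages_zero_score(self):
        m, aligned = self._simple(np.zeros((3, 2)), [0.3, -0.2], [0.01, 0.2])
        prof = compute_prs(m, aligned, aligned, ScoringConfig(standardize_scores=False))
        assert np.all(prof.raw == 0.0)

    def test_single_variant_formula(self):
        m, aligned = self._simple(np.array([[2.0]]), [np.log(1.5)], [0.001])
        prof = compute_prs(m, aligned, aligned, ScoringConfig(standardize_scores=False))
        assert prof.raw[0, -1] == pytest.approx(2 * np.log(1.5))

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        n_sub, n_var = 20, 15
        d = rng.integers(0, 3, (n_sub, n_var)).astype(float)
        w = rng.normal(0, 0.1, n_var)
        p = rng.random(n_var)
        m, aligned = self._simple(d, w, p)
        cfg = ScoringConfig(standardize_scores=False)
        prof = compute_prs(m, aligned, aligned, cfg)
        for k, t in enumerate(cfg.thresholds):
            for i in range(n_sub):
                expected = sum(
                    d[i, j] * w[j] for j in range(n_var) if p[j] <= t
                )
                assert abs(prof.raw[i, k] - expected) < 1e-10

    def test_threshold_nesting(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (10, 8)).astype(float)
        m, aligned = self._simple(d, rng.normal(size=8), rng.random(8))
        prof = compute_prs(m, aligned, aligned, ScoringConfig())
        for k in range(1, len(prof.thresholds)):
            assert set(prof.variant_keys[k - 1]) <= set(prof.variant_keys[k])
        assert prof.n_variants == sorted(prof.n_variants)

    def test_missing_dosage_mean_substitution(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        m, aligned = self._simple(d, [1.0], [0.001])
        prof = compute_prs(m, aligned, aligned, ScoringConfig(standardize_scores=False))
        assert prof.raw[2, -1] == pytest.approx(1.0)  # mean of 0 and 2

    @given(st.integers(min_value=0, max_value=7))
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_allele_flip_invariance(self, j):
        """Relabeling REF/ALT (and complementing dosages) leaves scores fixed."""
        rng = np.random.default_rng(10)
        d = rng.integers(0, 3, (12, 8)).astype(float)
        m, aligned = self._simple(d, rng.normal(size=8), rng.random(8))
        cfg = ScoringConfig(standardize_scores=False)
        ref = compute_prs(m, aligned, aligned, cfg)
        d2 = d.copy()
        d2[:, j] = 2 - d2[:, j]
        m2 = make_dosage_matrix(d2)
        aligned2 = aligned.copy()
        aligned2.loc[j, "flip"] = True  # effect allele now the other label
        flipped = compute_prs(m2, aligned2, aligned2, cfg)
        assert np.allclose(ref.raw, flipped.raw, atol=1e-12)

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (15, 10)).astype(float)
        m, aligned = self._simple(d, rng.normal(size=10), rng.random(10))
        cfg = ScoringConfig(standardize_scores=False)
        ref = compute_prs(m, aligned, aligned, cfg)
        perm = rng.permutation(10)
        shuffled = aligned.iloc[perm].reset_index(drop=True)
        out = compute_prs(m, shuffled, shuffled, cfg)
        assert np.allclose(ref.raw, out.raw, atol=1e-12)


class TestEndToEndScoring:
    def test_cohort_profiles_consistent(self, small_cohort):
        cfg = ScoringConfig()
        prof = score_gene_set(
            small_cohort.stats, small_cohort.dosage, small_cohort.annotation,
            small_cohort.sets[0], cfg,
        )
        assert prof.raw.shape == (small_cohort.dosage.n_subjects, 10)
        # standardized columns have unit variance where defined
        for k in range(10):
            if prof.n_variants[k] > 0 and prof.raw[:, k].std() > 0:
                assert prof.scores[:, k].std(ddof=1) == pytest.approx(1.0)
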