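import numpy as np
import pandas as pd
import pytest

from cfmeth.regions import build_regions
from cfmeth.signature import (
    MethylMatrix,
    build_matrix,
    map_to_signature,
    pick_informative_pc,
    run_pca,
    select_top_loadings,
)
from cfmeth.simulate import SimConfig, simulate_cohort, simulate_region_matrix


@pytest.fixture(scope="module")
def cohort_regions(small_cohort):
    _, samples, truth = small_cohort
    regions, _ = build_regions(samples)
    return samples, truth, regions


class TestBuildMatrix:
    def test_complete_coverage_keeps_all_rows(self, cohort_regions):
        samples, _, regions = cohort_regions
        m = build_matrix(regions, samples)
        assert len(m.values) + m.n_dropped_rows == len(regions)
        assert ((m.values.to_numpy() >= 0) & (m.values.to_numpy() <= 1)).all()

    def test_masked_row_dropped(self, cohort_regions):
        samples, _, regions = cohort_regions
        # demand impossible coverage in one region for one sample
        m_all = build_matrix(regions, samples, min_coverage=1)
        sid = samples[0].sample_id
        meth, total = regions[0].per_sample_counts[sid]
        regions[0].per_sample_counts[sid] = (0, 0)
        try:
            m = build_matrix(regions, samples, min_coverage=1)
            assert len(m.values) == len(m_all.values) - 1
        finally:
            regions[0].per_sample_counts[sid] = (meth, total)

    def test_needs_two_samples_per_group(self, cohort_regions):
        samples, _, regions = cohort_regions
        with pytest.raises(ValueError, match=">= 2"):
            build_matrix(regions, samples[:5])  # lone cancer sample


class TestRunPca:
    def test_rank_bound_seven_samples(self, cohort_regions):
        samples, _, regions = cohort_regions
        pca = run_pca(build_matrix(regions, samples))
        # 7 samples: at most 6 components carry variance
        assert pca.variances.size == 7
        assert pca.variances[6] <= 1e-12 * pca.variances[0]
        assert np.all(np.diff(pca.variances) <= 1e-12)

    def test_reconstruction_and_orthonormality(self, cohort_regions):
        samples, _, regions = cohort_regions
        m = build_matrix(regions, samples)
        pca = run_pca(m)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        back = pca.scores @ pca.components
        assert np.linalg.norm(back - Xc) <= 1e-8 * max(np.linalg.norm(Xc), 1)
        gram = pca.components @ pca.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_duplicated_sample_gives_null_direction(self, rng):
        base = rng.uniform(0.2, 0.8, size=(50, 3))
        df = pd.DataFrame(
            np.column_stack([base, base[:, -1]]),
            index=[f"r{i}" for i in range(50)],
            columns=["a", "b", "c", "c2"],
        )
        pca = run_pca(MethylMatrix(values=df))
        # a zero-variance direction exists between the duplicate columns
        assert pca.variances[-1] <= 1e-12 * pca.variances[0]
        dup_scores = pca.scores[2] - pca.scores[3]
        assert np.allclose(dup_scores, 0, atol=1e-8)

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.full((20, 4), 0.5), columns=list("abcd"))
        with pytest.raises(ValueError, match="degenerate"):
            run_pca(MethylMatrix(values=df))


class TestPickInformativePc:
    def test_single_sample_groups_rejected(self, rng):
        df = pd.DataFrame(rng.uniform(size=(30, 2)), columns=["a", "b"])
        pca = run_pca(MethylMatrix(values=df))
        with pytest.raises(ValueError, match=">= 2"):
            pick_informative_pc(pca, ["x", "y"])

    def test_planted_separation_recovered(self, rng):
        hits = 0
        for _ in range(25):
            df, groups, signal = simulate_region_matrix(rng, n_regions=400, n_signal=10)
            pca = run_pca(MethylMatrix(values=df))
            pc, p = pick_informative_pc(pca, groups)
            # oracle: component most aligned with the planted contrast
            g = np.asarray(groups) == "cancer"
            contrast = g.astype(float) - g.mean()
            align = np.abs(pca.scores.T @ contrast) / (
                np.linalg.norm(pca.scores, axis=0) * np.linalg.norm(contrast) + 1e-30
            )
            if pc == int(np.argmax(align)):
                hits += 1
        assert hits >= 24

    def test_null_calibration_bonferroni(self, rng):
        # without planted separation no component should look significant
        flagged = 0
        reps = 120
        for _ in range(reps):
            df, groups, _ = simulate_region_matrix(
                rng, n_regions=150, n_signal=1, delta=0.0
            )
            pca = run_pca(MethylMatrix(values=df))
            _, p = pick_informative_pc(pca, groups)
            k = int((pca.variances > 1e-12 * pca.variances[0]).sum())
            if p < 0.05 / k:
                flagged += 1
        assert flagged / reps <= 0.10


class TestSelectTopLoadings:
    def _pca(self, loadings):
        arr = np.asarray(loadings, dtype=float)[None, :]
        return type(
            "P", (), {
                "components": arr,
                "region_ids": [f"r{i}" for i in range(arr.shape[1])],
            },
        )()

    def test_fraction_count(self, rng):
        pca = self._pca(rng.normal(size=1000))
        sel, _ = select_top_loadings(pca, 0, 0.025)
        assert len(sel) == 25

    def test_ties_break_by_region_order(self):
        pca = self._pca(np.ones(10))
        sel, cutoff = select_top_loadings(pca, 0, 0.25)
        assert sel == ["r0", "r1", "r2"]  # ceil(0.25 * 10)
        assert cutoff == 1.0

    def test_fraction_bounds(self):
        pca = self._pca(np.arange(4.0))
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                select_top_loadings(pca, 0, bad)

    def test_selection_monotone_in_fraction(self, rng):
        pca = self._pca(rng.normal(size=200))
        small, _ = select_top_loadings(pca, 0, 0.05)
        large, _ = select_top_loadings(pca, 0, 0.10)
        assert set(small) <= set(large)

    def test_sign_flip_invariance(self, rng):
        df, groups, _ = simulate_region_matrix(rng, n_regions=300, n_signal=8)
        pca = run_pca(MethylMatrix(values=df))
        pc, p = pick_informative_pc(pca, groups)
        sel_before, _ = select_top_loadings(pca, pc, 0.05)
        pca.components[pc] *= -1
        pca.scores[:, pc] *= -1
        pc2, p2 = pick_informative_pc(pca, groups)
        sel_after, _ = select_top_loadings(pca, pc2, 0.05)
        assert pc2 == pc and p2 == pytest.approx(p)
        assert sel_after == sel_before


class TestMapToSignature:
    def test_gene_deduplication_and_empty(self, cohort_regions):
        samples, truth, regions = cohort_regions
        sel = map_to_signature([], regions, truth.gene_models, truth.emt_sets())
        assert sel.selected_genes == [] and sel.emt_signature_genes == []
        # two regions annotated to the same gene appear once
        by_gene = {}
        ids = [r.region_id for r in regions]
        full = map_to_signature(ids, regions, truth.gene_models, truth.emt_sets())
        assert len(full.selected_genes) == len(set(full.selected_genes))
        assert set(full.emt_signature_genes) <= set(full.selected_genes)

    def test_recovers_planted_em_genes(self):
        cfg = SimConfig(
            seed=31, n_islands=400, dmr_fraction=0.0, n_e_genes=10, n_m_genes=5
        )
        samples, truth, _ = simulate_cohort(cfg)
        regions, _ = build_regions(samples)
        m = build_matrix(regions, samples)
        pca = run_pca(m)
        pc, p = pick_informative_pc(pca, [s.group for s in samples])
        frac = 15 / len(m.values)
        sel_ids, cutoff = select_top_loadings(pca, pc, frac)
        sel = map_to_signature(
            sel_ids, regions, truth.gene_models, truth.emt_sets(), pc, p, cutoff
        )
        planted = truth.e_genes | truth.m_genes
        recovered = planted & set(sel.emt_signature_genes)
        assert len(recovered) / len(planted) >= 0.9
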