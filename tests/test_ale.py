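"""ALE union, null distributions, p-values, FDR and cluster extraction."""

import numpy as np
import pytest

from alekit.ale import (
    ALE,
    AnalysisConfig,
    NullDistribution,
    ale_to_p,
    ale_union,
    build_null_analytic,
    build_null_monte_carlo,
    extract_clusters,
    fdr_select,
    run_ale,
    union_discrete_distributions,
)
from alekit.corpus import Corpus, Experiment, Focus
from alekit.grid import GridError, StatMap, make_box_mask
from alekit.kernels import UncertaintyModel, modeled_activation_map


def _random_ma(grid, rng, scale=0.3):
    values = np.where(grid.mask, rng.uniform(0, scale, grid.shape), 0.0)
    return StatMap(grid=grid, values=values, kind="ma")


class TestAleUnion:
    def test_two_half_probabilities(self, grid16):
        maps = []
        for _ in range(2):
            v = np.zeros(grid16.shape)
            v[3, 3, 3] = 0.5
            maps.append(StatMap(grid=grid16, values=v, kind="ma"))
        assert ale_union(maps).values[3, 3, 3] == pytest.approx(0.75, abs=1e-15)

    def test_single_map_is_identity(self, grid16, rng):
        ma = _random_ma(grid16, rng)
        assert np.array_equal(ale_union([ma]).values, ma.values)

    def test_brute_force_product_formula(self, grid16, rng):
        maps = [_random_ma(grid16, rng) for _ in range(5)]
        expected = 1.0 - np.prod([1.0 - m.values for m in maps], axis=0)
        assert np.allclose(ale_union(maps).values, expected, atol=1e-12)
        assert np.all(ale_union(maps).values >= np.max([m.values for m in maps], axis=0) - 1e-15)

    def test_order_invariance_and_monotonicity(self, grid16, rng):
        maps = [_random_ma(grid16, rng) for _ in range(4)]
        a = ale_union(maps).values
        b = ale_union(maps[::-1]).values
        assert np.allclose(a, b, atol=1e-15)
        assert np.all(ale_union(maps).values >= ale_union(maps[:3]).values - 1e-15)

    def test_grid_mismatch(self, grid16, rng):
        other = make_box_mask((16, 16, 16), 2.0, (1.0, 0.0, 0.0))
        with pytest.raises(GridError):
            ale_union([_random_ma(grid16, rng), _random_ma(other, rng)])


class TestMonteCarloNull:
    def test_deterministic_given_seed(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=5)
        cfg = AnalysisConfig(rng_seed=42, null_iterations=20)
        a = build_null_monte_carlo(corpus, grid16, cfg)
        b = build_null_monte_carlo(corpus, grid16, cfg)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a._samples, b._samples)

    def test_small_kernel_concentrates_near_zero(self, grid16):
        corpus = Corpus([Experiment("e", 5, [Focus(10, 10, 10)])])
        cfg = AnalysisConfig(
            uncertainty=UncertaintyModel(fwhm_template_mm=0.5, fwhm_subject_mm=0.0),
            null_iterations=50,
            rng_seed=1,
        )
        null = build_null_monte_carlo(corpus, grid16, cfg)
        # one tiny kernel: almost all pooled voxels are zero, an atom of
        # roughly one-voxel mass sits at the peak value
        assert null.sf(1e-9) == pytest.approx(1.0 / grid16.n_mask_voxels, rel=0.5)

    def test_p_values_equal_direct_counting(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=4)
        cfg = AnalysisConfig(rng_seed=7, null_iterations=30)
        null = build_null_monte_carlo(corpus, grid16, cfg)
        samples = null._samples
        obs = rng.uniform(0, samples.max() * 1.1, size=1000)
        expected = np.maximum(
            (samples[None, :] >= obs[:, None]).mean(axis=1), 1.0 / len(samples)
        )
        assert np.allclose(null.sf(obs), expected, atol=1e-12)


class TestAnalyticNull:
    def test_single_experiment_matches_exhaustive_placement(self):
        # brute-force oracle: place the focus at every mask voxel, pool MA values
        grid = make_box_mask((8, 8, 8), 2.0, (0, 0, 0))
        corpus = Corpus([Experiment("e", 20, [Focus(6, 6, 6)])])
        cfg = AnalysisConfig()
        model = cfg.uncertainty
        pooled = []
        for idx in grid.mask_indices():
            exp = Experiment("probe", 20, [Focus.from_xyz(grid.voxel_to_mm(idx))])
            pooled.append(modeled_activation_map(exp, grid, model).values[grid.mask])
        pooled = np.concatenate(pooled)
        null = build_null_analytic(corpus, grid, cfg)
        assert np.isclose(
            null.probabilities @ null.values, pooled.mean(), rtol=1e-6
        )
        # compare tail masses at thresholds strictly between pooled atoms,
        # where binning cannot split an atom across the threshold
        distinct = np.unique(pooled)[-20:]
        for t in 0.5 * (distinct[:-1] + distinct[1:]):
            assert np.isclose(null.sf(t), (pooled >= t).mean(), rtol=1e-9, atol=1e-12)

    def test_point_mass_union(self):
        a, b = 0.2, 0.5
        target = 1 - (1 - a) * (1 - b)
        values, probs = union_discrete_distributions(
            [(np.array([a]), np.array([1.0])), (np.array([b]), np.array([1.0]))]
        )
        # a point mass off the bin grid is split between adjacent bins,
        # preserving the mean; all mass stays within one bin of the target
        assert probs @ values == pytest.approx(target, rel=1e-6)
        bin_width = np.max(np.diff(values))
        assert probs[np.abs(values - target) > bin_width].sum() < 1e-12

    def test_all_zero_degenerate(self):
        values, probs = union_discrete_distributions(
            [(np.array([0.0]), np.array([1.0]))] * 3
        )
        assert values[0] == 0.0 and probs[0] == 1.0

    def test_matches_monte_carlo_tail_quantiles(self, grid20, rng, corpus_factory):
        corpus = corpus_factory(rng, grid20, n_experiments=10, max_foci=6)
        cfg = AnalysisConfig(rng_seed=3, null_iterations=400)
        mc = build_null_monte_carlo(corpus, grid20, cfg)
        an = build_null_analytic(corpus, grid20, cfg)
        for q in (0.90, 0.95, 0.99):
            assert float(an.quantile(q)) == pytest.approx(float(mc.quantile(q)), rel=0.02)

    def test_probabilities_sum_to_one(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=6)
        null = build_null_analytic(corpus, grid16, AnalysisConfig())
        assert null.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_union_combine_rule_supported(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=3, max_foci=3)
        cfg = AnalysisConfig(combine_rule="union", rng_seed=2, null_iterations=400)
        an = build_null_analytic(corpus, grid16, cfg)
        mc = build_null_monte_carlo(corpus, grid16, cfg)
        assert float(an.quantile(0.95)) == pytest.approx(float(mc.quantile(0.95)), rel=0.03)


class TestPValues:
    def test_zero_ale_has_p_one(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=3)
        null = build_null_analytic(corpus, grid16, AnalysisConfig())
        ale = StatMap(grid=grid16, values=np.zeros(grid16.shape), kind="ale")
        assert np.all(ale_to_p(ale, null).in_mask() == 1.0)

    def test_above_support_uses_smallest_tail(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=3)
        cfg = AnalysisConfig(rng_seed=1, null_iterations=10)
        null = build_null_monte_carlo(corpus, grid16, cfg)
        v = np.zeros(grid16.shape)
        v[0, 0, 0] = min(1.0, float(null._samples.max()) * 1.5)
        p = ale_to_p(StatMap(grid=grid16, values=v, kind="ale"), null)
        assert p.values[0, 0, 0] == pytest.approx(1.0 / len(null._samples))

    def test_monotone_in_ale(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=3)
        null = build_null_analytic(corpus, grid16, AnalysisConfig())
        ales = np.linspace(0, 0.5, 100)
        p = null.sf(ales)
        assert np.all(np.diff(p) <= 1e-15)

    def test_json_round_trip(self, grid16, rng, corpus_factory, tmp_path):
        corpus = corpus_factory(rng, grid16, n_experiments=3)
        null = build_null_analytic(corpus, grid16, AnalysisConfig())
        path = tmp_path / "null.json"
        null.to_json(path)
        back = NullDistribution.from_json(path)
        assert np.allclose(back.probabilities, null.probabilities)
        assert np.allclose(back.values, null.values)
        assert float(back.quantile(0.95)) == pytest.approx(float(null.quantile(0.95)))


def _bh_reference(p, q):
    """Independent step-up implementation used as an oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = 0.0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            thresh = p[idx]
    return p <= thresh if thresh > 0 else np.zeros(m, dtype=bool)


class TestFdr:
    def test_step_up_by_hand(self):
        grid = make_box_mask((4, 1, 1), 1.0, (0, 0, 0))
        p = StatMap(grid=grid, values=np.array([[[0.01]], [[0.02]], [[0.03]], [[0.04]]]), kind="p")
        assert fdr_select(p, 0.05).values.sum() == 4

    def test_all_ones_rejects_nothing(self, grid16):
        p = StatMap(grid=grid16, values=np.ones(grid16.shape) * grid16.mask, kind="p")
        assert fdr_select(p, 0.05).values.sum() == 0

    def test_matches_reference_on_random_vectors(self, rng):
        grid = make_box_mask((10, 10, 1), 1.0, (0, 0, 0))
        for _ in range(100):
            vals = rng.uniform(0, 1, grid.shape) ** rng.uniform(0.5, 3)
            p = StatMap(grid=grid, values=vals, kind="p")
            q = float(rng.uniform(0.01, 0.3))
            got = fdr_select(p, q).values[grid.mask].astype(bool)
            assert np.array_equal(got, _bh_reference(vals[grid.mask], q))


def _flood_fill(binary, connectivity):
    """BFS connected components, independent of scipy labeling."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(binary.shape, dtype=int)
    next_label = 0
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        next_label += 1
        stack = [start]
        labels[start] = next_label
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < binary.shape[i] for i in range(3)):
                    if binary[n] and not labels[n]:
                        labels[n] = next_label
                        stack.append(n)
    return labels


class TestClusters:
    def test_extent_rule_boundary(self):
        # 2 mm isotropic: 12 voxels = 96 mm^3 (discard), 13 = 104 mm^3 (keep)
        grid = make_box_mask((20, 20, 20), 2.0, (0, 0, 0))
        v = np.zeros(grid.shape)
        v[2, 2, 2:14] = 1  # 12-voxel line
        v[10, 10, 2:15] = 1  # 13-voxel line
        binary = StatMap(grid=grid, values=v, kind="binary")
        ale = StatMap(grid=grid, values=v * 0.5, kind="ale")
        clusters = extract_clusters(binary, ale, AnalysisConfig(min_cluster_mm3=100.0))
        assert len(clusters) == 1
        assert clusters[0].n_voxels == 13
        assert clusters[0].size_mm3 == pytest.approx(104.0)

    def test_single_large_voxel_survives(self):
        grid = make_box_mask((4, 4, 4), (5.0, 8.0, 5.0), (0, 0, 0))  # 200 mm^3 voxels
        v = np.zeros(grid.shape)
        v[1, 2, 3] = 1
        binary = StatMap(grid=grid, values=v, kind="binary")
        ale = StatMap(grid=grid, values=v * 0.2, kind="ale")
        (c,) = extract_clusters(binary, ale, AnalysisConfig(min_cluster_mm3=100.0))
        assert np.allclose(c.weighted_center_mm, grid.voxel_to_mm((1, 2, 3)))
        assert c.size_mm3 == pytest.approx(200.0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_membership_matches_flood_fill(self, rng, connectivity):
        grid = make_box_mask((16, 16, 16), 2.0, (0, 0, 0))
        for _ in range(5):
            binary_vals = (rng.uniform(0, 1, grid.shape) < 0.2).astype(float)
            ale_vals = np.where(binary_vals > 0, rng.uniform(0.01, 1, grid.shape), 0)
            cfg = AnalysisConfig(min_cluster_mm3=1e-9, cluster_connectivity=connectivity)
            clusters = extract_clusters(
                StatMap(grid=grid, values=binary_vals, kind="binary"),
                StatMap(grid=grid, values=ale_vals, kind="ale"),
                cfg,
            )
            ref = _flood_fill(binary_vals > 0, connectivity)
            ref_sizes = sorted(np.bincount(ref.ravel())[1:], reverse=True)
            assert sorted((c.n_voxels for c in clusters), reverse=True) == ref_sizes

    def test_peak_tie_breaks_to_smallest_index(self):
        grid = make_box_mask((6, 6, 6), 2.0, (0, 0, 0))
        v = np.zeros(grid.shape)
        v[2, 2, 2:4] = 1
        ale = StatMap(grid=grid, values=v * 0.3, kind="ale")  # tied peaks
        (c,) = extract_clusters(
            StatMap(grid=grid, values=v, kind="binary"), ale, AnalysisConfig(min_cluster_mm3=1.0)
        )
        assert tuple(c.peak_mm) == tuple(grid.voxel_to_mm((2, 2, 2)))


class TestRunAle:
    def test_single_focus_recovered_with_permissive_thresholds(self, grid16):
        corpus = Corpus([Experiment("solo", 50, [Focus(16, 16, 16)])])
        cfg = AnalysisConfig(fdr_q=0.99, min_cluster_mm3=8.0)
        res = run_ale(corpus, grid16, cfg)
        assert len(res.clusters) == 1
        assert np.allclose(res.clusters[0].peak_mm, (16, 16, 16))

    def test_bitwise_deterministic(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=5)
        cfg = AnalysisConfig(rng_seed=9, null_method="monte_carlo", null_iterations=50)
        r1 = run_ale(corpus, grid16, cfg)
        r2 = run_ale(corpus, grid16, cfg)
        for attr in ("ale_map", "p_map", "threshold_mask"):
            assert np.array_equal(getattr(r1, attr).values, getattr(r2, attr).values)

    def test_estimator_api(self, grid16, rng, corpus_factory):
        corpus = corpus_factory(rng, grid16, n_experiments=4)
        est = ALE(fdr_q=0.1).fit(corpus, grid16)
        assert est.get_params()["fdr_q"] == 0.1
        assert set(est.sigmas_) == set(corpus.ids)
        assert est.ale_map_.kind == "ale"
        clone_params = ALE(**est.get_params()).get_params()
        assert clone_params == est.get_params()

    def test_empty_corpus_rejected(self, grid16):
        with pytest.raises(ValueError):
            run_ale(Corpus([], space_label="MNI"), grid16, AnalysisConfig())
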