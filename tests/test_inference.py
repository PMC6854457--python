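import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from opmbeam.geometry import SourceGrid
from opmbeam.inference import (
    BootstrapConfig,
    StatMap,
    bootstrap_conjunction,
    bootstrap_images,
    clusters_and_peaks,
    conjunction_p,
    fdr_mask,
    map_to_p,
    smooth_map,
)


def flat_grid(n):
    return SourceGrid((0, 0, 0), 0.003, (n, 1, 1), np.ones((n, 1, 1), bool))


def cube_grid(n=15):
    return SourceGrid((-0.021, -0.021, -0.021), 0.003, (n, n, n),
                      np.ones((n, n, n), bool))


def make_map(grid, values, kind):
    return StatMap(grid, grid.embed(np.asarray(values, dtype=float).ravel()), kind)


def brute_force_bh(p, q):
    """Step-up oracle: scan k from largest to smallest."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sig = np.zeros(m, dtype=bool)
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            sig[order[:k]] = True
            break
    return sig


def flood_fill_components(mask):
    """6-connected component labelling by breadth-first search."""
    visited = np.zeros_like(mask, dtype=bool)
    components = []
    shape = mask.shape
    for start in np.argwhere(mask):
        start = tuple(start)
        if visited[start]:
            continue
        queue, members = [start], []
        visited[start] = True
        while queue:
            v = queue.pop()
            members.append(v)
            for axis in range(3):
                for step in (-1, 1):
                    nb = list(v)
                    nb[axis] += step
                    nb = tuple(nb)
                    if (0 <= nb[axis] < shape[axis] and mask[nb]
                            and not visited[nb]):
                        visited[nb] = True
                        queue.append(nb)
        components.append(frozenset(members))
    return set(components)


class TestSmoothMap:
    def test_zero_fwhm_is_identity(self):
        grid = cube_grid()
        rng = np.random.default_rng(0)
        m = make_map(grid, rng.standard_normal(grid.n_sources), "F")
        out = smooth_map(m, 0.0)
        assert np.array_equal(out.values, m.values)

    def test_constant_map_unchanged_despite_boundaries(self, head):
        grid = SourceGrid.centered_cube(head, spacing=0.01, n=12)
        m = make_map(grid, np.full(grid.n_sources, 3.7), "F")
        out = smooth_map(m, 9.0)
        assert np.allclose(out.masked_values, 3.7, rtol=1e-12)

    def test_interior_impulse_has_gaussian_profile(self):
        grid = cube_grid(21)
        vals = np.zeros(grid.n_sources)
        centre = np.ravel_multi_index((10, 10, 10), grid.shape)
        vals[centre] = 1.0
        out = smooth_map(make_map(grid, vals, "F"), 9.0)
        sigma_mm = 9.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        expected = np.exp(-(3.0**2) / (2.0 * sigma_mm**2))
        ratio = out.values[11, 10, 10] / out.values[10, 10, 10]
        assert np.isclose(ratio, expected, atol=1e-6)

    def test_preserves_total_mass_in_interior(self):
        grid = cube_grid(25)
        vals = np.zeros(grid.n_sources)
        vals[np.ravel_multi_index((12, 12, 12), grid.shape)] = 5.0
        out = smooth_map(make_map(grid, vals, "F"), 9.0)
        assert np.isclose(np.nansum(out.values), 5.0, rtol=1e-6)


class TestMapToP:
    def test_zero_statistic_maps_to_one(self):
        m = make_map(flat_grid(3), [0.0, 0.0, 0.0], "F")
        p = map_to_p(m, (1, 60))
        assert np.allclose(p.masked_values, 1.0)

    def test_monotone_decreasing_in_f(self):
        m = make_map(flat_grid(50), np.linspace(0, 30, 50), "F")
        p = map_to_p(m, (1, 60)).masked_values
        assert np.all(np.diff(p) < 0)

    def test_quantile_round_trip(self):
        crit = stats.f.isf(0.05, 1, 60)
        p = map_to_p(make_map(flat_grid(1), [crit], "F"), (1, 60))
        assert np.isclose(p.masked_values[0], 0.05, atol=1e-9)


class TestConjunction:
    def test_identical_maps_pass_through(self):
        grid = flat_grid(10)
        p = make_map(grid, np.linspace(0.01, 0.9, 10), "p")
        out = conjunction_p([p, p, p])
        assert np.allclose(out.masked_values, p.masked_values)

    def test_dominates_every_participant(self):
        rng = np.random.default_rng(1)
        grid = flat_grid(100)
        maps = [make_map(grid, rng.uniform(size=100), "p") for _ in range(3)]
        out = conjunction_p(maps).masked_values
        for m in maps:
            assert np.all(out >= m.masked_values - 1e-15)

    def test_adding_a_participant_never_lowers_p(self):
        rng = np.random.default_rng(2)
        grid = flat_grid(60)
        maps = [make_map(grid, rng.uniform(size=60), "p") for _ in range(4)]
        p3 = conjunction_p(maps[:3]).masked_values
        p4 = conjunction_p(maps).masked_values
        assert np.all(p4 >= p3 - 1e-15)

    def test_grid_mismatch_rejected(self):
        a = make_map(flat_grid(5), np.full(5, 0.5), "p")
        b = make_map(flat_grid(6), np.full(6, 0.5), "p")
        with pytest.raises(ValueError, match="grid"):
            conjunction_p([a, b])

    def test_conservative_under_global_null(self):
        """Max-p of three independent null F tests rejects far less often
        than alpha at every voxel."""
        rng = np.random.default_rng(3)
        n_rep, n_per = 2000, 20
        grid = flat_grid(n_rep)
        from opmbeam.beamformer import SourcePowerTable, power_contrast_maps
        from opmbeam.simulate import COUNTING, SCENE
        labels = np.array([SCENE] * n_per + [COUNTING] * n_per, dtype=object)
        p_maps = []
        for _ in range(3):
            powers = rng.lognormal(size=(n_rep, 2 * n_per))
            F, _ = power_contrast_maps(SourcePowerTable(powers, labels, grid))
            p_maps.append(map_to_p(F, (1, 2 * n_per - 2)))
        conj = conjunction_p(p_maps).masked_values
        assert np.mean(conj <= 0.05) <= 0.05


class TestFdrMask:
    def test_all_ones_gives_empty_mask(self):
        m = make_map(flat_grid(20), np.ones(20), "p")
        out = fdr_mask(m, 0.005)
        assert np.all(out.masked_values == 0)

    def test_hand_executed_step_up(self):
        m = make_map(flat_grid(4), [0.001, 0.002, 0.2, 0.9], "p")
        out = fdr_mask(m, 0.05).masked_values
        assert np.array_equal(out, [1.0, 1.0, 0.0, 0.0])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(1, 80)
            p = rng.uniform(size=n) ** rng.uniform(0.3, 3.0)
            q = rng.uniform(0.001, 0.2)
            got = fdr_mask(make_map(flat_grid(n), p, "p"), q).masked_values
            assert np.array_equal(got.astype(bool), brute_force_bh(p, q))

    @settings(derandomize=True, max_examples=120)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        st.floats(0.001, 0.3),
    )
    def test_oracle_equivalence_property(self, p, q):
        p = np.asarray(p)
        got = fdr_mask(make_map(flat_grid(len(p)), p, "p"), q).masked_values
        assert np.array_equal(got.astype(bool), brute_force_bh(p, q))

    def test_lowering_q_never_adds_voxels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=300) ** 2
        m = make_map(flat_grid(300), p, "p")
        prev = fdr_mask(m, 0.2).masked_values
        for q in (0.1, 0.05, 0.01, 0.005, 0.001):
            cur = fdr_mask(m, q).masked_values
            assert np.all(cur <= prev)
            prev = cur


class TestClusters:
    def test_empty_mask_gives_empty_report(self):
        grid = cube_grid(5)
        mask = make_map(grid, np.zeros(grid.n_sources), "mask01")
        stat = make_map(grid, np.ones(grid.n_sources), "F")
        report = clusters_and_peaks(mask, stat)
        assert len(report) == 0
        assert report.to_dataframe().empty

    def test_edge_sharing_voxels_form_two_clusters(self):
        grid = cube_grid(4)
        mask3d = np.zeros(grid.shape)
        mask3d[1, 1, 1] = 1.0
        mask3d[2, 2, 1] = 1.0  # shares an edge, not a face
        mask = StatMap(grid, mask3d, "mask01")
        stat = make_map(grid, np.ones(grid.n_sources), "F")
        assert len(clusters_and_peaks(mask, stat)) == 2

    def test_face_sharing_voxels_form_one_cluster(self):
        grid = cube_grid(4)
        mask3d = np.zeros(grid.shape)
        mask3d[1, 1, 1] = mask3d[1, 1, 2] = 1.0
        report = clusters_and_peaks(
            StatMap(grid, mask3d, "mask01"),
            make_map(grid, np.ones(grid.n_sources), "F"),
        )
        assert len(report) == 1 and report.clusters[0].n_voxels == 2

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(6)
        grid = cube_grid(8)
        stat = make_map(grid, rng.standard_normal(grid.n_sources), "F")
        for _ in range(20):
            mask3d = (rng.uniform(size=grid.shape) < 0.3).astype(float)
            report = clusters_and_peaks(StatMap(grid, mask3d, "mask01"), stat)
            got = {frozenset(map(tuple, c.members)) for c in report.clusters}
            want = flood_fill_components(mask3d > 0)
            assert got == want

    def test_peak_is_cluster_member_with_maximal_statistic(self):
        rng = np.random.default_rng(7)
        grid = cube_grid(6)
        mask3d = (rng.uniform(size=grid.shape) < 0.4).astype(float)
        stat = make_map(grid, rng.standard_normal(grid.n_sources), "F")
        for c in clusters_and_peaks(StatMap(grid, mask3d, "mask01"), stat).clusters:
            member_vals = stat.values[tuple(np.array(c.members).T)]
            assert np.isclose(c.peak_value, member_vals.max())
            assert tuple(c.peak_index) in set(map(tuple, c.members))


class _StubLocalization:
    """Minimal refit-able object: F map is the mean of resampled trial values."""

    def __init__(self, grid, labels, values, rng_offset=0.0):
        self.grid = grid
        self.labels = labels
        self.values = values       # (n_sources, n_trials)

    def refit(self, idx):
        idx = np.asarray(idx, dtype=int)
        flat = self.values[:, idx].mean(axis=1)
        f = StatMap(self.grid, self.grid.embed(flat**2), "F")
        t = StatMap(self.grid, self.grid.embed(flat), "t")
        return f, t


class TestBootstrap:
    def _stub(self, seed=0, n=30):
        from opmbeam.simulate import COUNTING, SCENE
        rng = np.random.default_rng(seed)
        grid = flat_grid(12)
        labels = np.array([SCENE] * n + [COUNTING] * n, dtype=object)
        values = rng.standard_normal((grid.n_sources, 2 * n))
        return _StubLocalization(grid, labels, values)

    def test_distinct_replicates_from_distinct_draws(self):
        loc = self._stub()
        images = bootstrap_images(loc, 100, seed=1)
        flat = [tuple(np.round(img.masked_values, 12)) for img in images]
        assert len(set(flat)) == 100

    def test_seeded_reproducibility(self):
        loc = self._stub()
        a = bootstrap_images(loc, 5, seed=3)
        b = bootstrap_images(loc, 5, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.masked_values, y.masked_values)

    def test_percentage_map_is_exact_mean_of_masks(self):
        rng = np.random.default_rng(8)
        grid = flat_grid(40)
        image_lists = [
            [make_map(grid, rng.uniform(0, 30, 40), "F") for _ in range(6)]
            for _ in range(3)
        ]
        cfg = BootstrapConfig(n_boot_per_participant=6, n_conjunctions=50,
                              q=0.05, seed=9)
        percent = bootstrap_conjunction(image_lists, [(1, 40)] * 3, cfg,
                                        fwhm_mm=0.0)
        # replay the draws to accumulate the masks independently
        rng2 = np.random.default_rng(9)
        total = np.zeros(40)
        for _ in range(50):
            picks = [lst[rng2.integers(len(lst))] for lst in image_lists]
            pmaps = [map_to_p(m, (1, 40)) for m in picks]
            total += fdr_mask(conjunction_p(pmaps), 0.05).masked_values
        assert np.array_equal(percent.masked_values, 100.0 * total / 50)

    def test_always_significant_voxel_scores_hundred(self):
        grid = flat_grid(5)
        strong = make_map(grid, [1e4, 0.0, 0.0, 0.0, 0.0], "F")
        cfg = BootstrapConfig(n_boot_per_participant=1, n_conjunctions=20,
                              q=0.05, seed=0)
        percent = bootstrap_conjunction([[strong]] * 3, [(1, 30)] * 3, cfg,
                                        fwhm_mm=0.0)
        assert percent.masked_values[0] == 100.0
        assert np.all(percent.masked_values[1:] == 0.0)

    def test_bounds_and_kind(self):
        loc = self._stub(seed=10)
        images = bootstrap_images(loc, 4, seed=2)
        cfg = BootstrapConfig(n_boot_per_participant=4, n_conjunctions=10,
                              q=0.05, seed=1)
        percent = bootstrap_conjunction([images, images], [(1, 58)] * 2, cfg,
                                        fwhm_mm=0.0)
        vals = percent.masked_values
        assert percent.kind == "percent"
        assert np.all((vals >= 0) & (vals <= 100))
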