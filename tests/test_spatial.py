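"""Point-pattern statistics against brute-force and geometric oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import shapely

import gcniche as g


def half_square_points(n=4000, seed=0, side=1000.0):
    """Uniform points filling the left half of a square (DZ geometry fixture)."""
    rng = np.random.default_rng(seed)
    return np.column_stack([rng.uniform(0, side / 2, n), rng.uniform(0, side, n)])


def random_cellmap(n_a, n_b, seed=0, side=300.0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": rng.uniform(0, side, n),
            "y_um": rng.uniform(0, side, n),
            "phenotype": ["A"] * n_a + ["B"] * n_b,
        }
    )
    return g.CellMap(cells, shapely.box(0, 0, side, side))


class TestNNDistances:
    def test_single_pair_pythagoras(self):
        d = g.nn_distances([[0.0, 0.0]], [[3.0, 4.0]])
        assert d.tolist() == [5.0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0, 100, (100, 2))
        r = rng.uniform(0, 100, (80, 2))
        brute = np.sqrt(((q[:, None, :] - r[None, :, :]) ** 2).sum(-1)).min(axis=1)
        assert np.array_equal(g.nn_distances(q, r), brute) or np.allclose(
            g.nn_distances(q, r), brute, rtol=0, atol=1e-12
        )

    def test_coincident_point_zero(self):
        assert g.nn_distances([[1.0, 2.0]], [[1.0, 2.0], [5.0, 5.0]])[0] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            g.nn_distances([[0, 0]], np.empty((0, 2)))


class TestRandomizationTest:
    def test_colocated_pairs_detected_as_aggregation(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0, 200, (60, 2))
        a = b + rng.normal(0, 0.5, b.shape)  # each A within ~1 um of a B
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(120)],
                "x_um": np.concatenate([a[:, 0], b[:, 0]]),
                "y_um": np.concatenate([a[:, 1], b[:, 1]]),
                "phenotype": ["A"] * 60 + ["B"] * 60,
            }
        )
        cm = g.CellMap(cells, shapely.box(-5, -5, 205, 205))
        res = g.nn_randomization_test(cm, "A", "B", n_perm=199, seed=0)
        assert res.direction == "aggregation"
        assert res.median_observed < res.median_null

    def test_exclusion_detected_as_segregation(self):
        cm, _ = g.simulate_gc_map(
            g.TissueSimConfig(seed=21, dz_t_retention=0.0, t_intensity=0.002)
        )
        res = g.nn_randomization_test(
            g.with_aid_labels(cm), "T", "AID", n_perm=200, seed=0
        )
        assert res.direction == "segregation"
        assert res.p < 0.01

    def test_null_p_not_extreme_on_random_labels(self):
        cm = random_cellmap(80, 80, seed=3)
        res = g.nn_randomization_test(cm, "A", "B", n_perm=199, seed=1)
        assert res.p > 0.05 or res.direction == "none"

    def test_min_cells_enforced(self):
        cm = random_cellmap(3, 50, seed=4)
        with pytest.raises(ValueError):
            g.nn_randomization_test(cm, "A", "B")

    def test_low_n_perm_warns(self):
        cm = random_cellmap(20, 20, seed=5)
        with pytest.warns(UserWarning):
            g.nn_randomization_test(cm, "A", "B", n_perm=50, seed=0)


class TestInterface:
    def test_half_square_boundary_near_midline(self):
        pts = half_square_points(n=4000, seed=0)
        poly = shapely.box(0, 0, 1000, 1000)
        model = g.delineate_interface(pts, poly)
        verts = shapely.get_coordinates(model.boundary)
        assert len(verts) > 0
        assert np.abs(verts[:, 0] - 500.0).max() <= 20.0

    def test_band_layers_each_half_width(self):
        pts = half_square_points(n=2000, seed=1)
        poly = shapely.box(0, 0, 1000, 1000)
        model = g.delineate_interface(pts, poly, band_width=100.0)
        inner = np.array([[480.0, 500.0]])   # DZ side, ~20 um deep
        outer = np.array([[520.0, 500.0]])   # LZ side, ~20 um out
        beyond = np.array([[580.0, 500.0], [420.0, 500.0]])  # > 50 um + wiggle
        assert model.in_band(inner)[0] and model.in_band(outer)[0]
        assert not model.in_band(beyond).any()

    def test_signed_distance_zero_on_boundary_negative_in_dz(self):
        pts = half_square_points(n=2000, seed=2)
        poly = shapely.box(0, 0, 1000, 1000)
        model = g.delineate_interface(pts, poly)
        on_boundary = shapely.get_coordinates(model.boundary)[:1]
        assert abs(model.signed_distance(on_boundary)[0]) < 1e-9
        assert model.signed_distance([[200.0, 500.0]])[0] < 0
        assert model.signed_distance([[800.0, 500.0]])[0] > 0

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            g.delineate_interface(pts, shapely.box(0, 0, 10, 10))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            g.delineate_interface(np.array([[0.0, 0.0], [1.0, 1.0]]), shapely.box(0, 0, 2, 2))


@pytest.fixture(scope="module")
def square_model():
    pts = half_square_points(n=3000, seed=3)
    poly = shapely.box(0, 0, 1000, 1000)
    return g.delineate_interface(pts, poly, band_width=100.0)


@pytest.fixture(scope="module")
def model():
    pts = half_square_points(n=2000, seed=8)
    return g.delineate_interface(pts, shapely.box(0, 0, 1000, 1000))


class TestDensityProfile:
    def test_uniform_phenotype_flat_profile(self, square_model):
        rng = np.random.default_rng(4)
        n = 6000
        cells = pd.DataFrame(
            {
                "cell_id": [f"u{i}" for i in range(n)],
                "x_um": rng.uniform(0, 1000, n),
                "y_um": rng.uniform(0, 1000, n),
                "phenotype": "U",
            }
        )
        cm = g.CellMap(cells, shapely.box(0, 0, 1000, 1000))
        prof = g.density_profile(cm, square_model, bin_width=10.0)
        counts = prof.counts["U"].to_numpy()
        expected = counts.sum() * prof.areas / prof.areas.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy import stats

        assert stats.chi2.sf(chi2, df=len(counts) - 1) > 0.01

    def test_planted_decay_into_dz(self, square_model):
        # T density decays exponentially with depth into the DZ, flat outside
        rng = np.random.default_rng(5)
        xs = []
        # LZ side: uniform over 500..1000
        xs.append(rng.uniform(500, 1000, 3000))
        # DZ side: depth from boundary with exp scale 15 um (steep decay)
        depth = rng.exponential(15.0, 2000)
        xs.append(500 - depth[depth < 500])
        x = np.concatenate(xs)
        cells = pd.DataFrame(
            {
                "cell_id": [f"t{i}" for i in range(len(x))],
                "x_um": x,
                "y_um": rng.uniform(0, 1000, len(x)),
                "phenotype": "T",
            }
        )
        cm = g.CellMap(cells, shapely.box(0, 0, 1000, 1000))
        prof = g.density_profile(cm, square_model, bin_width=10.0)
        dens = prof.densities["T"].to_numpy()
        inner = dens[:5]     # DZ side, deepest first
        assert all(a < b for a, b in zip(inner, inner[1:]))

    def test_absent_phenotype_zero_profile(self, square_model):
        cm = random_cellmap(10, 10, seed=6, side=1000.0)
        prof = g.density_profile(cm, square_model, phenotypes=["missing"])
        assert (prof.densities["missing"] == 0).all()

    def test_bad_bin_width_rejected(self, square_model):
        cm = random_cellmap(10, 10, seed=7)
        with pytest.raises(ValueError):
            g.density_profile(cm, square_model, bin_width=0)


class TestRangeNormalized:
    def test_boundary_zero_deepest_one(self, model):
        pts = np.array(
            [[500.0, 500.0], [5.0, 500.0], [995.0, 500.0], [700.0, 500.0]]
        )
        comp = np.array(["DZ", "DZ", "LZ", "LZ"])
        out = g.range_normalized_distance(pts, model, comp)
        assert out["norm_d"].iloc[0] == pytest.approx(0.0, abs=0.05)
        assert out["norm_d"].iloc[1] == 1.0   # deepest DZ cell
        assert out["norm_d"].iloc[2] == 1.0   # deepest LZ cell
        assert bool(out["close"].iloc[0]) and not bool(out["close"].iloc[1])

    def test_threshold_splits_uniform_depth(self, model):
        xs = np.linspace(500.0, 0.0, 1001)  # uniform depth into DZ
        pts = np.column_stack([xs, np.full_like(xs, 500.0)])
        out = g.range_normalized_distance(pts, model, np.repeat("DZ", len(xs)))
        frac_close = out["close"].mean()
        assert frac_close == pytest.approx(0.4, abs=0.05)

    def test_singleton_compartment_flagged(self, model):
        pts = np.array([[400.0, 500.0], [600.0, 500.0], [700.0, 500.0]])
        out = g.range_normalized_distance(pts, model, np.array(["DZ", "LZ", "LZ"]))
        assert bool(out["flagged"].iloc[0]) and np.isnan(out["norm_d"].iloc[0])


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(20.0)
        res = g.correlate(x, 2 * x, n_perm=499, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 500)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = g.correlate(x, y, n_perm=500, seed=0)  # 5! = 120 <= 500
        assert res.exhaustive
        r_obs = np.corrcoef(x, y)[0, 1]
        count = sum(
            abs(np.corrcoef(x, y[list(p)])[0, 1]) >= abs(r_obs) - 1e-12
            for p in itertools.permutations(range(5))
        )
        assert res.p == pytest.approx(count / math.factorial(5))

    def test_symmetry_of_point_estimate(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert g.correlate(x, y, n_perm=99).r == pytest.approx(
            g.correlate(y, x, n_perm=99).r
        )

    def test_kendall_p_invariant_under_monotone_rescale(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        a = g.correlate(x, y, method="kendall", n_perm=299, seed=5)
        b = g.correlate(x, np.exp(y), method="kendall", n_perm=299, seed=5)
        assert a.p == b.p and a.r == pytest.approx(b.r)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = g.correlate(x, y, n_perm=99, b_boot=300, seed=1)
        assert res.ci_low <= res.r <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            g.correlate(np.ones(10), np.arange(10.0))


class TestProximityComparison:
    def test_planted_proximity_detected(self):
        rng = np.random.default_rng(13)
        r1 = rng.uniform(0, 200, (80, 2))
        r2 = rng.uniform(0, 200, (80, 2))
        a = r1[:40] + rng.normal(0, 1.0, (40, 2))  # A hugs R1
        n = len(a) + len(r1) + len(r2)
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "x_um": np.concatenate([a[:, 0], r1[:, 0], r2[:, 0]]),
                "y_um": np.concatenate([a[:, 1], r1[:, 1], r2[:, 1]]),
                "phenotype": ["A"] * len(a) + ["R1"] * len(r1) + ["R2"] * len(r2),
            }
        )
        cm = g.CellMap(cells, shapely.box(-10, -10, 210, 210))
        res = g.nn_proximity_comparison(cm, ["A"], ["R1", "R2"])
        med = res.medians.set_index(["query", "reference"])["median_um"]
        assert med[("A", "R1")] < med[("A", "R2")]
        assert res.pairwise["p"].iloc[0] < 0.01

    def test_symmetric_references_not_significant(self):
        cm = random_cellmap(60, 120, seed=14)
        # split B into two uniform halves
        cells = cm.cells.copy()
        b_idx = cells.index[cells.phenotype == "B"]
        cells.loc[b_idx[:60], "phenotype"] = "R1"
        cells.loc[b_idx[60:], "phenotype"] = "R2"
        cm2 = g.CellMap(cells, cm.polygon)
        res = g.nn_proximity_comparison(cm2, ["A"], ["R1", "R2"])
        assert res.pairwise["p"].iloc[0] > 0.05

    def test_missing_type_named_in_error(self):
        cm = random_cellmap(10, 10, seed=15)
        with pytest.raises(ValueError, match="ghost"):
            g.nn_proximity_comparison(cm, ["A"], ["ghost"])
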