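"""Synthetic archipelago generator: landscape, metrics, occupancy."""

import numpy as np
import pytest
from scipy import ndimage, stats
from scipy.special import expit

import skerrydiv as sd
from skerrydiv.synthetic import (
    ISLAND,
    MAINLAND,
    WATER,
    GENERALIST_MEANS,
    SPECIALIST_MEANS,
)
from skerrydiv.errors import ValidationError

from conftest import make_square


@pytest.fixture(scope="module")
def landscape():
    return sd.generate_landscape(sd.LandscapeParams(seed=3))


class TestLandscape:
    def test_seeded_determinism(self):
        p = sd.LandscapeParams(n_cols=8, n_rows=5, n_islands=40, seed=9)
        a = sd.generate_landscape(p)
        b = sd.generate_landscape(p)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_cell_size_must_divide_1km(self):
        with pytest.raises(ValidationError):
            sd.LandscapeParams(cell_size=300.0)

    def test_mainland_touches_west_and_is_connected(self, landscape):
        mainland = landscape.mask == MAINLAND
        assert mainland[:, 0].all()
        n_components = ndimage.label(mainland)[1]
        assert n_components == 1

    def test_partition_land_water_per_square(self, landscape):
        k = landscape.k
        rows, cols = landscape.squares_shape
        for si in range(rows):
            for sj in range(cols):
                block = landscape.mask[si * k:(si + 1) * k, sj * k:(sj + 1) * k]
                water = (block == WATER).sum()
                land = ((block == ISLAND) | (block == MAINLAND)).sum()
                assert water + land == k * k

    def test_island_size_decays_seaward(self):
        p = sd.LandscapeParams(
            n_cols=20, n_rows=10, n_islands=200, radius_decay=0.005,
            island_radius=2000.0, seed=5,
        )
        r = sd.generate_landscape(p)
        labels, n = ndimage.label(r.mask == ISLAND)
        assert n > 30
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        cy, cx = zip(*ndimage.center_of_mass(r.mask == ISLAND, labels,
                                             np.arange(1, n + 1)))
        # seaward distance proxy: x position (mainland sits on the west)
        res = stats.spearmanr(sizes, cx)
        assert res.statistic < 0
        assert res.pvalue < 0.01


class TestDeriveEnvironment:
    def test_land_area_arithmetic(self, landscape):
        squares = sd.derive_environment(landscape)
        k, cs = landscape.k, landscape.cell_size
        land = landscape.mask != WATER
        si, sj = 3, 4
        cells = land[si * k:(si + 1) * k, sj * k:(sj + 1) * k].sum()
        rec = {s.square_id: s for s in squares}[f"r{si:03d}c{sj:03d}"]
        assert rec.land_area == pytest.approx(cells * cs * cs)

    def test_isolated_cell_has_four_edge_shoreline(self):
        # 1x2 km map, 50 m cells: mainland column west, one lone island cell
        k = 20
        mask = np.full((k, 2 * k), WATER, dtype=np.int8)
        mask[:, 0] = MAINLAND
        mask[10, 30] = ISLAND
        r = sd.RasterLandscape(cell_size=50.0, mask=mask)
        squares = {s.square_id: s for s in sd.derive_environment(r)}
        assert squares["r000c001"].shoreline == pytest.approx(4 * 50.0)
        assert squares["r000c001"].land_area == pytest.approx(2500.0)

    def test_width_is_mainland_distance_plus_dist_sea(self, landscape):
        squares = sd.derive_environment(landscape)
        mainland = landscape.mask == MAINLAND
        d_main = ndimage.distance_transform_edt(~mainland, sampling=landscape.cell_size)
        k = landscape.k
        for s in squares:
            si = int(s.square_id[1:4])
            sj = int(s.square_id[5:8])
            expected = d_main[si * k + k // 2, sj * k + k // 2]
            assert s.width - s.dist_sea == pytest.approx(expected)
            assert s.dist_sea >= 0
            assert s.width >= s.dist_sea


def _grid_squares(n_side, rng):
    squares = []
    for i in range(n_side):
        for j in range(n_side):
            dist = float(rng.uniform(0, 10_000))
            squares.append(
                sd.SquareRecord(
                    f"g{i:02d}{j:02d}", x=1000.0 * j, y=1000.0 * i,
                    land_area=float(rng.uniform(1e4, 9e5)),
                    shoreline=float(rng.uniform(100, 4000)),
                    dist_sea=dist, width=dist + float(rng.uniform(0, 5000)),
                )
            )
    return squares


class TestSimulateOccurrences:
    def test_seeded_determinism(self, rng):
        squares = _grid_squares(8, np.random.default_rng(0))
        sp = sd.SimulationParams(seed=13)
        a = sd.simulate_occurrences(squares, sp)
        b = sd.simulate_occurrences(squares, sp)
        np.testing.assert_array_equal(
            a.occ.presence.to_numpy(), b.occ.presence.to_numpy()
        )

    def test_null_coefficients_give_half_occupancy(self):
        squares = _grid_squares(15, np.random.default_rng(1))[:200]
        zeros = {k: 0.0 for k in SPECIALIST_MEANS}
        sp = sd.SimulationParams(
            n_specialist=10, n_generalist=10,
            specialist_means=zeros, generalist_means=zeros,
            coef_sd=0.0, intercept_sd=0.0, field_amplitude=0.0, seed=21,
        )
        ds = sd.simulate_occurrences(squares, sp)
        frac = ds.occ.presence.to_numpy().mean()
        n = ds.occ.presence.size
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_specialist_richness_declines_seaward_distance(self):
        squares = _grid_squares(20, np.random.default_rng(2))
        ds = sd.simulate_occurrences(squares, sd.SimulationParams(seed=33))
        rt = sd.richness(ds)
        dist = [s.dist_sea for s in squares]
        r_spec = np.corrcoef(rt["specialist"], dist)[0, 1]
        r_gen = np.corrcoef(rt["generalist"], dist)[0, 1]
        assert r_spec < 0
        assert r_gen > 0

    def test_raising_coefficient_does_not_reduce_occupancy_above_mean(self):
        squares = _grid_squares(14, np.random.default_rng(3))
        base = {k: 0.0 for k in SPECIALIST_MEANS}
        raised = dict(base, shoreline=1.0)
        kw = dict(n_specialist=1, n_generalist=0, coef_sd=0.0, intercept_sd=0.0,
                  field_amplitude=0.0, seed=8)
        ds0 = sd.simulate_occurrences(squares, sd.SimulationParams(specialist_means=base, **kw))
        ds1 = sd.simulate_occurrences(squares, sd.SimulationParams(specialist_means=raised, **kw))
        shore = np.array([s.shoreline for s in squares])
        above = shore > shore.mean()
        n0 = ds0.occ.presence.to_numpy()[above].sum()
        n1 = ds1.occ.presence.to_numpy()[above].sum()
        assert n1 >= n0

    def test_truth_table_in_provenance(self, desk_ds):
        truth = sd.synthetic.truth_table(desk_ds)
        assert len(truth) == 48
        assert (truth.classification == "specialist").sum() == 19
        spec = truth[truth.classification == "specialist"]
        # group-mean signs are encoded in the drawn coefficients
        assert spec["dist_sea"].mean() < 0
        gen = truth[truth.classification == "generalist"]
        assert gen["dist_sea"].mean() > 0

    def test_group_sizes_and_redlist_mix(self, desk_ds):
        tf = desk_ds.occ.trait_frame()
        assert (tf.classification == "specialist").sum() == 19
        assert (tf.classification == "generalist").sum() == 29
        assert (tf.redlist != "none").sum() == 14
        spec_rl = tf[(tf.classification == "specialist") & (tf.redlist != "none")]
        assert len(spec_rl) == 7
        assert (spec_rl.redlist == "VU").sum() == 3
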