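"""Movement-kernel UD: oracle equivalence, closed forms, isopleth logic."""

import math

import numpy as np
import pytest

from roamrange import (
    BRBParams, compute_brb_ud, estimate_diffusion, extract_isopleth,
    isopleth_mask, SimConfig, simulate_track, clean_track, home_range,
)
from conftest import make_track


# ---------------------------------------------------------------------------
# Independent brute-force oracle: direct summation of every kernel
# contribution at every cell centre, written against the deposit rule
# itself (bridged substeps with variance hmin^2 + 4 D T p (1-p); endpoint
# deposits at hmin for gaps/sub-Lmin steps), with no windowing.
# ---------------------------------------------------------------------------

def brute_force_ud(track, params: BRBParams, diffusion: float) -> np.ndarray:
    xy = track.xy()
    t = track.times_s()
    x0 = xy[:, 0].min() - params.extent_pad
    x1 = xy[:, 0].max() + params.extent_pad
    y0 = xy[:, 1].min() - params.extent_pad
    y1 = xy[:, 1].max() + params.extent_pad
    n_cols = int(np.ceil((x1 - x0) / params.cell_size))
    n_rows = int(np.ceil((y1 - y0) / params.cell_size))
    xs = x0 + (np.arange(n_cols) + 0.5) * params.cell_size
    ys = y0 + (np.arange(n_rows) + 0.5) * params.cell_size

    deposits = []  # (x, y, weight, sigma)
    if len(xy) == 1:
        deposits.append((xy[0, 0], xy[0, 1], 1.0, params.hmin))
    else:
        T = np.diff(t)
        L = np.hypot(*np.diff(xy, axis=0).T)
        tmax = params.tmax_s if params.tmax_s is not None else 3.0 * np.median(T[T > 0])
        for i in range(len(T)):
            if T[i] <= 0:
                continue
            if T[i] <= tmax and L[i] >= params.lmin:
                for k in range(params.n_substeps):
                    p = (k + 0.5) / params.n_substeps
                    px, py = xy[i] + p * (xy[i + 1] - xy[i])
                    var = params.hmin**2 + 4.0 * diffusion * T[i] * p * (1.0 - p)
                    deposits.append((px, py, T[i] / params.n_substeps, math.sqrt(var)))
            else:
                for j in (i, i + 1):
                    deposits.append((xy[j, 0], xy[j, 1], T[i] / 2.0, params.hmin))

    grid = np.zeros((n_rows, n_cols))
    for px, py, w, s in deposits:
        for r in range(n_rows):
            for c in range(n_cols):
                d2 = (xs[c] - px) ** 2 + (ys[r] - py) ** 2
                grid[r, c] += (
                    w * params.cell_size**2 / (2 * math.pi * s**2)
                    * math.exp(-0.5 * d2 / s**2)
                )
    return grid / grid.sum()


SMALL = BRBParams(cell_size=20.0, hmin=25.0, extent_pad=100.0, diffusion_D=1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("xy,dt", [
        ([(0.0, 0.0)], 60),                                     # single fix
        ([(0, 0), (80, 30)], 60),                               # one bridged step
        ([(0, 0), (60, 0), (60, 90)], 60),                      # 3-fix track
        ([(0, 0), (2, 1), (120, 40), (125, 44), (60, 200)], 60),  # sub-Lmin mix
    ])
    def test_grid_matches_brute_force(self, xy, dt):
        track = make_track(xy, dt_s=dt)
        ud = compute_brb_ud(track, SMALL)
        oracle = brute_force_ud(track, SMALL, diffusion=SMALL.diffusion_D)
        assert ud.mass.shape == oracle.shape
        assert np.max(np.abs(ud.mass - oracle)) < 1e-10

    def test_long_gap_deposits_at_endpoints(self):
        # middle step is a 2 h gap (> Tmax) -> endpoint deposits dominate
        import pandas as pd

        track = make_track([(0, 0), (50, 0), (50, 0), (400, 0), (450, 0)], dt_s=60)
        ts0 = track.fixes["timestamp"].iloc[0]
        track.fixes["timestamp"] = ts0 + pd.to_timedelta([0, 60, 7260, 7320, 7380], unit="s")
        ud = compute_brb_ud(track, SMALL)
        oracle = brute_force_ud(track, SMALL, diffusion=SMALL.diffusion_D)
        assert np.max(np.abs(ud.mass - oracle)) < 1e-10
        # mass concentrates at the gap endpoints, not along the gap line
        xs, ys = ud.cell_centers()
        mid = ud.mass[np.argmin(np.abs(ys - 0.0)), np.argmin(np.abs(xs - 225.0))]
        end = ud.mass[np.argmin(np.abs(ys - 0.0)), np.argmin(np.abs(xs - 50.0))]
        assert end > 10 * mid


class TestDiffusionEstimate:
    def test_closed_form(self):
        # all steps 20 m in 60 s -> D = 400 / 240
        track = make_track([(0, 0), (20, 0), (40, 0), (60, 0)], dt_s=60)
        assert estimate_diffusion(track, BRBParams()) == pytest.approx(400 / 240)

    def test_all_steps_below_lmin_error(self):
        track = make_track([(0, 0), (1, 0), (2, 0)], dt_s=60)
        with pytest.raises(ValueError, match="no steps qualify"):
            estimate_diffusion(track, BRBParams())

    def test_order_of_magnitude_on_simulated_ou(self):
        # pure OU around the home anchor (no excursions): the plug-in
        # estimator is biased for OU (mean reversion shrinks steps, drift
        # inflates them), so only a factor-2 agreement is claimed
        est, truth = [], []
        for seed in range(30):
            cfg = SimConfig(deployment_hours=12.0, diffusion_true=1.0, seed=100 + seed)
            track, _ = simulate_track(cfg)
            clean, _ = clean_track(track)
            est.append(estimate_diffusion(clean, BRBParams()))
            truth.append(cfg.diffusion_true)
        ratio = np.mean(est) / np.mean(truth)
        assert 0.5 < ratio < 2.0


class TestGaussianClosedForm:
    def test_area_ratio_and_absolute_areas(self):
        # stationary track -> isotropic Gaussian, sd = hmin;
        # area(p) = 2 pi sigma^2 ln(1/(1-p))
        track = make_track([(500.0, 500.0)] * 6, dt_s=60)
        params = BRBParams(cell_size=5.0, hmin=25.0, extent_pad=250.0)
        ud = compute_brb_ud(track, params)
        assert abs(ud.mass.sum() - 1.0) < 1e-6
        a50 = extract_isopleth(ud, 50.0).total_area_ha
        a95 = extract_isopleth(ud, 95.0).total_area_ha
        assert a95 / a50 == pytest.approx(math.log(20) / math.log(2), rel=0.05)
        sigma2 = params.hmin**2
        assert a50 * 1e4 == pytest.approx(2 * math.pi * sigma2 * math.log(2), rel=0.05)
        assert a95 * 1e4 == pytest.approx(2 * math.pi * sigma2 * math.log(20), rel=0.05)


class TestIsopleths:
    def _gaussian_ud(self):
        track = make_track([(0.0, 0.0)] * 3, dt_s=60)
        return compute_brb_ud(track, BRBParams(cell_size=5.0, hmin=25.0, extent_pad=150.0))

    def test_level_validation(self):
        ud = self._gaussian_ud()
        for bad in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                extract_isopleth(ud, bad)

    def test_level_100_covers_whole_grid(self):
        ud = self._gaussian_ud()
        iso = extract_isopleth(ud, 100.0)
        assert iso.cell_mask.all()
        assert iso.total_area_ha == pytest.approx(
            ud.n_rows * ud.n_cols * ud.cell_size**2 / 1e4
        )

    def test_uniform_mass_selects_exact_count(self):
        from roamrange import UDGrid

        mass = np.zeros((20, 20))
        mass[:10, :10] = 1.0  # 100 equal cells
        mass /= mass.sum()
        ud = UDGrid(origin=(0.0, 0.0), cell_size=10.0, mass=mass)
        iso = extract_isopleth(ud, 50.0)
        assert iso.cell_mask.sum() == 50
        assert iso.total_area_ha == pytest.approx(50 * 100 / 1e4)

    def test_nesting_across_levels(self, roaming_dog):
        track, _ = roaming_dog
        clean, _ = clean_track(track)
        ud = compute_brb_ud(clean, BRBParams(cell_size=20.0))
        masks = [isopleth_mask(ud, lvl) for lvl in (10.0, 50.0, 90.0, 95.0)]
        for a, b in zip(masks, masks[1:]):
            assert (a <= b).all()  # smaller level set contained in larger

    def test_grid_refinement_stability(self):
        track = make_track([(0, 0), (60, 10), (110, 60), (130, 120)], dt_s=60)
        areas = {}
        for cell in (10.0, 5.0):
            ud = compute_brb_ud(track, BRBParams(cell_size=cell, diffusion_D=1.0))
            areas[cell] = extract_isopleth(ud, 95.0).total_area_ha
        assert areas[5.0] == pytest.approx(areas[10.0], rel=0.05)


class TestCentroids:
    def test_single_square_polygon_center(self):
        from roamrange import UDGrid

        mass = np.zeros((10, 10))
        mass[2:4, 2:4] = 1.0
        mass /= mass.sum()
        ud = UDGrid(origin=(0.0, 0.0), cell_size=10.0, mass=mass)
        iso = extract_isopleth(ud, 99.0)
        assert len(iso.centroids_xy) == 1
        assert iso.centroids_xy[0] == pytest.approx((30.0, 30.0))

    def test_l_shape_arithmetic_mean(self):
        from roamrange import UDGrid

        mass = np.zeros((5, 5))
        # cells centred at (5,5), (15,5), (5,15) for cell 10, origin 0
        mass[0, 0] = mass[0, 1] = mass[1, 0] = 1.0
        mass /= mass.sum()
        ud = UDGrid(origin=(0.0, 0.0), cell_size=10.0, mass=mass)
        iso = extract_isopleth(ud, 99.0)
        assert len(iso.centroids_xy) == 1
        cx, cy = iso.centroids_xy[0]
        assert (cx, cy) == pytest.approx((25 / 3, 25 / 3))

    def test_two_disjoint_polygons_two_centroids(self):
        from roamrange import UDGrid

        mass = np.zeros((10, 10))
        mass[1, 1] = mass[8, 8] = 1.0  # diagonal touch impossible: far apart
        mass /= mass.sum()
        ud = UDGrid(origin=(0.0, 0.0), cell_size=10.0, mass=mass)
        iso = extract_isopleth(ud, 99.0)
        assert len(iso.polygons) == 2
        assert len(iso.centroids_xy) == 2

    def test_diagonal_touch_is_two_polygons(self):
        from roamrange import UDGrid

        mass = np.zeros((5, 5))
        mass[1, 1] = mass[2, 2] = 1.0
        mass /= mass.sum()
        ud = UDGrid(origin=(0.0, 0.0), cell_size=10.0, mass=mass)
        iso = extract_isopleth(ud, 99.0)
        assert len(iso.polygons) == 2  # 4-connectivity: diagonals separate

    def test_home_pinned_dog_centroid_near_household(self):
        cfg = SimConfig(seed=21, deployment_hours=24.0)  # no attraction sites
        track, _ = simulate_track(cfg)
        clean, _ = clean_track(track)
        hr = home_range(clean, BRBParams(cell_size=10.0), levels=(50.0,))
        (cx, cy), = hr[50.0].centroids_xy
        hx, hy = clean.household_xy
        assert math.hypot(cx - hx, cy - hy) <= 2 * 10.0


def test_params_validation():
    with pytest.raises(ValueError):
        BRBParams(hmin=0.0)
    with pytest.raises(ValueError):
        BRBParams(cell_size=50.0, extent_pad=10.0)
    with pytest.raises(ValueError):
        compute_brb_ud(
            make_track([(0, 0), (500000, 500000)], dt_s=60),
            BRBParams(cell_size=10.0, max_cells=10000),
        )
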