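"""Raster covariates: TTLQV, densities, VRM, phenology, distance, design, VIF."""

import numpy as np
import pandas as pd
import pytest

from caribou_rsf.covariates import (
    DesignSpec,
    build_design,
    distance_to_coast,
    moving_window_density,
    ndvi_phenology,
    ttlqv_profile,
    ttlqv_scale,
    vif,
    vif_prune,
    vrm,
)
from caribou_rsf.raster import Raster


def stripe_raster(width, n_periods=8, cell=30.0):
    n = 2 * width * n_periods
    col = (np.arange(n) // width) % 2
    return Raster(np.tile(col, (n, 1)).astype(float), cell)


def v3_nested_loop(img, max_block):
    """Independent transect-definition oracle for the TTLQV statistic."""
    out = np.full(max_block, np.nan)
    for b in range(1, max_block + 1):
        vals = []
        for arr in (img, img.T):
            n = arr.shape[1]
            if n < 3 * b:
                continue
            for r in range(arr.shape[0]):
                x = arr[r]
                for i in range(0, n - 3 * b + 1):
                    s1 = x[i:i + b].sum()
                    s2 = x[i + b:i + 2 * b].sum()
                    s3 = x[i + 2 * b:i + 3 * b].sum()
                    vals.append((s1 - 2 * s2 + s3) ** 2 / (8 * b))
        if vals:
            out[b - 1] = float(np.mean(vals))
    return out


class TestTTLQV:
    def test_profile_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        img = (rng.random((18, 22)) < 0.4).astype(float)
        mine = ttlqv_profile(img, 6)
        oracle = v3_nested_loop(img, 6)
        np.testing.assert_allclose(mine, oracle, rtol=1e-12)

    @pytest.mark.parametrize("width", [4, 8, 16])
    def test_stripe_scale_near_patch_width(self, width):
        # the quadrat-variance peak sits at ~0.93x the patch width in the
        # continuous limit, so the detected block lands within one block of it
        r = stripe_raster(width)
        b_star = ttlqv_scale(r, 1, max_block=2 * width) / r.cell_size
        assert width - 1 <= b_star <= width

    def test_transpose_invariant(self):
        r = stripe_raster(4)
        rt = Raster(r.data.T.copy(), r.cell_size)
        assert ttlqv_scale(r, 1, max_block=12) == ttlqv_scale(rt, 1, max_block=12)

    def test_degenerate_indicator_raises(self):
        r = Raster(np.ones((20, 20)), 30.0)
        with pytest.raises(ValueError, match="degenerate"):
            ttlqv_scale(r, 0, max_block=4)  # class covers the whole raster
        with pytest.raises(ValueError, match="degenerate"):
            ttlqv_scale(r, 5, max_block=4)  # class absent


class TestDensity:
    def test_uniform_class_gives_density_one(self):
        r = Raster(np.ones((10, 10)), 30.0, nodata=-1)
        assert (moving_window_density(r, 1, 90.0).data == 1.0).all()

    def test_single_cell_center_value(self):
        a = np.zeros((9, 9))
        a[4, 4] = 1
        r = Raster(a, 30.0, nodata=-1)
        d = moving_window_density(r, 1, 90.0)
        assert d.data[4, 4] == pytest.approx(1 / 9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        r = Raster(rng.integers(0, 3, (20, 20)), 30.0, nodata=-1)
        d = moving_window_density(r, 2, 150.0).data  # 5x5 window
        for i, j in [(0, 0), (3, 17), (10, 10), (19, 2)]:
            win = r.data[max(i - 2, 0):i + 3, max(j - 2, 0):j + 3]
            assert d[i, j] == pytest.approx((win == 2).sum() / win.size)

    def test_full_window_equals_global_proportion(self):
        rng = np.random.default_rng(2)
        r = Raster(rng.integers(0, 2, (15, 15)), 30.0, nodata=-1)
        # window much larger than the raster: every cell sees all cells
        d = moving_window_density(r, 1, 30.0 * 61).data
        assert np.allclose(d, (r.data == 1).mean())

    def test_bounded(self):
        rng = np.random.default_rng(3)
        r = Raster(rng.integers(0, 4, (30, 30)), 30.0, nodata=-1)
        d = moving_window_density(r, 1, 210.0).data
        assert d.min() >= 0.0 and d.max() <= 1.0


class TestVRM:
    def test_flat_dem_zero(self):
        assert vrm(Raster(np.full((20, 20), 7.0), 30.0), 8).data.max() == 0.0

    def test_inclined_plane_zero(self):
        rr, cc = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        r = Raster(3.0 * rr - 2.0 * cc + 10, 30.0)
        assert vrm(r, 8).data.max() == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_invariant(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0, 5, (16, 16))
        a = vrm(Raster(z, 30.0), 4).data
        b = vrm(Raster(z + 123.4, 30.0), 4).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounded_zero_one(self):
        rng = np.random.default_rng(5)
        v = vrm(Raster(rng.normal(0, 30, (25, 25)), 30.0), 8).data
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 10, (15, 15))
        mine = vrm(Raster(z, 30.0), 5).data

        # independent nested-loop oracle: Horn gradients on the interior,
        # border replicated, unit normals summed over clamped 5x5 windows
        p = np.zeros_like(z)
        q = np.zeros_like(z)
        for i in range(1, 14):
            for j in range(1, 14):
                p[i, j] = ((z[i - 1, j + 1] + 2 * z[i, j + 1] + z[i + 1, j + 1])
                           - (z[i - 1, j - 1] + 2 * z[i, j - 1] + z[i + 1, j - 1])) / (8 * 30.0)
                q[i, j] = ((z[i - 1, j - 1] + 2 * z[i - 1, j] + z[i - 1, j + 1])
                           - (z[i + 1, j - 1] + 2 * z[i + 1, j] + z[i + 1, j + 1])) / (8 * 30.0)
        for arr in (p, q):
            arr[0, :] = arr[1, :]
            arr[-1, :] = arr[-2, :]
            arr[:, 0] = arr[:, 1]
            arr[:, -1] = arr[:, -2]
        norm = np.sqrt(1 + p**2 + q**2)
        nx, ny, nz = -p / norm, -q / norm, 1 / norm
        oracle = np.zeros_like(z)
        for i in range(15):
            for j in range(15):
                ii = np.clip(np.arange(i - 2, i + 3), 0, 14)
                jj = np.clip(np.arange(j - 2, j + 3), 0, 14)
                sx = nx[np.ix_(ii, jj)].sum()
                sy = ny[np.ix_(ii, jj)].sum()
                sz = nz[np.ix_(ii, jj)].sum()
                oracle[i, j] = 1 - np.sqrt(sx**2 + sy**2 + sz**2) / 25
        assert np.abs(mine - oracle).max() < 1e-10

    def test_too_small_dem_raises(self):
        with pytest.raises(ValueError):
            vrm(Raster(np.zeros((3, 3)), 30.0), 8)


class TestPhenology:
    def make_stack(self, series, doys=None):
        doys = doys or list(range(150, 150 + 10 * len(series), 10))
        return {d: Raster(np.full((2, 2), v), 30.0, nodata=np.nan)
                for d, v in zip(doys, series)}

    def test_standard_season(self):
        g, m, s = ndvi_phenology(self.make_stack([0.05, 0.2, 0.6, 0.3, 0.08]))
        assert (g.data[0, 0], m.data[0, 0], s.data[0, 0]) == (160, 170, 190)

    def test_never_green_is_nodata(self):
        g, m, s = ndvi_phenology(self.make_stack([0.05, 0.06, 0.04]))
        assert np.isnan(g.data).all() and np.isnan(m.data).all() and np.isnan(s.data).all()

    def test_tie_at_max_takes_earlier_date(self):
        g, m, s = ndvi_phenology(self.make_stack([0.05, 0.6, 0.6, 0.05]))
        assert m.data[0, 0] == 160

    def test_no_senescence_observed(self):
        g, m, s = ndvi_phenology(self.make_stack([0.05, 0.3, 0.6]))
        assert g.data[0, 0] == 160 and m.data[0, 0] == 170 and np.isnan(s.data[0, 0])

    def test_ordering_invariant(self, small_landscape):
        g, m, s = ndvi_phenology(small_landscape.ndvi)
        ok = np.isfinite(g.data) & np.isfinite(m.data) & np.isfinite(s.data)
        assert (g.data[ok] <= m.data[ok]).all() and (m.data[ok] <= s.data[ok]).all()

    def test_too_few_composites(self):
        with pytest.raises(ValueError):
            ndvi_phenology(self.make_stack([0.1, 0.2]))


class TestDistanceToCoast:
    def test_coast_cell_zero_and_straight_line(self):
        mask = np.zeros((12, 12), bool)
        mask[3, 1] = True
        d = distance_to_coast(Raster(mask, 30.0)).data
        assert d[3, 1] == 0.0
        assert d[3, 11] == pytest.approx(300.0)  # 10 cells due east

    def test_matches_all_pairs_minimum(self):
        rng = np.random.default_rng(6)
        mask = rng.random((30, 30)) < 0.04
        mask[4, 9] = True
        d = distance_to_coast(Raster(mask, 30.0)).data
        coords = np.argwhere(mask)
        for i in range(0, 30, 7):
            for j in range(0, 30, 5):
                bf = 30.0 * np.sqrt(((coords - [i, j]) ** 2).sum(axis=1)).min()
                assert d[i, j] == pytest.approx(bf)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            distance_to_coast(Raster(np.zeros((5, 5), bool), 30.0))


class TestBuildDesign:
    @pytest.fixture()
    def ready_stack(self, small_landscape):
        from caribou_rsf.covariates import attach_standard_layers

        if "vrm" not in small_landscape.layers:
            attach_standard_layers(small_landscape, max_block=8,
                                   density_classes=("dwarf_shrub",))
        return small_landscape

    def points_on(self, stack, n=400, seed=0):
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(stack.land)
        k = rng.integers(0, len(rows), n)
        x, y = stack.grid.rowcol_to_xy(rows[k], cols[k])
        return pd.DataFrame({"x": x, "y": y, "used": rng.integers(0, 2, n)})

    def test_reference_class_has_all_zero_dummies(self, ready_stack):
        pts = self.points_on(ready_stack)
        tab = build_design(pts, ready_stack, DesignSpec(covariates=("elevation",)))
        codes = ready_stack.veg_class.sample(tab.frame["x"].to_numpy(), tab.frame["y"].to_numpy())
        ref = ready_stack.class_names.index("sedge_grass_meadow")
        dummies = [c for c in tab.covariate_names if c.startswith("patch_")]
        in_ref = codes == ref
        assert in_ref.any()
        assert (tab.frame.loc[in_ref, dummies].to_numpy() == 0).all()
        assert "patch_sedge_grass_meadow" not in tab.covariate_names

    def test_standardized_columns_mean_zero_sd_one(self, ready_stack):
        pts = self.points_on(ready_stack, seed=1)
        tab = build_design(pts, ready_stack, DesignSpec(covariates=("elevation", "dist_coast", "vrm")))
        for name in ("elevation", "dist_coast", "vrm"):
            col = tab.frame[name].to_numpy()
            assert abs(col.mean()) < 1e-8
            assert col.std() == pytest.approx(1.0, abs=1e-8)

    def test_log_guard_at_zero_distance(self, ready_stack):
        # a point on the coast row has dist_coast 0 -> log(0 + cell_size)
        x, y = ready_stack.grid.rowcol_to_xy(0, 5)
        pts = pd.DataFrame({"x": [x], "y": [y], "used": [1]})
        spec = DesignSpec(covariates=("dist_coast",), standardize=False,
                          include_patch_dummies=False)
        tab = build_design(pts, ready_stack, spec)
        assert tab.frame["dist_coast"].iloc[0] == pytest.approx(np.log(30.0))

    def test_water_points_excluded_and_counted(self, ready_stack):
        wr, wc = np.nonzero(~ready_stack.land)
        x, y = ready_stack.grid.rowcol_to_xy(wr[:5], wc[:5])
        pts = pd.DataFrame({"x": x, "y": y, "used": 1})
        tab = build_design(pts, ready_stack, DesignSpec(covariates=()))
        assert len(tab.frame) == 0 and tab.n_excluded == 5

    def test_squared_terms_follow_standardization(self, ready_stack):
        pts = self.points_on(ready_stack, seed=2)
        spec = DesignSpec(covariates=("vrm",), squared_terms=("vrm",))
        tab = build_design(pts, ready_stack, spec)
        np.testing.assert_allclose(tab.frame["vrm_sq"], tab.frame["vrm"] ** 2)

    def test_stored_stats_reused_for_prediction(self, ready_stack):
        pts = self.points_on(ready_stack, seed=3)
        spec = DesignSpec(covariates=("elevation",))
        tab = build_design(pts, ready_stack, spec)
        other = self.points_on(ready_stack, seed=4)
        tab2 = build_design(other, ready_stack, spec, stats=tab.transforms)
        assert tab2.transforms["elevation"]["mean"] == tab.transforms["elevation"]["mean"]
        # with foreign stats the new table is not re-centered on itself
        assert abs(tab2.frame["elevation"].mean()) > 1e-8


class TestVIF:
    def test_orthogonal_columns_not_pruned(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        df = pd.DataFrame(q, columns=list("abcd"))
        keep, log = vif_prune(df)
        assert keep == list("abcd") and log == []
        assert np.allclose(vif(q), 1.0, atol=0.01)

    def test_duplicated_column_dropped_first(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        df = pd.DataFrame({"a": a, "b": rng.normal(size=100), "a2": a})
        keep, log = vif_prune(df)
        assert len(keep) == 2 and "b" in keep
        assert log[0][1] == np.inf

    def test_survivors_match_direct_r2(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 3))
        near = X[:, 0] + 0.9 * X[:, 1] + 0.02 * rng.normal(size=200)
        df = pd.DataFrame(np.column_stack([X, near]), columns=["a", "b", "c", "lc"])
        keep, log = vif_prune(df, threshold=3.0)
        # direct check: every survivor's R^2 against the others is < 2/3
        M = df[keep].to_numpy()
        for j in range(M.shape[1]):
            Z = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
            coef, *_ = np.linalg.lstsq(Z, M[:, j], rcond=None)
            resid = M[:, j] - Z @ coef
            r2 = 1 - resid.var() / M[:, j].var()
            assert 1.0 / (1.0 - r2) < 3.0
        assert log  # the near-collinear column (or a partner) was dropped

    def test_terminates_within_ncols_iterations(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(80, 2))
        cols = {f"c{i}": base[:, 0] + 1e-3 * i * base[:, 1] for i in range(5)}
        keep, log = vif_prune(pd.DataFrame(cols))
        assert len(log) <= 4 and len(keep) >= 1
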