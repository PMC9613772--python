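"""Ground-truth generator: determinism, class balance, plateau targeting,
correlation targeting, rendering consistency and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

import ktrdiv as kd
from ktrdiv.simulate import _activity_to_cyto_fraction, _smooth_flatfield


def window_sel(cfg):
    t = cfg.times_h
    return (t >= 8.5) & (t <= 40.0)


class TestSimulatePopulation:
    def test_seeded_determinism(self):
        cfg = kd.SimConfig(n_cells=12, seed=7)
        _, t1 = kd.simulate_cell_population(cfg)
        _, t2 = kd.simulate_cell_population(kd.SimConfig(n_cells=12, seed=7))
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        _, t1 = kd.simulate_cell_population(kd.SimConfig(n_cells=5, seed=1))
        _, t2 = kd.simulate_cell_population(kd.SimConfig(n_cells=5, seed=2))
        assert not t1.equals(t2)

    @pytest.mark.parametrize("n,frac,expected", [
        (100, 0.5, 50), (10, 0.25, 3), (7, 1.0, 7), (7, 0.0, 0)])
    def test_exact_class_balance(self, n, frac, expected):
        cfg = kd.SimConfig(n_cells=n, frac_dividing=frac, seed=0)
        cells, _ = kd.simulate_cell_population(cfg)
        assert sum(c.divides for c in cells) == expected

    def test_division_time_iff_divides(self):
        cells, _ = kd.simulate_cell_population(kd.SimConfig(n_cells=30, seed=4))
        for c in cells:
            assert (c.division_time_h is not None) == c.divides
            if c.divides:
                lo, hi = 16.0, 36.0
                assert lo <= c.division_time_h <= hi

    def test_frame_count(self):
        cfg = kd.SimConfig(n_cells=2, seed=0)
        cells, traces = kd.simulate_cell_population(cfg)
        assert cfg.n_frames == 193
        assert len(cells[0].erk_activity) == 193
        assert traces.groupby(["cell_id", "channel"]).size().eq(193).all()

    def test_plateau_median_effect_size(self):
        # empirical in-window medians of the latent series per class
        cfg = kd.SimConfig(n_cells=2000, effect_size_erk=0.4,
                           effect_size_akt=0.4, noise_sd=0.1, seed=0)
        cells, _ = kd.simulate_cell_population(cfg)
        sel = window_sel(cfg)
        div = np.median([c.erk_activity[sel] for c in cells if c.divides])
        nondiv = np.median([c.erk_activity[sel] for c in cells if not c.divides])
        assert div - nondiv == pytest.approx(0.4, abs=0.02)

    @pytest.mark.parametrize("dividing", [True, False])
    def test_correlation_targeting(self, dividing):
        cfg = kd.SimConfig(n_cells=500, seed=8)
        cells, _ = kd.simulate_cell_population(cfg)
        sel = window_sel(cfg)
        erk = np.concatenate([c.erk_activity[sel] for c in cells
                              if c.divides == dividing])
        akt = np.concatenate([c.akt_activity[sel] for c in cells
                              if c.divides == dividing])
        target = cfg.rho_div if dividing else cfg.rho_nondiv
        assert np.corrcoef(erk, akt)[0, 1] == pytest.approx(target, abs=0.05)

    def test_division_drop_injected(self):
        cfg = kd.SimConfig(n_cells=40, seed=5)
        cells, _ = kd.simulate_cell_population(cfg)
        for c in cells:
            if not c.divides:
                np.testing.assert_allclose(c.akt_cn, c.akt_activity)
                continue
            f = c.division_frame
            expect = np.clip(c.akt_activity[f] * (1 - cfg.drop_frac), 0.02, None)
            assert c.akt_cn[f] == pytest.approx(expect)
            # trace continues after the drop span (daughter tracking)
            np.testing.assert_allclose(
                c.akt_cn[f + cfg.drop_span_frames:],
                c.akt_activity[f + cfg.drop_span_frames:])

    @pytest.mark.parametrize("kw", [
        dict(n_cells=0), dict(frac_dividing=1.5),
        dict(division_window_h=(0.5, 36.0)), dict(rho_div=1.5),
        dict(drop_frac=0.0), dict(sampling_interval_h=0.0)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            kd.SimConfig(**kw)


class TestCrosstalkGenerator:
    def test_inhibition_suppresses_own_rise_only(self):
        cfg = kd.SimConfig(n_cells=60, frac_dividing=0.0, duration_h=12,
                           division_window_h=(2, 11), seed=6)
        ctrl = kd.simulate_crosstalk_experiment(cfg, None, seed=1)
        pert = kd.simulate_crosstalk_experiment(cfg, "erk", seed=1)
        late = lambda df, ch: df[(df.channel == ch) & (df.time_h > 6)][
            "cn_ratio"].median()
        assert late(pert, "erk") < late(ctrl, "erk") - 0.3
        assert late(pert, "akt") == pytest.approx(late(ctrl, "akt"), abs=0.05)

    def test_crosstalk_edge_propagates(self):
        cfg = kd.SimConfig(n_cells=60, frac_dividing=0.0, duration_h=12,
                           division_window_h=(2, 11),
                           crosstalk_erk_to_akt=0.8, seed=6)
        ctrl = kd.simulate_crosstalk_experiment(cfg, None, seed=1)
        pert = kd.simulate_crosstalk_experiment(cfg, "erk", seed=1)
        late = lambda df, ch: df[(df.channel == ch) & (df.time_h > 6)][
            "cn_ratio"].median()
        assert late(pert, "akt") < late(ctrl, "akt") - 0.3


class TestRender:
    def test_empty_scene_is_background(self, short_sim):
        cfg, cells, _ = short_sim
        rc = kd.RenderConfig(psf_sigma_px=0.0, gaussian_noise_sd=0.0,
                             flatfield_amplitude=0.0, background_offset=7.0)
        # a cell list is required, but a frame with every cell out of view
        # must be pure background: move one cell far outside
        lone = [kd.GroundTruthCell(
            cell_id=0, divides=False, division_time_h=None, division_frame=None,
            erk_activity=cells[0].erk_activity, akt_activity=cells[0].akt_activity,
            erk_cn=cells[0].erk_cn, akt_cn=cells[0].akt_cn,
            path=np.full_like(cells[0].path, -500.0))]
        movie = kd.render_timelapse(lone, rc, cfg)
        assert np.all(movie == 7.0)

    def test_component_count_matches_population(self):
        from scipy import ndimage as ndi
        cfg = kd.SimConfig(n_cells=30, frac_dividing=0.0, duration_h=2,
                           sampling_interval_h=0.5, division_window_h=(1.2, 1.8),
                           seed=9)
        cells, _ = kd.simulate_cell_population(cfg)
        rc = kd.RenderConfig(psf_sigma_px=0.0, gaussian_noise_sd=0.0,
                             flatfield_amplitude=0.0, background_offset=0.0)
        movie = kd.render_timelapse(cells, rc, cfg)
        n_comp = ndi.label(movie[0, 0] > 0)[1]
        assert n_comp == 30

    def test_oracle_quantification_recovers_cn(self, short_sim, ideal_render):
        # per-pixel means over the known disk/annulus, no segmentation
        cfg, cells, _ = short_sim
        rc, movie = ideal_render
        rows, cols = rc.image_shape
        rr, cc = np.mgrid[0:rows, 0:cols]
        for f in range(0, cfg.n_frames, 5):
            for cell in cells:
                if cell.divides and f >= cell.division_frame:
                    continue
                d2 = (rr - cell.path[f][0]) ** 2 + (cc - cell.path[f][1]) ** 2
                nuc = d2 <= rc.nucleus_radius_px ** 2
                ring = (d2 > rc.nucleus_radius_px ** 2) & \
                       (d2 <= rc.cyto_radius_px ** 2)
                cn = movie[f, 1][ring].mean() / movie[f, 1][nuc].mean()
                assert cn == pytest.approx(cell.erk_cn[f], rel=0.02)

    def test_division_renders_two_nuclei(self):
        from scipy import ndimage as ndi
        cfg = kd.SimConfig(n_cells=1, frac_dividing=1.0, duration_h=6,
                           sampling_interval_h=0.25,
                           division_window_h=(2, 5), seed=2)
        cells, _ = kd.simulate_cell_population(cfg)
        rc = kd.RenderConfig(psf_sigma_px=0.0, gaussian_noise_sd=0.0,
                             flatfield_amplitude=0.0, background_offset=0.0)
        movie = kd.render_timelapse(cells, rc, cfg)
        f = cells[0].division_frame
        assert ndi.label(movie[f - 1, 0] > 0)[1] == 1
        assert ndi.label(movie[f + 1, 0] > 0)[1] == 2

    def test_overlapping_nuclei_rejected(self, short_sim):
        cfg, cells, _ = short_sim
        clones = []
        for k in range(2):
            c = cells[0]
            clones.append(kd.GroundTruthCell(
                cell_id=k, divides=False, division_time_h=None,
                division_frame=None, erk_activity=c.erk_activity,
                akt_activity=c.akt_activity, erk_cn=c.erk_cn, akt_cn=c.akt_cn,
                path=c.path + k * 2.0))
        rc = kd.RenderConfig()
        with pytest.raises(ValueError, match="cells"):
            kd.render_timelapse(clones, rc, cfg)

    def test_cyto_fraction_map_clipped(self):
        assert _activity_to_cyto_fraction(0.0) == 0.05
        assert _activity_to_cyto_fraction(1e9) == 0.95
        a = 1.5
        phi = _activity_to_cyto_fraction(a)
        assert phi / (1 - phi) == pytest.approx(a)

    def test_flatfield_unit_mean(self):
        ff = _smooth_flatfield((64, 48), 0.2)
        assert ff.mean() == pytest.approx(1.0, abs=1e-12)


class TestFixtureIO:
    def test_trace_roundtrip(self, tmp_path, short_sim):
        cfg, cells, traces = short_sim
        paths = kd.write_fixture(traces, None, tmp_path, cells=cells)
        back = kd.read_traces(paths["traces"])
        pd.testing.assert_frame_equal(
            back, traces.reset_index(drop=True), check_dtype=False)

    def test_tiff_page_count_matches_frames(self, tmp_path):
        import tifffile
        cfg = kd.SimConfig(n_cells=2, duration_h=48.0,
                           sampling_interval_h=0.25, seed=0)
        cells, traces = kd.simulate_cell_population(cfg)
        rc = kd.RenderConfig(image_shape=(96, 96), gaussian_noise_sd=0.0)
        sub = [kd.GroundTruthCell(
            cell_id=c.cell_id, divides=False, division_time_h=None,
            division_frame=None, erk_activity=c.erk_activity,
            akt_activity=c.akt_activity, erk_cn=c.erk_cn, akt_cn=c.akt_cn,
            path=np.tile([[48.0, 30.0 + 36 * c.cell_id]], (cfg.n_frames, 1)))
            for c in cells]
        movie = kd.render_timelapse(sub, rc, cfg)
        paths = kd.write_fixture(traces, movie, tmp_path, cells=cells)
        assert tifffile.imread(paths["erk.tif"]).shape[0] == 193

    def test_empty_traces_header_only(self, tmp_path):
        paths = kd.write_fixture(pd.DataFrame(), None, tmp_path)
        back = pd.read_csv(paths["traces"])
        assert list(back.columns) == ["cell_id", "frame", "time_h",
                                      "channel", "cn_ratio"]
        assert len(back) == 0
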