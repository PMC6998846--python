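"""Plane flows, conservation, pathlines, circulation on velocity fields."""

import numpy as np
import pytest

from valveforge import quantification as quant
from valveforge import synthesis as syn
from valveforge.errors import InputError
from conftest import constant_waveform


def uniform_field(v_cmps=(0.0, 0.0, 10.0), shape=(25, 25, 25),
                  n_frames=2, mask=None):
    """Homogeneous velocity on a 1 mm grid centered at the origin."""
    g = syn.Grid(origin=(-(shape[0] - 1) / 2, -(shape[1] - 1) / 2,
                         -(shape[2] - 1) / 2),
                 voxel_size=(1.0, 1.0, 1.0), shape=shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    v = np.zeros((n_frames, 3) + shape)
    for c in range(3):
        v[:, c][:, mask] = v_cmps[c]
    times = (np.arange(n_frames) + 0.5) / n_frames
    return syn.VelocityField4D(grid=g, times=times, v=v, lumen_mask=mask,
                               venc=100.0, period=1.0)


class TestPlaneFlow:
    def test_plug_flow_in_tube(self):
        # plug v_z = 100 mm/s (10 cm/s) inside radius 10 mm → 31.42 mL/s;
        # fine grid so the trilinear rim band is narrow
        h = 0.2
        nxy = int(round(25.0 / h)) + 1
        shape = (nxy, nxy, 5)
        g = syn.Grid(origin=(-(nxy - 1) / 2 * h, -(nxy - 1) / 2 * h, -2.0),
                     voxel_size=(h, h, 1.0), shape=shape)
        x = g.axis_centers(0)
        X, Y = np.meshgrid(x, x, indexing="ij")
        mask = (np.hypot(X, Y) < 10.0)[:, :, None] & np.ones(5, bool)
        v = np.zeros((1, 3) + shape, dtype=np.float32)
        v[0, 2][mask] = 10.0
        f = syn.VelocityField4D(grid=g, times=np.array([0.5]), v=v,
                                lumen_mask=mask, venc=100.0, period=1.0)
        q = quant.plane_flow(f, quant.PlaneSpec(origin=(0, 0, 0),
                                                extent=12.0,
                                                sampling_step=0.2), 0)
        assert q == pytest.approx(10.0 * np.pi, rel=0.01)

    def test_zero_field(self):
        f = uniform_field((0.0, 0.0, 0.0))
        q = quant.plane_flow(f, quant.PlaneSpec(origin=(0, 0, 0)), 0)
        assert q == 0.0

    def test_oblique_plane_counts_normal_component(self):
        f = uniform_field((0.0, 0.0, 10.0))
        n = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        q_oblique = quant.plane_flow(
            f, quant.PlaneSpec(origin=(0, 0, 0), normal=tuple(n),
                               extent=5.0, sampling_step=0.25), 0)
        q_axial = quant.plane_flow(
            f, quant.PlaneSpec(origin=(0, 0, 0), extent=5.0,
                               sampling_step=0.25), 0)
        # same window size: oblique flux scales with cos(45°)
        assert q_oblique == pytest.approx(q_axial / np.sqrt(2), rel=1e-9)

    def test_synthetic_frame_carries_programmed_flux(self, phantom_field):
        plane = quant.PlaneSpec(origin=(0, 0, 30.0), extent=20.0)
        q_frames = np.asarray(phantom_field.meta["q_frames"])
        k = int(np.argmax(q_frames))
        assert quant.plane_flow(phantom_field, plane, k) == pytest.approx(
            q_frames[k], rel=0.02)

    def test_quadrature_error_quadratic_in_step(self, tube_steady_field):
        q0 = 10.0 * np.pi
        errs = []
        for step in (0.8, 0.4, 0.2):
            plane = quant.PlaneSpec(origin=(0, 0, 25.0), extent=13.0,
                                    sampling_step=step)
            errs.append(abs(quant.plane_flow(tube_steady_field, plane, 0)
                            - q0))
        assert errs[2] < errs[0]

    def test_plane_outside_grid_rejected(self, tube_steady_field):
        with pytest.raises(InputError):
            quant.plane_flow(tube_steady_field,
                             quant.PlaneSpec(origin=(0, 0, 900.0),
                                             extent=5.0), 0)


class TestQuantifyPlane:
    def test_net_equals_frame_average_identity(self, phantom_field):
        plane = quant.PlaneSpec(origin=(0, 0, 30.0), extent=20.0,
                                sampling_step=0.4)
        res = quant.quantify_plane(phantom_field, plane)
        assert res.net_flow == pytest.approx(float(res.q.mean()),
                                             rel=1e-12)
        assert res.peak_flow == res.q.max()

    def test_net_and_peak_match_pump_program(self, phantom_field):
        plane = quant.PlaneSpec(origin=(0, 0, 30.0), extent=20.0)
        res = quant.quantify_plane(phantom_field, plane)
        assert res.net_flow == pytest.approx(27.74, rel=0.02)
        assert res.peak_flow == pytest.approx(100.0, rel=0.02)
        assert res.regurgitant_fraction == 0.0

    def test_volume_split_and_regurgitant_fraction(self):
        # one forward frame, one backward frame of half amplitude
        f = uniform_field((0, 0, 10.0), n_frames=2)
        f.v[1, 2] *= -0.5
        plane = quant.PlaneSpec(origin=(0, 0, 0), extent=5.0,
                                sampling_step=0.5)
        res = quant.quantify_plane(f, plane)
        assert res.backward_volume == pytest.approx(
            res.forward_volume / 2, rel=1e-9)
        assert res.regurgitant_fraction == pytest.approx(0.5, rel=1e-9)
        assert res.net_flow == pytest.approx(
            (res.forward_volume - res.backward_volume) / f.period, rel=1e-9)

    def test_dicrotic_waveform_gives_regurgitation(self, tube_profile):
        from valveforge import waveform as wfm
        w = wfm.make_aortic_waveform(wfm.WaveformParams(
            systolic_duration=0.35, dicrotic_backflow_fraction=0.05,
            dicrotic_duration=0.1))
        acq = syn.AcquisitionParams.default_4d(tube_profile, n=32,
                                               n_frames=20)
        f = syn.sample_velocity_field(tube_profile, w, acq)
        res = quant.quantify_plane(
            f, quant.PlaneSpec(origin=(0, 0, 25.0), extent=13.0,
                               sampling_step=0.4))
        assert res.regurgitant_fraction > 0.0
        assert res.backward_volume > 0.0


class TestConservation:
    def test_identical_planes_give_zero(self, phantom_field):
        plane = quant.PlaneSpec(origin=(0, 0, 30.0), extent=20.0,
                                sampling_step=0.4)
        out = quant.conservation_check(phantom_field, plane, plane)
        assert out["relative_difference"] == 0.0

    def test_proximal_distal_agreement(self, phantom_field):
        out = quant.conservation_check(
            phantom_field,
            quant.PlaneSpec(origin=(0, 0, -10.0), extent=20.0),
            quant.PlaneSpec(origin=(0, 0, 30.0), extent=20.0))
        assert out["relative_difference"] <= 0.02

    def test_plane_position_invariance_in_straight_segments(
            self, phantom_field):
        nets = []
        for z in (-20.0, -10.0, 30.0, 45.0):
            res = quant.quantify_plane(
                phantom_field, quant.PlaneSpec(origin=(0, 0, z),
                                               extent=20.0))
            nets.append(res.net_flow)
        spread = (max(nets) - min(nets)) / max(nets)
        assert spread <= 0.02

    def test_noise_degrades_consistency_in_expectation(self,
                                                       tube_steady_field):
        planes = (quant.PlaneSpec(origin=(0, 0, 5.0), extent=13.0,
                                  sampling_step=0.5),
                  quant.PlaneSpec(origin=(0, 0, 35.0), extent=13.0,
                                  sampling_step=0.5))
        def mean_rel(noise_sd):
            rels = []
            for seed in (1, 2, 3, 4):
                f = syn.add_noise(tube_steady_field, noise_sd, seed)
                rels.append(quant.conservation_check(
                    f, *planes)["relative_difference"])
            return np.mean(rels)
        base, noisy = mean_rel(0.0), mean_rel(8.0)
        assert noisy > base


class TestAliasingSensitivity:
    def test_round_trip_below_venc_is_exact(self, tube_steady_field):
        f = tube_steady_field          # peak 20 cm/s < venc 100
        dec = syn.pc_decode(syn.pc_encode(f.v, f.venc), f.venc)
        g = syn.VelocityField4D(grid=f.grid, times=f.times,
                                v=dec.astype(np.float32),
                                lumen_mask=f.lumen_mask, venc=f.venc,
                                period=f.period)
        plane = quant.PlaneSpec(origin=(0, 0, 25.0), extent=13.0,
                                sampling_step=0.4)
        assert quant.plane_flow(g, plane, 0) == pytest.approx(
            quant.plane_flow(f, plane, 0), rel=1e-6)

    def test_aliasing_biases_net_flow(self, tube_steady_field):
        f = tube_steady_field
        venc = 15.0                    # below the 20 cm/s peak: wraps
        dec = syn.pc_decode(syn.pc_encode(f.v, venc), venc)
        g = syn.VelocityField4D(grid=f.grid, times=f.times,
                                v=dec.astype(np.float32),
                                lumen_mask=f.lumen_mask, venc=venc,
                                period=f.period)
        plane = quant.PlaneSpec(origin=(0, 0, 25.0), extent=13.0,
                                sampling_step=0.4)
        q_true = quant.plane_flow(f, plane, 0)
        q_alias = quant.plane_flow(g, plane, 0)
        assert abs(q_alias - q_true) / q_true > 0.05


class TestPathlines:
    def test_constant_field_exact(self):
        f = uniform_field((1.0, 0.0, 0.0))   # 10 mm/s along x
        pls = quant.trace_pathlines(f, np.array([[0.0, 0.0, 0.0]]),
                                    0.0, 1.0, 0.005)
        np.testing.assert_allclose(pls[0].positions[-1], [10.0, 0.0, 0.0],
                                   atol=1e-9)
        assert pls[0].terminated is None
        np.testing.assert_allclose(pls[0].positions[0], pls[0].seed)

    def test_solid_body_rotation_period(self):
        om = 2 * np.pi                      # one revolution per second
        shape = (25, 25, 25)
        x = np.arange(shape[0]) - 12.0
        X, Y, _ = np.meshgrid(x, x, x, indexing="ij")
        v = np.zeros((2, 3) + shape)
        v[:, 0] = -om * Y / 10.0            # mm/s → cm/s
        v[:, 1] = om * X / 10.0
        g = syn.Grid(origin=(-12, -12, -12), voxel_size=(1, 1, 1),
                     shape=shape)
        f = syn.VelocityField4D(grid=g, times=np.array([0.25, 0.75]), v=v,
                                lumen_mask=np.ones(shape, bool), venc=100,
                                period=1.0)
        seed = np.array([[5.0, 0.0, 0.0]])
        pls = quant.trace_pathlines(f, seed, 0.0, 1.0, 0.01)
        r = np.hypot(pls[0].positions[:, 0], pls[0].positions[:, 1])
        assert np.abs(r - 5.0).max() < 5e-4          # radius conserved
        end_err = np.linalg.norm(pls[0].positions[-1] - seed[0])
        assert end_err < 0.1 * 2 * np.pi * 5 / 100   # period to 0.1 %

    def test_forward_backward_reversibility(self):
        om = 2 * np.pi
        shape = (25, 25, 25)
        x = np.arange(shape[0]) - 12.0
        X, Y, _ = np.meshgrid(x, x, x, indexing="ij")
        v = np.zeros((2, 3) + shape)
        v[:, 0] = -om * Y / 10.0
        v[:, 1] = om * X / 10.0
        g = syn.Grid(origin=(-12, -12, -12), voxel_size=(1, 1, 1),
                     shape=shape)
        fwd = syn.VelocityField4D(grid=g, times=np.array([0.25, 0.75]),
                                  v=v, lumen_mask=np.ones(shape, bool),
                                  venc=100, period=1.0)
        bwd = syn.VelocityField4D(grid=g, times=np.array([0.25, 0.75]),
                                  v=-v, lumen_mask=np.ones(shape, bool),
                                  venc=100, period=1.0)
        seed = np.array([[5.0, 0.0, 0.0]])
        mid = quant.trace_pathlines(fwd, seed, 0.0, 0.37, 0.005)
        back = quant.trace_pathlines(bwd, mid[0].positions[-1][None, :],
                                     0.0, 0.37, 0.005)
        assert np.linalg.norm(back[0].positions[-1] - seed[0]) < 1e-6

    def test_seed_outside_grid_terminates_immediately(self):
        f = uniform_field((1.0, 0.0, 0.0))
        pls = quant.trace_pathlines(f, np.array([[500.0, 0.0, 0.0],
                                                 [0.0, 0.0, 0.0]]),
                                    0.0, 0.5, 0.01)
        assert pls[0].terminated == "left_grid"
        assert len(pls[0].positions) == 1
        assert pls[1].terminated is None

    def test_leaving_mask_recorded(self):
        shape = (25, 25, 25)
        mask = np.zeros(shape, bool)
        mask[:, :, :13] = True
        f = uniform_field((0.0, 0.0, 5.0), shape, mask=mask)
        pls = quant.trace_pathlines(f, np.array([[0.0, 0.0, -5.0]]),
                                    0.0, 1.0, 0.01)
        assert pls[0].terminated == "left_mask"

    def test_vortex_capture_winding(self, vortex_zoom_field):
        f, vx, centers, tangents = vortex_zoom_field
        c = centers[0]
        e1 = np.array([np.cos(np.pi / 3), np.sin(np.pi / 3), 0.0])
        seed = (c + 1.0 * e1)[None, :]
        tsys = 0.4357389
        pls = quant.trace_pathlines(f, seed, tsys + 0.06, 1.0, 0.002)
        w = quant.winding_number(pls[0], c, tangents[0])
        assert abs(w) >= 1.0


class TestCirculation:
    def test_matches_prescribed_strength(self, vortex_zoom_field):
        f, vx, centers, tangents = vortex_zoom_field
        gates = np.array(f.meta["gate"])
        k = int(np.argmax(gates))
        circ = quant.sinus_circulation(f, 0, k)
        assert circ == pytest.approx(vx.strength, rel=0.05)

    def test_gated_off_in_systole(self, vortex_zoom_field):
        f, vx, centers, tangents = vortex_zoom_field
        gates = np.array(f.meta["gate"])
        k_sys = int(np.argmin(gates))
        k_dia = int(np.argmax(gates))
        assert abs(quant.sinus_circulation(f, 0, k_sys)) < 1e-6
        assert abs(quant.sinus_circulation(f, 0, k_dia)) > 1.0

    def test_vortex_disabled_gives_noise_floor(self, phantom_field,
                                               default_profile):
        vx = syn.VortexParams()
        centers, tangents = syn.vortex_centers(default_profile, vx)
        circ = quant.sinus_circulation(phantom_field, 0, 0,
                                       center=centers[0],
                                       tangent=tangents[0])
        assert abs(circ) < 0.5

    def test_loop_outside_grid_rejected(self, vortex_zoom_field):
        f, vx, centers, tangents = vortex_zoom_field
        with pytest.raises(InputError):
            quant.sinus_circulation(f, 0, 0, loop_radius=50.0)


class TestOutputs:
    def test_pathline_csv_and_vtk(self, tmp_path):
        f = uniform_field((1.0, 0.0, 0.0))
        pls = quant.trace_pathlines(f, np.array([[0.0, 0.0, 0.0],
                                                 [1.0, 1.0, 1.0]]),
                                    0.0, 0.2, 0.02)
        quant.pathlines_to_csv(pls, tmp_path / "p.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "p.csv")
        assert set(df.columns) == {"pathline_id", "t", "x", "y", "z"}
        assert df["pathline_id"].nunique() == 2
        quant.pathlines_to_vtk(pls, tmp_path / "p.vtk")
        text = (tmp_path / "p.vtk").read_text()
        assert text.startswith("# vtk DataFile")
        assert "LINES 2" in text
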