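"""Config-driven end-to-end runner: geometry → waveform → synthesis →
quantification → report, with fixture configurations for testing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import quantification as quant
from . import synthesis as syn
from . import waveform as wf
from .errors import InputError, ValveForgeError

log = logging.getLogger("valveforge")

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; fixed ``rng_seed`` ⇒ reproducible."""

    geometry: geo.RootGeometryParams = field(
        default_factory=geo.RootGeometryParams)
    waveform: wf.WaveformParams = field(default_factory=wf.WaveformParams)
    acquisition: syn.AcquisitionParams | None = None
    vortex: syn.VortexParams | None = field(
        default_factory=syn.VortexParams)
    planes: tuple[quant.PlaneSpec, ...] | None = None
    seeds_spec: str = "orifice"          # "orifice" or explicit (n, 3) array
    explicit_seeds: tuple | None = None
    profile_shape: str = "parabolic"
    mesh_resolution: dict | None = None
    leaflet_state: str = "closed"
    n_pathline_seeds: int = 16
    rng_seed: int = 0
    output_dir: str = "valveforge_run"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def default_planes(profile: geo.RootProfile) -> tuple[quant.PlaneSpec, ...]:
    """Transverse planes 10 mm proximal and 30 mm distal to the annulus."""
    ext = profile.params.sinus_max_diameter / 2 + 3.0
    return (quant.PlaneSpec(origin=(0.0, 0.0, -10.0), extent=ext),
            quant.PlaneSpec(origin=(0.0, 0.0, 30.0), extent=ext))


def make_fixture(kind: str, scale: str = "small") -> RunConfig:
    """Self-contained run configurations used as test fixtures.

    ``straight_tube``: degenerate equal-diameter geometry (no bulge).
    ``default_phantom``: the default valve phantom with diastolic vortices.
    ``vortex_only``: a fine zoomed grid over one sinus with the bulk flow
    switched off.  ``small`` scales complete in well under a minute.
    """
    if scale not in ("small", "full"):
        raise InputError(f"unknown scale {scale!r}")
    small = scale == "small"
    if kind == "straight_tube":
        params = geo.RootGeometryParams(
            annulus_diameter=20.0, sinus_max_diameter=20.0,
            sinotubular_diameter=20.0, ascending_aorta_diameter=20.0,
            lvot_diameter=20.0, lvot_length=10.0, sinus_height=20.0,
            ascending_aorta_length=20.0)
        profile = geo.build_root_profile(params)
        acq = syn.AcquisitionParams.default_4d(
            profile, n=32 if small else 96,
            n_frames=10 if small else 30)
        planes = (quant.PlaneSpec(origin=(0, 0, -5.0), extent=13.0),
                  quant.PlaneSpec(origin=(0, 0, 25.0), extent=13.0))
        return RunConfig(geometry=params, acquisition=acq, vortex=None,
                         planes=planes,
                         mesh_resolution={"n_axial": 40 if small else 120,
                                          "n_circumferential":
                                              48 if small else 192},
                         output_dir="run_straight_tube")
    if kind == "default_phantom":
        params = geo.RootGeometryParams()
        profile = geo.build_root_profile(params)
        acq = syn.AcquisitionParams.default_4d(
            profile, n=48 if small else 64, n_frames=12 if small else 20)
        return RunConfig(geometry=params, acquisition=acq,
                         planes=default_planes(profile),
                         mesh_resolution={"n_axial": 60 if small else 120,
                                          "n_circumferential":
                                              96 if small else 192,
                                          "n_u": 48 if small else 64,
                                          "n_v": 16 if small else 20},
                         output_dir="run_default_phantom")
    if kind == "vortex_only":
        params = geo.RootGeometryParams()
        profile = geo.build_root_profile(params)
        vortex = syn.VortexParams()
        centers, _ = syn.vortex_centers(profile, vortex)
        c = centers[0]
        n = 48 if small else 96
        box = 16.0
        vox = box / n
        acq = syn.AcquisitionParams(
            voxel_size=(vox, vox, vox), field_of_view=(box, box, box),
            matrix_size=(n, n, n), n_frames=8 if small else 20,
            origin=tuple(c - box / 2 + vox / 2))
        return RunConfig(geometry=params, acquisition=acq, vortex=vortex,
                         profile_shape="none", planes=(),
                         output_dir="run_vortex_only")
    raise InputError(f"unknown fixture kind {kind!r}")


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    out = Path(config.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "rng_seed": config.rng_seed, "stages": {}}

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("geometry")
        profile = geo.build_root_profile(config.geometry)
        phantom = geo.assemble_phantom(config.geometry, config.leaflet_state,
                                       config.mesh_resolution)
        diag = geo.mesh_diagnostics(phantom, max_rays=1500)
        if write_outputs:
            geo.export_stl(phantom, out / "phantom.stl",
                           provenance={"params": asdict(config.geometry)})
        report["stages"]["geometry_s"] = time.perf_counter() - t0
        report["mesh_diagnostics"] = diag

        t0 = stage("waveform")
        wave = wf.make_aortic_waveform(config.waveform)
        if write_outputs:
            wave.to_csv(out / "waveform.csv")
        report["stages"]["waveform_s"] = time.perf_counter() - t0
        report["waveform_peak_mL_per_s"] = wave.peak_flow
        report["waveform_mean_mL_per_s"] = wf.mean_flow(wave)

        t0 = stage("synthesis")
        acq = config.acquisition or syn.AcquisitionParams.default_4d(profile)
        field4d = syn.sample_velocity_field(profile, wave, acq,
                                            config.vortex,
                                            config.profile_shape)
        if acq.noise_sd > 0:
            field4d = syn.add_noise(field4d, acq.noise_sd, config.rng_seed)
        if write_outputs:
            syn.export_nifti(field4d, out / "dataset")
        report["stages"]["synthesis_s"] = time.perf_counter() - t0

        t0 = stage("quantification")
        planes = config.planes
        if planes is None:
            planes = default_planes(profile)
        rows = []
        for i, plane in enumerate(planes):
            res = quant.quantify_plane(field4d, plane)
            rows.append({
                "plane": i, "z_mm": plane.origin[2],
                "net_flow_mL_per_s": res.net_flow,
                "peak_flow_mL_per_s": res.peak_flow,
                "forward_volume_mL": res.forward_volume,
                "backward_volume_mL": res.backward_volume,
                "regurgitant_fraction": res.regurgitant_fraction,
            })
        metrics = pd.DataFrame(rows)
        if write_outputs and len(rows):
            metrics.to_csv(out / "metrics.csv", index=False,
                           float_format="%.10g")
        report["planes"] = rows
        if len(planes) >= 2:
            report["conservation"] = quant.conservation_check(
                field4d, planes[0], planes[1])
        report["stages"]["quantification_s"] = time.perf_counter() - t0

        t0 = stage("pathlines")
        if config.seeds_spec == "orifice" and config.profile_shape != "none":
            seeds = quant.orifice_seeds(field4d,
                                        n_seeds=config.n_pathline_seeds)
        elif config.explicit_seeds is not None:
            seeds = np.asarray(config.explicit_seeds, dtype=np.float64)
        else:
            seeds = None
        if seeds is not None:
            dt = wave.period / 200.0
            pathlines = quant.trace_pathlines(field4d, seeds, 0.0,
                                              wave.period, dt)
            if write_outputs:
                quant.pathlines_to_csv(pathlines, out / "pathlines.csv")
                quant.pathlines_to_vtk(pathlines, out / "pathlines.vtk")
            report["n_pathlines"] = len(pathlines)
            report["pathline_termination"] = {
                s: int(sum(1 for p in pathlines if p.terminated == s))
                for s in (None, "left_mask", "left_grid")}
        report["stages"]["pathlines_s"] = time.perf_counter() - t0
    except ValveForgeError as exc:
        exc.args = (f"[stage {current_stage}] {exc}",)
        raise

    if write_outputs:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
    return report
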