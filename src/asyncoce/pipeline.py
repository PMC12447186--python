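"""Scene-driven pipeline: simulate -> recover -> dpga/revoce -> report.

A scene is a plain mapping (usually loaded from YAML):

    protocol:   the flat ScanProtocol mapping (f_a_hz, n_x, ...)
    components: list of {azimuth_deg, k, amplitude, phase} plane waves, OR
    sources:    {n_sources, circle_diameter_m, amplitude_m, ...} prong ring
    medium:     {k_bg, k_in, inclusion_radius_m, rho_kg_m3, ...}
    noise:      {snr_db} or {sigma}
    acquisition: {measurement, wrap, air_fraction, n_z, swap_axes}

All randomness flows from the single top-level seed recorded in provenance;
a report is reproducible from its scene + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dpga import analyze_volume
from .io import read_volume, scene_hash, write_kmap, write_volume
from .protocol import ScanProtocol, acquisition_duration, derive_demodulation, y_step_delay
from .recovery import RecoveryConfig, recover_volume
from .revoce import revoce_map
from .wavefield import (
    Grid,
    MediumMap,
    PlaneWaveComponent,
    SourceSet,
    plane_wave_generator,
    prong_generator,
    raster_sample,
    sigma_for_snr,
)
from .dpga import downsample_field, surface_slab_average

__all__ = ["build_scene_objects", "simulate_scene", "run_pipeline"]

STEPS = ("simulate", "recover", "dpga", "revoce", "report")


def build_scene_objects(scene: dict):
    """Instantiate (protocol, generator, medium) from a scene mapping."""
    protocol = ScanProtocol.from_dict(scene["protocol"])
    med = scene.get("medium", {})
    medium = MediumMap(
        k_bg=float(med.get("k_bg", 300.0)),
        k_in=float(med["k_in"]) if med.get("k_in") is not None else None,
        inclusion_center_m=tuple(med.get("inclusion_center_m", (0.0, 0.0))),
        inclusion_radius_m=float(med.get("inclusion_radius_m", 2.25e-3)),
        rho_kg_m3=float(med.get("rho_kg_m3", 1000.0)),
        blend_width_m=float(med.get("blend_width_m", 0.3e-3)),
    )
    if "components" in scene:
        comps = [
            PlaneWaveComponent.inplane(
                np.deg2rad(float(c.get("azimuth_deg", 0.0))),
                k=float(c.get("k", medium.k_bg)),
                s_ql=float(c.get("amplitude", 100e-9)),
                phi0=float(c.get("phase", 0.0)),
            )
            for c in scene["components"]
        ]
        gen = plane_wave_generator(comps, protocol.f0_hz)
    elif "sources" in scene:
        src = scene["sources"]
        sources = SourceSet(
            n_sources=int(src.get("n_sources", 1)),
            circle_diameter_m=float(src.get("circle_diameter_m", 0.020)),
            center_m=tuple(src.get("center_m", (0.0, 0.0))),
            amplitude_m=float(src.get("amplitude_m", 100e-9)),
            per_source_phase_rad=tuple(src["per_source_phase_rad"]) if src.get("per_source_phase_rad") else None,
            r_min_m=float(src.get("r_min_m", 0.5e-3)),
            angle_offset_rad=float(src.get("angle_offset_rad", 0.0)),
        )
        gen = prong_generator(sources, medium, protocol.f0_hz)
    else:
        raise ValueError("scene needs a 'components' or 'sources' block")
    return protocol, gen, medium


def simulate_scene(scene: dict, seed: int | None = None):
    """Raster-sample the scene's wave field into a raw DisplacementVolume."""
    protocol, gen, _medium = build_scene_objects(scene)
    acq = scene.get("acquisition", {})
    noise = scene.get("noise", {})
    sigma = float(noise.get("sigma", 0.0))
    if "snr_db" in noise:
        grid = Grid.from_protocol(protocol)
        X, Y = grid.mesh()
        probe = gen(X, Y, np.zeros_like(X))
        sigma = sigma_for_snr(float(np.sqrt(np.mean(probe.real**2))), float(noise["snr_db"]))
    return raster_sample(
        gen,
        protocol,
        noise_sigma=sigma,
        seed=seed,
        wrap=bool(acq.get("wrap", False)),
        measurement=str(acq.get("measurement", "real")),
        air_fraction=float(acq.get("air_fraction", 0.05)),
        n_z=int(acq.get("n_z", 1)),
        swap_axes=bool(acq.get("swap_axes", False)),
    )


def run_pipeline(scene: dict, steps, outdir, seed: int = 0, *, log=print) -> dict:
    """Execute pipeline steps in order, writing artifacts under outdir.

    Steps must respect data dependencies (recover needs a raw volume, map
    methods need a coherent one). The report step writes a JSON summary of
    median k/c/G per method and the applied masks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in steps:
        if s not in STEPS:
            raise ValueError(f"unknown step {s!r}")

    protocol = ScanProtocol.from_dict(scene["protocol"])
    demod = derive_demodulation(protocol)
    if log:
        log(
            f"protocol: f_c={demod['f_c']:.1f} cycles/m, delta_k={demod['delta_k']:.3f} px, "
            f"delta_t_y={y_step_delay(protocol) * 1e3:.4f} ms, "
            f"volume time={acquisition_duration('async', protocol):.3f} s"
        )

    prov = {"seed": seed, "scene_hash": scene_hash(scene)}
    artifacts: dict = {}
    report: dict = {"seed": seed, "scene_hash": prov["scene_hash"]}

    raw = coherent = None
    if "simulate" in steps:
        raw = simulate_scene(scene, seed=seed)
        artifacts["raw"] = write_volume(raw, outdir / "raw.h5", provenance=prov)
    if "recover" in steps:
        if raw is None:
            raw = read_volume(outdir / "raw.h5", expect_stage="raw")
        cfg = RecoveryConfig(**scene.get("recovery", {}))
        coherent = recover_volume(raw, cfg)
        artifacts["coherent"] = write_volume(coherent, outdir / "coherent.h5", provenance=prov)
    needs_map = {"dpga", "revoce", "report"} & set(steps)
    if needs_map and coherent is None and (outdir / "coherent.h5").exists():
        coherent = read_volume(outdir / "coherent.h5", expect_stage="coherent")
    if needs_map and coherent is None:
        if "recover" not in steps and ("dpga" in steps or "revoce" in steps):
            raise ValueError("map steps require a coherent volume: run 'recover' first")

    analysis = scene.get("analysis", {})
    rho = float(scene.get("medium", {}).get("rho_kg_m3", 1000.0))
    if "dpga" in steps:
        km = analyze_volume(coherent, method="dpga", rho_kg_m3=rho, **analysis.get("dpga", {}))
        artifacts["dpga"] = write_kmap(km, outdir / "dpga_kmap.h5", f0_hz=protocol.f0_hz)
        report["dpga"] = _summary(km)
        kmc = analyze_volume(coherent, method="conventional", rho_kg_m3=rho, **analysis.get("conventional", {}))
        report["conventional"] = _summary(kmc)
    if "revoce" in steps:
        enface = surface_slab_average(coherent)
        ny = coherent.S.shape[2]
        field = downsample_field(enface, ny, axis=0)
        if coherent.air_rows is not None:
            field = field[:, : coherent.air_rows.start]
        km = revoce_map(
            field, coherent.protocol.range_x_m / ny, coherent.dy,
            upsample_to=(35, 35), f0_hz=protocol.f0_hz, rho_kg_m3=rho,
        )
        artifacts["revoce"] = write_kmap(km, outdir / "revoce_kmap.h5", f0_hz=protocol.f0_hz)
        report["revoce"] = _summary(km)
    if "report" in steps:
        report["protocol"] = {
            "f_c_cycles_per_m": demod["f_c"],
            "delta_k_px": demod["delta_k"],
            "delta_t_y_s": y_step_delay(protocol),
            "volume_time_s": acquisition_duration("async", protocol),
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["report"] = path
    return {"artifacts": artifacts, "report": report}


def _summary(kmap) -> dict:
    k = np.asarray(kmap.k, float)
    ok = np.isfinite(k)
    out = {
        "median_k_cycles_per_m": float(np.nanmedian(k)) if ok.any() else None,
        "defined_fraction": float(ok.mean()),
        "method": kmap.meta.get("method"),
    }
    if kmap.c is not None:
        out["median_c_m_per_s"] = float(np.nanmedian(kmap.c)) if ok.any() else None
    if kmap.G is not None:
        out["median_G_pa"] = float(np.nanmedian(kmap.G)) if ok.any() else None
    return out
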