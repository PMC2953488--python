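"""Pipeline stages tying generation, reconstruction and analysis together.

Each stage is a plain function over the library API that writes its artifacts
(with provenance headers: package version, seed, config hash) into an output
directory and returns the objects it computed.  The CLI is a thin wrapper
around these functions; they are equally usable from Python.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig, config_hash
from .frames import RCSpec, evaluate_rc
from .pmf import Landmarks, PMFProfile, landmarks, profile_sd, wham
from .puckering import cremer_pople, classify_conformer, itinerary
from .surrogate import (
    PuckerPath,
    SurrogatePotential,
    generate_ring_trajectory,
    generate_umbrella_dataset,
)

log = logging.getLogger("glycopmf")

__all__ = [
    "provenance",
    "stage_simulate",
    "stage_wham",
    "stage_pucker",
    "stage_rc",
    "stage_report",
]


def provenance(cfg: RunConfig) -> list[str]:
    return [f"glycopmf v{__version__}", f"seed={cfg.seed}", f"config={config_hash(cfg)}"]


def _potential(cfg: RunConfig) -> SurrogatePotential:
    return SurrogatePotential(
        nodes=tuple(tuple(n) for n in cfg.potential.nodes),
        stationary=tuple(cfg.potential.stationary) if cfg.potential.stationary else None,
        wall_k=cfg.potential.wall_k,
    )


def _pucker_path(cfg: RunConfig) -> PuckerPath:
    return PuckerPath(
        anchors=tuple(tuple(a) for a in cfg.ring.anchors),
        angle_noise_sd=cfg.ring.angle_noise_sd,
        q_noise_sd=cfg.ring.q_noise_sd,
    )


def stage_simulate(cfg: RunConfig, outdir: str | Path) -> dict:
    """Generate the synthetic umbrella dataset and ring trajectory.

    Writes per-window sample TSVs plus a JSON manifest, a multi-frame XYZ
    ring trajectory and the matching per-frame RC2 series.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    head = provenance(cfg)
    pot = _potential(cfg)
    u = cfg.umbrella
    log.info("simulate: %d windows over [%.3g, %.3g] A, k=%.4g, seed=%d",
             u.n_windows, *u.rc_range, u.k, cfg.seed)
    windows = generate_umbrella_dataset(
        pot, n_windows=u.n_windows, rc_range=u.rc_range, k=u.k,
        temperature=cfg.temperature, dt=u.dt, D=u.D,
        n_equil=u.n_equil, n_prod=u.n_prod, seed=cfg.seed,
        bias_factor=u.bias_factor,
    )
    wdir = out / "windows"
    wdir.mkdir(exist_ok=True)
    files = []
    for w in windows:
        f = wdir / f"{w.label}.tsv"
        io.write_window_tsv(f, w, header=head)
        files.append(f.relative_to(out))
    io.write_manifest(out / "manifest.json", files,
                      meta={"provenance": head, "temperature": cfg.temperature})

    rc2 = np.linspace(cfg.ring.rc2_range[0], cfg.ring.rc2_range[1], cfg.ring.n_frames)
    frames = generate_ring_trajectory(_pucker_path(cfg), rc2,
                                      ring_radius=cfg.ring.radius, seed=cfg.seed)
    io.write_xyz(out / "ring.xyz", frames, header=head)
    df = pd.DataFrame({"frame_index": np.arange(rc2.size), "rc2_A": rc2})
    io.write_series_tsv(out / "rc2.tsv", df, header=head + ["units: rc2 in Angstrom"])
    log.info("simulate: wrote %d windows and %d ring frames to %s",
             len(windows), len(frames), out)
    return {"windows": windows, "manifest": out / "manifest.json",
            "ring": out / "ring.xyz", "rc2": out / "rc2.tsv"}


def stage_wham(cfg: RunConfig, manifest: str | Path, outdir: str | Path) -> tuple[PMFProfile, Landmarks]:
    """Reconstruct the PMF from a window manifest and extract landmarks."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    windows = io.read_manifest(manifest)
    profile = wham(windows, bin_width=cfg.wham.bin_width, temperature=cfg.temperature,
                   tol=cfg.wham.tol, max_iter=cfg.wham.max_iter,
                   bias_factor=cfg.umbrella.bias_factor)
    log.info("wham: %d windows, %d bins, converged in %d iterations (residual %.3e kBT)",
             len(windows), profile.bin_centers.size, profile.n_iter, profile.residual)
    lm = landmarks(profile, cfg.landmarks.reactant_window, cfg.landmarks.product_window)
    head = provenance(cfg) + ["units: Angstrom, kcal/mol"]
    io.write_pmf_tsv(out / "pmf.tsv", profile, header=head)
    io.write_landmarks_json(out / "landmarks.json", lm,
                            meta={"provenance": provenance(cfg)})
    log.info("wham: landmarks reactant=%.3f TS=%.3f product=%.3f barrier=%.2f dG=%.2f",
             lm.reactant_min, lm.ts_pos, lm.product_min, lm.barrier, lm.delta_g)
    return profile, lm


def stage_pucker(cfg: RunConfig, traj: str | Path, rc2_file: str | Path,
                 outdir: str | Path) -> pd.DataFrame:
    """Per-frame puckering series and per-region itinerary summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = io.read_xyz(traj) if str(traj).endswith(".xyz") else io.read_pdb(traj)
    rc2 = io.read_series_tsv(rc2_file).iloc[:, 1].to_numpy()
    if len(frames) != rc2.size:
        raise ValueError(f"trajectory has {len(frames)} frames but rc2 series has {rc2.size}")
    ring = ("O5", "C1", "C2", "C3", "C4", "C5")
    puckers = [cremer_pople(fr.positions(ring)) for fr in frames]
    labels = [classify_conformer(p).name for p in puckers]
    df = pd.DataFrame({
        "frame_index": np.arange(len(frames)),
        "rc2_A": rc2,
        "Q_A": [p.Q for p in puckers],
        "theta_deg": [p.theta for p in puckers],
        "phi_deg": [p.phi for p in puckers],
        "q_x_A": [p.q_x for p in puckers],
        "q_y_A": [p.q_y for p in puckers],
        "conformer": labels,
    })
    head = provenance(cfg)
    io.write_series_tsv(out / "pucker.tsv", df, header=head)
    result = itinerary(puckers, rc2, regions=cfg.regions)
    summary = result.stats.join(result.populations.add_prefix("frac_"))
    summary.insert(0, "region", summary.index)
    io.write_series_tsv(out / "regions.tsv", summary, header=head)
    log.info("pucker: %d frames; majority conformers %s", len(frames), result.majority)
    return df


def stage_rc(cfg: RunConfig, traj: str | Path, specs: list[RCSpec],
             outdir: str | Path) -> pd.DataFrame:
    """Evaluate reaction-coordinate monitors on every frame of a trajectory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    frames = io.read_xyz(traj) if str(traj).endswith(".xyz") else io.read_pdb(traj)
    data = {"frame_index": np.arange(len(frames)),
            "time_ps": [fr.time if fr.time is not None else float("nan") for fr in frames]}
    for spec in specs:
        data[spec.name] = [evaluate_rc(fr, spec) for fr in frames]
    df = pd.DataFrame(data)
    io.write_series_tsv(out / "monitors.tsv", df,
                        header=provenance(cfg) + ["units: Angstrom, ps"])
    log.info("rc: evaluated %d monitors on %d frames", len(specs), len(frames))
    return df


def stage_report(cfg: RunConfig, pmf_file: str | Path, outdir: str | Path,
                 pmf_file_2: str | Path | None = None) -> dict:
    """Landmark JSON report, optionally with the two-profile standard deviation."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    profile = io.read_pmf_tsv(pmf_file)
    lm = landmarks(profile, cfg.landmarks.reactant_window, cfg.landmarks.product_window)
    report = lm.to_dict()
    if pmf_file_2 is not None:
        other = io.read_pmf_tsv(pmf_file_2)
        lm2 = landmarks(other, cfg.landmarks.reactant_window, cfg.landmarks.product_window)
        report["profile_sd_ts_to_product"] = profile_sd(
            profile, other, rc_range=(lm.ts_pos, lm.product_min))
        report["second_profile"] = lm2.to_dict()
    report["meta"] = {"provenance": provenance(cfg)}
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    log.info("report: %s", {k: v for k, v in report.items() if k != "meta"})
    return report
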