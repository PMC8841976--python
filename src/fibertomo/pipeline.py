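"""End-to-end orchestration: input -> particles -> radius sweep -> plateaus
-> fiber masks -> thickness report (+ optional FSC), with reproducible,
persisted intermediates.

Input can be a grayscale volume (MRC/TIFF), a precomputed particle-centroid
CSV, or a phantom spec; runs are fully determined by the config + master
seed, and every numeric artifact is written with the config hash in its
filename so runs never silently overwrite each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, detect, density, fsc as fsc_mod, phantom as phantom_mod, thickness
from .density import GridGeometry
from .errors import FibertomoError, InvalidSpecError
from .volume import Volume, read_volume, write_volume

__all__ = ["RunConfig", "run", "compare_runs", "load_config"]

log = logging.getLogger("fibertomo")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (flat key=value config file friendly)."""

    # input: exactly one of the three
    volume_path: str | None = None
    particles_path: str | None = None
    phantom_spec_path: str | None = None
    phantom: "phantom_mod.PhantomSpec | None" = None  # programmatic phantom mode

    invert_contrast: bool = False
    threshold_method: str = "isodata"
    connectivity: int = 26
    min_voxels: int = 2

    n_neighbors: int = 40
    sweep_min_nm: float = 20.0
    sweep_max_nm: float = 200.0
    sweep_step_nm: float = 10.0
    plateau_rel_tol: float = 0.05
    plateau_min_span: int = 3
    min_object_voxels: int = 27
    decimate: int = 1

    bin_width_nm: float = 5.0
    exclude_border: bool = True
    prune_branches: int = 3

    run_fsc: bool = False
    fsc_criterion: float = 0.143
    fsc_noise_sigma: float = 0.0

    voxel_size_nm: float | tuple[float, float, float] | None = None  # for CSV input
    outdir: str = "fibertomo_out"
    seed: int = 0
    quiet: bool = False
    write_volumes: bool = True
    write_plots: bool = True

    def __post_init__(self):
        if self.sweep_min_nm >= self.sweep_max_nm or self.sweep_step_nm <= 0:
            raise InvalidSpecError("radius sweep requires min < max and step > 0")
        if self.n_neighbors < 1:
            raise InvalidSpecError("n_neighbors must be >= 1")
        if not 0.0 < self.fsc_criterion < 1.0:
            raise InvalidSpecError("fsc_criterion must be in (0, 1)")
        modes = [
            self.volume_path, self.particles_path, self.phantom_spec_path, self.phantom
        ]
        if sum(m is not None for m in modes) != 1:
            raise InvalidSpecError(
                "exactly one input mode (volume_path | particles_path | "
                "phantom_spec_path | phantom) must be set"
            )

    @property
    def sweep_radii(self) -> np.ndarray:
        return np.arange(
            self.sweep_min_nm, self.sweep_max_nm + 0.5 * self.sweep_step_nm,
            self.sweep_step_nm,
        )

    #: fields that do not influence any numeric output
    _LOGISTICAL = ("outdir", "quiet", "write_volumes", "write_plots")

    def config_hash(self) -> str:
        payload = {}
        for f in dataclasses.fields(self):
            if f.name in self._LOGISTICAL:
                continue
            v = getattr(self, f.name)
            if f.name == "phantom" and v is not None:
                v = dataclasses.asdict(v)
            payload[f.name] = v
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:8]


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Read a flat ``key = value`` run config; keyword overrides win."""
    fields_ = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not sep or key not in fields_:
                raise InvalidSpecError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(value, fields_[key].type)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _coerce(value: str, annotation: str):
    if value in ("None", ""):
        return None
    if value in ("True", "true"):
        return True
    if value in ("False", "false"):
        return False
    ann = str(annotation)
    if "int" in ann and "tuple" not in ann:
        return int(value)
    if "float" in ann:
        if "," in value:
            return tuple(float(v) for v in value.split(","))
        return float(value)
    return value


def _stage(report, name, t0, **counts):
    elapsed = time.perf_counter() - t0
    report["stages"].append({"stage": name, **counts})
    log.info("stage %-10s %s (%.2fs)", name,
             " ".join(f"{k}={v}" for k, v in counts.items()), elapsed)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and persists) the run report.

    Every intermediate is written under ``config.outdir`` with the config
    hash in the filename. Rerunning with the same config + seed reproduces
    all numeric outputs bit-identically. On a stage failure the error is
    re-raised annotated with the stage name; earlier outputs are retained.
    """
    logging.basicConfig(
        level=logging.WARNING if config.quiet else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
        stream=sys.stderr,
    )
    h = config.config_hash()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)

    def path(name):
        return os.path.join(outdir, f"{h}_{name}")

    report: dict = {
        "config": {
            f.name: (dataclasses.asdict(getattr(config, f.name))
                     if f.name == "phantom" and getattr(config, f.name) is not None
                     else getattr(config, f.name))
            for f in dataclasses.fields(config)
        },
        "config_hash": h,
        "seed": config.seed,
        "versions": {
            "fibertomo": __version__,
            "numpy": np.__version__,
            "python": sys.version.split()[0],
        },
        "stages": [],
    }
    stage_name = "input"
    try:
        particles, geometry, phantom_obj = _load_input(config, path, report)

        stage_name = "sweep"
        t0 = time.perf_counter()
        sweep = density.sweep_radii(
            particles, geometry, config.sweep_radii, k=config.n_neighbors,
            decimate=config.decimate, min_object_voxels=config.min_object_voxels,
        )
        plateaus = density.detect_plateaus(
            sweep, rel_tol=config.plateau_rel_tol, min_span=config.plateau_min_span
        )
        fallback_used = False
        if not plateaus:
            # fall back to the flattest point of the count curve
            counts = sweep.object_counts.astype(float)
            rel_slope = np.abs(np.diff(counts)) / np.maximum(counts[:-1], 1.0)
            i = int(np.argmin(rel_slope))
            plateaus = [float((sweep.radii[i] + sweep.radii[i + 1]) / 2.0)]
            fallback_used = True
        sweep.plateau_radii = plateaus
        sweep.to_csv(path("sweep.csv"))
        if config.write_plots:
            sweep.plot(path("sweep.png"))
        report["plateau_radii_nm"] = plateaus
        report["plateau_fallback"] = fallback_used
        _stage(report, "sweep", t0, n_radii=len(sweep.radii), n_plateaus=len(plateaus))

        stage_name = "thickness"
        t0 = time.perf_counter()
        results = []
        for r in plateaus:
            mask = density.segment_fibers(
                particles, geometry, r, k=config.n_neighbors, decimate=config.decimate
            )
            if config.write_volumes:
                write_volume(mask.as_volume(), path(f"fibermask_r{r:g}.mrc"))
            res = thickness.local_thickness(
                mask,
                bin_width_nm=config.bin_width_nm,
                exclude_border=config.exclude_border,
                prune_branches=config.prune_branches,
                label=f"r{r:g}",
            )
            results.append(res)
        table = thickness.radius_report(
            results, outdir=outdir, stem=f"{h}_thickness"
        )
        report["thickness"] = table.to_dict(orient="records")
        _stage(report, "thickness", t0, n_plateaus=len(results),
               n_skeleton_voxels=sum(r.n for r in results))

        if config.run_fsc and phantom_obj is not None:
            stage_name = "fsc"
            t0 = time.perf_counter()
            half_a, half_b = phantom_mod.split_even_odd(
                phantom_obj, config.seed, voxel_noise_sigma=config.fsc_noise_sigma
            )
            curve = fsc_mod.fsc_curve(half_a, half_b)
            res = fsc_mod.resolution_at(curve, config.fsc_criterion)
            curve.to_csv(path("fsc.csv"))
            if config.write_plots:
                curve.plot(path("fsc.png"), criterion=config.fsc_criterion)
            report["fsc"] = {
                "resolution_nm": res.resolution_nm,
                "criterion": res.criterion,
                "nyquist_limited": res.nyquist_limited,
                "low_quality": res.low_quality,
            }
            _stage(report, "fsc", t0, n_shells=len(curve.fsc))
    except FibertomoError as exc:
        report["error"] = {"stage": stage_name, "message": str(exc)}
        with open(path("report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        raise FibertomoError(f"stage {stage_name!r} failed: {exc}") from exc

    with open(path("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _load_input(config: RunConfig, path, report):
    """Resolve the input mode into (particles, grid geometry, phantom|None)."""
    t0 = time.perf_counter()
    phantom_obj = None
    if config.phantom is not None or config.phantom_spec_path is not None:
        spec = config.phantom
        if spec is None:
            spec = phantom_mod.spec_from_config(config.phantom_spec_path)
        if config.seed != spec.seed:
            spec = dataclasses.replace(spec, seed=config.seed)
        phantom_obj = phantom_mod.generate_phantom(spec)
        volume = phantom_obj.volume
        if config.write_volumes:
            write_volume(volume, path("phantom.mrc"))
        parts, mask, thr = detect.detect_particles(
            volume, config.threshold_method, config.connectivity, config.min_voxels
        )
        geometry = GridGeometry.from_volume(volume)
        report["n_true_particles"] = len(phantom_obj.particles)
    elif config.volume_path is not None:
        volume = read_volume(config.volume_path, voxel_size=config.voxel_size_nm)
        if config.invert_contrast:
            volume = detect.invert(volume)
        parts, mask, thr = detect.detect_particles(
            volume, config.threshold_method, config.connectivity, config.min_voxels
        )
        geometry = GridGeometry.from_volume(volume)
    else:
        if config.voxel_size_nm is None:
            raise InvalidSpecError("particle-CSV input requires voxel_size_nm")
        parts = detect.ParticleSet.from_csv(config.particles_path)
        # pad beyond the largest sweep radius so the density map keeps a zero
        # background even when a single particle's ball covers the bounding box
        geometry = GridGeometry.from_particles(
            parts, config.voxel_size_nm, pad_nm=config.sweep_max_nm * 1.2
        )
        mask = thr = None

    if mask is not None:
        if config.write_volumes:
            write_volume(
                Volume(mask.astype(np.float32), volume.voxel_size),
                path("binary_mask.mrc"),
            )
        report["detect_threshold"] = thr
    parts.to_csv(path("particles.csv"))
    report["n_particles"] = len(parts)
    _stage(report, "input", t0, n_particles=len(parts))
    return parts, geometry, phantom_obj


def compare_runs(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Tabulate modal-radius / SD / plateau deltas between two runs.

    Reports must come from compatible configs (same sweep grid and neighbor
    count); thickness rows are paired in plateau order.
    """
    ca, cb = report_a["config"], report_b["config"]
    for key in ("sweep_min_nm", "sweep_max_nm", "sweep_step_nm", "n_neighbors"):
        if ca.get(key) != cb.get(key):
            raise InvalidSpecError(
                f"incompatible configs: {key} differs ({ca.get(key)} vs {cb.get(key)})"
            )
    rows = []
    pa = report_a.get("plateau_radii_nm", [])
    pb = report_b.get("plateau_radii_nm", [])
    for i in range(max(len(pa), len(pb))):
        a = pa[i] if i < len(pa) else np.nan
        b = pb[i] if i < len(pb) else np.nan
        rows.append({"quantity": f"plateau_{i}_nm", "a": a, "b": b, "delta": b - a})
    ta = report_a.get("thickness", [])
    tb = report_b.get("thickness", [])
    for i in range(max(len(ta), len(tb))):
        for key in ("modal_radius_nm", "sd_nm"):
            a = ta[i][key] if i < len(ta) else np.nan
            b = tb[i][key] if i < len(tb) else np.nan
            rows.append(
                {"quantity": f"plateau_{i}_{key}", "a": a, "b": b, "delta": b - a}
            )
    return pd.DataFrame(rows)
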