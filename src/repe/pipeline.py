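"""End-to-end orchestration: phantom -> segmentation/registration -> electrode
shaping -> placement -> evaluation -> field study, with a reproducibility
manifest.

Seeding: one global ``seed`` is expanded into per-stage seeds as
``seed * 1000 + stage_index`` (stage order below); every random draw in the
run is tied to one of these.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from repe import __version__, evaluation, fields, phantom, positioning, segreg, shaping
from repe.core import BinaryMask, SulcusTrace
from repe.errors import ConfigError

STAGES = ("phantom", "segreg", "shape", "place", "evaluate", "fields")


@dataclass
class PipelineConfig:
    """Validated run configuration; every stochastic stage has an explicit seed."""

    seed: int
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 2.0
    sulcus_curvature: float = 0.25
    sulcus_depth_mm: float = 12.0
    electrode_width_mm: float = 20.0
    n_repositions: int = 5
    reposition_noise_sd_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    reposition_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    run_fields: bool = True
    field_references: tuple[str, ...] = ("oz",)
    field_shifts_mm: tuple[int, ...] = (0, 5, 10, 15)
    current_ma: float = 1.5
    solver_tol: float = 1e-6

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ConfigError("config must set an explicit 'seed'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        if int(cfg.seed) != cfg.seed:
            raise ConfigError("seed must be an integer")
        for name in ("grid_shape", "reposition_noise_sd_mm", "reposition_shift_mm"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.field_references = tuple(cfg.field_references)
        cfg.field_shifts_mm = tuple(int(s) for s in cfg.field_shifts_mm)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) * 1000 + STAGES.index(stage)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, write all artifacts under ``out_dir``, return the manifest.

    Deterministic given the config: identical configs produce byte-identical
    artifacts and therefore identical manifest checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    runtimes: dict[str, float] = {}

    def _stage(name):
        runtimes[name] = time.time()
        (out / name).mkdir(exist_ok=True)
        return out / name

    # -- phantom ------------------------------------------------------------
    d = _stage("phantom")
    grid = phantom.GridSpec(cfg.grid_shape, cfg.voxel_size_mm)
    sulcus = phantom.SulcusParams(
        curvature=cfg.sulcus_curvature, depth_mm=cfg.sulcus_depth_mm
    )
    pair = phantom.generate_template_pair(
        perturb_params=phantom.PerturbParams(
            scales=(1.06, 0.95, 1.03),
            shears=(0.03, 0.0, -0.02),
            rotations_deg=(4.0, -3.0, 5.0),
            translation_mm=(4.0, -6.0, 3.0),
        ),
        seed=cfg.stage_seed("phantom"),
        sulcus_params=sulcus,
        grid=grid,
    )
    pair.template_labels.save(d / "template_labels.nii.gz")
    pair.individual_intensity.save(d / "individual_t1.nii.gz")
    pair.individual_labels.save(d / "individual_labels.nii.gz")
    pair.template_sulcus.to_json(d / "template_sulcus.json")
    pair.truth.to_json(d / "truth.json")
    artifacts.update({p.name: p for p in d.iterdir()})
    runtimes["phantom"] = time.time() - runtimes["phantom"]

    # -- segmentation + registration ----------------------------------------
    d = _stage("segreg")
    ibrain, iscalp = segreg.extract_brain_and_scalp(pair.individual_intensity)
    from repe.core import Tissue

    template_brain = BinaryMask(
        pair.template_labels.mask(Tissue.GRAY, Tissue.WHITE),
        pair.template_labels.affine,
        role_tag="template_brain",
    )
    tm = segreg.fit_affine(ibrain, template_brain)
    ics = segreg.map_template_sulcus(pair.template_sulcus, tm)
    ibrain.save(d / "ibrain.nii.gz")
    iscalp.save(d / "iscalp.nii.gz")
    tm.save(d / "tm.mat")
    ics.to_json(d / "ics.json")
    artifacts.update({p.name: p for p in d.iterdir()})
    runtimes["segreg"] = time.time() - runtimes["segreg"]

    # -- electrode shaping --------------------------------------------------
    d = _stage("shape")
    surf = shaping.surface_from_mask(iscalp)
    icss = shaping.project_to_scalp(ics, surf)
    icss_clean = icss.dedupe()
    icssp = shaping.flatten_trace(icss_clean)
    outline = shaping.build_electrode_outline(
        icssp, cfg.electrode_width_mm, scalp_footprint=icss_clean.points
    )
    icss.to_json(d / "icss.json")
    icssp.to_json(d / "icssp.json")
    shaping.export_outline(outline, d / "electrode.svg")
    _write_json(
        {
            "width_mm": outline.width_mm,
            "area_mm2": outline.area_mm2,
            "plane_polygon_mm": outline.plane_polygon.tolist(),
        },
        d / "outline.json",
    )
    artifacts.update({p.name: p for p in d.iterdir()})
    runtimes["shape"] = time.time() - runtimes["shape"]

    # -- placement sheet + repositioning simulation -------------------------
    d = _stage("place")
    sheet = positioning.compute_placement_sheet(
        surf, pair.truth.fiducials, outline.scalp_footprint, tol_mm=cfg.voxel_size_mm * 2
    )
    reps = positioning.simulate_repositioning(
        outline.scalp_footprint,
        n_reps=cfg.n_repositions,
        noise_sd_mm=cfg.reposition_noise_sd_mm,
        systematic_shift_mm=cfg.reposition_shift_mm,
        seed=cfg.stage_seed("place"),
        surf=surf,
    )
    report = positioning.positioning_error(reps, icss_clean)
    _write_json(sheet.to_dict(), d / "placement_sheet.json")
    _write_json(report.to_dict(), d / "positioning_report.json")
    np.save(d / "repositions.npy", np.asarray(reps))
    artifacts.update({p.name: p for p in d.iterdir()})
    runtimes["place"] = time.time() - runtimes["place"]

    # -- evaluation ---------------------------------------------------------
    d = _stage("evaluate")
    rng = np.random.default_rng(cfg.stage_seed("evaluate"))
    # a simulated "manual" sulcus tracing: fewer points, small jitter
    n_manual = int(rng.integers(102, 118))
    take = np.sort(rng.choice(len(pair.truth.sulcus_gt), n_manual, replace=False))
    manual_ics = SulcusTrace(
        pair.truth.sulcus_gt.points[take] + rng.normal(0, 1.0, (n_manual, 3)),
        "individual",
    )
    manual_icss = shaping.project_to_scalp(manual_ics, surf)
    agreement = evaluation.trace_agreement(icss, manual_icss)
    _write_json(
        {
            "n_manual_points": n_manual,
            "mean_dist_mm": agreement.mean_dist_mm,
            "sd_dist_mm": agreement.sd_dist_mm,
            "icc": agreement.icc,
        },
        d / "agreement.json",
    )
    # systematic-displacement ANOVA on successive-repetition differences
    rows = []
    base = reps[0]
    for r, rep in enumerate(reps[1:], start=2):
        delta = rep - base
        for marker in range(delta.shape[0]):
            for ax, name in enumerate("xyz"):
                rows.append(
                    {
                        "subject": marker,
                        "condition": f"rep{r}-1",
                        "axis": name,
                        "delta_mm": delta[marker, ax],
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(d / "position_deltas.csv", index=False)
    anova = evaluation.rm_anova_table(table)
    _write_json([a.to_dict() for a in anova], d / "anova.json")
    artifacts.update({p.name: p for p in d.iterdir()})
    runtimes["evaluate"] = time.time() - runtimes["evaluate"]

    # -- field study --------------------------------------------------------
    if cfg.run_fields:
        d = _stage("fields")
        df = fields.run_montage_study(
            pair.individual_labels,
            icss_clean,
            pair.truth.sulcus_gt,
            pair.truth.fiducials,
            references=cfg.field_references,
            shifts_mm=cfg.field_shifts_mm,
            current_ma=cfg.current_ma,
            tol=cfg.solver_tol,
        )
        df.to_csv(d / "dose_table.csv", index=False)
        artifacts.update({p.name: p for p in d.iterdir()})
        runtimes["fields"] = time.time() - runtimes["fields"]

    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
        },
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "checksums": {name: _sha256(p) for name, p in sorted(artifacts.items())},
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
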