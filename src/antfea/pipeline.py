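"""End-to-end pipeline: outlines -> meshes -> solves -> intervals + stats.

Given a :class:`PipelineConfig` (YAML-loadable), the pipeline meshes every
outline at a common density (optionally chosen by the convergence protocol
on the reference model), assigns each model a side load normalized by the
square root of its area ratio to the reference (largest-area) model, runs
one linear static solve per model, writes per-element stress CSVs and
figures, then runs the intervals chain and the rank statistics on the pooled
element table.  A manifest (config hash, seeds, versions) makes every run
reproducible to identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convergence import ConvergenceConfig, LoadCaseSpec, run_convergence
from .fem import (CUTICLE, Material, build_load_case, element_table,
                  normalize_load, recover_stress, solve_linear_static,
                  write_displacement_csv, write_stress_csv)
from .geometry import Outline, RegionSpec, annotate_regions, load_outline_csv, \
    load_outline_svg, outline_area
from .intervals import DEFAULT_CANDIDATES, run_intervals_chain
from .meshing import triangulate
from .stats import stats_report
from .synthetic import generate_cohort
from .viz import render_colormap, render_tensor_plot

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable so the manifest can hash it."""

    outline_paths: list[str] = field(default_factory=list)
    synth_majors: int = 0
    synth_minors: int = 0
    density: float | None = None             # mm; or use the ladder below
    density_ladder: list[float] = field(default_factory=list)
    side_load_ref: float = 1.0               # N on the largest-area model
    load_angle: float = 45.0
    young_modulus: float = CUTICLE.young_modulus
    poisson_ratio: float = CUTICLE.poisson_ratio
    side_arc_fraction: float = 0.20
    corner_arc_fraction: float = 0.05
    interval_candidates: tuple[int, ...] = DEFAULT_CANDIDATES
    filter_percent: float = 2.0
    reference_model: str | None = None       # default: largest area
    seed: int = 0
    out_dir: str = "pipeline_out"
    render: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.interval_candidates is not None:
            cfg.interval_candidates = tuple(cfg.interval_candidates)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_outlines(config: PipelineConfig) -> list[Outline]:
    spec = RegionSpec(config.side_arc_fraction, config.corner_arc_fraction)
    outlines: list[Outline] = []
    for p in config.outline_paths:
        path = Path(p)
        if not path.exists():
            raise PipelineError(f"outline file not found: {p}")
        loader = load_outline_svg if path.suffix.lower() == ".svg" else load_outline_csv
        outlines.append(annotate_regions(loader(str(path)), spec))
    if config.synth_majors or config.synth_minors:
        outlines.extend(generate_cohort(config.synth_majors, config.synth_minors,
                                        seed=config.seed))
    if not outlines:
        raise PipelineError("no outlines: give outline_paths or synth counts")
    names = [o.name for o in outlines]
    if len(set(names)) != len(names):
        raise PipelineError(f"duplicate model names: {names}")
    return outlines


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the results bundle (also written to out_dir)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    material = Material(config.young_modulus, config.poisson_ratio)
    outlines = _load_outlines(config)

    areas = {o.name: outline_area(o) for o in outlines}
    ref = config.reference_model or max(areas, key=areas.get)
    if ref not in areas:
        raise PipelineError(f"reference model {ref!r} not among inputs {list(areas)}")

    density = config.density
    convergence_report = None
    if density is None:
        if len(config.density_ladder) >= 2:
            ref_outline = next(o for o in outlines if o.name == ref)
            rep = run_convergence(ref_outline, material,
                                  LoadCaseSpec(config.side_load_ref, config.load_angle),
                                  ConvergenceConfig(tuple(config.density_ladder)))
            density = rep.selected_density
            convergence_report = {"selected_density": rep.selected_density,
                                  "table": rep.table}
        else:
            raise PipelineError("give a density or a density_ladder of >= 2 entries")

    tables = []
    per_model = {}
    ref_max = None
    fields = {}
    for o in outlines:
        stage = "mesh"
        try:
            mesh = triangulate(o, density)
            stage = "solve"
            load = normalize_load(areas[o.name], areas[ref], config.side_load_ref)
            lc = build_load_case(mesh, load, config.load_angle)
            disp = solve_linear_static(mesh, material, lc)
            stage = "stress"
            fld = recover_stress(mesh, material, disp)
        except Exception as err:
            raise PipelineError(f"stage '{stage}' failed for model '{o.name}': {err}") from err
        write_stress_csv(fld, o.name, out / f"{o.name}_stress.csv")
        write_displacement_csv(disp, out / f"{o.name}_displacements.csv")
        tables.append(element_table(fld, o.name))
        fields[o.name] = (mesh, fld)
        per_model[o.name] = {"area_mm2": areas[o.name], "side_load_n": load,
                             "n_elements": mesh.n_elements,
                             "max_tresca": float(fld.tresca.max())}
        if o.name == ref:
            ref_max = float(fld.tresca.max())
        logger.info("model %s: %d elements, load %.3f N, max Tresca %.3g MPa",
                    o.name, mesh.n_elements, load, fld.tresca.max())

    if config.render:
        for name, (mesh, fld) in fields.items():
            render_colormap(fld, mesh, ref_max, out / f"{name}_colormap.png",
                            title=name)
            render_tensor_plot(fld, mesh, out / f"{name}_tensors.png", title=name)

    pooled = pd.concat(tables, ignore_index=True)
    pooled.to_csv(out / "element_table.csv", index=False)
    chain = run_intervals_chain(pooled, tuple(config.interval_candidates),
                                config.filter_percent)
    chain["matrix"].to_csv(out / "area_proportions.csv")
    report = stats_report(chain["filtered"])

    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "density": density,
        "reference_model": ref,
        "models": per_model,
        "intervals": {
            "n_intervals": chain["selection"].n_intervals,
            "upper_threshold": chain["upper_threshold"],
            "explained_variance_pct": chain["pca"].explained_variance_pct.tolist(),
            "r2_per_pair": chain["selection"].r2_per_pair,
        },
        "stats": report,
        "convergence": convergence_report,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"manifest": manifest, "chain": chain, "stats": report,
            "fields": fields, "element_table": pooled}
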