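"""Configuration-driven orchestration of the full reconstruction workflow.

A run takes either real inputs (mesh + electrode centroids or CT volume +
event table) or a synthetic-generation block, never both. For every SD and
every (r_diff, v_diff) tolerance combination it records the search outcome —
success flag, exact solution count, velocity estimate — for both the full and
the branch-reduced hit sequence, plus leave-one-out validation at the primary
combination. Per-SD failures (no 'could fit' trajectories) are first-class
results: the search failing is itself informative, so it is reported, never
swallowed. All randomness derives from the config seed and outputs are
byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .electrodes import ElectrodeSet, Volume3D, segment_metal, snap_to_mesh
from .errors import EventSchemaError, SDTrackError, SearchError
from .events import build_hit_sequence, read_events, reduce_hit_sequence
from .kinematics import estimate_velocity, validate_loo
from .mesh import (
    Patch,
    TriMesh,
    extract_patch,
    smooth_laplacian_edge_preserving,
    upsample_4split,
)
from .meshio import read_surface
from .search import (
    CANONICAL_COMBINATIONS,
    SearchParams,
    count_solutions,
    grow_solutions,
)

log = logging.getLogger("sdtrack")

__all__ = ["PipelineConfig", "run_pipeline", "prepare_patch", "summary_table"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; see ``from_dict`` for the schema."""

    seed: int
    output_dir: str
    synthetic: dict | None = None
    inputs: dict | None = None
    combinations: tuple = CANONICAL_COMBINATIONS
    r_max: float = 5.0
    patch_radius: float = 30.0
    smooth_iterations: int = 0
    smooth_step: float = 0.5
    upsample_iterations: int = 0
    prep_order: str = "smooth_first"     # or "upsample_first"
    n_samples: int = 100
    validate: bool = True
    log_level: str = "INFO"
    strip_order: list[str] | None = None

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of 'synthetic' or 'inputs'"
            )
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            seed=d.get("seed"),
            output_dir=d.get("output_dir", "sdtrack_out"),
            synthetic=d.get("synthetic"),
            inputs=d.get("inputs"),
            combinations=tuple(
                tuple(float(x) for x in c)
                for c in d.get("combinations", CANONICAL_COMBINATIONS)
            ),
            r_max=float(d.get("r_max", 5.0)),
            patch_radius=float(d.get("patch_radius", 30.0)),
            smooth_iterations=int(d.get("smooth_iterations", 0)),
            smooth_step=float(d.get("smooth_step", 0.5)),
            upsample_iterations=int(d.get("upsample_iterations", 0)),
            prep_order=d.get("prep_order", "smooth_first"),
            n_samples=int(d.get("n_samples", 100)),
            validate=bool(d.get("validate", True)),
            log_level=d.get("log_level", "INFO"),
            strip_order=d.get("strip_order"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def prepare_patch(
    mesh: TriMesh,
    electrodes: dict[str, int],
    radius: float = 30.0,
    smooth_iterations: int = 0,
    smooth_step: float = 0.5,
    upsample_iterations: int = 0,
    order: str = "smooth_first",
) -> Patch:
    """Cut the patch around the strip, then smooth and/or up-sample it.

    Both processing orders are available; the default smooths the coarse
    patch first (cheaper, and the interpolating subdivision then refines the
    already-smoothed geometry). Original vertex indices survive both steps,
    so the electrode vertex ids remain valid.
    """
    patch = extract_patch(mesh, electrodes, radius=radius)
    sub = patch.mesh
    steps = (
        ["smooth", "upsample"] if order == "smooth_first" else ["upsample", "smooth"]
    )
    for step in steps:
        if step == "smooth" and smooth_iterations > 0:
            sub = smooth_laplacian_edge_preserving(
                sub, iterations=smooth_iterations, step=smooth_step
            )
        elif step == "upsample" and upsample_iterations > 0:
            sub = upsample_4split(sub, iterations=upsample_iterations)
    if sub is not patch.mesh:
        n_old = patch.mesh.n_vertices
        parent = np.concatenate(
            [patch.parent_vertices, -np.ones(sub.n_vertices - n_old, dtype=np.int64)]
        )
        patch = Patch(
            mesh=sub,
            parent_vertices=parent,
            electrodes=patch.electrodes,
            boundary=sub.boundary_vertices.copy(),
            radius=patch.radius,
        )
    return patch


def _load_real_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    mesh = read_surface(inp["mesh"], format=inp.get("mesh_format"))
    if "electrodes_csv" in inp:
        eset = ElectrodeSet.from_csv(inp["electrodes_csv"])
    elif "ct_volume" in inp:
        vol = Volume3D.from_nifti(inp["ct_volume"])
        comps = segment_metal(vol, threshold=float(inp.get("hu_threshold", 3000)))
        centroids = np.array([c.centroid for c in comps])
        eset = snap_to_mesh(centroids, mesh, infer_order=True)
    else:
        raise ValueError("inputs need 'electrodes_csv' or 'ct_volume'")
    events = read_events(inp["events"])
    return mesh, eset, events


def _search_block(patch, seq, cfg, combos):
    """Run every tolerance combination on one hit sequence."""
    out = {}
    for (r_diff, v_diff) in combos:
        params = SearchParams(
            r_diff=r_diff, v_diff=v_diff, r_max=cfg.r_max,
            patch_radius=cfg.patch_radius, seed=cfg.seed,
        )
        dp = grow_solutions(patch, seq, params)
        total = count_solutions(dp)
        entry = {
            "success": total > 0,
            "count": str(total),
            "per_subrange_counts": {
                f"{c:g}": str(t) for c, t in dp.totals.items() if t > 0
            },
        }
        if total > 0:
            est = estimate_velocity(dp)
            entry["velocity_mm_min"] = round(est.velocity, 6)
            entry["segment_velocities"] = [
                round(float(v), 6) for v in est.segment_velocities
            ]
        out[f"r{r_diff:g}_v{v_diff:g}"] = entry
    return out


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Execute the full workflow and write the results bundle.

    Returns the results dict (also written as JSON under
    ``config.output_dir``, with a per-combination success-summary CSV for
    the full and reduced hit sequences).
    """
    if isinstance(config, str):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    if config.synthetic is not None:
        ds = synthetic.make_dataset(seed=config.seed, **config.synthetic)
        mesh, eset, events = ds.mesh, ds.electrodes, ds.events
    else:
        mesh, eset, events = _load_real_inputs(config)

    strip_order = config.strip_order or list(eset.labels)
    patch = prepare_patch(
        mesh, eset.as_dict(), radius=config.patch_radius,
        smooth_iterations=config.smooth_iterations,
        smooth_step=config.smooth_step,
        upsample_iterations=config.upsample_iterations,
        order="smooth_first" if config.prep_order == "smooth_first" else "upsample_first",
    )
    primary = config.combinations[0]

    results: dict = {"events": {}, "config_seed": config.seed}
    for ev in events:
        rec: dict = {}
        try:
            full = build_hit_sequence(ev)
        except EventSchemaError as exc:
            log.info("event %s skipped: %s", ev.event_id, exc)
            results["events"][ev.event_id] = {"skipped": str(exc)}
            continue
        reduced = reduce_hit_sequence(full, strip_order)
        rec["hit_sequence_full"] = full.to_json_dict()
        rec["hit_sequence_reduced"] = reduced.to_json_dict()
        for name, seq in (("full", full), ("reduced", reduced)):
            try:
                rec[name] = _search_block(patch, seq, config, config.combinations)
            except SearchError as exc:
                log.warning("event %s (%s): %s", ev.event_id, name, exc)
                rec[name] = {"error": str(exc)}
        if config.validate:
            params = SearchParams(
                r_diff=primary[0], v_diff=primary[1], r_max=config.r_max,
                patch_radius=config.patch_radius, seed=config.seed,
            )
            try:
                out = validate_loo(
                    patch, reduced, params,
                    n_samples=config.n_samples, seed=config.seed,
                )
                rec["validation"] = {
                    "reach_fraction": out.reach_fraction,
                    "success": out.success,
                    "mean_spatial_error_mm": None
                    if np.isnan(out.mean_spatial_error)
                    else round(out.mean_spatial_error, 6),
                    "steps": [
                        {
                            "withheld": s.withheld,
                            "failed": s.failed,
                            "reach_fraction": s.reach_fraction,
                        }
                        for s in out.steps
                    ],
                }
            except SDTrackError as exc:
                rec["validation"] = {"error": str(exc)}
        results["events"][ev.event_id] = rec

    results["summary"] = summary_table(results, config.combinations)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    for variant in ("full", "reduced"):
        pd.DataFrame(results["summary"][variant], index=[0]).to_csv(
            outdir / f"summary_{variant}.csv", index=False
        )
    return results


def summary_table(results: dict, combinations) -> dict:
    """Success counts per tolerance combination, shaped like a cohort table:
    one cell 'successes/total (pct%)' per combination, for full and reduced
    hit sequences."""
    out = {}
    for variant in ("full", "reduced"):
        row = {}
        for (r_diff, v_diff) in combinations:
            key = f"r{r_diff:g}_v{v_diff:g}"
            n = k = 0
            for rec in results["events"].values():
                block = rec.get(variant)
                if not isinstance(block, dict) or key not in block:
                    continue
                n += 1
                if block[key].get("success"):
                    k += 1
            pct = 100.0 * k / n if n else 0.0
            row[f"R_diff={r_diff:g} V_diff={v_diff:g}"] = f"{k}/{n} ({pct:.1f}%)"
        out[variant] = row
    return out
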