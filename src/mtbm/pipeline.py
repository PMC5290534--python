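"""End-to-end orchestration: cohort -> features -> tests -> report bundle.

A run is parameterized by a :class:`RunConfig` (usually loaded from YAML),
draws every random stream from one root seed, and writes a reproducible
bundle: a per-structure summary table (volumes, volume-test p, corrected
multivariate p for left / right / combined), JSON summaries, and template
surfaces annotated with the per-vertex maps (det J ratio, T², uncorrected
p, correlation r).  All numerical outputs are byte-stable under a fixed
config and seed; the wall-clock timestamp is confined to one header line of
``run_info.txt``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, generate_bilateral
from .errors import ValidationError
from .grid import compute_volume
from .morphometry import compute_jacobians, detj_vertex_field, subject_features
from .registration import mean_template
from .stats import (
    combine_structures,
    detj_ratio_map,
    residualize,
    score_correlation_map,
    validate_cohort,
    vertexwise_permutation_test,
    volume_permutation_ttest,
)
from .surface_io import read_surface, write_surface

log = logging.getLogger("mtbm")

_SEED_MOD = 2**31


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "mtbm_out"
    structures: list = field(default_factory=lambda: ["putamen"])
    sides: list = field(default_factory=lambda: ["left", "right"])
    n_perm: int = 1000
    seed: int = 0
    alpha_vertex: float = 0.05
    template: str = "mean"  # "mean" | path to an explicit template surface
    score_column: str = "santa_ana"
    log_level: str = "INFO"
    # synthetic mode: CohortSpec field overrides (structure/side/seed are set
    # per structure by the pipeline)
    cohort: dict = field(default_factory=dict)
    effect_sides: list = field(default_factory=lambda: ["left", "right"])
    # files mode: directory containing covariates.csv and
    # <structure>_<side>/<subject id>.vtk surfaces
    input_dir: str | None = None

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if not (0 < self.alpha_vertex < 1):
            raise ValidationError("alpha_vertex must lie in (0, 1)")
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _structure_seed(config: RunConfig, k: int) -> int:
    return (config.seed * 1_000_003 + 7919 * k) % _SEED_MOD


def _load_inputs(config: RunConfig):
    """Resolve surfaces and covariates per (structure, side).

    Returns {(structure, side): (subjects dict, table, extras)} where extras
    carries the synthetic ground truth when available.
    """
    out = {}
    if config.mode == "synthetic":
        for k, structure in enumerate(config.structures):
            spec = CohortSpec(
                structure=structure,
                seed=config.seed % _SEED_MOD,
                shape_seed=_structure_seed(config, k),
                **config.cohort,
            )
            sides = generate_bilateral(spec, effect_sides=tuple(config.effect_sides))
            for side in config.sides:
                c = sides[side]
                out[(structure, side)] = (
                    c.subjects,
                    validate_cohort(c.table),
                    {"effect_mask": c.effect_mask, "template": c.template},
                )
    else:
        if not config.input_dir:
            raise ValidationError("files mode requires input_dir")
        table = validate_cohort(
            pd.read_csv(os.path.join(config.input_dir, "covariates.csv"))
        )
        for structure in config.structures:
            for side in config.sides:
                d = os.path.join(config.input_dir, f"{structure}_{side}")
                subjects = {}
                for sid in table["id"]:
                    path = os.path.join(d, f"{sid}.vtk")
                    if not os.path.exists(path):
                        raise ValidationError(
                            f"missing surface for subject {sid}: {path}"
                        )
                    subjects[sid] = read_surface(path)
                out[(structure, side)] = (subjects, table, {})
    return out


def _resolve_template(config: RunConfig, subjects: dict):
    if config.template == "mean":
        return mean_template(subjects.values())
    return read_surface(config.template)


def _analyze_side(config: RunConfig, structure, side, subjects, table):
    """Volumes, features, and the multivariate permutation test for one side."""
    ids = list(table["id"])
    surfs = [subjects[i] for i in ids]
    template = _resolve_template(config, subjects)
    labels = (table["group"] == "high").to_numpy()
    volumes = np.array([compute_volume(s) for s in surfs])
    vba_p = volume_permutation_ttest(
        volumes, labels, n_perm=config.n_perm, seed=config.seed
    )
    feats = np.stack([subject_features(template, s) for s in surfs])
    n, R, M, C = feats.shape
    flat = np.nan_to_num(feats.reshape(n, R * M, C))
    resid = residualize(flat, table["age"].to_numpy())
    sm = vertexwise_permutation_test(
        resid,
        labels,
        n_perm=config.n_perm,
        seed=config.seed,
        alpha_vertex=config.alpha_vertex,
    )
    detj = np.stack(
        [
            detj_vertex_field(compute_jacobians(template, s)).ravel()
            for s in surfs
        ]
    )
    ratio = detj_ratio_map(detj[labels], detj[~labels])
    return {
        "structure": structure,
        "side": side,
        "template": template,
        "grid": (R, M),
        "ids": ids,
        "labels": labels,
        "volumes": volumes,
        "vba_p": vba_p,
        "statmap": sm,
        "detj": detj,
        "detj_ratio": ratio,
    }


def _summary_row(res) -> dict:
    vols, lab = res["volumes"], res["labels"]
    return {
        "structure": res["structure"],
        "side": res["side"],
        "vol_high_mean": float(vols[lab].mean()),
        "vol_high_sd": float(vols[lab].std(ddof=1)),
        "vol_low_mean": float(vols[~lab].mean()),
        "vol_low_sd": float(vols[~lab].std(ddof=1)),
        "p_vba": res["vba_p"],
        "p_mtbm": res["statmap"].corrected_p,
    }


def _write_side_outputs(config, res, out_dir):
    sm = res["statmap"]
    R, M = res["grid"]
    name = f"{res['structure']}_{res['side']}"
    write_surface(
        res["template"],
        os.path.join(out_dir, f"{name}_maps.vtk"),
        scalars={
            "detJ_ratio": np.nan_to_num(res["detj_ratio"], nan=1.0),
            "T2": sm.stat,
            "p_uncorrected": sm.p,
        },
    )
    summary = {
        "structure": res["structure"],
        "side": res["side"],
        "n_perm": sm.n_perm,
        "seed": sm.seed,
        "alpha_vertex": sm.alpha_vertex,
        "omnibus_count": sm.omnibus_count,
        "corrected_p": sm.corrected_p,
        "vba_p": res["vba_p"],
        "config_hash": config.hash(),
        "notes": sm.notes,
    }
    with open(os.path.join(out_dir, f"{name}_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def run_group_analysis(config: RunConfig) -> pd.DataFrame:
    """Full group comparison: VBA + mTBM per structure/side plus combined.

    Returns the summary table (one row per structure x {left, right,
    combined}) and writes the report bundle to ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.out_dir, exist_ok=True)
    inputs = _load_inputs(config)
    rows = []
    per_structure = {}
    for (structure, side), (subjects, table, _extras) in inputs.items():
        t0 = time.perf_counter()
        res = _analyze_side(config, structure, side, subjects, table)
        log.info(
            "%s %s: corrected p=%.4g vba p=%.4g (%.1fs)",
            structure,
            side,
            res["statmap"].corrected_p,
            res["vba_p"],
            time.perf_counter() - t0,
        )
        _write_side_outputs(config, res, config.out_dir)
        rows.append(_summary_row(res))
        per_structure.setdefault(structure, []).append(res)
    for structure, sides in per_structure.items():
        if len(sides) < 2:
            continue
        combined_p = combine_structures([r["statmap"] for r in sides])
        vols = np.sum([r["volumes"] for r in sides], axis=0)
        lab = sides[0]["labels"]
        vba_p = volume_permutation_ttest(
            vols, lab, n_perm=config.n_perm, seed=config.seed
        )
        rows.append(
            {
                "structure": structure,
                "side": "combined",
                "vol_high_mean": float(vols[lab].mean()),
                "vol_high_sd": float(vols[lab].std(ddof=1)),
                "vol_low_mean": float(vols[~lab].mean()),
                "vol_low_sd": float(vols[~lab].std(ddof=1)),
                "p_vba": vba_p,
                "p_mtbm": combined_p,
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(os.path.join(config.out_dir, "group_analysis.csv"), index=False)
    _write_run_info(config)
    return report


def run_correlation_analysis(config: RunConfig, score_column: str | None = None):
    """Vertex det J vs behavioral-score correlation maps per structure/side."""
    logging.basicConfig(level=config.log_level)
    score_column = score_column or config.score_column
    os.makedirs(config.out_dir, exist_ok=True)
    inputs = _load_inputs(config)
    summaries = []
    for (structure, side), (subjects, table, _extras) in inputs.items():
        if score_column not in table.columns:
            raise ValidationError(f"score column {score_column!r} not in covariates")
        scores = table[score_column].to_numpy(dtype=float)
        if np.ptp(scores) == 0:
            raise ValidationError(f"score column {score_column!r} is constant")
        ids = list(table["id"])
        template = _resolve_template(config, subjects)
        detj = np.stack(
            [
                detj_vertex_field(compute_jacobians(template, subjects[i])).ravel()
                for i in ids
            ]
        )
        cm = score_correlation_map(
            np.nan_to_num(detj, nan=1.0),
            scores,
            n_perm=config.n_perm,
            seed=config.seed,
            alpha_vertex=config.alpha_vertex,
        )
        name = f"{structure}_{side}"
        write_surface(
            template,
            os.path.join(config.out_dir, f"{name}_correlation.vtk"),
            scalars={"r": cm.r, "p_uncorrected": cm.p},
        )
        summary = {
            "structure": structure,
            "side": side,
            "score": score_column,
            "n_perm": cm.n_perm,
            "seed": cm.seed,
            "corrected_p": cm.corrected_p,
            "omnibus_count": cm.omnibus_count,
            "mean_r": float(cm.r.mean()),
            "config_hash": config.hash(),
        }
        with open(
            os.path.join(config.out_dir, f"{name}_correlation.json"), "w"
        ) as fh:
            json.dump(summary, fh, indent=2)
        summaries.append(summary)
    _write_run_info(config)
    return summaries


def _write_run_info(config: RunConfig):
    path = os.path.join(config.out_dir, "run_info.txt")
    with open(path, "w") as fh:
        fh.write(f"# run completed {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        fh.write(f"config_hash: {config.hash()}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def simulate_to_dir(config: RunConfig) -> str:
    """Write a synthetic cohort to disk in the package's exchange layout.

    Layout: ``<out>/covariates.csv`` plus one ``<structure>_<side>/``
    directory holding ``template.vtk`` and one ``<subject id>.vtk`` per
    subject, and ``ground_truth.json`` with the implanted-effect metadata.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    table_written = False
    for k, structure in enumerate(config.structures):
        spec = CohortSpec(
            structure=structure,
            seed=config.seed % _SEED_MOD,
            shape_seed=_structure_seed(config, k),
            **config.cohort,
        )
        sides = generate_bilateral(spec, effect_sides=tuple(config.effect_sides))
        for side in config.sides:
            c = sides[side]
            d = os.path.join(config.out_dir, f"{structure}_{side}")
            os.makedirs(d, exist_ok=True)
            write_surface(c.template, os.path.join(d, "template.vtk"))
            for sid, surf in c.subjects.items():
                write_surface(surf, os.path.join(d, f"{sid}.vtk"))
            truth = {
                "structure": structure,
                "side": side,
                "seed": c.spec.seed,
                "shape_seed": c.spec.shape_seed,
                "effect_scale": c.spec.effect_scale,
                "true_area_contrast": c.true_area_contrast,
                "mask_vertices": np.argwhere(c.effect_mask).tolist(),
                "spec": {
                    f.name: getattr(c.spec, f.name)
                    for f in dataclasses.fields(c.spec)
                    if isinstance(getattr(c.spec, f.name), (int, float, str))
                },
            }
            with open(os.path.join(d, "ground_truth.json"), "w") as fh:
                json.dump(truth, fh)
            if not table_written:
                c.table.to_csv(
                    os.path.join(config.out_dir, "covariates.csv"), index=False
                )
                table_written = True
    return config.out_dir
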