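"""Synthetic study cohorts: corresponded grids with controlled shape effects.

The generator emulates the study design the statistics are built for: two
exposure groups of 10 ("high") and 13 ("low") children aged 9-15, one
surface grid per subject per nucleus, all grids in vertex-wise
correspondence with a common template.  Three controlled signals are
implanted on top of a smooth base shape:

* an **anterior enlargement** in the high group — a raised-cosine-tapered
  local uniform scaling about the structure centroid over the anterior ring
  band, so the in-surface area contrast inside the flat part of the band is
  exactly ``effect_scale ** 2`` and parameter recovery is quantitative;
* a **linear age trend** in overall size (global scaling about the
  centroid);
* **smooth subject-specific variability** as band-limited harmonic radius
  perturbations about the medial axis (white noise would fold cells and is
  anatomically implausible).

Motor scores follow a higher-is-better convention with a negative slope
against mask-mean det J, so enlargement predicts worse performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .grid import SurfaceGrid
from .morphometry import compute_jacobians, detj_vertex_field
from .shapes import ellipsoid_grid

# semi-axes (mm) sized so the analytic ellipsoid volume matches typical
# structure volumes: putamen ~5000, globus pallidus ~1250, caudate ~4100 mm^3
BASE_SEMI_AXES = {
    "putamen": (20.0, 8.5, 7.0216),
    "globus_pallidus": (10.0, 6.0, 4.9736),
    "caudate": (22.0, 7.5, 5.9322),
}


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic structure cohort."""

    n_high: int = 10
    n_low: int = 13
    n_rings: int = 100
    n_around: int = 150
    structure: str = "putamen"
    side: str = "left"
    semi_axes: tuple | None = None  # default: BASE_SEMI_AXES[structure]
    effect_rings_frac: float = 0.25  # anterior ring band carrying the effect
    effect_taper_frac: float = 0.10  # raised-cosine taper width (ring fraction)
    effect_scale: float = 1.05  # local linear scale in the high group
    age_range: tuple = (9.0, 15.0)
    age_slope: float = 0.01  # fractional size growth per year
    noise_amp: float = 0.02  # SD of fractional radius perturbation
    noise_modes: int = 3  # highest harmonic order of the perturbation
    score_intercept: float = 37.0
    score_slope: float = -65.0  # score units per unit (mask-mean detJ - 1)
    score_sd: float = 6.0
    seed: int = 0
    # optional separate stream for per-subject shape noise: lets several
    # structures/sides of the same cohort share demographics (same seed)
    # while varying in shape
    shape_seed: int | None = None

    def __post_init__(self):
        if self.n_high < 2 or self.n_low < 2:
            raise ValidationError("both groups need at least 2 subjects")
        if self.effect_scale <= 0:
            raise ValidationError("effect_scale must be positive")
        if self.semi_axes is None:
            self.semi_axes = BASE_SEMI_AXES[self.structure]


@dataclass
class Cohort:
    """A generated cohort for one structure/side."""

    spec: CohortSpec
    template: SurfaceGrid
    subjects: dict  # id -> SurfaceGrid
    table: pd.DataFrame
    effect_mask: np.ndarray  # (n_rings, n_around) bool
    effect_weights: np.ndarray  # (n_rings,) taper profile in [0, 1]
    true_area_contrast: float  # implanted detJ contrast (effect_scale ** 2)


def effect_weights(spec: CohortSpec) -> np.ndarray:
    """Taper profile over rings: 1 on the anterior band, cosine to 0."""
    R = spec.n_rings
    flat = spec.effect_rings_frac * (R - 1)
    width = max(spec.effect_taper_frac * (R - 1), 1.0)
    i = np.arange(R, dtype=float)
    w = np.zeros(R)
    w[i <= flat] = 1.0
    ramp = (i > flat) & (i <= flat + width)
    w[ramp] = 0.5 * (1 + np.cos(np.pi * (i[ramp] - flat) / width))
    return w


def ground_truth_mask(spec: CohortSpec) -> np.ndarray:
    """Vertices where the implanted taper is at least half its maximum.

    The region is defined geometrically, so the mask exists even when
    effect_scale == 1.
    """
    w = effect_weights(spec)
    return np.repeat((w >= 0.5)[:, None], spec.n_around, axis=1)


def _apply_scaling(verts: np.ndarray, center: np.ndarray, s_per_vertex) -> np.ndarray:
    return center + np.asarray(s_per_vertex)[..., None] * (verts - center)


def _harmonic_noise(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Band-limited smooth fractional radius field, unit-free, SD ~ noise_amp."""
    R, M = spec.n_rings, spec.n_around
    i = (np.arange(R) + 0.5) / R
    j = np.arange(M) / M
    f = np.zeros((R, M))
    K = spec.noise_modes
    for l in range(1, K + 1):
        ring_mode = np.sin(np.pi * l * i)[:, None]
        for k in range(0, K + 1):
            a, b = rng.normal(size=2)
            f += ring_mode * (
                a * np.cos(2 * np.pi * k * j) + b * np.sin(2 * np.pi * k * j)
            )[None, :]
    sd = f.std()
    if sd > 0:
        f *= spec.noise_amp / sd
    return f


def _deform_subject(
    template: SurfaceGrid,
    spec: CohortSpec,
    in_high_group: bool,
    age: float,
    rng: np.random.Generator,
) -> SurfaceGrid:
    verts = template.vertices
    center = verts.reshape(-1, 3).mean(axis=0)
    if in_high_group and spec.effect_scale != 1.0:
        w = effect_weights(spec)[:, None]
        s = 1.0 + (spec.effect_scale - 1.0) * w
        verts = _apply_scaling(verts, center, np.broadcast_to(s, verts.shape[:2]))
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    g = 1.0 + spec.age_slope * (age - mid_age)
    verts = center + g * (verts - center)
    if spec.noise_amp > 0:
        eta = _harmonic_noise(rng, spec)
        axis = verts.mean(axis=1, keepdims=True)
        verts = axis + (1.0 + eta)[..., None] * (verts - axis)
    return SurfaceGrid(verts, structure=spec.structure, side=spec.side)


def _base_template(spec: CohortSpec) -> SurfaceGrid:
    grid = ellipsoid_grid(
        spec.semi_axes,
        n_rings=spec.n_rings,
        n_around=spec.n_around,
        structure=spec.structure,
        side=spec.side,
    )
    if spec.side == "right":
        # mirror across the sagittal plane; reverse the around index to
        # keep the outward orientation convention
        v = grid.vertices.copy()
        v[..., 1] = -v[..., 1]
        v = v[:, ::-1]
        grid = SurfaceGrid(np.ascontiguousarray(v), structure=spec.structure, side="right")
    return grid


def _demographics(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table without scores (ids, groups, ages, sex, water Mn)."""
    n = spec.n_high + spec.n_low
    groups = ["high"] * spec.n_high + ["low"] * spec.n_low
    ids = [f"{g}{k + 1:02d}" for g, cnt in (("high", spec.n_high), ("low", spec.n_low))
           for k in range(cnt)]
    ages = rng.uniform(*spec.age_range, size=n)
    # sex ratios follow the study's demographics (4M/6F high, 5M/8F low,
    # scaled to the requested group sizes); recorded, not modeled
    sexes = []
    for g, cnt in (("high", spec.n_high), ("low", spec.n_low)):
        n_m = round(cnt * (4 / 10 if g == "high" else 5 / 13))
        sx = np.array(["M"] * n_m + ["F"] * (cnt - n_m))
        rng.shuffle(sx)
        sexes.extend(sx.tolist())
    water = np.where(
        np.array(groups) == "high",
        rng.uniform(103, 264, size=n),
        np.exp(rng.uniform(np.log(0.2), np.log(27), size=n)),
    )
    return pd.DataFrame(
        {"id": ids, "group": groups, "age": ages, "sex": sexes, "water_mn": water}
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full corresponded cohort for one structure/side.

    Deterministic in ``spec.seed``: demographics, per-subject shape noise
    and score residuals each draw from dedicated substreams of the seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    demo_ss, score_ss, default_shape_ss = ss.spawn(3)
    shape_root = (
        np.random.SeedSequence(spec.shape_seed)
        if spec.shape_seed is not None
        else default_shape_ss
    )
    subj_ss = shape_root.spawn(spec.n_high + spec.n_low)
    template = _base_template(spec)
    table = _demographics(spec, np.random.default_rng(demo_ss))
    subjects: dict[str, SurfaceGrid] = {}
    mask = ground_truth_mask(spec)
    mask_means = []
    for row, sub_ss in zip(table.itertuples(index=False), subj_ss):
        rng = np.random.default_rng(sub_ss)
        surf = _deform_subject(template, spec, row.group == "high", row.age, rng)
        try:
            surf.validate()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # folds re-raised as errors below
                jac = compute_jacobians(template, surf)
        except Exception as exc:  # noqa: BLE001 - re-raised with guidance
            raise GenerationError(
                f"subject {row.id}: generated surface invalid ({exc}); "
                "reduce noise_amp or effect_scale"
            ) from exc
        if not jac.valid.all():
            raise GenerationError(
                f"subject {row.id}: folded cells in generated deformation; "
                "reduce noise_amp or effect_scale"
            )
        detj = detj_vertex_field(jac)
        mask_means.append(float(np.nanmean(detj[mask])))
        subjects[row.id] = surf
    score_rng = np.random.default_rng(score_ss)
    d = np.array(mask_means)
    scores = (
        spec.score_intercept
        + spec.score_slope * (d - 1.0)
        + score_rng.normal(0.0, spec.score_sd, size=len(d))
    )
    table = table.assign(santa_ana=scores, mask_mean_detj=d)
    return Cohort(
        spec=spec,
        template=template,
        subjects=subjects,
        table=table,
        effect_mask=mask,
        effect_weights=effect_weights(spec),
        true_area_contrast=spec.effect_scale**2,
    )


def generate_bilateral(spec: CohortSpec, effect_sides=("left", "right")):
    """Left/right cohorts of the same children (shared demographics).

    Returns ``{side: Cohort}``; the table (ages, sex, scores) is taken from
    the left cohort so both sides describe the same subjects.  The effect
    can be implanted unilaterally via ``effect_sides``.
    """
    out = {}
    base_shape = spec.shape_seed if spec.shape_seed is not None else spec.seed
    for k, side in enumerate(("left", "right")):
        s = replace(
            spec,
            side=side,
            effect_scale=spec.effect_scale if side in effect_sides else 1.0,
            # same seed -> same demographics; distinct shape noise per side
            shape_seed=(base_shape * 2 + k) % 2**31,
        )
        out[side] = generate_cohort(s)
    shared = out["left"].table.drop(columns=["mask_mean_detj"])
    for side in ("left", "right"):
        out[side].table = shared.copy()
    return out
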