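"""Seeded generator of multi-view 3-D cohorts with known ground truth.

Each subject's map, per view, is the sum of class-dependent spherical blob
effects (Gaussian falloff), linear covariate confounds (age slope and sex
offset over a designated region) and white voxel noise, all smoothed with
a Gaussian kernel; the default smoothing set-points reproduce the intrinsic
map smoothness regime of real component/FA maps (FWHM about 2.2 and 2.0
voxels).  The generator is the test bed for the whole pipeline: presets
provide a zero-signal (null) cohort, a strong-signal cohort, and a
*complementary* cohort in which neither view alone separates all three
classes but the two views together do.

"Mimic" subjects — generated from one class's effect distribution but
carrying another class's label — plant the systematic-misassignment
phenomenon probed by the stability analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data_model import BrainMask, MultiViewDataset, SubjectRecord, ViewDataset, save_map
from .preprocess import GAUSSIAN_FWHM

__all__ = [
    "Blob",
    "ViewSpec",
    "GeneratorConfig",
    "make_mask",
    "generate_cohort",
    "generate_complementary",
    "null_config",
    "strong_config",
    "complementary_config",
    "write_cohort",
]

#: voxel-to-world affine of the synthetic grid (isometric 3 mm spacing)
DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


@dataclass(frozen=True)
class Blob:
    """Spherical effect region with Gaussian falloff (sigma = radius / 2).

    ``amplitudes`` maps class label -> peak effect amplitude; classes not
    listed get 0.
    """

    center: tuple[float, float, float]
    radius: float
    amplitudes: Mapping[str, float]

    def __post_init__(self) -> None:
        amps = {str(k): float(v) for k, v in dict(self.amplitudes).items()}
        if not all(np.isfinite(list(amps.values()) or [0.0])):
            raise ValueError("blob amplitudes must be finite")
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")
        object.__setattr__(self, "amplitudes", amps)

    def f_field(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        sigma = self.radius / 2.0
        return np.exp(-d2 / (2.0 * sigma**2))


@dataclass(frozen=True)
class ViewSpec:
    """One view's generative settings."""

    name: str
    smoothing_sigma: float = 0.92
    noise_sd: float = 1.0
    effects: tuple[Blob, ...] = ()
    age_slope: float = 0.0
    sex_offset: float = 0.0
    confound_region: Blob | None = None

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generative settings (fully determined by ``seed``)."""

    views: tuple[ViewSpec, ...]
    shape: tuple[int, int, int] = (16, 16, 16)
    mask_kind: str = "ellipsoid"
    classes: tuple[str, ...] = ("A", "B", "C")
    n_per_class: int = 20
    age_range: tuple[float, float] = (38.0, 82.0)
    seed: int = 0
    mimics: tuple[tuple[str, str], ...] = ()  # (assigned label, effect class)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("at least two classes are required")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.mask_kind not in ("ellipsoid", "box"):
            raise ValueError(f"unknown mask kind {self.mask_kind!r}")
        for assigned, effect in self.mimics:
            if assigned not in self.classes or effect not in self.classes:
                raise ValueError(f"mimic classes {assigned, effect} unknown")
        object.__setattr__(self, "views", tuple(self.views))
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "mimics", tuple(tuple(m) for m in self.mimics))


def make_mask(
    shape: tuple[int, int, int], kind: str = "ellipsoid"
) -> BrainMask:
    """Ellipsoid (inscribed) or full-box mask on the synthetic grid."""
    if kind == "box":
        return BrainMask.from_volume(np.ones(shape, dtype=bool), DEFAULT_AFFINE)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [s / 2.0 - 0.5 for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return BrainMask.from_volume(r2 <= 1.0, DEFAULT_AFFINE)


def _class_distinguishable(view: ViewSpec, classes) -> bool:
    for a in classes:
        for b in classes:
            if a >= b:
                continue
            if any(
                abs(bl.amplitudes.get(a, 0.0) - bl.amplitudes.get(b, 0.0)) > 0
                for bl in view.effects
            ):
                return True
    return False


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[MultiViewDataset, dict]:
    """Draw a cohort; returns the dataset and a ground-truth sidecar.

    The sidecar records the configuration, covariates, each subject's
    *effect class* (differing from the label for planted mimics) and the
    per-view informative voxel sets.  Identical config (including seed)
    yields a bit-identical cohort.
    """
    import warnings

    mask = make_mask(config.shape, config.mask_kind)
    if not any(_class_distinguishable(v, config.classes) for v in config.views):
        warnings.warn(
            "no view carries a class-dependent effect; classes are "
            "distributionally identical",
            stacklevel=2,
        )
    labels = [c for c in config.classes for _ in range(config.n_per_class)]
    effect_classes = list(labels)
    ids = [f"s{i:03d}" for i in range(len(labels))]
    for m, (assigned, effect) in enumerate(config.mimics):
        ids.append(f"m{m:03d}")
        labels.append(assigned)
        effect_classes.append(effect)
    n = len(ids)
    root = np.random.SeedSequence(config.seed)
    demo_seed, *view_seeds = root.spawn(1 + len(config.views))
    rng = np.random.default_rng(demo_seed)
    ages = rng.uniform(*config.age_range, size=n)
    sexes = rng.integers(0, 2, size=n)
    age_center = float(np.mean(config.age_range))
    subjects = tuple(
        SubjectRecord(ids[i], labels[i], {"age": ages[i], "sex": float(sexes[i])})
        for i in range(n)
    )
    views = []
    informative: dict[str, np.ndarray] = {}
    for spec, vseed in zip(config.views, view_seeds):
        vrng = np.random.default_rng(vseed)
        fields = [b.f_field(config.shape) for b in spec.effects]
        conf_field = (
            spec.confound_region.f_field(config.shape)
            if spec.confound_region is not None
            else None
        )
        data = np.empty((n, mask.n_voxels))
        for i in range(n):
            vol = np.zeros(config.shape)
            for blob, f in zip(spec.effects, fields):
                amp = blob.amplitudes.get(effect_classes[i], 0.0)
                if amp:
                    vol += amp * f
            if conf_field is not None:
                vol += (
                    spec.age_slope * (ages[i] - age_center)
                    + spec.sex_offset * sexes[i]
                ) * conf_field
            if spec.noise_sd > 0:
                vol += vrng.normal(0.0, spec.noise_sd, config.shape)
            if spec.smoothing_sigma > 0:
                vol = gaussian_filter(vol, spec.smoothing_sigma)
            data[i] = mask.extract(vol)
        views.append(ViewDataset(spec.name, data, mask, subjects))
        info = np.zeros(config.shape, dtype=bool)
        for blob, f in zip(spec.effects, fields):
            amps = [blob.amplitudes.get(c, 0.0) for c in config.classes]
            if max(amps) - min(amps) > 0:
                info |= f > 0.05
        informative[spec.name] = mask.extract(info).astype(bool)
    sidecar = {
        "config": config,
        "subject_ids": tuple(ids),
        "labels": tuple(labels),
        "effect_classes": tuple(effect_classes),
        "ages": ages,
        "sexes": sexes,
        "informative_voxels": informative,
    }
    return MultiViewDataset(tuple(views)), sidecar


# --------------------------------------------------------------- presets
def _frac(shape, fx, fy, fz):
    return (fx * (shape[0] - 1), fy * (shape[1] - 1), fz * (shape[2] - 1))


def _preset_views(
    shape,
    amplitude: float,
    noise_sd: float,
    confounds: bool,
    layout: str,
) -> tuple[ViewSpec, ViewSpec]:
    """Two views at the measured-smoothness set-points.

    ``layout='shared'``: both views carry effects that jointly separate
    all classes.  ``layout='complementary'``: view 1 marks only class A,
    view 2 only class C, so each view leaves one class pair unresolved.
    """
    r = max(2.0, 0.18 * min(shape))
    conf = Blob(_frac(shape, 0.5, 0.5, 0.5), 0.3 * min(shape), {})
    if layout == "shared":
        v1_effects = (
            Blob(_frac(shape, 0.32, 0.32, 0.5), r, {"A": amplitude}),
            Blob(_frac(shape, 0.68, 0.68, 0.5), r, {"B": amplitude}),
        )
        v2_effects = (
            Blob(_frac(shape, 0.5, 0.32, 0.62), r, {"B": amplitude}),
            Blob(_frac(shape, 0.5, 0.68, 0.38), r, {"C": amplitude}),
        )
    elif layout == "complementary":
        v1_effects = (Blob(_frac(shape, 0.35, 0.35, 0.5), r, {"A": amplitude}),)
        v2_effects = (Blob(_frac(shape, 0.65, 0.65, 0.5), r, {"C": amplitude}),)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    age_slope = 0.02 if confounds else 0.0
    sex_offset = 0.3 if confounds else 0.0
    return (
        ViewSpec(
            "dmn",
            smoothing_sigma=2.16 / GAUSSIAN_FWHM,
            noise_sd=noise_sd,
            effects=v1_effects,
            age_slope=age_slope,
            sex_offset=sex_offset,
            confound_region=conf if confounds else None,
        ),
        ViewSpec(
            "fa",
            smoothing_sigma=2.00 / GAUSSIAN_FWHM,
            noise_sd=noise_sd,
            effects=v2_effects,
            age_slope=age_slope,
            sex_offset=sex_offset,
            confound_region=conf if confounds else None,
        ),
    )


def strong_config(
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 16, 16),
    n_per_class: int = 20,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    confounds: bool = True,
    mimics: tuple[tuple[str, str], ...] = (),
) -> GeneratorConfig:
    """Strong class-dependent regional effects in both views."""
    return GeneratorConfig(
        views=_preset_views(shape, amplitude, noise_sd, confounds, "shared"),
        shape=shape,
        n_per_class=n_per_class,
        seed=seed,
        mimics=mimics,
    )


def null_config(
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 16, 16),
    n_per_class: int = 20,
    noise_sd: float = 1.0,
    confounds: bool = True,
) -> GeneratorConfig:
    """Zero effect amplitudes: no class signal anywhere."""
    return GeneratorConfig(
        views=_preset_views(shape, 0.0, noise_sd, confounds, "shared"),
        shape=shape,
        n_per_class=n_per_class,
        seed=seed,
    )


def complementary_config(
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 16, 16),
    n_per_class: int = 20,
    amplitude: float = 2.0,
    noise_sd: float = 1.0,
) -> GeneratorConfig:
    """Each view resolves a different class boundary; neither resolves all.

    View 1 marks class A only (so it cannot tell B from C) and view 2
    marks class C only (so it cannot tell A from B); the three classes
    are separable only by combining the views.
    """
    return GeneratorConfig(
        views=_preset_views(shape, amplitude, noise_sd, False, "complementary"),
        shape=shape,
        n_per_class=n_per_class,
        seed=seed,
    )


def generate_complementary(
    config: GeneratorConfig | None = None, **preset_kwargs
) -> tuple[MultiViewDataset, dict]:
    """Generate a complementary-views cohort (>= 3 classes)."""
    if config is None:
        config = complementary_config(**preset_kwargs)
    if len(config.classes) < 3:
        raise ValueError("complementary cohorts need at least three classes")
    return generate_cohort(config)


def write_cohort(
    dataset: MultiViewDataset, outdir: str | Path, sidecar: dict | None = None
) -> dict:
    """Write a cohort to disk as NIfTI volumes + a subjects CSV.

    Produces ``<view>/<subject>.nii.gz`` per view, one ``mask_<view>.nii.gz``
    per view and ``subjects.csv``; returns the paths in a layout directly
    consumable by :func:`mvbc.data_model.load_view`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in dataset.subjects:
        row = {"subject_id": s.subject_id, "label": s.label}
        row.update(s.covariates)
        rows.append(row)
    table_path = outdir / "subjects.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    layout: dict = {"subject_table": table_path, "views": {}}
    for view in dataset.views:
        vdir = outdir / view.view_name
        vdir.mkdir(exist_ok=True)
        mask_path = outdir / f"mask_{view.view_name}.nii.gz"
        save_map(
            np.ones(view.mask.n_voxels), view.mask, mask_path, dtype=np.uint8
        )
        paths = []
        for i, s in enumerate(dataset.subjects):
            p = vdir / f"{s.subject_id}.nii.gz"
            save_map(view.data[i], view.mask, p)
            paths.append(p)
        layout["views"][view.view_name] = {"mask": mask_path, "volumes": paths}
    return layout
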