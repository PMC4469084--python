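"""Synthetic brain-MR phantom slices with exact ground truth.

Each phantom is a 2-D gray raster containing an elliptical "brain", a bright
skull ring around it, and one circular tumor blob strictly inside the brain.
Normal-brain and tumor pixel intensities are i.i.d. draws from declared
3-component Gaussian mixtures, optionally degraded by additive Gaussian (or
Rician) noise clipped to [0, 255].  Ground-truth masks and the true mixture
parameters ride along, so segmentation and mixture fitting can be scored
without any external data.

A cohort mimics the study design of n patients x 3 pseudo-sequences
(T1-, T2-, FLAIR-like contrast variants), with per-patient geometry and
intensity jitter drawn from one seeded stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .gmm import GMMParams

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "PhantomTruth",
    "CohortItem",
    "mixture_from_components",
    "generate_phantom",
    "generate_cohort",
    "default_sequence_specs",
    "save_phantom",
]

GRAY_MAX = 255.0


class GeometryError(ValueError):
    """Tumor blob not strictly inside the brain interior."""


def mixture_from_components(components) -> GMMParams:
    """Build GMMParams from (weight, mean, std) triples."""
    comps = sorted(components, key=lambda c: (c[1], -c[0]))
    w = np.array([c[0] for c in comps], dtype=float)
    mu = np.array([c[1] for c in comps], dtype=float)
    v = np.array([c[2] for c in comps], dtype=float) ** 2
    return GMMParams(weights=w, means=mu, variances=v)


@dataclass
class PhantomSpec:
    """Geometry, intensity mixtures and noise of one synthetic slice.

    Defaults describe the study conditions used throughout the package:
    a 128-pixel raster, a 4-pixel bright skull ring, well-separated normal
    (means 70/100/130) and tumor (means 170/200/230) mixtures and Gaussian
    noise of 4 gray levels.
    """

    image_size: int = 128
    brain_center: Optional[tuple] = None  # (row, col); image center if None
    brain_axes: Optional[tuple] = None  # semi-axes (a_row, a_col)
    skull_ring_width: int = 4
    skull_intensity: float = 245.0
    background_intensity: float = 10.0
    normal_mixture: Sequence[tuple] = field(
        default_factory=lambda: [(0.3, 70.0, 8.0), (0.4, 100.0, 10.0), (0.3, 130.0, 10.0)]
    )
    tumor_mixture: Sequence[tuple] = field(
        default_factory=lambda: [(0.25, 170.0, 8.0), (0.45, 200.0, 10.0), (0.30, 230.0, 8.0)]
    )
    tumor_center: Optional[tuple] = None
    tumor_radius: Optional[float] = None
    noise_std: float = 4.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Fill geometry defaults proportional to the raster size."""
        s = self.image_size
        bc = self.brain_center or (s / 2.0, s / 2.0)
        ba = self.brain_axes or (0.34 * s, 0.40 * s)
        tr = self.tumor_radius if self.tumor_radius is not None else 0.11 * s
        tc = self.tumor_center or (bc[0] - 0.10 * s, bc[1] + 0.12 * s)
        return replace(self, brain_center=bc, brain_axes=ba, tumor_center=tc, tumor_radius=tr)

    def validate(self) -> None:
        spec = self.resolved()
        for name, mix in (("normal_mixture", spec.normal_mixture), ("tumor_mixture", spec.tumor_mixture)):
            w = np.array([c[0] for c in mix], dtype=float)
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} weights must sum to 1 (got {w.sum()!r})")
            for _, mu, _ in mix:
                if not (0.0 <= mu <= GRAY_MAX):
                    raise ValueError(f"{name} mean {mu} outside the gray range [0, {GRAY_MAX}]")
        (cy, cx), (ay, ax) = spec.brain_center, spec.brain_axes
        ty, tx = spec.tumor_center
        r = spec.tumor_radius
        if r <= 0:
            raise GeometryError("tumor radius must be positive")
        ia, ib = ay - r, ax - r
        if ia <= 0 or ib <= 0 or ((ty - cy) / ia) ** 2 + ((tx - cx) / ib) ** 2 >= 1.0:
            raise GeometryError("tumor blob must lie strictly inside the brain ellipse")
        if ay + spec.skull_ring_width >= spec.image_size / 2 or ax + spec.skull_ring_width >= spec.image_size / 2:
            raise GeometryError("brain plus skull ring must fit inside the image")


@dataclass
class PhantomTruth:
    """Generated slice plus ground-truth masks and mixture parameters."""

    image: np.ndarray
    tumor_mask: np.ndarray
    normal_mask: np.ndarray
    skull_mask: np.ndarray
    true_tumor_mixture: GMMParams
    true_normal_mixture: GMMParams
    spec: PhantomSpec


@dataclass
class CohortItem:
    patient_id: int
    sequence: str
    truth: PhantomTruth


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _sample_mixture(rng: np.random.Generator, components, n: int) -> np.ndarray:
    w = np.array([c[0] for c in components], dtype=float)
    mu = np.array([c[1] for c in components], dtype=float)
    sd = np.array([c[2] for c in components], dtype=float)
    idx = rng.choice(len(components), size=n, p=w / w.sum())
    return rng.normal(mu[idx], sd[idx])


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom slice; identical spec (and seed) gives identical pixels."""
    spec.validate()
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    shape = (s, s)

    brain = _ellipse_mask(shape, spec.brain_center, spec.brain_axes)
    outer = _ellipse_mask(
        shape,
        spec.brain_center,
        (spec.brain_axes[0] + spec.skull_ring_width, spec.brain_axes[1] + spec.skull_ring_width),
    )
    skull = outer & ~brain
    tumor = _disk_mask(shape, spec.tumor_center, spec.tumor_radius)
    if (tumor & ~brain).any():
        raise GeometryError("rasterized tumor blob leaks outside the brain ellipse")
    normal = brain & ~tumor

    img = np.full(shape, spec.background_intensity, dtype=float)
    img[skull] = spec.skull_intensity
    img[normal] = _sample_mixture(rng, spec.normal_mixture, int(normal.sum()))
    img[tumor] = _sample_mixture(rng, spec.tumor_mixture, int(tumor.sum()))

    if spec.noise_std > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_std, shape)
        elif spec.noise_model == "rician":
            n1 = rng.normal(0.0, spec.noise_std, shape)
            n2 = rng.normal(0.0, spec.noise_std, shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
    img = np.clip(img, 0.0, GRAY_MAX)

    return PhantomTruth(
        image=img,
        tumor_mask=tumor,
        normal_mask=normal,
        skull_mask=skull,
        true_tumor_mixture=mixture_from_components(spec.tumor_mixture),
        true_normal_mixture=mixture_from_components(spec.normal_mixture),
        spec=spec,
    )


def default_sequence_specs(image_size: int = 128) -> dict:
    """Three contrast variants standing in for T1-, T2- and FLAIR-like modes.

    All three keep the tumor brighter than normal brain (the package's
    segmentation assumes a bright lesion band); they differ in the normal /
    tumor mixture placement so the pseudo-sequences are not copies.
    """
    base = PhantomSpec(image_size=image_size)
    t2 = replace(
        base,
        normal_mixture=[(0.35, 60.0, 8.0), (0.35, 90.0, 10.0), (0.30, 120.0, 10.0)],
        tumor_mixture=[(0.30, 175.0, 9.0), (0.40, 205.0, 10.0), (0.30, 235.0, 7.0)],
    )
    flair = replace(
        base,
        normal_mixture=[(0.30, 55.0, 8.0), (0.40, 85.0, 10.0), (0.30, 115.0, 10.0)],
        tumor_mixture=[(0.25, 165.0, 8.0), (0.45, 195.0, 10.0), (0.30, 225.0, 8.0)],
    )
    return {"T1": base, "T2": t2, "FLAIR": flair}


def generate_cohort(
    n_patients: int,
    per_sequence_specs,
    seed: int = 0,
) -> list:
    """Cohort of n patients, one phantom per pseudo-sequence variant.

    ``per_sequence_specs`` is a mapping (or list) of PhantomSpec variants.
    Per-patient jitter (tumor position/size, mixture means) comes from a
    single stream seeded by ``seed``, so the cohort is reproducible.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if isinstance(per_sequence_specs, dict):
        variants = list(per_sequence_specs.items())
    else:
        variants = [(f"seq{i + 1}", s) for i, s in enumerate(per_sequence_specs)]
    if not variants:
        raise ValueError("need at least one sequence variant")

    rng = np.random.default_rng(seed)
    items: list[CohortItem] = []
    for pid in range(1, n_patients + 1):
        dy, dx = rng.uniform(-4.0, 4.0, size=2)
        radius_scale = rng.uniform(0.85, 1.15)
        mean_shift = rng.uniform(-5.0, 5.0)
        for seq_name, spec in variants:
            child_seed = int(rng.integers(0, 2**31 - 1))
            base = spec.resolved()
            jittered = replace(
                base,
                tumor_center=(base.tumor_center[0] + dy, base.tumor_center[1] + dx),
                tumor_radius=base.tumor_radius * radius_scale,
                normal_mixture=[(w, m + mean_shift, s_) for w, m, s_ in base.normal_mixture],
                tumor_mixture=[(w, m + mean_shift, s_) for w, m, s_ in base.tumor_mixture],
                seed=child_seed,
            )
            items.append(CohortItem(patient_id=pid, sequence=seq_name, truth=generate_phantom(jittered)))
    return items


def save_phantom(truth: PhantomTruth, out_dir, stem: str = "phantom") -> dict:
    """Write image + masks as PNG and the true parameters as a JSON sidecar."""
    from .preprocess import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "tumor_mask": out_dir / f"{stem}_tumor_mask.png",
        "normal_mask": out_dir / f"{stem}_normal_mask.png",
        "skull_mask": out_dir / f"{stem}_skull_mask.png",
        "params": out_dir / f"{stem}_truth.json",
    }
    write_image(paths["image"], truth.image)
    write_image(paths["tumor_mask"], truth.tumor_mask, binary=True)
    write_image(paths["normal_mask"], truth.normal_mask, binary=True)
    write_image(paths["skull_mask"], truth.skull_mask, binary=True)
    with open(paths["params"], "w") as fh:
        json.dump(
            {
                "true_tumor_mixture": truth.true_tumor_mixture.to_dict(),
                "true_normal_mixture": truth.true_normal_mixture.to_dict(),
                "seed": truth.spec.seed,
                "image_size": truth.spec.image_size,
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}
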