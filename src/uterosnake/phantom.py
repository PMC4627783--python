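"""Seeded B-mode-like speckle phantoms with analytic ground truth.

Real laparoscopic-ultrasound frames are not redistributable, so every stage
of the pipeline is exercised on synthetic phantoms that emulate the salient
appearance of B-mode imaging: a smooth-bordered organ region brighter (or
darker) than its surround, fully developed multiplicative speckle modelled
as unit-mean gamma noise, blurred edges, and a few saturated specular
highlight spots. Each phantom carries its exact ground truth — the analytic
boundary contour, its rasterized mask, and jittered border samples standing
in for the points a clinician would draw.

All randomness flows from the single seed in the spec: the same spec gives
a bit-identical phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import (
    BinaryMask,
    ContourCurve,
    GrayImage,
    SeedPoints,
    ValidationError,
    rasterize_contour,
    write_contour,
    write_gray_image,
    write_mask,
    write_seed_points,
)

__all__ = ["OrganShape", "PhantomSpec", "PhantomCase", "generate", "generate_cohort"]

#: number of vertices used to sample the analytic truth contour
_N_CONTOUR = 256


@dataclass
class OrganShape:
    """Elliptical (optionally blob-perturbed) organ geometry.

    ``rotation_deg`` is the major-axis angle, counterclockwise from the
    column axis in the displayed image, matching the AULA convention of
    :mod:`uterosnake.measure`. ``perturb_amp`` > 0 switches on a low-order
    cyclic harmonic perturbation of the radius (harmonics 2–4, phases drawn
    from the phantom seed) that keeps the true contour analytic while
    breaking exact ellipticity.
    """

    center: tuple[float, float] = (128.0, 128.0)
    a: float = 60.0
    b: float = 40.0
    rotation_deg: float = 20.0
    perturb_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.b > self.a:
            raise ValidationError("organ semi-axes must satisfy a >= b")
        if self.b <= 0:
            raise ValidationError("organ semi-axes must be positive")
        if not (0 <= self.perturb_amp < 0.5):
            raise ValidationError("perturb_amp must lie in [0, 0.5)")

    def boundary(self, phi: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """(row, col) boundary points at parameter angles ``phi``."""
        theta = np.radians(self.rotation_deg)
        u = np.array([-np.sin(theta), np.cos(theta)])  # major-axis direction
        w = np.array([-np.cos(theta), -np.sin(theta)])  # minor-axis direction
        rho = np.ones_like(phi)
        if self.perturb_amp > 0:
            if rng is None:
                raise ValidationError("blob perturbation needs an RNG for its phases")
            amps = rng.dirichlet(np.ones(3)) * self.perturb_amp
            phases = rng.uniform(0, 2 * np.pi, size=3)
            for k, (amp, psi) in enumerate(zip(amps, phases), start=2):
                rho = rho + amp * np.cos(k * phi + psi)
        pts = (
            np.asarray(self.center)
            + rho[:, None] * (self.a * np.cos(phi)[:, None] * u
                              + self.b * np.sin(phi)[:, None] * w)
        )
        return pts


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    ``speckle_shape`` is the gamma shape parameter of the unit-mean
    multiplicative speckle (coefficient of variation 1/sqrt(shape));
    ``None`` disables speckle entirely. ``edge_blur_sigma`` blurs the
    two-level template before speckle is applied, so the border softens
    while the speckle statistics stay intact. ``n_specular`` saturated
    spots of radius 1–3 px are stamped at uniform random positions.
    """

    shape: tuple[int, int] = (256, 256)
    organ: OrganShape = field(default_factory=OrganShape)
    organ_mean: float = 150.0
    background_mean: float = 80.0
    speckle_shape: float | None = 4.0
    edge_blur_sigma: float = 2.0
    n_specular: int = 3
    n_seeds: int = 8
    seed_jitter_sd: float = 2.0
    seed_jitter_max: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.organ_mean == self.background_mean:
            raise ValidationError("organ and background means must differ")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValidationError("speckle_shape must be positive (or None)")
        if self.n_seeds < 3:
            raise ValidationError("need at least 3 seed points")
        h, w = self.shape
        margin = 5.0
        reach = self.organ.a * (1 + self.organ.perturb_amp)
        cr, cc = self.organ.center
        if (
            cr - reach < margin
            or cc - reach < margin
            or cr + reach > h - 1 - margin
            or cc + reach > w - 1 - margin
        ):
            raise ValidationError("organ does not fit inside the image with a 5 px margin")


@dataclass
class PhantomCase:
    """One generated phantom: image, exact truth, and simulated seed points."""

    image: GrayImage
    truth_mask: BinaryMask
    truth_contour: ContourCurve
    seeds: SeedPoints
    spec: PhantomSpec

    def write(self, out_dir: str | Path) -> None:
        """Write img.png, truth.png, truth_contour.csv, seeds.csv, spec.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gray_image(self.image, out / "img.png")
        write_mask(self.truth_mask, out / "truth.png")
        write_contour(self.truth_contour, out / "truth_contour.csv")
        write_seed_points(self.seeds, out / "seeds.csv")
        (out / "spec.json").write_text(json.dumps(asdict(self.spec), indent=2) + "\n")


def generate(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case from a spec.

    Stages: analytic boundary → rasterized two-level template → Gaussian
    edge blur of the template → multiplicative unit-mean gamma speckle →
    saturated specular spots → clip to [0, 255] and round to gray levels.
    """
    rng = np.random.default_rng(spec.seed)
    phi = np.linspace(0, 2 * np.pi, _N_CONTOUR, endpoint=False)
    contour = ContourCurve(spec.organ.boundary(phi, rng))
    truth = rasterize_contour(contour, spec.shape)

    template = np.where(truth.pixels, spec.organ_mean, spec.background_mean).astype(
        np.float64
    )
    if spec.edge_blur_sigma > 0:
        template = ndimage.gaussian_filter(template, spec.edge_blur_sigma)
    if spec.speckle_shape is not None:
        k = spec.speckle_shape
        template = template * rng.gamma(k, 1.0 / k, size=spec.shape)
    for _ in range(spec.n_specular):
        r = rng.uniform(0, spec.shape[0] - 1)
        c = rng.uniform(0, spec.shape[1] - 1)
        radius = rng.uniform(1.0, 3.0)
        rr, cc = np.ogrid[: spec.shape[0], : spec.shape[1]]
        template[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = 255.0
    pixels = np.rint(np.clip(template, 0, 255))

    seeds = _simulate_seeds(spec, contour, rng)
    return PhantomCase(
        image=GrayImage(pixels, source_id=f"phantom(seed={spec.seed})"),
        truth_mask=truth,
        truth_contour=contour,
        seeds=seeds,
        spec=spec,
    )


def _simulate_seeds(
    spec: PhantomSpec, contour: ContourCurve, rng: np.random.Generator
) -> SeedPoints:
    """Jittered samples of the true border, mimicking clinician-drawn points."""
    n = spec.n_seeds
    idx = (np.arange(n) * len(contour)) // n
    base = contour.vertices[idx]
    center = contour.vertices.mean(axis=0)
    radial = base - center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    offset = np.clip(
        rng.normal(0.0, spec.seed_jitter_sd, size=n),
        -spec.seed_jitter_max,
        spec.seed_jitter_max,
    )
    pts = base + offset[:, None] * radial
    h, w = spec.shape
    pts[:, 0] = np.clip(pts[:, 0], 0, h - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, w - 1)
    return SeedPoints(pts)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    variation: dict | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with independently drawn organ geometry.

    ``variation`` maps any of ``center_r``, ``center_c``, ``a``, ``b``,
    ``rotation_deg`` to a ``(low, high)`` range sampled uniformly per case
    (defaults emulate a modest case-to-case spread of uterine size and
    orientation). Per-case RNG seeds are derived deterministically from the
    master ``seed``; axes are swapped if a draw gives b > a. Raises when no
    geometry inside the ranges can fit in the image.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    base = base_spec or PhantomSpec()
    h, w = base.shape
    var = {
        "center_r": (h / 2 - 10, h / 2 + 10),
        "center_c": (w / 2 - 10, w / 2 + 10),
        "a": (45.0, 70.0),
        "b": (30.0, 45.0),
        "rotation_deg": (0.0, 180.0),
    }
    var.update(variation or {})
    master = np.random.default_rng(seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        rng = np.random.default_rng(case_seeds[i])
        draw = {k: float(rng.uniform(*v)) for k, v in var.items()}
        a, b = max(draw["a"], draw["b"]), min(draw["a"], draw["b"])
        organ = OrganShape(
            center=(draw["center_r"], draw["center_c"]),
            a=a,
            b=b,
            rotation_deg=draw["rotation_deg"] % 180.0,
            perturb_amp=base.organ.perturb_amp,
        )
        spec = PhantomSpec(
            shape=base.shape,
            organ=organ,
            organ_mean=base.organ_mean,
            background_mean=base.background_mean,
            speckle_shape=base.speckle_shape,
            edge_blur_sigma=base.edge_blur_sigma,
            n_specular=base.n_specular,
            n_seeds=base.n_seeds,
            seed_jitter_sd=base.seed_jitter_sd,
            seed_jitter_max=base.seed_jitter_max,
            seed=int(case_seeds[i]),
        )
        cases.append(generate(spec))
    return cases
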