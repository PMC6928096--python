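"""Synthetic phantom generation: geometry, resection simulation, rendering.

The digital phantom consists of two coaxial superellipsoidal zones (outer
peripheral, nested central) pierced by a cylindrical urethra along the
slicing axis, embedded in a darker agar-like background.  Resections are
simulated per slice as star-shaped cavities of controllable roughness,
asymmetry and peripheral-zone breach behaviour, so that every downstream
stage can be exercised against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as _gamma

from turpeval.volume import Label, LabelVolume, SliceStack

__all__ = [
    "PhantomSpec",
    "SkillProfile",
    "NoiseModel",
    "BreachEvent",
    "CaseBundle",
    "PhantomSpecError",
    "ResectionError",
    "build_phantom",
    "simulate_resection",
    "render_ultrasound",
    "generate_case",
    "EXPERT",
    "FELLOW",
    "AMATEUR",
    "named_profile",
]

#: Exponent of the superellipsoid |x/a|^p + |y/b|^p + |z/c|^p <= 1 chosen so
#: that the default 40 x 32 x 35 mm bounding box encloses a ~20 cm^3 organ.
DEFAULT_SHAPE_EXPONENT = 1.732

# Variance of a Rayleigh variate rescaled to unit mean (4/pi - 1).
_RAYLEIGH_UNIT_VAR = 4.0 / math.pi - 1.0


class PhantomSpecError(ValueError):
    """Raised when a phantom specification violates one of its invariants."""


class ResectionError(ValueError):
    """Raised when a skill profile cannot produce a valid resection."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric geometry and imaging grid of the digital phantom.

    Lengths in mm.  ``width_mm``/``depth_mm``/``height_mm`` bound the outer
    peripheral zone; ``central_zone_scale`` gives the per-axis fraction of the
    outer semi-axes occupied by the central zone.  The slicing axis is the
    urethra axis (height), slices are taken symmetrically about the equator.
    """

    width_mm: float = 40.0
    depth_mm: float = 32.0
    height_mm: float = 35.0
    central_zone_scale: tuple = (0.75, 0.75, 0.8)
    urethra_radius_mm: float = 1.5
    slice_spacing_mm: float = 0.5
    pixel_spacing_mm: float = 0.1
    n_slices: int = 40
    embedding_margin_mm: float = 4.0
    shape_exponent: float = DEFAULT_SHAPE_EXPONENT

    def __post_init__(self) -> None:
        self.validate()

    @property
    def outer_semi_axes_mm(self) -> tuple:
        return (self.width_mm / 2.0, self.depth_mm / 2.0, self.height_mm / 2.0)

    @property
    def central_semi_axes_mm(self) -> tuple:
        return tuple(a * s for a, s in zip(self.outer_semi_axes_mm, self.central_zone_scale))

    def validate(self) -> None:
        for name in ("width_mm", "depth_mm", "height_mm", "urethra_radius_mm",
                     "slice_spacing_mm", "pixel_spacing_mm"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_slices < 1:
            raise PhantomSpecError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.embedding_margin_mm < 0:
            raise PhantomSpecError("embedding_margin_mm must be >= 0")
        if len(self.central_zone_scale) != 3:
            raise PhantomSpecError("central_zone_scale must have three per-axis entries")
        if not all(0.0 < s < 1.0 for s in self.central_zone_scale):
            raise PhantomSpecError(
                "central_zone_scale must be axis-wise in (0, 1) so the central zone "
                f"lies strictly inside the peripheral zone, got {self.central_zone_scale}"
            )
        # in-plane central semi-axes bound the urethra
        cx, cy, _ = self.central_semi_axes_mm
        if self.urethra_radius_mm >= min(cx, cy):
            raise PhantomSpecError(
                f"urethra_radius_mm ({self.urethra_radius_mm}) must be smaller than the "
                f"smallest in-plane central semi-axis ({min(cx, cy):.3g})"
            )
        if self.n_slices * self.slice_spacing_mm > self.height_mm + 1e-9:
            raise PhantomSpecError(
                f"n_slices * slice_spacing_mm = {self.n_slices * self.slice_spacing_mm:.3g} "
                f"exceeds height_mm = {self.height_mm}"
            )
        if self.shape_exponent <= 0:
            raise PhantomSpecError("shape_exponent must be > 0")

    def grid_shape(self) -> tuple:
        nx = int(round((self.width_mm + 2 * self.embedding_margin_mm) / self.pixel_spacing_mm)) | 1
        ny = int(round((self.depth_mm + 2 * self.embedding_margin_mm) / self.pixel_spacing_mm)) | 1
        return ny, nx

    def pixel_coords_mm(self) -> tuple:
        """(y, x) physical coordinates of pixel centers, origin at urethra axis."""
        ny, nx = self.grid_shape()
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing_mm
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_spacing_mm
        return y, x

    def slice_positions_mm(self) -> np.ndarray:
        """z of each slice plane, symmetric about the equator."""
        k = np.arange(self.n_slices)
        return (k - (self.n_slices - 1) / 2.0) * self.slice_spacing_mm

    def analytic_volume_mm3(self) -> float:
        """Closed-form volume of the outer superellipsoidal envelope."""
        p = self.shape_exponent
        a, b, c = self.outer_semi_axes_mm
        return 8.0 * a * b * c * _gamma(1 + 1 / p) ** 3 / _gamma(1 + 3 / p)


@dataclass(frozen=True)
class SkillProfile:
    """Operator behaviour used to parameterize a simulated resection."""

    mean_resection_radius_mm: float = 10.0
    roughness_amplitude: float = 0.0
    roughness_harmonics: tuple = (2, 3, 5, 7, 11)
    asymmetry_offset_mm: float = 0.0
    breach_probability: float = 0.0
    breach_depth_fraction: float = 0.0
    breach_halfwidth_rad: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        if not 0.0 <= self.breach_probability <= 1.0:
            raise ValueError("breach_probability must lie in [0, 1]")
        if not 0.0 <= self.breach_depth_fraction <= 1.0:
            raise ValueError("breach_depth_fraction must lie in [0, 1]")
        if self.asymmetry_offset_mm < 0:
            raise ValueError("asymmetry_offset_mm must be >= 0")
        if self.breach_halfwidth_rad <= 0:
            raise ValueError("breach_halfwidth_rad must be > 0")


# Reference profiles with strictly ordered roughness / asymmetry / breach
# parameters, mirroring the three operator levels of the source experiment.
EXPERT = SkillProfile(roughness_amplitude=0.02, asymmetry_offset_mm=0.3,
                      breach_probability=0.0, breach_depth_fraction=0.0)
FELLOW = SkillProfile(roughness_amplitude=0.12, asymmetry_offset_mm=1.2,
                      breach_probability=0.1, breach_depth_fraction=0.3)
AMATEUR = SkillProfile(roughness_amplitude=0.30, asymmetry_offset_mm=2.5,
                       breach_probability=0.6, breach_depth_fraction=0.7)

_NAMED = {"expert": EXPERT, "fellow": FELLOW, "amateur": AMATEUR}


def named_profile(name: str, seed: int = 0) -> SkillProfile:
    """Return a built-in skill profile ('expert', 'fellow', 'amateur')."""
    try:
        base = _NAMED[name.lower()]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(_NAMED)}") from None
    return replace(base, seed=seed)


@dataclass(frozen=True)
class NoiseModel:
    """Phenomenological B-mode intensity model.

    Mean intensities must be strictly ordered central > peripheral >
    background > cavity (contrast agent makes the central zone bright, the
    water-filled urethra/cavity is darkest).  Speckle is multiplicative
    Rayleigh noise rescaled to unit mean; the image is then Gaussian-blurred.
    """

    mean_central: float = 0.85
    mean_peripheral: float = 0.55
    mean_background: float = 0.15
    mean_cavity: float = 0.05
    speckle_variance: float = 0.03
    blur_sigma_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mean_central > self.mean_peripheral > self.mean_background > self.mean_cavity):
            raise ValueError(
                "label means must satisfy central > peripheral > background > cavity"
            )
        if self.speckle_variance < 0 or self.blur_sigma_mm < 0:
            raise ValueError("speckle_variance and blur_sigma_mm must be >= 0")
        if not (0.0 <= self.mean_cavity and self.mean_central <= 1.0):
            raise ValueError("label means must lie in [0, 1]")

    def label_means(self) -> np.ndarray:
        means = np.zeros(4)
        means[Label.BACKGROUND] = self.mean_background
        means[Label.PERIPHERAL] = self.mean_peripheral
        means[Label.CENTRAL] = self.mean_central
        means[Label.CAVITY] = self.mean_cavity
        return means


@dataclass(frozen=True)
class BreachEvent:
    """Ground-truth record of one peripheral-zone breach."""

    slice_index: int
    angle_rad: float
    depth_fraction: float
    max_depth_mm: float


@dataclass
class CaseBundle:
    """Co-registered pre/post stacks with their ground truth for one case."""

    pre_labels: LabelVolume
    post_labels: LabelVolume
    pre_stack: SliceStack
    post_stack: SliceStack
    breaches: list
    spec: PhantomSpec
    skill: SkillProfile
    noise: NoiseModel
    meta: dict = field(default_factory=dict)


def _super_radius(v: np.ndarray, p: float) -> np.ndarray:
    """Generalized radius (|.|^p norm) with overflow-safe absolute values."""
    return np.abs(v) ** p


def build_phantom(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the pre-surgery ground-truth label volume.

    Outer superellipsoid = peripheral zone, nested scaled copy = central
    zone, cylinder of ``urethra_radius_mm`` along the slicing axis = CAVITY.
    Deterministic for a fixed spec.
    """
    spec.validate()
    p = spec.shape_exponent
    ax, ay, az = spec.outer_semi_axes_mm
    cx, cy, cz = spec.central_semi_axes_mm
    y, x = spec.pixel_coords_mm()
    xx = x[None, :]
    yy = y[:, None]
    r2 = xx ** 2 + yy ** 2
    urethra = r2 <= spec.urethra_radius_mm ** 2
    outer_xy = _super_radius(xx / ax, p) + _super_radius(yy / ay, p)
    central_xy = _super_radius(xx / cx, p) + _super_radius(yy / cy, p)

    slices = np.zeros((spec.n_slices,) + spec.grid_shape(), dtype=np.uint8)
    for k, z in enumerate(spec.slice_positions_mm()):
        lab = slices[k]
        lab[outer_xy <= 1.0 - _super_radius(z / az, p)] = Label.PERIPHERAL
        lab[central_xy <= 1.0 - _super_radius(z / cz, p)] = Label.CENTRAL
        lab[urethra] = Label.CAVITY
    return LabelVolume(
        slices,
        spec.pixel_spacing_mm,
        spec.slice_spacing_mm,
        meta={"kind": "pre", "spec": _spec_meta(spec)},
    )


def _spec_meta(spec: PhantomSpec) -> dict:
    return {
        "width_mm": spec.width_mm,
        "depth_mm": spec.depth_mm,
        "height_mm": spec.height_mm,
        "central_zone_scale": list(spec.central_zone_scale),
        "urethra_radius_mm": spec.urethra_radius_mm,
        "n_slices": spec.n_slices,
        "shape_exponent": spec.shape_exponent,
        "embedding_margin_mm": spec.embedding_margin_mm,
    }


def simulate_resection(phantom: LabelVolume, skill: SkillProfile,
                       n_angle_bins: int = 720):
    """Carve a skill-parameterized cavity into a pre-surgery volume.

    Per slice the boundary is a star-shaped curve around the (offset)
    urethra axis, radius(theta) = R * (1 + amplitude * sum of seeded
    harmonic perturbations), clipped to the central zone.  With probability
    ``breach_probability`` a slice additionally receives a raised-cosine
    angular bump that removes ``breach_depth_fraction`` of the local
    peripheral thickness.  Returns ``(post_volume, breach_events)``;
    fully reproducible for a fixed profile seed.
    """
    spec_meta = phantom.meta.get("spec", {})
    urethra_r = spec_meta.get("urethra_radius_mm")
    if urethra_r is not None and skill.mean_resection_radius_mm <= urethra_r:
        raise ResectionError(
            f"mean_resection_radius_mm ({skill.mean_resection_radius_mm}) must exceed "
            f"the urethra radius ({urethra_r}); no resection possible"
        )
    px = phantom.pixel_spacing_mm
    n_slices, ny, nx = phantom.shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * px
    y = (np.arange(ny) - (ny - 1) / 2.0) * px

    rng = np.random.default_rng(skill.seed)
    offset_dir = rng.uniform(0.0, 2 * math.pi)
    center = (skill.asymmetry_offset_mm * math.cos(offset_dir),
              skill.asymmetry_offset_mm * math.sin(offset_dir))
    xx = x[None, :] - center[0]
    yy = y[:, None] - center[1]
    dist = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)  # [-pi, pi)
    bins = np.minimum(((theta + math.pi) / (2 * math.pi) * n_angle_bins).astype(np.intp),
                      n_angle_bins - 1)
    flat_bins = bins.ravel()
    flat_dist = dist.ravel()
    harmonics = np.asarray(skill.roughness_harmonics, dtype=float)

    out = phantom.data.copy()
    events: list = []
    for k in range(n_slices):
        # one fixed-size draw block per slice: RNG consumption is independent
        # of breach_probability/depth so depth sweeps share the same events
        phases = rng.uniform(0.0, 2 * math.pi, size=harmonics.size)
        weights = rng.uniform(0.5, 1.0, size=harmonics.size)
        breach_u = rng.random()
        breach_angle = rng.uniform(-math.pi, math.pi)

        lab = out[k]
        inner = (lab == Label.CENTRAL) | (lab == Label.CAVITY)
        if not inner.any():
            continue
        tissue = inner | (lab == Label.PERIPHERAL)

        if skill.roughness_amplitude > 0 and harmonics.size:
            pert = np.zeros_like(theta)
            for h, ph, w in zip(harmonics, phases, weights):
                pert += w * np.cos(h * theta + ph)
            pert *= skill.roughness_amplitude / weights.sum()
            r_cav = skill.mean_resection_radius_mm * (1.0 + pert)
        else:
            r_cav = np.full_like(theta, skill.mean_resection_radius_mm)

        cavity = ((dist <= r_cav) & inner) | (lab == Label.CAVITY)

        if breach_u < skill.breach_probability:
            # per-angle extents of the inner region and of all tissue,
            # measured from the cavity center
            r_central = np.full(n_angle_bins, -np.inf)
            np.maximum.at(r_central, flat_bins[inner.ravel()], flat_dist[inner.ravel()])
            r_outer = np.full(n_angle_bins, -np.inf)
            np.maximum.at(r_outer, flat_bins[tissue.ravel()], flat_dist[tissue.ravel()])
            with np.errstate(invalid="ignore"):
                thickness = np.clip(r_outer - r_central, 0.0, None)
            thickness[~np.isfinite(thickness)] = 0.0

            dang = np.angle(np.exp(1j * (theta - breach_angle)))
            window = np.abs(dang) < skill.breach_halfwidth_rad
            profile = 0.5 * (1.0 + np.cos(math.pi * dang / skill.breach_halfwidth_rad))
            depth = skill.breach_depth_fraction * profile * thickness[bins]
            reach = np.where(np.isfinite(r_central[bins]), r_central[bins], -np.inf) + depth
            breach_px = tissue & window & (dist <= reach)
            if breach_px.any():
                cavity |= breach_px
                events.append(BreachEvent(
                    slice_index=k,
                    angle_rad=float(breach_angle),
                    depth_fraction=float(skill.breach_depth_fraction),
                    max_depth_mm=float(depth[breach_px].max()),
                ))
        lab[cavity] = Label.CAVITY
    meta = dict(phantom.meta)
    meta.update(kind="post", skill_seed=skill.seed)
    return (
        LabelVolume(out, phantom.pixel_spacing_mm, phantom.slice_spacing_mm, meta),
        events,
    )


def render_ultrasound(labels: LabelVolume, noise: NoiseModel) -> SliceStack:
    """Render a label volume into a pseudo-B-mode grayscale stack.

    Each pixel takes its label's mean intensity, multiplied by unit-mean
    Rayleigh speckle scaled to ``speckle_variance``, then Gaussian-blurred
    and clipped to [0, 1].  Zero variance and zero blur reproduce the label
    means exactly.
    """
    means = noise.label_means()
    rng = np.random.default_rng(noise.seed)
    img = means[labels.data].astype(np.float64)
    if noise.speckle_variance > 0:
        rayleigh = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=img.shape)
        factor = 1.0 + math.sqrt(noise.speckle_variance / _RAYLEIGH_UNIT_VAR) * (rayleigh - 1.0)
        img *= factor
    if noise.blur_sigma_mm > 0:
        sigma_px = noise.blur_sigma_mm / labels.pixel_spacing_mm
        img = gaussian_filter(img, sigma=(0.0, sigma_px, sigma_px))
    np.clip(img, 0.0, 1.0, out=img)
    return SliceStack(
        img.astype(np.float32),
        labels.pixel_spacing_mm,
        labels.slice_spacing_mm,
        meta={
            "seed": noise.seed,
            "speckle_variance": noise.speckle_variance,
            "blur_sigma_mm": noise.blur_sigma_mm,
            "label_means": means.tolist(),
        },
    )


def generate_case(spec: PhantomSpec, skill: SkillProfile, noise: NoiseModel,
                  seed: int | None = None) -> CaseBundle:
    """Build one co-registered pre/post case with ground truth.

    If ``seed`` is given it deterministically spawns per-stage seeds
    (resection, pre render, post render), overriding those carried by
    ``skill`` and ``noise``; the spawned values are recorded in the bundle
    metadata.
    """
    if seed is not None:
        stage = [int(s) for s in np.random.SeedSequence(seed).generate_state(3)]
        skill = replace(skill, seed=stage[0])
        noise_pre = replace(noise, seed=stage[1])
        noise_post = replace(noise, seed=stage[2])
        seeds = {"top": int(seed), "resection": stage[0],
                 "render_pre": stage[1], "render_post": stage[2]}
    else:
        noise_pre = noise
        noise_post = replace(noise, seed=noise.seed + 1)
        seeds = {"top": None, "resection": skill.seed,
                 "render_pre": noise_pre.seed, "render_post": noise_post.seed}
    pre = build_phantom(spec)
    post, breaches = simulate_resection(pre, skill)
    pre_stack = render_ultrasound(pre, noise_pre)
    post_stack = render_ultrasound(post, noise_post)
    return CaseBundle(
        pre_labels=pre,
        post_labels=post,
        pre_stack=pre_stack,
        post_stack=post_stack,
        breaches=breaches,
        spec=spec,
        skill=skill,
        noise=noise,
        meta={"seeds": seeds},
    )
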