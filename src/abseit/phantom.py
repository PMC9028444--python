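"""Randomised conductivity phantoms: background plus transformed basic shapes.

A phantom is a strictly positive background conductivity with a handful of
enclosures — unit spheres, cubes or octahedra pushed through a translation /
rotation / anisotropic-scaling transform — whose conductivity is a random
multiplicative contrast on the background.  The shape masks are evaluated in
3-D; the desk-scale domain is the z = 0 slice of those masks on a 2-D disc
mesh.  Sampling ranges deliberately overshoot physiological conductivities
(1e-5 to 1 S/m background, contrasts 1e-2 to 1e2, both log-uniform) so a
reconstruction model trained on them carries no bias toward any tissue band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import DiscMesh

SHAPE_KINDS = ("sphere", "cube", "octahedron")

SIGMA_BG_RANGE = (1e-5, 1.0)      # S/m, log-uniform
CONTRAST_RANGE = (1e-2, 1e2)      # dimensionless, log-uniform
SCALE_FRACTION = (0.10, 0.80)     # of the model radius, uniform
PERTURB_STD_RANGE = (1e-8, 1e-2)  # per-conductivity-value std, log-uniform
CONTACT_STDS = (1e-5, 1e-3, 1e-1)
TRANSLATION_FRACTION = 0.8        # "well inside the domain boundaries"


@dataclass(frozen=True)
class ShapeSpec:
    """One enclosure: a unit basic shape under translate-rotate-scale."""

    kind: str
    t: np.ndarray        # translation, model units (3,)
    s: np.ndarray        # per-axis scaling, model units (3,)
    euler: np.ndarray    # intrinsic xyz rotation angles, rad (3,)
    contrast: float      # multiplier on the background conductivity

    def __post_init__(self):
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for name in ("t", "s", "euler"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        if np.any(self.s == 0):
            raise ValueError("scaling components must be non-zero")
        if not (CONTRAST_RANGE[0] <= self.contrast <= CONTRAST_RANGE[1]):
            raise ValueError("contrast outside the sampled range")

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.euler).as_matrix()


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to deterministically rebuild one phantom."""

    sigma_bg: float
    enclosures: tuple = ()
    perturb_std: float | None = None   # None: fresh log-uniform draw per region
    contact_std: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if not (SIGMA_BG_RANGE[0] <= self.sigma_bg <= SIGMA_BG_RANGE[1]):
            raise ValueError("background conductivity outside [1e-5, 1] S/m")
        if self.perturb_std is not None and not (
                0 <= self.perturb_std <= PERTURB_STD_RANGE[1]):
            raise ValueError("perturb_std outside [0, 1e-2]")
        object.__setattr__(self, "enclosures", tuple(self.enclosures))


@dataclass
class ConductivityPhantom:
    mesh: DiscMesh
    sigma: np.ndarray     # per-element conductivity, S/m
    spec: PhantomSpec

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (np.all(np.isfinite(self.sigma)) and np.all(self.sigma > 0)):
            raise ValueError("phantom conductivities must be finite and positive")


def inverse_transform(points: np.ndarray, spec: ShapeSpec) -> np.ndarray:
    """Map world points into an enclosure's unit-shape frame.

    ``v' = (R (v - t)) / s`` with the division component-wise; rotation acts
    after translation, scaling last.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(spec.s == 0):
        raise ValueError("scaling components must be non-zero")
    return ((pts - spec.t) @ spec.rotation_matrix().T) / spec.s


def shape_mask(kind: str, points: np.ndarray) -> np.ndarray:
    """Unit-shape membership of already-transformed points (closed sets)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if kind == "sphere":
        return np.einsum("ij,ij->i", pts, pts) <= 1.0
    if kind == "cube":
        return np.abs(pts).max(axis=1) <= 1.0
    if kind == "octahedron":
        return np.abs(pts).sum(axis=1) <= 1.0
    raise ValueError(f"unknown shape kind {kind!r}")


def sample_enclosure(rng: np.random.Generator, radius: float) -> ShapeSpec:
    """Draw one enclosure spec from the stated sampling distributions."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lo, hi = SCALE_FRACTION
    while True:
        t = rng.uniform(-TRANSLATION_FRACTION * radius,
                        TRANSLATION_FRACTION * radius, size=3)
        if np.hypot(t[0], t[1]) <= TRANSLATION_FRACTION * radius:
            break
    return ShapeSpec(
        kind=SHAPE_KINDS[rng.integers(len(SHAPE_KINDS))],
        t=t,
        s=rng.uniform(lo * radius, hi * radius, size=3),
        euler=rng.uniform(0.0, 2 * np.pi, size=3),
        contrast=float(10.0 ** rng.uniform(np.log10(CONTRAST_RANGE[0]),
                                           np.log10(CONTRAST_RANGE[1]))),
    )


def sample_background(rng: np.random.Generator) -> float:
    """Log-uniform background conductivity on [1e-5, 1] S/m."""
    return float(10.0 ** rng.uniform(np.log10(SIGMA_BG_RANGE[0]),
                                     np.log10(SIGMA_BG_RANGE[1])))


def perturb_field(values: np.ndarray, std: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Multiply each value by an independent N(1, std) draw, kept positive."""
    if std < 0:
        raise ValueError("std must be non-negative")
    values = np.asarray(values, dtype=float)
    mult = rng.normal(1.0, std, size=values.shape)
    return values * np.maximum(mult, 1e-12)


def sample_phantom_spec(rng: np.random.Generator, radius: float,
                        n_enclosures: tuple = (1, 4)) -> PhantomSpec:
    """Draw a complete phantom spec (enclosure count uniform on the range)."""
    n = int(rng.integers(n_enclosures[0], n_enclosures[1] + 1))
    return PhantomSpec(
        sigma_bg=sample_background(rng),
        enclosures=tuple(sample_enclosure(rng, radius) for _ in range(n)),
        contact_std=CONTACT_STDS[rng.integers(len(CONTACT_STDS))],
    )


def build_phantom(mesh: DiscMesh, spec: PhantomSpec,
                  rng: np.random.Generator | None = None) -> ConductivityPhantom:
    """Realise a spec on a mesh: paint enclosure masks, then perturb.

    Enclosures are painted in order, later ones overwriting earlier ones
    where they overlap.  Each painted region (background included) is then
    perturbed multiplicatively with its own std — either ``spec.perturb_std``
    or, when that is None, a fresh log-uniform draw from [1e-8, 1e-2].
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pts = mesh.centroids3d()
    sigma = np.full(mesh.n_elements, spec.sigma_bg)
    regions = [np.ones(mesh.n_elements, dtype=bool)]
    for enc in spec.enclosures:
        mask = shape_mask(enc.kind, inverse_transform(pts, enc))
        if not mask.any():
            warnings.warn("enclosure covers no mesh element (off-slice or "
                          "tiny); kept as specified", stacklevel=2)
        sigma[mask] = spec.sigma_bg * enc.contrast
        for r in regions:
            r &= ~mask
        regions.append(mask)
    if spec.perturb_std != 0:
        lo, hi = np.log10(PERTURB_STD_RANGE[0]), np.log10(PERTURB_STD_RANGE[1])
        for region in regions:
            std = (spec.perturb_std if spec.perturb_std is not None
                   else float(10.0 ** rng.uniform(lo, hi)))
            if region.any():
                sigma[region] = perturb_field(sigma[region], std, rng)
    return ConductivityPhantom(mesh=mesh, sigma=sigma, spec=spec)


def _pixel_grid(radius: float, grid_size: int):
    """Pixel-centre physical coordinates; (0,0) top-left, y down in rows."""
    scale = 2.0 * radius / grid_size
    idx = np.arange(grid_size) - (grid_size - 1) / 2.0
    x = idx * scale
    y = -idx * scale
    X, Y = np.meshgrid(x, y)   # X varies along columns, Y along rows
    return X, Y, scale


def phys_to_pixel(xy, radius: float, grid_size: int = 64) -> tuple:
    """Physical (x, y) to fractional (col, row) pixel coordinates."""
    scale = 2.0 * radius / grid_size
    c = xy[0] / scale + (grid_size - 1) / 2.0
    r = -xy[1] / scale + (grid_size - 1) / 2.0
    return c, r


def rasterize_target(phantom: ConductivityPhantom | PhantomSpec,
                     radius: float | None = None,
                     grid_size: int = 64) -> np.ndarray:
    """Ground-truth conductivity raster on the reconstruction grid.

    Samples the *stated* (unperturbed) conductivity at pixel centres of the
    z = 0 plane; pixels outside the circular domain take the background
    value.  Accepts either a phantom or a bare spec plus the domain radius.
    """
    if isinstance(phantom, ConductivityPhantom):
        spec, radius = phantom.spec, phantom.mesh.radius
    else:
        spec = phantom
        if radius is None:
            raise ValueError("radius required when passing a bare spec")
    X, Y, _ = _pixel_grid(radius, grid_size)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    img = np.full(pts.shape[0], spec.sigma_bg)
    inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= radius ** 2
    for enc in spec.enclosures:
        mask = shape_mask(enc.kind, inverse_transform(pts, enc)) & inside
        img[mask] = spec.sigma_bg * enc.contrast
    return img.reshape(grid_size, grid_size)
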