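"""Stereoscopic gloss stimulus rendering.

Renders a smooth, randomly distorted sphere (a "potato") with a perfectly
specular surface reflecting an environment map at optical infinity, viewed
binocularly at close range.  Four stereoscopic conditions manipulate where
the reflected ray that indexes the environment is cast from, while the
geometry is always imaged from the two true eye positions:

- ``mirror``       each eye uses its own reflected ray (physically correct,
                   looks glossy; reflections detach from the surface in depth).
- ``painted``      both eyes use the cyclopean (mid-point) eye's reflected
                   ray, so the reflections stick to the surface like a
                   texture and the object looks matte in stereo.
- ``anti_mirror``  the two eyes' reflected rays are swapped at each surface
                   point, producing physically wrong disparities that still
                   look glossy.
- ``flat``         one eye's mirror image is shown to both eyes; the object
                   looks stereoscopically flat.

A separate layered (diffuse + specular) rendering path produces the
monocular glossy/matte pair, where rotating the specular layer in the image
plane destroys the impression of gloss without changing low-level image
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

__all__ = [
    "BINOCULAR_CONDITIONS",
    "Potato",
    "Scene",
    "StereoPair",
    "LayeredImage",
    "make_potato",
    "reflect",
    "render_condition",
    "render_layers",
    "make_monocular_pair",
]

BINOCULAR_CONDITIONS = ("mirror", "painted", "anti_mirror", "flat")


# ---------------------------------------------------------------------------
# potato geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Potato:
    """Star-shaped closed surface: r(u) = base_radius * (1 + amplitude * g(u)).

    ``g`` is a random superposition of low-order spherical harmonics
    normalized so that max|g| = 1, hence the radius stays within
    base_radius * (1 +/- amplitude) and the surface never self-intersects
    for amplitude < 1.  All randomness comes from ``seed``.  For speed the
    field is tabulated once on a dense (theta, phi) grid and sampled
    bilinearly; the surface is *defined* by that deterministic table.
    """

    seed: int
    n_modes: int
    amplitude: float
    base_radius: float
    _coeffs: tuple = field(repr=False)  # ((ell, m, a), ...)
    _table: np.ndarray = field(repr=False)  # g on the (theta, phi) grid

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        """Radius (mm) along unit directions ``dirs`` (..., 3)."""
        d = np.asarray(dirs, dtype=float)
        shape = d.shape[:-1]
        d = d.reshape(-1, 3)
        theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        phi = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
        nt, nphi = self._table.shape
        x = theta / np.pi * (nt - 1)
        y = phi / (2 * np.pi) * (nphi - 1)
        x0 = np.clip(np.floor(x).astype(int), 0, nt - 2)
        y0 = np.clip(np.floor(y).astype(int), 0, nphi - 2)
        fx = x - x0
        fy = y - y0
        tab = self._table
        g = (
            tab[x0, y0] * (1 - fx) * (1 - fy)
            + tab[x0 + 1, y0] * fx * (1 - fy)
            + tab[x0, y0 + 1] * (1 - fx) * fy
            + tab[x0 + 1, y0 + 1] * fx * fy
        )
        r = self.base_radius * (1.0 + self.amplitude * g)
        return r.reshape(shape)

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Signed field F(x) = |x| - r(x/|x|); zero on the surface."""
        p = np.asarray(points, dtype=float)
        norm = np.linalg.norm(p, axis=-1)
        norm_safe = np.where(norm == 0, 1.0, norm)
        u = p / norm_safe[..., None]
        return norm - self.radius(u)

    def normals(self, points: np.ndarray, eps: float | None = None) -> np.ndarray:
        """Outward unit surface normals at surface points (central differences)."""
        p = np.asarray(points, dtype=float)
        if eps is None:
            eps = 1e-4 * self.base_radius
        grad = np.empty_like(p)
        for ax in range(3):
            off = np.zeros(3)
            off[ax] = eps
            grad[..., ax] = (self.implicit(p + off) - self.implicit(p - off)) / (2 * eps)
        return grad / np.linalg.norm(grad, axis=-1, keepdims=True)

    @property
    def r_min(self) -> float:
        return self.base_radius * (1.0 - self.amplitude)

    @property
    def r_max(self) -> float:
        return self.base_radius * (1.0 + self.amplitude)

    def to_mesh(self, subdivisions: int = 4):
        """Triangulate as a watertight trimesh.Trimesh (icosphere remap)."""
        import trimesh

        sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        dirs = np.asarray(sphere.vertices)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        verts = dirs * self.radius(dirs)[:, None]
        return trimesh.Trimesh(vertices=verts, faces=sphere.faces, process=False)


def make_potato(
    seed: int,
    n_modes: int = 5,
    amplitude: float = 0.12,
    base_radius: float = 40.0,
) -> Potato:
    """Create a randomly distorted sphere.

    Parameters
    ----------
    seed : controls the harmonic coefficients; same seed -> identical shape.
    n_modes : highest spherical-harmonic order used (>= 1).
    amplitude : fractional radial distortion, in [0, 0.5).
    base_radius : mean radius in mm (40 mm subtends ~7 deg at 650 mm).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if not (0.0 <= amplitude < 0.5):
        raise ValueError(
            "amplitude must lie in [0, 0.5): larger distortions risk a "
            "non-positive radius (self-intersecting surface)"
        )
    rng = np.random.default_rng(seed)
    coeffs = []
    for ell in range(1, n_modes + 1):
        for m in range(-ell, ell + 1):
            # spectral taper keeps the shape smooth and potato-like
            coeffs.append((ell, m, rng.standard_normal() / (1.0 + ell)))
    table = _harmonic_table(coeffs)
    peak = float(np.max(np.abs(table)))
    if peak > 0:
        table = table / peak  # max|g| == 1 so radius spans (1 +/- amplitude) R0
    pot = Potato(seed, n_modes, amplitude, base_radius, tuple(coeffs), table)
    if np.any(pot.radius(_fibonacci_sphere(2048)) <= 0):
        raise ValueError("distortion produced a non-positive radius; reduce amplitude")
    return pot


def _harmonic_table(coeffs, n_theta: int = 257, n_phi: int = 513) -> np.ndarray:
    """Tabulate the random harmonic field g on a (theta, phi) grid.

    Exploits Y_lm separability: the associated-Legendre part depends only
    on theta, the azimuthal part is cos/sin(m phi).
    """
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi)
    g = np.zeros((n_theta, n_phi))
    for ell, m, a in coeffs:
        base = np.real(sph_harm_y(ell, abs(m), theta, 0.0))  # N_lm * P_lm(cos theta)
        if m == 0:
            az = np.ones_like(phi)
        elif m > 0:
            az = np.sqrt(2.0) * (-1) ** m * np.cos(m * phi)
        else:
            az = np.sqrt(2.0) * (-1) ** m * np.sin(abs(m) * phi)
        g += a * np.outer(base, az)
    return g


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = np.pi * (1 + 5**0.5) * i
    s = np.sqrt(1 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


# ---------------------------------------------------------------------------
# reflection
# ---------------------------------------------------------------------------

def reflect(V: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Specular reflection: omega = 2 (n . V) n - V.

    ``V`` is the unit direction from the surface point toward the eye and
    ``n`` the outward unit normal; the returned ``omega`` is the unit
    direction into the environment whose radiance reaches the eye.  The
    angle of incidence equals the angle of reflection and omega lies in the
    plane spanned by n and V.  Back-facing samples (n . V <= 0) are invalid.
    """
    V = np.asarray(V, dtype=float)
    n = np.asarray(n, dtype=float)
    ndv = np.sum(n * V, axis=-1, keepdims=True)
    if np.any(ndv <= 0):
        raise ValueError("back-facing sample: n . V must be > 0 for reflection")
    return 2.0 * ndv * n - V


# ---------------------------------------------------------------------------
# scene and ray casting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scene:
    """Viewing geometry: potato at the origin, eyes on the +z axis side.

    Distances in mm.  The default 65 mm interocular distance and 650 mm
    viewing distance give a vergence geometry matching near viewing; the
    object (radius 40 mm) subtends ~7 degrees.
    """

    potato: Potato
    env: "object"  # EnvironmentMap
    interocular_mm: float = 65.0
    view_distance_mm: float = 650.0
    image_px: int = 96
    fov_deg: float = 9.0

    def __post_init__(self) -> None:
        if self.interocular_mm <= 0:
            raise ValueError("eyes must be distinct (interocular_mm > 0)")
        if self.env is None:
            raise ValueError("scene requires an environment map")
        if self.view_distance_mm <= self.potato.r_max:
            raise ValueError("mesh behind or enclosing the eyes; increase viewing distance")

    @property
    def eye_left(self) -> np.ndarray:
        return np.array([-self.interocular_mm / 2.0, 0.0, self.view_distance_mm])

    @property
    def eye_right(self) -> np.ndarray:
        return np.array([self.interocular_mm / 2.0, 0.0, self.view_distance_mm])

    @property
    def eye_cyclopean(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.view_distance_mm])

    def eye(self, which: str) -> np.ndarray:
        return {"left": self.eye_left, "right": self.eye_right, "cyclopean": self.eye_cyclopean}[which]


def _camera_rays(scene: Scene, eye: np.ndarray) -> np.ndarray:
    """Unit ray directions through each pixel of a camera fixating the origin."""
    n = scene.image_px
    fwd = -eye / np.linalg.norm(eye)
    up_hint = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, up_hint)
    right /= np.linalg.norm(right)
    up = np.cross(right, fwd)
    half = np.tan(np.deg2rad(scene.fov_deg) / 2.0)
    # pixel centers; row 0 is the top of the image
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    xs, ys = np.meshgrid(c, -c)  # ys decreases down the rows
    d = (
        fwd[None, None, :]
        + half * xs[..., None] * right[None, None, :]
        + half * ys[..., None] * up[None, None, :]
    )
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def _intersect(potato: Potato, origin: np.ndarray, dirs: np.ndarray, n_samples: int = 48,
               n_bisect: int = 48) -> tuple[np.ndarray, np.ndarray]:
    """First intersection of rays with the star-shaped surface.

    Brackets the first sign change of the implicit field along each ray
    between the bounding-sphere entry/exit points, then bisects.  Returns
    (hit mask, points); points are valid only where hit.
    """
    d = dirs.reshape(-1, 3)
    o = origin
    b = d @ o
    c = float(o @ o) - potato.r_max**2
    disc = b**2 - c
    hit = disc > 0
    t0 = np.where(hit, -b - np.sqrt(np.maximum(disc, 0.0)), 0.0)
    t1 = np.where(hit, -b + np.sqrt(np.maximum(disc, 0.0)), 0.0)
    t0 = np.maximum(t0, 0.0)

    ts = t0[:, None] + (t1 - t0)[:, None] * np.linspace(0.0, 1.0, n_samples)[None, :]
    pts = o[None, None, :] + ts[..., None] * d[:, None, :]
    g = potato.implicit(pts)
    inside = g <= 0
    first = np.argmax(inside, axis=1)  # 0 if no crossing
    crossed = inside.any(axis=1) & (first > 0)
    hit &= crossed

    idx = np.where(hit)[0]
    lo = ts[idx, first[idx] - 1]
    hi = ts[idx, first[idx]]
    dh = d[idx]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        gm = potato.implicit(o[None, :] + mid[:, None] * dh)
        outside = gm > 0
        lo = np.where(outside, mid, lo)
        hi = np.where(outside, hi, mid)
    t_hit = 0.5 * (lo + hi)
    points = np.full((len(d), 3), np.nan)
    points[idx] = o[None, :] + t_hit[:, None] * dh
    return hit.reshape(dirs.shape[:-1]), points.reshape(dirs.shape)


@dataclass
class StereoPair:
    """Rendered left/right images plus per-pixel geometry for oracle tests.

    ``meta[eye]`` holds, per pixel: ``hit`` mask, surface ``point`` (mm,
    a surface-point identifier usable for correspondence checks),
    ``normal``, and the environment ``lookup`` direction actually used.
    """

    left: np.ndarray  # (H, W, 3) float in [0, 1]
    right: np.ndarray
    condition: str
    meta: dict

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right images must share dimensions")
        if self.condition not in BINOCULAR_CONDITIONS:
            raise ValueError(f"condition must be one of {BINOCULAR_CONDITIONS}")


def lookup_direction(scene: Scene, P: np.ndarray, n: np.ndarray, eye: str, condition: str) -> np.ndarray:
    """Environment lookup direction at surface point(s) P for one eye.

    This is the single place where the four conditions differ: the choice
    of the eye whose reflected ray indexes the environment.
    """
    if condition in ("mirror", "flat"):
        lookup_eye = eye
    elif condition == "painted":
        lookup_eye = "cyclopean"
    elif condition == "anti_mirror":
        lookup_eye = {"left": "right", "right": "left"}[eye]
    else:
        raise ValueError(f"unknown condition {condition!r}")
    E = scene.eye(lookup_eye)
    V = E[None, :] - P.reshape(-1, 3)
    V = V / np.linalg.norm(V, axis=-1, keepdims=True)
    nf = n.reshape(-1, 3)
    ndv = np.sum(nf * V, axis=-1)
    front = ndv > 0
    omega = np.full_like(V, np.nan)
    if front.any():
        omega[front] = reflect(V[front], nf[front])
    return omega.reshape(P.shape)


def _render_eye(scene: Scene, eye: str, condition: str) -> dict:
    E = scene.eye(eye)
    dirs = _camera_rays(scene, E)
    hit, P = _intersect(scene.potato, E, dirs)
    img = np.zeros((scene.image_px, scene.image_px, 3))
    normal = np.full_like(P, np.nan)
    omega = np.full_like(P, np.nan)
    if hit.any():
        Ph = P[hit]
        nh = scene.potato.normals(Ph)
        om = lookup_direction(scene, Ph, nh, eye, condition)
        # grazing points can be back-facing w.r.t. a *different* lookup eye
        # (painted / anti-mirror); those samples are excluded from the image
        valid = np.isfinite(om[:, 0])
        colors = np.zeros_like(om)
        colors[valid] = scene.env.sample(om[valid])
        img[hit] = colors
        normal[hit] = nh
        omega[hit] = om
        hit = hit.copy()
        hit[hit] = valid
    return {"image": img, "hit": hit, "point": P, "normal": normal, "lookup": omega}


def render_condition(scene: Scene, condition: str, seed: int = 0) -> StereoPair:
    """Render the stereo pair for one of the four binocular conditions.

    All conditions image the object from the true eye positions; only the
    environment-lookup rule differs.  ``flat`` renders the mirror pair and
    duplicates one eye's image into both channels; the eye is chosen by a
    seeded coin flip and recorded in ``meta['flat_source_eye']``.
    """
    if condition not in BINOCULAR_CONDITIONS:
        raise ValueError(f"condition must be one of {BINOCULAR_CONDITIONS}")
    base = "mirror" if condition == "flat" else condition
    left = _render_eye(scene, "left", base)
    right = _render_eye(scene, "right", base)
    meta = {"left": left, "right": right}
    if condition == "flat":
        source = "left" if np.random.default_rng(seed).integers(2) == 0 else "right"
        meta["flat_source_eye"] = source
        img = meta[source]["image"]
        return StereoPair(left=img.copy(), right=img.copy(), condition=condition, meta=meta)
    return StereoPair(left=left["image"], right=right["image"], condition=condition, meta=meta)


# ---------------------------------------------------------------------------
# monocular (layered) rendering
# ---------------------------------------------------------------------------

@dataclass
class LayeredImage:
    """Separable diffuse and specular layers sharing one silhouette."""

    diffuse: np.ndarray   # (H, W, 3)
    specular: np.ndarray  # (H, W, 3)
    silhouette: np.ndarray  # (H, W) bool


def render_layers(
    scene: Scene,
    eye: str = "cyclopean",
    light_dir: tuple[float, float, float] = (0.4, 0.5, 0.75),
    albedo: tuple[float, float, float] = (0.55, 0.45, 0.35),
    ambient: float = 0.25,
    k_specular: float = 0.7,
) -> LayeredImage:
    """Render separable Lambertian-diffuse and mirror-specular layers.

    The split makes the highlight-rotation manipulation exactly
    reproducible: the specular layer is the environment reflection, the
    diffuse layer a Lambertian base under a directional light plus ambient.
    """
    view = _render_eye(scene, eye, "mirror")
    hit = view["hit"]
    L = np.asarray(light_dir, dtype=float)
    L /= np.linalg.norm(L)
    diffuse = np.zeros_like(view["image"])
    if hit.any():
        lam = np.clip(view["normal"][hit] @ L, 0.0, None)
        shade = ambient + (1.0 - ambient) * lam
        diffuse[hit] = shade[:, None] * np.asarray(albedo)[None, :]
    specular = k_specular * view["image"]
    specular[~hit] = 0.0
    return LayeredImage(diffuse=diffuse, specular=specular, silhouette=hit)


def make_monocular_pair(layers: LayeredImage, rotation_deg: float = 45.0) -> tuple[np.ndarray, np.ndarray]:
    """Composite glossy and matte images from diffuse + specular layers.

    glossy = diffuse + specular in place; matte = diffuse + the specular
    layer rotated ``rotation_deg`` about the image center and masked to the
    object silhouette.  Both images share the silhouette exactly.  A
    rotation that moves the entire highlight off the silhouette raises a
    warning (the matte image then carries no specular energy).
    """
    glossy = np.clip(layers.diffuse + layers.specular, 0.0, 1.0)
    if rotation_deg == 0:
        return glossy, glossy.copy()
    rot = ndimage.rotate(
        layers.specular, angle=rotation_deg, axes=(1, 0), reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    rot = np.clip(rot, 0.0, None)
    rot[~layers.silhouette] = 0.0
    if layers.specular[layers.silhouette].sum() > 0 and rot[layers.silhouette].sum() == 0:
        warnings.warn("rotated highlight fell entirely outside the silhouette", stacklevel=2)
    matte = np.clip(layers.diffuse + rot, 0.0, 1.0)
    return glossy, matte
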