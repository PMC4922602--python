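"""Procedural equirectangular environment maps.

The renderer treats the illumination environment as located at optical
infinity, so radiance is a function of direction only.  Maps are stored as
equirectangular (latitude-longitude) RGB images and sampled bilinearly with
longitude wrap-around.  Three procedural families are provided in place of
photographic light probes: a smooth color gradient, a gradient with seeded
Gaussian blobs (crudely mimicking localized light sources), and colored
longitude bands.  All are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnvironmentMap", "make_envmap", "ENVMAP_KINDS"]

ENVMAP_KINDS = ("gradient", "blobs", "bands")


@dataclass(frozen=True)
class EnvironmentMap:
    """Equirectangular radiance map: rows span latitude, columns longitude."""

    data: np.ndarray  # (H, W, 3) float in [0, 1]
    name: str = "envmap"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("environment map must be an (H, W, 3) array")

    def sample(self, dirs: np.ndarray) -> np.ndarray:
        """Bilinearly sample radiance for unit direction vectors.

        Parameters
        ----------
        dirs : (..., 3) array of unit vectors.

        Returns
        -------
        (..., 3) RGB radiance.
        """
        d = np.asarray(dirs, dtype=float)
        shape = d.shape[:-1]
        d = d.reshape(-1, 3)
        h, w, _ = self.data.shape
        lon = np.arctan2(d[:, 1], d[:, 0])  # (-pi, pi]
        lat = np.arcsin(np.clip(d[:, 2], -1.0, 1.0))  # [-pi/2, pi/2]
        # continuous pixel coordinates; longitude wraps, latitude clamps
        x = (lon + np.pi) / (2 * np.pi) * w - 0.5
        y = (np.pi / 2 - lat) / np.pi * h - 0.5
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx = (x - x0)[:, None]
        fy = (y - y0)[:, None]
        x0w = np.mod(x0, w)
        x1w = np.mod(x0 + 1, w)
        y0c = np.clip(y0, 0, h - 1)
        y1c = np.clip(y0 + 1, 0, h - 1)
        img = self.data
        out = (
            img[y0c, x0w] * (1 - fx) * (1 - fy)
            + img[y0c, x1w] * fx * (1 - fy)
            + img[y1c, x0w] * (1 - fx) * fy
            + img[y1c, x1w] * fx * fy
        )
        return out.reshape(*shape, 3)


def _dir_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    lon = (np.arange(w) + 0.5) / w * 2 * np.pi - np.pi
    lat = np.pi / 2 - (np.arange(h) + 0.5) / h * np.pi
    lon_g, lat_g = np.meshgrid(lon, lat)
    x = np.cos(lat_g) * np.cos(lon_g)
    y = np.cos(lat_g) * np.sin(lon_g)
    z = np.sin(lat_g)
    return x, y, z


def make_envmap(kind: str = "blobs", seed: int = 0, shape: tuple[int, int] = (128, 256)) -> EnvironmentMap:
    """Build a procedural environment map.

    kind one of ``gradient`` (smooth RGB sky/ground gradient), ``blobs``
    (gradient plus seeded Gaussian light blobs) or ``bands`` (colored
    longitude stripes).
    """
    if kind not in ENVMAP_KINDS:
        raise ValueError(f"unknown environment map kind {kind!r}; choose from {ENVMAP_KINDS}")
    rng = np.random.default_rng(seed)
    x, y, z = _dir_grid(shape)
    img = np.empty((*shape, 3), dtype=float)

    # smooth base gradient used by all kinds
    img[..., 0] = 0.5 + 0.35 * z + 0.1 * x
    img[..., 1] = 0.45 + 0.3 * z - 0.1 * y
    img[..., 2] = 0.55 + 0.4 * z
    if kind == "gradient":
        pass
    elif kind == "blobs":
        n_blobs = 8
        for _ in range(n_blobs):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            width = rng.uniform(0.08, 0.35)
            color = rng.uniform(0.2, 1.0, size=3)
            cosang = x * v[0] + y * v[1] + z * v[2]
            bump = np.exp((cosang - 1.0) / width)
            img += bump[..., None] * color
    elif kind == "bands":
        lon = np.arctan2(y, x)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        freq = rng.integers(2, 5, size=3)
        for c in range(3):
            img[..., c] += 0.3 * np.sin(freq[c] * lon + phase[c])
    img -= img.min()
    img /= img.max()
    return EnvironmentMap(data=img, name=f"{kind}-{seed}")
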