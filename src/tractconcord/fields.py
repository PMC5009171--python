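"""Dense 2D displacement fields over a slice grid.

Conventions (used package-wide): pixel ``(i, j)`` has its center at
world position ``((i + 0.5) * spacing, (j + 0.5) * spacing)`` in mm.
A field stores the displacement ``u`` such that the represented map is
``T(x) = x + u(x)``.  Images are warped by *pull-back*:
``out(x) = img(T(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def pixel_centers_mm(shape: tuple[int, int], spacing: float) -> np.ndarray:
    """Return an ``(H, W, 2)`` array of pixel-center world coordinates."""
    ii, jj = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing,
        (np.arange(shape[1]) + 0.5) * spacing,
        indexing="ij",
    )
    return np.stack([ii, jj], axis=-1)


@dataclass
class DisplacementField2D:
    """Smooth dense displacement field for one slice, in mm.

    Attributes
    ----------
    u : ndarray, shape (H, W, 2)
        Displacement sampled at pixel centers.
    spacing : float
        Isotropic pixel size in mm.
    """

    u: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError("displacement array must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls, shape: tuple[int, int], spacing: float) -> "DisplacementField2D":
        return cls(np.zeros((*shape, 2)), spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.max(np.abs(self.u)) <= tol)

    # ------------------------------------------------------------------
    def evaluate(self, points_mm: np.ndarray) -> np.ndarray:
        """Bilinearly interpolate the displacement at world points (N, 2)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = pts / self.spacing - 0.5
        out = np.empty_like(pts)
        for c in range(2):
            out[:, c] = ndimage.map_coordinates(
                self.u[..., c], idx.T, order=1, mode="nearest"
            )
        return out

    def transform(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply ``T(x) = x + u(x)`` to world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts + self.evaluate(pts)

    def invert_points(
        self, points_mm: np.ndarray, n_iter: int = 80, tol: float = 1e-10
    ) -> np.ndarray:
        """Solve ``T(x) = p`` for ``x`` by damped fixed-point iteration."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        x = p.copy()
        for _ in range(n_iter):
            resid = p - self.transform(x)
            x = x + 0.7 * resid
            if np.max(np.abs(resid)) < tol:
                break
        return x

    # ------------------------------------------------------------------
    def warp_image(self, img: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Pull an image back through the field: ``out(x) = img(T(x))``."""
        grid = pixel_centers_mm(self.shape, self.spacing)
        coords = (grid + self.u) / self.spacing - 0.5
        return ndimage.map_coordinates(
            img.astype(float), [coords[..., 0], coords[..., 1]],
            order=order, mode="constant", cval=cval,
        )

    def compose(self, inner: "DisplacementField2D") -> "DisplacementField2D":
        """Return the field of ``T_self ∘ T_inner`` (inner applied first).

        ``w(x) = u_inner(x) + u_self(x + u_inner(x))``.
        """
        grid = pixel_centers_mm(self.shape, self.spacing).reshape(-1, 2)
        ui = inner.evaluate(grid)
        uo = self.evaluate(grid + ui)
        return DisplacementField2D((ui + uo).reshape(*self.shape, 2), self.spacing)

    def jacobian_determinant(self) -> np.ndarray:
        """Discrete Jacobian determinant of ``T`` at every pixel."""
        du = np.gradient(self.u, self.spacing, axis=(0, 1))
        # du[a][..., b] = d u_b / d x_a
        j00 = 1.0 + du[0][..., 0]
        j01 = du[0][..., 1]
        j10 = du[1][..., 0]
        j11 = 1.0 + du[1][..., 1]
        return j00 * j11 - j01 * j10

    def inverse(self, n_iter: int = 80, tol: float = 1e-10) -> "DisplacementField2D":
        """Approximate inverse field on the same grid."""
        grid = pixel_centers_mm(self.shape, self.spacing).reshape(-1, 2)
        x = self.invert_points(grid, n_iter=n_iter, tol=tol)
        return DisplacementField2D((x - grid).reshape(*self.shape, 2), self.spacing)


def smooth_random_field(
    shape: tuple[int, int],
    spacing: float,
    amplitude_mm: float,
    smoothness_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited random displacement, max norm scaled to ``amplitude_mm``.

    White noise smoothed by a Gaussian of characteristic length
    ``smoothness_mm``; returned as an (H, W, 2) array.
    """
    if amplitude_mm == 0:
        return np.zeros((*shape, 2))
    sigma_px = max(smoothness_mm / spacing, 1e-6)
    noise = rng.standard_normal((*shape, 2))
    for c in range(2):
        noise[..., c] = ndimage.gaussian_filter(noise[..., c], sigma_px)
    norms = np.linalg.norm(noise, axis=-1)
    peak = norms.max()
    if peak == 0:
        return np.zeros((*shape, 2))
    return noise * (amplitude_mm / peak)
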