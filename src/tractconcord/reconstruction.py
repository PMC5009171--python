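"""3D reconstruction of deformed serial sections.

Stages: (1) landmark-based 2D affine registration of each slice to its
block face, (2) stacking into an initial volume, (3) iterative
multivariate nonlinear refinement in which each slice is driven by a
weighted demons-style force toward its two neighbouring slices and the
matching reference-volume slice.  Anchoring to the reference is what
prevents curved structures from straightening when slices are aligned
only to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateLandmarksError, DivergenceError
from .fields import DisplacementField2D, pixel_centers_mm
from .phantom import SliceStack


# ----------------------------------------------------------------------
# affine
# ----------------------------------------------------------------------
@dataclass
class Affine2D:
    """6-DOF planar affine transform ``x -> M x + t`` (mm)."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateLandmarksError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "Affine2D":
        inv = np.linalg.inv(self.matrix)
        return Affine2D(inv, -inv @ self.translation)


def fit_affine_landmarks(src_points: np.ndarray, dst_points: np.ndarray):
    """Least-squares 6-DOF affine mapping ``src -> dst``.

    Returns ``(Affine2D, residual_rms_mm)``.  Requires at least three
    non-collinear pairs.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise DegenerateLandmarksError("landmark arrays must both be (N, 2)")
    if len(src) < 3:
        raise DegenerateLandmarksError("need at least 3 landmark pairs")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise DegenerateLandmarksError("landmarks are collinear")
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    aff = Affine2D(params[:2].T, params[2])
    resid = aff.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return aff, rms


def fit_stack_affines(stack: SliceStack) -> list[Affine2D]:
    """Fit the slice-to-block-face affine for every slice from its landmarks."""
    return [fit_affine_landmarks(lm[:, 0:2], lm[:, 2:4])[0] for lm in stack.landmarks]


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------
def _resample_slice(
    img: np.ndarray,
    block_to_slice: Affine2D,
    v: DisplacementField2D | None,
    spacing: float,
    with_validity: bool = False,
    order: int = 1,
):
    """Evaluate ``img(A(T_v(x)))`` on the block-face grid (pull-back).

    With ``with_validity`` also returns the mask of pixels whose sample
    point fell inside the source image (out-of-view pixels read 0).
    """
    grid = pixel_centers_mm(img.shape, spacing)
    p = grid.reshape(-1, 2)
    if v is not None:
        p = p + v.evaluate(p)
    q = block_to_slice.apply(p)
    coords = (q / spacing - 0.5).reshape(*img.shape, 2)
    # snap coordinates that are epsilon outside the grid (identity maps
    # must round-trip exactly instead of reading the zero padding)
    for ax, size in enumerate(img.shape):
        c = coords[..., ax]
        np.copyto(c, 0.0, where=(c > -1e-6) & (c < 0.0))
        np.copyto(c, size - 1.0, where=(c > size - 1.0) & (c < size - 1.0 + 1e-6))
    out = ndimage.map_coordinates(
        img.astype(float), [coords[..., 0], coords[..., 1]], order=order,
        mode="constant", cval=0.0,
    )
    if not with_validity:
        return out
    valid = (
        (coords[..., 0] >= 0) & (coords[..., 0] <= img.shape[0] - 1)
        & (coords[..., 1] >= 0) & (coords[..., 1] <= img.shape[1] - 1)
    )
    return out, valid


def initial_reconstruct(stack: SliceStack, affines: list[Affine2D] | None = None,
                        order: int = 3) -> np.ndarray:
    """Affine-align every slice to its block face and stack into a volume."""
    if affines is None:
        affines = fit_stack_affines(stack)
    if len(affines) != stack.n_slices:
        raise ConfigurationError("one affine per slice is required")
    sp = stack.in_plane_spacing_mm
    aligned = [
        _resample_slice(sl, aff.inverse(), None, sp, order=order)
        for sl, aff in zip(stack.slices, affines)
    ]
    return np.stack(aligned, axis=2)


def sample_reference_slices(
    volume: np.ndarray, voxel_size_mm: float, positions_mm: np.ndarray
) -> list[np.ndarray]:
    """Sample axis-2 planes of a volume at the given world positions."""
    vol = np.asarray(volume, dtype=float)
    ii, jj = np.meshgrid(np.arange(vol.shape[0]), np.arange(vol.shape[1]), indexing="ij")
    out = []
    for z in positions_mm:
        zi = np.full_like(ii, z / voxel_size_mm - 0.5, dtype=float)
        out.append(ndimage.map_coordinates(
            vol, [ii.astype(float), jj.astype(float), zi], order=1, mode="nearest"))
    return out


# ----------------------------------------------------------------------
# nonlinear refinement
# ----------------------------------------------------------------------
@dataclass
class ReconConfig:
    """Settings for the iterative multivariate nonlinear refinement."""

    n_iterations: int = 20
    weight_reference: float = 0.5
    weight_neighbors: float = 0.25  # per neighbour
    smoothing_sigma_mm: float = 1.5  # fluid-like smoothing of each update
    field_smoothing_sigma_mm: float = 0.7  # diffusion regularization of the field
    inner_steps: int = 6  # demons steps per slice per outer iteration
    convergence_tol: float = 0.002  # mean update magnitude, mm
    force_gain: float = 8.0
    max_step_mm: float | None = None  # default: one pixel

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.weight_reference < 0 or self.weight_neighbors < 0:
            raise ConfigurationError("cost weights must be non-negative")
        if self.weight_reference + self.weight_neighbors <= 0:
            raise ConfigurationError("at least one cost weight must be positive")


@dataclass
class ReconResult:
    """Output of nonlinear refinement."""

    slices: list
    fields: list  # per-slice DisplacementField2D (nonlinear part, block frame)
    affines: list
    cost_history: list = dc_field(default_factory=list)
    n_iterations_run: int = 0

    @property
    def volume(self) -> np.ndarray:
        return np.stack(self.slices, axis=2)


def _demons_force(moving: np.ndarray, fixed: np.ndarray, spacing: float) -> np.ndarray:
    """Sum-of-squared-difference demons displacement (mm) pulling
    ``moving`` toward ``fixed``; symmetrized gradient for stability."""
    diff = fixed - moving
    gm = np.stack(np.gradient(moving, spacing), axis=-1)
    gf = np.stack(np.gradient(fixed, spacing), axis=-1)
    grad = 0.5 * (gm + gf)
    return grad * diff[..., None]


def refine_nonlinear(
    stack: SliceStack,
    reference_volume: np.ndarray,
    config: ReconConfig,
    affines: list[Affine2D] | None = None,
    reference_voxel_size_mm: float | None = None,
) -> ReconResult:
    """Iteratively align each slice to its neighbours and the reference.

    Per iteration and slice, a demons-style displacement update is
    computed from a weighted combination of forces toward the previous
    slice, the next slice (current estimates, updated in index order)
    and the corresponding reference slice; the update is smoothed with a
    Gaussian of ``smoothing_sigma_mm`` and composed onto the running
    per-slice field.  Stops after ``n_iterations`` or when the mean
    update magnitude drops below ``convergence_tol``.
    """
    config.validate()
    sp = stack.in_plane_spacing_mm
    rvs = reference_voxel_size_mm if reference_voxel_size_mm is not None else sp
    if affines is None:
        affines = fit_stack_affines(stack)
    inv_affines = [a.inverse() for a in affines]

    ref = np.asarray(reference_volume, dtype=float)
    if ref.ndim == 3:
        ref_slices = sample_reference_slices(ref, rvs, stack.slice_positions_mm)
    else:
        raise ConfigurationError("reference_volume must be a 3D array")
    if ref_slices[0].shape != stack.slices[0].shape:
        raise ConfigurationError("reference grid does not match the slice grid")

    n = stack.n_slices
    fields = [DisplacementField2D.identity(s.shape, sp) for s in stack.slices]
    aligned, valid = [], []
    for sl, ia in zip(stack.slices, inv_affines):
        a, vmask = _resample_slice(sl, ia, None, sp, with_validity=True)
        aligned.append(a)
        valid.append(vmask)
    sigma_px = config.smoothing_sigma_mm / sp
    field_sigma_px = config.field_smoothing_sigma_mm / sp
    max_step = config.max_step_mm if config.max_step_mm is not None else sp

    cost_history = []
    n_bad = 0
    it_run = 0
    for it in range(config.n_iterations):
        total_update = 0.0
        total_cost = 0.0
        for i in range(n):
            terms = [(ref_slices[i], config.weight_reference)]
            if i > 0:
                terms.append((aligned[i - 1], config.weight_neighbors))
            if i < n - 1:
                terms.append((aligned[i + 1], config.weight_neighbors))
            wsum = sum(w for _, w in terms)
            cost_i = sum(
                (w / wsum) * float(np.mean(((aligned[i] - fixed) ** 2)[valid[i]]))
                for fixed, w in terms if w > 0
            )
            # "computing a warp field" for this slice = a short demons
            # registration against the fixed targets, not one gradient step
            for _ in range(config.inner_steps):
                upd = np.zeros((*aligned[i].shape, 2))
                for fixed, w in terms:
                    if w == 0:
                        continue
                    upd += (w / wsum) * _demons_force(aligned[i], fixed, sp)
                upd[~valid[i]] = 0.0  # out-of-view pixels carry no information
                upd *= config.force_gain
                for c in range(2):
                    upd[..., c] = ndimage.gaussian_filter(upd[..., c], sigma_px)
                norms = np.linalg.norm(upd, axis=-1)
                over = norms > max_step
                if over.any():
                    upd[over] *= (max_step / norms[over])[:, None]
                composed = fields[i].compose(DisplacementField2D(upd, sp))
                if field_sigma_px > 0:
                    vu = composed.u
                    for c in range(2):
                        vu[..., c] = ndimage.gaussian_filter(vu[..., c], field_sigma_px)
                    composed = DisplacementField2D(vu, sp)
                fields[i] = composed
                aligned[i], valid[i] = _resample_slice(
                    stack.slices[i], inv_affines[i], fields[i], sp, with_validity=True)
                total_update += float(np.mean(np.linalg.norm(upd, axis=-1))) \
                    / config.inner_steps
            total_cost += cost_i
        it_run = it + 1
        mean_update = total_update / n
        mean_cost = total_cost / n
        if cost_history and mean_cost > cost_history[-1] * (1 + 1e-3):
            n_bad += 1
            if n_bad >= 3:
                raise DivergenceError(
                    f"cost increased for 3 consecutive iterations "
                    f"(iteration {it_run}, cost {mean_cost:.6g})"
                )
        else:
            n_bad = 0
        cost_history.append(mean_cost)
        if mean_update < config.convergence_tol:
            break

    return ReconResult(
        slices=aligned,
        fields=fields,
        affines=affines,
        cost_history=cost_history,
        n_iterations_run=it_run,
    )


# ----------------------------------------------------------------------
# error metrics
# ----------------------------------------------------------------------
def landmark_errors(
    stack: SliceStack,
    affines: list[Affine2D],
    fields: list[DisplacementField2D] | None = None,
) -> np.ndarray:
    """Per-landmark residuals (mm) of the recovered block->slice map.

    The recovered map sends block-face coordinates through the running
    nonlinear field (if given) and the inverse fitted affine; a perfect
    reconstruction returns every landmark to its source position in the
    deformed slice.
    """
    errs = []
    for i, lm in enumerate(stack.landmarks):
        dst = lm[:, 2:4]
        src = lm[:, 0:2]
        p = dst
        if fields is not None:
            p = p + fields[i].evaluate(p)
        p = affines[i].inverse().apply(p)
        errs.append(np.linalg.norm(p - src, axis=1))
    return np.concatenate(errs)


def centerline_bow(volume: np.ndarray, spacing_mm: float,
                   percentile: float = 75.0) -> float:
    """Bow (mm) of the bright structure's per-slice centroid trajectory:
    mean in-plane distance of centroids from the chord joining the first
    and last slice centroids.  Serves as the curvature statistic for
    banana-problem checks."""
    vol = np.asarray(volume, dtype=float)
    cents = []
    for k in range(vol.shape[2]):
        sl = vol[:, :, k]
        w = np.clip(sl - np.percentile(sl, percentile), 0, None)
        if w.sum() <= 0:
            cents.append(np.array([np.nan, np.nan]))
            continue
        grid = pixel_centers_mm(sl.shape, spacing_mm)
        cents.append((w[..., None] * grid).sum(axis=(0, 1)) / w.sum())
    cents = np.asarray(cents)
    keep = ~np.isnan(cents[:, 0])
    cents = cents[keep]
    if len(cents) < 3:
        return 0.0
    # deviation of the centroid trajectory from the straight line through
    # the end slices (a straightened structure has zero bow)
    frac = np.linspace(0.0, 1.0, len(cents))[:, None]
    line = cents[0] + frac * (cents[-1] - cents[0])
    return float(np.mean(np.linalg.norm(cents - line, axis=1)))


def reconstruction_error(
    result: ReconResult,
    stack: SliceStack,
    reference_volume: np.ndarray,
    reference_voxel_size_mm: float | None = None,
) -> dict:
    """Quantify reconstruction quality against the synthetic ground truth."""
    sp = stack.in_plane_spacing_mm
    rvs = reference_voxel_size_mm if reference_voxel_size_mm is not None else sp
    errs = landmark_errors(stack, result.affines, result.fields)
    ref_slices = sample_reference_slices(
        np.asarray(reference_volume, dtype=float), rvs, stack.slice_positions_mm)
    rms = [
        float(np.sqrt(np.mean((a - r) ** 2)))
        for a, r in zip(result.slices, ref_slices)
    ]
    ref_vol = np.stack(ref_slices, axis=2)
    bow_ref = centerline_bow(ref_vol, sp)
    bow_rec = centerline_bow(result.volume, sp)
    ratio = bow_rec / bow_ref if bow_ref > 0 else np.nan
    return {
        "mean_landmark_error_mm": float(np.mean(errs)),
        "p95_landmark_error_mm": float(np.percentile(errs, 95)),
        "per_slice_intensity_rms": rms,
        "curvature_ratio": float(ratio),
    }
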