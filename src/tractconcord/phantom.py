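"""Synthetic phantoms: decussating tubular tracts, fiber fields, and
simulated serial sectioning with per-slice deformations.

World conventions: coordinates in mm, voxel indices 0-based, the center
of voxel ``i`` at ``(i + 0.5) * voxel_size``.  Axis 0 is left-right
(midline plane at half the x extent), axis 2 is the sectioning axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from ._rng import substream
from .errors import ConfigurationError, DeformationError, SectioningError
from .fields import DisplacementField2D, pixel_centers_mm, smooth_random_field

# roi_labels values
BACKGROUND = 0
DENTATE_LEFT = 1
PEDUNCLE_LEFT = 2
DECUSSATION = 3  # shared by both tracts
DENTATE_RIGHT = 4
PEDUNCLE_RIGHT = 5

ROI_LABELS = {
    "left": {"dentate": DENTATE_LEFT, "peduncle": PEDUNCLE_LEFT, "decussation": DECUSSATION},
    "right": {"dentate": DENTATE_RIGHT, "peduncle": PEDUNCLE_RIGHT, "decussation": DECUSSATION},
}

_MAX_POPULATIONS = 3
_TOTAL_FRACTION = 0.85


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class PhantomConfig:
    """Parameters of the synthetic decussating-tract phantom."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 1.0
    tube_radius_mm: float = 2.0
    arc_params: dict | None = None  # {"left": (5, 3) mm control points}; right mirrored
    crossing_zone_extent_mm: float = 6.0
    dispersion_kappa: float = 100.0
    rng_seed: int = 0
    dentate_arc_fraction: float = 0.18  # fraction of seed->crossing arc labelled dentate
    texture_amplitude: float = 0.4

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 axes, each >= 16 voxels")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if self.tube_radius_mm < self.voxel_size_mm:
            raise ConfigurationError("tube_radius_mm must be at least one voxel")
        if not self.dispersion_kappa > 0:
            raise ConfigurationError("dispersion_kappa must be positive")
        if self.crossing_zone_extent_mm <= 0:
            raise ConfigurationError("crossing_zone_extent_mm must be positive")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size_mm

    def control_points(self, side: str) -> np.ndarray:
        """Centerline control points for one side (5 x 3, mm)."""
        if self.arc_params is not None and side in self.arc_params:
            pts = np.asarray(self.arc_params[side], dtype=float)
        else:
            lx, ly, lz = self.extent_mm
            # the two tracts mingle at the crossing but their centerlines
            # pass at a small y offset, as decussating bundles do; the
            # right tract is the point reflection of the left
            left = np.array(
                [
                    [0.28 * lx, 0.50 * ly, 0.12 * lz],
                    [0.30 * lx, 0.42 * ly, 0.30 * lz],
                    [0.50 * lx, 0.46 * ly, 0.50 * lz],
                    [0.70 * lx, 0.58 * ly, 0.70 * lz],
                    [0.72 * lx, 0.50 * ly, 0.88 * lz],
                ]
            )
            if side == "left":
                pts = left
            else:
                pts = left.copy()
                pts[:, 0] = lx - pts[:, 0]
                pts[:, 1] = ly - pts[:, 1]
        if pts.shape != (5, 3):
            raise ConfigurationError("arc control points must have shape (5, 3)")
        return pts


@dataclass
class FiberField:
    """Up to three fiber populations per voxel on a 3D grid.

    ``orientations[i, j, k, p]`` is a unit axis (or zeros if population
    ``p`` is absent); ``fractions`` are sorted descending per voxel and
    sum to at most 1.  ``kappa`` is the shared Watson concentration.
    """

    orientations: np.ndarray  # (nx, ny, nz, 3, 3)
    fractions: np.ndarray  # (nx, ny, nz, 3)
    kappa: float
    voxel_size_mm: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    def n_populations(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=-1)


@dataclass
class Phantom:
    """Ground-truth tract geometry plus everything tracking/evaluation needs."""

    config: PhantomConfig
    tract_mask_left: np.ndarray
    tract_mask_right: np.ndarray
    roi_labels: np.ndarray
    seed_mask_left: np.ndarray
    seed_mask_right: np.ndarray
    target_mask_left: np.ndarray
    target_mask_right: np.ndarray
    exclusion_mask: np.ndarray
    fiber_field: FiberField
    intensity_volume: np.ndarray
    centerlines: dict = field(default_factory=dict)  # side -> dict(points, tangents, arclen)

    @property
    def voxel_size_mm(self) -> float:
        return self.config.voxel_size_mm

    @property
    def seed_mask(self) -> np.ndarray:
        return self.seed_mask_left | self.seed_mask_right

    @property
    def target_mask(self) -> np.ndarray:
        return self.target_mask_left | self.target_mask_right

    @property
    def tract_mask(self) -> np.ndarray:
        return self.tract_mask_left | self.tract_mask_right

    def seed_for(self, side: str) -> np.ndarray:
        return self.seed_mask_left if side == "left" else self.seed_mask_right

    def target_for(self, side: str) -> np.ndarray:
        # the "left" tract's own endpoint blob sits contralaterally by
        # construction, so each side targets its own centerline's end
        return self.target_mask_left if side == "left" else self.target_mask_right

    def reference_mask(self, side: str) -> np.ndarray:
        """Reference segmentation for one tract: its own tube plus the whole
        shared decussation (both tracts mingle there, so the full crossing
        is counted as reference for either side)."""
        own = self.tract_mask_left if side == "left" else self.tract_mask_right
        return own | (self.roi_labels == DECUSSATION)

    def roi_masks(self, side: str) -> dict[str, np.ndarray]:
        labels = ROI_LABELS[side]
        return {name: self.roi_labels == val for name, val in labels.items()}


# ----------------------------------------------------------------------
# phantom construction
# ----------------------------------------------------------------------
def _centerline(points: np.ndarray, n_samples: int = 800):
    """Cubic-spline centerline through 5 control points.

    Returns dense samples, unit tangents, cumulative arc length.
    """
    t = np.linspace(0.0, 1.0, len(points))
    spline = CubicSpline(t, points, axis=0)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = spline(ts)
    tan = spline(ts, 1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, tan, arclen


def voxel_centers_mm(grid_shape, voxel_size_mm) -> np.ndarray:
    axes = [(np.arange(n) + 0.5) * voxel_size_mm for n in grid_shape]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack(g, axis=-1)


def build_phantom(config: PhantomConfig) -> Phantom:
    """Construct the decussating two-tract phantom from its configuration."""
    config.validate()
    shape = tuple(int(n) for n in config.grid_shape)
    vs = config.voxel_size_mm
    x_mid = config.extent_mm[0] / 2.0

    sides = ("left", "right")
    lines = {}
    for side in sides:
        pts, tan, arclen = _centerline(config.control_points(side))
        sign = np.sign(pts[:, 0] - x_mid)
        sign = sign[sign != 0]
        n_cross = int(np.sum(np.diff(sign) != 0))
        if n_cross != 1:
            raise ConfigurationError(
                f"{side} centerline must cross the midline exactly once, got {n_cross}"
            )
        k_cross = int(np.argmin(np.abs(pts[:, 0] - x_mid)))
        lines[side] = {
            "points": pts,
            "tangents": tan,
            "arclen": arclen,
            "s_cross": arclen[k_cross],
        }
        if arclen[-1] < 6 * config.tube_radius_mm:
            raise ConfigurationError("grid too small for a non-degenerate arc")

    centers = voxel_centers_mm(shape, vs)
    flat = centers.reshape(-1, 3)

    dist, nearest, arcpos = {}, {}, {}
    for side in sides:
        tree = cKDTree(lines[side]["points"])
        d, idx = tree.query(flat)
        dist[side] = d.reshape(shape)
        nearest[side] = idx.reshape(shape)
        arcpos[side] = lines[side]["arclen"][idx].reshape(shape)

    r = config.tube_radius_mm
    tract = {side: dist[side] <= r for side in sides}

    # --- ROI labels -----------------------------------------------------
    in_zone = np.abs(centers[..., 0] - x_mid) <= config.crossing_zone_extent_mm / 2.0
    labels = np.zeros(shape, dtype=np.int8)
    for side, dent, ped in (
        ("left", DENTATE_LEFT, PEDUNCLE_LEFT),
        ("right", DENTATE_RIGHT, PEDUNCLE_RIGHT),
    ):
        s_cross = lines[side]["s_cross"]
        s = arcpos[side]
        dentate = tract[side] & (s <= config.dentate_arc_fraction * s_cross) & ~in_zone
        peduncle = tract[side] & (s > config.dentate_arc_fraction * s_cross) \
            & (s <= s_cross) & ~in_zone
        labels[dentate] = dent
        labels[peduncle] = ped
    labels[(tract["left"] | tract["right"]) & in_zone] = DECUSSATION

    # --- seed / target / exclusion masks --------------------------------
    blobs = {}
    for side in sides:
        pts = lines[side]["points"]
        d0 = np.linalg.norm(flat - pts[0], axis=1).reshape(shape)
        d1 = np.linalg.norm(flat - pts[-1], axis=1).reshape(shape)
        blobs[side] = {
            "seed": (d0 <= 1.2 * r) & tract[side],
            "target": (d1 <= 1.2 * r) & tract[side],
        }

    z_cross = lines["left"]["points"][np.argmin(np.abs(lines["left"]["points"][:, 0] - x_mid)), 2]
    exclusion = (np.abs(centers[..., 0] - x_mid) <= 0.55 * vs) & (
        centers[..., 2] <= z_cross - config.crossing_zone_extent_mm
    )

    for side in sides:
        for key in ("seed", "target"):
            if not blobs[side][key].any():
                raise ConfigurationError(f"{side} {key} mask is empty; grid too small")
            if (blobs[side][key] & exclusion).any():
                raise ConfigurationError("exclusion mask intersects seed/target")

    # --- fiber field -----------------------------------------------------
    # sharp falloff keeps the wrong-population probability low away from
    # the exact crossing point while both populations stay present
    sigma_f = 0.25 * r
    orientations = np.zeros((*shape, _MAX_POPULATIONS, 3))
    fractions = np.zeros((*shape, _MAX_POPULATIONS))

    weight = {side: np.exp(-(dist[side] ** 2) / (2 * sigma_f**2)) for side in sides}
    any_tract = tract["left"] | tract["right"]
    idxs = np.argwhere(any_tract)
    for ii, jj, kk in idxs:
        active = []
        for side in sides:
            # a population is present if the voxel is in that tube, or if it
            # sits in the crossing zone where both tracts' fibres mingle
            if tract[side][ii, jj, kk] or (in_zone[ii, jj, kk] and any_tract[ii, jj, kk]):
                axis = lines[side]["tangents"][nearest[side][ii, jj, kk]]
                active.append((weight[side][ii, jj, kk], axis))
        active.sort(key=lambda wa: -wa[0])
        total_w = sum(w for w, _ in active)
        for p, (w, axis) in enumerate(active[:_MAX_POPULATIONS]):
            orientations[ii, jj, kk, p] = axis
            fractions[ii, jj, kk, p] = _TOTAL_FRACTION * w / total_w

    fiber_field = FiberField(orientations, fractions, float(config.dispersion_kappa), vs)

    # --- intensity volume -------------------------------------------------
    sigma_i = 0.8 * r
    profile = np.maximum(
        np.exp(-(dist["left"] ** 2) / (2 * sigma_i**2)),
        np.exp(-(dist["right"] ** 2) / (2 * sigma_i**2)),
    )
    rng = substream(config.rng_seed, "texture")
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
    # two texture scales: the fine one carries the gradient information
    # that landmark detection and nonlinear registration rely on
    texture = coarse / coarse.std() + 0.5 * fine / fine.std()
    intensity = 0.8 * profile + config.texture_amplitude * texture

    return Phantom(
        config=config,
        tract_mask_left=tract["left"],
        tract_mask_right=tract["right"],
        roi_labels=labels,
        seed_mask_left=blobs["left"]["seed"],
        seed_mask_right=blobs["right"]["seed"],
        target_mask_left=blobs["left"]["target"],
        target_mask_right=blobs["right"]["target"],
        exclusion_mask=exclusion,
        fiber_field=fiber_field,
        intensity_volume=intensity,
        centerlines=lines,
    )


# ----------------------------------------------------------------------
# serial sectioning
# ----------------------------------------------------------------------
@dataclass
class SliceStack:
    """Ordered 2D sections with block-face references and landmarks.

    ``landmarks[i]`` is an ``(L, 4)`` array with columns
    ``x_src, y_src, x_dst, y_dst`` (mm): source coordinates live in the
    (possibly deformed) slice, destination coordinates in its block face.
    ``true_fields[i]`` stores the exact synthetic warp ``T`` such that
    ``slice(x) = block_face(T(x))``; identity for undeformed stacks.
    """

    slices: list
    block_faces: list
    landmarks: list
    in_plane_spacing_mm: float
    slice_spacing_mm: float
    true_fields: list
    slice_positions_mm: np.ndarray = None

    def __post_init__(self):
        n = len(self.slices)
        if not (len(self.block_faces) == len(self.landmarks) == len(self.true_fields) == n):
            raise ValueError("slices, block_faces, landmarks, true_fields must align")
        for lm in self.landmarks:
            if lm.shape[0] < 6:
                raise ValueError("each slice needs at least 6 landmark pairs")
        if self.slice_positions_mm is None:
            self.slice_positions_mm = (np.arange(n) + 0.5) * self.slice_spacing_mm

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def restack(self, which: str = "slices") -> np.ndarray:
        imgs = getattr(self, which)
        return np.stack(imgs, axis=2)


def _greedy_peaks(score: np.ndarray, taken: list, need: int, min_distance: int):
    order = np.argsort(score.ravel())[::-1]
    coords = np.column_stack(np.unravel_index(order, score.shape))
    picked = list(taken)
    out = []
    for c in coords:
        if all(max(abs(c[0] - p[0]), abs(c[1] - p[1])) >= min_distance for p in picked):
            picked.append(c)
            out.append(c)
            if len(out) >= need:
                break
    return out


def detect_landmarks(img: np.ndarray, spacing_mm: float, min_count: int = 6,
                     max_count: int = 12, min_distance_px: int = 3) -> np.ndarray:
    """Pick >= ``min_count`` well-separated corner-like points on an image.

    Harris corner responses first; high-gradient points fill in if the
    image is too bland.  Returns (L, 4) landmark rows with src == dst.
    """
    from skimage.feature import corner_harris, corner_peaks

    resp = corner_harris(img.astype(float), sigma=1.0)
    peaks = corner_peaks(resp, min_distance=min_distance_px,
                         threshold_rel=0.01, num_peaks=max_count)
    pts = [tuple(p) for p in peaks]
    if len(pts) < min_count:
        gm = ndimage.gaussian_gradient_magnitude(img.astype(float), 1.0)
        pts += [tuple(p) for p in
                _greedy_peaks(gm, pts, min_count - len(pts), min_distance_px)]
    coords = (np.asarray(pts, dtype=float) + 0.5) * spacing_mm
    return np.hstack([coords, coords])


def simulate_sectioning(
    volume: np.ndarray,
    voxel_size_mm: float,
    section_thickness_mm: float,
    retention_interval: int,
    axis: int = 2,
) -> SliceStack:
    """Cut a volume into sections of ``section_thickness_mm`` and keep
    every ``retention_interval``-th one.

    Retained-slice spacing is ``thickness * interval``; block faces are
    exact copies of the undeformed slices and true fields start as
    identity.
    """
    if retention_interval < 1 or int(retention_interval) != retention_interval:
        raise SectioningError("retention_interval must be a positive integer")
    if section_thickness_mm <= 0:
        raise SectioningError("section_thickness_mm must be positive")
    vol = np.moveaxis(np.asarray(volume, dtype=float), axis, 2)
    extent = vol.shape[2] * voxel_size_mm
    spacing = section_thickness_mm * retention_interval
    positions = []
    k = 0
    while True:
        z = k * spacing + section_thickness_mm / 2.0
        if z >= extent:
            break
        positions.append(z)
        k += 1
    if not positions or spacing > extent:
        raise SectioningError(
            f"slice spacing {spacing} mm exceeds volume extent {extent} mm"
        )
    positions = np.asarray(positions)

    ii, jj = np.meshgrid(np.arange(vol.shape[0]), np.arange(vol.shape[1]), indexing="ij")
    slices = []
    for z in positions:
        zi = np.full_like(ii, z / voxel_size_mm - 0.5, dtype=float)
        sl = ndimage.map_coordinates(vol, [ii.astype(float), jj.astype(float), zi],
                                     order=1, mode="nearest")
        slices.append(sl)

    block_faces = [s.copy() for s in slices]
    landmarks = [detect_landmarks(bf, voxel_size_mm) for bf in block_faces]
    fields = [DisplacementField2D.identity(s.shape, voxel_size_mm) for s in slices]
    return SliceStack(
        slices=slices,
        block_faces=block_faces,
        landmarks=landmarks,
        in_plane_spacing_mm=voxel_size_mm,
        slice_spacing_mm=spacing,
        true_fields=fields,
        slice_positions_mm=positions,
    )


# ----------------------------------------------------------------------
# per-slice deformation
# ----------------------------------------------------------------------
def _random_affine_displacement(shape, spacing, amplitude_mm, rng):
    grid = pixel_centers_mm(shape, spacing)
    center = np.asarray(shape) * spacing / 2.0
    angle = np.deg2rad(rng.uniform(-0.4, 0.4) * amplitude_mm)
    scale = 1.0 + rng.uniform(-0.004, 0.004) * amplitude_mm
    trans = rng.uniform(-0.15, 0.15, size=2) * amplitude_mm
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    rel = grid - center
    mapped = rel @ (scale * rot).T + center + trans
    return mapped - grid


def deform_stack(
    stack: SliceStack,
    amplitude_mm: float,
    smoothness_mm: float,
    seed: int,
    max_tries: int = 20,
    jacobian_floor: float = 0.1,
    interp_order: int = 3,
) -> SliceStack:
    """Warp every slice by an independent smooth random field composed
    with a small random affine.

    The combined per-slice displacement is rescaled so its maximum norm
    equals ``amplitude_mm``; fields whose Jacobian determinant dips to
    ``jacobian_floor`` or below are redrawn (folding would make the
    ground truth non-invertible).  Landmarks move consistently with the
    warp and ``true_fields`` stores the exact applied transforms.
    """
    if amplitude_mm < 0:
        raise DeformationError("amplitude_mm must be non-negative")
    sp = stack.in_plane_spacing_mm
    new_slices, new_landmarks, new_fields = [], [], []
    for i, base in enumerate(stack.block_faces):
        rng = substream(seed, f"warp-{i}")
        shape = base.shape
        if amplitude_mm == 0:
            fld = DisplacementField2D.identity(shape, sp)
        else:
            for attempt in range(max_tries):
                disp = _random_affine_displacement(shape, sp, amplitude_mm, rng)
                disp = disp + smooth_random_field(shape, sp, amplitude_mm, smoothness_mm, rng)
                peak = np.linalg.norm(disp, axis=-1).max()
                if peak > 0:
                    disp *= amplitude_mm / peak
                fld = DisplacementField2D(disp, sp)
                if fld.jacobian_determinant().min() > jacobian_floor:
                    break
            else:
                raise DeformationError(
                    f"slice {i}: could not draw a fold-free warp in {max_tries} tries"
                )
        total = stack.true_fields[i].compose(fld) \
            if not stack.true_fields[i].is_identity() else fld
        new_fields.append(total)
        new_slices.append(total.warp_image(base, order=interp_order)
                          if amplitude_mm > 0 else base.copy())

        lm = stack.landmarks[i].copy()
        dst = lm[:, 2:4]
        src = total.invert_points(dst, n_iter=200, tol=1e-12)
        resid = np.abs(total.transform(src) - dst).max()
        if resid > 1e-6:
            raise DeformationError(f"slice {i}: landmark inversion residual {resid:.2e}")
        lm[:, 0:2] = src
        new_landmarks.append(lm)

    return SliceStack(
        slices=new_slices,
        block_faces=[b.copy() for b in stack.block_faces],
        landmarks=new_landmarks,
        in_plane_spacing_mm=sp,
        slice_spacing_mm=stack.slice_spacing_mm,
        true_fields=new_fields,
        slice_positions_mm=stack.slice_positions_mm.copy(),
    )
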