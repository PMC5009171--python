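"""Probabilistic streamline tractography over a synthetic fiber field.

Semantics: streamlines are launched bidirectionally from jittered points
in every seed voxel; a branch terminates when it leaves the volume,
enters a voxel with no usable fiber population, exceeds the step budget,
or would turn more sharply than the curvature threshold allows (minimum
cosine between consecutive step directions).  Entering the exclusion
mask rejects the whole streamline; a streamline is accepted iff some
branch reaches the target mask, where it terminates.  Accepted
streamlines increment each visited voxel at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .errors import ConfigurationError, NormalizationError
from .phantom import FiberField, Phantom

# per-stream status / termination-reason codes used by the batch engine
_ACTIVE = 0
_TERM_OOB = 1
_TERM_CURVATURE = 2
_TERM_NO_POPULATION = 3
_TERM_MAX_STEPS = 4
_ACCEPTED = 5
_REJECTED_EXCLUSION = 6


def max_turn_angle_deg(curvature_threshold: float) -> float:
    """Maximum turning angle (degrees) allowed by a cosine threshold."""
    return float(np.degrees(np.arccos(curvature_threshold)))


@dataclass
class TrackingParams:
    """Streamline propagation parameters.

    Defaults follow the standard probabilistic-tracking setup: 0.5 mm
    steps, 2000 samples per seed voxel, 0.2 curvature threshold
    (a maximum turn of ~78 degrees) and no anisotropy threshold.
    """

    step_length_mm: float = 0.5
    samples_per_seed_voxel: int = 2000
    curvature_threshold: float = 0.2
    max_steps: int | None = None
    fraction_floor: float = 0.05
    rng_seed: int = 0
    normalize_by: str = "accepted"  # or "attempts"

    def validate(self) -> None:
        if not self.step_length_mm > 0:
            raise ConfigurationError("step_length_mm must be positive")
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise ConfigurationError("curvature_threshold must lie in [-1, 1]")
        if self.samples_per_seed_voxel < 1:
            raise ConfigurationError("samples_per_seed_voxel must be >= 1")
        if self.normalize_by not in ("accepted", "attempts"):
            raise ConfigurationError("normalize_by must be 'accepted' or 'attempts'")

    def resolve_max_steps(self, field: FiberField) -> int:
        if self.max_steps is not None:
            return int(self.max_steps)
        diag = np.linalg.norm(np.asarray(field.grid_shape) * field.voxel_size_mm)
        return int(np.ceil(4.0 * diag / self.step_length_mm))


@dataclass
class Streamline:
    points: np.ndarray  # (M, 3) mm
    status: str  # accepted | rejected_exclusion | rejected_no_target
    #          | terminated_curvature_then_rejected


@dataclass
class ConnectivityMap:
    """Per-voxel accepted-streamline visit counts."""

    counts: np.ndarray
    n_accepted: int
    n_attempted: int
    voxel_size_mm: float
    normalize_by: str = "accepted"

    @property
    def denominator(self) -> int:
        return self.n_accepted if self.normalize_by == "accepted" else self.n_attempted

    @property
    def is_empty(self) -> bool:
        return self.n_accepted == 0

    @property
    def normalized(self) -> np.ndarray:
        if self.denominator == 0:
            raise NormalizationError("no streamlines to normalize by")
        return self.counts / float(self.denominator)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else 0.0


def threshold_map(cmap: ConnectivityMap, t: float) -> np.ndarray:
    """Binary mask of voxels whose normalized value is >= ``t``.

    ``t = 0`` selects the support of the counts (any visited voxel).
    """
    if cmap.denominator == 0:
        raise NormalizationError("normalization undefined: zero accepted streamlines")
    if t == 0:
        return cmap.counts > 0
    return cmap.normalized >= t


# ----------------------------------------------------------------------
# direction sampling
# ----------------------------------------------------------------------
def _watson_cos(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample cos(theta) in [0, 1] from the bipolar Watson distribution
    (density ∝ exp(kappa * cos^2 theta)) by rejection from a truncated
    exponential envelope."""
    out = np.empty(n)
    remaining = np.arange(n)
    expmk = np.exp(-kappa)
    while remaining.size:
        u = rng.random(remaining.size)
        v = rng.random(remaining.size)
        t = 1.0 + np.log(u + (1.0 - u) * expmk) / kappa
        acc = (t >= 0.0) & (v <= np.exp(kappa * (t * t - t)))
        out[remaining[acc]] = t[acc]
        remaining = remaining[~acc]
    return out


def _perpendicular_basis(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros_like(mu)
    helper[np.arange(len(mu)), np.argmin(np.abs(mu), axis=1)] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)
    return e1, e2


def _draw_about_axes(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if np.isinf(kappa):
        return mu.copy()
    n = len(mu)
    t = _watson_cos(kappa, n, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    e1, e2 = _perpendicular_basis(mu)
    s = np.sqrt(np.clip(1.0 - t * t, 0.0, None))
    return (t[:, None] * mu
            + (s * np.cos(phi))[:, None] * e1
            + (s * np.sin(phi))[:, None] * e2)


def _sample_batch(
    field: FiberField,
    vox: np.ndarray,
    prev: np.ndarray,
    rng: np.random.Generator,
    fraction_floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one direction per stream from the populations of its voxel.

    Returns (directions, has_population).  Directions are sign-aligned
    with ``prev`` (fiber axes are antipodally symmetric).
    """
    fr = field.fractions[vox[:, 0], vox[:, 1], vox[:, 2]].copy()
    fr[fr < fraction_floor] = 0.0
    tot = fr.sum(axis=1)
    ok = tot > 0
    dirs = np.zeros((len(vox), 3))
    if ok.any():
        sel = np.where(ok)[0]
        r = rng.random(sel.size) * tot[sel]
        cum = np.cumsum(fr[sel], axis=1)
        pick = (cum > r[:, None]).argmax(axis=1)
        mu = field.orientations[vox[sel, 0], vox[sel, 1], vox[sel, 2], pick]
        d = _draw_about_axes(mu, field.kappa, rng)
        sign = np.sign(np.einsum("ij,ij->i", d, prev[sel]))
        sign[sign == 0] = 1.0
        dirs[sel] = d * sign[:, None]
    return dirs, ok


def sample_direction(
    field: FiberField,
    position_mm: np.ndarray,
    previous_direction: np.ndarray,
    rng: np.random.Generator,
    fraction_floor: float = 0.05,
) -> np.ndarray:
    """Sample a propagation direction at one world position.

    Selects a fiber population with probability proportional to its
    volume fraction (populations below ``fraction_floor`` excluded),
    draws from the Watson dispersion about its axis, and sign-flips to
    align with ``previous_direction``.

    Raises
    ------
    ConfigurationError
        If the position is outside the field extent.
    ValueError
        If the containing voxel has no usable population.
    """
    pos = np.asarray(position_mm, dtype=float)
    vox = np.floor(pos / field.voxel_size_mm).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(field.grid_shape)):
        raise ConfigurationError(f"position {pos} outside field extent")
    dirs, ok = _sample_batch(
        field, vox[None, :], np.asarray(previous_direction, dtype=float)[None, :],
        rng, fraction_floor,
    )
    if not ok[0]:
        raise ValueError("voxel has no fiber population above the fraction floor")
    return dirs[0]


# ----------------------------------------------------------------------
# batched propagation
# ----------------------------------------------------------------------
def _run_branch(
    pos: np.ndarray,
    dirs: np.ndarray,
    field: FiberField,
    target_mask: np.ndarray,
    exclusion_mask: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    record_positions: bool = False,
):
    """Propagate one branch for a batch of streamlines in lockstep.

    Returns (status, visit_matrix, position_log).  ``visit_matrix`` is a
    (steps, N) int32 array of linear voxel indices, -1 where a stream
    was no longer stepping.
    """
    n = len(pos)
    shape = np.asarray(field.grid_shape)
    vs = field.voxel_size_mm
    step = params.step_length_mm
    status = np.full(n, _ACTIVE, dtype=np.int8)
    visits = []
    pos_log = [pos.copy()] if record_positions else None
    tgt = target_mask.ravel()
    exc = exclusion_mask.ravel()

    for _ in range(params.resolve_max_steps(field)):
        act = np.where(status == _ACTIVE)[0]
        if act.size == 0:
            break
        pos[act] += step * dirs[act]
        vox = np.floor(pos[act] / vs).astype(np.int64)
        oob = np.any((vox < 0) | (vox >= shape), axis=1)
        status[act[oob]] = _TERM_OOB
        act = act[~oob]
        vox = vox[~oob]
        lin = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), field.grid_shape)

        hit_exc = exc[lin]
        status[act[hit_exc]] = _REJECTED_EXCLUSION
        hit_tgt = tgt[lin] & ~hit_exc
        status[act[hit_tgt]] = _ACCEPTED

        row = np.full(n, -1, dtype=np.int32)
        keep = ~hit_exc  # record visits for streams still alive or just accepted
        row[act[keep]] = lin[keep]
        visits.append(row)
        if record_positions:
            p = np.full((n, 3), np.nan)
            p[act] = pos[act]
            pos_log.append(p)

        moving = np.where(status == _ACTIVE)[0]
        if moving.size == 0:
            continue
        vox_m = np.floor(pos[moving] / vs).astype(np.int64)
        new_dirs, has_pop = _sample_batch(field, vox_m, dirs[moving], rng,
                                          params.fraction_floor)
        status[moving[~has_pop]] = _TERM_NO_POPULATION
        cosv = np.einsum("ij,ij->i", new_dirs, dirs[moving])
        too_sharp = has_pop & (cosv < params.curvature_threshold)
        status[moving[too_sharp]] = _TERM_CURVATURE
        good = has_pop & ~too_sharp
        dirs[moving[good]] = new_dirs[good]

    status[status == _ACTIVE] = _TERM_MAX_STEPS
    visit_matrix = (np.stack(visits, axis=0) if visits
                    else np.empty((0, n), dtype=np.int32))
    return status, visit_matrix, pos_log


def _initial_directions(field, vox, rng, params):
    prev = field.orientations[vox[:, 0], vox[:, 1], vox[:, 2], 0]
    dirs, ok = _sample_batch(field, vox, prev, rng, params.fraction_floor)
    return dirs, ok


def propagate(
    seed_point_mm: np.ndarray,
    field: FiberField,
    seed_mask: np.ndarray,
    target_mask: np.ndarray,
    exclusion_mask: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> Streamline:
    """Propagate a single bidirectional streamline from one seed point."""
    params.validate()
    pos = np.asarray(seed_point_mm, dtype=float)
    vox = np.floor(pos / field.voxel_size_mm).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(field.grid_shape)):
        raise ConfigurationError(f"seed point {pos} outside the volume")

    d0, ok = _initial_directions(field, vox[None, :], rng, params)
    if not ok[0]:
        return Streamline(points=pos[None, :].copy(), status="rejected_no_target")

    logs = []
    statuses = []
    for sgn in (1.0, -1.0):
        st, _, plog = _run_branch(
            pos[None, :].copy(), sgn * d0.copy(), field, target_mask,
            exclusion_mask, params, rng, record_positions=True,
        )
        statuses.append(st[0])
        pts = np.concatenate(plog, axis=0)
        pts = pts[~np.isnan(pts[:, 0])]
        logs.append(pts)

    fwd, bwd = logs
    points = np.vstack([bwd[::-1][:-1], fwd]) if len(bwd) > 1 else fwd
    if _REJECTED_EXCLUSION in statuses:
        status = "rejected_exclusion"
    elif _ACCEPTED in statuses:
        status = "accepted"
    elif all(s == _TERM_CURVATURE for s in statuses):
        status = "terminated_curvature_then_rejected"
    else:
        status = "rejected_no_target"
    return Streamline(points=points, status=status)


def run_tractography(
    phantom: Phantom,
    params: TrackingParams,
    side: str = "left",
    seed_mask: np.ndarray | None = None,
    target_mask: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    chunk_size: int = 10000,
) -> ConnectivityMap:
    """Run the full seeding scheme for one tract side.

    Launches ``samples_per_seed_voxel`` bidirectional streamlines from
    uniformly jittered points within every seed voxel.  Only accepted
    streamlines (reaching the target without touching the exclusion
    mask) contribute to the visit counts, each incrementing a voxel at
    most once.
    """
    params.validate()
    field = phantom.fiber_field
    vs = field.voxel_size_mm
    seed_mask = phantom.seed_for(side) if seed_mask is None else seed_mask
    target_mask = phantom.target_for(side) if target_mask is None else target_mask
    exclusion_mask = (phantom.exclusion_mask if exclusion_mask is None
                      else exclusion_mask)
    rng = substream(params.rng_seed, f"track-{side}")

    seed_vox = np.argwhere(seed_mask)
    counts = np.zeros(field.grid_shape, dtype=np.int64)
    n_accepted = 0
    n_attempted = 0

    spv = params.samples_per_seed_voxel
    all_vox = np.repeat(seed_vox, spv, axis=0)
    for start in range(0, len(all_vox), chunk_size):
        vox = all_vox[start:start + chunk_size]
        n = len(vox)
        n_attempted += n
        pos0 = (vox + rng.random((n, 3))) * vs
        d0, ok = _initial_directions(field, vox, rng, params)
        seed_lin = np.ravel_multi_index(
            (vox[:, 0], vox[:, 1], vox[:, 2]), field.grid_shape
        ).astype(np.int32)

        st_a, vis_a, _ = _run_branch(pos0.copy(), d0.copy(), field, target_mask,
                                     exclusion_mask, params, rng)
        st_b, vis_b, _ = _run_branch(pos0.copy(), -d0, field, target_mask,
                                     exclusion_mask, params, rng)
        rejected = (st_a == _REJECTED_EXCLUSION) | (st_b == _REJECTED_EXCLUSION)
        accepted = ok & ~rejected & ((st_a == _ACCEPTED) | (st_b == _ACCEPTED))

        for i in np.where(accepted)[0]:
            col = np.concatenate([vis_a[:, i], vis_b[:, i], seed_lin[i:i + 1]])
            uniq = np.unique(col[col >= 0])
            counts.flat[uniq] += 1
        n_accepted += int(accepted.sum())

    return ConnectivityMap(
        counts=counts,
        n_accepted=n_accepted,
        n_attempted=n_attempted,
        voxel_size_mm=vs,
        normalize_by=params.normalize_by,
    )
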