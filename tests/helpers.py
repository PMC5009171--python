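"""Hand-built miniature phantoms and brute-force oracles used by tests."""

import numpy as np

from tractconcord.phantom import FiberField, Phantom, PhantomConfig


def _phantom_from_parts(shape, voxel, field, seed_mask, target_mask,
                        exclusion_mask, tract_mask):
    zeros = np.zeros(shape, bool)
    cfg = PhantomConfig(grid_shape=shape, voxel_size_mm=voxel)
    return Phantom(
        config=cfg,
        tract_mask_left=tract_mask,
        tract_mask_right=zeros.copy(),
        roi_labels=np.zeros(shape, np.int8),
        seed_mask_left=seed_mask,
        seed_mask_right=zeros.copy(),
        target_mask_left=target_mask,
        target_mask_right=zeros.copy(),
        exclusion_mask=exclusion_mask,
        fiber_field=field,
        intensity_volume=tract_mask.astype(float),
    )


def straight_tube_phantom(shape=(24, 24, 40), voxel=1.0, radius=2.0,
                          kappa=np.inf, field_everywhere=False):
    """Single tube along axis 2, one +z fiber population."""
    shape = tuple(shape)
    centers = [(np.arange(n) + 0.5) * voxel for n in shape]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    cx, cy = shape[0] * voxel / 2, shape[1] * voxel / 2
    tube = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
    support = np.ones(shape, bool) if field_everywhere else tube
    orientations = np.zeros((*shape, 3, 3))
    fractions = np.zeros((*shape, 3))
    orientations[support, 0] = [0.0, 0.0, 1.0]
    fractions[support, 0] = 0.8
    field = FiberField(orientations, fractions, float(kappa), voxel)
    seed = tube & (Z <= 2 * voxel)
    target = tube & (Z >= (shape[2] - 2) * voxel)
    exclusion = np.zeros(shape, bool)
    return _phantom_from_parts(shape, voxel, field, seed, target, exclusion, tube)


def bend_phantom(angle_deg=80.0, shape=(48, 48, 32), voxel=1.0, z_bend=15.0):
    """Fiber field filling the grid: +z below the bend plane, tilted by
    ``angle_deg`` (in the x-z plane) above it.  Target beyond the bend."""
    shape = tuple(shape)
    centers = [(np.arange(n) + 0.5) * voxel for n in shape]
    X, Y, Z = np.meshgrid(*centers, indexing="ij")
    theta = np.deg2rad(angle_deg)
    bent = np.array([np.sin(theta), 0.0, np.cos(theta)])
    orientations = np.zeros((*shape, 3, 3))
    fractions = np.full((*shape, 3), 0.0)
    below = Z < z_bend
    orientations[below, 0] = [0.0, 0.0, 1.0]
    orientations[~below, 0] = bent
    fractions[..., 0] = 0.8
    field = FiberField(orientations, fractions, np.inf, voxel)
    cx, cy = shape[0] * voxel / 2, shape[1] * voxel / 2
    seed = ((X - cx) ** 2 + (Y - cy) ** 2 <= 1.0) & (Z <= 2 * voxel)
    target = Z >= z_bend + 2.0
    exclusion = np.zeros(shape, bool)
    tract = np.ones(shape, bool)
    return _phantom_from_parts(shape, voxel, field, seed, target, exclusion, tract)


def blocked_tube_phantom(shape=(24, 24, 40), voxel=1.0):
    """Straight tube with a full-plane exclusion slab between seed and target."""
    ph = straight_tube_phantom(shape=shape, voxel=voxel)
    Z = (np.arange(shape[2]) + 0.5) * voxel
    slab = np.zeros(shape, bool)
    slab[:, :, np.argmin(np.abs(Z - shape[2] * voxel / 2))] = True
    ph.exclusion_mask = slab
    return ph


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------
def brute_confusion(pred, ref, roi):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                if not roi[i, j, k]:
                    continue
                p, r = bool(pred[i, j, k]), bool(ref[i, j, k])
                if p and r:
                    tp += 1
                elif p and not r:
                    fp += 1
                elif not p and r:
                    fn += 1
                else:
                    tn += 1
    return tp, fp, tn, fn


def brute_dice(pred, ref):
    inter = a = b = 0
    for p, r in zip(pred.ravel(), ref.ravel()):
        a += bool(p)
        b += bool(r)
        inter += bool(p) and bool(r)
    return 0.0 if a + b == 0 else 2.0 * inter / (a + b)


def brute_auc(values, ref, roi):
    """Mann-Whitney statistic: probability that a reference voxel's value
    outranks a non-reference voxel's (ties count half), within the ROI."""
    pos = values[ref & roi]
    neg = values[~ref & roi]
    wins = 0.0
    for v in pos:
        for u in neg:
            if v > u:
                wins += 1.0
            elif v == u:
                wins += 0.5
    return wins / (len(pos) * len(neg))
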