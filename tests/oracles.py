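"""Independent brute-force oracles used to validate the implementation.

Everything here is written as directly as possible — explicit loops and
all-pairs distance matrices on tiny grids — and deliberately shares no
code path with the package internals it checks.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def points_mm(voxels: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    idx = np.argwhere(voxels).astype(float)
    return np.asarray(origin) + idx * np.asarray(spacing)


def brute_surface(voxels: np.ndarray) -> np.ndarray:
    """Surface voxels by explicit 6-neighbourhood enumeration."""
    out = np.zeros_like(voxels)
    nx, ny, nz = voxels.shape
    for i, j, k in np.argwhere(voxels):
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                on_surface = True
                break
            if not voxels[ni, nj, nk]:
                on_surface = True
                break
        out[i, j, k] = on_surface
    return out


def brute_surface_points(voxels, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    return points_mm(brute_surface(voxels), spacing, origin)


def brute_asd(va, vb, spacing) -> float:
    sa = brute_surface_points(va, spacing)
    sb = brute_surface_points(vb, spacing)
    d = cdist(sa, sb)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb))


def brute_hd95(va, vb, spacing) -> float:
    sa = brute_surface_points(va, spacing)
    sb = brute_surface_points(vb, spacing)
    d = cdist(sa, sb)
    return max(np.percentile(np.sort(d.min(axis=1)), 95),
               np.percentile(np.sort(d.min(axis=0)), 95))


def brute_hausdorff(va, vb, spacing) -> float:
    sa = brute_surface_points(va, spacing)
    sb = brute_surface_points(vb, spacing)
    d = cdist(sa, sb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_dsc(va, vb) -> float:
    inter = np.count_nonzero(va & vb)
    return 2.0 * inter / (np.count_nonzero(va) + np.count_nonzero(vb))


def brute_centroid(voxels, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    return points_mm(voxels, spacing, origin).mean(axis=0)


def brute_centroid_deviation(va, vb, spacing) -> float:
    ca = brute_centroid(va, spacing)
    cb = brute_centroid(vb, spacing)
    # the printed formula: sqrt((XA-XB)^2 + (YA-YB)^2 + (ZA-ZB)^2)
    return float(np.sqrt((ca[0] - cb[0]) ** 2 + (ca[1] - cb[1]) ** 2 + (ca[2] - cb[2]) ** 2))


def brute_expand(voxels, spacing, margin_mm) -> np.ndarray:
    """Margin expansion by all-pairs distance enumeration (tiny grids only)."""
    shape = voxels.shape
    all_idx = np.argwhere(np.ones(shape, dtype=bool)).astype(float) * np.asarray(spacing)
    src = points_mm(voxels, spacing)
    d = cdist(all_idx, src).min(axis=1)
    return (d <= margin_mm + 1e-9).reshape(shape)


def brute_ctvn_labels(voxels, spacing, landmarks, origin=(0.0, 0.0, 0.0)) -> dict:
    """Per-voxel subdivision by applying the plane rules one voxel at a time.

    Mirrors the stated conventions: four z-bands with half-open boundaries
    (a voxel exactly on a plane joins the superior band), N1 and the
    N2/N3 quadrants split left/right at the midline (exactly-on-midline
    is right), and N2/N3 split up/down at the midpoint of that band's
    occupied z-extent (at-or-above is up).
    """
    sx, sy, sz = spacing
    zs = {}
    for i, j, k in np.argwhere(voxels):
        z = origin[2] + k * sz
        if z < landmarks.z_femoral_head:
            band = 1
        elif z < landmarks.z_piriformis:
            band = 2
        elif z < landmarks.z_iliac_bifurcation:
            band = 3
        else:
            band = 4
        zs.setdefault(band, []).append(z)
    mids = {b: (min(v) + max(v)) / 2 for b, v in zs.items()}
    labels: dict[str, set] = {}
    for i, j, k in np.argwhere(voxels):
        x = origin[0] + i * sx
        z = origin[2] + k * sz
        if z < landmarks.z_femoral_head:
            band = 1
        elif z < landmarks.z_piriformis:
            band = 2
        elif z < landmarks.z_iliac_bifurcation:
            band = 3
        else:
            band = 4
        side = "left" if x > landmarks.midline_x else "right"
        if band == 1:
            name = f"CTV-N1_{side}"
        elif band == 4:
            name = "CTV-N4"
        else:
            half = "up" if z >= mids[band] else "down"
            name = f"CTV-N{band}_{side}-{half}"
        labels.setdefault(name, set()).add((i, j, k))
    return labels


def random_blob(rng: np.random.Generator, shape, n_seeds=3, n_grow=40) -> np.ndarray:
    """Small connected-ish random mask for oracle comparisons."""
    voxels = np.zeros(shape, dtype=bool)
    pts = [tuple(rng.integers(0, s) for s in shape) for _ in range(n_seeds)]
    for p in pts:
        voxels[p] = True
    for _ in range(n_grow):
        base = pts[rng.integers(0, len(pts))]
        step = rng.integers(-1, 2, size=3)
        cand = tuple(int(np.clip(b + s, 0, dim - 1))
                     for b, s, dim in zip(base, step, shape))
        voxels[cand] = True
        pts.append(cand)
    return voxels
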