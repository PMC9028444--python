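"""Image rotation by multiples of one electrode pitch (22.5 degrees).

Each of the 16 rotations is a sparse linear operator on flattened 64x64
images, composed as ``(exact 90-degree permutation)**(k // 4) @ (bilinear
base rotation by (k % 4) * 22.5 degrees)``.  The factorisation makes
rotation by any multiple of 90 degrees an exact pixel permutation and makes
``R[k + 4n] == P90**n @ R[k]`` hold exactly — the property behind the
network's exact equivariance at quarter turns.

Convention: positive k rotates the image content counterclockwise (x right,
y up; array rows run top to bottom).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

PITCH_DEG = 22.5


def _rot90_perm(n: int) -> sp.csr_matrix:
    """Permutation matrix of one exact CCW quarter turn (np.rot90)."""
    idx = np.arange(n * n).reshape(n, n)
    src = np.rot90(idx, 1).ravel()
    return sp.csr_matrix((np.ones(n * n), (np.arange(n * n), src)),
                         shape=(n * n, n * n))


def _bilinear_rotation(theta: float, n: int) -> sp.csr_matrix:
    """Bilinear CCW rotation about the image centre, edge-clamped."""
    ctr = (n - 1) / 2.0
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    u = c.ravel() - ctr
    v = r.ravel() - ctr
    cs = np.clip(ctr + u * np.cos(theta) - v * np.sin(theta), 0, n - 1)
    rs = np.clip(ctr + u * np.sin(theta) + v * np.cos(theta), 0, n - 1)
    r0 = np.clip(np.floor(rs).astype(int), 0, n - 2)
    c0 = np.clip(np.floor(cs).astype(int), 0, n - 2)
    fr = rs - r0
    fc = cs - c0
    rows = np.repeat(np.arange(n * n), 4)
    cols = np.stack([r0 * n + c0, r0 * n + c0 + 1,
                     (r0 + 1) * n + c0, (r0 + 1) * n + c0 + 1], axis=1).ravel()
    w = np.stack([(1 - fr) * (1 - fc), (1 - fr) * fc,
                  fr * (1 - fc), fr * fc], axis=1).ravel()
    return sp.csr_matrix((w, (rows, cols)), shape=(n * n, n * n))


@lru_cache(maxsize=4)
def rotation_operators(n: int = 64) -> tuple:
    """The 16 sparse rotation operators R[k], k * 22.5 degrees CCW."""
    p90 = _rot90_perm(n)
    base = [sp.identity(n * n, format="csr")]
    for b in range(1, 4):
        base.append(_bilinear_rotation(np.deg2rad(b * PITCH_DEG), n))
    ops = []
    quarter = sp.identity(n * n, format="csr")
    for a in range(4):
        for b in range(4):
            ops.append((quarter @ base[b]).tocsr())
        quarter = (p90 @ quarter).tocsr()
    # ops currently ordered a-major; reorder to k = 4*a + b = k
    return tuple(ops)


def rotate_image(img: np.ndarray, k: int) -> np.ndarray:
    """Rotate a 64x64 image CCW by ``k`` electrode pitches (k * 22.5 deg)."""
    n = img.shape[0]
    op = rotation_operators(n)[int(k) % 16]
    return (op @ img.ravel()).reshape(n, n)


@lru_cache(maxsize=4)
def disc_mask(n: int = 64) -> np.ndarray:
    """Pixels whose centres lie inside the inscribed circular domain."""
    ctr = (n - 1) / 2.0
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (r - ctr) ** 2 + (c - ctr) ** 2 <= (n / 2.0) ** 2


def rotate_target(img: np.ndarray, k: int) -> np.ndarray:
    """Rotate a ground-truth raster, keeping outside-domain pixels verbatim.

    The conductivity outside the circular domain is the constant background;
    interpolation artefacts at the corners are clipped away by restoring the
    original values there.
    """
    out = rotate_image(img, k)
    keep = ~disc_mask(img.shape[0])
    out[keep] = img[keep]
    return out
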