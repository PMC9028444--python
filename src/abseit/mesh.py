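"""Structured triangular disc meshes with 16-fold rotational symmetry.

The mesh is built from concentric rings: ring ``i`` (1-based) carries
``16*i`` nodes at radius ``R*i/n_rings``, plus a single centre node.  Each
of the 16 angular sectors is triangulated combinatorially (exact rational
comparisons) and replicated by index shifts, so rotating the node cloud by
one electrode pitch (2*pi/16) maps the mesh onto itself *exactly*: elements
permute by a precomputed permutation, nodes by an index offset.  This exact
symmetry is what makes the rotation <-> diagonal-shift consistency checks of
the voltage maps meaningful at tight tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np

N_ELECTRODES = 16


@dataclass(frozen=True)
class DiscMesh:
    """Triangular FEM mesh of a disc with equidistant boundary electrodes."""

    radius: float
    n_rings: int
    nodes: np.ndarray          # (n_nodes, 2)
    elements: np.ndarray       # (n_elements, 3) node indices, CCW
    electrode_segments: tuple  # 16 arrays of (n_seg, 2) boundary node pairs
    rot_perm: np.ndarray       # element permutation for one CCW sector step
    areas: np.ndarray = field(default=None)       # (n_elements,)
    centroids: np.ndarray = field(default=None)   # (n_elements, 2)
    grads: np.ndarray = field(default=None)       # (n_elements, 3, 2) P1 basis gradients

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def centroids3d(self) -> np.ndarray:
        """Element centroids embedded in the z=0 plane (for 3-D shape masks)."""
        c = self.centroids
        return np.column_stack([c, np.zeros(len(c))])

    def rotate_field(self, values: np.ndarray, n: int) -> np.ndarray:
        """Rotate a per-element field counterclockwise by ``n`` electrode pitches.

        Exact permutation: the returned field at the image of element ``e``
        under a CCW rotation by ``n * 2*pi/16`` equals ``values[e]``.
        """
        out = np.asarray(values, dtype=float)
        n = int(n) % N_ELECTRODES
        for _ in range(n):
            nxt = np.empty_like(out)
            nxt[self.rot_perm] = out
            out = nxt
        return out


def _ring_start(i: int) -> int:
    # node 0 is the centre; ring i (i >= 1) holds 16*i nodes
    return 1 + 8 * i * (i - 1)


def _sector_strip(i: int) -> list:
    """Triangles of one sector of the annulus between rings i-1 and i.

    Returned as (side, a, b) triples in sector-local node numbers, where
    ``side`` says whether the triangle's base edge lies on the outer ring.
    Comparisons use exact fractions so every sector gets the identical strip.
    """
    p, q = i - 1, i  # nodes per sector on inner/outer ring
    tris = []
    a = b = 0
    while a < p or b < q:
        adv_inner = (b == q) or (
            a < p and Fraction(a + 1, p) < Fraction(b + 1, q)
        )
        if adv_inner:
            tris.append(("inner", a, b))
            a += 1
        else:
            tris.append(("outer", a, b))
            b += 1
    return tris


@lru_cache(maxsize=8)
def build_mesh(radius: float = 28.0, n_rings: int = 14,
               n_elec: int = N_ELECTRODES,
               elec_width_angle: float = 2 * np.pi / 32) -> DiscMesh:
    """Build the symmetric disc mesh with ``16 * n_rings**2`` elements.

    ``n_rings=14`` gives 3136 elements, the desk-scale stand-in for the
    reference simulator's density setting.  ``elec_width_angle`` is quantised
    to an even number of boundary segments centred on each electrode's node so
    that the electrode set is itself 16-fold symmetric.
    """
    if n_elec != N_ELECTRODES:
        raise ValueError("only 16-electrode layouts are supported")
    if n_rings < 2:
        raise ValueError("need at least 2 rings")
    if radius <= 0:
        raise ValueError("radius must be positive")

    nodes = [np.zeros((1, 2))]
    for i in range(1, n_rings + 1):
        ang = 2 * np.pi * np.arange(16 * i) / (16 * i)
        r = radius * i / n_rings
        nodes.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    nodes = np.vstack(nodes)

    elements = []
    # innermost annulus: fan around the centre node
    for s in range(16):
        elements.append((0, 1 + s, 1 + (s + 1) % 16))
    # remaining annuli: replicate the combinatorial sector strip
    for i in range(2, n_rings + 1):
        strip = _sector_strip(i)
        si, so = _ring_start(i - 1), _ring_start(i)
        ni, no = 16 * (i - 1), 16 * i
        for s in range(16):
            oi, oo = s * (i - 1), s * i
            for side, a, b in strip:
                if side == "inner":
                    tri = (si + (oi + a) % ni, so + (oo + b) % no,
                           si + (oi + a + 1) % ni)
                else:
                    tri = (si + (oi + a) % ni, so + (oo + b) % no,
                           so + (oo + b + 1) % no)
                elements.append(tri)
    elements = np.asarray(elements, dtype=np.int64)

    # enforce CCW orientation
    p = nodes[elements]
    signed = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                    - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    # element permutation under one CCW sector step: elements are stored
    # annulus-major, sector-major, strip-position-minor, so the permutation is
    # a block roll within each annulus.
    rot_perm = np.empty(len(elements), dtype=np.int64)
    off = 0
    for i in range(1, n_rings + 1):
        block = 2 * i - 1
        idx = np.arange(16 * block).reshape(16, block)
        rot_perm[off:off + 16 * block] = off + np.roll(idx, -1, axis=0).ravel()
        off += 16 * block

    # electrode boundary segments: 2*h consecutive segments centred on the
    # node under each electrode centre angle 2*pi*k/16
    nb = 16 * n_rings
    sb = _ring_start(n_rings)
    h = max(1, int(round(nb * elec_width_angle / (4 * np.pi))))
    if 2 * h >= n_rings:
        raise ValueError("electrode width covers a full pitch; refine the mesh")
    segs = []
    for k in range(16):
        c = k * n_rings
        pairs = [(sb + (c + j) % nb, sb + (c + j + 1) % nb)
                 for j in range(-h, h)]
        segs.append(np.asarray(pairs, dtype=np.int64))

    # P1 geometry
    p = nodes[elements]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    areas = 0.5 * det
    centroids = p.mean(axis=1)
    # gradients of barycentric basis functions
    grads = np.empty((len(elements), 3, 2))
    grads[:, 1, 0] = v2[:, 1] / det
    grads[:, 1, 1] = -v2[:, 0] / det
    grads[:, 2, 0] = -v1[:, 1] / det
    grads[:, 2, 1] = v1[:, 0] / det
    grads[:, 0] = -grads[:, 1] - grads[:, 2]

    return DiscMesh(radius=float(radius), n_rings=int(n_rings), nodes=nodes,
                    elements=elements, electrode_segments=tuple(segs),
                    rot_perm=rot_perm, areas=areas, centroids=centroids,
                    grads=grads)
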