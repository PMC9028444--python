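"""The electrical impedance map (EIM): a 16x16 arrangement of one frame.

Row k holds the 13 voltages measured while pair (k, k+1) injects; columns
index the measurement pairs.  Entries where the measurement pair shares an
electrode with the injecting pair — the circular sub/main/super-diagonal
band, 48 cells — are structural zeros, leaving 16*13 = 208 data cells.

Rotating the conductivity counterclockwise by n electrode pitches shifts the
map cyclically by n along *both* axes (``shift_eim``), which is the exact
symmetry the rotation augmentation and the network architecture exploit.
"""

from __future__ import annotations

import numpy as np

from .forward import VoltageFrame, valid_measurement_pairs

EIM_SIZE = 16


def valid_mask() -> np.ndarray:
    """Boolean 16x16 mask of the 208 data cells (True = carries a voltage)."""
    mask = np.ones((EIM_SIZE, EIM_SIZE), dtype=bool)
    k = np.arange(EIM_SIZE)
    for d in (-1, 0, 1):
        mask[k, (k + d) % EIM_SIZE] = False
    return mask


_VALID = valid_mask()
# canonical (row, col) order of the 208 data cells: injection-major, ascending j
_ORDER = np.concatenate(
    [[k * EIM_SIZE + j for j in valid_measurement_pairs(k)] for k in range(EIM_SIZE)])


def build_eim(frame: VoltageFrame | np.ndarray) -> np.ndarray:
    """Pack a 208-value frame into the 16x16 map with its structural zeros."""
    values = frame.values if isinstance(frame, VoltageFrame) else np.asarray(frame, float)
    values = values.ravel()
    if values.size != _ORDER.size:
        raise ValueError(f"expected {_ORDER.size} voltages, got {values.size}")
    eim = np.zeros(EIM_SIZE * EIM_SIZE)
    eim[_ORDER] = values
    return eim.reshape(EIM_SIZE, EIM_SIZE)


def flatten_eim(eim: np.ndarray, meta: dict | None = None) -> VoltageFrame:
    """Recover the canonical 208-value frame; rejects corrupted zero cells."""
    eim = np.asarray(eim, dtype=float)
    if eim.shape != (EIM_SIZE, EIM_SIZE):
        raise ValueError("EIM must be 16x16")
    if np.any(eim[~_VALID] != 0):
        raise ValueError("structural-zero cells carry data; corrupted map")
    return VoltageFrame(values=eim.reshape(-1)[_ORDER], meta=meta or {})


def shift_eim(eim: np.ndarray, n: int) -> np.ndarray:
    """Cyclic diagonal shift by n: the EIM of the same field rotated CCW by
    ``n * 2*pi/16``.  Exact Z/16 group action; preserves the zero band."""
    n = int(n) % EIM_SIZE
    return np.roll(np.roll(eim, n, axis=0), n, axis=1)
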