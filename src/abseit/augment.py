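"""Training-time augmentation: measurement noise, rotation expansion, blending.

Three noise models mimic an EIT front end (thermal/jitter: multiplicative
per entry; quantisation: additive per entry; channel gain: one multiplicative
gain per injection row).  Rotation expansion exploits the exact diagonal-shift
symmetry of the map to mint 15 extra samples per simulated one, and
alpha-blending combines two samples — linear in conductivity, hence harmonic
in the measured voltages (constant injection current).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eim import EIM_SIZE, shift_eim, valid_mask
from .rotation import rotate_target

THERMAL_JITTER_STD = 1e-6   # default multiplicative measurement-noise std
QUANTIZATION_STD = 1e-8     # default additive measurement-noise std

_VALID = valid_mask()


@dataclass
class Sample:
    """One training pair: a voltage map and its ground-truth raster."""

    eim: np.ndarray                       # (16, 16)
    target: np.ndarray                    # (64, 64)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eim = np.asarray(self.eim, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.eim.shape != (EIM_SIZE, EIM_SIZE):
            raise ValueError("EIM must be 16x16")
        if self.target.shape != (64, 64):
            raise ValueError("target must be 64x64")
        if np.any(self.eim[~_VALID] != 0):
            raise ValueError("EIM violates the structural-zero pattern")


def _tag(sample: Sample, **kv) -> dict:
    prov = dict(sample.provenance)
    prov.setdefault("augmentations", [])
    prov["augmentations"] = list(prov["augmentations"]) + [kv]
    return prov


def apply_thermal_jitter(eim: np.ndarray, std: float = THERMAL_JITTER_STD,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiply every data cell by an independent N(1, std) draw."""
    if std < 0:
        raise ValueError("std must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    out = np.array(eim, dtype=float)
    out[_VALID] *= rng.normal(1.0, std, size=int(_VALID.sum()))
    return out


def apply_quantization(eim: np.ndarray, std: float = QUANTIZATION_STD,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Add independent N(0, std) noise to every data cell."""
    if std < 0:
        raise ValueError("std must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    out = np.array(eim, dtype=float)
    out[_VALID] += rng.normal(0.0, std, size=int(_VALID.sum()))
    return out


def apply_channel_gain(eim: np.ndarray, std: float,
                       rng: np.random.Generator | None = None,
                       mean_zero: bool = False) -> np.ndarray:
    """One multiplicative gain draw per injection row, applied to its cells.

    ``mean_zero=True`` reproduces the zero-mean draw exactly as printed in
    the source formula; the default N(1, std) models channel *gain spread*,
    which is the stated purpose (a zero-mean gain would erase whole rows).
    """
    if std < 0:
        raise ValueError("std must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    gains = rng.normal(0.0 if mean_zero else 1.0, std, size=EIM_SIZE)
    return np.array(eim, dtype=float) * gains[:, None]


def blend_voltages(u1: np.ndarray, u2: np.ndarray, alpha: float,
                   eps: float = 1e-12) -> np.ndarray:
    """Harmonic voltage blend ``(alpha/U1 + (1-alpha)/U2)**-1`` on data cells.

    Adjacent voltages can take opposite signs, so the harmonic denominator
    can pass through zero; cells where it is smaller than ``eps`` relative to
    the larger reciprocal fall back to the linear blend.
    """
    out = np.zeros_like(u1)
    m = _VALID & ((u1 != 0) & (u2 != 0))
    with np.errstate(divide="ignore"):
        denom = alpha / np.where(m, u1, 1.0) + (1 - alpha) / np.where(m, u2, 1.0)
    scale = np.maximum(np.abs(1.0 / np.where(m, u1, 1.0)),
                       np.abs(1.0 / np.where(m, u2, 1.0)))
    ok = m & (np.abs(denom) > eps * scale)
    out[ok] = 1.0 / denom[ok]
    lin = _VALID & ~ok
    out[lin] = alpha * u1[lin] + (1 - alpha) * u2[lin]
    return out


def alpha_blend(a: Sample, b: Sample, alpha: float) -> Sample:
    """Blend two samples: targets linearly, voltages harmonically."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    eim = blend_voltages(a.eim, b.eim, alpha)
    target = alpha * a.target + (1 - alpha) * b.target
    prov = {"blend": {"alpha": float(alpha),
                      "parents": [a.provenance.get("phantom"),
                                  b.provenance.get("phantom")]}}
    return Sample(eim=eim, target=target, provenance=prov)


def expand_rotations(s: Sample) -> list:
    """The sample plus its 15 rotated copies (shifted map, rotated raster)."""
    out = [s]
    for n in range(1, 16):
        out.append(Sample(eim=shift_eim(s.eim, n),
                          target=rotate_target(s.target, n),
                          provenance=_tag(s, rotation=n)))
    return out
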