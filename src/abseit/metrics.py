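"""GREIT-style figures of merit adapted to absolute (reference-free) images.

The classical GREIT metrics are defined on difference images; for absolute
images the scalar *median* of the reconstruction is subtracted first (an
ideal two-level image then has its background at exactly zero), after which
an evaluation mask selects pixels beyond half the extreme value.  Amplitude
response (AR) is the in-mask sum, position error (PE) the distance of the
mask centroid to the true target centre in pixels of the 64x64 grid, and
ringing (RNG) the population std of the out-of-mask pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_ORDER = ("AR", "PE", "RNG")


@dataclass(frozen=True)
class FiguresOfMerit:
    """AR / PE / RNG for one reconstruction; NaN marks an undefined metric."""

    AR: float
    PE: float
    RNG: float

    def as_tuple(self) -> tuple:
        return (self.AR, self.PE, self.RNG)


def median_subtract(image: np.ndarray) -> np.ndarray:
    """Centre an image by its scalar median (robust background removal)."""
    image = np.asarray(image, dtype=float)
    return image - np.median(image)


def eval_mask(centered: np.ndarray, target_sign: str = "below") -> np.ndarray:
    """Pixels strictly beyond half the extreme value of a centred image.

    ``below`` selects pixels < min/2 (non-conductive target), ``above``
    pixels > max/2.  The inequality is strict: a pixel exactly at half the
    extreme is excluded.
    """
    centered = np.asarray(centered, dtype=float)
    if target_sign == "below":
        thr = 0.5 * centered.min()
        mask = centered < thr
    elif target_sign == "above":
        thr = 0.5 * centered.max()
        mask = centered > thr
    else:
        raise ValueError("target_sign must be 'below' or 'above'")
    if not mask.any():
        warnings.warn("evaluation mask is empty (flat image?)", stacklevel=2)
    return mask


def amplitude_response(centered: np.ndarray, mask: np.ndarray) -> float:
    """Sum of centred pixel values inside the mask (NaN if the mask is empty)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    return float(np.asarray(centered, dtype=float)[mask].sum())


def position_error(mask: np.ndarray, truth: tuple,
                   centered: np.ndarray | None = None,
                   amplitude_weighted: bool = False) -> float:
    """Distance (pixels) from the mask centroid to the true (col, row) centre.

    The centroid is unweighted by default; ``amplitude_weighted=True`` weighs
    pixels by |centred value| (requires ``centered``).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    rows, cols = np.nonzero(mask)
    if amplitude_weighted:
        if centered is None:
            raise ValueError("amplitude weighting needs the centred image")
        w = np.abs(np.asarray(centered, dtype=float)[rows, cols])
        if w.sum() == 0:
            w = np.ones_like(w)
        cx, cy = np.average(cols, weights=w), np.average(rows, weights=w)
    else:
        cx, cy = cols.mean(), rows.mean()
    tx, ty = truth
    return float(np.hypot(cx - tx, cy - ty))


def ringing(centered: np.ndarray, mask: np.ndarray) -> float:
    """Population std of pixels outside the mask (NaN if mask covers all)."""
    mask = np.asarray(mask, dtype=bool)
    outside = np.asarray(centered, dtype=float)[~mask]
    if outside.size == 0:
        return float("nan")
    return float(outside.std(ddof=0))


def evaluate_image(image: np.ndarray, truth: tuple,
                   target_sign: str = "below") -> FiguresOfMerit:
    """All three figures of merit for one reconstruction."""
    centered = median_subtract(image)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = eval_mask(centered, target_sign)
    return FiguresOfMerit(AR=amplitude_response(centered, mask),
                          PE=position_error(mask, truth),
                          RNG=ringing(centered, mask))


def summarize_series(series: list) -> pd.DataFrame:
    """Mean +/- sample std per metric over a position series.

    NaN-flagged entries are excluded per metric; the number of valid entries
    is reported alongside.  Column order matches the headline tables.
    """
    if len(series) < 2:
        raise ValueError("need at least two entries to summarise")
    rows = {}
    for name in METRIC_ORDER:
        vals = np.array([getattr(f, name) for f in series], dtype=float)
        ok = vals[np.isfinite(vals)]
        rows[name] = {
            "mean": ok.mean() if ok.size else float("nan"),
            "std": ok.std(ddof=1) if ok.size > 1 else float("nan"),
            "n": int(ok.size),
        }
    return pd.DataFrame(rows, columns=list(METRIC_ORDER)).T[["mean", "std", "n"]]
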