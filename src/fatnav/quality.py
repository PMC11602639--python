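"""Image-sharpness quantification.

Two complementary measures of how crisp an image is:

* **Variance of the Laplacian** — the Laplace filter responds strongly at
  edges, so its variance grows as edges sharpen.  Motion blur suppresses
  edge energy, so the ratio of Laplacian variances of a corrected to an
  uncorrected image (>1 meaning improvement) summarises how much a motion
  correction helped.  Caveat: severe ghosting artefacts also carry edge
  energy and can inflate the variance, so the ratio is only meaningful for
  comparable artefact levels.
* **Edge-profile width** — the distance over which an intensity profile
  across a thin dark structure (e.g. the cerebral falx) falls from 75% to
  25% of its local dynamic range; smaller is sharper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "variance_of_laplacian",
    "variance_of_laplacian_3d",
    "sharpness_ratio",
    "profile_edge_width",
    "ProfileWidthReport",
]

_LAPLACIAN_2D = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def variance_of_laplacian(img) -> float:
    """Variance of the 5-point discrete Laplacian over the interior of a 2D image.

    Only the interior-valid convolution region is used (no padding), so
    constant and affine (linear-ramp) images score exactly 0.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if min(img.shape) < 3:
        raise ValueError("image must be at least 3x3")
    response = convolve2d(img, _LAPLACIAN_2D, mode="valid")
    return float(response.var())


def variance_of_laplacian_3d(vol) -> float:
    """7-point-stencil Laplacian variance over the interior of a 3D stack."""
    from scipy.ndimage import convolve

    data = vol.data if hasattr(vol, "data") else np.asarray(vol, dtype=float)
    if data.ndim != 3 or min(data.shape) < 3:
        raise ValueError("expected a 3D volume of at least 3 voxels per axis")
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = -6.0
    for axis in range(3):
        idx = [1, 1, 1]
        for off in (0, 2):
            idx[axis] = off
            kernel[tuple(idx)] = 1.0
        idx[axis] = 1
    response = convolve(data, kernel, mode="constant")[1:-1, 1:-1, 1:-1]
    return float(response.var())


def sharpness_ratio(corrected, uncorrected) -> float:
    """Ratio of Laplacian variances, corrected / uncorrected; >1 is improvement."""
    num = variance_of_laplacian(corrected)
    den = variance_of_laplacian(uncorrected)
    if den == 0:
        raise ValueError("degenerate input: uncorrected image has zero Laplacian variance")
    return num / den


@dataclass(frozen=True)
class ProfileWidthReport:
    """75%→25% edge widths of a dip in an intensity profile."""

    width_mm: float
    left_width_mm: float
    right_width_mm: float
    dip_index: int
    hi_frac: float = 0.75
    lo_frac: float = 0.25


def _flank_width(x_mm, frac, hi, lo):
    """Distance between the hi and lo crossings of a monotone-ish flank.

    ``frac`` runs from the dip (index 0, value 0) outward to the plateau
    (value 1); crossings are located by linear interpolation at the first
    crossing encountered walking outward from the dip.
    """
    positions = {}
    for level in (lo, hi):
        pos = None
        for i in range(len(frac) - 1):
            f0, f1 = frac[i], frac[i + 1]
            if (f0 - level) * (f1 - level) <= 0 and f0 != f1:
                w = (level - f0) / (f1 - f0)
                pos = x_mm[i] + w * (x_mm[i + 1] - x_mm[i])
                break
        if pos is None:
            return None
        positions[level] = pos
    return abs(positions[hi] - positions[lo])


def profile_edge_width(
    profile,
    spacing_mm: float,
    hi_frac: float = 0.75,
    lo_frac: float = 0.25,
    plateau_window: int | None = None,
) -> ProfileWidthReport:
    """Width of a dark dip's flanks between the 75% and 25% intensity levels.

    The dip is the profile's interior minimum; each flank is normalised
    between the local plateau (maximum within ``plateau_window`` samples on
    that side, default the whole side) and the dip minimum, and the positions
    where the normalised intensity crosses ``hi_frac`` and ``lo_frac`` are
    found by linear interpolation.  ``width_mm`` is the steeper (smaller)
    flank's width; both flanks are reported.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    i_min = int(np.argmin(y))
    if i_min in (0, y.size - 1):
        raise ValueError("no interior dip found in profile")

    widths = []
    for side in ("left", "right"):
        seg = y[i_min::-1] if side == "left" else y[i_min:]
        win = seg.size if plateau_window is None else min(plateau_window + 1, seg.size)
        plateau = seg[:win].max()
        if plateau <= y[i_min]:
            raise ValueError(f"no {side} plateau above the dip minimum")
        frac = (seg - y[i_min]) / (plateau - y[i_min])
        x_mm = np.arange(seg.size) * spacing_mm
        widths.append(_flank_width(x_mm, frac, hi_frac, lo_frac))

    valid = [w for w in widths if w is not None]
    if not valid:
        raise ValueError("no flank crosses both intensity levels")
    big = float(max(valid))
    left = widths[0] if widths[0] is not None else big
    right = widths[1] if widths[1] is not None else big
    return ProfileWidthReport(
        width_mm=float(min(valid)),
        left_width_mm=float(left),
        right_width_mm=float(right),
        dip_index=i_min,
        hi_frac=hi_frac,
        lo_frac=lo_frac,
    )
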