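"""Image-similarity metrics for navigator registration.

Three candidate cost functions are provided.  The concordance correlation
coefficient (CCC) measures agreement between paired voxel intensities,

    ρ_C = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

penalising both decorrelation and mean/variance shifts; it is the preferred
registration cost because its profile along each motion parameter is sharply
peaked at alignment with few spurious local extrema.  SSIM (standard Wang et
al. formulation) and RMSE are included for comparison.  Covariance and
variances use population (1/n) normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .volume import Volume3D

__all__ = ["ccc", "ssim", "rmse", "metric_profile", "MetricProfile", "count_local_maxima"]

_PARAMS = ("tx", "ty", "tz", "rz", "ry", "rx")
_METRICS = ("CCC", "SSIM", "RMSE")


def _as_arrays(x, y, mask=None):
    a = x.data if isinstance(x, Volume3D) else np.asarray(x, dtype=float)
    b = y.data if isinstance(y, Volume3D) else np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match image shape")
        a, b = a[mask], b[mask]
        if a.size < 2:
            raise ValueError("mask selects fewer than 2 voxels")
    return a.ravel(), b.ravel()


def ccc(x, y, mask=None) -> float:
    """Concordance correlation coefficient between two images, in [−1, 1].

    Symmetric in its arguments.  Raises on shape mismatch and on the
    degenerate case of two constant images with equal means (zero
    denominator).
    """
    a, b = _as_arrays(x, y, mask)
    am, bm = a.mean(), b.mean()
    sxy = np.mean((a - am) * (b - bm))
    sx2 = np.mean((a - am) ** 2)
    sy2 = np.mean((b - bm) ** 2)
    denom = sx2 + sy2 + (am - bm) ** 2
    if denom == 0:
        raise ValueError("degenerate input: both images constant with equal means")
    return float(2.0 * sxy / denom)


def ssim(x, y) -> float:
    """Mean structural similarity index.

    Gaussian sliding window (σ = 1.5, width 11), stabilisation constants
    C1 = (0.01·L)² and C2 = (0.03·L)² with L the dynamic range of the first
    (reference) image — the one asymmetry among the three metrics.
    """
    a, bx = (x.data if isinstance(x, Volume3D) else np.asarray(x, dtype=float)), (
        y.data if isinstance(y, Volume3D) else np.asarray(y, dtype=float)
    )
    if a.shape != bx.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {bx.shape}")
    data_range = float(np.ptp(a))
    if data_range == 0:
        data_range = 1.0
    return float(
        structural_similarity(
            a, bx, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


def rmse(x, y) -> float:
    """Root mean squared voxel-wise error; 0 iff the images are identical."""
    a, b = _as_arrays(x, y)
    return float(np.sqrt(np.mean((a - b) ** 2)))


_METRIC_FNS = {"CCC": ccc, "SSIM": ssim, "RMSE": rmse}


@dataclass(frozen=True)
class MetricProfile:
    """A similarity metric evaluated along one rigid-motion parameter."""

    parameter_name: str
    parameter_values: tuple[float, ...]
    metric_values: tuple[float, ...]
    metric_name: str

    def __post_init__(self):
        if len(self.parameter_values) != len(self.metric_values):
            raise ValueError("parameter and metric value lists must have equal length")
        if np.any(np.diff(self.parameter_values) <= 0):
            raise ValueError("parameter_values must be strictly increasing")

    @property
    def argbest(self) -> float:
        """Offset at which the metric is best (max for CCC/SSIM, min for RMSE)."""
        vals = np.asarray(self.metric_values)
        i = int(np.argmin(vals) if self.metric_name == "RMSE" else np.argmax(vals))
        return self.parameter_values[i]

    def to_rows(self):
        return list(zip(self.parameter_values, self.metric_values))


def metric_profile(
    fixed: Volume3D,
    moving: Volume3D,
    metric_name: str,
    parameter_name: str,
    offsets,
) -> MetricProfile:
    """Evaluate a metric as one motion parameter of ``moving`` is swept.

    For each offset a single-parameter rigid perturbation (translation in mm
    or rotation in degrees) is applied to ``moving`` and the metric computed
    against ``fixed``; the resulting curve is used to compare peak sharpness
    and the number of local extrema across metrics.
    """
    from .synthetic import apply_transform_imagespace
    from .transforms import RigidTransform

    if metric_name not in _METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; expected one of {_METRICS}")
    if parameter_name not in _PARAMS:
        raise ValueError(f"unknown parameter {parameter_name!r}; expected one of {_PARAMS}")
    offsets = [float(v) for v in offsets]
    if not offsets or np.any(np.diff(offsets) <= 0):
        raise ValueError("offsets must be non-empty and strictly increasing")

    fn = _METRIC_FNS[metric_name]
    values = []
    for off in offsets:
        params = dict.fromkeys(_PARAMS, 0.0)
        params[parameter_name] = off
        t = RigidTransform(
            (params["rz"], params["ry"], params["rx"]),
            (params["tx"], params["ty"], params["tz"]),
        )
        perturbed = apply_transform_imagespace(moving, t)
        values.append(fn(fixed, perturbed))
    return MetricProfile(parameter_name, tuple(offsets), tuple(values), metric_name)


def count_local_maxima(profile: MetricProfile, rel_tol: float = 1e-6) -> int:
    """Number of strict interior local maxima of a metric profile.

    RMSE profiles are negated first so "maxima" consistently means points of
    best similarity for every metric.
    """
    v = np.asarray(profile.metric_values, dtype=float)
    if profile.metric_name == "RMSE":
        v = -v
    tol = rel_tol * max(np.ptp(v), 1e-300)
    return int(np.sum((v[1:-1] > v[:-2] + tol) & (v[1:-1] > v[2:] + tol)))
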