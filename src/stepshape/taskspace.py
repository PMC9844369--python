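"""Task-space analysis of the stepping movement.

A planar two-segment model maps the hip and knee configuration to heel
height:

    heel_z = hip_z + thigh_l * sin(hip_a) + shank_l * sin(knee_a + hip_a)

where ``hip_a`` is the thigh angle relative to the horizontal axis and
``knee_a`` the shank angle relative to the thigh.  At the mean peak-height
configuration the constant-height contour of this map defines the
*equivalent* direction (combinations of hip and knee that leave heel height
unchanged) and its normal the *orthogonal* direction.  Per-block scatter of
the (hip, knee) configuration at peak foot height is summarised by the
85 %-coverage ellipse area, the variance projected on each direction, and a
tolerance cost: how much the outcome SD could be reduced by rigidly
translating the whole cloud to the most error-tolerant spot of the task
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LimbModel",
    "ModelAngles",
    "TaskSpaceBasis",
    "DispersionSummary",
    "forward_heel_height",
    "model_angles_from_recorded",
    "task_space_basis",
    "project_variances",
    "ellipse_area",
    "tolerance_cost",
    "dispersion_summary",
]


@dataclass(frozen=True)
class LimbModel:
    """Planar limb geometry: hip height and segment lengths, metres."""

    hip_z_m: float
    thigh_l_m: float
    shank_l_m: float

    def __post_init__(self) -> None:
        for name in ("hip_z_m", "thigh_l_m", "shank_l_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LimbModel.{name} must be > 0")


@dataclass(frozen=True)
class ModelAngles:
    """Model angles in radians: hip relative to horizontal, knee relative to thigh."""

    hip_a_rad: float
    knee_a_rad: float


@dataclass(frozen=True)
class TaskSpaceBasis:
    """Equivalent/orthogonal unit directions at a reference configuration.

    Directions live in (hip, knee) execution space; the same components
    apply whether that space is expressed in radians or degrees because the
    gradient scales uniformly in both coordinates.
    """

    ref_config: tuple[float, float]  # mean (hip, knee) of the points, input units
    e_eq: np.ndarray
    e_orth: np.ndarray


@dataclass(frozen=True)
class DispersionSummary:
    area_deg2: float
    var_eq: float
    var_orth: float
    t_cost: float


def forward_heel_height(model: LimbModel, hip_a_rad, knee_a_rad):
    """Heel height (m) of the two-segment model; accepts scalars or arrays."""
    hip_a = np.asarray(hip_a_rad, dtype=float)
    knee_a = np.asarray(knee_a_rad, dtype=float)
    out = model.hip_z_m + model.thigh_l_m * np.sin(hip_a) + model.shank_l_m * np.sin(knee_a + hip_a)
    return float(out) if out.ndim == 0 else out


def model_angles_from_recorded(hip_flex_deg, knee_flex_deg):
    """Bridge recorded flexion angles (degrees, anatomical reference) to model angles.

    At zero flexion the thigh points straight down (−90° from horizontal)
    and the extended knee continues the thigh line, so

        hip_a = hip_flex − 90°,   knee_a = knee_flex  (both → radians).
    """
    hip_a = np.deg2rad(np.asarray(hip_flex_deg, dtype=float) - 90.0)
    knee_a = np.deg2rad(np.asarray(knee_flex_deg, dtype=float))
    if hip_a.ndim == 0:
        return ModelAngles(float(hip_a), float(knee_a))
    return hip_a, knee_a


def heel_height_from_recorded(model: LimbModel, hip_flex_deg, knee_flex_deg):
    """Forward model evaluated directly on recorded flexion angles (degrees)."""
    hip_a = np.deg2rad(np.asarray(hip_flex_deg, dtype=float) - 90.0)
    knee_a = np.deg2rad(np.asarray(knee_flex_deg, dtype=float))
    return forward_heel_height(model, hip_a, knee_a)


def _height_gradient(model: LimbModel, hip_a_rad: float, knee_a_rad: float) -> np.ndarray:
    """d heel_z / d(hip_a, knee_a) at one configuration (per radian)."""
    c_hk = np.cos(knee_a_rad + hip_a_rad)
    return np.array(
        [model.thigh_l_m * np.cos(hip_a_rad) + model.shank_l_m * c_hk, model.shank_l_m * c_hk]
    )


def task_space_basis(points_deg: np.ndarray, model: LimbModel) -> TaskSpaceBasis:
    """Equivalent/orthogonal directions at the mean of ``points_deg``.

    ``points_deg`` is an (n, 2) array of recorded (hip_flex, knee_flex) in
    degrees.  The orthogonal direction is the normalised height gradient;
    the equivalent direction is its in-plane perpendicular (tangent to the
    constant-height contour).
    """
    pts = np.asarray(points_deg, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 2)")
    mean = pts.mean(axis=0)
    hip_a = np.deg2rad(mean[0] - 90.0)
    knee_a = np.deg2rad(mean[1])
    g = _height_gradient(model, hip_a, knee_a)
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise ValueError("singular configuration: height gradient vanishes at the mean")
    e_orth = g / norm
    e_eq = np.array([-e_orth[1], e_orth[0]])
    return TaskSpaceBasis(ref_config=(float(mean[0]), float(mean[1])), e_eq=e_eq, e_orth=e_orth)


def project_variances(points_deg: np.ndarray, basis: TaskSpaceBasis) -> tuple[float, float]:
    """Variance of the centered points projected on e_eq and e_orth (deg²)."""
    pts = np.asarray(points_deg, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    var_eq = float(np.var(centered @ basis.e_eq, ddof=1))
    var_orth = float(np.var(centered @ basis.e_orth, ddof=1))
    return var_eq, var_orth


def ellipse_area(points: np.ndarray, coverage: float = 0.85) -> float:
    """Area of the covariance ellipse covering ``coverage`` of a bivariate normal.

    area = pi * chi2_2(coverage) * sqrt(det(sample covariance)).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    cov = np.cov(pts.T, ddof=1)
    det = float(np.linalg.det(cov))
    det = max(det, 0.0)  # guard tiny negative round-off for collinear data
    return float(np.pi * stats.chi2.ppf(coverage, df=2) * np.sqrt(det))


def tolerance_cost(
    points_deg: np.ndarray,
    model: LimbModel,
    search_half_width_deg: float = 40.0,
    step_deg: float = 0.5,
) -> float:
    """Tolerance cost (m): outcome SD at the observed location minus the
    minimum outcome SD over rigid translations of the cloud.

    The cloud of (hip_flex, knee_flex) points in degrees is translated on a
    square grid of ± ``search_half_width_deg`` around its mean; at each
    offset the SD of the forward-model heel height over the translated
    points is evaluated.  A cost of 0 means the cloud already sits at the
    most error-tolerant location reachable by translation.
    """
    pts = np.asarray(points_deg, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    offsets = np.arange(-search_half_width_deg, search_half_width_deg + step_deg / 2, step_deg)
    if offsets.size == 0:
        raise ValueError("empty translation grid")

    def sd_height(hip_deg, knee_deg):
        h = heel_height_from_recorded(model, hip_deg, knee_deg)
        return h.std(axis=-1, ddof=1)

    sd_actual = float(sd_height(pts[:, 0], pts[:, 1]))
    # vectorize over the grid: (g, g, n) broadcast of translated clouds
    dh = offsets[:, None, None] + pts[None, None, :, 0]  # (g, 1, n)
    dk = offsets[None, :, None] + pts[None, None, :, 1]  # (1, g, n)
    hip_a = np.deg2rad(dh - 90.0)
    knee_a = np.deg2rad(dk)
    heights = (model.hip_z_m + model.thigh_l_m * np.sin(hip_a)
               + model.shank_l_m * np.sin(knee_a + hip_a))
    sd_grid = heights.std(axis=-1, ddof=1)
    return float(max(sd_actual - float(sd_grid.min()), 0.0))


def dispersion_summary(
    points_deg: np.ndarray,
    model: LimbModel,
    coverage: float = 0.85,
    search_half_width_deg: float = 40.0,
    step_deg: float = 0.5,
) -> DispersionSummary:
    """All per-block dispersion measures for one block's peak configurations."""
    basis = task_space_basis(points_deg, model)
    var_eq, var_orth = project_variances(points_deg, basis)
    return DispersionSummary(
        area_deg2=ellipse_area(points_deg, coverage),
        var_eq=var_eq,
        var_orth=var_orth,
        t_cost=tolerance_cost(points_deg, model, search_half_width_deg, step_deg),
    )
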