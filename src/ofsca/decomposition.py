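"""Oriented fractal scaling component analysis (OFSCA) of a 2D trajectory.

From the angle-resolved fluctuation functions, fit the scaling exponent
profile H(theta) over a stated log-scale band, locate its circular extrema
theta_max / theta_min, flip by 90 degrees to the component directions
theta_1 / theta_2 (the component with the larger exponent lies orthogonal to
the direction where the profile is minimal), and solve the 2x2 linear system
per sample to reconstruct the two oblique component time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ddma import AngularFluctuation, ScaleGrid, angular_fluctuation, default_angle_grid, default_scale_grid
from .synthetic import CopTrajectory

__all__ = [
    "ScalingProfile",
    "ExtremalAngles",
    "OfscaResult",
    "scaling_profile",
    "find_extremal_angles",
    "component_directions",
    "delta_theta",
    "sd_h",
    "reconstruct_components",
    "analyze_trial",
]

DEFAULT_FIT_RANGE = (1.5, 2.0)
DEFAULT_DEGENERACY_THRESHOLD = 0.02
_CONDITION_MAX = 1e5


@dataclass(frozen=True)
class ScalingProfile:
    """Angle-resolved scaling exponents and local log-log slopes."""

    angles: np.ndarray  # radians, axial grid over [0, pi)
    hurst: np.ndarray  # H(theta), one exponent per angle
    local_slopes: np.ndarray  # d log10 F / d log10 s_eff, angle x scale
    fit_range: tuple[float, float]

    @property
    def angles_deg(self) -> np.ndarray:
        return np.degrees(self.angles)


@dataclass(frozen=True)
class ExtremalAngles:
    theta_max_deg: float
    theta_min_deg: float
    h1: float
    h2: float
    degenerate: bool


def scaling_profile(
    af: AngularFluctuation,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> ScalingProfile:
    """Per-angle regression slope of log10 F vs log10 s_eff inside the band.

    ``fit_range`` is in log10 effective-scale units; at least three scale
    points must fall strictly inside it.  Local slopes are centered finite
    differences of the log-log curve over the full scale grid.
    """
    lo, hi = fit_range
    if not lo < hi:
        raise ValueError(f"fit_range must satisfy lo < hi, got {fit_range}")
    log_s = np.log10(af.grid.scales_eff)
    mask = (log_s > lo) & (log_s < hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"only {int(mask.sum())} scale points inside fit range {fit_range}; "
            "need at least 3"
        )
    with np.errstate(divide="ignore"):
        log_f = np.log10(af.F)
    if not np.all(np.isfinite(log_f[:, mask])):
        # zero fluctuation at some angle/scale: slope undefined, report 0
        log_f = np.where(np.isfinite(log_f), log_f, np.nan)
    hurst = np.full(af.angles.size, np.nan)
    ok = np.all(np.isfinite(log_f[:, mask]), axis=1)
    if np.any(ok):
        hurst[ok] = np.polyfit(log_s[mask], log_f[np.ix_(ok, mask)].T, 1)[0]
    hurst = np.where(np.isfinite(hurst), hurst, 0.0)
    local = np.gradient(log_f, log_s, axis=1)
    return ScalingProfile(
        angles=af.angles, hurst=hurst, local_slopes=local, fit_range=(lo, hi)
    )


def _circular_smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average on the circular (period-pi) angle grid."""
    return (np.roll(values, 1) + values + np.roll(values, -1)) / 3.0


def find_extremal_angles(
    profile: ScalingProfile,
    smoothing: bool = False,
    degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD,
) -> ExtremalAngles:
    """Circular argmax/argmin of H(theta); flat profiles are flagged isotropic.

    The search is exhaustive over the angle grid (wraparound is implicit in
    the grid's periodicity), with ties broken toward the smallest angle.
    A profile whose range falls below ``degeneracy_threshold`` carries no
    usable directional information and is flagged degenerate.
    """
    h = _circular_smooth3(profile.hurst) if smoothing else profile.hurst
    h_max, h_min = float(np.max(h)), float(np.min(h))
    if h_max - h_min < degeneracy_threshold:
        return ExtremalAngles(np.nan, np.nan, h_max, h_min, degenerate=True)
    i_max = int(np.argmax(h))  # argmax/argmin take the first (smallest) index on ties
    i_min = int(np.argmin(h))
    return ExtremalAngles(
        theta_max_deg=float(np.degrees(profile.angles[i_max])),
        theta_min_deg=float(np.degrees(profile.angles[i_min])),
        h1=h_max,
        h2=h_min,
        degenerate=False,
    )


def component_directions(theta_max_deg: float, theta_min_deg: float) -> tuple[float, float]:
    """Component axes from the profile extrema: a 90-degree axial flip.

    The projection annihilates a component when the projection axis is
    orthogonal to it, so the large-exponent component lies orthogonal to the
    direction where H(theta) is minimal: theta_1 = theta_min + 90 (mod 180)
    and theta_2 = theta_max + 90 (mod 180).
    """
    return (theta_min_deg + 90.0) % 180.0, (theta_max_deg + 90.0) % 180.0


def delta_theta(theta1_deg: float, theta2_deg: float) -> float:
    """Axial angle between the two component directions, folded to [0, 90]."""
    d = abs(theta1_deg - theta2_deg) % 180.0
    return min(d, 180.0 - d)


def sd_h(profile: ScalingProfile) -> float:
    """Standard deviation of H(theta) over the full angle grid (population)."""
    return float(np.std(profile.hurst))


def reconstruct_components(
    traj: CopTrajectory,
    theta1_deg: float,
    theta2_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Demix the trajectory into its two oblique components.

    Solves, per sample, [cos t1, cos t2; sin t1, sin t2] (e1, e2) = (ml, ap);
    this is the exact inverse of the oblique mixing when the true angles are
    supplied.  Near-collinear axes make the system ill-conditioned and raise.
    """
    t1, t2 = np.radians(theta1_deg), np.radians(theta2_deg)
    mix = np.array([[np.cos(t1), np.cos(t2)], [np.sin(t1), np.sin(t2)]])
    cond = np.linalg.cond(mix)
    if not np.isfinite(cond) or cond > _CONDITION_MAX:
        raise ValueError(
            f"demixing is singular: component axes {theta1_deg:.4f} and "
            f"{theta2_deg:.4f} deg are (near-)collinear (cond={cond:.3g})"
        )
    eps = np.linalg.solve(mix, np.vstack([traj.ml, traj.ap]))
    return eps[0], eps[1]


@dataclass
class OfscaResult:
    """Per-trial OFSCA decomposition summary.

    Angles are degrees in [0, 180) (axial); ``delta_theta_deg`` is folded to
    [0, 90].  ``h1 >= h2`` by construction.  When the H(theta) profile is
    flat (``degenerate``), no directions are reported and the angle fields
    are NaN.
    """

    theta1_deg: float
    theta2_deg: float
    delta_theta_deg: float
    h1: float
    h2: float
    sd_h: float
    theta_max_deg: float
    theta_min_deg: float
    degenerate: bool
    eps1_hat: np.ndarray | None = None
    eps2_hat: np.ndarray | None = None
    profile: ScalingProfile | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta1_deg": self.theta1_deg,
            "theta2_deg": self.theta2_deg,
            "delta_theta_deg": self.delta_theta_deg,
            "h1": self.h1,
            "h2": self.h2,
            "sd_h": self.sd_h,
            "theta_max_deg": self.theta_max_deg,
            "theta_min_deg": self.theta_min_deg,
            "degenerate": self.degenerate,
            "meta": {k: v for k, v in self.meta.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=float))


def analyze_trial(
    traj: CopTrajectory,
    order: int = 4,
    angle_count: int = 179,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    smoothing: bool = False,
    degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD,
    grid: ScaleGrid | None = None,
    reconstruct: bool = True,
) -> OfscaResult:
    """Full per-trial OFSCA pipeline, deterministic given input and settings.

    Composes the angular fluctuation functions, the H(theta) scaling profile,
    the extremal-direction search, the orthogonal flip to component
    directions, delta-theta and SD_H, and (optionally) the component
    reconstruction.  A flat profile yields a degenerate result with NaN
    angles and no components.
    """
    if grid is None:
        grid = default_scale_grid(order=order)
    angles = default_angle_grid(angle_count)
    if np.allclose(traj.ml, traj.ml[0]) and np.allclose(traj.ap, traj.ap[0]):
        # constant input: no fluctuations at any scale
        return OfscaResult(
            np.nan, np.nan, np.nan, 0.0, 0.0, 0.0, np.nan, np.nan,
            degenerate=True, meta=dict(traj.meta),
        )
    af = angular_fluctuation(traj, angles=angles, grid=grid)
    profile = scaling_profile(af, fit_range=fit_range)
    ext = find_extremal_angles(
        profile, smoothing=smoothing, degeneracy_threshold=degeneracy_threshold
    )
    if ext.degenerate:
        return OfscaResult(
            np.nan, np.nan, np.nan, ext.h1, ext.h2, sd_h(profile),
            np.nan, np.nan, degenerate=True, profile=profile, meta=dict(traj.meta),
        )
    theta1, theta2 = component_directions(ext.theta_max_deg, ext.theta_min_deg)
    eps1 = eps2 = None
    if reconstruct:
        eps1, eps2 = reconstruct_components(traj, theta1, theta2)
    return OfscaResult(
        theta1_deg=theta1,
        theta2_deg=theta2,
        delta_theta_deg=delta_theta(theta1, theta2),
        h1=ext.h1,
        h2=ext.h2,
        sd_h=sd_h(profile),
        theta_max_deg=ext.theta_max_deg,
        theta_min_deg=ext.theta_min_deg,
        degenerate=False,
        eps1_hat=eps1,
        eps2_hat=eps2,
        profile=profile,
        meta=dict(traj.meta),
    )
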