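"""Synthetic anisotropic sway: oblique two-component CoP trajectories and cohorts.

The generative model mirrors the anisotropy hypothesis under test: a 2D
center-of-pressure (CoP) trajectory is the linear superposition of two latent
fractional Brownian components with distinct Hurst exponents, oriented along
oblique axes theta_1 and theta_2 (measured from the mediolateral platform
axis, axial angles mod pi).  A cohort emulates a balanced posturography
protocol -- participants x (vision x head-rotation phase) conditions -- with
participant-level random intercepts and condition-level shifts of the angle
between the two component directions (delta-theta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fgn import generate_fgn, integrate_to_fbm

__all__ = [
    "ComponentSpec",
    "CopTrajectory",
    "ConditionEffect",
    "CohortDesign",
    "mix_components",
    "generate_trial",
    "generate_cohort",
    "generate_cohort_truth",
    "ground_truth_table",
    "write_cohort",
    "VISION_LEVELS",
    "PHASE_LEVELS",
    "DEFAULT_CONDITIONS",
]

VISION_LEVELS = ("EyesOpen", "EyesClosed")
PHASE_LEVELS = ("Before", "HeadRotation", "After")
#: full 2 x 3 protocol grid: both vision settings crossed with the
#: before / during / after head-rotation phases
DEFAULT_CONDITIONS = tuple((v, p) for v in VISION_LEVELS for p in PHASE_LEVELS)

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class ComponentSpec:
    """Orientation, persistence and magnitude of one latent sway component.

    ``angle_deg`` is axial (a direction and its opposite are the same axis)
    and is normalised into [0, 180).  ``amplitude`` scales the unit-variance
    fGn increments, keeping the Hurst exponent and the magnitude orthogonal
    parameters.
    """

    hurst: float
    angle_deg: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie strictly in (0, 1), got {self.hurst}")
        if not self.amplitude > 0.0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 180.0)

    @property
    def angle_rad(self) -> float:
        return np.radians(self.angle_deg)


@dataclass
class CopTrajectory:
    """A sampled 2D CoP trajectory: mediolateral and anteroposterior series."""

    ml: np.ndarray
    ap: np.ndarray
    sampling_rate: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.ndim != 1 or self.ap.ndim != 1:
            raise ValueError("ml and ap must be 1-D")
        if self.ml.size != self.ap.size:
            raise ValueError(
                f"ml and ap lengths differ: {self.ml.size} vs {self.ap.size}"
            )
        if self.ml.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return self.ml.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate

    def rotated(self, phi_deg: float) -> "CopTrajectory":
        """Trajectory rotated rigidly by ``phi_deg`` in the support plane."""
        phi = np.radians(phi_deg)
        ml = self.ml * np.cos(phi) - self.ap * np.sin(phi)
        ap = self.ml * np.sin(phi) + self.ap * np.cos(phi)
        return CopTrajectory(ml, ap, self.sampling_rate, dict(self.meta))


def mix_components(
    eps1: np.ndarray,
    eps2: np.ndarray,
    spec1: ComponentSpec,
    spec2: ComponentSpec,
    sampling_rate: float = 100.0,
    meta: dict | None = None,
) -> CopTrajectory:
    """Superpose two latent component series along their oblique axes.

    ml[i] = a1 * eps1[i] * cos(theta1) + a2 * eps2[i] * cos(theta2)
    ap[i] = a1 * eps1[i] * sin(theta1) + a2 * eps2[i] * sin(theta2)
    """
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    if eps1.shape != eps2.shape:
        raise ValueError(f"component lengths differ: {eps1.size} vs {eps2.size}")
    t1, t2 = spec1.angle_rad, spec2.angle_rad
    if abs(np.sin(t1 - t2)) < _COLLINEAR_TOL:
        raise ValueError(
            "component axes are collinear (angles equal mod 180 deg); "
            "the mixing matrix is singular"
        )
    ml = spec1.amplitude * eps1 * np.cos(t1) + spec2.amplitude * eps2 * np.cos(t2)
    ap = spec1.amplitude * eps1 * np.sin(t1) + spec2.amplitude * eps2 * np.sin(t2)
    return CopTrajectory(ml, ap, sampling_rate, meta or {})


def generate_trial(
    spec1: ComponentSpec,
    spec2: ComponentSpec,
    duration: float = 20.0,
    sampling_rate: float = 100.0,
    seed: int | np.random.Generator | None = None,
    meta: dict | None = None,
) -> CopTrajectory:
    """One synthetic trial: two fBm components mixed along oblique axes.

    Defaults correspond to a 20 s trial sampled at 100 Hz (n = 2000).
    Components are unit-variance fGn integrated to fBm; amplitudes act on the
    increment scale.
    """
    n = int(round(duration * sampling_rate))
    if n < 16:
        raise ValueError(f"duration * sampling_rate = {n} is too short to analyse")
    rng = np.random.default_rng(seed)
    eps1 = integrate_to_fbm(generate_fgn(n, spec1.hurst, rng))
    eps2 = integrate_to_fbm(generate_fgn(n, spec2.hurst, rng))
    traj = mix_components(eps1, eps2, spec1, spec2, sampling_rate, meta)
    traj.meta.setdefault("true_theta1_deg", spec1.angle_deg)
    traj.meta.setdefault("true_theta2_deg", spec2.angle_deg)
    traj.meta.setdefault("true_h1", spec1.hurst)
    traj.meta.setdefault("true_h2", spec2.hurst)
    return traj


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition shifts applied on top of the cohort baseline."""

    delta_theta_deg: float = 0.0
    h1: float = 0.0
    h2: float = 0.0


def _axial_fold(delta_deg: float) -> float:
    """Fold an axial angle difference into [0, 90] degrees."""
    d = abs(delta_deg) % 180.0
    return min(d, 180.0 - d)


@dataclass
class CohortDesign:
    """Design of a synthetic cohort emulating the six-condition protocol.

    Defaults: 17 participants x 6 conditions (2 vision x 3 head-rotation
    phases), 20 s trials at 100 Hz.  The major component is anteroposterior
    (theta1 = 90 deg) and persistent (H1 = 0.9); the minor one mediolateral
    (theta2 = 0 deg, H2 = 0.6).  ``random_intercept_sd`` spreads each
    participant's baseline delta-theta; ``trial_noise_sd`` adds independent
    trial-to-trial variability; ``effect_map`` shifts delta-theta and the
    Hurst exponents per (vision, phase) condition.
    """

    n_participants: int = 17
    conditions: tuple = DEFAULT_CONDITIONS
    trial_duration: float = 20.0
    sampling_rate: float = 100.0
    effect_map: dict = field(default_factory=dict)
    random_intercept_sd: float = 6.5
    trial_noise_sd: float = 9.5
    base_spec1: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(hurst=0.9, angle_deg=90.0)
    )
    base_spec2: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(hurst=0.6, angle_deg=0.0)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for cond in self.conditions:
            self._validate_condition(cond)
        for key in self.effect_map:
            cond = self._validate_condition(key)
            if cond not in self.conditions:
                raise ValueError(f"effect_map key {key!r} is not a design condition")

    @staticmethod
    def _validate_condition(cond) -> tuple:
        try:
            vision, phase = cond
        except (TypeError, ValueError):
            raise ValueError(f"condition {cond!r} is not a (vision, phase) pair")
        if vision not in VISION_LEVELS:
            raise ValueError(f"unknown vision level {vision!r}; expected {VISION_LEVELS}")
        if phase not in PHASE_LEVELS:
            raise ValueError(f"unknown phase level {phase!r}; expected {PHASE_LEVELS}")
        return (vision, phase)

    @property
    def base_delta_theta_deg(self) -> float:
        return _axial_fold(self.base_spec1.angle_deg - self.base_spec2.angle_deg)


def _draw_trial_parameters(design: CohortDesign, seed: int | None):
    """Per-trial ground-truth parameters and the RNG stream for each trial.

    Per trial the true angle between component axes is

        delta = base + intercept(participant) + effect(condition) + noise(trial)

    (folded axially into [0, 90]); theta1 carries half-sized per-trial
    orientation noise and theta2 = theta1 - delta.
    """
    if seed is None:
        seed = design.seed if design.seed is not None else 0
    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root.spawn(1)[0])
    intercepts = master.normal(0.0, design.random_intercept_sd, design.n_participants)

    for p in range(design.n_participants):
        participant = f"P{p + 1:02d}"
        for c, (vision, phase) in enumerate(design.conditions):
            effect = design.effect_map.get((vision, phase), ConditionEffect())
            if not isinstance(effect, ConditionEffect):
                effect = ConditionEffect(**dict(effect))
            # deterministic per-trial stream derived from the root sequence
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(1, p, c))
            trial_rng = np.random.default_rng(child)

            noise = trial_rng.normal(0.0, design.trial_noise_sd)
            # the linear-mixed-model response itself; NOT folded axially, so
            # intercept and condition shifts stay additive as in the model
            # being emulated (the constructed axes fold any rare excursion
            # beyond 90 deg geometrically)
            delta_true = (
                design.base_delta_theta_deg
                + intercepts[p]
                + effect.delta_theta_deg
                + noise
            )
            theta1 = (
                design.base_spec1.angle_deg
                + trial_rng.normal(0.0, design.trial_noise_sd / 2.0)
            ) % 180.0
            theta2 = (theta1 - delta_true) % 180.0
            h1 = float(np.clip(design.base_spec1.hurst + effect.h1, 0.05, 0.95))
            h2 = float(np.clip(design.base_spec2.hurst + effect.h2, 0.05, 0.95))

            spec1 = ComponentSpec(h1, theta1, design.base_spec1.amplitude)
            spec2 = ComponentSpec(h2, theta2, design.base_spec2.amplitude)
            meta = {
                "participant": participant,
                "vision": vision,
                "phase": phase,
                "true_delta_theta_deg": delta_true,
                "participant_intercept_deg": float(intercepts[p]),
            }
            yield spec1, spec2, meta, trial_rng


def generate_cohort(
    design: CohortDesign, seed: int | None = None
) -> list[CopTrajectory]:
    """Generate one trial per participant x condition with ground-truth labels.

    Ground truth is stored in each trajectory's ``meta`` for the statistics
    stage.  Reproducible: identical design + seed give identical trajectories
    and metadata.
    """
    return [
        generate_trial(
            spec1, spec2, design.trial_duration, design.sampling_rate, rng, meta
        )
        for spec1, spec2, meta, rng in _draw_trial_parameters(design, seed)
    ]


def generate_cohort_truth(design: CohortDesign, seed: int | None = None) -> pd.DataFrame:
    """Ground-truth per-trial table without synthesising the trajectories.

    Uses the identical random streams as :func:`generate_cohort`, so the
    table matches the metadata of the trajectories the same seed produces.
    Useful for exercising the statistics stage at scale.
    """
    rows = []
    for spec1, spec2, meta, _ in _draw_trial_parameters(design, seed):
        rows.append(
            {
                "participant": meta["participant"],
                "vision": meta["vision"],
                "phase": meta["phase"],
                "delta_theta": meta["true_delta_theta_deg"],
                "theta1": spec1.angle_deg,
                "theta2": spec2.angle_deg,
                "h1": spec1.hurst,
                "h2": spec2.hurst,
            }
        )
    return pd.DataFrame(rows)


def ground_truth_table(trials: list[CopTrajectory]) -> pd.DataFrame:
    """Tidy per-trial table of the generator's ground-truth parameters."""
    rows = []
    for t in trials:
        m = t.meta
        rows.append(
            {
                "participant": m["participant"],
                "vision": m["vision"],
                "phase": m["phase"],
                "delta_theta": m["true_delta_theta_deg"],
                "theta1": m["true_theta1_deg"],
                "theta2": m["true_theta2_deg"],
                "h1": m["true_h1"],
                "h2": m["true_h2"],
            }
        )
    return pd.DataFrame(rows)


def write_cohort(trials: list[CopTrajectory], out_dir: str | Path) -> Path:
    """Write per-trial CSVs, a manifest and a ground-truth JSON sidecar.

    Trial files have columns ``time_s,ml,ap``; the manifest lists
    ``participant,vision,phase,file``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth = []
    for i, traj in enumerate(trials):
        m = traj.meta
        fname = f"trial_{m['participant']}_{m['vision']}_{m['phase']}.csv"
        df = pd.DataFrame({"time_s": traj.time, "ml": traj.ml, "ap": traj.ap})
        df.to_csv(out / fname, index=False, float_format="%.6f")
        manifest_rows.append(
            {
                "participant": m["participant"],
                "vision": m["vision"],
                "phase": m["phase"],
                "file": fname,
            }
        )
        truth.append({k: v for k, v in m.items()})
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out / "manifest.csv"
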