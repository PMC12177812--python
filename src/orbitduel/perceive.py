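"""Cue-weighted prediction of the perceived target trajectory.

The perceived path is modelled as a weighted average of two cues carried
in different reference frames:

    perceived = k * eye_centered + (1 - k) * relative

applied to displacement vectors and re-anchored at the target centre.
The weight k reflects the relative reliability of the two cues and
depends on where the eyes are: pursuing the target favours the
eye-centered cue (0.5 < k < 1), pursuing an inducer favours the relative
cue (0 < k < 0.5), and peripheral fixation weights them about equally
(k = 0.5).  Defaults here are the midpoints of those intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import (EyeTrace, ViewingCondition, eye_centered_path, eye_trace,
                     relative_path, retinal_path)
from .kinematics import StimulusConfig, Trajectory

__all__ = [
    "WeightingParams",
    "perceived_path",
    "k_from_reliabilities",
    "default_k",
    "predict_perceived",
    "FramePaths",
    "compute_frames",
]

#: Default cue weight per viewing mode (midpoints of the qualitative
#: intervals: equal weighting when fixating peripherally, eye-centered
#: dominance under target pursuit, relative dominance under inducer pursuit).
DEFAULT_K = {"fixate": 0.5, "pursue_target": 0.75, "pursue_inducer": 0.25}


@dataclass(frozen=True)
class WeightingParams:
    """Cue weight k in [0, 1], optionally derived from cue precisions."""

    k: float
    precision_ec: float | None = None
    precision_rel: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"k must be in [0, 1], got {self.k}")

    @classmethod
    def from_reliabilities(cls, precision_ec: float, precision_rel: float) -> "WeightingParams":
        return cls(k=k_from_reliabilities(precision_ec, precision_rel),
                   precision_ec=precision_ec, precision_rel=precision_rel)


def k_from_reliabilities(precision_ec: float, precision_rel: float) -> float:
    """Reliability-weighted cue weight: k = p_ec / (p_ec + p_rel)."""
    if precision_ec <= 0 or precision_rel <= 0:
        raise ValueError("precisions must be > 0")
    return precision_ec / (precision_ec + precision_rel)


def default_k(condition: ViewingCondition) -> float:
    """Condition-dependent default cue weight."""
    return DEFAULT_K[condition.mode]


def perceived_path(ec: Trajectory, rel: Trajectory, w: WeightingParams | float) -> Trajectory:
    """Weighted combination of the eye-centered and relative paths.

    Acts on displacements and re-anchors the result at the (shared)
    target anchor.
    """
    k = w.k if isinstance(w, WeightingParams) else float(w)
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must be in [0, 1], got {k}")
    if not ec.same_time_base(rel):
        raise ValueError("eye-centered and relative paths are on different time bases")
    disp = k * ec.displacements() + (1.0 - k) * rel.displacements()
    return Trajectory(frame="perceived", anchor=ec.anchor, t=ec.t,
                      xy=ec.anchor + disp,
                      provenance={**ec.provenance, "k": k})


@dataclass
class FramePaths:
    """All intermediate paths of the model for one stimulus x condition."""

    target_world: Trajectory
    eyes: EyeTrace
    target_retinal: Trajectory
    target_ec: Trajectory
    inducer_world: Trajectory | None
    inducer_ec: Trajectory | None
    relative: Trajectory | None


def compute_frames(stimulus: StimulusConfig, condition: ViewingCondition,
                   check_inducers: bool = True) -> FramePaths:
    """Run the reference-frame cascade for a stimulus under a condition.

    The relative path is computed from inducer 0; with ``check_inducers``
    the synchrony of the other inducers is asserted (their displacement
    traces must agree to ~1e-9 of the orbit radius) rather than averaged.
    """
    tw = stimulus.target_trajectory()
    eyes = eye_trace(condition, stimulus)
    tr = retinal_path(tw, eyes)
    tec = eye_centered_path(tr, eyes)
    if stimulus.n_inducers == 0:
        return FramePaths(tw, eyes, tr, tec, None, None, None)
    iw = stimulus.inducer_trajectory(0)
    iec = eye_centered_path(retinal_path(iw, eyes), eyes)
    rel = relative_path(tec, iec)
    if check_inducers:
        tol = 1e-9 * stimulus.target.radius
        d0 = iec.displacements()
        for j in range(1, stimulus.n_inducers):
            other = eye_centered_path(retinal_path(stimulus.inducer_trajectory(j), eyes), eyes)
            if not np.allclose(other.displacements(), d0, atol=tol):
                raise AssertionError(f"inducer {j} is not synchronous with inducer 0")
    return FramePaths(tw, eyes, tr, tec, iw, iec, rel)


def predict_perceived(stimulus: StimulusConfig, condition: ViewingCondition,
                      k: float | None = None) -> Trajectory:
    """Predicted perceived target trajectory for a stimulus and condition.

    ``k`` defaults to the condition-dependent value.  The result is
    re-anchored at the target's world centre; with no inducers there is
    no relative cue and the prediction is the eye-centered path itself.
    """
    if k is None:
        k = default_k(condition)
    paths = compute_frames(stimulus, condition)
    center = np.asarray(stimulus.target.center)
    if paths.relative is None:
        disp = paths.target_ec.displacements()
        k_used = 1.0
    else:
        p = perceived_path(paths.target_ec, paths.relative, k)
        disp = p.displacements()
        k_used = k
    return Trajectory(frame="perceived", anchor=center, t=paths.target_world.t,
                      xy=center + disp,
                      provenance={"preset": stimulus.name, "condition": condition.mode,
                                  "k": k_used})
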