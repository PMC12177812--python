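"""Viewing conditions, eye traces, and reference-frame transforms.

The perceived-path model needs the target (and inducer) trajectories
expressed in three frames:

* retinal — world position minus eye position;
* eye-centered — retinal position plus an efference copy of the eye's
  own displacement (with a perfect efference copy this recovers the
  world path up to a constant translation);
* relative — difference between the eye-centered displacements of the
  target and the synchronously moving inducers.

Pursuit is modelled as zero-lag-by-default sinusoidal tracking with a
scalar gain: the eye orbits the pursued object's centre at ``gain``
times the object's orbital radius.  Latency clamps at t=0 rather than
extrapolating backwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import OrbitSpec, StimulusConfig, Trajectory, orbit_position

__all__ = [
    "ViewingCondition",
    "EyeTrace",
    "eye_trace",
    "retinal_path",
    "eye_centered_path",
    "relative_path",
    "FIXATE",
    "PURSUE_TARGET",
]

_MODES = ("fixate", "pursue_target", "pursue_inducer")


@dataclass(frozen=True)
class ViewingCondition:
    """Where the eyes are during a trial.

    ``mode`` is "fixate", "pursue_target" or "pursue_inducer" (with
    ``inducer_index`` 0-3).  ``pursuit_gain`` is the ratio of eye to
    object velocity (1 = perfect tracking, forced to 0 when fixating);
    ``pursuit_latency`` is a tracking delay in seconds; ``efference_gain``
    scales the efference copy of the eye displacement (1 = perfect).
    """

    mode: str = "fixate"
    fixation_point: tuple[float, float] = (0.0, 0.0)
    inducer_index: int = 0
    pursuit_gain: float = 1.0
    pursuit_latency: float = 0.0
    efference_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not 0.0 <= self.pursuit_gain <= 1.0:
            raise ValueError("pursuit_gain must be in [0, 1]")
        if not 0.0 <= self.efference_gain <= 1.5:
            raise ValueError("efference_gain must be in [0, 1.5]")
        if self.pursuit_latency < 0:
            raise ValueError("pursuit_latency must be >= 0")
        if self.mode == "fixate":
            object.__setattr__(self, "pursuit_gain", 0.0)


FIXATE = ViewingCondition(mode="fixate")
PURSUE_TARGET = ViewingCondition(mode="pursue_target")


def pursue_inducer(index: int = 0, **kw) -> ViewingCondition:
    return ViewingCondition(mode="pursue_inducer", inducer_index=index, **kw)


@dataclass
class EyeTrace:
    """Eye position and efference-copy samples on the stimulus time base.

    The efference vector is ``efference_gain`` times the eye's
    displacement from its own starting position.
    """

    t: np.ndarray
    eye: np.ndarray        # (n, 2) eye position
    efference: np.ndarray  # (n, 2) efference copy of eye displacement

    def same_time_base(self, traj: Trajectory, tol: float = 1e-9) -> bool:
        return self.t.shape == traj.t.shape and bool(np.allclose(self.t, traj.t, atol=tol))


def eye_trace(condition: ViewingCondition, stimulus: StimulusConfig) -> EyeTrace:
    """Simulate the eye for a viewing condition over a stimulus.

    Fixation holds the eye at the fixation point with zero efference.
    Pursuit follows ``eye(t) = c + g * (pos_obj(max(t - tau, 0)) - c)``
    where ``c`` is the pursued object's orbit centre.
    """
    t = stimulus.t
    if condition.mode == "fixate":
        eye = np.broadcast_to(np.asarray(condition.fixation_point, float), (t.size, 2)).copy()
    else:
        if condition.mode == "pursue_target":
            spec: OrbitSpec = stimulus.target
        else:
            spec = stimulus.inducer_spec(condition.inducer_index)
        t_eff = np.maximum(t - condition.pursuit_latency, 0.0)
        center = np.asarray(spec.center)
        eye = center + condition.pursuit_gain * (orbit_position(spec, t_eff) - center)
    efference = condition.efference_gain * (eye - eye[0])
    return EyeTrace(t=t, eye=eye, efference=efference)


def _require_same_base(traj: Trajectory, eyes: EyeTrace) -> None:
    if not eyes.same_time_base(traj):
        raise ValueError("trajectory and eye trace are on different time bases")


def retinal_path(world: Trajectory, eyes: EyeTrace) -> Trajectory:
    """Project a world trajectory onto the retina: world minus eye."""
    _require_same_base(world, eyes)
    return world.with_frame("retinal", anchor=world.anchor - eyes.eye[0],
                            xy=world.xy - eyes.eye)


def eye_centered_path(retinal: Trajectory, eyes: EyeTrace) -> Trajectory:
    """Reconstruct the eye-centered path: retinal plus efference copy."""
    _require_same_base(retinal, eyes)
    return retinal.with_frame("eye_centered", xy=retinal.xy + eyes.efference)


def relative_path(target_ec: Trajectory, inducer_ec: Trajectory) -> Trajectory:
    """Relative motion of the target with respect to the inducers.

    Pointwise difference of displacements (each path's positions minus
    its own anchor), re-anchored at the target anchor, so the inducer
    centre geometry does not enter.  Because the inducers move
    synchronously the result is the same for all four.
    """
    if not target_ec.same_time_base(inducer_ec):
        raise ValueError("target and inducer paths are on different time bases")
    disp = target_ec.displacements() - inducer_ec.displacements()
    return Trajectory(frame="relative", anchor=target_ec.anchor,
                      t=target_ec.t, xy=target_ec.anchor + disp,
                      provenance=dict(target_ec.provenance))
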