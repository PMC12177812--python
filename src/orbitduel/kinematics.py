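"""Orbit kinematics for dueling-orbit stimuli.

A stimulus consists of a small target disc orbiting a central point and
four large inducer discs, each orbiting its own centre, all four moving
synchronously.  Everything here lives in world coordinates: mathematical
y-up axes, arbitrary screen units.  Phase is measured clockwise from the
top (12 o'clock) of an orbit, so phase 0 at t=0 puts an object at its
highest orbital position, matching the standard starting configuration
of these displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "OrbitSpec",
    "StimulusConfig",
    "Trajectory",
    "orbit_position",
    "sample_trajectory",
    "common_period",
    "make_preset",
    "PRESET_NAMES",
]

# Frame labels a Trajectory may carry.
FRAMES = ("world", "retinal", "eye_centered", "relative", "perceived")


@dataclass(frozen=True)
class OrbitSpec:
    """Circular orbit: centre, radius, period, direction, starting phase.

    ``direction`` is "CW" or "CCW" as seen by the viewer (y-up axes).
    ``phase0`` is in degrees, measured clockwise from the top of the
    orbit and normalised to [0, 360).
    """

    center: tuple[float, float]
    radius: float
    period: float
    direction: str = "CW"
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        if self.direction not in ("CW", "CCW"):
            raise ValueError(f"direction must be 'CW' or 'CCW', got {self.direction!r}")
        object.__setattr__(self, "phase0", float(self.phase0) % 360.0)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def sign(self) -> int:
        """+1 for clockwise, -1 for counter-clockwise."""
        return 1 if self.direction == "CW" else -1

    def to_dict(self) -> dict:
        return {
            "center": [self.center[0], self.center[1]],
            "radius": self.radius,
            "period_s": self.period,
            "direction": self.direction,
            "phase0_deg": self.phase0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrbitSpec":
        return cls(
            center=tuple(d.get("center", (0.0, 0.0))),
            radius=d["radius"],
            period=d["period_s"],
            direction=d.get("direction", "CW"),
            phase0=d.get("phase0_deg", 0.0),
        )


def orbit_position(spec: OrbitSpec, t) -> np.ndarray:
    """World position(s) on the orbit at time(s) ``t``.

    The phase angle is ``alpha = phase0 + sign * 360 * t / period`` and the
    position is ``center + radius * (sin alpha, cos alpha)``, so alpha
    increases clockwise from the top in y-up coordinates.

    Returns shape (2,) for scalar ``t`` and (n, 2) for an array.
    """
    t = np.asarray(t, dtype=float)
    alpha = np.deg2rad(spec.phase0 + spec.sign * 360.0 * t / spec.period)
    xy = np.stack([np.sin(alpha), np.cos(alpha)], axis=-1) * spec.radius
    return xy + np.asarray(spec.center)


@dataclass
class Trajectory:
    """Uniformly sampled 2-D path with a declared reference frame.

    ``anchor`` is the path's nominal centre (the point displacements are
    measured from); ``t`` is strictly increasing with uniform spacing and
    half-open over the sampled interval, so a closed periodic curve does
    not duplicate its start point.
    """

    frame: str
    anchor: np.ndarray
    t: np.ndarray
    xy: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}; expected one of {FRAMES}")
        self.anchor = np.asarray(self.anchor, dtype=float).reshape(2)
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.t.size, 2):
            raise ValueError("xy must have shape (len(t), 2)")
        dts = np.diff(self.t)
        if self.t.size > 1 and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-9)):
            raise ValueError("t must be strictly increasing and uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    @property
    def n(self) -> int:
        return self.t.size

    def displacements(self) -> np.ndarray:
        """Positions relative to the anchor, shape (n, 2)."""
        return self.xy - self.anchor

    def with_frame(self, frame: str, anchor=None, xy=None, **prov) -> "Trajectory":
        return Trajectory(
            frame=frame,
            anchor=self.anchor if anchor is None else anchor,
            t=self.t,
            xy=self.xy if xy is None else xy,
            provenance={**self.provenance, **prov},
        )

    def same_time_base(self, other: "Trajectory", tol: float = 1e-9) -> bool:
        return self.t.shape == other.t.shape and bool(np.allclose(self.t, other.t, atol=tol))


def _check_sampling(duration: float, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if duration < dt:
        raise ValueError(f"duration ({duration}) must be >= dt ({dt})")
    n = duration / dt
    n_int = round(n)
    if abs(n - n_int) > 1e-6 * max(1.0, n_int):
        raise ValueError(f"duration/dt must be an integer, got {n}")
    return np.arange(n_int) * dt


def sample_trajectory(spec: OrbitSpec, duration: float, dt: float) -> Trajectory:
    """Half-open uniform sampling of the orbit on [0, duration)."""
    t = _check_sampling(duration, dt)
    return Trajectory(frame="world", anchor=np.asarray(spec.center), t=t,
                      xy=orbit_position(spec, t))


def common_period(target: OrbitSpec, inducer: OrbitSpec, max_den: int = 64) -> float:
    """Least time after which both orbits are simultaneously back at start.

    Requires the period ratio to be a reduced fraction p/q with
    p, q <= ``max_den``; with target period T1 = p*u and inducer period
    T2 = q*u the answer is lcm(T1, T2) = q*T1 = p*T2.
    """
    ratio = target.period / inducer.period
    frac = Fraction(ratio).limit_denominator(max_den)
    if frac.numerator <= 0 or frac.numerator > max_den:
        raise ValueError(
            f"period ratio {ratio} not expressible as p/q with p,q <= {max_den}; "
            "use rational speed ratios"
        )
    if not math.isclose(float(frac), ratio, rel_tol=1e-9):
        raise ValueError(
            f"period ratio {ratio} is not (close to) a simple rational; "
            "use rational speed ratios so a common repeat period exists"
        )
    return frac.denominator * target.period


@dataclass
class StimulusConfig:
    """Target orbit plus a shared inducer-orbit template and its centres.

    All inducers follow one template (synchronous motion), each about its
    own centre.  ``duration``/``dt`` define the half-open sampling grid
    shared by every trajectory derived from this stimulus.
    """

    target: OrbitSpec
    inducer_centers: list[tuple[float, float]]
    inducer_orbit: OrbitSpec | None
    duration: float
    dt: float
    name: str = "custom"
    ring_radius: float | None = None
    inferred: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.inducer_orbit is None) != (len(self.inducer_centers) == 0):
            raise ValueError("inducer_orbit and inducer_centers must be supplied together")
        _check_sampling(self.duration, self.dt)
        if self.target.period / self.dt < 64:
            raise ValueError("need at least 64 samples per target period")

    @property
    def n_inducers(self) -> int:
        return len(self.inducer_centers)

    @property
    def t(self) -> np.ndarray:
        return _check_sampling(self.duration, self.dt)

    def inducer_spec(self, index: int) -> OrbitSpec:
        if not 0 <= index < self.n_inducers:
            raise IndexError(f"inducer index {index} out of range (have {self.n_inducers})")
        return replace(self.inducer_orbit, center=tuple(self.inducer_centers[index]))

    def target_trajectory(self) -> Trajectory:
        return sample_trajectory(self.target, self.duration, self.dt)

    def inducer_trajectory(self, index: int = 0) -> Trajectory:
        return sample_trajectory(self.inducer_spec(index), self.duration, self.dt)

    def common_period(self) -> float:
        if self.inducer_orbit is None:
            return self.target.period
        return common_period(self.target, self.inducer_orbit)

    def to_dict(self) -> dict:
        d = {
            "target": self.target.to_dict(),
            "duration_s": self.duration,
            "dt_s": self.dt,
            "name": self.name,
        }
        if self.inducer_orbit is not None:
            orbit = self.inducer_orbit.to_dict()
            orbit.pop("center")
            d["inducers"] = {
                "centers": [list(c) for c in self.inducer_centers],
                "ring_radius": self.ring_radius,
                "orbit": orbit,
            }
        else:
            d["inducers"] = None
        if self.inferred:
            d["inferred"] = list(self.inferred)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusConfig":
        target = OrbitSpec.from_dict(d["target"])
        ind = d.get("inducers")
        if ind is None:
            centers: list[tuple[float, float]] = []
            orbit = None
            ring = None
        else:
            orbit_d = dict(ind["orbit"])
            orbit_d.setdefault("center", (0.0, 0.0))
            orbit = OrbitSpec.from_dict(orbit_d)
            ring = ind.get("ring_radius")
            if "centers" in ind:
                centers = [tuple(c) for c in ind["centers"]]
            else:
                centers = _cardinal_centers(target.center, float(ring))
        return cls(
            target=target,
            inducer_centers=centers,
            inducer_orbit=orbit,
            duration=d["duration_s"],
            dt=d["dt_s"],
            name=d.get("name", "custom"),
            ring_radius=ring,
            inferred=tuple(d.get("inferred", ())),
        )


def _cardinal_centers(center: Sequence[float], ring_radius: float) -> list[tuple[float, float]]:
    cx, cy = center
    return [
        (cx, cy + ring_radius),   # top
        (cx + ring_radius, cy),   # right
        (cx, cy - ring_radius),   # bottom
        (cx - ring_radius, cy),   # left
    ]


PRESET_NAMES = ("movie1", "movie2", "movie3", "movie4", "movie5", "movie6")

# (inducer direction, inducer phase0 deg, target-period factor, inducer-period
# factor, inferred parameters).  The base variant has inducers counter-rotating
# at matched speed and phase; the others change exactly one motion component.
# Where the original descriptions leave a component unstated, the preset keeps
# the unique value reproducing the reported percept shape and flags it.
_PRESETS: dict[str, tuple[str | None, float, float, float, tuple[str, ...]]] = {
    "movie1": (None, 0.0, 1.0, 1.0, ()),
    "movie2": ("CCW", 0.0, 1.0, 1.0, ()),
    "movie3": ("CCW", 180.0, 1.0, 1.0, ()),
    "movie4": ("CW", 180.0, 1.0, 1.0, ("inducer_phase0",)),
    # inducers 1.5x the target's angular speed
    "movie5": ("CCW", 0.0, 1.0, 2.0 / 3.0, ("inducer_direction",)),
    # target at half the inducers' angular speed
    "movie6": ("CCW", 0.0, 2.0, 1.0, ("inducer_direction",)),
}


def make_preset(
    name: str,
    *,
    target_radius: float = 1.0,
    ring_radius: float = 3.0,
    inducer_radius: float = 1.0,
    base_period: float = 2.0,
    center: tuple[float, float] = (0.0, 0.0),
    dt: float | None = None,
    samples_per_common_period: int = 720,
) -> StimulusConfig:
    """Build one of the six standard dueling-orbit configurations.

    movie1: target alone (CW from the top).  movie2: four counter-rotating
    inducers, matched speed and phase.  movie3: movie2 with the inducer
    phase offset by 180 deg.  movie4: co-rotating inducers (180 deg phase).
    movie5: inducers at 1.5x the target speed.  movie6: target at half the
    inducer speed.  Duration is always the common repeat period; default
    sampling is 720 points per common period.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    direction, phase0, t_fac, i_fac, inferred = _PRESETS[name]
    target = OrbitSpec(center=center, radius=target_radius,
                       period=base_period * t_fac, direction="CW", phase0=0.0)
    if direction is None:
        centers: list[tuple[float, float]] = []
        orbit = None
        duration = target.period
    else:
        orbit = OrbitSpec(center=(0.0, 0.0), radius=inducer_radius,
                          period=base_period * i_fac, direction=direction, phase0=phase0)
        centers = _cardinal_centers(center, ring_radius)
        duration = common_period(target, orbit)
    if dt is None:
        dt = duration / samples_per_common_period
    return StimulusConfig(
        target=target,
        inducer_centers=centers,
        inducer_orbit=orbit,
        duration=duration,
        dt=dt,
        name=name,
        ring_radius=None if direction is None else ring_radius,
        inferred=inferred,
    )
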