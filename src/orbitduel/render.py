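"""Schematic rasterisation of dueling-orbit stimuli.

Draws plain grayscale discs at the world positions of the target and
inducers, frame by frame, with optional overlays of the veridical and
predicted paths.  World coordinates are mathematical y-up; the flip to
raster y-down happens only here, at pixel-mapping time.  Output is a
PNG frame sequence or an animated GIF; rendering is deterministic for
fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .kinematics import StimulusConfig, Trajectory, orbit_position

__all__ = ["RenderSpec", "render_frames", "save_gif", "required_canvas_px"]


@dataclass(frozen=True)
class RenderSpec:
    """How to rasterise a stimulus."""

    canvas_px: int = 384
    background: int = 128          # 0-255 luminance
    target_disc_radius: float = 0.4    # world units ("small" target)
    inducer_disc_radius: float = 1.0   # world units ("large" inducers)
    target_luminance: int = 255
    inducer_luminance: int = 0
    fps: float = 30.0
    margin_frac: float = 0.05
    overlay_veridical: bool = False
    overlay_predicted: bool = False
    overlay_luminance: int = 200


def _world_extent(stimulus: StimulusConfig, spec: RenderSpec) -> float:
    """Half-width (world units) of the square region the stimulus occupies."""
    extent = stimulus.target.radius + spec.target_disc_radius
    if stimulus.inducer_orbit is not None:
        cx, cy = stimulus.target.center
        ring = max(np.hypot(x - cx, y - cy) for x, y in stimulus.inducer_centers)
        extent = max(extent, ring + stimulus.inducer_orbit.radius + spec.inducer_disc_radius)
    return extent


def required_canvas_px(stimulus: StimulusConfig, spec: RenderSpec,
                       min_px_per_unit: float = 16.0) -> int:
    """Smallest canvas that renders the stimulus at a usable resolution."""
    extent = _world_extent(stimulus, spec)
    return int(np.ceil(2 * extent * (1 + 2 * spec.margin_frac) * min_px_per_unit))


class _Mapper:
    """World (y-up) to raster (y-down) pixel mapping."""

    def __init__(self, stimulus: StimulusConfig, spec: RenderSpec):
        extent = _world_extent(stimulus, spec)
        self.scale = spec.canvas_px / (2 * extent * (1 + 2 * spec.margin_frac))
        self.center = np.asarray(stimulus.target.center, float)
        self.half = spec.canvas_px / 2.0

    def to_px(self, xy: np.ndarray) -> np.ndarray:
        rel = (np.atleast_2d(xy) - self.center) * self.scale
        return np.column_stack([self.half + rel[:, 0], self.half - rel[:, 1]])


def _disc(draw: ImageDraw.ImageDraw, cpx: np.ndarray, r_px: float, lum: int) -> None:
    x, y = float(cpx[0]), float(cpx[1])
    draw.ellipse([x - r_px, y - r_px, x + r_px, y + r_px], fill=lum)


def render_frames(stimulus: StimulusConfig, spec: RenderSpec = RenderSpec(),
                  predicted: Trajectory | None = None,
                  times: np.ndarray | None = None) -> list[Image.Image]:
    """Rasterise a stimulus; returns a list of PIL images.

    By default one frame per stimulus sample; pass ``times`` (e.g. a
    half-open grid at 1/fps) to render at a display frame rate instead.
    ``predicted`` (a perceived-path trajectory) is drawn as a polyline
    overlay when ``spec.overlay_predicted`` is set.
    """
    need = required_canvas_px(stimulus, spec)
    if spec.canvas_px < need:
        raise ValueError(
            f"canvas {spec.canvas_px}px too small for this stimulus; need >= {need}px")
    mapper = _Mapper(stimulus, spec)
    t = stimulus.t if times is None else np.asarray(times, float)
    target_px = mapper.to_px(orbit_position(stimulus.target, t))
    inducer_px = [mapper.to_px(orbit_position(stimulus.inducer_spec(j), t))
                  for j in range(stimulus.n_inducers)]
    overlays: list[np.ndarray] = []
    if spec.overlay_veridical:
        overlays.append(mapper.to_px(stimulus.target_trajectory().xy))
    if spec.overlay_predicted and predicted is not None:
        overlays.append(mapper.to_px(predicted.xy))
    frames = []
    for i in range(t.size):
        img = Image.new("L", (spec.canvas_px, spec.canvas_px), color=spec.background)
        draw = ImageDraw.Draw(img)
        for pts in overlays:
            draw.line([tuple(p) for p in pts] + [tuple(pts[0])],
                      fill=spec.overlay_luminance, width=1)
        for ind in inducer_px:
            _disc(draw, ind[i], spec.inducer_disc_radius * mapper.scale,
                  spec.inducer_luminance)
        _disc(draw, target_px[i], spec.target_disc_radius * mapper.scale,
              spec.target_luminance)
        frames.append(img)
    return frames


def save_gif(frames: list[Image.Image], path: str | Path, fps: float = 30.0) -> None:
    frames[0].save(Path(path), save_all=True, append_images=frames[1:],
                   duration=max(1, int(round(1000.0 / fps))), loop=0)
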