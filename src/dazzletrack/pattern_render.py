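"""Stimulus coloration textures and frame rasterization.

Three achromatic target colorations: a trinary noise pattern (the same
process as the screen background) and 100%-contrast square-wave gratings of
wavelength 8 px whose stripes are oriented orthogonal or parallel to the
square's instantaneous direction of motion. Intensities live in [0, 1].

Gratings are evaluated analytically on a rotated coordinate, so orienting a
texture never accumulates resampling error; trinary textures have no
orientation and pass through `orient_texture` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

GRATING_KINDS = ("orthogonal_grating", "parallel_grating")


@dataclass(frozen=True)
class Texture:
    """A square texture patch.

    ``pixels[row, col]`` with row 0 the *top* of the patch (raster
    convention); intensities in [0, 1]. Gratings carry their generating
    parameters so they can be re-oriented exactly.
    """

    pixels: np.ndarray
    kind: str
    wavelength: float | None = None
    phase: float = 0.0
    orientation: float = 0.0  # direction (radians) along which intensity varies

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class FrameRaster:
    """One rasterized screen frame plus its provenance."""

    pixels: np.ndarray
    trial_id: str = ""
    frame_index: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def make_trinary_texture(side: int, element: int = 2, rng=None) -> Texture:
    """I.i.d. equiprobable three-level {0, 1/2, 1} noise in element-sized blocks."""
    if rng is None:
        rng = np.random.default_rng()
    if side % element != 0:
        raise ValueError(f"side {side} not divisible by element {element}")
    cells = rng.integers(0, 3, size=(side // element, side // element))
    pixels = np.kron(cells, np.ones((element, element))) / 2.0
    return Texture(pixels=pixels, kind="trinary")


def _square_wave(u: np.ndarray, wavelength: float, phase: float) -> np.ndarray:
    """Duty-cycle-1/2 square wave on coordinate ``u``: levels {0, 1}."""
    return (np.floor((u + phase) / (wavelength / 2.0)) % 2).astype(float)


def make_grating_texture(side: int, wavelength: float = 8.0, phase: float = 0.0) -> Texture:
    """Axis-aligned 100%-contrast square-wave grating.

    Intensity varies along the x (column) axis, so stripe contours run
    vertically; use `orient_texture` to align stripes with a heading.
    """
    if wavelength < 2:
        raise ValueError("wavelength must be >= 2 px")
    cols = np.arange(side, dtype=float)
    row = _square_wave(cols, wavelength, phase)
    pixels = np.tile(row, (side, 1))
    return Texture(
        pixels=pixels,
        kind="orthogonal_grating",
        wavelength=wavelength,
        phase=phase,
        orientation=0.0,
    )


def orient_texture(texture: Texture, heading: float, mode: str) -> Texture:
    """Re-orient a grating relative to a motion heading.

    ``orthogonal``: stripe contours perpendicular to the motion (intensity
    varies along the heading). ``parallel``: contours along the motion
    (intensity varies perpendicular to it). Trinary textures are isotropic
    and returned unchanged.
    """
    if texture.kind == "trinary":
        return texture
    if mode not in ("orthogonal", "parallel"):
        raise ValueError(f"unknown orientation mode: {mode!r}")
    if texture.wavelength is None:
        raise ValueError("grating texture lacks wavelength metadata")

    axis = heading if mode == "orthogonal" else heading + np.pi / 2.0
    side = texture.side
    # pixel-centre coordinates, y up, origin at patch centre
    c = (side - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(side), np.arange(side))
    xs = jj - c
    ys = c - ii
    u = xs * np.cos(axis) + ys * np.sin(axis)
    pixels = _square_wave(u, texture.wavelength, texture.phase)
    return Texture(
        pixels=pixels,
        kind=f"{mode}_grating",
        wavelength=texture.wavelength,
        phase=texture.phase,
        orientation=axis % (2.0 * np.pi),
    )


def texture_for(coloration: str, side: int, heading: float = 0.0,
                wavelength: float = 8.0, element: int = 2, rng=None) -> Texture:
    """Build the texture for a coloration condition at a given heading."""
    if coloration == "trinary":
        return make_trinary_texture(side, element=element, rng=rng)
    base = make_grating_texture(side, wavelength=wavelength)
    return orient_texture(base, heading, mode=coloration)


def render_frame(
    states,
    textures,
    background: np.ndarray,
    screen_shape: tuple[int, int] | None = None,
    trial_id: str = "",
    frame_index: int = 0,
) -> FrameRaster:
    """Rasterize one frame: background first, agents in ascending id order.

    ``states`` is a sequence of objects with ``x``/``y`` attributes (px,
    arena-centred, y up); ``textures`` a matching sequence of Textures.
    Later ids occlude earlier ones. An agent whose square would extend
    beyond the screen is rejected.
    """
    pixels = np.array(background, dtype=float, copy=True)
    if screen_shape is not None and pixels.shape != tuple(screen_shape):
        raise ValueError("background does not match screen_shape")
    h, w = pixels.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    for i, (st, tex) in enumerate(zip(states, textures)):
        side = tex.side
        col0 = int(round(cx + st.x - side / 2.0))
        row0 = int(round(cy - st.y - side / 2.0))
        if col0 < 0 or row0 < 0 or col0 + side > w or row0 + side > h:
            raise ValueError(
                f"agent {i} at ({st.x:.1f}, {st.y:.1f}) extends beyond the screen"
            )
        pixels[row0 : row0 + side, col0 : col0 + side] = tex.pixels
    return FrameRaster(pixels=pixels, trial_id=trial_id, frame_index=frame_index)


def render_trajectory_frame(traj, frame: int, screen_side: int | None = None,
                            element: int = 2, rng=None) -> FrameRaster:
    """Render one frame of a simulated trial on a trinary background."""
    cfg = traj.config
    if screen_side is None:
        screen_side = int(cfg.arena_side + 2 * cfg.square_side)
        screen_side += screen_side % 2  # keep element tiling even
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    background = make_trinary_texture(screen_side, element=element, rng=rng).pixels
    states = [traj.state(frame, a) for a in range(traj.n_agents)]
    side = int(cfg.square_side)
    textures = [
        texture_for(cfg.coloration, side, heading=traj.heading[frame, a], rng=rng)
        for a in range(traj.n_agents)
    ]
    return render_frame(states, textures, background,
                        trial_id=f"seed{cfg.seed}", frame_index=frame)


def texture_to_csv(texture: Texture, path) -> None:
    """Write a texture's intensity grid as CSV (one row per pixel row)."""
    np.savetxt(path, texture.pixels, fmt="%.3f", delimiter=",")


def save_png(raster: FrameRaster, path) -> None:
    from PIL import Image

    arr = np.clip(raster.pixels * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
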