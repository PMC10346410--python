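"""Synthetic tree-scene generator with exact morphometric ground truth.

Scenes emulate the structure of field imagery of a tall conifer: one or
more thick near-vertical trunk strokes plus thinner branch strokes at
known angles and lengths, over a cluttered background.  Strokes are
rasterized without anti-aliasing as a Bresenham axis dilated by a
square footprint, so the axis pixel count — the quantity the
skeleton-based length measurement estimates — is known exactly per
stroke (see :func:`_square_footprint` for why square, not round).

Photometric condition tags (sunny / rainy / night / snowy / foggy /
typhoon) perturb only the RGB rendering — brightness, contrast, noise,
speckle, or a motion streak — and never the class mask, so a single
geometric scene can be re-rendered across weather conditions with
identical ground truth.

The generator exists to exercise the segmentation model and the
morphometry pipeline end to end; it makes no attempt at photorealism
(no foliage, occlusion or perspective).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from . import io as bio
from .morphometry import BRANCH, CLASS_NAMES, TRUNK

__all__ = [
    "Stroke",
    "SceneSpec",
    "GroundTruthStroke",
    "CONDITIONS",
    "render_stroke_axis",
    "render_scene",
    "random_scene",
    "make_dataset",
]

CONDITIONS = ("sunny", "rainy", "night", "snowy", "foggy", "typhoon")


@dataclass(frozen=True)
class Stroke:
    """A thick line segment: start point, axis length, angle, width.

    ``angle_deg`` is measured from the horizontal with y up (same
    convention the morphometry pipeline reports); ``length_px`` is the
    number of pixels on the rasterized axis.
    """

    start: tuple[int, int]  # (row, col)
    length_px: int
    angle_deg: float
    width_px: int = 3

    def __post_init__(self):
        if self.length_px < 2:
            raise ValueError("stroke axis needs at least 2 pixels")
        if self.width_px < 1:
            raise ValueError("stroke width must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene."""

    height: int = 256
    width: int = 256
    trunks: tuple[Stroke, ...] = ()
    branches: tuple[Stroke, ...] = ()
    clutter: int = 0
    clutter_size: tuple[int, int] = (3, 10)
    noise_sigma: float = 4.0
    condition: str = "sunny"
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class GroundTruthStroke:
    """Per-stroke ground truth as rendered (after clipping to bounds)."""

    class_label: int
    angle_deg: float
    length_px: int
    width_px: int

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.class_label]


def _square_footprint(width_px: int) -> np.ndarray:
    """Square structuring element of side ``width_px`` for stroke dilation.

    A square (rather than round) footprint keeps the stroke's boundary a
    digital straight line at every stroke angle.  The thinning operator
    used downstream converts boundary bumps into staircase pixels that
    inflate the skeleton count, so grid-aligned stroke edges are what
    makes the rendered axis length an exact, recoverable ground truth.
    """
    return np.ones((width_px, width_px), dtype=bool)


def render_stroke_axis(stroke: Stroke, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a stroke's axis, clipped to the image.

    Returns ``(rows, cols)`` of the axis pixels.  The endpoint is chosen
    so the unclipped Bresenham axis has exactly ``length_px`` pixels.
    Raises if the stroke falls entirely outside the image.
    """
    r0, c0 = stroke.start
    theta = np.radians(stroke.angle_deg)
    dx, dy_up = np.cos(theta), np.sin(theta)
    # scale so the dominant axis advances length_px - 1 steps
    step = max(abs(dx), abs(dy_up))
    t = (stroke.length_px - 1) / step
    r1 = int(round(r0 - dy_up * t))
    c1 = int(round(c0 + dx * t))
    rows, cols = _draw_line(r0, c0, r1, c1)
    h, w = shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not inside.any():
        raise ValueError(f"stroke {stroke} lies entirely outside a {shape} image")
    return rows[inside], cols[inside]


def _stroke_mask(stroke: Stroke, shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Binary footprint of a dilated stroke plus its clipped axis length."""
    rows, cols = render_stroke_axis(stroke, shape)
    axis = np.zeros(shape, dtype=bool)
    axis[rows, cols] = True
    footprint = ndimage.binary_dilation(axis, structure=_square_footprint(stroke.width_px))
    return footprint, int(rows.size)


_BASE_STYLE = {
    # background RGB, trunk RGB, branch RGB, brightness gain, extra noise
    "sunny": ((168, 186, 205), (96, 72, 48), (142, 112, 76), 1.0, 0.0),
    "rainy": ((120, 128, 138), (86, 66, 46), (128, 102, 72), 0.85, 6.0),
    "night": ((28, 32, 40), (60, 48, 36), (92, 76, 56), 0.9, 8.0),
    "snowy": ((208, 212, 220), (90, 70, 50), (136, 110, 78), 1.0, 3.0),
    "foggy": ((176, 180, 188), (96, 72, 48), (142, 112, 76), 1.0, 2.0),
    "typhoon": ((140, 150, 160), (92, 70, 48), (136, 108, 74), 0.9, 5.0),
}


def _photometric(rgb: np.ndarray, condition: str, rng: np.random.Generator) -> np.ndarray:
    """Condition-specific perturbation of the RGB render only."""
    out = rgb.astype(np.float64)
    if condition == "foggy":
        out = 0.45 * out + 0.55 * 230.0  # contrast collapse toward haze
    elif condition == "snowy":
        speckle = rng.random(out.shape[:2]) < 0.01
        out[speckle] = 245.0
    elif condition == "typhoon":
        # horizontal motion streak emulating wind shake during exposure
        kernel = np.ones(7) / 7.0
        out = ndimage.convolve1d(out, kernel, axis=1, mode="nearest")
    return out


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, list[GroundTruthStroke]]:
    """Render a scene to (RGB image, class mask, ground-truth records).

    Deterministic for a fixed spec (including its seed).  Branch strokes
    are painted after trunk strokes; the ground-truth length of each
    stroke is its clipped axis pixel count.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    class_mask = np.zeros(shape, dtype=np.uint8)
    truth: list[GroundTruthStroke] = []

    bg_color, trunk_color, branch_color, gain, extra_noise = _BASE_STYLE[spec.condition]
    rgb = np.empty((*shape, 3), dtype=np.float64)
    rgb[:] = bg_color
    # mild background texture so segmentation is not a constant-color lookup
    rgb += rng.normal(0.0, 6.0, size=(*shape, 1))

    for _ in range(spec.clutter):
        lo, hi = spec.clutter_size
        ry, rx = rng.integers(lo, hi + 1, size=2)
        cy = int(rng.integers(0, spec.height))
        cx = int(rng.integers(0, spec.width))
        yy, xx = np.mgrid[:spec.height, :spec.width]
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        shade = rng.uniform(-35.0, 35.0)
        rgb[blob] += shade  # background clutter never enters the class mask

    for strokes, label, color in (
        (spec.trunks, TRUNK, trunk_color),
        (spec.branches, BRANCH, branch_color),
    ):
        for stroke in strokes:
            footprint, axis_len = _stroke_mask(stroke, shape)
            class_mask[footprint] = label
            rgb[footprint] = color
            truth.append(
                GroundTruthStroke(label, stroke.angle_deg % 180.0, axis_len, stroke.width_px)
            )

    rgb = _photometric(rgb, spec.condition, rng) * gain
    sigma = spec.noise_sigma + extra_noise
    if sigma > 0:
        rgb += rng.normal(0.0, sigma, size=rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), class_mask, truth


def random_scene(
    seed: int,
    height: int = 256,
    width: int = 256,
    n_branches: tuple[int, int] = (2, 5),
    branch_length: tuple[int, int] = (40, 140),
    branch_width: tuple[int, int] = (2, 8),
    branch_angle: tuple[float, float] = (5.0, 175.0),
    condition: str = "sunny",
    clutter: int = 3,
    gap_px: int = 3,
    max_tries: int = 200,
) -> SceneSpec:
    """Draw a random scene spec with mutually disjoint strokes.

    Strokes are separated by at least ``gap_px`` background pixels so
    every rendered stroke is its own connected component and the
    ground-truth records map one-to-one onto measured instances.
    """
    rng = np.random.default_rng(seed)
    shape = (height, width)
    occupied = np.zeros(shape, dtype=bool)
    pad = _square_footprint(2 * gap_px + 1)

    def try_place(stroke: Stroke) -> bool:
        nonlocal occupied
        try:
            footprint, _ = _stroke_mask(stroke, shape)
        except ValueError:
            return False
        grown = ndimage.binary_dilation(footprint, structure=pad)
        if (grown & occupied).any():
            return False
        occupied |= grown
        return True

    trunk = Stroke(
        start=(int(height * 0.92), int(rng.integers(width // 3, 2 * width // 3))),
        length_px=int(height * 0.8),
        angle_deg=float(rng.uniform(80.0, 100.0)),
        width_px=int(rng.integers(9, 15)),
    )
    if not try_place(trunk):  # pragma: no cover - trunk always fits by construction
        raise RuntimeError("could not place trunk stroke")

    branches: list[Stroke] = []
    target = int(rng.integers(n_branches[0], n_branches[1] + 1))
    tries = 0
    margin = 6
    while len(branches) < target and tries < max_tries:
        tries += 1
        length = int(rng.integers(branch_length[0], branch_length[1] + 1))
        stroke = Stroke(
            start=(
                int(rng.integers(margin, height - margin)),
                int(rng.integers(margin, width - margin)),
            ),
            length_px=length,
            angle_deg=float(rng.uniform(*branch_angle)),
            width_px=int(rng.integers(branch_width[0], branch_width[1] + 1)),
        )
        rows, cols = render_stroke_axis(stroke, shape)
        if rows.size < stroke.length_px:  # clipped: keep strokes fully inside
            continue
        if try_place(stroke):
            branches.append(stroke)

    return SceneSpec(
        height=height,
        width=width,
        trunks=(trunk,),
        branches=tuple(branches),
        clutter=clutter,
        noise_sigma=4.0,
        condition=condition,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    height: int = 256,
    width: int = 256,
    conditions: tuple[str, ...] = ("sunny",),
    **scene_kwargs,
) -> dict:
    """Write an n-scene dataset in the VOC-style layout the trainer reads.

    Layout: ``images/<stem>.png``, ``masks/<stem>.png`` (indexed PNG),
    ``train.txt`` / ``val.txt`` split lists at a 9:1 ratio (validation
    count rounded down, but at least one item), and
    ``ground_truth.csv`` with the per-stroke records.
    """
    if n < 2:
        raise ValueError("dataset needs at least 2 scenes to split 9:1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    stems, gt_rows = [], []
    for i in range(n):
        stem = f"scene_{i:04d}"
        condition = conditions[i % len(conditions)]
        spec = random_scene(
            seed=int(rng.integers(0, 2**31 - 1)),
            height=height,
            width=width,
            condition=condition,
            **scene_kwargs,
        )
        image, mask, truth = render_scene(spec)
        bio.save_image(image, out / "images" / f"{stem}.png")
        bio.save_class_mask(mask, out / "masks" / f"{stem}.png")
        stems.append(stem)
        for k, g in enumerate(truth):
            gt_rows.append(
                f"{stem},{k},{g.class_name},{g.length_px},{g.angle_deg:.4f},{g.width_px}"
            )

    n_val = max(1, n // 10)
    val = stems[-n_val:]
    train = stems[:-n_val]
    (out / "train.txt").write_text("\n".join(train) + "\n")
    (out / "val.txt").write_text("\n".join(val) + "\n")
    header = "stem,stroke_id,class,length_px,angle_deg,width_px"
    (out / "ground_truth.csv").write_text("\n".join([header, *gt_rows]) + "\n")
    return {"dir": out, "train": train, "val": val, "n_strokes": len(gt_rows)}
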