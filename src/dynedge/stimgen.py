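"""Dynamic 1-D visual scenes: moving, flickering and static sub-images
composed around fixed or moving edges.

A scene is a time-indexed high-resolution luminance strip sampled every
``DT`` = 200 us.  The high-resolution pixel pitch equals the distance the
animated imagery travels in one time step (``speed * DT``), so motion is
realized as a one-pixel shift per step.  Flicker is texture animated
*perpendicular* to the receptor axis (columns of a 2-D texture stream past
the 1-D window), which modulates luminance in time without coherent
horizontal motion.  Static sub-images do not change.

An *edge* is a boundary between two half-fields with different image
dynamics.  Fixed edges sit exactly midway between the two central
receptors.  Moving-edge scenes contain a succession of edges sweeping left
to right at 50 deg/s, with the two image classes alternating sides; for a
"Fourier" region the internal texture moves with the boundaries, for a
"theta" region it moves opposite at equal speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .optics import INTER_RECEPTOR_ANGLE, r0_from_spacing
from .textures import (
    BLOCK_LEN,
    Texture1D,
    Texture2D,
    reject_saturated,
    synth_texture_2d,
    tile_texture_1d,
)

__all__ = [
    "DT",
    "ImageKind",
    "ImageClass",
    "EdgeKinematics",
    "ObjectType",
    "EdgeSpec",
    "StimulusScene",
    "CatalogEntry",
    "ScenarioCatalog",
    "animate_motion",
    "animate_flicker",
    "compose_scene",
    "FixedEdgeScene",
    "FullFieldScene",
    "MovingEdgeScene",
    "build_fixed_edge_catalog",
    "build_moving_edge_catalog",
]

#: integration time step [s]; one tenth of the fastest model time constant
DT = 2e-4
#: standard animation speeds [deg/s]
SPEEDS = (25.0, 50.0, 100.0)
#: speed of all moving edges and their imagery [deg/s]
EDGE_SPEED = 50.0
#: width of one image segment between successive moving edges [deg]
SEGMENT_DEG = 3.0


class ImageKind(Enum):
    MOTION_LEFT = "motion_left"
    MOTION_RIGHT = "motion_right"
    FLICKER = "flicker"
    STATIC = "static"


@dataclass(frozen=True)
class ImageClass:
    """One image-dynamics class: what the texture in a region does."""

    kind: ImageKind
    speed: Optional[float] = None  # deg/s; None for STATIC

    def __post_init__(self):
        if self.kind is ImageKind.STATIC:
            if self.speed is not None:
                raise ValueError("STATIC imagery has no speed")
        else:
            if self.speed not in SPEEDS:
                raise ValueError(f"speed must be one of {SPEEDS}")

    @property
    def label(self) -> str:
        if self.kind is ImageKind.STATIC:
            return "static"
        return f"{self.kind.value}@{self.speed:g}"

    def mirrored(self) -> "ImageClass":
        """The class seen after a left-right reflection of the scene."""
        if self.kind is ImageKind.MOTION_LEFT:
            return ImageClass(ImageKind.MOTION_RIGHT, self.speed)
        if self.kind is ImageKind.MOTION_RIGHT:
            return ImageClass(ImageKind.MOTION_LEFT, self.speed)
        return self


class EdgeKinematics(Enum):
    FIXED = "fixed"
    MOVING = "moving"


class ObjectType(Enum):
    FOURIER = "fourier"
    THETA = "theta"
    NA = "n/a"


def object_type(cls: ImageClass, kinematics: EdgeKinematics) -> ObjectType:
    """Object type of a region in a moving-edge scene.

    With edges sweeping rightward, internal texture moving right with them
    is a Fourier object; texture moving left (opposite) is a theta object.
    """
    if kinematics is not EdgeKinematics.MOVING:
        return ObjectType.NA
    if cls.kind is ImageKind.MOTION_RIGHT:
        return ObjectType.FOURIER
    if cls.kind is ImageKind.MOTION_LEFT:
        return ObjectType.THETA
    return ObjectType.NA


@dataclass(frozen=True)
class EdgeSpec:
    """Edge metadata for a scenario: class pair, kinematics, speed."""

    present: bool
    kinematics: EdgeKinematics
    left_class: ImageClass
    right_class: ImageClass
    edge_speed: Optional[float] = None  # deg/s, MOVING only

    def __post_init__(self):
        if self.present and self.kinematics is EdgeKinematics.MOVING:
            if self.edge_speed != EDGE_SPEED:
                raise ValueError(f"moving edges travel at {EDGE_SPEED} deg/s")

    @property
    def label(self) -> str:
        if not self.present:
            return f"ff:{self.left_class.label}"
        tag = "mov" if self.kinematics is EdgeKinematics.MOVING else "fix"
        return f"{tag}:{self.left_class.label}|{self.right_class.label}"

    def mirrored(self) -> "EdgeSpec":
        return EdgeSpec(
            self.present,
            self.kinematics,
            self.right_class.mirrored(),
            self.left_class.mirrored(),
            self.edge_speed,
        )


@dataclass
class StimulusScene:
    """Explicitly materialized scene: (n_steps, n_pixels) luminance frames."""

    frames: np.ndarray
    dt: float
    pixel_pitch: float
    edge: Optional[EdgeSpec] = None
    edge_position: Optional[np.ndarray] = None  # deg, MOVING only


# ---------------------------------------------------------------------------
# content sources: stream world-frame luminance for arbitrary step ranges
# ---------------------------------------------------------------------------


class _MotionSource:
    """Texture translating one pixel per step; shift=+1 moves leftward."""

    def __init__(self, n_cols, n_steps, shift, rng, pitch, block_len=BLOCK_LEN):
        self.shift = shift
        self.base = n_steps if shift < 0 else 0
        self.tex = tile_texture_1d(n_cols + n_steps, rng, block_len, pixel_pitch=pitch).values
        self.n_cols = n_cols

    def rows(self, t0, t1, j0, j1):
        sw = sliding_window_view(self.tex, j1 - j0)
        starts = self.base + self.shift * np.arange(t0, t1) + j0
        return sw[starts]


class _FlickerSource:
    """Columns of a 2-D texture streaming past the window, one row per step.

    Rows are generated block-by-block on demand (requests must come in
    non-decreasing time order) so long scenes never hold the full 2-D
    texture in memory.
    """

    def __init__(self, n_cols, rng, pitch, block_rows=BLOCK_LEN, max_redraws=50):
        self.n_cols = n_cols
        self.rng = rng
        self.pitch = pitch
        self.block_rows = block_rows
        self.max_redraws = max_redraws
        self._blocks = []  # list of (start_row, array)
        self._next_row = 0

    def _extend_to(self, row):
        while self._next_row < row:
            for _ in range(self.max_redraws):
                tex = synth_texture_2d(
                    self.block_rows, self.n_cols, self.rng, pixel_pitch=self.pitch
                )
                if not reject_saturated(tex):
                    break
            self._blocks.append((self._next_row, tex.values))
            self._next_row += self.block_rows

    def rows(self, t0, t1, j0, j1):
        self._extend_to(t1)
        self._blocks = [(s, b) for s, b in self._blocks if s + b.shape[0] > t0]
        out = np.empty((t1 - t0, j1 - j0))
        for s, b in self._blocks:
            lo, hi = max(t0, s), min(t1, s + b.shape[0])
            if lo < hi:
                out[lo - t0 : hi - t0] = b[lo - s : hi - s, j0:j1]
        return out


class _StaticSource:
    """Time-invariant texture strip."""

    def __init__(self, n_cols, rng, pitch, block_len=BLOCK_LEN):
        self.row = tile_texture_1d(n_cols, rng, block_len, pixel_pitch=pitch).values

    def rows(self, t0, t1, j0, j1):
        return np.broadcast_to(self.row[j0:j1], (t1 - t0, j1 - j0))


def _make_source(cls: ImageClass, n_cols, n_steps, rng, pitch):
    if cls.kind is ImageKind.MOTION_LEFT:
        return _MotionSource(n_cols, n_steps, +1, rng, pitch)
    if cls.kind is ImageKind.MOTION_RIGHT:
        return _MotionSource(n_cols, n_steps, -1, rng, pitch)
    if cls.kind is ImageKind.FLICKER:
        return _FlickerSource(n_cols, rng, pitch)
    return _StaticSource(n_cols, rng, pitch)


def _scene_geometry(pitch, n_receptors, spacing):
    """Even pixel count covering the receptor array plus full MTF support."""
    half_extent = (n_receptors - 1) / 2.0 * spacing + 2.0 * r0_from_spacing(spacing)
    n_half = int(math.ceil(half_extent / pitch)) + 2
    return 2 * n_half


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _scene_speed(*classes: ImageClass) -> float:
    speeds = {c.speed for c in classes if c.speed is not None}
    if len(speeds) != 1:
        raise ValueError("scene requires exactly one common animation speed")
    return speeds.pop()


# ---------------------------------------------------------------------------
# scene renderers
# ---------------------------------------------------------------------------


class FixedEdgeScene:
    """Two half-field sub-images butted together at the array center."""

    def __init__(
        self,
        left: ImageClass,
        right: ImageClass,
        n_steps: int,
        n_receptors: int,
        seed,
        dt: float = DT,
        spacing: float = INTER_RECEPTOR_ANGLE,
    ):
        speed = _scene_speed(left, right)
        self.dt = dt
        self.pixel_pitch = speed * dt
        self.n_steps = n_steps
        self.n_pixels = _scene_geometry(self.pixel_pitch, n_receptors, spacing)
        self.edge = EdgeSpec(True, EdgeKinematics.FIXED, left, right)
        half = self.n_pixels // 2
        ss = _seedseq(seed)
        rl, rr = (np.random.default_rng(s) for s in ss.spawn(2))
        self._left = _make_source(left, half, n_steps, rl, self.pixel_pitch)
        self._right = _make_source(right, half, n_steps, rr, self.pixel_pitch)

    def frames(self, t0: int, t1: int) -> np.ndarray:
        half = self.n_pixels // 2
        out = np.empty((t1 - t0, self.n_pixels))
        out[:, :half] = self._left.rows(t0, t1, 0, half)
        out[:, half:] = self._right.rows(t0, t1, 0, half)
        return out


class FullFieldScene:
    """A single image-dynamics class filling the whole visual field."""

    def __init__(
        self,
        cls: ImageClass,
        n_steps: int,
        n_receptors: int,
        seed,
        dt: float = DT,
        spacing: float = INTER_RECEPTOR_ANGLE,
    ):
        speed = _scene_speed(cls)
        self.dt = dt
        self.pixel_pitch = speed * dt
        self.n_steps = n_steps
        self.n_pixels = _scene_geometry(self.pixel_pitch, n_receptors, spacing)
        self.edge = EdgeSpec(False, EdgeKinematics.FIXED, cls, cls)
        rng = np.random.default_rng(_seedseq(seed))
        self._src = _make_source(cls, self.n_pixels, n_steps, rng, self.pixel_pitch)

    def frames(self, t0: int, t1: int) -> np.ndarray:
        return np.asarray(self._src.rows(t0, t1, 0, self.n_pixels))


class MovingEdgeScene:
    """A succession of edges sweeping rightward at 50 deg/s.

    The field is tiled with segments of width ``segment_deg`` whose contents
    alternate between two image classes; all boundaries (edges) translate
    one pixel per step.  Class A occupies even segments, class B odd ones,
    so each class appears alternately on the left and the right of
    successive edges.
    """

    def __init__(
        self,
        class_a: ImageClass,
        class_b: ImageClass,
        n_steps: int,
        n_receptors: int,
        seed,
        dt: float = DT,
        spacing: float = INTER_RECEPTOR_ANGLE,
        segment_deg: float = SEGMENT_DEG,
        edge_speed: float = EDGE_SPEED,
    ):
        self.dt = dt
        self.pixel_pitch = edge_speed * dt
        self.n_steps = n_steps
        self.n_pixels = _scene_geometry(self.pixel_pitch, n_receptors, spacing)
        self.segment_px = int(round(segment_deg / self.pixel_pitch))
        self.half_gap_px = int(round(spacing / 2.0 / self.pixel_pitch))
        if self.segment_px <= 2 * self.half_gap_px:
            raise ValueError("segments must be wider than the central gap")
        self.class_a = class_a
        self.class_b = class_b
        self.edge_speed = edge_speed
        ss = _seedseq(seed)
        ra, rb = (np.random.default_rng(s) for s in ss.spawn(2))
        self._a = _make_source(class_a, self.n_pixels, n_steps, ra, self.pixel_pitch)
        self._b = _make_source(class_b, self.n_pixels, n_steps, rb, self.pixel_pitch)
        self._phase = 0  # boundary k sits at pixel index k*segment_px + t

    def frames(self, t0: int, t1: int) -> np.ndarray:
        j = np.arange(self.n_pixels)[None, :]
        t = np.arange(t0, t1)[:, None]
        seg = (j - t - self._phase) // self.segment_px
        a = self._a.rows(t0, t1, 0, self.n_pixels)
        b = self._b.rows(t0, t1, 0, self.n_pixels)
        return np.where(seg % 2 == 0, a, b)

    def _classes_at_boundary(self, k: int):
        left = self.class_a if (k - 1) % 2 == 0 else self.class_b
        right = self.class_a if k % 2 == 0 else self.class_b
        return left, right

    def record_starts(self, t_lo: int, t_hi: int, win: int, stride: int):
        """Start steps of windows during which an edge stays strictly
        between the two central receptors, plus the classes on each side.

        Returns (starts, left_classes, right_classes).
        """
        c = self.n_pixels // 2  # pixel-boundary index of 0 deg
        g = self.half_gap_px
        P = self.segment_px
        lo_b, hi_b = c - g + 1, c + g - win  # admissible boundary pos at window start
        starts, lefts, rights = [], [], []
        for t in range(t_lo, min(t_hi, self.n_steps - win) + 1, stride):
            r = (self._phase + t) % P
            d = (r - lo_b) % P
            if d <= hi_b - lo_b:
                i = lo_b + d  # boundary pixel index at window start
                k = (i - self._phase - t) // P
                left, right = self._classes_at_boundary(k)
                starts.append(t)
                lefts.append(left)
                rights.append(right)
        return np.asarray(starts, dtype=np.int64), lefts, rights

    def edge_position(self, t: int) -> float:
        """Angular position (deg) of the edge nearest the array center."""
        c = self.n_pixels // 2
        r = (self._phase + t - c) % self.segment_px
        d = r if r <= self.segment_px - r else r - self.segment_px
        return d * self.pixel_pitch


# ---------------------------------------------------------------------------
# explicit spec-level operations (small scenes, materialized frames)
# ---------------------------------------------------------------------------


def animate_motion(
    texture: Texture1D, speed: float, direction: int, duration: float, dt: float = DT
) -> StimulusScene:
    """Animate a 1-D texture horizontally: one-pixel shift per step.

    ``direction`` +1 moves the imagery rightward, -1 leftward.  The texture
    pitch must equal ``speed * dt`` (the per-step travel distance).
    """
    if not math.isclose(texture.pixel_pitch, speed * dt, rel_tol=1e-9):
        raise ValueError("texture pixel_pitch must equal speed * dt")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    n_steps = int(round(duration / dt))
    width = len(texture) - n_steps
    if width <= 0:
        raise ValueError("texture too short for the requested duration")
    sw = sliding_window_view(texture.values, width)
    starts = (n_steps if direction > 0 else 0) + np.arange(n_steps) * (-direction)
    return StimulusScene(np.array(sw[starts]), dt, texture.pixel_pitch)


def animate_flicker(
    texture: Texture2D, speed: float, duration: float, dt: float = DT
) -> StimulusScene:
    """Animate a 2-D texture perpendicular to the array: row t fills the
    window at step t, giving temporal modulation with no coherent horizontal
    motion."""
    if not math.isclose(texture.pixel_pitch, speed * dt, rel_tol=1e-9):
        raise ValueError("texture pixel_pitch must equal speed * dt")
    n_steps = int(round(duration / dt))
    if texture.values.shape[0] < n_steps:
        raise ValueError("texture too short for the requested duration")
    return StimulusScene(texture.values[:n_steps].copy(), dt, texture.pixel_pitch)


def compose_scene(left: StimulusScene, right: StimulusScene, edge: EdgeSpec) -> StimulusScene:
    """Butt two time-aligned fragments together around a central edge."""
    if not math.isclose(left.dt, right.dt):
        raise ValueError("fragments must share dt")
    if not math.isclose(left.pixel_pitch, right.pixel_pitch):
        raise ValueError("fragments must share pixel pitch")
    if left.frames.shape[0] != right.frames.shape[0]:
        raise ValueError("fragments must be time-aligned")
    frames = np.concatenate([left.frames, right.frames], axis=1)
    return StimulusScene(frames, left.dt, left.pixel_pitch, edge)


# ---------------------------------------------------------------------------
# scenario catalogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    spec: EdgeSpec
    weight: int  # relative frequency units within its half
    count: int  # number of 10 ms outputs to generate


@dataclass
class ScenarioCatalog:
    entries: list
    total_output_count: int

    @property
    def edge_entries(self):
        return [e for e in self.entries if e.spec.present]

    @property
    def no_edge_entries(self):
        return [e for e in self.entries if not e.spec.present]

    def validate(self) -> None:
        n_edge = sum(e.count for e in self.edge_entries)
        n_ff = sum(e.count for e in self.no_edge_entries)
        if n_edge != n_ff:
            raise ValueError("edge and no-edge halves must have equal counts")
        if n_edge + n_ff != self.total_output_count:
            raise ValueError("entry counts do not sum to the total")


_DYNAMIC_KINDS = (ImageKind.MOTION_LEFT, ImageKind.MOTION_RIGHT, ImageKind.FLICKER)
#: frequency units per animation speed: the medium speed appears twice as often
_SPEED_WEIGHTS = {25.0: 1, 50.0: 2, 100.0: 1}


def build_fixed_edge_catalog(total_output_count: int) -> ScenarioCatalog:
    """The fixed-edge stimulus universe.

    Edge half: 18 dynamic-pair scenarios (3 unordered pairs of {motion
    left, motion right, flicker} x 2 sides x 3 speeds, medium speed twice as
    frequent) plus 6 static scenarios (3 dynamic classes x 2 sides at the
    medium speed, weighted like a medium-speed pair) -- 36 frequency units.
    No-edge half: full-field versions of the 3 dynamic classes, matched per
    class and per speed to their hemifield occupancy in the edge half
    (20 units per class: 4 slow / 12 medium / 4 fast); static full-field is
    excluded since it would produce all-zero signals.
    """
    half = total_output_count // 2
    if total_output_count % 2 or half % 36 or half % 60:
        raise ValueError("total_output_count must be divisible by 360")
    per_edge_unit = half // 36
    per_ff_unit = half // 60
    entries = []
    # 18 dynamic-pair scenarios
    pairs = [
        (ImageKind.MOTION_LEFT, ImageKind.MOTION_RIGHT),
        (ImageKind.MOTION_LEFT, ImageKind.FLICKER),
        (ImageKind.MOTION_RIGHT, ImageKind.FLICKER),
    ]
    for a, b in pairs:
        for la, lb in ((a, b), (b, a)):
            for speed, w in _SPEED_WEIGHTS.items():
                spec = EdgeSpec(
                    True,
                    EdgeKinematics.FIXED,
                    ImageClass(la, speed),
                    ImageClass(lb, speed),
                )
                entries.append(CatalogEntry(spec, w, w * per_edge_unit))
    # 6 static scenarios at the medium speed, medium-like weight
    for kind in _DYNAMIC_KINDS:
        dyn = ImageClass(kind, 50.0)
        static = ImageClass(ImageKind.STATIC)
        for left, right in ((dyn, static), (static, dyn)):
            spec = EdgeSpec(True, EdgeKinematics.FIXED, left, right)
            entries.append(CatalogEntry(spec, 2, 2 * per_edge_unit))
    # no-edge half: class and speed frequencies match hemifield occupancy
    for kind in _DYNAMIC_KINDS:
        for speed, units in ((25.0, 4), (50.0, 12), (100.0, 4)):
            cls = ImageClass(kind, speed)
            spec = EdgeSpec(False, EdgeKinematics.FIXED, cls, cls)
            entries.append(CatalogEntry(spec, units, units * per_ff_unit))
    catalog = ScenarioCatalog(entries, total_output_count)
    catalog.validate()
    return catalog


#: world-frame content classes for moving-edge scenes: Fourier objects move
#: with the edges (rightward), theta objects opposite (leftward)
_MOVING_CLASSES = (
    ImageClass(ImageKind.MOTION_RIGHT, EDGE_SPEED),  # Fourier
    ImageClass(ImageKind.MOTION_LEFT, EDGE_SPEED),  # theta
    ImageClass(ImageKind.FLICKER, EDGE_SPEED),
    ImageClass(ImageKind.STATIC),
)


def build_moving_edge_catalog(total_output_count: int) -> ScenarioCatalog:
    """The moving-edge stimulus universe.

    Edge half: every ordered pair of {Fourier, theta, flicker, static}
    (12 entries, both left/right assignments of each unordered pair) with
    equal frequency; all edges and imagery animated at 50 deg/s.  No-edge
    half: class-balanced full field {motion right, motion left, flicker} at
    50 deg/s.
    """
    half = total_output_count // 2
    if total_output_count % 2 or half % 12 or half % 3:
        raise ValueError("total_output_count must be divisible by 24")
    entries = []
    classes = _MOVING_CLASSES
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            for left, right in ((classes[i], classes[j]), (classes[j], classes[i])):
                spec = EdgeSpec(True, EdgeKinematics.MOVING, left, right, EDGE_SPEED)
                entries.append(CatalogEntry(spec, 1, half // 12))
    for cls in _MOVING_CLASSES[:3]:
        spec = EdgeSpec(False, EdgeKinematics.MOVING, cls, cls)
        entries.append(CatalogEntry(spec, 4, half // 3))
    catalog = ScenarioCatalog(entries, total_output_count)
    catalog.validate()
    return catalog
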