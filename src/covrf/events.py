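"""Sparse event-based shape simulator.

Emulates an event camera watching simple geometric shapes (triangle, square,
circle) whose outlines translate and scale over time.  Each movie is rendered
as thin binary contours in a supersampled high-resolution space (8x the
dataset resolution, i.e. 2400^2 for the default 300^2 frames, for sub-pixel
accuracy), area-downsampled to the dataset resolution, and converted to
two-polarity events by differencing consecutive frames and integrating the
per-pixel differences until they cross a contrast threshold -- the standard
event-camera generation model.  Bernoulli background noise and per-frame
sub-pixel ground-truth coordinates are attached.

Two dataset kinds are produced: a *spatial* dataset in which the starting
shape size varies log-uniformly over [10, 80] px (translation only), and a
*temporal* dataset in which each movie has a velocity parameter with
magnitude log-uniform over [0.16, 1.28] px/timestep that drives both the
scaling of the shapes (random sign) and their translation speed.  Movies are
50 frames of 1 ms at 300 x 300 px by default; activity is extremely sparse
(on the order of 1-3 per mille active pixels).

Noise convention: the background noise rate (default 5 per mille) is
Bernoulli per pixel *per movie* -- each pixel independently fires one noise
event of random polarity at one uniformly chosen frame with that
probability.  A per-pixel-per-frame convention is selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ShapeSpec",
    "MotionSpec",
    "EventMovie",
    "GEOMETRIES",
    "DEFAULT_EVENT_THRESHOLD",
    "DEFAULT_NOISE_RATE",
    "render_shape",
    "frames_to_events",
    "generate_movie",
    "make_dataset",
    "sparsity",
]

GEOMETRIES = ("triangle", "square", "circle")

#: Event-camera contrast threshold, in units of downsampled frame intensity.
#: A 1-px contour stroke downsamples to an intensity of about 1/8; the
#: threshold is calibrated (jointly with the size/velocity conventions
#: below) so the generated temporal datasets show the documented activity
#: levels: about 1 per mille active pixels at the slowest velocity
#: (0.16 px/step) and about 3 per mille at the fastest (1.28 px/step).
DEFAULT_EVENT_THRESHOLD = 0.15

#: Background noise rate in per mille (Bernoulli per pixel per movie).
DEFAULT_NOISE_RATE = 5.0

SIZE_RANGE = (10.0, 80.0)  # spatial-kind starting sizes, px at 300x300 scale
#: Temporal-kind starting sizes.  The slow-velocity movies derive nearly all
#: of their activity from the contour perimeter, so the temporal dataset
#: uses larger shapes than the spatial one (whose sizes are themselves the
#: studied variable).
TEMPORAL_SIZE_RANGE = (40.0, 90.0)
VELOCITY_RANGE = (0.16, 1.28)  # px/timestep at 300x300 scale
MIN_SIZE = 2.0  # px; shrinking shapes are clamped here


@dataclass
class ShapeSpec:
    """One shape: geometry, size (px), center position (x, y), orientation."""

    geometry: str
    size: float
    position: tuple[float, float]
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.size <= 0:
            raise ValueError("size must be positive")


@dataclass
class MotionSpec:
    """Per-shape motion: translation velocity and scale velocity (px/step)."""

    translation_velocity: tuple[float, float] = (0.0, 0.0)
    scale_velocity: float = 0.0
    dataset_kind: str = "spatial"

    def __post_init__(self) -> None:
        if self.dataset_kind not in ("spatial", "temporal"):
            raise ValueError("dataset_kind must be 'spatial' or 'temporal'")


@dataclass
class EventMovie:
    """Time-major two-polarity event tensor with ground-truth coordinates.

    frames: (T, 2, H, W) uint8 binary events (polarity 0 = ON, 1 = OFF);
    labels: (T, n_shapes, 2) float (x, y) px in [0, resolution);
    meta:   generator provenance (seed, specs, thresholds, flags).
    """

    frames: np.ndarray
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def resolution(self) -> int:
        return self.frames.shape[-1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _outline_points(spec: ShapeSpec, step: float) -> np.ndarray:
    """Sample the shape outline at ~`step` px spacing; returns (N, 2) (x, y)."""
    cx, cy = spec.position
    s = spec.size
    if spec.geometry == "circle":
        r = s / 2.0
        n = max(8, int(np.ceil(2 * np.pi * r / step)))
        th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    else:
        if spec.geometry == "square":
            h = s / 2.0
            corners = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
        else:  # equilateral triangle with side s, centered at the centroid
            rr = s / np.sqrt(3.0)
            ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                            np.pi / 2 + 4 * np.pi / 3])
            corners = rr * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        segs = []
        for i in range(len(corners)):
            a, b = corners[i], corners[(i + 1) % len(corners)]
            n = max(2, int(np.ceil(np.linalg.norm(b - a) / step)))
            t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
            segs.append(a + t * (b - a))
        pts = np.concatenate(segs, axis=0)
    c, sn = np.cos(spec.orientation), np.sin(spec.orientation)
    rot = np.array([[c, -sn], [sn, c]])
    pts = pts @ rot.T
    pts[:, 0] += cx
    pts[:, 1] += cy
    return pts


def render_shape(
    spec: ShapeSpec, resolution: int = 2400, base_resolution: int = 300
) -> np.ndarray:
    """Render one shape contour as a binary high-resolution grid.

    ``resolution`` is the supersampled canvas size; shape coordinates are
    given at ``base_resolution`` scale and mapped through the pixel-center
    convention x_hi = (x + 0.5) * f - 0.5 with f = resolution /
    base_resolution.  The stroke is one high-resolution pixel wide.
    """
    canvas = np.zeros((resolution, resolution), dtype=bool)
    _render_into(canvas, spec, resolution, base_resolution)
    return canvas


def _render_into(
    canvas: np.ndarray, spec: ShapeSpec, resolution: int, base_resolution: int
) -> None:
    f = resolution / base_resolution
    pts = _outline_points(spec, step=0.35 / f)
    hi = (pts + 0.5) * f - 0.5
    ij = np.rint(hi).astype(np.int64)
    keep = (
        (ij[:, 0] >= 0) & (ij[:, 0] < resolution)
        & (ij[:, 1] >= 0) & (ij[:, 1] < resolution)
    )
    ij = ij[keep]
    canvas[ij[:, 1], ij[:, 0]] = True


def _paste_shape(
    frame: np.ndarray, spec: ShapeSpec, resolution: int, supersample: int
) -> None:
    """Render one shape into a local supersampled patch and paste it.

    Equivalent to rendering on the full high-resolution canvas and
    area-downsampling, but restricted to the shape's bounding box (aligned
    to whole dataset pixels) for speed.  Overlapping shape contours add.
    """
    cx, cy = spec.position
    half = spec.size / 2.0 + 2.0
    bx0 = max(int(np.floor(cx - half)), 0)
    by0 = max(int(np.floor(cy - half)), 0)
    bx1 = min(int(np.ceil(cx + half)) + 1, resolution)
    by1 = min(int(np.ceil(cy + half)) + 1, resolution)
    if bx1 <= bx0 or by1 <= by0:
        return
    w, h = bx1 - bx0, by1 - by0
    local = ShapeSpec(
        spec.geometry, spec.size, (cx - bx0, cy - by0), spec.orientation
    )
    canvas = np.zeros((h * supersample, w * supersample), dtype=bool)
    _render_into_rect(canvas, local, supersample)
    frame[by0:by1, bx0:bx1] += (
        canvas.astype(np.float32)
        .reshape(h, supersample, w, supersample)
        .mean(axis=(1, 3))
    )


def _render_into_rect(canvas: np.ndarray, spec: ShapeSpec, f: int) -> None:
    """Mark outline pixels of `spec` (base-px coords) on a supersampled rect."""
    pts = _outline_points(spec, step=0.35 / f)
    hi = (pts + 0.5) * f - 0.5
    ij = np.rint(hi).astype(np.int64)
    keep = (
        (ij[:, 0] >= 0) & (ij[:, 0] < canvas.shape[1])
        & (ij[:, 1] >= 0) & (ij[:, 1] < canvas.shape[0])
    )
    ij = ij[keep]
    canvas[ij[:, 1], ij[:, 0]] = True


def _downsample(canvas: np.ndarray, factor: int) -> np.ndarray:
    """Area-average a high-resolution frame down by an integer factor."""
    h, w = canvas.shape
    out_h, out_w = h // factor, w // factor
    return (
        canvas.astype(np.float32)
        .reshape(out_h, factor, out_w, factor)
        .mean(axis=(1, 3))
    )


def frames_to_events(
    frame_t: np.ndarray,
    frame_prev: np.ndarray,
    accumulator: np.ndarray,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel integrate-to-threshold event generation.

    Adds the intensity difference between consecutive frames to a per-pixel
    accumulator; wherever the accumulator reaches +threshold a positive
    event is emitted and the threshold subtracted (symmetrically for
    negative).  Returns the (2, H, W) binary event frame and the updated
    accumulator.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    acc = accumulator + (frame_t.astype(np.float32) - frame_prev.astype(np.float32))
    pos = acc >= threshold
    neg = acc <= -threshold
    acc = acc - threshold * pos + threshold * neg
    events = np.stack([pos, neg]).astype(np.uint8)
    return events, acc


def _shape_at(spec: ShapeSpec, motion: MotionSpec, t: float,
              resolution: int) -> tuple[ShapeSpec, bool]:
    """Shape state at frame t; returns (spec, clamped?)."""
    x = spec.position[0] + motion.translation_velocity[0] * t
    y = spec.position[1] + motion.translation_velocity[1] * t
    clamped = False
    if not (0 <= x < resolution and 0 <= y < resolution):
        x = float(np.clip(x, 0, resolution - 1e-6))
        y = float(np.clip(y, 0, resolution - 1e-6))
        clamped = True
    size = spec.size + motion.scale_velocity * t
    if size < MIN_SIZE:
        size = MIN_SIZE
        clamped = True
    return (
        ShapeSpec(spec.geometry, size, (x, y), spec.orientation),
        clamped,
    )


def generate_movie(
    shape_specs: Sequence[ShapeSpec],
    motions: MotionSpec | Sequence[MotionSpec],
    noise_rate: float = DEFAULT_NOISE_RATE,
    seed: int | np.random.SeedSequence = 0,
    resolution: int = 300,
    n_frames: int = 50,
    threshold: float = DEFAULT_EVENT_THRESHOLD,
    supersample: int = 8,
    noise_convention: str = "per_movie",
) -> EventMovie:
    """Render one event movie with ground-truth coordinates.

    The shape trajectory is rendered at ``supersample * resolution`` and
    area-downsampled each frame; events are produced by
    :func:`frames_to_events` between consecutive frames (the event frame at
    index t covers the transition to intensity frame t+1, whose shape
    positions are the labels).  Background noise is overlaid afterwards.
    Deterministic for a fixed seed.
    """
    if isinstance(motions, MotionSpec):
        motions = [motions] * len(shape_specs)
    if len(motions) != len(shape_specs):
        raise ValueError("one MotionSpec per shape required")
    if noise_convention not in ("per_movie", "per_frame"):
        raise ValueError("noise_convention must be 'per_movie' or 'per_frame'")
    rng = np.random.default_rng(seed)
    hi_res = resolution * supersample
    n_shapes = len(shape_specs)
    frames = np.zeros((n_frames, 2, resolution, resolution), dtype=np.uint8)
    labels = np.zeros((n_frames, n_shapes, 2), dtype=np.float64)
    acc = np.zeros((resolution, resolution), dtype=np.float32)
    clamped_any = False

    def intensity(t: float) -> tuple[np.ndarray, list, bool]:
        frame = np.zeros((resolution, resolution), dtype=np.float32)
        states = []
        clamped = False
        for spec, mot in zip(shape_specs, motions):
            st, cl = _shape_at(spec, mot, t, resolution)
            clamped = clamped or cl
            states.append(st)
            _paste_shape(frame, st, resolution, supersample)
        return frame, states, clamped

    prev, _, cl = intensity(0.0)
    clamped_any |= cl
    for t in range(1, n_frames + 1):
        cur, states, cl = intensity(float(t))
        clamped_any |= cl
        ev, acc = frames_to_events(cur, prev, acc, threshold)
        frames[t - 1] = ev
        if states:
            labels[t - 1] = [st.position for st in states]
        prev = cur

    # background noise
    p = noise_rate / 1000.0
    if p > 0:
        if noise_convention == "per_movie":
            hits = rng.random((resolution, resolution)) < p
            ys, xs = np.nonzero(hits)
            ts = rng.integers(0, n_frames, size=ys.shape[0])
            pol = rng.integers(0, 2, size=ys.shape[0])
            frames[ts, pol, ys, xs] = 1
        else:
            noise = rng.random(frames.shape) < p / 2.0
            frames |= noise.astype(np.uint8)

    meta = {
        "resolution": resolution,
        "n_frames": n_frames,
        "threshold": threshold,
        "noise_rate": noise_rate,
        "noise_convention": noise_convention,
        "supersample": supersample,
        "clamped": bool(clamped_any),
        "shapes": [
            {
                "geometry": s.geometry,
                "size": s.size,
                "position": list(s.position),
                "orientation": s.orientation,
            }
            for s in shape_specs
        ],
        "motions": [
            {
                "translation_velocity": list(m.translation_velocity),
                "scale_velocity": m.scale_velocity,
                "dataset_kind": m.dataset_kind,
            }
            for m in motions
        ],
    }
    return EventMovie(frames=frames, labels=labels, meta=meta)


def _sample_movie_params(
    rng: np.random.Generator,
    kind: str,
    resolution: int,
    scale_velocity: float | None,
    size_range: tuple[float, float] | None = None,
    n_shapes: int = 3,
) -> tuple[list[ShapeSpec], list[MotionSpec], dict]:
    """Sample shapes and motions for one movie of the given dataset kind."""
    scale_f = resolution / 300.0
    if size_range is None:
        size_range = SIZE_RANGE if kind == "spatial" else TEMPORAL_SIZE_RANGE
    lo, hi = np.log(size_range[0]), np.log(size_range[1])
    vlo, vhi = np.log(VELOCITY_RANGE[0]), np.log(VELOCITY_RANGE[1])
    shapes: list[ShapeSpec] = []
    motions: list[MotionSpec] = []
    if kind == "temporal":
        if scale_velocity is None:
            speed = float(np.exp(rng.uniform(vlo, vhi))) * scale_f
        else:
            speed = float(scale_velocity) * scale_f
    else:
        speed = None
    if n_shapes == len(GEOMETRIES):
        geometries = GEOMETRIES
    else:
        geometries = tuple(rng.choice(GEOMETRIES, size=n_shapes))
    for geometry in geometries:
        size = float(np.exp(rng.uniform(lo, hi))) * scale_f
        margin = size / 2.0 + 2.0
        margin = min(margin, resolution / 2.0 - 1.0)
        pos = tuple(rng.uniform(margin, resolution - margin, size=2))
        orientation = float(rng.uniform(0.0, 2 * np.pi))
        shapes.append(ShapeSpec(geometry, size, pos, orientation))
        ang = rng.uniform(0.0, 2 * np.pi)
        if kind == "spatial":
            sp = float(np.exp(rng.uniform(vlo, vhi))) * scale_f
            motions.append(
                MotionSpec(
                    translation_velocity=(sp * np.cos(ang), sp * np.sin(ang)),
                    scale_velocity=0.0,
                    dataset_kind="spatial",
                )
            )
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            motions.append(
                MotionSpec(
                    translation_velocity=(speed * np.cos(ang), speed * np.sin(ang)),
                    scale_velocity=sign * speed,
                    dataset_kind="temporal",
                )
            )
    info = {"kind": kind}
    if kind == "temporal":
        info["velocity"] = speed / scale_f
    else:
        info["sizes"] = [s.size / scale_f for s in shapes]
    return shapes, motions, info


def make_dataset(
    kind: str,
    n_movies: int,
    seed: int = 0,
    resolution: int = 300,
    n_frames: int = 50,
    noise_rate: float = DEFAULT_NOISE_RATE,
    threshold: float = DEFAULT_EVENT_THRESHOLD,
    scale_velocity: float | None = None,
    validation_fraction: float = 0.2,
    supersample: int = 8,
    size_range: tuple[float, float] | None = None,
    n_shapes: int = 3,
) -> list[EventMovie]:
    """Generate a collection of event movies.

    ``spatial`` movies sample starting sizes log-uniformly in [10, 80] px
    (at 300-px scale) with translation speeds log-uniform in [0.16, 1.28]
    px/step; ``temporal`` movies sample one velocity parameter per movie
    (magnitude log-uniform in [0.16, 1.28], or fixed via
    ``scale_velocity``) that sets both the signed scaling rate and the
    translation speed of each shape.  At non-default resolutions all sizes
    and velocities scale proportionally.  The trailing
    ``validation_fraction`` of movies is tagged as the validation split.
    Deterministic per seed (per-movie child seeds are spawned from the
    master seed).
    """
    if kind not in ("spatial", "temporal"):
        raise ValueError("kind must be 'spatial' or 'temporal'")
    if n_movies < 1:
        raise ValueError("n_movies must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_movies)
    n_val = int(round(validation_fraction * n_movies))
    movies = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        shapes, motions, info = _sample_movie_params(
            rng, kind, resolution, scale_velocity, size_range, n_shapes
        )
        movie = generate_movie(
            shapes,
            motions,
            noise_rate=noise_rate,
            seed=child.spawn(1)[0],
            resolution=resolution,
            n_frames=n_frames,
            threshold=threshold,
            supersample=supersample,
        )
        movie.meta.update(info)
        movie.meta["index"] = i
        movie.meta["split"] = "validation" if i >= n_movies - n_val else "train"
        movie.meta["master_seed"] = int(seed) if np.isscalar(seed) else None
        movies.append(movie)
    return movies


def sparsity(movie: EventMovie) -> float:
    """Fraction of active pixels (polarities OR-ed) over T x H x W, in per mille."""
    active = movie.frames.any(axis=1)
    return float(active.mean() * 1000.0)


def save_dataset_hdf5(movies: Sequence[EventMovie], path) -> None:
    """Store a dataset as HDF5: per-movie `frames`/`labels` plus JSON meta."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, m in enumerate(movies):
            g = f.create_group(f"movie_{i:05d}")
            g.create_dataset("frames", data=m.frames, compression="gzip")
            g.create_dataset("labels", data=m.labels)
            g.attrs["meta"] = json.dumps(m.meta)


def load_dataset_hdf5(path) -> list[EventMovie]:
    import h5py

    movies = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            movies.append(
                EventMovie(
                    frames=g["frames"][()],
                    labels=g["labels"][()],
                    meta=json.loads(g.attrs["meta"]),
                )
            )
    return movies


def events_to_csv(movie: EventMovie, path) -> None:
    """Sparse export: CSV rows `t,x,y,polarity` (0-based, t in frames)."""
    t, p, y, x = np.nonzero(movie.frames)
    arr = np.stack([t, x, y, p], axis=1)
    np.savetxt(path, arr, fmt="%d", delimiter=",", header="t,x,y,polarity",
               comments="")
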