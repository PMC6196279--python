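"""Synthetic stimuli and spike encoders.

Three generators cover the experiments' input side:

* :func:`oriented_bar_image` -- a centered bar (default 8 px thick, 24 px
  long in a 32 x 32 frame) at an arbitrary orientation, bar pixels drawn
  uniformly from [0.8, 1.0], background zero.  The classic stimulus for
  developing orientation-selective receptive fields.
* :func:`poisson_encode` -- rate coding of a gray image into independent
  Poisson spike trains, with all pixel rates scaled so the *total population
  rate is constant* regardless of image brightness.  Supports either a fixed
  duration or an exact total spike count per sample.
* :func:`moving_symbol_stream` -- a DVS-like surrogate: contrast events
  emitted from the edge pixels of a glyph (poker suits) as it moves along a
  smooth random path, with event density proportional to instantaneous speed
  (a stationary object emits nothing).  This is a statistical stand-in for
  event-camera recordings, intended for pipeline tests, not a sensor model.

An IDX reader (the standard MNIST container format) is included for running
the same pipelines on real data; nothing in the package requires it.

All generators are pure functions of the provided numpy ``Generator``:
identical seeds give bitwise-identical streams.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .aer_core import EventStream

__all__ = [
    "EncodingConfig",
    "oriented_bar_image",
    "poisson_encode",
    "bar_sequence",
    "SampleSequence",
    "glyph_mask",
    "glyph_edge_pixels",
    "random_smooth_path",
    "moving_symbol_stream",
    "GLYPH_NAMES",
    "read_idx_images",
    "read_idx_labels",
    "load_idx_dataset",
]


@dataclass(frozen=True)
class EncodingConfig:
    """Poisson rate-coding parameters.

    ``total_rate`` is the constant whole-population event rate (events/s).
    Exactly one of ``duration_us`` / ``total_spikes`` selects the stopping
    rule; ``ist_us`` is the inter-symbol time separating successive samples
    (chosen >= the full leak-to-rest time so neuron states reset naturally
    between samples).
    """

    total_rate: float = 100_000.0
    duration_us: Optional[int] = None
    total_spikes: Optional[int] = 1000
    ist_us: int = 100_000

    def __post_init__(self):
        if self.total_rate <= 0:
            raise ValueError("total_rate must be positive")
        if (self.duration_us is None) == (self.total_spikes is None):
            raise ValueError("set exactly one of duration_us / total_spikes")
        if self.ist_us < 0:
            raise ValueError("ist_us must be non-negative")

    @property
    def sample_duration_us(self) -> int:
        """Nominal duration of one encoded sample."""
        if self.duration_us is not None:
            return int(self.duration_us)
        return int(round(self.total_spikes / self.total_rate * 1e6))


def oriented_bar_image(
    orientation_deg: float,
    size: int = 32,
    thickness: int = 8,
    length: int = 24,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """A centered bar at the given orientation with random pixel intensities.

    The bar is rasterized analytically: a pixel belongs to the bar when its
    center, rotated into the bar frame, falls within the half-thickness and
    half-length.  At 0 deg this yields exactly ``thickness x length`` pixels;
    oblique angles may deviate slightly (nearest-neighbor rasterization).
    Bar pixels draw intensities from U[0.8, 1.0]; background is 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    half_diag = 0.5 * float(np.hypot(length, thickness))
    if half_diag > size / 2.0:
        raise ValueError(
            f"bar (length {length}, thickness {thickness}) does not fit in a "
            f"{size}x{size} frame at arbitrary orientation"
        )
    center = (size - 1) / 2.0
    r, c = np.mgrid[0:size, 0:size]
    dr = r - center
    dc = c - center
    theta = np.deg2rad(orientation_deg)
    # bar frame: long axis along +x when orientation is 0 (horizontal bar)
    x = dc * np.cos(theta) + dr * np.sin(theta)
    y = -dc * np.sin(theta) + dr * np.cos(theta)
    mask = (np.abs(x) <= length / 2.0) & (np.abs(y) <= thickness / 2.0)
    img = np.zeros((size, size), dtype=np.float64)
    img[mask] = 0.8 + 0.2 * rng.random(int(mask.sum()))
    return img


def poisson_encode(
    image: np.ndarray,
    config: EncodingConfig,
    rng: np.random.Generator,
    t0_us: int = 0,
) -> EventStream:
    """Encode a gray image as Poisson spike trains at constant population rate.

    Pixel ``i`` fires at rate ``total_rate * I_i / sum(I)``.  In
    ``total_spikes`` mode the conditional property of the Poisson process is
    used: given the total count, event pixels are i.i.d. categorical with
    probabilities ``I_i / sum(I)`` and event times are i.i.d. uniform over the
    sample duration -- an exact draw that stops at the requested count.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    total_intensity = img.sum()
    if total_intensity <= 0:
        raise ValueError("cannot Poisson-encode an all-zero image")
    p = (img / total_intensity).ravel()
    if config.total_spikes is not None:
        n = int(config.total_spikes)
        duration = config.sample_duration_us
    else:
        duration = int(config.duration_us)
        n = int(rng.poisson(config.total_rate * duration / 1e6))
    addresses = rng.choice(p.size, size=n, p=p)
    times = np.sort(rng.random(n)) * duration
    return EventStream(
        t0_us + times.astype(np.int64),
        addresses,
        address_space=p.size,
        geometry=img.shape,
    )


@dataclass
class SampleSequence:
    """A concatenated stream of labeled samples with out-of-band boundaries.

    ``sample_starts[k]`` is the index of sample ``k``'s first event in
    ``stream``; ``onsets_us[k]`` its nominal onset time; ``labels[k]`` its
    class (an orientation in degrees for bar sequences).
    """

    stream: EventStream
    sample_starts: np.ndarray
    onsets_us: np.ndarray
    labels: List

    def __len__(self) -> int:
        return len(self.labels)

    def sample(self, k: int) -> EventStream:
        start = self.sample_starts[k]
        stop = self.sample_starts[k + 1] if k + 1 < len(self.labels) else len(self.stream)
        return EventStream(
            self.stream.timestamps[start:stop],
            self.stream.addresses[start:stop],
            self.stream.address_space,
            geometry=self.stream.geometry,
        )


def bar_sequence(
    orientations: Sequence[float],
    epochs: int,
    config: EncodingConfig,
    rng: np.random.Generator,
    size: int = 32,
    thickness: int = 8,
    length: int = 24,
) -> SampleSequence:
    """Poisson-encoded oriented bars in random per-epoch order.

    Each epoch presents every orientation once, in an order drawn from
    ``rng``; successive sample onsets are separated by the sample duration
    plus the inter-symbol time, long enough for all neurons to leak back to
    rest between samples.  Bar intensities are redrawn for every presentation.
    """
    orientations = list(orientations)
    ts_parts, ad_parts = [], []
    starts, onsets, labels = [], [], []
    t0 = 0
    n_events = 0
    step = config.sample_duration_us + config.ist_us
    for _ in range(epochs):
        order = rng.permutation(len(orientations))
        for idx in order:
            angle = orientations[idx]
            img = oriented_bar_image(angle, size, thickness, length, rng)
            s = poisson_encode(img, config, rng, t0_us=t0)
            ts_parts.append(s.timestamps)
            ad_parts.append(s.addresses)
            starts.append(n_events)
            onsets.append(t0)
            labels.append(angle)
            n_events += len(s)
            t0 += step
    stream = EventStream(
        np.concatenate(ts_parts) if ts_parts else np.empty(0, dtype=np.int64),
        np.concatenate(ad_parts) if ad_parts else np.empty(0, dtype=np.int64),
        address_space=size * size,
        geometry=(size, size),
    )
    return SampleSequence(
        stream,
        np.asarray(starts, dtype=np.int64),
        np.asarray(onsets, dtype=np.int64),
        labels,
    )


# ---------------------------------------------------------------------------
# DVS-like moving-symbol surrogate
# ---------------------------------------------------------------------------

GLYPH_NAMES: Tuple[str, ...] = ("club", "diamond", "heart", "spade")


def glyph_mask(name: str, size: int = 16) -> np.ndarray:
    """Binary mask of a poker-suit glyph, rasterized analytically."""
    r, c = np.mgrid[0:size, 0:size]
    s = size / 16.0  # geometry defined on a 16 x 16 canvas
    cc = (size - 1) / 2.0

    def disc(r0, c0, rad):
        return (r - r0 * s) ** 2 + (c - c0 * s) ** 2 <= (rad * s) ** 2

    if name == "diamond":
        return (np.abs(r - cc) + np.abs(c - cc)) <= 7.0 * s
    if name == "heart":
        lobes = disc(5.0, 4.8, 3.4) | disc(5.0, 10.2, 3.4)
        tip = (r >= 5.0 * s) & (np.abs(c - cc) <= (13.5 * s - r) * 0.72)
        return lobes | tip
    if name == "spade":
        lobes = disc(9.0, 4.8, 3.0) | disc(9.0, 10.2, 3.0)
        tip = (r <= 9.0 * s) & (np.abs(c - cc) <= (r - 0.5 * s) * 0.72)
        stem = (r >= 11.0 * s) & (np.abs(c - cc) <= 1.2 * s)
        return lobes | tip | stem
    if name == "club":
        discs = disc(4.5, 7.5, 3.0) | disc(8.5, 4.3, 3.0) | disc(8.5, 10.7, 3.0)
        stem = (r >= 10.0 * s) & (np.abs(c - cc) <= 1.2 * s)
        return discs | stem
    raise ValueError(f"unknown glyph {name!r}; choose from {GLYPH_NAMES}")


def glyph_edge_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the mask's edge (mask minus its erosion)."""
    mask = np.asarray(mask, dtype=bool)
    edge = mask & ~ndimage.binary_erosion(mask)
    return np.argwhere(edge)


def random_smooth_path(
    duration_us: int,
    field: Tuple[int, int],
    margin: float,
    rng: np.random.Generator,
    step_us: int = 1000,
    max_amplitude_px: float = 15.0,
) -> np.ndarray:
    """A smooth Lissajous-like path within the field, sampled every step.

    Returns an array of ``(t_us, row, col)`` waypoints.  The motion emulates
    a hand-held object wobbled slowly in front of the sensor: the object
    stays roughly centered, drifting by at most ``max_amplitude_px`` pixels
    (clipped so the trajectory keeps ``margin`` pixels from the border) over
    one or two oscillation cycles per sample.  Frequencies and phases are
    random per draw.
    """
    rows, cols = field
    t = np.arange(0, duration_us + step_us, step_us, dtype=np.float64)
    room_r = max(rows / 2.0 - margin, 0.0)
    room_c = max(cols / 2.0 - margin, 0.0)
    amp_r = min(room_r, max_amplitude_px) * (0.7 + 0.3 * rng.random())
    amp_c = min(room_c, max_amplitude_px) * (0.7 + 0.3 * rng.random())
    f_r = (1.0 + rng.random()) / duration_us  # 1..2 cycles over the duration
    f_c = (1.0 + rng.random()) / duration_us
    ph_r, ph_c = 2 * np.pi * rng.random(2)
    path_r = rows / 2.0 + amp_r * np.sin(2 * np.pi * f_r * t + ph_r)
    path_c = cols / 2.0 + amp_c * np.sin(2 * np.pi * f_c * t + ph_c)
    return np.column_stack([t, path_r, path_c])


def moving_symbol_stream(
    symbol: Union[str, np.ndarray],
    path: Optional[np.ndarray] = None,
    event_rate: float = 10_000.0,
    duration_us: int = 500_000,
    rng: Optional[np.random.Generator] = None,
    field: Tuple[int, int] = (128, 128),
    scale: int = 6,
) -> EventStream:
    """DVS-like event stream from a glyph moving along a smooth path.

    Events are drawn from the glyph's *edge* pixels (contrast events are
    edge-driven) at an instantaneous rate proportional to the path speed,
    normalized so the time-averaged rate is ``event_rate`` when moving.  A
    stationary path therefore produces no events.  ``scale`` magnifies the
    16 x 16 glyph canvas by pixel replication.
    """
    if rng is None:
        rng = np.random.default_rng()
    mask = glyph_mask(symbol) if isinstance(symbol, str) else np.asarray(symbol, bool)
    if scale > 1:
        mask = np.kron(mask, np.ones((scale, scale), dtype=bool))
    edges = glyph_edge_pixels(mask)
    if edges.size == 0:
        raise ValueError("glyph mask has no edge pixels")
    half = (np.asarray(mask.shape) - 1) / 2.0
    rows, cols = field
    if path is None:
        margin = float(max(mask.shape)) / 2.0 + 2.0
        if margin >= min(rows, cols) / 2.0:
            raise ValueError("glyph does not fit in the visual field")
        path = random_smooth_path(duration_us, field, margin, rng)
    path = np.asarray(path, dtype=np.float64)
    t_way = path[:, 0]
    pos = path[:, 1:3]
    speed = np.zeros(len(path))
    dt = np.diff(t_way)
    if len(path) > 1:
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.maximum(dt, 1)
        speed[:-1] = seg
        speed[-1] = seg[-1]
    mean_speed = speed.mean()
    if mean_speed <= 0:
        return EventStream(
            np.empty(0, np.int64), np.empty(0, np.int64),
            address_space=rows * cols, geometry=field,
        )
    rate = event_rate * speed / mean_speed  # events per second, per waypoint
    ts_parts, ad_parts = [], []
    for k in range(len(path) - 1):
        lam = rate[k] * dt[k] / 1e6
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        times = np.sort(t_way[k] + rng.random(n) * dt[k]).astype(np.int64)
        picks = edges[rng.integers(0, len(edges), size=n)]
        # linear interpolation of the glyph center within the segment
        frac = (times - t_way[k]) / dt[k]
        centers = pos[k] + np.outer(frac, pos[k + 1] - pos[k])
        rc = np.rint(centers - half + picks).astype(np.int64)
        np.clip(rc[:, 0], 0, rows - 1, out=rc[:, 0])
        np.clip(rc[:, 1], 0, cols - 1, out=rc[:, 1])
        ts_parts.append(times)
        ad_parts.append(rc[:, 0] * cols + rc[:, 1])
    if not ts_parts:
        return EventStream(
            np.empty(0, np.int64), np.empty(0, np.int64),
            address_space=rows * cols, geometry=field,
        )
    return EventStream(
        np.concatenate(ts_parts),
        np.concatenate(ad_parts),
        address_space=rows * cols,
        geometry=field,
    )


# ---------------------------------------------------------------------------
# IDX (MNIST container) reader -- optional, for real data
# ---------------------------------------------------------------------------

def read_idx_images(path) -> List[np.ndarray]:
    """Read an IDX image file into a list of [0, 1] gray images."""
    with open(path, "rb") as fh:
        magic = struct.unpack(">I", fh.read(4))[0]
        if magic != 0x00000803:
            raise ValueError(f"bad IDX image magic number {magic:#010x}")
        n, rows, cols = struct.unpack(">III", fh.read(12))
        data = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    if data.size != n * rows * cols:
        raise ValueError("truncated IDX image file")
    return list(data.reshape(n, rows, cols).astype(np.float64) / 255.0)


def read_idx_labels(path) -> np.ndarray:
    """Read an IDX label file."""
    with open(path, "rb") as fh:
        magic = struct.unpack(">I", fh.read(4))[0]
        if magic != 0x00000801:
            raise ValueError(f"bad IDX label magic number {magic:#010x}")
        n = struct.unpack(">I", fh.read(4))[0]
        data = np.frombuffer(fh.read(n), dtype=np.uint8)
    if data.size != n:
        raise ValueError("truncated IDX label file")
    return data.astype(np.int64)


def load_idx_dataset(images_path, labels_path) -> Tuple[List[np.ndarray], np.ndarray]:
    """Load a paired IDX image/label set, checking the lengths agree."""
    images = read_idx_images(images_path)
    labels = read_idx_labels(labels_path)
    if len(images) != len(labels):
        raise ValueError(
            f"image/label count mismatch: {len(images)} images, {len(labels)} labels"
        )
    return images, labels
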