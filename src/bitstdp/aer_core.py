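"""Address-event representation (AER) data model and stream utilities.

Neuromorphic sensors and event-driven simulators exchange *address events*:
(timestamp, address) pairs where the address identifies the spiking source
(a pixel of an event camera, an input line, a neuron).  This module provides
the in-memory container (:class:`EventStream`, a struct-of-arrays over numpy),
a plain-text CSV dialect for persistence, fixed-event-count slicing (the
"kesl" segmentation used to cut long recordings into samples) and pixel
address-space subsampling.

Conventions
-----------
* Timestamps are integer microseconds, non-negative, non-decreasing.
  Ties keep file/input order (stable).
* Pixel addresses are flattened row-major, 0-based: ``address = r * cols + c``.
* The CSV dialect is UTF-8, one event per line ``timestamp_us,address[,polarity]``,
  ``#``-prefixed comment lines, optional header line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Event",
    "EventStream",
    "AerParseError",
    "read_aer_csv",
    "write_aer_csv",
    "slice_by_event_count",
    "subsample_addresses",
]

CSV_HEADER = "timestamp_us,address"
CSV_HEADER_POL = "timestamp_us,address,polarity"


@dataclass(frozen=True)
class Event:
    """A single address event (integer microseconds, 0-based address)."""

    timestamp: int
    address: int
    polarity: Optional[int] = None


class AerParseError(ValueError):
    """Malformed AER-CSV input; carries the offending line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EventStream:
    """An ordered sequence of address events over a finite address space.

    Parameters
    ----------
    timestamps, addresses:
        Equal-length integer arrays.  Timestamps must be non-negative and
        non-decreasing; addresses must lie in ``[0, address_space)``.
    address_space:
        Number of distinct source addresses.
    polarities:
        Optional per-event sign flags (e.g. DVS ON/OFF), same length.
    geometry:
        Optional ``(rows, cols)`` for pixel sources; required by
        :func:`subsample_addresses`.  ``rows * cols`` must equal
        ``address_space``.
    """

    __slots__ = ("timestamps", "addresses", "polarities", "address_space", "geometry")

    def __init__(
        self,
        timestamps: Sequence[int],
        addresses: Sequence[int],
        address_space: int,
        polarities: Optional[Sequence[int]] = None,
        geometry: Optional[Tuple[int, int]] = None,
    ):
        ts = np.asarray(timestamps, dtype=np.int64)
        ad = np.asarray(addresses, dtype=np.int64)
        if ts.shape != ad.shape or ts.ndim != 1:
            raise ValueError("timestamps and addresses must be equal-length 1-D arrays")
        if address_space <= 0:
            raise ValueError("address_space must be positive")
        if ts.size:
            if ts.min() < 0:
                raise ValueError("timestamps must be non-negative")
            if np.any(np.diff(ts) < 0):
                raise ValueError("timestamps must be non-decreasing")
            if ad.min() < 0 or ad.max() >= address_space:
                raise ValueError(
                    f"addresses must lie in [0, {address_space}); "
                    f"found range [{ad.min()}, {ad.max()}]"
                )
        if geometry is not None:
            rows, cols = geometry
            if rows * cols != address_space:
                raise ValueError("geometry rows*cols must equal address_space")
        pol = None
        if polarities is not None:
            pol = np.asarray(polarities, dtype=np.int64)
            if pol.shape != ts.shape:
                raise ValueError("polarities must match event count")
        self.timestamps = ts
        self.addresses = ad
        self.polarities = pol
        self.address_space = int(address_space)
        self.geometry = tuple(geometry) if geometry is not None else None

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def __iter__(self) -> Iterator[Event]:
        if self.polarities is None:
            for t, a in zip(self.timestamps, self.addresses):
                yield Event(int(t), int(a))
        else:
            for t, a, p in zip(self.timestamps, self.addresses, self.polarities):
                yield Event(int(t), int(a), int(p))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        if self.address_space != other.address_space:
            return False
        if (self.polarities is None) != (other.polarities is None):
            return False
        same = np.array_equal(self.timestamps, other.timestamps) and np.array_equal(
            self.addresses, other.addresses
        )
        if same and self.polarities is not None:
            same = np.array_equal(self.polarities, other.polarities)
        return same

    def __repr__(self) -> str:
        return (
            f"EventStream(n={len(self)}, address_space={self.address_space}, "
            f"geometry={self.geometry})"
        )

    @classmethod
    def from_events(
        cls,
        events: Iterable[Event],
        address_space: int,
        geometry: Optional[Tuple[int, int]] = None,
    ) -> "EventStream":
        evs = list(events)
        pols = None
        if evs and evs[0].polarity is not None:
            pols = [e.polarity for e in evs]
        return cls(
            [e.timestamp for e in evs],
            [e.address for e in evs],
            address_space,
            polarities=pols,
            geometry=geometry,
        )

    def duration_us(self) -> int:
        """Span from first to last event (0 for empty/single-event streams)."""
        if len(self) < 2:
            return 0
        return int(self.timestamps[-1] - self.timestamps[0])


def read_aer_csv(
    path,
    address_space: int,
    strict_order: bool = True,
    geometry: Optional[Tuple[int, int]] = None,
) -> EventStream:
    """Read an AER-CSV file into an :class:`EventStream`.

    With ``strict_order=True`` (default) out-of-order timestamps raise
    :class:`AerParseError`; with ``strict_order=False`` events are stably
    re-sorted by timestamp.
    """
    ts, ad, pol = [], [], []
    n_pol = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.replace(",", "").replace("_", "").isalpha():
                continue  # header line
            parts = line.split(",")
            if len(parts) not in (2, 3):
                raise AerParseError(f"expected 2 or 3 fields, got {len(parts)}", lineno)
            try:
                t = int(parts[0])
                a = int(parts[1])
                p = int(parts[2]) if len(parts) == 3 else None
            except ValueError as exc:
                raise AerParseError(f"non-integer field in {line!r}", lineno) from exc
            if t < 0:
                raise AerParseError(f"negative timestamp {t}", lineno)
            if not 0 <= a < address_space:
                raise AerParseError(
                    f"address {a} outside address space [0, {address_space})", lineno
                )
            ts.append(t)
            ad.append(a)
            if p is not None:
                n_pol += 1
                pol.append(p)
    if n_pol and n_pol != len(ts):
        raise AerParseError("polarity column present on some lines but not all")
    ts_arr = np.asarray(ts, dtype=np.int64)
    if ts_arr.size and np.any(np.diff(ts_arr) < 0):
        if strict_order:
            raise AerParseError("timestamps out of order (set strict_order=False to re-sort)")
        order = np.argsort(ts_arr, kind="stable")
        ts = ts_arr[order]
        ad = np.asarray(ad, dtype=np.int64)[order]
        pol = np.asarray(pol, dtype=np.int64)[order] if n_pol else None
        return EventStream(ts, ad, address_space, polarities=pol, geometry=geometry)
    return EventStream(
        ts, ad, address_space, polarities=pol if n_pol else None, geometry=geometry
    )


def write_aer_csv(stream: EventStream, path) -> None:
    """Write a stream in the AER-CSV dialect (round-trips with read_aer_csv)."""
    with open(path, "w", encoding="utf-8") as fh:
        if stream.polarities is None:
            fh.write(CSV_HEADER + "\n")
            for t, a in zip(stream.timestamps, stream.addresses):
                fh.write(f"{t},{a}\n")
        else:
            fh.write(CSV_HEADER_POL + "\n")
            for t, a, p in zip(stream.timestamps, stream.addresses, stream.polarities):
                fh.write(f"{t},{a},{p}\n")


def slice_by_event_count(stream: EventStream, kesl: int) -> list:
    """Cut a stream into consecutive slices of exactly ``kesl`` events each.

    The trailing remainder (fewer than ``kesl`` events) is discarded so every
    slice carries identical event statistics.  Order is preserved.
    """
    if kesl < 1:
        raise ValueError(f"kesl must be >= 1, got {kesl}")
    n_slices = len(stream) // kesl
    out = []
    for k in range(n_slices):
        sl = slice(k * kesl, (k + 1) * kesl)
        pol = stream.polarities[sl] if stream.polarities is not None else None
        out.append(
            EventStream(
                stream.timestamps[sl],
                stream.addresses[sl],
                stream.address_space,
                polarities=pol,
                geometry=stream.geometry,
            )
        )
    return out


def subsample_addresses(stream: EventStream, factor: int) -> EventStream:
    """Reduce pixel resolution by an integer per-axis divisor.

    Pixel ``(r, c)`` maps to ``(r // factor, c // factor)``; timestamps and
    event count are unchanged.  Requires stream geometry, and the factor must
    divide both axes.
    """
    if stream.geometry is None:
        raise ValueError("subsample_addresses requires a stream with geometry")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rows, cols = stream.geometry
    if rows % factor or cols % factor:
        raise ValueError(f"factor {factor} does not divide geometry {stream.geometry}")
    if factor == 1:
        return stream
    new_rows, new_cols = rows // factor, cols // factor
    r = stream.addresses // cols
    c = stream.addresses % cols
    new_addr = (r // factor) * new_cols + (c // factor)
    return EventStream(
        stream.timestamps,
        new_addr,
        new_rows * new_cols,
        polarities=stream.polarities,
        geometry=(new_rows, new_cols),
    )
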