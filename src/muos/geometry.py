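"""Plan-view geometry of the micro-optic-stalk (μOS) device.

The device mimics the developing *Drosophila* eye–brain complex: two
large vertical reservoirs — the eye imaginal disc (EID, left, the sink)
and the brain lobe (BL, right, the source) — joined by an array of
equally spaced microchannels, each representing one optic-stalk (OS)
segment.  The channels are shallower than the reservoirs (10 µm vs
50 µm), so depth-averaged transport must carry a per-cell thickness.

Coordinates are continuous µm with the origin at the outer (left) wall
of the EID reservoir and x increasing toward the BL.  Rasters are
cell-centered with 0-based ``[y, x]`` indexing.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "LayoutError",
    "DeviceGeometry",
    "GridSpec",
    "DomainMask",
    "build_domain_mask",
    "make_straight_channel_mask",
    "OUTSIDE",
    "EID",
    "BL",
    "CHANNEL0",
]

# region-label codes used in DomainMask.labels
OUTSIDE = 0
EID = 1
BL = 2
CHANNEL0 = 3  # channel k carries label CHANNEL0 + k


class LayoutError(ValueError):
    """Raised when a geometry cannot be laid out as a valid device."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Dimensions of the μOS device in µm.

    Defaults are the fabricated device: 150 × 500 µm reservoirs of
    50 µm height and eight 90 µm optic-stalk channels of 10 µm height
    whose width tapers from 35 µm at the EID face to 37 µm at the BL
    face.
    """

    reservoir_width: float = 150.0
    reservoir_length: float = 500.0
    reservoir_height: float = 50.0
    n_channels: int = 8
    channel_length: float = 90.0
    channel_width_bl: float = 37.0   # W_OS1, at the brain-lobe face
    channel_width_eid: float = 35.0  # W_OS2, at the eye-disc face
    channel_height: float = 10.0
    channel_spacing: float = 35.0    # nominal edge-to-edge gap

    def __post_init__(self) -> None:
        lengths = {
            "reservoir_width": self.reservoir_width,
            "reservoir_length": self.reservoir_length,
            "reservoir_height": self.reservoir_height,
            "channel_length": self.channel_length,
            "channel_width_bl": self.channel_width_bl,
            "channel_width_eid": self.channel_width_eid,
            "channel_height": self.channel_height,
            "channel_spacing": self.channel_spacing,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if int(self.n_channels) != self.n_channels or self.n_channels < 1:
            raise ValueError(f"n_channels must be an integer >= 1, got {self.n_channels}")
        if self.n_channels * self.max_channel_width >= self.reservoir_length:
            raise LayoutError(
                f"{self.n_channels} channels of width {self.max_channel_width} µm "
                f"cannot fit against a {self.reservoir_length} µm reservoir face"
            )

    # -- derived layout ------------------------------------------------
    @property
    def max_channel_width(self) -> float:
        return max(self.channel_width_bl, self.channel_width_eid)

    @property
    def device_length(self) -> float:
        """Total x-extent: EID + channel array + BL."""
        return 2.0 * self.reservoir_width + self.channel_length

    @property
    def channel_span(self) -> tuple[float, float]:
        """x-interval occupied by the microchannel array."""
        return (self.reservoir_width, self.reservoir_width + self.channel_length)

    def channel_centerlines(self) -> np.ndarray:
        """y-positions of the channel centerlines.

        The nominal gap is honoured when the array fits on the reservoir
        face; otherwise the channels are redistributed with equal gaps
        (including end margins), which is how the fabricated device must
        place them since the printed nominal dimensions slightly
        over-fill the face.
        """
        n, w = self.n_channels, self.max_channel_width
        L = self.reservoir_length
        nominal = n * w + (n - 1) * self.channel_spacing
        if nominal <= L:
            y0 = (L - nominal) / 2.0 + w / 2.0
            pitch = w + self.channel_spacing
        else:
            gap = (L - n * w) / (n + 1)
            y0 = gap + w / 2.0
            pitch = w + gap
        return y0 + pitch * np.arange(n)

    def channel_width_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Channel width at axial position ``x`` (linear taper)."""
        x0, x1 = self.channel_span
        frac = np.clip((np.asarray(x, dtype=float) - x0) / (x1 - x0), 0.0, 1.0)
        return self.channel_width_eid + (self.channel_width_bl - self.channel_width_eid) * frac

    def channel_plan_area(self) -> float:
        """Analytic plan area of one channel (trapezoid), µm²."""
        return self.channel_length * (self.channel_width_bl + self.channel_width_eid) / 2.0

    # -- config I/O ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceGeometry":
        return cls(**d)


@dataclass(frozen=True)
class GridSpec:
    """Raster resolution for the computational domain.

    ``dx`` is the (square) cell size in µm.  Cells are centered: cell
    ``(j, i)`` covers ``[i*dx, (i+1)*dx] × [j*dx, (j+1)*dx]`` and its
    value lives at ``((i+0.5)*dx, (j+0.5)*dx)``.
    """

    dx: float = 1.0

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    def validate_for(self, geometry: DeviceGeometry) -> None:
        limit = min(geometry.channel_width_eid, geometry.channel_spacing) / 4.0
        if self.dx > limit:
            raise ValueError(
                f"dx={self.dx} µm too coarse to resolve channels; need dx <= {limit} µm"
            )


@dataclass(frozen=True)
class DomainMask:
    """Rasterized computational domain.

    ``inside`` flags wetted cells, ``thickness`` holds the local device
    height in µm (0 outside) and ``labels`` tags each cell with
    OUTSIDE / EID / BL / CHANNEL0+k.
    """

    inside: np.ndarray        # bool [ny, nx]
    thickness: np.ndarray     # float µm [ny, nx]
    labels: np.ndarray        # int [ny, nx]
    dx: float
    n_channels: int
    channel_span: tuple[float, float]
    geometry: Optional[DeviceGeometry] = None

    def __post_init__(self) -> None:
        if self.inside.shape != self.thickness.shape or self.inside.shape != self.labels.shape:
            raise ValueError("inside/thickness/labels shapes differ")
        if not np.array_equal(self.thickness > 0, self.inside):
            raise ValueError("thickness > 0 must hold exactly on inside cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.shape[1]) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.shape[0]) + 0.5) * self.dx

    def channel_cells(self, k: int) -> np.ndarray:
        if not 0 <= k < self.n_channels:
            raise IndexError(f"channel index {k} out of range [0, {self.n_channels})")
        return self.labels == CHANNEL0 + k


def _connected_to(labels: np.ndarray, channel_mask: np.ndarray, target_label: int) -> bool:
    """4-connectivity between a channel and a reservoir label (shared cell faces)."""
    tgt = labels == target_label
    for shift in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        rolled = np.roll(tgt, shift, axis=(0, 1))
        # roll wraps around; wrapped faces are outside the raster anyway
        if np.any(channel_mask & rolled):
            return True
    return False


def build_domain_mask(geometry: DeviceGeometry, grid: GridSpec) -> DomainMask:
    """Rasterize the device plan view into a :class:`DomainMask`.

    Raises :class:`LayoutError` for geometries whose channel array cannot
    be placed, and ``ValueError`` for grids too coarse to resolve it.
    """
    grid.validate_for(geometry)
    dx = grid.dx
    nx = int(np.ceil(geometry.device_length / dx - 1e-9))
    ny = int(np.ceil(geometry.reservoir_length / dx - 1e-9))
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(xc, yc)

    x0, x1 = geometry.channel_span
    labels = np.full((ny, nx), OUTSIDE, dtype=np.int32)
    labels[(X < x0) & (Y < geometry.reservoir_length)] = EID
    labels[(X > x1) & (X < geometry.device_length) & (Y < geometry.reservoir_length)] = BL

    centerlines = geometry.channel_centerlines()
    in_span = (X > x0) & (X < x1)
    halfwidth = geometry.channel_width_at(X) / 2.0
    for k, yk in enumerate(centerlines):
        cells = in_span & (np.abs(Y - yk) <= halfwidth)
        if np.any(labels[cells] >= CHANNEL0):
            raise LayoutError("channels overlap; reduce n_channels or widths")
        labels[cells] = CHANNEL0 + k

    inside = labels != OUTSIDE
    thickness = np.zeros((ny, nx))
    thickness[(labels == EID) | (labels == BL)] = geometry.reservoir_height
    thickness[labels >= CHANNEL0] = geometry.channel_height

    for k in range(geometry.n_channels):
        ch = labels == CHANNEL0 + k
        if not np.any(ch):
            raise LayoutError(f"channel {k} rasterized to zero cells at dx={dx}")
        if not (_connected_to(labels, ch, EID) and _connected_to(labels, ch, BL)):
            raise LayoutError(f"channel {k} is not connected to both reservoirs at dx={dx}")

    return DomainMask(
        inside=inside,
        thickness=thickness,
        labels=labels,
        dx=dx,
        n_channels=geometry.n_channels,
        channel_span=(x0, x1),
        geometry=geometry,
    )


def make_straight_channel_mask(
    length: float,
    width: float,
    height: float = 10.0,
    dx: float = 1.0,
) -> DomainMask:
    """A single straight uniform channel with no reservoirs.

    Used for validating the transport solver against the closed-form 1D
    solutions (linear for pure diffusion, exponential for uniform
    advection–diffusion).
    """
    nx = int(np.ceil(length / dx - 1e-9))
    ny = int(np.ceil(width / dx - 1e-9))
    labels = np.full((ny, nx), CHANNEL0, dtype=np.int32)
    inside = np.ones((ny, nx), dtype=bool)
    thickness = np.full((ny, nx), float(height))
    return DomainMask(
        inside=inside,
        thickness=thickness,
        labels=labels,
        dx=dx,
        n_channels=1,
        channel_span=(0.0, length),
        geometry=None,
    )
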