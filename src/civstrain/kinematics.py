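"""Cylindrical strain mapping and landmark tracking.

Displacement fields estimated on short-axis slices are physiologically
interpreted in a cylindrical frame about the left-ventricular long axis:
``u_r = u cos(theta) + v sin(theta)`` and ``u_theta = -u sin(theta) +
v cos(theta)``, with theta measured from +x toward +y about a user-supplied
centre.  Radial and circumferential strains follow as ``eps_rr =
d(u_r)/dr`` and ``eps_tt = (1/r) d(u_theta)/d(theta) + u_r / r``; the
Cartesian divergence ``E = du/dx + dv/dy`` quantifies in-plane
compressibility.  Strains are averaged over AHA 17-segment sectors
(reduced per slice level to 6/6/4 sectors, apex cap excluded) and
accumulated over the cardiac cycle as Eulerian increments starting at end
diastole.  Landmarks are advected through the per-interval dense fields by
spatial interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .civcore import VectorField, interpolate_field
from .exceptions import DataError, ParameterError

__all__ = [
    "PolarField",
    "StrainMap",
    "SegmentModel",
    "StrainCurve",
    "LandmarkTrack",
    "to_polar",
    "compute_strain",
    "divergence",
    "segment_average",
    "accumulate_strain",
    "track_landmarks",
]

#: sectors per slice level in the reduced AHA scheme (segment 17 excluded)
AHA_SECTORS = {"basal": 6, "mid": 6, "apical": 4}
#: first AHA segment number of each slice level
AHA_FIRST = {"basal": 1, "mid": 7, "apical": 13}


def _polar_grids(shape, center):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dx = xx - center[0]
    dy = yy - center[1]
    return np.hypot(dx, dy), np.arctan2(dy, dx)


@dataclass
class PolarField:
    """Per-pixel radial/circumferential displacement about a centre."""

    ur: np.ndarray
    utheta: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    center: tuple[float, float]


@dataclass
class StrainMap:
    """Per-pixel radial/circumferential strain and divergence.

    ``valid`` masks pixels where the cylindrical strains are defined
    (radius above ``r_min`` and full finite-difference stencil support).
    """

    eps_rr: np.ndarray
    eps_tt: np.ndarray
    div: np.ndarray
    valid: np.ndarray
    center: tuple[float, float]


def to_polar(u, v, center) -> PolarField:
    """Rotate a Cartesian displacement field into the cylindrical frame.

    Pointwise orthogonal rotation, so ``ur**2 + utheta**2 == u**2 + v**2``
    at every pixel.  The centre pixel itself has an undefined angle; the
    convention ``theta = 0`` there keeps all values finite.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError(f"component shapes differ: {u.shape} vs {v.shape}")
    if not (0 <= center[0] < u.shape[1] and 0 <= center[1] < u.shape[0]):
        raise ParameterError(f"center {center} outside image of shape {u.shape}")
    r, theta = _polar_grids(u.shape, center)
    ct, st = np.cos(theta), np.sin(theta)
    ur = u * ct + v * st
    ut = -u * st + v * ct
    return PolarField(ur, ut, r, theta, tuple(center))


def compute_strain(polar: PolarField, r_min: float = 5.0) -> StrainMap:
    """Radial and circumferential strain from a dense polar field.

    Derivatives are taken by resampling the ``u_r``/``u_theta`` grids on
    local radial/tangential stencils (step 1 px, bilinear interpolation)
    and centred differencing — no intermediate polar raster.  ``eps_tt``
    uses the arc-length form ``d(u_theta)/ds + u_r/r``, equivalent to
    ``(1/r) d(u_theta)/d(theta) + u_r/r``.  Pixels with ``r < r_min`` (the
    1/r terms blow up) or without full stencil support are masked.
    """
    r, theta = polar.r, polar.theta
    ct, st = np.cos(theta), np.sin(theta)
    h, w = r.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def sample(arr, px, py):
        return map_coordinates(arr, [py.ravel(), px.ravel()], order=1,
                               mode="nearest").reshape(arr.shape)

    # radial stencil: +-1 px along (cos t, sin t)
    eps_rr = 0.5 * (sample(polar.ur, xx + ct, yy + st)
                    - sample(polar.ur, xx - ct, yy - st))
    # tangential stencil: +-1 px of arc along (-sin t, cos t)
    dut_ds = 0.5 * (sample(polar.utheta, xx - st, yy + ct)
                    - sample(polar.utheta, xx + st, yy - ct))
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_tt = dut_ds + polar.ur / r
    div = divergence(polar.ur * ct - polar.utheta * st,
                     polar.ur * st + polar.utheta * ct)
    inside = ((xx >= 1) & (xx <= w - 2) & (yy >= 1) & (yy <= h - 2))
    valid = (r >= r_min) & inside
    eps_rr = np.where(valid, eps_rr, np.nan)
    eps_tt = np.where(valid, eps_tt, np.nan)
    return StrainMap(eps_rr, eps_tt, div, valid, polar.center)


def divergence(u, v) -> np.ndarray:
    """Cartesian divergence ``du/dx + dv/dy`` by finite differences.

    Centred differences in the interior, one-sided at the borders.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.gradient(u, axis=1) + np.gradient(v, axis=0)


@dataclass(frozen=True)
class SegmentModel:
    """Reduced AHA sector model for one short-axis slice.

    Sectors partition the full circle about ``center``: 6 for basal and mid
    slices, 4 for apical (the apex cap, segment 17, has no extent on a
    short-axis slice).  ``reference_angle`` is the angle (radians, from +x
    toward +y) of the first sector boundary — by default straight up in
    image coordinates (-y, i.e. -pi/2), standing in for the anterior
    RV insertion; sectors are numbered in the direction of increasing
    theta.
    """

    center: tuple[float, float]
    level: str = "mid"
    reference_angle: float = -np.pi / 2.0

    def __post_init__(self) -> None:
        if self.level not in AHA_SECTORS:
            raise ParameterError(
                f"level must be one of {sorted(AHA_SECTORS)}, got {self.level!r}"
            )

    @property
    def n_sectors(self) -> int:
        return AHA_SECTORS[self.level]

    @property
    def segment_numbers(self) -> list[int]:
        first = AHA_FIRST[self.level]
        return list(range(first, first + self.n_sectors))

    def sector_index(self, theta) -> np.ndarray:
        """Sector index (0-based) of each angle."""
        width = 2.0 * np.pi / self.n_sectors
        ang = np.mod(np.asarray(theta, dtype=float) - self.reference_angle,
                     2.0 * np.pi)
        return np.minimum((ang / width).astype(int), self.n_sectors - 1)


def segment_average(strain_map, model: SegmentModel, mask) -> dict[int, float]:
    """Mean of a per-pixel map over each AHA sector within a tissue mask.

    ``strain_map`` may be a bare 2-D array or one component of a
    :class:`StrainMap`.  NaNs (undefined strain) are excluded; a sector
    containing no masked pixels is reported as NaN (missing).
    """
    arr = np.asarray(strain_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise DataError(f"mask shape {mask.shape} does not match map {arr.shape}")
    if not mask.any():
        raise DataError("myocardium mask is empty")
    _, theta = _polar_grids(arr.shape, model.center)
    idx = model.sector_index(theta)
    out: dict[int, float] = {}
    for k, seg in enumerate(model.segment_numbers):
        sel = mask & (idx == k) & np.isfinite(arr)
        out[seg] = float(np.mean(arr[sel])) if sel.any() else float("nan")
    return out


@dataclass
class StrainCurve:
    """Cumulative per-segment strain time series, zero at end diastole."""

    time_ms: np.ndarray
    segments: list[int]
    eps_rr: np.ndarray  # (n_times, n_segments)
    eps_tt: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for si, seg in enumerate(self.segments):
            for ti, t in enumerate(self.time_ms):
                rows.append(
                    {"segment": seg, "time_ms": float(t),
                     "eps_rr": float(self.eps_rr[ti, si]),
                     "eps_tt": float(self.eps_tt[ti, si])}
                )
        return pd.DataFrame(rows)


def accumulate_strain(increments, frame_times) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-interval Eulerian strain increments over the cycle.

    ``increments`` has one row per frame interval (any trailing shape, e.g.
    one column per segment); ``frame_times`` has one entry per frame, the
    first being end diastole.  Returns ``(times, cumulative)`` where the
    cumulative series starts at exactly 0 at ``frame_times[0]``.
    """
    inc = np.atleast_1d(np.asarray(increments, dtype=float))
    times = np.asarray(frame_times, dtype=float)
    if times.ndim != 1 or times.size != inc.shape[0] + 1:
        raise DataError(
            f"need one frame time per interval boundary: {inc.shape[0]} intervals "
            f"but {times.size} times"
        )
    if np.any(np.diff(times) <= 0):
        raise DataError("frame times must be strictly increasing")
    zero = np.zeros((1,) + inc.shape[1:])
    return times, np.concatenate([zero, np.cumsum(inc, axis=0)], axis=0)


def build_strain_curves(rr_increments, tt_increments, frame_times,
                        segments) -> StrainCurve:
    """Assemble a :class:`StrainCurve` from per-interval segment means."""
    times, rr = accumulate_strain(rr_increments, frame_times)
    _, tt = accumulate_strain(tt_increments, frame_times)
    return StrainCurve(times, list(segments), np.atleast_2d(rr), np.atleast_2d(tt))


@dataclass
class LandmarkTrack:
    """Landmark positions per frame; ``positions[t, i]`` is (x, y) px."""

    positions: np.ndarray  # (n_frames, n_landmarks, 2)
    source: str = "estimated"

    def to_dataframe(self) -> pd.DataFrame:
        n_t, n_l, _ = self.positions.shape
        rows = [
            {"landmark": i, "frame": t,
             "x": float(self.positions[t, i, 0]),
             "y": float(self.positions[t, i, 1])}
            for i in range(n_l) for t in range(n_t)
        ]
        return pd.DataFrame(rows)


def _field_sampler(interval_field, shape):
    if callable(interval_field):
        return interval_field
    if isinstance(interval_field, VectorField):
        return lambda x, y: interpolate_field(
            interval_field, np.column_stack([x, y])
        )
    u, v = interval_field

    def sampler(x, y):
        du = map_coordinates(np.asarray(u, float), [y, x], order=1, mode="nearest")
        dv = map_coordinates(np.asarray(v, float), [y, x], order=1, mode="nearest")
        return du, dv

    return sampler


def track_landmarks(fields, initial_positions, frame_shape) -> LandmarkTrack:
    """Advect landmarks through a sequence of displacement fields.

    Each entry of ``fields`` covers one frame interval and may be a dense
    ``(U, V)`` pair, a :class:`~civstrain.civcore.VectorField`, or a
    callable ``f(x, y) -> (du, dv)``.  The instantaneous displacement at
    the current landmark location is obtained by bilinear interpolation
    and added to the position.  Positions are clipped to the frame (with a
    warning) if a landmark would exit.
    """
    pos = np.atleast_2d(np.asarray(initial_positions, dtype=float)).copy()
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise DataError(f"initial positions must be (n, 2), got {pos.shape}")
    h, w = frame_shape
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > w - 1) \
            or np.any(pos[:, 1] < 0) or np.any(pos[:, 1] > h - 1):
        raise DataError("initial landmark positions outside frame")
    track = [pos.copy()]
    for fld in fields:
        sampler = _field_sampler(fld, (h, w))
        du, dv = sampler(pos[:, 0], pos[:, 1])
        pos = pos + np.column_stack([np.ravel(du), np.ravel(dv)])
        clipped = np.clip(pos, [0, 0], [w - 1, h - 1])
        if not np.allclose(clipped, pos):
            warnings.warn("landmark left the frame; track clipped", stacklevel=2)
        pos = clipped
        track.append(pos.copy())
    return LandmarkTrack(np.stack(track, axis=0))
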