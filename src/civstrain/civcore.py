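"""Correlation image velocimetry: dense displacement from an image pair.

The estimator divides the first image into interrogation windows
("correlation boxes", side ``C_B``) laid out with 50% overlap, and for each
window finds the best-matching patch of the second image inside a search
region (side ``S_B``) by zero-mean normalized cross-correlation.  The
correlation peak is localized to sub-pixel precision with a three-point
Gaussian fit.  A second, hierarchical pass uses the first-pass field as a
predictor: the search is re-centred on the predicted displacement and the
second-image patch is counter-deformed with the locally linear (affine) fit
of the predictor, which accounts for the leading-order variation — strain
and rotation — of the displacement within a box.  Vectors failing a local
median test or a correlation-quality floor are replaced from their
neighbourhood, and the field is regularized by local quadratic surface
fitting, which leaves affine fields exactly invariant.

The public surface is both functional (``civ_pass``, ``reject_outliers``,
``smooth_field``, ``interpolate_field``) and object-based: ``CIVModel``
wraps an image pair plus parameters and ``fit()`` returns a ``CIVResults``
carrying the vector field, diagnostics and dense interpolation.

Sign convention: the displacement ``d`` at a point of image 1 maps that
point to its position in image 2.  Coordinates are 0-based pixel centres,
``x`` along columns, ``y`` along rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template

from .exceptions import CivstrainError, DataError, ParameterError
from .synthgen import validate_image

__all__ = [
    "CivParams",
    "VectorField",
    "CIVModel",
    "CIVResults",
    "BorderPeakError",
    "DegenerateWindowError",
    "correlation_surface",
    "subpixel_peak",
    "civ_pass",
    "reject_outliers",
    "smooth_field",
    "interpolate_field",
]

FLAG_VALID = 0
FLAG_REJECTED = 1
FLAG_FILLED = 2
_FLAG_NAMES = {FLAG_VALID: "valid", FLAG_REJECTED: "rejected", FLAG_FILLED: "filled"}
_FLAG_CODES = {v: k for k, v in _FLAG_NAMES.items()}


class BorderPeakError(CivstrainError):
    """Correlation maximum lies on the search border (search box too small)."""


class DegenerateWindowError(CivstrainError):
    """Interrogation window has (near-)zero intensity variance."""


@dataclass(frozen=True)
class CivParams:
    """Tuning parameters of the correlation estimator.

    Parameters
    ----------
    correlation_box : int
        Side ``C_B`` of the interrogation window in image 1, px.  The
        default 25 is the optimum found for 512x512 tag-grid images.
    search_box : int
        Side ``S_B`` of the search region in image 2, px (default 55); the
        largest first-pass shift is ``(S_B - C_B) // 2``.
    overlap : float
        Fractional overlap of neighbouring correlation boxes; measurement
        points are spaced ``C_B * (1 - overlap)`` apart (default 0.5).
    passes : int
        Number of correlation passes; passes beyond the first re-centre and
        counter-deform the search using the previous field (default 2).
    subpixel : str
        Peak interpolation: ``"gaussian"`` (three-point log fit per axis,
        parabolic fallback on non-positive samples) or ``"parabolic"``.
    outlier_median_threshold : float
        Maximum allowed deviation (px) from the 8-neighbourhood median
        before a vector is replaced (default 2).
    smoothing_scale : int
        Half-width, in grid steps, of the quadratic-surface smoothing
        window (default 2).
    min_correlation : float
        Vectors whose correlation peak falls below this are replaced
        (default 0.3).
    refine_search_extra : int
        On refinement passes the residual search region shrinks to
        ``C_B + refine_search_extra`` px (default 8).
    """

    correlation_box: int = 25
    search_box: int = 55
    overlap: float = 0.5
    passes: int = 2
    subpixel: str = "gaussian"
    outlier_median_threshold: float = 2.0
    smoothing_scale: int = 2
    min_correlation: float = 0.3
    refine_search_extra: int = 8

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        if not 0 < self.correlation_box < self.search_box:
            raise ParameterError(
                f"need 0 < correlation_box < search_box, got "
                f"({self.correlation_box}, {self.search_box})"
            )
        if image_shape is not None and self.search_box > min(image_shape):
            raise ParameterError(
                f"search_box {self.search_box} exceeds image extent {min(image_shape)}"
            )
        if not 0 <= self.overlap < 1:
            raise ParameterError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.passes < 1:
            raise ParameterError(f"passes must be >= 1, got {self.passes}")
        if self.subpixel not in ("gaussian", "parabolic"):
            raise ParameterError(f"unknown subpixel method {self.subpixel!r}")
        if self.smoothing_scale < 0:
            raise ParameterError("smoothing_scale must be >= 0")
        if not 0 <= self.min_correlation <= 1:
            raise ParameterError("min_correlation must be in [0, 1]")

    @property
    def grid_step(self) -> int:
        """Measurement-point spacing in pixels."""
        return max(1, int(round(self.correlation_box * (1.0 - self.overlap))))


@dataclass
class VectorField:
    """Displacement samples on a regular grid of measurement points.

    ``u``/``v``/``corr``/``flags`` are ``(len(y), len(x))`` arrays; ``x``
    and ``y`` are the pixel coordinates of the grid columns/rows.  Flags:
    0 = valid, 1 = rejected, 2 = filled (replaced from neighbourhood).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    corr: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        shape = (self.y.size, self.x.size)
        for name in ("u", "v", "corr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise DataError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.shape != shape:
            raise DataError(f"flags has shape {self.flags.shape}, expected {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def n_points(self) -> int:
        return self.u.size

    def valid_mask(self) -> np.ndarray:
        return self.flags != FLAG_REJECTED

    def copy(self) -> "VectorField":
        return VectorField(
            self.x.copy(), self.y.copy(), self.u.copy(), self.v.copy(),
            self.corr.copy(), self.flags.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
                "corr": self.corr.ravel(),
                "flag": [_FLAG_NAMES[f] for f in self.flags.ravel()],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "VectorField":
        x = np.unique(df["x"].to_numpy(dtype=float))
        y = np.unique(df["y"].to_numpy(dtype=float))
        if len(df) != x.size * y.size:
            raise DataError("field table is not a complete regular grid")
        shape = (y.size, x.size)
        order = np.lexsort((df["x"].to_numpy(), df["y"].to_numpy()))
        sub = df.iloc[order]
        flags = np.array([_FLAG_CODES.get(str(f), FLAG_VALID) for f in sub["flag"]])
        return cls(
            x, y,
            sub["u"].to_numpy(dtype=float).reshape(shape),
            sub["v"].to_numpy(dtype=float).reshape(shape),
            sub["corr"].to_numpy(dtype=float).reshape(shape),
            flags.reshape(shape),
        )


# ---------------------------------------------------------------------------
# correlation primitives


def correlation_surface(img1, img2, center, params: CivParams):
    """Normalized cross-correlation of one interrogation window.

    Correlates the ``C_B x C_B`` patch of ``img1`` centred at ``center``
    (x, y) against every ``C_B x C_B`` patch of ``img2`` inside the
    ``S_B x S_B`` search region about the same centre.  Returns
    ``(corr, origin)`` where ``corr[i, j]`` is the zero-mean NCC at shift
    ``(du, dv) = (origin[0] + j, origin[1] + i)``; values lie in [-1, 1].

    Raises
    ------
    DegenerateWindowError
        If the template patch has (near-)zero variance.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    params.validate(img1.shape)
    cx, cy = int(round(center[0])), int(round(center[1]))
    cb, sb = params.correlation_box, params.search_box
    hc = cb // 2
    if not (0 <= cy - hc and cy - hc + cb <= img1.shape[0]
            and 0 <= cx - hc and cx - hc + cb <= img1.shape[1]):
        raise ParameterError(f"correlation box at {center} overhangs image 1")
    template = img1[cy - hc : cy - hc + cb, cx - hc : cx - hc + cb]
    corr, origin = _search_correlate(template, img2, cx, cy, sb)
    return corr, origin


def _search_correlate(template, img2, cx, cy, search_side):
    """NCC of ``template`` over a clipped search region of ``img2``.

    Returns ``(corr, (du0, dv0))`` with the shift of ``corr[0, 0]``.
    """
    cb = template.shape[0]
    if template.std() < 1e-12:
        raise DegenerateWindowError("interrogation window has zero variance")
    hs = search_side // 2
    hc = cb // 2
    r0 = max(0, cy - hs)
    r1 = min(img2.shape[0], cy - hs + search_side)
    c0 = max(0, cx - hs)
    c1 = min(img2.shape[1], cx - hs + search_side)
    region = img2[r0:r1, c0:c1]
    if region.shape[0] < cb or region.shape[1] < cb:
        raise DegenerateWindowError("search region smaller than correlation box")
    corr = match_template(region, template, pad_input=False)
    # corr[i, j] matches template against region[i:i+cb, j:j+cb]; the patch
    # centre sits at image-2 pixel (c0 + j + hc, r0 + i + hc).
    origin = (c0 + hc - cx, r0 + hc - cy)
    return np.clip(corr, -1.0, 1.0), origin


def subpixel_peak(corr: np.ndarray, method: str = "gaussian"):
    """Sub-pixel location of the correlation maximum.

    Returns ``(px, py, peak)``: the fractional (column, row) index of the
    peak and the correlation value at the integer maximum.  The integer
    maximum is refined independently per axis by a three-point Gaussian fit
    (log-parabola); if any of the three samples is non-positive the fit
    falls back to a plain parabola.  The refinement is clamped to 0.5 px.

    Ties at the maximum are broken toward the smallest shift magnitude
    about the map centre, then smallest row, then column offset.

    Raises
    ------
    BorderPeakError
        If the integer maximum lies on the map border.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2:
        raise DataError(f"correlation map must be 2-D, got shape {corr.shape}")
    if min(corr.shape) < 3:
        raise BorderPeakError(
            f"correlation map {corr.shape} too small for an interior maximum"
        )
    peak_val = np.max(corr)
    cand = np.argwhere(corr >= peak_val - 1e-12)
    if len(cand) > 1:
        ctr = np.array([(corr.shape[0] - 1) / 2.0, (corr.shape[1] - 1) / 2.0])
        off = cand - ctr
        keys = (np.hypot(off[:, 0], off[:, 1]), off[:, 0], off[:, 1])
        cand = cand[np.lexsort(keys[::-1])]
    iy, ix = int(cand[0][0]), int(cand[0][1])
    if iy in (0, corr.shape[0] - 1) or ix in (0, corr.shape[1] - 1):
        raise BorderPeakError(f"correlation peak on border at ({ix}, {iy})")

    def refine(cm, c0, cp):
        if method == "gaussian" and min(cm, c0, cp) > 0:
            denom = np.log(cm) + np.log(cp) - 2.0 * np.log(c0)
            if denom < 0:
                return 0.5 * (np.log(cm) - np.log(cp)) / denom
        denom = cm - 2.0 * c0 + cp
        if denom < 0:
            return 0.5 * (cm - cp) / denom
        return 0.0

    dx = np.clip(refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1]), -0.5, 0.5)
    dy = np.clip(refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix]), -0.5, 0.5)
    return ix + float(dx), iy + float(dy), float(peak_val)


# ---------------------------------------------------------------------------
# single correlation pass


def _measurement_grid(shape, params: CivParams):
    """Pixel coordinates of box centres whose boxes fit inside the frame."""
    cb = params.correlation_box
    hc = cb // 2
    step = params.grid_step
    xs = np.arange(hc, shape[1] - (cb - hc) + 1, step)
    ys = np.arange(hc, shape[0] - (cb - hc) + 1, step)
    if xs.size == 0 or ys.size == 0:
        raise ParameterError("correlation box larger than image; no measurement points")
    return xs, ys


def _field_interpolators(field: VectorField):
    """Linear interpolators for (u, v) and the predictor Jacobian."""
    u = np.where(np.isfinite(field.u), field.u, 0.0)
    v = np.where(np.isfinite(field.v), field.v, 0.0)
    pts = (field.y, field.x)
    kw = dict(method="linear", bounds_error=False, fill_value=None)
    fu = RegularGridInterpolator(pts, u, **kw)
    fv = RegularGridInterpolator(pts, v, **kw)
    if field.y.size > 1 and field.x.size > 1:
        dudy, dudx = np.gradient(u, field.y, field.x)
        dvdy, dvdx = np.gradient(v, field.y, field.x)
    else:
        dudy = dudx = dvdy = dvdx = np.zeros_like(u)
    grads = [RegularGridInterpolator(pts, g, **kw) for g in (dudx, dudy, dvdx, dvdy)]
    return fu, fv, grads


def civ_pass(
    img1,
    img2,
    params: CivParams,
    predictor: VectorField | None = None,
) -> VectorField:
    """One correlation pass over the full measurement grid.

    Without a predictor this is a plain search at full ``S_B``.  With a
    predictor (a previous-pass field) the search for each point is
    re-centred on the interpolated prediction and the second-image patch is
    sampled under the local affine map of the predictor (counter-
    deformation), so that residual correlation only has to resolve the
    deviation from the locally linear motion; the residual search region
    shrinks to ``C_B + refine_search_extra``.

    Vectors whose window is degenerate (blank) or whose correlation peak
    lies on the search border are flagged ``rejected`` with zero
    displacement; `reject_outliers` fills them from their neighbourhood.
    """
    img1 = validate_image(img1)
    img2 = validate_image(img2)
    if img1.shape != img2.shape:
        raise DataError(f"image shapes differ: {img1.shape} vs {img2.shape}")
    params.validate(img1.shape)
    cb = params.correlation_box
    hc = cb // 2
    xs, ys = _measurement_grid(img1.shape, params)
    nu = np.zeros((ys.size, xs.size))
    nv = np.zeros_like(nu)
    ncorr = np.zeros_like(nu)
    nflags = np.full(nu.shape, FLAG_VALID, dtype=np.int8)

    if predictor is not None:
        fu, fv, grads = _field_interpolators(predictor)
        side = cb + params.refine_search_extra
        hs2 = side // 2
        off = np.arange(side, dtype=float) - hs2
        oxx, oyy = np.meshgrid(off, off)
    for i, cy in enumerate(ys):
        for j, cx in enumerate(xs):
            template = img1[cy - hc : cy - hc + cb, cx - hc : cx - hc + cb]
            try:
                if predictor is None:
                    corr, origin = _search_correlate(
                        template, img2, cx, cy, params.search_box
                    )
                    px, py, pk = subpixel_peak(corr, params.subpixel)
                    du = origin[0] + px
                    dv = origin[1] + py
                else:
                    pt = np.array([[cy, cx]], dtype=float)
                    pu = float(fu(pt)[0])
                    pv = float(fv(pt)[0])
                    supported = (
                        cx + pu - hs2 >= 0
                        and cx + pu + hs2 <= img2.shape[1] - 1
                        and cy + pv - hs2 >= 0
                        and cy + pv + hs2 <= img2.shape[0] - 1
                    )
                    if supported:
                        dudx, dudy, dvdx, dvdy = (float(g(pt)[0]) for g in grads)
                        # sample img2 under the predictor's local affine map
                        sx = cx + pu + (1.0 + dudx) * oxx + dudy * oyy
                        sy = cy + pv + dvdx * oxx + (1.0 + dvdy) * oyy
                        window = _bilinear_sample(img2, sx, sy)
                        if template.std() < 1e-12 or window.std() < 1e-12:
                            raise DegenerateWindowError("blank window")
                        corr = np.clip(
                            match_template(window, template, pad_input=False), -1, 1
                        )
                        px, py, pk = subpixel_peak(corr, params.subpixel)
                        half = (corr.shape[1] - 1) / 2.0, (corr.shape[0] - 1) / 2.0
                        du = pu + (px - half[0])
                        dv = pv + (py - half[1])
                    else:
                        # window overhangs the frame: counter-deformation has
                        # no support, so re-centre a plain clipped search on
                        # the (rounded) prediction instead
                        rpu, rpv = int(round(pu)), int(round(pv))
                        corr, origin = _search_correlate(
                            template, img2, cx + rpu, cy + rpv, side
                        )
                        px, py, pk = subpixel_peak(corr, params.subpixel)
                        du = rpu + origin[0] + px
                        dv = rpv + origin[1] + py
                nu[i, j], nv[i, j], ncorr[i, j] = du, dv, pk
            except (DegenerateWindowError, BorderPeakError):
                nflags[i, j] = FLAG_REJECTED
    return VectorField(xs.astype(float), ys.astype(float), nu, nv, ncorr, nflags)


def _bilinear_sample(img, sx, sy):
    """Bilinear lookup with edge replication outside the frame.

    Replication (rather than a constant fill) keeps the intensity
    statistics of windows that overhang the frame well conditioned for
    normalized correlation, and is robust to predictor round-off pushing
    coordinates infinitesimally outside the frame.
    """
    from scipy.ndimage import map_coordinates

    return map_coordinates(
        img, [sy.ravel(), sx.ravel()], order=1, mode="nearest"
    ).reshape(sx.shape)


# ---------------------------------------------------------------------------
# validation, smoothing, interpolation


def _neighbourhood_median(arr, i, j, good):
    vals = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < arr.shape[0] and 0 <= jj < arr.shape[1] and good[ii, jj]:
                vals.append(arr[ii, jj])
    return float(np.median(vals)) if vals else None


def reject_outliers(field: VectorField, params: CivParams) -> VectorField:
    """Local median test and quality floor; failures filled from neighbours.

    A vector is replaced when (a) it was flagged rejected by the pass,
    (b) its correlation peak is below ``min_correlation``, or (c) the norm
    of its deviation from the 8-neighbourhood median displacement exceeds
    ``outlier_median_threshold`` px.  Replacement value is the
    neighbourhood median (flag ``filled``); vectors with no usable
    neighbours are left unchanged.
    """
    out = field.copy()
    good = field.flags != FLAG_REJECTED
    suspect = np.zeros(field.shape, dtype=bool)
    for i in range(field.shape[0]):
        for j in range(field.shape[1]):
            if not good[i, j] or field.corr[i, j] < params.min_correlation:
                suspect[i, j] = True
                continue
            mu = _neighbourhood_median(field.u, i, j, good)
            mv = _neighbourhood_median(field.v, i, j, good)
            if mu is None:
                continue
            dev = np.hypot(field.u[i, j] - mu, field.v[i, j] - mv)
            if dev > params.outlier_median_threshold:
                suspect[i, j] = True
    trusted = good & ~suspect
    pending = suspect | ~good
    # cascade the fill inward so that clusters of bad vectors (e.g. frame
    # corners whose content left the field of view) are replaced from the
    # nearest trusted region rather than keeping meaningless values
    while pending.any():
        progress = False
        for i, j in np.argwhere(pending):
            mu = _neighbourhood_median(out.u, i, j, trusted)
            mv = _neighbourhood_median(out.v, i, j, trusted)
            if mu is None:
                continue
            out.u[i, j] = mu
            out.v[i, j] = mv
            out.flags[i, j] = FLAG_FILLED
            trusted[i, j] = True
            pending[i, j] = False
            progress = True
        if not progress:
            break
    return out


def smooth_field(field: VectorField, params: CivParams) -> VectorField:
    """Regularize by local quadratic surface fitting.

    Each component is replaced by the value at the centre of a least-squares
    quadratic surface fitted over a ``(2*scale+1)``-node square
    neighbourhood (clipped at the field border, so polynomial fields up to
    degree 2 — in particular any affine field — are reproduced exactly
    everywhere, border included).
    """
    scale = params.smoothing_scale
    if scale == 0:
        return field.copy()
    ny, nx = field.shape
    out = field.copy()
    cache: dict[tuple, np.ndarray] = {}
    for i in range(ny):
        for j in range(nx):
            i0, i1 = max(0, i - scale), min(ny, i + scale + 1)
            j0, j1 = max(0, j - scale), min(nx, j + scale + 1)
            key = (i - i0, i1 - i, j - j0, j1 - j)
            w = cache.get(key)
            if w is None:
                dy = np.arange(i0 - i, i1 - i, dtype=float)
                dx = np.arange(j0 - j, j1 - j, dtype=float)
                gx, gy = np.meshgrid(dx, dy)
                gx, gy = gx.ravel(), gy.ravel()
                design = np.column_stack(
                    [np.ones_like(gx), gx, gy, gx * gx, gx * gy, gy * gy]
                )
                # centre-evaluation row of the least-squares projector
                w = np.linalg.pinv(design)[0]
                cache[key] = w
            out.u[i, j] = w @ field.u[i0:i1, j0:j1].ravel()
            out.v[i, j] = w @ field.v[i0:i1, j0:j1].ravel()
    return out


def interpolate_field(field: VectorField, target):
    """Interpolate a vector field to pixels or arbitrary query points.

    ``target`` is either an image shape ``(height, width)`` — returning
    dense ``(U, V)`` arrays — or an ``(n, 2)`` array of (x, y) query points
    returning ``(u, v)`` vectors.  Interpolation is bilinear inside the
    measurement grid and nearest-neighbour (edge value) outside; it is
    exact at measurement points.

    Raises
    ------
    DataError
        If fewer than 4 finite vectors are available.
    """
    finite = np.isfinite(field.u) & np.isfinite(field.v)
    if np.count_nonzero(finite) < 4:
        raise DataError("need at least 4 valid vectors to interpolate")
    u = np.where(finite, field.u, 0.0)
    v = np.where(finite, field.v, 0.0)
    fu = RegularGridInterpolator((field.y, field.x), u, method="linear",
                                 bounds_error=False)
    fv = RegularGridInterpolator((field.y, field.x), v, method="linear",
                                 bounds_error=False)
    if (isinstance(target, tuple) and len(target) == 2
            and all(np.isscalar(t) for t in target)):
        h, w = target
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        qx, qy = xx.ravel(), yy.ravel()
        out_shape = (h, w)
    else:
        pts = np.asarray(target, dtype=float)
        qx, qy = pts[:, 0], pts[:, 1]
        out_shape = (pts.shape[0],)
    # clamp queries to the grid hull: bilinear inside, edge value outside
    cqx = np.clip(qx, field.x[0], field.x[-1])
    cqy = np.clip(qy, field.y[0], field.y[-1])
    q = np.column_stack([cqy, cqx])
    return fu(q).reshape(out_shape), fv(q).reshape(out_shape)


# ---------------------------------------------------------------------------
# model / results objects


class CIVModel:
    """Displacement-estimation problem for one image pair.

    Parameters
    ----------
    image1, image2 : 2-D arrays
        Grayscale frames of equal shape; intensities on any common scale.
    params : CivParams, optional
        Estimator tuning; defaults to the tag-grid optimum (25, 55).

    Examples
    --------
    >>> res = CIVModel(frame0, frame1).fit()      # doctest: +SKIP
    >>> res.field.to_dataframe().head()           # doctest: +SKIP
    """

    def __init__(self, image1, image2, params: CivParams | None = None):
        self.image1 = validate_image(image1)
        self.image2 = validate_image(image2)
        if self.image1.shape != self.image2.shape:
            raise DataError(
                f"image shapes differ: {self.image1.shape} vs {self.image2.shape}"
            )
        self.params = params or CivParams()
        self.params.validate(self.image1.shape)

    def fit(self, smooth_final: bool = True) -> "CIVResults":
        """Run the multi-pass correlation pipeline and return the results.

        Pass 1 correlates at full search size; each further pass uses the
        validated, smoothed previous field as predictor with counter-
        deformation.  The returned field has outliers filled; a final
        quadratic smoothing is applied unless ``smooth_final=False``.
        """
        p = self.params
        field = civ_pass(self.image1, self.image2, p)
        field = reject_outliers(field, p)
        for _ in range(p.passes - 1):
            predictor = smooth_field(field, p)
            field = civ_pass(self.image1, self.image2, p, predictor=predictor)
            field = reject_outliers(field, p)
        if smooth_final:
            field = smooth_field(field, p)
        return CIVResults(self, field)


class CIVResults:
    """Fitted displacement field with diagnostics.

    Attributes
    ----------
    field : VectorField
        One vector per measurement point (px), with correlation quality and
        validity flags.
    """

    def __init__(self, model: CIVModel, field: VectorField):
        self.model = model
        self.field = field
        self.params = model.params

    def dense(self, shape: tuple[int, int] | None = None):
        """Per-pixel (U, V) displacement via bilinear interpolation."""
        if shape is None:
            shape = self.model.image1.shape
        return interpolate_field(self.field, shape)

    def at(self, points):
        """Displacement interpolated at (x, y) query points, shape (n, 2)."""
        return interpolate_field(self.field, np.atleast_2d(points))

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.field.flags == FLAG_VALID))

    @property
    def rejection_fraction(self) -> float:
        return 1.0 - self.n_valid / self.field.n_points

    def mean_displacement(self) -> float:
        m = self.field.valid_mask()
        return float(np.mean(np.hypot(self.field.u[m], self.field.v[m])))

    def to_dataframe(self) -> pd.DataFrame:
        return self.field.to_dataframe()

    def plot(self, ax=None, background: bool = True, **quiver_kw):
        """Quiver plot of the vector field over the first image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if background:
            ax.imshow(self.model.image1, cmap="gray", origin="upper")
        f = self.field
        xx, yy = np.meshgrid(f.x, f.y)
        ax.quiver(xx, yy, f.u, -f.v, color="red", angles="xy",
                  scale_units="xy", **quiver_kw)
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        return ax

    def summary(self) -> str:
        f = self.field
        p = self.params
        lines = [
            "CIV displacement estimate",
            "=" * 40,
            f"image size:            {self.model.image1.shape[1]} x {self.model.image1.shape[0]} px",
            f"correlation box C_B:   {p.correlation_box} px",
            f"search box S_B:        {p.search_box} px",
            f"overlap:               {p.overlap:.0%}",
            f"passes:                {p.passes}",
            f"measurement grid:      {f.x.size} x {f.y.size} "
            f"({f.n_points} vectors, step {p.grid_step} px)",
            f"valid vectors:         {self.n_valid} "
            f"({100 * (1 - self.rejection_fraction):.1f}%)",
            f"filled vectors:        {int(np.count_nonzero(f.flags == FLAG_FILLED))}",
            f"mean |d|:              {self.mean_displacement():.3f} px",
            f"mean correlation:      {float(np.mean(f.corr[f.valid_mask()])):.3f}",
        ]
        return "\n".join(lines)
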