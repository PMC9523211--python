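"""Row-curvature salience: from smoothed trajectories to rendering weights.

Peristalsis bends initially straight rows of tracked feature points into
curves; the signed curvature of a degree-2 least-squares fit to each row is
the per-row motion feature τ.  Its lagged variation Δτ = τ(f) − τ(f − lag)
measures how strongly the row is being deformed *right now* (a static bend
— e.g. anatomical curvature or a probe shift — contributes nothing).  The
|Δτ| magnitudes are min–max normalised over the whole clip to y0 ∈ [0, 1],
thresholded at α (default 0.6) to find salient peristalsis, and passed
through a logistic of slope β to produce rendering weights y2 for the
colour overlay.

Direction handling: Δτ is stored as a sign/magnitude pair, where the
sign channel used for the motion graph is the lagged axial advection sign
of the row's transverse-deformation profile (+1 = the deformation pattern
moved in the forward image direction, −1 = backward).  The raw sign of the
curvature difference (growth vs decay of the bend) is kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_cine import Orientation
from .tracking import FeatureGrid, TrajectorySet

__all__ = [
    "RowCurvatures",
    "DeltaTauField",
    "SalienceField",
    "row_geometry",
    "fit_row_curvature",
    "compute_row_curvatures",
    "curvature_variation",
    "travel_direction_signs",
    "normalize_magnitude",
    "apply_threshold",
    "sigmoid_weights",
    "compute_salience",
    "render_overlay",
]


@dataclass(frozen=True)
class RowCurvatures:
    """Signed curvature τ (1/px) of each grid row's quadratic fit, per frame.

    ``tau[f, r]`` is twice the quadratic coefficient of the least-squares
    degree-2 fit of transverse position against axial position for row r at
    frame f; ``fit_valid`` is False where fewer than 3 valid points (or
    fewer than 3 distinct axial stations) were available.
    """

    tau: np.ndarray  # (T, n_rows)
    fit_valid: np.ndarray  # (T, n_rows) bool


@dataclass(frozen=True)
class DeltaTauField:
    """Lagged curvature variation, split into sign and magnitude.

    ``delta_tau = sign * magnitude`` elementwise.  ``travel_sign`` is the
    direction channel consumed by the motion graph: the sign of the lagged
    axial advection of each row's deformation profile, mapped so +1 means
    motion in the forward image direction.
    """

    delta_tau: np.ndarray  # (T, n_rows) signed
    magnitude: np.ndarray  # |delta_tau|
    sign: np.ndarray  # {+1, -1, 0}, raw sign of the curvature difference
    lag: int
    valid: np.ndarray  # (T, n_rows) bool
    travel_sign: np.ndarray | None = None  # {+1, -1, 0}


@dataclass(frozen=True)
class SalienceField:
    """Normalised salience y0, threshold residual y1, and render weights y2."""

    y0: np.ndarray  # (T, n_rows) in [0, 1]
    valid: np.ndarray
    alpha: float | None = None
    y1: np.ndarray | None = None
    salient_mask: np.ndarray | None = None
    beta: float | None = None
    y2: np.ndarray | None = None


def row_geometry(
    traj: TrajectorySet, grid: FeatureGrid, orientation: Orientation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axial positions, transverse displacements and validity per grid row.

    A "row" is the set of grid points sharing an initial transverse
    coordinate, ordered along the endometrial long axis.  For a horizontal
    endometrium the long axis is image x and the transverse axis image y;
    for a vertical one the roles swap (rows are then grid columns).

    Returns
    -------
    axial : (T, n_rows, n_pts) current axial positions
    trans_disp : (T, n_rows, n_pts) transverse displacement from frame 0
    valid : (T, n_rows, n_pts) bool
    """
    coords = traj.coords
    valid = traj.valid_mask
    if orientation.horizontal:
        axial = coords[..., 0]
        trans = coords[..., 1] - coords[0, ..., 1][None]
    else:
        # rows share an initial x: transpose the grid so axis 1 indexes rows
        coords = np.swapaxes(coords, 1, 2)
        valid = np.swapaxes(valid, 1, 2)
        axial = coords[..., 1]
        trans = coords[..., 0] - coords[0, ..., 0][None]
    return axial, trans, valid


def fit_row_curvature(
    axial: np.ndarray, trans: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one frame's rows with quadratics; return (tau, fit_valid).

    Parameters are single-frame slices ``(n_rows, n_pts)``.  τ is the
    signed second derivative (twice the quadratic coefficient) of the
    least-squares degree-2 fit of transverse value against axial position;
    rows with fewer than 3 usable points get ``fit_valid`` False.
    """
    n_rows = axial.shape[0]
    tau = np.zeros(n_rows)
    ok = np.zeros(n_rows, dtype=bool)
    for r in range(n_rows):
        m = valid[r]
        x = axial[r][m]
        y = trans[r][m]
        if x.size < 3 or np.unique(x).size < 3:
            continue
        # centre axial positions for numerical conditioning
        c = np.polyfit(x - x.mean(), y, 2)
        tau[r] = 2.0 * c[0]
        ok[r] = True
    return tau, ok


def compute_row_curvatures(
    traj: TrajectorySet, grid: FeatureGrid, orientation: Orientation
) -> RowCurvatures:
    """Per-frame, per-row signed curvature of the fitted quadratics."""
    axial, trans, valid = row_geometry(traj, grid, orientation)
    n_t, n_rows = axial.shape[:2]
    tau = np.zeros((n_t, n_rows))
    ok = np.zeros((n_t, n_rows), dtype=bool)
    for f in range(n_t):
        tau[f], ok[f] = fit_row_curvature(axial[f], trans[f], valid[f])
    return RowCurvatures(tau=tau, fit_valid=ok)


def _lagged_difference(series: np.ndarray, lag: int) -> np.ndarray:
    """x[f] - x[f-lag], using x[0] as the reference for the first frames."""
    out = np.zeros_like(series)
    n = series.shape[0]
    for f in range(1, n):
        ref = f - lag if f >= lag else 0
        out[f] = series[f] - series[ref]
    return out


def curvature_variation(curv: RowCurvatures, lag: int = 5) -> DeltaTauField:
    """Δτ: subtract the curvature ``lag`` frames earlier from the current one.

    For frames with fewer than ``lag`` predecessors the first frame is used
    as the reference; frame 0 has Δτ = 0 by convention.  The result is
    recorded as a sign/magnitude pair.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    delta = _lagged_difference(curv.tau, lag)
    valid = np.zeros_like(curv.fit_valid)
    n = curv.tau.shape[0]
    for f in range(1, n):
        ref = f - lag if f >= lag else 0
        valid[f] = curv.fit_valid[f] & curv.fit_valid[ref]
    delta = np.where(valid, delta, 0.0)
    return DeltaTauField(
        delta_tau=delta,
        magnitude=np.abs(delta),
        sign=np.sign(delta).astype(np.int8),
        lag=lag,
        valid=valid,
    )


def travel_direction_signs(
    traj: TrajectorySet,
    grid: FeatureGrid,
    orientation: Orientation,
    lag: int = 5,
    eps: float = 1e-9,
) -> np.ndarray:
    """Per-row, per-frame travel direction of the deformation pattern.

    For each row the transverse-displacement profile d(axial) is treated as
    a translating pattern; its lagged axial shift has the sign of the
    one-dimensional flow correlation  S = Σ_i −∂d/∂t · ∂d/∂axial  (positive
    when the pattern moves toward increasing axial coordinate).  S is mapped
    to the image's forward convention: forward is image-left for a
    horizontal endometrium and image-down for a vertical one.

    Returns an int8 array (T, n_rows) with values {+1 forward, −1 backward,
    0 indeterminate}.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    axial, trans, valid = row_geometry(traj, grid, orientation)
    d_t = _lagged_difference(trans, lag)

    # spatial derivative along the row at the mid-lag profile
    n_t = trans.shape[0]
    refs = np.array([f - lag if f >= lag else 0 for f in range(n_t)])
    mid = 0.5 * (trans + trans[refs])
    d_x = np.gradient(mid, axis=2) / np.maximum(np.gradient(axial[0], axis=1)[None], 1e-9)

    corr = -d_t * d_x
    corr = np.where(valid & valid[refs], corr, 0.0)
    s_axial = corr.sum(axis=2)  # (T, n_rows); + = toward increasing axial coord

    if orientation.horizontal:
        forward = -s_axial  # forward is image-left (decreasing x)
    else:
        forward = s_axial  # forward is image-down (increasing y)
    out = np.zeros_like(forward, dtype=np.int8)
    out[forward > eps] = 1
    out[forward < -eps] = -1
    return out


def normalize_magnitude(
    field: DeltaTauField, min_magnitude: float = 2e-4
) -> SalienceField:
    """Min–max normalise |Δτ| over all the clip's valid entries to y0 ∈ [0, 1].

    The scope is the whole clip, so frames keep their relative intensities;
    if every magnitude is equal (no curvature change anywhere) y0 is 0
    everywhere.  Invalid entries get y0 = 0.

    Relative normalisation presumes the clip contains real peristalsis:
    on a motionless (or rigidly translating) clip it would stretch the
    tracking noise floor to [0, 1].  ``min_magnitude`` (1/px) guards this:
    when the whole clip's largest |Δτ| stays below it — about a quarter-
    pixel bow over a 100 px row, beneath tracking resolution — salience is
    zero everywhere.
    """
    mag = field.magnitude
    if mag.size == 0:
        raise ValueError("empty field")
    valid = field.valid
    if valid.any():
        lo = mag[valid].min()
        hi = mag[valid].max()
    else:
        lo = hi = 0.0
    if hi > max(lo, min_magnitude):
        y0 = (mag - lo) / (hi - lo)
    else:
        y0 = np.zeros_like(mag)
    y0 = np.where(valid, np.clip(y0, 0.0, 1.0), 0.0)
    return SalienceField(y0=y0, valid=valid)


def apply_threshold(sal: SalienceField, alpha: float = 0.6) -> SalienceField:
    """y1 = y0 − α; entries with y0 strictly above α are salient peristalsis."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    y1 = sal.y0 - alpha
    mask = (sal.y0 > alpha) & sal.valid
    return replace(sal, alpha=alpha, y1=y1, salient_mask=mask)


def sigmoid_weights(sal: SalienceField, beta: float = 10.0) -> SalienceField:
    """y2 = 1 / (1 + exp(−β·y1)): logistic rendering weight with slope β."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if sal.y1 is None:
        raise ValueError("apply_threshold before sigmoid_weights")
    with np.errstate(over="ignore"):  # saturation at extreme beta is fine
        y2 = 1.0 / (1.0 + np.exp(-beta * sal.y1))
    return replace(sal, beta=beta, y2=y2)


def compute_salience(
    field: DeltaTauField,
    alpha: float = 0.6,
    beta: float = 10.0,
    min_magnitude: float = 2e-4,
) -> SalienceField:
    """Normalise, threshold and weight in one call."""
    return sigmoid_weights(
        apply_threshold(normalize_magnitude(field, min_magnitude), alpha), beta
    )


def render_overlay(
    frame: np.ndarray,
    sal: SalienceField,
    grid: FeatureGrid,
    frame_idx: int,
    roi,
    orientation: Orientation = Orientation.CERVIX_LEFT,
    color: tuple[int, int, int] = (255, 0, 0),
    row_signs: np.ndarray | None = None,
    backward_color: tuple[int, int, int] = (0, 0, 255),
) -> np.ndarray:
    """Blend the salience weights into an RGB copy of a grayscale frame.

    Per-row weights y2 are rescaled so that the threshold level contributes
    nothing (w = max(0, 2·(y2 − ½)), which is 0 at y1 ≤ 0 and approaches 1
    for fully salient rows), interpolated linearly between grid-row
    positions across the ROI band, multiplied by ``color`` and added to the
    grey values.  Pixels outside the ROI are untouched.  If ``row_signs``
    is given, backward-moving rows are tinted with ``backward_color``.
    """
    if sal.y2 is None:
        raise ValueError("salience field has no rendering weights")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("expected a grayscale frame")
    out = np.repeat(frame[..., None], 3, axis=-1)

    weights = np.maximum(0.0, 2.0 * (sal.y2[frame_idx] - 0.5))  # (n_rows,)
    if orientation.horizontal:
        row_pos = grid.initial_coords[:, 0, 1]  # y of each grid row
        lo, hi = roi.y0, roi.y0 + roi.height
        band = np.arange(lo, min(hi, frame.shape[0]))
        prof = np.interp(band, row_pos, weights)
        sl = (slice(lo, min(hi, frame.shape[0])), slice(roi.x0, min(roi.x0 + roi.width, frame.shape[1])))
        wmap = prof[:, None]
        if row_signs is not None:
            sgn = np.interp(band, row_pos, row_signs[frame_idx].astype(float))[:, None]
    else:
        row_pos = grid.initial_coords[0, :, 0]  # x of each grid column-row
        lo, hi = roi.x0, roi.x0 + roi.width
        band = np.arange(lo, min(hi, frame.shape[1]))
        prof = np.interp(band, row_pos, weights)
        sl = (slice(roi.y0, min(roi.y0 + roi.height, frame.shape[0])), slice(lo, min(hi, frame.shape[1])))
        wmap = prof[None, :]
        if row_signs is not None:
            sgn = np.interp(band, row_pos, row_signs[frame_idx].astype(float))[None, :]

    region = out[sl]
    col = np.asarray(color, dtype=np.float64)
    if row_signs is None:
        add = wmap[..., None] * col
    else:
        bcol = np.asarray(backward_color, dtype=np.float64)
        fwd = np.clip(sgn, 0.0, 1.0)[..., None]
        bwd = np.clip(-sgn, 0.0, 1.0)[..., None]
        add = wmap[..., None] * (fwd * col + bwd * bcol)
    out[sl] = region + add
    return np.clip(out, 0.0, 255.0)
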