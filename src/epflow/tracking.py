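"""Feature-point grid generation, optical-flow tracking, trajectory smoothing.

The endometrial ROI is seeded with an equally spaced grid of feature points
(15 px apart by default).  Each point is tracked between adjacent frames
with iterative Lucas–Kanade optical flow, yielding per-frame subpixel
displacements Δx; trajectories are then denoised with a temporal moving
average followed by a spatial moving average over the grid neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from skimage.registration import optical_flow_ilk

from .io_cine import CineClip, ROIRect

__all__ = [
    "FeatureGrid",
    "TrajectorySet",
    "generate_feature_grid",
    "track_displacements",
    "smooth_trajectories",
]


@dataclass(frozen=True)
class FeatureGrid:
    """Equally spaced feature points seeded inside the ROI.

    ``initial_coords[r, c]`` is the (x, y) pixel position of the point in
    grid row r (constant y) and grid column c (constant x).
    """

    rows: int
    cols: int
    spacing: int
    initial_coords: np.ndarray  # (rows, cols, 2) float, (x, y)

    @property
    def n_points(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class TrajectorySet:
    """Tracked grid-point positions and adjacent-frame displacements.

    Attributes
    ----------
    coords : ndarray, (T, rows, cols, 2)
        Subpixel (x, y) positions; ``coords[0]`` equals the grid's initial
        coordinates.
    displacements : ndarray, (T-1, rows, cols, 2)
        ``coords[t+1] - coords[t]`` wherever tracking is valid.
    valid_mask : ndarray, (T, rows, cols) bool
        Once a point is lost it stays invalid for all later frames.
    """

    coords: np.ndarray
    displacements: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def generate_feature_grid(roi: ROIRect, spacing: int = 15) -> FeatureGrid:
    """Seed aligned feature points at ``spacing``-pixel intervals in the ROI.

    Points lie at ``(x0 + i*spacing, y0 + j*spacing)`` for every i, j that
    stays strictly inside the half-open ROI extent.
    """
    if spacing < 1:
        raise ValueError("grid spacing must be >= 1 pixel")
    if roi.width < 2 * spacing or roi.height < 2 * spacing:
        raise ValueError(
            f"ROI {roi.width}x{roi.height} too small for a 2x2 grid at spacing "
            f"{spacing} (needs at least {2 * spacing} px in each direction)"
        )
    xs = np.arange(roi.x0, roi.x0 + roi.width, spacing, dtype=float)
    ys = np.arange(roi.y0, roi.y0 + roi.height, spacing, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError(
            f"ROI {roi.width}x{roi.height} too small for a 2x2 grid at spacing {spacing}"
        )
    coords = np.stack(np.meshgrid(xs, ys), axis=-1)  # (rows, cols, 2) = (x, y)
    return FeatureGrid(rows=len(ys), cols=len(xs), spacing=spacing, initial_coords=coords)


def _texture_validity(frame: np.ndarray, coords: np.ndarray, window: int, min_eig: float) -> np.ndarray:
    """Shi–Tomasi style check: points on texture-free patches are untrackable."""
    img = frame / 255.0
    tensor = structure_tensor(img, sigma=window / 4.0, order="rc")
    eigs = structure_tensor_eigenvalues(tensor)  # (2, H, W), descending
    min_eig_map = eigs[-1]
    sampled = map_coordinates(
        min_eig_map, [coords[..., 1].ravel(), coords[..., 0].ravel()], order=1, mode="nearest"
    ).reshape(coords.shape[:-1])
    return sampled > min_eig

def track_displacements(
    clip: CineClip,
    grid: FeatureGrid,
    window_size: int = 21,
    num_warp: int = 3,
    min_eigenvalue: float = 1e-3,
) -> TrajectorySet:
    """Track every grid point through the clip with Lucas–Kanade optical flow.

    Dense iterative-warping Lucas–Kanade flow (window ``window_size``) is
    computed for each adjacent frame pair and sampled at the current
    subpixel point positions.  Points seeded on texture-free patches, or
    that leave the frame, are invalid from that frame on.

    Parameters
    ----------
    window_size : int
        Side of the local least-squares window in pixels.
    num_warp : int
        Warping iterations of the flow solver (handles multi-pixel motion).
    min_eigenvalue : float
        Structure-tensor threshold below which a seed point is untrackable.
    """
    if clip.n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")
    h, w = clip.shape
    n_t = clip.n_frames

    coords = np.empty((n_t, grid.rows, grid.cols, 2), dtype=np.float64)
    coords[0] = grid.initial_coords
    valid = np.ones((n_t, grid.rows, grid.cols), dtype=bool)
    valid[0] = _texture_validity(clip.frames[0], grid.initial_coords, window_size, min_eigenvalue)

    radius = max(1, window_size // 2)
    # the grid moves at most a few pixels, so flow is only needed inside a
    # fixed band around the seeded points
    margin = window_size // 2 + 8
    x_lo = int(max(0, np.floor(grid.initial_coords[..., 0].min()) - margin))
    x_hi = int(min(w, np.ceil(grid.initial_coords[..., 0].max()) + margin + 1))
    y_lo = int(max(0, np.floor(grid.initial_coords[..., 1].min()) - margin))
    y_hi = int(min(h, np.ceil(grid.initial_coords[..., 1].max()) + margin + 1))
    frames32 = clip.frames[:, y_lo:y_hi, x_lo:x_hi].astype(np.float32)
    for t in range(n_t - 1):
        # optical_flow_ilk returns (row, col) displacement of frame t+1 -> t
        # when called as (reference=t, moving=t+1): flow maps t+1 onto t, so
        # the forward motion of a point from t to t+1 is +flow sampled at x_t.
        flow = optical_flow_ilk(
            frames32[t], frames32[t + 1], radius=radius, num_warp=num_warp, prefilter=True
        )
        xs = coords[t, ..., 0].ravel() - x_lo
        ys = coords[t, ..., 1].ravel() - y_lo
        dy = map_coordinates(flow[0], [ys, xs], order=1, mode="nearest")
        dx = map_coordinates(flow[1], [ys, xs], order=1, mode="nearest")
        coords[t + 1, ..., 0] = coords[t, ..., 0] + dx.reshape(grid.rows, grid.cols)
        coords[t + 1, ..., 1] = coords[t, ..., 1] + dy.reshape(grid.rows, grid.cols)

        inside = (
            (coords[t + 1, ..., 0] >= 0)
            & (coords[t + 1, ..., 0] <= w - 1)
            & (coords[t + 1, ..., 1] >= 0)
            & (coords[t + 1, ..., 1] <= h - 1)
        )
        valid[t + 1] = valid[t] & inside
        # lost points keep their last position to preserve array shape
        lost = ~valid[t + 1]
        coords[t + 1][lost] = coords[t][lost]

    displacements = np.diff(coords, axis=0)
    return TrajectorySet(coords=coords, displacements=displacements, valid_mask=valid)


def _masked_boxcar(values: np.ndarray, mask: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Moving average ignoring masked-out entries; window shrinks at borders."""
    if window == 1:
        return values
    from scipy.ndimage import uniform_filter1d

    weights = mask.astype(np.float64)
    num = uniform_filter1d(values * weights, size=window, axis=axis, mode="constant")
    den = uniform_filter1d(weights, size=window, axis=axis, mode="constant")
    out = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
    return out


def smooth_trajectories(
    traj: TrajectorySet, temporal_window: int = 5, spatial_window: int = 3
) -> TrajectorySet:
    """Denoise displacements: temporal boxcar per point, then spatial boxcar
    over the grid neighbourhood per frame.

    Windows must be odd; the averaging window shrinks at sequence and grid
    borders instead of padding, and invalid points are excluded from every
    average.  Positions are rebuilt from the smoothed displacements so the
    cumulative-sum invariant still holds.
    """
    for name, win in (("temporal", temporal_window), ("spatial", spatial_window)):
        if win < 1 or win % 2 == 0:
            raise ValueError(f"{name}_window must be odd and >= 1")

    disp = traj.displacements.copy()
    # a displacement t -> t+1 is meaningful where the point is valid at t+1
    dmask = traj.valid_mask[1:]
    mask4 = dmask[..., None] & np.ones_like(disp, dtype=bool)

    disp = _masked_boxcar(disp, mask4, temporal_window, axis=0)
    if spatial_window > 1:
        disp = _masked_boxcar(disp, mask4, spatial_window, axis=1)
        disp = _masked_boxcar(disp, mask4, spatial_window, axis=2)
    disp[~dmask] = 0.0

    coords = np.empty_like(traj.coords)
    coords[0] = traj.coords[0]
    coords[1:] = traj.coords[0][None] + np.cumsum(disp, axis=0)
    return replace(traj, coords=coords, displacements=disp)
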