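"""Motion graph, wave-event detection, and per-wave measurements.

The motion graph is the pair of per-frame counts (n_+, n_−) of rows whose
normalised curvature variation is salient and whose deformation pattern
travels in the forward (n_+) or backward (n_−) image direction.  Maximal
runs of wave activity become :class:`WaveEvent`\\ s, each classified by
direction (cervix-to-fundus CF, fundus-to-cervix FC, or mixed CF+FC),
graded for intensity (weak / moderate / strong from its normalised range
and amplitude), and measured for velocity (salient-front path length over
time, in mm/s, plus the dimensionless peak/wavelength shape ratio).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io_cine import CineClip, Orientation, ROIRect
from .salience import (
    DeltaTauField,
    SalienceField,
    compute_row_curvatures,
    compute_salience,
    curvature_variation,
    row_geometry,
    travel_direction_signs,
)
from .tracking import (
    FeatureGrid,
    TrajectorySet,
    generate_feature_grid,
    smooth_trajectories,
    track_displacements,
)

__all__ = [
    "Direction",
    "Intensity",
    "MotionGraph",
    "WaveEvent",
    "ClipReport",
    "PipelineResult",
    "build_motion_graph",
    "detect_wave_events",
    "classify_direction",
    "measure_intensity",
    "measure_velocity",
    "run_pipeline",
    "analyze_clip",
]


class Direction(str, enum.Enum):
    CF = "CF"  # cervix to fundus
    FC = "FC"  # fundus to cervix
    CF_FC = "CF_FC"  # both directions within one episode


class Intensity(str, enum.Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


@dataclass(frozen=True)
class MotionGraph:
    """Per-frame counts of salient forward (n_plus) and backward (n_minus) rows."""

    n_plus: np.ndarray  # (T,) int
    n_minus: np.ndarray  # (T,) int
    frame_rate: float
    total_rows: int

    @property
    def n_frames(self) -> int:
        return self.n_plus.shape[0]


@dataclass(frozen=True)
class WaveEvent:
    start_frame: int
    end_frame: int  # inclusive
    direction: Direction
    range: float  # normalised spatial extent (x-axis of the intensity plane)
    amplitude: float  # normalised peak height (y-axis)
    intensity_class: Intensity
    intensity_score: float  # range + amplitude
    velocity_mm_s: float
    shape_ratio: float  # amplitude / range (peak over wavelength)

    def to_dict(self) -> dict:
        return {
            "start_frame": self.start_frame,
            "end_frame": self.end_frame,
            "direction": self.direction.value,
            "range": self.range,
            "amplitude": self.amplitude,
            "intensity_class": self.intensity_class.value,
            "intensity_score": self.intensity_score,
            "velocity_mm_s": self.velocity_mm_s,
            "shape_ratio": self.shape_ratio,
        }


@dataclass(frozen=True)
class ClipReport:
    clip_id: str
    wave_count: int
    events: tuple[WaveEvent, ...]
    direction_counts: dict
    mean_intensity_score: float
    mean_velocity_mm_s: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clip_id": self.clip_id,
            "wave_count": self.wave_count,
            "events": [e.to_dict() for e in self.events],
            "direction_counts": dict(self.direction_counts),
            "mean_intensity_score": self.mean_intensity_score,
            "mean_velocity_mm_s": self.mean_velocity_mm_s,
            "config": dict(self.config),
        }


@dataclass(frozen=True)
class PipelineResult:
    """All intermediate stages of one clip analysis (for overlays/diagnostics)."""

    grid: FeatureGrid
    traj: TrajectorySet
    dtau: DeltaTauField
    salience: SalienceField
    graph: MotionGraph
    report: ClipReport


def build_motion_graph(
    sal: SalienceField, dtau: DeltaTauField, orientation: Orientation, frame_rate: float
) -> MotionGraph:
    """Count salient rows per frame by travel direction.

    Forward is image-left for a horizontal endometrium and image-down for a
    vertical one; the travel-sign channel of ``dtau`` already uses that
    convention.
    """
    if sal.salient_mask is None:
        raise ValueError("salience field has no threshold mask")
    signs = dtau.travel_sign if dtau.travel_sign is not None else dtau.sign
    if signs.shape != sal.salient_mask.shape:
        raise ValueError("salience and sign fields must share shape")
    n_plus = ((signs == 1) & sal.salient_mask).sum(axis=1).astype(int)
    n_minus = ((signs == -1) & sal.salient_mask).sum(axis=1).astype(int)
    return MotionGraph(
        n_plus=n_plus,
        n_minus=n_minus,
        frame_rate=frame_rate,
        total_rows=sal.salient_mask.shape[1],
    )


def detect_wave_events(
    graph: MotionGraph,
    min_count: int = 3,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 3.0,
) -> list[tuple[int, int]]:
    """Segment the motion graph into wave-event frame spans (inclusive).

    A frame is active when max(n_+, n_−) reaches ``min_count`` rows.  The
    lagged curvature variation of a single wave dips through zero mid-way
    (the bend stops growing and starts relaxing), so active runs separated
    by gaps shorter than ``merge_gap_s`` are merged first; surviving runs
    shorter than ``min_duration_s`` are then discarded.
    """
    if min_count < 1 or min_duration_s <= 0 or merge_gap_s < 0:
        raise ValueError("segmentation parameters must be positive")
    if graph.n_frames == 0:
        raise ValueError("empty motion graph")

    active = np.maximum(graph.n_plus, graph.n_minus) >= min_count
    runs: list[list[int]] = []
    for f in np.flatnonzero(active):
        if runs and f == runs[-1][1] + 1:
            runs[-1][1] = f
        else:
            runs.append([f, f])

    gap_frames = merge_gap_s * graph.frame_rate
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < gap_frames:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    min_frames = min_duration_s * graph.frame_rate
    return [(int(s), int(e)) for s, e in merged if (e - s + 1) >= min_frames]


def _side_present(counts: np.ndarray, min_count: int) -> bool:
    """A direction participates in an event when its curve rises above the
    noise floor: it reaches ``min_count`` rows somewhere in the span (an
    interior local maximum or an edge plateau both count as a peak)."""
    return counts.max(initial=0) >= min_count


def classify_direction(
    span: tuple[int, int],
    graph: MotionGraph,
    orientation: Orientation,
    min_count: int = 3,
) -> Direction:
    """CF / FC / CF+FC from the motion-graph pattern within the span.

    A pure one-way wave keeps the opposite curve at the noise floor; if
    both curves peak (alternately or simultaneously) the episode is mixed.
    Pure forward/backward is mapped to anatomy by the declared cervix side:
    forward motion with the cervix on the forward image side is CF.
    """
    s, e = span
    if not (0 <= s <= e < graph.n_frames):
        raise ValueError(f"invalid event span {span}")
    plus = _side_present(graph.n_plus[s : e + 1], min_count)
    minus = _side_present(graph.n_minus[s : e + 1], min_count)
    if not plus and not minus:
        raise ValueError(f"event span {span} contains no direction peaks")
    if plus and minus:
        return Direction.CF_FC
    forward = plus
    if orientation.cervix_on_forward_side:
        return Direction.CF if forward else Direction.FC
    return Direction.FC if forward else Direction.CF


def measure_intensity(
    span: tuple[int, int],
    graph: MotionGraph,
    sal: SalienceField,
    range_scale: float = 2.0,
    amp_scale: float = 2.0,
) -> tuple[float, float, Intensity, float]:
    """Range, amplitude, intensity class and score of one event.

    Range is the maximal fraction of simultaneously salient rows during the
    span, scaled by ``range_scale``; amplitude is the peak of
    (n_+ + n_−)/total rows scaled by ``amp_scale``.  With the default
    scales a wave involving half the rows sits at the class boundary 1.
    Class rule: both < 1 → weak, both > 1 → strong, otherwise moderate.
    """
    s, e = span
    total = graph.total_rows
    salient_rows = sal.salient_mask[s : e + 1].sum(axis=1)
    rng = salient_rows.max() / total * range_scale
    amp = (graph.n_plus + graph.n_minus)[s : e + 1].max() / total * amp_scale
    if rng < 1.0 and amp < 1.0:
        cls = Intensity.WEAK
    elif rng > 1.0 and amp > 1.0:
        cls = Intensity.STRONG
    else:
        cls = Intensity.MODERATE
    return float(rng), float(amp), cls, float(rng + amp)


def measure_velocity(
    span: tuple[int, int],
    sal: SalienceField,
    traj: TrajectorySet,
    grid: FeatureGrid,
    clip: CineClip,
    rng_amp: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Wave speed in mm/s and the peak/wavelength shape ratio.

    The axial centroid of the transverse-deformation pattern (|displacement|
    weighted axial position over the salient rows' valid points) is tracked
    through the span; its least-squares slope against time is the path
    length per unit time, converted with the pixel spacing.  The shape
    ratio is the event amplitude over its range.
    """
    s, e = span
    if e <= s:
        raise ValueError("zero-duration event span")
    axial, trans, valid = row_geometry(traj, grid, clip.orientation)
    if sal.salient_mask is None:
        raise ValueError("salience field has no threshold mask")

    frames, centroids = [], []
    for f in range(s, e + 1):
        rows = np.flatnonzero(sal.salient_mask[f])
        if rows.size == 0:
            continue
        w = np.abs(trans[f][rows])
        w = np.where(valid[f][rows], w, 0.0)
        total = w.sum()
        if total <= 1e-9:
            continue
        frames.append(f)
        centroids.append((w * axial[f][rows]).sum() / total)
    if len(frames) < 2:
        velocity = 0.0
    else:
        t = np.asarray(frames, dtype=float) / clip.frame_rate
        slope = np.polyfit(t, np.asarray(centroids), 1)[0]  # px/s
        velocity = abs(slope) * clip.pixel_spacing

    if rng_amp is None:
        shape_ratio = float("nan")
    else:
        rng, amp = rng_amp
        shape_ratio = amp / rng if rng > 0 else float("nan")
    return float(velocity), float(shape_ratio)


def run_pipeline(
    clip: CineClip,
    roi: ROIRect,
    config: RunConfig | None = None,
    clip_id: str = "clip",
) -> PipelineResult:
    """Full analysis of one cine clip; deterministic for fixed inputs."""
    cfg = config or RunConfig()
    roi.validate_inside(clip.shape)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    grid = stage("grid", generate_feature_grid, roi, cfg.grid_spacing)
    traj = stage(
        "tracking", track_displacements, clip, grid,
        window_size=cfg.flow_window, num_warp=cfg.num_warp,
    )
    traj = stage(
        "smoothing", smooth_trajectories, traj,
        temporal_window=cfg.temporal_window, spatial_window=cfg.spatial_window,
    )
    curv = stage("curvature", compute_row_curvatures, traj, grid, clip.orientation)
    dtau = stage("delta-tau", curvature_variation, curv, cfg.lag)
    signs = stage(
        "direction", travel_direction_signs, traj, grid, clip.orientation, cfg.lag
    )
    from dataclasses import replace as _replace

    dtau = _replace(dtau, travel_sign=signs)
    sal = stage("salience", compute_salience, dtau, cfg.alpha, cfg.beta, cfg.min_magnitude)
    graph = stage(
        "motion-graph", build_motion_graph, sal, dtau, clip.orientation, clip.frame_rate
    )
    spans = stage(
        "events", detect_wave_events, graph,
        cfg.min_count, cfg.min_duration_s, cfg.merge_gap_s,
    )

    events = []
    for span in spans:
        direction = classify_direction(span, graph, clip.orientation, cfg.min_count)
        rng, amp, cls, score = measure_intensity(
            span, graph, sal, cfg.range_scale, cfg.amp_scale
        )
        vel, ratio = measure_velocity(span, sal, traj, grid, clip, (rng, amp))
        events.append(
            WaveEvent(
                start_frame=span[0],
                end_frame=span[1],
                direction=direction,
                range=rng,
                amplitude=amp,
                intensity_class=cls,
                intensity_score=score,
                velocity_mm_s=vel,
                shape_ratio=ratio,
            )
        )

    counts = {d.value: 0 for d in Direction}
    for ev in events:
        counts[ev.direction.value] += 1
    report = ClipReport(
        clip_id=clip_id,
        wave_count=len(events),
        events=tuple(events),
        direction_counts=counts,
        mean_intensity_score=float(np.mean([e.intensity_score for e in events])) if events else 0.0,
        mean_velocity_mm_s=float(np.mean([e.velocity_mm_s for e in events])) if events else 0.0,
        config=cfg.to_dict(),
    )
    return PipelineResult(grid=grid, traj=traj, dtau=dtau, salience=sal, graph=graph, report=report)


def analyze_clip(
    clip: CineClip,
    roi: ROIRect,
    config: RunConfig | None = None,
    clip_id: str = "clip",
) -> ClipReport:
    """Analyse one clip and return its report (see :func:`run_pipeline`)."""
    return run_pipeline(clip, roi, config, clip_id).report
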