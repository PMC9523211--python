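"""Synthetic speckle phantom: cine clips with known peristaltic waves.

The generator emulates what a steady transvaginal probe sees: a static
speckle-textured field containing a horizontal (or vertical) endometrial
band, across which travelling transverse-displacement packets pass.  Each
packet is a raised-cosine bump of known amplitude (px), wavelength (the
bump's axial footprint, px) and speed (px/s) that enters from one edge of
the band and exits at the other; "both"-direction episodes launch a
forward packet followed shortly by a backward one, the way a mixed CF+FC
episode presents clinically.  Additive Gaussian intensity noise is drawn
from a seeded generator, so a fixed seed reproduces the clip bit for bit.

Desk-scale defaults: 128x128 px frames at 4 frames/s for 60 s, packet
speed ~20 px/s.  Relative to clinical recordings the time axis is
compressed (clinical waves take tens of seconds to cross the uterus); the
spatial deformation pattern, speckle texture and noise level are kept
realistic so the tracking and salience stages are exercised faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io_cine import CineClip, Orientation, ROIRect

__all__ = [
    "WaveSpec",
    "SyntheticSpec",
    "GroundTruthWave",
    "GroundTruth",
    "generate_speckle_background",
    "generate_peristalsis_clip",
    "default_roi",
    "random_spec",
]


@dataclass(frozen=True)
class WaveSpec:
    """One travelling peristaltic packet.

    direction: "forward" (image-left for a horizontal band), "backward",
    or "both" (a forward packet then a backward packet ~4 s later, forming
    one mixed episode).
    """

    start_s: float
    direction: str = "forward"
    amplitude_px: float = 4.5
    wavelength_px: float = 80.0
    speed_px_s: float = 20.0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.amplitude_px < 0:
            raise ValueError("amplitude must be >= 0")
        if self.speed_px_s <= 0 or self.wavelength_px <= 0:
            raise ValueError("speed and wavelength must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one phantom clip."""

    shape: tuple[int, int] = (128, 128)  # (H, W)
    frame_rate: float = 4.0
    duration_s: float = 60.0
    orientation: Orientation = Orientation.CERVIX_LEFT
    band_center: int = 64  # transverse centre of the endometrial band (px)
    band_thickness: int = 56  # full-displacement thickness (px)
    band_taper: int = 10  # cosine falloff outside the band (px)
    waves: tuple[WaveSpec, ...] = ()
    speckle_grain_px: float = 2.5
    noise_sigma: float = 2.0
    pixel_spacing_mm: float = 0.1
    rigid_drift_px: float = 0.0  # probe-slip control: whole-frame translation
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def axial_extent(self) -> int:
        h, w = self.shape
        return w if Orientation(self.orientation).horizontal else h


@dataclass(frozen=True)
class GroundTruthWave:
    start_frame: int
    end_frame: int
    direction: str  # forward / backward / both
    speed_px_s: float
    speed_mm_s: float
    amplitude_px: float


@dataclass(frozen=True)
class GroundTruth:
    waves: tuple[GroundTruthWave, ...] = field(default_factory=tuple)


def generate_speckle_background(
    shape: tuple[int, int], grain_size: float = 2.5, seed: int = 0
) -> np.ndarray:
    """Low-pass-filtered seeded noise rescaled to the [30, 220] intensity band."""
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("background must be at least 64x64")
    rng = np.random.default_rng(seed)
    # oversample so warping can sample outside the frame without artefacts
    noise = rng.standard_normal(shape)
    img = gaussian_filter(noise, sigma=grain_size / 2.0, mode="wrap")
    lo, hi = img.min(), img.max()
    return 30.0 + (img - lo) / (hi - lo) * 190.0


def _packet_profile(axial: np.ndarray, center: float, wavelength: float) -> np.ndarray:
    """Raised-cosine bump of full width ``wavelength`` centred at ``center``."""
    u = (axial - center) / wavelength
    out = np.zeros_like(axial, dtype=float)
    inside = np.abs(u) < 0.5
    out[inside] = np.cos(np.pi * u[inside]) ** 2
    return out


def _transverse_taper(transverse: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    half = spec.band_thickness / 2.0
    dist = np.abs(transverse - spec.band_center)
    taper = np.zeros_like(transverse, dtype=float)
    taper[dist <= half] = 1.0
    edge = (dist > half) & (dist <= half + spec.band_taper)
    taper[edge] = np.cos(np.pi / 2.0 * (dist[edge] - half) / spec.band_taper) ** 2
    return taper


def _sub_packets(wave: WaveSpec) -> list[tuple[float, str]]:
    """Elementary (start time, forward/backward) packets of one wave spec."""
    if wave.direction == "both":
        return [(wave.start_s, "forward"), (wave.start_s + 4.0, "backward")]
    return [(wave.start_s, wave.direction)]


def _packet_center(
    t: float, start_s: float, direction: str, extent: int, wavelength: float, speed: float
) -> float:
    """Axial position of a packet centre at time t (enters at the edge)."""
    travelled = speed * (t - start_s)
    if direction == "forward":  # image-left / image-down start from the far edge
        return extent - 1 + wavelength / 2.0 - travelled
    return -wavelength / 2.0 + travelled


def _transit_time(extent: int, wavelength: float, speed: float) -> float:
    return (extent - 1 + wavelength) / speed


def displacement_field(spec: SyntheticSpec, axial: np.ndarray, t: float) -> np.ndarray:
    """Superposed transverse displacement d(axial, t) of all packets (px)."""
    d = np.zeros_like(axial, dtype=float)
    for wave in spec.waves:
        for start_s, direction in _sub_packets(wave):
            if t < start_s:
                continue
            center = _packet_center(
                t, start_s, direction, spec.axial_extent, wave.wavelength_px, wave.speed_px_s
            )
            d += wave.amplitude_px * _packet_profile(axial, center, wave.wavelength_px)
    return d


def generate_peristalsis_clip(spec: SyntheticSpec) -> tuple[CineClip, GroundTruth]:
    """Render the phantom clip and its per-wave ground truth."""
    orientation = Orientation(spec.orientation)
    extent = spec.axial_extent
    for wave in spec.waves:
        for start_s, direction in _sub_packets(wave):
            end = start_s + _transit_time(extent, wave.wavelength_px, wave.speed_px_s)
            if start_s < 0 or end > spec.duration_s:
                raise ValueError(
                    f"wave starting at {start_s:.1f}s would end at {end:.1f}s, "
                    f"outside the {spec.duration_s:.1f}s clip"
                )

    h, w = spec.shape
    bg = generate_speckle_background(spec.shape, spec.speckle_grain_px, spec.seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if orientation.horizontal:
        axial, transverse = xx, yy
    else:
        axial, transverse = yy, xx
    taper = _transverse_taper(transverse, spec)

    n_frames = spec.n_frames
    frames = np.empty((n_frames, h, w), dtype=np.float64)
    for f in range(n_frames):
        t = f / spec.frame_rate
        d = displacement_field(spec, axial[0] if orientation.horizontal else axial[:, 0], t)
        if orientation.horizontal:
            dmap = taper * d[None, :]
            src_y, src_x = yy - dmap, xx
        else:
            dmap = taper * d[:, None]
            src_y, src_x = yy, xx - dmap
        if spec.rigid_drift_px:
            # slow sinusoidal whole-frame translation along the long axis
            shift = spec.rigid_drift_px * np.sin(2.0 * np.pi * t / spec.duration_s)
            if orientation.horizontal:
                src_x = src_x + shift
            else:
                src_y = src_y + shift
        warped = map_coordinates(bg, [src_y, src_x], order=3, mode="reflect")
        noisy = warped + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        frames[f] = np.clip(noisy, 0.0, 255.0)

    truth_waves = []
    for wave in spec.waves:
        packets = _sub_packets(wave)
        starts = [p[0] for p in packets]
        ends = [
            s + _transit_time(extent, wave.wavelength_px, wave.speed_px_s) for s in starts
        ]
        truth_waves.append(
            GroundTruthWave(
                start_frame=int(np.floor(min(starts) * spec.frame_rate)),
                end_frame=min(
                    n_frames - 1, int(np.ceil(max(ends) * spec.frame_rate))
                ),
                direction=wave.direction,
                speed_px_s=wave.speed_px_s,
                speed_mm_s=wave.speed_px_s * spec.pixel_spacing_mm,
                amplitude_px=wave.amplitude_px,
            )
        )

    clip = CineClip(
        frames=frames,
        frame_rate=spec.frame_rate,
        pixel_spacing=spec.pixel_spacing_mm,
        orientation=orientation,
    )
    return clip, GroundTruth(waves=tuple(truth_waves))


def default_roi(spec: SyntheticSpec) -> ROIRect:
    """ROI covering the phantom's endometrial band (flat-displacement zone)."""
    h, w = spec.shape
    half = spec.band_thickness // 2
    if Orientation(spec.orientation).horizontal:
        return ROIRect(x0=8, y0=spec.band_center - half + 2, width=w - 16, height=spec.band_thickness - 4)
    return ROIRect(x0=spec.band_center - half + 2, y0=8, width=spec.band_thickness - 4, height=h - 16)


def random_spec(
    n_waves: int,
    seed: int = 0,
    directions: tuple[str, ...] = ("forward", "backward"),
    amplitude_range: tuple[float, float] = (4.0, 5.5),
) -> SyntheticSpec:
    """A phantom recipe with ``n_waves`` well-separated seeded waves.

    Wave onsets are spaced ~14 s apart (with seeded jitter) so successive
    transits stay distinct; directions and amplitudes are drawn from the
    given sets.  Detection works on clip-relative salience, so amplitudes
    are kept comparable within a clip.
    """
    if not 1 <= n_waves <= 4:
        raise ValueError("supported range is 1..4 waves per clip")
    rng = np.random.default_rng(seed)
    waves = []
    for i in range(n_waves):
        start = 1.0 + 14.0 * i + rng.uniform(0.0, 2.0)
        waves.append(
            WaveSpec(
                start_s=start,
                direction=str(rng.choice(directions)),
                amplitude_px=float(rng.uniform(*amplitude_range)),
                wavelength_px=80.0,
                speed_px_s=20.0,
            )
        )
    return SyntheticSpec(waves=tuple(waves), seed=seed)
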