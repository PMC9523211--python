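"""Cine clip I/O: calibrated frame stacks, ROI configuration, overlay output.

A cine loop is a 2-minute transvaginal ultrasound recording exported as an
AVI/MP4 file.  The container carries no calibration, so pixel spacing
(mm/px) and — where the container metadata is unreliable — the frame rate
are supplied by the user, together with the anatomical orientation of the
endometrium (which image side the cervix lies on).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _avi

__all__ = [
    "Orientation",
    "CineClip",
    "ROIRect",
    "ClipConfig",
    "load_clip",
    "write_overlay_video",
    "load_config",
]

#: ITU-R BT.601 luma weights used to collapse RGB sources to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class Orientation(str, enum.Enum):
    """Which image side the cervix lies on.

    ``cervix_left``/``cervix_right`` declare a horizontally oriented
    endometrium (long axis along image x), ``cervix_up``/``cervix_down`` a
    vertical one.  The motion-graph convention takes image-left (horizontal)
    or image-down (vertical) as the "forward" direction.
    """

    CERVIX_LEFT = "cervix_left"
    CERVIX_RIGHT = "cervix_right"
    CERVIX_UP = "cervix_up"
    CERVIX_DOWN = "cervix_down"

    @property
    def horizontal(self) -> bool:
        return self in (Orientation.CERVIX_LEFT, Orientation.CERVIX_RIGHT)

    @property
    def cervix_on_forward_side(self) -> bool:
        """True when the cervix lies on the forward image side.

        Forward is image-left for a horizontal endometrium and image-down
        for a vertical one.
        """
        return self in (Orientation.CERVIX_LEFT, Orientation.CERVIX_DOWN)

    def flipped(self) -> "Orientation":
        """The orientation naming the opposite cervix side on the same axis."""
        return {
            Orientation.CERVIX_LEFT: Orientation.CERVIX_RIGHT,
            Orientation.CERVIX_RIGHT: Orientation.CERVIX_LEFT,
            Orientation.CERVIX_UP: Orientation.CERVIX_DOWN,
            Orientation.CERVIX_DOWN: Orientation.CERVIX_UP,
        }[self]


@dataclass(frozen=True)
class CineClip:
    """A calibrated grayscale cine stack.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W), float64 in [0, 255]
        Temporal order equals index order.
    frame_rate : float
        Frames per second (> 0).
    pixel_spacing : float
        Millimetres per pixel (> 0), assumed isotropic.
    orientation : Orientation
        Declared cervix side of the imaged endometrium.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: float
    orientation: Orientation = Orientation.CERVIX_LEFT

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if frames.shape[0] < 2:
            raise ValueError("a cine clip needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Clip duration in seconds (frame count / frame rate)."""
        return self.n_frames / self.frame_rate

    def time_reversed(self) -> "CineClip":
        return replace(self, frames=self.frames[::-1].copy())

    def mirrored(self) -> "CineClip":
        """Flip frames along the endometrial long axis and swap the cervix side."""
        axis = 2 if self.orientation.horizontal else 1
        return replace(
            self,
            frames=np.flip(self.frames, axis=axis).copy(),
            orientation=self.orientation.flipped(),
        )


@dataclass(frozen=True)
class ROIRect:
    """Axis-aligned rectangle around the endometrium.

    Half-open pixel extent ``[x0, x0 + width) x [y0, y0 + height)`` with
    0-based coordinates, x rightward and y downward.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI extent must be positive")

    def validate_inside(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"ROI {self} exceeds the {w}x{h} frame"
            )


@dataclass(frozen=True)
class ClipConfig:
    """Per-clip acquisition metadata read from a JSON or key=value file."""

    roi: ROIRect
    pixel_spacing_mm: float
    frame_rate: float | None
    orientation: Orientation = Orientation.CERVIX_LEFT
    extra: dict = field(default_factory=dict)


def load_clip(
    path: str | Path,
    pixel_spacing: float,
    frame_rate_override: float | None = None,
    orientation: Orientation | str = Orientation.CERVIX_LEFT,
) -> CineClip:
    """Read an AVI/MP4 cine file into a calibrated grayscale stack.

    RGB sources are collapsed to grayscale with BT.601 luma weights; the
    frame rate comes from the container unless overridden.  Uncompressed
    AVI is decoded natively; other containers are attempted through
    :mod:`imageio` when a video backend is installed.
    """
    path = Path(path)
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    if suffix == ".avi":
        rgb, native_rate = _avi.read_avi(path)
    else:
        rgb, native_rate = _read_via_imageio(path)

    if rgb.shape[0] < 2:
        raise ValueError(f"{path}: a cine clip needs at least 2 frames")

    gray = rgb.astype(np.float64) @ _LUMA
    rate = frame_rate_override if frame_rate_override is not None else native_rate
    return CineClip(
        frames=gray,
        frame_rate=float(rate),
        pixel_spacing=float(pixel_spacing),
        orientation=Orientation(orientation),
    )


def _read_via_imageio(path: Path) -> tuple[np.ndarray, float]:
    try:
        import imageio.v2 as iio

        reader = iio.get_reader(str(path))
        meta = reader.get_meta_data()
        frames = np.stack([np.asarray(f) for f in reader])
        reader.close()
    except Exception as exc:  # pragma: no cover - backend availability varies
        raise _avi.AviFormatError(
            f"{path}: cannot decode; install an imageio video backend or "
            "convert to uncompressed AVI"
        ) from exc
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    return frames[..., :3].astype(np.uint8), float(meta.get("fps", 25.0))


def write_overlay_video(
    frames, path: str | Path, frame_rate: float
) -> None:
    """Write a rendered RGB overlay sequence as an uncompressed AVI."""
    frames = [np.asarray(f) for f in frames]
    if len(frames) == 0:
        raise ValueError("cannot write an empty frame sequence")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share the same shape")
    if len(shape) != 3 or shape[-1] != 3:
        raise ValueError("overlay frames must be RGB (H, W, 3)")
    stack = np.clip(np.stack(frames), 0, 255).astype(np.uint8)
    _avi.write_avi(path, stack, frame_rate)


def load_config(path: str | Path) -> ClipConfig:
    """Parse a per-clip config file (JSON object or ``key=value`` lines).

    Recognised keys: ``roi.x0, roi.y0, roi.width, roi.height,
    pixel_spacing_mm, frame_rate, orientation``.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        flat: dict = {}

        def flatten(prefix: str, obj) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    flatten(f"{prefix}{k}." if isinstance(v, dict) else f"{prefix}{k}", v)
            else:
                flat[prefix] = obj

        for k, v in json.loads(text).items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    flat[f"{k}.{k2}"] = v2
            else:
                flat[k] = v
        raw = flat
    else:
        raw = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value

    try:
        roi = ROIRect(
            x0=int(raw["roi.x0"]),
            y0=int(raw["roi.y0"]),
            width=int(raw["roi.width"]),
            height=int(raw["roi.height"]),
        )
        spacing = float(raw["pixel_spacing_mm"])
    except KeyError as exc:
        raise ValueError(f"config missing required key {exc.args[0]!r}") from exc
    rate = raw.get("frame_rate")
    known = {
        "roi.x0", "roi.y0", "roi.width", "roi.height",
        "pixel_spacing_mm", "frame_rate", "orientation",
    }
    return ClipConfig(
        roi=roi,
        pixel_spacing_mm=spacing,
        frame_rate=float(rate) if rate is not None else None,
        orientation=Orientation(raw.get("orientation", "cervix_left")),
        extra={k: v for k, v in raw.items() if k not in known},
    )
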