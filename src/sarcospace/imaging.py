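"""Images, frame stacks, line ROIs and their file formats.

Coordinate convention: continuous pixel coordinates, x to the right and
y down, origin at the *center* of the top-left pixel.  Conversion to
micrometres multiplies by ``pixel_size`` (μm/px).

TIFF holds the raster; the pixel size travels in a JSON sidecar named
``<image>.json`` next to the TIFF (written automatically) or is supplied
explicitly.  A missing pixel size is always an error, never a silent
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError

__all__ = [
    "Image",
    "ImageStack",
    "LineROI",
    "read_image",
    "read_stack",
    "write_image",
    "write_stack",
    "read_roi",
    "write_roi",
    "write_results",
]


@dataclass(frozen=True)
class Image:
    """A single-channel 2-D intensity raster with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float  # μm/px

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidInputError(
                f"Image requires a non-empty 2-D raster, got shape {px.shape}"
            )
        if not self.pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImageStack:
    """Ordered frames sharing shape and pixel size."""

    frames: tuple[Image, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 1:
            raise InvalidInputError("ImageStack requires at least one frame")
        shape, ps = frames[0].shape, frames[0].pixel_size
        for i, f in enumerate(frames):
            if f.shape != shape or f.pixel_size != ps:
                raise InvalidInputError(
                    f"frame {i} has shape {f.shape}/pixel_size {f.pixel_size}, "
                    f"expected {shape}/{ps}"
                )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    def as_array(self) -> np.ndarray:
        """(n_frames, rows, cols) array view of the stack."""
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class LineROI:
    """Straight sampling line with an odd perpendicular averaging width.

    The odd width keeps the averaging band symmetric about the line; the
    conventional choice for striation profiles is ``width=5``.
    """

    p0: tuple[float, float]  # (x, y) px
    p1: tuple[float, float]
    width: int = 5

    def __post_init__(self) -> None:
        p0 = (float(self.p0[0]), float(self.p0[1]))
        p1 = (float(self.p1[0]), float(self.p1[1]))
        if p0 == p1:
            raise InvalidInputError("ROI endpoints must differ")
        if int(self.width) != self.width or self.width < 1 or self.width % 2 == 0:
            raise InvalidInputError(
                f"ROI width must be an odd integer >= 1, got {self.width}"
            )
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "width", int(self.width))

    @property
    def length(self) -> float:
        """Length in pixels."""
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def reversed(self) -> "LineROI":
        return LineROI(self.p1, self.p0, self.width)


# ---------------------------------------------------------------------------
# TIFF I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _resolve_pixel_size(path: Path, pixel_size: float | None) -> float:
    if pixel_size is not None:
        if not pixel_size > 0:
            raise InvalidInputError(f"pixel_size must be > 0, got {pixel_size}")
        return float(pixel_size)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "pixel_size_um" in meta:
            return float(meta["pixel_size_um"])
    raise InvalidInputError(
        f"pixel size for {path} not given and no sidecar {sidecar.name} found; "
        "pass pixel_size explicitly (μm/px)"
    )


def _load_pages(path: Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        photometric = tif.pages[0].photometric
        if photometric in (
            tifffile.PHOTOMETRIC.RGB,
            tifffile.PHOTOMETRIC.PALETTE,
        ):
            raise InvalidInputError(
                f"{path} is {photometric.name}; only single-channel grayscale "
                "TIFF is supported"
            )
        data = tif.asarray()
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        raise InvalidInputError(
            f"{path} has {data.shape[-1]} samples per pixel; only "
            "single-channel grayscale TIFF is supported"
        )
    return data


def read_image(path: str | Path, pixel_size: float | None = None) -> Image:
    """Read a single-page grayscale TIFF.

    Intensities are preserved losslessly for integer TIFFs.  Raises
    :class:`InvalidInputError` on RGB/palette input, on multipage files
    (use :func:`read_stack`) and when no pixel size can be resolved.
    """
    path = Path(path)
    data = _load_pages(path)
    if data.ndim == 3:
        raise InvalidInputError(
            f"{path} has {data.shape[0]} pages; use read_stack for stacks"
        )
    return Image(data, _resolve_pixel_size(path, pixel_size))


def read_stack(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Read a (possibly multipage) grayscale TIFF as a frame stack."""
    path = Path(path)
    data = _load_pages(path)
    if data.ndim == 2:
        data = data[None]
    ps = _resolve_pixel_size(path, pixel_size)
    return ImageStack(tuple(Image(frame, ps) for frame in data))


def write_image(image: Image, path: str | Path) -> Path:
    """Write a grayscale TIFF plus a pixel-size sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": image.pixel_size}, indent=2)
    )
    return path


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write frames as a multipage grayscale TIFF with sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.as_array(), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": stack.pixel_size}, indent=2)
    )
    return path


# ---------------------------------------------------------------------------
# ROI and result files


def read_roi(path: str | Path) -> LineROI:
    """Read a line ROI from JSON ``{"p0": [x, y], "p1": [x, y], "width": w}``."""
    path = Path(path)
    try:
        spec = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"{path}: malformed JSON ({exc})") from exc
    for key in ("p0", "p1"):
        if key not in spec:
            raise InvalidInputError(f"{path}: missing field '{key}'")
        pt = spec[key]
        if not (isinstance(pt, (list, tuple)) and len(pt) == 2):
            raise InvalidInputError(f"{path}: field '{key}' must be [x, y], got {pt!r}")
    return LineROI(tuple(spec["p0"]), tuple(spec["p1"]), spec.get("width", 5))


def write_roi(roi: LineROI, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps({"p0": list(roi.p0), "p1": list(roi.p1), "width": roi.width}, indent=2)
    )
    return path


def write_results(
    spacing,
    fit,
    out_dir: str | Path,
    stem: str = "spacing",
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write the per-distance CSV and the JSON summary report.

    CSV columns: distance index, left/right peak centers (μm), distance
    (μm) and the kept flag; the JSON mirrors the summary statistics and
    full fit diagnostics so a report round-trips every printed digit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}_distances.csv"
    json_path = out_dir / f"{stem}_summary.json"

    rows = [
        {
            "index": i,
            "left_center_um": d.left,
            "right_center_um": d.right,
            "distance_um": d.value,
            "kept": d.kept,
        }
        for i, d in enumerate(spacing.distances)
    ]
    pd.DataFrame(rows, columns=["index", "left_center_um", "right_center_um", "distance_um", "kept"]).to_csv(
        csv_path, index=False
    )

    summary = {
        "mean_um": spacing.mean,
        "sd_um": spacing.sd,
        "n": spacing.n,
        "fit": fit.to_dict() if fit is not None else None,
    }
    if extra:
        summary.update(extra)
    json_path.write_text(json.dumps(summary, indent=2, default=float))
    return csv_path, json_path
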