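"""Stain-intensity line profiles from RGB whole-mount images.

A digit is traced by a distal-to-proximal polyline; the image is sampled at
unit arclength steps along it and each RGB sample is converted to an
optical density (OD) by projecting per-channel Beer-Lambert absorbances
onto a fixed purple stain direction.  Unit-arclength stepping (rather than
raster stepping) keeps diagonal lines from being foreshortened relative to
axis-aligned ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .core_phenotype import DigitID, as_stage

__all__ = [
    "DEFAULT_STAIN_UNIT",
    "DEFAULT_BACKGROUND_RGB",
    "StainModel",
    "ProfileMeta",
    "IntensityProfile",
    "PolylineError",
    "sample_line",
    "purple_od",
    "extract_profile",
    "polyline_length",
    "read_polyline_csv",
    "write_polyline_csv",
    "read_profile_csv",
    "write_profile_csv",
]

MIN_PROFILE_SAMPLES = 32

#: Default absorbance direction of the purple stain (unit-normalized).
DEFAULT_STAIN_UNIT = np.array([0.59, 0.74, 0.33]) / np.linalg.norm([0.59, 0.74, 0.33])

#: Default pale-tissue background, RGB in [0, 1].
DEFAULT_BACKGROUND_RGB = (0.93, 0.91, 0.87)


class PolylineError(ValueError):
    """Raised for degenerate or out-of-bounds polylines."""


@dataclass(frozen=True)
class StainModel:
    """Color-to-OD mapping: project per-channel OD on a stain unit vector."""

    stain_rgb_unit: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_UNIT.copy())
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND_RGB
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        unit = np.asarray(self.stain_rgb_unit, dtype=float)
        if unit.shape != (3,) or not np.all(np.isfinite(unit)) or np.linalg.norm(unit) == 0:
            raise ValueError("stain_rgb_unit must be a finite non-zero 3-vector")
        object.__setattr__(self, "stain_rgb_unit", unit / np.linalg.norm(unit))
        bg = tuple(float(c) for c in self.background_rgb)
        if len(bg) != 3 or any(c <= 0 for c in bg):
            raise ValueError("background_rgb channels must be positive")
        object.__setattr__(self, "background_rgb", bg)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ProfileMeta:
    """Specimen/stage/digit annotation carried along with a profile."""

    specimen: str = ""
    stage: Optional[float] = None
    digit: Optional[DigitID] = None

    def __post_init__(self) -> None:
        if self.stage is not None:
            object.__setattr__(self, "stage", as_stage(self.stage))


@dataclass
class IntensityProfile:
    """Ordered distal-to-proximal OD samples for one digit."""

    samples: np.ndarray
    meta: ProfileMeta = field(default_factory=ProfileMeta)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < MIN_PROFILE_SAMPLES:
            raise ValueError(f"profile needs >= {MIN_PROFILE_SAMPLES} samples, got {s.size}")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("profile samples must be finite and non-negative")
        self.samples = s

    @property
    def n_raw(self) -> int:
        return int(self.samples.size)


def _as_polyline(line: np.ndarray) -> np.ndarray:
    pts = np.asarray(line, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise PolylineError("polyline must be an (n >= 2, 2) array of (x, y) points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if seg.sum() <= 0:
        raise PolylineError("polyline has zero arclength")
    return pts


def polyline_length(line: np.ndarray) -> float:
    """Total Euclidean arclength of a polyline in pixels."""
    pts = _as_polyline(line)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / float(np.iinfo(img.dtype).max)
    return img.astype(float, copy=False)


def sample_line(image: np.ndarray, line: np.ndarray) -> np.ndarray:
    """Sample RGB values at unit-arclength steps along *line*.

    Returns an ``(n, 3)`` array ordered as the polyline is (distal end
    first, by convention).  ``n`` equals ``round(arclength) + 1`` so a
    horizontal span of 100 pixels yields 100 samples, and the count stays
    within one sample of the Euclidean arclength for any orientation.
    Bilinear interpolation is used between pixel centers.
    """
    img = _as_float_image(image)
    pts = _as_polyline(line)
    h, w = img.shape[:2]
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > w - 1
        or pts[:, 1].max() > h - 1
    ):
        raise PolylineError(
            f"polyline exceeds image bounds {w}x{h}: "
            f"x in [{pts[:, 0].min():.1f}, {pts[:, 0].max():.1f}], "
            f"y in [{pts[:, 1].min():.1f}, {pts[:, 1].max():.1f}]"
        )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(round(total)) + 1, 2)
    t = np.linspace(0.0, total, n)
    xs = np.interp(t, cum, pts[:, 0])
    ys = np.interp(t, cum, pts[:, 1])
    coords = np.vstack([ys, xs])  # map_coordinates expects (row, col)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(img[:, :, c], coords, order=1, mode="nearest")
    return out


def purple_od(rgb_samples: np.ndarray, model: Optional[StainModel] = None) -> np.ndarray:
    """Convert RGB samples to stain OD.

    Per channel, OD = -log10((value + eps) / (background + eps)); the
    3-vector of channel ODs is projected onto the stain unit vector and
    clipped at zero, so background pixels map to ~0.
    """
    model = model or StainModel()
    rgb = np.asarray(rgb_samples, dtype=float)
    if rgb.ndim == 1:
        rgb = rgb[None, :]
    bg = np.asarray(model.background_rgb)
    od_vec = -np.log10((rgb + model.epsilon) / (bg + model.epsilon))
    return np.clip(od_vec @ model.stain_rgb_unit, 0.0, None)


def extract_profile(
    image: np.ndarray,
    line: np.ndarray,
    model: Optional[StainModel] = None,
    meta: Optional[ProfileMeta] = None,
    smooth_window: int = 1,
) -> IntensityProfile:
    """Sample a polyline and convert it to an OD profile in one step.

    ``smooth_window`` > 1 applies a centered moving average of that many
    samples (edge-truncated); the default of 1 leaves the profile raw.
    """
    od = purple_od(sample_line(image, line), model)
    if smooth_window > 1:
        kernel = np.ones(int(smooth_window))
        od = np.convolve(od, kernel, mode="same") / np.convolve(
            np.ones_like(od), kernel, mode="same"
        )
    return IntensityProfile(samples=od, meta=meta or ProfileMeta())


# -- plain-text I/O ---------------------------------------------------------


def read_polyline_csv(path: "str | Path") -> np.ndarray:
    """Read an (x, y)-per-row polyline CSV (header optional, distal first)."""
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError:
                continue  # header line
    if len(rows) < 2:
        raise PolylineError(f"no polyline points found in {path}")
    return np.asarray(rows, dtype=float)


def write_polyline_csv(path: "str | Path", line: np.ndarray) -> None:
    pts = _as_polyline(line)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        writer.writerows([[f"{x:.3f}", f"{y:.3f}"] for x, y in pts])


def write_profile_csv(path: "str | Path", profile: IntensityProfile) -> None:
    """Write a profile as CSV with '#'-prefixed metadata header lines."""
    meta = profile.meta
    with open(path, "w", newline="") as fh:
        fh.write(f"# specimen={meta.specimen}\n")
        fh.write(f"# stage={'' if meta.stage is None else meta.stage}\n")
        if meta.digit is not None:
            fh.write(f"# limb={meta.digit.limb.value}\n")
            fh.write(f"# digit={meta.digit.index}\n")
        writer = csv.writer(fh)
        writer.writerow(["position_px", "od"])
        for i, od in enumerate(profile.samples):
            writer.writerow([i, f"{od:.6f}"])


def read_profile_csv(path: "str | Path") -> IntensityProfile:
    """Inverse of :func:`write_profile_csv`."""
    header: dict[str, str] = {}
    values: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            if row[0].startswith("#"):
                key, _, val = row[0].lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
                continue
            try:
                values.append(float(row[1]))
            except (IndexError, ValueError):
                continue  # column header
    digit = None
    if "limb" in header and "digit" in header:
        digit = DigitID(header["limb"], int(header["digit"]))
    meta = ProfileMeta(
        specimen=header.get("specimen", ""),
        stage=float(header["stage"]) if header.get("stage") else None,
        digit=digit,
    )
    return IntensityProfile(samples=np.asarray(values), meta=meta)
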