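"""AIS morphometry from fluorescence line profiles and images.

The axon initial segment is measured on a 1-D intensity profile drawn along
the proximal axon (betaIV-spectrin channel): its proximal and distal
boundaries are the first and last positions where the intensity surpasses a
threshold defined *relative to the maximum* intensity of that profile
(default 30%, adjustable per image in the 10-30% range). Length is the
distance between the interpolated boundary crossings. Diameter is the full
width at half maximum of a perpendicular intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import DetectionError, GeometryError, ParameterError

__all__ = [
    "IntensityProfile",
    "AISMeasurement",
    "extract_profile",
    "measure_ais",
    "measure_diameter",
    "fwhm",
]


@dataclass
class IntensityProfile:
    """A 1-D fluorescence intensity profile sampled at uniform spacing.

    ``positions`` are in micrometres, 0 at the soma-proximal origin of the
    line; ``intensities`` are arbitrary fluorescence units, >= 0.
    """

    positions: np.ndarray
    intensities: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ParameterError("positions and intensities must be matching 1-D arrays")
        d = np.diff(self.positions)
        if self.positions.size >= 2 and (
            np.any(d <= 0) or np.max(np.abs(d - d[0])) > 1e-6 * d[0]
        ):
            raise ParameterError("positions must be strictly increasing and uniform")
        if np.any(self.intensities < 0):
            raise ParameterError("intensities must be >= 0")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")


@dataclass
class AISMeasurement:
    """Boundaries and length of one AIS from a line profile."""

    start_um: float
    end_um: float
    length_um: float
    threshold_fraction: float
    max_intensity_position_um: float
    diameter_um: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start_um < self.end_um:
            raise ParameterError("start must precede end")
        if not 0 < self.threshold_fraction < 1:
            raise ParameterError("threshold_fraction must be in (0, 1)")


def _smooth(y: np.ndarray, width_px: int) -> np.ndarray:
    """Moving average with reflective edge handling."""
    if width_px <= 1:
        return y
    pad = width_px // 2
    yp = np.pad(y, pad, mode="reflect")
    kernel = np.ones(width_px) / width_px
    out = np.convolve(yp, kernel, mode="same")[pad : pad + y.size]
    return out


def _interp_crossing(x0, x1, y0, y1, level):
    if y1 == y0:
        return x0
    return x0 + (x1 - x0) * (level - y0) / (y1 - y0)


def measure_ais(
    profile: IntensityProfile,
    threshold_fraction: float = 0.3,
    *,
    smooth_px: int = 3,
    subtract_background: bool = True,
) -> AISMeasurement:
    """Measure AIS boundaries by the relative-intensity-threshold method.

    After optional 3-pixel moving-average smoothing and background
    subtraction (the profile minimum), the boundaries are the first and last
    positions where the intensity surpasses ``threshold_fraction`` of the
    profile maximum, linearly interpolated between samples. With several
    disjoint suprathreshold runs (e.g. nodes of Ranvier in the background)
    the longest run is measured and the profile is flagged.
    """
    if not 0.05 <= threshold_fraction <= 0.5:
        raise ParameterError("threshold_fraction outside the supported [0.05, 0.5] range")
    x = profile.positions
    y = _smooth(profile.intensities, smooth_px)
    flags: list[str] = []
    if subtract_background:
        y = y - y.min()
    peak = float(y.max())
    if peak <= 0:
        raise DetectionError("profile has no intensity above background")
    level = threshold_fraction * peak
    above = y > level
    if not above.any():
        raise DetectionError("threshold never surpassed on this profile")

    # contiguous suprathreshold runs; keep the longest
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks], idx[-1]]
    if run_starts.size > 1:
        flags.append("multiple_suprathreshold_runs")
    k = int(np.argmax(run_ends - run_starts))
    i0, i1 = int(run_starts[k]), int(run_ends[k])

    if i0 > 0:
        start = _interp_crossing(x[i0 - 1], x[i0], y[i0 - 1], y[i0], level)
    else:
        start = float(x[0])
        flags.append("start_clipped")
    if i1 < x.size - 1:
        end = _interp_crossing(x[i1 + 1], x[i1], y[i1 + 1], y[i1], level)
    else:
        end = float(x[-1])
        flags.append("end_clipped")

    return AISMeasurement(
        start_um=float(start),
        end_um=float(end),
        length_um=float(end - start),
        threshold_fraction=threshold_fraction,
        max_intensity_position_um=float(x[np.argmax(y)]),
        flags=flags,
    )


def extract_profile(
    image: np.ndarray,
    path_px: np.ndarray,
    pixel_size_um: float,
    line_width_px: int = 1,
) -> IntensityProfile:
    """Sample image intensity along a polyline (bilinear interpolation).

    ``path_px`` is an ``(n, 2)`` array of ``(x, y)`` pixel coordinates with
    >= 2 vertices. The profile is resampled at one-pixel arc-length spacing
    and averaged across ``line_width_px`` perpendicular offsets.
    """
    image = np.asarray(image, dtype=float)
    path_px = np.asarray(path_px, dtype=float)
    if path_px.ndim != 2 or path_px.shape[0] < 2 or path_px.shape[1] != 2:
        raise GeometryError("path must be an (n>=2, 2) array of (x, y) coordinates")
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be > 0")

    seg = np.diff(path_px, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.r_[0.0, np.cumsum(seg_len)]
    total = arc[-1]
    if total <= 0:
        raise GeometryError("degenerate path of zero length")
    n_samples = max(int(np.floor(total)) + 1, 2)
    s = np.linspace(0.0, total, n_samples)
    xs = np.interp(s, arc, path_px[:, 0])
    ys = np.interp(s, arc, path_px[:, 1])

    # local tangent -> unit normal for width averaging
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm

    offsets = np.arange(line_width_px) - (line_width_px - 1) / 2.0
    vals = np.zeros((offsets.size, n_samples))
    h, w = image.shape
    for i, off in enumerate(offsets):
        px = xs + off * nx
        py = ys + off * ny
        if (px < 0).any() or (px > w - 1).any() or (py < 0).any() or (py > h - 1).any():
            raise GeometryError("sampling path exits the image")
        vals[i] = ndimage.map_coordinates(image, [py, px], order=1, mode="nearest")
    intensities = vals.mean(axis=0)
    return IntensityProfile(
        positions=s * pixel_size_um,
        intensities=np.clip(intensities, 0.0, None),
        pixel_size=pixel_size_um,
    )


def fwhm(positions: np.ndarray, values: np.ndarray, *, subtract_background: bool = True) -> float:
    """Full width at half maximum of a 1-D profile, interpolated on both flanks."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if subtract_background:
        y = y - y.min()
    j = int(np.argmax(y))
    half = y[j] / 2.0
    if y[j] <= 0:
        raise DetectionError("flat profile: no maximum")
    left = None
    for i in range(j, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = _interp_crossing(x[i - 1], x[i], y[i - 1], y[i], half)
            break
    right = None
    for i in range(j, x.size - 1):
        if y[i + 1] < half <= y[i]:
            right = _interp_crossing(x[i + 1], x[i], y[i + 1], y[i], half)
            break
    if left is None or right is None:
        raise DetectionError("half maximum not reached on both sides")
    return float(right - left)


def measure_diameter(
    image: np.ndarray,
    axis_polyline_px: np.ndarray,
    position_um: float,
    pixel_size_um: float,
    *,
    halfspan_um: float = 2.5,
) -> float:
    """AIS diameter at an arc-length position: FWHM of the perpendicular profile."""
    axis_polyline_px = np.asarray(axis_polyline_px, dtype=float)
    seg = np.diff(axis_polyline_px, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.r_[0.0, np.cumsum(seg_len)] * pixel_size_um
    if not 0 <= position_um <= arc[-1]:
        raise GeometryError("position outside the polyline extent")
    cx = np.interp(position_um, arc, axis_polyline_px[:, 0])
    cy = np.interp(position_um, arc, axis_polyline_px[:, 1])
    k = min(int(np.searchsorted(arc, position_um, side="right")), seg.shape[0]) - 1
    k = max(k, 0)
    t = seg[k] / seg_len[k]
    nx, ny = -t[1], t[0]

    half_px = halfspan_um / pixel_size_um
    offs = np.arange(-np.floor(half_px), np.floor(half_px) + 1)
    px = cx + offs * nx
    py = cy + offs * ny
    h, w = np.asarray(image).shape
    if (px < 0).any() or (px > w - 1).any() or (py < 0).any() or (py > h - 1).any():
        raise GeometryError("perpendicular profile exits the image")
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float), [py, px], order=1)
    return fwhm(offs * pixel_size_um, vals)
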