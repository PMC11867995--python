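"""Single-molecule spot detection, localization and cell-normalised profiles.

Spots are detected per frame as local maxima of a difference-of-Gaussians
band-pass exceeding a robust noise threshold, then refined by least-squares
fitting of a symmetric 2D Gaussian plus constant background.  Accepted
localizations are mapped into the owning cell's frame and normalised by its
dimensions: xi = along-axis offset / length, upsilon = cross-axis offset /
width, both in [-0.5, 0.5].

The short-axis (upsilon) histogram distinguishes compartments through the
peripherality index P, the fraction of localizations with |upsilon| >= 0.25.
For an ideal thin shell seen in a cylindrical cross-section the projected
density is proportional to 1/sqrt((w/2)^2 - b^2) and P -> 2/3; for a uniform
cytoplasmic volume it is proportional to sqrt((w/2)^2 - b^2) and
P -> 1 - (sqrt(3)/(2 pi) + 1/3) ~= 0.391.  Classification thresholds sit
midway between these analytic limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.ndimage import binary_dilation as ndi_binary_dilation
from scipy.ndimage import gaussian_filter1d
from scipy.stats import median_abs_deviation
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .segment import CellGeometry
from .simcell import ImagingConfig

__all__ = [
    "Localization",
    "AxialDensity",
    "SHELL_P",
    "VOLUME_P",
    "detect_spots",
    "fit_spot",
    "localize_frame",
    "localize_stack",
    "normalize_to_cell",
    "axial_density",
    "classify_compartment",
    "detect_foci",
]

#: analytic peripherality limits for a thin shell and a uniform volume,
#: cylindrical mid-section (see module docstring)
SHELL_P = 2.0 / 3.0
VOLUME_P = 1.0 - (math.sqrt(3.0) / (2.0 * math.pi) + 1.0 / 3.0)


@dataclass
class Localization:
    """One sub-pixel spot fit.  Positions and sigma are in nm (image frame)."""

    frame: int
    x: float
    y: float
    photons: float
    sigma: float
    success: bool = True
    cell_id: int | None = None
    xi: float | None = None       # along-axis, normalised by cell length
    upsilon: float | None = None  # cross-axis, normalised by cell width


@dataclass
class AxialDensity:
    """Short-axis localization density, normalised to unit area."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    n: int
    peripherality: float


# ---------------------------------------------------------------------------
# detection and fitting
# ---------------------------------------------------------------------------

def detect_spots(
    image: np.ndarray,
    noise_k: float = 5.0,
    psf_sigma_px: float = 1.3,
) -> np.ndarray:
    """Candidate spot pixels: DoG band-pass maxima above a robust threshold.

    The threshold is ``noise_k`` times the MAD-based noise scale of the
    band-passed image; non-maximum suppression uses one PSF radius.
    Returns an (n, 2) array of (row, col) candidates (possibly empty).
    """
    if noise_k <= 0:
        raise ValueError("noise_k must be positive")
    image = np.asarray(image, dtype=float)
    dog = difference_of_gaussians(image, psf_sigma_px * 0.7, psf_sigma_px * 2.0)
    noise = median_abs_deviation(dog, axis=None, scale="normal")
    if noise == 0 and np.ptp(dog) == 0:
        return np.empty((0, 2), dtype=int)
    thresh = max(noise_k * noise, 1e-12)
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(round(2.0 * psf_sigma_px))),
        threshold_abs=thresh,
        exclude_border=False,
    )
    return peaks


def _gauss_model(params, yy, xx):
    amp, x0, y0, sigma, bg = params
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma ** 2)) + bg


def fit_spot(
    roi: np.ndarray,
    cfg: ImagingConfig,
    origin: tuple[int, int] = (0, 0),
    frame: int = 0,
) -> Localization:
    """Least-squares symmetric 2D Gaussian + constant background fit.

    ``roi`` must be at least 7 px on a side and roughly centred on the
    candidate; ``origin`` is the (row, col) of roi[0, 0] in the full image.
    Photons are amplitude * 2 pi sigma^2 / gain.  Fits with sigma outside
    [0.5, 2] x psf_sigma, non-positive photons or non-convergence are
    returned with ``success=False`` rather than raising.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 7:
        raise ValueError("roi must be 2D with side >= 7 px")
    yy, xx = np.mgrid[0: roi.shape[0], 0: roi.shape[1]]
    bg0 = float(np.median(roi))
    amp0 = max(float(roi.max() - bg0), 1e-3)
    r0, c0 = np.unravel_index(np.argmax(roi), roi.shape)
    s_px = cfg.psf_sigma_px
    p0 = [amp0, float(c0), float(r0), s_px, bg0]

    def resid(p):
        return (_gauss_model(p, yy, xx) - roi).ravel()

    reject = Localization(frame=frame, x=np.nan, y=np.nan, photons=0.0,
                          sigma=np.nan, success=False)
    try:
        res = optimize.least_squares(
            resid, p0,
            bounds=([0.0, -1.0, -1.0, 0.25 * s_px, -np.inf],
                    [np.inf, roi.shape[1], roi.shape[0], 4.0 * s_px, np.inf]),
            max_nfev=200,
        )
    except Exception:
        return reject
    if not res.success:
        return reject
    amp, x0, y0, sigma, _bg = res.x
    if not (0.5 * s_px <= sigma <= 2.0 * s_px):
        return reject
    photons = amp * 2.0 * math.pi * sigma ** 2 / cfg.gain
    if photons <= 0:
        return reject
    return Localization(
        frame=frame,
        x=(origin[1] + x0) * cfg.pixel_size,
        y=(origin[0] + y0) * cfg.pixel_size,
        photons=float(photons),
        sigma=float(sigma * cfg.pixel_size),
    )


def localize_frame(
    image: np.ndarray,
    cfg: ImagingConfig,
    frame: int = 0,
    noise_k: float = 5.0,
    roi_half: int = 5,
) -> list[Localization]:
    """Detect and fit all spots in one frame; returns accepted fits only.

    Fits converging within 1.5 PSF sigma of a brighter accepted fit are
    treated as duplicate detections of the same emitter and dropped.
    """
    image = np.asarray(image, dtype=float)
    fits = []
    for r, c in detect_spots(image, noise_k, cfg.psf_sigma_px):
        rlo = max(0, r - roi_half)
        clo = max(0, c - roi_half)
        roi = image[rlo: r + roi_half + 1, clo: c + roi_half + 1]
        if min(roi.shape) < 7:
            continue
        loc = fit_spot(roi, cfg, origin=(rlo, clo), frame=frame)
        if loc.success:
            fits.append(loc)
    out: list[Localization] = []
    for loc in sorted(fits, key=lambda l: -l.photons):
        if all(math.hypot(loc.x - k.x, loc.y - k.y) > 1.5 * cfg.psf_sigma
               for k in out):
            out.append(loc)
    return out


def localize_stack(stack, cfg, noise_k: float = 5.0) -> list[Localization]:
    locs: list[Localization] = []
    for f in range(stack.shape[0]):
        locs.extend(localize_frame(stack[f], cfg, frame=f, noise_k=noise_k))
    return locs


# ---------------------------------------------------------------------------
# cell-normalised coordinates
# ---------------------------------------------------------------------------

def normalize_to_cell(
    loc: Localization,
    geometries: list[CellGeometry],
    max_dist_px: int = 2,
    clip: bool = True,
    exclude_poles: bool = False,
) -> Localization | None:
    """Assign a localization to a cell and normalise by its dimensions.

    The localization must fall inside a cell mask or within ``max_dist_px``
    of one; if two masks qualify it goes to the nearest centroid.  Returns
    ``None`` (caller should count drops) when no cell qualifies or, with
    ``exclude_poles``, when the point lies in a hemispherical cap, where
    the constant half-width normalisation is biased.
    """
    if not geometries:
        return None
    px = geometries[0].pixel_um
    x_um = loc.x / 1000.0
    y_um = loc.y / 1000.0
    col = int(round(x_um / px))
    row = int(round(y_um / px))

    candidates = []
    for g in geometries:
        ny, nx = g.mask.shape
        inside = 0 <= row < ny and 0 <= col < nx and g.mask[row, col]
        if not inside and max_dist_px > 0:
            rlo, rhi = max(0, row - max_dist_px), min(ny, row + max_dist_px + 1)
            clo, chi = max(0, col - max_dist_px), min(nx, col + max_dist_px + 1)
            inside = bool(np.any(g.mask[rlo:rhi, clo:chi]))
        if inside:
            cx, cy = g.centroid_um
            candidates.append((math.hypot(x_um - cx, y_um - cy), g))
    if not candidates:
        return None

    _, g = min(candidates, key=lambda t: t[0])
    cx, cy = g.centroid_um
    ca, sa = math.cos(g.orientation), math.sin(g.orientation)
    a = (x_um - cx) * ca + (y_um - cy) * sa
    b = -(x_um - cx) * sa + (y_um - cy) * ca
    if exclude_poles and abs(a) > (g.length - g.width) / 2.0:
        return None
    xi = a / g.length
    ups = b / g.width
    if clip:
        xi = float(np.clip(xi, -0.5, 0.5))
        ups = float(np.clip(ups, -0.5, 0.5))
    loc.cell_id = g.cell_id
    loc.xi = xi
    loc.upsilon = ups
    return loc


def axial_density(
    locs,
    n_bins: int = 30,
    smooth_bins: float = 1.0,
) -> AxialDensity:
    """Short-axis density profile of normalised localizations.

    ``locs`` may be Localization objects (with upsilon set) or a plain array
    of upsilon values.  The histogram over [-0.5, 0.5] is normalised to unit
    area; the peripherality index is the fraction with |upsilon| >= 0.25.
    """
    if len(locs) == 0:
        raise ValueError("no localizations")
    ups = np.asarray(
        [l.upsilon for l in locs] if isinstance(locs[0], Localization) else locs,
        dtype=float,
    )
    if np.any(np.isnan(ups)):
        raise ValueError("localizations must be normalised first")
    if len(ups) < 50:
        warnings.warn(f"only {len(ups)} localizations; density will be noisy",
                      stacklevel=2)
    counts, edges = np.histogram(ups, bins=n_bins, range=(-0.5, 0.5))
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    return AxialDensity(
        bin_edges=edges,
        counts=counts,
        density=density,
        smoothed=gaussian_filter1d(density, smooth_bins, mode="nearest"),
        n=len(ups),
        peripherality=float(np.mean(np.abs(ups) >= 0.25)),
    )


def classify_compartment(
    density: AxialDensity,
    peripheral_min: float = 0.55,
    central_max: float = 0.45,
) -> str:
    """Label a density profile peripheral / central / indeterminate.

    Default thresholds sit midway between the shell (2/3) and volume
    (~0.391) analytic limits of the peripherality index.
    """
    if density.peripherality >= peripheral_min:
        return "peripheral"
    if density.peripherality <= central_max:
        return "central"
    return "indeterminate"


# ---------------------------------------------------------------------------
# foci
# ---------------------------------------------------------------------------

def detect_foci(
    projection: np.ndarray,
    geom: CellGeometry,
    cfg: ImagingConfig,
    fold_k: float = 5.0,
    noise_k: float = 5.0,
) -> tuple[list[Localization], bool]:
    """Bright oligomeric foci within one cell.

    A focus is an accepted spot fit inside the cell mask whose photon count
    exceeds ``fold_k`` times the cell's median spot photons (or, with fewer
    than three spots, ``fold_k`` times the expected single-emitter photons
    from the config).  Returns (foci, has_foci).
    """
    if fold_k <= 1:
        raise ValueError("fold_k must be > 1")
    locs = localize_frame(projection, cfg, noise_k=noise_k)
    px = cfg.pixel_um
    # membrane spots straddle the mask outline; accept a 2 px rim
    rim = ndi_binary_dilation(geom.mask, iterations=2)
    in_cell = []
    for loc in locs:
        row = int(round(loc.y / 1000.0 / px))
        col = int(round(loc.x / 1000.0 / px))
        ny, nx = rim.shape
        if 0 <= row < ny and 0 <= col < nx and rim[row, col]:
            in_cell.append(loc)
    if not in_cell:
        return [], False
    photons = np.array([l.photons for l in in_cell])
    ref = float(np.median(photons)) if len(in_cell) >= 3 else cfg.photons_per_frame
    foci = [l for l in in_cell if l.photons > fold_k * ref]
    return foci, bool(foci)
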