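"""Synthetic single-molecule fluorescence microscopy of rod-shaped bacteria.

This module generates image stacks with known ground truth that emulate
HiLo-style single-molecule imaging of *E. coli*-like cells: spherocylindrical
cells roughly 1 µm wide and 2–5 µm long, fluorescent emitters placed either
uniformly through the cytoplasmic volume or uniformly over the periplasmic
shell (modelled as an infinitesimally thin surface at radius w/2), bright
membrane foci, exponential photobleaching, stroboscopic laser duty cycles,
a Gaussian PSF integrated over pixels, Poisson shot noise and Gaussian
camera read noise.

Coordinates
-----------
World coordinates are in micrometres with the x axis along image columns and
the y axis along rows; pixel centres sit at integer pixel indices.  Each cell
carries a local frame: ``a`` runs along the cell's long axis, ``b`` across it
(in the image plane) and ``c`` in depth.  Depth is tracked in the ground
truth but ignored during rendering: for ~1 µm cells under highly inclined
illumination the whole cell is near focus and the analysis operates on 2D
projections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "ImagingConfig",
    "CellSpec",
    "EmitterTruth",
    "Population",
    "FieldOfView",
    "place_emitters",
    "render_stack",
    "render_summed",
    "render_brightfield",
    "sample_cell_sums",
    "simulate_mobile_molecule",
    "make_population",
    "make_chain",
    "spherocylinder_mask",
    "paint_labels",
]

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# configuration and ground-truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition and camera parameters for the forward model.

    Defaults follow the imaging regime of the study this package models:
    30 Hz acquisition of 250 frames, with an optional stroboscopic duty
    cycle of 33.3 ms laser-on to 99.9 ms laser-off for tracking mobile
    molecules.  Camera numbers (100 nm pixels, gain 1 count/photon, offset
    100 counts, 2-count read noise) are a plausible sCMOS regime; every
    value is configurable.

    Parameters
    ----------
    pixel_size : float
        Image pixel size in nm.
    frame_rate : float
        Camera frame rate in Hz.
    n_frames : int
        Number of frames per stack.
    exposure : float
        Exposure time per frame in ms (informational; photon budgets are
        expressed per frame).
    strobe_on, strobe_off : float
        Laser duty cycle in ms.  ``strobe_off == 0`` means continuous
        illumination.  A frame counts as illuminated when the laser is on
        at the start of the frame.
    psf_sigma : float
        Standard deviation of the Gaussian PSF in nm.
    photons_per_frame : float
        Expected photons emitted by one emitter during one illuminated frame.
    bg_photons : float
        Expected background photons per pixel per frame.
    read_noise_sd : float
        Gaussian camera read noise, in counts, per frame.
    camera_offset : float
        Camera offset in counts per frame.
    gain : float
        Camera gain in counts per photon.
    bleach_mean_frames : float
        Mean of the exponential photobleaching lifetime in frames;
        ``inf`` disables bleaching.
    seed : int
        Default seed for generators constructed from this config.
    """

    pixel_size: float = 100.0
    frame_rate: float = 30.0
    n_frames: int = 250
    exposure: float = 33.3
    strobe_on: float = 33.3
    strobe_off: float = 0.0
    psf_sigma: float = 130.0
    photons_per_frame: float = 300.0
    bg_photons: float = 20.0
    read_noise_sd: float = 2.0
    camera_offset: float = 100.0
    gain: float = 1.0
    bleach_mean_frames: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_rate <= 0 or self.exposure <= 0:
            raise ValueError("pixel_size, frame_rate and exposure must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.strobe_on <= 0 or self.strobe_off < 0:
            raise ValueError("strobe_on must be > 0 and strobe_off >= 0")
        if self.psf_sigma < self.pixel_size / 4:
            raise ValueError("psf_sigma < pixel_size/4: PSF would be undersampled")
        if self.photons_per_frame <= 0 or self.bg_photons < 0:
            raise ValueError("photon rates must be non-negative (signal positive)")
        if self.read_noise_sd < 0 or self.camera_offset < 0 or self.gain <= 0:
            raise ValueError("invalid camera parameters")
        if self.bleach_mean_frames <= 0:
            raise ValueError("bleach_mean_frames must be positive (inf allowed)")

    # -- derived quantities -------------------------------------------------
    @property
    def pixel_um(self) -> float:
        return self.pixel_size / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def duty_fraction(self) -> float:
        """Fraction of frames that are laser-on."""
        return float(np.mean(self.on_frames()))

    def on_frames(self, n_frames: int | None = None) -> np.ndarray:
        """Boolean array: which frames fall in a laser-on window."""
        n = self.n_frames if n_frames is None else n_frames
        if self.strobe_off == 0:
            return np.ones(n, dtype=bool)
        period = self.strobe_on + self.strobe_off
        # 1 µs jitter absorbs float round-off at exact period multiples
        phase = np.mod(np.arange(n) * self.frame_ms + 1e-6, period)
        return phase < self.strobe_on

    def strobe_period_s(self) -> float:
        """Time between consecutive laser-on windows, in seconds."""
        if self.strobe_off == 0:
            return self.frame_ms / 1000.0
        return (self.strobe_on + self.strobe_off) / 1000.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CellSpec:
    """Geometry and emitter content of one simulated cell.

    The cell is a spherocylinder of total length ``length`` and width
    ``width`` (both µm), centred at ``center`` (µm, world frame) with its
    long axis at ``orientation`` radians from the x axis.
    ``compartment_counts`` maps ``{"cytoplasm", "periplasm_shell", "focus"}``
    to emitter counts.  ``chain_of`` groups cells belonging to one chain.
    """

    cell_id: int
    length: float
    width: float
    center: tuple[float, float]
    orientation: float = 0.0
    compartment_counts: dict = field(default_factory=dict)
    chain_of: int | None = None

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"invalid cell geometry: need length >= width > 0, "
                f"got l={self.length}, w={self.width}"
            )
        for k, v in self.compartment_counts.items():
            if k not in ("cytoplasm", "periplasm_shell", "focus"):
                raise ValueError(f"unknown compartment {k!r}")
            if v < 0:
                raise ValueError("compartment counts must be >= 0")

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def body_length(self) -> float:
        """Length of the cylindrical section (excluding hemispherical caps)."""
        return self.length - self.width

    def world_xy(self, a, b):
        """Map cell-frame (a, b) to world (x, y) in µm."""
        ca, sa = math.cos(self.orientation), math.sin(self.orientation)
        x = self.center[0] + a * ca - b * sa
        y = self.center[1] + a * sa + b * ca
        return x, y


@dataclass
class EmitterTruth:
    """Ground truth for one simulated emitter.

    Position is stored in the owning cell's frame: ``a`` along the long
    axis, ``b`` across it, ``c`` in depth (all µm).  ``bleach_frame`` is the
    (continuous) frame index after which the emitter is dark; an emitter is
    alive in frame ``f`` iff ``f < bleach_frame``.
    """

    cell_id: int
    compartment: str
    a: float
    b: float
    c: float
    photon_rate: float
    bleach_frame: float
    diffusion_coeff: float = 0.0


# ---------------------------------------------------------------------------
# emitter placement
# ---------------------------------------------------------------------------

def _sample_volume(n: int, length: float, width: float, rng: np.random.Generator):
    """Uniform points inside a spherocylinder, in cell-frame (a, b, c)."""
    r = width / 2.0
    body = length - width
    v_cyl = math.pi * r * r * body
    v_sph = (4.0 / 3.0) * math.pi * r ** 3
    in_cyl = rng.random(n) < v_cyl / (v_cyl + v_sph)

    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)

    k = int(in_cyl.sum())
    # cylindrical body: uniform along axis x uniform over the disk
    a[in_cyl] = rng.uniform(-body / 2.0, body / 2.0, k)
    rho = r * np.sqrt(rng.random(k))
    th = rng.uniform(0.0, _TWO_PI, k)
    b[in_cyl] = rho * np.cos(th)
    c[in_cyl] = rho * np.sin(th)

    # caps: uniform in a sphere, shifted to the nearer pole
    m = n - k
    u = rng.normal(size=(m, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    rad = r * rng.random(m) ** (1.0 / 3.0)
    pts = u * rad[:, None]
    shift = np.where(pts[:, 0] >= 0, body / 2.0, -body / 2.0)
    a[~in_cyl] = pts[:, 0] + shift
    b[~in_cyl] = pts[:, 1]
    c[~in_cyl] = pts[:, 2]
    return a, b, c


def _sample_shell(n: int, length: float, width: float, rng: np.random.Generator):
    """Uniform points on the spherocylinder surface (lateral wall + caps)."""
    r = width / 2.0
    body = length - width
    a_cyl = _TWO_PI * r * body
    a_caps = 4.0 * math.pi * r * r
    on_cyl = rng.random(n) < a_cyl / (a_cyl + a_caps)

    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)

    k = int(on_cyl.sum())
    a[on_cyl] = rng.uniform(-body / 2.0, body / 2.0, k)
    th = rng.uniform(0.0, _TWO_PI, k)
    b[on_cyl] = r * np.cos(th)
    c[on_cyl] = r * np.sin(th)

    m = n - k
    u = rng.normal(size=(m, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = r * u
    shift = np.where(pts[:, 0] >= 0, body / 2.0, -body / 2.0)
    a[~on_cyl] = pts[:, 0] + shift
    b[~on_cyl] = pts[:, 1]
    c[~on_cyl] = pts[:, 2]
    return a, b, c


def _sample_bleach(n: int, cfg: ImagingConfig, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(cfg.bleach_mean_frames):
        return np.full(n, math.inf)
    # every emitter is bright for at least its first frame
    return np.maximum(1.0, rng.exponential(cfg.bleach_mean_frames, n))


def place_emitters(
    spec: CellSpec,
    cfg: ImagingConfig,
    rng: np.random.Generator | int | None = None,
    focus_jitter_um: float = 0.01,
    n_foci: int = 1,
) -> list[EmitterTruth]:
    """Place the emitters requested by ``spec.compartment_counts``.

    Cytoplasmic emitters are uniform over the spherocylinder volume, shell
    emitters uniform over its surface.  Focus emitters are co-located (up to
    ``focus_jitter_um``) at ``n_foci`` (1 or 2) shared membrane points,
    modelling an oligomeric assembly.  Reproducible for a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if n_foci not in (1, 2):
        raise ValueError("n_foci must be 1 or 2")

    counts = spec.compartment_counts
    out: list[EmitterTruth] = []

    def emit(compartment, a, b, c):
        bf = _sample_bleach(len(a), cfg, rng)
        for i in range(len(a)):
            out.append(
                EmitterTruth(
                    cell_id=spec.cell_id,
                    compartment=compartment,
                    a=float(a[i]),
                    b=float(b[i]),
                    c=float(c[i]),
                    photon_rate=cfg.photons_per_frame,
                    bleach_frame=float(bf[i]),
                )
            )

    n_cyt = int(counts.get("cytoplasm", 0))
    if n_cyt:
        emit("cytoplasm", *_sample_volume(n_cyt, spec.length, spec.width, rng))

    n_shell = int(counts.get("periplasm_shell", 0))
    if n_shell:
        emit("periplasm_shell", *_sample_shell(n_shell, spec.length, spec.width, rng))

    n_focus = int(counts.get("focus", 0))
    if n_focus:
        anchors = np.column_stack(_sample_shell(n_foci, spec.length, spec.width, rng))
        which = rng.integers(0, n_foci, n_focus)
        jit = rng.normal(0.0, focus_jitter_um, (n_focus, 2))
        a = anchors[which, 0] + jit[:, 0]
        b = anchors[which, 1]  # keep on-membrane cross position
        c = anchors[which, 2]
        emit("focus", a, b, c + jit[:, 1] * 0.0)

    return out


# ---------------------------------------------------------------------------
# masks and rendering
# ---------------------------------------------------------------------------

def spherocylinder_mask(spec: CellSpec, shape: tuple[int, int], pixel_um: float) -> np.ndarray:
    """Boolean pixel mask of the cell footprint (pixel centre inside outline)."""
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]]
    x = cols * pixel_um - spec.center[0]
    y = rows * pixel_um - spec.center[1]
    ca, sa = math.cos(spec.orientation), math.sin(spec.orientation)
    a = x * ca + y * sa
    b = -x * sa + y * ca
    da = np.maximum(np.abs(a) - spec.body_length / 2.0, 0.0)
    return np.hypot(da, b) <= spec.radius


def paint_labels(cells: list[CellSpec], shape: tuple[int, int], pixel_um: float) -> np.ndarray:
    """16-bit label image of all cell footprints (label = cell_id + 1)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for spec in cells:
        labels[spherocylinder_mask(spec, shape, pixel_um)] = spec.cell_id + 1
    return labels


def _auto_shape(cells: list[CellSpec], pixel_um: float, margin_px: int = 8) -> tuple[int, int]:
    xmax = max(c.center[0] + c.length / 2.0 for c in cells)
    ymax = max(c.center[1] + c.length / 2.0 for c in cells)
    return (int(math.ceil(ymax / pixel_um)) + margin_px,
            int(math.ceil(xmax / pixel_um)) + margin_px)


def _emitter_footprint(x_px, y_px, photons, sigma_px, shape, half=None):
    """Integrated-Gaussian photon image of one emitter on a local window.

    Returns (row_slice, col_slice, window_array); expected photons per pixel
    are the PSF integral over the pixel area, so total photons are conserved
    up to window truncation.
    """
    if half is None:
        half = max(3, int(math.ceil(4 * sigma_px)))
    r0 = int(round(y_px))
    c0 = int(round(x_px))
    rlo, rhi = max(0, r0 - half), min(shape[0], r0 + half + 1)
    clo, chi = max(0, c0 - half), min(shape[1], c0 + half + 1)
    if rlo >= rhi or clo >= chi:
        return None
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    s = sigma_px * math.sqrt(2.0)
    fy = 0.5 * (erf((rr + 0.5 - y_px) / s) - erf((rr - 0.5 - y_px) / s))
    fx = 0.5 * (erf((cc + 0.5 - x_px) / s) - erf((cc - 0.5 - x_px) / s))
    return slice(rlo, rhi), slice(clo, chi), photons * np.outer(fy, fx)


def _camera(lam, cfg, rng, n_integrated=1):
    """Apply the camera model to an expected-photon image (any shape)."""
    counts = rng.poisson(lam).astype(np.float64) * cfg.gain
    counts += rng.normal(cfg.camera_offset * n_integrated,
                         cfg.read_noise_sd * math.sqrt(n_integrated), lam.shape)
    return np.clip(counts, 0.0, None)


@dataclass
class SimulatedStack:
    """A rendered stack plus its ground truth."""

    stack: np.ndarray             # (n_frames, ny, nx) counts
    labels: np.ndarray            # (ny, nx) uint16 cell labels
    truth: pd.DataFrame           # one row per emitter
    config: ImagingConfig
    cells: list[CellSpec]


def _truth_table(cells, emitters, pixel_um) -> pd.DataFrame:
    by_id = {c.cell_id: c for c in cells}
    rows = []
    for i, e in enumerate(emitters):
        spec = by_id[e.cell_id]
        x, y = spec.world_xy(e.a, e.b)
        rows.append((i, e.cell_id, e.compartment, x, y, e.a, e.b, e.c,
                     e.photon_rate, e.bleach_frame))
    return pd.DataFrame(
        rows,
        columns=["emitter", "cell", "compartment", "x_um", "y_um",
                 "a_um", "b_um", "c_um", "photons_per_frame", "bleach_frame"],
    )


def render_stack(
    cells: list[CellSpec],
    emitters: list[EmitterTruth],
    cfg: ImagingConfig,
    shape: tuple[int, int] | None = None,
    rng: np.random.Generator | int | None = None,
    trajectory: pd.DataFrame | None = None,
) -> SimulatedStack:
    """Render a multi-frame stack from immobile emitters (plus an optional
    mobile trajectory with columns frame/x_um/y_um/photons).

    Per frame, every emitter that is alive (frame < bleach_frame) and in a
    laser-on window contributes an integrated 2D Gaussian of its expected
    photons; each pixel is then Poisson(signal + bg_photons) * gain +
    Normal(camera_offset, read_noise_sd), clipped at zero.  Shot noise is
    sampled as independent Poisson draws for the flat background and for
    each emitter's footprint, which is identical in distribution to a
    single draw of the summed rate (Poisson additivity) and much faster.
    Emitters outside the image are clipped with a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    px = cfg.pixel_um
    if shape is None:
        shape = _auto_shape(cells, px)
    n = cfg.n_frames
    on = cfg.on_frames()
    by_id = {c.cell_id: c for c in cells}

    # static signal: footprint + per-frame on/off occupancy
    static = []
    for e in emitters:
        spec = by_id.get(e.cell_id)
        if spec is None:
            raise ValueError(f"emitter references unknown cell {e.cell_id}")
        x, y = spec.world_xy(e.a, e.b)
        fp = _emitter_footprint(x / px, y / px, e.photon_rate, cfg.psf_sigma_px, shape)
        if fp is None:
            warnings.warn("emitter outside image bounds; clipped", stacklevel=2)
            continue
        alive = on & (np.arange(n) < e.bleach_frame)
        static.append((fp, alive))

    if cfg.bg_photons > 0:
        counts = rng.poisson(float(cfg.bg_photons), (n, *shape)).astype(np.float64)
    else:
        counts = np.zeros((n, *shape))
    for (rs, cs, img), alive in static:
        idx = np.nonzero(alive)[0]
        if idx.size:
            view = counts[:, rs, cs]
            view[idx] += rng.poisson(
                np.broadcast_to(img, (idx.size, *img.shape))
            )
    if trajectory is not None:
        for fr, x, y, ph in trajectory[["frame", "x_um", "y_um",
                                        "photons"]].to_numpy():
            fr = int(fr)
            if not 0 <= fr < n:
                continue
            fp = _emitter_footprint(x / px, y / px, ph, cfg.psf_sigma_px, shape)
            if fp is None:
                warnings.warn("trajectory point outside image; clipped",
                              stacklevel=2)
                continue
            rs, cs, img = fp
            counts[fr, rs, cs] += rng.poisson(img)
    counts *= cfg.gain
    counts += cfg.camera_offset
    if cfg.read_noise_sd > 0:
        counts += cfg.read_noise_sd * rng.standard_normal((n, *shape))
    stack = np.clip(counts, 0.0, None)

    return SimulatedStack(
        stack=stack,
        labels=paint_labels(cells, shape, px),
        truth=_truth_table(cells, emitters, px),
        config=cfg,
        cells=cells,
    )


def render_summed(
    cells: list[CellSpec],
    emitters: list[EmitterTruth],
    cfg: ImagingConfig,
    shape: tuple[int, int] | None = None,
    rng: np.random.Generator | int | None = None,
    diffuse_photons_per_px: float = 0.0,
) -> SimulatedStack:
    """Render the time-summed image of a stack directly.

    A sum of independent Poisson frames is Poisson in the summed expectation
    and the summed read noise is Gaussian with sd * sqrt(n_frames), so the
    integrated image can be drawn in one pass without materialising frames.
    This is the fast path used for intensity-per-volume work at scale; it is
    distribution-identical to summing :func:`render_stack` output.

    ``diffuse_photons_per_px`` adds a uniform per-frame photon rate inside
    every cell footprint, emulating dense labelling of the whole cell.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    px = cfg.pixel_um
    if shape is None:
        shape = _auto_shape(cells, px)
    n = cfg.n_frames
    on = cfg.on_frames()
    frames_idx = np.arange(n)
    by_id = {c.cell_id: c for c in cells}

    lam = np.full(shape, float(cfg.bg_photons) * n)
    labels = paint_labels(cells, shape, px)
    if diffuse_photons_per_px > 0:
        lam[labels > 0] += diffuse_photons_per_px * n

    for e in emitters:
        spec = by_id.get(e.cell_id)
        if spec is None:
            raise ValueError(f"emitter references unknown cell {e.cell_id}")
        n_on = int(np.count_nonzero(on & (frames_idx < e.bleach_frame)))
        if n_on == 0:
            continue
        x, y = spec.world_xy(e.a, e.b)
        fp = _emitter_footprint(x / px, y / px, e.photon_rate * n_on,
                                cfg.psf_sigma_px, shape)
        if fp is None:
            warnings.warn("emitter outside image bounds; clipped", stacklevel=2)
            continue
        rs, cs, img = fp
        lam[rs, cs] += img

    summed = _camera(lam, cfg, rng, n_integrated=n)
    return SimulatedStack(
        stack=summed[None],
        labels=labels,
        truth=_truth_table(cells, emitters, px),
        config=cfg,
        cells=cells,
    )


def sample_cell_sums(
    spec: CellSpec,
    emitters: list[EmitterTruth],
    cfg: ImagingConfig,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-frame integrated cell intensity above offset, sampled at sum level.

    The offset-corrected sum of the camera model over a cell's mask is,
    exactly, ``gain * Poisson(total expected photons in the mask) +
    Normal(0, read_noise_sd * sqrt(area))`` per frame (Poisson additivity
    over pixels; the per-pixel zero clip is never active at typical
    offsets).  Sampling at this level needs one draw per frame instead of
    one per pixel, which makes population-scale screens tractable; it is
    distribution-identical to summing a rendered stack over the mask.
    """
    mask = spherocylinder_mask(spec, shape, cfg.pixel_um)
    area = int(mask.sum())
    n = cfg.n_frames
    sums = cfg.gain * rng.poisson(cfg.bg_photons * area, n).astype(np.float64)
    if cfg.read_noise_sd > 0:
        sums += cfg.read_noise_sd * math.sqrt(area) * rng.standard_normal(n)
    on = cfg.on_frames()
    frames_idx = np.arange(n)
    for e in emitters:
        x, y = spec.world_xy(e.a, e.b)
        fp = _emitter_footprint(x / cfg.pixel_um, y / cfg.pixel_um,
                                e.photon_rate, cfg.psf_sigma_px, shape)
        if fp is None:
            continue
        rs, cs, img = fp
        photons_in = float(img[mask[rs, cs]].sum())
        idx = np.nonzero(on & (frames_idx < e.bleach_frame))[0]
        if idx.size and photons_in > 0:
            sums[idx] += cfg.gain * rng.poisson(photons_in, idx.size)
    return sums


def render_brightfield(
    cells: list[CellSpec],
    cfg: ImagingConfig,
    shape: tuple[int, int] | None = None,
    rng: np.random.Generator | int | None = None,
    bg_level: float = 1000.0,
    contrast: float = 0.4,
    noise_sd: float = 8.0,
) -> np.ndarray:
    """A brightfield-like image: cells appear darker than the background."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    px = cfg.pixel_um
    if shape is None:
        shape = _auto_shape(cells, px)
    img = np.full(shape, bg_level)
    img[paint_labels(cells, shape, px) > 0] *= 1.0 - contrast
    img += rng.normal(0.0, noise_sd, shape)
    return img


# ---------------------------------------------------------------------------
# mobile molecules on chained cells
# ---------------------------------------------------------------------------

def make_chain(
    n_cells: int,
    length: float,
    width: float,
    start_center: tuple[float, float],
    orientation: float = 0.0,
    chain_id: int = 0,
    first_cell_id: int = 0,
) -> list[CellSpec]:
    """Collinear abutting cells sharing a chain id (a *tat*-mutant chain)."""
    ca, sa = math.cos(orientation), math.sin(orientation)
    cells = []
    for i in range(n_cells):
        cx = start_center[0] + i * length * ca
        cy = start_center[1] + i * length * sa
        cells.append(
            CellSpec(cell_id=first_cell_id + i, length=length, width=width,
                     center=(cx, cy), orientation=orientation, chain_of=chain_id)
        )
    return cells


def _check_chain(chain: list[CellSpec], tol: float = 1e-6) -> None:
    if not chain:
        raise ValueError("empty chain")
    phi = chain[0].orientation
    ca, sa = math.cos(phi), math.sin(phi)
    for a, b in zip(chain, chain[1:]):
        if abs(((a.orientation - b.orientation) + math.pi / 2) % math.pi - math.pi / 2) > 1e-3:
            raise ValueError("chain cells are not collinear")
        dx = b.center[0] - a.center[0]
        dy = b.center[1] - a.center[1]
        along = dx * ca + dy * sa
        across = -dx * sa + dy * ca
        if abs(across) > tol or abs(along - (a.length + b.length) / 2.0) > tol:
            raise ValueError("chain cells are not abutting")


def simulate_mobile_molecule(
    chain: list[CellSpec],
    D: float,
    cfg: ImagingConfig,
    rng: np.random.Generator | int | None = None,
    start_u: float | None = None,
) -> pd.DataFrame:
    """Brownian motion of one molecule on the contiguous shell of a chain.

    The chain's periplasm is modelled as the lateral surface of a single
    cylinder spanning the whole chain (caps flattened into reflecting ends).
    Per interval between laser-on frames the along-chain coordinate ``u``
    and the circumferential arc both receive independent Gaussian steps of
    variance ``2 D dt``; ``u`` reflects at the chain ends, so the molecule
    never leaves the shell and moves continuously across cell junctions.

    Returns a trajectory table with one row per laser-on frame:
    frame, u_um (along-chain), theta, b_um (in-plane cross offset),
    x_um, y_um (world), cell (id of the cell currently occupied), photons.
    """
    _check_chain(chain)
    if D < 0:
        raise ValueError("D must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    r = chain[0].radius
    L = sum(c.length for c in chain)
    phi = chain[0].orientation
    ca, sa = math.cos(phi), math.sin(phi)
    # chain start = proximal pole of the first cell
    x0 = chain[0].center[0] - (chain[0].length / 2.0) * ca
    y0 = chain[0].center[1] - (chain[0].length / 2.0) * sa
    edges = np.cumsum([c.length for c in chain])

    on_idx = np.nonzero(cfg.on_frames())[0]
    dt = cfg.strobe_period_s()
    sd = math.sqrt(2.0 * D * dt)

    u = L / 2.0 if start_u is None else float(start_u)
    theta = rng.uniform(0.0, _TWO_PI)
    rows = []
    for k, frame in enumerate(on_idx):
        if k > 0:
            u += rng.normal(0.0, sd)
            # reflect at chain ends
            u = abs(u)
            if u > L:
                u = L - (u - L) % (2 * L)
                u = abs(u)
            if sd > 0 and r > 0:
                theta = (theta + rng.normal(0.0, sd) / r) % _TWO_PI
        b = r * math.cos(theta)
        cell = chain[int(np.searchsorted(edges, min(u, L - 1e-12), side="right"))]
        x = x0 + u * ca - b * sa
        y = y0 + u * sa + b * ca
        rows.append((int(frame), u, theta, b, x, y, cell.cell_id,
                     cfg.photons_per_frame))
    return pd.DataFrame(
        rows, columns=["frame", "u_um", "theta", "b_um", "x_um", "y_um",
                       "cell", "photons"],
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class FieldOfView:
    fov_id: int
    repeat: int
    cells: list[CellSpec]
    emitters: list[EmitterTruth]
    shape: tuple[int, int]


@dataclass
class Population:
    """A simulated multi-repeat cell population with cell-level metadata."""

    fovs: list[FieldOfView]
    meta: pd.DataFrame  # cell, fov, repeat, condition, occupied, length, width
    config: ImagingConfig
    condition: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.meta)


def make_population(
    n_cells: int,
    occupancy: float,
    cfg: ImagingConfig,
    condition: str = "",
    n_repeats: int = 3,
    cells_per_fov: int = 16,
    length_range: tuple[float, float] = (2.0, 4.0),
    width: float = 1.0,
    rng: np.random.Generator | int | None = None,
    emitters_per_cell: int | None = None,
    compartment: str = "periplasm_shell",
) -> Population:
    """Build a population in the rare-single-molecule regime.

    Each cell independently receives exactly one shell emitter with
    probability ``occupancy`` (the study's regime is roughly 1 in 10 cells
    carrying a single labelled molecule).  Passing ``emitters_per_cell``
    switches to an abundant-labelling regime where every occupied cell gets
    that many emitters in ``compartment``.  Cells are laid out on a tile
    grid per field of view and split evenly over ``n_repeats`` biological
    repeats, giving the three-level cell / field-of-view / repeat structure
    of the real experiments.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    px = cfg.pixel_um
    tile_um = length_range[1] + 1.2
    tile_px = int(math.ceil(tile_um / px))
    grid = int(math.ceil(math.sqrt(cells_per_fov)))

    fovs: list[FieldOfView] = []
    meta_rows = []
    cell_id = 0
    fov_id = 0
    per_repeat = [n_cells // n_repeats] * n_repeats
    for i in range(n_cells - sum(per_repeat)):
        per_repeat[i] += 1

    for rep, n_rep in enumerate(per_repeat):
        remaining = n_rep
        while remaining > 0:
            n_here = min(cells_per_fov, remaining)
            remaining -= n_here
            cells = []
            emitters: list[EmitterTruth] = []
            for j in range(n_here):
                gr, gc = divmod(j, grid)
                centre = ((gc + 0.5) * tile_um, (gr + 0.5) * tile_um)
                length = rng.uniform(*length_range)
                occupied = bool(rng.random() < occupancy)
                if occupied:
                    n_emit = 1 if emitters_per_cell is None else emitters_per_cell
                    counts = {compartment: n_emit}
                else:
                    counts = {}
                spec = CellSpec(cell_id=cell_id, length=length, width=width,
                                center=centre,
                                orientation=rng.uniform(0.0, math.pi),
                                compartment_counts=counts)
                cells.append(spec)
                emitters.extend(place_emitters(spec, cfg, rng))
                meta_rows.append((cell_id, fov_id, rep, condition, occupied,
                                  length, width))
                cell_id += 1
            n_rows = int(math.ceil(n_here / grid))
            shape = (n_rows * tile_px, min(n_here, grid) * tile_px)
            fovs.append(FieldOfView(fov_id=fov_id, repeat=rep, cells=cells,
                                    emitters=emitters, shape=shape))
            fov_id += 1

    meta = pd.DataFrame(
        meta_rows,
        columns=["cell", "fov", "repeat", "condition", "occupied",
                 "length_um", "width_um"],
    )
    return Population(fovs=fovs, meta=meta, config=cfg, condition=condition)
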