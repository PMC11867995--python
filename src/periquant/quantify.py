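"""Per-cell fluorescence quantification and the periplasmic/total ratio.

The central statistic is the background-corrected ratio of
intensity-per-volume (ipv) measured with a cytoplasm-excluded dye to that
measured with a fully permeable dye,

    ratio_r = (mean ipv_xc,r - baseline_xc) / (mean ipv_s,r - baseline_s)

computed per biological repeat r, then pooled as a mean with a standard
error across repeats.  Because the two dyes are not equally bright in cells,
the ratio is a relative (not absolute) periplasmic fraction; an optional
brightness calibration factor rescales it.

Maximum-intensity projections are kept for display, gating and spot
finding; the quantitative ipv uses the frame-summed image, which is linear
in photon count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .segment import CellGeometry

__all__ = [
    "IntensityRecord",
    "RatioResult",
    "max_projection",
    "sum_projection",
    "cell_intensity",
    "peak_frame_intensity",
    "autofluorescence_baseline",
    "gate_fluorescent",
    "periplasmic_ratio",
    "repeat_summary",
]

log = logging.getLogger(__name__)


@dataclass
class IntensityRecord:
    """Integrated background-offset-corrected intensity of one cell."""

    cell_id: int
    condition: str
    repeat: int
    intensity: float          # counts above camera offset, summed over the mask
    volume: float             # µm³

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def ipv(self) -> float:
        """Intensity per volume, counts/µm³."""
        return self.intensity / self.volume


@dataclass
class RatioResult:
    """Background-corrected periplasmic/total ratio for one condition."""

    condition: str
    per_repeat: dict          # repeat id -> ratio (defined repeats only)
    ratio: float              # mean over defined repeats
    se: float                 # SD over repeats / sqrt(n_repeats)
    n_repeats: int
    n_cells: dict             # repeat id -> cell count (xc condition)
    undefined_repeats: list = field(default_factory=list)

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided t confidence interval over repeats."""
        if self.n_repeats < 2:
            return (-np.inf, np.inf)
        tcrit = sstats.t.ppf(1 - alpha / 2, self.n_repeats - 1)
        return (self.ratio - tcrit * self.se, self.ratio + tcrit * self.se)


def max_projection(stack: np.ndarray, n_frames: int | None = None) -> np.ndarray:
    """Pixel-wise maximum over the first ``n_frames`` frames."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, ny, nx) stack")
    n = stack.shape[0] if n_frames is None else n_frames
    if stack.shape[0] < n:
        raise ValueError(f"stack has {stack.shape[0]} frames, need {n}")
    return stack[:n].max(axis=0)


def sum_projection(stack: np.ndarray, n_frames: int | None = None) -> np.ndarray:
    """Pixel-wise sum over the first ``n_frames`` frames (quantitative image)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, ny, nx) stack")
    n = stack.shape[0] if n_frames is None else n_frames
    if stack.shape[0] < n:
        raise ValueError(f"stack has {stack.shape[0]} frames, need {n}")
    return stack[:n].sum(axis=0)


def cell_intensity(
    image: np.ndarray,
    geom: CellGeometry,
    camera_offset: float,
    n_frames_integrated: int = 1,
    condition: str = "",
    repeat: int = 0,
    floor_pixels: bool = False,
) -> IntensityRecord:
    """Integrate a cell's intensity above the camera offset.

    ``n_frames_integrated`` is the number of frames summed into ``image``
    (1 for a single frame or a max projection), so the subtracted offset is
    ``camera_offset * n_frames_integrated`` per pixel.  ``floor_pixels``
    clips individual pixels at zero before summing.
    """
    image = np.asarray(image, dtype=float)
    if geom.mask.shape != image.shape:
        raise ValueError("cell mask does not match image shape")
    vals = image[geom.mask] - camera_offset * n_frames_integrated
    if floor_pixels:
        vals = np.clip(vals, 0.0, None)
    return IntensityRecord(
        cell_id=geom.cell_id,
        condition=condition,
        repeat=repeat,
        intensity=float(vals.sum()),
        volume=geom.volume,
    )


def peak_frame_intensity(
    stack: np.ndarray,
    geom: CellGeometry,
    camera_offset: float,
    condition: str = "",
    repeat: int = 0,
) -> IntensityRecord:
    """Peak per-frame integrated cell intensity above the camera offset.

    The record's intensity is the maximum over frames of the cell's
    offset-corrected pixel sum.  For rare single molecules this is the
    sensitive gating statistic: a molecule bright for even one frame
    contributes its full per-frame photon budget to that frame's sum,
    whereas any time-integrated statistic dilutes short-lived molecules.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or geom.mask.shape != stack.shape[1:]:
        raise ValueError("cell mask does not match stack shape")
    sums = stack[:, geom.mask].sum(axis=1) - camera_offset * geom.mask.sum()
    return IntensityRecord(
        cell_id=geom.cell_id,
        condition=condition,
        repeat=repeat,
        intensity=float(sums.max()),
        volume=geom.volume,
    )


def autofluorescence_baseline(no_dye_records: list[IntensityRecord]) -> float:
    """Mean intensity-per-volume of cells imaged with no dye present."""
    if not no_dye_records:
        raise ValueError("need at least one no-dye record")
    return float(np.mean([r.ipv for r in no_dye_records]))


def gate_fluorescent(
    records: list[IntensityRecord],
    baseline: float,
    baseline_sd: float,
    k: float = 3.0,
) -> list[IntensityRecord]:
    """Keep cells exhibiting fluorescence: ipv > baseline + k * SD(no-dye ipv)."""
    if k <= 0:
        raise ValueError("k must be positive")
    thresh = baseline + k * baseline_sd
    return [r for r in records if r.ipv > thresh]


def periplasmic_ratio(
    records_xc: list[IntensityRecord],
    records_s: list[IntensityRecord],
    baseline_xc: float,
    baseline_s: float,
    min_cells: int = 10,
    brightness_factor: float = 1.0,
    condition: str | None = None,
) -> RatioResult:
    """Background-corrected ratio of xc (cytoplasm-excluded dye) to s
    (permeable dye) mean intensity-per-volume, per biological repeat.

    Repeats whose corrected denominator is <= 0 are flagged and dropped with
    a warning; if every repeat is undefined an error is raised.
    ``brightness_factor`` divides the ratio to correct for unequal in-cell
    dye brightness when a calibration is available.

    Each baseline may be a single pooled value or a mapping of repeat id to
    a per-repeat baseline; per-repeat baselines (from no-dye controls
    acquired alongside each biological repeat) keep the repeat-level ratios
    independent, which the across-repeat standard error assumes.
    """
    by_rep_xc = _group_by_repeat(records_xc)
    by_rep_s = _group_by_repeat(records_s)
    if set(by_rep_xc) != set(by_rep_s):
        raise ValueError("dye conditions must share the same repeat ids")
    for rep, recs in {**by_rep_xc, **by_rep_s}.items():
        if len(recs) < min_cells:
            raise ValueError(f"repeat {rep} has fewer than {min_cells} cells")

    def _base(baseline, rep):
        return baseline[rep] if isinstance(baseline, dict) else baseline

    per_repeat: dict = {}
    undefined = []
    for rep in sorted(by_rep_xc):
        num = np.mean([r.ipv for r in by_rep_xc[rep]]) - _base(baseline_xc, rep)
        den = np.mean([r.ipv for r in by_rep_s[rep]]) - _base(baseline_s, rep)
        if den <= 0:
            undefined.append(rep)
            log.warning("repeat %s: corrected denominator <= 0; ratio undefined", rep)
            warnings.warn(f"repeat {rep}: ratio undefined (denominator <= 0)",
                          stacklevel=2)
            continue
        per_repeat[rep] = float(num / den) / brightness_factor

    if not per_repeat:
        raise ValueError("ratio undefined for every repeat")
    vals = np.array(list(per_repeat.values()))
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    cond = condition
    if cond is None:
        cond = records_xc[0].condition if records_xc else ""
    return RatioResult(
        condition=cond,
        per_repeat=per_repeat,
        ratio=float(vals.mean()),
        se=se,
        n_repeats=len(vals),
        n_cells={rep: len(v) for rep, v in by_rep_xc.items()},
        undefined_repeats=undefined,
    )


def repeat_summary(records: list[IntensityRecord]) -> pd.DataFrame:
    """Per-repeat n, mean ipv and the mode of a kernel density estimate.

    The KDE mode is the 'peak intensity' of the repeat's ipv distribution;
    it is omitted (NaN) for repeats with fewer than two cells or zero
    variance.
    """
    rows = []
    for rep, recs in sorted(_group_by_repeat(records).items()):
        vals = np.array([r.ipv for r in recs])
        mode = np.nan
        if len(vals) >= 2 and vals.std() > 0:
            kde = sstats.gaussian_kde(vals)
            lo, hi = vals.min(), vals.max()
            pad = 0.1 * (hi - lo)
            grid = np.linspace(lo - pad, hi + pad, 512)
            mode = float(grid[np.argmax(kde(grid))])
        rows.append((rep, len(vals), float(vals.mean()), mode))
    return pd.DataFrame(rows, columns=["repeat", "n", "mean_ipv", "kde_mode"])


def _group_by_repeat(records: list[IntensityRecord]) -> dict:
    out: dict = {}
    for r in records:
        out.setdefault(r.repeat, []).append(r)
    return out
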