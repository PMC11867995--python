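"""Pipeline orchestration: simulate -> segment -> quantify -> localize ->
traces -> stats, driven by one YAML config with a single root seed.

Each stage reads the previous stage's CSV/TIFF outputs from the run
directory and writes its own; a manifest records the config hash, seed and
per-stage row counts so that identical config + seed reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import locfit, quantify, segment, simcell, traces
from .stats import GroupSample, significance_stars, welch_anova, welch_ttest

log = logging.getLogger("periquant.pipeline")

STAGES = ["simulate", "segment", "quantify", "localize", "traces", "stats"]


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} is not a mapping")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _imaging_config(config: dict, seed: int) -> simcell.ImagingConfig:
    return simcell.ImagingConfig(**{**config.get("imaging", {}), "seed": seed})


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")


def _read_csv(path: Path, stage: str) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(
            f"missing upstream output {path.name}: run stage producing it "
            f"before '{stage}'"
        )
    return pd.read_csv(path, comment="#")


def run_pipeline(config: dict, out_dir, stages=None, seed=None) -> dict:
    """Run the requested stages in order; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    seed = int(config.get("seed", 0) if seed is None else seed)
    chash = config_hash(config)
    header = f"# periquant seed={seed} config={chash}\n"

    manifest = {"seed": seed, "config_hash": chash, "stages": {}}
    mpath = out / "manifest.json"
    if mpath.exists():
        manifest = {**json.loads(mpath.read_text()), **manifest}

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        rows = _STAGE_FUNCS[stage](config, out, seed, header)
        dt = time.monotonic() - t0
        log.info("stage %-8s %6d rows  %.2fs", stage, rows, dt)
        manifest["stages"][stage] = {"rows": rows, "seconds": round(dt, 3)}

    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, out, seed, header) -> int:
    params = dict(config.get("simulate", {}))
    if "n_cells" not in params:
        raise PipelineError("config field simulate.n_cells is required")
    icfg = _imaging_config(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    pop = simcell.make_population(rng=rng, cfg=icfg, **params)
    truth_all = []
    for fov in pop.fovs:
        sim = simcell.render_stack(fov.cells, fov.emitters, icfg,
                                   shape=fov.shape, rng=rng)
        tifffile.imwrite(out / f"fov{fov.fov_id:03d}_stack.tif",
                         np.round(sim.stack).astype(np.uint16))
        tifffile.imwrite(out / f"fov{fov.fov_id:03d}_truth_labels.tif",
                         sim.labels)
        t = sim.truth.copy()
        t.insert(0, "fov", fov.fov_id)
        truth_all.append(t)
    truth = (pd.concat(truth_all, ignore_index=True) if truth_all
             else pd.DataFrame())
    _write_csv(truth, out / "truth_emitters.csv", header)
    _write_csv(pop.meta, out / "cells_meta.csv", header)
    return len(pop.meta)


def _stage_segment(config, out, seed, header) -> int:
    params = config.get("segment", {})
    icfg = _imaging_config(config, seed)
    meta = _read_csv(out / "cells_meta.csv", "segment")
    rows = []
    for fov_id in sorted(meta["fov"].unique()):
        stack = tifffile.imread(out / f"fov{fov_id:03d}_stack.tif")
        ref = stack.mean(axis=0)
        geoms = segment.segment_cells(ref, icfg.pixel_um, **params)
        segment.group_chains(geoms)
        labels = np.zeros(ref.shape, dtype=np.uint16)
        for g in geoms:
            labels[g.mask] = g.cell_id + 1
        tifffile.imwrite(out / f"fov{fov_id:03d}_seg_labels.tif", labels)
        for g in geoms:
            rows.append((fov_id, g.cell_id, g.centroid[0], g.centroid[1],
                         g.orientation, g.length, g.width, g.volume,
                         g.chain_id))
    df = pd.DataFrame(rows, columns=["fov", "cell", "row", "col",
                                     "orientation", "length_um", "width_um",
                                     "volume_um3", "chain"])
    _write_csv(df, out / "geometry.csv", header)
    return len(df)


def _load_geoms(out, fov_id, pixel_um, stage):
    geo = _read_csv(out / "geometry.csv", stage)
    path = out / f"fov{fov_id:03d}_seg_labels.tif"
    if not path.exists():
        raise PipelineError(f"missing upstream output {path.name} for '{stage}'")
    labels = tifffile.imread(path)
    geoms = []
    for row in geo[geo["fov"] == fov_id].itertuples():
        mask = labels == row.cell + 1
        if mask.any():
            geoms.append(segment.fit_geometry(mask, pixel_um, cell_id=row.cell))
    return geoms


def _stage_quantify(config, out, seed, header) -> int:
    params = config.get("quantify", {})
    icfg = _imaging_config(config, seed)
    meta = _read_csv(out / "cells_meta.csv", "quantify")
    rep_of_fov = dict(meta.groupby("fov")["repeat"].first())
    cond_of_fov = dict(meta.groupby("fov")["condition"].first())
    rows = []
    records = []
    for fov_id in sorted(meta["fov"].unique()):
        stack = tifffile.imread(out / f"fov{fov_id:03d}_stack.tif")
        summed = quantify.sum_projection(stack)
        for g in _load_geoms(out, fov_id, icfg.pixel_um, "quantify"):
            rec = quantify.cell_intensity(
                summed, g, icfg.camera_offset,
                n_frames_integrated=stack.shape[0],
                condition=str(cond_of_fov[fov_id]),
                repeat=int(rep_of_fov[fov_id]),
            )
            records.append(rec)
            rows.append((fov_id, g.cell_id, rec.condition, rec.repeat,
                         rec.intensity, rec.volume, rec.ipv))
    df = pd.DataFrame(rows, columns=["fov", "cell", "condition", "repeat",
                                     "intensity", "volume_um3", "ipv"])
    _write_csv(df, out / "intensity_records.csv", header)
    _write_csv(quantify.repeat_summary(records), out / "repeat_summary.csv",
               header)
    _ = params
    return len(df)


def _stage_localize(config, out, seed, header) -> int:
    params = config.get("localize", {})
    icfg = _imaging_config(config, seed)
    meta = _read_csv(out / "cells_meta.csv", "localize")
    rows = []
    for fov_id in sorted(meta["fov"].unique()):
        stack = tifffile.imread(out / f"fov{fov_id:03d}_stack.tif").astype(float)
        geoms = _load_geoms(out, fov_id, icfg.pixel_um, "localize")
        locs = locfit.localize_stack(stack, icfg,
                                     noise_k=params.get("noise_k", 5.0))
        for loc in locs:
            loc = locfit.normalize_to_cell(loc, geoms)
            if loc is None:
                continue
            rows.append((fov_id, loc.frame, loc.x, loc.y, loc.photons,
                         loc.sigma, loc.cell_id, loc.xi, loc.upsilon))
    df = pd.DataFrame(rows, columns=["fov", "frame", "x_nm", "y_nm",
                                     "photons", "sigma_nm", "cell",
                                     "xi", "upsilon"])
    _write_csv(df, out / "localizations.csv", header)
    if len(df) > 0:
        dens = locfit.axial_density(df["upsilon"].to_numpy())
        centres = 0.5 * (dens.bin_edges[:-1] + dens.bin_edges[1:])
        ddf = pd.DataFrame({"upsilon": centres, "density": dens.density,
                            "smoothed": dens.smoothed})
        ddf["peripherality"] = dens.peripherality
        ddf["classification"] = locfit.classify_compartment(dens)
        _write_csv(ddf, out / "axial_density.csv", header)
    return len(df)


def _stage_traces(config, out, seed, header) -> int:
    params = config.get("traces", {})
    icfg = _imaging_config(config, seed)
    meta = _read_csv(out / "cells_meta.csv", "traces")
    locs_df = _read_csv(out / "localizations.csv", "traces")
    t_rows, s_rows, k_rows = [], [], []
    spot_id = 0
    for fov_id in sorted(meta["fov"].unique()):
        stack = tifffile.imread(out / f"fov{fov_id:03d}_stack.tif").astype(float)
        proj = quantify.max_projection(stack)
        for g in _load_geoms(out, fov_id, icfg.pixel_um, "traces"):
            rows_, cols_ = np.nonzero(g.mask)
            sub = proj[rows_.min():rows_.max() + 1, cols_.min():cols_.max() + 1]
            peaks = locfit.detect_spots(sub, psf_sigma_px=icfg.psf_sigma_px)
            if len(peaks) == 0:
                continue
            best = peaks[int(np.argmax(sub[peaks[:, 0], peaks[:, 1]]))]
            pos = (float(rows_.min() + best[0]), float(cols_.min() + best[1]))
            try:
                tr = traces.extract_trace(stack, pos, spot_id=spot_id)
            except ValueError:
                continue
            tr.window = int(params.get("window", 12))
            tr.p = float(params.get("p", 2.0))
            tr.memory = int(params.get("memory", tr.window))
            try:
                tr = traces.analyze_trace(tr, params.get("min_step_k", 3.0))
            except ValueError:
                continue
            for f, (r, fl) in enumerate(zip(tr.raw, tr.filtered)):
                t_rows.append((spot_id, fov_id, g.cell_id, f, r, fl))
            for f, amp in tr.steps:
                s_rows.append((spot_id, fov_id, g.cell_id, f, amp,
                               traces.is_single_molecule(tr)))
            spot_id += 1
        fl_df = locs_df[locs_df["fov"] == fov_id]
        by_frame = {
            int(f): list(zip(sub_df["x_nm"], sub_df["y_nm"]))
            for f, sub_df in fl_df.groupby("frame")
        }
        if by_frame:
            for trk in traces.link_tracks(by_frame,
                                          d_max=params.get("d_max_nm", 500.0),
                                          max_gap=params.get("max_gap", 1)):
                for f, x, y in zip(trk.frames, trk.x, trk.y):
                    k_rows.append((fov_id, trk.track_id, f, x, y))
    _write_csv(pd.DataFrame(t_rows, columns=["spot", "fov", "cell", "frame",
                                             "raw", "filtered"]),
               out / "traces.csv", header)
    _write_csv(pd.DataFrame(s_rows, columns=["spot", "fov", "cell", "frame",
                                             "amplitude", "single_molecule"]),
               out / "steps.csv", header)
    _write_csv(pd.DataFrame(k_rows, columns=["fov", "track", "frame",
                                             "x_nm", "y_nm"]),
               out / "tracks.csv", header)
    return spot_id


def _stage_stats(config, out, seed, header) -> int:
    recs = _read_csv(out / "intensity_records.csv", "stats")
    groups = []
    for cond, sub in recs.groupby("condition"):
        per_rep = sub.groupby("repeat")["ipv"].mean()
        if len(per_rep) >= 2:
            groups.append(GroupSample(str(cond), per_rep.to_numpy()))
    rows = []
    if len(groups) >= 2:
        F, df1, df2, p = welch_anova(groups)
        rows.append(("welch_anova", " vs ".join(g.label for g in groups),
                     F, df1, df2, p, significance_stars(p)))
        if len(groups) == 2:
            t, df, pt = welch_ttest(groups[0], groups[1])
            rows.append(("welch_t", f"{groups[0].label} vs {groups[1].label}",
                         t, df, math.nan, pt, significance_stars(pt)))
    else:
        log.info("fewer than 2 conditions with >= 2 repeats; no tests run")
    df = pd.DataFrame(rows, columns=["test", "comparison", "statistic",
                                     "df1", "df2", "p", "stars"])
    _write_csv(df, out / "stats.csv", header)
    return len(df)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
    "localize": _stage_localize,
    "traces": _stage_traces,
    "stats": _stage_stats,
}
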