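# periquant

Single-molecule imaging analysis of **periplasmic vs cytoplasmic protein
localization** in rod-shaped bacteria, with a synthetic-microscopy
generator that provides ground truth for every stage.

Gram-negative bacteria such as *E. coli* have two compartments a labelled
protein can occupy: the cytoplasmic volume and the thin periplasmic
envelope between the inner and outer membranes.  Fluorogenic dyes that
differ in membrane permeability (a fully permeable dye vs a
cytoplasm-excluded one) make the two distinguishable by fluorescence
microscopy — down to single molecules.  `periquant` implements the
quantitative analysis such experiments need:

* **simcell** — synthetic image stacks of spherocylindrical cells
  (~1 µm × 2–5 µm) with emitters placed uniformly in the cytoplasmic
  volume or on the periplasmic shell, exponential photobleaching, Gaussian
  PSF, Poisson shot noise, camera read noise, stroboscopic duty cycles and
  chained cells with a contiguous shell compartment;
* **segment** — Otsu-based cell segmentation and spherocylinder geometry:
  volume `V = π(w/2)²(l−w) + (4/3)π(w/2)³`;
* **quantify** — per-cell intensity-per-volume (ipv), autofluorescence
  baselines from no-dye controls, fluorescence gating, and the
  background-corrected **periplasmic/total ratio**
  `R_r = (mean ipv_xc,r − baseline_xc)/(mean ipv_s,r − baseline_s)`
  per biological repeat, pooled with a standard error across repeats;
* **locfit** — spot detection, sub-pixel Gaussian fitting, cell-normalised
  coordinates (ξ, υ), short-axis density profiles and the peripherality
  index `P = fraction of |υ| ≥ 0.25`, whose analytic limits are 2/3 for a
  thin shell and ≈ 0.391 for a uniform volume; plus bright-focus
  detection;
* **traces** — aperture intensity traces, the edge-preserving
  **Chung–Kennedy filter** (12-frame window, 400 ms at 30 Hz),
  photobleaching step detection, single-molecule verification
  (exactly one downward step to baseline), and greedy track linking with
  MSD-based diffusion estimates;
* **stats** — Welch one-way ANOVA, Games–Howell post-hoc and Welch
  two-sided t tests on repeat-level ratios.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

Classify a single cell's labelling pattern from normalised localizations:

```python
import numpy as np
from periquant import (ImagingConfig, CellSpec, place_emitters, fit_geometry,
                       Localization, normalize_to_cell, axial_density,
                       classify_compartment)
from periquant.simcell import spherocylinder_mask

cfg = ImagingConfig(seed=1)          # 30 Hz, 250 frames, 100 nm pixels
rng = np.random.default_rng(1)

# one 3.2 x 1.0 um cell with 200 periplasmic-shell molecules
spec = CellSpec(cell_id=0, length=3.2, width=1.0, center=(2.6, 2.6),
                orientation=0.4,
                compartment_counts={"periplasm_shell": 200})
emitters = place_emitters(spec, cfg, rng)
geom = fit_geometry(spherocylinder_mask(spec, (52, 52), cfg.pixel_um),
                    cfg.pixel_um)
print(f"cell: l={geom.length:.2f} um, w={geom.width:.2f} um, "
      f"V={geom.volume:.2f} um^3")

locs = []
for e in emitters:
    x, y = spec.world_xy(e.a, e.b)
    loc = Localization(frame=0, x=x*1000 + rng.normal(0, 20),
                       y=y*1000 + rng.normal(0, 20),
                       photons=cfg.photons_per_frame, sigma=cfg.psf_sigma)
    loc = normalize_to_cell(loc, [geom], exclude_poles=True)
    if loc is not None:
        locs.append(loc)

density = axial_density(locs)
print(f"{density.n} localizations, peripherality P = "
      f"{density.peripherality:.3f}")
print("classification:", classify_compartment(density))
```

Output:

```
cell: l=3.25 um, w=1.00 um, V=2.28 um^3
136 localizations, peripherality P = 0.625
classification: peripheral
```

The fitted geometry recovers the simulated cell (3.2 × 1.0 µm); 136
mid-body localizations (cap regions are excluded, where the constant
half-width normalisation is biased) give P = 0.625 — between the ideal
shell limit 2/3 and the 20 nm-blurred value, and well above the 0.55
threshold — so the cell is called peripheral, i.e. the label sits in the
periplasm, not the cytoplasm.

## Command-line pipeline

The full recipe (simulate → segment → quantify → localize → traces →
stats) runs from one YAML config with a single root seed; identical
config + seed reproduces identical CSVs:

```sh
periquant run-all --config src/periquant/data/demo.yaml --out demo_run
```

Each stage can also be run individually (`periquant simulate …`,
`periquant segment …`, …); outputs are TIFF stacks, label masks and CSV
tables, with a `manifest.json` recording the seed, config hash and row
counts.

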