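"""Spot detection, Gaussian fitting, cell-normalised density profiles."""

import math

import numpy as np
import pytest

from periquant.locfit import (
    SHELL_P,
    VOLUME_P,
    Localization,
    axial_density,
    classify_compartment,
    detect_foci,
    detect_spots,
    fit_spot,
    localize_frame,
    normalize_to_cell,
)
from periquant.segment import fit_geometry
from periquant.simcell import (
    CellSpec,
    ImagingConfig,
    _emitter_footprint,
    place_emitters,
    render_summed,
    spherocylinder_mask,
)


def _spot_image(cfg, x_px, y_px, photons, shape=(40, 40), offset=None):
    """Noise-free expected image of one emitter (plus camera offset)."""
    img = np.full(shape, cfg.camera_offset if offset is None else offset)
    rs, cs, fp = _emitter_footprint(x_px, y_px, photons, cfg.psf_sigma_px,
                                    shape)
    img[rs, cs] += fp
    return img


class TestDetectSpots:
    def test_flat_frame_has_no_candidates(self):
        assert len(detect_spots(np.full((30, 30), 5.0))) == 0

    def test_single_emitter_found_within_one_pixel(self, cfg_full):
        img = _spot_image(cfg_full, 17.3, 11.6, 300.0)
        peaks = detect_spots(img, psf_sigma_px=cfg_full.psf_sigma_px)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 11.6) <= 1.0
        assert abs(peaks[0][1] - 17.3) <= 1.0

    def test_well_separated_emitters_both_found(self, cfg_full):
        img = _spot_image(cfg_full, 10.0, 10.0, 300.0)
        rs, cs, fp = _emitter_footprint(25.0, 28.0, 300.0,
                                        cfg_full.psf_sigma_px, img.shape)
        img[rs, cs] += fp
        assert len(detect_spots(img, psf_sigma_px=cfg_full.psf_sigma_px)) == 2

    def test_noise_k_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((10, 10)), noise_k=0.0)


class TestFitSpot:
    def test_noiseless_centre_recovered_to_nanometre(self, cfg_full):
        x0, y0 = 20.37, 19.81
        img = _spot_image(cfg_full, x0, y0, 300.0)
        roi = img[15:26, 15:26]
        loc = fit_spot(roi, cfg_full, origin=(15, 15))
        assert loc.success
        assert loc.x == pytest.approx(x0 * cfg_full.pixel_size, abs=1.0)
        assert loc.y == pytest.approx(y0 * cfg_full.pixel_size, abs=1.0)
        assert loc.photons == pytest.approx(300.0, rel=0.1)

    def test_small_roi_rejected(self, cfg_full):
        with pytest.raises(ValueError):
            fit_spot(np.zeros((5, 5)), cfg_full)

    def test_pure_noise_roi_rejected(self, cfg_full, rng):
        rejected = 0
        for _ in range(20):
            roi = rng.normal(100.0, 3.0, (11, 11))
            if not fit_spot(roi, cfg_full).success:
                rejected += 1
        assert rejected >= 15

    def test_localization_precision_matches_shot_noise_theory(self, cfg_full,
                                                              rng):
        """Empirical localization SD follows the Thompson-Larson-Webb
        prediction (PSF width, pixelation and background terms) within 50%
        at the 300-photon / 20-background working point."""
        x0, y0 = 5.31, 5.12
        n_photons, bg = 300.0, cfg_full.bg_photons
        errs = []
        for _ in range(300):
            lam = np.zeros((11, 11))
            rs, cs, fp = _emitter_footprint(x0, y0, n_photons,
                                            cfg_full.psf_sigma_px, lam.shape)
            lam[rs, cs] += fp
            img = rng.poisson(lam + bg) + 100.0
            loc = fit_spot(img, cfg_full)
            if loc.success:
                errs.append(loc.x - x0 * cfg_full.pixel_size)
        sd = np.std(errs)
        s, a = cfg_full.psf_sigma, cfg_full.pixel_size
        var = ((s**2 + a**2 / 12) / n_photons
               + 8 * math.pi * s**4 * bg / (a**2 * n_photons**2))
        predicted = math.sqrt(var)
        assert 0.5 * predicted < sd < 1.5 * predicted


class TestNormalizeToCell:
    def _geom(self, orientation=0.2, length=4.0):
        spec = CellSpec(cell_id=3, length=length, width=1.0,
                        center=(3.0, 3.0), orientation=orientation)
        return fit_geometry(spherocylinder_mask(spec, (64, 64), 0.1), 0.1,
                            cell_id=3), spec

    def _loc(self, x_um, y_um):
        return Localization(frame=0, x=x_um * 1000, y=y_um * 1000,
                            photons=100.0, sigma=130.0)

    def test_centroid_maps_to_origin(self):
        geom, _ = self._geom()
        loc = normalize_to_cell(self._loc(3.0, 3.0), [geom])
        assert loc.xi == pytest.approx(0.0, abs=0.01)
        assert loc.upsilon == pytest.approx(0.0, abs=0.01)
        assert loc.cell_id == 3

    def test_membrane_edge_maps_to_half_width(self):
        geom, spec = self._geom()
        x, y = spec.world_xy(0.0, 0.5)  # mid-length membrane edge
        loc = normalize_to_cell(self._loc(x, y), [geom])
        assert abs(loc.upsilon) == pytest.approx(0.5, abs=0.03)

    def test_far_localization_dropped(self):
        geom, _ = self._geom()
        assert normalize_to_cell(self._loc(0.2, 0.2), [geom]) is None

    def test_rotation_leaves_normalised_coords_unchanged(self):
        """The same cell-frame emitter gives the same (xi, upsilon) after
        rotating the whole cell by 37 degrees."""
        phi = 0.2 + math.radians(37.0)
        out = []
        for orientation in (0.2, phi):
            geom, spec = self._geom(orientation=orientation)
            for a, b in [(0.7, 0.2), (-1.1, -0.35), (0.0, 0.45)]:
                x, y = spec.world_xy(a, b)
                loc = normalize_to_cell(self._loc(x, y), [geom])
                out.append((loc.xi, loc.upsilon))
        first, second = out[:3], out[3:]
        for (xi1, u1), (xi2, u2) in zip(first, second):
            assert xi1 == pytest.approx(xi2, abs=0.02)
            assert u1 == pytest.approx(u2, abs=0.03)

    def test_pole_exclusion(self):
        geom, spec = self._geom()
        x, y = spec.world_xy(1.9, 0.0)  # inside a cap (body half = 1.5)
        assert normalize_to_cell(self._loc(x, y), [geom],
                                 exclude_poles=True) is None


class TestAxialDensity:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            axial_density([])

    def test_density_integrates_to_one(self, rng):
        d = axial_density(rng.uniform(-0.5, 0.5, 500))
        width = d.bin_edges[1] - d.bin_edges[0]
        assert d.density.sum() * width == pytest.approx(1.0)

    def test_central_localizations_have_zero_peripherality(self):
        d = axial_density(np.zeros(100))
        assert d.peripherality == 0.0

    def test_shell_and_volume_limits(self, cfg, rng):
        """Mid-section projections approach the analytic P limits."""
        spec = CellSpec(cell_id=0, length=22.0, width=1.0, center=(0, 0),
                        compartment_counts={"periplasm_shell": 30_000,
                                            "cytoplasm": 30_000})
        ems = place_emitters(spec, cfg, rng)
        for comp, limit in (("periplasm_shell", SHELL_P),
                            ("cytoplasm", VOLUME_P)):
            ups = [e.b for e in ems
                   if e.compartment == comp and abs(e.a) <= 10.5]
            assert axial_density(ups).peripherality == pytest.approx(
                limit, abs=0.02)


class TestClassify:
    def test_thresholds(self):
        def density(p):
            d = axial_density(np.linspace(-0.5, 0.5, 200))
            d.peripherality = p
            return d

        assert classify_compartment(density(0.66)) == "peripheral"
        assert classify_compartment(density(0.39)) == "central"
        assert classify_compartment(density(0.5)) == "indeterminate"
        assert classify_compartment(density(0.55)) == "peripheral"
        assert classify_compartment(density(0.45)) == "central"


class TestDetectFoci:
    def _cell(self, counts, seed, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2.6, 2.6),
                        orientation=0.4, compartment_counts=counts)
        ems = place_emitters(spec, cfg, seed)
        sim = render_summed([spec], ems, cfg, shape=(52, 52), rng=seed)
        geom = fit_geometry(sim.labels == 1, cfg.pixel_um)
        return sim.stack[0] / cfg.n_frames, geom

    def test_empty_cell_has_no_foci(self, cfg):
        img, geom = self._cell({}, 1, cfg)
        _, flag = detect_foci(img, geom, cfg)
        assert not flag

    def test_focus_cells_flagged(self, cfg):
        cfgb = ImagingConfig(n_frames=40, bg_photons=5.0, seed=7)
        hits = 0
        for seed in range(20):
            img, geom = self._cell(
                {"focus": 20, "periplasm_shell": 5}, seed, cfgb)
            _, flag = detect_foci(img, geom, cfgb)
            hits += int(flag)
        assert hits >= 19

    def test_dispersed_cells_not_flagged(self, cfg):
        cfgb = ImagingConfig(n_frames=40, bg_photons=5.0, seed=7)
        hits = 0
        for seed in range(20):
            img, geom = self._cell({"periplasm_shell": 8}, seed, cfgb)
            _, flag = detect_foci(img, geom, cfgb)
            hits += int(flag)
        assert hits <= 1

    def test_fold_k_must_exceed_one(self, cfg):
        img, geom = self._cell({}, 1, cfg)
        with pytest.raises(ValueError):
            detect_foci(img, geom, cfg, fold_k=1.0)


def test_localize_frame_end_to_end(cfg_full, rng):
    """Detection + fitting recovers isolated emitters at working SNR."""
    lam = np.full((60, 60), float(cfg_full.bg_photons))
    truth = [(12.4, 15.2), (40.1, 22.7), (28.9, 47.3)]
    for x, y in truth:
        rs, cs, fp = _emitter_footprint(x, y, 300.0, cfg_full.psf_sigma_px,
                                        lam.shape)
        lam[rs, cs] += fp
    img = rng.poisson(lam) + cfg_full.camera_offset
    locs = localize_frame(img.astype(float), cfg_full)
    assert len(locs) == 3
    found = sorted((l.x / 100.0, l.y / 100.0) for l in locs)
    for (fx, fy), (tx, ty) in zip(found, sorted(truth)):
        assert math.hypot(fx - tx, fy - ty) < 1.0
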