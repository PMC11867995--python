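"""Synthetic-microscopy generator: geometry, photophysics, camera model."""

import math

import numpy as np
import pytest

from periquant.simcell import (
    CellSpec,
    ImagingConfig,
    make_chain,
    make_population,
    place_emitters,
    render_stack,
    render_summed,
    sample_cell_sums,
    simulate_mobile_molecule,
    spherocylinder_mask,
)

# fraction of a uniform disk with |b| >= r/2 (semicircular projected density)
DISK_OUTER_HALF = 1.0 - (math.sqrt(3.0) / (2.0 * math.pi) + 1.0 / 3.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_frames": 0},
        {"pixel_size": -1.0},
        {"psf_sigma": 10.0},          # undersampled PSF
        {"strobe_on": 0.0},
        {"strobe_off": -5.0},
        {"photons_per_frame": 0.0},
        {"bleach_mean_frames": 0.0},
        {"gain": 0.0},
    ],
)
def test_imaging_config_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        ImagingConfig(**kwargs)


def test_stroboscopic_duty_cycle():
    """33.3 ms on / 99.9 ms off at 30 Hz illuminates every fourth frame."""
    cfg = ImagingConfig(strobe_on=33.3, strobe_off=99.9)
    on = cfg.on_frames(20)
    assert np.array_equal(np.nonzero(on)[0], np.arange(0, 20, 4))
    assert cfg.duty_fraction == pytest.approx(0.25, abs=0.01)
    assert cfg.strobe_period_s() == pytest.approx(0.1332)
    assert ImagingConfig().on_frames(10).all()


def test_cellspec_rejects_bad_geometry():
    with pytest.raises(ValueError):
        CellSpec(cell_id=0, length=0.8, width=1.0, center=(0, 0))
    with pytest.raises(ValueError):
        CellSpec(cell_id=0, length=3.0, width=1.0, center=(0, 0),
                 compartment_counts={"nucleus": 1})


class TestPlaceEmitters:
    def test_no_counts_gives_empty_list(self, cfg):
        spec = CellSpec(cell_id=0, length=3, width=1, center=(2, 2))
        assert place_emitters(spec, cfg, 0) == []

    def test_shell_emitters_sit_exactly_on_surface(self, cfg):
        """On a sphere (l = w) every shell emitter is at radius w/2."""
        spec = CellSpec(cell_id=0, length=1.0, width=1.0, center=(2, 2),
                        compartment_counts={"periplasm_shell": 5000})
        ems = place_emitters(spec, cfg, 1)
        r = np.array([math.sqrt(e.a**2 + e.b**2 + e.c**2) for e in ems])
        assert np.allclose(r, 0.5, atol=1e-12)

    def test_cylinder_shell_emitters_on_wall(self, cfg):
        spec = CellSpec(cell_id=0, length=4.0, width=1.0, center=(2, 2),
                        compartment_counts={"periplasm_shell": 5000})
        ems = place_emitters(spec, cfg, 1)
        mid = [e for e in ems if abs(e.a) <= 1.5]
        r = np.array([math.hypot(e.b, e.c) for e in mid])
        assert np.allclose(r, 0.5, atol=1e-12)

    def test_volume_cross_axis_distribution(self, cfg):
        """Uniform disk cross-section: P(|b| >= w/4) matches the analytic
        semicircular-projection value ~0.391 in the cylindrical body."""
        spec = CellSpec(cell_id=0, length=4.0, width=1.0, center=(3, 3),
                        compartment_counts={"cytoplasm": 100_000})
        ems = place_emitters(spec, cfg, 3)
        b = np.array([e.b for e in ems if abs(e.a) <= 1.5])
        frac = np.mean(np.abs(b) >= 0.25)
        assert frac == pytest.approx(DISK_OUTER_HALF, abs=0.01)

    def test_volume_emitters_inside(self, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2, 2),
                        compartment_counts={"cytoplasm": 2000})
        for e in place_emitters(spec, cfg, 2):
            da = max(abs(e.a) - 1.0, 0.0)
            assert math.sqrt(da**2 + e.b**2 + e.c**2) < 0.5 + 1e-12

    def test_focus_emitters_cluster(self, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2, 2),
                        compartment_counts={"focus": 30})
        ems = place_emitters(spec, cfg, 4)
        assert len(ems) == 30
        spread = np.std([e.a for e in ems])
        assert spread < 0.05  # co-located up to jitter

    def test_reproducible_for_fixed_seed(self, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2, 2),
                        compartment_counts={"cytoplasm": 50,
                                            "periplasm_shell": 50})
        a = place_emitters(spec, cfg, 9)
        b = place_emitters(spec, cfg, 9)
        assert all(x.a == y.a and x.b == y.b and x.c == y.c
                   for x, y in zip(a, b))


def test_bleach_survival_is_exponential(rng):
    cfg = ImagingConfig(bleach_mean_frames=50.0)
    spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2, 2),
                    compartment_counts={"periplasm_shell": 10_000})
    ems = place_emitters(spec, cfg, 11)
    alive_at_50 = np.mean([e.bleach_frame > 50 for e in ems])
    assert alive_at_50 == pytest.approx(math.exp(-1.0), abs=0.02)


class TestRenderStack:
    def test_dark_frame_equals_offset(self):
        cfg = ImagingConfig(n_frames=5, bg_photons=0.0, read_noise_sd=0.0)
        spec = CellSpec(cell_id=0, length=2.0, width=1.0, center=(2, 2))
        sim = render_stack([spec], [], cfg, shape=(40, 40), rng=0)
        assert np.all(sim.stack == cfg.camera_offset)

    def test_photon_conservation(self, rng):
        """Mean integrated signal above offset = gain * photons * duty."""
        cfg = ImagingConfig(n_frames=200, bg_photons=0.0, read_noise_sd=0.0,
                            strobe_on=33.3, strobe_off=99.9)
        spec = CellSpec(cell_id=0, length=2.0, width=1.0, center=(2, 2),
                        compartment_counts={"periplasm_shell": 1})
        ems = place_emitters(spec, cfg, 5)
        ems[0].bleach_frame = math.inf
        sim = render_stack([spec], ems, cfg, shape=(40, 40), rng=rng)
        per_frame = (sim.stack - cfg.camera_offset).sum(axis=(1, 2))
        expected = cfg.gain * cfg.photons_per_frame * cfg.duty_fraction
        assert per_frame.mean() == pytest.approx(expected, rel=0.05)
        # off frames are exactly dark
        assert np.all(per_frame[~cfg.on_frames()] == 0)

    def test_seeded_determinism(self, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2.6, 2.6),
                        compartment_counts={"cytoplasm": 5})
        ems = place_emitters(spec, cfg, 3)
        a = render_stack([spec], ems, cfg, shape=(52, 52), rng=123)
        b = render_stack([spec], ems, cfg, shape=(52, 52), rng=123)
        assert np.array_equal(a.stack, b.stack)
        assert np.array_equal(a.labels, b.labels)
        assert a.truth.equals(b.truth)

    def test_unknown_cell_rejected(self, cfg):
        spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2, 2))
        ems = place_emitters(
            CellSpec(cell_id=5, length=3.0, width=1.0, center=(2, 2),
                     compartment_counts={"cytoplasm": 1}), cfg, 0)
        with pytest.raises(ValueError, match="unknown cell"):
            render_stack([spec], ems, cfg, shape=(40, 40), rng=0)


def test_summed_render_matches_stack_statistics(rng):
    """The one-pass summed image is distribution-identical to summing the
    frame-by-frame render (checked on means and variances)."""
    cfg = ImagingConfig(n_frames=100, bleach_mean_frames=40.0, seed=5)
    spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2.6, 2.6),
                    compartment_counts={"periplasm_shell": 3})
    ems = place_emitters(spec, cfg, 8)
    stack_sums, summed_sums = [], []
    for _ in range(60):
        sim = render_stack([spec], ems, cfg, shape=(52, 52), rng=rng)
        stack_sums.append(sim.stack.sum() - cfg.camera_offset * cfg.n_frames
                          * sim.stack[0].size)
        s2 = render_summed([spec], ems, cfg, shape=(52, 52), rng=rng)
        summed_sums.append(s2.stack[0].sum() - cfg.camera_offset
                           * cfg.n_frames * s2.stack[0].size)
    m1, m2 = np.mean(stack_sums), np.mean(summed_sums)
    assert m1 == pytest.approx(m2, rel=0.02)


def test_cell_sum_sampler_matches_rendered_sums(rng):
    cfg = ImagingConfig(n_frames=150, bleach_mean_frames=60.0)
    spec = CellSpec(cell_id=0, length=3.0, width=1.0, center=(2.6, 2.6),
                    compartment_counts={"periplasm_shell": 1})
    ems = place_emitters(spec, cfg, 2)
    shape = (52, 52)
    mask = spherocylinder_mask(spec, shape, cfg.pixel_um)
    sim = render_stack([spec], ems, cfg, shape=shape, rng=rng)
    rendered = sim.stack[:, mask].sum(axis=1) - cfg.camera_offset * mask.sum()
    fast = sample_cell_sums(spec, ems, cfg, shape, rng)
    alive = np.arange(cfg.n_frames) < ems[0].bleach_frame
    for sel in (alive, ~alive):
        if sel.sum() > 10:
            assert rendered[sel].mean() == pytest.approx(
                fast[sel].mean(), rel=0.05, abs=50.0)


class TestMobileMolecule:
    def make_cfg(self):
        return ImagingConfig(strobe_on=33.3, strobe_off=99.9, n_frames=250)

    def test_immobile_when_D_zero(self):
        cfg = self.make_cfg()
        chain = make_chain(2, 3.0, 1.0, (1.5, 2.0))
        traj = simulate_mobile_molecule(chain, 0.0, cfg, rng=1)
        assert traj["u_um"].nunique() == 1
        assert traj["x_um"].nunique() == 1

    def test_msd_per_step(self, rng):
        """1D along-axis MSD per strobe interval ~ 2 D dt = 0.0266 µm²."""
        cfg = self.make_cfg()
        chain = make_chain(10, 4.0, 1.0, (2.0, 2.0))  # long: few reflections
        steps = []
        for _ in range(20):
            traj = simulate_mobile_molecule(chain, 0.1, cfg, rng=rng)
            steps.extend(np.diff(traj["u_um"].to_numpy()) ** 2)
        expected = 2 * 0.1 * cfg.strobe_period_s()
        assert np.mean(steps) == pytest.approx(expected, rel=0.1)

    def test_stays_on_shell_and_in_chain(self):
        cfg = self.make_cfg()
        chain = make_chain(3, 2.5, 1.0, (1.25, 2.0))
        traj = simulate_mobile_molecule(chain, 0.5, cfg, rng=3)
        L = 3 * 2.5
        assert traj["u_um"].between(0, L).all()
        assert np.allclose(np.abs(traj["b_um"]),
                           0.5 * np.abs(np.cos(traj["theta"])))

    def test_range_can_exceed_single_cell(self, rng):
        cfg = self.make_cfg()
        chain = make_chain(3, 2.0, 1.0, (1.0, 2.0))
        ranges = []
        for _ in range(10):
            traj = simulate_mobile_molecule(chain, 0.5, cfg, rng=rng)
            ranges.append(traj["u_um"].max() - traj["u_um"].min())
        assert max(ranges) > 2.0

    def test_non_abutting_chain_rejected(self):
        cfg = self.make_cfg()
        cells = [
            CellSpec(cell_id=0, length=3.0, width=1.0, center=(1.5, 2.0)),
            CellSpec(cell_id=1, length=3.0, width=1.0, center=(5.5, 2.0)),
        ]
        with pytest.raises(ValueError, match="abutting"):
            simulate_mobile_molecule(cells, 0.1, cfg, rng=0)


class TestMakePopulation:
    def test_occupancy_zero_and_one(self, cfg):
        pop0 = make_population(50, 0.0, cfg, rng=0)
        assert not pop0.meta["occupied"].any()
        assert all(not f.emitters for f in pop0.fovs)
        pop1 = make_population(50, 1.0, cfg, rng=0)
        assert pop1.meta["occupied"].all()
        assert sum(len(f.emitters) for f in pop1.fovs) == 50

    def test_occupancy_binomial(self, cfg):
        pop = make_population(10_000, 0.3, cfg, rng=1)
        n_occ = int(pop.meta["occupied"].sum())
        half = 2.576 * math.sqrt(10_000 * 0.3 * 0.7)
        assert abs(n_occ - 3000) < half

    def test_three_level_structure(self, cfg):
        pop = make_population(90, 0.5, cfg, n_repeats=3, cells_per_fov=16,
                              rng=2)
        assert set(pop.meta["repeat"]) == {0, 1, 2}
        assert pop.meta.groupby("repeat").size().tolist() == [30, 30, 30]
        assert pop.meta["cell"].is_unique

    def test_invalid_occupancy(self, cfg):
        with pytest.raises(ValueError):
            make_population(10, 1.5, cfg)
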