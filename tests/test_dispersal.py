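"""Fragment drift: buoyancy stages, mortality schedule, settlement, matrices."""

import numpy as np
import pytest

from clonescape.dispersal import (
    CurrentField,
    DispersalConfig,
    HabitatPatch,
    ParticleState,
    buoyancy_velocity,
    read_patches_csv,
    relative_inflow,
    run_dispersal,
    step_particle,
    survival_probability,
    write_patches_csv,
)
from clonescape.matrices import LabelledMatrix
from clonescape.synthetic_data import SynthConfig, simulate_bay


def uniform_field(n=12, cell=500.0, u=0.0, v=0.0, depth=10.0, hours=72, border_land=False):
    x = (np.arange(n) + 0.5) * cell
    y = (np.arange(n) + 0.5) * cell
    t = np.arange(hours + 1, dtype=float)
    mask = np.ones((n, n), bool)
    if border_land:
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    uu = np.full((len(t), n, n), u)
    vv = np.full((len(t), n, n), v)
    uu[:, ~mask] = 0.0
    vv[:, ~mask] = 0.0
    d = np.where(mask, depth, 0.0)
    return CurrentField(x=x, y=y, time=t, u=uu, v=vv, depth=d, mask=mask)


def no_mortality(**kw):
    """Config whose schedule kills nobody inside a short drift window."""
    kw.setdefault("weekly_mortality", (0.0, 0.0, 0.0, 1.0))
    return DispersalConfig(**kw)


class TestLifeHistory:
    @pytest.mark.parametrize(
        "age_h,expected", [(72, 0.0049), (240, 0.0), (480, -0.005)]
    )
    def test_buoyancy_stages(self, age_h, expected):
        assert buoyancy_velocity(age_h, DispersalConfig()) == expected

    def test_survival_schedule_breakpoints(self):
        cfg = DispersalConfig()
        day = 24.0
        assert survival_probability(0, cfg) == 1.0
        assert survival_probability(7 * day, cfg) == pytest.approx(0.75)
        assert survival_probability(14 * day, cfg) == pytest.approx(0.75 * 0.5)
        assert survival_probability(21 * day, cfg) == pytest.approx(0.75 * 0.5 * 0.25)
        assert survival_probability(28 * day, cfg) == 0.0

    def test_survival_monotone_nonincreasing(self):
        cfg = DispersalConfig()
        t = np.linspace(0, 28 * 24, 500)
        s = survival_probability(t, cfg)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_week4_ramp_reaches_zero_linearly(self):
        cfg = DispersalConfig()
        s21 = survival_probability(21 * 24, cfg)
        mid = survival_probability(24.5 * 24, cfg)
        assert mid == pytest.approx(s21 / 2)

    def test_mortality_schedule_validation(self):
        with pytest.raises(ValueError):
            DispersalConfig(weekly_mortality=(0.25, 0.5, 0.75, 0.9))


class TestStepParticle:
    def test_uniform_current_advances_360m_per_hour(self, rng):
        field = uniform_field(u=0.1)
        cfg = no_mortality()
        state = ParticleState(position=(3000.0, 3000.0, 0.0), age_h=0.0, source_patch="p")
        out = step_particle(state, field, cfg, rng)
        assert out.position[0] == pytest.approx(3000.0 + 360.0)
        assert out.position[1] == pytest.approx(3000.0)
        assert out.status == "drifting"
        assert out.age_h == 1.0

    def test_still_water_neutral_stage_leaves_position_unchanged(self, rng):
        field = uniform_field()
        cfg = no_mortality(fall_velocities=(0.0, 0.0, -0.005))
        state = ParticleState(position=(3000.0, 3000.0, 5.0), age_h=24.0, source_patch="p")
        out = step_particle(state, field, cfg, rng)
        assert out.position == pytest.approx((3000.0, 3000.0, 5.0))

    def test_sinking_stage_is_clipped_at_the_bed(self, rng):
        # fall speed 0.005 m/s = 18 m/h, water only 10 m deep
        field = uniform_field(depth=10.0)
        cfg = no_mortality()
        state = ParticleState(
            position=(3000.0, 3000.0, 0.0), age_h=15 * 24.0, source_patch="p"
        )
        out = step_particle(state, field, cfg, rng)
        assert out.position[2] == pytest.approx(10.0)

    def test_leaving_the_grid_beaches(self, rng):
        field = uniform_field(n=12, u=1.0)  # 3600 m per step
        cfg = no_mortality()
        state = ParticleState(position=(5500.0, 3000.0, 0.0), age_h=0.0, source_patch="p")
        out = step_particle(state, field, cfg, rng)
        assert out.status == "dead_beached"

    def test_settles_only_after_competency_delay(self, rng):
        field = uniform_field(depth=5.0)
        patch = HabitatPatch(id="dest", cells={(6, 6)}, area=1000.0)
        cfg = no_mortality(fall_velocities=(-0.005, 0.0, -0.005), settlement_delay_h=6)
        pos = (3250.0, 3250.0, 4.9)  # inside cell (6,6)
        early = step_particle(
            ParticleState(position=pos, age_h=2.0, source_patch="p"),
            field, cfg, rng, patches=[patch],
        )
        late = step_particle(
            ParticleState(position=pos, age_h=10.0, source_patch="p"),
            field, cfg, rng, patches=[patch],
        )
        assert early.status == "drifting"
        assert late.status == "settled"
        assert late.dest_patch == "dest"


class TestRunDispersal:
    def test_self_recruitment_limit(self):
        # still water, everything sinks, no mortality inside the window:
        # every particle settles where it was released
        field = uniform_field(n=12, depth=8.0)
        patches = [
            HabitatPatch(id="a", cells={(3, 3), (3, 4)}, area=2000.0),
            HabitatPatch(id="b", cells={(8, 8)}, area=500.0),
        ]
        cfg = no_mortality(
            fall_velocities=(-0.005, 0.0, -0.005),
            particles_per_release=50,
            release_interval_h=12,
            season_days=1.0,
            max_drift_days=2.0,
            seed=5,
        )
        res = run_dispersal(field, patches, cfg)
        assert np.allclose(np.diag(res.probability.values), 1.0)
        assert res.fate_counts["settled"].sum() == res.released_per_source * 2

    def test_fate_conservation_and_row_sums(self):
        cfg_s = SynthConfig(n_sites=4, n_patches=4, grid_shape=(30, 30), field_days=6, seed=2)
        field, patches = simulate_bay(cfg_s)
        cfg = DispersalConfig(
            particles_per_release=25,
            release_interval_h=24,
            season_days=2.0,
            max_drift_days=3.0,
            seed=9,
        )
        res = run_dispersal(field, patches, cfg)
        totals = res.fate_counts.sum(axis=1)
        assert (totals == res.released_per_source).all()
        assert np.all(res.probability.values.sum(axis=1) <= 1.0 + 1e-12)
        assert np.all(res.probability.values >= 0)

    def test_flow_is_probability_times_source_area(self):
        field = uniform_field(n=12, depth=8.0)
        patches = [
            HabitatPatch(id="a", cells={(3, 3)}, area=2000.0),
            HabitatPatch(id="b", cells={(8, 8)}, area=500.0),
        ]
        cfg = no_mortality(
            fall_velocities=(-0.005, 0.0, -0.005),
            particles_per_release=20,
            release_interval_h=24,
            season_days=1.0,
            max_drift_days=1.0,
            seed=1,
        )
        res = run_dispersal(field, patches, cfg)
        areas = np.array([2000.0, 500.0])
        assert np.allclose(res.flow.values, res.probability.values * areas[:, None])

    def test_all_dead_or_expired_without_habitat_by_28d(self):
        field = uniform_field(n=12, depth=8.0)
        patches = [HabitatPatch(id="a", cells={(3, 3)}, area=100.0)]
        cfg = DispersalConfig(
            particles_per_release=40,
            release_interval_h=24,
            season_days=1.0,
            max_drift_days=28.0,
            fall_velocities=(0.0049, 0.0, 0.0),  # never touches the bed
            seed=7,
        )
        res = run_dispersal(field, patches, cfg)
        assert res.fate_counts["settled"].sum() == 0
        assert res.fate_counts["died"].sum() + res.fate_counts["expired"].sum() == (
            res.released_per_source
        )

    def test_monte_carlo_repeatability_and_convergence(self):
        field = uniform_field(n=12, depth=8.0)
        patches = [HabitatPatch(id="a", cells={(5, 5), (5, 6)}, area=1000.0)]
        cfg = dict(
            fall_velocities=(-0.005, 0.0, -0.005),
            weekly_mortality=(0.3, 0.5, 0.75, 1.0),
            particles_per_release=200,
            release_interval_h=12,
            season_days=1.0,
            max_drift_days=2.0,
        )
        p1 = run_dispersal(field, patches, no_mortality(**{**cfg, "seed": 1}))
        p1b = run_dispersal(field, patches, no_mortality(**{**cfg, "seed": 1}))
        p2 = run_dispersal(field, patches, no_mortality(**{**cfg, "seed": 2}))
        assert np.array_equal(p1.probability.values, p1b.probability.values)
        p = p1.probability.values[0, 0]
        se = np.sqrt(max(p * (1 - p), 1e-9) / p1.released_per_source)
        assert abs(p2.probability.values[0, 0] - p) <= 3 * se + 1e-9

    def test_gyre_keeps_particles_in_domain_with_cfl_margin(self):
        cfg_s = SynthConfig(
            n_sites=3, n_patches=3, grid_shape=(30, 30), field_days=4,
            tidal_amplitude=0.0, seed=3,
        )
        field, patches = simulate_bay(cfg_s)
        # CFL: fastest current must move less than one cell per step
        cell = field.x[1] - field.x[0]
        vmax = max(np.abs(field.u).max(), np.abs(field.v).max())
        assert vmax * 3600.0 < cell
        cfg = no_mortality(
            particles_per_release=30, release_interval_h=24, season_days=1.0,
            max_drift_days=2.0, fall_velocities=(0.0049, 0.0, 0.0), seed=4,
        )
        res = run_dispersal(field, patches, cfg)
        # no particle can leave a closed basin except by beaching
        fates = res.fate_counts
        assert (fates.sum(axis=1) == res.released_per_source).all()

    def test_patch_without_water_cells_rejected(self):
        field = uniform_field(border_land=True)
        bad = HabitatPatch(id="x", cells={(0, 0)}, area=10.0)
        with pytest.raises(ValueError, match="no water cells"):
            run_dispersal(field, [bad], DispersalConfig())


class TestInflow:
    def test_column_sums_by_hand(self):
        m = LabelledMatrix(
            ("a", "b", "c"),
            np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 6.0], [0.5, 1.5, 2.5]]),
            kind="asymmetric",
        )
        inflow = relative_inflow(m)
        assert inflow.tolist() == [4.5, 3.5, 9.0]
        with_self = relative_inflow(m, include_self=True)
        assert with_self.tolist() == [5.5, 3.5, 11.5]

    def test_single_source_and_zero_matrix(self):
        z = LabelledMatrix(("a", "b"), np.zeros((2, 2)), kind="asymmetric")
        assert relative_inflow(z).tolist() == [0.0, 0.0]
        m = LabelledMatrix(("a", "b"), np.array([[0.0, 5.0], [0.0, 0.0]]), kind="asymmetric")
        assert relative_inflow(m).tolist() == [0.0, 5.0]

    def test_inflow_scales_linearly_with_flow(self, rng):
        vals = rng.random((4, 4))
        m = LabelledMatrix(tuple("abcd"), vals, kind="asymmetric")
        scaled = LabelledMatrix(tuple("abcd"), 3.0 * vals, kind="asymmetric")
        assert np.allclose(3.0 * relative_inflow(m), relative_inflow(scaled))


class TestIO:
    def test_field_netcdf_round_trip(self, tmp_path):
        field = uniform_field(n=12, u=0.05, v=-0.02, hours=5)
        path = tmp_path / "bay.nc"
        field.to_netcdf(path)
        back = CurrentField.from_netcdf(path)
        assert np.allclose(back.u, field.u)
        assert np.allclose(back.v, field.v)
        assert np.array_equal(back.mask, field.mask)

    def test_patches_csv_round_trip(self, tmp_path):
        patches = [
            HabitatPatch(id="a", cells={(3, 3), (3, 4)}, area=2000.0),
            HabitatPatch(id="b", cells={(8, 8)}, area=500.0),
        ]
        path = tmp_path / "patches.csv"
        write_patches_csv(patches, path)
        back = read_patches_csv(path)
        assert [(p.id, p.cells, p.area) for p in back] == [
            (p.id, p.cells, p.area) for p in patches
        ]
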