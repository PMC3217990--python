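import numpy as np
import pytest

from tidemarsh import slr
from tidemarsh.accretion import (
    AccretionParams,
    CalibrationEntry,
    DepositionLookup,
    RunSpec,
    calibrate,
    deposition_per_cycle,
    monthly_deposition_mass,
    run_grid,
    simulate_elevation,
)
from tidemarsh.tides import TideSeries


NO_SLR = slr.SLRCurve("none", 0.0, 0.0)


def euler_deposition_oracle(depths, step_hours, ssc_kg, w_s, refine=200):
    """Independent fine-step explicit integration of the depletion/
    replenishment equations (flood phase at ambient concentration,
    exponential depletion after local high water)."""
    t_coarse = np.arange(depths.size) * step_hours
    t_fine = np.arange((depths.size - 1) * refine + 1) * (step_hours / refine)
    d = np.interp(t_fine, t_coarse, depths)
    dt = step_hours / refine * 3600.0
    mass = 0.0
    conc = ssc_kg
    for i in range(1, d.size):
        if d[i] <= 0:
            conc = ssc_kg
            continue
        if d[i] >= d[i - 1]:  # flood: replenished
            conc = ssc_kg
            mass += w_s * conc * dt
        else:  # ebb: depleting column
            settle = w_s * conc * dt
            mass += settle
            conc -= settle / d[i]
            conc = max(conc, 0.0)
    return mass


class TestDepositionPerCycle:
    def test_zero_concentration_deposits_nothing(self):
        depths = np.maximum(0.5 * np.sin(np.linspace(0, np.pi, 60)), 0)
        p = AccretionParams(ssc=0.0)
        assert deposition_per_cycle(depths, 0.1, p) == 0.0

    def test_dry_event_deposits_nothing(self):
        p = AccretionParams(ssc=200.0)
        assert deposition_per_cycle(np.zeros(50), 0.1, p) == 0.0

    def test_negative_depth_raises(self):
        p = AccretionParams(ssc=200.0)
        with pytest.raises(ValueError):
            deposition_per_cycle(np.array([0.2, -0.1]), 0.1, p)

    def test_still_water_depletion_closed_form(self):
        # near-constant falling column of depth h over duration T settles
        # h*C0*(1 - exp(-w_s T / h)) per unit area
        h, T_hours, w_s, rho = 0.8, 6.0, 2.0e-4, 400.0
        n = int(T_hours / 0.01)
        depths = h - 1e-9 * np.arange(n)  # strictly falling, no replenishment
        p = AccretionParams(ssc=250.0, settling_velocity=w_s,
                            dry_bulk_density=rho)
        gain = deposition_per_cycle(depths, 0.01, p)
        c0 = 0.25
        expected = h * c0 * (1 - np.exp(-w_s * T_hours * 3600.0 / h)) / rho
        assert gain == pytest.approx(expected, rel=0.01)

    def test_matches_fine_step_euler_oracle(self):
        # asymmetric tidal bump: fast flood, slow ebb
        t = np.linspace(0, 1, 80)
        depths = np.maximum(1.2 * np.sin(np.pi * t**0.7), 0.0)
        w_s, rho = 1.0e-4, 400.0
        p = AccretionParams(ssc=200.0, settling_velocity=w_s,
                            dry_bulk_density=rho)
        gain = deposition_per_cycle(depths, 0.1, p)
        oracle = euler_deposition_oracle(depths, 0.1, 0.2, w_s) / rho
        assert gain == pytest.approx(oracle, rel=0.01)

    def test_monthly_mass_matches_euler_oracle(self, tide):
        bed = 0.2  # intertidal bed, several cycles
        w_s = 5.0e-5
        mass = monthly_deposition_mass(tide, bed, 0.15, w_s)
        oracle = euler_deposition_oracle(tide.levels - bed, tide.step, 0.15,
                                         w_s, refine=20)
        assert mass == pytest.approx(oracle, rel=0.01)


class TestSimulateElevation:
    def test_om_only_arithmetic(self, tide):
        spec = RunSpec(
            start_elevation=-0.5,
            params=AccretionParams(ssc=0.0, om_rate=2.0),
            slr=NO_SLR, horizon=50.0, checkpoint_step=10.0,
        )
        traj = simulate_elevation(spec, tide)
        assert traj.elevation_mhhw[-1] - traj.start == pytest.approx(
            0.10, abs=1e-9
        )

    def test_horizon_checkpoint_mismatch_raises(self, tide):
        with pytest.raises(ValueError):
            RunSpec(0.0, AccretionParams(100.0), slr.HIGH, horizon=90.0,
                    checkpoint_step=20.0)

    def test_no_slr_trajectory_below_ceiling(self, tide, datums, lookup):
        spec = RunSpec(-0.5, AccretionParams(300.0, om_rate=0.0), NO_SLR)
        traj = simulate_elevation(spec, tide, lookup=lookup, datums=datums)
        assert np.all(np.diff(traj.elevation_mhhw) >= -1e-12)
        ceiling = tide.levels.max() - datums.mhhw
        assert traj.elevation_mhhw[-1] <= ceiling + 1e-9

    def test_lookup_agrees_with_direct_integration(self, tide, datums, lookup):
        spec = RunSpec(0.0, AccretionParams(200.0, om_rate=2.0), slr.HIGH)
        direct = simulate_elevation(spec, tide, datums=datums)
        fast = simulate_elevation(spec, tide, lookup=lookup, datums=datums)
        assert fast.elevation_mhhw == pytest.approx(
            direct.elevation_mhhw, abs=0.01
        )

    def test_final_elevation_monotone_in_ssc_om_and_slr(self, tide, datums,
                                                        lookup):
        def final(ssc, om, curve):
            spec = RunSpec(-0.5, AccretionParams(ssc, om_rate=om), curve)
            return simulate_elevation(
                spec, tide, lookup=lookup, datums=datums
            ).final

        f = {(s, o): final(s, o, slr.HIGH)
             for s in (50.0, 150.0, 300.0) for o in (1.0, 3.0)}
        assert f[(50.0, 1.0)] <= f[(150.0, 1.0)] <= f[(300.0, 1.0)]
        assert f[(150.0, 1.0)] <= f[(150.0, 3.0)]
        assert final(150.0, 1.0, slr.HIGH) <= final(150.0, 1.0, slr.LOW)

    def test_om_rate_changes_century_elevation_at_most_20cm(self, tide,
                                                            datums, lookup):
        for ssc in (25.0, 300.0):
            for curve in (slr.LOW, slr.HIGH):
                hi = simulate_elevation(
                    RunSpec(0.0, AccretionParams(ssc, 3.0), curve),
                    tide, lookup=lookup, datums=datums).final
                lo = simulate_elevation(
                    RunSpec(0.0, AccretionParams(ssc, 1.0), curve),
                    tide, lookup=lookup, datums=datums).final
                assert 0.0 <= hi - lo <= 0.20 + 1e-9


class TestRunGrid:
    def test_full_grid_count_with_subtidal_pairing(self, tide, datums, lookup):
        runs = run_grid(
            (25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
            (1.0, 2.0, 3.0),
            (slr.LOW, slr.HIGH),
            (-2.4, -0.5, 0.0),
            tide, lookup=lookup, datums=datums,
        )
        # 7 ssc x 3 om x 2 slr x 2 vegetated starts + 7 x 1 x 2 x 1 subtidal
        assert len(runs) == 84 + 14
        assert all(om == 0.0 for (_, om, _, s) in runs if s == -2.4)

    def test_empty_ssc_raises(self, tide):
        with pytest.raises(ValueError):
            run_grid([], [1.0], [slr.LOW], [0.0], tide)

    def test_single_combination_matches_simulate(self, tide, datums, lookup):
        runs = run_grid([150.0], [2.0], [slr.HIGH], [0.0], tide,
                        lookup=lookup, datums=datums)
        assert len(runs) == 1
        traj = runs[(150.0, 2.0, "high", 0.0)]
        direct = simulate_elevation(
            RunSpec(0.0, AccretionParams(150.0, 2.0), slr.HIGH),
            tide, lookup=lookup, datums=datums,
        )
        assert traj.elevation_mhhw == pytest.approx(direct.elevation_mhhw)


class TestCalibrate:
    def test_degenerate_ranges_return_that_pair(self, tide):
        fixture = [
            CalibrationEntry(
                "zero sediment cannot sustain a marsh under high SLR",
                "duration", (0.0,), (0.0,), ("high",), (0.0,), "le", 0.0,
            )
        ]
        res = calibrate(fixture, [1e-4], [400.0], tide)
        assert res.settling_velocity == 1e-4
        assert res.dry_bulk_density == 400.0
        assert res.satisfied_all_mandatory

    def test_trivially_satisfiable_fixture_prefers_midrange(self, tide):
        fixture = [
            CalibrationEntry(
                "any parameters pass a vacuous bound",
                "duration", (100.0,), (1.0,), ("low",), (-0.5,), "le", 100.0,
            )
        ]
        res = calibrate(fixture, [1e-5, 1e-4, 1e-3], [200.0, 500.0, 800.0],
                        tide)
        assert res.settling_velocity == 1e-4
        assert res.dry_bulk_density == 500.0
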