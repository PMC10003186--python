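"""Distance/parameter scans, window averages, PMF estimator, minimum
location."""

import numpy as np
import pandas as pd
import pytest

from gborn import (
    GAS_CONSTANT,
    EnsembleSpec,
    GBConfig,
    ProfileTable,
    build_ho_system,
    build_salt_bridge_ensemble,
    distance_scan,
    ensemble_binned_profile,
    locate_minimum,
    parameter_scan,
    pmf_from_counts,
    ScanError,
)
from gborn.synthetic import FF99_HO_LJ


class TestProfileTable:
    def test_requires_increasing_d(self):
        with pytest.raises(ValueError, match="increasing"):
            ProfileTable(table=pd.DataFrame({"d": [2.0, 1.0], "x": [0, 0]}))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="count"):
            ProfileTable(table=pd.DataFrame({"d": [1.0], "count": [-1]}))

    def test_csv_round_trip(self, tmp_path, cfg):
        prof = distance_scan(build_ho_system, [2.0, 3.0, 4.0], cfg)
        path = tmp_path / "prof.csv"
        prof.to_csv(path)
        back = ProfileTable.from_csv(path)
        assert np.allclose(back.d, prof.d)
        assert np.allclose(back.column("G_int"), prof.column("G_int"), rtol=1e-9)
        assert back.metadata["rmax"] == 999.0


class TestDistanceScan:
    def test_far_field_decay(self, cfg):
        grid = np.arange(1.0, 8.01, 0.1)
        prof = distance_scan(lambda d: build_ho_system(d, rho_H=1.2), grid, cfg)
        last = prof.table.iloc[-1]
        # the vacuum term and its screening correction decay only as 1/d
        # individually; the net solvated quantities are near zero by 8 Å
        for col in ("dGself_total", "G_int", "coulomb_total"):
            assert abs(last[col]) < 0.2

    def test_single_point_grid(self, cfg):
        prof = distance_scan(build_ho_system, [2.5], cfg)
        assert len(prof.table) == 1

    def test_zero_charges_zero_columns(self, cfg):
        def builder(d):
            from dataclasses import replace

            sys = build_ho_system(d)
            atoms = tuple(replace(a, charge=0.0) for a in sys.atoms)
            return replace(sys, atoms=atoms)

        prof = distance_scan(builder, [1.5, 3.0, 6.0], cfg)
        for col in ("dGself_total", "E_vac_int", "G_gb_int", "G_int", "coulomb_total"):
            assert np.allclose(prof.column(col), 0.0)

    def test_builder_failure_names_d(self, cfg):
        def builder(d):
            if d > 2:
                raise RuntimeError("boom")
            return build_ho_system(d)

        with pytest.raises(ScanError, match="d=3"):
            distance_scan(builder, [1.0, 3.0], cfg)


class TestParameterScan:
    def test_five_rho_curves(self, cfg):
        profs = parameter_scan(
            build_ho_system,
            {"H-on-N": [1.1, 1.2, 1.3, 1.4, 1.5]},
            [999.0],
            cfg,
            d_grid=[1.57, 3.0],
        )
        assert len(profs) == 5
        labels = [p.metadata["rho_overrides"]["H-on-N"] for p in profs]
        assert labels == [1.1, 1.2, 1.3, 1.4, 1.5]

    def test_singleton_lists_match_distance_scan(self, cfg):
        grid = [1.5, 2.5, 4.0]
        (prof,) = parameter_scan(build_ho_system, {}, [999.0], cfg, d_grid=grid)
        direct = distance_scan(build_ho_system, grid, cfg)
        assert np.allclose(prof.column("G_int"), direct.column("G_int"))

    def test_absent_class_rejected(self, cfg):
        with pytest.raises(KeyError, match="N-amide"):
            parameter_scan(
                build_ho_system, {"N-amide": [1.5]}, [999.0], cfg, d_grid=[2.0]
            )

    def test_cartesian_product_size(self, cfg):
        profs = parameter_scan(
            build_ho_system,
            {"H-on-N": [1.1, 1.5], "O-carboxyl": [1.5, 1.6]},
            [10.0, 999.0],
            cfg,
            d_grid=[2.0],
        )
        assert len(profs) == 8


class TestEnsembleBinnedProfile:
    def test_identical_snapshots_average_to_single_value(self, cfg):
        spec = EnsembleSpec(family="saltbridge", d_values=(4.0,), snapshots_per_d=1,
                            sigma=0.0, seed=0)
        (snap,) = build_salt_bridge_ensemble(spec)
        ens = [snap, snap, snap]
        prof = ensemble_binned_profile(ens, [3.5, 4.5, 5.5], cfg)
        row0, row1 = prof.table.iloc[0], prof.table.iloc[1]
        assert row0["count"] == 3
        assert row1["count"] == 0
        assert np.isnan(row1["G_int"])
        single = ensemble_binned_profile([snap], [3.5, 4.5], cfg).table.iloc[0]
        assert row0["G_int"] == pytest.approx(single["G_int"], rel=1e-12)

    def test_empty_headline_window_warns(self, cfg):
        spec = EnsembleSpec(family="saltbridge", d_values=(6.0,), snapshots_per_d=2,
                            sigma=0.0, seed=0)
        ens = build_salt_bridge_ensemble(spec)
        with pytest.warns(RuntimeWarning, match="window"):
            ensemble_binned_profile(
                ens, [3.0, 4.0, 5.0, 6.5], cfg, headline_window=(3.9, 4.0)
            )

    def test_salt_bridge_window_monotonicities(self):
        """Window-averaged desolvation rises and interaction falls as the
        hydrogen intrinsic radius grows."""
        spec = EnsembleSpec(
            family="saltbridge",
            d_values=tuple(np.round(np.arange(3.90, 4.001, 0.02), 3)),
            snapshots_per_d=20,
            sigma=0.1,
            seed=11,
        )
        ens = build_salt_bridge_ensemble(spec)
        selfs, gints = [], []
        for rho_h in (1.1, 1.3, 1.5):
            cfg = GBConfig(born_mode="obc2", radius_overrides={"H-on-N": rho_h})
            row = ensemble_binned_profile(ens, [3.9, 4.0], cfg).table.iloc[0]
            assert row["count"] > 0
            selfs.append(row["dGself_total"])
            gints.append(row["G_int"])
        assert selfs[0] < selfs[1] < selfs[2]
        assert gints[0] > gints[1] > gints[2]

    def test_binned_g_int_negative_and_relaxing_with_d(self, cfg):
        spec = EnsembleSpec(
            family="saltbridge",
            d_values=(3.5, 4.5, 6.0, 8.0),
            snapshots_per_d=5,
            sigma=0.05,
            seed=4,
        )
        ens = build_salt_bridge_ensemble(spec)
        prof = ensemble_binned_profile(ens, [3.0, 4.0, 5.0, 7.0, 9.0], cfg)
        g = prof.table.dropna()["G_int"].to_numpy()
        assert np.all(g < 0)
        assert np.all(np.diff(g) > 0)


class TestPMF:
    def test_uniform_counts_give_flat_pmf(self):
        samples = np.repeat(np.arange(1.0, 2.01, 0.1), 50)
        prof = pmf_from_counts(samples, bin_width=0.1, d_ref=1.5, T=300.0)
        occupied = prof.table[prof.table["count"] > 0]
        assert np.allclose(occupied["pmf"], 0.0, atol=1e-12)

    def test_double_count_bin_value(self):
        samples = np.concatenate([np.full(100, 5.0), np.full(200, 6.0)])
        prof = pmf_from_counts(samples, bin_width=0.1, d_ref=5.0, T=300.0)
        t = prof.table
        val = t.loc[np.isclose(t["d"], 6.0), "pmf"].iloc[0]
        assert val == pytest.approx(-GAS_CONSTANT * 300.0 * np.log(2.0), rel=1e-12)
        assert val == pytest.approx(-0.4132, abs=2e-4)

    def test_reference_bin_is_zero_by_construction(self, rng):
        samples = rng.uniform(2.0, 8.0, 5000)
        prof = pmf_from_counts(samples, 0.25, d_ref=5.0)
        t = prof.table
        assert t.loc[np.isclose(t["d"], 5.0), "pmf"].iloc[0] == 0.0

    def test_empty_reference_bin_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            pmf_from_counts([1.0, 1.1], bin_width=0.1, d_ref=9.0)

    def test_empty_bins_undefined_not_infinite(self):
        samples = np.concatenate([np.full(10, 1.0), np.full(10, 2.0)])
        prof = pmf_from_counts(samples, 0.1, d_ref=1.0)
        mid = prof.table[(prof.table["d"] > 1.2) & (prof.table["d"] < 1.8)]
        assert mid["pmf"].isna().all()

    def test_duplicating_samples_leaves_pmf_invariant(self, rng):
        samples = rng.normal(5.0, 0.5, 2000)
        p1 = pmf_from_counts(samples, 0.2, d_ref=5.0)
        p2 = pmf_from_counts(np.concatenate([samples, samples]), 0.2, d_ref=5.0)
        a, b = p1.table["pmf"].to_numpy(), p2.table["pmf"].to_numpy()
        mask = np.isfinite(a)
        assert np.allclose(a[mask], b[mask], atol=1e-12)

    def test_recovers_harmonic_potential(self):
        from gborn import sample_boltzmann_1d

        k = 2.0  # kcal/mol/A^2
        grid = np.linspace(2.0, 8.0, 400)
        u = 0.5 * k * (grid - 5.0) ** 2
        samples = sample_boltzmann_1d((grid, u), T=300.0, n=100_000, seed=5)
        prof = pmf_from_counts(samples, 0.1, d_ref=5.0, T=300.0)
        t = prof.table[prof.table["count"] > 20]
        expect = 0.5 * k * (t["d"] - 5.0) ** 2
        assert np.all(np.abs(t["pmf"] - expect) < 3 * t["pmf_se"] + 0.02)


class TestLocateMinimum:
    def test_exact_parabola(self):
        d = np.arange(1.0, 3.01, 0.1)
        prof = ProfileTable(table=pd.DataFrame({"d": d, "e": (d - 2.0) ** 2}))
        res = locate_minimum(prof, "e")
        assert res.d_min == pytest.approx(2.0, abs=1e-12)
        assert not res.boundary

    def test_monotone_column_flags_boundary(self):
        d = np.arange(1.0, 3.01, 0.1)
        prof = ProfileTable(table=pd.DataFrame({"d": d, "e": -d}))
        res = locate_minimum(prof, "e")
        assert res.boundary
        assert res.d_min == pytest.approx(3.0)

    def test_off_grid_quadratic_refinement(self):
        d = np.arange(0.0, 2.01, 0.25)
        prof = ProfileTable(table=pd.DataFrame({"d": d, "e": 3 * (d - 1.1) ** 2 + 1}))
        res = locate_minimum(prof, "e")
        assert res.d_min == pytest.approx(1.1, abs=1e-9)
        assert res.value == pytest.approx(1.0, abs=1e-9)

    def test_ho_total_energy_minimum_interior(self, cfg):
        grid = np.arange(1.0, 3.001, 0.01)
        prof = distance_scan(
            lambda d: build_ho_system(d, rho_H=1.2, lj_params=FF99_HO_LJ), grid, cfg
        )
        res = locate_minimum(prof, "total")
        assert not res.boundary
        assert 1.0 < res.d_min < 3.0

    def test_too_few_rows_rejected(self):
        prof = ProfileTable(table=pd.DataFrame({"d": [1.0, 2.0], "e": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            locate_minimum(prof, "e")

    def test_missing_column_named(self, cfg):
        prof = distance_scan(build_ho_system, [1.0, 2.0, 3.0], cfg)
        with pytest.raises(KeyError, match="nope"):
            locate_minimum(prof, "nope")


@pytest.fixture(scope="module")
def breakdowns():
    cfg = GBConfig()
    from gborn import energy_breakdown

    out = {}
    for rho_h in (1.1, 1.2, 1.3, 1.4, 1.5):
        out[rho_h] = {
            d: energy_breakdown(build_ho_system(d, rho_H=rho_h), cfg)
            for d in (1.57, 5.0)
        }
    return out


class TestFigOneReproduction:
    """The exact two-atom analysis: trends at the energy-minimum distance."""

    def test_g_int_strictly_decreasing_in_rho_h(self, breakdowns):
        vals = [breakdowns[r][1.57].g_int for r in (1.1, 1.2, 1.3, 1.4, 1.5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rho_h_effect_localized_to_short_range(self, breakdowns):
        at_contact = abs(
            breakdowns[1.5][1.57].coulomb_total - breakdowns[1.1][1.57].coulomb_total
        )
        at_5 = abs(
            breakdowns[1.5][5.0].coulomb_total - breakdowns[1.1][5.0].coulomb_total
        )
        assert at_5 < 0.1 * at_contact
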