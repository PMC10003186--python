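"""Descreening integral: analytic branches vs the quadrature oracle, and
effective Born radii."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gborn import (
    GBConfig,
    born_radii,
    build_ho_system,
    descreen_integral_oracle,
    sphere_descreen_integral,
)

INF = math.inf


def closed_form_disjoint(a, d):
    """Exterior-sphere closed form (no cutoff): the reference expression."""
    return 0.5 * (a / (d * d - a * a) + (1.0 / (2.0 * d)) * math.log((d - a) / (d + a)))


class TestSphereDescreenIntegral:
    def test_disjoint_reference_value(self):
        # frozen from the closed form and confirmed by 1e-6 quadrature
        val = sphere_descreen_integral(1.5, 1.2, 3.0, INF)
        assert val == pytest.approx(0.008757, rel=1e-3)
        assert val == pytest.approx(closed_form_disjoint(1.2, 3.0), rel=1e-12)
        assert val == pytest.approx(
            descreen_integral_oracle(1.5, 1.2, 3.0, INF), rel=1e-6
        )

    def test_sphere_beyond_rmax_is_zero(self):
        assert sphere_descreen_integral(1.5, 1.0, 10.0, rmax=8.0) == 0.0

    def test_zero_radius_sphere_is_zero(self):
        for d in (0.0, 1.0, 5.0):
            assert sphere_descreen_integral(1.5, 0.0, d) == 0.0

    def test_overlapping_case_matches_oracle(self):
        got = sphere_descreen_integral(1.5, 1.2, 1.0, INF)
        want = descreen_integral_oracle(1.5, 1.2, 1.0, INF)
        assert got == pytest.approx(want, rel=1e-4)

    def test_engulfed_case_matches_oracle(self):
        got = sphere_descreen_integral(0.5, 3.0, 1.0, INF)
        want = descreen_integral_oracle(0.5, 3.0, 1.0, INF)
        assert got == pytest.approx(want, rel=1e-6)

    def test_monotone_decreasing_in_d_outside_contact(self):
        vals = [sphere_descreen_integral(1.5, 1.2, d) for d in np.arange(2.7, 10.0, 0.1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_far_field_leading_term(self):
        # a^3/(3 d^4) is the leading multipole of the descreening integral
        a, d = 1.2, 100.0
        assert sphere_descreen_integral(1.5, a, d) == pytest.approx(
            a**3 / (3 * d**4), rel=0.01
        )

    @pytest.mark.parametrize("bad", [(-1.0, 1.0, 2.0, INF), (1.5, -0.1, 2.0, INF),
                                     (1.5, 1.0, -2.0, INF), (1.5, 1.0, 2.0, 1.0)])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            sphere_descreen_integral(*bad)

    @given(
        rho=st.floats(0.5, 2.0),
        a=st.floats(0.5, 2.5),
        scale=st.floats(1.0, 5.0),
        rmax=st.floats(5.0, 50.0),
    )
    def test_rmax_monotonicity(self, rho, a, scale, rmax):
        d = rho + a * scale  # from contact to well-separated
        lo = sphere_descreen_integral(rho, a, d, rmax)
        hi = sphere_descreen_integral(rho, a, d, INF)
        assert hi >= lo >= 0.0


class TestOracle:
    def test_matches_closed_form_on_random_disjoint_geometries(self, rng):
        for _ in range(50):
            rho = rng.uniform(0.5, 2.0)
            a = rng.uniform(0.3, 2.5)
            d = rho + a + rng.uniform(0.05, 8.0)
            want = closed_form_disjoint(a, d)
            got = descreen_integral_oracle(rho, a, d, INF)
            assert got == pytest.approx(want, rel=1e-5)

    def test_rmax_clipping_reduces_value(self):
        full = descreen_integral_oracle(1.5, 1.2, 3.0, INF)
        clipped = descreen_integral_oracle(1.5, 1.2, 3.0, 3.5)
        assert 0 < clipped < full


def _branch_cases():
    """Stratified geometries covering every analytic branch."""
    cases = []
    rng = np.random.default_rng(7)
    for _ in range(60):  # disjoint exterior
        rho, a = rng.uniform(0.5, 2.0), rng.uniform(0.3, 2.5)
        cases.append((rho, a, rho + a + rng.uniform(0.01, 10.0), INF))
    for _ in range(60):  # sphere overlapping the inner boundary
        rho, a = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.5)
        cases.append((rho, a, rng.uniform(0.4 * (rho + a), 0.999 * (rho + a)), INF))
    for _ in range(40):  # probe engulfed: d + rho <= a
        rho = rng.uniform(0.2, 0.8)
        a = rng.uniform(2.5, 5.0)
        cases.append((rho, a, rng.uniform(0.0, a - rho), INF))
    for _ in range(60):  # rmax-clipped versions of mixed geometries
        rho, a = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.5)
        d = rng.uniform(0.5, 3.0) * (rho + a)
        rmax = rng.uniform(rho + 0.1, d + a + 1.0)
        cases.append((rho, a, d, rmax))
    return cases


@pytest.mark.parametrize("case", _branch_cases(), ids=lambda c: f"{c[0]:.2f}-{c[1]:.2f}-{c[2]:.2f}")
def test_analytic_branches_agree_with_oracle(case):
    """Analytic evaluation vs adaptive quadrature across all branches."""
    rho, a, d, rmax = case
    got = sphere_descreen_integral(rho, a, d, rmax)
    want = descreen_integral_oracle(rho, a, d, rmax)
    if want < 1e-12:
        assert got == pytest.approx(want, abs=1e-10)
    else:
        assert got == pytest.approx(want, rel=1e-4)


def test_monte_carlo_spot_check(rng):
    """Independent 3-D Monte-Carlo integral over the descreening sphere."""
    for rho, a, d, rmax in [(1.5, 1.2, 3.0, INF), (1.5, 1.2, 1.0, INF),
                            (1.2, 1.5, 2.0, 2.4)]:
        n = 400_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = a * rng.random(n) ** (1.0 / 3.0)
        pts = u * r[:, None] + np.array([d, 0.0, 0.0])
        rr = np.linalg.norm(pts, axis=1)
        inside = (rr >= rho) & (rr <= rmax)
        integrand = np.where(inside, 1.0 / (4.0 * np.pi * rr**4), 0.0)
        vol = 4.0 / 3.0 * np.pi * a**3
        est = vol * integrand.mean()
        se = vol * integrand.std() / math.sqrt(n)
        got = sphere_descreen_integral(rho, a, d, rmax)
        assert abs(got - est) < 5 * se + 1e-6


class TestBornRadii:
    def test_isolated_atom_fully_solvated(self, cfg):
        sys = build_ho_system(500.0)
        res = born_radii(sys, cfg)
        assert np.allclose(res.I, 0.0, atol=1e-10)
        assert np.allclose(res.effective_radius, res.rho, atol=1e-6)

    def test_ho_reference_radius(self, cfg):
        # R_O = 1/(1/1.5 - I) with I the frozen disjoint value above
        sys = build_ho_system(3.0, rho_H=1.2)
        res = born_radii(sys, cfg)
        r_o = dict(zip(res.atom_ids, res.effective_radius))["O"]
        assert r_o == pytest.approx(1.520, abs=5e-4)

    def test_rho_h_direction_on_descreening_integrals(self, cfg):
        """Growing the hydrogen radius descreens O more and H less."""
        i_o, i_h = [], []
        for rho_h in (1.1, 1.2, 1.3, 1.4, 1.5):
            res = born_radii(build_ho_system(1.57, rho_H=rho_h), cfg)
            by_id = dict(zip(res.atom_ids, res.I))
            i_o.append(by_id["O"])
            i_h.append(by_id["H"])
        assert all(a < b for a, b in zip(i_o, i_o[1:]))
        assert all(a > b for a, b in zip(i_h, i_h[1:]))

    def test_config_overrides_apply_by_class(self, cfg):
        from dataclasses import replace

        sys = build_ho_system(3.0, rho_H=1.2)
        res = born_radii(sys, replace(cfg, radius_overrides={"H-on-N": 1.5}))
        assert dict(zip(res.atom_ids, res.rho))["H"] == 1.5

    def test_far_limit_recovers_intrinsic_radii(self, cfg):
        for d in (50.0, 200.0, 900.0):
            res = born_radii(build_ho_system(d), cfg)
            assert np.allclose(res.effective_radius, res.rho, atol=1e-3)

    def test_plain_bounds_I_and_R(self, cfg, rng):
        """0 <= I <= 1/rho and R >= rho for random two-molecule systems."""
        from gborn import AtomSite, MolecularSystem

        for _ in range(20):
            n = 6
            atoms = tuple(
                AtomSite(
                    atom_id=f"x{i}",
                    class_label="bead",
                    position=rng.uniform(-4, 4, 3),
                    charge=0.0,
                    intrinsic_radius=rng.uniform(1.0, 2.0),
                    molecule_tag="A" if i < 3 else "B",
                )
                for i in range(n)
            )
            sys = MolecularSystem(atoms=atoms)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = born_radii(sys, cfg)
            assert np.all(res.I >= 0)
            assert np.all(res.I <= 1.0 / res.rho)
            assert np.all(res.effective_radius >= res.rho - 1e-9)

    def test_clamp_warns_on_pathological_overlap(self, cfg):
        from gborn import AtomSite, MolecularSystem

        # one small probe surrounded by a shell of big overlapping spheres:
        # the pairwise sum overshoots 1/rho and must be clamped
        probe = AtomSite(
            atom_id="probe",
            class_label="bead",
            position=(0.0, 0.0, 0.0),
            charge=0.0,
            intrinsic_radius=1.0,
            molecule_tag="A",
        )
        rng = np.random.default_rng(0)
        shell = []
        for i in range(24):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            shell.append(
                AtomSite(
                    atom_id=f"x{i}",
                    class_label="bead",
                    position=3.0 * u,
                    charge=0.0,
                    intrinsic_radius=2.0,
                    molecule_tag="B",
                )
            )
        atoms = (probe, *shell)
        with pytest.warns(RuntimeWarning, match="clamp"):
            res = born_radii(MolecularSystem(atoms=atoms), cfg)
        assert np.all(np.isfinite(res.effective_radius))
        assert np.all(res.effective_radius > 0)

    def test_obc2_isolated_radius_uses_offset(self):
        from gborn import isolated_radius

        cfg2 = GBConfig(born_mode="obc2")
        res = born_radii(build_ho_system(500.0), cfg2)
        assert np.allclose(res.effective_radius, isolated_radius(res.rho, cfg2))

    def test_drop_mode_vs_clip_mode(self):
        """Whole-atom dropping keeps more descreening than geometric
        clipping for atoms inside rmax, and both vanish beyond it."""
        clip = GBConfig(rmax=4.0)
        drop = GBConfig(rmax=4.0, rmax_mode="drop")
        sys = build_ho_system(3.5, rho_H=1.2)
        i_clip = born_radii(sys, clip).I
        i_drop = born_radii(sys, drop).I
        assert np.all(i_drop >= i_clip)
        far = build_ho_system(6.0, rho_H=1.2)
        assert np.allclose(born_radii(far, drop).I, 0.0)

    def test_adding_descreener_never_decreases_I(self, cfg):
        from gborn import AtomSite, MolecularSystem

        base = build_ho_system(3.0)
        extra = AtomSite(
            atom_id="X",
            class_label="bead",
            position=(1.5, 2.0, 0.0),
            charge=0.0,
            intrinsic_radius=1.6,
            molecule_tag="arg",
        )
        bigger = MolecularSystem(atoms=base.atoms + (extra,))
        i0 = born_radii(base, cfg).I
        i1 = born_radii(bigger, cfg).I[:2]
        assert np.all(i1 >= i0 - 1e-15)
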