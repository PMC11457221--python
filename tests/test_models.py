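"""Model families: closed forms, modulation factors, virtual-site corrections,
vectorised evaluation and serialization."""

import numpy as np
import pytest

from anisovdw.errors import DomainError, ValidationError
from anisovdw.geometry import (
    AngleConvention,
    AtomSite,
    MoleculeGeometry,
    MoleculeKind,
    Plane,
    make_angular_scan,
    make_probe_grid,
    place_virtual_sites,
)
from anisovdw.models import (
    AngularParams,
    Clamp,
    Component,
    ElementParams,
    Family,
    ModelSpec,
    PlacedVsite,
    SphericalParams,
    VsiteParams,
    cosine_factor,
    dispersion_cos,
    dispersion_spherical,
    evaluate_model,
    exchange_cos,
    exchange_spherical,
    vsite_exchange_correction,
)


def single_atom(element="I", vdw=1.98, pos=(0.0, 0.0, 0.0)):
    return MoleculeGeometry(
        atoms=(AtomSite(element, np.array(pos), vdw),),
        kind=MoleculeKind.HYDROGEN_HALIDE,
        sigma_hole_axis=np.array([0.0, -1.0, 0.0]),
    )


UNIT_PARAMS = SphericalParams({"I": ElementParams(A=1.0, b=1.0, C6=1.0)})


class TestSpherical:
    def test_zero_amplitude_gives_zero(self, hi):
        params = SphericalParams({"I": ElementParams(), "H": ElementParams()})
        assert exchange_spherical(params, hi, [1.0, 1.0, 1.0]) == 0.0

    def test_exchange_closed_form(self):
        mol = single_atom()
        assert exchange_spherical(UNIT_PARAMS, mol, [1.0, 0, 0]) == pytest.approx(np.exp(-1.0))
        assert exchange_spherical(UNIT_PARAMS, mol, [1e-9, 0, 0]) == pytest.approx(1.0)

    def test_dispersion_closed_form_and_scaling(self):
        mol = single_atom()
        e1 = dispersion_spherical(UNIT_PARAMS, mol, [1.0, 0, 0])
        e2 = dispersion_spherical(UNIT_PARAMS, mol, [2.0, 0, 0])
        assert e1 == pytest.approx(-1.0)
        assert e2 == pytest.approx(e1 / 64.0)

    @pytest.mark.parametrize("op", [exchange_spherical, dispersion_spherical])
    def test_additivity_over_atoms(self, op):
        """A two-atom molecule equals the sum of two single-atom evaluations."""
        params = SphericalParams(
            {"I": ElementParams(A=3.0, b=2.1, C6=5.0), "H": ElementParams(A=0.7, b=4.0, C6=0.3)}
        )
        mol = MoleculeGeometry(
            atoms=(
                AtomSite("I", np.array([0.0, 0, 0]), 1.98),
                AtomSite("H", np.array([0.0, 1.6, 0]), 1.2),
            ),
            kind=MoleculeKind.HYDROGEN_HALIDE,
            sigma_hole_axis=np.array([0.0, -1.0, 0.0]),
        )
        point = [1.3, 2.2, -0.4]
        parts = sum(
            op(params, single_atom(a.element, a.vdw_radius, a.position), point)
            for a in mol.atoms
        )
        assert op(params, mol, point) == pytest.approx(parts, rel=1e-12)

    def test_coincident_point_is_domain_error(self):
        with pytest.raises(DomainError):
            exchange_spherical(UNIT_PARAMS, single_atom(), [0.0, 0.0, 0.0])


class TestCosineFactor:
    def test_ninety_degrees_is_unity(self):
        for k in (0.5, 1.0, 2.0):
            assert cosine_factor(90.0, 0.7, k) == pytest.approx(1.0, abs=1e-30)

    def test_apex_value(self):
        assert cosine_factor(0.0, 0.34, 1.7) == pytest.approx(1 - 0.34)

    def test_halide_clamp_beyond_90(self):
        assert cosine_factor(150.0, 0.34, 2.0) == cosine_factor(90.0, 0.34, 2.0) == 1.0

    def test_water_window_deactivates(self):
        # |theta - theta_m| > 90 deg leaves the factor at exactly 1
        assert cosine_factor(170.0, 0.5, 1.0, theta_m=60.0, clamp="water_window") == 1.0
        assert cosine_factor(60.0, 0.5, 1.0, theta_m=60.0, clamp="water_window") == pytest.approx(0.5)

    @pytest.mark.parametrize("clamp,boundary,theta_m", [
        (Clamp.HALIDE_90, 90.0, 0.0),
        (Clamp.WATER_WINDOW, 155.0, 65.0),
    ])
    def test_clamp_continuity(self, clamp, boundary, theta_m):
        """The factor approaches 1 smoothly from both sides of the clamp."""
        for eps in (1.0, 0.1, 1e-3):
            below = cosine_factor(boundary - eps, 0.8, 1.3, theta_m, clamp)
            above = cosine_factor(min(boundary + eps, 180.0), 0.8, 1.3, theta_m, clamp)
            assert abs(below - 1.0) < 0.02 * eps + 1e-12
            assert abs(above - 1.0) < 1e-12

    @pytest.mark.parametrize("k", [0.0, -1.0, 2.5])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValidationError):
            cosine_factor(45.0, 0.3, k)


class TestCosModels:
    def test_zero_amplitude_collapses_to_spherical(self, hi):
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6, C6=1500), "H": ElementParams(A=2e4, b=4.0, C6=150)}
        )
        angular = AngularParams(W=0.0, Q=0.0, k=2.0)
        grid = make_angular_scan(hi, [0.7, 1.0], np.linspace(5, 175, 35), "halide_apex")
        for p in grid.positions:
            assert exchange_cos(params, angular, hi, p, "halide_apex") == pytest.approx(
                exchange_spherical(params, hi, p), rel=0, abs=0
            )
            assert dispersion_cos(params, angular, hi, p, "halide_apex") == pytest.approx(
                dispersion_spherical(params, hi, p), rel=0, abs=0
            )

    def test_hi_apex_exchange_reduced_34_percent(self, hi):
        """With W = 0.34 the heavy-atom exchange at the apex is 66% of its
        90-degree value at equal separation."""
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=0.0, b=4.0)}
        )
        angular = AngularParams(W=0.34, k=2.0)
        scan = make_angular_scan(hi, [1.0], [0.0, 90.0], "halide_apex")
        e0 = exchange_cos(params, angular, hi, scan.positions[0], "halide_apex")
        e90 = exchange_cos(params, angular, hi, scan.positions[1], "halide_apex")
        assert e0 / e90 == pytest.approx(0.66, abs=1e-12)

    def test_hi_dispersion_ratio_20_percent(self, hi):
        params = SphericalParams(
            {"I": ElementParams(C6=1500.0), "H": ElementParams(C6=0.0)}
        )
        angular = AngularParams(Q=0.2, k=2.0)
        scan = make_angular_scan(hi, [1.0], [0.0, 90.0], "halide_apex")
        d0 = dispersion_cos(params, angular, hi, scan.positions[0], "halide_apex")
        d90 = dispersion_cos(params, angular, hi, scan.positions[1], "halide_apex")
        assert abs(d0) / abs(d90) == pytest.approx(0.8, abs=1e-12)
        assert d0 < 0 and d90 < 0  # sign preserved

    def test_negative_w_enhances_sagittal_exchange(self, water):
        """A lone-pair-type amplitude (W < 0) gives a factor > 1 at theta_m."""
        params = SphericalParams(
            {"O": ElementParams(A=4.6e4, b=4.2), "H": ElementParams(A=2e4, b=4.0)}
        )
        angular = AngularParams(W=-0.35, k=1.0, theta_m=95.0)
        scan = make_angular_scan(water, [1.0], [95.0], "water_sagittal")
        enhanced = exchange_cos(params, angular, water, scan.positions[0], "water_sagittal")
        plain = exchange_spherical(params, water, scan.positions[0])
        assert enhanced > plain


class TestVsiteCorrection:
    def test_zero_amplitude(self, hi):
        (pos,) = place_virtual_sites(hi, [("halide_apex", 0.9, None)])
        site = PlacedVsite("halide_apex", pos, VsiteParams(A_vs=0.0, b_vs=4.0, d=0.9))
        assert vsite_exchange_correction([site], [0.0, 1.0, 0.0]) == 0.0

    def test_exponential_distance_ratio(self, hi):
        (pos,) = place_virtual_sites(hi, [("halide_apex", 0.9, None)])
        site = PlacedVsite("halide_apex", pos, VsiteParams(A_vs=5e3, b_vs=4.0, d=0.9))
        p1 = pos + np.array([0.0, -1.5, 0.0])
        p2 = pos + np.array([0.0, -2.0, 0.0])
        v1 = vsite_exchange_correction([site], p1)
        v2 = vsite_exchange_correction([site], p2)
        assert v1 < 0 and v2 < 0  # apex sites only dampen
        assert v1 / v2 == pytest.approx(np.exp(4.0 * 0.5), rel=1e-12)

    def test_water_pair_mirror_symmetry(self, water):
        """Symmetric lone-pair sites give a field that is mirror-symmetric
        through the molecular plane (evaluated on mirrored point pairs)."""
        positions = place_virtual_sites(water, [("water_lone_pair", 0.35, 95.0)])
        sites = [
            PlacedVsite("water_lone_pair", pos, VsiteParams(A_vs=1e3, b_vs=5.0, d=0.35, angle=95.0))
            for pos in positions
        ]
        o = water.heavy_atom.position
        rng = np.random.default_rng(7)
        for _ in range(20):
            offset = rng.normal(size=3)
            p_up = o + offset
            mirror = offset - 2 * float(offset @ water.plane_normal) * water.plane_normal
            p_down = o + mirror
            assert vsite_exchange_correction(sites, p_up) == pytest.approx(
                vsite_exchange_correction(sites, p_down), rel=1e-12
            )


@pytest.fixture(scope="module")
def grid50(hi):
    from anisovdw.geometry import filter_probe_grid_by_vdw

    grid = make_probe_grid(hi, Plane.HALIDE_2D, (4, 8), 1.0)
    return filter_probe_grid_by_vdw(grid, hi)


class TestEvaluateModel:

    def test_spherical_dispatch_matches_scalar_loop(self, hi, grid50):
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=2e4, b=4.0)}
        )
        spec = ModelSpec(Family.SPHERICAL, Component.EXCHANGE, params)
        vec = evaluate_model(spec, hi, grid50)
        loop = [exchange_spherical(params, hi, p) for p in grid50.positions]
        assert np.allclose(vec, loop, rtol=1e-13, atol=0)

    def test_cos_dispatch_matches_scalar_loop(self, hi, grid50):
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=2e4, b=4.0)}
        )
        angular = AngularParams(W=0.34, k=2.0)
        spec = ModelSpec(Family.COS, Component.EXCHANGE, params, angular)
        vec = evaluate_model(spec, hi, grid50)
        loop = [
            exchange_cos(params, angular, hi, p, AngleConvention.HALIDE_APEX)
            for p in grid50.positions
        ]
        assert np.allclose(vec, loop, rtol=1e-13, atol=0)

    def test_vsite_zero_amplitude_equals_spherical(self, hi, grid50):
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=2e4, b=4.0)}
        )
        sph = ModelSpec(Family.SPHERICAL, Component.EXCHANGE, params)
        vsite = ModelSpec(
            Family.VSITE,
            Component.EXCHANGE,
            params,
            vsites=(("halide_apex", VsiteParams(A_vs=0.0, b_vs=4.0, d=0.9)),),
        )
        assert np.array_equal(evaluate_model(sph, hi, grid50), evaluate_model(vsite, hi, grid50))

    def test_vsite_only_dampens(self, hi, grid50):
        params = SphericalParams(
            {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=2e4, b=4.0)}
        )
        sph = ModelSpec(Family.SPHERICAL, Component.EXCHANGE, params)
        vsite = ModelSpec(
            Family.VSITE,
            Component.EXCHANGE,
            params,
            vsites=(("halide_apex", VsiteParams(A_vs=5e3, b_vs=4.0, d=0.9)),),
        )
        assert np.all(evaluate_model(vsite, hi, grid50) <= evaluate_model(sph, hi, grid50))

    def test_long_range_limit(self, hi):
        """Every model term vanishes at 50 A for unit parameters."""
        mol = single_atom()
        far = mol.heavy_atom.position + np.array([0.0, -50.0, 0.0])
        assert abs(exchange_spherical(UNIT_PARAMS, mol, far)) < 1e-10
        assert abs(dispersion_spherical(UNIT_PARAMS, mol, far)) < 1e-10
        site = PlacedVsite(
            "halide_apex",
            place_virtual_sites(hi, [("halide_apex", 0.9, None)])[0],
            VsiteParams(A_vs=1.0, b_vs=1.0, d=0.9),
        )
        assert abs(vsite_exchange_correction([site], far)) < 1e-10


class TestModelSpec:
    def test_json_round_trip(self):
        spec = ModelSpec(
            Family.COS,
            Component.EXCHANGE,
            SphericalParams(
                {"I": ElementParams(A=2.8e5, b=3.6), "H": ElementParams(A=2e4, b=4.0)}
            ),
            AngularParams(W=0.34, k=1.97, theta_m=0.0),
        )
        assert ModelSpec.from_json(spec.to_json()) == spec

    def test_cos_requires_angular(self):
        with pytest.raises(ValidationError):
            ModelSpec(Family.COS, Component.EXCHANGE, UNIT_PARAMS)

    def test_vsite_dispersion_disallowed(self):
        with pytest.raises(ValidationError):
            ModelSpec(
                Family.VSITE,
                Component.DISPERSION,
                UNIT_PARAMS,
                vsites=(("halide_apex", VsiteParams(A_vs=1.0, b_vs=1.0, d=0.9)),),
            )

    @pytest.mark.parametrize("bad", [dict(W=1.5), dict(k=0.0), dict(k=2.5), dict(theta_m=-5.0)])
    def test_angular_invariants(self, bad):
        with pytest.raises(ValidationError):
            AngularParams(**bad)
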