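"""Fitting: metrics, threshold filter, parameter recovery, nesting,
equivariance, reproducibility, virtual-site scan and the combined water fit."""

import dataclasses

import numpy as np
import pytest

from anisovdw.errors import ValidationError
from anisovdw.fitting import (
    FitOptions,
    apply_exchange_threshold,
    compute_rmse,
    delta_reduction,
    anisotropy_summary,
    fit_model,
    fit_water_combined,
    scan_vsite_distance,
)
from anisovdw.models import Component, Family, ModelSpec
from anisovdw.synthetic import (
    generate_surface,
    paper_mimic_config,
    vsite_mimic_config,
    water_combined_configs,
)

FAST = FitOptions(seed=3, n_starts=8)


def noiseless_config(system="HI", spacing=0.25, family=None):
    cfg = paper_mimic_config(system, seed=3, noise_model="none", noise_sigma=0.0, spacing=spacing)
    if family is Family.SPHERICAL:
        truth = ModelSpec(Family.SPHERICAL, Component.EXCHANGE, cfg.truth_exchange.spherical)
        cfg = dataclasses.replace(cfg, truth_exchange=truth)
    return cfg


class TestMetrics:
    def test_rmse_identical_and_offset(self):
        v = np.arange(5.0)
        assert compute_rmse(v, v) == 0.0
        assert compute_rmse(v + 3.5, v) == pytest.approx(3.5)

    def test_rmse_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        manual = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 10.0)
        assert compute_rmse(a, b) == pytest.approx(manual, rel=1e-14)

    def test_rmse_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_rmse([], [])

    @pytest.mark.parametrize(
        "new,base,expected", [(1.0, 1.0, 0.0), (0.2, 1.0, 80.0), (0.0, 1.0, 100.0)]
    )
    def test_delta_reduction(self, new, base, expected):
        assert delta_reduction(new, base) == pytest.approx(expected)

    def test_delta_reduction_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            delta_reduction(1.0, 0.0)


class TestExchangeThreshold:
    def test_removes_above_threshold_only(self, hi_mimic_surface):
        # fixture is already filtered at 100; refilter a raw surface here
        cfg = paper_mimic_config("HI", seed=11, spacing=0.25)
        raw = generate_surface(cfg)
        cut = apply_exchange_threshold(raw)
        assert np.all(cut.exchange <= 100.0)
        # survivors match an independent brute-force scan
        survivors = sum(1 for e in raw.exchange if e <= 100.0)
        assert len(cut) == survivors
        assert len(cut.dispersion) == len(cut) == len(cut.grid)
        assert "exchange_threshold=100" in cut.provenance

    def test_infinite_threshold_is_identity(self):
        cfg = paper_mimic_config("HI", seed=2, spacing=0.5)
        raw = generate_surface(cfg)
        same = apply_exchange_threshold(raw, float("inf"))
        assert len(same) == len(raw)

    def test_nonpositive_threshold_rejected(self):
        cfg = paper_mimic_config("HI", seed=2, spacing=0.5)
        with pytest.raises(ValidationError):
            apply_exchange_threshold(generate_surface(cfg), 0.0)


class TestRecovery:
    def test_noiseless_spherical_parameters_recovered(self):
        cfg = noiseless_config(family=Family.SPHERICAL)
        surface = apply_exchange_threshold(generate_surface(cfg))
        result = fit_model(surface, "spherical", "exchange", options=FAST)
        truth = cfg.truth_exchange.spherical
        for el in ("I", "H"):
            got, want = result.spec.spherical.get(el), truth.get(el)
            assert got.A == pytest.approx(want.A, rel=1e-6)
            assert got.b == pytest.approx(want.b, rel=1e-6)
        assert result.rmse < 1e-8

    def test_noiseless_cos_amplitude_recovered(self):
        cfg = noiseless_config()
        surface = apply_exchange_threshold(generate_surface(cfg))
        result = fit_model(surface, "cos", "exchange", options=FAST)
        assert abs(result.spec.angular.W - 0.34) < 1e-4
        assert result.spec.angular.k == pytest.approx(2.0, abs=1e-3)

    def test_noiseless_dispersion_q_recovered(self):
        cfg = noiseless_config()
        surface = apply_exchange_threshold(generate_surface(cfg))
        result = fit_model(surface, "cos", "dispersion", options=FAST)
        assert abs(result.spec.angular.Q - 0.20) < 1e-4

    def test_spherical_family_cannot_fit_cos_truth(self):
        surface = apply_exchange_threshold(generate_surface(noiseless_config()))
        result = fit_model(surface, "spherical", "exchange", options=FAST)
        assert result.rmse > 0.1  # model mismatch leaves structure behind


class TestFitProperties:
    def test_nested_model_monotonicity(self, hi_mimic_fits):
        sph = hi_mimic_fits["spherical"].rmse
        assert hi_mimic_fits["cos"].rmse <= sph * (1 + 1e-8)
        assert hi_mimic_fits["vsite"].rmse <= sph * (1 + 1e-8)

    def test_delta_reported_against_shared_baseline(self, hi_mimic_fits):
        cos = hi_mimic_fits["cos"]
        assert cos.baseline_rmse == hi_mimic_fits["spherical"].rmse
        assert cos.delta_reduction == pytest.approx(
            100.0 * (1 - cos.rmse / cos.baseline_rmse)
        )

    def test_seeded_reproducibility_is_bit_identical(self, hi_mimic_surface):
        opts = FitOptions(seed=42, n_starts=6)
        a = fit_model(hi_mimic_surface, "cos", "exchange", options=opts)
        b = fit_model(hi_mimic_surface, "cos", "exchange", options=opts)
        assert a.spec == b.spec
        assert a.rmse == b.rmse

    def test_scale_equivariance(self, hi_mimic_surface):
        """Scaling all energies by s scales A and rmse by s, leaves shape
        parameters (b, W, k) unchanged."""
        s = 7.25
        scaled = dataclasses.replace(
            hi_mimic_surface,
            exchange=hi_mimic_surface.exchange * s,
            dispersion=hi_mimic_surface.dispersion * s,
        )
        opts = FitOptions(seed=5, n_starts=8)
        base = fit_model(hi_mimic_surface, "cos", "exchange", options=opts)
        big = fit_model(scaled, "cos", "exchange", options=opts)
        assert big.rmse == pytest.approx(s * base.rmse, rel=1e-6)
        for el in ("I", "H"):
            assert big.spec.spherical.get(el).A == pytest.approx(
                s * base.spec.spherical.get(el).A, rel=1e-5
            )
            assert big.spec.spherical.get(el).b == pytest.approx(
                base.spec.spherical.get(el).b, rel=1e-6
            )
        assert big.spec.angular.W == pytest.approx(base.spec.angular.W, rel=1e-5)
        assert big.spec.angular.k == pytest.approx(base.spec.angular.k, rel=1e-4)

    def test_unfiltered_surface_rejected(self):
        cfg = paper_mimic_config("HI", seed=2, spacing=0.5)
        raw = generate_surface(cfg)
        unfiltered = dataclasses.replace(
            raw, grid=dataclasses.replace(raw.grid, filtered=False)
        )
        with pytest.raises(ValidationError):
            fit_model(unfiltered, "spherical", "exchange")

    def test_underdetermined_fit_rejected(self, hi_mimic_surface):
        tiny = hi_mimic_surface.subset(np.arange(len(hi_mimic_surface)) < 3)
        with pytest.raises(ValidationError):
            fit_model(tiny, "cos", "exchange")


class TestVsiteScan:
    def test_single_distance_profile(self, hi_mimic_surface):
        scan = scan_vsite_distance(
            hi_mimic_surface, d_grid=[0.9], options=FitOptions(seed=3, n_starts=6)
        )
        assert len(scan.results) == 1
        assert scan.best is scan.results[0]
        assert scan.best_distance == 0.9

    def test_truth_distance_recovered_within_one_step(self):
        cfg = vsite_mimic_config("HI", seed=9, spacing=0.25)
        surface = apply_exchange_threshold(generate_surface(cfg))
        d_grid = np.round(np.arange(0.6, 1.21, 0.15), 10)
        scan = scan_vsite_distance(surface, d_grid=d_grid, options=FitOptions(seed=9, n_starts=6))
        assert abs(scan.best_distance - 0.9) <= 0.15 + 1e-12

    def test_empty_grid_rejected(self, hi_mimic_surface):
        with pytest.raises(ValidationError):
            scan_vsite_distance(hi_mimic_surface, d_grid=[])


@pytest.fixture(scope="module")
def surfaces():
    cfg_f, cfg_s = water_combined_configs(0)
    return (
        apply_exchange_threshold(generate_surface(cfg_f)),
        apply_exchange_threshold(generate_surface(cfg_s)),
    )


@pytest.fixture(scope="module")
def mode_fits(surfaces):
    frontal, sagittal = surfaces
    opts = FitOptions(seed=0, n_starts=8)
    base = fit_water_combined(frontal, sagittal, "none", options=opts)
    fits = {"none": base}
    for mode in ("LP", "SH", "both"):
        fits[mode] = fit_water_combined(frontal, sagittal, mode, options=opts, baseline=base)
    return fits


class TestWaterCombined:
    def test_none_mode_recovers_shared_spherical_truth(self):
        cfg_f, cfg_s = water_combined_configs(0, noise_sigma=0.0, noise_model="none")
        truth = ModelSpec(
            Family.SPHERICAL, Component.EXCHANGE, cfg_f.truth_exchange.spherical
        )
        cfg_f = dataclasses.replace(cfg_f, truth_exchange=truth)
        cfg_s = dataclasses.replace(cfg_s, truth_exchange=truth)
        frontal = apply_exchange_threshold(generate_surface(cfg_f))
        sagittal = apply_exchange_threshold(generate_surface(cfg_s))
        result = fit_water_combined(frontal, sagittal, "none", options=FitOptions(seed=1, n_starts=6))
        for el in ("O", "H"):
            assert result.spec.spherical.get(el).A == pytest.approx(
                truth.spherical.get(el).A, rel=1e-5
            )
        assert result.rmse < 1e-6

    def test_nested_mode_monotonicity(self, mode_fits):
        tol = 1 + 1e-8
        assert mode_fits["both"].rmse <= mode_fits["LP"].rmse * tol
        assert mode_fits["both"].rmse <= mode_fits["SH"].rmse * tol
        assert mode_fits["LP"].rmse <= mode_fits["none"].rmse * tol
        assert mode_fits["SH"].rmse <= mode_fits["none"].rmse * tol

    def test_sigma_hole_sites_help_more_than_lone_pairs(self, mode_fits):
        assert mode_fits["SH"].rmse < mode_fits["LP"].rmse

    def test_residuals_cover_both_blocks(self, surfaces, mode_fits):
        frontal, sagittal = surfaces
        for fit in mode_fits.values():
            assert fit.residuals is not None
            assert len(fit.residuals) == len(frontal) + len(sagittal)

    def test_invalid_mode_rejected(self, surfaces):
        with pytest.raises(ValidationError):
            fit_water_combined(*surfaces, "sigma")


class TestSummary:
    def test_summary_layout_and_recovered_w(self, hi_mimic_fits):
        table = anisotropy_summary({"HI": hi_mimic_fits})
        assert list(table.columns) == ["compound", "W (%)", "delta Cos (%)", "delta Vsite (%)"]
        assert table.loc[0, "compound"] == "HI"
        assert table.loc[0, "W (%)"] == pytest.approx(34.0, abs=1.0)
        assert table.loc[0, "delta Cos (%)"] > 0

    def test_spherical_truth_gives_near_zero_deltas(self):
        cfg = noiseless_config(family=Family.SPHERICAL)
        cfg = dataclasses.replace(cfg, noise_model="multiplicative_gaussian", noise_sigma=0.01)
        surface = apply_exchange_threshold(generate_surface(cfg))
        from anisovdw.fitting import fit_families

        fits = fit_families(
            surface, ["spherical", "cos", "vsite"], "exchange",
            options=FitOptions(seed=3, n_starts=6, vsite_free_distance=True),
        )
        table = anisotropy_summary({"HI": fits})
        assert abs(table.loc[0, "delta Cos (%)"]) < 5.0
        assert abs(table.loc[0, "delta Vsite (%)"]) < 5.0

    def test_missing_family_rejected(self, hi_mimic_fits):
        partial = {k: v for k, v in hi_mimic_fits.items() if k != "vsite"}
        with pytest.raises(ValidationError):
            anisotropy_summary({"HI": partial})
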