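"""Bounded nonlinear least-squares fitting of the model families to energy
surfaces, plus the RMSE / delta-reduction metrics.

The loss is unweighted least squares on the energies that survive the
exchange threshold (default 100 kJ/mol). Fits are multistart: a seeded
Latin-hypercube sample over the bounded parameter box (the cos^k / theta_m
landscape is multimodal), one heuristic start (decay constants at a typical
Born-Mayer value with amplitudes from a non-negative linear solve), and — for
the anisotropic families — a "nested" start at the spherical optimum with the
anisotropy switched off, which makes the nested-model RMSE monotonicity hold
by construction up to optimizer tolerance. Internally every parameter is
mapped to [0, 1] (log10 for the amplitudes A, C6, A_vs); reported parameters
are physical. Identical surface + options.seed gives bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from scipy.stats import qmc

from . import constants
from .errors import ValidationError
from .geometry import (
    AngleConvention,
    MoleculeGeometry,
    MoleculeKind,
    ProbeGrid,
    VsiteKind,
)
from .models import (
    AngularParams,
    Clamp,
    Component,
    ElementParams,
    Family,
    ModelSpec,
    SphericalParams,
    VsiteParams,
    VSITE_SIGN,
    _clamp_for,
    _distances,
    _hydrogen_apex_theta,
    cosine_factor,
)

__all__ = [
    "EnergySurface",
    "FitOptions",
    "FitResult",
    "VsiteScan",
    "anisotropy_summary",
    "apply_exchange_threshold",
    "compute_rmse",
    "delta_reduction",
    "fit_families",
    "fit_model",
    "fit_water_combined",
    "scan_vsite_distance",
]

_AMP_LO, _AMP_HI = -3.0, 9.0  # log10 bounds for A and A_vs (kJ/mol)
_C6_LO, _C6_HI = -3.0, 7.0  # log10 bounds for C6 (kJ A^6/mol)


@dataclass(frozen=True, eq=False)
class EnergySurface:
    """Probe grid plus exchange and dispersion reference energies (kJ/mol)."""

    grid: ProbeGrid
    exchange: np.ndarray
    dispersion: np.ndarray
    provenance: str = ""
    system: str | None = None
    molecule: MoleculeGeometry | None = None

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchange, dtype=float)
        dp = np.asarray(self.dispersion, dtype=float)
        n = len(self.grid)
        if len(ex) != n or len(dp) != n:
            raise ValidationError(
                f"energy vectors (lengths {len(ex)}, {len(dp)}) must match point count {n}"
            )
        if not (np.all(np.isfinite(ex)) and np.all(np.isfinite(dp))):
            raise ValidationError("energy vectors contain NaN or infinite values")
        object.__setattr__(self, "exchange", ex)
        object.__setattr__(self, "dispersion", dp)

    def __len__(self) -> int:
        return len(self.grid)

    def component(self, component: Component | str) -> np.ndarray:
        return self.exchange if Component(component) is Component.EXCHANGE else self.dispersion

    def subset(self, mask: np.ndarray, *, provenance: str | None = None) -> "EnergySurface":
        return replace(
            self,
            grid=self.grid.subset(mask),
            exchange=self.exchange[mask],
            dispersion=self.dispersion[mask],
            provenance=self.provenance if provenance is None else provenance,
        )


def compute_rmse(model_values, reference_values) -> float:
    """Root-mean-square error between two equal-length energy vectors."""
    a = np.asarray(model_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError(
            f"RMSE needs two equal-length non-empty vectors, got shapes {a.shape} and {b.shape}"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)))


def delta_reduction(rmse_new: float, rmse_baseline: float) -> float:
    """Percent reduction of RMSE relative to a baseline: 100 (1 - new/base)."""
    if not (rmse_baseline > 0):
        raise ValidationError(f"baseline RMSE must be > 0, got {rmse_baseline}")
    return 100.0 * (1.0 - rmse_new / rmse_baseline)


def apply_exchange_threshold(
    surface: EnergySurface,
    threshold: float = constants.DEFAULT_EXCHANGE_THRESHOLD,
) -> EnergySurface:
    """Drop points whose exchange energy exceeds ``threshold`` (kJ/mol).

    Removal applies to both component vectors and the grid; the threshold is
    recorded in the provenance.
    """
    if not (threshold > 0):
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    keep = surface.exchange <= threshold
    prov = surface.provenance
    if math.isfinite(threshold):
        prov = f"{prov} | exchange_threshold={threshold:g}" if prov else f"exchange_threshold={threshold:g}"
    return surface.subset(keep, provenance=prov)


# ---------------------------------------------------------------------------
# fit machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Controls for the multistart bounded least-squares fits.

    ``n_starts`` Latin-hypercube starts are drawn from a seeded generator on
    top of the deterministic heuristic and nested starts. The virtual-site
    options select the site kind, its (fixed) distance for the scan path, or
    free continuous optimization of the distance.
    """

    seed: int = 0
    n_starts: int = 16
    tol: float = 1e-12
    max_nfev: int | None = None
    vsite_kind: VsiteKind = VsiteKind.HALIDE_APEX
    vsite_distance: float = 0.9
    vsite_angle: float | None = None  # fixed angle for water site kinds; None = free
    vsite_free_distance: bool = False
    modulate_hydrogen: bool = False


@dataclass(frozen=True, eq=False)
class FitResult:
    """An optimized ModelSpec with its fit quality and diagnostics."""

    spec: ModelSpec
    rmse: float
    n_points: int
    baseline_rmse: float | None = None
    delta_reduction: float | None = None
    diagnostics: dict = field(default_factory=dict)
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValidationError("rmse must be >= 0")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def to_dict(self, include_residuals: bool = False) -> dict:
        d = {
            "spec": self.spec.to_dict(),
            "rmse": self.rmse,
            "n_points": self.n_points,
            "baseline_rmse": self.baseline_rmse,
            "delta_reduction": self.delta_reduction,
            "diagnostics": dict(self.diagnostics),
        }
        if include_residuals and self.residuals is not None:
            d["residuals"] = [float(v) for v in self.residuals]
        return d


@dataclass(frozen=True)
class _ParamDef:
    """One fit parameter: physical bounds, multistart sampling box, transform."""

    name: str
    lo: float
    hi: float
    s_lo: float
    s_hi: float
    log: bool = False  # bounds/sampling given in log10 space

    def physical(self, x_unit: float | np.ndarray):
        val = self.lo + np.asarray(x_unit) * (self.hi - self.lo)
        return 10.0**val if self.log else val

    def unit(self, value: float) -> float:
        v = math.log10(value) if self.log else value
        return min(1.0, max(0.0, (v - self.lo) / (self.hi - self.lo)))

    @property
    def unit_sample_box(self) -> tuple[float, float]:
        lo = (self.s_lo - self.lo) / (self.hi - self.lo)
        hi = (self.s_hi - self.lo) / (self.hi - self.lo)
        return lo, hi


def _amp_param(name: str) -> _ParamDef:
    return _ParamDef(name, _AMP_LO, _AMP_HI, 2.0, 7.0, log=True)


def _decay_param(name: str) -> _ParamDef:
    return _ParamDef(name, 0.1, 20.0, 1.0, 8.0)


def _c6_param(name: str) -> _ParamDef:
    return _ParamDef(name, _C6_LO, _C6_HI, 0.0, 4.0, log=True)


def _unpack(params: Sequence[_ParamDef], x_unit: np.ndarray) -> dict[str, float]:
    return {p.name: float(p.physical(x)) for p, x in zip(params, x_unit)}


@dataclass(frozen=True, eq=False)
class _Problem:
    params: tuple[_ParamDef, ...]
    model: callable  # dict -> (n,) energies
    to_spec: callable  # dict -> ModelSpec
    data: np.ndarray
    extra_starts: tuple[np.ndarray, ...] = ()


def _element_groups(molecule: MoleculeGeometry) -> list[tuple[str, list[int]]]:
    """Unique elements in atom order with their atom-column indices."""
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for j, el in enumerate(molecule.elements):
        if el not in groups:
            groups[el] = []
            order.append(el)
        groups[el].append(j)
    return [(el, groups[el]) for el in order]


def _multistart(problem: _Problem, options: FitOptions) -> tuple[dict, dict, np.ndarray]:
    """Run the multistart optimisation; returns (physical params, diagnostics, residuals)."""
    ndim = len(problem.params)
    data = problem.data

    def residual(x_unit: np.ndarray) -> np.ndarray:
        return problem.model(_unpack(problem.params, x_unit)) - data

    sampler = qmc.LatinHypercube(d=ndim, seed=options.seed)
    raw = sampler.random(options.n_starts)
    boxes = np.array([p.unit_sample_box for p in problem.params])  # (d, 2)
    lhs_starts = boxes[:, 0] + raw * (boxes[:, 1] - boxes[:, 0])
    starts = list(problem.extra_starts) + [s for s in lhs_starts]

    best = None
    winner = -1
    nfev_total = 0
    any_success = False
    for i, x0 in enumerate(starts):
        x0 = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
        res = least_squares(
            residual,
            x0,
            bounds=(np.zeros(ndim), np.ones(ndim)),
            method="trf",
            ftol=options.tol,
            xtol=options.tol,
            gtol=options.tol,
            max_nfev=options.max_nfev,
        )
        nfev_total += res.nfev
        any_success = any_success or bool(res.success)
        if best is None or res.cost < best.cost:
            best, winner = res, i
    phys = _unpack(problem.params, best.x)
    diagnostics = {
        "converged": any_success,
        "winner_start": winner,
        "n_starts": len(starts),
        "nfev": nfev_total,
        "status": int(best.status),
        "message": best.message,
    }
    return phys, diagnostics, best.fun


# -- problem builders --------------------------------------------------------


def _spherical_heuristic_start(
    params: Sequence[_ParamDef],
    design_fn,
    data: np.ndarray,
    component: Component,
    b0: float = 3.5,
) -> np.ndarray:
    """Unit-space start: decays at b0, amplitudes from a non-negative lstsq."""
    phys: dict[str, float] = {}
    for p in params:
        if p.name.startswith("b_"):
            phys[p.name] = b0
        elif p.name == "W" or p.name == "Q":
            phys[p.name] = 0.0
        elif p.name == "k":
            phys[p.name] = 1.0
        elif p.name == "theta_m":
            phys[p.name] = 90.0
        else:
            phys[p.name] = 1.0  # amplitudes, replaced below
    cols, amp_names = design_fn(phys)
    target = data if component is Component.EXCHANGE else -data
    mat = np.stack(cols, axis=1)
    if component is Component.DISPERSION:
        mat = -mat  # dispersion columns are negative
    try:
        sol, _ = nnls(mat, target)
    except Exception:  # pragma: no cover - nnls is robust, belt and braces
        sol = np.full(len(amp_names), 1.0)
    for name, a in zip(amp_names, sol):
        phys[name] = max(a, 1e-3)
    return np.array([p.unit(phys[p.name]) for p in params])


def _build_problem(
    surface: EnergySurface,
    family: Family,
    component: Component,
    molecule: MoleculeGeometry,
    options: FitOptions,
    nested_phys: dict[str, float] | None,
) -> _Problem:
    grid = surface.grid
    points = grid.positions
    r = _distances(points, molecule.positions)
    theta = grid.theta
    groups = _element_groups(molecule)
    heavy_el = molecule.atoms[0].element
    clamp = _clamp_for(molecule)
    fit_theta_m = molecule.kind is MoleculeKind.WATER
    theta_h = (
        _hydrogen_apex_theta(molecule, points)
        if options.modulate_hydrogen and molecule.kind is MoleculeKind.HYDROGEN_HALIDE
        else None
    )
    data = surface.component(component)

    params: list[_ParamDef] = []
    if component is Component.EXCHANGE:
        for el, _ in groups:
            params.append(_amp_param(f"A_{el}"))
            params.append(_decay_param(f"b_{el}"))
    else:
        for el, _ in groups:
            params.append(_c6_param(f"C6_{el}"))

    amp_name = "W" if component is Component.EXCHANGE else "Q"
    if family is Family.COS:
        params.append(_ParamDef(amp_name, -1.0, 1.0, -0.8, 0.8))
        params.append(_ParamDef("k", 1e-2, 2.0, 0.3, 2.0))
        if fit_theta_m:
            params.append(_ParamDef("theta_m", 0.0, 180.0, 10.0, 170.0))
    elif family is Family.VSITE:
        if component is not Component.EXCHANGE:
            raise ValidationError("vsite family is defined for exchange only")
        params.append(_amp_param("A_vs"))
        params.append(_decay_param("b_vs"))
        if options.vsite_free_distance:
            params.append(_ParamDef("d_vs", 0.01, 1.5, 0.2, 1.4))
        if options.vsite_kind is not VsiteKind.HALIDE_APEX and options.vsite_angle is None:
            params.append(_ParamDef("angle_vs", 0.0, 180.0, 20.0, 160.0))

    if not np.all(np.isfinite(theta)) and family is Family.COS:
        raise ValidationError("surface contains undefined-angle points; drop them before fitting")

    modulate_h = options.modulate_hydrogen and component is Component.EXCHANGE

    def base_columns(phys: dict) -> tuple[list[np.ndarray], list[str]]:
        """Per-element energy columns (amplitude factored out) and amp names."""
        cols, names = [], []
        for el, idx in groups:
            if component is Component.EXCHANGE:
                col = np.exp(-phys[f"b_{el}"] * r[:, idx]).sum(axis=1)
                names.append(f"A_{el}")
            else:
                col = -(r[:, idx] ** -6.0).sum(axis=1)
                names.append(f"C6_{el}")
            cols.append(col)
        return cols, names

    def model(phys: dict) -> np.ndarray:
        total = np.zeros(len(points))
        for el, idx in groups:
            if component is Component.EXCHANGE:
                amp, b = phys[f"A_{el}"], phys[f"b_{el}"]
                terms = amp * np.exp(-b * r[:, idx])
            else:
                amp = phys[f"C6_{el}"]
                terms = -amp * r[:, idx] ** -6.0
            if family is Family.COS:
                theta_m = phys.get("theta_m", 0.0)
                if el == heavy_el:
                    factor = cosine_factor(theta, phys[amp_name], phys["k"], theta_m, clamp)
                    terms = terms * factor[:, None]
                elif el == "H" and modulate_h and theta_h is not None:
                    factor = cosine_factor(theta_h, phys[amp_name], phys["k"], 0.0, Clamp.HALIDE_90)
                    terms = terms * factor[:, None]
            total += terms.sum(axis=1)
        if family is Family.VSITE:
            d_vs = phys.get("d_vs", options.vsite_distance)
            angle = phys.get("angle_vs", options.vsite_angle)
            from .geometry import place_virtual_sites

            sites = place_virtual_sites(molecule, [(options.vsite_kind, d_vs, angle)])
            sign = VSITE_SIGN[options.vsite_kind]
            for pos in sites:
                r_s = np.linalg.norm(points - pos, axis=1)
                total = total + sign * phys["A_vs"] * np.exp(-phys["b_vs"] * r_s)
        return total

    def to_spec(phys: dict) -> ModelSpec:
        elements = {}
        for el, _ in groups:
            if component is Component.EXCHANGE:
                elements[el] = ElementParams(A=phys[f"A_{el}"], b=phys[f"b_{el}"])
            else:
                elements[el] = ElementParams(C6=phys[f"C6_{el}"])
        spherical = SphericalParams(elements)
        angular = None
        vsites = None
        if family is Family.COS:
            angular = AngularParams(
                W=phys.get("W", 0.0),
                Q=phys.get("Q", 0.0),
                k=phys["k"],
                theta_m=phys.get("theta_m", 0.0),
            )
        if family is Family.VSITE:
            vsites = (
                (
                    options.vsite_kind,
                    VsiteParams(
                        A_vs=phys["A_vs"],
                        b_vs=phys["b_vs"],
                        d=phys.get("d_vs", options.vsite_distance),
                        angle=phys.get("angle_vs", options.vsite_angle),
                    ),
                ),
            )
        modulated = frozenset({"heavy", "H"}) if modulate_h else frozenset({"heavy"})
        return ModelSpec(
            family=family,
            component=component,
            spherical=spherical,
            angular=angular,
            vsites=vsites,
            modulated_atoms=modulated,
        )

    extra = [_spherical_heuristic_start(params, base_columns, data, component)]
    if nested_phys is not None and family is not Family.SPHERICAL:
        nested = dict(nested_phys)
        nested.setdefault(amp_name, 0.0)
        nested.setdefault("k", 1.0)
        nested.setdefault("theta_m", 90.0)
        nested.setdefault("A_vs", 10.0**_AMP_LO)
        nested.setdefault("b_vs", 4.0)
        nested.setdefault("d_vs", options.vsite_distance)
        nested.setdefault("angle_vs", 90.0)
        extra.append(np.array([p.unit(nested[p.name]) for p in params]))

    return _Problem(
        params=tuple(params),
        model=model,
        to_spec=to_spec,
        data=data,
        extra_starts=tuple(extra),
    )


def _resolve(surface: EnergySurface, molecule: MoleculeGeometry | None) -> MoleculeGeometry:
    molecule = molecule or surface.molecule
    if molecule is None:
        raise ValidationError("no molecule given and the surface carries none")
    return molecule


def fit_model(
    surface: EnergySurface,
    family: Family | str,
    component: Component | str,
    molecule: MoleculeGeometry | None = None,
    convention: AngleConvention | str | None = None,
    options: FitOptions | None = None,
    baseline: FitResult | None = None,
) -> FitResult:
    """Fit one model family to one component of a filtered surface.

    ``convention`` defaults to the grid's stored convention (the grid angles
    are used directly). For the anisotropic families a spherical baseline is
    fitted first (or taken from ``baseline``) and reported through
    ``baseline_rmse`` / ``delta_reduction``; its optimum also seeds a nested
    start with the anisotropy switched off.
    """
    family = Family(family)
    component = Component(component)
    options = options or FitOptions()
    molecule = _resolve(surface, molecule)
    if not surface.grid.filtered:
        raise ValidationError("surface must be vdW-filtered before fitting")
    if convention is not None and AngleConvention(convention) is not surface.grid.convention:
        raise ValidationError(
            f"requested convention {convention!r} does not match the grid's "
            f"{surface.grid.convention.value}; rebuild the grid"
        )

    nested_phys = None
    if family is not Family.SPHERICAL:
        if baseline is None:
            baseline = fit_model(surface, Family.SPHERICAL, component, molecule, None, options)
        nested_phys = _phys_from_spec(baseline.spec, component)

    problem = _build_problem(surface, family, component, molecule, options, nested_phys)
    if len(surface) < len(problem.params):
        raise ValidationError(
            f"underdetermined fit: {len(surface)} points for {len(problem.params)} parameters"
        )
    phys, diagnostics, residuals = _multistart(problem, options)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    base_rmse = baseline.rmse if baseline is not None else None
    return FitResult(
        spec=problem.to_spec(phys),
        rmse=rmse,
        n_points=len(surface),
        baseline_rmse=base_rmse,
        delta_reduction=delta_reduction(rmse, base_rmse) if base_rmse else None,
        diagnostics=diagnostics,
        residuals=residuals,
    )


def _phys_from_spec(spec: ModelSpec, component: Component) -> dict[str, float]:
    phys: dict[str, float] = {}
    for el, p in spec.spherical.elements.items():
        if component is Component.EXCHANGE:
            phys[f"A_{el}"] = max(p.A, 10.0**_AMP_LO)
            phys[f"b_{el}"] = p.b
        else:
            phys[f"C6_{el}"] = max(p.C6, 10.0**_C6_LO)
    return phys


def fit_families(
    surface: EnergySurface,
    families: Sequence[Family | str],
    component: Component | str,
    molecule: MoleculeGeometry | None = None,
    options: FitOptions | None = None,
) -> dict[str, FitResult]:
    """Fit several families to the same surface, sharing the spherical baseline."""
    families = [Family(f) for f in families]
    if Family.SPHERICAL not in families:
        families = [Family.SPHERICAL] + families
    results: dict[str, FitResult] = {}
    base = fit_model(surface, Family.SPHERICAL, component, molecule, None, options)
    results[Family.SPHERICAL.value] = base
    for fam in families:
        if fam is Family.SPHERICAL:
            continue
        results[fam.value] = fit_model(
            surface, fam, component, molecule, None, options, baseline=base
        )
    return results


# -- virtual-site distance scan ---------------------------------------------


@dataclass(frozen=True, eq=False)
class VsiteScan:
    """RMSE profile of fixed-distance virtual-site fits plus the best fit."""

    distances: np.ndarray
    results: tuple[FitResult, ...]
    best: FitResult
    best_distance: float
    baseline: FitResult

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d": self.distances, "rmse": [r.rmse for r in self.results]}
        )


def scan_vsite_distance(
    surface: EnergySurface,
    molecule: MoleculeGeometry | None = None,
    component: Component | str = Component.EXCHANGE,
    d_grid: Sequence[float] | None = None,
    options: FitOptions | None = None,
) -> VsiteScan:
    """Fit the vsite family at each fixed site distance and report the profile.

    The default grid is 0.1-1.5 A in 0.05 A steps. The full profile is
    returned so flat optima remain visible; ``best`` is the argmin-RMSE fit.
    """
    options = options or FitOptions()
    molecule = _resolve(surface, molecule)
    component = Component(component)
    if d_grid is None:
        d_grid = np.round(np.arange(0.1, 1.5 + 1e-9, 0.05), 10)
    d_grid = np.asarray([float(d) for d in d_grid])
    if d_grid.size == 0 or np.any(d_grid <= 0):
        raise ValidationError("d_grid must be non-empty with all distances > 0")

    baseline = fit_model(surface, Family.SPHERICAL, component, molecule, None, options)
    results = []
    for d in d_grid:
        opt_d = replace(options, vsite_distance=float(d), vsite_free_distance=False)
        results.append(
            fit_model(surface, Family.VSITE, component, molecule, None, opt_d, baseline=baseline)
        )
    best_idx = int(np.argmin([r.rmse for r in results]))
    return VsiteScan(
        distances=d_grid,
        results=tuple(results),
        best=results[best_idx],
        best_distance=float(d_grid[best_idx]),
        baseline=baseline,
    )


# -- combined water fit ------------------------------------------------------

_WATER_MODES = ("none", "LP", "SH", "both")


def fit_water_combined(
    frontal: EnergySurface,
    sagittal: EnergySurface,
    vsite_mode: str = "none",
    molecule: MoleculeGeometry | None = None,
    options: FitOptions | None = None,
    baseline: FitResult | None = None,
) -> FitResult:
    """Fit one exchange model to the concatenated frontal + sagittal surfaces.

    The spherical O/H parameters are shared across the two planes. Depending
    on ``vsite_mode`` a mirror-symmetric lone-pair pair (repulsive, in the
    sagittal plane), a sigma-hole pair (attractive, in the molecular plane),
    or both are added; each pair's amplitude, decay, distance d in (0, 1.5] A
    and angle from the bisector are free parameters. Residuals (frontal block
    first) are exposed for residual plots.
    """
    if vsite_mode not in _WATER_MODES:
        raise ValidationError(f"vsite_mode must be one of {_WATER_MODES}, got {vsite_mode!r}")
    options = options or FitOptions()
    molecule = molecule or frontal.molecule or sagittal.molecule
    if molecule is None:
        raise ValidationError("no molecule given and neither surface carries one")
    if molecule.kind is not MoleculeKind.WATER:
        raise ValidationError("fit_water_combined requires a water geometry")
    for s in (frontal, sagittal):
        if not s.grid.filtered:
            raise ValidationError("both surfaces must be vdW-filtered before fitting")

    points = np.vstack([frontal.grid.positions, sagittal.grid.positions])
    data = np.concatenate([frontal.exchange, sagittal.exchange])
    r = _distances(points, molecule.positions)
    groups = _element_groups(molecule)

    site_kinds: list[tuple[str, VsiteKind]] = []
    if vsite_mode in ("LP", "both"):
        site_kinds.append(("lp", VsiteKind.WATER_LONE_PAIR))
    if vsite_mode in ("SH", "both"):
        site_kinds.append(("sh", VsiteKind.WATER_SIGMA_HOLE))

    params: list[_ParamDef] = []
    for el, _ in groups:
        params.append(_amp_param(f"A_{el}"))
        params.append(_decay_param(f"b_{el}"))
    for tag, _kind in site_kinds:
        params.append(_amp_param(f"A_{tag}"))
        params.append(_decay_param(f"b_{tag}"))
        params.append(_ParamDef(f"d_{tag}", 0.01, 1.5, 0.2, 1.4))
        params.append(_ParamDef(f"angle_{tag}", 0.0, 180.0, 20.0, 160.0))

    from .geometry import place_virtual_sites

    def model(phys: dict) -> np.ndarray:
        total = np.zeros(len(points))
        for el, idx in groups:
            total += (phys[f"A_{el}"] * np.exp(-phys[f"b_{el}"] * r[:, idx])).sum(axis=1)
        for tag, kind in site_kinds:
            sites = place_virtual_sites(molecule, [(kind, phys[f"d_{tag}"], phys[f"angle_{tag}"])])
            sign = VSITE_SIGN[kind]
            for pos in sites:
                r_s = np.linalg.norm(points - pos, axis=1)
                total = total + sign * phys[f"A_{tag}"] * np.exp(-phys[f"b_{tag}"] * r_s)
        return total

    def base_columns(phys: dict) -> tuple[list[np.ndarray], list[str]]:
        cols, names = [], []
        for el, idx in groups:
            cols.append(np.exp(-phys[f"b_{el}"] * r[:, idx]).sum(axis=1))
            names.append(f"A_{el}")
        return cols, names

    def to_spec(phys: dict) -> ModelSpec:
        elements = {
            el: ElementParams(A=phys[f"A_{el}"], b=phys[f"b_{el}"]) for el, _ in groups
        }
        vsites = tuple(
            (
                kind,
                VsiteParams(
                    A_vs=phys[f"A_{tag}"],
                    b_vs=phys[f"b_{tag}"],
                    d=phys[f"d_{tag}"],
                    angle=phys[f"angle_{tag}"],
                ),
            )
            for tag, kind in site_kinds
        )
        if vsites:
            return ModelSpec(
                family=Family.VSITE,
                component=Component.EXCHANGE,
                spherical=SphericalParams(elements),
                vsites=vsites,
            )
        return ModelSpec(
            family=Family.SPHERICAL,
            component=Component.EXCHANGE,
            spherical=SphericalParams(elements),
        )

    if vsite_mode != "none" and baseline is None:
        baseline = fit_water_combined(frontal, sagittal, "none", molecule, options)

    extra = [
        _spherical_heuristic_start(
            params,
            base_columns,
            data,
            Component.EXCHANGE,
        )
    ]
    if baseline is not None and vsite_mode != "none":
        nested = _phys_from_spec(baseline.spec, Component.EXCHANGE)
        for tag, kind in site_kinds:
            nested[f"A_{tag}"] = 10.0**_AMP_LO
            nested[f"b_{tag}"] = 4.0
            nested[f"d_{tag}"] = 0.5
            # physically motivated angle starts: lone pairs near the normal,
            # sigma-holes near the O-H bond extensions
            nested[f"angle_{tag}"] = 90.0 if kind is VsiteKind.WATER_LONE_PAIR else 65.0
        extra.append(np.array([p.unit(nested[p.name]) for p in params]))

    problem = _Problem(
        params=tuple(params),
        model=model,
        to_spec=to_spec,
        data=data,
        extra_starts=tuple(extra),
    )
    if len(data) < len(params):
        raise ValidationError(
            f"underdetermined fit: {len(data)} points for {len(params)} parameters"
        )
    phys, diagnostics, residuals = _multistart(problem, options)
    diagnostics.update(
        {"vsite_mode": vsite_mode, "n_frontal": len(frontal), "n_sagittal": len(sagittal)}
    )
    rmse = float(np.sqrt(np.mean(residuals**2)))
    base_rmse = baseline.rmse if baseline is not None else None
    return FitResult(
        spec=to_spec(phys),
        rmse=rmse,
        n_points=len(data),
        baseline_rmse=base_rmse,
        delta_reduction=delta_reduction(rmse, base_rmse) if base_rmse else None,
        diagnostics=diagnostics,
        residuals=residuals,
    )


# -- summary table -----------------------------------------------------------

SUMMARY_COLUMNS = ("compound", "W (%)", "delta Cos (%)", "delta Vsite (%)")


def anisotropy_summary(fits: Mapping[str, Mapping[str, FitResult]]) -> pd.DataFrame:
    """Per-compound anisotropy table: W and the RMSE reductions of the two
    anisotropic exchange models relative to the spherical fit on the same
    filtered surface.

    ``fits`` maps compound -> {"spherical": ..., "cos": ..., "vsite": ...}.
    """
    rows = []
    for compound, per_family in fits.items():
        missing = {"spherical", "cos", "vsite"} - set(per_family)
        if missing:
            raise ValidationError(f"{compound}: missing family fits {sorted(missing)}")
        sph = per_family["spherical"]
        cos = per_family["cos"]
        vsite = per_family["vsite"]
        rows.append(
            {
                "compound": compound,
                "W (%)": 100.0 * cos.spec.angular.W,
                "delta Cos (%)": delta_reduction(cos.rmse, sph.rmse),
                "delta Vsite (%)": delta_reduction(vsite.rmse, sph.rmse),
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
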