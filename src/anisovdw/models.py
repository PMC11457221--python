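"""Anisotropic Buckingham model families for exchange and dispersion.

Three families are provided, all in kJ/mol with distances in A:

spherical
    exchange  E_x(p) = sum_a A_a * exp(-b_a * r_ap)
    dispersion E_d(p) = -sum_a C6_a / r_ap^6

cos (cosine-modulated)
    the heavy-atom term is multiplied by 1 - W * cos^k(theta - theta_m) for
    exchange (Q for dispersion), with theta the convention angle of the probe.
    For hydrogen halides theta_m = 0 and the angle is clamped at 90 deg (the
    factor is constant beyond 90 deg, where there is no sigma-hole); for water
    the modulation is active only in the window |theta - theta_m| <= 90 deg.
    Both clamps keep cos >= 0 wherever the modulation acts, so cos^k is
    well-defined for non-integer k; k is restricted to (0, 2] to avoid
    spurious periodicity. A positive amplitude *reduces* the interaction at
    the extremum (a sigma-hole); a negative amplitude enhances it (a lone
    pair).

vsite (virtual-site corrected, exchange only)
    spherical exchange plus per-site exponential terms sign * A_vs *
    exp(-b_vs * r_sp) at sites placed by
    :func:`anisovdw.geometry.place_virtual_sites`. Apex and sigma-hole sites
    are attractive (they dampen exchange that a spherical atom overestimates
    at the sigma-hole); lone-pair sites are repulsive (lone pairs locally
    enhance exchange).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import cosdg

from .errors import DomainError, ValidationError
from .geometry import (
    AngleConvention,
    MoleculeGeometry,
    MoleculeKind,
    ProbeGrid,
    VsiteKind,
    place_virtual_sites,
)

__all__ = [
    "AngularParams",
    "Clamp",
    "Component",
    "ElementParams",
    "Family",
    "ModelSpec",
    "PlacedVsite",
    "SphericalParams",
    "VsiteParams",
    "cosine_factor",
    "dispersion_cos",
    "dispersion_spherical",
    "evaluate_model",
    "exchange_cos",
    "exchange_spherical",
    "vsite_exchange_correction",
]

SCHEMA_VERSION = 1
_R_TOL = 1e-12


class Family(str, enum.Enum):
    SPHERICAL = "spherical"
    COS = "cos"
    VSITE = "vsite"


class Component(str, enum.Enum):
    EXCHANGE = "exchange"
    DISPERSION = "dispersion"


class Clamp(str, enum.Enum):
    HALIDE_90 = "halide_90"
    WATER_WINDOW = "water_window"


@dataclass(frozen=True)
class ElementParams:
    """Per-element Buckingham parameters: A (kJ/mol), b (1/A), C6 (kJ A^6/mol)."""

    A: float = 0.0
    b: float = 1.0
    C6: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValidationError(f"A must be >= 0, got {self.A}")
        if not (self.b > 0):
            raise ValidationError(f"b must be > 0, got {self.b}")
        if self.C6 < 0:
            raise ValidationError(f"C6 must be >= 0, got {self.C6}")


@dataclass(frozen=True)
class SphericalParams:
    """Per-element parameter table for the spherical Buckingham model."""

    elements: Mapping[str, ElementParams]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", dict(self.elements))

    def get(self, element: str) -> ElementParams:
        try:
            return self.elements[element]
        except KeyError:
            raise ValidationError(f"no parameters for element {element!r}") from None


@dataclass(frozen=True)
class AngularParams:
    """Cosine-modulation parameters.

    W scales the exchange modulation and Q the dispersion modulation (both
    unitless, in [-1, 1]; positive = reduction at the extremum). k in (0, 2]
    shapes the cosine; theta_m (degrees) displaces the extremum and is 0 for
    hydrogen halides.
    """

    W: float = 0.0
    Q: float = 0.0
    k: float = 2.0
    theta_m: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.W) > 1 or abs(self.Q) > 1:
            raise ValidationError(f"|W| and |Q| must be <= 1, got W={self.W}, Q={self.Q}")
        if not (0.0 < self.k <= 2.0):
            raise ValidationError(
                f"k must be in (0, 2] to avoid spurious periodicity, got {self.k}"
            )
        if not (0.0 <= self.theta_m <= 180.0):
            raise ValidationError(f"theta_m must be in [0, 180] degrees, got {self.theta_m}")


@dataclass(frozen=True)
class VsiteParams:
    """Virtual-site exponential term: A_vs (kJ/mol), b_vs (1/A), d (A), angle (deg)."""

    A_vs: float
    b_vs: float
    d: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.A_vs < 0:
            raise ValidationError(f"A_vs must be >= 0, got {self.A_vs}")
        if not (self.b_vs > 0):
            raise ValidationError(f"b_vs must be > 0, got {self.b_vs}")
        if not (self.d > 0):
            raise ValidationError(f"d must be > 0, got {self.d}")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise ValidationError(f"angle must be in [0, 180] degrees, got {self.angle}")


#: Sign of the exponential site term by site kind: apex/sigma-hole sites dampen
#: exchange (attractive), lone-pair sites enhance it (repulsive).
VSITE_SIGN: dict[VsiteKind, float] = {
    VsiteKind.HALIDE_APEX: -1.0,
    VsiteKind.WATER_SIGMA_HOLE: -1.0,
    VsiteKind.WATER_LONE_PAIR: +1.0,
}


@dataclass(frozen=True, eq=False)
class PlacedVsite:
    kind: VsiteKind
    position: np.ndarray
    params: VsiteParams


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified model: family, energy component and parameters."""

    family: Family
    component: Component
    spherical: SphericalParams
    angular: AngularParams | None = None
    vsites: tuple[tuple[VsiteKind, VsiteParams], ...] | None = None
    modulated_atoms: frozenset[str] = frozenset({"heavy"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "component", Component(self.component))
        if self.vsites is not None:
            object.__setattr__(
                self,
                "vsites",
                tuple((VsiteKind(k), p) for k, p in self.vsites),
            )
        object.__setattr__(self, "modulated_atoms", frozenset(self.modulated_atoms))
        if self.family is Family.COS and self.angular is None:
            raise ValidationError("cos family requires angular parameters")
        if self.family is Family.VSITE:
            if not self.vsites:
                raise ValidationError("vsite family requires at least one virtual site")
            if self.component is Component.DISPERSION:
                raise ValidationError("vsite family is defined for exchange only")

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": SCHEMA_VERSION,
            "family": self.family.value,
            "component": self.component.value,
            "spherical": {
                el: {"A": p.A, "b": p.b, "C6": p.C6} for el, p in self.spherical.elements.items()
            },
            "modulated_atoms": sorted(self.modulated_atoms),
        }
        if self.angular is not None:
            d["angular"] = {
                "W": self.angular.W,
                "Q": self.angular.Q,
                "k": self.angular.k,
                "theta_m": self.angular.theta_m,
            }
        if self.vsites is not None:
            d["vsites"] = [
                {
                    "kind": kind.value,
                    "A_vs": p.A_vs,
                    "b_vs": p.b_vs,
                    "d": p.d,
                    "angle": p.angle,
                }
                for kind, p in self.vsites
            ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unsupported ModelSpec schema_version {version!r}")
        angular = None
        if "angular" in d:
            angular = AngularParams(**d["angular"])
        vsites = None
        if "vsites" in d:
            vsites = tuple(
                (
                    VsiteKind(v["kind"]),
                    VsiteParams(A_vs=v["A_vs"], b_vs=v["b_vs"], d=v["d"], angle=v["angle"]),
                )
                for v in d["vsites"]
            )
        return cls(
            family=Family(d["family"]),
            component=Component(d["component"]),
            spherical=SphericalParams(
                {el: ElementParams(**p) for el, p in d["spherical"].items()}
            ),
            angular=angular,
            vsites=vsites,
            modulated_atoms=frozenset(d.get("modulated_atoms", {"heavy"})),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# evaluation primitives (vectorised; scalar API wraps them)
# ---------------------------------------------------------------------------


def _distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, m) distance matrix; raises DomainError on coincident pairs."""
    d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    if np.any(d < _R_TOL):
        raise DomainError("probe point coincides with an interaction center (r = 0)")
    return d


def _exchange_terms(params: SphericalParams, molecule: MoleculeGeometry, r: np.ndarray) -> np.ndarray:
    """(n, n_atoms) array of per-atom exchange terms A * exp(-b r)."""
    cols = []
    for j, atom in enumerate(molecule.atoms):
        p = params.get(atom.element)
        cols.append(p.A * np.exp(-p.b * r[:, j]))
    return np.stack(cols, axis=1)


def _dispersion_terms(params: SphericalParams, molecule: MoleculeGeometry, r: np.ndarray) -> np.ndarray:
    cols = []
    for j, atom in enumerate(molecule.atoms):
        p = params.get(atom.element)
        cols.append(-p.C6 / r[:, j] ** 6)
    return np.stack(cols, axis=1)


def cosine_factor(
    theta,
    amplitude: float,
    k: float,
    theta_m: float = 0.0,
    clamp: Clamp | str = Clamp.HALIDE_90,
):
    """Angular modulation factor 1 - amplitude * cos^k(theta_eff - theta_m).

    ``halide_90`` clamps theta at 90 deg (constant factor where there is no
    sigma-hole); ``water_window`` deactivates the modulation outside
    |theta - theta_m| <= 90 deg. Accepts scalars or arrays; returns the same.
    """
    clamp = Clamp(clamp)
    if not (0.0 < k <= 2.0):
        raise ValidationError(f"k must be in (0, 2] to avoid spurious periodicity, got {k}")
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < -1e-9) or np.any(theta_arr > 180.0 + 1e-9):
        raise ValidationError("theta must be in [0, 180] degrees")
    # cosdg is exact at the quadrant boundaries, so the factor is exactly 1
    # wherever the clamp makes the modulation vanish
    if clamp is Clamp.HALIDE_90:
        theta_eff = np.minimum(theta_arr, 90.0)
        c = cosdg(theta_eff - theta_m)
        mod = np.clip(c, 0.0, None) ** k
    else:
        dt = theta_arr - theta_m
        active = np.abs(dt) <= 90.0
        c = np.clip(cosdg(dt), 0.0, None)
        mod = np.where(active, c**k, 0.0)
    out = 1.0 - amplitude * mod
    return out if out.ndim else float(out)


def _clamp_for(molecule: MoleculeGeometry) -> Clamp:
    return Clamp.HALIDE_90 if molecule.kind is MoleculeKind.HYDROGEN_HALIDE else Clamp.WATER_WINDOW


def _hydrogen_apex_theta(molecule: MoleculeGeometry, points: np.ndarray) -> np.ndarray:
    """Angle at the halide hydrogen measured from the H apex (extension of X->H)."""
    x_pos = molecule.heavy_atom.position
    h_pos = molecule.atoms[1].position
    axis = (h_pos - x_pos) / np.linalg.norm(h_pos - x_pos)
    d = points - h_pos
    r = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (d @ axis) / r
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _modulation_matrix(
    spec_angular: AngularParams,
    amplitude: float,
    molecule: MoleculeGeometry,
    points: np.ndarray,
    theta: np.ndarray,
    modulated_atoms: frozenset[str],
) -> np.ndarray:
    """(n, n_atoms) multiplicative factors for the cos family."""
    n = len(points)
    clamp = _clamp_for(molecule)
    factors = np.ones((n, len(molecule.atoms)))
    if "heavy" in modulated_atoms:
        factors[:, 0] = cosine_factor(theta, amplitude, spec_angular.k, spec_angular.theta_m, clamp)
    if "H" in modulated_atoms:
        if molecule.kind is not MoleculeKind.HYDROGEN_HALIDE:
            raise ValidationError("hydrogen-term modulation is supported for hydrogen halides only")
        theta_h = _hydrogen_apex_theta(molecule, points)
        factors[:, 1] = cosine_factor(theta_h, amplitude, spec_angular.k, 0.0, Clamp.HALIDE_90)
    return factors


# ---------------------------------------------------------------------------
# public scalar operations
# ---------------------------------------------------------------------------


def _point_r(molecule: MoleculeGeometry, point) -> np.ndarray:
    return _distances(np.asarray(point, dtype=float)[None, :], molecule.positions)


def exchange_spherical(params: SphericalParams, molecule: MoleculeGeometry, point) -> float:
    """Spherical Buckingham exchange sum_a A_a exp(-b_a r) at one point (kJ/mol)."""
    r = _point_r(molecule, point)
    return float(_exchange_terms(params, molecule, r).sum())


def dispersion_spherical(params: SphericalParams, molecule: MoleculeGeometry, point) -> float:
    """Spherical dispersion -sum_a C6_a / r^6 at one point (kJ/mol)."""
    r = _point_r(molecule, point)
    return float(_dispersion_terms(params, molecule, r).sum())


def exchange_cos(
    params: SphericalParams,
    angular: AngularParams,
    molecule: MoleculeGeometry,
    point,
    convention: AngleConvention | str,
    modulated_atoms: frozenset[str] = frozenset({"heavy"}),
) -> float:
    """Cosine-modulated exchange at one point (heavy-atom term scaled by W)."""
    from .geometry import probe_angle

    point = np.asarray(point, dtype=float)
    theta = probe_angle(molecule, point, convention)
    r = _point_r(molecule, point)
    terms = _exchange_terms(params, molecule, r)
    factors = _modulation_matrix(
        angular, angular.W, molecule, point[None, :], np.array([theta]), frozenset(modulated_atoms)
    )
    return float((terms * factors).sum())


def dispersion_cos(
    params: SphericalParams,
    angular: AngularParams,
    molecule: MoleculeGeometry,
    point,
    convention: AngleConvention | str,
    modulated_atoms: frozenset[str] = frozenset({"heavy"}),
) -> float:
    """Cosine-modulated dispersion at one point (heavy-atom C6 scaled by Q)."""
    from .geometry import probe_angle

    point = np.asarray(point, dtype=float)
    theta = probe_angle(molecule, point, convention)
    r = _point_r(molecule, point)
    terms = _dispersion_terms(params, molecule, r)
    factors = _modulation_matrix(
        angular, angular.Q, molecule, point[None, :], np.array([theta]), frozenset(modulated_atoms)
    )
    return float((terms * factors).sum())


def vsite_exchange_correction(sites: Sequence[PlacedVsite], point) -> float:
    """Sum of per-site exponential corrections at one point (kJ/mol).

    Apex and sigma-hole sites contribute -A_vs * exp(-b_vs r) (non-positive,
    the correction only dampens); lone-pair sites contribute with a plus sign.
    """
    point = np.asarray(point, dtype=float)
    total = 0.0
    for s in sites:
        r = float(np.linalg.norm(point - s.position))
        if r < _R_TOL:
            raise DomainError("probe point coincides with a virtual site (r = 0)")
        total += VSITE_SIGN[s.kind] * s.params.A_vs * np.exp(-s.params.b_vs * r)
    return float(total)


def place_spec_vsites(spec: ModelSpec, molecule: MoleculeGeometry) -> list[PlacedVsite]:
    """Resolve the virtual sites of a ModelSpec to placed positions."""
    placed: list[PlacedVsite] = []
    for kind, p in spec.vsites or ():
        positions = place_virtual_sites(molecule, [(kind, p.d, p.angle)])
        placed.extend(PlacedVsite(kind, pos, p) for pos in positions)
    return placed


def evaluate_model(spec: ModelSpec, molecule: MoleculeGeometry, grid: ProbeGrid) -> np.ndarray:
    """Vectorised model energies aligned with ``grid`` points (kJ/mol)."""
    points = grid.positions
    r = _distances(points, molecule.positions)
    if spec.component is Component.EXCHANGE:
        terms = _exchange_terms(spec.spherical, molecule, r)
    else:
        terms = _dispersion_terms(spec.spherical, molecule, r)

    if spec.family is Family.SPHERICAL:
        return terms.sum(axis=1)

    if spec.family is Family.COS:
        theta = grid.theta
        if not np.all(np.isfinite(theta)):
            raise ValidationError(
                "cos-family evaluation needs a defined angle at every grid point; "
                "drop undefined-angle points first"
            )
        amp = spec.angular.W if spec.component is Component.EXCHANGE else spec.angular.Q
        factors = _modulation_matrix(
            spec.angular, amp, molecule, points, theta, spec.modulated_atoms
        )
        return (terms * factors).sum(axis=1)

    # vsite family: spherical exchange + site corrections
    energies = terms.sum(axis=1)
    for s in place_spec_vsites(spec, molecule):
        r_s = np.linalg.norm(points - s.position, axis=1)
        if np.any(r_s < _R_TOL):
            raise DomainError("probe point coincides with a virtual site (r = 0)")
        energies = energies + VSITE_SIGN[s.kind] * s.params.A_vs * np.exp(-s.params.b_vs * r_s)
    return energies
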