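"""Molecule geometries, probe grids, angular scans and virtual-site placement.

The probe-scan setup mirrors the standard protocol for quantifying exchange /
dispersion anisotropy with a noble-gas probe: a hydrogen halide is placed on
the y axis with the halogen at the grid anchor and the hydrogen above it, so
the sigma-hole axis (the extension of the H->X bond beyond the halogen) points
along -y.  Water sits at the centre of its grid with the H-O-H bisector
pointing along +y *away* from the hydrogens and the molecular plane normal
along +z; the "frontal" plane is the molecular (x-y) plane and the "sagittal"
plane is spanned by the bisector and the plane normal (y-z), reflecting the
two hydrogens onto each other.

Angle conventions (degrees, in [0, 180]):

``halide_apex``
    angle between the sigma-hole axis and the halogen->probe vector; 0 deg is
    the sigma-hole apex on the extension of the H-X bond.
``water_frontal``
    angle between the outward bisector and the in-plane component of the
    oxygen->probe vector.
``water_sagittal``
    angle between the outward bisector and the sagittal-plane component of the
    oxygen->probe vector; 90 deg is along the plane normal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from . import constants
from .errors import UndefinedAngleError, ValidationError

__all__ = [
    "AngleConvention",
    "AtomSite",
    "MoleculeGeometry",
    "MoleculeKind",
    "Plane",
    "ProbeGrid",
    "ProbePoint",
    "VsiteKind",
    "build_hydrogen_halide",
    "build_water",
    "filter_probe_grid_by_vdw",
    "make_angular_scan",
    "make_probe_grid",
    "place_virtual_sites",
    "probe_angle",
    "write_xyz",
]

_HALIDES = ("F", "Cl", "Br", "I")
_PROJECTION_TOL = 1e-12


class MoleculeKind(str, enum.Enum):
    HYDROGEN_HALIDE = "hydrogen_halide"
    WATER = "water"


class Plane(str, enum.Enum):
    HALIDE_2D = "halide_2d"
    WATER_FRONTAL = "water_frontal"
    WATER_SAGITTAL = "water_sagittal"
    WATER_3D = "water_3d"
    ANGULAR_SCAN = "angular_scan"


class AngleConvention(str, enum.Enum):
    HALIDE_APEX = "halide_apex"
    WATER_FRONTAL = "water_frontal"
    WATER_SAGITTAL = "water_sagittal"


class VsiteKind(str, enum.Enum):
    HALIDE_APEX = "halide_apex"
    WATER_SIGMA_HOLE = "water_sigma_hole"
    WATER_LONE_PAIR = "water_lone_pair"


#: Default angle convention used when building a grid of each plane type.
DEFAULT_CONVENTION: dict[Plane, AngleConvention] = {
    Plane.HALIDE_2D: AngleConvention.HALIDE_APEX,
    Plane.WATER_FRONTAL: AngleConvention.WATER_FRONTAL,
    Plane.WATER_SAGITTAL: AngleConvention.WATER_SAGITTAL,
    Plane.WATER_3D: AngleConvention.WATER_SAGITTAL,
}


def _as_unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < _PROJECTION_TOL:
        raise ValidationError("zero-length vector cannot be normalised")
    return v / n


@dataclass(frozen=True, eq=False)
class AtomSite:
    """A single atom: element symbol, Cartesian position (A), vdW radius (A)."""

    element: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not (self.vdw_radius > 0):
            raise ValidationError(f"vdw_radius must be > 0, got {self.vdw_radius}")


@dataclass(frozen=True, eq=False)
class MoleculeGeometry:
    """A probe-scan target with its named axes.

    The first atom is always the reference heavy atom (halogen or oxygen).
    ``sigma_hole_axis`` is meaningful for hydrogen halides; ``bisector_out``
    (pointing away from the hydrogens) and ``plane_normal`` for water.
    """

    atoms: tuple[AtomSite, ...]
    kind: MoleculeKind
    sigma_hole_axis: np.ndarray | None = None
    bisector_out: np.ndarray | None = None
    plane_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_hole_axis", "bisector_out", "plane_normal"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                    raise ValidationError(f"{name} must be unit length")
                object.__setattr__(self, name, v)
        if self.kind is MoleculeKind.WATER:
            if self.bisector_out is None or self.plane_normal is None:
                raise ValidationError("water geometry requires bisector_out and plane_normal")
            if abs(float(self.bisector_out @ self.plane_normal)) > 1e-9:
                raise ValidationError("bisector_out must be perpendicular to plane_normal")

    @property
    def heavy_atom(self) -> AtomSite:
        return self.atoms[0]

    @property
    def in_plane_axis(self) -> np.ndarray:
        """Unit vector in the molecular plane, perpendicular to the bisector (water)."""
        if self.bisector_out is None or self.plane_normal is None:
            raise ValidationError("in_plane_axis is defined for water geometries only")
        return np.cross(self.bisector_out, self.plane_normal)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)


@dataclass(frozen=True, eq=False)
class ProbePoint:
    """One probe location: position (A), distance to the reference heavy atom
    (A) and the convention-dependent angle (degrees)."""

    position: np.ndarray
    r_ref: float
    theta: float


@dataclass(frozen=True, eq=False)
class ProbeGrid:
    """A set of probe points stored as flat arrays.

    ``theta`` is NaN where the grid's angle convention is undefined for a
    point (zero-length projection); such points never survive surface
    generation. ``spacing`` is None for angular scans, which are not lattices.
    """

    positions: np.ndarray  # (n, 3) A
    r_ref: np.ndarray  # (n,) A
    theta: np.ndarray  # (n,) degrees, NaN if undefined
    plane: Plane
    convention: AngleConvention
    probe_element: str = constants.DEFAULT_PROBE_ELEMENT
    probe_vdw_radius: float = constants.BONDI_VDW_RADII["He"]
    spacing: float | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError("positions must have shape (n, 3)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "r_ref", np.asarray(self.r_ref, dtype=float))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if len(self.r_ref) != len(pos) or len(self.theta) != len(pos):
            raise ValidationError("r_ref/theta length must match point count")
        if self.spacing is not None and not (self.spacing > 0):
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        if not (self.probe_vdw_radius > 0):
            raise ValidationError("probe_vdw_radius must be > 0")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def points(self) -> list[ProbePoint]:
        return [
            ProbePoint(p, float(r), float(t))
            for p, r, t in zip(self.positions, self.r_ref, self.theta)
        ]

    def subset(self, mask: np.ndarray, *, filtered: bool | None = None) -> "ProbeGrid":
        return replace(
            self,
            positions=self.positions[mask],
            r_ref=self.r_ref[mask],
            theta=self.theta[mask],
            filtered=self.filtered if filtered is None else filtered,
        )


def build_hydrogen_halide(
    halide: str,
    bond_length: float | None = None,
    *,
    anchor: Sequence[float] = constants.HALIDE_GRID_ANCHOR,
    vdw_radii: dict[str, float] | None = None,
) -> MoleculeGeometry:
    """Build an H-X diatomic on the y axis with the halogen at ``anchor``.

    The hydrogen is placed above the halogen (+y) at the experimental covalent
    bond length unless overridden, so the sigma-hole axis is (0, -1, 0).
    """
    if halide not in _HALIDES:
        raise ValidationError(f"unknown halide {halide!r}; expected one of {_HALIDES}")
    radii = dict(constants.BONDI_VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)
    length = constants.HALIDE_BOND_LENGTHS[halide] if bond_length is None else float(bond_length)
    if not (length > 0):
        raise ValidationError(f"bond_length must be > 0, got {bond_length}")
    anchor = np.asarray(anchor, dtype=float)
    x_atom = AtomSite(halide, anchor, radii[halide])
    h_atom = AtomSite("H", anchor + np.array([0.0, length, 0.0]), radii["H"])
    return MoleculeGeometry(
        atoms=(x_atom, h_atom),
        kind=MoleculeKind.HYDROGEN_HALIDE,
        sigma_hole_axis=np.array([0.0, -1.0, 0.0]),
    )


def build_water(
    oh_length: float = constants.WATER_OH_LENGTH,
    hoh_angle: float = constants.WATER_HOH_ANGLE,
    *,
    anchor: Sequence[float] = constants.WATER_GRID_ANCHOR,
    vdw_radii: dict[str, float] | None = None,
) -> MoleculeGeometry:
    """Build a water monomer in the x-y plane, oxygen at ``anchor``.

    The bisector of the H-O-H angle points along +y away from the hydrogens;
    the plane normal is +z.
    """
    if not (oh_length > 0):
        raise ValidationError(f"O-H length must be > 0, got {oh_length}")
    if not (0.0 < hoh_angle < 180.0):
        raise ValidationError(f"H-O-H angle must be in (0, 180) degrees, got {hoh_angle}")
    radii = dict(constants.BONDI_VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)
    anchor = np.asarray(anchor, dtype=float)
    half = math.radians(hoh_angle) / 2.0
    # O->H unit vectors make an angle of (180 - hoh/2) with the outward bisector
    oh1 = np.array([math.sin(half), -math.cos(half), 0.0])
    oh2 = np.array([-math.sin(half), -math.cos(half), 0.0])
    o_atom = AtomSite("O", anchor, radii["O"])
    h1 = AtomSite("H", anchor + oh_length * oh1, radii["H"])
    h2 = AtomSite("H", anchor + oh_length * oh2, radii["H"])
    return MoleculeGeometry(
        atoms=(o_atom, h1, h2),
        kind=MoleculeKind.WATER,
        bisector_out=np.array([0.0, 1.0, 0.0]),
        plane_normal=np.array([0.0, 0.0, 1.0]),
    )


def _grid_axes(molecule: MoleculeGeometry, plane: Plane) -> list[np.ndarray]:
    if plane is Plane.HALIDE_2D:
        return [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
    if plane is Plane.WATER_FRONTAL:
        return [molecule.in_plane_axis, molecule.bisector_out]
    if plane is Plane.WATER_SAGITTAL:
        return [molecule.bisector_out, molecule.plane_normal]
    if plane is Plane.WATER_3D:
        return [molecule.in_plane_axis, molecule.bisector_out, molecule.plane_normal]
    raise ValidationError(f"cannot build a lattice for plane {plane}")


def make_probe_grid(
    molecule: MoleculeGeometry,
    plane: Plane | str,
    extent: Sequence[float],
    spacing: float,
    probe_element: str = constants.DEFAULT_PROBE_ELEMENT,
    *,
    probe_vdw_radius: float | None = None,
    convention: AngleConvention | None = None,
) -> ProbeGrid:
    """Build an unfiltered regular probe lattice.

    The halide grid starts at the origin (halogen on its left edge at [0, 4]);
    water grids are centred on the oxygen. ``extent`` must match the plane's
    dimensionality (2 values for the 2D planes, 3 for the 3D box). A lattice
    with extent e and spacing s has ``e/s + 1`` points per axis.
    """
    plane = Plane(plane)
    if not (spacing > 0):
        raise ValidationError(f"spacing must be > 0, got {spacing}")
    axes = _grid_axes(molecule, plane)
    extent = [float(e) for e in extent]
    if len(extent) != len(axes):
        raise ValidationError(
            f"extent of length {len(extent)} does not match plane {plane.value} "
            f"dimensionality {len(axes)}"
        )
    if probe_vdw_radius is None:
        try:
            probe_vdw_radius = constants.BONDI_VDW_RADII[probe_element]
        except KeyError:
            raise ValidationError(
                f"no default vdW radius for probe {probe_element!r}; pass probe_vdw_radius"
            ) from None

    counts = [int(round(e / spacing)) + 1 for e in extent]
    ticks = [spacing * np.arange(n) for n in counts]
    if plane is Plane.HALIDE_2D:
        origin = np.zeros(3)
    else:
        origin = molecule.heavy_atom.position - sum(
            (e / 2.0) * ax for e, ax in zip(extent, axes)
        )
    mesh = np.meshgrid(*ticks, indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=1)  # (n, ndim)
    positions = origin + offsets @ np.stack(axes)

    conv = convention or DEFAULT_CONVENTION[plane]
    r_ref, theta = _angles_for_points(molecule, positions, conv)
    return ProbeGrid(
        positions=positions,
        r_ref=r_ref,
        theta=theta,
        plane=plane,
        convention=conv,
        probe_element=probe_element,
        probe_vdw_radius=float(probe_vdw_radius),
        spacing=float(spacing),
        filtered=False,
    )


def _angles_for_points(
    molecule: MoleculeGeometry, positions: np.ndarray, convention: AngleConvention
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (r_ref, theta) under a convention; theta is NaN where undefined."""
    ref = molecule.heavy_atom.position
    d = np.atleast_2d(positions) - ref
    r = np.linalg.norm(d, axis=1)
    if convention is AngleConvention.HALIDE_APEX:
        axis = molecule.sigma_hole_axis
        if axis is None:
            raise ValidationError("halide_apex convention requires a sigma_hole_axis")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (d @ axis) / r
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        theta = np.where(r < _PROJECTION_TOL, np.nan, theta)
        return r, theta
    if convention is AngleConvention.WATER_FRONTAL:
        u, v = molecule.in_plane_axis, molecule.bisector_out
    elif convention is AngleConvention.WATER_SAGITTAL:
        u, v = molecule.plane_normal, molecule.bisector_out
    else:  # pragma: no cover - exhaustive enum
        raise ValidationError(f"unknown convention {convention}")
    cu, cv = d @ u, d @ v
    proj = np.hypot(cu, cv)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(cv / proj, -1.0, 1.0)))
    theta = np.where(proj < _PROJECTION_TOL, np.nan, theta)
    return r, theta


def probe_angle(
    molecule: MoleculeGeometry,
    point: Sequence[float],
    convention: AngleConvention | str,
) -> float:
    """Angle (degrees, in [0, 180]) of one probe point under a convention.

    Raises :class:`UndefinedAngleError` when the projection onto the
    convention's plane has zero length (e.g. a frontal angle requested for a
    probe straight above the oxygen).
    """
    convention = AngleConvention(convention)
    point = np.asarray(point, dtype=float)
    r, theta = _angles_for_points(molecule, point[None, :], convention)
    if not np.isfinite(theta[0]):
        raise UndefinedAngleError(
            f"probe angle under {convention.value} is undefined at point {point.tolist()}"
        )
    return float(theta[0])


def filter_probe_grid_by_vdw(grid: ProbeGrid, molecule: MoleculeGeometry) -> ProbeGrid:
    """Remove probe points closer to ANY atom than half the vdW-radius sum.

    The boundary is strict: a point exactly at half the sum is removed
    ("further away than"). Idempotent.
    """
    keep = np.ones(len(grid), dtype=bool)
    for atom in molecule.atoms:
        dist = np.linalg.norm(grid.positions - atom.position, axis=1)
        keep &= dist > 0.5 * (atom.vdw_radius + grid.probe_vdw_radius)
    return grid.subset(keep, filtered=True)


def drop_undefined_angles(grid: ProbeGrid) -> ProbeGrid:
    """Remove points whose convention angle is undefined (NaN theta)."""
    return grid.subset(np.isfinite(grid.theta))


def make_angular_scan(
    molecule: MoleculeGeometry,
    fractions: Iterable[float],
    angles: Iterable[float],
    convention: AngleConvention | str,
    probe_element: str = constants.DEFAULT_PROBE_ELEMENT,
    *,
    probe_vdw_radius: float | None = None,
) -> ProbeGrid:
    """Polar scan: one point per (fraction, angle).

    Each fraction f places the probe at f * (vdW_heavy + vdW_probe) from the
    reference heavy atom; the angle is interpreted under ``convention``
    (0 deg along the sigma-hole axis / outward bisector).
    """
    convention = AngleConvention(convention)
    fractions = [float(f) for f in fractions]
    angles = [float(a) for a in angles]
    if any(f <= 0 for f in fractions):
        raise ValidationError("fractions must be > 0")
    if probe_vdw_radius is None:
        probe_vdw_radius = constants.BONDI_VDW_RADII[probe_element]

    if convention is AngleConvention.HALIDE_APEX:
        if molecule.sigma_hole_axis is None:
            raise ValidationError("halide_apex scan requires a sigma_hole_axis")
        e0 = molecule.sigma_hole_axis
        # deterministic perpendicular: x-hat component orthogonal to the axis
        trial = np.array([1.0, 0.0, 0.0])
        perp = trial - (trial @ e0) * e0
        if np.linalg.norm(perp) < 1e-9:
            trial = np.array([0.0, 1.0, 0.0])
            perp = trial - (trial @ e0) * e0
        e1 = _as_unit(perp)
    elif convention is AngleConvention.WATER_FRONTAL:
        e0, e1 = molecule.bisector_out, molecule.in_plane_axis
    else:
        e0, e1 = molecule.bisector_out, molecule.plane_normal

    ref = molecule.heavy_atom.position
    vdw_sum = molecule.heavy_atom.vdw_radius + float(probe_vdw_radius)
    positions, r_ref, theta = [], [], []
    for f in fractions:
        dist = f * vdw_sum
        for a in angles:
            rad = math.radians(a)
            positions.append(ref + dist * (math.cos(rad) * e0 + math.sin(rad) * e1))
            r_ref.append(dist)
            theta.append(a)
    return ProbeGrid(
        positions=np.array(positions),
        r_ref=np.array(r_ref),
        theta=np.array(theta),
        plane=Plane.ANGULAR_SCAN,
        convention=convention,
        probe_element=probe_element,
        probe_vdw_radius=float(probe_vdw_radius),
        spacing=None,
        filtered=False,
    )


def place_virtual_sites(
    molecule: MoleculeGeometry,
    spec: Iterable[tuple[VsiteKind | str, float, float | None]],
) -> list[np.ndarray]:
    """Place massless interaction sites relative to the molecule.

    ``spec`` is a list of (kind, distance, angle) triples; the angle (degrees
    from the outward bisector) applies to the water site kinds and may be None
    for ``halide_apex``. Sigma-hole pairs lie in the molecular plane, lone-pair
    pairs in the sagittal plane; both are mirror-symmetric pairs at +-angle.
    """
    sites: list[np.ndarray] = []
    for kind, distance, angle in spec:
        kind = VsiteKind(kind)
        if not (distance > 0):
            raise ValidationError(f"virtual-site distance must be > 0, got {distance}")
        if kind is VsiteKind.HALIDE_APEX:
            if molecule.sigma_hole_axis is None:
                raise ValidationError("halide_apex site requires a sigma_hole_axis")
            sites.append(molecule.heavy_atom.position + distance * molecule.sigma_hole_axis)
            continue
        if angle is None or not (0.0 <= angle <= 180.0):
            raise ValidationError(
                f"water virtual sites need an angle in [0, 180] degrees, got {angle}"
            )
        if kind is VsiteKind.WATER_SIGMA_HOLE:
            lateral = molecule.in_plane_axis
        else:  # WATER_LONE_PAIR
            lateral = molecule.plane_normal
        rad = math.radians(angle)
        axial = math.cos(rad) * molecule.bisector_out
        for sign in (+1.0, -1.0):
            sites.append(
                molecule.heavy_atom.position
                + distance * (axial + sign * math.sin(rad) * lateral)
            )
    return sites


def write_xyz(
    path,
    molecule: MoleculeGeometry,
    *,
    virtual_sites: Iterable[np.ndarray] | None = None,
    probe_positions: Iterable[np.ndarray] | None = None,
    probe_element: str = constants.DEFAULT_PROBE_ELEMENT,
    comment: str = "",
) -> None:
    """Write molecule (+ optional virtual sites as 'X' and probe atoms) as XYZ."""
    rows: list[tuple[str, np.ndarray]] = [(a.element, a.position) for a in molecule.atoms]
    for site in [] if virtual_sites is None else virtual_sites:
        rows.append(("X", np.asarray(site, dtype=float)))
    for p in [] if probe_positions is None else probe_positions:
        rows.append((probe_element, np.asarray(p, dtype=float)))
    lines = [str(len(rows)), comment]
    for elem, pos in rows:
        lines.append(f"{elem} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
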