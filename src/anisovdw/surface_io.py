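"""Reader/writer for the surface CSV dialect and fit-report files.

A surface file is a plain CSV with a commented key-value header::

    # anisovdw-surface
    # format_version: 1
    # system: HI
    # plane: halide_2d
    # convention: halide_apex
    # spacing: 0.1
    # probe: He
    # probe_vdw_radius: 1.4
    # filtered: true
    # units: kJ/mol
    # provenance: synthetic:...
    x,y,z,e_exchange,e_dispersion
    ...

Energies are kJ/mol (the units tag is validated on read) and coordinates are
angstroms, written with 17 significant digits so the round trip is exact.
Probe angles and reference distances are always *recomputed* from the declared
molecule on read — never trusted from a file — so there is a single source of
truth for the geometry.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .errors import SurfaceFormatError, ValidationError
from .fitting import EnergySurface, FitResult
from .geometry import (
    AngleConvention,
    MoleculeGeometry,
    Plane,
    ProbeGrid,
    _angles_for_points,
    build_hydrogen_halide,
    build_water,
)

__all__ = [
    "read_surface_csv",
    "write_surface_csv",
    "write_fit_report",
    "write_residuals_csv",
]

FORMAT_VERSION = 1
MAGIC = "anisovdw-surface"
_COLUMNS = ("x", "y", "z", "e_exchange", "e_dispersion")
_KNOWN_SYSTEMS = ("HF", "HCl", "HBr", "HI", "water", "water_frontal", "water_sagittal")


def _molecule_for_system(system: str) -> MoleculeGeometry:
    if system.startswith("water"):
        return build_water()
    if system in ("HF", "HCl", "HBr", "HI"):
        return build_hydrogen_halide(system[1:])
    raise SurfaceFormatError(
        f"cannot rebuild a molecule for system {system!r}; expected one of {_KNOWN_SYSTEMS}"
    )


def write_surface_csv(surface: EnergySurface, path) -> None:
    """Write a surface in the CSV dialect (deterministic, byte-stable)."""
    if surface.system is None:
        raise ValidationError("surface has no system tag; set EnergySurface.system before writing")
    grid = surface.grid
    lines = [
        f"# {MAGIC}",
        f"# format_version: {FORMAT_VERSION}",
        f"# system: {surface.system}",
        f"# plane: {grid.plane.value}",
        f"# convention: {grid.convention.value}",
        f"# spacing: {'' if grid.spacing is None else format(grid.spacing, '.17g')}",
        f"# probe: {grid.probe_element}",
        f"# probe_vdw_radius: {grid.probe_vdw_radius:.17g}",
        f"# filtered: {'true' if grid.filtered else 'false'}",
        "# units: kJ/mol",
        f"# provenance: {surface.provenance}",
        ",".join(_COLUMNS),
    ]
    for pos, ex, dp in zip(grid.positions, surface.exchange, surface.dispersion):
        lines.append(
            f"{pos[0]:.17g},{pos[1]:.17g},{pos[2]:.17g},{ex:.17g},{dp:.17g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(text: str) -> tuple[dict[str, str], int]:
    header: dict[str, str] = {}
    n_header = 0
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if body == MAGIC:
            header["magic"] = body
        elif ":" in body:
            key, _, value = body.partition(":")
            header[key.strip()] = value.strip()
    if header.get("magic") != MAGIC:
        raise SurfaceFormatError(f"not a {MAGIC} file (missing magic header line)")
    return header, n_header


def read_surface_csv(path) -> EnergySurface:
    """Read a surface file, rebuilding the molecule and all derived geometry."""
    path = Path(path)
    text = path.read_text()
    header, n_header = _parse_header(text)

    version = header.get("format_version")
    if version != str(FORMAT_VERSION):
        raise SurfaceFormatError(f"unsupported format_version {version!r}")
    units = header.get("units")
    if units != "kJ/mol":
        raise SurfaceFormatError(f"unsupported energy units {units!r}; expected 'kJ/mol'")
    for key in ("system", "plane", "convention", "probe"):
        if key not in header:
            raise SurfaceFormatError(f"missing header field {key!r}")

    body = "\n".join(text.splitlines()[n_header:])
    frame = pd.read_csv(io.StringIO(body), dtype=str)  # numeric conversion below, per column
    for col in _COLUMNS:
        if col not in frame.columns:
            raise SurfaceFormatError(f"missing required column {col!r}")
    numeric = {}
    for col in _COLUMNS:
        values = np.empty(len(frame), dtype=float)
        for row, cell in enumerate(frame[col]):
            try:
                values[row] = float(cell)  # exact strtod; pandas' fast parser is not
            except (TypeError, ValueError):
                raise SurfaceFormatError(
                    f"non-numeric or missing value in column {col!r} at data row {row}"
                ) from None
        numeric[col] = values

    molecule = _molecule_for_system(header["system"])
    plane = Plane(header["plane"])
    convention = AngleConvention(header["convention"])
    positions = np.stack([numeric["x"], numeric["y"], numeric["z"]], axis=1)
    r_ref, theta = _angles_for_points(molecule, positions, convention)
    spacing_text = header.get("spacing", "")
    grid = ProbeGrid(
        positions=positions,
        r_ref=r_ref,
        theta=theta,
        plane=plane,
        convention=convention,
        probe_element=header["probe"],
        probe_vdw_radius=float(header.get("probe_vdw_radius", constants.BONDI_VDW_RADII["He"])),
        spacing=float(spacing_text) if spacing_text else None,
        filtered=header.get("filtered", "false").lower() == "true",
    )
    return EnergySurface(
        grid=grid,
        exchange=numeric["e_exchange"],
        dispersion=numeric["e_dispersion"],
        provenance=header.get("provenance", ""),
        system=header["system"],
        molecule=molecule,
    )


def write_fit_report(result: FitResult, path, *, include_residuals: bool = False) -> None:
    """Write a FitResult as versioned JSON."""
    payload = {"report_version": 1, **result.to_dict(include_residuals=include_residuals)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_residuals_csv(
    surfaces: dict[str, EnergySurface],
    results: dict[str, FitResult],
    path,
) -> None:
    """Per-point residual table for residual plots.

    ``surfaces`` maps block label -> surface; ``results`` maps fit label ->
    FitResult whose residuals cover the concatenated blocks in order.
    """
    n_total = sum(len(s) for s in surfaces.values())
    rows: dict[str, list] = {"block": [], "x": [], "y": [], "z": [], "e_reference": []}
    for label, s in surfaces.items():
        rows["block"].extend([label] * len(s))
        rows["x"].extend(s.grid.positions[:, 0])
        rows["y"].extend(s.grid.positions[:, 1])
        rows["z"].extend(s.grid.positions[:, 2])
        rows["e_reference"].extend(s.exchange)
    frame = pd.DataFrame(rows)
    for label, result in results.items():
        if result.residuals is None or len(result.residuals) != n_total:
            raise ValidationError(f"fit {label!r} has no residuals covering all blocks")
        frame[f"e_fit_{label}"] = frame["e_reference"].to_numpy() + result.residuals
        frame[f"residual_{label}"] = result.residuals
    frame.to_csv(path, index=False)
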