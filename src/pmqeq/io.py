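"""Extended-XYZ structure I/O, parameter files, and run configuration.

Extended XYZ is the sole structure format: the comment line carries
``Lattice="ax ay az bx by bz cx cy cz"`` (mandatory -- the solver is
strictly periodic), a ``Properties=...`` column layout, and optional
``total_charge`` and ``units`` keys.  File lengths default to angstrom, the
ecosystem convention, and are converted to bohr on read with the factor
:data:`pmqeq.core.BOHR_PER_ANGSTROM`; declare ``units=bohr`` (in the file or
via the API/CLI) for atomic-unit files.  Internally everything is bohr.

Qeq parameters are a small YAML mapping::

    elements:
      Na: {chi: -0.3, hardness: 0.8, sigma: 1.0, energy_offset: 0.0}
      Cl: {chi:  0.3, hardness: 0.9, sigma: 1.2}

Results are written as extended XYZ with per-atom charge (and force)
columns plus a JSON sidecar echoing energies, stress, solver diagnostics
and the run configuration.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (AtomicSystem, BOHR_PER_ANGSTROM, DerivativeBundle,
                   ElementParams, PmqeqError, QeqParameters, QeqResult)

__all__ = [
    "read_structure",
    "write_structure",
    "read_parameters",
    "write_parameters",
    "write_results",
    "RunConfig",
]


class StructureParseError(PmqeqError):
    """Malformed extended-XYZ input; message carries the line number."""


_KV_RE = re.compile(r'(\S+?)=("[^"]*"|\S+)')


def _parse_comment(line: str) -> dict:
    return {k: v.strip('"') for k, v in _KV_RE.findall(line)}


def _length_scale(units: str) -> float:
    units = units.lower()
    if units in ("angstrom", "ang", "a"):
        return BOHR_PER_ANGSTROM
    if units in ("bohr", "au"):
        return 1.0
    raise PmqeqError(f"unknown length unit {units!r}")


def read_structure(path, units: str = "angstrom") -> AtomicSystem:
    """Read one extended-XYZ frame; positions are returned in bohr.

    ``units`` sets the file's length unit unless the comment line declares
    its own ``units=`` key.  A missing ``Lattice`` record is an error: the
    solver requires a periodic cell.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path}, line 1: expected an atom count")
    if n < 1:
        raise StructureParseError(f"{path}, line 1: need at least one atom")
    if len(lines) < n + 2:
        raise StructureParseError(
            f"{path}: {n} atoms declared but only {len(lines) - 2} atom lines")
    meta = _parse_comment(lines[1])
    if "Lattice" not in meta:
        raise StructureParseError(
            f"{path}, line 2: missing Lattice record (periodic cell required)")
    scale = _length_scale(meta.get("units", units))
    try:
        lattice = np.array([float(x) for x in meta["Lattice"].split()])
        lattice = lattice.reshape(3, 3) * scale
    except ValueError:
        raise StructureParseError(f"{path}, line 2: Lattice needs 9 numbers")
    total_charge = float(meta.get("total_charge", 0.0))

    species, positions, charges = [], [], []
    has_charge_col = "charge" in meta.get("Properties", "")
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise StructureParseError(
                f"{path}, line {3 + k}: expected 'species x y z ...'")
        species.append(parts[0])
        try:
            positions.append([float(x) for x in parts[1:4]])
            if has_charge_col and len(parts) >= 5:
                charges.append(float(parts[4]))
        except ValueError:
            raise StructureParseError(
                f"{path}, line {3 + k}: non-numeric coordinate")
    system = AtomicSystem(lattice, species, np.array(positions) * scale,
                          total_charge=total_charge)
    if charges and len(charges) == n:
        system.charges = np.array(charges)  # informational passenger
    return system


def _format_comment(system: AtomicSystem, scale: float, columns: str,
                    extra: dict | None = None) -> str:
    lat = " ".join(f"{x:.14g}" for x in (system.lattice / scale).ravel())
    fields = [f'Lattice="{lat}"', f"Properties={columns}",
              f"total_charge={system.total_charge:.14g}"]
    if extra:
        fields += [f"{k}={v}" for k, v in extra.items()]
    return " ".join(fields)


def write_structure(path, system: AtomicSystem, units: str = "angstrom",
                    charges=None, forces=None):
    """Write an extended-XYZ frame (charges in e, forces in hartree/bohr
    regardless of the length unit of positions)."""
    scale = _length_scale(units)
    cols = "species:S:1:pos:R:3"
    if charges is not None:
        cols += ":charge:R:1"
    if forces is not None:
        cols += ":forces:R:3"
    lines = [str(system.n_atoms),
             _format_comment(system, scale, cols, {"units": units})]
    pos = system.positions / scale
    for i, s in enumerate(system.species):
        row = f"{s} " + " ".join(f"{x:.17g}" for x in pos[i])
        if charges is not None:
            row += f" {charges[i]:.17g}"
        if forces is not None:
            row += " " + " ".join(f"{x:.17g}" for x in forces[i])
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_parameters(path) -> QeqParameters:
    """Load the YAML element-parameter table (atomic units throughout)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "elements" not in data:
        raise PmqeqError(f"{path}: expected a top-level 'elements' mapping")
    elements = {}
    for name, entry in data["elements"].items():
        try:
            elements[name] = ElementParams(
                chi=float(entry["chi"]),
                hardness=float(entry["hardness"]),
                sigma=float(entry["sigma"]),
                energy_offset=float(entry.get("energy_offset", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise PmqeqError(
                f"{path}: element {name!r} needs chi, hardness, sigma ({exc})")
    override = data.get("chi_override")
    return QeqParameters(elements,
                         None if override is None else np.asarray(override, float))


def write_parameters(path, params: QeqParameters):
    data = {"elements": {
        name: {"chi": p.chi, "hardness": p.hardness, "sigma": p.sigma,
               "energy_offset": p.energy_offset}
        for name, p in params.elements.items()}}
    if params.chi_override is not None:
        data["chi_override"] = [float(x) for x in params.chi_override]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    structure: str = ""
    parameters: str = ""
    output: str = "pmqeq_out.xyz"
    units: str = "angstrom"
    grid_spacing: float | None = None
    eps_trunc: float = 1e-10
    tolerance: float = 1e-8
    max_iterations: int = 300
    warm_start: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("eps_trunc", "tolerance"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")
        if self.grid_spacing is not None and not self.grid_spacing > 0.0:
            raise ValueError("grid_spacing must be positive")

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def write_results(path, system: AtomicSystem, result: QeqResult,
                  bundle: DerivativeBundle | None = None,
                  units: str = "angstrom", config: RunConfig | None = None):
    """Write charges (and forces) as extended XYZ plus a JSON sidecar.

    The sidecar (same stem, ``.json``) carries energies, the stress tensor,
    iteration count, residual history and a config echo -- enough to
    reproduce every number in the file.  Returns the sidecar path.
    """
    if not result.converged:
        raise PmqeqError("refusing to write an unconverged result")
    forces = bundle.forces if bundle is not None else None
    write_structure(path, system, units=units, charges=result.charges,
                    forces=forces)
    sidecar = {
        "energy_elec_hartree": result.energy_elec,
        "energy_qeq_hartree": result.energy_qeq,
        "lagrange_multiplier": result.lagrange_multiplier,
        "iterations": result.iterations,
        "residual_maxnorm": result.residual_maxnorm,
        "residual_history": list(map(float, result.residual_history)),
        "total_charge": system.total_charge,
    }
    if bundle is not None and bundle.stress is not None:
        stress = 0.5 * (bundle.stress + bundle.stress.T)  # write symmetric
        sidecar["stress_hartree_per_bohr3"] = stress.tolist()
    if config is not None:
        sidecar["config"] = asdict(config)
    sidecar_path = Path(path).with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path
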