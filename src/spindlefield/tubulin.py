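"""Coarse-graining of atomic tubulin structures.

A tubulin monomer (~4500 atoms) is reduced to a single point carrying its
mass-weighted centre of gravity and the dipole moment of its internal charge
distribution.  The packaged defaults (369 D for alpha, 26 D for beta) are the
published coarse-grained moments of polymerised tubulin; the functions here
let the same reduction be run on any PDB-style structure with a user-supplied
partial-charge table.

Units: positions in nm, masses in u, charges in elementary charges, dipole
moments in Debye.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import constants


class MonomerKind(enum.Enum):
    ALPHA = "alpha"
    BETA = "beta"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure: position [nm], mass [u], partial charge [e]."""

    position: np.ndarray
    mass: float
    partial_charge: float
    serial: int = 0
    name: str = ""
    element: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        if not (self.mass > 0 and np.isfinite(self.mass)):
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class MonomerCG:
    """Coarse-grained monomer: kind, centre of gravity and dipole magnitude."""

    kind: MonomerKind
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    static_dipole_magnitude: float = 0.0  # Debye
    oscillating_fraction: float = constants.OSC_FRACTION

    def __post_init__(self):
        if self.static_dipole_magnitude < 0:
            raise ValueError("dipole magnitude must be non-negative")
        if not (0.0 < self.oscillating_fraction <= 1.0):
            raise ValueError("oscillating fraction must lie in (0, 1]")
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float))


def default_monomers() -> tuple[MonomerCG, MonomerCG]:
    """The packaged (alpha, beta) monomer pair with Table-default moments."""
    alpha = MonomerCG(MonomerKind.ALPHA,
                      static_dipole_magnitude=constants.DIPOLE_ALPHA_D)
    beta = MonomerCG(MonomerKind.BETA,
                     static_dipole_magnitude=constants.DIPOLE_BETA_D)
    return alpha, beta


def center_of_gravity(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Mass-weighted mean position sum(m_i r_i)/sum(m_i) [nm].

    Raises ``ValueError`` on an empty atom list or non-positive total mass.
    """
    if len(atoms) == 0:
        raise ValueError("cannot take the centre of gravity of zero atoms")
    masses = np.array([a.mass for a in atoms], dtype=float)
    positions = np.array([a.position for a in atoms], dtype=float)
    total = masses.sum()
    if not total > 0:
        raise ValueError("total mass must be positive")
    return masses @ positions / total


def dipole_moment(atoms: Sequence[AtomRecord],
                  origin: np.ndarray | None = None) -> np.ndarray:
    """Dipole moment sum(q_i (r_i - origin)) of the charge set, in Debye.

    ``origin`` defaults to the centre of gravity of the same atoms.  For a
    net-neutral charge set the result is independent of the origin.
    """
    if len(atoms) == 0:
        raise ValueError("cannot take the dipole moment of zero atoms")
    if origin is None:
        origin = center_of_gravity(atoms)
    origin = np.asarray(origin, dtype=float)
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError("origin must be a finite 3-vector")
    charges = np.array([a.partial_charge for a in atoms], dtype=float)
    positions = np.array([a.position for a in atoms], dtype=float)
    p_e_nm = charges @ (positions - origin)
    return p_e_nm * constants.DEBYE_PER_E_NM


def coarse_grain(atoms: Sequence[AtomRecord],
                 kind: MonomerKind = MonomerKind.ALPHA) -> MonomerCG:
    """Reduce one monomer's atoms to its CG record (COM + dipole magnitude)."""
    com = center_of_gravity(atoms)
    p = dipole_moment(atoms, origin=com)
    return MonomerCG(kind=kind, com=com,
                     static_dipole_magnitude=float(np.linalg.norm(p)))


# --- structure input -------------------------------------------------------

#: standard atomic masses [u] for the elements that occur in proteins
_ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "MG": 24.305, "ZN": 65.38, "FE": 55.845,
    "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


def _element_mass(element: str, name: str) -> float:
    key = element.strip().upper()
    if not key:
        # fall back on the first letter of the atom name (PDB convention)
        key = name.strip().lstrip("0123456789")[:1].upper()
    if key not in _ELEMENT_MASSES:
        raise ValueError(f"unknown element {element!r} for atom {name!r}")
    return _ELEMENT_MASSES[key]


def read_charge_table(path: str | Path) -> dict[int, float]:
    """Read a two-column sidecar table ``serial,charge_e`` (CSV, '#' comments)."""
    charges: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            serial_s, charge_s = line.replace(",", " ").split()
            charges[int(serial_s)] = float(charge_s)
        except ValueError as exc:
            raise ValueError(f"malformed charge-table line: {line!r}") from exc
    return charges


def load_structure(path: str | Path,
                   charges: str | Path | Mapping[int, float] | None = None,
                   charge_column: str | None = None) -> dict[str, list[AtomRecord]]:
    """Load a PDB file into per-chain atom lists with masses and charges.

    The PDB format has no charge column, so partial charges come from either
    a sidecar table (``charges``: path or mapping ``serial -> charge [e]``) or
    a declared column convention (``charge_column`` in ``{"occupancy",
    "b_factor"}``).  Coordinates are converted from Angstrom to nm.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if charge_column not in (None, "occupancy", "b_factor"):
        raise ValueError(f"unknown charge column convention {charge_column!r}")
    if isinstance(charges, (str, Path)):
        charges = read_charge_table(charges)
    if charges is None and charge_column is None:
        raise ValueError("a charge source is required: pass a sidecar table "
                         "or declare a charge column convention")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate fixture-grade headers
        structure = PDBParser(QUIET=True).get_structure("s", str(path))

    chains: dict[str, list[AtomRecord]] = {}
    for model in structure:
        for chain in model:
            records: list[AtomRecord] = []
            for atom in chain.get_atoms():
                serial = atom.get_serial_number()
                if charges is not None:
                    if serial not in charges:
                        raise ValueError(f"no charge for atom serial {serial}")
                    q = charges[serial]
                elif charge_column == "occupancy":
                    q = atom.get_occupancy()
                else:
                    q = atom.get_bfactor()
                records.append(AtomRecord(
                    position=np.asarray(atom.get_coord(), dtype=float) * 0.1,
                    mass=_element_mass(atom.element or "", atom.get_name()),
                    partial_charge=float(q),
                    serial=serial,
                    name=atom.get_name(),
                    element=atom.element or "",
                ))
            if records:
                chains[chain.id] = records
        break  # first model only
    if not chains:
        raise ValueError(f"no atoms found in {path}")
    return chains


def coarse_grain_structure(chains: Mapping[str, Sequence[AtomRecord]],
                           kinds: Mapping[str, MonomerKind] | None = None
                           ) -> dict[str, MonomerCG]:
    """Coarse-grain every chain of a loaded structure.

    ``kinds`` optionally maps chain ids to monomer kinds; unmapped chains
    default to alpha.
    """
    out: dict[str, MonomerCG] = {}
    for chain_id, atoms in chains.items():
        kind = (kinds or {}).get(chain_id, MonomerKind.ALPHA)
        out[chain_id] = coarse_grain(atoms, kind)
    return out
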