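"""Synthetic test inputs: toy structures, mini spindles, uniform fields.

Everything here is generated programmatically so the whole package is
testable without any external download.  The toy monomer is a synthetic
4-atom neutral "molecule" with analytically known centre of gravity and
dipole moment; the mini spindle is a 6-MT model (one astral, one kinetochore
and one polar MT per MTOC) that builds in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import constants
from .field import EvaluationGrid, FieldFrame, plane_grid
from .geometry import SpindleModel, SpindleParams, build_spindle

#: toy-monomer atoms: (name, element, position nm, mass-from-element, charge e)
_TOY_ATOMS = [
    ("C1", "C", (0.0, 0.0, 0.1), 0.5),
    ("C2", "C", (0.0, 0.0, -0.1), -0.5),
    ("N1", "N", (0.1, 0.0, 0.0), 0.25),
    ("O1", "O", (-0.1, 0.0, 0.0), -0.25),
]


@dataclass(frozen=True)
class ToyMonomer:
    """Paths and analytic ground truth of the toy structure fixture."""

    pdb_path: Path
    charge_path: Path
    com_nm: np.ndarray
    dipole_e_nm: np.ndarray  # sum q_i (r_i - com), e*nm

    @property
    def dipole_debye(self) -> np.ndarray:
        return self.dipole_e_nm * constants.DEBYE_PER_E_NM


def _pdb_atom_line(serial: int, name: str, chain: str, resseq: int,
                   pos_nm, element: str) -> str:
    x, y, z = (10.0 * v for v in pos_nm)  # nm -> Angstrom
    return (f"ATOM  {serial:5d} {name:<4s} GLY {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}")


def toy_monomer(out_dir: str | Path, two_chains: bool = False) -> ToyMonomer:
    """Write the 4-atom neutral toy structure (PDB + charge sidecar).

    With ``two_chains`` the same 4 atoms are emitted twice as chains A and B
    (the second translated by 5 nm in x) to exercise per-chain grouping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines, charges = [], []
    serial = 1
    chains = ["A", "B"] if two_chains else ["A"]
    for ci, chain in enumerate(chains):
        shift = np.array([5.0 * ci, 0.0, 0.0])
        for name, element, pos, q in _TOY_ATOMS:
            lines.append(_pdb_atom_line(serial, name, chain, 1,
                                        np.asarray(pos) + shift, element))
            charges.append(f"{serial},{q}")
            serial += 1
        lines.append("TER")
    lines.append("END")
    pdb_path = out_dir / "toy_monomer.pdb"
    pdb_path.write_text("\n".join(lines) + "\n")
    charge_path = out_dir / "toy_monomer_charges.csv"
    charge_path.write_text("# serial,charge_e\n" + "\n".join(charges) + "\n")

    from .tubulin import _ELEMENT_MASSES  # packaged element masses
    masses = np.array([_ELEMENT_MASSES[e] for _, e, _, _ in _TOY_ATOMS])
    pos = np.array([p for _, _, p, _ in _TOY_ATOMS])
    q = np.array([c for _, _, _, c in _TOY_ATOMS])
    com = masses @ pos / masses.sum()
    dipole = q @ (pos - com)
    return ToyMonomer(pdb_path, charge_path, com, dipole)


def mini_spindle(seed: int = 0, scenario: str = "fixed") -> SpindleModel:
    """A 6-MT spindle (2 astral, 2 kinetochore, 2 polar) for fast tests."""
    params = SpindleParams(
        n_astral_per_mtoc=1, n_kinetochore_per_mtoc=1, n_polar_per_mtoc=1,
        kappa_astral=12, kappa_kp=12, scenario=scenario)  # type: ignore[arg-type]
    return build_spindle(params, seed=seed)


def uniform_field(value: float = 1.0, half_span: float = 100.0,
                  pitch: float = 20.0,
                  grid: EvaluationGrid | None = None) -> FieldFrame:
    """Synthetic constant field frame (|E| = value everywhere) for tests."""
    grid = grid or plane_grid(half_span=half_span, pitch=pitch)
    E = np.zeros((len(grid), 3))
    E[:, 2] = value
    return FieldFrame(time=0.0, grid=grid, E_real=E,
                      clamp_counts=np.zeros(len(grid), dtype=np.int64),
                      meta={"synthetic": True})


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0):
    """CLI entry: write a named fixture to ``out_dir`` and return its object."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_monomer":
        return toy_monomer(out_dir)
    if kind == "mini_spindle":
        from .io import write_dipole_csv, write_model_json
        model = mini_spindle(seed)
        write_model_json(model, out_dir / "mini_spindle.json")
        write_dipole_csv(model, out_dir / "mini_spindle_dipoles.csv")
        return model
    if kind == "uniform_field":
        from .io import write_field_csv
        frame = uniform_field()
        write_field_csv(frame, out_dir / "uniform_field.csv")
        return frame
    raise ValueError(f"unknown fixture kind {kind!r}")
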