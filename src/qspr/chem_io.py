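"""Molecule input/output and structure preparation.

Molecules arrive as SMILES (.smi) or SDF (V2000) records and leave as
:class:`Molecule` objects carrying explicit hydrogens, one energy-minimised
3D conformer, and per-atom partial charges — the substrate every descriptor
in :mod:`qspr.descriptors` assumes.

Partial charges default to the Gasteiger–Marsili empirical scheme. A
charge-provider hook lets a caller substitute externally computed charges
(for example from a semiempirical QM run) supplied as a per-atom CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Bondi van der Waals radii (Å); elements outside the table fall back to
#: the carbon radius with a warning.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    """One atom of a prepared molecule."""

    element: str
    mass: float  # Da
    coords: np.ndarray  # shape (3,), Å
    partial_charge: float | None  # e
    is_hydrogen: bool
    vdw_radius: float  # Å

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass(frozen=True)
class Bond:
    """A bond between two atoms, by index into the molecule's atom list."""

    atom_i: int
    atom_j: int
    order: str  # single | double | triple | aromatic

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("bond endpoints must differ")
        if self.order not in ("single", "double", "triple", "aromatic"):
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class Molecule:
    """A molecule plus the underlying RDKit mol it was built from.

    ``prepared`` is True once explicit hydrogens, 3D coordinates and
    partial charges are all present.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    prepared: bool = False
    rdmol: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.atom_i < n and 0 <= b.atom_j < n):
                raise ValueError(f"bond ({b.atom_i},{b.atom_j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate matrix in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        q = [a.partial_charge for a in self.atoms]
        if any(c is None for c in q):
            raise ValueError(f"molecule {self.id!r} has atoms without partial charges")
        return np.array(q, dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


ChargeProvider = Callable[[Chem.Mol, str], Sequence[float]]


def gasteiger_charges(rdmol: Chem.Mol, mol_id: str) -> Sequence[float]:
    """Gasteiger–Marsili iterative partial-equalisation charges."""
    AllChem.ComputeGasteigerCharges(rdmol)
    charges = []
    for atom in rdmol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(q):
            raise ValueError(f"non-finite Gasteiger charge on atom of {mol_id!r}")
        charges.append(q)
    return charges


def charges_from_csv(path: str | Path) -> ChargeProvider:
    """Charge provider reading per-atom charges from a CSV.

    The file must have columns ``mol_id``, ``atom_index``, ``charge``;
    atom indices refer to the prepared (explicit-H) atom order.
    """
    table = pd.read_csv(path)
    required = {"mol_id", "atom_index", "charge"}
    if not required.issubset(table.columns):
        raise ValueError(f"charge CSV needs columns {sorted(required)}")
    grouped = {
        str(mid): g.sort_values("atom_index")["charge"].to_numpy()
        for mid, g in table.groupby("mol_id")
    }

    def provider(rdmol: Chem.Mol, mol_id: str) -> Sequence[float]:
        if mol_id not in grouped:
            raise KeyError(f"no charges for molecule {mol_id!r} in charge file")
        q = grouped[mol_id]
        if len(q) != rdmol.GetNumAtoms():
            raise ValueError(
                f"charge file has {len(q)} charges for {mol_id!r}, "
                f"molecule has {rdmol.GetNumAtoms()} atoms"
            )
        return q

    return provider


def _vdw_radius(symbol: str) -> float:
    if symbol not in BONDI_RADII:
        logger.warning("no Bondi radius for element %s; using %.2f Å", symbol, _DEFAULT_RADIUS)
    return BONDI_RADII.get(symbol, _DEFAULT_RADIUS)


_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


def _from_rdkit(rdmol: Chem.Mol, mol_id: str, prepared: bool) -> Molecule:
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    atoms = []
    for atom in rdmol.GetAtoms():
        pos = (
            np.array(conf.GetAtomPosition(atom.GetIdx()), dtype=float)
            if conf is not None
            else np.zeros(3)
        )
        q = None
        if atom.HasProp("_GasteigerCharge"):
            q = atom.GetDoubleProp("_GasteigerCharge")
        elif atom.HasProp("_PreparedCharge"):
            q = atom.GetDoubleProp("_PreparedCharge")
        atoms.append(
            Atom(
                element=atom.GetSymbol(),
                mass=atom.GetMass(),
                coords=pos,
                partial_charge=q,
                is_hydrogen=atom.GetAtomicNum() == 1,
                vdw_radius=_vdw_radius(atom.GetSymbol()),
            )
        )
    bonds = []
    for bond in rdmol.GetBonds():
        order = _BOND_ORDER.get(bond.GetBondType())
        if order is None:
            # dative/other exotic orders are treated as single for counting
            order = "single"
        if bond.GetIsAromatic():
            order = "aromatic"
        bonds.append(Bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, prepared=prepared, rdmol=rdmol)


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read molecules from a .smi or SDF (V2000) file.

    Parse failures are logged and skipped. Raises if the file is missing,
    the format is unknown, or no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".sd", ".mol") else "smiles"
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unknown format {fmt!r}; expected 'smiles' or 'sdf'")

    molecules: list[Molecule] = []
    n_failed = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            rdmol = Chem.MolFromSmiles(smiles)
            if rdmol is None:
                n_failed += 1
                logger.warning("line %d of %s: unparseable SMILES %r", lineno, path, smiles)
                continue
            molecules.append(_from_rdkit(rdmol, name, prepared=False))
    else:
        if "V3000" in path.read_text()[:20000]:
            raise ValueError(f"{path}: SDF V3000 records are not supported (V2000 only)")
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for idx, rdmol in enumerate(supplier):
            if rdmol is None:
                n_failed += 1
                logger.warning("record %d of %s failed to parse", idx, path)
                continue
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"mol_{idx}"
            molecules.append(_from_rdkit(rdmol, name, prepared=False))

    if not molecules:
        raise ValueError(f"{path}: no valid molecule records (of {n_failed} failures)")
    if n_failed:
        logger.warning("%s: skipped %d unparseable record(s)", path, n_failed)
    return molecules


def from_smiles(smiles: str, mol_id: str | None = None) -> Molecule:
    """Build an unprepared Molecule directly from a SMILES string."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return _from_rdkit(rdmol, mol_id or smiles, prepared=False)


def prepare_molecule(
    m: Molecule,
    seed: int = 7,
    charge_provider: ChargeProvider = gasteiger_charges,
) -> Molecule:
    """Add explicit hydrogens, embed one 3D conformer and assign charges.

    The conformer is generated with the ETKDG distance-geometry method
    seeded deterministically, then relaxed with MMFF94 (UFF fallback), so
    repeated calls with the same seed give bitwise-identical coordinates.
    Already-prepared molecules are returned unchanged.
    """
    if m.prepared:
        return m
    if m.rdmol is None:
        raise ValueError(f"molecule {m.id!r} has no structure to prepare")

    rdmol = Chem.AddHs(Chem.Mol(m.rdmol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        # retry with random coords before giving up (macrocycles etc.)
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise RuntimeError(f"3D embedding failed for molecule {m.id!r}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(rdmol):
            AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception as exc:  # pragma: no cover - rdkit-internal failures
        raise RuntimeError(f"force-field minimisation failed for {m.id!r}: {exc}") from exc

    charges = charge_provider(rdmol, m.id)
    if len(charges) != rdmol.GetNumAtoms():
        raise ValueError(f"charge provider returned {len(charges)} charges for {m.id!r}")
    for atom, q in zip(rdmol.GetAtoms(), charges):
        atom.SetDoubleProp("_GasteigerCharge", float(q))

    out = _from_rdkit(rdmol, m.id, prepared=True)
    for a in out.atoms:
        if a.partial_charge is None or not np.isfinite(a.partial_charge):
            raise ValueError(f"missing/non-finite charge after preparation of {m.id!r}")
    return out


DESCRIPTOR_COLUMNS = [
    "nsb",
    "nab",
    "n_oxygen",
    "n_nitrogen",
    "rel_oxygen",
    "rel_nitrogen",
    "max_h_charge",
    "grav3",
    "saaa",
    "shdw6",
    "hasa2",
    "alogp",
    "psa",
]


def write_descriptor_table(rows: Iterable[tuple], path: str | Path) -> None:
    """Write (id, DescriptorVector, target) rows to CSV.

    The CSV has an ``id`` column, the 13 descriptor columns, and a ``F``
    target column; it round-trips losslessly through
    :func:`read_descriptor_table`.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot write an empty descriptor table")
    records = []
    for mol_id, vec, target in rows:
        rec = {"id": mol_id}
        rec.update({c: getattr(vec, c) for c in DESCRIPTOR_COLUMNS})
        rec["F"] = target
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.12g")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a descriptor CSV back into a DataFrame indexed by id."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: descriptor table lacks an 'id' column")
    return df.set_index("id")
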