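import numpy as np
import pytest

from qspr import chem_io
from qspr.chem_io import Atom, Bond, Molecule

SMILES = {
    "methane": "C",
    "ethane": "CC",
    "hexane": "CCCCCC",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "tetrafluoromethane": "FC(F)(F)F",
}


@pytest.fixture(scope="session")
def prepared():
    """Prepared versions of the named fixture molecules, keyed by name."""
    return {
        name: chem_io.prepare_molecule(chem_io.from_smiles(smi, name), seed=7)
        for name, smi in SMILES.items()
    }


def make_toy(
    coords,
    elements=None,
    charges=None,
    masses=None,
    radii=None,
    bonds=(),
    mol_id="toy",
) -> Molecule:
    """Build a prepared Molecule directly from arrays (no RDKit involved)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = elements or ["C"] * n
    charges = charges if charges is not None else [0.0] * n
    masses = masses if masses is not None else [12.0] * n
    radii = radii if radii is not None else [chem_io.BONDI_RADII.get(e, 1.70) for e in elements]
    atoms = [
        Atom(
            element=e,
            mass=float(m),
            coords=c,
            partial_charge=float(q),
            is_hydrogen=e == "H",
            vdw_radius=float(r),
        )
        for e, m, c, q, r in zip(elements, masses, coords, charges, radii)
    ]
    return Molecule(
        id=mol_id,
        atoms=atoms,
        bonds=[Bond(i, j, order) for i, j, order in bonds],
        prepared=True,
    )
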