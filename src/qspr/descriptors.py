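"""Molecular descriptors for the oral-bioavailability QSPR model.

Eleven descriptors in three families — topological (bond and element
counts), electronic (maximum hydrogen partial charge) and geometric
(gravitational index, acceptor surface area, YZ shadow) plus the hybrid
charged-partial-surface-area descriptor HASA-2 — together with AlogP
(Ghose–Crippen) and topological polar surface area (Ertl), which feed the
absorption-plane classifiers.

Surface areas use a Shrake–Rupley solvent-accessible-surface sampler with
a deterministic Fibonacci sphere grid; the shadow descriptor rasterises
the van-der-Waals projection after principal-axis alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import Crippen, rdMolDescriptors

from .chem_io import Molecule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable numerical parameters of the descriptor engine."""

    probe_radius: float = 1.4  # Å, water probe
    n_sphere_points: int = 960
    grid_resolution: float = 0.1  # Å, shadow raster
    #: elements counted as hydrogen-bond acceptors
    acceptor_elements: tuple[str, ...] = ("N", "O")
    #: indices of atoms to exclude from the acceptor set (e.g. pyrrole N)
    acceptor_exclusions: tuple[int, ...] = ()


@dataclass(frozen=True)
class DescriptorVector:
    """The 11 model descriptors plus AlogP and PSA for one molecule."""

    nsb: int
    nab: int
    n_oxygen: int
    n_nitrogen: int
    rel_oxygen: float
    rel_nitrogen: float
    max_h_charge: float
    grav3: float
    saaa: float
    shdw6: float
    hasa2: float
    alogp: float
    psa: float

    def __post_init__(self) -> None:
        for name in ("nsb", "nab", "n_oxygen", "n_nitrogen"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if not (0 <= self.rel_oxygen <= 1 and 0 <= self.rel_nitrogen <= 1):
            raise ValueError("relative element counts must lie in [0, 1]")
        if not (0 < self.shdw6 <= 1):
            raise ValueError(f"shdw6 must lie in (0, 1], got {self.shdw6}")
        if self.saaa < 0 or self.psa < 0 or self.grav3 < 0:
            raise ValueError("saaa, psa and grav3 must be non-negative")


@dataclass(frozen=True)
class SurfaceReport:
    """Per-atom solvent-accessible surface areas (Å²)."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int
    total_area: float = field(init=False)

    def __post_init__(self) -> None:
        if np.any(self.per_atom_area < 0):
            raise ValueError("per-atom areas must be non-negative")
        object.__setattr__(self, "total_area", float(self.per_atom_area.sum()))


def _require_prepared(m: Molecule) -> None:
    if not m.prepared:
        raise ValueError(f"molecule {m.id!r} must be prepared (explicit H, 3D, charges)")


# ---------------------------------------------------------------- topology

def count_single_bonds(m: Molecule) -> int:
    """Number of single bonds, including bonds to explicit hydrogens."""
    _require_prepared(m)
    return sum(1 for b in m.bonds if b.order == "single")


def count_aromatic_bonds(m: Molecule) -> int:
    """Number of bonds flagged aromatic by the perception model."""
    _require_prepared(m)
    return sum(1 for b in m.bonds if b.order == "aromatic")


def count_element(m: Molecule, element: str) -> int:
    _require_prepared(m)
    return sum(1 for a in m.atoms if a.element == element)


def relative_count(m: Molecule, element: str) -> float:
    """Element count divided by total atom count (hydrogens included)."""
    _require_prepared(m)
    return count_element(m, element) / m.n_atoms


# --------------------------------------------------------------- electronic

def max_hydrogen_partial_charge(m: Molecule) -> float:
    """Maximum partial charge over hydrogen atoms (e).

    Returns 0 with a warning for molecules without hydrogens.
    """
    _require_prepared(m)
    h_charges = [a.partial_charge for a in m.atoms if a.is_hydrogen]
    if any(q is None for q in h_charges):
        raise ValueError(f"molecule {m.id!r} lacks partial charges")
    if not h_charges:
        logger.warning("molecule %r has no hydrogens; max H charge reported as 0", m.id)
        return 0.0
    return float(max(h_charges))


# ---------------------------------------------------------------- geometry

def gravitational_index(m: Molecule) -> float:
    """Σ_{i<j} m_i m_j / r_ij² over all atom pairs (Da²/Å²)."""
    _require_prepared(m)
    if m.n_atoms < 2:
        return 0.0
    x = m.coords
    mass = m.masses
    diff = x[:, None, :] - x[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu = np.triu_indices(m.n_atoms, k=1)
    r2 = r2[iu]
    if np.any(r2 <= 0):
        raise ValueError(f"coincident atoms in molecule {m.id!r}")
    return float(np.sum(mass[iu[0]] * mass[iu[1]] / r2))


def grav3(m: Molecule) -> float:
    """Cube root of the all-pairs gravitational index."""
    return gravitational_index(m) ** (1.0 / 3.0)


def gravitational_index_bonded(m: Molecule) -> float:
    """Bonded-pairs variant of the gravitational index (not used by the pipeline)."""
    _require_prepared(m)
    x, mass = m.coords, m.masses
    total = 0.0
    for b in m.bonds:
        r2 = float(np.sum((x[b.atom_i] - x[b.atom_j]) ** 2))
        if r2 <= 0:
            raise ValueError(f"coincident bonded atoms in molecule {m.id!r}")
        total += mass[b.atom_i] * mass[b.atom_j] / r2
    return total


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(
    m: Molecule, probe: float = 1.4, n_points: int = 960
) -> SurfaceReport:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is expanded to radius (vdW + probe) and sampled with a fixed
    Fibonacci point grid; points falling inside any neighbouring expanded
    sphere are occluded. Deterministic for fixed ``n_points``.
    """
    _require_prepared(m)
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    x = m.coords
    r = m.radii + probe
    n = m.n_atoms
    if n > 1:
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
        if np.any(d2[np.triu_indices(n, k=1)] <= 0):
            raise ValueError(f"coincident atoms in molecule {m.id!r}")
    unit = _fibonacci_sphere(n_points)
    areas = np.empty(n)
    for i in range(n):
        pts = x[i] + r[i] * unit
        if n > 1:
            neigh = np.flatnonzero((d2[i] < (r[i] + r) ** 2) & (np.arange(n) != i))
        else:
            neigh = np.array([], dtype=int)
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            exposed &= np.sum((pts - x[j]) ** 2, axis=1) > r[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * r[i] ** 2
    return SurfaceReport(per_atom_area=areas, probe_radius=probe, n_sphere_points=n_points)


def _acceptor_indices(m: Molecule, config: DescriptorConfig) -> list[int]:
    return [
        i
        for i, a in enumerate(m.atoms)
        if a.element in config.acceptor_elements and i not in config.acceptor_exclusions
    ]


def saaa(m: Molecule, surface: SurfaceReport, config: DescriptorConfig = DescriptorConfig()) -> float:
    """Mean solvent-accessible surface area per hydrogen-bond-acceptor atom (Å²).

    Acceptors are the molecule's N and O atoms by default; 0 with a warning
    when the molecule has none.
    """
    acceptors = _acceptor_indices(m, config)
    if not acceptors:
        logger.warning("molecule %r has no acceptor atoms; SAAA reported as 0", m.id)
        return 0.0
    return float(surface.per_atom_area[acceptors].mean())


def hasa2(m: Molecule, surface: SurfaceReport, config: DescriptorConfig = DescriptorConfig()) -> float:
    """Area-weighted surface charge of acceptor atoms: Σ_A |q_A|·√S_A (e·Å)."""
    acceptors = _acceptor_indices(m, config)
    if not acceptors:
        return 0.0
    q = m.charges[acceptors]
    s = surface.per_atom_area[acceptors]
    return float(np.sum(np.abs(q) * np.sqrt(s)))


def _principal_axes(x: np.ndarray) -> np.ndarray:
    """Rotate centred coordinates onto covariance principal axes.

    Axes are ordered by decreasing variance (X, Y, Z); each eigenvector's
    sign is fixed by making its largest-magnitude component positive.
    """
    centred = x - x.mean(axis=0)
    cov = np.cov(centred.T) if len(x) > 1 else np.eye(3)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    for k in range(3):
        col = vecs[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, k] = -col
    return centred @ vecs


def shadow_area(m: Molecule, grid_resolution: float = 0.1) -> tuple[float, float]:
    """(raw, normalized) YZ-plane shadow after principal-axis alignment.

    Atoms become disks of their vdW radius in the YZ plane; the union area
    is rasterised on a square grid and normalized by the disks' bounding
    rectangle. The normalized value is the SHDW-6 descriptor.
    """
    _require_prepared(m)
    if grid_resolution <= 0:
        raise ValueError("grid resolution must be positive")
    aligned = _principal_axes(m.coords)
    yz = aligned[:, 1:3]
    r = m.radii
    lo = (yz - r[:, None]).min(axis=0)
    hi = (yz + r[:, None]).max(axis=0)
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError(f"degenerate YZ bounding rectangle for molecule {m.id!r}")
    ny = max(2, int(np.ceil(extent[0] / grid_resolution)))
    nz = max(2, int(np.ceil(extent[1] / grid_resolution)))
    ys = lo[0] + (np.arange(ny) + 0.5) * extent[0] / ny
    zs = lo[1] + (np.arange(nz) + 0.5) * extent[1] / nz
    gy, gz = np.meshgrid(ys, zs, indexing="ij")
    covered = np.zeros((ny, nz), dtype=bool)
    for k in range(m.n_atoms):
        covered |= (gy - yz[k, 0]) ** 2 + (gz - yz[k, 1]) ** 2 <= r[k] ** 2
    cell = (extent[0] / ny) * (extent[1] / nz)
    raw = float(covered.sum() * cell)
    return raw, raw / float(extent[0] * extent[1])


def shdw6(m: Molecule, grid_resolution: float = 0.1) -> float:
    """Normalized YZ shadow (fraction of the bounding rectangle covered)."""
    return shadow_area(m, grid_resolution)[1]


# ------------------------------------------------------------ logP and PSA

def alogp(m: Molecule) -> float:
    """Ghose–Crippen atomic-contribution octanol/water logP."""
    _require_prepared(m)
    return float(Crippen.MolLogP(m.rdmol))


def psa(m: Molecule) -> float:
    """Ertl topological polar surface area (Å²) from N/O fragment contributions."""
    _require_prepared(m)
    return float(rdMolDescriptors.CalcTPSA(m.rdmol))


# ------------------------------------------------------------------ driver

def compute_all(m: Molecule, config: DescriptorConfig = DescriptorConfig()) -> DescriptorVector:
    """All 13 descriptor fields for one prepared molecule."""
    _require_prepared(m)
    try:
        surface = compute_sasa(m, probe=config.probe_radius, n_points=config.n_sphere_points)
        return DescriptorVector(
            nsb=count_single_bonds(m),
            nab=count_aromatic_bonds(m),
            n_oxygen=count_element(m, "O"),
            n_nitrogen=count_element(m, "N"),
            rel_oxygen=relative_count(m, "O"),
            rel_nitrogen=relative_count(m, "N"),
            max_h_charge=max_hydrogen_partial_charge(m),
            grav3=grav3(m),
            saaa=saaa(m, surface, config),
            shdw6=shdw6(m, config.grid_resolution),
            hasa2=hasa2(m, surface, config),
            alogp=alogp(m),
            psa=psa(m),
        )
    except Exception as exc:
        raise RuntimeError(f"descriptor computation failed for molecule {m.id!r}: {exc}") from exc
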