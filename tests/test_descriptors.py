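"""Descriptor engine: counts, charges, surfaces, shadows and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qspr import chem_io, descriptors as d
from conftest import make_toy


# ------------------------------------------------------- topological counts

@pytest.mark.parametrize(
    "name,nsb,nab,n_o,n_n",
    [
        ("methane", 4, 0, 0, 0),
        ("ethanol", 8, 0, 1, 0),
        ("benzene", 6, 6, 0, 0),
        ("naphthalene", 8, 11, 0, 0),
        ("aspirin", 13, 6, 4, 0),
        ("caffeine", 18, 5, 2, 4),
    ],
)
def test_hand_enumerated_counts(prepared, name, nsb, nab, n_o, n_n):
    m = prepared[name]
    assert d.count_single_bonds(m) == nsb
    assert d.count_aromatic_bonds(m) == nab
    assert d.count_element(m, "O") == n_o
    assert d.count_element(m, "N") == n_n


def test_relative_counts_use_total_atoms(prepared):
    aspirin = prepared["aspirin"]  # C9H8O4 → 21 atoms
    assert d.relative_count(aspirin, "O") == pytest.approx(4 / 21)
    caffeine = prepared["caffeine"]  # C8H10N4O2 → 24 atoms
    assert d.relative_count(caffeine, "N") == pytest.approx(4 / 24)
    assert d.relative_count(prepared["benzene"], "N") == 0.0


def test_counts_require_prepared_molecule():
    with pytest.raises(ValueError, match="prepared"):
        d.count_single_bonds(chem_io.from_smiles("CCO"))


def test_counts_invariant_under_atom_order(prepared):
    """Reversed SMILES atom order must not change any count."""
    a = chem_io.prepare_molecule(chem_io.from_smiles("OC(=O)c1ccccc1OC(C)=O", "rev"), seed=7)
    b = prepared["aspirin"]
    for fn in (d.count_single_bonds, d.count_aromatic_bonds):
        assert fn(a) == fn(b)
    for el in ("O", "N", "C"):
        assert d.count_element(a, el) == d.count_element(b, el)


# ------------------------------------------------------------------ charges

def test_max_h_charge_is_max_over_hydrogens():
    m = make_toy(
        np.eye(3) * 2.0,
        elements=["H", "H", "H"],
        charges=[0.031, 0.052, 0.047],
        masses=[1.008] * 3,
    )
    assert d.max_hydrogen_partial_charge(m) == pytest.approx(0.052)


def test_no_hydrogens_warns_and_returns_zero(prepared, caplog):
    with caplog.at_level("WARNING"):
        assert d.max_hydrogen_partial_charge(prepared["tetrafluoromethane"]) == 0.0
    assert any("no hydrogens" in r.message for r in caplog.records)


def test_hydroxyl_h_carries_max_charge(prepared):
    """In ethanol the O–H hydrogen is the most positive one."""
    m = prepared["ethanol"]
    o_idx = next(i for i, a in enumerate(m.atoms) if a.element == "O")
    oh_h = next(
        b.atom_j if b.atom_i == o_idx else b.atom_i
        for b in m.bonds
        if o_idx in (b.atom_i, b.atom_j) and any(m.atoms[k].is_hydrogen for k in (b.atom_i, b.atom_j))
    )
    assert m.atoms[oh_h].partial_charge == pytest.approx(d.max_hydrogen_partial_charge(m))


# ------------------------------------------------------ gravitational index

def brute_force_grav(m):
    total = 0.0
    for i in range(m.n_atoms):
        for j in range(i + 1, m.n_atoms):
            r2 = float(np.sum((m.coords[i] - m.coords[j]) ** 2))
            total += m.masses[i] * m.masses[j] / r2
    return total


def test_grav_single_atom_is_zero():
    assert d.gravitational_index(make_toy([[0.0, 0.0, 0.0]])) == 0.0


def test_grav_two_atom_closed_form():
    m = make_toy([[0, 0, 0], [1.54, 0, 0]], masses=[12.0, 12.0])
    g = d.gravitational_index(m)
    assert g == pytest.approx(144.0 / 1.54**2, rel=1e-12)
    assert d.grav3(m) == pytest.approx((144.0 / 1.54**2) ** (1 / 3), rel=1e-12)


def test_grav_matches_brute_force_on_fixtures(prepared):
    for m in prepared.values():
        if m.n_atoms > 1:
            assert d.gravitational_index(m) == pytest.approx(brute_force_grav(m), rel=1e-9)


def test_grav_coincident_atoms_error():
    m = make_toy([[0, 0, 0], [0, 0, 0]])
    with pytest.raises(ValueError, match="coincident"):
        d.gravitational_index(m)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(*[st.floats(-5, 5)] * 3), min_size=2, max_size=8, unique=True))
def test_grav_oracle_property(points):
    m = make_toy(points)
    assert d.gravitational_index(m) == pytest.approx(brute_force_grav(m), rel=1e-9)


# --------------------------------------------------------------------- SASA

def test_isolated_oxygen_sphere_area():
    m = make_toy([[0.0, 0.0, 0.0]], elements=["O"], masses=[15.999])
    rep = d.compute_sasa(m, probe=1.4)
    assert rep.total_area == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=0.01)


def test_separated_atoms_additivity():
    m = make_toy([[0, 0, 0], [50, 0, 0]], elements=["C", "O"], masses=[12.0, 15.999])
    rep = d.compute_sasa(m, probe=1.4)
    expected = 4 * np.pi * ((1.70 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
    assert rep.total_area == pytest.approx(expected, rel=0.01)


def test_sasa_convergence_in_n_points(prepared):
    m = prepared["ethanol"]
    a = d.compute_sasa(m, n_points=960).total_area
    b = d.compute_sasa(m, n_points=1920).total_area
    assert abs(a - b) / b < 0.005


def test_sasa_nonnegative_and_total_is_sum(prepared):
    rep = d.compute_sasa(prepared["aspirin"])
    assert np.all(rep.per_atom_area >= 0)
    assert rep.total_area == pytest.approx(rep.per_atom_area.sum())


def test_occluded_atom_has_reduced_area():
    m = make_toy([[0, 0, 0], [1.5, 0, 0]], elements=["C", "C"])
    rep = d.compute_sasa(m)
    assert rep.per_atom_area[0] < 4 * np.pi * (1.70 + 1.4) ** 2


# ------------------------------------------------------------- SAAA / HASA-2

def test_saaa_isolated_oxygen():
    m = make_toy([[0.0, 0.0, 0.0]], elements=["O"], masses=[15.999])
    rep = d.compute_sasa(m, probe=1.4)
    assert d.saaa(m, rep) == pytest.approx(4 * np.pi * 2.92**2, rel=0.01)


def test_saaa_no_acceptors_warns(prepared, caplog):
    m = prepared["hexane"]
    rep = d.compute_sasa(m)
    with caplog.at_level("WARNING"):
        assert d.saaa(m, rep) == 0.0
    assert any("no acceptor" in r.message for r in caplog.records)


def test_saaa_is_mean_over_acceptors():
    m = make_toy([[0, 0, 0], [40, 0, 0]], elements=["N", "O"], masses=[14.0, 16.0])
    rep = d.SurfaceReport(per_atom_area=np.array([10.0, 20.0]), probe_radius=1.4,
                          n_sphere_points=960)
    assert d.saaa(m, rep) == pytest.approx(15.0)


def test_hasa2_weighted_sum():
    m = make_toy([[0, 0, 0], [40, 0, 0]], elements=["N", "O"], charges=[-0.3, -0.5])
    rep = d.SurfaceReport(per_atom_area=np.array([25.0, 16.0]), probe_radius=1.4,
                          n_sphere_points=960)
    assert d.hasa2(m, rep) == pytest.approx(0.3 * 5 + 0.5 * 4)


def test_hasa2_no_acceptors_zero(prepared):
    m = prepared["hexane"]
    assert d.hasa2(m, d.compute_sasa(m)) == 0.0


def test_acceptor_exclusion_list():
    m = make_toy([[0, 0, 0], [40, 0, 0]], elements=["N", "O"], charges=[-0.3, -0.5])
    rep = d.SurfaceReport(per_atom_area=np.array([25.0, 16.0]), probe_radius=1.4,
                          n_sphere_points=960)
    cfg = d.DescriptorConfig(acceptor_exclusions=(0,))
    assert d.saaa(m, rep, cfg) == pytest.approx(16.0)
    assert d.hasa2(m, rep, cfg) == pytest.approx(0.5 * 4)


# ------------------------------------------------------------------- shadow

def mc_shadow_oracle(yz, radii, n_samples=200_000, seed=0):
    """Monte-Carlo area of a union of disks inside its bounding rectangle."""
    rng = np.random.default_rng(seed)
    lo = (yz - radii[:, None]).min(axis=0)
    hi = (yz + radii[:, None]).max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    inside = np.zeros(n_samples, dtype=bool)
    for c, r in zip(yz, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r**2
    box = float(np.prod(hi - lo))
    return inside.mean() * box, box


def _aligned_yz(m):
    x = m.coords - m.coords.mean(axis=0)
    vals, vecs = np.linalg.eigh(np.cov(x.T))
    vecs = vecs[:, np.argsort(vals)[::-1]]
    for k in range(3):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    return (x @ vecs)[:, 1:3]


def test_single_atom_shadow_is_circle_in_square():
    m = make_toy([[0.0, 0.0, 0.0]])
    assert d.shdw6(m) == pytest.approx(np.pi / 4, rel=0.01)


def test_coincident_atoms_same_shadow():
    m = make_toy([[0, 0, 0], [0, 0, 0]])
    assert d.shdw6(m) == pytest.approx(np.pi / 4, rel=0.01)


def test_shadow_in_unit_interval(prepared):
    for m in prepared.values():
        assert 0 < d.shdw6(m) <= 1


def test_shadow_matches_mc_oracle(prepared):
    for name in ("ethanol", "benzene", "aspirin"):
        m = prepared[name]
        raw, _ = d.shadow_area(m)
        mc, _ = mc_shadow_oracle(_aligned_yz(m), m.radii)
        assert raw == pytest.approx(mc, rel=0.02)


def test_shadow_translation_invariance(prepared):
    m = prepared["aspirin"]
    shifted = make_toy(
        m.coords + np.array([13.0, -4.0, 2.5]),
        elements=[a.element for a in m.atoms],
        charges=[a.partial_charge for a in m.atoms],
        masses=[a.mass for a in m.atoms],
    )
    assert d.shdw6(shifted) == pytest.approx(d.shdw6(m), rel=0.01)


def test_shadow_axis_permutation_invariance(prepared):
    m = prepared["aspirin"]
    permuted = make_toy(
        m.coords[:, [2, 0, 1]],
        elements=[a.element for a in m.atoms],
        charges=[a.partial_charge for a in m.atoms],
        masses=[a.mass for a in m.atoms],
    )
    assert d.shdw6(permuted) == pytest.approx(d.shdw6(m), rel=0.01)


def test_shadow_rejects_bad_resolution(prepared):
    with pytest.raises(ValueError, match="resolution"):
        d.shadow_area(prepared["ethanol"], grid_resolution=0.0)


# ------------------------------------------------------------- AlogP / PSA

def test_benzene_psa_zero(prepared):
    assert d.psa(prepared["benzene"]) == 0.0


def test_ethanol_psa_single_fragment(prepared):
    assert d.psa(prepared["ethanol"]) == pytest.approx(20.23, abs=0.01)


def test_alkane_alogp_monotone_in_chain_length():
    values = []
    for n in range(2, 11):
        m = chem_io.prepare_molecule(chem_io.from_smiles("C" * n), seed=3)
        values.append(d.alogp(m))
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[0] > 0


# ------------------------------------------------------------- compute_all

def test_compute_all_benzene(prepared):
    v = d.compute_all(prepared["benzene"])
    assert v.nab == 6 and v.n_oxygen == 0 and v.psa == 0.0


def test_compute_all_deterministic(prepared):
    a = d.compute_all(prepared["caffeine"])
    b = d.compute_all(prepared["caffeine"])
    assert a == b


def test_compute_all_no_nan_on_fixture_panel(prepared):
    from qspr.chem_io import DESCRIPTOR_COLUMNS

    for m in prepared.values():
        v = d.compute_all(m)
        for col in DESCRIPTOR_COLUMNS:
            assert np.isfinite(getattr(v, col)), f"{m.id}.{col}"


def test_compute_all_error_names_molecule():
    bad = make_toy([[0, 0, 0], [0, 0, 0]], mol_id="dupe")
    with pytest.raises(RuntimeError, match="dupe"):
        d.compute_all(bad)
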