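"""Structural metrics against constructed geometry and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from statecompare import mdstruct as md
from statecompare import synthetic as syn
from conftest import subset_system


def tiny_system(coords, names=None, resids=None, **kw):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return md.MolecularSystem(
        names=np.asarray(names if names is not None else ["C"] * n),
        resnames=np.asarray(kw.pop("resnames", ["X"] * n)),
        resids=np.asarray(resids if resids is not None else np.arange(1, n + 1)),
        segids=np.asarray(["A"] * n),
        frames=coords[None], **kw)


# ---------------------------------------------------------------------------
# loading


def test_load_matches_manifest_atom_count(tmp_path):
    t = syn.build_toy_structure(syn.ToySystemParams(seed=1))
    syn.write_fixtures({"s": t}, tmp_path, ground_truth={"n_atoms": t.n_atoms})
    back = md.load_system(tmp_path / "s.pdb")
    assert back.n_atoms == t.n_atoms


def test_multi_model_pdb_frames(tmp_path):
    base = syn.build_toy_structure(syn.ToySystemParams(
        pore_shape=None, helix_tilt=None))
    frames = [base]
    for dz in (0.1, 0.2, 0.3, 0.4):
        shifted = subset_system(base, np.arange(base.n_atoms))
        shifted.frames = base.frames + dz
        frames.append(shifted)
    traj = md.stack_frames(frames)
    md.write_pdb(traj, tmp_path / "traj.pdb")
    back = md.load_system(tmp_path / "traj.pdb")
    assert back.n_frames == 5


def test_energy_without_parameters_raises():
    s = tiny_system([[0, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="parameters required"):
        md.pairwise_energy(s, np.array([0]), np.array([1]))


def test_stack_frames_rejects_mismatched_atom_counts():
    a = tiny_system(np.zeros((4, 3)))
    b = tiny_system(np.zeros((5, 3)))
    with pytest.raises(ValueError):
        md.stack_frames([a, b])


# ---------------------------------------------------------------------------
# RMSD


def test_rmsd_self_is_zero():
    X = np.random.default_rng(0).normal(size=(20, 3))
    assert md.rmsd_kabsch(X, X) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_invariant_under_rigid_motion():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 3))
    R = Rotation.random(random_state=2).as_matrix()
    assert md.rmsd_kabsch(X, X @ R.T + np.array([3.0, -2.0, 7.0])) == \
        pytest.approx(0.0, abs=1e-9)


def brute_force_rmsd(A, B):
    """Independent oracle: minimise RMSD over rotations by multi-start
    local search on the rotation vector."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def f(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1)))

    best = np.inf
    for seed_rot in Rotation.random(40, random_state=3):
        res = minimize(f, seed_rot.as_rotvec(), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def test_rmsd_matches_brute_force_oracle():
    rng = np.random.default_rng(4)
    A = rng.normal(size=(4, 3)) * 3.0
    B = A + rng.normal(size=(4, 3)) * 0.4
    assert md.rmsd_kabsch(A, B) == pytest.approx(brute_force_rmsd(A, B), abs=1e-6)


def test_rmsd_requires_three_atoms():
    with pytest.raises(ValueError):
        md.rmsd_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# helix tilt & thickness


@pytest.mark.parametrize("tilt", [0.0, 30.0, 90.0])
def test_helix_tilt_constructed(tilt):
    t = syn.build_toy_structure(syn.ToySystemParams(helix_tilt=tilt))
    assert md.helix_tilt(t, (1, 18), segid="HLX")[0] == pytest.approx(tilt, abs=0.5)


def test_helix_tilt_with_corotated_normal():
    """Rigid rotation of system + normal leaves the tilt unchanged."""
    t = syn.build_toy_structure(syn.ToySystemParams(helix_tilt=30.0))
    R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
    rotated = subset_system(t, np.arange(t.n_atoms))
    rotated.frames = t.frames @ R.T
    got = md.helix_tilt(rotated, (1, 18), normal=R @ np.array([0.0, 0.0, 1.0]),
                        segid="HLX")[0]
    assert got == pytest.approx(30.0, abs=0.5)


def test_membrane_thinning_series():
    sys38 = syn.build_toy_structure(syn.ToySystemParams(
        bilayer_thickness=3.8, pore_shape=None, helix_tilt=None))
    sys26 = syn.build_toy_structure(syn.ToySystemParams(
        bilayer_thickness=2.6, pore_shape=None, helix_tilt=None))
    traj = md.stack_frames([sys38, sys26])
    series = md.membrane_thickness(traj)
    np.testing.assert_allclose(series, [3.8, 2.6], atol=1e-12)
    assert series[0] - series[1] == pytest.approx(1.2, abs=1e-12)


def test_thickness_one_leaflet_rejected():
    coords = [[i * 8.0, 0, 10.0] for i in range(6)]
    s = tiny_system(coords, names=["P"] * 6)
    with pytest.raises(ValueError, match="one leaflet"):
        md.membrane_thickness(s)


# ---------------------------------------------------------------------------
# pore profile


def test_cylinder_pore_radius():
    """Lining centres 5 A from axis, vdW 1.5 A -> free radius 3.5 A."""
    t = syn.build_toy_structure(syn.ToySystemParams(pore_radius=3.5, lining_vdw=1.5))
    prof = md.pore_profile(t, selection=t.select(resnames="POR"),
                           axis_xy=(0, 0), z_range=(-15, 15), step=1.0)
    np.testing.assert_allclose(prof.radius, 3.5, atol=0.05)


def test_cone_profile_matches_analytic_and_classes():
    t = syn.build_toy_structure(syn.ToySystemParams(
        pore_shape="cone", pore_radius=(1.0, 6.0)))
    prof = md.pore_profile(t, selection=t.select(resnames="POR"),
                           axis_xy=(0, 0), z_range=(-17, 17), step=0.5)
    half_t = 19.0
    analytic = 1.0 + 5.0 * (prof.z + half_t) / (2 * half_t)
    assert np.max(np.abs(prof.radius - analytic)) < 0.1
    assert np.all(np.diff(prof.radius) > -0.05)       # monotone within jitter
    assert {"intermediate", "open"} <= set(prof.classes)


def test_hourglass_waist_is_sub_water():
    t = syn.build_toy_structure(syn.ToySystemParams(
        pore_shape="hourglass", pore_radius=(1.0, 5.0)))
    prof = md.pore_profile(t, selection=t.select(resnames="POR"),
                           axis_xy=(0, 0), z_range=(-15, 15), step=0.5)
    assert prof.min_radius < 1.15
    waist = int(np.argmin(prof.radius))
    assert prof.classes[waist] == "sub_water"


def test_pore_slice_matches_dense_sampling_oracle():
    """Stochastic oracle: brute-force max of min_i(|p-a_i|-R_i) over the slice."""
    t = syn.build_toy_structure(syn.ToySystemParams(
        pore_shape="cone", pore_radius=(2.0, 5.0)))
    sel = t.select(resnames="POR")
    X = t.coords[sel]
    radii = t.effective_radii(sel)
    rng = np.random.default_rng(5)
    for z in (-10.0, 0.0, 10.0):
        near = np.abs(X[:, 2] - z) < 10.0      # distant rings never set the min
        Xn, rn = X[near], radii[near]
        oracle = -np.inf
        for _ in range(20):
            pts = np.column_stack([rng.uniform(-4, 4, 2000),
                                   rng.uniform(-4, 4, 2000),
                                   np.full(2000, z)])
            d = np.linalg.norm(pts[:, None, :] - Xn[None], axis=2) - rn[None, :]
            oracle = max(oracle, d.min(axis=1).max())
        prof = md.pore_profile(t, selection=sel, axis_xy=(0, 0),
                               z_range=(z, z), step=1.0)
        assert prof.radius[0] == pytest.approx(oracle, abs=0.1)


# ---------------------------------------------------------------------------
# solvent density


def test_uniformly_filled_pore_is_hydrated():
    t = syn.build_toy_structure(syn.ToySystemParams(
        n_waters_in_pore=1500, n_bulk_waters=1500, seed=6))
    prof = md.solvent_density_profile(t, cylinder_radius=4.0, axis_xy=(0, 0),
                                      bin_width=2.0)
    assert prof.hydrated
    assert prof.bulk_density > 0


def test_dewetted_band_flags_vapor_lock():
    t = syn.build_toy_structure(syn.ToySystemParams(
        n_waters_in_pore=1500, n_bulk_waters=1500, seed=6))
    waters = t.select(resnames="HOH")
    band = waters[np.abs(t.coords[waters, 2]) < 5.0]
    keep = np.setdiff1d(np.arange(t.n_atoms), band)
    dewetted = subset_system(t, keep)
    prof = md.solvent_density_profile(dewetted, cylinder_radius=4.0,
                                      axis_xy=(0, 0), bin_width=2.0)
    assert not prof.hydrated
    in_band = np.abs(prof.z) < 4.0
    assert np.all(prof.density[in_band] == 0.0)


def test_bin_halving_conserves_water_count():
    t = syn.build_toy_structure(syn.ToySystemParams(
        n_waters_in_pore=800, n_bulk_waters=800, seed=8))
    zr = (-45.0, 45.0)
    p1 = md.solvent_density_profile(t, cylinder_radius=6.0, axis_xy=(0, 0),
                                    bin_width=1.0, z_range=zr)
    p2 = md.solvent_density_profile(t, cylinder_radius=6.0, axis_xy=(0, 0),
                                    bin_width=0.5, z_range=zr)
    n1, n2 = p1.water_count.sum(), p2.water_count.sum()
    assert abs(n1 - n2) / n1 < 0.01


# ---------------------------------------------------------------------------
# contacts


def test_single_contact_counted_once():
    coords = [[0, 0, 0], [20, 0, 0], [3.9, 0, 0]]
    s = tiny_system(coords, names=["CA", "CA", "C1"],
                    resnames=["ALA", "ALA", "LIP"], resids=[1, 2, 50])
    cm = md.lipid_contacts(s, s.select(resnames="ALA"), s.select(resnames="LIP"))
    counts = cm.series()
    assert counts[1] == 1.0
    assert counts[2] == 0.0


def test_identical_conditions_zero_relative_difference():
    t = syn.build_toy_structure(syn.ToySystemParams(seed=9))
    cm = md.lipid_contacts(t, t.select(segids="HLX"), t.select(resnames="LIP"))
    rd = md.relative_difference(cm, cm)
    assert np.all(rd["relative_difference"] == 0.0)
    assert np.all(rd["abs_difference"] == 0.0)


def test_planted_gains_and_losses_recovered_by_sign():
    """Red/blue sign map of contact changes reproduces the plant exactly."""
    base = [[i * 20.0, 0, 0] for i in range(6)]
    protein = tiny_system(base, names=["CA"] * 6, resnames=["ALA"] * 6)

    def with_lipids(contact_resids):
        coords = list(base)
        names = ["CA"] * 6
        resnames = ["ALA"] * 6
        resids = list(range(1, 7))
        rid = 100
        for r in contact_resids:
            coords.append([(r - 1) * 20.0 + 3.5, 0, 0])
            names.append("C1"); resnames.append("LIP"); rid += 1; resids.append(rid)
        return tiny_system(coords, names=names, resnames=resnames, resids=resids)

    ref = with_lipids([1, 2, 3])          # residues 1-3 have contacts
    tension = with_lipids([4, 5, 6])      # contacts move to residues 4-6
    cm_ref = md.lipid_contacts(ref, ref.select(resnames="ALA"),
                               ref.select(resnames="LIP"))
    cm_ten = md.lipid_contacts(tension, tension.select(resnames="ALA"),
                               tension.select(resnames="LIP"))
    rd = md.relative_difference(cm_ten, cm_ref).set_index("resid")
    for r in (1, 2, 3):
        assert rd.loc[r, "relative_difference"] < 0
    for r in (4, 5, 6):
        assert rd.loc[r, "relative_difference"] > 0


def test_empty_selection_rejected():
    s = tiny_system([[0, 0, 0]])
    with pytest.raises(ValueError, match="empty selection"):
        md.lipid_contacts(s, np.array([], dtype=int), np.array([0]))


# ---------------------------------------------------------------------------
# order parameters


def test_all_trans_vertical_chains_scd():
    t = syn.build_toy_structure(syn.ToySystemParams(
        chain_tilt=0.0, pore_shape=None, helix_tilt=None))
    op = md.order_parameters(t, syn.TOY_CHAIN_MAP)
    np.testing.assert_allclose(op.table["s_cd"], -0.5, atol=1e-12)


def test_isotropic_orientations_average_to_zero():
    rng = np.random.default_rng(10)
    n = 10000
    c = rng.normal(size=(n, 3)) * 30.0
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    coords = np.empty((2 * n, 3))
    coords[0::2] = c
    coords[1::2] = c + 1.09 * v
    names = np.array(["C1", "H1A"] * n)
    resids = np.repeat(np.arange(1, n + 1), 2)
    s = tiny_system(coords, names=names, resids=resids,
                    resnames=["LIP"] * (2 * n))
    op = md.order_parameters(s, {"C1": ["H1A"]})
    assert op.table.loc[0, "s_cd"] == pytest.approx(0.0, abs=0.02)


def test_horizontal_chains_less_ordered_than_vertical():
    """Tension-style horizontal reorientation drives |S_CD| down."""
    vert = syn.build_toy_structure(syn.ToySystemParams(
        chain_tilt=0.0, pore_shape=None, helix_tilt=None))
    horiz = syn.build_toy_structure(syn.ToySystemParams(
        chain_tilt=90.0, pore_shape=None, helix_tilt=None))
    s_vert = md.order_parameters(vert, syn.TOY_CHAIN_MAP).table["s_cd"]
    s_horiz = md.order_parameters(horiz, syn.TOY_CHAIN_MAP).table["s_cd"]
    # azimuth-averaged closed form: S(t) = (3 sin^2(t)/2 - 1) / 2
    assert np.all(np.abs(s_horiz) < np.abs(s_vert))
    np.testing.assert_allclose(s_horiz, 0.25, atol=0.02)


def test_missing_hydrogens_warns_and_omits():
    s = tiny_system([[0, 0, 0]], names=["C1"], resnames=["LIP"])
    with pytest.warns(UserWarning, match="omitted"):
        op = md.order_parameters(s, {"C1": ["H1A"]})
    assert len(op.table) == 0


# ---------------------------------------------------------------------------
# SASA


def test_isolated_atom_sasa_closed_form():
    s = tiny_system([[0, 0, 0]], radii=np.array([1.7]))
    area = md.pocket_sasa(s, [1], probe=1.4, n_points=960, frame=0)
    assert area == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.01)


def test_fused_spheres_bury_surface():
    s2 = tiny_system([[0, 0, 0], [1.5, 0, 0]], radii=np.array([1.7, 1.7]))
    area2 = md.pocket_sasa(s2, [1, 2], frame=0)
    single = 4 * math.pi * (1.7 + 1.4) ** 2
    assert area2 < 2 * single


def test_collapsed_pocket_has_smaller_area():
    rng = np.random.default_rng(11)
    ring = np.array([[8 * math.cos(a), 8 * math.sin(a), z]
                     for z in (-2.0, 0.0, 2.0)
                     for a in np.linspace(0, 2 * math.pi, 12, endpoint=False)])
    open_sys = tiny_system(ring, radii=np.full(len(ring), 1.7))
    collapsed = ring.copy()
    collapsed[:, :2] *= (8 - 3) / 8          # lining moved 3 A inward
    closed_sys = tiny_system(collapsed, radii=np.full(len(ring), 1.7))
    resids = list(range(1, len(ring) + 1))
    assert md.pocket_sasa(closed_sys, resids, frame=0) < \
        md.pocket_sasa(open_sys, resids, frame=0)


def test_sasa_empty_residue_list_rejected():
    s = tiny_system([[0, 0, 0]])
    with pytest.raises(ValueError):
        md.pocket_sasa(s, [])


# ---------------------------------------------------------------------------
# pairwise energies


def param_system(coords, charges, sigmas, epsilons):
    s = tiny_system(coords)
    s.charges = np.asarray(charges, dtype=float)
    s.sigmas = np.asarray(sigmas, dtype=float)
    s.epsilons = np.asarray(epsilons, dtype=float)
    return s


def test_lj_minimum_energy():
    r = 2 ** (1 / 6) * 3.4
    s = param_system([[0, 0, 0], [r, 0, 0]], [0, 0], [3.4, 3.4], [0.8, 0.8])
    e = md.pairwise_energy(s, np.array([0]), np.array([1]))
    assert e.lj == pytest.approx(-0.8, rel=1e-12)
    assert e.coulomb == 0.0
    assert e.total == pytest.approx(e.lj + e.coulomb)


def test_coulomb_unit_charges_at_ten_angstrom():
    s = param_system([[0, 0, 0], [10.0, 0, 0]], [1.0, -1.0], [1.0, 1.0], [0.0, 0.0])
    e = md.pairwise_energy(s, np.array([0]), np.array([1]))
    assert e.coulomb == pytest.approx(-138.935458, rel=1e-6)


def test_energy_matches_brute_force_double_loop():
    rng = np.random.default_rng(12)
    coords = rng.uniform(-4, 4, size=(5, 3))
    q = rng.uniform(-0.5, 0.5, 5)
    sig = rng.uniform(2.5, 3.5, 5)
    eps = rng.uniform(0.1, 0.9, 5)
    s = param_system(coords, q, sig, eps)
    ga, gb = np.array([0, 1]), np.array([2, 3, 4])
    e = md.pairwise_energy(s, ga, gb, cutoff=50.0)
    elj = ec = 0.0
    for i in ga:
        for j in gb:
            r = np.linalg.norm(coords[i] - coords[j])
            sij = 0.5 * (sig[i] + sig[j])
            eij = math.sqrt(eps[i] * eps[j])
            elj += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
            ec += 1389.35458 * q[i] * q[j] / r
    assert e.lj == pytest.approx(elj, abs=1e-9)
    assert e.coulomb == pytest.approx(ec, abs=1e-9)


def test_energy_symmetric_and_additive():
    rng = np.random.default_rng(13)
    coords = rng.uniform(-5, 5, size=(6, 3))
    s = param_system(coords, rng.uniform(-0.3, 0.3, 6),
                     rng.uniform(2.5, 3.5, 6), rng.uniform(0.1, 0.5, 6))
    ga, gb = np.array([0, 1]), np.array([2, 3, 4, 5])
    e_ab = md.pairwise_energy(s, ga, gb, cutoff=50.0)
    e_ba = md.pairwise_energy(s, gb, ga, cutoff=50.0)
    assert e_ab.total == pytest.approx(e_ba.total, rel=1e-12)
    e1 = md.pairwise_energy(s, ga, np.array([2, 3]), cutoff=50.0)
    e2 = md.pairwise_energy(s, ga, np.array([4, 5]), cutoff=50.0)
    assert e_ab.total == pytest.approx(e1.total + e2.total, rel=1e-12)


def test_doubling_epsilon_doubles_lj_exactly():
    rng = np.random.default_rng(14)
    coords = rng.uniform(-5, 5, size=(6, 3))
    eps = rng.uniform(0.1, 0.5, 6)
    s1 = param_system(coords, np.zeros(6), np.full(6, 3.2), eps)
    eps2 = eps.copy()
    eps2[2:] *= 4.0          # eps_ij = sqrt(eps_i eps_j): x4 on B doubles eps_ij
    s2 = param_system(coords, np.zeros(6), np.full(6, 3.2), eps2)
    ga, gb = np.array([0, 1]), np.array([2, 3, 4, 5])
    e1 = md.pairwise_energy(s1, ga, gb, cutoff=50.0)
    e2 = md.pairwise_energy(s2, ga, gb, cutoff=50.0)
    assert e2.lj == pytest.approx(2.0 * e1.lj, rel=1e-12)
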