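"""Structural metrics for membrane-channel systems and toy fixtures.

Operates on a light-weight :class:`MolecularSystem` (names, residues,
coordinates in Angstrom, optional frames, vdW radii and nonbonded
parameters) loaded from single- or multi-model PDB files via MDAnalysis.
Provides the metrics used to characterise channel gating states: Kabsch
RMSD, helix tilt, phosphate-to-phosphate membrane thickness, largest-sphere
pore radius profiles with water-passage classification, axial solvent
density, residue-lipid contact maps and their relative differences, acyl
S_CD order parameters, Shrake-Rupley pocket surface area, and pairwise
Lennard-Jones/Coulomb group-group energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = [
    "MolecularSystem",
    "PoreProfile",
    "DensityProfile",
    "ContactMap",
    "OrderParameters",
    "PairwiseEnergy",
    "load_system",
    "write_pdb",
    "stack_frames",
    "rmsd_kabsch",
    "helix_tilt",
    "membrane_thickness",
    "pore_profile",
    "solvent_density_profile",
    "lipid_contacts",
    "relative_difference",
    "order_parameters",
    "pocket_sasa",
    "pairwise_energy",
    "DEFAULT_VDW",
]

#: Coulomb prefactor e^2/(4 pi eps0), kJ mol^-1 A e^-2 (138.935458 kJ/mol at 1 nm)
COULOMB_KJ_A = 1389.35458

#: pore-radius classes (A): below the first threshold water cannot pass,
#: above the second it passes freely
PORE_CLASS_THRESHOLDS = (1.15, 2.3)

#: element-based fallback vdW radii, A
DEFAULT_VDW = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}

WATER_RESNAMES = {"HOH", "SOL", "TIP3", "WAT"}


@dataclass
class MolecularSystem:
    """Atoms + optional frames; the substrate of every metric here."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    segids: np.ndarray
    frames: np.ndarray                     # (n_frames, n_atoms, 3), A
    box: np.ndarray | None = None          # (3,), A
    radii: np.ndarray | None = None        # A
    charges: np.ndarray | None = None      # e
    sigmas: np.ndarray | None = None       # A
    epsilons: np.ndarray | None = None     # kJ/mol

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        n = self.frames.shape[1]
        for arr_name in ("names", "resnames", "resids", "segids"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.shape[0] != n:
                raise ValueError(f"{arr_name} length {arr.shape[0]} != atom count {n}")
            setattr(self, arr_name, arr)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii[np.isfinite(self.radii)] <= 0):
                raise ValueError("vdW radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Frame-0 coordinates (A)."""
        return self.frames[0]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]

    def select(self, names=None, resnames=None, resids=None, segids=None,
               exclude_h: bool = False) -> np.ndarray:
        """Boolean-AND selection; each criterion is a value or sequence."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for arr, crit in ((self.names, names), (self.resnames, resnames),
                          (self.resids, resids), (self.segids, segids)):
            if crit is None:
                continue
            if np.isscalar(crit) or isinstance(crit, str):
                crit = [crit]
            mask &= np.isin(arr, np.asarray(list(crit)))
        if exclude_h:
            mask &= ~np.char.startswith(self.names.astype(str), "H")
        return np.nonzero(mask)[0]

    def effective_radii(self, idx=None) -> np.ndarray:
        """Per-atom vdW radii; element-guessed defaults fill missing values."""
        idx = np.arange(self.n_atoms) if idx is None else np.asarray(idx)
        out = np.empty(len(idx))
        for j, i in enumerate(idx):
            r = self.radii[i] if self.radii is not None else np.nan
            if not np.isfinite(r):
                elem = str(self.names[i])[0].upper()
                r = DEFAULT_VDW.get(elem, 1.7)
            out[j] = r
        return out


@dataclass
class PoreProfile:
    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray                  # (n, 2)
    classes: list[str]

    @property
    def min_radius(self) -> float:
        return float(np.min(self.radius))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "radius_A": self.radius,
                             "class": self.classes})


@dataclass
class DensityProfile:
    z: np.ndarray
    water_count: np.ndarray
    density: np.ndarray                    # nm^-3
    bulk_density: float
    hydrated_bins: np.ndarray
    hydrated: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "water_count": self.water_count,
                             "density_nm3": self.density,
                             "hydrated": self.hydrated_bins})


@dataclass
class ContactMap:
    counts: pd.DataFrame                   # resid, mean_contacts

    def series(self) -> pd.Series:
        return self.counts.set_index("resid")["mean_contacts"]


@dataclass
class OrderParameters:
    table: pd.DataFrame                    # carbon, s_cd, n_samples
    selection: str = "all"


@dataclass
class PairwiseEnergy:
    coulomb: float
    lj: float
    total: float
    sd_coulomb: float = 0.0
    sd_lj: float = 0.0
    sd_total: float = 0.0
    per_frame: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# I/O


def load_system(structure_path, trajectory_path=None,
                parameter_table=None) -> MolecularSystem:
    """Load a (multi-model) PDB, optional trajectory and parameter CSV.

    The parameter CSV maps (resname, name) -> sigma_A, epsilon_kJmol,
    charge_e, vdw_A; missing entries stay NaN and fall back to element
    defaults where a metric allows it.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is not None:
            u = mda.Universe(str(structure_path), str(trajectory_path))
        else:
            u = mda.Universe(str(structure_path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = np.array(u.dimensions[:3], dtype=float)
        names = u.atoms.names.astype(str)
        resnames = u.atoms.resnames.astype(str)
        resids = u.atoms.resids.astype(int)
        try:
            segids = u.atoms.segids.astype(str)
        except (AttributeError, mda.exceptions.NoDataError):
            segids = np.array([""] * len(names))

    sys = MolecularSystem(names=names, resnames=resnames, resids=resids,
                          segids=segids, frames=frames, box=box)
    if parameter_table is not None:
        apply_parameter_table(sys, parameter_table)
    return sys


def apply_parameter_table(system: MolecularSystem, table) -> None:
    """Attach sigma/epsilon/charge/vdw from a CSV or DataFrame keyed on
    (resname, name)."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    lut = {(str(r["resname"]), str(r["name"])): r for _, r in df.iterrows()}
    n = system.n_atoms
    sig = np.full(n, np.nan)
    eps = np.full(n, np.nan)
    chg = np.full(n, np.nan)
    vdw = np.full(n, np.nan)
    for i in range(n):
        row = lut.get((str(system.resnames[i]), str(system.names[i])))
        if row is None:
            continue
        sig[i] = row.get("sigma_A", np.nan)
        eps[i] = row.get("epsilon_kJmol", np.nan)
        chg[i] = row.get("charge_e", np.nan)
        vdw[i] = row.get("vdw_A", np.nan)
    system.sigmas, system.epsilons, system.charges, system.radii = sig, eps, chg, vdw


def write_pdb(system: MolecularSystem, path) -> None:
    """Write as (multi-model, when several frames) PDB via MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        resid_keys = list(dict.fromkeys(
            zip(system.segids.tolist(), system.resids.tolist())))
        res_index = {k: i for i, k in enumerate(resid_keys)}
        atom_res = np.array([res_index[(s, r)] for s, r in
                             zip(system.segids.tolist(), system.resids.tolist())])
        seg_keys = list(dict.fromkeys(system.segids.tolist()))
        seg_index = {k: i for i, k in enumerate(seg_keys)}
        res_seg = np.array([seg_index[k[0]] for k in resid_keys])
        u = mda.Universe.empty(system.n_atoms, n_residues=len(resid_keys),
                               n_segments=len(seg_keys),
                               atom_resindex=atom_res,
                               residue_segindex=res_seg, trajectory=True)
        u.add_TopologyAttr("names", system.names.astype(str))
        u.add_TopologyAttr(
            "resnames",
            [str(system.resnames[np.nonzero(atom_res == i)[0][0]])
             for i in range(len(resid_keys))])
        u.add_TopologyAttr("resids", [k[1] for k in resid_keys])
        u.add_TopologyAttr("segids", [k or "SYS" for k in seg_keys])
        if system.box is not None:
            u.dimensions = [*system.box, 90.0, 90.0, 90.0]
        with mda.Writer(str(path), multiframe=system.n_frames > 1,
                        n_atoms=system.n_atoms) as w:
            for f in range(system.n_frames):
                u.atoms.positions = system.frames[f]
                w.write(u.atoms)


def stack_frames(systems: Sequence[MolecularSystem]) -> MolecularSystem:
    """Concatenate equal-topology systems into one multi-frame trajectory."""
    first = systems[0]
    for s in systems[1:]:
        if s.n_atoms != first.n_atoms:
            raise ValueError("frame atom counts differ")
    frames = np.concatenate([s.frames for s in systems], axis=0)
    return MolecularSystem(names=first.names, resnames=first.resnames,
                           resids=first.resids, segids=first.segids,
                           frames=frames, box=first.box, radii=first.radii,
                           charges=first.charges, sigmas=first.sigmas,
                           epsilons=first.epsilons)


# ---------------------------------------------------------------------------
# RMSD & geometry


def rmsd_kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal-superposition RMSD (A) between paired coordinate sets."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = A @ R.T - B
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def rmsd_trajectory(system: MolecularSystem, ref_frame: int = 0,
                    selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame Kabsch RMSD to a reference frame."""
    idx = np.arange(system.n_atoms) if selection is None else selection
    ref = system.frames[ref_frame][idx]
    return np.array([rmsd_kabsch(system.frames[f][idx], ref)
                     for f in range(system.n_frames)])


def helix_tilt(system: MolecularSystem, residue_range: tuple[int, int],
               normal: np.ndarray = (0.0, 0.0, 1.0),
               segid: str | None = None) -> np.ndarray:
    """Angle (deg, per frame) between a helix's Calpha principal axis and
    the membrane normal, folded into [0, 90]."""
    resids = np.arange(residue_range[0], residue_range[1] + 1)
    idx = system.select(names="CA", resids=resids, segids=segid)
    if len(idx) < 6:
        raise ValueError(f"need >= 6 CA atoms in range {residue_range}, got {len(idx)}")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    out = []
    for f in range(system.n_frames):
        X = system.frames[f][idx]
        # average out the ~3.6-residue helical wobble before the axis fit;
        # otherwise the phase of a short helix biases the principal axis
        if len(X) >= 8:
            kern = np.ones(4) / 4.0
            X = np.column_stack([np.convolve(X[:, c], kern, mode="valid")
                                 for c in range(3)])
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        axis = Vt[0]
        cosang = abs(float(np.dot(axis, n)))
        out.append(math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))))
    return np.array(out)


def membrane_thickness(system: MolecularSystem,
                       phosphate_selection: dict | None = None) -> np.ndarray:
    """Mean upper-leaflet minus mean lower-leaflet phosphate z, nm, per frame.

    Leaflets are split by the sign of z relative to the phosphate midplane.
    """
    sel = phosphate_selection or {"names": "P"}
    idx = system.select(**sel)
    if len(idx) == 0:
        raise ValueError("no phosphate atoms matched the selection")
    out = []
    for f in range(system.n_frames):
        z = system.frames[f][idx, 2]
        mid = z.mean()
        upper, lower = z[z > mid], z[z <= mid]
        if len(upper) == 0 or len(lower) == 0:
            raise ValueError("all phosphates in one leaflet")
        out.append((upper.mean() - lower.mean()) / 10.0)
    return np.array(out)


# ---------------------------------------------------------------------------
# pore & solvent


def _free_radius(point, tree, radii, k):
    d, i = tree.query(point, k=k)
    return float(np.min(d - radii[i]))


def pore_profile(system: MolecularSystem, selection: np.ndarray | None = None,
                 axis_xy: tuple[float, float] | None = None,
                 z_range: tuple[float, float] | None = None,
                 step: float = 0.25, frame: int = 0,
                 search_bound: float = 15.0) -> PoreProfile:
    """Largest-sphere pore radius along z (HOLE-style).

    At each z slice, radius(z) = max over in-plane (x, y) of
    min_i(|p - a_i| - R_i) over the pore-lining atoms; the maximiser is found
    by local search seeded from the previous slice centre.  Slices are
    classified by the water-passage thresholds (1.15 A / 2.3 A).
    """
    if selection is None:
        selection = system.select()
        keep = ~np.isin(system.resnames[selection], list(WATER_RESNAMES))
        selection = selection[keep]
    if len(selection) == 0:
        raise ValueError("empty pore-lining selection")
    X = system.frames[frame][selection]
    radii = system.effective_radii(selection)
    tree = cKDTree(X)
    k = min(64, len(X))
    if axis_xy is None:
        axis_xy = (float(X[:, 0].mean()), float(X[:, 1].mean()))
    if z_range is None:
        z_range = (float(X[:, 2].min()), float(X[:, 2].max()))
    zs = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    centers, radii_out, classes = [], [], []
    seed = np.array(axis_xy, dtype=float)
    for z in zs:
        def neg_f(xy, z=z):
            return -_free_radius(np.array([xy[0], xy[1], z]), tree, radii, k)

        best = None
        for s in (seed, np.array(axis_xy)):
            res = minimize(neg_f, s, method="Nelder-Mead",
                           options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
            if np.linalg.norm(res.x - np.array(axis_xy)) > search_bound:
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            r, c = float("inf"), np.array(axis_xy)
        else:
            r, c = -float(best.fun), best.x
            seed = c
        centers.append(c)
        radii_out.append(max(r, 0.0))
        classes.append(_pore_class(r))
    return PoreProfile(z=zs, radius=np.array(radii_out),
                       center_xy=np.array(centers), classes=classes)


def _pore_class(r: float) -> str:
    lo, hi = PORE_CLASS_THRESHOLDS
    if not np.isfinite(r):
        return "open"
    if r < lo:
        return "sub_water"
    if r > hi:
        return "open"
    return "intermediate"


def solvent_density_profile(system: MolecularSystem,
                            water_selection: dict | None = None,
                            cylinder_radius: float = 8.0,
                            bin_width: float = 0.5,
                            axis_xy: tuple[float, float] | None = None,
                            z_range: tuple[float, float] | None = None,
                            membrane_zrange: tuple[float, float] | None = None,
                            hydration_fraction: float = 0.2,
                            frame: int = 0) -> DensityProfile:
    """Water number density along the pore axis, in a cylinder of the given
    radius, with bulk calibration from bins outside the membrane span.

    ``hydrated`` overall iff the minimum in-membrane density is at least
    ``hydration_fraction`` of bulk (a dewetted vapor lock drops to ~0).
    """
    wsel = water_selection or {"resnames": sorted(WATER_RESNAMES), "names": ["O", "OW", "OH2"]}
    idx = system.select(**wsel)
    if len(idx) == 0:
        raise ValueError("no water atoms matched the selection")
    W = system.frames[frame][idx]
    if axis_xy is None:
        non_w = system.select()
        non_w = non_w[~np.isin(system.resnames[non_w], list(WATER_RESNAMES))]
        ref = system.frames[frame][non_w] if len(non_w) else W
        axis_xy = (float(ref[:, 0].mean()), float(ref[:, 1].mean()))
    r_xy = np.hypot(W[:, 0] - axis_xy[0], W[:, 1] - axis_xy[1])
    inside = r_xy <= cylinder_radius
    if z_range is None:
        z_range = (float(W[:, 2].min()) - bin_width, float(W[:, 2].max()) + bin_width)
    edges = np.arange(z_range[0], z_range[1] + bin_width, bin_width)
    counts, _ = np.histogram(W[inside, 2], bins=edges)
    zc = 0.5 * (edges[:-1] + edges[1:])
    vol_nm3 = math.pi * cylinder_radius ** 2 * bin_width / 1000.0
    density = counts / vol_nm3
    if membrane_zrange is None:
        p_idx = system.select(names="P")
        if len(p_idx):
            pz = system.frames[frame][p_idx, 2]
            membrane_zrange = (float(pz.min()), float(pz.max()))
        else:
            span = z_range[1] - z_range[0]
            membrane_zrange = (z_range[0] + 0.25 * span, z_range[1] - 0.25 * span)
    in_mem = (zc >= membrane_zrange[0]) & (zc <= membrane_zrange[1])
    bulk_bins = ~in_mem
    if not np.any(bulk_bins):
        raise ValueError("no bins outside the membrane span for bulk calibration")
    bulk = float(np.mean(density[bulk_bins]))
    if bulk <= 0:
        raise ValueError("zero bulk density; cannot calibrate hydration")
    hydrated_bins = density >= hydration_fraction * bulk
    hydrated = bool(np.all(hydrated_bins[in_mem])) if np.any(in_mem) else True
    return DensityProfile(z=zc, water_count=counts, density=density,
                          bulk_density=bulk, hydrated_bins=hydrated_bins,
                          hydrated=hydrated)


# ---------------------------------------------------------------------------
# contacts, order parameters


def lipid_contacts(system: MolecularSystem, protein_selection: np.ndarray,
                   lipid_selection: np.ndarray, cutoff: float = 4.0) -> ContactMap:
    """Mean per-residue heavy-atom contact count with lipids.

    A contact is a (protein heavy atom, lipid heavy atom) pair within the
    cutoff; counts are summed per protein residue and averaged over frames.
    """
    if len(protein_selection) == 0 or len(lipid_selection) == 0:
        raise ValueError("empty selection")
    pres = system.resids[protein_selection]
    uniq = np.unique(pres)
    acc = {r: 0.0 for r in uniq}
    for f in range(system.n_frames):
        P = system.frames[f][protein_selection]
        L = system.frames[f][lipid_selection]
        tree = cKDTree(L)
        neighbours = tree.query_ball_point(P, r=cutoff)
        for res, nb in zip(pres, neighbours):
            acc[res] += len(nb)
    rows = [(int(r), acc[r] / system.n_frames) for r in uniq]
    return ContactMap(counts=pd.DataFrame(rows, columns=["resid", "mean_contacts"]))


def relative_difference(map_tension: ContactMap, map_ref: ContactMap) -> pd.DataFrame:
    """Per-residue contact change between conditions.

    Reports the absolute difference, the per-residue relative difference
    (C_t - C_r) / max(C_r, 1), and a per-panel-maximum normalisation
    (C_t - C_r) / max_r(C_r); rows where the reference count is 0 are
    flagged ``undefined_reference``.
    """
    a = map_tension.series()
    b = map_ref.series()
    resids = sorted(set(a.index) | set(b.index))
    ct = a.reindex(resids).fillna(0.0)
    cr = b.reindex(resids).fillna(0.0)
    max_ref = float(cr.max()) if float(cr.max()) > 0 else 1.0
    out = pd.DataFrame({
        "resid": resids,
        "contacts_tension": ct.values,
        "contacts_ref": cr.values,
        "abs_difference": (ct - cr).values,
        "relative_difference": ((ct - cr) / np.maximum(cr, 1.0)).values,
        "relative_to_max": ((ct - cr) / max_ref).values,
        "undefined_reference": (cr.values == 0),
    })
    return out


def order_parameters(system: MolecularSystem, chain_atom_map: dict,
                     lipid_resids: np.ndarray | None = None,
                     normal: np.ndarray = (0.0, 0.0, 1.0),
                     selection: str = "all") -> OrderParameters:
    """Acyl-chain deuterium order parameters S_CD per carbon.

    ``chain_atom_map`` maps each chain carbon name to its attached hydrogen
    names, e.g. ``{"C2": ["H2R", "H2S"], ...}``.  S_CD = <(3 cos^2 theta - 1)/2>
    with theta the C-H angle to the bilayer normal, averaged over hydrogens,
    lipids and frames.  Carbons with no resolvable hydrogens are omitted with
    a warning.
    """
    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    rows = []
    for carbon, hydrogens in chain_atom_map.items():
        vals = []
        for f in range(system.n_frames):
            X = system.frames[f]
            c_idx = system.select(names=carbon, resids=lipid_resids)
            for ci in c_idx:
                resid = system.resids[ci]
                for hname in hydrogens:
                    h_idx = system.select(names=hname, resids=[resid])
                    for hi in h_idx:
                        v = X[hi] - X[ci]
                        norm = np.linalg.norm(v)
                        if norm == 0:
                            continue
                        cos = np.dot(v, n) / norm
                        vals.append(0.5 * (3 * cos ** 2 - 1))
        if not vals:
            warnings.warn(f"no hydrogens found for carbon {carbon!r}; omitted")
            continue
        rows.append((carbon, float(np.mean(vals)), len(vals)))
    return OrderParameters(table=pd.DataFrame(rows, columns=["carbon", "s_cd", "n_samples"]),
                           selection=selection)


# ---------------------------------------------------------------------------
# SASA & energies


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def pocket_sasa(system: MolecularSystem, pocket_residues: Sequence[int],
                probe: float = 1.4, n_points: int = 960,
                frame: int | None = None) -> np.ndarray | float:
    """Shrake-Rupley accessible surface area (A^2) summed over residues.

    All atoms of the system occlude; the area is accumulated only for atoms
    belonging to ``pocket_residues``.  Returns per-frame values (array) or a
    scalar when ``frame`` is given.
    """
    if len(pocket_residues) == 0:
        raise ValueError("empty pocket residue list")
    pocket_idx = system.select(resids=list(pocket_residues))
    if len(pocket_idx) == 0:
        raise ValueError("pocket residues match no atoms")
    all_radii = system.effective_radii()
    pts = _sphere_points(n_points)
    frames = range(system.n_frames) if frame is None else [frame]
    out = []
    for f in frames:
        X = system.frames[f]
        tree = cKDTree(X)
        total = 0.0
        rmax = float(all_radii.max()) + probe
        for i in pocket_idx:
            ri = all_radii[i] + probe
            surface = X[i] + ri * pts
            nb = tree.query_ball_point(X[i], r=ri + rmax)
            nb = [j for j in nb if j != i]
            if nb:
                d = np.linalg.norm(surface[:, None, :] - X[nb][None, :, :], axis=2)
                buried = np.any(d < (all_radii[nb] + probe)[None, :], axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
            total += frac * 4.0 * math.pi * ri ** 2
        out.append(total)
    return float(out[0]) if frame is not None else np.array(out)


def pairwise_energy(system: MolecularSystem, group_a: np.ndarray,
                    group_b: np.ndarray, window_frames: Sequence[int] | None = None,
                    cutoff: float = 12.0) -> PairwiseEnergy:
    """Pairwise Lennard-Jones + Coulomb energy between two atom groups.

    E_LJ = sum 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6] with Lorentz-Berthelot
    combining (sig_ij arithmetic, eps_ij geometric), E_C = f q_i q_j / r with
    f = e^2/(4 pi eps0) = 138.935458 kJ/mol at 1 nm; plain distance cutoff
    (no switching).  Mean +/- sd over the analysis window of frames.
    """
    for name, arr in (("charges", system.charges), ("sigmas", system.sigmas),
                      ("epsilons", system.epsilons)):
        if arr is None:
            raise ValueError(f"parameters required: system has no {name}")
        need = np.concatenate([group_a, group_b])
        bad = need[~np.isfinite(np.asarray(arr)[need])]
        if len(bad):
            names = [f"{system.resnames[i]}:{system.names[i]}" for i in bad[:5]]
            raise ValueError(f"missing {name} for atoms {names}")
    if window_frames is None:
        window_frames = range(system.n_frames)
    qa, qb = system.charges[group_a], system.charges[group_b]
    sa, sb = system.sigmas[group_a], system.sigmas[group_b]
    ea, eb = system.epsilons[group_a], system.epsilons[group_b]
    sig_ij = 0.5 * (sa[:, None] + sb[None, :])
    eps_ij = np.sqrt(ea[:, None] * eb[None, :])
    qq = qa[:, None] * qb[None, :]
    ec_l, elj_l = [], []
    for f in window_frames:
        A = system.frames[f][group_a]
        B = system.frames[f][group_b]
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
        within = (d <= cutoff) & (d > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where(within, (sig_ij / np.where(within, d, 1.0)) ** 6, 0.0)
            elj = float(np.sum(4.0 * eps_ij * (sr6 ** 2 - sr6) * within))
            ec = float(np.sum(np.where(within, COULOMB_KJ_A * qq / np.where(within, d, 1.0), 0.0)))
        ec_l.append(ec)
        elj_l.append(elj)
    ec_a, elj_a = np.array(ec_l), np.array(elj_l)
    tot = ec_a + elj_a
    per_frame = pd.DataFrame({"frame": list(window_frames), "coulomb_kJmol": ec_a,
                              "lj_kJmol": elj_a, "total_kJmol": tot})
    ddof = 1 if len(ec_a) > 1 else 0
    return PairwiseEnergy(
        coulomb=float(ec_a.mean()), lj=float(elj_a.mean()), total=float(tot.mean()),
        sd_coulomb=float(ec_a.std(ddof=ddof)), sd_lj=float(elj_a.std(ddof=ddof)),
        sd_total=float(tot.std(ddof=ddof)), per_frame=per_frame,
    )
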