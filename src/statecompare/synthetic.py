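"""Synthetic inputs with known ground truth for all three analysis arms.

Generates (i) 3pESEEM echo traces with a planted deuterium modulation depth
on a stretched-exponential echo decay, (ii) two-state peptide-level HDX
uptake tables from residue protection factors with planted regional
deprotection, and (iii) toy membrane/pore/helix/water coordinate systems
with exactly known thickness, tilt, free pore radii and contacts.  Every
generator is seeded and its parameters are recorded in a JSON manifest so
that downstream recovery can be tested against truth without any download.
"""

from __future__ import annotations

import dataclasses
import json
import math

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eseem import EchoTrace
from .hdx import PeptideUptakeTable
from .mdstruct import MolecularSystem, write_pdb

__all__ = [
    "EseemSimParams",
    "HdxSimParams",
    "ToySystemParams",
    "simulate_eseem_trace",
    "simulate_accessibility_panel",
    "simulate_hdx_dataset",
    "build_toy_structure",
    "write_fixtures",
    "default_peptide_map",
    "TOY_CHAIN_MAP",
]

_MHZ_NS = 1e-3

#: carbon -> hydrogens map of the toy acyl pseudo-chains
TOY_CHAIN_MAP = {f"C{i}": [f"H{i}A", f"H{i}B"] for i in range(1, 9)}

_SEQ_ALPHABET = "ACDEFGHIKLMNQRSTVWY"  # no proline unless planted explicitly


# ---------------------------------------------------------------------------
# ESEEM


@dataclass
class EseemSimParams:
    """Acquisition + physics parameters of a simulated 3pESEEM trace.

    tau and the T grid follow the stimulated-echo convention (T from 400 ns
    in 12 ns steps); depth_k in [0, 1] is the total deuterium modulation
    depth; nu_D the effective deuterium Larmor frequency (MHz, an X-band
    default declared in the manifest, not inferred from any measurement);
    noise_sigma is Gaussian noise as a fraction of the echo amplitude.
    """

    tau: float = 200.0
    t_start: float = 400.0
    t_step: float = 12.0
    n_points: int = 1024
    depth_k: float = 0.3
    nu_D: float = 2.25
    damping_time: float = 8000.0
    bg_amplitude: float = 1.0
    bg_time: float = 20000.0
    bg_stretch: float = 1.0
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_k <= 1.0:
            raise ValueError("depth_k must be in [0, 1]")
        if self.t_step <= 0 or self.t_start <= 0 or self.n_points < 8:
            raise ValueError("non-positive/degenerate T grid")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.nu_D <= 0:
            raise ValueError("nu_D must be positive")
        if self.tau <= 0 or self.damping_time <= 0 or self.bg_time <= 0:
            raise ValueError("tau, damping_time, bg_time must be positive")


def eseem_closed_form(T, params: EseemSimParams) -> np.ndarray:
    """Noiseless normalised modulation m(T) (trace = background * (1 + m))."""
    k, nu, tau = params.depth_k, params.nu_D, params.tau
    blind = 1.0 - np.cos(2 * np.pi * nu * tau * _MHZ_NS)
    osc = 1.0 - np.cos(2 * np.pi * nu * (np.asarray(T) + tau) * _MHZ_NS)
    return -(k / 4.0) * blind * osc * np.exp(-np.asarray(T) / params.damping_time)


def eseem_background(T, params: EseemSimParams) -> np.ndarray:
    return params.bg_amplitude * np.exp(
        -np.power(np.asarray(T) / params.bg_time, params.bg_stretch))


def simulate_eseem_trace(params: EseemSimParams, label: str = "") -> EchoTrace:
    """Simulate one echo trace: B(T) * (1 + m(T)) + Gaussian noise."""
    T = params.t_start + params.t_step * np.arange(params.n_points)
    bg = eseem_background(T, params)
    signal = bg * (1.0 + eseem_closed_form(T, params))
    rng = np.random.default_rng(params.seed)
    if params.noise_sigma > 0:
        signal = signal + rng.normal(0.0, params.noise_sigma * params.bg_amplitude,
                                     size=T.shape)
    return EchoTrace(T=T, amplitude=signal, tau=params.tau, label=label)


def simulate_accessibility_panel(depths, shared: EseemSimParams,
                                 seed_offsets=None) -> list[EchoTrace]:
    """One trace per (label, depth) under identical acquisition settings.

    Noise seeds are derived from the shared seed plus a per-trace offset
    (defaults to the trace index), so panels are reproducible and two entries
    only coincide when both depth and seed offset coincide.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("empty panel")
    labels = [d[0] for d in depths]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate residue labels in panel")
    if seed_offsets is None:
        seed_offsets = list(range(len(depths)))
    traces = []
    for (label, k), off in zip(depths, seed_offsets):
        p = dataclasses.replace(shared, depth_k=float(k),
                                seed=(shared.seed * 1009 + int(off)) % (2 ** 31))
        traces.append(simulate_eseem_trace(p, label=label))
    return traces


# ---------------------------------------------------------------------------
# HDX


@dataclass
class HdxSimParams:
    """Two-state per-residue protection-factor model of peptide HDX uptake.

    Per-residue uptake follows 1 - exp(-k_int * t / P); a peptide's uptake is
    the sum over its exchangeable residues (all but its first residue and any
    prolines).  State B equals state A except inside ``deprotected_regions``,
    where the protection factor is divided by the fold change.
    """

    sequence_length: int = 125
    peptide_set: tuple | None = None            # ((start, end), ...) 1-based inclusive
    timepoints: tuple = (0.5, 1.0, 2.0, 10.0, 60.0)
    n_replicates: int = 3
    base_protection: float = 600.0
    deprotected_regions: tuple = ()             # ((start, end, fold_change), ...)
    intrinsic_rate: float = 60.0                # per minute
    noise_sd: float = 0.05                      # Da
    prolines: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_set is None:
            self.peptide_set = default_peptide_map(self.sequence_length)
        for (a, b) in self.peptide_set:
            if not (1 <= a <= b <= self.sequence_length):
                raise ValueError(f"peptide ({a},{b}) outside 1..{self.sequence_length}")
        tp = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        covered = {}
        for (a, b, fold) in self.deprotected_regions:
            if fold <= 0:
                raise ValueError("fold_change must be > 0")
            for r in range(a, b + 1):
                if r in covered and covered[r] != fold:
                    raise ValueError(
                        f"residue {r} in overlapping regions with contradictory folds")
                covered[r] = fold
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.noise_sd < 0 or self.base_protection <= 0 or self.intrinsic_rate <= 0:
            raise ValueError("invalid rate/protection/noise parameters")


def default_peptide_map(length: int, cut_spacing: int = 3,
                        max_span: int = 3) -> tuple:
    """Deterministic cut-site digest with overlapping fragments.

    Cleavage sites sit every ``cut_spacing`` residues (plus the termini);
    every run of 1..``max_span`` consecutive inter-site intervals becomes a
    peptide, giving the short nested fragments and ~3-6x redundancy of a
    well-behaved proteolytic HDX digest.
    """
    sites = sorted({0, length} | {i for i in range(cut_spacing, length, cut_spacing)})
    peptides = []
    for j, c in enumerate(sites[:-1]):
        for k in range(1, max_span + 1):
            if j + k >= len(sites):
                break
            peptides.append((c + 1, sites[j + k]))
    return tuple(sorted(set(peptides)))


def toy_sequence(length: int, prolines=()) -> str:
    seq = [_SEQ_ALPHABET[i % len(_SEQ_ALPHABET)] for i in range(length)]
    for p in prolines:
        seq[p - 1] = "P"
    return "".join(seq)


def _protection_profile(params: HdxSimParams, state_b: bool) -> np.ndarray:
    P = np.full(params.sequence_length + 1, params.base_protection)
    if state_b:
        for (a, b, fold) in params.deprotected_regions:
            P[a:b + 1] = params.base_protection / fold
    return P


def exchangeable_residues(start: int, end: int, sequence: str) -> list[int]:
    """Residues of a peptide that contribute uptake: all but the peptide's
    first residue and prolines."""
    return [r for r in range(start + 1, end + 1) if sequence[r - 1] != "P"]


def expected_uptake(start: int, end: int, t: float, P: np.ndarray,
                    sequence: str, k_int: float) -> float:
    res = exchangeable_residues(start, end, sequence)
    return float(sum(1.0 - math.exp(-k_int * t / P[r]) for r in res))


def simulate_hdx_dataset(params: HdxSimParams,
                         state_names=("A", "B")) -> tuple[PeptideUptakeTable, PeptideUptakeTable]:
    """Simulate matched uptake tables for the reference state and the state
    with planted regional deprotection."""
    seq = toy_sequence(params.sequence_length, params.prolines)
    rng = np.random.default_rng(params.seed)
    tables = []
    for state_i, state in enumerate(state_names):
        P = _protection_profile(params, state_b=(state_i == 1))
        rows = []
        for (a, b) in params.peptide_set:
            pep = seq[a - 1:b]
            for t in params.timepoints:
                mu = expected_uptake(a, b, t, P, seq, params.intrinsic_rate)
                noise = rng.normal(0.0, params.noise_sd, size=params.n_replicates)
                for rep in range(1, params.n_replicates + 1):
                    rows.append((pep, a, b, state, t, rep,
                                 max(mu + noise[rep - 1], 0.0)))
        df = pd.DataFrame(rows, columns=["peptide", "start", "end", "state",
                                         "exposure_min", "replicate", "uptake_Da"])
        tables.append(PeptideUptakeTable(data=df,
                                         protein_length=params.sequence_length))
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class ToySystemParams:
    """Geometry of a toy bilayer/pore/helix/water system (exact ground truth).

    Thickness and box are nm (coordinates are built in Angstrom); pore radii
    are *free* radii in Angstrom (lining sphere centres sit at
    free_radius + lining_vdw from the axis); tilts in degrees.  Components
    are optional: pore_shape=None omits the pore, helix_tilt=None the helix.
    """

    bilayer_thickness: float = 3.8          # nm
    n_lipids_per_leaflet: int = 36
    chain_tilt: float = 0.0                 # deg from membrane normal
    pore_shape: str | None = "cylinder"     # cylinder | cone | hourglass | None
    pore_radius: float | tuple = 5.0        # A (min,max) for cone/hourglass
    lining_vdw: float = 1.5                 # A
    helix_tilt: float | None = 0.0          # deg; None omits the helix
    helix_n_res: int = 18
    n_waters_in_pore: int = 0
    n_bulk_waters: int = 0                  # waters in the slabs above/below
    box: tuple = (10.0, 10.0, 10.0)         # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bilayer_thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.pore_shape not in (None, "cylinder", "cone", "hourglass"):
            raise ValueError(f"unknown pore shape {self.pore_shape!r}")
        if self.pore_shape is not None:
            rmax = self.pore_radius if np.isscalar(self.pore_radius) else max(self.pore_radius)
            if rmax <= 0:
                raise ValueError("pore_radius must be positive")
            if 2 * (rmax + self.lining_vdw) >= min(self.box[0], self.box[1]) * 10.0:
                raise ValueError("pore wider than box")
        if not 0 <= self.chain_tilt <= 90:
            raise ValueError("chain_tilt must be in [0, 90] degrees")
        if self.helix_tilt is not None and not 0 <= self.helix_tilt <= 90:
            raise ValueError("helix_tilt must be in [0, 90] degrees")


def _pore_free_radius(params: ToySystemParams, z: float, half_t: float) -> float:
    r = params.pore_radius
    if params.pore_shape == "cylinder":
        return float(r)
    rmin, rmax = r
    if params.pore_shape == "cone":
        frac = (z + half_t) / (2 * half_t)          # bottom -> top
        return float(rmin + (rmax - rmin) * frac)
    # hourglass: waist rmin at z = 0, rmax at both membrane faces
    return float(rmin + (rmax - rmin) * abs(z) / half_t)


def build_toy_structure(params: ToySystemParams) -> MolecularSystem:
    """Emit pseudo-atoms realising the requested geometry exactly.

    Leaflet phosphates sit at z = +/- thickness/2 so the phosphate-based
    thickness is exact by construction; acyl pseudo-chains (with explicit
    hydrogens perpendicular to the chain axis) tilt by ``chain_tilt``;
    pore-lining spheres realise the requested free-radius profile; an ideal
    alpha-helix Calpha trace is rotated by ``helix_tilt`` about x; water
    oxygens fill the pore.
    """
    rng = np.random.default_rng(params.seed)
    t = params.bilayer_thickness * 10.0
    half_t = t / 2.0
    bx, by, bz = (v * 10.0 for v in params.box)
    names, resnames, resids, segids, xyz, radii = [], [], [], [], [], []

    def add(name, resname, resid, segid, pos, radius):
        names.append(name); resnames.append(resname); resids.append(resid)
        segids.append(segid); xyz.append(pos); radii.append(radius)

    # --- pore exclusion zone for lipid placement
    if params.pore_shape is not None:
        rmax_pore = (params.pore_radius if np.isscalar(params.pore_radius)
                     else max(params.pore_radius))
        excl = rmax_pore + params.lining_vdw + 4.0
    else:
        excl = 0.0

    # --- ideal alpha-helix Calpha trace
    if params.helix_tilt is not None:
        n_res = params.helix_n_res
        coords = np.array([[2.3 * math.cos(math.radians(100.0 * i)),
                            2.3 * math.sin(math.radians(100.0 * i)),
                            1.5 * i] for i in range(n_res)])
        coords -= coords.mean(axis=0)
        a = math.radians(params.helix_tilt)
        rot_x = np.array([[1, 0, 0],
                          [0, math.cos(a), -math.sin(a)],
                          [0, math.sin(a), math.cos(a)]])
        coords = coords @ rot_x.T
        center = np.array([min(bx / 4.0, excl + 12.0), 0.0, 0.0])
        for i, c in enumerate(coords + center):
            add("CA", "ALA", i + 1, "HLX", tuple(c), 1.7)

    # --- lipids: grid in the xy annulus outside the pore
    pitch = 8.0
    nx = int(bx // pitch)
    sites = []
    for ix in range(nx):
        for iy in range(int(by // pitch)):
            x = -bx / 2 + pitch / 2 + ix * pitch
            y = -by / 2 + pitch / 2 + iy * pitch
            if math.hypot(x, y) > excl and abs(x) < bx / 2 - 2 and abs(y) < by / 2 - 2:
                sites.append((x, y))
    if len(sites) < params.n_lipids_per_leaflet:
        raise ValueError(
            f"box too small: {len(sites)} lipid sites < {params.n_lipids_per_leaflet}")
    tilt = math.radians(params.chain_tilt)
    resid = 1000
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for leaflet, zsign in (("upper", 1.0), ("lower", -1.0)):
        for li in range(params.n_lipids_per_leaflet):
            x, y = sites[li]
            resid += 1
            add("P", "LIP", resid, "MEMB", (x, y, zsign * half_t), 1.8)
            azi = golden * (li + (0 if zsign > 0 else params.n_lipids_per_leaflet))
            # chain axis tilted from -z (upper) / +z (lower) by chain_tilt
            u = np.array([math.sin(tilt) * math.cos(azi),
                          math.sin(tilt) * math.sin(azi),
                          -zsign * math.cos(tilt)])
            # orthonormal frame around the chain axis for C-H placement
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(u, ref)) > 0.99:
                ref = np.array([1.0, 0.0, 0.0])
            v1 = np.cross(u, ref); v1 /= np.linalg.norm(v1)
            v2 = np.cross(u, v1)
            head = np.array([x, y, zsign * half_t])
            for ci in range(1, 9):
                c = head + u * (1.5 * ci)
                add(f"C{ci}", "LIP", resid, "MEMB", tuple(c), 1.7)
                psi = golden * (li * 8 + ci)
                h_dir = math.cos(psi) * v1 + math.sin(psi) * v2
                add(f"H{ci}A", "LIP", resid, "MEMB", tuple(c + 1.09 * h_dir), 1.2)
                add(f"H{ci}B", "LIP", resid, "MEMB", tuple(c - 1.09 * h_dir), 1.2)

    # --- pore lining rings
    if params.pore_shape is not None:
        ring_n = 36
        resid = 5000
        for z in np.arange(-half_t, half_t + 0.25, 0.5):
            r_centers = _pore_free_radius(params, float(z), half_t) + params.lining_vdw
            resid += 1
            for jj in range(ring_n):
                ang = 2 * math.pi * jj / ring_n
                add("PO", "POR", resid, "PORE",
                    (r_centers * math.cos(ang), r_centers * math.sin(ang), float(z)),
                    params.lining_vdw)

    # --- waters: in-pore plus optional bulk slabs above/below the membrane
    resid = 9000
    if params.n_waters_in_pore and params.pore_shape is not None:
        for _ in range(params.n_waters_in_pore):
            z = rng.uniform(-half_t, half_t)
            rfree = _pore_free_radius(params, z, half_t)
            rr = math.sqrt(rng.uniform(0, 1)) * max(rfree - 1.0, 0.2)
            ang = rng.uniform(0, 2 * math.pi)
            resid += 1
            add("O", "HOH", resid, "WAT", (rr * math.cos(ang), rr * math.sin(ang), z), 1.52)
    if params.n_bulk_waters:
        z_lo, z_hi = half_t + 2.0, bz / 2.0 - 2.0
        if z_hi <= z_lo:
            raise ValueError("box too thin for bulk water slabs")
        for _ in range(params.n_bulk_waters):
            zsign = 1.0 if rng.uniform() < 0.5 else -1.0
            pos = (rng.uniform(-bx / 2 + 2, bx / 2 - 2),
                   rng.uniform(-by / 2 + 2, by / 2 - 2),
                   zsign * rng.uniform(z_lo, z_hi))
            resid += 1
            add("O", "HOH", resid, "WAT", pos, 1.52)

    return MolecularSystem(
        names=np.array(names), resnames=np.array(resnames),
        resids=np.array(resids), segids=np.array(segids),
        frames=np.array(xyz, dtype=float)[None],
        box=np.array([bx, by, bz]), radii=np.array(radii, dtype=float))


# ---------------------------------------------------------------------------
# fixtures


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_fixtures(bundle: dict, out_dir, ground_truth: dict | None = None) -> dict:
    """Write generated objects to disk and return a manifest.

    Traces become two-column ASCII (.dat), uptake tables CSV, systems PDB
    (multi-model when multi-frame); ``ground_truth`` (e.g. the parameter
    dataclasses, seeds included) is embedded verbatim in manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "ground_truth": _jsonable(ground_truth or {})}
    for name, obj in bundle.items():
        if isinstance(obj, EchoTrace):
            path = out / f"{name}.dat"
            obj.write(path)
        elif isinstance(obj, PeptideUptakeTable):
            path = out / f"{name}.csv"
            obj.write_csv(path)
        elif isinstance(obj, MolecularSystem):
            path = out / f"{name}.pdb"
            write_pdb(obj, path)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            raise TypeError(f"cannot serialise fixture {name!r} of type {type(obj)}")
        manifest["files"][name] = str(path.name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
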