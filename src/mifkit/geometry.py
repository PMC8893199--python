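"""Trimer solvent-channel geometry from PDB coordinates.

A C3-symmetric homotrimer encloses a solvent channel along its 3-fold
axis.  This module locates that axis from the inter-chain Kabsch
rotation, profiles the free channel radius along it with an axial probe
(at each axial sample the free radius is the minimum, over atoms in a
slab, of the perpendicular distance to the axis minus the atom's van der
Waals radius), and reports the gate constriction, closest inter-subunit
atom distances, and Kabsch superposition RMSD between structures.

The axial probe is valid for channels coincident with the symmetry axis;
it deliberately replaces general Voronoi-based tunnel tracing.
Van der Waals radii are the Bondi (1964) set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Bondi (1964) van der Waals radii, Angstrom, keyed by element symbol.
BONDI_VDW = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "CU": 1.40, "NI": 1.63,
}
DEFAULT_VDW = 1.70

#: Side-chain "tip" atom used to anchor the gate plane, by residue name.
SIDECHAIN_TIP = {
    "CYS": "SG", "TYR": "OH", "ALA": "CB", "SER": "OG", "THR": "OG1",
    "PHE": "CZ", "TRP": "CH2", "HIS": "NE2", "MET": "SD", "GLY": "CA",
    "VAL": "CB", "LEU": "CG", "ILE": "CD1", "ASP": "CG", "GLU": "CD",
    "ASN": "CG", "GLN": "CD", "LYS": "NZ", "ARG": "CZ", "PRO": "CG",
}

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "altloc", "element",
                "x", "y", "z", "occupancy"]


@dataclass
class StructureModel:
    """Atom table (chain, residue, atom, altloc, element, xyz, occupancy)
    plus an element-keyed vdW radius table."""

    atoms: pd.DataFrame
    vdw: dict | None = None

    def __post_init__(self) -> None:
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns {sorted(missing)}")
        if len(self.atoms) == 0:
            raise ValueError("structure contains no atoms")
        xyz = self.coords
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if self.vdw is None:
            self.vdw = dict(BONDI_VDW)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def chains(self) -> list[str]:
        return sorted(self.atoms["chain"].unique())

    def vdw_radii(self) -> np.ndarray:
        return np.array([self.vdw.get(e.upper(), DEFAULT_VDW)
                         for e in self.atoms["element"]])


@dataclass
class Axis:
    """A line in space: anchor point and unit direction."""

    point: np.ndarray
    direction: np.ndarray


@dataclass
class ChannelProfile:
    axis: Axis
    samples: pd.DataFrame           # columns z, radius, nearest_residue
    gate_z: float
    gate_radius: float
    gate_residue: int


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    chain_mapping: dict


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def read_pdb(path, exclude_waters: bool = True, exclude_hetero: bool = True,
             vdw: dict | None = None) -> StructureModel:
    """Read ATOM/HETATM records of the first model into a StructureModel.

    Waters and heteroatoms are excluded by default; alternate locations
    are retained with their identifiers.  Bondi vdW radii are attached
    (overridable via ``vdw``).
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    rows = []
    for chain in st[0]:
        for res in chain:
            if exclude_waters and res.is_water():
                continue
            if exclude_hetero and res.het_flag == "H" and not res.is_water():
                continue
            for atom in res:
                rows.append((chain.name, res.seqid.num, res.name,
                             atom.name, atom.altloc or "",
                             atom.element.name.upper(),
                             atom.pos.x, atom.pos.y, atom.pos.z, atom.occ))
    if not rows:
        raise ValueError(f"{path}: zero atoms after filtering")
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return StructureModel(atoms=atoms, vdw=vdw)


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as standard PDB ATOM records (one chain per label)."""
    st = gemmi.Structure()
    st.name = "mifkit"
    gm = gemmi.Model("1")
    for chain_name, chain_df in model.atoms.groupby("chain", sort=True):
        ch = gemmi.Chain(str(chain_name))
        for (resnum, resname), res_df in chain_df.groupby(
                ["resnum", "resname"], sort=True):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.het_flag = "A"  # force ATOM records
            for row in res_df.itertuples():
                at = gemmi.Atom()
                at.name = row.atom
                at.altloc = row.altloc if row.altloc else "\0"
                at.element = gemmi.Element(row.element.capitalize())
                at.pos = gemmi.Position(row.x, row.y, row.z)
                at.occ = row.occupancy
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def transform_model(model: StructureModel, rotation: np.ndarray,
                    translation: np.ndarray) -> StructureModel:
    """Apply a rigid transform x -> R x + t to all coordinates."""
    new = model.atoms.copy()
    new[["x", "y", "z"]] = model.coords @ np.asarray(rotation).T + translation
    return StructureModel(atoms=new, vdw=dict(model.vdw))


# ---------------------------------------------------------------------------
# superposition

def kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition of P onto Q.

    Returns (rotation, translation, rmsd) such that ``P @ R.T + t``
    minimizes the RMSD to Q; the rotation is proper (det = +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need matching point sets with >= 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return R, t, rmsd


def _chain_atom_table(model: StructureModel, chain: str,
                      selection=None) -> pd.DataFrame:
    df = model.atoms[model.atoms["chain"] == chain]
    if selection is not None:
        names = [selection] if isinstance(selection, str) else list(selection)
        df = df[df["atom"].isin(names)]
    # one conformer per atom: keep the first altloc
    df = df.sort_values("altloc").drop_duplicates(["resnum", "atom"])
    return df.set_index(["resnum", "atom"])


def _paired_coords(model_a, chain_a, model_b, chain_b, selection=None):
    ta = _chain_atom_table(model_a, chain_a, selection)
    tb = _chain_atom_table(model_b, chain_b, selection)
    common = ta.index.intersection(tb.index)
    return (ta.loc[common, ["x", "y", "z"]].to_numpy(),
            tb.loc[common, ["x", "y", "z"]].to_numpy())


def superpose_rmsd(model_a: StructureModel, model_b: StructureModel,
                   selection="CA") -> SuperpositionResult:
    """Kabsch superposition RMSD between two structures.

    Atoms are paired by (chain mapping, residue number, atom name) on the
    given selection (backbone alpha-carbons by default, which also keeps
    mutated side chains out of the comparison).  For trimers all three
    cyclic chain mappings are tried and the best kept; reflective
    mappings are non-physical for a C3 assembly and are not considered.
    """
    ca, cb = model_a.chains, model_b.chains
    if len(ca) == len(cb) == 3:
        mappings = [{ca[i]: cb[(i + k) % 3] for i in range(3)}
                    for k in range(3)]
    else:
        if len(ca) != len(cb):
            raise ValueError("chain counts differ; no natural mapping")
        mappings = [dict(zip(ca, cb))]

    best = None
    for mapping in mappings:
        Ps, Qs = [], []
        for c_a, c_b in mapping.items():
            p, q = _paired_coords(model_a, c_a, model_b, c_b, selection)
            Ps.append(p)
            Qs.append(q)
        P, Q = np.vstack(Ps), np.vstack(Qs)
        if P.shape[0] < 3:
            continue
        R, t, rmsd = kabsch(P, Q)
        if best is None or rmsd < best.rmsd:
            best = SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                                       n_atoms=P.shape[0],
                                       chain_mapping=mapping)
    if best is None:
        raise ValueError("no common atoms between the structures")
    return best


# ---------------------------------------------------------------------------
# symmetry axis

def _rotation_axis_angle(R: np.ndarray):
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0)))
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return axis / np.linalg.norm(axis), float(angle)


def detect_symmetry_axis(model: StructureModel,
                         chains: list[str] | None = None,
                         angle_tol: float = 15.0,
                         axis_tol: float = 5.0) -> Axis:
    """Locate the trimer 3-fold axis from inter-chain Kabsch rotations.

    The axis direction is the rotation axis of the proper rotation that
    superposes chain A onto chain B; the A->C rotation must agree within
    ``axis_tol`` degrees, and both rotation angles must be 120 +/-
    ``angle_tol`` degrees, otherwise the model is rejected as not
    C3-symmetric.  The axis anchor is the centroid of the three chains.
    The direction sign is fixed by the third moment of the atom
    distribution along the axis (positive skew), falling back to the
    largest coordinate component for symmetric models.
    """
    chains = chains or model.chains
    if len(chains) != 3:
        raise ValueError(f"axis detection needs exactly 3 chains, got {chains}")
    a, b, c = chains
    # >= 80% shared residue numbering between the chains
    res_sets = [set(model.atoms.loc[model.atoms["chain"] == ch, "resnum"])
                for ch in chains]
    shared = res_sets[0] & res_sets[1] & res_sets[2]
    if any(len(shared) < 0.8 * len(s) for s in res_sets):
        raise ValueError("chains share < 80% of residue numbering")

    axes = []
    for other in (b, c):
        P, Q = _paired_coords(model, a, model, other)
        R, _, _ = kabsch(P, Q)
        axis, angle = _rotation_axis_angle(R)
        if abs(angle - 120.0) > angle_tol:
            raise ValueError(
                f"not C3-symmetric: chain {a}->{other} rotation is "
                f"{angle:.1f} deg, expected 120 +/- {angle_tol}")
        axes.append(axis)
    if np.dot(axes[0], axes[1]) < 0:
        axes[1] = -axes[1]
    cross_angle = np.degrees(np.arccos(
        np.clip(abs(np.dot(axes[0], axes[1])), -1.0, 1.0)))
    if cross_angle > axis_tol:
        raise ValueError(f"A->B and A->C rotation axes disagree by "
                         f"{cross_angle:.2f} deg")
    direction = axes[0] + axes[1]
    direction /= np.linalg.norm(direction)

    sel = model.atoms["chain"].isin(chains)
    coords = model.atoms.loc[sel, ["x", "y", "z"]].to_numpy()
    point = coords.mean(axis=0)
    # orientation convention so the axis is reproducible under rigid motion
    s = (coords - point) @ direction
    skew = float(np.sum(s ** 3))
    if abs(skew) > 1e-6 * max(float(np.sum(s ** 2)) ** 1.5, 1e-12):
        if skew < 0:
            direction = -direction
    elif direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    return Axis(point=point, direction=direction)


# ---------------------------------------------------------------------------
# channel profiling

def _gate_plane_z(model: StructureModel, axis: Axis, residue: int) -> float:
    """Axial coordinate of the side-chain tip plane of ``residue``."""
    res = model.atoms[model.atoms["resnum"] == residue]
    if res.empty:
        raise ValueError(f"residue {residue} absent from model")
    zs = []
    for _, chain_df in res.groupby("chain"):
        resname = chain_df["resname"].iloc[0]
        tip_name = SIDECHAIN_TIP.get(resname)
        tip = chain_df[chain_df["atom"] == tip_name] if tip_name else chain_df
        if tip.empty:
            tip = chain_df
        xyz = tip[["x", "y", "z"]].to_numpy()
        zs.append(np.mean((xyz - axis.point) @ axis.direction))
    return float(np.mean(zs))


def channel_profile(model: StructureModel, axis: Axis,
                    z_min: float | None = None, z_max: float | None = None,
                    step: float = 0.2, slab_half_width: float = 1.0,
                    gate_residue: int | None = None) -> ChannelProfile:
    """Free-radius profile of the axial solvent channel.

    At each axial sample the free radius is the minimum over atoms within
    ``slab_half_width`` of the sample plane of (perpendicular distance to
    the axis - vdW radius), clamped at zero.  Each alternate conformer
    contributes independently, so the most restrictive conformer governs.
    Samples with no atoms in the slab have radius NaN.

    The gate is the local minimum of the profile nearest the plane of the
    ``gate_residue`` side-chain tips (global minimum when no gate residue
    is given).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rel = model.coords - axis.point
    s = rel @ axis.direction
    perp = rel - np.outer(s, axis.direction)
    rho = np.linalg.norm(perp, axis=1)
    free = rho - model.vdw_radii()

    lo = s.min() if z_min is None else z_min
    hi = s.max() if z_max is None else z_max
    grid = np.arange(step * np.ceil(lo / step), hi + 1e-9, step)

    radii = np.full(grid.size, np.nan)
    nearest = np.full(grid.size, -1, dtype=int)
    resnums = model.atoms["resnum"].to_numpy()
    for i, z in enumerate(grid):
        # small tolerance so atoms exactly on the slab boundary are kept
        # regardless of floating-point error from rigid transforms
        in_slab = np.abs(s - z) <= slab_half_width + 1e-9
        if not np.any(in_slab):
            continue
        vals = free[in_slab]
        j = int(np.argmin(vals))
        radii[i] = max(vals[j], 0.0)
        nearest[i] = resnums[np.nonzero(in_slab)[0][j]]
    samples = pd.DataFrame({"z": grid, "radius": radii,
                            "nearest_residue": nearest})

    valid = np.isfinite(radii)
    if not np.any(valid):
        raise ValueError("no atoms near the axis in the requested z range")
    # local minima of the sampled profile (plateaus count once)
    r = radii.copy()
    r[~valid] = np.inf
    is_min = np.ones(grid.size, dtype=bool)
    is_min[1:] &= r[1:] <= r[:-1]
    is_min[:-1] &= r[:-1] <= r[1:]
    is_min &= valid
    cand = np.nonzero(is_min)[0]
    if gate_residue is not None:
        plane = _gate_plane_z(model, axis, gate_residue)
        order = np.lexsort((r[cand], np.abs(grid[cand] - plane)))
    else:
        order = np.argsort(r[cand])
    g = cand[order[0]]
    return ChannelProfile(axis=axis, samples=samples,
                          gate_z=float(grid[g]), gate_radius=float(radii[g]),
                          gate_residue=int(nearest[g]))


def min_intersubunit_distance(model: StructureModel, residue_number: int,
                              atom_name: str):
    """Closest inter-chain center-to-center distance for one named atom.

    All alternate-location combinations are considered.  Returns
    (distance, (chain_i, chain_j), (altloc_i, altloc_j)).
    """
    sel = model.atoms[(model.atoms["resnum"] == residue_number) &
                      (model.atoms["atom"] == atom_name)]
    if sel.empty:
        raise ValueError(f"atom {atom_name} of residue {residue_number} "
                         "not found")
    if sel["chain"].nunique() < 2:
        raise ValueError(f"atom {atom_name}/{residue_number} present in "
                         "fewer than 2 chains")
    best = (np.inf, None, None)
    recs = list(sel.itertuples())
    for i, ai in enumerate(recs):
        for aj in recs[i + 1:]:
            if ai.chain == aj.chain:
                continue
            d = float(np.sqrt((ai.x - aj.x) ** 2 + (ai.y - aj.y) ** 2 +
                              (ai.z - aj.z) ** 2))
            if d < best[0]:
                best = (d, (ai.chain, aj.chain), (ai.altloc, aj.altloc))
    return best
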