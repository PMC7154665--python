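"""Rigid superposition (Kabsch) and van-der-Waals clash detection.

Dipeptide fragments are aligned onto the Xxx-Yyy main-chain atoms of a helix
window and the posed fragment is screened against the helix environment for
steric overlap, splitting contacts into same-strand and neighboring-strand.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CmpHelixError, GeometryError
from .model import Structure, TripletAssignment, register_triplets

#: Bondi van der Waals radii, Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Heavy-atom distance below which a covalent bond is inferred (A).
BOND_CUTOFF = 1.9
BOND_CUTOFF_H = 1.3


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    atom_map: list[tuple[int, int]] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperposeResult:
    """Least-squares optimal rigid transform mapping mobile onto target.

    Kabsch/SVD solution; requires >= 3 non-collinear matched pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise CmpHelixError("superpose requires two equally shaped (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superpose requires at least 3 matched pairs")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise GeometryError("collinear atom set: rotation underdetermined")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    diff = mobile @ rot.T + trans - target
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperposeResult(rotation=rot, translation=trans, rmsd=rmsd,
                           atom_map=[(i, i) for i in range(n)])


def _mainchain_coords(residues, which=("N", "CA", "C")) -> np.ndarray:
    coords = []
    for res in residues:
        for name in which:
            a = res.atom(name)
            if a is None:
                raise CmpHelixError(
                    f"residue {res.label}{res.seq_index} lacks main-chain atom {name}"
                )
            coords.append(a.pos)
    return np.asarray(coords)


def align_fragment_to_helix(
    frag: Structure,
    helix: Structure,
    chain_id: str | None = None,
    triplet_index: int = 1,
    ta: TripletAssignment | None = None,
) -> tuple[SuperposeResult, Structure]:
    """Pose a dipeptide fragment onto a helix window.

    The fragment's first two backbone-bearing residues are matched (N, CA, C)
    against the Xxx and Yyy residues of the selected triplet; the returned
    fragment copy carries the helix coordinate frame.
    """
    frag_res = [r for ch in frag.peptide_chains() for r in ch.residues]
    if len(frag_res) < 2:
        raise CmpHelixError("fragment must expose two residues with main-chain atoms")
    if ta is None:
        ta = register_triplets(helix)
    if chain_id is None:
        chain_id = next(iter(ta.chains))
    triplets = {t.triplet_index: t for t in ta.chains[chain_id]}
    if triplet_index not in triplets:
        raise CmpHelixError(f"chain {chain_id} has no triplet {triplet_index}")
    trip = triplets[triplet_index]
    mobile = _mainchain_coords(frag_res[:2])
    target = _mainchain_coords([trip.xxx, trip.yyy])
    result = superpose(mobile, target)
    posed = copy.deepcopy(frag)
    for ch in posed.chains:
        for res in ch.residues:
            for at in res.atoms:
                at.pos = result.apply(at.pos[None, :])[0]
    return result, posed


@dataclass
class ClashContact:
    atom_a: str  # "chain/res label+index/atom"
    atom_b: str
    chain_a: str
    chain_b: str
    distance: float
    vdw_sum: float
    overlap: float


@dataclass
class ClashReport:
    contacts: list[ClashContact]
    overlap_threshold: float

    @property
    def n_total(self) -> int:
        return len(self.contacts)

    def count_intra(self, strand_id: str) -> int:
        return sum(1 for c in self.contacts if c.chain_b == strand_id)

    def count_inter(self, strand_id: str) -> int:
        return sum(1 for c in self.contacts if c.chain_b != strand_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "atom_a": c.atom_a, "atom_b": c.atom_b,
                    "chain_a": c.chain_a, "chain_b": c.chain_b,
                    "distance_A": c.distance, "vdw_sum_A": c.vdw_sum,
                    "overlap_A": c.overlap,
                }
                for c in self.contacts
            ]
        )


def _flat_atoms(s: Structure):
    out = []
    for ch in s.chains:
        for res in ch.residues:
            for at in res.atoms:
                el = at.element.upper()
                if el not in VDW_RADII:
                    raise CmpHelixError(f"unknown element {at.element!r} on atom {at.name}")
                out.append((f"{ch.id}/{res.label}{res.seq_index}/{at.name}", ch.id, el, at.pos))
    return out


def _bond_graph(coords: np.ndarray, elements: list[str]) -> list[set[int]]:
    tree = cKDTree(coords)
    adj: list[set[int]] = [set() for _ in range(len(coords))]
    for i, j in tree.query_pairs(BOND_CUTOFF):
        cutoff = BOND_CUTOFF_H if "H" in (elements[i], elements[j]) else BOND_CUTOFF
        if np.linalg.norm(coords[i] - coords[j]) < cutoff:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def _within_n_bonds(adj, i: int, j: int, n: int = 3) -> bool:
    if i == j:
        return True
    frontier = {i}
    seen = {i}
    for _ in range(n):
        frontier = {k for f in frontier for k in adj[f] if k not in seen}
        if j in frontier:
            return True
        seen |= frontier
    return False


def detect_clashes(
    posed: Structure, environment: Structure, overlap_threshold: float = 0.4
) -> ClashReport:
    """Van-der-Waals clashes between a posed fragment and its environment.

    A pair clashes when its distance falls below r_vdw(a) + r_vdw(b) -
    overlap_threshold.  Pairs separated by three covalent bonds or fewer
    (bond graph inferred by distance over the combined system) are excluded.
    Same-strand vs neighboring-strand splits are available on the report via
    the environment chain id of each contact.
    """
    posed_atoms = _flat_atoms(posed)
    env_atoms = _flat_atoms(environment)
    if not posed_atoms or not env_atoms:
        return ClashReport([], overlap_threshold)
    all_coords = np.asarray([a[3] for a in posed_atoms + env_atoms])
    all_elements = [a[2] for a in posed_atoms + env_atoms]
    adj = _bond_graph(all_coords, all_elements)
    n_posed = len(posed_atoms)
    env_tree = cKDTree(all_coords[n_posed:])
    max_r = max(VDW_RADII[e] for e in all_elements)
    contacts = []
    for ip, (name_a, chain_a, el_a, pos_a) in enumerate(posed_atoms):
        for je in env_tree.query_ball_point(pos_a, 2 * max_r):
            name_b, chain_b, el_b, pos_b = env_atoms[je]
            d = float(np.linalg.norm(pos_a - pos_b))
            vdw = VDW_RADII[el_a] + VDW_RADII[el_b]
            overlap = vdw - d
            if overlap <= overlap_threshold:
                continue
            if _within_n_bonds(adj, ip, n_posed + je, 3):
                continue
            contacts.append(
                ClashContact(name_a, name_b, chain_a, chain_b, d, vdw, overlap)
            )
    contacts.sort(key=lambda c: -c.overlap)
    return ClashReport(contacts, overlap_threshold)
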