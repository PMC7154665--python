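"""Atomic structure model and collagen triplet registration.

The in-memory model is a small chain → residue → atom hierarchy tailored to
collagen model peptides (CMPs).  Reading and writing of PDB/mmCIF files is
delegated to :mod:`gemmi`; only the first model is kept, alternate locations
are resolved to the highest-occupancy conformer, and residues are ordered by
(sequence number, insertion code).

Collagen chains follow the [Xxx-Yyy-Gly]_n repeat with a conserved glycine.
:func:`register_triplets` recovers the reading frame of that repeat from the
residue labels alone (``gly_anchor`` scheme), tolerating capping groups and
nonstandard residue names such as bridged diproline (ProM) units, which are
treated as ordinary torsion-bearing residues whenever they expose N/CA/C.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormatError,
    RegistrationError,
    SerializationError,
)

BACKBONE_ATOMS = ("N", "CA", "C")

#: Role labels for the collagen repeat positions.
ROLE_XXX = "Xxx"
ROLE_YYY = "Yyy"
ROLE_GLY = "Gly"
ROLE_UNASSIGNED = "unassigned"


@dataclass
class Atom:
    """A named atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """A residue: label, 1-based ordinal index within its chain, atoms, role."""

    label: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)
    role: str = ROLE_UNASSIGNED

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def add_atom(self, atom: Atom) -> None:
        if self.atom(atom.name) is not None:
            raise ValueError(f"duplicate atom name {atom.name!r} in residue {self.label}{self.seq_index}")
        self.atoms.append(atom)

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def coords(self, *names: str) -> list[np.ndarray]:
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(f"residue {self.label}{self.seq_index} lacks atom {n}")
            out.append(a.pos)
        return out


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """An ordered collection of chains."""

    id: str = ""
    chains: list[Chain] = field(default_factory=list)

    def peptide_chains(self) -> list[Chain]:
        """Chains restricted to polymer residues.

        A residue counts as polymer when it exposes at least two of the
        backbone atoms N, CA, C — waters and small-molecule ligands fall out,
        while a peptide residue with one missing backbone atom stays in the
        chain (its torsions are reported as undefined downstream).  A chain
        with no polymer residue is dropped entirely.
        """
        out = []
        for ch in self.chains:
            residues = [
                r for r in ch.residues
                if sum(r.atom(n) is not None for n in BACKBONE_ATOMS) >= 2
            ]
            if residues:
                out.append(Chain(ch.id, residues))
        return out

    def all_atoms(self) -> list[tuple[str, Residue, Atom]]:
        """Flat (chain id, residue, atom) listing in file order."""
        return [(ch.id, res, at) for ch in self.chains for res in ch.residues for at in res.atoms]


@dataclass
class Triplet:
    triplet_index: int
    xxx: Residue
    yyy: Residue
    gly: Residue


@dataclass
class TripletAssignment:
    """Per-chain [Xxx-Yyy-Gly] triplet registration."""

    chains: dict[str, list[Triplet]]

    def n_triplets(self, chain_id: str) -> int:
        return len(self.chains[chain_id])


# ---------------------------------------------------------------------------
# Reading / writing


def _convert_gemmi(gst: gemmi.Structure, structure_id: str) -> Structure:
    if len(gst) == 0:
        raise EmptyStructureError(f"{structure_id}: file contains no model")
    model = gst[0]
    st = Structure(id=structure_id)
    for gch in model:
        chain = Chain(id=gch.name)
        residues = sorted(gch, key=lambda r: (r.seqid.num, r.seqid.icode))
        for ordinal, gres in enumerate(residues, start=1):
            res = Residue(label=gres.name, seq_index=ordinal)
            # altloc resolution: highest occupancy, alphabetic tie-break
            by_name: dict[str, gemmi.Atom] = {}
            for gat in gres:
                prev = by_name.get(gat.name)
                if (
                    prev is None
                    or gat.occ > prev.occ
                    or (gat.occ == prev.occ and (gat.altloc or "~") < (prev.altloc or "~"))
                ):
                    by_name[gat.name] = gat
            for gat in gres:  # preserve file atom order
                chosen = by_name.get(gat.name)
                if chosen is gat:
                    res.add_atom(
                        Atom(gat.name, gat.element.name, np.array([gat.pos.x, gat.pos.y, gat.pos.z]))
                    )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            st.chains.append(chain)
    if not st.chains:
        raise EmptyStructureError(f"{structure_id}: first model contains no atoms")
    return st


def read_structure(path: str | os.PathLike, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF coordinate file into a :class:`Structure`.

    All ATOM/HETATM records of the first model are retained (waters included;
    use :meth:`Structure.peptide_chains` for the polymer subset).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "auto":
            gst = gemmi.read_structure(path)
        elif fmt == "pdb":
            gst = gemmi.read_pdb(path)
        elif fmt == "mmcif":
            gst = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and fmt not in ("auto", "pdb", "mmcif"):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    name = os.path.splitext(os.path.basename(path))[0]
    return _convert_gemmi(gst, name)


def write_structure(s: Structure, path: str | os.PathLike, format: str = "pdb") -> None:
    """Write a structure as fixed-width PDB (with TER records per chain)."""
    if format.lower() != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    gst = gemmi.Structure()
    gst.name = s.id or "cmphelix"
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.label
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            for at in res.atoms:
                if len(at.name) > 4:
                    raise SerializationError(
                        f"atom name {at.name!r} exceeds the 4-character PDB field"
                    )
                if not np.all(np.isfinite(at.pos)):
                    raise SerializationError(f"non-finite coordinates on atom {at.name}")
                gat = gemmi.Atom()
                gat.name = at.name
                gat.element = gemmi.Element(at.element)
                gat.pos = gemmi.Position(*at.pos)
                gat.occ = 1.0
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    gst.add_model(model)
    gst.setup_entities()
    gst.write_pdb(os.fspath(path))


# ---------------------------------------------------------------------------
# Triplet registration


def register_triplets(
    s: Structure, scheme: str = "gly_anchor", min_gly_fraction: float = 0.8
) -> TripletAssignment:
    """Assign the [Xxx-Yyy-Gly] reading frame of every peptide chain.

    For each chain the frame offset (0, 1 or 2) placing the most GLY residues
    at the Gly slot is chosen; incomplete terminal triplets are dropped.  A
    chain where no frame reaches ``min_gly_fraction`` correctly placed
    glycines is rejected as not collagen-like.
    """
    if scheme != "gly_anchor":
        raise ValueError(f"unknown registration scheme {scheme!r}")
    chains = s.peptide_chains()
    if not chains:
        raise RegistrationError(f"{s.id}: no peptide chain with backbone atoms; nothing to register")
    assignment: dict[str, list[Triplet]] = {}
    for ch in chains:
        res = ch.residues
        if len(res) < 3:
            raise RegistrationError(f"chain {ch.id}: fewer than 3 residues")
        best_frame, best_frac, best_count = None, -1.0, -1
        for frame in range(3):
            n_trip = (len(res) - frame) // 3
            if n_trip == 0:
                continue
            n_gly = sum(1 for t in range(n_trip) if res[frame + 3 * t + 2].label == "GLY")
            frac = n_gly / n_trip
            if frac > best_frac or (frac == best_frac and n_gly > best_count):
                best_frame, best_frac, best_count = frame, frac, n_gly
        if best_frame is None or best_frac < min_gly_fraction:
            raise RegistrationError(
                f"chain {ch.id}: no reading frame places >= {min_gly_fraction:.0%} GLY "
                "at the Gly slot (not a collagen-like chain)"
            )
        triplets = []
        n_trip = (len(res) - best_frame) // 3
        for t in range(n_trip):
            xxx, yyy, gly = res[best_frame + 3 * t : best_frame + 3 * t + 3]
            if gly.label != "GLY":
                continue
            xxx.role, yyy.role, gly.role = ROLE_XXX, ROLE_YYY, ROLE_GLY
            triplets.append(Triplet(t + 1, xxx, yyy, gly))
        assignment[ch.id] = triplets
    return TripletAssignment(chains=assignment)
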