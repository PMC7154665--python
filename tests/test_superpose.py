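"""Kabsch superposition (vs quaternion oracle) and clash detection."""

import copy
import itertools

import numpy as np
import pytest

from cmphelix.builder import HelixSpec, TORSION_PRESETS, build_strand, build_triple_helix
from cmphelix.errors import CmpHelixError, GeometryError
from cmphelix.geometry import rotation_about_axis
from cmphelix.model import Atom, Chain, Residue, Structure
from cmphelix.superpose import (
    VDW_RADII,
    align_fragment_to_helix,
    detect_clashes,
    superpose,
)


def quaternion_superpose_rmsd(mobile, target):
    """Independent Horn quaternion solution of the optimal rigid alignment."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    diff = p @ rot.T - q
    return float(np.sqrt((diff**2).sum() / len(mobile)))


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        res = superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_rigid_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        rot = rotation_about_axis((1, 2, 3), 37.0)
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        res = superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, rot, atol=1e-9)
        assert np.allclose(res.apply(pts), moved, atol=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(50):
            mobile = rng.normal(size=(5, 3)) * 4
            target = rng.normal(size=(5, 3)) * 4
            res = superpose(mobile, target)
            assert res.rmsd == pytest.approx(
                quaternion_superpose_rmsd(mobile, target), abs=1e-9
            )

    def test_rmsd_symmetric_in_arguments(self, rng):
        mobile = rng.normal(size=(7, 3))
        target = rng.normal(size=(7, 3))
        assert superpose(mobile, target).rmsd == pytest.approx(
            superpose(target, mobile).rmsd, abs=1e-9
        )

    def test_rotation_is_proper_orthonormal(self, rng):
        res = superpose(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            superpose(line, line)


def _fragment_from_helix(helix, chain_idx=0, start_res=3):
    chain = helix.chains[chain_idx]
    frag_res = [copy.deepcopy(r) for r in chain.residues[start_res : start_res + 2]]
    return Structure("frag", [Chain("F", frag_res)])


class TestFragmentAlignment:
    def test_self_fragment_aligns_exactly(self, ppg10_helix):
        frag = _fragment_from_helix(ppg10_helix, 0, 3)  # Xxx,Yyy of triplet 2
        res, posed = align_fragment_to_helix(frag, ppg10_helix, chain_id="A", triplet_index=2)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_builder_fragment_close_to_helix(self, ppg10_helix):
        frag_strand = build_strand(HelixSpec(n_triplets=1))
        frag = Structure("f", [Chain("F", frag_strand.chains[0].residues[:2])])
        res, _ = align_fragment_to_helix(frag, ppg10_helix, chain_id="A", triplet_index=5)
        assert res.rmsd < 0.3

    def test_perturbed_torsion_increases_rmsd(self, ppg10_helix):
        base = dict(TORSION_PRESETS["ppg10_computed"])
        frag0 = Structure("f", [Chain("F", build_strand(
            HelixSpec(n_triplets=1, torsions=base)).chains[0].residues[:2])])
        pert = dict(base)
        pert["phi_yyy"] += 15.0
        frag1 = Structure("f", [Chain("F", build_strand(
            HelixSpec(n_triplets=1, torsions=pert)).chains[0].residues[:2])])
        r0, _ = align_fragment_to_helix(frag0, ppg10_helix, chain_id="A", triplet_index=5)
        r1, _ = align_fragment_to_helix(frag1, ppg10_helix, chain_id="A", triplet_index=5)
        assert r1.rmsd > r0.rmsd


def two_atom_structures(distance):
    a = Structure("a", [Chain("X", [Residue("LIG", 1, [Atom("C1", "C", np.zeros(3))])])])
    b = Structure(
        "b",
        [Chain("Y", [Residue("LIG", 1, [Atom("C2", "C", np.array([distance, 0.0, 0.0]))])])],
    )
    return a, b


def brute_force_clashes(posed, environment, threshold=0.4, bond_cut=1.9):
    """All-pairs oracle with its own bond-graph BFS."""
    def atoms(s):
        return [
            (ch.id, at.element.upper(), at.pos)
            for ch in s.chains for r in ch.residues for at in r.atoms
        ]

    pa, ea = atoms(posed), atoms(environment)
    allatoms = pa + ea
    n = len(allatoms)
    adj = [set() for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        cut = 1.3 if "H" in (allatoms[i][1], allatoms[j][1]) else bond_cut
        if np.linalg.norm(allatoms[i][2] - allatoms[j][2]) < cut:
            adj[i].add(j)
            adj[j].add(i)

    def bond_distance_leq(i, j, k):
        seen = {i}
        frontier = {i}
        for _ in range(k):
            frontier = {m for f in frontier for m in adj[f]} - seen
            if j in frontier:
                return True
            seen |= frontier
        return False

    out = set()
    for i, (ca, ea_, pos_a) in enumerate(pa):
        for j, (cb, eb, pos_b) in enumerate(ea):
            d = np.linalg.norm(pos_a - pos_b)
            if d < VDW_RADII[ea_] + VDW_RADII[eb] - threshold and not bond_distance_leq(
                i, len(pa) + j, 3
            ):
                out.add((i, j))
    return out


class TestClashes:
    def test_two_carbons_at_two_angstrom_clash(self):
        a, b = two_atom_structures(2.0)
        rep = detect_clashes(a, b)
        assert rep.n_total == 1
        assert rep.contacts[0].overlap == pytest.approx(1.4)

    def test_two_carbons_at_contact_distance_do_not(self):
        a, b = two_atom_structures(3.8)
        assert detect_clashes(a, b).n_total == 0

    def test_unknown_element_named_in_error(self):
        a, b = two_atom_structures(2.0)
        a.chains[0].residues[0].atoms[0].element = "Xx"
        with pytest.raises(CmpHelixError, match="Xx"):
            detect_clashes(a, b)

    def test_matches_brute_force_oracle(self):
        helix = build_triple_helix(HelixSpec(n_triplets=3, n_chains=3))
        posed = Structure("A", [helix.chains[0]])
        env = Structure("BC", helix.chains[1:])
        fast = detect_clashes(posed, env, 0.4)
        slow = brute_force_clashes(posed, env, 0.4)
        assert fast.n_total == len(slow)
        # and on a contrived clashing variant
        squeezed = copy.deepcopy(helix)
        for res in squeezed.chains[1].residues:
            for at in res.atoms:
                at.pos = at.pos * 0.9
        posed2 = Structure("A", [squeezed.chains[0]])
        env2 = Structure("BC", squeezed.chains[1:])
        assert detect_clashes(posed2, env2, 0.4).n_total == len(
            brute_force_clashes(posed2, env2, 0.4)
        )

    def test_invariant_under_rigid_motion(self, ppg10_helix, rng):
        posed = Structure("A", [ppg10_helix.chains[0]])
        env = Structure("BC", ppg10_helix.chains[1:])
        before = detect_clashes(posed, env, 0.2)
        moved = copy.deepcopy(ppg10_helix)
        rot = rotation_about_axis(rng.normal(size=3), 63.0)
        shift = rng.normal(size=3) * 10
        for ch in moved.chains:
            for r in ch.residues:
                for at in r.atoms:
                    at.pos = rot @ at.pos + shift
        after = detect_clashes(Structure("A", [moved.chains[0]]), Structure("BC", moved.chains[1:]), 0.2)
        assert after.n_total == before.n_total

    def test_radial_probe_clean_inward_probe_clashes(self, ppg10_helix):
        # a substituent-like probe atom anchored 1.5 A from the chain-A atom
        # closest to the neighboring strands: pointing away from the helix
        # core it touches nothing, pointing toward the core it collides with
        # a neighboring strand
        env = Structure("BC", ppg10_helix.chains[1:])
        env_pos = np.array([a.pos for _, _, a in env.all_atoms()])
        center = np.array([a.pos for _, _, a in ppg10_helix.all_atoms()]).mean(axis=0)
        best = None
        for res in ppg10_helix.chains[0].residues:
            for at in res.atoms:
                d = np.linalg.norm(env_pos - at.pos, axis=1).min()
                if best is None or d < best[0]:
                    best = (d, at.pos)
        _, anchor = best
        outward = anchor - center
        outward /= np.linalg.norm(outward)
        nearest_env = env_pos[np.argmin(np.linalg.norm(env_pos - anchor, axis=1))]
        inward = nearest_env - anchor
        inward /= np.linalg.norm(inward)
        for direction, expect_clash in ((outward, False), (inward, True)):
            # 1.0 A arm: inward lands ~2.2 A from the neighboring strand -
            # a clear vdW clash, yet too far for a covalent bond to be
            # inferred
            probe = Structure(
                "probe",
                [Chain("P", [Residue("PRB", 1, [Atom("C1", "C", anchor + 1.0 * direction)])])],
            )
            rep = detect_clashes(probe, env, 0.4)
            if expect_clash:
                assert rep.n_total >= 1
            else:
                assert rep.n_total == 0
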