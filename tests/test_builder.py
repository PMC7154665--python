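"""Helix builder: torsion fidelity, puckers, assembly and melt generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from cmphelix.builder import (
    HelixSpec,
    TORSION_PRESETS,
    build_strand,
    build_triple_helix,
    generate_melt_curve,
    set_ring_pucker,
)
from cmphelix.errors import BuilderError
from cmphelix.melt import trimer_fraction
from cmphelix.model import Structure, register_triplets
from cmphelix.pucker import classify_pucker
from cmphelix.superpose import detect_clashes
from cmphelix.torsions import average_profile, backbone_torsions


def measured_profile(structure, selection="all"):
    ta = register_triplets(structure)
    return average_profile(backbone_torsions(structure, ta), selection)


def test_strand_reproduces_preset_torsions_exactly():
    s = build_strand(HelixSpec(n_triplets=10))
    prof = measured_profile(s)
    for key, value in TORSION_PRESETS["ppg10_computed"].items():
        mean, sd = prof.stats[key]
        assert mean == pytest.approx(value, abs=1e-3)
        assert sd < 1e-3
    assert prof.stats["phi_xxx"][0] == pytest.approx(-75.0, abs=1e-6)


def test_cis_omega_bond():
    torsions = dict(TORSION_PRESETS["ppg10_computed"])
    torsions["omega_yyy"] = 0.0
    s = build_strand(HelixSpec(n_triplets=4, torsions=torsions))
    prof = measured_profile(s)
    assert prof.stats["omega_yyy"][0] == pytest.approx(0.0, abs=1e-3)


def test_noise_sd_realized_in_angles():
    spec = HelixSpec(n_triplets=10, noise_sd=3.0, seed=42)
    s = build_strand(spec)
    ta = register_triplets(s)
    recs = backbone_torsions(s, ta)
    from cmphelix.geometry import wrap_angle

    devs = []
    for r in recs:
        role = {"Xxx": "xxx", "Yyy": "yyy", "Gly": "gly"}[r.role]
        for ang in ("phi", "psi", "omega"):
            v = getattr(r, ang)
            if v is not None:
                devs.append(wrap_angle(v - spec.torsions[f"{ang}_{role}"]))
    devs = np.asarray(devs)
    assert len(devs) > 80
    assert np.std(devs) == pytest.approx(3.0, abs=0.8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    dphi_x=st.floats(-20, 20), dpsi_x=st.floats(-20, 20),
    dphi_y=st.floats(-20, 20), dpsi_y=st.floats(-20, 20),
)
def test_builder_analyzer_round_trip_in_torsion_box(dphi_x, dpsi_x, dphi_y, dpsi_y):
    torsions = dict(TORSION_PRESETS["ppg10_computed"])
    torsions["phi_xxx"] += dphi_x
    torsions["psi_xxx"] += dpsi_x
    torsions["phi_yyy"] += dphi_y
    torsions["psi_yyy"] += dpsi_y
    s = build_strand(HelixSpec(n_triplets=3, torsions=torsions))
    prof = measured_profile(s)
    for key in ("phi_xxx", "psi_xxx", "phi_yyy", "psi_yyy"):
        assert prof.stats[key][0] == pytest.approx(torsions[key], abs=1e-3)


def test_all_residues_are_l_amino_acids(ppg10_strand):
    # improper chirality test: positive signed volume of (N, C, CB) about CA
    for res in ppg10_strand.chains[0].residues:
        if res.label == "GLY":
            continue
        n, ca, c, cb = (res.atom(x).pos for x in ("N", "CA", "C", "CB"))
        sv = np.linalg.det(np.vstack([n - ca, c - ca, cb - ca]))
        assert sv > 0


class TestTripleHelix:
    def test_three_chains_register(self, ppg10_helix):
        ta = register_triplets(ppg10_helix)
        assert sorted(ta.chains) == ["A", "B", "C"]
        assert all(len(v) == 10 for v in ta.chains.values())

    def test_profile_matches_preset(self, ppg10_helix):
        prof = measured_profile(ppg10_helix, {"central_n": 9})
        for key, value in TORSION_PRESETS["ppg10_computed"].items():
            assert prof.stats[key][0] == pytest.approx(value, abs=0.1)

    def test_backbone_separation(self, ppg10_helix):
        bb = {
            ch.id: np.array(
                [a.pos for r in ch.residues for a in r.atoms if a.name in ("N", "CA", "C", "O")]
            )
            for ch in ppg10_helix.chains
        }
        dmin = min(
            cKDTree(bb[a]).query(bb[b])[0].min() for a in bb for b in bb if a < b
        )
        assert dmin > 2.4

    def test_no_interchain_clashes(self, ppg10_helix):
        posed = Structure("A", [ppg10_helix.chains[0]])
        env = Structure("BC", ppg10_helix.chains[1:])
        report = detect_clashes(posed, env, overlap_threshold=0.4)
        assert report.n_total == 0

    def test_requires_three_chains(self):
        with pytest.raises(BuilderError):
            build_triple_helix(HelixSpec(n_triplets=5, n_chains=1))


class TestRingPucker:
    @pytest.mark.parametrize("state", ["endo", "exo"])
    def test_round_trip_every_pro_slot(self, state):
        s = build_strand(HelixSpec(n_triplets=3))
        for res in s.chains[0].residues:
            if res.label == "PRO":
                set_ring_pucker(res, state)
                assert classify_pucker(res).label == state

    def test_backbone_unmoved(self):
        s = build_strand(HelixSpec(n_triplets=2))
        res = s.chains[0].residues[0]
        before = {n: res.atom(n).pos.copy() for n in ("N", "CA", "C", "O")}
        set_ring_pucker(res, "exo")
        for n, pos in before.items():
            assert np.allclose(res.atom(n).pos, pos)

    def test_amplitude_in_pyrrolidine_range(self, ppg10_strand):
        amps = [
            classify_pucker(res).amplitude
            for res in ppg10_strand.chains[0].residues
            if res.label == "PRO"
        ]
        assert all(0.3 <= a <= 0.5 for a in amps)

    def test_hyp_gets_hydroxyl(self):
        s = build_strand(HelixSpec(n_triplets=2, yyy_residue="HYP"))
        hyps = [r for r in s.chains[0].residues if r.label == "HYP"]
        assert hyps and all(r.atom("OD1") is not None for r in hyps)


class TestMeltGeneration:
    def test_noiseless_midpoint_at_tm(self):
        curve = generate_melt_curve(tm=46.5, noise_sd=0.0)
        assert float(trimer_fraction(np.array([46.5]), 46.5, 800.0)[0]) == pytest.approx(0.5, abs=1e-9)
        # the signal at Tm is the mean of the two baselines
        fa, fb = 1.0, -0.002
        ua, ub = 0.05, -0.001
        expected = 0.5 * (fa + fb * 46.5) + 0.5 * (ua + ub * 46.5)
        assert np.interp(46.5, curve.temperature, curve.signal) == pytest.approx(expected, abs=1e-4)

    def test_cold_limit_is_folded_baseline(self):
        curve = generate_melt_curve(tm=46.5, noise_sd=0.0, t_min=10.0)
        fa, fb = 1.0, -0.002
        assert curve.signal[0] == pytest.approx(fa + fb * curve.temperature[0], abs=1e-3)

    def test_seeds_change_residuals_not_the_underlying_curve(self):
        clean = generate_melt_curve(tm=40.0, noise_sd=0.0)
        c1 = generate_melt_curve(tm=40.0, noise_sd=0.02, seed=1)
        c2 = generate_melt_curve(tm=40.0, noise_sd=0.02, seed=2)
        assert not np.allclose(c1.signal, c2.signal)
        assert abs((c1.signal - clean.signal).mean()) < 0.01
        assert abs((c2.signal - clean.signal).mean()) < 0.01
        # same seed reproduces exactly
        assert np.allclose(c1.signal, generate_melt_curve(tm=40.0, noise_sd=0.02, seed=1).signal)

    def test_invalid_grids_rejected(self):
        with pytest.raises(BuilderError):
            generate_melt_curve(tm=46.5, n_points=5)
        with pytest.raises(BuilderError):
            generate_melt_curve(tm=90.0)
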