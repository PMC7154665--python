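"""Proline five-ring pucker: pseudorotation parameters and endo/exo calls.

The pyrrolidine ring of proline flips between two envelope-like states,
Cgamma-endo and Cgamma-exo.  In collagen helices the Xxx position favors
endo and the Yyy position exo, and that preference feeds directly into
triple-helix stability, so a robust discrete call matters more than the full
continuous description.

The discrete call uses the signed displacement of CG from the N-CA-CD ring
base plane, referenced to the side of the residue's carbonyl carbon: endo
when CG sits on the carbonyl side, exo when opposite, ambiguous when the
displacement is below 0.1 A (flatter than crystal precision can call).
Pseudorotation phase and amplitude (Cremer-Pople, ring order
N-CA-CB-CG-CD) are reported alongside for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .model import ROLE_XXX, ROLE_YYY, Residue, Structure, TripletAssignment

RING_ATOMS = ("N", "CA", "CB", "CG", "CD")

#: |CG out-of-plane displacement| below which a ring is not callable (A).
AMBIGUITY_FLOOR = 0.1

#: CD-N distance below which the five-ring is considered closed (A).
RING_CLOSURE_CUTOFF = 1.8


@dataclass
class PuckerState:
    phase: float  # pseudorotation phase, degrees in [0, 360)
    amplitude: float  # total puckering amplitude Q, Angstrom
    label: str  # endo | exo | ambiguous
    cg_displacement: float  # signed, positive toward the carbonyl side


@dataclass
class ProMRecord:
    """User-supplied fixture describing a diproline module.

    ``ring_flip_energy`` is the relative energy (kJ/mol) of the Yyy-ring flip:
    negative values indicate exo preference, positive ones endo preference.
    """

    name: str
    ring_flip_energy: float | None = None
    marks: dict | None = None
    torsions: dict | None = None


def _cremer_pople(coords: np.ndarray) -> tuple[float, float]:
    """Phase (deg) and total amplitude Q (A) of a 5-ring."""
    n = 5
    center = coords.mean(axis=0)
    rel = coords - center
    j = np.arange(n)
    rp = (rel * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    rpp = (rel * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise GeometryError("degenerate ring geometry")
    normal /= nn
    z = rel @ normal
    q_cos = np.sqrt(2.0 / n) * (z * np.cos(4 * np.pi * j / n)).sum()
    q_sin = -np.sqrt(2.0 / n) * (z * np.sin(4 * np.pi * j / n)).sum()
    amplitude = float(np.sqrt((z**2).sum()))
    phase = float(np.degrees(np.arctan2(q_sin, q_cos)) % 360.0)
    return phase, amplitude


def classify_pucker(res: Residue) -> PuckerState:
    """Cgamma-endo/exo call for a proline-like residue.

    Requires ring atoms N, CA, CB, CG, CD and the carbonyl C (side
    reference).  endo: CG on the same side of the N-CA-CD base plane as the
    carbonyl carbon; exo: opposite; ambiguous: |displacement| < 0.1 A.
    """
    missing = [a for a in RING_ATOMS if res.atom(a) is None]
    if missing:
        raise GeometryError(
            f"residue {res.label}{res.seq_index}: missing ring atoms {missing}"
        )
    if res.atom("C") is None:
        raise GeometryError(
            f"residue {res.label}{res.seq_index}: missing carbonyl C (side reference)"
        )
    n, ca, cb, cg, cd = (res.atom(a).pos for a in RING_ATOMS)
    c = res.atom("C").pos
    base_normal = np.cross(ca - n, cd - n)
    nb = np.linalg.norm(base_normal)
    if nb < 1e-12:
        raise GeometryError("collinear N, CA, CD: base plane undefined")
    base_normal /= nb
    origin = (n + ca + cd) / 3.0
    d_cg = float(base_normal @ (cg - origin))
    d_c = float(base_normal @ (c - origin))
    # sign convention: positive displacement = toward the carbonyl side
    if d_c < 0:
        d_cg, d_c = -d_cg, -d_c
    phase, amplitude = _cremer_pople(np.vstack([n, ca, cb, cg, cd]))
    if abs(d_cg) < AMBIGUITY_FLOOR or d_c == 0.0:
        label = "ambiguous"
    elif d_cg > 0:
        label = "endo"
    else:
        label = "exo"
    return PuckerState(phase=phase, amplitude=amplitude, label=label, cg_displacement=d_cg)


def has_closed_ring(res: Residue) -> bool:
    """True when N..CD are present and CD-N closes a five-ring."""
    if any(res.atom(a) is None for a in RING_ATOMS):
        return False
    return float(np.linalg.norm(res.atom("CD").pos - res.atom("N").pos)) < RING_CLOSURE_CUTOFF


@dataclass
class PuckerTally:
    counts: dict[str, dict[str, int]]  # role key ("xxx"/"yyy") -> label -> count
    records: pd.DataFrame

    def fraction(self, role: str, label: str) -> float:
        c = self.counts[role]
        total = sum(c.values())
        return c.get(label, 0) / total if total else float("nan")


def pucker_profile(s: Structure, ta: TripletAssignment) -> PuckerTally:
    """Endo/exo/ambiguous tally at the Xxx and Yyy positions.

    Only residues with a closed pyrrolidine ring participate (glycines and
    non-cyclic residues such as arginine are skipped).
    """
    counts = {"xxx": {"endo": 0, "exo": 0, "ambiguous": 0},
              "yyy": {"endo": 0, "exo": 0, "ambiguous": 0}}
    rows = []
    for chain_id, triplets in ta.chains.items():
        for trip in triplets:
            for role_key, res in (("xxx", trip.xxx), ("yyy", trip.yyy)):
                if not has_closed_ring(res):
                    continue
                state = classify_pucker(res)
                counts[role_key][state.label] += 1
                rows.append(
                    {
                        "chain": chain_id,
                        "triplet": trip.triplet_index,
                        "position": role_key,
                        "residue": res.label,
                        "label": state.label,
                        "phase_deg": state.phase,
                        "amplitude_A": state.amplitude,
                        "cg_displacement_A": state.cg_displacement,
                    }
                )
    return PuckerTally(counts=counts, records=pd.DataFrame(rows))


def flip_preference_label(ring_flip_energy: float, tol: float = 1.0) -> str:
    """Discrete ring-flip preference from a relative flip energy (kJ/mol).

    Negative energies favor the exo state, positive the endo state; within
    ``tol`` of zero the preference is called balanced.
    """
    e = float(ring_flip_energy)
    if not np.isfinite(e):
        raise ValueError("ring-flip energy must be finite")
    if e < -tol:
        return "exo-preferring"
    if e > tol:
        return "endo-preferring"
    return "balanced"


# re-export for callers iterating positions
POSITION_ROLES = {ROLE_XXX: "xxx", ROLE_YYY: "yyy"}
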