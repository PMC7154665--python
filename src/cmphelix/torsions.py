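"""Backbone torsion computation and circular statistics for collagen triplets.

Conventions: phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1), i.e. omega is attached to the peptide
bond *following* residue i (trans ~ +-180 deg).  Angles are degrees in
[-180, 180).  Chain termini and residues with missing backbone atoms yield
undefined (None) entries, never fabricated values.

Triplet-averaged profiles use directional (circular) statistics: the mean is
the argument of the summed unit vectors and the SD is sqrt(-2 ln R) converted
to degrees.  For the tightly clustered angles of a collagen helix this is
numerically indistinguishable from arithmetic averaging, but it is exact
across the +-180 wrap where omega lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CmpHelixError, GeometryError, UndefinedStatisticError
from .geometry import dihedral, wrap_angle
from .model import Structure, TripletAssignment

ANGLE_NAMES = ("phi", "psi", "omega")
ROLE_KEYS = {"Xxx": "xxx", "Yyy": "yyy", "Gly": "gly"}

#: Canonical key order of a full triplet torsion profile.
PROFILE_KEYS = tuple(f"{a}_{r}" for r in ("xxx", "yyy", "gly") for a in ANGLE_NAMES)


@dataclass
class TorsionRecord:
    chain_id: str
    triplet_index: int
    role: str
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None
    undefined_reason: dict = field(default_factory=dict)


@dataclass
class TripletProfile:
    """Circular mean +- SD per (role x angle), pooled over chains."""

    stats: dict[str, tuple[float, float]]  # key e.g. "phi_xxx" -> (mean, sd)
    n_triplets: int
    selection: str

    def means(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.stats.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"angle": k, "mean_deg": m, "sd_deg": s}
            for k, (m, s) in self.stats.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class DeviationReport:
    deviations: dict[str, float]
    max_deviation: float
    threshold: float
    preorganized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"angle": k, "abs_deviation_deg": v} for k, v in self.deviations.items()]
        )


def _safe_dihedral(points) -> tuple[float | None, str]:
    try:
        return dihedral(*points), ""
    except GeometryError as exc:
        return None, str(exc)


def backbone_torsions(s: Structure, ta: TripletAssignment) -> list[TorsionRecord]:
    """Per-residue phi/psi/omega for every registered triplet residue."""
    records: list[TorsionRecord] = []
    chains = {ch.id: ch.residues for ch in s.peptide_chains()}
    for chain_id, triplets in ta.chains.items():
        residues = chains[chain_id]
        index_of = {id(r): i for i, r in enumerate(residues)}
        for trip in triplets:
            for res in (trip.xxx, trip.yyy, trip.gly):
                i = index_of[id(res)]
                rec = TorsionRecord(chain_id, trip.triplet_index, res.role)
                prev_res = residues[i - 1] if i > 0 else None
                next_res = residues[i + 1] if i + 1 < len(residues) else None
                n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
                if None in (n, ca, c):
                    missing = [x for x, a in zip(("N", "CA", "C"), (n, ca, c)) if a is None]
                    rec.undefined_reason = {a: f"missing backbone atom {missing}" for a in ANGLE_NAMES}
                    records.append(rec)
                    continue
                if prev_res is not None and prev_res.atom("C") is not None:
                    rec.phi, why = _safe_dihedral(
                        (prev_res.atom("C").pos, n.pos, ca.pos, c.pos)
                    )
                    if why:
                        rec.undefined_reason["phi"] = why
                else:
                    rec.undefined_reason["phi"] = "chain start or missing C(i-1)"
                if next_res is not None and next_res.atom("N") is not None:
                    rec.psi, why = _safe_dihedral((n.pos, ca.pos, c.pos, next_res.atom("N").pos))
                    if why:
                        rec.undefined_reason["psi"] = why
                    if next_res.atom("CA") is not None:
                        rec.omega, why = _safe_dihedral(
                            (ca.pos, c.pos, next_res.atom("N").pos, next_res.atom("CA").pos)
                        )
                        if why:
                            rec.undefined_reason["omega"] = why
                    else:
                        rec.undefined_reason["omega"] = "missing CA(i+1)"
                else:
                    rec.undefined_reason["psi"] = "chain end or missing N(i+1)"
                    rec.undefined_reason["omega"] = "chain end or missing N(i+1)"
                records.append(rec)
    return records


def circular_mean_sd(angles) -> tuple[float, float]:
    """Circular mean and SD (degrees) of angles in degrees.

    Mean is the argument of the summed unit vectors, wrapped to [-180, 180);
    SD is sqrt(-2 ln R) in degrees.  Raises for an empty sample or a sample
    with vanishing resultant (uniform: mean undefined).
    """
    a = np.asarray(list(angles), dtype=float)
    if a.size == 0:
        raise UndefinedStatisticError("circular mean of empty sample")
    rad = np.radians(a)
    z = np.exp(1j * rad).mean()
    if abs(z) < 1e-12:
        raise UndefinedStatisticError("resultant length ~ 0: circular mean undefined")
    mean = wrap_angle(np.degrees(np.angle(z)))
    sd = float(np.degrees(stats.circstd(rad)))
    return mean, sd


def records_to_frame(records: list[TorsionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chain": r.chain_id,
                "triplet": r.triplet_index,
                "role": r.role,
                "phi": r.phi,
                "psi": r.psi,
                "omega": r.omega,
            }
            for r in records
        ]
    )


def _central_window(n_available: int, n_wanted: int) -> tuple[int, int]:
    """1-based inclusive triplet window of n_wanted triplets centered on the
    chain midpoint; ties broken toward the N-terminus."""
    start = (n_available - n_wanted) // 2 + 1
    return start, start + n_wanted - 1


def average_profile(
    records: list[TorsionRecord],
    selection: dict | str = "all",
    per_chain: bool = False,
) -> TripletProfile:
    """Pool selected triplets (across chains by default) into a profile.

    ``selection`` is either ``"all"`` or ``{"central_n": k}``, the latter
    keeping the k consecutive triplets most distant from both termini of each
    chain (N-terminal tie-break).
    """
    by_chain: dict[str, list[TorsionRecord]] = {}
    for r in records:
        by_chain.setdefault(r.chain_id, []).append(r)

    selected: list[TorsionRecord] = []
    desc = "all"
    for chain_id, recs in by_chain.items():
        n_avail = max(r.triplet_index for r in recs)
        if isinstance(selection, dict) and "central_n" in selection:
            k = int(selection["central_n"])
            if k < 1 or k > n_avail:
                raise CmpHelixError(
                    f"chain {chain_id}: cannot select {k} central triplets out of {n_avail}"
                )
            lo, hi = _central_window(n_avail, k)
            desc = f"central {k}"
            selected.extend(r for r in recs if lo <= r.triplet_index <= hi)
        elif selection == "all":
            selected.extend(recs)
        else:
            raise ValueError(f"unknown selection {selection!r}")

    stats_out: dict[str, tuple[float, float]] = {}
    groups: dict[str, dict[str, list[float]]] = {}
    for r in selected:
        rk = ROLE_KEYS[r.role]
        for ang in ANGLE_NAMES:
            v = getattr(r, ang)
            if v is not None:
                key = f"{ang}_{rk}"
                if per_chain:
                    groups.setdefault(key, {}).setdefault(r.chain_id, []).append(v)
                else:
                    groups.setdefault(key, {}).setdefault("pooled", []).append(v)
    for key in PROFILE_KEYS:
        if key not in groups:
            continue
        if per_chain:
            chain_means = [circular_mean_sd(v)[0] for v in groups[key].values()]
            stats_out[key] = circular_mean_sd(chain_means)
        else:
            stats_out[key] = circular_mean_sd(groups[key]["pooled"])
    n_triplets = len({r.triplet_index for r in selected})
    return TripletProfile(stats=stats_out, n_triplets=n_triplets, selection=desc)


def circular_difference(a: float, b: float) -> float:
    """Absolute circular difference in degrees, in [0, 180]."""
    return abs(wrap_angle(a - b))


def deviation_report(
    torsions: TripletProfile | dict[str, float],
    reference: TripletProfile | dict[str, float],
    threshold: float = 15.0,
) -> DeviationReport:
    """Per-angle absolute circular deviation from a reference torsion set.

    Main-chain preorganization holds when every deviation stays below the
    threshold (default 15 deg).  The two sets must define identical angle
    keys; the report is symmetric in its arguments.
    """
    t = torsions.means() if isinstance(torsions, TripletProfile) else dict(torsions)
    ref = reference.means() if isinstance(reference, TripletProfile) else dict(reference)
    if set(t) != set(ref):
        raise CmpHelixError(
            f"angle key mismatch: {sorted(set(t) ^ set(ref))}"
        )
    if not t:
        raise CmpHelixError("empty torsion sets")
    dev = {k: circular_difference(t[k], ref[k]) for k in t}
    mx = max(dev.values())
    return DeviationReport(dev, mx, threshold, mx < threshold)
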