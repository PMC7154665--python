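"""Published reference values used as inputs and presets.

These are experimental/computed numbers for the Ac-(PPG)5-PRG-PPG-[XY]G-(PPG)3-NH2
peptide family and the (PPG)10 host lattice that the analysis modules compare
against: crystal-derived triplet torsion profiles, the four-category
triple-helix suitability marks with their summed score, CD-derived transition
temperatures, and the dipeptide torsions of the bridged diproline (ProM)
modules.  They are fixture data, never recomputed by this package.
"""

from __future__ import annotations

# Mean main-chain torsions of (PPG)10, rounded values (degrees).
PPG10_ROUNDED_MEANS = {
    "phi_xxx": -75.0,
    "psi_xxx": 164.0,
    "phi_yyy": -60.0,
    "psi_yyy": 152.0,
}

# Lowest-energy Ac-ProM1-OMe dipeptide main-chain torsions (degrees).
PROM1_DIPEPTIDE_TORSIONS = {
    "phi_xxx": -67.0,
    "psi_xxx": 170.0,
    "phi_yyy": -74.0,
    "psi_yyy": 160.0,
}

#: Main-chain preorganization bound: every torsion must deviate from the
#: (PPG)10 means by less than this (degrees).
PREORGANIZATION_THRESHOLD = 15.0

# Crystal triplet-averaged torsion profiles (mean, SD) in degrees, central
# nine triplets, for the ProM2-substituted CMP and the (PPG)10 reference.
CRYSTAL_PROFILES = {
    "ProM2-CMP": {
        "phi_xxx": (-73.8, 5.0),
        "psi_xxx": (163.6, 4.7),
        "omega_xxx": (174.2, 3.9),
        "phi_yyy": (-59.9, 3.5),
        "psi_yyy": (151.2, 3.8),
        "omega_yyy": (172.8, 4.1),
        "phi_gly": (-68.4, 3.9),
        "psi_gly": (173.8, 4.2),
        "omega_gly": (178.8, 2.9),
    },
    "PPG10": {
        "phi_xxx": (-74.5, 2.9),
        "psi_xxx": (164.3, 4.1),
        "omega_xxx": (176.0, 2.5),
        "phi_yyy": (-60.1, 3.6),
        "psi_yyy": (152.4, 2.6),
        "omega_yyy": (175.4, 3.4),
        "phi_gly": (-71.7, 3.7),
        "psi_gly": (175.9, 3.1),
        "omega_gly": (179.7, 2.0),
    },
}

# Experimental CD transition temperatures (deg C) of the CMP series,
# Ac-(PPG)5-PRG-PPG-[XY]G-(PPG)3-NH2 with [XY] as keyed below.
TRANSITION_TEMPERATURES = {
    "ProPro": 46.5,
    "ProHyp": 49.8,
    "ProM1": 39.3,
    "H2-ProM1": 39.9,
    "HO-ProM1": 43.0,
    "(HO)2-ProM1": 44.1,
    "(MeO)2-ProM1": 43.6,
    "(EtO)2-ProM1": 44.5,
    "ProM2": 43.8,
    "H2-ProM2": 45.1,
    "(HO)2-ProM2": 37.9,
    "(MeO)2-ProM2": 40.2,
    "(EtO)2-ProM2": 38.9,
}

# Four-category suitability marks and published summed score S, ordered by
# decreasing Tm.  Columns: main_chain, ring_flip, adaptability, sterics,
# S symbol, Tm (deg C).
RANKING_TABLE = [
    ("ProHyp", "o", "+", "+", "o", "++", 49.8),
    ("ProPro", "+", "-", "+", "o", "+", 46.5),
    ("H2-ProM2", "o", "+", "o", "o", "+", 45.1),
    ("(EtO)2-ProM1", "+", "o", "o", "o", "+", 44.5),
    ("(HO)2-ProM1", "+", "o", "o", "o", "+", 44.1),
    ("ProM2", "o", "+", "o", "o", "+", 43.8),
    ("(MeO)2-ProM1", "+", "o", "o", "o", "+", 43.6),
    ("HO-ProM1", "+", "o", "o", "o", "+", 43.0),
    ("(MeO)2-ProM2", "o", "+", "o", "-", "-", 40.2),
    ("H2-ProM1", "o", "-", "o", "o", "-", 39.9),
    ("ProM1", "o", "-", "o", "o", "-", 39.3),
    ("(EtO)2-ProM2", "o", "+", "o", "-", "-", 38.9),
    ("(HO)2-ProM2", "-", "+", "o", "o", "-", 37.9),
]
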