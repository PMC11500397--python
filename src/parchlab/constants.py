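"""Amino-acid alphabets, charge conventions and synthetic hazard defaults."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, in the conventional alphabetical one-letter order.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Residue names treated as solvent when reading PDB files.
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"})
ION_RESNAMES = {"NA": "Na+", "SOD": "Na+", "CL": "Cl-", "CLA": "Cl-"}

#: Formal charge at neutral pH. Histidine defaults to 0 (configurable where used).
FORMAL_CHARGE = {aa: 0 for aa in AA_ORDER}
FORMAL_CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})

#: Residues counted as charged for triad charge classes (His excluded by default).
CHARGED_RESIDUES = frozenset("DEKR")

# ---------------------------------------------------------------------------
# Synthetic hazard model defaults
#
# Escape hazard per recorded frame: h_aa(T) = a_aa * exp(-E_aa / T).
# A larger activation parameter E_aa means water escapes later, i.e. the
# residue type is more hydrophilic.  The ordering below runs from the most
# hydrophilic (lysine, the reference) to the most hydrophobic (leucine); the
# E values are linearly spaced so the time-averaged contact autocorrelation
# spans roughly 0.05-0.85 under the default annealing schedule.
# ---------------------------------------------------------------------------

HYDROPHILICITY_ORDER = list("KREDQNHSTGPYCWAMFVIL")

_E_VALUES = np.linspace(2200.0, 600.0, len(HYDROPHILICITY_ORDER))

#: aa -> (prefactor a_aa, activation E_aa), arbitrary temperature units.
DEFAULT_HAZARD_MODEL: dict[str, tuple[float, float]] = {
    aa: (1.0, float(e)) for aa, e in zip(HYDROPHILICITY_ORDER, _E_VALUES)
}

# Rough natural relative abundances used when drawing synthetic residue types.
# Values are renormalised within the charged {D,E,K,R} and uncharged classes.
_NATURAL_FREQ = {
    "L": 9.9, "A": 8.2, "G": 7.1, "V": 6.9, "S": 6.6, "I": 5.9, "T": 5.3,
    "F": 3.9, "P": 4.7, "N": 4.1, "Q": 3.9, "Y": 2.9, "M": 2.4, "H": 2.3,
    "W": 1.1, "C": 1.4,
    "E": 6.7, "K": 5.8, "R": 5.5, "D": 5.5,
}

CHARGED_TYPE_WEIGHTS = {
    aa: _NATURAL_FREQ[aa] / sum(_NATURAL_FREQ[x] for x in "DEKR") for aa in "DEKR"
}
_UNCHARGED = [aa for aa in AA_ORDER if aa not in CHARGED_RESIDUES]
UNCHARGED_TYPE_WEIGHTS = {
    aa: _NATURAL_FREQ[aa] / sum(_NATURAL_FREQ[x] for x in _UNCHARGED)
    for aa in _UNCHARGED
}
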