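"""Amino-acid alphabet constants shared across the package.

The background composition is the Robinson & Robinson proteome-average
table, the composition classically used to parameterise local-alignment
statistics; it is embedded as constants so decoy generation and E-value
calibration are stable across runs and environments.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Index lookup for :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Gap character used internally; '.' is accepted on input and converted.
GAP: str = "-"

#: Placeholder for unknown/ambiguous residues.
UNKNOWN: str = "X"

# Robinson-Robinson average amino-acid frequencies (renormalised to sum 1).
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

#: Background frequencies aligned with :data:`AMINO_ACIDS`, summing to 1.
BACKGROUND: np.ndarray = np.array([_RR[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

BACKGROUND_DICT: dict[str, float] = dict(zip(AMINO_ACIDS, BACKGROUND))


def sample_background(rng: np.random.Generator, length: int) -> str:
    """Draw an i.i.d. background-composition peptide of ``length`` residues."""
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)
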