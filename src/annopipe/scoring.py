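"""Shared scoring constants: alphabet, substitution matrix, null model.

The 20 standard amino acids are indexed in the order ``ARNDCQEGHILKMFPSTWYV``
(the classic substitution-matrix ordering); index 20 is the ambiguity
symbol ``X``, which scores 0 against everything (neutral).  Background
amino-acid frequencies are the BLOSUM62 marginals; the same composition is
used by the search engine's null model and by the fixture generators.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

AA = "ARNDCQEGHILKMFPSTWYV"
AA_X = AA + "X"
X_INDEX = 20
AA_INDEX = {a: i for i, a in enumerate(AA_X)}

PROTEIN_ALPHABET = frozenset(AA) | {"X", "*"}
DNA_ALPHABET = frozenset("ACGTN")

# BLOSUM62 marginal (background) amino-acid frequencies, in AA order.
_BLOSUM62_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

# Gumbel parameters for gapped BLOSUM62 with gap open 11 / extend 1
# (the published values used by BLAST for this scoring system).
GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041

EULER_GAMMA = 0.5772156649015329


@functools.cache
def background_frequencies() -> np.ndarray:
    """Length-20 vector of background amino-acid frequencies (sums to 1)."""
    bg = np.array([_BLOSUM62_BG[a] for a in AA], dtype=float)
    return bg / bg.sum()


@functools.cache
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 integer array in AA_X order; X rows/cols are 0."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = int(mat[a, b])
    return out


@functools.cache
def blosum62_rows() -> tuple:
    """blosum62() as nested Python lists (fast row lookup in the DP loops)."""
    return tuple(tuple(int(v) for v in row) for row in blosum62())


@functools.cache
def conditional_substitution() -> np.ndarray:
    """P(a | b): probability of residue a given a homologous residue b.

    Derived from the BLOSUM62 half-bit log-odds s(a,b) and the marginals
    p_a via P(a|b) proportional to p_a * 2**(s(a,b)/2), normalised over a
    for each b.  Used for pseudocount mixing in profile construction and
    for drawing biologically plausible point mutations in fixtures.
    Rows are b (the conditioning residue), columns a.
    """
    bg = background_frequencies()
    s = blosum62()[:20, :20].astype(float)
    cond = bg[None, :] * np.power(2.0, s / 2.0)  # cond[b, a]; s is symmetric
    cond /= cond.sum(axis=1, keepdims=True)
    return cond


def encode(residues: str) -> list[int]:
    """Encode a protein string to integer indices; unknowns map to X."""
    idx = AA_INDEX
    x = X_INDEX
    return [idx.get(c, x) for c in residues]


def decode(indices) -> str:
    return "".join(AA_X[i] for i in indices)
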