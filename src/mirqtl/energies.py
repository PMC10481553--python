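"""Embedded thermodynamic parameters for the default RNA folding engine.

This is a deliberately compact approximation of the nearest-neighbour model:
stacking free energies for the 16 allowed base-pair stacks (Watson-Crick plus
G:U wobble) and size-dependent penalties for hairpin, bulge and internal
loops, with an affine multiloop term. It is NOT the full Turner 2004
parameter set (no dangles, no terminal-AU penalties, no tetraloop bonuses,
no loop asymmetry terms); the folding contract allows a full-featured
external predictor to be plugged in where those refinements matter. Values
are in kcal/mol at 37 degC and are in the range of the published
nearest-neighbour measurements, which keeps the -15 kcal/mol precursor
stability threshold meaningful.
"""

from __future__ import annotations

import numpy as np

# Base encoding used throughout the folding code.
BASES = "ACGT"  # T stands for U internally
A, C, G, T = 0, 1, 2, 3

# Pair type indices: AU, UA, GC, CG, GU, UG (first base is 5' of the pair).
N_PAIRS = 6
PAIRIDX = -np.ones((4, 4), dtype=np.int64)
PAIRIDX[A, T] = 0
PAIRIDX[T, A] = 1
PAIRIDX[G, C] = 2
PAIRIDX[C, G] = 3
PAIRIDX[G, T] = 4
PAIRIDX[T, G] = 5

# Stack free energies, indexed [outer pair][inner pair] where the inner pair
# is (i+1, j-1) for an outer pair (i, j). Approximate nearest-neighbour
# magnitudes: GC-rich stacks are strongest, wobble stacks weakest.
STACK = np.array(
    [
        #  AU     UA     GC     CG     GU     UG
        [-0.90, -1.30, -2.10, -2.20, -0.60, -1.40],  # AU
        [-1.10, -0.90, -2.40, -2.10, -1.40, -1.00],  # UA
        [-2.20, -2.10, -3.30, -2.40, -1.50, -2.50],  # GC
        [-2.10, -2.40, -3.40, -3.30, -2.10, -2.10],  # CG
        [-0.60, -1.40, -2.10, -2.50, -0.50, -0.20],  # GU
        [-1.40, -1.00, -2.50, -2.10, -0.20, -0.50],  # UG
    ],
    dtype=np.float64,
)

MIN_HAIRPIN = 3  # minimum unpaired bases closing a hairpin loop
MAXLOOP = 30  # largest bulge/internal loop (total unpaired) considered
MAX_SEQ = 600  # longest sequence the precomputed loop tables cover

# Multiloop: E = ML_CLOSE + ML_BRANCH * (branches incl. the closing pair).
ML_CLOSE = 3.4
ML_BRANCH = 0.4

INF = 1e9


def _extrapolate(table: dict[int, float], max_len: int) -> np.ndarray:
    """Tabulated penalties with Jacobson-Stockmayer log extrapolation."""
    arr = np.full(max_len + 1, INF)
    last = max(table)
    for size, val in table.items():
        arr[size] = val
    for size in range(last + 1, max_len + 1):
        arr[size] = table[last] + 1.07 * np.log(size / last)
    return arr


HAIRPIN_LOOP = _extrapolate(
    {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}, MAX_SEQ
)
BULGE_LOOP = _extrapolate({1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}, MAXLOOP)
INTERNAL_LOOP = _extrapolate({2: 1.7, 3: 2.7, 4: 3.3, 5: 3.6, 6: 4.0}, MAXLOOP)


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T(/U) string to the integer alphabet of the engine."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    lut[ord("U")] = T
    arr = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({ch for ch in seq.upper() if ch not in "ACGTU"})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return arr.astype(np.int64)
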