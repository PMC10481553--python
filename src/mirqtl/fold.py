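"""Minimum-free-energy folding of nested RNA secondary structures.

The default engine is a Zuker-style dynamic program over the embedded
nearest-neighbour tables in :mod:`mirqtl.energies`. Alongside it this module
provides an independent reference path used for validation:
``enumerate_structures`` generates every nested structure of a short
sequence and ``structure_energy`` evaluates a structure by loop
decomposition, so ``exhaustive_mfe`` realizes the same energy model by brute
force. The two paths share only the parameter tables.

The energy model: allowed pairs are Watson-Crick plus G:U wobble; a hairpin
loop needs >= 3 unpaired bases; bulge/internal loops are capped at
MAXLOOP=30 total unpaired bases; multiloops cost an affine closing penalty
plus a per-branch term. Pseudoknots are out of scope.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .energies import (
    BULGE_LOOP,
    HAIRPIN_LOOP,
    INF,
    INTERNAL_LOOP,
    MAX_SEQ,
    MAXLOOP,
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSE,
    PAIRIDX,
    STACK,
    encode,
)
from .util import normalize_seq

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


_EPS = 1e-7


@dataclass(frozen=True)
class HairpinStructure:
    """A folded sequence: dot-bracket string, pair table and its energy.

    ``pair_table`` is 1-based like the classic RNA conventions: entry ``k``
    holds the partner of position ``k`` (0 when unpaired); entry 0 is unused.
    """

    sequence: str
    dot_bracket: str
    pair_table: tuple[int, ...]
    mfe: float

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """0-based (i, j) pairs with i < j."""
        return tuple(
            (k - 1, self.pair_table[k] - 1)
            for k in range(1, len(self.sequence) + 1)
            if self.pair_table[k] > k
        )

    def partner(self, pos0: int) -> int:
        """0-based partner of 0-based position, or -1 when unpaired."""
        return self.pair_table[pos0 + 1] - 1


@njit(cache=False)
def _dp_fill(s, pairidx, stack, hairpin, bulge, internal, maxloop, ml_close, ml_branch, inf):
    n = s.shape[0]
    V = np.full((n, n), inf)
    M = np.full((n, n), inf)
    M1 = np.full((n, n), inf)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            pij = pairidx[s[i], s[j]]
            if pij >= 0:
                best = hairpin[j - i - 1] if (j - i - 1) <= MAX_SEQ else inf
                # stack on the adjacent inner pair
                pin = pairidx[s[i + 1], s[j - 1]]
                if pin >= 0 and V[i + 1, j - 1] < inf / 2:
                    e = stack[pij, pin] + V[i + 1, j - 1]
                    if e < best:
                        best = e
                # bulge and internal loops up to maxloop total unpaired
                for k in range(i + 1, min(i + maxloop + 2, j - 4) + 1):
                    n1 = k - i - 1
                    if n1 > maxloop:
                        break
                    lmin = j - 1 - (maxloop - n1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(lmin, j):
                        n2 = j - l - 1
                        if n1 + n2 == 0:
                            continue  # stack handled above
                        if V[k, l] >= inf / 2:
                            continue
                        if n1 == 0 or n2 == 0:
                            pen = bulge[n1 + n2]
                        else:
                            pen = internal[n1 + n2]
                        e = pen + V[k, l]
                        if e < best:
                            best = e
                # multiloop: >=2 branches strictly inside
                for k in range(i + 2, j - 1):
                    if M[i + 1, k - 1] < inf / 2 and M1[k, j - 1] < inf / 2:
                        e = ml_close + ml_branch + M[i + 1, k - 1] + M1[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # M1: exactly one branch starting at i, optional unpaired tail
            best1 = inf
            if j > i and M1[i, j - 1] < inf / 2:
                best1 = M1[i, j - 1]
            if V[i, j] < inf / 2:
                e = V[i, j] + ml_branch
                if e < best1:
                    best1 = e
            M1[i, j] = best1
            # M: >=1 branch, free unpaired bases anywhere
            bestm = inf
            if j > i and M[i, j - 1] < inf / 2:
                bestm = M[i, j - 1]
            for k in range(i, j - 3):
                if V[k, j] >= inf / 2:
                    continue
                prefix = 0.0
                if k > i:
                    if M[i, k - 1] < prefix:
                        prefix = M[i, k - 1]
                e = prefix + V[k, j] + ml_branch
                if e < bestm:
                    bestm = e
            M[i, j] = bestm
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for k in range(0, j - 3):
            if V[k, j] >= inf / 2:
                continue
            e = (W[k - 1] if k > 0 else 0.0) + V[k, j]
            if e < best:
                best = e
        W[j] = best
    return V, M, M1, W


def _traceback(s, V, M, M1, W) -> list[tuple[int, int]]:
    """Recover one MFE pair set, mirroring the fill order deterministically."""
    n = s.shape[0]
    pairs: list[tuple[int, int]] = []
    stack: list[tuple] = [("W", n - 1)]
    while stack:
        task = stack.pop()
        kind = task[0]
        if kind == "W":
            j = task[1]
            if j < 0:
                continue
            if j > 0 and abs(W[j] - W[j - 1]) < _EPS:
                stack.append(("W", j - 1))
                continue
            if abs(W[j]) < _EPS and j == 0:
                continue
            for k in range(0, j - 3):
                prev = W[k - 1] if k > 0 else 0.0
                if V[k, j] < INF / 2 and abs(W[j] - (prev + V[k, j])) < _EPS:
                    stack.append(("V", k, j))
                    if k > 0:
                        stack.append(("W", k - 1))
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in W")
        elif kind == "V":
            i, j = task[1], task[2]
            pairs.append((i, j))
            e = V[i, j]
            if abs(e - HAIRPIN_LOOP[j - i - 1]) < _EPS:
                continue
            pij = PAIRIDX[s[i], s[j]]
            pin = PAIRIDX[s[i + 1], s[j - 1]]
            if (
                pin >= 0
                and V[i + 1, j - 1] < INF / 2
                and abs(e - (STACK[pij, pin] + V[i + 1, j - 1])) < _EPS
            ):
                stack.append(("V", i + 1, j - 1))
                continue
            found = False
            for k in range(i + 1, min(i + MAXLOOP + 2, j - 4) + 1):
                n1 = k - i - 1
                if n1 > MAXLOOP:
                    break
                lmin = max(k + 4, j - 1 - (MAXLOOP - n1))
                for l in range(lmin, j):
                    n2 = j - l - 1
                    if n1 + n2 == 0 or V[k, l] >= INF / 2:
                        continue
                    pen = BULGE_LOOP[n1 + n2] if (n1 == 0 or n2 == 0) else INTERNAL_LOOP[n1 + n2]
                    if abs(e - (pen + V[k, l])) < _EPS:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if (
                    M[i + 1, k - 1] < INF / 2
                    and M1[k, j - 1] < INF / 2
                    and abs(e - (ML_CLOSE + ML_BRANCH + M[i + 1, k - 1] + M1[k, j - 1])) < _EPS
                ):
                    stack.append(("M", i + 1, k - 1))
                    stack.append(("M1", k, j - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in V")
        elif kind == "M1":
            i, j = task[1], task[2]
            if j > i and abs(M1[i, j] - M1[i, j - 1]) < _EPS:
                stack.append(("M1", i, j - 1))
            elif V[i, j] < INF / 2 and abs(M1[i, j] - (V[i, j] + ML_BRANCH)) < _EPS:
                stack.append(("V", i, j))
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M1")
        else:  # M
            i, j = task[1], task[2]
            if j > i and abs(M[i, j] - M[i, j - 1]) < _EPS:
                stack.append(("M", i, j - 1))
                continue
            found = False
            for k in range(i, j - 3):
                if V[k, j] >= INF / 2:
                    continue
                prefix = min(0.0, M[i, k - 1]) if k > i else 0.0
                if abs(M[i, j] - (prefix + V[k, j] + ML_BRANCH)) < _EPS:
                    stack.append(("V", k, j))
                    if k > i and prefix < 0:
                        stack.append(("M", i, k - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M")
    return pairs


@functools.lru_cache(maxsize=4096)
def fold(sequence: str) -> HairpinStructure:
    """Fold a sequence to its minimum-free-energy nested structure.

    Deterministic: repeated calls return the identical structure. An
    unstructured sequence (no favourable pairs) returns an all-dot structure
    at 0 kcal/mol. Ties against the empty structure resolve to the empty
    structure, so a returned structure with pairs always has mfe < 0.
    """
    seq = normalize_seq(sequence)
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 10 nt)")
    if len(seq) > MAX_SEQ:
        raise ValueError(f"sequence longer than supported ({len(seq)} > {MAX_SEQ} nt)")
    s = encode(seq)
    V, M, M1, W = _dp_fill(
        s, PAIRIDX, STACK, HAIRPIN_LOOP, BULGE_LOOP, INTERNAL_LOOP,
        MAXLOOP, ML_CLOSE, ML_BRANCH, INF,
    )
    mfe = min(float(W[len(seq) - 1]), 0.0)
    pairs = _traceback(s, V, M, M1, W) if mfe < -_EPS else []
    n = len(seq)
    pt = [0] * (n + 1)
    db = ["."] * n
    for i, j in pairs:
        pt[i + 1] = j + 1
        pt[j + 1] = i + 1
        db[i] = "("
        db[j] = ")"
    return HairpinStructure(seq, "".join(db), tuple(pt), round(mfe, 6))


# ---------------------------------------------------------------------------
# Reference path: loop-decomposition evaluation and exhaustive enumeration.
# ---------------------------------------------------------------------------

def structure_energy(sequence: str, pairs) -> float:
    """Free energy of one explicit nested structure by loop decomposition.

    Independent of the dynamic program: walks the structure tree and sums
    hairpin/stack/bulge/internal/multiloop terms from the shared tables.
    Returns +inf for structures outside the model (unpairable bases, loops
    above MAXLOOP, hairpin loops below the minimum).
    """
    s = encode(normalize_seq(sequence))
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    for i, j in plist:
        if PAIRIDX[s[i], s[j]] < 0 or j - i - 1 < MIN_HAIRPIN:
            return INF
    # children of each pair under nesting (crossing pairs -> invalid)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    open_stack: list[tuple[int, int]] = []
    for p in plist:
        while open_stack and open_stack[-1][1] < p[0]:
            open_stack.pop()
        if open_stack:
            outer = open_stack[-1]
            if p[1] > outer[1]:
                return INF  # crossing
            children[outer].append(p)
        open_stack.append(p)
    energy = 0.0
    for (i, j), kids in children.items():
        if not kids:
            energy += HAIRPIN_LOOP[j - i - 1]
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                energy += STACK[PAIRIDX[s[i], s[j]], PAIRIDX[s[k], s[l]]]
            elif n1 + n2 > MAXLOOP:
                return INF
            elif n1 == 0 or n2 == 0:
                energy += BULGE_LOOP[n1 + n2]
            else:
                energy += INTERNAL_LOOP[n1 + n2]
        else:
            energy += ML_CLOSE + ML_BRANCH * (len(kids) + 1)
    return energy


def enumerate_structures(sequence: str) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every nested structure (as 0-based pair tuples), incl. empty."""
    s = encode(normalize_seq(sequence))
    n = len(s)

    def gen(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        if j - i + 1 <= 0:
            yield ()
            return
        # i unpaired
        yield from gen(i + 1, j)
        # i paired to k
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if PAIRIDX[s[i], s[k]] < 0:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield ((i, k),) + inner + outer

    yield from gen(0, n - 1)


def exhaustive_mfe(sequence: str) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Brute-force MFE over all nested structures; validation oracle only.

    Exponential in length; intended for sequences of <= ~20 nt.
    """
    best_e, best_p = 0.0, ()
    for pairs in enumerate_structures(sequence):
        e = structure_energy(sequence, pairs)
        if e < best_e - 1e-12:
            best_e, best_p = e, pairs
    return best_e, best_p
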