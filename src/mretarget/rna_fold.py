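"""Minimum-free-energy RNA structure prediction used by the feature encoder.

Two routines are provided, mirroring the classic Vienna pair of tools:

* :func:`fold_single` - single-strand MFE structure of one sequence
  (dynamic program over base-pair stabilities with a minimum hairpin loop
  of 3 nt), returning a dot-bracket string and an energy.
* :func:`fold_duplex` - intermolecular co-fold of a miRNA against a target
  window using nearest-neighbor stacking energies (Turner-style table),
  small bulge/internal-loop penalties, and a duplex-initiation cost.

This is a deliberately compact nearest-neighbor model, not a full Turner
2004 implementation: it guarantees determinism, balanced brackets, and
negative energies whenever pairs are reported, which is the contract the
downstream encoder relies on.  Energies are in kcal/mol.

The O(n^3) single-strand DP is JIT-compiled with numba; the first call in a
process pays a one-off compilation cost of a few seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from mretarget.errors import DataError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# Pair stabilities for the single-strand DP (kcal/mol).
_PAIR_ENERGY = np.zeros((4, 4), dtype=np.float64)
_PAIR_ENERGY[_BASE_INDEX["G"], _BASE_INDEX["C"]] = -3.0
_PAIR_ENERGY[_BASE_INDEX["C"], _BASE_INDEX["G"]] = -3.0
_PAIR_ENERGY[_BASE_INDEX["A"], _BASE_INDEX["U"]] = -2.0
_PAIR_ENERGY[_BASE_INDEX["U"], _BASE_INDEX["A"]] = -2.0
_PAIR_ENERGY[_BASE_INDEX["G"], _BASE_INDEX["U"]] = -1.0
_PAIR_ENERGY[_BASE_INDEX["U"], _BASE_INDEX["G"]] = -1.0

# Pair types for the duplex stacking table: AU, UA, GC, CG, GU, UG.
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _i, (_a, _b) in enumerate([("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]):
    _PAIR_TYPE[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _i

# Nearest-neighbor stacking energies, kcal/mol; rows = 5' pair of the stack
# read along the miRNA strand, columns = 3' pair.  Approximate Turner values.
_STACK = np.array(
    [
        #  AU     UA     GC     CG     GU     UG
        [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],  # AU
        [-1.3, -0.9, -2.1, -2.4, -1.0, -1.3],  # UA
        [-2.4, -2.2, -3.3, -3.4, -1.5, -2.5],  # GC
        [-2.1, -2.1, -2.4, -3.3, -1.4, -2.1],  # CG
        [-1.3, -1.4, -2.1, -2.5, -0.5, +1.3],  # GU
        [-1.0, -0.6, -1.4, -1.5, +0.3, -0.5],  # UG
    ],
    dtype=np.float64,
)

_DUPLEX_INIT = 4.1  # duplex initiation cost, kcal/mol
_LOOP_OPEN = 1.8    # bulge/internal-loop opening
_LOOP_PER_NT = 0.4  # per unpaired nucleotide
_MAX_LOOP = 4       # max unpaired run on either strand inside the duplex
_MIN_HAIRPIN = 3    # minimum hairpin loop for single-strand folding

_INF = 1e9


def encode_bases(seq: str) -> np.ndarray:
    """Map an RNA string to integer codes; N is folded as A (weakest pairer)."""
    s = seq.replace("N", "A")
    try:
        return np.array([_BASE_INDEX[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise DataError(f"cannot fold sequence with symbol {exc.args[0]!r}") from exc


@njit(cache=True)
def _fold_dp(codes, pair_energy):  # pragma: no cover - exercised via fold_single
    n = codes.shape[0]
    E = np.zeros((n, n), dtype=np.float64)
    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            e = pair_energy[codes[i], codes[j]]
            if e < 0.0:
                v = E[i + 1, j - 1] + e
                if v < best:
                    best = v
            for k in range(i + 1, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return E


def fold_single(seq: str) -> tuple[str, float]:
    """MFE dot-bracket structure of a single RNA strand.

    Returns ``(structure, energy)``; an unfoldable sequence (e.g. poly-A)
    yields all dots and energy 0.0.  Deterministic traceback.
    """
    if len(seq) < 2:
        return "." * len(seq), 0.0
    codes = encode_bases(seq)
    E = _fold_dp(codes, _PAIR_ENERGY)
    n = len(seq)
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= _MIN_HAIRPIN and E[i, j] == 0.0:
            continue
        e = E[i, j]
        if e == 0.0:
            continue
        pe = _PAIR_ENERGY[codes[i], codes[j]]
        if pe < 0.0 and j - i > _MIN_HAIRPIN and e == E[i + 1, j - 1] + pe:
            struct[i], struct[j] = "(", ")"
            stack.append((i + 1, j - 1))
        elif e == E[i + 1, j]:
            stack.append((i + 1, j))
        elif e == E[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if e == E[i, k] + E[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return "".join(struct), float(E[0, n - 1])


@njit(cache=True)
def _duplex_dp(q, t, pair_type, stack_tab):  # pragma: no cover - via fold_duplex
    nq, nt = q.shape[0], t.shape[0]
    E = np.full((nq, nt), _INF, dtype=np.float64)
    Pi = np.full((nq, nt), -1, dtype=np.int64)
    Pj = np.full((nq, nt), -1, dtype=np.int64)
    for i in range(nq):
        for j in range(nt):
            p2 = pair_type[q[i], t[j]]
            if p2 < 0:
                continue
            best = _DUPLEX_INIT
            bi, bj = -1, -1
            ilo = i - 1 - _MAX_LOOP
            if ilo < 0:
                ilo = 0
            for i2 in range(ilo, i):
                jhi = j + 1 + _MAX_LOOP
                if jhi > nt - 1:
                    jhi = nt - 1
                for j2 in range(j + 1, jhi + 1):
                    if E[i2, j2] >= _INF:
                        continue
                    gap_q = i - i2 - 1
                    gap_t = j2 - j - 1
                    if gap_q == 0 and gap_t == 0:
                        p1 = pair_type[q[i2], t[j2]]
                        cost = stack_tab[p1, p2]
                    else:
                        cost = _LOOP_OPEN + _LOOP_PER_NT * (gap_q + gap_t)
                    v = E[i2, j2] + cost
                    if v < best:
                        best = v
                        bi, bj = i2, j2
            E[i, j] = best
            Pi[i, j] = bi
            Pj[i, j] = bj
    return E, Pi, Pj


def fold_duplex(mirna_seq: str, target_seq: str) -> tuple[str, str, float, list]:
    """Co-fold a miRNA against a target window (antiparallel duplex).

    Returns ``(mirna_structure, target_structure, mfe, pairs)`` where the
    structures are dot-bracket strings over the respective inputs ('(' on
    the miRNA strand, ')' on the target strand), ``pairs`` is a list of
    ``(mirna_index, target_index)`` 0-based pairs, and ``mfe`` <= 0 whenever
    any pair is reported.  When no duplex with negative energy exists the
    structures are all dots and mfe is 0.0.
    """
    if not mirna_seq or not target_seq:
        raise DataError("fold_duplex requires two non-empty sequences")
    q = encode_bases(mirna_seq)
    t = encode_bases(target_seq)
    E, Pi, Pj = _duplex_dp(q, t, _PAIR_TYPE, _STACK)
    best = float(np.min(E))
    qs = ["."] * len(q)
    ts = ["."] * len(t)
    if best >= 0.0:
        return "".join(qs), "".join(ts), 0.0, []
    i, j = np.unravel_index(int(np.argmin(E)), E.shape)
    pairs = []
    while i >= 0 and j >= 0:
        pairs.append((int(i), int(j)))
        qs[i], ts[j] = "(", ")"
        i, j = int(Pi[i, j]), int(Pj[i, j])
    pairs.reverse()
    return "".join(qs), "".join(ts), best, pairs
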