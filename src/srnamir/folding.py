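"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over pseudoknot-free structures with a
nearest-neighbor energy model: sequence-dependent stacking energies for
adjacent base pairs, size-dependent hairpin and interior/bulge loop
penalties, and an affine multiloop cost.  The model is deliberately compact
(no dangles, no coaxial stacking, no terminal-AU penalties) so that the
energy of *any* structure is well defined and the DP optimum can be checked
against exhaustive enumeration on short sequences.

Energies are kcal/mol; the open (all-unpaired) chain scores 0, so the MFE is
never positive.  T and U are equivalent on input.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired bases closed by a pair
MAX_INTERIOR = 30  # max total unpaired bases in an interior/bulge loop
MIN_FOLD_LEN = 8

# base coding: A=0 C=1 G=2 T/U=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair types AU UA GC CG GU UG -> 0..5, -1 = not pairable
PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _i, (_a, _b) in enumerate([(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]):
    PAIR_TYPE[_a, _b] = _i

# stacking energies: STACK[pt(i,j), pt(i+1,j-1)], approximate Turner values
STACK = np.array(
    [
        #  AU     UA     GC     CG     GU     UG
        [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],  # AU
        [-1.3, -0.9, -2.4, -2.1, -1.0, -1.3],  # UA
        [-2.4, -2.2, -3.3, -3.4, -1.5, -2.5],  # GC
        [-2.1, -2.1, -2.4, -3.3, -1.4, -2.1],  # CG
        [-1.3, -1.4, -2.1, -2.5, -0.5, 1.3],  # GU
        [-1.0, -0.6, -1.4, -1.5, 0.3, -0.5],  # UG
    ],
    dtype=np.float64,
)

# multiloop affine cost: closing + per-branch + per-unpaired
ML_CLOSE = 3.4
ML_BRANCH = 0.4
ML_UNPAIRED = 0.0

_RT_LOOP = 1.75 * 0.616  # Jacobson-Stockmayer extrapolation slope


def _loop_tables(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Hairpin and interior/bulge loop penalties for sizes 0..n."""
    hp = np.full(n + 1, INF)
    il = np.full(n + 1, INF)
    hp_small = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    il_small = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    for size in range(MIN_HAIRPIN, n + 1):
        hp[size] = hp_small.get(size, 6.4 + _RT_LOOP * math.log(size / 9.0))
    for size in range(1, n + 1):
        il[size] = il_small.get(size, 4.4 + _RT_LOOP * math.log(size / 6.0))
    return hp, il


_HP_CACHE, _IL_CACHE = _loop_tables(4096)


def encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[c] for c in s], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGTU base in sequence: {e.args[0]!r}") from None


@njit(cache=True)
def _fill(s, pair_type, stack, hp, il, ml_close, ml_branch, ml_unpaired, max_interior):
    n = s.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_type[s[i], s[j]]
            if pt >= 0:
                # hairpin
                best = hp[j - i - 1]
                # stack / interior / bulge
                for k in range(i + 1, j - 1):
                    d1 = k - i - 1
                    if d1 > max_interior:
                        break
                    lmin = j - 1 - (max_interior - d1)
                    if lmin < k + 1:
                        lmin = k + 1
                    for l in range(j - 1, lmin - 1, -1):
                        if l - k <= MIN_HAIRPIN:
                            break
                        if V[k, l] >= INF:
                            continue
                        d2 = j - l - 1
                        if d1 == 0 and d2 == 0:
                            e = stack[pt, pair_type[s[k], s[l]]]
                        else:
                            e = il[d1 + d2]
                        cand = V[k, l] + e
                        if cand < best:
                            best = cand
                # multiloop closure (>= 2 inner branches)
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = WM[i + 1, k] + WM[k + 1, j - 1] + ml_close + ml_branch
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM: part of a multiloop containing >= 1 branch
            best = INF
            if V[i, j] < best:
                best = V[i, j] + ml_branch
            if WM[i + 1, j] + ml_unpaired < best:
                best = WM[i + 1, j] + ml_unpaired
            if WM[i, j - 1] + ml_unpaired < best:
                best = WM[i, j - 1] + ml_unpaired
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    cand = WM[i, k - 1] + WM[k, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    return V, WM


def _exterior(V: np.ndarray) -> np.ndarray:
    """Prefix minima over the exterior loop (branches are free)."""
    n = V.shape[0]
    W = np.zeros(n)
    for j in range(1, n):
        best = W[j - 1]
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF:
                prev = W[i - 1] if i > 0 else 0.0
                cand = prev + V[i, j]
                if cand < best:
                    best = cand
        W[j] = best
    return W


_TOL = 1e-6


def _traceback(s, V, WM, W, hp, il) -> list[tuple[int, int]]:
    n = s.shape[0]
    pairs: list[tuple[int, int]] = []
    work: list[tuple[str, int, int]] = []

    # exterior loop
    j = n - 1
    while j > 0:
        if abs(W[j] - W[j - 1]) <= _TOL:
            j -= 1
            continue
        for i in range(0, j - MIN_HAIRPIN):
            prev = W[i - 1] if i > 0 else 0.0
            if V[i, j] < INF and abs(prev + V[i, j] - W[j]) <= _TOL:
                work.append(("V", i, j))
                j = i - 1
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("exterior traceback failed")

    while work:
        state, i, j = work.pop()
        if state == "V":
            pairs.append((i, j))
            if abs(V[i, j] - hp[j - i - 1]) <= _TOL:
                continue
            pt = PAIR_TYPE[s[i], s[j]]
            found = False
            for k in range(i + 1, j - 1):
                d1 = k - i - 1
                if d1 > MAX_INTERIOR or found:
                    break
                for l in range(j - 1, k + MIN_HAIRPIN, -1):
                    d2 = j - l - 1
                    if d1 + d2 > MAX_INTERIOR:
                        break
                    if V[k, l] >= INF:
                        continue
                    e = (
                        STACK[pt, PAIR_TYPE[s[k], s[l]]]
                        if d1 == 0 and d2 == 0
                        else il[d1 + d2]
                    )
                    if abs(V[k, l] + e - V[i, j]) <= _TOL:
                        work.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                    if (
                        abs(
                            WM[i + 1, k]
                            + WM[k + 1, j - 1]
                            + ML_CLOSE
                            + ML_BRANCH
                            - V[i, j]
                        )
                        <= _TOL
                    ):
                        work.append(("M", i + 1, k))
                        work.append(("M", k + 1, j - 1))
                        found = True
                        break
            if not found:  # pragma: no cover - defensive
                raise AssertionError(f"V traceback failed at ({i},{j})")
        else:  # multiloop component
            while True:
                if V[i, j] < INF and abs(WM[i, j] - (V[i, j] + ML_BRANCH)) <= _TOL:
                    work.append(("V", i, j))
                    break
                if abs(WM[i, j] - (WM[i + 1, j] + ML_UNPAIRED)) <= _TOL and WM[
                    i + 1, j
                ] < INF:
                    i += 1
                    continue
                if abs(WM[i, j] - (WM[i, j - 1] + ML_UNPAIRED)) <= _TOL and WM[
                    i, j - 1
                ] < INF:
                    j -= 1
                    continue
                done = False
                for k in range(i + 1, j):
                    if WM[i, k - 1] < INF and WM[k, j] < INF:
                        if abs(WM[i, k - 1] + WM[k, j] - WM[i, j]) <= _TOL:
                            work.append(("M", i, k - 1))
                            work.append(("M", k, j))
                            done = True
                            break
                if done:
                    break
                raise AssertionError(  # pragma: no cover - defensive
                    f"WM traceback failed at ({i},{j})"
                )
    return pairs


def pairs_to_dotbracket(pairs, n: int) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def pair_table(structure: str) -> np.ndarray:
    """partner index per position, -1 if unpaired."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    for i, j in pairs_from_dotbracket(structure):
        pt[i] = j
        pt[j] = i
    return pt


def structure_energy(seq: str, structure: str) -> float:
    """Energy of a given structure under the package's nearest-neighbor model.

    This is the model definition the DP optimizes; it is usable on any
    pseudoknot-free structure (e.g. for exhaustive-enumeration checks).
    """
    s = encode(seq)
    pairs = pairs_from_dotbracket(structure)
    if len(structure) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    partner = {i: j for i, j in pairs}
    partner.update({j: i for i, j in pairs})
    for i, j in pairs:
        if PAIR_TYPE[s[i], s[j]] < 0:
            raise ValueError(f"non-canonical pair {seq[i]}:{seq[j]} at ({i},{j})")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError(f"loop closed by ({i},{j}) shorter than {MIN_HAIRPIN}")
    energy = 0.0
    for i, j in pairs:
        children = []
        k = i + 1
        while k < j:
            if partner.get(k, -1) > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            energy += _HP_CACHE[j - i - 1]
        elif len(children) == 1:
            (k, l) = children[0]
            d1, d2 = k - i - 1, j - l - 1
            if d1 == 0 and d2 == 0:
                energy += STACK[PAIR_TYPE[s[i], s[j]], PAIR_TYPE[s[k], s[l]]]
            else:
                energy += _IL_CACHE[d1 + d2]
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            energy += (
                ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
            )
    return energy


def fold_mfe(seq: str) -> tuple[str, float]:
    """Fold a sequence, returning (dot-bracket structure, MFE in kcal/mol).

    Deterministic; the open chain scores 0 so the returned MFE is <= 0.
    Raises ValueError for sequences shorter than MIN_FOLD_LEN or containing N.
    """
    if len(seq) < MIN_FOLD_LEN:
        raise ValueError(f"sequence too short to fold (< {MIN_FOLD_LEN} nt)")
    s = encode(seq)
    n = len(s)
    V, WM = _fill(
        s,
        PAIR_TYPE,
        STACK,
        _HP_CACHE[: n + 1].copy(),
        _IL_CACHE[: n + 1].copy(),
        ML_CLOSE,
        ML_BRANCH,
        ML_UNPAIRED,
        MAX_INTERIOR,
    )
    W = _exterior(V)
    mfe = float(W[n - 1])
    if mfe >= -_TOL:
        return "." * n, 0.0
    pairs = _traceback(s, V, WM, W, _HP_CACHE[: n + 1], _IL_CACHE[: n + 1])
    return pairs_to_dotbracket(pairs, n), mfe
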