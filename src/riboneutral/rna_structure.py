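"""Target secondary structure, base-pair-replacement mutagenesis, and the
structure-based (SB) folding score.

The target structure of the reference ribozyme is a set of canonical base
pairs split into two crossing-free layers — the nested secondary structure
and one pseudoknot layer — plus a list of tertiary-contact positions (30 for
the 197-nt group I intron reference). The SB score measures how well a
sequence folds into that target: it is the summed negative log equilibrium
probability of every target pair under a thermodynamic folding model
(a McCaskill-style partition function with a simple pair + stacking energy
model). The pseudoknot layer is scored on its own crossing-free sub-problem,
with the nested target pairs forbidden, which keeps the whole computation in
the crossing-free regime while still rewarding pseudoknot formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import alphabet as ab
from .errors import FormatError, GenerationError, InputError
from .msa_kit import ReferenceSequence

__all__ = [
    "SecondaryStructure",
    "FoldingParams",
    "parse_structure",
    "bpr_mutate",
    "pair_probability_matrix",
    "sb_score",
]


@dataclass(frozen=True)
class SecondaryStructure:
    """Target base pairs (1-based, i<j) in two layers, plus tertiary positions.

    Invariants: no position belongs to more than one pair; within each layer
    no two pairs cross; every pseudoknot pair crosses at least one nested
    pair; tertiary positions lie in [1, length].
    """

    length: int
    nested: tuple[tuple[int, int], ...]
    pseudoknot: tuple[tuple[int, int], ...] = ()
    tertiary_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "nested", tuple(tuple(p) for p in self.nested))
        object.__setattr__(self, "pseudoknot", tuple(tuple(p) for p in self.pseudoknot))
        object.__setattr__(
            self, "tertiary_positions", frozenset(self.tertiary_positions)
        )
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise InputError(f"pair ({i},{j}) outside 1..{self.length}")
            if i in seen or j in seen:
                raise InputError(f"position reused by pair ({i},{j})")
            seen.update((i, j))
        for layer in (self.nested, self.pseudoknot):
            for a in range(len(layer)):
                for b in range(a + 1, len(layer)):
                    if _cross(layer[a], layer[b]):
                        raise InputError(
                            f"pairs {layer[a]} and {layer[b]} cross within one layer"
                        )
        for pk in self.pseudoknot:
            if not any(_cross(pk, nn) for nn in self.nested):
                raise InputError(
                    f"pseudoknot pair {pk} does not cross any nested pair"
                )
        for t in self.tertiary_positions:
            if not (1 <= t <= self.length):
                raise InputError(f"tertiary position {t} outside 1..{self.length}")

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return self.nested + self.pseudoknot

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.nested:
            chars[i - 1], chars[j - 1] = "(", ")"
        for i, j in self.pseudoknot:
            chars[i - 1], chars[j - 1] = "[", "]"
        return "".join(chars)


def _cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted((tuple(p), tuple(q)))
    return i < k < j < l


def parse_structure(
    text: str, tertiary_positions=(),
) -> SecondaryStructure:
    """Parse extended dot-bracket: ``()`` nested layer, ``[]`` pseudoknot layer,
    ``.`` unpaired."""
    text = text.strip()
    if not text:
        raise FormatError("empty structure string")
    nested, pseudo = [], []
    stacks = {"(": [], "[": []}
    closer = {")": "(", "]": "["}
    layer = {"(": nested, "[": pseudo}
    for pos, c in enumerate(text, start=1):
        if c in "([":
            stacks[c].append(pos)
        elif c in ")]":
            op = closer[c]
            if not stacks[op]:
                raise FormatError(f"unbalanced '{c}' at position {pos}")
            layer[op].append((stacks[op].pop(), pos))
        elif c != ".":
            raise FormatError(f"invalid structure character {c!r} at position {pos}")
    for op, st in stacks.items():
        if st:
            raise FormatError(f"unclosed '{op}' at position {st[-1]}")
    return SecondaryStructure(
        length=len(text),
        nested=tuple(sorted(nested)),
        pseudoknot=tuple(sorted(pseudo)),
        tertiary_positions=frozenset(tertiary_positions),
    )


@dataclass(frozen=True)
class FoldingParams:
    """Simple pair + stacking energy model (arbitrary units, kT-scaled).

    Only canonical pairs (GC/CG, GU/UG, AU/UA) have finite pairing energy;
    adjacent pairs (i,j),(i+1,j-1) earn an extra stacking bonus.
    """

    gc_energy: float = -3.0
    au_energy: float = -2.0
    gu_energy: float = -1.0
    stacking: float = -1.0
    min_hairpin: int = 3
    kT: float = 1.0

    def pair_weight_matrix(self, codes: np.ndarray) -> np.ndarray:
        """(L, L) Boltzmann weight of pairing positions i and j; 0 if the
        nucleotide combination is non-canonical or the loop is too short."""
        L = codes.size
        e = np.zeros((ab.Q_RNA, ab.Q_RNA))
        for (a, b), en in zip(
            ab.CANONICAL_PAIRS,
            (self.gc_energy, self.gc_energy, self.gu_energy,
             self.gu_energy, self.au_energy, self.au_energy),
        ):
            e[a, b] = en
        w = np.zeros((L, L))
        for i in range(L):
            for j in range(i + self.min_hairpin + 1, L):
                en = e[codes[i], codes[j]]
                if en != 0.0:
                    w[i, j] = np.exp(-en / self.kT)
        return w


@njit(cache=True)
def _pf_inside(w, sigma, min_hairpin):
    L = w.shape[0]
    # Z[i, j+1] = partition function of interval i..j (Z[i, i] = empty = 1)
    Z = np.ones((L + 1, L + 1))
    Zb = np.zeros((L, L))
    for span in range(1, L + 1):
        for i in range(0, L - span + 1):
            j = i + span - 1
            if w[i, j] > 0.0 and j - i - 1 >= min_hairpin:
                inner = Z[i + 1, j]
                innerb = Zb[i + 1, j - 1] if (j - 1) - (i + 1) >= 1 else 0.0
                Zb[i, j] = w[i, j] * (inner + (sigma - 1.0) * innerb)
            tot = Z[i, j]  # j unpaired
            for k in range(i, j):
                if Zb[k, j] > 0.0:
                    tot += Z[i, k] * Zb[k, j]
            Z[i, j + 1] = tot
    return Z, Zb


@njit(cache=True)
def _pf_outside(w, sigma, Z, Zb):
    L = w.shape[0]
    Out = np.zeros((L, L))
    for span in range(L, 1, -1):
        for i in range(0, L - span + 1):
            j = i + span - 1
            if Zb[i, j] == 0.0:
                continue
            val = Z[0, i] * Z[j + 1, L]
            for k in range(0, i):
                for l in range(j + 1, L):
                    if Zb[k, l] > 0.0 and Out[k, l] > 0.0:
                        stack = sigma if (k == i - 1 and l == j + 1) else 1.0
                        val += (
                            w[k, l]
                            * stack
                            * Out[k, l]
                            * Z[k + 1, i]
                            * Z[j + 1, l]
                        )
            Out[i, j] = val
    return Out


def pair_probability_matrix(
    seq: str | np.ndarray,
    params: FoldingParams = FoldingParams(),
    layer: str = "nested",
    struct: SecondaryStructure | None = None,
) -> np.ndarray:
    """Equilibrium base-pair probabilities over all crossing-free structures.

    For ``layer="pseudoknot"`` the nested-layer target pairs of ``struct``
    are forbidden, so the pseudoknot pairs are scored on their own
    crossing-free sub-problem. Entries are in [0, 1]; each row sums to at
    most 1 (a position pairs with at most one partner).
    """
    codes = ab.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    L = codes.size
    if L < 2 * params.min_hairpin:
        raise InputError(f"sequence of length {L} too short to fold")
    w = params.pair_weight_matrix(codes)
    if layer == "pseudoknot":
        if struct is None:
            raise InputError("pseudoknot layer requires the target structure")
        for i, j in struct.nested:
            w[i - 1, j - 1] = 0.0
    elif layer != "nested":
        raise InputError(f"unknown layer {layer!r}")
    sigma = float(np.exp(-params.stacking / params.kT))
    Z, Zb = _pf_inside(w, sigma, params.min_hairpin)
    Out = _pf_outside(w, sigma, Z, Zb)
    p = Zb * Out / Z[0, L]
    return p + p.T


DEFAULT_PROB_FLOOR = 1e-6


def sb_score(
    seq: str | np.ndarray,
    struct: SecondaryStructure,
    params: FoldingParams = FoldingParams(),
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Structure-based score: lower means better folding into the target.

    ``SB(x) = -sum ln p_ij`` over nested target pairs (nested-layer
    probabilities) plus ``-sum ln p'_ij`` over pseudoknot target pairs
    (probabilities with the nested layer masked). Probabilities are floored
    at ``prob_floor`` so that non-canonical or unformable target pairs give a
    large but finite penalty.
    """
    codes = ab.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if codes.size != struct.length:
        raise InputError("sequence/structure length mismatch")
    score = 0.0
    p = pair_probability_matrix(codes, params, layer="nested")
    for i, j in struct.nested:
        score -= np.log(max(p[i - 1, j - 1], prob_floor))
    if struct.pseudoknot:
        pk = pair_probability_matrix(codes, params, layer="pseudoknot", struct=struct)
        for i, j in struct.pseudoknot:
            score -= np.log(max(pk[i - 1, j - 1], prob_floor))
    return float(score)


def bpr_mutate(
    ref: ReferenceSequence,
    struct: SecondaryStructure,
    n_mut: int,
    keep_tertiary: bool = False,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 50,
) -> str:
    """Base-pair-replacement mutagenesis at exact Hamming distance ``n_mut``.

    Mutable units are the target pairs (rewritten jointly into one of the six
    canonical ordered pairs, different from the current one) and the unpaired
    positions (rewritten to one of the three other nucleotides). With
    ``keep_tertiary`` every unit touching a tertiary-contact position is
    frozen. Units are hit in random order until the realized Hamming distance
    to the reference is exactly ``n_mut``; a pair rewrite moves the distance
    by up to 2, so the walk retries from scratch if it overshoots too long.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    refc = ref.codes
    L = len(ref)
    if struct.length != L:
        raise InputError("structure length does not match reference")
    tertiary = struct.tertiary_positions if keep_tertiary else frozenset()
    pair_units = [
        (i - 1, j - 1)
        for i, j in struct.pairs
        if i not in tertiary and j not in tertiary
    ]
    paired_pos = {p for ij in struct.pairs for p in ij}
    free_units = [
        p - 1 for p in range(1, L + 1) if p not in paired_pos and p not in tertiary
    ]
    n_mutable = 2 * len(pair_units) + len(free_units)
    if n_mut > n_mutable:
        raise InputError(f"n_mut={n_mut} exceeds {n_mutable} mutable positions")
    if n_mut == 0:
        return ref.residues
    units = [("p", u) for u in pair_units] + [("f", u) for u in free_units]
    canon = ab.CANONICAL_PAIRS
    for _ in range(max_restarts):
        x = refc.copy()
        d = 0
        for _ in range(200 * n_mut + 500):
            kind, u = units[rng.integers(len(units))]
            if kind == "p":
                i, j = u
                cur = (x[i], x[j])
                choices = [c for c in canon if c != cur]
                a, b = choices[rng.integers(len(choices))]
                d += (int(a != refc[i]) - int(x[i] != refc[i])) + (
                    int(b != refc[j]) - int(x[j] != refc[j])
                )
                x[i], x[j] = a, b
            else:
                cur = x[u]
                a = (cur + 1 + rng.integers(3)) % ab.Q_RNA
                d += int(a != refc[u]) - int(cur != refc[u])
                x[u] = a
            if d == n_mut:
                return ab.decode(x)
    raise GenerationError(
        f"could not reach Hamming distance {n_mut} after {max_restarts} restarts"
    )
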