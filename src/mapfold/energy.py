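"""A compact nearest-neighbor free-energy model for RNA secondary structure.

This is a deliberately small "turner-lite" parameterization: stacking free
energies for all Watson-Crick and wobble pair steps, logarithmic length
penalties for hairpin, bulge and internal loops, and an affine multiloop
cost.  There are no dangling ends, coaxial stacks, terminal AU penalties or
special tetraloop bonuses, so absolute energies are not comparable with
full Turner-2004 implementations; the model is self-consistent, which is
what the exhaustive-enumeration checks and synthetic-structure recovery
rely on.  The parameter set is pluggable: any object exposing the same
attributes can be passed to the folding routines.

Energy of a structure = sum over helical stacks of the stack free energy
(+ per-nucleotide SHAPE pseudo-energies, each nucleotide contributing once
per stack it participates in, i.e. twice for helix-interior positions) +
sum over loops of the loop penalty.  Exterior (unpaired, external) bases
are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT = 1.98720425864083e-3  # kcal / (mol K)

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair-type codes: 0 = not pairable, then CG, GC, GU, UG, AU, UA
PAIR_TYPES = {
    ("C", "G"): 1,
    ("G", "C"): 2,
    ("G", "U"): 3,
    ("U", "G"): 4,
    ("A", "U"): 5,
    ("U", "A"): 6,
}
N_PAIR_TYPES = 7
_FLIP = {0: 0, 1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5}  # (i,j) -> (j,i) pair type

# stack free energies (kcal/mol) for a pair step: row = outer pair (i, j),
# column = inner pair (i+1, j-1).  Values follow the shape of the published
# Watson-Crick/wobble stacking hierarchy (GC-rich steps most stable, wobble
# steps weakest), symmetrized so that E[p][q] == E[flip(q)][flip(p)].
_STACK_RAW = {
    ("CG", "CG"): -3.26, ("CG", "GC"): -2.36, ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11, ("CG", "AU"): -2.11, ("CG", "UA"): -2.08,
    ("GC", "CG"): -3.42, ("GC", "GC"): -3.26, ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51, ("GC", "AU"): -2.35, ("GC", "UA"): -2.24,
    ("GU", "CG"): -2.51, ("GU", "GC"): -2.11, ("GU", "GU"): -0.50,
    ("GU", "UG"): 0.47,  ("GU", "AU"): -1.27, ("GU", "UA"): -1.36,
    ("UG", "CG"): -1.53, ("UG", "GC"): -1.41, ("UG", "GU"): 0.30,
    ("UG", "UG"): -0.50, ("UG", "AU"): -1.00, ("UG", "UA"): -0.55,
    ("AU", "CG"): -2.24, ("AU", "GC"): -2.08, ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36, ("AU", "AU"): -0.93, ("AU", "UA"): -1.10,
    ("UA", "CG"): -2.35, ("UA", "GC"): -2.11, ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27, ("UA", "AU"): -1.33, ("UA", "UA"): -0.93,
}


def _build_stack_table() -> np.ndarray:
    name_to_code = {"CG": 1, "GC": 2, "GU": 3, "UG": 4, "AU": 5, "UA": 6}
    E = np.full((N_PAIR_TYPES, N_PAIR_TYPES), np.inf)
    for (outer, inner), g in _STACK_RAW.items():
        E[name_to_code[outer], name_to_code[inner]] = g
    # enforce the physical reversal symmetry exactly
    S = E.copy()
    for p in range(1, 7):
        for q in range(1, 7):
            mirror = E[_FLIP[q], _FLIP[p]]
            S[p, q] = 0.5 * (E[p, q] + mirror)
    return S


@dataclass
class EnergyModel:
    """Parameter set consumed by the folding recursions.

    All energies in kcal/mol at the reference temperature of 37 C; the
    partition function uses RT at the configured temperature but the free
    energies themselves carry no enthalpy decomposition.
    """

    stack: np.ndarray = field(default_factory=_build_stack_table)
    hairpin_base: float = 5.4       # closing a minimal (3-nt) hairpin loop
    bulge_base: float = 3.8
    internal_base: float = 4.0
    loop_log_coeff: float = 1.08    # ~1.75*RT(37C): Jacobson-Stockmayer slope
    internal_asym: float = 0.5      # per nt of loop asymmetry
    internal_asym_max: float = 3.0
    ml_close: float = 3.4           # multiloop closing penalty (a)
    ml_branch: float = 0.4          # per branch, closing pair included (b)
    duplex_init: float = 4.1        # intermolecular duplex initiation

    def hairpin(self, loop_len: int) -> float:
        return self.hairpin_base + self.loop_log_coeff * np.log(loop_len / 3.0)

    def bulge(self, loop_len: int) -> float:
        return self.bulge_base + self.loop_log_coeff * np.log(float(loop_len))

    def internal(self, u1: int, u2: int) -> float:
        total = u1 + u2
        asym = min(self.internal_asym_max, self.internal_asym * abs(u1 - u2))
        return self.internal_base + self.loop_log_coeff * np.log(total / 2.0) + asym

    def loop_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized hairpin/bulge/internal penalties for loop sizes 0..n."""
        sizes = np.arange(n + 2, dtype=float)
        with np.errstate(divide="ignore"):
            hp = self.hairpin_base + self.loop_log_coeff * np.log(sizes / 3.0)
            bu = self.bulge_base + self.loop_log_coeff * np.log(sizes)
            it = self.internal_base + self.loop_log_coeff * np.log(sizes / 2.0)
        hp[:3] = np.inf  # hairpin loops shorter than 3 are forbidden
        bu[0] = it[:2] = np.inf
        return hp, bu, it


DEFAULT_MODEL = EnergyModel()


def encode_sequence(sequence: str) -> np.ndarray:
    """RNA string -> int codes (A=0, C=1, G=2, U=3); T tolerated as U."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return np.array([BASE_INDEX[b] for b in seq], dtype=np.int8)


def pair_type_matrix(codes: np.ndarray) -> np.ndarray:
    """n x n matrix of pair-type codes (0 where the bases cannot pair)."""
    lut = np.zeros((4, 4), dtype=np.int8)
    for (a, b), t in PAIR_TYPES.items():
        lut[BASE_INDEX[a], BASE_INDEX[b]] = t
    return lut[codes[:, None], codes[None, :]]


def pair_code(a: str, b: str) -> int:
    return PAIR_TYPES.get((a.upper().replace("T", "U"), b.upper().replace("T", "U")), 0)


def is_gc(a: str, b: str) -> bool:
    return {a.upper(), b.upper()} == {"G", "C"}
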