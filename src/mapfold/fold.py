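"""SHAPE-directed thermodynamic folding.

Minimum-free-energy structure prediction, McCaskill partition-function
base-pairing probabilities with per-nucleotide Shannon entropy, windowed
consensus folding for molecules longer than one folding window, and
intermolecular duplex energetics — all over the compact nearest-neighbor
model in :mod:`mapfold.energy`.

SHAPE reactivities enter as Deigan-style pseudo-energies
``dG(i) = m * ln(S_i + 1) + b`` added once per nucleotide per helical stack
it participates in (slope m = 1.8, intercept b = -0.6 kcal/mol by default).
A maximum pairing distance (600 nt by default) forces local pairings, as is
standard for long-RNA probing analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .energy import (
    DEFAULT_MODEL,
    GAS_CONSTANT,
    EnergyModel,
    encode_sequence,
    is_gc,
    pair_code,
    pair_type_matrix,
)
from .reactivity import ReactivityProfile

__all__ = [
    "FoldConfig",
    "SecondaryStructure",
    "PairProbabilityMatrix",
    "shape_pseudo_energy",
    "fold_mfe",
    "pair_probabilities",
    "windowed_fold",
    "structure_energy_report",
    "energy_of_structure",
    "duplex_energy",
]


@dataclass
class FoldConfig:
    """Folding parameters.

    slope / intercept
        Deigan pseudo-energy parameters in kcal/mol.
    max_pair_distance
        Maximum allowed i-j separation; forces local structure.
    min_hairpin_loop
        Minimal unpaired nucleotides closing a hairpin.
    temperature
        Kelvin; enters only the Boltzmann weights of the partition
        function (the free-energy table is a fixed 37 C parameterization).
    window / step / edge_trim
        Windowed-folding geometry for molecules longer than ``window``:
        overlapping windows every ``step`` nt, with ``edge_trim`` nt
        discarded from every non-terminal window edge before averaging.
    max_interior_loop
        Cap on unpaired nucleotides in one interior loop (model constraint).
    entropy_log_base
        Base of the Shannon-entropy logarithm (10 by convention).
    """

    slope: float = 1.8
    intercept: float = -0.6
    max_pair_distance: int = 600
    min_hairpin_loop: int = 3
    temperature: float = 310.15
    window: int = 1200
    step: int = 100
    edge_trim: int = 300
    max_interior_loop: int = 30
    entropy_log_base: float = 10.0
    model: EnergyModel = field(default_factory=lambda: DEFAULT_MODEL)

    def __post_init__(self) -> None:
        if self.max_pair_distance < self.min_hairpin_loop + 1:
            raise ValueError("max_pair_distance must exceed min_hairpin_loop")
        if self.window <= 2 * self.edge_trim:
            raise ValueError("window must exceed twice the edge trim")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature


@dataclass
class SecondaryStructure:
    """Pseudoknot-free pair table over a sequence, with free energy.

    ``pair_table[k]`` is the 1-based partner of position k+1 (0 = unpaired).
    """

    sequence: str
    pair_table: np.ndarray
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.pair_table = np.asarray(self.pair_table, dtype=np.int64)
        if len(self.pair_table) != len(self.sequence):
            raise ValueError("pair table and sequence length differ")
        for i1, j in enumerate(self.pair_table, start=1):
            if j and self.pair_table[j - 1] != i1:
                raise ValueError(f"pair table asymmetric at ({i1}, {j})")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """1-based (i, j) with i < j."""
        return [(i + 1, int(j)) for i, j in enumerate(self.pair_table) if j > i + 1]

    def n_paired(self) -> int:
        return int(np.sum(self.pair_table > 0))

    def dotbracket(self) -> str:
        out = []
        for i1, j in enumerate(self.pair_table, start=1):
            out.append("." if j == 0 else ("(" if j > i1 else ")"))
        return "".join(out)


@dataclass
class PairProbabilityMatrix:
    """Symmetric base-pair probabilities with derived per-position tracks."""

    p: np.ndarray
    sequence: str | None = None
    log_base: float = 10.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("probability matrix must be square")

    def __len__(self) -> int:
        return self.p.shape[0]

    @property
    def unpaired_prob(self) -> np.ndarray:
        """q_i = 1 - sum_j p_ij (clipped into [0, 1])."""
        return np.clip(1.0 - self.p.sum(axis=1), 0.0, 1.0)

    @property
    def entropy(self) -> np.ndarray:
        """Shannon entropy of each position's pairing distribution.

        H_i = -sum_j p_ij log(p_ij) - q_i log(q_i), with 0 log 0 = 0 and the
        configured log base.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(self.p > 0, np.log(self.p), 0.0)
            h = -(self.p * lp).sum(axis=1)
            q = self.unpaired_prob
            h -= np.where(q > 0, q * np.log(q), 0.0)
        return h / np.log(self.log_base)

    def pairs_above(self, threshold: float) -> list[tuple[int, int, float]]:
        """1-based pairs with p strictly above ``threshold``."""
        iu, ju = np.nonzero(np.triu(self.p, k=1) > threshold)
        return [(int(i) + 1, int(j) + 1, float(self.p[i, j])) for i, j in zip(iu, ju)]


def shape_pseudo_energy(
    profile: ReactivityProfile | np.ndarray | None,
    cfg: FoldConfig,
    n: int | None = None,
) -> np.ndarray:
    """Deigan pseudo-energy per nucleotide: m*ln(S+1) + b; masked -> 0."""
    if profile is None:
        if n is None:
            raise ValueError("need a length when no profile is given")
        return np.zeros(n)
    if isinstance(profile, ReactivityProfile):
        S = profile.values.copy()
        mask = profile.mask.copy()
    else:
        S = np.asarray(profile, dtype=float).copy()
        mask = ~np.isfinite(S) | (S <= -999.0)
    low = S < -1.0
    if np.any(low & ~mask):
        warnings.warn(
            f"{int((low & ~mask).sum())} reactivities below -1 clamped", stacklevel=2
        )
        S[low] = -1.0 + 1e-6
    ps = cfg.slope * np.log1p(S) + cfg.intercept
    ps[mask] = 0.0
    return ps


def _tables(cfg: FoldConfig, n: int):
    m = cfg.model
    hp, bu, it = m.loop_tables(n)
    return m.stack, hp, bu, it


def _run_mfe(codes: np.ndarray, ps: np.ndarray, cfg: FoldConfig):
    ptype = pair_type_matrix(codes)
    ES, hp, bu, it = _tables(cfg, len(codes))
    m = cfg.model
    V, WM, W = _kernels.mfe_fill(
        ptype, ES, hp, bu, it, m.internal_asym, m.internal_asym_max,
        m.ml_close, m.ml_branch, ps,
        cfg.min_hairpin_loop, cfg.max_pair_distance, cfg.max_interior_loop,
    )
    return ptype, V, WM, W


_TOL = 1e-4


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _TOL * max(1.0, abs(a), abs(b))


def _traceback(codes, ptype, V, WM, W, ps, cfg: FoldConfig) -> np.ndarray:
    """Deterministic traceback: 5'-most pairs first, stacks preferred."""
    n = len(codes)
    m = cfg.model
    ES, hp, bu, it = _tables(cfg, n)
    minloop, maxd, maxint = (
        cfg.min_hairpin_loop, cfg.max_pair_distance, cfg.max_interior_loop
    )
    pt = np.zeros(n, dtype=np.int64)
    stack: list[tuple[str, int, int]] = []

    j = n - 1
    while j >= 0:
        if _close(W[j + 1], W[j]):
            j -= 1
            continue
        found = False
        for u in range(max(0, j - maxd), j + 1):
            if V[u, j] < _kernels.INF and _close(W[u] + V[u, j], W[j + 1]):
                stack.append(("V", u, j))
                j = u - 1
                found = True
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("exterior traceback failed")

    while stack:
        kind, i, j = stack.pop()
        if kind == "V":
            pt[i], pt[j] = j + 1, i + 1
            target = V[i, j]
            if _close(target, hp[j - i - 1]):
                continue
            found = False
            kmax = min(i + maxint + 1, j - 1)
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                lmin = max(k + minloop + 1, j - 1 - (maxint - u1))
                for l in range(j - 1, lmin - 1, -1):
                    if ptype[k, l] == 0 or V[k, l] >= _kernels.INF:
                        continue
                    u2 = j - l - 1
                    if u1 == 0 and u2 == 0:
                        e = ES[ptype[i, j], ptype[k, l]] + ps[i] + ps[j] + ps[k] + ps[l]
                    else:
                        e = _kernels._interior_energy(
                            u1, u2, bu, it, m.internal_asym, m.internal_asym_max
                        )
                    if _close(target, e + V[k, l]):
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for u in range(i + 1, j - 1):
                if WM[i + 1, u] < _kernels.INF and WM[u + 1, j - 1] < _kernels.INF:
                    if _close(target, m.ml_close + m.ml_branch
                              + WM[i + 1, u] + WM[u + 1, j - 1]):
                        stack.append(("M", i + 1, u))
                        stack.append(("M", u + 1, j - 1))
                        found = True
                        break
            if not found:  # pragma: no cover - defensive
                raise RuntimeError(f"traceback failed at pair ({i}, {j})")
        else:  # multiloop segment
            while True:
                target = WM[i, j]
                if V[i, j] < _kernels.INF and _close(target, V[i, j] + m.ml_branch):
                    stack.append(("V", i, j))
                    break
                if i + 1 <= j and _close(target, WM[i + 1, j]):
                    i += 1
                    continue
                if i <= j - 1 and _close(target, WM[i, j - 1]):
                    j -= 1
                    continue
                found = False
                for u in range(i, j):
                    if WM[i, u] < _kernels.INF and WM[u + 1, j] < _kernels.INF:
                        if _close(target, WM[i, u] + WM[u + 1, j]):
                            stack.append(("M", i, u))
                            stack.append(("M", u + 1, j))
                            found = True
                            break
                if not found:  # pragma: no cover - defensive
                    raise RuntimeError(f"multiloop traceback failed on [{i}, {j}]")
                break
    return pt


def fold_mfe(
    sequence: str,
    profile: ReactivityProfile | None = None,
    cfg: FoldConfig | None = None,
) -> SecondaryStructure:
    """Minimum free energy pseudoknot-free structure, optionally SHAPE-directed.

    The reported energy includes the SHAPE pseudo-energy terms when a
    profile is supplied.
    """
    cfg = cfg or FoldConfig()
    codes = encode_sequence(sequence)
    if len(codes) < 5:
        raise ValueError("sequence must be at least 5 nt")
    ps = shape_pseudo_energy(profile, cfg, n=len(codes))
    if len(ps) != len(codes):
        raise ValueError("profile length does not match sequence")
    ptype, V, WM, W = _run_mfe(codes, ps, cfg)
    pt = _traceback(codes, ptype, V, WM, W, ps, cfg)
    return SecondaryStructure(sequence, pt, energy=float(W[len(codes)]))


def pair_probabilities(
    sequence: str,
    profile: ReactivityProfile | None = None,
    cfg: FoldConfig | None = None,
) -> PairProbabilityMatrix:
    """McCaskill partition-function base-pair probabilities.

    Uses the same energy model (and pseudo-energies) as :func:`fold_mfe`;
    the per-nucleotide rescaling keeps the computation finite for long
    windows.
    """
    cfg = cfg or FoldConfig()
    codes = encode_sequence(sequence)
    n = len(codes)
    ps = shape_pseudo_energy(profile, cfg, n=n)
    if len(ps) != n:
        raise ValueError("profile length does not match sequence")
    ptype, V, WM, W = _run_mfe(codes, ps, cfg)
    RT = cfg.RT
    # rescale around the MFE with a small safety margin
    kappa = float(np.exp(1.07 * min(W[n], 0.0) / (n * RT)))
    m = cfg.model
    ES, hp, bu, it = _tables(cfg, n)
    Zb, Zm, Zm1, zx, zy, kpow = _kernels.pf_inside(
        ptype, ES, hp, bu, it, m.internal_asym, m.internal_asym_max,
        m.ml_close, m.ml_branch, ps,
        cfg.min_hairpin_loop, cfg.max_pair_distance, cfg.max_interior_loop,
        RT, kappa,
    )
    P = _kernels.pf_outside(
        ptype, ES, bu, it, m.internal_asym, m.internal_asym_max,
        m.ml_close, m.ml_branch, ps,
        cfg.min_hairpin_loop, cfg.max_pair_distance, cfg.max_interior_loop,
        RT, Zb, Zm, Zm1, zx, zy, kpow,
    )
    if not np.all(np.isfinite(P)):  # pragma: no cover - defensive
        raise FloatingPointError("partition function overflow despite rescaling")
    return PairProbabilityMatrix(P, sequence=sequence, log_base=cfg.entropy_log_base)


def partition_function(
    sequence: str,
    profile: ReactivityProfile | None = None,
    cfg: FoldConfig | None = None,
) -> float:
    """ln Z over the configured model (unscaled)."""
    cfg = cfg or FoldConfig()
    codes = encode_sequence(sequence)
    n = len(codes)
    ps = shape_pseudo_energy(profile, cfg, n=n)
    ptype, V, WM, W = _run_mfe(codes, ps, cfg)
    RT = cfg.RT
    kappa = float(np.exp(1.07 * min(W[n], 0.0) / (n * RT)))
    m = cfg.model
    ES, hp, bu, it = _tables(cfg, n)
    _, _, _, zx, _, _ = _kernels.pf_inside(
        ptype, ES, hp, bu, it, m.internal_asym, m.internal_asym_max,
        m.ml_close, m.ml_branch, ps,
        cfg.min_hairpin_loop, cfg.max_pair_distance, cfg.max_interior_loop,
        RT, kappa,
    )
    return float(np.log(zx[n]) - n * np.log(kappa))


def _children(pt: np.ndarray, i: int, j: int) -> list[tuple[int, int]]:
    """Directly enclosed pairs of closing pair (i, j), 0-based."""
    out, k = [], i + 1
    while k < j:
        p = pt[k]
        if p > k + 1:
            out.append((k, int(p) - 1))
            k = int(p)
        else:
            k += 1
    return out


def energy_of_structure(
    structure: SecondaryStructure,
    cfg: FoldConfig | None = None,
    ps: np.ndarray | None = None,
) -> float:
    """Free energy of a given structure by loop decomposition.

    Mirrors the model the folding recursions optimize; with ``ps`` the
    SHAPE pseudo-energies are added per stack as in the fold.
    """
    cfg = cfg or FoldConfig()
    m = cfg.model
    seq = structure.sequence.upper().replace("T", "U")
    pt = structure.pair_table
    n = len(pt)
    if ps is None:
        ps = np.zeros(n)
    total = 0.0
    ext = _children(pt, -1, n)
    closed = list(ext)
    while closed:
        i, j = closed.pop()
        kids = _children(pt, i, j)
        closed.extend(kids)
        if not kids:
            total += m.hairpin(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                t_out = pair_code(seq[i], seq[j])
                t_in = pair_code(seq[k], seq[l])
                total += m.stack[t_out, t_in] + ps[i] + ps[j] + ps[k] + ps[l]
            elif u1 == 0 or u2 == 0:
                total += m.bulge(u1 + u2)
            else:
                total += m.internal(u1, u2)
        else:
            total += m.ml_close + m.ml_branch * (1 + len(kids))
    return float(total)


def structure_energy_report(
    structure: SecondaryStructure,
    cfg: FoldConfig | None = None,
) -> dict:
    """Energy and base-pair content of a structure (counting is model-free)."""
    seq = structure.sequence.upper().replace("T", "U")
    pairs = structure.pairs
    gc = sum(1 for i, j in pairs if is_gc(seq[i - 1], seq[j - 1]))
    energy = energy_of_structure(structure, cfg) if pairs else 0.0
    return {"energy": energy, "total_bp": len(pairs), "gc_bp": gc}


def windowed_fold(
    sequence: str,
    profile: ReactivityProfile | None = None,
    cfg: FoldConfig | None = None,
) -> tuple[PairProbabilityMatrix, SecondaryStructure]:
    """Consensus fold of a long molecule from overlapping windows.

    Each window is folded independently (MFE + pair probabilities);
    ``edge_trim`` nucleotides are discarded from every non-terminal window
    edge; probabilities are averaged over the windows retaining both
    partners, and the consensus structure keeps MFE pairs present in more
    than half of the windows covering them (crossing conflicts resolved by
    vote, then averaged probability, then 5' position).  For sequences no
    longer than one window this reduces exactly to the direct fold.
    """
    cfg = cfg or FoldConfig()
    n = len(sequence)
    if n <= cfg.window:
        return (
            pair_probabilities(sequence, profile, cfg),
            fold_mfe(sequence, profile, cfg),
        )
    starts = list(range(0, n - cfg.window + 1, cfg.step))
    if starts[-1] != n - cfg.window:
        starts.append(n - cfg.window)
    psum = np.zeros((n, n))
    pcount = np.zeros((n, n))
    votes: dict[tuple[int, int], int] = {}
    cover: dict[tuple[int, int], int] = {}
    for s in starts:
        e = s + cfg.window
        sub_seq = sequence[s:e]
        sub_prof = None
        if profile is not None:
            sub_prof = ReactivityProfile(
                profile.values[s:e], profile.stderr[s:e], profile.mask[s:e]
            )
        lo = s + (cfg.edge_trim if s > 0 else 0)
        hi = e - (cfg.edge_trim if e < n else 0)
        ppm = pair_probabilities(sub_seq, sub_prof, cfg)
        mfe = fold_mfe(sub_seq, sub_prof, cfg)
        sl = slice(lo - s, hi - s)
        psum[lo:hi, lo:hi] += ppm.p[sl, sl]
        pcount[lo:hi, lo:hi] += 1
        retained = range(lo - s + 1, hi - s + 1)  # 1-based window coords
        rset = set(retained)
        for (wi, wj) in mfe.pairs:
            if wi in rset and wj in rset:
                votes[(wi + s, wj + s)] = votes.get((wi + s, wj + s), 0) + 1
        cover_key = (lo + 1, hi)
        cover[cover_key] = cover.get(cover_key, 0) + 1
    with np.errstate(invalid="ignore"):
        pavg = np.where(pcount > 0, psum / np.maximum(pcount, 1), 0.0)
    ppm_out = PairProbabilityMatrix(pavg, sequence=sequence,
                                    log_base=cfg.entropy_log_base)

    def n_covering(i: int, j: int) -> int:
        c = 0
        for (lo1, hi1), cnt in cover.items():
            if lo1 <= i and j <= hi1:
                c += cnt
        return c

    kept: list[tuple[int, int]] = []
    order = sorted(
        votes.items(),
        key=lambda kv: (-kv[1], -pavg[kv[0][0] - 1, kv[0][1] - 1], kv[0][0]),
    )
    pt = np.zeros(n, dtype=np.int64)
    for (i, j), v in order:
        if v * 2 <= n_covering(i, j):
            continue
        if pt[i - 1] or pt[j - 1]:
            continue
        crossing = any((a < i < b < j) or (i < a < j < b) for a, b in kept)
        if crossing:
            continue
        kept.append((i, j))
        pt[i - 1], pt[j - 1] = j, i
    ps = shape_pseudo_energy(profile, cfg, n=n)
    struct = SecondaryStructure(sequence, pt)
    struct.energy = energy_of_structure(struct, cfg, ps=ps)
    return ppm_out, struct


def duplex_energy(
    seq_a: str,
    seq_b: str,
    cfg: FoldConfig | None = None,
    max_bulge: int = 5,
) -> dict:
    """Optimal gapless-or-bulged intermolecular duplex by dynamic programming.

    Antiparallel hybrid of ``seq_a`` (5'->3') with ``seq_b``; consecutive
    duplex pairs are scored with the stacking table, single-strand bulges up
    to ``max_bulge`` nt with the bulge penalty, plus one duplex-initiation
    term.  Returns the energy and the pair composition of the optimal
    duplex, or (0, 0, 0) when no favorable duplex exists.
    """
    cfg = cfg or FoldConfig()
    m = cfg.model
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    A = seq_a.upper().replace("T", "U")
    B = seq_b.upper().replace("T", "U")
    na, nb = len(A), len(B)
    INF = _kernels.INF
    D = np.full((na, nb), INF)
    back: dict[tuple[int, int], tuple[int, int]] = {}
    for x in range(na):
        for y in range(nb):
            t = pair_code(A[x], B[y])
            if t == 0:
                continue
            best, arg = m.duplex_init, None
            for gx in range(0, max_bulge + 1):
                for gy in range(0, max_bulge + 1):
                    if gx > 0 and gy > 0:
                        continue  # internal loops excluded: gapless or bulged
                    xp, yp = x - 1 - gx, y + 1 + gy
                    if xp < 0 or yp >= nb or D[xp, yp] >= INF:
                        continue
                    tp = pair_code(A[xp], B[yp])
                    if gx == 0 and gy == 0:
                        e = m.stack[tp, t]
                    else:
                        e = m.bulge(gx + gy)
                    if D[xp, yp] + e < best:
                        best, arg = D[xp, yp] + e, (xp, yp)
            D[x, y] = best
            if arg is not None:
                back[(x, y)] = arg
    if not np.any(D < INF):
        return {"energy": 0.0, "total_bp": 0, "gc_bp": 0}
    x, y = np.unravel_index(np.argmin(D), D.shape)
    if D[x, y] >= 0:
        return {"energy": 0.0, "total_bp": 0, "gc_bp": 0}
    energy = float(D[x, y])
    bp = gc = 0
    cur: tuple[int, int] | None = (int(x), int(y))
    while cur is not None:
        cx, cy = cur
        bp += 1
        if is_gc(A[cx], B[cy]):
            gc += 1
        cur = back.get(cur)
    return {"energy": energy, "total_bp": bp, "gc_bp": gc}
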