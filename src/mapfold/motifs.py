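"""Sequence-level cis-element scans.

Perfect reverse-complement palindromes (candidate dimerization sites —
two copies of such a sequence can duplex in trans), polypurine tracts
(plus-strand primers) and G-quadruplex candidates.  Coordinates are
1-based inclusive; only the given (plus) strand is scanned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotifHit",
    "reverse_complement",
    "find_palindromes",
    "find_purine_tracts",
    "find_gquad",
]

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (RNA; no G·U)."""
    return "".join(_WC[c] for c in reversed(seq))


@dataclass(frozen=True)
class MotifHit:
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    sequence: str
    kind: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates do not match sequence length")


def _norm(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid RNA letters: {sorted(bad)}")
    return seq


def find_palindromes(
    sequence: str, min_len: int = 6, max_len: int = 12
) -> list[MotifHit]:
    """Maximal even-length self-reverse-complementary substrings.

    A palindrome here means a substring equal to its own Watson-Crick
    reverse complement (no G·U), so that two molecules can pair the motif
    in trans — the retroviral dimerization-site geometry.  Each palindromic
    center is extended maximally; hits are clipped to ``max_len`` (centered)
    and overlapping hits are deduplicated keeping the longest (ties go to
    the leftmost).
    """
    if min_len % 2 != 0:
        raise ValueError("min_len must be even")
    seq = _norm(sequence)
    n = len(seq)
    raw: list[MotifHit] = []
    for center in range(1, n):  # boundary between center-1 and center (0-based)
        r = 0
        while (
            center - r - 1 >= 0
            and center + r < n
            and _WC[seq[center - r - 1]] == seq[center + r]
        ):
            r += 1
        length = 2 * r
        if length < min_len:
            continue
        if length > max_len:
            r = max_len // 2
            length = 2 * r
        s0 = center - r  # 0-based start
        raw.append(
            MotifHit(s0 + 1, s0 + length, seq[s0 : s0 + length], "palindrome",
                     float(length))
        )
    kept: list[MotifHit] = []
    for hit in sorted(raw, key=lambda h: (-len(h.sequence), h.start)):
        if any(hit.start <= k.end and k.start <= hit.end for k in kept):
            continue
        kept.append(hit)
    return sorted(kept, key=lambda h: h.start)


def find_purine_tracts(sequence: str, min_len: int = 10) -> list[MotifHit]:
    """Maximal runs of purines (A/G) of at least ``min_len`` nt."""
    seq = _norm(sequence)
    hits: list[MotifHit] = []
    start = None
    for k, c in enumerate(seq + "#"):  # sentinel terminates the final run
        if c in "AG":
            if start is None:
                start = k
        else:
            if start is not None and k - start >= min_len:
                hits.append(
                    MotifHit(start + 1, k, seq[start:k], "purine_tract",
                             float(k - start))
                )
            start = None
    return hits


def gquad_score(g: int, span: int, loops: tuple[int, int, int],
                max_span: int = 30) -> float:
    """Heuristic G-quadruplex score.

    Rewards more stacked tetrads and compactness, penalizes uneven loops:
    10*(g-2) + (max_span - span) - var(loop lengths).  This is this
    package's own documented scoring convention for ranking candidates
    matching the canonical G{g}N{l1}G{g}N{l2}G{g}N{l3}G{g} motif.
    """
    return 10.0 * (g - 2) + (max_span - span) - float(np.var(loops))


def find_gquad(
    sequence: str,
    min_tetrad: int = 2,
    max_span: int = 30,
    min_loop: int = 1,
) -> list[MotifHit]:
    """Candidate G-quadruplexes: four G-runs of length >= ``min_tetrad``.

    Enumerates all placements of four G-runs with loop lengths >=
    ``min_loop`` within a total span of ``max_span`` nt, scores them with
    :func:`gquad_score`, and resolves overlaps keeping the highest score
    (ties to the leftmost, then the shortest).
    """
    seq = _norm(sequence)
    n = len(seq)
    is_g = [c == "G" for c in seq]
    run_len = [0] * (n + 1)  # G-run length starting at each position
    for k in range(n - 1, -1, -1):
        run_len[k] = run_len[k + 1] + 1 if is_g[k] else 0
    raw: list[MotifHit] = []
    for g in range(min_tetrad, max_span // 4 + 1):
        for s0 in range(n):
            if run_len[s0] < g:
                continue
            # positions of the remaining three runs via loop lengths
            max_total_loops = max_span - 4 * g
            if max_total_loops < 3 * min_loop:
                continue
            for l1 in range(min_loop, max_total_loops - 2 * min_loop + 1):
                p2 = s0 + g + l1
                if p2 + g > n or run_len[p2] < g:
                    continue
                for l2 in range(min_loop, max_total_loops - l1 - min_loop + 1):
                    p3 = p2 + g + l2
                    if p3 + g > n or run_len[p3] < g:
                        continue
                    for l3 in range(min_loop, max_total_loops - l1 - l2 + 1):
                        p4 = p3 + g + l3
                        if p4 + g > n or run_len[p4] < g:
                            continue
                        span = 4 * g + l1 + l2 + l3
                        raw.append(
                            MotifHit(
                                s0 + 1,
                                s0 + span,
                                seq[s0 : s0 + span],
                                "gquad",
                                gquad_score(g, span, (l1, l2, l3), max_span),
                            )
                        )
    kept: list[MotifHit] = []
    for hit in sorted(raw, key=lambda h: (-h.score, h.start, h.end)):
        if any(hit.start <= k.end and k.start <= hit.end for k in kept):
            continue
        kept.append(hit)
    return sorted(kept, key=lambda h: h.start)
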