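"""Two-state structure comparison analytics.

Model-free and model-based comparison of probing datasets from two
experimental states (e.g. in-cell vs refolded): sliding-window summary
tracks, Gini inequality profiles, the delta-reactivity significance
framework, highly probable base pairs, low-SHAPE/low-entropy (lowSS)
regions, the state-independent well-folded core, base-pair-level
sensitivity/PPV scoring, local base-pair content and G-minus-A sequence
composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .fold import PairProbabilityMatrix, SecondaryStructure
from .reactivity import ReactivityProfile
from .regions import Region, RegionSet

__all__ = [
    "WindowConfig",
    "ComparisonScore",
    "sliding_stat",
    "gini",
    "gini_profile",
    "delta_shape",
    "hp_basepairs",
    "lowss_regions",
    "well_folded_core",
    "score_structures",
    "local_bp_content",
    "g_minus_a",
    "segment_composition",
]


@dataclass
class WindowConfig:
    """Sliding-window geometry.

    ``stat_window`` (odd, default 51) smooths reactivity/entropy/Gini
    tracks; ``comp_window`` (default 75) is used for composition and local
    base-pair content.  ``edge_policy`` controls positions whose centered
    window leaves the molecule: "shrink" clips the window, "nan" masks.
    """

    stat_window: int = 51
    comp_window: int = 75
    step: int = 1
    edge_policy: str = "shrink"
    min_data_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.stat_window % 2 != 1:
            raise ValueError("stat_window must be odd")
        if self.stat_window < 3 or self.comp_window < 3:
            raise ValueError("windows must be at least 3 nt")
        if self.edge_policy not in ("shrink", "nan"):
            raise ValueError("edge_policy must be 'shrink' or 'nan'")


def _as_values_mask(track) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, ReactivityProfile):
        return track.values, track.mask
    v = np.asarray(track, dtype=float)
    return v, ~np.isfinite(v)


def sliding_stat(
    track,
    cfg: WindowConfig | None = None,
    stat: str = "median",
    second=None,
    window: int | None = None,
) -> np.ndarray:
    """Centered sliding-window statistic over a (maskable) track.

    ``stat`` is "median", "mean" or "pearson" (the latter correlates with
    ``second`` inside each window).  Masked values are excluded; windows
    with less than half their positions carrying data give NaN.
    """
    cfg = cfg or WindowConfig()
    w = window or cfg.stat_window
    half = w // 2
    v, m = _as_values_mask(track)
    n = len(v)
    if second is not None:
        v2, m2 = _as_values_mask(second)
        if len(v2) != n:
            raise ValueError("tracks have different lengths")
        m = m | m2
    out = np.full(n, np.nan)
    for c in range(0, n, cfg.step):
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n:
            if cfg.edge_policy == "nan":
                continue
            lo, hi = max(0, lo), min(n, hi)
        sel = ~m[lo:hi]
        if sel.sum() < (hi - lo) * cfg.min_data_frac or sel.sum() == 0:
            continue
        vals = v[lo:hi][sel]
        if stat == "median":
            out[c] = np.median(vals)
        elif stat == "mean":
            out[c] = np.mean(vals)
        elif stat == "pearson":
            if sel.sum() < 3:
                continue
            out[c] = sstats.pearsonr(vals, v2[lo:hi][sel]).statistic
        else:
            raise ValueError(f"unknown stat {stat!r}")
    return out


def gini(x: np.ndarray) -> float:
    """Gini index of a non-negative sample via the sorted-rank identity.

    G = sum_ij |x_i - x_j| / (2 n^2 mean); NaN for n < 2 or zero mean.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    total = x.sum()
    if n < 2 or total == 0:
        return np.nan
    ranks = np.arange(1, n + 1)
    g = (2 * (ranks * x).sum() - (n + 1) * total) / (n * total)
    return float(max(g, 0.0))  # guard tiny negative rounding on near-constant x


def gini_profile(
    track, cfg: WindowConfig | None = None
) -> tuple[np.ndarray, float]:
    """Sliding-window Gini track plus the global Gini index.

    Reactivities are clipped below at 0 (the index is defined for
    non-negative values); windows with insufficient data or zero mean are
    NaN.
    """
    cfg = cfg or WindowConfig()
    v, m = _as_values_mask(track)
    v = np.where(m, np.nan, np.clip(v, 0.0, None))
    n = len(v)
    half = cfg.stat_window // 2
    out = np.full(n, np.nan)
    for c in range(n):
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n:
            if cfg.edge_policy == "nan":
                continue
            lo, hi = max(0, lo), min(n, hi)
        vals = v[lo:hi]
        vals = vals[np.isfinite(vals)]
        if len(vals) < (hi - lo) * cfg.min_data_frac or len(vals) < 2:
            continue
        out[c] = gini(vals)
    allv = v[np.isfinite(v)]
    return out, gini(allv) if len(allv) >= 2 else np.nan


def _smooth_with_errors(
    values: np.ndarray, stderr: np.ndarray, mask: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centered w-nt mean of values and propagated standard errors."""
    n = len(values)
    half = w // 2
    sv = np.full(n, np.nan)
    se = np.full(n, np.nan)
    for c in range(n):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        sel = ~mask[lo:hi]
        k = sel.sum()
        if k == 0:
            continue
        sv[c] = values[lo:hi][sel].mean()
        se[c] = np.sqrt(np.nansum(stderr[lo:hi][sel] ** 2)) / k
    return sv, se


def delta_shape(
    profile_a: ReactivityProfile,
    profile_b: ReactivityProfile,
    smooth_window: int = 3,
    z_coeff: float = 1.96,
    score_thresh: float = 1.0,
    min_hits: int = 3,
    hit_window: int = 5,
) -> tuple[RegionSet, dict]:
    """Significant per-nucleotide reactivity differences between two states.

    After 3-nt smoothing of values and propagated errors, a position is a
    primary hit when the Z-factor 1 - z_coeff*(se_A+se_B)/|delta| is
    positive (the difference exceeds its propagated uncertainty) and the
    standard score of delta is at least ``score_thresh`` in magnitude.  A
    site is *called* when it is a primary hit and at least ``min_hits`` of
    any ``hit_window``-nt stretch containing it are primary hits.  Returns
    the called regions (labelled by sign: which state is more reactive) and
    the per-position tracks.
    """
    if len(profile_a) != len(profile_b):
        raise ValueError("profiles have different lengths")
    n = len(profile_a)
    va, ea = _smooth_with_errors(
        profile_a.values, profile_a.stderr, profile_a.mask, smooth_window
    )
    vb, eb = _smooth_with_errors(
        profile_b.values, profile_b.stderr, profile_b.mask, smooth_window
    )
    delta = va - vb
    with np.errstate(invalid="ignore", divide="ignore"):
        zfactor = 1.0 - z_coeff * (ea + eb) / np.abs(delta)
    finite = np.isfinite(delta)
    if finite.sum() >= 2 and np.nanstd(delta) > 0:
        sscore = (delta - np.nanmean(delta)) / np.nanstd(delta)
    else:
        sscore = np.zeros(n)
    primary = finite & (zfactor > 0) & (np.abs(sscore) >= score_thresh)
    called = np.zeros(n, dtype=bool)
    half = hit_window // 2
    for c in np.nonzero(primary)[0]:
        for w0 in range(c - hit_window + 1, c + 1):
            w1 = w0 + hit_window
            if w0 < 0 or w1 > n:
                continue
            if primary[w0:w1].sum() >= min_hits:
                called[c] = True
                break
    regions = []
    for r in RegionSet.from_mask(called):
        sign = np.sign(np.nanmean(delta[r.start - 1 : r.end]))
        regions.append(
            Region(r.start, r.end, label="A>B" if sign >= 0 else "B>A")
        )
    tracks = {
        "delta": delta,
        "zfactor": zfactor,
        "sscore": sscore,
        "primary": primary,
        "called": called,
    }
    return RegionSet(regions, label="delta-shape"), tracks


def hp_basepairs(
    ppm: PairProbabilityMatrix, threshold: float = 0.8
) -> list[tuple[int, int, float]]:
    """Highly probable base pairs: probability strictly above ``threshold``.

    For threshold >= 0.5 at most one partner per position can qualify
    (two would sum above 1).
    """
    return ppm.pairs_above(threshold)


def lowss_regions(
    reactivity_track,
    entropy_track,
    cfg: WindowConfig | None = None,
    merge_gap: int = 10,
    min_len: int = 40,
) -> RegionSet:
    """Regions of both low SHAPE reactivity and low Shannon entropy.

    Both tracks are median-smoothed with ``stat_window``; a qualifying run
    has smoothed reactivity strictly below the global median reactivity AND
    smoothed entropy strictly below the global median entropy.  Runs
    separated by at most ``merge_gap`` nt are merged and regions shorter
    than ``min_len`` nt dropped.
    """
    cfg = cfg or WindowConfig()
    rv, rm = _as_values_mask(reactivity_track)
    ev, em = _as_values_mask(entropy_track)
    if len(rv) != len(ev):
        raise ValueError("tracks have different lengths")
    sr = sliding_stat(reactivity_track, cfg, "median")
    se = sliding_stat(entropy_track, cfg, "median")
    med_r = np.median(rv[~rm]) if (~rm).any() else np.nan
    med_e = np.median(ev[~em]) if (~em).any() else np.nan
    ok = (
        np.isfinite(sr) & np.isfinite(se) & (sr < med_r) & (se < med_e)
    )
    return (
        RegionSet.from_mask(ok, label="lowSS")
        .merge(merge_gap)
        .filter_min_length(min_len)
    )


def _pairs_inside(pairs, region: Region) -> set[tuple[int, int]]:
    return {
        (i, j)
        for (i, j) in pairs
        if region.start <= i <= region.end and region.start <= j <= region.end
    }


def well_folded_core(
    lowss_a: RegionSet,
    lowss_b: RegionSet,
    mfe_a: SecondaryStructure,
    mfe_b: SecondaryStructure,
    hp_a: list[tuple[int, int, float]],
    hp_b: list[tuple[int, int, float]],
) -> tuple[RegionSet, float]:
    """State-independent well-folded core from two states' lowSS regions.

    Candidates are the interval intersections of the two lowSS sets; a
    candidate joins the core iff (i) at least half of the MFE pairs with
    both endpoints inside it are shared between the states and (ii) it
    contains at least one highly probable pair present in both states.
    Returns the core and its coverage as a percentage of molecule length.
    """
    if len(mfe_a) != len(mfe_b):
        raise ValueError("states have different molecule lengths")
    n = len(mfe_a)
    hp_a_set = {(i, j) for i, j, _ in hp_a}
    hp_b_set = {(i, j) for i, j, _ in hp_b}
    core = []
    for cand in lowss_a.intersect(lowss_b):
        pa = _pairs_inside(mfe_a.pairs, cand)
        pb = _pairs_inside(mfe_b.pairs, cand)
        shared = pa & pb
        denom = max(len(pa), len(pb))
        if denom and len(shared) < 0.5 * denom:
            continue
        hp_shared = _pairs_inside(hp_a_set & hp_b_set, cand)
        if not hp_shared:
            continue
        core.append(Region(cand.start, cand.end, label="core"))
    core_set = RegionSet(core, label="well-folded core")
    return core_set, 100.0 * core_set.total_length() / n


@dataclass
class ComparisonScore:
    """Base-pair agreement between a reference and a predicted structure."""

    sensitivity: float  # % of reference pairs recovered
    ppv: float          # % of predicted pairs present in the reference
    matched: int

    def __iter__(self):
        return iter((self.sensitivity, self.ppv, self.matched))


def _helix_runs(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into stacked helices ((i,j) followed by (i+1, j-1))."""
    pset = set(pairs)
    runs, seen = [], set()
    for (i, j) in sorted(pairs):
        if (i, j) in seen:
            continue
        run = [(i, j)]
        seen.add((i, j))
        k, l = i + 1, j - 1
        while (k, l) in pset:
            run.append((k, l))
            seen.add((k, l))
            k, l = k + 1, l - 1
        runs.append(run)
    return runs


def score_structures(
    reference: SecondaryStructure,
    predicted: SecondaryStructure,
    slip: int = 0,
    helix_completion: bool = False,
) -> ComparisonScore:
    """Sensitivity and positive predictive value of a predicted structure.

    A predicted pair is a true positive when it matches a reference pair
    exactly (slip=0) or within +/-1 on either index (slip=1).  With
    ``helix_completion`` a predicted helix sharing at least one matched
    pair is first extended with the remaining pairs of the reference helix
    it matches (an explicit reconstruction of manual helix completion);
    both options are off by default.
    """
    if len(reference) != len(predicted):
        raise ValueError("structures have different lengths")
    ref = set(reference.pairs)
    pred = set(predicted.pairs)
    if helix_completion and pred:
        matched_exact = ref & pred
        for run in _helix_runs(sorted(ref)):
            if any(p in matched_exact for p in run):
                pred |= set(run)
    if slip == 0:
        tp = len(ref & pred)
    elif slip == 1:
        def hits(p, targets):
            i, j = p
            cands = {(i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)}
            return bool(cands & targets)
        tp = sum(1 for p in pred if hits(p, ref))
    else:
        raise ValueError("slip must be 0 or 1")
    sens = 100.0 * min(tp, len(ref)) / len(ref) if ref else 0.0
    ppv = 100.0 * tp / len(pred) if pred else 0.0
    return ComparisonScore(sens, ppv, tp)


def local_bp_content(
    pairs, length: int, cfg: WindowConfig | None = None
) -> np.ndarray:
    """% of nucleotides engaged in the given pairs, per centered window."""
    cfg = cfg or WindowConfig()
    paired = np.zeros(length, dtype=bool)
    for entry in pairs:
        i, j = entry[0], entry[1]
        paired[i - 1] = paired[j - 1] = True
    half = cfg.comp_window // 2
    out = np.empty(length)
    for c in range(length):
        lo, hi = max(0, c - half), min(length, c + half + 1)
        out[c] = 100.0 * paired[lo:hi].sum() / (hi - lo)
    return out


def g_minus_a(sequence: str, cfg: WindowConfig | None = None) -> np.ndarray:
    """count(G) - count(A) in a centered ``comp_window`` sliding window."""
    cfg = cfg or WindowConfig()
    seq = sequence.upper().replace("T", "U")
    isg = np.array([c == "G" for c in seq], dtype=int)
    isa = np.array([c == "A" for c in seq], dtype=int)
    n = len(seq)
    half = cfg.comp_window // 2
    out = np.empty(n, dtype=int)
    for c in range(n):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        out[c] = isg[lo:hi].sum() - isa[lo:hi].sum()
    return out


def segment_composition(sequence: str, regions: RegionSet) -> dict:
    """Per-region nucleotide composition fractions (A/C/G/U)."""
    seq = sequence.upper().replace("T", "U")
    out = {}
    for r in regions:
        sub = seq[r.start - 1 : r.end]
        total = len(sub)
        out[r.label or f"{r.start}-{r.end}"] = {
            b: sub.count(b) / total for b in "ACGU"
        }
    return out
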