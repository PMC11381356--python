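"""Two-channel mutation counts -> normalized SHAPE reactivity profiles.

Chemical probing with a SHAPE reagent (e.g. NAI) followed by mutational
profiling yields, for each nucleotide, the number of mutation events and the
effective read depth in a reagent-treated ("modified") and an untreated
channel.  Flexible, mostly unpaired nucleotides acquire adducts and show
elevated mutation rates; the untreated channel measures the reverse
transcription background.  This module turns such count tables into
normalized reactivity profiles: raw reactivity is the per-position mutation
rate difference, low-depth positions are masked, and profiles are scaled by
the model-free boxplot normalization so that the mean of the top decile of
retained reactivities equals 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

NO_DATA = -999.0  #: file-format sentinel for masked positions

__all__ = [
    "MutationCountTable",
    "ReactivityProfile",
    "raw_reactivity",
    "depth_filter",
    "normalize_boxplot",
    "replicate_stats",
    "rate_comparison_test",
    "NO_DATA",
]


@dataclass
class MutationCountTable:
    """Per-position mutation events and effective depths for one channel.

    Positions are 1-based and contiguous from 1; ``events[i] <= depth[i]``.
    """

    nt: np.ndarray          # unicode array of RNA letters
    events: np.ndarray      # integer counts
    depth: np.ndarray       # integer effective depths

    def __post_init__(self) -> None:
        self.nt = np.asarray(self.nt, dtype="U1")
        self.events = np.asarray(self.events, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if not (len(self.nt) == len(self.events) == len(self.depth)):
            raise ValueError("nt, events and depth must have equal length")
        if np.any(self.events > self.depth):
            raise ValueError("mutation events exceed depth")
        if np.any(self.events < 0) or np.any(self.depth < 0):
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return len(self.nt)

    @property
    def positions(self) -> np.ndarray:
        """1-based position index."""
        return np.arange(1, len(self) + 1)

    @property
    def rate(self) -> np.ndarray:
        """Per-position mutation rate; NaN where depth is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.events / self.depth
        return np.where(self.depth > 0, r, np.nan)

    @property
    def sequence(self) -> str:
        return "".join(self.nt)


@dataclass
class ReactivityProfile:
    """Per-nucleotide SHAPE reactivity with standard errors and no-data mask.

    ``mask[i] is True`` means position ``i`` carries no data; masked entries
    never enter normalization, averaging or correlation.  Values may be
    negative (untreated rate above modified rate).  ``meta`` records the
    normalization factor and the depth threshold that produced the profile.
    """

    values: np.ndarray
    stderr: np.ndarray | None = None
    mask: np.ndarray | None = None
    sequence: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.values)
        if self.stderr is None:
            self.stderr = np.zeros(n)
        self.stderr = np.asarray(self.stderr, dtype=float).copy()
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool).copy()
        if len(self.stderr) != n or len(self.mask) != n:
            raise ValueError("values, stderr and mask must have equal length")
        self.values[self.mask] = np.nan
        self.stderr[self.mask] = np.nan

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self) -> "ReactivityProfile":
        return ReactivityProfile(
            self.values.copy(),
            self.stderr.copy(),
            self.mask.copy(),
            self.sequence,
            dict(self.meta),
        )


def _check_aligned(mod: MutationCountTable, untr: MutationCountTable) -> None:
    if len(mod) != len(untr):
        raise ValueError("channel tables have different lengths")
    if not np.array_equal(mod.nt, untr.nt):
        raise ValueError("channel tables disagree on the nucleotide sequence")


def raw_reactivity(
    mod: MutationCountTable, untr: MutationCountTable
) -> ReactivityProfile:
    """Unnormalized reactivity: mutation-rate difference between channels.

    r_i = events_mod/depth_mod - events_untr/depth_untr, with a binomial
    error propagation for the standard error.  Positions with zero depth in
    either channel are masked, not an error.
    """
    _check_aligned(mod, untr)
    rm, ru = mod.rate, untr.rate
    values = rm - ru
    with np.errstate(invalid="ignore", divide="ignore"):
        var = rm * (1 - rm) / mod.depth + ru * (1 - ru) / untr.depth
    stderr = np.sqrt(var)
    mask = (mod.depth == 0) | (untr.depth == 0)
    return ReactivityProfile(
        np.where(mask, np.nan, values),
        np.where(mask, np.nan, stderr),
        mask,
        sequence=mod.sequence,
        meta={"normalized": False},
    )


def depth_filter(
    mod: MutationCountTable,
    untr: MutationCountTable,
    threshold: int = 5000,
) -> tuple[np.ndarray, float]:
    """Mask positions whose effective depth falls below ``threshold``.

    A position is masked iff depth < threshold (strict) in *either* channel;
    depth exactly at the threshold is retained.  Returns the boolean mask
    (True = masked) and the fraction of positions retained.
    """
    _check_aligned(mod, untr)
    mask = (mod.depth < threshold) | (untr.depth < threshold)
    retained = 1.0 - mask.mean() if len(mask) else 0.0
    return mask, float(retained)


def _boxplot_factor(values: np.ndarray, long_profile: bool) -> tuple[float, np.ndarray]:
    """Normalization factor under the model-free boxplot rule.

    Short profiles (<= 500 nt): outliers are values above Q3 + 1.5*IQR,
    capped at 10% of the data; the factor is the mean of the top 10% of the
    remaining values.  When the IQR collapses to zero (zero-inflated
    profiles), the quartiles fall back to the positive values.  Long
    profiles: the top 2% are treated as outliers and the factor is the mean
    of the 2-10% band.  Returns (factor, outlier flags aligned with
    ``values``).
    """
    n = len(values)
    order = np.argsort(values)[::-1]  # descending
    if long_profile:
        n_out = int(n * 0.02)
        n_band = max(int(n * 0.10) - n_out, 1)
    else:
        q1, q3 = np.percentile(values, [25, 75])
        if q3 - q1 == 0 and np.any(values > 0):
            q1, q3 = np.percentile(values[values > 0], [25, 75])
        cut = q3 + 1.5 * (q3 - q1)
        n_out = min(int(np.sum(values > cut)), n // 10)
        n_band = max(int((n - n_out) * 0.10), 1)
    outliers = np.zeros(n, dtype=bool)
    outliers[order[:n_out]] = True
    band = order[n_out : n_out + n_band]
    factor = float(np.mean(values[band]))
    return factor, outliers


def normalize_boxplot(profile: ReactivityProfile) -> ReactivityProfile:
    """Scale a profile so the mean of the top retained decile equals 1.

    The standard SHAPE boxplot normalization: flag high outliers, take the
    mean of the next top band as the normalization factor, and divide every
    value (and its standard error) by it.  Idempotent: a normalized profile
    renormalizes with factor 1.  Raises on a non-positive factor (degenerate
    profile).
    """
    vals = profile.unmasked()
    if len(vals) < 50:
        warnings.warn(
            f"only {len(vals)} unmasked positions; normalization may be unstable",
            stacklevel=2,
        )
    if len(vals) == 0:
        raise ValueError("cannot normalize an all-masked profile")
    factor, _ = _boxplot_factor(vals, long_profile=len(profile) > 500)
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"degenerate profile: normalization factor {factor!r}")
    out = profile.copy()
    out.values = profile.values / factor
    out.stderr = profile.stderr / factor
    out.meta = dict(profile.meta)
    out.meta.update({"normalized": True, "norm_factor": factor})
    return out


def replicate_stats(
    profiles: Sequence[ReactivityProfile],
) -> tuple[ReactivityProfile, np.ndarray]:
    """Average replicate profiles and report pairwise Pearson correlation.

    The average at a position uses the unmasked replicate values; the output
    is masked only where *all* replicates are masked.  The returned matrix
    holds pairwise Pearson r on jointly unmasked positions (r^2 = r*r).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("replicate profiles have different lengths")
    vals = np.vstack([p.values for p in profiles])
    errs = np.vstack([p.stderr for p in profiles])
    masks = np.vstack([p.mask for p in profiles])
    counts = (~masks).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(masks, np.nan, vals), axis=0)
        # standard error of the mean from propagated per-replicate errors
        se = np.sqrt(np.nansum(np.where(masks, np.nan, errs) ** 2, axis=0))
    se = np.where(counts > 0, se / np.maximum(counts, 1), np.nan)
    out_mask = counts == 0
    avg = ReactivityProfile(
        np.where(out_mask, np.nan, mean),
        np.where(out_mask, np.nan, se),
        out_mask,
        sequence=profiles[0].sequence,
        meta={"n_replicates": len(profiles)},
    )
    k = len(profiles)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            joint = ~(masks[i] | masks[j])
            if joint.sum() < 3:
                rij = np.nan
            else:
                rij = stats.pearsonr(vals[i][joint], vals[j][joint]).statistic
            r[i, j] = r[j, i] = rij
    return avg, r


def rate_comparison_test(
    mod: MutationCountTable, untr: MutationCountTable
) -> dict:
    """Wilcoxon rank-sum test of modified vs untreated per-position rates.

    Two-sided; uses the exact null distribution for small samples without
    ties (so the toy {1,2,3} vs {4,5,6} case gives p = 0.1) and the normal
    approximation otherwise.  Returns the statistic, p-value and channel
    medians.
    """
    _check_aligned(mod, untr)
    rm = mod.rate[np.isfinite(mod.rate)]
    ru = untr.rate[np.isfinite(untr.rate)]
    if len(rm) == 0 or len(ru) == 0:
        raise ValueError("no positions with data in one of the channels")
    res = stats.mannwhitneyu(rm, ru, alternative="two-sided", method="auto")
    return {
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "median_modified": float(np.median(rm)),
        "median_untreated": float(np.median(ru)),
    }
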