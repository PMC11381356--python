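"""Conformer-mixture analysis for dimerization studies.

A probed RNA population can be a mixture of conformers — typically monomer
and dimer, with the dimer fraction f measured independently (e.g. by gel
quantification).  The ensemble reactivity at each position is then the
population-weighted sum f*dimer + (1-f)*monomer, which makes the dimer
profile recoverable by linear deconvolution.  This module provides the
deconvolution, a least-squares estimator of the mixing fraction, and the
replicate-based differential-reactivity test used to locate sites
protected in the dimer (reactivity drop above a threshold with a
per-site t-test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .reactivity import ReactivityProfile
from .regions import Region, RegionSet

__all__ = [
    "MixtureModel",
    "deconvolve",
    "estimate_fraction",
    "differential_sites",
]


@dataclass
class MixtureModel:
    """A two-conformer mixture: ensemble = f*dimer + (1-f)*monomer."""

    f: float
    monomer: ReactivityProfile
    dimer: ReactivityProfile
    ensemble: ReactivityProfile

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("dimer fraction must lie in [0, 1]")


def deconvolve(
    ensemble: ReactivityProfile,
    monomer: ReactivityProfile,
    f: float,
) -> ReactivityProfile:
    """Recover the dimer profile from ensemble and monomer at fraction f.

    dimer_i = (ensemble_i - (1-f)*monomer_i) / f, with the standard error
    propagated as sqrt(se_ens^2 + (1-f)^2 se_mono^2)/f.  Negative
    deconvolved reactivities are retained (and counted in ``meta``), so any
    downstream clipping or renormalization decision stays explicit.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("dimer fraction must lie in (0, 1]")
    if len(ensemble) != len(monomer):
        raise ValueError("profiles have different lengths")
    mask = ensemble.mask | monomer.mask
    values = (ensemble.values - (1 - f) * monomer.values) / f
    stderr = np.sqrt(ensemble.stderr**2 + (1 - f) ** 2 * monomer.stderr**2) / f
    negatives = int(np.sum(values[~mask] < 0))
    return ReactivityProfile(
        np.where(mask, np.nan, values),
        np.where(mask, np.nan, stderr),
        mask,
        sequence=ensemble.sequence,
        meta={"dimer_fraction": f, "n_negative": negatives},
    )


def estimate_fraction(
    ensemble: ReactivityProfile,
    monomer: ReactivityProfile,
    dimer: ReactivityProfile,
    min_informative: int = 10,
) -> float:
    """Least-squares estimate of the dimer fraction from three profiles.

    Minimizes sum_i (ensemble_i - f*dimer_i - (1-f)*monomer_i)^2 over the
    jointly unmasked positions; closed form, clipped to [0, 1].  Requires
    monomer and dimer to differ on at least ``min_informative`` positions.
    """
    if not (len(ensemble) == len(monomer) == len(dimer)):
        raise ValueError("profiles have different lengths")
    joint = ~(ensemble.mask | monomer.mask | dimer.mask)
    d = dimer.values[joint] - monomer.values[joint]
    e = ensemble.values[joint] - monomer.values[joint]
    informative = np.abs(d) > 1e-12
    if informative.sum() < min_informative:
        raise ValueError(
            f"monomer and dimer differ on only {int(informative.sum())} "
            f"positions (need {min_informative})"
        )
    f_hat = float(np.dot(d, e) / np.dot(d, d))
    return float(np.clip(f_hat, 0.0, 1.0))


def differential_sites(
    profiles_a: list[ReactivityProfile],
    profiles_b: list[ReactivityProfile],
    drop_threshold: float = 0.15,
    alpha: float = 0.05,
    equal_var: bool = False,
    bh_correct: bool = False,
) -> tuple[RegionSet, pd.DataFrame]:
    """Sites with a significant reactivity drop from condition A to B.

    A site is called when mean(A) - mean(B) exceeds ``drop_threshold``
    strictly AND the two-sample two-sided t-test across replicates gives
    p < ``alpha``.  Welch's unequal-variance test is the default; no
    multiple-testing correction is applied unless ``bh_correct`` is set
    (per-site criteria are reported as-is, matching common practice for
    this assay).  Returns called regions plus the full per-site table.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least two replicates per condition")
    n = len(profiles_a[0])
    for p in (*profiles_a, *profiles_b):
        if len(p) != n:
            raise ValueError("replicate profiles have different lengths")
    A = np.vstack([p.values for p in profiles_a])
    B = np.vstack([p.values for p in profiles_b])
    mean_a = np.nanmean(A, axis=0)
    mean_b = np.nanmean(B, axis=0)
    drop = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sstats.ttest_ind(
            A, B, axis=0, equal_var=equal_var, nan_policy="omit"
        )
    pvals = np.asarray(res.pvalue, dtype=float)
    if bh_correct:
        finite = np.isfinite(pvals)
        adj = np.full(n, np.nan)
        if finite.any():
            adj[finite] = sstats.false_discovery_control(pvals[finite])
        pvals_eff = adj
    else:
        pvals_eff = pvals
    called = (
        np.isfinite(drop)
        & np.isfinite(pvals_eff)
        & (drop > drop_threshold)
        & (pvals_eff < alpha)
    )
    table = pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "drop": drop,
            "pvalue": pvals,
            "called": called,
        }
    )
    regions = RegionSet(
        [Region(r.start, r.end, label="A>B") for r in RegionSet.from_mask(called)],
        label="differential",
    )
    return regions, table
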