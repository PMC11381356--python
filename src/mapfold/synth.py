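"""Synthetic SHAPE-MaP data with planted ground truth.

Real mutational-profiling experiments start from sequencing reads; here
every downstream stage is instead exercised against molecules whose true
secondary structure is known.  The generator plants pseudoknot-free helices,
designs Watson-Crick-compatible sequences, and emulates the two-channel
measurement: each nucleotide carries a latent reactivity drawn from a
paired or unpaired distribution, the untreated channel measures only the
reverse-transcription background rate, and the modified channel adds a
reactivity-proportional increment.  Two-state datasets share planted
helices inside designated core regions and re-draw the rest independently,
mirroring an in-cell vs refolded comparison design; monomer/dimer mixtures
are produced by linear weighting of reactivity profiles.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` substreams (one per stage, spawned in a fixed
documented order), so identical seeds reproduce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reactivity import MutationCountTable, ReactivityProfile
from .regions import Region, RegionSet

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"

__all__ = [
    "PlantedStructure",
    "SimulationParams",
    "SimulatedCounts",
    "TwoStateDataset",
    "StructurePlacementError",
    "make_structure",
    "design_sequence",
    "simulate_counts",
    "simulate_replicate",
    "simulate_two_states",
    "mix_profiles",
    "plant_motifs",
]


class StructurePlacementError(RuntimeError):
    """Raised when helices cannot be placed under the structural constraints."""


@dataclass
class PlantedStructure:
    """A pseudoknot-free set of planted helices over a molecule.

    ``pair_table`` holds the 1-based partner of each position (0 =
    unpaired); position i lives at index i-1.  Helices are recorded as
    (i_start, j_start, stem_len) with i_start pairing j_start, i_start+1
    pairing j_start-1, and so on.
    """

    length: int
    helices: list[tuple[int, int, int]]
    pair_table: np.ndarray
    max_pair_distance: int = 600

    def __post_init__(self) -> None:
        self.pair_table = np.asarray(self.pair_table, dtype=np.int64)
        self.validate()

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All planted pairs (i, j), i < j, 1-based."""
        return [
            (i + 1, int(j))
            for i, j in enumerate(self.pair_table)
            if j > i + 1
        ]

    def n_paired(self) -> int:
        return int(np.sum(self.pair_table > 0))

    def validate(self) -> None:
        pt = self.pair_table
        if len(pt) != self.length:
            raise ValueError("pair table length mismatch")
        for i1, j in enumerate(pt, start=1):
            if j == 0:
                continue
            if not 1 <= j <= self.length or j == i1:
                raise ValueError(f"position {i1}: invalid partner {j}")
            if pt[j - 1] != i1:
                raise ValueError(f"pair table asymmetric at ({i1}, {j})")
        pairs = self.pairs
        for i, j in pairs:
            if j - i < 4:
                raise ValueError(f"pair ({i},{j}) closes a loop shorter than 3")
            if j - i > self.max_pair_distance:
                raise ValueError(f"pair ({i},{j}) exceeds max pairing distance")
        for a, (i, j) in enumerate(pairs):
            for k, l in pairs[a + 1 :]:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")


@dataclass
class SimulationParams:
    """Measurement-model parameters for two-channel count simulation.

    depth_mean
        Mean effective read depth per position (Poisson), default 50 000 —
        the depth regime of a well-covered amplicon MaP experiment.
    untreated_rate_range
        Uniform interval for the per-position background mutation rate of
        reverse transcription.
    mod_scale
        Mutation-rate increment per unit of latent reactivity in the
        reagent-treated channel (additive model, clipped to [0, 1]).
    paired_react_mean / unpaired_shape, unpaired_scale
        Latent reactivity distributions: Exponential(mean 0.08) for paired
        positions, Gamma(shape 2, scale 0.35) for unpaired ones — generator
        conventions mimicking typical SHAPE reactivity benchmarks, not
        values taken from any single experiment.
    """

    depth_mean: float = 50_000.0
    untreated_rate_range: tuple[float, float] = (0.0002, 0.002)
    mod_scale: float = 0.02
    paired_react_mean: float = 0.08
    unpaired_shape: float = 2.0
    unpaired_scale: float = 0.35
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.untreated_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("untreated_rate_range must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0 <= self.mod_scale <= 1:
            raise ValueError("mod_scale must lie in [0, 1]")


@dataclass
class SimulatedCounts:
    """One simulated channel plus its ground truth."""

    table: MutationCountTable
    latent: np.ndarray        # latent reactivity x_i
    background: np.ndarray    # untreated rate b_i
    rate: np.ndarray          # true channel rate used for the draw


def _substreams(seed, n: int) -> list[np.random.Generator]:
    """Fixed-order per-stage RNG substreams from one seed (int or spawned)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _helix_ok(
    i: int, j: int, stem: int, pt: np.ndarray, maxd: int
) -> bool:
    """Can a helix (i, j, stem) be added to pair table ``pt`` (1-based i, j)?"""
    n = len(pt)
    if i < 1 or j > n:
        return False
    if j - i > maxd:
        return False
    if j - i - 2 * (stem - 1) < 4:  # innermost loop >= 3
        return False
    arms = list(range(i, i + stem)) + list(range(j - stem + 1, j + 1))
    if any(pt[p - 1] != 0 for p in arms):
        return False
    for p1, q in enumerate(pt, start=1):
        if q <= p1:
            continue
        # outer candidate pair (i, j) must nest with every existing pair
        if (p1 < i < q < j) or (i < p1 < j < q):
            return False
    return True


def _add_helix(pt: np.ndarray, i: int, j: int, stem: int) -> None:
    for k in range(stem):
        pt[i - 1 + k] = j - k
        pt[j - 1 - k] = i + k


def _place_helices(
    length: int,
    n_helices: int,
    stem_len_range: tuple[int, int],
    rng: np.random.Generator,
    max_pair_distance: int,
    pair_table: np.ndarray | None = None,
    allowed: np.ndarray | None = None,
    span_cap: int | None = None,
    max_attempts_per_helix: int = 2000,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    pt = np.zeros(length, dtype=np.int64) if pair_table is None else pair_table
    helices: list[tuple[int, int, int]] = []
    lo, hi = stem_len_range
    if lo < 3:
        raise ValueError("stem lengths must be >= 3")
    cap = min(max_pair_distance, length, span_cap or length)
    for _ in range(n_helices):
        free = pt == 0 if allowed is None else (pt == 0) & allowed
        starts = np.nonzero(free)[0] + 1
        if len(starts) == 0:
            raise StructurePlacementError("no free positions left for helices")
        placed = False
        for _attempt in range(max_attempts_per_helix):
            stem = int(rng.integers(lo, hi + 1))
            i = int(starts[rng.integers(len(starts))])
            span_min = 2 * (stem - 1) + 4
            if span_min > cap:
                continue
            if not free[i - 1 : i + stem - 1].all() or i + stem - 1 > length:
                continue
            # enumerate feasible partners for this start, then sample one
            feasible = []
            for j in range(i + span_min, min(i + cap, length) + 1):
                if not free[j - stem : j].all():
                    continue
                if allowed is not None and not allowed[j - stem : j].all():
                    continue
                if _helix_ok(i, j, stem, pt, max_pair_distance):
                    feasible.append(j)
            if feasible:
                j = int(feasible[rng.integers(len(feasible))])
                _add_helix(pt, i, j, stem)
                helices.append((i, j, stem))
                placed = True
                break
        if not placed:
            raise StructurePlacementError(
                f"could not place helix {len(helices) + 1} of {n_helices} "
                f"after {max_attempts_per_helix} attempts"
            )
    return pt, helices


def make_structure(
    length: int,
    n_helices: int,
    stem_len_range: tuple[int, int] = (4, 8),
    seed: int | None = None,
    max_pair_distance: int = 600,
) -> PlantedStructure:
    """Plant ``n_helices`` non-crossing helices by rejection sampling.

    Raises :class:`StructurePlacementError` if a helix cannot be placed
    after a bounded number of attempts.
    """
    if length < 30:
        raise ValueError("length must be >= 30")
    rng = np.random.default_rng(seed)
    pt, helices = _place_helices(
        length, n_helices, stem_len_range, rng, max_pair_distance
    )
    return PlantedStructure(length, helices, pt, max_pair_distance)


def design_sequence(
    structure: PlantedStructure,
    gc_fraction: float = 0.5,
    seed: int | None = None,
) -> str:
    """Design an RNA sequence realizing every planted pair as Watson-Crick.

    Each planted pair becomes G·C with probability ``gc_fraction`` and A·U
    otherwise (orientation random); unpaired positions are uniform ACGU.
    """
    rng = np.random.default_rng(seed)
    seq = [""] * structure.length
    for i, j in structure.pairs:
        if rng.random() < gc_fraction:
            a, b = ("G", "C") if rng.random() < 0.5 else ("C", "G")
        else:
            a, b = ("A", "U") if rng.random() < 0.5 else ("U", "A")
        seq[i - 1], seq[j - 1] = a, b
    for k in range(structure.length):
        if not seq[k]:
            seq[k] = RNA_ALPHABET[rng.integers(4)]
    return "".join(seq)


def _draw_latent(
    structure: PlantedStructure, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    paired = structure.pair_table > 0
    x = np.empty(structure.length)
    x[paired] = rng.exponential(params.paired_react_mean, size=paired.sum())
    x[~paired] = rng.gamma(
        params.unpaired_shape, params.unpaired_scale, size=(~paired).sum()
    )
    return x


def simulate_counts(
    structure: PlantedStructure,
    params: SimulationParams,
    channel: str = "modified",
    seed: int | None = None,
    *,
    sequence: str | None = None,
    latent: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> SimulatedCounts:
    """Simulate one channel of MaP mutation counts over a planted structure.

    Latent reactivity x_i comes from the paired/unpaired distributions (or
    is passed in, so replicates can share it); the untreated rate b_i is
    uniform over ``untreated_rate_range``; the modified channel draws events
    at rate b_i + mod_scale * x_i (clipped to [0, 1]), the untreated channel
    at b_i.  Depth is Poisson(depth_mean) and events Binomial(depth, rate).
    """
    if channel not in ("modified", "untreated"):
        raise ValueError("channel must be 'modified' or 'untreated'")
    rng_latent, rng_bg, rng_seq, rng_counts = _substreams(seed, 4)
    n = structure.length
    if latent is None:
        latent = _draw_latent(structure, params, rng_latent)
    if background is None:
        lo, hi = params.untreated_rate_range
        background = rng_bg.uniform(lo, hi, size=n)
    if sequence is None:
        sequence = design_sequence(structure, 0.5, rng_seq.integers(2**31))
    if channel == "modified":
        rate = background + params.mod_scale * latent
        clipped = rate > 1.0
        if clipped.any():
            logger.info("clipped %d modified rates to 1.0", int(clipped.sum()))
        rate = np.clip(rate, 0.0, 1.0)
    else:
        rate = background.copy()
    depth = rng_counts.poisson(params.depth_mean, size=n)
    events = rng_counts.binomial(depth, rate)
    table = MutationCountTable(np.array(list(sequence)), events, depth)
    return SimulatedCounts(table, np.asarray(latent), np.asarray(background), rate)


def simulate_replicate(
    structure: PlantedStructure,
    params: SimulationParams,
    seed: int | None = None,
    *,
    sequence: str,
    latent: np.ndarray,
    background: np.ndarray,
) -> tuple[SimulatedCounts, SimulatedCounts]:
    """One replicate = a paired (modified, untreated) channel draw."""
    s_mod, s_untr = np.random.SeedSequence(seed).spawn(2)
    mod = simulate_counts(
        structure, params, "modified", s_mod,
        sequence=sequence, latent=latent, background=background,
    )
    untr = simulate_counts(
        structure, params, "untreated", s_untr,
        sequence=sequence, latent=latent, background=background,
    )
    return mod, untr


@dataclass
class TwoStateDataset:
    """Two experimental states sharing planted helices inside core regions."""

    sequence: str
    structures: dict          # state -> PlantedStructure
    latent: dict              # state -> latent reactivity array
    replicates: dict          # state -> list of (modified, untreated) SimulatedCounts
    core_regions: RegionSet
    params: SimulationParams
    seed: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def simulate_two_states(
    core_regions: RegionSet,
    length: int,
    params: SimulationParams | None = None,
    seed: int | None = None,
    *,
    n_replicates: int = 2,
    core_stem_range: tuple[int, int] = (5, 8),
    flank_stem_range: tuple[int, int] = (4, 7),
    core_helix_spacing: int = 20,
    flank_helix_spacing: int = 90,
    gc_fraction: float = 0.8,
    max_pair_distance: int = 600,
) -> TwoStateDataset:
    """Simulate two states that share structure only inside the core.

    Helices inside ``core_regions`` are identical in both states (about one
    helix per ``core_helix_spacing`` nt, confined to a single core
    interval); outside the core, each state gets its own sparser helices,
    drawn on disjoint position sets so that one sequence can realize both
    states' pairs as Watson-Crick.  Each state emits ``n_replicates``
    (modified, untreated) count-table pairs sharing the state's latent
    reactivities and the molecule-wide background rates.
    """
    if params is None:
        params = SimulationParams()
    for r in core_regions:
        if r.end > length:
            raise ValueError(f"core region {r} outside [1, {length}]")
    if n_replicates < 2:
        raise ValueError("need at least two replicates per state")
    rngs = _substreams(seed, 6)
    rng_core, rng_a, rng_b, rng_seq, rng_latent, rng_counts = rngs

    core_mask = core_regions.to_mask(length)
    core_pt = np.zeros(length, dtype=np.int64)
    core_helices: list[tuple[int, int, int]] = []
    for region in core_regions:
        n_hel = max(len(region) // core_helix_spacing, 1)
        allowed = np.zeros(length, dtype=bool)
        allowed[region.start - 1 : region.end] = True
        try:
            core_pt, placed = _place_helices(
                length, n_hel, core_stem_range, rng_core, max_pair_distance,
                pair_table=core_pt, allowed=allowed, span_cap=len(region),
            )
        except StructurePlacementError as err:
            raise StructurePlacementError(
                f"core region {region.start}-{region.end}: {err}"
            ) from err
        core_helices.extend(placed)

    n_flank = max(int((length - core_regions.total_length()) // flank_helix_spacing), 0)
    structures: dict[str, PlantedStructure] = {}
    used_outside = core_mask.copy()  # positions unavailable to the *other* state
    state_helices: dict[str, list] = {}
    for state, rng in (("A", rng_a), ("B", rng_b)):
        allowed = ~used_outside
        pt = core_pt.copy()
        try:
            pt, placed = _place_helices(
                length, n_flank, flank_stem_range, rng, max_pair_distance,
                pair_table=pt, allowed=allowed, span_cap=150,
            )
        except StructurePlacementError as err:
            raise StructurePlacementError(f"state {state} flank: {err}") from err
        for (i, j, stem) in placed:
            used_outside[i - 1 : i + stem - 1] = True
            used_outside[j - stem : j] = True
        structures[state] = PlantedStructure(
            length, core_helices + placed, pt, max_pair_distance
        )
        state_helices[state] = placed

    # one sequence realizing the union of both states' pairs
    union_pt = np.zeros(length, dtype=np.int64)
    union_helices = core_helices + state_helices["A"] + state_helices["B"]
    for (i, j, stem) in union_helices:
        _add_helix(union_pt, i, j, stem)
    union = PlantedStructure.__new__(PlantedStructure)  # skip crossing validation:
    union.length = length                               # A/B flank helices may cross
    union.helices = union_helices                       # each other; the sequence only
    union.pair_table = union_pt                         # needs WC complementarity
    union.max_pair_distance = max_pair_distance
    sequence = design_sequence(union, gc_fraction, rng_seq.integers(2**31))

    latent = {
        st: _draw_latent(structures[st], params, rng_latent) for st in ("A", "B")
    }
    lo, hi = params.untreated_rate_range
    background = rng_latent.uniform(lo, hi, size=length)

    replicates: dict[str, list] = {st: [] for st in ("A", "B")}
    for st in ("A", "B"):
        for _rep in range(n_replicates):
            rep_seed = rng_counts.integers(2**31)
            replicates[st].append(
                simulate_replicate(
                    structures[st], params, rep_seed,
                    sequence=sequence, latent=latent[st], background=background,
                )
            )
    return TwoStateDataset(
        sequence, structures, latent, replicates, core_regions, params, seed
    )


def mix_profiles(
    monomer: ReactivityProfile, dimer: ReactivityProfile, f: float
) -> ReactivityProfile:
    """Linear ensemble of conformer profiles: f·dimer + (1-f)·monomer.

    Emulates a population in which a fraction ``f`` of molecules is dimeric;
    the measured ensemble reactivity is the population-weighted sum.  The
    no-data mask is the union of the input masks.
    """
    if len(monomer) != len(dimer):
        raise ValueError("monomer and dimer profiles have different lengths")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    mask = monomer.mask | dimer.mask
    values = f * dimer.values + (1 - f) * monomer.values
    stderr = np.sqrt((f * dimer.stderr) ** 2 + ((1 - f) * monomer.stderr) ** 2)
    return ReactivityProfile(
        np.where(mask, np.nan, values),
        np.where(mask, np.nan, stderr),
        mask,
        sequence=monomer.sequence,
        meta={"dimer_fraction": f},
    )


def plant_motifs(
    background_base: str,
    length: int,
    motifs: list[tuple[str, int]],
) -> str:
    """Embed motif sequences at 1-based starts in a homopolymer background.

    Raises on out-of-range or overlapping motifs.
    """
    if background_base not in RNA_ALPHABET:
        raise ValueError(f"background base {background_base!r} not in {RNA_ALPHABET}")
    seq = [background_base] * length
    occupied = np.zeros(length, dtype=bool)
    for motif, start in motifs:
        end = start + len(motif) - 1
        if start < 1 or end > length:
            raise ValueError(f"motif {motif!r} at {start} outside [1, {length}]")
        if occupied[start - 1 : end].any():
            raise ValueError(f"motif {motif!r} at {start} overlaps another motif")
        occupied[start - 1 : end] = True
        seq[start - 1 : end] = list(motif)
    return "".join(seq)
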