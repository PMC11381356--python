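# Methods

This note records the models, conventions and numerical choices behind
`mapfold`, in the spirit of a package's own methods documentation: what is
computed, under which assumptions, and where the genuinely open design
choices were made.

## Measurement model of the synthetic-data generator

The generator replaces sequencing data with a two-channel count model over
molecules of known (planted) secondary structure.

*Planted structures.* Helices `(i, j, stem)` are placed by rejection
sampling under the structural invariants (pair-table symmetry, minimum
hairpin loop of 3 nt, non-crossing nesting, maximum pairing distance
600 nt).  Starts are drawn from currently unpaired allowed positions and a
partner is sampled uniformly from the feasible set for that start, which
lets dense regions fill without violating the invariants; placement
failure after a bounded number of attempts raises an explicit error.

*Sequences.* Each planted pair becomes G·C with probability
`gc_fraction` (A·U otherwise, random orientation); unpaired positions are
uniform over {A, C, G, U}.  A consequence worth knowing: random unpaired
letters occasionally create a register-shifted competitor of a planted
helix with lower model energy, so per-molecule recovery of planted pairs
is a random variable (observed 0.85–1.0 per molecule, ~0.98 aggregated
over five molecules at the default conditions).

*Counts.* Latent reactivity `x_i` is Exponential(mean 0.08) at paired and
Gamma(shape 2, scale 0.35) at unpaired positions — conventions chosen to
mimic the shape of typical SHAPE reactivity distributions (low, peaked
near zero for paired; broad with mean ≈ 0.7 for unpaired), not values
measured in any one experiment.  The untreated channel draws events at a
background rate `b_i ~ Uniform(2e-4, 2e-3)` per position; the modified
channel at `b_i + 0.02·x_i` (clipped to [0, 1], clipping logged).  Depth
is Poisson(50 000) per position, events Binomial(depth, rate).  At these
settings the unpaired-vs-paired rate-difference separation is detectable
per molecule (rank-sum p ≪ 0.01) and replicate profiles correlate at
r > 0.99, comparable to a well-covered amplicon experiment.

*Two-state datasets.* Both states share the helices planted inside the
designated core regions (about one helix per 20 nt of core, stems 5–8,
GC-rich at `gc_fraction = 0.8`); outside the core each state receives its
own sparser helices (about one per 90 nt, spans capped at 150 nt so flank
structure stays local).  The two states' private helices are placed on
disjoint position sets so that a single sequence realizes both states'
pairs as Watson–Crick.  Replicates share the state's latent reactivities
and the molecule-wide background rates and differ only in counting noise.
Latent reactivities are resampled per state, so the two states differ
both in structure (outside the core) and in noise realization — the
situation the comparison statistics are meant to resolve.

*Randomness.* A single integer seed expands into per-stage substreams via
`numpy.random.SeedSequence.spawn` in a fixed documented order (core
placement, state A flanks, state B flanks, sequence design, latent draws,
counts).  Identical seeds reproduce byte-identical outputs.

What the generator does **not** emulate: read-level artifacts (PCR bias,
mutation-calling ambiguity), position-correlated background, reagent
single-strand selectivity differences between nucleotides, and
post-transcriptional modifications.  Passing the synthetic benchmarks
therefore demonstrates the correctness and calibration of the analysis
chain, not robustness to those real-data artifacts.

## Reactivity pipeline

Raw reactivity is the per-position mutation-rate difference with binomial
error propagation.  Positions with zero depth, or depth strictly below
the threshold (default 5000×) in either channel, are masked — 5000 itself
is retained.  The no-data sentinel is −999 in files; in memory masking is
an explicit boolean array and masked values never enter any statistic.

Normalization follows the model-free boxplot rule: values above
Q3 + 1.5·IQR are outliers (at most 10% of the data), and the
normalization factor is the mean of the top 10% of the retained values;
profiles longer than 500 nt instead exclude the top 2% and average the
2–10% band.  When the IQR collapses to zero (zero-inflated profiles) the
quartiles fall back to the positive values — without this guard such
profiles would flag their entire signal as outliers.  The rule is
idempotent (renormalizing changes nothing) and scale-equivariant, and the
factor is recorded in the profile metadata.  Negative reactivities
(untreated above treated) are retained everywhere except the Gini index,
which requires non-negative values and therefore clips at zero.

Replicates are averaged over unmasked values (output masked only where
all replicates are masked), with pairwise Pearson r reported on jointly
unmasked positions.  The treated-vs-untreated comparison uses the
two-sided Wilcoxon rank-sum test, exact for small tie-free samples.

## Energy model and folding

The folding engine optimizes a compact nearest-neighbor model:

* stacking free energies for all 36 Watson–Crick/wobble pair steps,
  symmetrized to respect strand-reversal symmetry exactly;
* hairpin `5.4 + 1.08·ln(l/3)`, bulge `3.8 + 1.08·ln(l)` and internal
  `4.0 + 1.08·ln((u1+u2)/2) + min(3, 0.5·|u1−u2|)` kcal/mol loop
  penalties (Jacobson–Stockmayer-type logarithmic length dependence);
* affine multiloops: 3.4 kcal/mol closing plus 0.4 per branch (closing
  pair included), unpaired multiloop nucleotides free;
* no dangling ends, coaxial stacking, terminal-AU penalties or special
  tetraloops; interior loops capped at 30 unpaired nucleotides (a model
  constraint, as in standard implementations).

Consequently absolute ΔG values are **not** comparable with full
Turner-2004 engines — on random sequences the rank correlation with such
an engine is ≈ 0.75 and designed hairpins fold identically, which is the
intended level of agreement.  Correctness claims rest instead on
self-consistency: for short sequences the DP minimum and the partition
function equal a brute-force enumeration over *all* pseudoknot-free
structures under the same model to 1e-6.  The parameter set is a plain
dataclass (`EnergyModel`) and can be swapped wholesale.

SHAPE pseudo-energies follow the Deigan form `m·ln(S+1) + b` (defaults
1.8/−0.6 kcal/mol), added for each of the four nucleotides of every
helical stack — helix-interior nucleotides participate in two stacks and
are counted twice, terminal ones once.  Masked positions contribute zero;
reactivities below −1 are clamped to −1+ε with a warning.

The MFE fill is the classic closed/multiloop/exterior decomposition; the
partition function uses an unambiguous variant of the same decomposition
(last-branch conditioning in multiloop segments) with a full outside pass
for pair probabilities.  All inside and outside quantities carry a
per-nucleotide rescaling factor `kappa = exp(1.07·E_MFE/(n·RT))` so the
computation stays finite for window-sized molecules; the factor cancels
exactly in `p_ij`.  Temperature (default 310.15 K) enters the Boltzmann
weights only — the free-energy table has no enthalpy decomposition, so
refolding at other temperatures rescales rather than re-ranks structures.
Shannon entropies use log base 10 (configurable).

Traceback is deterministic: exterior and multiloop branches are taken
5′-most first; within a closed pair, interior-loop candidates are scanned
by ascending 5′ start and descending 3′ end (stacks preferred).
Energy-tie resolution therefore never depends on floating-point noise
beyond a relative tolerance of 1e-4.

Molecules longer than one window (default 1200 nt, step 100, edge trim
300) are folded per window; `edge_trim` nucleotides are discarded from
every non-terminal window edge, probabilities are averaged over windows
retaining both partners, and the consensus structure keeps MFE pairs
predicted in more than half of their covering windows (crossing conflicts
resolved by vote, then averaged probability, then 5′ position).  For
sequences within one window this reduces exactly to the direct fold.

The intermolecular duplex is a separate dynamic program: antiparallel
hybrid scored with the same stacking table, single-strand bulges up to
5 nt, one duplex-initiation penalty of 4.1 kcal/mol, no intramolecular
structure — intended for short primer/site hybridizations, not for long
bimolecular folds.

## Comparison analytics

Sliding statistics use centered windows (default 51 nt, odd), exclude
masked values, and mask windows with less than half their positions
carrying data; edges either shrink the window (default) or mask.  The
Gini index is computed by the sorted-rank identity, equal to the pairwise
mean absolute difference normalized by twice the mean; windows with zero
mean (after clipping negatives) are undefined.

The ΔSHAPE-style difference caller smooths values and propagated errors
over 3-nt windows, requires a positive Z-factor
`1 − 1.96·(se_A+se_B)/|Δ|` *and* a standard score |Z| ≥ 1, and calls a
site only when at least 3 positions of some 5-nt window qualify.  Under
null simulations (replicate pairs from one state) the per-nucleotide call
rate is ~3%, below the 5% nominal level.  Signs are assigned after
smoothing.

lowSS regions: both the reactivity and the entropy track are
median-smoothed (51 nt); a qualifying run has smoothed reactivity
strictly below the global median reactivity and smoothed entropy strictly
below the global median entropy; runs separated by ≤ 10 nt merge, and
regions shorter than 40 nt are dropped.  The merge gap and minimum length
are conventions (config-exposed), so region *counts* are comparable only
qualitatively across parameter choices.  A caveat observed on synthetic
molecules with largely unstructured flanks: confidently unpaired regions
also have near-zero entropy, which pushes the global entropy median down
and makes the entropy gate conservative — detection of a true structured
core can fail in one state for unlucky draws.

The well-folded core intersects the two states' lowSS sets; a candidate
joins the core iff at least half of the MFE pairs lying entirely inside
it are shared between states and it contains at least one highly probable
pair (p > 0.8, strict) present in both states.  Coverage is reported as a
percentage of molecule length.

Sensitivity (`100·TP/|reference|`) and PPV (`100·TP/|predicted|`) count
exact pair matches by default; `slip=1` tolerates ±1 on either index, and
an explicit `helix_completion` flag first extends any predicted helix
that shares a pair with a reference helix by the remainder of that
reference helix — a reconstruction of manual helix completion; both are
off by default.

## Interactions

Ensemble deconvolution and mixing are exact linear inverses of each other
for f ∈ (0, 1]; deconvolved negative reactivities are flagged and
retained, never clipped, so downstream normalization decisions stay
explicit.  The default order is deconvolve-after-normalize (both orders
are possible by composing the functions; normalization is
scale-equivariant, so the orders differ only through the outlier set).
The mixing-fraction estimator is the closed-form least-squares projection
clipped to [0, 1]; it is exact on noiseless input and lands within 0.03
of f = 0.4 in ≥ 95% of simulations at per-site noise σ = 0.05 over 500
sites.  Differential sites require a strict reactivity drop > 0.15 *and*
a two-sided two-sample t-test p < 0.05 across replicates; Welch's
unequal-variance form is the default (a pooled-variance switch exists),
and no multiple-testing correction is applied by default, matching the
per-site criterion common for this assay — a Benjamini–Hochberg switch is
provided for conservative use.

## Motif scans

Palindromes are maximal even-length substrings equal to their own
Watson–Crick reverse complement — G·U is deliberately excluded because a
dimerization palindrome must duplex with a second copy of itself in
trans, where a wobble self-complement does not survive the strand swap.
Hits are clipped to the configured maximum length and deduplicated to the
longest (leftmost on ties).  Purine tracts are maximal A/G runs (default
≥ 10 nt).  G-quadruplex candidates match `G{g}N{l1}G{g}N{l2}G{g}N{l3}G{g}`
with g ≥ 2, loops ≥ 1, span ≤ 30, and are ranked by this package's own
documented score `10·(g−2) + (30 − span) − var(loops)` (overlaps resolved
to the highest score); the enumeration, not the score, is the testable
part.  Only the plus strand is scanned, and all coordinates everywhere
are 1-based inclusive (BED export converts explicitly).

## Problem sizes used by the test and acceptance suites

Enumeration oracles run on 1000 random sequences of 5–15 nt (every
structure enumerated); recovery benchmarks use 200-nt molecules at
50 000× depth aggregated over five seeds; the end-to-end two-state
benchmark uses one 900-nt molecule with two 180-nt core regions and two
replicates per state; null calibrations use 100 simulations (50 in the
acceptance script).  These sizes keep a full run in the tens of seconds
on one CPU while leaving every statistical assertion with comfortable
margins.

## Known limitations

* Absolute free energies are model-specific; only comparisons within the
  package are meaningful.
* Pseudoknots are outside the structure space (both folding and the
  generator); externally predicted pseudoknots can be represented as
  annotations but are not recomputed.
* The windowed consensus can drop pairs near window edges of genuinely
  long-range helices (mitigated, not eliminated, by edge trimming).
* lowSS detection depends on global medians and is sensitive to the
  overall structured fraction of the molecule (see above).
* The generator's sequence design does not forbid spurious
  complementarity, so planted structures are recoverable in aggregate but
  not guaranteed per molecule.
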