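import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mapfold.fold import FoldConfig
from mapfold.reactivity import normalize_boxplot, raw_reactivity
from mapfold.synth import (
    SimulationParams,
    design_sequence,
    make_structure,
    simulate_counts,
)


@pytest.fixture(scope="session")
def fold_cfg():
    return FoldConfig()


@pytest.fixture(scope="session")
def planted_200():
    """A 200-nt molecule with 8 planted GC-rich helices plus simulated SHAPE.

    Session-scoped: several tests reuse the same probing experiment.
    """
    structure = make_structure(200, 8, (5, 8), seed=11)
    sequence = design_sequence(structure, gc_fraction=0.85, seed=12)
    params = SimulationParams()
    mod = simulate_counts(structure, params, "modified", 14, sequence=sequence)
    untr = simulate_counts(
        structure, params, "untreated", 15, sequence=sequence,
        latent=mod.latent, background=mod.background,
    )
    profile = normalize_boxplot(raw_reactivity(mod.table, untr.table))
    return {
        "structure": structure,
        "sequence": sequence,
        "mod": mod,
        "untr": untr,
        "profile": profile,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)
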