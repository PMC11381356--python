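"""End-to-end reproducible pipeline over synthetic two-state data.

One seeded run chains: simulate two-state count data -> reactivity profiles
(depth filter, normalization, replicate averaging) -> SHAPE-directed
folding (MFE + pair probabilities + entropy) per state -> two-state
comparison (delta reactivity, Gini, lowSS regions, well-folded core,
sensitivity/PPV, highly probable pairs, local bp content) -> motif scans,
and writes every artifact plus a summary report and the resolved
configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .compare import (
    WindowConfig,
    delta_shape,
    gini_profile,
    hp_basepairs,
    local_bp_content,
    lowss_regions,
    score_structures,
    sliding_stat,
    well_folded_core,
)
from .fold import FoldConfig, windowed_fold
from .motifs import find_gquad, find_palindromes, find_purine_tracts
from .reactivity import (
    depth_filter,
    normalize_boxplot,
    rate_comparison_test,
    raw_reactivity,
    replicate_stats,
)
from .regions import RegionSet
from .synth import SimulationParams, simulate_two_states

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "pipeline_run", "state_profiles"]


@dataclass
class RunConfig:
    """Flat, human-readable configuration for one pipeline run."""

    seed: int = 0
    out_dir: str = "mapfold_run"
    length: int = 900
    core_regions: str = "151-330,541-720"
    replicates: int = 2
    depth: float = 50_000.0
    min_depth: int = 5000
    slope: float = 1.8
    intercept: float = -0.6
    max_pair_distance: int = 600
    window: int = 1200
    step: int = 100
    edge_trim: int = 300
    stat_window: int = 51
    comp_window: int = 75
    hp_threshold: float = 0.8
    lowss_merge_gap: int = 10
    lowss_min_len: int = 40
    drop_threshold: float = 0.15
    alpha: float = 0.05

    def fold_config(self) -> FoldConfig:
        return FoldConfig(
            slope=self.slope,
            intercept=self.intercept,
            max_pair_distance=self.max_pair_distance,
            window=self.window,
            step=self.step,
            edge_trim=self.edge_trim,
        )

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            stat_window=self.stat_window, comp_window=self.comp_window
        )

    def core_region_set(self) -> RegionSet:
        if not self.core_regions.strip():
            return RegionSet()
        pairs = []
        for tok in self.core_regions.split(","):
            s, e = tok.strip().split("-")
            pairs.append((int(s), int(e)))
        return RegionSet.from_tuples(pairs, label="core-truth")

    def serialize(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def parse(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            cast = type(getattr(defaults, key))
            kwargs[key] = cast(val)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def state_profiles(replicates, min_depth: int):
    """Replicate count pairs -> (averaged normalized profile, pairwise r)."""
    profs = []
    for mod, untr in replicates:
        raw = raw_reactivity(mod.table, untr.table)
        dmask, _ = depth_filter(mod.table, untr.table, min_depth)
        raw.mask |= dmask
        raw.values[raw.mask] = np.nan
        raw.stderr[raw.mask] = np.nan
        profs.append(normalize_boxplot(raw))
    return replicate_stats(profs)


def pipeline_run(config: RunConfig) -> dict:
    """Run the full synthetic two-state pipeline; returns the summary dict."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.serialize(out / "run_config.txt")
    stage_times: dict[str, float] = {}
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    def _stage(name):
        stage_times[name] = time.time()
        logger.info("stage %s", name)

    try:
        _stage("simulate")
        params = SimulationParams(depth_mean=config.depth)
        ds = simulate_two_states(
            config.core_region_set(), config.length, params, config.seed,
            n_replicates=config.replicates,
            max_pair_distance=config.max_pair_distance,
        )
        mio.write_fasta(out / "molecule.fa", [("synthetic", ds.sequence)])
        for st in ("A", "B"):
            for k, (mod, untr) in enumerate(ds.replicates[st], start=1):
                mio.write_counts(out / f"state{st}_rep{k}_modified.tsv", mod.table)
                mio.write_counts(out / f"state{st}_rep{k}_untreated.tsv", untr.table)

        _stage("reactivity")
        profiles, rep_r = {}, {}
        for st in ("A", "B"):
            avg, rmat = state_profiles(ds.replicates[st], config.min_depth)
            avg.sequence = ds.sequence
            profiles[st] = avg
            rep_r[st] = float(rmat[0, 1])
            mio.write_map(out / f"state{st}.map", avg)
        wtest = rate_comparison_test(
            ds.replicates["A"][0][0].table, ds.replicates["A"][0][1].table
        )

        _stage("fold")
        fcfg = config.fold_config()
        ppm, mfe = {}, {}
        for st in ("A", "B"):
            ppm[st], mfe[st] = windowed_fold(ds.sequence, profiles[st], fcfg)
            mio.write_ct(out / f"state{st}.ct", mfe[st], name=f"state{st}")
            mio.write_dotbracket(out / f"state{st}.db", mfe[st], name=f"state{st}")
            mio.write_pair_probs(out / f"state{st}_pairs.tsv", ppm[st])

        _stage("compare")
        wcfg = config.window_config()
        hp = {st: hp_basepairs(ppm[st], config.hp_threshold) for st in ("A", "B")}
        lowss = {}
        for st in ("A", "B"):
            lowss[st] = lowss_regions(
                profiles[st], ppm[st].entropy, wcfg,
                merge_gap=config.lowss_merge_gap, min_len=config.lowss_min_len,
            )
            mio.write_regions(out / f"state{st}_lowss.tsv", lowss[st])
            mio.write_track(
                out / f"state{st}_entropy.tsv", ppm[st].entropy, "entropy"
            )
            mio.write_track(
                out / f"state{st}_median_shape.tsv",
                sliding_stat(profiles[st], wcfg, "median"),
                "median_reactivity",
            )
            mio.write_track(
                out / f"state{st}_mfe_bp_content.tsv",
                local_bp_content(mfe[st].pairs, ds.length, wcfg),
                "mfe_bp_pct",
            )
            mio.write_track(
                out / f"state{st}_hp_bp_content.tsv",
                local_bp_content(hp[st], ds.length, wcfg),
                "hp_bp_pct",
            )
        core, coverage = well_folded_core(
            lowss["A"], lowss["B"], mfe["A"], mfe["B"], hp["A"], hp["B"]
        )
        mio.write_regions(out / "core.tsv", core)
        ds_regions, _tracks = delta_shape(profiles["A"], profiles["B"])
        mio.write_regions(out / "delta_shape_sites.tsv", ds_regions)
        score = score_structures(mfe["A"], mfe["B"])
        gini_tracks = {
            st: gini_profile(profiles[st], wcfg) for st in ("A", "B")
        }

        _stage("motifs")
        pals = find_palindromes(ds.sequence)
        ppts = find_purine_tracts(ds.sequence)
        gq = find_gquad(ds.sequence)

        n = ds.length
        summary.update(
            {
                "length": n,
                "replicate_pearson_r": rep_r,
                "rate_wilcoxon_p": wtest["pvalue"],
                "global_median_reactivity": {
                    st: float(np.nanmedian(profiles[st].values))
                    for st in ("A", "B")
                },
                "global_gini": {st: gini_tracks[st][1] for st in ("A", "B")},
                "mfe_energy": {st: mfe[st].energy for st in ("A", "B")},
                "total_bp": {st: len(mfe[st].pairs) for st in ("A", "B")},
                "hp_bp_nt_pct": {
                    st: 100.0 * 2 * len(hp[st]) / n for st in ("A", "B")
                },
                "lowss_count": {st: len(lowss[st]) for st in ("A", "B")},
                "core_coverage_pct": coverage,
                "core_regions": [(r.start, r.end) for r in core],
                "sensitivity_pct": score.sensitivity,
                "ppv_pct": score.ppv,
                "delta_shape_sites": int(_tracks["called"].sum()),
                "n_palindromes": len(pals),
                "n_purine_tracts": len(ppts),
                "n_gquad": len(gq),
            }
        )
    except Exception as err:
        stage = list(stage_times)[-1] if stage_times else "setup"
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    # timing and provenance go to the log, keeping summary.json
    # byte-identical across reruns of the same seed and config
    total = time.time() - t_start
    log_path = out / "run_log.txt"
    rerun = log_path.exists() and config.config_hash() in log_path.read_text()
    with open(log_path, "a") as fh:
        fh.write(
            f"seed={config.seed} config_hash={config.config_hash()} "
            f"total_s={total:.2f}"
            + (" (rerun of identical config)" if rerun else "")
            + "\n"
        )
        names = list(stage_times)
        for k, name in enumerate(names):
            t0 = stage_times[name]
            t1 = stage_times[names[k + 1]] if k + 1 < len(names) else t_start + total
            fh.write(f"  stage {name}: {t1 - t0:.2f}s\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("pipeline finished in %.1fs", total)
    return summary
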