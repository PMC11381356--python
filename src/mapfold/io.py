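"""Readers and writers for the small text formats of the probing ecosystem.

FASTA (via Biopython), 6-column CT connectivity tables and dot-bracket,
SHAPE reactivity files (2-column ``.shape`` and 4-column ``.map`` with the
-999 no-data sentinel), mutation-count TSVs, interval tables and pair
probability tables.  All coordinates are written 1-based inclusive; BED
0-based half-open output is an explicit conversion.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import PairProbabilityMatrix, SecondaryStructure
from .reactivity import NO_DATA, MutationCountTable, ReactivityProfile
from .regions import Region, RegionSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_ct",
    "write_ct",
    "write_dotbracket",
    "read_shape",
    "read_map",
    "write_shape",
    "write_map",
    "read_counts",
    "write_counts",
    "read_regions",
    "write_regions",
    "write_pair_probs",
]


def read_fasta(path, rna: bool = True) -> list[tuple[str, str]]:
    """(name, sequence) records; T converted to U when ``rna``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        records.append((rec.id, seq))
    if not records:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return records


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_ct(path) -> SecondaryStructure:
    """Standard 6-column CT file; validates pair-table symmetry."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    header = lines[0].split()
    n = int(header[0])
    energy = 0.0
    for tok_i, tok in enumerate(header):
        if tok.lower().startswith("energy") or tok == "=":
            try:
                energy = float(header[tok_i + 1].lstrip("="))
            except (IndexError, ValueError):
                pass
    seq = []
    pt = np.zeros(n, dtype=np.int64)
    for ln in lines[1 : n + 1]:
        f = ln.split()
        idx, base, partner = int(f[0]), f[1], int(f[4])
        seq.append(base.upper().replace("T", "U"))
        pt[idx - 1] = partner
    bad = [
        (i + 1, int(j))
        for i, j in enumerate(pt)
        if j and pt[j - 1] != i + 1
    ]
    if bad:
        raise ValueError(f"{path}: asymmetric pair table at {bad[:5]}")
    return SecondaryStructure("".join(seq), pt, energy=energy)


def write_ct(path, structure: SecondaryStructure, name: str = "structure") -> None:
    n = len(structure)
    pt = structure.pair_table
    with open(path, "w") as fh:
        fh.write(f"{n} ENERGY = {structure.energy:.2f} {name}\n")
        for i in range(n):
            nxt = i + 2 if i + 1 < n else 0
            fh.write(
                f"{i + 1} {structure.sequence[i]} {i} {nxt} {int(pt[i])} {i + 1}\n"
            )


def write_dotbracket(path, structure: SecondaryStructure, name: str = "structure") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{structure.sequence}\n{structure.dotbracket()}\n")


def _check_contiguous(pos: np.ndarray, path) -> None:
    if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
        raise ValueError(f"{path}: positions must be contiguous from 1")


def read_shape(path) -> ReactivityProfile:
    """2-column ``.shape`` (position, reactivity); -999 means no data.

    The format carries no standard errors; they are left undefined (NaN)
    on unmasked positions.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["pos", "val"])
    _check_contiguous(df["pos"].to_numpy(), path)
    vals = df["val"].to_numpy(dtype=float)
    mask = vals <= NO_DATA
    prof = ReactivityProfile(np.where(mask, np.nan, vals), None, mask)
    prof.stderr[:] = np.nan
    prof.stderr[mask] = np.nan
    return prof


def read_map(path) -> ReactivityProfile:
    """4-column ``.map`` (position, reactivity, stderr, nt)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["pos", "val", "err", "nt"]
    )
    _check_contiguous(df["pos"].to_numpy(), path)
    vals = df["val"].to_numpy(dtype=float)
    errs = df["err"].to_numpy(dtype=float)
    mask = vals <= NO_DATA
    return ReactivityProfile(
        np.where(mask, np.nan, vals),
        np.where(mask, np.nan, errs),
        mask,
        sequence="".join(df["nt"].astype(str)),
    )


def write_shape(path, profile: ReactivityProfile) -> None:
    with open(path, "w") as fh:
        for i, (v, m) in enumerate(zip(profile.values, profile.mask), start=1):
            out = NO_DATA if m else v
            fh.write(f"{i}\t{out:.6f}\n")


def write_map(path, profile: ReactivityProfile) -> None:
    seq = profile.sequence or "N" * len(profile)
    with open(path, "w") as fh:
        for i, (v, e, m) in enumerate(
            zip(profile.values, profile.stderr, profile.mask), start=1
        ):
            vv = NO_DATA if m else v
            ee = 0.0 if (m or not np.isfinite(e)) else e
            fh.write(f"{i}\t{vv:.6f}\t{ee:.6f}\t{seq[i - 1]}\n")


def read_counts(path) -> MutationCountTable:
    df = pd.read_csv(path, sep="\t")
    _check_contiguous(df["position"].to_numpy(), path)
    return MutationCountTable(
        df["nt"].to_numpy(dtype="U1"),
        df["events"].to_numpy(dtype=np.int64),
        df["depth"].to_numpy(dtype=np.int64),
    )


def write_counts(path, table: MutationCountTable) -> None:
    pd.DataFrame(
        {
            "position": table.positions,
            "nt": table.nt,
            "events": table.events,
            "depth": table.depth,
        }
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t")
    return RegionSet(
        [
            Region(int(r.start), int(r.end), str(getattr(r, "label", "")))
            for r in df.itertuples()
        ]
    )


def write_regions(path, regions: RegionSet, bed0: bool = False) -> None:
    """1-based inclusive TSV by default; ``bed0`` converts to half-open BED."""
    rows = []
    for r in regions:
        if bed0:
            rows.append({"start": r.start - 1, "end": r.end, "label": r.label})
        else:
            rows.append({"start": r.start, "end": r.end, "label": r.label})
    pd.DataFrame(rows, columns=["start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_pair_probs(
    path, ppm: PairProbabilityMatrix, min_p: float = 1e-4
) -> None:
    """Upper-triangular (i, j, p) TSV of pair probabilities >= ``min_p``."""
    iu, ju = np.nonzero(np.triu(ppm.p, k=1) >= min_p)
    with open(path, "w") as fh:
        fh.write("i\tj\tp\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i + 1}\t{j + 1}\t{ppm.p[i, j]:.6f}\n")


def write_track(path, values, name: str = "value") -> None:
    """(position, value) TSV; NaN written as the -999 sentinel."""
    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"position\t{name}\n")
        for i, v in enumerate(vals, start=1):
            fh.write(f"{i}\t{(NO_DATA if not np.isfinite(v) else v):.6f}\n")
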