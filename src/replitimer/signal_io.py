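"""Probe-level signal containers, feature intervals, and file I/O.

Tiled-array data are represented as per-chromosome arrays of probe
positions (bp, the midpoint of the array feature) and log2 ratios.
Genomic features (known origins, centromeres, hotspots, genes) are
0-based half-open intervals, BED semantics at the file boundary.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeTable",
    "ReplicateSet",
    "FeatureSet",
    "read_probe_table",
    "read_replicates",
    "scale_normalize",
    "average_replicates",
]


def _open_text(path, mode: str = "rt"):
    """Open a path, transparently decompressing ``.gz``."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class ProbeTable:
    """Position-sorted probe signal for one track.

    Parameters
    ----------
    data
        Mapping of chromosome name to ``(positions, values)`` arrays.
        Positions must be strictly increasing integers; values are log2
        ratios (unitless).
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]]):
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, val) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape:
                raise ValueError(f"{chrom}: position/value length mismatch")
            if pos.size and np.any(np.diff(pos) <= 0):
                bad = pos[1:][np.diff(pos) <= 0][0]
                raise ValueError(
                    f"{chrom}: probe positions not strictly increasing at {bad}"
                )
            if np.any(np.isnan(val)):
                raise ValueError(f"{chrom}: NaN values in probe table")
            clean[chrom] = (pos, val)
        self._data = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self._data)

    def positions(self, chrom: str) -> np.ndarray:
        return self._data[chrom][0]

    def values(self, chrom: str) -> np.ndarray:
        return self._data[chrom][1]

    def items(self):
        return self._data.items()

    @property
    def n_probes(self) -> int:
        return sum(p.size for p, _ in self._data.values())

    def with_values(self, new: dict[str, np.ndarray]) -> "ProbeTable":
        """Same grid, new values."""
        return ProbeTable(
            {c: (p.copy(), np.asarray(new[c], float)) for c, (p, _) in self._data.items()}
        )

    def all_values(self) -> np.ndarray:
        if not self._data:
            return np.empty(0)
        return np.concatenate([v for _, v in self._data.values()])

    def same_grid(self, other: "ProbeTable") -> bool:
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self.positions(c), other.positions(c))
            for c in self.chromosomes
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame({"chrom": c, "pos": p, "value": v})
            for c, (p, v) in self._data.items()
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "value"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeTable":
        data = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            data[str(chrom)] = (
                grp["pos"].to_numpy(np.int64),
                grp["value"].to_numpy(float),
            )
        return cls(data)

    def write(self, path) -> None:
        """Write as 4-column bedGraph-style TSV (chrom, start, end, value)."""
        with _open_text(path, "wt") as fh:
            for chrom, (pos, val) in self._data.items():
                for p, v in zip(pos, val):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6f}\n")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeTable):
            return NotImplemented
        return self.same_grid(other) and all(
            np.array_equal(self.values(c), other.values(c)) for c in self.chromosomes
        )


@dataclass
class ReplicateSet:
    """Replicate probe tables for one condition, on an identical grid."""

    condition: str
    replicates: list[ProbeTable] = field(default_factory=list)

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("ReplicateSet needs at least one replicate")
        ref = self.replicates[0]
        for i, rep in enumerate(self.replicates[1:], start=2):
            if rep.chromosomes != ref.chromosomes:
                raise ValueError(
                    f"{self.condition}: replicate {i} chromosome set differs"
                )
            for c in ref.chromosomes:
                a, b = ref.positions(c), rep.positions(c)
                if not np.array_equal(a, b):
                    k = min(a.size, b.size)
                    diff = np.nonzero(a[:k] != b[:k])[0]
                    off = a[diff[0]] if diff.size else a[min(k, a.size - 1)]
                    raise ValueError(
                        f"{self.condition}: replicate {i} grid mismatch on "
                        f"{c} near position {off}"
                    )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def chromosomes(self) -> list[str]:
        return self.replicates[0].chromosomes

    def positions(self, chrom: str) -> np.ndarray:
        return self.replicates[0].positions(chrom)


class FeatureSet:
    """Named genomic intervals (0-based, half-open), sorted per chromosome.

    Backed by a DataFrame with columns ``chrom, start, end`` and optional
    ``name``, ``score`` and ``anchor`` (a point position, e.g. an origin's
    ARS consensus sequence).
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"FeatureSet missing column {col!r}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("FeatureSet interval with start >= end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def midpoints(self) -> np.ndarray:
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy(np.int64)

    @classmethod
    def from_records(cls, records, columns=("chrom", "start", "end", "name")):
        return cls(pd.DataFrame.from_records(list(records), columns=list(columns)))

    @classmethod
    def read_bed(cls, path) -> "FeatureSet":
        names = ["chrom", "start", "end", "name", "score", "strand"]
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep="\t", header=None, comment="#")
        df = df.iloc[:, :6]
        df.columns = names[: df.shape[1]]
        return cls(df)

    def write_bed(self, path) -> None:
        with _open_text(path, "wt") as fh:
            cols = [c for c in ("chrom", "start", "end", "name", "score") if c in self.df]
            self.df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_probe_table(path, *, grid_check: ProbeTable | None = None,
                     chromosomes: list[str] | None = None) -> ProbeTable:
    """Read a probe table from TSV/bedGraph (chrom, start, end, value).

    Probe position is the interval midpoint.  Rows with NaN values are
    dropped and counted in the log.  With ``grid_check`` the loaded grid
    must match the given table's; with ``chromosomes`` unknown chromosome
    names raise.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
    n_nan = int(df["value"].isna().sum())
    if n_nan:
        logger.info("read_probe_table(%s): dropped %d NaN probes", path, n_nan)
        df = df.dropna(subset=["value"])
    if chromosomes is not None:
        unknown = sorted(set(df["chrom"]) - set(chromosomes))
        if unknown:
            raise ValueError(f"unknown chromosomes in {path}: {', '.join(unknown)}")
    df["pos"] = (df["start"] + df["end"]) // 2
    data = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if np.any(np.diff(pos) <= 0):
            bad = pos[1:][np.diff(pos) <= 0][0]
            raise ValueError(f"{path}: unsorted or duplicate position {bad} on {chrom}")
        data[str(chrom)] = (pos, grp["value"].to_numpy(float))
    table = ProbeTable(data)
    if grid_check is not None and not table.same_grid(grid_check):
        for c in grid_check.chromosomes:
            if c not in table._data:
                raise ValueError(f"{path}: grid mismatch, chromosome {c} missing")
            a, b = grid_check.positions(c), table.positions(c)
            k = min(a.size, b.size)
            bad = np.nonzero(a[:k] != b[:k])[0]
            off = a[bad[0]] if bad.size else a[min(k, a.size - 1)]
            raise ValueError(f"{path}: grid mismatch on {c} near position {off}")
    return table


def read_replicates(paths, condition: str) -> ReplicateSet:
    """Read several probe tables that must share one grid."""
    tables = []
    first = None
    for p in paths:
        t = read_probe_table(p, grid_check=first)
        first = first or t
        tables.append(t)
    return ReplicateSet(condition, tables)


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation (unscaled)."""
    return float(np.median(np.abs(x - np.median(x))))


def scale_normalize(reps: ReplicateSet) -> ReplicateSet:
    """Scale-normalize replicates: recentre each to median 0, then rescale
    so every replicate's MAD equals the geometric mean of replicate MADs.

    Robust analogue of across-replicate scale normalization for two-channel
    log ratios; order within each replicate is preserved.  Raises on a
    degenerate replicate (MAD = 0).
    """
    if reps.n_replicates < 2:
        raise ValueError("scale_normalize requires at least 2 replicates")
    centred = []
    mads = []
    for i, rep in enumerate(reps.replicates, start=1):
        vals = {c: rep.values(c) - np.median(rep.all_values()) for c in rep.chromosomes}
        flat = np.concatenate([vals[c] for c in rep.chromosomes])
        m = _mad(flat)
        if m == 0:
            raise ValueError(f"{reps.condition}: replicate {i} has MAD 0 (degenerate signal)")
        centred.append(vals)
        mads.append(m)
    target = float(np.exp(np.mean(np.log(mads))))
    out = []
    for rep, vals, m in zip(reps.replicates, centred, mads):
        out.append(rep.with_values({c: v * (target / m) for c, v in vals.items()}))
    return ReplicateSet(reps.condition, out)


def average_replicates(reps: ReplicateSet) -> ProbeTable:
    """Probewise mean across replicates."""
    ref = reps.replicates[0]
    return ref.with_values({
        c: np.mean([r.values(c) for r in reps.replicates], axis=0)
        for c in ref.chromosomes
    })
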