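"""Genomic bin schemes and target-region panels.

All coordinates are 0-based, half-open (BED convention).  A
:class:`BinScheme` is an ordered set of non-overlapping intervals per
chromosome with an inclusion mask (blacklist-style exclusion); fragment
membership is decided by the fragment's 5' start position.  On the human
genome the canonical widths are 1 Mb for methylation/copy-number bins and
5 Mb for fragment bins; on the miniature simulator genome the same logic
runs at proportionally scaled widths (default ``bin_scale = 1/50``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: scale factor mapping human bin widths onto the miniature genome
DEFAULT_BIN_SCALE = 1.0 / 50.0
MB = 1_000_000


@dataclass
class BinScheme:
    """Ordered, non-overlapping genomic intervals with an exclusion mask."""

    frame: pd.DataFrame  # columns: chrom, start, end, bin_id, included

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "bin_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"bin frame missing columns: {sorted(missing)}")
        if "included" not in self.frame.columns:
            self.frame = self.frame.assign(included=True)
        self.frame = self.frame.reset_index(drop=True)
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
            if not (np.diff(starts) > 0).all() or (starts[1:] < ends[:-1]).any():
                raise ValueError(f"bins on {chrom} must be sorted and non-overlapping")

    @classmethod
    def tile(cls, chrom_lengths: dict[str, int], width: int,
             exclude: set[str] | None = None) -> "BinScheme":
        """Tile chromosomes with fixed-width bins (last partial bin kept)."""
        rows = []
        for chrom, length in chrom_lengths.items():
            for start in range(0, length, width):
                end = min(start + width, length)
                rows.append((chrom, start, end, f"{chrom}:{start}-{end}"))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])
        if exclude:
            frame["included"] = ~frame["bin_id"].isin(exclude)
        return cls(frame)

    @classmethod
    def from_reference(cls, reference, width: int) -> "BinScheme":
        return cls.tile(dict(zip(reference.chrom_names, reference.chrom_lengths)), width)

    @classmethod
    def from_bed(cls, path) -> "BinScheme":
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "bin_id"],
            usecols=[0, 1, 2, 3], dtype={"chrom": str},
        )
        return cls(frame)

    def to_bed(self, path, included_only: bool = False) -> None:
        frame = self.included_frame() if included_only else self.frame
        frame[["chrom", "start", "end", "bin_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def included_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["included"]].reset_index(drop=True)

    @property
    def bin_ids(self) -> list[str]:
        """Identifiers of included bins, scheme order."""
        return self.included_frame()["bin_id"].tolist()

    def __len__(self) -> int:
        return int(self.frame["included"].sum())

    def assign(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Row index in :meth:`included_frame` per position, -1 if outside."""
        inc = self.included_frame()
        out = np.full(len(positions), -1, dtype=np.int64)
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom, sub in inc.groupby("chrom", sort=False):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            rows = sub.index.to_numpy()
            pos = positions[mask]
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
            res = np.where(ok, rows[np.clip(j, 0, len(rows) - 1)], -1)
            out[mask] = res
        return out

    def gc_fraction(self, reference) -> np.ndarray:
        """GC fraction of each included bin from a :class:`MiniReference`."""
        inc = self.included_frame()
        gc = np.empty(len(inc))
        for i, row in inc.iterrows():
            codes = reference.codes(reference.chrom_index(row["chrom"]))
            window = codes[row["start"] : row["end"]]
            valid = window >= 0
            gc[i] = ((window == 1) | (window == 2))[valid].mean() if valid.any() else np.nan
        return gc


@dataclass
class TargetRegions:
    """A capture panel of target regions with baseline methylation levels.

    ``frame`` columns: chrom, start, end, region_id, baseline (healthy
    methylation ratio in [0, 1]).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        base = self.frame["baseline"]
        if ((base < 0) | (base > 1)).any():
            raise ValueError("baseline methylation ratios must be in [0, 1]")

    @property
    def region_ids(self) -> list[str]:
        return self.frame["region_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def default_panel(cls, reference, n_regions: int = 450, width: int = 1_000,
                      seed: int = 20_190_501) -> "TargetRegions":
        """Evenly spaced panel with seeded baselines in [0.15, 0.55].

        The baseline draw is part of the panel definition (shared by every
        simulated sample), not of per-sample noise, so its seed is a fixed
        panel property.
        """
        rng = np.random.default_rng(seed)
        rows = []
        total = sum(reference.chrom_lengths)
        per_chrom = [
            max(1, round(n_regions * ln / total)) for ln in reference.chrom_lengths
        ]
        # adjust rounding drift on the last chromosome
        per_chrom[-1] += n_regions - sum(per_chrom)
        k = 0
        for chrom, length, n_c in zip(
            reference.chrom_names, reference.chrom_lengths, per_chrom
        ):
            spacing = length // n_c
            for i in range(n_c):
                start = i * spacing
                end = min(start + width, length)
                rows.append((chrom, start, end, f"region_{k:04d}"))
                k += 1
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
        frame["baseline"] = rng.uniform(0.15, 0.55, size=len(frame))
        return cls(frame)

    def to_bed(self, path) -> None:
        cols = self.frame[["chrom", "start", "end", "region_id", "baseline"]]
        cols.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "TargetRegions":
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "region_id", "baseline"],
            dtype={"chrom": str},
        )
        return cls(frame)


def default_bin_schemes(reference, bin_scale: float = DEFAULT_BIN_SCALE):
    """(methylation/copy-number scheme, fragment scheme) at scaled widths."""
    small = max(1, int(round(1 * MB * bin_scale)))
    large = max(1, int(round(5 * MB * bin_scale)))
    return (
        BinScheme.from_reference(reference, small),
        BinScheme.from_reference(reference, large),
    )
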