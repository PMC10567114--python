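"""Readers and writers for the package's on-disk formats.

Fragment tables, methylation count tables, label tables and feature
matrices are plain tab-delimited text (gzip accepted on input by file
suffix); bin schemes and target panels are BED; cohort manifests are YAML.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path

import pandas as pd
import yaml

from cfmosaic.bins import BinScheme, TargetRegions
from cfmosaic.features import FragmentRecord
from cfmosaic.reference import MiniReference
from cfmosaic.simulate import bin_baselines

FRAGMENT_COLUMNS = ["sample_id", "chrom", "start", "length"]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> pd.DataFrame:
    """Read a fragment TSV, validating each line.

    Columns: sample_id, chrom, start (0-based), length.  A header line is
    optional.  Malformed lines raise with their line number; an empty file
    yields an empty table with a warning.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts == FRAGMENT_COLUMNS:
                continue
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            sid, chrom, start_s, length_s = parts
            try:
                start, length = int(start_s), int(length_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: start and length must be integers"
                ) from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate {start}")
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length {length}")
            rows.append((sid, chrom, start, length))
    if not rows:
        warnings.warn(f"{path}: no fragment records found")
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_fragments(fragments, path) -> None:
    """Write a fragment table (DataFrame or iterable of records) as TSV."""
    if not isinstance(fragments, pd.DataFrame):
        fragments = pd.DataFrame(
            [FragmentRecord(*f) for f in fragments], columns=FRAGMENT_COLUMNS
        )
    with _open_text(path, "wt") as fh:
        fragments.to_csv(fh, sep="\t", index=False)


def read_methylation(path) -> pd.DataFrame:
    """Read a methylation count table (sample_id, interval_id, counts)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "interval_id", "methylated", "unmethylated"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (frame[["methylated", "unmethylated"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return frame


def read_labels(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns or "class_label" not in frame.columns:
        raise ValueError(f"{path}: label table needs sample_id and class_label columns")
    return frame


def load_cohort(cohort_dir) -> dict:
    """Load a simulated cohort directory back into the in-memory bundle form."""
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    paths = manifest["paths"]
    reference = MiniReference.from_fasta(cohort_dir / paths["reference_fasta"])
    meth_bins = BinScheme.from_bed(cohort_dir / paths["meth_bins_bed"])
    frag_bins = BinScheme.from_bed(cohort_dir / paths["frag_bins_bed"])
    panel = TargetRegions.from_bed(cohort_dir / paths["target_regions_bed"])
    return {
        "manifest": manifest,
        "reference": reference,
        "meth_bins": meth_bins,
        "frag_bins": frag_bins,
        "panel": panel,
        "bin_baselines": bin_baselines(meth_bins),
        "labels": read_labels(cohort_dir / paths["labels_tsv"]),
        "fragments": read_fragments(cohort_dir / paths["fragments_tsv"]),
        "target_methylation": read_methylation(
            cohort_dir / paths["target_methylation_tsv"]
        ),
        "bin_methylation": read_methylation(cohort_dir / paths["bin_methylation_tsv"]),
    }
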