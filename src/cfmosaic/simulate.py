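"""Seeded synthetic cfDNA cohort simulation.

Fragments are generated at the level the downstream feature extractors
consume: (chromosome, 0-based 5' start of the forward read, length).
Lengths are drawn from the class's tumor-fraction-weighted length mixture;
starts are drawn by first sampling a 4-mer end motif from the class motif
distribution and then a uniformly random indexed reference position of that
motif, optionally re-weighted by the class's copy-number segments.
Methylation counts are binomial draws around tumor-fraction-scaled shifts
of the interval baselines.  Every output is a pure function of the design
and the master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cfmosaic.bins import BinScheme, TargetRegions, default_bin_schemes
from cfmosaic.profiles import (
    CLASS_LABELS,
    LENGTHS,
    ClassProfile,
    default_profiles,
)
from cfmosaic.reference import ALL_MOTIFS, MiniReference, build_reference

#: seeded per-bin baseline methylation range for genome-wide bins
GWM_BASELINE_RANGE = (0.60, 0.80)
#: standard deviation of per-bin biological noise on genome-wide shifts
GWM_BIN_NOISE_SD = 0.01


def bin_baselines(scheme: BinScheme, seed: int = 20_190_502) -> pd.Series:
    """Deterministic healthy methylation baseline per included bin."""
    rng = np.random.default_rng(seed)
    ids = scheme.bin_ids
    lo, hi = GWM_BASELINE_RANGE
    return pd.Series(rng.uniform(lo, hi, size=len(ids)), index=ids)


def simulate_fragments(
    profile: ClassProfile,
    reference: MiniReference,
    n: int,
    seed: int,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Draw ``n`` fragments for one sample.

    Returns a fragment table with columns ``sample_id, chrom, start,
    length``; starts index the reference position whose 4-mer equals the
    sampled end motif, and per-segment copy-number weights are applied by
    rejection sampling so expected per-bin counts scale with
    ``2**log2_ratio``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    lengths = rng.choice(LENGTHS, size=n, p=profile.flen_mixture)

    weights = _position_weights(profile, reference)
    chrom_idx = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        todo = n - filled
        motifs = rng.choice(256, size=todo, p=profile.motif_dist)
        c, s = _sample_positions(motifs, reference, rng)
        if weights is not None:
            keep = rng.random(todo) < weights[c, s]
            c, s = c[keep], s[keep]
        take = min(len(c), todo)
        chrom_idx[filled : filled + take] = c[:take]
        starts[filled : filled + take] = s[:take]
        filled += take

    chrom_names = np.array(reference.chrom_names)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom_names[chrom_idx],
            "start": starts,
            "length": lengths,
        }
    )


def _sample_positions(motifs: np.ndarray, reference: MiniReference, rng):
    """Uniformly sample an indexed (chrom, pos) for each requested motif."""
    chrom = np.empty(motifs.size, dtype=np.int64)
    pos = np.empty(motifs.size, dtype=np.int64)
    for m in np.unique(motifs):
        table = reference.motif_positions[m]
        if table.size == 0:
            raise ValueError(f"motif {ALL_MOTIFS[m]} has no indexed reference position")
        sel = motifs == m
        rows = rng.integers(0, len(table), size=int(sel.sum()))
        chrom[sel] = table[rows, 0]
        pos[sel] = table[rows, 1]
    return chrom, pos


def _position_weights(profile: ClassProfile, reference: MiniReference):
    """Per-base acceptance weights in [0, 1] encoding copy-number segments."""
    if not profile.cna_segments:
        return None
    ratios = np.array([2.0 ** seg[3] for seg in profile.cna_segments])
    w_max = max(1.0, ratios.max())
    weights = np.full(
        (len(reference.chrom_names), max(reference.chrom_lengths)), 1.0 / w_max
    )
    for (chrom, start, end, log2r) in profile.cna_segments:
        ci = reference.chrom_index(chrom)
        weights[ci, start:end] = (2.0 ** log2r) / w_max
    return weights


def simulate_methylation(
    profile: ClassProfile,
    intervals,
    depth: int,
    seed: int,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Binomial methylated/unmethylated counts for one sample.

    ``intervals`` is either a :class:`TargetRegions` panel (per-region
    ``dmr_effects`` apply) or a ``(BinScheme, baselines)`` pair for
    genome-wide bins (``gwm_shift`` plus per-bin noise applies).  The
    success probability of each interval is
    ``clip(baseline + tumor_fraction * shift, 0, 1)``.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    if isinstance(intervals, TargetRegions):
        ids = intervals.region_ids
        baselines = intervals.frame["baseline"].to_numpy()
        shifts = np.asarray(profile.dmr_effects, dtype=float)
        if shifts.size != len(ids):
            raise ValueError(
                f"profile has {shifts.size} region effects but panel has {len(ids)}"
            )
    else:
        scheme, base = intervals
        ids = scheme.bin_ids
        baselines = base.loc[ids].to_numpy()
        noise = rng.normal(0.0, GWM_BIN_NOISE_SD, size=len(ids))
        shifts = profile.gwm_shift + noise
    p = np.clip(baselines + profile.tumor_fraction * shifts, 0.0, 1.0)
    meth = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "interval_id": ids,
            "methylated": meth,
            "unmethylated": depth - meth,
        }
    )


@dataclass
class CohortDesign:
    """Sizes, depths and seeding of a synthetic cohort."""

    class_counts: dict[str, int]
    fragments_per_sample: int = 50_000
    target_depth: int = 2_000
    bin_depth: int = 1_000
    master_seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    bin_scale: float = 1.0 / 50.0
    profiles: dict[str, ClassProfile] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for label, count in self.class_counts.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if count <= 0 or int(count) != count:
                raise ValueError(f"sample count for {label!r} must be a positive integer")
        for name in ("fragments_per_sample", "target_depth", "bin_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic stream of per-sample seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)])


def simulate_cohort_frames(design: CohortDesign):
    """Simulate a cohort fully in memory.

    Returns a dict with the reference, bin schemes, target panel, label
    table, concatenated fragment table and the two methylation tables.
    """
    reference = build_reference(
        design.master_seed, design.n_chrom, design.chrom_length
    )
    meth_bins, frag_bins = default_bin_schemes(reference, design.bin_scale)
    panel = TargetRegions.default_panel(reference)
    baselines = bin_baselines(meth_bins)
    profiles = design.profiles or default_profiles()

    labels = []
    for label in CLASS_LABELS:
        count = design.class_counts.get(label, 0)
        labels += [(f"{label}_{i:03d}", label) for i in range(count)]
    label_frame = pd.DataFrame(labels, columns=["sample_id", "class_label"])
    seeds = _derive_seeds(design.master_seed, 3 * len(label_frame))

    fragments, target_tables, bin_tables = [], [], []
    for i, (sid, label) in enumerate(label_frame.itertuples(index=False)):
        prof = profiles[label]
        fragments.append(
            simulate_fragments(
                prof, reference, design.fragments_per_sample, int(seeds[3 * i]), sid
            )
        )
        target_tables.append(
            simulate_methylation(prof, panel, design.target_depth, int(seeds[3 * i + 1]), sid)
        )
        bin_tables.append(
            simulate_methylation(
                prof, (meth_bins, baselines), design.bin_depth, int(seeds[3 * i + 2]), sid
            )
        )
    label_frame["seed_fragments"] = seeds[0::3][: len(label_frame)]
    label_frame["seed_targets"] = seeds[1::3][: len(label_frame)]
    label_frame["seed_bins"] = seeds[2::3][: len(label_frame)]
    return {
        "reference": reference,
        "meth_bins": meth_bins,
        "frag_bins": frag_bins,
        "panel": panel,
        "bin_baselines": baselines,
        "labels": label_frame,
        "fragments": pd.concat(fragments, ignore_index=True),
        "target_methylation": pd.concat(target_tables, ignore_index=True),
        "bin_methylation": pd.concat(bin_tables, ignore_index=True),
    }


def simulate_cohort(design: CohortDesign, out_dir) -> Path:
    """Simulate a cohort and write it to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_cohort_frames(design)

    paths = {
        "reference_fasta": "reference.fa",
        "meth_bins_bed": "meth_bins.bed",
        "frag_bins_bed": "frag_bins.bed",
        "target_regions_bed": "target_regions.bed",
        "fragments_tsv": "fragments.tsv",  # uncompressed so outputs are byte-reproducible
        "target_methylation_tsv": "target_methylation.tsv",
        "bin_methylation_tsv": "bin_methylation.tsv",
        "labels_tsv": "labels.tsv",
    }
    bundle["reference"].to_fasta(out / paths["reference_fasta"])
    bundle["meth_bins"].to_bed(out / paths["meth_bins_bed"])
    bundle["frag_bins"].to_bed(out / paths["frag_bins_bed"])
    bundle["panel"].to_bed(out / paths["target_regions_bed"])
    bundle["fragments"].to_csv(out / paths["fragments_tsv"], sep="\t", index=False)
    bundle["target_methylation"].to_csv(
        out / paths["target_methylation_tsv"], sep="\t", index=False
    )
    bundle["bin_methylation"].to_csv(
        out / paths["bin_methylation_tsv"], sep="\t", index=False
    )
    bundle["labels"].to_csv(out / paths["labels_tsv"], sep="\t", index=False)

    manifest = {
        "master_seed": design.master_seed,
        "class_counts": {k: int(v) for k, v in design.class_counts.items()},
        "fragments_per_sample": design.fragments_per_sample,
        "target_depth": design.target_depth,
        "bin_depth": design.bin_depth,
        "bin_scale": design.bin_scale,
        "paths": paths,
        "samples": [
            {
                "sample_id": row.sample_id,
                "class_label": row.class_label,
                "seed_fragments": int(row.seed_fragments),
                "seed_targets": int(row.seed_targets),
                "seed_bins": int(row.seed_bins),
            }
            for row in bundle["labels"].itertuples(index=False)
        ],
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def cohort_checksum(out_dir) -> dict[str, str]:
    """MD5 of every cohort file, for reproducibility checks."""
    out = Path(out_dir)
    sums = {}
    for path in sorted(out.iterdir()):
        if path.is_file():
            sums[path.name] = hashlib.md5(path.read_bytes()).hexdigest()
    return sums
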