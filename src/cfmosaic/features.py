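"""Per-sample cfDNA feature extraction.

Nine feature groups are produced per sample:

========  ==========================================================
TM        methylation ratio at each of the 450 target regions
GWM       methylation ratio per genome-wide bin
CNA       log2 copy ratio per bin (GC-corrected, median-normalized,
          outlier-smoothed read counts)
FLEN      fragment-length frequency (%) for lengths 100-250 bp (151)
SHORT     fragments <=150 bp per fragment bin
LONG      fragments 151-250 bp per fragment bin
TOTAL     SHORT + LONG per fragment bin
RATIO     SHORT / LONG per fragment bin
EM        frequency of the 256 4-mer reference motifs at fragment
          5' ends
========  ==========================================================

SHORT/LONG/TOTAL are z-score normalized downstream with statistics fitted
on training samples only; RATIO, FLEN, EM, TM, GWM and CNA enter models on
their natural scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from cfmosaic.bins import BinScheme, TargetRegions
from cfmosaic.profiles import LENGTHS, MAX_LEN, MIN_LEN, SHORT_MAX
from cfmosaic.reference import ALL_MOTIFS, MiniReference, motif_codes

FEATURE_GROUPS = ["TM", "GWM", "CNA", "FLEN", "SHORT", "LONG", "TOTAL", "RATIO", "EM"]
#: groups that are z-scored with training-cohort statistics
ZSCORED_GROUPS = ["SHORT", "LONG", "TOTAL"]


class FragmentRecord(NamedTuple):
    """One sequenced cfDNA fragment."""

    sample_id: str
    chrom: str
    start: int
    length: int


def as_fragment_frame(fragments) -> pd.DataFrame:
    """Accept a fragment DataFrame or an iterable of records."""
    if isinstance(fragments, pd.DataFrame):
        return fragments
    return pd.DataFrame(list(fragments), columns=["sample_id", "chrom", "start", "length"])


def in_range(frame: pd.DataFrame) -> pd.DataFrame:
    """Fragments retained for analysis: 100 <= length <= 250."""
    ln = frame["length"]
    return frame[(ln >= MIN_LEN) & (ln <= MAX_LEN)]


def methylation_ratio(methylated, unmethylated):
    """Methylated / (methylated + unmethylated); NaN where both are zero.

    Accepts scalars or arrays.  A zero-coverage interval is a missing
    value, not a zero ratio.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("counts must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if np.ndim(methylated) == 0 and np.ndim(unmethylated) == 0:
        return float(ratio) if total > 0 else float("nan")
    return ratio


def _ratio_series(table: pd.DataFrame, ids: list[str], what: str) -> pd.Series:
    sub = table.set_index("interval_id")
    missing = [i for i in ids if i not in sub.index]
    if missing:
        raise KeyError(f"{what} missing from methylation table: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    sub = sub.loc[ids]
    vals = methylation_ratio(sub["methylated"].to_numpy(), sub["unmethylated"].to_numpy())
    return pd.Series(vals, index=ids)


def extract_tm(table: pd.DataFrame, regions: TargetRegions) -> pd.Series:
    """Methylation ratio per target region, panel order."""
    return _ratio_series(table, regions.region_ids, "regions")


def extract_gwm(table: pd.DataFrame, bins: BinScheme) -> pd.Series:
    """Methylation ratio per included genome-wide bin."""
    return _ratio_series(table, bins.bin_ids, "bins")


def extract_cna(
    fragments,
    bins: BinScheme,
    gc: np.ndarray,
    lowess_frac: float = 0.65,
    mad_multiplier: float = 4.0,
) -> pd.Series:
    """Log2 copy ratio per bin from binned fragment counts.

    Pipeline: count fragment 5' starts per included bin; divide by the
    LOESS trend of count against bin GC fraction; scale by the sample
    median of corrected counts; winsorize beyond median +/- 4 MAD; log2.
    """
    frame = in_range(as_fragment_frame(fragments))
    idx = bins.assign(frame["chrom"].to_numpy(), frame["start"].to_numpy())
    counts = np.bincount(idx[idx >= 0], minlength=len(bins)).astype(float)
    if counts.sum() == 0:
        raise ValueError("no fragments fall in any included bin")
    gc = np.asarray(gc, dtype=float)
    if gc.shape != counts.shape:
        raise ValueError("gc must have one entry per included bin")
    if np.ptp(gc) < 1e-12:  # constant GC: nothing to correct
        trend = np.full_like(counts, counts.mean())
    else:
        trend = lowess(counts, gc, frac=lowess_frac, return_sorted=False)
    trend = np.clip(trend, np.finfo(float).tiny, None)
    corrected = counts / trend
    med = np.median(corrected)
    if med <= 0:
        raise ValueError("median corrected count is zero; coverage too sparse")
    norm = corrected / med
    center = np.median(norm)
    mad = np.median(np.abs(norm - center))
    if mad > 0:
        lo, hi = center - mad_multiplier * mad, center + mad_multiplier * mad
        norm = np.clip(norm, max(lo, 0.0), hi)
    norm = np.clip(norm, 2.0 ** -10, None)  # floor empty bins before log2
    return pd.Series(np.log2(norm), index=bins.bin_ids)


def extract_flen(fragments) -> pd.Series:
    """Fragment-length frequency (%) over 100-250 bp; sums to 100."""
    frame = in_range(as_fragment_frame(fragments))
    if len(frame) == 0:
        raise ValueError("no fragments with length in [100, 250]")
    counts = np.bincount(frame["length"].to_numpy() - MIN_LEN, minlength=len(LENGTHS))
    freq = 100.0 * counts / counts.sum()
    return pd.Series(freq, index=[f"len_{l}" for l in LENGTHS])


def extract_fragment_bin_features(fragments, bins: BinScheme) -> pd.DataFrame:
    """Per-bin short (<=150 bp), long (151-250 bp), total counts and ratio.

    ``ratio`` is NaN (missing, to be imputed downstream) where a bin has no
    long fragments.
    """
    frame = in_range(as_fragment_frame(fragments))
    idx = bins.assign(frame["chrom"].to_numpy(), frame["start"].to_numpy())
    keep = idx >= 0
    idx = idx[keep]
    short_flag = (frame["length"].to_numpy() <= SHORT_MAX)[keep]
    n_bins = len(bins)
    short = np.bincount(idx[short_flag], minlength=n_bins)
    long_ = np.bincount(idx[~short_flag], minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(long_ > 0, short / np.where(long_ > 0, long_, 1), np.nan)
    return pd.DataFrame(
        {"short": short, "long": long_, "total": short + long_, "ratio": ratio},
        index=bins.bin_ids,
    )


def extract_em(fragments, reference: MiniReference) -> pd.Series:
    """Frequency of the 256 4-mer end motifs, lexicographic order; sums to 1.

    The motif is the reference 4-mer on the forward strand starting at the
    fragment's 5' start.  Fragments whose 4-mer window contains a non-ACGT
    base (or runs past the chromosome end) are excluded from both numerator
    and denominator.
    """
    frame = as_fragment_frame(fragments)
    counts = np.zeros(256, dtype=np.int64)
    for chrom, sub in frame.groupby("chrom", sort=False):
        ci = reference.chrom_index(chrom)  # raises KeyError if absent
        codes = motif_codes(reference.codes(ci))
        starts = sub["start"].to_numpy()
        if (starts < 0).any():
            raise ValueError(f"negative fragment start on {chrom}")
        valid = starts < codes.size
        mc = codes[starts[valid]]
        mc = mc[mc >= 0]
        counts += np.bincount(mc, minlength=256)
    total = counts.sum()
    if total == 0:
        raise ValueError("no fragments with an unambiguous 4-mer window")
    return pd.Series(counts / total, index=ALL_MOTIFS)


@dataclass
class NormalizationModel:
    """Per-feature mean/SD fitted on training samples."""

    mean: pd.Series
    sd: pd.Series
    flagged: list[str] = field(default_factory=list)


def fit_normalization(matrix: pd.DataFrame, training_mask=None) -> NormalizationModel:
    """Fit z-score statistics on training rows only.

    Zero-variance features get SD 1 and are flagged so they transform to
    exactly zero.
    """
    if training_mask is None:
        training_mask = np.ones(len(matrix), dtype=bool)
    train = matrix.loc[np.asarray(training_mask)]
    if len(train) < 2:
        raise ValueError("need at least 2 training samples to fit normalization")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    flagged = sd.index[sd == 0].tolist()
    sd = sd.mask(sd == 0, 1.0)
    return NormalizationModel(mean=mean, sd=sd, flagged=flagged)


def apply_normalization(model: NormalizationModel, matrix: pd.DataFrame) -> pd.DataFrame:
    return (matrix - model.mean) / model.sd


@dataclass
class MultiFeatureSet:
    """Sample-by-feature matrices for the nine feature groups.

    ``matrices`` maps group name to a samples x features DataFrame whose
    rows are aligned across groups.  ``zscored`` records which groups have
    been z-score normalized; ``normalization`` holds the fitted statistics.
    """

    matrices: dict[str, pd.DataFrame]
    zscored: list[str] = field(default_factory=list)
    normalization: dict[str, NormalizationModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in FEATURE_GROUPS if g not in self.matrices]
        if missing:
            raise ValueError(f"feature groups missing: {missing}")
        index = self.matrices[FEATURE_GROUPS[0]].index
        for g in FEATURE_GROUPS:
            if not self.matrices[g].index.equals(index):
                raise ValueError(f"sample index of group {g} is misaligned")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[FEATURE_GROUPS[0]].index.tolist()

    def subset(self, sample_ids) -> "MultiFeatureSet":
        return MultiFeatureSet(
            {g: m.loc[sample_ids] for g, m in self.matrices.items()},
            zscored=list(self.zscored),
            normalization=dict(self.normalization),
        )

    def concatenated(self) -> pd.DataFrame:
        """Single frame of all groups with ``GROUP:feature`` column names."""
        parts = [
            self.matrices[g].rename(columns=lambda c, g=g: f"{g}:{c}")
            for g in FEATURE_GROUPS
        ]
        return pd.concat(parts, axis=1)

    def normalize(self, training_mask=None) -> "MultiFeatureSet":
        """Z-score SHORT/LONG/TOTAL on training statistics; impute NaNs.

        Missing values (zero-coverage ratios, empty-bin RATIO entries) are
        imputed with the training-cohort feature median.
        """
        out: dict[str, pd.DataFrame] = {}
        models: dict[str, NormalizationModel] = {}
        mask = (
            np.ones(len(self.sample_ids), dtype=bool)
            if training_mask is None
            else np.asarray(training_mask)
        )
        for g in FEATURE_GROUPS:
            mat = self.matrices[g]
            med = mat.loc[mask].median(axis=0)
            mat = mat.fillna(med.fillna(0.0))
            if g in ZSCORED_GROUPS:
                model = fit_normalization(mat, mask)
                models[g] = model
                mat = apply_normalization(model, mat)
            out[g] = mat
        return MultiFeatureSet(out, zscored=list(ZSCORED_GROUPS), normalization=models)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for g, mat in self.matrices.items():
            mat.to_csv(path / f"{g}.tsv", sep="\t", index_label="sample_id")
        meta = {
            "groups": FEATURE_GROUPS,
            "zscored": self.zscored,
            "n_samples": len(self.sample_ids),
            "n_features": {g: int(self.matrices[g].shape[1]) for g in FEATURE_GROUPS},
        }
        (path / "feature_groups.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path) -> "MultiFeatureSet":
        path = Path(path)
        meta = json.loads((path / "feature_groups.json").read_text())
        matrices = {
            g: pd.read_csv(path / f"{g}.tsv", sep="\t", index_col="sample_id")
            for g in meta["groups"]
        }
        return cls(matrices, zscored=meta.get("zscored", []))


def assemble_feature_set(per_group: dict[str, pd.DataFrame]) -> MultiFeatureSet:
    """Bundle per-group matrices, requiring all nine groups."""
    missing = [g for g in FEATURE_GROUPS if g not in per_group]
    if missing:
        raise ValueError(f"feature groups missing: {missing}")
    return MultiFeatureSet({g: per_group[g] for g in FEATURE_GROUPS})


def extract_sample_features(
    fragments,
    target_table: pd.DataFrame,
    bin_table: pd.DataFrame,
    panel: TargetRegions,
    meth_bins: BinScheme,
    frag_bins: BinScheme,
    reference: MiniReference,
    gc: np.ndarray | None = None,
) -> dict[str, pd.Series]:
    """All nine raw feature vectors for one sample."""
    if gc is None:
        gc = meth_bins.gc_fraction(reference)
    frag_frame = as_fragment_frame(fragments)
    bin_feats = extract_fragment_bin_features(frag_frame, frag_bins)
    return {
        "TM": extract_tm(target_table, panel),
        "GWM": extract_gwm(bin_table, meth_bins),
        "CNA": extract_cna(frag_frame, meth_bins, gc),
        "FLEN": extract_flen(frag_frame),
        "SHORT": bin_feats["short"].astype(float),
        "LONG": bin_feats["long"].astype(float),
        "TOTAL": bin_feats["total"].astype(float),
        "RATIO": bin_feats["ratio"],
        "EM": extract_em(frag_frame, reference),
    }


def extract_cohort_features(bundle: dict, progress: bool = False) -> MultiFeatureSet:
    """Extract the nine feature groups for every sample of a cohort bundle.

    ``bundle`` is the in-memory dict produced by
    :func:`cfmosaic.simulate.simulate_cohort_frames` (or loaded from disk by
    :func:`cfmosaic.io.load_cohort`).
    """
    reference = bundle["reference"]
    meth_bins, frag_bins = bundle["meth_bins"], bundle["frag_bins"]
    panel = bundle["panel"]
    gc = meth_bins.gc_fraction(reference)
    frag_groups = dict(tuple(bundle["fragments"].groupby("sample_id", sort=False)))
    target_groups = dict(tuple(bundle["target_methylation"].groupby("sample_id", sort=False)))
    bin_groups = dict(tuple(bundle["bin_methylation"].groupby("sample_id", sort=False)))

    rows: dict[str, list[pd.Series]] = {g: [] for g in FEATURE_GROUPS}
    sample_ids = bundle["labels"]["sample_id"].tolist()
    for sid in sample_ids:
        feats = extract_sample_features(
            frag_groups[sid], target_groups[sid], bin_groups[sid],
            panel, meth_bins, frag_bins, reference, gc=gc,
        )
        for g in FEATURE_GROUPS:
            rows[g].append(feats[g].rename(sid))
    matrices = {g: pd.DataFrame(rows[g]) for g in FEATURE_GROUPS}
    return assemble_feature_set(matrices)
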