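"""Class profiles: the generative parameters of the synthetic cfDNA cohort.

Each cohort class (healthy plus five cancer types: breast, colorectal,
gastric, liver, lung) is described by a :class:`ClassProfile` holding

* a fragment-length mixture: plasma cfDNA of healthy donors peaks sharply
  at 167 bp (mononucleosome plus linker); tumor-derived DNA is shorter.
  The defaults are discretized Gaussian mixtures over 100-250 bp whose
  short-fragment mass (<=150 bp) is calibrated so the expected short/long
  count ratio is 0.27 for healthy cohorts and 0.29 for cancer cohorts;
* a 256-entry 4-mer end-motif distribution, with a shared cancer tilt of
  +/-20% relative frequency on ten designated motifs (five up: CAAA, TAGA,
  CAGA, CAAG, CAAT; five down: CGCT, CGCC, CGCA, GCCT, CGTT) and a smaller
  class-specific tilt so tissue of origin is learnable from motifs;
* methylation effects: signed per-target-region shifts (hyper- and
  hypo-DMRs) and a negative genome-wide shift (global tumor
  hypomethylation), both expressed at tumor level and scaled by the
  class's tumor fraction when counts are simulated;
* copy-number segments: class-specific genomic intervals with a cfDNA-level
  log2 copy ratio derived from an integer tumor copy number diluted by the
  tumor fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cfmosaic.reference import MOTIF_INDEX_OF

#: supported cohort classes, healthy first
CLASS_LABELS = ["healthy", "breast", "colorectal", "gastric", "liver", "lung"]
CANCER_CLASSES = CLASS_LABELS[1:]

#: fragment lengths retained for analysis
MIN_LEN, MAX_LEN = 100, 250
LENGTHS = np.arange(MIN_LEN, MAX_LEN + 1)
#: short fragments are <=150 bp, long fragments 151-250 bp
SHORT_MAX = 150

#: designated differential end motifs (cancer vs healthy)
MOTIFS_UP = ["CAAA", "TAGA", "CAGA", "CAAG", "CAAT"]
MOTIFS_DOWN = ["CGCT", "CGCC", "CGCA", "GCCT", "CGTT"]

#: cohort-mean short/long count ratios the defaults are calibrated to
HEALTHY_RATIO = 0.27
CANCER_RATIO = 0.29
#: short-fragment probability of the pure-tumor length distribution
TUMOR_P_SHORT = 0.35


def calibrate_short_fraction(target_ratio: float) -> float:
    """Per-fragment short probability giving an expected short/long ratio.

    If each fragment is short with probability ``p`` then the expected
    short/long count ratio is ``p / (1 - p)``; inverting gives
    ``p = r / (1 + r)``.

    >>> round(calibrate_short_fraction(1.0), 3)
    0.5
    """
    if not target_ratio > 0:
        raise ValueError(f"target_ratio must be > 0, got {target_ratio}")
    return target_ratio / (1.0 + target_ratio)


def _discrete_gaussian_mixture(modes, sds, weights) -> np.ndarray:
    """Gaussian mixture discretized onto the 100-250 bp grid, normalized."""
    pdf = np.zeros_like(LENGTHS, dtype=float)
    for mode, sd, w in zip(modes, sds, weights):
        pdf += w * np.exp(-0.5 * ((LENGTHS - mode) / sd) ** 2) / sd
    return pdf / pdf.sum()


def _reweight_short_mass(dist: np.ndarray, p_short: float) -> np.ndarray:
    """Rescale the <=150 bp and >150 bp halves so P(length<=150)=p_short."""
    short = LENGTHS <= SHORT_MAX
    out = dist.copy()
    out[short] *= p_short / dist[short].sum()
    out[~short] *= (1.0 - p_short) / dist[~short].sum()
    return out


def healthy_flen_dist() -> np.ndarray:
    """Healthy fragment-length distribution: sharp mononucleosome peak at 167 bp.

    A broad and a narrow component share the 167 bp centre; the narrow one
    reproduces the sharp modal peak seen in cfDNA size profiles so the mode
    is stable even at moderate fragment counts.  Short-fragment mass is set
    to ``calibrate_short_fraction(0.27)``.
    """
    base = _discrete_gaussian_mixture([167, 167], [20.0, 2.0], [0.65, 0.35])
    return _reweight_short_mass(base, calibrate_short_fraction(HEALTHY_RATIO))


def tumor_flen_dist() -> np.ndarray:
    """Tumor fragment-length distribution: shorter, modal length 145 bp."""
    base = _discrete_gaussian_mixture([145, 145], [20.0, 2.0], [0.65, 0.35])
    return _reweight_short_mass(base, TUMOR_P_SHORT)


def default_tumor_fraction() -> float:
    """Tumor fraction at which the length mixture yields a 0.29 short/long ratio.

    Solves ``(1-t)*p_h + t*p_t = p_c`` for ``t`` with ``p_h``, ``p_t``,
    ``p_c`` the healthy, tumor and cancer-cohort short-fragment
    probabilities.
    """
    p_h = calibrate_short_fraction(HEALTHY_RATIO)
    p_c = calibrate_short_fraction(CANCER_RATIO)
    return (p_c - p_h) / (TUMOR_P_SHORT - p_h)


@dataclass
class ClassProfile:
    """Generative parameters for one cohort class."""

    class_label: str
    tumor_fraction: float
    flen_healthy_dist: np.ndarray
    flen_tumor_dist: np.ndarray
    motif_dist: np.ndarray
    #: signed tumor-level methylation shift per target region
    dmr_effects: np.ndarray
    #: signed tumor-level genome-wide methylation shift
    gwm_shift: float
    #: (chrom_name, start, end, log2_copy_ratio) at cfDNA level
    cna_segments: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("flen_healthy_dist", "flen_tumor_dist", "motif_dist"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.class_label == "healthy" and self.tumor_fraction != 0.0:
            raise ValueError("healthy class must have tumor_fraction 0")

    @property
    def flen_mixture(self) -> np.ndarray:
        t = self.tumor_fraction
        return (1.0 - t) * self.flen_healthy_dist + t * self.flen_tumor_dist


def _tilt_motifs(dist: np.ndarray, tilts: dict[str, float]) -> np.ndarray:
    """Apply relative frequency changes, renormalizing the rest uniformly."""
    out = dist.copy()
    idx = np.array([MOTIF_INDEX_OF[m] for m in tilts], dtype=int)
    rel = np.array(list(tilts.values()), dtype=float)
    out[idx] = dist[idx] * (1.0 + rel)
    rest = np.setdiff1d(np.arange(256), idx)
    excess = out.sum() - 1.0
    out[rest] -= excess / rest.size
    if (out < 0).any():
        raise ValueError("motif tilt produced negative frequencies")
    return out


#: class-specific motif tilts (disjoint from the ten shared motifs)
_CLASS_MOTIFS = {
    "breast": ["AACC", "AACG", "AACT", "AAGA", "AAGC", "AAGG"],
    "colorectal": ["ACCA", "ACCC", "ACCG", "ACCT", "ACGA", "ACGC"],
    "gastric": ["AGCA", "AGCC", "AGCG", "AGCT", "AGGA", "AGGC"],
    "liver": ["ATCA", "ATCC", "ATCG", "ATCT", "ATGA", "ATGC"],
    "lung": ["CACC", "CACG", "CACT", "CAGC", "CAGG", "CAGT"],
}

#: 450-region target panel: 339 hyper-DMRs, 63 hypo-DMRs, 48 null regions
N_TARGET_REGIONS = 450
N_HYPER, N_HYPO = 339, 63
#: tumor-level methylation shifts (scaled by tumor fraction at simulation)
HYPER_SHIFT, HYPO_SHIFT = 0.5, -0.5
#: extra tumor-level hyper shift on each class's private block of regions
CLASS_DMR_SHIFT = 0.8
CLASS_DMR_BLOCK = 20
#: tumor-level genome-wide methylation shift (global hypomethylation)
GWM_SHIFT = -0.2

#: class-specific copy-number segments as (chrom, start, end, tumor copies)
_CLASS_CNA = {
    "breast": [("chr1", 0, 100_000, 6)],
    "colorectal": [("chr1", 150_000, 250_000, 0)],
    "gastric": [("chr1", 300_000, 400_000, 6)],
    "liver": [("chr2", 0, 100_000, 6), ("chr2", 150_000, 250_000, 0)],
    "lung": [("chr2", 300_000, 400_000, 0)],
}


def cfdna_log2_ratio(tumor_copies: float, tumor_fraction: float) -> float:
    """cfDNA-level log2 copy ratio of a segment with the given tumor copies."""
    return float(np.log2(1.0 + tumor_fraction * (tumor_copies / 2.0 - 1.0)))


def base_dmr_effects() -> np.ndarray:
    """Shared cancer-vs-healthy target-region effects (tumor level)."""
    eff = np.zeros(N_TARGET_REGIONS)
    eff[:N_HYPER] = HYPER_SHIFT
    eff[N_HYPER : N_HYPER + N_HYPO] = HYPO_SHIFT
    return eff


def default_profiles(
    motif_shift: float = 0.20,
    class_motif_shift: float = 0.30,
    tumor_fraction: float | None = None,
) -> dict[str, ClassProfile]:
    """Default profiles for the healthy class and the five cancer classes.

    ``motif_shift`` is the shared relative end-motif change on the ten
    designated motifs; ``class_motif_shift`` the class-private tilt.
    ``tumor_fraction`` defaults to the mixture solution that calibrates the
    cancer-cohort short/long ratio to 0.29.
    """
    tf = default_tumor_fraction() if tumor_fraction is None else tumor_fraction
    healthy_motifs = np.full(256, 1.0 / 256.0)
    flen_h, flen_t = healthy_flen_dist(), tumor_flen_dist()

    profiles = {
        "healthy": ClassProfile(
            class_label="healthy",
            tumor_fraction=0.0,
            flen_healthy_dist=flen_h,
            flen_tumor_dist=flen_t,
            motif_dist=healthy_motifs,
            dmr_effects=np.zeros(N_TARGET_REGIONS),
            gwm_shift=0.0,
        )
    }
    shared_tilt = {m: motif_shift for m in MOTIFS_UP}
    shared_tilt.update({m: -motif_shift for m in MOTIFS_DOWN})
    for ci, label in enumerate(CANCER_CLASSES):
        tilt = dict(shared_tilt)
        tilt.update({m: class_motif_shift for m in _CLASS_MOTIFS[label]})
        eff = base_dmr_effects()
        block = slice(ci * CLASS_DMR_BLOCK, (ci + 1) * CLASS_DMR_BLOCK)
        eff[block] += CLASS_DMR_SHIFT
        segments = [
            (chrom, s, e, cfdna_log2_ratio(copies, tf))
            for chrom, s, e, copies in _CLASS_CNA[label]
        ]
        profiles[label] = ClassProfile(
            class_label=label,
            tumor_fraction=tf,
            flen_healthy_dist=flen_h,
            flen_tumor_dist=flen_t,
            motif_dist=_tilt_motifs(healthy_motifs, tilt),
            dmr_effects=eff,
            gwm_shift=GWM_SHIFT,
            cna_segments=segments,
        )
    return profiles
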