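"""Miniature reference genome with a 4-mer start-position index.

End-motif profiling needs the reference base context at each fragment's
forward-read 5' end.  Running against a full human reference is impractical
for simulation-driven testing, so the simulator works on a small random
genome (default two chromosomes of 1 Mb) that is long enough for every one
of the 256 possible 4-mers to occur many times.  The same class also wraps
user-supplied FASTA references for end-motif lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
#: the 256 4-mers in lexicographic order (AAAA ... TTTT)
ALL_MOTIFS = ["".join(m) for m in itertools.product(BASES, repeat=4)]
MOTIF_INDEX_OF = {m: i for i, m in enumerate(ALL_MOTIFS)}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def motif_codes(codes: np.ndarray) -> np.ndarray:
    """4-mer code (0..255) at every start position; -1 for ambiguous windows."""
    n = codes.size - 3
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    c0, c1, c2, c3 = codes[:n], codes[1 : n + 1], codes[2 : n + 2], codes[3 : n + 3]
    out = (c0.astype(np.int32) << 6) | (c1.astype(np.int32) << 4) \
        | (c2.astype(np.int32) << 2) | c3.astype(np.int32)
    bad = (c0 < 0) | (c1 < 0) | (c2 < 0) | (c3 < 0)
    out[bad] = -1
    return out


@dataclass
class MiniReference:
    """A small in-memory reference with an index of 4-mer start positions.

    Attributes
    ----------
    chrom_names, chrom_lengths, sequences
        Parallel per-chromosome identifiers, lengths (bp) and A/C/G/T strings.
    motif_positions
        ``(256,)`` object array; entry ``m`` is a ``(k, 2)`` int array of
        ``(chrom_index, position)`` rows, sorted, at which the reference
        4-mer equals motif ``m``.
    """

    chrom_names: list[str]
    chrom_lengths: list[int]
    sequences: list[str]
    motif_positions: list[np.ndarray] = field(repr=False, default_factory=list)
    _codes: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self._codes:
            self._codes = [encode_sequence(s) for s in self.sequences]
        if not self.motif_positions:
            self.motif_positions = self._build_index()

    def _build_index(self) -> list[np.ndarray]:
        per_motif: list[list[np.ndarray]] = [[] for _ in range(256)]
        for ci, codes in enumerate(self._codes):
            mc = motif_codes(codes)
            order = np.argsort(mc, kind="stable")
            sorted_codes = mc[order]
            # group equal codes in one pass
            uniq, starts = np.unique(sorted_codes, return_index=True)
            bounds = np.append(starts, mc.size)
            for u, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
                if u < 0:
                    continue
                pos = np.sort(order[lo:hi])
                rows = np.column_stack([np.full(pos.size, ci, dtype=np.int64), pos])
                per_motif[u].append(rows)
        return [
            np.concatenate(rows) if rows else np.empty((0, 2), dtype=np.int64)
            for rows in per_motif
        ]

    @property
    def motif_index(self) -> dict[str, np.ndarray]:
        """Map motif string -> (k, 2) array of (chrom_index, position)."""
        return {m: self.motif_positions[i] for i, m in enumerate(ALL_MOTIFS)}

    def codes(self, chrom_index: int) -> np.ndarray:
        return self._codes[chrom_index]

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in reference") from None

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[self.chrom_index(chrom)][start:end]

    def missing_motifs(self) -> list[str]:
        return [m for i, m in enumerate(ALL_MOTIFS) if self.motif_positions[i].size == 0]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.chrom_names, self.sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "MiniReference":
        names: list[str] = []
        seqs: list[str] = []
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if names:
                        seqs.append("".join(chunks))
                    names.append(line[1:].split()[0])
                    chunks = []
                else:
                    chunks.append(line.upper())
        if names:
            seqs.append("".join(chunks))
        if not names:
            raise ValueError(f"no sequences found in FASTA {path}")
        return cls(names, [len(s) for s in seqs], seqs)


def build_reference(seed: int, n_chrom: int = 2, chrom_length: int = 1_000_000) -> MiniReference:
    """Generate a seeded random reference and index all 4-mer positions.

    Parameters
    ----------
    seed
        Seed for the base composition; identical seeds give identical
        references.
    n_chrom, chrom_length
        Genome shape.  ``chrom_length`` must be at least 10 kb so that all
        256 motifs are expected to occur (mean spacing 256 bp).

    Raises
    ------
    ValueError
        If the genome is too short to host every 4-mer; the message names
        the missing motifs.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000 bp")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = [
        "".join(np.array(list(BASES))[rng.integers(0, 4, size=chrom_length)])
        for _ in range(n_chrom)
    ]
    ref = MiniReference(names, [chrom_length] * n_chrom, seqs)
    missing = ref.missing_motifs()
    if missing:
        raise ValueError(
            "reference too short: motifs with no indexed position: " + ",".join(missing)
        )
    return ref
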