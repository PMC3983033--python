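"""Genome assemblies, intervals, sequence scans and mappability.

Coordinates are 0-based half-open everywhere inside the package; the I/O
layer (:mod:`intbias.io`) converts 1-based formats (GFF) at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STRANDS = ("+", "-", ".")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeAssembly:
    """An ordered set of chromosomes with optional nucleotide sequence.

    Parameters
    ----------
    chrom_names:
        Chromosome identifiers in genome order.
    chrom_lengths:
        Mapping chromosome -> length in bp; all lengths positive.
    sequence:
        Optional mapping chromosome -> uppercase sequence over {A,C,G,T,N};
        when present, ``len(sequence[c]) == chrom_lengths[c]``.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self):
        for c in self.chrom_names:
            if self.chrom_lengths[c] <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        if self.sequence is not None:
            for c in self.chrom_names:
                s = self.sequence[c]
                if len(s) != self.chrom_lengths[c]:
                    raise ValueError(
                        f"sequence length mismatch on {c}: "
                        f"{len(s)} != {self.chrom_lengths[c]}"
                    )
                if set(s) - set("ACGTN"):
                    raise ValueError(f"invalid alphabet on {c}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def require_sequence(self) -> dict[str, str]:
        if self.sequence is None:
            raise ValueError("assembly has no sequence")
        return self.sequence

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {self.chrom_lengths[iv.chrom]}"
            )


@dataclass
class RestrictionMap:
    """Sorted restriction-enzyme cut positions per chromosome."""

    enzyme: str
    sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for c, arr in self.sites.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"sites on {c} not strictly increasing")
            self.sites[c] = arr

    def on(self, chrom: str) -> np.ndarray:
        return self.sites.get(chrom, np.empty(0, dtype=np.int64))


def _scan(seq: str, motif: str) -> np.ndarray:
    """All (overlapping) forward-strand start positions of motif in seq."""
    pat = re.compile("(?=" + re.escape(motif) + ")")
    return np.fromiter(
        (m.start() for m in pat.finditer(seq)), dtype=np.int64
    )


def find_motif_sites(assembly: GenomeAssembly, motif: str) -> dict[str, np.ndarray]:
    """Start positions of every motif occurrence, per chromosome.

    Palindromic motifs (reverse-complement equal to themselves, e.g. TA and
    TTAA) are scanned on the forward strand only, because every reverse-strand
    occurrence coincides with a forward one.  Non-palindromic motifs are
    scanned on both strands and the merged position set is returned.
    """
    if not motif:
        raise ValueError("empty motif")
    if set(motif) - set("ACGT"):
        raise ValueError(f"ambiguous motif alphabet: {motif!r}")
    seqs = assembly.require_sequence()
    rc = reverse_complement(motif)
    out = {}
    for c in assembly.chrom_names:
        pos = _scan(seqs[c], motif)
        if rc != motif:
            pos = np.union1d(pos, _scan(seqs[c], rc))
        out[c] = pos
    return out


def find_restriction_sites(assembly: GenomeAssembly, enzyme: str) -> RestrictionMap:
    """Restriction map of all recognition-sequence occurrences."""
    return RestrictionMap(enzyme=enzyme, sites=find_motif_sites(assembly, enzyme))


def build_mappability_mask(
    assembly: GenomeAssembly, read_length: int
) -> dict[str, np.ndarray]:
    """Boolean per-position mask of uniquely mappable read start sites.

    A position ``p`` on chromosome ``c`` is mappable iff the ``read_length``-mer
    starting at ``p`` occurs at exactly one genomic locus, counting occurrences
    on both strands (a read whose forward and reverse-complement sequence hit
    the same locus still maps uniquely).  k-mers containing N are unmappable.
    Positions within ``read_length - 1`` of a chromosome end carry no full
    k-mer and are marked unmappable.

    This is a brute-force k-mer dictionary, adequate for the multi-megabase
    synthetic assemblies this package targets.
    """
    seqs = assembly.require_sequence()
    k = int(read_length)
    if k < 1:
        raise ValueError("read_length must be >= 1")
    shortest = min(assembly.chrom_lengths.values())
    if k > shortest:
        raise ValueError("read_length exceeds shortest chromosome")

    # canonical k-mer -> set of loci (chrom index, position), capped at 2
    hits: dict[str, tuple] = {}
    for ci, c in enumerate(assembly.chrom_names):
        seq = seqs[c]
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            canon = min(kmer, reverse_complement(kmer))
            prev = hits.get(canon)
            if prev is None:
                hits[canon] = (ci, p)
            elif prev != (ci, p):
                hits[canon] = False  # multi-locus

    mask = {}
    for ci, c in enumerate(assembly.chrom_names):
        seq = seqs[c]
        L = assembly.chrom_lengths[c]
        m = np.zeros(L, dtype=bool)
        for p in range(L - k + 1):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            canon = min(kmer, reverse_complement(kmer))
            m[p] = hits[canon] == (ci, p)
        mask[c] = m
    return mask
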