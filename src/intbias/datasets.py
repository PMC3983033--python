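"""In-memory containers for integration events, controls, genes and Hi-C."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, GenomicInterval


@dataclass
class IntegrationSet:
    """Oriented genomic point events for one integration system.

    ``events`` is a DataFrame with columns ``chrom`` (str), ``position``
    (int, 0-based bp) and ``orientation`` ({'+','-'}); an optional
    ``tumor_id`` column labels tumor-screen events.  Events are unique per
    (chrom, position, orientation).
    """

    system: str
    events: pd.DataFrame
    motif: str | None = None

    def __post_init__(self):
        ev = self.events.reset_index(drop=True)
        required = {"chrom", "position", "orientation"}
        if not required <= set(ev.columns):
            raise ValueError(f"events must have columns {sorted(required)}")
        if not ev["orientation"].isin(["+", "-"]).all():
            raise ValueError("orientation must be '+' or '-'")
        key = ["chrom", "position", "orientation"]
        if "tumor_id" in ev.columns:
            key = ["tumor_id"] + key  # screens may hit one locus in many tumors
        if ev.duplicated(key).any():
            raise ValueError(f"duplicate events on key {key}")
        ev["position"] = ev["position"].astype(np.int64)
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    def validate_bounds(self, assembly: GenomeAssembly) -> None:
        for c, grp in self.events.groupby("chrom"):
            L = assembly.chrom_lengths.get(c)
            if L is None:
                raise ValueError(f"unknown chromosome {c}")
            if (grp["position"] < 0).any() or (grp["position"] >= L).any():
                raise ValueError(f"positions out of bounds on {c}")

    def positions_on(self, chrom: str) -> np.ndarray:
        sel = self.events["chrom"] == chrom
        return self.events.loc[sel, "position"].to_numpy()

    def by_chrom(self):
        return self.events.groupby("chrom", sort=False)


@dataclass
class ControlSet:
    """Per-integration matched random control loci.

    ``positions`` has shape (n_events, m): row i holds the m control
    positions for event i of ``parent`` (same chromosome and orientation as
    the event).  ``kept`` marks events for which controls could be drawn;
    dropped events are excluded from control-based analyses and reported.
    """

    parent: IntegrationSet
    m: int
    positions: np.ndarray
    kept: np.ndarray
    eligible_sizes: np.ndarray
    with_replacement: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.parent)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (n, self.m):
            raise ValueError("positions must be (n_events, m)")
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.with_replacement is None:
            self.with_replacement = np.zeros(n, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def control_frame(self) -> pd.DataFrame:
        """Long-format controls of kept events: chrom, position, orientation,
        parent_index, control_index."""
        ev = self.parent.events
        idx = np.flatnonzero(self.kept)
        rows = {
            "chrom": np.repeat(ev["chrom"].to_numpy()[idx], self.m),
            "position": self.positions[idx].ravel(),
            "orientation": np.repeat(ev["orientation"].to_numpy()[idx], self.m),
            "parent_index": np.repeat(idx, self.m),
            "control_index": np.tile(np.arange(self.m), idx.size),
        }
        return pd.DataFrame(rows)

    def control_set_frame(self, j: int) -> pd.DataFrame:
        """The j-th control pseudo-dataset (one control per kept event)."""
        ev = self.parent.events
        idx = np.flatnonzero(self.kept)
        return pd.DataFrame(
            {
                "chrom": ev["chrom"].to_numpy()[idx],
                "position": self.positions[idx, j],
                "orientation": ev["orientation"].to_numpy()[idx],
            }
        )


@dataclass
class Transcript:
    exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    utr5: list[GenomicInterval]
    utr3: list[GenomicInterval]


@dataclass
class GeneModel:
    """A gene with TSS/TTS and one or more transcript structures."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    tts: int
    transcripts: list[Transcript] = field(default_factory=list)
    has_full_ids: bool = True

    def __post_init__(self):
        iv = self.interval
        if iv.strand == "+":
            if self.tss != iv.start or self.tts != iv.end:
                raise ValueError(f"{self.gene_id}: tss/tts inconsistent with + strand")
        elif iv.strand == "-":
            if self.tss != iv.end or self.tts != iv.start:
                raise ValueError(f"{self.gene_id}: tss/tts inconsistent with - strand")
        else:
            raise ValueError(f"{self.gene_id}: gene must be stranded")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class ContactMatrix:
    """Symmetric normalized Hi-C contact frequencies for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if (m < 0).any():
            raise ValueError("contact matrix must be non-negative")
        if not np.allclose(m, m.T, rtol=1e-6, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Annotation:
    """Bundle of synthetic (or loaded) annotation elements."""

    genes: list[GeneModel]
    tads: list[GenomicInterval]
    boundaries: list[GenomicInterval]
    cpg_islands: list[GenomicInterval]

    def tss_positions(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g.tss)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in out.items()}
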