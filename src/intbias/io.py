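"""Readers and writers for the standard text formats used by the pipeline.

Internal coordinates are 0-based half-open; BED is read/written verbatim
and GFF (1-based, inclusive) is converted at this boundary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import ContactMatrix, IntegrationSet
from .genome import GenomeAssembly, GenomicInterval
from .tracks import FeatureTrack


def read_fasta(path) -> GenomeAssembly:
    names, lengths, seqs = [], {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
        lengths[rec.id] = len(rec.seq)
    if not names:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly(chrom_names=names, chrom_lengths=lengths, sequence=seqs)


def write_fasta(assembly: GenomeAssembly, path) -> None:
    seqs = assembly.require_sequence()
    records = [SeqRecord(Seq(seqs[c]), id=c, description="") for c in assembly.chrom_names]
    SeqIO.write(records, str(path), "fasta")


def read_intervals(path, format: str = "BED",
                   assembly: GenomeAssembly | None = None) -> list[GenomicInterval]:
    """Read intervals from BED (0-based half-open) or GFF (1-based inclusive).

    Malformed lines raise with the offending line number; with an assembly
    given, coordinates beyond chromosome ends raise too.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF"):
        raise ValueError(f"unknown format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "BED":
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    strand = f[5] if len(f) >= 6 else "."
                else:  # GFF: chrom source type start end score strand ...
                    chrom = f[0]
                    start, end = int(f[3]) - 1, int(f[4])
                    strand = f[6] if len(f) >= 7 and f[6] in "+-" else "."
                iv = GenomicInterval(chrom, start, end, strand)
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {e}") from e
            if assembly is not None:
                assembly.check_interval(iv)
            out.append(iv)
    return out


def write_intervals(intervals, path, format: str = "BED") -> None:
    fmt = format.upper()
    with open(path, "w") as fh:
        for iv in intervals:
            if fmt == "BED":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            elif fmt == "GFF":
                fh.write(
                    f"{iv.chrom}\tintbias\tregion\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t.\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


def read_integrations(path, system: str, motif: str | None = None) -> IntegrationSet:
    """Integration events from a BED6-like file (orientation in the strand column)."""
    ivs = read_intervals(path, "BED")
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "position": [iv.start for iv in ivs],
            "orientation": [iv.strand for iv in ivs],
        }
    )
    return IntegrationSet(system=system, events=df, motif=motif)


def write_integrations(integrations: IntegrationSet, path) -> None:
    with open(path, "w") as fh:
        for row in integrations.events.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                f"{integrations.system}\t0\t{row.orientation}\n"
            )


def write_controls(control_set, path) -> None:
    """Controls as BED6 plus parent-event and control indices."""
    df = control_set.control_frame()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.position}\t{row.position + 1}\t"
                f"ctl\t0\t{row.orientation}\t{row.parent_index}\t{row.control_index}\n"
            )


def write_bedgraph(track: FeatureTrack, assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for c in assembly.chrom_names:
            L = assembly.chrom_lengths[c]
            v = track.values[c]
            for i, x in enumerate(v):
                if np.isnan(x):
                    continue
                end = min((i + 1) * track.bin_size, L)
                fh.write(f"{c}\t{i * track.bin_size}\t{end}\t{x:.6g}\n")


def read_bedgraph(path, assembly: GenomeAssembly, bin_size: int,
                  name: str = "track") -> FeatureTrack:
    """Load a bedGraph onto a fixed binning (NaN where no record covers a bin)."""
    values = {
        c: np.full(math.ceil(L / bin_size), np.nan)
        for c, L in assembly.chrom_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            try:
                chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from e
            b0, b1 = start // bin_size, (end - 1) // bin_size + 1
            values[chrom][b0:b1] = val
    return FeatureTrack(name=name, bin_size=bin_size, values=values)


def read_expression(path) -> pd.Series:
    """Two-column TSV (gene id, expression value) -> Series indexed by gene id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "value"],
                     comment="#")
    return df.set_index("gene_id")["value"].astype(float)


def write_expression(expr: pd.Series, path) -> None:
    expr.rename("value").to_csv(path, sep="\t", header=False)


def read_contact_matrix(path, chrom: str, bin_size: int) -> ContactMatrix:
    """Dense whitespace-delimited Hi-C matrix."""
    m = np.loadtxt(path)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=m)


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    np.savetxt(path, cm.matrix, fmt="%.6g")


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=_json_default))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
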