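"""Fixed-bin genome-wide signal tracks and their preprocessing.

The preprocessing mirrors common ChIP-seq practice: read starts are counted
in small consecutive bins (default 25 bp), depth-normalized, smoothed with a
running mean, resampled to a coarser spacing, and optionally expressed as a
log2 signal/control ratio.  Missing values are NaN and are excluded from all
window means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeAssembly, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class FeatureTrack:
    """Genome-wide numeric signal on a fixed binning.

    ``values[c][i]`` covers bp ``[i*bin_size, (i+1)*bin_size)`` of chromosome
    ``c``; array length is ``ceil(chrom_length / bin_size)``.  NaN marks
    missing data.
    """

    name: str
    bin_size: int
    values: dict[str, np.ndarray]
    kind: str = "signal"  # {"signal", "distance_transform"}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        for c, arr in self.values.items():
            self.values[c] = np.asarray(arr, dtype=float)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def check_shape(self, assembly: GenomeAssembly) -> None:
        for c, L in assembly.chrom_lengths.items():
            expect = math.ceil(L / self.bin_size)
            if len(self.values[c]) != expect:
                raise ValueError(
                    f"track {self.name}: {c} has {len(self.values[c])} bins, "
                    f"expected {expect}"
                )

    def value_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track value of the bin containing each position."""
        arr = self.values[chrom]
        idx = np.clip(np.asarray(positions, dtype=np.int64) // self.bin_size,
                      0, len(arr) - 1)
        return arr[idx]

    def window_mean(self, chrom: str, centers: np.ndarray, window: int) -> np.ndarray:
        """NaN-aware mean of the track over ``[c - window/2, c + window/2)``.

        Windows are expressed on the track's binning: all bins overlapping the
        window contribute equally.  Windows extending beyond the chromosome are
        truncated to the available bins; fully off-chromosome windows give NaN.
        """
        arr = self.values[chrom]
        nb = len(arr)
        centers = np.asarray(centers, dtype=np.int64)
        lo = (centers - window // 2) // self.bin_size
        hi = (centers + window - window // 2 - 1) // self.bin_size + 1
        lo = np.clip(lo, 0, nb)
        hi = np.clip(hi, 0, nb)
        finite = np.nan_to_num(arr, nan=0.0)
        csum = np.concatenate([[0.0], np.cumsum(finite)])
        ccnt = np.concatenate([[0], np.cumsum(~np.isnan(arr))])
        tot = csum[hi] - csum[lo]
        cnt = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
        return out


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Running mean of width ``window``, truncated at the array ends.

    Interior points average the full window; near the edges the mean is taken
    over the part of the window that exists (so a constant array is mapped to
    itself, and an impulse is spread over exactly ``window`` points away from
    the edges).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(np.nan_to_num(x, nan=0.0))])
    ccnt = np.concatenate([[0], np.cumsum(~np.isnan(x))])
    i = np.arange(n)
    lo = np.maximum(i - (window - 1) // 2, 0)
    hi = np.minimum(i + window // 2 + 1, n)
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def bin_counts(
    positions: dict[str, np.ndarray], assembly: GenomeAssembly, bin_size: int
) -> FeatureTrack:
    """Count read starts (or events) per fixed-size bin."""
    values = {}
    for c, L in assembly.chrom_lengths.items():
        nb = math.ceil(L / bin_size)
        pos = np.asarray(positions.get(c, np.empty(0, dtype=np.int64)))
        if pos.size and ((pos < 0).any() or (pos >= L).any()):
            raise ValueError(f"positions out of bounds on {c}")
        values[c] = np.bincount(pos // bin_size, minlength=nb).astype(float)
    return FeatureTrack(name="counts", bin_size=bin_size, values=values,
                        metadata={"stage": "raw_counts"})


def bin_and_normalize_track(
    coverage: FeatureTrack | dict[str, np.ndarray],
    assembly: GenomeAssembly,
    bin_size: int = 25,
    smooth_window: int = 6,
    sample_spacing: int = 100,
    control: FeatureTrack | None = None,
    depth_target: float = 1e7,
    epsilon: float = 1.0,
    name: str = "track",
) -> FeatureTrack:
    """Bin, depth-normalize, smooth, resample and (optionally) log2-ratio.

    Parameters
    ----------
    coverage:
        Either read-start positions per chromosome, or an already-binned
        count track at ``bin_size``.
    control:
        An already processed control track on the SAME output binning
        (``sample_spacing``); the output is then
        ``log2((signal + epsilon) / (control + epsilon))``.
    depth_target:
        Total count the raw bins are scaled to before smoothing, so tracks of
        different sequencing depth are comparable.
    """
    if bin_size < 1 or sample_spacing < 1:
        raise ValueError("bin_size and sample_spacing must be positive")
    if sample_spacing % bin_size != 0:
        raise ValueError("sample_spacing must be a multiple of bin_size")

    if isinstance(coverage, FeatureTrack):
        if coverage.bin_size != bin_size:
            raise ValueError("coverage track binning mismatch")
        counts = coverage
    else:
        counts = bin_counts(coverage, assembly, bin_size)

    total = sum(np.nansum(v) for v in counts.values.values())
    scale = depth_target / total if total > 0 else 1.0
    step = sample_spacing // bin_size
    out_values = {}
    for c in assembly.chrom_names:
        v = counts.values[c] * scale
        v = running_mean(v, smooth_window)
        out_values[c] = v[::step].copy()
    out = FeatureTrack(
        name=name,
        bin_size=sample_spacing,
        values=out_values,
        metadata={
            "bin_size_raw": bin_size,
            "smooth_window": smooth_window,
            "depth_target": depth_target,
            "epsilon": epsilon,
        },
    )
    if control is not None:
        if control.bin_size != out.bin_size:
            raise ValueError(
                f"control binning {control.bin_size} != signal {out.bin_size}"
            )
        for c in assembly.chrom_names:
            s, k = out.values[c], control.values[c]
            if len(s) != len(k):
                raise ValueError(f"control bin count mismatch on {c}")
            out.values[c] = np.log2((s + epsilon) / (k + epsilon))
        out.metadata["control"] = control.name
        out.metadata["transform"] = "log2_ratio"
    return out


def distance_transform_values(
    positions: np.ndarray, elements: np.ndarray | list[GenomicInterval]
) -> np.ndarray:
    """-log2(distance + 1) to the nearest element for each query position.

    ``elements`` is either an array of point positions or a list of intervals
    (distance 0 inside an interval).  Positions on an element score 0; a
    position at distance 1 scores -1.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if len(elements) == 0:
        return np.full(positions.shape, np.nan)
    if isinstance(elements, np.ndarray) or np.isscalar(elements[0]):
        starts = np.sort(np.asarray(elements, dtype=np.int64))
        ends = starts + 1
    else:
        order = np.argsort([iv.start for iv in elements])
        starts = np.asarray([elements[i].start for i in order], dtype=np.int64)
        ends = np.asarray([elements[i].end for i in order], dtype=np.int64)
    # distance to nearest interval [start, end)
    idx = np.searchsorted(starts, positions, side="right")
    d_left = np.full(positions.shape, np.iinfo(np.int64).max, dtype=np.int64)
    has_left = idx > 0
    d_left[has_left] = np.maximum(
        0, positions[has_left] - (ends[idx[has_left] - 1] - 1)
    )
    d_right = np.full(positions.shape, np.iinfo(np.int64).max, dtype=np.int64)
    has_right = idx < len(starts)
    d_right[has_right] = np.maximum(0, starts[idx[has_right]] - positions[has_right])
    d = np.minimum(d_left, d_right).astype(float)
    return -np.log2(d + 1.0)


def distance_transform_track(
    elements: dict[str, np.ndarray] | list[GenomicInterval],
    assembly: GenomeAssembly,
    bin_size: int = 100,
    name: str = "distance",
) -> FeatureTrack:
    """Genome-wide -log2(distance+1)-to-nearest-element track.

    The value of each bin is the transform evaluated at the bin start.
    """
    if isinstance(elements, dict):
        per_chrom: dict[str, object] = dict(elements)
    else:
        per_chrom = {}
        for iv in elements:
            per_chrom.setdefault(iv.chrom, []).append(iv)
    values = {}
    for c, L in assembly.chrom_lengths.items():
        nb = math.ceil(L / bin_size)
        pos = np.arange(nb, dtype=np.int64) * bin_size
        el = per_chrom.get(c, np.empty(0, dtype=np.int64))
        values[c] = distance_transform_values(pos, el)
    return FeatureTrack(name=name, bin_size=bin_size, values=values,
                        kind="distance_transform")
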