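"""Synthetic genomes, annotations, feature tracks, biased integration
profiles and tumor screens with serialized ground truth.

The generator exists so that every downstream stage of the pipeline has a
parameter-recovery test: integration intensity follows a log-linear
(exponential-tilt) model over feature tracks at configurable coupling
scales, which is exactly the monotone bias structure the association
statistics are designed to detect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datasets import Annotation, GeneModel, IntegrationSet, Transcript
from .genome import GenomeAssembly, GenomicInterval, RestrictionMap
from .tracks import FeatureTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ground-truth models


@dataclass
class FeatureCoupling:
    feature: str
    beta: float
    scale: int = 0  # bp; 0 couples to the value at the site itself

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("coupling scale must be >= 0")


@dataclass
class BiasModel:
    """Log-linear integration intensity specification.

    log intensity(p) = baseline + sum_f beta_f * feature_f(p at scale s_f);
    orientation is drawn independently, with probability ``gene_sense_prob``
    of matching the host gene's strand inside genes and 1/2 elsewhere.
    """

    motif: str | None = None
    coefficients: list[FeatureCoupling] = field(default_factory=list)
    baseline: float = 0.0
    gene_sense_prob: float | None = None

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "baseline": self.baseline,
            "gene_sense_prob": self.gene_sense_prob,
            "coefficients": [
                {"feature": c.feature, "beta": c.beta, "scale": c.scale}
                for c in self.coefficients
            ],
        }


@dataclass
class CISLocus:
    chrom: str
    position: int
    strength: float  # per-tumor hit rate parameter; P(hit) = 1 - exp(-strength)
    activating: bool = True
    orientation: str = "+"

    def __post_init__(self):
        if self.strength <= 0:
            raise ValueError("selection strength must be > 0")


@dataclass
class ScreenTruth:
    true_cis_loci: list[CISLocus]
    background_model: BiasModel

    def to_dict(self) -> dict:
        return {
            "true_cis_loci": [
                {
                    "chrom": l.chrom,
                    "position": l.position,
                    "strength": l.strength,
                    "activating": l.activating,
                    "orientation": l.orientation,
                }
                for l in self.true_cis_loci
            ],
            "background_model": self.background_model.to_dict(),
        }


# ---------------------------------------------------------------------------
# assembly & annotation


def make_assembly(
    chrom_lengths: dict[str, int] | list[int],
    gc: float = 0.42,
    seed: int = 0,
) -> GenomeAssembly:
    """I.i.d. random nucleotide assembly at the stated GC fraction."""
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = {f"chr{i + 1}": L for i, L in enumerate(chrom_lengths)}
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for c, L in chrom_lengths.items():
        draw = rng.choice(alphabet, size=L, p=p)
        seqs[c] = draw.tobytes().decode("ascii")
    return GenomeAssembly(
        chrom_names=list(chrom_lengths),
        chrom_lengths=dict(chrom_lengths),
        sequence=seqs,
    )


def _lognormal_sizes(rng, mean: float, sd: float, n: int) -> np.ndarray:
    """Lognormal draws parameterized by their arithmetic mean and sd."""
    var = sd**2
    sigma2 = math.log(1 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2
    return np.maximum(1, rng.lognormal(mu, math.sqrt(sigma2), size=n)).astype(np.int64)


def _build_transcript(iv: GenomicInterval, rng, n_exons: int) -> Transcript:
    """Partition a gene span into 5'UTR / exon / intron / 3'UTR intervals."""
    L = len(iv)
    n_exons = max(1, min(n_exons, L // 40))
    n_pieces = 2 * n_exons - 1  # exons alternating with introns
    cuts = np.sort(rng.choice(np.arange(1, L), size=n_pieces - 1, replace=False)) \
        if n_pieces > 1 else np.empty(0, dtype=np.int64)
    edges = np.concatenate([[0], cuts, [L]])
    pieces = [
        GenomicInterval(iv.chrom, iv.start + int(edges[i]), iv.start + int(edges[i + 1]),
                        iv.strand)
        for i in range(n_pieces)
    ]
    exons = pieces[0::2]
    introns = pieces[1::2]
    # carve UTRs off the terminal exons (strand-aware)
    first, last = (exons[0], exons[-1]) if iv.strand == "+" else (exons[-1], exons[0])
    utr5, utr3 = [], []
    core_exons = []
    for ex in exons:
        lo, hi = ex.start, ex.end
        if ex is first:
            w = max(1, min(len(ex) // 5, len(ex) - 1)) if len(ex) > 1 else 0
            if w:
                if iv.strand == "+":
                    utr5.append(GenomicInterval(ex.chrom, lo, lo + w, iv.strand))
                    lo += w
                else:
                    utr5.append(GenomicInterval(ex.chrom, hi - w, hi, iv.strand))
                    hi -= w
        if ex is last and hi > lo:
            w = max(1, min((hi - lo) // 5, hi - lo - 1)) if hi - lo > 1 else 0
            if w:
                if iv.strand == "+":
                    utr3.append(GenomicInterval(ex.chrom, hi - w, hi, iv.strand))
                    hi -= w
                else:
                    utr3.append(GenomicInterval(ex.chrom, lo, lo + w, iv.strand))
                    lo += w
        if hi > lo:
            core_exons.append(GenomicInterval(ex.chrom, lo, hi, iv.strand))
    return Transcript(exons=core_exons, introns=introns, utr5=utr5, utr3=utr3)


def make_annotation(
    assembly: GenomeAssembly,
    n_genes: int = 100,
    gene_length_dist: tuple[float, float] = (20_000, 15_000),
    tad_size_dist: tuple[float, float] = (300_000, 100_000),
    boundary_size_dist: tuple[float, float] = (50_000, 15_000),
    cpg_tss_fraction: float = 0.6,
    cpg_density: float = 1e-5,
    overlap_fraction: float = 0.0,
    id_complete_fraction: float = 1.0,
    seed: int = 0,
) -> Annotation:
    """Random gene models, TAD/boundary tiling and CpG islands.

    Genes are placed without overlap; an extra ``overlap_fraction`` of the
    gene count is then added as deliberately overlapping pairs (half nested,
    half partially overlapping) to exercise the overlap filter.  TADs and
    boundaries alternate and tile each chromosome exactly.
    """
    rng = np.random.default_rng(seed)
    chroms = assembly.chrom_names
    lengths = assembly.chrom_lengths
    total = assembly.total_length

    # --- genes: non-overlapping placement by rejection
    genes: list[GeneModel] = []
    sizes = _lognormal_sizes(rng, *gene_length_dist, n_genes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    probs = np.array([lengths[c] for c in chroms], dtype=float) / total
    gi = 0
    for size in sizes:
        placed = False
        for _ in range(200):
            c = chroms[rng.choice(len(chroms), p=probs)]
            if lengths[c] <= size + 2:
                continue
            start = int(rng.integers(0, lengths[c] - size))
            if all(start + size <= s or start >= e for s, e in occupied[c]):
                occupied[c].append((start, start + size))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(_make_gene(f"gene{gi:04d}", c, start, start + int(size),
                                        strand, rng, id_complete_fraction))
                gi += 1
                placed = True
                break
        if not placed:
            raise ValueError("infeasible gene packing: genome too small/dense")

    # --- deliberately overlapping extra genes
    n_extra = int(round(overlap_fraction * len(genes)))
    base = rng.choice(len(genes), size=n_extra, replace=False) if n_extra else []
    for k, bi in enumerate(base):
        host = genes[bi].interval
        strand = "+" if rng.random() < 0.5 else "-"
        if k % 2 == 0 and len(host) >= 8:  # nested
            s = host.start + len(host) // 4
            e = host.start + (3 * len(host)) // 4
        else:  # partial
            shift = max(1, len(host) // 2)
            s = host.start + shift
            e = min(lengths[host.chrom], host.end + shift)
            if e - s < 2:
                continue
        genes.append(_make_gene(f"gene{gi:04d}", host.chrom, int(s), int(e),
                                strand, rng, id_complete_fraction))
        gi += 1

    # --- TAD / boundary alternating tiling
    tads, boundaries = [], []
    for c in chroms:
        pos, is_boundary = 0, True
        L = lengths[c]
        while pos < L:
            dist = boundary_size_dist if is_boundary else tad_size_dist
            size = int(_lognormal_sizes(rng, *dist, 1)[0])
            end = min(pos + size, L)
            iv = GenomicInterval(c, pos, end)
            (boundaries if is_boundary else tads).append(iv)
            pos = end
            is_boundary = not is_boundary

    # --- CpG islands: near a fraction of TSSs plus random background islands
    cpg = []
    for g in genes:
        if rng.random() < cpg_tss_fraction:
            s = max(0, g.tss - 500)
            e = min(lengths[g.chrom], g.tss + 500)
            if e > s:
                cpg.append(GenomicInterval(g.chrom, s, e))
    for c in chroms:
        n_rand = rng.poisson(cpg_density * lengths[c])
        for _ in range(n_rand):
            s = int(rng.integers(0, max(1, lengths[c] - 1000)))
            cpg.append(GenomicInterval(c, s, min(lengths[c], s + 1000)))

    return Annotation(genes=genes, tads=tads, boundaries=boundaries, cpg_islands=cpg)


def _make_gene(gene_id, chrom, start, end, strand, rng, id_complete_fraction):
    iv = GenomicInterval(chrom, start, end, strand)
    tss, tts = (start, end) if strand == "+" else (end, start)
    tx = _build_transcript(iv, rng, n_exons=1 + int(rng.poisson(3)))
    return GeneModel(
        gene_id=gene_id, interval=iv, tss=tss, tts=tts, transcripts=[tx],
        has_full_ids=bool(rng.random() < id_complete_fraction),
    )


# ---------------------------------------------------------------------------
# feature tracks


@dataclass
class FeatureSpec:
    """Recipe for one synthetic feature track.

    ``bumps`` adds deterministic Gaussian-shaped signal of the given
    amplitude and width (bp) at annotation anchors: 'tss', 'tts',
    'gene_body' (flat over genes), 'cpg', 'interface' (TAD-boundary
    junctions).  ``latent`` mixes in a named shared component with the given
    loading, so that pairs of tracks can carry a controlled correlation.
    """

    name: str
    baseline: float = 0.0
    noise_sd: float = 1.0
    autocorr_length: int = 1000  # bp at which the noise ACF drops to exp(-1/2)
    bumps: list[tuple[str, float, int]] = field(default_factory=list)
    latent: tuple[str, float] | None = None


def _anchor_positions(element: str, annotation: Annotation) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    if element == "tss":
        for g in annotation.genes:
            out.setdefault(g.chrom, []).append(g.tss)
    elif element == "tts":
        for g in annotation.genes:
            out.setdefault(g.chrom, []).append(g.tts)
    elif element == "cpg":
        for iv in annotation.cpg_islands:
            out.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
    elif element == "interface":
        for iv in annotation.tads:
            out.setdefault(iv.chrom, []).extend([iv.start, iv.end])
    else:
        raise ValueError(f"unknown bump anchor {element!r}")
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def _smooth_unit_noise(rng, n_bins: int, sigma_bins: float) -> np.ndarray:
    x = rng.standard_normal(n_bins)
    if sigma_bins > 0:
        x = gaussian_filter1d(x, sigma_bins, mode="reflect")
        s = x.std()
        if s > 0:
            x = x / s
    return x


def make_feature_tracks(
    assembly: GenomeAssembly,
    annotation: Annotation,
    specs: list[FeatureSpec],
    bin_size: int = 100,
    seed: int = 0,
) -> tuple[list[FeatureTrack], dict]:
    """Generate feature tracks and the ground-truth recipe used.

    Noise is Gaussian-smoothed white noise rescaled to unit variance, so the
    autocorrelation is exp(-d^2 / (2 * autocorr_length^2)) and equals
    exp(-1/2) at d = autocorr_length.
    """
    rng = np.random.default_rng(seed)
    latent_names = sorted({s.latent[0] for s in specs if s.latent is not None})
    latents = {
        name: {
            c: _smooth_unit_noise(
                np.random.default_rng(rng.integers(2**31)),
                math.ceil(L / bin_size),
                1000 / bin_size,
            )
            for c, L in assembly.chrom_lengths.items()
        }
        for name in latent_names
    }
    tracks = []
    for spec in specs:
        sigma_bins = spec.autocorr_length / (math.sqrt(2) * bin_size)
        values = {}
        for c, L in assembly.chrom_lengths.items():
            nb = math.ceil(L / bin_size)
            arr = np.full(nb, float(spec.baseline))
            if spec.noise_sd > 0:
                arr += spec.noise_sd * _smooth_unit_noise(rng, nb, sigma_bins)
            if spec.latent is not None:
                name, loading = spec.latent
                arr += loading * latents[name][c]
            centers = (np.arange(nb) + 0.5) * bin_size
            for element, amplitude, width in spec.bumps:
                if element == "gene_body":
                    for g in annotation.genes:
                        if g.chrom != c:
                            continue
                        b0 = g.interval.start // bin_size
                        b1 = (g.interval.end - 1) // bin_size + 1
                        arr[b0:b1] += amplitude
                    continue
                for p in _anchor_positions(element, annotation).get(c, []):
                    lo = max(0, int((p - 4 * width) // bin_size))
                    hi = min(nb, int((p + 4 * width) // bin_size) + 1)
                    d = centers[lo:hi] - p
                    arr[lo:hi] += amplitude * np.exp(-0.5 * (d / width) ** 2)
            values[c] = arr
        tracks.append(FeatureTrack(name=spec.name, bin_size=bin_size, values=values))
    truth = {
        "bin_size": bin_size,
        "seed": seed,
        "features": [
            {
                "name": s.name,
                "baseline": s.baseline,
                "noise_sd": s.noise_sd,
                "autocorr_length": s.autocorr_length,
                "bumps": s.bumps,
                "latent": s.latent,
            }
            for s in specs
        ],
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# integration profiles


def _feature_value_at_scale(track: FeatureTrack, chrom: str,
                            positions: np.ndarray, scale: int) -> np.ndarray:
    if scale <= track.bin_size:
        v = track.value_at(chrom, positions)
    else:
        v = track.window_mean(chrom, positions, scale)
    return np.nan_to_num(v, nan=0.0)


def candidate_sites(
    assembly: GenomeAssembly,
    motif: str | None,
    motif_sites: dict[str, np.ndarray] | None = None,
    mask: dict[str, np.ndarray] | None = None,
    restriction_map: RestrictionMap | None = None,
    max_restriction_distance: int | None = 1000,
) -> dict[str, dict[str, np.ndarray]]:
    """Eligible (position, orientation) pairs per chromosome.

    Returns ``{chrom: {"+": positions, "-": positions}}`` with mappability and
    restriction-recoverability (an upstream cut site within
    ``max_restriction_distance``, strand-aware) already applied.
    """
    from .controls import upstream_restriction_distances

    out = {}
    for c in assembly.chrom_names:
        if motif is not None:
            if motif_sites is None:
                from .genome import find_motif_sites

                motif_sites = find_motif_sites(assembly, motif)
            pos = motif_sites[c]
        else:
            pos = np.arange(assembly.chrom_lengths[c], dtype=np.int64)
        if mask is not None:
            pos = pos[mask[c][pos]]
        per_ori = {}
        for ori in "+-":
            p = pos
            if restriction_map is not None and max_restriction_distance is not None:
                d = upstream_restriction_distances(p, ori, restriction_map.on(c))
                p = p[np.isfinite(d) & (d <= max_restriction_distance)]
            per_ori[ori] = p
        out[c] = per_ori
    return out


def _gene_sense_logp(annotation: Annotation | None, chrom: str,
                     positions: np.ndarray, ori: str,
                     gene_sense_prob: float | None) -> np.ndarray:
    """log P(orientation | position) under the orientation rule."""
    n = len(positions)
    if gene_sense_prob is None or annotation is None:
        return np.full(n, math.log(0.5))
    p_sense = np.full(n, 0.5)
    strands = {}
    for g in annotation.genes:
        if g.chrom == chrom:
            strands[(g.interval.start, g.interval.end)] = g.strand
    sense = np.full(n, False)
    in_gene = np.full(n, False)
    for (s, e), strand in strands.items():
        inside = (positions >= s) & (positions < e)
        in_gene |= inside
        sense[inside] = strand == ori
    p_sense[in_gene] = gene_sense_prob
    p = np.where(in_gene & ~sense, 1 - p_sense, p_sense)
    p[~in_gene] = 0.5
    return np.log(p)


def candidate_log_weights(
    assembly: GenomeAssembly,
    model: BiasModel,
    tracks: dict[str, FeatureTrack] | None = None,
    annotation: Annotation | None = None,
    candidates: dict | None = None,
    mask: dict[str, np.ndarray] | None = None,
    restriction_map: RestrictionMap | None = None,
    max_restriction_distance: int | None = 1000,
):
    """Candidate (site, orientation) pairs with their log sampling weights.

    Returns ``(blocks, positions, logw)`` where ``blocks`` lists
    (chrom, orientation, size) runs concatenated in ``positions``/``logw``.
    Computing this once and passing it as ``weights=`` to repeated
    :func:`simulate_integrations` calls avoids re-evaluating the intensity
    over tens of millions of candidates per draw.
    """
    tracks = tracks or {}
    if candidates is None:
        candidates = candidate_sites(
            assembly, model.motif, mask=mask, restriction_map=restriction_map,
            max_restriction_distance=max_restriction_distance,
        )
    blocks, positions, logw = [], [], []
    for c, per_ori in candidates.items():
        for ori, pos in per_ori.items():
            if pos.size == 0:
                continue
            eta = np.full(pos.size, float(model.baseline), dtype=np.float32)
            for coup in model.coefficients:
                tr = tracks.get(coup.feature)
                if tr is None:
                    raise KeyError(
                        f"bias model references missing track {coup.feature!r}")
                eta += coup.beta * _feature_value_at_scale(
                    tr, c, pos, coup.scale).astype(np.float32)
            eta += _gene_sense_logp(
                annotation, c, pos, ori, model.gene_sense_prob
            ).astype(np.float32)
            blocks.append((c, ori, pos.size))
            positions.append(pos)
            logw.append(eta)
    if not positions:
        raise ValueError("no candidate sites")
    return blocks, np.concatenate(positions), np.concatenate(logw)


def simulate_integrations(
    assembly: GenomeAssembly,
    model: BiasModel,
    n: int,
    tracks: dict[str, FeatureTrack] | None = None,
    annotation: Annotation | None = None,
    restriction_map: RestrictionMap | None = None,
    mask: dict[str, np.ndarray] | None = None,
    max_restriction_distance: int | None = 1000,
    seed: int = 0,
    system: str = "synthetic",
    candidates: dict | None = None,
    weights: tuple | None = None,
) -> IntegrationSet:
    """Draw ``n`` integrations without replacement from the log-linear model.

    Each eligible (site, orientation) pair carries weight
    ``exp(baseline + sum_f beta_f * feature_f(site at scale s_f)) * P(ori)``;
    pairs are drawn without replacement via Gumbel top-k keys, which is an
    exact sequential weighted draw.
    """
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = candidate_log_weights(
            assembly, model, tracks=tracks, annotation=annotation,
            candidates=candidates, mask=mask, restriction_map=restriction_map,
            max_restriction_distance=max_restriction_distance,
        )
    blocks, positions, logw = weights
    if n > positions.size:
        raise ValueError(f"n={n} exceeds candidate count {positions.size}")
    gumbel = rng.gumbel(size=logw.size).astype(np.float32)
    top = np.sort(np.argpartition(-(logw + gumbel), n - 1)[:n])
    # map selected flat indices back to their (chrom, orientation) block
    offsets = np.cumsum([0] + [size for _, _, size in blocks])
    block_of = np.searchsorted(offsets, top, side="right") - 1
    ev = pd.DataFrame(
        {
            "chrom": [blocks[b][0] for b in block_of],
            "position": positions[top],
            "orientation": [blocks[b][1] for b in block_of],
        }
    ).sort_values(["chrom", "position"], kind="mergesort")
    return IntegrationSet(system=system, events=ev, motif=model.motif)


def simulate_tumor_screen(
    assembly: GenomeAssembly,
    truth: ScreenTruth,
    n_tumors: int = 20,
    integrations_per_tumor: int = 15,
    tracks: dict[str, FeatureTrack] | None = None,
    annotation: Annotation | None = None,
    restriction_map: RestrictionMap | None = None,
    mask: dict[str, np.ndarray] | None = None,
    max_restriction_distance: int | None = 1000,
    scatter_sd: int = 5000,
    homogeneity: float = 0.95,
    seed: int = 0,
    system: str = "screen",
    weights: tuple | None = None,
) -> IntegrationSet:
    """Tumor screen = per-tumor biased background + planted selected loci.

    Each tumor receives ``integrations_per_tumor`` background events from the
    truth's bias model (drawn as one batch over all tumors and partitioned,
    which keeps one weight evaluation per screen) and, independently per
    true CIS locus, one selected integration with probability
    ``1 - exp(-strength)``, scattered N(0, ``scatter_sd``) around the locus.
    Activating loci keep a fixed orientation with probability
    ``homogeneity``.
    """
    rng = np.random.default_rng(seed)
    model = truth.background_model
    candidates = candidate_sites(
        assembly, model.motif, mask=mask, restriction_map=restriction_map,
        max_restriction_distance=max_restriction_distance,
    )
    if model.motif is not None:  # planted events snap to eligible motif sites
        motif_positions = {
            c: np.unique(np.concatenate([candidates[c]["+"], candidates[c]["-"]]))
            if (candidates[c]["+"].size or candidates[c]["-"].size)
            else np.empty(0, dtype=np.int64)
            for c in candidates
        }
    else:
        motif_positions = {}
    if weights is None:
        weights = candidate_log_weights(
            assembly, model, tracks=tracks, annotation=annotation,
            candidates=candidates,
        )
    background = simulate_integrations(
        assembly, model, n_tumors * integrations_per_tumor,
        seed=int(rng.integers(2**31)), weights=weights,
    ).events
    background = background.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    frames = []
    for t in range(n_tumors):
        bg = background.iloc[
            t * integrations_per_tumor : (t + 1) * integrations_per_tumor
        ].copy()
        bg["tumor_id"] = t
        rows = [bg]
        for locus in truth.true_cis_loci:
            if rng.random() >= 1 - math.exp(-locus.strength):
                continue
            p = int(round(locus.position + rng.normal(0, scatter_sd)))
            p = int(np.clip(p, 0, assembly.chrom_lengths[locus.chrom] - 1))
            sites = motif_positions.get(locus.chrom)
            if sites is not None and sites.size:
                i = np.searchsorted(sites, p)
                nearest = min(
                    (j for j in (i - 1, i) if 0 <= j < sites.size),
                    key=lambda j: abs(int(sites[j]) - p),
                )
                p = int(sites[nearest])
            if locus.activating and rng.random() < homogeneity:
                ori = locus.orientation
            else:
                ori = locus.orientation if rng.random() < 0.5 else (
                    "-" if locus.orientation == "+" else "+")
                if not locus.activating:
                    ori = "+" if rng.random() < 0.5 else "-"
            rows.append(pd.DataFrame(
                {"chrom": [locus.chrom], "position": [p],
                 "orientation": [ori], "tumor_id": [t]}))
        frames.append(pd.concat(rows, ignore_index=True))
    ev = pd.concat(frames, ignore_index=True)
    ev = ev.drop_duplicates(["tumor_id", "chrom", "position", "orientation"])
    return IntegrationSet(system=system, events=ev, motif=model.motif)
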