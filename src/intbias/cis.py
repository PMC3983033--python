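"""Common-integration-site (CIS) calling and spurious-CIS filtering.

Tumor-screen integrations are smoothed with a Gaussian kernel (sd 30 kb by
default) on a 1 kb evaluation grid; the genome-wide significance threshold
comes from Monte-Carlo null screens of equal size placed uniformly over the
(mappable) genome, with per-grid-point p-values taken against the pooled
null height distribution and Bonferroni correction over grid points.
Called CISs are then tested against a matched unselected profile: a CIS
whose region does not contain significantly more tumor integrations than
unselected integrations (one-sided binomial, BH-FDR) is flagged spurious,
i.e. explainable by intrinsic integration bias rather than selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

from .annotation import RegionSet
from .datasets import Annotation, ControlSet, GeneModel, IntegrationSet
from .genome import GenomeAssembly, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class CISCall:
    """One significant kernel-density peak with its region and annotations."""

    chrom: str
    peak: int
    region: GenomicInterval
    peak_height: float
    call_p: float
    n_cis_integrations: int = 0
    n_unselected_in_region: int = 0
    spurious_p: float = np.nan
    spurious_q: float = np.nan
    spurious: bool | None = None
    activating: bool | None = None
    nearest_tss_gene: str | None = None
    nearest_tss_distance: int | None = None


def _grid_density(positions: np.ndarray, n_grid: int, spacing: int,
                  sigma_bins: float) -> np.ndarray:
    counts = np.bincount(
        np.clip(positions // spacing, 0, n_grid - 1), minlength=n_grid
    ).astype(float)
    return gaussian_filter1d(counts, sigma_bins, mode="constant")


def _uniform_sampler(assembly: GenomeAssembly, mask: dict | None):
    """Returns a function drawing N uniform positions over the (mappable) genome."""
    if mask is not None:
        mappable = {c: np.flatnonzero(mask[c]) for c in assembly.chrom_names}
        sizes = np.array([mappable[c].size for c in assembly.chrom_names], float)
        if sizes.sum() == 0:
            raise ValueError("mask has no mappable positions")
        probs = sizes / sizes.sum()

        def draw(rng, n):
            ci = rng.choice(len(assembly.chrom_names), size=n, p=probs)
            out = {}
            for k, c in enumerate(assembly.chrom_names):
                sel = ci == k
                if sel.any():
                    out[c] = mappable[c][rng.integers(0, mappable[c].size,
                                                      size=int(sel.sum()))]
            return out
    else:
        sizes = np.array([assembly.chrom_lengths[c] for c in assembly.chrom_names],
                         float)
        probs = sizes / sizes.sum()

        def draw(rng, n):
            ci = rng.choice(len(assembly.chrom_names), size=n, p=probs)
            out = {}
            for k, c in enumerate(assembly.chrom_names):
                sel = ci == k
                if sel.any():
                    out[c] = rng.integers(0, assembly.chrom_lengths[c],
                                          size=int(sel.sum()))
            return out
    return draw


def gkc_null_heights(
    n_events: int,
    assembly: GenomeAssembly,
    kernel_sd: int = 30_000,
    grid_spacing: int = 1000,
    null_reps: int = 2000,
    mask: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Pooled kernel-density heights of ``null_reps`` uniform null screens.

    The heights at all grid points of all replicates are exchangeable under
    the uniform null and form the reference distribution for the pointwise
    CIS-call p-values.
    """
    rng = np.random.default_rng(seed)
    draw = _uniform_sampler(assembly, mask)
    sigma_bins = kernel_sd / grid_spacing
    n_grid = {c: int(np.ceil(assembly.chrom_lengths[c] / grid_spacing))
              for c in assembly.chrom_names}
    total = sum(n_grid.values())
    out = np.empty(null_reps * total, dtype=np.float32)
    ofs = 0
    for _ in range(null_reps):
        sample = draw(rng, n_events)
        for c in assembly.chrom_names:
            pos = sample.get(c, np.empty(0, dtype=np.int64))
            out[ofs : ofs + n_grid[c]] = _grid_density(
                pos, n_grid[c], grid_spacing, sigma_bins)
            ofs += n_grid[c]
    return out


def gkc_call(
    tumor_integrations: IntegrationSet,
    assembly: GenomeAssembly,
    kernel_sd: int = 30_000,
    grid_spacing: int = 1000,
    alpha: float = 0.05,
    null_reps: int = 2000,
    mask: dict | None = None,
    dedup_per_tumor: bool = True,
    seed: int = 0,
    null_heights: np.ndarray | None = None,
) -> list[CISCall]:
    """Gaussian-kernel-convolution CIS calling with a Monte-Carlo null.

    The kernel density of tumor integration positions (optionally
    deduplicated per tumor at identical positions) is evaluated on a
    ``grid_spacing`` grid; ``null_reps`` datasets of equal size placed
    uniformly over the mappable genome give the pooled null height
    distribution, and the call threshold is its ``1 - alpha/n_grid``
    quantile (Bonferroni over grid points).  Contiguous super-threshold
    runs merge into one call at their maximum; regions are the runs extended
    by ``kernel_sd`` on either side.

    ``null_heights`` (as produced by :func:`gkc_null_heights` for the same
    event count, genome and kernel) can be passed to reuse one Monte-Carlo
    null across many screens of identical size, e.g. in calibration loops.
    """
    ev = tumor_integrations.events
    if len(ev) == 0:
        raise ValueError("no integrations")
    if dedup_per_tumor and "tumor_id" in ev.columns:
        ev = ev.drop_duplicates(["tumor_id", "chrom", "position"])
    n_events = len(ev)
    if null_reps < 10 / alpha:
        raise ValueError(
            f"null_reps={null_reps} too small to resolve the Bonferroni "
            f"threshold at alpha={alpha}; increase null_reps to >= "
            f"{int(np.ceil(10 / alpha))} or use an analytic null"
        )
    sigma_bins = kernel_sd / grid_spacing
    n_grid_per_chrom = {
        c: int(np.ceil(assembly.chrom_lengths[c] / grid_spacing))
        for c in assembly.chrom_names
    }
    n_grid_total = sum(n_grid_per_chrom.values())

    if null_heights is None:
        null_heights = gkc_null_heights(
            n_events, assembly, kernel_sd=kernel_sd, grid_spacing=grid_spacing,
            null_reps=null_reps, mask=mask, seed=seed)
    null_sorted = np.sort(np.asarray(null_heights))
    threshold = float(np.quantile(null_sorted, 1 - alpha / n_grid_total))

    calls = []
    for c in assembly.chrom_names:
        pos = ev.loc[ev["chrom"] == c, "position"].to_numpy()
        ng = n_grid_per_chrom[c]
        dens = _grid_density(pos, ng, grid_spacing, sigma_bins)
        above = dens > threshold
        if not above.any():
            continue
        edges = np.diff(np.concatenate([[0], above.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            peak_bin = s + int(np.argmax(dens[s:e]))
            height = float(dens[peak_bin])
            # pooled-null pointwise p, Bonferroni over grid points
            tail = null_sorted.size - np.searchsorted(null_sorted, height,
                                                      side="left")
            p_point = (tail + 1) / (null_sorted.size + 1)
            region = GenomicInterval(
                c,
                max(0, int(s * grid_spacing) - kernel_sd),
                min(assembly.chrom_lengths[c],
                    int(e * grid_spacing) + kernel_sd),
            )
            calls.append(CISCall(
                chrom=c,
                peak=int(peak_bin * grid_spacing),
                region=region,
                peak_height=height,
                call_p=float(min(1.0, p_point * n_grid_total)),
            ))
    calls = _merge_overlapping(calls)
    for call in calls:
        in_region = (
            (ev["chrom"] == call.chrom)
            & (ev["position"] >= call.region.start)
            & (ev["position"] < call.region.end)
        )
        call.n_cis_integrations = int(in_region.sum())
    return calls


def _merge_overlapping(calls: list[CISCall]) -> list[CISCall]:
    """Merge calls with overlapping regions (keep the higher peak)."""
    merged: list[CISCall] = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.region.start)):
        if merged and merged[-1].chrom == call.chrom and \
                merged[-1].region.end > call.region.start:
            prev = merged[-1]
            keep = prev if prev.peak_height >= call.peak_height else call
            keep.region = GenomicInterval(
                call.chrom,
                min(prev.region.start, call.region.start),
                max(prev.region.end, call.region.end),
            )
            merged[-1] = keep
            log.info("merged overlapping CIS regions at %s:%d",
                     call.chrom, call.region.start)
        else:
            merged.append(call)
    return merged


def define_cis_regions(
    runs: list[tuple[str, int, int]], kernel_sd: int,
    assembly: GenomeAssembly,
) -> list[GenomicInterval]:
    """Super-threshold runs extended by the kernel sd, clipped to chromosomes."""
    return [
        GenomicInterval(c, max(0, s - kernel_sd),
                        min(assembly.chrom_lengths[c], e + kernel_sd))
        for c, s, e in runs
    ]


def spurious_cis_test(
    calls: list[CISCall],
    unselected: IntegrationSet,
    n_tumor_total: int,
    n_unselected_total: int | None = None,
    fdr_alpha: float = 0.05,
) -> list[CISCall]:
    """One-sided binomial filter for CISs explainable by intrinsic bias.

    Per CIS, n_cis tumor integrations and n_unselected unselected
    integrations fall in the region; the test asks for an excess of tumor
    hits among the region's n_cis + n_unselected hits, with success
    probability p0 = N_tumor / (N_tumor + N_unselected) (the marginal
    chance a region hit originates from the tumor dataset).  Low p = true
    CIS; after BH-FDR across CISs, q >= ``fdr_alpha`` flags the CIS
    spurious.  The test is monotone: more tumor hits never increase p.
    """
    if n_unselected_total is None:
        n_unselected_total = len(unselected)
    uev = unselected.events
    p0 = n_tumor_total / (n_tumor_total + n_unselected_total)
    ps = []
    for call in calls:
        in_region = (
            (uev["chrom"] == call.chrom)
            & (uev["position"] >= call.region.start)
            & (uev["position"] < call.region.end)
        )
        call.n_unselected_in_region = int(in_region.sum())
        k, ntr = call.n_cis_integrations, call.n_cis_integrations + call.n_unselected_in_region
        call.spurious_p = float(stats.binom.sf(k - 1, ntr, p0)) if ntr > 0 else 1.0
        ps.append(call.spurious_p)
    if ps:
        qs = multipletests(ps, method="fdr_bh")[1]
        for call, q in zip(calls, qs):
            call.spurious_q = float(q)
            call.spurious = bool(q >= fdr_alpha)
    return calls


def classify_activating(
    call: CISCall,
    genes: list[GeneModel],
    tumor_integrations: IntegrationSet,
    homogeneity: float = 0.9,
) -> bool:
    """Activating iff the peak is intergenic, or intragenic with >= the
    required orientation homogeneity among region integrations."""
    host = None
    for g in genes:
        if g.interval.contains(call.chrom, call.peak):
            host = g
            break
    if host is None:
        call.activating = True
        return True
    ev = tumor_integrations.events
    in_region = ev[
        (ev["chrom"] == call.chrom)
        & (ev["position"] >= call.region.start)
        & (ev["position"] < call.region.end)
    ]
    if len(in_region) == 0:
        call.activating = True
        return True
    n_plus = int((in_region["orientation"] == "+").sum())
    frac = max(n_plus, len(in_region) - n_plus) / len(in_region)
    call.activating = bool(frac >= homogeneity)
    return call.activating


def annotate_nearest_tss(
    call: CISCall, genes: list[GeneModel], require_full_ids: bool = True
) -> tuple[str | None, int | None]:
    """Nearest-TSS gene for a CIS peak; equidistant ties break on gene id."""
    best = None
    for g in genes:
        if require_full_ids and not g.has_full_ids:
            continue
        if g.chrom != call.chrom:
            continue
        d = abs(g.tss - call.peak)
        if best is None or (d, g.gene_id) < best[:2]:
            best = (d, g.gene_id)
    if best is None:
        call.nearest_tss_gene = None
        call.nearest_tss_distance = None
        return None, None
    call.nearest_tss_gene = best[1]
    call.nearest_tss_distance = int(best[0])
    return best[1], int(best[0])


def tss_density_track(
    genes: list[GeneModel], assembly: GenomeAssembly,
    sd: int = 1_000_000, spacing: int = 1000,
) -> dict[str, np.ndarray]:
    """Genome-wide Gaussian TSS density sampled on a regular grid."""
    out = {}
    for c in assembly.chrom_names:
        ng = int(np.ceil(assembly.chrom_lengths[c] / spacing))
        tss = np.array([g.tss for g in genes if g.chrom == c], dtype=np.int64)
        out[c] = _grid_density(tss, ng, spacing, sd / spacing)
    return out


def tss_density_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    genes: list[GeneModel],
    assembly: GenomeAssembly,
    sd: int = 1_000_000,
    spacing: int = 1000,
    alternative: str = "less",
) -> tuple[float, float]:
    """Mann-Whitney U comparison of local TSS density between two
    integration groups (events as frames with chrom/position columns).

    With ``alternative='less'`` the test asks whether group A (e.g.
    integrations of spurious CISs) sits at LOWER TSS density — farther from
    genes — than group B.
    """
    density = tss_density_track(genes, assembly, sd, spacing)

    def vals(df):
        out = []
        for row in df.itertuples(index=False):
            g = density[row.chrom]
            out.append(g[min(int(round(row.position / spacing)), len(g) - 1)])
        return np.asarray(out)

    a, b = vals(group_a), vals(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def cis_region_bias(
    unselected: IntegrationSet,
    controls: ControlSet,
    cis_regions: list[GenomicInterval],
    genes: list[GeneModel],
    assembly: GenomeAssembly,
    flank: int = 100_000,
) -> pd.DataFrame:
    """Unselected-integration enrichment in CIS regions, per background.

    Backgrounds: genome-wide, genic (union of genes +/- ``flank``), and
    intergenic (the complement).  Within each, the observed unselected count
    inside CIS regions is compared with the expectation from matched
    controls (binomial test; log2 observed/expected ratio).
    """
    ev = unselected.events.loc[controls.kept]
    ctl = controls.control_frame()
    cis_rs = RegionSet(cis_regions)
    genic_ivs = []
    for g in genes:
        genic_ivs.append(GenomicInterval(
            g.chrom, max(0, g.interval.start - flank),
            min(assembly.chrom_lengths[g.chrom], g.interval.end + flank),
        ))
    genic_rs = RegionSet(genic_ivs)

    in_cis_i = cis_rs.contains(ev["chrom"].to_numpy(), ev["position"].to_numpy())
    in_cis_c = cis_rs.contains(ctl["chrom"].to_numpy(), ctl["position"].to_numpy())
    in_gen_i = genic_rs.contains(ev["chrom"].to_numpy(), ev["position"].to_numpy())
    in_gen_c = genic_rs.contains(ctl["chrom"].to_numpy(), ctl["position"].to_numpy())

    rows = []
    for bg, sel_i, sel_c in (
        ("genome", np.ones(len(ev), bool), np.ones(len(ctl), bool)),
        ("genic", in_gen_i, in_gen_c),
        ("intergenic", ~in_gen_i, ~in_gen_c),
    ):
        N_i, N_c = int(sel_i.sum()), int(sel_c.sum())
        k_i = int((in_cis_i & sel_i).sum())
        k_c = int((in_cis_c & sel_c).sum())
        if N_c == 0 or N_i == 0:
            rows.append({"background": bg, "obs": k_i, "ctrl": k_c,
                         "log2_ratio": np.nan, "p": np.nan})
            continue
        frac_c = k_c / N_c
        expct = frac_c * N_i
        lr = float(np.log2(k_i / expct)) if k_i > 0 and expct > 0 else (
            0.0 if k_i == expct else np.nan)
        p = (stats.binomtest(k_i, N_i, frac_c).pvalue if 0 < frac_c < 1
             else (1.0 if k_i == round(frac_c * N_i) else np.nan))
        rows.append({"background": bg, "obs": k_i, "ctrl": k_c,
                     "expected": expct, "log2_ratio": lr, "p": p})
    return pd.DataFrame(rows)


def cis_table(calls: list[CISCall]) -> pd.DataFrame:
    """Supplementary-table-shaped summary of CIS calls."""
    return pd.DataFrame([
        {
            "chr": c.chrom, "start": c.region.start, "end": c.region.end,
            "peak": c.peak, "peak_height": c.peak_height, "call_p": c.call_p,
            "nC": c.n_cis_integrations, "nU": c.n_unselected_in_region,
            "pvalue": c.spurious_p, "qvalue": c.spurious_q,
            "verdict": ("spurious" if c.spurious else "true")
            if c.spurious is not None else "untested",
            "activating": c.activating, "symbol": c.nearest_tss_gene,
        }
        for c in calls
    ])
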