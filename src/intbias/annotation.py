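"""Gene-, transcript-, expression- and TAD-level integration bias.

All bias statistics compare integration counts against matched-control
counts: for a region the enrichment is log2((I/C) * (N_C/N_I)), the
expected in-region fraction under the null is the control fraction, and
significance comes from two-sided binomial tests with Benjamini-Hochberg
FDR across tested cells.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .datasets import Annotation, ControlSet, GeneModel, IntegrationSet
from .genome import GenomeAssembly, GenomicInterval, reverse_complement

log = logging.getLogger(__name__)

REGION_CLASSES = ("genic", "TSS_upstream", "TSS_downstream", "other")
TRANSCRIPT_CLASSES = ("5'UTR", "3'UTR", "exon", "intron")


# ---------------------------------------------------------------------------
# gene filtering


def filter_overlapping_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Drop partially overlapping gene pairs; for nested pairs keep the larger.

    Partial overlap removes BOTH genes of the pair.  For complete overlap
    (one interval containing the other) only the larger is retained; equal
    intervals keep the one with the smaller start, then lexicographically
    smaller id.
    """
    removed = set()
    by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append((i, g))
    for items in by_chrom.values():
        items.sort(key=lambda t: (t[1].interval.start, t[1].interval.end))
        active: list[tuple[int, GeneModel]] = []
        for i, g in items:
            active = [(j, h) for j, h in active if h.interval.end > g.interval.start]
            for j, h in active:
                a, b = g.interval, h.interval
                a_in_b = b.start <= a.start and a.end <= b.end
                b_in_a = a.start <= b.start and b.end <= a.end
                if a_in_b and b_in_a:  # identical spans
                    removed.add(max(i, j, key=lambda k: genes[k].gene_id))
                elif a_in_b:
                    removed.add(i)
                elif b_in_a:
                    removed.add(j)
                else:  # partial overlap: both go
                    removed.add(i)
                    removed.add(j)
            active.append((i, g))
    kept = [g for i, g in enumerate(genes) if i not in removed]
    if removed:
        log.info("filter_overlapping_genes: removed %d/%d genes",
                 len(removed), len(genes))
    return kept


# ---------------------------------------------------------------------------
# region membership helpers


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class RegionSet:
    """A union of (possibly stranded) intervals with fast point membership."""

    def __init__(self, intervals: list[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        self.trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv.strand
            )
        self.merged = {c: _merge(v) for c, v in per_chrom.items()}

    def contains(self, chrom: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=bool)
        chrom = np.asarray(chrom)
        positions = np.asarray(positions)
        for c in np.unique(chrom):
            if c not in self.merged:
                continue
            starts, ends = self.merged[c]
            sel = chrom == c
            idx = np.searchsorted(starts, positions[sel], side="right")
            inside = (idx > 0) & (positions[sel] < ends[np.maximum(idx - 1, 0)])
            out[sel] = inside
        return out

    def strand_at(self, chrom: str, position: int) -> str | None:
        tree = self.trees.get(chrom)
        if tree is None:
            return None
        hits = tree[position]
        if not hits:
            return None
        return sorted(hits)[0].data


def region_class_intervals(
    genes: list[GeneModel], tss_window: int = 1000
) -> dict[str, list[GenomicInterval]]:
    """Stranded interval lists for the gene region classes (classes overlap)."""
    genic, up, down = [], [], []
    for g in genes:
        iv = g.interval
        genic.append(iv)
        if iv.strand == "+":
            if g.tss > 0:
                up.append(GenomicInterval(iv.chrom, max(0, g.tss - tss_window),
                                          g.tss, iv.strand))
            down.append(GenomicInterval(iv.chrom, g.tss, g.tss + tss_window,
                                        iv.strand))
        else:
            up.append(GenomicInterval(iv.chrom, g.tss, g.tss + tss_window,
                                      iv.strand))
            if g.tss > 0:
                down.append(GenomicInterval(iv.chrom, max(0, g.tss - tss_window),
                                            g.tss, iv.strand))
    return {"genic": genic, "TSS_upstream": up, "TSS_downstream": down}


def transcript_class_intervals(
    genes: list[GeneModel],
) -> dict[str, list[GenomicInterval]]:
    out = {c: [] for c in TRANSCRIPT_CLASSES}
    for g in genes:
        for tx in g.transcripts:
            out["5'UTR"].extend(tx.utr5)
            out["3'UTR"].extend(tx.utr3)
            out["exon"].extend(tx.exons)
            out["intron"].extend(tx.introns)
    return out


# ---------------------------------------------------------------------------
# bias statistics


def _class_bias_table(
    integrations: IntegrationSet,
    controls: ControlSet,
    class_intervals: dict[str, list[GenomicInterval]],
    add_other: bool = False,
) -> pd.DataFrame:
    ev = integrations.events
    kept = controls.kept
    ev = ev.loc[kept].reset_index(drop=True)  # compare on events with controls
    ctl = controls.control_frame()
    n_i, n_c = len(ev), len(ctl)
    if n_c == 0:
        raise ValueError("no controls genome-wide")
    rows = []
    in_any_i = np.zeros(n_i, dtype=bool)
    in_any_c = np.zeros(n_c, dtype=bool)
    for cls, ivs in class_intervals.items():
        rs = RegionSet(ivs)
        in_i = rs.contains(ev["chrom"].to_numpy(), ev["position"].to_numpy())
        in_c = rs.contains(ctl["chrom"].to_numpy(), ctl["position"].to_numpy())
        in_any_i |= in_i
        in_any_c |= in_c
        rows.append(_bias_row(cls, ev, ctl, in_i, in_c, rs))
    if add_other:
        rows.append(_bias_row("other", ev, ctl, ~in_any_i, ~in_any_c, None))
    df = pd.DataFrame(rows)
    for col, qcol in (("p", "q"), ("orient_p", "orient_q")):
        ok = df[col].notna()
        df[qcol] = np.nan
        if ok.any():
            df.loc[ok, qcol] = multipletests(df.loc[ok, col], method="fdr_bh")[1]
    return df


def _bias_row(cls, ev, ctl, in_i, in_c, region_set):
    k_i, k_c = int(in_i.sum()), int(in_c.sum())
    n_i, n_c = len(ev), len(ctl)
    frac_c = k_c / n_c
    if k_i > 0 and k_c > 0:
        log2_ratio = float(np.log2((k_i / k_c) * (n_c / n_i)))
    else:
        log2_ratio = np.nan
    p = (
        stats.binomtest(k_i, n_i, min(max(frac_c, 0.0), 1.0)).pvalue
        if 0 < frac_c < 1
        else (1.0 if (frac_c in (0.0, 1.0) and k_i == round(frac_c * n_i)) else np.nan)
    )
    # orientation: sense fraction among in-class events vs in-class controls
    orient_stat = orient_p = np.nan
    k_i_sense = k_c_sense = 0
    if region_set is not None and k_i > 0 and k_c > 0:
        sense_i = _sense_flags(ev, in_i, region_set)
        sense_c = _sense_flags(ctl, in_c, region_set)
        k_i_sense = int(np.nansum(sense_i))
        k_c_sense = int(np.nansum(sense_c))
        n_i_known = int(np.isfinite(sense_i).sum())
        n_c_known = int(np.isfinite(sense_c).sum())
        if n_i_known > 0 and n_c_known > 0:
            p0 = k_c_sense / n_c_known
            orient_stat = k_i_sense / n_i_known - p0
            if 0 < p0 < 1:
                orient_p = stats.binomtest(k_i_sense, n_i_known, p0).pvalue
            elif k_i_sense == round(p0 * n_i_known):
                orient_p = 1.0
    return {
        "region_class": cls, "obs": k_i, "ctrl": k_c, "n_obs": n_i, "n_ctrl": n_c,
        "expected": frac_c * n_i, "log2_ratio": log2_ratio, "p": p,
        "obs_sense": k_i_sense, "ctrl_sense": k_c_sense,
        "orient_stat": orient_stat, "orient_p": orient_p,
    }


def _sense_flags(df, in_class, region_set):
    """1.0 sense / 0.0 antisense / NaN unknown, for in-class events only."""
    out = np.full(int(in_class.sum()), np.nan)
    rows = df.loc[np.asarray(in_class)]
    for k, row in enumerate(rows.itertuples(index=False)):
        strand = region_set.strand_at(row.chrom, row.position)
        if strand in ("+", "-"):
            out[k] = 1.0 if strand == row.orientation else 0.0
    return out


def region_bias(
    integrations: IntegrationSet,
    controls: ControlSet,
    genes: list[GeneModel],
    tss_window: int = 1000,
) -> pd.DataFrame:
    """Enrichment of integrations vs matched controls in gene region classes.

    Classes (which may overlap): genic, within ``tss_window`` bp upstream /
    downstream of a TSS, and 'other' (none of those).
    """
    return _class_bias_table(
        integrations, controls, region_class_intervals(genes, tss_window),
        add_other=True,
    )


def transcript_class_bias(
    integrations: IntegrationSet, controls: ControlSet, genes: list[GeneModel]
) -> pd.DataFrame:
    """As :func:`region_bias`, over 5'UTR / 3'UTR / exon / intron classes."""
    return _class_bias_table(
        integrations, controls, transcript_class_intervals(genes)
    )


# ---------------------------------------------------------------------------
# gene alignment profile


def gene_alignment_profile(
    integrations: IntegrationSet,
    controls: ControlSet,
    genes: list[GeneModel],
    flank: int = 5000,
    n_flank_bins: int = 10,
    n_body_bins: int = 20,
) -> pd.DataFrame:
    """Meta-gene profile of integration enrichment, split by orientation.

    Genes (pre-filtered for overlap) are aligned from ``flank`` bp upstream
    of the TSS, across a length-normalized gene body, to ``flank`` bp
    downstream of the TTS.  Per bin b and orientation o (sense/antisense
    relative to the gene), the profile is
    log2((I_b / C_b) * (N_C / N_I)) using the events and controls of that
    orientation class.  Bins with zero controls are NaN and flagged.
    """
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        lo = max(0, g.interval.start - flank)
        hi = g.interval.end + flank
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, gi)

    nb = 2 * n_flank_bins + n_body_bins

    def _bin_counts(df):
        counts = {"sense": np.zeros(nb), "antisense": np.zeros(nb)}
        totals = {"sense": 0, "antisense": 0}
        for row in df.itertuples(index=False):
            tree = trees.get(row.chrom)
            hits = sorted(tree[row.position]) if tree is not None else []
            if not hits:
                continue
            g = genes[hits[0].data]
            b = _gene_bin(g, row.position, flank, n_flank_bins, n_body_bins)
            if b is None:
                continue
            o = "sense" if row.orientation == g.strand else "antisense"
            counts[o][b] += 1
            totals[o] += 1
        return counts, totals

    ev = integrations.events.loc[controls.kept]
    ci, ti = _bin_counts(ev)
    ctl = controls.control_frame()
    cc, tc = _bin_counts(ctl)
    n_i, n_c = len(ev), len(ctl)
    if n_c == 0:
        raise ValueError("no controls genome-wide")
    rows = []
    for b in range(nb):
        row = {"bin": b, "segment": ("upstream" if b < n_flank_bins else
                                     "body" if b < n_flank_bins + n_body_bins
                                     else "downstream")}
        for o in ("sense", "antisense"):
            i_b, c_b = ci[o][b], cc[o][b]
            if c_b > 0 and i_b > 0:
                row[f"log2_ratio_{o}"] = float(np.log2((i_b / c_b) * (n_c / n_i)))
            else:
                row[f"log2_ratio_{o}"] = np.nan
            row[f"obs_{o}"] = int(i_b)
            row[f"ctrl_{o}"] = int(c_b)
        rows.append(row)
    return pd.DataFrame(rows)


def _gene_bin(g: GeneModel, pos: int, flank: int, n_flank: int, n_body: int):
    iv = g.interval
    if iv.start <= pos < iv.end:
        frac = ((pos - iv.start) / len(iv) if iv.strand == "+"
                else (iv.end - 1 - pos) / len(iv))
        return n_flank + min(int(frac * n_body), n_body - 1)
    if iv.strand == "+":
        d_up, d_dn = iv.start - pos, pos - (iv.end - 1)
    else:
        d_up, d_dn = pos - (iv.end - 1), iv.start - pos
    if 0 < d_up <= flank:
        frac = 1 - d_up / flank
        return min(int(frac * n_flank), n_flank - 1)
    if 0 < d_dn <= flank:
        frac = (d_dn - 1) / flank
        return n_flank + n_body + min(int(frac * n_flank), n_flank - 1)
    return None


# ---------------------------------------------------------------------------
# expression quantiles & trend test


def expression_groups(genes: list[GeneModel], expression: pd.Series,
                      n_quantiles: int = 4) -> pd.Series:
    """Group 0 = zero expression; groups 1..n = quantiles of the rest."""
    expr = expression.reindex([g.gene_id for g in genes]).fillna(0.0)
    groups = pd.Series(0, index=expr.index, dtype=int)
    pos = expr[expr > 0]
    if len(pos):
        qs = np.quantile(pos, np.linspace(0, 1, n_quantiles + 1)[1:-1])
        groups.loc[pos.index] = 1 + np.searchsorted(qs, pos, side="left")
    return groups


def cochran_armitage_trend(table: np.ndarray, scores=None,
                           continuity: bool = False) -> tuple[float, float]:
    """Cochran-Armitage test for trend in a 2 x k count table.

    Row 0 is the 'case' series (integrations), row 1 the reference
    (controls).  Columns with zero total are excluded with a warning.  The
    statistic is the permutation-variance standardized score-weighted excess
    z = U / sqrt(Var U) with a two-sided normal p-value (the classical
    statistic carries no continuity correction and tracks the inclusive
    permutation tail well away from tiny tables).  With integer scores U
    lives on an integer lattice; ``continuity=True`` shrinks |U| by half
    the lattice spacing before standardizing, a conservative option for
    very small tables.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    k = table.shape[1]
    scores = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(
        scores, dtype=float)
    col = table.sum(axis=0)
    keep = col > 0
    if not keep.all():
        warnings.warn("excluding all-zero columns from trend test")
        table, scores, col = table[:, keep], scores[keep], col[keep]
    n1, n2 = table.sum(axis=1)
    N = n1 + n2
    if N == 0 or n1 == 0 or n2 == 0:
        return 0.0, 1.0
    U = float(np.sum(scores * (table[0] - n1 * col / N)))
    var = n1 * n2 * (N * np.sum(col * scores**2) - np.sum(col * scores) ** 2) / (
        N**2 * (N - 1)
    )
    if var <= 0:
        return 0.0, 1.0
    absU = abs(U)
    if continuity and np.allclose(scores, np.round(scores)):
        diffs = np.abs(np.subtract.outer(scores, scores)).astype(np.int64)
        lattice = int(np.gcd.reduce(diffs[diffs > 0])) if (diffs > 0).any() else 0
        absU = max(absU - lattice / 2, 0.0)
    z = np.sign(U) * absU / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def expression_quantile_bias(
    integrations: IntegrationSet,
    controls: ControlSet,
    genes: list[GeneModel],
    expression: pd.Series,
    tss_window: int = 1000,
    n_quantiles: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed/expected integration counts by gene-expression group.

    Genes are split into a zero-expression group plus expression quantiles;
    per region class (genic / TSS_upstream / TSS_downstream) and group,
    integration and control counts are tabulated and a Cochran-Armitage
    trend test (equally spaced scores) is run on the 2 x (1+n_quantiles)
    table.
    """
    groups = expression_groups(genes, expression, n_quantiles)
    ev = integrations.events.loc[controls.kept]
    ctl = controls.control_frame()
    cells = []
    trends = []
    for cls in ("genic", "TSS_upstream", "TSS_downstream"):
        tab = np.zeros((2, n_quantiles + 1))
        for gval in range(n_quantiles + 1):
            sub = [g for g in genes if groups[g.gene_id] == gval]
            ivs = region_class_intervals(sub, tss_window)[cls] if sub else []
            rs = RegionSet(ivs)
            k_i = int(rs.contains(ev["chrom"].to_numpy(),
                                  ev["position"].to_numpy()).sum())
            k_c = int(rs.contains(ctl["chrom"].to_numpy(),
                                  ctl["position"].to_numpy()).sum())
            tab[0, gval], tab[1, gval] = k_i, k_c
            expct = k_c * len(ev) / len(ctl)
            cells.append({
                "region_class": cls, "group": gval, "n_genes": len(sub),
                "obs": k_i, "ctrl": k_c, "expected": expct,
                "log2_ratio": float(np.log2(k_i / expct))
                if k_i > 0 and expct > 0 else np.nan,
            })
        z, p = cochran_armitage_trend(tab)
        trends.append({"region_class": cls, "trend_z": z, "trend_p": p})
    return pd.DataFrame(cells), pd.DataFrame(trends)


# ---------------------------------------------------------------------------
# TAD interfaces


def interface_signed_distances(
    chroms: np.ndarray,
    positions: np.ndarray,
    tads: list[GenomicInterval],
    boundaries: list[GenomicInterval],
) -> np.ndarray:
    """Signed distance of each event to its nearest TAD-boundary interface.

    Positive = into the TAD, negative = into the boundary; events are counted
    only up to the midpoint of their containing element (each event is
    assigned to the interface of its own element half), NaN otherwise.
    """
    out = np.full(len(positions), np.nan)
    for sign, elements in ((+1, tads), (-1, boundaries)):
        for iv in elements:
            sel = (chroms == iv.chrom) & (positions >= iv.start) & (
                positions < iv.end)
            if not sel.any():
                continue
            pos = positions[sel]
            mid = (iv.start + iv.end) / 2
            d = np.where(pos < mid, pos - iv.start, iv.end - pos)
            out[sel] = sign * d
    return out


def tad_interface_profile(
    integrations: IntegrationSet,
    controls: ControlSet,
    tads: list[GenomicInterval],
    boundaries: list[GenomicInterval],
    bin: int = 1000,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Integration enrichment around TAD-boundary interfaces.

    All interfaces are aligned at 0 (negative axis into the boundary,
    positive into the TAD); counting is truncated at the midpoint of each
    element; per bin the value is log2((I_b/C_b) * (N_C/N_I)).
    """
    ev = integrations.events.loc[controls.kept]
    ctl = controls.control_frame()
    d_i = interface_signed_distances(
        ev["chrom"].to_numpy(), ev["position"].to_numpy(), tads, boundaries)
    d_c = interface_signed_distances(
        ctl["chrom"].to_numpy(), ctl["position"].to_numpy(), tads, boundaries)
    n_i, n_c = len(ev), len(ctl)
    if n_c == 0:
        raise ValueError("no controls genome-wide")
    d_i, d_c = d_i[np.isfinite(d_i)], d_c[np.isfinite(d_c)]
    if max_distance is None:
        max_distance = max(
            np.abs(d_i).max() if d_i.size else bin,
            np.abs(d_c).max() if d_c.size else bin,
        )
    edges = np.arange(-(int(max_distance) // bin + 1) * bin,
                      (int(max_distance) // bin + 2) * bin, bin)
    h_i, _ = np.histogram(d_i, bins=edges)
    h_c, _ = np.histogram(d_c, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((h_i / h_c) * (n_c / n_i))
    ratio[(h_i == 0) | (h_c == 0)] = np.nan
    return pd.DataFrame({
        "distance": centers, "obs": h_i, "ctrl": h_c, "log2_ratio": ratio,
    })


def cmh_interface_test(
    integrationsA: IntegrationSet,
    controlsA: ControlSet,
    integrationsB: IntegrationSet,
    controlsB: ControlSet,
    tads: list[GenomicInterval],
    boundaries: list[GenomicInterval],
    window: int = 10_000,
    n_strata: int = 4,
) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel comparison of interface bias between systems.

    Within ``window`` bp on either side of the interface, events are
    stratified by absolute interface distance into ``n_strata`` bins; each
    stratum contributes the 2x2 table
    [[obs_A, ctrl_A], [obs_B, ctrl_B]] of in-stratum counts.  Under the null
    of equal interface enrichment relative to matched controls, the common
    odds ratio is 1 (chi-square without continuity correction).
    """
    edges = np.linspace(0, window, n_strata + 1)

    def counts(int_set, ctl_set):
        ev = int_set.events.loc[ctl_set.kept]
        ctl = ctl_set.control_frame()
        d_e = interface_signed_distances(
            ev["chrom"].to_numpy(), ev["position"].to_numpy(), tads, boundaries)
        d_c = interface_signed_distances(
            ctl["chrom"].to_numpy(), ctl["position"].to_numpy(), tads, boundaries)
        h_e, _ = np.histogram(np.abs(d_e[np.isfinite(d_e)]), bins=edges)
        h_c, _ = np.histogram(np.abs(d_c[np.isfinite(d_c)]), bins=edges)
        return h_e, h_c

    eA, cA = counts(integrationsA, controlsA)
    eB, cB = counts(integrationsB, controlsB)
    tables = []
    for s in range(n_strata):
        t = np.array([[eA[s], cA[s]], [eB[s], cB[s]]], dtype=float)
        if t.sum(axis=1).min() > 0 and t.sum(axis=0).min() > 0:
            tables.append(t)
    if not tables:
        return 0.0, 1.0
    st = StratifiedTable(np.stack(tables, axis=-1))
    res = st.test_null_odds(correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# motif fraction


def motif_fraction(
    integrations: IntegrationSet, assembly: GenomeAssembly, motif: str
) -> tuple[float, pd.Series]:
    """Fraction of integrations whose site sequence is the canonical motif.

    The site sequence is the ``len(motif)``-mer starting at the integration
    position (reverse-complemented for '-' events of non-palindromic
    motifs).  Returns the on-motif fraction and a tally of the off-motif
    sequences observed.
    """
    if len(integrations) == 0:
        raise ValueError("empty integration set")
    seqs = assembly.require_sequence()
    k = len(motif)
    rc_needed = reverse_complement(motif) != motif
    observed = []
    for row in integrations.events.itertuples(index=False):
        s = seqs[row.chrom][row.position : row.position + k]
        if len(s) < k:
            s = s.ljust(k, "N")
        if rc_needed and row.orientation == "-":
            s = reverse_complement(s)
        observed.append(s)
    observed = pd.Series(observed)
    frac = float((observed == motif).mean())
    return frac, observed[observed != motif].value_counts()
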