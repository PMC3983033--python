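"""Multi-scale association of integration proximity with feature tracks.

For every feature, scores are taken in a small window (default 200 bp) at
each locus and at exponentially increasing distances (scales) up- and
downstream; after per-feature rank normalization, a two-sample t-score
compares the at-site scores with the scale-s scores.  The same statistic
computed on each of the m matched-control pseudo-datasets yields the
control-adjusted statistic T = Z_I - mean_j(Z_Cj), which under the null is
Normal(0, sqrt(1 + 1/m)); that analytic null gives the p-values, with
Benjamini-Hochberg FDR over the feature x scale matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ContactMatrix, ControlSet, IntegrationSet
from .tracks import FeatureTrack

log = logging.getLogger(__name__)


def default_scales(base: int = 100, factor: int = 2, count: int = 15) -> np.ndarray:
    """Exponential scale grid: base * factor**k for k = 0..count-1 (bp)."""
    return base * factor ** np.arange(count, dtype=np.int64)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScaleScoreMatrix:
    """Per-locus feature scores at distance 0 and at each scale.

    ``scores`` has shape (n_loci, 1 + n_scales): column 0 is the mean track
    value in the window centered at the locus; column k is the mean of the
    two window means centered ``scales[k-1]`` bp up- and downstream
    (edge-truncated windows fall back to the available side).
    """

    feature: str
    scales: np.ndarray
    scores: np.ndarray
    window: int = 200

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=np.int64)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")


def score_at_scales(
    chroms: np.ndarray,
    positions: np.ndarray,
    track: FeatureTrack,
    scales: np.ndarray,
    window: int = 200,
) -> ScaleScoreMatrix:
    """Window-mean feature scores at each locus, at distance 0 and each scale."""
    scales = np.asarray(scales, dtype=np.int64)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    scores = np.full((n, 1 + len(scales)), np.nan)
    for c in np.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        pos = positions[sel]
        scores[sel, 0] = track.window_mean(c, pos, window)
        for k, s in enumerate(scales):
            up = track.window_mean(c, pos - s, window)
            dn = track.window_mean(c, pos + s, window)
            both = np.nanmean(np.stack([up, dn]), axis=0)
            scores[sel, k + 1] = both
    return ScaleScoreMatrix(feature=track.name, scales=scales, scores=scores,
                            window=window)


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Map finite values to (0, 1] by average rank / count; NaN preserved."""
    flat = np.asarray(values, dtype=float)
    out = np.full(flat.shape, np.nan)
    ok = np.isfinite(flat)
    n = int(ok.sum())
    if n:
        out[ok] = stats.rankdata(flat[ok]) / n
    return out


# ---------------------------------------------------------------------------
# the control-adjusted statistic


def tscore(a: np.ndarray, b: np.ndarray, ddof: int = 1) -> np.ndarray | float:
    """Two-sample t-score (common n): (mean a - mean b) / sqrt((var a + var b)/n).

    Accepts 1-D samples or stacked 2-D arrays (..., n) compared along the
    last axis.  Degenerate zero-variance comparisons return signed inf (mean
    difference nonzero) or 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("samples must have equal n")
    n = a.shape[-1]
    # NaN-free inputs take the fast (non-masked) reductions
    if np.isnan(a).any() or np.isnan(b).any():
        mean, var = np.nanmean, np.nanvar
    else:
        mean, var = np.mean, np.var
    with np.errstate(invalid="ignore", divide="ignore"):
        num = mean(a, axis=-1) - mean(b, axis=-1)
        den = np.sqrt((var(a, axis=-1, ddof=ddof)
                       + var(b, axis=-1, ddof=ddof)) / n)
        t = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                     np.sign(num) * np.inf)
        t = np.where((den == 0) & (num == 0), 0.0, t)
    return float(t) if t.ndim == 0 else t


def adjusted_T(
    t_integrations: np.ndarray | float, t_controls: np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Control-adjusted statistic and its analytic two-sided p-value.

    T = Z_I - mean_j(Z_Cj).  With Z_I and the m control scores independent
    standard normal under the null, T ~ Normal(0, sqrt(1 + 1/m)).
    ``t_controls``'s last axis indexes the m control sets.
    """
    t_i = np.asarray(t_integrations, dtype=float)
    t_c = np.asarray(t_controls, dtype=float)
    m = t_c.shape[-1]
    T = t_i - t_c.mean(axis=-1)
    sd = np.sqrt(1 + 1 / m)
    p = 2 * stats.norm.sf(np.abs(T) / sd)
    if T.ndim == 0:
        return float(T), float(p)
    return T, p


@dataclass
class ScaleAssociationResult:
    """Feature x scale matrices of the control-adjusted statistic."""

    scales: np.ndarray
    T: pd.DataFrame  # features x scales
    p: pd.DataFrame
    q: pd.DataFrame
    smallest_significant_scale: pd.Series = None
    alpha: float = 0.05

    def __post_init__(self):
        if self.smallest_significant_scale is None:
            sss = {}
            for f in self.q.index:
                sig = self.q.loc[f] < self.alpha
                sss[f] = float(self.q.columns[sig.to_numpy()][0]) if sig.any() else np.nan
            self.smallest_significant_scale = pd.Series(sss)


def scale_association(
    integrations: IntegrationSet,
    controls: ControlSet,
    tracks: list[FeatureTrack],
    scales: np.ndarray | None = None,
    window: int = 200,
    alpha: float = 0.05,
    ddof: int = 1,
) -> ScaleAssociationResult:
    """Full control-adjusted association pipeline over features and scales.

    Per feature: score integrations and each of the m control pseudo-datasets
    at all scales, rank-normalize pooled over all loci and scales of that
    feature, compute the at-site vs at-scale t-score for each dataset, form
    T = Z_I - mean(Z_Cj) with its analytic normal p-value, and apply BH-FDR
    jointly over the feature x scale matrix.
    """
    scales = default_scales() if scales is None else np.asarray(scales, np.int64)
    ev = integrations.events.loc[controls.kept]
    chroms_i = ev["chrom"].to_numpy()
    pos_i = ev["position"].to_numpy()
    m = controls.m
    T_rows, p_rows = [], []
    for track in tracks:
        ssm_i = score_at_scales(chroms_i, pos_i, track, scales, window)
        ssm_c = [
            score_at_scales(
                chroms_i, controls.positions[controls.kept, j], track, scales, window
            )
            for j in range(m)
        ]
        pooled = np.concatenate([ssm_i.scores.ravel()]
                                + [s.scores.ravel() for s in ssm_c])
        ranked = rank_normalize(pooled)
        size = ssm_i.scores.size
        r_i = ranked[:size].reshape(ssm_i.scores.shape)
        r_c = [
            ranked[size * (j + 1) : size * (j + 2)].reshape(ssm_i.scores.shape)
            for j in range(m)
        ]
        T_s, p_s = [], []
        for k in range(len(scales)):
            t_i = tscore(r_i[:, 0], r_i[:, k + 1], ddof=ddof)
            t_c = np.array([tscore(r[:, 0], r[:, k + 1], ddof=ddof) for r in r_c])
            if not np.isfinite(t_i) or not np.all(np.isfinite(t_c)):
                T_s.append(np.nan)  # degenerate zero-variance cell
                p_s.append(np.nan)
                continue
            T, p = adjusted_T(t_i, t_c)
            T_s.append(T)
            p_s.append(p)
        T_rows.append(T_s)
        p_rows.append(p_s)
    names = [t.name for t in tracks]
    T = pd.DataFrame(T_rows, index=names, columns=scales.astype(float))
    P = pd.DataFrame(p_rows, index=names, columns=scales.astype(float))
    Q = P.copy()
    flat = P.to_numpy().ravel()
    ok = np.isfinite(flat)
    qf = np.full(flat.shape, np.nan)
    if ok.any():
        qf[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    Q.iloc[:, :] = qf.reshape(P.shape)
    return ScaleAssociationResult(scales=scales, T=T, p=P, q=Q, alpha=alpha)


def classify_macro_micro(
    smallest_scales: dict[str, pd.Series]
) -> pd.DataFrame:
    """Label features macro / micro from their smallest significant scales.

    Per system, each feature's smallest significant scale is rank-normalized
    across features; a feature is a macrofeature if its rank exceeds the
    cross-feature mean rank in EVERY system, a microfeature if it is at or
    below the mean in every system, and 'none' if it is never significant in
    some system (no label can then be assigned).
    """
    systems = list(smallest_scales)
    features = smallest_scales[systems[0]].index
    ranks = {}
    for s in systems:
        sss = smallest_scales[s]
        r = pd.Series(np.nan, index=features)
        ok = sss.notna()
        if ok.any():
            r[ok] = stats.rankdata(sss[ok]) / ok.sum()
        ranks[s] = r
    labels = []
    for f in features:
        rs = [ranks[s][f] for s in systems]
        if any(not np.isfinite(r) for r in rs):
            labels.append("none")
        elif all(r > np.nanmean(ranks[s]) for r, s in zip(rs, systems)):
            labels.append("macrofeature")
        elif all(r <= np.nanmean(ranks[s]) for r, s in zip(rs, systems)):
            labels.append("microfeature")
        else:
            labels.append("none")
    out = pd.DataFrame({"label": labels}, index=features)
    for s in systems:
        out[f"rank_{s}"] = ranks[s]
    return out


# ---------------------------------------------------------------------------
# feature orientation bias


def orientation_bias(
    integrations: IntegrationSet,
    tracks: list[FeatureTrack],
    window: int = 200,
    ddof: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Up- vs downstream feature asymmetry around oriented integrations.

    Per feature, rank-normalized window means immediately upstream
    ([pos-window, pos), in the event's orientation) are compared with the
    downstream window by the two-sample t-score; positive t means higher
    signal upstream.  The summary is (fraction of features with positive t)
    - 0.5 with a two-sided binomial p over features.
    """
    ev = integrations.events
    chroms = ev["chrom"].to_numpy()
    pos = ev["position"].to_numpy()
    plus = (ev["orientation"] == "+").to_numpy()
    rows = []
    for track in tracks:
        up = np.full(len(ev), np.nan)
        dn = np.full(len(ev), np.nan)
        for c in np.unique(chroms):
            sel = chroms == c
            left = track.window_mean(c, pos[sel] - (window - window // 2), window)
            right = track.window_mean(c, pos[sel] + (window - window // 2), window)
            p_sel = plus[sel]
            up[sel] = np.where(p_sel, left, right)
            dn[sel] = np.where(p_sel, right, left)
        pooled = rank_normalize(np.concatenate([up, dn]))
        t = tscore(pooled[: len(ev)], pooled[len(ev):], ddof=ddof)
        rows.append({"feature": track.name, "t": t})
    df = pd.DataFrame(rows).set_index("feature")
    finite = df["t"].dropna()
    n_pos = int((finite > 0).sum())
    n_feat = len(finite)
    summary = {
        "fraction_positive_minus_half": n_pos / n_feat - 0.5 if n_feat else np.nan,
        "p": stats.binomtest(n_pos, n_feat, 0.5).pvalue if n_feat else np.nan,
        "n_features": n_feat,
    }
    return df, summary


def orientation_bias_strata(
    integrations: IntegrationSet,
    tracks: list[FeatureTrack],
    genes,
    window: int = 200,
) -> dict[str, tuple[pd.DataFrame, dict]]:
    """Feature orientation bias within TSS-orientation strata.

    Events are stratified by their orientation relative to the gene with
    the nearest TSS ('sense_tss' / 'antisense_tss'), plus the unstratified
    'all'; each stratum gets its own :func:`orientation_bias` result, so a
    global asymmetry can be separated from one explained by gene
    orientation.
    """
    ev = integrations.events
    tss = {}
    for g in genes:
        tss.setdefault(g.chrom, []).append((g.tss, g.strand))
    nearest_strand = np.full(len(ev), "", dtype=object)
    for c, pairs in tss.items():
        pairs.sort()
        pos_arr = np.array([p for p, _ in pairs])
        strands = np.array([s for _, s in pairs])
        sel = np.flatnonzero((ev["chrom"] == c).to_numpy())
        if sel.size == 0:
            continue
        p = ev["position"].to_numpy()[sel]
        idx = np.searchsorted(pos_arr, p)
        left = np.clip(idx - 1, 0, len(pos_arr) - 1)
        right = np.clip(idx, 0, len(pos_arr) - 1)
        pick = np.where(
            np.abs(pos_arr[left] - p) <= np.abs(pos_arr[right] - p),
            left, right)
        nearest_strand[sel] = strands[pick]
    sense = nearest_strand == ev["orientation"].to_numpy()
    known = nearest_strand != ""
    out = {"all": orientation_bias(integrations, tracks, window)}
    for label, mask in (("sense_tss", sense & known),
                        ("antisense_tss", ~sense & known)):
        if mask.sum() < 2:
            continue
        sub = IntegrationSet(
            integrations.system,
            ev.loc[mask].reset_index(drop=True),
            motif=integrations.motif,
        )
        out[label] = orientation_bias(sub, tracks, window)
    return out


def cluster_profiles(T: pd.DataFrame) -> np.ndarray:
    """Hierarchical clustering (euclidean, Ward) of feature association
    profiles across scales; returns the scipy linkage matrix.  Display
    utility only — no statistics depend on it."""
    from scipy.cluster import hierarchy

    mat = T.fillna(0.0).to_numpy()
    return hierarchy.linkage(mat, method="ward", metric="euclidean")


# ---------------------------------------------------------------------------
# Hi-C contact decay exponent


def hic_alpha(
    matrix: ContactMatrix, locus: int, window: int = 400_000
) -> float:
    """Local contact-decay exponent (slope of log10 contact vs log10 distance).

    Contacts of the locus's bin with bins within ``window`` bp on either
    side are averaged per distance; zero-contact distances are excluded (and
    counted in the log); the slope of the OLS fit of log10 mean contact on
    log10 distance is returned.  More negative slopes mean faster decay
    (more compact local chromatin).
    """
    b = int(locus) // matrix.bin_size
    if not 0 <= b < matrix.n_bins:
        raise ValueError("locus outside matrix")
    w = int(window) // matrix.bin_size
    dists, contacts = [], []
    for d in range(1, w + 1):
        vals = []
        if b - d >= 0:
            vals.append(matrix.matrix[b, b - d])
        if b + d < matrix.n_bins:
            vals.append(matrix.matrix[b, b + d])
        if vals:
            dists.append(d * matrix.bin_size)
            contacts.append(float(np.mean(vals)))
    dists = np.asarray(dists, dtype=float)
    contacts = np.asarray(contacts, dtype=float)
    keep = contacts > 0
    n_zero = int((~keep).sum())
    if n_zero:
        log.debug("hic_alpha: excluded %d zero-contact distance bins", n_zero)
    if keep.sum() < 2:
        return np.nan
    slope = np.polyfit(np.log10(dists[keep]), np.log10(contacts[keep]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# analytic-null calibration (Monte Carlo)


def null_calibration(
    n: int = 10_000,
    m: int = 10,
    n_cells: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    batch: int = 50,
) -> dict:
    """Monte-Carlo calibration of the control-adjusted statistic's null.

    Simulates ``n_cells`` independent feature-scale cells: per cell, at-site
    and at-scale rank scores are i.i.d. (exchangeable null) for the
    integration set and each of the m control sets; T is computed through
    :func:`tscore` and :func:`adjusted_T`.  Returns the empirical Var(T)
    (theory: 1 + 1/m) and the two-sided rejection rate at ``alpha``
    (theory: alpha).
    """
    rng = np.random.default_rng(seed)
    sd = np.sqrt(1 + 1 / m)
    crit = stats.norm.isf(alpha / 2) * sd
    Ts = np.empty(n_cells)
    done = 0
    while done < n_cells:
        nb = min(batch, n_cells - done)
        a = rng.random((nb, 1 + m, n), dtype=np.float32)
        b = rng.random((nb, 1 + m, n), dtype=np.float32)
        t = tscore(a, b)  # (nb, 1+m)
        T, _ = adjusted_T(t[:, 0], t[:, 1:])
        Ts[done : done + nb] = T
        done += nb
    return {
        "var_T": float(np.var(Ts)),
        "rejection_rate": float(np.mean(np.abs(Ts) > crit)),
        "n_cells": n_cells,
        "expected_var": 1 + 1 / m,
        "alpha": alpha,
    }
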