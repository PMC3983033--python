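"""Matched random controls for integration sets.

Each integration is matched to ``m`` random loci that (i) carry the
system-specific motif where one exists, (ii) lie at the same distance to
the nearest upstream restriction site as the integration (within a
configurable tolerance, default exact), and (iii) fall in uniquely
mappable sequence.  "Upstream" is taken relative to the event's
orientation by default; an orientation-agnostic (absolute-left) mode is
available for sonication-based protocols where no restriction constraint
applies.
"""

from __future__ import annotations

import logging

import numpy as np

from .datasets import ControlSet, IntegrationSet
from .genome import GenomeAssembly, RestrictionMap

log = logging.getLogger(__name__)


def upstream_restriction_distances(
    positions: np.ndarray, orientation: str, sites: np.ndarray
) -> np.ndarray:
    """Distance to the nearest restriction site on the 5' side of each event.

    For '+' events the 5' side is lower coordinates (distance = position -
    nearest site <= position); for '-' events it is mirrored.  Events with no
    upstream site get +inf (flagged undefined).
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    sites = np.asarray(sites, dtype=np.int64)
    out = np.full(positions.shape, np.inf)
    if sites.size == 0:
        return out
    if orientation == "+":
        idx = np.searchsorted(sites, positions, side="right")
        has = idx > 0
        out[has] = positions[has] - sites[idx[has] - 1]
    elif orientation == "-":
        idx = np.searchsorted(sites, positions, side="left")
        has = idx < sites.size
        out[has] = sites[idx[has]] - positions[has]
    else:
        raise ValueError(f"invalid orientation {orientation!r}")
    return out


def upstream_restriction_distance(
    position: int, orientation: str, rmap: RestrictionMap, chrom: str,
    assembly: GenomeAssembly | None = None,
) -> float:
    """Scalar convenience wrapper; inf when no upstream site exists."""
    if assembly is not None:
        L = assembly.chrom_lengths[chrom]
        if not 0 <= position < L:
            raise ValueError(f"position {position} outside {chrom} (length {L})")
    return float(
        upstream_restriction_distances(
            np.array([position]), orientation, rmap.on(chrom)
        )[0]
    )


def enumerate_eligible_loci(
    position: int,
    orientation: str,
    chrom: str,
    candidate_sites: dict[str, np.ndarray],
    rmap: RestrictionMap | None,
    mask: dict[str, np.ndarray] | None,
    tolerance: int = 0,
    exclude_self: bool = True,
) -> np.ndarray:
    """All loci on the event's chromosome eligible as its matched controls.

    Candidates are the motif sites (or every position, for motif-free
    systems) that are mappable and whose upstream restriction distance
    matches the event's within ``tolerance``; the event's own locus is
    excluded.
    """
    cand = np.asarray(candidate_sites[chrom], dtype=np.int64)
    if mask is not None:
        cand = cand[mask[chrom][cand]]
    if rmap is not None:
        d_event = upstream_restriction_distances(
            np.array([position]), orientation, rmap.on(chrom)
        )[0]
        if not np.isfinite(d_event):
            return np.empty(0, dtype=np.int64)
        d = upstream_restriction_distances(cand, orientation, rmap.on(chrom))
        cand = cand[np.abs(d - d_event) <= tolerance]
    if exclude_self:
        cand = cand[cand != position]
    return cand


def sample_matched_controls(
    integrations: IntegrationSet,
    candidate_sites: dict[str, np.ndarray],
    rmap: RestrictionMap | None = None,
    mask: dict[str, np.ndarray] | None = None,
    m: int = 10,
    tolerance: int = 0,
    seed: int = 0,
    on_insufficient: str = "replace",  # or "drop"
    exclude_self: bool = True,
) -> ControlSet:
    """Draw ``m`` matched random controls per integration.

    Controls are uniform over each event's eligible loci, drawn without
    replacement when the eligible set allows it and with replacement (with a
    warning) otherwise, unless ``on_insufficient='drop'``; events with an
    empty eligible set are always dropped and reported.  Control orientation
    is copied from the event.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if on_insufficient not in ("replace", "drop"):
        raise ValueError("on_insufficient must be 'replace' or 'drop'")
    rng = np.random.default_rng(seed)
    ev = integrations.events
    n = len(ev)
    positions = np.zeros((n, m), dtype=np.int64)
    kept = np.ones(n, dtype=bool)
    with_repl = np.zeros(n, dtype=bool)
    sizes = np.zeros(n, dtype=np.int64)

    # group events by (chrom, orientation) and bucket candidate distances once
    for (chrom, ori), grp in ev.groupby(["chrom", "orientation"], sort=False):
        cand = np.asarray(candidate_sites[chrom], dtype=np.int64)
        if mask is not None:
            cand = cand[mask[chrom][cand]]
        pos = grp["position"].to_numpy()
        if rmap is not None:
            sites = rmap.on(chrom)
            d_cand = upstream_restriction_distances(cand, ori, sites)
            finite = np.isfinite(d_cand)
            cand, d_cand = cand[finite], d_cand[finite]
            order = np.argsort(d_cand, kind="mergesort")
            cand, d_cand = cand[order], d_cand[order]
            d_event = upstream_restriction_distances(pos, ori, sites)
            lo = np.searchsorted(d_cand, d_event - tolerance, side="left")
            hi = np.searchsorted(d_cand, d_event + tolerance, side="right")
        else:
            cand = np.sort(cand)
            lo = np.zeros(pos.size, dtype=np.int64)
            hi = np.full(pos.size, cand.size, dtype=np.int64)
            d_event = np.zeros(pos.size)
        # distance-unconstrained systems share one (possibly huge) eligible
        # set; rejection-sample indices instead of materializing copies
        if rmap is None and cand.size > 100 * m:
            for k, row in enumerate(grp.index):
                i = np.searchsorted(cand, pos[k])
                has_self = exclude_self and i < cand.size and cand[i] == pos[k]
                sizes[row] = cand.size - int(has_self)
                picked: list[int] = []
                seen: set[int] = set()
                while len(picked) < m:
                    for p in cand[rng.integers(0, cand.size, size=2 * m)]:
                        if (exclude_self and p == pos[k]) or p in seen:
                            continue
                        seen.add(int(p))
                        picked.append(int(p))
                        if len(picked) == m:
                            break
                positions[row] = picked
            continue
        for k, row in enumerate(grp.index):
            if not np.isfinite(d_event[k]):
                kept[row] = False
                continue
            elig = cand[lo[k]:hi[k]]
            if exclude_self:
                elig = elig[elig != pos[k]]
            sizes[row] = elig.size
            if elig.size == 0:
                kept[row] = False
            elif elig.size >= m:
                positions[row] = rng.choice(elig, size=m, replace=False)
            elif on_insufficient == "replace":
                positions[row] = rng.choice(elig, size=m, replace=True)
                with_repl[row] = True
            else:
                kept[row] = False

    n_drop = int((~kept).sum())
    if n_drop:
        log.warning("%d/%d events dropped (empty eligible set)", n_drop, n)
    if with_repl.any():
        log.warning("%d events drew controls with replacement (eligible < m)",
                    int(with_repl.sum()))
    return ControlSet(
        parent=integrations, m=m, positions=positions, kept=kept,
        eligible_sizes=sizes, with_replacement=with_repl,
    )


def validate_controls(
    control_set: ControlSet,
    motif_sites: dict[str, np.ndarray] | None,
    rmap: RestrictionMap | None,
    mask: dict[str, np.ndarray] | None,
    tolerance: int = 0,
) -> dict:
    """Check every emitted control against the three matching constraints.

    Returns per-constraint violation counts; all zeros means the control set
    is valid.
    """
    ev = control_set.parent.events
    bad_motif = bad_dist = bad_map = 0
    m = control_set.m
    sorted_sites = (
        {c: np.sort(s) for c, s in motif_sites.items()}
        if motif_sites is not None else None
    )
    for (chrom, ori), grp in ev.groupby(["chrom", "orientation"], sort=False):
        rows = grp.index[control_set.kept[grp.index]]
        if rows.size == 0:
            continue
        ctl = control_set.positions[rows].ravel()
        if sorted_sites is not None:
            ss = sorted_sites[chrom]
            idx = np.searchsorted(ss, ctl)
            hit = (idx < ss.size) & (ss[np.minimum(idx, ss.size - 1)] == ctl)
            bad_motif += int((~hit).sum())
        if mask is not None:
            bad_map += int((~mask[chrom][ctl]).sum())
        if rmap is not None:
            sites = rmap.on(chrom)
            d_event = upstream_restriction_distances(
                ev.loc[rows, "position"].to_numpy(), ori, sites)
            d_ctl = upstream_restriction_distances(ctl, ori, sites).reshape(
                rows.size, m)
            bad_dist += int((np.abs(d_ctl - d_event[:, None]) > tolerance).sum())
    return {
        "n_events_checked": int(control_set.kept.sum()),
        "motif_violations": bad_motif,
        "distance_violations": bad_dist,
        "mappability_violations": bad_map,
    }
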