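"""Conditional-independence analysis of integration proximity.

Feature scores at integration and control loci are discretized into
tertiles and joined with a binary integration-proximity indicator; discrete
Bayesian-network structures are learned by an annealed hill-climber over
add/delete/reverse edge moves maximizing a decomposable score (BDeu by
default, BIC optionally).  Bootstrapped structure learning yields, per
feature, the fraction of bootstraps in which it enters the indicator's
Markov blanket (confidence) and the mean conditional mutual information
with the indicator given the rest of the blanket (strength).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing


def normalize_by_controls(
    values: np.ndarray,
    control_values: np.ndarray,
    log_scale: bool = False,
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """Normalize per-integration scores by their matched-control mean.

    Ratio mode divides by the control mean (zero means replaced by
    ``pseudocount``, logged); ``log_scale=True`` subtracts instead, for
    features already on a log scale.
    """
    values = np.asarray(values, dtype=float)
    ctrl_mean = np.nanmean(np.asarray(control_values, dtype=float), axis=1)
    if log_scale:
        return values - ctrl_mean
    zero = ctrl_mean == 0
    if zero.any():
        log.warning("normalize_by_controls: %d zero control means -> pseudocount",
                    int(zero.sum()))
        ctrl_mean = np.where(zero, pseudocount, ctrl_mean)
    return values / ctrl_mean


def discretize_tertiles(values: np.ndarray) -> np.ndarray:
    """Empirical-tertile codes {0,1,2}; ties go deterministically to the lower bin."""
    values = np.asarray(values, dtype=float)
    q1, q2 = np.nanquantile(values, [1 / 3, 2 / 3])
    codes = np.full(values.shape, 2, dtype=np.int8)
    codes[values <= q2] = 1
    codes[values <= q1] = 0
    if q1 == q2:
        log.warning("discretize_tertiles: degenerate cut points (heavy ties)")
    return codes


@dataclass
class DiscreteDataset:
    """Loci x variables matrix of discrete codes.

    Columns are features (tertile codes 0..2) plus one binary
    integration-proximity indicator (1 = integration locus, 0 = matched
    control locus).
    """

    data: pd.DataFrame
    indicator: str = "integration"

    def __post_init__(self):
        if self.indicator not in self.data.columns:
            raise ValueError(f"missing indicator column {self.indicator!r}")
        self.data = self.data.astype(np.int8).reset_index(drop=True)
        self.arities = {
            c: int(self.data[c].max()) + 1 for c in self.data.columns
        }
        if (self.data < 0).any().any():
            raise ValueError("negative codes")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def build_discrete_dataset(
    integration_scores: pd.DataFrame,
    control_scores: pd.DataFrame,
    indicator: str = "integration",
) -> DiscreteDataset:
    """Pool integration and control loci rows and tertile-discretize features.

    Discretization cut points are taken on the pooled rows, so the indicator
    stays informative; the alternative preprocessing (per-integration
    control normalization via :func:`normalize_by_controls`) can be applied
    to ``integration_scores`` beforehand.
    """
    feats = list(integration_scores.columns)
    if list(control_scores.columns) != feats:
        raise ValueError("feature columns differ between rows kinds")
    pooled = pd.concat([integration_scores, control_scores], ignore_index=True)
    codes = {f: discretize_tertiles(pooled[f].to_numpy()) for f in feats}
    codes[indicator] = np.concatenate(
        [np.ones(len(integration_scores), dtype=np.int8),
         np.zeros(len(control_scores), dtype=np.int8)]
    )
    return DiscreteDataset(pd.DataFrame(codes), indicator=indicator)


# ---------------------------------------------------------------------------
# scores


def _family_counts(child: np.ndarray, parents: list[np.ndarray],
                   r: int, q_arities: list[int]) -> np.ndarray:
    """Contingency counts N_jk (parent config j, child state k)."""
    q = int(np.prod(q_arities)) if q_arities else 1
    idx = np.zeros(len(child), dtype=np.int64)
    for p, a in zip(parents, q_arities):
        idx = idx * a + p
    flat = idx * r + child
    return np.bincount(flat, minlength=q * r).reshape(q, r)


def bdeu_score(counts: np.ndarray, ess: float = 1.0) -> float:
    """BDeu family log-marginal-likelihood from an N_jk count matrix."""
    q, r = counts.shape
    a_jk = ess / (q * r)
    a_j = ess / q
    n_j = counts.sum(axis=1)
    return float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )


def bic_score(counts: np.ndarray) -> float:
    """BIC family score: maximized log-likelihood minus (1/2) log N penalty."""
    q, r = counts.shape
    n_j = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / n_j), 0.0).sum()
    N = counts.sum()
    params = q * (r - 1)
    return float(ll - 0.5 * math.log(max(N, 1)) * params)


class _ScoreCache:
    def __init__(self, dataset: DiscreteDataset, score: str, ess: float):
        self.cols = {c: dataset.data[c].to_numpy() for c in dataset.columns}
        self.arities = dataset.arities
        self.score = score
        self.ess = ess
        self.cache: dict[tuple, float] = {}

    def local(self, child: str, parents: frozenset) -> float:
        key = (child, parents)
        if key not in self.cache:
            ps = sorted(parents)
            counts = _family_counts(
                self.cols[child], [self.cols[p] for p in ps],
                self.arities[child], [self.arities[p] for p in ps],
            )
            self.cache[key] = (
                bdeu_score(counts, self.ess) if self.score == "bdeu"
                else bic_score(counts)
            )
        return self.cache[key]


# ---------------------------------------------------------------------------
# structure search


def _has_path(parents: dict[str, frozenset], src: str, dst: str) -> bool:
    """True if dst is an ancestor-path source of src... i.e. src ->* dst."""
    stack, seen = [src], set()
    children = {}
    for c, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(c)
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(children.get(u, []))
    return False


def dag_score(parents: dict[str, frozenset], cache: _ScoreCache) -> float:
    return sum(cache.local(c, ps) for c, ps in parents.items())


def learn_structure(
    dataset: DiscreteDataset,
    score: str = "bdeu",
    ess: float = 1.0,
    max_parents: int = 3,
    n_iter: int = 3000,
    t0: float = 5.0,
    cooling: float = 0.999,
    seed: int = 0,
) -> dict[str, frozenset]:
    """Annealed hill-climb over DAGs maximizing a decomposable score.

    Moves are single-edge add / delete / reverse with acyclicity and
    ``max_parents`` enforced; proposals are accepted by the Metropolis rule
    under a geometric cooling schedule, and the best DAG seen is greedily
    polished before being returned as a child -> parents mapping.
    """
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if score not in ("bdeu", "bic"):
        raise ValueError(f"unknown score {score!r}")
    if len(dataset.columns) < 2:
        raise ValueError("need at least 2 columns")
    rng = np.random.default_rng(seed)
    cache = _ScoreCache(dataset, score, ess)
    nodes = dataset.columns
    parents: dict[str, frozenset] = {v: frozenset() for v in nodes}
    current = dag_score(parents, cache)
    best, best_score = dict(parents), current
    temp = t0
    for _ in range(n_iter):
        i, j = rng.choice(len(nodes), size=2, replace=False)
        u, v = nodes[i], nodes[j]
        delta, apply = _propose(parents, u, v, cache, max_parents)
        if apply is None:
            temp *= cooling
            continue
        if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-12)):
            apply()
            current += delta
            if current > best_score:
                best_score, best = current, dict(parents)
        temp *= cooling
    # greedy polish from the best DAG found
    parents = dict(best)
    improved = True
    while improved:
        improved = False
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                delta, apply = _propose(parents, u, v, cache, max_parents)
                if apply is not None and delta > 1e-12:
                    apply()
                    improved = True
    return {v: frozenset(ps) for v, ps in parents.items()}


def _propose(parents, u, v, cache, max_parents):
    """Score delta and applier for toggling/reversing edge u -> v."""
    if u in parents[v]:  # delete, or reverse
        new_v = parents[v] - {u}
        delta_del = cache.local(v, new_v) - cache.local(v, parents[v])
        # reverse (remove u->v, add v->u) is legal iff no other u ->* v path
        tmp = dict(parents)
        tmp[v] = new_v
        can_rev = len(parents[u]) < max_parents and not _has_path(tmp, u, v)
        if can_rev:
            new_u = parents[u] | {v}
            delta_rev = delta_del + cache.local(u, new_u) - cache.local(u, parents[u])
        else:
            delta_rev = -np.inf
        if delta_rev > delta_del:
            def apply_rev(parents=parents, v=v, u=u, new_v=new_v, new_u=new_u):
                parents[v] = new_v
                parents[u] = new_u
            return delta_rev, apply_rev

        def apply_del(parents=parents, v=v, new_v=new_v):
            parents[v] = new_v
        return delta_del, apply_del
    # add u -> v: legal iff no v ->* u path already
    if len(parents[v]) >= max_parents or _has_path(parents, v, u):
        return 0.0, None
    new_v = parents[v] | {u}
    delta = cache.local(v, new_v) - cache.local(v, parents[v])

    def apply_add(parents=parents, v=v, new_v=new_v):
        parents[v] = new_v
    return delta, apply_add


def markov_blanket(parents: dict[str, frozenset], node: str) -> set[str]:
    """Parents, children, and co-parents of children of ``node``."""
    blanket = set(parents[node])
    for c, ps in parents.items():
        if node in ps:
            blanket.add(c)
            blanket |= set(ps) - {node}
    return blanket


# ---------------------------------------------------------------------------
# conditional mutual information


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> float:
    """Plug-in CMI I(X;Y|Z) in bits from discrete code columns.

    ``z`` may be None (plain mutual information), a single column, or a
    (n, k) matrix of conditioning columns; empty strata contribute nothing.
    The plug-in estimator is non-negative and symmetric in (x, y).
    """
    x = np.asarray(x).astype(np.int64)
    y = np.asarray(y).astype(np.int64)
    n = len(x)
    if z is None or (hasattr(z, "size") and np.asarray(z).size == 0):
        zcode = np.zeros(n, dtype=np.int64)
    else:
        z = np.asarray(z).astype(np.int64)
        if z.ndim == 1:
            z = z[:, None]
        zcode = np.zeros(n, dtype=np.int64)
        for col in z.T:
            zcode = zcode * (col.max() + 1) + col
    rx, ry, rz = x.max() + 1, y.max() + 1, zcode.max() + 1
    flat = (zcode * rx + x) * ry + y
    nxyz = np.bincount(flat, minlength=rz * rx * ry).reshape(rz, rx, ry)
    nz = nxyz.sum(axis=(1, 2), keepdims=True)
    nxz = nxyz.sum(axis=2, keepdims=True)
    nyz = nxyz.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = nxyz * np.log2((nxyz * nz) / (nxz * nyz))
    return float(np.nansum(np.where(nxyz > 0, term, 0.0)) / n)


# ---------------------------------------------------------------------------
# bootstrapped blankets


@dataclass
class MarkovBlanketSummary:
    """Per-feature bootstrap confidence and mean CMI strength."""

    table: pd.DataFrame  # columns: confidence, mean_cmi, n_blankets
    B: int

    def top_features(self, k: int) -> list[str]:
        return list(self.table.sort_values("confidence", ascending=False).index[:k])


def bootstrap_blankets(
    dataset: DiscreteDataset,
    B: int = 400,
    bootstrap_size: int = 20_000,
    seed: int = 0,
    **learner_kwargs,
) -> MarkovBlanketSummary:
    """Bootstrap the structure learner and summarize the indicator's blanket.

    Each of the B bootstraps resamples ``bootstrap_size`` rows with
    replacement (capped at the dataset size with a warning), learns a DAG,
    extracts the indicator's Markov blanket, and computes each member's CMI
    with the indicator given the other blanket members.  Confidence is the
    fraction of bootstraps a feature enters the blanket; strength is its
    mean CMI over those bootstraps.  Features never in any blanket are
    omitted from the summary table.
    """
    rng = np.random.default_rng(seed)
    n = len(dataset)
    size = min(bootstrap_size, n)
    if size < bootstrap_size:
        log.warning("bootstrap_size %d capped at dataset size %d",
                    bootstrap_size, n)
    ind = dataset.indicator
    hits: dict[str, int] = {}
    cmis: dict[str, list[float]] = {}
    for b in range(B):
        idx = rng.integers(0, n, size=size)
        sub = DiscreteDataset(dataset.data.iloc[idx], indicator=ind)
        dag = learn_structure(sub, seed=int(rng.integers(2**31)),
                              **learner_kwargs)
        blanket = markov_blanket(dag, ind)
        for f in blanket:
            others = sorted(blanket - {f})
            z = sub.data[others].to_numpy() if others else None
            cmi = conditional_mutual_information(
                sub.data[ind].to_numpy(), sub.data[f].to_numpy(), z)
            hits[f] = hits.get(f, 0) + 1
            cmis.setdefault(f, []).append(cmi)
    rows = {
        f: {"confidence": hits[f] / B, "mean_cmi": float(np.mean(cmis[f])),
            "n_blankets": hits[f]}
        for f in hits
    }
    table = pd.DataFrame(rows).T.sort_values("confidence", ascending=False) \
        if rows else pd.DataFrame(columns=["confidence", "mean_cmi", "n_blankets"])
    return MarkovBlanketSummary(table=table, B=B)
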