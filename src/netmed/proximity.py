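"""Interactome-based proximity of a protein set to disease gene modules.

For a query protein set Q and a disease gene set D, the observed proximity
is the mean over q in Q of the minimum shortest-path distance from q to D
("closest" distance).  Significance is assessed against a Monte-Carlo null:
random gene sets of the same size as D (or, optionally, randomized query
proteins, optionally degree-matched) give a null distribution of distances,
summarized as

    z = (d_observed - mean(d_random)) / sd(d_random)

with sd computed with the n-1 denominator.  Negative z means the query is
closer to the disease module than random expectation.  One-sided lower-tail
p-values are Phi(z); Benjamini-Hochberg adjustment is applied within each
query across its diseases, flagged at a configurable FDR level (default 25%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .interactome import (
    UNREACHABLE,
    DegreeBins,
    Interactome,
    NoMappedGenesError,
    build_degree_bins,
    distances_to_set,
    min_distance_to_set,
    single_source_distances,
)

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


class NoFiniteDistanceError(ValueError):
    """Raised when no query protein reaches any disease gene."""


@dataclass(frozen=True)
class ProximityConfig:
    """Parameters of the proximity null model.

    randomize_side
        ``"disease_genes"``: each replicate replaces the disease gene set by
        a random gene set of the same size.  ``"query_proteins"``: the query
        side is randomized instead.
    matching
        ``"size_only"`` draws replacements uniformly from the graph's nodes;
        ``"size_and_degree"`` draws each replacement from the donor node's
        degree bin.
    """

    n_random: int = 1000
    randomize_side: str = "disease_genes"
    matching: str = "size_only"
    fdr_alpha: float = 0.25
    master_seed: int = 0
    min_bin_occupancy: int = 100

    def __post_init__(self) -> None:
        if self.n_random < 2:
            raise ValueError("n_random must be >= 2")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.randomize_side not in ("disease_genes", "query_proteins"):
            raise ValueError(f"unknown randomize_side: {self.randomize_side!r}")
        if self.matching not in ("size_only", "size_and_degree"):
            raise ValueError(f"unknown matching: {self.matching!r}")


@dataclass
class ProximityResult:
    """One (query set, disease) proximity record."""

    query: str
    disease: str
    d_observed: float
    mu_random: float
    sigma_random: float
    z: float
    p: float
    p_adjusted: float = float("nan")
    significant: bool = False
    n_random: int = 0
    dropped_genes: int = 0
    note: str = ""


# -- observed statistic ------------------------------------------------------


def _observed_with_drops(g: Interactome, query: Iterable[str],
                         disease_genes: Iterable[str]) -> tuple[float, int]:
    q = g.restrict_genes(query, "query")
    if not q:
        raise NoMappedGenesError("no query proteins mapped to the interactome")
    dist = distances_to_set(g, disease_genes)  # raises NoMappedGenesError if empty
    finite = [dist[p] for p in sorted(q) if p in dist]
    dropped = len(q) - len(finite)
    if not finite:
        raise NoFiniteDistanceError(
            "no query protein reaches any disease gene")
    if dropped:
        logger.warning("%d query protein(s) unreachable from disease genes, dropped",
                       dropped)
    return float(np.mean(finite)), dropped


def observed_proximity(g: Interactome, query: Iterable[str],
                       disease_genes: Iterable[str]) -> float:
    """Mean over query proteins of the minimum distance to the disease genes.

    Query proteins that cannot reach any disease gene are excluded from the
    mean (counted and logged).  A single-protein query reduces to
    :func:`netmed.interactome.min_distance_to_set`.
    """
    d, _ = _observed_with_drops(g, query, disease_genes)
    return d


# -- null model --------------------------------------------------------------


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # per-replicate substreams: seed + replicate index (kept below 2**31)
    return [np.random.default_rng((seed + i) % _SEED_MOD) for i in range(n)]


def _degree_matched_draw(donors: Sequence[str], bins: DegreeBins,
                         rng: np.random.Generator) -> list[str]:
    """One replicate set: a bin-mate for each donor, distinct within the set."""
    chosen: set[str] = set()
    out: list[str] = []
    for donor in donors:
        pool = bins.pool(donor)
        avail = [n for n in pool if n not in chosen]
        if not avail:
            logger.warning("degree bin exhausted for donor %s: uniform fallback", donor)
            avail = [n for n in bins._node_to_bin if n not in chosen]
        pick = avail[rng.integers(len(avail))]
        chosen.add(pick)
        out.append(pick)
    return out


def sample_null(g: Interactome, query: Iterable[str], disease_genes: Iterable[str],
                cfg: ProximityConfig, *, seed: int | None = None,
                degree_bins: DegreeBins | None = None) -> np.ndarray:
    """Null distribution of the proximity statistic.

    Returns ``cfg.n_random`` replicate distances.  Deterministic given the
    seed (defaults to ``cfg.master_seed``); replicate i uses the substream
    ``seed + i``.
    """
    seed = cfg.master_seed if seed is None else seed
    q = sorted(g.restrict_genes(query, "query"))
    d = sorted(g.restrict_genes(disease_genes, "disease genes"))
    if not q or not d:
        raise NoMappedGenesError("query or disease set empty after mapping")
    nodes = g.node_list()
    node_idx = {n: i for i, n in enumerate(nodes)}
    rngs = _replicate_rngs(seed, cfg.n_random)

    if cfg.matching == "size_and_degree" and degree_bins is None:
        degree_bins = build_degree_bins(g, cfg.min_bin_occupancy)

    if cfg.randomize_side == "disease_genes":
        # distances from each (fixed) query protein to every node
        qdist = np.full((len(q), len(nodes)), np.inf)
        for r, prot in enumerate(q):
            for n, dd in single_source_distances(g, prot).items():
                qdist[r, node_idx[n]] = dd
        k = len(d)
        if k > len(nodes):
            raise ValueError("disease set larger than sampling pool")
        samples = np.empty((cfg.n_random, k), dtype=np.int64)
        for i, rng in enumerate(rngs):
            if cfg.matching == "size_and_degree":
                picks = _degree_matched_draw(d, degree_bins, rng)
                samples[i] = [node_idx[n] for n in picks]
            else:
                samples[i] = rng.choice(len(nodes), size=k, replace=False)
        # (n_query, n_random, k) -> min over the random set, mean over query
        mins = qdist[:, samples].min(axis=2)
        with np.errstate(invalid="ignore"):
            vals = np.where(np.isfinite(mins), mins, np.nan)
            out = np.nanmean(vals, axis=0)
        return out

    # randomize_side == "query_proteins"
    dist = distances_to_set(g, d)
    darr = np.full(len(nodes), np.inf)
    for n, dd in dist.items():
        darr[node_idx[n]] = dd
    k = len(q)
    samples = np.empty((cfg.n_random, k), dtype=np.int64)
    for i, rng in enumerate(rngs):
        if cfg.matching == "size_and_degree":
            picks = _degree_matched_draw(q, degree_bins, rng)
            samples[i] = [node_idx[n] for n in picks]
        else:
            samples[i] = rng.choice(len(nodes), size=k, replace=False)
    vals = darr[samples]
    with np.errstate(invalid="ignore"):
        vals = np.where(np.isfinite(vals), vals, np.nan)
        return np.nanmean(vals, axis=1)


# -- z, p, FDR ----------------------------------------------------------------


def zscore(d_observed: float, null: Sequence[float]) -> float:
    """Standardized proximity: (d_observed - mean(null)) / sd(null), sd with n-1.

    Degenerate null (sd == 0): returns 0 when d_observed equals the null
    mean, otherwise a signed infinity.
    """
    arr = np.asarray(null, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("null must contain at least 2 finite entries")
    mu = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        if d_observed == mu:
            return 0.0
        logger.warning("degenerate null (sd=0): z is a signed infinity")
        return float("inf") if d_observed > mu else float("-inf")
    return (d_observed - mu) / sd


def p_from_z(z: float) -> float:
    """Lower-tail standard-normal probability Phi(z).

    Strongly negative z (closer than random) maps to small p.  Infinite
    sentinels map to 0 and 1.
    """
    if np.isneginf(z):
        return 0.0
    if np.isposinf(z):
        return 1.0
    return float(norm.cdf(z))


def bh_adjust(pvalues: Sequence[float], alpha: float = 0.25) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, significance flags at *alpha*), in the input
    order.  Empty input returns empty lists.
    """
    pvalues = list(pvalues)
    if not pvalues:
        return [], []
    if any(p < 0 or p > 1 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return list(map(float, adj)), list(map(bool, reject))


# -- the full table ------------------------------------------------------------


RESULT_COLUMNS = ["query", "disease", "d_observed", "mu_random", "sigma_random",
                  "z", "p", "p_adjusted", "significant", "n_random",
                  "dropped_genes", "note"]


def proximity_table(g: Interactome, queries: Mapping[str, Iterable[str]],
                    diseases: Mapping[str, Iterable[str]],
                    cfg: ProximityConfig) -> pd.DataFrame:
    """Proximity of every query set to every disease, with BH-FDR per query.

    Rows are sorted within each query by z ascending (most negative, i.e.
    closest-beyond-chance, first); per-pair failures become NA rows carrying
    the reason in ``note``.  Deterministic under ``cfg.master_seed``.
    """
    if not queries or not diseases:
        raise ValueError("queries and diseases must be non-empty")
    degree_bins = (build_degree_bins(g, cfg.min_bin_occupancy)
                   if cfg.matching == "size_and_degree" else None)
    results: list[ProximityResult] = []
    pair_index = 0
    for qname in queries:
        per_query: list[ProximityResult] = []
        for dname in diseases:
            pair_seed = (cfg.master_seed + 100003 * pair_index) % _SEED_MOD
            pair_index += 1
            try:
                d_obs, dropped = _observed_with_drops(g, queries[qname], diseases[dname])
                null = sample_null(g, queries[qname], diseases[dname], cfg,
                                   seed=pair_seed, degree_bins=degree_bins)
                finite = null[np.isfinite(null)]
                z = zscore(d_obs, finite)
                res = ProximityResult(
                    query=qname, disease=dname, d_observed=d_obs,
                    mu_random=float(finite.mean()),
                    sigma_random=float(finite.std(ddof=1)),
                    z=z, p=p_from_z(z), n_random=int(cfg.n_random),
                    dropped_genes=dropped)
            except (NoMappedGenesError, NoFiniteDistanceError, ValueError) as exc:
                res = ProximityResult(
                    query=qname, disease=dname, d_observed=float("nan"),
                    mu_random=float("nan"), sigma_random=float("nan"),
                    z=float("nan"), p=float("nan"), note=str(exc))
            per_query.append(res)
        ok = [r for r in per_query if np.isfinite(r.p)]
        if ok:
            adj, flags = bh_adjust([r.p for r in ok], cfg.fdr_alpha)
            for r, a, f in zip(ok, adj, flags):
                r.p_adjusted, r.significant = a, f
        per_query.sort(key=lambda r: (bool(np.isnan(r.z)),
                                      0.0 if np.isnan(r.z) else r.z, r.disease))
        results.extend(per_query)
    return pd.DataFrame([vars(r) for r in results], columns=RESULT_COLUMNS)
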