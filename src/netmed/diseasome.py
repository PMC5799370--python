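"""Four-layer disease–disease networks (diseasomes).

Diseases are connected in four complementary layers over one shared node
set:

* **gene** — the two diseases share at least one associated gene
  (score: shared-gene count, edge iff n > 0);
* **interaction** — the gene products of the two diseases are physically
  wired to each other in the interactome more than size-matched random gene
  sets (score: z of the cross-set interaction count, edge iff z > 0);
* **symptom** — the diseases' strongly supported symptoms (TF-IDF > 3.5)
  overlap (score: Jaccard index, edge iff J > 0.5);
* **comorbidity** — the diseases co-occur in insurance claims more than
  expected (score: relative risk, edge iff RR > 1).

All thresholds are strict inequalities.  Diseases missing from a data
source are isolated nodes in that layer (degree 0), not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .interactome import Interactome
from .proximity import zscore

logger = logging.getLogger(__name__)

LAYER_KINDS = ("gene", "interaction", "symptom", "comorbidity")

_SEED_MOD = 2**31


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class DiseasomeLayer:
    """One disease–disease layer: a scored, thresholded undirected edge set."""

    kind: str
    nodes: set[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({a!r}, {b!r})")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def score(self, a: str, b: str) -> float | None:
        return self.edges.get(_pair(a, b))

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(a, b, s) for (a, b), s in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "score"])

    def summary(self) -> dict:
        deg = self.degrees()
        return {
            "kind": self.kind,
            "threshold": self.threshold,
            "nodes": len(self.nodes),
            "edges": self.n_edges,
            "isolated": sum(1 for v in deg.values() if v == 0),
            "mean_degree": float(np.mean(list(deg.values()))) if deg else 0.0,
        }


# -- set similarity -----------------------------------------------------------


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a ∩ b| / |a ∪ b|.  Undefined (raises) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def filter_redundant_diseases(disease_genes: Mapping[str, Iterable[str]],
                              threshold: float = 0.5) -> dict[str, set[str]]:
    """Drop near-duplicate disease terms by gene-set Jaccard similarity.

    Greedy pass over diseases sorted by descending gene-set size, ties
    broken by name: a disease is dropped if its Jaccard index with any
    already-kept disease exceeds *threshold*.  Deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = {k: set(v) for k, v in disease_genes.items()}
    order = sorted(items, key=lambda k: (-len(items[k]), k))
    kept: dict[str, set[str]] = {}
    for name in order:
        genes = items[name]
        if any(jaccard(genes, kg) > threshold for kg in kept.values()):
            logger.info("redundancy filter: dropping %s", name)
            continue
        kept[name] = genes
    return {k: items[k] for k in disease_genes if k in kept}


# -- layers -------------------------------------------------------------------


def gene_layer(disease_genes: Mapping[str, Iterable[str]],
               nodes: Iterable[str] | None = None,
               n_min: int = 0) -> DiseasomeLayer:
    """Shared-gene layer: edge iff the gene-set intersection exceeds *n_min*."""
    m = {k: set(v) for k, v in disease_genes.items()}
    if len(m) < 2:
        raise ValueError("need at least 2 diseases")
    node_set = set(nodes) if nodes is not None else set(m)
    names = sorted(n for n in node_set if n in m)
    edges: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = len(m[a] & m[b])
            if shared > n_min:
                edges[_pair(a, b)] = float(shared)
    return DiseasomeLayer(kind="gene", nodes=node_set, edges=edges, threshold=n_min)


def count_connecting_interactions(g: Interactome, a: Iterable[str],
                                  b: Iterable[str]) -> int:
    """Distinct interactome edges with one endpoint in *a* and the other in *b*.

    An edge whose endpoints both lie in a ∩ b counts once; symmetric in
    (a, b).  Genes absent from the graph are ignored.
    """
    sa = set(a) & set(g.graph.nodes)
    sb = set(b) & set(g.graph.nodes)
    count = 0
    for u, v in g.graph.edges:
        if (u in sa and v in sb) or (v in sa and u in sb):
            count += 1
    return count


def _edge_index_arrays(g: Interactome, node_idx: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    eu, ev = [], []
    for u, v in g.graph.edges:
        eu.append(node_idx[u])
        ev.append(node_idx[v])
    return np.asarray(eu, dtype=np.int64), np.asarray(ev, dtype=np.int64)


def interaction_layer(g: Interactome, disease_genes: Mapping[str, Iterable[str]],
                      n_random: int = 1000, seed: int = 0,
                      z_min: float = 0.0,
                      nodes: Iterable[str] | None = None) -> DiseasomeLayer:
    """Interactome-wiring layer.

    For each disease pair, the observed number of interactions connecting
    the two gene sets is compared with the counts for *n_random* random
    pairs of size-matched gene sets drawn uniformly from the graph's nodes;
    the edge carries z = (observed - null mean)/null sd and is kept iff
    z > *z_min*.  Deterministic under *seed* (replicate i of pair j uses
    substream ``seed + 100003*j + i``).
    """
    m = {k: set(v) & set(g.graph.nodes) for k, v in disease_genes.items()}
    node_set = set(nodes) if nodes is not None else set(disease_genes)
    names = sorted(n for n in node_set if n in disease_genes)
    all_nodes = g.node_list()
    node_idx = {n: i for i, n in enumerate(all_nodes)}
    eu, ev = _edge_index_arrays(g, node_idx)
    n = len(all_nodes)

    def mask(s: set[str]) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for gene in s:
            out[node_idx[gene]] = True
        return out

    edges: dict[tuple[str, str], float] = {}
    pair_index = 0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair_seed = (seed + 100003 * pair_index) % _SEED_MOD
            pair_index += 1
            sa, sb = m[a], m[b]
            if not sa or not sb:
                continue
            ma, mb = mask(sa), mask(sb)
            observed = int(np.sum((ma[eu] & mb[ev]) | (mb[eu] & ma[ev])))
            ka, kb = len(sa), len(sb)
            null = np.empty(n_random)
            for r in range(n_random):
                rng = np.random.default_rng((pair_seed + r) % _SEED_MOD)
                ra = np.zeros(n, dtype=bool)
                ra[rng.choice(n, size=ka, replace=False)] = True
                rb = np.zeros(n, dtype=bool)
                rb[rng.choice(n, size=kb, replace=False)] = True
                null[r] = np.sum((ra[eu] & rb[ev]) | (rb[eu] & ra[ev]))
            z = zscore(float(observed), null)
            if z > z_min:
                edges[_pair(a, b)] = float(z)
    return DiseasomeLayer(kind="interaction", nodes=node_set, edges=edges,
                          threshold=z_min)


def symptom_layer(profiles: Mapping[str, Mapping[str, float]],
                  tfidf_min: float = 3.5, jaccard_min: float = 0.5,
                  nodes: Iterable[str] | None = None) -> DiseasomeLayer:
    """Symptom-similarity layer.

    Each disease's symptom set is the symptoms scoring strictly above
    *tfidf_min*; an edge is kept iff the Jaccard index of the two sets is
    strictly above *jaccard_min* (score: the Jaccard index).  Diseases whose
    filtered symptom set is empty participate in no edges.
    """
    if not profiles:
        raise ValueError("symptom profiles are empty")
    node_set = set(nodes) if nodes is not None else set(profiles)
    filtered: dict[str, set[str]] = {}
    for d in sorted(n for n in node_set if n in profiles):
        strong = {s for s, score in profiles[d].items() if score > tfidf_min}
        if not strong:
            logger.info("symptom layer: %s has no symptom above %.2f", d, tfidf_min)
        filtered[d] = strong
    names = sorted(filtered)
    edges: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if not filtered[a] and not filtered[b]:
                continue
            j = jaccard(filtered[a], filtered[b])
            if j > jaccard_min:
                edges[_pair(a, b)] = j
    return DiseasomeLayer(kind="symptom", nodes=node_set, edges=edges,
                          threshold=jaccard_min)


def comorbidity_layer(rr: Mapping[tuple[str, str], float], rr_min: float = 1.0,
                      nodes: Iterable[str] | None = None) -> DiseasomeLayer:
    """Comorbidity layer: edge iff relative risk strictly above *rr_min*.

    Pairs absent from the table get no edge.  When *nodes* is given, edges
    are restricted to that node set.
    """
    if not rr:
        raise ValueError("comorbidity table is empty")
    node_set = set(nodes) if nodes is not None else {d for p in rr for d in p}
    edges: dict[tuple[str, str], float] = {}
    for (a, b), val in rr.items():
        if val <= 0:
            raise ValueError(f"relative risk must be positive: {(a, b)} -> {val}")
        if a == b or a not in node_set or b not in node_set:
            continue
        if val > rr_min:
            edges[_pair(a, b)] = float(val)
    return DiseasomeLayer(kind="comorbidity", nodes=node_set, edges=edges,
                          threshold=rr_min)


def build_layers(g: Interactome, disease_genes: Mapping[str, Iterable[str]],
                 symptoms: Mapping[str, Mapping[str, float]] | None,
                 comorbidity: Mapping[tuple[str, str], float] | None,
                 *, n_random: int = 1000, seed: int = 0,
                 tfidf_min: float = 3.5, jaccard_min: float = 0.5,
                 rr_min: float = 1.0, z_min: float = 0.0,
                 kinds: Iterable[str] = LAYER_KINDS) -> list[DiseasomeLayer]:
    """Build the requested layers over one shared disease node set."""
    nodes = set(disease_genes)
    layers: list[DiseasomeLayer] = []
    for kind in kinds:
        if kind == "gene":
            layers.append(gene_layer(disease_genes, nodes=nodes))
        elif kind == "interaction":
            layers.append(interaction_layer(g, disease_genes, n_random=n_random,
                                            seed=seed, z_min=z_min, nodes=nodes))
        elif kind == "symptom":
            if symptoms is None:
                raise ValueError("symptom layer requested but no symptom profiles given")
            layers.append(symptom_layer(symptoms, tfidf_min=tfidf_min,
                                        jaccard_min=jaccard_min, nodes=nodes))
        elif kind == "comorbidity":
            if comorbidity is None:
                raise ValueError("comorbidity layer requested but no table given")
            layers.append(comorbidity_layer(comorbidity, rr_min=rr_min, nodes=nodes))
        else:
            raise ValueError(f"unknown layer kind: {kind!r}")
    return layers
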