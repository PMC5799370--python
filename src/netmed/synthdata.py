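"""Seed-reproducible synthetic test beds for the whole pipeline.

Real interactomes and curated disease annotations are large, proprietary or
licence-encumbered; the generators here emulate their statistical structure
with planted, recoverable ground truth:

* a sparse heavy-tailed interactome (preferential attachment; a uniform
  random-graph mode exists for null-calibration tests where degree
  heterogeneity would confound);
* diseases as localized gene modules grown by random walk with restart,
  with exact pairwise gene overlaps forced by shared seed genes;
* a query protein set wired at a chosen graph distance to one target
  disease module (the recoverable analogue of a drug-target protein family
  sitting next to a disease module);
* symptom TF-IDF tables where designated disease pairs overlap above the
  strong-support cutoff, and comorbidity tables with a controllable
  fraction of relative risks above 1.

Every generator is a pure function of (config, seed): rerunning with the
same inputs reproduces the fixtures byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .interactome import Interactome, distances_to_set

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults give a 500-node preferential-attachment interactome with 10
    disease modules of 15-25 genes, a 3-protein query wired at distance 1
    to the first disease, and symptom/comorbidity tables sized so the full
    pipeline runs in seconds.
    """

    n_nodes: int = 500
    attachment: int = 2                  # edges added per new node (PA mode)
    mode: str = "preferential_attachment"  # or "erdos_renyi"
    edge_probability: float = 0.02       # ER mode only
    n_diseases: int = 10
    module_size_range: tuple[int, int] = (15, 25)
    module_locality: float = 0.5         # P(next module gene is a neighbor)
    overlap: Mapping[tuple[int, int], int] = field(default_factory=dict)
    query_size: int = 3
    query_target: int = 0                # disease index the query is wired to
    query_distance: int = 1              # max min-distance from query to target module
    symptom_vocabulary: int = 200
    symptoms_per_disease: int = 10
    symptom_strong_fraction: float = 0.7  # fraction of scores above the cutoff
    symptom_cutoff: float = 3.5
    symptom_strong_range: tuple[float, float] = (4.0, 8.0)
    symptom_weak_range: tuple[float, float] = (0.5, 3.4)
    symptom_similar_fraction: float = 0.0  # fraction of pairs forced similar
    symptom_similar_pairs: tuple[tuple[int, int], ...] = ()
    comorbid_fraction: float = 0.3       # fraction of pairs with RR > 1
    comorbid_pairs: tuple[tuple[int, int], ...] = ()  # forced RR > 1
    hub_index: int | None = None         # disease planted central in all layers
    hub_gene_overlap: int = 2
    hub_cross_edges: int = 8
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 5:
            raise ValueError("n_nodes must be >= 5")
        lo, hi = self.module_size_range
        if not 1 <= lo <= hi <= self.n_nodes:
            raise ValueError("invalid module_size_range")
        if self.mode not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        for pair, o in self.overlap.items():
            if o > lo:
                raise ValueError(f"overlap {o} for pair {pair} exceeds the "
                                 f"minimum module size {lo}")

    def disease_name(self, i: int) -> str:
        return f"disease_{i:02d}"


def _rng(cfg: ScenarioConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng((cfg.master_seed + offset) % _SEED_MOD)


# -- interactome ---------------------------------------------------------------


def generate_interactome(cfg: ScenarioConfig) -> Interactome:
    """Synthetic interactome; connected and heavy-tailed in PA mode.

    Preferential attachment starts from a complete seed graph on
    m0 = max(3, attachment + 1) nodes, then each new node attaches to
    ``attachment`` distinct existing nodes with probability proportional to
    degree; the edge count is C(m0, 2) + (n - m0) * attachment.
    """
    rng = _rng(cfg, 0)
    names = [f"G{i:04d}" for i in range(cfg.n_nodes)]
    g = Interactome(name="synthetic")
    if cfg.mode == "erdos_renyi":
        p = cfg.edge_probability
        for i in range(cfg.n_nodes):
            g.graph.add_node(names[i])
        iu, jv = np.triu_indices(cfg.n_nodes, k=1)
        keep = rng.random(iu.size) < p
        for a, b in zip(iu[keep], jv[keep]):
            g.graph.add_edge(names[a], names[b])
        return g

    m = cfg.attachment
    m0 = max(3, m + 1)
    if cfg.n_nodes <= m0:
        raise ValueError("n_nodes must exceed the seed clique size")
    repeated: list[int] = []
    for i in range(m0):
        for j in range(i + 1, m0):
            g.graph.add_edge(names[i], names[j])
            repeated += [i, j]
    for new in range(m0, cfg.n_nodes):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            g.graph.add_edge(names[new], names[t])
            repeated += [new, t]
    return g


# -- disease modules -----------------------------------------------------------


def plant_disease_modules(g: Interactome, cfg: ScenarioConfig) -> dict[str, set[str]]:
    """Disease gene modules with exact planted pairwise overlaps.

    Each pair (i, j) in ``cfg.overlap`` (plus hub pairs when a hub is
    planted) is given that many shared seed genes; modules are then grown by
    random walk with restart, drawing only genes not claimed by any other
    module, so the realized pairwise intersections equal the planted
    overlaps exactly.  ``module_locality`` is the probability that the next
    gene is drawn from the module's graph neighborhood rather than uniformly.
    """
    rng = _rng(cfg, 1)
    nodes = g.node_list()
    k = cfg.n_diseases
    lo, hi = cfg.module_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(k)]

    overlap = {tuple(sorted(p)): o for p, o in cfg.overlap.items()}
    if cfg.hub_index is not None:
        for j in range(k):
            if j != cfg.hub_index:
                p = tuple(sorted((cfg.hub_index, j)))
                overlap.setdefault(p, cfg.hub_gene_overlap)

    modules: list[set[str]] = [set() for _ in range(k)]
    claimed: set[str] = set()

    def draw_free(rng: np.random.Generator) -> str:
        avail = [n for n in nodes if n not in claimed]
        if not avail:
            raise ValueError("graph too small for the requested modules")
        return avail[rng.integers(len(avail))]

    for (i, j), o in sorted(overlap.items()):
        if i >= k or j >= k:
            raise ValueError(f"overlap pair {(i, j)} outside disease range")
        for _ in range(o):
            gene = draw_free(rng)
            claimed.add(gene)
            modules[i].add(gene)
            modules[j].add(gene)
    for i in range(k):
        if len(modules[i]) > sizes[i]:
            raise ValueError(f"planted overlaps exceed module size for disease {i}")

    adj = g.graph.adj
    for i in range(k):
        mod = modules[i]
        if not mod:
            gene = draw_free(rng)
            claimed.add(gene)
            mod.add(gene)
        while len(mod) < sizes[i]:
            pick: str | None = None
            if rng.random() < cfg.module_locality:
                frontier = sorted({w for u in mod for w in adj[u]} - claimed)
                if frontier:
                    pick = frontier[rng.integers(len(frontier))]
            if pick is None:
                pick = draw_free(rng)
            claimed.add(pick)
            mod.add(pick)
    return {cfg.disease_name(i): modules[i] for i in range(k)}


def plant_query_set(g: Interactome, modules: Mapping[str, set[str]],
                    cfg: ScenarioConfig) -> set[str]:
    """A query protein set at the configured distance to the target module.

    Query proteins are drawn from nodes whose minimum distance to the target
    module equals ``query_distance`` (distance 0 draws from the module
    itself); if too few such nodes exist, a random outside node is re-wired
    by one added edge to a node at distance ``query_distance - 1``,
    guaranteeing a minimum distance <= the configured value.  Distances to
    the other, non-target modules are left unconstrained.
    """
    rng = _rng(cfg, 2)
    target = cfg.disease_name(cfg.query_target)
    if target not in modules:
        raise ValueError(f"target disease {target!r} not among modules")
    module = modules[target]
    d = cfg.query_distance
    all_module_genes = set().union(*modules.values())

    if d == 0:
        pool = sorted(module)
        if cfg.query_size > len(pool):
            raise ValueError("query larger than the target module")
        idx = rng.choice(len(pool), size=cfg.query_size, replace=False)
        return {pool[i] for i in sorted(idx)}

    dist = distances_to_set(g, module)
    candidates = sorted(n for n in g.node_list()
                        if dist.get(n) == d and n not in all_module_genes)
    query: set[str] = set()
    take = min(cfg.query_size, len(candidates))
    if take:
        idx = rng.choice(len(candidates), size=take, replace=False)
        query = {candidates[i] for i in sorted(idx)}
    if len(query) < cfg.query_size:
        anchors = sorted(n for n in g.node_list() if dist.get(n) == d - 1)
        outside = sorted(n for n in g.node_list()
                         if n not in all_module_genes and n not in query
                         and dist.get(n, np.inf) > d)
        needed = cfg.query_size - len(query)
        if len(outside) < needed or not anchors:
            raise ValueError("graph too small to plant the query set")
        for _ in range(needed):
            node = outside.pop(int(rng.integers(len(outside))))
            anchor = anchors[rng.integers(len(anchors))]
            g.graph.add_edge(node, anchor)
            logger.info("planted query: wired %s to %s", node, anchor)
            query.add(node)
    return query


# -- symptoms and comorbidity ----------------------------------------------------


def _similar_pairs(cfg: ScenarioConfig, rng: np.random.Generator,
                   which: str) -> set[tuple[int, int]]:
    k = cfg.n_diseases
    all_pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if which == "symptom":
        forced = {tuple(sorted(p)) for p in cfg.symptom_similar_pairs}
        frac = cfg.symptom_similar_fraction
    else:
        forced = {tuple(sorted(p)) for p in cfg.comorbid_pairs}
        frac = cfg.comorbid_fraction
    if cfg.hub_index is not None:
        forced |= {tuple(sorted((cfg.hub_index, j)))
                   for j in range(k) if j != cfg.hub_index}
    remaining = [p for p in all_pairs if p not in forced]
    n_extra = int(round(frac * len(all_pairs)))
    n_extra = max(0, min(n_extra, len(remaining)))
    extra: set[tuple[int, int]] = set()
    if n_extra:
        idx = rng.choice(len(remaining), size=n_extra, replace=False)
        extra = {remaining[i] for i in sorted(idx)}
    return forced | extra


def generate_symptoms_and_comorbidity(
        modules: Mapping[str, set[str]], cfg: ScenarioConfig,
) -> tuple[dict[str, dict[str, float]], dict[tuple[str, str], float]]:
    """Symptom TF-IDF profiles and a comorbidity relative-risk table.

    Non-similar diseases receive disjoint symptom blocks from the
    vocabulary, so with ``symptom_similar_fraction`` 0 (and no forced pairs)
    the symptom layer at the default thresholds is empty by construction.
    A designated similar pair shares ~70% of its strong symptoms, putting
    the Jaccard index of the strong sets above 0.5.  Relative risks are
    drawn above 1 for the designated comorbid fraction of pairs and below 1
    otherwise.
    """
    names = sorted(modules)
    k = len(names)
    if k != cfg.n_diseases:
        raise ValueError("module count does not match config")
    if cfg.symptom_vocabulary < k * cfg.symptoms_per_disease:
        raise ValueError("symptom vocabulary too small for disjoint blocks")

    rng_s = _rng(cfg, 3)
    sim_pairs = _similar_pairs(cfg, rng_s, "symptom")
    nsym = cfg.symptoms_per_disease
    blocks = {i: [f"S{i * nsym + t:04d}" for t in range(nsym)] for i in range(k)}

    # symptom identity: start from disjoint blocks, then overwrite the
    # higher-index member of each similar pair with a mostly-shared set
    sets: dict[int, list[str]] = {i: list(blocks[i]) for i in range(k)}
    n_shared = int(np.ceil(0.7 * nsym))  # J >= 0.7k/(1.3k) ~ 0.54 > 0.5
    for (i, j) in sorted(sim_pairs):
        donor = sets[i]
        idx = rng_s.choice(nsym, size=n_shared, replace=False)
        shared = [donor[t] for t in sorted(idx)]
        own = [s for s in blocks[j] if s not in shared][: nsym - n_shared]
        sets[j] = shared + own

    profiles: dict[str, dict[str, float]] = {}
    slo, shi = cfg.symptom_strong_range
    wlo, whi = cfg.symptom_weak_range
    for i, name in enumerate(names):
        prof: dict[str, float] = {}
        n_strong = int(round(cfg.symptom_strong_fraction * len(sets[i])))
        for t, sym in enumerate(sets[i]):
            if t < n_strong:
                prof[sym] = float(np.round(rng_s.uniform(slo, shi), 4))
            else:
                prof[sym] = float(np.round(rng_s.uniform(wlo, whi), 4))
        profiles[name] = prof
    # shared symptoms must be strong on both sides for the planted Jaccard
    for (i, j) in sorted(sim_pairs):
        for sym in set(sets[i]) & set(sets[j]):
            hi_score = float(np.round(rng_s.uniform(slo, shi), 4))
            profiles[names[i]][sym] = hi_score
            profiles[names[j]][sym] = hi_score

    rng_c = _rng(cfg, 4)
    com_pairs = _similar_pairs(cfg, rng_c, "comorbid")
    rr: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pair = (names[i], names[j])
            if (i, j) in com_pairs:
                rr[pair] = float(np.round(rng_c.uniform(1.2, 3.0), 4))
            else:
                rr[pair] = float(np.round(rng_c.uniform(0.3, 0.9), 4))
    return profiles, rr


# -- whole scenarios -------------------------------------------------------------


@dataclass
class Scenario:
    """A generated test bed plus its planted ground truth."""

    config: ScenarioConfig
    interactome: Interactome
    disease_genes: dict[str, set[str]]
    query: set[str]
    symptoms: dict[str, dict[str, float]]
    comorbidity: dict[tuple[str, str], float]

    @property
    def query_name(self) -> str:
        return "query"

    def manifest(self) -> dict:
        cfg = self.config
        return {
            "config": _config_dict(cfg),
            "planted": {
                "query_target": cfg.disease_name(cfg.query_target),
                "query_distance": cfg.query_distance,
                "query_proteins": sorted(self.query),
                "hub": cfg.disease_name(cfg.hub_index) if cfg.hub_index is not None else None,
                "gene_overlaps": {f"{cfg.disease_name(i)}|{cfg.disease_name(j)}": o
                                  for (i, j), o in sorted(cfg.overlap.items())},
            },
            "sizes": {d: len(s) for d, s in sorted(self.disease_genes.items())},
            "interactome": {"nodes": self.interactome.n_nodes,
                            "edges": self.interactome.n_edges},
        }


def _config_dict(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["overlap"] = {f"{i}|{j}": o for (i, j), o in sorted(cfg.overlap.items())}
    return d


def _wire_hub(g: Interactome, modules: Mapping[str, set[str]],
              cfg: ScenarioConfig) -> None:
    """Add cross edges between the hub module and every other module.

    Pushes the observed cross-set interaction count well above the
    size-matched null, so the hub's interaction-layer z is positive.
    """
    rng = _rng(cfg, 5)
    hub = cfg.disease_name(cfg.hub_index)
    hub_genes = sorted(modules[hub])
    for name in sorted(modules):
        if name == hub:
            continue
        other = sorted(modules[name] - set(hub_genes))
        for _ in range(cfg.hub_cross_edges):
            u = hub_genes[rng.integers(len(hub_genes))]
            v = other[rng.integers(len(other))]
            g.graph.add_edge(u, v)


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate a full scenario: graph, modules, query, symptoms, comorbidity."""
    g = generate_interactome(cfg)
    modules = plant_disease_modules(g, cfg)
    if cfg.hub_index is not None:
        _wire_hub(g, modules, cfg)
    query = plant_query_set(g, modules, cfg)
    symptoms, rr = generate_symptoms_and_comorbidity(modules, cfg)
    return Scenario(config=cfg, interactome=g, disease_genes=modules,
                    query=query, symptoms=symptoms, comorbidity=rr)


def hub_scenario(master_seed: int = 0, **overrides) -> ScenarioConfig:
    """Default scenario with disease_00 planted central in all four layers."""
    # one shared gene per hub partner: 9 seed genes always fit the smallest
    # module, and the hub's gene-layer degree is n_diseases - 1 regardless
    params = dict(hub_index=0, hub_gene_overlap=1, comorbid_fraction=0.2,
                  symptom_similar_fraction=0.0, master_seed=master_seed)
    params.update(overrides)
    return ScenarioConfig(**params)


def write_scenario(sc: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario in the exact dialects the readers consume."""
    from . import io as nio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "diseases": outdir / "diseases.gmt",
        "queries": outdir / "queries.gmt",
        "symptoms": outdir / "symptoms.tsv",
        "comorbidity": outdir / "comorbidity.tsv",
        "manifest": outdir / "manifest.json",
    }
    sc.interactome.save_edgelist(paths["network"])
    nio.write_gmt({d: sc.disease_genes[d] for d in sorted(sc.disease_genes)},
                  paths["diseases"], description="synthetic disease module")
    nio.write_gmt({sc.query_name: sc.query}, paths["queries"],
                  description="synthetic query protein set")
    nio.write_symptoms(sc.symptoms, paths["symptoms"])
    nio.write_comorbidity(sc.comorbidity, paths["comorbidity"])
    paths["manifest"].write_text(json.dumps(sc.manifest(), indent=2, sort_keys=True) + "\n")
    return paths
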