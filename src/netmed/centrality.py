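"""Cross-layer disease centrality.

Within each diseasome layer a disease's centrality is its raw degree (edge
count, printed as an integer); the final prioritization score is the
arithmetic mean of the per-layer degrees.  A leave-one-layer-out variant
checks that the ranking is not driven by a single data source.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diseasome import DiseasomeLayer


def degree_centrality(layer: DiseasomeLayer) -> dict[str, int]:
    """Raw edge count per disease; isolated nodes get 0 (not normalized)."""
    return layer.degrees()


def average_from_degrees(degrees: Mapping[str, Sequence[float]],
                         layer_names: Sequence[str]) -> pd.DataFrame:
    """Centrality table from per-disease per-layer degree vectors.

    The average is the arithmetic mean of the listed degrees.  Rows are
    sorted by average descending, ties broken by disease name ascending;
    ``rank`` runs 1..n in that order.
    """
    if not degrees:
        raise ValueError("no diseases")
    n_layers = {len(v) for v in degrees.values()}
    if len(n_layers) != 1:
        raise ValueError("all diseases must have one degree per layer")
    if n_layers != {len(layer_names)}:
        raise ValueError("degree vectors do not match layer_names")
    rows = []
    for disease in degrees:
        vec = list(degrees[disease])
        rows.append({"disease": disease,
                     **{f"{k}_degree": v for k, v in zip(layer_names, vec)},
                     "average_degree": sum(vec) / len(vec)})
    df = pd.DataFrame(rows)
    df = df.sort_values(["average_degree", "disease"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def average_centrality(layers: Sequence[DiseasomeLayer]) -> pd.DataFrame:
    """Per-disease mean of per-layer degrees, ranked.

    Layers must share one node set.  The result is invariant to layer order
    up to column order.
    """
    if len(layers) < 1:
        raise ValueError("need at least one layer")
    node_sets = {frozenset(l.nodes) for l in layers}
    if len(node_sets) != 1:
        raise ValueError("layers do not share a node set")
    per_layer = [degree_centrality(l) for l in layers]
    degrees = {d: [pl[d] for pl in per_layer] for d in sorted(layers[0].nodes)}
    return average_from_degrees(degrees, [l.kind for l in layers])


def robustness_excluding_layer(layers: Sequence[DiseasomeLayer],
                               excluded_kind: str) -> pd.DataFrame:
    """Centrality table averaged over all layers except *excluded_kind*."""
    if len(layers) < 2:
        raise ValueError("need at least two layers to exclude one")
    kinds = [l.kind for l in layers]
    if excluded_kind not in kinds:
        raise ValueError(f"no layer of kind {excluded_kind!r} among {kinds}")
    remaining = [l for l in layers if l.kind != excluded_kind]
    return average_centrality(remaining)
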