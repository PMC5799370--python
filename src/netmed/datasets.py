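"""Small published reference tables shipped with the package.

These are the curated summary tables of the cGMP-cluster diseasome study:
the per-layer degree block of the 12-disease cluster, and the z-scores and
one-sided p-values of the sGC-subunit proximity screen.  They serve as
arithmetic fixtures (the degree block feeds the centrality averaging; the
z/p table checks the z-to-p conversion), not as inputs to the network
algorithms, whose underlying interactome and annotation sources are not
redistributable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LAYER_NAMES = ["gene", "interaction", "symptom", "comorbidity"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("netmed.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_cgmp_cluster_degrees() -> pd.DataFrame:
    """Per-layer degrees of the 12 diseases in the cGMP-related cluster.

    Columns: disease, gene_degree, interaction_degree, symptom_degree,
    comorbidity_degree.
    """
    return _load("cgmp_cluster_degrees.tsv")


def cgmp_cluster_degree_vectors() -> dict[str, list[int]]:
    """The same block as ``{disease: [gene, interaction, symptom, comorbidity]}``."""
    df = load_cgmp_cluster_degrees()
    cols = [f"{k}_degree" for k in LAYER_NAMES]
    return {row["disease"]: [int(row[c]) for c in cols] for _, row in df.iterrows()}


def load_sgc_proximity_reference() -> pd.DataFrame:
    """Published sGC-subunit proximity z-scores and p-values.

    Columns: query, disease, z (3 decimals), p (5 decimals), stable_5dp
    (1 where Phi(z) at the printed z precision rounds exactly to the
    printed p).
    """
    return _load("sgc_proximity_reference.tsv")
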