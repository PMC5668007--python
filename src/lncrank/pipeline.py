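"""End-to-end glue: load a data bundle and prepare vectors and features.

These helpers tie the loaders, the vectorizer and the feature store together
for the CLI and for scripted analyses.  They work on any directory that holds
the standard file bundle (see :mod:`lncrank.simulate` for the file names), be
it synthetic or curated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .features import FeatureStore
from .genome import (
    AssociationSet,
    PathwayCatalog,
    PathwayGrouping,
    SubstructurePartition,
    build_association_set,
    build_substructure_partition,
    group_pathways,
    load_disease_genes,
    load_expression,
    load_gene_catalog,
    load_gmt,
    load_lncrna_fasta,
    load_pairs,
)
from .simulate import BUNDLE_FILES
from .vectorize import DiseaseVector, vectorize_all


@dataclass(frozen=True)
class LoadedBundle:
    partition: SubstructurePartition
    catalog: PathwayCatalog
    disease_genes: dict[str, frozenset[str]]
    expression: pd.DataFrame
    sequences: dict[str, str]
    positives: list[tuple[str, str]]
    benchmark_pairs: list[tuple[str, str]]


def load_bundle(directory: str | Path) -> LoadedBundle:
    """Load every file of a standard bundle directory."""
    d = Path(directory)
    genes = load_gene_catalog(d / BUNDLE_FILES["genes"])
    partition = build_substructure_partition(genes)
    catalog = load_gmt(d / BUNDLE_FILES["pathways"])
    disease_genes = load_disease_genes(
        d / BUNDLE_FILES["disease_genes"], known_genes=[g.gene_id for g in genes]
    )
    expression = load_expression(d / BUNDLE_FILES["expression"])
    sequences = load_lncrna_fasta(d / BUNDLE_FILES["lncrnas"])
    positives = load_pairs(d / BUNDLE_FILES["associations"], ("disease_id", "lncrna_id"))
    bench_path = d / BUNDLE_FILES["benchmark"]
    benchmark = (
        load_pairs(bench_path, ("disease_id_1", "disease_id_2")) if bench_path.exists() else []
    )
    return LoadedBundle(partition, catalog, disease_genes, expression, sequences, positives, benchmark)


@dataclass(frozen=True)
class PreparedData:
    vectors: dict[str, DiseaseVector]
    grouping: PathwayGrouping
    store: FeatureStore
    associations: AssociationSet


def prepare(
    bundle: LoadedBundle,
    k1: int = 9,
    k2: int = 8,
    n_groups: int = 30,
    alpha: float = 0.05,
    sided: str = "two",
    kmer_size: int = 3,
) -> PreparedData:
    """Vectorize diseases, build the feature store and the association set."""
    grouping = group_pathways(bundle.catalog, n_groups)
    vectors = vectorize_all(
        bundle.disease_genes, bundle.partition, bundle.catalog, grouping,
        k1=k1, k2=k2, alpha=alpha, sided=sided,
    )
    store = FeatureStore.build(
        vectors, bundle.sequences,
        disease_genes=bundle.disease_genes,
        expression=bundle.expression,
        kmer_size=kmer_size,
    )
    associations = build_association_set(
        sorted(bundle.disease_genes), sorted(bundle.sequences), bundle.positives
    )
    return PreparedData(vectors, grouping, store, associations)
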