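"""Shared fixtures: synthetic universes at the default and at toy scale."""

from __future__ import annotations

import pytest

from lncrank.features import FeatureStore
from lncrank.genome import PathwayCatalog, build_association_set, group_pathways
from lncrank.simulate import FixtureSpec, FixtureBundle, generate_bundle
from lncrank.vectorize import vectorize_all


def pathway_catalog_of(bundle: FixtureBundle) -> PathwayCatalog:
    return PathwayCatalog(tuple((pid, frozenset(m)) for pid, m in bundle.pathways))


def prepare_bundle(bundle: FixtureBundle, n_groups: int = 30):
    """(vectors, store, association set) for a generated bundle."""
    catalog = pathway_catalog_of(bundle)
    grouping = group_pathways(catalog, min(n_groups, catalog.n_pathways))
    vectors = vectorize_all(bundle.disease_genes, bundle.partition, catalog, grouping)
    store = FeatureStore.build(
        vectors, bundle.sequences, bundle.disease_genes, bundle.expression
    )
    assoc = build_association_set(
        sorted(bundle.disease_genes), sorted(bundle.sequences), list(bundle.positives)
    )
    return vectors, store, assoc


@pytest.fixture(scope="session")
def default_bundle() -> FixtureBundle:
    """The standard desk-scale universe (seed 1)."""
    return generate_bundle(FixtureSpec())


@pytest.fixture(scope="session")
def default_prepared(default_bundle):
    return prepare_bundle(default_bundle)


@pytest.fixture(scope="session")
def small_bundle() -> FixtureBundle:
    """A small universe for cheap end-to-end checks."""
    spec = FixtureSpec(
        n_genes=300, n_substructures=30, n_pathways=60, pathway_size=15,
        n_diseases=12, genes_per_disease=8, n_lncrnas=15, seq_length=120,
        seed=11,
    )
    return generate_bundle(spec)


@pytest.fixture(scope="session")
def small_prepared(small_bundle):
    return prepare_bundle(small_bundle, n_groups=10)
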