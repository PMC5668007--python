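"""Gene catalog loading, substructure partitioning, grouping and association sets."""

from __future__ import annotations

import numpy as np
import pytest

from lncrank.genome import (
    CHROMOSOMES,
    GeneRecord,
    PathwayCatalog,
    build_association_set,
    build_substructure_partition,
    group_pathways,
    load_gene_catalog,
)
from lncrank.simulate import FixtureSpec, generate_bundle


def write_catalog(path, rows):
    lines = ["gene_id\tchromosome\tarm\tposition"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadGeneCatalog:
    def test_records_sorted_by_position(self, tmp_path):
        p = write_catalog(tmp_path / "g.tsv", [("g3", 1, "p", 300), ("g1", 1, "p", 100), ("g2", 1, "p", 200)])
        recs = load_gene_catalog(p)
        assert [r.gene_id for r in recs] == ["g1", "g2", "g3"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write_catalog(tmp_path / "g.tsv", [("g1", 1, "p", 1), ("g1", 2, "q", 5)])
        with pytest.raises(ValueError, match="duplicate gene_id"):
            load_gene_catalog(p)

    def test_karyotype_order_before_position(self, tmp_path):
        p = write_catalog(tmp_path / "g.tsv", [("a", 2, "q", 1), ("b", 1, "p", 999)])
        recs = load_gene_catalog(p)
        assert [r.gene_id for r in recs] == ["b", "a"]

    def test_chr10_sorts_after_chr2(self, tmp_path):
        # karyotype order is numeric, not lexicographic
        p = write_catalog(tmp_path / "g.tsv", [("a", 10, "p", 1), ("b", 2, "p", 1)])
        assert [r.gene_id for r in load_gene_catalog(p)] == ["b", "a"]

    @pytest.mark.parametrize(
        "row, message",
        [
            (("g1", 99, "p", 1), "unknown chromosome"),
            (("g1", 1, "z", 1), "unknown arm"),
            (("g1", 1, "p", 0), "position must be >= 1"),
            (("g1", 1, "p", "xyz"), "not an integer"),
            (("g1", "MT", "p", 1), "arm='whole'"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, row, message):
        p = write_catalog(tmp_path / "g.tsv", [row])
        with pytest.raises(ValueError, match=message) as err:
            load_gene_catalog(p)
        assert "line 2" in str(err.value)


class TestSubstructurePartition:
    def test_full_catalog_yields_45_substructures(self):
        genes = [
            GeneRecord(f"g{i}", c, "whole" if c in {"13", "14", "15", "22", "MT"} else arm, 1 + i)
            for i, (c, arm) in enumerate(
                (c, a) for c in CHROMOSOMES for a in ("p", "q")
            )
        ]
        part = build_substructure_partition(genes)
        assert part.n_substructures == 45

    def test_two_substructures_for_one_divided_chromosome(self):
        genes = [GeneRecord("a", "1", "p", 5), GeneRecord("b", "1", "q", 2)]
        part = build_substructure_partition(genes, undivided=["MT"])
        labels = [lab for lab, mem in part.substructures if mem]
        assert labels == ["chr1p", "chr1q"]

    def test_all_undivided_gives_25_substructures(self):
        part = build_substructure_partition([], undivided=CHROMOSOMES)
        assert part.n_substructures == 25

    def test_whole_arm_on_divided_chromosome_rejected(self):
        with pytest.raises(ValueError, match="arm='whole' on divided"):
            build_substructure_partition([GeneRecord("a", "1", "whole", 1)])

    def test_empty_substructures_are_retained(self):
        part = build_substructure_partition([GeneRecord("a", "1", "p", 1)])
        assert part.n_substructures == 45
        assert part.members("chr1p") == ("a",)
        assert part.members("chrMT") == ()

    def test_partition_completeness_on_random_catalogs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 120))
            genes = []
            for i in range(n):
                c = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
                arm = "whole" if c in {"13", "14", "15", "22", "MT"} else ("p", "q")[int(rng.integers(2))]
                genes.append(GeneRecord(f"g{i}", c, arm, int(rng.integers(1, 10**6))))
            part = build_substructure_partition(genes)
            assert part.n_genes == n
            assert len(part.all_genes) == n  # no gene in two substructures

    def test_members_sorted_by_position_then_id(self):
        genes = [GeneRecord("b", "1", "p", 7), GeneRecord("a", "1", "p", 7), GeneRecord("c", "1", "p", 2)]
        part = build_substructure_partition(genes)
        assert part.members("chr1p") == ("c", "a", "b")


def make_catalog(m: int) -> PathwayCatalog:
    return PathwayCatalog(tuple((f"p{i:04d}", frozenset({f"g{i}"})) for i in range(m)))


class TestGroupPathways:
    @pytest.mark.parametrize(
        "m, t, sizes",
        [
            (303, 30, (10,) * 29 + (13,)),
            (10, 5, (2, 2, 2, 2, 2)),
            (7, 3, (2, 2, 3)),
        ],
    )
    def test_group_sizes(self, m, t, sizes):
        assert group_pathways(make_catalog(m), t).sizes == sizes

    def test_groups_partition_preserving_order(self):
        grouping = group_pathways(make_catalog(17), 4)
        flat = [i for g in grouping.groups for i in g]
        assert flat == list(range(17))

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError, match="n_groups"):
            group_pathways(make_catalog(5), 6)


class TestAssociationSet:
    def test_published_scale_counts(self):
        diseases = [f"d{i}" for i in range(162)]
        lncrnas = [f"l{i}" for i in range(187)]
        positives = [(diseases[i % 162], lncrnas[i % 187]) for i in range(454)]
        assert len(set(positives)) == 454
        assoc = build_association_set(diseases, lncrnas, positives)
        assert assoc.n_positive == 454
        assert assoc.n_unlabeled == 29840

    def test_no_positives(self):
        assoc = build_association_set(["d1", "d2"], ["l1", "l2"], [])
        assert assoc.n_unlabeled == 4

    def test_saturated(self):
        pairs = [(d, l) for d in ["a", "b", "c"] for l in ["x", "y", "z"]]
        assoc = build_association_set(["a", "b", "c"], ["x", "y", "z"], pairs)
        assert assoc.n_unlabeled == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown disease id"):
            build_association_set(["d1"], ["l1"], [("dX", "l1")])

    def test_conservation_invariant(self):
        assoc = build_association_set(["d1", "d2", "d3"], ["l1", "l2"], [("d1", "l1")])
        assert assoc.n_positive + assoc.n_unlabeled == 6


def test_generated_bundle_round_trips_through_loaders(tmp_path, caplog):
    """The synthetic bundle parses cleanly back into equivalent objects."""
    import logging

    from lncrank.pipeline import load_bundle
    from lncrank.simulate import generate_universe

    spec = FixtureSpec(n_genes=150, n_substructures=15, n_pathways=20, pathway_size=10,
                       n_diseases=6, genes_per_disease=5, n_lncrnas=8, seq_length=90, seed=4)
    generate_universe(spec, tmp_path)
    with caplog.at_level(logging.WARNING, logger="lncrank"):
        loaded = load_bundle(tmp_path)
    assert not caplog.records
    bundle = generate_bundle(spec)
    assert loaded.partition.n_genes == 150
    assert set(loaded.disease_genes) == set(bundle.disease_genes)
    assert all(loaded.disease_genes[d] == bundle.disease_genes[d] for d in bundle.disease_genes)
    assert loaded.sequences == bundle.sequences
    assert sorted(loaded.positives) == sorted(bundle.positives)
    np.testing.assert_allclose(
        loaded.expression.to_numpy(), bundle.expression.to_numpy(), rtol=1e-5
    )
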