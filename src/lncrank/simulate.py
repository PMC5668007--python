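"""Seeded generator of toy disease-gene-lncRNA universes.

The generator emulates the statistical structure the prediction method relies
on, at desk scale and fully reproducibly from one seed:

* **Chromosome preference** — every disease picks one or two preferred
  chromosome substructures and draws most of its genes from them
  (``clustering_prob``), so disease gene sets form tight positional clusters
  the way real disease genes do.
* **Pathway enrichment** — about half of the pathways are planted around a
  disease's gene pool, so disease gene sets enrich a handful of pathways.
* **Co-expression** — tissue expression is log-normal.  Each substructure has
  a latent log-profile; a disease's genes scatter around the latent profile of
  its first preferred substructure, so diseases sharing a substructure also
  share expression structure.  The lncRNA of a planted positive pair gets the
  mean log-profile of its associated diseases' genes plus Gaussian noise
  (``coexpression_noise``), planting a co-expression signal for true pairs.
* **Positive associations** — positives are sampled within "clusters" of
  diseases that share a preferred substructure, mimicking lncRNAs associated
  with families of related diseases; benchmark similar-disease pairs are the
  disease pairs sharing a preferred substructure.

The output is a bundle of the same plain-text formats the loaders read, so
every pipeline stage can be exercised without downloads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import (
    CHROMOSOMES,
    DEFAULT_UNDIVIDED,
    GeneRecord,
    SubstructurePartition,
    build_substructure_partition,
)

BUNDLE_FILES = {
    "genes": "genes.tsv",
    "pathways": "pathways.gmt",
    "disease_genes": "disease_genes.tsv",
    "expression": "expression.tsv",
    "lncrnas": "lncrnas.fasta",
    "associations": "associations.tsv",
    "benchmark": "benchmark_pairs.tsv",
    "spec": "fixture_spec.yaml",
}


def default_substructure_layout(n_substructures: int = 45) -> list[tuple[str, str]]:
    """(chromosome, arm) per substructure under the default partition rules."""
    layout: list[tuple[str, str]] = []
    for chrom in CHROMOSOMES:
        if chrom in DEFAULT_UNDIVIDED:
            layout.append((chrom, "whole"))
        else:
            layout.append((chrom, "p"))
            layout.append((chrom, "q"))
    if not 1 <= n_substructures <= len(layout):
        raise ValueError(f"n_substructures must be in [1, {len(layout)}], got {n_substructures}")
    return layout[:n_substructures]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic universe.

    Defaults describe a desk-scale universe: 900 genes spread evenly over the
    45 default substructures (20 genes each, enough for length-9 entropy
    windows), a 303-pathway catalog (the scale of the real human pathway
    catalog, so 30 groups split as 29x10+13), 40 diseases of 12 genes drawn
    with probability 0.9 from their preferred substructures, and 60 lncRNAs of
    400 nt with 16-tissue expression.
    """

    n_genes: int = 900
    n_substructures: int = 45
    n_pathways: int = 303
    pathway_size: int = 25
    n_diseases: int = 40
    genes_per_disease: int = 12
    clustering_prob: float = 0.9
    n_lncrnas: int = 60
    seq_length: int = 400
    n_tissues: int = 16
    coexpression_noise: float = 0.2
    gene_noise: float = 0.25
    substructure_scale: float = 0.5
    disease_scale: float = 0.15
    background_scale: float = 0.6
    pathway_disease_bias: float = 0.5
    positive_fraction: float = 0.1
    gc_bias: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_substructures", "n_pathways", "pathway_size",
                     "n_diseases", "genes_per_disease", "n_lncrnas", "seq_length", "n_tissues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("clustering_prob", "positive_fraction", "pathway_disease_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genes_per_disease > self.n_genes:
            raise ValueError("genes_per_disease cannot exceed n_genes")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size cannot exceed n_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class FixtureBundle:
    """In-memory synthetic universe (the file bundle's contents)."""

    spec: FixtureSpec
    genes: pd.DataFrame                       # gene_id, chromosome, arm, position
    partition: SubstructurePartition
    pathways: tuple[tuple[str, tuple[str, ...]], ...]
    disease_genes: dict[str, frozenset[str]]
    preferred: dict[str, tuple[int, ...]]     # disease -> preferred substructure indices
    expression: pd.DataFrame
    sequences: dict[str, str]
    positives: tuple[tuple[str, str], ...]
    benchmark_pairs: tuple[tuple[str, str], ...]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.disease_genes))

    @property
    def lncrnas(self) -> tuple[str, ...]:
        return tuple(sorted(self.sequences))


def generate_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Build a synthetic universe deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    layout = default_substructure_layout(spec.n_substructures)

    # -- gene catalog: even split over substructures, remainder to the first ones
    base, rem = divmod(spec.n_genes, len(layout))
    sizes = [base + (1 if i < rem else 0) for i in range(len(layout))]
    if min(sizes) == 0:
        raise ValueError("n_genes is too small to populate every substructure")
    records: list[GeneRecord] = []
    chrom_counter: dict[str, int] = {}
    sub_members: list[list[str]] = []
    gid = 0
    for (chrom, arm), size in zip(layout, sizes):
        members = []
        for _ in range(size):
            gid += 1
            pos = chrom_counter.get(chrom, 0) + 1000
            chrom_counter[chrom] = pos
            gene_id = f"G{gid:04d}"
            records.append(GeneRecord(gene_id, chrom, arm, pos))
            members.append(gene_id)
        sub_members.append(members)
    genes_df = pd.DataFrame(
        [(r.gene_id, r.chromosome, r.arm, r.position) for r in records],
        columns=["gene_id", "chromosome", "arm", "position"],
    )
    partition = build_substructure_partition(records)
    all_genes = [r.gene_id for r in records]

    # -- diseases: preferred substructures and clustered gene sets
    disease_ids = [f"D{i + 1:03d}" for i in range(spec.n_diseases)]
    preferred: dict[str, tuple[int, ...]] = {}
    disease_genes: dict[str, frozenset[str]] = {}
    for d in disease_ids:
        n_pref = int(rng.integers(1, 3))
        pref = tuple(sorted(rng.choice(len(layout), size=n_pref, replace=False).tolist()))
        preferred[d] = pref
        pool = [g for s in pref for g in sub_members[s]]
        n_clustered = min(int(rng.binomial(spec.genes_per_disease, spec.clustering_prob)), len(pool))
        chosen = set(rng.choice(pool, size=n_clustered, replace=False).tolist())
        outside = [g for g in all_genes if g not in chosen]
        n_rest = spec.genes_per_disease - len(chosen)
        if n_rest > 0:
            chosen |= set(rng.choice(outside, size=n_rest, replace=False).tolist())
        disease_genes[d] = frozenset(chosen)

    # -- pathways: half planted around a disease's neighborhood, half uniform
    pathways: list[tuple[str, tuple[str, ...]]] = []
    for j in range(spec.n_pathways):
        pid = f"PW{j + 1:04d}"
        if rng.random() < spec.pathway_disease_bias:
            d = disease_ids[j % spec.n_diseases]
            pool = sorted(set(disease_genes[d]) | {g for s in preferred[d] for g in sub_members[s]})
            n_in = min(int(round(0.6 * spec.pathway_size)), len(pool))
            members = set(rng.choice(pool, size=n_in, replace=False).tolist())
            outside = [g for g in all_genes if g not in members]
            members |= set(rng.choice(outside, size=spec.pathway_size - n_in, replace=False).tolist())
        else:
            members = set(rng.choice(all_genes, size=spec.pathway_size, replace=False).tolist())
        pathways.append((pid, tuple(sorted(members))))

    # -- latent log-expression structure
    sub_latent = rng.normal(0.0, spec.substructure_scale, size=(len(layout), spec.n_tissues))
    disease_latent = {
        d: sub_latent[preferred[d][0]] + rng.normal(0.0, spec.disease_scale, spec.n_tissues)
        for d in disease_ids
    }
    primary: dict[str, str] = {}
    for d in disease_ids:  # first disease (in id order) owning a gene is its primary
        for g in sorted(disease_genes[d]):
            primary.setdefault(g, d)
    gene_log = np.empty((len(all_genes), spec.n_tissues))
    for i, g in enumerate(all_genes):
        if g in primary:
            gene_log[i] = disease_latent[primary[g]] + rng.normal(0.0, spec.gene_noise, spec.n_tissues)
        else:
            gene_log[i] = rng.normal(0.0, spec.background_scale, spec.n_tissues)

    # -- positive pairs sampled within clusters of substructure-sharing diseases
    lnc_ids = [f"L{i + 1:03d}" for i in range(spec.n_lncrnas)]
    n_pos = int(round(spec.positive_fraction * spec.n_diseases * spec.n_lncrnas))
    anchor = {l: disease_ids[int(rng.integers(spec.n_diseases))] for l in lnc_ids}
    clusters = {
        l: [d for d in disease_ids if set(preferred[d]) & set(preferred[anchor[l]])]
        for l in lnc_ids
    }
    positives: list[tuple[str, str]] = []
    pos_set: set[tuple[str, str]] = set()
    li = 0
    attempts = 0
    while len(positives) < n_pos and attempts < 50 * n_pos:
        attempts += 1
        l = lnc_ids[li % spec.n_lncrnas]
        li += 1
        cluster = clusters[l]
        d = cluster[int(rng.integers(len(cluster)))]
        if (d, l) in pos_set:
            d = disease_ids[int(rng.integers(spec.n_diseases))]  # cluster saturated; spill over
        if (d, l) not in pos_set:
            pos_set.add((d, l))
            positives.append((d, l))
    positives.sort()

    # -- lncRNA expression: mean gene log-profile of associated diseases + noise
    gene_index = {g: i for i, g in enumerate(all_genes)}
    lnc_diseases: dict[str, list[str]] = {l: [] for l in lnc_ids}
    for d, l in positives:
        lnc_diseases[l].append(d)
    lnc_log = np.empty((len(lnc_ids), spec.n_tissues))
    for i, l in enumerate(lnc_ids):
        assoc = sorted(set(lnc_diseases[l]))
        if assoc:
            rows = sorted({gene_index[g] for d in assoc for g in disease_genes[d]})
            lnc_log[i] = gene_log[rows].mean(axis=0) + rng.normal(0.0, spec.coexpression_noise, spec.n_tissues)
        else:
            lnc_log[i] = rng.normal(0.0, spec.background_scale, spec.n_tissues)

    tissue_cols = [f"tissue_{t + 1}" for t in range(spec.n_tissues)]
    expression = pd.DataFrame(
        np.round(np.exp(np.concatenate([gene_log, lnc_log])), 6),
        index=all_genes + lnc_ids,
        columns=tissue_cols,
    )
    expression.index.name = "id"

    # -- sequences: i.i.d. nucleotides, optional GC bias for associated lncRNAs
    sequences: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for l in lnc_ids:
        gc = 0.5 + (spec.gc_bias if lnc_diseases[l] else 0.0)
        gc = min(max(gc, 0.02), 0.98)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences[l] = "".join(rng.choice(bases, size=spec.seq_length, p=p).tolist())

    benchmark = tuple(
        (disease_ids[i], disease_ids[j])
        for i in range(spec.n_diseases)
        for j in range(i + 1, spec.n_diseases)
        if set(preferred[disease_ids[i]]) & set(preferred[disease_ids[j]])
    )

    return FixtureBundle(
        spec=spec,
        genes=genes_df,
        partition=partition,
        pathways=tuple(pathways),
        disease_genes=disease_genes,
        preferred=preferred,
        expression=expression,
        sequences=sequences,
        positives=tuple(positives),
        benchmark_pairs=benchmark,
    )


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to its plain-text file formats; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {key: out / name for key, name in BUNDLE_FILES.items()}

    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["pathways"], "w") as fh:
        for pid, members in bundle.pathways:
            fh.write("\t".join([pid, "synthetic pathway", *members]) + "\n")
    with open(paths["disease_genes"], "w") as fh:
        fh.write("disease_id\tgene_id\n")
        for d in sorted(bundle.disease_genes):
            for g in sorted(bundle.disease_genes[d]):
                fh.write(f"{d}\t{g}\n")
    bundle.expression.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    with open(paths["lncrnas"], "w") as fh:
        for l in sorted(bundle.sequences):
            fh.write(f">{l}\n")
            seq = bundle.sequences[l]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["associations"], "w") as fh:
        fh.write("disease_id\tlncrna_id\n")
        for d, l in sorted(bundle.positives):
            fh.write(f"{d}\t{l}\n")
    with open(paths["benchmark"], "w") as fh:
        fh.write("disease_id_1\tdisease_id_2\n")
        for a, b in bundle.benchmark_pairs:
            fh.write(f"{a}\t{b}\n")
    bundle.spec.to_yaml(paths["spec"])
    return paths


def generate_universe(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic universe and write its file bundle."""
    return write_bundle(generate_bundle(spec), out_dir)
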