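"""Gene catalogs, chromosome substructures, pathway catalogs and association sets.

The human genome is modelled as an ordered set of chromosome *substructures*:
the p-arm and q-arm of each divided chromosome, one entry for each undivided
chromosome, and the mitochondrion.  Acrocentric chromosomes 13, 14, 15 and 22
carry essentially no annotated protein-coding genes on their p-arms and are
kept whole by default, which together with the mitochondrion yields the
standard 45-substructure partition.  Genes inside a substructure are ordered
by base-pair position, giving each disease gene set a well-defined binary
occupancy series per substructure.

Pathway catalogs (GMT gene sets) are ordered lexicographically by pathway id
and split into ``T`` near-equal consecutive groups; disease-enriched pathways
produce a second family of binary series over those groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Karyotype order used everywhere: autosomes 1..22, X, Y, mitochondrion last.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

#: Chromosomes kept as a single substructure under the default partition.
DEFAULT_UNDIVIDED: frozenset[str] = frozenset({"13", "14", "15", "22", "MT"})

ARMS = ("p", "q", "whole")

_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}
# p and whole sort before q; "whole" only occurs on undivided chromosomes.
_ARM_RANK = {"p": 0, "whole": 0, "q": 1}


@dataclass(frozen=True, order=False)
class GeneRecord:
    """A gene with its chromosomal location.

    ``position`` is the 1-based base-pair start; it is only ever used to order
    genes within a substructure, so its resolution is irrelevant.
    """

    gene_id: str
    chromosome: str
    arm: str
    position: int

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_INDEX:
            raise ValueError(f"unknown chromosome label {self.chromosome!r} for gene {self.gene_id!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm label {self.arm!r} for gene {self.gene_id!r}")
        if self.chromosome == "MT" and self.arm != "whole":
            raise ValueError(f"mitochondrial gene {self.gene_id!r} must have arm='whole', got {self.arm!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1 for gene {self.gene_id!r}, got {self.position}")

    @property
    def sort_key(self) -> tuple[int, int, int, str]:
        return (_CHROM_INDEX[self.chromosome], _ARM_RANK[self.arm], self.position, self.gene_id)


def load_gene_catalog(path: str | Path) -> list[GeneRecord]:
    """Read a gene catalog TSV (``gene_id  chromosome  arm  position``).

    Records are returned sorted by (karyotype order, arm, position, gene_id).
    Duplicated gene ids and malformed rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chromosome", "arm", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[GeneRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            pos = int(row["position"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {line}: position {row['position']!r} is not an integer") from None
        try:
            records.append(GeneRecord(str(row["gene_id"]), str(row["chromosome"]), str(row["arm"]), pos))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from None
    seen: dict[str, int] = {}
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {rec.gene_id!r}")
        seen[rec.gene_id] = 1
    records.sort(key=lambda r: r.sort_key)
    return records


@dataclass(frozen=True)
class SubstructurePartition:
    """Ordered chromosome substructures with positionally sorted member genes."""

    substructures: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def n_substructures(self) -> int:
        return len(self.substructures)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.substructures)

    @property
    def n_genes(self) -> int:
        return sum(len(members) for _, members in self.substructures)

    def members(self, label: str) -> tuple[str, ...]:
        for lab, mem in self.substructures:
            if lab == label:
                return mem
        raise KeyError(label)

    def gene_to_substructure(self) -> dict[str, int]:
        """Map each gene id to the index of its substructure."""
        out: dict[str, int] = {}
        for i, (_, members) in enumerate(self.substructures):
            for g in members:
                out[g] = i
        return out

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(g for _, members in self.substructures for g in members)


def build_substructure_partition(
    genes: Iterable[GeneRecord],
    undivided: Iterable[str] = DEFAULT_UNDIVIDED,
) -> SubstructurePartition:
    """Partition a gene catalog into ordered chromosome substructures.

    Every chromosome not in ``undivided`` contributes a p and a q substructure;
    each undivided chromosome (and the mitochondrion) contributes one.  Empty
    substructures are retained so the partition length is a fixed function of
    the rules, not of the catalog.
    """
    undivided_set = frozenset(str(u) for u in undivided)
    unknown = undivided_set - set(CHROMOSOMES)
    if unknown:
        raise ValueError(f"unknown chromosome label(s) in undivided set: {sorted(unknown)}")

    buckets: dict[tuple[str, str], list[GeneRecord]] = {}
    for rec in genes:
        if rec.chromosome in undivided_set:
            key = (rec.chromosome, "whole")
        else:
            if rec.arm == "whole":
                raise ValueError(
                    f"gene {rec.gene_id!r} has arm='whole' on divided chromosome {rec.chromosome}"
                )
            key = (rec.chromosome, rec.arm)
        buckets.setdefault(key, []).append(rec)

    subs: list[tuple[str, tuple[str, ...]]] = []
    for chrom in CHROMOSOMES:
        keys = [(chrom, "whole")] if chrom in undivided_set else [(chrom, "p"), (chrom, "q")]
        for chrom_, arm in keys:
            label = f"chr{chrom_}" if arm == "whole" else f"chr{chrom_}{arm}"
            members = sorted(buckets.get((chrom_, arm), []), key=lambda r: (r.position, r.gene_id))
            subs.append((label, tuple(r.gene_id for r in members)))
    return SubstructurePartition(tuple(subs))


@dataclass(frozen=True)
class PathwayCatalog:
    """Pathway gene sets, ordered lexicographically by pathway id."""

    pathways: tuple[tuple[str, frozenset[str]], ...]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.pathways)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.pathways:
            out |= members
        return frozenset(out)

    @property
    def universe_size(self) -> int:
        return len(self.universe)


def load_gmt(path: str | Path) -> PathwayCatalog:
    """Read pathway gene sets from a GMT file (id, description, genes...)."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected id, description and >=1 gene")
            pid = fields[0]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}: line {lineno}: pathway {pid!r} has no member genes")
            if pid in pathways:
                raise ValueError(f"{path}: duplicate pathway id {pid!r}")
            pathways[pid] = members
    return PathwayCatalog(tuple(sorted(pathways.items())))


@dataclass(frozen=True)
class PathwayGrouping:
    """A partition of pathway indices 0..M-1 into T consecutive groups."""

    groups: tuple[tuple[int, ...], ...]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)


def group_pathways(catalog: PathwayCatalog, n_groups: int) -> PathwayGrouping:
    """Split the ordered pathway list into ``n_groups`` consecutive groups.

    The first ``n_groups - 1`` groups have size ``floor(M / n_groups)``; the
    remainder goes into the last group (so with 303 pathways and 30 groups the
    first 29 hold 10 pathways and the last holds 13).
    """
    m = catalog.n_pathways
    if not 1 <= n_groups <= m:
        raise ValueError(f"n_groups must be in [1, {m}], got {n_groups}")
    base = m // n_groups
    groups: list[tuple[int, ...]] = []
    start = 0
    for _ in range(n_groups - 1):
        groups.append(tuple(range(start, start + base)))
        start += base
    groups.append(tuple(range(start, m)))
    return PathwayGrouping(tuple(groups))


def load_disease_genes(
    path: str | Path,
    known_genes: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Read a disease→gene table (TSV ``disease_id  gene_id``, one pair a line).

    Gene ids absent from ``known_genes`` (when given) are dropped with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "disease_id" not in df.columns or "gene_id" not in df.columns:
        raise ValueError(f"{path}: expected columns disease_id, gene_id")
    known = None if known_genes is None else frozenset(known_genes)
    mapping: dict[str, set[str]] = {}
    dropped = 0
    for _, row in df.iterrows():
        d, g = str(row["disease_id"]), str(row["gene_id"])
        if known is not None and g not in known:
            dropped += 1
            continue
        mapping.setdefault(d, set()).add(g)
    if dropped:
        logger.warning("%s: dropped %d disease-gene pairs with gene ids outside the catalog", path, dropped)
    return {d: frozenset(gs) for d, gs in mapping.items()}


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix TSV (first column id, remaining columns tissues).

    Values are coerced to float; missing entries become 0 with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row id(s) {dups[:5]}")
    df = df.apply(pd.to_numeric, errors="coerce")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing expression values set to 0", path, n_missing)
        df = df.fillna(0.0)
    return df


def load_lncrna_fasta(path: str | Path) -> dict[str, str]:
    """Read lncRNA sequences from FASTA; uppercased, U converted to T."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate lncRNA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def load_pairs(path: str | Path, columns: tuple[str, str]) -> list[tuple[str, str]]:
    """Read a two-column id pair TSV (associations or benchmark pairs)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [(str(a), str(b)) for a, b in zip(df[columns[0]], df[columns[1]])]


@dataclass(frozen=True)
class AssociationSet:
    """Known positive disease-lncRNA pairs and the complementary unlabeled pairs."""

    diseases: tuple[str, ...]
    lncrnas: tuple[str, ...]
    positives: tuple[tuple[str, str], ...]
    unlabeled: tuple[tuple[str, str], ...]

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_unlabeled(self) -> int:
        return len(self.unlabeled)


def build_association_set(
    diseases: Sequence[str],
    lncrnas: Sequence[str],
    positives: Iterable[tuple[str, str]],
) -> AssociationSet:
    """Exhaustively pair diseases and lncRNAs; pairs not in ``positives`` are unlabeled."""
    dset, lset = set(diseases), set(lncrnas)
    pos: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for d, l in positives:
        if d not in dset:
            raise ValueError(f"positive pair references unknown disease id {d!r}")
        if l not in lset:
            raise ValueError(f"positive pair references unknown lncRNA id {l!r}")
        if (d, l) not in seen:
            seen.add((d, l))
            pos.append((d, l))
    unl = tuple(p for p in product(diseases, lncrnas) if p not in seen)
    logger.info(
        "association set: %d diseases x %d lncRNAs -> %d positive, %d unlabeled",
        len(diseases), len(lncrnas), len(pos), len(unl),
    )
    return AssociationSet(tuple(diseases), tuple(lncrnas), tuple(pos), unl)
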