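"""Disease vectorization by k-mer window entropy of binary status series.

A disease is turned into two fixed-length real vectors:

* ``v_chr`` (length S): for each chromosome substructure, mark the positions
  of the disease's genes in the substructure's positional gene order with 1,
  slide a window of size ``k1`` over the resulting 0/1 series, and take the
  Shannon entropy (natural log) of the window-pattern distribution.
* ``v_path`` (length T): mark pathways enriched by the disease's gene set
  (Fisher exact, ``p <= alpha``) in the ordered pathway list, cut the list
  into T consecutive groups, and take the ``k2``-window pattern entropy of
  each group's 0/1 series.

Entropy is 0 when a series is shorter than the window (no windows exist) and
when all windows show the same pattern; it grows with the positional
irregularity of the disease's footprint, so diseases whose genes pile up on
the same substructures get vectors pointing in similar directions.  The raw
concatenated status series are retained for the whole-series baseline
similarity methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .enrichment import pathway_enrichment
from .genome import PathwayCatalog, PathwayGrouping, SubstructurePartition


def map_disease_to_series(
    d_g: frozenset[str] | set[str],
    partition: SubstructurePartition,
) -> list[np.ndarray]:
    """Binary occupancy series of a disease gene set, one per substructure."""
    genes = set(d_g)
    return [
        np.fromiter((1 if g in genes else 0 for g in members), dtype=np.int8, count=len(members))
        for _, members in partition.substructures
    ]


def kmer_entropy(series: np.ndarray, k: int) -> float:
    """Shannon entropy (nats) of the k-window pattern distribution of a 0/1 series.

    Windows slide with step 1 and do not wrap; a series with fewer than k
    elements has no windows and entropy 0.  Only observed patterns contribute
    (0*ln 0 := 0).
    """
    if k < 1:
        raise ValueError(f"window size k must be >= 1, got {k}")
    series = np.asarray(series)
    n_windows = series.size - k + 1
    if n_windows <= 0:
        return 0.0
    windows = sliding_window_view(series.astype(np.int64), k)
    codes = windows @ (1 << np.arange(k, dtype=np.int64))
    _, counts = np.unique(codes, return_counts=True)
    freqs = counts / n_windows
    return float(-np.sum(freqs * np.log(freqs)))


@dataclass(frozen=True)
class DiseaseVector:
    """The two entropy sub-vectors of a disease plus its raw status series."""

    disease_id: str
    v_chr: np.ndarray   # length S
    v_path: np.ndarray  # length T
    raw_chr: np.ndarray   # concatenated gene status series, length = catalog size
    raw_path: np.ndarray  # pathway status series, length = number of pathways
    k1: int
    k2: int

    @property
    def config(self) -> tuple[int, int, int, int]:
        """(S, T, k1, k2) — two vectors are comparable iff configs match."""
        return (self.v_chr.size, self.v_path.size, self.k1, self.k2)


def vectorize_disease(
    d_g: frozenset[str] | set[str],
    partition: SubstructurePartition,
    catalog: PathwayCatalog,
    grouping: PathwayGrouping,
    k1: int = 9,
    k2: int = 8,
    alpha: float = 0.05,
    sided: str = "two",
    disease_id: str = "",
) -> DiseaseVector:
    """Run the full vectorization of one disease gene set."""
    chr_series = map_disease_to_series(d_g, partition)
    v_chr = np.array([kmer_entropy(s, k1) for s in chr_series], dtype=float)

    enriched = pathway_enrichment(d_g, catalog, alpha=alpha, sided=sided)
    path_status = enriched["activated"].to_numpy().astype(np.int8)
    v_path = np.array(
        [kmer_entropy(path_status[np.array(g, dtype=int)], k2) for g in grouping.groups],
        dtype=float,
    )

    raw_chr = (
        np.concatenate(chr_series) if chr_series else np.zeros(0, dtype=np.int8)
    )
    return DiseaseVector(disease_id, v_chr, v_path, raw_chr, path_status, k1, k2)


def vectorize_all(
    disease_genes: dict[str, frozenset[str]],
    partition: SubstructurePartition,
    catalog: PathwayCatalog,
    grouping: PathwayGrouping,
    k1: int = 9,
    k2: int = 8,
    alpha: float = 0.05,
    sided: str = "two",
) -> dict[str, DiseaseVector]:
    """Vectorize every disease in a disease→gene map (sorted by disease id)."""
    return {
        d: vectorize_disease(
            disease_genes[d], partition, catalog, grouping,
            k1=k1, k2=k2, alpha=alpha, sided=sided, disease_id=d,
        )
        for d in sorted(disease_genes)
    }


def vectors_to_frame(vectors: dict[str, DiseaseVector]) -> "pd.DataFrame":
    """Tabulate vectors: one row per disease, columns chr_1..chr_S, path_1..path_T."""
    import pandas as pd

    rows = {}
    for d, vec in vectors.items():
        rows[d] = np.concatenate([vec.v_chr, vec.v_path])
    some = next(iter(vectors.values()))
    cols = [f"chr_{i + 1}" for i in range(some.v_chr.size)] + [
        f"path_{i + 1}" for i in range(some.v_path.size)
    ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "disease_id"
    return df.sort_index()
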