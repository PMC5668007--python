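"""lncRNA sub-vectors and disease-lncRNA pair feature assembly.

A disease-lncRNA pair is described by up to five sub-vectors:

* ``sf1`` — the disease's chromosome-substructure entropy vector (length S);
* ``sf2`` — the disease's pathway-group entropy vector (length T);
* ``sf3`` — the lncRNA sequence's k-mer frequency vector (length 4^k);
* ``sf4`` — the lncRNA's expression profile over tissues;
* ``sf5`` — (max, min, mean) Spearman correlation between the lncRNA's
  expression profile and the profiles of the disease's genes.

Feature type W in 0..7 selects which optional sub-vectors join the always
present sf1 and sf3: bit 0 adds sf2, bit 1 adds sf4, bit 2 adds sf5, matching
the eight published combinations.  Concatenation order is sf1..sf5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .vectorize import DiseaseVector

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_CODE = {c: i for i, c in enumerate(ALPHABET)}

#: Sub-vector membership per feature type (sf1 and sf3 are always present).
FEATURE_TYPE_MEMBERS: dict[int, tuple[str, ...]] = {
    w: tuple(
        sf
        for sf, present in (
            ("sf1", True),
            ("sf2", bool(w & 1)),
            ("sf3", True),
            ("sf4", bool(w & 2)),
            ("sf5", bool(w & 4)),
        )
        if present
    )
    for w in range(8)
}


def kmer_index(k: int) -> list[str]:
    """All 4^k k-mers in alphabetic order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def kmer_frequencies(seq: str, k: int = 3) -> np.ndarray:
    """Sliding-window k-mer frequencies of a nucleotide sequence.

    The sequence is uppercased with U→T.  Windows containing characters
    outside ACGT are skipped and excluded from the denominator, so the result
    is a probability vector whenever at least one valid window exists (and all
    zeros otherwise).
    """
    if k < 1:
        raise ValueError(f"k-mer size must be >= 1, got {k}")
    seq = seq.upper().replace("U", "T")
    out = np.zeros(4 ** k)
    codes = np.fromiter((_BASE_CODE.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    n_windows = len(seq) - k + 1
    if n_windows <= 0:
        return out
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return out
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    encoded = windows[valid] @ powers
    counts = np.bincount(encoded, minlength=4 ** k)
    return counts / counts.sum()


def coexpression(
    lnc_profile: np.ndarray,
    gene_profiles: np.ndarray,
) -> tuple[float, float, float]:
    """(max, min, mean) Spearman correlation of an lncRNA profile with gene profiles.

    ``gene_profiles`` is a (genes x tissues) array; rows are the expression
    profiles of the disease's genes that have expression data (the caller
    skips genes without it).  A zero-variance profile on either side yields
    correlation 0; with no gene profiles at all the result is (0, 0, 0) with a
    warning.
    """
    lnc_profile = np.asarray(lnc_profile, dtype=float)
    gene_profiles = np.atleast_2d(np.asarray(gene_profiles, dtype=float))
    if gene_profiles.size == 0:
        logger.warning("no disease genes with expression data; co-expression set to (0, 0, 0)")
        return (0.0, 0.0, 0.0)
    rhos = []
    for row in gene_profiles:
        if np.ptp(lnc_profile) == 0 or np.ptp(row) == 0:
            rhos.append(0.0)
            continue
        rho = spearmanr(lnc_profile, row).statistic
        rhos.append(0.0 if np.isnan(rho) else float(rho))
    arr = np.array(rhos)
    return (float(arr.max()), float(arr.min()), float(arr.mean()))


def _spearman_matrix(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Spearman correlations between every row of ``left`` and of ``right``.

    Zero-variance rows correlate 0 with everything (matching `coexpression`).
    """
    def center_ranks(mat: np.ndarray) -> np.ndarray:
        ranks = rankdata(mat, axis=1)
        ranks -= ranks.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(ranks, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(norms > 0, ranks / np.where(norms == 0, 1, norms), 0.0)
        return out

    return center_ranks(left) @ center_ranks(right).T


def feature_length(
    w: int,
    n_substructures: int = 45,
    n_groups: int = 30,
    kmer_size: int = 3,
    n_tissues: int = 16,
) -> int:
    """Dimensionality of a pair vector as a pure function of the configuration."""
    members = FEATURE_TYPE_MEMBERS[w]
    sizes = {
        "sf1": n_substructures,
        "sf2": n_groups,
        "sf3": 4 ** kmer_size,
        "sf4": n_tissues,
        "sf5": 3,
    }
    return sum(sizes[m] for m in members)


def assemble_pair(
    d_vec: DiseaseVector,
    seq_kmers: np.ndarray,
    expr_profile: np.ndarray | None,
    coexp: tuple[float, float, float] | None,
    w: int,
) -> np.ndarray:
    """Concatenate the selected sub-vectors of one disease-lncRNA pair."""
    if w not in FEATURE_TYPE_MEMBERS:
        raise ValueError(f"feature type W must be in 0..7, got {w}")
    blocks: list[np.ndarray] = []
    for member in FEATURE_TYPE_MEMBERS[w]:
        if member == "sf1":
            blocks.append(d_vec.v_chr)
        elif member == "sf2":
            blocks.append(d_vec.v_path)
        elif member == "sf3":
            blocks.append(np.asarray(seq_kmers, dtype=float))
        elif member == "sf4":
            if expr_profile is None:
                raise ValueError("feature type requires sf4 but no expression profile was given")
            blocks.append(np.asarray(expr_profile, dtype=float))
        elif member == "sf5":
            if coexp is None:
                raise ValueError("feature type requires sf5 but no co-expression statistics were given")
            blocks.append(np.asarray(coexp, dtype=float))
    return np.concatenate(blocks)


@dataclass(frozen=True)
class FeatureStore:
    """Precomputed per-disease, per-lncRNA and per-pair feature blocks.

    ``matrix`` gathers pair vectors for any list of (disease, lncRNA) pairs
    without recomputation, which keeps cross-validation loops cheap.
    """

    diseases: tuple[str, ...]
    lncrnas: tuple[str, ...]
    v_chr: np.ndarray    # (D, S)
    v_path: np.ndarray   # (D, T)
    seq_kmers: np.ndarray  # (L, 4^k)
    profiles: np.ndarray | None    # (L, tissues); NaN row = missing expression
    coexp: np.ndarray | None       # (D, L, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_d_index", {d: i for i, d in enumerate(self.diseases)})
        object.__setattr__(self, "_l_index", {l: i for i, l in enumerate(self.lncrnas)})

    @classmethod
    def build(
        cls,
        vectors: dict[str, DiseaseVector],
        sequences: dict[str, str],
        disease_genes: dict[str, frozenset[str]] | None = None,
        expression: pd.DataFrame | None = None,
        kmer_size: int = 3,
    ) -> "FeatureStore":
        """Assemble all blocks; expression-dependent blocks need ``expression``.

        Co-expression is computed with a rank-matrix product equivalent to
        per-pair Spearman correlations (zero-variance rows give 0).
        """
        diseases = tuple(sorted(vectors))
        lncrnas = tuple(sorted(sequences))
        v_chr = np.stack([vectors[d].v_chr for d in diseases])
        v_path = np.stack([vectors[d].v_path for d in diseases])
        seq_kmers = np.stack([kmer_frequencies(sequences[l], kmer_size) for l in lncrnas])

        profiles = None
        coexp = None
        if expression is not None:
            n_tissues = expression.shape[1]
            profiles = np.full((len(lncrnas), n_tissues), np.nan)
            for i, l in enumerate(lncrnas):
                if l in expression.index:
                    profiles[i] = expression.loc[l].to_numpy(dtype=float)
            if disease_genes is not None:
                lnc_corr_ready = np.nan_to_num(profiles, nan=0.0)
                expr_genes = expression.index
                corr = _spearman_matrix(lnc_corr_ready, expression.to_numpy(dtype=float))
                gene_pos = {g: j for j, g in enumerate(expr_genes)}
                coexp = np.zeros((len(diseases), len(lncrnas), 3))
                for di, d in enumerate(diseases):
                    cols = [gene_pos[g] for g in sorted(disease_genes.get(d, frozenset())) if g in gene_pos]
                    if not cols:
                        logger.warning(
                            "disease %s has no genes with expression data; co-expression set to 0", d
                        )
                        continue
                    sub = corr[:, cols]
                    coexp[di, :, 0] = sub.max(axis=1)
                    coexp[di, :, 1] = sub.min(axis=1)
                    coexp[di, :, 2] = sub.mean(axis=1)
        return cls(diseases, lncrnas, v_chr, v_path, seq_kmers, profiles, coexp)

    @property
    def n_tissues(self) -> int:
        if self.profiles is None:
            raise ValueError("feature store was built without expression data")
        return self.profiles.shape[1]

    def matrix(self, pairs: list[tuple[str, str]], w: int) -> np.ndarray:
        """Stack the type-W feature vectors of the given pairs, in order."""
        if w not in FEATURE_TYPE_MEMBERS:
            raise ValueError(f"feature type W must be in 0..7, got {w}")
        members = FEATURE_TYPE_MEMBERS[w]
        if ("sf4" in members or "sf5" in members) and self.profiles is None:
            raise ValueError(f"feature type {w} needs expression data, but none was loaded")
        d_idx = np.array([self._d_index[d] for d, _ in pairs], dtype=int)
        l_idx = np.array([self._l_index[l] for _, l in pairs], dtype=int)
        blocks: list[np.ndarray] = []
        for member in members:
            if member == "sf1":
                blocks.append(self.v_chr[d_idx])
            elif member == "sf2":
                blocks.append(self.v_path[d_idx])
            elif member == "sf3":
                blocks.append(self.seq_kmers[l_idx])
            elif member == "sf4":
                block = self.profiles[l_idx]
                if np.isnan(block).any():
                    bad = sorted({pairs[i][1] for i in np.where(np.isnan(block).any(axis=1))[0]})
                    raise ValueError(f"missing expression profile for lncRNA id(s) {bad[:5]}")
                blocks.append(block)
            elif member == "sf5":
                if self.coexp is None:
                    raise ValueError(f"feature type {w} needs co-expression data, but none was built")
                nan_rows = np.isnan(self.profiles[l_idx]).any(axis=1)
                if nan_rows.any():
                    bad = sorted({pairs[i][1] for i in np.where(nan_rows)[0]})
                    raise ValueError(f"missing expression profile for lncRNA id(s) {bad[:5]}")
                blocks.append(self.coexp[d_idx, l_idx])
        return np.concatenate(blocks, axis=1)

    def to_frame(self, pairs: list[tuple[str, str]], w: int) -> pd.DataFrame:
        mat = self.matrix(pairs, w)
        cols = [f"f_{i + 1}" for i in range(mat.shape[1])]
        df = pd.DataFrame(mat, columns=cols)
        df.insert(0, "disease_id", [d for d, _ in pairs])
        df.insert(1, "lncrna_id", [l for _, l in pairs])
        return df
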