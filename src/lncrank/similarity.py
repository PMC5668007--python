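"""Disease-disease similarity from entropy vectors via subspace angles.

For two diseases the principal angle between their chromosome-entropy vectors
(``simGe``) and between their pathway-entropy vectors (``simPe``) are combined
into

    Sim(d1, d2) = exp(-[theta * simGe + (1 - theta) * simPe])

so identical directions give similarity 1 and orthogonal directions give
``exp(-pi/2)`` per component.  When either vector of a component has zero norm
the angle for that component is defined as 0 (the similarity-maximal branch of
the defining equations); a strict mode instead returns similarity 0 for such
degenerate pairs.

The whole-series baselines apply the same angle→exponential pipeline directly
to the concatenated raw 0/1 status series, and ``benchmark_roc`` evaluates any
of these scores against a gold standard of similar disease pairs by ranking
them among randomly sampled non-benchmark pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import rank_auc
from .vectorize import DiseaseVector

SIM_METHODS = ("entropy", "status_gene", "status_path")


def subspace_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Principal angle between two nonzero vectors, in [0, pi/2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("subspace_angle requires nonzero vectors; zero-norm handling is the caller's")
    cosine = min(1.0, abs(float(x @ y)) / (nx * ny))
    return float(np.arccos(cosine))


def _component_angle(x: np.ndarray, y: np.ndarray, strict: bool) -> float | None:
    """Angle with the zero-norm branch: 0 (or None in strict mode) when degenerate."""
    if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
        return None if strict else 0.0
    return subspace_angle(x, y)


def sim_components(d1: DiseaseVector, d2: DiseaseVector, strict: bool = False) -> tuple[float, float]:
    """(simGe, simPe) angles for a disease pair, with the zero-norm convention."""
    if d1.config != d2.config:
        raise ValueError(f"disease vector configuration mismatch: {d1.config} vs {d2.config}")
    ge = _component_angle(d1.v_chr, d2.v_chr, strict)
    pe = _component_angle(d1.v_path, d2.v_path, strict)
    if ge is None or pe is None:
        return (float("nan"), float("nan"))
    return (ge, pe)


def integrated_similarity(
    d1: DiseaseVector,
    d2: DiseaseVector,
    theta: float = 0.8,
    strict: bool = False,
) -> float:
    """Similarity in (0, 1]: exp(-[theta*simGe + (1-theta)*simPe])."""
    if not 0 <= theta <= 1:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    ge, pe = sim_components(d1, d2, strict=strict)
    if np.isnan(ge):
        return 0.0  # strict mode: geneless/pathwayless pair deemed dissimilar
    return float(np.exp(-(theta * ge + (1 - theta) * pe)))


def status_series_similarity(d1: DiseaseVector, d2: DiseaseVector, which: str = "gene") -> float:
    """Baseline similarity on the raw concatenated 0/1 series (gene or pathway)."""
    if which not in ("gene", "pathway"):
        raise ValueError(f"which must be 'gene' or 'pathway', got {which!r}")
    x = d1.raw_chr if which == "gene" else d1.raw_path
    y = d2.raw_chr if which == "gene" else d2.raw_path
    if x.shape != y.shape:
        raise ValueError(f"status series length mismatch: {x.shape} vs {y.shape}")
    angle = _component_angle(np.asarray(x, float), np.asarray(y, float), strict=False)
    return float(np.exp(-angle))


def pair_score(
    d1: DiseaseVector,
    d2: DiseaseVector,
    method: str = "entropy",
    theta: float = 0.8,
) -> float:
    """Score one disease pair with the chosen similarity method."""
    if method == "entropy":
        return integrated_similarity(d1, d2, theta=theta)
    if method == "status_gene":
        return status_series_similarity(d1, d2, which="gene")
    if method == "status_path":
        return status_series_similarity(d1, d2, which="pathway")
    raise ValueError(f"method must be one of {SIM_METHODS}, got {method!r}")


@dataclass(frozen=True)
class BenchmarkRocResult:
    average_auc: float
    overall_auc: float
    per_repeat_auc: np.ndarray
    pooled_scores: np.ndarray = field(repr=False)
    pooled_labels: np.ndarray = field(repr=False)


def benchmark_roc(
    vectors: dict[str, DiseaseVector],
    benchmark_pairs: list[tuple[str, str]],
    theta: float = 0.8,
    method: str = "entropy",
    n_random: int = 560,
    repeats: int = 100,
    seed: int = 0,
) -> BenchmarkRocResult:
    """Rank benchmark similar-disease pairs against random non-benchmark pairs.

    Per repeat, ``n_random`` candidate pairs are sampled (without replacement,
    excluding the benchmark) and an AUC is computed from the benchmark-pair
    scores versus the sampled-pair scores.  The average AUC is the mean over
    repeats; the overall AUC pools every repeat's scores.
    """
    if not benchmark_pairs:
        raise ValueError("benchmark set is empty")
    missing = sorted({d for pair in benchmark_pairs for d in pair} - set(vectors))
    if missing:
        raise ValueError(f"benchmark references diseases without vectors: {missing[:5]}")

    bench = {tuple(sorted(p)) for p in benchmark_pairs}
    ids = sorted(vectors)
    candidates = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if (ids[i], ids[j]) not in bench
    ]
    if n_random > len(candidates):
        raise ValueError(f"n_random={n_random} exceeds the {len(candidates)} available non-benchmark pairs")

    pos_scores = np.array(
        [pair_score(vectors[a], vectors[b], method, theta) for a, b in sorted(bench)]
    )
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(repeats)
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for r in range(repeats):
        idx = rng.choice(len(candidates), size=n_random, replace=False)
        neg_scores = np.array(
            [pair_score(vectors[candidates[i][0]], vectors[candidates[i][1]], method, theta) for i in idx]
        )
        per_repeat[r] = rank_auc(pos_scores, neg_scores)
        pooled_scores.append(np.concatenate([pos_scores, neg_scores]))
        pooled_labels.append(
            np.concatenate([np.ones(pos_scores.size, int), np.zeros(neg_scores.size, int)])
        )
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    overall = rank_auc(scores[labels == 1], scores[labels == 0])
    return BenchmarkRocResult(float(per_repeat.mean()), overall, per_repeat, scores, labels)
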