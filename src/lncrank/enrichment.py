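"""Fisher's exact test enrichment of disease gene sets.

A disease gene set is tested against every pathway (or every chromosome
substructure) with a 2x2 exact test on the table

    [[L - B, B], [A - L - n + B, n - B]]

where ``A`` is the universe size, ``L`` the feature-set size, ``n`` the number
of disease genes inside the universe and ``B`` the overlap.  The p-value is
computed with exact integer arithmetic over the hypergeometric support, so the
two-sided tie rule ("tables at most as likely as the observed one") is
unambiguous.  A feature is *activated* when ``p <= alpha`` (default 0.05); no
multiple-testing correction is applied — activation flags feed the downstream
status series, they are not reported discoveries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping

import pandas as pd

from .genome import PathwayCatalog, SubstructurePartition

logger = logging.getLogger(__name__)

SIDEDNESS = ("two", "right")


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 enrichment table parameterized by its margins and overlap."""

    universe: int  # A
    feature: int   # L
    query: int     # n
    overlap: int   # B

    def __post_init__(self) -> None:
        a, l, n, b = self.universe, self.feature, self.query, self.overlap
        cells = {
            "L - B": l - b,
            "B": b,
            "A - L - n + B": a - l - n + b,
            "n - B": n - b,
        }
        for name, value in cells.items():
            if value < 0:
                raise ValueError(f"contingency cell {name} is negative ({value})")

    @property
    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a, l, n, b = self.universe, self.feature, self.query, self.overlap
        return ((l - b, b), (a - l - n + b, n - b))


def _support_weights(a: int, l: int, n: int) -> tuple[int, list[int]]:
    """Integer hypergeometric weights C(L,b)*C(A-L,n-b) over the support of b."""
    lo = max(0, n + l - a)
    hi = min(l, n)
    return lo, [comb(l, b) * comb(a - l, n - b) for b in range(lo, hi + 1)]


def fisher_exact_p(table: ContingencyTable, sided: str = "two") -> float:
    """Exact p-value for an enrichment contingency table.

    ``right`` gives P(X >= B) for hypergeometric overlap X; ``two`` sums the
    probabilities of all tables with the observed margins that are at most as
    likely as the observed table (ties resolved exactly in integers).
    """
    if sided not in SIDEDNESS:
        raise ValueError(f"sided must be one of {SIDEDNESS}, got {sided!r}")
    a, l, n, b = table.universe, table.feature, table.query, table.overlap
    lo, weights = _support_weights(a, l, n)
    total = comb(a, n)
    if sided == "right":
        num = sum(weights[b - lo:])
    else:
        w_obs = weights[b - lo]
        num = sum(w for w in weights if w <= w_obs)
    return num / total


def _enrich(
    d_g: frozenset[str] | set[str],
    features: Iterable[tuple[str, frozenset[str] | set[str]]],
    universe: frozenset[str] | set[str],
    alpha: float,
    sided: str,
) -> pd.DataFrame:
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a = len(universe)
    query = set(d_g) & set(universe)
    n = len(query)
    if n == 0:
        logger.warning("disease gene set has no genes in the universe; all p-values set to 1")
    rows = []
    for fid, members in features:
        members = set(members) & set(universe)
        l = len(members)
        if n == 0:
            p = 1.0
        else:
            b = len(query & members)
            p = fisher_exact_p(ContingencyTable(a, l, n, b), sided=sided)
        rows.append((fid, p, p <= alpha))
    return pd.DataFrame(rows, columns=["feature_id", "p_value", "activated"])


def pathway_enrichment(
    d_g: frozenset[str] | set[str],
    catalog: PathwayCatalog,
    alpha: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Test a disease gene set against every pathway in the catalog.

    The universe is the union of all pathway genes; disease genes outside it
    do not count toward ``n``.
    """
    universe = catalog.universe
    return _enrich(d_g, catalog.pathways, universe, alpha, sided)


def substructure_enrichment(
    d_g: frozenset[str] | set[str],
    partition: SubstructurePartition,
    alpha: float = 0.05,
    sided: str = "two",
) -> pd.DataFrame:
    """Test a disease gene set against every chromosome substructure.

    The universe is the full gene catalog held by the partition (the caller
    controls whether that catalog is protein-coding only).
    """
    universe = partition.all_genes
    features = [(label, frozenset(members)) for label, members in partition.substructures]
    return _enrich(d_g, features, universe, alpha, sided)


def enrichment_summary(
    results: Mapping[str, pd.DataFrame],
) -> tuple[dict[int, int], pd.Series]:
    """Summarize per-disease enrichment results.

    Returns a histogram ``{activated-feature count: number of diseases}`` and
    the per-feature fraction of diseases activating it.
    """
    if not results:
        raise ValueError("need at least one disease's enrichment result")
    hist: dict[int, int] = {}
    counts: pd.Series | None = None
    for df in results.values():
        k = int(df["activated"].sum())
        hist[k] = hist.get(k, 0) + 1
        activated = df.set_index("feature_id")["activated"].astype(int)
        counts = activated if counts is None else counts.add(activated, fill_value=0)
    fractions = counts / len(results)
    fractions.name = "fraction_activated"
    return hist, fractions
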