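"""Hypergeometric overlap tests between gene lists.

Given two gene lists of sizes ``size_a`` and ``size_b`` drawn from a
common measured-gene universe of size ``N``, the upper-tail
hypergeometric probability P(X >= k) of observing at least the k genes
they share is the standard enrichment test for list overlap.  The tail is
accumulated in log space via log-gamma so that p-values far below float
underflow (printed in atlas studies as, e.g., p < 1e-134) still have an
exact log10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class OverlapTest:
    """Result of one hypergeometric overlap test."""

    n_universe: int
    size_a: int
    size_b: int
    overlap: int
    p_upper: float
    log10_p: float
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.overlap > min(self.size_a, self.size_b):
            raise ValueError("overlap exceeds the smaller list size")


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_overlap(k: int, size_a: int, size_b: int, n_universe: int) -> OverlapTest:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, size_a, size_b).

    The probability mass terms C(a, j) C(N-a, b-j) / C(N, b) for
    j = k .. min(a, b) are summed with log-sum-exp; both the probability
    (which may underflow to 0.0) and its exact log10 are returned.
    """
    if not (0 <= size_a <= n_universe and 0 <= size_b <= n_universe):
        raise ValueError("list sizes must lie in [0, n_universe]")
    if k < 0 or k > min(size_a, size_b):
        raise ValueError(f"impossible overlap k={k} for sizes ({size_a}, {size_b})")
    k_min = max(0, size_a + size_b - n_universe)  # smallest possible overlap
    if k <= k_min:
        return OverlapTest(n_universe, size_a, size_b, int(k), 1.0, 0.0)
    j = np.arange(k, min(size_a, size_b) + 1, dtype=float)
    log_terms = (
        _log_binom(size_a, j)
        + _log_binom(n_universe - size_a, size_b - j)
        - _log_binom(n_universe, np.array(float(size_b)))
    )
    log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)
    return OverlapTest(
        n_universe, size_a, size_b, int(k),
        p_upper=float(np.exp(log_p)),
        log10_p=log_p / np.log(10.0),
    )


def compare_gene_lists(
    list_a: Sequence[str], list_b: Sequence[str], universe: Sequence[str]
) -> OverlapTest:
    """Test the overlap of two explicit gene lists against a universe.

    Both lists must be subsets of the universe; the shared genes are
    carried on the result.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValueError(f"genes absent from the universe: {stray[:10]}")
    shared = a & b
    test = hypergeom_overlap(len(shared), len(a), len(b), len(uni))
    return OverlapTest(
        test.n_universe, test.size_a, test.size_b, test.overlap,
        test.p_upper, test.log10_p, genes=tuple(sorted(shared)),
    )


def compare_top_k(ranking_a, ranking_b, k: int = 20, universe_size: int | None = None) -> OverlapTest:
    """Overlap of the top-k genes of two rankings over the same universe."""
    from regiontx.enrichment import _ranking_genes

    genes_a = _ranking_genes(ranking_a)
    genes_b = _ranking_genes(ranking_b)
    n = universe_size if universe_size is not None else len(genes_a)
    if k > n or k > len(genes_a) or k > len(genes_b):
        raise ValueError(f"k={k} exceeds the ranking universe")
    top_a, top_b = set(genes_a[:k]), set(genes_b[:k])
    shared = top_a & top_b
    test = hypergeom_overlap(len(shared), k, k, n)
    return OverlapTest(
        test.n_universe, test.size_a, test.size_b, test.overlap,
        test.p_upper, test.log10_p, genes=tuple(sorted(shared)),
    )
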