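"""Exact hypergeometric overlap tests and Bonferroni-corrected annotation.

Over-representation is assessed on an explicit detected-gene background:
with N background genes, K in set A, n in set B and k shared, the p-value
is the exact upper tail P(X >= k) of Hypergeometric(N, K, n). Evaluation
goes through log-gamma arithmetic (scipy's survival function), which stays
accurate at the extreme tails these screens produce (p ~ 1e-56). Pathway
annotation applies a Bonferroni correction over the collection — the
"expectation value" e = min(1, m * p) — with e < 0.1 called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from plaquesig.io import GeneSet, GeneSetCollection, ValidationError


@dataclass
class OverlapResult:
    """The (N, K, n, k) overlap contingency and its exact upper-tail p."""

    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    expected_k: float
    fold_enrichment: float  # nan when expected_k == 0

    def as_dict(self) -> dict:
        return {"N": self.N, "K": self.K, "n": self.n, "k": self.k,
                "p_hyper": self.p_hyper, "expected_k": self.expected_k,
                "fold_enrichment": self.fold_enrichment}


@dataclass
class EnrichmentRow:
    """One pathway set's annotation against a query set."""

    set_name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    e_value: float
    significant: bool


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Sum_{j=k}^{min(K,n)} C(K,j) C(N-K,n-j) / C(N,n), evaluated in log
    space. P(X >= 0) = 1 by convention.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v != int(v) or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ValidationError(f"set sizes exceed background: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValidationError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    # scipy parameterization: M=N population, n=K successes, N=n draws.
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0)


def overlap_test(set_a: GeneSet, set_b: GeneSet, background: GeneSet) -> OverlapResult:
    """Hypergeometric overlap of two sets restricted to a background."""
    if len(background) == 0:
        raise ValidationError("background is empty")
    bg = background.members
    a = set_a.members & bg
    b = set_b.members & bg
    for name, s in ((set_a.name, a), (set_b.name, b)):
        if not s:
            raise ValidationError(
                f"set {name!r} is empty after restriction to the background")
    N, K, n, k = len(bg), len(a), len(b), len(a & b)
    expected = n * K / N
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(N, K, n, k, hypergeom_tail(N, K, n, k), expected, fold)


def venn_counts(set_a: GeneSet, set_b: GeneSet,
                background: GeneSet) -> tuple[int, int, int, int]:
    """(|A only|, |B only|, |A and B|, N) after background restriction."""
    if len(background) == 0:
        raise ValidationError("background is empty")
    bg = background.members
    a = set_a.members & bg
    b = set_b.members & bg
    inter = a & b
    return (len(a - b), len(b - a), len(inter), len(bg))


def annotate(query: GeneSet, collection: GeneSetCollection,
             background: GeneSet, e_cut: float = 0.1) -> list[EnrichmentRow]:
    """Annotate a query set against a pathway collection on a background.

    One row per pathway set; e = min(1, m * p) with m the collection size;
    significant iff e < ``e_cut`` (strict). Rows are ordered by raw p
    ascending, ties broken by set name. Pathway sets empty on the
    background yield k = 0, p = 1 rows rather than errors.
    """
    if len(collection) == 0:
        raise ValidationError("pathway collection is empty")
    bg = background.members
    if not bg:
        raise ValidationError("background is empty")
    q = query.members & bg
    if not q:
        raise ValidationError(
            f"query set {query.name!r} is empty after restriction to the background")
    m = len(collection)
    rows = []
    for s in collection:
        members = s.members & bg
        k = len(q & members)
        p = hypergeom_tail(len(bg), len(members), len(q), k)
        e = min(1.0, m * p)
        rows.append(EnrichmentRow(s.name, len(bg), len(members), len(q), k,
                                  p, e, e < e_cut))
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows


def enrichment_table(rows: list[EnrichmentRow]):
    """Annotation rows as a DataFrame for TSV export."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in rows]).set_index("set_name")
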