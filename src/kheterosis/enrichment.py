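"""GO-term over-representation of gene sets against a whole-background.

One-sided hypergeometric tests with Bonferroni control over the tested
terms; optional propagation of annotations up an is_a/part_of parent map
before counting; plain sorted set intersection for comparing pattern gene
sets between crosses.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

ENRICHMENT_COLUMNS = (
    "term_id",
    "set_hits",
    "set_size",
    "background_hits",
    "background_size",
    "p",
    "p_bonferroni",
)


class EnrichmentError(ValueError):
    """Raised for inconsistent count configurations or gene sets."""


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail over-representation probability P(X >= k).

    X ~ Hypergeometric(N, K, n): ``k`` annotated genes in a set of ``n``,
    drawn from a background of ``N`` genes of which ``K`` carry the term.
    Summed in log space for stable small tails.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise EnrichmentError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    upper = min(n, K)
    if k > upper:
        return 0.0
    xs = np.arange(k, upper + 1)
    return float(np.exp(logsumexp(stats.hypergeom.logpmf(xs, N, K, n))))


def propagate_annotation(
    annotation: Mapping[str, Iterable[str]],
    parents: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Extend each gene's terms with all ancestors in the parent map.

    The parent map must be acyclic; a cycle raises an error.
    """
    closure: dict[str, set[str]] = {}

    def ancestors(term: str, trail: tuple[str, ...] = ()) -> set[str]:
        if term in closure:
            return closure[term]
        if term in trail:
            raise EnrichmentError(f"cycle in parent map at term {term!r}")
        result: set[str] = set()
        for parent in parents.get(term, ()):  # direct parents plus their closures
            result.add(parent)
            result |= ancestors(parent, trail + (term,))
        closure[term] = result
        return result

    out: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        full = set(terms)
        for t in list(full):
            full |= ancestors(t)
        out[gene] = full
    return out


def enrich(
    set_genes: Sequence[str],
    annotation: Mapping[str, Iterable[str]],
    background: Sequence[str],
    parents: Mapping[str, Iterable[str]] | None = None,
    min_term_size: int = 2,
    max_term_frac: float = 0.5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term hit by the set.

    The background defines N; terms are counted over background genes only.
    Terms with at least one set hit and a background count K within
    ``[min_term_size, max_term_frac * N]`` are tested; the Bonferroni factor
    is the number of tested terms. Rows come back sorted by raw p (ties by
    term id).
    """
    background_set = set(background)
    offenders = sorted(set(set_genes) - background_set)
    if offenders:
        raise EnrichmentError(f"set genes absent from background: {offenders[:10]}")
    if parents is not None:
        annotation = propagate_annotation(annotation, parents)
    N = len(background_set)
    n = len(set(set_genes))
    term_background: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    genes_in_set = set(set_genes)
    for gene in background_set:
        for term in annotation.get(gene, ()):
            if not term:
                raise EnrichmentError(f"empty term id annotating gene {gene!r}")
            term_background[term] = term_background.get(term, 0) + 1
            if gene in genes_in_set:
                term_hits[term] = term_hits.get(term, 0) + 1
    max_K = max_term_frac * N
    tested = sorted(
        t for t, k in term_hits.items() if min_term_size <= term_background[t] <= max_K
    )
    rows = []
    for term in tested:
        k, K = term_hits[term], term_background[term]
        rows.append((term, k, n, K, N, hypergeom_test(k, n, K, N)))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    m = len(df)
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)


def intersect_sets(a: Iterable[str], b: Iterable[str]) -> list[str]:
    """Deduplicated sorted intersection of two gene lists."""
    return sorted(set(a) & set(b))
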