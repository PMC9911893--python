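"""GO over-representation against the genomic background.

One-sided hypergeometric tail test per term (equivalent to one-sided
Fisher's exact enrichment), Benjamini–Hochberg adjustment, and the
clusterProfiler-style cutoffs (adjusted p < 0.05, q < 0.2).  The q-value
is approximated by the BH-adjusted p (the pi0 = 1 limit of Storey's
estimator), a documented divergence that is conservative.  The background
is the annotated genome: genes without any GO term do not contribute to
N.  Annotations can optionally be closed under the ontology's true-path
rule through a child->parent edge table.
"""

from __future__ import annotations

from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


def propagate_annotations(
    gene_terms: Mapping[str, Iterable[str]],
    parent_edges: Iterable[tuple[str, str]],
) -> dict[str, set[str]]:
    """Close annotations under ancestry: a gene with a term has all its ancestors.

    ``parent_edges`` are (child, parent) rows and must be acyclic; the
    operation is idempotent.
    """
    parents: dict[str, set[str]] = {}
    for child, parent in parent_edges:
        parents.setdefault(child, set()).add(parent)
    # cycle check over the full edge set
    ts = TopologicalSorter({c: ps for c, ps in parents.items()})
    try:
        ts.prepare()
    except CycleError as exc:
        raise EnrichmentError(f"cycle in GO parent edges: {exc.args}") from exc

    ancestors: dict[str, set[str]] = {}

    def _ancestors(term: str) -> set[str]:
        if term not in ancestors:
            acc: set[str] = set()
            for p in parents.get(term, ()):
                acc.add(p)
                acc |= _ancestors(p)
            ancestors[term] = acc
        return ancestors[term]

    out: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        closed = set(terms)
        for term in terms:
            closed |= _ancestors(term)
        out[gene] = closed
    return out


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the over-representation p-value.

    k successes in a sample of n, from a population of N containing K
    successes.
    """
    if not (0 <= k <= min(n, K)) or K > N or n > N or min(k, K, n, N) < 0:
        raise EnrichmentError(
            f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Iterable[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving with input."""
    pvals = list(pvals)
    if not pvals:
        return []
    if any(not 0.0 < p <= 1.0 for p in pvals):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def enrich(
    gene_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
    p_adj_cutoff: float = 0.05,
    q_cutoff: float = 0.2,
    parent_edges: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` against ``background``.

    Only annotated genes count: N is the number of background genes with
    at least one term, n the number of annotated set genes.  Terms with
    k >= 1 set genes are tested; results are sorted by ascending p (ties
    by term id).  ``significant`` requires adjusted p below
    ``p_adj_cutoff`` and q below ``q_cutoff``.
    """
    if parent_edges is not None:
        annotations = propagate_annotations(annotations, parent_edges)
    background = set(background)
    gene_set = set(gene_set) & background
    annotated_bg = {g for g in background if annotations.get(g)}
    annotated_set = {g for g in gene_set if annotations.get(g)}
    N = len(annotated_bg)
    n = len(annotated_set)
    if n == 0:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p", "p_adj", "q", "significant"]
        )
    term_bg: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in annotated_bg:
        for term in annotations[gene]:
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in annotated_set:
                term_set[term] = term_set.get(term, 0) + 1
    rows = []
    for term in sorted(term_set):
        k = term_set[term]
        K = term_bg[term]
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "p": hypergeom_tail(k, K, n, N)}
        )
    frame = pd.DataFrame(rows)
    frame["p_adj"] = bh_adjust(frame["p"])
    frame["q"] = frame["p_adj"]  # BH surrogate for Storey's q (pi0 = 1)
    frame["significant"] = (frame["p_adj"] < p_adj_cutoff) & (frame["q"] < q_cutoff)
    return frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
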