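"""GO-style compartment filtering and hypergeometric over-representation.

Annotations are flat gene -> term associations (no ontology-graph
propagation). Compartment filtering keeps genes carrying at least one of a
set of cellular-component terms; enrichment tests each biological-process
term by the one-sided hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the background size, K the background genes carrying the term,
n the study-set size and k the study genes carrying the term. Multiple
terms are corrected by Bonferroni (default) or Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class AnnotationError(KeyError):
    """Unknown term or namespace."""


@dataclass
class GeneAnnotation:
    """Flat gene -> GO-term mapping with term metadata.

    ``gene_terms`` maps each gene to its set of term ids; ``term_info`` maps
    each term id to ``(name, namespace)`` with namespace in {"CC", "BP"}.
    """

    gene_terms: dict[str, frozenset[str]]
    term_info: dict[str, tuple[str, str]]
    _term_genes: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self):
        for gene in self.gene_terms:
            if not gene:
                raise AnnotationError("empty gene id in annotation")
        inverse: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                if t not in self.term_info:
                    raise AnnotationError(f"term {t!r} used but has no metadata")
                inverse.setdefault(t, set()).add(gene)
        self._term_genes = {t: frozenset(g) for t, g in inverse.items()}

    @classmethod
    def from_tables(cls, pairs: pd.DataFrame, term_meta: pd.DataFrame) -> "GeneAnnotation":
        """Build from a (gene, term) table and a (term, name, namespace) table."""
        info = {
            r.term: (r.name, r.namespace) for r in term_meta.itertuples(index=False)
        }
        gt: dict[str, set[str]] = {}
        for r in pairs.itertuples(index=False):
            gt.setdefault(r.gene, set()).add(r.term)
        return cls({g: frozenset(t) for g, t in gt.items()}, info)

    def genes_with(self, term: str) -> frozenset[str]:
        if term not in self.term_info:
            raise AnnotationError(f"unknown term {term!r}")
        return self._term_genes.get(term, frozenset())

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return sorted(t for t, (_, ns) in self.term_info.items() if ns == namespace)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int  # study genes with term
    n: int  # study size
    K: int  # background genes with term
    N: int  # background size
    p: float
    p_adj: float
    fold: float


def filter_by_terms(
    genes: Iterable[str], annotation: GeneAnnotation, terms: Iterable[str]
) -> frozenset[str]:
    """Genes annotated with at least one of the given terms."""
    carriers: set[str] = set()
    for t in terms:
        carriers |= annotation.genes_with(t)
    return frozenset(genes) & carriers


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    annotation: GeneAnnotation,
    namespace: str = "BP",
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Over-representation test of every namespace term in the study set.

    Terms with no annotated gene in the background are skipped. Results are
    sorted by raw p-value, ties by term id.
    """
    study = frozenset(study)
    background = frozenset(background)
    if not background:
        raise ValueError("background gene set is empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")

    N, n = len(background), len(study)
    rows = []
    for term in annotation.terms_in_namespace(namespace):
        carriers = annotation.genes_with(term) & background
        K = len(carriers)
        if K == 0:
            continue
        k = len(carriers & study)
        p = hypergeom_pvalue(k, n, K, N)
        fold = (k / n) / (K / N) if n else 0.0
        rows.append((term, annotation.term_info[term][0], k, K, p, fold))
    if not rows:
        return []

    raw = [r[4] for r in rows]
    if correction == "bonferroni":
        adj = [min(1.0, len(raw) * p) for p in raw]
    else:
        adj = multipletests(raw, method="fdr_bh")[1].tolist()
    results = [
        EnrichmentResult(term=t, name=name, k=k, n=n, K=K, N=N, p=p, p_adj=a, fold=f)
        for (t, name, k, K, p, f), a in zip(rows, adj)
    ]
    return sorted(results, key=lambda r: (r.p, r.term))


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term", "name", "k", "n", "K", "N", "p", "p_adj", "fold"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results], columns=cols)


def compartment_genes(
    annotation: GeneAnnotation, compartments: Mapping[str, Mapping]
) -> dict[str, frozenset[str]]:
    """All genes of each configured compartment (union over its CC terms)."""
    return {
        comp: filter_by_terms(
            set().union(*(annotation.genes_with(t) for t in comp_def["terms"])),
            annotation,
            comp_def["terms"],
        )
        for comp, comp_def in compartments.items()
    }
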