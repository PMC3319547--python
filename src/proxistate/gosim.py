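"""Wang graph-based GO term similarity, fragment-level GO similarity, and
the pairwise co-expression statistic.

Wang's measure scores two ontology terms by how much of each term's
ancestor sub-DAG the other shares.  Within the sub-DAG of a term t each
ancestor x carries an S-value: S_t(t) = 1 and

    S_t(x) = max over child edges (c -> x) inside the sub-DAG of
             w(relation) * S_t(c)

with relation contribution weights w(is_a) = 0.8 and w(part_of) = 0.6 by
convention.  With SV(t) = sum of S-values,

    sim(t1, t2) = sum over shared ancestors x of (S_t1(x) + S_t2(x))
                  / (SV(t1) + SV(t2))

Fragment-level similarity averages the m-by-n matrix of term similarities
between the two fragments' term lists (one entry per gene-term occurrence
by default).

The co-expression statistic for two loci i and j sums, over database links
k whose genes fall one in each locus,

    E(i, j) = sum_k g1_k(i) * g2_k(j) * r_k / (N_i * N_j)

where g is the fraction of the 1-Mb locus covered by the gene, N the gene
count of the locus, and r_k the expression-profile Pearson correlation of
the linked pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from .core import GenomeBinning, overlap_length, GenomicInterval

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

NAMESPACES = ("MF", "BP", "CC")


class GOGraph:
    """One GO namespace as a DAG of child -> parent edges with relation
    contribution weights."""

    def __init__(self, namespace: str,
                 edges: list[tuple[str, str, str]] | None = None,
                 terms: list[str] | None = None,
                 relation_weights: dict[str, float] | None = None):
        self.namespace = namespace
        self.weights = dict(DEFAULT_RELATION_WEIGHTS)
        if relation_weights:
            self.weights.update(relation_weights)
        self.graph = nx.DiGraph()
        for t in terms or []:
            self.graph.add_node(t)
        for child, parent, rel in edges or []:
            if rel not in self.weights:
                raise ValueError(f"unknown relation {rel!r}")
            self.graph.add_edge(child, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph is cyclic")
        self._svalue_cache: dict[str, dict[str, float]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def s_values(self, term: str) -> dict[str, float]:
        """S-values of ``term`` over its ancestor closure (term included)."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in {self.namespace} graph")
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        anc = nx.descendants(self.graph, term) | {term}
        sub = self.graph.subgraph(anc)
        S = {term: 1.0}
        # children before parents: process in topological order of the
        # child->parent DAG, which is exactly nx topological order.
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            best = 0.0
            for child, _, data in sub.in_edges(node, data=True):
                if child in S:
                    best = max(best, self.weights[data["relation"]] * S[child])
            S[node] = best
        self._svalue_cache[term] = S
        return S


def wang_similarity(t1: str, t2: str, graph: GOGraph) -> float:
    """Wang semantic similarity of two terms of one namespace, in [0, 1]."""
    S1 = graph.s_values(t1)
    S2 = graph.s_values(t2)
    shared = set(S1) & set(S2)
    if not shared:
        return 0.0
    num = sum(S1[x] + S2[x] for x in shared)
    return num / (sum(S1.values()) + sum(S2.values()))


def term_similarity_matrix(terms: list[str], graph: GOGraph) -> np.ndarray:
    """Dense pairwise Wang similarity for a vocabulary of terms (symmetric)."""
    n = len(terms)
    M = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            M[a, b] = M[b, a] = wang_similarity(terms[a], terms[b], graph)
    return M


def fragment_go_similarity(terms_i: list[str], terms_j: list[str],
                           graph: GOGraph,
                           deduplicate: bool = False) -> float:
    """Average Wang similarity over the m-by-n term-pair matrix of two
    fragments' GO term lists.

    Duplicate terms (the same term annotated through several genes) are
    retained by default — each gene-term occurrence contributes one row or
    column.  Returns NaN (masked) when either list is empty.
    """
    if deduplicate:
        terms_i = sorted(set(terms_i))
        terms_j = sorted(set(terms_j))
    if not terms_i or not terms_j:
        return float("nan")
    total = 0.0
    cache: dict[tuple[str, str], float] = {}
    for a in terms_i:
        for b in terms_j:
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = wang_similarity(key[0], key[1], graph)
            total += cache[key]
    return total / (len(terms_i) * len(terms_j))


# ---------------------------------------------------------------------------
# co-expression


@dataclass
class CoexpressionIndex:
    """Gene geometry pre-resolved against a fragment universe so the
    pairwise statistic can be evaluated for many pairs quickly."""

    gene_fragment: dict[str, list[tuple[int, float]]]  # gene -> [(frag, g)]
    n_genes: np.ndarray                                # per-fragment N

    @classmethod
    def build(cls, genes: pd.DataFrame, binning: GenomeBinning) -> "CoexpressionIndex":
        gene_fragment: dict[str, list[tuple[int, float]]] = {}
        n_genes = np.zeros(binning.n_fragments, dtype=np.int64)
        for row in genes.itertuples():
            if row.chrom not in binning.chromosome_lengths:
                continue
            gene_iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            hits: list[tuple[int, float]] = []
            for frag in binning.fragments_of(row.chrom):
                ov = overlap_length(frag.as_interval(), gene_iv)
                if ov > 0:
                    hits.append((frag.index, ov / frag.length))
                    n_genes[frag.index] += 1
            gene_fragment[str(row.gene_id)] = hits
        return cls(gene_fragment, n_genes)


def coexpression(i: int, j: int, index: CoexpressionIndex,
                 links: pd.DataFrame,
                 normalization: str = "gene_counts") -> float:
    """Average co-expression E(i, j) between two loci.

    ``links`` columns: gene1, gene2, r.  Both link orientations are
    summed, making E symmetric.  ``normalization``: "gene_counts" divides
    by N_i * N_j (masked/NaN when either locus is gene-free);
    "link_count" divides by the number of spanning links.
    """
    total = 0.0
    n_links = 0
    for row in links.itertuples():
        h1 = index.gene_fragment.get(str(row.gene1), [])
        h2 = index.gene_fragment.get(str(row.gene2), [])
        for fa, ga in h1:
            for fb, gb in h2:
                if (fa == i and fb == j) or (fa == j and fb == i):
                    total += ga * gb * row.r
                    n_links += 1
    if normalization == "gene_counts":
        Ni, Nj = index.n_genes[i], index.n_genes[j]
        if Ni == 0 or Nj == 0:
            return float("nan")
        return total / (Ni * Nj)
    if normalization == "link_count":
        return total / n_links if n_links else 0.0
    raise ValueError(f"unknown normalization {normalization!r}")


def coexpression_pairs(pairs_i: np.ndarray, pairs_j: np.ndarray,
                       index: CoexpressionIndex, links: pd.DataFrame,
                       normalization: str = "gene_counts") -> np.ndarray:
    """Vectorized E over many unordered pairs (single pass over links)."""
    acc: dict[tuple[int, int], float] = {}
    cnt: dict[tuple[int, int], int] = {}
    for row in links.itertuples():
        for fa, ga in index.gene_fragment.get(str(row.gene1), []):
            for fb, gb in index.gene_fragment.get(str(row.gene2), []):
                if fa == fb:
                    continue
                key = (fa, fb) if fa < fb else (fb, fa)
                acc[key] = acc.get(key, 0.0) + ga * gb * row.r
                cnt[key] = cnt.get(key, 0) + 1
    out = np.zeros(len(pairs_i))
    for n, (i, j) in enumerate(zip(pairs_i, pairs_j)):
        key = (int(i), int(j)) if i < j else (int(j), int(i))
        total = acc.get(key, 0.0)
        if normalization == "gene_counts":
            Ni, Nj = index.n_genes[int(i)], index.n_genes[int(j)]
            out[n] = total / (Ni * Nj) if Ni and Nj else np.nan
        elif normalization == "link_count":
            c = cnt.get(key, 0)
            out[n] = total / c if c else 0.0
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    return out
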