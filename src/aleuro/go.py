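"""DAG-aware GO term enrichment: classic Fisher and the weight01 variant.

Annotations obey the true-path rule: a gene annotated to a term is annotated
to every ancestor, so propagated sets are computed bottom-up as the union of
direct annotations and all children's propagated sets.

*classic* scores each term independently with a one-sided Fisher test
(hypergeometric upper tail) on study vs population membership.  *weight01*
decorrelates parent-child terms: terms are visited bottom-up (children
before parents, lexicographic tie-break); when a child is more significant
than its parent's provisional p-value, the child's genes are down-weighted
by the log-p ratio ``log p_parent / log p_child`` (in (0, 1)) before the
parent's p is recomputed from the weighted counts.  Leaves therefore always
coincide with classic, and signal concentrated in an enriched child is
absorbed there rather than echoed up the ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from aleuro.deg import bh_adjust


@dataclass
class GoDag:
    """Term DAG (child -> parent, is_a semantics) with gene annotations."""

    edges: pd.DataFrame  # columns: child, parent
    direct: dict  # term -> set of genes
    propagated: dict | None = None
    graph: nx.DiGraph = field(init=False)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_edges_from(self.edges.itertuples(index=False, name=None))
        for t in self.direct:
            g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"annotation graph has a cycle through edge "
                             f"{cyc[0][0]} -> {cyc[0][1]}")
        self.graph = g

    @classmethod
    def from_tables(cls, annotations: pd.DataFrame,
                    edges: pd.DataFrame) -> "GoDag":
        direct: dict = {}
        for gene, term in annotations[["gene", "term"]].itertuples(
                index=False, name=None):
            direct.setdefault(term, set()).add(gene)
        return cls(edges=edges[["child", "parent"]].copy(), direct=direct)

    @property
    def terms(self):
        return sorted(self.graph.nodes)

    def children(self, term):
        return sorted(self.graph.predecessors(term))

    @property
    def roots(self):
        return sorted(t for t in self.graph.nodes
                      if self.graph.out_degree(t) == 0)


def propagate_true_path(dag: GoDag) -> GoDag:
    """Fill propagated(term) = direct(term) union children's propagated."""
    propagated: dict = {}
    # edges point child -> parent, so a topological order of the graph
    # lists children before their parents
    for term in nx.topological_sort(dag.graph):
        genes = set(dag.direct.get(term, set()))
        for child in dag.graph.predecessors(term):
            genes |= propagated[child]
        propagated[term] = genes
    dag.propagated = propagated
    return dag


def _fisher_upper_tail(k: int, n_study: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n_study)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n_study))


def term_enrichment(dag: GoDag, study, mode: str = "classic",
                    population=None) -> pd.DataFrame:
    """Per-term enrichment p-values plus BH FDR.

    ``study`` must be a subset of the annotated population (the union of all
    propagated annotations unless ``population`` is given).  Returns a
    DataFrame indexed by term with study/population counts, ``p_classic``,
    ``p_weight01`` (NaN unless requested) and ``fdr`` on the requested
    mode's p-values, sorted by FDR then term id.
    """
    if dag.propagated is None:
        propagate_true_path(dag)
    study = set(study)
    if not study:
        raise ValueError("empty study set")
    if population is None:
        population = set().union(*dag.propagated.values()) \
            if dag.propagated else set()
    population = set(population)
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    N, n_study = len(population), len(study)

    terms = dag.terms
    ann = {t: dag.propagated.get(t, set()) & population for t in terms}
    p_classic = {}
    for t in terms:
        K = len(ann[t])
        k = len(ann[t] & study)
        p_classic[t] = _fisher_upper_tail(k, n_study, K, N) if K else 1.0

    if mode == "classic":
        p_final = dict(p_classic)
        p_w = {t: np.nan for t in terms}
    elif mode == "weight01":
        p_w = _weight01(dag, ann, study, n_study, N)
        p_final = p_w
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = pd.DataFrame({
        "study_count": [len(ann[t] & study) for t in terms],
        "population_count": [len(ann[t]) for t in terms],
        "p_classic": [p_classic[t] for t in terms],
        "p_weight01": [p_w[t] for t in terms],
    }, index=pd.Index(terms, name="term"))
    out["fdr"] = bh_adjust([p_final[t] for t in terms])
    return out.sort_values(["fdr", "p_classic"], kind="mergesort")


def _weight01(dag: GoDag, ann: dict, study: set, n_study: int,
              N: int) -> dict:
    """Bottom-up decorrelating pass with log-p-ratio down-weighting."""
    weights = {g: 1.0 for g in set().union(*ann.values())} if ann else {}
    p_final: dict = {}

    def weighted_p(term) -> float:
        genes = ann[term]
        if not genes:
            return 1.0
        K = int(round(sum(weights[g] for g in genes)))
        k = int(round(sum(weights[g] for g in genes if g in study)))
        K = max(K, k)
        if K == 0:
            return 1.0
        return _fisher_upper_tail(k, n_study, min(K, N), N)

    # children before parents; lexicographic among ties for determinism
    order = list(nx.lexicographical_topological_sort(dag.graph))
    for term in order:
        p_here = weighted_p(term)
        children = dag.children(term)
        sig_children = [c for c in children if p_final[c] < p_here]
        if sig_children:
            for c in sig_children:
                # ratio in (0, 1): how much less significant the parent is
                lp, lc = np.log(max(p_here, 1e-300)), np.log(
                    max(p_final[c], 1e-300))
                ratio = lp / lc if lc < 0 else 1.0
                ratio = float(np.clip(ratio, 0.0, 1.0))
                for g in ann[c]:
                    weights[g] *= ratio
            p_here = weighted_p(term)
        p_final[term] = p_here
    return p_final
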