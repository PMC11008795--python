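"""DAG-aware GO-term enrichment with the elim decorrelation procedure.

Terms are tested by one-sided Fisher's exact test (hypergeometric upper
tail) for over-representation of a study set within a universe, walking the
is_a DAG from the most specific terms upward.  When a term reaches the
elimination cutoff, its annotated genes are removed from all ancestors'
annotation sets before those are tested, so general terms are not flagged
merely because a specific descendant carries the signal.

Reporting filters: a term passes iff p <= 0.05 and it is represented by at
least 3 study transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "AnnotationMap",
    "load_obo",
    "read_annotations",
    "elim_fisher",
    "top_representative",
]


@dataclass
class GoDag:
    """is_a-only GO DAG; edges run child -> parent."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        dangling = [n for n, d in self.graph.nodes(data=True) if "name" not in d]
        if dangling:
            raise ValueError(f"dangling parent term(s): {sorted(dangling)}")

    @property
    def terms(self):
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", "")

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str):
        return list(self.graph.successors(term))

    def ancestors(self, term: str):
        return nx.descendants(self.graph, term)  # along child->parent edges

    def most_specific_first(self):
        """Terms in reverse topological order of the is_a hierarchy
        (every child precedes its parents)."""
        return list(nx.topological_sort(self.graph))


def load_obo(path) -> GoDag:
    """Load an OBO 1.2-style ontology keeping only is_a edges.

    Obsolete terms are dropped (and logged); a cycle or a reference to an
    undefined parent is a hard error.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    for n, data in multi.nodes(data=True):
        g.add_node(n, **{k: data[k] for k in ("name", "namespace") if k in data})
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    logger.info("loaded ontology: %d terms, %d is_a edges",
                g.number_of_nodes(), g.number_of_edges())
    return GoDag(g)


@dataclass
class AnnotationMap:
    """transcript -> direct GO terms, with the is_a closure computed on load."""

    direct: dict
    dag: GoDag
    propagated: dict = field(init=False)

    def __post_init__(self) -> None:
        known = set(self.dag.graph.nodes)
        anc_cache: dict = {}
        prop = {}
        for tx, terms in self.direct.items():
            s = set(t for t in terms if t in known)
            closure = set(s)
            for t in s:
                if t not in anc_cache:
                    anc_cache[t] = self.dag.ancestors(t)
                closure |= anc_cache[t]
            prop[tx] = closure
        self.propagated = prop

    def genes_per_term(self, restrict=None) -> dict:
        out: dict = {}
        universe = self.propagated.keys() if restrict is None else restrict
        for tx in universe:
            for term in self.propagated.get(tx, ()):
                out.setdefault(term, set()).add(tx)
        return out


def read_annotations(path, dag: GoDag, evalue_max: float = 1e-3) -> AnnotationMap:
    """Read a transcript/term TSV (transcript_id, term_id[, evalue]).

    When an ``evalue`` column is present, rows above ``evalue_max`` are
    dropped (pooling of annotation sources is the producer's concern).
    """
    df = pd.read_csv(path, sep="\t")
    if "evalue" in df.columns:
        df = df[df["evalue"] < evalue_max]
    direct: dict = {}
    for tx, term in zip(df["transcript_id"], df["term_id"]):
        direct.setdefault(str(tx), set()).add(str(term))
    return AnnotationMap(direct, dag)


def _fisher_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n): one-sided over-representation."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def elim_fisher(study, universe, annot: AnnotationMap, dag: GoDag,
                elim_cutoff: float = 0.01, namespace: str = "biological_process",
                alpha: float = 0.05, min_count: int = 3) -> pd.DataFrame:
    """elim-decorrelated Fisher enrichment of ``study`` within ``universe``.

    Terms are processed most-specific-first; a term with p <= ``elim_cutoff``
    has its annotated universe genes removed from every ancestor's annotation
    set before the ancestor is tested.  ``namespace=None`` tests all
    namespaces.  Returns a table sorted by p with the reporting-filter flag
    (p <= alpha and >= min_count study transcripts).
    """
    study = set(study)
    universe = set(universe)
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    cols = ["term_id", "name", "namespace", "n_study", "n_universe", "p",
            "passes_filters"]
    if not study:
        return pd.DataFrame(columns=cols)
    term_genes = annot.genes_per_term(restrict=universe)
    N = len(universe)
    n = len(study)
    eliminated: dict = {}
    rows = []
    for term in dag.most_specific_first():
        if namespace is not None and dag.namespace(term) != namespace:
            continue
        genes = term_genes.get(term, set())
        genes = genes - eliminated.get(term, set())
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study)
        p = _fisher_upper(k, K, n, N)
        rows.append({
            "term_id": term, "name": dag.name(term),
            "namespace": dag.namespace(term),
            "n_study": k, "n_universe": K, "p": p,
            "passes_filters": bool(p <= alpha and k >= min_count),
        })
        if p <= elim_cutoff:
            full = term_genes.get(term, set())
            for anc in dag.ancestors(term):
                eliminated.setdefault(anc, set()).update(full)
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values(["p", "term_id"]).reset_index(drop=True)


def top_representative(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k passing terms by ascending p; ties by descending study count,
    then term id."""
    if table.empty:
        return table.copy()
    passing = table[table["passes_filters"].astype(bool)].copy()
    passing = passing.sort_values(
        ["p", "n_study", "term_id"], ascending=[True, False, True]
    )
    return passing.head(k).reset_index(drop=True)
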