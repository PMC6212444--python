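"""GO biological-process enrichment: classic Fisher, KS score test, elim.

Annotations follow the true-path rule (a gene annotated to a term is
annotated to all its ancestors).  The classic Fisher test asks whether
candidate genes over-represent a term (one-sided hypergeometric); the
KS-like test compares the Z_ST scores of a term's genes against all other
scored genes (alternative: term scores stochastically larger).  The elim
algorithm walks the DAG bottom-up and, whenever a term tests significant,
removes its originally annotated genes from all ancestor terms before
those are tested, decorrelating parent-child results.  Raw elim p-values
are treated as corrected; no further multiple-testing adjustment is
applied.
"""

from __future__ import annotations

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

__all__ = [
    "load_obo",
    "annotate_genes",
    "classic_fisher",
    "ks_score_test",
    "elim",
]


def load_obo(path, namespace: str = "biological_process") -> nx.MultiDiGraph:
    """Parse an OBO 1.2 ontology; edges point child -> parent (is_a).

    Terms outside ``namespace`` are dropped (pass ``None`` to keep all);
    obsolete terms are dropped by the parser.  A cyclic is_a graph is
    rejected.
    """
    graph = obonet.read_obo(str(path))
    keep_edges = [
        (u, v, k) for u, v, k in graph.edges(keys=True) if k == "is_a"
    ]
    dag = nx.MultiDiGraph()
    dag.add_nodes_from(graph.nodes(data=True))
    dag.add_edges_from((u, v, "is_a") for u, v, _ in keep_edges)
    if namespace is not None:
        drop = [
            n
            for n, d in dag.nodes(data=True)
            if d.get("namespace", namespace) != namespace
        ]
        dag.remove_nodes_from(drop)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("cyclic is_a relationships in ontology")
    return dag


def ancestors(dag: nx.MultiDiGraph, term: str) -> set[str]:
    """All is_a ancestors of a term (edges point child -> parent)."""
    return nx.descendants(dag, term)


def annotate_genes(gene2go: pd.DataFrame, dag: nx.MultiDiGraph) -> dict[str, set[str]]:
    """term -> gene set after true-path propagation.

    ``gene2go`` columns: gene_id, go_id.  Annotations to terms absent from
    the DAG are ignored.  Propagation is idempotent by construction.
    """
    term_genes: dict[str, set[str]] = {t: set() for t in dag.nodes}
    for gene_id, go_id in zip(gene2go["gene_id"], gene2go["go_id"]):
        if go_id not in term_genes:
            continue
        term_genes[go_id].add(gene_id)
        for anc in ancestors(dag, go_id):
            term_genes[anc].add(gene_id)
    return term_genes


def _term_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["go_id", "n_annotated", "n_significant", "p_value"]
    ).sort_values(["p_value", "go_id"]).reset_index(drop=True)


def classic_fisher(
    candidates: set[str],
    universe: set[str],
    term_genes: dict[str, set[str]],
    min_sig: int = 5,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher test per term.

    Only terms with at least ``min_sig`` candidate genes are reported.
    """
    candidates = set(candidates)
    universe = set(universe)
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    N, n = len(universe), len(candidates)
    rows = []
    for term, genes in term_genes.items():
        tg = genes & universe
        k = len(tg & candidates)
        if k < min_sig:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, len(tg), n))
        rows.append({"go_id": term, "n_annotated": len(tg), "n_significant": k, "p_value": p})
    return _term_frame(rows)


def ks_score_test(
    scores: pd.Series,
    term_genes: dict[str, set[str]],
    min_size: int = 5,
) -> pd.DataFrame:
    """One-sided two-sample KS test of term scores vs the remaining genes.

    ``scores`` maps gene -> Z_ST.  Terms with fewer than ``min_size``
    scored genes, or with an empty scored complement, are skipped.  The
    alternative is that the term's scores are stochastically larger.
    """
    scored = scores.dropna()
    rows = []
    for term, genes in term_genes.items():
        in_term = scored.index.isin(genes)
        x = scored[in_term]
        y = scored[~in_term]
        if len(x) < min_size or len(y) == 0:
            continue
        # alternative='less': CDF of term scores lies below -> scores larger
        res = stats.ks_2samp(x, y, alternative="less")
        rows.append(
            {
                "go_id": term,
                "n_annotated": int(len(x)),
                "n_significant": int(len(x)),
                "p_value": float(res.pvalue),
            }
        )
    return _term_frame(rows)


def elim(
    dag: nx.MultiDiGraph,
    term_genes: dict[str, set[str]],
    base_test: str = "fisher",
    cutoff: float = 0.01,
    candidates: set[str] | None = None,
    universe: set[str] | None = None,
    scores: pd.Series | None = None,
    min_sig: int = 5,
) -> pd.DataFrame:
    """elim decorrelation over the base test (``fisher`` or ``ks``).

    Terms are processed children-before-parents (lexicographic topological
    order, edges child -> parent, so iteration order within a level is
    fixed by term id).  Each term is tested on its *current* gene set;
    when its p-value falls below ``cutoff`` its originally annotated genes
    are removed from every ancestor's current set before those are tested.
    Result filtering (min counts) uses the original annotation, so terms
    whose counts were reduced by elimination remain reported.
    """
    if base_test not in {"fisher", "ks"}:
        raise ValueError("base_test must be 'fisher' or 'ks'")
    if base_test == "fisher":
        if candidates is None or universe is None:
            raise ValueError("fisher elim needs candidates and universe")
        candidates = set(candidates)
        universe = set(universe)
        N, n_cand = len(universe), len(candidates)
    else:
        if scores is None:
            raise ValueError("ks elim needs gene scores")
        scored = scores.dropna()

    current = {t: set(g) for t, g in term_genes.items()}
    rows = []
    for term in nx.lexicographical_topological_sort(dag):
        genes_now = current.get(term, set())
        original = term_genes.get(term, set())
        if base_test == "fisher":
            tg = genes_now & universe
            k = len(tg & candidates)
            p = float(stats.hypergeom.sf(k - 1, N, len(tg), n_cand)) if tg else 1.0
            keep = len(original & candidates) >= min_sig
            n_annot, n_sig = len(tg), k
        else:
            in_term = scored.index.isin(genes_now)
            x, y = scored[in_term], scored[~in_term]
            if len(x) >= 1 and len(y) >= 1:
                p = float(stats.ks_2samp(x, y, alternative="less").pvalue)
            else:
                p = 1.0
            keep = len(original & set(scored.index)) >= min_sig
            n_annot, n_sig = int(len(x)), int(len(x))
        if p < cutoff:
            for anc in ancestors(dag, term):
                if anc in current:
                    current[anc] -= original
        if keep:
            rows.append(
                {"go_id": term, "n_annotated": n_annot, "n_significant": n_sig, "p_value": p}
            )
    return _term_frame(rows)
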