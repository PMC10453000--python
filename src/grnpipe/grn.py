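"""Class-specific GRN reconstruction from expression and a gold standard.

Association scores are Spearman correlations computed only for gold-standard
TF->target pairs, then background-corrected CLR-style: each gene's pair
score is standardized against that gene's distribution of absolute
correlations with every gene in the matrix, and the edge weight combines
the two endpoint z-scores. Communities are detected with Infomap (or
Leiden) and assigned to classes by hypergeometric enrichment against
class-specific template gene sets.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

logger = logging.getLogger(__name__)


def validate_gold_standard(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop duplicates and reject self-pairs; preserves first-seen order."""
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for tf, tg in pairs:
        if tf == tg:
            raise ValueError(f"self-pair in gold standard: {tf}")
        if (tf, tg) not in seen:
            seen.add((tf, tg))
            out.append((tf, tg))
    return out


@dataclass
class WeightedNetwork:
    """Directed TF->target edges retained from the gold standard.

    ``edges`` columns: tf, target, rho (signed Spearman), weight (CLR z).
    """

    edges: pd.DataFrame
    z_threshold: float

    @property
    def genes(self) -> list[str]:
        if self.edges.empty:
            return []
        return sorted(set(self.edges["tf"]) | set(self.edges["target"]))

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ClassGRN:
    """One class's subnetwork: member genes, induced gold-standard edges,
    and per-gene classifier importance weights (filled by the classifier)."""

    label: str
    genes: list[str]
    edges: pd.DataFrame  # columns: tf, target, rho, weight
    importances: pd.Series | None = None
    communities: list[int] = field(default_factory=list)

    @property
    def tfs(self) -> list[str]:
        if self.edges.empty:
            return []
        return sorted(set(self.edges["tf"]))

    def influence(self) -> pd.Series:
        """Node influence = connection count (degree) within the class GRN."""
        deg = pd.Series(0, index=pd.Index(self.genes, name="gene"), dtype=int)
        for col in ("tf", "target"):
            counts = self.edges[col].value_counts()
            deg = deg.add(counts.reindex(deg.index, fill_value=0), fill_value=0)
        return deg.astype(int)


def class_template_scores(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Correlate every gene with each class's one-vs-rest indicator.

    Returns a gene-by-class matrix of Pearson correlations in [-1, 1];
    zero-variance genes score 0 by convention. Requires >= 2 classes and
    >= 2 samples per class.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some expression columns")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    small = counts[counts < 2]
    if len(small) > 0:
        raise ValueError(f"class with < 2 samples: {list(small.index)}")

    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = np.sqrt((Xc**2).sum(axis=1))
    classes = sorted(counts.index)
    scores = np.zeros((X.shape[0], len(classes)))
    for j, cls in enumerate(classes):
        y = (labels == cls).to_numpy(dtype=float)
        yc = y - y.mean()
        ysd = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc @ yc) / (xsd * ysd)
        scores[:, j] = np.nan_to_num(r, nan=0.0)
    return pd.DataFrame(scores, index=expr.index, columns=classes)


def _spearman_rows(expr: pd.DataFrame, rows: list[str]) -> pd.DataFrame:
    """Spearman correlation of the given genes against every gene in expr."""
    ranks = np.apply_along_axis(rankdata, 1, expr.to_numpy(dtype=float))
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    sd = np.sqrt((rc**2).sum(axis=1))
    sd[sd == 0] = np.inf  # zero-variance genes correlate 0 with everything
    rc /= sd[:, None]
    idx = expr.index.get_indexer(rows)
    corr = rc[idx] @ rc.T
    return pd.DataFrame(corr, index=rows, columns=expr.index)


def reconstruct_network(
    expr: pd.DataFrame,
    gold: list[tuple[str, str]],
    z_threshold: float = 2.0,
) -> WeightedNetwork:
    """Score gold-standard pairs and retain background-corrected edges.

    For each gold pair, the absolute Spearman correlation across all
    training samples is standardized within each endpoint gene's
    distribution of absolute correlations against all genes (CLR-style),
    and the edge weight is ``sqrt(relu(z_i)^2 + relu(z_j)^2) / sqrt(2)``.
    Edges with weight >= ``z_threshold`` are retained. Pairs referencing
    genes absent from the matrix are skipped with a warning.
    """
    gold = validate_gold_standard(gold)
    present = set(expr.index)
    usable = [(a, b) for a, b in gold if a in present and b in present]
    skipped = len(gold) - len(usable)
    if skipped:
        logger.warning("skipping %d gold pairs with genes absent from matrix", skipped)
    cols = ["tf", "target", "rho", "weight"]
    if not usable:
        return WeightedNetwork(pd.DataFrame(columns=cols), z_threshold)

    gold_genes = sorted({g for pair in usable for g in pair})
    corr = _spearman_rows(expr, gold_genes)
    acorr = corr.abs().to_numpy()
    # background: each gold gene's |rho| distribution over all other genes
    self_idx = corr.columns.get_indexer(gold_genes)
    mask = np.ones_like(acorr, dtype=bool)
    mask[np.arange(len(gold_genes)), self_idx] = False
    mu = np.array([acorr[i, mask[i]].mean() for i in range(len(gold_genes))])
    sd = np.array([acorr[i, mask[i]].std(ddof=0) for i in range(len(gold_genes))])
    sd = np.maximum(sd, 1e-12)
    row_of = {g: i for i, g in enumerate(gold_genes)}
    col_of = {g: i for i, g in enumerate(corr.columns)}

    records = []
    for tf, tg in usable:
        rho = corr.iat[row_of[tf], col_of[tg]]
        a = abs(rho)
        z_i = (a - mu[row_of[tf]]) / sd[row_of[tf]]
        z_j = (a - mu[row_of[tg]]) / sd[row_of[tg]]
        w = np.sqrt(max(z_i, 0.0) ** 2 + max(z_j, 0.0) ** 2) / np.sqrt(2.0)
        if w >= z_threshold:
            records.append((tf, tg, float(rho), float(w)))
    edges = pd.DataFrame(records, columns=cols)
    return WeightedNetwork(edges, z_threshold)


def detect_communities(
    net: WeightedNetwork, seed: int = 0, method: str = "infomap"
) -> dict[str, int]:
    """Partition network genes into subnetworks (communities).

    ``method`` is "infomap" (map equation) or "leiden" (modularity).
    Every node lands in exactly one community; deterministic under seed.
    Empty network -> empty partition.
    """
    if len(net) == 0:
        return {}
    genes = net.genes
    idx = {g: i for i, g in enumerate(genes)}
    g = ig.Graph(
        n=len(genes),
        edges=[(idx[a], idx[b]) for a, b in zip(net.edges["tf"], net.edges["target"])],
        directed=True,
    )
    weights = net.edges["weight"].tolist()
    if method == "infomap":
        ig.set_random_number_generator(random.Random(seed))
        try:
            clustering = g.community_infomap(edge_weights=weights)
        finally:
            ig.set_random_number_generator(random)
        membership = clustering.membership
    elif method == "leiden":
        part = leidenalg.find_partition(
            g.as_undirected(combine_edges="sum"),
            leidenalg.ModularityVertexPartition,
            weights=weights,
            seed=seed,
        )
        membership = part.membership
    else:
        raise ValueError(f"unknown community method: {method!r}")
    return {genes[i]: int(m) for i, m in enumerate(membership)}


def enrichment_pvalue(
    overlap: int, universe_size: int, class_set_size: int, community_size: int
) -> float:
    """Hypergeometric upper-tail probability of drawing at least ``overlap``
    class genes in a community of the given size."""
    return float(
        hypergeom.sf(overlap - 1, universe_size, class_set_size, community_size)
    )


def assign_subnetworks(
    partition: dict[str, int],
    templates: pd.DataFrame,
    net: WeightedNetwork,
    top_k: int = 100,
    alpha: float = 0.05,
) -> dict[str, ClassGRN]:
    """Map communities to classes by hypergeometric enrichment.

    The class-specific gene set is the ``top_k`` genes by template score.
    A community is assigned to the class with the smallest enrichment p
    when that p clears a Bonferroni-corrected ``alpha`` over all
    class x community tests; each community maps to at most one class.
    The class GRN is the union of its assigned communities with induced
    edges. Classes may end up with empty GRNs (reported via logging).
    """
    classes = list(templates.columns)
    comm_ids = sorted(set(partition.values()))
    comm_genes = {
        cid: {g for g, c in partition.items() if c == cid} for cid in comm_ids
    }
    universe = list(templates.index)
    universe_set = set(universe)
    M = len(universe)
    n_tests = max(len(classes) * len(comm_ids), 1)

    top_sets = {
        cls: set(templates[cls].nlargest(top_k).index) for cls in classes
    }

    # community -> (best class, best p)
    assignment: dict[int, tuple[str, float]] = {}
    for cid in comm_ids:
        cg = comm_genes[cid] & universe_set
        best: tuple[str, float] | None = None
        for cls in classes:
            k = len(cg & top_sets[cls])
            p = enrichment_pvalue(k, M, len(top_sets[cls]), len(cg))
            if best is None or p < best[1] or (p == best[1] and cls < best[0]):
                best = (cls, p)
        if best is not None and best[1] * n_tests < alpha:
            assignment[cid] = best

    grns: dict[str, ClassGRN] = {}
    for cls in classes:
        cids = sorted(cid for cid, (c, _) in assignment.items() if c == cls)
        genes = sorted(set().union(*(comm_genes[c] for c in cids)) if cids else set())
        gene_set = set(genes)
        if net.edges.empty:
            edges = net.edges.copy()
        else:
            edges = net.edges[
                net.edges["tf"].isin(gene_set) & net.edges["target"].isin(gene_set)
            ].reset_index(drop=True)
        if not genes:
            logger.warning("class %s has an empty GRN", cls)
        grns[cls] = ClassGRN(label=cls, genes=genes, edges=edges, communities=cids)
    return grns


@dataclass
class StructureMetrics:
    """Per-class node/edge counts and degree distributions."""

    summary: pd.DataFrame  # columns: class, n_nodes, n_edges, n_tfs
    targets_per_tf: dict[str, pd.Series]
    regulators_per_target: dict[str, pd.Series]


def grn_metrics(class_grns: dict[str, ClassGRN]) -> StructureMetrics:
    """Structural metrics: sum of targets-per-TF = sum of regulators-per-target
    = edge count, per class."""
    rows = []
    tpt: dict[str, pd.Series] = {}
    rpt: dict[str, pd.Series] = {}
    for cls, grn in sorted(class_grns.items()):
        if grn.edges.empty:
            tpt[cls] = pd.Series(dtype=int)
            rpt[cls] = pd.Series(dtype=int)
            rows.append((cls, len(grn.genes), 0, 0))
            continue
        tpt[cls] = grn.edges["tf"].value_counts().sort_index()
        rpt[cls] = grn.edges["target"].value_counts().sort_index()
        rows.append((cls, len(grn.genes), len(grn.edges), len(tpt[cls])))
    summary = pd.DataFrame(rows, columns=["class", "n_nodes", "n_edges", "n_tfs"])
    return StructureMetrics(summary, tpt, rpt)


def export_network(grn: ClassGRN, path) -> None:
    """Write a class GRN as GraphML.

    Node attributes: influence (connection count) and importance (classifier
    weight, 0 when unassigned); edge attribute: weight. Round-trips through
    a generic GraphML reader.
    """
    g = nx.DiGraph()
    influence = grn.influence()
    imp = grn.importances
    for gene in grn.genes:
        g.add_node(
            gene,
            influence=int(influence.get(gene, 0)),
            importance=float(imp.get(gene, 0.0)) if imp is not None else 0.0,
        )
    for row in grn.edges.itertuples(index=False):
        g.add_edge(row.tf, row.target, weight=float(row.weight))
    g.graph["class"] = grn.label
    nx.write_graphml(g, path)
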