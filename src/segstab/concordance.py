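"""Clustering-concordance evaluation of gene lists.

The stability of a gene list is assessed by clustering cells with
k-means restricted to that list's genes (K equal to the number of
predefined classes) and scoring the concordance of the clustering with
the predefined class labels.  Four metrics are computed from the pair
counts (a, b, c, d) over all N(N-1)/2 unordered cell pairs:

    ARI     = 2(ad - bc) / [(a+b)(b+d) + (a+c)(c+d)]
    Jaccard = a / (a + b + c)
    FM      = sqrt( [a/(a+b)] [a/(a+c)] )
    Purity  = (1/N) * sum over clusters of the best-matching class overlap

where a counts pairs in the same class and same cluster, b same cluster
but different classes, c same class but different clusters, and d
different in both.  Because k-means is stochastic, the evaluation is
repeated (default 10 times) and metrics are summarised as mean +/- sd.
A *low* concordance indicates the list carries little cell-type signal,
i.e. the genes are stably expressed across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CellAnnotation, ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class PairCounts:
    """Pair-classification counts comparing two partitions of N cells."""

    a: int
    b: int
    c: int
    d: int
    n_cells: int

    def __post_init__(self):
        total = self.n_cells * (self.n_cells - 1) // 2
        if self.a + self.b + self.c + self.d != total:
            raise ValueError("pair counts do not sum to N(N-1)/2")


def _contingency(truth, clustering) -> np.ndarray:
    truth = np.asarray(truth)
    clustering = np.asarray(clustering)
    if truth.shape != clustering.shape:
        raise ValidationError("partitions cover different cell sets")
    _, ti = np.unique(truth, return_inverse=True)
    _, ci = np.unique(clustering, return_inverse=True)
    table = np.zeros((ti.max() + 1, ci.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, ci), 1)
    return table


def pair_counts(truth, clustering) -> PairCounts:
    """(a, b, c, d) via the contingency-table fast path."""

    table = _contingency(truth, clustering)
    n = int(table.sum())

    def comb2(x):
        return (x * (x - 1)) // 2

    a = int(comb2(table).sum())
    same_cluster = int(comb2(table.sum(axis=0)).sum())  # pairs sharing a cluster
    same_class = int(comb2(table.sum(axis=1)).sum())
    b = same_cluster - a
    c = same_class - a
    d = comb2(n) - a - b - c
    return PairCounts(a=a, b=b, c=c, d=d, n_cells=n)


def pair_counts_bruteforce(truth, clustering) -> PairCounts:
    """O(N^2) enumeration over all unordered pairs (reference path)."""
    truth = np.asarray(truth)
    clustering = np.asarray(clustering)
    if truth.shape != clustering.shape:
        raise ValidationError("partitions cover different cell sets")
    n = truth.size
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_class = truth[i] == truth[j]
            same_cluster = clustering[i] == clustering[j]
            if same_class and same_cluster:
                a += 1
            elif same_cluster:
                b += 1
            elif same_class:
                c += 1
            else:
                d += 1
    return PairCounts(a=a, b=b, c=c, d=d, n_cells=n)


def ari(pc: PairCounts) -> float:
    """Adjusted Rand index from pair counts (printed-formula form)."""
    a, b, c, d = pc.a, pc.b, pc.c, pc.d
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


def jaccard(pc: PairCounts) -> float:
    if pc.a + pc.b + pc.c == 0:
        return 0.0
    return pc.a / (pc.a + pc.b + pc.c)


def fm(pc: PairCounts) -> float:
    """Fowlkes-Mallows index; degenerate denominators give 0."""
    if pc.a + pc.b == 0 or pc.a + pc.c == 0:
        return 0.0
    return float(np.sqrt((pc.a / (pc.a + pc.b)) * (pc.a / (pc.a + pc.c))))


def purity(truth, clustering) -> float:
    """Sum over clusters of the best-matching class overlap, over N."""
    table = _contingency(truth, clustering)
    n = table.sum()
    if n == 0:
        raise ValidationError("empty partitions")
    return float(table.max(axis=0).sum() / n)


@dataclass
class ConcordanceScores:
    """Per-repeat metric values with mean +/- sd summaries."""

    per_run: pd.DataFrame  # columns ari, jaccard, fm, purity; one row per repeat
    gene_list_size: int

    @property
    def mean(self) -> pd.Series:
        return self.per_run.mean()

    @property
    def sd(self) -> pd.Series:
        if len(self.per_run) < 2:
            return pd.Series(0.0, index=self.per_run.columns)
        return self.per_run.std(ddof=1)

    def summary_frame(self, scale100: bool = True) -> pd.DataFrame:
        """mean +/- sd per metric, x100 to match the usual reporting scale."""
        k = 100.0 if scale100 else 1.0
        return pd.DataFrame({"mean": self.mean * k, "sd": self.sd * k})


def _score(truth_labels, cluster_labels) -> dict[str, float]:
    pc = pair_counts(truth_labels, cluster_labels)
    return {
        "ari": ari(pc),
        "jaccard": jaccard(pc),
        "fm": fm(pc),
        "purity": purity(truth_labels, cluster_labels),
    }


def evaluate_gene_list(
    m: ExpressionMatrix,
    genes,
    truth: CellAnnotation,
    reps: int = 10,
    seed: int | None = None,
) -> ConcordanceScores:
    """Score a gene list by repeated k-means concordance with true classes.

    Cells are clustered on the log-expression submatrix restricted to
    the list's genes (cells as observations, genes as features, no
    per-gene standardisation or dimension reduction), with K set to the
    number of predefined classes.  Each repeat uses a sub-seed derived
    from ``seed``; k-means uses random centroid initialisation with 10
    restarts, keeping the best-inertia solution.
    """
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in set(m.gene_ids)]
    if len(present) < 2:
        raise ValidationError(
            f"fewer than 2 genes of the list are present in the matrix "
            f"({len(present)}/{len(genes)})"
        )
    sub = m.subset_genes(present)
    X = sub.values.T  # cells x genes
    if not m.log_transformed:
        X = np.log2(X + 1.0)
    labels = truth.labels_for(m.cell_ids)
    k = int(np.unique(labels).size)
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(reps):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        km = KMeans(n_clusters=k, init="random", n_init=10, random_state=sub_seed)
        pred = km.fit_predict(X)
        rows.append(_score(labels, pred))
    return ConcordanceScores(per_run=pd.DataFrame(rows), gene_list_size=len(present))


def size_matched_subset(
    genes, target_size: int, reps: int = 10, seed: int | None = None
) -> list[list[str]]:
    """Random size-matched subsets of a gene list (without replacement)."""
    genes = [str(g) for g in genes]
    if target_size > len(genes):
        raise ValueError(
            f"target_size {target_size} exceeds list length {len(genes)}"
        )
    rng = np.random.default_rng(seed)
    return [
        list(rng.choice(genes, size=target_size, replace=False)) for _ in range(reps)
    ]
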