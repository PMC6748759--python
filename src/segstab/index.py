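"""Rank-aggregated stability index and SEG selection.

Genes are ranked in increasing order for each stability feature
(lambda, sigma2, omega*, F), ranks are rescaled to [0, 1], and the
stability index of a gene is the average over features of one minus its
scaled rank — so the index lies in [0, 1] with larger values indicating
more stable expression.  Stably expressed genes (SEGs) are selected by
requiring a stability-index rank percentile above 80 together with a
reversed (small-value-is-high) rank percentile above 60 for every
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import compute_features
from .io import CellAnnotation, ExpressionMatrix, filter_genes_by_zeros, log_transform
from .mixture import EMConfig

DEFAULT_FEATURES = ("lambda_", "sigma2", "omega_star", "f_stat")


def scaled_rank(v) -> np.ndarray:
    """Increasing-order ranks (average ties) rescaled to [0, 1].

    Missing entries are excluded from the ranking and returned missing.
    +inf is a legal value and ranks last.
    """
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, np.nan)
    valid = ~np.isnan(v)
    nv = int(valid.sum())
    if nv == 0:
        raise ValueError("scaled_rank: all entries missing")
    if nv == 1:
        out[valid] = 0.0
        return out
    ranks = rankdata(v[valid], method="average")
    out[valid] = (ranks - 1.0) / (nv - 1.0)
    return out


@dataclass
class StabilityResult:
    """Per-gene scaled feature ranks and aggregated stability index."""

    gene_ids: list[str]
    scaled_ranks: pd.DataFrame
    index: pd.Series
    features_used: list[str]
    is_seg: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.scaled_ranks.copy()
        df.columns = [f"rank_{c}" for c in df.columns]
        df["index"] = self.index
        if self.is_seg is not None:
            df["is_seg"] = self.is_seg
        return df


def stability_index(
    feature_table: pd.DataFrame, features: tuple[str, ...] | None = None
) -> StabilityResult:
    """Aggregate feature ranks into the per-gene stability index.

    Uses lambda_, sigma2 and omega_star, plus f_stat when the column is
    present (4 features with labels, 3 without).  Genes with any missing
    used feature receive a missing index.
    """
    ft = feature_table
    if features is None:
        features = tuple(
            c for c in DEFAULT_FEATURES if c in ft.columns and ft[c].notna().any()
        )
    if int(ft.get("valid", ft[list(features)].notna().all(axis=1)).sum()) < 2:
        raise ValueError("need at least 2 valid genes to rank")
    ranks = pd.DataFrame(
        {f: scaled_rank(ft[f].to_numpy()) for f in features}, index=ft.index
    )
    index = (1.0 - ranks).mean(axis=1, skipna=False)
    return StabilityResult(
        gene_ids=list(ft.index),
        scaled_ranks=ranks,
        index=index,
        features_used=list(features),
    )


def select_segs(
    res: StabilityResult,
    index_pct: float = 80.0,
    feature_pct: float = 60.0,
) -> list[str]:
    """Select SEGs by the two-condition percentile rule.

    A gene is a SEG when its stability-index rank percentile strictly
    exceeds ``index_pct`` (higher index -> higher percentile) and, for
    every feature used, its reversed rank percentile strictly exceeds
    ``feature_pct`` (smaller feature value -> higher percentile).
    Percentile of a gene = 100 * (rank - 1)/(G - 1) with average ranks
    for ties, over the genes with a defined index.
    """
    idx = res.index.to_numpy(dtype=float)
    index_percentile = 100.0 * scaled_rank(idx)
    # scaled rank s of a feature (increasing) gives reversed percentile 100*(1-s)
    seg = index_percentile > index_pct
    for f in res.features_used:
        reversed_pct = 100.0 * (1.0 - res.scaled_ranks[f].to_numpy(dtype=float))
        seg &= reversed_pct > feature_pct
    seg &= ~np.isnan(idx)
    res.is_seg = pd.Series(seg, index=res.index.index)
    selected = [g for g, s in zip(res.gene_ids, seg) if s]
    if not selected:
        import warnings

        warnings.warn("SEG selection is empty at the given thresholds")
    return selected


def union_gene_lists(*lists) -> list[str]:
    """Set union of gene lists preserving first-seen order."""
    if len(lists) == 1 and isinstance(lists[0], (list, tuple)) and lists[0] and not isinstance(lists[0][0], str):
        lists = tuple(lists[0])
    seen: dict[str, None] = {}
    for lst in lists:
        for g in lst:
            seen[str(g)] = None
    return list(seen)


@dataclass
class ReproducibilityResult:
    """Pairwise Pearson correlations of stability indices across subsamples."""

    correlations: np.ndarray
    indices: list[pd.Series] = field(repr=False, default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def sd(self) -> float:
        return float(np.std(self.correlations, ddof=1)) if self.correlations.size > 1 else 0.0


def _pipeline_index(
    m: ExpressionMatrix,
    labels: CellAnnotation | None,
    max_zero_fraction: float,
    config: EMConfig,
) -> pd.Series:
    """filter -> log -> features -> index for one (sub)matrix."""
    sub = filter_genes_by_zeros(m, max_zero_fraction)
    if not sub.log_transformed:
        sub = log_transform(sub)
    lab = labels.subset(sub.cell_ids) if labels is not None else None
    ft = compute_features(sub, lab, config)
    return stability_index(ft).index.dropna()


def subsample_reproducibility(
    m: ExpressionMatrix,
    labels: CellAnnotation | None = None,
    fraction: float = 0.8,
    reps: int = 10,
    seed: int | None = None,
    max_zero_fraction: float = 0.8,
    config: EMConfig | None = None,
) -> ReproducibilityResult:
    """Reproducibility of the stability index under cell subsampling.

    Each replicate samples floor(fraction * n_cells) cells without
    replacement, re-runs the full pipeline (gene filter, log transform
    if needed, mixture features, index), and Pearson correlations are
    reported over the gene intersection of every replicate pair.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if reps < 2:
        raise ValueError("reps must be at least 2")
    config = config or EMConfig()
    n_take = int(np.floor(fraction * m.n_cells))
    ss = np.random.SeedSequence(seed)
    indices: list[pd.Series] = []
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        cells = rng.choice(m.n_cells, size=n_take, replace=False)
        indices.append(_pipeline_index(m.subset_cells(np.sort(cells)), labels,
                                       max_zero_fraction, config))
    cors = []
    for i in range(reps):
        for j in range(i + 1, reps):
            common = indices[i].index.intersection(indices[j].index)
            if len(common) < 10:
                raise ValueError(
                    f"gene intersection of replicates {i},{j} below 10 genes"
                )
            cors.append(
                float(np.corrcoef(indices[i][common], indices[j][common])[0, 1])
            )
    return ReproducibilityResult(correlations=np.asarray(cors), indices=indices)
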