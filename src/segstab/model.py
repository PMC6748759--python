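"""Model/Results interface to the stability framework.

`StabilityModel` bundles an expression matrix (with optional cell-class
annotation) together with the preprocessing and EM settings;
``fit()`` runs gene filter -> log transform -> per-gene mixture fits ->
feature table -> rank aggregation and returns a `StabilityResults`
carrying the feature estimates, scaled ranks, the stability index and
SEG selection, with a text ``summary()``.

Example
-------
>>> from segstab import simulate, StabilityModel
>>> ds = simulate.generate(n_genes=200, n_cells=400, seed=0)
>>> res = StabilityModel(ds.matrix, ds.annotation).fit()
>>> segs = res.select_segs()
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import concordance as _concordance
from . import index as _index
from .features import compute_features
from .io import (
    CellAnnotation,
    ExpressionMatrix,
    filter_genes_by_zeros,
    log_transform,
)
from .mixture import EMConfig


class StabilityModel:
    """Gene expression stability model for a genes x cells matrix.

    Parameters
    ----------
    data
        ExpressionMatrix or a genes x cells DataFrame of non-negative
        quantifications (raw scale unless ``log_transformed`` says
        otherwise).
    annotation
        Optional per-cell class labels; enables the F-statistic feature.
    max_zero_fraction
        Genes with a strictly larger zero fraction are removed (default
        0.8, i.e. the >80%-zeros filter).
    em_config
        EM control parameters for the per-gene mixture fits.
    """

    def __init__(
        self,
        data: ExpressionMatrix | pd.DataFrame,
        annotation: CellAnnotation | None = None,
        max_zero_fraction: float = 0.8,
        em_config: EMConfig | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = ExpressionMatrix.from_frame(data)
        self.data = data
        self.annotation = annotation
        self.max_zero_fraction = max_zero_fraction
        self.em_config = em_config or EMConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        labels: pd.Series | dict | None = None,
        **kwargs,
    ) -> "StabilityModel":
        ann = None
        if labels is not None:
            labels = pd.Series(labels)
            ann = CellAnnotation(list(labels.index.astype(str)),
                                 list(labels.astype(str)))
        return cls(ExpressionMatrix.from_frame(df), ann, **kwargs)

    def _preprocess(self) -> tuple[ExpressionMatrix, CellAnnotation | None]:
        m = filter_genes_by_zeros(self.data, self.max_zero_fraction)
        if not m.log_transformed:
            m = log_transform(m)
        ann = (
            self.annotation.subset(m.cell_ids) if self.annotation is not None else None
        )
        return m, ann

    def fit(self) -> "StabilityResults":
        """Run the full pipeline and return the fitted results."""
        m, ann = self._preprocess()
        features = compute_features(m, ann, self.em_config)
        res = _index.stability_index(features)
        return StabilityResults(model=self, matrix=m, annotation=ann,
                                features=features, ranking=res)


@dataclass
class StabilityResults:
    """Fitted per-gene stability features, ranks and index."""

    model: StabilityModel
    matrix: ExpressionMatrix
    annotation: CellAnnotation | None
    features: pd.DataFrame
    ranking: _index.StabilityResult

    @property
    def index(self) -> pd.Series:
        """Per-gene stability index in [0, 1]; larger = more stable."""
        return self.ranking.index

    @property
    def scaled_ranks(self) -> pd.DataFrame:
        return self.ranking.scaled_ranks

    @property
    def features_used(self) -> list[str]:
        return self.ranking.features_used

    def select_segs(self, index_pct: float = 80.0, feature_pct: float = 60.0) -> list[str]:
        """SEGs by the index >80 / per-feature >60 percentile rule."""
        return _index.select_segs(self.ranking, index_pct, feature_pct)

    def to_frame(self) -> pd.DataFrame:
        """Features, scaled ranks, index and SEG flag in one table."""
        out = self.features.join(self.ranking.to_frame())
        return out

    def evaluate_gene_list(self, genes, reps: int = 10, seed: int | None = None):
        """Concordance of k-means on the list's genes with true classes."""
        if self.annotation is None:
            raise ValueError("evaluation requires a cell annotation")
        return _concordance.evaluate_gene_list(
            self.matrix, genes, self.annotation, reps=reps, seed=seed
        )

    def subsample_reproducibility(
        self, fraction: float = 0.8, reps: int = 10, seed: int | None = None
    ):
        """Index reproducibility under repeated cell subsampling."""
        return _index.subsample_reproducibility(
            self.model.data,
            self.model.annotation,
            fraction=fraction,
            reps=reps,
            seed=seed,
            max_zero_fraction=self.model.max_zero_fraction,
            config=self.model.em_config,
        )

    def summary(self, top: int = 10) -> str:
        """Human-readable overview of the fit."""
        ft = self.features
        n_valid = int(ft["valid"].sum())
        lines = [
            "Gene expression stability (Gamma-Gaussian mixture + rank aggregation)",
            "=" * 70,
            f"genes (post filter): {len(ft):>6d}    cells: {self.matrix.n_cells}",
            f"valid mixture fits:  {n_valid:>6d}    features: {', '.join(self.features_used)}",
            f"stability index:     mean {self.index.mean():.3f}, "
            f"median {self.index.median():.3f}",
            "",
            f"top {top} most stable genes:",
        ]
        head = self.index.sort_values(ascending=False).head(top)
        tab = pd.DataFrame(
            {
                "index": head,
                "lambda": ft.loc[head.index, "lambda_"],
                "sigma2": ft.loc[head.index, "sigma2"],
                "omega": ft.loc[head.index, "omega"],
            }
        )
        lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
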