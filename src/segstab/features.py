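"""Per-gene stability features.

Four features quantify how stably a gene is expressed across single
cells:

* ``lambda_`` — mixing proportion of the Gamma (low/"off") component of
  the fitted Gamma-Gaussian mixture; low values mean unimodal expression.
* ``sigma2`` — variance of the Gaussian (expressed) component.
* ``omega_star`` — the zero fraction omega regularised by the min-max
  scaled Gaussian mean, omega* = omega * minmax(mu), correcting the
  dropout bias against lowly expressed genes.
* ``f_stat`` — one-way ANOVA F across predefined cell classes (only when
  labels are supplied); genes expressed at the same mean level in every
  class have small F.

The feature table is an ordinary pandas DataFrame indexed by gene, with
a boolean ``valid`` column flagging genes whose mixture fit succeeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CellAnnotation, ExpressionMatrix, ValidationError
from .mixture import (
    DegenerateInputError,
    EMConfig,
    FitFailureError,
    fit_gamma_gaussian,
)

FEATURE_COLUMNS = ["lambda_", "sigma2", "omega_star", "f_stat"]


def compute_zero_fraction(m: ExpressionMatrix) -> np.ndarray:
    """Fraction of zero entries per gene (omega)."""
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValidationError("empty matrix")
    return (m.values == 0).mean(axis=1)


def minmax_scale(v) -> np.ndarray:
    """Scale a vector to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=float)
    if v.size < 1:
        raise ValueError("minmax_scale needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("minmax_scale requires finite input")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def regularize_zero_proportion(omega, mu) -> np.ndarray:
    """omega* = omega * minmax(mu), elementwise over genes.

    Entries where ``mu`` is missing (failed fit) come out missing; the
    min-max scaling is computed over the valid genes only.
    """
    omega = np.asarray(omega, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if omega.shape != mu.shape:
        raise ValueError("omega and mu must have equal length")
    out = np.full_like(omega, np.nan)
    valid = np.isfinite(mu)
    if valid.any():
        out[valid] = omega[valid] * minmax_scale(mu[valid])
    return out


def f_statistic(values, labels) -> float:
    """One-way ANOVA F-statistic of one gene's expression across classes.

    Computed on all cells (zeros included).  Conventions for degenerate
    cases: no variation at all -> 0; zero within-class variance with
    nonzero between-class variance -> +inf (ranked most unstable).
    Classes with fewer than 2 cells must be dropped by the caller
    (dataset-level decision); with fewer than 2 usable classes the
    feature is undefined and NaN is returned.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    n = values.size
    p = classes.size
    if p < 2 or n <= p:
        return np.nan
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for k in range(p):
        grp = values[inv == k]
        gm = grp.mean()
        ssb += grp.size * (gm - grand) ** 2
        ssw += float(((grp - gm) ** 2).sum())
    if ssw <= 0.0:
        return 0.0 if ssb <= 1e-12 else np.inf
    return (ssb / (p - 1)) / (ssw / (n - p))


def _usable_classes(labels: np.ndarray) -> np.ndarray:
    """Mask of cells in classes with at least 2 members."""
    classes, counts = np.unique(labels, return_counts=True)
    keep = set(classes[counts >= 2])
    return np.array([l in keep for l in labels])


def compute_features(
    m: ExpressionMatrix,
    labels: CellAnnotation | None = None,
    config: EMConfig | None = None,
) -> pd.DataFrame:
    """Fit the mixture per gene and assemble the stability feature table.

    The matrix must already be log-transformed (and normally gene
    filtered).  Per-gene mixture failures set ``valid=False`` rather
    than aborting; omega* is computed across the valid genes.

    Returns a DataFrame indexed by gene with columns lambda_, sigma2,
    mu, omega, omega_star, valid and (when labels are given) f_stat.
    """
    if not m.log_transformed:
        raise ValidationError("compute_features expects a log-transformed matrix")
    config = config or EMConfig()

    omega = compute_zero_fraction(m)
    lam = np.full(m.n_genes, np.nan)
    mu = np.full(m.n_genes, np.nan)
    sig2 = np.full(m.n_genes, np.nan)
    valid = np.zeros(m.n_genes, dtype=bool)

    for g in range(m.n_genes):
        row = m.values[g]
        pos = row[row > 0]
        try:
            fit = fit_gamma_gaussian(pos, config)
        except (DegenerateInputError, FitFailureError):
            continue
        lam[g] = fit.lambda_
        mu[g] = fit.mu
        sig2[g] = fit.sigma2
        valid[g] = True

    table = pd.DataFrame(
        {
            "lambda_": lam,
            "sigma2": sig2,
            "mu": mu,
            "omega": omega,
            "omega_star": regularize_zero_proportion(omega, mu),
            "valid": valid,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )

    if labels is not None:
        lab = labels.labels_for(m.cell_ids)
        mask = _usable_classes(lab)
        if np.unique(lab[mask]).size < 2:
            table["f_stat"] = np.nan
        else:
            sub = m.values[:, mask]
            sub_lab = lab[mask]
            table["f_stat"] = [f_statistic(sub[g], sub_lab) for g in range(m.n_genes)]
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
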