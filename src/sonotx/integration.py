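"""Radiomic–transcriptomic integration.

Two operations connect the imaging and expression sides:

* ``correlate`` — pairwise Pearson correlation of radiomic features with
  expression of selected genes/miRNAs, with the classical t-transform
  two-sided p-value, optionally restricted to one stage's samples (the
  per-stage view is the default mode of use: pooled correlations conflate
  stage effects).
* ``cca`` — canonical correspondence analysis: constrained ordination of a
  nonnegative abundance table (samples x biomarkers, e.g. linear CPM)
  against explanatory variables (a stage indicator), via chi-square
  standardization, weighted regression on the constraints and SVD of the
  fitted matrix.  With one binary constraint exactly one constrained axis
  exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMap", "correlate", "CCAResult", "cca"]


@dataclass
class CorrelationMap:
    """Long-form pairwise Pearson map with significance stars."""

    table: pd.DataFrame  # columns: feature, gene, r, p, stars
    n_samples: int

    def matrix(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="feature", columns="gene", values=value)


def _pearson_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate(
    radiomic: pd.DataFrame,
    expression: pd.DataFrame,
    samples: list[str] | None = None,
    bh: bool = False,
) -> CorrelationMap:
    """Pearson r and two-sided p for every (radiomic feature, gene) pair.

    Both tables are samples x columns; rows are aligned on their shared
    index (optionally restricted to ``samples``, e.g. one stage).  A
    zero-variance column yields r = 0, p = 1.  Raw p-values are starred at
    0.05 (*) and 0.01 (**); BH adjustment is available but off by default.
    """
    common = radiomic.index.intersection(expression.index)
    if samples is not None:
        common = common.intersection(pd.Index(samples))
    if len(common) < 4:
        raise ValueError("need at least 4 overlapping samples")
    x = radiomic.loc[common]
    y = expression.loc[common]
    n = len(common)
    rows = []
    for feat in x.columns:
        fx = x[feat].to_numpy(dtype=float)
        sfx = fx.std()
        for gene in y.columns:
            gy = y[gene].to_numpy(dtype=float)
            sgy = gy.std()
            if sfx == 0 or sgy == 0:
                r, p = 0.0, 1.0
            else:
                r = float(np.mean((fx - fx.mean()) * (gy - gy.mean())) / (sfx * sgy))
                r = float(np.clip(r, -1.0, 1.0))
                p = _pearson_p(r, n)
            rows.append({"feature": feat, "gene": gene, "r": r, "p": p})
    table = pd.DataFrame(rows)
    pcol = table["p"].to_numpy()
    if bh:
        from statsmodels.stats.multitest import multipletests

        pcol = multipletests(pcol, method="fdr_bh")[1]
        table["q"] = pcol
    table["stars"] = np.where(pcol < 0.01, "**", np.where(pcol < 0.05, "*", ""))
    return CorrelationMap(table=table, n_samples=n)


@dataclass
class CCAResult:
    """Constrained ordination result."""

    eigenvalues: np.ndarray  # constrained eigenvalues, descending
    site_scores: pd.DataFrame  # samples x axes
    species_scores: pd.DataFrame  # biomarkers x axes
    total_inertia: float

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigenvalues.sum())


def cca(abundance: pd.DataFrame, constraints: pd.DataFrame | pd.Series) -> CCAResult:
    """Canonical correspondence analysis (ter Braak weighted-averaging form).

    ``abundance`` must be nonnegative with no all-zero row or column;
    ``constraints`` holds numeric explanatory columns (a 0/1 stage
    indicator in the typical use).  Eigenvalues equal the squared singular
    values of the row-weighted regression fit to the chi-square
    standardized matrix and agree with the classical algorithm.
    """
    y = abundance.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("abundance must be nonnegative")
    if (y.sum(axis=1) == 0).any() or (y.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column in abundance")
    if isinstance(constraints, pd.Series):
        constraints = constraints.to_frame()
    x = constraints.loc[abundance.index].to_numpy(dtype=float)

    total = y.sum()
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total_inertia = float((qbar**2).sum())

    # weighted (by row mass) centering of constraints, then projection in
    # the sqrt(r)-scaled space
    xc = x - np.average(x, axis=0, weights=r)
    z = xc * np.sqrt(r)[:, None]
    # fitted values of qbar under weighted least squares on the constraints
    zz = z.T @ z
    fitted = z @ np.linalg.pinv(zz) @ (z.T @ qbar)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * (s[0] if s.size else 1.0)))
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    eigenvalues = s**2

    axes = [f"CCA{k + 1}" for k in range(rank)]
    site = (u * s) / np.sqrt(r)[:, None]
    species = vt.T / np.sqrt(c)[:, None]
    return CCAResult(
        eigenvalues=eigenvalues,
        site_scores=pd.DataFrame(site, index=abundance.index, columns=axes),
        species_scores=pd.DataFrame(species, index=abundance.columns, columns=axes),
        total_inertia=total_inertia,
    )
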