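"""Expression-side analysis: normalization, differential expression,
stage-specific Venn logic, the six-biomarker filter, and gene-set enrichment.

Counts enter as features x samples matrices (mRNA or miRNA).  Normalization
is log2(CPM + 1).  Differential expression uses a per-feature Welch t-test
on the normalized values with Benjamini–Hochberg correction across
features; the fold-change filter operates on linear CPM group means.
Stage-specific sets follow Venn logic: a feature is stage-specific when it
is differentially expressed versus healthy in that stage's comparison but
not in the other stage's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize",
    "cpm",
    "DEResult",
    "de_test",
    "StageSpecificSets",
    "stage_specific_sets",
    "biomarker_filter",
    "enrichment",
]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to a library size of 1e6."""
    counts = counts.astype(float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero-library columns: {bad}")
    return counts.div(libsize, axis=1) * 1e6


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) transform of a features x samples count matrix."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return np.log2(cpm(counts) + 1.0)


@dataclass
class DEResult:
    """Per-feature two-group differential-expression results (B vs A)."""

    table: pd.DataFrame  # index: feature; columns: log2fc, fc, p, q, de_flag
    group_a: str
    group_b: str
    p_cutoff: float
    fc_cutoff: float

    @property
    def flagged(self) -> set[str]:
        return set(self.table.index[self.table["de_flag"]])


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p; degenerate inputs (zero variance both sides,
    equal means) give p = 1."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def de_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
) -> DEResult:
    """Welch t-test per feature on log2(CPM+1), BH across features.

    A feature is flagged when p < ``p_cutoff`` AND the linear-CPM fold
    change between group means exceeds ``fc_cutoff`` in either direction
    (``max(FC, 1/FC) > fc_cutoff``).  ``log2fc`` is B-vs-A on linear CPM
    group means (a 0.5-count offset guards empty groups' zero means).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    norm = normalize(counts)
    lin = cpm(counts)
    xa = norm[group_a].to_numpy()
    xb = norm[group_b].to_numpy()
    pvals = np.array([_welch_p(xa[k], xb[k]) for k in range(norm.shape[0])])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    mean_a = lin[group_a].mean(axis=1).to_numpy()
    mean_b = lin[group_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    fc = 2.0**log2fc
    passes_fc = np.maximum(fc, 1.0 / fc) > fc_cutoff
    flag = (pvals < p_cutoff) & passes_fc
    table = pd.DataFrame(
        {"log2fc": log2fc, "fc": fc, "p": pvals, "q": qvals, "de_flag": flag},
        index=counts.index,
    )
    return DEResult(table=table, group_a="A", group_b="B",
                    p_cutoff=p_cutoff, fc_cutoff=fc_cutoff)


@dataclass
class StageSpecificSets:
    """Venn decomposition of two stage-vs-healthy DE comparisons."""

    specific_T2c: set[str]
    specific_T3b: set[str]
    shared: set[str]
    de_all_tumor: set[str]  # recorded for the Venn report, not subtracted


def stage_specific_sets(
    de_t2c_vs_h: DEResult,
    de_t3b_vs_h: DEResult,
    de_all_vs_h: DEResult,
) -> StageSpecificSets:
    """Stage-specific = flagged in that stage's healthy comparison only."""
    universes = {frozenset(r.table.index) for r in (de_t2c_vs_h, de_t3b_vs_h, de_all_vs_h)}
    if len(universes) != 1:
        raise ValueError("DE results cover different feature universes")
    a = de_t2c_vs_h.flagged
    b = de_t3b_vs_h.flagged
    return StageSpecificSets(
        specific_T2c=a - b,
        specific_T3b=b - a,
        shared=a & b,
        de_all_tumor=de_all_vs_h.flagged,
    )


def biomarker_filter(de_t2c_vs_t3b: DEResult, panel: list[str]) -> pd.DataFrame:
    """Apply the p < p_cutoff and |FC| > fc_cutoff filter to a biomarker panel.

    Returns the passing panel members with their direction ("up" means
    higher in group B of the comparison, here the T3b side).
    """
    tbl = de_t2c_vs_t3b.table
    missing = [g for g in panel if g not in tbl.index]
    if missing:
        raise ValueError(f"panel members absent from universe: {missing}")
    sub = tbl.loc[panel]
    fc_ok = np.maximum(sub["fc"], 1.0 / sub["fc"]) > de_t2c_vs_t3b.fc_cutoff
    passing = sub[(sub["p"] < de_t2c_vs_t3b.p_cutoff) & fc_ok].copy()
    passing["direction"] = np.where(passing["log2fc"] > 0, "up", "down")
    return passing[["log2fc", "fc", "p", "q", "direction"]]


def enrichment(
    feature_set: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set, BH q.

    With universe size N, set size K, query size n and overlap k the
    p-value is P[X >= k], X ~ Hypergeom(N, K, n).
    """
    if not universe:
        raise ValueError("empty universe")
    bad = feature_set - universe
    if bad:
        raise ValueError("query features outside universe")
    n_univ = len(universe)
    n_query = len(feature_set & universe)
    rows = []
    for name, members in collection.items():
        if not members <= universe:
            raise ValueError(f"gene set {name!r} not contained in universe")
        k_set = len(members)
        overlap = len(feature_set & members)
        if n_query == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_univ, k_set, n_query))
        rows.append({"set": name, "set_size": k_set, "overlap": overlap, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    return df
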