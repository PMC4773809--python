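"""Differentiation outliers and population-structure summaries.

Outliers are loci whose F_ST is unexpectedly high given a predictor (DAF
or heterozygosity): an ordinary least-squares fit of F_ST on the predictor
is computed and loci with internally studentized residuals above +2
(one-sided; only unusually *high* differentiation is of interest) are
flagged. A second, independent flag marks loci above the 95th percentile
of raw F_ST.

Structure summaries operate on the populations x variants DAF matrix:
principal components of the column-centered matrix, hierarchical
clustering of populations (Euclidean distance, average linkage), pooled
per-group distribution summaries, and per-category total DAF (category
sums are intentionally uncapped and may exceed 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .panel import PanelMap
from .variants import PtcCall


@dataclass
class RegressionOutlierReport:
    predictor: str
    slope: float
    intercept: float
    resid_sd: float
    studentized: np.ndarray        # internally studentized residuals
    outlier: np.ndarray            # studentized > +2
    percentile_95: float
    above_95th: np.ndarray         # raw y strictly above the 95th percentile
    threshold: float = 2.0


def regress_outliers(x: np.ndarray, y: np.ndarray, predictor: str = "daf",
                     threshold: float = 2.0) -> RegressionOutlierReport:
    """OLS of per-locus F_ST (y) on a predictor (x) with residual outliers.

    Residuals are internally studentized (leverage-corrected); a locus is
    an outlier when its studentized residual exceeds +``threshold``. The
    95th-percentile flag on raw y (linear interpolation, strict >) is
    computed independently and survives a degenerate regression
    (constant x).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 loci with defined predictor and F_ST")

    p95 = float(np.percentile(y[ok], 95))
    above = np.zeros(len(y), dtype=bool)
    above[ok] = y[ok] > p95

    studentized = np.full(len(y), np.nan)
    if np.ptp(x[ok]) == 0 or np.allclose(y[ok], y[ok][0]):
        # degenerate: no regression (constant predictor) or zero residuals
        slope = intercept = resid_sd = 0.0
        if np.ptp(x[ok]) > 0:  # constant y: fit exists, residuals all zero
            slope, intercept = 0.0, float(y[ok][0])
            studentized[ok] = 0.0
        outlier = np.zeros(len(y), dtype=bool)
    else:
        model = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
        infl = model.get_influence()
        studentized[ok] = infl.resid_studentized_internal
        intercept, slope = (float(b) for b in model.params)
        resid_sd = float(np.sqrt(model.mse_resid))
        outlier = np.zeros(len(y), dtype=bool)
        outlier[ok] = studentized[ok] > threshold

    return RegressionOutlierReport(
        predictor=predictor, slope=slope, intercept=intercept,
        resid_sd=resid_sd, studentized=studentized, outlier=outlier,
        percentile_95=p95, above_95th=above, threshold=threshold,
    )


# -- DAF matrix and structure ---------------------------------------------

def daf_matrix(ptcs: list[PtcCall], panel: PanelMap
               ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Populations x variants matrix of per-population DAF (%).

    Row order follows the panel's population order. Entries where a
    population has no called genotypes are set to 0 with the mask (True =
    observed) returned alongside. Returns (matrix, mask, populations,
    variant ids).
    """
    pops = panel.populations
    ids = [f"{p.chrom}:{p.pos}" for p in ptcs]
    M = np.zeros((len(pops), len(ptcs)))
    mask = np.zeros_like(M, dtype=bool)
    for j, ptc in enumerate(ptcs):
        for i, pop in enumerate(pops):
            v = ptc.pop_daf.get(pop, float("nan")) if ptc.pop_daf else float("nan")
            if np.isfinite(v):
                M[i, j] = v
                mask[i, j] = True
    return M, mask, pops, ids


def pca_structure(matrix: np.ndarray, n_components: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of populations (rows = observations) via SVD of the
    column-centered matrix; no unit-variance scaling (DAFs share units).

    Sign convention: each component is oriented so its largest-magnitude
    loading is positive. Returns (scores, loadings, variance_explained).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 populations and >= 2 variants")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("rank-0 matrix: populations are identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components or len(s), len(s))
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    var = s ** 2 / (X.shape[0] - 1)
    explained = var[:k] / var.sum()
    return scores, Vt[:k], explained


def hca_structure(matrix: np.ndarray, labels: list[str]
                  ) -> tuple[np.ndarray, str]:
    """Average-linkage hierarchical clustering of populations on Euclidean
    DAF distances. Returns (scipy linkage matrix, Newick string)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return Z, linkage_to_newick(Z, labels)


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram into k clusters."""
    return fcluster(Z, t=k, criterion="maxclust")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        length_l = node.dist - node.left.dist
        length_r = node.dist - node.right.dist
        return f"({rec(node.left)}:{length_l:.6g},{rec(node.right)}:{length_r:.6g})"

    return rec(root) + ";"


# -- group and category summaries -----------------------------------------

def group_summaries(matrix: np.ndarray, populations: list[str],
                    group_of: dict[str, str]) -> pd.DataFrame:
    """Median and quartiles of per-variant DAFs pooled within each
    population group (exact order statistics; empty groups excluded)."""
    rows = []
    groups: dict[str, list[int]] = {}
    for i, pop in enumerate(populations):
        if pop not in group_of:
            raise KeyError(f"population {pop!r} has no group assignment")
        groups.setdefault(group_of[pop], []).append(i)
    for grp, idx in groups.items():
        vals = matrix[idx].ravel()
        if vals.size == 0:
            import warnings

            warnings.warn(f"group {grp!r} empty; excluded")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": grp, "n_values": vals.size,
                     "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows)


def category_daf(gene_daf_by_pop: pd.DataFrame, category_of: dict[str, str],
                 vocabulary: set[str] | None = None) -> pd.DataFrame:
    """Per-category, per-population total DAF.

    ``gene_daf_by_pop`` is the output of ``aggregate_gene_daf`` (columns
    ``gene_id`` plus ``daf_<pop>``). Unmapped genes go to "unclustered"; a
    category outside the supplied closed vocabulary raises, naming the
    gene. A TOTAL row holds the per-population grand totals.
    """
    daf_cols = [c for c in gene_daf_by_pop.columns if c.startswith("daf_")]
    sums: dict[str, dict[str, float]] = {}
    for row in gene_daf_by_pop.itertuples(index=False):
        cat = category_of.get(row.gene_id, "unclustered")
        if vocabulary is not None and cat != "unclustered" and cat not in vocabulary:
            raise ValueError(f"gene {row.gene_id!r} mapped to unknown category {cat!r}")
        acc = sums.setdefault(cat, {c: 0.0 for c in daf_cols})
        for c in daf_cols:
            acc[c] += getattr(row, c)
    out = pd.DataFrame(
        [{"category": cat, **vals} for cat, vals in sums.items()]
    )
    total = {"category": "TOTAL", **{c: out[c].sum() for c in daf_cols}}
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
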