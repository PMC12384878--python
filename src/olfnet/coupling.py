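"""Transcriptomic eigengenes and the eigengene x imaging-metric coupling grid.

An "eigengene" is a principal-component score summarizing a tissue's major
axis of co-expression (10 components for blood, 4 per brain region by
default).  Expression counts are CPM-scaled, log2(x+1)-transformed and
gene-centered, then decomposed by SVD.  The coupling grid fits one simple
linear model per (region, metric, eigengene) cell on within-region
z-scored variables — so the slope equals the Pearson correlation — and
controls the false-discovery rate over the whole grid with
Benjamini-Hochberg (560 cells under the default 8 regions x 10 eigengenes
x 7 metrics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Normalization and PCA
# ---------------------------------------------------------------------------


def normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million scaling, log2(x + 1), then gene-wise centering.

    ``expr`` is genes x subjects.  CPM makes the profile invariant to
    library size; centering removes per-gene baseline abundance so the PCA
    captures co-variation, not mean expression."""
    if expr.shape[1] < 2:
        raise ConfigurationError("need at least 2 subjects to normalize")
    if (expr.to_numpy() < 0).any():
        raise DataIntegrityError("expression counts must be nonnegative")
    lib = expr.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise DataIntegrityError(f"zero library size for subject(s): {list(zero.index)}")
    cpm = expr / lib * 1e6
    logged = np.log2(cpm + 1.0)
    return logged.sub(logged.mean(axis=1), axis=0)


@dataclass
class EigengeneSet:
    """PCA loadings (genes x K), unit-variance scores (subjects x K),
    variance-explained fractions, for one tissue."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    tissue: str = ""

    @property
    def K(self) -> int:
        return self.scores.shape[1]


def compute_eigengenes(normalized: pd.DataFrame, K: int, tissue: str = "") -> EigengeneSet:
    """SVD-based PCA of a normalized genes x subjects matrix.

    Scores are standardized to unit sample variance; loadings are the
    right singular vectors over genes.  Sign convention: the
    largest-|loading| gene of each component loads positively."""
    n_genes, n_subj = normalized.shape
    if K > min(n_genes, n_subj - 1):
        raise ConfigurationError(
            f"K={K} exceeds min(genes, subjects-1) = {min(n_genes, n_subj - 1)}"
        )
    M = normalized.to_numpy().T  # subjects x genes
    M = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    var = s**2
    var_explained = (var / var.sum())[:K]

    loadings = Vt[:K].T            # genes x K
    scores = U[:, :K] * s[:K]      # subjects x K, raw PC scores
    # fix signs, then standardize scores to unit variance
    for k in range(K):
        g = np.argmax(np.abs(loadings[:, k]))
        if loadings[g, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
        sd = scores[:, k].std(ddof=1)
        if sd > 0:
            scores[:, k] /= sd
    comp_names = [f"PC{k + 1}" for k in range(K)]
    return EigengeneSet(
        loadings=pd.DataFrame(loadings, index=normalized.index, columns=comp_names),
        scores=pd.DataFrame(scores, index=normalized.columns, columns=comp_names),
        variance_explained=var_explained,
        tissue=tissue,
    )


def top_loading_genes(eigengenes: EigengeneSet, component: int, n: int = 200) -> list:
    """Genes ranked by |loading| on one component (1-based), descending;
    ties broken alphabetically; returns min(n, total genes)."""
    if not 1 <= component <= eigengenes.K:
        raise ConfigurationError(f"component {component} not in 1..{eigengenes.K}")
    col = eigengenes.loadings.iloc[:, component - 1]
    ranked = sorted(col.index, key=lambda g: (-abs(col[g]), g))
    return ranked[: min(n, len(ranked))]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values: monotone-enforced, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(np.isnan(p)):
        raise DataIntegrityError("NaN p-value passed to BH correction")
    if np.any((p < 0) | (p > 1)):
        raise DataIntegrityError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Coupling grid
# ---------------------------------------------------------------------------


def coupling_grid(
    imaging_table: pd.DataFrame,
    eigengene_scores: pd.DataFrame,
    regions=None,
    metrics=None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """One record per (region, metric, eigengene): within-region z-scored
    simple regression of eigengene on metric, so beta equals Pearson r.

    Subjects are inner-joined between the imaging table and the score
    matrix (logged).  Cells with fewer than 4 overlapping subjects get a
    missing-statistics flag and are excluded from the BH family; all
    remaining cells are corrected jointly."""
    if regions is None:
        regions = sorted(imaging_table["region"].unique().tolist())
    if metrics is None:
        metrics = sorted(imaging_table["metric"].unique().tolist())
    eg_names = list(eigengene_scores.columns)

    records = []
    for region in regions:
        reg = imaging_table[imaging_table["region"] == region]
        wide = reg.pivot_table(index="subject_id", columns="metric", values="value")
        common = wide.index.intersection(eigengene_scores.index)
        n_dropped = len(wide.index.symmetric_difference(eigengene_scores.index))
        if n_dropped:
            logger.info("region %s: %d non-overlapping subjects dropped", region, n_dropped)
        for metric in metrics:
            x_full = wide.loc[common, metric] if metric in wide.columns else pd.Series(dtype=float)
            for k, eg in enumerate(eg_names, start=1):
                y_full = eigengene_scores.loc[common, eg] if len(common) else pd.Series(dtype=float)
                ok = x_full.notna() if len(common) else pd.Series(dtype=bool)
                n_cell = int(ok.sum()) if len(common) else 0
                if n_cell < 4:
                    records.append(dict(region=region, metric=metric, eigengene=k,
                                        n=n_cell, beta=np.nan, r=np.nan, p=np.nan,
                                        r_squared=np.nan, missing=True))
                    continue
                x = x_full[ok].to_numpy()
                y = y_full[ok].to_numpy()
                xsd, ysd = x.std(ddof=1), y.std(ddof=1)
                if xsd == 0 or ysd == 0:
                    records.append(dict(region=region, metric=metric, eigengene=k,
                                        n=n_cell, beta=np.nan, r=np.nan, p=np.nan,
                                        r_squared=np.nan, missing=True))
                    continue
                xz = (x - x.mean()) / xsd
                yz = (y - y.mean()) / ysd
                # slope of yz ~ xz is exactly the Pearson correlation
                beta = float(xz @ yz / (xz @ xz))
                r, p = scipy.stats.pearsonr(x, y)
                records.append(dict(region=region, metric=metric, eigengene=k,
                                    n=n_cell, beta=beta, r=float(r), p=float(p),
                                    r_squared=float(r) ** 2, missing=False))
    grid = pd.DataFrame(records)
    grid["fdr"] = np.nan
    tested = ~grid["missing"]
    if tested.any():
        grid.loc[tested, "fdr"] = bh_fdr(grid.loc[tested, "p"].to_numpy())
    grid["significant"] = grid["fdr"] < fdr_level
    return grid


def top_regions_per_pair(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per (metric, eigengene) pair, keep the k regions with the largest
    |r|; ties broken by region name."""
    tested = records[~records["missing"]].copy()
    tested["_abs_r"] = tested["r"].abs()
    tested = tested.sort_values(["metric", "eigengene", "_abs_r", "region"],
                                ascending=[True, True, False, True], kind="stable")
    out = tested.groupby(["metric", "eigengene"], sort=True).head(k)
    return out.drop(columns="_abs_r").reset_index(drop=True)
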