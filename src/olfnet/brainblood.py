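"""Cross-tissue principal-component coupling and gene-set over-representation.

Correlates the top PCs of expression between tissue pairs (blood vs. brain
region, region vs. region) with both Pearson and Spearman tests under
Benjamini-Hochberg control, intersects the top-200 |loading| gene lists of
significant PC pairs (discarding intersections below five genes), and
tests the intersections for over-representation against a GMT gene-set
collection with the upper-tail hypergeometric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .coupling import EigengeneSet, bh_fdr, top_loading_genes
from .exceptions import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# PC pair correlations
# ---------------------------------------------------------------------------


def pc_pair_correlations(
    eigengene_sets: dict,
    top_k: int = 4,
    fdr_level: float = 0.05,
    pool_families: bool = False,
) -> pd.DataFrame:
    """All tissue-pair x PC-pair Pearson and Spearman correlations.

    Subjects are intersected per tissue pair; pairs with fewer than 4
    shared subjects are skipped with a log entry.  BH adjustment runs in
    one family per test type by default (``pool_families`` merges them).
    A pair is significant when min(fdr_pearson, fdr_spearman) < level."""
    if len(eigengene_sets) < 2:
        raise ConfigurationError("need at least 2 tissues")
    records = []
    for tissue_a, tissue_b in combinations(sorted(eigengene_sets), 2):
        sa, sb = eigengene_sets[tissue_a], eigengene_sets[tissue_b]
        common = sa.scores.index.intersection(sb.scores.index)
        if len(common) < 4:
            logger.info("skipping pair (%s, %s): only %d shared subjects",
                        tissue_a, tissue_b, len(common))
            continue
        ka = min(top_k, sa.K)
        kb = min(top_k, sb.K)
        for pa in range(1, ka + 1):
            for pb in range(1, kb + 1):
                x = sa.scores.loc[common].iloc[:, pa - 1].to_numpy()
                y = sb.scores.loc[common].iloc[:, pb - 1].to_numpy()
                pr = scipy.stats.pearsonr(x, y)
                sr = scipy.stats.spearmanr(x, y)
                records.append(dict(
                    tissue_a=tissue_a, tissue_b=tissue_b, pc_a=pa, pc_b=pb,
                    n=len(common),
                    pearson_r=float(pr.statistic), p_pearson=float(pr.pvalue),
                    spearman_rho=float(sr.statistic), p_spearman=float(sr.pvalue),
                ))
    if not records:
        raise DataIntegrityError("no tissue pair had at least 4 shared subjects")
    df = pd.DataFrame(records)
    if pool_families:
        pooled = bh_fdr(np.concatenate([df["p_pearson"], df["p_spearman"]]))
        df["fdr_pearson"] = pooled[: len(df)]
        df["fdr_spearman"] = pooled[len(df):]
    else:
        df["fdr_pearson"] = bh_fdr(df["p_pearson"].to_numpy())
        df["fdr_spearman"] = bh_fdr(df["p_spearman"].to_numpy())
    df["significant"] = np.minimum(df["fdr_pearson"], df["fdr_spearman"]) < fdr_level
    return df


# ---------------------------------------------------------------------------
# Top-loading intersections
# ---------------------------------------------------------------------------


def intersect_top_loadings(
    set_a: EigengeneSet,
    set_b: EigengeneSet,
    pc_a: int,
    pc_b: int,
    n: int = 200,
    min_overlap: int = 5,
) -> list:
    """Sorted intersection of the two top-n |loading| gene lists; empty
    (a skip marker) when the overlap has fewer than ``min_overlap`` genes.
    Symmetric in its arguments."""
    genes_a = set(top_loading_genes(set_a, pc_a, n))
    genes_b = set(top_loading_genes(set_b, pc_b, n))
    overlap = sorted(genes_a & genes_b)
    if len(overlap) < min_overlap:
        return []
    return overlap


# ---------------------------------------------------------------------------
# GMT gene sets and hypergeometric ORA
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe; set genes outside the
    universe are filtered and empty sets dropped at construction."""

    sets: dict          # set_id -> (description, [genes])
    universe: list

    def __post_init__(self):
        uni = set(self.universe)
        filtered = {}
        for set_id, (desc, genes) in self.sets.items():
            kept = sorted(set(genes) & uni)
            if kept:
                filtered[set_id] = (desc, kept)
        self.sets = filtered
        self.universe = sorted(uni)


def read_gmt(path: str | Path, universe=None) -> GeneSetCollection:
    """Read a tab-separated GMT file (set_id, description, genes...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataIntegrityError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = (parts[1], parts[2:])
    if universe is None:
        universe = sorted({g for _, genes in sets.values() for g in genes})
    return GeneSetCollection(sets=sets, universe=list(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([set_id, desc, *genes])
        for set_id, (desc, genes) in sorted(collection.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(query_genes, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list
    against every set in the collection, BH-corrected across sets and
    sorted by FDR.

    Query genes outside the universe are logged and dropped; an empty
    query after filtering is an error."""
    universe = set(collection.universe)
    query = sorted(set(query_genes))
    outside = [g for g in query if g not in universe]
    if outside:
        logger.info("dropping %d query genes outside the universe", len(outside))
    query = [g for g in query if g in universe]
    if not query:
        raise DataIntegrityError("query is empty after filtering to the universe")

    M = len(universe)
    n_query = len(query)
    qset = set(query)
    records = []
    for set_id, (_, genes) in collection.sets.items():
        K = len(genes)
        k = len(qset & set(genes))
        p = float(scipy.stats.hypergeom.sf(k - 1, M, K, n_query))
        records.append(dict(set_id=set_id, overlap_k=k, set_size=K,
                            query_size=n_query, universe_size=M, p=p))
    df = pd.DataFrame(records)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["fdr", "p", "set_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def coupling_report(
    pair_records: pd.DataFrame,
    eigengene_sets: dict,
    collection: GeneSetCollection | None,
    out_dir: str | Path,
    n_top: int = 200,
    min_overlap: int = 5,
) -> list:
    """Write the PC-pair correlation table, per-significant-pair
    intersection gene lists, and enrichment tables; deterministic ordering.
    Returns the written file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "pc_pair_correlations.csv"
    pair_records.sort_values(["tissue_a", "tissue_b", "pc_a", "pc_b"]).to_csv(
        path, index=False, float_format="%.10g")
    written.append(path)

    sig = pair_records[pair_records["significant"]]
    for _, row in sig.iterrows():
        tag = f"{row.tissue_a}_PC{row.pc_a}__{row.tissue_b}_PC{row.pc_b}"
        overlap = intersect_top_loadings(
            eigengene_sets[row.tissue_a], eigengene_sets[row.tissue_b],
            int(row.pc_a), int(row.pc_b), n=n_top, min_overlap=min_overlap,
        )
        if not overlap:
            logger.info("pair %s: intersection below %d genes, skipped", tag, min_overlap)
            continue
        gene_path = out / f"intersection_{tag}.txt"
        gene_path.write_text("\n".join(overlap) + "\n")
        written.append(gene_path)
        if collection is not None:
            enr = hypergeometric_enrichment(overlap, collection)
            enr_path = out / f"enrichment_{tag}.csv"
            enr.to_csv(enr_path, index=False, float_format="%.10g")
            written.append(enr_path)
    return written
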