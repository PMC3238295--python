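"""Preferential expression measures and paralog expression divergence.

The atlas is a genes x tissues matrix of average-difference (AD) microarray
signals.  For a retained gene, PEM(g, t) = log10(S / A) where S is the signal
of gene g in tissue t and A its arithmetic mean signal across tissues; genes
with A < 50 (no detectable expression) or A > 999 (saturating) are excluded.
A gene counts as *expressed* in a tissue when S >= 200; expression breadth is
the percentage of tissues above that cutoff and PEM_MAX the per-gene maximum
PEM.  Pairwise expression divergence between paralogs is summarised per
duplication-age class with a choice of classical metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy import stats

from .errors import InputError

EXPRESSED_THRESHOLD = 200.0
A_MIN = 50.0
A_MAX = 999.0


@dataclass
class PEMatrix:
    pem: pd.DataFrame                  # genes x tissues, log10(S/A)
    mean_signal: pd.Series             # per-gene A
    expressed: pd.DataFrame            # per-cell S >= threshold flags
    breadth_pct: pd.Series
    pem_max: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> reason


def _average_probes(atlas: pd.DataFrame, probe_gene_map: dict[str, str]) -> pd.DataFrame:
    genes = atlas.index.to_series().map(probe_gene_map)
    if genes.isna().any():
        missing = atlas.index[genes.isna()][:5].tolist()
        raise InputError(f"probes without gene mapping: {missing}")
    return atlas.groupby(genes.values).mean()


def compute_pem(
    atlas: pd.DataFrame,
    expressed_threshold: float = EXPRESSED_THRESHOLD,
    a_min: float = A_MIN,
    a_max: float = A_MAX,
    probe_gene_map: Optional[dict[str, str]] = None,
) -> PEMatrix:
    """PEM matrix over retained genes (probe averaging, then AD-mean filter,
    then PEM).  Zero-signal cells yield no PEM value (flagged NaN)."""
    if (atlas.values < 0).any():
        raise InputError("atlas contains negative signals")
    if atlas.columns.duplicated().any():
        raise InputError("duplicate tissue names")
    if probe_gene_map is not None:
        atlas = _average_probes(atlas, probe_gene_map)
    mean_signal = atlas.mean(axis=1)
    excluded: dict[str, str] = {}
    for gene, a in mean_signal.items():
        if a == 0:
            excluded[gene] = "zero mean signal"
        elif a < a_min:
            excluded[gene] = f"AD_avg < {a_min:g}"
        elif a > a_max:
            excluded[gene] = f"AD_avg > {a_max:g}"
    kept = atlas.drop(index=list(excluded))
    a_kept = mean_signal.drop(index=list(excluded))
    with np.errstate(divide="ignore"):
        pem = np.log10(kept.div(a_kept, axis=0))
    pem = pem.where(kept > 0)  # zero signals: no PEM, flagged as NaN
    expressed = kept >= expressed_threshold
    breadth = 100.0 * expressed.sum(axis=1) / kept.shape[1]
    return PEMatrix(
        pem=pem,
        mean_signal=a_kept,
        expressed=expressed,
        breadth_pct=breadth,
        pem_max=pem.max(axis=1),
        excluded=excluded,
    )


def _cluster_order(matrix: np.ndarray, labels: list[str]) -> list[str]:
    """Average-linkage euclidean ordering with deterministic tie-breaking
    (input rows pre-sorted by label)."""
    if len(labels) < 3:
        return labels
    order = np.argsort(labels)
    z = linkage(pdist(matrix[order]), method="average")
    return [labels[order[i]] for i in leaves_list(z)]


def taxon_tissue_matrix(
    pem: PEMatrix,
    timing: dict[str, str],
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Mean PEM per (duplication taxon, tissue) with hierarchical row/column
    orderings — the matrix behind a taxon x tissue expression heatmap.

    ``timing`` maps gene -> taxon of its creating duplication; taxa with no
    retained genes are omitted.
    """
    frame = pem.pem.copy()
    taxa = frame.index.to_series().map(timing)
    frame = frame[taxa.notna().values]
    if frame.empty:
        raise InputError("no timed genes with PEM values")
    matrix = frame.groupby(taxa.dropna().values).mean()
    row_order = _cluster_order(np.nan_to_num(matrix.values), list(matrix.index))
    col_order = _cluster_order(np.nan_to_num(matrix.values.T), list(matrix.columns))
    return matrix, row_order, col_order


def preferential_tissue_genes(pem: PEMatrix, tissue: str, pem_min: float = 0.4
                              ) -> list[str]:
    """Genes with PEM(g, tissue) strictly above ``pem_min``, strongest first."""
    if tissue not in pem.pem.columns:
        raise InputError(f"unknown tissue {tissue!r}")
    col = pem.pem[tissue].dropna()
    hits = col[col > pem_min].sort_values(ascending=False)
    return list(hits.index)


_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "pearson": lambda x, y: float(stats.pearsonr(x, y).statistic),
    "spearman": lambda x, y: float(stats.spearmanr(x, y).statistic),
    "kendall": lambda x, y: float(stats.kendalltau(x, y).statistic),
    "manhattan": lambda x, y: float(np.abs(x - y).sum()),
}


def pair_divergence(
    expression: pd.DataFrame,
    pairs_with_age: Iterable[tuple[str, str, str]],
    metric: str = "pearson",
    age_order: Optional[list[str]] = None,
    expressed_threshold: float = EXPRESSED_THRESHOLD,
) -> dict:
    """Per-pair expression similarity/distance plus per-age-class summaries.

    ``pairs_with_age`` yields (gene_a, gene_b, age_class); pairs missing an
    expression row are dropped (counted).  Correlation metrics on a constant
    profile are undefined: such pairs are flagged and excluded from summaries.
    ``breadth_diff`` is the absolute difference in expression breadth.
    Summaries (median and quartiles) are ordered oldest to youngest when
    ``age_order`` is given.
    """
    if metric not in (*_METRICS, "breadth_diff"):
        raise InputError(f"unknown metric {metric!r}")
    values: list[tuple[str, str, str, float]] = []
    dropped = flagged = 0
    for a, b, age in pairs_with_age:
        if a not in expression.index or b not in expression.index:
            dropped += 1
            continue
        x = expression.loc[a].to_numpy(dtype=float)
        y = expression.loc[b].to_numpy(dtype=float)
        if metric == "breadth_diff":
            bx = 100.0 * (x >= expressed_threshold).mean()
            by = 100.0 * (y >= expressed_threshold).mean()
            val = abs(bx - by)
        elif metric in ("pearson", "spearman", "kendall") and (
                np.ptp(x) == 0 or np.ptp(y) == 0):
            flagged += 1
            continue
        else:
            val = _METRICS[metric](x, y)
        values.append((a, b, age, val))
    by_age: dict[str, list[float]] = {}
    for _, _, age, val in values:
        by_age.setdefault(age, []).append(val)
    ages = age_order if age_order is not None else sorted(by_age)
    summaries = {}
    for age in ages:
        vals = np.asarray(by_age.get(age, []), dtype=float)
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summaries[age] = {"n": int(vals.size), "q1": float(q1),
                              "median": float(med), "q3": float(q3)}
        else:
            summaries[age] = {"n": 0, "q1": None, "median": None, "q3": None}
    return {
        "metric": metric,
        "pairs": values,
        "summaries": summaries,
        "n_dropped": dropped,
        "n_flagged_constant": flagged,
    }


def write_pem(pem: PEMatrix, path) -> None:
    pem.pem.to_csv(path, sep="\t", index_label="gene", float_format="%.4f")
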