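"""Gene-signature module scoring and per-cell signature labeling.

A module score is the mean log-normalised expression of a gene set minus
the mean over an expression-matched control set: genes are binned by
dataset-wide mean expression into ``n_bins`` bins and, for every set gene,
``n_ctrl_per_bin`` control genes are drawn (seeded) from its bin. Scores
are therefore centred near zero for sets that behave like their
expression-matched background.

One-vs-rest enrichment compares the scores of each group's cells against
all other cells with a Wilcoxon rank-sum test; because module scores can be
negative, the reported log2 fold change is computed after shifting all
group means by the global minimum plus a small epsilon, and the shift is
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    source: str = ""


@dataclass
class ModuleScoreVector:
    scores: pd.Series
    gene_set: str
    n_bins: int
    n_ctrl_per_bin: int
    seed: int
    genes_used: list[str] = field(default_factory=list)


def _as_dense_col_means(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.mean(axis=0)).ravel()
    return np.asarray(matrix).mean(axis=0)


def module_score(
    lognorm,
    gene_ids: list[str],
    gene_set: GeneSet | list[str],
    n_bins: int = 25,
    n_ctrl_per_bin: int = 50,
    seed: int = 0,
) -> ModuleScoreVector:
    """Expression-matched module score per cell (seeded, deterministic).

    Raises if no set gene is present in the matrix; missing genes are
    dropped with a warning.
    """
    if isinstance(gene_set, GeneSet):
        name, genes = gene_set.name, gene_set.genes
    else:
        name, genes = "gene_set", list(gene_set)
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if not present:
        raise ValueError(f"no gene of set {name!r} present; missing: {missing}")
    if missing:
        warnings.warn(f"set {name!r}: dropped {len(missing)} absent genes")

    means = _as_dense_col_means(lognorm)
    n_genes = len(gene_ids)
    # canonical ordering: mean expression with gene-id tie-break, so that
    # binning and control draws are invariant to the matrix's column order
    names = np.asarray(gene_ids, dtype=object)
    order = np.lexsort((names, means))
    bins = np.empty(n_genes, dtype=np.int64)
    bins[order] = np.arange(n_genes) * n_bins // n_genes

    rng = np.random.default_rng(seed)
    set_idx = np.array([index[g] for g in present])
    control = set()
    for gi in sorted(set_idx, key=lambda i: gene_ids[i]):
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[np.argsort(names[pool])]
        take = min(n_ctrl_per_bin, pool.size)
        control.update(pool[rng.choice(pool.size, size=take, replace=False)].tolist())
    control -= set(set_idx.tolist())
    ctrl_idx = np.array(sorted(control), dtype=np.int64)

    def mean_over(idx):
        sub = lognorm[:, idx]
        return np.asarray(sub.mean(axis=1)).ravel()

    set_means = mean_over(set_idx)
    if ctrl_idx.size == 0:
        # the set exhausts its expression bins (e.g. the full gene
        # universe): the matched baseline is the set itself
        warnings.warn(f"set {name!r} leaves no control genes; scores are 0")
        scores = np.zeros_like(set_means)
    else:
        scores = set_means - mean_over(ctrl_idx)
    return ModuleScoreVector(
        scores=pd.Series(scores, name=name),
        gene_set=name,
        n_bins=n_bins,
        n_ctrl_per_bin=n_ctrl_per_bin,
        seed=seed,
        genes_used=present,
    )


def one_vs_rest_enrichment(
    scores: pd.Series | np.ndarray,
    group_labels: pd.Series | np.ndarray,
    min_group_size: int = 3,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of each group's scores against all other cells.

    Log2 fold change is computed on group means shifted positive by the
    global minimum score plus ``eps``; both the shift and eps are recorded.
    Groups smaller than ``min_group_size`` are skipped with a warning.
    """
    s = np.asarray(scores, dtype=float)
    labels = pd.Series(np.asarray(group_labels))
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    shift = -float(s.min()) + eps
    rows = []
    for g in groups:
        mask = (labels == g).to_numpy()
        if mask.sum() < min_group_size:
            warnings.warn(f"group {g!r} has < {min_group_size} cells, skipped")
            continue
        a, b = s[mask], s[~mask]
        stat, p = stats.ranksums(a, b)
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "mean_score": float(a.mean()),
                "rest_mean_score": float(b.mean()),
                "lfc": float(np.log2((a.mean() + shift) / (b.mean() + shift))),
                "statistic": float(stat),
                "p": float(p),
                "shift": shift,
                "eps": eps,
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def label_cells_by_signature(
    score_matrix: pd.DataFrame,
    margin_z: float = 0.5,
) -> pd.Series:
    """Assign each cell the signature with the highest z-scaled score.

    A cell is labeled only when its best z-score is positive and exceeds the
    runner-up by ``margin_z``; otherwise ``Unassigned``. Exact ties between
    the top two scores fall into the margin band and are Unassigned, which
    makes the rule invariant to signature column order.
    """
    if score_matrix.shape[1] < 2:
        raise ValueError("need at least two signatures")
    z = (score_matrix - score_matrix.mean()) / score_matrix.std(ddof=0).replace(0, np.nan)
    vals = z.to_numpy()
    order = np.argsort(vals, axis=1)
    best = vals[np.arange(len(z)), order[:, -1]]
    second = vals[np.arange(len(z)), order[:, -2]]
    assignable = (best > 0) & (best - second > margin_z)
    cols = score_matrix.columns.to_numpy()
    labels = np.where(assignable, cols[order[:, -1]], "Unassigned")
    return pd.Series(labels, index=score_matrix.index, name="signature")


def expression_dot_summary(
    lognorm,
    gene_ids: list[str],
    genes: list[str],
    group_labels: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Per gene x group: fraction of cells expressing (> 0) and mean
    expression, both over all cells of the group and over the expressing
    cells only (both variants emitted; the all-cell mean is the default
    reading)."""
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in genes if g in index]
    missing = [g for g in genes if g not in index]
    if missing:
        warnings.warn(f"dropped absent genes: {missing}")
    labels = pd.Series(np.asarray(group_labels))
    X = lognorm[:, [index[g] for g in present]]
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    rows = []
    for g in sorted(labels.unique()):
        mask = (labels == g).to_numpy()
        sub = dense[mask]
        frac = (sub > 0).mean(axis=0) if sub.size else np.zeros(len(present))
        mean_all = sub.mean(axis=0) if sub.size else np.zeros(len(present))
        with np.errstate(invalid="ignore"):
            nexpr = (sub > 0).sum(axis=0)
            mean_expr = np.where(nexpr > 0, sub.sum(axis=0) / np.maximum(nexpr, 1), 0.0)
        for gi, gene in enumerate(present):
            rows.append(
                {
                    "gene": gene,
                    "group": g,
                    "fraction_expressing": float(frac[gi]),
                    "mean_expression": float(mean_all[gi]),
                    "mean_expression_in_expressing": float(mean_expr[gi]),
                }
            )
    return pd.DataFrame(rows)
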