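"""Four-layer nucleus quality control.

Layers, applied per sample in pipeline order:

1. fixed thresholds on UMIs, detected genes and mitochondrial fraction;
2. outlier removal against a second-degree polynomial fit of detected genes
   on log10(UMI);
3. consensus doublet voting: a pluggable scorer is run repeatedly with
   derived seeds and cells flagged in more than a fixed fraction of runs are
   removed;
4. heterotypic doublet removal: per-class marker scores are modelled as
   two-component Gaussian mixtures and cells exceeding the
   mean(lower) + 4*SD(lower) threshold for more than one class are removed.

Membership is order-independent when the layer masks are intersected; the
pipeline applies them sequentially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .synthetic import CountMatrix


@dataclass
class QCThresholds:
    min_umi: int = 500
    min_genes: int = 1200
    max_umi: int = 250_000
    max_genes: int = 15_000
    max_mito_frac: float = 0.10
    poly_degree: int = 2
    poly_residual_max: float = 2000.0
    consensus_iters: int = 100
    consensus_flag_frac: float = 0.10
    gmm_sd_mult: float = 4.0

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi or self.min_genes >= self.max_genes:
            raise ValueError("lower bounds must be below upper bounds")
        if not 0 < self.max_mito_frac <= 1 or not 0 < self.consensus_flag_frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")


@dataclass
class QCReport:
    """Per-layer keep masks and fitted parameters of a QC run."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    removal_counts: dict[str, int] = field(default_factory=dict)
    poly_coefficients: np.ndarray | None = None
    gmm_params: dict[str, dict] = field(default_factory=dict)
    flag_fractions: np.ndarray | None = None

    def record(self, layer: str, keep: np.ndarray) -> None:
        self.masks[layer] = keep
        self.removal_counts[layer] = int((~keep).sum())

    @property
    def kept(self) -> np.ndarray:
        """Cells passing every recorded layer."""
        masks = list(self.masks.values())
        out = masks[0].copy()
        for m in masks[1:]:
            out &= m
        return out


def umi_and_gene_counts(matrix: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    c = matrix.counts
    umi = np.asarray(c.sum(axis=1)).ravel()
    genes = np.asarray((c > 0).sum(axis=1)).ravel()
    return umi, genes


def basic_filters(matrix: CountMatrix, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Fixed-threshold layer; bounds inclusive, mito fraction strict at >max."""
    thresholds = thresholds or QCThresholds()
    if matrix.gene_flags is None:
        raise ValueError("gene table carries no mitochondrial flags")
    if matrix.n_cells == 0:
        return np.zeros(0, dtype=bool)
    umi, genes = umi_and_gene_counts(matrix)
    mito_umi = np.asarray(matrix.counts[:, matrix.gene_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(umi > 0, mito_umi / np.maximum(umi, 1), 0.0)
    keep = (
        (umi >= thresholds.min_umi)
        & (umi <= thresholds.max_umi)
        & (genes >= thresholds.min_genes)
        & (genes <= thresholds.max_genes)
        & (mito_frac <= thresholds.max_mito_frac)
    )
    return keep


def polynomial_outlier_filter(
    umi_per_cell: np.ndarray,
    genes_per_cell: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep cells whose detected-gene count lies within ``poly_residual_max``
    of a degree-2 least-squares fit of genes on log10(UMI).

    Returns (keep mask, polynomial coefficients highest degree first).
    """
    thresholds = thresholds or QCThresholds()
    umi = np.asarray(umi_per_cell, dtype=float)
    genes = np.asarray(genes_per_cell, dtype=float)
    if umi.size < thresholds.poly_degree + 2:
        raise ValueError("too few cells to anchor the polynomial fit")
    if (umi <= 0).any():
        raise ValueError("UMI counts must be positive for the log fit")
    lx = np.log10(umi)
    coef = np.polyfit(lx, genes, deg=thresholds.poly_degree)
    predicted = np.polyval(coef, lx)
    keep = np.abs(genes - predicted) <= thresholds.poly_residual_max
    return keep, coef


# ---------------------------------------------------------------------------
# Consensus doublet voting
# ---------------------------------------------------------------------------


def consensus_doublet_filter(
    matrix: CountMatrix,
    scorer,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``scorer(matrix, iteration_seed) -> bool array`` repeatedly and
    remove cells flagged in strictly more than ``consensus_flag_frac`` of
    runs. Returns (keep mask, per-cell flag fraction)."""
    thresholds = thresholds or QCThresholds()
    n = matrix.n_cells
    seeds = np.random.SeedSequence(seed).generate_state(thresholds.consensus_iters) % (2**31)
    votes = np.zeros(n, dtype=np.int64)
    for s in seeds:
        flags = np.asarray(scorer(matrix, int(s)), dtype=bool)
        if flags.shape != (n,):
            raise ValueError(
                f"scorer returned {flags.shape} flags for {n} cells"
            )
        votes += flags
    frac = votes / thresholds.consensus_iters
    keep = frac <= thresholds.consensus_flag_frac
    return keep, frac


def simulated_doublet_scorer(
    matrix: CountMatrix,
    seed: int,
    sim_ratio: float = 1.0,
    n_neighbors: int = 20,
    percentile: float = 95.0,
    n_projection_dims: int = 20,
) -> np.ndarray:
    """Built-in reference doublet scorer.

    Simulates ``sim_ratio * n`` synthetic doublets as random parent-pair
    sums, embeds observed and simulated cells in log1p CP10K space reduced
    by a seeded Gaussian random projection, scores each observed cell by
    the fraction of simulated doublets among its nearest neighbors, and
    flags cells above the ``percentile``-th score. A minimal stand-in
    exercising the consensus machinery; not a production doublet caller.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(matrix.counts.todense(), dtype=np.float32)
    n, g = X.shape
    n_sim = max(int(sim_ratio * n), 1)
    ii = rng.integers(0, n, size=n_sim)
    jj = rng.integers(0, n, size=n_sim)
    both = np.vstack([X, X[ii] + X[jj]])
    libs = both.sum(axis=1)
    lognorm = np.log1p(both * (1e4 / np.maximum(libs, 1))[:, None])
    proj = (rng.standard_normal((g, min(n_projection_dims, g))) / np.sqrt(g)).astype(np.float32)
    dense = lognorm @ proj
    k = min(n_neighbors, dense.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(dense)
    _, idx = nn.kneighbors(dense[:n])
    neighbor_is_sim = idx[:, 1:] >= n
    score = neighbor_is_sim.mean(axis=1)
    thr = np.percentile(score, percentile)
    return score > thr


# ---------------------------------------------------------------------------
# Marker scores and GMM heterotypic filter
# ---------------------------------------------------------------------------


def lognormalize(matrix: CountMatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """Counts-per-``target_sum`` followed by log1p."""
    libs = np.asarray(matrix.counts.sum(axis=1)).ravel()
    norm = sp.diags(target_sum / np.maximum(libs, 1)) @ matrix.counts.astype(np.float64)
    return norm.log1p().tocsr()


def marker_score(
    lognorm: sp.spmatrix,
    gene_ids: list[str],
    marker_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Mean log-normalised expression of each class's markers, per cell."""
    index = {g: i for i, g in enumerate(gene_ids)}
    scores = {}
    for cls, markers in marker_sets.items():
        present = [index[g] for g in markers if g in index]
        missing = [g for g in markers if g not in index]
        if missing:
            warnings.warn(f"{cls}: {len(missing)} marker genes absent, dropped")
        if not present:
            raise ValueError(f"class {cls!r} has no marker genes in the matrix")
        scores[cls] = np.asarray(lognorm[:, present].mean(axis=1)).ravel()
    return pd.DataFrame(scores)


def gmm_heterotypic_filter(
    score_matrix: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    min_component_weight: float = 0.01,
) -> tuple[np.ndarray, dict[str, float], dict[str, dict]]:
    """Flag cells exceeding the per-class GMM threshold for >= 2 classes.

    Per class a two-component univariate Gaussian mixture is fit by EM
    (k-means init, seeded); the class threshold is mean(lower component) +
    ``gmm_sd_mult`` * SD(lower component). Returns (keep mask, per-class
    thresholds, per-class fitted parameters).
    """
    thresholds = thresholds or QCThresholds()
    if score_matrix.shape[1] < 2:
        raise ValueError("need scores for at least two classes")
    n = score_matrix.shape[0]
    exceed = np.zeros(n, dtype=np.int64)
    cut: dict[str, float] = {}
    params: dict[str, dict] = {}
    for cls in score_matrix.columns:
        x = score_matrix[cls].to_numpy(dtype=float).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            init_params="kmeans",
            random_state=seed,
            max_iter=500,
        ).fit(x)
        if not gm.converged_:
            raise RuntimeError(f"EM did not converge for class {cls!r}")
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_.ravel()
        lower = int(np.argmin(means))
        if weights.min() < min_component_weight:
            warnings.warn(f"class {cls!r}: degenerate mixture component, skipped")
            continue
        thr = means[lower] + thresholds.gmm_sd_mult * sds[lower]
        cut[cls] = float(thr)
        params[cls] = {
            "means": means.tolist(),
            "sds": sds.tolist(),
            "weights": weights.tolist(),
            "threshold": float(thr),
        }
        exceed += (x.ravel() > thr)
    keep = exceed < 2
    return keep, cut, params


def drop_blacklist_cells(
    matrix: CountMatrix,
    blacklist: list[str],
    min_count: int = 1,
) -> np.ndarray:
    """Keep mask removing cells expressing any blacklisted gene at
    >= ``min_count`` counts (generic regional-contamination utility)."""
    idx = [i for i, g in enumerate(matrix.gene_ids) if g in set(blacklist)]
    if not idx:
        return np.ones(matrix.n_cells, dtype=bool)
    hits = np.asarray((matrix.counts[:, idx] >= min_count).sum(axis=1)).ravel()
    return hits == 0


def _subset(matrix: CountMatrix, idx: np.ndarray) -> CountMatrix:
    return CountMatrix(
        counts=matrix.counts[idx],
        cell_ids=[matrix.cell_ids[i] for i in idx],
        gene_ids=matrix.gene_ids,
        gene_flags=matrix.gene_flags,
        gene_meta=matrix.gene_meta,
    )


def run_qc(
    matrix: CountMatrix,
    marker_sets: dict[str, list[str]],
    thresholds: QCThresholds | None = None,
    scorer=simulated_doublet_scorer,
    seed: int = 0,
    sample_labels: np.ndarray | None = None,
) -> QCReport:
    """Apply the four layers sequentially and return the full report.

    With ``sample_labels`` the consensus voting and the mixture fits run
    independently per sample, mirroring per-sample QC; the fixed-threshold
    and polynomial layers are scale diagnostics and stay global.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    n = matrix.n_cells
    keep1 = basic_filters(matrix, thresholds)
    report.record("basic", keep1)

    umi, genes = umi_and_gene_counts(matrix)
    keep2 = np.zeros(n, dtype=bool)
    sub = np.flatnonzero(keep1)
    if sub.size >= thresholds.poly_degree + 2:
        k, coef = polynomial_outlier_filter(umi[sub], genes[sub], thresholds)
        keep2[sub[k]] = True
        report.poly_coefficients = coef
    else:
        keep2 = keep1.copy()
    report.record("polynomial", keep2 | ~keep1)

    if sample_labels is None:
        groups = {"all": np.arange(n)}
    else:
        labels = np.asarray(sample_labels)
        groups = {s: np.flatnonzero(labels == s) for s in pd.unique(labels)}

    keep3 = np.ones(n, dtype=bool)
    keep4 = np.ones(n, dtype=bool)
    frac = np.zeros(n)
    sample_seeds = np.random.SeedSequence(seed).generate_state(len(groups)) % (2**31)
    for (name, idx), s_seed in zip(groups.items(), sample_seeds):
        block = _subset(matrix, idx) if sample_labels is not None else matrix
        k3, f = consensus_doublet_filter(block, scorer, thresholds, seed=int(s_seed))
        keep3[idx] = k3
        frac[idx] = f
        lognorm = lognormalize(block)
        scores = marker_score(lognorm, matrix.gene_ids, marker_sets)
        k4, _, params = gmm_heterotypic_filter(scores, thresholds, seed=int(s_seed))
        keep4[idx] = k4
        report.gmm_params[str(name)] = params
    report.flag_fractions = frac
    report.record("consensus", keep3)
    report.record("gmm", keep4)
    return report
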