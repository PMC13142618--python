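"""Spatially variable gene detection on imaging-ST samples.

Spatial connectivity is a Delaunay triangulation of cell centroids; global
autocorrelation is Moran's I,

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),

with z the centered gene values and S0 the total weight. Weights are the
binary Delaunay adjacency, row-standardised by default. Significance is a
one-sided (greater) permutation test with the +1 pseudo-count formula
p = (1 + #{I_perm >= I_obs}) / (1 + n_perm), which cannot return zero at
finite permutation counts. Per-sample analysis is restricted to the gray
matter domain and to samples with a minimum number of observations; scores
are aggregated as unweighted means across retained samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError

from .synthetic import SpatialSample

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    n_nodes: int

    def weights(self, row_standardize: bool = True) -> sp.csr_matrix:
        if not row_standardize:
            return self.adjacency.astype(float)
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
        return (sp.diags(inv) @ self.adjacency).tocsr()


@dataclass
class MoranResult:
    gene: str
    sample: str
    I: float
    p: float
    n_perm: int
    n_cells: int


def delaunay_graph(coords: np.ndarray, jitter: bool = False, seed: int = 0) -> NeighborGraph:
    """Binary adjacency from the Delaunay triangulation of 2-D points.

    Duplicate or collinear points make the triangulation degenerate; with
    ``jitter`` the coordinates are perturbed by <= 0.01 um, otherwise the
    error suggests it.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if jitter:
        rng = np.random.default_rng(seed)
        pts = pts + rng.uniform(-0.01, 0.01, size=pts.shape)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(
            "degenerate point configuration (collinear or duplicate points); "
            "retry with jitter=True"
        ) from exc
    n = pts.shape[0]
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    ii, jj = zip(*edges)
    row = np.concatenate([ii, jj])
    col = np.concatenate([jj, ii])
    adj = sp.csr_matrix((np.ones(len(row)), (row, col)), shape=(n, n))
    return NeighborGraph(adjacency=adj, n_nodes=n)


def morans_i(values: np.ndarray, graph: NeighborGraph, row_standardize: bool = True) -> float:
    """Global Moran's I of ``values`` on the graph."""
    x = np.asarray(values, dtype=float)
    if x.size != graph.n_nodes:
        raise ValueError("values length must equal the number of nodes")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined")
    W = graph.weights(row_standardize)
    s0 = W.sum()
    return float(graph.n_nodes / s0 * (z @ (W @ z)) / denom)


def morans_i_permutation(
    values: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 100,
    seed: int = 0,
    row_standardize: bool = True,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Moran's I with a permutation p-value (one-sided greater by default)."""
    x = np.asarray(values, dtype=float)
    observed = morans_i(x, graph, row_standardize)
    z = x - x.mean()
    denom = float(z @ z)
    W = graph.weights(row_standardize)
    s0 = W.sum()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        i_perm = graph.n_nodes / s0 * (zp @ (W @ zp)) / denom
        if alternative == "greater":
            count += i_perm >= observed
        else:
            count += abs(i_perm) >= abs(observed)
    p = (1 + count) / (1 + n_perm)
    return observed, float(p)


def per_sample_svg(
    samples: list[SpatialSample],
    domain: str = "GM",
    min_obs: int = 50,
    n_perm: int = 100,
    seed: int = 0,
    conditions: dict[str, str] | None = None,
    top_k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample Moran's I over a domain, aggregated across samples.

    Returns (per-sample table, aggregate table with per-gene per-condition
    mean I / mean p / number of samples, top-k genes by mean I per
    condition). Samples with fewer than ``min_obs`` cells in the domain are
    skipped and logged. Genes with zero variance within a sample are
    recorded with missing I.
    """
    rows = []
    retained = 0
    seeds = np.random.SeedSequence(seed).generate_state(max(len(samples), 1)) % (2**31)
    for si, sample in enumerate(samples):
        mask = sample.domain == domain
        n = int(mask.sum())
        if n < min_obs:
            logger.info("sample %s skipped: %d %s cells < %d",
                        sample.sample_id, n, domain, min_obs)
            continue
        retained += 1
        coords = np.column_stack([sample.x_um[mask], sample.y_um[mask]])
        graph = delaunay_graph(coords)
        cond = (conditions or {}).get(sample.sample_id, "all")
        gene_seeds = np.random.SeedSequence(int(seeds[si])).generate_state(
            len(sample.panel_genes)
        ) % (2**31)
        for gi, gene in enumerate(sample.panel_genes):
            vals = sample.panel_counts[mask, gi].astype(float)
            if vals.std() == 0:
                rows.append({"sample": sample.sample_id, "condition": cond,
                             "gene": gene, "I": np.nan, "p": np.nan, "n_cells": n})
                continue
            i_obs, p = morans_i_permutation(
                vals, graph, n_perm=n_perm, seed=int(gene_seeds[gi])
            )
            rows.append({"sample": sample.sample_id, "condition": cond,
                         "gene": gene, "I": i_obs, "p": p, "n_cells": n})
    if retained == 0:
        raise ValueError(f"no sample retains >= {min_obs} cells in domain {domain!r}")
    per_sample = pd.DataFrame(rows)
    agg = (
        per_sample.groupby(["condition", "gene"])
        .agg(mean_I=("I", "mean"), mean_p=("p", "mean"), n_samples=("I", "count"))
        .reset_index()
    )
    top = (
        agg.sort_values(["condition", "mean_I"], ascending=[True, False])
        .groupby("condition")
        .head(top_k)
        .reset_index(drop=True)
    )
    return per_sample, agg, top
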