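"""Donor classification into multicellular program groups.

Two rules are implemented. The hierarchical astrocyte rule classifies a
sample as UPR-high when AR1 astrocytes exceed 10% of the astrocyte
composition (after excluding ventricle-specific SVZCs from the
denominator), otherwise Reactive when AR2 exceeds 10%, otherwise
Homeostatic. The four-way microglia rule classifies a donor by the
fractions of M1-like and UPR-like cells: Reactive (>10% M1), UPR-high
(>10% UPR), Homeostatic (both <=10%), or Mixed (both >10%). All threshold
comparisons are strict; boundary equality falls to the lower branch.

The module also provides the mixed-rate and cross-region-consistency
statistics and a sample-to-sample divergence matrix estimated with a
k-nearest-neighbor (k=6) Kullback-Leibler estimator on per-cell latent
coordinates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import NearestNeighbors


@dataclass
class StratificationRule:
    """Hierarchical threshold rule over subpopulation fractions."""

    primary_subpop: str = "AR1"
    primary_threshold: float = 0.10
    secondary_subpop: str = "AR2"
    secondary_threshold: float = 0.10
    excluded_subpops: tuple[str, ...] = ("SVZC",)
    labels: tuple[str, str, str] = ("UPR", "Reactive", "Homeostatic")

    def __post_init__(self) -> None:
        if not (0 < self.primary_threshold < 1 and 0 < self.secondary_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if {self.primary_subpop, self.secondary_subpop} & set(self.excluded_subpops):
            raise ValueError("excluded subpopulations overlap the rule subpopulations")


def astro_stratify(
    compositions: pd.DataFrame,
    rule: StratificationRule | None = None,
) -> pd.DataFrame:
    """Apply the hierarchical rule to per-sample astrocyte compositions.

    ``compositions`` rows are samples, columns astrocyte subtypes, values
    cell counts (or proportions). Excluded subtypes are removed from the
    denominator before fractions are computed. Samples with an empty
    denominator are labeled ``Unassigned`` with a warning.
    """
    rule = rule or StratificationRule()
    cols = [c for c in compositions.columns if c not in rule.excluded_subpops]
    denom = compositions[cols].sum(axis=1)
    frac_primary = compositions.get(rule.primary_subpop, 0) / denom.replace(0, np.nan)
    frac_secondary = compositions.get(rule.secondary_subpop, 0) / denom.replace(0, np.nan)
    labels = np.where(
        frac_primary > rule.primary_threshold,
        rule.labels[0],
        np.where(frac_secondary > rule.secondary_threshold, rule.labels[1], rule.labels[2]),
    ).astype(object)
    empty = denom == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} sample(s) without astrocytes left Unassigned")
        labels[empty.to_numpy()] = "Unassigned"
    return pd.DataFrame(
        {
            "label": labels,
            f"frac_{rule.primary_subpop}": frac_primary,
            f"frac_{rule.secondary_subpop}": frac_secondary,
            "rule": "astro_hierarchical",
        },
        index=compositions.index,
    )


def fourway_stratify(
    m1_fraction: pd.Series | np.ndarray,
    upr_fraction: pd.Series | np.ndarray,
    threshold: float = 0.10,
) -> pd.Series:
    """Quadrant rule on microglial program fractions (strict inequalities)."""
    m1 = pd.Series(m1_fraction)
    upr = pd.Series(np.asarray(upr_fraction), index=m1.index)
    if ((m1 < 0) | (m1 > 1) | (upr < 0) | (upr > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    labels = np.where(
        (m1 > threshold) & (upr > threshold),
        "Mixed",
        np.where(
            m1 > threshold,
            "Reactive",
            np.where(upr > threshold, "UPR-high", "Homeostatic"),
        ),
    )
    return pd.Series(labels, index=m1.index, name="label")


def mixed_rate(assignments: pd.Series | pd.DataFrame) -> tuple[float, int, int]:
    """Fraction of donors labeled Mixed; returns (rate, count, denominator)."""
    labels = assignments["label"] if isinstance(assignments, pd.DataFrame) else assignments
    if len(labels) == 0:
        raise ValueError("no assignments")
    count = int((labels == "Mixed").sum())
    return count / len(labels), count, len(labels)


def cross_region_consistency(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-donor modal label and region agreement.

    ``assignments`` carries columns (donor_id, region, label). Agreement is
    the fraction of a donor's regions matching its modal label; modal ties
    break toward non-Homeostatic labels, then lexicographically.
    """
    if assignments.groupby("donor_id")["region"].nunique().max() < 2:
        raise ValueError("need at least one donor observed in >= 2 regions")
    rows = []
    for donor, grp in assignments.groupby("donor_id"):
        counts = Counter(grp["label"])
        top = max(counts.values())
        candidates = sorted(
            [lab for lab, c in counts.items() if c == top],
            key=lambda lab: (lab == "Homeostatic", lab),
        )
        modal = candidates[0]
        rows.append(
            {
                "donor_id": donor,
                "modal_label": modal,
                "agreement": counts[modal] / len(grp),
                "n_regions": len(grp),
            }
        )
    return pd.DataFrame(rows).set_index("donor_id")


# ---------------------------------------------------------------------------
# Sample-level divergence
# ---------------------------------------------------------------------------


def _knn_kl(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """kNN Kullback-Leibler divergence estimate D(A || B).

    Wang-Kulkarni-Verdu estimator: (d/n) * sum log(nu_k / rho_k) +
    log(m / (n - 1)) with rho_k the k-th neighbor radius within A
    (excluding self) and nu_k the k-th neighbor radius from A into B.
    """
    n, d = a.shape
    m = b.shape[0]
    rho = NearestNeighbors(n_neighbors=k + 1).fit(a).kneighbors(a)[0][:, -1]
    nu = NearestNeighbors(n_neighbors=k).fit(b).kneighbors(a)[0][:, -1]
    eps = 1e-12
    return float(d * np.mean(np.log((nu + eps) / (rho + eps))) + np.log(m / (n - 1)))


@dataclass
class DivergenceMatrix:
    distances: pd.DataFrame
    k: int
    cell_counts: pd.Series = field(default_factory=pd.Series)


def sample_divergence_matrix(
    coords: np.ndarray | pd.DataFrame,
    sample_labels: pd.Series | np.ndarray,
    k: int = 6,
    min_cells: int = 500,
) -> DivergenceMatrix:
    """Symmetrized kNN-KL divergence between per-sample cell distributions
    in a latent space.

    Samples with fewer than ``min_cells`` cells are dropped; ``k`` must be
    below every retained sample's cell count. The result is
    (d(A,B) + d(B,A)) / 2 clipped below at zero, with zero diagonal.
    """
    X = np.asarray(coords, dtype=float)
    labels = pd.Series(np.asarray(sample_labels))
    counts = labels.value_counts()
    kept = sorted(counts[counts >= min_cells].index)
    if not kept:
        raise ValueError("no sample passes the minimum-cell filter")
    for s in kept:
        if k >= counts[s]:
            raise ValueError(f"k={k} >= cells in sample {s!r}")
    groups = {s: X[(labels == s).to_numpy()] for s in kept}
    n = len(kept)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 0.5 * (_knn_kl(groups[kept[i]], groups[kept[j]], k)
                       + _knn_kl(groups[kept[j]], groups[kept[i]], k))
            mat[i, j] = mat[j, i] = max(d, 0.0)
    return DivergenceMatrix(
        distances=pd.DataFrame(mat, index=kept, columns=kept),
        k=k,
        cell_counts=counts.loc[kept],
    )


def group_samples(divergence: DivergenceMatrix, n_groups: int) -> pd.Series:
    """Generic agglomerative grouping of the divergence matrix (average
    linkage on the precomputed distances); any community-detection backend
    can be substituted."""
    model = AgglomerativeClustering(
        n_clusters=n_groups, metric="precomputed", linkage="average"
    )
    labels = model.fit_predict(divergence.distances.to_numpy())
    return pd.Series(labels, index=divergence.distances.index, name="group")
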