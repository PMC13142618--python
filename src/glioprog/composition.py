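"""Subject-level compositional analysis of glial subpopulations.

Single-cell compositions are constrained to sum to one, so raw proportions
are compared only after a centered log-ratio (CLR) transformation:

    clr_ij = ln((c_ij + pc) / g_j(c_ij + pc)),

with ``pc`` a pseudocount of 1 and ``g_j`` the geometric mean over the
sample's subpopulation counts. Condition contrasts use the Mann-Whitney U
test on CLR values, Braak-stage profiles average subject-level CLR within
stage, and pathology correlations are Spearman rank correlations against
Lewy-body densities after a minimum-nuclei filter.

Region (Pu / CN) is always an analysis stratum; the two regions are never
pooled into one sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CompositionTable:
    """Per-sample subpopulation cell counts with proportions and metadata.

    Rows index samples (donor x region); ``meta`` carries the join keys
    (donor_id, region, condition, braak_stage, sex) aligned on the same
    index.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        props = self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
        return props


def sample_compositions(
    annotations: pd.DataFrame,
    level: str = "subpopulation",
    within: str | None = None,
    sample_keys: tuple[str, ...] = ("donor_id", "region"),
) -> CompositionTable:
    """Count cells per sample x category.

    ``within`` restricts both numerator and denominator to one parent cell
    class (e.g. astrocyte subtypes only). Samples present in the metadata but
    empty after restriction are retained as zero rows with a warning.
    """
    if level not in annotations.columns:
        raise ValueError(f"unknown annotation level {level!r}")
    ann = annotations
    if within is not None:
        ann = ann[ann["cell_class"] == within]
    counts = (
        ann.groupby([*sample_keys, level], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    all_samples = annotations.groupby(list(sample_keys), observed=True).size().index
    counts = counts.reindex(all_samples, fill_value=0)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} sample(s) have no cells at this level")
    meta_cols = [
        c for c in ("donor_id", "region", "condition", "braak_stage", "sex")
        if c in annotations.columns
    ]
    meta = (
        annotations.groupby(list(sample_keys), observed=True)[meta_cols]
        .first()
        .reindex(counts.index)
    )
    return CompositionTable(counts=counts, meta=meta)


def clr_transform(table: CompositionTable | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of per-sample counts (natural log).

    Every output row sums to zero. With pseudocount 0 the transform is only
    defined on strictly positive rows, where it is invariant to scaling a
    row's counts by a positive constant.
    """
    counts = table.counts if isinstance(table, CompositionTable) else table
    x = counts.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("counts + pseudocount must be positive")
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def compare_conditions(
    clr: pd.DataFrame,
    group_labels: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per subpopulation between two groups of
    samples, with BH adjustment across subpopulations.

    Exact enumeration is used when both groups have at most ``exact_max_n``
    samples and the values are untied; otherwise the normal approximation
    with mid-ranks and tie correction.
    """
    labels = group_labels.reindex(clr.index)
    groups = [g for g in labels.dropna().unique()]
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError("group_labels must define exactly two groups")
        group_a, group_b = sorted(map(str, groups))
    a_idx = labels == group_a
    b_idx = labels == group_b
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for subpop in clr.columns:
        a = clr.loc[a_idx, subpop].to_numpy()
        b = clr.loc[b_idx, subpop].to_numpy()
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "subpopulation": subpop,
                "U": float(res.statistic),
                "p": float(min(res.pvalue, 1.0)),
                "median_diff": float(np.median(a) - np.median(b)),
                "direction": f"up_in_{group_a}" if np.median(a) > np.median(b) else f"up_in_{group_b}",
                "n_a": int(a.size),
                "n_b": int(b.size),
            }
        )
    out = pd.DataFrame(rows).set_index("subpopulation")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def braak_stage_profile(
    clr: pd.DataFrame,
    stages: pd.Series,
    min_subjects: int = 2,
    zscore: bool = False,
) -> pd.DataFrame:
    """Mean subject-level CLR per Braak LB stage (subpopulation x stage).

    Stage cells backed by fewer than ``min_subjects`` subjects are missing.
    With ``zscore`` each subpopulation row is standardised across its
    non-missing stages.
    """
    stages = stages.reindex(clr.index)
    grouped = clr.groupby(stages)
    means = grouped.mean()
    ns = grouped.size()
    means[ns < min_subjects] = np.nan
    profile = means.T  # subpopulation x stage
    profile.columns.name = "braak_stage"
    if zscore:
        mu = profile.mean(axis=1)
        sd = profile.std(axis=1, ddof=0)
        profile = profile.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return profile


def abundance_correlation(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between subpopulation
    abundances across samples (symmetric, unit diagonal)."""
    if values.shape[0] < 3:
        raise ValueError("need at least three samples")
    sd = values.std(ddof=0)
    degenerate = sd[sd == 0].index
    if len(degenerate):
        warnings.warn(
            f"zero-variance columns set to missing: {list(degenerate)}"
        )
    corr = values.corr(method="pearson")
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    for c in degenerate:
        corr.loc[c, c] = np.nan
    return corr


def pathology_correlation(
    annotations: pd.DataFrame,
    lb_density: pd.DataFrame,
    subpopulations: list[str] | None = None,
    min_cells: int = 50,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Spearman correlation of CLR subpopulation abundance vs Lewy-body
    density, per region.

    ``lb_density`` has columns (donor_id, region, lb_density). Donors
    contributing fewer than ``min_cells`` nuclei in a region are excluded
    before the CLR; fewer than three remaining donors in a region is an
    error.
    """
    rows = []
    for region, ann_r in annotations.groupby("region", observed=True):
        totals = ann_r.groupby("donor_id", observed=True).size()
        keep_donors = totals[totals >= min_cells].index
        ann_r = ann_r[ann_r["donor_id"].isin(keep_donors)]
        dens = lb_density[lb_density["region"] == region].set_index("donor_id")["lb_density"]
        donors = sorted(set(ann_r["donor_id"]) & set(dens.index))
        if len(donors) < 3:
            raise ValueError(
                f"region {region!r}: fewer than 3 donors after the "
                f">= {min_cells}-nuclei filter"
            )
        comp = (
            ann_r[ann_r["donor_id"].isin(donors)]
            .groupby(["donor_id", "subpopulation"], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(donors)
        )
        clr = clr_transform(comp, pseudocount=pseudocount)
        cols = subpopulations if subpopulations is not None else list(clr.columns)
        for subpop in cols:
            if subpop not in clr.columns:
                continue
            rho, p = stats.spearmanr(clr[subpop], dens.reindex(donors))
            rows.append(
                {
                    "region": region,
                    "subpopulation": subpop,
                    "rho": float(rho),
                    "p": float(p),
                    "n_donors": len(donors),
                }
            )
    return pd.DataFrame(rows)
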