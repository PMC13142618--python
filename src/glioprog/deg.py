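"""Wilcoxon differential expression and the tier / overlap logic.

Per-gene statistics for one two-group contrast: two-sided Wilcoxon
rank-sum with tie correction (exact enumeration for small untied groups),
log2 fold change of de-logged group means (epsilon 1e-9), the expressing
fraction ``pts`` in the test group, and BH adjustment across genes.

Significant DEGs satisfy p_adj < 0.05, pts > 0.1 and |LFC| >= 0.25 and are
partitioned into four magnitude tiers: Tier 1 (|LFC| >= 2.0), Tier 2
([1.0, 2.0)), Tier 3 ([0.5, 1.0)), Tier 4 ([0.25, 0.5)).

Overlap logic follows a dual-threshold strategy: the candidate universe is
every gene passing a strict threshold (default |LFC| >= 1.0, p_adj < 0.05)
in at least one comparison; its presence elsewhere is evaluated at a
relaxed threshold (0.5 for the three-way Venn, 0.25 across cell types) and
requires sign concordance with the strict occurrence. Clone-derived and
non-coding identifiers (AC/AL/AP/AF followed by a digit, or the LINC
prefix) are filtered out first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

NONCODING_RE = re.compile(r"^(?:(?:AC|AL|AP|AF)\d|LINC)")


@dataclass
class TierThresholds:
    tier1_lfc: float = 2.0
    tier2_lfc: float = 1.0
    tier3_lfc: float = 0.5
    tier4_lfc: float = 0.25
    p_adj_max: float = 0.05
    pts_min: float = 0.1

    def __post_init__(self) -> None:
        if not self.tier1_lfc > self.tier2_lfc > self.tier3_lfc > self.tier4_lfc > 0:
            raise ValueError("tier boundaries must be strictly decreasing and positive")


@dataclass
class OverlapSpec:
    strict_lfc: float = 1.0
    relaxed_lfc: float = 0.5
    p_adj_max: float = 0.05
    direction_consistent: bool = True
    min_intersection_display: int = 10

    def __post_init__(self) -> None:
        if self.relaxed_lfc > self.strict_lfc:
            raise ValueError("relaxed_lfc must not exceed strict_lfc")


def wilcoxon_de(
    lognorm,
    gene_ids: list[str],
    labels: pd.Series | np.ndarray,
    group: str,
    reference: str,
    eps: float = 1e-9,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum of ``group`` vs ``reference``.

    LFC = log2((mean expm1 in group + eps) / (mean expm1 in reference +
    eps)); ``pts`` is the expressing fraction in the test group (pts_ref is
    also reported). Exact p-values are used when both groups have at most
    ``exact_max_n`` cells, otherwise the tie-corrected normal
    approximation.
    """
    labels = pd.Series(np.asarray(labels))
    ga = (labels == group).to_numpy()
    gb = (labels == reference).to_numpy()
    n_a, n_b = int(ga.sum()), int(gb.sum())
    if n_a < 3 or n_b < 3:
        raise ValueError("both groups need at least 3 cells")
    X = lognorm
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    A, B = dense[ga], dense[gb]
    method = "exact" if max(n_a, n_b) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(A, B, alternative="two-sided", method=method, axis=0)
    pvals = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    lfc = np.log2((mean_a + eps) / (mean_b + eps))
    out = pd.DataFrame(
        {
            "statistic": np.asarray(res.statistic, dtype=float),
            "lfc": lfc,
            "p": pvals,
            "pts": (A > 0).mean(axis=0),
            "pts_ref": (B > 0).mean(axis=0),
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["lfc"] >= 0, "up", "down")
    out.attrs["contrast"] = {"group": group, "reference": reference,
                             "n_group": n_a, "n_reference": n_b, "eps": eps}
    return out


def assign_tier(abs_lfc: np.ndarray, thresholds: TierThresholds) -> np.ndarray:
    tiers = np.full(len(abs_lfc), "", dtype=object)
    tiers[abs_lfc >= thresholds.tier4_lfc] = "Tier 4"
    tiers[abs_lfc >= thresholds.tier3_lfc] = "Tier 3"
    tiers[abs_lfc >= thresholds.tier2_lfc] = "Tier 2"
    tiers[abs_lfc >= thresholds.tier1_lfc] = "Tier 1"
    return tiers


def significant_degs(
    table: pd.DataFrame,
    thresholds: TierThresholds | None = None,
) -> pd.DataFrame:
    """Filter to significant DEGs and attach magnitude tiers."""
    thresholds = thresholds or TierThresholds()
    abs_lfc = table["lfc"].abs()
    keep = (
        (table["p_adj"] < thresholds.p_adj_max)
        & (table["pts"] > thresholds.pts_min)
        & (abs_lfc >= thresholds.tier4_lfc)
    )
    out = table[keep].copy()
    out["tier"] = assign_tier(out["lfc"].abs().to_numpy(), thresholds)
    return out


def filter_noncoding(gene_ids) -> list[str]:
    """Drop clone-based / non-coding gene identifiers.

    AC, AL, AP, AF followed immediately by a digit (clone-derived names like
    AC012345.1) and any LINC-prefixed id are removed; symbols like ACTB or
    ALDH1L1 are kept. Case-sensitive.
    """
    return [g for g in gene_ids if not NONCODING_RE.match(g)]


def _passes(table: pd.DataFrame, gene: str, lfc_min: float, p_adj_max: float) -> bool:
    if gene not in table.index:
        return False
    row = table.loc[gene]
    return bool(abs(row["lfc"]) >= lfc_min and row["p_adj"] < p_adj_max)


def dual_threshold_overlap(
    tables: dict[str, pd.DataFrame],
    spec: OverlapSpec | None = None,
) -> pd.DataFrame:
    """Three-set Venn membership under the strict/relaxed dual threshold.

    Returns one row per universe gene with boolean presence per comparison,
    the assigned Venn region, and the strict LFC sign. Genes whose strict
    occurrences disagree in sign are excluded and reported with region
    ``sign_conflict``.
    """
    spec = spec or OverlapSpec()
    if len(tables) != 3:
        raise ValueError("Venn mode requires exactly three comparisons")
    names = list(tables)
    clean = {
        name: t.loc[[g for g in filter_noncoding(t.index)]] for name, t in tables.items()
    }
    universe: dict[str, list[str]] = {}
    for name, t in clean.items():
        strict = t[(t["lfc"].abs() >= spec.strict_lfc) & (t["p_adj"] < spec.p_adj_max)]
        for g in strict.index:
            universe.setdefault(g, []).append(name)
    rows = []
    for gene, strict_in in sorted(universe.items()):
        signs = {np.sign(clean[name].loc[gene, "lfc"]) for name in strict_in}
        if len(signs) > 1:
            rows.append({"gene": gene, **{n: False for n in names},
                         "region": "sign_conflict", "sign": 0})
            continue
        sign = signs.pop()
        present = {}
        for name in names:
            if name in strict_in:
                present[name] = True
                continue
            t = clean[name]
            ok = _passes(t, gene, spec.relaxed_lfc, spec.p_adj_max)
            if ok and spec.direction_consistent:
                ok = np.sign(t.loc[gene, "lfc"]) == sign
            present[name] = bool(ok)
        region = "&".join(n for n in names if present[n])
        rows.append({"gene": gene, **present, "region": region, "sign": int(sign)})
    return pd.DataFrame(rows).set_index("gene")


def cross_celltype_intersections(
    tables: dict[str, pd.DataFrame],
    spec: OverlapSpec | None = None,
) -> pd.DataFrame:
    """UpSet-style intersection sizes of one comparison's DEGs across cell
    types, split by direction.

    Uses the same strict/relaxed logic with the relaxed LFC defaulting to
    0.25; every non-empty presence pattern is emitted with a
    ``displayable`` flag marking intersections of more than
    ``min_intersection_display`` genes.
    """
    spec = spec or OverlapSpec(relaxed_lfc=0.25)
    if len(tables) < 2:
        raise ValueError("need at least two cell types")
    names = list(tables)
    clean = {
        name: t.loc[[g for g in filter_noncoding(t.index)]] for name, t in tables.items()
    }
    membership: dict[tuple[str, int], list[str]] = {}
    genes: dict[str, list[str]] = {}
    for name, t in clean.items():
        strict = t[(t["lfc"].abs() >= spec.strict_lfc) & (t["p_adj"] < spec.p_adj_max)]
        for g in strict.index:
            genes.setdefault(g, []).append(name)
    rows = []
    patterns: dict[tuple[str, ...], dict[str, int]] = {}
    for gene, strict_in in genes.items():
        signs = {np.sign(clean[n].loc[gene, "lfc"]) for n in strict_in}
        if len(signs) > 1:
            continue
        sign = signs.pop()
        present = []
        for name in names:
            if name in strict_in:
                present.append(name)
                continue
            t = clean[name]
            ok = _passes(t, gene, spec.relaxed_lfc, spec.p_adj_max)
            if ok and spec.direction_consistent:
                ok = np.sign(t.loc[gene, "lfc"]) == sign
            if ok:
                present.append(name)
        key = tuple(present)
        entry = patterns.setdefault(key, {"up": 0, "down": 0})
        entry["up" if sign > 0 else "down"] += 1
    for key, counts in sorted(patterns.items()):
        total = counts["up"] + counts["down"]
        rows.append(
            {
                "cell_types": "&".join(key),
                "degree": len(key),
                "n_up": counts["up"],
                "n_down": counts["down"],
                "n_total": total,
                "displayable": total > spec.min_intersection_display,
            }
        )
    return pd.DataFrame(rows)
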