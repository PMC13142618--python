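"""Differential expression, tiers, noncoding filtering, overlap logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioprog.deg import (
    OverlapSpec,
    TierThresholds,
    assign_tier,
    cross_celltype_intersections,
    dual_threshold_overlap,
    filter_noncoding,
    significant_degs,
    wilcoxon_de,
)


class TestWilcoxonDE:
    def test_identical_groups(self, rng):
        X = rng.poisson(3.0, size=(10, 20)).astype(float)
        X = np.vstack([X, X])
        labels = np.repeat(["a", "b"], 10)
        out = wilcoxon_de(np.log1p(X), [f"g{i}" for i in range(20)], labels, "a", "b")
        assert (out["p"] == 1.0).all()
        np.testing.assert_allclose(out["lfc"], 0.0, atol=1e-12)

    def test_exact_four_vs_four_enumeration(self):
        """{5,6,7,8} vs {1,2,3,4}: two-sided exact p = 2/70."""
        col = np.array([5.0, 6, 7, 8, 1, 2, 3, 4]).reshape(-1, 1)
        labels = np.repeat(["hi", "lo"], 4)
        out = wilcoxon_de(col, ["g0"], labels, "hi", "lo")
        assert out.loc["g0", "p"] == pytest.approx(2 / 70)
        assert out.loc["g0", "lfc"] > 0

    def test_pts_is_test_group_prevalence(self):
        X = np.array(
            [[1.0], [1.0], [0.0], [0.0],  # group a: 50% expressing
             [1.0], [0.0], [0.0], [0.0]]  # group b: 25%
        )
        labels = np.repeat(["a", "b"], 4)
        out = wilcoxon_de(X, ["g0"], labels, "a", "b")
        assert out.loc["g0", "pts"] == pytest.approx(0.5)
        assert out.loc["g0", "pts_ref"] == pytest.approx(0.25)

    def test_monotone_transform_preserves_p(self, rng):
        """Rank-test p-values are invariant to strictly monotone per-gene
        transforms (not the LFC)."""
        X = rng.gamma(2.0, 1.0, size=(60, 5))
        labels = rng.permutation(np.repeat(["a", "b"], 30))
        genes = [f"g{i}" for i in range(5)]
        p1 = wilcoxon_de(X, genes, labels, "a", "b")["p"]
        p2 = wilcoxon_de(np.sqrt(X) + 3, genes, labels, "a", "b")["p"]
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), rtol=1e-9)

    def test_group_too_small(self):
        with pytest.raises(ValueError, match="at least 3"):
            wilcoxon_de(np.ones((4, 2)), ["a", "b"], ["x", "x", "y", "y"], "x", "y")


class TestTiers:
    @pytest.mark.parametrize(
        "lfc,tier",
        [(2.0, "Tier 1"), (3.5, "Tier 1"), (1.0, "Tier 2"), (1.99, "Tier 2"),
         (0.9, "Tier 3"), (0.5, "Tier 3"), (0.25, "Tier 4"), (0.49, "Tier 4")],
    )
    def test_boundaries(self, lfc, tier):
        table = pd.DataFrame(
            {"lfc": [lfc], "p_adj": [0.01], "pts": [0.5], "p": [0.001]},
            index=pd.Index(["g"], name="gene"),
        )
        out = significant_degs(table)
        assert out.loc["g", "tier"] == tier

    def test_below_floor_excluded(self):
        table = pd.DataFrame(
            {"lfc": [0.2, -0.2], "p_adj": [1e-10, 1e-10], "pts": [0.9, 0.9],
             "p": [1e-12, 1e-12]},
            index=pd.Index(["g1", "g2"], name="gene"),
        )
        assert significant_degs(table).empty

    def test_prevalence_and_significance_gates(self):
        table = pd.DataFrame(
            {"lfc": [1.5, 1.5, 1.5], "p_adj": [0.04, 0.06, 0.04],
             "pts": [0.5, 0.5, 0.1], "p": [0.01] * 3},
            index=pd.Index(["keep", "p_fail", "pts_fail"], name="gene"),
        )
        out = significant_degs(table)
        assert list(out.index) == ["keep"]

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=0.25, max_value=10.0, allow_nan=False))
    def test_tiers_partition_significant_range(self, abs_lfc):
        """Every |LFC| >= 0.25 maps to exactly one tier."""
        tier = assign_tier(np.array([abs_lfc]), TierThresholds())[0]
        assert tier in {"Tier 1", "Tier 2", "Tier 3", "Tier 4"}


class TestNoncodingFilter:
    def test_clone_ids_removed_symbols_kept(self):
        """Regex behavior vs a hand-built list of clone-based and symbol
        identifiers."""
        kept = filter_noncoding(
            ["AC012345.1", "ACTB", "AL627309.1", "ALDH1L1", "AP006222.2",
             "APOE", "AF127936.1", "AFM", "LINC00507", "GFAP", "LINCMD1"]
        )
        assert kept == ["ACTB", "ALDH1L1", "APOE", "AFM", "GFAP"]

    def test_case_sensitive(self):
        assert filter_noncoding(["linc00507", "Ac012345.1"]) == ["linc00507", "Ac012345.1"]


def _table(entries):
    """entries: gene -> (lfc, p_adj)"""
    genes = list(entries)
    return pd.DataFrame(
        {
            "lfc": [entries[g][0] for g in genes],
            "p_adj": [entries[g][1] for g in genes],
            "p": [entries[g][1] / 2 for g in genes],
            "pts": 0.5,
        },
        index=pd.Index(genes, name="gene"),
    )


class TestDualThresholdOverlap:
    def test_strict_plus_relaxed_intersection(self):
        tables = {
            "UPR": _table({"G1": (1.2, 0.01), "G2": (0.1, 0.9)}),
            "PD": _table({"G1": (0.6, 0.01), "G2": (0.1, 0.9)}),
            "Reactive": _table({"G1": (0.1, 0.9), "G2": (0.1, 0.9)}),
        }
        out = dual_threshold_overlap(tables, OverlapSpec(relaxed_lfc=0.5))
        assert out.loc["G1", "region"] == "UPR&PD"

    def test_direction_inconsistent_not_shared(self):
        tables = {
            "UPR": _table({"G1": (1.2, 0.01)}),
            "PD": _table({"G1": (-0.8, 0.01)}),
            "Reactive": _table({"G1": (0.0, 1.0)}),
        }
        out = dual_threshold_overlap(tables, OverlapSpec(relaxed_lfc=0.5))
        assert out.loc["G1", "region"] == "UPR"

    def test_sign_conflict_between_strict_occurrences_excluded(self):
        tables = {
            "UPR": _table({"G1": (1.5, 0.01)}),
            "PD": _table({"G1": (-1.5, 0.01)}),
            "Reactive": _table({"G1": (0.0, 1.0)}),
        }
        out = dual_threshold_overlap(tables)
        assert out.loc["G1", "region"] == "sign_conflict"

    def test_noncoding_filtered_before_overlap(self):
        tables = {
            "UPR": _table({"AC099999.1": (2.0, 0.001), "GFAP": (1.5, 0.001)}),
            "PD": _table({"AC099999.1": (2.0, 0.001), "GFAP": (0.0, 1.0)}),
            "Reactive": _table({"GFAP": (0.0, 1.0)}),
        }
        out = dual_threshold_overlap(tables)
        assert "AC099999.1" not in out.index
        assert list(out.index) == ["GFAP"]

    def test_regions_partition_universe(self, rng):
        """Venn regions are disjoint and exhaustive: each universe gene has
        exactly one region."""
        genes = [f"G{i}" for i in range(40)]
        tables = {
            name: _table(
                {g: (float(rng.normal(0, 1.2)), float(rng.uniform(0, 0.2)))
                 for g in genes}
            )
            for name in ("A", "B", "C")
        }
        out = dual_threshold_overlap(tables)
        valid = out[out["region"] != "sign_conflict"]
        assert (valid["region"] != "").all()
        # region string is consistent with the presence booleans
        for gene, row in valid.iterrows():
            members = [n for n in ("A", "B", "C") if row[n]]
            assert row["region"] == "&".join(members)

    def test_requires_three_tables(self):
        with pytest.raises(ValueError):
            dual_threshold_overlap({"A": _table({}), "B": _table({})})


class TestCrossCelltype:
    def test_identical_tables_full_intersection(self):
        t = _table({"G1": (1.5, 0.01), "G2": (-2.0, 0.001), "G3": (0.1, 0.9)})
        out = cross_celltype_intersections({"astro": t, "micro": t.copy()})
        full = out[out["cell_types"] == "astro&micro"]
        assert full["n_total"].iloc[0] == 2
        assert full["n_up"].iloc[0] == 1 and full["n_down"].iloc[0] == 1

    def test_disjoint_strict_sets_singletons_only(self):
        ta = _table({"G1": (1.5, 0.01), "G2": (0.0, 1.0)})
        tb = _table({"G1": (0.0, 1.0), "G2": (1.5, 0.01)})
        out = cross_celltype_intersections({"a": ta, "b": tb})
        assert set(out["cell_types"]) == {"a", "b"}

    def test_matches_bruteforce_oracle(self, rng):
        """Exhaustive set arithmetic on a 30-gene toy input."""
        genes = [f"G{i}" for i in range(30)]
        cell_types = ["astro", "micro", "oligo"]
        tables = {
            ct: _table(
                {g: (float(rng.normal(0, 1.0)), float(rng.uniform(0, 0.15)))
                 for g in genes}
            )
            for ct in cell_types
        }
        spec = OverlapSpec(relaxed_lfc=0.25)
        out = cross_celltype_intersections(tables, spec)

        # brute force: for each gene decide its pattern independently
        expected: dict[tuple, dict] = {}
        for g in genes:
            strict_in = [
                ct for ct in cell_types
                if abs(tables[ct].loc[g, "lfc"]) >= 1.0
                and tables[ct].loc[g, "p_adj"] < 0.05
            ]
            if not strict_in:
                continue
            signs = {np.sign(tables[ct].loc[g, "lfc"]) for ct in strict_in}
            if len(signs) > 1:
                continue
            sign = signs.pop()
            present = tuple(
                ct for ct in cell_types
                if ct in strict_in
                or (
                    abs(tables[ct].loc[g, "lfc"]) >= 0.25
                    and tables[ct].loc[g, "p_adj"] < 0.05
                    and np.sign(tables[ct].loc[g, "lfc"]) == sign
                )
            )
            e = expected.setdefault(present, {"up": 0, "down": 0})
            e["up" if sign > 0 else "down"] += 1
        got = {
            tuple(r["cell_types"].split("&")): (r["n_up"], r["n_down"])
            for _, r in out.iterrows()
        }
        assert got == {k: (v["up"], v["down"]) for k, v in expected.items()}

    def test_displayable_flag_strictly_more_than_ten(self):
        entries = {f"G{i}": (1.5, 0.01) for i in range(10)}
        t = _table(entries)
        out = cross_celltype_intersections({"a": t, "b": t.copy()})
        assert not out["displayable"].iloc[0]  # exactly 10 is not "> 10"
        entries["G10"] = (1.5, 0.01)
        t = _table(entries)
        out = cross_celltype_intersections({"a": t, "b": t.copy()})
        assert out[out["n_total"] == 11]["displayable"].iloc[0]
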