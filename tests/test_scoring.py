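"""Occupancy scores, polymerase classes, correlations, activator summaries."""

import numpy as np
import pandas as pd
import pytest

from snapcall import scoring
from snapcall.tag_model import make_tags


def spearman_oracle(x, y):
    """Rank (average ties) then Pearson, from first principles."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), float)
        i = 0
        sv = np.asarray(v, float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return np.nan if denom == 0 else float((rx * ry).sum() / denom)


def _tags(starts, times=None, matches=None):
    n = len(starts)
    return make_tags(chrom=["chr1"] * n, start=list(starts),
                     end=[s + 36 for s in starts], strand=["+"] * n,
                     times_sequenced=times or [1] * n,
                     n_matches=matches or [1] * n)


class TestRegionScore:
    def test_unique_tags(self):
        sc = scoring.region_score(_tags([100] * 10), "chr1", 0, 500)
        assert sc.total == 10 and sc.pct_unique == 1.0

    def test_multi_tag_adds_capped_weight(self):
        tags = _tags([100] * 11, times=[1] * 10 + [4],
                     matches=[1] * 10 + [8])
        sc = scoring.region_score(tags, "chr1", 0, 500)
        assert sc.total == pytest.approx(10.5)
        assert sc.pct_unique == pytest.approx(10 / 10.5)

    def test_empty_region_conventions(self):
        sc = scoring.region_score(_tags([100]), "chr1", 5000, 6000)
        assert sc.total == 0 and sc.pct_unique == 0.0
        with pytest.raises(ValueError):
            scoring.region_score(_tags([100]), "chr1", 100, 100)

    def test_unique_tags_contribute_times_sequenced(self):
        sc = scoring.region_score(_tags([100], times=[7]), "chr1", 0, 500)
        assert sc.total == 7

    def test_additivity_over_disjoint_regions(self):
        rng = np.random.default_rng(5)
        tags = _tags(list(rng.integers(0, 2000, 80)),
                     times=list(rng.integers(1, 4, 80)),
                     matches=list(rng.integers(1, 5, 80)))
        # split at a point no tag straddles
        a = scoring.region_score(tags, "chr1", 0, 3000)
        cut = 2500
        b = scoring.region_score(tags, "chr1", 0, cut)
        c = scoring.region_score(tags, "chr1", cut, 3000)
        assert a.total == pytest.approx(b.total + c.total)
        assert a.unique_component == pytest.approx(
            b.unique_component + c.unique_component)


class TestClassifyPolymerase:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["POLR2B", "POLR3D"])

    def test_one_sided_and_unoccupied(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = scoring.classify_polymerase(
                self._table([[100.0, 0.0], [0.0, 0.0]]))
        assert list(out["pol_class"]) == ["POL2", "UNOCCUPIED"]

    def test_median_normalized_dual_call(self):
        rows = [[100, 2], [110, 3], [90, 1],      # pol II cohort
                [2, 50], [1, 55], [3, 45],        # pol III cohort
                [95, 40]]                         # dual: both near medians
        out = scoring.classify_polymerase(self._table(rows))
        assert list(out["pol_class"][:3]) == ["POL2"] * 3
        assert list(out["pol_class"][3:6]) == ["POL3"] * 3
        assert out["pol_class"].iloc[6] == "DUAL"

    def test_minority_score_below_dual_fraction_stays_single(self):
        rows = [[100, 2], [110, 3], [90, 1],
                [2, 50], [1, 55], [3, 45],
                [95, 10]]                         # 10/50 = 0.2 < 0.25
        out = scoring.classify_polymerase(self._table(rows))
        assert out["pol_class"].iloc[6] == "POL2"


class TestCorrelationMatrix:
    def test_self_and_reversed_columns(self):
        t = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [4.0, 3, 2, 1]})
        corr = scoring.correlation_matrix(t)
        assert corr.loc["A", "A"] == 1.0
        assert corr.loc["A", "B"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        t = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [5.0, 5, 5, 5]})
        corr = scoring.correlation_matrix(t)
        assert np.isnan(corr.loc["A", "B"])
        assert corr.loc["B", "B"] == 1.0

    def test_exclusions_and_minimum_rows(self):
        t = pd.DataFrame({"A": [1.0, 2, 3], "B": [1.0, 2, 3]},
                         index=["x", "y", "z"])
        with pytest.raises(ValueError):
            scoring.correlation_matrix(t, exclusions=["x"])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rank_pearson_oracle_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        t = pd.DataFrame({"A": rng.integers(0, 5, n).astype(float),
                          "B": rng.integers(0, 5, n).astype(float)})
        corr = scoring.correlation_matrix(t)
        expected = spearman_oracle(t["A"].values, t["B"].values)
        if np.isnan(expected):
            assert np.isnan(corr.loc["A", "B"])
        else:
            assert corr.loc["A", "B"] == pytest.approx(expected)


class TestActivatorSummary:
    def test_uniform_cohort(self):
        presence = pd.DataFrame(
            {a: [True] * 4 for a in scoring.ACTIVATORS},
            index=[f"L{i}" for i in range(4)])
        per, combos = scoring.activator_combo_summary(presence)
        assert (per["pct"] == 100.0).all()
        full = combos[(combos[list(scoring.ACTIVATORS)].all(axis=1))]
        assert full["count"].iloc[0] == 4
        assert combos["count"].sum() == 4

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            scoring.activator_combo_summary(
                pd.DataFrame(columns=list(scoring.ACTIVATORS)))

    def test_benchmark_combinations_match_planted_truth(self, benchmark,
                                                        benchmark_result):
        """Activator usage summary reproduces the planted combinations."""
        presence = benchmark_result["activator_presence"]
        truth = benchmark["truth"].factor_table
        loci = benchmark_result["loci"]
        # map each locus to its planted gene by coordinate overlap
        genes = benchmark["genes"]
        mapped = {}
        for _, l in loci.iterrows():
            hit = genes[(genes.chrom == l.chrom)
                        & (genes.start - 500 < l.end)
                        & (genes.end + 500 > l.start)]
            assert len(hit) == 1
            mapped[l.locus_id] = hit.iloc[0]["gene_id"]
        for locus_id, gene_id in mapped.items():
            for a in scoring.ACTIVATORS:
                assert presence.loc[locus_id, a] == truth.loc[gene_id, a], \
                    (locus_id, gene_id, a)
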