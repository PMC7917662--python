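"""Rarefaction, agglomeration, and alpha-diversity estimators."""

import itertools
import math

import numpy as np
import pytest

from dsslong.cohort_io import CohortValidationError, FeatureTable, TaxonomyMap
from dsslong.community_metrics import (
    agglomerate,
    alpha_diversity,
    chao1,
    phylum_ratio_series,
    rarefy,
    shannon,
    to_relative_abundance,
)
from dsslong.exposure_screen import merge_groups


class TestRarefy:
    def test_single_taxon_sample(self):
        t = FeatureTable(["s"], ["f"], np.array([[20000]]))
        out = rarefy(t, depth=10000, seed=0)
        assert out.counts[0, 0] == 10000

    def test_shallow_sample_dropped(self):
        t = FeatureTable(["deep", "shallow"], ["f"],
                         np.array([[15000], [9999]]))
        out = rarefy(t, depth=10000, seed=0)
        assert out.sample_ids == ["deep"]

    def test_all_shallow_is_error(self):
        t = FeatureTable(["s"], ["f"], np.array([[10]]))
        with pytest.raises(CohortValidationError):
            rarefy(t, depth=10000)

    def test_deterministic_under_seed(self, small_cohort):
        a = rarefy(small_cohort.table, 10000, seed=5)
        b = rarefy(small_cohort.table, 10000, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_hypergeometric_moments(self):
        # repeated rarefaction of one sample: per-taxon mean/variance follow
        # the multivariate hypergeometric law
        counts = np.array([[6000, 3000, 1000]])
        t = FeatureTable(["s"], ["a", "b", "c"], counts)
        draws = np.array([rarefy(t, 500, seed=k).counts[0] for k in range(400)])
        N, n = 10000, 500
        for j, K in enumerate([6000, 3000, 1000]):
            mean = n * K / N
            var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
            assert draws[:, j].mean() == pytest.approx(mean, rel=0.02)
            assert draws[:, j].var() == pytest.approx(var, rel=0.25)


class TestRelativeAbundance:
    def test_proportions(self):
        t = FeatureTable(["s"], ["a", "b", "c"], np.array([[2, 2, 6]]))
        ra = to_relative_abundance(t)
        assert list(ra.iloc[0]) == pytest.approx([0.2, 0.2, 0.6])

    def test_rows_sum_to_one_and_scale_invariance(self, small_cohort):
        ra = to_relative_abundance(small_cohort.table)
        assert np.allclose(ra.sum(axis=1), 1.0, atol=1e-9)
        scaled = FeatureTable(small_cohort.table.sample_ids,
                              small_cohort.table.feature_ids,
                              small_cohort.table.counts * 3)
        assert np.allclose(to_relative_abundance(scaled).to_numpy(),
                           ra.to_numpy())

    def test_zero_sample_is_error(self):
        t = FeatureTable(["s"], ["a"], np.array([[0]]))
        with pytest.raises(CohortValidationError):
            to_relative_abundance(t)


class TestAgglomerate:
    def test_same_genus_features_summed(self, tiny_table, tiny_taxonomy):
        out = agglomerate(tiny_table, tiny_taxonomy, rank="genus")
        assert "Lactobacillus" in out.feature_ids
        col = out.feature_ids.index("Lactobacillus")
        assert list(out.counts[:, col]) == [5, 4, 2]  # fA + fB

    def test_per_sample_totals_conserved(self, small_cohort):
        out = agglomerate(small_cohort.table, small_cohort.taxonomy, "genus")
        assert out.sample_sums().equals(small_cohort.table.sample_sums())

    def test_unassigned_binned_as_uncultured_parent(self, tiny_table, tiny_taxonomy):
        out = agglomerate(tiny_table, tiny_taxonomy, rank="genus")
        assert "uncultured Enterobacteriaceae" in out.feature_ids

    def test_fully_unassigned_binned(self):
        t = FeatureTable(["s"], ["f"], np.array([[4]]))
        tax = TaxonomyMap({"f": (None,) * 7})
        out = agglomerate(t, tax, rank="genus")
        assert out.feature_ids == ["Unassigned"]

    def test_ra_commutes_with_agglomeration(self, small_cohort):
        # normalize-then-agglomerate(RA sums) == agglomerate-then-normalize
        table, tax = small_cohort.table, small_cohort.taxonomy
        ra_first = to_relative_abundance(table)
        genus_cols = {}
        from dsslong.community_metrics import _agglomerated_label
        for f in table.feature_ids:
            genus_cols.setdefault(_agglomerated_label(tax[f], 5), []).append(f)
        summed = {g: ra_first[cols].sum(axis=1) for g, cols in genus_cols.items()}
        agg_first = to_relative_abundance(agglomerate(table, tax, "genus"))
        for g in agg_first.columns:
            assert np.allclose(agg_first[g].to_numpy(), summed[g].to_numpy(),
                               atol=1e-12)


class TestChao1:
    def test_no_singletons_equals_observed(self):
        assert chao1([5, 4, 3, 2]) == 4.0

    def test_hand_evaluated_bias_corrected_formula(self):
        # S_obs=5, F1=2 singletons, F2=1 doubleton -> 5 + 2*1/(2*2) = 5.5
        assert chao1([1, 1, 2, 5, 9]) == pytest.approx(5.5)

    def test_exhaustive_small_vectors_match_formula(self):
        for vec in itertools.product(range(5), repeat=4):
            if sum(vec) == 0:
                continue
            arr = np.array(vec)
            s_obs = int((arr > 0).sum())
            f1 = int((arr == 1).sum())
            f2 = int((arr == 2).sum())
            expected = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
            assert chao1(arr) == pytest.approx(expected)
            assert chao1(arr) >= s_obs

    def test_reorder_invariance(self):
        assert chao1([1, 2, 3, 0, 1]) == chao1([0, 1, 1, 2, 3])


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
        assert shannon([5, 5, 5, 5], base=2) == pytest.approx(2.0)

    def test_single_taxon_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_merging_taxa_never_increases_entropy(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v = rng.integers(0, 10, size=6)
            if v.sum() == 0 or (v > 0).sum() < 2:
                continue
            h = shannon(v)
            merged = v.copy()[:-1]
            merged[0] += v[-1]
            assert shannon(merged) <= h + 1e-12

    def test_alpha_diversity_frame(self, tiny_table):
        out = alpha_diversity(tiny_table)
        assert list(out.columns) == ["chao1", "shannon"]
        assert set(out.index) == set(tiny_table.sample_ids)
        assert (out["shannon"] >= 0).all()


class TestPhylumRatio:
    @staticmethod
    def _group_ra(values_by_day, phyla=("Bacteroidetes", "Proteobacteria")):
        import pandas as pd
        idx = pd.MultiIndex.from_tuples(
            [(2, d) for d in sorted(values_by_day)], names=["dose", "day"])
        return pd.DataFrame(
            [values_by_day[d] for d in sorted(values_by_day)],
            index=idx, columns=list(phyla),
        )

    def test_constant_ratio_correlation_undefined(self):
        ra = self._group_ra({d: (0.4, 0.2) for d in range(0, 14, 2)})
        res = phylum_ratio_series(ra, "Bacteroidetes", "Proteobacteria", dose=2)
        assert all(r == pytest.approx(2.0) for r in res.ratios)
        assert not res.correlation.defined

    def test_linear_decreasing_ratio(self):
        ra = self._group_ra({d: (0.5 - 0.03 * d, 0.1) for d in range(0, 14, 2)})
        res = phylum_ratio_series(ra, "Bacteroidetes", "Proteobacteria", dose=2)
        assert res.correlation.r == pytest.approx(-1.0)
        assert res.fit.r_squared == pytest.approx(1.0)

    def test_zero_denominator_days_excluded(self):
        vals = {d: (0.4, 0.2) for d in range(0, 14, 2)}
        vals[4] = (0.4, 0.0)
        ra = self._group_ra(vals)
        res = phylum_ratio_series(ra, "Bacteroidetes", "Proteobacteria", dose=2)
        assert res.excluded_days == (4,)
        assert len(res.ratios) == 6

    def test_synthetic_cohort_high_dose_ratio_declines(self, default_cohort):
        # Proteobacteria bloom faster than Bacteroidetes at the top dose, so
        # the Bacteroidetes/Proteobacteria ratio trends downward
        c = default_cohort
        phylum = agglomerate(c.table, c.taxonomy, rank="phylum")
        group_ra = merge_groups(phylum, c.metadata)
        res = phylum_ratio_series(group_ra, "Bacteroidetes", "Proteobacteria",
                                  dose=3)
        assert res.correlation.defined
        assert res.correlation.r < 0
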