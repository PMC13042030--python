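import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest

from gwarch.architecture import HitTable, TraitParams, simulate_hits
from gwarch.classify import (
    acat_combine,
    classify_traits,
    hit_summary,
    prune_traits,
)
from gwarch.synthetic import make_enrichment_matrix


class TestAcat:
    def test_single_p_identity(self):
        for p in (0.013, 0.4, 0.97):
            assert np.isclose(acat_combine([p]), p, atol=1e-12)

    def test_all_half_gives_half(self):
        assert np.isclose(acat_combine([0.5] * 7), 0.5, atol=1e-12)

    def test_worked_example(self):
        # T = (tan(0.49 pi) + tan(0)) / 2 = 15.9103; p = 0.5 - atan(T)/pi
        combined = acat_combine([0.01, 0.5])
        assert abs(combined - 0.01999) < 1e-4

    def test_null_uniformity_across_k(self):
        rng = np.random.default_rng(4)
        for k in (2, 10, 220):
            passes = 0
            for _ in range(10):
                p = rng.uniform(size=(3000, k))
                t = np.tan((0.5 - p) * np.pi).mean(axis=1)
                combined = 0.5 - np.arctan(t) / np.pi
                passes += kstest(combined, "uniform").pvalue > 0.05
            assert passes >= 9, f"k={k}"

    @given(
        st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8),
        st.integers(0, 7),
        st.floats(0.1, 0.9),
    )
    def test_monotone_in_each_input(self, pvals, idx, factor):
        idx = idx % len(pvals)
        smaller = list(pvals)
        smaller[idx] = pvals[idx] * factor
        assert acat_combine(smaller) <= acat_combine(pvals) + 1e-12

    def test_boundary_values_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = acat_combine([0.0, 0.5])
        assert 0 < out < 1e-10


class TestClassifyTraits:
    def test_no_signal_no_brain_labels(self):
        m = make_enrichment_matrix(12, planted_brain=[], seed=0)
        res = classify_traits(m)
        assert not res["brain_related"].any()

    def test_planted_signal_recovered(self):
        m = make_enrichment_matrix(12, planted_brain=[0, 5], signal_strength=8,
                                   seed=1)
        res = classify_traits(m)
        assert res["brain_related"].tolist() == [
            i in (0, 5) for i in range(12)
        ]

    def test_threshold_is_strict(self):
        """ACAT of identical inputs is the identity, so a constant CNS row
        probes the boundary exactly."""
        m = make_enrichment_matrix(4, planted_brain=[], seed=2)
        thr = 0.05 / (10 * 4)
        pv = m.pvalues.copy()
        cns = m.columns_in("CNS")
        pv.loc["trait000", cns] = thr * (1 + 1e-6)  # at/above: excluded
        pv.loc["trait001", cns] = thr * (1 - 1e-6)
        m2 = type(m)(pvalues=pv, categories=m.categories)
        res = classify_traits(m2)
        assert not res.loc["trait000", "brain_related"]
        assert res.loc["trait001", "brain_related"]

    def test_order_independence(self):
        m = make_enrichment_matrix(10, planted_brain=[3], signal_strength=8,
                                   seed=3)
        res = classify_traits(m)
        m_rev = type(m)(pvalues=m.pvalues.iloc[::-1], categories=m.categories)
        res_rev = classify_traits(m_rev)
        assert (
            res["brain_related"].sort_index()
            .equals(res_rev["brain_related"].sort_index())
        )

    def test_missing_cns_category_rejected(self):
        m = make_enrichment_matrix(4, planted_brain=[], seed=0)
        cats = m.categories.replace("CNS", "other")
        m2 = type(m)(pvalues=m.pvalues, categories=cats)
        with pytest.raises(ValueError, match="CNS"):
            classify_traits(m2)

    def test_detection_power_increases_with_signal(self):
        recovered = []
        for delta in (0.0, 2.0, 4.0, 6.0):
            hits = 0
            for seed in range(3):
                m = make_enrichment_matrix(
                    10, planted_brain=[0, 1, 2], signal_strength=delta,
                    seed=10 + seed,
                )
                res = classify_traits(m)
                hits += res["brain_related"][:3].sum()
            recovered.append(hits)
        assert all(np.diff(recovered) >= 0)
        assert recovered[0] <= 1 and recovered[-1] == 9


class TestHitSummary:
    def test_median_conventions(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "trait": "t",
                "variant": ["a", "b", "c"],
                "maf": [0.1, 0.2, 0.3],
                "z": [5.5, -6.0, 7.0],
                "block": [0, 1, 2],
            }
        )
        s = hit_summary(HitTable(df, {"t": {}}))
        assert s.median_abs_z == 6.0
        assert s.median_maf == 0.2

    def test_cdf_properties(self, ref_sim):
        s = hit_summary(ref_sim.hits)
        assert np.all(np.diff(s.maf_cdf) >= 0)
        assert s.maf_cdf[-1] == 1.0
        assert np.all(np.diff(s.z_cdf) >= 0)

    def test_strong_selection_trait_has_higher_maf_lower_z(
        self, fs_ref, fs_strong, toy_table
    ):
        """The brain-trait-like condition (stronger selection, larger target)
        yields hits at higher MAF and of weaker significance."""
        ref = simulate_hits(
            TraitParams(h2=0.5, L=1e8, N=3e5, trait="r"),
            fs_ref, toy_table, seed=40, n_s=20,
        )
        frames = [
            simulate_hits(
                TraitParams(h2=0.5, L=3e8, N=3e5, trait="b"),
                fs_strong, toy_table, seed=41 + i, n_s=20,
            ).hits.df
            for i in range(6)
        ]
        df = pd.concat(frames, ignore_index=True)
        df["variant"] = [f"v{i:05d}" for i in range(len(df))]
        s_ref = hit_summary(ref.hits)
        s_strong = hit_summary(HitTable(df, {"b": {"n": 3e5}}))
        assert s_strong.median_maf > s_ref.median_maf
        assert s_strong.median_abs_z < s_ref.median_abs_z

    def test_empty_table_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            columns=["trait", "variant", "maf", "z", "block"]
        )
        with pytest.raises(ValueError):
            hit_summary(HitTable(df, {}))


class TestPruneTraits:
    def _rg(self, names, mat):
        return pd.DataFrame(mat, index=names, columns=names)

    def test_correlated_pair_keeps_first(self):
        rg = self._rg(["a", "b"], [[1.0, 0.6], [0.6, 1.0]])
        assert prune_traits(["a", "b"], rg) == ["a"]

    def test_uncorrelated_all_kept(self):
        rg = self._rg(["a", "b", "c"], np.eye(3))
        assert prune_traits(["a", "b", "c"], rg) == ["a", "b", "c"]

    def test_chain_keeps_alternating_traits(self):
        names = list("abcde")
        mat = np.eye(5)
        for i in range(4):
            mat[i, i + 1] = mat[i + 1, i] = 0.6
        assert prune_traits(names, self._rg(names, mat)) == ["a", "c", "e"]

    def test_missing_estimate_skips_trait(self):
        mat = np.eye(3)
        mat[0, 1] = mat[1, 0] = np.nan
        rg = self._rg(["a", "b", "c"], mat)
        assert prune_traits(["a", "b", "c"], rg) == ["a", "c"]

    def test_asymmetric_matrix_rejected(self):
        rg = self._rg(["a", "b"], [[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(ValueError):
            prune_traits(["a", "b"], rg)
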