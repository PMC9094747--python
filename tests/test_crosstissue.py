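"""Edge survey, significance rules, classification, receptor bins, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from myokinet.crosstissue import (
    apply_2sd,
    apply_p_threshold,
    bin_by_receptor,
    classify_edges,
    count_significant,
    ora_hypergeometric,
    survey,
    threshold_2sd,
)
from myokinet.io_filter import GeneSet, log_cpm


def _edge_frame(r_male, r_female=None, tissue="liver"):
    r_male = np.asarray(r_male, float)
    r_female = r_male if r_female is None else np.asarray(r_female, float)
    n = len(r_male)
    return pd.DataFrame(
        {
            "myokine": [f"M{i}" for i in range(n)],
            "target_tissue": [tissue] * n,
            "target_gene": [f"G{i}" for i in range(n)],
            "bicor_male": r_male,
            "p_male": np.ones(n),
            "bicor_female": r_female,
            "p_female": np.ones(n),
        }
    )


class TestSurvey:
    def test_shape_one_myokine_one_tissue(self, rng):
        cols = [f"s{i}" for i in range(20)]
        sex = pd.Series(["male"] * 10 + ["female"] * 10, index=cols)
        mus = pd.DataFrame(rng.normal(size=(3, 20)), index=["MYO", "ESR1", "AR"], columns=cols)
        liv = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"L{i}" for i in range(10)], columns=cols)
        edges = survey(mus, ["MYO"], {"liver": liv}, sex)
        assert len(edges) == 10
        assert edges["p_male"].notna().all() and edges["p_female"].notna().all()

    def test_matches_bicor_matrix_per_stratum(self, default_cohort_logged):
        cfg, logged, samples, truth = default_cohort_logged
        from myokinet.bicor import bicor_matrix

        myok = list(truth.receptor_map.index[:5])
        edges = survey(logged["muscle"], myok, {"liver": logged["liver"].iloc[:50]}, samples["sex"])
        female = samples.index[samples["sex"] == "female"]
        ref = bicor_matrix(logged["muscle"].loc[myok], logged["liver"].iloc[:50], sample_subset=female)
        got = edges.pivot_table(index="myokine", columns="target_gene", values="bicor_female", observed=True)
        got = got.loc[myok, ref.r.columns]
        np.testing.assert_allclose(got.to_numpy(), ref.r.to_numpy(), atol=1e-12)

    def test_understaffed_stratum_skips_tissue_with_warning(self, rng):
        cols = [f"s{i}" for i in range(12)]
        sex = pd.Series(["male"] * 9 + ["female"] * 3, index=cols)
        mus = pd.DataFrame(rng.normal(size=(1, 12)), index=["MYO"], columns=cols)
        liv = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"L{i}" for i in range(5)], columns=cols)
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="no target tissue"):
                survey(mus, ["MYO"], {"liver": liv}, sex)

    def test_unknown_myokine_rejected(self, rng):
        mus = pd.DataFrame(rng.normal(size=(1, 8)), index=["MYO"])
        with pytest.raises(KeyError, match="GHOST"):
            survey(mus, ["GHOST"], {"liver": mus}, pd.Series(["male"] * 8))


class TestThreshold2SD:
    def test_planted_outlier_is_the_only_flag(self, rng):
        # bounded null support so mean + 2 SD clears every null coefficient
        r = rng.uniform(-0.05, 0.05, 400)
        r[7] = 0.5
        edges = _edge_frame(r)
        flags, mu, sigma = threshold_2sd(edges, "liver", "male")
        assert flags.sum() == 1 and flags.iloc[7]

    def test_matches_direct_count_oracle(self, rng):
        r = rng.normal(size=500)
        edges = _edge_frame(r)
        flags, mu, sigma = threshold_2sd(edges, "liver", "male")
        expected = np.abs(r) > r.mean() + 2 * r.std()
        assert (flags.to_numpy() == expected).all()
        assert mu == pytest.approx(r.mean()) and sigma == pytest.approx(r.std())

    def test_degenerate_distribution_rejected(self):
        edges = _edge_frame(np.full(150, 0.3))
        with pytest.raises(ValueError, match="degenerate"):
            threshold_2sd(edges, "liver", "male")

    def test_flags_invariant_to_row_order(self, rng):
        r = rng.normal(size=300)
        edges = _edge_frame(r)
        perm = edges.sample(frac=1, random_state=0)
        f1 = apply_2sd(edges).set_index("myokine")["sig_male"]
        f2 = apply_2sd(perm).set_index("myokine")["sig_male"]
        assert f1.sort_index().equals(f2.sort_index())


class TestClassification:
    def test_truth_table(self):
        edges = _edge_frame([0.5, 0.1, 0.5, 0.5], [0.1, 0.5, 0.5, -0.5])
        edges["sig_male"] = [True, False, True, True]
        edges["sig_female"] = [False, True, True, True]
        out = classify_edges(edges)
        assert list(out["sex_class"]) == ["male_only", "female_only", "shared", "none"]
        assert list(out["discordant"]) == [False, False, False, True]

    def test_flags_required_first(self):
        with pytest.raises(ValueError, match="flags not set"):
            classify_edges(_edge_frame([0.1]))

    def test_sex_relabeling_swaps_classes(self, rng):
        r_m = rng.normal(0, 0.1, 300)
        r_f = rng.normal(0, 0.1, 300)
        e1 = classify_edges(apply_2sd(_edge_frame(r_m, r_f)))
        e2 = classify_edges(apply_2sd(_edge_frame(r_f, r_m)))
        c1 = e1["sex_class"].value_counts()
        c2 = e2["sex_class"].value_counts()
        assert c1["male_only"] == c2["female_only"]
        assert c1["female_only"] == c2["male_only"]
        assert c1["shared"] == c2["shared"]


class TestReceptorBins:
    def test_missing_receptor_row_named(self, rng):
        mus = pd.DataFrame(rng.normal(size=(2, 10)), index=["MYO", "ESR1"])
        with pytest.raises(KeyError, match="AR"):
            bin_by_receptor(["MYO"], mus, pd.Series(["male"] * 10))

    def test_degenerate_threshold_bins_everything_both(self, rng):
        cols = [f"s{i}" for i in range(30)]
        sex = pd.Series(["male"] * 15 + ["female"] * 15, index=cols)
        mus = pd.DataFrame(
            rng.normal(size=(3, 30)), index=["MYO", "ESR1", "AR"], columns=cols
        )
        bins = bin_by_receptor(["MYO"], mus, sex, p_threshold=1.0)
        assert (bins["bin"] == "both").all()

    def test_receptor_driven_myokine_binned_correctly(self, default_cohort_logged):
        cfg, logged, samples, truth = default_cohort_logged
        myok = list(truth.receptor_map.index)
        bins = bin_by_receptor(myok, logged["muscle"], samples["sex"], 0.01)
        merged = bins.merge(truth.receptor_map.reset_index(), on="myokine", suffixes=("_called", "_true"))
        esr1 = merged[merged["bin_true"] == "ESR1"]
        assert (esr1["bin_called"] == "ESR1").mean() >= 0.9


class TestCounting:
    def test_empty_edge_set_all_zero(self):
        edges = classify_edges(apply_p_threshold(_edge_frame(np.zeros(5)), 0.01))
        out = count_significant(edges)
        assert out["n_significant"].sum() == 0

    def test_manual_six_edge_tally(self):
        edges = _edge_frame([0.5, 0.5, 0.1, 0.5, 0.1, 0.5], [0.5, 0.1, 0.5, 0.5, 0.1, -0.5])
        edges["sig_male"] = [True, True, False, True, False, True]
        edges["sig_female"] = [True, False, True, True, False, True]
        edges = classify_edges(edges)
        out = count_significant(edges, ["sex_class"]).set_index("sex_class")["n_significant"]
        assert out["shared"] == 2 and out["male_only"] == 1 and out["female_only"] == 1

    def test_row_permutation_invariance(self, rng):
        edges = classify_edges(apply_p_threshold(_edge_frame(rng.normal(size=50)), 0.5))
        a = count_significant(edges)
        b = count_significant(edges.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_grouping_key_rejected(self):
        edges = classify_edges(apply_p_threshold(_edge_frame([0.1]), 0.01))
        with pytest.raises(ValueError, match="unknown grouping"):
            count_significant(edges, ["banana"])


class TestORA:
    def test_exact_tail_sum_on_toy(self):
        """universe 20, pathway 5, hits 5, overlap 4: p must equal the
        closed-form hypergeometric tail sum."""
        universe = GeneSet("u", tuple(f"g{i}" for i in range(20)))
        hits = GeneSet("h", ("g0", "g1", "g2", "g3", "g10"))
        pathways = {"P": {"g0", "g1", "g2", "g3", "g4"}}
        out = ora_hypergeometric(hits, universe, pathways)
        expected = sum(
            comb(5, k) * comb(15, 5 - k) for k in (4, 5)
        ) / comb(20, 5)
        assert out.loc[0, "pvalue"] == pytest.approx(expected, abs=1e-12)
        assert out.loc[0, "overlap"] == 4

    def test_pathway_equal_to_hits_is_extreme(self):
        universe = GeneSet("u", tuple(f"g{i}" for i in range(50)))
        hits = GeneSet("h", tuple(f"g{i}" for i in range(5)))
        out = ora_hypergeometric(hits, universe, {"exact": set(hits.genes)})
        expected = 1.0 / comb(50, 5)
        assert out.loc[0, "pvalue"] == pytest.approx(expected, rel=1e-9)
        assert out.loc[0, "enrichment_ratio"] == pytest.approx(10.0)

    def test_null_hits_give_uniform_pvalues(self, rng):
        genes = [f"g{i}" for i in range(400)]
        universe = GeneSet("u", tuple(genes))
        pathways = {
            f"P{j}": set(rng.choice(genes, 40, replace=False)) for j in range(200)
        }
        hits = GeneSet("h", tuple(rng.choice(genes, 50, replace=False)))
        out = ora_hypergeometric(hits, universe, pathways)
        # discrete p-values are stochastically >= uniform; KS against the
        # uniform must not reject in the anti-conservative direction
        d_plus = np.max(
            np.arange(1, 201) / 200 - np.sort(out["pvalue"].to_numpy())
        )
        assert d_plus < 1.63 / np.sqrt(200)  # 1% one-sided KS band

    def test_hit_outside_universe_rejected(self):
        universe = GeneSet("u", ("a", "b"))
        hits = GeneSet("h", ("a", "z"))
        with pytest.raises(ValueError, match="z"):
            ora_hypergeometric(hits, universe, {"P": {"a"}})

    def test_empty_pathways_rejected(self):
        with pytest.raises(ValueError, match="no pathways"):
            ora_hypergeometric(GeneSet("h", ("a",)), GeneSet("u", ("a",)), {})
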