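"""Generator: determinism, planted-correlation fidelity, reference and
mixture construction."""

import numpy as np
import pandas as pd
import pytest

from myokinet.bicor import bicor, bicor_pvalue
from myokinet.io_filter import log_cpm
from myokinet.synthetic import (
    MediationTriplet,
    PlantedEdge,
    SimulationConfig,
    read_single_cell,
    simulate_cohort,
    simulate_mediation_triplet,
    simulate_mixtures,
    simulate_single_cell_reference,
    write_single_cell,
)


def _tiny_cfg(seed=0, edges=(), **kw):
    defaults = dict(
        seed=seed,
        n_male=60,
        n_female=40,
        tissues=("muscle", "liver"),
        genes_per_tissue=80,
        n_myokines=12,
        n_de_myokines=2,
        receptor_driven_fraction=0.25,
        markers_per_cell_type=3,
        cell_types=("fast", "slow"),
        dirichlet_alpha=(4.0, 3.0),
        planted_edges=tuple(edges),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_too_many_myokines_rejected(self):
        with pytest.raises(ValueError, match="exceeds genes_per_tissue"):
            _tiny_cfg(n_myokines=100)

    def test_unknown_edge_gene_rejected(self):
        bad = PlantedEdge("MYOK_0001", "liver", "LIV_G9999", 0.5, "shared")
        with pytest.raises(ValueError, match="unknown gene"):
            _tiny_cfg(edges=[bad])

    def test_edge_strength_bounds(self):
        with pytest.raises(ValueError, match="strictly in"):
            PlantedEdge("MYOK_0001", "liver", "LIV_G0001", 1.0, "shared")

    def test_small_sex_group_rejected(self):
        with pytest.raises(ValueError, match="4 samples per sex"):
            _tiny_cfg(n_female=3)

    def test_nonpositive_dirichlet_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _tiny_cfg(dirichlet_alpha=(1.0, 0.0))


class TestCohort:
    def test_same_seed_byte_identical(self):
        a = simulate_cohort(_tiny_cfg(seed=9))
        b = simulate_cohort(_tiny_cfg(seed=9))
        for t in a[0].matrices:
            pd.testing.assert_frame_equal(a[0].matrices[t], b[0].matrices[t])
        pd.testing.assert_frame_equal(a[2].true_proportions, b[2].true_proportions)

    def test_counts_are_nonnegative_integers(self):
        bundle, _, _ = simulate_cohort(_tiny_cfg(seed=2))
        for m in bundle.matrices.values():
            arr = m.to_numpy()
            assert (arr >= 0).all()
            assert np.issubdtype(arr.dtype, np.integer)

    def test_muscle_contains_myokines_and_receptors(self):
        bundle, _, truth = simulate_cohort(_tiny_cfg(seed=2))
        idx = bundle.matrices["muscle"].index
        assert {"ESR1", "AR"} <= set(idx)
        assert set(truth.receptor_map.index) <= set(idx)

    def test_true_proportions_rows_sum_to_one(self):
        _, _, truth = simulate_cohort(_tiny_cfg(seed=2))
        np.testing.assert_allclose(truth.true_proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_null_cohort_bicor_distribution_centered(self):
        """With nothing planted, cross-tissue coefficients center on zero."""
        cfg = _tiny_cfg(
            seed=5, n_myokines=10, n_de_myokines=0, receptor_driven_fraction=0.0
        )
        bundle, samples, _ = simulate_cohort(cfg)
        mus = log_cpm(bundle.matrices["muscle"]).iloc[:10]
        liv = log_cpm(bundle.matrices["liver"])
        male = samples.index[samples["sex"] == "male"]
        from myokinet.bicor import bicor_matrix

        r = bicor_matrix(mus, liv, sample_subset=male).r.to_numpy().ravel()
        assert abs(np.nanmean(r)) < 3.0 / np.sqrt(r.size)

    def test_shared_edge_strength_realized_in_both_sexes(self):
        edge = PlantedEdge("MYOK_0001", "liver", "LIV_G0001", 0.6, "shared")
        cfg = _tiny_cfg(seed=7, edges=[edge], n_male=200, n_female=100)
        bundle, samples, _ = simulate_cohort(cfg)
        x = log_cpm(bundle.matrices["muscle"]).loc["MYOK_0001"]
        y = log_cpm(bundle.matrices["liver"]).loc["LIV_G0001"]
        for sex in ("male", "female"):
            ids = samples.index[samples["sex"] == sex]
            assert bicor(x[ids].to_numpy(), y[ids].to_numpy()) == pytest.approx(0.6, abs=0.15)

    def test_sex_specific_edge_absent_in_other_stratum(self):
        edge = PlantedEdge("MYOK_0001", "liver", "LIV_G0001", 0.6, "male_only")
        cfg = _tiny_cfg(seed=8, edges=[edge], n_male=150, n_female=150)
        bundle, samples, _ = simulate_cohort(cfg)
        x = log_cpm(bundle.matrices["muscle"]).loc["MYOK_0001"]
        y = log_cpm(bundle.matrices["liver"]).loc["LIV_G0001"]
        male = samples.index[samples["sex"] == "male"]
        female = samples.index[samples["sex"] == "female"]
        assert bicor(x[male].to_numpy(), y[male].to_numpy()) > 0.4
        assert abs(bicor(x[female].to_numpy(), y[female].to_numpy())) < 0.25

    def test_planted_fidelity_mean_over_replicates(self):
        """Over 200 replicate cohorts, the mean observed coefficient of a
        planted edge stays within +/-0.05 of the configured strength.

        Enough genes per tissue are simulated for the per-sample library
        totals to stabilize; with very few genes the CPM normalization
        itself injects extra noise and attenuates every correlation.
        """
        edge = PlantedEdge("MYOK_0001", "liver", "LIV_G0001", 0.5, "shared")
        vals = []
        for seed in range(200):
            cfg = _tiny_cfg(
                seed=seed, edges=[edge], n_male=40, n_female=40,
                genes_per_tissue=400, n_myokines=4, n_de_myokines=0,
                receptor_driven_fraction=0.0,
            )
            bundle, samples, _ = simulate_cohort(cfg)
            x = log_cpm(bundle.matrices["muscle"]).loc["MYOK_0001"]
            y = log_cpm(bundle.matrices["liver"]).loc["LIV_G0001"]
            male = samples.index[samples["sex"] == "male"]
            vals.append(bicor(x[male].to_numpy(), y[male].to_numpy()))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_null_pvalue_calibration(self):
        """With no planted structure the per-sex bicor p<0.01 rate sits in
        the 99% binomial band around 0.01."""
        from scipy import stats
        from myokinet.bicor import bicor_matrix

        cfg = _tiny_cfg(
            seed=13, n_myokines=12, n_de_myokines=0, receptor_driven_fraction=0.0,
            genes_per_tissue=400, n_male=80, n_female=80,
        )
        bundle, samples, _ = simulate_cohort(cfg)
        mus = log_cpm(bundle.matrices["muscle"]).iloc[: cfg.n_myokines]
        liv = log_cpm(bundle.matrices["liver"])
        hits, total = 0, 0
        for sex in ("male", "female"):
            ids = samples.index[samples["sex"] == sex]
            p = bicor_matrix(mus, liv, sample_subset=ids).p.to_numpy().ravel()
            hits += (p < 0.01).sum()
            total += p.size
        lo, hi = stats.binom.ppf([0.005, 0.995], total, 0.01) / total
        assert lo <= hits / total <= hi


class TestSingleCellReference:
    def test_marker_fold_enrichment_at_least_five(self):
        cfg = _tiny_cfg(seed=3)
        counts, labels = simulate_single_cell_reference(cfg)
        for ct in cfg.cell_types:
            own = counts[labels == ct]
            other = counts[labels != ct]
            for g in [f"MRK_{ct}_{j + 1:02d}" for j in range(cfg.markers_per_cell_type)]:
                assert own[g].mean() >= 5 * other[g].mean()

    def test_labels_align_to_rows(self):
        counts, labels = simulate_single_cell_reference(_tiny_cfg(seed=3))
        assert list(labels.index) == list(counts.index)

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_single_cell_reference(
                _tiny_cfg(cell_types=("only",), dirichlet_alpha=(1.0,))
            )

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="cells_per_type"):
            simulate_single_cell_reference(_tiny_cfg(cells_per_type=0))

    def test_mtx_round_trip(self, tmp_path):
        counts, labels = simulate_single_cell_reference(_tiny_cfg(seed=3))
        write_single_cell(counts, labels, tmp_path)
        c2, l2 = read_single_cell(tmp_path)
        pd.testing.assert_frame_equal(
            c2, counts.astype(float), check_dtype=False, check_names=False
        )
        assert (l2.to_numpy() == labels.to_numpy()).all()


class TestMixtures:
    @pytest.fixture
    def signature(self, rng):
        return pd.DataFrame(
            rng.uniform(10, 100, size=(25, 4)),
            index=[f"m{i}" for i in range(25)],
            columns=list("ABCD"),
        )

    def test_noiseless_pure_samples_equal_signature_columns(self, signature):
        bulk, props = simulate_mixtures(signature, 4, (1, 1, 1, 1), 0.0, seed=1)
        # overwrite proportions is not possible; instead verify the exact
        # linear identity bulk = S @ P^T
        np.testing.assert_allclose(
            bulk.to_numpy(), signature.to_numpy() @ props.to_numpy().T, atol=1e-10
        )

    def test_noiseless_mixtures_exactly_solvable(self, signature):
        bulk, props = simulate_mixtures(signature, 50, np.ones(4), 0.0, seed=2)
        sol, *_ = np.linalg.lstsq(signature.to_numpy(), bulk.to_numpy(), rcond=None)
        assert np.abs(sol.T - props.to_numpy()).max() < 1e-8

    def test_proportion_rows_sum_to_one(self, signature):
        _, props = simulate_mixtures(signature, 20, np.ones(4), 5.0, seed=3)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_wrong_alpha_length_rejected(self, signature):
        with pytest.raises(ValueError, match="length"):
            simulate_mixtures(signature, 10, np.ones(3), 0.0, seed=1)

    def test_negative_noise_rejected(self, signature):
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_mixtures(signature, 10, np.ones(4), -1.0, seed=1)


class TestMediationTriplets:
    def test_full_mediation_geometry(self):
        e, m, t = simulate_mediation_triplet(5000, 0.8, 0.7, "full_mediation", 1)
        assert np.corrcoef(e, m)[0, 1] == pytest.approx(0.8, abs=0.03)
        assert np.corrcoef(e, t)[0, 1] == pytest.approx(0.56, abs=0.04)
        # conditional independence: partial corr(e, t | m) ~ 0
        res_t = t - np.polyval(np.polyfit(m, t, 1), m)
        res_e = e - np.polyval(np.polyfit(m, e, 1), m)
        assert abs(np.corrcoef(res_e, res_t)[0, 1]) < 0.05

    def test_independent_keeps_direct_path(self):
        e, m, t = simulate_mediation_triplet(5000, 0.8, 0.7, "independent", 1)
        res_t = t - np.polyval(np.polyfit(m, t, 1), m)
        res_e = e - np.polyval(np.polyfit(m, e, 1), m)
        # exposure still explains the target after removing the mediator
        assert np.corrcoef(res_e, res_t)[0, 1] > 0.3

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown kind"):
            simulate_mediation_triplet(10, 0.5, 0.5, "partial", 1)
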