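from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexland import (
    CorrelationMatrix,
    CrossCoupling,
    GeneModule,
    SyntheticCohortConfig,
    activity_scores,
    dichotomize_scores,
    gene_module_correlation,
    generate_cohort,
    module_coexpression,
    module_conservation,
    nacc,
    nacc_profile,
    quartile_nacc,
    subgroup_nacc_test,
)

import _oracles
from conftest import make_dataset
from test_network import corr_from_weights, random_corr


class TestModuleCoexpression:
    def test_identical_genes_mean_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        x = np.vstack([v, v, v] + [rng.standard_normal(30) for _ in range(7)])
        ds = make_dataset(x)
        out = module_coexpression(["g1", "g2", "g3"], ds, n_random=50, seed=1)
        assert out.mean_pairwise_r == pytest.approx(1.0)

    def test_two_gene_module_equals_single_pair_r(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.standard_normal((5, 40)))
        out = module_coexpression(["g1", "g2"], ds, n_random=0, seed=0)
        expected, _ = stats.pearsonr(
            ds.values.loc["g1"], ds.values.loc["g2"]
        )
        assert out.mean_pairwise_r == pytest.approx(expected, abs=1e-10)

    def test_missing_genes_raise(self):
        ds = make_dataset(np.zeros((3, 5)) + np.arange(5))
        with pytest.raises(ValueError, match="zz"):
            module_coexpression(["g1", "zz", "yy"], ds, n_random=0)

    def test_null_p_uniform_under_independence(self):
        """Random modules in an independent-gene dataset give ~0 mean r
        and a uniform empirical p over repeated draws (KS check)."""
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.standard_normal((100, 80)))
        pvals, means = [], []
        for i in range(200):
            genes = [f"g{j + 1}" for j in rng.choice(100, size=5, replace=False)]
            out = module_coexpression(genes, ds, n_random=99, seed=1000 + i)
            pvals.append(out.empirical_p)
            means.append(out.mean_pairwise_r)
        assert abs(np.mean(means)) < 0.05
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestNACC:
    def test_all_pairs_connected(self):
        genes = list("abcd")
        corr = corr_from_weights({p: 0.9 for p in itertools.combinations(genes, 2)})
        assert nacc(genes, corr, 0.5) == 1.0

    def test_no_pair_connected(self):
        genes = list("abcd")
        corr = corr_from_weights({p: 0.2 for p in itertools.combinations(genes, 2)})
        assert nacc(genes, corr, 0.5) == 0.0

    def test_four_of_ten_pairs(self):
        genes = list("abcde")
        pairs = list(itertools.combinations(genes, 2))
        weights = {p: (0.9 if i < 4 else 0.1) for i, p in enumerate(pairs)}
        assert nacc(genes, corr_from_weights(weights), 0.5) == pytest.approx(0.4)

    def test_fewer_than_two_genes_raises(self):
        corr = corr_from_weights({("a", "b"): 0.5})
        with pytest.raises(ValueError):
            nacc(["a"], corr, 0.3)

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            corr = random_corr(rng, 20)
            size = int(rng.integers(2, 9))
            genes = list(rng.choice(corr.gene_ids, size=size, replace=False))
            cutoff = float(rng.uniform(0.1, 0.9))
            expected = _oracles.pair_fraction_above(genes, corr.weight, cutoff)
            assert nacc(genes, corr, cutoff) == pytest.approx(expected)


class TestNACCProfile:
    def test_cross_only_complete_bipartite(self):
        a, b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        weights = {(x, y): 0.9 for x in a for y in b}
        prof = nacc_profile(a, b, corr_from_weights(weights), [0.3, 0.5],
                            combine_mode="cross_only")
        np.testing.assert_array_equal(prof.nacc, [1.0, 1.0])

    def test_union_counts_within_and_between(self):
        a, b = ["a1", "a2"], ["b1", "b2"]
        weights = {("a1", "a2"): 0.9, ("b1", "b2"): 0.9}
        prof = nacc_profile(a, b, corr_from_weights(weights), [0.5])
        assert prof.nacc[0] == pytest.approx(2 / 6)

    def test_profile_non_increasing_for_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            corr = random_corr(rng, 15)
            genes = list(rng.choice(corr.gene_ids, size=6, replace=False))
            prof = nacc_profile(genes, None, corr, [0.3, 0.4, 0.5, 0.6, 0.7])
            assert (np.diff(prof.nacc) <= 1e-12).all()

    def test_overlap_in_cross_only_raises(self):
        corr = corr_from_weights({("a", "b"): 0.5, ("a", "c"): 0.5})
        with pytest.raises(ValueError, match="overlap"):
            nacc_profile(["a", "b"], ["b", "c"], corr, [0.3],
                         combine_mode="cross_only")

    def test_planted_cross_coupling_detected(self):
        """Cross-block NACC at 0.5 is high with tau=0.7 coupling and ~0
        without, matching the generator's closed form."""
        def run(tau):
            cfg = SyntheticCohortConfig(
                n_datasets=2, samples_per_dataset=200, n_genes=40,
                modules=((10, 0.8), (10, 0.8)),
                cross_couplings=(CrossCoupling(0, 1, tau),),
                covariate_fraction=0.0, seed=5,
            )
            cohort, truth = generate_cohort(cfg)
            corr = CorrelationMatrix.from_dataset(cohort.pooled_values())
            prof = nacc_profile(
                truth.module_genes["M1"], truth.module_genes["M2"], corr,
                [0.5], combine_mode="cross_only",
            )
            return prof.nacc[0]

        assert run(0.7) > 0.8
        assert run(0.0) < 0.05


class TestSubgroupNACCTest:
    @staticmethod
    def coupled_dataset(tau_alt, seed, tau_base=0.0):
        cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=400, n_genes=40,
            modules=((15, 0.8), (15, 0.8)),
            cross_couplings=(CrossCoupling(0, 1, tau_base, tau_alt),),
            covariate_fraction=0.25, seed=seed,
        )
        cohort, truth = generate_cohort(cfg)
        values = cohort.pooled_values()
        labels = truth.covariates
        small = labels.index[labels == "mut"].tolist()
        large = labels.index[labels == "wt"].tolist()
        return truth, values, small, large

    def test_seeded_p_values_reproducible(self):
        truth, values, small, large = self.coupled_dataset(0.8, seed=6)
        kwargs = dict(cutoffs=[0.3, 0.5], n_resample=50, seed=9,
                      combine_mode="cross_only")
        a = subgroup_nacc_test(truth.module_genes["M1"], truth.module_genes["M2"],
                               values, small, large, **kwargs)
        b = subgroup_nacc_test(truth.module_genes["M1"], truth.module_genes["M2"],
                               values, small, large, **kwargs)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_detects_planted_mutant_coupling(self):
        truth, values, small, large = self.coupled_dataset(0.8, seed=7)
        prof = subgroup_nacc_test(
            truth.module_genes["M1"], truth.module_genes["M2"], values,
            small, large, cutoffs=[0.3, 0.4, 0.5, 0.6], n_resample=200,
            seed=1, combine_mode="cross_only",
        )
        assert (prof.p_values < 0.05).all()
        assert (prof.nacc > prof.null_mean).all()

    def test_small_group_larger_than_reference_raises(self):
        truth, values, small, large = self.coupled_dataset(0.0, seed=8)
        with pytest.raises(ValueError, match="exceeds"):
            subgroup_nacc_test(
                truth.module_genes["M1"], truth.module_genes["M2"], values,
                large, small, cutoffs=[0.3], n_resample=10, seed=0,
            )

    def test_reports_null_mean_and_sd(self):
        truth, values, small, large = self.coupled_dataset(0.4, seed=9, tau_base=0.4)
        prof = subgroup_nacc_test(
            truth.module_genes["M1"], truth.module_genes["M2"], values,
            small, large, cutoffs=[0.3, 0.5], n_resample=100, seed=2,
        )
        assert prof.null_mean.shape == (2,)
        assert (prof.null_sd >= 0).all()
        frame = prof.to_frame()
        assert list(frame.columns) == ["cutoff", "nacc", "null_mean", "null_sd", "p"]


class TestQuartileNACC:
    def test_quartile_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(10)
        for n in (35, 40, 61):
            ds = make_dataset(rng.standard_normal((10, n)))
            out = quartile_nacc(["g1", "g2"], ["g3", "g4"], ds, "g5",
                                cutoffs=[0.3], combine_mode="cross_only")
            assert set(out) == {"Q1", "Q2", "Q3", "Q4", "all"}
        # sizes checked indirectly via the partition arithmetic
        sizes = [len(a) for a in np.array_split(np.arange(61), 4)]
        assert max(sizes) - min(sizes) <= 1

    def test_missing_stratifier_raises(self):
        ds = make_dataset(np.random.default_rng(0).standard_normal((5, 40)))
        with pytest.raises(KeyError, match="nope"):
            quartile_nacc(["g1", "g2"], None, ds, "nope", cutoffs=[0.3])

    def test_coupling_tracks_stratifier_quartiles(self):
        """When cross-module coupling is switched on only in 'mut'
        samples, quartiles of a gene tracking that state show higher
        interconnection where coupling is active."""
        cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=400, n_genes=41,
            modules=((15, 0.8), (15, 0.8)),
            cross_couplings=(CrossCoupling(0, 1, 0.0, 0.8),),
            covariate_fraction=0.5, seed=11,
        )
        cohort, truth = generate_cohort(cfg)
        ds = cohort.datasets[0]
        # stratifier: a pseudo-gene anticorrelated with mutant state
        strat = np.where(truth.covariates.to_numpy() == "mut", -1.0, 1.0)
        strat = strat + 0.1 * np.random.default_rng(1).standard_normal(len(strat))
        values = ds.values.copy()
        values.loc["strat"] = strat
        ds2 = make_dataset(values.to_numpy(), gene_ids=values.index.tolist(),
                           sample_ids=ds.sample_ids)
        out = quartile_nacc(
            truth.module_genes["M1"], truth.module_genes["M2"], ds2, "strat",
            cutoffs=[0.4], combine_mode="cross_only",
        )
        assert out["Q1"].nacc[0] > out["Q4"].nacc[0] + 0.3


class TestActivityScores:
    def test_all_gene_module_scores_half(self):
        rng = np.random.default_rng(12)
        ds = make_dataset(rng.standard_normal((9, 7)))
        mod = GeneModule("all", frozenset(ds.gene_ids))
        scores = activity_scores([mod], ds)
        np.testing.assert_allclose(
            scores.sample_scores("all").to_numpy(), (9 + 1) / (2 * 9)
        )

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((20, 10))
        ds = make_dataset(x)
        mod = GeneModule("m", frozenset(["g1", "g2", "g3", "g4", "g5"]))
        base = activity_scores([mod], ds).scores
        y = x.copy()
        y[:, 0] = np.exp(2.0 * y[:, 0]) - 3.0  # strictly increasing, sample 1 only
        transformed = activity_scores([mod], make_dataset(y)).scores
        pd.testing.assert_frame_equal(base, transformed)

    def test_scores_invariant_to_module_gene_order(self):
        rng = np.random.default_rng(14)
        ds = make_dataset(rng.standard_normal((10, 6)))
        a = GeneModule("m", frozenset(["g1", "g2", "g3"]))
        b = GeneModule("m", frozenset(["g3", "g1", "g2"]))
        pd.testing.assert_frame_equal(
            activity_scores([a], ds).scores, activity_scores([b], ds).scores
        )

    def test_expression_sum_mode(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0], [10.0, 10.0]])
        mod = GeneModule("m", frozenset(["g1", "g2"]))
        scores = activity_scores([mod], ds, mode="expression_sum")
        np.testing.assert_allclose(
            scores.sample_scores("m").to_numpy(), [4.0, 6.0]
        )

    def test_mostly_missing_module_raises(self):
        ds = make_dataset(np.zeros((4, 3)) + np.arange(3))
        mod = GeneModule("m", frozenset(["g1", "x1", "x2", "x3"]))
        with pytest.raises(ValueError, match="present"):
            activity_scores([mod], ds)

    def test_partially_missing_module_warns_and_scores_subset(self):
        rng = np.random.default_rng(15)
        ds = make_dataset(rng.standard_normal((6, 5)))
        mod = GeneModule("m", frozenset(["g1", "g2", "g3", "nope"]))
        with pytest.warns(UserWarning, match="3/4"):
            scores = activity_scores([mod], ds)
        expected = activity_scores(
            [GeneModule("m", frozenset(["g1", "g2", "g3"]))], ds
        ).scores
        pd.testing.assert_frame_equal(scores.scores, expected)

    def test_recovers_planted_amplitudes(self):
        cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=200, n_genes=500,
            modules=((20, 0.8),), covariate_fraction=0.0,
            score_amplitude=True, seed=16,
        )
        cohort, truth = generate_cohort(cfg)
        ds = cohort.datasets[0]
        mod = GeneModule("M1", frozenset(truth.module_genes["M1"]))
        scores = activity_scores([mod], ds).sample_scores("M1")
        amplitude = truth.amplitudes.loc["M1"].to_numpy()
        rho, _ = stats.spearmanr(scores.to_numpy(), amplitude)
        assert rho > 0.9


class TestGeneModuleCorrelation:
    def test_monotone_transform_of_score_gives_one(self):
        rng = np.random.default_rng(17)
        ds = make_dataset(rng.standard_normal((10, 30)))
        mod = GeneModule("m", frozenset(["g1", "g2", "g3"]))
        scores = activity_scores([mod], ds)
        s = scores.sample_scores("m").to_numpy()
        values = ds.values.copy()
        values.loc["probe"] = np.exp(s)  # strictly increasing in the score
        ds2 = make_dataset(values.to_numpy(), gene_ids=values.index.tolist())
        assert gene_module_correlation(scores, "m", "probe", ds2) == pytest.approx(1.0)

    def test_independent_gene_near_zero(self):
        rng = np.random.default_rng(18)
        ds = make_dataset(rng.standard_normal((50, 200)))
        mod = GeneModule("m", frozenset([f"g{i}" for i in range(1, 6)]))
        scores = activity_scores([mod], ds)
        rho = gene_module_correlation(scores, "m", "g50", ds)
        assert abs(rho) < 0.2

    def test_loaded_gene_matches_spearmanr_oracle(self):
        cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=150, n_genes=100,
            modules=((10, 0.64),), covariate_fraction=0.0, seed=19,
        )
        cohort, truth = generate_cohort(cfg)
        ds = cohort.datasets[0]
        mod = GeneModule("M1", frozenset(truth.module_genes["M1"]))
        scores = activity_scores([mod], ds)
        gene = truth.module_genes["M1"][0]
        rho = gene_module_correlation(scores, "M1", gene, ds)
        expected, _ = stats.spearmanr(
            scores.sample_scores("M1").to_numpy(), ds.values.loc[gene].to_numpy()
        )
        assert rho == pytest.approx(expected)
        assert rho > 0.5

    def test_constant_gene_flagged(self):
        ds = make_dataset([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        mod = GeneModule("m", frozenset(["g2", "g3"]))
        scores = activity_scores([mod], ds)
        with pytest.raises(ValueError, match="constant"):
            gene_module_correlation(scores, "m", "g1", ds)


class TestDichotomize:
    def test_mean_rule(self):
        ds = make_dataset([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        mod = GeneModule("m", frozenset(["g1", "g2"]))
        scores = activity_scores([mod], ds, mode="expression_sum")
        labels = dichotomize_scores(scores, "m")
        assert labels.tolist() == ["below", "below", "above"]

    def test_all_equal_scores_all_below(self):
        ds = make_dataset([[2.0, 2.0, 2.0]])
        mod = GeneModule("m", frozenset(["g1"]))
        scores = activity_scores([mod], ds, mode="expression_sum")
        assert dichotomize_scores(scores, "m").tolist() == ["below"] * 3

    def test_affine_invariance(self):
        rng = np.random.default_rng(20)
        ds = make_dataset(rng.standard_normal((5, 12)))
        mod = GeneModule("m", frozenset(["g1", "g2"]))
        scores = activity_scores([mod], ds, mode="expression_sum")
        labels = dichotomize_scores(scores, "m")
        scaled = activity_scores([mod], ds, mode="expression_sum")
        scaled.scores = scaled.scores * 3.5 + 11.0
        pd.testing.assert_series_equal(labels, dichotomize_scores(scaled, "m"))


class TestModuleConservation:
    def test_identical_matrices_keep_whole_module(self):
        genes = [f"g{i}" for i in range(6)]
        corr = corr_from_weights({p: 0.8 for p in itertools.combinations(genes, 2)})
        mod = GeneModule("m", frozenset(genes))
        core = module_conservation(mod, corr, corr, cutoff=0.6)
        assert core.core_genes == frozenset(genes)
        assert len(core.conserved_edges) == 15

    def test_independent_other_matrix_empty_core(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(8)]
        corr_src = corr_from_weights(
            {p: 0.8 for p in itertools.combinations(genes, 2)}
        )
        other_ds = make_dataset(rng.standard_normal((8, 100)), gene_ids=genes)
        corr_other = CorrelationMatrix.from_dataset(other_ds.values)
        mod = GeneModule("m", frozenset(genes))
        core = module_conservation(mod, corr_src, corr_other, cutoff=0.6)
        assert core.core_genes == frozenset()
        assert len(core.conserved_edges) == 0

    def test_planted_shared_core_recovered_exactly(self):
        """20-gene module in the source; only 5 of the genes share a
        factor in the second dataset -> conserved core = those 5."""
        src_cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=300, n_genes=100,
            modules=((20, 0.8),), covariate_fraction=0.0, seed=22,
        )
        other_cfg = SyntheticCohortConfig(
            n_datasets=1, samples_per_dataset=300, n_genes=100,
            modules=((5, 0.8),), covariate_fraction=0.0, seed=23,
        )
        src_cohort, src_truth = generate_cohort(src_cfg)
        other_cohort, other_truth = generate_cohort(other_cfg)
        corr_src = CorrelationMatrix.from_dataset(src_cohort.pooled_values())
        corr_other = CorrelationMatrix.from_dataset(other_cohort.pooled_values())
        mod = GeneModule("basal", frozenset(src_truth.module_genes["M1"]))
        core = module_conservation(mod, corr_src, corr_other, cutoff=0.6)
        assert core.core_genes == frozenset(other_truth.module_genes["M1"])
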