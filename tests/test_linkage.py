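"""Joint linkage mapping: nested design, permutation threshold, stepwise
selection (with an exhaustive-enumeration oracle), effects, support
intervals."""

import numpy as np
import pandas as pd
import pytest
from oracles import random_design, stable_subsets

import nilqtl as nq
from nilqtl import linkage
from nilqtl.linkage import (
    _added_group_test,
    _basis,
    build_nested_design,
    fit_final_model,
    stepwise_select,
)


def noiseless_dataset(seed=101, effect=1.5, n_pop=3, n_lines=60, n_mark=21):
    cfg = nq.SimConfig(
        n_populations=n_pop, lines_per_population=n_lines,
        chromosomes=[(100.0, n_mark)], traits=("y",),
        qtl=[nq.PlantedQTL(1, 50.0, {"y": effect})],
        residual_sd=0.0, env_effect_sd=0.0, gxe_sd=0.0, rep_sd=0.0,
        pop_mean_sd=0.5, monomorphic_fraction=0.0,
        environments=1, reps_per_environment=1, seed=seed,
    )
    geno, gmap, pheno = nq.simulate_dataset(cfg)
    means = nq.compute_line_means(pheno)
    return cfg, geno, gmap, means


class TestDesign:
    def test_group_column_counts_follow_polymorphism(self, small_dataset,
                                                     small_means):
        _, geno, gmap, _ = small_dataset
        design = build_nested_design(small_means, geno, gmap, "y")
        mask = nq.polymorphic_mask(geno)
        for m, g in design.groups.items():
            assert g.cols.shape[1] == int(mask[m].sum())
            assert len(g.pops) == g.cols.shape[1]
            assert (g.cols.std(axis=0) > 0).all()

    def test_monomorphic_marker_excluded(self):
        cfg, geno, gmap, means = noiseless_dataset()
        geno.dosage[:, 0] = 0.0
        design = build_nested_design(means, geno, gmap, "y")
        assert gmap.markers[0] not in design.groups

    def test_population_block_coding(self, small_dataset, small_means):
        _, geno, gmap, _ = small_dataset
        design = build_nested_design(small_means, geno, gmap, "y")
        assert design.base.shape[1] == len(design.pop_levels)  # intercept + P-1
        assert (design.base[:, 0] == 1).all()

    def test_unknown_trait_raises(self, small_dataset, small_means):
        _, geno, gmap, _ = small_dataset
        with pytest.raises(KeyError, match="zzz"):
            build_nested_design(small_means, geno, gmap, "zzz")


class TestPermutationThreshold:
    def test_quantile_is_first_order_statistic_at_20_perms(self, small_dataset,
                                                           small_means):
        _, geno, gmap, _ = small_dataset
        design = build_nested_design(small_means, geno, gmap, "y")
        thr, minima = linkage.permutation_threshold(
            design, n_perm=20, alpha=0.05, seed=9, return_minima=True)
        assert thr == np.sort(minima)[0]

    def test_same_seed_same_threshold(self, small_dataset, small_means):
        _, geno, gmap, _ = small_dataset
        design = build_nested_design(small_means, geno, gmap, "y")
        a = linkage.permutation_threshold(design, 50, 0.05, seed=3)
        b = linkage.permutation_threshold(design, 50, 0.05, seed=3)
        assert a == b

    def test_too_few_permutations_rejected(self, small_dataset, small_means):
        _, geno, gmap, _ = small_dataset
        design = build_nested_design(small_means, geno, gmap, "y")
        with pytest.raises(ValueError, match=">= 20"):
            linkage.permutation_threshold(design, n_perm=10)


class TestStepwise:
    def test_noiseless_selects_causal_marker(self):
        cfg, geno, gmap, means = noiseless_dataset()
        design = build_nested_design(means, geno, gmap, "y")
        res = stepwise_select(design, p_enter=1e-6)
        assert res.selected == ["c1m010"]

    def test_zero_entry_threshold_gives_empty_model(self):
        cfg, geno, gmap, means = noiseless_dataset()
        design = build_nested_design(means, geno, gmap, "y")
        res = stepwise_select(design, p_enter=0.0)
        assert res.selected == []

    def test_pure_noise_candidates_do_not_displace_causal(self, rng):
        cfg, geno, gmap, means = noiseless_dataset()
        # scramble all other chromosome-half markers into pure noise
        causal = gmap.marker_index("c1m010")
        for j in range(geno.n_markers):
            if abs(j - causal) > 3:
                geno.dosage[:, j] = rng.choice([0, 2], size=geno.n_lines,
                                               p=[0.9, 0.1])
        design = build_nested_design(means, geno, gmap, "y")
        res = stepwise_select(design, p_enter=1e-6)
        assert "c1m010" in res.selected

    @pytest.mark.parametrize("causal_effect", [0.0, 1.2])
    def test_matches_exhaustive_stable_subset_enumeration(self, causal_effect):
        rng = np.random.default_rng(17 + int(causal_effect * 10))
        agreement = 0
        for trial in range(20):
            design = random_design(rng, causal_effect=causal_effect)
            res = stepwise_select(design, p_enter=0.05)
            stable = stable_subsets(design, 0.05, 0.05)
            assert frozenset(res.selected) in stable
            if len(stable) == 1:
                agreement += 1
        assert agreement > 0  # unique-solution cases occur and are matched

    def test_model_r2_never_decreases_along_forward_path(self):
        cfg, geno, gmap, means = noiseless_dataset(effect=0.8)
        design = build_nested_design(means, geno, gmap, "y")
        res = stepwise_select(design, p_enter=0.5, p_exit=1.0)
        r2 = []
        for k in range(len(res.selected) + 1):
            fitted = fit_final_model(design, res.selected[:k])
            r2.append(fitted.model_r2)
        assert np.all(np.diff(r2) >= -1e-12)


class TestFinalModel:
    def test_noiseless_effect_recovered_exactly(self):
        cfg, geno, gmap, means = noiseless_dataset(effect=1.5)
        design = build_nested_design(means, geno, gmap, "y")
        fitted = fit_final_model(design, ["c1m010"])
        for p in design.pop_levels:
            name = f"c1m010:{p}"
            if name in fitted.coef.index:
                assert fitted.coef[name] == pytest.approx(1.5, abs=1e-8)

    def test_mixed_sign_population_effects_recovered(self):
        effects = [1.5, -1.5, 1.0, -1.0, 1.2]
        cfg = nq.SimConfig(
            n_populations=5, lines_per_population=80,
            chromosomes=[(100.0, 21)], traits=("y",),
            qtl=[nq.PlantedQTL(1, 50.0, {"y": effects})],
            residual_sd=0.1, env_effect_sd=0.0, gxe_sd=0.0, rep_sd=0.0,
            pop_mean_sd=0.0, monomorphic_fraction=0.0,
            environments=1, reps_per_environment=1, seed=300,
        )
        geno, gmap, pheno = nq.simulate_dataset(cfg)
        means = nq.compute_line_means(pheno)
        design = build_nested_design(means, geno, gmap, "y")
        fitted = fit_final_model(design, ["c1m010"])
        signs = []
        for p, e in zip(design.pop_levels, effects):
            name = f"c1m010:{p}"
            if name in fitted.coef.index:
                assert fitted.coef[name] == pytest.approx(e, abs=0.2)
                if fitted.pvalues[name] < 0.05:
                    signs.append(np.sign(fitted.coef[name]))
        assert {1.0, -1.0} <= set(signs)  # allelic series: both signs significant

    def test_population_without_introgression_reported_nd(self):
        cfg, geno, gmap, means = noiseless_dataset()
        # erase the introgression around the QTL in population 1
        sel = geno.populations == "Z001"
        causal = gmap.marker_index("c1m010")
        geno.dosage[np.ix_(sel, range(causal - 3, causal + 4))] = 0.0
        # rebuild phenotype-free mapping on the altered genotypes
        mapper = nq.JointLinkageMapper(p_enter=1e-6, compute_intervals=False
                                       ).fit(means, geno, gmap, "y")
        if len(mapper.qtl_):
            row = mapper.qtl_.iloc[0]
            assert row["effect[Z001]"] == "n.d."


class TestSupportInterval:
    def test_interval_contains_peak_and_respects_bounds(self, small_dataset,
                                                        small_means):
        _, geno, gmap, _ = small_dataset
        mapper = nq.JointLinkageMapper(p_enter=1e-4).fit(
            small_means, geno, gmap, "y")
        assert len(mapper.qtl_) >= 1
        for _, row in mapper.qtl_.iterrows():
            assert row["SI_left_cM"] <= row["peak_cM"] <= row["SI_right_cM"]
            lo, hi = gmap.span(int(row["chrom"]))
            assert lo <= row["SI_left_cM"] and row["SI_right_cM"] <= hi

    def test_peak_pseudomarker_is_aliased_never_significant(self):
        cfg, geno, gmap, means = noiseless_dataset(effect=1.0)
        design = build_nested_design(means, geno, gmap, "y")
        fitted = fit_final_model(design, ["c1m010"])
        Qf = _basis(fitted.X)
        d = nq.expected_dosage_at(geno, gmap, 1, 50.0)[design.geno_rows]
        cols = []
        for p in design.pop_levels:
            v = np.zeros(design.n)
            v[design.populations == p] = d[design.populations == p]
            cols.append(v)
        _, pval, q = _added_group_test(design.y, Qf, np.column_stack(cols))
        assert q == 0  # perfectly aliased with the fitted peak group


class TestSummaries:
    def test_zero_selected_markers_gives_empty_table(self, small_dataset,
                                                     small_means):
        _, geno, gmap, _ = small_dataset
        mapper = nq.JointLinkageMapper(p_enter=0.0).fit(
            small_means, geno, gmap, "y")
        qtl, summary = nq.summarize_qtl({"y": mapper})
        assert len(qtl) == 0
        assert summary.loc[0, "n_qtl"] == 0
        # population-only model still has an R^2
        assert 0.0 <= mapper.model_r2_ <= 1.0

    def test_counts_column_matches_significant_populations(self, small_dataset,
                                                           small_means):
        _, geno, gmap, _ = small_dataset
        mapper = nq.JointLinkageMapper(p_enter=1e-4, compute_intervals=False
                                       ).fit(small_means, geno, gmap, "y")
        for _, row in mapper.qtl_.iterrows():
            n = sum(
                1 for p in pd.unique(geno.populations)
                if row[f"p[{p}]"] != "n.d." and float(row[f"p[{p}]"]) < 0.05
            )
            assert row["n_significant_pops"] == n
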