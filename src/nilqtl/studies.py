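"""Simulation studies validating the mapping pipeline's statistical behavior.

Each study generates data with the BC4S2 simulator, runs the corresponding
analysis stage exactly as a user would, and measures an operating
characteristic: genome-wide type-I error of the permutation-calibrated scan,
additive-effect recovery and support-interval coverage, entry-mean
heritability recovery, false pleiotropy-edge rate under an independent-effects
null, and power to detect a planted shared QTL. They are used by the test
suite and by ``scripts/acceptance.py``; problem sizes are chosen so each study
runs in minutes on one core.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import PlantedQTL, SimConfig
from . import simulate as sim
from .linkage import (
    JointLinkageMapper,
    build_nested_design,
    fit_final_model,
    permutation_threshold,
    stepwise_select,
    support_interval,
)
from .phenotypes import compute_line_means, estimate_variance_components
from .pleiotropy import PleiotropyAnalyzer


def _line_means_quiet(pheno: pd.DataFrame) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*single plot.*")
        return compute_line_means(pheno)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def type_one_error_study(n_runs: int = 200, n_perm: int = 100,
                         alpha: float = 0.05, seed: int = 0,
                         n_populations: int = 2, lines_per_population: int = 100,
                         n_markers: int = 40) -> dict:
    """Genome-wide false-positive rate of the permutation-calibrated scan.

    Each run simulates genotypes with NO planted QTL, draws a pure-noise
    trait, calibrates the entry threshold by permutation, and records whether
    the stepwise scan declares at least one QTL.
    """
    hits = 0
    for s in _seeds(seed, n_runs):
        cfg = SimConfig(
            n_populations=n_populations,
            lines_per_population=lines_per_population,
            chromosomes=[(100.0, n_markers)], traits=("y",),
            residual_sd=1.0, env_effect_sd=0.0, gxe_sd=0.0, rep_sd=0.0,
            pop_mean_sd=0.3, monomorphic_fraction=0.0,
            environments=1, reps_per_environment=1, seed=int(s),
        )
        geno, gmap, pheno = sim.simulate_dataset(cfg)
        means = _line_means_quiet(pheno)
        design = build_nested_design(means, geno, gmap, "y")
        thr = permutation_threshold(design, n_perm, alpha, seed=int(s) + 1)
        res = stepwise_select(design, thr)
        hits += bool(res.selected)
    return {"false_positive_rate": hits / n_runs, "n_runs": n_runs,
            "alpha": alpha}


def effect_recovery_study(n_runs: int = 100, seed: int = 0,
                          n_populations: int = 5,
                          lines_per_population: int = 100,
                          variance_fraction: float = 0.10,
                          effect: float = 1.0) -> dict:
    """Additive-effect recovery and support-interval coverage for one planted
    QTL explaining ``variance_fraction`` of the line-mean variance.

    The residual SD is sized from the BC4S2 dosage variance
    (E[d] = 1/16, E[d^2] = 7/64) so the QTL explains the requested fraction
    in expectation. Reports the mean estimated effect (averaged over
    populations and runs, taken at the selected QTL nearest the planted
    position), its Monte-Carlo SE, and the fraction of runs whose support
    interval covers the planted position.
    """
    var_d = 7 / 64 - (1 / 16) ** 2
    var_q = effect ** 2 * var_d
    resid_sd = float(np.sqrt(var_q * (1 - variance_fraction) / variance_fraction))
    true_pos = 50.0
    estimates, covered, found = [], 0, 0
    for s in _seeds(seed, n_runs):
        cfg = SimConfig(
            n_populations=n_populations,
            lines_per_population=lines_per_population,
            chromosomes=[(100.0, 51)], traits=("y",),
            qtl=[PlantedQTL(1, true_pos, {"y": effect})],
            residual_sd=resid_sd, env_effect_sd=0.0, gxe_sd=0.0, rep_sd=0.0,
            pop_mean_sd=0.0, monomorphic_fraction=0.0,
            environments=1, reps_per_environment=1, seed=int(s),
        )
        geno, gmap, pheno = sim.simulate_dataset(cfg)
        means = _line_means_quiet(pheno)
        design = build_nested_design(means, geno, gmap, "y")
        res = stepwise_select(design, p_enter=1e-4)
        if not res.selected:
            continue
        found += 1
        peak = min(res.selected,
                   key=lambda m: abs(design.groups[m].pos_cM - true_pos))
        fitted = fit_final_model(design, res.selected)
        for p in design.groups[peak].pops:
            name = f"{peak}:{p}"
            if name in fitted.coef.index:
                estimates.append(fitted.coef[name])
        left, right = support_interval(fitted, peak, geno, gmap,
                                       step_cM=0.1, alpha=0.05)
        covered += left <= true_pos <= right
    estimates = np.asarray(estimates)
    return {
        "true_effect": effect,
        "mean_effect": float(estimates.mean()),
        "se_mean_effect": float(estimates.std(ddof=1) / np.sqrt(n_runs)),
        "si_coverage": covered / found if found else np.nan,
        "detection_rate": found / n_runs,
        "n_runs": n_runs,
    }


def heritability_recovery_study(targets=(0.3, 0.7, 0.9), seed: int = 0,
                                n_populations: int = 5,
                                lines_per_population: int = 100,
                                environments: int = 2, reps: int = 2,
                                n_replicates: int = 20) -> dict:
    """Recovery of planted entry-mean heritability.

    Genotypes are simulated first; the GxE and residual SDs are then solved
    so the realized genetic variance hits each H2 target exactly, with the
    non-genetic entry-mean variance split 30% GxE / 70% residual (keeping
    each planted component well above its own sampling noise, so the
    zero-truncation of negative moment estimates stays inactive). A single
    500-line draw's H2 estimate has a Monte-Carlo sd of ~0.04 at low H2 and
    a small-sample downward (Jensen) ratio bias, so variance components are
    averaged over ``n_replicates`` independent draws before forming the
    ratio.
    """
    out = {}
    for target, s0 in zip(targets, _seeds(seed, len(targets))):
        ests = []
        for s in _seeds(int(s0), n_replicates):
            cfg = SimConfig(
                n_populations=n_populations,
                lines_per_population=lines_per_population,
                chromosomes=[(100.0, 21)], traits=("y",),
                qtl=[PlantedQTL(1, 50.0, {"y": 2.0})],
                residual_sd=1.0, env_effect_sd=0.2, gxe_sd=0.0, rep_sd=0.1,
                pop_mean_sd=0.0, monomorphic_fraction=0.0,
                environments=environments, reps_per_environment=reps,
                seed=int(s),
            )
            gmap = sim.simulate_map(cfg)
            geno = sim.simulate_population_genotypes(cfg, gmap)
            var_g = float(np.var(sim.genetic_values(cfg, geno, gmap)["y"],
                                 ddof=1))
            # H2 = vg / (vg + K) with K = s2_GE/E + s2_err/(E R)
            K = var_g * (1 / target - 1)
            cfg.gxe_sd = float(np.sqrt(0.3 * K * environments))
            cfg.residual_sd = float(np.sqrt(0.7 * K * environments * reps))
            pheno = sim.simulate_phenotypes(cfg, geno, gmap)
            vc = estimate_variance_components(pheno)
            ests.append(vc.table.loc["y"])
        avg = pd.concat(ests, axis=1).mean(axis=1)
        h2 = avg["sigma2_g"] / (avg["sigma2_g"] + avg["sigma2_ge"] / environments
                                + avg["sigma2_err"] / (environments * reps))
        out[target] = float(h2)
    return out


def segregation_study(seed: int = 0, n_lines: int = 3000) -> dict:
    """Realized BC4S2 donor-genome fraction and adjacent-marker recombination
    versus the Haldane expectation (from >= 10^4 simulated gametes)."""
    cfg = SimConfig(n_populations=2, lines_per_population=n_lines // 2,
                    chromosomes=[(150.0, 16)], traits=("y",),
                    monomorphic_fraction=0.0, seed=seed)
    geno = sim.simulate_population_genotypes(cfg, sim.simulate_map(cfg))
    frac = geno.dosage.mean(axis=1) / 2
    rec = {}
    rng = np.random.default_rng(seed + 1)
    for d in (1.0, 10.0, 50.0):
        pos = np.array([0.0, d])
        hap_a, hap_b = np.zeros(2, dtype=np.int8), np.ones(2, dtype=np.int8)
        n_gam = 20_000
        r_obs = sum(
            int(g[0] != g[1])
            for g in (sim.meiosis_gamete(hap_a, hap_b, pos, d, rng)
                      for _ in range(n_gam))
        ) / n_gam
        rec[d] = {"observed": r_obs,
                  "expected": float(0.5 * (1 - np.exp(-2 * d / 100)))}
    return {
        "donor_fraction_mean": float(frac.mean()),
        "donor_fraction_se": float(frac.std(ddof=1) / np.sqrt(len(frac))),
        "expected_donor_fraction": 1 / 32,
        "recombination": rec,
    }


def _synthetic_qtl_tables(rng, n_pairs: int, n_pops: int, rho: float):
    """Two traits with n_pairs QTL each on separate chromosomes; QTL i of
    trait A overlaps only QTL i of trait B. Effect vectors are bivariate
    normal with correlation rho (rho=0: independent-effects null)."""
    pops = [f"Z{k:03d}" for k in range(1, n_pops + 1)]
    qa, qb, ea, eb = [], [], [], []
    for i in range(n_pairs):
        qa.append({"trait": "t1", "chrom": i + 1, "peak_marker": f"a{i}",
                   "peak_cM": 20.0, "SI_left_cM": 10.0, "SI_right_cM": 30.0})
        qb.append({"trait": "t2", "chrom": i + 1, "peak_marker": f"b{i}",
                   "peak_cM": 25.0, "SI_left_cM": 15.0, "SI_right_cM": 35.0})
        z1 = rng.normal(size=n_pops)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n_pops)
        for p, v1, v2 in zip(pops, z1, z2):
            ea.append({"trait": "t1", "peak_marker": f"a{i}", "population": p,
                       "effect": v1})
            eb.append({"trait": "t2", "peak_marker": f"b{i}", "population": p,
                       "effect": v2})
    return ({"t1": pd.DataFrame(qa), "t2": pd.DataFrame(qb)},
            {"t1": pd.DataFrame(ea), "t2": pd.DataFrame(eb)})


def fdr_null_study(n_runs: int = 200, n_pairs: int = 10, n_pops: int = 10,
                   q: float = 0.05, seed: int = 0) -> dict:
    """False pleiotropy-edge rate when overlapping QTL have independently
    drawn effect vectors (no true effect correlation)."""
    rng = np.random.default_rng(seed)
    flagged = tested = 0
    for _ in range(n_runs):
        qtl, eff = _synthetic_qtl_tables(rng, n_pairs, n_pops, rho=0.0)
        res = PleiotropyAnalyzer(q=q).fit(qtl, eff)
        tested += int(res.edges_["p"].notna().sum())
        flagged += int(res.edges_["significant"].sum())
    rate = flagged / tested
    return {"edge_rate": rate, "n_tested": tested, "q": q,
            "mc_se": float(np.sqrt(rate * (1 - rate) / tested)) if rate > 0
            else float(np.sqrt(q * (1 - q) / tested))}


def pleiotropy_power_study(n_runs: int = 100, seed: int = 0,
                           n_populations: int = 10,
                           lines_per_population: int = 60) -> dict:
    """Power to recover a planted shared QTL with proportional per-population
    effects on two traits as a significant positive pleiotropy edge.

    Runs the real mapping path per trait (stepwise selection, final model,
    support intervals) before the effect-correlation test.
    """
    detected = 0
    base = np.linspace(0.8, 2.0, n_populations)
    for s in _seeds(seed, n_runs):
        rng = np.random.default_rng(int(s))
        eff_a = rng.permutation(base)
        eff_b = 0.6 * eff_a                      # proportional -> r = 1
        cfg = SimConfig(
            n_populations=n_populations,
            lines_per_population=lines_per_population,
            chromosomes=[(60.0, 13)], traits=("u", "v"),
            qtl=[PlantedQTL(1, 30.0, {"u": eff_a, "v": eff_b})],
            residual_sd=0.25, env_effect_sd=0.0, gxe_sd=0.0, rep_sd=0.0,
            pop_mean_sd=0.2, monomorphic_fraction=0.0,
            environments=1, reps_per_environment=1, seed=int(s),
        )
        geno, gmap, pheno = sim.simulate_dataset(cfg)
        means = _line_means_quiet(pheno)
        mappers = {}
        for trait in ("u", "v"):
            mappers[trait] = JointLinkageMapper(
                p_enter=1e-3, step_cM=0.5, seed=int(s)
            ).fit(means, geno, gmap, trait)
        res = PleiotropyAnalyzer(q=0.05).fit(
            {t: m.qtl_ for t, m in mappers.items()},
            {t: m.effects_ for t, m in mappers.items()})
        sig = res.edges_[(res.edges_["significant"]) &
                         (res.edges_["sign"] == "positive")]
        detected += len(sig) > 0
    return {"detection_rate": detected / n_runs, "n_runs": n_runs}
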