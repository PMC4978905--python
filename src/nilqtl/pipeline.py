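"""End-to-end orchestration: simulate/load -> impute -> line means -> PCA ->
joint linkage mapping -> pleiotropy, with a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import linkage, pca, phenotypes, pleiotropy, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run: either a simulation config or paths
    to a genotype TSV / map TSV / phenotype CSV."""

    outdir: Path
    sim: simulate.SimConfig | None = None
    genotype_path: Path | None = None
    map_path: Path | None = None
    phenotype_path: Path | None = None
    traits: list[str] | None = None
    pca_traits: list[str] | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    q_fdr: float = 0.05
    si_step_cM: float = 0.1
    compute_intervals: bool = True
    seed: int = 0

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        has_files = all(p is not None for p in
                        (self.genotype_path, self.map_path, self.phenotype_path))
        if (self.sim is None) == (not has_files):
            raise ValueError("provide either a simulation config or all three "
                             "input paths, not both/neither")


def load_run_config(path, outdir=None, seed: int | None = None) -> RunConfig:
    """Read a RunConfig from TOML. Top-level keys mirror RunConfig fields; a
    ``[sim]`` table holds SimConfig fields, with ``[[sim.qtl]]`` entries of
    chromosome / position_cM / trait_effects."""
    import tomllib
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = None
    if "sim" in raw:
        s = raw.pop("sim")
        qtl = [simulate.PlantedQTL(q["chromosome"], q["position_cM"],
                                   q["trait_effects"])
               for q in s.pop("qtl", [])]
        if "chromosomes" in s:
            s["chromosomes"] = [tuple(c) for c in s["chromosomes"]]
        sim = simulate.SimConfig(qtl=qtl, **s)
    for k in ("genotype_path", "map_path", "phenotype_path"):
        if k in raw:
            raw[k] = Path(raw[k])
    cfg = RunConfig(outdir=Path(outdir or raw.pop("outdir", "nilqtl-run")),
                    sim=sim, **{k: v for k, v in raw.items() if k != "outdir"})
    if seed is not None:
        cfg.seed = seed
        if cfg.sim is not None:
            cfg.sim.seed = seed
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes every interface file plus ``manifest.json``
    (stages, parameters, realized thresholds, file checksums). Any stage
    failure aborts with the stage name attached."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "parameters": {
        "n_perm": config.n_perm, "alpha": config.alpha,
        "q_fdr": config.q_fdr, "seed": config.seed,
        "si_step_cM": config.si_step_cM,
        "permutation_scheme": "within-population shuffle",
    }, "files": {}}
    stage = "init"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "simulate" if config.sim else "load"
        t0 = time.time()
        if config.sim:
            geno, gmap, plots = simulate.simulate_dataset(config.sim)
            paths = simulate.write_dataset(geno, gmap, plots, out / "inputs")
            for k, p in paths.items():
                manifest["files"][f"inputs/{p.name}"] = _sha256(p)
        else:
            geno, gmap = gt.load_dataset(config.genotype_path, config.map_path)
            plots = pd.read_csv(config.phenotype_path)
        manifest["stages"].append({"stage": stage, "seconds": time.time() - t0,
                                   "n_lines": int(geno.n_lines),
                                   "n_markers": int(geno.n_markers)})

        # ---- impute -------------------------------------------------------
        stage = "impute"
        t0 = time.time()
        imputer = gt.FlankingImputer(gmap)
        geno = imputer.fit_transform(geno)
        imputer.audit_.to_csv(out / "imputation_audit.tsv", sep="\t", index=False)
        manifest["stages"].append({
            "stage": stage, "seconds": time.time() - t0,
            "n_imputed_cells": int(imputer.imputed_mask_.sum())})

        # ---- line means / heritability / derived traits -------------------
        stage = "prep"
        t0 = time.time()
        means = phenotypes.compute_line_means(plots)
        vc = phenotypes.estimate_variance_components(plots)
        h2 = phenotypes.heritability(vc)
        means = phenotypes.derive_traits(means)
        trait_cols = [c for c in means.columns if c not in ("line_id", "population")]
        desc, rmat, pmat = phenotypes.trait_framework(means, trait_cols)
        desc = desc.merge(h2.rename("H2"), left_on="trait", right_index=True,
                          how="left")
        means.to_csv(out / "line_means.csv", index=False)
        desc.to_csv(out / "trait_stats.csv", index=False)
        phenotypes.correlation_stars(rmat, pmat).to_csv(out / "trait_correlations.csv")
        vc.table.to_csv(out / "variance_components.csv")
        manifest["stages"].append({"stage": stage, "seconds": time.time() - t0,
                                   "n_lines": int(len(means))})

        # ---- PCA traits ---------------------------------------------------
        stage = "pca"
        t0 = time.time()
        pca_traits = config.pca_traits or trait_cols
        if len(pca_traits) >= 2:
            model = pca.KernelTraitPCA(traits=pca_traits).fit(means)
            means = pca.score_lines(model, means)
            model.loadings_frame().to_csv(out / "pca_loadings.csv")
            model.scree_frame().to_csv(out / "pca_scree.csv", index=False)
            means.to_csv(out / "line_means_with_pcs.csv", index=False)
            n_retained = model.n_retained_
            manifest["stages"].append({
                "stage": stage, "seconds": time.time() - t0,
                "n_retained": n_retained,
                "eigenvalues": [round(float(e), 4) for e in model.eigenvalues_]})
        else:
            logger.warning("fewer than 2 traits; PCA stage skipped")
            n_retained = 0
            manifest["stages"].append({"stage": stage, "skipped": True,
                                       "seconds": time.time() - t0})

        # ---- joint linkage mapping ----------------------------------------
        stage = "map-qtl"
        t0 = time.time()
        map_traits = config.traits or (
            trait_cols + [f"PC{k + 1}" for k in range(n_retained)])
        seeds = np.random.SeedSequence([config.seed, 5]).generate_state(len(map_traits))
        mappers: dict[str, linkage.JointLinkageMapper] = {}
        for trait, s in zip(map_traits, seeds):
            mappers[trait] = linkage.JointLinkageMapper(
                n_permutations=config.n_perm, alpha=config.alpha,
                step_cM=config.si_step_cM, si_alpha=0.05,
                seed=int(s % (2 ** 31)),
                compute_intervals=config.compute_intervals,
            ).fit(means, geno, gmap, trait)
            logger.info("%s: %d QTL, threshold %.4g", trait,
                        len(mappers[trait].selected_), mappers[trait].threshold_)
        qtl, summary = linkage.summarize_qtl(mappers)
        qtl.to_csv(out / "qtl_table.csv", index=False)
        summary.to_csv(out / "model_summary.csv", index=False)
        effects = pd.concat([m.effects_ for m in mappers.values()],
                            ignore_index=True) if mappers else pd.DataFrame()
        effects.to_csv(out / "qtl_effects.csv", index=False)
        manifest["stages"].append({
            "stage": stage, "seconds": time.time() - t0,
            "thresholds": {t: float(m.threshold_) for t, m in mappers.items()},
            "n_qtl": {t: len(m.selected_) for t, m in mappers.items()}})

        # ---- pleiotropy ---------------------------------------------------
        stage = "pleiotropy"
        t0 = time.time()
        qtl_tables = {t: m.qtl_ for t, m in mappers.items()}
        effect_tables = {t: m.effects_ for t, m in mappers.items()}
        pl = pleiotropy.PleiotropyAnalyzer(q=config.q_fdr).fit(
            qtl_tables, effect_tables)
        pl.edges_.to_csv(out / "pleiotropy_edges.csv", index=False)
        pleiotropy.network_edge_list(pl.graph_).to_csv(
            out / "pleiotropy_network.csv", index=False)
        manifest["stages"].append({
            "stage": stage, "seconds": time.time() - t0,
            "bh_cutoff": pl.cutoff_,
            "n_tested_pairs": int(pl.edges_["p"].notna().sum()),
            "n_significant": int(pl.edges_["significant"].sum())})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_report(artifact_dir) -> Path:
    """Summary text + figures from a completed run directory; missing stage
    outputs produce a partial report with warnings, not a crash."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    art = Path(artifact_dir)
    lines: list[str] = ["# nilqtl run report", ""]

    def have(name: str) -> bool:
        return (art / name).exists()

    if have("trait_stats.csv"):
        stats = pd.read_csv(art / "trait_stats.csv")
        lines.append("## Trait descriptives and heritability")
        lines.append(stats.to_string(index=False))
        lines.append("")
    else:
        lines.append("WARNING: trait_stats.csv missing")

    if have("pca_scree.csv"):
        scree = pd.read_csv(art / "pca_scree.csv")
        lines.append("## PCA variance explained")
        lines.append(scree.to_string(index=False))
        lines.append("")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(scree["component"], scree["eigenvalue"])
        ax.axhline(1.0, ls="--", c="k", lw=0.8)
        ax.set_ylabel("eigenvalue")
        fig.tight_layout()
        fig.savefig(art / "fig_scree.png", dpi=120)
        plt.close(fig)

    if have("pca_loadings.csv"):
        load = pd.read_csv(art / "pca_loadings.csv", index_col=0)
        k = min(3, load.shape[1])
        fig, axes = plt.subplots(1, k, figsize=(4 * k, 3), squeeze=False)
        for j in range(k):
            axes[0, j].bar(load.index, load.iloc[:, j])
            axes[0, j].set_title(load.columns[j])
            axes[0, j].tick_params(axis="x", rotation=60)
        fig.tight_layout()
        fig.savefig(art / "fig_loadings.png", dpi=120)
        plt.close(fig)

    n_qtl_total = 0
    if have("qtl_table.csv"):
        qtl = pd.read_csv(art / "qtl_table.csv")
        n_qtl_total = len(qtl)
        lines.append("## QTL per trait")
        if len(qtl):
            counts = qtl.groupby("trait").size().rename("n_qtl")
            lines.append(counts.to_string())
            fig, ax = plt.subplots(figsize=(7, 3))
            for _, r in qtl.iterrows():
                ax.plot([r["SI_left_cM"], r["SI_right_cM"]],
                        [r["chrom"], r["chrom"]], lw=3, alpha=0.6)
                ax.plot(r["peak_cM"], r["chrom"], "k|", ms=10)
            ax.set_xlabel("cM")
            ax.set_ylabel("chromosome")
            fig.tight_layout()
            fig.savefig(art / "fig_qtl_map.png", dpi=120)
            plt.close(fig)
        else:
            lines.append("zero QTL detected")
        lines.append("")

    if have("qtl_effects.csv"):
        eff = pd.read_csv(art / "qtl_effects.csv")
        if len(eff):
            piv = eff.pivot_table(index="population",
                                  columns=["trait", "peak_marker"],
                                  values="effect")
            fig, ax = plt.subplots(figsize=(max(4, 0.4 * piv.shape[1]), 3.5))
            im = ax.imshow(piv.to_numpy(float), aspect="auto", cmap="RdBu_r")
            ax.set_yticks(range(len(piv.index)), piv.index)
            ax.set_xticks([])
            ax.set_xlabel("QTL (trait x peak)")
            fig.colorbar(im, ax=ax, label="additive effect vs B73")
            fig.tight_layout()
            fig.savefig(art / "fig_effects_heatmap.png", dpi=120)
            plt.close(fig)

    if have("pleiotropy_network.csv"):
        import networkx as nx
        net = pd.read_csv(art / "pleiotropy_network.csv")
        lines.append("## Pleiotropy network")
        lines.append(net.to_string(index=False) if len(net) else "no significant edges")
        lines.append("")
        if len(net):
            g = nx.Graph()
            for _, r in net.iterrows():
                g.add_edge(r["trait_A"], r["trait_B"], weight=r["weight"],
                           sign=r["sign"])
            fig, ax = plt.subplots(figsize=(5, 5))
            pos = nx.circular_layout(g)
            colors = ["tab:orange" if d["sign"] == "positive" else "gray"
                      for _, _, d in g.edges(data=True)]
            widths = [4 * d["weight"] for _, _, d in g.edges(data=True)]
            nx.draw_networkx(g, pos, ax=ax, edge_color=colors, width=widths,
                             node_color="lightsteelblue")
            ax.axis("off")
            fig.tight_layout()
            fig.savefig(art / "fig_pleiotropy_network.png", dpi=120)
            plt.close(fig)

    lines.append(f"Total QTL: {n_qtl_total}")
    report = art / "report.txt"
    report.write_text("\n".join(lines))
    return report
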