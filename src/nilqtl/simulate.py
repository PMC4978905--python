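"""Simulation of BC4S2 maize-teosinte introgression populations.

Each near-isogenic line (NIL) descends from one F1 (recurrent x donor) plant
by four backcrosses to the recurrent parent and two generations of selfing.
Meiosis places crossovers as a Poisson process on the cM scale (no
interference), so recombination between loci follows the Haldane map function.
Expected per-locus donor-allele frequency at BC4S2 is 1/32 and the expected
heterozygote frequency after BC4 (before selfing) is 1/16.

Phenotypes follow a plot-level mixed model: population mean + planted-QTL
genotypic value + environment + line-by-environment interaction + replicate
within environment + residual, one record per line x environment x replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GeneticMap, GenotypeMatrix, load_dataset

#: kernel traits simulated directly; FFD and L/W are derived downstream
BASE_TRAITS = ("Wt50k", "area", "width", "length", "roundness", "perimeter")


@dataclass(frozen=True)
class PlantedQTL:
    """A causal locus with per-population additive effects.

    ``trait_effects`` maps trait name to either a scalar (shared across
    populations) or a length-``n_populations`` sequence; the value is the
    substitution effect per donor allele in trait units, so a dosage-2 line
    differs from dosage-0 by twice the effect.
    """

    chromosome: int
    position_cM: float
    trait_effects: Mapping[str, float | Sequence[float]]

    def effects_for(self, trait: str, n_populations: int) -> np.ndarray:
        e = self.trait_effects.get(trait, 0.0)
        arr = np.broadcast_to(np.asarray(e, float), (n_populations,)).copy()
        return arr


def _per_trait(value, traits: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {t: float(value.get(t, 0.0)) for t in traits}
    return {t: float(value) for t in traits}


@dataclass
class SimConfig:
    """Parameters of a simulated NIL study; the seed fully determines output."""

    n_populations: int = 10
    lines_per_population: int = 86
    n_backcross: int = 4
    n_self: int = 2
    chromosomes: Sequence[tuple[float, int]] = (
        # (length_cM, n_markers): ten chromosomes, 728 markers total,
        # lengths roughly following the maize consensus map
        (196.0, 98), (158.0, 79), (157.0, 79), (152.0, 76), (145.0, 73),
        (130.0, 65), (128.0, 64), (140.0, 70), (127.0, 64), (121.0, 60),
    )
    environments: int = 2
    reps_per_environment: int | Sequence[int] = (3, 2)
    traits: Sequence[str] = BASE_TRAITS
    trait_means: Mapping[str, float] = field(default_factory=dict)
    qtl: Sequence[PlantedQTL] = ()
    residual_sd: float | Mapping[str, float] = 1.0
    env_effect_sd: float | Mapping[str, float] = 0.5
    gxe_sd: float | Mapping[str, float] = 0.5
    rep_sd: float | Mapping[str, float] = 0.25
    pop_mean_sd: float | Mapping[str, float] = 0.5
    monomorphic_fraction: float = 0.24
    missing_rate: float = 0.0
    map_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_populations < 1 or self.lines_per_population < 1:
            raise ValueError("population and line counts must be >= 1")
        if self.n_backcross < 1 or self.n_self < 0:
            raise ValueError("need >= 1 backcross and >= 0 selfing generations")
        if len(self.chromosomes) == 0:
            raise ValueError("at least one chromosome required")
        for L, m in self.chromosomes:
            if L <= 0:
                raise ValueError("zero-length chromosome")
            if m < 2:
                raise ValueError("each chromosome needs >= 2 markers")
        if self.environments < 1:
            raise ValueError("need >= 1 environment")
        for r in self.rep_counts():
            if r < 1:
                raise ValueError("each environment needs >= 1 replicate")
        if not (0.0 <= self.monomorphic_fraction < 1.0):
            raise ValueError("monomorphic_fraction must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        traits = set(self.traits)
        for q in self.qtl:
            if not (1 <= q.chromosome <= len(self.chromosomes)):
                raise ValueError(f"QTL chromosome {q.chromosome} out of range")
            L = self.chromosomes[q.chromosome - 1][0]
            if not (0.0 <= q.position_cM <= L):
                raise ValueError(f"QTL position {q.position_cM} outside chromosome")
            extra = set(q.trait_effects) - traits
            if extra:
                raise ValueError(f"QTL effects reference unknown traits: {sorted(extra)}")
            if all(np.all(np.asarray(v) == 0) for v in q.trait_effects.values()):
                raise ValueError("planted QTL must have at least one nonzero effect")

    def rep_counts(self) -> list[int]:
        r = self.reps_per_environment
        if isinstance(r, (int, np.integer)):
            return [int(r)] * self.environments
        r = list(r)
        if len(r) != self.environments:
            raise ValueError("reps_per_environment length must match environments")
        return [int(x) for x in r]

    def trait_sd(self, which: str) -> dict[str, float]:
        return _per_trait(getattr(self, which), self.traits)


def default_config(seed: int = 0) -> SimConfig:
    """The study conditions the simulator emulates by default: 10 BC4S2
    populations of 86 lines in a shared recurrent background, 728 SNPs on 10
    chromosomes, 2 environments with 3+2 replicates, six measured kernel
    traits with shared (pleiotropic) and private QTL.

    Trait means/scales follow typical maize kernel values (Wt50k ~12.6 g,
    area ~58 mm^2, length ~11 mm, width ~6.5 mm); QTL effects are sized so a
    handful of loci produce heritabilities in the 0.7-0.95 range seen for
    such traits, with allelic series (mixed-sign population effects) at some
    loci and negatively pleiotropic shape effects through length/width.
    """
    rng = np.random.default_rng(seed)
    n_pop = 10

    def series(base: float, spread: float) -> np.ndarray:
        return base + spread * rng.normal(size=n_pop)

    qtl = [
        # size cluster on chr 1 (long arm): area/length/perimeter/Wt50k
        PlantedQTL(1, 150.0, {
            "area": series(-1.6, 0.5), "length": series(-0.18, 0.05),
            "perimeter": series(-0.5, 0.15), "Wt50k": series(-0.45, 0.12),
        }),
        # pericentromeric chr 5 cluster, strong pleiotropic size/weight QTL
        PlantedQTL(5, 70.0, {
            "area": series(-2.2, 0.4), "length": series(-0.22, 0.05),
            "perimeter": series(-0.65, 0.1), "Wt50k": series(-0.6, 0.1),
        }),
        # chr 8 size/weight QTL
        PlantedQTL(8, 60.0, {
            "area": series(-1.2, 0.6), "perimeter": series(-0.4, 0.2),
            "Wt50k": series(-0.35, 0.15), "length": series(-0.12, 0.06),
        }),
        # shape QTL: width down, roundness down -> L/W up (negative pleiotropy)
        PlantedQTL(2, 40.0, {
            "width": series(-0.12, 0.04), "roundness": series(-0.9, 0.3),
        }),
        PlantedQTL(4, 55.0, {
            "width": series(0.08, 0.05), "roundness": series(0.7, 0.35),
        }),
        # density (FFD enters via Wt50k vs area decoupling)
        PlantedQTL(2, 90.0, {"Wt50k": series(-0.3, 0.08)}),
        # allelic-series weight QTL on chr 3
        PlantedQTL(3, 80.0, {"Wt50k": series(0.0, 0.4)}),
        # private small QTL
        PlantedQTL(6, 50.0, {"length": series(-0.1, 0.04)}),
        PlantedQTL(7, 30.0, {"area": series(-0.8, 0.3)}),
    ]
    return SimConfig(
        trait_means={
            "Wt50k": 12.65, "area": 58.13, "width": 6.51,
            "length": 10.99, "roundness": 81.14, "perimeter": 32.10,
        },
        qtl=qtl,
        residual_sd={
            "Wt50k": 0.55, "area": 1.4, "width": 0.16,
            "length": 0.16, "roundness": 1.0, "perimeter": 0.45,
        },
        env_effect_sd={
            "Wt50k": 0.4, "area": 1.0, "width": 0.08,
            "length": 0.15, "roundness": 0.5, "perimeter": 0.4,
        },
        gxe_sd={
            "Wt50k": 0.25, "area": 0.6, "width": 0.06,
            "length": 0.07, "roundness": 0.45, "perimeter": 0.2,
        },
        rep_sd={
            "Wt50k": 0.15, "area": 0.4, "width": 0.03,
            "length": 0.05, "roundness": 0.2, "perimeter": 0.15,
        },
        pop_mean_sd={
            "Wt50k": 0.3, "area": 0.8, "width": 0.07,
            "length": 0.12, "roundness": 0.5, "perimeter": 0.25,
        },
        seed=seed,
    )


def simulate_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced markers per chromosome (optional uniform jitter)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for c, (L, m) in enumerate(config.chromosomes, start=1):
        pos = np.linspace(0.0, L, m)
        if config.map_jitter > 0:
            gap = L / (m - 1)
            jit = rng.uniform(-config.map_jitter, config.map_jitter, m) * gap
            jit[0] = jit[-1] = 0.0
            pos = np.sort(pos + jit)
            pos = np.maximum.accumulate(pos + np.arange(m) * 1e-9)
        for k, p in enumerate(pos):
            rows.append((f"c{c}m{k:03d}", c, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]))


def meiosis_gamete(hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray,
                   length_cM: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete for one chromosome.

    Crossovers fall as a Poisson process with rate 1 per 100 cM; the gamete
    copies from one parental haplotype and switches at each crossover.
    Evaluated at the given marker positions (exact at those loci).
    """
    n_xo = rng.poisson(length_cM / 100.0)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return (hap_a if start == 0 else hap_b).copy()
    xo = np.sort(rng.uniform(0.0, length_cM, n_xo))
    phase = (start + np.searchsorted(xo, positions, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b)


def _simulate_line(founder_donor: list[np.ndarray], positions: list[np.ndarray],
                   lengths: list[float], n_backcross: int, n_self: int,
                   rng: np.random.Generator) -> np.ndarray:
    """One BC(n)S(m) line; returns concatenated dosage across chromosomes."""
    dosages = []
    for hap_donor, pos, L in zip(founder_donor, positions, lengths):
        b73 = np.zeros_like(hap_donor)
        ind = (b73, hap_donor)  # F1
        for _ in range(n_backcross):
            gam = meiosis_gamete(ind[0], ind[1], pos, L, rng)
            ind = (b73, gam)
        for _ in range(n_self):
            g1 = meiosis_gamete(ind[0], ind[1], pos, L, rng)
            g2 = meiosis_gamete(ind[0], ind[1], pos, L, rng)
            ind = (g1, g2)
        dosages.append(ind[0] + ind[1])
    return np.concatenate(dosages)


def simulate_population_genotypes(config: SimConfig, gmap: GeneticMap) -> GenotypeMatrix:
    """Gamete-level simulation of all NIL populations.

    Per population, a fraction of markers (``monomorphic_fraction``) is forced
    monomorphic by fixing the donor founder allele to the recurrent state,
    emulating SNPs that do not segregate in that cross. ``missing_rate``
    masks random cells to NA to exercise imputation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lengths = [L for L, _ in config.chromosomes]
    positions = [gmap.positions(c) for c in gmap.chromosomes]
    n_mark = gmap.n_markers
    chrom_sizes = [len(p) for p in positions]

    line_ids, pops, rows = [], [], []
    for p in range(config.n_populations):
        pop = f"Z{p + 1:03d}"
        # per-population monomorphic markers: donor founder carries the
        # recurrent allele there, so the population cannot segregate
        mono = rng.random(n_mark) < config.monomorphic_fraction
        founder = []
        off = 0
        for sz in chrom_sizes:
            hap = np.ones(sz, dtype=np.int8)
            hap[mono[off:off + sz]] = 0
            founder.append(hap)
            off += sz
        for i in range(config.lines_per_population):
            line_ids.append(f"{pop}L{i + 1:03d}")
            pops.append(pop)
            rows.append(
                _simulate_line(founder, positions, lengths,
                               config.n_backcross, config.n_self, rng)
            )
    dosage = np.array(rows, dtype=float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    return GenotypeMatrix(np.array(line_ids), np.array(pops),
                          gmap.markers.copy(), dosage)


def qtl_marker_columns(config: SimConfig, gmap: GeneticMap) -> list[int]:
    """Map-column index of the marker nearest each planted QTL (snap rule)."""
    cols = []
    for q in config.qtl:
        idx = gmap.chrom_indices(q.chromosome)
        pos = gmap.positions(q.chromosome)
        cols.append(int(idx[np.argmin(np.abs(pos - q.position_cM))]))
    return cols


def genetic_values(config: SimConfig, geno: GenotypeMatrix,
                   gmap: GeneticMap) -> pd.DataFrame:
    """Per-line genotypic value for each trait from the planted QTL.

    Contribution of QTL q in population p: effect[p] * dosage at the marker
    nearest the planted position.
    """
    pops = pd.unique(geno.populations)
    pop_idx = pd.Series(np.arange(len(pops)), index=pops)
    pcode = pop_idx[geno.populations].to_numpy()
    cols = qtl_marker_columns(config, gmap)
    g = {t: np.zeros(geno.n_lines) for t in config.traits}
    for q, col in zip(config.qtl, cols):
        d = geno.dosage[:, col]
        for t in q.trait_effects:
            eff = q.effects_for(t, config.n_populations)
            g[t] += eff[pcode] * d
    out = pd.DataFrame(g)
    out.insert(0, "population", geno.populations)
    out.insert(0, "line_id", geno.line_ids)
    return out


def simulate_phenotypes(config: SimConfig, geno: GenotypeMatrix,
                        gmap: GeneticMap) -> pd.DataFrame:
    """Plot-level phenotypes: one record per line x environment x replicate."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    traits = list(config.traits)
    gv = genetic_values(config, geno, gmap)
    pops = pd.unique(geno.populations)
    reps = config.rep_counts()

    means = {t: float(config.trait_means.get(t, 0.0)) for t in traits}
    res_sd = config.trait_sd("residual_sd")
    env_sd = config.trait_sd("env_effect_sd")
    gxe_sd = config.trait_sd("gxe_sd")
    rep_sd = config.trait_sd("rep_sd")
    pop_sd = config.trait_sd("pop_mean_sd")

    pop_off = {t: dict(zip(pops, pop_sd[t] * rng.normal(size=len(pops))))
               for t in traits}
    env_eff = {t: env_sd[t] * rng.normal(size=config.environments) for t in traits}
    rep_eff = {t: [rep_sd[t] * rng.normal(size=r) for r in reps] for t in traits}
    gxe = {t: gxe_sd[t] * rng.normal(size=(geno.n_lines, config.environments))
           for t in traits}

    records = []
    for j in range(config.environments):
        for k in range(reps[j]):
            block = {
                "line_id": geno.line_ids,
                "population": geno.populations,
                "environment": np.repeat(f"env{j + 1}", geno.n_lines),
                "replicate": np.repeat(k + 1, geno.n_lines),
            }
            for t in traits:
                noise = res_sd[t] * rng.normal(size=geno.n_lines)
                popvec = pd.Series(pop_off[t])[geno.populations].to_numpy()
                block[t] = (
                    means[t] + popvec + gv[t].to_numpy()
                    + env_eff[t][j] + gxe[t][:, j] + rep_eff[t][j][k] + noise
                )
            records.append(pd.DataFrame(block))
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["environment", "replicate", "line_id"],
                           kind="mergesort").reset_index(drop=True)


def planted_heritability(config: SimConfig, geno: GenotypeMatrix,
                         gmap: GeneticMap, trait: str) -> float:
    """Realized entry-mean heritability implied by the planted architecture:
    H2 = var(g) / (var(g) + s2_GxE/E + s2_err/(E*R~)) with R~ the harmonic
    mean of replicates per environment and var(g) the realized variance of
    genotypic values (QTL only; population offsets are part of the line term
    in mapping but are excluded here to describe within-study genetic signal
    including between-population differences, they are added when pop_mean_sd
    is nonzero via the offsets' expected variance).
    """
    gv = genetic_values(config, geno, gmap)[trait].to_numpy()
    var_g = float(np.var(gv, ddof=1)) + config.trait_sd("pop_mean_sd")[trait] ** 2
    E = config.environments
    reps = config.rep_counts()
    r_h = len(reps) / sum(1.0 / r for r in reps)
    s_gxe = config.trait_sd("gxe_sd")[trait] ** 2
    s_err = config.trait_sd("residual_sd")[trait] ** 2
    return var_g / (var_g + s_gxe / E + s_err / (E * r_h))


def write_dataset(geno: GenotypeMatrix, gmap: GeneticMap,
                  pheno: pd.DataFrame, outdir) -> dict[str, Path]:
    """Write genotype TSV, map TSV and phenotype CSV; round-trips through
    :func:`nilqtl.genotypes.load_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "map": outdir / "map.tsv",
        "phenotypes": outdir / "phenotypes.csv",
    }
    geno.to_tsv(paths["genotypes"])
    gmap.to_tsv(paths["map"])
    pheno.to_csv(paths["phenotypes"], index=False)
    return paths


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, GeneticMap, pd.DataFrame]:
    """Convenience: map + genotypes + phenotypes in one call."""
    gmap = simulate_map(config)
    geno = simulate_population_genotypes(config, gmap)
    pheno = simulate_phenotypes(config, geno, gmap)
    return geno, gmap, pheno
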