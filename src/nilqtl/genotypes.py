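"""Genotype containers, I/O, flanking-marker imputation and pseudomarker dosages.

Genotypes are dosages of the donor (teosinte) allele relative to the recurrent
parent (B73): 0 = homozygous B73, 1 = heterozygous, 2 = homozygous donor.
After imputation, cells may hold fractional expected dosages in [0, 2].

The imputation and pseudomarker rules assume donor ancestry along a chromosome
behaves as a two-state Markov chain with Haldane (no-interference) transition
probabilities, which is exact for the crossover process used by the simulator
and a good approximation for real BC-derived introgression lines whose donor
genome sits in long blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CALLS = {"0", "1", "2", "NA"}


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM under the Haldane map
    function, r = (1 - exp(-2d))/2 with d in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions (cM) on 1-based chromosomes.

    ``table`` has columns ``marker``, ``chrom``, ``pos_cM`` sorted by
    (chrom, pos_cM); positions are strictly increasing within a chromosome and
    marker names are unique genome-wide.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["marker", "chrom", "pos_cM"]
        if list(t.columns[:3]) != required:
            raise ValueError(f"map table must have columns {required}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name in map: {dup!r}")
        for c, sub in t.groupby("chrom"):
            pos = sub["pos_cM"].to_numpy(float)
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chrom"].unique().tolist())

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Column indices (into map order) of the markers on ``chrom``."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def positions(self, chrom: int) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_cM"].to_numpy(float)

    def span(self, chrom: int) -> tuple[float, float]:
        pos = self.positions(chrom)
        if pos.size == 0:
            raise KeyError(f"no such chromosome: {chrom}")
        return float(pos[0]), float(pos[-1])

    def marker_index(self, marker: str) -> int:
        idx = np.flatnonzero(self.markers == marker)
        if idx.size == 0:
            raise KeyError(f"unknown marker: {marker}")
        return int(idx[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t")
        t["chrom"] = t["chrom"].astype(int)
        t["pos_cM"] = t["pos_cM"].astype(float)
        t = t.sort_values(["chrom", "pos_cM"], kind="mergesort")
        return cls(t[["marker", "chrom", "pos_cM"]])


@dataclass
class GenotypeMatrix:
    """Line x marker donor-allele dosages with population labels.

    ``dosage`` is float (NaN = missing); columns follow the map order of the
    accompanying :class:`GeneticMap`. ``imputed_mask`` is set by the imputer.
    """

    line_ids: np.ndarray
    populations: np.ndarray
    markers: np.ndarray
    dosage: np.ndarray
    imputed_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids)
        self.populations = np.asarray(self.populations)
        self.markers = np.asarray(self.markers)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.line_ids) != n or len(self.populations) != n:
            raise ValueError("line_ids/populations length mismatch with dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker count mismatch with dosage columns")
        if len(set(self.line_ids.tolist())) != n:
            raise ValueError("duplicate line ids")

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def population_list(self) -> list[str]:
        """Populations in order of first appearance."""
        return list(pd.unique(self.populations))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.line_ids.copy(),
            self.populations.copy(),
            self.markers.copy(),
            self.dosage.copy(),
            None if self.imputed_mask is None else self.imputed_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=self.markers)
        df.insert(0, "population", self.populations)
        df.insert(0, "line_id", self.line_ids)
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        # integer-looking values written without decimals, NaN as NA
        geno = df.iloc[:, 2:]
        as_obj = geno.copy().astype(object)
        intish = np.isclose(geno.to_numpy(float) % 1, 0)
        vals = geno.to_numpy(float)
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                v = vals[i, j]
                if np.isnan(v):
                    as_obj.iloc[i, j] = "NA"
                elif intish[i, j]:
                    as_obj.iloc[i, j] = str(int(round(v)))
                else:
                    as_obj.iloc[i, j] = repr(float(v))
        out = pd.concat([df.iloc[:, :2], as_obj], axis=1)
        out.to_csv(path, sep="\t", index=False)


def load_dataset(genotype_path, map_path,
                 allow_fractional: bool = False) -> tuple[GenotypeMatrix, GeneticMap]:
    """Read a genotype TSV and map TSV, reordering markers to map order.

    Raises ``ValueError`` on markers absent from the map, map markers absent
    from the genotype file, or cells outside {0, 1, 2, NA}. With
    ``allow_fractional`` (for re-reading imputed matrices), any numeric value
    in [0, 2] is accepted.
    """
    gmap = GeneticMap.from_tsv(map_path)
    raw = pd.read_csv(genotype_path, sep="\t", dtype=str, keep_default_na=False)
    if list(raw.columns[:2]) != ["line_id", "population"]:
        raise ValueError("genotype file must start with columns line_id, population")
    file_markers = list(raw.columns[2:])
    map_markers = set(gmap.markers.tolist())
    unknown = [m for m in file_markers if m not in map_markers]
    if unknown:
        raise ValueError(f"markers not in map: {unknown[:5]}")
    missing = map_markers - set(file_markers)
    if missing:
        raise ValueError(f"map markers absent from genotype file: {sorted(missing)[:5]}")

    cells = raw[list(gmap.markers)].to_numpy(dtype=str)
    bad = ~np.isin(cells, list(VALID_CALLS))
    if bad.any() and not allow_fractional:
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype value {str(cells[i, j])!r} for line "
            f"{raw['line_id'].iloc[i]!r} at marker {str(gmap.markers[j])!r}"
        )
    try:
        dosage = np.where(cells == "NA", "nan", cells).astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric genotype cell: {exc}") from exc
    with np.errstate(invalid="ignore"):
        out_of_range = np.nan_to_num(dosage, nan=1.0)
    if ((out_of_range < 0) | (out_of_range > 2)).any():
        raise ValueError("genotype dosages must lie in [0, 2]")
    return (
        GenotypeMatrix(
            raw["line_id"].to_numpy(),
            raw["population"].to_numpy(),
            gmap.markers.copy(),
            dosage,
        ),
        gmap,
    )


def _markov_donor_prob(a_left: np.ndarray, a_right: np.ndarray,
                       d_left: float, d_right: float) -> np.ndarray:
    """P(donor allele at the query locus) per gamete, given donor-allele
    probabilities at the flanking loci and Haldane transitions.

    ``a_left``/``a_right`` are haplotype donor probabilities in [0,1] (0 or 1
    for called homozygotes, 0.5 per gamete for a heterozygous flank, fractional
    after imputation). The two flanks bracket the query at map distances
    ``d_left`` and ``d_right`` (cM).
    """
    rl = float(haldane_r(d_left))
    rr = float(haldane_r(d_right))
    rlr = float(haldane_r(d_left + d_right))
    # w[a,b] = P(query donor | left state a, right state b)

    def w(a: int, b: int) -> float:
        pl = (1 - rl) if a == 1 else rl          # P(left a -> query donor)
        pr = (1 - rr) if b == 1 else rr          # P(query donor -> right b)
        denom = (1 - rlr) if a == b else rlr     # P(left a -> right b)
        if denom <= 0:
            return 0.5
        return pl * pr / denom

    aL = np.asarray(a_left, float)
    aR = np.asarray(a_right, float)
    return (
        w(1, 1) * aL * aR
        + w(1, 0) * aL * (1 - aR)
        + w(0, 1) * (1 - aL) * aR
        + w(0, 0) * (1 - aL) * (1 - aR)
    )


def _expected_dosage(gl: np.ndarray, gr: np.ndarray,
                     d_left: float, d_right: float) -> np.ndarray:
    """E[dosage] at a locus between two flanking genotypes (per line).

    The two gametes of a line are treated as independent with per-gamete donor
    probability g/2 at each flank.
    """
    gl = np.asarray(gl, float)
    gr = np.asarray(gr, float)
    p = _markov_donor_prob(gl / 2.0, gr / 2.0, d_left, d_right)
    # agreement rule: equal flanks pass through exactly (dominant case of
    # long introgression blocks); the expectation is used only when they differ
    return np.where(gl == gr, gl, 2.0 * p)


class FlankingImputer:
    """Fill missing genotype calls from the nearest flanking markers.

    Rules, applied per line and chromosome:

    * nearest non-missing flanks agree -> that value (``"agree"``);
    * flanks disagree -> expected dosage under Haldane two-state transition
      probabilities given the flanking distances (``"expect"``);
    * no flank on one side (chromosome end) -> copy the nearest non-missing
      value (``"edge"``).

    A line with an entirely missing chromosome is left missing with a warning.

    Parameters
    ----------
    gmap : GeneticMap
        Map providing marker order and cM positions.

    Attributes
    ----------
    imputed_mask_ : bool ndarray, lines x markers
        True where a value was filled in by :meth:`transform`.
    audit_ : pandas.DataFrame
        One row per imputed cell: line_id, marker, imputed_value, rule.
    """

    def __init__(self, gmap: GeneticMap):
        self.gmap = gmap

    def get_params(self, deep: bool = True) -> dict:
        return {"gmap": self.gmap}

    def set_params(self, **params) -> "FlankingImputer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, geno: GenotypeMatrix, y=None) -> "FlankingImputer":
        return self

    def transform(self, geno: GenotypeMatrix) -> GenotypeMatrix:
        out = geno.copy()
        dosage = out.dosage
        mask = np.zeros_like(dosage, dtype=bool)
        audit_rows: list[tuple] = []
        for chrom in self.gmap.chromosomes:
            cols = self.gmap.chrom_indices(chrom)
            pos = self.gmap.positions(chrom)
            sub = dosage[:, cols]
            miss = np.isnan(sub)
            if not miss.any():
                continue
            for i in np.flatnonzero(miss.any(axis=1)):
                row = sub[i]
                obs = np.flatnonzero(~np.isnan(row))
                if obs.size == 0:
                    warnings.warn(
                        f"line {out.line_ids[i]!r}: chromosome {chrom} entirely "
                        "missing; left unimputed"
                    )
                    continue
                for j in np.flatnonzero(np.isnan(row)):
                    k = np.searchsorted(obs, j)
                    left = obs[k - 1] if k > 0 else None
                    right = obs[k] if k < obs.size else None
                    if left is None:
                        val, rule = row[right], "edge"
                    elif right is None:
                        val, rule = row[left], "edge"
                    elif row[left] == row[right]:
                        val, rule = row[left], "agree"
                    else:
                        val = float(
                            _expected_dosage(
                                row[left], row[right],
                                pos[j] - pos[left], pos[right] - pos[j],
                            )
                        )
                        rule = "expect"
                    dosage[i, cols[j]] = val
                    mask[i, cols[j]] = True
                    audit_rows.append(
                        (out.line_ids[i], self.gmap.markers[cols[j]], float(val), rule)
                    )
        out.imputed_mask = mask
        self.imputed_mask_ = mask
        self.audit_ = pd.DataFrame(
            audit_rows, columns=["line_id", "marker", "imputed_value", "rule"]
        )
        return out

    def fit_transform(self, geno: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(geno).transform(geno)


def impute_flanking(geno: GenotypeMatrix, gmap: GeneticMap) -> GenotypeMatrix:
    """Functional wrapper around :class:`FlankingImputer`."""
    return FlankingImputer(gmap).fit_transform(geno)


def polymorphic_mask(geno: GenotypeMatrix, tol: float = 1e-9) -> pd.DataFrame:
    """Population x marker boolean mask: True where the population shows dosage
    variation (> tol) at the marker.

    Monomorphic (population, marker) cells carry no introgression information
    and are excluded from nested-marker tests downstream.
    """
    pops = geno.population_list
    rows = []
    for p in pops:
        sub = geno.dosage[geno.populations == p]
        with np.errstate(invalid="ignore"):
            rng = np.nanmax(sub, axis=0) - np.nanmin(sub, axis=0)
        rows.append(np.nan_to_num(rng, nan=0.0) > tol)
    return pd.DataFrame(np.vstack(rows), index=pops, columns=geno.markers)


def expected_dosage_at(geno: GenotypeMatrix, gmap: GeneticMap,
                       chrom: int, pos_cM: float) -> np.ndarray:
    """Per-line expected donor dosage at an arbitrary cM position.

    At an observed marker the observed column is returned exactly; between
    markers the flanking-marker conditional expectation is used (same rule as
    imputation). Requires a complete (imputed) matrix.
    """
    cols = gmap.chrom_indices(chrom)
    if cols.size == 0:
        raise KeyError(f"no such chromosome: {chrom}")
    pos = gmap.positions(chrom)
    if pos_cM < pos[0] - 1e-9 or pos_cM > pos[-1] + 1e-9:
        raise ValueError(
            f"position {pos_cM} cM outside chromosome {chrom} span "
            f"[{pos[0]}, {pos[-1]}]"
        )
    j = int(np.argmin(np.abs(pos - pos_cM)))
    if abs(pos[j] - pos_cM) < 1e-9:
        return geno.dosage[:, cols[j]].copy()
    right = int(np.searchsorted(pos, pos_cM))
    left = right - 1
    gl = geno.dosage[:, cols[left]]
    gr = geno.dosage[:, cols[right]]
    if np.isnan(gl).any() or np.isnan(gr).any():
        raise ValueError("expected_dosage_at requires an imputed (complete) matrix")
    return _expected_dosage(gl, gr, pos_cM - pos[left], pos[right] - pos_cM)
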